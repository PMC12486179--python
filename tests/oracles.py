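"""Independent brute-force oracles used to freeze expected values.

These deliberately avoid the code paths they check: the ball-fit filter
enumerates structuring-element offsets and array shifts directly, the
Euler characteristic counts cells of the cubical complex, and the local
thickness oracle tests every (voxel, candidate sphere centre) pair.
"""

from __future__ import annotations

import numpy as np


def ball_offsets(radius_mm: float, spacing) -> np.ndarray:
    """Integer offsets whose physical distance is <= radius (same discrete
    ball definition as the implementation, built independently)."""
    spacing = np.asarray(spacing, dtype=float)
    half = np.round(radius_mm / spacing).astype(int)
    offs = []
    for i in range(-half[0], half[0] + 1):
        for j in range(-half[1], half[1] + 1):
            for k in range(-half[2], half[2] + 1):
                d2 = (i * spacing[0]) ** 2 + (j * spacing[1]) ** 2 + (k * spacing[2]) ** 2
                if d2 <= radius_mm**2 + 1e-9:
                    offs.append((i, j, k))
    return np.array(offs, dtype=int)


def brute_force_ball_fit(mask: np.ndarray, radius_mm: float, spacing,
                         iterations: int = 1) -> np.ndarray:
    """Voxels at which the discrete ball fits inside the mask, ``iterations``
    times over (iterated erosion by shifting; out-of-bounds = background)."""
    offs = ball_offsets(radius_mm, spacing)
    current = np.asarray(mask, dtype=bool)
    shape = np.array(mask.shape)
    for _ in range(iterations):
        fits = np.ones_like(current)
        for off in offs:
            shifted = np.zeros_like(current)
            src = [slice(max(o, 0), int(s) + min(o, 0)) for o, s in zip(off, shape)]
            dst = [slice(max(-o, 0), int(s) + min(-o, 0)) for o, s in zip(off, shape)]
            shifted[tuple(dst)] = current[tuple(src)]
            fits &= shifted
        current = fits
    return current


def brute_force_size_filter(mask: np.ndarray, min_diameter: float, step: float,
                            spacing) -> np.ndarray:
    """Largest-inscribed-sphere component filter: keep every connected
    component (26-connectivity) containing a voxel where the iterated step
    ball fits; restore kept components fully."""
    from scipy import ndimage  # labelling only; the filter logic is local

    k = int(round(min_diameter / (2.0 * step)))
    survivors = brute_force_ball_fit(mask, step, spacing, iterations=k)
    labels, n = ndimage.label(mask, structure=np.ones((3, 3, 3), dtype=bool))
    out = np.zeros_like(np.asarray(mask, dtype=bool))
    for lab in range(1, n + 1):
        comp = labels == lab
        if (comp & survivors).any():
            out |= comp
    return out


def euler_characteristic_cubical(mask: np.ndarray) -> int:
    """chi = V - E + F - C of the closed cubical complex of the occupied
    voxels (equivalent to foreground 26-connectivity)."""
    m = np.asarray(mask, dtype=bool)
    # vertices: corner (i,j,k) exists if any of the up-to-8 incident voxels
    # is occupied; pad so every corner is interior to the padded grid
    p = np.pad(m, 1, mode="constant")

    def union_shifts(arr, axes):
        """OR of arr over all 0/1 shifts along the given axes."""
        out = np.zeros(tuple(s + 1 for s in arr.shape), dtype=bool)
        shifts = [(0, 1) if ax in axes else (0,) for ax in range(3)]
        for dx in shifts[0]:
            for dy in shifts[1]:
                for dz in shifts[2]:
                    out[dx:arr.shape[0] + dx, dy:arr.shape[1] + dy,
                        dz:arr.shape[2] + dz] |= arr
        # restrict to the corner lattice of the original array
        return out

    v = int(union_shifts(p, axes=(0, 1, 2)).sum())
    e = sum(int(union_shifts(p, axes=tuple(a for a in range(3) if a != ax)).sum())
            for ax in range(3))
    f = sum(int(union_shifts(p, axes=(ax,)).sum()) for ax in range(3))
    c = int(p.sum())
    return v - e + f - c


def brute_force_local_thickness(mask: np.ndarray, spacing) -> np.ndarray:
    """Per-voxel diameter of the largest sphere inscribed in the mask that
    covers the voxel, by trying every candidate centre (O(n^2); <= 32^3)."""
    m = np.asarray(mask, dtype=bool)
    spacing = np.asarray(spacing, dtype=float)
    from scipy import ndimage

    edt = ndimage.distance_transform_edt(m, sampling=spacing)
    centres = np.argwhere(m)
    radii = edt[m]
    out = np.zeros(m.shape, dtype=float)
    targets = np.argwhere(m)
    tw = targets * spacing
    cw = centres * spacing
    for t_i, t in enumerate(targets):
        d = np.sqrt(((cw - tw[t_i]) ** 2).sum(axis=1))
        covered = radii >= d - 1e-9
        if covered.any():
            out[tuple(t)] = 2.0 * radii[covered].max()
    return out


def sphere_mask(shape, centre_vox, radius_mm, spacing) -> np.ndarray:
    g = np.indices(shape).astype(float)
    d2 = sum(((g[a] - centre_vox[a]) * spacing[a]) ** 2 for a in range(3))
    return d2 <= radius_mm**2
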