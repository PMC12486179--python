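# cysthead

Quantitative analysis of cystic lesions in the femoral head from
volumetric micro-CT, for researchers studying subchondral bone cysts in
osteoarthritis (OA) and osteonecrosis of the femoral head (ONFH).

Subchondral cysts — interior voids more than 1 mm in inscribed diameter —
differ between the two diseases in size, spatial distribution across the
head, and the remodelling state of the surrounding trabecular bone.
`cysthead` re-implements the full specimen analysis chain as a tested,
reusable library:

* **Cyst extraction** (`cysthead.cystdetect`): binarize bone with a fixed
  8-bit window (90–255), build the filled head envelope, subtract bone to
  get the empty space, then remove every void whose largest inscribed
  sphere is under 1 mm by *opening by reconstruction* — incremental 3D
  erosion in 0.5 mm steps followed by geodesic restoration of the
  survivors to their exact original shape.  Reported per head:
  Cyst.N, Cyst.V, CystV.Ave, CystV.Min, CystV.Max.
* **Six-region segmentation** (`cysthead.headseg`): a reference plane
  through the head, fovea and neck/calcar centres splits the head into
  anterior/posterior hemispheres; two planes parallel to the main
  trabeculae direction (MTD) cut lateral/central/medial pillars at
  30 % / 40 % / 30 % of the head width.  Each cyst is assigned to the
  region holding its largest overlap fraction.
* **Peri-cyst morphometry** (`cysthead.microarch`): on the Cys-Tb shell
  (trabecular bone within 0.5 mm of the cyst surface), the standard
  panel — BV/TV (%), BS/BV (1/mm), Tb.Th and Tb.Sp (μm, inscribed-sphere
  local thickness), Tb.N = 1/(Tb.Th+Tb.Sp) (1/mm), SMI (surface-dilation
  definition, 6·V·S′/S²), DA (mean-intercept-length fabric, longest over
  shortest axis), and Conn.D = (1 − χ)/TV (1/mm³).
* **2D histomorphometry** (`cysthead.histo2d`): osteoid (O.Th, OV/BV,
  OS/BS, OS/BV) and eroded-surface (ES/BS, ES/BV, ES/TV) panels on
  labelled undecalcified sections, plus Weidner microvessel density.
* **Group statistics** (`cysthead.groupstats`): the cohort-study decision
  tree — Kolmogorov–Smirnov (Lilliefors) normality routing into a pooled
  t-test or Mann–Whitney U, and the chi-squared family for categorical
  baseline variables.
* **Synthetic phantoms** (`cysthead.phantom`): femoral-head volumes with a
  thresholded Gaussian-random-field trabecular texture, cortical shell,
  rim-sealed spherical cysts and full ground truth, so every stage is
  testable without any scan data.

## Worked example

```python
import numpy as np
from cysthead import phantom, cystdetect, headseg, microarch

spec = phantom.PhantomSpec(
    head_radius=8.0, voxel_size=0.15,
    cyst_specs=[phantom.CystSpec((0.0, 2.5, 2.0), 3.0),
                phantom.CystSpec((4.0, -1.5, -1.0), 2.0),
                phantom.CystSpec((-4.2, 1.5, 0.0), 1.5)],
    seed=7)
volume, truth = phantom.generate_head(spec)

labels, records, s = cystdetect.detect_cysts(volume)
print(s.cyst_n, round(s.cyst_v, 2))          # 3 20.05

bone = cystdetect.binarize_bone(volume)
total = cystdetect.total_region(bone)
regions, geom = headseg.segment_regions(total, truth.landmarks)
headseg.apply_region_assignment(
    records, headseg.assign_cyst_region(labels, regions))
for r in records:
    print(f"cyst {r.id}: V={r.volume:.2f} mm3  region {r.region} "
          f"({r.pillar}, {r.hemisphere})")
```

```
cyst 1: V=1.71 mm3  region I (lateral, anterior)
cyst 2: V=14.15 mm3  region II (central, anterior)
cyst 3: V=4.19 mm3  region VI (medial, posterior)
```

All three carved cysts are recovered (the detected volumes sit within a
few percent of the analytic sphere volumes 14.14, 4.19 and 1.77 mm³) and
each is assigned to the pillar and hemisphere containing its centre.  The
peri-cyst trabecular panel for the largest cyst:

```python
cyst_mask = labels.like(np.asarray(labels.values) == 2)
roi = microarch.cys_tb_shell(cyst_mask, 0.5, total)
panel = microarch.compute_panel(bone, roi, total=total, seed=7)
print(panel.as_dict())
```

```
{'bv_tv': 79.89, 'bs_bv': 5.197, 'tb_th': 609.2, 'tb_sp': 415.5,
 'tb_n': 0.976, 'smi': 0.21, 'da': 1.203, 'conn_d': -0.113}
```

The shell is dominated by the sclerotic rim sealing the phantom cyst,
hence the high bone fraction and the plate-like (near-zero) SMI.

A command-line interface wraps the same stages:

```bash
cysthead run --config run.yaml        # full pipeline from a YAML config
cysthead phantom --out demo/ --cyst "0,2.5,2,3.0" --seed 7
cysthead detect --volume demo/phantom.nii.gz --out demo/out
cysthead segment --volume v.nii.gz --landmarks lm.json --out regions.nii.gz
cysthead morpho --bone bone.nii.gz --cysts labels.nii.gz --out morpho.csv
cysthead stats --table cohort.csv --out table1.csv
```

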