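# mucoshell

Radiotherapy dose to the oral mucosa is conventionally reported on a solid
oral-cavity contour (OCC) that lumps the mucosal lining together with the
musculature of the tongue and floor of mouth. Because acute mucositis is a
surface toxicity, `mucoshell` instead characterises the dose on a **mucosal
surface contour (MSC)**: a 3 mm-thick wall of tissue following the actual
mucosal surfaces, the thickness motivated by cadaveric measurements of oral
mucosal thickness (3.12 ± 1.43 mm). The package provides, for physicists and
dose–response modellers:

* **Structure construction** — expansion of a clinician-delineated thin
  mucosal sheet into the 3 mm MSC wall, and derivation of an "OCC surface"
  (the 3 mm annulus extending inward from the outer surface of the solid
  contour) for geometry comparisons. All morphology uses Euclidean distance
  transforms in millimetres, so anisotropic voxels are handled exactly.
* **Dosimetry** — conversion of physical dose *D* delivered in *n* fractions
  to the equivalent dose in 2 Gy fractions under the linear-quadratic model,

      EQD2 = D · (d + α/β) / (2 + α/β),   d = D/n,   α/β = 10 Gy,

  cumulative relative dose–volume histograms (DVH), mean and maximum EQD2
  with the maximum's world-coordinate location.
* **Cohort comparison** — per-patient percent reduction of the mean mucosal
  dose, 100·(mean_OCC − mean_MSC)/mean_OCC, with cohort median and range, and
  median DVH curves with min–max range envelopes.
* **A seeded synthetic phantom** — an oral-cavity-like ellipsoid with an
  interior tongue, its mucosal lining sheet, an overlapping spherical PTV and
  a medially concentrated dose distribution, so the whole pipeline runs
  without any patient data.

Volumes are NIfTI (`.nii`/`.nii.gz`, axis-aligned grids only), reports are
CSV, configuration is YAML.

## Worked example

```python
from mucoshell import (PhantomSpec, generate_phantom, build_patient_comparison)

case = generate_phantom(PhantomSpec())          # default 1 mm phantom, seed 0
c = build_patient_comparison(case.occ_solid, case.msc_truth, case.ptv,
                             case.dose, case.scheme)
print(f"OCC volume  {c.vol_occ_cm3:6.1f} cm^3   MSC volume {c.vol_msc_cm3:5.1f} cm^3 "
      f"  OCC-surface {c.vol_occ_surface_cm3:5.1f} cm^3")
print(f"mean EQD2   OCC {c.mean_occ_gy:5.2f} Gy   MSC {c.mean_msc_gy:5.2f} Gy "
      f"  reduction {c.reduction_pct:5.2f} %")
print(f"OCC max {c.occ_max_gy:5.2f} Gy   in PTV: {c.occ_max_in_ptv} "
      f"  in MSC: {c.occ_max_in_msc}")
```

prints

```
OCC volume   197.8 cm^3   MSC volume  64.9 cm^3   OCC-surface  44.7 cm^3
mean EQD2   OCC 35.88 Gy   MSC 26.72 Gy   reduction 25.52 %
OCC max 69.79 Gy   in PTV: True   in MSC: False
```

i.e. the solid contour is three times the volume of the mucosal shell (the
difference being mostly tongue musculature), switching to the shell lowers
the reported mean mucosal EQD2 by about a quarter, and the plan maximum sits
in deep muscle inside the PTV — a region the shell deliberately excludes.

The same pipeline is available from the shell:

```sh
mucoshell phantom --seed 0 --out-dir case0/
mucoshell shell --sheet case0/sheet.nii.gz --thickness 3.0 --out case0/msc.nii.gz
mucoshell occ-surface --solid case0/occ.nii.gz --out case0/occ_surface.nii.gz
mucoshell metrics --dose case0/dose.nii.gz --fractions 30 \
    --structures case0/occ.nii.gz --structures case0/msc.nii.gz \
    --ptv case0/ptv.nii.gz --out metrics.csv --dvh-out dvh.csv
mucoshell compare --cohort cohort.yaml --out summary.csv --dvh-out cohort_dvh.csv
```

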