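# Methods

## Geometric conventions

All geometry lives on axis-aligned regular voxel grids in world millimetres
(x left–right, y anterior–posterior, z inferior–superior). The centre of
voxel (i, j, k) is `origin + (i, j, k)·spacing` with 0-based indices. A voxel
belongs to a structure iff its centre does; volumes are occupied-voxel counts
times the voxel volume, with no partial-volume weighting. This single rule
makes every volume exactly computable and its discretisation error
quantifiable by the resolution-convergence tests. Oblique NIfTI affines are
rejected rather than resampled (axes stored with a negative step are flipped
on read), so file round-trips are exact: masks bit-exactly, dose to float32
precision.

## Shell constructions

Both bespoke structures are built from Euclidean distance transforms computed
in millimetres with the grid spacing as sampling, never from voxel-count
structuring elements; this behaves correctly on anisotropic grids and
converges to analytic volumes as spacing shrinks. A distance exactly equal to
a threshold counts as inside (ties inclusive, stated once).

* **Sheet → wall (MSC).** The mucosal lining arrives as a thin delineated
  sheet; the wall is every voxel whose centre lies within `thickness/2`
  (default total thickness 3 mm) of a sheet-voxel centre. The expansion is
  symmetric about the sheet, keeping the clinician's line at the wall's
  mid-surface: the delineation marks the visible mucosal surface and the
  tissue extends to either side of that surface estimate. A one-sided
  variant (full-thickness expansion clipped to a side mask) is exposed for
  workflows that treat the line as the outer mucosal boundary.
* **Solid → inward annulus (OCC surface).** The annulus keeps the voxels of
  the solid whose distance to the nearest exterior voxel centre is at most
  the thickness — the solid minus its mm-accurate erosion. Exterior includes
  the region beyond the grid bounding box, so a solid touching the grid edge
  still receives a wall there. 3-D Euclidean distance is used throughout
  (not slice-wise 2-D contraction).

**Digitisation bias worth knowing about.** With voxel-centre membership and
inclusive ties, a sheet expanded by t/2 has digital thickness
`(2·floor(t/2h)+1)·h` for through-wall spacing h. When t/(2h) is an integer
(e.g. t = 3 mm at h = 0.5 mm) this is t + h — one extra layer per side — so a
3 mm wall digitises to 3.5 mm and a 20×20 mm sheet yields 1400 mm³ rather
than 1200 mm³. When t/(2h) is half-integral (h = 0.2 mm) the digital
thickness is exactly t. The analytic-oracle tests therefore probe the slab at
0.2 mm through-wall sampling and additionally freeze the coarse-spacing
digital values (1400 mm³ at 0.5 mm; the 19-voxel digital ball of radius
1.5 mm at 1 mm) as regression facts. The sphere annulus has no such parity
trap: at 0.5 mm spacing its volume is within 2% of the closed form
(4/3)π(30³−27³).

## Dosimetry

Physical dose D delivered in n fractions is converted per voxel to the
equivalent dose in 2 Gy fractions, `EQD2 = D·(d + α/β)/(2 + α/β)` with
d = D/n varying voxel by voxel and a single plan-level n. The default
α/β = 10 Gy is the conventional acute-tissue value; 2 Gy per fraction is a
fixed point of the conversion. Dose is sampled at structure voxel centres:
directly when grids coincide, trilinearly otherwise (dose is smooth; masks
are never interpolated — they are resampled nearest-neighbour). DVHs are
cumulative and relative ("volume receiving at least D", in percent) on a
fixed axis of 0.1 Gy bins by default — fine enough that binning error
(bounded by one bin width on the implied mean) is negligible. Maximum-dose
locations are reported in world mm; ties resolve to the lexicographically
smallest voxel index, for determinism. Cohort DVH statistics (pointwise
median and min–max envelope) re-evaluate each patient's curve on a shared
axis; curves carry their samples, so re-evaluation is exact rather than
interpolated.

The per-patient comparison pairs the MSC against the full solid OCC (the
clinically reported structure); the OCC-surface annulus enters the geometry
comparison only. Percent reductions are computed on EQD2 means by default,
with physical-dose means available as an option.

## The synthetic phantom

The phantom emulates the geometry that drives the OCC-vs-MSC contrast, not a
CT image. Defaults (all overridable):

| parameter | default | meaning |
|---|---|---|
| spacing | 1 mm isotropic | grid resolution (≤ 2 mm so a 3 mm wall resolves) |
| extent | 120×120×100 mm | grid size |
| cavity semi-axes | 35, 45, 30 mm | oral-cavity ellipsoid (lat, AP, SI) |
| tongue semi-axes / offset | 25, 35, 18 mm / (0, 0, −12) | interior tongue, resting on the floor of mouth |
| posterior opening half-angle | 40° | cap of the cavity boundary with no mucosal wall (oropharyngeal opening) |
| PTV centre / radius | (0, 25, −5) mm / 25 mm | medially/posteriorly placed spherical target |
| prescription / fractions | 65 Gy / 30 | plan; EQD2 ≈ 65.9 Gy at the prescription |
| hotspot fraction / sigma | 5% / 15 mm | in-PTV hotspot centred on the tongue core |
| falloff sigma | 10 mm | Gaussian falloff outside the PTV |
| noise SD | 0 Gy (off) | optional seeded Gaussian dose noise, clipped at 0 |

The mucosal sheet is the one-voxel inner boundary layer of the cavity minus
the posterior cap, plus the superior-facing boundary layer of the tongue
(the dorsum; outward normal with positive z). The ground-truth MSC is the
3 mm expansion of that sheet. The dose is the prescription inside the PTV
and falls off outside as a Gaussian of the Euclidean distance to the PTV
surface; inside the PTV it is additionally scaled by a mild hotspot factor,
`1 + 0.05·exp(−|x − tongue centre|²/(2·15²))`. IMRT plans carry a few-percent
hotspot where beams overlap in deep tissue; centring it on the tongue's core
gives the plan a unique maximum at the in-PTV voxel nearest the tongue
centre — in tongue musculature, within the PTV, robustly clear of the
mucosal wall — rather than leaving the maximum's position to an arbitrary
tie-break on a flat plateau. The factor applies only inside the PTV so the
maximum cannot migrate just outside the target surface (the Gaussian falloff
is flat there).

Cohorts draw per-patient jitter from a single seeded stream: ±10% on cavity
and tongue semi-axes, ±8 mm on each PTV-centre coordinate, ±5 mm on the PTV
radius (uniform). A draw that violates the anatomy invariants (tongue inside
the closed cavity) is redrawn, with a bounded retry count. Identical spec
and seed give bit-identical cases.

**What the phantom does and does not show.** It reproduces the structural
causes of the published contrast — a thin lining versus a bulky solid, a
medial high-dose region overlapping muscle, an open posterior border — so
passing tests demonstrate the pipeline's correctness and the direction of
every finding (positive reduction in all cases, greater PTV overlap for the
solid contour, shell larger than the solid's own surface annulus, maximum in
muscle inside the PTV). It does not model real contour irregularity, air
gaps, dental artefacts or beam physics, so the magnitudes (e.g. the ~21–34%
reduction range across a default cohort) characterise the phantom, not any
patient population.

## Problem sizes and numerical choices

Tests and the acceptance script run the phantom at 1 mm spacing (1.4 M
voxels; the resolution-convergence check also runs one case at 0.5 mm), an
11-patient cohort, and analytic oracles on 140³ grids — sizes chosen so the
oracle tolerances (2–5%) are comfortably resolvable. Distance thresholds are
inclusive; median uses midpoint interpolation for even counts; the DVH axis
extends to the first bin multiple strictly above the maximum sample; empty
masks are rejected by every operation that needs a non-empty input, and
volume/overlap accept empties (returning 0).

## Known limitations

* No DICOM RTSTRUCT/RTDOSE import; NIfTI only, axis-aligned grids only.
* No contour-polygon rasterisation or mesh-based surfaces; structures are
  voxel masks throughout.
* EQD2 is the only fractionation correction; no NTCP/toxicity modelling and
  no statistical testing across cohorts (medians and ranges only).
* The one-sided sheet expansion requires the caller to supply the side mask;
  the package does not infer sheet orientation.
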