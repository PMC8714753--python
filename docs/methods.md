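# Methods

## The scoring model

Incisional hernia repair augments the abdominal wall — a layered soft-tissue
composite — with a textile mesh. Under cyclic pressure loads (breathing,
coughing, straining) the mesh-tissue compound can be overloaded at its
interface, and an overloaded compound slips and eventually fails as a
recurrence. The package scores a planned or completed repair by its **GRIP**
(gained resistance to impacts related to pressure) and compares it with the
**CRIP** (critical resistance to impacts related to pressure) that the
individual hernia requires.

The inputs are dimensionless coefficients from dynamic intermittent strain
(DIS) bench testing:

* `c_mesh` — the mesh's dynamic-stiction coefficient (Progrip 1.44,
  Dynamesh Cicat 1.0, Ultrapro 0.25, Optilene 0.4, Ultrapro Advanced 0.5,
  Adhesix 0.1). Wet/dry and lubricant conditions can shift these by tens of
  percent; that variation is exposed only as an optional multiplicative
  `adjustment` on a device (default 1.0) because no per-device wet/dry
  values are tabulated. Anisotropy is recorded as a note, never applied
  numerically.
* `c_pos` — the mesh plane: onlay 0.5, retromuscular sublay 1.0,
  intraperitoneal underlay (IPOM) 0.9.
* per-element fixation coefficients — suture 0.5 per bite, tack 0.3,
  strong (Securestrap-style) tack 0.5, glue spot 0.15, with flat glued area
  converting at two 8-mm spots per cm².

The **fixation factor** is `FF = Σ count_i · c_i` (so 100 suture points give
FF 50, matching the FF50 labeling convention), the **mesh-defect area
ratio** is `MDAR = A_mesh / A_defect` with `A_defect` the *largest* of the
resting, Valsalva and intraoperative measurements of the unstable area, and
the adopted combination rule is

```
GRIP = MDAR · c_mesh · c_pos · FF
```

The multiplicative form is a design choice of this package: each coefficient
scales the retention the compound can build, the rule is linear in FF (as
the FF-scaled repair-option curves require), and it reproduces the published
single-patient design example within rounding — 600/94 · 1.0 · 1.0 · 35 =
223.4 against the printed 227, a 1.6% gap most plausibly explained by an
unrounded defect area near 92.5 cm² in the original calculation. The rule is
registered by name in `GRIP_RULES` and every report records which rule
produced its numbers, so an alternative combination rule can be swapped in
without touching callers.

**CRIP is a user input.** The critical threshold is computed preoperatively
from the hernia's geometry and distension by methods outside this package's
scope; plans therefore normally carry a direct CRIP value. For option
exploration only, a single-point-calibrated model
`CRIP ≈ k · A_defect · (1 + distension/100)` is provided, with
`k = 62 / (94 · 1.2)` anchored on the worked example; every report that uses
it is flagged non-normative. No tissue-quality coefficient enters the rule:
human tissue quality varies ~18-fold but no per-patient values are
tabulated, so pretending to model it would be false precision.

**Durability.** `safety_margin = GRIP / CRIP`; a repair is durable when the
margin reaches the configured threshold (default 1.0 — the repair must
surpass its CRIP; the worked example's 3.7 is an observed margin, not a
requirement). The boundary is closed: a margin exactly at the threshold
counts as durable. Warnings, not errors, are raised for an unsecured mesh
(FF = 0, which occurs clinically) and for a minimal overlap below the 50 mm
empirical recommendation. Notch effects and stress concentrations are
outside the model.

**Option exploration** sweeps circular defect diameters against fixation
variants and adjunct-technique tags. The tags are bookkeeping only: a
sandwich reconstruction (SW) adds one mesh-layer equivalent to the MDAR, a
double peritoneal flap (DPF) and a transversus abdominis release (TAR) are
recorded without numeric effect (they gain operative space, which the planar
area model cannot express).

## Morphometry

The morphometry stage consumes finished integer label volumes (NIfTI or
NRRD; the label dictionary travels in a JSON sidecar because neither format
has a portable slot for it). Segmentation itself — in the clinical workflow
a deep network — is out of scope. Coordinates are voxel centers, zero
origin, spacing in mm; areas are reported in cm².

Two area estimators are provided for sheet-like regions:

* `projected_plane` — the voxel cloud is rotated into its PCA best-fit
  plane, rasterized at the smallest voxel pitch (with the in-plane basis
  snapped toward the voxel axes and aliasing holes closed), and the
  occupied footprint counted. Exact for flat regions; underestimates curved
  ones by the projection.
* `surface_mesh` — the same rasterization keeps the top height per pixel
  and the resulting height field is triangulated. This was chosen over the
  more obvious half-of-the-marching-cubes-boundary because the boundary
  mesh of a binary volume acquires staircase facets on steeply sloped
  sheets and a rim contribution of thickness × perimeter / 2; on the
  spherical-cap phantom these inflate the estimate by ~11% at 1 mm voxels,
  while the height-field triangulation is within ~3% (disc) and ~2% (cap).
  Its own limitation: it assumes the region is a single-valued sheet over
  its best-fit plane, which holds for abdominal-wall segments but not for
  closed or strongly folded surfaces.

**Displacement** between rest and Valsalva uses a closest-surface-point
estimator: for every rest-state surface voxel, the distance to the nearest
load-state surface voxel of the same region. This replaces full non-rigid
registration deliberately — it is deterministic, dependency-light, exact
for pure normal motion of a smooth surface, and sufficient at phantom
scale; it underestimates tangential sliding. The method name is recorded in
every output. Isodistance bands bucket magnitudes into fixed-width
intervals (`ceil(max/step)` bands, one band for an all-zero map) for
stress-zone visualization.

**Distension** is `100 · (A_load − A_rest) / A_rest`. A resting orifice
below 1 cm² (configurable) reports *indeterminate* instead of an explosive
percentage — the published example has a rest area < 1 cm² against 28 cm²
under load. Inside the planning pipeline a missing Valsalva measurement is
replaced by the cohort-median 20% distension; inside the statistics stage
missing stays missing, never imputed.

## Cohort statistics

Registry tables are delimited text with a schema-version comment line.
Loading validates every row (group membership, NAS pain scores in 0–10,
BMI–height–weight consistency within rounding, non-negative counts) and
collects failures into a rejects report rather than dropping them silently.

Group comparisons use the Mann-Whitney U test with midrank tie handling.
When both groups have ≤ 20 observations the two-sided p-value comes from
the exact permutation null of the rank sum, computed by a subset-sum
dynamic program over the doubled midranks (doubling makes tied midranks
integer; subset counts stay below 2^53 for N ≤ 40, so float64 arithmetic is
exact). Larger groups use the normal approximation with tie-corrected
variance and a 0.5 continuity correction — the convention of the common
online calculators; it agrees with the exact null to about one percentage
point of p already at n = 8 per group. Two-sided p is
`min(1, 2·min(P(U≤u), P(U≥u)))`; all-tied data gives p = 1 on both paths.
No multiple-testing adjustment is applied by default (raw per-variable
p-values, as registry analyses conventionally report them); Holm step-down
is available behind a flag. Trend lines are ordinary least squares with the
product-moment correlation; histograms support a truncation bound that
routes extreme values into an overflow bucket for display while the median
stays untruncated.

## Synthetic data

The source registry's patient-level data are not public, so the generator
emulates its structure: 119 primary and 44 recurrent repairs with group
medians of 78 / 161 cm² (hernia area), 42 / 84 (fixation points),
150 / 228.5 min (operating time; the source reports both 228 and 229 and
the midpoint is used), 6 days stay, a 15% complication probability, median
NAS 0, and a distension distribution with median 20%, a 0.1 point mass at
exactly zero, and truncation at 1800% by resampling (never clipping).
About a quarter of records carry no distension (patients scanned at rest
only). Sizes, times and counts are log-normal — the corresponding clinical
histograms are strongly right-skewed with extreme tails — with
`σ = ln(max/median)/2.6` fitted from the printed extremes (2.6 ≈ the
standard-normal quantile of the expected maximum of ~120 draws); where no
extreme is printed a moderate σ of 0.3–0.5 is used. The stay distribution
targets the typical 3–14-day range; pathological outliers (a 113-day stay
occurred once) are not modeled. Derived fields are never sampled: each
record's mesh is sized from its circular-equivalent defect plus sampled
overlap, and MDAR, GRIP and CRIP are computed through the scoring pipeline,
so generated registries are internally consistent by construction and any
GRIP–CRIP correlation arises only through the shared hernia-area draw.
These families are stand-ins for unpublished empirical distributions and
are labeled as such in the generated ground-truth metadata; passing tests
show that the *pipeline* recovers configured structure, not that real
registries follow log-normals.

Phantom pairs provide analytic ground truth for morphometry: the rest state
is a flat 3 mm sheet with a circular orifice of radius r (area πr²), the
load state replaces the orifice by a spherical-cap shell of height h (cap
surface π(r² + h²); maximum surface displacement exactly h, attained at the
orifice center). Defaults — 5 cm radius, 4 cm bulge, 1 mm isotropic voxels
on a 160×160×70 grid — match the scale of a realistic severe bulge (the
published displacement map peaks near 4 cm). Phantom generation is fully
deterministic; the config seed exists for provenance only.

## Numerical conventions and limitations

* MDAR and safety margins are reported to one decimal, distension and area
  deviations to whole percent; internal computation is at full precision.
  The open question of whether the original MDAR used a rounded defect area
  is moot at one decimal (600/94 prints 6.4 either way).
* All lengths cm (meshes) or mm (overlap, voxels); areas cm²; conversion
  only at I/O boundaries, with unit-suffixed keys required in plan files.
* Determinism: every generator takes an explicit seed; identical config and
  seed give byte-identical outputs, and each output embeds the tool
  version, a hash of the analysis-relevant configuration, the seed and the
  scoring-rule name.
* The model is planar and quasi-static: no 3D mesh curvature, no
  finite-element mechanics, no recurrence-hazard prediction, no glue-curing
  kinetics (only the final per-spot coefficient), no tissue coefficient.
  Test problem sizes (163-record cohorts, 160³-scale phantoms) were chosen
  to exercise every code path at the study's own scale.
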