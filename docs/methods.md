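# Methods

This note documents the models, defaults and numerical choices behind
`fetalflux`, and what the synthetic-data results do and do not demonstrate
about real acquisitions.

## Signal models

### Cine phase-contrast flow

Through-plane velocity is encoded linearly in signal phase with the
convention that the velocity-encoding limit VENC corresponds to a phase of
π: `v = (φ/π)·VENC`. Phases live in (−π, π]; a velocity beyond VENC wraps
to the opposite sign. The default per-vessel VENCs (cm/s) follow standard
fetal-sheep protocol values: AAo/MPA/DAo/DA 150, SVC/CCA/DV 100, LPA/RPA
80, UV 50. Cine series default to 15 cardiac phases; at a fetal heart rate
of 140 bpm this gives a temporal resolution of 60000/140/15 ≈ 28.6 ms.

Flow is the ROI sum of velocity times pixel area per cardiac phase,
converted to mL/min (1 cm/s over 1 cm² = 60 mL/min), with the mean over
phases reported. Correction steps:

* **Background offset** — per-phase mean velocity over a user-supplied
  static-tissue mask is subtracted everywhere. The operation is idempotent
  and exact for a spatially constant offset; real eddy-current fields have
  spatial structure (typically modelled with low-order polynomials), which
  this deliberately does not attempt.
* **Aliasing unwrap** (opt-in) — pixels whose sign opposes the ROI median
  and whose magnitude exceeds VENC/2 are shifted by 2·VENC toward the
  median sign. Off by default because protocol VENCs are chosen to avoid
  wrap.
* **Lumen segmentation** — either a user mask or an Otsu-style threshold on
  the time-averaged magnitude followed by the largest connected component.
  This is adequate for phantoms; real vessel segmentation is manual.

The flow phantom uses a fully developed laminar (parabolic) profile because
it admits the closed-form flow `π R² v_peak/2`, giving an independent
oracle for the integration code. Discretising the profile onto a 1-mm grid
biases the integral by well under 1% for lumen radii ≥ 8 px, which sets the
2% acceptance band.

### T2 relaxometry and oximetry

T2-prepared signal decays mono-exponentially, `S(t) = S0·e^(−t/T2)`, over
the default preparation times {32, 64, 96, 128, 160, 192} ms. The default
fit minimises signal-domain squared residuals (trust-region reflective,
`xtol=ftol=gtol=1e-14`) initialised from the log-linear solution, so the
two methods coincide exactly on noiseless data while the iterative fit
keeps correct noise weighting at low SNR. A non-decaying signal pins T2 at
an upper bound (1e5 ms) with a flag rather than failing.

The vessel ROI is eroded to its **central 60% by area** before averaging:
pixels are ranked by Euclidean distance to the mask boundary and the
deepest k kept, k the largest count with k/n ≤ 0.6. Area-fraction ranking
(rather than radius scaling) is well defined for non-circular masks and
deterministic under the distance-then-row-major tie-break.

T2 relates to oxygen saturation Y through a quadratic-in-desaturation
(Luz–Meiboom-family) calibration, `1/T2 = 1/T2_plateau + K·(1−Y)²`,
inverted as `Y = 1 − sqrt((1/T2 − 1/T2_plateau)/K)` (the only root with
Y ≤ 1). **The shipped constants — T2_plateau = 250 ms, K = 0.02 /ms — are
provisional**: they give blood-realistic T2 values (≈134 ms at Y = 0.585,
≈71 ms at Y = 0.29) but are not a measured sheep-blood calibration, and
every output manifest flags them as provisional. A haematocrit adjustment
enters as a linear modifier of K around a reference Hct of 0.30 (zero slope
by default). Because dT2/dY → 0 at full saturation, noise can push a
fitted T2 past the plateau; the pipeline treats over-plateau fits as fully
saturated, while the library function raises beyond a configurable
clamp tolerance (default 0.02 on the Y scale).

Non-rigid motion correction is out of scope; a rigid translational ROI
re-centring is available and off by default.

## Circulation model

Measured vessels: UV, DV, AAo, MPA, DA, DAo, SVC, LPA, RPA, and left/right
carotids. Combination rules: `PBF = LPA + RPA`, `RVCO = DA + PBF`,
`LVCO = AAo` (coronary flow excluded), `CVO = RVCO + LVCO`. Two quantities
are *derived, not measured*, and every output flags them as such:

* **Foramen ovale flow** `FO = LVCO − PBF` — left-heart inflow minus
  pulmonary venous return; the only derivation available from this vessel
  set.
* **Lower-trunk flow** `DAo − UV` — descending-aortic flow minus the
  placental return.

A negative FO is flagged, never clipped. Distribution metrics divide by
CVO; a zero CVO raises rather than propagating NaN into group statistics.
The conservation check verifies the anatomical identity `MPA = DA + PBF`
(relative discrepancy, absolute if MPA = 0) and that the exact partition
`DA + PBF + FO + PBF = CVO` sums to 100%.

## Oxygen transport

Units are the single genuinely error-prone spot: with [Hb] in g/L, Y as a
fraction and Q in mL/min, content is `1.36·Hb·Y` mL O2 per **litre** of
blood, so all transport rates carry a /1000 to land in mL O2/min. The
extraction fraction uses the same vessel pairs as the consumption
equations — fetal (UV, DAo), cerebral (AAo, SVC) — which makes
`VO2 = OEF·DO2` an algebraic identity (tested to 1e-12). Negative
extraction is flagged, not clipped, as it signals inconsistent oximetry.
Haemoglobin is taken per state; a scan-mean convention can be emulated by
averaging upstream. Dissolved oxygen is neglected.

## Biometry

Label maps use 0/1/2 for background/body/brain with brain ⊂ body, so fetal
volume counts both labels; this is what makes a relative brain weight
meaningful. Volume-to-weight conversion factors default to 1.03 (body) and
1.04 g/mL (brain) — literature-scale tissue densities, flagged provisional.

## Statistics

The design is a split plot: group between subjects (unbalanced 12 vs 9),
oxygenation state within (2 levels, so sphericity holds identically and no
epsilon correction applies). Tests use two error strata: group against
subjects-within-group (computed on per-subject means), state and
group×state against the state×subject-within-group residual. Under
unbalance the within-stratum SS are **Type III** (partial) SS via
effect-coded model comparison; the implementation reproduces R's
`car::Anova(type = 3)` split-plot output exactly, and is checked in the
test suite against an independent brute-force oracle (orthonormal
within-contrast transformation) on 200 random designs at 1e-9.

Pairwise comparisons are fixed to the four cell contrasts the design
implies — group within each state (unpaired pooled-variance t) and state
within each group (paired t) — Bonferroni-corrected with m = 4, α = 0.05.

Calibration checks: on pure-noise 12-vs-9 cohorts the type-I error of each
effect is 5% ± 1% (5000 replicates), and power for a programmed
group×state interaction rises monotonically over {0.5, 1, 1.5, 2} SD,
exceeding 50% at 1 SD. The power simulations include a subject random
intercept at ICC 0.5 (half the unit marginal variance between subjects),
the repeated-measures structure that makes within-subject contrasts more
precise than the marginal SD suggests.

## The synthetic cohort

The generator draws each variable from its group×state normal distribution
truncated to physical ranges by rejection sampling (no point mass at the
bounds), with a shared subject identity across the two states. Two
identities hold *by construction*: `MPA = DA + LPA + RPA` exactly, and the
programmed FO (`AAo − LPA − RPA`) is recorded so the end-to-end derivation
chain can be verified against it.

Defaults encode the study design the package emulates: n = 12 control vs
n = 9 growth-restricted; arterial (AAo) saturation 58.5 ± 7.5% /
47.4 ± 7.3% (control/FGR, normoxia) falling to 29 ± 7.6% / 27.4 ± 6.1%
under acute hypoxia; haemoglobin 92–100 ± 9–11 g/L; heart rate
140–148 ± 10–21 bpm; fetal weight 1800 ± 200 g (control) vs 1400 ± 180 g
(FGR) with similar brain weights, so relative brain weight is higher in
FGR. **Per-vessel flow means are not ground truth from any publication**
(no such table is printed anywhere this package draws on); they are
plausible fetal-sheep values at ~0.45 L/min/kg combined ventricular output,
flagged provisional in every manifest, and expected to be edited.

Effects reported as significant in this design are programmed at roughly
two pooled SDs of group separation (e.g. DV 110 → 170 mL/min; FGR AAo
raised so programmed FO separates clearly; PBF 70 → 35 mL/min at normoxia
only); null effects are programmed at zero. Two SDs is the separation at
which a 12-vs-9 design with Bonferroni-corrected pairwise tests detects an
effect reliably — i.e. the detectability the emulated study demonstrably
had. Venous saturations under hypoxia are set so cerebral VO2 stays constant
while cerebral OEF rises (the brain-sparing signature); fetal OEF is only
approximately state-stable under the default desaturations. With these
defaults the full qualitative pattern reproduces in ≈80–85% of replicate
cohorts; the shortfall from 100% is dominated by the two "no effect" checks,
each of which fails at the nominal ~5% false-positive rate by construction.

What the generator does **not** emulate: within-subject correlation between
states (states are drawn independently given the subject identity), k-space
physics, gating jitter, eddy-current fields with spatial structure,
non-rigid motion, partial-volume mixtures at vessel edges, or maternal
physiology. Passing tests therefore demonstrate the correctness of the
quantification and statistical chain under its stated signal models, not
robustness to scanner artefacts.

## Problem sizes and determinism

Phantoms default to 10-px lumen radius on ~33² grids with 15 cardiac
phases; the full imaging study (21 subjects × 2 states × 11 vessels + 7
T2 series each) runs in a couple of seconds, and the replicate studies in
the test suite use value-level mode (imaging chain bypassed) since imaging
noise is ~0.5% of flow and does not move the cohort statistics. All
randomness flows through integer seeds (`numpy` `default_rng` /
`SeedSequence`); reruns with the same config and seed are byte-identical,
which the test suite asserts on whole run directories.

## Known limitations

* FO and lower-trunk flows are algebraic derivations, not measurements;
  their validity rests on the circulation topology and on LVCO excluding
  coronary flow.
* The T2→SO2 calibration and the volume→weight factors ship as provisional
  defaults and must be replaced for quantitative use on real data.
* The ANOVA is a classical split-plot, not a mixed-effects (REML) model; it
  requires complete two-state data per subject.
* Uterine-artery flow receives no special treatment (maternal gating is an
  acquisition-time concern outside this package's scope).
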