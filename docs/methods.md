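# Methods

## Problem setting

In regulatory rodent toxicology, every study carries a concurrent
control group (CCG) of vehicle-treated animals. A virtual control
group (VCG) replaces some or all CCG animals with measurements drawn
from historical control data (HCD) of the same facility, reducing
animal use (3R). Whether that replacement is scientifically safe is an
empirical question: the package quantifies it as the *reproducibility*
of a completed study's Dunnett conclusions under repeated resampling
of its controls from an HCD pool.

The worked case is a 28-day oral-gavage study in male Wistar Han rats
with treatment-related hypercalcemia: serum calcium of 2.57 ± 0.06
mmol/L in controls and 2.57 ± 0.05, 2.64 ± 0.04, 2.69 ± 0.04 mmol/L in
three dose groups (n = 10 each); two-sided Dunnett's test flags dose
groups 2 and 3. The study used isoflurane anesthesia before blood
withdrawal; the HCD pool spans a facility-wide changeover from CO₂
(elevates blood electrolytes through acidosis) to isoflurane (lowers
them), which makes the pooled calcium distribution bimodal and acts as
a hidden confounder — "hidden" because standard SEND exports do not
record the anesthetic.

## Synthetic data generator

No public animal-level data exist for this setting, so the generator
emulates the documented distributional structure; all parameters are
configurable and the defaults are:

| parameter | default | origin |
|---|---|---|
| isoflurane calcium stratum | N(2.55, 0.07²) mmol/L | reported stratum moments |
| CO₂ calcium stratum | N(2.87, 0.14²) mmol/L | reported stratum moments |
| CO₂ mixture weight *w* | 0.44 | fitted (see below) |
| pool size | 30 studies × 10 animals | reported study count, 10-per-group design |
| study years | uniform 2011–2021, changeover at 2017 | reported selection window and changeover |
| phosphate strata | N(2.05, 0.15²) / N(2.30, 0.15²), corr 0.5 with calcium | stand-in (not reported) |
| initial body weight | uniform 150–250 g | stand-in within the reported 100–250 g filter |
| day-28 body weight | N(300, 20²) g, independent | stand-in |

The CO₂ share *w* is not reported; it is identified by least squares
against the reported pool moments (2.68 ± 0.19 and 2.69 ± 0.20 mmol/L
give *w* ≈ 0.407 and 0.443 respectively), and 0.44 is the default. The
CO₂ study count is `round(w · n_studies)`; CO₂ studies get years
strictly before the changeover. Randomness comes from a single integer
seed expanded into per-study `SeedSequence` substreams (domain-tagged
so pool, fixture and resampling streams never collide); the same seed
reproduces a pool bit for bit.

The legacy-study fixture draws each group from its normal and then
**moment-matches** (z-standardize, affine rescale) so sample mean and
SD hit the targets to float precision. This makes the original Dunnett
result an exact function of the printed summary statistics — the
fixture's only true degrees of freedom are the control animals'
body-weight/calcium pairing (relevant for sentinel selection) and the
individual values' configuration, which the pooled test does not see.

What the generator does *not* emulate: between-study (cage, batch,
season) random effects, non-normal tails, within-animal longitudinal
structure, and any body-weight–electrolyte dependence. Passing tests
therefore demonstrate the pipeline's correctness and the confounder
mechanism, not distributional fidelity to any real facility's data.

## Statistical kernels

*Dunnett test.* Two-sided, pooled within-group variance over all
groups (df = N − k − 1 with k dose groups), adjusted p-values
p_i = 1 − P(max_j |T_j| ≤ |t_i|) under the equicorrelated multivariate
t with λ_i = √(n_i/(n_i+n_0)). The probability is evaluated as a
deterministic double quadrature: 96-point Gauss–Legendre over the
χ_ν/√ν mixing variable × 64-point Gauss–Hermite over the shared
control factor. Accuracy is ~1e−6 (cross-checked in the tests against
scipy's randomized-QMC implementation at 5e−3 tolerance); determinism
matters because the engine promises byte-identical reports for a fixed
seed. Quantiles q(α, k, ν) are found by Brent root-finding on the same
CDF and cached. Two-sidedness is required for the "inverted
significant" outcome category to be observable at all; the direction
of each contrast is recorded separately as sign(x̄_i − x̄_0).
Significance uses p ≤ α. Degenerate inputs: zero pooled variance with
equal means gives p = 1; with unequal means it is an error.

*Welch test, Cohen's d, extreme contrast.* Welch–Satterthwaite df with
a t-based CI (via scipy); Cohen's d uses the (n_i − 1)-weighted pooled
SD and is reported as a magnitude. The extreme contrast compares the k
largest against the k smallest pool values (ties broken by original
index, making the selection deterministic) with a Welch CI and
Cohen's d — a gauge of the largest effect the pool itself could fake.

## Resampling engine

Per scenario: the original Dunnett result is computed once; sentinels
are selected once (a deterministic function of the control group):
sort by initial body weight, keep ⌊n/2⌋ lightest + ⌊n/2⌋ heaviest,
plus the animal at rank ⌊(N+1)/2⌋ when n is odd (for N = 10, n = 5:
ranks 1, 2, 5, 9, 10). Pool filters are applied in a fixed order
(anesthetic match, then the sentinels' calcium mean ± 2·SD closed
interval; the intersection is order-invariant, the order is fixed only
for reproducible provenance logs). The anesthetic match also removes
animals with unknown anesthetic, since their stratum cannot be
verified. Each iteration draws (group size − n_keep) animals uniformly
without replacement from the filtered pool — animal-level, so
correlated endpoints stay linked — assembles the virtual control at
constant group size, re-runs Dunnett against the unchanged dose
groups, and classifies each dose group's outcome:

| original | VCG | category |
|---|---|---|
| ns | ns | consistent non-significant |
| ns | sig | inconsistently significant |
| sig | ns | inconsistently non-significant |
| sig | sig, same direction | consistent significant |
| sig | sig, opposite direction | inverted significant |

Reproducibility [%] = 100 × (consistent) / iterations, per dose group.
Iteration randomness uses substreams of (scenario seed, iteration
index), so iterations are order-independent and reports byte-stable.
The six standard sub-scenarios combine {unfiltered pool, anesthetic-
matched pool} × {replace all, keep 2 sentinels, keep 5 sentinels};
sentinel scenarios always apply the range filter.

## Confounder screen

`stratified_summary` reports n/mean/SD and a central-t CI of the mean
per level of any design covariate. `year_shift_scan` compares every
adjacent calendar-year pair by Welch's t-test and flags a boundary
when the Bonferroni-adjusted p ≤ 0.01 *and* the absolute mean gap
exceeds 2× the earlier year's SD — thresholds chosen so a ~0.3 mmol/L
step at ~30 animals/year is flagged while year-to-year sampling noise
at these sizes is not. The screen is a triage tool, not changepoint
inference; causal attribution stays with the analyst.

## Problem sizes and numerical choices

Scenario runs use the documented 500 iterations (a 500-iteration
percentage has Monte-Carlo SE ≈ 2.2 pp at 50% and ≈ 0.6 pp at 98%);
convergence checks in the tests use 5,000. Property simulations use
10⁴ replicates. Moment matching is exact to 1e−12; the Dunnett CDF to
~1e−6; range filters and selection windows are closed intervals (the
underlying selection criteria are stated as "between" without openness
qualifiers, and closed intervals are assumed throughout).

## Known sensitivities and limitations

- **Borderline dose group 2.** The gap between dose group 2 (2.64)
  and a well-matched virtual control (~2.55–2.57) is ~0.07–0.09
  mmol/L, while the critical distance is ~0.056–0.060. Scenario
  percentages for this group are therefore sensitive to sub-0.01
  mmol/L details that two-decimal summary statistics cannot pin down;
  expected values computed from the rounded moments can differ by
  several percentage points from results obtained on unrounded raw
  data.
- **Scenario 2a, dose group 1.** Under any i.i.d. normal isoflurane
  stratum consistent with the printed moments, the VCG sample mean
  varies by only ≈ 0.022 mmol/L across iterations, which caps the
  inconsistently-significant rate for dose group 1 near 4–12%. The
  reported ≈26% rate implies an effective control-vs-stratum gap of
  ≈0.04 mmol/L on the unrounded data; the generator, calibrated to
  the rounded moments, reproduces the qualitative ordering of the
  scenarios but lands higher (≈90%) on this one percentage.
- **Sentinel scenarios are realization-dependent.** Sentinels are
  picked by body weight, which is independent of calcium here, so the
  kept animals' calcium mean ± 2·SD window — and with it the CO₂
  leakage into the filtered pool — varies from fixture to fixture.
  With a narrow window the half-sentinel scenario reproduces all dose
  groups at ~100%; an unluckily wide or shifted window can degrade
  dose group 2 substantially. The per-iteration logs make this
  traceable (every virtual control value maps to an animal id).
- Sodium/potassium are supported as endpoint codes but ship with no
  calibrated generator parameters; phosphate and body-weight
  parameters are documented stand-ins, so no quantitative claims are
  made for secondary endpoints.
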