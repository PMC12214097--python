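# Methods

This note documents the models and procedures implemented in `subacrodyn`,
the assumptions they make, the parameters that matter, and the design
choices taken where the underlying clinical protocol leaves the details
open.

## Coordinate and axis conventions

Landmark coordinates are in centimeters on the ultrasound image plane: x is
the mediolateral axis, y increases with depth from the transducer (default
scan depth 3.0 cm). The vertical acromiohumeral distance is
`vahd = gt_y − acromion_y`, i.e. positive when the greater tuberosity lies
deeper than the horizontal plane through the lateral acromion edge, so
*smaller* values mean a narrower subacromial space. Negative values
(tuberosity superficial to the acromial plane) are physically meaningful on
pathological input; they are retained and surfaced as warnings, never
clipped. All distances are cm and all follow-up times days throughout.

## Cycle segmentation and mVAHD extraction

The segmentation signal is the VAHD series itself. Excursion "peaks"
(tuberosity beneath the acromion) are local *minima* of VAHD detected with
prominence-based extremum detection (`scipy.signal.find_peaks` on the
negated series); the bounding local maxima are the neutral-position
"troughs". Abduction spans trough→peak, adduction peak→trough. Defaults:

- `min_prominence = 0.1 cm`. Typical excursions are 0.4–0.6 cm from a
  ~0.9 cm neutral distance, while labeling jitter is of order 0.02 cm, so
  0.1 cm separates real cycles from noise with a wide margin on both sides.
- `expected_cycles = 3`, matching the acquisition protocol of three
  movement cycles per clip; when more are present the first complete
  cycles are used.
- Ties/plateaus in extremum location resolve to the earliest frame.

**Peak-frame membership.** The shared excursion-peak frame is assigned to
the abduction phase by default; the adduction segment starts at the
following frame. With shared ("both") membership the adduction minimum over
its segment is mathematically capped at `min(m_ab, m_ad)`, which makes the
two phase minima unidentifiable whenever the abduction minimum is the
deeper one — and the abduction-phase minimum *is* systematically deeper in
observed cohorts. Abduction-only membership keeps the two minima separately
identifiable (the noise-free simulator round-trip recovers both exactly);
`peak_membership="both"` remains available, in which case a perfectly
symmetric cycle yields equal phase minima.

**Aggregation.** The posture-level mVAHD is by default the mean of the
three per-cycle phase minima; `global_min` (the minimum over all frames of
the phase) is available. Clinical protocols state only that the minimum is
identified "across the cycles"; the mean is less noise-sensitive, and the
choice is explicit in every result object.

Resampling from acquisition rate (e.g. 300 fps) to the labeling rate
(default 4 fps) selects the source frame nearest each target grid time,
keeping original timestamps; no interpolation or upsampling.

## Outcome rules

- **SPADI**: 5 pain + 8 function items, each 0–10; domain = item mean × 10,
  total = mean of all 13 items × 10.
- **Early treatment success**: strictly more than 30% reduction at week 4
  in any of the three VAS subdomains (rest, night, overhead). A subdomain
  with baseline 0 cannot improve relatively and is ineligible; all three at
  0 is an error, not a success. The success criterion is scale-invariant.
- **Recurrence labeling** (responders only): a repeat injection within
  365 days of the index injection (in hospital, or phone-confirmed
  elsewhere) is a recurrence at that day count; a repeat after day 365 is
  administratively "no recurrence" at 365; documented follow-up coverage of
  ≥ 365 days without shoulder complaint, or phone-confirmed resolution, is
  "no recurrence" at 365; otherwise the patient is censored at the last
  known contact day. Non-responders are `not_applicable`. The 365-day
  administrative time for non-recurrent responders is a convention (the
  time actually used in published survival analyses of this design is not
  stated); censoring phone non-responders at last known contact is likewise
  a convention chosen here.
- **Static thresholds** are strict: biceps peritendinous effusion > 1 mm,
  subdeltoid bursa > 2 mm.
- **Historical matching** is greedy nearest-age without replacement, cases
  in ascending id order, controls within ±5 years, ties to the earlier pool
  record. Greedy matching is order-dependent by construction; the fixed
  processing order makes it reproducible.

## Statistics

- **Empirical AUC** is the Mann–Whitney probability that a positive
  outranks a negative (ties 1/2), computed from midranks in O(N log N).
  Orientation is explicit: higher mVAHD scores toward early success, lower
  mVAHD toward recurrence. The 95% CI uses the DeLong placement-value
  variance (Wald on the AUC scale, clipped to [0, 1]). Clinical packages
  often default to a different CI construction (e.g. the Hanley–McNeil
  exponential form), a known source of CI discrepancies; point AUCs are
  unaffected.
- **Youden cutoff**: candidate thresholds are midpoints between consecutive
  sorted unique scores plus ±∞; ties in J break toward higher sensitivity,
  then the lower threshold, making the cutoff deterministic.
- **Binormal closed form**: Φ((μ₊ − μ₋)/√(σ₊² + σ₋²)), the analytic oracle
  for the group-conditional simulations.
- **Logistic regression** (statsmodels MLE): ORs with Wald 95% CIs,
  covariates age, sex, side (categoricals dummy-coded, first level
  reference). On separation-degenerate data the fit falls back to IRLS
  with a pseudoinverse covariance and the CI is flagged unreliable.
- **Cox PH** (lifelines): Efron tie handling (the only method lifelines
  implements; Breslow is not offered), Wald 95% CIs, same covariates.
- **Kaplan–Meier / log-rank** (lifelines): product-limit curves and the
  two-group log-rank chi-square (1 df). The per-group mean survival time is
  the restricted mean (area under the KM curve) up to the largest observed
  time pooled across groups; its SE is the Greenwood-based large-sample
  form Var = Σⱼ Aⱼ² dⱼ/(nⱼ(nⱼ−dⱼ)) with Aⱼ the remaining area from tⱼ,
  computed here directly from the event table (lifelines'
  `restricted_mean_survival_time` variance describes the restricted
  event-time distribution, not the estimator, and is not used).
- **Group comparisons**: continuous unpaired variables are tested with an
  independent t-test when both groups pass Shapiro–Wilk at α = 0.05,
  otherwise Mann–Whitney U; groups under 3 observations skip the gate and
  use Mann–Whitney with a warning. Paired comparisons use Wilcoxon
  signed-rank. Categorical variables use Pearson chi-square without
  continuity correction, switching to Fisher's exact test when any expected
  cell of a 2×2 table is below 5. No multiple-testing correction is applied
  anywhere, matching the analysis style this battery mirrors.

## Synthetic data

**Trajectories.** Within each cycle of duration T the clean VAHD follows a
raised-cosine descent from `baseline_vahd` to `target_min_ab` over the
first half-cycle; the ascent starts at `target_min_ad` on the first frame
after the mid-cycle trough and returns to baseline by the cycle end. The
mediolateral excursion is a coupled raised cosine. Independent N(0, σ)
jitter is added to every landmark coordinate (acromion held at a fixed
position plus jitter), emulating manual frame-by-frame labeling error.
Defaults: 3 cycles, 4 fps, 4 s/cycle (16 frames per cycle, so a frame falls
exactly on each mid-cycle trough), baseline 0.9 cm, σ = 0.02 cm. Exact
noise-free round-trip of both minima requires `target_min_ab ≤
target_min_ad` (the physiological ordering) and a frame on the mid-cycle;
both hold at defaults.

**Cohorts, mode (a) — group-conditional.** Each patient's four mVAHD
metrics are drawn from their outcome group's multivariate normal with the
published means/SDs and an exchangeable inter-metric correlation ρ = 0.6
(metrics from the same shoulder are correlated; no published estimate
exists, and the value affects no single-metric AUC). Draws are untruncated
by default so the binormal oracle applies exactly; `truncate_at_zero`
clips for physically plausible cohorts. Group-level VAS/SPADI summaries
generate the score columns; the three VAS subdomains of one patient share a
common factor (correlation 0.8), since a patient's pain levels move
together — with independent subdomains the "any subdomain > 30%" rule
would be triggered far too often. Because group membership *defines* the
outcome in this mode (the non-success group is exactly the set with no
>30% subdomain reduction — a joint constraint that marginal summaries
cannot encode), downstream analyses use the group-encoded outcome; the
rule-derived label is reported alongside for comparison. Recurrence-group
event times are truncated-exponential within the 365-day window with mean
180 days (chosen once as a plausible within-window scale; no distributional
information is published); a configurable fraction (default 0.1) of
non-recurrent patients are censored before day 365.

**Cohorts, mode (b) — generative.** mVAHD comes from one population
normal; early success from a logistic model with a specified OR per cm of
the driving metric; recurrence times from an exponential
proportional-hazards model with a specified HR per cm; censoring is
independent Uniform(0, c) with c solved numerically so the expected
censored fraction matches the configured value. This mode exists for
parameter-recovery and CI-coverage testing, where the ground truth must be
known exactly.

**What passing tests do and do not show.** The generators reproduce the
first two moments of the published groups, the stated group sizes, and the
event/censoring mechanics — enough to validate the estimators and to check
that the published AUCs are consistent with the published group summaries
under normality. They do not reproduce the joint distribution of metrics,
covariates and outcomes in real patients (unknown), skewness or floor
effects of real mVAHD measurements, or the historical cohort's actual
time-to-event distribution; agreement on synthetic data therefore validates
the *machinery*, not clinical claims about real cohorts. Patient-level
quantities such as adjusted ORs/HRs, mean times to recurrence and the
between-arm log-rank p cannot be recomputed from summaries and are covered
by recovery/coverage properties instead of value reproduction.

## Problem sizes and numerical choices

The AUC reproduction uses 2000 replicates per target (Monte-Carlo SE of the
mean AUC ≈ 0.06/√2000 ≈ 0.001, negligible against the 0.05 agreement band).
CI-coverage checks use 200 simulations at n = 2000. Parameter-recovery uses
200 clips at jitter σ = 0.05 cm. The pipeline's two-arm survival demo sizes
the synthetic standard arm to the dual-target responder count with a
recurrence fraction of 0.5 and mean 150 days — a deliberately less durable
arm, as historical standard-injection cohorts show. All randomness flows
from one top-level seed through spawned child streams (`numpy
SeedSequence`), making every report byte-reproducible.

## Known limitations

- Landmark detection itself (and any image reading: tears, calcifications,
  tendinopathies) is out of scope; inputs are labeled coordinate tables.
- The segmentation assumes one dominant excursion per cycle; double-dip
  cycles with secondary prominence above threshold would be split.
- Greedy age matching does not minimize total age distance (not an optimal
  assignment); it mirrors the simple clinical matching procedure.
- Logistic CIs under separation are flagged, not corrected (no Firth
  penalization).
- Cox ties: Efron only.
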