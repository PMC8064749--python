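# Methods

This note documents the models, parameter choices and numerical decisions
behind prurikit, and what the synthetic-data generators do and do not
emulate.

## Heat-response classification

The classifier works on the instantaneous discharge frequency (IF): for
each consecutive spike pair the frequency 1/ISI is assigned to the *later*
spike, since the frequency is only known when the second spike arrives. The
IF series is 3-point median smoothed (interior points replaced by the
median of themselves and both neighbours; endpoints passed through
unchanged), which removes single-point outliers without broadening genuine
rate transients. Smoothing is applied to the stimulus window only — spikes
from stimulus onset to E + plateau duration, where E = rise time +
conduction latency from skin.

The decision rule compares P, the time of the maximum smoothed IF (ties
broken by earliest occurrence, conservative toward an early, QC-like peak),
with E:

- onset burst → QC, regardless of P (bursting fibers occasionally have
  their largest smoothed IF in the plateau);
- P > E + tol → SC; |P − E| ≤ tol without a burst → unclassified;
  P < E − tol → QC. Default tol = 0.1 s, the same order as the 200-ms
  stimulus rise time; configurable.

**Burst rule.** A burst is ≥ 3 IF points at ≥ 20 Hz within
[L, L + rise + 0.2 s], where L is the conduction latency — the earliest
time a response can appear in the recording, since spike timestamps include
conduction delay. The discharge must also *adapt*: the mean IF over the
final half of the plateau must fall below 0.5 × the peak IF of the burst
window. Adaptation is judged against the onset discharge rather than the
global peak: against a global peak, a slowly adapting fiber whose peak sits
in the plateau would trivially "adapt" relative to its own late maximum
whenever one late interspike interval is short by chance, and such fibers
would leak into the QC class. All four burst parameters are configurable;
no numeric burst definition exists in the field, so these are declared
package defaults.

Boundary conventions: conduction velocity exactly 2 m/s is Aδ; a von Frey
threshold of exactly 6 bar counts as mechano-sensitive (MSA). Classification
is invariant to uniform time translation of train and stimulus onset.

## Pruritogen response scoring

The analysis window starts at the *end* of the injection interval, so
spikes during needle insertion and injection are excluded
(`from_injection_end=False` restores counting from injection start).
Baseline prorating is linear: expected spontaneous APs over a w-second
window = baseline count × w/60. Negative nets are retained — clipping would
bias population means upward — and the ≥ 10 APs/5 min responsiveness rule
applies to the signed value; exactly 10 is responsive. Early-terminated
recordings are treated as zero-padded to the analysis window (a recording
stopped after three silent minutes contributes no further spikes by
construction). Time-course bins are half-open [k·10, (k+1)·10) so each
spike is counted exactly once.

The χ² of association is the closed-form Pearson statistic on the joint
responsiveness table without continuity correction; on the published table
(both 28, ALA-only 11, BAM-only 26, neither 1) it reproduces the printed
χ²(1) = 6.44, p = 0.0112, which fixed the variant choice. The split-plot
(fiber type between, pruritogen within) ANOVA is delegated to
`pingouin.mixed_anova` behind the module interface and verified against
hand-computed sums of squares. With a 2-level within factor the sphericity
correction factor is identically 1.

**Scheffé post hoc.** Contrasts among the g×w cell means use the
within-subject error mean square for comparisons inside a group, and the
pooled error (MS_between + (w−1)·MS_within)/w for comparisons across
groups, with df = df_bs + df_ws for the pooled case (a simple pooled-df
approximation; exact Satterthwaite df would differ slightly for very
unbalanced groups). Each contrast F is referred to the Scheffé criterion:
p = sf(F/(k−1); k−1, df_error) with k the number of cells, which protects
all possible contrasts simultaneously.

## gLMS psychophysics

Ratings live on the 0–100 generalized Labeled Magnitude Scale with anchors
at 0/1/6/17/35/53/100; the first rating falls at 0.5 min after injection
and the grid steps by 0.5 min. Duration runs from the first nonzero rating
to the first zero after the *last* nonzero rating — intermediate zeros in a
waxing/waning sensation do not terminate it — and is censored at the
session end (20-min cap) when no terminating zero exists. AUC is the
trapezoidal integral over the same span with an implicit zero half a minute
before onset (ratings are interval samples of a continuous percept; step
integration would over-weight the first sample). Series with zero peak have
no defined duration or AUC and are excluded from those analyses; peak
analyses use all subjects, duration/AUC analyses use the all-nonzero
subject subset.

**RM-ANOVA with Greenhouse–Geisser correction.** Implemented in-package
from sums of squares, one or two within factors, with ε̂ = tr(E)²/(k·tr(E²))
where E is the covariance of orthonormalised (Helmert) within-subject
contrast scores and k the effect df; for main effects in a two-way design
the contrasts act on the factor's marginal means. ε̂ is clipped to
[1/k, 1]. Corrected p-values agree with R `car::Anova` to 1e-9 on a frozen
test dataset (pingouin's two-way interaction ε differs; pingouin itself
warns it may be inaccurate there, so the cross-checks use pingouin for main
effects and `car`-derived frozen values for the interaction). Subjects with
missing cells are excluded listwise. Null calibration (29 subjects, 5×3
within design, iid normal responses): the GG-corrected tests of the
5-level and 3-level main effects reject at 4.4–4.6% at nominal 5%; the
8-df interaction test is valid but conservative (≈3.5%) at this sample
size — the documented behaviour of the GG correction, which guarantees
level ≤ α.

A between-subjects sex factor is screened with mixed ANOVAs on each within
factor's marginal means and dropped when no sex term reaches p < 0.05
(there is no three-way mixed model in the dependency stack, and the study
protocol drops sex at exactly this screening step). Bonferroni post hoc
families are all pairwise comparisons within the tested factor.

## ISH quantification

Positivity is strict (> threshold puncta; human 5, macaque 3, per-species
configuration). SEM of per-donor percentages uses the n−1 denominator; with
one donor SEM is reported absent. Donors with zero A-positive neurons are
excluded from the per-donor mean but their neurons still enter the
aggregated pooled counts, so the two summaries answer different questions
and generally differ under donor imbalance. Each counted neuron is treated
as unique (no cross-section deduplication). For the macaque panel the three
DRG sections play the role of donors.

## Synthetic-data generators

All spike trains are inhomogeneous Poisson processes with deterministic
rate functions sampled by thinning — the recorded discharge shapes are
known only qualitatively, so the rate forms are declared model choices:

- **QC heat response**: boxcar burst at 80 Hz from 20% into the temperature
  ramp to its end, then exponential adaptation (τ = 0.6 s) over the
  plateau.
- **SC heat response**: gamma-shaped rate r(t) ∝ (t/t_p)² exp(2(1 − t/t_p))
  peaking at t_p = rise + 1.5 s, maximum 50 Hz, no onset component.
- Conduction latencies are uniform on 0.1–0.5 s, consistent with C-fiber
  conduction velocities < 2 m/s over a few centimetres of skin-to-electrode
  distance.
- **Injections**: spontaneous activity at 0.02 Hz throughout (CMHs are
  near-silent at rest), ~2 artifact spikes during the 5-s injection, and an
  evoked post-injection rate A/τ·e^(−t/τ) normalised so the expected evoked
  count inside the 300-s window equals A. Per fiber, A = 0 with probability
  1 − p (p = configured responder incidence) and gamma-distributed (shape 2)
  for responders, scaled so the *population* mean equals the configured
  target net APs — defaults 83/52 (QC to ALA/BAM8-22) and 10/94 (SC),
  stored in `data/defaults.yaml`, with decay constants 60/45/25/90 s.
  Vehicles evoke nothing beyond artifacts.
- **Ratings**: mean percept M·(1 − e^(−t/0.35 min))·e^(−max(0, t−1)/τ) so
  curves peak between 1 and 2 min; itch decay τ = 8 min for
  histamine-containing stimuli versus 4 min otherwise, pain qualities
  3 min. A log-normal subject gain multiplies both signal and rating noise
  (σ = 1.5 gLMS units), so a zero-gain subject rates flat zero; percepts
  below 0.5 register as exact zeros, and the protocol stop rule (minimum
  5 min, maximum 20, stop after three successive zeros on every quality)
  truncates the session.
- **Puncta cohorts**: marker states drawn per neuron from a configured
  joint distribution over the 2³ combinations (defaults give
  P(X1+|D+) ≈ 88%, X1 ⊂ V1); counts are negative binomial with mean 25
  (shape 5) for positive and mean 0.8 (shape 1) for negative states, so
  thresholding miscalls ≈1–2% of neurons.

What the generators do **not** emulate: biophysical membrane dynamics,
bursting microstructure or refractoriness beyond a minimal ISI guard,
mast-cell/flare mechanisms, inter-subject correlation structure in ratings
beyond a single multiplicative gain, rating quantisation toward anchor
positions, or section-level clustering in puncta counts. Passing tests
therefore demonstrate that the analysis code recovers known ground truth
under these idealised conditions, not that it is robust to every artefact
of real recordings.

## Problem sizes and tolerances

Unit tests use cohorts of 5–100 fibers/subjects; recovery checks use 200
fibers (classification), 500 fibers per cell (net-AP means), 500 neurons
(co-expression) and 120–200 subjects (ratings), each asserted within three
standard errors of the configured value. The RM-ANOVA null calibration uses
10,000 replications. Float comparisons against brute-force oracles use
1e-9 relative tolerance; counts must match exactly. Degenerate inputs are
errors, not silent results: empty IF series for peak time, zero-variance
differences for the paired t, zero-margin 2×2 tables, all-zero rating
series for duration/AUC, inconsistent joint puncta probabilities.
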