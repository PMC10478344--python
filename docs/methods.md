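# Methods

This note documents the statistical procedures the package implements,
the defaults and why they were chosen, what the synthetic-data generator
does and does not emulate, and the numerical conventions that matter for
reproducing results.

## Octant geometry and angle conventions

All angles are degrees, counterclockwise, reported in [0, 360). The
communion axis sits at 0°/360° (LM) and the agency axis at 90° (PA);
octant midpoints are PA 90°, BC 135°, DE 180°, FG 225°, HI 270°,
JK 315°, LM 360°, NO 45°. Signed circular differences are mapped into
(−180°, 180°], with exact opposition kept at +180° so the mapping is
single-valued.

## Structural summary parameters

The interpersonal profile of a scale is the vector of eight Pearson
correlations with the octant scores, computed on pairwise-complete
observations (retained protocols may still contain a small number of
blanks). A constant scale or octant raises an error rather than silently
producing a zero correlation.

Because the octant angles are equally spaced, the least-squares cosine
fit e + a·cos(θ − Θ) has the closed form given in the README: the design
{1, cos θ, sin θ} is orthogonal at these angles, so the vector
components x, y are exactly the cosine/sine regression coefficients and
Θ (the vector angle) coincides with the fitted curve's peak. R² is
defined as 1 − SS_residual/SS_total around the profile mean — the
explained-variance convention. Degenerate cases: a flat profile has
amplitude 0, an undefined angle (reported as NaN) and undefined R²
(reported as NaN with a warning), never a crash and never a silent 0
or 1.

Interpretation gating uses heuristic cut-offs: |e| ≥ .10 (elevated),
R² ≥ .70 (prototypical; .80 good), a ≥ .10 (differentiated, only
reported when prototypical), and angles only interpreted when both the
prototypicality and amplitude cut-offs pass. The liberal .10 threshold
suits normative samples with restricted pathology range; more
conservative work may pass stricter `Cutoffs`.

## Bootstrap confidence intervals

Case resampling with replacement (participants as the resampling unit,
scale and octant scores drawn jointly), B = 2000 by default, percentile
intervals at the 95% level. Percentile rather than BCa intervals keep
the estimator simple and symmetric-agnostic; coverage is verified by
simulation (92–98% band at n = 856, B = 500, 500 replications — run as
part of the test suite).

The angular displacement is circular, so its interval is built by
recentering: each bootstrap angle is reduced to its signed deviation
from the point estimate in (−180°, 180°], percentiles are taken on the
deviations, and the bounds are the point estimate plus those percentiles
(mod 360). Intervals may therefore straddle 0°/360° with a numerically
larger lower bound, which is the intended reading. The deviation
percentiles are clamped to include zero so the interval always contains
the point estimate; resamples with degenerate correlations
(zero-variance columns) are dropped and counted, and a result carries a
warning when more than 10% of resamples were lost. Samples below n = 20
are refused.

Paired contrasts refit both scales' profiles on the same resampled rows,
difference the parameters per resample (angles differenced on the circle
and signed into (−180°, 180°]) and report percentile CIs on the
differences. A difference is "significant" when its CI excludes zero;
angles are additionally only called distinct when the point difference
is at least 22.5° (half an octant), below which two scales are not
interpreted as thematically different. When either scale fails the R² or
amplitude cut-off on its point estimate, the angular contrast is
computed but suppressed ("excluded") — computing-then-suppressing keeps
the intermediate values auditable while respecting the gating rule. The
point difference and the bootstrap mean of differences are reported
separately and not forced to agree.

## Randomization test of order relations

For k equally spaced variables, every unordered pair of off-diagonal
correlation cells whose angular-distance classes differ yields one order
prediction (the closer class predicted larger); k = 8 gives 288
predictions over the 28 cells (classes of 8, 8, 8 and 4 cells at 45°,
90°, 135°, 180°). The correspondence index is
(met − violated)/predictions; exact ties (within 1e−10 on the
correlation scale) count in the denominator but not the numerator — the
Hubert–Arabie convention. Published analyses do not always state their
tie convention, so the tolerance is configurable and the convention is
documented here rather than assumed to match any specific printed value.

The null relabels the variable order. Because the index is invariant
under rotations and reflections of the circle, enumerating the (k−1)!
relabelings with the first variable fixed (5040 at k = 8) yields the
same p-value as the k!/(2k) = 2520 distinct circular orders or all k!
permutations; the exhaustive p is the proportion of relabelings
(including the observed one) whose index is at least the observed one.
Its floor at k = 8 is 2/5040 = 1/2520 ≈ .0004. A sampled mode (with the
observed order added, the add-one convention) covers k where exhaustion
is infeasible.

## Scoring, screening and reliability

Scales aggregate items by sum or mean. Proration: a participant's score
is computed when at least 80% of the scale's items are answered — sum
scales return mean(answered) × item count, mean scales the mean of
answered items — otherwise the score is missing. The 80% rule is this
package's choice: screening already caps whole-protocol missingness at
2%, but scale-level handling must still be defined for the residual
blanks.

Screening excludes a protocol when (1) strictly more than 2% of items
are blank, (2) the infrequency (careless-responding) validity score
exceeds the normative mean by more than 2.5 normative SDs, or (3) it is
manually flagged; exclusions are attributed to the first matching rule
in that fixed order so ledger counts are disjoint and deterministic.
Screening is idempotent on the retained set.

McDonald's ω_t = (Σλ)² / ((Σλ)² + Σψ) from a single-factor fit of the
item Pearson correlations. The default estimator is a minres-style
iterated principal-axis fit. A full-likelihood (ML) fit is available but
not the default because it is non-identified in the independence limit:
a diagonal covariance is reproduced exactly by a "factor" loading on a
single item, with the same likelihood as the zero-loading solution, so
ω_t from ML does not converge to 0 for mutually independent items.
Minres matches only the off-diagonal structure and behaves correctly
there. Polychoric-based estimation is out of scope for the default path.
Fits require at least 3 items and 50 complete rows; ML non-convergence
falls back to principal axis with a warning, never a silent default.

## Synthetic data generator

Latent model: each surface has a general factor g and two circle factors
X, Y. Octant j loads √c0 on g and √c1·(cos θ_j, sin θ_j) on (X, Y),
giving the circulant block corr(O_j, O_k) = c0 + c1·cos(θ_j − θ_k). A
scale with target profile (e, a, Θ) loads e/√c0 on g and a/√c1 on the
circle factors at angle Θ, which reproduces corr(S, O_k) = e +
a·cos(θ_k − Θ) exactly. Scale-scale correlations default to what this
shared structure implies (α_i α_j + γ_i γ_j cos(Θ_i − Θ_j)); overrides
are allowed but PSD-checked. Feasibility is enforced, not patched: a
profile whose implied communality exceeds 1 raises an error, and PSD
repair (eigenvalue clipping + renormalization) aborts if it would move
any target entry by more than .01.

Defaults: c0 = c1 = 0.3 (adjacent octants r ≈ .51, orthogonal ≈ .30,
opposite ≈ 0) — a strict circumplex riding on a general factor, typical
of problem-type circumplex inventories; n = 856 as the study-emulation
sample size. Likert discretization uses normal-quantile thresholds with
equal category probabilities by default and a geometric skew option for
floor effects; discretization attenuates correlations (hence amplitudes)
roughly uniformly across octants, leaving Θ essentially unbiased.
Missingness is MCAR. Careless responders answer uniformly at random and
receive elevated infrequency scores.

The packaged fixture holds 929 item-level protocols over two surfaces
(problems: 32 items, 0–4, 4 per octant; sensitivities: 64 items, 1–8, 8
per octant), three 10-item external scales (1–5) and an 8-item
infrequency scale (0–3). Archetype targets: a cold detachment scale
(problems e .19, a .28, Θ 184.2°; sensitivities −.05/.21/351.3°), a
social-anxiety scale (.36/.25/245.1°; .05/.11/33.2°) and a psychoticism
scale with a modest vindictive theme (.25/.12/147.4°; .09/.09/340.7°).
Items load .9 on their latent. Exactly 31 protocols are built
incomplete (8–27 blanks of 134 items, > 2%), 39 careless (infrequency
totals rejection-resampled above the 2.5-SD threshold, attentive totals
below it) and 3 manually flagged, so screening deterministically retains
856 with disjoint ledger counts 31/39/3. The rejection step exists
because without it roughly 1% of attentive responders would randomly
cross the infrequency threshold and break the engineered counts.

What the generator does **not** emulate: non-normal latents (copulas),
differential item difficulty/discrimination within a scale, reverse-keyed
items, systematic (non-MCAR) missingness, demographic covariates, or
cross-surface octant correlations (the two surfaces' latents are
independent; only the scales bridge them). Passing tests on this data
therefore demonstrate the correctness and calibration of the estimators
under a clean measurement model, not robustness to the messiness of real
questionnaire data.

## Pipeline and determinism

The full study run executes screening → scoring → reliability →
structure check (per surface, on retained participants' octant
intercorrelations, before profiling) → SSM + bootstrap per scale per
surface → gating → contrasts → convergence calls → report. All stage
seeds derive deterministically from the single config seed, so a run is
a pure function of (inputs, config, seed) and the JSON report is
byte-identical across repeats. Report tables round parameters to 2
decimals, angles to 1 and R² to 3; the JSON keeps full precision.
Convergence calls: "convergent" (angle-difference CI contains 0),
"statistically distinct but overlapping" (CI excludes 0, |ΔΘ| < 22.5°),
"distinct" (CI excludes 0, |ΔΘ| ≥ 22.5°), or "excluded" (gating).

Problem sizes used by the test suite: the bootstrap coverage study runs
500 replications at n = 856 with B = 500; parameter recovery uses
n = 100,000; the pipeline integration test uses B = 200 on the packaged
fixture. These sizes make the full suite complete in a few minutes while
keeping the simulation-based assertions well-powered.

## Known limitations

- Percentile (not BCa) intervals; slight undercoverage is possible for
  strongly biased statistics, though the calibration study shows the
  95% intervals hold within [92%, 98%] under study conditions.
- ω_t is computed on Pearson correlations; for coarse ordinal items it
  is attenuated relative to a polychoric-based estimate.
- The order-relations test assumes equally spaced theoretical angles.
- Between-sample contrasts (independent groups) are out of scope; all
  contrasts are within-sample, paired.
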