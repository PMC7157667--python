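# Methods

This note documents the statistical procedures implemented in psychosense,
the generative model behind the synthetic observers, and the numerical and
design choices that were genuinely open.

## Psychometric model and fitting

Performance is modelled as P(x) = γ + (1 − γ − λ)(1 − exp(−(x/α)^β)) with
γ fixed at 0.5 (2AFC chance), contrast x and scale α in percent contrast,
dimensionless shape β, and lapse λ. The fit maximises the Bernoulli
log-likelihood of per-contrast correct/total counts over (α, β, λ) with
bounds α ∈ [min x/10, max x·10], β ∈ [0.5, 10], λ ∈ [0, 0.05] —
the λ ceiling follows common practice of bounding lapses at 5% so that
threshold and lapse remain jointly identifiable from 5-point data.

Optimisation is L-BFGS-B in (log α, β, λ) with an analytic gradient and
eight deterministic starts: five on a log-spaced α grid (β = 2, λ = 0.02),
plus the best point of a coarse 48×24×5 likelihood grid within each of
three β bands. The banded starts matter: with shallow or non-monotone
count data the likelihood can have separate modes at moderate β and at the
β boundary (trading steepness against lapse), and α-only starts can all
drain into one basin. With this start set the fitted likelihood was never
below an exhaustive 200×100×6 grid search on 900 random datasets (the test
suite asserts a 0.01-nat tolerance on 100). Likelihood ties between starts
break toward the lowest α.

Saturated data (all correct or all incorrect) leave α unidentified; the
fit returns the boundary estimate with `converged=False` and a warning
rather than a silent number.

Two conventions are fixed here because the field uses both: the **75%
threshold** is read on the full performance scale (P = 0.75), not at 75%
of the γ-to-ceiling span; and **slope** is dP/d(log₁₀ x) evaluated at the
75% threshold, in probability per log₁₀-contrast unit. Both are computed
in closed form from the fitted parameters.

## Difference measures and alignment

Threshold differences are taken on log₁₀ thresholds (BL−IP, OP−BL, OP−IP
as in the README); log base 10 was chosen because typical sub-1% contrast
thresholds then give difference magnitudes of order 0.1, the scale on
which the generator's amplitudes are expressed. OP−IP is computed as
(BL−IP) + (OP−BL), which makes the three-way identity exact in floating
point rather than approximate. Slope differences subtract raw slopes with
the same orientation; reaction-time differences use per-cell means after
one-sided trimming (trials slower than the cell mean + 2 SD are dropped;
fast outliers are kept, since anticipations are handled at acquisition).

Exclusion is sequential: (1) participants whose log₁₀ baseline threshold
is more than 2 SD from the cohort mean are removed, with mean/SD computed
on the full input cohort; (2) mean/SD of the mid-salience (39.5 dB) BL−IP
are recomputed on the survivors and |z| > 2 participants removed.
Re-running exclusion on the kept set can remove further participants
(the statistics shift), so only the ≤ relation is guaranteed, and the
report records each removal's criterion and z-score.

Grouping uses the sign of BL−IP at 39.5 dB; an exact zero is classed as
enhancement with a warning (ties are measure-zero under the continuous
model, but CSV-round-tripped data can produce them). The optimal salience
is the argmax of the five BL−IP values, ties breaking to the lowest bin
with a warning; the same BL−IP-derived index anchors the OP−BL and OP−IP
alignments. Aligned bin ±k averages the existing source bins at distance
k, so all three bins are defined for any optimal index (an edge optimum
contributes a single source bin at each distance).

## Inference

One-sample t-tests are two-sided; the Benjamini–Hochberg family is one
panel — the 5 salience levels of one comparison, or the 3 aligned bins —
matching how such panels are presented, rather than pooling all
comparisons. Hedges' g uses J = 1 − 3/(4(n−1) − 1) and a normal
approximation CI (g ± 1.96·SE, SE² = 1/n + g²/2(n−1)); exact noncentral-t
CIs would be tighter at small n but the normal form is the common
reporting convention for this design. The repeated-measures ANOVA uses the
standard within-subject decomposition with df (k−1, (k−1)(n−1)) and
generalized eta squared SS_effect/(SS_effect + SS_subjects + SS_error); no
sphericity correction is estimated from data (out of scope). Post-hoc
contrasts are paired t-tests, BH-adjusted as one family.

The power calculator uses the classical repeated-measures convention:
noncentrality λ = f²·N·m·ε/(1 − ρ) with numerator df (m−1)ε and
denominator df (N−1)(m−1)ε, defaults ρ = 0.5, ε = 1. (Power software
supports two effect-size conventions; this is the one under which
f = 0.3, m = 5, α = 0.05 yields power 0.872 at N = 17 and 0.847 at
N = 16, so the smallest N reaching 0.85 is 17.) The implementation is
tested against an independent numerical integration of the noncentral-F
tail.

## Synthetic observers

The generator's defaults are the study conditions end-to-end: 11 auditory
conditions × 5 contrasts × 20 trials per cell per observer (1100 trials in
10 randomised blocks of 110); baseline log₁₀ thresholds from
N(−0.352, 0.188); IP amplitude 0.135 log units; enhancement probability
0.5; tuning width 1 bin; β = 2; λ = 0.02; cohort size 20. Reaction times
are log-normal (median 500 ms, σ = 0.25) and exist only to exercise the
trimming rule. Effect tuning is Gaussian in salience *index* rather than
dB because the alignment analysis operates on bins; this is a modelling
stand-in — the data motivating this pipeline say only that an optimal
salience exists per observer, not how effects fall off around it. The OP
condition has its own amplitude (default 0) rather than forced
suppression, so the generator can produce OP benefit or cost.

What the generator does *not* emulate: session/block fatigue or learning,
eye movements, non-stationary lapse rates, heterogeneous β across
observers, or any correlation between baseline sensitivity and effect
amplitude. Passing recovery tests therefore show that the pipeline's
estimators are consistent under the stated model, not that real data meet
those assumptions.

## Diagnostics

**Selection bias.** Aligning to the argmax bin inflates the optimal-bin
estimate under the null by σ·E[max of 5 standard normals] ≈ 1.163σ for
independent zero-mean per-salience estimates with SD σ. In the real
pipeline the five BL−IP estimates share one BL fit, so they are *not*
independent: the common BL noise cancels in the across-salience spread but
would inflate a between-observer SD. The bias experiment therefore
estimates σ as the pooled within-observer across-salience SD, which
isolates the per-salience (IP-fit) noise and makes the 1.163 law the
correct reference. The measured ratio on full-pipeline null cohorts runs a
few percent above 1.163 (≈ 1.22–1.24): psychometric-fit noise is slightly
heavy-tailed relative to the Gaussian idealisation (occasional
near-boundary fits), and max statistics are sensitive to tails. The
procedure is reported as a diagnostic; correcting the bias (e.g. by
split-half alignment) is deliberately out of scope because the published
procedure being modelled aligns and tests on the same data.

**Recovery.** The argmax-recovery rate is scored on enhancement-direction
observers, against the generative s*. For suppression observers the argmax
of BL−IP is by construction the bin *farthest* from s* (their IP effect
raises thresholds most at s*), so "recovering s* by argmax" is not a
meaningful target for them; the all-observer rate is reported alongside.
With 200 trials per cell and amplitude 0.2 the enhancement recovery rate
is ~0.98; at the study's 20 trials per cell estimation noise (per-salience
SD ≈ 0.12 log units) dominates individual argmax estimates, which is
precisely why the aligned-bin analysis and its bias diagnostic are needed.

## Problem sizes and determinism

Replicate experiments default to 50 cohorts of 18 observers (recovery) and
21 null cohorts of 20 observers, i.e. 420 independent null observers
(selection bias), chosen so that Monte-Carlo SE on the bias ratio is below
0.01 while a full run stays in the minutes range on one core. All
randomness flows from named integer seeds: cohort seeds spawn per-observer
design and outcome seeds, and replicate experiments draw sub-seeds from a
single generator, so every result is bit-reproducible given the seed.

## Known limitations

- The Weibull MLE is a point estimate; no credible or confidence intervals
  on α and β are produced (the downstream analyses use only the derived
  threshold and slope).
- The Hedges' g CI is a normal approximation; at n < 10 its coverage is
  approximate.
- The exclusion rule's sequential recomputation is one defensible reading
  of a two-step criterion; computing both steps on the input cohort gives
  slightly different boundaries for borderline observers.
- Exact-zero grouping differences and argmax ties are resolved by fixed,
  warned conventions (enhancement; lowest bin); they occur with probability
  zero under the generative model.
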