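# Methods

## The problem

A panel of healthcare experts rates a catalog of candidate quality
indicators (here: 29 emergency-department performance indicators in five
factors — Capacity, Temporal, Quality, Outcomes, Financial expenditures) on
a 1–5 Likert scale over one or more survey rounds. The analysis must
decide, per round, which indicators the panel *agrees* on (these are
accepted and removed from later questionnaires), pool the rest into a
revised questionnaire, test whether panel opinion is stable between
rounds, and finally rank the retained indicators. The package implements
three consensus engines over this pipeline and the synthetic-panel
machinery needed to test them, since real multi-round panel responses are
rarely shareable.

## Consensus engines

Let expert *k* rate indicator *p* with Likert level `r_pk`, and let
`w_k = years_k / Σ_j years_j` be the expert's *degree of importance* — the
share of the panel's pooled years of relevant experience. All engines
accept an indicator when its agreement percentage **strictly exceeds** the
round's threshold; ties are rejected.

**DM (classical Delphi).** Agreement is the weighted share of ratings ≥ 4.
The panel median and interquartile range are reported alongside because
percent-above-cutoff alone hides dispersion. Default threshold 75.

**FDM (fuzzy Delphi).** Ratings are mapped to triangular fuzzy numbers
(TFNs) by a five-level scale; the group opinion `g` is the component-wise
weighted mean; agreement is the weighted share of experts whose normalized
Euclidean distance `d(a_k, g) = sqrt(Σ_i (a_ki − g_i)² / 3)` is at most
`δ` (default 0.2).

**MOFD (modified fuzzy Delphi).** Each expert receives a continuous
consistency index

```
C_k = β·S(a_k, g) + (1 − β)·(1 − [γ·d_H(a_k, g) + (1 − γ)·d_inf(a_k, g)])
```

with `S(a,b) = 1 − mean_i |a_i − b_i|` the similarity coefficient,
`d_H` the weighted Hamming distance with component weights
`α = (0.25, 0.5, 0.25)` (the mode carries half the emphasis), and
`d_inf` the support-gap distance `max(0, max(l_a, l_b) − min(u_a, u_b))`,
which is positive only when the two supports are disjoint. Agreement is
`100·Σ_k w_k C_k`. Defaults `β = γ = 0.5` weight similarity and distance,
and Hamming and infimum, equally. Because `C_k` is continuous, MOFD
produces tie-free agreement values where the share-above-cutoff engines
produce ties.

Note that all three engines measure *coherence*, not *importance*: a panel
unanimously rating an indicator 1 has perfect FDM/MOFD agreement. In a
Delphi study that is the intended semantics — consensus on unimportance is
still consensus — but users ranking "critical" indicators should read the
defuzzified group score alongside the agreement percentage.

### Fuzzification scale and defuzzification

The default scale is the standard five-level unit-interval TFN ladder
(1→(0,0,.25), 2→(0,.25,.5), 3→(.25,.5,.75), 4→(.5,.75,1), 5→(.75,1,1))
with half-step overlaps; it is configurable (any mapping whose defuzzified
values strictly increase with the level is accepted). Defuzzification is
the centroid `(l+m+u)/3` by default, with the `(l+2m+u)/4` weighted-mean
convention available. The "infimum distance" has no single canonical
definition in the fuzzy-distance literature; the support-gap reading used
here is zero for any overlapping supports and is deliberately pluggable.

### Thresholds

Published multi-round studies typically tune per-round thresholds to the
observed agreement distribution without reporting the rule. Thresholds are
therefore explicit per-round configuration; when a round has none, the
package falls back to the rounded median of that round's agreement values
(`suggest_threshold`), which splits a bimodal panel cleanly but is
documented as a heuristic, not a standard.

### Missing data and dropout

Missing ratings are kept as missing at parse time and replaced by the
neutral level 3 only when a round dataset is assembled; panel members who
skip a round entirely are retained with all ratings missing and hence
imputed neutral. This mirrors common practice for second-round response
attrition, but it does pull the imputed experts' opinions toward the scale
midpoint — the imputation count is logged so users can judge the impact.

## Sentiment scoring of comments

Per factor, each commenting expert's negative (positive) intensity is the
fraction of their comment's tokens present in the negative (positive)
lexicon (tokens: Unicode-lowercased, punctuation stripped, whitespace
split; no stemming or negation handling). The factor score is the
experience-weighted mean intensity with weights renormalized over the
experts who commented, so factors with few comments are not deflated. The
polarity label is by dominance, with Neutral reserved for exact ties. The
bundled lexicon is a compact, hand-curated list of opinion unigrams common
in healthcare operations feedback; any one-token-per-line word lists can
replace it.

## Stability testing

The Mann-Whitney U test compares the two rounds' per-indicator agreement
values over the shared item set. The package reports U, a z value, and a
two-sided p; the verdict is *stable* when p exceeds the significance level
(default 0.05), i.e. no detectable shift in panel opinion. (Some applied
reports invert this reading and cite a significant difference as evidence
of convergence; the conventional no-shift reading is used here.) A paired
Wilcoxon signed-rank variant is provided for users who regard the rounds
as before/after measurements of the same panel.

p-values come from exact enumeration (via scipy) whenever the combined
sample is ≤ 12 and tie-free. The asymptotic branch uses the
continuity-corrected normal approximation with tie-corrected variance and,
for tie-free data, an Edgeworth kurtosis refinement built on the exact
fourth central moment of U,

```
μ4 = n1·n2·(n+1)/240 · [5·n1·n2·(n1+n2) − 2(n1² + n2²) + 3·n1·n2 − 2(n1+n2)]
```

(derived symbolically and verified against full enumeration for all
n1, n2 ≤ 8). With the refinement the asymptotic two-sided p is within
0.02 of exact enumeration whenever both groups have at least 3 members;
for groups of size 1–2 the U distribution is too discrete for any
normal-series approximation (at n1 = 1 it is exactly uniform), which is
why the exact branch exists and is preferred at small n.

## Ranking

Retained indicators are ordered by the agreement value from the round in
which each was accepted (descending); exact ties break by the defuzzified
group score (descending), then catalog order — a deterministic permutation
with 1-based ranks. Cross-round agreement values are treated as directly
comparable, which is how multi-round studies print a single final ranking;
thresholds differing between rounds make this an approximation users
should be aware of. `compare_conditions` reports side-by-side top-k lists
and their overlap for rankings obtained under different operating
conditions (e.g. normal operations vs a patient surge).

## Synthetic panels

The generator draws a panel of `n_experts` (default 45) with integer
experience uniform on 3–11 years, and per indicator a latent importance
`θ_p ∈ [0,1]` and dispersion `σ_p > 0`. A rating is
`clamp(round(1 + 4(θ_p + ε)), 1, 5)` with `ε ~ N(0, σ_p²)` — a transparent
discretized-Gaussian mechanism chosen over an ordinal-logit for
inspectability. Missingness (default 2%) and round-2 dropout (default
48.89%, emulating a ~51% second-round response rate) are independent coin
flips. One `numpy` Generator is consumed in a fixed order (panel →
ratings per round, expert-major → missingness → dropout → comments), so a
(config, seed) pair reproduces a study bit-for-bit.

Ground-truth labels derive from the generating parameters alone: accept
iff `θ ≥ 0.85` and `σ ≤ 0.15`; reject iff `θ ≤ 0.40` or `σ ≥ 0.45`;
otherwise indeterminate (excluded from recovery scoring). The standard
recovery benchmark pairs 10 accept-type (θ = 0.9, σ = 0.1) with 10
reject-type (θ = 0.3, σ = 0.5) indicators: under MOFD with the median
threshold fallback the two groups separate by ~5 agreement points
(≈ 91+ vs ≤ 86 across seeds), so classification accuracy is routinely
100%. The stability benchmark re-simulates a second round with unchanged
θ and dropout disabled — neutral-imputed dropouts would shift the round-2
distribution, which is precisely not the unchanged-opinion premise being
tested.

What the generator does *not* model: inter-expert correlation,
specialty-specific biases, item non-response that depends on the
indicator, or learning between rounds. Passing recovery tests therefore
show the engines detect location/dispersion structure under clean
conditions, not that they are robust to the full messiness of real panel
data.

## Numerical conventions

All reals are double precision; validity checks use absolute tolerance
1e-9. Weights must sum to 1 within 1e-6. Percentages printed in reports
are rounded half-up to 2 decimals (matching how survey tables are
printed); internal computations are never rounded. Aggregated TFNs clip
float dust so `l ≤ m ≤ u` holds exactly. Degenerate inputs (empty panels,
single-expert indicators, zero total experience, empty lexicons) raise
`ValueError` rather than returning sentinel values.

## Problem sizes used in the shipped benchmarks

The test suite and the reproduction script use 200 replicates for the
recovery benchmark and 100 for the stability benchmark, each on a
45-expert, 20-indicator panel — large enough that the binomial noise on
the reported rates is ~1–3 percentage points, and small enough to run on
a laptop in about a minute and a half.

## Known limitations

* The published study's raw responses are unavailable, so its agreement
  percentages, sentiment magnitudes, and U/z statistics cannot be
  recomputed; the bundled tables regression-test the filtering, retention,
  ranking, and labelling logic instead.
* The second-round published table leaves FDM cells blank for several
  items FDM had not accepted in round 1; the fixture mirrors the table
  (NaN) and those cells simply never pass a threshold.
* The MOFD consistency index is generous to mild disagreement (two experts
  at opposite scale ends still score ≈ 0.65); threshold choice, not the
  index, carries most of the selectivity.
* Lexicon sentiment scoring is unigram-only: negation ("not good") and
  domain idioms invert or escape it.
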