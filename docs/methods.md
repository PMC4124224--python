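# Methods

## Model and assumptions

`ecovuln` builds a composite vulnerability index for $n$ regions scored on
$m$ indicators. The method is purely data-driven: weights come from the
information content of each indicator column, not from expert judgement.
Its assumptions are modest but worth stating:

- Indicators are compared after z-scoring, so only the *pattern* of values
  across regions matters, never the raw scale or unit. Any positive affine
  rescaling of a column leaves every downstream quantity unchanged (this is
  property-tested to 1e-9).
- The entropy of a column is computed on proportions of the *translated*
  z-scores, not the raw data. Consequently the weights respond to the shape
  of the standardized column (including its skewness and the position of
  its minimum relative to the translation amplitude), not to the raw
  coefficient of variation.
- Each indicator is either benefit-type ("positive": larger is better) or
  cost-type ("contrarian": larger values signal more vulnerability
  pressure). The orientation decides whether $p_{ij}$ or $1 - p_{ij}$
  enters the composite index.

## Pipeline and numerical choices

1. **Standardization** uses the population standard deviation
   (divide by $n$). This is the convention that reproduces the reference
   case-study tables and is also the natural choice when the $n$ regions
   are the entire population of interest rather than a sample. Matrices
   need $n \ge 2$; a single observation has a degenerate population SD and
   is rejected at construction. A constant column (SD 0) raises an error by
   default; an explicit `drop` policy removes it with a logged warning,
   because silently dropping a column changes every weight.
2. **Translation amplitude** $A$ must satisfy $A > |\min x_{ij}|$ whenever
   any z-score is negative. The default rule picks the smallest multiple of
   0.1 strictly greater than $|\min x_{ij}|$ (e.g. $|{-2.1209}| \to 2.2$,
   $|{-1.0}| \to 1.1$); a user-supplied $A$ overrides it. Small admissible
   $A$ maximizes discrimination: as $A \to \infty$ every proportion tends
   to $1/n$, entropies tend to 1, and the weights collapse to equality.
   `amplitude_sensitivity` makes this decay inspectable per amplitude.
3. **Entropies** are clamped into $[0, 1]$ only against floating-point
   overshoot below $10^{-12}$; anything larger is reported as an error
   (it means the proportion columns do not sum to 1). Proportions are
   strictly positive by construction; should a zero ever reach the entropy
   stage (e.g. through a hand-built proportion grid) the $0\ln 0 = 0$
   convention applies with a logged warning.
4. **Aggregation.** The default `weighted_complement` mode computes
   $V_j = \sum_{i \in \text{pos}} w_i p_{ij} + \sum_{k \in \text{con}} w_k (1 - p_{kj})$.
   With all indicators contrarian its region-mean is exactly $(n-1)/n$ for
   *any* weights summing to 1 (each proportion column sums to 1), which the
   tests assert to 1e-9; this identity is also what ties the mode to the
   reference case-study results. The alternative `literal_ratio` mode
   computes the quotient of the positive part over the contrarian part; it
   requires both orientation groups to be non-empty and does **not**
   reproduce the case-study numbers — it exists as an explicit, documented
   opt-in.
5. **Ranking** sorts by descending $V$ with stable tie-breaking by input
   order, so results are deterministic and auditable. The package reports
   the descending order without imposing an interpretation of which pole is
   "most vulnerable"; the index is a relative discrimination device, not a
   calibrated severity scale, and no class thresholds are defined.
6. **Rounding** (`report_decimals`, default 4) applies to report files
   only; every computation runs at full double precision.

## The packaged case study

The western-Jilin fixture (9 districts/counties × 10 indicators) ships with
the package together with its catalog. All ten indicators are encoded
cost-type: each one (water shortage, drought/flood frequency, degradation,
salinization, desertification) drives vulnerability upward. Under the
default mode with $A = 2.2$ the pipeline reproduces the published
standardized, translated and proportion tables at their printed 4-decimal
precision, the composite extrema (max at Fuyu, min at Tiaobei) within the
rounding chain of those tables, and the full ranking — which is, on this
fixture, identical under entropy weights and equal weights. The source
index list skips the name of the 9th indicator; the fixture keeps it
positionally with a placeholder label. Full-precision extrema (0.9382 /
0.8644) differ from the published 0.9376 / 0.8636 by under 0.001 because
the published values were evidently recomputed from the 4-dp rounded
intermediate tables; this package never rounds mid-pipeline.

## Synthetic data

`generate_matrix` draws each indicator column i.i.d. across regions from a
log-normal distribution parameterized by its mean (`base_scale`) and
coefficient of variation (`dispersion`): $\sigma^2 = \ln(1 + c^2)$,
log-mean $\ln\mu - \sigma^2/2$. Log-normality guarantees strict positivity
(so the linear-scaling comparison normalization is exercisable) and gives
the heavy-tailed, scale-heterogeneous look of real indicator tables, at the
case-study's shape by default (9 × 10).

What it emulates — and what it does not: the generator reproduces only the
*statistical* shape the method consumes (small $n$, positive values,
controllable per-column dispersion). Columns are independent, with no
spatial correlation between neighbouring regions, no cross-indicator
correlation and no climate or hydrology dynamics. Passing tests therefore
demonstrate the algebraic and statistical correctness of the pipeline, not
that the index captures real ecological vulnerability.

One property deserves a note. Higher cross-region dispersion concentrates
an indicator's *raw* shares and lowers its entropy, so the high-dispersion
column should win the weight — and does, in 100/100 seeded draws, when the
entropy-weighting stage is applied to the generated positive columns
directly. After z-scoring the effect disappears by design (every column
then has variance 1), so the test measures the property at the weighting
stage, where it is well-defined.

A second empirical observation: duplicating one region's row perturbs every
entropy (both $k = 1/\ln n$ and all proportions change), so on a 9-row
matrix the *full* weight ordering is not invariant — near-tied weights
swap. The stable property is high rank agreement (Spearman ρ > 0.85 for
every possible duplicated region on the packaged fixture), and that is what
the suite asserts.

## Problem sizes

All shipped computations are desk-scale: the case study is a 9 × 10 matrix
and runs in well under a second; property tests use random matrices up to
8 × 5, the dispersion property 100 draws at 50 × 2, and the generator's
moment check one draw at 2000 × 2.

## Known limitations

- No missing-value handling: cells must be finite; imputation is out of
  scope and rejected explicitly.
- No robust standardization (median/MAD), winsorization or outlier
  handling; a single extreme region can dominate a column's z-scores.
- The comparison normalizations (`range`, `linear_scaling`, `vector`) are
  utilities for side-by-side inspection only and never feed the default
  pipeline.
- No subjective or hybrid weighting (AHP, Delphi, combined schemes) and no
  vulnerability class bands.
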