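# Methods

## Signal carrier and units

The signal passed between transcriptional gates is promoter activity,
treated as a proxy for the RNA polymerase flux leaving a promoter. All
packaged parameters are in **RPU_G**: fluorescence normalized to a
constitutive reference promoter integrated in a genomic landing pad,

    activity = (<YFP>_measured − <YFP>_blank) / (<YFP>_ref − <YFP>_blank),

with the blank being wild-type autofluorescence. Negative
background-subtracted values are clipped to 0 with a warning rather than
raising, since OFF states routinely sit at the autofluorescence floor.
Three conversion constants tie RPU_G to other scales and live in the
library file so they can be re-calibrated:

| constant | default | meaning |
|---|---|---|
| `flux_per_rpu_per_dna` | 0.019 | RNAP/s per RPU per DNA copy |
| `landing_pad_copy_number` | 3.5 | effective copy number of the (origin-proximal) landing-pad site |
| `rpug_per_rpu` | 6.33 | divisor mapping genome-referenced RPU_G to plasmid-referenced RPU |

So 1 RPU_G = 0.019 × 3.5 ≈ 0.067 RNAP/s. The 6.33 divisor is treated as
an opaque calibrated constant.

## Gate model

A NOT gate is a repressor gene plus its output promoter; its steady-state
response to input promoter activity x is the repressive Hill function

    y(x) = y_min + (y_max − y_min) / (1 + (x/K)^n),

strictly decreasing, with y(0) = y_max. The packaged library carries six
TetR-family gates with their genome-measured parameters, each gate also
holding a linear growth model (relative OD600 = intercept + slope·x,
packaged as neutral (1, 0) because per-gate coefficients are not published
— users fit their own with `fit_growth`) and a cytometry noise CV
(packaged default 0.3, a typical single-cell lognormal spread; it only
affects the distribution stand-in, never the median predictions).

### Hill fitting

`fit_hill` minimizes squared residuals in log10(y). The OFF state is one
to two decades below the ON state; a linear-space objective would fit the
ON plateau and ignore y_min entirely, while the log objective weights the
decades comparably. Bounds: y_min > 0, y_max > y_min (enforced by fitting
the span y_max − y_min), K > 0, n ∈ (0.5, 8]. Five deterministic starts
derived from the data (min/max output, geometric-mean input, the
mid-range crossing point, n ∈ {1, 1.5, 2, 4, 6}) guard against local
minima; the lowest-cost candidate is returned. A fit is flagged
non-converged when the optimizer fails, the fitted dynamic range collapses
below 0.1% (no measurable response), or n pins at a bound. Preconditions:
≥ 5 distinct inputs spanning ≥ one decade, all outputs positive. On
noiseless 12-point curves from any packaged gate the generating parameters
are recovered to machine precision.

Medians summarize gate/circuit cytometry populations (lower-median
convention for even counts); geometric means are used only in the
two-reporter terminator assay. Both follow the respective measurement
protocols.

## Circuit engine

### Synthesis

Truth tables (arity 1–4; rows in binary counting order, input 1 most
significant; hex codes are most-significant-row-first) are minimized to a
product-of-sums with exact Quine–McCluskey (via `sympy.logic.POSform`,
exact and fast at these arities) and converted by De Morgan into
NOR/NOT-only hardware: each sum clause C becomes its complement
¬C = NOR(literals), and the conjunction of clauses becomes NOR(¬C₁ … ¬Cₘ).
NOR fan-in is capped at 2 — a physical gate integrates at most two input
promoters — with wider sums decomposed through OR = NOT∘NOR chains. NOT
gates on the same source are shared. Every synthesized netlist is verified
by exhaustive Boolean evaluation against the requested table before it is
returned.

### Steady-state prediction

Sensors emit y_min (input bit 0) or y_max (bit 1). Gates are evaluated in
topological order; a two-input gate's effective input is

- **split** semantics (two copies of the repressor gene, each driven by
  one input promoter, in different genomic loci): x_eff = x₁ + x₂;
- **tandem** semantics (two promoters in series before one repressor
  gene): x_eff = x_down + α·x_up, where α ∈ [0, 1] attenuates the
  upstream promoter to model roadblocking by repressor bound at the
  downstream promoter. α = 1 is the ordinary additive model and makes the
  two semantics exactly equivalent (a tested invariant). No published
  closed form exists for the non-additive tandem model, so a single
  attenuation scalar is exposed rather than hard-coding one.

**Total RNAP flux** per state = Σ over gates of x_eff + Σ of sensor output
activities (sensors counted exactly once); reported in RPU_G, RPU and
RNAP/s. **Growth score** per state aggregates each gate's clipped linear
growth factor clip(intercept + slope·x_eff, 0, 1); the default
aggregation is the product (the simplest multiplicative-burden model),
with min-over-gates available via `EngineConfig(growth_aggregation="min")`
since the aggregation rule is not otherwise pinned down.

### Assignment search

`assign_gates` enumerates injective repressor→gate assignments
exhaustively (≤ P(6, g) ≤ 720 with the packaged library), discards those
whose worst per-state growth score falls below the cutoff (default 0.75),
and maximizes the **circuit score** = min(ON-state outputs) /
max(OFF-state outputs); ties break to the lexicographically first
repressor tuple. If nothing survives the growth filter the best infeasible
candidate is returned with a `growth_infeasible` flag rather than failing,
so the caller can still inspect the design.

The predicted single-cell distribution of a state is a lognormal with the
predicted median and the output gate's noise CV
(σ_log = √ln(1 + CV²)) — a deliberately simple stand-in sufficient for
separability analysis, not a mechanistic noise model.

## Terminator insulation

Terminator strength T_S is the fold-reduction in transcription across a
terminator; readthrough = 1/T_S. Two assays:

- **Cytometry**: T_S = (⟨GFP⟩/⟨RFP⟩)_term / (⟨GFP⟩/⟨RFP⟩)_ref on
  autofluorescence-subtracted geometric means, GFP upstream and RFP
  downstream of the candidate in an inducible two-reporter construct
  (T_S = 30 ⇒ 97% blocked; T_S = 6 ⇒ 17% readthrough). Invariant to
  common rescaling of both channels.
- **Coverage**: readthrough = mean(25-bp window directly downstream, in
  the direction of transcription) / mean(25-bp window directly upstream)
  on a strand-specific per-base profile normalized to
  reads/total-mapped-nt × 10⁹. The windows abut the annotated boundaries
  (1-based inclusive, GFF3 convention) without overlapping the terminator
  body; minus-strand annotations mirror the windows. A pseudocount of 0.1
  normalized units on both means prevents division by zero in silent
  regions; it is configurable, and it bounds the smallest measurable
  readthrough at roughly 0.1/depth — at the generator's default depth of
  1000× it biases a true readthrough of 0.001 by about +10%, within the
  25% recovery band the test suite enforces.

The after/before ratio is a readthrough (small = strong); the reciprocal
strength is reported alongside so both assays share one scale, and
ranking (`rank_terminators`) sorts by descending strength with stable
ties and an exclusion set for previously used parts. Bidirectional double
terminators destined to flank a landing pad must pass strictly
T_S > 105 forward and T_S > 25 reverse.

### att-site off-target screen

An integrase att site is rejected if **any** of three criteria fires:
(i) an exact shared substring of ≥ 28 nt with the genome on either strand
(a surrogate for a megablast hit); (ii) best local alignment covering
> 30% of the att site; (iii) best local alignment with Karlin–Altschul
E-value < 0.1. Alignment is Smith–Waterman (Biopython PairwiseAligner,
match +2 / mismatch −3 / gap open −5 / extend −2) with blastn-like
λ = 0.625, K = 0.41 and a two-strand search space. This in-package
surrogate is not guaranteed to reproduce NCBI hit lists; because the test
is a conservative reject-if-any filter, occasional extra rejections are
acceptable and missed marginal hits are the only risk, mitigated by the
exact-seed criterion.

## Synthetic data

The generators emulate the study conditions, not arbitrary data: 30,000
cytometry events per sample (typical acquisition), lognormal populations
parameterized by median and CV (cytometry fluorescence is right-skewed;
the lognormal is median-unbiased so summary statistics match targets
exactly in expectation), 12-point log-spaced dose–response grids across
the driving sensor's dynamic range with three lognormal-noise replicates
(mirroring the 12-concentration, three-day characterization design), and
piecewise-constant expected coverage with Poisson per-base counts and
multiplicative step drops at planted terminators (default depth 1000×).
All generators are pure functions of (parameters, seed) and are
byte-reproducible.

What the synthetic data does **not** model: cytometry gating artifacts and
instrument autofluorescence, non-lognormal population structure
(bimodality during switching), read-level sequencing error or mappability
variation in coverage, and promoter-context effects on gate response.
Passing tests therefore demonstrate correctness of the estimators and the
engine under the stated statistical assumptions, not robustness to every
artifact of real instruments.

## Problem sizes in the test suite

Exhaustive synthesis checks cover all 270 non-constant truth tables of
arity ≤ 3; readthrough recovery uses 100 seeds at depth 1000× across
planted readthroughs spanning four decades on an 1,800-bp replicon;
Hill-recovery suites use the 12-point grid throughout. These sizes make
the full suite run in well under a minute while keeping every estimate's
Monte-Carlo error far below the tolerance being asserted.

## Known limitations

- Steady state only: no dynamics, no state-dependent sensor crosstalk.
- The two-point sensor model (OFF/ON) ignores intermediate inducer
  concentrations unless a dose_response entry is supplied.
- The growth aggregation rule (product vs min) and the tandem attenuation
  α are modeling choices exposed as parameters, not measured quantities.
- The off-target screen is a conservative surrogate for BLAST, not a
  replacement.
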