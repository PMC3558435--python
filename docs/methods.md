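# Methods

## The estimator

The population of a displaced-persons site is estimated as

```
N̂ = C × x̄ × m
```

where `C` is the consensus count of residential structures visible on a
very high resolution satellite image, `x̄` is the pooled occupancy (people
per household or per structure) from a screened literature registry, and
`m ≥ 1` is a households-per-structure multiplier (1 unless the site's
residential structures are known to hold several households each). The
product is rounded half away from zero to a whole person count, as is
every integer the package reports; half-away (not banker's) rounding is
forced by internal consistency of the published tables the fixtures
reproduce (a consensus of 1418.5 must print 1419).

**Assumptions.** Every residential structure is visible and marked exactly
once; occupancy reported in the literature transfers to the site at the
analysis date; household-based reports can be mapped to structures by a
single site-level multiplier. Each assumption fails in characteristic
ways — connected roofs and collapsed buildings in dense urban sites break
the first, stale or implausible reports the second — and the validation
module exists precisely to quantify the resulting error where a reference
figure is available.

## Duplicate counts and agreement

Counting is organised on a square grid (default cell 200 m, matching the
counting protocol the method was validated with) overlaid from a
configurable origin. Cells are half-open `[edge, edge+cell)` in both axes,
zero-based from the origin, so each mark lands in exactly one cell and
per-cell counts sum to the global count. Marks are taken as-is in the
source file's coordinate system; no reprojection is attempted.

The residential/other split is driven entirely by a configured
category→residential map: analysts demonstrably disagree about marginal
structures (latrines, showers, sheds), so the tool refuses to guess and
errors on any unmapped category.

Consensus is the arithmetic mean over however many analysts counted
(single-analyst sites are legal; so are crowd-sourced many-analyst
counts). Agreement between two duplicate counts is `|a−b|` and
`100·|a−b|/max(a,b)` to one decimal — the larger count as denominator
reproduces 29 of the 33 packaged agreement cells; the four it cannot
reproduce are flagged `known_discrepancy` in the fixtures (one cell
printed against the smaller denominator, three cells adjusted to a
comparable area by an undocumented rule, for which a per-analyst
comparable-area override hook is provided).

## Evidence hierarchy and pooling

Reports enter the registry with explicit enumerations for the three rubric
attributes; the tool never infers "same crisis region" from geography,
keeping every scoring decision auditable in the registry itself. Point
values are loaded from a packaged, versioned rubric file
(`data/rubric_v1.json`) so the hierarchy can be refined without code
change.

Eligibility: a report must carry a collection date within 10 years before
the analysis date (boundary inclusive, whole-day arithmetic; undated
reports are excluded rather than guessed, since the window cannot be
verified), its full text must have been available with primary occupancy
data, and for urban sites it must reflect urban populations. Every
exclusion is logged with all violated rules; the filter is idempotent.

Representativeness uses the registry's provenance level but demotes a
"current" report whose date falls in the 3–10 year window to the
previous-period level (4 points). "Within 3 years" is boundary-inclusive.
A survey is "large" (8 points) only on strict inequalities — >200
households for simple/systematic sampling, >400 households *and* >20
clusters for cluster sampling — and any noted technical flaw demotes it
to 6.

Pooling is the score-weighted mean at full floating precision. A
*compat* mode rounds the pooled occupancy to one decimal before
multiplying; the published tables print one-decimal occupancies and their
estimates are exactly the products of those printed values, so compat mode
reproduces them bit-exactly while default mode carries full precision for
new analyses. The consensus count is rounded before multiplication (the
alternative — rounding only at the end — reproduces the same published
estimates, but rounding the count first is what the printed
count×occupancy products show).

Mixed-unit registries are pooled as-is and the multiplier applied once to
the pooled mean; per-report unit conversion would require per-report
multipliers that are generally unknowable. No confidence interval is
computed by default — with one to eleven reports per site, sparsity makes
a meaningful interval hard to defend — but a clearly flagged nonparametric
resampling extension (`resample_occupancy_interval`) is available.

## Validation

Precision is the signed difference to the reference figure with the
reference as denominator, reported to one decimal. Banding (good <10%,
moderate 10–30%, poor >30%) operates on the integer-rounded absolute
percent: the published classification places a site at +30.4% in the
moderate band, which is only consistent with rounding to the integer
first. The raw one-decimal percent is always reported alongside the band.

## Synthetic data

The simulator fabricates what real runs consume, from a known truth:

* **Sites** — structures per category placed uniformly, on a jittered
  block lattice (planned camps), or in Gaussian clusters (informal slums);
  per-structure occupants drawn from a discretized gamma with mean and
  dispersion (coefficient of variation) per category, minimum one occupant
  — positive and right-skewed like real household sizes. Dispersion 0
  gives a degenerate, exactly checkable site.
* **Analysts** — per-category detection probability (missed structures),
  Poisson false positives at a stated rate per true structure placed
  uniformly in the bounding box (debris and straw bales read as
  dwellings), and a category-confusion matrix. The residential flag of a
  mark follows its *observed* label, as it would for a real analyst.
* **Report banks** — evidence tiers, each with a count, a multiplicative
  bias and a lognormal noise factor normalized to mean one (so noisy
  tiers remain unbiased in expectation), carrying the rubric attribute
  levels and a collection date realising its tier.

All randomness flows through explicit seeds (no global state); the
recovery experiment spawns per-replicate seeds from one master generator,
so runs are reproducible end to end. Under identity confusion and
residential false positives, the expected estimate is
`detection × (1 + fp_rate) × bias × truth`, which the recovery experiment
verifies at Monte-Carlo tolerance: the default checks use 100 replicates
of a 500-structure site (standard error of the mean relative error
≈ 0.2%), sizes chosen to make the binomial oracle sharp at desk scale.

**What passing synthetic tests do not show.** The simulator has no
imagery: it cannot represent visibility limits (tree cover, connected
roofs, multi-storey buildings), analyst fatigue or correlated errors
between analysts viewing the same hard image, nor literature whose bias is
correlated with its evidence tier in unknown ways. Recovery results bound
arithmetic and plumbing errors, not the field accuracy of the method.

## Numerical and degenerate-input choices

* All integer reporting: round half away from zero (decimal arithmetic,
  not float `round`). Percents and occupancies: one decimal, same rule.
* Two zero counts agree perfectly (0%); agreement is undefined on negative
  counts and errors.
* An empty registry aborts the pipeline at the estimator stage with
  "no occupancy information"; zero total weight is impossible because
  scores are bounded below by 2.
* An empty mark set tabulates to an empty (zero) table; consensus over no
  analysts errors.
* Grid policy for out-of-extent marks is explicit: strict (error with
  coordinates), clip, or flag.

## Known limitations

* The per-attribute decompositions behind the published information
  indices are not public; only index arithmetic, not those
  decompositions, is asserted against the fixtures.
* The comparable-area adjustment behind one site's footnoted agreement
  cells is undocumented; the override hook supports the mechanism but the
  printed cells are not asserted.
* The estimator is a point estimate by design; the resampling interval is
  an extension and inherits the registry's sparsity.
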