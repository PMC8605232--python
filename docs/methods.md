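# Methods

## Geometry and bird apportionment

A house of inner width $W$ contains $r$ tiered-structure rows and $r+1$
aisles of measured widths $a_1,\dots,a_{r+1}$ (left wall to right wall,
relative to the entrance door). Structure rows are assumed equally wide;
their common width is derived as $s = (W - \sum_i a_i)/r$ rather than taken
from a reported, rounded figure, because the per-transect bird counts are
only self-consistent with the derived value (a 2-decimal rounded $s$ shifts
counts by several birds in a 7,800-hen house). The reported value is kept as
a cross-check with a 0.01 m tolerance.

Transect widths partition $W$ exactly: wall transects take $a + s/2$,
central transects $a + s$. The flock is apportioned proportionally to width,
$\hat n_i = \mathrm{round}(N w_i / W)$, with **half-away-from-zero**
rounding — the convention is identifiable from the data, since a four-transect
house with equal aisles yields exact halves (1562.5/2187.5) that banker's
rounding would split differently. A relative epsilon (1e-9) guards the
comparison against binary floating-point shortfall on exact halves.
Apportionment is purely width-proportional; house length never enters (every
transect spans the full length) and no per-tier area accounting is done.

Stocking density (birds per m² of usable area) is **truncated**, not
rounded, to two decimals; the published six-flock table contains two cells
(7700/990, 7840/915) that discriminate the two conventions and both are
consistent only with truncation.

Vertical levels are coded 1–4 = litter, first tier, second tier, top tier.

## Scoring schemes and prevalence

The whole-flock transect scheme has 12 binary indicators; a hen may be
counted under several at once, so indicator counts are not disjoint. The two
graded schemes score a fixed sample (default $n=50$) on 0/1/2 severity
scales (plus 0/1 wound scales in one scheme); within one indicator the
levels are mutually exclusive. Indicator codes are stable snake_case
identifiers (`fl_head`, `wounds_feet`, `enlarged_crop`, …); the descriptive
definitions ride along as metadata.

Transect prevalence is $100\,k/\hat n_i$ with the apportioned $\hat n_i$ as
basis. Fixed-sample prevalence is $100\,k/n$ with
$\mathrm{SE} = 100\sqrt{\hat p(1-\hat p)/(n-1)}$: the $n-1$ denominator is
deliberate — at $n=50$, $p=24\%$ it gives 6.1 where the $1/n$ form gives
6.0, and the $n-1$ form reproduces the published cells. Aggregation across
subunits (flocks, observers, transect kinds, vertical levels) reports the
mean of subunit prevalences and the standard error of that mean (ddof = 1);
a single-subunit group reports SE 0 with an explicit `se_defined = False`
flag. Whole-flock descriptive items (beak trimming, antagonistic incidents,
flightiness ∈ {calm, cautious, flighty}, birds needing care, producer
mortality) are validated and echoed verbatim; `"unknown"` is a legal
mortality value and is never coerced to a number.

## Binomial GLM

Counts are aggregated to cells (e.g. flock × observer × transect) with
successes $k$ out of trials $m$ and modeled with a fixed-effects
binomial-logit GLM. Only fixed factors are supported — the comparisons this
package performs list no random effects — with treatment coding and the
first level in sort order as reference; all reported inference is invariant
to that choice (property-tested).

The fit is IRLS with a per-iteration monotone log-likelihood guarantee
(step-halving fallback), convergence at max |Δβ| < 1e-8 or 100 iterations,
and an additional stop on a likelihood plateau (|Δℓ| < 1e-12), which is how
separated fits terminate: coefficients beyond ±10 on the logit scale are
flagged as separation and their contrasts as non-estimable. Responses with
no variation (no affected birds anywhere, or all affected) are not fitted at
all; they carry a `no_variation` flag and are reported descriptively.
Rank-deficient designs raise an error naming the aliased columns; factors
with a single observed level are dropped with a warning.

Factor significance uses the likelihood-ratio chi-square of the nested fit
without the factor (df = levels − 1). The original field analyses were run
in a mixed-model procedure whose default tests are F-type; the printed P
values of those analyses are therefore not numeric targets here, and the
likelihood-ratio test is validated instead by construction: brute-force
likelihood-grid agreement on small designs, type-I calibration under the
null, and reference-coding invariance.

Pairwise comparisons of factor least-squares means (balanced averages over
the other factors' levels, on the logit scale) are Tukey-adjusted via the
studentized-range distribution with residual df = cells − parameters; when
the fit is saturated (df ≤ 0) the normal approximation is used with a
warning. With $k=2$ levels the adjusted P equals the unadjusted two-sided P.
The compact letter display is built by greedy insertion over the LS-means
sorted descending (ties broken by level name): a level joins every existing
group it is non-significant with, else opens a new group; levels sharing no
letter differ at α.

Spearman correlation assigns average ranks to ties and tests with the
$t$-approximation on $n-2$ df (delegated to `scipy.stats.spearmanr`;
a naive ranking oracle cross-checks it in the tests). Zero rank variance
leaves ρ undefined with a flag rather than an exception. Method-agreement
matrices require ≥ 3 flocks per method pair (pairwise deletion) and carry
a unit diagonal; the three cross-scheme comparable indicators are severe
head feather loss, severe back feather loss, and dirtiness at the mild
level of the graded schemes.

## Simulator

The generator emulates the conditions the scheme was developed under:
~7,500-hen flocks, houses with 2–4 transects, 4 vertical levels, transect-
scheme true prevalences of 0–1 % and graded-scheme prevalences up to ~40 %.

* **Indicators** are independent Bernoulli per bird and indicator
  (multi-label). Real indicators co-occur within birds; no dependence
  structure is published, so independence is the default and a shared
  per-bird frailty hook is left to future work.
* **Placement** is multinomial over transect widths (the homogeneity null).
  `wall_bias` multiplies the wall-transect weights of affected birds only,
  reproducing — as a simulated property, not a claim about real hens — the
  reported tendency for dirtier birds and breast feather loss to concentrate
  along walls. No quantitative magnitude is published; `wall_bias` is a free
  parameter and is never calibrated to the field tables.
* **Observation**: counted ~ Binomial(affected present, sensitivity) +
  Binomial(unaffected present, fp_rate), independent per observer. Error is
  uniform across indicators by default (the one reported observer effect,
  on dirtiness, motivates an optional per-indicator override at the config
  level by simulating indicators separately).
* **Graded sampling** is simple random sampling without replacement;
  an affected sampled bird scores 2 with probability π₂ (default 0.5), else
  1. π₂ affects only graded-scheme emulation, never transect counts.
* **Randomness**: one global seed drives an independent
  `(seed, operation-name)` stream per operation (CRC-32 of the name mixed
  into a `SeedSequence`), so adding operations never perturbs existing
  draws and identical configs reproduce byte-for-byte.

What the simulator does **not** capture: diurnal movement and feeding
cycles, vertical-level preference dynamics, indicator co-occurrence,
age/strain effects, and observer drift over time. Passing recovery and
power checks therefore demonstrate internal statistical consistency of the
sampling designs, not field validity.

## Power experiments

`power_experiment` draws one flock from each of two configurations that
differ only in true prevalence, assesses both with the chosen design
(whole-flock transect counts, or a 50-bird sample scored at level ≥ 1), and
tests the flock factor with the likelihood-ratio chi-square; power is the
rejection fraction with its Monte-Carlo SE. Replicate flocks are seeded by
(seed, replicate) only — not by method — so running both methods with one
seed is a paired experiment on identical flocks. Under identical
configurations the procedure doubles as a type-I calibration and comes out
at the nominal α within Monte-Carlo error.

Problem sizes used by the test suite and the reproduction script — 400
replicates for calibration and power, 2,000 for estimator recovery, 200 for
the wall-gradient check — were chosen to keep Monte-Carlo error small
relative to the tested margins (3 MC-SE bands throughout).

## Reference data

`aviary_transect.reference` transcribes the published six-flock layout,
density, graded-cell and descriptive tables used as golden inputs. One
flock's aisle widths are typographically garbled in the source table; the
shipped values are a reconstruction that reproduces the printed bird counts
exactly, but that flock is excluded from all golden comparisons. One
published SE cell (32 ± 6.6) computes to 6.664 under the $n-1$ formula;
golden SE checks therefore use a one-unit-in-the-last-decimal tolerance
(≤ 0.1), which every cell satisfies.

## Known limitations

* Equal structure-row widths are assumed; houses with unequal rows would
  need per-row widths (the derivation generalizes, the data format does not
  yet).
* No overdispersion or random-effect machinery: prevalences are modeled as
  pure binomial counts within cells.
* The GLM's likelihood-ratio P values are asymptotic; with very sparse
  counts (expected successes < ~5 per cell) they are approximate, which is
  visible as mild conservatism in the type-I calibration.
* Free-range/outdoor areas and 3-D tier geometry are out of scope.
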