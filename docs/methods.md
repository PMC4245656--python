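# Methods

## Model

A chemical's priority is the product of two normalized composite
indicators, one for intrinsic hazard and one for workplace exposure
potential. The multiplicative form encodes the assumption that risk
requires both: a potent carcinogen nobody handles, and a ubiquitous but
benign solvent, should both rank below a moderately toxic, widely handled
substance. Compared with additive schemes, the product also makes the
ranking insensitive to monotone rescaling of either axis only through the
normalization step — hence the normalization convention matters and is
documented below.

### Hazard composite (0–100 raw points)

Nine GHS-derived endpoints are scored from their hazard class and summed.

| Endpoint | classes → points | max |
|---|---|---|
| T1 acute toxicity (oral, dermal) | 1→6, 2→4, 3→2, 4→1 | 6 |
| T2 acute toxicity (inhalation) | 1→5, 2→3, 3→2, 4→1 | 5 |
| T3 irritation (skin, eyes) | 1→6, 2→4 | 6 |
| T4 sensitization (skin, respiratory) | 1→9 | 9 |
| T5 aspiration hazard | 1→5, 2→3 | 5 |
| T6 germ cell mutagenicity | 1A→20, 1B→16, 2→12 | 20 |
| T7 reproductive toxicity | 1A→20, 1B→16, 2→12 | 20 |
| T8 carcinogenicity | 1A→20, 1B→16, 2→12 | 20 |
| T9 target organ toxicity (repeated) | 1→9, 2→7 | 9 |

*No data* scores the endpoint maximum — a deliberate precautionary stance:
an untested chemical is treated like a top-class one until data say
otherwise. *Not classified* and *not applicable* score 0. The CMR block
(T6–T8) sums to at most 60, the other six endpoints to 40. Target organ
toxicity from a *single* exposure is not an endpoint: such classifications
derive from animal test conditions unrepresentative of workplaces.

Labels that do not exist for an endpoint (class 4 irritation, class 3 for
a CMR endpoint, undivided class 1 for CMR, subdivided 1A/1B elsewhere) are
validation errors, not zero-scoring cells. Where a source scheme does not
subdivide CMR class 1, the CSV reader maps a bare `1` to `1A` —
conservative, consistent with the merge rule.

**Conservative merge.** When several sources classify the same endpoint,
the highest-scoring class wins. Point ties are broken by a documented
severity order: a definite class beats *no data* beats *not classified*
beats *not applicable*; among definite classes, lower class number first,
A before B. The merge is idempotent, order-independent, and never returns
a class scoring below any input (exhaustively tested over all valid label
pairs).

### Exposure composite (0–100 raw points)

Five indicators, banded by fixed cut-points and scored:

| Indicator | Class 1 / 2 / 3 / 4 / 5 criteria | points (C1…C5) |
|---|---|---|
| E1 handling volume (t/y) | >1000 / 10–1000 / 1–10 / 0.1–1 / <0.1 | 30, 24, 18, 12, 6 |
| E2 workers | >300 / 100–300 / 50–100 / 5–50 / <5 | 10, 8, 6, 4, 2 |
| E3 workplaces | same as E2 | 10, 8, 6, 4, 2 |
| E4 volatility (bp °C) or dustiness | <50 / 50–150 / >150; TLV-notation / powder / pellet | 10, 8, 6 |
| E5 measured exposure | LG (ppm): >500 / 50–500 / 5–50 / 0.5–5 / <0.5; solid (mg/m³): >10 / 1–10 / 0.1–1 / 0.01–0.1 / <0.01 | 40, 32, 24, 16, 8 |

Band conventions, chosen once and applied everywhere: printed ranges like
"10–1000" overlap at their endpoints, so every band is left-closed /
right-open except at the Class 2 / Class 1 boundary, where the Class 1
criterion (">1000") is strict and Class 2 is closed above. The volatility
band 50–150 °C is closed at both ends because its neighbours are strict.
The lowest solid measured-exposure bound (<0.01 mg/m³) continues the
decade pattern of the published cut-points, whose lowest solid cell is
blank. These conventions make every classifier a total, monotone step
function — every non-negative value falls in exactly one band.

Missing exposure data scores 0 (*not classified*) — the opposite of the
hazard side's precautionary *no data* rule, mirroring the asymmetry of the
published point grids. Circulation volume substitutes for handling volume
when the latter is missing (E1 only). Measured exposure requires a
physical state to fix its unit (ppm vs mg/m³); a unit/state mismatch is a
validation error.

### Normalization and ranking

Raw vectors are min–max normalized to 0–10 **over the evaluated set** (the
published score table confirms set-relative scaling: its maximum hazard
entry is exactly 10.00). Consequences worth knowing: scores are not
comparable across inventories, and the set minimum always normalizes to 0
regardless of its absolute points. `fixed_range=True` (CLI
`--fixed-range`) normalizes against the theoretical [0, 100] instead; the
two coincide exactly when the set attains both raw extremes (property
tested). A degenerate set (all raw scores equal) normalizes to all zeros
with a logged warning rather than dividing by zero.

Totals and ranks are computed at full float precision; 2-dp rounding is
display only (`--full-precision` disables it). The published table itself
multiplies unrounded scores — its printed 2-dp pairs reproduce the printed
totals only to ±0.05. Ties (total, then normalized hazard, then CAS
ascending) are an artifact convention; real inventories rarely tie.

Duplicate CAS numbers in one inventory are an error (ambiguous identity).
CAS check-digit failures on *distinct* identifiers only warn: regulatory
lists legitimately contain family pseudo-CAS entries (e.g. the Stoddard
solvent group), and at least one published table entry is a misprint
(ethyl acrylate printed as 140-88-3; the registry value is 140-88-5).

### Correlation report

`correlation_report` computes Pearson r with two-sided p-values from the
t distribution on n − 2 degrees of freedom — numerically identical to the
slope test of the corresponding simple regression, which is how the
original evaluation described its "regression analysis". Three blocks:
each indicator sub-score vs the total score (r1), vs its parent composite
(r2), and the 5 × 5 pairwise sub-score matrix, plus the hazard-vs-exposure
composite r. Correlations of constant columns are reported as missing with
a reason code, not as 0. No multiple-testing correction is applied, by
design parity with the original analysis.

## Synthetic inventories

The original 62-chemical evaluation inventory was never published, so the
generator produces statistically comparable stand-ins: hazard classes
drawn per endpoint from configurable weights (default: uniform over each
endpoint's valid labels), volumes and measured exposures log-uniform
(the cut-points are decade-structured, so log-uniform draws populate every
band; defaults 10⁻²–10⁴ t/y, 10⁻²–10³ ppm, 10⁻³–10² mg/m³), counts
log-uniform over 1–1000, 70% liquids/gases with boiling points uniform on
20–300 °C, solids uniform over the three dustiness categories, and
optional per-field missingness. Synthetic CAS identifiers carry valid
check digits. One integer seed makes the inventory byte-reproducible.

What the generator does **not** emulate: the real inventory's selection
bias (all 62 substances had CMR toxicity), correlations between indicators
(e.g. the published handling-volume–distribution r of 0.613 — real
high-volume chemicals are handled at more sites), or realistic marginal
class frequencies. Tests passing on synthetic data therefore demonstrate
the algorithm's correctness and invariances, not that the published
correlation coefficients are recovered — those depend on the unpublished
raw data and are explicitly not reproduction targets. Structural
properties that *are* checked: every sub-score-vs-composite correlation is
positive in expectation (each sub-score is a summand of its composite);
because a single n = 62 draw estimates the weakest such correlation
(distribution vs exposure, population value ≈ 0.3) with sampling noise
≈ 0.1, that check averages over five replicate inventories rather than
asserting on one draw.

## Numerical and design choices

* Point grids live in one overridable YAML config; a SHA-256 of the active
  tables is logged per run for provenance. Shipped defaults are the
  published grids (hazard maxima sum to 100; exposure maxima partition as
  30/10/10/10/40).
* Scoring is exact integer arithmetic until normalization; only the final
  normalized scores are floats.
* The ranker follows the scikit-learn estimator contract (`fit` learns the
  normalization bounds, `transform` scores a table, `get_params`/
  `set_params` round-trip), so it composes with sklearn pipelines.
  `transform` on records outside the fitted set can yield scores outside
  [0, 10] if their raw scores exceed the fitted bounds; the standard usage
  is `fit_transform` on one inventory.
* CSV round trips are lossless: floats are written in shortest
  round-tripping form, and write → read → compare equality is tested on
  generated inventories.

## Problem sizes

The test suite and acceptance script run inventories of 6–2000 chemicals
(62 for the evaluation-scale checks, matching the original study size;
500–2000 only for distributional convergence checks) and complete in well
under a minute on one CPU.

## Known limitations

* No exposure modelling: the tool bands supplied measurements; it does not
  estimate dispersion, dermal uptake, or vapor pressure (boiling point is
  the sole liquid/gas volatility criterion).
* Source-scheme → GHS translation (IARC groups, ACGIH A-categories, …) is
  the user's responsibility; the inventory CSV accepts already-translated
  GHS classes, optionally several per cell.
* Set-relative scores are ordinal within one inventory; do not compare
  them, or totals, across inventories without `--fixed-range`.
* The worker/workplace prose description of the band boundaries in the
  original write-up conflicts with its printed table at two boundaries;
  the printed table (Class 1 > 300, Class 2 100–300) is followed.
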