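# crirs — chemical risk ranking and scoring for workplace inventories

`crirs` prioritizes hazardous workplace chemicals for regulatory attention.
It is aimed at occupational-health practitioners and regulators who hold a
chemical inventory — GHS hazard classifications plus workplace exposure
determinants — and need a defensible, reproducible ordering of which
substances to control first, without running a full risk assessment per
substance.

## The method

Each chemical gets two raw scores on a 0–100 scale:

* **Hazard** — nine GHS-derived toxicity endpoints (T1–T9). The three CMR
  endpoints (germ cell mutagenicity, reproductive toxicity, carcinogenicity)
  carry 20 points each; acute oral/dermal and inhalation toxicity,
  irritation, sensitization, aspiration hazard, and repeated-exposure target
  organ toxicity share the remaining 40. Each endpoint's points come from
  its GHS class (e.g. carcinogenicity 1A → 20, 1B → 16, 2 → 12). *No data*
  scores like the top class (precautionary); *not classified* / *not
  applicable* score 0. Multiple source classifications per endpoint are
  merged conservatively.
* **Exposure** — five banded workplace indicators: handling volume (30 pts;
  circulation substitutes when missing), worker count (10), workplace count
  (10), volatility/dustiness (10; boiling point for liquids/gases, ACGIH-style
  dustiness category for solids), and measured exposure (40; ppm or mg/m³).
  Continuous determinants are banded by fixed cut-points (control banding);
  missing data bands as *not classified* and scores 0.

Both raw scores are min–max normalized over the evaluated set,

&nbsp;&nbsp;&nbsp;&nbsp; hvᵢ = (HVᵢ − HVmin) / (HVmax − HVmin) × 10,

and the **total score = hazard score × exposure score** (0–100) ranks the
inventory. The multiplication means a chemical must be both hazardous *and*
plausibly encountered to rank high. A `CorrelationReport` quantifies how
much each indicator block drives the totals (Pearson r with t-test
p-values).

The core API is a scikit-learn style transformer:

```python
from crirs import CrirsRanker, read_inventory

records = read_inventory("inventory.csv")
scored = CrirsRanker().fit_transform(records)   # DataFrame, one row per chemical
```

`rank_chemicals(records)` is the one-call equivalent.

## Worked example

```
$ crirs simulate --n 6 --seed 11 --out demo.csv
$ crirs rank demo.csv
rank,name,cas,raw_hazard,raw_exposure,cmr,other_toxicity,handling,distribution,measured,hazard_score,exposure_score,total_score
1,SYN-0004,6594-15-6,82,68,56,26,12,24,32,7.14,7.86,56.12
2,SYN-0001,3584-93-8,90,42,60,30,18,16,8,10.0,3.21,32.14
3,SYN-0006,3620-73-3,71,80,60,11,30,18,32,3.21,10.0,32.14
4,SYN-0005,6852-61-5,75,38,52,23,12,18,8,4.64,2.5,11.61
5,SYN-0002,8031-09-2,80,24,48,32,6,10,8,6.43,0.0,0.0
6,SYN-0003,6060-32-8,62,34,32,30,6,20,8,0.0,1.79,0.0
```

Reading the output: `raw_hazard`/`raw_exposure` are the 0–100 point sums
(`cmr + other_toxicity` and `handling + distribution + measured`
respectively); `hazard_score`/`exposure_score` are their 0–10 normalized
values — the set maximum (raw 90 and raw 80 here) maps to 10.00, the set
minimum to 0.00 — and `total_score` is their product. Rows 2 and 3 tie at
32.14; the tie goes to the higher hazard score. The set minimum on either
axis always totals 0: under set-relative normalization the bottom chemical
of an inventory carries no signal of its own.

Other subcommands: `crirs score` (input order), `crirs correlate`
(indicator-vs-total, indicator-vs-composite, and pairwise correlation
blocks), `crirs validate` (schema check with per-row diagnostics, exit 1 on
failure). `--config tables.yaml` overrides any scoring-table cell;
`--fixed-range` normalizes against the theoretical 0–100 instead of the
set; `--full-precision` disables 2-dp display rounding. The inventory CSV
schema is documented in `crirs/io.py` and `docs/methods.md`.

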