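# Methods

## The model

`nmbtender` scores each offer in a tender lot by its net monetary benefit
over a fixed time horizon. The computation runs in eight steps, mirroring the
trace the package prints for each device:

1. fix the time horizon `H` (months); internally `H_days = round(365 · H/12)`
   days, so a 12-month horizon is exactly 365 days;
2. baseline quality-adjusted survival, `QALD_base = u_base · H_days`, the
   expected quality-adjusted life days if no adverse event occurs;
3. expected disutility from endpoint events,
   `QALD_loss = Σ_i r_i · (d_i · t_i / H) · H_days`, where `r_i` is the
   device's probability of endpoint `i` within the horizon, `d_i` the utility
   decrement one event causes and `t_i` how long it persists (months);
4. net quality-adjusted survival `QALD_net = QALD_base − QALD_loss`
   (reported also as QALYs = QALDs / 365);
5. monetized benefit `B = QALD_net / 365 · λ` at the willingness-to-pay
   threshold `λ` (currency per QALY);
6. expected costs `C = P + Σ_i r_i · c_i` — the offered price plus
   per-endpoint event costs;
7. `B − C`;
8. the NMB, identical to step 7.

Admissible offers are ranked by decreasing NMB and the first-ranked device
wins. The model is a single expected-value calculation: rates are lot-level
expectations over the horizon, not a patient-level pathway, so there is no
state-transition (Markov) structure, no discounting (the intended horizons
are about a year), and endpoint contributions are additive.

### Assumptions

- Event disutilities combine additively and each event occurs at most once
  per patient within the horizon; for the low event rates typical of devices
  that reach a tender (a few percent) the additive error is second-order.
- A transient utility loss is equivalent to a proportionally smaller constant
  loss over the whole horizon: `adjusted = d · t / H`. Consequently
  `(d·k, t/k)` describes the same burden for any `k > 0` (an invariance the
  test suite asserts). The adjustment is computed as `d · (t/H)` so the
  identity at `t = H` is exact in floating point.
- Death is handled through the same rate × disutility × duration term as any
  endpoint; a user wanting "death forfeits all remaining utility" sets
  `d = u_base` and `t = H`. No mortality-specific arm exists because the
  model defines none.

## Parameters

| parameter | units | default | notes |
|---|---|---|---|
| `horizon_months` `H` | months | — (12 in the example) | analysis horizon; disutility durations may not exceed it |
| `baseline_utility` `u_base` | — | — (0.93 in the example) | utility with no events, in (0, 1] |
| `wtp_per_qaly` `λ` | currency/QALY | — (60,000 in the example) | willingness-to-pay threshold |
| `starting_price` | currency | — | maximum admissible bid; offers exactly at the cap are admitted (tender practice admits at-cap bids; "strictly below" readings differ) |
| `days_per_year` | days | 365 | QALD↔QALY calendar convention |
| per-endpoint `d_i`, `t_i`, `c_i` | —, months, currency | — | lot-level fixed parameters, 1–10 endpoints (3 is the documented profile) |
| `rate_unit` | — | `fraction` | device CSV rates as fractions or percent; internal representation is always a fraction |
| `include_price` | — | on | whether the offered price enters the cost side; off restricts the score to clinical components |

All arithmetic runs at full double precision; rounding (QALDs/QALYs to 4
decimals, currency to 2, thousands separators in the Anglo convention) is
applied only when rendering reports, and a single `--decimals` override
covers both. Numerical tolerances in tests compare currency at 0.01 absolute.

## Validation and degenerate inputs

- Offers are excluded (not errored) for a price above the starting price or
  any rate outside [0, 1]; an endpoint-id mismatch is flagged as a distinct
  *structural* outcome since it indicates a data-entry problem rather than a
  losing bid. Validation of one offer never depends on the other offers.
- Lots with duplicate endpoint ids, non-positive horizon/WTP/starting price,
  or out-of-range utilities are rejected at construction with all violations
  listed at once.
- A negative net QALD (disutility exceeding baseline survival) has no
  interpretation here; it is clamped to zero with a logged warning instead of
  raising, since it can only arise from implausible inputs.
- Ties in the ranking are broken deterministically: equal NMB → lower price
  first, then lexicographic device id. Determinism is non-negotiable for a
  procurement tool; the specific order is this package's convention.

## Two-scale presentation

Many administrations require results on separate 0–30 (price) and 0–70
(quality) scales. The underlying reparameterization conventions vary between
administrations, so the package ships its own documented default and keeps it
strictly presentational:

- price score: `30 · p_min / p` (`--price-rule proportional`, default), or a
  linear interpolation mapping the starting price to 0 and the lowest offer
  to 30 (`interpolated`); the best-priced device always scores exactly 30;
- quality score: `70 · q / q_max` with `q` the monetized benefit net of event
  costs, *excluding* the price (already scored on the other scale); the
  best-quality device scores exactly 70;
- both scores are clipped to their scales.

A fixed 30/70 weighting is not guaranteed to order devices the same way as
the raw NMB. The package treats agreement as a diagnostic, not a theorem: it
logs a warning whenever the two orders differ, and the test suite measures
the agreement fraction on random tenders without asserting it is 1.

## The synthetic-tender generator

Property tests draw whole tenders from `SyntheticTenderSpec`, seeded and
reproducible. Defaults model a realistic advanced-device lot: a 12-month
horizon, baseline utility in [0.70, 1.0], WTP in [20,000, 100,000] per QALY
(spanning common international thresholds), per-endpoint event rates in
[0, 0.05] (devices with higher complication rates do not reach tenders),
disutilities in [0.05, 0.95] with durations up to the horizon, event costs up
to 50,000, and offers in [200, 1,000] against a 1,000 starting price with 5%
of offers deliberately over-priced so the exclusion path is exercised. Range
feasibility is checked before drawing: the worst-case total disutility must
stay below the minimum baseline utility, so generated tenders never hit the
negative-net-QALD clamp.

The generator emulates tender-level *expected* rates only. It does not
simulate patient-level outcomes, correlated endpoints, sampling noise in the
rates, or strategic bidding; passing its property suite shows the arithmetic
and invariants are right, not that the three-endpoint model approximates any
particular full economic analysis on real data.

## The packaged carotid-stent example

The shipped example re-evaluates a real 2021 tender (three carotid stents;
endpoints minor stroke / major stroke / death at 12 months; WTP 60,000
euro/QALY). Its published record contains the device rates, prices, the
baseline quality-adjusted survival (339.45 QALDs, hence `u_base = 0.93`), the
winning device's trace totals, and the three final NMBs — but **not** the
lot's per-endpoint disutilities, durations, or costs. Those had to be
back-solved, and the algebra admits no faithful solution: writing each
endpoint's monetary loss per event as `k_i = (d_i t_i/H)·λ + c_i`, the 3×3
linear system matching all three published NMBs forces `k < 0` for major
stroke, and the published disutility total for the winner (26.2625 QALDs)
exceeds the maximum reachable from its published rates with disutilities ≤ 1
(9.417 QALDs). The calibration shipped in `data/carotid_lot.json` therefore
reproduces the *winning* device's NMB exactly (50,591.34), fixes a plausible
major-stroke loss, and fits the remaining per-event costs by non-negative
least squares; this preserves the published ranking while placing the other
two devices at 44,880.88 and 39,010.26 rather than their published 41,118 and
40,900. The fixture data file and its sidecar note label these parameters
non-authoritative, and the worked-example tests instead verify the published
step trace on a single composite endpoint constructed from the published
intermediate totals themselves.

## Known limitations

- Additive, single-period expected-value model: no discounting, no repeat
  events, no endpoint correlation, no uncertainty propagation (no
  probabilistic sensitivity analysis).
- One lot per run; no multi-winner or framework-agreement allocation.
- The two-scale mapping is a convention of this package, configurable but not
  harmonized with any particular administration's rulebook.
- The packaged example's fixed parameters are calibration artifacts
  (see above); conclusions about the real devices should rest on the
  published rates and NMBs, not on these back-solved values.
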