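# nmbtender

Value-based scoring and ranking of medical-device offers in competitive
tenders, using the net monetary benefit (NMB) of each device as its tender
score.

Procurement offices evaluating high-technology devices (stents, valves,
implants) increasingly want the tender score to reflect clinical value, not
just price. `nmbtender` implements a deliberately simple decision-analytic
model for that purpose: a tender lot is described by a small set of clinical
endpoints (typically three, e.g. minor stroke / major stroke / death), each
with a lot-level disutility `d_i`, a disutility duration `t_i`, and a cost per
event `c_i`; each competing device contributes only its offered price `P` and
its per-endpoint event rates `r_i` over the analysis horizon `H`. The score of
a device is

```
NMB = (u_base − Σ_i r_i · d_i · t_i / H) · (H_days / 365) · λ − (P + Σ_i r_i · c_i)
```

where `u_base` is the baseline utility in the absence of events and `λ` is the
willingness-to-pay threshold per QALY (60,000 euro/QALY in the shipped
example). Quality-adjusted survival is tracked in quality-adjusted life days
(QALDs) through the intermediate steps and converted to QALYs for reporting.
Offers are ranked by decreasing NMB; the top admissible offer wins the lot.
Transient utility losses are normalized onto the horizon with
`adjusted disutility = d · t / H`, so a 0.30 loss lasting 1 of 12 months acts
as a constant disutility of 0.025.

The package also provides offer admission rules (price cap at the lot's
starting price, rate sanity checks, endpoint matching), an optional
administrative presentation on the conventional 0–30 price / 0–70 quality
scales, auditable report files, and a seeded synthetic-tender generator used
by the property tests.

## Worked example

The packaged example re-evaluates a 2021 tender for carotid-endarterectomy
stents (three devices, endpoints minor stroke / major stroke / death at 12
months, rates supplied as percentages):

```
$ nmbtender demo --two-scale
rank  device_id        manufacturer              price              NMB  price/30 quality/70  total/100
   1  abbott           Abbott                   530.00        50,591.34     23.09      70.00      93.09
   2  cardinal         Cardinal Health          518.00        44,880.88     23.63      62.16      85.79
   3  medtronic        Medtronic                408.00        39,010.26     30.00      53.98      83.98

Winner: abbott
```

Each NMB is in euro per patient over the 12-month horizon: the winning device
converts 338.46 net QALDs into 55,637.64 euro of monetized benefit at the
60,000 euro/QALY threshold and carries 5,046.30 euro of expected costs
(price + event costs), hence a score of 50,591.34. Abbott wins despite the
highest price because its event rates are by far the lowest — exactly the
trade-off the NMB is designed to arbitrate. The `price/30` and `quality/70`
columns are the optional two-scale presentation. Note that the lot's
per-endpoint disutilities and costs are back-solved calibration values, not
published clinical estimates; see `src/nmbtender/data/carotid_notes.md`.

Run your own lot from files:

```
nmbtender compute --lot LOT.json --devices DEVICES.csv \
    [--rate-unit percent|fraction] [--no-include-price] \
    [--two-scale] [--price-rule proportional|interpolated] \
    [--decimals N] --out DIR
```

The output directory receives `report.txt` (a per-device eight-step trace and
the ranking), `ranking.csv`, `steps.csv`, and `run_summary.json` (input
digests and configuration, for tender auditability). Reports are byte-stable
for identical inputs.

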