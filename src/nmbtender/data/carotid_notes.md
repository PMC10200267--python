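# Notes on the packaged carotid-stent example

The lot re-evaluates a 2021 Italian tender for carotid-endarterectomy stents
with three clinical endpoints (minor stroke, major stroke, death) over a
12-month horizon at a willingness-to-pay threshold of 60,000 euro/QALY.
Rates in `carotid_devices.csv` are percentages at 12 months, as the source
tender documents print them (`rate_unit="percent"`).

## What is authoritative

- the 12-month event rates of the three devices;
- the price offers (530 / 518 / 408 euro — see discrepancies below);
- horizon (12 months), WTP threshold (60,000 euro/QALY);
- the winning device's published three-endpoint NMB: 50,591 euro (Abbott);
- baseline utility 0.93, back-derived from the published baseline
  quality-adjusted survival of 339.45 QALDs over 365 days (339.45/365 = 0.93).

## What is NOT authoritative

The per-endpoint disutilities, disutility durations and costs per event
("fixed parameters" of the original lot) were never published. The values in
`carotid_lot.json` are calibration artifacts, back-solved so that the model
reproduces the winning device's published NMB exactly (50,591.3435 euro). The
published NMBs of the other two devices (41,118 and 40,900 euro) are
mathematically unreachable under this three-endpoint model with non-negative
parameters and the published rates — solving the 3x3 linear system for the
per-event monetary losses yields a negative loss for major stroke. The
calibration therefore fixes a plausible major-stroke loss and fits the
remaining costs by non-negative least squares, which preserves the published
ranking (Abbott > Cardinal Health > Medtronic) and yields ~44,881 and
~39,010 euro for the other two devices. The per-event cost magnitudes absorb
whatever the unpublished full model contained and must not be read as
clinical cost estimates.

The starting price (600 euro) is likewise a fixture value chosen above all
published offers; the original starting price was not published.

## Source discrepancies recorded, not resolved

The source text and its summary table disagree on two points; this fixture
follows the table:

- second device price: 518 (table) vs 508 (text);
- third device: "Medtronic, 408" (table) vs "Johnson & Johnson" with price
  418 (text). The third device's event rates (0.89 / 3.12 / 1.78 %) are
  attributed in the text to Johnson & Johnson.
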