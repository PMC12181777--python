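# Methods

This note documents the models, parameter choices and numerical decisions
behind `beadsim`, and what its synthetic benchmarks do and do not establish
about real instrument data.

## Virtual deck and labware

Labware is described by small JSON documents (a flat normalized form, plus a
supported subset of the Opentrons-style dialect with `ordering`/`wells`/
`dimensions`).  Geometry is 2-D: a well centre is
`slot_origin + a1_offset + ((col−1)·pitch, row_index·pitch)` in mm, with
rows running along +y from row A.  Slot origins form the vendor's 3-wide
grid with 132.5 × 90.5 mm pitch; the fit check allows 1 mm over the nominal
128 × 85 mm slot because the standard SLAS footprint is 127.76 × 85.48 mm.
Well pitch defaults to 9 mm for 96-well plates (ANSI/SLAS geometry).  The
54-vial rack is modelled as a 6 × 9 grid at 13 mm pitch — the position count
is given by the hardware, the arrangement is our assumption.  Each labware
carries a height used only by the camera-collision rule.  Screening
capacity counts microplate wells only; tip racks, vial racks and the tool
holder do not contribute.

## Protocol engine

Plans are ordered, hardware-agnostic step lists; simulation executes them
against per-mount pipette state machines with a monotone simulated clock.
Invariants enforced at run time: a tool-carrying pipette can neither
aspirate nor dispense; tool pick-up requires a bare shaft; dispensing is
bounded by held liquid; every partial dispense must be completed by a
touch-and-coalesce on the same target.  Coalescence is bookkeeping: the
pending droplet volume transfers to the well (no droplet physics).  Air
gaps are aspirated segments between droplets; dispensing expels tip-end air
for free, and a tip may be dropped holding only air.  The liquid ledger
aggregates per-label aspirated/dispensed volumes from the event log, so
conservation (aspirated = dispensed + residual) is auditable after any run.

Durations: only the ≈5 s per-well image time is an instrument property; the
remaining defaults (2 s motions, 5 s tip handling, 10 s tool handling) are
plausible placeholders and configurable.  Consequently the simulated clock
is *not* a throughput prediction: a full-plate nine-interval scan has
unstated real-world overheads the engine does not model, and the scheduler
exposes its timing rather than claiming to reproduce wall-clock totals.

Imaging intervals are anchored per-well (relative to each well's dispense);
the scheduler serializes colliding requests onto the single camera in well
order, shifting later captures by multiples of the per-well time, and flags
an interval as infeasible when some capture is delayed by more than
`(n_wells − 1) × per_well_time` — the previous sweep was still running.
The schedule is still returned with the shifts applied.

Collision safety is a single rule: while the camera tool is carried, its
working height (default 120 mm) must clear every occupied labware except
the target plate and the tool's own holder; violations are planning errors.

## Camera service

The wire format is newline-delimited JSON over a local TCP stream — chosen
for inspectability; any simple serialized format would satisfy the
contract.  Per request the service captures one frame, writes
`<run>_<slot>_<well>_<seq>.png` (lossless PNG, 8-bit RGB, default 640×480)
plus a CSV index row, and acknowledges with the filename; malformed
messages and sequence regressions get error replies and produce no files.
A `latest.png` option replaces the live-feed window, which is not
reproducible headlessly.

## Forward model (synthetic imaging)

The generator renders one circular bead per well on a dark background
(default level 6/255), disk level `round(bg + opacity·(255 − bg))`, an
optional disk-mean blur (radius 2 px) to soften the bead edge, and clipped
per-channel additive Gaussian noise (default σ = 3 counts).  Per-frame
seeds are spawned from the camera seed, so renders are bit-reproducible.

Gelation opacity is a two-sided log-Gaussian bump in R = CaCl₂%/alginate%
with `r_crit = 1` (peak at CaCl₂ = alginate, matching the observed turnover
between 1.5 % and 5 % CaCl₂ at 1.5 % alginate), `peak_opacity = 0.9`,
rise width 0.5 and fall width 1.1 in log-R.  The asymmetry (steeper rise)
encodes that crosslinker-starved beads are harder to see than equally
mis-ratioed over-crosslinked ones, which is what makes the lowest-CaCl₂
column of the screen the faintest in every row.  Any continuous unimodal
form with these orderings would serve; the chosen one is smooth, two-
parameter, and exactly peaked at `r_crit`.

Disintegration: saturating rise `k_rise = 0.003 /s` (≈5.5 min time
constant, matching a steady pre-chelation climb over tens of minutes),
decay `k_decay = 0.01 /s` (≈70 s half-life, so the intensity collapses
within the first few minutes after chelator addition), baseline opacity 0.1, plateau 0.85.  The screen
renderer applies a maturation factor `1 − e^(−k_rise·t_capture)` so a
30-min capture is essentially fully gelled.

Bead radius is constant (100 px) by default and configurable; radius does
not vary with concentration because no quantitative size–concentration
relation is available.  There is no crosslinking-front, diffusion or optics
simulation — the generator's job is controlled, truth-paired imagery for
the analysis pipeline, not gel physics.

## Inverse analysis

Segmentation pipeline: BT.601 grayscale → optional histogram equalization →
global threshold (Otsu by default; fixed-threshold mode retained for oracle
comparisons) → morphological open/close (disk radius 2) → connected
components → discard components under `min_area` → select the component
nearest the image centre (a bead forms where the droplet lands;
`center_bias=False` falls back to largest).

Equalization is the classic integer cdf mapping
`out(v) = round(255·(cdf(v) − cdf_min)/(N − cdf_min))`; a constant image is
returned unchanged.  `equalize='auto'` triggers when the grayscale p99−p1
range is below `contrast_trigger` (40 levels), and the same range gate is
re-applied after equalization as a minimum-contrast guard: an image whose
range still sits under the trigger is reported as bead-free rather than
thresholded into a noise mask.  This gate is what makes equalization
genuinely *required* for transparent beads: without it a global
threshold would confidently segment beads of arbitrarily low contrast, and
with it the pipeline's found/not-found behaviour matches the practice of
only trusting enhanced images for faint beads.  `min_area = 500 px`
(≈13 px radius at 640×480) rejects the blob-sized structures that
blur-correlated noise produces after equalization, while remaining ~60×
below the default bead area.

Intensity statistics (mean, sd, pixel count, p5/p25/p50/p75/p95) are always
computed on the **raw** grayscale under the mask: the 0–255 opacity
interpretation is only meaningful before equalization, so enhancement
influences where the mask is, never the reported numbers.  "Distribution"
error bars are operationalized as sd plus quantiles.  Screen tables report
raw means only; no per-image or global normalization is applied.

Kinetics: the onset is found by an exhaustive two-segment scan over
candidate change points (series are short, so O(n) fits are cheap and
deterministic): head fitted by a saturating rise `P + (B−P)e^(−kt)`
(linear fallback if the fit fails), tail by `b + A·e^(−k(t−t_onset))`,
both via bounded least squares (rates in [1e−7, 10] /s, levels in
[0, 300]).  The minimal-total-RSS split is accepted only if it beats the
single-segment rise fit by a factor of 2 (RSS ratio 0.5), otherwise no
onset is reported — a monotone series never yields a spurious onset because
splitting a smooth trajectory cannot halve its residual.  Fitting requires
≥4 usable time points.

## What the synthetic benchmarks show

Passing tests establish that the inverse pipeline is correct *with respect
to the forward model*: exact opacity recovery on noise-free renders, IoU ≥
0.9 under realistic noise, the critical-ratio turnover surviving the full
render→analyze loop, and decay rates recovered to a few percent from 8-bit
imagery.  Real well images differ in ways the generator deliberately omits:
non-circular and off-centre beads, meniscus shadows and reflections,
uneven illumination, well-wall edges, and multi-bead wells.  Results on
synthetic data bound algorithmic error only; parameters such as
`contrast_trigger`, `min_area` and morphology radius would need re-tuning
on instrument data.

## Problem sizes

Benchmarks use the study-scale sizes throughout: the 4 × 6 concentration
grid, 640 × 480 frames, 20-frame time-lapses over 0–900 s, 100 noisy beads
for segmentation scoring, 50 time-lapse replicates for kinetics recovery,
and 100 randomized protocol configurations for the engine invariants.
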