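# Methods

This note documents the models, conventions and parameter choices behind
the package, including the points where the underlying method leaves the
formula to the implementer.

## Background threshold and Total Signal

The detection limit is estimated operationally: for each non-fluorescent
sibling control well, take the *maximal* regional value; the threshold is
B = mean + 3·sd of those maxima. Conventions:

- **Sample sd (n−1)** throughout. With one control, sd is taken as 0 and
  the model is flagged (`single_control`).
- **Strict inequality**: a region at exactly B is background. This is
  deterministic and conservative; with sd = 0, B equals the control mean
  exactly and nothing at that level counts as signal.
- For Gaussian control maxima the rule leaves a one-sided ≈0.135 %
  false-detection rate on fresh controls (the 3σ tail) — verified by
  Monte-Carlo in the test suite.

Total Signal is the per-scan sum of regions strictly above B, averaged
across replicate scans *after* per-scan computation. When no region
qualifies, the fallbacks are (1) sum the experimental channel over the
regions where a spatially congruent reference channel exceeds *its own*
threshold, or (2) take the single maximal regional value of the current
scan. Reading (2) as the per-scan maximum (rather than per-region maxima
across replicates) is a convention of this implementation. Both fallbacks
mark the result below-detection and propagate a `FALLBACK_USED` flag into
the time course.

**S:B ratio** is reported as TS / B. The numerator/denominator choice is
not fully pinned down by the method description ("calculated as described
in the text"); dividing by the stated detection limit makes the ratio
read as "how many detection limits of signal" and is documented here as
the package's convention.

Autofluorescence *inside* an occupied region is summed into TS by
design — the method excludes background regions, it does not subtract
background within signal regions. Consequently a deep trough (say 10 % of
baseline) reads high by roughly 90·a/TS₀ percentage points, where a is
the per-region autofluorescence level. At ≥100:1 signal-to-background
this is a fraction of a percentage point; it matters only for weak
expressers, which screening practice removes by sorter-based pre-sorting.

## Normalization and control correction

Each subject is normalized to its own baseline: the first session by
time, or a named pre-treatment session. The baseline point is set to
100 exactly (no floating-point division residue). A zero baseline cannot
anchor percentages: the subject is flagged `BELOW_DETECTION_BASELINE` and
`EXCLUDED`, kept in the output, and omitted from group statistics (a
config switch in the statistics helpers, mirroring the practice of
pre-sorting out low expressers).

Because every corrected value divides by the *same* estimated control
mean, corrected percentages within a timepoint are not independent: the
naive across-fish sem of corrected values omits the shared
correction-factor error. `corrected_group_mean` therefore reports the
delta-method standard error of a corrected group mean,
SE² = SE(t̄)² + (t̄·SE(c̄)/100)², and is what recovery checks and group
summaries should use.

The untreated-control correction is **multiplicative**:
corrected = 100 · treated % / mean(control %) per channel and timepoint.
The method's description ("correction factor") does not write the
formula; the multiplicative form preserves the percent scale, maps the
controls' own mean to exactly 100, and cancels any drift shared
multiplicatively by controls and treated fish — all three properties are
asserted in tests. Timepoints with fewer than two usable controls fall
back to the uncorrected value with a `NO_CONTROLS` flag.

## Assay-quality statistics

All Z statistics use the screening-window form
Z = 1 − 3(σ₁+σ₂)/|μ₁−μ₂| with interpretation bands >0.5 excellent,
(0, 0.5] acceptable, exactly 0 binary-only, <0 improve. Degenerate
windows (equal means) return a −∞ sentinel with a `DEGENERATE` flag;
sentinels are reported, never dropped silently, and means over
per-individual values exclude them and say so.

- **Per-individual Z'**: σ_i from each subject's successive replicate
  scans; the negative sample is the pooled per-scan maxima of
  negative-control wells from the same sessions (the closest realizable
  analogue of a negative control population on this scale). Subjects with
  a single scan are excluded with a warning.
- **State-transition Z**: when the prior state is the normalization
  anchor, every prior percentage is exactly 100 and σ_prior = 0 by
  construction. For a non-anchor reference (e.g. scoring regeneration
  against the post-ablation trough) the across-fish sd of that state is
  used. Both paths are exposed because the reference-state choice
  materially changes recovery-phase Z values.

No multiple-testing correction is applied; raw p-values are reported
(paired t-tests for matched pre/post comparisons, Welch t-tests for
dose-group comparisons).

## Throughput model

per_subject_s = plate_scan_s / wells;
capacity/day = ⌊hours·3600 / (per_subject_s + handling_s/wells)⌋ with a
flat 15 s/plate robotics handling constant and 96 wells. Raw, un-bucketed
integers are reported; published capacity figures are "> N" lower bounds
and are checked with ≥. The 24 h default models continuous operation and
is an explicit flag, since round-the-clock screening is itself an
assumption. One published per-subject cell (2×2 pattern, 0.94 s) is
internally inconsistent with its own plate time (94 s/96 = 0.98 s); the
model reports 0.98 and only the capacity bound is asserted for that row.

## Simulator

What it emulates, and the defaults (all overridable per scenario):

| parameter | default | rationale |
|---|---|---|
| expression distribution | lognormal, median 5000 RFU, σ_log 0.6 | strictly positive, right-skewed; central 95 % spans exp(3.92·0.6) ≈ 10.5× — the order-of-magnitude sibling spread |
| autofluorescence | additive Gaussian per region, mean 20, sd 8 RFU, truncated at 0 | scalar reduction of spectral/age-dependent background; implies B ≈ 45 RFU, so the default regime is ~100:1 S:B |
| replicate cv | 0.05 | within-session scan-to-scan repeatability of an anesthetized fish |
| session factor | lognormal, σ 0.10 per subject×session | fish are re-arrayed, re-anesthetized and refocused between sessions; between-session variation necessarily exceeds within-session cv — this is the "non-induced fluctuation" the control correction exists for |
| shared drift | lognormal, σ 0.05 per session | plate-wide gain/dye drift, removed exactly by the correction factor |
| replicates/session | 3 | standard practice of averaging three independent scans |
| position | REGIONAL(k): k regions uniform at random per session; GLOBAL: all regions | re-array between sessions; anesthetized fish hold position within a session |

Time-course models (deterministic fraction-of-baseline trajectories,
recorded as ground truth): exponential ablation to a floor with
saturating recovery; Hill-plateau dose response; delayed exponential
induction; multiplicative oxidative-stress effects with a scavenger
multiplier. The ablation decline rate (0.4/h) empties the targeted
population well within a 24 h prodrug window, so the washout read sits at
the floor.

The **ablation recovery scenario** raises the expression median to
15,000 RFU (~330:1), modelling a pre-sorted strong-reporter cohort: fish
must stay well above detection at a 10 % trough, and the
autofluorescence-in-region bias discussed above must stay well inside the
across-fish noise for the trough to read at the true floor. The
**induction screen** calibrates the induced amplitude so the noise-free
percentage slope of a positive equals a stated multiple (default 5×) of
the *measured* control-slope sd under the configured noise — effect sizes
in a k·SD screen are only meaningful in units of the controls' own
variability.

What the simulator does **not** model: optics (point-spread, meniscus,
z-focus physics), spectral autofluorescence structure and cross-talk,
fish orientation beyond region occupancy, circadian or developmental
expression trends, and movement between replicate scans. Passing
recovery tests therefore demonstrate the correctness of the processing
chain under the stated noise structure, not robustness to optical or
behavioural artefacts in real plates.

Per-individual Z' in simulation tracks the S:B regime as expected:
excellent (>0.5) for bright global reporters at ~100:1, collapsing below
0 once per-region signal approaches the detection limit (near 2:1 with
the default autofluorescence share, where regions flicker in and out of
the Total-Signal sum between replicate scans).

## Numerical and interface choices

- Region order is row-major, 0-based, row 0 nearest the plate row label;
  well IDs are case-insensitive on read, normalized (`A1`) on write;
  time is hpf as float, dpf converted at the boundary.
- One canonical export dialect (`arqiv-v1`) is defined in-repo; vendor
  schemas map onto it via a `Dialect` column mapping, never auto-sniffed.
- Tidy TSV floats are written with `repr` so write→read is lossless.
- Hit-call ties at exactly mean + k·sd are NEGATIVE (strict rule).
- All randomness flows from one seeded generator per dataset; emission is
  byte-deterministic (sorted rows, fixed float formatting, `\n` endings).
- Problem sizes in the test suite and acceptance script (n = 24/group
  ablation, 16/dose, 500+100 screen, 10⁵ Monte-Carlo draws) are chosen so
  every statistical check has comfortable power while the whole suite
  runs in seconds.

## Known limitations

- Background is pooled across sessions per channel; a session-resolved
  threshold would track gain drift at the cost of noisier B estimates.
- The ROS model is a single-timepoint multiplicative effect; no kinetics
  of dye loading or oxidation are modelled.
- `relative_fluorescence` reports group summaries only; no curve fitting
  (e.g. IC50 estimation) is provided anywhere — dose series are reported
  as percentages by design.
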