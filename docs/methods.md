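# Methods

`cbfar` re-implements, as a reusable and tested pipeline, the multimodal
analysis of cerebral blood-flow autoregulation (CBF AR) and body-fluid
shifts during positive end-expiratory pressure (PEEP) and graded hemorrhage
challenges, as performed in a single-animal (porcine) monitoring
experiment.  The raw animal recordings are not publicly deposited, so the
package pairs the analysis code with a seeded synthetic-signal generator
that reproduces the *structure* of that session — the challenge script, the
waveform families, and a known ground-truth autoregulation state — and uses
it to validate every stage.

## The challenge session

The canonical script has 16 challenges in fixed order: an anesthesia
transition (isoflurane → propofol, transient systemic-pressure rise), three
PEEP series at 10/15/20 cmH2O, three interleaved bleeds of 15 % of the
estimated blood volume each, one CO2 inhalation, a final PEEP 10, and a
terminal (lethal) bleed.  Estimated blood volume uses 65 mL/kg at 68.7 kg
body mass; with 3-decimal truncation the per-bleed and cumulative volumes
display as 0.669, 1.339 and 2.009 L (truncation, not rounding — rounding
would print 0.670/1.340 and contradict the recorded bookkeeping).

Epoch timing: each PEEP step lasts about 8 minutes in the canonical
configuration (480 s, with 300-s gaps whose trailing 240 s serve as the
next epoch's baseline).  Tests and the worked examples use the *compact*
configuration — 90-s epochs, 120-s gaps with 60-s baselines, 100 Hz
sampling, a ~62-min session — chosen once as the package's standard
problem size; every algorithm is window-parameterised, so nothing depends
on the session length.

## Signal reductions

* **Beat detection** — prominence-based peak picking (SciPy `find_peaks`)
  on a zero-phase 15-Hz low-passed copy of the waveform, with a refractory
  period of 60/max_hr s (defaults min_hr 40, max_hr 250 bpm).  Foot =
  minimum in the preceding inter-beat interval; pulse amplitude =
  systolic − foot, hence non-negative by construction.
* **Trends** — non-overlapping block averages (the 10-s averages feeding
  the reactivity indices, stamped at block end) and sliding trailing-window
  means (default 10-s window, 1-s step).  Trailing windows make every
  trend causal; a value stamped exactly at an epoch start belongs to the
  challenge, not the baseline (half-open baseline windows).
* **REG integral** — first difference × rate (no extra smoothing; the 60-s
  integral handles noise), rectification, then a trailing 60-s running sum
  × 1/rate emitted per sample once one full window exists.  The first
  difference kills constant offsets exactly and attenuates respiratory
  baseline wander relative to the pulse slope; for a pure sinusoid
  A·sin(2πft) the steady-state integral has the closed form
  60·A·2πf·(2/π) = 240·A·f, which the tests verify to 1 %.

## Reactivity indices (PRx, REGx)

PRx is the Pearson correlation of the last 30 paired 10-s averages of
arterial pressure and ICP, advanced one average (10 s) at a time, so the
first value appears at 300 s of signal; REGx substitutes 10-s averages of
the REG integral.  Windows in which either input is constant yield a
missing value, never 0 (0 is a meaningful "dissociated" reading).  The
implementation uses globally centred running sums; a unit test requires
agreement with a direct per-window Pearson evaluation to 1e−12.  Values
near −1 indicate intact reactivity (slow pressure waves countered by the
cranial channels), near +1 passive pressure-following.

## Autoregulation classification

Each (challenge, modality) cell is reduced to a sign: with Δ = (challenge
extremum − baseline mean)/|baseline mean|, |Δ| < 3 % is "0"; an
above-threshold rise *and* fall within one epoch is "mixed"; otherwise the
sign of the larger excursion (ties to +).  The 3 % threshold is a package
default exposed in the API: the source experiment judged signs visually, so
there is no recorded numeric threshold.  Classification then compares each
modality sign with the SAP sign — opposite clean signs = active AR,
identical = passive, any 0/mixed = excluded.  Pulse-amplitude modalities
(CFa, REG1d) are judged on per-beat amplitude trends; all others on 10-s
sliding means.

The packaged reference grid (`data/reference_challenge_signs.tsv`)
transcribes the published 16-challenge sign table verbatim, along with the
published per-modality active counts.  Applying the stated rule
mechanically to that grid reproduces the published counts in five columns
(CFm, LDF, ICP, CVP, pO2) and gives exactly one more in the other five
(CFa, REG1d, CBF, PAP, CO2).  The source analysis excluded
artifact-contaminated segments by hand without marking them in the grid;
the uniform +1 pattern is consistent with one such unrecorded exclusion per
column.  The package does not guess which cells were excluded: it reports
the rule's counts and documents the discrepancy (asserted cell-for-cell in
the test suite).  Percentages are reported as round-half-away integers
(7/16 → 44 %, 6/16 → 38 %).

Stagewise percent-change tables (mean ICP and REG integral at PEEP 15/20)
measure each entry at the challenge-window value farthest from the stage
baseline mean, so passive stages produce negative entries; each PEEP
series is referenced to its own pre-series baseline (the pre-first-bleed
period for stage 1).

## Scalar indices

Shock index SI = HR/SBP; pulse pressure PP = SBP − DBP; cerebral perfusion
pressure CPP = mean SAP − mean ICP.  The Kerdo autonomic-balance index is
implemented in two variants: the modified, as-recorded form
(1 − DBP/HR) + 100 (default; >100 = sympathetic predominance) and the
classic 100·(1 − DBP/HR).  The modified form is dimensionally inconsistent
(DBP/HR is not a pure ratio) but is kept as default because it is the form
the source analysis used.  Start-vs-end comparisons use Welch's
unequal-variance t-test on the first and last 30 minutes of a trend (the
source states only "t-test"; Welch is the safer default), and
between-channel agreement uses Pearson r on paired timestamps.  On the
four active-stage percent-change pairs of the reference table, ICP vs REG
integral gives r = 0.804 (r² = 0.646); the source rounds this to 0.81 and
labels it R², an inconsistency the package does not try to resolve.

## Bioimpedance

**EIS.**  Spectra are fitted to the four-parameter Cole dispersion
Z(f) = R∞ + (R0 − R∞)/(1 + (j·2πf·τ)^α) by joint real+imaginary
least squares (lmfit), with R0 initialised from the lowest-frequency |Z|,
R∞ from the highest, τ from the reactance peak, and multi-start over α ∈
{0.7, 0.9, 1.0}; R0 > R∞ is enforced by fitting R∞ and the positive
difference.  Extracellular resistance Re = R0; intracellular
Ri = R0·R∞/(R0 − R∞).  Volumes use a resistivity-cylinder model
V = ρ·L²/R with default L = 35 cm, ρ_ec = 40 Ω·cm, ρ_ic = 100 Ω·cm —
conventional order-of-magnitude constants for a calf segment, chosen once;
all downstream results are normalised so the absolute scale cancels.  The
split of extracellular volume into intravascular and interstitial parts is
an *approximation*: the device used in the source experiment applies a
proprietary partition, so the package uses a configurable intravascular
fraction (default 0.35) with a linear hematocrit correction, and labels
the dependent outputs approximate.  Vec = Vb + Vi holds exactly by
construction in every operation.

**Normalisation and transfers.**  Each compartment series is divided by
its mean over the pre-first-bleed baseline window; fluid transfer is
F_x(t) = −(V_x(t) − baseline mean), so a compartment that loses volume
shows positive transfer-out and Fc + Fi + Fb + (total change) = 0 to
machine precision.

**IPG.**  Per beat: TIN = foot-to-peak time; TOUT = time from the peak
until the waveform has returned 90 % of the way to the next beat's foot
(linear interpolation between samples; the 90 % criterion keeps the metric
finite on exponentially decaying pulses and is configurable); %BF =
pulse amplitude × local HR, expressed as percent change from the
pre-first-bleed baseline segment.

## The synthetic generator

Per-beat waveforms use an asymmetric gamma-like pulse (unit peak at 25 %
of the cycle, fast upstroke, slow decay) driven by a phase accumulator, so
heart-rate drift changes beat spacing continuously.  Epoch responses use
logistic onset/offset envelopes (time-scale 5 s, centres lagging the epoch
boundaries by 15 s, i.e. transitions complete within ~30 s), which avoids
discontinuities that would break beat detection; hemorrhage responses
persist, all others decay after the epoch.  Slow activity comprises a
two-component vasogenic (B-wave-like) oscillation at 0.020 and 0.0314 Hz
(±2.5 mmHg in SAP) and a 0.25-Hz respiratory sinusoid on ICP and REG.
Default responses: SAP falls 0.9 mmHg per cmH2O of PEEP, 10 mmHg per 15 %
bleed (25 mmHg for the terminal bleed), rises 8 mmHg under CO2 and
10 mmHg at the anesthesia transition; heart rate rises 8 bpm per bleed
with a slow upward drift thereafter; pulse pressure narrows with
cumulative hemorrhage.  These magnitudes are plausible mid-range values
for an anesthetised pig chosen once for the generator; only their signs
and the active/passive coupling are load-bearing for the analyses.

The ground-truth autoregulation state is a per-epoch flag: in active
epochs the cranial channels (ICP, REG pulse amplitude, CF pulse amplitude)
respond to SAP changes with the opposite sign and the slow waves couple
invertedly; in passive epochs both follow pressure.  Amplitude modulation
is exponential (`exp(gain·ΔSAP)`), keeping amplitudes positive under deep
hypotension.  All randomness (noise, oscillator phases) comes from one
`numpy` generator seeded explicitly; identical inputs give bit-identical
bundles.

What the generator does **not** emulate: real porcine waveform morphology
(dicrotic notches, baroreflex dynamics), temperature, anesthetic
pharmacology, measurement artifacts, or non-stationary noise.  Passing
recovery tests therefore show that the pipeline correctly implements and
inverts the stated model of the session — not that it would classify noisy
clinical recordings with the same 99 % agreement.

The EIS forward model generates spectra from prescribed compartment
trajectories through the same resistivity constants the analysis uses,
plus complex Gaussian noise (default sd 0.02 Ω).  The round trip
(trajectory → spectra → Cole fit → volumes) recovers the trajectory within
2 % and correlation > 0.99 at default noise; this validates the fitting
chain, not the resistivity constants themselves.

## Numerical choices and degenerate inputs

Flat waveforms yield empty beat series (not errors); windows without beats
yield flagged NaN vitals; zero-variance correlation windows yield NaN;
zero baseline means raise errors (a relative change is undefined); display
truncation uses `floor(round(x·1000, 6))/1000` so that decimal values
represented as float dust (0.67199999…) still truncate to the intended
0.672 while 0.669825 truncates to 0.669.  Sign-grid cells that combine
symbols (`+/-`, `-/+`, `+/0`) all map to the excluded "mixed" label.

## Problem sizes used in tests

Simulation-based tests run the compact 16-epoch script at 100 Hz
(~372 000 samples per channel); the ground-truth recovery check uses 20
seeds with independently randomised per-epoch profiles (960 classified
cells) and requires ≥ 90 % agreement; EIS round trips fit 62–124 spectra
of 25 log-spaced frequencies between 1 kHz and 1 MHz.  These sizes are the
package's chosen standard test conditions.

## Known limitations

* The intravascular/interstitial split is a documented approximation; use
  the normalised extracellular volume when absolute partitioning matters.
* The sign threshold (3 %) is a free parameter; very small real responses
  near the threshold will flip between 0 and a clean sign.
* `%BF` is a relative index only; no absolute flow calibration is
  attempted.
* Input recordings must be uniformly sampled; there is no gap handling.
* The reference grid's published active counts cannot all be reproduced
  from the grid alone (see the classification section); the package
  reports rule-derived counts and flags the five discordant columns rather
  than imitating unrecorded manual exclusions.
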