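# Methods

## The selection statistic

For a window `x` of length `N` and a candidate mother wavelet, `wavehar`
computes a full `n`-level wavelet packet decomposition (both children of
every node are split), pools the `2^n` terminal sub-band coefficient
sets `C₁ … C_m` (`m` = padded window length), and evaluates

* energy `E = Σ Cᵢ²`,
* the energy probability distribution `Pᵢ = Cᵢ² / E`,
* Shannon entropy `S = −Σ Pᵢ ln Pᵢ` with `0·ln 0 := 0`, and
* the fitness ratio `ξ = E / S`.

`ξ` is computed per axis and averaged over the three axes (a
vector-magnitude mode exists), then averaged over windows — an
unweighted mean of per-window ratios, not a ratio of means.  Pooling all
terminal coefficients into a single distribution is the default; a
per-node mode (ratio per sub-band, averaged) is available behind the
`pooling` switch.  Candidates are ranked by mean ξ per activity and
overall, descending, ties broken lexicographically by name so output is
deterministic.

Two structural properties matter in practice and are enforced by tests:

* **Amplitude scaling.** `E` scales with amplitude squared while `S` is
  scale-invariant, so `ξ(a·x) = a²·ξ(x)`.  Data recorded in m/s² yield
  ratios 9.80665² ≈ 96.17 times larger than the same data in g.  Unit
  conversion is therefore always explicit (`convert_units`), and no
  ranking ever changes under a global unit change.
* **Log-base invariance.** Replacing `ln` with `log₂` divides every
  entropy by `ln 2` and multiplies every ξ by the same constant, so
  rankings are base-independent.  Natural log (nats) is the default.

Degenerate windows — zero energy, or zero entropy (all energy in one
coefficient, making ξ undefined) — are excluded from averages with a
logged count rather than propagating infinities.

A caveat when candidate lists mix families: biorthogonal analysis
filters are not orthonormal, so their `E` term is not the window energy
(rbio5.5 inflates it, bior5.5 deflates it).  This is a property of the
statistic itself, not an implementation artefact; comparisons among
orthogonal candidates are energy-calibrated by Parseval.

## Transform engine

The packet transform is a two-channel filter-bank cascade under
**periodization**: the window is zero-padded to the next multiple of
`2^level` (125 → 128 at defaults; zero padding adds exactly zero
energy), and each stage circularly convolves with the analysis pair and
downsamples by two.  The phase convention (analysis offset `L/2`,
synthesis offset `L/2 − 1` for filter length `L`) matches the standard
periodization mode of established wavelet libraries, which the tests use
as an independent cross-check alongside a naive direct-convolution
oracle.  Periodization keeps coefficient counts exactly dyadic and makes
Parseval exact for orthonormal filters (relative error ≤ 1e−8 enforced,
observed ~1e−11), including the wrap-around case where a long filter
(coif14, L = 84; db37, L = 74) exceeds the node length at deep levels —
orthonormality survives folding because the filter autocorrelation
vanishes at every nonzero even lag.  Perfect reconstruction holds for
all eleven candidates, biorthogonal included.

Filter coefficients come from the standard published constructions as
shipped by PyWavelets; nodes are kept in natural (Paley) order with a
Gray-code helper (`natural_to_frequency_order`) for frequency-ordered
views.  The sign convention for the high-pass filter follows that
library; tests compare up to a global sign.

Defaults: level 3 (8 sub-bands of 3.125 Hz at 50 Hz), window 2.5 s,
target rate 50 Hz.  125-sample windows shorter than no candidate's
filter (longest: coif14, 84 taps).

## Preprocessing

Recordings are parsed from delimited text through per-dataset column
schemas (templates shipped for eight common public HAR collections plus
the synthetic layout); unparseable rows are dropped with a logged count.
Resampling to the common 50 Hz uses rational-ratio polyphase filtering
(`scipy.signal.resample_poly`), which anti-aliases when decimating;
upsampling low-rate sources (e.g. 20 Hz) is supported and logged.
Labels map to the nearest original sample.  Windows are non-overlapping
by default and label-pure: the window grid restarts at every label
change, so no window straddles an activity boundary and each label run
of length `L` yields `⌊L/window⌋` windows; overlap fraction and a
majority-vote policy are configuration options.

## Features and evaluation

Per axis and per terminal sub-band: coefficient mean, RMS and variance
(unbiased, `m − 1` denominator); per axis additionally the pooled ξ,
replicated across that axis's sub-band slots (a per-node-ξ mode exists).
At the defaults this is 4 × 8 × 3 = 96 features per window, ordered
deterministically by (axis, node, feature).

Evaluation is stratified k-fold cross-validation (k = 10), record-wise
(not subject-wise — a deliberate, flagged choice matching common
practice; subject-wise splitting would lower absolute accuracies).
Scaler and classifier are fit on training folds only; pooled
out-of-fold predictions produce the confusion matrix and metrics.
Classifiers:

* **Decision tree** — entropy (information-gain) splitting with a
  minimum leaf size of 5.  This is the closest scikit-learn analogue of
  C4.5: true C4.5 uses gain-*ratio* splitting and error-based pruning;
  the leaf-size floor plays the pruning's variance-limiting role.
* **SVM** — RBF kernel, C = 1, `gamma="scale"`, one-vs-rest, on
  per-fold z-scored features.

Metrics follow the per-class contingency definitions (precision
TP/(TP+FP), recall TP/(TP+FN), F1 their harmonic mean, 0/0 := 0);
balanced accuracy is the unweighted mean of per-class recalls and
"macro F1" the unweighted mean of per-class F1 — both robust to class
imbalance.

## Synthetic benchmark

The generator emulates what a waist/thigh-worn accelerometer records
over a few seconds, in m/s² with gravity kept in the signal (an
explicit g-units mode exercises the unit-scaling law):

* **Gravity and orientation.** A ~9.81 m/s² offset along the device
  orientation, drawn per recording ("subject") as a tilt from vertical
  (8° ± 2° for upright activities, 60° ± 10° for sitting) plus a slow
  ±2° within-recording drift.  Upright activities deliberately share one
  orientation distribution: orientation is a property of how the sensor
  is worn, not of the activity, so it must not act as a class
  fingerprint.
* **Periodic motion.** A fundamental stride frequency with per-axis
  harmonic amplitude profiles, slow amplitude modulation (log-normal
  common envelope, sd 0.4, plus ±45% per-harmonic modulation) and ~4%
  stride-to-stride frequency jitter; per-subject cadence (±6%) and
  overall amplitude (log-sd 0.3) draws.
* **Class structure.** Six classes: sitting and standing (static);
  walking (1.85 Hz, power in the 2nd harmonic ≈ 3.7 Hz → sub-band 1),
  stair climbing (1.80 Hz, power in the 4th harmonic ≈ 7.2 Hz →
  sub-band 2), jogging (2.6 Hz, 2nd/3rd harmonics spanning bands 1–2),
  and jumping (bursts: Poisson-timed, exponentially decaying, randomly
  oriented impulses).  Walking and stairs overlap in cadence and
  amplitude on purpose — they are told apart by *where* in the spectrum
  their harmonic power sits, which is exactly the property on which
  mother wavelets differ: haar's short filters leak ≈ 26% of the strong,
  amplitude-modulated fundamental's energy out of the lowest sub-band
  (coif14: ≈ 1%), flooding the discriminative bands with nuisance
  variance.
* **Noise.** Additive white Gaussian noise, 0.06–0.54 m/s² depending on
  activity vigour.

Defaults: 6 subjects × 20 windows = 120 windows per class (720 total) at
50 Hz / 2.5 s, class-balanced by construction, all randomness from one
seed.  These sizes keep a full selection-plus-evaluation run in seconds
on one core while leaving per-replicate classification accuracies in the
mid-70s to high-80s (%) — off both the ceiling and the floor, so wavelet
quality is measurable.

What the benchmark does *not* model: biomechanically realistic gait
waveforms (real steps are impact transients plus smooth swing, not pure
harmonic stacks), soft-tissue artefacts, sensor saturation or
miscalibration, label noise, and class imbalance.  Passing results on it
show that the pipeline's statistics behave as derived and that the
selection mechanism responds to spectral compactness as intended — not
that a particular wavelet is best for any real dataset.

`matched_wavelet_signals` provides the sharpest test of the selection
premise: windows synthesized from sparse level-3 packets of a chosen
wavelet (2 nonzero coefficients per axis by default, plus light noise)
concentrate their energy under that wavelet by construction, and the
ranking recovers the generating wavelet almost surely — in either
direction (coif14-matched signals rank coif14 over haar; piecewise-
constant haar-matched signals rank haar over coif14).

## Numerical and design choices

* Window/rate/level defaults (2.5 s, 50 Hz, level 3) are the analysis
  protocol's; all are configuration parameters.
* Zero-energy and zero-entropy windows: excluded and counted, never
  NaN/inf.
* Rankings: strict descending mean ξ, lexicographic tie-break.
* Resampling ratios use a `Fraction` with denominator ≤ 10⁴ (exact for
  all rates of interest, incl. 204.8 → 50 Hz).
* Classes with fewer members than k: fold count shrinks to the smallest
  class size (with a warning) rather than failing.
* Reproducibility: a single integer seed drives simulation, fold
  shuffling and any stochastic classifier internals; repeat runs are
  bit-identical.

## Known limitations

* The ξ statistic is unit- and scale-bound; absolute values are only
  comparable within one dataset and unit system.
* Among smooth high-vanishing-moment candidates (sym18, coif14, db37,
  …) ξ differences on the synthetic benchmark are small — such wavelets
  code smooth oscillations almost equally compactly — so their relative
  order there is not meaningful, only the contrast against short-filter
  wavelets (haar, rbio1.3) is.
* Record-wise cross-validation shares subjects between folds; use the
  evaluation as a wavelet comparison under a fixed protocol, not as an
  estimate of deployment accuracy.
* C4.5 proper (gain ratio, error-based pruning) is approximated by an
  entropy-criterion tree with a leaf-size floor.
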