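# wavehar

Mother-wavelet selection for wearable-sensor human activity recognition
(HAR), built around the wavelet packet transform (WPT) and the
energy-to-Shannon-entropy fitness ratio.

## The problem

Classifying activities (walking, jogging, sitting, …) from a body-worn
tri-axial accelerometer usually starts by decomposing each short signal
window into frequency sub-bands with a wavelet transform.  The choice of
*mother wavelet* — the prototype function whose filter bank drives the
decomposition — materially affects recognition accuracy, because a
wavelet that resembles the signal concentrates its energy in few
coefficients, while a mismatched one smears it across sub-bands.

`wavehar` implements a principled selection procedure: decompose each
2.5 s window (125 samples at 50 Hz) with an *n*-level WPT (default
*n* = 3, i.e. 8 sub-bands), and score each candidate wavelet by the
energy-to-Shannon-entropy ratio of its coefficients

```
E = Σᵢ Cᵢ²        Pᵢ = Cᵢ² / E        S = −Σᵢ Pᵢ ln Pᵢ        ξ = E / S
```

where `Cᵢ` are the pooled terminal-level packet coefficients and
`0·ln 0 := 0`.  A high ξ marks a wavelet that captures much energy in a
narrow (low-entropy) coefficient distribution.  Candidates are ranked by
ξ averaged over windows, per activity and overall; the winner feeds a
sub-band feature pipeline (mean, RMS, variance, ξ per band and axis — 96
features per window at the defaults) evaluated with stratified 10-fold
cross-validated decision-tree and RBF-SVM classifiers, reported as
per-class precision/recall/F1, balanced accuracy and macro F1.

The eleven stock candidates span six families: haar; db5, db37; sym5,
sym18; coif5, coif14; bior1.3, bior5.5; rbio1.3, rbio5.5.  Any other
standard discrete wavelet name is also accepted.

The package includes a seeded synthetic benchmark generator (six
activity classes with per-subject cadence, amplitude and sensor-
orientation variation) so the entire pipeline runs end-to-end with no
external data, plus configurable delimited-text readers for common
public dataset layouts (WISDM, HARTH, MHEALTH, PAMAP2, …).

## Worked example

```python
import wavehar as w

segments = w.make_benchmark(seed=1)          # 6 classes x 120 windows
report = w.select_mother_wavelet(segments, list(w.CANDIDATE_WAVELETS))
print(report.overall.head(4).to_string(index=False))
```

```
wavelet  mean_energy  mean_entropy  mean_ratio  rank
rbio5.5         4751         2.845        1707     1
bior1.3         4497         3.007        1578     2
  sym18         4387         2.883        1569     3
 coif14         4387         2.883        1568     4
```

Energies are in (m/s²)², entropies in nats, so ξ is in (m/s²)²/nat.  The
smooth, high-vanishing-moment wavelets (sym18, coif14, …) cluster at the
top while haar and rbio1.3 sit near the bottom (ranks 9–10): smooth
oscillatory motion signals are compactly coded by smooth wavelets.  Note
that for orthogonal wavelets the mean energy is identical (4387 — exactly
the windows' energy, by Parseval); biorthogonal analysis filters are not
energy-preserving, which inflates (rbio5.5) or deflates (bior5.5) their
E term — a unit-bound quirk of ξ worth knowing when candidates mix
families.

Does the ranking matter downstream?

```python
table = w.compare_wavelets_classification(
    segments, ["coif14", "haar"], ("dt", "svm"), k=10, seed=1)
print(table.to_string(index=False))
```

```
wavelet  balanced_accuracy_dt  macro_f1_dt  balanced_accuracy_svm  macro_f1_svm
 coif14             78.611111     0.785478              85.833333      0.858441
   haar             72.916667     0.730603              78.750000      0.789119
```

coif14-based features beat haar-based ones by ~6 points of balanced
accuracy for both classifiers on the same windows, folds and seeds.

The same pipeline is available from the shell:

```sh
wavehar simulate --seed 1 --data-dir bench/
wavehar select   --seed 1 --data-dir bench/ --out-dir out/
wavehar evaluate --seed 1 --data-dir bench/ --out-dir out/ --wavelets coif14,haar
```

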