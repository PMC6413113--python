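# Methods

## Band power

A trial is an (electrodes × samples) matrix; the standard montage has 64
electrodes at 10-10 locations. Per electrode, band power is the raw
(unnormalized) sum of squared DFT magnitudes over the bins inside the
band. Bin inclusion is half-open, `low ≤ f_k < high`, so the α (8–13 Hz)
and β (13–30 Hz) bands do not double-count the 13 Hz bin; the DC bin is
never included. The default window is rectangular; a Hann taper is
available. Bands reaching or exceeding Nyquist are rejected. Trials must
hold at least two cycles of the lowest band edge (4 Hz).

Defaults for trial geometry are 3.5 s at 500 Hz — a 0.5 s presentation
plus 3 s retention window of a Sternberg-style task. These are package
choices: sampling rate and analysis-window length are free parameters of
the pipeline, not properties of the method.

Centering subtracts the dataset-mean spectral value (one scalar over all
trials × bands × electrodes) by default before enhancement; per-trial and
no centering are available. The raw map channels use the uncentered
powers — the original spectral maps are deliberately left on their
absolute scale, that is what the parallel mechanism pairs against.

## Feature enhancement

Per trial, each of the 192 centered values is squashed through
σ(A) = 1/(1+e^(−s·A)) with fixed slope s = 0.15, then the 192 squashed
values are jointly min-max rescaled to [0, 1]. Properties relied on
downstream:

- every enhanced value is in [0, 1]; non-degenerate trials attain both 0
  and 1 exactly;
- the map is strictly increasing over a trial's raw values, so the
  within-trial ordering of electrodes/bands is preserved exactly — and is
  invariant under any positive per-trial affine rescaling of the raw
  powers, which is why the enhanced channels resist scale jitter;
- the transform is *not* shift-invariant (the sigmoid is nonlinear);
  this is intentional, the squash tempers the squared-magnitude scale.

The algebraically equivalent closed form is implemented in log space
(`log1p`/`logaddexp`) and retained purely as a verification oracle; the
production path is the explicit composition, which is stable for
arbitrarily large |A| via `scipy.special.expit`. The published
closed-form notation admits a second reading (extrema applied to −s·A)
that yields exactly the reversed map 1 − A′; it contradicts the
composition it is meant to summarize, so the composition-consistent
reading is the default and the reversed variant sits behind
`literal_eq9` for comparison.

Degenerate trials (all 192 values equal within `epsilon_degenerate`,
default 1e-12, measured on the squashed range) map to 0.5 everywhere and
are flagged rather than erroring, so downstream tensors remain valid.

### Slope/scale coupling

The fixed slope 0.15 makes the sigmoid responsive roughly for centered
powers in ±50 and saturating beyond ±100. Because the unnormalized DFT
power grows with trial length and the square of signal amplitude, the
informative range of the enhancement is tied to the data's units. The
synthetic generator's amplitudes are calibrated so centered powers land
in that range (see below). Real data in other units would need a
consistent unit convention or a different slope.

## Scalp grid and maps

The 64 electrodes occupy a fixed 10×11 grid with row occupancies
3/5/9/9/11/9/9/5/3/1 (a head outline); the mapping is injective and the
46 off-scalp cells are structural zeros at every resolution — no scalp
mask, no extrapolation. Rows whose horizontal placement is not forced by
their occupancy are centered symmetrically (occupancy-9 rows at columns
2–10), consistent with the left–right symmetry of the 10-10 montage.
Electrode indices are treated as opaque positions defined by the layout;
no 10-10 label table is assumed.

Rendering upsamples deterministically: nearest-neighbour replication
(identity at native resolution, preserves the value multiset) or
corner-aligned bilinear interpolation (every output pixel bounded by its
four surrounding cells). Default map resolution is the native 10×11;
224×224 bilinear is available for image-sized tensors. The 6-channel
order is fixed as [θ, α, β, θ′, α′, β′]. PNG export min-max scales the
selected 3 channels jointly per image for display only.

An alternative construction for topographic maps exists in the
literature — azimuthal-equidistant projection of 3-D electrode positions
with Clough–Tocher interpolation — but this package implements the
discrete grid, which is self-contained and exactly invertible.

## Synthetic generator

Each trial is 1/f-shaped broadband noise (white noise spectrally shaped
by 1/max(f, 1 Hz), per-electrode variance normalized) plus one sinusoid
per band and electrode with random in-band frequency and random phase.
Defaults: noise SD 0.01 a.u., base amplitudes (θ, α, β) =
(0.004, 0.006, 0.003) a.u. — α dominant, β weakest, matching the usual
resting spectral profile — 13 subjects, 4 levels × 20 trials each.

The workload effect multiplies the oscillation amplitude on the frontal
electrodes (the 17 electrodes of the top three grid rows, mirroring
prefrontal involvement in memory tasks) by
(1 + effect_size·(level−1))^w_b with band exponents w = (0.75, 1.0, 1.25),
so higher bands gain more at higher levels. A lognormal per-subject gain
(σ = 0.2) scales a subject's entire signal, modeling inter-subject
amplitude variability. Generation is bit-reproducible for a fixed seed on
one platform.

Amplitude calibration: with these values, in-band noise power per
electrode is ≈ 13–33 a.u.² and oscillation power ≈ 12–110 a.u.², so
dataset-centered powers fall mostly within ±60 — inside the sigmoid's
responsive range. The numbers follow from Parseval's theorem and the
1/f in-band variance fractions; they were fixed from this arithmetic, not
fitted.

What the generator does *not* emulate: artifacts (blinks, EMG), volume
conduction and inter-electrode correlation structure, non-stationarity
within a trial, realistic α reactivity, or the reported level-1 anomaly
(low-load trials contaminated by task-unrelated activity) — the
`level1_noise_boost` flag can imitate the latter with excess broadband
noise but is off by default. Passing tests therefore demonstrate the
pipeline's correctness and the mechanism of the enhancement, not
classifier performance on real EEG.

## Evaluation protocols

- **6:2:2 split**: within every (subject, level) cell, trials are
  shuffled and apportioned by largest remainder, so per-cell counts match
  the ratios to within one trial. Cells with < 3 trials warn and get a
  best-effort assignment.
- **4-fold CV** over the 80% train+validation pool, stratified by
  (subject, level) via scikit-learn's `StratifiedKFold`; when a cell is
  smaller than k it warns and falls back to stratifying by level only.
  The mean validation error across folds is the model-selection score.
- **LOSO**: one split per subject; the held-out subject never appears in
  training.

The classifier is a compact two-branch NumPy MLP: each branch flattens
its 3 channels, applies one hidden ReLU layer (32 units by default) with
branch-private parameters, and the concatenated branch features feed a
softmax over the 4 classes. Training uses minibatch SGD (batch 32) with
momentum 0.9 and learning rate 0.001 under cross-entropy, per-branch
feature standardization fitted on the training set, 150 epochs by
default with the best-validation-loss parameters restored. Argmax ties
break toward the lowest class index. In 3-channel mode a single branch is
used. This is a deliberate desk-scale design: it exercises the
parallel-branch contract, the protocols and the map construction on one
CPU; it does not attempt to reproduce accuracies attainable with
full-size pretrained CNNs on real recordings.

Problem sizes used by the test bench and acceptance script — 13 subjects
× 4 × 20 trials for the end-to-end run, 6 subjects × 4 × 10 trials × 10
seeds for the jitter comparison, native 10×11 maps throughout — are the
package's standard desk-scale configuration; the generator also exposes a
preset reproducing the 2670-trial, 13-subject manifest shape of the
public dataset family this pipeline is designed around.

## Numerical and design notes

- Band-power equivalence with a naive O(N²) DFT oracle is maintained to
  better than 1e-8 relative; the closed-form/composition identity to
  1e-10 absolute.
- Comparison tables report mean accuracy in percent with the "increased
  rate" in percentage points (93.71 vs 92.62 → 1.09).
- Every pipeline artifact written by `run_pipeline` carries the SHA-256
  hash (16 hex chars) of the fully serialized run configuration, in a
  JSON field or a leading `#` comment line, so outputs trace to exact
  settings and seed.
- Known limitations: the enhancement's slope/unit coupling above; grid
  maps carry no inter-electrode distance information beyond adjacency;
  the NumPy classifier is single-threaded and makes no claim of parity
  with deep CNN feature extractors.
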