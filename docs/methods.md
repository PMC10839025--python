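# Methods

`gasfeeg` classifies single-channel EEG epochs as *normal* or *focal*
(seizure-onset-zone) activity by re-casting the time series as images and
applying classical computer-vision features and classifiers. This note
records the model, the conventions chosen where the procedure admitted
more than one reading, and what the synthetic data can and cannot
establish.

## Pipeline

1. **Epoching.** A signal of `n` samples is cut into consecutive windows
   of `epoch_len = 256` samples (no overlap by default); the trailing
   partial window is dropped. A 20-s recording at 512 Hz (10,240
   samples) therefore yields 40 epochs.
2. **GASF encoding.** Each epoch is min-max rescaled, mapped to polar
   angles `φ_i = arccos(x̃_i)`, and rendered as the Gramian angular
   summation field `G[i,j] = cos(φ_i + φ_j)`, a symmetric 256×256 matrix
   with entries in [−1, 1]. The matrix is computed through the algebraic
   identity `x̃_i x̃_j − √(1−x̃_i²)√(1−x̃_j²)`, which vectorizes and is
   exactly symmetric in floating point; tests verify agreement with the
   direct trigonometric evaluation to 1e−9 and the diagonal law
   `G[i,i] = 2x̃_i² − 1` to 1e−12.
3. **Quantization.** `pixel = round_half_up(255·(v+1)/2)` maps the
   matrix to an 8-bit grayscale image for the keypoint detectors. The
   dequantization error is bounded by 1/255.
4. **Keypoints.** SIFT (DoG scale-space extrema, contrast/edge
   rejection, 128-dimensional gradient descriptor) or ORB (multiscale
   FAST corners with intensity-centroid orientation, rotation-steered
   BRIEF bitstring). Descriptors are extracted from the quantized 8-bit
   image.
5. **Bag of visual words.** Training-split descriptors are pooled and
   clustered with Lloyd k-means (k-means++ seeding, fixed seed) into
   `k = 100` visual words; each image becomes the length-k histogram of
   nearest-word assignments (L1-normalized frequency by default, raw
   counts available).
6. **Chi-square selection.** Each histogram column is scored by
   `Σ_c (obs_c − exp_c)²/exp_c`, where `obs_c` is the column mass in
   class c and `exp_c` the mass expected under label independence; the
   top `k_select = 10` columns are kept. The selector is fitted on the
   training partition only.
7. **Classification.** RBF-SVM, random forest and k-NN on the selected
   features; held-out evaluation reports accuracy, precision, recall,
   specificity, F1, trapezoidal ROC AUC and log-loss, plus the confusion
   counts and ROC points.
8. **Noise robustness.** Held-out signals are corrupted in the raw
   signal domain with zero-mean Gaussian noise at SNR ∈ {5, 10, 15, 20} dB
   (`P_noise = P_signal / 10^(SNR/10)`, signal power = mean squared
   sample) and pushed through the *frozen* vocabulary, selection and
   classifier; nothing is refitted, which the sweep asserts by hashing.

## Conventions and open choices

* **Rescale range.** The min-max formula `(t − min)/(max − min)` maps to
  [0, 1], while the stated working range of the angular encoding is
  [−1, 1]. Both are implemented (`rescale_mode="unit"` / `"symmetric"`);
  the default is symmetric, following the stated intent. The two produce
  different images (angles in [0, π/2] vs [0, π]).
* **Normalization scope** is per epoch, not per signal: normalization
  sits inside the epoch loop of the procedure.
* **ORB bitstring.** The BRIEF string length `nd ∈ {128, 256, 512}` is a
  parameter with default 128. The library detector in use fixes 256
  bits, so the descriptor is computed here: `nd` comparison pairs drawn
  once from N(0, (31/5)²) inside a 31×31 patch (fixed pattern seed, part
  of the descriptor definition), rotated by the keypoint orientation,
  compared on a σ=2 Gaussian-smoothed image; bit = 1 iff I(p) < I(q).
  Keypoints whose rotated patch would leave the image are dropped.
* **Binary descriptors in k-means.** ORB bitstrings are unpacked to 0/1
  vectors so centroids are real-valued and both descriptor types share
  one clustering path.
* **Vocabulary order invariance.** The pooled descriptor matrix is
  sorted lexicographically before clustering, so the vocabulary does not
  depend on the order in which images were processed.
* **Split.** Default is image-level stratified 90/10, matching the
  published partition arithmetic (4,000 → 3,600/400). Image-level
  splitting lets epochs of one signal span both partitions, an
  information leak; `group_by_signal=True` keeps all epochs of a signal
  on one side and is used wherever "held-out" must mean unseen signals
  (e.g. the noise-monotonicity check).
* **Unstated hyperparameters.** SVM: C=1, RBF `gamma="scale"`; RF: 100
  trees, unlimited depth; k-NN: 5 neighbours. SVM ROC uses decision
  values; SVM log-loss uses Platt scaling (logistic fit on training
  decision values). Zero-denominator metrics are reported as 0 with a
  warning flag.
* **Noise evaluation pool.** Whether the published robustness protocol
  corrupted 40 signals or 40 epochs per class is ambiguous; both are
  supported (`noise_unit`), defaulting to signals. Per-class rows treat
  that class as positive (one-vs-rest); for a binary problem the two
  accuracy rows coincide while F1 differs.

## Synthetic data

The generator states a two-class world: **normal** = 8–13 Hz amplitude-
modulated rhythm over a 1/f (pink) noise floor (σ = 0.35); **focal** =
2–6 Hz dominant rhythm plus Poisson-timed (0.5 /s) spike-wave transients
with peak amplitude 3–5× the background standard deviation. Defaults are
50 signals per class, 20 s at 512 Hz. One global seed spawns per-signal
child seeds `(seed, class, index)`, so any subset is reproducible
regardless of batch size.

This emulates the gross spectral and transient contrast between the two
clinical classes — enough to give the GASF images visibly different
texture — but none of the hard parts of real EEG: electrode artifacts,
non-stationarity across minutes, inter-patient variability, or the
subtlety of focal signatures outside seizures. A green recovery test
therefore establishes that the pipeline is implemented coherently and
can separate separable classes; it does not establish clinical accuracy,
and the published accuracy tables (measured on clinical recordings) are
deliberately not reproduction targets.

## Numerical details

* Values are clipped to [−1, 1] (tolerance 1e−12) before `arccos`.
* Quantization rounds half up, so `v = 0 → 128`.
* Nearest-centroid ties in encoding and chi-square score ties in
  selection break to the lowest index.
* Constant epochs and zero-power signals raise dedicated errors rather
  than producing NaNs; empty keypoint sets propagate as all-zero
  histogram rows.
* The chi-square statistic on nonnegative feature mass equals the
  classical contingency statistic when features are counts; its p-values
  are calibrated for count-like features (verified against a Poisson
  null) but are heuristic for L1-normalized frequencies, where scores
  are used only for ranking.

## Known limitations

* skimage's SIFT/ORB implementations back the detectors; thresholds are
  pinned in `ExtractorConfig` but numeric keypoint positions may differ
  from other SIFT/ORB implementations (e.g. OpenCV's).
* `run_all` caching is coarse: the whole run is reused when the config
  hash matches, rather than per-stage invalidation.
* Binary-aware (Hamming-medoid) clustering for ORB is not implemented;
  unpacked 0/1 k-means is the single clustering path.
* Multichannel montages, EDF/BDF input and classes beyond the binary
  normal/focal pair are out of scope.
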