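# Methods

## Reflection data and resolution

Input is merged reflection data: unique Miller indices with one observed
value each — an intensity I_obs or, when no intensities are present, an
amplitude F_obs — plus optional uncertainties. MTZ files are read through
gemmi; observed-intensity columns (MTZ type `J`) are preferred over
amplitude columns (type `F`), and within a type the first column in file
order is used, which for multi-wavelength depositions selects the
first-listed dataset. Reflections with non-finite values or negative
uncertainties are dropped (with a logged count); negative merged
intensities are legitimate and kept. A plain-text dialect (`cell`/`kind`
header plus `h k l value sigma` rows at repr precision) provides exact
round-trips for fixtures and interchange.

Each reflection's resolution is computed from the general triclinic
reciprocal metric tensor G*: 1/d² = h G* hᵀ. The implementation is
cross-checked against gemmi's d-spacing on random triclinic cells to
1e-9 relative tolerance.

## Window table

Hexagonal ice diffracts at characteristic d-spacings; the shipped table
(`icering/data/ice_ring_ranges.csv`, versioned, overridable) lists eight
lettered windows A–H as closed intervals in 1/d²: 0.0640–0.0690,
0.0733–0.0765, 0.0838–0.0876, 0.1370–0.1440, 0.1950–0.2000,
0.2310–0.2380, 0.2600–0.2680 and 0.2790–0.2870 Å⁻², i.e. ring centres
near 3.88, 3.65, 3.42, 2.67, 2.25, 2.07, 1.95 and 1.88 Å.

## Histogram featurization

Each selected window is histogrammed into an 80 × 80 grid (`numpy
histogram2d` semantics: half-open bins, closed top edge).

* **x axis.** The displayed interval is the ring interval widened by
  `x_pad` ring widths per side (default 1, so the ring occupies the
  central third of the columns), binned uniformly in 1/d². Reflections
  are approximately uniform in reciprocal volume, which makes column
  occupancy even; the margin matters because a ring that fills its whole
  window at a uniform multiplicative factor would otherwise be almost
  invariant under the per-window percentile clipping and invisible. The
  binning coordinate is a config switch; 1/d² is the default.
* **y axis.** Clipped to the 0.5th–95th percentile of the displayed
  values (linear-interpolation percentile convention, stated so tests
  can be exact). Values outside the clip interval are excluded, not
  clamped — the clip exists to remove extreme outliers. A degenerate
  (constant-value) window puts all mass in the bottom row.
* **Normalization.** The count grid is divided by its maximum (a zero
  grid stays zero), making network inputs scale-free. Normalization is
  per plot, not global.
* **Orientation.** Row 0 is the lowest value bin (bottom), column 0 the
  window's low-resolution edge, fixed so sensitivity maps are
  comparable across plots.
* **Selection.** Only windows whose full displayed interval lies inside
  the data's resolution span are plotted; truncated windows are
  excluded rather than half-filled.

Windows with fewer than `min_reflections = 30` displayed reflections are
flagged low-count and reported nonpredictable: sparse histograms are a
known source of misclassification, and a warning is more honest than a
guess.

## Blank discrimination

Resolution shells omitted during integration produce (partially) blank
windows that the network has never seen. The discriminator cuts the
displayed interval into 5 equal sub-bins in 1/d² and flags the window
when any sub-bin's mean observed value falls below 0.01 × the set-wide
mean. An *empty* sub-bin counts as blank evidence only when the window
holds at least 5 reflections per sub-bin on average — in sparse data an
empty fifth of a window is expected by chance, and treating it as blank
would flood low-count datasets with false alarms. A window with no
reflections at all is blank trivially. Blank plots bypass the network
and are reported nonpredictable with a user warning.

## Network

Architecture (fixed shape, configurable widths): four blocks of
[conv 3×3 → batch norm → ReLU] × 2 → max pool 2×2, then flatten →
dense → dropout → dense → dropout → one sigmoid unit. Defaults: filters
(4, 8, 16, 16), dense (64, 32), dropout 0.3. These widths were chosen so
a full training run on a 1,600-plot corpus completes in about 1–2
minutes on one CPU; the engine is written in numpy (im2col-style shifted
GEMMs for the convolutions, analytic backward passes throughout,
gradient-checked against central differences) and is memory-bandwidth
bound, so width is the main cost driver. All widths are overridable;
the parameter-count arithmetic is unit-tested at a much wider
configuration as well. No automated hyperparameter search is performed.

Training: binary cross-entropy on the single logit, Adam at 1e-3, batch
size 32, 8 epochs by default; 80% of the plots go to the training split
and 20% to validation (seeded permutation), and the weights of the
best-validation-loss epoch are retained. Class weighting
(inverse-frequency, mean weight 1) is on by default because realistic
corpora are heavily imbalanced (~7.5% positives). Every stochastic step
(weight init, shuffling, dropout) draws from explicit seeded generators;
two runs with the same seed produce bit-identical histories.

Transfer learning continues optimization from a trained base at the
deliberately moderate rate 5e-4 (the default `transfer_learning_rate`),
so features already learned on one observable survive fine-tuning on the
other; zero-epoch transfer is exactly prediction-preserving. The
package's experiments follow the standard order for this workflow:
the amplitude network is trained fresh and the intensity network is
derived from it by transfer.

Classification threshold is 0.5, with the tie classified contaminated —
conservative toward flagging artefacts. Dataset aggregation is a logical
OR over the predictable windows; if no window is predictable the dataset
verdict is nonpredictable. Model bundles serialize architecture, plot
configuration and weights together so prediction always re-uses the
featurization the model was trained with.

### Sensitivity maps

SmoothGrad: the mean absolute input gradient of the score over
`n_samples` noise-perturbed copies of the plot (Gaussian noise with
standard deviation `noise_sigma` × input range; inference-mode batch
statistics). With one sample and zero noise this is the plain gradient
magnitude. Averaged over synthetic test plots, saliency concentrates on
the central ring columns and is lowest in the top/left/right edge bands.

## Evaluation

`ConfusionCounts` (positives = contaminated) feed accuracy = (tp+tn)/N,
sensitivity = tp/(tp+fn), specificity = tn/(tn+fp); zero denominators
raise an undefined-metric error rather than returning a number. Reports
attach normal-approximation (Wald) binomial 95% confidence intervals —
the CI method is presentation, clearly labelled, and not required to
match any external convention. Nonpredictable datasets are excluded from
the counts and reported separately. Published confusion counts of
external detectors on a 197-set benchmark ship as a fixture
(`published_benchmark_counts.csv`); those tools are not rerun here.

## Synthetic data

The simulator emulates exactly the statistics the classifier sees — the
(resolution, value) marginal — rather than full structure factors:

* unique Miller indices (one hemisphere) enumerated to d_min for a
  random orthorhombic cell, optionally subsampled to `n_target`;
* mean intensity ⟨I⟩(d) = A·exp(−B/(2d²)); per-reflection intensities
  are acentric (exponential) draws with Gaussian noise of sd
  `sigma_fraction`·⟨I⟩; amplitudes are F = √max(I, 0);
* contamination multiplies the intensities of a seeded fraction f of the
  reflections inside a ring interval by a spike factor s ≥ 1. f < 1
  models "accumulating" ice, where contaminated and clean measurements
  coexist at one resolution; a seeded random subset realizes that
  phenomenology directly;
* blank shells are omitted or zeroed per window.

Ground-truth labels apply the same visibility rule a human annotator
uses on the histograms: a spiked window is labelled contaminated only if
the spike changes the occupancy of ≥ 1% of the grid cells, measured by
overlaying the plot with and without the spike on a shared grid
(value axis clipped on the observed data). Sub-visible spikes are
labelled clean; naked-eye visibility criteria that cannot be automated
are represented by the spike-factor bands instead.

Corpus defaults: 7.5% of windows contaminated (mirroring the imbalance
of real annotated corpora), cells drawn from U(55, 85) Å — large enough
that reciprocal-lattice shells are dense across every window; small
cells would produce striped, unrealistic histograms — d_min from
U(1.55, 1.75) Å so all eight windows are present, Wilson B from
U(10, 35) Å², noise fraction U(0.05, 0.25), 15,000 reflections per set
(800–3,000 for deliberately low-count sets, 5% of the corpus), 2% blank
windows. Difficulty bands: strong spikes s ∈ [4, 8] with f ∈ [0.8, 1],
weak s ∈ [1.8, 3] with f ∈ [0.5, 1] (straddling the visibility rule on
purpose), accumulating s ∈ [3, 6] with f ∈ [0.3, 0.6]. The manifest
records every generated plot with its difficulty draw and whether it
entered the training arrays (blank and low-count plots do not).

What the simulator does *not* model: French–Wilson conversion of
intensities to amplitudes (it uses the plain square root), symmetry-
related multiplicity and completeness structure, anisotropy, detector
effects, and resolution-dependent ring profiles narrower than the
tabulated intervals. Passing the synthetic benchmarks therefore shows
that the pipeline recovers ring-like multiplicative artefacts from
(d, value) marginals under realistic falloff, noise and imbalance — not
that it matches any particular performance level on real deposited data.

## Problem sizes used by the tests and the acceptance script

Label recovery trains the default architecture on 1,600 simulated
amplitude plots (spike factors ≥ 3: the strong + accumulating mix, 7.5%
positives, class weighting, fixed seeds) and scores a fresh 60-dataset
held-out corpus; the test suite repeats this for three seeds and pools
the confusion counts. The transfer experiment fine-tunes that base for 4
epochs on an 80-dataset intensity corpus and compares base vs transferred
accuracy on a 40-dataset intensity held-out corpus. Blank discrimination
uses simulator-constructed blank windows (both omit and zero modes)
against unmodified sets of 1,000–15,000 reflections. Saliency maps are
averaged over 24–32 held-out plots with 8 SmoothGrad samples each. These
sizes were chosen as the smallest at which the corresponding effects are
stable and fast to compute on a single CPU.

## Known limitations

* The network defaults are deliberately small; for harder, more weakly
  contaminated corpora wider filters and more epochs are advisable.
* The blank discriminator's density guard means a genuinely blank
  sub-region of a very sparse window cannot be distinguished from
  sampling noise; such windows fall back to the low-count warning path.
* The saliency and averaged-plot geometry checks assume the default
  `x_pad = 1` margin (ring in the central third of columns).
* Confidence intervals use the normal approximation and degenerate to
  zero width at proportions of 0 or 1.
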