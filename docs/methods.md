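# Methods

`huecat` implements a probing protocol for asking whether a learned
visual representation carries *categorical* structure over the hue
circle, together with the analyses that distinguish categorical from
continuous behavior and a psychophysics-style analysis path that uses
identical machinery on observer response tables.

## The probing protocol

The hue spectrum is the circular family of fully saturated,
maximum-brightness colors, parameterized by a fraction `h ∈ [0, 1)`
(the edges of the RGB cube; `hue_to_rgb` is the standard HSV→RGB map at
S = V = 1).  A *band set* is K narrow circular intervals with centers
`shift + k/K`; the summed band widths are 20% of the circle, so each
band's width is `0.2/K`.

One probing cell works as follows.

1. Render training stimuli: the word "color" (font size 40, one of five
   DejaVu faces, binary glyph coverage) at a random position on a
   mid-grey 224×224 background, glyph pixels carrying a hue drawn
   uniformly from class k's band.
2. Push the rasters through a *frozen* feature extractor and train a
   probe head — a single affine softmax layer on standardized features,
   minibatch SGD (batch 64, learning rate 0.2), 500 train / 50
   validation samples per class, 5 epochs, keeping the per-epoch
   checkpoint with the best validation accuracy.
3. Evaluate the head on 60 freshly rendered stimuli at each of 100
   spectrum bins (bin b covers `[b/N, (b+1)/N)`; evaluation hues are
   bin centers).  The per-bin *mode* of the 60 predictions gives the
   one-dimensional mode row; its class transitions (circular bin edges
   where the mode changes) are the cell's border estimates.

The full experiment repeats this for K = 4…9 and 150 band shifts
spanning the circle (900 cells).  Transitions accumulated over cells
form the *transition count*; circular peak detection on the raw count
(scipy `find_peaks` on a 3× tiled signal, minimum separation 5 bins,
prominence 10% of the maximum — the count signal is also smoothed with
a circular Gaussian, σ = 1.5 bins, for display) yields the border set,
and each category's *prototype* is the circular mean of its member-bin
hues weighted by `1/(count+1)` (reciprocal weighting; +1 avoids
division by zero at untouched bins).

## Categorical vs. continuous signatures

Two simulated responders bracket the hypotheses without any training:

* **categorical** — carries planted circular borders; every evaluation
  hue is labeled by the class associated with its planted category
  (category→class via band-center membership; categories holding no
  band center map to the class whose center is nearest the category
  midpoint), so transitions sit on the planted borders for any shift;
* **continuous** — labels each hue with the circularly nearest band
  center, so transitions sit at inter-center midpoints and track the
  bands exactly.

Both flip each sample label to a uniform other class with probability
ε (default 0.05 in the study conditions; with 60 samples per bin the
mode is essentially never flipped, so ε models sample-level noise, not
row-level noise).

The *shift analysis* quantifies which regime a row stack matches.  Rows
are colored by their band-center hues and mapped to unit-circle
coordinate signals `(cos 2πh, sin 2πh)`; for each unordered row pair
the circular cross-correlation (summed over the x and y signals, all
lags, FFT-based) gives an optimal lag.  Lags are folded by the band
period `n_bins/K` — note this is rational (100/7 ≈ 14.29), and folding
by an integer approximation corrupts large lags, so the fold subtracts
the nearest integer multiple of the rational period before rounding to
bins; the folded support is −7…7 for K = 7.  Categorical stacks pile
shifts near zero; continuous stacks spread them over the period.  The
two count tables (positive shift distances, each pair once) are
compared with Fisher's exact test — full enumeration of fixed-margin
tables when the total is ≤ 200, otherwise Monte-Carlo over
Patefield-sampled tables (≥ 10⁵ draws, standard error reported) — and
with a histogram-intersection overlap statistic
`100 · Σ min(p_i, q_i)` (the overlap measure is our choice; the
comparison it supports is qualitative).

## The scratch categorical reference network

To exercise the full pipeline end-to-end without any external weights,
`make_scratch_category_backbone` trains a small convolutional network
from scratch to classify word stimuli into planted hue categories: the
raster is mean-pooled to 28×28, a 1×1 convolution (3→32 channels, ReLU)
is applied, global max pooling collapses space, and a dense ReLU layer
(16 units) feeds the softmax output.  Training uses label smoothing 0.1
and weight decay 3·10⁻³ for 100 epochs (SGD + momentum, lr 0.05 with
0.98/epoch decay), well past validation convergence (the run aborts if
validation accuracy never reaches 0.95).  The long smoothed-label
training matters: it collapses within-category feature variation toward
tight class clusters, which is exactly the property that makes the
frozen trunk (exposed up to the dense hidden layer) behave
categorically under probing.  The narrow 16-unit penultimate layer is
deliberate — wider layers retain more within-category hue gradient and
measurably blur the recovered borders.  Probing this extractor with
shifting bands recovers the planted borders to within ±0.01 of the hue
circle at desk scale.

## Evolutionary border search

The search treats a set of 7 circular borders as a genome.  Training
bands for a genome: each class spans two adjacent borders; with span s,
bands of width 0.1 s sit just inside either border, separated from it
by a 0.05 s gap.  Fitness is *learning speed*: the validation accuracy
of a probe head trained for only 3 epochs on those bands — genomes
whose borders align with the representation's categories learn faster.
Selection is rank-tiered (55% / 30% / 15% from the 1st / 2nd / 3rd
quartiles of 25; the bottom quartile never reproduces) with 10 elites
copied unchanged; recombination merges cross-parent border pairs closer
than 5% of the circle (closest first, disjointly) into their circular
mean and draws 7 from the pool; mutation shifts each border with
probability 2.5% by a wrapped normal (SD 2.5% of the circle) and is
switched off after generation 30 of 40.  Populations hold 100 genomes;
the study design pools the top 10 of 12 replicates (120 solutions) and
reports per-ordinal circular medians (borders sorted from anchor 0)
with RMS circular dispersion.

For desk-scale testing an analytic fitness oracle stands beside the
trained-head fitness: the Bayes accuracy of a readout on *purely
categorical* features, i.e. each planted category predicts its
majority class and the score is the correctly-assigned band mass.  We
use Bayes accuracy rather than raw per-class purity because purity is
blind to two classes sharing one category; that blindness creates a
broad neutral plateau (many borders crowded into few categories) on
which the search stalls, whereas the trained-head fitness — and the
Bayes form — penalize it.  With the oracle, 3 replicates at full scale
recover planted borders with per-ordinal median error < 0.01.

## Generalization experiments

*Within-category:* 7 training bands (width 10% of each category span)
slide from the left border to the right border in 10 steps (step
centers at `j/9` of the span, so the end steps straddle the borders),
15 repetitions per step, trained on multi-word stimuli — three target
words in the class hue plus two random-hue distractor words drawn on
top, on a random-hue background at 50% brightness.  Error is the
misclassification rate over the spectrum bins inside each training
band.  Under a categorical representation the end steps (bands
straddling borders) misclassify about half their band while interior
steps stay at the noise floor.

*Colored objects:* 14 classes — two bands per category, width 1/5 of
the category span, centered on the category's half midpoints — each
assigned a closed outline shape.  Shapes are filled by the enclosure
rule: a pixel is interior iff drawn line pixels exist strictly to its
left, right, above and below (a deliberately simple scan-based fill;
the 4-px lines are then redrawn on top).  The 14 outline families are
parametric (ellipses, polygons, stars, Fourier blobs, flowers, a
heart), regenerated per draw with random rotation/scale; held-out
evaluation outlines are generated after the training outlines.  Per
permutation of the shape→band assignment a probe head is trained and
each class is evaluated on 80 outlines × 100 fill hues.  A color-only
representation caps home-category accuracy at ~0.5 (two classes share
each category); shape-bearing features exceed that ceiling.

*Psychophysics path:* observer tables are the complete 35×35
match-to-sample grid (35 target hues × 35 shifts of a 7-hue choice
comb).  Per table row the chosen-class sequence over targets is
reduced to transitions with the very same machinery used for network
rows, at 35-bin resolution; counts accumulate over rows and observers.
The alignment test statistic is the mean pairwise Pearson correlation
between observers' per-bin transition counts; the null distribution
circularly shifts each observer's count vector by an independent
uniform offset per bootstrap replicate, and p is the fraction of null
statistics ≥ the observed one.  The observer simulator draws a
per-observer jittered copy of the planted borders, matches each target
to the choice sharing its category (nearest in hue if the category
holds several; nearest-hue fallback if it holds none) and lapses to a
uniform choice with a configurable rate.  The fallback means single
observers also show weak off-border transition bumps — real structure
of the design, visible beneath the seven dominant peaks.

## What the synthetic data does and does not show

Every experiment here runs on synthetic stimuli and either simulated
responders or the scratch-trained reference network.  Passing tests
therefore demonstrate that the *pipeline* — stimulus generation, probe
training, transition/peak/prototype analytics, the shift signature,
the evolutionary search and the bootstrap — behaves correctly and
recovers planted ground truth through a genuinely trained
representation.  They do not, by themselves, say anything about any
particular pretrained network; for that, any extractor satisfying the
`FeatureExtractor` contract (a deterministic raster → fixed-length
vector map) can be plugged into the same drivers.

## Numerical and design choices

- Hues are fractions in [0, 1); all circular arithmetic wraps modulo 1.
  Band membership uses half-open intervals so shared edges are
  unambiguous.
- Glyphs render without anti-aliasing so "glyph pixels carry exactly
  the target color" is exact; mid-grey is (128,128,128) and 50%
  brightness rounds half-up (max background channel 128).
- Mode ties break to the lowest class index; a circular mode row never
  has exactly one transition.
- Cross-correlation tie-breaks: smallest |shift|, then negative.
- The desk preset (50 shifts, K ∈ {5,6,7}, 100/20 samples per class,
  20 evaluation samples per bin, population 40, 15 generations) scales
  counts only — formulas and thresholds are identical to the full
  design.  The full-scale problem sizes used by the verification
  script are stated in the README.
- Failed probe trainings are excluded from accumulation and counted;
  the run log records them.
- A single global seed fans out via `numpy.random.SeedSequence([seed,
  *keys])`, making every sub-experiment independently reproducible.

## Known limitations

- The probe optimizer settings (batch size, learning rate) are fixed
  choices; row-level noise depends on them even though border locations
  are robust.
- The enclosure fill is direction-based, not topological: concave
  shapes may fill pockets a flood fill would not, exactly as the rule
  dictates.
- The scratch reference network is small and its categorical sharpness
  depends on prolonged smoothed-label training; it is a reference
  implementation of the extractor contract, not a model of any
  particular architecture.
- The overlap statistic (histogram intersection) is one of several
  reasonable definitions; treat cross-study comparisons of its value
  with care.
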