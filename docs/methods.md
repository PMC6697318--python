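# Methods

This note records the package's modeling and implementation choices in its
own terms: what is computed, under which conventions, and why.

## Domain model

A B-scan is a 2-D grayscale image with intensities in [0, 1], the vitreous at
row 0 and depth increasing with the row index.  Two acquisition geometries
are modeled: spectral-domain (SD; 384/768/1024 × 496 px) and swept-source
(SS; 512 × 992 px).  An annotation is a triple of fractional per-column row
coordinates — ILM, CC, CSI — satisfying `ilm ≤ cc ≤ csi` at every column and
staying inside the image.  A label mask assigns every pixel one of four
labels (0 vitreous, 1 retina, 2 choroid, 3 sclera).  Masks rasterized from
annotations are column-monotone by construction; raw network predictions need
not be, so monotonicity is a query, not an invariant.

## Rasterization

Fractional boundaries are snapped to pixel rows by round-half-up,
`R(t) = floor(t + 0.5)`.  A pixel at row `r` in a column with rounded
boundaries `R(ilm), R(cc), R(csi)` is

- vitreous if `r < R(ilm)`
- retina if `R(ilm) ≤ r ≤ R(cc)` (Bruch's membrane is merged into the retina
  compartment: it is too thin to resolve as its own layer)
- choroid if `R(cc) < r ≤ R(csi)`
- sclera if `r > R(csi)`

This is a full partition for any ordered trace triple, and because the label
encoding follows anatomical depth order, the label equals the sum of three
indicator steps — the implementation used.  The inverse map (mask → lines)
takes the first retina row, last retina row and last choroid row per column,
with explicit collapse rules for degenerate columns; for any mask produced by
the forward map the round trip is exact.

## Synthetic phantoms and simulated graders

Phantoms emulate the gross axial reflectivity of a posterior-segment scan:
dark vitreous (0.05), bright retina (0.60), darker textured choroid (0.35)
with a thin dark choriocapillaris band below the CC, brighter sclera (0.55),
multiplied by unit-mean gamma speckle.  Boundaries are sinusoids (fundamental
plus half-amplitude second harmonic, random phase/frequency) around mean
depths 0.15/0.45/0.70 of image height; configurations whose boundaries cross
or leave the image are rejected, not silently clipped.

Simulated graders redraw the true boundaries with a per-line constant bias
plus smooth correlated jitter: white noise convolved with a Gaussian kernel
normalized to unit L2 norm, so the pointwise standard deviation equals the
nominal sigma exactly while neighbouring columns remain correlated over
~40 px (humans draw continuous lines, not independent per-column errors).
Default group sigmas (ILM, CC, CSI in px) are L (2.0, 3.0, 9.0),
EO (1.2, 1.8, 5.0), RC (0.8, 1.2, 3.0) — the CSI is always the noisiest line,
and laymen are noisier than expert ophthalmologists, who are noisier than
reading-center experts.  These are package defaults for synthetic
benchmarking, not estimates of any real grader population.  Jittered lines
are re-projected onto the ordering invariant by clamping and clipped to the
image.  Every annotation is deterministic given (grader seed, run index,
image id), with the image id hashed by CRC-32 so results are stable across
processes.

The benchmark fixture is 30 SD + 30 SS phantoms with ground truth, 9 grader
profiles (3 per group, with per-grader biases drawn at N(0, sigma/3)), and 3
simulated runs per grader per image — 1620 annotations.

## Augmentation and splitting

Each labeled scan contributes itself, its left–right mirror, and one copy
rotated by an angle drawn uniformly from ±8° (bilinear for images, nearest
neighbour for masks, edge-replicated borders), tripling the dataset.  The
train/validation split is grouped: all augmented variants of a source image
land on the same side, the training side being the largest grouped subset not
exceeding `floor(0.8 · n)`.  With groups of three this hits the target
exactly: 6210 → 4968/1242.

## Network

The segmenter is a U-shaped encoder–decoder with skip connections: per
resolution level a block of 3×3 same-padding convolutions with ReLU, 2×2 max
pooling on descent, learned 2×2 stride-2 transposed-convolution upsampling on
ascent, channel doubling per level, and a 1×1 convolution to four class
logits.  The default uses **six** resolution levels — one more than the
classic five-level U-Net — and **three** convolutions per level, which makes
the receptive field of an output pixel cover the whole 512×512 input.  This
is not assumed but measured: `receptive_field_support` replays the
architecture backwards as an influence map (3×3 convolution → 3×3 dilation;
transposed convolution → 2× block reduction; pooling → 2× block repeat; skip
concatenation → union over both paths) and is itself validated in the test
suite against a perturbation oracle on a real network.  Closed-form
receptive-field formulas are only an upper bound here because they ignore
pooling-block alignment; the probe is exact.  At six levels the probe shows
full 512×512 coverage; at four levels it does not.

Training: unweighted pixel-wise softmax cross-entropy, Adam (default learning
rate 6e-5), Xavier-uniform initialization, mini-batches of four, ten epochs,
no further regularization; optional patience-based early stopping on
validation loss.  Inputs of any geometry are resized to the network size
(bicubic for images, nearest for masks) and predictions resized back with
nearest neighbour.  Prediction is per-pixel argmax of the softmax, ties going
to the lowest class index.

All tensor arithmetic is hand-written numpy (float32, NHWC layout).  The k×k
convolution is computed as k² shifted-view channel matmuls against the
zero-padded input, which keeps the work in BLAS without materializing an
im2col buffer; backward passes are derived analytically and verified against
float64 central differences in the test suite.

## Agreement scoring

For one compartment, the IOU (Jaccard index) of two masks is
`|A ∩ B| / |A ∪ B|` over its pixel supports; when the compartment is absent
from both masks the score is defined as 1.0 (both raters agree it is
absent).  Four designs are computed over an n-image benchmark:

- intra-grader: all three unordered run pairs per image → 3n scores per
  compartment (180 at n = 60);
- inter-grader: all three unordered grader pairs within a group, first runs
  → 3n scores;
- CNN vs group: the prediction against each group member's first run → 3n
  scores;
- CNN vs ground truth → n scores.

Each score set carries provenance (image id, pair label) and is summarized by
its five-number summary plus mean — the numbers behind one box plot.

## Statistical comparison

Two score sets are compared with a two-sided test at the 1% significance
level: Welch's unequal-variance t-test when both samples pass a Shapiro-Wilk
normality gate at alpha 0.05, and the Mann-Whitney U-test otherwise.
Mann-Whitney p-values use exact enumeration for small tie-free samples
(pooled n ≤ 12) and the normal approximation with tie and continuity
corrections otherwise.  Degenerate inputs are handled explicitly: a constant
sample never passes the normality gate, and two identical constant samples
compare at p = 1.  The test suite cross-checks Welch against a direct
textbook-formula computation, Mann-Whitney against exhaustive permutation
enumeration, and the full gate-then-test pipeline against simulated null data
(observed type-I error 0.007 at the nominal 0.01 over 2000 replicates of two
n = 180 samples).

## Scaled configurations

The full-scale recipe (512×512, six levels, 64 base channels, lr 6e-5) is the
package default but is sized for GPU hardware.  For CPU demonstrations and
the acceptance run a documented scaled configuration is used: 128×128 inputs,
five levels, eight base channels, two convolutions per level, Adam at 1e-3,
four epochs, with phantom boundary curvature scaled proportionally to the
smaller image height.  On 200 training / 50 held-out phantoms this reaches
held-out mean IOU ≥ 0.96 in every compartment in about two CPU-minutes,
preserving the qualitative ordering (choroid hardest, vitreous/sclera
easiest).

## Reproducibility

Every stochastic stage takes an explicit seed; the pipeline derives per-stage
seeds from one master seed by hashing the stage name, so a rerun with the
same configuration reproduces every artifact bit for bit on one machine.
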