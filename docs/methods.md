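# Methods

## The problem and the approach

A cryo-EM reconstruction is a 3D scalar grid whose level of detail —
its resolution, in Angstrom — is conventionally summarized by one FSC
number. `cryores` treats resolution assessment as supervised
classification instead. Density maps are simulated from atomic models
at known resolutions, and networks are trained to recover the
resolution class from the map alone: a global 3-class label
(high <5 Å, medium 5–10 Å inclusive, low >10 Å) for whole maps, and a
10-bin per-voxel label (half-open bins [0,2), [2,3), …, [9,10),
[10,∞)) for local-resolution estimation, where voxel-wise labels in
practice come from tools such as MonoRes or ResMap.

## Gaussian-atom simulation

Every atom contributes an isotropic 3D Gaussian. The normative
property is spectral: the rotationally averaged Fourier amplitude of
the atom kernel must fall to one half of its zero-frequency value at
spatial frequency s = 1/R. Since the transform of exp(−r²/2σ²) is
proportional to exp(−2π²σ²s²), solving exp(−2π²σ²/R²) = 1/2 gives

    σ(R) = R · sqrt(ln 2 / 2) / π  ≈ 0.187 · R   [Angstrom].

At the highest training resolution (2.5 Å on a 1 Å grid) σ ≈ 0.47 Å is
*below* the voxel size. Sampling such a Gaussian in real space aliases
badly — the measured half-amplitude crossing lands ~9–30% off contract
depending on the sub-voxel atom offset. The simulator therefore works
in Fourier space: it multiplies the exact point-atom structure factor
(computed per axis and contracted with a BLAS matmul) by the Gaussian
transfer function on the DFT frequency grid and inverse-transforms.
On the sampled grid the contract then holds by construction; measured
single-atom ratios at 2.5/7.5/12.5 Å are 0.499/0.503/0.493, the
residual deviation coming from the discreteness of the radial shell.

Two consequences are handled explicitly:

* **Exact zeros.** Empty-cube removal and mask construction rely on
  empty space being exactly zero. After synthesis, voxels whose
  amplitude is below `zero_tol` (default 3·10⁻⁴) times the map peak are
  clamped to exact zero. Because the kernel decays with distance this
  zeroes everything beyond a structure-dependent support radius while
  perturbing the half-amplitude ratio by well under 1%. A fixed-radius
  ball clamp was measured to distort the spectrum of sub-voxel kernels
  by several percent and is not used.
* **Negative side lobes.** A band-limited sub-voxel kernel necessarily
  rings; the small negative lobes are genuine spectral content (their
  removal drags the half-amplitude ratio down to 0.17–0.43 at R ≤
  3.5 Å) and are preserved. Simulated maps may therefore contain small
  negative values before min-max normalization.

Atoms are translated so their centroid sits at the box center, with
the shift clamped per axis so a structure that fits the box never
crosses its boundary. Atom weights default to 1.0, with an option to
weight by atomic number; the rendered map is linear in the weights.

## Synthetic structures

Because the pipeline must run without downloads, training structures
are generated: stiff, self-avoiding random chains with an exact 1.5 Å
step (backbone-bond scale). The walk direction persists within
segments (persistence 0.92, direction redrawn at rate 1/15 per step,
segment length ≈ 15 atoms ≈ 22 Å) and atoms respect a ~1.2 Å
excluded-volume distance, relaxed progressively if the walk is
trapped. The stiffness matters: real protein maps owe their
resolution-dependent appearance largely to secondary-structure
elements — helices read as cylinders at medium resolution and merge
into blobs at low resolution — and rod-like segments reproduce that
signature. Shapeless random-walk blobs, tried first, yield corpora on
which small-sample classification degenerates to memorization
(multi-layer perceptrons plateau at 50–75% held-out accuracy while a
linear baseline reaches 83–93%); with stiff chains the same networks
reach 90–100%.

Desk-scale corpora use 1000-atom chains in a 25.6 Å extent (0.8 of the
32 Å box edge), i.e. ≈ 0.06 atoms/Å³, near real protein packing
density, and filling the box the way the full-scale simulated corpus
is described. Local-resolution phantoms render one shared structure at
several resolutions and stitch axis-aligned slabs (or concentric
shells), so every in-mask voxel has an exact, by-construction 10-bin
label; labels depend only on the region resolution, not the density
scale.

## Preprocessing

All rules operate on (input, label) pairs in lockstep and preserve
shape equality at every stage:

* **Min-max normalization** to [0,1]; a constant map maps to all zeros
  (and then counts as empty downstream).
* **Central crop / trailing zero-pad** to 64³ for experimental-style
  inputs: oversized axes lose their outer parts symmetrically,
  undersized axes get zeros appended at the end.
* **Power-of-two padding** for the patch branch: each volume grows to
  the smallest power-of-two cube ≥ its largest dimension, padding split
  evenly per axis with the odd leftover voxel assigned front or back by
  a seeded coin flip. These are deliberately two distinct protocols.
* **Masking**: binary masks zero everything outside the structure; by
  default the mask is taken from the label volume (background sentinel
  −1), or it may be supplied externally.
* **Partitioning**: non-overlapping 16³ cubes; cubes whose input is
  identically zero are dropped (exact-zero test by default; a
  `zero_tol` exists for noisy maps), with label cubes removed in
  lockstep and corner offsets recorded so predictions can be
  reassembled; removed positions re-fill with the background sentinel.
* **Splitting**: validation and test sizes are round(ratio·n), training
  takes the remainder; deterministic given the seed.

## Architectures and training

The three networks follow their published layer listings exactly;
hidden widths and filter counts are constructor arguments so that
desk-scale variants train in tens of seconds while the defaults give
the full-size networks (the 64³ dense classifier has 262,245,403
trainable parameters; the first convolutional layer of the 3D CNN has
11,008).

Implementation notes:

* Convolutions are stride-1 with 'same' zero padding (asymmetric for
  even kernels, TensorFlow convention); forward passes run as im2col
  GEMMs chunked over the batch, backward passes as per-kernel-offset
  GEMMs, all in float32.
* The U-Net takes its skip connection from each encoder level's
  channel-dropout output and joins it with the 2³-kernel convolution
  of the upsampled deeper features; upsampling is parameter-free
  nearest-neighbor.
* The 3-class loss is sparse softmax cross-entropy on integer labels;
  the U-Net loss is per-voxel categorical cross-entropy with
  background-sentinel voxels excluded by a weight mask (accuracy
  excludes them the same way).
* "Iterations" in the early-stopping rules are read as epochs (traces
  are recorded per epoch). Training stops at the epoch budget or once
  max(patience, 1) consecutive epochs pass without a new validation-
  loss minimum; the weights of the best epoch are restored.
* Optimizers: constant-rate gradient descent and Adam, both with an
  optional L2 weight-decay term (default 0). Desk-scale dense-network
  runs use Adam (lr 10⁻³, batch 16, weight decay 10⁻³): at ~100
  training maps the published full-batch recipe overfits before it
  generalizes.
* ELU is used on the first two CNN convolutions, ReLU on the third;
  prediction ties break to the lowest class index (argmax).
* All weight initialization (He), shuffling and dropout draw from
  seeded generators; training is bit-reproducible on a fixed device.

Desk-scale configurations used by the tests and the acceptance script:
dense net (200, 50) hidden units; CNN filters (4, 8, 16) with a
32-unit dense layer; U-Net filters (8, 16, 32) with dropout 0.2,
Adam lr 3·10⁻³, patience 10 over a 24-epoch budget (shorter budgets
can stop inside an early validation-loss plateau before the voxel
classifier converges). The 3-class runs use 150 maps (50 per class) split
72/8/20 — the same ratios as the published patch-repository split —
because at this corpus size the 60/20/20 split leaves too few training
maps for the dense net to clear 90% reliably. The U-Net runs use ten
two-bin (2.5 Å / 12.5 Å) slab phantoms, 32³ boxes, ~80 patch cubes.

## Evaluation

Confusion matrices count published × predicted classes (rows = true).
Combined agreement is 100·trace/total. Per-class sensitivity,
specificity, PPV and NPV are computed through the partial-class-
membership formulation — expected co-membership counts
TP_k = Σᵢ tᵢₖ·pᵢₖ and so on — which reduces exactly to one-vs-rest
counting for crisp labels; both entry points are exposed. Percentages
are rounded half-up to one decimal (the only convention under which
19/26 prints as 73.10% and 10/18 as 55.60%) and formatted with two
decimals for report parity. Ratios with empty denominators are
reported as NA, never 0 or 100.

The boundary scan simulates one normalized map per grid point
(1.5–15.0 Å in 0.5 Å steps, a distinct random structure each),
classifies it, and reports every resolution at which the predicted
class changes. The cross-evaluation grid feeds each evaluation set to
each model and tabulates categorical accuracies, emitting NaN for
incompatible pairs rather than aborting.

## What the synthetic tests do and do not show

The generator reproduces the *geometry* of the published study —
noise-free Gaussian-atom maps, box-filling structures, exact voxel
labels, the stated class bins and split ratios — but not experimental
reality: there is no noise, no CTF, no solvent, no heterogeneity, and
the structures are synthetic chains rather than real folds. Passing
the desk-scale learning checks shows the architectures, losses and
pipeline plumbing learn the intended signal at small scale; it does
not certify accuracy on experimental maps, where the published study
itself saw agreement drop to ~60%. The published full-scale accuracies
(92.73% / 99.75% global test, 88.3% / 94.7% voxel-wise) require the
38,013-map simulated corpus and EMDB-derived label volumes plus GPU
training, and are out of scope; the package reports its own desk-scale
measurements instead.

## Known limitations

* Heterogeneous experimental voxel spacings are preserved, not
  resampled; callers must resample if they need 1 Å/voxel inputs.
* The NumPy layer stack is single-device CPU code; full-size (64³)
  network *training* is out of reach — full-size builds are used for
  parameter-count and geometry checks only.
* The amplitude-threshold zero clamp makes far-field support
  data-dependent; maps of very diffuse structures keep more low-level
  ringing than a fixed-radius cutoff would.
* Phantom regions are axis-aligned slabs or concentric shells; real
  local-resolution fields are smooth and irregular.
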