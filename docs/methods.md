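# Methods

## Data model

A fibre orientation distribution (FOD) is an antipodally symmetric spherical
function per voxel, stored as coefficients of the *real, even-order*
spherical-harmonic (SH) basis with orthonormal normalisation and MRtrix-style
channel ordering (`l` ascending, then `m` from −l to +l).  The basis size is
`(lmax+1)(lmax+2)/2`: 28 channels at the default `lmax = 6`.  `SHImage`
carries the 4-D coefficient grid plus physical voxel sizes only; no full
affine is kept because nothing in this pipeline needs world-space
registration.  Basis functions are built from `scipy.special.sph_harm_y`
as √2·Im(Y_l^|m|) for m<0, Y_l^0, and √2·Re(Y_l^m) for m>0 (Condon–Shortley
phase included); the unit tests check every channel against an independent
associated-Legendre recurrence written from the textbook formulas.

**Rotation of SH coefficients** is implemented by sampling the rotated
function on a 512-point golden-spiral lattice (≥ 4× the coefficient count)
and refitting by least squares, rather than by Wigner-matrix recursion.  The
sample-and-refit operator is exact for band-limited inputs up to quadrature
error; the per-band norm preservation and composition tests bound that error
below 1e−6, which is far under the interpolation error of any spatial
resampling it is combined with.

**Cropping** interprets slice ranges as 0-based inclusive intervals
(137−10+1 = 128 slices kept).  **Regridding** preserves the physical field
of view: voxel size scales by old_dims/new_dims per axis, values are
interpolated trilinearly per channel on voxel-centre coordinates (the
upstream tool the data-preparation step mimics does not name its kernel, so
the conventional choice is used and stated here).

## Synthetic phantoms

The generator emulates the qualitative structure of brain FOD training
data, not its intensity statistics: an ellipsoidal "brain" support with
exactly zero background; 1–3 smooth fibre bundles (quadratic Bézier
centrelines, tubular cross-section, default radius 3 mm) whose voxels carry
a single-fibre SH lobe aligned with the local tangent, summed in crossing
voxels; an isotropic "ventricle" ellipsoid carrying only the l = 0 channel;
Gaussian coefficient noise (sd 0.005) inside the brain mask; and per-subject
geometric jitter (sd 0.5 mm on the control points) to mimic inter-subject
variability.  Ground-truth bundle masks and streamline sets are emitted with
each phantom, so tract metrics can be tested without tractography.

The single-fibre lobe is a Watson-like kernel `exp(κ((u·t)² − 1))` with
κ = 5, fitted once to the SH basis.  κ was chosen so that (a) the lmax = 6
truncation ringing stays within 2 % of the per-voxel peak amplitude
(the suite asserts amplitude ≥ −0.02·max on a dense direction grid), and
(b) two orthogonal crossing lobes still resolve into two distinct maxima
within 15° of the true tangents.  Aligning the lobe to a tangent uses the
zonal-harmonic addition theorem (coefficients `c_l·√(4π/(2l+1))·Y_lm(t)`),
which is mathematically identical to rotating the canonical lobe through
the SH rotation operator — the suite asserts the equality — but vectorises
over all bundle voxels at once.

Default conditions: 16×16×8 grid at 2 mm voxels for metric-level tests,
32×32×16 for training runs; bundle amplitude 1, ventricle amplitude 1,
background amplitude 0.2.  Seeding: one root seed expands to per-subject
child seeds by `seed + index`, with a separate fixed-offset stream for
geometry jitter, so cohorts are reproducible element-wise and
order-independent.  What passing tests on phantoms do *not* show: realism of
intensity histograms, partial-volume effects, scanner noise structure, or
anatomical priors — conclusions about real data need real data.

## Augmentation

Each dataset expands to five instances: the original, one small rotation
about each principal axis, and one triply-rotated variant (R_z·R_y·R_x),
all angles drawn N(0, 1°).  "Four slightly rotated versions" decomposes as
3 single-axis + 1 triple because that is the only split consistent with one
rotation "around each main axis" plus the separately described triple
variant, and it reproduces the ×5 pool arithmetic (965 → 4825).  Rotation
resamples the spatial grid trilinearly about the grid centre with zero
padding (boundary effects are negligible at 1° angles) and, by default,
also reorients the per-voxel SH coefficients with the same rotation
(`reorient_sh=False` gives grid-only rotation for comparison).

## Networks

The four sub-networks are declared as layer tables (`NetSpec`) and validated
by a symbolic shape trace at construction.  Full scale: the Generator lifts
a 5000-dimensional latent onto a 4×4×4 grid with a transposed convolution
(3200 channels, batch norm, leaky-ReLU 0.1), then five blocks of
nearest-neighbour upsampling + 3×3×3 convolution reduce channels
3200→1600→800→400→200→28, the last block upsampling only in-plane (2,2,1)
and ending in tanh — output 28×128×128×64.  The critic uses six strided
convolutions 28→125→250→500→1000→2000→1 (kernel 4, stride 2, the fifth
layer (4,4,3)/(2,2,1), batch norm in layers 2–5, leaky slopes
0.2/0.05/…/0.05, no final activation); the Encoder is identical except its
final layer emits the latent dimension; the Code Discriminator is the MLP
5000→4096→4096→1 with batch norm and leaky-ReLU 0.2 in its first two
layers.

Design choices where the tables are silent: the latent enters as
`latent_dim` channels on a 1×1×1 grid (standard DCGAN lifting); layer order
is conv → batch norm → activation; initialisation is fan-in-scaled normal,
seeded per network; batch norm in the critic is kept as tabled even though
WGAN-GP practice often omits it — fidelity wins, and a scaled variant can
disable it by editing the spec.  The Encoder is deterministic (a single
latent vector, no mean/log-variance split); Gaussianity of encoded latents
is enforced adversarially by the Code Discriminator.

`ModelScale` derives desk-scale variants from the same tables: output dims
must be divisible by (32, 32, 16) — the fixed spatial factor between the
lifting grid and the output — channel counts multiply by a factor (floor 2),
and the two resolution-dependent kernels (Generator lifting, critic final
collapse) become `dims/(32,32,16)`, which reproduces the printed kernels
exactly at full scale.  The reference desk scale is 32×32×16, channel
multiplier 1/50, latent 64.  Paper-scale networks instantiate on CPU for
shape/parameter checks using zero-fill initialisation (allocation without
touching pages), since their ~10⁹ parameters exceed what a test should
materialise.

## Autodiff engine

No deep-learning framework is part of the dependency set, so the networks
run on `fodgan.autodiff`, a ~500-line reverse-mode engine over NumPy arrays:
broadcasting arithmetic, reductions, matmul, im2col/col2im (convolution and
transposed convolution are compositions of these two linear primitives with
matmul), nearest-neighbour upsampling with its block-sum adjoint, and the
pointwise nonlinearities.  Backward passes construct graphs from the same
primitives, so second derivatives — required because the gradient penalty's
parameter gradient differentiates through the critic's input gradient — are
exact; the suite checks them against finite differences and against the
closed form for a linear critic.  The patch copy/scatter kernels are jitted
with numba; batch norm is composed from primitives (mean/power/multiply) so
it is transparent to the double backward.  Everything is float32 in
training, float64 in numerical tests.

## Training

One epoch is one schedule iteration on freshly drawn batches: compute
`L_GE` and step E once and G twice, *recomputing the loss before every
optimiser step on the same batch*; then four iterations of fresh batches
and a D step on `L_D`; then one CD step on `L_CD`.  "Epoch" cannot mean a
full data pass at the stated batch size, so a schedule iteration is the
operative unit.  Fresh batches for each D loop follow standard WGAN-GP
practice.  Adam uses the framework-conventional β = (0.9, 0.999); only the
learning rate (1e−4) is part of the recipe.  Interpolant coefficients α, β,
γ are drawn per batch item.  The gradient-norm penalty adds 1e−12 inside
the square root for differentiability at the origin; for a constant critic
this shifts the penalty by ~2e−6, far inside every tolerance used.

λ = 50 000 is kept unchanged at desk scale: the L1 term is a *sum* over all
voxel-channels, so it dominates the O(1) adversarial terms by orders of
magnitude at any scale, and Adam's per-parameter normalisation makes the
absolute magnitude of the dominant term immaterial.  Intensity
normalisation maps each channel into [−1, 1] (tanh range) by its cohort-wide
max-abs, computed once and stored with the checkpoint; out-of-range values
at application time are clipped and counted.

Determinism: all randomness flows from the run seed through one PCG64
generator whose state is checkpointed, so two same-seed runs produce
bit-identical loss trajectories and a resumed run reproduces an
uninterrupted one exactly.  A non-finite loss aborts with a checkpoint
rather than propagating NaNs.

Held-out reconstruction (`reconstruction_l1`) is evaluated with batch-norm
*batch* statistics — the same normalisation the training objective uses —
with running buffers snapshotted and restored; running statistics lag the
batch statistics badly at short epoch counts and would conflate
normalisation drift with reconstruction quality.  Generation from a trained
checkpoint uses the conventional inference path (running statistics).

## Validation metrics

Dice is the exact overlap formula (error, not 0, for two empty masks).
Pairwise SSD enumerates unordered pairs.  Global efficiency uses edge
lengths 1/weight (brain-connectivity-toolbox convention), Dijkstra
shortest paths via `scipy.sparse.csgraph`, efficiency 0 for disconnected
pairs, and a mean over all n(n−1) ordered pairs; a hand-rolled
Floyd–Warshall is the independent oracle in tests.  Connectomes normalise
to total weight two (each connection counted twice in a symmetric matrix).
The Mantel statistic is the Pearson correlation of upper-triangle entries
(Spearman selectable); the p-value permutes node labels of one matrix with
the add-one estimator, default 9999 permutations.  Streamline resampling is
equidistant in arc length with endpoints preserved exactly.  Rasterisation
walks every segment with a 3-D DDA (voxels are marked when *traversed*, not
when a vertex lands in them), which keeps masks continuous at coarse
spacing.  The apparent-fibre-density map is the FOD's spherical integral
(c₀·√4π) — a deliberate simplification of fixel-wise AFD, which would need
FOD segmentation; the along-tract machinery accepts any scalar map, so an
externally computed AFD volume can be substituted.  Tract "volume" is mask
voxel count × voxel volume.  Along-tract profiles trilinearly sample the
map at 100 resampled points per streamline and report mean/sd across
streamlines per increment.  Rank-sum comparisons delegate to
`scipy.stats.mannwhitneyu` (two-sided).

## Problem sizes in the default test run

The suite runs everything end-to-end at sizes chosen for a single-CPU
desk machine: metric tests on 16×16×8 phantoms; training-mechanics tests at
batch 2 for 2–8 epochs; the end-to-end acceptance run at the reference desk
scale (32×32×16, latent 64, batch 6, λ = 50 000, κ = 10) for 40 epochs on a
20-phantom cohort with 4 held out, which is enough for the reconstruction
term to fall well below its epoch-1 value while exercising every code path
of the objective; the Mantel calibration uses 200 replicates of 999
permutations on 20-node matrices.  Full-scale training (thousands of epochs
on hundreds of subjects) is a multi-GPU undertaking outside the package's
test scope; the architecture itself instantiates and shape-checks at full
scale.

## Known limitations

- The engine is CPU-only and unoptimised beyond the jitted patch kernels;
  it is a faithful numerical implementation, not a performance framework.
- Phantoms do not model partial volume, noise floors, or realistic
  intensity distributions; metric values on phantoms are not comparable to
  values on scanner data.
- AFD is the l = 0 spherical integral, not fixel-wise AFD.
- The Encoder is deterministic; there is no reparameterised posterior, so
  the autoencoder branch is a regularised autoencoder rather than a full
  VAE even though the λ-dominated regime behaves like one.
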