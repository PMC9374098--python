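# Methods

This note records what `protondl` computes and why each piece is built the way
it is. It is the package's scientific account of itself; the README covers
usage.

## Problem

Pencil-beam (PB) proton dose algorithms ray-trace water-equivalent path length
(WEPL) only along each pencil's central axis and spread dose laterally under a
homogeneous-medium assumption. At lateral tissue interfaces this is wrong: the
true range of protons passing on either side of an interface differs, and
scatter differs through dense material. Transport-based calculations (Monte
Carlo in the clinic) capture this but cost far more. `protondl` learns the
map from (PB dose, CT) to transport-quality dose with a 3D HD U-Net, and
ships a deterministic synthetic simulator so the whole study runs on one CPU
with no clinical data.

## Synthetic simulator

Two dose engines share one field decomposition and one parametric depth-dose
model (flat entrance plateau at 1/3.5 of the peak, Gaussian proximal shoulder,
Gaussian distal falloff of width 1.2% of range; spread-out peaks are
non-negative least-squares combinations of pristine peaks). They differ
exactly where PB and transport differ:

* **PB engine** — pencils on a lateral lattice; each pencil ray-traces WEPL on
  its own axis only and deposits a lateral Gaussian whose width grows with
  geometric depth. Off-axis heterogeneity is invisible (the PB blind spot).
* **Transport engine** — the lateral fluence and its carried WEPL are marched
  layer by layer along the beam axis on a lattice at least twice as fine as
  the pencil pitch. Each fluence element accumulates the WEPL of the material
  it actually traverses, and lateral spreading is a conservative explicit
  diffusion whose coefficient scales with local stopping power. Fluence that
  drifts across an interface carries its upstream WEPL with it, producing the
  range mixing a pencil superposition cannot. The result is renormalized to
  the PB integral dose.

In homogeneous media the two constructions coincide (the diffusion reproduces
the PB engine's quadratic lateral-variance growth in water exactly); gamma
1%/1 mm agreement on the shipped water fixture is 100% when the field and its
penumbra are contained in the grid. On the shipped lateral-slab fixture (bone
half-slab plus air ridge across the field) agreement drops to ~87%, and the
slab-induced range shift matches the piecewise-WEPL closed form. This
asymmetry — agree in water, disagree at interfaces — is the training signal.

Site families (`headneck_like`, `liver_like`, `lung_like`, `prostate_like`)
randomize body shape, inserts (air cavities, bone, lung tissue), target
position, and beam arrangement, with per-site anatomy chosen so PB-vs-reference
composite gamma sits well below 90% on average — a discrepancy magnitude in
the spirit of clinical PB-vs-MC gaps, so the conversion task is non-trivial.
Cases are deterministic given the seed.

## Conversion model

The HD U-Net uses densely connected convolution blocks (each conv's output is
concatenated onto its input, channels growing by the growth rate) and dense
downsampling (max-pooled features carried alongside strided-conv features), and
plain U-Net upsampling (nearest-neighbour + conv + skip concatenation) to keep
memory bounded. All units are conv → batch norm → ReLU. The full-size
configuration maps a 128 x 128 x 16 two-channel patch (normalized PB dose,
windowed CT) to an 8 x 8 x 1 bottleneck and back to a one-channel dose patch.
The desk-scale configuration used for CPU experiments shrinks the growth rate
and pool schedule.

One deliberate departure from a plain image-to-image network: the final
1 x 1 x 1 convolution is zero-initialized and the PB input channel is added
back before the final ReLU, so the untrained model is exactly the identity on
its PB input. The function class is unchanged; what changes is conditioning —
the network only has to learn the PB-to-reference *correction*, which makes
minutes-scale CPU training converge where the direct map does not.

The network, reverse-mode autodiff, and Adam are implemented in numpy inside
`protondl.nn` (no deep-learning framework is available in the target
environment); every op is gradient-checked against central differences in the
test suite.

## Preprocessing (Method-1 per-beam pipeline)

Each beam is brought to a default field orientation (gantry 270) before the
network sees it, so the model learns a single beam direction. Rotations about
the beam isocenter are performed on an enlarged lattice-aligned canvas so
off-center isocenters never rotate dose out of the volume; arbitrary angles
use order-3 spline interpolation clipped to the input range, and quarter/half
turns are exact index permutations. Doses are normalized by the 95th
percentile of the PB dose over voxels above 5% of its maximum (the same factor
is applied to the paired reference dose); CT is windowed from (-1000, 2000) HU
onto [0, 1]. Conversion inverts each step: predict in the default orientation,
de-normalize, rotate back, crop to the native grid, and sum beams. With an
identity model this whole chain reproduces the PB composite to well under 3%
relative RMSE over the 10%-isodose region, which bounds the preprocessing loss.

Training patches are placed by drawing a voxel uniformly from the >5%-of-max
dose region and positioning the patch uniformly among all placements that
contain it: every patch sees treated voxels, with coverage concentrated where
dose is. (A `discrepancy_fraction` knob can center part of the draws on the
PB-vs-reference discrepancy volume instead; in our desk-scale studies it did
not improve held-out accuracy and defaults to off.) Whole-volume inference
tiles the PB dose bounding box — expanded by half a patch on every side —
with 50%-overlap sliding windows and averages overlapping predictions; outside
that region the PB dose passes through unchanged, since a correction model has
nothing to correct where the input deposits no dose. Restricting the tiling
roughly halves conversion time on rotated canvases.

## Evaluation

The 3D gamma index (default 1%/1 mm, global normalization, 10% low-dose
threshold) searches a sub-voxel lattice (step <= 1/3 of the distance
tolerance) within a sphere of radius 3x the distance tolerance, visiting
offsets in shells of increasing distance so the search can stop early per
voxel. The implementation is verified voxel-for-voxel against a deliberately
naive exhaustive-search oracle in the test suite. Masked MSE, cumulative DVH
curves, and the 3%/3% dose-difference histogram complete the per-case report.

## Experiments

The five standard protocols (`single_site`, `cross_site`, `leave_one_out`,
`joint`, `fine_tune`) mirror the questions a clinical study asks: does the
model generalize across sites, and can a model pretrained on three site
families be adapted to a fourth with a short fine-tune at a fixed low learning
rate (1e-4)? At desk scale the headline checks are: (a) on held-out cases the
converted dose beats the PB baseline in mean gamma passing rate and has lower
masked MSE on every test case, and (b) the fine-tuned model approaches a
jointly trained model on the held-out family.

A note on what desk-scale training can and cannot deliver. Masked MSE
improves early and on every held-out case: partial corrections — moving the
predicted dose toward the reference without matching it exactly — reduce
squared error monotonically. The 1%/1 mm gamma passing rate is far stricter: a
failing voxel only flips to passing once the local correction is nearly exact
in both dose and position, so gamma gains lag MSE gains substantially. At the
shipped desk budget (about 300k parameters, 12 epochs, minutes of single-CPU
training) the converted dose lowers masked MSE on most held-out cases (mean
MSE drops by roughly 15-25%) while mean gamma passing moves by under one
point; extending the same recipe to 40+ epochs lowers MSE on every held-out
case and raises mean gamma passing by roughly four points over the PB
baseline. That four-point plateau was robust: longer schedules,
doubled growth rate, deeper pooling, beam-axis-spanning patches,
discrepancy-centered patch sampling and discrepancy-weighted losses all
failed to beat the plain recipe. Closing most of the PB-to-reference gamma
gap appears to require full-scale capacity and training time (the full-size
configuration and 200-epoch schedule shipped as `FULL_SCALE_CONFIG` /
`FULL_SCALE_TRAIN_CONFIG`), not a desk-scale run.
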