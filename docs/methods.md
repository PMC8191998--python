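# Methods

`somafind` detects cytoplasmically labelled neuronal somata in large
dual-channel 3D fluorescence volumes (e.g. serial two-photon tomography of
whole mouse brains) in two steps: a deliberately over-sensitive classical
candidate detector, followed by a 3D residual network that rejects the
resulting false positives. This note records the model, its assumptions, the
parameters that matter, the numerical choices, and what the synthetic
validation does and does not show.

## The two-step model

Thresholding-based detection alone cannot be tuned well on whole-brain data:
bright non-cellular structures (debris on the tissue surface, contents of
blood vessels) are locally indistinguishable from somata by brightness and
size, so any threshold either misses cells or floods the output with
artefacts. The pipeline therefore splits the problem:

1. **Candidate detection** finds *everything* of roughly soma-like brightness
   and size — including artefacts — aiming for near-perfect recall.
2. **Candidate classification** inspects a dual-channel patch of raw data
   around each candidate and rejects non-cells. The decisive signal is the
   channel contract: a cytoplasmic label (e.g. mCherry) appears only in the
   signal channel, while autofluorescent artefacts appear in both channels.

### Candidate detection

Each plane of the signal channel is median filtered (square window derived
from the smoothing scale, minimum 3 voxels) and convolved with a negated
Laplacian of Gaussian (sigma = 0.2 × soma diameter, converted to voxels per
axis), which turns compact bright blobs into positive peaks. Each filtered
plane is binarised at `mean + k·SD` computed over that plane only
(population SD, strict inequality; a constant plane therefore produces an
empty mask). Per-plane statistics make the threshold robust to slow
depth-dependent intensity changes.

The thresholded 3D mask is then filtered with an anisotropy-aware ellipsoidal
footprint (default 6 µm lateral and 15 µm axial full widths, halved to
semi-axes): a position survives only if at least a fraction (default 0.6) of
the footprint covers thresholded voxels. This removes neurites, speckle, and
other thin structures. Footprint positions extending beyond the volume count
out-of-bounds voxels as empty, which tightens the criterion at borders where
surface debris concentrates.

Surviving voxels are merged into candidates by 26-connected component
labelling (anisotropic voxels make diagonal continuity common). A cluster
whose voxel count exceeds 1.5 × the voxel volume of a soma-diameter sphere is
assumed to be several fused cells and is split by an iterative procedure: the
ellipsoidal overlap criterion is applied to the cluster's own voxels,
connected passing positions are recorded, the cluster mask is eroded with the
6-connected cross, and the process repeats (up to 10 rounds or until nothing
passes). Positions recorded in different rounds closer than half a soma
diameter are averaged, and each cluster voxel is assigned to the nearest
surviving position. If nothing ever passes the cluster is kept whole.
Candidate coordinates are the mean voxel coordinate of each final cluster.

Default parameters (all in physical units so one set serves different voxel
sizes; the reference acquisition is 2 × 2 × 5 µm):

| parameter | default | role |
| --- | --- | --- |
| soma diameter | 16 µm | sets the smoothing scale and the split criterion; the one knob to retune for other cell types |
| LoG sigma | 0.2 × diameter | blob-enhancement scale |
| threshold | mean + 10 SD | per-plane binarisation |
| ellipsoid widths | 6 µm lateral, 15 µm axial | noise-removal footprint |
| overlap fraction | 0.6 | footprint coverage needed to survive |
| split iterations | 10 | erosion rounds when splitting |

The axial ellipsoid width is exposed as a parameter because it must grow when
plane spacing is coarse: at 20 µm plane spacing the default 15 µm footprint
spans less than one plane and cannot be built at all; widening it (e.g. to
30 µm) restores a usable filter at the cost of axial specificity.

### Candidate classification

A 50 × 50 × 100 µm window centred on each candidate is cropped from both
channels, resampled to 50 × 50 × 20 voxels (linear interpolation; the window
extent per axis is rounded to whole voxels first; out-of-volume regions are
zero-padded), standardised per channel (zero mean, unit SD over the cuboid,
SD floor 1e-6), and fed to a 3D residual network with a 2-way softmax head.
Per-cuboid standardisation needs no dataset statistics, which keeps the
classifier portable across acquisition systems with different gain.

The architecture family follows the classic residual-network layouts
generalised to 3D — depths 18/34 with basic blocks, 50/101/152 with
bottleneck blocks (block counts 3-4-6-3 at depth 50) — with a strided 3×3×3
stem convolution, 2×2×2 average pooling, four stages, global average pooling
and a dense head. Because the input is anisotropic (20 voxels axially versus
50 in-plane), the stem and pool reduce all three axes while stages 3-4 stride
in-plane only, keeping at least two axial positions before the global pool.
The stem kernel, the use of average rather than max pooling, and the stage
channel widths (base width 16 by default, i.e. 16/32/64/128 before bottleneck
expansion) are implementation choices; the narrow default keeps CPU training
practical. The network is implemented directly in numpy (im2col-style GEMM
convolutions with explicit backward passes) so the package has no deep
learning framework dependency; gradients are verified against finite
differences in the test suite.

Training follows the reference regime: Adam at learning rate 1e-4, batch
size 32, categorical cross-entropy, 10% of the data held back for
validation, and stopping when the validation loss plateaus (no improvement
above 1e-3 for 5 epochs, 100 epochs maximum; the best-validation weights are
restored). Training examples are augmented on the fly — each of three
transformation families fires independently with 10% probability: a flip
along a uniformly chosen axis, a rotation about a uniformly chosen axis
(uniform in ±45°, linear interpolation, zero fill), and a circular
translation along a uniformly chosen axis by up to 5% of its length. Both
channels always receive the identical transform. The 10% probability is
applied per family, not per axis. The decision threshold on the cell
probability is 0.5 and is exposed as a knob.

`retrain` continues optimisation from saved weights on new (typically small,
experiment-specific) data with a fresh optimiser state and the same stopping
rule — the intended workflow when acquisition characteristics shift.
Models serialise to a `.npz` weight file plus a JSON sidecar recording the
architecture and normalisation, which `retrain`/`classify` check before
loading.

## Synthetic data

The phantom generator produces seeded dual-channel volumes with exact ground
truth so that every stage is testable without external data. It emulates:
soma-like blobs added only to the signal channel; artefacts added to both
channels (cell-sized bright blobs, vessel-like cylinders of 1-3 voxel radius
and ≥ 30 µm length running mostly in-plane, and irregular debris clusters
within 3 voxels of a volume face); flat background with independent Gaussian
noise per channel; and anisotropic sampling. Objects are placed either
"separated" (all centres at least one mean soma diameter apart) or
"clustered" (cells in deliberately fused groups, to exercise splitting).

Cells are rendered as Gaussian domes of scale diameter/4 (about 13% of peak
intensity at the nominal radius). This models the PSF-blurred appearance of
a cytoplasmically filled soma — brightest mid-cell — and was chosen over a
hard-edged ball after measurement: the detector's Laplacian-of-Gaussian
scale (3.2 µm) responds to a flat-interior plateau only at its rim, so
plateau phantoms threshold as annuli in their central planes and cells
centred between planes drop below the 0.6 overlap criterion. The dome
profile restores the regime the detector is designed for. Intensities are
arbitrary units; only the signal-to-noise ratio matters because the
threshold is statistical. Defaults (peak cell amplitude 200 over background
100 with noise SD 10, i.e. peak z-score ≈ 20 per plane) are calibrated so
the default detection parameters fire.

What the phantoms do **not** model: the optical point-spread function proper,
photobleaching, tiling seams, illumination gradients, densely packed cortex
where somata overlap extensively, and the irregular (non-spherical) shapes of
real cytoplasmically filled cells. Passing the synthetic suite therefore
demonstrates the algorithmic contracts (sensitivity bias, artefact rejection
via the channel contract, splitting, retraining benefit), not performance on
any particular real acquisition.

`downsample_axially` keeps every Nth plane (bitwise) and scales the plane
spacing, mimicking re-acquisition at coarser axial sampling. On 50-cell
phantoms detection recall is essentially unchanged at 10 µm sampling,
while at 20 µm (≥ the soma diameter) cells centred between planes vanish and
recall drops markedly even with the axial filter width raised to 30 µm —
the generator reproduces the qualitative degradation expected once plane
spacing exceeds the object size.

## Evaluation

Detections are matched one-to-one to ground truth by greedy nearest-first
assignment within a physical radius (default one soma diameter, 16 µm);
greedy matching is deterministic and agrees with exhaustive optimal
assignment on well-separated instances (oracle-tested). Precision, recall
and F1 derive from the match counts, which satisfy TP + FN = |truth| and
TP + FP = |detections| by construction. Region-wise count vectors are
compared by the Pearson correlation coefficient and the ordinary
least-squares slope of one count vector regressed on the other; the
intercept is fitted by default, with a through-origin option, since the
choice is not dictated by the procedure being replicated.

## Numerical choices and degenerate inputs

- Population (not sample) SD and strict inequality in the threshold, so
  constant planes give empty masks.
- Overlap counts are computed with an integer correlation kernel and
  compared against `fraction × footprint size` with a 1e-9 slack, so no
  float rounding can flip a voxel.
- The marker XML dialect stores integer coordinates (rounded
  half-away-from-zero); sub-voxel centroid precision is lost on export by
  design, for interoperability with annotation tools.
- Networks run in float32; training uses batch statistics, inference uses
  running batch-norm statistics, so repeated inference is bitwise
  deterministic.
- All randomness (phantoms, training split, augmentation) flows through
  explicitly seeded generators; fixed seeds reproduce volumes, candidate
  lists and reports bitwise.

## Problem sizes in the shipped validation

The test suite and the acceptance script run entirely on phantoms sized for
a desktop CPU: detection volumes of 256 × 256 × 40-48 voxels
(≈ 0.5 × 0.5 × 0.2 mm) with 25-50 cells, classifier training sets of 200
cuboids, and the depth-18 network at base width 8 for trained-model checks
(depth 50 is exercised architecturally). These sizes were chosen so the full
validation completes in minutes while still containing every failure mode
the contracts guard against; the pipeline itself is plane-chunked and
processes arbitrarily many planes on a single machine.

## Known limitations

- The too-large criterion compares thresholded cluster volume to the nominal
  soma sphere; dim fused cells whose thresholded cores are small can escape
  splitting (the clustered phantom mode exhibits this).
- Greedy matching is near-optimal, not optimal, at very high detection
  densities.
- The per-plane statistical threshold assumes bright objects occupy a small
  fraction of each plane; in small fields of view dominated by bright
  extended artefacts the inflated plane SD suppresses dim cells.
- The numpy network trains at CPU speed: suitable for the few-hundred to
  few-thousand cuboid retraining workflow, not for training on ~10^5 cuboids
  from scratch.
- No GPU path, no multi-tile stitching or illumination correction, and no
  atlas registration — region counts accept any supplied integer label
  volume.
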