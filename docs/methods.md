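# Methods

## Scope and design

The package treats a scaffold-protein study of the Hippo pathway as a set
of measurement procedures, each validated against synthetic data whose
ground truth is known exactly.  The guiding choice throughout is that the
generators favour *exactness of the oracle over visual realism*: cells are
convex, intensities are set levels per compartment, and noise is additive
Gaussian, because then every per-cell metric has a knowable true value and
a disagreement between pipeline and truth is a defect, not ambiguity.

## Synthetic image model

A field (default 512×512 px, dimensionless pixels, float intensities in
arbitrary units) contains non-overlapping circular cells placed fully
inside the frame by rejection sampling; an infeasible request (too many
cells for the frame) fails loudly rather than degrading.  Each cell holds
one elliptical nucleus with geometric-mean radius ~N(11, 1.5) px, target
minor/major axis ratio (default 0.75), random orientation, and a centroid
offset from the cell centre by `displacement_frac · cell_radius` along a
random direction (shrunk if the nucleus would leave the cell).  Centres
are snapped to integer pixels; together with drawing circles through the
disk rasterizer this makes rasterized masks reflection-symmetric, so the
concentric fixture (displacement 0, axis ratio 1) has nuclear displacement
exactly 0 and axis ratio exactly 1, to the bit.

Channels are rendered as set levels: DNA = background outside nuclei and a
bright nuclear level inside; actin = background / cell-body level / fiber
level; protein = background outside cells, one cytoplasmic level, one
nuclear level.  Condition effects are therefore ratios of channel means —
the wild-type and KSR1-null fixtures set nuclear protein levels 100 and 62
(a 38% reduction) — rather than absolute units, which the source assays do
not define.  Stress fibers are random chords (~2 px wide, lengths
~N(mean, sd) per condition, count ~Poisson per cell) clipped to the cell.
Components shorter than 10 px (the package-wide fiber length floor) are
not stress fibers by definition and are excluded from both the truth mask
and the detector output.  Additive Gaussian noise (default sd 4, ~10% of
the cytoplasmic level) is applied to all channels; there is no Poisson
shot term or PSF model, so the images exercise thresholding and watershed
behaviour but not deconvolution or photon statistics.  Passing tests
demonstrate correct recovery under this model, not performance on real
micrographs — the measurement contracts (masks in, metrics out) are
backend-agnostic so a learned segmenter can replace the classical one
without touching the metric code.

Ground truth records the exact instance masks and the per-cell metrics
obtained by running the measurement suite on the truth masks over the
noise-free image — i.e. what a perfect segmentation would report — which
makes truth/measurement comparisons exact by construction while analytic
oracles (moment ellipse of a 40×20 ellipse, closed-form set levels) are
asserted independently in the test suite.

## Segmentation

*Nuclei*: median filter (disk radius 2) → global Otsu → 8-connected
components → drop < 50 px² → split touching nuclei by watershed on the
smoothed distance transform, seeded at local maxima ≥ 10 px apart.  A
constant channel makes Otsu undefined and raises a degenerate-input error.

*Cell bodies*: Otsu on the Gaussian-smoothed (σ = 1) actin + protein
composite, closed (disk radius 1) and hole-filled, then marker-controlled
watershed on the inverted composite with nuclei as markers, so cell label
k contains nucleus label k.  The small smoothing radius and closing radius
were chosen because larger values measurably bias cell centroids (bright
fibers near the boundary pull the threshold contour) and bridge adjacent
cells; with σ = 1 the worst-case nuclear-displacement error on clean
fields is ~3%.  Border-touching cells are excluded from measurement.

*Stress fibers*: a two-stage pixel/object scheme.  The pixel stage
thresholds the actin channel at the in-cell Otsu level (fiber bundles are
brighter than the diffuse cell body); the object stage keeps components
that are elongated (major axis ≥ 10 px) and supported by a multiscale
tubularity (Sato) filter response in ≥ 30% of their pixels.  The
background outside cells is filled with the median in-cell actin level
before the ridge filter so the cell-boundary step contributes no response.
The intensity-based pixel stage keeps the mask pixel-accurate (the ridge
response alone is systematically wider than the bundle); the ridge gate
suppresses bright non-fibrous blobs.

## Morphometrics

Axis lengths come from the second central moments of the nuclear region
(standard image-moment ellipse); *eccentricity* here is the minor/major
axis-length ratio (1 = round), deliberately named `eccentricity_ratio` to
avoid confusion with the conic convention.  *Solidity* is region area over
the area of the convex hull taken over pixel centers
(`convex_hull_image(..., offset_coordinates=False)`): with this convention
any rasterization of a convex shape — whose pixel set is exactly the
lattice points inside a convex region — has solidity exactly 1, whereas
the default corner-based hull adds a half-pixel fringe and caps solidity
of a perfect disk at ~0.95.  *Nuclear displacement* is the distance
between the nuclear centroid and the whole-cell centroid (the segmented
cytoplasmic region includes the nucleus).  Protein intensities are plain
means over the nucleus and over cell-minus-nucleus; a cell whose
cytoplasm is empty is flagged rather than silently reported.  A nucleus
overlapping two cells invalidates those cells (logged warning).

## Expression and array statistics

ΔΔCT: technical replicates are averaged per (sample, gene); each qPCR run
is one biological sample; ΔΔCT subtracts the mean calibrator ΔCT.  The
condition summary fold is 2^(−mean ΔΔCT) — the geometric mean of
per-sample folds — so the calibrator condition's fold is exactly 1 by
construction; the SE is reported over per-sample folds.  With the default
noise (well sd 0.15 cycles, 3 wells × 3 runs) a single simulated
experiment recovers a fold with ~7% multiplicative sd and no bias; the
recovery experiments therefore report the mean fold over 20 simulated
experiments.  No amplification-efficiency correction is modelled.

RPPA: per-protein two-sided two-sample t-test and mean log2 difference vs
control; the differential filter is |log2FC| ≥ log2(2) AND p < 0.05 with
no multiplicity correction by default (a Benjamini–Hochberg flag exists
but is off, matching the stated raw-p convention); ranking is by |log2FC|
among passing proteins with ties broken by protein id, padded in score
order (and flagged) when fewer than `top_n` pass.

## Route scoring

Routes are simple directed paths up to 4 edges (configurable) enumerated
in deterministic (length, lexicographic) order with an explicit truncation
flag at a configurable cap.  The three criteria are made disjoint — a
ranked protein counts once, in the lowest-numbered applicable criterion —
so the unweighted total cannot double-count; components are always
reported separately so any weighting can be applied downstream.  Adjacency
for c2/c3 ignores edge direction (the more inclusive reading of "directly
linked" / "via a single mediator"); the ranked list passed in is the
universe for c2/c3, defaulting to the top-100.  Edge signs are parsed
(up-regulates/activates → activation, down-regulates/inhibits →
inhibition, else unknown) and retained; they do not affect the score but
an activation-only edge filter is available for route enumeration.
Correctness is established against two independent oracles on random
graphs ≤ 8 nodes: exhaustive permutation enumeration for paths and a BFS
undirected-distance oracle for (c1, c2, c3).

## Mass photometry

Masses are fit directly (not histogram bins) with Gaussian-mixture EM,
k = 1..4, k-means initialization at a fixed seed, model chosen by BIC; a
5-kDa histogram is attached for reporting only.  Fewer than 50 events with
k_max ≥ 2 is an error; identical masses yield a degenerate zero-width
peak.  The complex call requires a mixture peak with weight ≥ 0.1 whose
center exceeds every individual-sample peak by more than 2× the pooled
width of the dominant A and B peaks, and additionally reports whether that
center is within the same tolerance of the sum of the dominant A and B
centers (1:1 stoichiometry check).  Well-separated designs (> 4σ,
n ≥ 2000) recover centers within 5 kDa and weights within 0.05 across
seeds.

## Pipeline and reproducibility

The driver validates its YAML config strictly (unknown keys anywhere are
errors, and validation happens before any stage runs), fans one global
seed out to fixed per-stage child seeds via `numpy.random.SeedSequence`,
and writes plain TSVs with a fixed float format, making a full run
byte-reproducible for a given (config, seed).  Default problem sizes —
11 images × 10 cells per condition, 20-replicate qPCR recovery, 200-seed
RPPA power checks, 50-seed mixture recovery — were chosen so the whole
validation suite runs in a few minutes on one CPU while keeping Monte
Carlo error well inside each check's tolerance.

## Known limitations

Convex cells and set-level intensities cannot probe segmentation of
irregular or touching-cell morphologies; the noise model omits shot noise,
uneven illumination and chromatin texture; qPCR efficiency is assumed
ideal; RPPA spatial/plate effects are not modelled; route scoring treats
the interaction network as exact rather than sampled; and the
mass-photometry model assumes Gaussian peaks with shared-width species and
a perfectly linear calibration.
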