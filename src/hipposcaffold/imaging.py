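"""Single-cell fluorescence morphometrics.

Segments nuclei, cell bodies and actin stress fibers from 3-channel
(DNA / actin / target protein) images and computes a per-cell morphometric
suite: areas, axis-ratio "eccentricity", solidity, nuclear displacement,
stress-fiber coverage and nuclear / cytoplasmic protein intensities.

The segmentation backends are deterministic classical operators
(median + Otsu + distance-transform watershed for nuclei, marker-controlled
watershed for cell bodies, a multiscale tubularity filter for fibers).
The measurement contracts are backend-agnostic: any routine producing
instance label masks can be substituted upstream of :func:`measure_cells`.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.ndimage as ndi
from scipy import stats
from skimage.feature import peak_local_max
from skimage.filters import gaussian, median, sato, threshold_otsu
from skimage.measure import label as cc_label
from skimage.measure import regionprops
from skimage.morphology import closing, convex_hull_image, disk
from skimage.segmentation import relabel_sequential, watershed

logger = logging.getLogger(__name__)

CHANNEL_NAMES = ("dna", "actin", "protein")

#: minimum major-axis length (px) for a component to count as a stress fiber;
#: shorter actin fragments are not reported as fibers anywhere in the package
FIBER_LENGTH_MIN = 10.0


class DegenerateChannelError(ValueError):
    """Raised when a channel is constant and an auto-threshold is undefined."""


def _drop_small(labels: np.ndarray, min_area: float) -> np.ndarray:
    """Zero out labelled components with area strictly below ``min_area``."""
    counts = np.bincount(labels.ravel())
    small = np.flatnonzero(counts < min_area)
    out = labels.copy()
    out[np.isin(labels, small[small > 0])] = 0
    return out


@dataclass
class CellImage:
    """Multi-channel 2-D fluorescence image.

    channels maps ``dna`` / ``actin`` / ``protein`` to 2-D float arrays in
    arbitrary intensity units; all channels share one shape, coordinates are
    0-based (row, col).
    """

    channels: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        missing = [c for c in CHANNEL_NAMES if c not in self.channels]
        if missing:
            raise ValueError(f"missing channels: {missing}")
        shapes = {c: a.shape for c, a in self.channels.items()}
        if len(set(shapes.values())) != 1:
            raise ValueError(f"channel shapes differ: {shapes}")
        for name, arr in self.channels.items():
            if arr.ndim != 2:
                raise ValueError(f"channel {name!r} is not 2-D")
            if not np.all(np.isfinite(arr)):
                raise ValueError(f"channel {name!r} has non-finite values")

    @property
    def shape(self) -> tuple[int, int]:
        return next(iter(self.channels.values())).shape


@dataclass
class CellRecord:
    """Morphometric vector of one segmented cell.

    ``eccentricity_ratio`` is the minor/major axis-length ratio of the
    nuclear moment ellipse (1 = perfectly round), *not* the conic-section
    eccentricity.  ``nuclear_displacement`` is the Euclidean distance in
    pixels between the nuclear centroid and the whole-cell centroid.
    """

    cell_id: int
    nuclear_area: float
    cell_area: float
    eccentricity_ratio: float
    solidity: float
    nc_area_ratio: float
    nuclear_displacement: float
    pct_fiber_area: float
    mean_nuc_intensity: float
    mean_cyto_intensity: float
    fiber_lengths: list[float] = field(default_factory=list)
    flags: frozenset[str] = frozenset()

    #: names usable as the ``metric`` argument of :func:`estimate_effect`
    METRICS = (
        "nuclear_area",
        "cell_area",
        "eccentricity_ratio",
        "solidity",
        "nc_area_ratio",
        "nuclear_displacement",
        "pct_fiber_area",
        "mean_nuc_intensity",
        "mean_cyto_intensity",
    )


@dataclass
class EffectEstimate:
    """Condition-level effect on one metric: percent change of group means
    plus a rank-test p-value."""

    metric: str
    mean_ref: float
    mean_alt: float
    percent_change: float
    p_value: float
    test: str
    n_ref: int
    n_alt: int


# ---------------------------------------------------------------------------
# segmentation
# ---------------------------------------------------------------------------

def segment_nuclei(
    image: CellImage,
    min_area: float = 50.0,
    median_radius: int = 2,
    peak_min_distance: int = 10,
) -> np.ndarray:
    """Segment nuclei from the DNA channel.

    Median denoise (disk radius ``median_radius``) -> global Otsu threshold
    -> 8-connected components -> drop components below ``min_area`` px^2 ->
    split touching nuclei by a distance-transform watershed seeded at local
    maxima at least ``peak_min_distance`` px apart.  Returns an integer label
    mask (0 = background, labels 1..K).
    """
    dna = np.asarray(image.channels["dna"], dtype=float)
    if np.ptp(dna) == 0:
        raise DegenerateChannelError(
            "dna channel is constant; Otsu threshold is undefined"
        )
    denoised = median(dna, footprint=disk(median_radius))
    if np.ptp(denoised) == 0:
        raise DegenerateChannelError(
            "dna channel is constant after median filtering; "
            "Otsu threshold is undefined"
        )
    fg = denoised > threshold_otsu(denoised)
    lbl = cc_label(fg, connectivity=2)
    lbl = _drop_small(lbl, min_area)
    fg = lbl > 0
    if not fg.any():
        return np.zeros_like(lbl, dtype=np.int32)

    # split fused nuclei: watershed on the smoothed distance transform
    dist = ndi.distance_transform_edt(fg)
    dist_s = gaussian(dist, sigma=1.0)
    coords = peak_local_max(
        dist_s, min_distance=peak_min_distance, labels=fg, exclude_border=False
    )
    markers = np.zeros_like(lbl, dtype=np.int32)
    for i, (r, c) in enumerate(coords, start=1):
        markers[r, c] = i
    if markers.max() == 0:
        out = lbl
    else:
        out = watershed(-dist_s, markers, mask=fg)
        out = _drop_small(out, min_area)
    out, _, _ = relabel_sequential(out)
    return out.astype(np.int32)


def segment_cells(
    image: CellImage,
    nuclei: np.ndarray,
    smooth_sigma: float = 1.0,
    closing_radius: int = 1,
) -> np.ndarray:
    """Segment whole-cell bodies, one instance per nucleus.

    Foreground is an Otsu threshold of the smoothed actin + protein
    composite, morphologically closed and hole-filled; instances are then
    assigned by a marker-controlled watershed on the inverted composite with
    the nuclei as markers, so each cell label k contains nucleus label k.
    Cells touching the image border are retained in the mask but excluded
    later by :func:`measure_cells`.
    """
    if nuclei.max() == 0:
        raise ValueError("no nuclei provided; cannot seed cell segmentation")
    composite = gaussian(
        np.asarray(image.channels["actin"], dtype=float)
        + np.asarray(image.channels["protein"], dtype=float),
        sigma=smooth_sigma,
    )
    if np.ptp(composite) == 0:
        raise DegenerateChannelError(
            "actin+protein composite is constant; Otsu threshold is undefined"
        )
    fg = composite > threshold_otsu(composite)
    fg = closing(fg, disk(closing_radius))
    fg = ndi.binary_fill_holes(fg)
    fg |= nuclei > 0  # a cell always contains its nucleus
    cells = watershed(-composite, markers=nuclei, mask=fg)
    return cells.astype(np.int32)


def segment_stress_fibers(
    image: CellImage,
    cells: np.ndarray,
    ridge_sigmas: tuple[float, ...] = (1.0, 2.0),
    length_min: float = FIBER_LENGTH_MIN,
    ridge_support_min: float = 0.3,
) -> np.ndarray:
    """Segment actin stress fibers inside segmented cells.

    Two-stage pixel/object scheme: the pixel stage thresholds the actin
    channel at the Otsu level within the cell foreground (fiber bundles are
    brighter than the diffuse cell body); the object stage keeps only
    elongated components (major-axis length >= ``length_min``) whose pixels
    are supported by a multiscale tubularity (ridge) filter response above
    its own Otsu level in at least ``ridge_support_min`` of the component.
    The background outside cells is filled with the median in-cell actin
    level before the ridge filter so the cell-boundary step produces no
    spurious ridge response.  Returns a binary mask restricted to cell
    pixels; an empty mask is a valid result.
    """
    actin = np.asarray(image.channels["actin"], dtype=float)
    fg = cells > 0
    if not fg.any():
        return np.zeros_like(cells, dtype=bool)
    avals = actin[fg]
    if np.ptp(avals) == 0:
        return np.zeros_like(cells, dtype=bool)
    pixel_mask = (actin > threshold_otsu(avals)) & fg

    work = actin.copy()
    work[~fg] = np.median(avals)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # sato warns on constant images
        ridge = sato(work, sigmas=ridge_sigmas, black_ridges=False)
    rvals = ridge[fg]
    if np.ptp(rvals) == 0:
        return np.zeros_like(cells, dtype=bool)
    ridge_mask = (ridge > threshold_otsu(rvals)) & fg

    lbl = cc_label(pixel_mask, connectivity=2)
    keep = np.zeros_like(pixel_mask)
    for prop in regionprops(lbl):
        if prop.axis_major_length < length_min:
            continue
        comp = lbl == prop.label
        if (comp & ridge_mask).sum() / prop.area >= ridge_support_min:
            keep[comp] = True
    return keep


# ---------------------------------------------------------------------------
# measurement
# ---------------------------------------------------------------------------

def _solidity(region_mask: np.ndarray, bbox: tuple[int, int, int, int]) -> float:
    """Region area / pixel-center convex-hull area.

    The hull is taken over pixel centers (not corners), so any rasterization
    of a convex shape — whose pixel set is exactly the lattice points inside
    the convex region — has solidity exactly 1; concavities reduce it.
    """
    r0, c0, r1, c1 = bbox
    crop = region_mask[r0:r1, c0:c1]
    hull = convex_hull_image(crop, offset_coordinates=False)
    return float(crop.sum() / hull.sum())


def _border_labels(mask: np.ndarray) -> set[int]:
    edges = np.concatenate([mask[0, :], mask[-1, :], mask[:, 0], mask[:, -1]])
    return set(np.unique(edges[edges > 0]).tolist())


def measure_cells(
    image: CellImage,
    nuclei: np.ndarray,
    cells: np.ndarray,
    fibers: np.ndarray | None = None,
) -> list[CellRecord]:
    """Compute one :class:`CellRecord` per non-border cell.

    Axis lengths come from the second central moments of the nuclear region
    (the standard image-moment ellipse); eccentricity_ratio = minor/major.
    Intensities are means of the protein channel over the nucleus and over
    cell-minus-nucleus (cytoplasm).  Fiber metrics come from fiber-mask
    components clipped to the cell.  A nucleus overlapping two cells causes
    those cells to be skipped with a warning; a cell whose cytoplasm is empty
    is flagged ``empty_cytoplasm`` with NaN cytoplasmic intensity.
    """
    if fibers is None:
        fibers = np.zeros_like(cells, dtype=bool)
    protein = np.asarray(image.channels["protein"], dtype=float)
    border = _border_labels(cells)

    # map cell label -> nucleus labels whose pixels fall in that cell
    nuc_of_cell: dict[int, set[int]] = {}
    skip: set[int] = set()
    for nprop in regionprops(nuclei):
        owners = np.unique(cells[nuclei == nprop.label])
        owners = [int(o) for o in owners if o > 0]
        if len(owners) > 1:
            logger.warning(
                "nucleus %d spans cells %s; skipping those cells",
                nprop.label, owners,
            )
            skip.update(owners)
            continue
        if owners:
            nuc_of_cell.setdefault(owners[0], set()).add(int(nprop.label))

    records: list[CellRecord] = []
    for cprop in regionprops(cells):
        cid = int(cprop.label)
        if cid in border or cid in skip:
            continue
        nuc_labels = nuc_of_cell.get(cid, set())
        if len(nuc_labels) != 1:
            logger.warning("cell %d has %d nuclei; skipped", cid, len(nuc_labels))
            continue
        nid = next(iter(nuc_labels))
        nmask = nuclei == nid
        cmask = cells == cid
        nprop = regionprops(nmask.astype(np.uint8))[0]

        major = nprop.axis_major_length
        ecc = float(nprop.axis_minor_length / major) if major > 0 else 1.0
        cyto = cmask & ~nmask
        flags: set[str] = set()
        if cyto.any():
            mean_cyto = float(protein[cyto].mean())
        else:
            mean_cyto = float("nan")
            flags.add("empty_cytoplasm")

        fib_in_cell = fibers & cmask
        flbl = cc_label(fib_in_cell, connectivity=2)
        fiber_lengths = [
            float(p.axis_major_length) for p in regionprops(flbl)
        ]

        d = float(np.hypot(
            nprop.centroid[0] - cprop.centroid[0],
            nprop.centroid[1] - cprop.centroid[1],
        ))
        records.append(CellRecord(
            cell_id=cid,
            nuclear_area=float(nprop.area),
            cell_area=float(cprop.area),
            eccentricity_ratio=min(ecc, 1.0),
            solidity=_solidity(nmask, nprop.bbox),
            nc_area_ratio=float(nprop.area / cprop.area),
            nuclear_displacement=d,
            pct_fiber_area=100.0 * float(fib_in_cell.sum()) / float(cprop.area),
            mean_nuc_intensity=float(protein[nmask].mean()),
            mean_cyto_intensity=mean_cyto,
            fiber_lengths=sorted(fiber_lengths),
            flags=frozenset(flags),
        ))
    records.sort(key=lambda r: r.cell_id)
    return records


def estimate_effect(
    records_ref: list[CellRecord],
    records_alt: list[CellRecord],
    metric: str,
    test: str = "rank-sum-2",
) -> EffectEstimate:
    """Percent change of group means on one metric with a rank-test p-value.

    ``test`` is ``rank-sum-2`` (two-sided Mann-Whitney U, exact method for
    small untied samples) or ``rank-multi`` (Kruskal-Wallis, useful when the
    two groups are slices of a larger design).
    """
    if metric not in CellRecord.METRICS:
        raise ValueError(
            f"unknown metric {metric!r}; valid metrics: {CellRecord.METRICS}"
        )
    if len(records_ref) < 2 or len(records_alt) < 2:
        raise ValueError("need at least 2 records per group")
    x = np.array([getattr(r, metric) for r in records_ref], dtype=float)
    y = np.array([getattr(r, metric) for r in records_alt], dtype=float)
    if test == "rank-sum-2":
        res = stats.mannwhitneyu(x, y, alternative="two-sided", method="auto")
        p = float(res.pvalue)
    elif test == "rank-multi":
        p = float(stats.kruskal(x, y).pvalue)
    else:
        raise ValueError(
            f"unknown test {test!r}; valid tests: ['rank-sum-2', 'rank-multi']"
        )
    mean_ref, mean_alt = float(x.mean()), float(y.mean())
    if mean_ref == 0:
        pct = float("nan")
    else:
        pct = 100.0 * (mean_alt - mean_ref) / mean_ref
    return EffectEstimate(
        metric=metric,
        mean_ref=mean_ref,
        mean_alt=mean_alt,
        percent_change=pct,
        p_value=p,
        test=test,
        n_ref=len(x),
        n_alt=len(y),
    )
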