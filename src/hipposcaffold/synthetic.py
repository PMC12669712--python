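"""Seeded synthetic-data generators with recorded ground truth.

Every input the pipeline consumes can be simulated here with known truth:

* multi-channel cell images (DNA / actin / protein) with exact instance
  masks and noise-free per-cell morphometrics;
* qPCR cycle-threshold (CT) tables with known fold changes;
* grouped RPPA log2 expression tables with planted differential proteins;
* signed directed interaction networks with a planted source->target route
  and a ranked list with planted overlap counts;
* single-molecule mass-photometry event lists from Gaussian mixtures.

All generators are pure functions of (design, seed): the same arguments
always produce byte-identical output.

Cells are rendered as convex (circular) bodies with elliptical nuclei so
that every ground-truth metric is exact by construction; intensities are
set levels per compartment (background outside cells, a cytoplasmic level,
a nuclear level) with additive Gaussian noise, so condition effects are
encoded as ratios of channel means rather than absolute units.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import networkx as nx
import yaml
from skimage.draw import disk as draw_disk
from skimage.draw import ellipse as draw_ellipse
from skimage.draw import line as draw_line

from skimage.measure import label as cc_label
from skimage.measure import regionprops

from .imaging import FIBER_LENGTH_MIN, CellImage, CellRecord, measure_cells
from .network import ACTIVATION, INHIBITION, UNKNOWN

_SEED_MOD = 2**31 - 1


def _child_seed(seed: int, *indices: int) -> int:
    """Derive a stable child seed from a parent seed and a tuple of indices."""
    ss = np.random.SeedSequence([int(seed) % _SEED_MOD, *[int(i) for i in indices]])
    return int(ss.generate_state(1)[0] % _SEED_MOD)


# ---------------------------------------------------------------------------
# image generation
# ---------------------------------------------------------------------------

@dataclass
class EffectProfile:
    """Per-condition effect sizes for the image generator.

    Intensity fields are arbitrary units; geometric fields are pixels.
    ``nucleus_axis_ratio_mean`` is the target minor/major ratio in (0, 1];
    ``nucleus_displacement_frac_mean`` is the nuclear centroid offset as a
    fraction of the cell radius.
    """

    condition_name: str
    cells_per_image: int = 10
    nucleus_radius_mean: float = 11.0
    nucleus_radius_sd: float = 1.5
    nucleus_axis_ratio_mean: float = 0.75
    nucleus_displacement_frac_mean: float = 0.15
    cell_radius_mean: float = 26.0
    cell_radius_sd: float = 3.0
    yap_nuclear_mean: float = 100.0
    yap_cyto_mean: float = 40.0
    fiber_count_mean: float = 5.0
    fiber_length_mean: float = 30.0
    fiber_length_sd: float = 6.0
    background_level: float = 5.0
    noise_sd: float = 4.0
    dna_level: float = 200.0
    actin_level: float = 60.0
    fiber_level: float = 140.0

    def __post_init__(self) -> None:
        if self.cells_per_image < 1:
            raise ValueError("cells_per_image must be >= 1")
        if not (0.0 < self.nucleus_axis_ratio_mean <= 1.0):
            raise ValueError("nucleus_axis_ratio_mean must be in (0, 1]")
        if self.nucleus_displacement_frac_mean < 0:
            raise ValueError("nucleus_displacement_frac_mean must be >= 0")
        for name in (
            "nucleus_radius_mean", "cell_radius_mean", "yap_nuclear_mean",
            "yap_cyto_mean", "fiber_count_mean", "fiber_length_mean",
            "background_level", "noise_sd",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    @classmethod
    def from_yaml(cls, path) -> "EffectProfile":
        with open(path, "r", encoding="utf-8") as fh:
            data = yaml.safe_load(fh)
        return cls(**data)


@dataclass
class GroundTruth:
    """Exact masks and noise-free per-cell metrics for one generated image.

    Nucleus label k lies inside cell label k.  ``per_cell_truth`` holds the
    morphometric records measured from the truth masks on the noise-free
    image (the values a perfect segmentation would recover).
    """

    nuclei_mask: np.ndarray
    cell_mask: np.ndarray
    fiber_mask: np.ndarray
    per_cell_truth: list[CellRecord]


def generate_cell_image(
    profile: EffectProfile,
    image_shape: tuple[int, int] = (512, 512),
    seed: int = 0,
) -> tuple[CellImage, GroundTruth]:
    """Render one synthetic 3-channel field of cells with exact ground truth.

    Non-overlapping circular cells are placed fully inside the frame; each
    contains one elliptical nucleus whose centroid is offset from the cell
    centre by ``displacement_frac * cell_radius`` along a random direction.
    The DNA channel is bright in nuclei, the actin channel shows the cell
    body plus bright line-segment fibers, and the protein channel has set
    levels per compartment.  Additive Gaussian noise (sd ``noise_sd``) is
    applied to every channel.
    """
    rows, cols = image_shape
    if rows < 128 or cols < 128:
        raise ValueError("image_shape must be at least 128x128")
    rng = np.random.default_rng(int(seed) % _SEED_MOD)

    # sample cell radii, then place non-overlapping centres by rejection
    radii = np.clip(
        rng.normal(profile.cell_radius_mean, profile.cell_radius_sd,
                   profile.cells_per_image),
        profile.nucleus_radius_mean * 1.6, None,
    )
    centres: list[tuple[float, float]] = []
    max_tries = 5000
    for i, r in enumerate(radii):
        margin = r + 2
        if rows - 2 * margin <= 0 or cols - 2 * margin <= 0:
            raise ValueError(
                f"image_shape {image_shape} too small for cell radius {r:.1f}"
            )
        for attempt in range(max_tries):
            # integer-snapped centres keep rasterized disks reflection-
            # symmetric, so mask centroids equal the nominal centres exactly
            cy = float(round(rng.uniform(margin, rows - margin)))
            cx = float(round(rng.uniform(margin, cols - margin)))
            if all(
                np.hypot(cy - oy, cx - ox) > r + radii[j] + 2
                for j, (oy, ox) in enumerate(centres)
            ):
                centres.append((cy, cx))
                break
        else:
            raise ValueError(
                f"could not place {profile.cells_per_image} non-overlapping "
                f"cells of radius ~{profile.cell_radius_mean:.0f} px in a "
                f"{rows}x{cols} image; reduce cells_per_image or enlarge the image"
            )

    cell_mask = np.zeros((rows, cols), dtype=np.int32)
    nuclei_mask = np.zeros((rows, cols), dtype=np.int32)
    fiber_mask = np.zeros((rows, cols), dtype=bool)

    for k, ((cy, cx), r_cell) in enumerate(zip(centres, radii), start=1):
        rr, cc = draw_disk((cy, cx), r_cell, shape=(rows, cols))
        cell_mask[rr, cc] = k

        # nucleus: ellipse with geometric-mean radius r_n and the target
        # minor/major ratio; offset from the cell centre by the displacement
        # fraction, shrunk if needed so the nucleus stays inside the cell
        r_n = max(2.0, rng.normal(profile.nucleus_radius_mean,
                                  profile.nucleus_radius_sd))
        ratio = profile.nucleus_axis_ratio_mean
        a = r_n / np.sqrt(ratio)   # semi-major
        b = r_n * np.sqrt(ratio)   # semi-minor
        max_off = max(0.0, r_cell - a - 1.5)
        off = min(profile.nucleus_displacement_frac_mean * r_cell, max_off)
        theta = rng.uniform(0, 2 * np.pi)
        ny = float(round(cy + off * np.sin(theta)))
        nx_ = float(round(cx + off * np.cos(theta)))
        orient = rng.uniform(0, np.pi)
        if ratio == 1.0:
            # exact symmetric disk: concentric-circle truth has d = 0, e = 1
            rr, cc = draw_disk((ny, nx_), r_n, shape=(rows, cols))
        else:
            rr, cc = draw_ellipse(ny, nx_, b, a, shape=(rows, cols),
                                  rotation=orient)
        nuclei_mask[rr, cc] = k

        # stress fibers: thickened random chords clipped to the cell body
        n_fibers = rng.poisson(profile.fiber_count_mean)
        for _ in range(n_fibers):
            length = max(4.0, rng.normal(profile.fiber_length_mean,
                                         profile.fiber_length_sd))
            ang = rng.uniform(0, np.pi)
            fy = cy + rng.uniform(-0.5, 0.5) * r_cell
            fx = cx + rng.uniform(-0.5, 0.5) * r_cell
            y0 = int(round(fy - length / 2 * np.sin(ang)))
            x0 = int(round(fx - length / 2 * np.cos(ang)))
            y1 = int(round(fy + length / 2 * np.sin(ang)))
            x1 = int(round(fx + length / 2 * np.cos(ang)))
            y0, y1 = np.clip([y0, y1], 0, rows - 1)
            x0, x1 = np.clip([x0, x1], 0, cols - 1)
            seg = np.zeros((rows, cols), dtype=bool)
            rr, cc = draw_line(y0, x0, y1, x1)
            seg[rr, cc] = True
            seg |= np.roll(seg, 1, axis=0)  # ~2 px wide
            fiber_mask |= seg & (cell_mask == k)

    # only elongated components count as stress fibers, matching the
    # reporting convention of the measurement suite; sub-length fragments
    # (rare clipping artifacts) are dropped before rendering
    flbl = cc_label(fiber_mask, connectivity=2)
    for prop in regionprops(flbl):
        if prop.axis_major_length < FIBER_LENGTH_MIN:
            fiber_mask[flbl == prop.label] = False

    cells_fg = cell_mask > 0
    nuc_fg = nuclei_mask > 0

    dna = np.full((rows, cols), profile.background_level, dtype=float)
    dna[nuc_fg] = profile.dna_level

    actin = np.full((rows, cols), profile.background_level, dtype=float)
    actin[cells_fg] = profile.actin_level
    actin[fiber_mask] = profile.fiber_level

    protein = np.full((rows, cols), profile.background_level, dtype=float)
    protein[cells_fg] = profile.yap_cyto_mean
    protein[nuc_fg] = profile.yap_nuclear_mean

    clean = CellImage(channels={"dna": dna, "actin": actin, "protein": protein})
    truth_records = measure_cells(clean, nuclei_mask, cell_mask, fiber_mask)
    truth = GroundTruth(
        nuclei_mask=nuclei_mask,
        cell_mask=cell_mask,
        fiber_mask=fiber_mask,
        per_cell_truth=truth_records,
    )

    noisy = {
        name: np.clip(
            arr + rng.normal(0.0, profile.noise_sd, arr.shape), 0.0, None
        )
        for name, arr in clean.channels.items()
    }
    return CellImage(channels=noisy), truth


@dataclass
class ConditionSet:
    """Images and ground truths grouped by condition name."""

    images: dict[str, list[tuple[CellImage, GroundTruth]]]

    def truth_records(self, condition: str) -> list[CellRecord]:
        return [
            r for _, t in self.images[condition] for r in t.per_cell_truth
        ]


def generate_condition_set(
    profiles: list[EffectProfile],
    n_images: int = 12,
    image_shape: tuple[int, int] = (512, 512),
    seed: int = 0,
) -> ConditionSet:
    """Generate ``n_images`` fields per condition, deterministically per seed.

    With default profiles (10 cells/image) and ``n_images=12`` each
    condition carries >=100 cells, matching the scale at which per-condition
    statistics are meant to be computed.
    """
    if n_images < 1:
        raise ValueError("n_images must be >= 1")
    out: dict[str, list[tuple[CellImage, GroundTruth]]] = {}
    for ci, profile in enumerate(profiles):
        if profile.condition_name in out:
            raise ValueError(f"duplicate condition {profile.condition_name!r}")
        out[profile.condition_name] = [
            generate_cell_image(
                profile, image_shape, seed=_child_seed(seed, ci, ii)
            )
            for ii in range(n_images)
        ]
    return ConditionSet(images=out)


# ---------------------------------------------------------------------------
# qPCR CT tables
# ---------------------------------------------------------------------------

@dataclass
class CTDesign:
    """Design of a synthetic qPCR experiment.

    ``true_fold_change[gene][condition]`` is the expression level relative to
    the calibrator condition; the reference gene must be 1 everywhere.  Each
    run is an independent biological sample assayed in ``replicates``
    technical wells; CT noise is Gaussian per well.
    """

    genes: list[str]
    reference_gene: str
    conditions: list[str]
    calibrator_condition: str
    true_fold_change: dict[str, dict[str, float]]
    reference_ct_mean: float = 18.0
    replicates: int = 3
    ct_noise_sd: float = 0.15
    runs: int = 3

    def __post_init__(self) -> None:
        if self.reference_gene not in self.genes:
            raise ValueError("reference_gene must be listed in genes")
        if self.calibrator_condition not in self.conditions:
            raise ValueError("calibrator_condition must be one of conditions")
        if self.ct_noise_sd < 0:
            raise ValueError("ct_noise_sd must be >= 0")
        for gene in self.genes:
            for cond in self.conditions:
                fc = self.true_fold_change.get(gene, {}).get(cond)
                if fc is None:
                    raise ValueError(f"missing fold change for ({gene}, {cond})")
                if fc <= 0:
                    raise ValueError(
                        f"fold change for ({gene}, {cond}) must be positive"
                    )
        for cond in self.conditions:
            if self.true_fold_change[self.reference_gene][cond] != 1:
                raise ValueError("reference gene fold change must be 1 everywhere")

    @classmethod
    def from_yaml(cls, path) -> "CTDesign":
        with open(path, "r", encoding="utf-8") as fh:
            return cls(**yaml.safe_load(fh))


def generate_ct_table(design: CTDesign, seed: int = 0) -> pd.DataFrame:
    """Simulate a CT table: one row per (condition, gene, run, replicate).

    CT for gene g in condition c is ``reference_ct_mean - log2(expression)``
    plus Gaussian well noise, where expression is the designed fold change
    relative to the calibrator; the reference gene's CT is therefore
    condition-independent (fold change 1 everywhere).
    """
    rng = np.random.default_rng(int(seed) % _SEED_MOD)
    rows = []
    for cond in design.conditions:
        for run in range(1, design.runs + 1):
            sample_id = f"{cond}_run{run}"
            for gene in design.genes:
                expr = design.true_fold_change[gene][cond]
                base_ct = design.reference_ct_mean - np.log2(expr)
                for rep in range(1, design.replicates + 1):
                    ct = base_ct + rng.normal(0.0, design.ct_noise_sd)
                    rows.append((sample_id, cond, gene, rep, run, ct))
    return pd.DataFrame(
        rows,
        columns=["sample_id", "condition", "gene", "replicate", "run", "ct"],
    )


# ---------------------------------------------------------------------------
# signed PPI networks with planted route and ranked-list overlap
# ---------------------------------------------------------------------------

@dataclass
class NetworkDesign:
    """Random signed digraph with a planted source->target route.

    ``ranked_overlap_plan = (c1, c2, c3)`` plants exactly that many ranked
    proteins at graph distance 0 (on the route), 1 (adjacent satellites) and
    2 (behind one mediator) from route nodes; with ``edge_prob = 0`` the
    planted route scores exactly that triple.
    """

    n_nodes: int = 30
    edge_prob: float = 0.05
    sign_probs: tuple[float, float, float] = (0.45, 0.35, 0.20)
    source: str = "KSR1"
    target: str = "YAP1"
    planted_route: list[str] = field(
        default_factory=lambda: ["KSR1", "STK4", "LATS1", "YAP1"]
    )
    ranked_list_size: int = 20
    ranked_overlap_plan: tuple[int, int, int] = (2, 3, 1)

    def __post_init__(self) -> None:
        if self.planted_route[0] != self.source or self.planted_route[-1] != self.target:
            raise ValueError("planted_route must run from source to target")
        if len(set(self.planted_route)) != len(self.planted_route):
            raise ValueError("planted_route must be a simple path")
        if self.ranked_list_size < sum(self.ranked_overlap_plan):
            raise ValueError("ranked_list_size must cover the overlap plan")
        if not np.isclose(sum(self.sign_probs), 1.0):
            raise ValueError("sign_probs must sum to 1")


def generate_ppi_network(
    design: NetworkDesign, seed: int = 0
) -> tuple[nx.DiGraph, list[str], list[str]]:
    """Build (graph, ranked list, planted route).

    The planted route's edges are always present (activation sign).  The
    ranked list contains, in order: the planted route nodes, the planted
    adjacent satellites, the planted distance-2 leaves, then off-graph
    filler proteins up to ``ranked_list_size``.
    """
    c1_plan, c2_plan, c3_plan = design.ranked_overlap_plan
    route = [n.upper() for n in design.planted_route]
    if c1_plan > len(route):
        raise ValueError("overlap plan c1 exceeds route length")
    needed = len(route) + c2_plan + 2 * c3_plan
    if needed > design.n_nodes:
        raise ValueError(
            f"overlap plan needs {needed} nodes but n_nodes={design.n_nodes}"
        )
    rng = np.random.default_rng(int(seed) % _SEED_MOD)
    g = nx.DiGraph()
    g.add_nodes_from(route)
    for u, v in zip(route, route[1:]):
        g.add_edge(u, v, signs=frozenset({ACTIVATION}))

    sat_nodes = [f"SAT{i:03d}" for i in range(1, c2_plan + 1)]
    for i, s in enumerate(sat_nodes):
        anchor = route[i % len(route)]
        g.add_edge(anchor, s, signs=frozenset({ACTIVATION}))
    med_nodes = [f"MED{i:03d}" for i in range(1, c3_plan + 1)]
    leaf_nodes = [f"LEAF{i:03d}" for i in range(1, c3_plan + 1)]
    for i, (m, leaf) in enumerate(zip(med_nodes, leaf_nodes)):
        anchor = route[i % len(route)]
        g.add_edge(anchor, m, signs=frozenset({ACTIVATION}))
        g.add_edge(m, leaf, signs=frozenset({ACTIVATION}))

    n_bg = design.n_nodes - g.number_of_nodes()
    bg_nodes = [f"BG{i:03d}" for i in range(1, n_bg + 1)]
    g.add_nodes_from(bg_nodes)

    if design.edge_prob > 0:
        signs = (ACTIVATION, INHIBITION, UNKNOWN)
        nodes = sorted(g.nodes)
        for u in nodes:
            for v in nodes:
                if u == v or g.has_edge(u, v):
                    continue
                if rng.random() < design.edge_prob:
                    s = signs[rng.choice(3, p=design.sign_probs)]
                    g.add_edge(u, v, signs=frozenset({s}))

    ranked = list(route[:c1_plan]) + sat_nodes + leaf_nodes
    n_fill = design.ranked_list_size - len(ranked)
    ranked += [f"FILLER{i:03d}" for i in range(1, n_fill + 1)]
    return g, ranked, route


# ---------------------------------------------------------------------------
# mass photometry events
# ---------------------------------------------------------------------------

@dataclass
class MassDesign:
    """Gaussian mixture of molecular species with a linear contrast calibration.

    mass = a * contrast + b, so simulated contrasts are (mass - b) / a.
    """

    species: list[tuple[str, float, float]]  # (name, mass kDa, fraction)
    n_events: int = 3000
    mass_sd: float = 8.0
    contrast_slope: float = 1000.0
    contrast_intercept: float = 0.0

    def __post_init__(self) -> None:
        fracs = [f for _, _, f in self.species]
        if not np.isclose(sum(fracs), 1.0):
            raise ValueError("species fractions must sum to 1")
        if any(m <= 0 for _, m, _ in self.species):
            raise ValueError("species masses must be positive")
        if self.contrast_slope == 0:
            raise ValueError("contrast_slope must be nonzero")


def generate_mass_events(design: MassDesign, seed: int = 0):
    """Draw landing-event contrasts from the designed mass mixture, shuffled."""
    from .massphoto import MassEventSet

    rng = np.random.default_rng(int(seed) % _SEED_MOD)
    masses = np.array([m for _, m, _ in design.species])
    fracs = np.array([f for _, _, f in design.species])
    comp = rng.choice(len(design.species), size=design.n_events, p=fracs)
    events = rng.normal(masses[comp], design.mass_sd)
    rng.shuffle(events)
    contrasts = (events - design.contrast_intercept) / design.contrast_slope
    return MassEventSet(
        values=contrasts,
        units="contrast",
        calibration=(design.contrast_slope, design.contrast_intercept),
    )


# ---------------------------------------------------------------------------
# RPPA tables
# ---------------------------------------------------------------------------

def generate_rppa_table(
    n_proteins: int = 200,
    n_per_group: int = 3,
    planted: dict[str, float] | None = None,
    noise_sd: float = 0.1,
    seed: int = 0,
):
    """Simulate a normalized log2 RPPA matrix with planted group effects.

    Control samples are N(0, noise_sd) per protein; treated samples are
    shifted by the planted log2 effects; unplanted proteins share the null
    distribution across groups.  Protein ids are P0001..; planted keys must
    be valid ids.
    """
    from .assays import RPPATable

    if n_per_group < 2:
        raise ValueError("n_per_group must be >= 2")
    planted = planted or {}
    rng = np.random.default_rng(int(seed) % _SEED_MOD)
    proteins = [f"P{i:04d}" for i in range(1, n_proteins + 1)]
    unknown = set(planted) - set(proteins)
    if unknown:
        raise ValueError(f"planted effects for unknown proteins: {sorted(unknown)}")
    cols = [f"control_{i}" for i in range(1, n_per_group + 1)] + [
        f"treated_{i}" for i in range(1, n_per_group + 1)
    ]
    values = rng.normal(0.0, noise_sd, size=(n_proteins, 2 * n_per_group))
    shift = np.array([planted.get(p, 0.0) for p in proteins])
    values[:, n_per_group:] += shift[:, None]
    frame = pd.DataFrame(values, index=proteins, columns=cols)
    groups = pd.Series(
        ["control"] * n_per_group + ["treated"] * n_per_group, index=cols
    )
    return RPPATable(values=frame, groups=groups)


__all__ = [
    "EffectProfile", "GroundTruth", "ConditionSet", "CTDesign",
    "NetworkDesign", "MassDesign",
    "generate_cell_image", "generate_condition_set", "generate_ct_table",
    "generate_ppi_network", "generate_mass_events", "generate_rppa_table",
]
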