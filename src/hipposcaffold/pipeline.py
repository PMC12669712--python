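"""End-to-end synthetic experiment driver.

Runs the full suite — image simulation and quantification, ddCT expression,
RPPA filter/rank, signed-network route scoring and mass-photometry complex
detection — from one validated configuration and a single seed, writing
per-stage TSVs plus a consolidated summary.  Identical (config, seed) runs
produce byte-identical outputs: the global seed is fanned out to fixed
per-stage child seeds so stages can be re-run independently.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import assays, imaging, io, massphoto, network, synthetic
from .fixture_data import CT_DESIGN_NAMES, load_ct_design, load_profile

logger = logging.getLogger(__name__)

STAGES = ("images", "qpcr", "rppa", "routes", "massphoto")

# fixed per-stage seed offsets: one run seed, independent stage streams
_STAGE_OFFSET = {name: i + 1 for i, name in enumerate(STAGES)}

_DEFAULT_PARAMS: dict[str, dict] = {
    "images": {
        "conditions": ["wt", "ksr1_null"],
        "n_images": 11,
        "image_shape": [512, 512],
    },
    "qpcr": {"designs": list(CT_DESIGN_NAMES)},
    "rppa": {
        "n_proteins": 200,
        "n_per_group": 3,
        "noise_sd": 0.1,
        "n_planted": 10,
        "planted_log2fc": 2.0,
        "fc_min": 2.0,
        "alpha": 0.05,
        "top_n": 100,
    },
    "routes": {"max_len": 4, "top_k": 20, "edge_prob": 0.05},
    "massphoto": {
        "mass_a": 100.0,
        "mass_b": 150.0,
        "complex_fraction": 0.3,
        "n_events": 3000,
        "mass_sd": 8.0,
        "k_max": 4,
    },
}


class ConfigError(ValueError):
    """Raised when a run configuration fails validation."""


@dataclass
class RunConfig:
    """Validated pipeline configuration: seed, stage toggles, per-stage
    parameter blocks and an output directory.  Unknown keys are rejected."""

    seed: int
    out_dir: Path
    stages: dict[str, bool] = field(
        default_factory=lambda: {s: True for s in STAGES}
    )
    params: dict[str, dict] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.out_dir = Path(self.out_dir)
        unknown = set(self.stages) - set(STAGES)
        if unknown:
            raise ConfigError(f"unknown stage(s): {sorted(unknown)}")
        for s in STAGES:
            self.stages.setdefault(s, True)
        unknown = set(self.params) - set(STAGES)
        if unknown:
            raise ConfigError(f"unknown parameter block(s): {sorted(unknown)}")
        merged = {}
        for stage in STAGES:
            block = dict(_DEFAULT_PARAMS[stage])
            overrides = self.params.get(stage, {})
            bad = set(overrides) - set(block)
            if bad:
                raise ConfigError(
                    f"unknown key(s) in params.{stage}: {sorted(bad)}"
                )
            block.update(overrides)
            merged[stage] = block
        self.params = merged

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path, "r", encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        known = {"seed", "out_dir", "stages", "params"}
        unknown = set(data) - known
        if unknown:
            raise ConfigError(f"unknown config key(s): {sorted(unknown)}")
        if "seed" not in data or "out_dir" not in data:
            raise ConfigError("config requires 'seed' and 'out_dir'")
        return cls(
            seed=int(data["seed"]),
            out_dir=Path(data["out_dir"]),
            stages=data.get("stages", {}) or {},
            params=data.get("params", {}) or {},
        )

    def stage_seed(self, stage: str) -> int:
        return synthetic._child_seed(self.seed, _STAGE_OFFSET[stage])


@dataclass
class ReportBundle:
    """Paths of the per-stage outputs plus the consolidated summary table."""

    out_dir: Path
    summary: pd.DataFrame
    outputs: dict[str, list[Path]]


def _stage_images(cfg: RunConfig, out: Path) -> tuple[pd.DataFrame, list[Path]]:
    p = cfg.params["images"]
    profiles = [load_profile(name) for name in p["conditions"]]
    cs = synthetic.generate_condition_set(
        profiles,
        n_images=p["n_images"],
        image_shape=tuple(p["image_shape"]),
        seed=cfg.stage_seed("images"),
    )
    paths = []
    records_by_cond = {}
    for cond, items in cs.images.items():
        recs = []
        for img, _truth in items:
            nuclei = imaging.segment_nuclei(img)
            cells = imaging.segment_cells(img, nuclei)
            fibers = imaging.segment_stress_fibers(img, cells)
            recs.extend(imaging.measure_cells(img, nuclei, cells, fibers))
        records_by_cond[cond] = recs
        path = out / f"cells_{cond}.tsv"
        io.write_tsv(io.records_to_frame(recs), path)
        paths.append(path)
    rows = []
    ref_cond = p["conditions"][0]
    for cond in p["conditions"][1:]:
        for metric in ("mean_nuc_intensity", "pct_fiber_area",
                       "nuclear_displacement", "eccentricity_ratio"):
            eff = imaging.estimate_effect(
                records_by_cond[ref_cond], records_by_cond[cond], metric
            )
            rows.append({
                "stage": "images",
                "quantity": f"{metric}:{cond}_vs_{ref_cond}",
                "value": eff.percent_change,
                "p_value": eff.p_value,
            })
    eff_path = out / "image_effects.tsv"
    io.write_tsv(pd.DataFrame(rows), eff_path)
    paths.append(eff_path)
    return pd.DataFrame(rows), paths


def _stage_qpcr(cfg: RunConfig, out: Path) -> tuple[pd.DataFrame, list[Path]]:
    p = cfg.params["qpcr"]
    rows, paths = [], []
    for i, name in enumerate(p["designs"]):
        design = load_ct_design(name)
        table = synthetic.generate_ct_table(
            design, seed=synthetic._child_seed(cfg.stage_seed("qpcr"), i)
        )
        target = next(g for g in design.genes if g != design.reference_gene)
        rel = assays.ddct(table, target, design.reference_gene,
                          design.calibrator_condition)
        alt = next(c for c in design.conditions
                   if c != design.calibrator_condition)
        fold = rel.fold(alt)
        rows.append({
            "stage": "qpcr",
            "quantity": f"{name}:fold",
            "value": fold,
            "p_value": float("nan"),
        })
        rows.append({
            "stage": "qpcr",
            "quantity": f"{name}:percent_change",
            "value": assays.percent_change(fold, 1.0),
            "p_value": float("nan"),
        })
        path = out / f"ct_{name}.tsv"
        io.write_tsv(table, path)
        paths.append(path)
    frame = pd.DataFrame(rows)
    path = out / "qpcr_effects.tsv"
    io.write_tsv(frame, path)
    paths.append(path)
    return frame, paths


def _stage_rppa(cfg: RunConfig, out: Path):
    p = cfg.params["rppa"]
    planted = {
        f"P{i:04d}": p["planted_log2fc"] * (1 if i % 2 else -1)
        for i in range(1, p["n_planted"] + 1)
    }
    table = synthetic.generate_rppa_table(
        n_proteins=p["n_proteins"],
        n_per_group=p["n_per_group"],
        planted=planted,
        noise_sd=p["noise_sd"],
        seed=cfg.stage_seed("rppa"),
    )
    differential, ranked = assays.rppa_filter_rank(
        table, fc_min=p["fc_min"], alpha=p["alpha"], top_n=p["top_n"]
    )
    path = out / "rppa_ranked.tsv"
    io.write_tsv(ranked, path)
    recovered = len(set(differential) & set(planted))
    frame = pd.DataFrame([{
        "stage": "rppa",
        "quantity": "planted_recovered",
        "value": recovered,
        "p_value": float("nan"),
    }])
    io.write_tsv(frame, out / "rppa_effects.tsv")
    return frame, [path, out / "rppa_effects.tsv"], ranked


def _stage_routes(cfg: RunConfig, out: Path, ranked_proteins=None):
    p = cfg.params["routes"]
    design = synthetic.NetworkDesign(edge_prob=p["edge_prob"])
    graph, ranked, _route = synthetic.generate_ppi_network(
        design, seed=cfg.stage_seed("routes")
    )
    routes, truncated = network.enumerate_routes(
        graph, design.source, design.target, max_len=p["max_len"]
    )
    scores = [network.score_route(r, graph, ranked) for r in routes]
    ordered, hubs = network.rank_routes_identify_hub(
        routes, scores, top_k=p["top_k"]
    )
    frame = network.routes_to_frame(ordered)
    path = out / "routes.tsv"
    io.write_tsv(frame, path)
    top = ordered[0]
    rows = pd.DataFrame([
        {"stage": "routes", "quantity": "n_routes", "value": len(routes),
         "p_value": float("nan")},
        {"stage": "routes", "quantity": "best_route_total",
         "value": top[1].total, "p_value": float("nan")},
        {"stage": "routes", "quantity": "hub",
         "value": ";".join(sorted(hubs)), "p_value": float("nan")},
    ])
    io.write_tsv(rows, out / "route_effects.tsv")
    return rows, [path, out / "route_effects.tsv"]


def _stage_massphoto(cfg: RunConfig, out: Path):
    p = cfg.params["massphoto"]
    seed = cfg.stage_seed("massphoto")
    ma, mb, cf = p["mass_a"], p["mass_b"], p["complex_fraction"]
    design_a = synthetic.MassDesign(
        species=[("A", ma, 1.0)], n_events=p["n_events"], mass_sd=p["mass_sd"]
    )
    design_b = synthetic.MassDesign(
        species=[("B", mb, 1.0)], n_events=p["n_events"], mass_sd=p["mass_sd"]
    )
    design_mix = synthetic.MassDesign(
        species=[
            ("A", ma, (1 - cf) / 2),
            ("B", mb, (1 - cf) / 2),
            ("A:B", ma + mb, cf),
        ],
        n_events=p["n_events"],
        mass_sd=p["mass_sd"],
    )
    fits = {}
    for label, design, off in (("a", design_a, 1), ("b", design_b, 2),
                               ("mix", design_mix, 3)):
        events = synthetic.generate_mass_events(
            design, seed=synthetic._child_seed(seed, off)
        )
        fits[label] = massphoto.fit_mass_peaks(
            events, k_max=p["k_max"], seed=synthetic._child_seed(seed, off)
        )
    call = massphoto.detect_complex(fits["a"], fits["b"], fits["mix"])
    peak_rows = [
        {"sample": label, "center_kda": pk.center, "width_kda": pk.width,
         "weight": pk.weight}
        for label, ps in fits.items() for pk in ps.peaks
    ]
    path = out / "mass_peaks.tsv"
    io.write_tsv(pd.DataFrame(peak_rows), path)
    rows = pd.DataFrame([
        {"stage": "massphoto", "quantity": "complex_detected",
         "value": int(call.is_complex), "p_value": float("nan")},
        {"stage": "massphoto", "quantity": "complex_center_kda",
         "value": call.complex_peak.center if call.complex_peak else float("nan"),
         "p_value": float("nan")},
    ])
    io.write_tsv(rows, out / "mass_effects.tsv")
    return rows, [path, out / "mass_effects.tsv"]


def run_pipeline(config: RunConfig) -> ReportBundle:
    """Execute all enabled stages and write a consolidated summary TSV."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    summaries: list[pd.DataFrame] = []
    outputs: dict[str, list[Path]] = {}
    ranked = None
    for stage in STAGES:
        if not config.stages.get(stage, True):
            continue
        logger.info("[%s] running with seed %d", stage, config.stage_seed(stage))
        if stage == "images":
            frame, paths = _stage_images(config, out)
        elif stage == "qpcr":
            frame, paths = _stage_qpcr(config, out)
        elif stage == "rppa":
            frame, paths, ranked = _stage_rppa(config, out)
        elif stage == "routes":
            frame, paths = _stage_routes(config, out, ranked)
        else:
            frame, paths = _stage_massphoto(config, out)
        summaries.append(frame)
        outputs[stage] = paths
    summary = (
        pd.concat(summaries, ignore_index=True)
        if summaries
        else pd.DataFrame(columns=["stage", "quantity", "value", "p_value"])
    )
    summary_path = out / "summary.tsv"
    io.write_tsv(summary, summary_path)
    meta = {"seed": config.seed, "stages": {s: bool(config.stages.get(s, True))
                                            for s in STAGES}}
    (out / "run_meta.yaml").write_text(
        yaml.safe_dump(meta, sort_keys=True), encoding="utf-8"
    )
    return ReportBundle(out_dir=out, summary=summary, outputs=outputs)
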