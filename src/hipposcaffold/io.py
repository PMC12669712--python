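"""File-format helpers: multi-page TIFF images, TSV tables, event CSVs.

Images travel as one TIFF page per channel (dna, actin, protein) with an
optional label-mask TIFF and a JSON sidecar of ground-truth records; all
tables are tab-separated UTF-8 with a header row.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .imaging import CHANNEL_NAMES, CellImage, CellRecord

FLOAT_FMT = "%.6g"


def write_image_tiff(image: CellImage, path) -> None:
    """Write a CellImage as a multi-page TIFF (page order dna, actin, protein)."""
    stack = np.stack(
        [np.asarray(image.channels[c], dtype=np.float32) for c in CHANNEL_NAMES]
    )
    tifffile.imwrite(path, stack, photometric="minisblack")


def read_image_tiff(path, channel_order: tuple[str, ...] = CHANNEL_NAMES) -> CellImage:
    """Read a multi-page TIFF into a CellImage (pages mapped by channel_order)."""
    stack = tifffile.imread(path)
    if stack.ndim == 2:
        stack = stack[None]
    if stack.shape[0] != len(channel_order):
        raise ValueError(
            f"expected {len(channel_order)} pages, found {stack.shape[0]}"
        )
    return CellImage(channels={
        name: np.asarray(stack[i], dtype=float)
        for i, name in enumerate(channel_order)
    })


def write_mask_tiff(mask: np.ndarray, path) -> None:
    tifffile.imwrite(path, np.asarray(mask, dtype=np.int32))


def records_to_frame(records: list[CellRecord]) -> pd.DataFrame:
    """Tabulate cell records, one row per cell (fiber lengths comma-joined)."""
    rows = []
    for r in records:
        d = dataclasses.asdict(r)
        d["fiber_lengths"] = ",".join(f"{v:.2f}" for v in r.fiber_lengths)
        d["flags"] = ";".join(sorted(r.flags))
        rows.append(d)
    return pd.DataFrame(rows)


def write_tsv(frame: pd.DataFrame, path, index: bool = False) -> None:
    frame.to_csv(path, sep="\t", index=index, float_format=FLOAT_FMT,
                 lineterminator="\n")


def read_tsv(path, **kwargs) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", **kwargs)


def write_truth_json(records: list[CellRecord], path) -> None:
    payload = []
    for r in records:
        d = dataclasses.asdict(r)
        d["flags"] = sorted(r.flags)
        payload.append(d)
    Path(path).write_text(json.dumps(payload, indent=1), encoding="utf-8")


def read_mass_events(path):
    """Read a landing-event CSV with a ``mass_kda`` or ``contrast`` column."""
    from .massphoto import MassEventSet

    frame = pd.read_csv(path)
    if "mass_kda" in frame.columns:
        return MassEventSet(values=frame["mass_kda"].to_numpy(), units="mass")
    if "contrast" in frame.columns:
        if not {"cal_slope", "cal_intercept"} <= set(frame.columns):
            raise ValueError(
                "contrast events need cal_slope and cal_intercept columns"
            )
        return MassEventSet(
            values=frame["contrast"].to_numpy(),
            units="contrast",
            calibration=(
                float(frame["cal_slope"].iloc[0]),
                float(frame["cal_intercept"].iloc[0]),
            ),
        )
    raise ValueError("event CSV needs a mass_kda or contrast column")
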