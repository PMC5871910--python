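"""Table dialects, layout JSON, and the run manifest.

All tables are UTF-8 CSV with a leading ``# scwb-schema=1`` comment
line; floats use '.' decimals; non-converged fits keep NaN fields as
empty cells.  Writes are atomic (temp file + rename).
"""

from __future__ import annotations

import hashlib
import json
import os
import tempfile
from pathlib import Path

import pandas as pd

SCHEMA_LINE = "# scwb-schema=1"

REQUIRED_COLUMNS = {
    "profiles": ["lane_id", "round", "channel", "target", "position_um",
                 "intensity_afu"],
    "fits": ["lane_id", "target", "mu_um", "sigma_um", "auc", "snr", "r2",
             "converged", "qc_pass"],
    "calls": ["lane_id", "has_p185", "has_terbb2", "ratio_t_over_p185"],
    "cells": ["lane_id", "is_cell", "is_epithelial", "is_her2_pos",
              "is_terbb2_pos"],
    "ladder": ["protein", "mass_kda", "distance_um"],
}

__all__ = ["write_table", "read_table", "write_layout", "read_layout",
           "write_manifest", "file_digest", "SCHEMA_LINE"]


def _atomic_write(path: Path, text: str) -> None:
    fd, tmp = tempfile.mkstemp(dir=path.parent, suffix=".tmp")
    try:
        with os.fdopen(fd, "w", encoding="utf-8", newline="") as fh:
            fh.write(text)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


def write_table(df: pd.DataFrame, path, kind: str | None = None) -> None:
    path = Path(path)
    if kind is not None:
        _check_schema(df, kind)
    csv = df.to_csv(index=False, lineterminator="\n")
    _atomic_write(path, SCHEMA_LINE + "\n" + csv)


def _check_schema(df: pd.DataFrame, kind: str) -> None:
    req = REQUIRED_COLUMNS.get(kind)
    if req is None:
        raise KeyError(f"unknown table kind {kind!r}")
    missing = [c for c in req if c not in df.columns]
    if missing:
        raise ValueError(f"{kind} table missing column(s): {', '.join(missing)}")


def read_table(path, kind: str | None = None) -> pd.DataFrame:
    df = pd.read_csv(path, comment="#", float_precision="round_trip")
    if kind is not None:
        _check_schema(df, kind)
    return df


def write_layout(layout: dict, path) -> None:
    _atomic_write(Path(path), json.dumps(layout, indent=2, sort_keys=True) + "\n")


def read_layout(path, profiles: pd.DataFrame | None = None) -> dict:
    with open(path, encoding="utf-8") as fh:
        layout = json.load(fh)
    if "lanes" not in layout or "um_per_px" not in layout:
        raise ValueError("layout JSON missing required keys 'lanes'/'um_per_px'")
    if profiles is not None:
        missing = set(profiles["lane_id"].unique()) - set(layout["lanes"])
        if missing:
            raise ValueError(f"layout missing lane(s): {sorted(missing)[:5]}")
    return layout


def file_digest(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def write_image(image, path) -> None:
    """Write a single-channel 16-bit grayscale TIFF."""
    import tifffile

    tifffile.imwrite(path, image)


def read_image(path):
    import tifffile

    return tifffile.imread(path)


def write_manifest(manifest: dict, path) -> None:
    counts = manifest.get("counts", {})
    order = ["lanes", "cells", "epithelial", "her2_pos", "terbb2_pos"]
    present = [counts[k] for k in order if k in counts]
    if any(a < b for a, b in zip(present, present[1:])):
        raise ValueError(f"inconsistent manifest counts: {counts}")
    _atomic_write(Path(path), json.dumps(manifest, indent=2, sort_keys=True) + "\n")
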