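"""CSV readers/writers, block joining and configuration documents.

Spectra travel as wide CSV (sample_id, cultivar, replicate, then one
column per wavenumber); lab panels as named-column CSV with empty cells
for missing values; configuration as a single YAML or JSON document with
a ``seed`` field.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .synth import LAB_PARAMS, LabPanel, SpectraBlock

__all__ = [
    "write_spectra_csv",
    "read_spectra_csv",
    "write_panel_csv",
    "read_panel_csv",
    "join_blocks",
    "load_config",
    "save_config",
]

_LABEL_COLS = ["sample_id", "cultivar", "replicate"]


def write_spectra_csv(block: SpectraBlock, path: str | Path) -> None:
    df = pd.DataFrame(block.X, columns=[repr(float(w)) for w in block.grid])
    df.insert(0, "replicate", block.replicate)
    df.insert(0, "cultivar", block.cultivar)
    df.insert(0, "sample_id", block.sample_id)
    df.to_csv(path, index=False)


def read_spectra_csv(path: str | Path) -> SpectraBlock:
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in _LABEL_COLS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing label columns {missing}")
    wn_cols = [c for c in df.columns if c not in _LABEL_COLS]
    try:
        grid = np.array([float(c) for c in wn_cols])
    except ValueError as e:
        raise ValueError(f"{path}: non-numeric wavenumber header: {e}") from e
    d = np.diff(grid)
    if not (np.all(d > 0) or np.all(d < 0)):
        raise ValueError(f"{path}: wavenumber header is not strictly monotone")
    X = df[wn_cols].to_numpy(float)
    if not np.all(np.isfinite(X)):
        r, c = np.argwhere(~np.isfinite(X))[0]
        raise ValueError(f"{path}: non-finite value at row {r}, column {wn_cols[c]}")
    return SpectraBlock(
        grid=grid,
        X=X,
        sample_id=df["sample_id"].to_numpy(str),
        cultivar=df["cultivar"].to_numpy(str),
        replicate=df["replicate"].to_numpy(int),
    )


def write_panel_csv(panel: LabPanel, path: str | Path) -> None:
    values = panel.values.astype(object).copy()
    values[panel.missing_mask] = None
    df = pd.DataFrame(values, columns=list(LAB_PARAMS))
    df.insert(0, "harvest", panel.harvest)
    df.insert(0, "cultivar", panel.cultivar)
    df.insert(0, "sample_id", panel.sample_id)
    df.to_csv(path, index=False)


def read_panel_csv(path: str | Path) -> LabPanel:
    df = pd.read_csv(path, float_precision="round_trip")
    needed = ["sample_id", "cultivar", "harvest", *LAB_PARAMS]
    missing = [c for c in needed if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    values = df[list(LAB_PARAMS)].to_numpy(float)
    mask = np.isnan(values)
    values = np.where(mask, 0.0, values)
    return LabPanel(
        sample_id=df["sample_id"].to_numpy(str),
        cultivar=df["cultivar"].to_numpy(str),
        harvest=df["harvest"].to_numpy(int),
        values=values,
        missing_mask=mask,
    )


def join_blocks(
    spectra: SpectraBlock, panel: LabPanel, complete_case: bool = True
) -> tuple[SpectraBlock, LabPanel]:
    """Align spectra rows with panel fruits by sample_id.

    With ``complete_case``, fruits carrying any masked lab value are
    dropped from both blocks.  The returned panel holds one row per
    retained fruit, in spectra order; the returned spectra keep all
    replicate rows of retained fruits.
    """
    panel_ids = set(panel.sample_id.tolist())
    keep_ids = panel_ids & set(spectra.sample_id.tolist())
    if not keep_ids:
        raise ValueError("spectra and panel share no sample_ids")
    if complete_case:
        complete = set(panel.sample_id[panel.complete_case_mask()].tolist())
        keep_ids &= complete
        if not keep_ids:
            raise ValueError("no complete-case fruits remain after joining")

    row_keep = np.array([sid in keep_ids for sid in spectra.sample_id])
    out_spectra = SpectraBlock(
        grid=spectra.grid.copy(),
        X=spectra.X[row_keep],
        sample_id=spectra.sample_id[row_keep],
        cultivar=spectra.cultivar[row_keep],
        replicate=spectra.replicate[row_keep],
    )
    panel_index = {sid: i for i, sid in enumerate(panel.sample_id)}
    fruit_ids = list(dict.fromkeys(out_spectra.sample_id.tolist()))
    rows = np.array([panel_index[sid] for sid in fruit_ids])
    out_panel = LabPanel(
        sample_id=panel.sample_id[rows],
        cultivar=panel.cultivar[rows],
        harvest=panel.harvest[rows],
        values=panel.values[rows],
        missing_mask=panel.missing_mask[rows],
    )
    return out_spectra, out_panel


def load_config(path: str | Path) -> dict:
    path = Path(path)
    text = path.read_text()
    if path.suffix in (".yaml", ".yml"):
        cfg = yaml.safe_load(text)
    else:
        cfg = json.loads(text)
    if "seed" not in cfg:
        raise ValueError(f"{path}: config must contain a 'seed' field")
    return cfg


def save_config(cfg: dict, path: str | Path) -> None:
    path = Path(path)
    if path.suffix in (".yaml", ".yml"):
        path.write_text(yaml.safe_dump(cfg, sort_keys=False))
    else:
        path.write_text(json.dumps(cfg, indent=2))
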