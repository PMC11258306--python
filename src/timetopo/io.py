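"""Tab-separated and YAML I/O for the pipeline's tables and configs.

All tables are plain TSV with a one-line header; an optional leading
comment line carries the pipeline config hash for provenance (lines
starting with ``#`` are ignored on read).
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import pandas as pd
import yaml

from .dsp import AOIMatrix, MarkerRoles
from .graphstats import validate_cell_table


def _write_tsv(frame: pd.DataFrame, path, config_hash: str | None = None,
               index: bool = False) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        if config_hash:
            fh.write(f"# config_hash={config_hash}\n")
        frame.to_csv(fh, sep="\t", index=index)


def _read_tsv(path, **kwargs) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", **kwargs)


def write_cell_table(cells: pd.DataFrame, path, config_hash: str | None = None):
    validate_cell_table(cells)
    _write_tsv(cells, path, config_hash)


def read_cell_table(path) -> pd.DataFrame:
    cells = _read_tsv(path, dtype={"roi_id": str, "cell_id": str, "cls": str})
    return validate_cell_table(cells)


def write_table(frame: pd.DataFrame, path, config_hash: str | None = None,
                index: bool = False):
    _write_tsv(frame, path, config_hash, index=index)


def read_table(path) -> pd.DataFrame:
    return _read_tsv(path)


def write_aoi_matrix(matrix: AOIMatrix, counts_path, meta_path,
                     config_hash: str | None = None) -> None:
    """Write counts and sidecar metadata as two TSVs (markers as columns)."""
    _write_tsv(matrix.counts, counts_path, config_hash, index=True)
    meta = matrix.meta.copy()
    meta["_housekeepers"] = ";".join(matrix.roles.housekeepers)
    meta["_isotypes"] = ";".join(matrix.roles.isotypes)
    meta["_hyb_controls"] = ";".join(matrix.roles.hyb_controls)
    _write_tsv(meta, meta_path, config_hash, index=True)


def read_aoi_matrix(counts_path, meta_path) -> AOIMatrix:
    counts = _read_tsv(counts_path, index_col=0)
    meta = _read_tsv(meta_path, index_col=0)
    roles = MarkerRoles(
        housekeepers=_split_role(meta, "_housekeepers"),
        isotypes=_split_role(meta, "_isotypes"),
        hyb_controls=_split_role(meta, "_hyb_controls"),
    )
    meta = meta.drop(columns=[c for c in meta.columns if c.startswith("_")])
    return AOIMatrix(counts=counts, meta=meta, roles=roles)


def _split_role(meta: pd.DataFrame, col: str) -> list[str]:
    if col not in meta.columns or meta[col].isna().all():
        return []
    val = str(meta[col].iloc[0])
    return [v for v in val.split(";") if v]


def write_yaml(obj, path) -> None:
    """Serialize a dataclass (or plain mapping) to YAML."""
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        obj = dataclasses.asdict(obj)
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        yaml.safe_dump(obj, fh, sort_keys=True)


def read_yaml(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)
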