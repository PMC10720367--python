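"""Readers and writers for the pipeline's tabular formats.

Genotypes travel either as a HapMap-like TSV (rs, alleles, chrom, pos,
then one column per line, calls AA/AB/BB or 0/1/2) or as a wide CSV
(lines x markers, dosage codes).  Missing codes NA, NN, -, . and empty
are all accepted.  Every writer can prepend a provenance header
(# key: value lines) which the readers skip.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from .simdata import GeneticMap, GenotypeMatrix

MISSING_CODES = {"NA", "NN", "-", ".", ""}
_DOSAGE_TO_LETTER = {0.0: "BB", 1.0: "AB", 2.0: "AA"}
_LETTER_TO_DOSAGE = {"BB": 0.0, "AB": 1.0, "BA": 1.0, "AA": 2.0}


def provenance_header(meta: dict[str, Any]) -> str:
    return "".join(f"# {k}: {v}\n" for k, v in meta.items())


def config_digest(obj: Any) -> str:
    blob = json.dumps(obj, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def _write_with_header(df: pd.DataFrame, path: Path, meta: dict | None,
                       sep: str, index: bool) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        if meta:
            fh.write(provenance_header(meta))
        df.to_csv(fh, sep=sep, index=index)


def write_hapmap(
    genotypes: GenotypeMatrix, gmap: GeneticMap, path: str | Path,
    calls_as: str = "letters", meta: dict | None = None,
) -> None:
    """HapMap-like TSV: rs, alleles, chrom, pos, then one column per line."""
    gdf = gmap.table.set_index("marker_id")
    rows = []
    for j, mk in enumerate(genotypes.marker_ids):
        rec: dict[str, Any] = {
            "rs": mk, "alleles": "A/B",
            "chrom": gdf.loc[mk, "chromosome"],
            "pos": int(gdf.loc[mk].get("position_bp", j) or j),
        }
        for i, line in enumerate(genotypes.line_ids):
            v = genotypes.calls[i, j]
            if np.isnan(v):
                rec[line] = "NN"
            elif calls_as == "letters":
                rec[line] = _DOSAGE_TO_LETTER[v]
            else:
                rec[line] = str(int(v))
        rows.append(rec)
    _write_with_header(pd.DataFrame(rows), Path(path), meta, "\t", index=False)


def write_wide_csv(genotypes: GenotypeMatrix, path: str | Path,
                   meta: dict | None = None) -> None:
    df = genotypes.to_frame()
    df.index.name = "line_id"
    _write_with_header(df, Path(path), meta, ",", index=True)


def _parse_call(token) -> float:
    if token is None or (isinstance(token, float) and np.isnan(token)):
        return np.nan
    token = str(token).strip()
    if token in MISSING_CODES or token.lower() == "nan":
        return np.nan
    if token in _LETTER_TO_DOSAGE:
        return _LETTER_TO_DOSAGE[token]
    try:
        v = float(token)
    except ValueError:
        raise ValueError(f"unknown allele code {token!r}") from None
    if v not in (0.0, 1.0, 2.0):
        raise ValueError(f"unknown allele code {token!r}")
    return v


def read_genotypes(path: str | Path, subfamily: pd.Series | None = None
                   ) -> GenotypeMatrix:
    """Read HapMap-like TSV or wide CSV; dialect detected from the header."""
    path = Path(path)
    with open(path) as fh:
        header = fh.readline()
        while header.startswith("#"):
            header = fh.readline()
    is_hapmap = header.split("\t")[0].strip() in ("rs", "rs#")
    if is_hapmap:
        df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
        if df["rs"].duplicated().any():
            dup = df.loc[df["rs"].duplicated(), "rs"].iloc[0]
            raise ValueError(f"duplicate marker id {dup!r}")
        marker_ids = list(df["rs"])
        line_cols = [c for c in df.columns if c not in
                     ("rs", "rs#", "alleles", "chrom", "pos")]
        calls = np.array([[_parse_call(v) for v in df[c]] for c in line_cols])
        line_ids = line_cols
    else:
        df = pd.read_csv(path, comment="#", index_col=0, dtype=str)
        if pd.Index(df.columns).duplicated().any():
            dup = df.columns[pd.Index(df.columns).duplicated()][0]
            raise ValueError(f"duplicate marker id {dup!r}")
        marker_ids = list(df.columns)
        line_ids = list(df.index.astype(str))
        calls = np.array([[_parse_call(v) for v in row]
                          for row in df.to_numpy()])
    sub = None
    if subfamily is not None:
        sub = subfamily.reindex(line_ids).to_numpy()
    return GenotypeMatrix(list(line_ids), marker_ids, calls.astype(float), sub)


def write_map(gmap: GeneticMap, path: str | Path, meta: dict | None = None) -> None:
    _write_with_header(gmap.table, Path(path), meta, ",", index=False)


def read_map(path: str | Path) -> GeneticMap:
    return GeneticMap(pd.read_csv(path, comment="#"))


def write_table(df: pd.DataFrame, path: str | Path, meta: dict | None = None,
                sep: str = ",") -> None:
    _write_with_header(df, Path(path), meta, sep, index=False)


def read_table(path: str | Path, sep: str = ",") -> pd.DataFrame:
    return pd.read_csv(path, comment="#", sep=sep)


def write_yaml(obj: dict, path: str | Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        yaml.safe_dump(obj, fh, sort_keys=True)


def read_yaml(path: str | Path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)


def write_json(obj: Any, path: str | Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)

    def default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        return str(o)

    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, default=default)
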