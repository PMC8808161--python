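"""Readers and writers for the plain-text formats used throughout the package.

Counts are genes x samples TSV (first column ``gene_id``, one column per
sample). Metadata is one row per sample. Gene sets use the standard GMT
layout: ``name<TAB>description<TAB>gene1<TAB>gene2...``.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

__all__ = [
    "read_counts",
    "write_counts",
    "read_metadata",
    "write_metadata",
    "read_gmt",
    "write_gmt",
    "read_json",
    "write_json",
]

METADATA_COLUMNS = [
    "sample_id",
    "cohort",
    "sofa24",
    "sofa72",
    "qsofa",
    "died_in_hospital",
    "survival_time_days",
    "event",
    "blood_culture_positive",
    "age",
    "sex",
    "endotype",
]

COHORTS = ("ER_discovery", "ER_validation", "ICU", "healthy")


class DataFormatError(ValueError):
    """Raised when an input file violates the expected layout."""


def read_counts(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", index_col=0)
    except OSError as exc:  # pragma: no cover - passthrough with context
        raise DataFormatError(f"cannot read counts from {path}: {exc}") from exc
    if df.index.name is None or df.empty:
        raise DataFormatError(f"{path}: expected gene_id index column and sample columns")
    if df.index.duplicated().any():
        raise DataFormatError(f"{path}: duplicate gene ids")
    if df.columns.duplicated().any():
        raise DataFormatError(f"{path}: duplicate sample ids")
    values = df.to_numpy()
    if (values < 0).any() or not (values == values.astype(int)).all():
        raise DataFormatError(f"{path}: counts must be nonnegative integers")
    return df.astype(int)


def write_counts(counts: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    out = counts.copy()
    out.index.name = "gene_id"
    out.to_csv(path, sep="\t")
    return path


def read_metadata(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in METADATA_COLUMNS if c not in df.columns]
    if missing:
        raise DataFormatError(f"{path}: missing metadata columns {missing}")
    if df["sample_id"].duplicated().any():
        raise DataFormatError(f"{path}: duplicate sample ids")
    bad = set(df["cohort"]) - set(COHORTS)
    if bad:
        raise DataFormatError(f"{path}: unknown cohorts {sorted(bad)}")
    df["endotype"] = df["endotype"].fillna("").astype(str)
    return df.set_index("sample_id", drop=False)


def write_metadata(meta: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    meta.to_csv(path, sep="\t", index=False)
    return path


def read_gmt(path: str | Path) -> dict[str, list[str]]:
    path = Path(path)
    sets: dict[str, list[str]] = {}
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise DataFormatError(f"{path}:{lineno}: GMT lines need name, description, >=1 gene")
        name = fields[0]
        if name in sets:
            raise DataFormatError(f"{path}:{lineno}: duplicate gene-set name {name!r}")
        sets[name] = fields[2:]
    return sets


def write_gmt(sets: dict[str, list[str]], path: str | Path, description: str = "sepstrat") -> Path:
    path = Path(path)
    lines = [
        "\t".join([name, description, *genes]) for name, genes in sets.items()
    ]
    path.write_text("\n".join(lines) + "\n")
    return path


def read_json(path: str | Path):
    return json.loads(Path(path).read_text())


def write_json(obj, path: str | Path) -> Path:
    path = Path(path)
    path.write_text(json.dumps(obj, indent=2, sort_keys=True, default=_jsonable) + "\n")
    return path


def _jsonable(obj):
    import numpy as np

    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")
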