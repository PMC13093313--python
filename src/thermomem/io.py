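"""TSV / GMT readers and writers with validation.

Canonical table dialect: UTF-8, tab-separated, '.' decimal, no quoting.
"""

from __future__ import annotations

import pathlib
from typing import Mapping

import numpy as np
import pandas as pd

SAMPLE_FACTORS = {"family", "priming", "temperature"}
PRIMING_LEVELS = {"naive", "primed"}
TEMPERATURE_LEVELS = {"control", "stress"}


class ParseError(ValueError):
    pass


class ConsistencyError(ValueError):
    pass


def read_counts(path) -> pd.DataFrame:
    """Read a genes x samples integer count matrix (first column = gene ids)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.duplicated().any():
        dup = df.index[df.index.duplicated()][0]
        raise ParseError(f"duplicated gene id {dup!r} in {path}")
    if df.columns.duplicated().any():
        dup = df.columns[df.columns.duplicated()][0]
        raise ParseError(f"duplicated sample id {dup!r} in {path}")
    vals = df.to_numpy()
    if not np.issubdtype(vals.dtype, np.number):
        bad = df.columns[[not np.issubdtype(t, np.number) for t in df.dtypes]][0]
        raise ParseError(f"non-numeric counts in column {bad!r} of {path}")
    if not np.allclose(vals, np.round(vals)):
        i, j = np.argwhere(~np.isclose(vals, np.round(vals)))[0]
        raise ParseError(f"non-integer count at gene {df.index[i]!r}, sample {df.columns[j]!r}")
    if (vals < 0).any():
        i, j = np.argwhere(vals < 0)[0]
        raise ParseError(f"negative count at gene {df.index[i]!r}, sample {df.columns[j]!r}")
    return df.astype(np.int64)


def read_samples(path) -> pd.DataFrame:
    """Read the per-sample factor table (family, priming, temperature, ...)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.duplicated().any():
        raise ParseError(f"duplicated sample id in {path}")
    missing = SAMPLE_FACTORS - set(df.columns)
    if missing:
        raise ParseError(f"sample table missing column(s) {sorted(missing)} in {path}")
    bad_p = set(df["priming"].unique()) - PRIMING_LEVELS
    if bad_p:
        raise ParseError(f"unknown priming level(s) {sorted(bad_p)} in {path}")
    bad_t = set(df["temperature"].unique()) - TEMPERATURE_LEVELS
    if bad_t:
        raise ParseError(f"unknown temperature level(s) {sorted(bad_t)} in {path}")
    return df


def check_consistency(counts: pd.DataFrame, samples: pd.DataFrame) -> None:
    extra = set(counts.columns) - set(samples.index)
    if extra:
        raise ConsistencyError(f"samples in counts but not in sample table: {sorted(extra)[:5]}")


def read_annotations(path, dialect: str = "tsv") -> dict:
    """Read a gene -> class map (TSV: gene_id<TAB>class) or a GMT term-set file.

    Returns {gene: class} for dialect "tsv" and {term: set(genes)} for "gmt".
    """
    path = pathlib.Path(path)
    if dialect == "tsv":
        out: dict[str, str] = {}
        with open(path) as fh:
            for ln, line in enumerate(fh, start=1):
                line = line.rstrip("\n")
                if not line or line.startswith("#"):
                    continue
                parts = line.split("\t")
                if len(parts) < 2 or not parts[0] or not parts[1]:
                    raise ParseError(f"malformed annotation line {ln} in {path}: {line!r}")
                out[parts[0]] = parts[1]
        return out
    if dialect == "gmt":
        terms: dict[str, set] = {}
        with open(path) as fh:
            for ln, line in enumerate(fh, start=1):
                line = line.rstrip("\n")
                if not line:
                    continue
                parts = line.split("\t")
                if len(parts) < 3:
                    raise ParseError(f"malformed GMT line {ln} in {path} (need term, desc, genes)")
                terms[parts[0]] = set(g for g in parts[2:] if g)
        return terms
    raise ValueError(f"unknown annotation dialect {dialect!r}")


def read_survival(path) -> pd.DataFrame:
    """Read survival records: individual, time, event plus group columns."""
    df = pd.read_csv(path, sep="\t")
    for col in ("time", "event"):
        if col not in df.columns:
            raise ParseError(f"survival table missing column {col!r} in {path}")
    if (df["time"] <= 0).any():
        row = df.index[df["time"] <= 0][0]
        raise ParseError(f"non-positive survival time at row {row} in {path}")
    if not df["event"].isin([0, 1]).all():
        raise ParseError(f"event indicator must be 0/1 in {path}")
    return df


def write_table(df: pd.DataFrame, path, index_label: str | None = None) -> str:
    pathlib.Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index_label=index_label)
    return str(path)
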