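"""Readers and writers for the pipeline's tabular formats.

Canonical on-disk formats: counts as TSV with genes in rows (gene_id first
column, sample ids in the header), metadata as TSV, survival records as CSV,
gene sets as GMT, ground truth as JSON, configuration as YAML. CSV count
tables are accepted on read by delimiter sniffing.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .cohort import CohortParams, CohortTruth, GeneSpec, Individual, MarkerSpec

log = logging.getLogger("wormage")


class FormatError(ValueError):
    """Malformed input file."""


def _sniff_sep(path) -> str:
    with open(path) as fh:
        first = fh.readline()
    return "\t" if first.count("\t") >= first.count(",") else ","


def read_counts(path) -> pd.DataFrame:
    """Read a gene x sample count table; strict non-negative-integer coercion."""
    path = Path(path)
    df = pd.read_csv(path, sep=_sniff_sep(path), index_col=0)
    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()][0]
        raise FormatError(f"duplicate gene id {dup!r} in {path}")
    if df.columns.has_duplicates:
        dup = df.columns[df.columns.duplicated()][0]
        raise FormatError(f"duplicate sample id {dup!r} in {path}")
    values = df.to_numpy()
    if not np.issubdtype(values.dtype, np.number):
        bad = np.argwhere(~np.vectorize(np.isreal)(values))
        r, c = bad[0]
        raise FormatError(
            f"non-numeric entry {values[r, c]!r} at gene {df.index[r]!r}, "
            f"sample {df.columns[c]!r}"
        )
    frac = np.modf(values.astype(float))[0]
    if np.any(frac != 0):
        r, c = np.argwhere(frac != 0)[0]
        raise FormatError(
            f"non-integer count {values[r, c]!r} at gene {df.index[r]!r}, "
            f"sample {df.columns[c]!r}"
        )
    if np.any(values < 0):
        r, c = np.argwhere(values < 0)[0]
        raise FormatError(
            f"negative count at gene {df.index[r]!r}, sample {df.columns[c]!r}"
        )
    out = df.astype(np.int64)
    out.index.name = "gene_id"
    return out


def write_counts(counts: pd.DataFrame, path) -> None:
    counts.to_csv(path, sep="\t", index_label="gene_id")


META_COLUMNS = ["sample_id", "age_days", "group", "marker", "marker_code", "batch"]


def read_meta(path, counts: pd.DataFrame | None = None) -> pd.DataFrame:
    """Read sample metadata; optionally cross-validate against a count table."""
    path = Path(path)
    meta = pd.read_csv(path, sep=_sniff_sep(path))
    missing = [c for c in META_COLUMNS if c not in meta.columns]
    if missing:
        raise FormatError(f"metadata missing columns {missing} in {path}")
    meta["marker_code"] = meta["marker_code"].astype(int)
    if not set(meta["marker_code"]) <= {-1, 0, 1}:
        raise FormatError("marker_code must be one of -1, 0, +1")
    tc = meta["group"] == "timecourse"
    if not ((meta["marker_code"] == 0) == tc).all():
        raise FormatError("marker_code 0 must coincide with group 'timecourse'")
    if meta["sample_id"].duplicated().any():
        raise FormatError("duplicate sample_id in metadata")
    if counts is not None:
        validate_counts_meta(counts, meta)
    return meta


def validate_counts_meta(counts: pd.DataFrame, meta: pd.DataFrame) -> None:
    missing = set(counts.columns) - set(meta["sample_id"])
    if missing:
        raise FormatError(f"samples missing from metadata: {sorted(missing)[:5]}")
    extra = set(meta["sample_id"]) - set(counts.columns)
    if extra:
        raise FormatError(f"metadata samples absent from counts: {sorted(extra)[:5]}")


def write_meta(meta: pd.DataFrame, path) -> None:
    meta.to_csv(path, sep="\t", index=False)


def read_gmt(path) -> dict:
    """Parse a GMT file into {set name: list of members} preserving order.

    Duplicate members within a set are dropped (logged); blank lines are
    ignored; CRLF and LF files parse identically.
    """
    sets: dict[str, list] = {}
    with open(path, newline=None) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\r\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3 or not fields[2:]:
                raise FormatError(
                    f"{path}:{lineno}: gene set needs name, description, >=1 member"
                )
            name, members = fields[0], [m for m in fields[2:] if m]
            if not members:
                raise FormatError(f"{path}:{lineno}: gene set {name!r} is empty")
            if name in sets:
                raise FormatError(f"{path}:{lineno}: duplicate set name {name!r}")
            deduped = list(dict.fromkeys(members))
            if len(deduped) < len(members):
                log.info("gene set %r: %d duplicate members dropped",
                         name, len(members) - len(deduped))
            sets[name] = deduped
    return sets


def write_gmt(sets: dict, path, descriptions: dict | None = None) -> None:
    with open(path, "w") as fh:
        for name, members in sets.items():
            desc = (descriptions or {}).get(name, "na")
            fh.write("\t".join([name, desc, *members]) + "\n")


SURVIVAL_COLUMNS = ["individual_id", "group", "day", "event"]


def read_survival(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in SURVIVAL_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"survival table missing columns {missing}")
    if not set(df["event"]) <= {"death", "censor"}:
        raise FormatError("event must be 'death' or 'censor'")
    if (df["day"] <= 0).any():
        raise FormatError("survival times must be positive")
    return df


def write_survival(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)


def write_truth(truth: CohortTruth, path) -> None:
    payload = {
        "params": dataclasses.asdict(truth.params) if truth.params else None,
        "individuals": [dataclasses.asdict(i) for i in truth.individuals],
        "genes": [dataclasses.asdict(g) for g in truth.genes],
        "sample_composition": truth.sample_composition,
    }
    with open(path, "w") as fh:
        json.dump(payload, fh)


def read_truth(path) -> CohortTruth:
    with open(path) as fh:
        payload = json.load(fh)
    params = None
    if payload.get("params"):
        p = dict(payload["params"])
        p["markers"] = tuple(MarkerSpec(**m) for m in p["markers"])
        for key in ("archetype_fractions", "timepoints", "amplitude_range",
                    "baseline_range", "dispersion_range"):
            p[key] = tuple(p[key])
        params = CohortParams(**p)
    return CohortTruth(
        individuals=[Individual(**i) for i in payload["individuals"]],
        genes=[GeneSpec(**g) for g in payload["genes"]],
        sample_composition=payload["sample_composition"],
        params=params,
    )


def read_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise FormatError(f"config {path} must be a YAML mapping")
    return cfg


def write_table(df: pd.DataFrame, path, index=True) -> None:
    df.to_csv(path, sep="\t", index=index)


def read_table(path, index_col=0) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=index_col)
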