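"""TSV/JSON readers and writers with provenance headers.

All tables are tab-separated with a header row; provenance (package version,
seed, config hash) is embedded as ``# key: value`` comment lines above the
header and ignored on read.  Trace files carry a 0-based ``cycle`` column
plus one ``ratio_<roi>`` column per ROI (or paired ``f350_<roi>`` /
``f380_<roi>`` columns, from which ratios are computed).
"""

from __future__ import annotations

import hashlib
import json
from importlib.metadata import PackageNotFoundError, version as _pkg_version
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .exceptions import SchemaError
from .fura import FuraTrace
from .hwe import XGenotypeCounts
from .ordinal import validate_cohort

try:
    PACKAGE_VERSION = _pkg_version("neuromir")
except PackageNotFoundError:  # running from a source tree
    PACKAGE_VERSION = "0.1.0"

_COUNT_COLUMNS = ["n_AA", "n_AG", "n_GG", "n_A", "n_G"]


def config_hash(config: dict | None) -> str:
    payload = json.dumps(config or {}, sort_keys=True, default=str)
    return hashlib.sha256(payload.encode()).hexdigest()[:12]


def provenance(seed: int | None = None, config: dict | None = None,
               **extra) -> dict:
    prov = {"package": "neuromir", "version": PACKAGE_VERSION,
            "config_hash": config_hash(config)}
    if seed is not None:
        prov["seed"] = seed
    prov.update(extra)
    return prov


def _header_lines(prov: dict | None) -> str:
    if not prov:
        return ""
    return "".join(f"# {k}: {v}\n" for k, v in prov.items())


def write_table(df: pd.DataFrame, path, prov: dict | None = None) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(_header_lines(prov))
        df.to_csv(fh, sep="\t", index=False)


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")


def write_cohort(cohort: pd.DataFrame, path, prov: dict | None = None) -> None:
    out = cohort.copy()
    out["diagnosis"] = out["diagnosis"].astype(str)
    write_table(out, path, prov)


def read_cohort(path) -> pd.DataFrame:
    df = read_table(path)
    if df.empty:
        raise SchemaError(f"{path}: empty cohort file")
    return validate_cohort(df)


def write_traces(traces: list[FuraTrace], path, prov: dict | None = None) -> None:
    if not traces:
        raise SchemaError("no traces to write")
    n = len(traces[0])
    data = {"cycle": np.asarray(traces[0].cycle)}
    for tr in traces:
        if len(tr) != n:
            raise SchemaError("traces differ in length")
        data[f"ratio_{tr.roi_id}"] = tr.ratio
    write_table(pd.DataFrame(data), path, prov)


def read_traces(path) -> list[FuraTrace]:
    df = read_table(path)
    if "cycle" not in df.columns:
        raise SchemaError(f"{path}: trace file needs a 'cycle' column")
    cycle = df["cycle"].to_numpy(dtype=int)
    traces: list[FuraTrace] = []
    ratio_cols = [c for c in df.columns if c.startswith("ratio_")]
    f350_cols = [c for c in df.columns if c.startswith("f350_")]
    for col in ratio_cols:
        traces.append(FuraTrace(cycle=cycle, ratio=df[col].to_numpy(float),
                                roi_id=col[len("ratio_"):]))
    for col in f350_cols:
        roi = col[len("f350_"):]
        partner = f"f380_{roi}"
        if partner not in df.columns:
            raise SchemaError(f"{path}: {col} has no matching {partner}")
        traces.append(FuraTrace.from_channels(cycle, df[col].to_numpy(float),
                                              df[partner].to_numpy(float),
                                              roi_id=roi))
    if not traces:
        raise SchemaError(f"{path}: no ratio_* or f350_*/f380_* columns found")
    return traces


def write_genotype_counts(counts: XGenotypeCounts, path,
                          prov: dict | None = None) -> None:
    row = {c: getattr(counts, c) for c in _COUNT_COLUMNS}
    write_table(pd.DataFrame([row]), path, prov)


def read_genotype_counts(path) -> XGenotypeCounts:
    """Read either a five-column count TSV or a per-subject sex+genotype table."""
    df = read_table(path)
    if df.empty:
        raise SchemaError(f"{path}: empty genotype file")
    if set(_COUNT_COLUMNS).issubset(df.columns):
        if len(df) != 1:
            raise SchemaError(f"{path}: count tables must have exactly one row")
        row = df.iloc[0]
        return XGenotypeCounts(**{c: int(row[c]) for c in _COUNT_COLUMNS})
    if {"sex", "genotype"}.issubset(df.columns):
        tally = dict.fromkeys(_COUNT_COLUMNS, 0)
        for i, rec in df.iterrows():
            sex = str(rec["sex"]).upper()[:1]
            g = "".join(sorted(str(rec["genotype"]).upper()))
            if sex == "F" and g in ("AA", "AG", "GG"):
                tally[f"n_{g}"] += 1
            elif sex == "M" and g in ("A", "G"):
                tally[f"n_{g}"] += 1
            else:
                raise SchemaError(
                    f"{path}: row {i}: cannot interpret sex={rec['sex']!r} "
                    f"genotype={rec['genotype']!r}")
        return XGenotypeCounts(**tally)
    raise SchemaError(
        f"{path}: expected columns {_COUNT_COLUMNS} or ['sex', 'genotype']")


def write_json(payload: dict, path, prov: dict | None = None) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if prov:
        payload = {**payload, "provenance": prov}
    path.write_text(json.dumps(payload, indent=2, default=_json_default) + "\n")


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")


def load_config_file(path) -> dict:
    """Load a YAML (or JSON, a YAML subset) key-value configuration file."""
    text = Path(path).read_text()
    data = yaml.safe_load(text)
    if data is None:
        return {}
    if not isinstance(data, dict):
        raise SchemaError(f"{path}: config must be a key-value mapping")
    return data
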