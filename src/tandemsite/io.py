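"""CSV schemas, config handling, seeded RNG management and reporting.

Concentrations are stored in molar and times in minutes everywhere;
equilibrium constants appear in reports as negative base-10 logarithms
(pK).  Every report embeds the seed and a hash of the configuration that
produced it.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from tandemsite.errors import ValidationError
from tandemsite.fitting import GroupSummary

logger = logging.getLogger("tandemsite")

TIMECOURSE_COLUMNS = ("experiment_id", "conc_tracer_M", "conc_competitor_M",
                      "time_min", "bound_pct")
SATURATION_COLUMNS = ("experiment_id", "conc_tracer_M", "total_binding",
                      "nonspecific_binding")
_CONC_COLUMNS = ("conc_tracer_M", "conc_competitor_M")


def read_binding_csv(path) -> pd.DataFrame:
    """Read and validate a time-course or saturation-curve CSV.

    The schema is detected from the header; all numeric cells are
    checked, and malformed or negative-concentration rows are reported
    with their line numbers.  The detected kind is stored in
    ``df.attrs["kind"]`` (``"timecourse"`` or ``"saturation"``).
    """
    path = Path(path)
    if not path.exists():
        raise ValidationError(f"no such file: {path}")
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        raise ValidationError(f"{path}: file is empty") from None
    if df.empty:
        raise ValidationError(f"{path}: no data rows")

    cols = set(df.columns)
    if set(TIMECOURSE_COLUMNS) <= cols:
        kind, required = "timecourse", TIMECOURSE_COLUMNS
    elif set(SATURATION_COLUMNS) <= cols:
        kind, required = "saturation", SATURATION_COLUMNS
    else:
        raise ValidationError(
            f"{path}: header matches neither the time-course schema "
            f"{TIMECOURSE_COLUMNS} nor the saturation schema "
            f"{SATURATION_COLUMNS}")

    for col in required:
        if col == "experiment_id":
            continue
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[vals.isna()]
        if len(bad):
            # +2: header line and 1-based numbering
            raise ValidationError(
                f"{path}: non-numeric value in column '{col}' at line(s) "
                f"{[int(i) + 2 for i in bad[:5]]}")
        df[col] = vals
    for col in _CONC_COLUMNS:
        if col in df.columns:
            bad = df.index[df[col] < 0]
            if len(bad):
                raise ValidationError(
                    f"{path}: negative concentration in column '{col}' at "
                    f"line(s) {[int(i) + 2 for i in bad[:5]]}")
    df.attrs["kind"] = kind
    return df


def write_binding_csv(df: pd.DataFrame, path) -> None:
    """Write a binding table; round-trips through :func:`read_binding_csv`."""
    df.to_csv(path, index=False, float_format="%.10g")


def load_config(path) -> dict:
    """Load a structured (YAML) config file."""
    path = Path(path)
    if not path.exists():
        raise ValidationError(f"no such config file: {path}")
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValidationError(f"{path}: config must be a mapping")
    return cfg


def config_hash(config: dict | None) -> str:
    """Stable short hash of a configuration mapping."""
    blob = json.dumps(config or {}, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def rng_from_seed(seed: int) -> np.random.Generator:
    """Seeded generator; all randomized operations derive from one seed."""
    return np.random.default_rng(np.random.SeedSequence(int(seed)))


def _summary_records(summary: GroupSummary) -> list[dict]:
    sig = {(r["condition"], r["parameter"]): bool(r["significant"])
           for _, r in summary.comparisons.iterrows()}
    records = []
    for cond, row in summary.table.iterrows():
        rec: dict = {"condition": cond}
        for col, val in row.items():
            rec[col] = None if pd.isna(val) else float(val)
        for param in ("pK_D", "k_off", "pK_A"):
            if f"{param}_mean" in rec:
                rec[f"{param}_significant"] = sig.get((cond, param), False)
        records.append(rec)
    return records


def report(summary: GroupSummary, out_base, formats=("csv", "json"),
           seed: int | None = None, config: dict | None = None) -> dict:
    """Write the group summary as CSV and/or JSON report files.

    The tables mirror the layout of the published parameter tables:
    per-condition means +/- SEM of pK_D, k_off and pK_A with significance
    flags from the Dunnett comparison against the reference condition.
    CSV and JSON carry identical numbers; both embed the seed and config
    hash.  Returns a mapping format -> written path.
    """
    out_base = Path(out_base)
    records = _summary_records(summary)
    meta = {"reference": summary.reference, "seed": seed,
            "config_hash": config_hash(config)}
    written = {}
    try:
        if "csv" in formats:
            path = out_base.with_suffix(".csv")
            df = pd.DataFrame(records)
            for key, val in meta.items():
                df[key] = val
            df.to_csv(path, index=False, float_format="%.10g")
            written["csv"] = path
        if "json" in formats:
            path = out_base.with_suffix(".json")
            with open(path, "w") as fh:
                json.dump({"meta": meta, "conditions": records}, fh, indent=2)
            written["json"] = path
    except OSError as exc:
        raise ValidationError(f"cannot write report: {exc}") from exc
    return written
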