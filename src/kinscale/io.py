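"""Delimited-text readers and writers for the pipeline's table schemas.

Two table layouts are shared across stages:

* **kinetics table** — one row per enzyme:
  ``enzyme_id,k_cat,K_M[,sd_kcat,sd_km,source,gh_family,mode,has_cbm,is_wildtype,parent_id]``
* **rate table** (long format) — one row per replicate measurement:
  ``enzyme_id,E0,S0,replicate,rate``

Files are UTF-8 with a header row, ``.`` decimal and comma separation by
default (tab via ``dialect="tsv"``). Numbers are serialized with
``repr``-level precision so that write→read round-trips are exact.
"""

from __future__ import annotations

import json
import platform
from dataclasses import asdict, is_dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .datamodel import EnzymeRecord, KineticParams, MMDataset
from .errors import SchemaError, ValidationError

_KINETICS_MANDATORY = ("enzyme_id", "k_cat", "K_M")
_RATE_MANDATORY = ("enzyme_id", "E0", "S0", "replicate", "rate")


def _sep(dialect: str) -> str:
    if dialect in ("csv", ","):
        return ","
    if dialect in ("tsv", "\t"):
        return "\t"
    raise SchemaError(f"unknown dialect {dialect!r}; use 'csv' or 'tsv'")


def _read_frame(path, dialect: str, mandatory: Sequence[str]) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    # round_trip parsing: written repr-precision decimals must reparse
    # to the identical double
    df = pd.read_csv(path, sep=_sep(dialect), float_precision="round_trip")
    missing = [c for c in mandatory if c not in df.columns]
    if missing:
        raise SchemaError(f"{path.name}: missing mandatory column(s) {missing}")
    return df


def _opt(row: pd.Series, col: str, default):
    if col not in row.index or pd.isna(row[col]):
        return default
    return row[col]


def read_kinetics_table(
    path, dialect: str = "csv"
) -> list[tuple[EnzymeRecord, KineticParams]]:
    """Read a per-enzyme kinetic-parameter table.

    Annotation columns are optional and default to ``unknown``; row order
    is preserved. Raises :class:`SchemaError` for missing mandatory
    columns and :class:`ValidationError` for non-positive parameters or
    duplicate enzyme ids, naming the offending row.
    """
    df = _read_frame(path, dialect, _KINETICS_MANDATORY)
    dup = df["enzyme_id"][df["enzyme_id"].duplicated()]
    if not dup.empty:
        raise ValidationError(f"duplicate enzyme_id(s): {sorted(set(dup))}")
    out = []
    for i, row in df.iterrows():
        if not (row["k_cat"] > 0 and row["K_M"] > 0):
            raise ValidationError(
                f"row {i} (enzyme {row['enzyme_id']}): k_cat and K_M must be > 0"
            )
        has_cbm = _opt(row, "has_cbm", "unknown")
        if isinstance(has_cbm, str) and has_cbm in ("True", "False"):
            has_cbm = has_cbm == "True"
        record = EnzymeRecord(
            enzyme_id=str(row["enzyme_id"]),
            gh_family=_opt(row, "gh_family", "unknown"),
            mode=str(_opt(row, "mode", "unknown")),
            has_cbm=has_cbm,
            is_wildtype=bool(_opt(row, "is_wildtype", True)),
            parent_id=_opt(row, "parent_id", None),
        )
        flags = _opt(row, "flags", "")
        params = KineticParams(
            enzyme_id=str(row["enzyme_id"]),
            k_cat=float(row["k_cat"]),
            K_M=float(row["K_M"]),
            sd_kcat=float(_opt(row, "sd_kcat", 0.0)),
            sd_km=float(_opt(row, "sd_km", 0.0)),
            source=str(_opt(row, "source", "table")),
            flags=tuple(f for f in str(flags).split(";") if f),
        )
        out.append((record, params))
    return out


def write_kinetics_table(
    entries: Iterable[tuple[EnzymeRecord, KineticParams]], path, dialect: str = "csv"
) -> None:
    rows = []
    for rec, par in entries:
        rows.append(
            {
                "enzyme_id": rec.enzyme_id,
                "k_cat": par.k_cat,
                "K_M": par.K_M,
                "sd_kcat": par.sd_kcat,
                "sd_km": par.sd_km,
                "source": par.source,
                "flags": ";".join(par.flags),
                "gh_family": rec.gh_family,
                "mode": rec.mode,
                "has_cbm": rec.has_cbm,
                "is_wildtype": rec.is_wildtype,
                "parent_id": rec.parent_id if rec.parent_id is not None else "",
            }
        )
    cols = [
        "enzyme_id", "k_cat", "K_M", "sd_kcat", "sd_km", "source", "flags",
        "gh_family", "mode", "has_cbm", "is_wildtype", "parent_id",
    ]
    pd.DataFrame(rows, columns=cols).to_csv(path, sep=_sep(dialect), index=False)


def read_rate_table(path, dialect: str = "csv") -> list[MMDataset]:
    """Read a long-format rate table into one :class:`MMDataset` per enzyme.

    Rows are grouped by ``enzyme_id``; within each dataset loads are sorted
    ascending. Dataset invariants (≥3 distinct loads, non-negative rates,
    E0 > 0) are enforced on construction.
    """
    df = _read_frame(path, dialect, _RATE_MANDATORY)
    datasets = []
    for enzyme_id, grp in df.groupby("enzyme_id", sort=False):
        e0 = grp["E0"].unique()
        if len(e0) != 1:
            raise ValidationError(f"{enzyme_id}: enzyme concentration E0 varies within one dataset")
        loads = sorted(grp["S0"].unique())
        rates = [tuple(grp.loc[grp["S0"] == s, "rate"]) for s in loads]
        datasets.append(MMDataset(str(enzyme_id), float(e0[0]), loads, rates))
    return datasets


def write_rate_table(datasets: Iterable[MMDataset], path, dialect: str = "csv") -> None:
    rows = []
    for ds in datasets:
        for s, reps in zip(ds.loads, ds.rates):
            for j, v in enumerate(reps, start=1):
                rows.append(
                    {"enzyme_id": ds.enzyme_id, "E0": ds.enzyme_conc, "S0": s,
                     "replicate": j, "rate": v}
                )
    pd.DataFrame(rows, columns=list(_RATE_MANDATORY)).to_csv(
        path, sep=_sep(dialect), index=False
    )


def _jsonable(obj):
    if is_dataclass(obj) and not isinstance(obj, type):
        return {k: _jsonable(v) for k, v in asdict(obj).items()}
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    return obj


def write_run_summary(path, *, config=None, seed=None, inputs=None, extra=None) -> None:
    """Write a machine-readable run summary (JSON).

    Echoes the configuration, seed and package/library versions so a run
    can be reproduced byte-identically from the summary alone.
    """
    import kinscale

    summary = {
        "package": "kinscale",
        "version": kinscale.__version__,
        "python": platform.python_version(),
        "numpy": np.__version__,
        "pandas": pd.__version__,
        "seed": seed,
        "config": _jsonable(config),
        "inputs": _jsonable(inputs),
    }
    if extra:
        summary.update(_jsonable(extra))
    Path(path).write_text(json.dumps(summary, indent=2, sort_keys=True) + "\n")


def write_report(results, path, dialect: str = "csv") -> None:
    """Serialize a stage output to delimited text.

    Dispatches on the result type: kinetics entries, rate datasets,
    a :class:`~kinscale.lfer.ScalingFit`, a
    :class:`~kinscale.calibration.CalibrationFit`, or a DataFrame. An
    empty list yields a header-only kinetics table.
    """
    from .calibration import CalibrationFit
    from .lfer import ScalingFit

    if isinstance(results, pd.DataFrame):
        results.to_csv(path, sep=_sep(dialect), index=False)
        return
    if isinstance(results, ScalingFit):
        _write_scaling_fit(results, path, dialect)
        return
    if isinstance(results, CalibrationFit):
        pd.DataFrame([_jsonable(results)]).to_csv(path, sep=_sep(dialect), index=False)
        return
    results = list(results)
    if not results:
        pd.DataFrame(columns=list(_KINETICS_MANDATORY)).to_csv(
            path, sep=_sep(dialect), index=False
        )
        return
    first = results[0]
    if isinstance(first, MMDataset):
        write_rate_table(results, path, dialect)
    elif isinstance(first, tuple) and isinstance(first[0], EnzymeRecord):
        write_kinetics_table(results, path, dialect)
    elif isinstance(first, KineticParams):
        write_kinetics_table([(EnzymeRecord(p.enzyme_id), p) for p in results], path, dialect)
    else:
        raise TypeError(f"do not know how to serialize {type(first).__name__}")


def _write_scaling_fit(fit, path, dialect: str) -> None:
    # Scalar summary first, then the banded grid as additional columns.
    head = pd.DataFrame(
        [{
            "slope_a": fit.slope_a,
            "intercept_lnA": fit.intercept_lnA,
            "phi": fit.phi,
            "se_slope": fit.se_slope,
            "se_intercept": fit.se_intercept,
            "r_squared": fit.r_squared,
            "n_used": fit.n_used,
            "n_outliers": fit.n_outliers,
            "outlier_ids": ";".join(fit.outlier_ids),
        }]
    )
    path = Path(path)
    head.to_csv(path, sep=_sep(dialect), index=False)
    bands = pd.DataFrame(
        {
            "x": fit.bands.x,
            "fit": fit.bands.fit,
            "conf_lo": fit.bands.conf_lo,
            "conf_hi": fit.bands.conf_hi,
            "pred_lo": fit.bands.pred_lo,
            "pred_hi": fit.bands.pred_hi,
        }
    )
    bands.to_csv(path.with_suffix(".bands" + path.suffix), sep=_sep(dialect), index=False)
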