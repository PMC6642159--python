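"""Readers and writers for the tidy CSV / JSON / YAML interchange formats.

Schemas
-------
expression CSV:       label, zt, replicate_id, value
pk CSV:               sex, feeding, zt_dose, t_h, mouse_id, matrix, concentration
bioluminescence CSV:  series_id, t_h, counts

Fits are written as JSON records; PBPK parameters and estimation configs
as YAML.  Readers validate headers and values and raise errors naming
the offending row.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .estimation import PKGroupDataset
from .pbpk import MATRICES, CircadianRate, PBPKParameters
from .rhythmometry import CircadianComponent, TimedReplicates

__all__ = [
    "read_expression_csv",
    "write_expression_csv",
    "read_pk_csv",
    "write_pk_csv",
    "read_biolum_csv",
    "write_biolum_csv",
    "write_json",
    "params_to_yaml",
    "params_from_yaml",
]


def _read_csv(path, required: set[str]) -> pd.DataFrame:
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        raise ValueError(f"{path}: file is empty") from None
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing column(s) {sorted(missing)}")
    if df.empty:
        raise ValueError(f"{path}: no data rows")
    return df


def _numeric(df: pd.DataFrame, col: str, path) -> pd.Series:
    vals = pd.to_numeric(df[col], errors="coerce")
    bad = vals.isna() & df[col].notna()
    if bad.any():
        row = int(df.index[bad][0]) + 2  # header is line 1
        raise ValueError(f"{path}: non-numeric {col!r} at line {row}")
    if vals.isna().any():
        row = int(df.index[vals.isna()][0]) + 2
        raise ValueError(f"{path}: missing {col!r} at line {row}")
    return vals.astype(float)


def read_expression_csv(path) -> list[TimedReplicates]:
    """Read grouped circadian expression data, one TimedReplicates per label."""
    df = _read_csv(path, {"label", "zt", "replicate_id", "value"})
    zt = _numeric(df, "zt", path)
    _numeric(df, "value", path)
    bad = ~((zt >= 0) & (zt < 24))
    if bad.any():
        row = int(df.index[bad][0]) + 2
        raise ValueError(f"{path}: zt outside [0, 24) at line {row}")
    out = []
    for label, g in df.groupby("label", sort=False):
        zts = sorted(g["zt"].astype(float).unique())
        values = [list(g.loc[g["zt"] == z, "value"].astype(float)) for z in zts]
        out.append(TimedReplicates(zt_hours=zts, values_per_zt=values, label=str(label)))
    return out


def write_expression_csv(path, data: list[TimedReplicates]) -> None:
    rows = []
    for tr in data:
        for zt, vals in zip(tr.zt_hours, tr.values_per_zt):
            for j, v in enumerate(vals):
                rows.append({"label": tr.label, "zt": zt, "replicate_id": j, "value": v})
    pd.DataFrame(rows).to_csv(path, index=False)


def read_pk_csv(path) -> list[PKGroupDataset]:
    """Read talinolol PK data, one PKGroupDataset per (sex, feeding, zt_dose)."""
    df = _read_csv(path, {"sex", "feeding", "zt_dose", "t_h", "mouse_id", "matrix", "concentration"})
    _numeric(df, "t_h", path)
    _numeric(df, "zt_dose", path)
    conc = _numeric(df, "concentration", path)
    if (conc < 0).any():
        row = int(df.index[conc < 0][0]) + 2
        raise ValueError(f"{path}: negative concentration at line {row}")
    bad_m = ~df["matrix"].isin(MATRICES)
    if bad_m.any():
        row = int(df.index[bad_m][0]) + 2
        raise ValueError(f"{path}: unknown matrix at line {row} (expected {MATRICES})")
    out = []
    for (sex, feeding, zt_dose), g in df.groupby(["sex", "feeding", "zt_dose"], sort=False):
        times = np.sort(g["t_h"].astype(float).unique())
        concentrations: dict[str, list[np.ndarray]] = {m: [] for m in MATRICES}
        mouse_ids: list[list[str]] = []
        for t in times:
            gt = g[g["t_h"] == t]
            mice = list(dict.fromkeys(gt["mouse_id"]))
            mouse_ids.append([str(m) for m in mice])
            for m in MATRICES:
                vals = []
                for mouse in mice:
                    sel = gt[(gt["mouse_id"] == mouse) & (gt["matrix"] == m)]
                    if len(sel) != 1:
                        raise ValueError(
                            f"{path}: expected exactly one {m!r} value for mouse "
                            f"{mouse!r} at t={t:g} (group {sex}/{feeding}/ZT{zt_dose:g})"
                        )
                    vals.append(float(sel["concentration"].iloc[0]))
                concentrations[m].append(np.asarray(vals))
        out.append(
            PKGroupDataset(
                sex=str(sex), feeding=str(feeding), zt_dose=float(zt_dose),
                times=times, concentrations=concentrations, mouse_ids=mouse_ids,
            )
        )
    return out


def write_pk_csv(path, datasets: list[PKGroupDataset]) -> None:
    pd.concat([ds.to_dataframe() for ds in datasets], ignore_index=True).to_csv(
        path, index=False
    )


def read_biolum_csv(path) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Read bioluminescence traces keyed by series_id -> (t_h, counts)."""
    df = _read_csv(path, {"series_id", "t_h", "counts"})
    _numeric(df, "t_h", path)
    _numeric(df, "counts", path)
    out = {}
    for sid, g in df.groupby("series_id", sort=False):
        g = g.sort_values("t_h")
        out[str(sid)] = (g["t_h"].to_numpy(float), g["counts"].to_numpy(float))
    return out


def write_biolum_csv(path, series: dict[str, tuple[np.ndarray, np.ndarray]]) -> None:
    rows = []
    for sid, (t, y) in series.items():
        rows.append(pd.DataFrame({"series_id": sid, "t_h": t, "counts": y}))
    pd.concat(rows, ignore_index=True).to_csv(path, index=False)


def write_json(path, obj) -> None:
    def default(o):
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.floating, np.integer)):
            return o.item()
        if hasattr(o, "to_dict"):
            return o.to_dict()
        raise TypeError(f"not JSON-serialisable: {type(o)}")

    Path(path).write_text(json.dumps(obj, indent=2, default=default) + "\n")


def params_to_yaml(path, params: PBPKParameters) -> None:
    Path(path).write_text(yaml.safe_dump(params.to_dict(), sort_keys=False))


def _rate_from_dict(d: dict) -> CircadianRate:
    comps = tuple(
        CircadianComponent(c["period_h"], c["rel_amplitude"], c["acrophase_h"])
        for c in d.get("components", [])
    )
    return CircadianRate(mean_rate=d["mean_rate_per_h"], components=comps)


def params_from_yaml(path) -> PBPKParameters:
    d = yaml.safe_load(Path(path).read_text())
    return PBPKParameters(
        ka=d["ka_per_h"], k_ib=d["k_ib_per_h"],
        k_pl_il=d.get("k_pl_il_per_h", 0.0),
        k_pl_li=d["k_pl_li_per_h"], k_li_pl=d["k_li_pl_per_h"],
        pgp_ileum=_rate_from_dict(d["pgp_ileum"]),
        pgp_liver=_rate_from_dict(d["pgp_liver"]),
        renal=_rate_from_dict(d["renal"]),
        intestinal=_rate_from_dict(d["intestinal"]),
        body_weight_g=d["body_weight_g"], V_plasma_mL=d["V_plasma_mL"],
        W_ileum_g=d["W_ileum_g"], W_liver_g=d["W_liver_g"],
    )
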