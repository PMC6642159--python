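"""Non-compartmental summaries of destructive-sampling PK data.

With destructive sampling no animal yields a full concentration-time
profile, so profiles are assembled combinatorially: every way of picking
one mouse per time point gives a candidate curve.  All combinations are
enumerated when their number is below a cap (4 mice at each of 6 time
points gives 4^6 = 4096 curves); above the cap a seeded random subset is
drawn.  AUC(0-8h) (trapezoidal, with an optional concentration-zero
anchor at t=0 for oral dosing) and Cmax are computed per curve and
summarised by mean and SD.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .estimation import PKGroupDataset

__all__ = ["PKSummary", "trapezoid_auc", "combinatorial_curves", "auc_cmax_stats"]


@dataclass
class PKSummary:
    """Combinatorial AUC/Cmax summary for one group x matrix."""

    group: str
    matrix: str
    n_curves: int
    auc_mean: float
    auc_sd: float
    cmax_mean: float
    cmax_sd: float
    per_curve: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if self.n_curves < 1:
            raise ValueError("n_curves must be >= 1")
        if self.auc_sd < 0 or self.cmax_sd < 0:
            raise ValueError("standard deviations must be >= 0")

    def to_dict(self) -> dict:
        return {
            "group": self.group, "matrix": self.matrix, "n_curves": self.n_curves,
            "auc_0_8_mean": self.auc_mean, "auc_0_8_sd": self.auc_sd,
            "cmax_mean": self.cmax_mean, "cmax_sd": self.cmax_sd,
        }


def trapezoid_auc(times, conc, anchor_zero: bool = True, window_end: float = 8.0) -> float:
    """Trapezoidal AUC over [0, ``window_end``] hours.

    ``anchor_zero`` prepends a (t=0, C=0) point when the first sample is
    later than t=0, as appropriate after an oral dose (the first sample
    in the talinolol study is at 30 min).
    """
    t = np.asarray(times, dtype=float)
    c = np.asarray(conc, dtype=float)
    if t.ndim != 1 or t.shape != c.shape:
        raise ValueError("times and conc must be 1-d arrays of equal length")
    if np.any(np.diff(t) <= 0):
        raise ValueError("times must be strictly increasing")
    if t[0] < 0 or t[-1] > window_end + 1e-12:
        raise ValueError(f"times must lie within [0, {window_end}]")
    if anchor_zero and t[0] > 0:
        t = np.concatenate(([0.0], t))
        c = np.concatenate(([0.0], c))
    if t.size < 2:
        raise ValueError("need >= 2 points for a trapezoidal AUC")
    return float(np.trapezoid(c, t))


def combinatorial_curves(
    group: PKGroupDataset, matrix: str, cap: int = 50_000, seed: int | None = 0
) -> np.ndarray:
    """All (or a capped random subset of) one-mouse-per-time-point curves.

    Returns an ``(n_curves, n_times)`` concentration array aligned with
    ``group.times``.  Exhaustive enumeration when the number of
    combinations is at most ``cap``; otherwise ``cap`` seeded draws.
    """
    if matrix not in group.concentrations:
        raise KeyError(f"unknown matrix {matrix!r}")
    per_time = group.concentrations[matrix]
    counts = [len(v) for v in per_time]
    if min(counts) < 1:
        raise ValueError("empty time point")
    n_comb = int(np.prod(counts, dtype=np.int64))
    if n_comb <= cap:
        idx = np.array(list(itertools.product(*(range(n) for n in counts))))
    else:
        rng = np.random.default_rng(seed)
        idx = np.column_stack([rng.integers(n, size=cap) for n in counts])
    curves = np.empty((idx.shape[0], len(per_time)))
    for j, vals in enumerate(per_time):
        curves[:, j] = np.asarray(vals)[idx[:, j]]
    return curves


def auc_cmax_stats(
    group: PKGroupDataset,
    matrix: str,
    cap: int = 50_000,
    seed: int | None = 0,
    anchor_zero: bool = True,
    keep_per_curve: bool = False,
) -> PKSummary:
    """Mean and SD of AUC(0-8h) and Cmax over the combinatorial curve set.

    Cmax is taken over the observed time points only (no interpolation).
    """
    curves = combinatorial_curves(group, matrix, cap=cap, seed=seed)
    t = group.times
    if anchor_zero and t[0] > 0:
        tt = np.concatenate(([0.0], t))
        cc = np.concatenate((np.zeros((curves.shape[0], 1)), curves), axis=1)
    else:
        tt, cc = t, curves
    aucs = np.trapezoid(cc, tt, axis=1)
    cmaxs = curves.max(axis=1)
    n = curves.shape[0]
    per_curve = (
        pd.DataFrame({"auc_0_8": aucs, "cmax": cmaxs}) if keep_per_curve else None
    )
    return PKSummary(
        group=f"{group.sex}_{group.feeding}_zt{group.zt_dose:g}",
        matrix=matrix,
        n_curves=n,
        auc_mean=float(aucs.mean()),
        auc_sd=float(aucs.std(ddof=1)) if n > 1 else 0.0,
        cmax_mean=float(cmaxs.mean()),
        cmax_sd=float(cmaxs.std(ddof=1)) if n > 1 else 0.0,
        per_curve=per_curve,
    )
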