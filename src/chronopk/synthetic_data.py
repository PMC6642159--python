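"""Synthetic data generators emulating the three mouse experiment designs.

The circadian P-gp study rests on three data types, none of which is
publicly deposited, so the package generates statistically faithful
stand-ins for every pipeline stage:

* destructive-sampling expression data (P-gp protein, Abcb1a/b mRNA):
  replicate animals at each Zeitgeber time, values following a cosinor
  mean curve with lognormal inter-animal scatter;
* destructive-sampling talinolol PK: virtual mice with lognormally
  perturbed PBPK rate parameters (shared across their plasma, ileum and
  liver values, since one animal yields all three matrices at its
  sacrifice time), simulated forward and read out with proportional
  assay noise and a lower limit of determination of 0.05 ug/mL;
* dense ex-vivo bioluminescence traces: damped cosine on a baseline with
  a linear trend and additive Gaussian noise, 10-min sampling for days.

Default noise magnitudes: 20% CV expression scatter, 20% CV inter-animal
parameter variability, 7.5% proportional assay CV (HPLC reproducibility
in the 2-10% range).  All generators are deterministic under a fixed
seed with independent substreams per animal.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .estimation import PKGroupDataset
from .pbpk import MATRICES, DoseEvent, PBPKParameters, simulate
from .rhythmometry import CosinorResults, DampedCosineResults, TimedReplicates

__all__ = [
    "ExperimentDesign",
    "NoiseModel",
    "gen_expression",
    "gen_pk_experiment",
    "gen_bioluminescence",
]

RATE_PATHS = ("ka", "k_ib", "k_pl_li", "k_li_pl")
MESOR_FIELDS = ("pgp_ileum", "pgp_liver", "renal", "intestinal")


@dataclass
class ExperimentDesign:
    """Sampling design shared by the three experiment types."""

    zts: tuple[float, ...] = (0.0, 3.0, 6.0, 9.0, 12.0, 15.0, 18.0, 21.0)
    n_per_zt: int = 5
    pk_times: tuple[float, ...] = (0.5, 1.0, 2.0, 4.0, 6.0, 8.0)
    n_mice_per_time: int = 5
    dose_zts: tuple[float, ...] = (3.0, 15.0)
    biolum_duration_h: float = 144.0
    biolum_dt_min: float = 10.0

    def __post_init__(self) -> None:
        if self.n_per_zt < 1 or self.n_mice_per_time < 1:
            raise ValueError("animal counts must be positive")
        if any(not (0 <= z < 24) for z in self.zts):
            raise ValueError("sampling ZTs must lie in [0, 24)")
        if self.biolum_duration_h <= 0 or self.biolum_dt_min <= 0:
            raise ValueError("bioluminescence design must be positive")

    @property
    def biolum_n_points(self) -> int:
        return int(round(self.biolum_duration_h * 60.0 / self.biolum_dt_min))


@dataclass
class NoiseModel:
    """Noise magnitudes for the generators (all coefficients of variation)."""

    expression_cv: float = 0.20
    pk_inter_animal_cv: float = 0.20
    pk_assay_cv: float = 0.075
    lod_ug_per_ml: float = 0.05
    biolum_sd: float = 0.05
    biolum_trend_slope: float = 0.0

    def __post_init__(self) -> None:
        for name in ("expression_cv", "pk_inter_animal_cv", "pk_assay_cv"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


def _lognormal_multiplier(rng: np.random.Generator, cv: float, size=None):
    """Unit-mean lognormal multiplier with the given coefficient of variation."""
    if cv == 0:
        return np.ones(size) if size is not None else 1.0
    sigma2 = np.log(1.0 + cv**2)
    return rng.lognormal(mean=-sigma2 / 2.0, sigma=np.sqrt(sigma2), size=size)


def gen_expression(
    design: ExperimentDesign,
    fit: CosinorResults,
    noise: NoiseModel = NoiseModel(),
    seed: int | None = 0,
    label: str = "synthetic",
) -> TimedReplicates:
    """Destructive-sampling expression data around a cosinor mean curve."""
    rng = np.random.default_rng(seed)
    values = []
    for zt in design.zts:
        mean = float(fit.predict(zt))
        mult = _lognormal_multiplier(rng, noise.expression_cv, size=design.n_per_zt)
        values.append(list(mean * mult))
    return TimedReplicates(zt_hours=list(design.zts), values_per_zt=values, label=label)


def _perturbed(params: PBPKParameters, rng: np.random.Generator, cv: float) -> PBPKParameters:
    """One virtual mouse: independent lognormal multipliers on each rate."""
    from .pbpk import CircadianRate

    p = params
    for path in RATE_PATHS:
        p = p.replace(**{path: getattr(p, path) * float(_lognormal_multiplier(rng, cv))})
    for f in MESOR_FIELDS:
        r: CircadianRate = getattr(p, f)
        p = p.replace(
            **{f: CircadianRate(
                mean_rate=r.mean_rate * float(_lognormal_multiplier(rng, cv)),
                components=r.components,
            )}
        )
    return p


def gen_pk_experiment(
    design: ExperimentDesign,
    params: PBPKParameters,
    noise: NoiseModel = NoiseModel(),
    seed: int | None = 0,
    sex: str = "F",
    feeding: str = "fed",
    dose_mg_per_kg: float = 100.0,
    censor: bool = True,
    sim_rtol: float = 1e-8,
    sim_atol: float = 1e-10,
) -> tuple[PKGroupDataset, ...]:
    """Destructive-sampling talinolol PK at each dosing ZT of the design.

    Each virtual mouse receives its own lognormally perturbed parameter
    set (shared across matrices, so its plasma, ileum and liver values
    are internally consistent), is simulated forward, and is read out at
    its sacrifice time with proportional assay noise.  Values below the
    limit of determination are floored at the limit when ``censor`` is
    set (the flag mirrors reporting at the assay floor).
    """
    rng = np.random.default_rng(seed)
    datasets = []
    times = np.asarray(design.pk_times, dtype=float)
    for zt in design.dose_zts:
        dose = DoseEvent(dose_mg_per_kg=dose_mg_per_kg, zt_dose=zt)
        conc: dict[str, list[list[float]]] = {m: [[] for _ in times] for m in MATRICES}
        for i, t_sac in enumerate(times):
            for _ in range(design.n_mice_per_time):
                p_mouse = _perturbed(params, rng, noise.pk_inter_animal_cv)
                sim = simulate(
                    p_mouse, dose, t_end=float(times.max()),
                    t_eval=times, rtol=sim_rtol, atol=sim_atol,
                )
                for m in MATRICES:
                    c = float(sim.concentration(m)[i])
                    c *= float(_lognormal_multiplier(rng, noise.pk_assay_cv))
                    if censor and c < noise.lod_ug_per_ml:
                        c = noise.lod_ug_per_ml
                    conc[m][i].append(c)
        datasets.append(
            PKGroupDataset(
                sex=sex, feeding=feeding, zt_dose=zt, times=times,
                concentrations={m: [np.asarray(v) for v in conc[m]] for m in MATRICES},
            )
        )
    return tuple(datasets)


def gen_bioluminescence(
    design: ExperimentDesign,
    fit: DampedCosineResults,
    noise: NoiseModel = NoiseModel(),
    seed: int | None = 0,
    baseline: float = 1000.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Dense photon-count trace from a damped cosine plus trend and noise.

    ``y(t) = baseline * (1 + A e^(-lambda t) cos(2 pi (t - phi)/T))
    + trend_slope * t + Gaussian(0, baseline * biolum_sd)``.
    Returns (t_hours, counts) with ``duration_h * 60 / dt_min`` points.
    """
    rng = np.random.default_rng(seed)
    n = design.biolum_n_points
    t = np.arange(n) * design.biolum_dt_min / 60.0
    clean = baseline * fit.predict(t)
    y = clean + noise.biolum_trend_slope * t
    if noise.biolum_sd > 0:
        y = y + rng.normal(0.0, baseline * noise.biolum_sd, size=n)
    return t, y
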