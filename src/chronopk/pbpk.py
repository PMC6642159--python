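"""Circadian physiologically-based model of oral talinolol disposition.

Talinolol is a pure P-glycoprotein (P-gp) substrate: it is absorbed from
the gut lumen into the ileum mucosa by passive diffusion, effluxed back
into the lumen by apical P-gp, transferred to plasma, exchanged with the
liver (whose P-gp secretes drug into bile and hence back to the lumen),
and eliminated unmetabolised in urine (from plasma) and faeces (from the
lumen).  Efflux and clearance rate constants carry multiplicative cosine
modulation so that disposition depends on the Zeitgeber time of dosing.

Compartments (amounts in ug): gut lumen, ileum mucosa, plasma, liver,
plus cumulative urine and faeces.  The system conserves mass exactly:

    dA_lum/dt = -ka*A_lum - r_int(t)*A_lum + r_pgpI(t)*A_il + r_pgpL(t)*A_li
    dA_il/dt  =  ka*A_lum + k_pl_il*A_pl - r_pgpI(t)*A_il - k_ib*A_il
    dA_pl/dt  =  k_ib*A_il - k_pl_il*A_pl - k_pl_li*A_pl + k_li_pl*A_li - r_ren(t)*A_pl
    dA_li/dt  =  k_pl_li*A_pl - k_li_pl*A_li - r_pgpL(t)*A_li
    dA_ur/dt  =  r_ren(t)*A_pl
    dA_fe/dt  =  r_int(t)*A_lum

The plasma->ileum distribution term k_pl_il models perfusion of the
mucosa by systemic drug (tissue homogenate concentrations include
vascular and interstitial drug); setting it to 0 recovers the purely
unidirectional absorption topology.

with each circadian rate r_x(t) = mesor * (1 + sum_k alpha_k *
cos(2 pi ((zt_dose + t) - phi_k)/T_k)), alpha_k the component amplitude
as a fraction of the mesor (sum alpha_k <= 1 keeps rates non-negative).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy.integrate import solve_ivp

from .rhythmometry import CircadianComponent

__all__ = [
    "CircadianRate",
    "PBPKParameters",
    "DoseEvent",
    "SimResult",
    "circadian_rate_value",
    "simulate",
    "mass_balance_residual",
    "model_auc",
    "get_param",
    "set_param",
]

ALLOWED_PERIODS = (24.0, 12.0, 8.0)
COMPARTMENTS = ("lumen", "ileum", "plasma", "liver", "urine_cum", "feces_cum")
MATRICES = ("plasma", "ileum", "liver")


@dataclass(frozen=True)
class CircadianRate:
    """First-order rate constant with multiplicative cosine modulation.

    ``mean_rate`` is the rhythm-adjusted mean (mesor, 1/h); component
    amplitudes are dimensionless fractions of the mesor and must sum to
    at most 1 so the instantaneous rate never goes negative.  The clock
    argument is Zeitgeber time (h after light onset).
    """

    mean_rate: float
    components: tuple[CircadianComponent, ...] = ()

    def __post_init__(self) -> None:
        if self.mean_rate < 0:
            raise ValueError(f"mean_rate must be >= 0, got {self.mean_rate}")
        comps = tuple(self.components)
        object.__setattr__(self, "components", comps)
        for c in comps:
            if c.period not in ALLOWED_PERIODS:
                raise ValueError(f"period {c.period} h not in {ALLOWED_PERIODS}")
        total = sum(c.amplitude for c in comps)
        if total > 1.0 + 1e-12:
            raise ValueError(
                f"sum of relative amplitudes {total:.4g} > 1 would allow a negative rate"
            )

    def value(self, zt):
        """Instantaneous rate (1/h) at Zeitgeber time ``zt`` (hours)."""
        zt = np.asarray(zt, dtype=float)
        mod = np.ones_like(zt)
        for c in self.components:
            mod = mod + c.amplitude * np.cos(2 * np.pi * (zt - c.acrophase) / c.period)
        out = self.mean_rate * mod
        return out if out.ndim else float(out)


def circadian_rate_value(r: CircadianRate, zt):
    """Evaluate a circadian rate law at Zeitgeber time ``zt``."""
    return r.value(zt)


def _const(rate: float) -> CircadianRate:
    return CircadianRate(mean_rate=rate)


@dataclass(frozen=True)
class PBPKParameters:
    """Kinetic constants and physiology of the talinolol model.

    Rates are 1/h.  Default organ sizes are nominal mouse physiology
    (25 g body weight, 1.2 mL plasma, 1.3 g liver, 0.25 g ileum mucosa);
    calibration absorbs any scale error into the rate estimates because
    tissue data are concentrations per wet weight.
    """

    ka: float = 1.5                 # lumen -> ileum passive absorption
    k_ib: float = 1.0               # ileum -> plasma transfer
    k_pl_il: float = 0.0            # plasma -> ileum distribution (perfusion);
                                    # 0 = unidirectional absorption topology
    k_pl_li: float = 0.8            # plasma -> liver uptake
    k_li_pl: float = 0.5            # liver -> plasma return
    pgp_ileum: CircadianRate = field(default_factory=lambda: _const(0.6))
    pgp_liver: CircadianRate = field(default_factory=lambda: _const(0.4))
    renal: CircadianRate = field(default_factory=lambda: _const(1.0))
    intestinal: CircadianRate = field(default_factory=lambda: _const(1e-5))
    body_weight_g: float = 25.0
    V_plasma_mL: float = 1.2
    W_ileum_g: float = 0.25
    W_liver_g: float = 1.3

    def __post_init__(self) -> None:
        for name in ("ka", "k_ib", "k_pl_il", "k_pl_li", "k_li_pl"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("body_weight_g", "V_plasma_mL", "W_ileum_g", "W_liver_g"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")

    def replace(self, **kwargs) -> "PBPKParameters":
        return replace(self, **kwargs)

    def to_dict(self) -> dict:
        def rate_dict(r: CircadianRate) -> dict:
            return {
                "mean_rate_per_h": r.mean_rate,
                "components": [
                    {"period_h": c.period, "rel_amplitude": c.amplitude, "acrophase_h": c.acrophase}
                    for c in r.components
                ],
            }

        return {
            "ka_per_h": self.ka,
            "k_ib_per_h": self.k_ib,
            "k_pl_il_per_h": self.k_pl_il,
            "k_pl_li_per_h": self.k_pl_li,
            "k_li_pl_per_h": self.k_li_pl,
            "pgp_ileum": rate_dict(self.pgp_ileum),
            "pgp_liver": rate_dict(self.pgp_liver),
            "renal": rate_dict(self.renal),
            "intestinal": rate_dict(self.intestinal),
            "body_weight_g": self.body_weight_g,
            "V_plasma_mL": self.V_plasma_mL,
            "W_ileum_g": self.W_ileum_g,
            "W_liver_g": self.W_liver_g,
        }


@dataclass(frozen=True)
class DoseEvent:
    """A single oral gavage dose, referenced to Zeitgeber time."""

    dose_mg_per_kg: float = 100.0
    zt_dose: float = 3.0
    route: str = "oral"

    def __post_init__(self) -> None:
        if self.dose_mg_per_kg <= 0:
            raise ValueError("dose must be > 0")
        if not (0 <= self.zt_dose < 24):
            raise ValueError("zt_dose must lie in [0, 24)")
        if self.route != "oral":
            raise ValueError("only oral dosing is modelled")

    def dose_ug(self, body_weight_g: float) -> float:
        # mg/kg * g body weight = ug
        return self.dose_mg_per_kg * body_weight_g


@dataclass
class SimResult:
    """Simulated amounts (ug) and concentrations on a regular time grid.

    ``t`` is hours post-dose; plasma concentration is ug/mL, tissue
    concentrations ug/g wet weight.
    """

    t: np.ndarray
    amounts: dict[str, np.ndarray]
    concentrations: dict[str, np.ndarray]
    dose_ug: float
    zt_dose: float

    def total_amount(self) -> np.ndarray:
        return sum(self.amounts[c] for c in COMPARTMENTS)

    def concentration(self, matrix: str) -> np.ndarray:
        if matrix not in self.concentrations:
            raise KeyError(f"unknown matrix {matrix!r}; expected one of {MATRICES}")
        return self.concentrations[matrix]

    def interp_concentration(self, matrix: str, times) -> np.ndarray:
        times = np.asarray(times, dtype=float)
        if times.min() < self.t[0] - 1e-12 or times.max() > self.t[-1] + 1e-12:
            raise ValueError("requested times outside simulated grid")
        return np.interp(times, self.t, self.concentration(matrix))


def _rate_coeffs(r: CircadianRate, zt_dose: float):
    """Precompute (mesor, amp*mesor, omega, phase-shifted angle offset)."""
    amps = np.array([c.amplitude for c in r.components])
    omegas = np.array([2 * np.pi / c.period for c in r.components])
    # r(t) = mesor * (1 + sum amps * cos(omega*(zt_dose + t) - omega*phi))
    offsets = np.array([2 * np.pi * (zt_dose - c.acrophase) / c.period for c in r.components])
    return r.mean_rate, amps, omegas, offsets


def simulate(
    p: PBPKParameters,
    d: DoseEvent,
    t_end: float = 8.0,
    dt_out: float = 0.1,
    *,
    t_eval: Sequence[float] | None = None,
    rtol: float = 1e-8,
    atol: float = 1e-10,
    method: str = "LSODA",
) -> SimResult:
    """Integrate the circadian PBPK system for one oral dose.

    The full dose enters the gut lumen at t=0.  Output is reported on a
    regular grid of step ``dt_out`` unless explicit ``t_eval`` times are
    given (these must start at >= 0 and end at <= t_end).
    """
    if t_end <= 0:
        raise ValueError("t_end must be > 0")
    dose = d.dose_ug(p.body_weight_g)

    # flatten the circadian coefficients to plain python scalars; the RHS is
    # called thousands of times per calibration so it avoids numpy overhead
    coeffs = []
    for r in (p.pgp_ileum, p.pgp_liver, p.renal, p.intestinal):
        mean, amps, omegas, offsets = _rate_coeffs(r, d.zt_dose)
        coeffs.append((float(mean), [(float(a), float(w), float(o))
                                     for a, w, o in zip(amps, omegas, offsets)]))
    cos = math.cos

    def rate(i: int, t: float) -> float:
        mean, terms = coeffs[i]
        if not terms:
            return mean
        mod = 1.0
        for a, w, o in terms:
            mod += a * cos(w * t + o)
        return mean * mod

    ka, k_ib, k_pl_il = p.ka, p.k_ib, p.k_pl_il
    k_pl_li, k_li_pl = p.k_pl_li, p.k_li_pl

    def rhs(t, y):
        lum, il, pl, li = y[0], y[1], y[2], y[3]
        r_pgpI = rate(0, t)
        r_pgpL = rate(1, t)
        r_ren = rate(2, t)
        r_int = rate(3, t)
        abs_flux = ka * lum
        effI = r_pgpI * il
        effL = r_pgpL * li
        dist = k_pl_il * pl
        return [
            -abs_flux - r_int * lum + effI + effL,
            abs_flux + dist - effI - k_ib * il,
            k_ib * il - dist - k_pl_li * pl + k_li_pl * li - r_ren * pl,
            k_pl_li * pl - k_li_pl * li - effL,
            r_ren * pl,
            r_int * lum,
        ]

    if t_eval is None:
        t_grid = np.arange(0.0, t_end + dt_out / 2, dt_out)
        t_grid[-1] = min(t_grid[-1], t_end)
    else:
        t_grid = np.asarray(t_eval, dtype=float)
        if t_grid.min() < 0 or t_grid.max() > t_end + 1e-12:
            raise ValueError("t_eval must lie within [0, t_end]")

    y0 = [dose, 0.0, 0.0, 0.0, 0.0, 0.0]
    sol = solve_ivp(rhs, (0.0, t_end), y0, method=method, t_eval=t_grid, rtol=rtol, atol=atol)
    if not sol.success:
        raise RuntimeError(f"ODE integration failed: {sol.message}")
    Y = sol.y
    if not np.all(np.isfinite(Y)):
        raise RuntimeError("non-finite state in simulation")
    neg_tol = max(1e-9 * dose, 100 * atol)
    if Y.min() < -neg_tol:
        raise RuntimeError(f"negative amount beyond tolerance: min={Y.min():.3g} ug")
    Y = np.clip(Y, 0.0, None)

    amounts = {c: Y[i] for i, c in enumerate(COMPARTMENTS)}
    concentrations = {
        "plasma": amounts["plasma"] / p.V_plasma_mL,
        "ileum": amounts["ileum"] / p.W_ileum_g,
        "liver": amounts["liver"] / p.W_liver_g,
    }
    return SimResult(
        t=sol.t, amounts=amounts, concentrations=concentrations,
        dose_ug=dose, zt_dose=d.zt_dose,
    )


def mass_balance_residual(s: SimResult, dose_ug: float | None = None) -> float:
    """Max over the grid of |total drug - dose| / dose (conservation check)."""
    dose = s.dose_ug if dose_ug is None else dose_ug
    return float(np.max(np.abs(s.total_amount() - dose)) / dose)


def model_auc(s: SimResult, matrix: str, window: tuple[float, float] = (0.0, 8.0)) -> float:
    """Trapezoidal AUC of a matrix concentration over a time window."""
    lo, hi = window
    if lo < s.t[0] - 1e-12 or hi > s.t[-1] + 1e-12:
        raise ValueError(f"window {window} outside simulated grid [{s.t[0]}, {s.t[-1]}]")
    c = s.concentration(matrix)
    inside = (s.t > lo) & (s.t < hi)
    tt = np.concatenate(([lo], s.t[inside], [hi]))
    cc = np.concatenate(([np.interp(lo, s.t, c)], c[inside], [np.interp(hi, s.t, c)]))
    return float(np.trapezoid(cc, tt))


# -- parameter paths ---------------------------------------------------------
# Dotted paths name scalar degrees of freedom inside PBPKParameters, e.g.
# "ka", "renal.mean_rate", "pgp_ileum.amp0", "renal.phase0".  Used by the
# calibration and sensitivity machinery to build modified parameter sets.

def get_param(p: PBPKParameters, path: str) -> float:
    head, _, rest = path.partition(".")
    if not rest:
        return float(getattr(p, head))
    r: CircadianRate = getattr(p, head)
    if rest == "mean_rate":
        return r.mean_rate
    kind, idx = rest[:-1], int(rest[-1])
    if kind not in ("amp", "phase"):
        raise KeyError(f"unknown parameter path {path!r}")
    if idx >= len(r.components):
        raise KeyError(f"{path!r}: rate has only {len(r.components)} component(s)")
    comp = r.components[idx]
    return comp.amplitude if kind == "amp" else comp.acrophase


def set_param(p: PBPKParameters, path: str, value: float) -> PBPKParameters:
    head, _, rest = path.partition(".")
    if not rest:
        return p.replace(**{head: float(value)})
    r: CircadianRate = getattr(p, head)
    if rest == "mean_rate":
        new_r = CircadianRate(mean_rate=float(value), components=r.components)
    else:
        kind, idx = rest[:-1], int(rest[-1])
        comps = list(r.components)
        c = comps[idx]
        if kind == "amp":
            comps[idx] = CircadianComponent(c.period, float(value), c.acrophase)
        elif kind == "phase":
            comps[idx] = CircadianComponent(c.period, c.amplitude, float(value) % c.period)
        else:
            raise KeyError(f"unknown parameter path {path!r}")
        new_r = CircadianRate(mean_rate=r.mean_rate, components=tuple(comps))
    return p.replace(**{head: new_r})


def set_params(p: PBPKParameters, updates: dict[str, float]) -> PBPKParameters:
    """Apply several dotted-path updates, validating combined amplitudes."""
    for path, value in updates.items():
        p = set_param(p, path, value)
    return p
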