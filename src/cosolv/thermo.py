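"""Thermodynamic co-solvency models and two-pass outlier curation.

Two models cover the two data geometries:

* the Buchowski–Ksiazczak (λh) equation for a solute in one neat solvent
  across temperature,

      ln[1 + λ(1 − x)/x] = λ·h·(1/T − 1/Tm),

  a two-parameter implicit relation that passes through the pure-melt
  point x = 1 at T = Tm.  λ reflects solute association, h the
  energetics of dissolution (λh carries units of kelvin);

* the Jouyban–Acree model for a solute in a binary solvent across
  composition and temperature,

      ln x1 = x2*·ln x2_sat + x3*·ln x3_sat
              + (x2*·x3*/T)·Σ_{i=0..2} Ji·(x2* − x3*)^i,

  where x2*, x3* = 1 − x2* are solute-free solvent fractions and the
  neat-solvent saturation anchors x2_sat(T), x3_sat(T) come from λh fits
  or from ln x vs 1/T interpolation of neat records.

Curation mirrors a fixed two-pass procedure: fit on everything, drop
points whose percentage error against the pass-1 back-computed values
exceeds a threshold (default 10%), refit on the rest.  Exactly two
passes, never iterated to convergence.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq, least_squares

from .datasets import Dataset
from .metrics import mape, percentage_error, rmsd

__all__ = [
    "LambdaHParams", "JouybanAcreeParams", "NeatAnchor", "CurationReport",
    "lambda_h_predict", "lambda_h_fit",
    "jouyban_acree_predict", "jouyban_acree_fit",
    "curate",
]


class FitError(RuntimeError):
    pass


class CurationError(RuntimeError):
    pass


# --------------------------------------------------------------------------
# lambda-h (Buchowski-Ksiazczak)
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class LambdaHParams:
    """λh parameters: λ (dimensionless, > 0), h [K], melting point t_m [K]."""

    lam: float
    h: float
    t_m: float

    def __post_init__(self) -> None:
        if self.lam <= 0:
            raise ValueError(f"lambda={self.lam} must be > 0")
        if self.t_m <= 0:
            raise ValueError(f"t_m={self.t_m} K must be > 0")


def lambda_h_predict(params: LambdaHParams, temperature) -> float | np.ndarray:
    """Saturation mole fraction x(T) from the λh equation.

    Solves ln[1 + λ(1−x)/x] = λh(1/T − 1/Tm) for x in (0, 1] by bisection
    (the left-hand side is strictly decreasing in x, so the bracket is
    guaranteed).  Residual of the returned root is below 1e−12.
    """
    temps = np.atleast_1d(np.asarray(temperature, dtype=float))
    out = np.empty_like(temps)
    lam, h, t_m = params.lam, params.h, params.t_m
    for i, T in enumerate(temps):
        if not 0.0 < T <= t_m:
            raise ValueError(f"temperature {T} K outside (0, t_m={t_m}]")
        rhs = lam * h * (1.0 / T - 1.0 / t_m)
        if rhs <= 0.0:
            out[i] = 1.0
            continue

        def f(x, rhs=rhs):
            return np.log1p(lam * (1.0 - x) / x) - rhs

        lo = 1e-300
        if f(1.0) > 0.0:  # rhs < 0 handled above; f(1)=−rhs ≤ 0 always
            raise FitError("no root in (0, 1]")
        x = brentq(f, lo, 1.0, xtol=1e-15, rtol=8.9e-16, maxiter=200)
        out[i] = x
    return float(out[0]) if np.ndim(temperature) == 0 else out


def lambda_h_fit(records: Dataset | tuple, t_m: float,
                 x0: tuple[float, float] = (1.0, None)) -> tuple[LambdaHParams, dict]:
    """Fit (λ, h) to neat-solvent records by least squares in log10 x.

    ``records`` is a Dataset (or a ``(T, x)`` pair of arrays) for one
    solute in one neat solvent.  Requires at least 3 points spanning at
    least 2 distinct temperatures.  Returns the parameters and a stats
    dict (log10-scale residual, linear-scale MAPE/RMSD).
    """
    if isinstance(records, Dataset):
        T = records.temperatures
        x = records.x
    else:
        T, x = map(np.asarray, records)
    if len(T) < 2 or len(np.unique(T)) < 2:
        raise FitError("need records spanning at least 2 temperatures")
    if np.any(T > t_m):
        raise FitError("records above the melting temperature")

    # van't Hoff-style initial h from the lam=1 closed form
    slope = np.polyfit(1.0 / T - 1.0 / t_m, np.log(x), 1)[0]
    h0 = -slope if x0[1] is None else x0[1]
    lam0 = x0[0]

    def resid(theta):
        lam, h = np.exp(theta[0]), theta[1]
        pred = lambda_h_predict(LambdaHParams(lam, h, t_m), T)
        return np.log10(pred) - np.log10(x)

    sol = least_squares(resid, [np.log(lam0), h0], method="lm", xtol=1e-14,
                        ftol=1e-14, gtol=1e-14)
    lam, h = float(np.exp(sol.x[0])), float(sol.x[1])
    params = LambdaHParams(lam, h, t_m)
    pred = lambda_h_predict(params, T)
    stats = {
        "n": int(len(T)),
        "log10_rss": float(np.sum(sol.fun ** 2)),
        "mape": mape(x, pred),
        "rmsd": rmsd(x, pred),
    }
    return params, stats


# --------------------------------------------------------------------------
# Jouyban-Acree
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class NeatAnchor:
    """ln x_sat(T) for a solute in one neat solvent.

    Backed either by a λh fit or by linear interpolation of ln x against
    1/T through the supplied neat-solvent points (extrapolating the same
    line outside their range).
    """

    temps: tuple[float, ...]
    ln_x: tuple[float, ...]
    lh_params: LambdaHParams | None = None

    @classmethod
    def from_records(cls, records: Dataset, t_m: float | None = None) -> "NeatAnchor":
        """Build from neat-solvent records; fits λh when t_m is given."""
        T = records.temperatures
        lnx = np.log(records.x)
        lh = None
        if t_m is not None and len(np.unique(T)) >= 2:
            lh, _ = lambda_h_fit(records, t_m)
        order = np.argsort(T)
        return cls(tuple(T[order]), tuple(lnx[order]), lh)

    @classmethod
    def from_points(cls, temps, ln_x) -> "NeatAnchor":
        order = np.argsort(temps)
        return cls(tuple(np.asarray(temps, float)[order]),
                   tuple(np.asarray(ln_x, float)[order]))

    def __call__(self, temperature) -> float | np.ndarray:
        if self.lh_params is not None:
            x = lambda_h_predict(self.lh_params, temperature)
            return np.log(x)
        inv_t = 1.0 / np.asarray(self.temps)
        lnx = np.asarray(self.ln_x)
        if len(self.temps) == 1:
            return np.full_like(np.asarray(temperature, float), lnx[0]) \
                if np.ndim(temperature) else float(lnx[0])
        coef = np.polyfit(inv_t, lnx, 1)
        out = np.polyval(coef, 1.0 / np.asarray(temperature, dtype=float))
        return float(out) if np.ndim(temperature) == 0 else out


@dataclass(frozen=True)
class JouybanAcreeParams:
    """J0, J1, J2 [K] plus the two neat-solvent anchors."""

    j0: float
    j1: float
    j2: float
    anchor2: NeatAnchor  # solvent1 (organic), x2* = 1 endpoint
    anchor3: NeatAnchor  # solvent2 (water), x2* = 0 endpoint

    @property
    def j(self) -> np.ndarray:
        return np.array([self.j0, self.j1, self.j2])


def jouyban_acree_predict(params: JouybanAcreeParams, x2_star,
                          temperature) -> float | np.ndarray:
    """ln x1 of the solute at solute-free composition x2* and T [K]."""
    x2 = np.asarray(x2_star, dtype=float)
    if np.any((x2 < 0) | (x2 > 1)):
        raise ValueError("x2_star outside [0, 1]")
    T = np.asarray(temperature, dtype=float)
    if np.any(T <= 0):
        raise ValueError("temperature must be > 0 K")
    x3 = 1.0 - x2
    d = x2 - x3
    excess = (x2 * x3 / T) * (params.j0 + params.j1 * d + params.j2 * d ** 2)
    out = x2 * params.anchor2(T) + x3 * params.anchor3(T) + excess
    return float(out) if np.ndim(out) == 0 else out


def jouyban_acree_fit(records: Dataset | tuple, anchor2: NeatAnchor,
                      anchor3: NeatAnchor) -> tuple[JouybanAcreeParams, dict]:
    """Regress (J0, J1, J2) on mixed-composition records.

    The model is linear in the J's once the anchors are fixed: each mixed
    point contributes

        y = [ln x1 − x2*·ln x2_sat(T) − x3*·ln x3_sat(T)]·T/(x2*·x3*)

    against the polynomial basis {1, (x2*−x3*), (x2*−x3*)²}; plain linear
    least squares solves it.  Needs >= 4 mixed records at >= 3 distinct
    compositions (rank of the cubic basis).
    """
    if isinstance(records, Dataset):
        mixed = [r for r in records if 0.0 < r.x2_star < 1.0]
        x2 = np.array([r.x2_star for r in mixed])
        T = np.array([r.temperature for r in mixed])
        lnx = np.log(np.array([r.x_solute for r in mixed]))
    else:
        x2, T, lnx = map(np.asarray, records)
        keep = (x2 > 0) & (x2 < 1)
        x2, T, lnx = x2[keep], T[keep], lnx[keep]
    if len(x2) < 4:
        raise FitError("need at least 4 mixed-composition records")
    x3 = 1.0 - x2
    d = x2 - x3
    basis = np.column_stack([np.ones_like(d), d, d ** 2])
    if np.linalg.matrix_rank(basis) < 3:
        raise FitError("rank-deficient composition design "
                       "(need >= 3 distinct compositions)")
    y = (lnx - x2 * anchor2(T) - x3 * anchor3(T)) * T / (x2 * x3)
    coef, res, *_ = np.linalg.lstsq(basis, y, rcond=None)
    params = JouybanAcreeParams(float(coef[0]), float(coef[1]), float(coef[2]),
                                anchor2, anchor3)
    pred = np.exp(jouyban_acree_predict(params, x2, T))
    xexp = np.exp(lnx)
    stats = {"n": int(len(x2)), "mape": mape(xexp, pred),
             "rmsd": rmsd(xexp, pred)}
    return params, stats


# --------------------------------------------------------------------------
# two-pass curation
# --------------------------------------------------------------------------

@dataclass
class CurationReport:
    """Outcome of the fixed two-pass outlier-removal procedure."""

    retained: Dataset
    excluded: Dataset
    excluded_pe: list[float]
    initial_params: object
    final_params: object
    initial_mape: float
    final_mape: float
    threshold: float
    stable: bool = True  # a hypothetical third pass would exclude nothing
    model: str = "lambda-h"

    def to_json(self) -> str:
        p = self.final_params
        if isinstance(p, LambdaHParams):
            pdict = {"lam": p.lam, "h": p.h, "t_m": p.t_m}
        else:
            pdict = {"j0": p.j0, "j1": p.j1, "j2": p.j2}
        return json.dumps({
            "model": self.model,
            "params": pdict,
            "stats": {"mape": self.final_mape,
                      "initial_mape": self.initial_mape,
                      "n": len(self.retained),
                      "n_excluded": len(self.excluded),
                      "threshold_pct": self.threshold,
                      "stable": self.stable},
        }, indent=2)


def _fit_and_predict(records: Dataset, model: str, **kw):
    if model in ("lambda-h", "lh"):
        params, _ = lambda_h_fit(records, kw["t_m"])
        pred = lambda_h_predict(params, records.temperatures)
    elif model in ("ja", "jouyban-acree"):
        params, _ = jouyban_acree_fit(records, kw["anchor2"], kw["anchor3"])
        pred = np.exp(jouyban_acree_predict(
            params, records.x2, records.temperatures))
    else:
        raise ValueError(f"unknown model {model!r}")
    return params, np.atleast_1d(pred)


def curate(records: Dataset, model: str = "lambda-h",
           threshold: float = 10.0, **model_kw) -> CurationReport:
    """Two-pass curation of a solubility dataset against a fitted model.

    Pass 1 fits the chosen model to every record; records whose linear-
    scale percentage error against the back-computed values is *strictly*
    above ``threshold`` (percent) are excluded; pass 2 refits on the
    retained records.  Points with PE exactly at the threshold are kept.

    For the λh model pass ``t_m=...``; for the Jouyban–Acree model pass
    ``anchor2=...`` and ``anchor3=...`` (mixed-composition records only
    are fitted; neat records, if present, are always retained).

    The report's ``stable`` flag records whether a hypothetical third
    pass would exclude further points; the procedure never takes one.
    """
    if len(records) == 0:
        raise CurationError("empty dataset")
    params1, pred1 = _fit_and_predict(records, model, **model_kw)

    if model in ("ja", "jouyban-acree"):
        fit_mask = np.array([0.0 < r.x2_star < 1.0 for r in records])
    else:
        fit_mask = np.ones(len(records), dtype=bool)
    x_obs = records.x[fit_mask]
    pe1 = np.abs(x_obs - pred1) / x_obs * 100.0
    initial_mape = float(np.mean(pe1))

    excl_flags = np.zeros(len(records), dtype=bool)
    excl_flags[np.flatnonzero(fit_mask)] = pe1 > threshold

    retained = Dataset([r for r, e in zip(records, excl_flags) if not e],
                       provenance=records.provenance + "|curated")
    excluded = Dataset([r for r, e in zip(records, excl_flags) if e],
                       provenance=records.provenance + "|excluded")
    excluded_pe = [float(p) for p, e
                   in zip(pe1, excl_flags[fit_mask]) if e]
    if sum(fit_mask) - len(excluded) < (2 if model.startswith("l") else 4):
        raise CurationError(
            f"curation excluded too many records ({len(excluded)} of "
            f"{int(sum(fit_mask))}) to refit")

    params2, pred2 = _fit_and_predict(retained, model, **model_kw)
    if model in ("ja", "jouyban-acree"):
        mask2 = np.array([0.0 < r.x2_star < 1.0 for r in retained])
    else:
        mask2 = np.ones(len(retained), dtype=bool)
    x2obs = retained.x[mask2]
    pe2 = np.abs(x2obs - pred2) / x2obs * 100.0
    final_mape = float(np.mean(pe2))

    return CurationReport(
        retained=retained, excluded=excluded, excluded_pe=excluded_pe,
        initial_params=params1, final_params=params2,
        initial_mape=initial_mape, final_mape=final_mape,
        threshold=threshold, stable=bool(np.all(pe2 <= threshold)),
        model=model)
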