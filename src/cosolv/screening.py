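"""Green-solvent screening: predict, locate optima, filter by EI, rank.

The driver sweeps an ensemble model across candidate aqueous binary
systems on a solute-free composition grid, records which grid points lie
inside the applicability domain, finds the composition of maximum
predicted solubility at a reference temperature, and re-expresses the
predicted surface as Jouyban–Acree parameters so the result can be used
without the model.  Candidates are admitted to the ranking only when
their environmental index is strictly below a threshold (default 0.5);
lower EI breaks score ties.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datasets import Dataset, SolventMeta
from .ensemble import EnsembleModel, applicability_domain
from .saturation import FusionProps, patch_miscibility, solve_saturation
from .sigma import (CosmoParameterSet, SigmaProfile, descriptor_vector)
from .thermo import JouybanAcreeParams, NeatAnchor, jouyban_acree_fit

__all__ = ["ScreeningResult", "screen_system", "refit_ja", "rank_solvents",
           "optimal_composition"]

logger = logging.getLogger("cosolv.screening")


@dataclass
class ScreeningResult:
    """Predicted solubility surface for one solute + organic/water system."""

    solute_id: str
    solvent1_id: str
    grid: np.ndarray                 # x2* values
    temperatures: np.ndarray         # K
    pred_log10x: np.ndarray          # (len(grid), len(temperatures))
    in_domain: np.ndarray            # same shape, bool
    reference_T: float = 298.15
    ei: float | None = None
    ja_params: JouybanAcreeParams | None = None
    backfit_mape: float | None = None
    all_out_of_domain: bool = False
    warning: str = ""

    @property
    def in_domain_fraction(self) -> float:
        return float(np.mean(self.in_domain))

    @property
    def x2_opt(self) -> float | None:
        """Composition of maximum predicted solubility at the reference T."""
        j = int(np.argmin(np.abs(self.temperatures - self.reference_T)))
        col = self.pred_log10x[:, j]
        ok = self.in_domain[:, j]
        if not np.any(ok):
            return None
        masked = np.where(ok, col, -np.inf)
        return float(self.grid[int(np.argmax(masked))])

    @property
    def log10x_opt(self) -> float | None:
        j = int(np.argmin(np.abs(self.temperatures - self.reference_T)))
        col = np.where(self.in_domain[:, j], self.pred_log10x[:, j], -np.inf)
        return None if np.all(np.isneginf(col)) else float(col.max())


def optimal_composition(x2_grid, values) -> float:
    """argmax helper: composition with the largest solubility value."""
    x2_grid = np.asarray(x2_grid, float)
    values = np.asarray(values, float)
    if x2_grid.shape != values.shape or x2_grid.size == 0:
        raise ValueError("grid/value shape mismatch or empty input")
    return float(x2_grid[int(np.argmax(values))])


def screen_system(ensemble: EnsembleModel, solute_profile: SigmaProfile,
                  organic_profile: SigmaProfile, water_profile: SigmaProfile,
                  fusion: FusionProps,
                  solute_id: str = "solute", solvent1_id: str = "organic",
                  grid=None, temperatures=(298.15,),
                  reference_T: float = 298.15,
                  params: CosmoParameterSet | None = None) -> ScreeningResult:
    """Predict the solubility surface of one binary aqueous system.

    For every (x2*, T) grid point the descriptor vector is built (the
    computed-solubility descriptor comes from the iterative saturation
    solver, with miscibility-flagged compositions repaired by the linear
    ln x extrapolation), the ensemble predicts log10 x, and the
    applicability domain is checked.  A result where every point falls
    outside the domain is returned flagged rather than ranked.
    """
    params = params or CosmoParameterSet()
    grid = np.asarray([0.0, 0.05, 0.1, 0.15, 0.2, 0.25, 0.3, 0.35, 0.4,
                       0.45, 0.5, 0.55, 0.6, 0.65, 0.7, 0.75, 0.8, 0.85,
                       0.9, 0.95, 1.0] if grid is None else grid, float)
    temperatures = np.asarray(temperatures, float)
    pred = np.zeros((len(grid), len(temperatures)))
    dom = np.zeros_like(pred, dtype=bool)

    for j, T in enumerate(temperatures):
        ln_x_cosmo = np.zeros(len(grid))
        flags = np.zeros(len(grid), dtype=bool)
        vectors = []
        for i, x2 in enumerate(grid):
            comps = [(organic_profile, x2), (water_profile, 1.0 - x2)]
            comps = [(prof, f) for prof, f in comps if f > 0.0]
            state = solve_saturation(solute_profile, comps, fusion, T,
                                     params)
            ln_x_cosmo[i] = np.log(state.x_sat)
            flags[i] = state.miscible_flag
            vectors.append((comps, x2))
        if np.any(flags):
            ln_x_cosmo = patch_miscibility(ln_x_cosmo, flags, grid)
        for i, (comps, x2) in enumerate(vectors):
            vec = descriptor_vector(solute_profile, comps, T,
                                    ln_x_cosmo[i] / np.log(10.0), params)
            pred[i, j] = ensemble.predict(vec.values)
            dom[i, j], _ = applicability_domain(ensemble, vec.values)

    res = ScreeningResult(solute_id=solute_id, solvent1_id=solvent1_id,
                          grid=grid, temperatures=temperatures,
                          pred_log10x=pred, in_domain=dom,
                          reference_T=reference_T)
    if not np.any(dom):
        res.all_out_of_domain = True
        res.warning = "all grid points outside the applicability domain"
        return res
    refit_ja(res)
    return res


def refit_ja(result: ScreeningResult) -> JouybanAcreeParams:
    """Re-express a predicted surface as Jouyban–Acree parameters.

    The predicted neat-solvent endpoints anchor the model (so endpoint
    reproduction is exact by construction); J0–J2 are regressed on the
    in-domain mixed compositions.  The back-fit MAPE (linear scale) is
    stored on the result.
    """
    ln10 = np.log(10.0)
    g, T = result.grid, result.temperatures
    i2 = int(np.argmin(np.abs(g - 1.0)))
    i3 = int(np.argmin(np.abs(g - 0.0)))
    anchor2 = NeatAnchor.from_points(T, result.pred_log10x[i2] * ln10)
    anchor3 = NeatAnchor.from_points(T, result.pred_log10x[i3] * ln10)

    x2_pts, t_pts, lnx_pts = [], [], []
    for i, x2 in enumerate(g):
        if not 0.0 < x2 < 1.0:
            continue
        for j, temp in enumerate(T):
            if result.in_domain[i, j]:
                x2_pts.append(x2)
                t_pts.append(temp)
                lnx_pts.append(result.pred_log10x[i, j] * ln10)
    params, stats = jouyban_acree_fit(
        (np.array(x2_pts), np.array(t_pts), np.array(lnx_pts)),
        anchor2, anchor3)
    result.ja_params = params
    result.backfit_mape = stats["mape"]
    return params


def rank_solvents(results: list[ScreeningResult],
                  meta: dict[str, SolventMeta],
                  ei_threshold: float = 0.5,
                  reference_T: float = 298.15) -> pd.DataFrame:
    """Filter candidates by EI < threshold (strict) and rank by solubility.

    Sort key: maximum in-domain predicted log10 x at the reference
    temperature, descending; ties broken by lower EI.  Candidates with
    missing EI or no in-domain predictions are excluded with a warning.
    """
    rows = []
    for res in results:
        m = meta.get(res.solvent1_id)
        if m is None:
            logger.warning("candidate %s has no EI metadata; excluded",
                           res.solvent1_id)
            continue
        res.ei = m.ei
        if not m.ei < ei_threshold:
            logger.info("candidate %s filtered out (EI=%.3g >= %.3g)",
                        res.solvent1_id, m.ei, ei_threshold)
            continue
        if res.all_out_of_domain or res.log10x_opt is None:
            logger.warning("candidate %s entirely out of domain; excluded",
                           res.solvent1_id)
            continue
        rows.append({
            "solute": res.solute_id,
            "solvent1": res.solvent1_id,
            "ei": m.ei,
            "x2_opt": res.x2_opt,
            "log10x_opt": res.log10x_opt,
            "j0": res.ja_params.j0 if res.ja_params else np.nan,
            "j1": res.ja_params.j1 if res.ja_params else np.nan,
            "j2": res.ja_params.j2 if res.ja_params else np.nan,
            "backfit_mape": res.backfit_mape,
            "in_domain_fraction": res.in_domain_fraction,
            "warning": res.warning + (m.notes and f" [{m.notes}]" or ""),
        })
    df = pd.DataFrame(rows, columns=[
        "solute", "solvent1", "ei", "x2_opt", "log10x_opt",
        "j0", "j1", "j2", "backfit_mape", "in_domain_fraction", "warning"])
    if len(df):
        df = df.sort_values(["log10x_opt", "ei"],
                            ascending=[False, True],
                            kind="mergesort").reset_index(drop=True)
        df.index = df.index + 1
        df.index.name = "rank"
    return df
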