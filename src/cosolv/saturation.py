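"""Iterative saturation-solubility estimates from σ-potentials.

A solid solute dissolves until its activity matches the chemical
potential of the pure solid, fixed by the fusion properties:

    ln(γ_sat · x_sat) = −ΔfusG(T)/RT,   ΔfusG(T) = ΔHfus·(1 − T/Tm).

γ depends on composition (the dissolved solute reshapes the mixture), so
the equation is solved by damped fixed-point iteration in ln x: from the
current iterate the saturated-mixture σ-profile is rebuilt, the solute's
activity coefficient follows from the σ-potential difference between the
mixture and the pure solute, and x is updated.  When the update pushes x
to 1 without satisfying the solid–liquid condition the solver reports
complete miscibility instead of a saturation point; a screening curve
containing such points is repaired by extrapolating the last five valid
points linearly in ln x vs composition.

The activity-coefficient construction here is deliberately minimal (band
integral of the σ-potential difference, no combinatorial term): the
output serves as a *descriptor* where rank consistency matters, not as a
quantitative solubility claim.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .constants import R_GAS
from .sigma import CosmoParameterSet, SigmaProfile, mix_profiles, sigma_potential

__all__ = ["FusionProps", "SaturationState", "fusion_gibbs",
           "ln_gamma_solute", "solve_saturation", "patch_miscibility"]


class SaturationError(RuntimeError):
    pass


@dataclass(frozen=True)
class FusionProps:
    """Melting temperature t_m [K] and fusion enthalpy h_fus [J/mol]."""

    t_m: float
    h_fus: float

    def __post_init__(self) -> None:
        if self.t_m <= 0 or self.h_fus <= 0:
            raise ValueError("t_m and h_fus must be positive")


@dataclass(frozen=True)
class SaturationState:
    x_sat: float
    gamma_sat: float
    ln_activity: float
    converged: bool
    iterations: int
    miscible_flag: bool


def fusion_gibbs(props: FusionProps, temperature: float) -> float:
    """ΔfusG(T) = ΔHfus·(1 − T/Tm) [J/mol]; zero at Tm, positive below."""
    if temperature <= 0:
        raise ValueError("temperature must be > 0 K")
    return props.h_fus * (1.0 - temperature / props.t_m)


def ln_gamma_solute(solute: SigmaProfile, mixture: SigmaProfile,
                    temperature: float,
                    params: CosmoParameterSet | None = None,
                    mu_solute: np.ndarray | None = None) -> float:
    """ln γ of the solute in a mixture from σ-potential differences.

    (A_solute/a_eff)·Σ P̂_solute(σ)·[μ_mix(σ) − μ_solute(σ)] / RT — the
    residual (electrostatic + HB) part only; no combinatorial term.
    ``mu_solute`` may carry a precomputed pure-solute potential.
    """
    params = params or CosmoParameterSet()
    rt = R_GAS * temperature / 1000.0
    mu_mix = sigma_potential(mixture, temperature, params).mu
    if mu_solute is None:
        mu_solute = sigma_potential(solute, temperature, params).mu
    n_contacts = solute.total_area / params.a_eff
    return float(n_contacts
                 * np.sum(solute.weights * (mu_mix - mu_solute)) / rt)


def solve_saturation(solute_profile: SigmaProfile,
                     solvent_components: list[tuple[SigmaProfile, float]],
                     props: FusionProps, temperature: float,
                     params: CosmoParameterSet | None = None,
                     x_init: float = 1e-4, damping: float = 0.5,
                     tol: float = 1e-8, max_iter: int = 200) -> SaturationState:
    """Iterate the solid–liquid equilibrium to the saturation mole fraction.

    ``solvent_components`` are (profile, solute-free fraction) pairs
    summing to 1.  Each cycle recomputes the saturated-mixture profile at
    the current solute fraction, evaluates ln γ, and updates

        ln x ← (1−d)·ln x + d·[−max(0, ΔfusG)/RT − ln γ(x)]

    until |Δln x| < tol.  If the undamped update drives x to 1 the state
    is flagged completely miscible (x_sat = 1, not a saturation point).
    """
    params = params or CosmoParameterSet()
    fracs = np.array([f for _, f in solvent_components])
    if abs(fracs.sum() - 1.0) > 1e-9 or np.any(fracs < 0):
        raise ValueError("solvent fractions must be >= 0 and sum to 1")
    dg = max(0.0, fusion_gibbs(props, temperature))
    rt_j = R_GAS * temperature
    target = -dg / rt_j  # ln(gamma*x) at equilibrium

    ln_x = np.log(x_init)
    ln_gamma = 0.0
    mu_pure = sigma_potential(solute_profile, temperature, params).mu
    for it in range(1, max_iter + 1):
        x = float(np.exp(ln_x))
        comps = [(solute_profile, x)] + [
            (prof, (1.0 - x) * f) for prof, f in solvent_components]
        mixture = mix_profiles(comps)
        ln_gamma = ln_gamma_solute(solute_profile, mixture, temperature,
                                   params, mu_solute=mu_pure)
        proposal = target - ln_gamma
        if proposal >= 0.0:
            # solver escaped to x >= 1: complete miscibility, no SLE point
            return SaturationState(x_sat=1.0, gamma_sat=float(np.exp(ln_gamma)),
                                   ln_activity=ln_gamma,  # ln(gamma*1)
                                   converged=False, iterations=it,
                                   miscible_flag=True)
        ln_x_new = (1.0 - damping) * ln_x + damping * proposal
        delta = abs(ln_x_new - ln_x)
        ln_x = ln_x_new
        if delta < tol * damping:
            x = float(np.exp(ln_x))
            return SaturationState(x_sat=x, gamma_sat=float(np.exp(ln_gamma)),
                                   ln_activity=ln_gamma + ln_x,
                                   converged=True, iterations=it,
                                   miscible_flag=False)
    raise SaturationError(
        f"saturation iteration not converged in {max_iter} cycles "
        f"(last ln x = {ln_x:.6f}, ln gamma = {ln_gamma:.6f})")


def patch_miscibility(ln_x: np.ndarray, flags: np.ndarray,
                      x2_grid: np.ndarray | None = None,
                      n_fit: int = 5) -> np.ndarray:
    """Replace miscibility-flagged points by a linear ln x extension.

    A least-squares line through the last ``n_fit`` unflagged points
    preceding each flagged point (in ln x vs composition) replaces the
    flagged values; unflagged points are returned bit-exactly.
    """
    ln_x = np.asarray(ln_x, dtype=float)
    flags = np.asarray(flags, dtype=bool)
    if ln_x.shape != flags.shape:
        raise ValueError("curve and flags differ in length")
    grid = (np.arange(len(ln_x), dtype=float) if x2_grid is None
            else np.asarray(x2_grid, dtype=float))
    out = ln_x.copy()
    for i in np.flatnonzero(flags):
        valid = np.flatnonzero(~flags[:i])
        if len(valid) < n_fit:
            raise SaturationError(
                f"point {i}: fewer than {n_fit} valid points precede the "
                "miscibility region; cannot extrapolate")
        idx = valid[-n_fit:]
        coef = np.polyfit(grid[idx], ln_x[idx], 1)
        out[i] = np.polyval(coef, grid[i])
    return out
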