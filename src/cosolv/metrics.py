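"""Error statistics used throughout: PE, MAPE, RMSD and log10 reporting.

Percentage error (PE) is the absolute relative deviation of an estimate
from the observation, in percent; MAPE is its arithmetic mean over a set
of points; RMSD is the root-mean-square deviation in the units of the
inputs.  Solubilities are reported as log10 of the mole fraction.
"""

from __future__ import annotations

import numpy as np

__all__ = ["percentage_error", "mape", "rmsd", "to_log10"]


def percentage_error(x_exp: float, x_est: float) -> float:
    """|x_exp − x_est| / x_exp × 100.  Requires x_exp > 0."""
    x_exp = np.asarray(x_exp, dtype=float)
    if np.any(x_exp <= 0.0):
        raise ValueError("percentage error undefined for x_exp <= 0")
    return float(np.abs(x_exp - x_est) / x_exp * 100.0) if np.ndim(x_exp) == 0 \
        else np.abs(x_exp - np.asarray(x_est, float)) / x_exp * 100.0


def mape(x_exp, x_est) -> float:
    """Mean of per-point percentage errors, in percent."""
    x_exp = np.asarray(x_exp, dtype=float)
    x_est = np.asarray(x_est, dtype=float)
    if x_exp.shape != x_est.shape:
        raise ValueError(f"shape mismatch: {x_exp.shape} vs {x_est.shape}")
    if x_exp.size == 0:
        raise ValueError("mape requires at least one point")
    if np.any(x_exp <= 0.0):
        raise ValueError("mape undefined for x_exp <= 0")
    return float(np.mean(np.abs(x_est - x_exp) / x_exp) * 100.0)


def rmsd(x_exp, x_est) -> float:
    """Root-mean-square deviation, same units as the inputs."""
    x_exp = np.asarray(x_exp, dtype=float)
    x_est = np.asarray(x_est, dtype=float)
    if x_exp.shape != x_est.shape:
        raise ValueError(f"shape mismatch: {x_exp.shape} vs {x_est.shape}")
    if x_exp.size == 0:
        raise ValueError("rmsd requires at least one point")
    return float(np.sqrt(np.mean((x_est - x_exp) ** 2)))


def to_log10(x_solute) -> float:
    """Base-10 log of a mole-fraction solubility; defined on (0, 1]."""
    x = np.asarray(x_solute, dtype=float)
    if np.any(x <= 0.0) or np.any(x > 1.0):
        raise ValueError("mole fraction must lie in (0, 1]")
    out = np.log10(x)
    return float(out) if out.ndim == 0 else out
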