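"""Synthetic data generators: σ-profiles, solubility datasets, tables.

Everything downstream of real quantum-chemistry output and literature
compilations is exercised on data built here: smooth non-negative
σ-profiles with prescribed total surface area, solubility datasets drawn
from known λh / Jouyban–Acree ground truth with multiplicative
log-normal noise, and descriptor→target regression tables with a known
generating function.  All generators are pure functions of (spec, seed);
regeneration with the same seed is bit-identical.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .datasets import Dataset, SolubilityRecord
from .sigma import SIGMA_GRID, SigmaProfile
from .thermo import (JouybanAcreeParams, LambdaHParams, NeatAnchor,
                     jouyban_acree_predict, lambda_h_predict)

__all__ = [
    "ProfileSpec", "make_profile",
    "water_like_profile", "alkane_like_profile", "amide_like_profile",
    "make_lambda_h_dataset", "make_ja_dataset", "make_descriptor_table",
    "TARGET_FUNCTIONS",
]


@dataclass(frozen=True)
class ProfileSpec:
    """Sum-of-Gaussians σ-profile: (center e/Å², width e/Å², area Å²)."""

    peaks: tuple[tuple[float, float, float], ...]
    total_area: float

    def __post_init__(self) -> None:
        for c, w, a in self.peaks:
            if w <= 0:
                raise ValueError("peak width must be > 0")
            if a < 0:
                raise ValueError("peak area must be >= 0")
        if self.total_area <= 0:
            raise ValueError("total_area must be > 0")


def make_profile(spec: ProfileSpec) -> SigmaProfile:
    """Sample the Gaussian mixture on the grid, rescale to total_area."""
    p = np.zeros_like(SIGMA_GRID)
    for center, width, area in spec.peaks:
        p += area * np.exp(-0.5 * ((SIGMA_GRID - center) / width) ** 2)
    p = np.clip(p, 0.0, None)
    s = p.sum()
    if s <= 0:
        raise ValueError("spec generated an empty profile")
    return SigmaProfile(p * (spec.total_area / s))


def water_like_profile(total_area: float = 43.0) -> SigmaProfile:
    """Narrow bimodal polar profile: strong donor and acceptor wings."""
    return make_profile(ProfileSpec(
        peaks=((-0.016, 0.004, 1.0), (0.0, 0.004, 0.5), (0.016, 0.004, 1.0)),
        total_area=total_area))


def alkane_like_profile(total_area: float = 150.0) -> SigmaProfile:
    """Apolar profile: all surface near sigma = 0."""
    return make_profile(ProfileSpec(
        peaks=((0.0, 0.005, 1.0),), total_area=total_area))


def amide_like_profile(total_area: float = 160.0) -> SigmaProfile:
    """Default synthetic solute: HB donor peak, acceptor peak, apolar bulk."""
    return make_profile(ProfileSpec(
        peaks=((-0.018, 0.004, 0.5), (0.0, 0.006, 2.0), (0.014, 0.004, 0.6)),
        total_area=total_area))


def _noisy(x: np.ndarray, noise_cv: float, rng: np.random.Generator
           ) -> np.ndarray:
    """Multiplicative log-normal noise with coefficient of variation cv."""
    if noise_cv == 0.0:
        return x
    sigma = np.sqrt(np.log1p(noise_cv ** 2))
    return x * rng.lognormal(-0.5 * sigma ** 2, sigma, size=x.shape)


def make_lambda_h_dataset(params: LambdaHParams, temperatures,
                          noise_cv: float = 0.0, seed: int = 0,
                          solute_id: str = "synthetic_solute",
                          solvent_id: str = "synthetic_solvent",
                          outlier_idx: tuple[int, ...] = (),
                          outlier_factor: float = 1.5
                          ) -> tuple[Dataset, LambdaHParams]:
    """Solubility records drawn from a known λh ground truth.

    ``outlier_idx`` plants gross outliers by multiplying those records'
    mole fractions by ``outlier_factor`` (a 1.5 factor is a ~50%
    percentage error, far beyond the 10% curation threshold).
    """
    rng = np.random.default_rng(seed)
    temps = np.asarray(temperatures, float)
    x = np.atleast_1d(lambda_h_predict(params, temps)).astype(float)
    x = _noisy(x, noise_cv, rng)
    x[list(outlier_idx)] *= outlier_factor
    x = np.clip(x, 1e-12, 1.0)
    recs = [SolubilityRecord(solute_id=solute_id, solvent1_id=solvent_id,
                             solvent2_id="", x2_star=1.0,
                             temperature=float(T), x_solute=float(xx),
                             source="measured")
            for T, xx in zip(temps, x)]
    return Dataset(recs, provenance=f"synthetic lambda-h seed={seed}"), params


def make_ja_dataset(params: JouybanAcreeParams, compositions, temperatures,
                    noise_cv: float = 0.0, seed: int = 0,
                    solute_id: str = "synthetic_solute",
                    solvent1_id: str = "organic", solvent2_id: str = "water",
                    outlier_idx: tuple[int, ...] = (),
                    outlier_factor: float = 1.5
                    ) -> tuple[Dataset, JouybanAcreeParams]:
    """Records on a composition × temperature grid from known J's."""
    rng = np.random.default_rng(seed)
    recs = []
    x_list, meta = [], []
    for x2 in np.asarray(compositions, float):
        for T in np.asarray(temperatures, float):
            lnx = jouyban_acree_predict(params, x2, T)
            x_list.append(np.exp(lnx))
            meta.append((x2, T))
    x_arr = _noisy(np.array(x_list), noise_cv, rng)
    x_arr[list(outlier_idx)] *= outlier_factor
    x_arr = np.clip(x_arr, 1e-12, 1.0)
    for (x2, T), xx in zip(meta, x_arr):
        recs.append(SolubilityRecord(
            solute_id=solute_id, solvent1_id=solvent1_id,
            solvent2_id=solvent2_id if x2 < 1.0 else "",
            x2_star=float(x2), temperature=float(T), x_solute=float(xx),
            source="measured"))
    return Dataset(recs, provenance=f"synthetic JA seed={seed}"), params


def _linear_target(d: np.ndarray) -> np.ndarray:
    w = np.array([2.0, -1.0, 0.8, -0.5, 0.6, -0.4, 0.3, -0.2])
    return -3.0 + d @ w


def _smooth_target(d: np.ndarray) -> np.ndarray:
    """A curved but well-conditioned map onto realistic log10 x values."""
    return (-2.5 + 1.5 * np.tanh(2.0 * d[:, 0] - 1.0)
            + 0.8 * d[:, 1] * d[:, 2] - 0.6 * d[:, 3] ** 2
            + 0.4 * np.sin(np.pi * d[:, 4]) + 0.3 * d[:, 5]
            - 0.2 * d[:, 6] + 0.1 * d[:, 7])


TARGET_FUNCTIONS = {"linear": _linear_target, "smooth": _smooth_target}


def make_descriptor_table(n: int, target_fn: str = "smooth",
                          noise_sd: float = 0.03, seed: int = 0
                          ) -> tuple[np.ndarray, np.ndarray]:
    """(descriptors, targets): 8 uniform columns + f(descriptors) + noise.

    Targets are log10 mole fractions (<= 0 by construction of the named
    functions); ``noise_sd`` is additive Gaussian noise in log10 units.
    """
    if n < 50:
        raise ValueError("need n >= 50")
    if target_fn not in TARGET_FUNCTIONS:
        raise ValueError(f"unknown target function {target_fn!r}")
    rng = np.random.default_rng(seed)
    d = rng.uniform(0.0, 1.0, size=(n, 8))
    y = TARGET_FUNCTIONS[target_fn](d)
    y = y + rng.normal(0.0, noise_sd, size=n) if noise_sd > 0 else y
    return d, y
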