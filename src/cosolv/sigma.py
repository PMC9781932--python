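"""σ-profile algebra, σ-potentials and the two molecular-descriptor families.

A σ-profile P(σ) is the histogram of a molecule's COSMO screening-charge
density over its surface: area [Å²] per charge-density bin [e/Å²].  From
the (mixture) profile the σ-potential μ_s(σ) follows as the self-consistent
chemical-potential cost of placing a surface patch of polarity σ in that
environment:

    μ(σ) = −(RT/a_eff)·ln Σ_σ′ P̂(σ′)·exp{(a_eff/RT)·[μ(σ′) − e(σ,σ′)]}

with P̂ the area-normalised profile and e(σ,σ′) the pairwise contact
energy (misfit + hydrogen bond + dispersion).  Solved by damped
successive substitution.

Two descriptor families are derived:

* affinity descriptors HBA / HBD / HYD — band averages of μ over the
  electronegative (σ ∈ [−0.03, −0.01]), electropositive ([0.01, 0.03])
  and near-neutral ([−0.01, 0.01]) ranges, taken as solute-inverted
  minus solvent differences so that complementarity (donor vs acceptor)
  is scored;
* energy descriptors — the solute's total interaction energy and the
  relative misfit / H-bond / van der Waals shares (which close to 1).
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace

import numpy as np

from .constants import R_GAS

__all__ = [
    "SIGMA_GRID", "BANDS", "SigmaProfile", "CosmoParameterSet",
    "SigmaPotential", "AffinityDescriptors", "EnergyDescriptors",
    "DescriptorVector", "DESCRIPTOR_NAMES",
    "load_sigma_profile", "save_sigma_profile", "mix_profiles",
    "contact_energy", "sigma_potential", "band_value",
    "affinity_descriptors", "interaction_energies", "energy_descriptors",
    "descriptor_vector", "minmax_normalize",
]

#: internal uniform grid, e/Å² (covers the descriptor bands with margin)
SIGMA_GRID = np.round(np.arange(-0.035, 0.035 + 1e-12, 0.001), 10)

#: descriptor bands [σ_lo, σ_hi], e/Å²
BANDS = {
    "HBA": (-0.030, -0.010),   # affinity for HB donors (electronegative σ)
    "HBD": (0.010, 0.030),     # affinity for HB acceptors (electropositive σ)
    "HYD": (-0.010, 0.010),    # hydrophobicity (near-neutral σ)
}

DESCRIPTOR_NAMES = ["log10x_cosmo", "HBA", "HBD", "HYD",
                    "dE_tot", "dE_HB", "dE_vdW", "dE_misfit"]


class ProfileFormatError(ValueError):
    pass


class ConvergenceError(RuntimeError):
    pass


@dataclass(frozen=True)
class SigmaProfile:
    """Charge-density histogram on the standard uniform grid.

    ``p[i]`` is the surface area [Å²] in the bin centred at
    ``SIGMA_GRID[i]``; ``total_area`` is their sum.
    """

    p: np.ndarray
    sigma: np.ndarray = field(default_factory=lambda: SIGMA_GRID.copy())

    def __post_init__(self) -> None:
        object.__setattr__(self, "p", np.asarray(self.p, dtype=float))
        object.__setattr__(self, "sigma", np.asarray(self.sigma, dtype=float))
        if self.p.shape != self.sigma.shape:
            raise ProfileFormatError("p and sigma grids differ in length")
        if np.any(self.p < -1e-12):
            raise ProfileFormatError("negative area in sigma profile")
        if self.total_area <= 0:
            raise ProfileFormatError("profile has no surface area")

    @property
    def total_area(self) -> float:
        return float(np.sum(self.p))

    @property
    def weights(self) -> np.ndarray:
        """Area-normalised probability weights P̂(σ)."""
        return self.p / self.total_area

    def band_mass(self, lo: float, hi: float) -> float:
        m = (self.sigma >= lo - 1e-12) & (self.sigma <= hi + 1e-12)
        return float(np.sum(self.p[m]))

    def inverted(self) -> "SigmaProfile":
        """Mirror image P(−σ) (grid is symmetric about zero)."""
        return SigmaProfile(self.p[::-1].copy(), self.sigma)


@dataclass(frozen=True)
class CosmoParameterSet:
    """Interaction parameters for the contact-energy expressions.

    All energies are kJ/mol per contact of effective area ``a_eff``.

    a_eff : Å², average contact area between two surface segments
    alpha_prime : kJ/mol / (e/Å²)², misfit (electrostatic) prefactor
    c_hb : kJ/mol / (e/Å²), hydrogen-bond prefactor (> 0; the min-cascade
        bracket is <= 0, so E_HB <= 0)
    sigma_hb : e/Å², polarity threshold for hydrogen bonding
    tau_vdw : kJ/mol/Å², effective dispersion coefficient (a single
        value stands in for element-specific ones)
    hb_variant : "cascade" uses min(0, min(0, σ_don+σ_hb),
        min(0, σ_acc−σ_hb)); "product" uses the alternative
        min(0, σ_don+σ_hb)·max(0, σ_acc−σ_hb)/σ_hb form found in other
        formulations.  Default is the cascade.
    """

    a_eff: float = 6.25
    alpha_prime: float = 3000.0
    c_hb: float = 80.0
    sigma_hb: float = 0.0085
    tau_vdw: float = 0.0
    hb_variant: str = "cascade"

    def __post_init__(self) -> None:
        if self.a_eff <= 0:
            raise ValueError("a_eff must be > 0")
        if self.sigma_hb < 0:
            raise ValueError("sigma_hb must be >= 0")
        if self.hb_variant not in ("cascade", "product"):
            raise ValueError(f"unknown hb_variant {self.hb_variant!r}")


@dataclass(frozen=True)
class SigmaPotential:
    """Converged σ-potential μ(σ) [kJ/mol per contact] at one temperature."""

    mu: np.ndarray
    temperature: float
    sigma: np.ndarray = field(default_factory=lambda: SIGMA_GRID.copy())
    iterations: int = 0
    residual: float = 0.0

    def inverted(self) -> "SigmaPotential":
        """μ(−σ): the solute-side reflection used by affinity descriptors."""
        return replace(self, mu=self.mu[::-1].copy())


@dataclass(frozen=True)
class AffinityDescriptors:
    hba: float
    hbd: float
    hyd: float


@dataclass(frozen=True)
class EnergyDescriptors:
    e_tot: float
    de_misfit: float
    de_hb: float
    de_vdw: float
    defined: bool = True


@dataclass(frozen=True)
class DescriptorVector:
    """The ordered 8-descriptor model input."""

    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (8,):
            raise ValueError("descriptor vector must have exactly 8 entries")
        object.__setattr__(self, "values", v)

    def as_dict(self) -> dict[str, float]:
        return dict(zip(DESCRIPTOR_NAMES, map(float, self.values)))


# --------------------------------------------------------------------------
# profile I/O and algebra
# --------------------------------------------------------------------------

def _rebin_conserving(src_sigma: np.ndarray, src_p: np.ndarray,
                      dst_sigma: np.ndarray) -> np.ndarray:
    """Area-conserving rebinning via the cumulative-area curve.

    Bin edges are taken midway between centres; the cumulative area is
    interpolated onto the destination edges and differenced, so the total
    area is conserved exactly for any destination grid covering the
    source support.
    """
    def edges(centres):
        mid = 0.5 * (centres[1:] + centres[:-1])
        first = centres[0] - (mid[0] - centres[0])
        last = centres[-1] + (centres[-1] - mid[-1])
        return np.concatenate([[first], mid, [last]])

    if len(src_sigma) == 1:  # single bin: put everything in nearest dst bin
        out = np.zeros_like(dst_sigma)
        out[np.argmin(np.abs(dst_sigma - src_sigma[0]))] = src_p[0]
        return out
    src_e = edges(src_sigma)
    dst_e = edges(dst_sigma)
    cum = np.concatenate([[0.0], np.cumsum(src_p)])
    cum_at = np.interp(dst_e, src_e, cum, left=0.0, right=cum[-1])
    return np.diff(cum_at)


def load_sigma_profile(path_or_buf) -> SigmaProfile:
    """Read a two-column (σ [e/Å²], p(σ) [Å²]) text profile.

    Whitespace- or tab-separated; ``#`` comments allowed.  The profile is
    rebinned onto the standard internal grid conservatively (total area
    preserved to well below 0.1%).
    """
    if hasattr(path_or_buf, "read"):
        text = path_or_buf.read()
    else:
        with open(path_or_buf) as fh:
            text = fh.read()
    rows = []
    for ln in text.splitlines():
        ln = ln.split("#", 1)[0].strip()
        if not ln:
            continue
        parts = ln.replace(",", " ").split()
        if len(parts) < 2:
            raise ProfileFormatError(f"bad profile line: {ln!r}")
        rows.append((float(parts[0]), float(parts[1])))
    if not rows:
        raise ProfileFormatError("empty sigma-profile file")
    arr = np.array(rows)
    sig, p = arr[:, 0], arr[:, 1]
    if np.any(np.diff(sig) <= 0):
        raise ProfileFormatError("sigma column must be strictly increasing")
    if np.any(p < 0):
        raise ProfileFormatError("negative p(sigma) in profile")
    support = sig[p > 0]
    if support.size and (support.min() < SIGMA_GRID[0] - 5e-4
                         or support.max() > SIGMA_GRID[-1] + 5e-4):
        raise ProfileFormatError(
            "profile support extends beyond the internal grid "
            f"[{SIGMA_GRID[0]}, {SIGMA_GRID[-1]}] e/A^2")
    return SigmaProfile(_rebin_conserving(sig, p, SIGMA_GRID))


def save_sigma_profile(profile: SigmaProfile, path) -> None:
    with open(path, "w") as fh:
        fh.write("# sigma [e/A^2]  p(sigma) [A^2]\n")
        for s, p in zip(profile.sigma, profile.p):
            fh.write(f"{s: .4f} {p:.10g}\n")


def mix_profiles(components: list[tuple[SigmaProfile, float]]) -> SigmaProfile:
    """Mole-fraction-weighted sum of σ-profiles.

    Fractions must be >= 0 and sum to 1 within 1e−9.  The mixture's total
    area is the composition-weighted mean of the component areas.
    """
    if not components:
        raise ValueError("no components to mix")
    fracs = np.array([f for _, f in components], dtype=float)
    if np.any(fracs < 0) or abs(fracs.sum() - 1.0) > 1e-9:
        raise ValueError(f"mole fractions {fracs} must be >= 0 and sum to 1")
    p = np.zeros_like(SIGMA_GRID)
    for prof, f in components:
        if prof.p.shape != p.shape:
            raise ValueError("profiles must share the standard grid")
        p = p + f * prof.p
    return SigmaProfile(p)


# --------------------------------------------------------------------------
# contact energies and the sigma-potential
# --------------------------------------------------------------------------

def contact_energy(sigma, sigma_prime, params: CosmoParameterSet):
    """Pairwise contact energies (E_misfit, E_HB, E_vdW) [kJ/mol].

    E_misfit = a_eff·(α′/2)·(σ+σ′)²  >= 0
    E_HB     = a_eff·c_hb·min(0, σ_don+σ_hb) when σ_acc > σ_hb, else 0
               (σ_don = min(σ,σ′), σ_acc = max(σ,σ′)); always <= 0
    E_vdW    = a_eff·(τ + τ′) = 2·a_eff·τ_vdw — independent of σ.

    Inputs broadcast; returns a triple of arrays (or floats).
    """
    s = np.asarray(sigma, dtype=float)
    sp = np.asarray(sigma_prime, dtype=float)
    e_mf = params.a_eff * (params.alpha_prime / 2.0) * (s + sp) ** 2
    s_don = np.minimum(s, sp)
    s_acc = np.maximum(s, sp)
    don = np.minimum(0.0, s_don + params.sigma_hb)
    if params.hb_variant == "cascade":
        # the acceptor-side min acts as a gate: the term vanishes unless
        # the acceptor patch exceeds +sigma_hb, however negative the
        # donor; the donor excess then sets the magnitude
        bracket = np.where(s_acc > params.sigma_hb, don, 0.0)
    else:  # product variant used by other formulations
        acc_pos = np.maximum(0.0, s_acc - params.sigma_hb)
        bracket = np.minimum(0.0, don * acc_pos
                             / max(params.sigma_hb, 1e-300))
    e_hb = params.a_eff * params.c_hb * bracket
    e_vdw = np.broadcast_to(2.0 * params.a_eff * params.tau_vdw,
                            np.broadcast_shapes(s.shape, sp.shape)).copy()
    if np.ndim(sigma) == 0 and np.ndim(sigma_prime) == 0:
        return float(e_mf), float(e_hb), float(e_vdw)
    return e_mf, e_hb, e_vdw


def _energy_matrix(params: CosmoParameterSet) -> np.ndarray:
    """e(σ, σ′) over the grid × grid; symmetric."""
    s = SIGMA_GRID[:, None]
    sp = SIGMA_GRID[None, :]
    e_mf, e_hb, e_vdw = contact_energy(s, sp, params)
    return e_mf + e_hb + e_vdw


def sigma_potential(profile: SigmaProfile, temperature: float,
                    params: CosmoParameterSet | None = None,
                    tol: float = 1e-8, max_iter: int = 500,
                    damping: float = 0.5) -> SigmaPotential:
    """Solve the σ-potential fixed point for a (mixture) profile.

    Damped successive substitution starting from μ = 0; converged when
    max|Δμ| < tol·RT.  RT is in kJ/mol.
    """
    if temperature <= 0:
        raise ValueError("temperature must be > 0 K")
    params = params or CosmoParameterSet()
    rt = R_GAS * temperature / 1000.0  # kJ/mol
    # μ and e are both carried per contact segment (area a_eff), so the
    # a_eff/RT of the per-area formulation cancels to 1/RT here
    beta = 1.0 / rt
    w = profile.weights  # P̂(σ′), sums to 1
    e = _energy_matrix(params)

    mu = np.zeros_like(SIGMA_GRID)
    prev_resid = np.inf
    for it in range(1, max_iter + 1):
        # log-sum-exp over σ′ for each σ row
        z = beta * (mu[None, :] - e)
        zmax = z.max(axis=1, keepdims=True)
        log_integral = zmax[:, 0] + np.log(np.sum(
            w[None, :] * np.exp(z - zmax), axis=1))
        mu_new = -rt * log_integral
        mu_next = (1.0 - damping) * mu + damping * mu_new
        resid = float(np.max(np.abs(mu_next - mu)))
        mu = mu_next
        # geometric estimate of the distance still to go: with observed
        # contraction rho, the remaining tail is ~ resid*rho/(1-rho)
        rho = min(resid / prev_resid if prev_resid > 0 else 0.0, 0.95)
        remaining = resid * rho / (1.0 - rho)
        prev_resid = resid
        if it > 1 and max(resid, remaining) < 0.25 * tol * rt:
            return SigmaPotential(mu=mu, temperature=temperature,
                                  iterations=it, residual=resid)
    raise ConvergenceError(
        f"sigma-potential not converged in {max_iter} iterations "
        f"(last residual {resid:.3e} kJ/mol)")


def band_value(potential: SigmaPotential, band: tuple[float, float]) -> float:
    """Arithmetic mean of μ over the closed σ band."""
    lo, hi = band
    m = (potential.sigma >= lo - 1e-12) & (potential.sigma <= hi + 1e-12)
    if not np.any(m):
        raise ValueError(f"band [{lo}, {hi}] contains no grid points")
    return float(np.mean(potential.mu[m]))


def affinity_descriptors(solute_potential: SigmaPotential,
                         solvent_potential: SigmaPotential,
                         bands: dict | None = None) -> AffinityDescriptors:
    """Relative HBA / HBD / HYD from solute (inverted) vs solvent potentials.

    The solute potential is σ-inverted (μ(−σ)) so that its donor face is
    scored against the solvent's acceptor band and vice versa:

        HBD = band(μ_solute_inv, HBD) − band(μ_solvent, HBA)
        HBA = band(μ_solute_inv, HBA) − band(μ_solvent, HBD)
        HYD = band(μ_solute_inv, HYD) − band(μ_solvent, HYD)
    """
    if solute_potential.mu.shape != solvent_potential.mu.shape \
            or not np.allclose(solute_potential.sigma,
                               solvent_potential.sigma):
        raise ValueError("potentials must share one grid")
    if abs(solute_potential.temperature
           - solvent_potential.temperature) > 1e-9:
        raise ValueError("potentials must share one temperature")
    bands = bands or BANDS
    inv = solute_potential.inverted()
    hbd = band_value(inv, bands["HBD"]) - band_value(solvent_potential,
                                                     bands["HBA"])
    hba = band_value(inv, bands["HBA"]) - band_value(solvent_potential,
                                                     bands["HBD"])
    hyd = band_value(inv, bands["HYD"]) - band_value(solvent_potential,
                                                     bands["HYD"])
    return AffinityDescriptors(hba=hba, hbd=hbd, hyd=hyd)


# --------------------------------------------------------------------------
# energy descriptors
# --------------------------------------------------------------------------

def interaction_energies(solute: SigmaProfile, partner: SigmaProfile,
                         params: CosmoParameterSet | None = None
                         ) -> tuple[float, float, float]:
    """Profile-averaged (E_misfit, E_HB, E_vdW) per solute–partner contact.

    Double sum over both profiles' probability weights; a coarse ensemble
    average of the pairwise contact energies.
    """
    params = params or CosmoParameterSet()
    e_mf, e_hb, e_vdw = contact_energy(SIGMA_GRID[:, None],
                                       SIGMA_GRID[None, :], params)
    ws = solute.weights[:, None] * partner.weights[None, :]
    return (float(np.sum(ws * e_mf)), float(np.sum(ws * e_hb)),
            float(np.sum(ws * e_vdw)))


def energy_descriptors(component_energies: list[tuple[float, float, float]],
                       composition: list[float]) -> EnergyDescriptors:
    """Relative energy contributions, composition-averaged over components.

    Per component i the shares are ΔE_j = E_j / Σ_j E_j (closing to 1
    whenever the denominator is nonzero); the mixture descriptor is the
    mole-fraction-weighted sum, and e_tot is the weighted total energy.
    A zero denominator is flagged: shares are set to 0 with
    ``defined=False``.
    """
    comp = np.asarray(composition, dtype=float)
    if len(component_energies) == 0:
        raise ValueError("need at least one component")
    if len(component_energies) != len(comp):
        raise ValueError("composition length mismatch")
    if np.any(comp < 0) or abs(comp.sum() - 1.0) > 1e-9:
        raise ValueError("composition must be >= 0 and sum to 1")

    e = np.asarray(component_energies, dtype=float)  # (n, 3): mf, hb, vdw
    totals = e.sum(axis=1)
    defined = True
    shares = np.zeros_like(e)
    for i, tot in enumerate(totals):
        if tot == 0.0:
            defined = False
        else:
            shares[i] = e[i] / tot
    mix_share = comp @ shares
    e_tot = float(comp @ totals)
    return EnergyDescriptors(e_tot=e_tot,
                             de_misfit=float(mix_share[0]),
                             de_hb=float(mix_share[1]),
                             de_vdw=float(mix_share[2]),
                             defined=defined)


def descriptor_vector(solute_profile: SigmaProfile,
                      solvent_components: list[tuple[SigmaProfile, float]],
                      temperature: float,
                      computed_log_solubility: float,
                      params: CosmoParameterSet | None = None,
                      bands: dict | None = None) -> DescriptorVector:
    """Assemble the ordered 8-descriptor model input for one system.

    [log10 x_COSMO, HBA, HBD, HYD, ΔE_tot, ΔE_HB, ΔE_vdW, ΔE_misfit]

    ``solvent_components`` are (profile, solute-free mole fraction) pairs.
    Solvent-side potentials are computed for the solute-free mixture (the
    infinite-dilution limit); the energy descriptors are composition-
    weighted relative contributions of the solute's contact energies with
    each solvent component.  ``computed_log_solubility`` is supplied by
    the caller (typically the iterative saturation estimate).  ΔE_tot is
    carried as the raw solute total energy; like every other column it is
    min-max normalised per dataset before model training.
    """
    params = params or CosmoParameterSet()
    solvent_mix = mix_profiles(solvent_components)
    mu_solvent = sigma_potential(solvent_mix, temperature, params)
    mu_solute = sigma_potential(solute_profile, temperature, params)
    aff = affinity_descriptors(mu_solute, mu_solvent, bands)
    comp_e = [interaction_energies(solute_profile, prof, params)
              for prof, _ in solvent_components]
    fracs = [f for _, f in solvent_components]
    en = energy_descriptors(comp_e, fracs)
    return DescriptorVector(np.array([
        computed_log_solubility, aff.hba, aff.hbd, aff.hyd,
        en.e_tot, en.de_hb, en.de_vdw, en.de_misfit,
    ]))


def minmax_normalize(table: np.ndarray,
                     bounds: tuple[np.ndarray, np.ndarray] | None = None):
    """Column-wise min-max scaling to [0, 1]; returns (scaled, (lo, hi)).

    Constant columns map to 0.  When ``bounds`` is given it is applied
    instead of being estimated (used to freeze training-set scaling).
    """
    t = np.asarray(table, dtype=float)
    if bounds is None:
        lo, hi = t.min(axis=0), t.max(axis=0)
    else:
        lo, hi = bounds
    span = np.where(hi > lo, hi - lo, 1.0)
    return (t - lo) / span, (lo, hi)
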