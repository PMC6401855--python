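"""Reported quantities derived from a converged brush solution.

Bound ions per chain, the deprotonated polymer fraction profile, the local
pH, per-species volume fractions, and a first-moment brush height. "Inside
the brush" means layers where the polymer volume fraction exceeds 1e-4 of
its maximum — a reproducible region definition for prose-level summaries.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass

import numpy as np

from .chemistry import M_TO_NM3
from .core import SCFTSolution

__all__ = [
    "StatePointReport",
    "bound_ions_per_chain",
    "bound_mg_per_chain",
    "deprotonated_fraction_profile",
    "local_ph_profile",
    "volume_fraction_profiles",
    "brush_height",
    "brush_region",
    "build_report",
]

BRUSH_THRESHOLD = 1e-4


def _require_polymer(solution: SCFTSolution) -> None:
    if solution.problem is None or solution.problem.sigma_p <= 0:
        raise ValueError("observable undefined without grafted polymer")


def bound_ions_per_chain(solution: SCFTSolution, state: str) -> float:
    """Average number of monomers per chain in a given state.

    ``state`` is one of 'free' (bare deprotonated), 'H', 'Na', 'Mg'.
    Uses the monomer-number-density form N = dz sum_k sum_i <rho_i> f_i,state
    / sigma_p, which is exact irrespective of the state volumes.
    """
    _require_polymer(solution)
    p = solution.problem
    f = solution.fractions
    dens = solution.rho_A * f.A[state] + solution.rho_G * f.G[state]
    return float(p.grid.dz * dens.sum() / p.sigma_p)


def bound_mg_per_chain(solution: SCFTSolution) -> float:
    """Number of chain-bound Mg2+ ions per grafted chain."""
    return bound_ions_per_chain(solution, "Mg")


def deprotonated_fraction_profile(solution: SCFTSolution) -> np.ndarray:
    """Volume-weighted deprotonated (bare negative) monomer fraction f_P-(z).

    Layers without polymer are reported as NaN (missing), not zero.
    """
    _require_polymer(solution)
    p = solution.problem
    f = solution.fractions

    def phi_type(rho_m, fm):
        return rho_m * sum(fm[s] * p.state_volume[s] for s in p.state_volume)

    phi_A = phi_type(solution.rho_A, f.A)
    phi_G = phi_type(solution.rho_G, f.G)
    phi_p = phi_A + phi_G
    out = np.full(p.grid.n_layers, np.nan)
    mask = phi_p > 0
    out[mask] = (f.A["free"] * phi_A + f.G["free"] * phi_G)[mask] / phi_p[mask]
    return out


def local_ph_profile(solution: SCFTSolution) -> np.ndarray:
    """pH(z) = -log10 of the local molar H+ concentration."""
    rho_H = solution.rho["H"]
    if np.any(rho_H <= 0):
        raise ValueError("H+ density must be positive everywhere")
    return -np.log10(rho_H / M_TO_NM3)


def volume_fraction_profiles(solution: SCFTSolution) -> dict:
    """Per-layer volume fractions phi_gamma = rho_gamma v_gamma plus polymer."""
    cat = solution.problem.bulk.catalog
    out = {s: solution.rho[s] * cat.volume[s] for s in solution.rho}
    out["polymer"] = solution.phi_p
    return out


def brush_region(solution: SCFTSolution, threshold: float = BRUSH_THRESHOLD) -> np.ndarray:
    """Boolean mask of layers where phi_p exceeds threshold * max(phi_p)."""
    phi = solution.phi_p
    if not np.any(phi > 0):
        raise ValueError("no polymer present")
    return phi > threshold * phi.max()


def brush_height(solution: SCFTSolution) -> float:
    """First-moment height h = 2 * <z>_phi of the polymer profile, nm."""
    phi = solution.phi_p
    if not np.any(phi > 0):
        raise ValueError("no polymer present")
    z = solution.problem.grid.centers
    return float(2.0 * np.sum(z * phi) / np.sum(phi))


@dataclass
class StatePointReport:
    """Scalar summary of one converged state point."""

    sequence: str
    sigma_p: float
    c_mgcl2_M: float
    c_nacl_M: float
    pH_bulk: float
    T: float
    n_mg_per_chain: float
    n_na_per_chain: float
    n_h_per_chain: float
    n_deprotonated_per_chain: float
    brush_height_nm: float
    ph_min: float
    ph_min_z_nm: float
    ph_max: float
    ph_max_z_nm: float
    phi_p_peak: float
    phi_p_peak_z_nm: float
    max_deprotonated_fraction: float
    residual_norm: float
    n_iter: int
    converged: bool
    seed: int | None = None
    n_conformations: int | None = None

    def to_dict(self) -> dict:
        return asdict(self)


def build_report(
    solution: SCFTSolution,
    sequence: str,
    c_mgcl2_M: float,
    c_nacl_M: float,
    seed: int | None = None,
) -> StatePointReport:
    """Assemble the scalar observables of one state point."""
    p = solution.problem
    z = p.grid.centers
    ph = local_ph_profile(solution)
    has_polymer = p.sigma_p > 0 and np.any(solution.phi_p > 0)
    if has_polymer:
        mask = brush_region(solution)
        fpm = deprotonated_fraction_profile(solution)
        fpm_brush = fpm[mask & np.isfinite(fpm)]
        height = brush_height(solution)
    else:
        mask = np.ones(p.grid.n_layers, dtype=bool)
        fpm_brush = np.array([])
        height = float("nan")
    ph_brush = np.where(mask, ph, p.bulk.pH)
    i_min = int(np.argmin(ph_brush))
    i_max = int(np.argmax(ph_brush))
    i_peak = int(np.argmax(solution.phi_p))
    return StatePointReport(
        sequence=sequence,
        sigma_p=p.sigma_p,
        c_mgcl2_M=c_mgcl2_M,
        c_nacl_M=c_nacl_M,
        pH_bulk=p.bulk.pH,
        T=p.bulk.T,
        n_mg_per_chain=bound_ions_per_chain(solution, "Mg") if has_polymer else 0.0,
        n_na_per_chain=bound_ions_per_chain(solution, "Na") if has_polymer else 0.0,
        n_h_per_chain=bound_ions_per_chain(solution, "H") if has_polymer else 0.0,
        n_deprotonated_per_chain=bound_ions_per_chain(solution, "free") if has_polymer else 0.0,
        brush_height_nm=height,
        ph_min=float(ph_brush[i_min]),
        ph_min_z_nm=float(z[i_min]),
        ph_max=float(ph_brush[i_max]),
        ph_max_z_nm=float(z[i_max]),
        phi_p_peak=float(solution.phi_p[i_peak]),
        phi_p_peak_z_nm=float(z[i_peak]),
        max_deprotonated_fraction=float(fpm_brush.max()) if fpm_brush.size else float("nan"),
        residual_norm=solution.residual_norm,
        n_iter=solution.n_iter,
        converged=solution.converged,
        seed=seed,
        n_conformations=p.ensemble.n_conformations,
    )
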