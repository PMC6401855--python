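"""Coupled SCFT field equations for the grafted oligomer brush.

Two unknown fields live on the layer grid: the lateral-pressure (packing)
field pi(z), in kT/nm^3, enforcing that the species volume fractions fill
every layer exactly, and the electrostatic potential psi(z), in kT/e,
obeying the discretized Poisson equation. Both are gauged to vanish in the
bulk. Everything else — free-species densities, monomer-state fractions,
conformation weights — follows from (pi, psi) in closed form:

* rho_gamma(z) = rho_gamma^b exp(-pi v_gamma - z_gamma psi)        (Boltzmann)
* f_bound/f_free = K0 rho_ion(z) v_w  per binding branch           (mass action)
* P(alpha) ∝ g_alpha exp(-sum_k n_i(alpha;k) w_i(k)),
  w_i = ln f_i-(k) + pi(k) v_p - psi(k) relative to its bulk value (chain pdf)

The residual vector stacks the per-layer packing violation and the Poisson
residual; a damped Newton iteration with a finite-difference Jacobian and an
Armijo line search drives it below tolerance, with geometric continuation in
grafting density for crowded brushes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.linalg

from .chains import ConformationEnsemble
from .chemistry import BindingConstants, BulkState, bjerrum_length
from .grid import Grid

__all__ = [
    "FieldState",
    "MonomerFractions",
    "SCFTProblem",
    "SCFTSolution",
    "species_density_profiles",
    "monomer_state_fractions",
    "conformation_weights",
    "average_monomer_densities",
    "charge_density",
    "residual_vector",
    "solve_fields",
    "grand_potential_per_area",
]

#: exponent clip bound for Boltzmann factors during early iterations
EXP_CLIP = 500.0

#: default monomer (deprotonated reference state) volume, nm^3
V_MONOMER = 0.30

ION_BRANCHES = ("H", "Na", "Mg")
STATES = ("free", "H", "Na", "Mg")  # free = bare deprotonated site


@dataclass
class FieldState:
    """The two unknown fields on the layer grid, bulk-gauged to zero."""

    pi: np.ndarray
    psi: np.ndarray

    @classmethod
    def zeros(cls, grid: Grid) -> "FieldState":
        return cls(pi=np.zeros(grid.n_layers), psi=np.zeros(grid.n_layers))

    def pack(self) -> np.ndarray:
        return np.concatenate([self.pi, self.psi])

    @classmethod
    def unpack(cls, x: np.ndarray) -> "FieldState":
        n = x.size // 2
        return cls(pi=np.asarray(x[:n], dtype=float), psi=np.asarray(x[n:], dtype=float))

    def copy(self) -> "FieldState":
        return FieldState(self.pi.copy(), self.psi.copy())


@dataclass
class MonomerFractions:
    """Per-layer state fractions for both monomer types.

    ``A`` and ``G`` are dicts mapping state name ('free', 'H', 'Na', 'Mg')
    to an array over layers; the four fractions sum to one per layer by
    construction of the closed-form normalization.
    """

    A: dict
    G: dict

    def for_type(self, mono: str) -> dict:
        return self.A if mono == "A" else self.G


@dataclass
class SCFTSolution:
    """Converged fields plus every derived profile."""

    fields: FieldState
    rho: dict  # free-species density profiles, nm^-3
    fractions: MonomerFractions
    P: np.ndarray  # probability per distinct occupancy class, sums to 1
    rho_A: np.ndarray  # average monomer number densities, nm^-3
    rho_G: np.ndarray
    phi_p: np.ndarray  # ensemble-average polymer volume fraction
    rho_q: np.ndarray  # ensemble-average charge density, e/nm^3
    residual_norm: float
    n_iter: int
    converged: bool
    problem: "SCFTProblem | None" = None
    residual_history: list = field(default_factory=list)


class SCFTProblem:
    """One state point: sequence ensemble + bulk + constants + grafting density.

    Precomputes the sparse occupancy matrices and bulk reference quantities so
    that residual evaluations are cheap, and supports batched evaluation over
    many field vectors at once (used for the finite-difference Jacobian).
    """

    def __init__(
        self,
        ensemble: ConformationEnsemble,
        bulk: BulkState,
        constants: BindingConstants,
        sigma_p: float,
        v_monomer: float = V_MONOMER,
        monomer_charge: float = -1.0,
    ) -> None:
        if sigma_p < 0:
            raise ValueError("grafting density must be >= 0")
        if ensemble.n_distinct == 0:
            raise ValueError("empty conformation ensemble")
        self.ensemble = ensemble
        self.grid: Grid = ensemble.grid
        self.bulk = bulk
        self.constants = constants
        self.sigma_p = float(sigma_p)
        self.v_monomer = float(v_monomer)
        self.monomer_charge = float(monomer_charge)

        cat = bulk.catalog
        self.vw = cat.vw
        self.species = ("w", "H", "OH", "Na", "Mg", "Cl")
        self.valence = np.array([cat.valence[s] for s in self.species], dtype=float)
        self.volume = np.array([cat.volume[s] for s in self.species], dtype=float)
        self.rho_b = np.array([bulk.rho[s] for s in self.species])
        # reduced dielectric permittivity, e^2/(kT nm): eps~ = 1/(4 pi l_B)
        self.eps_tilde = 1.0 / (4.0 * np.pi * bjerrum_length(bulk.eps_r, bulk.T))

        ens = ensemble
        self.CA = ens.counts_A.astype(float).tocsr()
        self.CG = ens.counts_G.astype(float).tocsr()
        self.log_g = np.log(ens.multiplicity.astype(float))
        self.monomers_per_chain = {
            "A": float(ens.counts_A[0].sum() if ens.n_distinct else 0),
            "G": float(ens.counts_G[0].sum() if ens.n_distinct else 0),
        }
        # per-state volumes: bound complexes carry the summed volume of parts
        self.state_volume = {
            "free": self.v_monomer,
            "H": self.v_monomer + cat.volume["H"],
            "Na": self.v_monomer + cat.volume["Na"],
            "Mg": self.v_monomer + cat.volume["Mg"],
        }
        # per-state charges relative to the bare (deprotonated) site
        q = self.monomer_charge
        self.state_charge = {"free": q, "H": q + 1.0, "Na": q + 1.0, "Mg": q + 2.0}
        # bulk-state fractions fix the gauge of the conformation weights
        fb = self._fractions_from_densities(
            {s: np.atleast_1d(self.bulk.rho[s]) for s in ("H", "Na", "Mg")}
        )
        self.bulk_fractions = fb
        self._w_gauge = {
            "A": float(np.log(fb.A["free"][0])),
            "G": float(np.log(fb.G["free"][0])),
        }
        self.clip_events = 0

    # ------------------------------------------------------------------
    def species_densities(self, fields: FieldState) -> dict:
        """Boltzmann density profiles of the six free species (Eq.-level)."""
        expo = (
            -fields.pi[:, None] * self.volume[None, :]
            - fields.psi[:, None] * self.valence[None, :]
        )
        clipped = np.abs(expo) > EXP_CLIP
        if clipped.any():
            self.clip_events += int(clipped.sum())
            expo = np.clip(expo, -EXP_CLIP, EXP_CLIP)
        rho = self.rho_b[None, :] * np.exp(expo)
        return {s: rho[:, j] for j, s in enumerate(self.species)}

    def _fractions_from_densities(self, rho_ions: dict, pi=None) -> MonomerFractions:
        """Closed-form four-state mass-action fractions per monomer type."""
        out = {}
        for mono in ("A", "G"):
            K_H, K_Na, K_Mg = self.constants.for_type(mono)
            tH = K_H * rho_ions["H"] * self.vw
            tNa = K_Na * rho_ions["Na"] * self.vw
            tMg = K_Mg * rho_ions["Mg"] * self.vw
            denom = 1.0 + tH + tNa + tMg
            out[mono] = {
                "free": 1.0 / denom,
                "H": tH / denom,
                "Na": tNa / denom,
                "Mg": tMg / denom,
            }
        return MonomerFractions(A=out["A"], G=out["G"])

    def monomer_fractions(self, fields: FieldState, rho: dict | None = None) -> MonomerFractions:
        if rho is None:
            rho = self.species_densities(fields)
        return self._fractions_from_densities({s: rho[s] for s in ION_BRANCHES})

    def monomer_field(self, mono: str, fields: FieldState, fractions: MonomerFractions) -> np.ndarray:
        """Per-monomer conformation-weight field w_i(k), gauged to 0 in bulk."""
        f_free = fractions.for_type(mono)["free"]
        return (
            np.log(f_free)
            - self._w_gauge[mono]
            + fields.pi * self.v_monomer
            - fields.psi * (-self.monomer_charge)  # -psi for a -1 site
        )

    def conformation_logweights(self, w_A: np.ndarray, w_G: np.ndarray) -> np.ndarray:
        return self.log_g - (self.CA @ w_A + self.CG @ w_G)

    def conformation_weights(self, fields: FieldState, fractions: MonomerFractions) -> np.ndarray:
        """Normalized conformation probabilities P(alpha) via log-sum-exp."""
        lw = self.conformation_logweights(
            self.monomer_field("A", fields, fractions),
            self.monomer_field("G", fields, fractions),
        )
        lw -= lw.max()
        P = np.exp(lw)
        total = P.sum()
        if total == 0 or not np.isfinite(total):
            raise FloatingPointError("degenerate conformation weights")
        return P / total

    def average_monomer_densities(self, P: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """<rho_A>(z), <rho_G>(z) in nm^-3."""
        scale = self.sigma_p / self.grid.dz
        return scale * (self.CA.T @ P), scale * (self.CG.T @ P)

    def polymer_volume_fraction(
        self, rho_A: np.ndarray, rho_G: np.ndarray, fractions: MonomerFractions
    ) -> np.ndarray:
        phi = np.zeros(self.grid.n_layers)
        for mono, rho_m in (("A", rho_A), ("G", rho_G)):
            f = fractions.for_type(mono)
            v_eff = sum(f[s] * self.state_volume[s] for s in STATES)
            phi = phi + rho_m * v_eff
        return phi

    def charge_density(
        self,
        rho: dict,
        rho_A: np.ndarray,
        rho_G: np.ndarray,
        fractions: MonomerFractions,
    ) -> np.ndarray:
        """<rho_q>(z) in e/nm^3 (free ions + monomer states)."""
        q = sum(self.bulk.catalog.valence[s] * rho[s] for s in self.species)
        for mono, rho_m in (("A", rho_A), ("G", rho_G)):
            f = fractions.for_type(mono)
            q = q + rho_m * sum(f[s] * self.state_charge[s] for s in STATES)
        return q

    def poisson_residual(self, psi: np.ndarray, rho_q: np.ndarray) -> np.ndarray:
        """eps~ lap(psi)/dz^2 + rho_q with Neumann wall / far-field Dirichlet.

        Ghost closures: psi_{-1} = psi_0 (zero-field surface) and psi_n = 0
        one spacing beyond the last layer center.
        """
        dz2 = self.grid.dz**2
        lap = np.empty_like(psi)
        lap[0] = psi[1] - psi[0]
        lap[1:-1] = psi[:-2] - 2.0 * psi[1:-1] + psi[2:]
        lap[-1] = psi[-2] - 2.0 * psi[-1]
        return self.eps_tilde * lap / dz2 + rho_q

    # ------------------------------------------------------------------
    def residual(self, x: np.ndarray) -> np.ndarray:
        """Stacked per-layer residuals: packing block then Poisson block."""
        fields = FieldState.unpack(x)
        rho = self.species_densities(fields)
        fractions = self.monomer_fractions(fields, rho)
        if self.sigma_p > 0:
            P = self.conformation_weights(fields, fractions)
            rho_A, rho_G = self.average_monomer_densities(P)
        else:
            rho_A = rho_G = np.zeros(self.grid.n_layers)
        phi_p = self.polymer_volume_fraction(rho_A, rho_G, fractions)
        phi_free = sum(rho[s] * self.bulk.catalog.volume[s] for s in self.species)
        r_pack = phi_p + phi_free - 1.0
        rho_q = self.charge_density(rho, rho_A, rho_G, fractions)
        r_pois = self.poisson_residual(fields.psi, rho_q)
        return np.concatenate([r_pack, r_pois])

    def residual_many(self, X: np.ndarray, chunk: int = 64) -> np.ndarray:
        """Vectorized residuals for many stacked field vectors (rows of X)."""
        X = np.atleast_2d(X)
        m, n2 = X.shape
        n = n2 // 2
        out = np.empty_like(X)
        for lo in range(0, m, chunk):
            hi = min(lo + chunk, m)
            Pi = X[lo:hi, :n]
            Psi = X[lo:hi, n:]
            expo = -Pi[:, :, None] * self.volume - Psi[:, :, None] * self.valence
            np.clip(expo, -EXP_CLIP, EXP_CLIP, out=expo)
            rho = self.rho_b * np.exp(expo)  # (b, n, 6)
            frac = {}
            for mono in ("A", "G"):
                K_H, K_Na, K_Mg = self.constants.for_type(mono)
                tH = K_H * rho[:, :, 1] * self.vw
                tNa = K_Na * rho[:, :, 3] * self.vw
                tMg = K_Mg * rho[:, :, 4] * self.vw
                denom = 1.0 + tH + tNa + tMg
                frac[mono] = (1.0 / denom, tH / denom, tNa / denom, tMg / denom)
            if self.sigma_p > 0:
                qref = -self.monomer_charge
                w_A = (
                    np.log(frac["A"][0]) - self._w_gauge["A"]
                    + Pi * self.v_monomer - qref * Psi
                )
                w_G = (
                    np.log(frac["G"][0]) - self._w_gauge["G"]
                    + Pi * self.v_monomer - qref * Psi
                )
                lw = self.log_g[:, None] - (self.CA @ w_A.T + self.CG @ w_G.T)
                lw -= lw.max(axis=0, keepdims=True)
                P = np.exp(lw)
                P /= P.sum(axis=0, keepdims=True)
                scale = self.sigma_p / self.grid.dz
                rho_A = scale * (self.CA.T @ P).T  # (b, n)
                rho_G = scale * (self.CG.T @ P).T
            else:
                rho_A = rho_G = np.zeros_like(Pi)
            sv = self.state_volume
            sq = self.state_charge
            phi_p = np.zeros_like(Pi)
            q_poly = np.zeros_like(Pi)
            for mono, rho_m in (("A", rho_A), ("G", rho_G)):
                f0, fH, fNa, fMg = frac[mono]
                phi_p += rho_m * (
                    f0 * sv["free"] + fH * sv["H"] + fNa * sv["Na"] + fMg * sv["Mg"]
                )
                q_poly += rho_m * (
                    f0 * sq["free"] + fH * sq["H"] + fNa * sq["Na"] + fMg * sq["Mg"]
                )
            out[lo:hi, :n] = phi_p + rho @ self.volume - 1.0
            rho_q = rho @ self.valence + q_poly
            dz2 = self.grid.dz**2
            lap = np.empty_like(Psi)
            lap[:, 0] = Psi[:, 1] - Psi[:, 0]
            lap[:, 1:-1] = Psi[:, :-2] - 2.0 * Psi[:, 1:-1] + Psi[:, 2:]
            lap[:, -1] = Psi[:, -2] - 2.0 * Psi[:, -1]
            out[lo:hi, n:] = self.eps_tilde * lap / dz2 + rho_q
        return out

    # ------------------------------------------------------------------
    def grand_potential(self, x: np.ndarray) -> float:
        """Bulk-gauged semi-grand potential per unit area, beta W / A.

        Field-substituted form: all internal degrees of freedom (densities,
        fractions, conformation weights) sit at their own extrema, leaving

            beta W/A = -sigma_p ln(Q/G) - sum_gamma int (rho - rho_b) dz
                       - int pi dz - (eps~/2) int (dpsi/dz)^2 dz

        whose finite-difference gradient w.r.t. (pi, psi) reproduces the
        stacked residual vector times dz (envelope theorem). The squared
        gradient uses the same Neumann-wall / Dirichlet-far closures as the
        discrete Poisson operator, so the two stationarity routes agree.
        """
        fields = FieldState.unpack(x)
        dz = self.grid.dz
        rho = self.species_densities(fields)
        W = 0.0
        if self.sigma_p > 0:
            fractions = self.monomer_fractions(fields, rho)
            lw = self.conformation_logweights(
                self.monomer_field("A", fields, fractions),
                self.monomer_field("G", fields, fractions),
            )
            lmax = lw.max()
            logQ = lmax + np.log(np.exp(lw - lmax).sum())
            logG = np.log(self.ensemble.multiplicity.sum())
            W -= self.sigma_p * (logQ - logG)
        for j, s in enumerate(self.species):
            W -= dz * np.sum(rho[s] - self.rho_b[j])
        W -= dz * np.sum(fields.pi)
        psi = fields.psi
        grads = np.concatenate([np.diff(psi), [0.0 - psi[-1]]])  # far Dirichlet ghost
        W -= 0.5 * self.eps_tilde * np.sum(grads**2) / dz
        return float(W)

    def solution_from_fields(
        self, fields: FieldState, n_iter: int = 0, history=None
    ) -> SCFTSolution:
        rho = self.species_densities(fields)
        fractions = self.monomer_fractions(fields, rho)
        if self.sigma_p > 0:
            P = self.conformation_weights(fields, fractions)
            rho_A, rho_G = self.average_monomer_densities(P)
        else:
            P = self.ensemble.multiplicity / self.ensemble.multiplicity.sum()
            rho_A = rho_G = np.zeros(self.grid.n_layers)
        phi_p = self.polymer_volume_fraction(rho_A, rho_G, fractions)
        rho_q = self.charge_density(rho, rho_A, rho_G, fractions)
        r = self.residual(fields.pack())
        rnorm = float(np.abs(r).max())
        return SCFTSolution(
            fields=fields,
            rho=rho,
            fractions=fractions,
            P=P,
            rho_A=rho_A,
            rho_G=rho_G,
            phi_p=phi_p,
            rho_q=rho_q,
            residual_norm=rnorm,
            n_iter=n_iter,
            converged=rnorm <= 1e-6,
            problem=self,
            residual_history=list(history or []),
        )


# ----------------------------------------------------------------------
# spec-surface functions (thin wrappers over SCFTProblem methods)

def species_density_profiles(fields: FieldState, problem: SCFTProblem) -> dict:
    return problem.species_densities(fields)


def monomer_state_fractions(
    problem: SCFTProblem, fields: FieldState, rho: dict | None = None
) -> MonomerFractions:
    return problem.monomer_fractions(fields, rho)


def conformation_weights(
    problem: SCFTProblem, fields: FieldState, fractions: MonomerFractions
) -> np.ndarray:
    return problem.conformation_weights(fields, fractions)


def average_monomer_densities(problem: SCFTProblem, P: np.ndarray):
    rho_A, rho_G = problem.average_monomer_densities(P)
    fractions = problem.monomer_fractions(FieldState.zeros(problem.grid))
    return rho_A, rho_G, problem.polymer_volume_fraction(rho_A, rho_G, fractions)


def charge_density(problem, rho, rho_A, rho_G, fractions) -> np.ndarray:
    return problem.charge_density(rho, rho_A, rho_G, fractions)


def residual_vector(fields: FieldState, problem: SCFTProblem) -> np.ndarray:
    return problem.residual(fields.pack())


def grand_potential_per_area(problem: SCFTProblem, fields: FieldState) -> float:
    return problem.grand_potential(fields.pack())


# ----------------------------------------------------------------------
# solver

def _fd_jacobian(problem: SCFTProblem, x: np.ndarray, r0: np.ndarray) -> np.ndarray:
    n2 = x.size
    h = 1e-7 * np.maximum(1.0, np.abs(x))
    X = np.tile(x, (n2, 1))
    X[np.arange(n2), np.arange(n2)] += h
    R = problem.residual_many(X)
    return (R - r0[None, :]).T / h[None, :]


def _newton(
    problem: SCFTProblem,
    x0: np.ndarray,
    tol: float,
    max_iter: int,
    history: list,
) -> tuple[np.ndarray, bool]:
    x = x0.copy()
    r = problem.residual(x)
    rnorm = np.abs(r).max()
    for _ in range(max_iter):
        history.append(float(rnorm))
        if rnorm <= tol:
            return x, True
        J = _fd_jacobian(problem, x, r)
        try:
            step = scipy.linalg.solve(J, -r)
        except scipy.linalg.LinAlgError:
            step = np.linalg.lstsq(J, -r, rcond=None)[0]
        lam, ok = 1.0, False
        f0 = float(r @ r)
        while lam >= 1e-4:
            x_try = x + lam * step
            r_try = problem.residual(x_try)
            if np.isfinite(r_try).all() and float(r_try @ r_try) <= (1 - 1e-4 * lam) * f0:
                ok = True
                break
            lam *= 0.5
        if not ok:
            return x, False
        x, r = x_try, r_try
        rnorm = np.abs(r).max()
    history.append(float(rnorm))
    return x, rnorm <= tol


def solve_fields(
    problem: SCFTProblem,
    init: FieldState | None = None,
    tol: float = 1e-8,
    max_iter: int = 100,
) -> SCFTSolution:
    """Solve the stacked field equations by damped Newton iteration.

    Deterministic given the ensemble and the initial guess. On
    non-convergence the best iterate is returned with ``converged=False``.
    """
    x0 = (init or FieldState.zeros(problem.grid)).pack()
    history: list = []
    problem.clip_events = 0
    x, ok = _newton(problem, x0, tol, max_iter, history)
    fields = FieldState.unpack(x)
    sol = problem.solution_from_fields(fields, n_iter=len(history) - 1, history=history)
    sol.converged = ok and sol.residual_norm <= tol
    return sol


def solve_state_point(
    ensemble: ConformationEnsemble,
    bulk: BulkState,
    constants: BindingConstants,
    sigma_p: float,
    v_monomer: float = V_MONOMER,
    init: FieldState | None = None,
    tol: float = 1e-8,
    max_iter: int = 100,
) -> SCFTSolution:
    """Solve one state point with geometric continuation in grafting density.

    Crowded brushes (large sigma_p) are reached by warm-starting along an
    ascending ladder of grafting densities; each rung that fails is bisected
    (in log sigma_p) down to a minimum step.
    """

    def make(sp: float) -> SCFTProblem:
        return SCFTProblem(ensemble, bulk, constants, sp, v_monomer=v_monomer)

    if sigma_p == 0 or init is not None:
        return solve_fields(make(sigma_p), init=init, tol=tol, max_iter=max_iter)

    sigma_start = min(0.005, sigma_p)
    ladder = [sigma_start]
    while ladder[-1] < sigma_p:
        ladder.append(min(ladder[-1] * 3.2, sigma_p))

    fields = FieldState.zeros(ensemble.grid)
    sol = None
    i = 0
    while i < len(ladder):
        sp = ladder[i]
        sol = solve_fields(make(sp), init=fields, tol=tol, max_iter=max_iter)
        if sol.converged:
            fields = sol.fields
            i += 1
            continue
        prev = ladder[i - 1] if i > 0 else sigma_start / 10.0
        mid = float(np.sqrt(prev * sp))
        if not (prev * 1.0001 < mid < sp * 0.9999):
            return sol  # cannot refine further; report the failure
        ladder.insert(i, mid)
    assert sol is not None
    return sol
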