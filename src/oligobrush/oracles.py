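"""Independent small-scale references for validating the field solver.

Two oracles: closed-form non-interacting mass-action fractions at zero
fields, and a brute-force extremization of the semi-grand potential on toy
problems small enough that the fields can be found without the Newton
machinery — the scalar potential is finite-differenced and its stationary
point located with a generic root finder, never touching the analytic
residual assembly. Toy conformations are hand-written occupancy tables so
the oracle isolates the field solver from the chain generator.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.optimize

from .chains import ConformationEnsemble
from .chemistry import BindingConstants, BulkState, SpeciesCatalog, solve_bulk
from .core import FieldState, SCFTProblem
from .grid import Grid

__all__ = [
    "ToyProblem",
    "noninteracting_fraction_oracle",
    "brute_force_field_solution",
    "fixture_state_points",
]


def noninteracting_fraction_oracle(bulk: BulkState, constants: BindingConstants) -> dict:
    """Four-state fractions per monomer type at zero fields (bulk activities).

    Written as an explicit partition sum over the four states so it can serve
    as an independent check of the closed-form fraction solver.
    """
    vw = bulk.catalog.vw
    out = {}
    for mono in ("A", "G"):
        K_H, K_Na, K_Mg = constants.for_type(mono)
        weights = {
            "free": 1.0,
            "H": K_H * bulk.rho["H"] * vw,
            "Na": K_Na * bulk.rho["Na"] * vw,
            "Mg": K_Mg * bulk.rho["Mg"] * vw,
        }
        Z = sum(weights.values())
        out[mono] = {s: w / Z for s, w in weights.items()}
    return out


@dataclass
class ToyProblem:
    """A field problem small enough for direct extremization.

    Hand-written conformation occupancies on a tiny grid; ``monomer_charge``
    set to zero together with binding constants of zero gives an exactly
    charge-free system (psi must vanish identically).
    """

    grid: Grid
    n_A: np.ndarray
    n_G: np.ndarray
    bulk: BulkState
    constants: BindingConstants
    sigma_p: float
    v_monomer: float = 0.30
    monomer_charge: float = -1.0
    multiplicity: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.grid.n_layers > 3:
            raise ValueError("toy problems use at most 3 layers")
        if np.atleast_2d(self.n_A).shape[0] > 10:
            raise ValueError("toy problems use at most 10 conformations")

    def ensemble(self) -> ConformationEnsemble:
        return ConformationEnsemble.from_occupancies(
            self.grid, self.n_A, self.n_G, self.multiplicity
        )

    def problem(self) -> SCFTProblem:
        return SCFTProblem(
            self.ensemble(),
            self.bulk,
            self.constants,
            self.sigma_p,
            v_monomer=self.v_monomer,
            monomer_charge=self.monomer_charge,
        )


def _fd_gradient(fun, x: np.ndarray, h: float = 1e-6) -> np.ndarray:
    """Central-difference gradient of a scalar function."""
    g = np.empty_like(x)
    for i in range(x.size):
        xp = x.copy()
        xm = x.copy()
        xp[i] += h
        xm[i] -= h
        g[i] = (fun(xp) - fun(xm)) / (2.0 * h)
    return g


def brute_force_field_solution(toy: ToyProblem, tol: float = 1e-10) -> FieldState:
    """Extremize the semi-grand potential directly over all field unknowns.

    The scalar potential W(pi, psi) is differentiated by central finite
    differences and its stationary point located with a generic root finder;
    the analytic residual assembly of the main solver is never invoked.
    """
    prob = toy.problem()
    W = prob.grand_potential
    n2 = 2 * toy.grid.n_layers
    x0 = np.zeros(n2)
    res = scipy.optimize.root(
        lambda x: _fd_gradient(W, x), x0, method="hybr", tol=tol
    )
    grad = _fd_gradient(W, res.x)
    if not res.success and np.abs(grad).max() > 1e-7:
        raise RuntimeError(f"brute-force extremization failed: {res.message}")
    return FieldState.unpack(res.x)


def fixture_state_points() -> list[dict]:
    """Canonical reduced-scale test grid of state points.

    3 sequences x 3 grafting densities x 4 MgCl2 concentrations at 10 mM
    NaCl, pH 7, 298 K; every fixture echoes its seed and reduced ensemble
    size. The 0 mM MgCl2 points carry the Mg branch with a zero bulk density
    (the K terms multiply zero cleanly).
    """
    points = []
    for seq in ("A6G6", "G6A6", "(AG)6"):
        for sigma_p in (0.005, 0.05, 0.5):
            for c_mg_mM in (0, 3, 50, 180):
                points.append(
                    {
                        "sequence": seq,
                        "sigma_p": sigma_p,
                        "c_mgcl2_M": c_mg_mM * 1e-3,
                        "c_nacl_M": 0.010,
                        "pH": 7.0,
                        "T": 298.0,
                        "seed": 20181403,
                        "ensemble": "reduced",
                        "max_conformations": 3000,
                        "rotations_per_state": 1,
                    }
                )
    return points


def default_toy(
    c_nacl: float = 0.010,
    sigma_p: float = 0.02,
    neutral: bool = False,
    with_mg: bool = False,
) -> ToyProblem:
    """A standard 3-layer, 2-conformation toy used across the test suite."""
    grid = Grid(n_layers=3, dz=0.3)
    n_A = np.array([[1, 1, 0], [1, 0, 1]])
    n_G = np.array([[0, 1, 1], [1, 1, 0]])
    catalog = SpeciesCatalog()
    if neutral:
        catalog = SpeciesCatalog(
            valence={s: 0 for s in catalog.valence}, volume=dict(catalog.volume)
        )
        constants = BindingConstants(0, 0, 0, 0, 0, 0)
        charge = 0.0
    else:
        constants = BindingConstants.from_parameters()
        charge = -1.0
    bulk = solve_bulk(c_nacl, 0.003 if with_mg else 0.0, 7.0, catalog=catalog)
    return ToyProblem(
        grid=grid,
        n_A=n_A,
        n_G=n_G,
        bulk=bulk,
        constants=constants,
        sigma_p=sigma_p,
        monomer_charge=charge,
    )
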