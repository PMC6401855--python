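"""Solution chemistry: species catalog, binding constants, bulk reference state.

The brush exchanges water, H+, OH-, Na+, Mg2+ and Cl- with a bulk reservoir.
This module converts tabulated thermodynamic inputs (binding free energies,
pKa values, salt concentrations, bulk pH) into the dimensionless equilibrium
constants and the bulk densities that parameterize the field equations.

Conventions
-----------
* energies in kT (inputs in kJ/mol), lengths in nm, charges in units of e;
* molar concentrations convert via 1 M = 0.602214 nm^-3;
* every mass-action expression uses the dimensionless activity rho * v_w,
  with v_w the water molecular volume; pKa values (molar constants) are
  converted into this convention, while association constants derived from
  binding free energies are used directly as K0 = exp(-dG0 / RT).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import constants as _const

#: nm^-3 per mol/L
M_TO_NM3 = _const.Avogadro * 1e-24  # 0.602214076

#: gas constant in kJ/(mol K)
R_KJ = 8.314e-3

#: default water molecular volume, nm^3
V_WATER = 0.030

FREE_SPECIES = ("w", "H", "OH", "Na", "Mg", "Cl")


def bjerrum_length(eps_r: float = 78.5, T: float = 298.0) -> float:
    """Bjerrum length e^2/(4 pi eps0 eps_r kT) in nm (0.714 nm at defaults)."""
    lb_m = _const.e**2 / (4.0 * np.pi * _const.epsilon_0 * eps_r * _const.k * T)
    return lb_m * 1e9


@dataclass(frozen=True)
class SpeciesCatalog:
    """Valences (e) and molecular volumes (nm^3) of the free species.

    Defaults: water 0.030 nm^3 (H+/OH- treated as water-sized), Na+ and Cl-
    0.05 nm^3, Mg2+ (aquo) 0.18 nm^3.
    """

    valence: dict = field(
        default_factory=lambda: {"w": 0, "H": +1, "OH": -1, "Na": +1, "Mg": +2, "Cl": -1}
    )
    volume: dict = field(
        default_factory=lambda: {
            "w": V_WATER,
            "H": V_WATER,
            "OH": V_WATER,
            "Na": 0.05,
            "Mg": 0.18,
            "Cl": 0.05,
        }
    )

    def __post_init__(self) -> None:
        for s in FREE_SPECIES:
            if s not in self.valence or s not in self.volume:
                raise ValueError(f"catalog missing species {s!r}")
            if self.volume[s] <= 0:
                raise ValueError(f"volume of {s!r} must be positive")

    @property
    def vw(self) -> float:
        return self.volume["w"]


def equilibrium_constant_from_free_energy(dG0_kJ: float, T: float = 298.0) -> float:
    """Dimensionless association constant K0 = exp(-dG0 / RT).

    ``dG0_kJ`` is the standard reaction free energy in kJ/mol of the
    formation (association) reaction, referred to the rho*v_w activity
    convention.
    """
    if T <= 0:
        raise ValueError("temperature must be positive")
    return float(np.exp(-dG0_kJ / (R_KJ * T)))


def free_energy_from_equilibrium_constant(K0: float, T: float = 298.0) -> float:
    """Inverse of :func:`equilibrium_constant_from_free_energy` (kJ/mol)."""
    return float(-R_KJ * T * np.log(K0))


def association_constant_from_pKa(pKa: float, vw: float = V_WATER) -> float:
    """Protonation (association) constant in the rho*v_w convention.

    The molar acid constant is Ka = 10^-pKa; its reciprocal is the molar
    association constant, converted to the dimensionless convention by the
    molar-to-nm^-3 factor and the reference volume v_w.
    """
    if vw <= 0:
        raise ValueError("vw must be positive")
    return float(10.0**pKa / (M_TO_NM3 * vw))


@dataclass(frozen=True)
class BindingConstants:
    """Dimensionless equilibrium constants of the six association reactions.

    K_iX is the constant of i(-) + X <-> iX for monomer type i in {A, G} and
    X in {H+, Na+, Mg2+}; all referred to the rho*v_w activity convention.
    Reaction volume changes are zero: a bound complex carries the summed
    volume of its parts, so no explicit exp(-beta pi dv) factor appears in
    the mass-action laws.
    """

    K_AH: float
    K_GH: float
    K_ANa: float
    K_GNa: float
    K_AMg: float
    K_GMg: float

    def __post_init__(self) -> None:
        for name in ("K_AH", "K_GH", "K_ANa", "K_GNa", "K_AMg", "K_GMg"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    @classmethod
    def from_parameters(
        cls,
        pKa_A: float = 3.5,
        pKa_G: float = 1.6,
        dG_AMg: float = -32.1,
        dG_GMg: float = -35.6,
        dG_ANa: float = -21.0,
        dG_GNa: float = -21.0,
        T: float = 298.0,
        vw: float = V_WATER,
        mg_exchange_pathway: bool = True,
        reference: str = "direct",
    ) -> "BindingConstants":
        """Build from adenine/guanine pKa values and binding free energies (kJ/mol).

        The Mg2+ free energies are experimentally derived in a NaCl
        background in which Mg2+ displaces non-specifically associated Na+;
        with ``mg_exchange_pathway`` (the default) they are read as exchange
        free energies relative to the Na+-dressed site, so the bare-site
        association free energy is dG_iMg + dG_iNa. Setting the flag false
        uses the quoted values directly as bare-site constants.

        ``reference`` selects the standard state of the exp(-dG/RT)
        constants: 'direct' uses them as the dimensionless constants of the
        rho*v_w mass-action laws with no conversion (how the model equations
        are written); 'molar' treats them as association constants in M^-1
        and rescales onto the rho*v_w activity scale. pKa values are molar
        by definition and always converted.
        """
        if reference == "molar":
            conv = 1.0 / (M_TO_NM3 * vw)
        elif reference == "direct":
            conv = 1.0
        else:
            raise ValueError("reference must be 'molar' or 'direct'")
        dG_AMg_bare = dG_AMg + (dG_ANa if mg_exchange_pathway else 0.0)
        dG_GMg_bare = dG_GMg + (dG_GNa if mg_exchange_pathway else 0.0)
        return cls(
            K_AH=association_constant_from_pKa(pKa_A, vw),
            K_GH=association_constant_from_pKa(pKa_G, vw),
            K_ANa=conv * equilibrium_constant_from_free_energy(dG_ANa, T),
            K_GNa=conv * equilibrium_constant_from_free_energy(dG_GNa, T),
            K_AMg=conv * equilibrium_constant_from_free_energy(dG_AMg_bare, T),
            K_GMg=conv * equilibrium_constant_from_free_energy(dG_GMg_bare, T),
        )

    def for_type(self, mono: str) -> tuple[float, float, float]:
        """(K_H, K_Na, K_Mg) for monomer type ``mono``."""
        if mono == "A":
            return self.K_AH, self.K_ANa, self.K_AMg
        if mono == "G":
            return self.K_GH, self.K_GNa, self.K_GMg
        raise ValueError(f"unknown monomer type {mono!r}")

    def swapped(self) -> "BindingConstants":
        """A/G label swap (used by the metamorphic symmetry tests)."""
        return replace(
            self,
            K_AH=self.K_GH, K_GH=self.K_AH,
            K_ANa=self.K_GNa, K_GNa=self.K_ANa,
            K_AMg=self.K_GMg, K_GMg=self.K_AMg,
        )


@dataclass(frozen=True)
class BulkState:
    """Bulk electrolyte reference state.

    Densities are number densities in nm^-3 and satisfy electroneutrality and
    the bulk incompressibility sum(rho v) = 1. ``beta_mu`` holds the exchange
    chemical potentials relative to the standard state, beta(mu - mu0) =
    ln(rho_b v_w), in the gauge where the lateral pressure field pi and the
    electrostatic potential psi vanish in the bulk; the density-profile
    expressions then return exactly the bulk densities at zero fields.
    """

    rho: dict
    beta_mu: dict
    pH: float
    pKw: float
    T: float
    eps_r: float
    catalog: SpeciesCatalog

    @property
    def bjerrum(self) -> float:
        return bjerrum_length(self.eps_r, self.T)

    def density_array(self, species=FREE_SPECIES) -> np.ndarray:
        return np.array([self.rho[s] for s in species])


def solve_bulk(
    c_nacl: float,
    c_mgcl2: float,
    pH: float,
    T: float = 298.0,
    catalog: SpeciesCatalog | None = None,
    pKw: float = 14.0,
    eps_r: float = 78.5,
) -> BulkState:
    """Construct the bulk reference state from salt concentrations (M) and pH.

    Cl- is fixed by electroneutrality, water by incompressibility; H+ and OH-
    follow the bulk pH and the water ion product.
    """
    if c_nacl < 0 or c_mgcl2 < 0:
        raise ValueError("salt concentrations must be >= 0")
    if not (0.0 < pH < 14.0):
        raise ValueError("bulk pH must lie in (0, 14)")
    if catalog is None:
        catalog = SpeciesCatalog()

    rho_H = M_TO_NM3 * 10.0 ** (-pH)
    rho_OH = M_TO_NM3 * 10.0 ** (-(pKw - pH))
    rho_Na = M_TO_NM3 * c_nacl
    rho_Mg = M_TO_NM3 * c_mgcl2
    rho_Cl = rho_Na + 2.0 * rho_Mg + rho_H - rho_OH
    if rho_Cl < 0:
        raise ValueError(
            "implied bulk Cl- density is negative: add salt or lower the pH"
        )
    rho = {"H": rho_H, "OH": rho_OH, "Na": rho_Na, "Mg": rho_Mg, "Cl": rho_Cl}
    occupied = sum(rho[s] * catalog.volume[s] for s in rho)
    if occupied >= 1.0:
        raise ValueError("ion volume fractions exceed unity: unphysical bulk")
    rho["w"] = (1.0 - occupied) / catalog.vw

    beta_mu = {s: float(np.log(rho[s] * catalog.vw)) for s in FREE_SPECIES if rho[s] > 0}
    return BulkState(
        rho=rho, beta_mu=beta_mu, pH=pH, pKw=pKw, T=T, eps_r=eps_r, catalog=catalog
    )
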