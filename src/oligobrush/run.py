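"""State-point and sweep execution with structured output.

Composes the chain generator, bulk chemistry, field solver and observables
into reproducible runs: one TSV profile table plus one JSON summary per
state point, both embedding the resolved parameter echo; (config, seed)
determines all outputs bit-exactly.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .chains import ChainGeometry, build_sequence, generate_ensemble
from .chemistry import BindingConstants, SpeciesCatalog, solve_bulk
from .config import RunConfig
from .core import SCFTSolution, solve_state_point
from .grid import Grid
from .observables import (
    build_report,
    deprotonated_fraction_profile,
    local_ph_profile,
    volume_fraction_profiles,
)

__all__ = ["prepare_inputs", "run_state_point", "run_sweep", "profile_table"]


def prepare_inputs(cfg: RunConfig):
    """Resolve config sections into model objects (ensemble excluded)."""
    ch = cfg.chemistry
    catalog = SpeciesCatalog(
        volume={
            "w": ch["v_water"],
            "H": ch["v_water"],
            "OH": ch["v_water"],
            "Na": ch["v_na"],
            "Mg": ch["v_mg"],
            "Cl": ch["v_cl"],
        }
    )
    constants = BindingConstants.from_parameters(
        pKa_A=ch["pKa_A"],
        pKa_G=ch["pKa_G"],
        dG_AMg=ch["dG_AMg"],
        dG_GMg=ch["dG_GMg"],
        dG_ANa=ch["dG_ANa"],
        dG_GNa=ch["dG_GNa"],
        T=cfg.system["temperature_K"],
        vw=ch["v_water"],
        mg_exchange_pathway=ch["mg_exchange_pathway"],
        reference=ch["reference"],
    )
    bulk = solve_bulk(
        cfg.system["nacl_mM"] * 1e-3,
        cfg.system["mgcl2_mM"] * 1e-3,
        cfg.system["ph"],
        T=cfg.system["temperature_K"],
        catalog=catalog,
        pKw=ch["pKw"],
        eps_r=ch["eps_r"],
    )
    geo = cfg.geometry
    geometry = ChainGeometry(
        bond_length=geo["bond_length"],
        bond_angle_deg=geo["bond_angle_deg"],
        dihedral_deg=(
            geo["dihedral_trans"],
            geo["dihedral_gauche"],
            -geo["dihedral_gauche"],
        ),
        first_monomer_z=geo["first_monomer_z"],
    )
    grid = Grid(n_layers=cfg.grid["n_layers"], dz=cfg.grid["dz"])
    return catalog, constants, bulk, geometry, grid


def profile_table(solution: SCFTSolution) -> pd.DataFrame:
    """Per-layer profile table of one state point."""
    p = solution.problem
    phi = volume_fraction_profiles(solution)
    f = solution.fractions
    df = pd.DataFrame({"z_nm": p.grid.centers})
    df["phi_polymer"] = phi["polymer"]
    for s in ("w", "Na", "Mg", "Cl", "H", "OH"):
        df[f"phi_{s}"] = phi[s]
    for mono in ("A", "G"):
        fm = f.for_type(mono)
        for state, col in (("free", "minus"), ("H", "H"), ("Na", "Na"), ("Mg", "Mg")):
            df[f"f_{mono}_{col}"] = fm[state]
    df["f_P_minus"] = deprotonated_fraction_profile(solution) if p.sigma_p > 0 else np.nan
    df["psi_kT_per_e"] = solution.fields.psi
    df["pi_kT_per_nm3"] = solution.fields.pi
    df["pH_local"] = local_ph_profile(solution)
    df["rho_q_e_per_nm3"] = solution.rho_q
    return df


def run_state_point(
    cfg: RunConfig,
    out_dir=None,
    ensemble=None,
    init=None,
    tag: str | None = None,
):
    """Run one state point; optionally write <tag>.tsv and <tag>.json.

    Returns (report, solution, ensemble). A pre-generated ensemble can be
    passed in to share it across a sweep.
    """
    catalog, constants, bulk, geometry, grid = prepare_inputs(cfg)
    seq = build_sequence(cfg.system["sequence"])
    ens = cfg.ensemble
    if ensemble is None:
        ensemble = generate_ensemble(
            seq,
            geometry,
            grid,
            rotations_per_state=ens["rotations_per_state"],
            seed=ens["seed"],
            max_conformations=ens["max_conformations"] or None,
        )
    solution = solve_state_point(
        ensemble,
        bulk,
        constants,
        cfg.system["sigma_p"],
        v_monomer=cfg.chemistry["v_monomer"],
        init=init,
        tol=cfg.solver["tol"],
        max_iter=cfg.solver["max_iter"],
    )
    report = build_report(
        solution,
        sequence=str(seq),
        c_mgcl2_M=cfg.system["mgcl2_mM"] * 1e-3,
        c_nacl_M=cfg.system["nacl_mM"] * 1e-3,
        seed=ens["seed"],
    )
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        tag = tag or _tag(cfg)
        table = profile_table(solution)
        header = [f"# oligobrush {__version__}"] + [
            f"# {line}" for line in cfg.echo().splitlines()
        ]
        with open(out_dir / f"{tag}.tsv", "w") as fh:
            fh.write("\n".join(header) + "\n")
            table.to_csv(fh, sep="\t", index=False, float_format="%.10g")
        payload = {
            "version": __version__,
            "parameters": {k: dict(getattr(cfg, k)) for k in
                           ("system", "chemistry", "geometry", "grid", "ensemble", "solver")},
            "report": report.to_dict(),
        }
        with open(out_dir / f"{tag}.json", "w") as fh:
            json.dump(payload, fh, indent=2, sort_keys=True)
            fh.write("\n")
    return report, solution, ensemble


def _tag(cfg: RunConfig) -> str:
    s = cfg.system
    seq = s["sequence"].replace("(", "").replace(")", "")
    return f"{seq}_sp{s['sigma_p']:g}_mg{s['mgcl2_mM']:g}mM"


def run_sweep(cfg: RunConfig, out_dir) -> pd.DataFrame:
    """Run the config's sweep grid with warm-started continuation.

    Sweeps ascending sigma_p then ascending MgCl2, warm-starting each solve
    from the previous converged fields at the same grafting density. Writes
    per-point outputs plus an aggregate ``sweep.tsv``.
    """
    import copy

    sigmas = sorted(cfg.sweep["sigma_p"]) or [cfg.system["sigma_p"]]
    salts = sorted(cfg.sweep["mgcl2_mM"]) or [cfg.system["mgcl2_mM"]]
    rows = []
    ensemble = None
    for sp in sigmas:
        init = None
        for mg in salts:
            sub = copy.deepcopy(cfg)
            sub.system["sigma_p"] = sp
            sub.system["mgcl2_mM"] = mg
            report, solution, ensemble = run_state_point(
                sub, out_dir=out_dir, ensemble=ensemble, init=init
            )
            init = solution.fields if solution.converged else None
            rows.append(report.to_dict())
    agg = pd.DataFrame(rows)
    agg.to_csv(Path(out_dir) / "sweep.tsv", sep="\t", index=False, float_format="%.10g")
    return agg
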