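"""Rotational isomeric state (RIS) ensemble of an end-grafted oligomer.

The oligomer is a freely-rotating bead chain with fixed bond length and bond
angle; each interior torsion takes one of three isomeric states (trans,
gauche+, gauche-). Every torsion assignment is embedded in 3D, subjected to
random solid-body rotations about the grafted bead, rejected if any bead
center dips below the wall, and binned into the layer grid. The resulting
per-layer occupancy counts n_A(alpha; k), n_G(alpha; k) are the only chain
information the field equations need.

No intra-chain excluded volume is enforced beyond wall rejection: steric
repulsion between monomers is carried by the packing constraint of the field
theory, not by the single-chain ensemble.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
from scipy.sparse import csr_matrix
from scipy.spatial.transform import Rotation

from .grid import Grid

__all__ = [
    "ChainSequence",
    "ChainGeometry",
    "ConformationEnsemble",
    "build_sequence",
    "enumerate_dihedral_states",
    "embed_conformation",
    "bin_to_layers",
    "generate_ensemble",
]


@dataclass(frozen=True)
class ChainSequence:
    """Ordered monomer identities; the first monomer is grafted to the wall."""

    monomers: tuple
    grafted_index: int = 0

    def __post_init__(self) -> None:
        if len(self.monomers) < 1:
            raise ValueError("a chain needs at least one monomer")
        bad = set(self.monomers) - {"A", "G"}
        if bad:
            raise ValueError(f"unknown monomer identities: {sorted(bad)}")
        if self.grafted_index != 0:
            raise ValueError("the grafted monomer is always the first listed")

    def __len__(self) -> int:
        return len(self.monomers)

    @property
    def n_A(self) -> int:
        return sum(1 for m in self.monomers if m == "A")

    @property
    def n_G(self) -> int:
        return sum(1 for m in self.monomers if m == "G")

    @property
    def is_A(self) -> np.ndarray:
        return np.array([m == "A" for m in self.monomers])

    def swapped(self) -> "ChainSequence":
        """Exchange A and G identities (G6A6 is swapped(A6G6))."""
        return ChainSequence(tuple("A" if m == "G" else "G" for m in self.monomers))

    def __str__(self) -> str:
        return "".join(self.monomers)


def build_sequence(spec: str) -> ChainSequence:
    """Expand a compact sequence string into a :class:`ChainSequence`.

    Grammar: concatenated blocks ``<letters><repeat>``, with parentheses
    grouping multi-letter repeats. ``A6G6`` -> AAAAAAGGGGGG,
    ``(AG)6`` -> AGAGAGAGAGAG, ``A1`` (or bare ``A``) -> A.
    """
    import re

    if not spec:
        raise ValueError("empty sequence specification")
    monomers: list[str] = []
    pos = 0
    token = re.compile(r"\(([A-Za-z]+)\)(\d+)|([A-Za-z])(\d*)")
    while pos < len(spec):
        m = token.match(spec, pos)
        if m is None:
            raise ValueError(f"cannot parse sequence spec at {spec[pos:]!r}")
        if m.group(1) is not None:
            unit, count = m.group(1), int(m.group(2))
        else:
            unit, count = m.group(3), int(m.group(4) or "1")
        if count == 0:
            raise ValueError("zero-length block in sequence spec")
        monomers.extend(unit * count)
        pos = m.end()
    seq = ChainSequence(tuple(monomers))  # validates the letters
    return seq


@dataclass(frozen=True)
class ChainGeometry:
    """Coarse-grained backbone geometry.

    The printed model leaves the virtual-bond geometry open; the defaults are
    standard RIS conventions for a nucleotide-scale bead chain: bond length
    0.6 nm (the order of the ssDNA P-P virtual bond), bond angle 112 degrees
    at each bead, torsions 180 / +60 / -60 degrees, and the grafted bead held
    half a layer above the wall.
    """

    bond_length: float = 0.6
    bond_angle_deg: float = 112.0
    dihedral_deg: tuple = (180.0, 60.0, -60.0)
    first_monomer_z: float = 0.15

    def __post_init__(self) -> None:
        if self.bond_length <= 0:
            raise ValueError("bond_length must be positive")
        if len(self.dihedral_deg) != 3:
            raise ValueError("exactly three dihedral states are required")
        if self.first_monomer_z < 0:
            raise ValueError("the grafted monomer cannot sit below the wall")


def enumerate_dihedral_states(n_monomers: int) -> np.ndarray:
    """All torsion-state assignments of a linear bead chain.

    A chain of N beads has max(N - 3, 0) interior torsions (the first bond
    fixes no torsion, the second bond's azimuth is absorbed by the solid-body
    spin); each torsion takes 3 states, giving 3^(N-3) assignments returned
    as an integer array of shape (3^d, d) with entries in {0, 1, 2}.
    """
    if n_monomers < 1:
        raise ValueError("n_monomers must be >= 1")
    d = max(n_monomers - 3, 0)
    if d == 0:
        return np.zeros((1, 0), dtype=np.int8)
    grids = np.meshgrid(*([np.arange(3, dtype=np.int8)] * d), indexing="ij")
    return np.stack([g.ravel() for g in grids], axis=1)


def _canonical_backbones(assignments: np.ndarray, geometry: ChainGeometry, n_monomers: int) -> np.ndarray:
    """Embed every torsion assignment in a canonical frame.

    Returns positions of shape (n_assign, N, 3) with bead 0 at the origin and
    the first bond along +z. Vectorized over assignments.
    """
    m = assignments.shape[0]
    b = geometry.bond_length
    theta_s = np.deg2rad(180.0 - geometry.bond_angle_deg)  # angle between bond vectors
    cos_t, sin_t = np.cos(theta_s), np.sin(theta_s)
    phis = np.deg2rad(np.asarray(geometry.dihedral_deg))

    pos = np.zeros((m, n_monomers, 3))
    if n_monomers == 1:
        return pos
    u = np.zeros((m, n_monomers - 1, 3))
    u[:, 0] = (0.0, 0.0, 1.0)
    if n_monomers >= 3:
        # second bond in the x-z plane at the bond angle
        u[:, 1] = (sin_t, 0.0, cos_t)
    for i in range(2, n_monomers - 1):
        u_prev = u[:, i - 1]
        u_pprev = u[:, i - 2]
        if abs(sin_t) < 1e-12:
            u[:, i] = u_prev if cos_t > 0 else -u_prev
            continue
        phi = phis[assignments[:, i - 2]]
        # in-plane unit vector such that phi = 180 deg reproduces u_{i-2} (trans
        # continues the planar zig-zag)
        a = cos_t * u_prev - u_pprev
        a /= np.linalg.norm(a, axis=1, keepdims=True)
        n = np.cross(u_prev, a)
        u[:, i] = cos_t * u_prev + sin_t * (
            np.cos(phi)[:, None] * a + np.sin(phi)[:, None] * n
        )
    pos[:, 1:] = b * np.cumsum(u, axis=1)
    return pos


def embed_conformation(
    assignment: np.ndarray,
    geometry: ChainGeometry,
    rotation: np.ndarray,
    n_monomers: int | None = None,
) -> np.ndarray | None:
    """Embed one torsion assignment under a rigid-body rotation.

    ``rotation`` is a proper 3x3 rotation matrix applied about the grafted
    bead, which is then placed at (0, 0, first_monomer_z). Returns the
    (N, 3) coordinates, or None if any bead center falls below the wall
    (rejection is a normal outcome, not an error).
    """
    assignment = np.atleast_2d(np.asarray(assignment, dtype=np.int8))
    if n_monomers is None:
        n_monomers = assignment.shape[1] + 3
    pos = _canonical_backbones(assignment, geometry, n_monomers)[0]
    pos = pos @ np.asarray(rotation).T
    pos[:, 2] += geometry.first_monomer_z
    if np.any(pos[:, 2] < 0):
        return None
    return pos


def bin_to_layers(
    coords: np.ndarray, seq: ChainSequence, grid: Grid
) -> tuple[np.ndarray, np.ndarray]:
    """Per-layer occupancy counts (n_A, n_G) of one embedded conformation."""
    z = np.asarray(coords)[:, 2]
    if np.any(z < 0):
        raise ValueError("coordinates below the wall cannot be binned")
    layers = grid.layer_of(z)
    if np.any(layers >= grid.n_layers):
        raise ValueError("conformation extends beyond the grid top")
    is_A = seq.is_A
    n_A = np.bincount(layers[is_A], minlength=grid.n_layers).astype(np.int64)
    n_G = np.bincount(layers[~is_A], minlength=grid.n_layers).astype(np.int64)
    return n_A, n_G


@dataclass
class ConformationEnsemble:
    """Binned occupancy counts of the accepted conformations.

    Identical occupancy vectors are merged; ``multiplicity`` counts how many
    accepted embeddings produced each distinct row, so statistical weights are
    preserved exactly. ``counts_A`` / ``counts_G`` are sparse CSR matrices of
    shape (n_distinct, n_layers).
    """

    grid: Grid
    counts_A: csr_matrix
    counts_G: csr_matrix
    multiplicity: np.ndarray
    seed: int | None = None
    n_embedded: int = 0
    meta: dict = field(default_factory=dict)

    @property
    def n_conformations(self) -> int:
        """Total number of accepted embeddings (with multiplicity)."""
        return int(self.multiplicity.sum())

    @property
    def n_distinct(self) -> int:
        return self.counts_A.shape[0]

    @property
    def acceptance_rate(self) -> float:
        return self.n_conformations / self.n_embedded if self.n_embedded else float("nan")

    def swapped(self) -> "ConformationEnsemble":
        """Exchange the A and G occupancy arrays (label-swap symmetry)."""
        return ConformationEnsemble(
            grid=self.grid,
            counts_A=self.counts_G,
            counts_G=self.counts_A,
            multiplicity=self.multiplicity,
            seed=self.seed,
            n_embedded=self.n_embedded,
            meta=dict(self.meta),
        )

    # -- plain-text cache -------------------------------------------------
    def to_tsv(self) -> str:
        """Serialize to a tabular text block (bit-exact round trip)."""
        lines = [
            f"# n_layers\t{self.grid.n_layers}",
            f"# dz\t{self.grid.dz!r}",
            f"# seed\t{self.seed}",
            f"# n_embedded\t{self.n_embedded}",
        ]
        for k, v in sorted(self.meta.items()):
            lines.append(f"# meta:{k}\t{v!r}")
        lines.append("conformation\tmonomer\tlayer\tcount\tmultiplicity")
        A = self.counts_A.tocoo()
        G = self.counts_G.tocoo()
        rows = []
        for label, mat in (("A", A), ("G", G)):
            for r, c, v in zip(mat.row, mat.col, mat.data):
                rows.append((int(r), label, int(c), int(v)))
        rows.sort()
        for r, label, c, v in rows:
            lines.append(f"{r}\t{label}\t{c}\t{v}\t{int(self.multiplicity[r])}")
        return "\n".join(lines) + "\n"

    def save(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(self.to_tsv())

    @classmethod
    def from_tsv(cls, text: str) -> "ConformationEnsemble":
        header: dict = {}
        meta: dict = {}
        body: list[str] = []
        for line in io.StringIO(text):
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("# "):
                key, _, val = line[2:].partition("\t")
                if key.startswith("meta:"):
                    meta[key[5:]] = eval(val)  # noqa: S307 - own round-trip format
                else:
                    header[key] = val
            elif not line.startswith("conformation\t"):
                body.append(line)
        grid = Grid(n_layers=int(header["n_layers"]), dz=float(eval(header["dz"])))
        seed = None if header.get("seed") in (None, "None") else int(header["seed"])
        rows_A, rows_G, mult = [], [], {}
        for line in body:
            r, label, c, v, g = line.split("\t")
            (rows_A if label == "A" else rows_G).append((int(r), int(c), int(v)))
            mult[int(r)] = int(g)
        n = max(mult) + 1 if mult else 0
        multiplicity = np.zeros(n, dtype=np.int64)
        for r, g in mult.items():
            multiplicity[r] = g

        def build(rows):
            if rows:
                r, c, v = map(np.asarray, zip(*rows))
            else:
                r = c = v = np.zeros(0, dtype=np.int64)
            return csr_matrix((v, (r, c)), shape=(n, grid.n_layers), dtype=np.int64)

        return cls(
            grid=grid,
            counts_A=build(rows_A),
            counts_G=build(rows_G),
            multiplicity=multiplicity,
            seed=seed,
            n_embedded=int(header.get("n_embedded", 0)),
            meta=meta,
        )

    @classmethod
    def load(cls, path) -> "ConformationEnsemble":
        with open(path) as fh:
            return cls.from_tsv(fh.read())

    @classmethod
    def from_occupancies(
        cls, grid: Grid, n_A: np.ndarray, n_G: np.ndarray, multiplicity=None
    ) -> "ConformationEnsemble":
        """Build directly from dense occupancy arrays (used by toy problems)."""
        n_A = np.atleast_2d(np.asarray(n_A))
        n_G = np.atleast_2d(np.asarray(n_G))
        if multiplicity is None:
            multiplicity = np.ones(n_A.shape[0], dtype=np.int64)
        return cls(
            grid=grid,
            counts_A=csr_matrix(n_A, dtype=np.int64),
            counts_G=csr_matrix(n_G, dtype=np.int64),
            multiplicity=np.asarray(multiplicity, dtype=np.int64),
            n_embedded=int(np.sum(multiplicity)),
        )


def generate_ensemble(
    seq: ChainSequence,
    geometry: ChainGeometry,
    grid: Grid,
    rotations_per_state: int = 38,
    seed: int = 0,
    max_conformations: int | None = None,
) -> ConformationEnsemble:
    """Generate the binned RIS ensemble of a grafted chain.

    Every torsion assignment is embedded under ``rotations_per_state``
    independent uniform solid-body rotations; embeddings with any bead below
    the wall are rejected. Identical occupancy vectors are merged with
    multiplicities. Deterministic for a given seed. ``max_conformations``
    optionally subsamples the accepted embeddings (seeded) to a target count.
    """
    if rotations_per_state < 1:
        raise ValueError("rotations_per_state must be >= 1")
    N = len(seq)
    assignments = enumerate_dihedral_states(N)
    canonical = _canonical_backbones(assignments, geometry, N)
    n_assign = assignments.shape[0]
    rng = np.random.default_rng(seed)
    is_A = seq.is_A

    all_rows = []
    n_embedded = 0
    for _ in range(rotations_per_state):
        R = Rotation.random(n_assign, random_state=rng).as_matrix()
        pos = np.einsum("aij,anj->ani", R, canonical)
        z = pos[..., 2] + geometry.first_monomer_z
        n_embedded += n_assign
        ok = np.all(z >= 0.0, axis=1)
        z = z[ok]
        if z.size == 0:
            continue
        layers = np.floor(z / grid.dz).astype(np.int64)
        if np.any(layers >= grid.n_layers):
            raise ValueError("conformation extends beyond the grid top; enlarge the grid")
        # dense occupancy rows: A counts then G counts, int8 is ample (<=12)
        rows = np.zeros((z.shape[0], 2 * grid.n_layers), dtype=np.int8)
        idx = np.arange(z.shape[0])[:, None]
        np.add.at(rows, (idx, layers + np.where(is_A, 0, grid.n_layers)[None, :]), 1)
        all_rows.append(rows)

    if not all_rows:
        raise RuntimeError("all conformations rejected: inconsistent geometry")
    rows = np.concatenate(all_rows, axis=0)
    if max_conformations is not None and rows.shape[0] > max_conformations:
        pick = rng.choice(rows.shape[0], size=max_conformations, replace=False)
        pick.sort()
        rows = rows[pick]
    uniq, counts = np.unique(rows, axis=0, return_counts=True)
    nl = grid.n_layers
    return ConformationEnsemble(
        grid=grid,
        counts_A=csr_matrix(uniq[:, :nl].astype(np.int64)),
        counts_G=csr_matrix(uniq[:, nl:].astype(np.int64)),
        multiplicity=counts.astype(np.int64),
        seed=seed,
        n_embedded=n_embedded,
        meta={
            "sequence": str(seq),
            "bond_length": geometry.bond_length,
            "bond_angle_deg": geometry.bond_angle_deg,
            "dihedral_deg": tuple(geometry.dihedral_deg),
            "first_monomer_z": geometry.first_monomer_z,
            "rotations_per_state": rotations_per_state,
        },
    )
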