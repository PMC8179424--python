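"""Toy coarse-grained dimer structures.

Stands in for a two-chain chaperone dimer with three domains per chain
(N-terminal nucleotide-binding domain at the top, middle M domain, and the
C-terminal dimerisation domain at the bottom).  Chains are Cα-bead rods that
meet at the C domains and splay apart towards the N domains; three named
geometries mirror the conformational states of interest:

* ``open``    — wide N-terminal separation;
* ``closedA`` — N-terminally closed, symmetric;
* ``closedB`` — as closedA but with one chain kinked toward its partner
  (asymmetric contraction), shrinking the designated inter-chain M-domain
  bead distances by a configurable fraction.

Coordinates are deterministic for a fixed seed; the seeded jitter depends
only on bead index, so two geometries built with the same seed differ only
by the systematic geometry change.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import biotite.structure as bst
from biotite.structure.io.pdb import PDBFile

BEAD_SPACING = 3.8     # Å, Cα-Cα
BEAD_RADIUS = 2.0      # Å, toy van-der-Waals radius


@dataclass
class ToyStructure:
    coords: np.ndarray        # (n_atoms, 3), Å
    chain_id: np.ndarray      # 'A' / 'B'
    res_id: np.ndarray        # 1-based, unique within chain
    element: np.ndarray
    vdw_radius: np.ndarray
    mass: np.ndarray
    domain_map: dict          # domain label -> (res_lo, res_hi) inclusive

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("coordinates must be finite")
        for ch in np.unique(self.chain_id):
            rid = self.res_id[self.chain_id == ch]
            if len(np.unique(rid)) != len(rid):
                raise ValueError("residue indices must be unique within a chain")

    @property
    def n_atoms(self) -> int:
        return len(self.coords)

    def select(self, chain: str | None = None, res_range: tuple[int, int] | None = None,
               domain: str | None = None) -> np.ndarray:
        """Boolean mask over atoms."""
        mask = np.ones(self.n_atoms, dtype=bool)
        if chain is not None:
            mask &= self.chain_id == chain
        if domain is not None:
            res_range = self.domain_map[domain]
        if res_range is not None:
            mask &= (self.res_id >= res_range[0]) & (self.res_id <= res_range[1])
        return mask

    def atom_index(self, chain: str, res: int) -> int:
        idx = np.flatnonzero((self.chain_id == chain) & (self.res_id == res))
        if idx.size == 0:
            raise KeyError(f"no atom for chain {chain} residue {res}")
        return int(idx[0])


def make_toy_dimer(n_res_per_domain: int = 8, geometry: str = "closedA",
                   seed: int = 0, contraction: float = 0.2,
                   jitter: float = 0.3) -> ToyStructure:
    """Build the two-chain Cα-bead dimer in one of the named geometries.

    Residues run bottom-up per chain: C domain 1..n, M domain n+1..2n,
    N domain 2n+1..3n.  ``contraction`` is the fractional inward shift of
    the kinked chain's M-domain beads in the closedB geometry.
    """
    if n_res_per_domain < 5:
        raise ValueError("n_res_per_domain must be >= 5")
    if geometry not in ("open", "closedA", "closedB"):
        raise ValueError(f"unknown geometry {geometry!r}")
    n = n_res_per_domain
    n_chain = 3 * n
    sep = {"open": 60.0, "closedA": 20.0, "closedB": 20.0}[geometry]

    z = np.arange(n_chain) * BEAD_SPACING
    frac = z / z[-1]                      # 0 at C (bottom), 1 at N (top)
    wobble = 1.5 * np.sin(np.arange(n_chain) * 2.0)

    rng = np.random.default_rng(seed)
    jit = rng.normal(0.0, jitter, size=(2, n_chain, 3))  # geometry-independent

    coords = []
    for c, side in enumerate((-1.0, +1.0)):
        x = side * (2.0 + sep / 2.0 * frac)
        if geometry == "closedB" and side > 0:
            m_sel = slice(n, 2 * n)          # kink chain B toward its partner
            x = x.copy()
            x[m_sel] *= (1.0 - contraction)
            x[:n] *= (1.0 - contraction / 2.0)
        coords.append(np.column_stack([x, wobble * side, z]) + jit[c])
    coords = np.concatenate(coords)

    return ToyStructure(
        coords=coords,
        chain_id=np.repeat(["A", "B"], n_chain),
        res_id=np.tile(np.arange(1, n_chain + 1), 2),
        element=np.full(2 * n_chain, "C"),
        vdw_radius=np.full(2 * n_chain, BEAD_RADIUS),
        mass=np.full(2 * n_chain, 12.0),
        domain_map={"C": (1, n), "M": (n + 1, 2 * n), "N": (2 * n + 1, 3 * n)},
    )


def designated_pairs(structure: ToyStructure) -> list[tuple[tuple[str, int], tuple[str, int]]]:
    """Three inter-chain M-domain bead pairs (first, middle, last M residue)
    used as FRET attachment points; by construction they contract from
    closedA to closedB."""
    lo, hi = structure.domain_map["M"]
    mids = [lo, (lo + hi) // 2, hi]
    return [(("A", r), ("B", r)) for r in mids]


def pair_distance(structure: ToyStructure, pair) -> float:
    (ca, ra), (cb, rb) = pair
    i, j = structure.atom_index(ca, ra), structure.atom_index(cb, rb)
    return float(np.linalg.norm(structure.coords[i] - structure.coords[j]))


def interpolate_coords(start: ToyStructure, end: ToyStructure,
                       n_frames: int = 100) -> np.ndarray:
    """Linear coordinate interpolation between two conformations,
    returned as a (n_frames, n_atoms, 3) array including both endpoints."""
    if start.n_atoms != end.n_atoms:
        raise ValueError("structures must share the atom count")
    lam = np.linspace(0.0, 1.0, n_frames)[:, None, None]
    return (1 - lam) * start.coords[None] + lam * end.coords[None]


# ---------------------------------------------------------------------------
# multi-model PDB I/O (biotite)

def _to_atom_array(structure: ToyStructure) -> bst.AtomArray:
    arr = bst.AtomArray(structure.n_atoms)
    arr.coord = structure.coords.astype(np.float32)
    arr.chain_id = structure.chain_id
    arr.res_id = structure.res_id
    arr.res_name = np.full(structure.n_atoms, "ALA")
    arr.atom_name = np.full(structure.n_atoms, "CA")
    arr.element = structure.element
    return arr


def write_pdb(path, structure: ToyStructure, coords_stack: np.ndarray | None = None) -> None:
    """Write the structure (or a multi-model ensemble sharing its topology)
    as a PDB file."""
    arr = _to_atom_array(structure)
    if coords_stack is None:
        model = arr
    else:
        model = bst.from_template(arr, coords_stack.astype(np.float32))
    f = PDBFile()
    f.set_structure(model)
    f.write(str(path))


def read_pdb_ensemble(path, template: ToyStructure | None = None):
    """Read a (multi-model) PDB; returns ``(coords_stack, ToyStructure)``."""
    f = PDBFile.read(str(path))
    stack = f.get_structure()           # AtomArrayStack
    coords = np.asarray(stack.coord, dtype=float)
    first = stack[0]
    struct = ToyStructure(
        coords=coords[0].copy(),
        chain_id=np.asarray(first.chain_id),
        res_id=np.asarray(first.res_id),
        element=np.asarray(first.element),
        vdw_radius=np.full(coords.shape[1], BEAD_RADIUS)
        if template is None else template.vdw_radius,
        mass=np.full(coords.shape[1], 12.0) if template is None else template.mass,
        domain_map={} if template is None else template.domain_map,
    )
    return coords, struct
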