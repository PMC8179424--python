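"""Structure-ensemble observables: superposition RMSD, domain-fitted RMSD,
radius of gyration, named distance series, contact PCA, and the
hierarchical-timescale event report.

Selections follow 1-based residue numbering; the named defaults reflect the
middle-domain elements that transmit nucleotide-site strain in the
chaperone system this package models: the M-loop (residues 323-340) at the
folding-client binding site, the M-helix (376-408), and the piston residue
Arg380 at its N-terminal end.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

# named default selections (1-based residue ranges)
M_LOOP = (323, 340)
M_HELIX = (376, 408)
PISTON_RESIDUE = 380


@dataclass
class Trajectory:
    """Frames x atoms coordinate block with per-atom metadata."""

    coords: np.ndarray                  # (n_frames, n_atoms, 3), Å
    times: np.ndarray | None = None     # ns
    chain_id: np.ndarray | None = None
    res_id: np.ndarray | None = None
    atom_name: np.ndarray | None = None
    mass: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise ValueError("coords must have shape (frames, atoms, 3)")
        if self.times is None:
            self.times = np.arange(self.n_frames, dtype=float)
        else:
            self.times = np.asarray(self.times, dtype=float)
            if np.any(np.diff(self.times) < 0):
                raise ValueError("timestamps must be monotone")
        if self.mass is None:
            self.mass = np.ones(self.n_atoms)

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[1]

    def select(self, chain=None, res_range=None, names=None) -> np.ndarray:
        """Atom indices matching the chain / residue-range / atom-name
        predicates; raises if the selection is empty."""
        mask = np.ones(self.n_atoms, dtype=bool)
        if chain is not None and self.chain_id is not None:
            mask &= self.chain_id == chain
        if res_range is not None and self.res_id is not None:
            mask &= (self.res_id >= res_range[0]) & (self.res_id <= res_range[1])
        if names is not None and self.atom_name is not None:
            mask &= np.isin(self.atom_name, np.atleast_1d(names))
        idx = np.flatnonzero(mask)
        if idx.size == 0:
            raise ValueError("empty selection")
        return idx

    @classmethod
    def from_structure(cls, structure, coords_stack: np.ndarray,
                       times=None) -> "Trajectory":
        """Build from a ToyStructure-like topology and a coordinate stack."""
        return cls(coords_stack, times,
                   chain_id=np.asarray(structure.chain_id),
                   res_id=np.asarray(structure.res_id),
                   mass=np.asarray(structure.mass, dtype=float))


def superpose(mobile: np.ndarray, reference: np.ndarray,
              weights: np.ndarray | None = None):
    """Least-squares optimal rigid superposition (Kabsch, via SVD).

    Returns ``(rotation, translation, rmsd)`` with the convention
    ``aligned = mobile @ rotation.T + translation``.
    """
    mob = np.asarray(mobile, float)
    ref = np.asarray(reference, float)
    if mob.shape != ref.shape or mob.shape[0] < 3:
        raise ValueError("need matching selections with >= 3 atoms")
    w = np.ones(len(mob)) if weights is None else np.asarray(weights, float)
    w = w / w.sum()
    mc = (w[:, None] * mob).sum(0)
    rc = (w[:, None] * ref).sum(0)
    a = mob - mc
    b = ref - rc
    h = (w[:, None] * a).T @ b
    u, s, vt = np.linalg.svd(h)
    if s[1] < 1e-12 * max(s[0], 1.0):
        raise ValueError("degenerate (collinear) fit selection")
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rot = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    trans = rc - rot @ mc
    aligned = a @ rot.T + rc
    rmsd = float(np.sqrt((w * ((aligned - ref) ** 2).sum(1)).sum()))
    return rot, trans, rmsd


def domain_rmsd(traj: Trajectory, fit_idx: np.ndarray, measure_idx: np.ndarray,
                reference: np.ndarray) -> np.ndarray:
    """Per-frame: superpose on ``fit_idx``, then RMSD over ``measure_idx``
    without refitting — reports how one region moves in the frame of
    another (e.g. M-domain motion in the N-domain frame)."""
    ref = np.asarray(reference, float)
    out = np.empty(traj.n_frames)
    for f in range(traj.n_frames):
        rot, trans, _ = superpose(traj.coords[f][fit_idx], ref[fit_idx])
        moved = traj.coords[f][measure_idx] @ rot.T + trans
        out[f] = np.sqrt(((moved - ref[measure_idx]) ** 2).sum(1).mean())
    return out


def radius_of_gyration(traj: Trajectory, idx: np.ndarray | None = None,
                       mass_weighted: bool = True) -> np.ndarray:
    """Rg(t) = sqrt(sum m_i |r_i - r_cm|^2 / sum m_i)."""
    idx = np.arange(traj.n_atoms) if idx is None else np.asarray(idx)
    m = traj.mass[idx] if mass_weighted else np.ones(idx.size)
    if m.sum() <= 0:
        raise ValueError("zero total mass")
    x = traj.coords[:, idx, :]
    cm = (m[None, :, None] * x).sum(1) / m.sum()
    d2 = ((x - cm[:, None, :]) ** 2).sum(2)
    return np.sqrt((m[None, :] * d2).sum(1) / m.sum())


def distance_series(traj: Trajectory, idx1: np.ndarray, idx2: np.ndarray,
                    mode: str = "mass-center") -> np.ndarray:
    """Per-frame Euclidean distance between two atom groups.

    ``mode='mass-center'`` uses mass-weighted centres; ``mode='atom'``
    requires single-atom groups.
    """
    idx1, idx2 = np.atleast_1d(idx1), np.atleast_1d(idx2)
    if idx1.size == 0 or idx2.size == 0:
        raise ValueError("empty atom group")
    if mode == "atom":
        if idx1.size != 1 or idx2.size != 1:
            raise ValueError("atom mode requires single-atom groups")
        d = traj.coords[:, idx1[0]] - traj.coords[:, idx2[0]]
        return np.linalg.norm(d, axis=1)
    if mode != "mass-center":
        raise ValueError("mode must be 'atom' or 'mass-center'")
    m1 = traj.mass[idx1]
    m2 = traj.mass[idx2]
    c1 = (m1[None, :, None] * traj.coords[:, idx1]).sum(1) / m1.sum()
    c2 = (m2[None, :, None] * traj.coords[:, idx2]).sum(1) / m2.sum()
    return np.linalg.norm(c1 - c2, axis=1)


# ---------------------------------------------------------------------------
# contact PCA

@dataclass
class ContactPCAResult:
    pairs: list                        # (atom_i, atom_j) contact pairs
    eigenvalues: np.ndarray            # descending
    eigenvectors: np.ndarray           # columns, matching `pairs` order
    projections: dict                  # label -> (n_frames, 2)
    loadings: pd.DataFrame             # per-contact |weight| on PC1/PC2
    dropped: list = field(default_factory=list)   # zero-variance pairs


def contact_pca(trajs: dict, atom_idx: np.ndarray, cutoff: float = 10.0,
                n_components: int = 2) -> ContactPCAResult:
    """Correlation-based PCA of inter-residue contact distances.

    Builds the pair list from ``atom_idx`` atoms whose distance falls below
    ``cutoff`` in any frame of any trajectory, z-scores each distance
    coordinate over the pooled frames, eigendecomposes the correlation
    matrix, and projects every trajectory onto the leading components.
    Zero-variance coordinates are dropped with a record.
    """
    labels = list(trajs)
    atom_idx = np.asarray(atom_idx)
    ii, jj = np.triu_indices(atom_idx.size, k=1)

    # contact pairs: within cutoff in any frame
    within = np.zeros(ii.size, dtype=bool)
    dists_per_traj = {}
    for lab in labels:
        x = trajs[lab].coords[:, atom_idx, :]
        d = np.linalg.norm(x[:, ii, :] - x[:, jj, :], axis=2)  # (F, n_pairs)
        dists_per_traj[lab] = d
        within |= (d < cutoff).any(axis=0)
    if within.sum() < 2:
        raise ValueError("fewer than 2 contact pairs within the cutoff")
    ii, jj = ii[within], jj[within]
    pooled = np.concatenate([dists_per_traj[lab][:, within] for lab in labels])

    mean = pooled.mean(0)
    std = pooled.std(0)
    keep = std > 1e-10
    dropped = [(int(atom_idx[a]), int(atom_idx[b]))
               for a, b in zip(ii[~keep], jj[~keep])]
    if keep.sum() < 2:
        raise ValueError("all contact coordinates have zero variance")
    ii, jj = ii[keep], jj[keep]
    z = (pooled[:, keep] - mean[keep]) / std[keep]

    corr = (z.T @ z) / len(z)
    evals, evecs = np.linalg.eigh(corr)
    order = np.argsort(evals)[::-1]
    evals = np.clip(evals[order], 0.0, None)
    evecs = evecs[:, order]

    projections = {}
    start = 0
    for lab in labels:
        nf = len(dists_per_traj[lab])
        projections[lab] = z[start:start + nf] @ evecs[:, :n_components]
        start += nf

    pairs = [(int(atom_idx[a]), int(atom_idx[b])) for a, b in zip(ii, jj)]
    loadings = pd.DataFrame({
        "pair": pairs,
        "pc1": np.abs(evecs[:, 0]),
        "pc2": np.abs(evecs[:, 1]) if evecs.shape[1] > 1 else 0.0,
    }).sort_values("pc1", ascending=False, ignore_index=True)

    return ContactPCAResult(pairs, evals, evecs, projections, loadings, dropped)


# ---------------------------------------------------------------------------
# hierarchical timescale report

def timescale_report(series: dict, thresholds: dict,
                     window: int = 5) -> pd.DataFrame:
    """First-crossing event table for a set of time series.

    Each series is smoothed with a ``window``-sample running mean; the event
    time is the first time the smoothed series crosses its threshold
    (upward).  The returned table is ordered by event time with absent
    events (never crossed) last, so a hierarchy of planted response times
    appears as the row order.
    """
    rows = []
    for name, (t, y) in series.items():
        t = np.asarray(t, float)
        y = np.asarray(y, float)
        if window > 1 and y.size >= window:
            kernel = np.ones(window) / window
            ys = np.convolve(y, kernel, mode="valid")
            ts = t[window - 1:]
        else:
            ys, ts = y, t
        thr = thresholds[name]
        above = ys >= thr
        if above.any():
            rows.append({"series": name, "event_time": float(ts[np.argmax(above)]),
                         "threshold": thr, "crossed": True})
        else:
            rows.append({"series": name, "event_time": np.inf,
                         "threshold": thr, "crossed": False})
    df = pd.DataFrame(rows).sort_values("event_time", ignore_index=True)
    return df
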