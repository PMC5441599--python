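"""MD-trajectory post-processing: RMSD, clustering, end-to-end regimes and
quenching-state classification.

The analysis chain mirrors standard practice for disordered-peptide
trajectories: heavy-atom RMSD after optimal rigid-body superposition
(Kabsch), single-linkage conformational clustering (clusters = connected
components of the graph linking frames closer than a cutoff, default
0.25 nm), a ternary open/intermediate/close regime assignment of the
end-to-end distance (C-beta i..j, thresholds 1.3 / 2.5 nm) with
hysteresis-style transition counting, and a binary dark/fluorescent
classification by the fluorophore-quencher ring-center distance
(r* = 0.55 nm) whose autocorrelation is fit to a single-exponential
two-state model.

Coordinates are nanometres throughout; residue indices are 1-based.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import sparse
from scipy.sparse.csgraph import connected_components

from .datatypes import (BRIGHT, CLOSE, DARK, INTERMEDIATE, OPEN,
                        CorrelationCurve, StateSequence)

__all__ = [
    "TrajectoryEnsemble",
    "QuenchCriterion",
    "RegimeThresholds",
    "ClusterResult",
    "TransitionStats",
    "TRP_RING_ATOMS",
    "kabsch_rmsd",
    "rmsd",
    "pairwise_rmsd",
    "select_atoms",
    "single_linkage_cluster",
    "min_rmsd_to_reference",
    "end_to_end_series",
    "count_transitions",
    "quench_series",
    "quench_autocorrelation",
]

#: side-chain ring atoms of tryptophan (the quencher); the fluorophore ring
#: group has no standard naming and must be supplied explicitly.
TRP_RING_ATOMS = ("CG", "CD1", "CD2", "NE1", "CE2", "CE3", "CZ2", "CZ3", "CH2")


@dataclass
class TrajectoryEnsemble:
    """Reference structure plus per-frame coordinates with atom metadata.

    ``atoms`` columns: resid (1-based), resname, name, element.
    Coordinates in nm, frame spacing in ns.
    """

    atoms: pd.DataFrame
    reference: np.ndarray
    frames: np.ndarray
    dt_frame_ns: float = 1.0

    def __post_init__(self) -> None:
        self.reference = np.asarray(self.reference, dtype=float)
        self.frames = np.asarray(self.frames, dtype=float)
        n = len(self.atoms)
        if self.reference.shape != (n, 3):
            raise ValueError("reference shape does not match the atom table")
        if self.frames.ndim != 3 or self.frames.shape[1:] != (n, 3):
            raise ValueError("frames must have shape (n_frames, n_atoms, 3)")
        if not (np.all(np.isfinite(self.reference)) and np.all(np.isfinite(self.frames))):
            raise ValueError("coordinates must be finite")
        if self.dt_frame_ns <= 0:
            raise ValueError("dt_frame_ns must be positive")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.frames.shape[1]

    @property
    def duration_us(self) -> float:
        return self.n_frames * self.dt_frame_ns * 1e-3

    # ---- I/O ------------------------------------------------------------
    @classmethod
    def from_pdb(cls, pdb_path, frames_path=None, dt_frame_ns: float = 1.0):
        """Topology and reference coordinates from a PDB file (via
        MDAnalysis, Angstrom -> nm); frames from a plain coordinate table
        or, if omitted, the reference as a single frame."""
        import MDAnalysis as mda

        u = mda.Universe(str(pdb_path))
        ag = u.atoms
        elements = [getattr(a, "element", "") or _guess_element(a.name) for a in ag]
        atoms = pd.DataFrame({
            "resid": ag.resids.astype(int),
            "resname": [r for r in ag.resnames],
            "name": [n for n in ag.names],
            "element": elements,
        })
        ref = ag.positions.astype(float) / 10.0
        if frames_path is not None:
            frames = read_frames_table(frames_path, len(ag))
        else:
            frames = ref[None]
        return cls(atoms, ref, frames, dt_frame_ns)

    def write_pdb(self, path, frame: int | None = None) -> None:
        """Write the reference (or one frame) as PDB via MDAnalysis."""
        import MDAnalysis as mda

        coords = self.reference if frame is None else self.frames[frame]
        u = mda.Universe.empty(self.n_atoms, n_residues=int(self.atoms["resid"].nunique()),
                               atom_resindex=pd.factorize(self.atoms["resid"])[0],
                               trajectory=True)
        u.add_TopologyAttr("names", self.atoms["name"].tolist())
        resorder = self.atoms.drop_duplicates("resid")
        u.add_TopologyAttr("resnames", resorder["resname"].tolist())
        u.add_TopologyAttr("resids", resorder["resid"].tolist())
        u.atoms.positions = coords * 10.0
        u.atoms.write(str(path))

    def write_frames_table(self, path) -> None:
        f, a, _ = self.frames.shape
        idx_f = np.repeat(np.arange(f), a)
        idx_a = np.tile(np.arange(a), f)
        flat = self.frames.reshape(-1, 3)
        df = pd.DataFrame({"frame": idx_f, "atom": idx_a,
                           "x_nm": flat[:, 0], "y_nm": flat[:, 1], "z_nm": flat[:, 2]})
        df.to_csv(path, index=False)


def _guess_element(name: str) -> str:
    return name.strip("0123456789")[:1].upper() or "X"


def read_frames_table(path, n_atoms: int) -> np.ndarray:
    df = pd.read_csv(path)
    n_frames = int(df["frame"].max()) + 1
    frames = np.full((n_frames, n_atoms, 3), np.nan)
    frames[df["frame"].to_numpy(), df["atom"].to_numpy()] = \
        df[["x_nm", "y_nm", "z_nm"]].to_numpy()
    if np.any(np.isnan(frames)):
        raise ValueError("frames table is missing atoms in some frames")
    return frames


# ---- selections ---------------------------------------------------------

def select_atoms(atoms: pd.DataFrame, resids=None, names=None,
                 heavy_only: bool = False) -> np.ndarray:
    """Indices of atoms matching the given residue ids / atom names."""
    mask = np.ones(len(atoms), dtype=bool)
    if resids is not None:
        mask &= atoms["resid"].isin(np.atleast_1d(resids)).to_numpy()
    if names is not None:
        mask &= atoms["name"].isin(list(np.atleast_1d(names))).to_numpy()
    if heavy_only:
        mask &= (atoms["element"].str.upper() != "H").to_numpy()
    return np.flatnonzero(mask)


# ---- RMSD ---------------------------------------------------------------

def kabsch_rmsd(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Minimum RMSD between paired coordinate sets after optimal rigid-body
    superposition (rotation + translation), batched over leading axes.

    Uses the SVD trace identity: with centered A, B and H = A^T B,
    rmsd^2 = (|A|^2 + |B|^2 - 2(s1 + s2 +/- s3))/k, the sign chosen to keep
    the rotation proper.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    a, b = np.broadcast_arrays(a, b)
    k = a.shape[-2]
    ac = a - a.mean(axis=-2, keepdims=True)
    bc = b - b.mean(axis=-2, keepdims=True)
    ga = np.einsum("...ki,...ki->...", ac, ac)
    gb = np.einsum("...ki,...ki->...", bc, bc)
    h = np.einsum("...ki,...kj->...ij", ac, bc)
    u, s, vt = np.linalg.svd(h)
    sign = np.sign(np.linalg.det(u) * np.linalg.det(vt))
    trace = s[..., 0] + s[..., 1] + sign * s[..., 2]
    msd = np.maximum(ga + gb - 2.0 * trace, 0.0) / k
    return np.sqrt(msd)


def rmsd(frame_a: np.ndarray, frame_b: np.ndarray,
         selection: np.ndarray | None = None) -> float:
    """Superposed RMSD (nm) between two frames on an atom selection."""
    a = np.asarray(frame_a, dtype=float)
    b = np.asarray(frame_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("frames have mismatched atom counts")
    if selection is not None:
        a = a[selection]
        b = b[selection]
    if a.shape[0] < 3:
        raise ValueError("need at least three atoms for superposition")
    return float(kabsch_rmsd(a, b))


def pairwise_rmsd(coords: np.ndarray) -> np.ndarray:
    """Dense pairwise superposed-RMSD matrix (small ensembles only)."""
    n = coords.shape[0]
    ii, jj = np.triu_indices(n, k=1)
    d = np.zeros((n, n))
    vals = _rmsd_pairs(coords, ii, jj)
    d[ii, jj] = vals
    d[jj, ii] = vals
    return d


def _rmsd_pairs(coords, ii, jj, chunk: int = 200_000) -> np.ndarray:
    out = np.empty(ii.size)
    for s in range(0, ii.size, chunk):
        sl = slice(s, s + chunk)
        out[sl] = kabsch_rmsd(coords[ii[sl]], coords[jj[sl]])
    return out


# ---- clustering ---------------------------------------------------------

@dataclass
class ClusterResult:
    """Single-linkage clustering output.

    ``labels`` are 1-based and sorted by population (cluster 1 is the
    largest); ``populations_pct`` and ``medoid_frames`` are indexed by
    cluster label - 1.
    """

    labels: np.ndarray
    populations_pct: np.ndarray
    medoid_frames: np.ndarray
    cutoff_nm: float

    @property
    def n_clusters(self) -> int:
        return self.populations_pct.size

    def members(self, label: int) -> np.ndarray:
        return np.flatnonzero(self.labels == label)


def _cluster_edges(coords, cutoff, n_pivots=8):
    """Edge list (i, j) with superposed RMSD < cutoff, using
    triangle-inequality pruning against a set of pivot frames."""
    n = coords.shape[0]
    piv = np.unique(np.linspace(0, n - 1, min(n_pivots, n)).astype(int))
    dpiv = np.stack([kabsch_rmsd(coords, coords[p][None]) for p in piv])  # (P, n)
    rows, cols = [], []
    for i in range(n - 1):
        j = np.arange(i + 1, n)
        lb = np.abs(dpiv[:, i, None] - dpiv[:, j]).max(axis=0)
        cand = j[lb < cutoff]
        if cand.size == 0:
            continue
        d = kabsch_rmsd(coords[i][None], coords[cand])
        hit = cand[d < cutoff]
        rows.append(np.full(hit.size, i))
        cols.append(hit)
    if rows:
        return np.concatenate(rows), np.concatenate(cols)
    return np.empty(0, int), np.empty(0, int)


def single_linkage_cluster(ensemble, selection: np.ndarray | None = None,
                           cutoff_nm: float = 0.25,
                           n_pivots: int = 8) -> ClusterResult:
    """Single-linkage conformational clustering at an RMSD cutoff.

    Clusters are the connected components of the graph with an edge
    wherever the pairwise superposed RMSD is below ``cutoff_nm``; they are
    sorted and numbered by their frequency of occurrence.  The
    representative of each cluster is its medoid (member minimizing the
    summed RMSD to the other members).  Exact at desk scale (intended for
    up to ~2e4 frames; pruning against pivot frames keeps the pair count
    manageable).
    """
    frames = ensemble.frames if isinstance(ensemble, TrajectoryEnsemble) else np.asarray(ensemble)
    if frames.ndim != 3:
        raise ValueError("expected frames of shape (n_frames, n_atoms, 3)")
    if selection is not None:
        if len(selection) == 0:
            raise ValueError("empty atom selection")
        frames = frames[:, selection, :]
    n = frames.shape[0]
    if n < 1:
        raise ValueError("need at least one frame")
    coords = frames - frames.mean(axis=1, keepdims=True)
    rows, cols = _cluster_edges(coords, cutoff_nm, n_pivots)
    graph = sparse.coo_matrix((np.ones(rows.size), (rows, cols)), shape=(n, n))
    n_comp, comp = connected_components(graph, directed=False)
    sizes = np.bincount(comp, minlength=n_comp)
    # sort components by size (desc), ties by first occurrence (asc)
    first = np.full(n_comp, n)
    np.minimum.at(first, comp, np.arange(n))
    order = np.lexsort((first, -sizes))
    rank = np.empty(n_comp, int)
    rank[order] = np.arange(1, n_comp + 1)
    labels = rank[comp]
    pops = 100.0 * sizes[order] / n
    medoids = np.empty(n_comp, int)
    for new_label, old in enumerate(order, start=1):
        members = np.flatnonzero(comp == old)
        if members.size == 1:
            medoids[new_label - 1] = members[0]
            continue
        sub = coords[members]
        ii, jj = np.triu_indices(members.size, k=1)
        d = _rmsd_pairs(sub, ii, jj)
        sums = np.zeros(members.size)
        np.add.at(sums, ii, d)
        np.add.at(sums, jj, d)
        medoids[new_label - 1] = members[np.argmin(sums)]
    return ClusterResult(labels, pops, medoids, cutoff_nm)


def min_rmsd_to_reference(ensemble, targets, selection: np.ndarray | None = None):
    """Minimum superposed RMSD from any frame of the ensemble to each
    target structure; returns arrays (min_rmsd_nm, argmin_frame).

    ``targets`` is one (n_atoms, 3) structure or a sequence of them (e.g.
    medoid structures of another ensemble's clusters).
    """
    frames = ensemble.frames if isinstance(ensemble, TrajectoryEnsemble) else np.asarray(ensemble)
    if frames.shape[0] == 0:
        raise ValueError("empty ensemble")
    tgt = np.asarray(targets, dtype=float)
    single = tgt.ndim == 2
    if single:
        tgt = tgt[None]
    if selection is not None:
        frames = frames[:, selection, :]
        tgt = tgt[:, selection, :]
    mins = np.empty(tgt.shape[0])
    amins = np.empty(tgt.shape[0], int)
    for t in range(tgt.shape[0]):
        d = kabsch_rmsd(frames, tgt[t][None])
        amins[t] = int(np.argmin(d))
        mins[t] = d[amins[t]]
    if single:
        return float(mins[0]), int(amins[0])
    return mins, amins


# ---- end-to-end regimes -------------------------------------------------

@dataclass
class RegimeThresholds:
    """Open/close regime thresholds on the end-to-end distance (strict
    inequalities: d < d_close -> close, d > d_open -> open, else
    intermediate)."""

    d_close_nm: float = 1.3
    d_open_nm: float = 2.5
    resid_pair: tuple = (1, 14)
    atom_name: str = "CB"

    def __post_init__(self) -> None:
        if not self.d_close_nm < self.d_open_nm:
            raise ValueError("d_close must be below d_open")


def _single_atom(atoms: pd.DataFrame, resid: int, name: str) -> int:
    idx = select_atoms(atoms, resids=resid, names=name)
    if idx.size == 0:
        res = atoms.loc[atoms["resid"] == resid, "resname"]
        resname = res.iloc[0] if len(res) else "<absent>"
        raise ValueError(f"no atom {name!r} in residue {resid} ({resname}); "
                         "glycine and non-standard residues need another selection")
    return int(idx[0])


def classify_distances(d_nm: np.ndarray, thresholds: RegimeThresholds) -> np.ndarray:
    labels = np.full(d_nm.shape, INTERMEDIATE, dtype=np.int8)
    labels[d_nm < thresholds.d_close_nm] = CLOSE
    labels[d_nm > thresholds.d_open_nm] = OPEN
    return labels


def end_to_end_series(ensemble: TrajectoryEnsemble,
                      thresholds: RegimeThresholds | None = None):
    """Per-frame end-to-end distance (C-beta to C-beta) and its ternary
    regime assignment.  Returns (distances_nm, StateSequence)."""
    thresholds = thresholds or RegimeThresholds()
    r1, r2 = thresholds.resid_pair
    i = _single_atom(ensemble.atoms, r1, thresholds.atom_name)
    j = _single_atom(ensemble.atoms, r2, thresholds.atom_name)
    delta = ensemble.frames[:, i, :] - ensemble.frames[:, j, :]
    d = np.linalg.norm(delta, axis=1)
    labels = classify_distances(d, thresholds)
    return d, StateSequence(labels, ensemble.dt_frame_ns, "ternary")


@dataclass
class TransitionStats:
    n_transitions: int
    rate_per_us: float
    total_time_us: float


def count_transitions(states: StateSequence,
                      total_time_us: float | None = None) -> TransitionStats:
    """Count open <-> close regime switches and the mean transition rate.

    Last-assigned-regime (hysteresis) semantics: intermediate frames keep
    the previously assigned regime, so an excursion into the intermediate
    band and back does not count.  Both switching directions contribute to
    N_T; rate = N_T / total simulation time.
    """
    if states.n < 2:
        raise ValueError("need at least two frames")
    if total_time_us is None:
        total_time_us = states.duration_us
    v = states.values
    assigned = v[(v == OPEN) | (v == CLOSE)]
    if assigned.size == 0:
        warnings.warn("no frame ever entered the open or close regime",
                      stacklevel=2)
        return TransitionStats(0, 0.0, total_time_us)
    n_t = int(np.count_nonzero(assigned[1:] != assigned[:-1]))
    return TransitionStats(n_t, n_t / total_time_us, total_time_us)


# ---- quenching ----------------------------------------------------------

@dataclass
class QuenchCriterion:
    """Dark-state criterion: geometric centers of the fluorophore and
    quencher ring systems closer than ``r_star_nm`` (strict <).

    ``group_a``/``group_b`` are atom-name lists; optional residue filters
    disambiguate when names repeat across residues.  The tryptophan ring
    default is :data:`TRP_RING_ATOMS`; the fluorophore ring group has no
    standard naming and must be supplied.
    """

    group_a: tuple
    group_b: tuple = TRP_RING_ATOMS
    r_star_nm: float = 0.55
    resid_a: int | None = None
    resid_b: int | None = None

    def __post_init__(self) -> None:
        self.group_a = tuple(self.group_a)
        self.group_b = tuple(self.group_b)
        if not self.group_a or not self.group_b:
            raise ValueError("ring-atom groups must be non-empty")
        if self.r_star_nm <= 0:
            raise ValueError("r_star must be positive")


def _resolve_group(atoms, names, resid, label) -> np.ndarray:
    idx = select_atoms(atoms, resids=resid, names=names)
    found = set(atoms["name"].iloc[idx])
    missing = [n for n in names if n not in found]
    if missing:
        raise ValueError(f"ring group {label} has unresolved atoms: {missing}")
    return idx


def quench_series(ensemble: TrajectoryEnsemble,
                  criterion: QuenchCriterion) -> StateSequence:
    """Binary fluorescent(1)/dark(0) classification per frame by the
    ring-center distance criterion (dark iff distance < r*)."""
    ia = _resolve_group(ensemble.atoms, criterion.group_a, criterion.resid_a, "A")
    ib = _resolve_group(ensemble.atoms, criterion.group_b, criterion.resid_b, "B")
    if set(ia) & set(ib):
        raise ValueError("ring groups overlap; they must be disjoint")
    ca = ensemble.frames[:, ia, :].mean(axis=1)
    cb = ensemble.frames[:, ib, :].mean(axis=1)
    d = np.linalg.norm(ca - cb, axis=1)
    values = np.where(d < criterion.r_star_nm, DARK, BRIGHT).astype(np.int8)
    return StateSequence(values, ensemble.dt_frame_ns, "binary")


def quench_autocorrelation(states: StateSequence, *,
                           start_time_us: float = 0.0,
                           max_lag_frames: int | None = None,
                           n_segments: int = 10,
                           min_pairs: int = 100,
                           convention: str = "as_printed"):
    """Autocorrelation of the fluorescent-state signal and its two-state fit.

    Computes the direct (brute-force) normalized autocorrelation of the
    binary bright signal on a logarithmic lag subset, subtracts the
    baseline 1, attaches per-lag standard errors from ``n_segments``
    equal-length segments, restricts to lags with at least ``min_pairs``
    contributing pairs and fits ``a_r exp(-tau/tau_r)``.

    ``start_time_us`` discards an initial equilibration window before the
    analysis (the protocol used to separate a slow initial regime from the
    equilibrated one).  Returns (CorrelationCurve in excess convention,
    DynamicFit).
    """
    from .correlate import direct_correlation, log_lag_indices
    from .fitting import fit_two_state

    seq = states.window(start_ns=start_time_us * 1e3)
    v = seq.values
    if np.all(v == v[0]):
        raise ValueError("signal never switches state; correlation amplitude undefined")
    sig = (v == BRIGHT).astype(float)
    n = sig.size
    if max_lag_frames is None:
        max_lag_frames = n // 10
    seg_len = n // n_segments
    max_lag_frames = min(max_lag_frames, max(2, seg_len // 4))
    lags = log_lag_indices(n, max_lag=max_lag_frames)
    dt_s = seq.dt_ns * 1e-9
    curve = direct_correlation(sig, dt_s, lags=lags)
    seg_curves = [direct_correlation(sig[i * seg_len:(i + 1) * seg_len], dt_s, lags=lags)
                  for i in range(n_segments)]
    stack = np.vstack([c.values for c in seg_curves])
    sem = stack.std(axis=0, ddof=1) / np.sqrt(n_segments)
    curve = CorrelationCurve(curve.lags_s, curve.values, sem, "raw", curve.npairs)
    curve = curve.select(curve.npairs >= min_pairs).to_excess()
    fit = fit_two_state(curve, convention=convention)
    return curve, fit
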