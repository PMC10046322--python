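"""Rigid-body superposition and first-line ensemble stability statistics.

RMSD series are measured against a reference structure after least-squares
fitting (Kabsch, reflection excluded). RMSF uses the iteratively converged
average structure as the reference: every frame is fitted to the current
mean, the mean is recomputed, and the cycle repeats until the mean moves
by less than 1e-6 A (at most 10 iterations) - this removes the arbitrary
bias of fitting to any single frame. Clustering is hierarchical
average-linkage on the pairwise best-fit RMSD matrix, cut to k clusters
(k=2 by default, matching the two dominant conformational states typically
resolved for lid-gated hydrolases).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .io import Ensemble, SelectionMask, Structure

__all__ = [
    "SuperpositionResult",
    "RMSFProfile",
    "ClusterAssignment",
    "kabsch",
    "rmsd_series",
    "rmsf_profile",
    "rmsf_difference",
    "radius_of_gyration",
    "cluster_frames",
    "iterative_mean_fit",
]


@dataclass
class SuperpositionResult:
    """Optimal rigid transform mapping mobile onto reference coordinates."""

    rotation: np.ndarray     # (3, 3), det = +1
    translation: np.ndarray  # (3,), angstrom
    rmsd: float              # masked RMSD after the fit, angstrom

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return coords @ self.rotation.T + self.translation


@dataclass
class RMSFProfile:
    """Per-residue root-mean-square fluctuation about the average structure."""

    values: np.ndarray        # (n_res,), angstrom
    residue_ids: np.ndarray   # author numbering
    mask: SelectionMask
    reference: np.ndarray     # converged average coordinates of masked atoms

    def __post_init__(self):
        if np.any(self.values < 0):
            raise ValueError("RMSF values must be non-negative")
        if len(self.values) != len(self.residue_ids):
            raise ValueError("one RMSF value per residue required")


@dataclass
class ClusterAssignment:
    labels: np.ndarray          # (F,) 0-based cluster label per frame
    fractions: np.ndarray       # (k,) population fraction per cluster
    representatives: np.ndarray  # (k,) medoid frame index per cluster

    def __post_init__(self):
        if not np.isclose(self.fractions.sum(), 1.0):
            raise ValueError("cluster fractions must sum to 1")
        for c, rep in enumerate(self.representatives):
            if self.labels[rep] != c:
                raise ValueError(f"representative {rep} not in cluster {c}")


def _masked(coords: np.ndarray, mask: SelectionMask | None) -> np.ndarray:
    return coords if mask is None else coords[mask.indices]


def kabsch(mobile: np.ndarray, reference: np.ndarray,
           mask: SelectionMask | None = None) -> SuperpositionResult:
    """Least-squares rigid superposition of mobile onto reference.

    Reflections are excluded (det(R) = +1). Raises on fewer than three
    masked atoms or a collinear/degenerate masked point set.
    """
    mob = _masked(np.asarray(mobile, dtype=float), mask)
    ref = _masked(np.asarray(reference, dtype=float), mask)
    if mob.shape != ref.shape:
        raise ValueError(f"shape mismatch {mob.shape} vs {ref.shape}")
    if len(mob) < 3:
        raise ValueError("superposition needs at least 3 masked atoms")
    mob_c = mob.mean(axis=0)
    ref_c = ref.mean(axis=0)
    a = mob - mob_c
    b = ref - ref_c
    # collinearity check: centered reference must span >= 2 dimensions
    if np.linalg.matrix_rank(b, tol=1e-8 * max(1.0, np.abs(b).max())) < 2:
        raise ValueError("masked atoms are collinear; superposition is degenerate")
    h = a.T @ b
    u, s, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    diag = np.diag([1.0, 1.0, d])
    rot = vt.T @ diag @ u.T
    trans = ref_c - rot @ mob_c
    fitted = mob @ rot.T + trans
    rmsd = float(np.sqrt(np.mean(np.sum((fitted - ref) ** 2, axis=1))))
    return SuperpositionResult(rotation=rot, translation=trans, rmsd=rmsd)


def rmsd_series(ensemble: Ensemble, reference: "Structure | np.ndarray",
                fit_mask: SelectionMask | None = None,
                measure_mask: SelectionMask | None = None) -> np.ndarray:
    """Per-frame RMSD (A) to a reference after fitting each frame on fit_mask."""
    ref = reference.coords if isinstance(reference, Structure) else np.asarray(reference)
    if measure_mask is None:
        measure_mask = fit_mask
    out = np.empty(ensemble.n_frames)
    for f in range(ensemble.n_frames):
        fit = kabsch(ensemble.frames[f], ref, fit_mask)
        moved = fit.apply(ensemble.frames[f])
        diff = _masked(moved, measure_mask) - _masked(ref, measure_mask)
        out[f] = np.sqrt(np.mean(np.sum(diff ** 2, axis=1)))
    return out


def iterative_mean_fit(frames: np.ndarray, mask: SelectionMask | None = None,
                       tol: float = 1e-6, max_iter: int = 10):
    """Fit all frames to their converged average structure.

    Returns (fitted_frames, mean_coords). The mean is recomputed after each
    fitting pass until it shifts by less than ``tol`` angstrom (RMS), at
    most ``max_iter`` passes.
    """
    fitted = np.array(frames, dtype=float, copy=True)
    mean = fitted[0].copy()
    for _ in range(max_iter):
        for f in range(len(fitted)):
            fitted[f] = kabsch(fitted[f], mean, mask).apply(fitted[f])
        new_mean = fitted.mean(axis=0)
        shift = np.sqrt(np.mean(np.sum((new_mean - mean) ** 2, axis=1)))
        mean = new_mean
        if shift < tol:
            break
    return fitted, mean


def rmsf_profile(ensemble: Ensemble, mask: SelectionMask) -> RMSFProfile:
    """Per-residue RMSF about the iteratively converged average structure.

    The mask is expected to pick one atom per residue (typically C-alpha);
    with several atoms per residue the per-residue value is the RMS over
    that residue's atoms.
    """
    if ensemble.n_frames < 2:
        raise ValueError("RMSF needs at least 2 frames")
    fitted, mean = iterative_mean_fit(ensemble.frames, mask)
    sub = fitted[:, mask.indices, :]
    msd = np.mean(np.sum((sub - mean[mask.indices]) ** 2, axis=2), axis=0)  # per atom
    resids = ensemble.topology.res_ids[mask.indices]
    unique = list(dict.fromkeys(resids.tolist()))
    values = np.array([np.sqrt(msd[resids == r].mean()) for r in unique])
    return RMSFProfile(values=values, residue_ids=np.array(unique),
                       mask=mask, reference=mean[mask.indices])


def rmsf_difference(profile_a: RMSFProfile, profile_b: RMSFProfile,
                    structure: Structure | None = None, path=None) -> np.ndarray:
    """Delta RMSF (a - b) per residue; optionally written to a PDB B-factor column.

    Atoms of residues outside the profiles get B-factor 0.
    """
    if not np.array_equal(profile_a.residue_ids, profile_b.residue_ids):
        raise ValueError("RMSF profiles cover different residue sets")
    delta = profile_a.values - profile_b.values
    if path is not None:
        if structure is None:
            raise ValueError("writing a B-factor PDB requires a structure")
        from .io import write_structure

        per_res = dict(zip(profile_a.residue_ids.tolist(), delta))
        bfac = np.array([per_res.get(int(r), 0.0) for r in structure.res_ids])
        write_structure(structure, path, bfactors=bfac)
    return delta


def radius_of_gyration(ensemble: Ensemble,
                       mask: SelectionMask | None = None) -> np.ndarray:
    """Mass-weighted radius of gyration per frame (A); element masses."""
    idx = mask.indices if mask is not None else np.arange(ensemble.n_atoms)
    if len(idx) == 0:
        raise ValueError("empty mask")
    m = ensemble.topology.masses()[idx]
    sub = ensemble.frames[:, idx, :]
    com = (m[None, :, None] * sub).sum(axis=1) / m.sum()
    sq = np.sum((sub - com[:, None, :]) ** 2, axis=2)
    return np.sqrt((m[None, :] * sq).sum(axis=1) / m.sum())


def pairwise_rmsd_matrix(ensemble: Ensemble,
                         mask: SelectionMask | None = None) -> np.ndarray:
    """Symmetric (F, F) matrix of per-pair best-fit RMSD on the mask.

    Uses the closed-form Kabsch RMSD via batched 3x3 SVDs:
    rmsd^2 = (|A|^2 + |B|^2 - 2 (s1 + s2 +/- s3)) / n with the s3 sign
    flipped for reflection-excluded pairs.
    """
    frames = ensemble.frames if mask is None else ensemble.frames[:, mask.indices]
    f, n, _ = frames.shape
    x = frames - frames.mean(axis=1, keepdims=True)
    g = np.einsum("fia,fia->f", x, x)
    h = np.einsum("fia,gib->fgab", x, x)          # (F, F, 3, 3) cross-covariances
    _, s, _ = np.linalg.svd(h)
    det = np.linalg.det(h)
    trace_s = s.sum(axis=-1) - 2.0 * s[..., 2] * (det < 0)
    msd = (g[:, None] + g[None, :] - 2.0 * trace_s) / n
    out = np.sqrt(np.clip(msd, 0.0, None))
    np.fill_diagonal(out, 0.0)
    return 0.5 * (out + out.T)


def cluster_frames(ensemble: Ensemble, mask: SelectionMask | None = None,
                   k: int = 2) -> ClusterAssignment:
    """Average-linkage hierarchical clustering on pairwise best-fit RMSD.

    The dendrogram is cut at exactly ``k`` clusters; clusters are relabeled
    by decreasing population (ties by lowest member frame index) and each
    cluster is represented by its medoid (lowest frame index on ties).
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > ensemble.n_frames:
        raise ValueError(f"k={k} exceeds frame count {ensemble.n_frames}")
    dmat = pairwise_rmsd_matrix(ensemble, mask)
    if ensemble.n_frames == 1 or k == ensemble.n_frames:
        raw = np.arange(ensemble.n_frames) if k == ensemble.n_frames \
            else np.zeros(1, dtype=int)
    else:
        z = linkage(squareform(dmat, checks=False), method="average")
        raw = fcluster(z, t=k, criterion="maxclust") - 1
    # relabel by population, break ties by first member index
    order = sorted(
        np.unique(raw),
        key=lambda c: (-(raw == c).sum(), int(np.flatnonzero(raw == c)[0])),
    )
    labels = np.empty_like(raw)
    for new, old in enumerate(order):
        labels[raw == old] = new
    kk = len(order)
    fractions = np.array([(labels == c).mean() for c in range(kk)])
    reps = np.empty(kk, dtype=int)
    for c in range(kk):
        members = np.flatnonzero(labels == c)
        cost = dmat[np.ix_(members, members)].sum(axis=1)
        reps[c] = members[int(np.argmin(cost))]  # argmin takes lowest index on ties
    return ClusterAssignment(labels=labels, fractions=fractions,
                             representatives=reps)
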