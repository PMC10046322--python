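"""Cross-correlation and collective-motion statistics.

The dynamic cross-correlation matrix (DCCM) reports, for every C-alpha
pair, the normalized equal-time covariance of displacements about the
average structure,

    C_ij = <dr_i . dr_j> / sqrt(<dr_i^2><dr_j^2>),

i.e. the scalar-product (trace-of-block) convention that yields the
familiar [-1, 1] correlation maps: +1 fully correlated, -1 fully
anti-correlated motion. Frames are superposed onto the iteratively
converged average structure on the analysis mask first, so global rigid
motion does not leak into the correlations.

PCA eigendecomposes the 3N x 3N covariance of the superposed coordinates;
free-energy surfaces are -kT ln of the normalized sample density over two
chosen coordinates, shifted so the occupied minimum is zero.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import BOLTZMANN_KCAL
from .io import Ensemble, SelectionMask
from .superpose import iterative_mean_fit

__all__ = ["CorrelationMatrix", "PCAResult", "FESGrid",
           "dccm", "pca", "fes_2d", "mode_displacement_map"]


@dataclass
class CorrelationMatrix:
    values: np.ndarray        # (n_res, n_res), in [-1, 1], unit diagonal
    residue_ids: np.ndarray
    provenance: str = ""

    def __post_init__(self):
        v = self.values
        if not np.allclose(v, v.T, atol=1e-10):
            raise ValueError("correlation matrix must be symmetric")
        if not np.allclose(np.diag(v), 1.0, atol=1e-10):
            raise ValueError("correlation diagonal must be 1")
        if v.min() < -1 - 1e-10 or v.max() > 1 + 1e-10:
            raise ValueError("correlation entries must lie in [-1, 1]")


@dataclass
class PCAResult:
    eigenvalues: np.ndarray    # descending, A^2
    eigenvectors: np.ndarray   # (3N, n_components), orthonormal columns
    mean_coords: np.ndarray    # (N, 3) converged average of masked atoms
    projections: np.ndarray    # (F, n_components), centered on the mean
    residue_ids: np.ndarray
    total_variance: float      # trace of the full coordinate covariance

    def __post_init__(self):
        if np.any(np.diff(self.eigenvalues) > 1e-12):
            raise ValueError("eigenvalues must be sorted descending")
        if np.any(self.eigenvalues < -1e-10):
            raise ValueError("eigenvalues must be non-negative")
        gram = self.eigenvectors.T @ self.eigenvectors
        if np.abs(gram - np.eye(gram.shape[0])).max() > 1e-8:
            raise ValueError("eigenvectors must be orthonormal")


@dataclass
class FESGrid:
    """Free energy (kcal/mol) over a 2D histogram; empty bins are masked."""

    x_edges: np.ndarray
    y_edges: np.ndarray
    free_energy: np.ndarray     # (nx, ny); NaN where empty
    empty: np.ndarray           # (nx, ny) bool
    temperature: float

    def __post_init__(self):
        occ = self.free_energy[~self.empty]
        if occ.size and not np.isclose(np.nanmin(occ), 0.0, atol=1e-10):
            raise ValueError("minimum over occupied bins must be 0")

    @property
    def x_centers(self):
        return 0.5 * (self.x_edges[:-1] + self.x_edges[1:])

    @property
    def y_centers(self):
        return 0.5 * (self.y_edges[:-1] + self.y_edges[1:])

    def minimum_location(self):
        """(x, y) bin-center of the global free-energy minimum."""
        masked = np.where(self.empty, np.inf, self.free_energy)
        i, j = np.unravel_index(np.argmin(masked), masked.shape)
        return float(self.x_centers[i]), float(self.y_centers[j])


def _fitted_displacements(ensemble: Ensemble, mask: SelectionMask,
                          fit_mask: SelectionMask | None = None):
    fitted, mean = iterative_mean_fit(ensemble.frames,
                                      fit_mask if fit_mask is not None else mask)
    sub = fitted[:, mask.indices, :]
    return sub - mean[mask.indices], mean[mask.indices]


def dccm(ensemble: Ensemble, mask: SelectionMask,
         fit_mask: SelectionMask | None = None) -> CorrelationMatrix:
    """Dynamic cross-correlation matrix over the masked (C-alpha) atoms.

    Frames are superposed on ``fit_mask`` (default: the analysis mask).
    """
    if ensemble.n_frames < 2:
        raise ValueError("DCCM needs at least 2 frames")
    disp, _ = _fitted_displacements(ensemble, mask, fit_mask)   # (F, n, 3)
    inner = np.einsum("fia,fja->ij", disp, disp) / ensemble.n_frames
    var = np.diag(inner)
    resids = ensemble.topology.res_ids[mask.indices]
    zero = np.flatnonzero(var <= 0)
    if len(zero):
        raise ValueError(
            f"zero-variance atom at residue {int(resids[zero[0]])}; "
            "correlation is undefined"
        )
    c = inner / np.sqrt(np.outer(var, var))
    c = np.clip(c, -1.0, 1.0)
    np.fill_diagonal(c, 1.0)
    c = 0.5 * (c + c.T)
    return CorrelationMatrix(values=c, residue_ids=resids,
                             provenance=mask.provenance)


def pca(ensemble: Ensemble, mask: SelectionMask,
        n_components: int = 2,
        fit_mask: SelectionMask | None = None) -> PCAResult:
    """PCA of the superposed masked coordinates.

    Eigenvector signs are fixed by making each vector's largest-magnitude
    coordinate positive, so results are deterministic across platforms.
    """
    if ensemble.n_frames < 2:
        raise ValueError("PCA needs at least 2 frames")
    disp, mean = _fitted_displacements(ensemble, mask, fit_mask)
    f, n, _ = disp.shape
    x = disp.reshape(f, 3 * n)
    cov = x.T @ x / f
    evals, evecs = np.linalg.eigh(cov)
    evals = np.clip(evals[::-1], 0.0, None)
    evecs = evecs[:, ::-1]
    rank = int(np.sum(evals > 1e-10 * max(evals[0], 1e-30)))
    if n_components > rank:
        raise ValueError(f"n_components={n_components} exceeds rank {rank}")
    evecs = evecs[:, :n_components].copy()
    for c in range(n_components):
        imax = int(np.argmax(np.abs(evecs[:, c])))
        if evecs[imax, c] < 0:
            evecs[:, c] *= -1
    proj = x @ evecs
    return PCAResult(
        eigenvalues=evals[:n_components], eigenvectors=evecs,
        mean_coords=mean, projections=proj,
        residue_ids=ensemble.topology.res_ids[mask.indices],
        total_variance=float(evals.sum()),
    )


def fes_2d(x: np.ndarray, y: np.ndarray, n_bins: int = 60,
           temperature: float = 300.0, ranges=None) -> FESGrid:
    """Free-energy surface F = -kT ln(P/P_max) over a 2D histogram.

    Empty bins are masked (NaN), not assigned a numeric energy.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 1 or x.shape != y.shape:
        raise ValueError("x and y must be equal-length, non-empty")
    hist, xe, ye = np.histogram2d(x, y, bins=n_bins, range=ranges)
    kt = BOLTZMANN_KCAL * temperature
    empty = hist == 0
    with np.errstate(divide="ignore"):
        fe = -kt * np.log(hist / hist.max())
    fe[empty] = np.nan
    return FESGrid(x_edges=xe, y_edges=ye, free_energy=fe, empty=empty,
                   temperature=temperature)


def radial_profile(grid: FESGrid, r_max: float, n_annuli: int = 15,
                   center=(0.0, 0.0)):
    """Radially averaged free energy F(r) about ``center``.

    Averages occupied bins in equal-width annuli (at least 3 bins each);
    returns (r, F) arrays. The natural reduction for checking the
    quadratic well of a Gaussian basin.
    """
    xc, yc = np.meshgrid(grid.x_centers, grid.y_centers, indexing="ij")
    r = np.hypot(xc - center[0], yc - center[1])
    edges = np.linspace(0.0, r_max, n_annuli + 1)
    rs, fs = [], []
    for lo, hi in zip(edges[:-1], edges[1:]):
        sel = ~grid.empty & (r >= lo) & (r < hi)
        if sel.sum() >= 3:
            rs.append(float(r[sel].mean()))
            fs.append(float(grid.free_energy[sel].mean()))
    return np.array(rs), np.array(fs)


def mode_displacement_map(result: PCAResult, component: int = 1,
                          structure=None, path=None) -> np.ndarray:
    """Per-residue displacement magnitude along one PC (1-based).

    Magnitude = Euclidean norm of the residue's 3-vector in the eigenvector,
    scaled by sqrt(eigenvalue) so units are angstrom. Optionally written to
    the B-factor column of ``structure``.
    """
    if not 1 <= component <= result.eigenvectors.shape[1]:
        raise ValueError(f"component {component} not computed")
    vec = result.eigenvectors[:, component - 1].reshape(-1, 3)
    mags = np.linalg.norm(vec, axis=1) * np.sqrt(result.eigenvalues[component - 1])
    if path is not None:
        if structure is None:
            raise ValueError("writing a B-factor PDB requires a structure")
        from .io import write_structure

        per_res = dict(zip(result.residue_ids.tolist(), mags))
        bfac = np.array([per_res.get(int(r), 0.0) for r in structure.res_ids])
        write_structure(structure, path, bfactors=bfac)
    return mags
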