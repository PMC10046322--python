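"""Lid coordinate frame, catalytic-triad distances, and restraint compliance.

The lid frame is an internal coordinate system anchored on three catalytic-
region C-alpha atoms: the origin sits on the catalytic serine (residue 146
by default), the x-axis points toward residue 244, the y-axis is the
Gram-Schmidt-orthogonalized direction toward residue 284, and z = x cross y
(right-handed). Because it is rebuilt per frame from internal anchors, any
point expressed in it is invariant under global rigid motion; the z
component of the lid centroid tracks lid opening and closing, while x/y
capture twist.

Triad side-chain distances follow the catalytic hydrogen-bond topology of
the Ser-His-Glu charge relay: d1 = Ser OG ... His NE2 and d2 = Glu
carboxylate (minimum over OE1/OE2) ... His ND1; the atom pairs are
configurable.

Distance restraints are flat-bottom harmonic on the upper side only:
E = 0 for d <= bound and E = k (d - bound)^2 beyond (note: k Delta^2, not
k/2 Delta^2, the AMBER restraint convention - this doubles energies
relative to the physics-textbook form). The default bound of 5.5 A and
force constant 32 kcal/mol/A^2 confine a reactive near-attack geometry; a
frame is "catalytic-state compliant" when every restraint has zero energy.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .correlation import FESGrid, fes_2d
from .io import Ensemble, Structure

__all__ = [
    "LocalFrame",
    "LidTrace",
    "TriadDistanceSeries",
    "DistanceRestraint",
    "RestraintSpec",
    "build_lid_frame",
    "lid_trace",
    "triad_distances",
    "distance_fes",
    "restraint_energy",
    "catalytic_state_fraction",
]


@dataclass
class LocalFrame:
    """Right-handed orthonormal frame anchored on three C-alpha atoms."""

    origin: np.ndarray        # (3,), angstrom
    basis: np.ndarray         # (3, 3); rows are x, y, z unit vectors
    anchors: tuple            # (origin resid, x resid, y resid)

    def __post_init__(self):
        gram = self.basis @ self.basis.T
        if np.abs(gram - np.eye(3)).max() > 1e-10:
            raise ValueError("frame basis is not orthonormal")
        if np.linalg.det(self.basis) < 0:
            raise ValueError("frame basis is left-handed")

    def to_local(self, points: np.ndarray) -> np.ndarray:
        return (np.asarray(points, dtype=float) - self.origin) @ self.basis.T


@dataclass
class LidTrace:
    """Per-frame lid-centroid position in the local frame (x, y, z in A)."""

    coords: np.ndarray        # (F, 3)
    lid_residues: tuple
    anchors: tuple

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        if not np.isfinite(self.coords).all():
            raise ValueError("non-finite lid-trace coordinates")

    @property
    def z(self) -> np.ndarray:
        return self.coords[:, 2]

    def state_occupancies(self, threshold: float | None = None,
                          open_direction: float = 1.0):
        """(closed, open) fractions by thresholding the z coordinate.

        Default threshold: midpoint between the minimum and maximum z,
        suitable for well-separated two-state traces. ``open_direction``
        states which way along z the lid opens (+1: larger z is open,
        -1: smaller z is open); it depends on how the anchor residues sit
        relative to the lid in the particular fold.
        """
        z = self.z
        if threshold is None:
            threshold = 0.5 * (z.min() + z.max())
        high_frac = float((z > threshold).mean())
        open_frac = high_frac if open_direction >= 0 else 1.0 - high_frac
        return 1.0 - open_frac, open_frac


@dataclass
class TriadDistanceSeries:
    """Per-frame catalytic side-chain distances d1, d2 (angstrom)."""

    d1: np.ndarray
    d2: np.ndarray
    definition: dict
    degenerate: np.ndarray = None    # frames where an atom pair coincided

    def __post_init__(self):
        self.d1 = np.asarray(self.d1, dtype=float)
        self.d2 = np.asarray(self.d2, dtype=float)
        if self.d1.shape != self.d2.shape:
            raise ValueError("d1 and d2 must have equal length")
        if np.any(self.d1 < 0) or np.any(self.d2 < 0):
            raise ValueError("distances must be non-negative")
        if self.degenerate is None:
            self.degenerate = np.zeros(len(self.d1), dtype=bool)


def _ca_coord(structure: Structure, coords: np.ndarray, resid: int) -> np.ndarray:
    sel = (structure.res_ids == resid) & (structure.atom_names == "CA")
    idx = np.flatnonzero(sel)
    if len(idx) == 0:
        raise ValueError(f"no C-alpha atom for residue {resid}")
    return coords[idx[0]]


def build_lid_frame(structure: Structure, coords: np.ndarray | None = None,
                    origin_res: int = 146, x_res: int = 244,
                    y_res: int = 284) -> LocalFrame:
    """Local frame from three anchor C-alpha atoms (per-conformer).

    x = unit(origin -> x_res); y = Gram-Schmidt unit(origin -> y_res)
    perpendicular to x; z = x cross y. Collinear anchors raise.
    """
    if coords is None:
        coords = structure.coords
    o = _ca_coord(structure, coords, origin_res)
    ax = _ca_coord(structure, coords, x_res) - o
    ay = _ca_coord(structure, coords, y_res) - o
    nx_ = np.linalg.norm(ax)
    if nx_ < 1e-10:
        raise ValueError("origin and x anchors coincide")
    x = ax / nx_
    y_raw = ay - (ay @ x) * x
    ny = np.linalg.norm(y_raw)
    if ny < 1e-8 * max(np.linalg.norm(ay), 1.0) or ny < 1e-10:
        raise ValueError(
            f"anchors {origin_res}, {x_res}, {y_res} are collinear"
        )
    y = y_raw / ny
    z = np.cross(x, y)
    return LocalFrame(origin=o, basis=np.vstack([x, y, z]),
                      anchors=(origin_res, x_res, y_res))


def lid_trace(ensemble: Ensemble, lid_residues=range(192, 197),
              origin_res: int = 146, x_res: int = 244,
              y_res: int = 284) -> LidTrace:
    """Per-frame lid-subset C-alpha centroid in the per-frame local frame."""
    top = ensemble.topology
    lid_residues = tuple(int(r) for r in lid_residues)
    sel = np.isin(top.res_ids, lid_residues) & (top.atom_names == "CA")
    idx = np.flatnonzero(sel)
    if len(idx) == 0:
        raise ValueError(f"no lid C-alpha atoms among residues {lid_residues}")
    out = np.empty((ensemble.n_frames, 3))
    for f in range(ensemble.n_frames):
        frame = build_lid_frame(top, ensemble.frames[f], origin_res, x_res, y_res)
        centroid = ensemble.frames[f][idx].mean(axis=0)
        out[f] = frame.to_local(centroid)
    return LidTrace(coords=out, lid_residues=lid_residues,
                    anchors=(origin_res, x_res, y_res))


DEFAULT_TRIAD_PAIRS = {
    "d1": ((146, ("OG",)), (270, ("NE2",))),
    "d2": ((240, ("OE1", "OE2")), (270, ("ND1",))),
}


def _pair_distance(structure: Structure, coords: np.ndarray, pair) -> float:
    """Minimum distance over the named atom combinations of a residue pair."""
    (res_a, names_a), (res_b, names_b) = pair
    best = None
    for res, names in ((res_a, names_a), (res_b, names_b)):
        for name in names:
            if not np.any((structure.res_ids == res)
                          & (structure.atom_names == name)):
                raise ValueError(f"residue {res} has no atom named {name!r}")
    for na in names_a:
        ia = np.flatnonzero((structure.res_ids == res_a)
                            & (structure.atom_names == na))[0]
        for nb in names_b:
            ib = np.flatnonzero((structure.res_ids == res_b)
                                & (structure.atom_names == nb))[0]
            d = float(np.linalg.norm(coords[ia] - coords[ib]))
            best = d if best is None else min(best, d)
    return best


def triad_distances(ensemble: Ensemble, pairs=None) -> TriadDistanceSeries:
    """Catalytic side-chain distance series d1, d2 over the ensemble.

    Coincident atom pairs yield distance 0 and are flagged in
    ``degenerate`` rather than raising.
    """
    if pairs is None:
        pairs = DEFAULT_TRIAD_PAIRS
    top = ensemble.topology
    d1 = np.empty(ensemble.n_frames)
    d2 = np.empty(ensemble.n_frames)
    for f in range(ensemble.n_frames):
        d1[f] = _pair_distance(top, ensemble.frames[f], pairs["d1"])
        d2[f] = _pair_distance(top, ensemble.frames[f], pairs["d2"])
    degenerate = (d1 == 0.0) | (d2 == 0.0)
    return TriadDistanceSeries(d1=d1, d2=d2, definition=dict(pairs),
                               degenerate=degenerate)


def distance_fes(series: TriadDistanceSeries, n_bins: int = 60,
                 temperature: float = 300.0) -> FESGrid:
    """Free-energy landscape over (d1, d2); delegates to the 2D FES builder."""
    return fes_2d(series.d1, series.d2, n_bins=n_bins, temperature=temperature)


@dataclass
class DistanceRestraint:
    """Flat-bottom upper-bound harmonic restraint on one atom pair.

    Atoms are addressed as (residue number, atom name) pairs; the energy
    is E = k (d - bound)^2 for d > bound, else 0.
    """

    atom_a: tuple              # (resid, atom name)
    atom_b: tuple
    bound: float = 5.5         # angstrom
    k: float = 32.0            # kcal/mol/A^2

    def __post_init__(self):
        if self.bound <= 0:
            raise ValueError("restraint bound must be positive")
        if self.k < 0:
            raise ValueError("force constant must be non-negative")

    def energy(self, d: float) -> float:
        excess = d - self.bound
        return float(self.k * excess * excess) if excess > 0 else 0.0


@dataclass
class RestraintSpec:
    restraints: list = field(default_factory=list)

    @classmethod
    def catalytic_default(cls, ligand_atom: tuple,
                          ser: int = 146, his: int = 270, glu: int = 240,
                          bound: float = 5.5, k: float = 32.0):
        """The three catalytic-state restraints: ligand-Ser, Ser-His, His-Glu.

        ``ligand_atom`` names the restrained ligand carbonyl carbon as a
        (residue number, atom name) pair; it must be supplied explicitly.
        """
        return cls([
            DistanceRestraint(ligand_atom, (ser, "OG"), bound, k),
            DistanceRestraint((ser, "OG"), (his, "NE2"), bound, k),
            DistanceRestraint((his, "ND1"), (glu, "OE1"), bound, k),
        ])


def _resolve_atom(structure: Structure, atom: tuple) -> int:
    resid, name = atom
    idx = np.flatnonzero((structure.res_ids == int(resid))
                         & (structure.atom_names == name))
    if len(idx) == 0:
        raise ValueError(f"cannot resolve atom {name!r} of residue {resid}")
    return int(idx[0])


def restraint_energy(structure: Structure, coords: np.ndarray,
                     spec: RestraintSpec):
    """Per-restraint energies (kcal/mol) and compliance flags for one frame."""
    energies = []
    compliant = []
    for r in spec.restraints:
        ia = _resolve_atom(structure, r.atom_a)
        ib = _resolve_atom(structure, r.atom_b)
        d = float(np.linalg.norm(coords[ia] - coords[ib]))
        e = r.energy(d)
        energies.append(e)
        compliant.append(e == 0.0)
    return np.array(energies), np.array(compliant, dtype=bool)


def catalytic_state_fraction(ensemble: Ensemble, spec: RestraintSpec) -> float:
    """Fraction of frames with every restraint satisfied (all energies zero)."""
    n_ok = 0
    for f in range(ensemble.n_frames):
        _, ok = restraint_energy(ensemble.topology, ensemble.frames[f], spec)
        if ok.all():
            n_ok += 1
    return n_ok / ensemble.n_frames
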