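"""Geometric disulfide-bond design screen.

For a candidate residue pair the hypothetical cystine is modeled from
backbone geometry alone: each S-gamma is placed at the ideal C-beta bond
length (1.81 A) and C-alpha - C-beta - S-gamma angle (114.6 deg), scanning
the chi1 dihedral on a 5-degree grid, and the chi1 combination whose
S-S separation is closest to the ideal bond length (2.04 A) is retained.
Glycines get an ideal C-beta reconstructed from N/CA/C (bond 1.53 A,
angles 110.5 deg, L-configuration).

The geometric acceptance windows are the native-cystine statistics: the
chi3 dihedral (CB-SG-SG'-CB') must fall within +/-30 deg of either of the
two native rotamer centers -87 deg / +97 deg (circular arithmetic), and
both C-alpha - C-beta - S-gamma angles within 114.6 +/- 10 deg. (Screening
reports for this class of tool sometimes print the angle as
"C-alpha - C-beta - C-gamma"; cysteine has no C-gamma - the angle screened
here is to S-gamma.) An S-S distance of 1.5-2.5 A must also be reachable
for a bond to be formable.

Candidates that survive the geometry are then filtered against functional
sites: any residue with an atom within 10 A of the catalytic triad or
within 5 A of another important region (lid, binding pocket), or on an
explicit conserved-residue blacklist, is rejected with the reason recorded.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import RegionDefinition, Structure

__all__ = [
    "DisulfideCandidate",
    "FunctionalSiteFilter",
    "model_cystine",
    "apply_criteria",
    "apply_site_filters",
    "scan_all_pairs",
    "place_atom",
    "reconstruct_cbeta",
]

SG_BOND = 1.81          # CB-SG bond length, angstrom
SS_BOND = 2.04          # ideal SG-SG' bond length, angstrom
CA_CB_SG_ANGLE = 114.6  # deg
SS_MIN, SS_MAX = 1.5, 2.5  # formable S-S bond distance window
CB_BOND = 1.53          # CA-CB bond length for ideal reconstruction
CB_ANGLE = 110.5        # N-CA-CB and C-CA-CB angle, deg


def _angle(a, b, c) -> float:
    """Angle a-b-c in degrees."""
    u, v = a - b, c - b
    cosang = np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v))
    return float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))


def _dihedral(p0, p1, p2, p3) -> float:
    """Dihedral p0-p1-p2-p3 in degrees, in (-180, 180]."""
    b0, b1, b2 = p1 - p0, p2 - p1, p3 - p2
    b1n = b1 / np.linalg.norm(b1)
    v = b0 - np.dot(b0, b1n) * b1n
    w = b2 - np.dot(b2, b1n) * b1n
    x = np.dot(v, w)
    y = np.dot(np.cross(b1n, v), w)
    ang = float(np.degrees(np.arctan2(y, x)))
    return 180.0 if ang <= -180.0 else ang


def place_atom(a, b, c, bond: float, angle_deg: float,
               dihedral_deg: float) -> np.ndarray:
    """Place atom D given A, B, C with |CD|, angle B-C-D and dihedral A-B-C-D."""
    bc = c - b
    bc /= np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    norm = np.linalg.norm(n)
    if norm < 1e-10:
        raise ValueError("reference atoms are collinear; cannot place atom")
    n /= norm
    m = np.cross(n, bc)
    ang = np.radians(angle_deg)
    dih = np.radians(dihedral_deg)
    d_local = bond * np.array([
        -np.cos(ang),
        -np.sin(ang) * np.cos(dih),
        -np.sin(ang) * np.sin(dih),
    ])
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def reconstruct_cbeta(n, ca, c) -> np.ndarray:
    """Ideal C-beta from backbone N, CA, C (bond 1.53 A, angles 110.5 deg).

    The branch is chosen to give the L-amino-acid configuration.
    """
    u1 = (n - ca) / np.linalg.norm(n - ca)
    u2 = (c - ca) / np.linalg.norm(c - ca)
    bis = -(u1 + u2)
    bis /= np.linalg.norm(bis)
    perp = np.cross(u2, u1)
    norm = np.linalg.norm(perp)
    if norm < 1e-10:
        raise ValueError("backbone N, CA, C are collinear")
    perp /= norm
    cos_t = np.cos(np.radians(CB_ANGLE))
    alpha = cos_t / np.dot(bis, u1)
    beta = np.sqrt(max(0.0, 1.0 - alpha * alpha))
    direction = alpha * bis + beta * perp
    return ca + CB_BOND * direction / np.linalg.norm(direction)


@dataclass
class DisulfideCandidate:
    """A residue pair with modeled cystine geometry and per-criterion record."""

    res_i: int
    res_j: int
    chain_i: str = "A"
    chain_j: str = "A"
    sg_i: np.ndarray = None
    sg_j: np.ndarray = None
    chi1_i: float = 0.0
    chi1_j: float = 0.0
    chi3: float = 0.0                 # CB-SG-SG'-CB' dihedral, deg
    angle_i: float = 0.0              # CA-CB-SG, deg
    angle_j: float = 0.0
    ss_distance: float = 0.0          # SG-SG', angstrom
    criteria: dict = field(default_factory=dict)   # name -> bool
    passes: bool | None = None
    fail_reasons: list = field(default_factory=list)
    rejection_reasons: list = field(default_factory=list)  # site filters

    def __post_init__(self):
        if not -180.0 < self.chi3 <= 180.0:
            raise ValueError("chi3 must lie in (-180, 180]")
        for ang in (self.angle_i, self.angle_j):
            if not 0.0 < ang < 180.0:
                raise ValueError("bond angles must lie in (0, 180)")


@dataclass
class FunctionalSiteFilter:
    """Exclusion rules protecting functional sites of the enzyme."""

    triad_residues: tuple = (146, 240, 270)
    triad_radius: float = 10.0
    regions: tuple = ()               # RegionDefinition instances
    region_radius: float = 5.0
    blacklist: tuple = ()             # conserved residue numbers

    def __post_init__(self):
        if self.triad_radius <= 0 or self.region_radius <= 0:
            raise ValueError("exclusion radii must be positive")


def _residue_atoms(structure: Structure, resid: int, chain=None):
    sel = structure.res_ids == resid
    if chain is not None:
        sel &= structure.chain_ids == chain
    idx = np.flatnonzero(sel)
    if len(idx) == 0:
        raise ValueError(f"residue {resid} not found")
    return {str(structure.atom_names[i]): i for i in idx}, idx


def _backbone_and_cb(structure: Structure, resid: int, chain=None):
    atoms, _ = _residue_atoms(structure, resid, chain)
    missing = [a for a in ("N", "CA", "C") if a not in atoms]
    if missing:
        raise ValueError(f"residue {resid} lacks backbone atoms {missing}")
    n = structure.coords[atoms["N"]]
    ca = structure.coords[atoms["CA"]]
    c = structure.coords[atoms["C"]]
    cb = structure.coords[atoms["CB"]] if "CB" in atoms \
        else reconstruct_cbeta(n, ca, c)
    return n, ca, c, cb


def _sg_grid(n, ca, cb, chi1_step: float):
    """Candidate SG positions over the chi1 grid (N-CA-CB-SG dihedral)."""
    chi1 = np.arange(-180.0 + chi1_step, 180.0 + 1e-9, chi1_step)
    pos = np.array([place_atom(n, ca, cb, SG_BOND, CA_CB_SG_ANGLE, c)
                    for c in chi1])
    return chi1, pos


def model_cystine(structure: Structure, res_i: int, res_j: int,
                  chi1_step: float = 5.0, chain_i=None,
                  chain_j=None) -> DisulfideCandidate:
    """Model the hypothetical cystine for one residue pair (geometry only).

    The chi1 x chi1' grid point minimizing |SG-SG' - 2.04 A| is retained
    (ties: lowest grid indices). Geometric impossibility (e.g. distant
    residues) is recorded as a failing candidate, not an error.
    """
    if res_i == res_j:
        raise ValueError("a disulfide needs two distinct residues")
    ni, cai, ci, cbi = _backbone_and_cb(structure, res_i, chain_i)
    nj, caj, cj, cbj = _backbone_and_cb(structure, res_j, chain_j)
    chi1s_i, sgs_i = _sg_grid(ni, cai, cbi, chi1_step)
    chi1s_j, sgs_j = _sg_grid(nj, caj, cbj, chi1_step)
    dmat = np.linalg.norm(sgs_i[:, None, :] - sgs_j[None, :, :], axis=-1)
    flat = int(np.argmin(np.abs(dmat - SS_BOND)))
    bi, bj = np.unravel_index(flat, dmat.shape)
    sg_i, sg_j = sgs_i[bi], sgs_j[bj]
    cand = DisulfideCandidate(
        res_i=int(res_i), res_j=int(res_j),
        chain_i=str(structure.chain_ids[np.flatnonzero(structure.res_ids == res_i)[0]]),
        chain_j=str(structure.chain_ids[np.flatnonzero(structure.res_ids == res_j)[0]]),
        sg_i=sg_i, sg_j=sg_j,
        chi1_i=float(chi1s_i[bi]), chi1_j=float(chi1s_j[bj]),
        chi3=_dihedral(cbi, sg_i, sg_j, cbj),
        angle_i=_angle(cai, cbi, sg_i), angle_j=_angle(caj, cbj, sg_j),
        ss_distance=float(dmat[bi, bj]),
    )
    apply_criteria(cand)
    return cand


def _circular_dev(angle: float, center: float) -> float:
    return abs((angle - center + 180.0) % 360.0 - 180.0)


def chi3_deviation(chi3: float, center_minus: float = -87.0,
                   center_plus: float = 97.0) -> float:
    """Circular distance of chi3 to the nearest native rotamer center."""
    return min(_circular_dev(chi3, center_minus), _circular_dev(chi3, center_plus))


def apply_criteria(candidate: DisulfideCandidate,
                   chi3_center_minus: float = -87.0,
                   chi3_center_plus: float = 97.0,
                   chi3_halfwidth: float = 30.0,
                   angle_center: float = CA_CB_SG_ANGLE,
                   angle_halfwidth: float = 10.0):
    """Evaluate the geometric windows on a candidate; records flags in place.

    Pass requires chi3 within the halfwidth of either center (circular),
    both CA-CB-SG angles within the angle window, and an S-S distance in
    the formable range.
    """
    dev = chi3_deviation(candidate.chi3, chi3_center_minus, chi3_center_plus)
    crit = {
        "chi3": dev <= chi3_halfwidth,
        "angle_i": abs(candidate.angle_i - angle_center) <= angle_halfwidth,
        "angle_j": abs(candidate.angle_j - angle_center) <= angle_halfwidth,
        "ss_distance": SS_MIN <= candidate.ss_distance <= SS_MAX,
    }
    candidate.criteria = crit
    candidate.passes = all(crit.values())
    candidate.fail_reasons = [k for k, ok in crit.items() if not ok]
    return candidate.passes, candidate.fail_reasons


def apply_site_filters(candidates, structure: Structure,
                       site_filter: FunctionalSiteFilter):
    """Reject candidates near functional sites; nothing is silently dropped.

    Returns (retained, all_candidates); every rejected candidate carries
    its reasons in ``rejection_reasons``.
    """
    triad_idx = np.flatnonzero(np.isin(structure.res_ids,
                                       site_filter.triad_residues))
    if len(triad_idx) == 0 and site_filter.triad_residues:
        raise ValueError(
            f"triad residues {site_filter.triad_residues} not in structure"
        )
    region_idx = []
    for region in site_filter.regions:
        region.validate(structure)
        region_idx.append(
            (region.name, np.flatnonzero(np.isin(structure.res_ids,
                                                 region.residues)))
        )
    retained = []
    for cand in candidates:
        reasons = []
        for resid in (cand.res_i, cand.res_j):
            if resid in site_filter.blacklist:
                reasons.append(f"conserved residue {resid}")
            _, idx = _residue_atoms(structure, resid)
            xyz = structure.coords[idx]
            if len(triad_idx):
                dmin = np.linalg.norm(
                    xyz[:, None, :] - structure.coords[triad_idx][None], axis=-1
                ).min()
                if dmin <= site_filter.triad_radius:
                    reasons.append(
                        f"residue {resid} within {site_filter.triad_radius} A "
                        f"of catalytic triad ({dmin:.1f} A)"
                    )
            for name, ridx in region_idx:
                if np.isin(idx, ridx).all():
                    continue  # the candidate residue itself is the region
                dmin = np.linalg.norm(
                    xyz[:, None, :] - structure.coords[ridx][None], axis=-1
                ).min()
                if dmin <= site_filter.region_radius:
                    reasons.append(
                        f"residue {resid} within {site_filter.region_radius} A "
                        f"of region {name} ({dmin:.1f} A)"
                    )
        cand.rejection_reasons = reasons
        if not reasons:
            retained.append(cand)
    return retained, list(candidates)


def scan_all_pairs(structure: Structure,
                   site_filter: FunctionalSiteFilter | None = None,
                   cb_prefilter: float = 8.0,
                   chi1_step: float = 5.0) -> pd.DataFrame:
    """Screen all residue pairs for disulfide engineering.

    Pairs with C-beta - C-beta distance above ``cb_prefilter`` (a generous
    upper bound for any disulfide) are skipped for tractability. The table
    is sorted by |S-S - 2.04 A| then |chi3 deviation|; deterministic.
    """
    resids = []
    cbs = []
    for r in np.unique(structure.res_ids):
        try:
            _, _, _, cb = _backbone_and_cb(structure, int(r))
        except ValueError:
            continue
        resids.append(int(r))
        cbs.append(cb)
    cbs = np.asarray(cbs)
    rows = []
    for a in range(len(resids)):
        for b in range(a + 1, len(resids)):
            if np.linalg.norm(cbs[a] - cbs[b]) > cb_prefilter:
                continue
            cand = model_cystine(structure, resids[a], resids[b],
                                 chi1_step=chi1_step)
            if site_filter is not None:
                apply_site_filters([cand], structure, site_filter)
            rows.append({
                "res_i": cand.res_i, "res_j": cand.res_j,
                "chi3_deg": round(cand.chi3, 2),
                "angle_i_deg": round(cand.angle_i, 2),
                "angle_j_deg": round(cand.angle_j, 2),
                "ss_distance_A": round(cand.ss_distance, 3),
                "passes_geometry": bool(cand.passes),
                "fail_reasons": ";".join(cand.fail_reasons),
                "site_rejections": ";".join(cand.rejection_reasons),
                "verdict": "pass" if cand.passes and not cand.rejection_reasons
                           else "fail",
                "_rank_ss": abs(cand.ss_distance - SS_BOND),
                "_rank_chi3": chi3_deviation(cand.chi3),
            })
    df = pd.DataFrame(rows)
    if len(df):
        df = df.sort_values(["_rank_ss", "_rank_chi3", "res_i", "res_j"],
                            kind="mergesort").drop(columns=["_rank_ss",
                                                            "_rank_chi3"])
        df = df.reset_index(drop=True)
    return df
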