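"""The multi-lattice snapshot indexing pipeline.

Given the observed scattering vectors of one snapshot image and the known
unit cell, the indexer:

1. pairs every g vector with the reflection families whose magnitude |h|
   falls inside a Bragg-derived relative window (``build_candidate_pairs``);
2. traces one RF-space geodesic per (g, symmetry-equivalent h) combination
   through the four-chart voxel accumulator (``accumulate``);
3. extracts local maxima of the visit counts as orientation candidates,
   clustered over symmetry-equivalent copies;
4. matches observed g vectors to the predicted reciprocal lattice of each
   candidate (``match_gvectors``), refines the orientation by orthogonal
   Procrustes with iterative outlier trimming (``refine_orientation``);
5. accepts solutions by minimum match count, completeness of the predicted
   pattern, and a uniqueness-overlap filter (``accept_solutions``).

The three user-tolerance formulas (the magnitude pairing window, the
angular matching bound, and the equivalent z-rotation pre-selection) are
isolated in :func:`gvector_magnitude_tolerance`,
:func:`angular_deviation_bound` and :func:`equivalent_z_rotation` so each
can be swapped independently.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.spatial import cKDTree
from scipy.spatial.transform import Rotation as _SciRotation

from .cells import (ReflectionFamily, UnitCell, generate_families,
                    laue_operators, reflection_list)
from .geometry import (BeamGeometry, bragg_theta, excitation_errors,
                       gvectors_to_detector, peaks_to_gvectors)
from .rfspace import (FrustumAccumulator, Rotation, voxel_angular_radius)


class UnderdeterminedError(ValueError):
    """Too few / collinear matches to fit an orientation."""


@dataclass(frozen=True)
class FelixParams:
    """Tuning parameters of the indexing pipeline.

    Angles in degrees, reciprocal lengths in nm^-1, fractions in [0, 1].

    Attributes
    ----------
    n_voxels:
        Voxels per axis per chart (N_v).
    v_min:
        Minimum geodesic visits for a voxel to seed a candidate.
    f_v:
        Candidate voxels must also reach ``f_v`` times the global maximum.
    sigma_2theta_deg, sigma_eta_deg:
        User estimates of the scattering-angle / azimuth uncertainty.
    d_min_nm:
        Resolution cutoff for the reflection list.
    sigma_scale:
        Dimensionless scale on the magnitude pairing window.
    delta_omega_max_deg:
        Pre-selection bound on the equivalent z-rotation of a match.
    n_min:
        Minimum matched g vectors surviving outlier removal.
    c_min:
        Minimum completeness (matched / predicted recordable spots).
    u_max:
        Maximum matched-peak overlap fraction with an accepted solution.
    r_profile_inv_nm:
        Spherical profile radius used for the completeness denominator.
    max_candidates:
        Compute guard: at most this many candidate clusters are refined.
    eq6_axis:
        Axis of the equivalent-rotation pre-selection, "z" (lab vertical,
        default) or "x" (beam axis).
    """

    n_voxels: int
    v_min: int
    f_v: float
    sigma_2theta_deg: float
    sigma_eta_deg: float
    d_min_nm: float
    sigma_scale: float = 0.2
    delta_omega_max_deg: float = 30.0
    n_min: int = 10
    c_min: float = 0.5
    u_max: float = 0.5
    r_profile_inv_nm: float = 0.0086
    max_candidates: int = 200
    max_refine_iter: int = 10
    cluster_tol_deg: float = 0.0   # 0 -> twice the voxel angular radius
    eq6_axis: str = "z"

    def __post_init__(self) -> None:
        if self.n_voxels < 2:
            raise ValueError("n_voxels must be >= 2")
        for name in ("f_v", "c_min", "u_max"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        for name in ("v_min", "sigma_2theta_deg", "sigma_eta_deg",
                     "d_min_nm", "sigma_scale", "delta_omega_max_deg",
                     "n_min"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be > 0")
        if self.r_profile_inv_nm < 0:
            raise ValueError("r_profile_inv_nm must be >= 0")
        if self.eq6_axis not in ("z", "x"):
            raise ValueError("eq6_axis must be 'z' or 'x'")

    @property
    def cluster_tol_rad(self) -> float:
        if self.cluster_tol_deg > 0:
            return math.radians(self.cluster_tol_deg)
        return 2.0 * voxel_angular_radius(self.n_voxels)


# ---------------------------------------------------------------------------
# tolerance formulas (isolated so each can be swapped independently)

def gvector_magnitude_tolerance(theta_rad, params: FelixParams):
    """Relative |g| pairing window from the 2-theta uncertainty.

    Differentiating Bragg's law |g| = 2 sin(theta)/lambda gives
    d|g|/|g| = d(theta)/tan(theta); with d(theta) = sigma_2theta/2 and the
    user scale factor sigma this yields the acceptance window for
    | |g| - |h| | / |h|.
    """
    t = np.tan(np.asarray(theta_rad, float))
    half = math.radians(params.sigma_2theta_deg) / 2.0
    return params.sigma_scale * half / np.maximum(t, 1e-12)


def angular_deviation_bound(two_theta_rad, params: FelixParams):
    """Upper bound (rad) on the deviation between the outgoing rays of a
    predicted reflection and an observed spot.

    The user uncertainties live in detector angles: sigma_2theta along the
    polar (2-theta) direction and sigma_eta along the azimuth, whose arc
    shrinks as sin(2-theta); the bound is their quadrature sum.  Comparing
    outgoing-ray directions (rather than reciprocal directions q-hat vs
    g-hat) makes the criterion independent of the excitation error, which
    displaces low-resolution g vectors from their lattice points by up to
    r_profile/|q| without moving the spot on the detector.
    """
    s2t = math.radians(params.sigma_2theta_deg)
    se = math.radians(params.sigma_eta_deg)
    return np.sqrt(s2t ** 2
                   + (se * np.sin(np.asarray(two_theta_rad, float))) ** 2)


def equivalent_z_rotation(q_pred: np.ndarray, g_obs: np.ndarray,
                          axis: str = "z") -> np.ndarray:
    """|angle| (rad) of the residual rotation about the lab z (or x) axis
    bringing each predicted point onto its observed g, from the projections
    onto the plane normal to that axis.  Pairs whose projections vanish are
    unconstrained and report 0.
    """
    if axis == "z":
        a, b = 0, 1
    else:
        a, b = 1, 2
    cross = q_pred[..., a] * g_obs[..., b] - q_pred[..., b] * g_obs[..., a]
    dot = q_pred[..., a] * g_obs[..., a] + q_pred[..., b] * g_obs[..., b]
    norm = np.hypot(np.hypot(q_pred[..., a], q_pred[..., b]),
                    np.hypot(g_obs[..., a], g_obs[..., b]))
    ang = np.abs(np.arctan2(cross, dot))
    return np.where(norm > 1e-12, ang, 0.0)


# ---------------------------------------------------------------------------
# pipeline stages

@dataclass(frozen=True)
class CandidatePair:
    """One (g vector, reflection family) magnitude-compatible pairing."""

    g_index: int
    family_index: int
    mismatch: float          # | |g| - |h| | / |h|


def build_candidate_pairs(gvectors: np.ndarray,
                          families: Sequence[ReflectionFamily],
                          params: FelixParams,
                          wavelength_nm: float) -> list[CandidatePair]:
    """All (g, family) pairs within the magnitude window, in (g, family) order."""
    g = np.atleast_2d(np.asarray(gvectors, float))
    if len(g) == 0 or len(families) == 0:
        return []
    gmag = np.linalg.norm(g, axis=1)
    fmag = np.array([f.magnitude for f in families])
    order = np.argsort(fmag)
    fmag_sorted = fmag[order]
    theta = bragg_theta(gmag, wavelength_nm)
    tol = gvector_magnitude_tolerance(theta, params)
    out: list[CandidatePair] = []
    for i in range(len(g)):
        t = float(tol[i])
        lo = gmag[i] / (1.0 + t)
        hi = gmag[i] / (1.0 - t) if t < 1.0 else np.inf
        j0, j1 = np.searchsorted(fmag_sorted, [lo, hi])
        idx = np.sort(order[j0:j1])
        for j in idx:
            mism = abs(gmag[i] - fmag[j]) / fmag[j]
            out.append(CandidatePair(i, int(j), float(mism)))
    return out


@dataclass
class AccumulationResult:
    """Per-geodesic bookkeeping of one accumulation pass."""

    g_index: np.ndarray        # (M,) observed-spot index per geodesic
    family_index: np.ndarray   # (M,)
    member_index: np.ndarray   # (M,) index into family.members
    visits: np.ndarray         # (M,) voxels incremented per geodesic

    @property
    def n_geodesics(self) -> int:
        return len(self.g_index)

    @property
    def n_degenerate(self) -> int:
        return int(np.sum(self.visits == 0))


def accumulate(pairs: Sequence[CandidatePair], gvectors: np.ndarray,
               families: Sequence[ReflectionFamily],
               accumulator: FrustumAccumulator) -> AccumulationResult:
    """Trace one geodesic per (g, equivalent reflection) combination."""
    g = np.atleast_2d(np.asarray(gvectors, float))
    if len(pairs) == 0:
        z = np.zeros(0, np.int64)
        return AccumulationResult(z, z, z, z)
    ghat = g / np.linalg.norm(g, axis=1)[:, None]
    g_blocks, f_blocks, m_blocks, h_blocks = [], [], [], []
    for p in pairs:
        fam = families[p.family_index]
        m = fam.multiplicity
        g_blocks.append(np.full(m, p.g_index, np.int64))
        f_blocks.append(np.full(m, p.family_index, np.int64))
        m_blocks.append(np.arange(m, dtype=np.int64))
        h_blocks.append(fam.qvecs)
    g_idx = np.concatenate(g_blocks)
    f_idx = np.concatenate(f_blocks)
    m_idx = np.concatenate(m_blocks)
    hvec = np.concatenate(h_blocks)
    hhat = hvec / np.linalg.norm(hvec, axis=1)[:, None]
    visits = accumulator.trace_pairs(ghat[g_idx], hhat)
    return AccumulationResult(g_idx, f_idx, m_idx, visits)


@dataclass
class MatchSet:
    """Unique g <-> hkl assignments for one orientation candidate."""

    g_index: np.ndarray        # (n,)
    hkl: np.ndarray            # (n, 3) int
    g_obs: np.ndarray          # (n, 3) observed g vectors
    q_ref: np.ndarray          # (n, 3) unrotated B @ hkl
    deviation_rad: np.ndarray  # (n,) angular deviation at assignment time

    def __len__(self) -> int:
        return len(self.g_index)

    def select(self, mask: np.ndarray) -> "MatchSet":
        return MatchSet(self.g_index[mask], self.hkl[mask], self.g_obs[mask],
                        self.q_ref[mask], self.deviation_rad[mask])


def _as_reflection_arrays(reflections) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(reflections, tuple):
        return reflections
    hkl = np.concatenate([f.members for f in reflections])
    q = np.concatenate([f.qvecs for f in reflections])
    return hkl, q


def match_gvectors(orientation: Rotation, gvectors: np.ndarray, reflections,
                   params: FelixParams, wavelength_nm: float,
                   extra_tol_rad: float = 0.0) -> MatchSet:
    """Assign observed g vectors to predicted reflections of one orientation.

    ``reflections`` is either a sequence of :class:`ReflectionFamily` or the
    ``(hkl, q)`` arrays from :func:`pyfelix.cells.reflection_list`.  A pair
    is assignable when (a) its equivalent z-rotation is within the
    pre-selection bound, (b) the angular deviation is within the matching
    bound (optionally widened by ``extra_tol_rad`` when seeding from a
    voxel centre), and (c) the magnitude mismatch is within the pairing
    window.  Assignment is greedy by smallest angular deviation, one g per
    hkl and vice versa.
    """
    hkl_all, q0_all = _as_reflection_arrays(reflections)
    g = np.atleast_2d(np.asarray(gvectors, float))
    empty = MatchSet(np.zeros(0, int), np.zeros((0, 3), int),
                     np.zeros((0, 3)), np.zeros((0, 3)), np.zeros(0))
    if len(g) == 0 or len(hkl_all) == 0:
        return empty
    u = orientation.as_matrix()
    qp = q0_all @ u.T
    qnorm = np.linalg.norm(qp, axis=1)
    theta = bragg_theta(qnorm, wavelength_nm)
    k = 1.0 / wavelength_nm
    k_in = np.array([k, 0.0, 0.0])
    kout_p = qp + k_in
    two_theta_p = np.arccos(np.clip(
        kout_p[:, 0] / np.linalg.norm(kout_p, axis=1), -1.0, 1.0))
    ang_bound = angular_deviation_bound(two_theta_p, params) + extra_tol_rad
    # |g| of an observed spot differs from |q| of its lattice point by up
    # to the excitation error (at most r_profile under the spherical
    # partiality model), so the magnitude window is the Bragg-derived
    # pairing window widened to at least that displacement
    mag_win = np.maximum(
        qnorm * gvector_magnitude_tolerance(theta, params),
        params.r_profile_inv_nm)
    # observed g all lie on the Ewald sphere; a predicted point can only
    # match if it is within the combined magnitude + ray-deviation window
    # of the sphere
    r3 = mag_win + ang_bound / wavelength_nm
    exc = np.abs(np.linalg.norm(kout_p, axis=1) - k)
    near = np.nonzero(exc <= r3)[0]
    if len(near) == 0:
        return empty
    tree = cKDTree(g)
    ub = float(r3[near].max())
    nq = min(4, len(g))
    dist, gi = tree.query(qp[near], k=nq, distance_upper_bound=ub)
    if nq == 1:
        dist, gi = dist[:, None], gi[:, None]
    cand: list[tuple[float, int, int]] = []
    gmag = np.linalg.norm(g, axis=1)
    kout_o = g + k_in
    for col in range(nq):
        ok = np.isfinite(dist[:, col])
        for row in np.nonzero(ok)[0]:
            j = near[row]
            i = int(gi[row, col])
            dev = _angle_between(kout_p[j], kout_o[i])
            if dev > ang_bound[j]:
                continue
            if abs(gmag[i] - qnorm[j]) > mag_win[j]:
                continue
            dz = equivalent_z_rotation(qp[j], g[i], params.eq6_axis)
            if dz > math.radians(params.delta_omega_max_deg):
                continue
            cand.append((dev, i, int(j)))
    if not cand:
        return empty
    cand.sort(key=lambda c: (c[0], c[1], c[2]))
    used_g: set[int] = set()
    used_h: set[int] = set()
    rows: list[tuple[float, int, int]] = []
    for dev, i, j in cand:
        if i in used_g or j in used_h:
            continue
        used_g.add(i)
        used_h.add(j)
        rows.append((dev, i, j))
    rows.sort(key=lambda r: r[1])
    devs = np.array([r[0] for r in rows])
    gi_arr = np.array([r[1] for r in rows], int)
    hj = np.array([r[2] for r in rows], int)
    return MatchSet(gi_arr, hkl_all[hj], g[gi_arr], q0_all[hj], devs)


def _angle_between(a: np.ndarray, b: np.ndarray) -> float:
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    c = float(np.dot(a, b) / (na * nb))
    return math.acos(min(1.0, max(-1.0, c)))


def refine_orientation(orientation: Rotation, matches: MatchSet,
                       params: FelixParams) -> tuple[Rotation, MatchSet]:
    """Orthogonal-Procrustes orientation fit with iterative outlier removal.

    Fits the rotation aligning the unit reference vectors B@hkl onto the
    observed g-hat directions, then drops assignments whose angular
    residual exceeds max(3*sigma_eta, 3 * median residual), iterating until
    stable (at most ``max_refine_iter`` rounds).
    """
    current = matches
    rot = orientation
    for _ in range(params.max_refine_iter):
        if len(current) < 2:
            raise UnderdeterminedError("fewer than 2 matches")
        b = current.q_ref / np.linalg.norm(current.q_ref, axis=1)[:, None]
        a = current.g_obs / np.linalg.norm(current.g_obs, axis=1)[:, None]
        sv = np.linalg.svd(b, compute_uv=False)
        if sv[1] <= 1e-8 * sv[0]:
            raise UnderdeterminedError("matches are collinear")
        fit, _ = _SciRotation.align_vectors(a, b)
        u = fit.as_matrix()
        rot = Rotation.from_matrix(u)
        res = np.arccos(np.clip(np.sum(a * (b @ u.T), axis=1), -1.0, 1.0))
        thr = max(3.0 * math.radians(params.sigma_eta_deg),
                  3.0 * float(np.median(res)))
        drop = res > thr
        if not drop.any():
            return rot, current
        current = current.select(~drop)
    return rot, current


@dataclass
class IndexingSolution:
    """An accepted crystal orientation with its matched peaks."""

    rotation: Rotation
    g_index: np.ndarray          # matched observed-peak indices
    hkl: np.ndarray              # (n, 3) assigned Miller indices
    deviation_rad: np.ndarray
    n_matched: int
    completeness: float
    seed_visits: int             # visit count V of the seeding voxel

    def matched_table(self):
        import pandas as pd

        return pd.DataFrame({
            "peak": self.g_index,
            "h": self.hkl[:, 0], "k": self.hkl[:, 1], "l": self.hkl[:, 2],
            "deviation_deg": np.degrees(self.deviation_rad),
        })


def accept_solutions(drafts: Sequence[IndexingSolution],
                     params: FelixParams) -> list[IndexingSolution]:
    """Filter drafts by N_min / completeness, then remove duplicates.

    Processing in descending n_matched, a draft whose matched-peak set
    overlaps an accepted one by more than ``u_max`` (normalized by the
    smaller set) is dropped.
    """
    good = [d for d in drafts
            if d.n_matched >= params.n_min and d.completeness >= params.c_min]
    good.sort(key=lambda d: -d.n_matched)
    accepted: list[IndexingSolution] = []
    for d in good:
        s = set(d.g_index.tolist())
        dup = False
        for a in accepted:
            t = set(a.g_index.tolist())
            ov = len(s & t) / max(1, min(len(s), len(t)))
            if ov > params.u_max:
                dup = True
                break
        if not dup:
            accepted.append(d)
    return accepted


def _laue_quats(cell: UnitCell) -> np.ndarray:
    return np.array([Rotation.from_matrix(m).q
                     for m in laue_operators(cell.laue_class)])


def _cluster_candidates(maxima, acc: FrustumAccumulator, ops_q: np.ndarray,
                        tol_rad: float, cap: int
                        ) -> list[tuple[Rotation, int]]:
    """Greedy symmetry-aware clustering of local maxima (best visits first)."""
    kept: list[tuple[Rotation, int]] = []
    expanded: list[np.ndarray] = []
    cos_half = math.cos(tol_rad / 2.0)
    for m in maxima:
        rot = acc.rotation_at(m.chart, m.index)
        if expanded:
            dots = np.abs(np.concatenate(expanded) @ rot.q)
            if dots.max() >= cos_half:
                continue
        kept.append((rot, m.visits))
        # symmetry-equivalent copies rot * S for dedup tests
        eq = np.array([quat_mult_batch(rot.q, oq) for oq in ops_q])
        expanded.append(eq)
        if len(kept) >= cap:
            break
    return kept


def quat_mult_batch(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    w1, x1, y1, z1 = a
    w2, x2, y2, z2 = b
    return np.array([
        w1 * w2 - x1 * x2 - y1 * y2 - z1 * z2,
        w1 * x2 + x1 * w2 + y1 * z2 - z1 * y2,
        w1 * y2 - x1 * z2 + y1 * w2 + z1 * x2,
        w1 * z2 + x1 * y2 - y1 * x2 + z1 * w2,
    ])


def _predicted_recordable(u: np.ndarray, q0_all: np.ndarray,
                          geom: BeamGeometry, r_profile: float) -> int:
    qp = q0_all @ u.T
    exc = excitation_errors(qp, geom)
    near = exc <= r_profile
    if not near.any():
        return 0
    _, rec = gvectors_to_detector(qp[near], geom)
    return int(rec.sum())


def index_image(peaks_or_gvectors: np.ndarray, cell: UnitCell,
                geom: BeamGeometry, params: FelixParams,
                accumulator: FrustumAccumulator | None = None,
                families: Sequence[ReflectionFamily] | None = None
                ) -> list[IndexingSolution]:
    """Index all crystal lattices in one snapshot image.

    ``peaks_or_gvectors`` is an (n, 2) array of detector positions (metres
    from the beam centre) or an (n, 3) array of reciprocal-space g vectors
    (nm^-1).  Returns accepted solutions sorted by n_matched descending.
    The whole pipeline is deterministic: identical inputs give identical
    output.
    """
    arr = np.asarray(peaks_or_gvectors, float)
    if arr.size == 0:
        return []
    if arr.ndim != 2 or arr.shape[1] not in (2, 3):
        raise ValueError("expected (n, 2) peak positions or (n, 3) g vectors")
    g = peaks_to_gvectors(arr, geom) if arr.shape[1] == 2 else arr
    if families is None:
        families = generate_families(cell, params.d_min_nm)
    refl = reflection_list(cell, params.d_min_nm)

    pairs = build_candidate_pairs(g, families, params, geom.wavelength_nm)
    acc = accumulator if accumulator is not None \
        else FrustumAccumulator(params.n_voxels)
    if acc.n_voxels != params.n_voxels:
        raise ValueError("accumulator n_voxels differs from params.n_voxels")
    acc.reset()
    accumulate(pairs, g, families, acc)

    maxima = acc.local_maxima(params.v_min, params.f_v)
    ops_q = _laue_quats(cell)
    cands = _cluster_candidates(maxima, acc, ops_q, params.cluster_tol_rad,
                                params.max_candidates)

    seed_extra = 2.0 * voxel_angular_radius(params.n_voxels)
    drafts: list[IndexingSolution] = []
    for rot0, visits in cands:
        m0 = match_gvectors(rot0, g, refl, params, geom.wavelength_nm,
                            extra_tol_rad=seed_extra)
        if len(m0) < 2:
            continue
        try:
            rot1, _ = refine_orientation(rot0, m0, params)
            m1 = match_gvectors(rot1, g, refl, params, geom.wavelength_nm)
            if len(m1) < 2:
                continue
            rot2, m2 = refine_orientation(rot1, m1, params)
        except UnderdeterminedError:
            continue
        n_pred = _predicted_recordable(rot2.as_matrix(), refl[1], geom,
                                       params.r_profile_inv_nm)
        comp = len(m2) / n_pred if n_pred > 0 else 0.0
        drafts.append(IndexingSolution(rot2, m2.g_index, m2.hkl,
                                       m2.deviation_rad, len(m2), comp,
                                       visits))
    return accept_solutions(drafts, params)
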