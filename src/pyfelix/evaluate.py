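"""Scoring indexing results against ground truth and misorientation analysis.

Two crystal orientations R1, R2 of the same lattice are compared through
their misorientation: the minimal rotation angle of S * R1 * R2^-1 over the
proper Laue operators S (left- and right-multiplication give the same
minimum for a group).  The axis and Rodrigues-Frank vector of the minimizer
characterize the interface between crystals in an agglomerate; projected
RF-vector densities expose preferred contact facets.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .rfspace import Rotation, quat_multiply


def laue_quaternions(laue_ops: Sequence[np.ndarray]) -> np.ndarray:
    """Proper Laue rotations as an (m, 4) array of unit quaternions."""
    return np.array([Rotation.from_matrix(m).q for m in laue_ops])


def _conj(q: np.ndarray) -> np.ndarray:
    return q * np.array([1.0, -1.0, -1.0, -1.0])


@dataclass(frozen=True)
class Misorientation:
    """Minimal symmetry-reduced rotation between two orientations."""

    angle_deg: float
    axis: np.ndarray            # unit 3-vector of the minimizer
    rf_vector: np.ndarray | None  # axis*tan(angle/2); None at ~180 deg

    @property
    def angle_rad(self) -> float:
        return math.radians(self.angle_deg)


def misorientation(r1: Rotation, r2: Rotation,
                   laue_ops: Sequence[np.ndarray]) -> Misorientation:
    """Symmetry-reduced misorientation between two orientations.

    Symmetric in its arguments; zero when the orientations are related by a
    Laue operator.
    """
    ops_q = laue_ops if isinstance(laue_ops, np.ndarray) \
        else laue_quaternions(laue_ops)
    # crystal-frame relative rotation: orientations are equivalent under
    # right-multiplication by a Laue operator (U ~ U S), so the reducible
    # rotation is R2^-1 R1 with S applied on either side
    m = quat_multiply(_conj(r2.q), r1.q)
    # scalar part of S*M is dot(q_S, conj(M)); maximize |.| to minimize angle
    w = ops_q @ _conj(m)
    best = int(np.argmax(np.abs(w)))
    qmin = quat_multiply(ops_q[best], m)
    rot = Rotation(qmin)
    axis, angle = rot.axis_angle()
    rf = axis * math.tan(angle / 2.0) if angle < math.radians(179.9) else None
    return Misorientation(math.degrees(angle), axis, rf)


def misorientation_angles(q1: np.ndarray, q2: np.ndarray,
                          ops_q: np.ndarray) -> np.ndarray:
    """Vectorized symmetry-reduced angles (rad) between quaternion arrays."""
    q1 = np.atleast_2d(q1)
    q2 = np.atleast_2d(q2)
    m = _quat_multiply_batch(q2 * np.array([1.0, -1.0, -1.0, -1.0]), q1)
    w = np.abs(m * np.array([1.0, -1.0, -1.0, -1.0]) @ ops_q.T)
    return 2.0 * np.arccos(np.clip(w.max(axis=-1), -1.0, 1.0))


def _quat_multiply_batch(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    w1, x1, y1, z1 = a[..., 0], a[..., 1], a[..., 2], a[..., 3]
    w2, x2, y2, z2 = b[..., 0], b[..., 1], b[..., 2], b[..., 3]
    return np.stack([
        w1 * w2 - x1 * x2 - y1 * y2 - z1 * z2,
        w1 * x2 + x1 * w2 + y1 * z2 - z1 * y2,
        w1 * y2 - x1 * z2 + y1 * w2 + z1 * x2,
        w1 * z2 + x1 * y2 - y1 * x2 + z1 * w2,
    ], axis=-1)


@dataclass
class AccuracyReport:
    """Ensemble indexing-accuracy summary against ground truth."""

    per_image: list[tuple[int, int, int]]   # (n_true, n_found, n_correct)
    tolerance_deg: float

    @property
    def n_true(self) -> int:
        return sum(r[0] for r in self.per_image)

    @property
    def n_found(self) -> int:
        return sum(r[1] for r in self.per_image)

    @property
    def n_correct(self) -> int:
        return sum(r[2] for r in self.per_image)

    @property
    def mean_correct_per_image(self) -> float:
        return self.n_correct / max(1, len(self.per_image))

    @property
    def fraction_found_correct(self) -> float:
        """Fraction of found crystals that match a true orientation."""
        return self.n_correct / self.n_found if self.n_found else 0.0

    def as_dict(self) -> dict:
        return {
            "n_images": len(self.per_image),
            "n_true": self.n_true, "n_found": self.n_found,
            "n_correct": self.n_correct,
            "mean_correct_per_image": self.mean_correct_per_image,
            "fraction_found_correct": self.fraction_found_correct,
            "tolerance_deg": self.tolerance_deg,
        }


def match_to_truth(found: Sequence[Sequence[Rotation]],
                   truth: Sequence[Sequence[Rotation]],
                   tolerance_deg: float,
                   laue_ops: Sequence[np.ndarray]) -> AccuracyReport:
    """Greedy one-to-one matching of found vs true orientations per image.

    Pairs are consumed in increasing misorientation order; a pair counts as
    correct when its symmetry-reduced misorientation is within tolerance.
    """
    if not tolerance_deg > 0:
        raise ValueError("tolerance must be > 0")
    if len(found) != len(truth):
        raise ValueError("found and truth must have one entry per image")
    ops_q = laue_quaternions(laue_ops)
    tol = math.radians(tolerance_deg)
    rows = []
    for sols, true in zip(found, truth):
        n_f, n_t = len(sols), len(true)
        n_c = 0
        if n_f and n_t:
            qf = np.array([r.q for r in sols])
            qt = np.array([r.q for r in true])
            ang = misorientation_angles(qf[:, None, :], qt[None, :, :], ops_q)
            order = np.argsort(ang, axis=None, kind="stable")
            used_f: set[int] = set()
            used_t: set[int] = set()
            for flat in order:
                i, j = divmod(int(flat), n_t)
                if i in used_f or j in used_t:
                    continue
                used_f.add(i)
                used_t.add(j)
                if ang[i, j] <= tol:
                    n_c += 1
        rows.append((n_t, n_f, n_c))
    return AccuracyReport(rows, tolerance_deg)


@dataclass
class MisorientationSurvey:
    """Within-image pairwise misorientations of an indexed ensemble."""

    angles_deg: np.ndarray          # (n,)
    rf_vectors: np.ndarray          # (n, 3); NaN rows where undefined
    bin_edges: np.ndarray
    histogram: np.ndarray           # density over bin_edges

    def projection(self, plane: str = "xy", bins: int = 64,
                   extent: float = 1.0) -> tuple[np.ndarray, np.ndarray,
                                                 np.ndarray]:
        """Binned 2D density of RF vectors projected on xy/yz/xz."""
        cols = {"xy": (0, 1), "yz": (1, 2), "xz": (0, 2)}[plane]
        rf = self.rf_vectors[np.all(np.isfinite(self.rf_vectors), axis=1)]
        h, ex, ey = np.histogram2d(rf[:, cols[0]], rf[:, cols[1]], bins=bins,
                                   range=[[-extent, extent], [-extent, extent]])
        return h, ex, ey


def misorientation_survey(per_image_solutions: Sequence[Sequence[Rotation]],
                          laue_ops: Sequence[np.ndarray],
                          bins: int = 180,
                          angle_range: tuple[float, float] = (0.0, 180.0)
                          ) -> MisorientationSurvey:
    """All unordered within-image orientation pairs, symmetry-reduced."""
    ops_q = laue_quaternions(laue_ops)
    angles: list[float] = []
    rfs: list[np.ndarray] = []
    for sols in per_image_solutions:
        for i in range(len(sols)):
            for j in range(i + 1, len(sols)):
                mis = misorientation(sols[i], sols[j], ops_q)
                angles.append(mis.angle_deg)
                rfs.append(mis.rf_vector if mis.rf_vector is not None
                           else np.full(3, np.nan))
    ang = np.array(angles)
    rf = np.array(rfs) if rfs else np.zeros((0, 3))
    hist, edges = np.histogram(ang, bins=bins, range=angle_range,
                               density=len(ang) > 0)
    return MisorientationSurvey(ang, rf, edges, hist)


def random_misorientation_baseline(laue_ops: Sequence[np.ndarray],
                                   n_samples: int,
                                   rng: np.random.Generator,
                                   bins: int = 180,
                                   angle_range: tuple[float, float] = (0.0, 180.0)
                                   ) -> tuple[np.ndarray, np.ndarray]:
    """Monte-Carlo symmetry-reduced misorientation density of random pairs.

    Returns (bin_edges, density); the density integrates to 1.  This is the
    null distribution against which agglomerate excesses are judged.
    """
    if n_samples < 1000:
        warnings.warn("fewer than 1000 samples gives a noisy baseline",
                      stacklevel=2)
    ops_q = laue_quaternions(laue_ops)
    q1 = rng.normal(size=(n_samples, 4))
    q1 /= np.linalg.norm(q1, axis=1)[:, None]
    q2 = rng.normal(size=(n_samples, 4))
    q2 /= np.linalg.norm(q2, axis=1)[:, None]
    ang = np.degrees(misorientation_angles(q1, q2, ops_q))
    hist, edges = np.histogram(ang, bins=bins, range=angle_range,
                               density=True)
    return edges, hist


# ---------------------------------------------------------------------------
# end-to-end accuracy studies (simulate -> index -> score)

def indexing_accuracy_study(scenario, crystals_per_image: int, n_images: int,
                            rng: np.random.Generator,
                            tolerance_deg: float = 1.0,
                            params=None) -> AccuracyReport:
    """Simulate, index and score ``n_images`` snapshots of one scenario.

    The default correctness tolerance of 1 degree is well below typical
    random misorientations and well above the refined-orientation error of
    a correctly seeded solution.
    """
    from .indexer import index_image
    from .rfspace import FrustumAccumulator
    from .simulate import simulate_image

    params = params or scenario.felix_params()
    ops = scenario.cell.laue_operators()
    acc = FrustumAccumulator(params.n_voxels)
    found, truth = [], []
    for _ in range(n_images):
        img = simulate_image(crystals_per_image, scenario, rng)
        sols = index_image(img.peaks_xy, scenario.cell, scenario.geometry,
                           params, accumulator=acc)
        found.append([s.rotation for s in sols])
        truth.append(img.orientations)
    return match_to_truth(found, truth, tolerance_deg, ops)
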