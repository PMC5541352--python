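"""Rotations, Rodrigues-Frank vectors, geodesics and the frustum accumulator.

Orientation space (the rotation group) is parametrized by unit quaternions
q = (q0, q1, q2, q3) with q and -q identified; the Rodrigues-Frank (RF)
image of a rotation by angle omega about axis n-hat is

    r = n-hat * tan(omega / 2) = (q1, q2, q3) / q0,

which diverges as omega -> 180 deg.  To search all of orientation space in
finite volume, the quaternion sphere is covered by four congruent charts
("frustums"): chart k collects the quaternions whose k-th component has the
largest magnitude, with local coordinates equal to the remaining three
components divided by the dominant one — always inside [-1, 1]^3.  Chart 0
is classical RF space truncated to rotations up to 90 deg; charts 1-3 cover
the near-180-deg rotations about axes close to x, y, z.  Geodesics (sets of
rotations mapping one unit vector onto another) are straight lines in every
chart, and their chart segments join across chart faces, so the whole
infinite RF line is rasterized as at most four cube-clipped segments.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from . import _tracer


class RFDomainError(ValueError):
    """RF vector requested for a rotation at/near 180 degrees."""


class DegenerateGeodesicError(ValueError):
    """Geodesic requested for an antipodal (g = -h) direction pair."""


def _canonical(q: np.ndarray) -> np.ndarray:
    n = np.linalg.norm(q)
    if not np.isfinite(n) or n == 0:
        raise ValueError("zero or non-finite quaternion")
    q = q / n
    for comp in q:
        if comp != 0.0:
            if comp < 0.0:
                q = -q
            break
    return q


class Rotation:
    """A proper rotation stored as a canonical unit quaternion (q0 >= 0).

    Quaternions are scalar-first.  The class is deliberately small; heavy
    numerics operate on raw arrays and convert at the boundaries.
    """

    __slots__ = ("q",)

    def __init__(self, quaternion) -> None:
        q = np.asarray(quaternion, float).copy()
        if q.shape != (4,):
            raise ValueError("quaternion must have shape (4,)")
        self.q = _canonical(q)

    # -- constructors -------------------------------------------------
    @classmethod
    def identity(cls) -> "Rotation":
        return cls([1.0, 0.0, 0.0, 0.0])

    @classmethod
    def from_axis_angle(cls, axis, angle_rad: float) -> "Rotation":
        axis = np.asarray(axis, float)
        n = np.linalg.norm(axis)
        if n == 0:
            raise ValueError("zero rotation axis")
        half = 0.5 * angle_rad
        return cls(np.concatenate([[math.cos(half)],
                                   math.sin(half) * axis / n]))

    @classmethod
    def from_matrix(cls, m) -> "Rotation":
        """Shepperd's method, stable for all rotation angles."""
        m = np.asarray(m, float)
        t = np.trace(m)
        if t > 0:
            s = math.sqrt(t + 1.0) * 2
            q = np.array([0.25 * s,
                          (m[2, 1] - m[1, 2]) / s,
                          (m[0, 2] - m[2, 0]) / s,
                          (m[1, 0] - m[0, 1]) / s])
        else:
            i = int(np.argmax(np.diag(m)))
            j, k = (i + 1) % 3, (i + 2) % 3
            s = math.sqrt(max(1e-15, 1.0 + m[i, i] - m[j, j] - m[k, k])) * 2
            q = np.empty(4)
            q[0] = (m[k, j] - m[j, k]) / s
            q[1 + i] = 0.25 * s
            q[1 + j] = (m[j, i] + m[i, j]) / s
            q[1 + k] = (m[k, i] + m[i, k]) / s
        return cls(q)

    @classmethod
    def random(cls, rng: np.random.Generator) -> "Rotation":
        """Uniform (Haar) random rotation from a Gaussian 4-vector."""
        return cls(rng.normal(size=4))

    # -- conversions --------------------------------------------------
    def as_matrix(self) -> np.ndarray:
        w, x, y, z = self.q
        return np.array([
            [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
            [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
            [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
        ])

    def axis_angle(self) -> tuple[np.ndarray, float]:
        """Rotation axis (unit) and angle in [0, pi]."""
        vec = self.q[1:]
        s = np.linalg.norm(vec)
        angle = 2.0 * math.atan2(s, self.q[0])
        axis = vec / s if s > 0 else np.array([1.0, 0.0, 0.0])
        return axis, angle

    @property
    def angle(self) -> float:
        return self.axis_angle()[1]

    # -- algebra ------------------------------------------------------
    def compose(self, other: "Rotation") -> "Rotation":
        """self * other (apply ``other`` first)."""
        return Rotation(quat_multiply(self.q, other.q))

    __mul__ = compose

    def inv(self) -> "Rotation":
        return Rotation(self.q * np.array([1.0, -1.0, -1.0, -1.0]))

    def apply(self, v: np.ndarray) -> np.ndarray:
        return np.asarray(v, float) @ self.as_matrix().T

    def approx_equal(self, other: "Rotation", atol_rad: float = 1e-9) -> bool:
        d = abs(float(np.dot(self.q, other.q)))
        return 2.0 * math.acos(min(1.0, d)) <= atol_rad

    def __repr__(self) -> str:
        return f"Rotation(q={np.array2string(self.q, precision=8)})"


def quat_multiply(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    w1, x1, y1, z1 = a
    w2, x2, y2, z2 = b
    return np.array([
        w1 * w2 - x1 * x2 - y1 * y2 - z1 * z2,
        w1 * x2 + x1 * w2 + y1 * z2 - z1 * y2,
        w1 * y2 - x1 * z2 + y1 * w2 + z1 * x2,
        w1 * z2 + x1 * y2 - y1 * x2 + z1 * w2,
    ])


def rotation_to_rf(rotation: Rotation, eps_rad: float = 1e-9) -> np.ndarray:
    """RF vector r = n-hat tan(omega/2) = vector part / scalar part.

    Raises :class:`RFDomainError` within ``eps_rad`` of 180 deg, where the
    RF parametrization diverges; use :func:`chart_map` there instead.
    """
    q = rotation.q
    if q[0] <= math.sin(eps_rad / 2.0) + 0.0:
        raise RFDomainError(
            "rotation angle at/near 180 deg has no finite RF vector; "
            "use chart_map for a bounded parametrization"
        )
    return q[1:] / q[0]


def rf_to_rotation(r: np.ndarray) -> Rotation:
    r = np.asarray(r, float)
    return Rotation(np.concatenate([[1.0], r]))


def chart_map(rotation: Rotation) -> tuple[int, np.ndarray]:
    """Map a rotation to (chart id, local coordinates in [-1, 1]^3).

    The chart is the index of the largest-magnitude quaternion component
    (lowest index wins ties); the coordinates are the remaining components
    divided by the dominant one, which is invariant under q -> -q.
    """
    q = rotation.q
    k = int(np.argmax(np.abs(q)))
    coords = np.delete(q, k) / q[k]
    return k, coords


def chart_unmap(chart: int, coords: np.ndarray) -> Rotation:
    """Inverse of :func:`chart_map` (up to quaternion sign)."""
    if not 0 <= chart <= 3:
        raise ValueError("chart must be in {0, 1, 2, 3}")
    coords = np.asarray(coords, float)
    if coords.shape != (3,):
        raise ValueError("coords must have shape (3,)")
    q = np.insert(coords, chart, 1.0)
    return Rotation(q)


@dataclass(frozen=True)
class Geodesic:
    """The line of rotations mapping h-hat onto g-hat in RF space.

    ``anchor`` is the RF vector of the minimal rotation (axis || h x g);
    ``direction`` is the unit line direction (|| h + g).  ``g_index`` and
    ``hkl`` carry provenance through the indexing pipeline.
    """

    anchor: np.ndarray
    direction: np.ndarray
    g_index: int = -1
    hkl: tuple[int, int, int] | None = None

    def point(self, t: float) -> np.ndarray:
        return self.anchor + t * self.direction

    def rotation(self, t: float) -> Rotation:
        return rf_to_rotation(self.point(t))

    def quaternion_plane(self) -> tuple[np.ndarray, np.ndarray]:
        """Orthonormal basis (u, v) of the great-circle plane in R^4."""
        u = np.concatenate([[1.0], self.anchor])
        u /= np.linalg.norm(u)
        v = np.concatenate([[0.0], self.direction])
        return u, v


def geodesic_from_pair(g, h, *, g_index: int = -1,
                       hkl: tuple[int, int, int] | None = None) -> Geodesic:
    """Geodesic of rotations taking reflection ``h`` onto observed ``g``.

    Both arguments are 3-vectors (only directions matter).  Antipodal pairs
    raise :class:`DegenerateGeodesicError`; collinear pairs give the line
    through the origin along h-hat (the identity is a solution).
    """
    g = np.asarray(g.vector if hasattr(g, "vector") else g, float)
    h = np.asarray(h, float)
    ng, nh = np.linalg.norm(g), np.linalg.norm(h)
    if ng == 0 or nh == 0:
        raise ValueError("zero-length vector has no direction")
    ghat, hhat = g / ng, h / nh
    c = float(np.dot(hhat, ghat))
    cross = np.cross(hhat, ghat)
    s = float(np.linalg.norm(cross))
    if s < 1e-12:
        if c < 0:
            raise DegenerateGeodesicError(
                "g and h are antipodal: the solution set has no finite "
                "RF anchor"
            )
        return Geodesic(np.zeros(3), hhat, g_index, hkl)
    theta = math.atan2(s, c)
    anchor = cross / s * math.tan(0.5 * theta)
    direction = (hhat + ghat)
    direction /= np.linalg.norm(direction)
    return Geodesic(anchor, direction, g_index, hkl)


@dataclass(frozen=True)
class LocalMaximum:
    """A candidate voxel: chart, (i, j, k) index and its visit count."""

    chart: int
    index: tuple[int, int, int]
    visits: int


class _SparseCounts:
    """Dict-backed voxel counters for grids too large to hold densely."""

    def __init__(self, n_voxels: int) -> None:
        self.n_voxels = n_voxels
        self.data: dict[tuple[int, int, int, int], int] = {}

    def __call__(self, chart: int, i: int, j: int, k: int) -> None:
        key = (chart, i, j, k)
        self.data[key] = self.data.get(key, 0) + 1


class FrustumAccumulator:
    """Per-voxel visit counters over the four-chart covering of rotations.

    Parameters
    ----------
    n_voxels:
        Voxels per axis per chart (N_v); total 4 * N_v^3 counters.
    dtype:
        Counter dtype for dense storage (default int16; raise to int32 for
        extremely crowded images).
    sparse:
        Force sparse (dict) storage.  By default dense storage is used
        unless the array would exceed ``memory_limit_bytes``.
    """

    def __init__(self, n_voxels: int, dtype=np.int16, sparse: bool | None = None,
                 memory_limit_bytes: int = 4 * 2 ** 30) -> None:
        if n_voxels < 1:
            raise ValueError("n_voxels must be >= 1")
        self.n_voxels = int(n_voxels)
        dense_bytes = 4 * self.n_voxels ** 3 * np.dtype(dtype).itemsize
        if sparse is None:
            sparse = dense_bytes > memory_limit_bytes
        self.sparse = bool(sparse)
        if self.sparse:
            self._sparse = _SparseCounts(self.n_voxels)
            self.counts = None
        else:
            self.counts = np.zeros((4,) + (self.n_voxels,) * 3, dtype=dtype)
            self._sparse = None
        self._traced_visits = 0

    # -- tracing ------------------------------------------------------
    def trace(self, geodesic: Geodesic) -> int:
        """Trace one geodesic; returns the number of voxels incremented."""
        u, v = geodesic.quaternion_plane()
        if self.sparse:
            n = _tracer.trace_plane_python(u, v, self._sparse)
        else:
            n = int(_tracer.trace_plane_single(u, v, self.counts))
        self._traced_visits += n
        return n

    def trace_pairs(self, ghat: np.ndarray, hhat: np.ndarray) -> np.ndarray:
        """Trace one geodesic per (g-hat, h-hat) row pair (compiled path).

        Degenerate (antipodal) pairs are skipped and report 0 visits.
        """
        ghat = np.ascontiguousarray(ghat, float)
        hhat = np.ascontiguousarray(hhat, float)
        visits = np.zeros(len(ghat), np.int64)
        if self.sparse:
            for i in range(len(ghat)):
                try:
                    geo = geodesic_from_pair(ghat[i], hhat[i])
                except DegenerateGeodesicError:
                    continue
                u, v = geo.quaternion_plane()
                visits[i] = _tracer.trace_plane_python(u, v, self._sparse)
        else:
            _tracer.trace_pairs(ghat, hhat, self.counts, visits)
        self._traced_visits += int(visits.sum())
        return visits

    # -- inspection ---------------------------------------------------
    def total(self) -> int:
        if self.sparse:
            return sum(self._sparse.data.values())
        return int(self.counts.sum(dtype=np.int64))

    @property
    def traced_visits(self) -> int:
        """Sum of per-geodesic visit counts (conservation check)."""
        return self._traced_visits

    def max(self) -> int:
        if self.sparse:
            return max(self._sparse.data.values(), default=0)
        return int(self.counts.max())

    def counts_dense(self) -> np.ndarray:
        if not self.sparse:
            return self.counts
        out = np.zeros((4,) + (self.n_voxels,) * 3, np.int64)
        for (c, i, j, k), v in self._sparse.data.items():
            out[c, i, j, k] = v
        return out

    def reset(self) -> None:
        if self.sparse:
            self._sparse.data.clear()
        else:
            self.counts[:] = 0
        self._traced_visits = 0

    # -- candidate extraction -----------------------------------------
    def local_maxima(self, v_min: int, f_v: float,
                     max_results: int = 1_000_000) -> list[LocalMaximum]:
        """Voxels >= all 26 in-chart neighbours with V >= max(V_min, f_V*V_max).

        Sorted by visits descending, ties by (chart, linear index).
        """
        if not 0.0 <= f_v <= 1.0:
            raise ValueError("f_v must be in [0, 1]")
        if v_min < 1:
            raise ValueError("v_min must be >= 1")
        vmax = self.max()
        if vmax == 0:
            return []
        counts = self.counts_dense()
        thr = max(float(v_min), f_v * vmax)
        cand = np.argwhere(counts >= thr)
        n = self.n_voxels
        out: list[LocalMaximum] = []
        for c, i, j, k in cand:
            v = counts[c, i, j, k]
            nb = counts[c,
                        max(0, i - 1):i + 2,
                        max(0, j - 1):j + 2,
                        max(0, k - 1):k + 2]
            if v >= nb.max():
                out.append(LocalMaximum(int(c), (int(i), int(j), int(k)),
                                        int(v)))
        out.sort(key=lambda m: (-m.visits, m.chart,
                                (m.index[0] * n + m.index[1]) * n + m.index[2]))
        return out[:max_results]

    def rotation_at(self, chart: int, index: Sequence[int]) -> Rotation:
        """Rotation of the centre of voxel ``index`` in ``chart``."""
        return voxel_to_rotation(chart, index, self.n_voxels)

    def to_hdf5(self, path, dataset: str = "frustum_counts") -> None:
        """Dump the counters as an HDF5 dataset of shape (4, N_v, N_v, N_v)."""
        import h5py

        with h5py.File(path, "w") as f:
            f.create_dataset(dataset, data=self.counts_dense(),
                             compression="gzip")
            f[dataset].attrs["n_voxels"] = self.n_voxels


def voxel_to_rotation(chart: int, index: Sequence[int], n_voxels: int
                      ) -> Rotation:
    """Rotation at a voxel centre (inverse chart map of the centre coords)."""
    idx = np.asarray(index, int)
    if np.any(idx < 0) or np.any(idx >= n_voxels):
        raise ValueError(f"voxel index {tuple(idx)} out of range for "
                         f"n_voxels={n_voxels}")
    coords = -1.0 + (idx + 0.5) * 2.0 / n_voxels
    return chart_unmap(chart, coords)


def trace_geodesic(geodesic: Geodesic, accumulator: FrustumAccumulator) -> int:
    """Free-function form of :meth:`FrustumAccumulator.trace`."""
    return accumulator.trace(geodesic)


def find_local_maxima(accumulator: FrustumAccumulator, v_min: int,
                      f_v: float) -> list[LocalMaximum]:
    """Free-function form of :meth:`FrustumAccumulator.local_maxima`."""
    return accumulator.local_maxima(v_min, f_v)


def voxel_angular_radius(n_voxels: int) -> float:
    """Half-diagonal of a chart voxel expressed as a rotation angle (rad).

    Used to widen matching tolerances when seeding from a voxel centre.
    """
    return 2.0 * math.sqrt(3.0) / n_voxels
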