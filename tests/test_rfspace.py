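"""Rotations, RF vectors, charts, geodesics and the voxel accumulator."""

import math

import numpy as np
import pytest

from pyfelix import (DegenerateGeodesicError, FrustumAccumulator, Geodesic,
                     RFDomainError, Rotation, chart_map, chart_unmap,
                     find_local_maxima, geodesic_from_pair, rotation_to_rf,
                     trace_geodesic, voxel_to_rotation)
from pyfelix.rfspace import voxel_angular_radius


# -- Rotation -----------------------------------------------------------

def test_quaternion_matrix_roundtrip_against_scipy():
    from scipy.spatial.transform import Rotation as SR

    rng = np.random.default_rng(1)
    for _ in range(200):
        q = rng.normal(size=4)
        r = Rotation(q)
        assert np.isclose(np.linalg.norm(r.q), 1.0, atol=1e-12)
        # scipy uses scalar-last quaternions
        m_ref = SR.from_quat(np.r_[r.q[1:], r.q[0]]).as_matrix()
        assert np.allclose(r.as_matrix(), m_ref, atol=1e-12)
        r2 = Rotation.from_matrix(m_ref)
        assert min(np.linalg.norm(r2.q - r.q),
                   np.linalg.norm(r2.q + r.q)) < 1e-9


def test_axis_angle_roundtrip():
    rng = np.random.default_rng(2)
    for _ in range(100):
        axis = rng.normal(size=3)
        axis /= np.linalg.norm(axis)
        ang = rng.uniform(1e-6, math.pi - 1e-6)
        a2, g2 = Rotation.from_axis_angle(axis, ang).axis_angle()
        assert np.isclose(g2, ang, atol=1e-12)
        assert np.allclose(a2 * np.sign(a2 @ axis), axis, atol=1e-9)


# -- RF vectors ----------------------------------------------------------

def test_rf_examples():
    assert np.allclose(rotation_to_rf(Rotation.identity()), 0.0)
    r90z = Rotation.from_axis_angle([0, 0, 1], math.pi / 2)
    assert np.allclose(rotation_to_rf(r90z), [0, 0, 1], atol=1e-12)
    r120 = Rotation.from_axis_angle([1, 1, 1], 2 * math.pi / 3)
    assert np.allclose(rotation_to_rf(r120), [1, 1, 1], atol=1e-12)


def test_rf_magnitude_is_tan_half_angle():
    rng = np.random.default_rng(3)
    for _ in range(50):
        r = Rotation(rng.normal(size=4))
        if r.angle > math.radians(179):
            continue
        assert np.isclose(np.linalg.norm(rotation_to_rf(r)),
                          math.tan(r.angle / 2), atol=1e-9)


def test_rf_diverges_at_180deg():
    r180 = Rotation.from_axis_angle([0, 0, 1], math.pi)
    with pytest.raises(RFDomainError, match="chart_map"):
        rotation_to_rf(r180)


# -- charts --------------------------------------------------------------

def test_chart_examples_and_tie_rule():
    k, c = chart_map(Rotation.identity())
    assert k == 0 and np.allclose(c, 0.0)
    k, c = chart_map(Rotation([0, 0, 0, 1.0]))
    assert k == 3 and np.allclose(c, 0.0)
    # 90 deg about z ties components 0 and 3: lowest index wins
    k, c = chart_map(Rotation.from_axis_angle([0, 0, 1], math.pi / 2))
    assert k == 0 and np.allclose(c, [0, 0, 1], atol=1e-12)


def test_chart_covering_roundtrip():
    """10^5 random rotations: one chart each, coords in the cube, exact
    round trip."""
    rng = np.random.default_rng(4)
    q = rng.normal(size=(100_000, 4))
    q /= np.linalg.norm(q, axis=1)[:, None]
    k = np.argmax(np.abs(q), axis=1)
    dom = q[np.arange(len(q)), k]
    coords = np.delete(
        q, 0, axis=1)  # placeholder, recomputed per-row below
    # vectorized chart map
    mask = np.ones_like(q, bool)
    mask[np.arange(len(q)), k] = False
    coords = (q[mask].reshape(-1, 3) / dom[:, None])
    assert np.all(np.abs(coords) <= 1.0 + 1e-12)
    # spot-check object API round trip on a subsample
    for row in rng.choice(len(q), 500, replace=False):
        rot = Rotation(q[row])
        kk, cc = chart_map(rot)
        back = chart_unmap(kk, cc)
        assert abs(abs(float(back.q @ rot.q)) - 1.0) < 1e-12


def test_chart_unmap_validates():
    with pytest.raises(ValueError):
        chart_unmap(4, np.zeros(3))


# -- geodesics -----------------------------------------------------------

def test_geodesic_example_x_to_y():
    geo = geodesic_from_pair(np.array([0, 1.0, 0]), np.array([1.0, 0, 0]))
    assert np.allclose(geo.anchor, [0, 0, 1], atol=1e-12)
    assert np.allclose(geo.direction, np.array([1, 1, 0]) / math.sqrt(2))
    rot = geo.rotation(0.0)
    assert np.allclose(rot.apply([1.0, 0, 0]), [0, 1, 0], atol=1e-12)
    assert np.isclose(rot.angle, math.pi / 2)


def test_geodesic_collinear_passes_origin():
    geo = geodesic_from_pair(np.array([2.0, 0, 0]), np.array([1.0, 0, 0]))
    assert np.allclose(geo.anchor, 0.0)
    assert np.allclose(geo.direction, [1, 0, 0])


def test_geodesic_antipodal_degenerate():
    with pytest.raises(DegenerateGeodesicError):
        geodesic_from_pair(np.array([-1.0, 0, 0]), np.array([1.0, 0, 0]))


def test_geodesic_oracle_all_points_map_h_to_g():
    """50 random pairs x 20 sampled points: rotation maps h-hat to g-hat."""
    rng = np.random.default_rng(5)
    for _ in range(50):
        g = rng.normal(size=3)
        h = rng.normal(size=3)
        geo = geodesic_from_pair(g, h)
        ghat, hhat = g / np.linalg.norm(g), h / np.linalg.norm(h)
        for t in rng.uniform(-5, 5, size=20):
            got = geo.rotation(t).apply(hhat)
            assert np.linalg.norm(got - ghat) < 1e-9


def test_geodesic_plane_is_orthonormal():
    rng = np.random.default_rng(6)
    for _ in range(20):
        geo = geodesic_from_pair(rng.normal(size=3), rng.normal(size=3))
        u, v = geo.quaternion_plane()
        assert np.isclose(u @ u, 1) and np.isclose(v @ v, 1)
        assert abs(u @ v) < 1e-12


# -- tracing -------------------------------------------------------------

def test_axis_line_hits_one_column(warm_tracer):
    """A z-axis geodesic crosses all 10 voxels of the central chart-0
    column (and the matching column of chart 3, its 180-deg partner)."""
    acc = FrustumAccumulator(10)
    geo = Geodesic(np.zeros(3), np.array([0.0, 0.0, 1.0]))
    visits = acc.trace(geo)
    c = acc.counts
    assert c[0].sum() == 10
    assert np.all(c[0][5, 5, :] == 1)
    assert c[1].sum() == 0 and c[2].sum() == 0
    assert c[3].sum() == 10
    assert visits == acc.total() == 20


def test_accumulator_conservation(warm_tracer):
    rng = np.random.default_rng(7)
    acc = FrustumAccumulator(20)
    total = 0
    for _ in range(100):
        geo = geodesic_from_pair(rng.normal(size=3), rng.normal(size=3))
        total += trace_geodesic(geo, acc)
    assert acc.total() == total == acc.traced_visits


def test_trace_pairs_matches_single_traces(warm_tracer):
    rng = np.random.default_rng(8)
    g = rng.normal(size=(50, 3))
    h = rng.normal(size=(50, 3))
    ghat = g / np.linalg.norm(g, axis=1)[:, None]
    hhat = h / np.linalg.norm(h, axis=1)[:, None]
    acc1 = FrustumAccumulator(16)
    visits = acc1.trace_pairs(ghat, hhat)
    acc2 = FrustumAccumulator(16)
    single = [trace_geodesic(geodesic_from_pair(g[i], h[i]), acc2)
              for i in range(50)]
    assert np.array_equal(visits, single)
    assert np.array_equal(acc1.counts, acc2.counts)


def test_dda_agrees_with_dense_sampling_oracle(warm_tracer):
    """Voxels from exact boundary stepping = voxels from dense point
    sampling of the quaternion circle, up to boundary-grazing cells."""
    rng = np.random.default_rng(9)
    n = 20
    for _ in range(10):
        geo = geodesic_from_pair(rng.normal(size=3), rng.normal(size=3))
        acc = FrustumAccumulator(n)
        acc.trace(geo)
        traced = {tuple(idx) for idx in np.argwhere(acc.counts_dense() > 0)}
        u, v = geo.quaternion_plane()
        phis = np.linspace(0, np.pi, 40_000, endpoint=False)
        pts = np.cos(phis)[:, None] * u + np.sin(phis)[:, None] * v
        k = np.argmax(np.abs(pts), axis=1)
        dom = pts[np.arange(len(pts)), k]
        mask = np.ones_like(pts, bool)
        mask[np.arange(len(pts)), k] = False
        coords = pts[mask].reshape(-1, 3) / dom[:, None]
        vox = np.clip(((coords + 1.0) / (2.0 / n)).astype(int), 0, n - 1)
        sampled = {(int(kk), *map(int, vv)) for kk, vv in zip(k, vox)}
        assert sampled <= traced
        # only boundary-grazing voxels may be missed by the sampler
        assert len(traced - sampled) <= max(3, int(0.1 * len(traced)))


def test_voxel_visited_at_most_once_per_geodesic(warm_tracer):
    rng = np.random.default_rng(10)
    for _ in range(20):
        geo = geodesic_from_pair(rng.normal(size=3), rng.normal(size=3))
        acc = FrustumAccumulator(12)
        acc.trace(geo)
        assert acc.max() <= 1


def test_sparse_matches_dense(warm_tracer):
    rng = np.random.default_rng(11)
    dense = FrustumAccumulator(15)
    sparse = FrustumAccumulator(15, sparse=True)
    assert sparse.sparse and not dense.sparse
    g = rng.normal(size=(30, 3))
    h = rng.normal(size=(30, 3))
    ghat = g / np.linalg.norm(g, axis=1)[:, None]
    hhat = h / np.linalg.norm(h, axis=1)[:, None]
    vd = dense.trace_pairs(ghat, hhat)
    vs = sparse.trace_pairs(ghat, hhat)
    assert np.array_equal(vd, vs)
    assert np.array_equal(dense.counts_dense(), sparse.counts_dense())


def test_sparse_selected_automatically_for_huge_grids():
    acc = FrustumAccumulator(1024, memory_limit_bytes=2 ** 30)
    assert acc.sparse


def test_accumulator_hdf5_dump(tmp_path, warm_tracer):
    import h5py

    acc = FrustumAccumulator(12)
    rng = np.random.default_rng(14)
    acc.trace_pairs(*(x / np.linalg.norm(x, axis=1)[:, None]
                      for x in (rng.normal(size=(5, 3)),
                                rng.normal(size=(5, 3)))))
    acc.to_hdf5(tmp_path / "dump.h5")
    with h5py.File(tmp_path / "dump.h5") as f:
        data = np.asarray(f["frustum_counts"])
    assert data.shape == (4, 12, 12, 12)
    assert np.array_equal(data, acc.counts_dense())


def test_antipodal_pair_skipped_with_zero_visits(warm_tracer):
    acc = FrustumAccumulator(10)
    v = acc.trace_pairs(np.array([[1.0, 0, 0]]), np.array([[-1.0, 0, 0]]))
    assert v[0] == 0 and acc.total() == 0


# -- local maxima --------------------------------------------------------

def test_local_maxima_semantics():
    acc = FrustumAccumulator(8)
    acc.counts[0, 4, 4, 4] = 10
    acc.counts[2, 1, 1, 1] = 4
    out = find_local_maxima(acc, v_min=5, f_v=0.5)
    assert [(m.chart, m.index, m.visits) for m in out] == [(0, (4, 4, 4), 10)]
    # lowering v_min does not rescue the second peak: 4 < 0.5 * 10
    out = find_local_maxima(acc, v_min=1, f_v=0.5)
    assert len(out) == 1
    # without the relative criterion both appear, sorted by visits
    out = find_local_maxima(acc, v_min=1, f_v=0.0)
    assert [(m.chart, m.visits) for m in out] == [(0, 10), (2, 4)]


def test_local_maxima_plateau_deterministic():
    acc = FrustumAccumulator(8)
    acc.counts[1, 2, 2, 2] = 7
    acc.counts[1, 2, 2, 3] = 7
    out = find_local_maxima(acc, v_min=1, f_v=0.5)
    assert [(m.chart, m.index) for m in out] == [(1, (2, 2, 2)), (1, (2, 2, 3))]


def test_empty_accumulator_has_no_maxima():
    assert find_local_maxima(FrustumAccumulator(8), 1, 0.5) == []


def test_local_maxima_input_validation():
    acc = FrustumAccumulator(8)
    with pytest.raises(ValueError):
        acc.local_maxima(1, 1.5)
    with pytest.raises(ValueError):
        acc.local_maxima(0, 0.5)


# -- voxel <-> rotation --------------------------------------------------

def test_voxel_centers():
    rot = voxel_to_rotation(0, (5, 5, 5), 11)
    assert np.allclose(rot.q, [1, 0, 0, 0], atol=1e-12)
    rot = voxel_to_rotation(3, (5, 5, 5), 11)
    assert np.isclose(rot.angle, math.pi)
    axis, _ = rot.axis_angle()
    assert np.allclose(np.abs(axis), [0, 0, 1], atol=1e-12)


def test_voxel_roundtrip_random_addresses():
    rng = np.random.default_rng(12)
    n = 17
    for _ in range(200):
        chart = int(rng.integers(4))
        idx = tuple(int(i) for i in rng.integers(0, n, 3))
        rot = voxel_to_rotation(chart, idx, n)
        k, c = chart_map(rot)
        assert k == chart
        back = tuple(np.clip(((c + 1.0) / (2.0 / n)).astype(int), 0, n - 1))
        assert back == idx


def test_voxel_out_of_range():
    with pytest.raises(ValueError):
        voxel_to_rotation(0, (0, 0, 99), 10)


def test_voxel_angular_radius_scale():
    # the seed-error bound is the voxel half-diagonal expressed as an
    # angle: sqrt(3)/2 times the angular spacing of axis neighbours
    a = voxel_to_rotation(0, (150, 150, 150), 300)
    b = voxel_to_rotation(0, (151, 150, 150), 300)
    delta = (a.inv() * b).angle
    assert np.isclose(voxel_angular_radius(300), math.sqrt(3) / 2 * delta,
                      rtol=0.01)
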