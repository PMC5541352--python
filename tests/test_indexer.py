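"""Candidate pairing, matching, refinement, acceptance and full indexing."""

import math

import numpy as np
import pytest

from pyfelix import (FelixParams, FrustumAccumulator, IndexingSolution,
                     Rotation, UnderdeterminedError, accept_solutions,
                     accumulate, build_candidate_pairs, generate_families,
                     index_image, match_gvectors, match_to_truth,
                     misorientation, predict_spots, refine_orientation,
                     reflection_list, simulate_image)
from pyfelix.geometry import peaks_to_gvectors
from pyfelix.indexer import (angular_deviation_bound,
                             gvector_magnitude_tolerance)


def toy_params(**kw):
    base = dict(n_voxels=50, v_min=2, f_v=0.5, sigma_2theta_deg=0.3,
                sigma_eta_deg=0.3, d_min_nm=0.45)
    base.update(kw)
    return FelixParams(**base)


# -- tolerance formulas --------------------------------------------------

def test_magnitude_tolerance_follows_bragg_derivative():
    p = toy_params(sigma_scale=1.0)
    theta = math.radians(10.0)
    expect = (math.radians(0.3) / 2) / math.tan(theta)
    assert np.isclose(gvector_magnitude_tolerance(theta, p), expect)
    # the scale factor acts linearly
    p2 = toy_params(sigma_scale=0.2)
    assert np.isclose(gvector_magnitude_tolerance(theta, p2), 0.2 * expect)


def test_angular_bound_limits():
    p = toy_params()
    # at 2theta -> 0 only the polar term remains
    assert np.isclose(angular_deviation_bound(0.0, p), math.radians(0.3))
    b90 = angular_deviation_bound(math.pi / 2, p)
    assert np.isclose(b90, math.radians(0.3) * math.sqrt(2))


# -- candidate pairing ---------------------------------------------------

def test_pairing_exact_magnitude_always_accepted(toy_cubic):
    fams = generate_families(toy_cubic, 0.45)
    p = toy_params()
    g = fams[0].qvecs[:1]  # |g| == |h| exactly
    pairs = build_candidate_pairs(g, fams, p, wavelength_nm=0.1)
    assert any(c.family_index == 0 and c.mismatch == 0.0 for c in pairs)


def test_pairing_relative_window_semantics(toy_cubic):
    fams = generate_families(toy_cubic, 0.45)
    # choose sigma_scale so the relative window is exactly 5% for this g
    g = fams[0].qvecs[:1] * 1.10
    lam = 0.1
    theta = math.asin(np.linalg.norm(g) * lam / 2)
    scale = 0.05 * math.tan(theta) / (math.radians(0.3) / 2)
    p = toy_params(sigma_scale=scale)
    pairs = build_candidate_pairs(g, fams, p, wavelength_nm=lam)
    assert not any(c.family_index == 0 for c in pairs)  # 10% > 5%


def test_pairing_matches_bruteforce_oracle(toy_cubic):
    fams = generate_families(toy_cubic, 0.45)
    p = toy_params(sigma_scale=2.0)
    rng = np.random.default_rng(0)
    g = rng.normal(size=(3, 3))
    g *= (rng.uniform(1.0, 2.2, 3) / np.linalg.norm(g, axis=1))[:, None]
    lam = 0.1
    pairs = build_candidate_pairs(g, fams, p, wavelength_nm=lam)
    got = {(c.g_index, c.family_index) for c in pairs}
    expect = set()
    for i in range(len(g)):
        gm = np.linalg.norm(g[i])
        tol = gvector_magnitude_tolerance(math.asin(gm * lam / 2), p)
        for j, f in enumerate(fams):
            if abs(gm - f.magnitude) / f.magnitude <= tol:
                expect.add((i, j))
    assert got == expect


def test_empty_pairs_empty_accumulator(toy_cubic, warm_tracer):
    acc = FrustumAccumulator(20)
    res = accumulate([], np.zeros((0, 3)), [], acc)
    assert res.n_geodesics == 0 and acc.total() == 0


def test_single_pair_conservation(toy_cubic, warm_tracer):
    fams = generate_families(toy_cubic, 0.9)
    p = toy_params(d_min_nm=0.9)
    g = fams[0].qvecs[:1]
    pairs = build_candidate_pairs(g, fams, p, 0.1)[:1]
    acc = FrustumAccumulator(30)
    res = accumulate(pairs, g, fams, acc)
    assert res.n_geodesics == fams[0].multiplicity
    assert acc.total() == res.visits.sum()


# -- matching ------------------------------------------------------------

@pytest.fixture(scope="module")
def lyso_exact(lysozyme):
    """Exact observed g vectors of a known lysozyme orientation."""
    rot = Rotation.random(np.random.default_rng(21))
    spots = predict_spots(rot, lysozyme.cell, lysozyme.geometry,
                          lysozyme.d_min_nm, lysozyme.r_profile_inv_nm)
    g = peaks_to_gvectors(spots.xy_m, lysozyme.geometry)
    return rot, spots, g


def test_match_exact_orientation_recovers_all_hkl(lysozyme, lyso_exact):
    rot, spots, g = lyso_exact
    p = lysozyme.felix_params()
    refl = reflection_list(lysozyme.cell, p.d_min_nm)
    m = match_gvectors(rot, g, refl, p, lysozyme.geometry.wavelength_nm)
    assert len(m) == len(g)
    # assignments reproduce the generator's ground-truth Miller indices
    order = np.argsort(m.g_index)
    assert np.array_equal(m.hkl[order], spots.hkl)
    assert np.all(m.deviation_rad < 1e-6)


def test_match_rejects_far_orientation(lysozyme, lyso_exact):
    rot, spots, g = lyso_exact
    p = lysozyme.felix_params()
    refl = reflection_list(lysozyme.cell, p.d_min_nm)
    far = rot * Rotation.from_axis_angle([1, 0, 0], math.radians(5.0))
    m = match_gvectors(far, g, refl, p, lysozyme.geometry.wavelength_nm)
    # 5 deg away with sub-degree bounds: essentially nothing matches
    assert len(m) < 0.05 * len(g)


def test_match_assignments_are_unique(lysozyme, lyso_exact):
    rot, spots, g = lyso_exact
    p = lysozyme.felix_params()
    refl = reflection_list(lysozyme.cell, p.d_min_nm)
    m = match_gvectors(rot, g, refl, p, lysozyme.geometry.wavelength_nm)
    assert len(np.unique(m.g_index)) == len(m)
    assert len({tuple(h) for h in m.hkl}) == len(m)
    assert np.all(m.g_index < len(g))


# -- refinement ----------------------------------------------------------

def test_refine_recovers_true_orientation(lysozyme, lyso_exact):
    """Exact reciprocal points + 1-deg perturbed seed -> <0.01 deg error."""
    rot, spots, g = lyso_exact
    p = lysozyme.felix_params()
    refl = reflection_list(lysozyme.cell, p.d_min_nm)
    seed = rot * Rotation.from_axis_angle([0, 1, 0], math.radians(1.0))
    # observations exactly on the rotated lattice (no partiality offset)
    m = match_gvectors(seed, spots.q, refl, p,
                       lysozyme.geometry.wavelength_nm,
                       extra_tol_rad=math.radians(1.5))
    refined, kept = refine_orientation(seed, m, p)
    err = misorientation(refined, rot,
                         lysozyme.cell.laue_operators()).angle_deg
    assert err < 0.01
    assert len(kept) >= 0.9 * len(m)


def test_refine_drops_planted_outlier(lysozyme, lyso_exact):
    rot, spots, g = lyso_exact
    p = lysozyme.felix_params()
    refl = reflection_list(lysozyme.cell, p.d_min_nm)
    m = match_gvectors(rot, g, refl, p, lysozyme.geometry.wavelength_nm)
    m = m.select(np.arange(len(m)) < 20)
    # corrupt one observed direction by 10 degrees
    bad = m.g_obs.copy()
    c, s = math.cos(math.radians(10)), math.sin(math.radians(10))
    rotz = np.array([[c, -s, 0], [s, c, 0], [0, 0, 1]])
    bad[7] = rotz @ bad[7]
    m.g_obs = bad
    refined, kept = refine_orientation(rot, m, p)
    assert len(kept) == 19
    assert m.g_index[7] not in kept.g_index
    err = misorientation(refined, rot,
                         lysozyme.cell.laue_operators()).angle_deg
    assert err < 0.05


def test_refine_underdetermined_cases(lysozyme, lyso_exact):
    rot, spots, g = lyso_exact
    p = lysozyme.felix_params()
    refl = reflection_list(lysozyme.cell, p.d_min_nm)
    m = match_gvectors(rot, g, refl, p, lysozyme.geometry.wavelength_nm)
    with pytest.raises(UnderdeterminedError):
        refine_orientation(rot, m.select(np.arange(len(m)) < 1), p)
    # collinear matches: duplicate one row direction
    two = m.select(np.arange(len(m)) < 2)
    two.q_ref[1] = 2.0 * two.q_ref[0]
    two.g_obs[1] = 2.0 * two.g_obs[0]
    with pytest.raises(UnderdeterminedError, match="collinear"):
        refine_orientation(rot, two, p)


# -- acceptance ----------------------------------------------------------

def _draft(n, completeness, g_indices, seed_visits=50):
    return IndexingSolution(Rotation.identity(), np.asarray(g_indices),
                            np.zeros((len(g_indices), 3), int),
                            np.zeros(len(g_indices)), n, completeness,
                            seed_visits)


def test_accept_filters_and_dedup():
    p = toy_params(n_min=10, c_min=0.5, u_max=0.5)
    a = _draft(20, 0.9, range(20))
    twin = _draft(20, 0.9, range(20))
    low_c = _draft(20, 0.4, range(100, 120))
    few = _draft(5, 0.9, range(200, 205))
    partial = _draft(12, 0.8, range(12, 24))   # 8/12 overlap with a -> drop
    disjoint = _draft(15, 0.8, range(300, 315))
    out = accept_solutions([a, twin, low_c, few, partial, disjoint], p)
    assert out == [a, disjoint] or out == [twin, disjoint]
    assert len(out) == 2


def test_accept_monotone_in_n_min_and_c_min():
    """Loosening c_min or N_min never decreases the accepted count."""
    rng = np.random.default_rng(13)
    drafts = [_draft(int(rng.integers(2, 40)), float(rng.uniform(0, 1)),
                     rng.choice(500, size=40, replace=False))
              for _ in range(30)]
    grid = [(20, 0.8), (15, 0.6), (10, 0.5), (5, 0.25), (2, 0.05)]
    counts = [len(accept_solutions(drafts, toy_params(n_min=n, c_min=c)))
              for n, c in grid]
    assert counts == sorted(counts)


# -- full pipeline -------------------------------------------------------

def test_empty_image_gives_no_solutions(lysozyme):
    p = lysozyme.felix_params()
    assert index_image(np.zeros((0, 2)), lysozyme.cell, lysozyme.geometry,
                       p) == []


def test_single_crystal_lysozyme_recovery(lysozyme, lysozyme_single_image,
                                          warm_tracer):
    """One noise-free crystal is found with sub-0.2-deg accuracy."""
    img = lysozyme_single_image
    sols = index_image(img.peaks_xy, lysozyme.cell, lysozyme.geometry,
                       lysozyme.felix_params())
    assert len(sols) == 1
    err = misorientation(sols[0].rotation, img.orientations[0],
                         lysozyme.cell.laue_operators()).angle_deg
    assert err < 0.2
    assert sols[0].completeness > 0.8
    assert sols[0].n_matched >= 0.9 * img.n_peaks


def test_indexing_is_deterministic(lysozyme, lysozyme_single_image,
                                   warm_tracer):
    img = lysozyme_single_image
    p = lysozyme.felix_params()
    a = index_image(img.peaks_xy, lysozyme.cell, lysozyme.geometry, p)
    b = index_image(img.peaks_xy, lysozyme.cell, lysozyme.geometry, p)
    assert len(a) == len(b)
    for sa, sb in zip(a, b):
        assert np.array_equal(sa.rotation.q, sb.rotation.q)
        assert np.array_equal(sa.g_index, sb.g_index)
        assert np.array_equal(sa.hkl, sb.hkl)
        assert sa.completeness == sb.completeness


def test_no_phantom_assignments(lysozyme, lysozyme_single_image, warm_tracer):
    img = lysozyme_single_image
    sols = index_image(img.peaks_xy, lysozyme.cell, lysozyme.geometry,
                       lysozyme.felix_params())
    for s in sols:
        assert np.all(s.g_index >= 0) and np.all(s.g_index < img.n_peaks)
        assert len(np.unique(s.g_index)) == s.n_matched


def test_five_crystal_image_recovers_all(rho_g6, warm_tracer):
    """Five cubic crystals with (almost surely) disjoint spot sets."""
    rng = np.random.default_rng(31)
    img = simulate_image(5, rho_g6, rng)
    sols = index_image(img.peaks_xy, rho_g6.cell, rho_g6.geometry,
                       rho_g6.felix_params())
    rep = match_to_truth([[s.rotation for s in sols]], [img.orientations],
                         1.0, rho_g6.cell.laue_operators())
    assert rep.n_found == 5 and rep.n_correct == 5


def test_five_crystal_regression_statistic(rho_g6, warm_tracer):
    """>= 4 of 5 crystals recovered in nearly all seeded trials."""
    acc = FrustumAccumulator(rho_g6.felix_params().n_voxels)
    ops = rho_g6.cell.laue_operators()
    good = 0
    n_trials = 6
    for seed in range(n_trials):
        rng = np.random.default_rng(1000 + seed)
        img = simulate_image(5, rho_g6, rng)
        sols = index_image(img.peaks_xy, rho_g6.cell, rho_g6.geometry,
                           rho_g6.felix_params(), accumulator=acc)
        rep = match_to_truth([[s.rotation for s in sols]],
                             [img.orientations], 1.0, ops)
        if rep.n_correct >= 4:
            good += 1
    assert good >= n_trials - 1
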