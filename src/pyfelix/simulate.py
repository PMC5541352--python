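"""Synthetic multi-crystal snapshot generator with ground truth.

Each simulated image is the union of the predicted Bragg spots of N
randomly (Haar-uniformly) oriented crystals of a given cell, placed on a
flat detector with a hard spherical partiality model, optionally perturbed
by positional noise, random peak loss and spurious peaks.  Ground-truth
orientations and per-spot provenance are recorded before noise is applied.

Three named scenarios reproduce typical serial-crystallography study
conditions across the symmetry ladder:

* ``rho-g6``  — cubic zeolite RHO-G6 (a = 6.39 nm, Laue m-3m, I-centred,
  9000 eV, 0.090 m, 2.0 A cutoff);
* ``lysozyme`` — tetragonal hen egg-white lysozyme (7.90, 7.90, 3.80 nm,
  4/mmm, 9340 eV, 0.090 m, 3.0 A);
* ``at1r``    — monoclinic AT1R GPCR (7.28, 4.10, 16.77 nm, beta = 99.4,
  2/m, C-centred, 7800 eV, 0.130 m, 3.0 A).

Each preset also carries the indexing parameters optimal for its symmetry
(N_v = 300/400/600, f_V = 0.7/0.5/0.3, sigma_2theta = sigma_eta =
0.3/0.15/0.15 deg).  Preset simulations are noise-free; the dataclass
default for custom scenarios is 1 pixel of positional noise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import NamedTuple

import numpy as np
from scipy.optimize import minimize_scalar
from scipy.spatial import cKDTree

from .cells import UnitCell
from .geometry import BeamGeometry, predict_spots
from .indexer import FelixParams
from .rfspace import Rotation


class SimulationError(ValueError):
    pass


@dataclass(frozen=True)
class SimulationScenario:
    """Crystal + beam geometry + noise model + indexing preset."""

    name: str
    cell: UnitCell
    geometry: BeamGeometry
    d_min_nm: float
    r_profile_inv_nm: float = 0.0086
    pos_sigma_px: float = 1.0     # positional noise, detector pixels
    miss_rate: float = 0.0        # probability of losing a true peak
    spurious_rate: float = 0.0    # expected spurious peaks per image
    merge_radius_px: float = 1.0  # peaks closer than this are merged
    felix: FelixParams | None = None

    def felix_params(self, **overrides) -> FelixParams:
        if self.felix is None:
            raise SimulationError(f"scenario {self.name!r} has no preset "
                                  "indexing parameters")
        return replace(self.felix, **overrides) if overrides else self.felix


def _preset(name: str, cell: UnitCell, energy_ev: float, distance_m: float,
            d_min_nm: float, n_voxels: int, f_v: float,
            sigma_deg: float) -> SimulationScenario:
    geom = BeamGeometry.from_energy(energy_ev, distance_m)
    params = FelixParams(
        n_voxels=n_voxels, v_min=10, f_v=f_v,
        sigma_2theta_deg=sigma_deg, sigma_eta_deg=sigma_deg,
        d_min_nm=d_min_nm,
    )
    return SimulationScenario(name, cell, geom, d_min_nm,
                              pos_sigma_px=0.0, felix=params)


def scenario_rho_g6() -> SimulationScenario:
    cell = UnitCell(6.39, 6.39, 6.39, laue_class="m-3m", centering="I")
    return _preset("rho-g6", cell, 9000.0, 0.090, 0.20, 300, 0.7, 0.3)


def scenario_lysozyme() -> SimulationScenario:
    cell = UnitCell(7.90, 7.90, 3.80, laue_class="4/mmm", centering="P")
    return _preset("lysozyme", cell, 9340.0, 0.090, 0.30, 400, 0.5, 0.15)


def scenario_at1r() -> SimulationScenario:
    cell = UnitCell(7.28, 4.10, 16.77, beta=99.4, laue_class="2/m",
                    centering="C")
    return _preset("at1r", cell, 7800.0, 0.130, 0.30, 600, 0.3, 0.15)


SCENARIOS = {
    "rho-g6": scenario_rho_g6,
    "lysozyme": scenario_lysozyme,
    "at1r": scenario_at1r,
}


def get_scenario(name: str) -> SimulationScenario:
    try:
        return SCENARIOS[name]()
    except KeyError:
        raise SimulationError(
            f"unknown scenario {name!r}; available: {', '.join(SCENARIOS)}"
        ) from None


def random_orientation(rng: np.random.Generator) -> Rotation:
    """Haar-uniform random rotation (normalized Gaussian quaternion)."""
    return Rotation.random(rng)


@dataclass
class SyntheticImage:
    """Peak list plus the ground truth that generated it.

    ``provenance[i]`` is a tuple of ``(crystal_index, (h, k, l))`` entries
    for peak i — empty for spurious peaks, more than one entry when spots
    of different crystals merged within one pixel.
    """

    peaks_xy: np.ndarray                       # (n, 2) metres
    orientations: list[Rotation]
    provenance: list[tuple[tuple[int, tuple[int, int, int]], ...]]

    @property
    def n_peaks(self) -> int:
        return len(self.peaks_xy)

    @property
    def n_crystals(self) -> int:
        return len(self.orientations)


def simulate_image(n_crystals: int, scenario: SimulationScenario,
                   rng: np.random.Generator) -> SyntheticImage:
    """Simulate one snapshot containing ``n_crystals`` random crystals."""
    if n_crystals < 0:
        raise SimulationError("n_crystals must be >= 0")
    orientations = [random_orientation(rng) for _ in range(n_crystals)]
    xy_parts: list[np.ndarray] = []
    prov: list[tuple[tuple[int, tuple[int, int, int]], ...]] = []
    for ci, rot in enumerate(orientations):
        spots = predict_spots(rot, scenario.cell, scenario.geometry,
                              scenario.d_min_nm, scenario.r_profile_inv_nm)
        xy_parts.append(spots.xy_m)
        prov.extend(((ci, tuple(int(x) for x in hkl)),)
                    for hkl in spots.hkl)
    xy = np.concatenate(xy_parts) if xy_parts else np.zeros((0, 2))

    # peak loss
    if scenario.miss_rate > 0 and len(xy):
        keep = rng.random(len(xy)) >= scenario.miss_rate
        xy = xy[keep]
        prov = [p for p, k in zip(prov, keep) if k]
    # positional noise
    if scenario.pos_sigma_px > 0 and len(xy):
        xy = xy + rng.normal(
            scale=scenario.pos_sigma_px * scenario.geometry.pixel_size_m,
            size=xy.shape)
    # spurious peaks, uniform on the panel
    if scenario.spurious_rate > 0:
        n_sp = rng.poisson(scenario.spurious_rate)
        if n_sp:
            he = scenario.geometry.half_extent_m
            sp = rng.uniform(-he, he, size=(n_sp, 2))
            xy = np.concatenate([xy, sp]) if len(xy) else sp
            prov.extend(() for _ in range(n_sp))
    # merge peaks closer than merge_radius_px
    if len(xy) > 1 and scenario.merge_radius_px > 0:
        xy, prov = _merge_close_peaks(
            xy, prov, scenario.merge_radius_px * scenario.geometry.pixel_size_m)
    return SyntheticImage(xy, orientations, prov)


def _merge_close_peaks(xy, prov, radius_m):
    tree = cKDTree(xy)
    pairs = tree.query_pairs(radius_m, output_type="ndarray")
    if len(pairs) == 0:
        return xy, prov
    parent = np.arange(len(xy))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i, j in pairs:
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[max(ri, rj)] = min(ri, rj)
    roots = np.array([find(i) for i in range(len(xy))])
    out_xy, out_prov = [], []
    for r in np.unique(roots):
        sel = roots == r
        out_xy.append(xy[sel].mean(axis=0))
        merged: list = []
        for p in (prov[i] for i in np.nonzero(sel)[0]):
            merged.extend(p)
        out_prov.append(tuple(merged))
    return np.array(out_xy), out_prov


def poisson_crystal_counts(mean_crystals: float, n_images: int,
                           rng: np.random.Generator) -> np.ndarray:
    """Per-image crystal counts under random (Poisson) crystal arrival."""
    if mean_crystals < 0:
        raise SimulationError("mean_crystals must be >= 0")
    return rng.poisson(mean_crystals, size=n_images)


def poisson_image_ensemble(mean_crystals: float, n_images: int,
                           scenario: SimulationScenario,
                           rng: np.random.Generator) -> list[SyntheticImage]:
    """Simulate an ensemble with Poisson-distributed crystals per image."""
    counts = poisson_crystal_counts(mean_crystals, n_images, rng)
    return [simulate_image(int(c), scenario, rng) for c in counts]


class PoissonExpectations(NamedTuple):
    one_crystal_fraction: float
    hit_fraction: float
    multi_crystal_fraction: float


def poisson_expectations(mean_crystals: float) -> PoissonExpectations:
    """Closed-form image-class fractions under Poisson crystal arrival.

    With mean lambda: P(exactly one) = lambda e^-lambda, P(at least one,
    the hit fraction) = 1 - e^-lambda, P(more than one) = 1 - e^-lambda -
    lambda e^-lambda.
    """
    lam = float(mean_crystals)
    if lam < 0:
        raise SimulationError("mean_crystals must be >= 0")
    e = math.exp(-lam)
    return PoissonExpectations(lam * e, 1.0 - e, 1.0 - e - lam * e)


def max_one_crystal_fraction() -> tuple[float, PoissonExpectations]:
    """Poisson mean maximizing the fraction of exactly-one-crystal images.

    Returns (lambda*, expectations at lambda*); the maximum single-crystal
    fraction is e^-1 = 36.8%, reached when the hit fraction is 63.2%.
    """
    res = minimize_scalar(
        lambda lam: -poisson_expectations(lam).one_crystal_fraction,
        bounds=(1e-6, 10.0), method="bounded",
        options={"xatol": 1e-10},
    )
    lam = float(res.x)
    return lam, poisson_expectations(lam)
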