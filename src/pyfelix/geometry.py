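"""Detector <-> reciprocal-space mapping and Ewald-sphere spot prediction.

Laboratory frame: the X-ray beam travels along +x; the flat detector sits
perpendicular to the beam at distance L.  A detector peak is given in metres
relative to the beam centre, with its first coordinate along lab +y and its
second along lab +z.  The azimuth eta is measured from +y toward +z, so a
peak at (p, 0) has eta = 0.

A scattering vector ("g vector", nm^-1) is g = k_out - k_in with
|k_in| = |k_out| = 1/lambda, which puts every observed g on the Ewald
sphere: |g + k_in| = 1/lambda.  Its magnitude obeys Bragg's law
|g| = 2 sin(theta) / lambda = 1/d.

Spot prediction uses a hard spherical profile: a reciprocal-lattice point
q = U B hkl is recorded when its excitation error
| |q + k_in| - 1/lambda | is at most the profile radius r, and the outgoing
ray lands on the finite detector.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .cells import UnitCell, reflection_list

#: h*c in eV*nm, for photon energy <-> wavelength conversion.
HC_EV_NM = 1239.8419843320026

#: Profile radius (nm^-1) used throughout unless overridden: the value that
#: works well for snapshot lysozyme data and is adopted as package default.
DEFAULT_PROFILE_RADIUS_INV_NM = 0.0086


class GeometryError(ValueError):
    """Undefined detector mapping (e.g. peak exactly at the beam centre)."""


@dataclass(frozen=True)
class BeamGeometry:
    """Monochromatic beam plus a single flat detector panel.

    Parameters
    ----------
    wavelength_nm:
        X-ray wavelength (nm).
    distance_m:
        Sample-to-detector distance L (m).
    pixel_size_m:
        Edge of a square pixel (m); used for noise scales and peak merging.
    half_extent_m:
        Half-width of the square sensitive area (m); rays outside are
        flagged not recordable.
    """

    wavelength_nm: float
    distance_m: float
    pixel_size_m: float = 110e-6
    half_extent_m: float = 0.0955

    def __post_init__(self) -> None:
        if not self.wavelength_nm > 0:
            raise GeometryError("wavelength must be > 0")
        if not self.distance_m > 0:
            raise GeometryError("detector distance must be > 0")

    @classmethod
    def from_energy(cls, energy_ev: float, distance_m: float,
                    **kw) -> "BeamGeometry":
        return cls(HC_EV_NM / energy_ev, distance_m, **kw)

    @property
    def k_in(self) -> np.ndarray:
        """Incident wavevector (1/lambda, 0, 0) in nm^-1."""
        return np.array([1.0 / self.wavelength_nm, 0.0, 0.0])


@dataclass(frozen=True)
class GVector:
    """Observed scattering vector with derived Bragg angles."""

    vector: np.ndarray       # (3,) nm^-1, lab frame
    magnitude: float         # nm^-1, = 2 sin(theta)/lambda
    two_theta: float         # rad, in (0, pi)
    eta: float               # rad, in [0, 2*pi)


def peaks_to_gvectors(xy_m: np.ndarray, geom: BeamGeometry) -> np.ndarray:
    """Vectorized detector-position -> g-vector map; returns (n, 3) nm^-1."""
    xy = np.atleast_2d(np.asarray(xy_m, float))
    if not np.all(np.isfinite(xy)):
        raise GeometryError("non-finite peak coordinates")
    r = np.linalg.norm(xy, axis=1)
    if np.any(r == 0):
        raise GeometryError("peak at the beam centre: eta undefined")
    dirs = np.column_stack([np.full(len(xy), geom.distance_m),
                            xy[:, 0], xy[:, 1]])
    k = 1.0 / geom.wavelength_nm
    k_out = k * dirs / np.linalg.norm(dirs, axis=1)[:, None]
    return k_out - geom.k_in


def peak_to_gvector(xy_m, geom: BeamGeometry) -> GVector:
    """Map one detector peak (metres from beam centre) to a GVector."""
    g = peaks_to_gvectors(np.asarray(xy_m, float)[None, :], geom)[0]
    mag = float(np.linalg.norm(g))
    two_theta = math.atan2(math.hypot(xy_m[0], xy_m[1]), geom.distance_m)
    eta = math.atan2(xy_m[1], xy_m[0]) % (2 * math.pi)
    return GVector(g, mag, two_theta, eta)


def gvectors_to_detector(g: np.ndarray, geom: BeamGeometry
                         ) -> tuple[np.ndarray, np.ndarray]:
    """Intersect outgoing rays with the detector plane.

    Returns ``(xy_m, recordable)``; positions are NaN where the ray is
    backscattered or misses the panel (``recordable`` False there).
    """
    g = np.atleast_2d(np.asarray(g, float))
    k_out = g + geom.k_in
    with np.errstate(divide="ignore", invalid="ignore"):
        xy = geom.distance_m * k_out[:, 1:] / k_out[:, :1]
    forward = k_out[:, 0] > 0
    on_panel = np.all(np.abs(xy) <= geom.half_extent_m, axis=1)
    recordable = forward & on_panel & np.all(np.isfinite(xy), axis=1)
    xy = np.where(recordable[:, None], xy, np.nan)
    return xy, recordable


def gvector_to_detector(g, geom: BeamGeometry) -> tuple[np.ndarray, bool]:
    """Single-vector convenience wrapper around :func:`gvectors_to_detector`."""
    vec = g.vector if isinstance(g, GVector) else np.asarray(g, float)
    xy, rec = gvectors_to_detector(vec[None, :], geom)
    return xy[0], bool(rec[0])


def bragg_theta(magnitude: np.ndarray, wavelength_nm: float) -> np.ndarray:
    """Bragg angle theta (rad) from |g| = 2 sin(theta)/lambda."""
    s = np.clip(np.asarray(magnitude, float) * wavelength_nm / 2.0, 0.0, 1.0)
    return np.arcsin(s)


@dataclass(frozen=True)
class SpotPrediction:
    """Reflections excited for one orientation, with detector positions."""

    hkl: np.ndarray          # (n, 3) int
    q: np.ndarray            # (n, 3) reciprocal points U B hkl, nm^-1
    xy_m: np.ndarray         # (n, 2) detector positions
    excitation: np.ndarray   # (n,) | |q+k_in| - 1/lambda |, nm^-1

    def __len__(self) -> int:
        return len(self.hkl)


def excitation_errors(q: np.ndarray, geom: BeamGeometry) -> np.ndarray:
    """Distance of reciprocal points from the Ewald sphere (nm^-1)."""
    k = 1.0 / geom.wavelength_nm
    return np.abs(np.linalg.norm(q + geom.k_in, axis=1) - k)


def predict_spots(orientation, cell: UnitCell, geom: BeamGeometry,
                  d_min_nm: float,
                  r_profile_inv_nm: float = DEFAULT_PROFILE_RADIUS_INV_NM
                  ) -> SpotPrediction:
    """Predict all recordable Bragg spots for one crystal orientation.

    ``orientation`` is a 3x3 rotation matrix or an object with
    ``as_matrix()``.  A reflection is kept when its excitation error is at
    most ``r_profile_inv_nm`` and the outgoing ray hits the detector.
    Output is sorted by (h, k, l).
    """
    if r_profile_inv_nm < 0:
        raise GeometryError("profile radius must be >= 0")
    u = orientation.as_matrix() if hasattr(orientation, "as_matrix") \
        else np.asarray(orientation, float)
    hkl, q0 = reflection_list(cell, d_min_nm)
    q = q0 @ u.T
    exc = excitation_errors(q, geom)
    near = exc <= r_profile_inv_nm
    xy, rec = gvectors_to_detector(q[near], geom)
    keep = rec
    return SpotPrediction(hkl[near][keep], q[near][keep], xy[keep],
                          exc[near][keep])
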