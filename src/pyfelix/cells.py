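"""Unit-cell algebra, Laue point groups and reflection-family generation.

Conventions
-----------
* Cell lengths in nanometres, angles in degrees.
* The direct basis matrix ``A`` has the cell vectors **a**, **b**, **c** as
  columns, with **a** along Cartesian x and **b** in the xy plane.  For the
  monoclinic setting (unique axis b) this puts the two-fold axis along y.
* The reciprocal basis ``B = inv(A).T`` uses the crystallographic
  (2*pi-free) convention ``a* . a = 1``, so ``|B @ (h,k,l)| = 1/d_hkl`` and
  ``det(B) = 1/V``.
* Only the proper-rotation subgroup of a Laue class is generated; lattice
  centering is applied as a reflection-condition filter (h+k+l even for I,
  h+k even for C, ...), which is all that snapshot spot prediction needs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Iterable

import numpy as np


class LatticeError(ValueError):
    """Invalid cell, symmetry symbol or resolution request."""


#: Laue classes with their proper-rotation generators (integer Cartesian
#: matrices valid in the conventional setting described in the module docs).
_GENERATORS: dict[str, list[tuple[tuple[int, ...], ...]]] = {
    "-1": [],
    # two-fold about b (unique axis b, beta != 90)
    "2/m": [((-1, 0, 0), (0, 1, 0), (0, 0, -1))],
    "mmm": [((1, 0, 0), (0, -1, 0), (0, 0, -1)),
            ((-1, 0, 0), (0, -1, 0), (0, 0, 1))],
    # 4-fold about c, 2-fold about a
    "4/mmm": [((0, -1, 0), (1, 0, 0), (0, 0, 1)),
              ((1, 0, 0), (0, -1, 0), (0, 0, -1))],
    # 4-fold about c, 3-fold about the body diagonal
    "m-3m": [((0, -1, 0), (1, 0, 0), (0, 0, 1)),
             ((0, 0, 1), (1, 0, 0), (0, 1, 0))],
}

SUPPORTED_LAUE_CLASSES = tuple(_GENERATORS)

_CENTERING_RULES = {
    "P": lambda h, k, l: np.ones_like(h, dtype=bool),
    "I": lambda h, k, l: (h + k + l) % 2 == 0,
    "C": lambda h, k, l: (h + k) % 2 == 0,
    "A": lambda h, k, l: (k + l) % 2 == 0,
    "B": lambda h, k, l: (h + l) % 2 == 0,
    "F": lambda h, k, l: ((h % 2 == k % 2) & (k % 2 == l % 2)),
}


def laue_operators(laue_class: str) -> list[np.ndarray]:
    """Proper-rotation subgroup of a Laue class as 3x3 Cartesian matrices.

    The group is built by brute-force closure of the generators; the result
    always contains the identity and is closed under multiplication and
    inversion.
    """
    if laue_class not in _GENERATORS:
        raise LatticeError(
            f"unsupported Laue class {laue_class!r}; supported: "
            + ", ".join(SUPPORTED_LAUE_CLASSES)
        )
    gens = [np.array(g, dtype=np.int64) for g in _GENERATORS[laue_class]]
    eye = np.eye(3, dtype=np.int64)
    group = {tuple(eye.ravel()): eye}
    frontier = [eye]
    while frontier:
        nxt = []
        for m in frontier:
            for g in gens:
                prod = g @ m
                key = tuple(prod.ravel())
                if key not in group:
                    group[key] = prod
                    nxt.append(prod)
        frontier = nxt
    ops = [m.astype(float) for m in group.values()]
    ops.sort(key=lambda m: tuple(m.ravel()))
    return ops


@dataclass(frozen=True)
class UnitCell:
    """Crystal unit cell with Laue symmetry and lattice centering.

    Lengths in nm, angles in degrees.
    """

    a: float
    b: float
    c: float
    alpha: float = 90.0
    beta: float = 90.0
    gamma: float = 90.0
    laue_class: str = "-1"
    centering: str = "P"

    def __post_init__(self) -> None:
        for name in ("a", "b", "c"):
            if not getattr(self, name) > 0:
                raise LatticeError(f"cell length {name} must be > 0")
        for name in ("alpha", "beta", "gamma"):
            ang = getattr(self, name)
            if not 0.0 < ang < 180.0:
                raise LatticeError(f"cell angle {name} must be in (0, 180)")
        if self.laue_class not in _GENERATORS:
            raise LatticeError(
                f"unsupported Laue class {self.laue_class!r}; supported: "
                + ", ".join(SUPPORTED_LAUE_CLASSES)
            )
        if self.centering not in _CENTERING_RULES:
            raise LatticeError(f"unsupported centering {self.centering!r}")
        if not self.volume_nm3 > 0:
            raise LatticeError("degenerate cell: volume <= 0")

    @property
    def direct_matrix(self) -> np.ndarray:
        """3x3 matrix with the cell vectors a, b, c as columns (nm)."""
        ca, cb, cg = (math.cos(math.radians(x))
                      for x in (self.alpha, self.beta, self.gamma))
        sg = math.sin(math.radians(self.gamma))
        v = math.sqrt(max(0.0, 1 - ca * ca - cb * cb - cg * cg
                          + 2 * ca * cb * cg))
        return np.array([
            [self.a, self.b * cg, self.c * cb],
            [0.0, self.b * sg, self.c * (ca - cb * cg) / sg],
            [0.0, 0.0, self.c * v / sg],
        ])

    @property
    def volume_nm3(self) -> float:
        return float(np.linalg.det(self.direct_matrix))

    def laue_operators(self) -> list[np.ndarray]:
        return laue_operators(self.laue_class)


@dataclass(frozen=True)
class ReciprocalBasis:
    """Reciprocal basis matrix B (columns a*, b*, c*, nm^-1), a*.a = 1."""

    matrix: np.ndarray
    convention: str = "crystallographic (a*.a = 1, no 2pi)"

    def __post_init__(self) -> None:
        object.__setattr__(self, "matrix", np.asarray(self.matrix, float))

    def hkl_to_q(self, hkl: np.ndarray) -> np.ndarray:
        return np.asarray(hkl, float) @ self.matrix.T


def reciprocal_basis(cell: UnitCell) -> ReciprocalBasis:
    """B = inverse-transpose of the direct basis; det(B) = 1/V."""
    a = cell.direct_matrix
    det = np.linalg.det(a)
    if det <= 0:
        raise LatticeError("degenerate cell: volume <= 0")
    return ReciprocalBasis(np.linalg.inv(a).T)


def hkl_operators(cell: UnitCell) -> list[np.ndarray]:
    """Laue rotations expressed in Miller-index space (integer matrices).

    For a symmetry rotation S of the lattice, the reciprocal point
    ``q = B h`` maps to ``S q = B h'`` with ``h' = B^-1 S B h``; in the
    conventional settings used here these matrices are exactly integral.
    """
    b = reciprocal_basis(cell).matrix
    binv = np.linalg.inv(b)
    out = []
    for s in laue_operators(cell.laue_class):
        n = binv @ s @ b
        ni = np.rint(n)
        if not np.allclose(n, ni, atol=1e-8):
            raise LatticeError(
                f"Laue operator is not integral in index space for cell {cell}"
            )
        out.append(ni.astype(np.int64))
    return out


@dataclass
class ReflectionFamily:
    """Orbit of symmetry-equivalent reflections (Laue group + Friedel).

    ``members`` holds every distinct equivalent integer triple, ``qvecs``
    the corresponding reciprocal vectors B @ hkl (nm^-1).  All members share
    one magnitude |h| and d-spacing d = 1/|h|.
    """

    representative: tuple[int, int, int]
    members: np.ndarray
    qvecs: np.ndarray
    magnitude: float
    d_spacing: float = field(default=0.0)

    def __post_init__(self) -> None:
        if self.d_spacing == 0.0:
            self.d_spacing = 1.0 / self.magnitude

    @property
    def multiplicity(self) -> int:
        return len(self.members)


def centering_mask(hkl: np.ndarray, centering: str) -> np.ndarray:
    """Boolean mask of reflections allowed by the lattice centering."""
    hkl = np.asarray(hkl)
    rule = _CENTERING_RULES[centering]
    return rule(hkl[..., 0], hkl[..., 1], hkl[..., 2])


@lru_cache(maxsize=32)
def _reflection_arrays(cell: UnitCell, d_min_nm: float,
                       max_reflections: int) -> tuple[np.ndarray, np.ndarray]:
    if not d_min_nm > 0:
        raise LatticeError("d_min must be > 0")
    b = reciprocal_basis(cell).matrix
    q_max = 1.0 / d_min_nm
    lengths = np.linalg.norm(cell.direct_matrix, axis=0)
    hmax = np.floor(q_max * lengths + 1e-9).astype(int)
    # quick size guard before materializing the grid
    approx = np.prod(2 * hmax.astype(float) + 1)
    if approx > 50 * max_reflections:
        raise LatticeError(
            f"~{approx:.2g} candidate reflections at d_min={d_min_nm} nm; "
            "increase d_min or raise max_reflections"
        )
    ranges = [np.arange(-m, m + 1) for m in hmax]
    hh, kk, ll = np.meshgrid(*ranges, indexing="ij")
    hkl = np.column_stack([hh.ravel(), kk.ravel(), ll.ravel()]).astype(np.int64)
    hkl = hkl[np.any(hkl != 0, axis=1)]
    q = hkl @ b.T
    keep = np.linalg.norm(q, axis=1) <= q_max * (1 + 1e-12)
    hkl, q = hkl[keep], q[keep]
    keep = centering_mask(hkl, cell.centering)
    hkl, q = hkl[keep], q[keep]
    if len(hkl) > max_reflections:
        raise LatticeError(
            f"{len(hkl)} reflections at d_min={d_min_nm} nm exceeds the cap "
            f"of {max_reflections}; increase d_min or raise max_reflections"
        )
    order = np.lexsort((hkl[:, 2], hkl[:, 1], hkl[:, 0]))
    return hkl[order], q[order]


def reflection_list(cell: UnitCell, d_min_nm: float,
                    max_reflections: int = 2_000_000
                    ) -> tuple[np.ndarray, np.ndarray]:
    """All centering-allowed reflections with ``|B hkl| <= 1/d_min``.

    Returns ``(hkl, q)`` sorted lexicographically by (h, k, l); (0,0,0) is
    excluded.  Cached per (cell, d_min).
    """
    return _reflection_arrays(cell, float(d_min_nm), int(max_reflections))


def generate_families(cell: UnitCell, d_min_nm: float,
                      max_reflections: int = 2_000_000
                      ) -> list[ReflectionFamily]:
    """Partition all in-resolution reflections into Laue+Friedel orbits.

    Families are sorted by |h| ascending (ties by representative); the
    representative is the lexicographically greatest triple in the orbit.
    """
    hkl, q = reflection_list(cell, d_min_nm, max_reflections)
    if len(hkl) == 0:
        return []
    ops = hkl_operators(cell)
    allops = np.array(ops + [-o for o in ops])  # include Friedel mates
    images = np.einsum("oij,nj->oni", allops, hkl)
    cmax = int(np.abs(images).max()) + 1
    base = 2 * cmax + 1

    def encode(t: np.ndarray) -> np.ndarray:
        return ((t[..., 0] + cmax) * base + (t[..., 1] + cmax)) * base \
            + (t[..., 2] + cmax)

    keys = encode(images)
    rep_keys = keys.max(axis=0)
    uniq = np.unique(rep_keys)

    b = reciprocal_basis(cell).matrix
    families: list[ReflectionFamily] = []
    for key in uniq:
        # decode representative
        l = key % base - cmax
        k = key // base % base - cmax
        h = key // (base * base) - cmax
        rep = (int(h), int(k), int(l))
        orbit = np.unique(np.array([o @ np.array(rep) for o in allops]), axis=0)
        qs = orbit @ b.T
        mags = np.linalg.norm(qs, axis=1)
        mag = float(mags.mean())
        if np.ptp(mags) > 1e-10 * mag:
            raise LatticeError(f"orbit of {rep} has unequal |h| (numerical)")
        families.append(ReflectionFamily(rep, orbit, qs, mag))
    families.sort(key=lambda f: (f.magnitude, f.representative))
    return families


def families_table(families: Iterable[ReflectionFamily]):
    """Reflection families as a pandas DataFrame (h k l |h| d multiplicity)."""
    import pandas as pd

    rows = [
        {"h": f.representative[0], "k": f.representative[1],
         "l": f.representative[2], "magnitude_inv_nm": f.magnitude,
         "d_nm": f.d_spacing, "multiplicity": f.multiplicity}
        for f in families
    ]
    return pd.DataFrame(rows)
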