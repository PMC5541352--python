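"""Configuration, peak-list and solution-stream formats, and the pipeline.

File formats (see also docs/formats.md):

* Peak lists: CSV with header ``image_id,x_m,y_m[,intensity]`` or an HDF5
  file with one group per image holding a ``peaks`` dataset of shape
  (n, 2) or (n, 3); units are metres from the beam centre.
* Solution streams: a versioned plain-text format listing, per image and
  per solution, the orientation quaternion, the reciprocal basis vectors
  of the oriented lattice (rows a*, b*, c*, nm^-1), n_matched,
  completeness and the matched (peak, hkl) table.
* Run configuration: an INI file with sections [scenario] or
  [cell]+[geometry], [felix], [simulate] and [run].

Every artifact written by :func:`run_pipeline` embeds the SHA-256 hash of
the canonical configuration, so a run is reproducible byte for byte from
its config and seed.
"""

from __future__ import annotations

import configparser
import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .cells import UnitCell, reciprocal_basis
from .geometry import BeamGeometry
from .indexer import FelixParams, IndexingSolution, index_image
from .rfspace import FrustumAccumulator, Rotation
from .simulate import (SimulationScenario, get_scenario, poisson_crystal_counts,
                       simulate_image)

log = logging.getLogger("pyfelix")

STREAM_MAGIC = "# pyfelix-stream"
STREAM_VERSION = 1


class FormatError(ValueError):
    """Malformed peak list, stream or configuration."""


@dataclass
class PeakList:
    """Ordered peaks of one image (metres from the beam centre)."""

    image_id: str
    xy_m: np.ndarray
    intensity: np.ndarray | None = None


# ---------------------------------------------------------------------------
# peak lists

def write_peaks(images: list[PeakList], path) -> None:
    """Write peak lists as CSV (.csv/.tsv/.txt) or HDF5 (.h5/.hdf5)."""
    path = Path(path)
    if path.suffix.lower() in (".h5", ".hdf5"):
        _write_peaks_h5(images, path)
    else:
        _write_peaks_csv(images, path)


def read_peaks(path) -> list[PeakList]:
    """Read peak lists; CSV and HDF5 layouts of the same data parse
    identically.  Raises :class:`FormatError` with the offending row for
    malformed input; an empty file yields an empty list with a warning.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"peak file not found: {path}")
    if path.suffix.lower() in (".h5", ".hdf5"):
        return _read_peaks_h5(path)
    return _read_peaks_csv(path)


def _write_peaks_csv(images, path) -> None:
    with open(path, "w") as f:
        f.write("image_id,x_m,y_m,intensity\n")
        for img in images:
            inten = img.intensity
            if len(img.xy_m) == 0:
                # header-only marker row keeps empty images round-trippable
                f.write(f"{img.image_id},,,\n")
            for i, (x, y) in enumerate(np.atleast_2d(img.xy_m)):
                v = "" if inten is None else repr(float(inten[i]))
                f.write(f"{img.image_id},{float(x)!r},{float(y)!r},{v}\n")


def _read_peaks_csv(path) -> list[PeakList]:
    import pandas as pd

    try:
        df = pd.read_csv(path, dtype={"image_id": str})
    except pd.errors.EmptyDataError:
        log.warning("empty peak file %s", path)
        return []
    for col in ("image_id", "x_m", "y_m"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing column {col!r}")
    out: list[PeakList] = []
    for image_id, grp in df.groupby("image_id", sort=False):
        empty = grp["x_m"].isna() & grp["y_m"].isna()
        grp = grp[~empty]
        bad = grp.index[grp["x_m"].isna() | grp["y_m"].isna()]
        if len(bad):
            raise FormatError(
                f"{path}: malformed row {int(bad[0]) + 2} (missing coordinate)")
        xy = grp[["x_m", "y_m"]].to_numpy(float)
        if not np.all(np.isfinite(xy)):
            row = int(grp.index[~np.all(np.isfinite(xy), axis=1)][0]) + 2
            raise FormatError(f"{path}: malformed row {row} (non-finite)")
        inten = None
        if "intensity" in grp.columns and grp["intensity"].notna().any():
            inten = grp["intensity"].to_numpy(float)
        out.append(PeakList(str(image_id), xy.reshape(-1, 2), inten))
    if not out:
        log.warning("peak file %s contains no images", path)
    return out


def _write_peaks_h5(images, path) -> None:
    import h5py

    with h5py.File(path, "w") as f:
        f.attrs["format"] = "pyfelix-peaks"
        f.attrs["version"] = 1
        for i, img in enumerate(images):
            grp = f.create_group(f"image_{i:06d}")
            grp.attrs["image_id"] = img.image_id
            data = np.asarray(img.xy_m, float).reshape(-1, 2)
            if img.intensity is not None:
                data = np.column_stack([data, img.intensity])
            grp.create_dataset("peaks", data=data)


def _read_peaks_h5(path) -> list[PeakList]:
    import h5py

    out: list[PeakList] = []
    with h5py.File(path, "r") as f:
        for name in sorted(f.keys()):
            grp = f[name]
            if "peaks" not in grp:
                raise FormatError(f"{path}: group {name} lacks 'peaks'")
            data = np.asarray(grp["peaks"])
            if data.size and (data.ndim != 2 or data.shape[1] not in (2, 3)):
                raise FormatError(f"{path}: group {name} has bad peak shape")
            data = data.reshape(-1, data.shape[1] if data.size else 2)
            inten = data[:, 2] if data.size and data.shape[1] == 3 else None
            out.append(PeakList(str(grp.attrs.get("image_id", name)),
                                data[:, :2].copy(), inten))
    if not out:
        log.warning("peak file %s contains no images", path)
    return out


# ---------------------------------------------------------------------------
# solution streams

def write_solutions(per_image: list[tuple[str, list[IndexingSolution]]],
                    cell: UnitCell, path, config_hash: str = "") -> None:
    """Write a text solution stream (one block per image, one per solution).

    The three ``astar/bstar/cstar`` rows are the reciprocal basis vectors
    of the oriented lattice, i.e. the columns of U @ B in nm^-1.
    """
    b = reciprocal_basis(cell).matrix
    with open(path, "w") as f:
        f.write(f"{STREAM_MAGIC} {STREAM_VERSION}\n")
        if config_hash:
            f.write(f"# config_hash {config_hash}\n")
        for image_id, sols in per_image:
            f.write(f"begin image {image_id}\n")
            for s in sols:
                ub = s.rotation.as_matrix() @ b
                f.write("begin solution\n")
                f.write("quaternion " + " ".join(f"{float(x)!r}" for x in s.rotation.q)
                        + "\n")
                for label, col in zip(("astar", "bstar", "cstar"), ub.T):
                    f.write(f"{label} " + " ".join(f"{float(x)!r}" for x in col) + "\n")
                f.write(f"n_matched {s.n_matched}\n")
                f.write(f"completeness {float(s.completeness)!r}\n")
                f.write(f"seed_visits {s.seed_visits}\n")
                f.write("peaks\n")
                for gi, hkl, dev in zip(s.g_index, s.hkl,
                                        np.degrees(s.deviation_rad)):
                    f.write(f"  {gi} {hkl[0]} {hkl[1]} {hkl[2]} {dev:.6f}\n")
                f.write("end solution\n")
            f.write("end image\n")


def read_solutions(path) -> list[tuple[str, list[IndexingSolution]]]:
    """Parse a solution stream written by :func:`write_solutions`."""
    lines = Path(path).read_text().splitlines()
    if not lines or not lines[0].startswith(STREAM_MAGIC):
        raise FormatError(f"{path}: not a pyfelix solution stream")
    version = int(lines[0].split()[-1])
    if version != STREAM_VERSION:
        raise FormatError(f"{path}: stream version {version} unsupported "
                          f"(expected {STREAM_VERSION})")
    out: list[tuple[str, list[IndexingSolution]]] = []
    i = 1
    cur_id = None
    cur_sols: list[IndexingSolution] = []
    while i < len(lines):
        line = lines[i].strip()
        if line.startswith("#") or not line:
            i += 1
            continue
        if line.startswith("begin image"):
            cur_id = line[len("begin image"):].strip()
            cur_sols = []
            i += 1
        elif line == "end image":
            out.append((cur_id, cur_sols))
            cur_id = None
            i += 1
        elif line == "begin solution":
            i, sol = _parse_solution(lines, i + 1, path)
            cur_sols.append(sol)
        else:
            raise FormatError(f"{path}: unexpected line {i + 1}: {line!r}")
    return out


def _parse_solution(lines, i, path):
    quat = None
    n_matched = 0
    completeness = 0.0
    seed_visits = 0
    rows = []
    while i < len(lines):
        line = lines[i].strip()
        if line == "end solution":
            if quat is None:
                raise FormatError(f"{path}: solution without quaternion")
            rows_a = np.array(rows) if rows else np.zeros((0, 5))
            sol = IndexingSolution(
                Rotation(quat), rows_a[:, 0].astype(int),
                rows_a[:, 1:4].astype(int),
                np.radians(rows_a[:, 4]), n_matched, completeness,
                seed_visits)
            return i + 1, sol
        if line.startswith("quaternion"):
            quat = np.array([float(x) for x in line.split()[1:]])
        elif line.startswith(("astar", "bstar", "cstar")):
            pass  # derived from the quaternion; informational in the stream
        elif line.startswith("n_matched"):
            n_matched = int(line.split()[1])
        elif line.startswith("completeness"):
            completeness = float(line.split()[1])
        elif line.startswith("seed_visits"):
            seed_visits = int(line.split()[1])
        elif line == "peaks":
            pass
        else:
            rows.append([float(x) for x in line.split()])
        i += 1
    raise FormatError(f"{path}: unterminated solution block")


# ---------------------------------------------------------------------------
# truth files

def write_truth(images, path) -> None:
    """Ground truth as JSON: quaternions + per-peak provenance per image."""
    doc = {"format": "pyfelix-truth", "version": 1, "images": []}
    for i, img in enumerate(images):
        doc["images"].append({
            "image_id": f"image_{i:06d}",
            "orientations": [list(map(float, r.q)) for r in img.orientations],
            "provenance": [[[int(ci), *map(int, hkl)] for ci, hkl in peak]
                           for peak in img.provenance],
        })
    Path(path).write_text(json.dumps(doc, indent=1))


def read_truth(path) -> list[list[Rotation]]:
    """Per-image true orientations from a truth JSON file."""
    doc = json.loads(Path(path).read_text())
    if doc.get("format") != "pyfelix-truth":
        raise FormatError(f"{path}: not a pyfelix truth file")
    return [[Rotation(q) for q in img["orientations"]]
            for img in doc["images"]]


# ---------------------------------------------------------------------------
# run configuration

@dataclass
class RunConfig:
    """Fully serializable description of one simulate->index->evaluate run."""

    scenario: SimulationScenario
    params: FelixParams
    seed: int = 0
    n_images: int = 1
    n_crystals: int | None = 1        # fixed crystals per image, or ...
    poisson_mean: float | None = None  # ... Poisson-distributed counts
    tolerance_deg: float = 1.0

    def config_hash(self) -> str:
        text = repr((dataclasses.asdict(self.scenario.cell),
                     dataclasses.asdict(self.scenario.geometry),
                     self.scenario.d_min_nm, self.scenario.r_profile_inv_nm,
                     self.scenario.pos_sigma_px, self.scenario.miss_rate,
                     self.scenario.spurious_rate,
                     dataclasses.asdict(self.params), self.seed,
                     self.n_images, self.n_crystals, self.poisson_mean,
                     self.tolerance_deg))
        return hashlib.sha256(text.encode()).hexdigest()[:16]


_FELIX_REQUIRED = ("n_voxels", "v_min", "f_v", "sigma_2theta_deg",
                   "sigma_eta_deg", "d_min_nm")


def read_config(path) -> RunConfig:
    """Parse an INI run configuration; missing required keys are named."""
    cp = configparser.ConfigParser(inline_comment_prefixes=("#", ";"))
    if not Path(path).exists():
        raise FormatError(f"config file not found: {path}")
    cp.read(path)

    preset = cp.get("scenario", "preset", fallback=None)
    if preset:
        scenario = get_scenario(preset)
        params = scenario.felix_params()
    else:
        scenario = _scenario_from_config(cp, path)
        params = None

    if cp.has_section("felix"):
        fields = {}
        for key, raw in cp.items("felix"):
            if key not in {f.name for f in dataclasses.fields(FelixParams)}:
                raise FormatError(f"{path}: unknown [felix] key {key!r}")
            typ = {f.name: f.type for f in dataclasses.fields(FelixParams)}[key]
            fields[key] = int(raw) if typ == "int" else \
                (raw if key == "eq6_axis" else float(raw))
        if params is None:
            missing = [k for k in _FELIX_REQUIRED if k not in fields]
            if missing:
                raise FormatError(
                    f"{path}: [felix] missing required keys: "
                    + ", ".join(missing))
            params = FelixParams(**fields)
        else:
            params = dataclasses.replace(params, **fields)
    elif params is None:
        raise FormatError(f"{path}: [felix] section required without a "
                          "scenario preset")

    noise = {}
    for key in ("pos_sigma_px", "miss_rate", "spurious_rate"):
        if cp.has_option("simulate", key):
            noise[key] = cp.getfloat("simulate", key)
    if noise:
        scenario = dataclasses.replace(scenario, **noise)
    scenario = dataclasses.replace(scenario, felix=params)

    n_crystals = None
    poisson_mean = None
    if cp.has_option("simulate", "poisson_mean"):
        poisson_mean = cp.getfloat("simulate", "poisson_mean")
    else:
        n_crystals = cp.getint("simulate", "n_crystals", fallback=1)
    return RunConfig(
        scenario=scenario, params=params,
        seed=cp.getint("run", "seed", fallback=0),
        n_images=cp.getint("simulate", "n_images", fallback=1),
        n_crystals=n_crystals, poisson_mean=poisson_mean,
        tolerance_deg=cp.getfloat("run", "tolerance_deg", fallback=1.0),
    )


def _scenario_from_config(cp, path) -> SimulationScenario:
    for sec in ("cell", "geometry"):
        if not cp.has_section(sec):
            raise FormatError(f"{path}: [{sec}] section required without a "
                              "scenario preset")
    try:
        cell = UnitCell(
            a=cp.getfloat("cell", "a"), b=cp.getfloat("cell", "b"),
            c=cp.getfloat("cell", "c"),
            alpha=cp.getfloat("cell", "alpha", fallback=90.0),
            beta=cp.getfloat("cell", "beta", fallback=90.0),
            gamma=cp.getfloat("cell", "gamma", fallback=90.0),
            laue_class=cp.get("cell", "laue_class"),
            centering=cp.get("cell", "centering", fallback="P"),
        )
    except configparser.NoOptionError as e:
        raise FormatError(f"{path}: [cell] missing key {e.option!r}") from None
    if cp.has_option("geometry", "energy_ev"):
        geom = BeamGeometry.from_energy(
            cp.getfloat("geometry", "energy_ev"),
            cp.getfloat("geometry", "distance_m"))
    else:
        geom = BeamGeometry(cp.getfloat("geometry", "wavelength_nm"),
                            cp.getfloat("geometry", "distance_m"))
    extra = {}
    for key in ("pixel_size_m", "half_extent_m"):
        if cp.has_option("geometry", key):
            extra[key] = cp.getfloat("geometry", key)
    if extra:
        geom = dataclasses.replace(geom, **extra)
    d_min = cp.getfloat("cell", "d_min_nm", fallback=None)
    if d_min is None:
        d_min = cp.getfloat("felix", "d_min_nm")
    r_prof = cp.getfloat("geometry", "r_profile_inv_nm", fallback=0.0086)
    return SimulationScenario("custom", cell, geom, d_min,
                              r_profile_inv_nm=r_prof)


# ---------------------------------------------------------------------------
# pipeline

def run_pipeline(config: RunConfig, outdir) -> dict:
    """simulate -> index -> evaluate one configuration; write artifacts.

    Writes ``peaks.csv``, ``truth.json``, ``solutions.txt`` and
    ``report.json`` under ``outdir`` and returns the report dict.  The
    whole run is deterministic in (config, seed).
    """
    from .evaluate import match_to_truth

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    chash = config.config_hash()
    sc = config.scenario
    rng = np.random.default_rng(config.seed)
    log.info("run %s: scenario=%s seed=%d images=%d", chash, sc.name,
             config.seed, config.n_images)

    if config.poisson_mean is not None:
        counts = poisson_crystal_counts(config.poisson_mean, config.n_images,
                                        rng)
    else:
        counts = np.full(config.n_images, config.n_crystals, int)

    images = [simulate_image(int(c), sc, rng) for c in counts]
    write_peaks([PeakList(f"image_{i:06d}", img.peaks_xy)
                 for i, img in enumerate(images)], outdir / "peaks.csv")
    write_truth(images, outdir / "truth.json")

    acc = FrustumAccumulator(config.params.n_voxels)
    per_image = []
    for i, img in enumerate(images):
        sols = index_image(img.peaks_xy, sc.cell, sc.geometry, config.params,
                           accumulator=acc)
        log.info("image %d: %d peaks, %d crystals true, %d found",
                 i, img.n_peaks, img.n_crystals, len(sols))
        per_image.append((f"image_{i:06d}", sols))
    write_solutions(per_image, sc.cell, outdir / "solutions.txt", chash)

    report = match_to_truth(
        [[s.rotation for s in sols] for _, sols in per_image],
        [img.orientations for img in images],
        config.tolerance_deg, sc.cell.laue_operators(),
    ).as_dict()
    report["config_hash"] = chash
    report["scenario"] = sc.name
    report["seed"] = config.seed
    (outdir / "report.json").write_text(json.dumps(report, indent=1))
    return report
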