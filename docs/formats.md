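# File formats

All formats are plain text or HDF5; units are metres on the detector and
nm⁻¹ in reciprocal space, angles in degrees.

## Peak lists

CSV with header, one row per peak:

```
image_id,x_m,y_m,intensity
image_000000,0.0123,-0.0045,
image_000001,,,
```

* `x_m`, `y_m`: metres from the beam centre (first coordinate along lab
  +y, second along lab +z; beam along +x).
* `intensity` is optional and unused by the indexer.
* A row with empty coordinates marks an image with zero peaks so empty
  images round-trip.

The equivalent HDF5 layout (`.h5`/`.hdf5`) has root attributes
`format="pyfelix-peaks"`, `version=1` and one group per image
(`image_000000`, ...) with an `image_id` attribute and a `peaks` dataset
of shape (n, 2) or (n, 3) (third column = intensity).  `read_peaks` parses
both layouts identically.

## Solution streams

Versioned text, inspired by serial-crystallography stream formats:

```
# pyfelix-stream 1
# config_hash 0123456789abcdef
begin image image_000000
begin solution
quaternion 0.98... 0.01... -0.1... 0.05...
astar 0.124... -0.011... 0.002...
bstar ...
cstar ...
n_matched 129
completeness 0.963
seed_visits 57
peaks
  0 -3 1 12 0.004213
  ...
end solution
end image
```

* `quaternion`: scalar-first unit quaternion of the crystal orientation
  (full precision; reading reconstructs it to 1e-12).
* `astar/bstar/cstar`: reciprocal basis vectors of the oriented lattice,
  the columns of U·B in nm⁻¹ (informational; derived from the
  quaternion).
* `peaks` rows: observed-peak index, h, k, l, angular deviation (deg).

A version number other than the reader's raises an error.

## Ground truth

JSON (`format="pyfelix-truth"`, `version=1`): per image the list of true
orientations (scalar-first quaternions) and per-peak provenance — a list
of `[crystal_index, h, k, l]` entries per peak (empty for spurious peaks,
two or more entries for merged peaks).

## Run configuration (INI)

```ini
[scenario]
preset = lysozyme          # or omit and give [cell] + [geometry]

[cell]                     # required without a preset
a = 7.90                   # nm
b = 7.90
c = 3.80
alpha = 90                 # degrees
beta = 90
gamma = 90
laue_class = 4/mmm         # m-3m | 4/mmm | mmm | 2/m | -1
centering = P              # P I C A B F

[geometry]
energy_ev = 9340           # or wavelength_nm
distance_m = 0.090
pixel_size_m = 110e-6      # optional
half_extent_m = 0.0955     # optional

[felix]                    # any FelixParams field; all six below are
n_voxels = 400             # required when no preset is given
v_min = 10
f_v = 0.5
sigma_2theta_deg = 0.15
sigma_eta_deg = 0.15
d_min_nm = 0.30

[simulate]
n_images = 10
n_crystals = 5             # or: poisson_mean = 1.0
pos_sigma_px = 0
miss_rate = 0
spurious_rate = 0

[run]
seed = 1
tolerance_deg = 1.0
```

`run_pipeline` writes `peaks.csv`, `truth.json`, `solutions.txt` and
`report.json` into the output directory; every artifact embeds the
SHA-256 hash of the configuration.
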