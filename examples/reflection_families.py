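"""Reflection families of the three study cells.

Lists how many symmetry-equivalent reflection families each unit cell has
inside its resolution cutoff — the driver of indexing difficulty: every
observed spot must be tried against every magnitude-compatible family, so
lower symmetry (smaller orbits, more families) means more geodesics.
"""

from pyfelix import generate_families, get_scenario
from pyfelix.cells import families_table

for name in ("rho-g6", "lysozyme", "at1r"):
    sc = get_scenario(name)
    fams = generate_families(sc.cell, sc.d_min_nm)
    n_refl = sum(f.multiplicity for f in fams)
    print(f"{name:9s} ({sc.cell.laue_class:5s}, {sc.cell.centering}-centred): "
          f"{len(fams):6d} families / {n_refl} reflections "
          f"to d_min = {sc.d_min_nm * 10:.1f} A")
    df = families_table(fams).head(3)
    print(df.to_string(index=False), "\n")
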