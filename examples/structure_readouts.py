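"""Structural readouts on a toy coordinate set: superposition RMSD,
the peroxidatic-resolving Cys sulfur distance, and relative solvent
accessibility of an active-site residue.

Real use parses a PDB file with `read_pdb`; here the Structure is built
in memory so the example is self-contained.
"""

import numpy as np

from gpxprx import (
    Structure,
    kabsch_superpose,
    relative_accessibility,
    residue_pair_distance,
    shrake_rupley_sasa,
)

# a small fold-like point cloud and a rigidly moved copy
rng = np.random.default_rng(4)
coords = rng.uniform(-8, 8, size=(30, 3))
theta = 0.8
R = np.array([[np.cos(theta), -np.sin(theta), 0],
              [np.sin(theta), np.cos(theta), 0],
              [0, 0, 1]])
moved = coords @ R.T + [5.0, -2.0, 1.0]
sup = kabsch_superpose(coords, moved)
print(f"RMSD of the superposed copies: {sup.rmsd:.2e} Å "
      "(a rigid motion superposes exactly)")

# two cysteine sulfurs placed 14.3 Å apart: too far for a disulfide bond
# without a conformational change
s = Structure(
    chains=["A", "A", "A", "A"],
    res_seqs=[61, 61, 107, 107],
    res_names=["CYS", "CYS", "CYS", "CYS"],
    atom_names=["CA", "SG", "CA", "SG"],
    elements=["C", "S", "C", "S"],
    coords=np.array([[0, 0, 0], [1.8, 0, 0], [14.0, 0, 0], [16.1, 0, 0]]),
    radii=np.array([1.7, 1.8, 1.7, 1.8]),
)
d = residue_pair_distance(s, ("A", 61), ("A", 107), atom_name="SG")
print(f"Cys61 SG - Cys107 SG distance: {d.distance:.1f} Å")

# solvent accessibility of one residue, normalized by its own exposed area
areas = shrake_rupley_sasa(s)
iso = Structure(["A"], [61], ["CYS"], ["SG"], ["S"],
                np.zeros((1, 3)), np.array([1.8]))
rel = relative_accessibility(s, [("A", 61)],
                             reference_max={"CYS": float(shrake_rupley_sasa(iso).sum() * 2)})
print(f"per-atom SASA of the four atoms: {np.round(areas, 1)} Å²")
print(f"relative accessibility of Cys61: {rel:.0f}% of its reference maximum")
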