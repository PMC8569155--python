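#!/usr/bin/env python
"""Build the 3D capsomer models and measure their surface organisation.

Constructs the prolate (2,0)/(7,0) portal shell and the isometric T=4 shell
at the default 110.85 A lattice constant, exports them (CSV + PDB
pseudo-atoms), and reports ring structure, helical parameters, the
pentamer-to-pentamer lattice walk, hexamer environments and the
pentamer-hexamer dihedral angles of both shells.

Writes results/phi12_prolate.{csv,pdb}, results/sapibov5_t4.{csv,pdb} and
results/model_report.json.
"""

import json
from pathlib import Path

import numpy as np

from capsidkit.geometry import (
    build_icosahedral_lattice,
    build_prolate_lattice,
    dihedral_angles,
    export_lattice,
    helical_params,
    ring_partition,
    shortest_pentamer_path,
)
from capsidkit.lattice import LatticeVectors

RESULTS = Path(__file__).resolve().parents[1] / "results"


def hexamer_environments(lat):
    idx = {c.id: c for c in lat.capsomers}
    adj = {c.id: set() for c in lat.capsomers}
    for i, j in lat.edges:
        adj[i].add(j)
        adj[j].add(i)
    only_hex = [
        c.id
        for c in lat.capsomers
        if c.kind == "hexamer"
        and all(idx[n].kind == "hexamer" for n in adj[c.id])
    ]
    return only_hex


def main():
    RESULTS.mkdir(exist_ok=True)
    prolate = build_prolate_lattice(LatticeVectors(2, 0, 7, 0), portal=True)
    t4 = build_icosahedral_lattice(2, 0)

    export_lattice(prolate, RESULTS / "phi12_prolate.csv", "csv")
    export_lattice(prolate, RESULTS / "phi12_prolate.pdb", "pdb")
    export_lattice(t4, RESULTS / "sapibov5_t4.csv", "csv")
    export_lattice(t4, RESULTS / "sapibov5_t4.pdb", "pdb")

    rings = ring_partition(prolate)
    helix = helical_params(prolate)
    walk = shortest_pentamer_path(prolate)
    only_hex = hexamer_environments(prolate)
    dih_pro = dihedral_angles(prolate)
    dih_iso = dihedral_angles(t4)

    report = {
        "lattice_constant_A": prolate.lattice_constant,
        "prolate": {
            "capsomers": prolate.counts(),
            "midsection_rings": [len(r) for r in rings],
            "helical_rise_A": helix.rise,
            "helical_twist_deg": helix.twist,
            "tube_radius_A": helix.tube_radius,
            "pentamer_walk_steps": walk.n_steps,
            "pentamer_walk_hexamers_between": walk.n_hexamers_between,
            "hexamers_with_only_hexamer_neighbors": len(only_hex),
            "pentamer_hexamer_dihedral_mean_deg": dih_pro.mean,
            "pentamer_hexamer_dihedral_std_deg": dih_pro.std,
        },
        "isometric_t4": {
            "capsomers": t4.counts(),
            "pentamer_hexamer_dihedral_mean_deg": dih_iso.mean,
            "pentamer_hexamer_dihedral_std_deg": dih_iso.std,
        },
        "dihedral_mean_difference_deg": abs(dih_pro.mean - dih_iso.mean),
    }
    (RESULTS / "model_report.json").write_text(json.dumps(report, indent=2) + "\n")

    print(f"prolate shell: {prolate.counts()}")
    print(
        f"midsection: {len(rings)} rings of {len(rings[0])} hexamers, "
        f"rise {helix.rise:.1f} A, twist {helix.twist:.1f} deg, "
        f"{len(only_hex)} hexamers see only hexamers"
    )
    print(
        f"shortest bottom-to-top pentamer walk: {walk.n_steps} steps, "
        f"{walk.n_hexamers_between} hexamers strictly between"
    )
    print(
        f"pentamer dihedrals: prolate {dih_pro.mean:.2f}+-{dih_pro.std:.2f} deg, "
        f"isometric {dih_iso.mean:.2f}+-{dih_iso.std:.2f} deg "
        f"(difference of means {abs(dih_pro.mean - dih_iso.mean):.2f} deg)"
    )


if __name__ == "__main__":
    main()
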