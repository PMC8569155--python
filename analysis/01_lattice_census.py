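#!/usr/bin/env python
"""Capsomer and subunit accounting of the prolate and isometric shells.

Computes the T/Q numbers and censuses of the prolate phi12 procapsid
(cap (2,0), midsection (7,0), portal at one vertex) and the isometric
SaPIbov5 procapsid (T=4), then solves the inverse problem: which
architectures are compatible with the observed subunit or hexamer counts.

Writes results/lattice_census.json and results/architecture_scan.csv.
"""

import json
from pathlib import Path

import pandas as pd

from capsidkit.lattice import (
    LatticeVectors,
    architecture_counts,
    enumerate_architectures,
)

RESULTS = Path(__file__).resolve().parents[1] / "results"


def arch_row(arch):
    return {
        "h1": arch.vectors.h1,
        "k1": arch.vectors.k1,
        "h2": arch.vectors.h2,
        "k2": arch.vectors.k2,
        "t_end": arch.t_end,
        "t_mid": arch.t_mid,
        "shape": arch.shape,
        "portal": arch.has_portal,
        "pentamers": arch.pentamer_sites,
        "hexamers": arch.hexamer_count,
        "cp_subunits": arch.cp_equivalent_subunits,
    }


def main():
    RESULTS.mkdir(exist_ok=True)
    prolate = architecture_counts(LatticeVectors(2, 0, 7, 0), has_portal=True)
    isometric = architecture_counts(LatticeVectors.isometric(2, 0), has_portal=True)
    iso_no_portal = architecture_counts(LatticeVectors.isometric(2, 0))

    census = {
        "phi12_prolate_portal": arch_row(prolate),
        "sapibov5_isometric_portal": arch_row(isometric),
        "sapibov5_isometric_portal_free": arch_row(iso_no_portal),
    }
    (RESULTS / "lattice_census.json").write_text(json.dumps(census, indent=2) + "\n")

    # inverse problem: what explains 540 subunits (no portal) / 80 hexamers?
    scan = []
    for arch in enumerate_architectures(subunits=540, max_component=20):
        scan.append({**arch_row(arch), "constraint": "subunits=540"})
    for arch in enumerate_architectures(hexamers=80, max_component=20):
        scan.append({**arch_row(arch), "constraint": "hexamers=80"})
    df = pd.DataFrame(scan)
    df.to_csv(RESULTS / "architecture_scan.csv", index=False)

    print(
        f"prolate phi12: T_end={prolate.t_end} T_mid={prolate.t_mid} -> "
        f"{prolate.cp_equivalent_subunits} CP copies, "
        f"{prolate.hexamer_count} hexamers + {prolate.pentamer_sites} pentamers + portal"
    )
    print(
        f"isometric SaPIbov5 (portal): {isometric.cp_equivalent_subunits} CP-equivalent "
        f"copies, {isometric.hexamer_count} hexamers + {isometric.pentamer_sites} pentamers"
    )
    print(f"architectures matching 540 subunits or 80 hexamers: {len(df)} (see CSV)")


if __name__ == "__main__":
    main()
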