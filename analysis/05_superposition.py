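#!/usr/bin/env python
"""Rigid-body superposition benchmarks and (optionally) real subunits.

Without input files this driver validates the superposition stack on
synthetic structures: exact recovery of a planted rigid transform, RMSD
under coordinate noise, and core extraction on a two-domain model whose
second domain is rigidly displaced — the same analysis pattern used when
comparing a capsid protein with its homolog (conserved core vs mobile
N-arm/E-loop).  With ``--structure`` it superposes two chains of a real
PDB/mmCIF model instead.

Writes results/superposition_report.csv.
"""

import argparse
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.spatial.transform import Rotation

from capsidkit.superpose import (
    ChainModel,
    chain_from_structure,
    core_rmsd,
    superpose,
)
from capsidkit.synthetic import gen_perturbed_structure, random_chain

RESULTS = Path(__file__).resolve().parents[1] / "results"


def synthetic_benchmarks():
    rows = []
    ch = random_chain(300, seed=41)
    R = Rotation.from_euler("zyx", [35.0, -60.0, 20.0], degrees=True).as_matrix()
    t = np.array([15.0, -8.0, 42.0])

    clean = gen_perturbed_structure(ch, R, t, noise_sigma=0.0, seed=42)
    res = superpose(clean.moving, clean.target)
    rows.append(
        {
            "case": "planted rigid transform, no noise",
            "n_pairs": len(res.matched_pairs),
            "rmsd_all_A": res.rmsd_all,
            "rmsd_core_A": res.rmsd_core,
            "core_pairs": len(res.core_pairs),
            "rotation_error": float(np.abs(res.rotation - R).max()),
        }
    )

    for sigma in (0.5, 1.0):
        noisy = gen_perturbed_structure(ch, R, t, noise_sigma=sigma, seed=43)
        res = superpose(noisy.moving, noisy.target)
        rows.append(
            {
                "case": f"gaussian noise sigma={sigma} A (expect ~{sigma*np.sqrt(3):.2f})",
                "n_pairs": len(res.matched_pairs),
                "rmsd_all_A": res.rmsd_all,
                "rmsd_core_A": res.rmsd_core,
                "core_pairs": len(res.core_pairs),
                "rotation_error": np.nan,
            }
        )

    # two-domain model: conserved core + rigidly displaced arm
    moved = ch.coords.copy()
    moved[200:] += np.array([0.0, 28.0, 0.0])
    target = ChainModel("Y", ch.residue_numbers, ch.residue_names, moved)
    res = core_rmsd(ch, target, superpose(ch, target))
    rows.append(
        {
            "case": "two-domain model (100 of 300 residues displaced 28 A)",
            "n_pairs": len(res.matched_pairs),
            "rmsd_all_A": res.rmsd_all,
            "rmsd_core_A": res.rmsd_core,
            "core_pairs": len(res.core_pairs),
            "rotation_error": np.nan,
        }
    )
    return rows


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--structure", type=Path, help="PDB/mmCIF file (optional)")
    ap.add_argument("--chain-a", default="B")
    ap.add_argument("--chain-b", default="A")
    args = ap.parse_args()

    RESULTS.mkdir(exist_ok=True)
    if args.structure:
        a = chain_from_structure(args.structure, args.chain_a)
        b = chain_from_structure(args.structure, args.chain_b)
        res = core_rmsd(a, b, superpose(a, b))
        rows = [
            {
                "case": f"{args.structure.name} chain {args.chain_a} vs {args.chain_b}",
                "n_pairs": len(res.matched_pairs),
                "rmsd_all_A": res.rmsd_all,
                "rmsd_core_A": res.rmsd_core,
                "core_pairs": len(res.core_pairs),
                "rotation_error": np.nan,
            }
        ]
    else:
        rows = synthetic_benchmarks()

    df = pd.DataFrame(rows)
    df.to_csv(RESULTS / "superposition_report.csv", index=False)
    with pd.option_context("display.width", 120):
        print(df.to_string(index=False))


if __name__ == "__main__":
    main()
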