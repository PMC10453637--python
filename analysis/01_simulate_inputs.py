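#!/usr/bin/env python
"""Generate the synthetic study inputs with planted ground truth.

Writes, under --out (default results/data):
  * wt.pdb / gv.pdb     — two multi-model ensembles; "gv" relaxed, "wt" with
                          an engineered steric clash at the focal position
  * states.pdb          — a three-state ensemble (occupancies 0.6/0.3/0.1)
                          for the state-discovery analysis
  * msa.fasta           — 998 homologs with a planted G 0.47 / A 0.50 column
  * hits.tsv            — 5000-row tabular hit list with known pass fraction
Each artifact gets a .truth.json sidecar with its planted truth.
"""

import argparse
from pathlib import Path

from metastab.synthetic_data import (
    TrajectorySpec,
    simulate_hit_table,
    simulate_metastable_trajectory,
    simulate_msa,
)
from metastab.traj_io import write_multi_model_pdb


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--out", type=Path, default=Path("results/data"))
    ap.add_argument("--n-frames", type=int, default=600)
    args = ap.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    specs = {
        "states": TrajectorySpec(n_frames=args.n_frames, seed=args.seed),
        "gv": TrajectorySpec(
            n_frames=args.n_frames,
            occupancies=(1.0,),
            state_displacements=((0.0, 0.0, 0.0),),
            noise_sigma=0.05,
            seed=args.seed + 1,
        ),
        "wt": TrajectorySpec(
            n_frames=args.n_frames,
            occupancies=(1.0,),
            displaced_residues=(7,),
            state_displacements=((-1.6, 0.0, 0.0),),
            noise_sigma=0.05,
            seed=args.seed + 2,
        ),
    }
    for label, spec in specs.items():
        traj, truth = simulate_metastable_trajectory(spec)
        path = args.out / f"{label}.pdb"
        write_multi_model_pdb(traj, path)
        truth.to_json(f"{path}.truth.json")
        print(f"{label}: {traj.n_frames} frames, {traj.n_atoms} atoms -> {path}")

    msa_text, msa_truth = simulate_msa(
        998, 12, {6: {"G": 0.47, "A": 0.50, "S": 0.03}}, seed=args.seed
    )
    (args.out / "msa.fasta").write_text(msa_text)
    msa_truth.to_json(args.out / "msa.fasta.truth.json")
    print(f"msa: 998 homologs, planted G/A column at position 6 -> {args.out / 'msa.fasta'}")

    hits_text, hits_truth = simulate_hit_table(5000, seed=args.seed)
    (args.out / "hits.tsv").write_text(hits_text)
    hits_truth.to_json(args.out / "hits.tsv.truth.json")
    print(
        f"hits: 5000 rows, planted pass fraction "
        f"{hits_truth.planted_pass_fraction:.4f} -> {args.out / 'hits.tsv'}"
    )


if __name__ == "__main__":
    main()
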