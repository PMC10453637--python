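#!/usr/bin/env python
"""Discover metastable states in the planted three-state ensemble.

Reads results/data/states.pdb (from 01_simulate_inputs.py), featurizes on
focal-to-neighbor minimum heavy-atom distances, standardizes, projects on two
principal components, scans K = 1..9 with the elbow heuristic, and compares
recovered occupancies and frame labels against the planted truth.  Writes the
elbow curve, state assignments, free-energy landscape, and representative
frames under --out (default results/states).
"""

import argparse
import json
from pathlib import Path

import numpy as np

from metastab import featurize, states, traj_io
from metastab.pipeline import _write_elbow_tsv, _write_landscape_tsv, _write_states_tsv
from metastab.synthetic_data import TrajectorySpec


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--data", type=Path, default=Path("results/data"))
    ap.add_argument("--out", type=Path, default=Path("results/states"))
    args = ap.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    traj = traj_io.read_multi_model_pdb(args.data / "states.pdb")
    truth = json.loads((args.data / "states.pdb.truth.json").read_text())
    selection = TrajectorySpec(seed=args.seed).planted_selection()

    feats = featurize.standardize(featurize.min_distance_features(traj, selection))
    proj = states.pca_project(feats, 2)
    print(
        "explained variance fractions:",
        np.round(proj.explained_variance_fraction, 3).tolist(),
    )

    scan = states.elbow_select_k(proj, 9, seed=args.seed)
    print("inertia curve:", np.round(scan.inertias, 1).tolist())
    print(f"elbow-selected K = {scan.chosen_k}")

    model = states.fit_kmeans(proj, scan.chosen_k, seed=args.seed)
    occ = np.sort(model.occupancies)[::-1]
    planted = np.sort(truth["planted_occupancies"])[::-1]
    print("recovered occupancies:", np.round(occ, 3).tolist())
    print("planted occupancies:  ", planted.tolist())
    print("max |occupancy error|:", float(np.round(np.abs(occ - planted).max(), 4)))

    _write_elbow_tsv(scan, args.out / "elbow.tsv")
    _write_states_tsv(model, args.out / "state_labels.tsv")
    _write_landscape_tsv(states.free_energy_landscape(proj, 60), args.out / "landscape.tsv")
    for s in range(model.k):
        frame = states.representative_frame(model, proj, s)
        traj_io.write_frame_pdb(traj, frame, args.out / f"state{s}_representative.pdb")
        print(f"state {s}: occupancy {model.occupancies[s]:.3f}, representative frame {frame}")


if __name__ == "__main__":
    main()
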