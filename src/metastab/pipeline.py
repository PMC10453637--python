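"""End-to-end orchestration of the stability and conservation analyses.

``run_stability_analysis`` chains featurization -> state discovery ->
local-energy summaries for each focal position of each input ensemble, and
compares two variants when two inputs are given.  All numeric defaults in
:class:`RunConfig` are the canonical analysis parameters: 5 A contact cutoff,
2 PCA components, elbow scan over K = 1..9, 200 frames from the most
populated state, 1000 bootstrap iterations at the 95% level.  One seed in
the config drives every stochastic step.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np

import metastab
from metastab import featurize, states, stability, conservation, traj_io
from metastab.errors import MetastabError

logger = logging.getLogger("metastab")


@dataclass
class RunConfig:
    """All knobs of a stability-analysis run; round-trips through JSON."""

    inputs: dict[str, str] = field(default_factory=dict)  # label -> multi-model PDB path
    focal_positions: tuple[int, ...] = ()
    cutoff: float = 5.0
    n_components: int = 2
    k_max: int = 9
    frames_per_state: int = 200
    n_boot: int = 1000
    ci_level: float = 0.95
    seed: int = 0
    output_dir: str = "results"
    reference_frame: int = 0
    explicit_neighbors: dict[int, tuple[int, ...]] = field(default_factory=dict)
    score_tables: dict[str, str] = field(default_factory=dict)  # label -> TSV path
    landscape_bins: int = 60

    def to_json(self, path: str | Path) -> None:
        payload = asdict(self)
        payload["focal_positions"] = list(self.focal_positions)
        payload["explicit_neighbors"] = {str(k): list(v) for k, v in self.explicit_neighbors.items()}
        Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        payload = json.loads(Path(path).read_text())
        payload["focal_positions"] = tuple(payload.get("focal_positions", ()))
        payload["explicit_neighbors"] = {
            int(k): tuple(v) for k, v in payload.get("explicit_neighbors", {}).items()
        }
        return cls(**payload)


def _stage(name: str):
    """Context manager tagging stage failures and logging timings."""

    class _Stage:
        def __enter__(self):
            self.t0 = time.perf_counter()
            return self

        def __exit__(self, exc_type, exc, tb):
            dt = time.perf_counter() - self.t0
            if exc is not None:
                raise MetastabError(f"stage {name!r} failed: {exc}") from exc
            logger.info("stage %s finished in %.2f s", name, dt)

    return _Stage()


def analyze_trajectory(
    traj: traj_io.Trajectory,
    focal: int,
    config: RunConfig,
) -> dict:
    """Featurize -> discover states -> summarize local energy for one focal position."""
    with _stage(f"featurize[{focal}]"):
        if focal in config.explicit_neighbors:
            selection = traj_io.ResidueSelection(
                tuple(config.explicit_neighbors[focal]) + (focal,), focal=focal
            )
        else:
            selection = featurize.contact_neighborhood(
                traj, focal, config.cutoff, frame=config.reference_frame
            )
        feats = featurize.standardize(featurize.min_distance_features(traj, selection))
    with _stage(f"states[{focal}]"):
        proj = states.pca_project(feats, config.n_components)
        scan = states.elbow_select_k(proj, config.k_max, config.seed)
        model = states.fit_kmeans(proj, scan.chosen_k, config.seed)
        top = model.most_populated_state
        rep_frames = {s: states.representative_frame(model, proj, s) for s in range(model.k)}
        landscape, xe, ye = states.free_energy_landscape(proj, config.landscape_bins)
    with _stage(f"stability[{focal}]"):
        sampled = stability.sample_state_frames(
            model, top, config.frames_per_state, config.seed
        )
        table = stability.surrogate_score_table(traj, frames=[int(f) for f in sampled])
        summary = stability.local_energy_summary(
            table,
            [int(f) for f in sampled],
            selection,
            n_boot=config.n_boot,
            level=config.ci_level,
            seed=config.seed,
        )
    return {
        "selection": selection,
        "features": feats,
        "projection": proj,
        "elbow": scan,
        "model": model,
        "representative_frames": rep_frames,
        "landscape": (landscape, xe, ye),
        "sampled_frames": sampled,
        "summary": summary,
    }


def run_stability_analysis(config: RunConfig) -> dict:
    """Run the full analysis for every input ensemble and focal position.

    Writes the elbow scan, occupancies, representative-frame PDBs,
    local-energy summaries, variant comparisons (for exactly two inputs)
    and a manifest under ``config.output_dir``; returns the report dict.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"kind": "stability_report", "seed": config.seed, "labels": {}, "comparisons": []}
    results: dict[str, dict[int, dict]] = {}
    for label, path in config.inputs.items():
        with _stage(f"read[{label}]"):
            traj = traj_io.read_multi_model_pdb(path)
        results[label] = {}
        report["labels"][label] = {}
        for focal in config.focal_positions:
            res = analyze_trajectory(traj, focal, config)
            results[label][focal] = res
            prefix = out / f"{label}_{focal}"
            _write_elbow_tsv(res["elbow"], f"{prefix}_elbow.tsv")
            _write_states_tsv(res["model"], f"{prefix}_states.tsv")
            _write_landscape_tsv(res["landscape"], f"{prefix}_landscape.tsv")
            for s, fidx in res["representative_frames"].items():
                traj_io.write_frame_pdb(traj, fidx, f"{prefix}_state{s}_representative.pdb")
            model = res["model"]
            summary = res["summary"]
            report["labels"][label][str(focal)] = {
                "neighborhood": list(res["selection"].residue_indices),
                "chosen_k": int(res["elbow"].chosen_k),
                "inertias": [float(i) for i in res["elbow"].inertias],
                "occupancies": [float(o) for o in model.occupancies],
                "most_populated_state": int(model.most_populated_state),
                "representative_frames": {str(s): int(f) for s, f in res["representative_frames"].items()},
                "n_frames_used": int(summary.n_frames_used),
                "local_energy_mean": float(summary.mean),
                "local_energy_ci": [float(summary.ci_low), float(summary.ci_high)],
                "units": summary.units,
            }
    if len(config.inputs) == 2:
        (la, _), (lb, _) = config.inputs.items()
        for focal in config.focal_positions:
            cmp = stability.compare_variants(
                results[la][focal]["summary"], results[lb][focal]["summary"], seed=config.seed
            )
            cmp["variant_a"], cmp["variant_b"] = la, lb
            report["comparisons"].append(cmp)
    manifest = {
        "package": "metastab",
        "version": metastab.__version__,
        "seed": config.seed,
        "config": json.loads(json.dumps(asdict(config), default=list)),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True) + "\n")
    (out / "stability_report.json").write_text(json.dumps(report, indent=1, sort_keys=True) + "\n")
    validate_report(report)
    return report


def run_conservation(
    msa_path: str | Path,
    hits_path: str | Path | None,
    query_id: str,
    positions,
    residue_set: str = "",
    query_length: int | None = None,
    output_dir: str | Path | None = None,
) -> dict:
    """Filter homolog hits and profile residue conservation at query positions."""
    report: dict = {"kind": "conservation_report", "query_id": query_id}
    if hits_path is not None:
        with _stage("filter_hits"):
            hits = conservation.read_blast_tabular(hits_path, query_length=query_length)
            kept = conservation.filter_hits(hits)
        report["n_hits"] = len(hits)
        report["n_retained"] = len(kept)
        if not kept:
            report["warning"] = "no hits survive the coverage/identity filters"
    with _stage("frequencies"):
        table = conservation.residue_frequencies(msa_path, query_id)
        report["positions"] = conservation.position_report(table, positions, residue_set)["positions"]
        report["residue_set"] = residue_set.upper()
    if output_dir is not None:
        out = Path(output_dir)
        out.mkdir(parents=True, exist_ok=True)
        conservation.write_frequency_tsv(table, out / "frequencies.tsv")
        (out / "conservation_report.json").write_text(json.dumps(report, indent=1, sort_keys=True) + "\n")
    validate_report(report)
    return report


def report_schema() -> dict:
    """The JSON schema the emitted reports conform to (shipped resource)."""
    text = resources.files("metastab").joinpath("resources/report_schema.json").read_text()
    return json.loads(text)


def validate_report(report: dict) -> None:
    """Structural validation of a report against the shipped schema.

    Checks the required keys and primitive types of the matching schema
    branch; raises ``ValueError`` on violation.
    """
    schema = report_schema()
    kind = report.get("kind")
    branch = next((b for b in schema["oneOf"] if b["properties"]["kind"]["const"] == kind), None)
    if branch is None:
        raise ValueError(f"unknown report kind {kind!r}")
    for key in branch["required"]:
        if key not in report:
            raise ValueError(f"report missing required key {key!r}")
    types = {"object": dict, "array": list, "string": str, "integer": int, "number": (int, float)}
    for key, spec in branch["properties"].items():
        if key in report and "type" in spec:
            if not isinstance(report[key], types[spec["type"]]):
                raise ValueError(f"report key {key!r} has wrong type")


def _write_elbow_tsv(scan: states.ElbowScan, path) -> None:
    lines = ["k\tinertia\tchosen"]
    for k, inertia in zip(scan.k_values, scan.inertias):
        lines.append(f"{int(k)}\t{inertia:.8g}\t{int(k == scan.chosen_k)}")
    Path(path).write_text("\n".join(lines) + "\n")


def _write_states_tsv(model: states.StateModel, path) -> None:
    lines = ["frame\tstate"] + [f"{f}\t{int(s)}" for f, s in enumerate(model.labels)]
    Path(path).write_text("\n".join(lines) + "\n")


def _write_landscape_tsv(landscape, path) -> None:
    grid, xe, ye = landscape
    lines = ["# rows: first-component bins; cols: second-component bins; 'nan' = unvisited"]
    lines.append("# x_edges\t" + "\t".join(f"{v:.6g}" for v in xe))
    lines.append("# y_edges\t" + "\t".join(f"{v:.6g}" for v in ye))
    for row in grid.filled(np.nan):
        lines.append("\t".join(f"{v:.6g}" for v in row))
    Path(path).write_text("\n".join(lines) + "\n")
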