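"""End-to-end orchestration: map → rules → simulations → topology → hubs.

``run_paper_pipeline`` executes the full analysis for a map: census and
validation, Boolean translation, stochastic simulation of the stimulus-off
and stimulus-on scenarios with activity levels and phenotype courses,
topology reports in both modes, and the MCC hub ranking with its top-k
subnetwork.  ``export_report`` writes every artefact as CSV/JSON with a
checksum MANIFEST so a bundle can be verified byte-for-byte.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import dynamics, logic, map_model, phenotype, synthetic, topology


class PipelineStageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineConfig:
    map_source: str = "fixture"  # "fixture" or a path to an edge table / SBML file
    stimulus_node: str = "TGFB"
    n_steps: int = 5000
    window: int = 50
    ensemble: int = 100
    markers: phenotype.MarkerConfig | None = None
    hub_k: int = 25
    seed: int = 1

    def __post_init__(self) -> None:
        if self.hub_k < 1:
            raise ValueError("hub_k must be >= 1")


@dataclass
class ScenarioResult:
    clamp: float
    profile: dynamics.ActivityProfile
    course: phenotype.PhenotypeCourse


@dataclass
class ReportBundle:
    config: PipelineConfig
    map: map_model.RegulatoryMap
    summary: map_model.MapSummary
    issues: list[map_model.ValidationIssue]
    model: logic.LogicModel
    scenarios: dict[str, ScenarioResult]
    topology_reports: dict[str, topology.TopologyReport]
    hub_ranking: topology.HubRanking
    hub_subnetwork: map_model.RegulatoryMap


def load_map(source: str) -> map_model.RegulatoryMap:
    if source == "fixture":
        return synthetic.emt_core_fixture()
    path = Path(source)
    if not path.exists():
        raise FileNotFoundError(f"map file not found: {path}")
    if path.suffix.lower() in (".xml", ".sbml"):
        return map_model.read_celldesigner_sbml(path)
    return map_model.read_edge_table(path)


def _stage(name, fn, *args, **kwargs):
    try:
        return fn(*args, **kwargs)
    except Exception as exc:  # noqa: BLE001 - stage name is the contract
        raise PipelineStageError(name, exc) from exc


def run_paper_pipeline(config: PipelineConfig) -> ReportBundle:
    """Execute every stage; any failure propagates with its stage name."""
    map_ = _stage("read", load_map, config.map_source)
    issues = _stage("validate", map_model.validate_map, map_)
    summary = _stage("summarize", map_model.summarize_map, map_)
    model = _stage("infer_rules", logic.infer_rules, map_)
    markers = config.markers or phenotype.default_marker_config()

    scenarios: dict[str, ScenarioResult] = {}
    for label, clamp in (("stimulus_off", 0.0), ("stimulus_on", 1.0)):
        sim_cfg = dynamics.SimulationConfig(
            scheme="asynchronous",
            n_steps=config.n_steps,
            clamps={config.stimulus_node: clamp},
            initial="epithelial",
            seed=config.seed,
        )
        profile = _stage(
            f"activity_profile[{label}]",
            dynamics.activity_profile,
            model,
            sim_cfg,
            config.window,
            config.ensemble,
            markers,
        )
        course = _stage(f"phenotype_course[{label}]", phenotype.phenotype_course, profile, markers)
        scenarios[label] = ScenarioResult(clamp=clamp, profile=profile, course=course)

    reports = {
        mode: _stage(f"topology[{mode}]", topology.topology_report, map_, mode)
        for mode in ("directed", "undirected")
    }
    ranking = _stage("mcc_scores", topology.mcc_scores, map_)
    k = min(config.hub_k, map_.n_species)
    sub = _stage("top_k_subnetwork", topology.top_k_subnetwork, ranking, k, map_)
    return ReportBundle(
        config=config,
        map=map_,
        summary=summary,
        issues=issues,
        model=model,
        scenarios=scenarios,
        topology_reports=reports,
        hub_ranking=ranking,
        hub_subnetwork=sub,
    )


# ---------------------------------------------------------------------------
# export / verify


def _profile_frame(profile: dynamics.ActivityProfile) -> pd.DataFrame:
    rows = []
    for w in range(profile.n_windows):
        for j, node in enumerate(profile.node_order):
            rows.append((w, node, float(profile.values[w, j])))
    return pd.DataFrame(rows, columns=["window", "node", "activity"])


def export_report(bundle: ReportBundle, out_dir: str | Path) -> Path:
    """Write all artefacts with stable names plus a sha256 MANIFEST."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    (out / "map_summary.json").write_text(bundle.summary.to_json() + "\n", encoding="utf-8")
    issues = [i.__dict__ for i in bundle.issues]
    (out / "validation_issues.json").write_text(json.dumps(issues, indent=2) + "\n", encoding="utf-8")

    rules = {
        node: logic.rule_to_text(bundle.model.rules[node])
        for node in bundle.model.node_order
    }
    (out / "logic_rules.json").write_text(json.dumps(rules, indent=2, sort_keys=True) + "\n", encoding="utf-8")

    for label, scen in sorted(bundle.scenarios.items()):
        _profile_frame(scen.profile).to_csv(out / f"activity_{label}.csv", index=False)
        course = pd.DataFrame(
            {
                "window": range(len(scen.course.calls)),
                "label": [c.label for c in scen.course.calls],
                "epithelial_fraction": [float(c.epithelial_fraction) for c in scen.course.calls],
                "mesenchymal_fraction": [float(c.mesenchymal_fraction) for c in scen.course.calls],
            }
        )
        course.to_csv(out / f"phenotype_{label}.csv", index=False)

    topo = {mode: rep.to_dict() for mode, rep in bundle.topology_reports.items()}
    (out / "topology.json").write_text(json.dumps(topo, indent=2, sort_keys=True) + "\n", encoding="utf-8")

    hubs = pd.DataFrame(
        {
            "node": bundle.hub_ranking.ranked,
            "mcc": [bundle.hub_ranking.scores[n] for n in bundle.hub_ranking.ranked],
        }
    )
    hubs.to_csv(out / "hub_ranking.csv", index=False)
    map_model.write_edge_table(bundle.hub_subnetwork, out / "hub_subnetwork.csv")

    meta = {
        "seed": bundle.config.seed,
        "map_source": bundle.config.map_source,
        "stimulus_node": bundle.config.stimulus_node,
        "n_steps": bundle.config.n_steps,
        "window": bundle.config.window,
        "ensemble": bundle.config.ensemble,
        "hub_k": bundle.config.hub_k,
    }
    (out / "run_metadata.json").write_text(json.dumps(meta, indent=2, sort_keys=True) + "\n", encoding="utf-8")

    manifest_lines = []
    for path in sorted(out.iterdir()):
        if path.name == "MANIFEST" or not path.is_file():
            continue
        digest = hashlib.sha256(path.read_bytes()).hexdigest()
        manifest_lines.append(f"{digest}  {path.name}")
    (out / "MANIFEST").write_text("\n".join(manifest_lines) + "\n", encoding="utf-8")
    return out


def verify_report(out_dir: str | Path) -> list[str]:
    """Return the names of files whose checksum does not match MANIFEST."""
    out = Path(out_dir)
    manifest = out / "MANIFEST"
    if not manifest.exists():
        raise FileNotFoundError(f"no MANIFEST in {out}")
    bad = []
    for line in manifest.read_text(encoding="utf-8").splitlines():
        if not line.strip():
            continue
        digest, name = line.split(None, 1)
        path = out / name.strip()
        if not path.exists() or hashlib.sha256(path.read_bytes()).hexdigest() != digest:
            bad.append(name.strip())
    return bad
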