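"""Declarative end-to-end analysis pipeline.

A config (nested dict, typically loaded from YAML) names the stages to run
and their inputs; :func:`run_pipeline` validates it up front, executes the
stages in order, and returns an :class:`AnalysisReport` with per-stage
status - a failing stage is recorded, not raised, so partial studies still
produce a report.  Every tolerance and seed used is echoed into the report,
making a rerun reproducible.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Dict, List

import numpy as np

from . import interactions as ia
from .alignment import column_profile
from .dataset import VelocityDataset
from .fitting import fit_global, fit_inhibition_series
from .mechanism import classify_inhibition, double_reciprocal_pattern, infer_mechanism, replot_effects
from .native_contacts import native_contact_map, q_trajectory
from .speciation import BindingSystem, speciate
from .structure import DomainDefinition, read_structure_file, read_trajectory

__all__ = ["AnalysisReport", "run_pipeline", "validate_config", "parse_domains"]

log = logging.getLogger("pkmech")

KNOWN_STAGES = (
    "speciation",
    "fit",
    "inhibition",
    "mechanism",
    "interactions",
    "qtraj",
    "conserve",
)


@dataclass
class AnalysisReport:
    inputs: Dict[str, Any] = field(default_factory=dict)
    results: Dict[str, Dict[str, Any]] = field(default_factory=dict)
    settings: Dict[str, Any] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "inputs": self.inputs,
            "results": self.results,
            "settings": self.settings,
        }


def parse_domains(spec: str) -> DomainDefinition:
    """Parse 'name:start-end,start-end' into a :class:`DomainDefinition`."""
    name, _, rest = spec.partition(":")
    if not rest:
        raise ValueError(f"domain spec {spec!r} must look like 'A:1-65,165-334'")
    ranges = []
    for chunk in rest.split(","):
        start, _, end = chunk.partition("-")
        ranges.append((int(start), int(end)))
    return DomainDefinition(name, tuple(ranges))


def _jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj


def validate_config(config: Dict[str, Any], base_dir: Path) -> None:
    """Reject unknown stage names and missing input files before any work."""
    stages = config.get("stages")
    if not isinstance(stages, list) or not stages:
        raise ValueError("config must contain a non-empty 'stages' list")
    for stage in stages:
        kind = stage.get("stage")
        if kind not in KNOWN_STAGES:
            raise ValueError(
                f"unknown stage {kind!r}; known stages: {KNOWN_STAGES}"
            )
        for key in ("data", "pdb", "reference", "traj", "alignment"):
            if key in stage:
                path = base_dir / stage[key]
                if not path.exists():
                    raise ValueError(f"stage {kind!r}: missing input file {path}")
        if kind == "mechanism":
            for inh in stage.get("inhibitions", []):
                path = base_dir / inh["data"]
                if not path.exists():
                    raise ValueError(f"mechanism stage: missing input file {path}")


def _run_stage(stage: Dict[str, Any], base_dir: Path) -> Any:
    kind = stage["stage"]
    if kind == "speciation":
        system = BindingSystem(
            total_metal=float(stage["total_metal"]),
            total_ligand=float(stage["total_ligand"]),
            kd=float(stage["kd"]),
        )
        return speciate(system)
    if kind == "fit":
        data = VelocityDataset.read_table(
            base_dir / stage["data"], varied=stage.get("varied", "a")
        )
        return fit_global(
            data,
            stage["model"],
            weights=stage.get("weights", "none"),
            n_starts=int(stage.get("n_starts", 8)),
            seed=int(stage.get("seed", 0)),
        )
    if kind == "inhibition":
        data = VelocityDataset.read_table(
            base_dir / stage["data"], varied=stage.get("varied", "a")
        )
        fit = fit_inhibition_series(data, seed=int(stage.get("seed", 0)))
        call = classify_inhibition(fit, replot_effects(data))
        return {"fit": fit.best, "kind": fit.kind, "call": call}
    if kind == "mechanism":
        data = VelocityDataset.read_table(
            base_dir / stage["data"], varied=stage.get("varied", "a")
        )
        pattern = double_reciprocal_pattern(data)
        calls = []
        for inh in stage.get("inhibitions", []):
            idata = VelocityDataset.read_table(
                base_dir / inh["data"], varied=inh.get("varied", "a")
            )
            fit = fit_inhibition_series(idata, seed=int(stage.get("seed", 0)))
            call = classify_inhibition(fit, replot_effects(idata))
            calls.append((call, inh["varied_substrate"], inh["analog_of"]))
        mech = infer_mechanism(pattern, calls)
        return {"pattern": pattern, "mechanism": mech}
    if kind == "interactions":
        s = read_structure_file(base_dir / stage["pdb"])
        if "chain" in stage:
            s = s.select_chain(stage["chain"])
        which = stage.get("kind", "all")
        out: Dict[str, Any] = {}
        if which in ("pi_pi", "all"):
            out["pi_pi"] = ia.pi_pi_pairs(s)
        if which in ("salt_bridges", "all"):
            out["salt_bridges"] = ia.salt_bridges(s)
        if which in ("hbonds", "all"):
            out["hbonds"] = ia.hbonds(s)
        if which in ("interface", "all") and "domain_a" in stage:
            out["interface"] = ia.interface_contacts(
                s,
                parse_domains(stage["domain_a"]),
                parse_domains(stage["domain_b"]),
                exclude=tuple(
                    tuple(r) for r in stage.get("exclude", [])
                ),
            )
        return out
    if kind == "qtraj":
        ref = read_structure_file(base_dir / stage["reference"])
        frames = read_trajectory(
            (base_dir / stage["traj"]).read_text(), source=str(stage["traj"])
        )
        selection = (
            parse_domains(stage["domain"]) if "domain" in stage else None
        )
        contacts = native_contact_map(
            ref,
            cutoff=float(stage.get("cutoff", 8.0)),
            min_seq_sep=int(stage.get("min_seq_sep", 3)),
            selection=selection,
        )
        return q_trajectory(
            frames,
            contacts,
            tolerance_factor=float(stage.get("tolerance_factor", 1.2)),
            selection=selection,
        )
    if kind == "conserve":
        return column_profile(
            base_dir / stage["alignment"],
            stage["reference_id"],
            [int(p) for p in stage["positions"]],
        )
    raise ValueError(f"unknown stage {kind!r}")  # pragma: no cover


def run_pipeline(config: Dict[str, Any], base_dir: str | Path = ".") -> AnalysisReport:
    """Validate, then execute every configured stage in order."""
    base_dir = Path(base_dir)
    validate_config(config, base_dir)
    report = AnalysisReport(settings={"base_dir": str(base_dir)})
    for k, stage in enumerate(config["stages"]):
        name = stage.get("name", f"{stage['stage']}-{k}")
        report.inputs[name] = _jsonable(
            {key: val for key, val in stage.items() if key != "name"}
        )
        try:
            result = _run_stage(stage, base_dir)
            report.results[name] = {"status": "ok", "output": _jsonable(result)}
            log.info("stage %s: ok", name)
        except Exception as exc:  # per-stage failure is a result, not a crash
            report.results[name] = {"status": "error", "error": str(exc)}
            log.warning("stage %s: failed (%s)", name, exc)
    return report
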