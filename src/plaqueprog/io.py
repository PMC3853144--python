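"""Readers/writers and run configuration for the end-to-end pipeline."""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from plaqueprog.vessel_geometry import (
    MatchedPairDataset,
    NodeGrid,
    NODE_COLUMNS,
    STRESS_COLUMNS,
)
from plaqueprog.cohort import CohortConfig, GroundTruth

log = logging.getLogger("plaqueprog")


@dataclasses.dataclass
class PipelineConfig:
    """Resolved settings for one pipeline run; round-trips through YAML."""

    cohort: CohortConfig = dataclasses.field(default_factory=CohortConfig)
    alpha: float = 0.05
    n_permutations: int = 200
    permutation_scope: str = "within_patient"
    out_dir: str = "results/run"
    seed: int = 0
    verbosity: str = "INFO"

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["cohort"]["nodes_range"] = list(d["cohort"]["nodes_range"])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        cohort = d.pop("cohort", {})
        if "nodes_range" in cohort:
            cohort["nodes_range"] = tuple(cohort["nodes_range"])
        return cls(cohort=CohortConfig(**cohort), **d)

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


def write_config(config: PipelineConfig, path) -> None:
    Path(path).write_text(yaml.safe_dump(config.to_dict(), sort_keys=True))


def read_config(path) -> PipelineConfig:
    return PipelineConfig.from_dict(yaml.safe_load(Path(path).read_text()))


def write_node_grid(grid: NodeGrid, path) -> None:
    """Node table CSV (UTF-8, '.' decimal): the package's geometry dialect."""
    frame = grid.to_frame()
    cols = NODE_COLUMNS + [c for c in STRESS_COLUMNS if c in frame.columns]
    frame[cols].to_csv(path, index=False)


def read_node_grid(path) -> NodeGrid:
    frame = pd.read_csv(path)
    missing = set(NODE_COLUMNS) - set(frame.columns)
    if missing:
        raise ValueError(f"node CSV missing columns: {sorted(missing)}")
    patients = frame["patient_id"].unique()
    scans = frame["scan_id"].unique()
    if len(patients) != 1 or len(scans) != 1:
        raise ValueError("node CSV must hold exactly one (patient, scan)")
    table = frame.drop(columns=["patient_id", "scan_id"])
    return NodeGrid(patient_id=str(patients[0]), scan_id=int(scans[0]), table=table)


def write_pair_dataset(pair: MatchedPairDataset, path) -> None:
    frame = pair.table.copy()
    frame.insert(0, "period", pair.period_label)
    frame.insert(0, "patient_id", pair.patient_id)
    frame.to_csv(path, index=False)


def read_pair_dataset(path) -> MatchedPairDataset:
    frame = pd.read_csv(path)
    patient = frame["patient_id"].iloc[0]
    period = frame["period"].iloc[0]
    return MatchedPairDataset(
        patient_id=str(patient),
        period_label=str(period),
        table=frame.drop(columns=["patient_id", "period"]),
    )


def write_ground_truth(truth: GroundTruth, path) -> None:
    Path(path).write_text(json.dumps(dataclasses.asdict(truth), indent=2, default=_jsonify))


def write_json(obj, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, default=_jsonify))


def _jsonify(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    raise TypeError(f"not JSON-serialisable: {type(obj)}")


def fits_to_table(rows: list[dict]) -> pd.DataFrame:
    """Per-pair fit results as a (patient, period, nodes, p, r) table."""
    return pd.DataFrame(rows, columns=["patient", "period", "nodes", "p", "r"])
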