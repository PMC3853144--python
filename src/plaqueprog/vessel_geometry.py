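"""Idealised carotid node grids and baseline/follow-up scan matching.

A scan is represented as a stack of cross-sectional slices along the
vessel axis (z, mm), each carrying 100 lumen nodes evenly spaced in
angle.  The carotid bifurcation is the registration landmark: slice 0
sits at the bifurcation, negative slice indices run down the common
carotid artery (CCA), positive indices up the internal carotid artery
(ICA).  Slice spacing is 2 mm, matching the MRI slice thickness of the
serial-imaging protocol this geometry idealises.

Wall thickness increase (WTI) at a matched node is

    WTI = wall thickness at follow-up - wall thickness at baseline   (mm)

and is the progression response used by :mod:`plaqueprog.spatial_lme`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
import pandas as pd

NODES_PER_SLICE = 100
SLICE_SPACING_MM = 2.0

#: canonical column order of the node-table CSV dialect
NODE_COLUMNS = [
    "patient_id",
    "scan_id",
    "slice_index",
    "node_index",
    "x_mm",
    "y_mm",
    "z_mm",
    "wall_thickness_mm",
]
STRESS_COLUMNS = ["pws_kpa", "fss_dyn_cm2"]


class GeometryError(ValueError):
    """Invalid vessel geometry input or incompatible scans."""


@dataclass
class NodeGrid:
    """Per-scan table of lumen nodes.

    ``table`` columns: slice_index, node_index, x_mm, y_mm, z_mm,
    wall_thickness_mm and, after stress painting, pws_kpa / fss_dyn_cm2.
    ``segment`` is derived from slice_index (CCA < 0, bifurcation = 0,
    ICA > 0).
    """

    patient_id: str
    scan_id: int
    table: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        t = self.table
        if not np.all(np.isfinite(t[["x_mm", "y_mm", "z_mm"]].to_numpy())):
            raise GeometryError("non-finite node coordinates")
        if not np.all(t["wall_thickness_mm"].to_numpy() > 0):
            raise GeometryError("wall thickness must be positive at every node")
        counts = t.groupby("slice_index")["node_index"].count()
        if not np.all(counts.to_numpy() == NODES_PER_SLICE):
            bad = counts[counts != NODES_PER_SLICE].index.tolist()
            raise GeometryError(f"slices {bad} do not carry {NODES_PER_SLICE} nodes")

    @property
    def slice_indices(self) -> np.ndarray:
        return np.sort(self.table["slice_index"].unique())

    @property
    def n_nodes(self) -> int:
        return len(self.table)

    def coords(self) -> np.ndarray:
        return self.table[["x_mm", "y_mm", "z_mm"]].to_numpy(float)

    def segment_labels(self) -> pd.Series:
        s = self.table["slice_index"]
        return pd.Series(
            np.where(s < 0, "CCA", np.where(s == 0, "bifurcation", "ICA")),
            index=self.table.index,
            name="segment",
        )

    def to_frame(self) -> pd.DataFrame:
        """Node table in the CSV dialect (patient/scan columns included)."""
        out = self.table.copy()
        out.insert(0, "scan_id", self.scan_id)
        out.insert(0, "patient_id", self.patient_id)
        return out


@dataclass
class MatchedPairDataset:
    """Registered baseline/follow-up node pairs with WTI and baseline stresses.

    ``table`` columns: slice_index, node_index, x_mm, y_mm, z_mm (baseline
    geometry), wt_baseline_mm, wt_followup_mm, wti_mm and optionally
    pws_kpa / fss_dyn_cm2 (baseline stresses).
    """

    patient_id: str
    period_label: str
    table: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        wti = self.table["wti_mm"].to_numpy(float)
        diff = (
            self.table["wt_followup_mm"].to_numpy(float)
            - self.table["wt_baseline_mm"].to_numpy(float)
        )
        if not np.allclose(wti, diff, rtol=0, atol=1e-12):
            raise GeometryError("wti_mm is not follow-up minus baseline thickness")
        if (self.table["slice_index"] == 0).any():
            raise GeometryError("bifurcation slice must not enter a matched dataset")

    @property
    def n_nodes(self) -> int:
        return len(self.table)

    def coords(self) -> np.ndarray:
        return self.table[["x_mm", "y_mm", "z_mm"]].to_numpy(float)

    def has_predictor(self, predictor: str) -> bool:
        return _predictor_column(predictor) in self.table.columns


class RegressionArrays(NamedTuple):
    """Aligned (coords, x, y) arrays for one scan pair plus a degeneracy flag."""

    coords: np.ndarray
    x: np.ndarray
    y: np.ndarray
    degenerate: bool


def _predictor_column(predictor: str) -> str:
    key = predictor.strip().lower()
    if key == "pws":
        return "pws_kpa"
    if key == "fss":
        return "fss_dyn_cm2"
    raise ValueError(f"unknown predictor {predictor!r}; expected 'PWS' or 'FSS'")


def build_cylinder_grid(
    patient_id: str,
    scan_id: int,
    n_slices_cca: int,
    n_slices_ica: int,
    lumen_radius_profile,
    wall_thickness_profile,
) -> NodeGrid:
    """Build an idealised straight-tube carotid grid.

    Slices run from ``-n_slices_cca`` to ``+n_slices_ica``; the slice at
    index 0 is the bifurcation landmark.  Slice i sits at z = 2*i mm.
    ``lumen_radius_profile`` gives one lumen radius (mm) per slice in
    ascending slice order; ``wall_thickness_profile`` is per-slice
    per-node, shape (n_slices, 100), in mm.
    """
    if n_slices_cca < 1 or n_slices_ica < 1:
        raise GeometryError("need at least one slice on each side of the bifurcation")
    slice_ids = np.arange(-n_slices_cca, n_slices_ica + 1)
    n_slices = len(slice_ids)
    radii = np.asarray(lumen_radius_profile, float)
    thick = np.asarray(wall_thickness_profile, float)
    if radii.shape != (n_slices,):
        raise GeometryError(
            f"lumen_radius_profile must have {n_slices} entries, got {radii.shape}"
        )
    if thick.shape != (n_slices, NODES_PER_SLICE):
        raise GeometryError(
            f"wall_thickness_profile must have shape ({n_slices}, {NODES_PER_SLICE})"
        )
    for i, s in enumerate(slice_ids):
        if not radii[i] > 0:
            raise GeometryError(f"non-positive lumen radius at slice {s}")
        if not np.all(thick[i] > 0):
            raise GeometryError(f"non-positive wall thickness at slice {s}")

    theta = 2.0 * np.pi * np.arange(NODES_PER_SLICE) / NODES_PER_SLICE
    rows = []
    for i, s in enumerate(slice_ids):
        rows.append(
            pd.DataFrame(
                {
                    "slice_index": s,
                    "node_index": np.arange(NODES_PER_SLICE),
                    "x_mm": radii[i] * np.cos(theta),
                    "y_mm": radii[i] * np.sin(theta),
                    "z_mm": SLICE_SPACING_MM * float(s),
                    "wall_thickness_mm": thick[i],
                }
            )
        )
    table = pd.concat(rows, ignore_index=True)
    return NodeGrid(patient_id=patient_id, scan_id=int(scan_id), table=table)


def match_scan_pair(
    baseline: NodeGrid, followup: NodeGrid, period_label: str | None = None
) -> MatchedPairDataset:
    """Register two scans at the bifurcation and compute node-wise WTI.

    Nodes are matched by (slice offset from the bifurcation, angular
    index); slices present in only one scan are dropped, and only CCA and
    ICA slices (the bifurcation slice excluded) enter the dataset.
    Baseline coordinates carry over — spatial correlation downstream is
    computed on the baseline configuration.
    """
    if baseline.patient_id != followup.patient_id:
        raise GeometryError(
            f"patient mismatch: {baseline.patient_id!r} vs {followup.patient_id!r}"
        )
    for grid, name in ((baseline, "baseline"), (followup, "follow-up")):
        if 0 not in grid.slice_indices:
            raise GeometryError(f"{name} scan has no bifurcation slice (index 0)")

    common = np.intersect1d(baseline.slice_indices, followup.slice_indices)
    common = common[common != 0]
    if common.size == 0:
        raise GeometryError("no overlapping CCA/ICA slices between the two scans")

    keep = ["slice_index", "node_index", "x_mm", "y_mm", "z_mm", "wall_thickness_mm"]
    base = baseline.table[baseline.table["slice_index"].isin(common)]
    carried = [c for c in STRESS_COLUMNS if c in base.columns]
    base = base[keep + carried].rename(columns={"wall_thickness_mm": "wt_baseline_mm"})
    fu = followup.table[followup.table["slice_index"].isin(common)]
    fu = fu[["slice_index", "node_index", "wall_thickness_mm"]].rename(
        columns={"wall_thickness_mm": "wt_followup_mm"}
    )
    merged = base.merge(fu, on=["slice_index", "node_index"], how="inner")
    merged = merged.sort_values(["slice_index", "node_index"]).reset_index(drop=True)
    merged["wti_mm"] = merged["wt_followup_mm"] - merged["wt_baseline_mm"]
    if period_label is None:
        period_label = f"T{baseline.scan_id}-T{followup.scan_id}"
    return MatchedPairDataset(
        patient_id=baseline.patient_id, period_label=period_label, table=merged
    )


def extract_regression_arrays(
    dataset: MatchedPairDataset, predictor: str
) -> RegressionArrays:
    """Aligned (coords, x, y) arrays for the spatial regression.

    ``x`` is the baseline stress field named by ``predictor`` ("PWS" or
    "FSS"), ``y`` is WTI.  A constant predictor is returned but flagged
    ``degenerate`` so the model stage can refuse it explicitly.
    """
    if dataset.n_nodes == 0:
        raise GeometryError("empty matched dataset")
    col = _predictor_column(predictor)
    if col not in dataset.table.columns:
        raise GeometryError(
            f"dataset for {dataset.patient_id} has no {predictor.upper()} field"
        )
    x = dataset.table[col].to_numpy(float)
    y = dataset.table["wti_mm"].to_numpy(float)
    if np.isnan(x).any() or np.isnan(y).any():
        raise GeometryError("missing values in regression arrays")
    degenerate = bool(np.ptp(x) < 1e-12)
    return RegressionArrays(dataset.coords(), x, y, degenerate)
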