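"""Sign classification and longitudinal sign-change bookkeeping.

Each scan pair's fitted correlation is classified at level alpha = 0.05:

- ``P``  — significantly positive: p < alpha and r > 0;
- ``N``  — significantly negative: p < alpha and r < 0;
- ``NS`` — otherwise (no significant correlation).

A patient "kept" the correlation sign when every one of at least two
observed periods carries the same significant category (all P or all N);
patients observed in a single period cannot demonstrate reproducibility
and count as not kept, as does any transition into NS.

The package ships reference per-pair correlation tables (patient,
period, node count, p, r for WTI vs baseline PWS and vs baseline FSS)
transcribed from the published 16-patient serial carotid MRI study these
analyses model; :func:`reproduce_tables` re-derives every per-period
count, total and sign-grid entry from those raw cells.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd

ALPHA = 0.05
CATEGORIES = ("P", "N", "NS")
PERIODS = ("T1-T2", "T2-T3", "T3-T4")

#: published summary figures for patients changing the FSS correlation sign
#: disagree between the study's abstract (12, 75%) and results text
#: (14, 87.5%); both are flagged in the report next to the derived value.
FSS_CHANGED_PUBLISHED = {"abstract": 12, "results": 14}


@dataclass
class SignSummary:
    """Per-period counts and longitudinal kept/changed bookkeeping."""

    predictor: str
    period_counts: dict[str, tuple[int, int, int]]  # period -> (P, N, NS)
    total_counts: tuple[int, int, int]
    kept_by_patient: dict[str, bool]
    n_kept: int
    n_changed_or_ns: int
    pct_kept: float
    pct_changed_or_ns: float

    @property
    def n_patients(self) -> int:
        return len(self.kept_by_patient)


def classify(p_value: float, r_value: float, alpha: float = ALPHA) -> str:
    """Sign category of one scan pair; p exactly equal to alpha is NS.

    A p printed as 0.0000 (rounded below 5e-5) is simply a small number
    and classifies as significant like any p < alpha.
    """
    if not (0 <= p_value <= 1):
        raise ValueError(f"p-value {p_value} outside [0, 1]")
    if p_value < alpha and r_value > 0:
        return "P"
    if p_value < alpha and r_value < 0:
        return "N"
    return "NS"


def classify_records(records: pd.DataFrame, alpha: float = ALPHA) -> pd.DataFrame:
    """Add a ``category`` column to a (patient, period, p, r) table."""
    out = records.copy()
    out["category"] = [
        classify(p, r, alpha) for p, r in zip(out["p"], out["r"])
    ]
    return out


def count_period(records: pd.DataFrame, alpha: float = ALPHA):
    """(P, N, NS) counts over the records of one predictor and period."""
    if records.duplicated(subset=["patient"]).any():
        dupes = records.loc[records.duplicated(subset=["patient"]), "patient"]
        raise ValueError(f"duplicate patient records: {sorted(set(dupes))}")
    if len(records) == 0:
        return (0, 0, 0)
    cats = classify_records(records, alpha)["category"]
    return (
        int((cats == "P").sum()),
        int((cats == "N").sum()),
        int((cats == "NS").sum()),
    )


def sign_kept(categories) -> bool:
    """True iff >= 2 observed periods all share the same significant sign."""
    cats = [c for c in categories if c is not None and c == c]
    if len(cats) < 2:
        return False
    return all(c == cats[0] for c in cats) and cats[0] in ("P", "N")


def sign_grid(records: pd.DataFrame, alpha: float = ALPHA) -> pd.DataFrame:
    """Per-patient period-by-period category grid plus the kept flag.

    Rows indexed by patient; period columns hold P/N/NS or NaN where the
    patient was not observed.
    """
    cats = classify_records(records, alpha)
    grid = cats.pivot(index="patient", columns="period", values="category")
    grid = grid.reindex(columns=list(PERIODS))
    grid = grid.reindex(
        sorted(grid.index, key=lambda s: (len(s), s))  # P1, P2, ... P16
    )
    grid["sign_kept"] = [
        sign_kept(row[list(PERIODS)].tolist()) for _, row in grid.iterrows()
    ]
    return grid


def summarize(records: pd.DataFrame, predictor: str, alpha: float = ALPHA) -> SignSummary:
    """Full sign summary for one predictor's per-pair records."""
    if records.empty:
        raise ValueError("no records to summarize")
    period_counts = {}
    totals = np.zeros(3, int)
    for period in PERIODS:
        sub = records[records["period"] == period]
        counts = count_period(sub, alpha)
        if len(sub):
            period_counts[period] = counts
        totals += np.asarray(counts)
    grid = sign_grid(records, alpha)
    kept = {pid: bool(v) for pid, v in grid["sign_kept"].items()}
    n_patients = len(kept)
    n_kept = sum(kept.values())
    return SignSummary(
        predictor=predictor,
        period_counts=period_counts,
        total_counts=tuple(int(c) for c in totals),
        kept_by_patient=kept,
        n_kept=n_kept,
        n_changed_or_ns=n_patients - n_kept,
        pct_kept=round(100.0 * n_kept / n_patients, 2),
        pct_changed_or_ns=round(100.0 * (n_patients - n_kept) / n_patients, 2),
    )


def load_reference_table(predictor: str) -> pd.DataFrame:
    """Packaged per-pair (patient, period, nodes, p, r) reference table."""
    key = predictor.strip().lower()
    if key not in ("pws", "fss"):
        raise ValueError(f"unknown predictor {predictor!r}")
    path = resources.files("plaqueprog.data").joinpath(f"reference_{key}.csv")
    with resources.as_file(path) as f:
        table = pd.read_csv(f)
    expected = {"patient", "period", "nodes", "p", "r"}
    if set(table.columns) != expected:
        raise ValueError(f"reference table schema mismatch: {list(table.columns)}")
    return table


def reproduce_tables(alpha: float = ALPHA) -> dict:
    """Re-derive all summary counts and the sign grid from the raw cells.

    Returns a dict with, per predictor: per-period (P, N, NS) counts,
    totals over the 38 pairs, the per-patient sign grid, kept counts and
    percentages.  The FSS entry also flags the two mutually inconsistent
    published changed-sign figures next to the derived value.
    """
    report: dict = {}
    for predictor in ("PWS", "FSS"):
        records = load_reference_table(predictor)
        summary = summarize(records, predictor, alpha)
        grid = sign_grid(records, alpha)
        entry = {
            "n_pairs": int(len(records)),
            "period_counts": {k: list(v) for k, v in summary.period_counts.items()},
            "total_counts": list(summary.total_counts),
            "sign_grid": grid.reset_index().to_dict(orient="records"),
            "n_kept": summary.n_kept,
            "n_changed_or_ns": summary.n_changed_or_ns,
            "pct_kept": summary.pct_kept,
            "pct_changed_or_ns": summary.pct_changed_or_ns,
        }
        if predictor == "FSS":
            entry["published_changed_sign_figures"] = dict(FSS_CHANGED_PUBLISHED)
            entry["derived_changed_or_ns"] = summary.n_changed_or_ns
        report[predictor] = entry
    return report
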