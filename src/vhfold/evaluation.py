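"""Test-set evaluation: per-structure region RMSDs and aggregate tables.

Produces the standard report shape for variable-domain modelling: whole
domain (own optimal fit), frame, and the three CDR loops measured in the
frame superposition, plus breakdowns by CDR3 loop length and by maximal
sequence identity (MSI) to the training set.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from . import regions as regions_mod
from .geometry import region_rmsd
from .structure_io import BackboneStructure

REGION_COLUMNS = ["whole_domain", "frame", "cdr1", "cdr2", "cdr3"]


@dataclass
class EvalRecord:
    record_id: str
    whole_domain: float
    frame: float
    cdr1: float
    cdr2: float
    cdr3: float
    cdr3_length: int
    msi: float | None = None

    def validate(self) -> None:
        vals = [self.whole_domain, self.frame, self.cdr1, self.cdr2, self.cdr3]
        if any(not np.isfinite(v) or v < 0 for v in vals):
            raise ValueError("RMSDs must be finite and non-negative")
        if self.cdr3_length < 1:
            raise ValueError("cdr3_length must be >= 1")


def evaluate_pair(model: BackboneStructure, reference: BackboneStructure,
                  numbering=None, msi: float | None = None,
                  boundaries=regions_mod.DEFAULT_BOUNDARIES) -> EvalRecord:
    """Region RMSD record for one model/reference pair (same sequence)."""
    if model.sequence != reference.sequence:
        raise ValueError("model and reference sequences differ")
    rm = regions_mod.assign_regions(reference.sequence, numbering=numbering,
                                    boundaries=boundaries)
    report = region_rmsd(model, reference, rm)
    rec = EvalRecord(model.source_id or reference.source_id,
                     report.whole_domain, report.frame,
                     report.cdr1, report.cdr2, report.cdr3,
                     cdr3_length=rm.cdr3_length, msi=msi)
    rec.validate()
    return rec


def records_frame(records: list[EvalRecord]) -> pd.DataFrame:
    return pd.DataFrame([{
        "id": r.record_id, **{c: getattr(r, c) for c in REGION_COLUMNS},
        "cdr3_length": r.cdr3_length, "msi": r.msi,
    } for r in records])


def aggregate(records: list[EvalRecord]) -> pd.DataFrame:
    """Mean, sample sd and median per region, in the standard table shape.

    A single record yields sd 0 with an ``n=1`` flag column.
    """
    if not records:
        raise ValueError("no records to aggregate")
    df = records_frame(records)
    n = len(df)
    rows = []
    for col in REGION_COLUMNS:
        rows.append({
            "region": col,
            "mean": df[col].mean(),
            "sd": df[col].std(ddof=1) if n > 1 else 0.0,
            "median": df[col].median(),
            "n": n,
            "sd_undefined": n == 1,
        })
    return pd.DataFrame(rows)


def format_table(summary: pd.DataFrame) -> str:
    """Delimited text report: region, mean±sd, median, n."""
    lines = ["region\tmean±sd\tmedian\tn"]
    for _, row in summary.iterrows():
        lines.append(f"{row['region']}\t{row['mean']:.2f}±{row['sd']:.2f}"
                     f"\t{row['median']:.2f}\t{int(row['n'])}")
    return "\n".join(lines) + "\n"


def rmsd_vs_length(records: list[EvalRecord]) -> pd.DataFrame:
    """Mean CDR3 RMSD per CDR3 loop length, with counts."""
    df = records_frame(records)
    grouped = df.groupby("cdr3_length")["cdr3"].agg(["mean", "count"]).reset_index()
    return grouped.rename(columns={"mean": "cdr3_rmsd_mean", "count": "n"})


def rmsd_vs_msi(records: list[EvalRecord], bin_edges: list[float]
                ) -> tuple[pd.DataFrame, float | None]:
    """Half-open MSI bins plus a Spearman rank correlation of MSI vs whole-domain RMSD.

    Returns (binned report, rho); rho is None when MSI is constant (flagged).
    """
    df = records_frame(records)
    if df["msi"].isna().any():
        raise ValueError("all records must carry an MSI value")
    labels = [f"[{lo:g},{hi:g})" for lo, hi in zip(bin_edges[:-1], bin_edges[1:])]
    df["msi_bin"] = pd.cut(df["msi"], bins=bin_edges, right=False, labels=labels)
    binned = (df.groupby("msi_bin", observed=False)["whole_domain"]
              .agg(["mean", "median", "count"]).reset_index()
              .rename(columns={"mean": "rmsd_mean", "median": "rmsd_median", "count": "n"}))
    if df["msi"].nunique() < 2:
        return binned, None
    rho = stats.spearmanr(df["msi"], df["whole_domain"]).statistic
    return binned, float(rho)
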