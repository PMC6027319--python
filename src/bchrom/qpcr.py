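"""Gene dosage ratios from qPCR Ct values by the 2^-dCT method.

The gene dosage ratio GDR = 2^-(Ct_target - Ct_normalizer) estimates the
genomic copy number of a target sequence relative to a single-copy gene
(HPRT here), assuming perfect per-cycle doubling.  Comparing mean GDRs of
B-carrying and B-free individuals quantifies B-chromosome amplification.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import pandas as pd

logger = logging.getLogger(__name__)


class QPCRError(ValueError):
    pass


@dataclass(frozen=True)
class GDRRecord:
    sample_id: str
    ct_target: float
    ct_hprt: float

    @property
    def delta_ct(self) -> float:
        return self.ct_target - self.ct_hprt

    @property
    def gdr(self) -> float:
        return 2.0 ** (-self.delta_ct)


def gene_dosage_ratio(
    ct_target: float, ct_hprt: float, sample_id: str = ""
) -> GDRRecord:
    """2^-dCT gene dosage ratio for one sample."""
    for name, ct in (("target", ct_target), ("normalizer", ct_hprt)):
        if ct is None or not math.isfinite(ct) or ct <= 0:
            raise QPCRError(f"{sample_id}: {name} Ct must be positive and finite")
    return GDRRecord(sample_id, ct_target, ct_hprt)


def gdr_table(ct_table: pd.DataFrame) -> pd.DataFrame:
    """GDR per sample from a Ct table.

    Expects columns sample_id, ct_target, ct_hprt and optionally group.
    Technical replicates (repeated sample_id rows) are averaged on the Ct
    scale before dCT.  Rows with missing Ct are skipped with a warning.
    """
    required = {"sample_id", "ct_target", "ct_hprt"}
    if not required <= set(ct_table.columns):
        raise QPCRError(f"Ct table must have columns {sorted(required)}")
    agg: dict[str, str | callable] = {"ct_target": "mean", "ct_hprt": "mean"}
    if "group" in ct_table.columns:
        agg["group"] = "first"
    merged = ct_table.groupby("sample_id", sort=False).agg(agg).reset_index()
    rows = []
    for _, row in merged.iterrows():
        if pd.isna(row["ct_target"]) or pd.isna(row["ct_hprt"]):
            logger.warning("sample %s: missing Ct, skipped", row["sample_id"])
            continue
        rec = gene_dosage_ratio(row["ct_target"], row["ct_hprt"], row["sample_id"])
        rows.append(
            {
                "sample_id": rec.sample_id,
                "group": row.get("group", ""),
                "delta_ct": rec.delta_ct,
                "gdr": rec.gdr,
            }
        )
    return pd.DataFrame(rows)


def group_fold(
    gdr: pd.DataFrame, group_b: str = "B+", group_0: str = "B-"
) -> dict[str, float | bool]:
    """Mean GDR per group, the B+:B- fold, and whether the groups separate.

    ``separated`` is True when every B+ GDR exceeds every B- GDR.
    """
    for g in (group_b, group_0):
        if (gdr["group"] == g).sum() < 1:
            raise QPCRError(f"empty group {g}")
    b_vals = gdr.loc[gdr["group"] == group_b, "gdr"]
    o_vals = gdr.loc[gdr["group"] == group_0, "gdr"]
    return {
        "mean_b_plus": float(b_vals.mean()),
        "mean_b_minus": float(o_vals.mean()),
        "fold": float(b_vals.mean() / o_vals.mean()),
        "separated": bool(b_vals.min() > o_vals.max()),
    }
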