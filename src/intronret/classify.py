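"""Intron categorisation from Z scores and IRSdiff.

Procedure (on the coverage-filtered, tested introns):

1. introns with irs_diff < 0 AND z < 0 are set aside as ``EXCLUDED_NEGATIVE``
   (likely false positives; they take no part in cutoff derivation);
2. Z scores of the remainder are split into quartiles (descending
   convention); the minimum irs_diff among introns above the first-quartile
   threshold becomes the affected/unaffected cutoff ``c``;
3. irs_diff >= c -> affected, else ``UNAFFECTED``;
4. affected introns with irs_diff > strong_cut (default 2, strict) are
   ``STRONGLY_AFFECTED``, the rest ``MILDLY_AFFECTED``;
5. independently of the category, ``high_confidence_z`` records z > the
   first-quartile threshold (the high-Z "strongly affected" set used by the
   sequence-feature analyses).
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np
import pandas as pd


class IntronCategory(str, Enum):
    STRONGLY_AFFECTED = "STRONGLY_AFFECTED"
    MILDLY_AFFECTED = "MILDLY_AFFECTED"
    UNAFFECTED = "UNAFFECTED"
    EXCLUDED_NEGATIVE = "EXCLUDED_NEGATIVE"
    LOW_COVERAGE = "LOW_COVERAGE"


def z_quartiles(z_scores, method: str = "midpoint") -> tuple[float, float]:
    """Quartile thresholds of Z scores under the descending-sort convention.

    Returns ``(q1_threshold, q3_threshold)``: the values above which the top
    25% and top 75% of the Z scores lie.  ``method`` is any numpy quantile
    interpolation rule (default midpoint).
    """
    z = np.asarray(z_scores, dtype=float)
    if z.size < 4:
        raise ValueError("need at least 4 z scores to form quartiles")
    bad = np.flatnonzero(~np.isfinite(z))
    if bad.size:
        raise ValueError(f"non-finite z scores at positions {bad.tolist()}")
    q1 = float(np.quantile(z, 0.75, method=method))
    q3 = float(np.quantile(z, 0.25, method=method))
    return q1, q3


@dataclass
class ClassificationResult:
    """Category table plus the thresholds the procedure derived."""

    table: pd.DataFrame  # intron_id, category, z_score, irs_diff, high_confidence_z
    q1_threshold: float
    q3_threshold: float
    irs_diff_cutoff: float

    def counts(self) -> dict[str, int]:
        c = self.table["category"].value_counts()
        return {cat.value: int(c.get(cat.value, 0)) for cat in IntronCategory}


def classify_introns(
    summaries: pd.DataFrame,
    strong_cut: float = 2.0,
    quantile_method: str = "midpoint",
) -> ClassificationResult:
    """Assign each tested intron exactly one category.

    ``summaries`` is the condition-summary table (needs intron_id, irs_diff,
    z_score and, if present, a ``tested`` flag; untested rows are ignored).
    Ties at ``strong_cut`` (irs_diff exactly equal) count as mildly affected.
    """
    df = summaries
    if "tested" in df.columns:
        df = df[df["tested"]]
    df = df[["intron_id", "irs_diff", "z_score"]].reset_index(drop=True)

    negative = (df["irs_diff"] < 0) & (df["z_score"] < 0)
    rest = df[~negative]
    q1, q3 = z_quartiles(rest["z_score"].to_numpy(), method=quantile_method)
    top = rest[rest["z_score"] > q1]
    if top.empty:
        raise ValueError("no introns above the first-quartile Z threshold")
    cutoff = float(top["irs_diff"].min())

    category = np.where(
        negative,
        IntronCategory.EXCLUDED_NEGATIVE.value,
        np.where(
            df["irs_diff"] >= cutoff,
            np.where(
                df["irs_diff"] > strong_cut,
                IntronCategory.STRONGLY_AFFECTED.value,
                IntronCategory.MILDLY_AFFECTED.value,
            ),
            IntronCategory.UNAFFECTED.value,
        ),
    )
    table = pd.DataFrame(
        {
            "intron_id": df["intron_id"],
            "category": category,
            "z_score": df["z_score"],
            "irs_diff": df["irs_diff"],
            "high_confidence_z": (df["z_score"] > q1) & ~negative,
        }
    )
    return ClassificationResult(table=table, q1_threshold=q1, q3_threshold=q3, irs_diff_cutoff=cutoff)
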