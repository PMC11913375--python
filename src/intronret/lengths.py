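"""Intron-length stratification of splicing defects.

Default bins follow the short/ultra-short intron classes of the analysed
transcriptome: 20-40, 40-60, 60-100, 100-500 and >500 nt, lower-inclusive /
upper-exclusive so shared edges are not double counted.  A 10-nt preset over
[20, 100) supports the fine-resolution scan.  Between-bin comparisons use
two-sided Wilcoxon rank-sum tests: exact enumeration of all splits (with
mid-ranks for ties) when the pooled sample is small, normal approximation
with tie correction otherwise.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations as _combinations
from math import comb
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .features import group_irs_curves

logger = logging.getLogger(__name__)

DEFAULT_EDGES = (20, 40, 60, 100, 500, None)
#: pooled sample size up to which the rank-sum test enumerates all splits
EXACT_LIMIT = 20


@dataclass(frozen=True)
class LengthBin:
    label: str
    lower: int  # inclusive
    upper: int | None  # exclusive; None = unbounded


def make_bins(edges: Sequence[int | None] = DEFAULT_EDGES) -> list[LengthBin]:
    """Length bins from an edge sequence (last edge may be None = open)."""
    finite = [e for e in edges if e is not None]
    if sorted(finite) != finite or len(set(finite)) != len(finite):
        raise ValueError("bin edges must be strictly increasing")
    bins = []
    for lo, hi in zip(edges, edges[1:]):
        label = f"{lo}-{hi}" if hi is not None else f">={lo}"
        bins.append(LengthBin(label=label, lower=lo, upper=hi))
    return bins


def ten_nt_bins(lower: int = 20, upper: int = 100) -> list[LengthBin]:
    """The 10-nt-resolution preset over [lower, upper)."""
    return make_bins(tuple(range(lower, upper + 1, 10)))


def bin_by_length(
    lengths: Mapping[str, int] | pd.DataFrame,
    bins: Sequence[LengthBin] | None = None,
) -> pd.DataFrame:
    """Assign each intron to exactly one length bin.

    ``lengths``: mapping intron_id -> length, or a DataFrame with intron_id
    and length columns.  Introns shorter than the first edge get bin label
    ``"<{first}"`` (reported, but excluded from the standard bins); anything
    beyond the last finite edge of a bounded partition gets ``">={last}"``
    only if such an open bin exists, else label ``"unbinned"``.
    """
    if bins is None:
        bins = make_bins()
    if isinstance(lengths, pd.DataFrame):
        items = list(zip(lengths["intron_id"], lengths["length"]))
    else:
        items = list(lengths.items())
    first_edge = bins[0].lower
    rows = []
    for intron_id, length in items:
        if length < 1:
            raise ValueError(f"intron {intron_id}: length must be >= 1")
        if length < first_edge:
            label = f"<{first_edge}"
        else:
            label = "unbinned"
            for b in bins:
                if length >= b.lower and (b.upper is None or length < b.upper):
                    label = b.label
                    break
        rows.append({"intron_id": intron_id, "length": length, "bin": label})
    return pd.DataFrame(rows)


def rank_sum_test(a: Sequence[float], b: Sequence[float]) -> float:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) p value.

    Exact path (pooled n <= EXACT_LIMIT): mid-ranks of the pooled sample,
    then enumeration of every assignment of ranks to group A; the p value is
    the fraction of splits whose U statistic is at least as far from its null
    mean as the observed one.  Larger samples use the tie-corrected normal
    approximation.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    n1, n2 = a.size, b.size
    if n1 == 0 or n2 == 0:
        raise ValueError("both samples must be non-empty")
    if n1 + n2 <= EXACT_LIMIT:
        pooled = np.concatenate([a, b])
        ranks = stats.rankdata(pooled)  # mid-ranks
        mu = n1 * (n1 + n2 + 1) / 2.0  # null mean of the rank sum of A
        obs = ranks[:n1].sum()
        dev = abs(obs - mu) - 1e-9
        hits = 0
        for idx in _combinations(range(n1 + n2), n1):
            if abs(ranks[list(idx)].sum() - mu) >= dev:
                hits += 1
        return hits / comb(n1 + n2, n1)
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
    return float(res.pvalue)


def compare_bins(values_by_bin: Mapping[str, Sequence[float]]) -> pd.DataFrame:
    """All-vs-all rank-sum p-value matrix between length bins.

    Bins with no values are excluded with a warning.  Returns a symmetric
    DataFrame (diagonal 1.0) indexed by bin label.
    """
    usable = {k: np.asarray(v, dtype=float) for k, v in values_by_bin.items() if len(v) > 0}
    for k in values_by_bin:
        if k not in usable:
            logger.warning("bin %s has no values; excluded from comparisons", k)
    if len(usable) < 2:
        raise ValueError("need at least 2 non-empty bins to compare")
    labels = list(usable)
    mat = pd.DataFrame(np.ones((len(labels), len(labels))), index=labels, columns=labels)
    for i, j in _combinations(range(len(labels)), 2):
        p = rank_sum_test(usable[labels[i]], usable[labels[j]])
        mat.iloc[i, j] = p
        mat.iloc[j, i] = p
    return mat


def length_defect_profile(
    summaries: pd.DataFrame,
    assignments: pd.DataFrame,
    categories: pd.DataFrame | None = None,
):
    """Per-bin retention summaries, ECDF tables and category composition.

    ``summaries``: condition-summary table (mean_wt, irs_diff per intron).
    ``assignments``: output of :func:`bin_by_length`.
    ``categories``: optional category table for the per-bin composition.

    Returns ``(profiles, ecdf, composition)`` DataFrames; composition is None
    when no categories are given.
    """
    merged = assignments.merge(summaries, on="intron_id", how="inner")
    rows = []
    diff_by_bin: dict[str, np.ndarray] = {}
    for label, sub in merged.groupby("bin", sort=False):
        q = sub[["mean_wt", "irs_diff"]].quantile([0.25, 0.5, 0.75])
        rows.append(
            {
                "bin": label,
                "n": len(sub),
                "irs_wt_q1": q.loc[0.25, "mean_wt"],
                "irs_wt_median": q.loc[0.5, "mean_wt"],
                "irs_wt_q3": q.loc[0.75, "mean_wt"],
                "irs_diff_q1": q.loc[0.25, "irs_diff"],
                "irs_diff_median": q.loc[0.5, "irs_diff"],
                "irs_diff_q3": q.loc[0.75, "irs_diff"],
            }
        )
        diff_by_bin[label] = sub["irs_diff"].to_numpy()
    profiles = pd.DataFrame(rows)
    ecdf = group_irs_curves(diff_by_bin)
    composition = None
    if categories is not None:
        comp = assignments.merge(categories[["intron_id", "category"]], on="intron_id")
        composition = (
            comp.groupby(["bin", "category"], sort=False).size().rename("n").reset_index()
        )
    return profiles, ecdf, composition
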