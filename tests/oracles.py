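"""Independent reference implementations used only to check the package.

Each oracle takes a deliberately different route from the code under test:
the junction oracle tests every (read, intron) pair by raw interval
arithmetic on hand-parsed CIGAR strings; the Fisher oracle enumerates
hypergeometric tables; the rank-sum oracle enumerates subsets via the
U pair-counting definition; the Welch oracle is the plain textbook formula.
"""

from __future__ import annotations

import re
from itertools import combinations
from math import comb, sqrt

import numpy as np
import pysam
from scipy import stats

_CIGAR_RE = re.compile(r"(\d+)([MIDNSHP=XB])")


def _segments(pos: int, cigar: str):
    """(blocks, gaps) from a CIGAR string; D merges into the running block."""
    blocks, gaps = [], []
    cur_start = cur_end = pos
    for num, op in _CIGAR_RE.findall(cigar):
        n = int(num)
        if op in "MD=X":
            cur_end += n
        elif op == "N":
            blocks.append((cur_start, cur_end))
            gaps.append((cur_end, cur_end + n))
            cur_start = cur_end = cur_end + n
    blocks.append((cur_start, cur_end))
    return blocks, gaps


def brute_force_counts(sam_path, introns, min_anchor=5):
    """Per-intron [eejr, eijr, iejr] by testing every (read, intron) pair."""
    counts = {i.intron_id: [0, 0, 0] for i in introns}
    with pysam.AlignmentFile(str(sam_path), "r") as af:
        for read in af.fetch(until_eof=True):
            if read.is_unmapped or read.is_secondary or read.is_supplementary:
                continue
            blocks, gaps = _segments(read.reference_start, read.cigarstring)
            for intr in introns:
                if intr.chrom != read.reference_name:
                    continue
                hit = None
                for k, (gs, ge) in enumerate(gaps):
                    if (gs, ge) == (intr.start, intr.end):
                        lb, rb = blocks[k], blocks[k + 1]
                        if lb[1] - lb[0] >= min_anchor and rb[1] - rb[0] >= min_anchor:
                            hit = 0
                if hit is None:
                    for bs, be in blocks:
                        if bs <= intr.start - min_anchor and be >= intr.start + min_anchor:
                            hit = 1
                            break
                        if bs <= intr.end - min_anchor and be >= intr.end + min_anchor:
                            hit = 2
                            break
                if hit is not None:
                    counts[intr.intron_id][hit] += 1
    return counts


def fisher_two_sided(table) -> float:
    """Two-sided Fisher p by summing hypergeometric pmf <= observed."""
    (a, b), (c, d) = table
    row1, col1, n = a + b, a + c, a + b + c + d
    lo = max(0, row1 + col1 - n)
    hi = min(row1, col1)
    ks = np.arange(lo, hi + 1)
    pmf = stats.hypergeom.pmf(ks, n, row1, col1)
    p_obs = stats.hypergeom.pmf(a, n, row1, col1)
    return float(pmf[pmf <= p_obs * (1 + 1e-7)].sum())


def ranksum_exact(a, b) -> float:
    """Two-sided rank-sum p by subset enumeration of the U statistic.

    U counts pairs (x in A, y in B) with x > y, ties as 1/2; the p value is
    the fraction of equally-sized subsets whose U deviates from n1*n2/2 at
    least as much as observed.
    """
    pooled = list(a) + list(b)
    n1, n2 = len(a), len(b)
    mu = n1 * n2 / 2.0

    def u_of(idx):
        inside = set(idx)
        u = 0.0
        for i in inside:
            for j in range(n1 + n2):
                if j in inside:
                    continue
                if pooled[i] > pooled[j]:
                    u += 1.0
                elif pooled[i] == pooled[j]:
                    u += 0.5
        return u

    obs = abs(u_of(range(n1)) - mu)
    hits = sum(1 for idx in combinations(range(n1 + n2), n1) if abs(u_of(idx) - mu) >= obs - 1e-9)
    return hits / comb(n1 + n2, n1)


def welch_z(x, y) -> tuple[float, float]:
    """Textbook two-sample Z with unpooled sample variances: (z, p)."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    z = (y.mean() - x.mean()) / sqrt(x.var(ddof=1) / len(x) + y.var(ddof=1) / len(y) + 1e-6)
    return z, 2 * stats.norm.sf(abs(z))
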