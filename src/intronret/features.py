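"""Splice-site sequence features.

Covers the sequence-level analyses of the pipeline: extraction of donor and
acceptor windows in transcript orientation, per-position probability and
information-content matrices (sequence-logo tables), differential logos as
per-position Jensen-Shannon divergences with signed base differences,
per-position Fisher exact tests, exonic signature groups and the U5 snRNA
loop1 complementarity score.

The exonic signature of an intron is the 3-mer ending its 5' exon plus the
first nucleotide of its 3' exon.  Groups (IUPAC B = {C,G,T}, H = {A,C,T}),
assigned with precedence top to bottom so they partition all introns:

    AAG-G   last3 == AAG and first1 == G
    AAG-H   last3 == AAG and first1 in H
    BBH-H   last3 in B,B,H and first1 in H
    NNN-N   everything else
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import pyfaidx
from scipy import stats

from ._util import revcomp
from .annotation import IntronRecord

logger = logging.getLogger(__name__)

ALPHABET = ("A", "C", "G", "T")
_BASE_INDEX = {b: i for i, b in enumerate(ALPHABET)}
IUPAC_B = frozenset("CGT")
IUPAC_H = frozenset("ACT")


class SignatureGroup(str, Enum):
    AAG_G = "AAG-G"
    AAG_H = "AAG-H"
    BBH_H = "BBH-H"
    NNN_N = "NNN-N"


def assign_signature_group(last3_exon: str, first1_exon3: str) -> SignatureGroup:
    """Signature group of one intron from its exonic 3-mer and 1-mer context.

    Ambiguous characters (anything outside ACGT) fall through to NNN-N.
    """
    if len(last3_exon) != 3 or len(first1_exon3) != 1:
        raise ValueError("need a 3-mer and a 1-mer")
    last3 = last3_exon.upper().replace("U", "T")
    first1 = first1_exon3.upper().replace("U", "T")
    if any(b not in _BASE_INDEX for b in last3 + first1):
        return SignatureGroup.NNN_N
    if last3 == "AAG" and first1 == "G":
        return SignatureGroup.AAG_G
    if last3 == "AAG" and first1 in IUPAC_H:
        return SignatureGroup.AAG_H
    if (
        last3[0] in IUPAC_B
        and last3[1] in IUPAC_B
        and last3[2] in IUPAC_H
        and first1 in IUPAC_H
    ):
        return SignatureGroup.BBH_H
    return SignatureGroup.NNN_N


def extract_site_windows(
    genome: str | Path | pyfaidx.Fasta | Mapping[str, str],
    introns: Sequence[IntronRecord],
    e5: int = 3,
    i5: int = 6,
    i3: int = 6,
    e3: int = 1,
) -> pd.DataFrame:
    """Donor/acceptor sequence windows in transcript orientation.

    The 5' window spans the last ``e5`` exonic plus first ``i5`` intronic nt
    around the donor; the 3' window the last ``i3`` intronic plus first
    ``e3`` exonic nt around the acceptor.  Minus-strand windows are reverse
    complemented.  Introns whose windows would run off the contig are dropped
    with a warning; introns shorter than i5 + i3 keep overlapping intronic
    context and are flagged.

    Returns columns intron_id, strand, length, five_prime_window,
    three_prime_window, last3_exon, first1_exon3, signature_group,
    intronic_overlap.
    """
    if e5 < 3 or e3 < 1:
        raise ValueError("need e5 >= 3 and e3 >= 1 for the exonic signature context")
    if isinstance(genome, (str, Path)):
        genome = pyfaidx.Fasta(str(genome))

    def fetch(chrom: str, start: int, end: int) -> str:
        seq = genome[chrom]
        if isinstance(seq, str):
            return seq[start:end].upper()
        return str(seq[start:end]).upper()

    def contig_len(chrom: str) -> int:
        seq = genome[chrom]
        return len(seq)

    rows = []
    for intr in introns:
        if intr.chrom not in genome:
            raise KeyError(f"chromosome {intr.chrom!r} missing from genome FASTA")
        clen = contig_len(intr.chrom)
        if intr.strand == "+":
            lo, hi = intr.start - e5, intr.end + e3
        else:
            lo, hi = intr.start - e3, intr.end + e5
        if lo < 0 or hi > clen:
            logger.warning("intron %s too close to contig end; dropped", intr.intron_id)
            continue
        if intr.strand == "+":
            five = fetch(intr.chrom, intr.start - e5, intr.start + i5)
            three = fetch(intr.chrom, intr.end - i3, intr.end + e3)
        else:
            five = revcomp(fetch(intr.chrom, intr.end - i5, intr.end + e5))
            three = revcomp(fetch(intr.chrom, intr.start - e3, intr.start + i3))
        last3 = five[e5 - 3 : e5]
        first1 = three[i3]
        rows.append(
            {
                "intron_id": intr.intron_id,
                "strand": intr.strand,
                "length": intr.length,
                "five_prime_window": five,
                "three_prime_window": three,
                "last3_exon": last3,
                "first1_exon3": first1,
                "signature_group": assign_signature_group(last3, first1).value,
                "intronic_overlap": intr.length < i5 + i3,
            }
        )
    return pd.DataFrame(rows)


@dataclass
class PositionMatrix:
    """Per-position base counts, probabilities and information content."""

    counts: np.ndarray  # (L, 4) ints
    probabilities: np.ndarray  # (L, 4)
    information: np.ndarray  # (L,) bits in [0, 2]
    n_sequences: int
    n_ambiguous: int = 0

    @property
    def length(self) -> int:
        return self.counts.shape[0]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.probabilities, columns=[f"p_{b}" for b in ALPHABET])
        for i, b in enumerate(ALPHABET):
            df[f"n_{b}"] = self.counts[:, i]
        df.insert(0, "position", np.arange(self.length))
        df["information_bits"] = self.information
        return df


def build_matrix(windows: Sequence[str]) -> PositionMatrix:
    """Probability / information matrix from equal-length sequence windows.

    Ambiguous bases are excluded from their column's count (tallied in
    ``n_ambiguous``).  Information content per column is
    2 + sum_b p log2 p bits, with 0 log 0 := 0.
    """
    if not windows:
        raise ValueError("need at least one window")
    length = len(windows[0])
    if any(len(w) != length for w in windows):
        raise ValueError("windows must have equal length")
    counts = np.zeros((length, 4), dtype=int)
    ambiguous = 0
    for w in windows:
        for j, b in enumerate(w.upper()):
            i = _BASE_INDEX.get(b)
            if i is None:
                ambiguous += 1
            else:
                counts[j, i] += 1
    col_n = counts.sum(axis=1, keepdims=True)
    if (col_n == 0).any():
        raise ValueError("a column has no unambiguous bases")
    probs = counts / col_n
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(probs > 0, probs * np.log2(probs), 0.0)
    info = 2.0 + plogp.sum(axis=1)
    return PositionMatrix(
        counts=counts,
        probabilities=probs,
        information=np.clip(info, 0.0, 2.0),
        n_sequences=len(windows),
        n_ambiguous=ambiguous,
    )


def _jsd_bits(p: np.ndarray, q: np.ndarray) -> np.ndarray:
    m = 0.5 * (p + q)
    with np.errstate(divide="ignore", invalid="ignore"):
        kl_pm = np.where(p > 0, p * np.log2(p / m), 0.0).sum(axis=-1)
        kl_qm = np.where(q > 0, q * np.log2(q / m), 0.0).sum(axis=-1)
    return 0.5 * kl_pm + 0.5 * kl_qm


def diff_matrix(p: PositionMatrix, q: PositionMatrix) -> pd.DataFrame:
    """Differential-logo table between two position matrices.

    Per position: Jensen-Shannon divergence in bits (in [0, 1]) and signed
    per-base probability differences p - q.
    """
    if p.length != q.length:
        raise ValueError(f"window geometry mismatch: {p.length} vs {q.length}")
    jsd = _jsd_bits(p.probabilities, q.probabilities)
    out = pd.DataFrame({"position": np.arange(p.length), "jsd_bits": jsd})
    for i, b in enumerate(ALPHABET):
        out[f"d_{b}"] = p.probabilities[:, i] - q.probabilities[:, i]
    return out


def position_fisher(
    windows_a: Sequence[str],
    windows_b: Sequence[str],
    position: int,
    base_set: str | Sequence[str],
) -> tuple[float, float, tuple[tuple[int, int], tuple[int, int]]]:
    """Two-sided Fisher exact test for base-set enrichment at one position.

    Builds the 2x2 table [base in set vs not] x [group A vs B] and returns
    (sample odds ratio, two-sided p value, table).  The odds ratio is the
    unconditional sample estimate (ad/bc).
    """
    if not windows_a or not windows_b:
        raise ValueError("both groups must be non-empty")
    if position < 0 or position >= len(windows_a[0]):
        raise ValueError(f"position {position} outside window of length {len(windows_a[0])}")
    bases = {b.upper().replace("U", "T") for b in base_set}

    def split(windows):
        inset = sum(1 for w in windows if w[position].upper() in bases)
        return inset, len(windows) - inset

    a_in, a_out = split(windows_a)
    b_in, b_out = split(windows_b)
    table = ((a_in, a_out), (b_in, b_out))
    odds, p = stats.fisher_exact(table, alternative="two-sided")
    return float(odds), float(p), table


def u5_pairing_score(
    last3_exon: str, loop_register: str = "CUU", allow_wobble: bool = False
) -> int:
    """Number of base pairs between the 5'-exon 3-mer and the U5 loop1 register.

    The exon 3-mer (5'->3') is paired antiparallel against the register
    (given 5'->3'; the wild-type loop1 register is CUU, the mutant rescue
    register GAA).  Watson-Crick pairs always count; G.U wobbles only when
    ``allow_wobble``.  DNA and RNA alphabets are both accepted (T == U).
    """
    if len(last3_exon) != 3 or len(loop_register) != 3:
        raise ValueError("exon context and loop register must both be 3-mers")
    exon = last3_exon.upper().replace("T", "U")
    loop = loop_register.upper().replace("T", "U")
    pairs = {("A", "U"), ("U", "A"), ("G", "C"), ("C", "G")}
    if allow_wobble:
        pairs |= {("G", "U"), ("U", "G")}
    return sum((x, y) in pairs for x, y in zip(exon, loop[::-1]))


def group_irs_curves(values_by_group: Mapping[str, Sequence[float]]) -> pd.DataFrame:
    """Empirical CDF tables per group (right-continuous, reaching 1).

    Returns columns group, value, cum_frac with one row per distinct value.
    Empty groups are omitted with a warning.
    """
    frames = []
    for group, values in values_by_group.items():
        v = np.sort(np.asarray(values, dtype=float))
        if v.size == 0:
            logger.warning("group %s has no values; omitted from ECDF", group)
            continue
        uniq, counts = np.unique(v, return_counts=True)
        cum = np.cumsum(counts) / v.size
        frames.append(pd.DataFrame({"group": group, "value": uniq, "cum_frac": cum}))
    if not frames:
        return pd.DataFrame(columns=["group", "value", "cum_frac"])
    return pd.concat(frames, ignore_index=True)
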