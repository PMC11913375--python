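"""Synthetic short-intron transcriptome with known retention ground truth.

The generator emulates a bulk RNA-seq splicing study in a short-intron-rich
fungal transcriptome: a toy genome of single-transcript multi-exon genes
whose intron lengths concentrate at short/ultra-short sizes (default mixture
mean ~56 nt), GT...AG introns, configurable exonic-signature composition
(AAG-G / AAG-H / BBH-H / NNN-N), and per-intron true retention fractions
rho for a wild-type (WT) and a knockdown (KD) condition with three
replicates each.

Reads are the minimal sufficient data for junction-based retention scoring:
spliced molecules yield gapped alignments whose N operation spans the intron
exactly; retained molecules yield contiguous alignments crossing the donor
or acceptor boundary (chosen with equal probability).  No intron-internal
coverage, paired ends, quality models or expression differences between
genes are simulated.

Replicate counts are negative binomial around ``coverage_mean`` with
configurable dispersion; retained reads are a binomial split of each
replicate's total.  ``deterministic=True`` replaces all draws by rounded
expectations, giving exactly reproducible counts for round-trip tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import pysam

from ._util import revcomp, write_fasta
from .annotation import IntronRecord
from .features import SignatureGroup

MAX_GAP = 1 << 28  # largest intron length representable as one CIGAR N op

_BASES = np.array(list("ACGT"))
_B_SET = "CGT"
_H_SET = "ACT"

CONDITIONS = ("WT", "KD")


class SimConfigError(ValueError):
    """Raised for infeasible or inconsistent simulation configurations."""


RhoSpec = float | Mapping[str, float]


@dataclass
class SimConfig:
    """Parameters of the synthetic study.

    Defaults are the emulated study conditions: ~56 nt mean intron length,
    signature composition matching the observed group frequencies
    (AAG-G 3.0%, AAG-H 6.5%, BBH-H 19.3%, NNN-N 71.2%), a low basal
    retention in WT and a group-ordered increase under knockdown
    (AAG-G least, BBH-H most affected), 3 replicates per condition,
    100 nt single-end reads.
    """

    n_genes: int = 120
    exons_per_gene: tuple[int, int] = (3, 7)  # inclusive range
    exon_length: tuple[int, int] = (60, 300)  # inclusive range, nt
    #: (weight, lower, upper) bins; lengths uniform over [lower, upper)
    intron_length_mixture: tuple[tuple[float, int, int], ...] = (
        (0.22, 20, 40),
        (0.55, 40, 60),
        (0.19, 60, 100),
        (0.035, 100, 200),
        (0.005, 200, 500),
    )
    canonical_sites: bool = True
    signature_proportions: Mapping[str, float] = field(
        default_factory=lambda: {
            SignatureGroup.AAG_G.value: 0.030,
            SignatureGroup.AAG_H.value: 0.065,
            SignatureGroup.BBH_H.value: 0.193,
            SignatureGroup.NNN_N.value: 0.712,
        }
    )
    coverage_mean: float = 100.0
    dispersion: float = 10.0  # negative-binomial size parameter
    deterministic: bool = False  # counts = rounded expectations
    rho_wt: RhoSpec = 0.05
    rho_kd: RhoSpec = field(
        default_factory=lambda: {
            SignatureGroup.AAG_G.value: 0.10,
            SignatureGroup.AAG_H.value: 0.18,
            SignatureGroup.NNN_N.value: 0.35,
            SignatureGroup.BBH_H.value: 0.45,
        }
    )
    #: optional (lower, upper, multiplier) rows applied to rho_kd by intron
    #: length (upper None = unbounded); result clipped to [0, 1]
    length_multiplier_kd: tuple[tuple[int, int | None, float], ...] | None = None
    n_replicates: int = 3
    read_length: int = 100
    min_anchor: int = 5
    n_chroms: int = 2
    intergenic_spacer: int = 200
    seed: int = 0

    def validate(self) -> None:
        weights = [w for w, _, _ in self.intron_length_mixture]
        if abs(sum(weights) - 1.0) > 1e-9:
            raise SimConfigError("intron length mixture weights must sum to 1")
        for w, lo, hi in self.intron_length_mixture:
            if w < 0 or lo < 4 or hi <= lo:
                raise SimConfigError(f"bad mixture bin ({w}, {lo}, {hi})")
        if abs(sum(self.signature_proportions.values()) - 1.0) > 1e-9:
            raise SimConfigError("signature proportions must sum to 1")
        for rho in (self.rho_wt, self.rho_kd):
            for v in rho.values() if isinstance(rho, Mapping) else [rho]:
                if not 0.0 <= v <= 1.0:
                    raise SimConfigError("retention fractions must lie in [0, 1]")
        if self.read_length < 2 * self.min_anchor:
            raise SimConfigError("read_length must be >= 2 * min_anchor")
        if self.exon_length[0] < 4:
            raise SimConfigError("exons must be >= 4 nt to carry the signature context")
        if 2 * self.exon_length[0] < self.read_length:
            raise SimConfigError(
                "flanking exons too short for gapped reads: need "
                "2 * min exon length >= read_length"
            )
        if self.exons_per_gene[0] < 2:
            raise SimConfigError("genes need at least 2 exons to contain an intron")
        if self.n_replicates < 1 or self.n_genes < 1:
            raise SimConfigError("n_genes and n_replicates must be >= 1")

    def rho(self, condition: str, group: str, length: int) -> float:
        spec = self.rho_wt if condition == "WT" else self.rho_kd
        value = spec[group] if isinstance(spec, Mapping) else float(spec)
        if condition == "KD" and self.length_multiplier_kd:
            for lo, hi, mult in self.length_multiplier_kd:
                if length >= lo and (hi is None or length < hi):
                    value *= mult
                    break
        return float(min(max(value, 0.0), 1.0))


def _sample_signature(rng: np.random.Generator, group: str) -> tuple[str, str]:
    """A concrete (last3, first1) exonic context for a signature group."""
    if group == SignatureGroup.AAG_G.value:
        return "AAG", "G"
    if group == SignatureGroup.AAG_H.value:
        return "AAG", rng.choice(list(_H_SET))
    if group == SignatureGroup.BBH_H.value:
        last3 = rng.choice(list(_B_SET)) + rng.choice(list(_B_SET)) + rng.choice(list(_H_SET))
        return last3, rng.choice(list(_H_SET))
    # NNN-N: rejection-sample the complement of the three specific rules
    from .features import assign_signature_group

    while True:
        last3 = "".join(rng.choice(_BASES, size=3))
        first1 = str(rng.choice(_BASES))
        if assign_signature_group(last3, first1) is SignatureGroup.NNN_N:
            return last3, first1


@dataclass
class SyntheticGenome:
    """In-memory result of :func:`simulate_genome`."""

    sequences: dict[str, str]
    gtf: str
    introns: list[IntronRecord]
    truth: pd.DataFrame  # intron_id, chrom, start, end, strand, index, group,
    # length, rho_wt, rho_kd (+ flanking exon lengths for the read simulator)
    config: SimConfig

    def write_fasta(self, path: str | Path) -> Path:
        return write_fasta(self.sequences, path)

    def write_gtf(self, path: str | Path) -> Path:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        path.write_text(self.gtf)
        return path

    def write_truth(self, path: str | Path) -> Path:
        from ._util import write_tsv

        cols = [
            "intron_id", "chrom", "start", "end", "strand", "index",
            "signature_group", "length", "rho_wt", "rho_kd",
        ]
        return write_tsv(self.truth[cols], path)


def simulate_genome(config: SimConfig, seed: int | None = None) -> SyntheticGenome:
    """Generate the toy genome, exon annotation and per-intron ground truth.

    Deterministic given the seed (``config.seed`` unless overridden).  Genes
    are laid out left to right on ``n_chroms`` chromosomes with random
    strand; every gene has a single transcript.
    """
    config.validate()
    rng = np.random.default_rng(config.seed if seed is None else seed)

    chrom_seqs: dict[str, list[str]] = {f"chr{i + 1}": [] for i in range(config.n_chroms)}
    chrom_len: dict[str, int] = {c: 0 for c in chrom_seqs}
    gtf_rows: list[tuple[str, int, int, str, str, str]] = []
    introns: list[IntronRecord] = []
    truth_rows: list[dict] = []

    weights = np.array([w for w, _, _ in config.intron_length_mixture])
    bins = [(lo, hi) for _, lo, hi in config.intron_length_mixture]
    groups = list(config.signature_proportions)
    group_p = np.array([config.signature_proportions[g] for g in groups])

    def random_seq(n: int) -> str:
        return "".join(rng.choice(_BASES, size=n))

    for g in range(config.n_genes):
        gene_id = f"g{g + 1:04d}"
        chrom = f"chr{g % config.n_chroms + 1}"
        strand = "+" if rng.random() < 0.5 else "-"
        n_exons = int(rng.integers(config.exons_per_gene[0], config.exons_per_gene[1] + 1))
        exon_lens = [
            int(rng.integers(config.exon_length[0], config.exon_length[1] + 1))
            for _ in range(n_exons)
        ]
        intron_lens = []
        for _ in range(n_exons - 1):
            b = int(rng.choice(len(bins), p=weights))
            lo, hi = bins[b]
            intron_lens.append(int(rng.integers(lo, hi)))

        # transcript-oriented sequence pieces
        exon_seqs = [list(random_seq(n)) for n in exon_lens]
        intron_seqs = []
        intron_groups = []
        for k, ilen in enumerate(intron_lens):
            group = groups[int(rng.choice(len(groups), p=group_p))]
            last3, first1 = _sample_signature(rng, group)
            exon_seqs[k][-3:] = list(last3)
            exon_seqs[k + 1][0] = first1
            iseq = list(random_seq(ilen))
            if config.canonical_sites:
                iseq[:2] = ["G", "T"]
                iseq[-2:] = ["A", "G"]
            intron_seqs.append("".join(iseq))
            intron_groups.append(group)
        exon_strs = ["".join(e) for e in exon_seqs]

        tx_parts = []
        for k in range(n_exons):
            tx_parts.append(exon_strs[k])
            if k < n_exons - 1:
                tx_parts.append(intron_seqs[k])
        gene_seq = "".join(tx_parts)

        offset = chrom_len[chrom]
        genomic = gene_seq if strand == "+" else revcomp(gene_seq)
        chrom_seqs[chrom].append(genomic + random_seq(config.intergenic_spacer))
        chrom_len[chrom] += len(genomic) + config.intergenic_spacer

        # exon coordinates (0-based half-open, genomic)
        tx_coords = []
        pos = 0
        for k in range(n_exons):
            tx_coords.append((pos, pos + exon_lens[k]))
            pos += exon_lens[k]
            if k < n_exons - 1:
                pos += intron_lens[k]
        gene_len = pos
        if strand == "+":
            exon_coords = [(offset + s, offset + e) for s, e in tx_coords]
        else:
            exon_coords = [(offset + gene_len - e, offset + gene_len - s) for s, e in tx_coords]
            exon_coords.sort()
        for s, e in exon_coords:
            gtf_rows.append((chrom, s + 1, e, strand, gene_id, f"{gene_id}.t1"))

        # introns: genomic gaps between consecutive exons; transcript index
        gaps = [
            (exon_coords[k][1], exon_coords[k + 1][0]) for k in range(n_exons - 1)
        ]
        # flanking genomic exon lengths for the read simulator
        flanks = [
            (
                exon_coords[k][1] - exon_coords[k][0],
                exon_coords[k + 1][1] - exon_coords[k + 1][0],
            )
            for k in range(n_exons - 1)
        ]
        if strand == "+":
            order = list(range(n_exons - 1))
        else:
            order = list(range(n_exons - 2, -1, -1))
            intron_groups = intron_groups[::-1]
            intron_lens = intron_lens[::-1]
        for idx, gpos in enumerate(order, start=1):
            start, end = gaps[gpos]
            rec = IntronRecord(
                intron_id=f"{gene_id}.i{idx}",
                gene_id=gene_id,
                chrom=chrom,
                start=start,
                end=end,
                strand=strand,
                index=idx,
            )
            if rec.length >= MAX_GAP:
                raise SimConfigError(f"intron {rec.intron_id} longer than representable gap")
            introns.append(rec)
            group = intron_groups[idx - 1]
            truth_rows.append(
                {
                    "intron_id": rec.intron_id,
                    "chrom": chrom,
                    "start": start,
                    "end": end,
                    "strand": strand,
                    "index": idx,
                    "signature_group": group,
                    "length": rec.length,
                    "rho_wt": config.rho("WT", group, rec.length),
                    "rho_kd": config.rho("KD", group, rec.length),
                    "left_exon_len": flanks[gpos][0],
                    "right_exon_len": flanks[gpos][1],
                }
            )

    sequences = {c: "".join(parts) for c, parts in chrom_seqs.items()}
    gtf_rows.sort(key=lambda r: (r[0], r[1]))
    gtf_lines = [
        f'{c}\tintronret_sim\texon\t{s}\t{e}\t.\t{strand}\t.\t'
        f'gene_id "{gid}"; transcript_id "{tid}";'
        for c, s, e, strand, gid, tid in gtf_rows
    ]
    introns.sort(key=lambda i: (i.chrom, i.start, i.end))
    truth = pd.DataFrame(truth_rows).sort_values(["chrom", "start", "end"]).reset_index(drop=True)
    return SyntheticGenome(
        sequences=sequences,
        gtf="\n".join(gtf_lines) + "\n",
        introns=introns,
        truth=truth,
        config=config,
    )


def _draw_totals(rng, config: SimConfig, size: int) -> np.ndarray:
    if config.deterministic:
        return np.full(size, int(round(config.coverage_mean)), dtype=np.int64)
    r = config.dispersion
    p = r / (r + config.coverage_mean)
    return rng.negative_binomial(r, p, size=size)


def _draw_retained(rng, config: SimConfig, totals: np.ndarray, rho: np.ndarray) -> np.ndarray:
    if config.deterministic:
        return np.rint(totals * rho).astype(np.int64)
    return rng.binomial(totals, rho)


def sample_sheet(config: SimConfig) -> pd.DataFrame:
    """Sample metadata table (sample_id, condition, replicate)."""
    rows = [
        {"sample_id": f"{cond}_{rep}", "condition": cond, "replicate": rep}
        for cond in CONDITIONS
        for rep in range(1, config.n_replicates + 1)
    ]
    return pd.DataFrame(rows)


def simulate_junction_counts(
    truth: pd.DataFrame, config: SimConfig, seed: int | None = None
) -> pd.DataFrame:
    """Draw junction counts directly, skipping read emission.

    Statistically equivalent to counting the simulator's reads (total
    junction-spanning reads per intron/replicate are negative binomial,
    retained reads a Binomial(N, rho) thinning split evenly between the
    donor and acceptor side) and considerably faster for calibration and
    recovery experiments at many introns.
    """
    config.validate()
    rng = np.random.default_rng(config.seed if seed is None else seed)
    m = len(truth)
    frames = []
    for cond in CONDITIONS:
        rho = truth["rho_wt" if cond == "WT" else "rho_kd"].to_numpy(dtype=float)
        for rep in range(1, config.n_replicates + 1):
            totals = _draw_totals(rng, config, m)
            retained = _draw_retained(rng, config, totals, rho)
            if config.deterministic:
                eij = retained // 2
            else:
                eij = rng.binomial(retained, 0.5)
            frames.append(
                pd.DataFrame(
                    {
                        "intron_id": truth["intron_id"],
                        "chrom": truth["chrom"],
                        "start": truth["start"],
                        "end": truth["end"],
                        "strand": truth["strand"],
                        "length": truth["length"],
                        "sample_id": f"{cond}_{rep}",
                        "condition": cond,
                        "replicate": rep,
                        "eejr": totals - retained,
                        "eijr": eij,
                        "iejr": retained - eij,
                    }
                )
            )
    return pd.concat(frames, ignore_index=True)


@dataclass
class SimReads:
    """Result of :func:`simulate_alignments`."""

    sample_sheet: pd.DataFrame  # sample_id, condition, replicate, path
    realized_counts: pd.DataFrame  # same schema as count_junctions output

    def write_sample_sheet(self, path: str | Path) -> Path:
        from ._util import write_tsv

        return write_tsv(self.sample_sheet, path)


def simulate_alignments(
    sim: SyntheticGenome,
    out_dir: str | Path,
    seed: int | None = None,
) -> SimReads:
    """Emit spliced and boundary-crossing reads as one SAM file per sample.

    Per intron, replicate and condition, N ~ NegBin(coverage_mean,
    dispersion) junction-spanning molecules are drawn, of which
    K ~ Binomial(N, rho) are retained.  The N - K spliced molecules become
    gapped alignments whose single N operation spans the intron exactly,
    with both anchors >= min_anchor and the left-anchor length uniform over
    its feasible range.  Retained molecules become contiguous alignments
    crossing the donor or acceptor boundary (equal probability), again with
    >= min_anchor on both sides, placed uniformly, and constrained to the
    two flanking exons plus the intron so that each read touches only its
    own intron's junctions.

    The returned ``realized_counts`` table holds the per-intron, per-sample
    junction counts implied by the emitted reads under the counter's own
    assignment rule (gap match -> eejr; otherwise start-window before
    end-window), so a deterministic round trip through the counter matches
    it exactly.
    """
    config = sim.config
    config.validate()
    rng = np.random.default_rng(config.seed if seed is None else seed)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    header = {
        "HD": {"VN": "1.6", "SO": "unsorted"},
        "SQ": [{"SN": c, "LN": len(s)} for c, s in sim.sequences.items()],
    }
    chrom_index = {c: i for i, c in enumerate(sim.sequences)}
    sheet = sample_sheet(config)
    paths = []
    counts_frames = []
    t = sim.truth
    ra = config.read_length
    anchor = config.min_anchor

    for sample in sheet.itertuples(index=False):
        path = out_dir / f"{sample.sample_id}.sam"
        paths.append(str(path))
        rho = t["rho_wt" if sample.condition == "WT" else "rho_kd"].to_numpy(dtype=float)
        totals = _draw_totals(rng, config, len(t))
        retained = _draw_retained(rng, config, totals, rho)
        realized = np.zeros((len(t), 3), dtype=np.int64)
        with pysam.AlignmentFile(str(path), "w", header=header) as sam:
            serial = 0
            for i, row in enumerate(t.itertuples(index=False)):
                start, end, L = row.start, row.end, row.length
                left_len, right_len = row.left_exon_len, row.right_exon_len
                chrom = row.chrom
                n_spliced = int(totals[i] - retained[i])
                n_retained = int(retained[i])

                a_lo = max(anchor, ra - right_len)
                a_hi = min(ra - anchor, left_len)
                if a_lo > a_hi:
                    raise SimConfigError(
                        f"intron {row.intron_id}: flanking exons too short for "
                        f"{ra} nt gapped reads"
                    )
                for _ in range(n_spliced):
                    a = int(rng.integers(a_lo, a_hi + 1))
                    read = pysam.AlignedSegment()
                    read.query_name = f"{sample.sample_id}:{row.intron_id}:s{serial}"
                    serial += 1
                    read.reference_id = chrom_index[chrom]
                    read.reference_start = start - a
                    read.flag = 0
                    read.mapping_quality = 60
                    read.cigarstring = f"{a}M{L}N{ra - a}M"
                    seq = sim.sequences[chrom]
                    read.query_sequence = seq[start - a : start] + seq[end : end + ra - a]
                    sam.write(read)
                    realized[i, 0] += 1

                if config.deterministic:
                    sides = np.zeros(n_retained, dtype=np.int64)
                    sides[1::2] = 1
                else:
                    sides = rng.integers(0, 2, size=n_retained)
                for side in sides:
                    if side == 0:  # cross the genomic-start (donor-side) boundary
                        e_lo = max(anchor, ra - L - right_len)
                        e_hi = min(ra - anchor, left_len)
                        e = int(rng.integers(e_lo, e_hi + 1))
                        rs = start - e
                    else:  # cross the genomic-end (acceptor-side) boundary
                        e_lo = max(anchor, ra - L - left_len)
                        e_hi = min(ra - anchor, right_len)
                        e = int(rng.integers(e_lo, e_hi + 1))
                        rs = end + e - ra
                    read = pysam.AlignedSegment()
                    read.query_name = f"{sample.sample_id}:{row.intron_id}:r{serial}"
                    serial += 1
                    read.reference_id = chrom_index[chrom]
                    read.reference_start = rs
                    read.flag = 0
                    read.mapping_quality = 60
                    read.cigarstring = f"{ra}M"
                    read.query_sequence = sim.sequences[chrom][rs : rs + ra]
                    sam.write(read)
                    # counter's rule: start window has priority over end window
                    if rs <= start - anchor and rs + ra >= start + anchor:
                        realized[i, 1] += 1
                    else:
                        realized[i, 2] += 1

        df = t[["intron_id", "chrom", "start", "end", "strand", "length"]].copy()
        df["sample_id"] = sample.sample_id
        df["condition"] = sample.condition
        df["replicate"] = sample.replicate
        df["eejr"] = realized[:, 0]
        df["eijr"] = realized[:, 1]
        df["iejr"] = realized[:, 2]
        counts_frames.append(df)

    sheet = sheet.copy()
    sheet["path"] = paths
    return SimReads(
        sample_sheet=sheet,
        realized_counts=pd.concat(counts_frames, ignore_index=True),
    )
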