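import sys
from pathlib import Path

import pandas as pd
import pysam
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for oracles.py

from intronret.annotation import IntronRecord


def write_sam(path, chrom_lengths, reads):
    """Write minimal single-end SAM records.

    ``reads``: iterable of (qname, chrom, pos0, cigar) or with a trailing
    flag value.
    """
    header = {
        "HD": {"VN": "1.6"},
        "SQ": [{"SN": c, "LN": n} for c, n in chrom_lengths.items()],
    }
    with pysam.AlignmentFile(str(path), "w", header=header) as sam:
        for rec in reads:
            qname, chrom, pos, cigar = rec[:4]
            flag = rec[4] if len(rec) > 4 else 0
            a = pysam.AlignedSegment()
            a.query_name = qname
            a.reference_id = list(chrom_lengths).index(chrom)
            a.reference_start = pos
            a.cigarstring = cigar
            a.flag = flag
            a.mapping_quality = 60
            sam.write(a)
    return Path(path)


def make_intron(intron_id, chrom, start, end, strand="+", index=1, gene_id=None):
    return IntronRecord(
        intron_id=intron_id,
        gene_id=gene_id or intron_id.split(".")[0],
        chrom=chrom,
        start=start,
        end=end,
        strand=strand,
        index=index,
    )


def counts_row(intron_id, sample_id, condition, replicate, eejr, eijr, iejr, **extra):
    row = {
        "intron_id": intron_id,
        "chrom": extra.get("chrom", "chr1"),
        "start": extra.get("start", 0),
        "end": extra.get("end", 50),
        "strand": extra.get("strand", "+"),
        "length": extra.get("length", 50),
        "sample_id": sample_id,
        "condition": condition,
        "replicate": replicate,
        "eejr": eejr,
        "eijr": eijr,
        "iejr": iejr,
    }
    return row


@pytest.fixture
def toy_gtf(tmp_path):
    """Two genes: '+' two-exon and '-' three-exon (the worked examples)."""
    lines = [
        # gene A, + strand: exons (1,100) and (151,250) -> intron [100,150)
        'chr1\ttest\texon\t1\t100\t.\t+\t.\tgene_id "gA"; transcript_id "gA.t1";',
        'chr1\ttest\texon\t151\t250\t.\t+\t.\tgene_id "gA"; transcript_id "gA.t1";',
        # gene B, - strand: exons (1,100), (151,250), (301,400)
        'chr2\ttest\texon\t1\t100\t.\t-\t.\tgene_id "gB"; transcript_id "gB.t1";',
        'chr2\ttest\texon\t151\t250\t.\t-\t.\tgene_id "gB"; transcript_id "gB.t1";',
        'chr2\ttest\texon\t301\t400\t.\t-\t.\tgene_id "gB"; transcript_id "gB.t1";',
    ]
    p = tmp_path / "toy.gtf"
    p.write_text("\n".join(lines) + "\n")
    return p
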