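"""Small shared helpers: sequence ops, TSV conventions, checksums."""

from __future__ import annotations

import hashlib
from pathlib import Path

import pandas as pd

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

#: fixed float formatting so repeated runs produce byte-identical TSVs
FLOAT_FORMAT = "%.6g"


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (N passes through)."""
    return seq.translate(_COMPLEMENT)[::-1]


def write_tsv(df: pd.DataFrame, path: str | Path) -> Path:
    """Write a DataFrame as TSV with the package's fixed float format."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False, float_format=FLOAT_FORMAT)
    return path


def read_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_fasta(sequences: dict[str, str], path: str | Path, width: int = 60) -> Path:
    """Write sequences as a wrapped FASTA file (fixed 60-column default)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")
    return path


def sha256_file(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()
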