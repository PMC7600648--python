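"""Readers and writers for the pipeline's delimited-text formats.

All tables are tab-separated UTF-8 with '.' decimal separators and a
header line.  Protein positions are 1-based inclusive everywhere.
"""

from __future__ import annotations

from pathlib import Path
from typing import Mapping

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .incorporation import PSM_COLUMNS, parse_site_states

__all__ = [
    "read_fasta",
    "write_fasta",
    "read_psm_table",
    "write_psm_table",
    "write_table",
]

_VALID_RESIDUES = set("ACDEFGHIKLMNPQRSTVWY")


def read_fasta(path: str | Path) -> dict[str, str]:
    """Protein id -> uppercase sequence; rejects duplicates and junk.

    Sequences may only contain the 20 standard residue letters.
    """
    path = Path(path)
    proteins: dict[str, str] = {}
    for record in SeqIO.parse(str(path), "fasta"):
        if record.id in proteins:
            raise ValueError(f"{path}: duplicate FASTA id {record.id!r}")
        seq = str(record.seq).upper()
        bad = set(seq) - _VALID_RESIDUES
        if bad:
            raise ValueError(
                f"{path}: record {record.id!r} contains non-residue "
                f"characters {sorted(bad)}"
            )
        proteins[record.id] = seq
    if not proteins:
        raise ValueError(f"{path}: no FASTA records found")
    return proteins


def write_fasta(proteins: Mapping[str, str], path: str | Path, width: int = 60) -> None:
    records = [
        SeqRecord(Seq(seq), id=pid, description="") for pid, seq in proteins.items()
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(records)


def read_psm_table(path: str | Path, sep: str = "\t") -> pd.DataFrame:
    """Load and validate a PSM table; errors carry 1-based line numbers."""
    path = Path(path)
    try:
        df = pd.read_csv(path, sep=sep, dtype={"site_states": "string"})
    except pd.errors.ParserError as exc:
        raise ValueError(f"{path}: malformed table: {exc}") from exc
    missing = [c for c in PSM_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s): {missing}")
    df["site_states"] = df["site_states"].fillna("")
    for idx, row in df.iterrows():
        line = idx + 2  # header is line 1
        seq = row["sequence"]
        if not isinstance(seq, str) or not seq:
            raise ValueError(f"{path}:{line}: empty peptide sequence")
        bad = set(seq) - _VALID_RESIDUES
        if bad:
            raise ValueError(
                f"{path}:{line}: non-residue characters {sorted(bad)} in sequence"
            )
        try:
            states = parse_site_states(row["site_states"])
        except ValueError as exc:
            raise ValueError(f"{path}:{line}: {exc}") from None
        if len(states) != seq.count("R"):
            raise ValueError(
                f"{path}:{line}: {len(states)} site states for "
                f"{seq.count('R')} Arg positions"
            )
        if not (0.0 <= row["pep"] <= 1.0):
            raise ValueError(f"{path}:{line}: PEP {row['pep']} outside [0,1]")
        if row["intensity"] < 0:
            raise ValueError(f"{path}:{line}: negative intensity")
        if int(row["charge"]) < 1:
            raise ValueError(f"{path}:{line}: charge must be >= 1")
    return df


def write_psm_table(df: pd.DataFrame, path: str | Path, sep: str = "\t") -> None:
    df.to_csv(path, sep=sep, index=False, float_format="%.6g")


def write_table(df: pd.DataFrame, path: str | Path, sep: str = "\t") -> None:
    """Write any result table with stable float formatting."""
    df.to_csv(path, sep=sep, index=False, float_format="%.6g")
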