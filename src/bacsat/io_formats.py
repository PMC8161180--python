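"""Genome and table input/output.

Genomes are plain nucleotide strings read from FASTA (one :class:`Genome`
per record, order preserved, sequence uppercased).  All pipeline tables are
tab-separated text with a fixed header line, which keeps them diff-friendly
and trivially round-trippable.

Coordinates everywhere in this package are 1-based and inclusive of both
ends, the convention used by NCBI feature tables.  Ambiguity characters
(``N`` and the other IUPAC letters) are retained in sequences but never
participate in seed or motif matches downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, List, Optional, Sequence, Tuple

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

#: Characters accepted in genome sequences (IUPAC nucleotide alphabet).
IUPAC_ALPHABET = frozenset("ACGTRYSWKMBDHVN")

#: The four unambiguous bases.
DNA = "ACGT"

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")


def reverse_complement(seq: str) -> str:
    """Reverse complement over the full IUPAC alphabet."""
    return seq.translate(_COMPLEMENT)[::-1]


class FastaFormatError(ValueError):
    """Raised for malformed FASTA input (bad header or non-IUPAC characters)."""


class UndefinedValueError(ValueError):
    """Raised when a statistic is undefined for the given input."""


class SchemaError(ValueError):
    """Raised when a tabular file lacks required columns."""


@dataclass(frozen=True)
class Genome:
    """A single nucleotide sequence with its accession (or any label).

    ``length_nt`` and ``gc_percent`` are derived; GC% is computed over the
    unambiguous A/C/G/T positions only.
    """

    id: str
    sequence: str

    @property
    def length_nt(self) -> int:
        return len(self.sequence)

    @property
    def gc_percent(self) -> float:
        return gc_percent(self)


def gc_percent(genome: Genome) -> float:
    """GC content as a percentage: 100 * (G + C) / (A + C + G + T).

    Ambiguity characters are excluded from both numerator and denominator.
    Raises :class:`UndefinedValueError` if no unambiguous base is present.
    """
    seq = genome.sequence
    counts = {b: seq.count(b) for b in DNA}
    total = sum(counts.values())
    if total == 0:
        raise UndefinedValueError(
            f"genome {genome.id!r} has no unambiguous A/C/G/T bases"
        )
    return 100.0 * (counts["G"] + counts["C"]) / total


def _validate_sequence(record_id: str, seq: str) -> None:
    for offset, ch in enumerate(seq):
        if ch not in IUPAC_ALPHABET:
            raise FastaFormatError(
                f"record {record_id!r}: non-nucleotide character {ch!r} "
                f"at offset {offset}"
            )


def read_fasta(path) -> List[Genome]:
    """Read a FASTA file into a list of :class:`Genome` (file order).

    Sequences are uppercased.  A file whose first non-blank line is not a
    ``>`` header, or a record containing characters outside the IUPAC
    alphabet, raises :class:`FastaFormatError` naming the record and offset.
    """
    path = Path(path)
    text_head = ""
    with open(path) as fh:
        for line in fh:
            if line.strip():
                text_head = line
                break
    if text_head and not text_head.startswith(">"):
        raise FastaFormatError(f"{path}: first record has a malformed header")
    genomes: List[Genome] = []
    for record in SeqIO.parse(str(path), "fasta"):
        seq = str(record.seq).upper()
        _validate_sequence(record.id, seq)
        genomes.append(Genome(id=record.id, sequence=seq))
    return genomes


def write_fasta(genomes: Iterable[Genome], path, width: int = 70) -> None:
    """Write genomes to FASTA (wrapped lines)."""
    records = [
        SeqRecord(Seq(g.sequence), id=g.id, description="") for g in genomes
    ]
    with open(path, "w") as fh:
        SeqIO.write(records, fh, "fasta")


# ---------------------------------------------------------------------------
# Tandem-repeat table I/O.  The TandemRepeat type itself lives in `detect`;
# tables are exchanged through these two functions so every stage shares one
# schema.
# ---------------------------------------------------------------------------

REPEAT_COLUMNS = [
    "genome_id",
    "start_nt",
    "end_nt",
    "period_nt",
    "n_repeats",
    "ni",
    "homogeneity",
    "similarity_score",
    "units",
]


def repeats_to_frame(trs: Sequence["TandemRepeat"]) -> pd.DataFrame:  # noqa: F821
    rows = [
        {
            "genome_id": tr.genome_id,
            "start_nt": tr.start_nt,
            "end_nt": tr.end_nt,
            "period_nt": tr.period_nt,
            "n_repeats": tr.n_repeats,
            "ni": tr.ni,
            "homogeneity": tr.homogeneity,
            "similarity_score": (
                "" if tr.similarity_score is None else repr(tr.similarity_score)
            ),
            "units": ",".join(tr.units),
        }
        for tr in trs
    ]
    return pd.DataFrame(rows, columns=REPEAT_COLUMNS)


def write_repeat_table(trs: Sequence["TandemRepeat"], path) -> None:  # noqa: F821
    """Write tandem repeats as a fixed-header TSV (byte-stable for a fixed
    input ordering)."""
    repeats_to_frame(trs).to_csv(path, sep="\t", index=False)


def read_repeat_table(path) -> List["TandemRepeat"]:  # noqa: F821
    """Read a repeat TSV written by :func:`write_repeat_table`.

    Raises :class:`SchemaError` if any required column is missing.
    """
    from .detect import TandemRepeat

    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in REPEAT_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing columns {missing}")
    out: List[TandemRepeat] = []
    for row in df.itertuples(index=False):
        sim = None if row.similarity_score == "" else float(row.similarity_score)
        out.append(
            TandemRepeat(
                genome_id=row.genome_id,
                start_nt=int(row.start_nt),
                period_nt=int(row.period_nt),
                units=tuple(row.units.split(",")) if row.units else (),
                ni=int(row.ni),
                homogeneity=float(row.homogeneity),
                similarity_score=sim,
            )
        )
    return out
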