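"""Core sequence records shared across the pipeline stages.

Reads are held as plain Python objects with numpy quality arrays; FASTQ
round-tripping goes through Biopython so the on-disk format is standard
phred+33 FASTQ.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

VALID_BASES = frozenset("ACGTN")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (A/C/G/T/N)."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class ReadRecord:
    """A single sequenced read with per-base phred qualities.

    ``mate`` is 1 or 2 for paired reads, 0 for unpaired. Downstream
    stages treat all reads as single-end; the mate flag is carried only
    so that FASTQ output can keep conventional ``/1`` ``/2`` naming.
    """

    read_id: str
    sequence: str
    qualities: np.ndarray  # uint8 phred scores, same length as sequence
    mate: int = 0
    library_id: str = ""

    def __post_init__(self) -> None:
        self.qualities = np.asarray(self.qualities, dtype=np.uint8)
        if len(self.sequence) != len(self.qualities):
            raise ValueError(
                f"read {self.read_id}: sequence length {len(self.sequence)} "
                f"!= quality length {len(self.qualities)}"
            )

    def __len__(self) -> int:
        return len(self.sequence)


def write_fastq(reads: Iterable[ReadRecord], path: str | Path) -> int:
    """Write reads as phred+33 FASTQ. Returns the number written."""
    n = 0
    with open(path, "w") as fh:
        for r in reads:
            qual = "".join(chr(q + 33) for q in r.qualities)
            fh.write(f"@{r.read_id}\n{r.sequence}\n+\n{qual}\n")
            n += 1
    return n


def read_fastq(path: str | Path, library_id: str = "") -> list[ReadRecord]:
    """Load a FASTQ file into ReadRecords (mate inferred from /1 or /2 suffix)."""
    out: list[ReadRecord] = []
    for rec in SeqIO.parse(str(path), "fastq"):
        mate = 0
        if rec.id.endswith("/1"):
            mate = 1
        elif rec.id.endswith("/2"):
            mate = 2
        out.append(
            ReadRecord(
                read_id=rec.id,
                sequence=str(rec.seq).upper(),
                qualities=np.asarray(
                    rec.letter_annotations["phred_quality"], dtype=np.uint8
                ),
                mate=mate,
                library_id=library_id,
            )
        )
    return out


def write_fasta(seqs: dict[str, str], path: str | Path) -> None:
    """Write a name -> sequence mapping as FASTA (60-column wrap)."""
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def iter_fastq_ids(path: str | Path) -> Iterator[str]:
    for rec in SeqIO.parse(str(path), "fastq"):
        yield rec.id
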