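"""Feature annotations of repeat reference contigs, with GFF3 I/O.

Internally every interval is 0-based half-open. GFF3 files follow the
standard's 1-based inclusive convention; conversion happens only at the
file boundary.

The feature vocabulary is that of LTR retrotransposons and cut-and-paste
DNA transposons: flanking long terminal repeats (``LTR``) or terminal
inverted repeats (``TIR``), and the internal coding regions — capsid
protein (``GAG``), aspartic proteinase (``AP``), reverse transcriptase
(``RT``), RNase H (``RH``) and integrase (``IT``); ``transposase`` for
class II elements. Anything else is ``other_gene``.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

GENE_FEATURES = frozenset({"GAG", "AP", "RT", "RH", "IT", "transposase", "other_gene"})
TERMINAL_FEATURES = frozenset({"LTR", "TIR"})
KNOWN_FEATURES = GENE_FEATURES | TERMINAL_FEATURES

# LTRharvest/LTRdigest-style GFF3 types and protein-match names mapped to
# the internal vocabulary; types mapping to None are ignored.
_GFF_TYPE_MAP: dict[str, str | None] = {
    "long_terminal_repeat": "LTR",
    "LTR_retrotransposon": None,
    "repeat_region": None,
    "RR_tract": None,
    "target_site_duplication": None,
    "terminal_inverted_repeat": "TIR",
    "protein_match": "__by_name__",
}
_PROTEIN_NAME_MAP = {
    "RT": "RT",
    "RVT": "RT",
    "IN": "IT",
    "IT": "IT",
    "INT": "IT",
    "GAG": "GAG",
    "AP": "AP",
    "PROT": "AP",
    "RH": "RH",
    "RNASEH": "RH",
    "TRANSPOSASE": "transposase",
}


@dataclass(frozen=True)
class FeatureAnnotation:
    """One annotated component interval on a reference contig."""

    contig_id: str
    feature: str
    start: int  # 0-based inclusive
    end: int  # 0-based exclusive

    def __post_init__(self) -> None:
        if not 0 <= self.start < self.end:
            raise ValueError(f"bad interval [{self.start}, {self.end})")

    @property
    def length(self) -> int:
        return self.end - self.start


def write_gff3(annotations: Iterable[FeatureAnnotation], path: str | Path) -> None:
    """Write annotations as GFF3 (1-based inclusive coordinates)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for a in annotations:
            fh.write(
                f"{a.contig_id}\trepeatfp\t{_gff_type(a.feature)}\t"
                f"{a.start + 1}\t{a.end}\t.\t+\t.\tName={a.feature}\n"
            )


def _gff_type(feature: str) -> str:
    if feature == "LTR":
        return "long_terminal_repeat"
    if feature == "TIR":
        return "terminal_inverted_repeat"
    return "protein_match"


def read_gff3(path: str | Path) -> list[FeatureAnnotation]:
    """Read a GFF3 feature file, mapping LTRdigest-style types.

    ``long_terminal_repeat`` becomes ``LTR``; ``protein_match`` records
    are classified by their ``Name`` attribute (RT/IT/GAG/AP/RH,
    unrecognised names become ``other_gene``); container records such as
    ``LTR_retrotransposon`` and ``repeat_region`` are skipped.
    """
    out: list[FeatureAnnotation] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 9:
                raise ValueError(f"{path}:{lineno}: malformed GFF3 record")
            contig, _, gtype, start, end, _, _, _, attrs = parts[:9]
            mapped = _GFF_TYPE_MAP.get(gtype, "other_gene")
            if mapped is None:
                continue
            if mapped == "__by_name__":
                name = _attr(attrs, "Name") or _attr(attrs, "name") or ""
                key = name.upper().split("_")[0]
                mapped = _PROTEIN_NAME_MAP.get(key, "other_gene")
            out.append(FeatureAnnotation(contig, mapped, int(start) - 1, int(end)))
    return out


def _attr(attrs: str, key: str) -> str | None:
    for item in attrs.split(";"):
        if "=" in item:
            k, v = item.split("=", 1)
            if k.strip() == key:
                return v.strip()
    return None
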