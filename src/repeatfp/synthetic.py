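"""Synthetic genome and read-library simulator with recorded ground truth.

The simulator emulates the statistical structure that the downstream
copy-number analysis assumes: a background of unique sequence, a set of
single-copy conserved genes (UCOS analogues) used as the depth baseline,
and multi-copy transposable-element families of both classes whose
copies diverge from their family consensus by an i.i.d. substitution
process. Satellite families tile a short motif, producing the
low-complexity clusters seen in de novo repeat graphs.

Copies and genes are *inserted* into the background rather than written
over it, so adding repeat content grows the genome while leaving the
single-copy space untouched — which is exactly the regime in which
normalising repeat coverage by single-copy coverage recovers copy
number.

Everything is deterministic under a fixed seed; a :class:`TruthSet`
records every placement and every mutated site so that recovery can be
scored exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np

from .annotations import FeatureAnnotation
from .records import ReadRecord

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_IDX = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _IDX[_b] = _i


def seq_to_idx(seq: str) -> np.ndarray:
    """DNA string -> uint8 array of base indices 0..3 (N and others -> 255)."""
    return _IDX[np.frombuffer(seq.encode(), dtype=np.uint8)]


def idx_to_seq(arr: np.ndarray) -> str:
    return _BASES[arr].tobytes().decode()


def random_dna(rng: np.random.Generator, n: int) -> np.ndarray:
    return rng.integers(0, 4, size=n, dtype=np.uint8)


def mutate(
    rng: np.random.Generator, arr: np.ndarray, divergence: float
) -> tuple[np.ndarray, tuple[int, ...], str]:
    """Apply Binomial(len, divergence) substitutions at distinct sites.

    Returns (mutated array, sorted mutated offsets, alt bases string).
    """
    n_mut = int(rng.binomial(len(arr), divergence)) if divergence > 0 else 0
    if n_mut == 0:
        return arr.copy(), (), ""
    offsets = np.sort(rng.choice(len(arr), size=n_mut, replace=False))
    out = arr.copy()
    shifts = rng.integers(1, 4, size=n_mut, dtype=np.uint8)
    out[offsets] = (out[offsets] + shifts) % 4
    return out, tuple(int(o) for o in offsets), idx_to_seq(out[offsets])


# ---------------------------------------------------------------------------
# specifications


@dataclass
class FamilySpec:
    """Specification of one repeat family to plant in the synthetic genome."""

    family_id: str
    te_class: str  # "I", "II" or "satellite"
    superfamily: str
    consensus_length: int
    copy_number: int
    per_copy_divergence: float = 0.0
    feature_layout: tuple[tuple[str, int, int], ...] | None = None
    sequence: str | None = None  # fix the consensus instead of drawing it

    def __post_init__(self) -> None:
        if self.te_class not in ("I", "II", "satellite"):
            raise ValueError(f"unknown te_class {self.te_class!r}")
        if self.copy_number < 0:
            raise ValueError("copy_number must be >= 0")
        if not 0.0 <= self.per_copy_divergence < 0.5:
            raise ValueError("per_copy_divergence must be in [0, 0.5)")
        if self.sequence is not None and len(self.sequence) != self.consensus_length:
            raise ValueError("sequence length != consensus_length")
        if self.feature_layout is not None:
            self._check_layout()

    def _check_layout(self) -> None:
        prev_end = 0
        ltr_lens = []
        for name, start, end in sorted(self.feature_layout, key=lambda f: f[1]):
            if not 0 <= start < end <= self.consensus_length:
                raise ValueError(f"feature {name} outside consensus")
            if start < prev_end:
                raise ValueError(f"feature {name} overlaps a previous feature")
            prev_end = end
            if name == "LTR":
                ltr_lens.append(end - start)
        if self.te_class == "I" and ltr_lens and len(set(ltr_lens)) > 1:
            raise ValueError("the two LTR intervals must have equal length")


def class_i_layout(length: int, ltr_len: int | None = None) -> tuple[tuple[str, int, int], ...]:
    """Canonical LTR-retroelement layout: LTR, GAG, AP, RT, RH, IT, LTR.

    Internal ORFs are placed with small spacers mirroring the structure
    of Gypsy/Copia elements; proportions scale with ``length``.
    """
    ltr = ltr_len if ltr_len is not None else max(100, length // 8)
    inner = length - 2 * ltr
    if inner < 600:
        raise ValueError("consensus too short for a class I layout")
    orfs = ("GAG", "AP", "RT", "RH", "IT")
    spacer = inner // 12
    orf_len = (inner - 6 * spacer) // 5
    layout = [("LTR", 0, ltr)]
    pos = ltr + spacer
    for name in orfs:
        layout.append((name, pos, pos + orf_len))
        pos += orf_len + spacer
    layout.append(("LTR", length - ltr, length))
    return tuple(layout)


def class_ii_layout(length: int, tir_len: int = 30) -> tuple[tuple[str, int, int], ...]:
    """Cut-and-paste DNA transposon layout: TIR, transposase, TIR."""
    if length < 2 * tir_len + 200:
        raise ValueError("consensus too short for a class II layout")
    pad = (length - 2 * tir_len) // 10
    return (
        ("TIR", 0, tir_len),
        ("transposase", tir_len + pad, length - tir_len - pad),
        ("TIR", length - tir_len, length),
    )


@dataclass
class LibraryProfile:
    """Sequencing-library parameters for the paired-end read simulator.

    ``mean_depth`` is fold coverage of the genome (and hence of the
    single-copy space, since repeats are inserted, not overlaid).
    Default qualities are constant Q35 with a linearly decaying 10-base
    tail reaching Q8, so that end-trimming at Q20 has work to do.
    """

    read_length: int = 60
    mean_depth: float = 5.0
    base_error_rate: float = 0.002
    insert_size_mean: float = 300.0
    insert_size_sd: float = 30.0
    seed: int = 0
    library_id: str = "lib"

    def __post_init__(self) -> None:
        if self.read_length not in (60, 80) and self.read_length < 20:
            raise ValueError("read_length too short")
        if self.mean_depth <= 0:
            raise ValueError("mean_depth must be > 0")
        if self.insert_size_mean < self.read_length:
            raise ValueError("insert size shorter than read length")

    def quality_profile(self) -> np.ndarray:
        """Per-position phred scores (identical for every simulated read)."""
        q = np.full(self.read_length, 35, dtype=np.uint8)
        tail = min(10, self.read_length)
        q[-tail:] = np.linspace(35, 8, tail).round().astype(np.uint8)
        return q


# ---------------------------------------------------------------------------
# ground truth


@dataclass(frozen=True)
class Placement:
    """One planted copy of a repeat family on the synthetic genome."""

    family_id: str
    copy_index: int
    start: int
    end: int
    mut_offsets: tuple[int, ...] = ()  # consensus offsets substituted in this copy
    mut_bases: str = ""  # the substituted bases, parallel to mut_offsets


@dataclass(frozen=True)
class UcosPlacement:
    ucos_id: str
    start: int
    end: int


@dataclass
class TruthSet:
    """Complete ground truth of a synthetic genome build."""

    genome_size: int
    families: dict[str, FamilySpec]
    placements: list[Placement]
    ucos: list[UcosPlacement]

    def copy_number(self, family_id: str) -> int:
        return sum(1 for p in self.placements if p.family_id == family_id)

    def occupancy(self, family_id: str) -> float:
        """Fraction of genome bases occupied by the family's copies."""
        bases = sum(p.end - p.start for p in self.placements if p.family_id == family_id)
        return bases / self.genome_size

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, TruthSet):
            return NotImplemented
        return (
            self.genome_size == other.genome_size
            and sorted(self.ucos, key=lambda u: u.ucos_id)
            == sorted(other.ucos, key=lambda u: u.ucos_id)
            and sorted(self.placements, key=lambda p: (p.family_id, p.copy_index))
            == sorted(other.placements, key=lambda p: (p.family_id, p.copy_index))
            and {k: _spec_key(v) for k, v in self.families.items()}
            == {k: _spec_key(v) for k, v in other.families.items()}
        )


def _spec_key(s: FamilySpec) -> tuple:
    return (
        s.family_id,
        s.te_class,
        s.superfamily,
        s.consensus_length,
        s.copy_number,
        s.per_copy_divergence,
    )


def write_truth(truth: TruthSet, path: str | Path) -> None:
    """Serialise a TruthSet as TSV; read_truth round-trips it exactly."""
    with open(path, "w") as fh:
        fh.write("#record\tid\tfield1\tfield2\tfield3\tfield4\tfield5\tfield6\n")
        fh.write(f"genome\t.\t{truth.genome_size}\t.\t.\t.\t.\t.\n")
        for fid in sorted(truth.families):
            s = truth.families[fid]
            fh.write(
                f"family\t{fid}\t{s.te_class}\t{s.superfamily}\t"
                f"{s.consensus_length}\t{s.copy_number}\t{s.per_copy_divergence!r}\t.\n"
            )
        for p in sorted(truth.placements, key=lambda p: (p.family_id, p.copy_index)):
            offs = ",".join(map(str, p.mut_offsets)) or "."
            bases = p.mut_bases or "."
            fh.write(
                f"placement\t{p.family_id}\t{p.copy_index}\t{p.start}\t{p.end}\t"
                f"{offs}\t{bases}\t.\n"
            )
        for u in sorted(truth.ucos, key=lambda u: u.ucos_id):
            fh.write(f"ucos\t{u.ucos_id}\t{u.start}\t{u.end}\t.\t.\t.\t.\n")


def read_truth(path: str | Path) -> TruthSet:
    genome_size = 0
    families: dict[str, FamilySpec] = {}
    placements: list[Placement] = []
    ucos: list[UcosPlacement] = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            kind = parts[0]
            if kind == "genome":
                genome_size = int(parts[2])
            elif kind == "family":
                families[parts[1]] = FamilySpec(
                    family_id=parts[1],
                    te_class=parts[2],
                    superfamily=parts[3],
                    consensus_length=int(parts[4]),
                    copy_number=int(parts[5]),
                    per_copy_divergence=float(parts[6]),
                )
            elif kind == "placement":
                offs = () if parts[5] == "." else tuple(int(x) for x in parts[5].split(","))
                bases = "" if parts[6] == "." else parts[6]
                placements.append(
                    Placement(parts[1], int(parts[2]), int(parts[3]), int(parts[4]), offs, bases)
                )
            elif kind == "ucos":
                ucos.append(UcosPlacement(parts[1], int(parts[2]), int(parts[3])))
    return TruthSet(genome_size, families, placements, ucos)


# ---------------------------------------------------------------------------
# genome construction


@dataclass
class ReferenceBuild:
    """Everything :func:`build_reference` produces."""

    genome: str
    consensus: dict[str, str]  # family_id -> consensus sequence
    ucos: dict[str, str]  # ucos_id -> gene sequence
    annotations: list[FeatureAnnotation]
    truth: TruthSet


def _make_consensus(rng: np.random.Generator, spec: FamilySpec) -> np.ndarray:
    if spec.sequence is not None:
        return seq_to_idx(spec.sequence)
    if spec.te_class == "satellite":
        motif = random_dna(rng, int(rng.integers(5, 12)))
        reps = spec.consensus_length // len(motif) + 1
        return np.tile(motif, reps)[: spec.consensus_length]
    return random_dna(rng, spec.consensus_length)


def build_reference(
    specs: Sequence[FamilySpec],
    n_ucos: int = 20,
    ucos_length: int = 1500,
    background_length: int = 500_000,
    seed: int = 0,
) -> ReferenceBuild:
    """Assemble a synthetic genome with planted repeats and UCOS genes.

    Each family contributes ``copy_number`` copies, each independently
    mutated away from the consensus at ``Binomial(length, divergence)``
    sites; each UCOS gene appears exactly once. All inserts land at
    uniformly drawn, non-overlapping insertion points in the background.
    """
    if not specs:
        raise ValueError("no family specifications given")
    ids = [s.family_id for s in specs]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate family_id in specs")
    if n_ucos < 0 or ucos_length <= 0 or background_length <= 0:
        raise ValueError("counts and lengths must be positive")

    total_insert = sum(s.copy_number * s.consensus_length for s in specs) + n_ucos * ucos_length
    if total_insert > background_length:
        raise ValueError(
            f"requested insert length {total_insert} exceeds background {background_length}"
        )

    rng = np.random.default_rng(seed)
    background = random_dna(rng, background_length)

    consensus: dict[str, np.ndarray] = {s.family_id: _make_consensus(rng, s) for s in specs}
    ucos_seqs: dict[str, np.ndarray] = {
        f"UCOS{i:04d}": random_dna(rng, ucos_length) for i in range(n_ucos)
    }

    # (sort_point, label, copy_index, seq, offsets, bases)
    inserts: list[tuple[int, str, int, np.ndarray, tuple[int, ...], str]] = []
    for s in specs:
        cons = consensus[s.family_id]
        for c in range(s.copy_number):
            seq, offs, bases = mutate(rng, cons, s.per_copy_divergence)
            point = int(rng.integers(0, background_length + 1))
            inserts.append((point, s.family_id, c, seq, offs, bases))
    for uid, seq in ucos_seqs.items():
        point = int(rng.integers(0, background_length + 1))
        inserts.append((point, uid, -1, seq, (), ""))

    inserts.sort(key=lambda t: (t[0], t[1], t[2]))
    pieces: list[np.ndarray] = []
    placements: list[Placement] = []
    ucos_placements: list[UcosPlacement] = []
    prev = 0
    offset = 0
    for point, label, cidx, seq, offs, bases in inserts:
        pieces.append(background[prev:point])
        start = point + offset
        end = start + len(seq)
        pieces.append(seq)
        if cidx >= 0:
            placements.append(Placement(label, cidx, start, end, offs, bases))
        else:
            ucos_placements.append(UcosPlacement(label, start, end))
        offset += len(seq)
        prev = point
    pieces.append(background[prev:])
    genome_arr = np.concatenate(pieces)

    annotations = [
        FeatureAnnotation(s.family_id, name, a, b)
        for s in specs
        if s.feature_layout
        for name, a, b in s.feature_layout
    ]

    spec_map = {s.family_id: s for s in specs}
    truth = TruthSet(
        genome_size=len(genome_arr),
        families=spec_map,
        placements=placements,
        ucos=ucos_placements,
    )
    return ReferenceBuild(
        genome=idx_to_seq(genome_arr),
        consensus={k: idx_to_seq(v) for k, v in consensus.items()},
        ucos={k: idx_to_seq(v) for k, v in ucos_seqs.items()},
        annotations=annotations,
        truth=truth,
    )


# ---------------------------------------------------------------------------
# read simulation


def simulate_reads(genome: str, profile: LibraryProfile) -> list[ReadRecord]:
    """Simulate paired-end reads with uniform fragment starts.

    The number of pairs is ``int(round(mean_depth * G / (2 * read_length)))``
    (round-half-to-even at the .5 boundary, i.e. Python's ``round``).
    Read ids encode the true fragment coordinates as
    ``{library}:{i}:{fragment_start}:{fragment_length}/{mate}`` so that
    error rates and mapping can be scored against the source without a
    side table. Sequencing errors are i.i.d. substitutions at
    ``base_error_rate``; qualities come from the profile's quality model
    and are independent of the injected errors.
    """
    G = len(genome)
    L = profile.read_length
    if G < profile.insert_size_mean:
        raise ValueError("genome shorter than mean insert size")
    n_pairs = int(round(profile.mean_depth * G / (2 * L)))
    rng = np.random.default_rng(profile.seed)
    garr = seq_to_idx(genome)
    qual = profile.quality_profile()

    frag_lens = rng.normal(profile.insert_size_mean, profile.insert_size_sd, size=n_pairs)
    frag_lens = np.clip(frag_lens.round().astype(np.int64), L, G)
    starts = (rng.random(n_pairs) * (G - frag_lens + 1)).astype(np.int64)
    n_err1 = rng.binomial(L, profile.base_error_rate, size=n_pairs)
    n_err2 = rng.binomial(L, profile.base_error_rate, size=n_pairs)

    reads: list[ReadRecord] = []
    lib = profile.library_id
    for i in range(n_pairs):
        s, flen = int(starts[i]), int(frag_lens[i])
        fwd = garr[s : s + L]
        rev = (3 - garr[s + flen - L : s + flen])[::-1]
        if n_err1[i]:
            fwd = _inject(rng, fwd, int(n_err1[i]))
        if n_err2[i]:
            rev = _inject(rng, rev, int(n_err2[i]))
        stem = f"{lib}:{i}:{s}:{flen}"
        reads.append(ReadRecord(f"{stem}/1", idx_to_seq(fwd), qual, 1, lib))
        reads.append(ReadRecord(f"{stem}/2", idx_to_seq(rev), qual, 2, lib))
    return reads


def _inject(rng: np.random.Generator, arr: np.ndarray, n_err: int) -> np.ndarray:
    out = arr.copy()
    pos = rng.choice(len(arr), size=n_err, replace=False)
    out[pos] = (out[pos] + rng.integers(1, 4, size=n_err, dtype=np.uint8)) % 4
    return out


def source_interval(read_id: str) -> tuple[int, int, int]:
    """Decode (fragment_start, fragment_length, mate) from a simulated read id."""
    stem, mate = read_id.rsplit("/", 1)
    _, _, start, flen = stem.rsplit(":", 3)
    return int(start), int(flen), int(mate)
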