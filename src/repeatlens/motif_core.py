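"""Motif alphabet, allele structures, tiling decomposition and classification.

The EIF4A3 5'UTR repeat array is built from three near-identical units that
share a 10-nt head (TCGGCAGCGG) and differ only in their central nucleotides:

* ``CA18``   — TCGGCAGCGG **CA** GCGAGG (18 nt, 3 CpGs)
* ``CACA20`` — TCGGCAGCGG **CACA** GCGAGG (20 nt, 3 CpGs)
* ``CGCA20`` — TCGGCAGCGG **CGCA** GCGAGG (20 nt, 4 CpGs; the
  disease-associated unit, enriched in pathogenic alleles)

An allele is an ordered list of these units, optionally interrupted by short
non-motif insertions.  This module provides the exact tiling decomposition of
a raw sequence into units, its inverse (composition), CpG accounting, and the
recessive classification rules (pathogenic candidacy requires >=14 repeats
carrying at least one CGCA20 unit; both alleles pathogenic => affected).
"""

from __future__ import annotations

import re
from collections import Counter
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Iterator, Sequence

from .errors import (
    AlphabetError,
    DecompositionError,
    SequenceError,
    StructureError,
    UsageError,
)

_DNA_RE = re.compile(r"^[ACGT]+$")

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def _check_dna(seq: str, what: str = "sequence") -> str:
    if not seq or not _DNA_RE.match(seq):
        raise SequenceError(f"{what} must be a non-empty uppercase ACGT string, got {seq!r}")
    return seq


# ---------------------------------------------------------------------------
# Alphabet
# ---------------------------------------------------------------------------

DEFAULT_MOTIFS: tuple[tuple[str, str], ...] = (
    ("CA18", "TCGGCAGCGGCAGCGAGG"),
    ("CACA20", "TCGGCAGCGGCACAGCGAGG"),
    ("CGCA20", "TCGGCAGCGGCGCAGCGAGG"),
)

#: Identifier of the disease-associated motif in the default alphabet.
DISEASE_MOTIF = "CGCA20"


@dataclass(frozen=True)
class MotifAlphabet:
    """An ordered set of (motif_id, sequence) repeat units."""

    entries: tuple[tuple[str, str], ...] = DEFAULT_MOTIFS

    def __post_init__(self):
        ids = [m for m, _ in self.entries]
        if len(ids) != len(set(ids)):
            raise AlphabetError(f"duplicate motif ids in alphabet: {ids}")
        for _, seq in self.entries:
            _check_dna(seq, "motif sequence")

    @classmethod
    def default(cls) -> "MotifAlphabet":
        return cls(DEFAULT_MOTIFS)

    @property
    def ids(self) -> tuple[str, ...]:
        return tuple(m for m, _ in self.entries)

    def sequence(self, motif_id: str) -> str:
        for m, seq in self.entries:
            if m == motif_id:
                return seq
        raise AlphabetError(f"unknown motif id {motif_id!r}; alphabet has {self.ids}")

    def cpg_count(self, motif_id: str) -> int:
        return self.sequence(motif_id).count("CG")

    def contains_motif(self, seq: str) -> bool:
        """True if any full motif occurs as a substring of ``seq``."""
        return any(m in seq for _, m in self.entries)

    def sorted_by_length(self) -> list[tuple[str, str]]:
        return sorted(self.entries, key=lambda e: -len(e[1]))


DEFAULT_ALPHABET = MotifAlphabet.default()


# ---------------------------------------------------------------------------
# Allele structure
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Insertion:
    """A non-motif segment spliced after the motif at ``after_index`` (0-based)."""

    after_index: int
    sequence: str


@dataclass(frozen=True)
class AlleleStructure:
    """An ordered motif list plus optional non-motif insertion segments."""

    motifs: tuple[str, ...]
    insertions: tuple[Insertion, ...] = ()
    label: str | None = None

    def __post_init__(self):
        object.__setattr__(self, "motifs", tuple(self.motifs))
        object.__setattr__(self, "insertions", tuple(self.insertions))

    @property
    def repeat_count(self) -> int:
        return len(self.motifs)

    @property
    def has_insertions(self) -> bool:
        return bool(self.insertions)

    def motif_counts(self) -> Counter:
        return Counter(self.motifs)

    def structure_key(self) -> tuple:
        """Hashable identity ignoring the label."""
        return (self.motifs, self.insertions)

    def __str__(self) -> str:
        return format_nomenclature(self)


class AlleleClass(Enum):
    CONTROL_TYPICAL = "CONTROL_TYPICAL"
    DISEASE_MOTIF_CARRIER = "DISEASE_MOTIF_CARRIER"
    PATHOGENIC_CANDIDATE = "PATHOGENIC_CANDIDATE"
    ATYPICAL_INSERTION = "ATYPICAL_INSERTION"


class AffectedStatus(Enum):
    AFFECTED = "AFFECTED"
    CARRIER = "CARRIER"
    UNAFFECTED = "UNAFFECTED"


@dataclass(frozen=True)
class ClassificationConfig:
    """Thresholds for pathogenic candidacy, exposed as configuration.

    Control alleles in the reference cohort span 2-12 repeats and patient
    alleles 14-16 (plus one 17-repeat allele asserted pathogenic in
    homozygosis); 13-repeat alleles were observed in neither group, so any
    allele whose repeat count falls strictly between ``control_max_repeats``
    and ``min_pathogenic_repeats`` is flagged as being in the indeterminate
    zone.
    """

    min_pathogenic_repeats: int = 14
    control_max_repeats: int = 12
    disease_motif: str = DISEASE_MOTIF

    def indeterminate_zone(self, repeat_count: int) -> bool:
        return self.control_max_repeats < repeat_count < self.min_pathogenic_repeats


DEFAULT_CLASSIFICATION = ClassificationConfig()


@dataclass(frozen=True)
class DiploidGenotype:
    """Two allele structures plus optional genotypes at the 5 flanking SNPs."""

    allele1: AlleleStructure
    allele2: AlleleStructure
    snp_genotypes: tuple | None = None
    sample_id: str = ""

    @property
    def heterozygous(self) -> bool:
        return self.allele1.structure_key() != self.allele2.structure_key()


# ---------------------------------------------------------------------------
# Compose / decompose
# ---------------------------------------------------------------------------


def compose_allele(structure: AlleleStructure, alphabet: MotifAlphabet = DEFAULT_ALPHABET) -> str:
    """Concatenate motif sequences in order, splicing insertions after their index."""
    n = structure.repeat_count
    by_index: dict[int, list[str]] = {}
    for ins in structure.insertions:
        if not (0 <= ins.after_index < n):
            raise StructureError(
                f"insertion after_index {ins.after_index} out of range for {n} motifs"
            )
        _check_dna(ins.sequence, "insertion sequence")
        by_index.setdefault(ins.after_index, []).append(ins.sequence)
    parts: list[str] = []
    for i, motif_id in enumerate(structure.motifs):
        parts.append(alphabet.sequence(motif_id))
        parts.extend(by_index.get(i, ()))
    return "".join(parts)


def _tilings(
    dna: str,
    alphabet: MotifAlphabet,
    allow_insertions: bool,
    max_insertion_len: int,
    limit: int = 1,
) -> Iterator[tuple[tuple[str, ...], tuple[Insertion, ...]]]:
    """Yield up to ``limit`` exact tilings by depth-first backtracking.

    Motif matches are preferred longest-first; an insertion is only attempted
    after at least one motif, kept as short as possible, and must not contain
    a full motif occurrence.  Tracks the deepest failing offset for error
    reporting (stored on the generator via the ``fail`` attribute trick is
    avoided; the caller recomputes it).
    """
    motifs = alphabet.sorted_by_length()
    n = len(dna)
    found = 0
    # stack entries: (pos, motifs_so_far, insertions_so_far)
    def rec(pos: int, acc: list[str], ins: list[Insertion]):
        nonlocal found
        if found >= limit:
            return
        if pos == n:
            if acc:
                found += 1
                yield tuple(acc), tuple(ins)
            return
        for motif_id, seq in motifs:
            if dna.startswith(seq, pos):
                acc.append(motif_id)
                yield from rec(pos + len(seq), acc, ins)
                acc.pop()
                if found >= limit:
                    return
        if allow_insertions and acc:
            # shortest insertion first; must end the sequence or be followed
            # by a motif match
            for k in range(1, min(max_insertion_len, n - pos) + 1):
                seg = dna[pos : pos + k]
                if alphabet.contains_motif(seg):
                    break
                end = pos + k
                if end == n:
                    ins.append(Insertion(len(acc) - 1, seg))
                    yield from rec(end, acc, ins)
                    ins.pop()
                elif any(dna.startswith(s, end) for _, s in motifs):
                    ins.append(Insertion(len(acc) - 1, seg))
                    yield from rec(end, acc, ins)
                    ins.pop()
                if found >= limit:
                    return

    yield from rec(0, [], [])


def _first_failing_offset(dna: str, alphabet: MotifAlphabet) -> int:
    """Deepest offset reachable by greedy tiling — the first position where
    no motif matches."""
    pos = 0
    motifs = alphabet.sorted_by_length()
    while pos < len(dna):
        for _, seq in motifs:
            if dna.startswith(seq, pos):
                pos += len(seq)
                break
        else:
            return pos
    return pos


def decompose_sequence(
    dna: str,
    alphabet: MotifAlphabet = DEFAULT_ALPHABET,
    allow_insertions: bool = False,
    max_insertion_len: int = 20,
    auto_orient: bool = False,
    label: str | None = None,
) -> AlleleStructure:
    """Tile ``dna`` exactly into alphabet motifs (optionally with insertions).

    For the default alphabet the tiling is unique: all three units start with
    the same 10-nt head and end in GG, so motif boundaries can only occur at
    GG|TC junctions.  Backtracking is used anyway so that user-supplied
    alphabets where greedy matching fails are still handled correctly.

    With ``auto_orient`` the reverse complement is tried if the given
    orientation does not tile (the genomic strand of the printed motifs is
    not standardized).
    """
    _check_dna(dna, "allele sequence")
    for candidate in ((dna,) if not auto_orient else (dna, reverse_complement(dna))):
        for motifs, insertions in _tilings(
            candidate, alphabet, allow_insertions, max_insertion_len, limit=1
        ):
            return AlleleStructure(motifs=motifs, insertions=insertions, label=label)
    offset = _first_failing_offset(dna, alphabet)
    raise DecompositionError(
        f"sequence of length {len(dna)} is not tileable by the alphabet "
        f"(first failing offset {offset}"
        + ("" if allow_insertions else "; insertions disabled") + ")",
        offset=offset,
    )


def enumerate_tilings(
    dna: str,
    alphabet: MotifAlphabet = DEFAULT_ALPHABET,
    allow_insertions: bool = False,
    max_insertion_len: int = 20,
    limit: int = 16,
) -> list[AlleleStructure]:
    """All exact tilings (up to ``limit``); used to assert tiling uniqueness."""
    _check_dna(dna, "allele sequence")
    return [
        AlleleStructure(motifs=m, insertions=i)
        for m, i in _tilings(dna, alphabet, allow_insertions, max_insertion_len, limit=limit)
    ]


# ---------------------------------------------------------------------------
# CpG accounting
# ---------------------------------------------------------------------------


def count_cpg(
    x: str | AlleleStructure, alphabet: MotifAlphabet = DEFAULT_ALPHABET
) -> int:
    """Number of CG dinucleotides in a sequence or composed structure.

    CG cannot overlap itself, so a plain substring count is exact.  Motif
    junctions in the default alphabet are G|T and never create CpGs, making
    the count additive over motifs for insertion-free alleles.
    """
    if isinstance(x, AlleleStructure):
        x = compose_allele(x, alphabet)
    else:
        _check_dna(x)
    return x.count("CG")


def cpg_positions(seq: str) -> list[int]:
    """0-based positions of the C of every CG dinucleotide."""
    _check_dna(seq)
    return [m.start() for m in re.finditer("CG", seq)]


# ---------------------------------------------------------------------------
# Classification
# ---------------------------------------------------------------------------


def classify_allele(
    structure: AlleleStructure, config: ClassificationConfig = DEFAULT_CLASSIFICATION
) -> AlleleClass:
    """Classify one allele.

    Insertion-bearing alleles are atypical regardless of composition;
    otherwise pathogenic candidacy requires both the repeat-count threshold
    and at least one disease motif.
    """
    if structure.has_insertions:
        return AlleleClass.ATYPICAL_INSERTION
    n_disease = structure.motifs.count(config.disease_motif)
    if n_disease >= 1 and structure.repeat_count >= config.min_pathogenic_repeats:
        return AlleleClass.PATHOGENIC_CANDIDATE
    if n_disease >= 1:
        return AlleleClass.DISEASE_MOTIF_CARRIER
    return AlleleClass.CONTROL_TYPICAL


def classify_genotype(
    g: DiploidGenotype, config: ClassificationConfig = DEFAULT_CLASSIFICATION
) -> AffectedStatus:
    """Recessive model: affected iff both alleles are pathogenic candidates."""
    c1 = classify_allele(g.allele1, config) is AlleleClass.PATHOGENIC_CANDIDATE
    c2 = classify_allele(g.allele2, config) is AlleleClass.PATHOGENIC_CANDIDATE
    if c1 and c2:
        return AffectedStatus.AFFECTED
    if c1 or c2:
        return AffectedStatus.CARRIER
    return AffectedStatus.UNAFFECTED


# ---------------------------------------------------------------------------
# Cohort summary
# ---------------------------------------------------------------------------


@dataclass
class CohortSummary:
    n_individuals: int
    n_alleles: int
    distinct_alleles: int
    structure_freqs: dict[str, float]
    repeat_count_freqs: dict[int, float]
    heterozygosity: float
    carrier_allele_fraction: float
    min_repeats: int
    max_repeats: int

    def carrier_percent(self, whole: bool = False) -> float:
        """Carrier-allele fraction as a percentage (2 decimals, or nearest
        whole percent when ``whole``)."""
        pct = 100.0 * self.carrier_allele_fraction
        return round(pct) if whole else round(pct, 2)


def summarize_cohort(
    genotypes: Sequence[DiploidGenotype],
    config: ClassificationConfig = DEFAULT_CLASSIFICATION,
) -> CohortSummary:
    """Allele spectrum, heterozygosity and carrier-allele fraction of a cohort."""
    if not genotypes:
        raise UsageError("summarize_cohort requires at least one genotype")
    alleles = [a for g in genotypes for a in (g.allele1, g.allele2)]
    n = len(alleles)
    struct_counts = Counter(format_nomenclature(a) for a in alleles)
    repeat_counts = Counter(a.repeat_count for a in alleles)
    het = sum(g.heterozygous for g in genotypes) / len(genotypes)
    carriers = sum(a.motifs.count(config.disease_motif) >= 1 for a in alleles)
    return CohortSummary(
        n_individuals=len(genotypes),
        n_alleles=n,
        distinct_alleles=len(struct_counts),
        structure_freqs={k: round(v / n, 4) for k, v in struct_counts.most_common()},
        repeat_count_freqs={k: round(v / n, 4) for k, v in sorted(repeat_counts.items())},
        heterozygosity=het,
        carrier_allele_fraction=carriers / n,
        min_repeats=min(repeat_counts),
        max_repeats=max(repeat_counts),
    )


# ---------------------------------------------------------------------------
# Nomenclature strings
# ---------------------------------------------------------------------------

_RUN_RE = re.compile(r"^(\d+)x(\w+)$")
_INS_RE = re.compile(r"^\[ins:([ACGT]+)\]$")


def format_nomenclature(structure: AlleleStructure) -> str:
    """Serialize a structure, e.g. ``3xCACA20+CA18`` or ``2xCA18+[ins:AAAA]+CA18``.

    Runs of identical motifs are collapsed as ``NxID``; insertions appear as
    ``[ins:SEQ]`` tokens after the motif they follow.  ``parse_nomenclature``
    is the exact inverse.
    """
    ins_after: dict[int, list[str]] = {}
    for ins in structure.insertions:
        ins_after.setdefault(ins.after_index, []).append(ins.sequence)
    tokens: list[str] = []
    run_id, run_len = None, 0

    def flush():
        nonlocal run_id, run_len
        if run_len:
            tokens.append(run_id if run_len == 1 else f"{run_len}x{run_id}")
        run_id, run_len = None, 0

    for i, motif_id in enumerate(structure.motifs):
        if motif_id == run_id:
            run_len += 1
        else:
            flush()
            run_id, run_len = motif_id, 1
        if i in ins_after:
            flush()
            tokens.extend(f"[ins:{seq}]" for seq in ins_after[i])
    flush()
    return "+".join(tokens)


def parse_nomenclature(
    s: str, alphabet: MotifAlphabet = DEFAULT_ALPHABET, label: str | None = None
) -> AlleleStructure:
    """Inverse of :func:`format_nomenclature`."""
    motifs: list[str] = []
    insertions: list[Insertion] = []
    for token in s.split("+"):
        token = token.strip()
        if not token:
            raise StructureError(f"empty token in nomenclature string {s!r}")
        m = _INS_RE.match(token)
        if m:
            if not motifs:
                raise StructureError("insertion token before any motif")
            insertions.append(Insertion(len(motifs) - 1, m.group(1)))
            continue
        m = _RUN_RE.match(token)
        if m:
            count, motif_id = int(m.group(1)), m.group(2)
        else:
            count, motif_id = 1, token
        alphabet.sequence(motif_id)  # raises AlphabetError if unknown
        motifs.extend([motif_id] * count)
    return AlleleStructure(tuple(motifs), tuple(insertions), label=label)
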