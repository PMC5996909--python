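"""Sequence-level model of heterozygote Sanger reads and their deconvolution.

When both alleles of a diploid amplicon are sequenced together, the read is
the position-wise superposition of the two allele sequences: wherever they
disagree (typically downstream of a length difference, where the two arrays
go out of frame) the base call is the IUPAC union of the bases present.
``superpose`` is this forward model; ``deconvolve`` inverts it by exact
branch-and-bound search over motif tilings compatible with the ambiguity
pattern, scoring each candidate pair by mismatches against the forward model.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations_with_replacement

from Bio.Data.IUPACData import ambiguous_dna_values

from .errors import DeconvolutionError, ResourceError, SequenceError
from .motif_core import (
    DEFAULT_ALPHABET,
    AlleleStructure,
    MotifAlphabet,
    compose_allele,
    format_nomenclature,
    _check_dna,
)

#: Fixed 30-nt amplicon flanks used by the synthetic generator (primer-side
#: 5' and run-off 3'); arbitrary non-motif sequence.
DEFAULT_FLANKS = (
    "ATTGCCTAGTCAGGTTAAGCTGACCTGAAT",
    "CCATGATTACGGATTCACTGGCCGTCGTTT",
)

# base-set <-> IUPAC code tables derived from Biopython
_CODE_TO_SET: dict[str, frozenset[str]] = {
    code: frozenset(bases)
    for code, bases in ambiguous_dna_values.items()
    if code not in ("X",)
}
_SET_TO_CODE: dict[frozenset[str], str] = {}
for code, s in _CODE_TO_SET.items():
    _SET_TO_CODE.setdefault(s, code)


#: union code for every ordered pair of IUPAC codes (hot path of superpose)
_PAIR_UNION: dict[tuple[str, str], str] = {
    (a, b): _SET_TO_CODE[sa | sb]
    for a, sa in _CODE_TO_SET.items()
    for b, sb in _CODE_TO_SET.items()
}


def iupac_union(*bases: str) -> str:
    """IUPAC code for the union of the base sets of the given codes."""
    s: frozenset[str] = frozenset()
    for b in bases:
        try:
            s |= _CODE_TO_SET[b]
        except KeyError:
            raise SequenceError(f"not an IUPAC DNA code: {b!r}")
    return _SET_TO_CODE[s]


@dataclass(frozen=True)
class MixedSequence:
    """IUPAC superposition of a diploid amplicon's two allele sequences."""

    iupac: str
    amplicon_flanks: tuple[str, str] = DEFAULT_FLANKS
    sample_id: str = ""

    @property
    def length(self) -> int:
        return len(self.iupac)


def superpose(
    seq1: str,
    seq2: str,
    flanks: tuple[str, str] = DEFAULT_FLANKS,
    sample_id: str = "",
) -> MixedSequence:
    """Position-wise IUPAC union of two 5'-aligned amplicons.

    Amplicons are ``flank5 + allele + flank3``; beyond the end of the shorter
    amplicon the code comes from the longer alone.
    """
    _check_dna(seq1), _check_dna(seq2)
    f5, f3 = flanks
    a = f5 + seq1 + f3
    b = f5 + seq2 + f3
    if len(a) > len(b):
        a, b = b, a
    pu = _PAIR_UNION
    out = [pu[x, y] for x, y in zip(a, b)]
    out.append(b[len(a):])
    return MixedSequence("".join(out), flanks, sample_id=sample_id)


@dataclass
class DeconvolutionResult:
    """Ranked candidate genotypes explaining a mixed sequence.

    ``candidates`` is sorted by mismatch count, then lexicographically on the
    (canonically ordered) nomenclature pair; ``exhaustive`` is True when the
    bounded search enumerated the full compatible space.
    """

    candidates: list[tuple[tuple[AlleleStructure, AlleleStructure], int]]
    exhaustive: bool = True

    @property
    def best(self) -> tuple[AlleleStructure, AlleleStructure]:
        return self.candidates[0][0]

    @property
    def ambiguous(self) -> bool:
        zero = [c for c, m in self.candidates if m == self.candidates[0][1]]
        return len(zero) > 1


def _compatible(seq: str, mixed_sets: list[frozenset], start: int) -> bool:
    """Is ``seq`` contained position-wise in the IUPAC base sets of the mixed
    sequence starting at offset ``start``?"""
    if start + len(seq) > len(mixed_sets):
        return False
    for i, base in enumerate(seq):
        if base not in mixed_sets[start + i]:
            return False
    return True


def _enumerate_compatible_alleles(
    mixed: MixedSequence,
    alphabet: MotifAlphabet,
    max_repeats: int,
    node_budget: int,
) -> list[tuple[AlleleStructure, int]]:
    """All insertion-free structures whose amplicon is position-wise
    compatible with a prefix of the mixed sequence.  Returns (structure,
    amplicon_length) pairs."""
    f5, f3 = mixed.amplicon_flanks
    L = mixed.length
    mixed_sets = [_CODE_TO_SET[c] for c in mixed.iupac]
    if not _compatible(f5, mixed_sets, 0):
        raise DeconvolutionError("5' flank incompatible with mixed sequence")
    out: list[tuple[AlleleStructure, int]] = []
    nodes = 0

    def rec(pos: int, motifs: list[str]):
        nonlocal nodes
        nodes += 1
        if nodes > node_budget:
            raise ResourceError(
                f"deconvolution search exceeded {node_budget} nodes at "
                f"{len(out)} candidates; reduce max_repeats"
            )
        if motifs and pos + len(f3) <= L and _compatible(f3, mixed_sets, pos):
            out.append((AlleleStructure(tuple(motifs)), pos + len(f3)))
        if len(motifs) >= max_repeats:
            return
        for motif_id, seq in alphabet.entries:
            if _compatible(seq, mixed_sets, pos):
                motifs.append(motif_id)
                rec(pos + len(seq), motifs)
                motifs.pop()

    rec(len(f5), [])
    return out


def deconvolve(
    mixed: MixedSequence,
    alphabet: MotifAlphabet = DEFAULT_ALPHABET,
    max_repeats: int = 20,
    budget: int = 0,
    node_budget: int = 500_000,
) -> DeconvolutionResult:
    """Infer the two underlying allele structures from a mixed sequence.

    Exact search: enumerates every motif tiling compatible with the IUPAC
    constraints, pairs tilings so that the longer amplicon spans the whole
    read, and keeps pairs whose forward superposition differs from the input
    at <= ``budget`` positions (default 0, exact).  All ties are reported.
    """
    cands = _enumerate_compatible_alleles(mixed, alphabet, max_repeats, node_budget)
    f5, f3 = mixed.amplicon_flanks
    # precompose candidate amplicons once; score pairs with early exit
    amplicons = [
        (a, f5 + compose_allele(a, alphabet) + f3, la) for a, la in cands
    ]
    pu = _PAIR_UNION
    target = mixed.iupac
    results: list[tuple[tuple[AlleleStructure, AlleleStructure], int]] = []
    best_partial: tuple | None = None
    for (a, sa, la), (b, sb, lb) in combinations_with_replacement(amplicons, 2):
        if max(la, lb) != mixed.length:
            continue
        if len(sa) > len(sb):
            sa2, sb2 = sb, sa
        else:
            sa2, sb2 = sa, sb
        limit = budget if best_partial is None else max(budget, best_partial[1] - 1)
        mism = 0
        for i in range(len(sb2)):
            if i < len(sa2):
                u = pu[sa2[i], sb2[i]]
            else:
                u = sb2[i]
            if u != target[i]:
                mism += 1
                if mism > limit + 1:
                    break
        pair = tuple(sorted((a, b), key=lambda s: format_nomenclature(s)))
        if mism <= budget:
            results.append(((pair[0], pair[1]), mism))
        elif best_partial is None or mism < best_partial[1]:
            best_partial = ((pair[0], pair[1]), mism)
    if not results:
        raise DeconvolutionError(
            f"no candidate pair within mismatch budget {budget}",
            best_partial=best_partial,
        )
    results.sort(
        key=lambda r: (
            r[1],
            format_nomenclature(r[0][0]),
            format_nomenclature(r[0][1]),
        )
    )
    # deduplicate unordered pairs
    seen: set = set()
    unique = []
    for (a, b), m in results:
        key = (a.structure_key(), b.structure_key(), m)
        if key not in seen:
            seen.add(key)
            unique.append(((a, b), m))
    return DeconvolutionResult(candidates=unique, exhaustive=True)
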