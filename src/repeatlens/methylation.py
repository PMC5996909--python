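"""In-silico bisulfite conversion, clone filtering and methylation calling.

Bisulfite treatment deaminates unmethylated cytosines to uracil (read as T)
while 5-methylcytosine at CpG sites is protected.  The forward model here
converts each non-CpG cytosine with the stated conversion efficiency and
each CpG cytosine only when unmethylated; only the top (motif-sense) strand
is modelled, since cloned PCR products do not track strand.

Clone filtering mirrors the standard quality thresholds used by clone-based
methylation callers: minimum conversion rate 95%, minimum sequence identity
90%, at most 20% N calls at cytosine positions, and at most 20% gapped
columns.  Identity excludes C->T differences at reference cytosine
positions, which are bisulfite-expected rather than sequencing errors (at
CpG cytosines a T simply means the site was unmethylated).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from Bio import Align
from scipy import stats

from .errors import ParameterError, UsageError
from .motif_core import (
    DEFAULT_ALPHABET,
    AlleleStructure,
    compose_allele,
    cpg_positions,
    _check_dna,
)


@dataclass(frozen=True)
class MethylationProfile:
    """Per-CpG methylation probabilities on a composed reference allele."""

    reference_allele: AlleleStructure
    per_cpg_prob: tuple[float, ...]
    alphabet: object = DEFAULT_ALPHABET

    def __post_init__(self):
        if any(not 0.0 <= p <= 1.0 for p in self.per_cpg_prob):
            raise ParameterError("per-CpG probabilities must be in [0, 1]")
        if len(self.per_cpg_prob) != len(self.cpg_positions):
            raise ParameterError(
                f"profile has {len(self.per_cpg_prob)} probabilities for "
                f"{len(self.cpg_positions)} CpG sites"
            )

    @property
    def reference_sequence(self) -> str:
        return compose_allele(self.reference_allele, self.alphabet)

    @property
    def cpg_positions(self) -> list[int]:
        return cpg_positions(self.reference_sequence)

    @classmethod
    def uniform(cls, allele: AlleleStructure, prob: float, alphabet=DEFAULT_ALPHABET):
        n = len(cpg_positions(compose_allele(allele, alphabet)))
        return cls(allele, (prob,) * n, alphabet)


def bisulfite_convert(
    reference: str,
    methylation_states: Sequence[bool],
    conversion_efficiency: float = 1.0,
    seed: int | np.random.Generator | None = None,
) -> str:
    """Simulate one bisulfite-converted read of ``reference``.

    ``methylation_states`` has one boolean per CpG site (True = methylated).
    Non-CpG cytosines convert C->T with probability ``conversion_efficiency``;
    CpG cytosines convert only when unmethylated (also subject to the
    efficiency).  Guanines, including the G of each CpG, are untouched.
    """
    _check_dna(reference)
    if not 0.0 <= conversion_efficiency <= 1.0:
        raise ParameterError("conversion efficiency must be in [0, 1]")
    cpgs = cpg_positions(reference)
    if len(methylation_states) != len(cpgs):
        raise UsageError(
            f"{len(methylation_states)} methylation states given for "
            f"{len(cpgs)} CpG sites"
        )
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    cpg_set = set(cpgs)
    meth = dict(zip(cpgs, methylation_states))
    out = list(reference)
    for i, base in enumerate(out):
        if base != "C":
            continue
        if i in cpg_set and meth[i]:
            continue  # protected
        if rng.random() < conversion_efficiency:
            out[i] = "T"
    return "".join(out)


@dataclass(frozen=True)
class FilterParams:
    min_conversion: float = 0.95
    min_identity: float = 0.90
    max_n_at_c: float = 0.20
    max_gaps: float = 0.20


DEFAULT_FILTERS = FilterParams()


@dataclass
class CloneRecord:
    read: str
    kept: bool
    fail_reasons: tuple[str, ...]
    conversion: float
    identity: float
    n_at_c: float
    gap_fraction: float
    #: read base aligned to each reference position (None for gap)
    ref_aligned: list | None = None


@dataclass
class CloneSet:
    clones: list[CloneRecord]
    reference: str
    filter_params: FilterParams

    @property
    def kept(self) -> list[CloneRecord]:
        return [c for c in self.clones if c.kept]


def _make_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1
    aligner.mismatch_score = -1
    aligner.open_gap_score = -2
    aligner.extend_gap_score = -2
    # N never rewards a match
    aligner.wildcard = None
    return aligner


def _align_to_reference(reference: str, read: str) -> tuple[list, float]:
    """Global alignment; returns (read base per reference position, gap
    fraction over alignment columns)."""
    aligner = _make_aligner()
    aln = aligner.align(reference, read)[0]
    ref_aligned: list = [None] * len(reference)
    columns = 0
    gap_columns = 0
    ref_idx = aln.indices[0]
    read_idx = aln.indices[1]
    for k in range(aln.shape[1]):
        columns += 1
        ri, qi = ref_idx[k], read_idx[k]
        if ri < 0 or qi < 0:
            gap_columns += 1
            continue
        ref_aligned[ri] = read[qi]
    return ref_aligned, (gap_columns / columns if columns else 0.0)


def filter_clones(
    reads: Sequence[str],
    reference: str,
    params: FilterParams = DEFAULT_FILTERS,
) -> CloneSet:
    """Align clone reads to the (unconverted) reference and apply the four
    quality thresholds; every violated threshold is listed in fail_reasons."""
    _check_dna(reference)
    cpg_set = set(cpg_positions(reference))
    c_positions = [i for i, b in enumerate(reference) if b == "C"]
    non_cpg_c = [i for i in c_positions if i not in cpg_set]
    records = []
    for read in reads:
        ref_aligned, gap_fraction = _align_to_reference(reference, read.upper())
        # conversion: non-CpG reference Cs read as T, over those read as C or T
        conv_t = sum(1 for i in non_cpg_c if ref_aligned[i] == "T")
        conv_tot = sum(1 for i in non_cpg_c if ref_aligned[i] in ("C", "T"))
        conversion = conv_t / conv_tot if conv_tot else 0.0
        # identity over aligned columns, excluding bisulfite-expected C->T at
        # any reference C (CpG or not) and ignoring N calls
        match = mism = 0
        for i, b in enumerate(reference):
            q = ref_aligned[i]
            if q is None or q == "N":
                continue
            if q == b or (b == "C" and q == "T"):
                match += 1
            else:
                mism += 1
        identity = match / (match + mism) if (match + mism) else 0.0
        n_at_c = (
            sum(1 for i in c_positions if ref_aligned[i] == "N") / len(c_positions)
            if c_positions
            else 0.0
        )
        reasons = []
        if identity < 0.5:
            reasons.append("unaligned")
        else:
            if conversion < params.min_conversion:
                reasons.append("conversion")
            if identity < params.min_identity:
                reasons.append("identity")
            if n_at_c > params.max_n_at_c:
                reasons.append("n_at_c")
            if gap_fraction > params.max_gaps:
                reasons.append("gaps")
        records.append(
            CloneRecord(
                read=read,
                kept=not reasons,
                fail_reasons=tuple(reasons),
                conversion=conversion,
                identity=identity,
                n_at_c=n_at_c,
                gap_fraction=gap_fraction,
                ref_aligned=ref_aligned,
            )
        )
    return CloneSet(records, reference, params)


@dataclass
class MethylationSummary:
    per_cpg: list[float]          # methylated fraction per CpG (NaN if no calls)
    per_cpg_calls: list[tuple[int, int]]  # (methylated, total) per CpG
    global_fraction: float
    methylated_calls: int
    total_calls: int
    n_clones: int


def quantify_methylation(
    clone_set: CloneSet, positions: Sequence[int] | None = None
) -> MethylationSummary:
    """Per-CpG and global methylation fractions over kept clones.

    At each CpG reference position a kept clone contributes a methylated call
    if it reads C, an unmethylated call if it reads T, and no call otherwise.
    The global fraction pools all calls, so it equals the call-count-weighted
    mean of the per-CpG fractions.
    """
    kept = clone_set.kept
    if not kept:
        raise UsageError("no clones passed filtering; nothing to quantify")
    if positions is None:
        positions = cpg_positions(clone_set.reference)
    per_cpg = []
    calls = []
    meth_total = call_total = 0
    for pos in positions:
        m = sum(1 for c in kept if c.ref_aligned[pos] == "C")
        u = sum(1 for c in kept if c.ref_aligned[pos] == "T")
        calls.append((m, m + u))
        per_cpg.append(m / (m + u) if (m + u) else float("nan"))
        meth_total += m
        call_total += m + u
    return MethylationSummary(
        per_cpg=per_cpg,
        per_cpg_calls=calls,
        global_fraction=meth_total / call_total if call_total else float("nan"),
        methylated_calls=meth_total,
        total_calls=call_total,
        n_clones=len(kept),
    )


def methylation_matrix(clone_set: CloneSet, positions: Sequence[int] | None = None):
    """Clone x CpG matrix of calls: 1 methylated, 0 unmethylated, NaN no call."""
    if positions is None:
        positions = cpg_positions(clone_set.reference)
    kept = clone_set.kept
    mat = np.full((len(kept), len(positions)), np.nan)
    for r, c in enumerate(kept):
        for j, pos in enumerate(positions):
            b = c.ref_aligned[pos]
            if b == "C":
                mat[r, j] = 1.0
            elif b == "T":
                mat[r, j] = 0.0
    return mat


def fisher_exact_2x2(table) -> float:
    """Two-sided Fisher exact p for a 2x2 count table (point-probability
    method: sum of hypergeometric probabilities <= that of the observed
    table)."""
    t = np.asarray(table)
    if t.shape != (2, 2):
        raise UsageError("table must be 2x2")
    if (t < 0).any() or not np.issubdtype(t.dtype, np.integer):
        if (t != np.floor(t)).any() or (t < 0).any():
            raise UsageError("table must hold non-negative integers")
        t = t.astype(int)
    _, p = stats.fisher_exact(t, alternative="two-sided")
    return float(p)


def compare_groups(
    summary_a: MethylationSummary, summary_b: MethylationSummary
) -> tuple[float, np.ndarray]:
    """Pooled 2x2 Fisher test of methylated vs unmethylated CpG calls
    between two groups; returns (p, table)."""
    table = np.array(
        [
            [summary_a.methylated_calls, summary_a.total_calls - summary_a.methylated_calls],
            [summary_b.methylated_calls, summary_b.total_calls - summary_b.methylated_calls],
        ]
    )
    return fisher_exact_2x2(table), table


def per_cpg_tests(
    summary_a: MethylationSummary,
    summary_b: MethylationSummary,
    alpha: float = 0.05,
) -> list[tuple[int, float, bool]]:
    """Per-CpG Fisher tests with Bonferroni correction; returns
    (cpg_index, p, significant_after_correction)."""
    if len(summary_a.per_cpg_calls) != len(summary_b.per_cpg_calls):
        raise UsageError("groups were quantified over different CpG panels")
    k = len(summary_a.per_cpg_calls)
    out = []
    for i, ((ma, ta), (mb, tb)) in enumerate(
        zip(summary_a.per_cpg_calls, summary_b.per_cpg_calls)
    ):
        p = fisher_exact_2x2([[ma, ta - ma], [mb, tb - mb]])
        out.append((i, p, p * k < alpha))
    return out
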