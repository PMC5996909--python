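"""Pairwise linkage disequilibrium and EM haplotype frequency estimation.

The marker panel is the five SNPs flanking the repeat locus, in plus-strand
order SNP1 (rs11150824) - SNP2 (rs2289534) - [repeat] - SNP3 (rs3829612) -
SNP4 (rs10782008) - SNP5 (rs12943620); the repeat locus itself is phased
jointly as a categorical marker whose alleles are structure nomenclature
strings.  Phasing is the standard EM over haplotype-pair expansions of
unphased multi-locus genotypes, exact for the <=8-locus panels used here.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Hashable, Sequence

import numpy as np
import pandas as pd

from .errors import DataError, LDUndefinedError, ParameterError, UsageError

DEFAULT_PANEL_IDS = (
    "rs11150824",
    "rs2289534",
    "REPEAT",
    "rs3829612",
    "rs10782008",
    "rs12943620",
)


@dataclass(frozen=True)
class MarkerPanel:
    """Ordered markers; type is SNP except for the categorical repeat locus."""

    markers: tuple[tuple[str, str], ...] = tuple(
        (mid, "REPEAT_LOCUS" if mid == "REPEAT" else "SNP") for mid in DEFAULT_PANEL_IDS
    )

    @property
    def ids(self) -> tuple[str, ...]:
        return tuple(m for m, _ in self.markers)

    @property
    def n_loci(self) -> int:
        return len(self.markers)


# ---------------------------------------------------------------------------
# Pairwise LD
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class LDStats:
    D: float
    D_prime: float
    allele_freqs: tuple[float, float, float, float]  # pA, pa, pB, pb


def d_prime(hap_counts) -> LDStats:
    """D and D' from a 2x2 haplotype count table [[AB, Ab], [aB, ab]].

    D = pAB - pA*pB; D' = |D| / Dmax with Dmax = min(pA*pb, pa*pB) for D > 0
    and min(pA*pB, pa*pb) for D < 0.  Monomorphic margins make LD undefined
    and raise rather than returning 0.
    """
    t = np.asarray(hap_counts, dtype=float)
    if t.shape != (2, 2) or (t < 0).any():
        raise UsageError("hap_counts must be a non-negative 2x2 table")
    n = t.sum()
    if n == 0:
        raise UsageError("at least one haplotype must be observed")
    p = t / n
    pA, pa = p[0].sum(), p[1].sum()
    pB, pb = p[:, 0].sum(), p[:, 1].sum()
    if min(pA, pa) == 0 or min(pB, pb) == 0:
        raise LDUndefinedError("LD undefined: monomorphic locus")
    D = p[0, 0] - pA * pB
    if D > 0:
        Dmax = min(pA * pb, pa * pB)
    elif D < 0:
        Dmax = min(pA * pB, pa * pb)
    else:
        return LDStats(0.0, 0.0, (pA, pa, pB, pb))
    return LDStats(float(D), float(abs(D) / Dmax), (pA, pa, pB, pb))


def pairwise_d_prime(
    haplotypes: Sequence[Sequence[Hashable]], freqs: Sequence[float]
) -> pd.DataFrame:
    """All pairwise D' values from multi-locus haplotype frequencies.

    Multi-allelic loci (the categorical repeat marker) are collapsed to
    major-allele-vs-rest before applying the biallelic formula.  Returns a
    loci x loci DataFrame with NaN where LD is undefined.
    """
    haps = [tuple(h) for h in haplotypes]
    f = np.asarray(freqs, dtype=float)
    n_loci = len(haps[0])
    out = np.full((n_loci, n_loci), np.nan)
    for i, j in itertools.combinations(range(n_loci), 2):
        ai = _major_allele(haps, f, i)
        aj = _major_allele(haps, f, j)
        table = np.zeros((2, 2))
        for h, w in zip(haps, f):
            table[0 if h[i] == ai else 1, 0 if h[j] == aj else 1] += w
        try:
            out[i, j] = out[j, i] = d_prime(table).D_prime
        except LDUndefinedError:
            pass
    return pd.DataFrame(out)


def _major_allele(haps, freqs, locus):
    weights: dict = {}
    for h, w in zip(haps, freqs):
        weights[h[locus]] = weights.get(h[locus], 0.0) + w
    return max(weights, key=weights.get)


def shared_haplotype(
    h1: Sequence[Hashable], h2: Sequence[Hashable]
) -> tuple[int, bool]:
    """Marker-by-marker identity count between two haplotype vectors."""
    if len(h1) != len(h2):
        raise UsageError(
            f"haplotype vectors are from different panels ({len(h1)} vs {len(h2)} markers)"
        )
    n = sum(a == b for a, b in zip(h1, h2))
    return n, n == len(h1)


# ---------------------------------------------------------------------------
# EM phasing
# ---------------------------------------------------------------------------


@dataclass
class HaplotypeEstimate:
    """MLE haplotype frequencies with per-individual most-probable phases."""

    haplotypes: list[tuple]
    frequencies: np.ndarray
    loglik: float
    loglik_path: list[float]
    iterations: int
    converged: bool
    phases: list[tuple[tuple, tuple]]  # per individual, MAP ordered pair
    panel: MarkerPanel

    def frequency_table(self) -> pd.DataFrame:
        df = pd.DataFrame(self.haplotypes, columns=list(self.panel.ids)[: len(self.haplotypes[0])])
        df["frequency"] = self.frequencies
        return df.sort_values("frequency", ascending=False).reset_index(drop=True)

    def summary(self) -> str:
        lines = [
            "EM haplotype frequency estimate",
            f"  haplotypes enumerated: {len(self.haplotypes)}",
            f"  log-likelihood: {self.loglik:.6f}",
            f"  iterations: {self.iterations} (converged: {self.converged})",
            "",
            self.frequency_table().to_string(
                index=False, float_format=lambda x: f"{x:.4f}"
            ),
        ]
        return "\n".join(lines)


class HaplotypePhaser:
    """EM model for haplotype frequencies from unphased multi-locus genotypes.

    Parameters
    ----------
    genotypes : sequence
        One entry per individual: a sequence over loci, each locus either an
        unordered pair of allele codes or ``None`` for missing (missing loci
        are marginalized over the alleles observed in the cohort).
    panel : MarkerPanel, optional
        Marker metadata used in reports.
    """

    def __init__(self, genotypes: Sequence, panel: MarkerPanel | None = None, sample_ids=None):
        if not genotypes:
            raise UsageError("at least one genotype is required")
        self.genotypes = [tuple(self._norm_locus(l) for l in g) for g in genotypes]
        n_loci = {len(g) for g in self.genotypes}
        if len(n_loci) != 1:
            raise UsageError("all genotypes must cover the same loci")
        self.n_loci = n_loci.pop()
        if self.n_loci > 8:
            raise UsageError("exhaustive EM phasing supports at most 8 loci")
        self.panel = panel or MarkerPanel()
        self.sample_ids = list(sample_ids) if sample_ids is not None else [
            f"S{i}" for i in range(len(self.genotypes))
        ]
        # observed allele universe per locus (for marginalizing missing data)
        self.locus_alleles: list[tuple] = []
        for locus in range(self.n_loci):
            seen = set()
            for g in self.genotypes:
                if g[locus] is not None:
                    seen.update(g[locus])
            if not seen:
                raise DataError(f"locus {locus} has no observed alleles")
            self.locus_alleles.append(tuple(sorted(seen, key=repr)))

    @staticmethod
    def _norm_locus(locus):
        if locus is None:
            return None
        a, b = locus
        return tuple(sorted((a, b), key=repr))

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, panel: MarkerPanel | None = None):
        """Rows = individuals, columns = loci, cells = (a, b) tuples or None."""
        genotypes = [tuple(row) for row in df.itertuples(index=False)]
        return cls(genotypes, panel=panel, sample_ids=list(df.index))

    # -- expansion ---------------------------------------------------------

    def _expand_pairs(self, genotype) -> list[tuple[tuple, tuple]]:
        """All ordered haplotype pairs compatible with one unphased genotype."""
        per_locus: list[list[tuple]] = []
        for locus, g in enumerate(genotype):
            if g is None:
                per_locus.append(
                    [(a, b) for a in self.locus_alleles[locus] for b in self.locus_alleles[locus]]
                )
            else:
                a, b = g
                per_locus.append([(a, b)] if a == b else [(a, b), (b, a)])
        pairs = []
        for combo in itertools.product(*per_locus):
            h1 = tuple(c[0] for c in combo)
            h2 = tuple(c[1] for c in combo)
            pairs.append((h1, h2))
        return pairs

    # -- fitting -----------------------------------------------------------

    def fit(self, max_iter: int = 1000, tol: float = 1e-8, seed: int | None = None) -> HaplotypeEstimate:
        """Run EM to convergence (tol on the log-likelihood).

        Initialization is uniform over the enumerated haplotypes, which makes
        the fit deterministic; ``seed`` only matters if a random restart is
        ever requested and is accepted for interface stability.
        """
        # group identical genotypes so EM cost scales with distinct patterns
        pattern_counts: dict[tuple, int] = {}
        pattern_of_sample: list[tuple] = []
        for g in self.genotypes:
            pattern_counts[g] = pattern_counts.get(g, 0) + 1
            pattern_of_sample.append(g)
        patterns = list(pattern_counts)
        expansions = {p: self._expand_pairs(p) for p in patterns}
        for p, ex in expansions.items():
            if not ex:
                idx = pattern_of_sample.index(p)
                raise DataError(
                    f"no compatible haplotype pair for sample {self.sample_ids[idx]}"
                )
        hap_index: dict[tuple, int] = {}
        for ex in expansions.values():
            for h1, h2 in ex:
                hap_index.setdefault(h1, len(hap_index))
                hap_index.setdefault(h2, len(hap_index))
        haps = list(hap_index)
        H = len(haps)
        # per pattern: integer arrays of (i, j) haplotype indices
        pat_pairs = {
            p: (
                np.array([hap_index[h1] for h1, _ in ex], dtype=np.int64),
                np.array([hap_index[h2] for _, h2 in ex], dtype=np.int64),
            )
            for p, ex in expansions.items()
        }
        freqs = np.full(H, 1.0 / H)
        n_total = len(self.genotypes)
        loglik_path: list[float] = []
        prev_ll = -math.inf
        converged = False
        it = 0
        for it in range(1, max_iter + 1):
            new = np.zeros(H)
            ll = 0.0
            for p, count in pattern_counts.items():
                ii, jj = pat_pairs[p]
                w = freqs[ii] * freqs[jj]
                tot = w.sum()
                if tot <= 0:
                    raise DataError("EM degenerated to zero likelihood")
                ll += count * math.log(tot)
                w = w / tot * count
                np.add.at(new, ii, w)
                np.add.at(new, jj, w)
            loglik_path.append(ll)
            if ll + 1e-12 < prev_ll:
                raise AssertionError("EM log-likelihood decreased")  # pragma: no cover
            if abs(ll - prev_ll) < tol:
                converged = True
                break
            prev_ll = ll
            freqs = new / (2 * n_total)
        # MAP phase per individual; ties broken toward the pair whose first
        # haplotype has the higher frequency
        phases = []
        for g in self.genotypes:
            ii, jj = pat_pairs[g]
            w = freqs[ii] * freqs[jj]
            order = sorted(
                range(len(w)),
                key=lambda k: (-w[k], -max(freqs[ii[k]], freqs[jj[k]])),
            )
            k = order[0]
            h1, h2 = haps[ii[k]], haps[jj[k]]
            if freqs[hap_index[h2]] > freqs[hap_index[h1]]:
                h1, h2 = h2, h1
            phases.append((h1, h2))
        return HaplotypeEstimate(
            haplotypes=haps,
            frequencies=freqs,
            loglik=loglik_path[-1],
            loglik_path=loglik_path,
            iterations=it,
            converged=converged,
            phases=phases,
            panel=self.panel,
        )


def em_phase(
    genotypes: Sequence,
    max_iter: int = 1000,
    tol: float = 1e-8,
    seed: int | None = None,
    panel: MarkerPanel | None = None,
) -> HaplotypeEstimate:
    """Functional wrapper around :class:`HaplotypePhaser`."""
    return HaplotypePhaser(genotypes, panel=panel).fit(max_iter=max_iter, tol=tol, seed=seed)
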