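"""Tests for bisulfite conversion, clone filtering, methylation
quantification and the Fisher exact test."""

import math

import numpy as np
import pytest
from scipy import stats

from repeatlens.errors import ParameterError, UsageError
from repeatlens.methylation import (
    FilterParams,
    MethylationProfile,
    bisulfite_convert,
    compare_groups,
    filter_clones,
    fisher_exact_2x2,
    methylation_matrix,
    per_cpg_tests,
    quantify_methylation,
)
from repeatlens.motif_core import compose_allele, cpg_positions, parse_nomenclature
from repeatlens.synth import generate_bisulfite_dataset


@pytest.fixture
def ref_8(control_8):
    return compose_allele(control_8)


class TestBisulfiteConvert:
    def test_full_methylation_protects_every_cpg(self, ref_8):
        cpgs = cpg_positions(ref_8)
        read = bisulfite_convert(ref_8, [True] * len(cpgs), 1.0, seed=0)
        for i, b in enumerate(ref_8):
            if b == "C":
                assert read[i] == ("C" if i in cpgs else "T")
            else:
                assert read[i] == b

    def test_no_methylation_converts_all_cytosines(self, ref_8):
        cpgs = cpg_positions(ref_8)
        read = bisulfite_convert(ref_8, [False] * len(cpgs), 1.0, seed=0)
        assert "C" not in read
        assert read.count("G") == ref_8.count("G")

    def test_conversion_rate_within_binomial_ci(self, ref_8):
        """1000 reads at efficiency 0.9: the observed non-CpG conversion
        fraction lies in the exact 99.9% binomial interval."""
        cpgs = set(cpg_positions(ref_8))
        non_cpg_c = [i for i, b in enumerate(ref_8) if b == "C" and i not in cpgs]
        rng = np.random.default_rng(7)
        states = [True] * len(cpg_positions(ref_8))
        converted = total = 0
        for _ in range(1000):
            read = bisulfite_convert(ref_8, states, 0.9, seed=rng)
            converted += sum(read[i] == "T" for i in non_cpg_c)
            total += len(non_cpg_c)
        lo, hi = stats.binom.interval(0.999, total, 0.9)
        assert lo <= converted <= hi

    def test_state_length_mismatch_rejected(self, ref_8):
        with pytest.raises(UsageError):
            bisulfite_convert(ref_8, [True], 1.0, seed=0)

    def test_bad_efficiency_rejected(self, ref_8):
        with pytest.raises(ParameterError):
            bisulfite_convert(ref_8, [True] * len(cpg_positions(ref_8)), 1.1)


class TestFilterClones:
    def test_perfect_converted_clone_kept(self, ref_8):
        read = bisulfite_convert(ref_8, [False] * len(cpg_positions(ref_8)), 1.0, seed=0)
        cs = filter_clones([read], ref_8)
        assert cs.clones[0].kept and cs.clones[0].fail_reasons == ()

    def test_low_conversion_rejected_with_reason(self, ref_8):
        """A clone converted at 90% fails the 95% conversion threshold."""
        recs, _ = generate_bisulfite_dataset(
            MethylationProfile.uniform(parse_nomenclature("5xCACA20+CA18+CACA20+CA18"), 0.0),
            n_samples=1,
            clones_per_sample=1,
            planted_failures=[{"sample": 0, "clone": 0, "kind": "conversion", "value": 0.90}],
            seed=1,
        )
        cs = filter_clones([recs[0][1]], ref_8)
        assert not cs.clones[0].kept
        assert cs.clones[0].fail_reasons == ("conversion",)
        assert cs.clones[0].conversion < 0.95

    def test_each_planted_violation_rejected_with_matching_reason(self, control_8, ref_8):
        """A batch with one planted violation per threshold: exactly the
        planted clones are rejected, each for its planted reason."""
        profile = MethylationProfile.uniform(control_8, 0.02)
        planted = [
            {"sample": 0, "clone": 1, "kind": "conversion", "value": 0.88},
            {"sample": 0, "clone": 3, "kind": "identity", "value": 0.15},
            {"sample": 1, "clone": 0, "kind": "n_at_c", "value": 0.30},
            {"sample": 1, "clone": 4, "kind": "gaps", "value": 0.30},
        ]
        recs, truth = generate_bisulfite_dataset(
            profile, n_samples=2, clones_per_sample=5,
            planted_failures=planted, seed=3,
        )
        cs = filter_clones([r for _, r in recs], ref_8)
        planted_map = dict(truth["planted_failures"])
        for (cid, _), clone in zip(recs, cs.clones):
            if cid in planted_map:
                assert not clone.kept, cid
                assert planted_map[cid] in clone.fail_reasons, cid
            else:
                assert clone.kept, (cid, clone.fail_reasons)

    def test_relaxing_thresholds_never_shrinks_kept_set(self, control_8, ref_8):
        profile = MethylationProfile.uniform(control_8, 0.02)
        recs, _ = generate_bisulfite_dataset(
            profile, n_samples=2, clones_per_sample=5, efficiency=0.96,
            planted_failures=[{"sample": 0, "clone": 0, "kind": "conversion", "value": 0.88}],
            seed=5,
        )
        reads = [r for _, r in recs]
        strict = filter_clones(reads, ref_8)
        relaxed = filter_clones(
            reads, ref_8,
            FilterParams(min_conversion=0.80, min_identity=0.80, max_n_at_c=0.5, max_gaps=0.5),
        )
        kept_strict = {i for i, c in enumerate(strict.clones) if c.kept}
        kept_relaxed = {i for i, c in enumerate(relaxed.clones) if c.kept}
        assert kept_strict <= kept_relaxed


class TestQuantifyMethylation:
    def test_fully_methylated_clones_give_100_percent(self, ref_8):
        states = [True] * len(cpg_positions(ref_8))
        reads = [bisulfite_convert(ref_8, states, 1.0, seed=s) for s in range(5)]
        q = quantify_methylation(filter_clones(reads, ref_8))
        assert q.global_fraction == 1.0
        assert all(f == 1.0 for f in q.per_cpg)

    def test_single_clone_roundtrip_recovers_states(self, ref_8):
        """Efficiency 1: one clone's calls reproduce the planted states."""
        cpgs = cpg_positions(ref_8)
        rng = np.random.default_rng(17)
        states = (rng.random(len(cpgs)) < 0.5).tolist()
        read = bisulfite_convert(ref_8, states, 1.0, seed=0)
        mat = methylation_matrix(filter_clones([read], ref_8))
        assert mat.shape == (1, len(cpgs))
        assert [bool(v) for v in mat[0]] == states

    def test_thirty_percent_site(self, ref_8):
        """One CpG methylated in 3 of 10 clones quantifies to 30%."""
        cpgs = cpg_positions(ref_8)
        reads = []
        for k in range(10):
            states = [False] * len(cpgs)
            states[4] = k < 3
            reads.append(bisulfite_convert(ref_8, states, 1.0, seed=0))
        q = quantify_methylation(filter_clones(reads, ref_8))
        assert q.per_cpg[4] == pytest.approx(0.3)

    def test_global_equals_weighted_mean_of_per_cpg(self, control_8, ref_8):
        recs, _ = generate_bisulfite_dataset(
            MethylationProfile.uniform(control_8, 0.1),
            n_samples=3, clones_per_sample=5, seed=9,
        )
        q = quantify_methylation(filter_clones([r for _, r in recs], ref_8))
        num = sum(m for m, _ in q.per_cpg_calls)
        den = sum(t for _, t in q.per_cpg_calls)
        assert q.global_fraction == pytest.approx(num / den, abs=1e-12)

    def test_zero_kept_clones_rejected(self, ref_8):
        cs = filter_clones([], ref_8)
        with pytest.raises(UsageError):
            quantify_methylation(cs)


def fisher_oracle(a, b, c, d):
    """Full enumeration of tables with fixed margins; two-sided p is the sum
    of hypergeometric point probabilities <= that of the observed table."""
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2

    def pmf(x):
        return (
            math.comb(r1, x) * math.comb(r2, c1 - x) / math.comb(n, c1)
        )

    p_obs = pmf(a)
    total = 0.0
    for x in range(max(0, c1 - r2), min(r1, c1) + 1):
        px = pmf(x)
        if px <= p_obs * (1 + 1e-12):
            total += px
    return min(total, 1.0)


class TestFisherExact:
    def test_symmetric_table_p_one(self):
        assert fisher_exact_2x2([[5, 5], [5, 5]]) == pytest.approx(1.0)

    def test_diagonal_table_hand_oracle(self):
        """[[10,0],[0,10]]: both extreme tables, p = 2/C(20,10)."""
        p = fisher_exact_2x2([[10, 0], [0, 10]])
        assert p == pytest.approx(2 / math.comb(20, 10), rel=1e-12)

    def test_random_tables_match_enumeration(self):
        rng = np.random.default_rng(13)
        for _ in range(100):
            a, b, c, d = (int(x) for x in rng.integers(0, 15, 4))
            if (a + b == 0) or (c + d == 0) or (a + c == 0) or (b + d == 0):
                continue
            p = fisher_exact_2x2([[a, b], [c, d]])
            assert p == pytest.approx(fisher_oracle(a, b, c, d), abs=1e-12)

    def test_negative_counts_rejected(self):
        with pytest.raises(UsageError):
            fisher_exact_2x2([[1, -2], [3, 4]])

    def test_group_comparison_pools_calls(self, control_8, ref_8):
        recs_a, _ = generate_bisulfite_dataset(
            MethylationProfile.uniform(control_8, 0.3), n_samples=2,
            clones_per_sample=5, seed=21,
        )
        recs_b, _ = generate_bisulfite_dataset(
            MethylationProfile.uniform(control_8, 0.02), n_samples=2,
            clones_per_sample=5, seed=22,
        )
        qa = quantify_methylation(filter_clones([r for _, r in recs_a], ref_8))
        qb = quantify_methylation(filter_clones([r for _, r in recs_b], ref_8))
        p, table = compare_groups(qa, qb)
        assert table[0][0] == qa.methylated_calls
        assert p < 0.05  # 30% vs 2% over hundreds of calls
        tests = per_cpg_tests(qa, qb)
        assert len(tests) == len(qa.per_cpg_calls)
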