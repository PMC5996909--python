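"""Synthetic-data generator for every input the pipeline consumes.

The defaults emulate the study conditions of the reference cohort: 380
unaffected diploid individuals drawn under Hardy-Weinberg from a stylized
allele spectrum (modal 7- and 8-repeat alleles at roughly 25% and 23%,
repeat counts spanning 2-17, about 1% of alleles carrying the
disease-associated CGCA20 motif, heterozygosity around 85%); five flanking
biallelic SNPs in weak linkage disequilibrium (max pairwise D' below 0.48);
dual-luciferase plates built by inverting the relative-activity formula
around planted per-motif effects (approximately -0.46% per CACA20 and
-1.46% per CGCA20 motif); and bisulfite clone sets in the low-methylation
regime (about 1.7% vs 2.8% methylated CpG calls), 10 clones per sample.

The exact per-structure counts of the real cohort were never published as
text, so the spectrum is explicitly *stylized* configuration, not data.
Every generator records the planted ground truth so that downstream
recovery tests can be scored without regeneration, and every output is
reproducible from a single integer seed (split hierarchically per
sub-generator).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .deconv import DEFAULT_FLANKS, superpose
from .errors import ParameterError
from .expression import NEGATIVE, POSITIVE
from .methylation import MethylationProfile, bisulfite_convert
from .motif_core import (
    DEFAULT_ALPHABET,
    AlleleStructure,
    DiploidGenotype,
    compose_allele,
    format_nomenclature,
    parse_nomenclature,
)

# ---------------------------------------------------------------------------
# Default allele spectrum (stylized)
# ---------------------------------------------------------------------------

#: (nomenclature, frequency) pairs; frequencies are normalized at use.  The
#: carrier structures (with CGCA20) total 1% of alleles.
DEFAULT_SPECTRUM: tuple[tuple[str, float], ...] = (
    ("2xCACA20", 0.010),
    ("2xCACA20+CA18", 0.030),
    ("3xCACA20+CA18", 0.060),
    ("4xCACA20+CA18", 0.070),
    ("3xCACA20+CA18+CACA20+CA18", 0.100),
    ("6xCA18", 0.020),
    ("4xCACA20+CA18+CACA20+CA18", 0.2546),
    ("5xCACA20+CA18+CACA20+CA18", 0.2321),
    ("6xCACA20+CA18+CACA20+CA18", 0.090),
    ("7xCACA20+CA18+CACA20+CA18", 0.060),
    ("8xCACA20+CA18+CACA20+CA18", 0.030),
    ("9xCACA20+CA18+CACA20+CA18", 0.0333),
    # CGCA-carrier alleles, 1% in total
    ("CACA20+8xCGCA20+CACA20+CA18", 0.004),
    ("CACA20+10xCGCA20+CA18", 0.003),
    ("2xCACA20+14xCGCA20+CA18", 0.003),
)

#: The published pathogenic constructs (14 and 16 repeats) and the four
#: control constructs used in the reporter assay.
CONSTRUCT_4 = "3xCACA20+CA18"
CONSTRUCT_7 = "4xCACA20+CA18+CACA20+CA18"
CONSTRUCT_10 = "7xCACA20+CA18+CACA20+CA18"
CONSTRUCT_12 = "CACA20+10xCGCA20+CA18"
CONSTRUCT_14 = "2xCACA20+10xCGCA20+CACA20+CA18"
CONSTRUCT_16 = "CACA20+13xCGCA20+CACA20+CA18"
DEFAULT_CONSTRUCTS = (
    CONSTRUCT_4, CONSTRUCT_7, CONSTRUCT_10, CONSTRUCT_12, CONSTRUCT_14, CONSTRUCT_16,
)

#: Planted per-motif activity effects (percent per added motif), matching the
#: published pairwise arithmetic.
DEFAULT_BETAS = {"CA18": -0.46, "CACA20": -0.46, "CGCA20": -1.46}
DEFAULT_INTERCEPT = 25.0

# ---------------------------------------------------------------------------
# Default SNP haplotype distribution (weak LD)
# ---------------------------------------------------------------------------


def default_snp_haplotypes() -> list[tuple[tuple[int, ...], float]]:
    """Haplotype frequencies over the 5 biallelic SNPs with weak LD.

    Built as near-independence (product of per-SNP allele frequencies) with
    a bounded multiplicative perturbation favouring a few haplotypes; the
    resulting max pairwise D' stays below 0.48 (asserted in tests).
    """
    p1 = (0.70, 0.30)  # per-SNP frequencies of allele 0 / 1
    p2 = (0.50, 0.50)
    p3 = (0.60, 0.40)
    p4 = (0.55, 0.45)
    p5 = (0.65, 0.35)
    boost = {
        (0, 0, 0, 0, 0): 1.6,
        (1, 1, 1, 1, 1): 1.8,
        (0, 1, 0, 1, 0): 1.4,
    }
    haps = []
    for h in np.ndindex(2, 2, 2, 2, 2):
        f = p1[h[0]] * p2[h[1]] * p3[h[2]] * p4[h[3]] * p5[h[4]]
        haps.append((tuple(int(x) for x in h), f * boost.get(h, 1.0)))
    total = sum(f for _, f in haps)
    return [(h, f / total) for h, f in haps]


# ---------------------------------------------------------------------------
# Cohort generation
# ---------------------------------------------------------------------------


@dataclass
class CohortSpec:
    n_individuals: int = 380
    allele_spectrum: tuple[tuple[str, float], ...] = DEFAULT_SPECTRUM
    snp_haplotype_freqs: list | None = None
    #: planted genotypes overriding the first samples, as (allele1, allele2)
    #: nomenclature pairs — e.g. an affected 16-repeat homozygote
    planted: tuple[tuple[str, str], ...] = ()
    inbreeding: float = 0.0
    seed: int = 0

    def normalized_spectrum(self) -> list[tuple[AlleleStructure, float]]:
        total = sum(f for _, f in self.allele_spectrum)
        if total <= 0:
            raise ParameterError("allele spectrum frequencies must sum to > 0")
        return [
            (parse_nomenclature(nom), f / total) for nom, f in self.allele_spectrum
        ]


@dataclass
class CohortData:
    genotypes: list[DiploidGenotype]
    mixed_records: list[tuple[str, str]]      # (sample_id, IUPAC amplicon)
    allele_records: list[tuple[str, str]]     # (sample|allele{1,2}, sequence)
    snp_table: pd.DataFrame
    ground_truth: dict


def generate_cohort(spec: CohortSpec, alphabet=DEFAULT_ALPHABET) -> CohortData:
    """Sample a diploid cohort with SNP haplotypes and mixed amplicons.

    Allele pairs follow Hardy-Weinberg (with an optional inbreeding
    coefficient: probability of forcing the second allele identical to the
    first); SNP haplotypes are drawn independently of the repeat allele from
    the weak-LD haplotype distribution, except that planted samples keep
    their drawn haplotypes.  The mixed amplicon of each sample is the IUPAC
    superposition of its two allele sequences between the fixed flanks.
    """
    rng = np.random.default_rng(spec.seed)
    spectrum = spec.normalized_spectrum()
    structures = [s for s, _ in spectrum]
    weights = np.array([f for _, f in spectrum])
    hap_freqs = spec.snp_haplotype_freqs or default_snp_haplotypes()
    haps = [h for h, _ in hap_freqs]
    hap_w = np.array([f for _, f in hap_freqs], dtype=float)
    hap_w = hap_w / hap_w.sum()
    if not 0.0 <= spec.inbreeding <= 1.0:
        raise ParameterError("inbreeding coefficient must be in [0, 1]")

    genotypes: list[DiploidGenotype] = []
    truth_rows = []
    for i in range(spec.n_individuals):
        sid = f"S{i:04d}"
        if i < len(spec.planted):
            a1 = parse_nomenclature(spec.planted[i][0])
            a2 = parse_nomenclature(spec.planted[i][1])
        else:
            k1 = int(rng.choice(len(structures), p=weights))
            if spec.inbreeding > 0 and rng.random() < spec.inbreeding:
                k2 = k1
            else:
                k2 = int(rng.choice(len(structures), p=weights))
            a1, a2 = structures[k1], structures[k2]
        hap1 = haps[int(rng.choice(len(haps), p=hap_w))]
        hap2 = haps[int(rng.choice(len(haps), p=hap_w))]
        snp_gt = tuple(tuple(sorted((x, y))) for x, y in zip(hap1, hap2))
        genotypes.append(DiploidGenotype(a1, a2, snp_gt, sample_id=sid))
        truth_rows.append(
            {
                "sample": sid,
                "allele1": format_nomenclature(a1),
                "allele2": format_nomenclature(a2),
                "hap1": list(hap1),
                "hap2": list(hap2),
                "planted": i < len(spec.planted),
            }
        )

    allele_records = []
    mixed_records = []
    for g in genotypes:
        s1 = compose_allele(g.allele1, alphabet)
        s2 = compose_allele(g.allele2, alphabet)
        allele_records.append((f"{g.sample_id}|allele1", s1))
        allele_records.append((f"{g.sample_id}|allele2", s2))
        mixed_records.append((g.sample_id, superpose(s1, s2, DEFAULT_FLANKS).iupac))

    snp_table = pd.DataFrame(
        [
            {"sample": g.sample_id, **{f"snp{j+1}": f"{a}/{b}" for j, (a, b) in enumerate(g.snp_genotypes)}}
            for g in genotypes
        ]
    )
    truth = {
        "seed": spec.seed,
        "spectrum": [(nom, f) for nom, f in spec.allele_spectrum],
        "samples": truth_rows,
        "flanks": list(DEFAULT_FLANKS),
    }
    return CohortData(genotypes, mixed_records, allele_records, snp_table, truth)


# ---------------------------------------------------------------------------
# Luciferase plates
# ---------------------------------------------------------------------------

#: Control firefly/renilla ratios used when inverting the activity formula.
NEG_RATIO = 0.02
POS_RATIO = 1.02
RENILLA_LEVEL = 1_000_000.0


def expected_percent(
    structure: AlleleStructure | str,
    betas: dict[str, float] = DEFAULT_BETAS,
    intercept: float = DEFAULT_INTERCEPT,
) -> float:
    """Planted mean activity of a construct: intercept + sum beta * count."""
    if isinstance(structure, str):
        structure = parse_nomenclature(structure)
    counts = structure.motif_counts()
    return intercept + sum(betas.get(m, 0.0) * c for m, c in counts.items())


def generate_luciferase_dataset(
    betas: dict[str, float] = DEFAULT_BETAS,
    intercept: float = DEFAULT_INTERCEPT,
    noise_sd: float = 0.0,
    constructs: Sequence[str] = DEFAULT_CONSTRUCTS,
    replicates: int = 3,
    seed: int = 0,
) -> tuple[pd.DataFrame, dict]:
    """Plate of firefly/renilla wells realizing planted per-motif effects.

    Each experimental well's percent activity is the construct's planted mean
    plus Gaussian noise; the percent is mapped back to a firefly/renilla
    ratio by inverting the relative-activity formula around fixed control
    ratios.  Percents outside (-20, 120) are clipped and flagged.
    """
    if noise_sd < 0:
        raise ParameterError("noise_sd must be >= 0")
    rng = np.random.default_rng(seed)
    rows = []
    clipped = []
    truth_percents = {}
    for rep in range(1, replicates + 1):
        rows.append(
            {"construct_id": NEGATIVE, "replicate": rep,
             "firefly": NEG_RATIO * RENILLA_LEVEL, "renilla": RENILLA_LEVEL}
        )
        rows.append(
            {"construct_id": POSITIVE, "replicate": rep,
             "firefly": POS_RATIO * RENILLA_LEVEL, "renilla": RENILLA_LEVEL}
        )
    for nom in constructs:
        mean_pct = expected_percent(nom, betas, intercept)
        truth_percents[nom] = mean_pct
        for rep in range(1, replicates + 1):
            pct = mean_pct + (rng.normal(0.0, noise_sd) if noise_sd else 0.0)
            if not -20.0 < pct < 120.0:
                clipped.append((nom, rep, pct))
                pct = float(np.clip(pct, -20.0, 120.0))
            ratio = NEG_RATIO + pct / 100.0 * (POS_RATIO - NEG_RATIO)
            rows.append(
                {"construct_id": nom, "replicate": rep,
                 "firefly": ratio * RENILLA_LEVEL, "renilla": RENILLA_LEVEL}
            )
    truth = {
        "betas": dict(betas),
        "intercept": intercept,
        "noise_sd": noise_sd,
        "construct_percents": truth_percents,
        "neg_ratio": NEG_RATIO,
        "pos_ratio": POS_RATIO,
        "clipped_wells": clipped,
        "seed": seed,
    }
    return pd.DataFrame(rows), truth


# ---------------------------------------------------------------------------
# Bisulfite clone sets
# ---------------------------------------------------------------------------


def generate_bisulfite_dataset(
    profile: MethylationProfile,
    n_samples: int = 7,
    clones_per_sample: int = 10,
    efficiency: float = 1.0,
    planted_failures: Sequence[dict] = (),
    seed: int = 0,
) -> tuple[list[tuple[str, str]], dict]:
    """Clone FASTA records (id, read) for a group of samples.

    Each clone draws per-CpG methylation states from the profile and is
    bisulfite-converted at the given efficiency.  ``planted_failures`` are
    dicts like ``{"sample": 0, "clone": 0, "kind": "conversion",
    "value": 0.90}`` that overwrite one clone with a deliberate threshold
    violation (kinds: conversion, identity, n_at_c, gaps); the truth records
    exactly which clone ids were sabotaged.
    """
    rng = np.random.default_rng(seed)
    ref = profile.reference_sequence
    cpgs = profile.cpg_positions
    probs = np.asarray(profile.per_cpg_prob)
    records: list[tuple[str, str]] = []
    states_truth = {}
    planted_ids = []
    planted_map = {(pf["sample"], pf["clone"]): pf for pf in planted_failures}
    for s in range(n_samples):
        for c in range(clones_per_sample):
            cid = f"sample{s}|clone{c}"
            states = rng.random(len(cpgs)) < probs
            pf = planted_map.get((s, c))
            if pf is None:
                read = bisulfite_convert(ref, states, efficiency, seed=rng)
            else:
                read = _sabotage_clone(ref, states, pf, rng)
                planted_ids.append((cid, pf["kind"]))
            records.append((cid, read))
            states_truth[cid] = states.astype(int).tolist()
    truth = {
        "per_cpg_prob": probs.tolist(),
        "efficiency": efficiency,
        "cpg_positions": cpgs,
        "states": states_truth,
        "planted_failures": planted_ids,
        "seed": seed,
    }
    return records, truth


def _sabotage_clone(ref: str, states, pf: dict, rng: np.random.Generator) -> str:
    """Build a clone that violates exactly one filter threshold."""
    from .motif_core import cpg_positions as _cpgs

    kind = pf["kind"]
    if kind == "conversion":
        # convert exactly floor(rate * n) of the non-CpG Cs so the measured
        # conversion rate is deterministically below threshold
        rate = pf.get("value", 0.90)
        cpg_set = set(_cpgs(ref))
        non_cpg_c = [i for i, b in enumerate(ref) if b == "C" and i not in cpg_set]
        k = int(rate * len(non_cpg_c))
        read = list(ref)
        for i in rng.choice(non_cpg_c, size=k, replace=False):
            read[i] = "T"
        return "".join(read)
    read = list(bisulfite_convert(ref, states, 1.0, seed=rng))
    if kind == "identity":
        # mutate A/G positions (not C/T, which identity excludes at ref Cs)
        targets = [i for i, b in enumerate(ref) if b in "AG"]
        k = int(len(ref) * pf.get("value", 0.15))
        for i in rng.choice(targets, size=min(k, len(targets)), replace=False):
            read[i] = {"A": "C", "G": "T"}[ref[i]]
    elif kind == "n_at_c":
        c_pos = [i for i, b in enumerate(ref) if b == "C"]
        k = int(np.ceil(len(c_pos) * pf.get("value", 0.30)))
        for i in rng.choice(c_pos, size=k, replace=False):
            read[i] = "N"
    elif kind == "gaps":
        frac = pf.get("value", 0.30)
        keep = int(len(read) * (1.0 - frac))
        read = read[:keep]
    else:
        raise ParameterError(f"unknown planted failure kind {kind!r}")
    return "".join(read)
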