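"""End-to-end pipeline: synthesize (or load) inputs, then decompose,
deconvolve, classify, phase, model expression and quantify methylation,
collecting every stage's headline numbers into one machine-readable report.
"""

from __future__ import annotations

import hashlib
import json
import os
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd

from . import __version__
from .deconv import MixedSequence, deconvolve, superpose
from .errors import RepeatLensError, UsageError
from .expression import MotifActivityModel, one_way_anova_tukey, relative_activity
from .haplotypes import HaplotypePhaser, pairwise_d_prime
from .methylation import (
    MethylationProfile,
    compare_groups,
    filter_clones,
    quantify_methylation,
)
from .motif_core import (
    AffectedStatus,
    classify_genotype,
    compose_allele,
    decompose_sequence,
    format_nomenclature,
    parse_nomenclature,
    summarize_cohort,
)
from .synth import (
    CohortSpec,
    DEFAULT_BETAS,
    DEFAULT_CONSTRUCTS,
    DEFAULT_INTERCEPT,
    generate_bisulfite_dataset,
    generate_cohort,
    generate_luciferase_dataset,
)


@dataclass
class RunConfig:
    """Configuration for a full synthetic-cohort pipeline run."""

    seed: int = 0
    n_individuals: int = 60
    n_deconvolve: int = 20          # mixed amplicons to re-deconvolve
    luciferase_noise_sd: float = 1.0
    luciferase_replicates: int = 12
    methylation_probs: tuple[float, float] = (0.017, 0.028)  # patients, controls
    bisulfite_samples: int = 7
    clones_per_sample: int = 10
    stages: tuple[str, ...] = (
        "cohort", "deconvolve", "haplotype", "expression", "methylation",
    )
    out_dir: str | None = None

    @classmethod
    def from_json(cls, path: str) -> "RunConfig":
        with open(path) as fh:
            data = json.load(fh)
        cfg = cls(**data)
        cfg.validate()
        return cfg

    def validate(self):
        known = {"cohort", "deconvolve", "haplotype", "expression", "methylation"}
        bad = set(self.stages) - known
        if bad:
            raise UsageError(f"unknown stages: {sorted(bad)}")
        if self.n_individuals < 1:
            raise UsageError("n_individuals must be positive")


def _config_hash(config: RunConfig) -> str:
    payload = json.dumps(asdict(config), sort_keys=True, default=list)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def run_pipeline(config: RunConfig) -> dict:
    """Execute the enabled stages in dependency order and return the report.

    All randomness derives from ``config.seed`` (hierarchically split per
    stage), so re-running with the same config reproduces the report
    byte-for-byte apart from the provenance timestamp.
    """
    config.validate()
    ss = np.random.SeedSequence(config.seed)
    stage_seeds = {
        name: int(child.generate_state(1)[0] % (2**31))
        for name, child in zip(
            ("cohort", "deconvolve", "haplotype", "expression", "methylation"),
            ss.spawn(5),
        )
    }
    report: dict = {
        "provenance": {
            "package_version": __version__,
            "seed": config.seed,
            "config_hash": _config_hash(config),
            "rounding": "percents reported to 2 decimals",
        }
    }
    cohort = None
    if "cohort" in config.stages:
        spec = CohortSpec(n_individuals=config.n_individuals, seed=stage_seeds["cohort"])
        cohort = generate_cohort(spec)
        summary = summarize_cohort(cohort.genotypes)
        statuses = [classify_genotype(g).value for g in cohort.genotypes]
        report["cohort"] = {
            "n_individuals": summary.n_individuals,
            "distinct_alleles": summary.distinct_alleles,
            "heterozygosity": round(summary.heterozygosity, 4),
            "carrier_allele_percent": summary.carrier_percent(),
            "min_repeats": summary.min_repeats,
            "max_repeats": summary.max_repeats,
            "status_counts": {s: statuses.count(s) for s in set(statuses)},
        }

    if "deconvolve" in config.stages:
        if cohort is None:
            raise UsageError("deconvolve stage requires the cohort stage")
        rng = np.random.default_rng(stage_seeds["deconvolve"])
        idx = rng.choice(
            len(cohort.genotypes), size=min(config.n_deconvolve, len(cohort.genotypes)),
            replace=False,
        )
        recovered = 0
        ambiguous = 0
        for i in idx:
            g = cohort.genotypes[i]
            mixed = superpose(compose_allele(g.allele1), compose_allele(g.allele2))
            result = deconvolve(mixed)
            truth = tuple(
                sorted(
                    (g.allele1, g.allele2), key=lambda s: format_nomenclature(s)
                )
            )
            zero = [c for c, m in result.candidates if m == 0]
            if any(
                c[0].structure_key() == truth[0].structure_key()
                and c[1].structure_key() == truth[1].structure_key()
                for c in zero
            ):
                recovered += 1
            if len(zero) > 1:
                ambiguous += 1
        report["deconvolution"] = {
            "n_samples": int(len(idx)),
            "recovery_rate": round(recovered / len(idx), 4),
            "ambiguity_rate": round(ambiguous / len(idx), 4),
        }

    if "haplotype" in config.stages:
        if cohort is None:
            raise UsageError("haplotype stage requires the cohort stage")
        genotypes = []
        for g in cohort.genotypes:
            repeat_gt = tuple(
                sorted(
                    (format_nomenclature(g.allele1), format_nomenclature(g.allele2))
                )
            )
            loci = [g.snp_genotypes[0], g.snp_genotypes[1], repeat_gt,
                    g.snp_genotypes[2], g.snp_genotypes[3], g.snp_genotypes[4]]
            genotypes.append(tuple(loci))
        est = HaplotypePhaser(genotypes).fit()
        snp_only = [
            (g.snp_genotypes[0], g.snp_genotypes[1], g.snp_genotypes[2],
             g.snp_genotypes[3], g.snp_genotypes[4])
            for g in cohort.genotypes
        ]
        snp_est = HaplotypePhaser(snp_only).fit()
        ld = pairwise_d_prime(snp_est.haplotypes, snp_est.frequencies)
        report["haplotype"] = {
            "n_haplotypes": len(est.haplotypes),
            "loglik": round(est.loglik, 4),
            "iterations": est.iterations,
            "converged": est.converged,
            "top_haplotypes": [
                {"haplotype": list(map(str, h)), "frequency": round(float(f), 4)}
                for h, f in sorted(
                    zip(est.haplotypes, est.frequencies), key=lambda t: -t[1]
                )[:5]
            ],
            "max_pairwise_d_prime": round(float(np.nanmax(ld.values)), 4),
        }

    if "expression" in config.stages:
        wells, truth = generate_luciferase_dataset(
            betas=DEFAULT_BETAS,
            intercept=DEFAULT_INTERCEPT,
            noise_sd=config.luciferase_noise_sd,
            constructs=DEFAULT_CONSTRUCTS,
            replicates=config.luciferase_replicates,
            seed=stage_seeds["expression"],
        )
        acts = relative_activity(wells)
        structures = [parse_nomenclature(a.construct_id) for a in acts]
        fit = MotifActivityModel(acts, structures).fit()
        groups = {}
        ratios = wells[~wells["construct_id"].isin(("NEGATIVE", "POSITIVE"))]
        for cid, grp in ratios.groupby("construct_id"):
            neg = wells[wells["construct_id"] == "NEGATIVE"]
            pos = wells[wells["construct_id"] == "POSITIVE"]
            neg_r = (neg["firefly"] / neg["renilla"]).mean()
            pos_r = (pos["firefly"] / pos["renilla"]).mean()
            groups[cid] = (
                100 * ((grp["firefly"] / grp["renilla"]) - neg_r) / (pos_r - neg_r)
            ).tolist()
        anova = one_way_anova_tukey(groups)
        report["expression"] = {
            "activities": {a.construct_id: round(a.percent, 2) for a in acts},
            "coefficients": {k: round(float(v), 4) for k, v in fit.params.items()},
            "anova_F": round(anova.F, 4),
            "anova_p": float(anova.p_value),
            "n_significant_pairs": len(anova.significant_pairs()),
            "true_betas": truth["betas"],
        }

    if "methylation" in config.stages:
        patient_allele = parse_nomenclature("CACA20+13xCGCA20+CACA20+CA18")
        control_allele = parse_nomenclature("5xCACA20+CA18+CACA20+CA18")
        p_pat, p_ctl = config.methylation_probs
        seeds = np.random.SeedSequence(stage_seeds["methylation"]).spawn(2)
        results = {}
        summaries = []
        for name, allele, prob, child in (
            ("patients", patient_allele, p_pat, seeds[0]),
            ("controls", control_allele, p_ctl, seeds[1]),
        ):
            profile = MethylationProfile.uniform(allele, prob)
            records, truth = generate_bisulfite_dataset(
                profile,
                n_samples=config.bisulfite_samples,
                clones_per_sample=config.clones_per_sample,
                efficiency=1.0,
                seed=int(child.generate_state(1)[0] % (2**31)),
            )
            clone_set = filter_clones([r for _, r in records], profile.reference_sequence)
            summary = quantify_methylation(clone_set)
            summaries.append(summary)
            results[name] = {
                "n_clones_kept": summary.n_clones,
                "global_methylation_percent": round(100 * summary.global_fraction, 2),
                "planted_percent": round(100 * prob, 2),
            }
        p, table = compare_groups(summaries[0], summaries[1])
        results["fisher_pooled_p"] = float(p)
        results["fisher_table"] = table.tolist()
        report["methylation"] = results

    if config.out_dir:
        os.makedirs(config.out_dir, exist_ok=True)
        with open(os.path.join(config.out_dir, "report.json"), "w") as fh:
            json.dump(report, fh, indent=2)
    return report
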