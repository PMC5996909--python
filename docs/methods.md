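# Methods

`repeatlens` models the tandem-repeat array in the *EIF4A3* 5′UTR and the
assays used to characterize it. This note documents the models, their
assumptions, the defaults that matter, and what the synthetic data do and do
not establish.

## The repeat locus and its motif alphabet

The array is built from three units sharing a 10-nt head (`TCGGCAGCGG`) and
differing only in central nucleotides:

| id | sequence | length | CpGs |
|------|----------------------|--------|------|
| CA18 | `TCGGCAGCGGCAGCGAGG` | 18 nt | 3 |
| CACA20 | `TCGGCAGCGGCACAGCGAGG` | 20 nt | 3 |
| CGCA20 | `TCGGCAGCGGCGCAGCGAGG` | 20 nt | 4 |

An allele is an ordered motif list, optionally interrupted by short
non-motif insertions (observed insertions are 12 or 20 nt, so the default
`max_insertion_len` is 20). Because every unit ends in `GG` and starts with
`TC`, motif boundaries in a pure-motif sequence can only fall at `GG|TC`
junctions, which makes exact tiling unique for this alphabet (asserted
exhaustively for all compositions up to six motifs). Decomposition
nevertheless uses longest-match backtracking so that user-supplied alphabets
without this property still decompose correctly. Junctions contain no CpG
(`G|T`), so CpG counts are additive over motifs: the published 16-repeat
pathogenic allele (1 CACA20, 13 CGCA20, 1 CACA20, 1 CA18) carries 61 CpGs
against 24 for any 8-repeat CA18/CACA20 allele — a gain of 37.

Classification is recessive: an allele is a pathogenic candidate iff it has
≥ 14 repeats and ≥ 1 CGCA20 (both thresholds configurable; controls span
2–12 repeats, patients 14–16, and the one known 17-repeat allele is
pathogenic-candidate). Repeat counts of 13 fall in an explicit
"indeterminate zone" — no cohort has ever shown one, so the classifier
flags rather than guesses. A genotype is AFFECTED iff both alleles are
pathogenic candidates, CARRIER iff exactly one. Insertion-bearing alleles
are classified atypical regardless of composition and are excluded from
per-motif expression modelling.

The strand of the printed motifs is not standardized; `auto_orient` tries
the reverse complement when the given orientation does not tile.

## Heterozygote deconvolution

Sequencing a diploid amplicon superposes the two allele sequences. The
forward model 5′-aligns the two amplicons (`flank5 + allele + flank3`, fixed
30-nt flanks in the synthetic generator) and emits the IUPAC union at each
position; no peak heights or quality values are modelled, only
presence/absence of bases. Inversion is exact: every motif tiling
compatible with the positional IUPAC sets is enumerated by branch-and-bound
(bounded by `max_repeats`, default 20, and a node budget), tilings are
paired so the longer amplicon spans the read, and pairs are scored by
forward-model mismatches. All zero-mismatch candidates are returned — real
ambiguities are enumerated, never hidden; a mismatch budget (≤ 2) is
available to mimic base-calling noise but defaults to 0. Soundness (the
generating pair always appears among the zero-mismatch candidates) is
asserted on 200 random heterozygotes. The ambiguity rate on uniformly
random allele pairs is high (roughly half the pairs admit more than one
zero-mismatch explanation, typically differing in which same-length motif
was assigned where); on cohort-shaped spectra, where alleles are blocky
runs, it is considerably lower. No comparable published rate exists.

## Unequal crossing-over simulator

Crossover between misaligned arrays is modelled at motif granularity:
products of parents `p1`, `p2` at breakpoints `b1`, `b2` are
`p1[:b1] + p2[b2:]` and `p2[:b2] + p1[b1:]`, conserving total motif count.
Sub-motif breakpoints are deliberately excluded — the shared 10-nt head
keeps register at motif boundaries, and sub-motif exchange would create
units never observed in any allele. There is no replication-slippage mode:
the locus is transgenerationally stable, unlike dynamic-mutation loci, and
the simulator makes that contrast explicit (with `crossover_rate = 0`
structures are immutable across generations).

`evolve_population` is a Wright–Fisher resampler over a pool of `2N`
alleles; with probability `crossover_rate` per transmission, the transmitted
allele is a random product of an unequal crossover between the parent's two
homologs, with the breakpoint pair uniform over misalignments (`b1 ≠ b2`)
whose products both fall in the viable range 2–20 motifs (observed range
2–17 plus headroom). The expected transmitted size equals the parental mean
— the per-meiosis size process is a martingale — so the mean motif count is
conserved in expectation while variance grows; a single small population
still wanders, which is why the conservation test averages over replicate
trajectories.

`derivation_distance` finds the minimal number of crossover events deriving
a target allele from a pool, counting an event built from intermediates
costing *i* and *j* events as *i + j + 1*. The search is exact within
`max_events` (capped at 4; the space is exponential) and returns one witness
path. No recombination rate or ancestral pool is known for the real locus:
simulator outputs are properties of the model, not inferences about
*EIF4A3* history.

## Haplotypes and linkage disequilibrium

The marker panel is the five flanking SNPs in plus-strand order
rs11150824, rs2289534, [repeat], rs3829612, rs10782008, rs12943620, with the
repeat locus included as a categorical marker (alleles are structure
nomenclature strings). Pairwise LD uses the standard normalization
D′ = |D|/D_max with D = p_AB − p_A·p_B; monomorphic margins raise an error
rather than returning 0, and multi-allelic loci are collapsed to
major-allele-vs-rest before the biallelic formula. Because the published
"D′ < 0.48" does not name a marker pair, the package always reports the
full pairwise matrix and its maximum.

Phasing is maximum-likelihood EM over haplotype-pair expansions of unphased
genotypes, exact for ≤ 8 loci. Identical genotype patterns are grouped, so
cost scales with distinct patterns rather than sample size. Initialization
is uniform (deterministic); convergence is |Δ log L| < 1e-8 with at most
1000 iterations, and the log-likelihood is checked non-decreasing on every
run. Missing loci are marginalized over the alleles observed in the cohort.
MAP phase ties break toward the pair whose first haplotype has the higher
estimated frequency.

## Expression modelling

Relative luciferase activity anchors each construct's mean firefly/Renilla
ratio between the negative and positive control means:
`percent = 100 · (r̄_construct − r̄_neg) / (r̄_pos − r̄_neg)`. Well ratios
are averaged per construct before normalization; the SE is propagated from
replicate variance of the experimental ratios with controls treated as
fixed. The statistic is invariant to rescaling all firefly counts.

Two per-motif estimators coexist deliberately:

* `per_motif_effect` reproduces the pairwise attribution convention used for
  the published comparisons: activity drop divided by the *total* motifs
  added, credited to the dominant added type (4- vs 10-repeat: 2.76 % / 6 =
  0.46 % per CACA20; 12- vs 16-repeat: 5.84 % / 4 = 1.46 % per CGCA20).
  Values are reported at 2 decimals to match the source precision.
* `MotifActivityModel` is the principled alternative: OLS of percent on
  per-type motif counts, with leave-one-construct-out refits as a stability
  diagnostic. With zero noise it recovers planted coefficients to machine
  precision. Note the two estimators disagree whenever more than one motif
  type is added: the 12→16 extension adds 3 CGCA20 + 1 CACA20, so under a
  linear model its drop is 3β_CGCA + β_CACA, not 4 motifs at the CGCA rate.

Significance testing is one-way ANOVA with Tukey HSD post hoc pairs at
α = 0.05, delegated to scipy/statsmodels.

## Bisulfite methylation

The forward model converts non-CpG cytosines C→T with the stated conversion
efficiency and CpG cytosines only when unmethylated; only the top
(motif-sense) strand is modelled, since cloned PCR products do not track
strand. Clone filtering aligns each read globally to the unconverted
reference (match +1, mismatch −1, gap −2) and applies four thresholds:
conversion ≥ 95 % (fraction of non-CpG reference Cs read as T among those
read as C or T), identity ≥ 90 %, N-calls at cytosine positions ≤ 20 %, and
gap columns ≤ 20 %. Identity excludes C/T differences at *all* reference
cytosines: a T at a CpG cytosine is the unmethylated call, exactly as
bisulfite-expected as conversion at non-CpG cytosines, and counting it as a
mismatch would reject every legitimately unmethylated clone in this CpG
density (roughly one CpG per 5–7 bp of motif). Every violated threshold is
listed per clone; reads under 50 % identity are flagged unalignable.

Quantification counts, per CpG position over kept clones, C as methylated
and T as unmethylated (anything else is no-call); the global fraction pools
all calls and therefore equals the call-weighted mean of per-CpG fractions.
Group comparison defaults to one pooled 2×2 Fisher exact test of
methylated/unmethylated calls (mirroring a global low-methylation
comparison such as 1.7 % vs 2.8 %); per-CpG Fisher tests with Bonferroni
correction are available since the published per-CpG procedure is ambiguous.
The real clone sets were never deposited, so these percentages are a regime
the generator emulates, not numeric targets.

## Synthetic cohort generator

The generator produces every input the pipeline consumes, with planted
ground truth serialized alongside:

* **Diploid cohort** — default n = 380 individuals under Hardy–Weinberg
  (optional inbreeding coefficient, default 0, since the disease is
  consanguinity-prone) from a *stylized* spectrum: modal 7-repeat (25.46 %)
  and 8-repeat (23.21 %) alleles, repeat counts 2–17, a pure-CA18 allele,
  and CGCA20-carrier alleles totalling 1 %. The real per-structure counts
  were only ever shown graphically, so this spectrum is configuration, not
  data. Expected heterozygosity under the default spectrum is ≈ 0.85.
* **SNP panel** — five biallelic SNPs drawn from a fixed haplotype
  distribution built as near-independence with bounded boosts to a few
  haplotypes; its exact max pairwise D′ is 0.078, comfortably inside the
  weak-LD regime (< 0.48) the real block shows.
* **Luciferase plates** — wells realize `percent = intercept + Σ β·count +
  N(0, σ)` inverted through the activity formula around control ratios
  0.02/1.02; defaults β_CA18 = β_CACA20 = −0.46, β_CGCA20 = −1.46,
  intercept 25 %.
* **Bisulfite clones** — per-CpG Bernoulli states through the conversion
  model (10 clones per sample, 7 samples per group by default), with
  optional planted filter violations built to breach exactly one threshold
  deterministically.

One integer seed drives everything, split hierarchically per sub-generator;
identical seed and spec give byte-identical outputs.

**What passing tests show — and do not.** Recovery tests prove the
estimators invert the package's own forward models at realistic sizes; they
cannot validate trace-level artifacts of real Sanger data (peak-height
asymmetries, primer slippage), luminometer noise beyond Gaussian, cloning
bias in bisulfite libraries, or the true allele spectrum of any population.
Figure-level results of the source cohort (the 43-allele catalogue, 85 %
heterozygosity, the exact haplotype sharing) derive from undeposited data
and are covered by model properties instead.

## Problem sizes and numerical choices

Default test and pipeline runs use: 1000 alleles for round-trip checks, 200
heterozygotes for deconvolution soundness, EM recovery at n = 100 and
n = 10,000 (pattern grouping keeps the latter cheap), 12 replicates for the
noisy luciferase fit, and 7 × 10 clones per methylation group — sizes chosen
to match the study design where one exists and to keep Monte-Carlo error
well inside the asserted tolerances elsewhere. EM tolerance is 1e-8 on the
log-likelihood; D′ uses exact proportion arithmetic; percents are reported
to 2 decimals to match the source precision. Deconvolution and derivation
searches carry explicit node budgets and raise a resource error with the
frontier size rather than degrading silently.

## Known limitations

* Insertion-bearing alleles do not recombine in the simulator (v1).
* The deconvolution forward model is sequence-level only; it cannot use
  peak heights to break ties a trace reader might resolve.
* The EM phaser enumerates haplotypes exhaustively and is limited to 8 loci.
* Clone-based methylation tools rarely publish their internal alignment
  scoring; the affine scores used here are a documented convention of this
  package, not a reimplementation of any particular tool.
* The luciferase per-motif betas for CA18 and CACA20 are nearly collinear
  with the intercept across the published construct set, so their noisy
  estimates are the least stable — visible in the leave-one-out diagnostic.
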