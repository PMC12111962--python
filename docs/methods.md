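# Methods

## Scope and model

`luadcohort` implements the statistical core of a small-cohort vs
large-reference comparative exome analysis: germline carrier
prioritization, SBS-96 signature refitting, driver-gene consensus with
resampling nulls, and per-gene frequency / burden contrasts. It starts
from *annotated* variant tables: variant calling, VEP-style annotation,
ancestry estimation and the internals of external driver-detection tools
(dNdScv, MutSigCV, OncodriveFML) are upstream of the package and consumed
as inputs (annotated TSVs and per-gene ranking tables).

## Germline prioritization

A variant is retained when, in cascade order, (1) its clinical-significance
label is Pathogenic or Likely pathogenic, (2) its allele frequency is
*strictly* below the threshold (default 0.05) in every reporting
population — the maximum over populations governs, the conservative
reading of "rare in any population", (3) its gene is on the
susceptibility list, and (4) it passed review (a boolean input flag; the
package performs no visual review). Uncertain-significance variants pass
the same frequency/gene/review gates and additionally need at least two of
three predictor votes: CADD phred strictly above 20, PolyPhen "Probably
damaging" or "Possibly damaging", SIFT "Deleterious". A missing predictor
never counts as a vote, so partially annotated variants can only fail the
2-of-3 rule, never sneak past it. Every variant receives exactly one
decision; exclusions carry the first failing criterion as a machine-readable
reason code. ACMG/AMP classification itself is not re-derived — the label
is an input annotation, as in the upstream annotation workflow.

## SBS-96 catalogs and refitting

Substitutions are canonicalized to the 96 pyrimidine-referenced channels
(purine-reference records are reverse-complemented together with their
3-mer context), so catalogs are strand-invariant by construction. Only
single-nucleotide variants are counted; indels and records with ambiguous
context are excluded (the latter logged). Exposures are refit per patient
by non-negative least squares, min ‖m − S·e‖₂ subject to e ≥ 0
(`scipy.optimize.nnls`). This deliberately omits the forward-selection /
sparsity heuristics of published assignment tools: plain NNLS is
deterministic, has a well-defined optimum, and is sufficient for the
cohort-contrast statistics the package computes; exposures for signatures
truly absent from the data are empirically driven to near zero by the
optimum itself (the tests bound the leakage at < 0.02 proportion in ≥ 90%
of patients at 3,000 SNVs). Cohort profiles are the arithmetic mean of
per-patient *proportions* rather than pooled counts, so a single
hyper-mutated patient cannot dominate the cohort summary; patients with
zero attributed SNVs are undefined and excluded from the mean. Presence of
a signature in a patient is "attributed proportion > ε" with ε = 0 by
default (any positive attribution counts); ε is configurable because the
choice is a genuine judgment call and flips patients with trace
attributions.

## Shared exact tests

All cohort contrasts funnel through one statistics module. The two-sided
Fisher exact test uses the probability-mass rule — sum the probabilities
of all tables with the observed margins whose probability does not exceed
the observed table's, with a relative 1e-7 tie guard — delegated to
`scipy.stats.fisher_exact`, whose convention this is; the test suite
verifies agreement with an exact-integer enumeration oracle to < 1e-12
over every table with total ≤ 40. The Wilcoxon–Mann–Whitney test uses
exact permutation enumeration (midranks, so ties are handled) when the
pooled sample size is ≤ 20, and the normal approximation with tie and
continuity corrections above that; an all-tied degenerate input returns
p = 1. Bonferroni correction is min(1, m·p) with the family size m
defaulting to the number of signatures compared. Empirical p-values from
resampling use the add-one convention (1 + exceedances)/(B + 1), so p is
never zero and attains its floor 1/(B + 1) exactly when no resample
reaches the observed statistic — consistent with reporting bounds like
"p < 2 × 10⁻⁵" at B = 50,000.

## Driver consensus and its nulls

Each tool's candidate set is the best-ranked ⌈fraction·G⌉ genes (ceiling;
the rounding convention is ours, ties broken by score then lexicographic
symbol for determinism), and the consensus statistic is the size of the
set of genes in ≥ 2 of 3 deciles. The coincidence null draws, per
resample, three independent uniform random gene sets of the observed
decile sizes from the shared universe — the literal "random gene samples"
null; correlation-preserving alternatives are out of scope. The
cross-cohort overlap null draws independent random subsets of sizes |A|
and |B| from the universe and records their intersection; because that
intersection is exactly hypergeometric(|U|, |A|, |B|), the implementation
samples the hypergeometric directly (mathematically identical,
dramatically faster at B = 50,000), and reports the analytic expectation
|A|·|B|/|U| alongside. The resampling universe defaults to the genes
scored by all participating tables. The built-in stand-in ranker scores
each gene by the upper-tail Poisson probability of its nonsilent count
given expectation = cohort nonsilent rate per base × gene length; it is a
pluggable placeholder for the external tools, not a reimplementation of
any of them.

The subsample bias experiment draws B random m-patient subsets (default
m = 25) from the reference cohort without replacement, re-ranks genes on
each subset alone, and records the top decile's intersection with a
reference driver list and the fraction outside it. The resulting
distributions separate two effects: how much candidate recovery degrades
at small m (the sample-size artifact), and whether a query cohort's
non-reference fraction exceeds the null's 95th percentile (a real
divergence).

## Frequencies and burden

Per-gene frequency counts mutated *patients* (a patient with several hits
in a gene counts once); silent mutations are excluded from mutated status
by default, the usual driver-frequency convention, and the choice is
configurable. TMB is the count of missense, nonsense, nonstop and
splice-site mutations divided by the capture size in Mb (default 37.5);
the cohort median is the standard midpoint-of-order-statistics median.
Genes observed in only one cohort are compared against 0/total in the
other and flagged. The multiple-testing default for per-gene contrasts is
Bonferroni, switchable to none to reproduce single-gene quoted p-values.

## Synthetic cohorts

The generator produces the statistical structure the pipeline assumes,
with the planted truth recorded for every stage. Per patient the mutation
count is Poisson with configurable mean (default 345, which at the default
class mix puts the median TMB near 6–7 nonsynonymous mutations/Mb, the
scale of a LUAD exome cohort); a configurable fraction (default 0.08) are
indels. Each SNV's channel is drawn from the patient's mixture of catalog
signature profiles, the mixture itself a Dirichlet draw (flat by default);
the truth block records the realized per-signature attribution, which is
the correct refitting target since it is what actually generated the
catalog. Genes receive mutations proportionally to coding length times a
planted driver multiplier; coordinates are synthetic positions inside
end-to-end gene footprints, and the 3-mer context is stored per record so
no reference FASTA is needed (a pyfaidx-backed context extractor exists
for real tables that lack the column). Half the SNVs are emitted on the
purine strand to keep canonicalization honest. Planted germline carriers
(default rate 0.32, roughly a third of patients) receive exactly one
qualifying variant — 70% P/LP, 30% VUS passing 2-of-3 — while non-carriers
may receive a decoy that fails exactly one cascade criterion, cycling
through all five failure branches so every exclusion path is exercised.
Ranking tables mix a shared latent score (planted drivers boosted by a
configurable number of SDs) with per-tool noise; concordance 1 gives
identical orders, 0 gives independent ones. Patient metadata mirrors a
late-stage-heavy, smoking-enriched cohort with an explicit "unknown"
smoking category for incomplete denominators.

All randomness flows from a single master seed through
`numpy.random.SeedSequence` children, one per generation stage in fixed
order, so identical configs are byte-identical and adding records to one
stage never perturbs another. The pipeline derives named child seeds the
same way and echoes them in its JSON report.

What the generator does **not** emulate: linkage and haplotype structure,
read-level error processes, realistic gene-length heterogeneity (lengths
default to uniform 1.5 kb), mutation-class dependence on gene identity, and
signature profiles of the real COSMIC catalog (the bundled catalog is
synthetic and labeled as such). Passing tests therefore demonstrate the
correctness and calibration of the statistical machinery, not the
biological fidelity of any particular dataset.

## Numerical choices and limitations

Problem sizes in the test suite and the reproduction script — 25-patient
query cohorts, 250-patient references, universes of 1,000 genes, B = 2,000
for calibration checks and B = 50,000 for single tests, 20 replicate seeds
— were chosen as the smallest sizes at which the checked properties are
stable, keeping the default runs fast on a laptop. Exact-test tolerances:
the Fisher routine is checked to 1e-12 against enumeration; NNLS refit
accuracy is bounded at mean L1 error < 0.05 at 3,000 SNVs/patient. The
empirical-p floor means no resampling p-value can be reported below
1/(B + 1): claims smaller than that require a larger B, not a smaller
number. Known limitations: no de-novo signature extraction (NMF), no
DBS/ID signatures, no survival or pathway analysis, and the consensus
statistic (joint-set size) is one reasonable operationalization of
"coincidence among rankings" — alternatives (rank-correlation statistics)
are not implemented.
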