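"""Synthetic cohorts with planted ground truth.

Generates everything the downstream stages consume — somatic mutation
tables whose SBS-96 channels are drawn from known signature mixtures,
germline variant tables with planted carriers and single-failure decoys,
patient metadata, and three tool rankings with tunable concordance — so the
whole pipeline is testable end to end with no external download, and every
recovered quantity can be checked against the planted truth.

Randomness: one master seed; each generation stage (metadata, somatic,
germline, rankings) consumes its own child generator spawned
deterministically from ``numpy.random.SeedSequence(seed)``, in that fixed
order, so adding records to one stage never perturbs another.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .germline import GermlineVariant, write_germline_tsv
from .signatures import CHANNELS_96, write_maf
from .drivers import RankingTable, rank_from_scores, write_ranking_tsv

__all__ = [
    "SimConfig",
    "SyntheticCohort",
    "CohortTruth",
    "generate_cohort",
    "generate_rankings",
    "synthetic_signature_catalog",
    "load_bundled_catalog",
    "write_cohort",
    "pick_planted_drivers",
]

#: decoy kinds cycle over every single-failure branch of the germline cascade
DECOY_KINDS = ("af", "gene_list", "review", "insufficient_predictors",
               "significance")

_SNV_CLASSES = ("missense", "silent", "nonsense", "splice_site",
                "nonstop", "other")
_SNV_CLASS_PROBS = (0.62, 0.18, 0.07, 0.05, 0.01, 0.07)

_STAGES = ("I", "II", "III", "IV")
_STAGE_PROBS = (0.08, 0.08, 0.20, 0.64)    # late-stage-heavy cohort

_PYRIMIDINE_PARTNER = {"A": "T", "C": "G", "G": "C", "T": "A"}


@dataclass
class SimConfig:
    """Study conditions for one synthetic cohort.

    Defaults emulate a small lung-adenocarcinoma exome cohort: 25 patients,
    a flat-Dirichlet mixture over the catalog signatures, roughly a third
    of patients carrying a qualifying germline variant, and a
    predominantly late-stage, smoking-enriched population.
    """

    n_patients: int = 25
    n_genes: int = 1000
    gene_length: int = 1500          # coding bases per gene (uniform default)
    gene_lengths: Sequence[float] | None = None
    mutation_rate: float = 345.0     # expected somatic mutations per patient
    indel_fraction: float = 0.08     # fraction of mutations that are indels
    planted_drivers: Mapping[str, float] = field(default_factory=dict)
    signature_mixture: Sequence[float] | None = None   # Dirichlet alphas, K
    carrier_rate: float = 0.32
    decoy_rate: float = 0.5          # non-carriers receiving one decoy variant
    plp_carrier_fraction: float = 0.7  # carriers with P/LP (rest rescued VUS)
    n_susceptibility_genes: int = 152
    ranking_concordance: float = 0.7
    driver_score_boost: float = 3.0  # latent-score SDs added to drivers
    smoking_probs: tuple[float, float, float] = (0.40, 0.28, 0.32)
    # (ever, never, unknown)
    seed: int = 0

    def __post_init__(self):
        if self.n_patients <= 0 or self.n_genes <= 0:
            raise ValueError("n_patients and n_genes must be positive")
        if self.gene_lengths is not None and len(self.gene_lengths) != self.n_genes:
            raise ValueError("gene_lengths must cover all n_genes")
        if not 0 <= self.carrier_rate <= 1:
            raise ValueError("carrier_rate must be in [0, 1]")
        if not 0 <= self.ranking_concordance <= 1:
            raise ValueError("ranking_concordance must be in [0, 1]")
        if not 0 <= self.indel_fraction < 1:
            raise ValueError("indel_fraction must be in [0, 1)")
        if self.signature_mixture is not None and any(
            a <= 0 for a in self.signature_mixture
        ):
            raise ValueError("Dirichlet concentrations must be positive")
        if any(m < 1 for m in self.planted_drivers.values()):
            raise ValueError("driver rate multipliers must be >= 1")
        if abs(sum(self.smoking_probs) - 1) > 1e-9:
            raise ValueError("smoking_probs must sum to 1")

    @property
    def gene_names(self) -> list[str]:
        return [f"G{i:04d}" for i in range(1, self.n_genes + 1)]

    @property
    def susceptibility_genes(self) -> list[str]:
        return [f"CSG{i:03d}" for i in range(1, self.n_susceptibility_genes + 1)]

    def lengths_series(self) -> pd.Series:
        if self.gene_lengths is not None:
            vals = np.asarray(self.gene_lengths, dtype=float)
        else:
            vals = np.full(self.n_genes, float(self.gene_length))
        return pd.Series(vals, index=self.gene_names)

    @classmethod
    def from_dict(cls, d: Mapping) -> "SimConfig":
        d = dict(d)
        if "smoking_probs" in d:
            d["smoking_probs"] = tuple(d["smoking_probs"])
        if "planted_drivers" in d and d["planted_drivers"] is not None:
            d["planted_drivers"] = dict(d["planted_drivers"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "SimConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def pick_planted_drivers(
    n_genes: int, n_drivers: int, multiplier: float
) -> dict[str, float]:
    """Evenly spaced driver genes over the universe, all at one multiplier."""
    idx = np.linspace(0, n_genes - 1, n_drivers).round().astype(int)
    return {f"G{i + 1:04d}": float(multiplier) for i in idx}


@dataclass
class CohortTruth:
    """Planted ground truth recorded at generation time."""

    exposures: pd.DataFrame        # realized per-patient signature proportions
    mixture_weights: pd.DataFrame  # the Dirichlet draws the SNVs came from
    signature_counts: pd.DataFrame  # per-patient SNVs attributed per signature
    drivers: frozenset[str]
    carriers: frozenset[str]


@dataclass
class SyntheticCohort:
    patients: pd.DataFrame         # patient_id, smoking, stage, sex, age
    somatic: pd.DataFrame          # MAF-like dialect
    germline: list[GermlineVariant]
    truth: CohortTruth
    config: SimConfig

    @property
    def patient_ids(self) -> list[str]:
        return list(self.patients["patient_id"])


# ---------------------------------------------------------------------------
# signature catalog
# ---------------------------------------------------------------------------

def synthetic_signature_catalog(
    n_signatures: int = 5, seed: int = 101, concentration: float = 0.1
) -> pd.DataFrame:
    """A synthetic signature catalog (NOT COSMIC signatures).

    Each signature is an independent Dirichlet draw over the 96 channels;
    the low default concentration yields sparse, well-separated profiles
    like real mutational processes. Columns are named SynSig1.. so they can
    never be mistaken for COSMIC SBS identities.
    """
    rng = np.random.default_rng(seed)
    profiles = rng.dirichlet(np.full(96, concentration), size=n_signatures).T
    cols = [f"SynSig{i}" for i in range(1, n_signatures + 1)]
    cat = pd.DataFrame(profiles, index=CHANNELS_96, columns=cols)
    cat.index.name = "Type"
    return cat


def load_bundled_catalog() -> pd.DataFrame:
    """The 5-signature synthetic catalog shipped with the package."""
    from .signatures import read_signature_catalog

    ref = importlib.resources.files("luadcohort") / "data" / "synthetic_sbs96_5sig.tsv"
    with importlib.resources.as_file(ref) as path:
        return read_signature_catalog(path)


# ---------------------------------------------------------------------------
# cohort generation
# ---------------------------------------------------------------------------

def _patient_ids(n: int) -> list[str]:
    return [f"P{i:03d}" for i in range(1, n + 1)]


def _generate_metadata(config: SimConfig, rng: np.random.Generator
                       ) -> pd.DataFrame:
    n = config.n_patients
    smoking = rng.choice(["ever", "never", "unknown"], size=n,
                         p=config.smoking_probs)
    stage = rng.choice(_STAGES, size=n, p=_STAGE_PROBS)
    sex = rng.choice(["F", "M"], size=n, p=[0.56, 0.44])
    age = np.clip(rng.normal(58.8, 14.5, size=n), 18, 95).round().astype(int)
    return pd.DataFrame({
        "patient_id": _patient_ids(n),
        "smoking": smoking, "stage": stage, "sex": sex, "age": age,
    })


def _channel_parts(channel: str) -> tuple[str, str, str]:
    """(ref, alt, context3) of a channel label on the pyrimidine strand."""
    five, rest = channel[0], channel[2:]
    ref, alt, three = rest[0], rest[2], rest[4]
    return ref, alt, f"{five}{ref}{three}"


_CHANNEL_PARTS = [_channel_parts(c) for c in CHANNELS_96]
_REVCOMP3 = {
    ctx: "".join(_PYRIMIDINE_PARTNER[b] for b in reversed(ctx))
    for _, _, ctx in _CHANNEL_PARTS
}


def _generate_somatic(
    config: SimConfig, catalog: pd.DataFrame, rng: np.random.Generator
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    k = catalog.shape[1]
    alphas = (np.asarray(config.signature_mixture, dtype=float)
              if config.signature_mixture is not None else np.ones(k))
    if len(alphas) != k:
        raise ValueError(
            f"signature_mixture has {len(alphas)} concentrations but the "
            f"catalog holds {k} signatures"
        )
    genes = config.gene_names
    if not genes:
        raise ValueError("empty gene set")
    lengths = config.lengths_series()
    weights = lengths.copy()
    for g, mult in config.planted_drivers.items():
        if g not in weights.index:
            raise ValueError(f"planted driver {g!r} not in the gene universe")
        weights[g] *= mult
    gene_p = (weights / weights.sum()).to_numpy()
    starts = np.concatenate([[0], np.cumsum(lengths.to_numpy())[:-1]]).astype(int)
    start_by_gene = dict(zip(genes, starts))
    len_by_gene = dict(zip(genes, lengths.astype(int)))

    profiles = catalog.to_numpy()        # 96 x K
    pids = _patient_ids(config.n_patients)
    mix = rng.dirichlet(alphas, size=config.n_patients)

    rows = []
    sig_counts = np.zeros((config.n_patients, k), dtype=np.int64)
    for pi, pid in enumerate(pids):
        n_mut = rng.poisson(config.mutation_rate)
        n_indel = rng.binomial(n_mut, config.indel_fraction)
        n_snv = n_mut - n_indel
        per_sig = rng.multinomial(n_snv, mix[pi])
        sig_counts[pi] = per_sig
        chan_idx = []
        for s in range(k):
            if per_sig[s] == 0:
                continue
            chan_counts = rng.multinomial(per_sig[s], profiles[:, s])
            chan_idx.append(np.repeat(np.arange(96), chan_counts))
        chan_idx = (np.concatenate(chan_idx) if chan_idx
                    else np.empty(0, dtype=int))
        rng.shuffle(chan_idx)
        gene_idx = rng.choice(config.n_genes, size=n_mut, p=gene_p)
        classes = rng.choice(_SNV_CLASSES, size=n_snv, p=_SNV_CLASS_PROBS)
        flip = rng.random(n_snv) < 0.5   # emit half the SNVs purine-stranded
        for j in range(n_snv):
            g = genes[gene_idx[j]]
            ref, alt, ctx = _CHANNEL_PARTS[chan_idx[j]]
            if flip[j]:
                ctx = _REVCOMP3[ctx]
                ref = _PYRIMIDINE_PARTNER[ref]
                alt = _PYRIMIDINE_PARTNER[alt]
            pos = start_by_gene[g] + int(rng.integers(len_by_gene[g])) + 1
            rows.append((pid, g, "1", pos, ref, alt, classes[j], ctx))
        for j in range(n_indel):
            g = genes[gene_idx[n_snv + j]]
            pos = start_by_gene[g] + int(rng.integers(len_by_gene[g])) + 1
            base = "ACGT"[int(rng.integers(4))]
            ins = "ACGT"[int(rng.integers(4))]
            if rng.random() < 0.5:
                ref, alt = base, base + ins       # insertion
            else:
                ref, alt = base + ins, base       # deletion
            rows.append((pid, g, "1", pos, ref, alt, "indel", ""))
    somatic = pd.DataFrame(
        rows, columns=["patient_id", "gene", "chrom", "pos", "ref", "alt",
                       "variant_class", "context3"],
    )
    counts = pd.DataFrame(sig_counts, index=pids, columns=catalog.columns)
    totals = counts.sum(axis=1).to_numpy()
    with np.errstate(invalid="ignore"):
        expo = counts.div(counts.sum(axis=1), axis=0)
    expo[totals == 0] = np.nan
    mixdf = pd.DataFrame(mix, index=pids, columns=catalog.columns)
    return somatic, expo, counts, mixdf


def _log_uniform_af(rng: np.random.Generator) -> dict[str, float]:
    """Rare allele frequencies (1e-6..1e-3) for two population databases."""
    return {
        "gnomad": float(10 ** rng.uniform(-6, -3)),
        "thousand_genomes": float(10 ** rng.uniform(-6, -3)),
    }


def _qualifying_variant(pid: str, gene: str, plp: bool,
                        rng: np.random.Generator, vid: str) -> GermlineVariant:
    if plp:
        sig = "Pathogenic" if rng.random() < 0.5 else "Likely pathogenic"
        return GermlineVariant(
            patient_id=pid, gene=gene, clinical_significance=sig,
            af_by_population=_log_uniform_af(rng),
            cadd_phred=float(rng.uniform(15, 40)),
            polyphen=None, sift=None, review_pass=True, variant_id=vid,
        )
    # VUS rescued by the 2-of-3 predictor rule: meet exactly 2 or all 3
    met = rng.permutation(3)[: int(rng.integers(2, 4))]
    return GermlineVariant(
        patient_id=pid, gene=gene, clinical_significance="Uncertain significance",
        af_by_population=_log_uniform_af(rng),
        cadd_phred=float(rng.uniform(20.5, 40)) if 0 in met
        else float(rng.uniform(1, 19.5)),
        polyphen=("Probably damaging" if rng.random() < 0.5
                  else "Possibly damaging") if 1 in met else "Benign",
        sift="Deleterious" if 2 in met else "Tolerated",
        review_pass=True, variant_id=vid,
    )


def _decoy_variant(pid: str, kind: str, susceptibility: list[str],
                   rng: np.random.Generator, vid: str) -> GermlineVariant:
    """A variant failing exactly the ``kind`` criterion of the cascade."""
    gene = susceptibility[int(rng.integers(len(susceptibility)))]
    base = dict(
        patient_id=pid, gene=gene,
        clinical_significance=("Pathogenic" if rng.random() < 0.5
                               else "Likely pathogenic"),
        af_by_population=_log_uniform_af(rng),
        cadd_phred=float(rng.uniform(15, 40)),
        polyphen=None, sift=None, review_pass=True, variant_id=vid,
    )
    if kind == "af":
        base["af_by_population"] = {"gnomad": float(rng.uniform(0.05, 0.5))}
    elif kind == "gene_list":
        base["gene"] = f"OFF{int(rng.integers(1, 100)):03d}"
    elif kind == "review":
        base["review_pass"] = False
    elif kind == "significance":
        base["clinical_significance"] = "other"
    elif kind == "insufficient_predictors":
        base["clinical_significance"] = "Uncertain significance"
        met = int(rng.integers(3)) if rng.random() < 0.5 else -1  # 1 or 0 met
        base["cadd_phred"] = (float(rng.uniform(20.5, 40)) if met == 0
                              else float(rng.uniform(1, 19.5)))
        base["polyphen"] = "Possibly damaging" if met == 1 else "Benign"
        base["sift"] = "Deleterious" if met == 2 else "Tolerated"
    else:
        raise ValueError(f"unknown decoy kind {kind!r}")
    return GermlineVariant(**base)


def _generate_germline(config: SimConfig, rng: np.random.Generator
                       ) -> tuple[list[GermlineVariant], frozenset[str]]:
    variants: list[GermlineVariant] = []
    carriers: set[str] = set()
    susc = config.susceptibility_genes
    vcounter = 0
    for pid in _patient_ids(config.n_patients):
        if rng.random() < config.carrier_rate:
            carriers.add(pid)
            gene = susc[int(rng.integers(len(susc)))]
            plp = rng.random() < config.plp_carrier_fraction
            vcounter += 1
            variants.append(_qualifying_variant(
                pid, gene, plp, rng, f"V{vcounter:04d}"))
        elif rng.random() < config.decoy_rate:
            kind = DECOY_KINDS[int(rng.integers(len(DECOY_KINDS)))]
            vcounter += 1
            variants.append(_decoy_variant(
                pid, kind, susc, rng, f"V{vcounter:04d}"))
    return variants, frozenset(carriers)


def generate_cohort(config: SimConfig, catalog: pd.DataFrame
                    ) -> SyntheticCohort:
    """Generate a full synthetic cohort against a signature catalog.

    The truth block records the realized per-patient signature attribution
    (the proportions of that patient's SNVs actually drawn from each
    signature), the Dirichlet mixture weights behind them, the planted
    driver set and the planted carrier set.
    """
    ss = np.random.SeedSequence(config.seed)
    meta_rng, somatic_rng, germ_rng, _ = (
        np.random.default_rng(c) for c in ss.spawn(4)
    )
    patients = _generate_metadata(config, meta_rng)
    somatic, expo, sig_counts, mixdf = _generate_somatic(
        config, catalog, somatic_rng)
    germline, carriers = _generate_germline(config, germ_rng)
    truth = CohortTruth(
        exposures=expo, mixture_weights=mixdf, signature_counts=sig_counts,
        drivers=frozenset(config.planted_drivers),
        carriers=carriers,
    )
    return SyntheticCohort(patients=patients, somatic=somatic,
                           germline=germline, truth=truth, config=config)


def generate_rankings(cohort: SyntheticCohort,
                      config: SimConfig | None = None
                      ) -> list[RankingTable]:
    """Three per-gene rankings with tunable inter-tool concordance.

    Each tool's score mixes a shared latent component (in which planted
    drivers receive ``driver_score_boost`` standard deviations) with
    tool-specific noise: concordance 1 reproduces the shared order in all
    three tables, concordance 0 gives three independent random orders.
    """
    config = config or cohort.config
    c = config.ranking_concordance
    genes = config.gene_names
    ss = np.random.SeedSequence(config.seed)
    rng = np.random.default_rng(ss.spawn(4)[3])
    shared = rng.normal(size=len(genes))
    boost = np.array([config.driver_score_boost
                      if g in config.planted_drivers else 0.0 for g in genes])
    shared = shared + boost
    tables = []
    for tool in ("toolA", "toolB", "toolC"):
        noise = rng.normal(size=len(genes))
        score = c * shared + (1.0 - c) * noise
        tables.append(rank_from_scores(
            pd.Series(score, index=genes), tool, higher_is_better=True))
    return tables


# ---------------------------------------------------------------------------
# writers
# ---------------------------------------------------------------------------

def write_cohort(cohort: SyntheticCohort, outdir,
                 rankings: Sequence[RankingTable] | None = None,
                 relative_to: Path | None = None) -> dict:
    """Write the cohort in the pipeline's TSV dialects; returns the paths
    (relative to ``relative_to`` when given, for reproducible reports)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "somatic": outdir / "somatic.tsv",
        "germline": outdir / "germline.tsv",
        "metadata": outdir / "metadata.tsv",
        "susceptibility_genes": outdir / "susceptibility_genes.txt",
    }
    write_maf(cohort.somatic, paths["somatic"])
    write_germline_tsv(cohort.germline, paths["germline"])
    cohort.patients.to_csv(paths["metadata"], sep="\t", index=False)
    paths["susceptibility_genes"].write_text(
        "\n".join(cohort.config.susceptibility_genes) + "\n")
    if rankings is not None:
        for r in rankings:
            p = outdir / f"ranking_{r.tool}.tsv"
            write_ranking_tsv(r, p)
            paths[f"ranking_{r.tool}"] = p
    if relative_to is not None:
        return {k: str(v.relative_to(relative_to)) for k, v in paths.items()}
    return {k: str(v) for k, v in paths.items()}
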