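"""Germline variant prioritization cascade and carrier-rate comparison.

A germline short variant is retained when it

1. is reported as "Pathogenic" or "Likely pathogenic" (clinical-significance
   annotation supplied on input, ACMG/AMP-style),
2. has population allele frequency below a threshold (default 0.05, strict)
   in every population reported,
3. lies in a cancer-susceptibility gene list, and
4. passed manual review (modeled as a boolean flag).

Variants of uncertain significance (VUS) are rescued only when, in addition
to the frequency/gene/review conditions, at least two of three in-silico
predictors agree on damage: CADD phred > 20, PolyPhen "Probably damaging" or
"Possibly damaging", SIFT "Deleterious". Missing predictor values never
count as met. A patient is a carrier when at least one of their variants is
retained.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .stats import fisher_exact_two_sided

logger = logging.getLogger(__name__)

__all__ = [
    "GermlineVariant",
    "GeneList",
    "Decision",
    "classify_variant",
    "apply_filter",
    "CarrierTable",
    "carrier_proportion",
    "compare_carrier_rates",
    "read_germline_tsv",
    "write_germline_tsv",
    "read_gene_list",
    "read_germline_vcf",
]

PLP_LABELS = frozenset({"Pathogenic", "Likely pathogenic"})
VUS_LABEL = "Uncertain significance"
SIGNIFICANCE_VOCAB = frozenset({*PLP_LABELS, VUS_LABEL, "other"})
DAMAGING_POLYPHEN = frozenset({"Probably damaging", "Possibly damaging"})

RETAINED_PLP = "retained_PLP"
RETAINED_VUS = "retained_VUS"

#: exclusion reason codes, in the order criteria are evaluated
REASON_VOCABULARY = "vocabulary"
REASON_SIGNIFICANCE = "significance"
REASON_AF = "af"
REASON_GENE_LIST = "gene_list"
REASON_REVIEW = "review"
REASON_PREDICTORS = "insufficient_predictors"


@dataclass(frozen=True)
class GermlineVariant:
    patient_id: str
    gene: str
    clinical_significance: str
    af_by_population: Mapping[str, float]
    cadd_phred: float | None = None
    polyphen: str | None = None
    sift: str | None = None
    review_pass: bool = True
    variant_id: str | None = None

    def max_af(self) -> float:
        """Maximum allele frequency over all reporting populations; 0.0
        when no population reports the variant."""
        if not self.af_by_population:
            return 0.0
        vals = [v for v in self.af_by_population.values() if v == v]
        return max(vals) if vals else 0.0


@dataclass(frozen=True)
class GeneList:
    genes: frozenset[str]
    name: str = "susceptibility"

    def __post_init__(self):
        if not self.genes:
            raise ValueError("gene list is empty")

    def __contains__(self, gene: str) -> bool:
        return gene in self.genes


@dataclass(frozen=True)
class Decision:
    status: str           # retained_PLP | retained_VUS | excluded
    reason: str | None    # first failing criterion when excluded

    @property
    def retained(self) -> bool:
        return self.status in (RETAINED_PLP, RETAINED_VUS)


def _predictor_votes(v: GermlineVariant) -> int:
    votes = 0
    if v.cadd_phred is not None and v.cadd_phred == v.cadd_phred and v.cadd_phred > 20:
        votes += 1
    if v.polyphen in DAMAGING_POLYPHEN:
        votes += 1
    if v.sift == "Deleterious":
        votes += 1
    return votes


def classify_variant(
    v: GermlineVariant, genes: GeneList, af_threshold: float = 0.05
) -> Decision:
    """One decision per variant with the first failing criterion as reason.

    Criteria are evaluated in cascade order: significance label, allele
    frequency (strictly below ``af_threshold`` in every population), gene
    list membership, manual-review flag, and — for VUS only — the 2-of-3
    predictor rule.
    """
    if not 0 < af_threshold <= 1:
        raise ValueError("af_threshold must be in (0, 1]")
    sig = v.clinical_significance
    if sig not in SIGNIFICANCE_VOCAB:
        logger.warning(
            "variant %s: unknown significance label %r", v.variant_id, sig
        )
        return Decision("excluded", REASON_VOCABULARY)
    if sig == "other":
        return Decision("excluded", REASON_SIGNIFICANCE)
    if v.max_af() >= af_threshold:   # "less than" is strict
        return Decision("excluded", REASON_AF)
    if v.gene not in genes:
        return Decision("excluded", REASON_GENE_LIST)
    if not v.review_pass:
        return Decision("excluded", REASON_REVIEW)
    if sig in PLP_LABELS:
        return Decision(RETAINED_PLP, None)
    if _predictor_votes(v) >= 2:
        return Decision(RETAINED_VUS, None)
    return Decision("excluded", REASON_PREDICTORS)


@dataclass
class CarrierTable:
    """Per-variant decisions plus derived per-patient carrier status."""

    decisions: pd.DataFrame   # patient_id, gene, status, reason per variant
    carriers: pd.Series       # patient_id -> bool

    @property
    def carrier_set(self) -> frozenset[str]:
        return frozenset(self.carriers.index[self.carriers])

    @property
    def n_carriers(self) -> int:
        return int(self.carriers.sum())


def apply_filter(
    variants: Iterable[GermlineVariant],
    genes: GeneList,
    af_threshold: float = 0.05,
    patient_ids: Iterable[str] | None = None,
) -> CarrierTable:
    """Run the cascade over a variant list and derive carrier status.

    ``patient_ids`` optionally fixes the patient universe so that patients
    with no germline record at all still appear (as non-carriers).
    """
    rows = []
    for v in variants:
        d = classify_variant(v, genes, af_threshold)
        rows.append({
            "patient_id": v.patient_id,
            "gene": v.gene,
            "variant_id": v.variant_id,
            "status": d.status,
            "reason": d.reason,
        })
    decisions = pd.DataFrame(
        rows, columns=["patient_id", "gene", "variant_id", "status", "reason"]
    )
    if patient_ids is not None:
        universe = pd.Index(list(patient_ids), name="patient_id")
    else:
        universe = pd.Index(sorted(decisions["patient_id"].unique()),
                            name="patient_id")
    retained = decisions[decisions["status"].isin((RETAINED_PLP, RETAINED_VUS))]
    carriers = pd.Series(False, index=universe, name="carrier")
    carriers.loc[carriers.index.intersection(retained["patient_id"])] = True
    return CarrierTable(decisions=decisions, carriers=carriers)


def carrier_proportion(table: CarrierTable, n_patients: int) -> float:
    """Fraction of patients carrying >= 1 retained variant."""
    if n_patients == 0:
        raise ValueError("n_patients must be positive")
    k = table.n_carriers
    if k > n_patients:
        raise ValueError(f"{k} carriers exceed {n_patients} patients")
    return k / n_patients


def compare_carrier_rates(k1: int, n1: int, k2: int, n2: int) -> float:
    """Two-sided Fisher exact p for carrier counts in two cohorts."""
    return fisher_exact_two_sided(k1, n1, k2, n2)


# ---------------------------------------------------------------------------
# I/O: germline TSV dialect, gene lists, minimal VCF
# ---------------------------------------------------------------------------

#: fixed columns of the germline TSV; any column starting with ``af_`` is
#: read as one population's allele frequency
GERMLINE_BASE_COLUMNS = [
    "patient_id", "gene", "clinical_significance",
    "cadd_phred", "polyphen", "sift", "review_pass",
]


def read_germline_tsv(path) -> list[GermlineVariant]:
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    missing = [c for c in GERMLINE_BASE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"germline table {path} missing columns {missing}")
    af_cols = [c for c in df.columns if c.startswith("af_")]
    out = []
    for _, r in df.iterrows():
        afs = {c[3:]: float(r[c]) for c in af_cols if pd.notna(r[c])}
        cadd = float(r["cadd_phred"]) if pd.notna(r["cadd_phred"]) else None
        out.append(GermlineVariant(
            patient_id=str(r["patient_id"]),
            gene=str(r["gene"]),
            clinical_significance=str(r["clinical_significance"]),
            af_by_population=afs,
            cadd_phred=cadd,
            polyphen=str(r["polyphen"]) if pd.notna(r["polyphen"]) else None,
            sift=str(r["sift"]) if pd.notna(r["sift"]) else None,
            review_pass=bool(r["review_pass"]),
            variant_id=str(r["variant_id"]) if "variant_id" in df.columns
            and pd.notna(r["variant_id"]) else None,
        ))
    return out


def write_germline_tsv(variants: Iterable[GermlineVariant], path) -> None:
    pops: list[str] = []
    rows = []
    variants = list(variants)
    for v in variants:
        for p in v.af_by_population:
            if p not in pops:
                pops.append(p)
    for v in variants:
        row = {
            "patient_id": v.patient_id,
            "gene": v.gene,
            "variant_id": v.variant_id,
            "clinical_significance": v.clinical_significance,
            "cadd_phred": v.cadd_phred,
            "polyphen": v.polyphen,
            "sift": v.sift,
            "review_pass": v.review_pass,
        }
        for p in pops:
            row[f"af_{p}"] = v.af_by_population.get(p, np.nan)
        rows.append(row)
    # %.17g round-trips doubles exactly through the text dialect
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False,
                              float_format="%.17g")


def read_gene_list(path, name: str | None = None) -> GeneList:
    """One gene symbol per line; blank lines and '#' comments ignored."""
    genes = set()
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line and not line.startswith("#"):
                genes.add(line)
    return GeneList(frozenset(genes), name=name or str(path))


DEFAULT_VCF_KEYMAP = {
    "gene": "GENE",
    "clinical_significance": "CLNSIG",
    "cadd_phred": "CADD_PHRED",
    "polyphen": "POLYPHEN",
    "sift": "SIFT",
    "af": "AF_POPS",          # comma-separated pop=freq pairs
    "review_pass": "REVIEW_PASS",
}


def read_germline_vcf(path, patient_id: str,
                      keymap: Mapping[str, str] | None = None
                      ) -> list[GermlineVariant]:
    """Minimal single-sample VCF reader; annotations pulled from INFO keys.

    ``keymap`` maps logical field names to INFO keys (see
    ``DEFAULT_VCF_KEYMAP``). Clinical-significance values may use ClinVar
    underscore style (``Likely_pathogenic``, ``Uncertain_significance``).
    """
    from cyvcf2 import VCF

    km = dict(DEFAULT_VCF_KEYMAP)
    if keymap:
        km.update(keymap)
    out = []
    for rec in VCF(str(path)):
        info = dict(rec.INFO)
        sig = str(info.get(km["clinical_significance"], "other"))
        sig = sig.replace("_", " ")
        afs = {}
        raw_af = info.get(km["af"])
        if raw_af:
            for pair in str(raw_af).split(","):
                pop, _, val = pair.partition("=")
                afs[pop] = float(val)
        cadd = info.get(km["cadd_phred"])
        pp = info.get(km["polyphen"])
        sift = info.get(km["sift"])
        out.append(GermlineVariant(
            patient_id=patient_id,
            gene=str(info.get(km["gene"], "")),
            clinical_significance=sig,
            af_by_population=afs,
            cadd_phred=float(cadd) if cadd is not None else None,
            polyphen=str(pp).replace("_", " ") if pp is not None else None,
            sift=str(sift) if sift is not None else None,
            review_pass=bool(int(info.get(km["review_pass"], 1))),
            variant_id=f"{rec.CHROM}:{rec.POS}:{rec.REF}>{rec.ALT[0]}",
        ))
    return out
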