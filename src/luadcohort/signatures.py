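"""SBS-96 mutational-signature catalogs, refitting and cohort contrasts.

A single-base substitution is classified by the mutated pyrimidine and its
immediate 5' and 3' flanking bases, giving 6 substitutions x 16 flank
combinations = 96 channels. Per-patient channel counts are refit against a
signature catalog (each signature a probability profile over the 96
channels) by non-negative least squares, and cohort-level comparisons use
the mean of per-patient signature *proportions* so that patients with high
mutational burden do not dominate the cohort summary.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import nnls

from .stats import bonferroni, fisher_exact_two_sided, mann_whitney_two_sided

logger = logging.getLogger(__name__)

__all__ = [
    "CHANNELS_96",
    "SUBSTITUTIONS",
    "canonicalize_snv",
    "build_catalog",
    "read_signature_catalog",
    "write_signature_catalog",
    "refit_exposures",
    "ExposureTable",
    "cohort_signature_summary",
    "compare_signature_between_cohorts",
    "signature_presence_test",
    "read_maf",
    "write_maf",
    "extract_context_from_fasta",
    "NONSILENT_CLASSES",
    "TMB_CLASSES",
]

_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}

#: the six pyrimidine-referenced substitutions, catalog-file order
SUBSTITUTIONS = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")

#: variant classes counted as nonsilent when collapsing to mutated-gene status
NONSILENT_CLASSES = frozenset(
    {"missense", "nonsense", "nonstop", "splice_site", "indel", "other"}
)

#: variant classes entering the tumor-mutational-burden numerator
TMB_CLASSES = frozenset({"missense", "nonsense", "nonstop", "splice_site"})

#: required columns of the tab-separated somatic mutation dialect (1-based pos)
MAF_COLUMNS = [
    "patient_id", "gene", "chrom", "pos", "ref", "alt",
    "variant_class", "context3",
]


def _build_channels() -> list[str]:
    chans = []
    for sub in SUBSTITUTIONS:
        for five in "ACGT":
            for three in "ACGT":
                chans.append(f"{five}[{sub}]{three}")
    return chans


#: the 96 channel labels, substitution-major order ("A[C>A]A" first)
CHANNELS_96: list[str] = _build_channels()
_CHANNEL_INDEX = {c: i for i, c in enumerate(CHANNELS_96)}


def _revcomp(seq: str) -> str:
    return "".join(_COMPLEMENT[b] for b in reversed(seq))


def canonicalize_snv(ref: str, alt: str, context3: str) -> str:
    """Map an SNV with its 3-mer context to one of the 96 channel labels.

    Substitutions whose reference base is a purine (A/G) are
    reverse-complemented so every channel is pyrimidine-referenced.

    Raises ``ValueError`` for ambiguous bases (N), non-SNVs, or a context
    whose middle base disagrees with ``ref``; callers counting mutation
    lists skip such records with a log entry.
    """
    ref, alt, context3 = ref.upper(), alt.upper(), context3.upper()
    if len(ref) != 1 or len(alt) != 1 or ref == alt:
        raise ValueError(f"not an SNV: {ref}>{alt}")
    if ref not in "ACGT" or alt not in "ACGT" or any(
        b not in "ACGT" for b in context3
    ):
        raise ValueError(f"ambiguous base in {ref}>{alt} {context3}")
    if len(context3) != 3 or context3[1] != ref:
        raise ValueError(f"context {context3} inconsistent with ref {ref}")
    if ref in "AG":
        context3 = _revcomp(context3)
        ref, alt = _COMPLEMENT[ref], _COMPLEMENT[alt]
    return f"{context3[0]}[{ref}>{alt}]{context3[2]}"


def _is_snv(ref: str, alt: str) -> bool:
    return (
        len(ref) == 1 and len(alt) == 1 and ref != alt
        and ref in "ACGT" and alt in "ACGT"
    )


def build_catalog(mutations: pd.DataFrame) -> pd.DataFrame:
    """Patient x 96-channel count matrix from a somatic mutation table.

    Only single-nucleotide variants are counted; indels and other non-SNV
    records are excluded, so each row sum equals that patient's SNV count.
    Records whose context cannot be canonicalized are skipped and logged.
    """
    counts: dict[str, np.ndarray] = {}
    skipped = 0
    for patient, ref, alt, ctx in zip(
        mutations["patient_id"], mutations["ref"],
        mutations["alt"], mutations["context3"],
    ):
        if not _is_snv(str(ref), str(alt)):
            continue
        try:
            chan = canonicalize_snv(str(ref), str(alt), str(ctx))
        except ValueError:
            skipped += 1
            continue
        row = counts.setdefault(str(patient), np.zeros(96, dtype=np.int64))
        row[_CHANNEL_INDEX[chan]] += 1
    if skipped:
        logger.warning("skipped %d SNVs with unusable context", skipped)
    if not counts:
        return pd.DataFrame(columns=CHANNELS_96, dtype=np.int64)
    mat = pd.DataFrame.from_dict(counts, orient="index", columns=CHANNELS_96)
    mat.index.name = "patient_id"
    return mat.sort_index()


# ---------------------------------------------------------------------------
# signature catalog I/O (COSMIC SBS text dialect)
# ---------------------------------------------------------------------------

def read_signature_catalog(path) -> pd.DataFrame:
    """Read a catalog in the COSMIC SBS text format.

    Tab-separated; first column ``Type`` holds channel labels like
    ``A[C>A]A``, remaining columns one probability profile per signature.
    Rows are reindexed into the package's canonical channel order; each
    column must be non-negative and sum to 1 within 1e-8.
    """
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    first = df.columns[0]
    df = df.set_index(first)
    missing = set(CHANNELS_96) - set(df.index)
    if missing:
        raise ValueError(f"catalog at {path} lacks channels: {sorted(missing)[:4]}...")
    df = df.loc[CHANNELS_96].astype(float)
    if (df.values < 0).any():
        raise ValueError("negative entries in signature catalog")
    sums = df.sum(axis=0)
    bad = sums[(sums - 1.0).abs() > 1e-8]
    if len(bad):
        raise ValueError(f"signature columns do not sum to 1: {dict(bad)}")
    df.index.name = "Type"
    return df


def write_signature_catalog(catalog: pd.DataFrame, path) -> None:
    catalog.to_csv(path, sep="\t", index=True, index_label="Type")


# ---------------------------------------------------------------------------
# exposure refitting
# ---------------------------------------------------------------------------

@dataclass
class ExposureTable:
    """Per-patient attributed mutation counts and derived proportions.

    ``exposures``: patients x K non-negative attributed counts (NNLS
    solution). ``proportions``: exposures normalized per patient; rows for
    patients with an all-zero channel catalog are NaN (undefined) and are
    excluded from cohort summaries.
    """

    exposures: pd.DataFrame
    proportions: pd.DataFrame

    @property
    def signatures(self) -> list[str]:
        return list(self.exposures.columns)

    def defined(self) -> pd.DataFrame:
        """Proportions restricted to patients with >= 1 attributed SNV."""
        return self.proportions.dropna(how="any")


def refit_exposures(catalog: pd.DataFrame, sigs: pd.DataFrame) -> ExposureTable:
    """Refit per-patient signature exposures by non-negative least squares.

    For each patient row m solves ``min ||m - S e||_2 s.t. e >= 0`` where S
    is the channels x K signature matrix. No sparsity heuristics are
    applied: the solution is the plain NNLS optimum, deterministic in the
    inputs.
    """
    if list(catalog.columns) != CHANNELS_96:
        raise ValueError("catalog channels not aligned to the 96 canonical labels")
    s = sigs.to_numpy(dtype=float)
    expo = np.zeros((len(catalog), s.shape[1]))
    for i, row in enumerate(catalog.to_numpy(dtype=float)):
        if row.sum() == 0:
            continue
        expo[i], _ = nnls(s, row)
    exposures = pd.DataFrame(expo, index=catalog.index, columns=sigs.columns)
    totals = exposures.sum(axis=1)
    props = exposures.div(totals, axis=0)
    props[totals == 0] = np.nan
    return ExposureTable(exposures=exposures, proportions=props)


def cohort_signature_summary(table: ExposureTable) -> pd.Series:
    """Mean of per-patient signature proportions across the cohort.

    Patients with undefined proportions (zero attributed SNVs) are excluded
    from the mean. The result sums to 1 across signatures. Using the mean
    of *proportions* rather than pooled counts keeps high-burden patients
    from dominating the cohort profile.
    """
    defined = table.defined()
    if defined.empty:
        raise ValueError("no patient with defined signature proportions")
    return defined.mean(axis=0)


def compare_signature_between_cohorts(
    props_a: Sequence[float],
    props_b: Sequence[float],
    m_tests: int = 1,
) -> tuple[float, float]:
    """Two-sided Wilcoxon-Mann-Whitney on per-patient proportions of one
    signature in two cohorts; returns (raw p, Bonferroni-adjusted p)."""
    raw = mann_whitney_two_sided(props_a, props_b)
    return raw, bonferroni(raw, m_tests)


def signature_presence_test(
    present_a: int, n_a: int, present_b: int, n_b: int
) -> float:
    """Two-sided Fisher exact p for a signature's presence rate in two
    cohorts (presence = attributed proportion above a caller-chosen
    epsilon; counts are supplied already thresholded)."""
    return fisher_exact_two_sided(present_a, n_a, present_b, n_b)


def presence_counts(
    proportions: pd.Series, presence_epsilon: float = 0.0
) -> tuple[int, int]:
    """(number present, number evaluable) for one signature's per-patient
    proportions; NaN rows (undefined patients) are not evaluable."""
    defined = proportions.dropna()
    return int((defined > presence_epsilon).sum()), int(len(defined))


# ---------------------------------------------------------------------------
# somatic table I/O
# ---------------------------------------------------------------------------

def read_maf(path) -> pd.DataFrame:
    """Read the MAF-like tab-separated somatic dialect.

    Required columns: patient_id, gene, chrom, pos (1-based), ref, alt,
    variant_class, context3. Extra columns pass through untouched.
    """
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "context3": str})
    missing = [c for c in MAF_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"somatic table {path} missing columns {missing}")
    return df


def write_maf(mutations: pd.DataFrame, path) -> None:
    mutations.to_csv(path, sep="\t", index=False)


def extract_context_from_fasta(
    fasta_path, chrom: str, pos: int
) -> str:
    """3-mer reference context around a 1-based position, uppercase, on the
    reference strand. For real somatic tables that lack a context column."""
    from pyfaidx import Fasta

    fa = Fasta(str(fasta_path))
    seq = fa[chrom][pos - 2 : pos + 1]
    return str(seq).upper()
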