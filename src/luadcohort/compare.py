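"""Per-gene somatic frequency contrasts and tumor mutational burden.

Frequencies count mutated *patients*: a patient with several mutations in a
gene contributes once to that gene's numerator. TMB is the count of
nonsynonymous mutations (splice site, missense, nonsense, nonstop) divided
by the captured exome size in megabases (default 37.5 Mb).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .signatures import NONSILENT_CLASSES, TMB_CLASSES
from .stats import bonferroni, fisher_exact_two_sided

__all__ = [
    "gene_frequency_table",
    "compare_gene_frequencies",
    "compute_tmb",
    "TmbResult",
    "DEFAULT_CAPTURE_MB",
]

DEFAULT_CAPTURE_MB = 37.5


def gene_frequency_table(
    somatic: pd.DataFrame,
    n_patients: int,
    include_silent: bool = False,
) -> pd.DataFrame:
    """Per-gene mutated-patient counts and fractions.

    Silent mutations are excluded from "mutated" status by default, the
    usual driver-frequency convention; pass ``include_silent=True`` to
    count every variant class.
    """
    if n_patients <= 0:
        raise ValueError("n_patients must be positive")
    df = somatic
    if not include_silent:
        df = df[df["variant_class"].isin(NONSILENT_CLASSES)]
    mutated = df.groupby("gene")["patient_id"].nunique().astype(int)
    out = pd.DataFrame({
        "mutated": mutated,
        "total": n_patients,
        "frequency": mutated / n_patients,
    })
    out.index.name = "gene"
    return out.sort_index()


def compare_gene_frequencies(
    counts_a: pd.DataFrame,
    counts_b: pd.DataFrame,
    correction: str = "bonferroni",
) -> pd.DataFrame:
    """Two-sided Fisher exact test per gene between two cohorts.

    Inputs are frames with ``mutated``/``total`` columns indexed by gene
    (the output of :func:`gene_frequency_table`). A gene present in only
    one cohort is compared against 0 / that cohort's total, flagged in the
    ``one_sided_presence`` column. ``correction`` is ``"bonferroni"`` over
    the genes tested or ``"none"`` (to reproduce single-gene quoted
    p-values).
    """
    if correction not in ("bonferroni", "none"):
        raise ValueError("correction must be 'bonferroni' or 'none'")
    total_a = int(counts_a["total"].max()) if len(counts_a) else 0
    total_b = int(counts_b["total"].max()) if len(counts_b) else 0
    genes = sorted(set(counts_a.index) | set(counts_b.index))
    rows = []
    for g in genes:
        ka = int(counts_a.loc[g, "mutated"]) if g in counts_a.index else 0
        na = int(counts_a.loc[g, "total"]) if g in counts_a.index else total_a
        kb = int(counts_b.loc[g, "mutated"]) if g in counts_b.index else 0
        nb = int(counts_b.loc[g, "total"]) if g in counts_b.index else total_b
        p = fisher_exact_two_sided(ka, na, kb, nb)
        rows.append({
            "gene": g,
            "mutated_a": ka, "total_a": na,
            "mutated_b": kb, "total_b": nb,
            "freq_a": ka / na if na else np.nan,
            "freq_b": kb / nb if nb else np.nan,
            "freq_diff": (ka / na if na else np.nan)
                         - (kb / nb if nb else np.nan),
            "p_raw": p,
            "one_sided_presence": (g not in counts_a.index)
                                  or (g not in counts_b.index),
        })
    out = pd.DataFrame(rows).set_index("gene")
    m = len(out)
    if correction == "bonferroni":
        out["p_adjusted"] = [bonferroni(p, m) for p in out["p_raw"]]
    else:
        out["p_adjusted"] = out["p_raw"]
    return out


@dataclass
class TmbResult:
    per_patient: pd.DataFrame   # patient_id-indexed: count, capture_mb, tmb
    median: float


def compute_tmb(
    somatic: pd.DataFrame,
    capture_mb: float = DEFAULT_CAPTURE_MB,
    patient_ids=None,
) -> TmbResult:
    """Tumor mutational burden per patient plus the cohort median.

    Counts records with variant_class in {missense, nonsense, nonstop,
    splice_site}; silent and indel records are excluded. ``patient_ids``
    optionally fixes the patient universe so mutation-free patients appear
    with TMB 0. The median is the standard midpoint-of-order-statistics
    definition.
    """
    if capture_mb <= 0:
        raise ValueError("capture_mb must be positive")
    qualifying = somatic[somatic["variant_class"].isin(TMB_CLASSES)]
    counts = qualifying.groupby("patient_id").size()
    if patient_ids is not None:
        counts = counts.reindex(list(patient_ids), fill_value=0)
    else:
        counts = counts.reindex(sorted(somatic["patient_id"].unique()),
                                fill_value=0)
    per = pd.DataFrame({
        "count": counts.astype(int),
        "capture_mb": capture_mb,
        "tmb": counts / capture_mb,
    })
    per.index.name = "patient_id"
    return TmbResult(per_patient=per, median=float(per["tmb"].median()))
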