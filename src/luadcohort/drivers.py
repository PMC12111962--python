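"""Consensus driver-gene candidacy with empirical bootstrap nulls.

Three selection-detection tools each rank every gene; a gene is a consensus
candidate when it sits in the top decile of at least two of the three
rankings. Because small cohorts make the individual rankings noisy, the
evidence is assessed against resampling nulls: the size of the >=2-of-3
joint set versus random gene sets of the same sizes, the overlap of two
cohorts' joint sets versus random subsets of the gene universe, and a
subsampling experiment that measures how much of the apparent cohort
specificity is a sample-size artifact.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import poisson

from .signatures import NONSILENT_CLASSES
from .stats import empirical_pvalue

__all__ = [
    "RankingTable",
    "rank_from_scores",
    "read_ranking_tsv",
    "write_ranking_tsv",
    "top_decile",
    "joint_detection",
    "ConsensusResult",
    "multi_tool_coincidence_test",
    "OverlapTestResult",
    "cross_cohort_overlap_test",
    "recurrence_ranker",
    "SubsampleBiasResult",
    "subsample_bias_test",
    "null_summary",
]

_SUBSET_CHUNK = 4000   # resamples per vectorized chunk (memory bound)


@dataclass
class RankingTable:
    """One tool's per-gene ordering: rank 1 is the strongest candidate."""

    tool: str
    table: pd.DataFrame   # columns gene, score, rank

    def __post_init__(self):
        t = self.table
        need = {"gene", "score", "rank"}
        if not need.issubset(t.columns):
            raise ValueError(f"ranking table needs columns {sorted(need)}")
        if t["gene"].duplicated().any():
            dup = t.loc[t["gene"].duplicated(), "gene"].iloc[0]
            raise ValueError(f"duplicate gene {dup!r} in ranking {self.tool}")
        ranks = np.sort(t["rank"].to_numpy())
        if not np.array_equal(ranks, np.arange(1, len(t) + 1)):
            raise ValueError(
                f"ranks in {self.tool} are not a permutation of 1..{len(t)}"
            )

    @property
    def genes(self) -> frozenset[str]:
        return frozenset(self.table["gene"])

    def __len__(self) -> int:
        return len(self.table)


def rank_from_scores(
    scores: Mapping[str, float] | pd.Series,
    tool: str,
    higher_is_better: bool = True,
) -> RankingTable:
    """Build a RankingTable from per-gene scores.

    Ties are broken deterministically by lexicographic gene symbol, so the
    lexicographically smaller symbol gets the better rank.
    """
    s = pd.Series(scores, dtype=float)
    key = -s if higher_is_better else s
    order = pd.DataFrame({"gene": s.index, "key": key.to_numpy(),
                          "score": s.to_numpy()})
    order = order.sort_values(["key", "gene"], kind="mergesort")
    order["rank"] = np.arange(1, len(order) + 1)
    return RankingTable(tool, order[["gene", "score", "rank"]]
                        .reset_index(drop=True))


def read_ranking_tsv(path) -> RankingTable:
    """Read a ranking TSV (columns tool, gene, score, rank); validates the
    rank-permutation property."""
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    need = ["tool", "gene", "score", "rank"]
    missing = [c for c in need if c not in df.columns]
    if missing:
        raise ValueError(f"ranking table {path} missing columns {missing}")
    tools = df["tool"].unique()
    if len(tools) != 1:
        raise ValueError(f"expected one tool per file, found {list(tools)}")
    return RankingTable(str(tools[0]), df[["gene", "score", "rank"]])


def write_ranking_tsv(ranking: RankingTable, path) -> None:
    out = ranking.table.copy()
    out.insert(0, "tool", ranking.tool)
    out.to_csv(path, sep="\t", index=False)


def top_decile(ranking: RankingTable, fraction: float = 0.10) -> frozenset[str]:
    """The best-ranked ceil(fraction * G) genes of one tool."""
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    g = len(ranking)
    if g == 0:
        raise ValueError("empty ranking table")
    k = math.ceil(fraction * g)
    top = ranking.table.loc[ranking.table["rank"] <= k, "gene"]
    return frozenset(top)


def joint_detection(
    sets: Sequence[Iterable[str]], min_tools: int = 2
) -> frozenset[str]:
    """Genes appearing in at least ``min_tools`` of the given sets."""
    if not 1 <= min_tools <= len(sets):
        raise ValueError("min_tools must be between 1 and the number of sets")
    counts: dict[str, int] = {}
    for s in sets:
        for gene in set(s):
            counts[gene] = counts.get(gene, 0) + 1
    return frozenset(g for g, c in counts.items() if c >= min_tools)


def null_summary(null_stats: np.ndarray) -> dict:
    """Count, mean and quantiles of a null distribution, for JSON reports."""
    qs = np.quantile(null_stats, [0.05, 0.25, 0.5, 0.75, 0.95])
    return {
        "count": int(len(null_stats)),
        "mean": float(np.mean(null_stats)),
        "quantiles": {
            "q05": float(qs[0]), "q25": float(qs[1]), "q50": float(qs[2]),
            "q75": float(qs[3]), "q95": float(qs[4]),
        },
    }


def _random_membership(
    rng: np.random.Generator, b: int, universe_size: int, subset_size: int
) -> np.ndarray:
    """Boolean (b, universe_size) membership of b uniform random subsets."""
    u = rng.random((b, universe_size))
    idx = np.argpartition(u, subset_size - 1, axis=1)[:, :subset_size]
    member = np.zeros((b, universe_size), dtype=bool)
    np.put_along_axis(member, idx, True, axis=1)
    return member


@dataclass
class ConsensusResult:
    decile_sets: dict[str, frozenset[str]]
    joint_set: frozenset[str]
    observed_stat: int
    null_stats: np.ndarray
    p_empirical: float
    B: int
    seed: int

    def to_report(self) -> dict:
        return {
            "tools": sorted(self.decile_sets),
            "decile_sizes": {t: len(s) for t, s in
                             sorted(self.decile_sets.items())},
            "joint_set": sorted(self.joint_set),
            "observed_stat": self.observed_stat,
            "p_empirical": self.p_empirical,
            "B": self.B,
            "seed": self.seed,
            "null": null_summary(self.null_stats),
        }


def multi_tool_coincidence_test(
    rankings: Sequence[RankingTable],
    fraction: float = 0.10,
    min_tools: int = 2,
    B: int = 50_000,
    seed: int = 0,
) -> ConsensusResult:
    """Is the >=2-of-3 top-decile joint set larger than chance?

    The null treats each tool's decile as an independent uniform random
    gene set of the same size drawn from the shared universe; for each of B
    resamples the joint-set size is recomputed, and the empirical p-value
    uses the add-one convention (1 + exceedances) / (B + 1).
    """
    universes = {r.genes for r in rankings}
    if len(universes) != 1:
        raise ValueError("rankings must share one gene universe")
    universe = sorted(universes.pop())
    n = len(universe)
    deciles = {r.tool: top_decile(r, fraction) for r in rankings}
    joint = joint_detection(list(deciles.values()), min_tools)
    observed = len(joint)
    sizes = [len(s) for s in deciles.values()]

    rng = np.random.default_rng(seed)
    null = np.empty(B, dtype=np.int64)
    done = 0
    while done < B:
        b = min(_SUBSET_CHUNK, B - done)
        hits = np.zeros((b, n), dtype=np.int8)
        for size in sizes:
            hits += _random_membership(rng, b, n, size)
        null[done:done + b] = (hits >= min_tools).sum(axis=1)
        done += b
    p = empirical_pvalue(observed, null)
    return ConsensusResult(
        decile_sets=deciles, joint_set=joint, observed_stat=observed,
        null_stats=null, p_empirical=p, B=B, seed=seed,
    )


@dataclass
class OverlapTestResult:
    set_a: frozenset[str]
    set_b: frozenset[str]
    universe: frozenset[str]
    observed_overlap: int
    expected_overlap: float   # analytic |A||B|/|U|
    null_stats: np.ndarray
    p_empirical: float
    B: int
    seed: int

    def to_report(self) -> dict:
        return {
            "size_a": len(self.set_a), "size_b": len(self.set_b),
            "universe_size": len(self.universe),
            "observed_overlap": self.observed_overlap,
            "expected_overlap": self.expected_overlap,
            "p_empirical": self.p_empirical,
            "B": self.B, "seed": self.seed,
            "null": null_summary(self.null_stats),
        }


def cross_cohort_overlap_test(
    set_a: Iterable[str],
    set_b: Iterable[str],
    universe: Iterable[str],
    B: int = 50_000,
    seed: int = 0,
) -> OverlapTestResult:
    """Is the overlap of two cohorts' candidate sets larger than chance?

    Null: independently draw random subsets of sizes |A| and |B| from the
    universe and record their intersection size. That intersection is
    exactly hypergeometric(|U|, |A|, |B|), so the null is sampled directly
    from that distribution; the analytic expectation |A||B|/|U| is reported
    alongside.
    """
    set_a, set_b = frozenset(set_a), frozenset(set_b)
    universe = frozenset(universe)
    if not set_a <= universe or not set_b <= universe:
        raise ValueError("candidate sets must be contained in the universe")
    observed = len(set_a & set_b)
    n = len(universe)
    rng = np.random.default_rng(seed)
    null = rng.hypergeometric(len(set_a), n - len(set_a), len(set_b), size=B)
    p = empirical_pvalue(observed, null)
    return OverlapTestResult(
        set_a=set_a, set_b=set_b, universe=universe,
        observed_overlap=observed,
        expected_overlap=len(set_a) * len(set_b) / n,
        null_stats=null, p_empirical=p, B=B, seed=seed,
    )


# ---------------------------------------------------------------------------
# stand-in recurrence ranker and the sample-size bias experiment
# ---------------------------------------------------------------------------

def _nonsilent_gene_counts(
    somatic: pd.DataFrame, genes: Sequence[str]
) -> pd.Series:
    mask = somatic["variant_class"].isin(NONSILENT_CLASSES)
    counts = somatic.loc[mask].groupby("gene").size()
    return counts.reindex(genes, fill_value=0).astype(np.int64)


def _poisson_recurrence_ranking(
    gene_counts: pd.Series, gene_lengths: pd.Series, tool: str
) -> RankingTable:
    lengths = gene_lengths.reindex(gene_counts.index)
    if lengths.isna().any():
        missing = lengths.index[lengths.isna()][0]
        raise ValueError(f"gene {missing!r} has no length")
    if (lengths <= 0).any():
        raise ValueError("gene lengths must be positive")
    total = gene_counts.sum()
    rate = total / lengths.sum()           # cohort nonsilent rate per base
    mu = rate * lengths.to_numpy(dtype=float)
    k = gene_counts.to_numpy()
    # P(X >= k) under Poisson(mu); k = 0 gives 1
    score = poisson.sf(k - 1, mu)
    return rank_from_scores(
        pd.Series(score, index=gene_counts.index), tool,
        higher_is_better=False,
    )


def recurrence_ranker(
    somatic: pd.DataFrame,
    gene_lengths: Mapping[str, float] | pd.Series,
    tool: str = "recurrence",
) -> RankingTable:
    """Rank genes by the upper-tail Poisson probability of their nonsilent
    mutation count.

    Each gene's expected count is the cohort-wide nonsilent rate per coding
    base times its coding length; genes are ranked ascending by
    P(X >= observed) so that unexpectedly recurrent genes come first, ties
    broken lexicographically. This is the pluggable stand-in for external
    selection-detection tools.
    """
    gene_lengths = pd.Series(gene_lengths, dtype=float)
    mask = somatic["variant_class"].isin(NONSILENT_CLASSES)
    unmeasured = set(somatic.loc[mask, "gene"]) - set(gene_lengths.index)
    if unmeasured:
        raise ValueError(
            f"mutated gene {sorted(unmeasured)[0]!r} has no length")
    counts = _nonsilent_gene_counts(somatic, list(gene_lengths.index))
    return _poisson_recurrence_ranking(counts, gene_lengths, tool)


@dataclass
class SubsampleBiasResult:
    subsample_size: int
    intersections: np.ndarray          # per-resample |decile ∩ reference list|
    proportion_nonreference: np.ndarray
    B: int
    seed: int
    observed_quantile: float | None = None   # of a supplied observed fraction

    def to_report(self) -> dict:
        rep = {
            "subsample_size": self.subsample_size,
            "B": self.B, "seed": self.seed,
            "intersections": null_summary(self.intersections),
            "proportion_nonreference":
                null_summary(self.proportion_nonreference),
        }
        if self.observed_quantile is not None:
            rep["observed_quantile"] = self.observed_quantile
        return rep


RankerFn = Callable[[pd.Series, pd.Series], RankingTable]


def subsample_bias_test(
    reference_somatic: pd.DataFrame,
    reference_driver_list: Iterable[str],
    gene_lengths: Mapping[str, float] | pd.Series,
    m: int = 25,
    B: int = 200,
    seed: int = 0,
    fraction: float = 0.10,
    ranker: RankerFn | None = None,
    observed_nonreference_fraction: float | None = None,
) -> SubsampleBiasResult:
    """How much driver-list overlap does an m-patient cohort recover?

    For each of B resamples, draw m patients without replacement from the
    reference cohort, re-rank genes on their mutations alone, take the top
    decile, and record (i) its intersection size with the reference driver
    list and (ii) the fraction of decile genes outside that list. The
    resulting distributions quantify the sample-size effect; an observed
    non-reference fraction from a query cohort can be placed on the null as
    a quantile.

    ``ranker`` maps (per-gene nonsilent counts, gene lengths) to a
    RankingTable; the default is the Poisson recurrence ranker.
    """
    gene_lengths = pd.Series(gene_lengths, dtype=float)
    patients = np.asarray(sorted(reference_somatic["patient_id"].unique()))
    if m >= len(patients):
        raise ValueError(
            f"subsample size {m} must be below the cohort size {len(patients)}"
        )
    ref_set = frozenset(reference_driver_list)
    # per-patient x per-gene nonsilent count matrix, computed once
    mask = reference_somatic["variant_class"].isin(NONSILENT_CLASSES)
    pivot = (
        reference_somatic.loc[mask]
        .groupby(["patient_id", "gene"]).size().unstack(fill_value=0)
        .reindex(index=patients, columns=gene_lengths.index, fill_value=0)
    )
    counts_matrix = pivot.to_numpy(dtype=np.int64)

    if ranker is None:
        def ranker(counts: pd.Series, lengths: pd.Series) -> RankingTable:
            return _poisson_recurrence_ranking(counts, lengths, "recurrence")

    rng = np.random.default_rng(seed)
    inter = np.empty(B, dtype=np.int64)
    nonref = np.empty(B, dtype=float)
    for i in range(B):
        pick = rng.choice(len(patients), size=m, replace=False)
        counts = pd.Series(counts_matrix[pick].sum(axis=0),
                           index=gene_lengths.index)
        ranking = ranker(counts, gene_lengths)
        decile = top_decile(ranking, fraction)
        inter[i] = len(decile & ref_set)
        nonref[i] = 1.0 - inter[i] / len(decile)
    quantile = None
    if observed_nonreference_fraction is not None:
        quantile = float(
            np.mean(nonref <= observed_nonreference_fraction)
        )
    return SubsampleBiasResult(
        subsample_size=m, intersections=inter,
        proportion_nonreference=nonref, B=B, seed=seed,
        observed_quantile=quantile,
    )
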