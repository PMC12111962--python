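"""Configuration-driven orchestration of the full analysis.

Stages run in dependency order — simulate, germline, signatures, drivers,
compare — on either synthetic cohorts (a ``simulate`` block in the config)
or user-supplied tables. All randomness flows from one master seed; each
randomized stage consumes a named child seed derived deterministically from
it, and every child seed is echoed in the run report so any stage can be
re-run in isolation. The report is a JSON-serializable dict that
round-trips losslessly and is byte-identical across runs with the same
config and seed.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .compare import compare_gene_frequencies, compute_tmb, gene_frequency_table
from .drivers import (
    cross_cohort_overlap_test,
    joint_detection,
    multi_tool_coincidence_test,
    read_ranking_tsv,
    subsample_bias_test,
    top_decile,
)
from .germline import (
    apply_filter,
    carrier_proportion,
    compare_carrier_rates,
    read_germline_tsv,
    read_gene_list,
    GeneList,
)
from .signatures import (
    build_catalog,
    cohort_signature_summary,
    compare_signature_between_cohorts,
    presence_counts,
    read_maf,
    read_signature_catalog,
    refit_exposures,
    signature_presence_test,
)
from .synthetic import (
    SimConfig,
    generate_cohort,
    generate_rankings,
    load_bundled_catalog,
    write_cohort,
)

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "PipelineError", "run_pipeline", "write_report"]

STAGES = ("simulate", "germline", "signatures", "drivers", "compare")

#: fixed order in which named child seeds are derived from the master seed
CHILD_SEED_NAMES = (
    "simulate_query", "simulate_reference",
    "drivers_coincidence", "drivers_overlap", "drivers_subsample",
)


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r}: {message}")
        self.stage = stage


@dataclass
class Thresholds:
    af_threshold: float = 0.05
    fraction: float = 0.10
    min_tools: int = 2
    B: int = 50_000
    capture_mb: float = 37.5
    presence_epsilon: float = 0.0
    correction: str = "bonferroni"
    subsample_m: int = 25
    subsample_B: int = 200

    def __post_init__(self):
        if not 0 < self.af_threshold <= 1:
            raise ValueError("af_threshold must be in (0, 1]")
        if not 0 < self.fraction <= 1:
            raise ValueError("fraction must be in (0, 1]")
        if self.B < 1 or self.subsample_B < 1:
            raise ValueError("resample counts must be positive")


@dataclass
class RunConfig:
    """Validated run configuration (YAML schema version 1)."""

    seed: int = 0
    outdir: str = "luadcohort_out"
    stages: dict = field(default_factory=lambda: {s: True for s in STAGES})
    simulate: dict | None = None       # {"query": {...}, "reference": {...}}
    inputs: dict = field(default_factory=dict)
    thresholds: Thresholds = field(default_factory=Thresholds)
    catalog: str = "bundled"
    schema_version: int = 1

    @classmethod
    def from_dict(cls, d: Mapping) -> "RunConfig":
        d = dict(d)
        th = d.pop("thresholds", {}) or {}
        stages = {s: True for s in STAGES}
        stages.update(d.pop("stages", {}) or {})
        unknown = set(stages) - set(STAGES)
        if unknown:
            raise ValueError(f"unknown stages in config: {sorted(unknown)}")
        cfg = cls(stages=stages, thresholds=Thresholds(**th), **d)
        if cfg.simulate is None and cfg.stages.get("simulate"):
            cfg.stages["simulate"] = False
        return cfg

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})


def _child_seeds(master: int) -> dict[str, int]:
    state = np.random.SeedSequence(master).generate_state(len(CHILD_SEED_NAMES))
    return {name: int(s % (2**31)) for name, s in zip(CHILD_SEED_NAMES, state)}


def _json_safe(obj):
    if isinstance(obj, dict):
        return {str(k): _json_safe(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple, set, frozenset)):
        items = list(obj)
        if isinstance(obj, (set, frozenset)):
            items = sorted(items)
        return [_json_safe(v) for v in items]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return [_json_safe(v) for v in obj.tolist()]
    return obj


def write_report(report: dict, path) -> None:
    """Serialize the run report deterministically (sorted keys, fixed
    separators) so identical runs are byte-identical."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(_json_safe(report), fh, indent=2, sort_keys=True)
        fh.write("\n")


# ---------------------------------------------------------------------------
# stage implementations
# ---------------------------------------------------------------------------

@dataclass
class _RunState:
    """In-memory handoff between stages."""

    sig_catalog: pd.DataFrame | None = None
    query_somatic: pd.DataFrame | None = None
    query_patients: list[str] | None = None
    query_germline: list | None = None
    query_rankings: list | None = None
    query_gene_lengths: pd.Series | None = None
    gene_list: GeneList | None = None
    ref_somatic: pd.DataFrame | None = None
    ref_patients: list[str] | None = None
    ref_germline: list | None = None
    ref_rankings: list | None = None
    ref_gene_lengths: pd.Series | None = None
    query_truth = None
    ref_truth = None


def _rel(path, outdir: Path) -> str:
    return str(Path(path).relative_to(outdir))


def _load_catalog(config: RunConfig) -> pd.DataFrame:
    if config.catalog == "bundled":
        return load_bundled_catalog()
    return read_signature_catalog(config.catalog)


def _stage_simulate(config: RunConfig, state: _RunState, seeds: dict,
                    outdir: Path) -> dict:
    block = config.simulate or {}
    if "query" not in block:
        raise PipelineError("simulate", "simulate block needs a 'query' entry")
    rep: dict = {}
    for role in ("query", "reference"):
        if role not in block or block[role] is None:
            continue
        sub = dict(block[role])
        sub.setdefault("seed", seeds[f"simulate_{role}"])
        sim = SimConfig.from_dict(sub)
        cohort = generate_cohort(sim, state.sig_catalog)
        rankings = generate_rankings(cohort)
        paths = write_cohort(cohort, outdir / "sim" / role, rankings,
                             relative_to=outdir)
        if role == "query":
            state.query_somatic = cohort.somatic
            state.query_patients = cohort.patient_ids
            state.query_germline = cohort.germline
            state.query_rankings = rankings
            state.query_gene_lengths = sim.lengths_series()
            state.query_truth = cohort.truth
            state.gene_list = GeneList(frozenset(sim.susceptibility_genes))
        else:
            state.ref_somatic = cohort.somatic
            state.ref_patients = cohort.patient_ids
            state.ref_germline = cohort.germline
            state.ref_rankings = rankings
            state.ref_gene_lengths = sim.lengths_series()
            state.ref_truth = cohort.truth
        rep[role] = {
            "seed": sim.seed,
            "n_patients": sim.n_patients,
            "n_somatic_records": int(len(cohort.somatic)),
            "n_germline_records": len(cohort.germline),
            "n_planted_drivers": len(cohort.truth.drivers),
            "n_planted_carriers": len(cohort.truth.carriers),
            "paths": paths,
        }
    return rep


def _load_inputs(config: RunConfig, state: _RunState) -> None:
    inp = config.inputs
    if state.query_somatic is None and "somatic" in inp:
        state.query_somatic = read_maf(inp["somatic"])
        state.query_patients = sorted(
            state.query_somatic["patient_id"].unique())
    if state.query_germline is None and "germline" in inp:
        state.query_germline = read_germline_tsv(inp["germline"])
    if state.gene_list is None and "gene_list" in inp:
        state.gene_list = read_gene_list(inp["gene_list"])
    if state.query_rankings is None and "rankings" in inp:
        state.query_rankings = [read_ranking_tsv(p) for p in inp["rankings"]]
    if state.ref_somatic is None and "reference_somatic" in inp:
        state.ref_somatic = read_maf(inp["reference_somatic"])
        state.ref_patients = sorted(state.ref_somatic["patient_id"].unique())
    if state.ref_rankings is None and "reference_rankings" in inp:
        state.ref_rankings = [read_ranking_tsv(p)
                              for p in inp["reference_rankings"]]
    if "metadata" in inp and state.query_patients is None:
        meta = pd.read_csv(inp["metadata"], sep="\t")
        state.query_patients = list(meta["patient_id"])


def _stage_germline(config: RunConfig, state: _RunState, outdir: Path,
                    warnings: list) -> dict:
    if state.query_germline is None:
        raise PipelineError("germline", "no germline variant table available")
    if state.gene_list is None:
        raise PipelineError("germline", "no susceptibility gene list available")
    th = config.thresholds
    table = apply_filter(state.query_germline, state.gene_list,
                         th.af_threshold, patient_ids=state.query_patients)
    n = len(table.carriers)
    prop = carrier_proportion(table, n)
    rep = {
        "n_patients": n,
        "n_carriers": table.n_carriers,
        "carrier_proportion": prop,
        "decision_counts": {
            k: int(v) for k, v in
            table.decisions["status"].value_counts().sort_index().items()
        },
    }
    ref_counts = config.inputs.get("reference_carrier_counts")
    if state.ref_germline is not None:
        ref_table = apply_filter(state.ref_germline, state.gene_list,
                                 th.af_threshold,
                                 patient_ids=state.ref_patients)
        ref_counts = (ref_table.n_carriers, len(ref_table.carriers))
    if ref_counts is not None:
        k2, n2 = int(ref_counts[0]), int(ref_counts[1])
        rep["reference"] = {
            "n_carriers": k2, "n_patients": n2,
            "carrier_proportion": k2 / n2 if n2 else None,
            "fisher_p": compare_carrier_rates(
                table.n_carriers, n, k2, n2),
        }
    out = outdir / "germline_decisions.tsv"
    outdir.mkdir(parents=True, exist_ok=True)
    table.decisions.to_csv(out, sep="\t", index=False)
    rep["decisions_path"] = _rel(out, outdir)
    return rep


def _stage_signatures(config: RunConfig, state: _RunState, outdir: Path,
                      warnings: list) -> dict:
    if state.query_somatic is None:
        raise PipelineError("signatures", "no somatic mutation table available")
    th = config.thresholds
    sigs = state.sig_catalog
    cat_q = build_catalog(state.query_somatic)
    expo_q = refit_exposures(cat_q, sigs)
    rep = {
        "n_signatures": sigs.shape[1],
        "query_mean_proportions": {
            s: float(v) for s, v in cohort_signature_summary(expo_q).items()
        },
    }
    outdir.mkdir(parents=True, exist_ok=True)
    expo_q.proportions.to_csv(outdir / "query_signature_proportions.tsv",
                              sep="\t")
    rep["query_proportions_path"] = "query_signature_proportions.tsv"
    if state.ref_somatic is not None:
        cat_r = build_catalog(state.ref_somatic)
        expo_r = refit_exposures(cat_r, sigs)
        rep["reference_mean_proportions"] = {
            s: float(v) for s, v in cohort_signature_summary(expo_r).items()
        }
        m = sigs.shape[1]
        contrasts = {}
        for s in sigs.columns:
            a = expo_q.defined()[s].to_numpy()
            b = expo_r.defined()[s].to_numpy()
            raw, adj = compare_signature_between_cohorts(a, b, m_tests=m)
            ka, na = presence_counts(expo_q.proportions[s],
                                     th.presence_epsilon)
            kb, nb = presence_counts(expo_r.proportions[s],
                                     th.presence_epsilon)
            contrasts[s] = {
                "mww_p_raw": raw, "mww_p_bonferroni": adj,
                "present_query": ka, "n_query": na,
                "present_reference": kb, "n_reference": nb,
                "presence_fisher_p": signature_presence_test(ka, na, kb, nb),
            }
        rep["contrasts"] = contrasts
        rep["m_tests"] = m
    return rep


def _stage_drivers(config: RunConfig, state: _RunState, seeds: dict,
                   outdir: Path, warnings: list) -> dict:
    if state.query_rankings is None:
        raise PipelineError("drivers", "no ranking tables available")
    th = config.thresholds
    cons = multi_tool_coincidence_test(
        state.query_rankings, fraction=th.fraction, min_tools=th.min_tools,
        B=th.B, seed=seeds["drivers_coincidence"],
    )
    rep = {"coincidence": cons.to_report()}
    if state.ref_rankings is not None:
        ref_joint = joint_detection(
            [top_decile(r, th.fraction) for r in state.ref_rankings],
            th.min_tools,
        )
        universe = frozenset.union(*(r.genes for r in state.query_rankings))
        ref_universe = frozenset.union(*(r.genes for r in state.ref_rankings))
        shared_universe = universe & ref_universe
        overlap = cross_cohort_overlap_test(
            cons.joint_set & shared_universe, ref_joint & shared_universe,
            shared_universe, B=th.B, seed=seeds["drivers_overlap"],
        )
        rep["cross_cohort_overlap"] = overlap.to_report()
        if state.ref_somatic is not None and state.ref_gene_lengths is not None:
            if len(cons.joint_set):
                observed_nonref = 1.0 - len(cons.joint_set & ref_joint) / len(
                    cons.joint_set)
            else:
                observed_nonref = None
            bias = subsample_bias_test(
                state.ref_somatic, ref_joint, state.ref_gene_lengths,
                m=th.subsample_m, B=th.subsample_B,
                seed=seeds["drivers_subsample"], fraction=th.fraction,
                observed_nonreference_fraction=observed_nonref,
            )
            rep["subsample_bias"] = bias.to_report()
            if observed_nonref is not None:
                rep["subsample_bias"]["observed_nonreference_fraction"] = (
                    observed_nonref)
    return rep


def _stage_compare(config: RunConfig, state: _RunState, outdir: Path,
                   warnings: list) -> dict:
    if state.query_somatic is None:
        raise PipelineError("compare", "no somatic mutation table available")
    th = config.thresholds
    nq = len(state.query_patients)
    freq_q = gene_frequency_table(state.query_somatic, nq)
    tmb_q = compute_tmb(state.query_somatic, th.capture_mb,
                        patient_ids=state.query_patients)
    rep = {
        "query_n_patients": nq,
        "query_tmb_median": tmb_q.median,
        "query_n_mutated_genes": int(len(freq_q)),
    }
    outdir.mkdir(parents=True, exist_ok=True)
    freq_q.to_csv(outdir / "query_gene_frequencies.tsv", sep="\t")
    tmb_q.per_patient.to_csv(outdir / "query_tmb.tsv", sep="\t")
    rep["frequencies_path"] = "query_gene_frequencies.tsv"
    rep["tmb_path"] = "query_tmb.tsv"
    ref_freq = None
    if state.ref_somatic is not None:
        nr = len(state.ref_patients)
        ref_freq = gene_frequency_table(state.ref_somatic, nr)
        tmb_r = compute_tmb(state.ref_somatic, th.capture_mb,
                            patient_ids=state.ref_patients)
        rep["reference_n_patients"] = nr
        rep["reference_tmb_median"] = tmb_r.median
    elif "reference_gene_counts" in config.inputs:
        ref_freq = pd.read_csv(config.inputs["reference_gene_counts"],
                               sep="\t", index_col="gene")
    if ref_freq is not None:
        comp = compare_gene_frequencies(freq_q, ref_freq,
                                        correction=th.correction)
        comp.to_csv(outdir / "gene_frequency_comparison.tsv", sep="\t")
        rep["comparison_path"] = "gene_frequency_comparison.tsv"
        sig = comp[comp["p_adjusted"] < 0.05].sort_values("p_adjusted")
        rep["n_genes_tested"] = int(len(comp))
        rep["n_significant_adjusted"] = int(len(sig))
        rep["top_genes"] = {
            g: {"p_raw": float(r["p_raw"]),
                "p_adjusted": float(r["p_adjusted"]),
                "freq_a": float(r["freq_a"]), "freq_b": float(r["freq_b"])}
            for g, r in sig.head(10).iterrows()
        }
    return rep


def run_pipeline(config: RunConfig) -> dict:
    """Execute the enabled stages in dependency order; returns the report.

    Identical config + master seed produce an identical report. A stage
    whose inputs are unavailable raises :class:`PipelineError` naming the
    stage; stages disabled in the config are recorded as skipped.
    """
    outdir = Path(config.outdir)
    seeds = _child_seeds(config.seed)
    state = _RunState()
    state.sig_catalog = _load_catalog(config)
    warnings: list[str] = []
    report: dict = {
        "schema_version": config.schema_version,
        "version": __version__,
        "seed": config.seed,
        "child_seeds": seeds,
        "thresholds": vars(config.thresholds).copy(),
        "stages": {},
        "warnings": warnings,
    }
    for stage in STAGES:
        if not config.stages.get(stage, False):
            report["stages"][stage] = {"skipped": True}
            continue
        logger.info("running stage %s", stage)
        if stage == "simulate":
            rep = _stage_simulate(config, state, seeds, outdir)
        elif stage == "germline":
            _load_inputs(config, state)
            rep = _stage_germline(config, state, outdir, warnings)
        elif stage == "signatures":
            _load_inputs(config, state)
            rep = _stage_signatures(config, state, outdir, warnings)
        elif stage == "drivers":
            _load_inputs(config, state)
            rep = _stage_drivers(config, state, seeds, outdir, warnings)
        else:
            _load_inputs(config, state)
            rep = _stage_compare(config, state, outdir, warnings)
        rep = dict(rep)
        rep["skipped"] = False
        report["stages"][stage] = rep
    write_report(report, outdir / "report.json")
    return report
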