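"""SBS-96 channel logic, catalog construction, refitting and contrasts."""

import math

import numpy as np
import pandas as pd
import pytest

from luadcohort import (
    CHANNELS_96,
    SimConfig,
    build_catalog,
    canonicalize_snv,
    cohort_signature_summary,
    compare_signature_between_cohorts,
    generate_cohort,
    read_signature_catalog,
    refit_exposures,
    signature_presence_test,
    write_signature_catalog,
)
from luadcohort.signatures import presence_counts

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


def _mut(pid, ref, alt, ctx, vclass="missense", gene="G0001"):
    return {"patient_id": pid, "gene": gene, "chrom": "1", "pos": 1,
            "ref": ref, "alt": alt, "variant_class": vclass, "context3": ctx}


class TestCanonicalize:
    @pytest.mark.parametrize(
        "ref,alt,ctx,expected",
        [
            ("C", "A", "ACA", "A[C>A]A"),          # already pyrimidine
            ("G", "T", "TGT", "A[C>A]A"),          # reverse complement
            ("A", "G", "CAT", "A[T>C]G"),          # purine ref, asymmetric ctx
            ("T", "G", "GTC", "G[T>G]C"),
        ],
    )
    def test_channel_labels(self, ref, alt, ctx, expected):
        assert canonicalize_snv(ref, alt, ctx) == expected

    def test_all_96_channels_reachable(self):
        seen = {canonicalize_snv(c[2], c[4], c[0] + c[2] + c[6])
                for c in CHANNELS_96}
        assert seen == set(CHANNELS_96)

    @pytest.mark.parametrize(
        "ref,alt,ctx",
        [("N", "A", "ANA"), ("C", "C", "ACA"), ("C", "A", "AGA"),
         ("C", "A", "AC"), ("CT", "A", "ACA")],
    )
    def test_bad_input_rejected(self, ref, alt, ctx):
        with pytest.raises(ValueError):
            canonicalize_snv(ref, alt, ctx)


class TestBuildCatalog:
    def test_single_snv(self):
        m = pd.DataFrame([_mut("P1", "C", "A", "ACA")])
        cat = build_catalog(m)
        assert cat.loc["P1"].sum() == 1
        assert cat.loc["P1", "A[C>A]A"] == 1

    def test_indels_excluded(self):
        rows = [_mut("P1", "C", "A", "ACA") for _ in range(10)]
        rows += [_mut("P1", "AT", "A", "", "indel") for _ in range(3)]
        cat = build_catalog(pd.DataFrame(rows))
        assert cat.loc["P1"].sum() == 10

    def test_strand_invariance(self):
        rng = np.random.default_rng(42)
        rows = []
        for i in range(500):
            chan = CHANNELS_96[rng.integers(96)]
            ref, alt = chan[2], chan[4]
            ctx = chan[0] + ref + chan[6]
            rows.append(_mut(f"P{i % 5}", ref, alt, ctx))
        fwd = pd.DataFrame(rows)
        rev = fwd.copy()
        rev["ref"] = rev["ref"].map(_COMP)
        rev["alt"] = rev["alt"].map(_COMP)
        rev["context3"] = rev["context3"].map(
            lambda c: "".join(_COMP[b] for b in reversed(c)))
        pd.testing.assert_frame_equal(build_catalog(fwd), build_catalog(rev))

    def test_empty_input(self):
        cat = build_catalog(pd.DataFrame(columns=["patient_id", "ref", "alt",
                                                  "context3"]))
        assert cat.shape == (0, 96)


class TestCatalogIO:
    def test_roundtrip(self, catalog, tmp_path):
        p = tmp_path / "cat.tsv"
        write_signature_catalog(catalog, p)
        back = read_signature_catalog(p)
        pd.testing.assert_frame_equal(back, catalog)

    def test_rejects_unnormalized_columns(self, catalog, tmp_path):
        bad = catalog * 2
        p = tmp_path / "bad.tsv"
        write_signature_catalog(bad, p)
        with pytest.raises(ValueError, match="sum to 1"):
            read_signature_catalog(p)


class TestRefit:
    def test_single_signature_gets_everything(self, catalog):
        sigs = catalog.iloc[:, :1]
        m = pd.DataFrame([_mut("P1", "C", "A", "ACA")] * 7)
        expo = refit_exposures(build_catalog(m), sigs)
        assert expo.proportions.loc["P1"].iloc[0] == pytest.approx(1.0)

    def test_disjoint_support_recovers_exact_split(self):
        s1 = np.zeros(96); s1[:48] = 1 / 48
        s2 = np.zeros(96); s2[48:] = 1 / 48
        sigs = pd.DataFrame({"s1": s1, "s2": s2}, index=CHANNELS_96)
        row = np.concatenate([np.full(48, 700 / 48), np.full(48, 300 / 48)])
        cat = pd.DataFrame([row], index=["P1"], columns=CHANNELS_96)
        expo = refit_exposures(cat, sigs)
        assert expo.proportions.loc["P1", "s1"] == pytest.approx(0.7, abs=1e-10)
        assert expo.proportions.loc["P1", "s2"] == pytest.approx(0.3, abs=1e-10)

    def test_zero_row_flagged_undefined(self, catalog):
        cat = pd.DataFrame(np.zeros((1, 96)), index=["P1"],
                           columns=CHANNELS_96)
        expo = refit_exposures(cat, catalog)
        assert (expo.exposures.loc["P1"] == 0).all()
        assert expo.proportions.loc["P1"].isna().all()
        assert expo.defined().empty

    def test_residual_never_grows_with_extra_signature(self, catalog):
        rng = np.random.default_rng(3)
        row = rng.poisson(5.0, size=96).astype(float)
        cat = pd.DataFrame([row], index=["P1"], columns=CHANNELS_96)
        def resid(sigs):
            expo = refit_exposures(cat, sigs)
            fitted = sigs.to_numpy() @ expo.exposures.loc["P1"].to_numpy()
            return np.linalg.norm(row - fitted)
        for k in range(1, catalog.shape[1]):
            assert resid(catalog.iloc[:, :k + 1]) <= resid(
                catalog.iloc[:, :k]) + 1e-9

    def test_recovery_improves_with_mutation_count(self, catalog):
        errors = []
        for rate in (300, 3000, 30000):
            errs = []
            for seed in range(3):
                cfg = SimConfig(seed=seed, n_patients=8, n_genes=100,
                                mutation_rate=rate, indel_fraction=0.0)
                cohort = generate_cohort(cfg, catalog)
                expo = refit_exposures(build_catalog(cohort.somatic), catalog)
                errs.append((expo.proportions - cohort.truth.exposures)
                            .abs().sum(axis=1).mean())
            errors.append(np.mean(errs))
        assert errors[0] > errors[1] > errors[2]


class TestCohortSummary:
    def _expo(self, rows, sigs=("a", "b")):
        props = pd.DataFrame(rows, columns=sigs)
        from luadcohort.signatures import ExposureTable
        return ExposureTable(exposures=props * 100, proportions=props)

    def test_mean_of_proportions(self):
        expo = self._expo([[1.0, 0.0], [0.0, 1.0]])
        assert cohort_signature_summary(expo).tolist() == [0.5, 0.5]

    def test_single_patient(self):
        expo = self._expo([[0.25, 0.75]])
        assert cohort_signature_summary(expo).tolist() == [0.25, 0.75]

    def test_undefined_patient_excluded(self):
        expo = self._expo([[1.0, 0.0], [np.nan, np.nan]])
        assert cohort_signature_summary(expo).tolist() == [1.0, 0.0]

    def test_invariant_to_scaling_one_patients_burden(self, catalog):
        # holding channel proportions fixed, an integer multiple of one
        # patient's mutation count leaves the mean of proportions unchanged
        rng = np.random.default_rng(9)
        rows = rng.poisson(4.0, size=(3, 96)).astype(float) + 1
        cat = pd.DataFrame(rows, index=["P1", "P2", "P3"],
                           columns=CHANNELS_96)
        scaled = cat.copy()
        scaled.loc["P2"] *= 7
        s1 = cohort_signature_summary(refit_exposures(cat, catalog))
        s2 = cohort_signature_summary(refit_exposures(scaled, catalog))
        pd.testing.assert_series_equal(s1, s2, atol=1e-9, rtol=0)

    def test_summary_sums_to_one(self, catalog):
        rng = np.random.default_rng(1)
        cat = pd.DataFrame(rng.poisson(3.0, size=(5, 96)),
                           index=[f"P{i}" for i in range(5)],
                           columns=CHANNELS_96)
        s = cohort_signature_summary(refit_exposures(cat, catalog))
        assert s.sum() == pytest.approx(1.0, abs=1e-8)


class TestCohortContrasts:
    def test_identical_cohorts(self):
        raw, adj = compare_signature_between_cohorts([0.2] * 6, [0.2] * 6)
        assert raw == 1.0 and adj == 1.0

    def test_bonferroni_arithmetic(self):
        x = list(np.linspace(0.5, 0.9, 10))
        y = list(np.linspace(0.0, 0.4, 10))
        raw, adj = compare_signature_between_cohorts(x, y, m_tests=36)
        assert raw == pytest.approx(2 / math.comb(20, 10), rel=1e-12)
        assert adj == pytest.approx(min(1.0, 36 * raw), rel=1e-12)

    def test_presence_fisher(self):
        assert signature_presence_test(0, 10, 0, 10) == 1.0
        assert signature_presence_test(0, 10, 10, 10) == pytest.approx(
            2 / math.comb(20, 10), rel=1e-9)

    def test_presence_epsilon_semantics(self):
        props = pd.Series([0.005, 0.0, np.nan])
        assert presence_counts(props, 0.0) == (1, 2)
        assert presence_counts(props, 0.01) == (0, 2)
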