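import pandas as pd
import pytest

from luadcohort import (
    GeneList,
    GermlineVariant,
    SimConfig,
    generate_cohort,
    load_bundled_catalog,
    pick_planted_drivers,
)

SUSCEPTIBILITY = frozenset(
    {"BRCA1", "TP53", "MUTYH", "SERPINA1", "CDKN2A", "RAD50"}
)


@pytest.fixture(scope="session")
def catalog():
    return load_bundled_catalog()


@pytest.fixture(scope="session")
def gene_list():
    return GeneList(SUSCEPTIBILITY, name="susceptibility")


def _v(pid, gene, sig, af, cadd=None, polyphen=None, sift=None, review=True):
    return GermlineVariant(
        patient_id=pid, gene=gene, clinical_significance=sig,
        af_by_population={"gnomad": af}, cadd_phred=cadd,
        polyphen=polyphen, sift=sift, review_pass=review,
        variant_id=f"{pid}-{gene}",
    )


@pytest.fixture(scope="session")
def twelve_variants():
    """Twelve germline variants exercising every branch of the cascade,
    with the expected decision for each."""
    cases = [
        (_v("P01", "BRCA1", "Pathogenic", 1e-4), "retained_PLP", None),
        (_v("P02", "TP53", "Likely pathogenic", 1e-3), "retained_PLP", None),
        # allele frequency exactly at the threshold fails ("less than" is strict)
        (_v("P03", "MUTYH", "Pathogenic", 0.05), "excluded", "af"),
        (_v("P04", "SERPINA1", "Pathogenic", 0.2), "excluded", "af"),
        (_v("P05", "NOTALIST", "Pathogenic", 1e-4), "excluded", "gene_list"),
        (_v("P06", "RAD50", "Pathogenic", 1e-4, review=False),
         "excluded", "review"),
        # VUS rescued: CADD > 20 and damaging PolyPhen (2 of 3)
        (_v("P07", "CDKN2A", "Uncertain significance", 1e-3, cadd=21,
            polyphen="Possibly damaging", sift="Tolerated"),
         "retained_VUS", None),
        # VUS rescued: CADD and SIFT (2 of 3)
        (_v("P08", "BRCA1", "Uncertain significance", 1e-4, cadd=25,
            polyphen="Benign", sift="Deleterious"), "retained_VUS", None),
        # only CADD met
        (_v("P09", "TP53", "Uncertain significance", 1e-4, cadd=25),
         "excluded", "insufficient_predictors"),
        # CADD exactly 20 does not count ("higher than 20" is strict)
        (_v("P10", "MUTYH", "Uncertain significance", 1e-4, cadd=20,
            polyphen="Probably damaging", sift="Tolerated"),
         "excluded", "insufficient_predictors"),
        (_v("P11", "RAD50", "other", 1e-4), "excluded", "significance"),
        (_v("P12", "CDKN2A", "Conflicting interpretations", 1e-4),
         "excluded", "vocabulary"),
    ]
    return cases


@pytest.fixture(scope="session")
def small_cohort(catalog):
    cfg = SimConfig(
        seed=7, n_patients=25, n_genes=200, mutation_rate=120,
        planted_drivers=pick_planted_drivers(200, 8, 10.0),
    )
    return generate_cohort(cfg, catalog), cfg
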