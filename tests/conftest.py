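import pandas as pd
import pytest

import mrkit as mk
from mrkit.synthetic import SimConfig


@pytest.fixture
def outlier_config() -> SimConfig:
    """A strong-instrument study with one gross pleiotropic outlier: 20
    clean instruments plus one whose outcome effect is shifted by 10 of
    its outcome SEs.  Exposure SEs are small so instrument strength does
    not mask the outcome-side residual."""
    return SimConfig(k=21, beta_true=0.05, seed=7,
                     se_exp_range=(0.005, 0.01), outlier_spec=[(5, 10.0)])


@pytest.fixture
def egfr_all() -> pd.DataFrame:
    """All 11 selenium instruments against eGFR."""
    return mk.selenium_fixture("egfr")


@pytest.fixture
def egfr_kept(egfr_all) -> pd.DataFrame:
    """The 10 instruments retained after the outcome-association exclusion."""
    kept, _ = mk.exclude_outcome_associated(egfr_all)
    return kept


@pytest.fixture
def bun_all() -> pd.DataFrame:
    """All 11 selenium instruments against BUN."""
    return mk.selenium_fixture("bun")


def _records_from_table(table: pd.DataFrame, beta_col: str, se_col: str, p_col: str,
                        flip_alleles: bool = False):
    records = []
    for row in table.itertuples(index=False):
        ea, oa = row.effect_allele, row.other_allele
        if flip_alleles:
            ea, oa = oa, ea
        records.append(mk.SummaryStatRecord(
            snp_id=row.snp_id, chrom=str(row.chrom),
            effect_allele=ea, other_allele=oa, eaf=row.eaf,
            beta=getattr(row, beta_col), se=getattr(row, se_col),
            pval=getattr(row, p_col)))
    return records


@pytest.fixture
def selenium_records():
    """(exposure, egfr, bun) record lists built from the packaged panel,
    all on the exposure allele coding."""
    table = mk.selenium_table()
    exposure = _records_from_table(table, "beta_exp", "se_exp", "p_exp")
    egfr = _records_from_table(table, "beta_egfr", "se_egfr", "p_egfr")
    bun = _records_from_table(table, "beta_bun", "se_bun", "p_bun")
    return exposure, egfr, bun


@pytest.fixture
def selenium_files(tmp_path, selenium_records):
    """Exposure and outcome summary-statistic TSVs in the default dialect."""
    exposure, egfr, bun = selenium_records
    paths = {}
    for name, records in [("exposure", exposure), ("egfr", egfr), ("bun", bun)]:
        path = tmp_path / f"{name}.tsv"
        mk.write_sumstats(records, path)
        paths[name] = str(path)
    return paths
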