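import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from targetmr.sumstats import CANONICAL_COLUMNS, SummaryTable, TraitMeta

settings.register_profile(
    "deterministic", deadline=None, derandomize=True,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("deterministic")


def make_table(rows: list[dict], trait: TraitMeta | None = None) -> SummaryTable:
    """Build a validated SummaryTable from sparse row dicts (defaults filled)."""
    defaults = {"chrom": "6", "pos": 0, "effect_allele": "A",
                "other_allele": "G", "eaf": 0.3, "beta": 0.1, "se": 0.02,
                "pval": 1e-9, "n": 100_000.0}
    full = []
    for i, row in enumerate(rows):
        d = dict(defaults, snp_id=f"rs{i}", pos=1000 + i)
        d.update(row)
        full.append(d)
    return SummaryTable.from_frame(pd.DataFrame(full)[CANONICAL_COLUMNS])


def make_harmonized(beta_x, beta_y, se_y, se_x=None, n_x=300_000.0,
                    n_y=150_000.0) -> pd.DataFrame:
    """Bare harmonized frame for direct estimator tests."""
    beta_x = np.asarray(beta_x, dtype=float)
    beta_y = np.asarray(beta_y, dtype=float)
    se_y = np.asarray(se_y, dtype=float)
    se_x = np.full_like(beta_x, 1e-4) if se_x is None else np.asarray(se_x, float)
    from scipy import stats
    return pd.DataFrame({
        "snp_id": [f"rs{i}" for i in range(len(beta_x))],
        "beta_x": beta_x, "se_x": se_x,
        "p_x": np.clip(2 * stats.norm.sf(np.abs(beta_x / se_x)),
                       np.finfo(float).tiny, 1.0),
        "n_x": n_x,
        "beta_y": beta_y, "se_y": se_y,
        "p_y": np.clip(2 * stats.norm.sf(np.abs(beta_y / se_y)),
                       np.finfo(float).tiny, 1.0),
        "n_y": n_y,
    })


def harmonized_from_sim(exposure: SummaryTable, outcome: SummaryTable) -> pd.DataFrame:
    """Join simulated tables (shared panel, shared alleles) into the
    harmonized layout without going through allele matching."""
    x, y = exposure.df, outcome.df
    return pd.DataFrame({
        "snp_id": x["snp_id"], "beta_x": x["beta"], "se_x": x["se"],
        "p_x": x["pval"], "n_x": x["n"], "beta_y": y["beta"],
        "se_y": y["se"], "p_y": y["pval"], "n_y": y["n"],
    })


@pytest.fixture(scope="session")
def study_corpus(tmp_path_factory):
    """Small synthetic study (2 targets x 2 biomarkers x 2 sources x 3
    outcomes) materialized once per session."""
    from targetmr.simulate import make_study_corpus
    outdir = tmp_path_factory.mktemp("corpus")
    return make_study_corpus(outdir, seed=11)
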