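import numpy as np
import pytest

from proxymr.gwas_io import HarmonizedSet, SummaryStats, VariantAssociation
from proxymr.synthetic_data import default_study_config, simulate_gwas_trio


def make_assoc(rsid="rs1", ea="A", oa="G", beta=0.1, se=0.02, pval=None, n=10_000, eaf=0.3):
    if pval is None:
        from scipy.stats import norm

        pval = float(np.clip(2 * norm.sf(abs(beta / se)), 1e-300, 1.0))
    return VariantAssociation(
        rsid=rsid, effect_allele=ea, other_allele=oa, beta=beta, se=se,
        pval=pval, n=n, eaf=eaf,
    )


def make_stats(label, assocs):
    return SummaryStats.from_records(label, assocs)


def make_harmonized(beta_x, se_x, beta_y, se_y, beta_x2=None, se_x2=None,
                    n_x=10_000, n_x2=10_000, n_y=10_000):
    beta_x = np.asarray(beta_x, dtype=float)
    m = len(beta_x)
    kw = {}
    if beta_x2 is not None:
        kw.update(
            beta_x2=np.asarray(beta_x2, dtype=float),
            se_x2=np.broadcast_to(np.asarray(se_x2, dtype=float), (m,)).copy(),
            n_x2=np.full(m, n_x2, dtype=float),
            exposure2_label="exposure2",
        )
    return HarmonizedSet(
        rsids=[f"rs{i + 1}" for i in range(m)],
        effect_allele=["A"] * m,
        other_allele=["G"] * m,
        beta_x=beta_x,
        se_x=np.broadcast_to(np.asarray(se_x, dtype=float), (m,)).copy(),
        beta_y=np.asarray(beta_y, dtype=float),
        se_y=np.broadcast_to(np.asarray(se_y, dtype=float), (m,)).copy(),
        n_x=np.full(m, n_x, dtype=float),
        n_y=np.full(m, n_y, dtype=float),
        **kw,
    )


@pytest.fixture(scope="session")
def default_trio():
    """One generator realization at the default study conditions."""
    return simulate_gwas_trio(default_study_config(seed=7))


@pytest.fixture(scope="session")
def default_config():
    return default_study_config(seed=7)
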