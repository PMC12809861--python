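import numpy as np
import pytest

from twinace.core_data import Dataset, MemberRecord, PairRecord
from twinace.estimation import fit_bivariate_ace
from twinace.liability_model import BivariateACEParams, get_disease_model
from twinace.synthetic_data import SimConfig, simulate_population


@pytest.fixture(scope="session")
def sz_model():
    return get_disease_model("maudsley_sz")


@pytest.fixture(scope="session")
def broad_model():
    return get_disease_model("maudsley_broad")


def make_member(index, affected=None, score=None, phenotype="SZ", measure="score",
                **covs):
    return MemberRecord(
        member_index=index,
        affected={phenotype: affected},
        cognitive_scores={measure: score},
        **covs,
    )


def make_pair(pair_id, zygosity, members):
    return PairRecord(pair_id=str(pair_id), zygosity=zygosity, members=tuple(members))


def make_dataset(pairs, measure="score", phenotype="SZ"):
    return Dataset(pairs=tuple(pairs), measure_names=(measure,),
                   phenotype_names=(phenotype,))


@pytest.fixture(scope="session")
def recovery_truth():
    # standardized cognitive trait: h2=0.70, c2=0.10, e2=0.20
    return BivariateACEParams(
        a_x=float(np.sqrt(0.70)), c_x=float(np.sqrt(0.10)), e_x=float(np.sqrt(0.20)),
        rg=-0.30, rc=0.0, re=0.10, mu=0.0,
    )


@pytest.fixture(scope="session")
def population_2000(recovery_truth, sz_model):
    """Large population sample shared across recovery tests (no covariates)."""
    cfg = SimConfig(
        n_pairs={"MZ": 2000, "DZ": 2000, "SIB": 2000},
        truth=recovery_truth,
        disease=sz_model,
        seed=20260904,
        generate_covariates=False,
    )
    return simulate_population(cfg)


@pytest.fixture(scope="session")
def recovery_fit(population_2000, sz_model):
    """Shared fit of the large recovery dataset (no CIs)."""
    return fit_bivariate_ace(
        population_2000, "score", "SZ", sz_model, compute_ci=False, seed=1
    )
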