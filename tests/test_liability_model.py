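import numpy as np
import pytest
from scipy import integrate
from scipy.stats import multivariate_normal, norm

from twinace.core_data import MemberRecord, PairRecord
from twinace.liability_model import (
    BivariateACEParams,
    DiseaseModel,
    InvalidParameterPoint,
    disease_profiles,
    expected_pair_covariance,
    get_disease_model,
    kinship_coefficient,
    pair_loglik,
    threshold_from_prevalence,
)

# ---------------------------------------------------------------------------
# oracles
# ---------------------------------------------------------------------------

def threshold_oracle(prevalence):
    """Invert the numerically integrated normal CDF by bisection."""
    def upper_tail(t):
        val, _ = integrate.quad(norm.pdf, t, 10.0, epsabs=1e-14, epsrel=1e-13)
        return val

    lo, hi = -9.0, 9.0
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if upper_tail(mid) > prevalence:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def loglik_oracle(pair, params, disease, measure, phenotype):
    """Brute-force integration of the latent liabilities."""
    sigma = expected_pair_covariance(
        params, disease, kinship_coefficient(pair.zygosity)
    )
    tau = disease.tau
    ys, ds_ = [None, None], [None, None]
    for m in pair.members:
        ys[m.member_index - 1] = m.cognitive_scores.get(measure)
        ds_[m.member_index - 1] = m.affected.get(phenotype)
    iy = [j for j in (0, 1) if ys[j] is not None]
    il = [j + 2 for j in (0, 1) if ds_[j] is not None]
    dvals = [ds_[j] for j in (0, 1) if ds_[j] is not None]

    ll = 0.0
    if iy:
        s_yy = sigma[np.ix_(iy, iy)]
        yv = np.array([ys[j] for j in iy], float)
        mean = np.full(len(iy), params.mu)
        ll += multivariate_normal.logpdf(yv, mean, s_yy)
    if il:
        if iy:
            s_ly = sigma[np.ix_(il, iy)]
            coef = s_ly @ np.linalg.inv(s_yy)
            cmean = coef @ (yv - mean)
            ccov = sigma[np.ix_(il, il)] - coef @ s_ly.T
        else:
            cmean = np.zeros(len(il))
            ccov = sigma[np.ix_(il, il)]

        def limits(d):
            return (tau, 9.0) if d == 1 else (-9.0, tau)

        if len(il) == 1:
            lo, hi = limits(dvals[0])
            p, _ = integrate.quad(
                lambda l: norm.pdf(l, cmean[0], np.sqrt(ccov[0, 0])), lo, hi,
                epsabs=1e-12,
            )
        else:
            lo1, hi1 = limits(dvals[0])
            lo2, hi2 = limits(dvals[1])
            f = multivariate_normal(cmean, ccov).pdf
            p, _ = integrate.dblquad(
                lambda l2, l1: f([l1, l2]), lo1, hi1, lo2, hi2,
                epsabs=1e-10, epsrel=1e-10,
            )
        ll += np.log(p)
    return ll


# ---------------------------------------------------------------------------
# thresholds and kinship
# ---------------------------------------------------------------------------

class TestThreshold:
    def test_median_prevalence(self):
        assert threshold_from_prevalence(0.5) == pytest.approx(0.0, abs=1e-12)

    @pytest.mark.parametrize("k,expected", [(0.0075, 2.4324), (0.017, 2.1201)])
    def test_paper_prevalences(self, k, expected):
        assert threshold_from_prevalence(k) == pytest.approx(expected, abs=5e-5)

    @pytest.mark.parametrize("k", [0.0032, 0.0075, 0.01, 0.017, 0.5])
    def test_against_integration_oracle(self, k):
        assert threshold_from_prevalence(k) == pytest.approx(
            threshold_oracle(k), abs=1e-10
        )

    @pytest.mark.parametrize("k", [0.0, 1.0, -0.1, 1.5])
    def test_invalid_prevalence(self, k):
        with pytest.raises(ValueError):
            threshold_from_prevalence(k)


class TestKinship:
    @pytest.mark.parametrize("zyg,expected", [("MZ", 1.0), ("DZ", 0.5), ("SIB", 0.5)])
    def test_map(self, zyg, expected):
        assert kinship_coefficient(zyg) == expected

    def test_unknown(self):
        with pytest.raises(ValueError):
            kinship_coefficient("HZ")


class TestDiseaseProfiles:
    def test_builtin_profiles(self):
        profiles = disease_profiles()
        assert set(profiles) == {
            "maudsley_sz", "maudsley_bd1", "maudsley_broad",
            "polderman_sz", "polderman_bd1",
        }
        sz = profiles["maudsley_sz"]
        assert (sz.h2, sz.c2, sz.e2, sz.prevalence) == (0.84, 0.0, 0.16, 0.0075)
        assert profiles["maudsley_bd1"].h2 == 0.85
        assert profiles["maudsley_bd1"].prevalence == 0.0032
        assert profiles["maudsley_broad"].h2 == 0.90
        assert profiles["maudsley_broad"].prevalence == 0.017
        assert profiles["polderman_sz"].c2 == 0.01

    def test_unknown_profile(self):
        with pytest.raises(KeyError):
            get_disease_model("nonexistent")

    def test_invariants_enforced(self):
        with pytest.raises(ValueError):
            DiseaseModel(h2=0.9, c2=0.2, e2=0.1, prevalence=0.01)
        with pytest.raises(ValueError):
            DiseaseModel(h2=0.8, c2=0.0, e2=0.2, prevalence=0.0)


# ---------------------------------------------------------------------------
# pair covariance
# ---------------------------------------------------------------------------

def std_params(h2=0.3, c2=0.1, rg=0.0, rc=0.0, re=0.0, mu=0.0, v=1.0):
    e2 = 1.0 - h2 - c2
    return BivariateACEParams(
        a_x=np.sqrt(v * h2), c_x=np.sqrt(v * c2), e_x=np.sqrt(v * e2),
        rg=rg, rc=rc, re=re, mu=mu,
    )


class TestExpectedPairCovariance:
    def test_mz_liability_covariance(self, sz_model):
        sigma = expected_pair_covariance(std_params(), sz_model, 1.0)
        assert sigma[2, 3] == pytest.approx(0.84, abs=1e-12)

    def test_dz_liability_covariance(self, sz_model):
        sigma = expected_pair_covariance(std_params(), sz_model, 0.5)
        assert sigma[2, 3] == pytest.approx(0.42, abs=1e-12)

    def test_zero_correlations_decouple_traits(self, sz_model):
        sigma = expected_pair_covariance(std_params(), sz_model, 0.5)
        assert np.allclose(sigma[:2, 2:], 0.0)

    def test_within_member_cross_trait_product_rule(self, broad_model):
        # rg=0.42, h2_x=0.30, h2_d=0.90 -> cross-trait covariance ~ 0.218
        sigma = expected_pair_covariance(std_params(h2=0.30, rg=0.42),
                                         broad_model, 1.0)
        assert sigma[0, 2] == pytest.approx(0.42 * np.sqrt(0.30 * 0.90), abs=1e-12)
        assert sigma[0, 2] == pytest.approx(0.218, abs=5e-4)

    def test_symmetry_and_unit_liability_variance(self, sz_model):
        sigma = expected_pair_covariance(std_params(rg=0.4, re=-0.2), sz_model, 0.5)
        assert np.allclose(sigma, sigma.T)
        assert sigma[2, 2] == sigma[3, 3] == 1.0

    def test_always_psd_for_valid_inputs(self, sz_model):
        # the ACE structure is a sum of PSD components, so any valid
        # correlation combination yields a PSD matrix (boundary combos
        # are exactly singular); the guard exists for defensive depth
        rng = np.random.default_rng(5)
        for _ in range(50):
            h2 = rng.uniform(0, 1)
            c2 = rng.uniform(0, 1 - h2)
            params = std_params(
                h2=h2, c2=c2, rg=rng.choice([-1.0, 1.0, rng.uniform(-1, 1)]),
                re=rng.choice([-1.0, 1.0, rng.uniform(-1, 1)]),
            )
            for r_a in (1.0, 0.5):
                sigma = expected_pair_covariance(params, sz_model, r_a)
                assert np.linalg.eigvalsh(sigma)[0] > -1e-10

    def test_non_psd_guard_fires_on_invalid_structure(self, sz_model):
        from twinace.correlation_models import _sigma_from_corr

        values = {"r_wtct": 0.9, "r_ctct_mz": -0.9, "r_ctct_dz": 0.0,
                  "r_ctwt_mz": 0.9, "r_ctwt_dz": 0.0}
        with pytest.raises(InvalidParameterPoint):
            _sigma_from_corr(values, 1.0, 0.84, 0.42, 1.0)

    def test_cross_twin_cognitive_correlation_monotone_in_kinship(self, sz_model):
        params = std_params(h2=0.5, c2=0.2)
        mz = expected_pair_covariance(params, sz_model, 1.0)
        dz = expected_pair_covariance(params, sz_model, 0.5)
        assert mz[0, 1] / mz[0, 0] == pytest.approx(0.7)
        assert dz[0, 1] / dz[0, 0] == pytest.approx(0.45)
        assert mz[0, 1] > dz[0, 1]


# ---------------------------------------------------------------------------
# pair likelihood
# ---------------------------------------------------------------------------

def two_member_pair(zyg, y1, y2, d1, d2):
    def member(i, y, d):
        return MemberRecord(member_index=i, affected={"SZ": d},
                            cognitive_scores={"score": y})
    return PairRecord(pair_id="p", zygosity=zyg,
                      members=(member(1, y1, d1), member(2, y2, d2)))


class TestPairLoglik:
    def test_singleton_unaffected_no_cognition_median_prevalence(self):
        disease = DiseaseModel(h2=0.84, c2=0.0, e2=0.16, prevalence=0.5)
        pair = PairRecord(
            pair_id="s", zygosity="MZ",
            members=(MemberRecord(member_index=1, affected={"SZ": 0},
                                  cognitive_scores={"score": None}),),
        )
        ll = pair_loglik(pair, std_params(), disease, "score", "SZ")
        assert ll == pytest.approx(np.log(0.5), abs=1e-10)

    def test_mz_concordant_orthant_against_quadrature(self, sz_model):
        pair = two_member_pair("MZ", None, None, 1, 1)
        params = std_params()
        ll = pair_loglik(pair, params, sz_model, "score", "SZ")
        oracle = loglik_oracle(pair, params, sz_model, "score", "SZ")
        assert ll == pytest.approx(oracle, abs=1e-6)

    def test_full_pair_against_quadrature(self, sz_model):
        pair = two_member_pair("DZ", 0.8, -1.1, 1, 0)
        params = std_params(h2=0.5, c2=0.1, rg=-0.4, re=0.2)
        ll = pair_loglik(pair, params, sz_model, "score", "SZ")
        oracle = loglik_oracle(pair, params, sz_model, "score", "SZ")
        assert ll == pytest.approx(oracle, abs=1e-6)

    def test_missing_elements_marginalised(self, sz_model):
        pair = two_member_pair("MZ", 0.3, None, None, 1)
        params = std_params(h2=0.4, rg=0.3)
        ll = pair_loglik(pair, params, sz_model, "score", "SZ")
        oracle = loglik_oracle(pair, params, sz_model, "score", "SZ")
        assert ll == pytest.approx(oracle, abs=1e-6)

    def test_empty_pair_raises(self, sz_model):
        pair = PairRecord(
            pair_id="e", zygosity="MZ",
            members=(MemberRecord(member_index=1, affected={"SZ": None},
                                  cognitive_scores={"score": None}),),
        )
        with pytest.raises(ValueError, match="no observed data"):
            pair_loglik(pair, std_params(), sz_model, "score", "SZ")

    def test_affection_patterns_sum_to_one(self, sz_model):
        params = std_params(h2=0.5, c2=0.15, rg=-0.35, re=0.25)
        y1, y2 = 0.4, -0.9
        total = 0.0
        base = None
        for d1 in (0, 1):
            for d2 in (0, 1):
                pair = two_member_pair("MZ", y1, y2, d1, d2)
                ll = pair_loglik(pair, params, sz_model, "score", "SZ")
                if base is None:
                    # common continuous density factors out
                    cont = two_member_pair("MZ", y1, y2, None, None)
                    base = pair_loglik(cont, params, sz_model, "score", "SZ")
                total += np.exp(ll - base)
        assert total == pytest.approx(1.0, abs=1e-8)

    def test_marginal_affection_probability_is_prevalence(self, sz_model):
        # integrate the single-member model over the two affection states
        params = std_params(h2=0.5, rg=-0.3)
        pair_aff = PairRecord(
            pair_id="a", zygosity="MZ",
            members=(MemberRecord(member_index=1, affected={"SZ": 1},
                                  cognitive_scores={"score": None}),),
        )
        ll = pair_loglik(pair_aff, params, sz_model, "score", "SZ")
        assert np.exp(ll) == pytest.approx(sz_model.prevalence, abs=1e-8)

    def test_member_swap_invariance(self, sz_model):
        params = std_params(h2=0.45, c2=0.2, rg=0.3, re=-0.15)
        a = two_member_pair("DZ", 0.7, -0.2, 1, 0)
        b = two_member_pair("DZ", -0.2, 0.7, 0, 1)
        ll_a = pair_loglik(a, params, sz_model, "score", "SZ")
        ll_b = pair_loglik(b, params, sz_model, "score", "SZ")
        assert ll_a == pytest.approx(ll_b, abs=1e-10)

    def test_randomised_pairs_against_quadrature(self, sz_model):
        rng = np.random.default_rng(11)
        for _ in range(20):
            h2 = rng.uniform(0.05, 0.8)
            c2 = rng.uniform(0.0, 0.9 - h2)
            params = std_params(
                h2=h2, c2=c2,
                rg=rng.uniform(-0.8, 0.8), re=rng.uniform(-0.8, 0.8),
                mu=rng.normal(0, 1),
            )
            zyg = rng.choice(["MZ", "DZ", "SIB"])
            pair = two_member_pair(
                zyg, rng.normal(0, 1), rng.normal(0, 1),
                int(rng.integers(0, 2)), int(rng.integers(0, 2)),
            )
            ll = pair_loglik(pair, params, sz_model, "score", "SZ")
            oracle = loglik_oracle(pair, params, sz_model, "score", "SZ")
            assert ll == pytest.approx(oracle, abs=1e-6)
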