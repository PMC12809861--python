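"""Bivariate ACE liability-threshold model for twin/sibling pairs.

A pair is modelled as a 4-variate normal over (y1, y2, l1, l2): the
cognitive scores of both members and their latent disease liabilities.
The liability side is fully fixed (variance proportions and a threshold
derived from population prevalence); the cognitive side and the A/C/E
cross-trait correlations are free.  The pair log-likelihood is the
full-information likelihood of the observed continuous sub-vector times
the conditional probability of the observed affection pattern, an
orthant of the conditional normal of the liabilities.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from typing import Callable, Mapping, Sequence

import numpy as np
import yaml
from scipy.special import ndtr
from scipy.stats import norm

from .bvn import bvn_cdf
from .core_data import Dataset, PairRecord

__all__ = [
    "DiseaseModel",
    "BivariateACEParams",
    "threshold_from_prevalence",
    "kinship_coefficient",
    "expected_pair_covariance",
    "pair_loglik",
    "disease_profiles",
    "get_disease_model",
    "PreparedData",
    "prepare_data",
    "dataset_loglik",
]

_KINSHIP = {"MZ": 1.0, "DZ": 0.5, "SIB": 0.5}

_LOG_TINY = -745.0  # log of smallest positive double, used to floor log-probs


class InvalidParameterPoint(ValueError):
    """Parameter combination implies a non-PSD pair covariance."""


def threshold_from_prevalence(prevalence: float) -> float:
    """Liability threshold tau with upper-tail mass equal to the prevalence."""
    if not 0.0 < prevalence < 1.0:
        raise ValueError(f"prevalence must be in (0, 1), got {prevalence}")
    return float(norm.isf(prevalence))


def kinship_coefficient(zygosity: str) -> float:
    """Expected additive-genetic correlation between pair members."""
    try:
        return _KINSHIP[zygosity]
    except KeyError:
        raise ValueError(f"unknown zygosity {zygosity!r}") from None


@dataclass(frozen=True)
class DiseaseModel:
    """Fixed liability-scale parameters of a diagnostic phenotype."""

    h2: float
    c2: float
    e2: float
    prevalence: float
    name: str = ""

    def __post_init__(self) -> None:
        if abs(self.h2 + self.c2 + self.e2 - 1.0) > 1e-12:
            raise ValueError("liability variance proportions must sum to 1")
        if min(self.h2, self.c2, self.e2) < 0:
            raise ValueError("liability variance proportions must be non-negative")
        if not 0.0 < self.prevalence < 1.0:
            raise ValueError("prevalence must be in (0, 1)")

    @property
    def tau(self) -> float:
        return threshold_from_prevalence(self.prevalence)

    def cross_member_cov(self, zygosity: str) -> float:
        """Model-implied cross-member liability covariance (unit variances)."""
        return kinship_coefficient(zygosity) * self.h2 + self.c2


def disease_profiles() -> dict[str, DiseaseModel]:
    """Built-in named disease parameter profiles (main + sensitivity sets)."""
    text = resources.files("twinace").joinpath("profiles.yaml").read_text()
    raw = yaml.safe_load(text)
    return {
        name: DiseaseModel(
            h2=v["h2"], c2=v["c2"], e2=v["e2"], prevalence=v["prevalence"], name=name
        )
        for name, v in raw.items()
    }


def get_disease_model(name: str) -> DiseaseModel:
    profiles = disease_profiles()
    try:
        return profiles[name]
    except KeyError:
        raise KeyError(
            f"unknown disease profile {name!r}; available: {sorted(profiles)}"
        ) from None


@dataclass(frozen=True)
class BivariateACEParams:
    """Free parameters: cognitive ACE paths, cross-trait correlations, mean."""

    a_x: float
    c_x: float
    e_x: float
    rg: float
    rc: float
    re: float
    mu: float = 0.0
    beta: np.ndarray = field(default_factory=lambda: np.zeros(0))

    def __post_init__(self) -> None:
        if self.e_x <= 0:
            raise ValueError("e_x must be positive")
        for name in ("rg", "rc", "re"):
            if abs(getattr(self, name)) > 1.0:
                raise ValueError(f"{name} must lie in [-1, 1]")
        object.__setattr__(self, "beta", np.asarray(self.beta, float))

    @property
    def total_variance(self) -> float:
        return self.a_x**2 + self.c_x**2 + self.e_x**2

    @property
    def h2(self) -> float:
        return self.a_x**2 / self.total_variance

    @property
    def c2(self) -> float:
        return self.c_x**2 / self.total_variance

    @property
    def e2(self) -> float:
        return self.e_x**2 / self.total_variance


def expected_pair_covariance(
    params: BivariateACEParams, disease: DiseaseModel, r_a: float
) -> np.ndarray:
    """Model-implied 4x4 covariance over (y1, y2, l1, l2).

    Liability entries are on the unit-variance scale.  Raises
    :class:`InvalidParameterPoint` when the implied matrix is not PSD,
    which the optimiser treats as an invalid point rather than a crash.
    """
    a, c, e = params.a_x, params.c_x, params.e_x
    var_y = a * a + c * c + e * e
    cov_yy = r_a * a * a + c * c
    cov_ll = r_a * disease.h2 + disease.c2
    sa, sc, se = np.sqrt(disease.h2), np.sqrt(disease.c2), np.sqrt(disease.e2)
    within = params.rg * a * sa + params.rc * c * sc + params.re * e * se
    cross = r_a * params.rg * a * sa + params.rc * c * sc
    sigma = np.array(
        [
            [var_y, cov_yy, within, cross],
            [cov_yy, var_y, cross, within],
            [within, cross, 1.0, cov_ll],
            [cross, within, cov_ll, 1.0],
        ]
    )
    eig = np.linalg.eigvalsh(sigma)
    if eig[0] < -1e-10:
        raise InvalidParameterPoint(
            f"pair covariance not PSD (min eigenvalue {eig[0]:.3e})"
        )
    return sigma


# ---------------------------------------------------------------------------
# Vectorised dataset likelihood
# ---------------------------------------------------------------------------

@dataclass
class _Group:
    """Pairs sharing kinship and missingness pattern; vectorised jointly."""

    r_a: float
    iy: tuple[int, ...]  # observed cognition slots among (0, 1)
    il: tuple[int, ...]  # observed liability slots among (0, 1)
    y: np.ndarray        # (n, len(iy))
    x: np.ndarray        # (n, len(iy), p) covariate rows
    d: np.ndarray        # (n, len(il)) affection indicators


@dataclass
class PreparedData:
    """Dataset flattened into homogeneous groups for one measure x phenotype."""

    groups: list[_Group]
    n_pairs_used: int
    n_covariates: int


def prepare_data(
    ds: Dataset,
    measure: str,
    phenotype: str,
    design: Mapping[tuple[str, int], np.ndarray] | None = None,
) -> PreparedData:
    """Group usable pairs by (kinship, missingness pattern)."""
    if measure not in ds.measure_names:
        raise KeyError(f"unknown measure {measure!r}; dataset has {ds.measure_names}")
    if phenotype not in ds.phenotype_names:
        raise KeyError(
            f"unknown phenotype {phenotype!r}; dataset has {ds.phenotype_names}"
        )
    p_cov = 0
    if design:
        p_cov = len(next(iter(design.values())))
    buckets: dict[tuple, list] = {}
    n_used = 0
    for pair in ds.pairs:
        r_a = kinship_coefficient(pair.zygosity)
        ys, xs, dss = [None, None], [None, None], [None, None]
        for m in pair.members:
            slot = m.member_index - 1
            ys[slot] = m.cognitive_scores.get(measure)
            dss[slot] = m.affected.get(phenotype)
            if design is not None:
                xs[slot] = design.get((pair.pair_id, m.member_index))
        iy = tuple(j for j in (0, 1) if ys[j] is not None)
        il = tuple(j for j in (0, 1) if dss[j] is not None)
        if not iy and not il:
            continue
        n_used += 1
        key = (r_a, iy, il)
        row_y = [ys[j] for j in iy]
        row_x = [
            xs[j] if xs[j] is not None else np.zeros(p_cov) for j in iy
        ]
        row_d = [dss[j] for j in il]
        buckets.setdefault(key, []).append((row_y, row_x, row_d))

    groups = []
    for (r_a, iy, il), rows in sorted(buckets.items()):
        y = np.array([r[0] for r in rows], float).reshape(len(rows), len(iy))
        x = np.array([r[1] for r in rows], float).reshape(len(rows), len(iy), p_cov)
        d = np.array([r[2] for r in rows], int).reshape(len(rows), len(il))
        groups.append(_Group(r_a=r_a, iy=iy, il=il, y=y, x=x, d=d))
    return PreparedData(groups=groups, n_pairs_used=n_used, n_covariates=p_cov)


def _mvn_logpdf(resid: np.ndarray, cov: np.ndarray) -> np.ndarray:
    """Log-density of centred rows under N(0, cov); cov is 1x1 or 2x2."""
    k = cov.shape[0]
    sign, logdet = np.linalg.slogdet(cov)
    if sign <= 0:
        raise InvalidParameterPoint("continuous block not positive definite")
    sol = np.linalg.solve(cov, resid.T).T
    quad = np.einsum("ij,ij->i", resid, sol)
    return -0.5 * (k * np.log(2.0 * np.pi) + logdet + quad)


def _group_loglik(g: _Group, sigma: np.ndarray, tau: float, mean: np.ndarray) -> np.ndarray:
    """Per-pair log-likelihood for one homogeneous group.

    ``mean`` is (n, len(iy)): the covariate-shifted cognitive means.
    """
    idx_y = [j for j in g.iy]
    idx_l = [2 + j for j in g.il]
    ll = np.zeros(g.y.shape[0])

    if idx_y:
        s_yy = sigma[np.ix_(idx_y, idx_y)]
        resid = g.y - mean
        ll += _mvn_logpdf(resid, s_yy)

    if idx_l:
        s_ll = sigma[np.ix_(idx_l, idx_l)]
        if idx_y:
            s_ly = sigma[np.ix_(idx_l, idx_y)]
            coef = np.linalg.solve(s_yy, s_ly.T).T      # (nl, ny)
            cond_cov = s_ll - coef @ s_ly.T
            cond_mean = resid @ coef.T                  # (n, nl)
        else:
            cond_cov = s_ll
            cond_mean = np.zeros((g.y.shape[0], len(idx_l)))

        sd = np.sqrt(np.diag(cond_cov))
        if np.any(sd <= 0):
            raise InvalidParameterPoint("conditional liability variance <= 0")
        z = (tau - cond_mean) / sd                      # (n, nl)
        s = 1.0 - 2.0 * g.d                             # +1 unaffected, -1 affected
        if len(idx_l) == 1:
            prob = ndtr(s[:, 0] * z[:, 0])
        else:
            rho = cond_cov[0, 1] / (sd[0] * sd[1])
            rho = float(np.clip(rho, -1.0, 1.0))
            prob = bvn_cdf(s[:, 0] * z[:, 0], s[:, 1] * z[:, 1], s[:, 0] * s[:, 1] * rho)
        with np.errstate(divide="ignore"):
            ll += np.maximum(np.log(np.maximum(prob, 0.0)), _LOG_TINY)
    return ll


def dataset_loglik(
    prep: PreparedData,
    sigma_fn: Callable[[float], np.ndarray],
    tau: float,
    mu: float,
    beta: np.ndarray | None = None,
) -> float:
    """Summed pair log-likelihood; -inf at invalid parameter points.

    ``sigma_fn`` maps a kinship coefficient to the 4x4 pair covariance.
    """
    beta = np.zeros(prep.n_covariates) if beta is None else np.asarray(beta, float)
    total = 0.0
    sigmas: dict[float, np.ndarray] = {}
    try:
        for g in prep.groups:
            if g.r_a not in sigmas:
                sigmas[g.r_a] = sigma_fn(g.r_a)
            mean = mu + (g.x @ beta if prep.n_covariates else np.zeros_like(g.y))
            total += float(np.sum(_group_loglik(g, sigmas[g.r_a], tau, mean)))
    except InvalidParameterPoint:
        return -np.inf
    return total


def pair_loglik(
    pair: PairRecord,
    params: BivariateACEParams,
    disease: DiseaseModel,
    measure: str,
    phenotype: str,
    design: Mapping[tuple[str, int], np.ndarray] | None = None,
) -> float:
    """Log-likelihood of a single pair under the bivariate ACE model."""
    names = {measure}
    for m in pair.members:
        names.update(m.cognitive_scores)
    ds = Dataset(
        pairs=(pair,), measure_names=tuple(sorted(names)), phenotype_names=(phenotype,)
    )
    prep = prepare_data(ds, measure, phenotype, design)
    if prep.n_pairs_used == 0:
        raise ValueError(f"pair {pair.pair_id} has no observed data")
    return dataset_loglik(
        prep,
        lambda r_a: expected_pair_covariance(params, disease, r_a),
        disease.tau,
        params.mu,
        params.beta,
    )
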