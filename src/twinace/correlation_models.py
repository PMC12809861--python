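"""Constrained saturated correlation model for cognition x liability pairs.

Estimates, by FIML on the same 4-variate normal machinery as the ACE
model: one within-twin/sibling cross-trait correlation (shared across
zygosity and birth order), MZ and DZ/sibling cross-twin cross-trait
correlations, and MZ and DZ/sibling cross-twin within-cognition
correlations.  The liability cross-twin correlations are fixed at the
active disease profile's h2 + c2 (MZ) and 0.5*h2 + c2 (DZ/sibling).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.optimize import approx_fprime, brentq
from scipy.stats import chi2

from .core_data import Dataset
from .estimation import _atanh_safe, _minimize, _BIG
from .liability_model import (
    DiseaseModel,
    InvalidParameterPoint,
    PreparedData,
    dataset_loglik,
    prepare_data,
)

__all__ = ["CorrelationSet", "fit_constrained_correlations"]

_FREE_CORRS = ("r_wtct", "r_ctct_mz", "r_ctct_dz", "r_ctwt_mz", "r_ctwt_dz")


@dataclass
class CorrelationSet:
    """Estimated and fixed correlations of the constrained model."""

    r_wtct: float
    r_ctct_mz: float
    r_ctct_dz: float
    r_ctwt_mz: float
    r_ctwt_dz: float
    fixed_disease_mz: float
    fixed_disease_dz: float
    mu: float
    total_variance: float
    beta: np.ndarray
    loglik: float
    n_pairs_used: int
    ci: dict[str, tuple[float, float]] = field(default_factory=dict)
    ci_flags: dict[str, dict] = field(default_factory=dict)
    convergence: dict = field(default_factory=dict)

    def significant(self, name: str) -> bool | None:
        """95% CI excludes 0; None when no CI is available."""
        if name not in self.ci:
            return None
        lo, hi = self.ci[name]
        return bool(lo > 0.0 or hi < 0.0)


def _sigma_from_corr(
    values: Mapping[str, float], v: float, fixed_mz: float, fixed_dz: float, r_a: float
) -> np.ndarray:
    """4x4 covariance over (y1, y2, l1, l2) from the correlation set."""
    mz = r_a == 1.0
    r_ctwt = values["r_ctwt_mz"] if mz else values["r_ctwt_dz"]
    r_ctct = values["r_ctct_mz"] if mz else values["r_ctct_dz"]
    r_ll = fixed_mz if mz else fixed_dz
    s = np.sqrt(v)
    wt = values["r_wtct"] * s
    ct = r_ctct * s
    sigma = np.array(
        [
            [v, r_ctwt * v, wt, ct],
            [r_ctwt * v, v, ct, wt],
            [wt, ct, 1.0, r_ll],
            [ct, wt, r_ll, 1.0],
        ]
    )
    eig = np.linalg.eigvalsh(sigma)
    if eig[0] < -1e-10:
        raise InvalidParameterPoint("correlation structure not PSD")
    return sigma


def _make_nll(prep: PreparedData, disease: DiseaseModel, fixed: Mapping[str, float]):
    tau = disease.tau
    fixed_mz = disease.h2 + disease.c2
    fixed_dz = 0.5 * disease.h2 + disease.c2
    free = [c for c in _FREE_CORRS if c not in fixed]
    p = prep.n_covariates

    def unpack(x: np.ndarray) -> tuple[float, np.ndarray, float, dict[str, float]]:
        mu = x[0]
        beta = x[1 : 1 + p]
        v = float(np.exp(np.clip(x[1 + p], -300, 300)))
        values = dict(fixed)
        for i, name in enumerate(free):
            values[name] = float(np.tanh(x[2 + p + i]))
        return mu, beta, v, values

    def nll(x: np.ndarray) -> float:
        mu, beta, v, values = unpack(x)
        ll = dataset_loglik(
            prep,
            lambda r_a: _sigma_from_corr(values, v, fixed_mz, fixed_dz, r_a),
            tau,
            mu,
            beta,
        )
        return -ll if np.isfinite(ll) else _BIG

    return nll, unpack, free


def _pack(mu: float, beta: np.ndarray, v: float, corrs: Mapping[str, float],
          free: Sequence[str], p: int) -> np.ndarray:
    x = np.zeros(2 + p + len(free))
    x[0] = mu
    x[1 : 1 + p] = beta
    x[1 + p] = np.log(max(v, 1e-12))
    for i, name in enumerate(free):
        x[2 + p + i] = _atanh_safe(corrs.get(name, 0.0))
    return x


def fit_constrained_correlations(
    ds: Dataset,
    measure: str,
    phenotype: str,
    disease: DiseaseModel,
    design: Mapping[tuple[str, int], np.ndarray] | None = None,
    constraints: Mapping[str, float] | None = None,
    n_starts: int = 3,
    seed: int = 0,
    compute_ci: bool = True,
    ci_params: Sequence[str] = ("r_wtct",),
    ci_level: float = 0.95,
) -> CorrelationSet:
    """ML fit of the constrained correlation model."""
    if ds.n_pairs == 0:
        raise ValueError("empty dataset")
    prep = prepare_data(ds, measure, phenotype, design)
    if prep.n_pairs_used == 0:
        raise ValueError("no usable pairs (no observed cognition or affection)")
    fixed = dict(constraints or {})
    nll, unpack, free = _make_nll(prep, disease, fixed)

    # moment start: pooled mean/variance, correlations at 0
    ys = np.concatenate([g.y.ravel() for g in prep.groups]) if prep.groups else np.zeros(0)
    mu0 = float(np.mean(ys)) if ys.size else 0.0
    v0 = float(np.var(ys)) if ys.size > 1 else 1.0
    x0 = _pack(mu0, np.zeros(prep.n_covariates), v0 or 1.0, {}, free, prep.n_covariates)

    rng = np.random.default_rng(seed)
    best = None
    for i in range(max(n_starts, 1)):
        xs = x0 if i == 0 else x0 + rng.normal(0.0, 0.3, x0.size)
        res = _minimize(nll, xs)
        if best is None or res.fun < best.fun:
            best = res
    mu, beta, v, corrs = unpack(best.x)
    grad_norm = float(np.linalg.norm(approx_fprime(best.x, nll, 1.5e-8)))
    if not best.success:
        warnings.warn(f"correlation fit did not converge cleanly: {best.message}",
                      stacklevel=2)

    out = CorrelationSet(
        r_wtct=corrs["r_wtct"],
        r_ctct_mz=corrs["r_ctct_mz"],
        r_ctct_dz=corrs["r_ctct_dz"],
        r_ctwt_mz=corrs["r_ctwt_mz"],
        r_ctwt_dz=corrs["r_ctwt_dz"],
        fixed_disease_mz=disease.h2 + disease.c2,
        fixed_disease_dz=0.5 * disease.h2 + disease.c2,
        mu=mu,
        total_variance=v,
        beta=beta,
        loglik=float(-best.fun),
        n_pairs_used=prep.n_pairs_used,
        convergence={"success": bool(best.success), "grad_norm": grad_norm,
                     "n_starts": n_starts, "seed": seed},
    )
    if compute_ci:
        for name in ci_params:
            if name in fixed:
                continue
            _profile_corr_ci(out, prep, disease, fixed, name, corrs, ci_level)
    return out


def _profile_corr_ci(
    result: CorrelationSet,
    prep: PreparedData,
    disease: DiseaseModel,
    base_fixed: Mapping[str, float],
    param: str,
    mle_corrs: Mapping[str, float],
    level: float,
) -> None:
    """Profile-likelihood CI for one correlation; bound endpoints flagged."""
    target = float(chi2.ppf(level, 1))
    nll_max = -result.loglik
    mle = mle_corrs[param]
    flags = {"lo_at_bound": False, "hi_at_bound": False, "unreliable": False}
    cache: dict[float, float] = {}

    def dev(t: float) -> float:
        t = float(t)
        if t not in cache:
            fixed = dict(base_fixed)
            fixed[param] = t
            nll, unpack, free = _make_nll(prep, disease, fixed)
            x0 = _pack(result.mu, result.beta, result.total_variance, mle_corrs,
                       free, prep.n_covariates)
            res = _minimize(nll, x0, maxiter=150, ftol=1e-10)
            cache[t] = max(2.0 * (float(res.fun) - nll_max), 0.0)
        return cache[t]

    def endpoint(direction: int) -> float:
        bound = float(direction)
        step = 0.05
        t_in = mle
        while True:
            t = mle + direction * step
            if (direction > 0 and t >= bound) or (direction < 0 and t <= bound):
                t = bound
            if dev(t) >= target:
                lo, hi = (t_in, t) if direction > 0 else (t, t_in)
                try:
                    return float(
                        brentq(lambda u: dev(u) - target, lo, hi, xtol=2e-3, maxiter=40)
                    )
                except ValueError:
                    flags["unreliable"] = True
                    return t
            if t == bound:
                flags["hi_at_bound" if direction > 0 else "lo_at_bound"] = True
                return bound
            t_in = t
            step *= 2.0

    result.ci[param] = (endpoint(-1), endpoint(+1))
    result.ci_flags[param] = flags
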