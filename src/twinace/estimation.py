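"""Maximum-likelihood fitting of the bivariate ACE model.

Free parameters live on unconstrained coordinates (variance proportions
through a stick-breaking logistic map, correlations through tanh, the
total variance through log), so a plain quasi-Newton local search from
several deterministically jittered starts suffices.  Confidence
intervals are profile-likelihood intervals; an interval endpoint that
never crosses the deviance target before hitting the parameter bound is
reported at the bound and flagged, mirroring the boundary convention of
SEM output ("NA" endpoints).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.optimize import approx_fprime, brentq, minimize
from scipy.special import expit, logit
from scipy.stats import chi2

from .core_data import Dataset
from .liability_model import (
    BivariateACEParams,
    DiseaseModel,
    PreparedData,
    dataset_loglik,
    expected_pair_covariance,
    prepare_data,
)

__all__ = [
    "FitResult",
    "LRTRecord",
    "fit_bivariate_ace",
    "profile_ci",
    "likelihood_ratio_test",
    "fit_submodel",
]

_BIG = 1e12
_CORR_BOUND = 1.0 - 1e-9

#: quantities that may be fixed by constraints or profiled
VARIANCE_QUANTITIES = ("h2", "c2", "e2")
CORRELATION_QUANTITIES = ("rg", "rc", "re")
DERIVED_QUANTITIES = ("rph_a", "rph_e")

_BOUNDS = {
    "h2": (0.0, 1.0),
    "c2": (0.0, 1.0),
    "e2": (0.0, 1.0),
    "rg": (-1.0, 1.0),
    "rc": (-1.0, 1.0),
    "re": (-1.0, 1.0),
    "rph_a": (-1.0, 1.0),
    "rph_e": (-1.0, 1.0),
}


def _atanh_safe(r: float) -> float:
    return float(np.arctanh(np.clip(r, -_CORR_BOUND, _CORR_BOUND)))


def _logit_safe(p: float) -> float:
    return float(logit(np.clip(p, 1e-9, 1.0 - 1e-9)))


class _Layout:
    """Mapping between the unconstrained vector and natural quantities.

    ``fixed`` holds standardized quantities pinned at constants — used
    both for sub-models (e.g. ``{"rg": 0}``) and for profile likelihood
    (e.g. ``{"h2": t}``).  Fixing ``rph_a`` substitutes
    ``rg = rph_a / sqrt(h2 * h2_d)``; analogously for ``rph_e``.
    """

    def __init__(
        self,
        p_cov: int,
        disease: DiseaseModel,
        fixed: Mapping[str, float],
        free_disease_h2: bool = False,
    ) -> None:
        self.p_cov = p_cov
        self.disease = disease
        self.fixed = dict(fixed)
        self.free_disease_h2 = free_disease_h2
        if free_disease_h2 and disease.c2 != 0:
            raise ValueError("free_disease_h2 requires a zero-c2 disease profile")

        bad = set(self.fixed) - set(_BOUNDS)
        if bad:
            raise ValueError(f"cannot fix unknown quantities {sorted(bad)}")
        if "rph_a" in self.fixed and "rg" in self.fixed:
            raise ValueError("cannot fix both rg and rph_a")
        if "rph_e" in self.fixed and "re" in self.fixed:
            raise ValueError("cannot fix both re and rph_e")

        self.fixed_vp = [q for q in VARIANCE_QUANTITIES if q in self.fixed]
        if len(self.fixed_vp) >= 2:
            rest = 1.0 - sum(self.fixed[q] for q in self.fixed_vp)
            if rest < -1e-12:
                raise ValueError("fixed variance proportions exceed 1")

        names = ["mu"] + [f"beta{i}" for i in range(p_cov)] + ["logV"]
        if len(self.fixed_vp) == 0:
            names += ["z_vp1", "z_vp2"]
        elif len(self.fixed_vp) == 1:
            names += ["z_vp"]
        if "rg" not in self.fixed and "rph_a" not in self.fixed:
            names.append("z_rg")
        # rc is structurally unidentified when the disease profile has c2 = 0
        self.rc_free = (
            disease.c2 > 0 and "rc" not in self.fixed and "rph_c" not in self.fixed
        )
        if self.rc_free:
            names.append("z_rc")
        if "re" not in self.fixed and "rph_e" not in self.fixed:
            names.append("z_re")
        if free_disease_h2:
            names.append("z_h2d")
        self.names = names
        self.index = {n: i for i, n in enumerate(names)}

    @property
    def n_free(self) -> int:
        return len(self.names)

    def unpack(self, x: np.ndarray) -> dict | None:
        """Unconstrained vector -> natural quantities (None if infeasible)."""
        g = lambda n: x[self.index[n]]
        nat: dict = {
            "mu": g("mu"),
            "beta": np.array([g(f"beta{i}") for i in range(self.p_cov)]),
            "V": float(np.exp(np.clip(g("logV"), -300, 300))),
        }
        f = self.fixed
        if len(self.fixed_vp) == 0:
            h2 = float(expit(g("z_vp1")))
            c2 = (1.0 - h2) * float(expit(g("z_vp2")))
            e2 = 1.0 - h2 - c2
        elif len(self.fixed_vp) == 1:
            q = self.fixed_vp[0]
            t = f[q]
            share = (1.0 - t) * float(expit(g("z_vp")))
            if q == "h2":
                h2, c2, e2 = t, share, 1.0 - t - share
            elif q == "c2":
                c2, h2, e2 = t, share, 1.0 - t - share
            else:
                e2, h2, c2 = t, share, 1.0 - t - share
        else:
            h2 = f.get("h2", None)
            c2 = f.get("c2", None)
            e2 = f.get("e2", None)
            known = {k: v for k, v in (("h2", h2), ("c2", c2), ("e2", e2)) if v is not None}
            if len(known) == 2:
                missing = (set(VARIANCE_QUANTITIES) - set(known)).pop()
                known[missing] = 1.0 - sum(known.values())
            h2, c2, e2 = known["h2"], known["c2"], known["e2"]
        if min(h2, c2, e2) < -1e-12:
            return None
        nat.update(h2=max(h2, 0.0), c2=max(c2, 0.0), e2=max(e2, 0.0))

        if self.free_disease_h2:
            h2_d = float(expit(g("z_h2d")))
        else:
            h2_d = self.disease.h2
        nat["h2_d"] = h2_d

        if "rg" in f:
            nat["rg"] = f["rg"]
        elif "rph_a" in f:
            denom = np.sqrt(nat["h2"] * h2_d)
            if denom < 1e-12:
                if abs(f["rph_a"]) > 1e-12:
                    return None
                nat["rg"] = 0.0
            else:
                rg = f["rph_a"] / denom
                if abs(rg) > 1.0:
                    return None
                nat["rg"] = rg
        else:
            nat["rg"] = float(np.tanh(g("z_rg")))

        if self.rc_free:
            nat["rc"] = float(np.tanh(g("z_rc")))
        else:
            nat["rc"] = f.get("rc", 0.0)

        if "re" in f:
            nat["re"] = f["re"]
        elif "rph_e" in f:
            denom = np.sqrt(nat["e2"] * self.disease.e2)
            if denom < 1e-12:
                if abs(f["rph_e"]) > 1e-12:
                    return None
                nat["re"] = 0.0
            else:
                re = f["rph_e"] / denom
                if abs(re) > 1.0:
                    return None
                nat["re"] = re
        else:
            nat["re"] = float(np.tanh(g("z_re")))
        return nat

    def pack(self, nat: Mapping) -> np.ndarray:
        """Natural quantities -> unconstrained start vector (best effort)."""
        x = np.zeros(self.n_free)
        s = lambda n, v: x.__setitem__(self.index[n], v)
        s("mu", nat.get("mu", 0.0))
        beta = np.asarray(nat.get("beta", np.zeros(self.p_cov)))
        for i in range(self.p_cov):
            s(f"beta{i}", beta[i] if i < len(beta) else 0.0)
        s("logV", np.log(max(nat.get("V", 1.0), 1e-12)))
        h2, c2 = nat.get("h2", 0.4), nat.get("c2", 0.2)
        if len(self.fixed_vp) == 0:
            s("z_vp1", _logit_safe(h2))
            s("z_vp2", _logit_safe(c2 / max(1.0 - h2, 1e-12)))
        elif len(self.fixed_vp) == 1:
            q = self.fixed_vp[0]
            t = self.fixed[q]
            if q == "h2":
                share = c2
            else:
                share = h2
            s("z_vp", _logit_safe(share / max(1.0 - t, 1e-12)))
        if "z_rg" in self.index:
            s("z_rg", _atanh_safe(nat.get("rg", 0.0)))
        if "z_rc" in self.index:
            s("z_rc", _atanh_safe(nat.get("rc", 0.0)))
        if "z_re" in self.index:
            s("z_re", _atanh_safe(nat.get("re", 0.0)))
        if "z_h2d" in self.index:
            s("z_h2d", _logit_safe(nat.get("h2_d", self.disease.h2)))
        return x


def _params_from_natural(nat: Mapping) -> BivariateACEParams:
    v = nat["V"]
    return BivariateACEParams(
        a_x=float(np.sqrt(v * nat["h2"])),
        c_x=float(np.sqrt(v * nat["c2"])),
        e_x=float(np.sqrt(max(v * nat["e2"], 1e-300))),
        rg=nat["rg"],
        rc=nat["rc"],
        re=nat["re"],
        mu=nat["mu"],
        beta=nat["beta"],
    )


def _make_nll(prep: PreparedData, disease: DiseaseModel, layout: _Layout):
    tau = disease.tau

    def nll(x: np.ndarray) -> float:
        nat = layout.unpack(x)
        if nat is None:
            return _BIG
        if layout.free_disease_h2:
            d = DiseaseModel(
                h2=nat["h2_d"],
                c2=0.0,
                e2=1.0 - nat["h2_d"],
                prevalence=disease.prevalence,
            )
        else:
            d = disease
        params = _params_from_natural(nat)
        ll = dataset_loglik(
            prep,
            lambda r_a: expected_pair_covariance(params, d, r_a),
            tau,
            nat["mu"],
            nat["beta"],
        )
        if not np.isfinite(ll):
            return _BIG
        return -ll

    return nll


def _minimize(nll, x0: np.ndarray, maxiter: int = 300, ftol: float = 1e-12):
    return minimize(
        nll,
        x0,
        method="L-BFGS-B",
        options={"maxiter": maxiter, "ftol": ftol, "gtol": 1e-7},
    )


def _multi_start(nll, layout: _Layout, base_nat: Mapping, n_starts: int, seed: int,
                 maxiter: int = 300):
    """Deterministic multi-start local search; returns the best result."""
    rng = np.random.default_rng(seed)
    x0 = layout.pack(base_nat)
    starts = [x0]
    for _ in range(max(n_starts - 1, 0)):
        starts.append(x0 + rng.normal(0.0, 0.4, size=x0.size))
    best = None
    for xs in starts:
        res = _minimize(nll, xs, maxiter=maxiter)
        if best is None or res.fun < best.fun:
            best = res
    # restarting from the incumbent resets the Hessian approximation and
    # recovers from premature line-search termination
    polish = _minimize(nll, best.x, maxiter=maxiter)
    if polish.fun < best.fun:
        best = polish
    return best


@dataclass
class LRTRecord:
    statistic: float
    df: int
    p: float


@dataclass
class _FitContext:
    """Everything needed to re-optimise for profiles and sub-models."""

    prep: PreparedData
    disease: DiseaseModel
    base_fixed: dict
    free_disease_h2: bool
    mle_natural: dict
    seed: int


@dataclass
class FitResult:
    estimates: dict[str, float]
    beta: np.ndarray
    loglik: float
    ci: dict[str, tuple[float, float]] = field(default_factory=dict)
    ci_flags: dict[str, dict] = field(default_factory=dict)
    convergence: dict = field(default_factory=dict)
    n_pairs_used: int = 0
    fixed: dict = field(default_factory=dict)
    disease: DiseaseModel | None = None
    lrt: dict[str, LRTRecord] = field(default_factory=dict)
    _ctx: _FitContext | None = field(default=None, repr=False)

    @property
    def converged(self) -> bool:
        return bool(self.convergence.get("success", False))

    def params(self) -> BivariateACEParams:
        return _params_from_natural(self._ctx.mle_natural)


def _base_natural(prep: PreparedData) -> dict:
    """Moment-based starting values: OLS mean model, sample variance."""
    ys, xs = [], []
    for g in prep.groups:
        for j in range(len(g.iy)):
            ys.append(g.y[:, j])
            xs.append(g.x[:, j, :])
    if ys:
        y = np.concatenate(ys)
        x = np.vstack(xs)
        design = np.column_stack([np.ones_like(y), x])
        coef, *_ = np.linalg.lstsq(design, y, rcond=None)
        resid = y - design @ coef
        v = float(np.var(resid)) or 1.0
        mu, beta = float(coef[0]), coef[1:]
    else:
        mu, beta, v = 0.0, np.zeros(prep.n_covariates), 1.0
    return {"mu": mu, "beta": beta, "V": v, "h2": 0.4, "c2": 0.2, "rg": 0.0,
            "rc": 0.0, "re": 0.0}


def fit_bivariate_ace(
    ds: Dataset,
    measure: str,
    phenotype: str,
    disease: DiseaseModel,
    constraints: Mapping[str, float] | None = None,
    design: Mapping[tuple[str, int], np.ndarray] | None = None,
    n_starts: int = 5,
    seed: int = 0,
    free_disease_h2: bool = False,
    compute_ci: bool = True,
    ci_params: Sequence[str] = ("h2", "c2", "e2", "rg", "re", "rph_a"),
    ci_level: float = 0.95,
) -> FitResult:
    """Fit the bivariate ACE liability model by FIML.

    ``constraints`` pins standardized quantities (``h2``, ``c2``, ``e2``,
    ``rg``, ``rc``, ``re``, ``rph_a``, ``rph_e``) at constants, which is
    how sub-models for likelihood-ratio tests are expressed.
    """
    if ds.n_pairs == 0:
        raise ValueError("empty dataset")
    prep = prepare_data(ds, measure, phenotype, design)
    if prep.n_pairs_used == 0:
        raise ValueError("no usable pairs (no observed cognition or affection)")
    kinships = {g.r_a for g in prep.groups}
    if len(kinships) < 2:
        warnings.warn(
            "only one kinship class present; A and C are poorly separated",
            stacklevel=2,
        )

    fixed = dict(constraints or {})
    layout = _Layout(prep.n_covariates, disease, fixed, free_disease_h2)
    nll = _make_nll(prep, disease, layout)
    base_nat = _base_natural(prep)
    res = _multi_start(nll, layout, base_nat, n_starts, seed)
    nat = layout.unpack(res.x)
    if nat is None:  # pragma: no cover - optimum cannot sit on an infeasible point
        raise RuntimeError("optimiser returned an infeasible point")

    grad = approx_fprime(res.x, nll, 1.4901161193847656e-08)
    grad_norm = float(np.linalg.norm(grad))
    converged = bool(res.success) and np.isfinite(res.fun)
    if not converged:
        warnings.warn(f"fit did not converge cleanly: {res.message}", stacklevel=2)

    estimates = {
        "h2": nat["h2"], "c2": nat["c2"], "e2": nat["e2"],
        "rg": nat["rg"], "rc": nat["rc"], "re": nat["re"],
        "mu": nat["mu"], "total_variance": nat["V"],
    }
    if free_disease_h2:
        estimates["h2_d"] = nat["h2_d"]

    ctx = _FitContext(
        prep=prep,
        disease=disease,
        base_fixed=fixed,
        free_disease_h2=free_disease_h2,
        mle_natural=nat,
        seed=seed,
    )
    fit = FitResult(
        estimates=estimates,
        beta=nat["beta"],
        loglik=float(-res.fun),
        convergence={
            "success": converged,
            "grad_norm": grad_norm,
            "message": str(res.message),
            "n_starts": n_starts,
            "seed": seed,
        },
        n_pairs_used=prep.n_pairs_used,
        fixed=fixed,
        disease=disease,
        _ctx=ctx,
    )
    if compute_ci:
        for name in ci_params:
            if name in fixed:
                continue
            if name == "rc" and not layout.rc_free:
                # structurally unidentified: reported as exactly 0, no CI
                fit.ci["rc"] = (0.0, 0.0)
                fit.ci_flags["rc"] = {"fixed_structural": True}
                continue
            profile_ci(fit, name, level=ci_level)
    return fit


def _quantity_value(nat: Mapping, disease: DiseaseModel, name: str) -> float:
    if name == "rph_a":
        return nat["rg"] * float(np.sqrt(nat["h2"] * disease.h2))
    if name == "rph_e":
        return nat["re"] * float(np.sqrt(nat["e2"] * disease.e2))
    return nat[name]


def _profile_refit(ctx: _FitContext, name: str, t: float, warm_nat: Mapping):
    """Deviance of the profile at quantity == t, plus the solution."""
    fixed = dict(ctx.base_fixed)
    fixed[name] = float(t)
    layout = _Layout(ctx.prep.n_covariates, ctx.disease, fixed, ctx.free_disease_h2)
    nll = _make_nll(ctx.prep, ctx.disease, layout)

    # keep the warm start feasible under the new constraint
    warm = dict(warm_nat)
    if name in VARIANCE_QUANTITIES:
        others = [q for q in VARIANCE_QUANTITIES if q != name]
        rest = max(1.0 - t, 1e-12)
        old_rest = max(sum(warm_nat[q] for q in others), 1e-12)
        for q in others:
            warm[q] = warm_nat[q] * rest / old_rest
        warm[name] = t
    best = _minimize(nll, layout.pack(warm), maxiter=150, ftol=1e-10)
    if not np.isfinite(best.fun) or best.fun >= _BIG:
        best = _minimize(nll, layout.pack(_base_natural(ctx.prep)), maxiter=150, ftol=1e-10)
    nat = layout.unpack(best.x)
    return float(best.fun), nat


def profile_ci(
    fit: FitResult, param: str, level: float = 0.95
) -> tuple[float, float]:
    """Profile-likelihood interval for a standardized or derived quantity.

    Endpoints where the profile deviance never reaches the chi-square
    target before the parameter bound are reported at the bound and
    flagged ``at_bound`` (the printed-table "NA" convention).
    """
    if fit._ctx is None:
        raise ValueError("fit result does not carry a refit context")
    if not fit.converged:
        warnings.warn("profiling a non-converged fit", stacklevel=2)
    if param not in _BOUNDS:
        raise ValueError(f"cannot profile {param!r}")
    ctx = fit._ctx
    target = float(chi2.ppf(level, 1))
    nll_max = -fit.loglik
    mle = _quantity_value(ctx.mle_natural, ctx.disease, param)
    lo_b, hi_b = _BOUNDS[param]
    flags = {"lo_at_bound": False, "hi_at_bound": False, "unreliable": False}

    cache: dict[float, tuple[float, Mapping]] = {}

    def dev(t: float) -> float:
        t = float(t)
        if t in cache:
            return cache[t][0]
        warm = ctx.mle_natural
        if cache:
            nearest = min(cache, key=lambda u: abs(u - t))
            warm = cache[nearest][1] or ctx.mle_natural
        fun, nat = _profile_refit(ctx, param, t, warm)
        d = 2.0 * (fun - nll_max)
        if d < -1e-3:
            flags["unreliable"] = True
        d = max(d, 0.0)
        cache[t] = (d, nat)
        return d

    def endpoint(direction: int) -> float:
        bound = hi_b if direction > 0 else lo_b
        step = 0.05
        t_in = mle
        while True:
            t = mle + direction * step
            if (direction > 0 and t >= bound) or (direction < 0 and t <= bound):
                t = bound
            d = dev(t)
            if d >= target:
                lo, hi = (t_in, t) if direction > 0 else (t, t_in)
                try:
                    root = brentq(
                        lambda u: dev(u) - target, lo, hi, xtol=2e-3, maxiter=40
                    )
                except ValueError:
                    flags["unreliable"] = True
                    return t
                return float(root)
            if t == bound:
                flags["hi_at_bound" if direction > 0 else "lo_at_bound"] = True
                return bound
            t_in = t
            step *= 2.0

    lo = endpoint(-1)
    hi = endpoint(+1)
    fit.ci[param] = (lo, hi)
    fit.ci_flags[param] = flags
    return lo, hi


def likelihood_ratio_test(full: FitResult, nested: FitResult, df: int) -> LRTRecord:
    """LRT of a nested sub-model against the full model."""
    if df <= 0:
        raise ValueError("df must be >= 1")
    if nested.loglik > full.loglik + 1e-6:
        raise ValueError("nested model has higher likelihood than the full model")
    stat = max(2.0 * (full.loglik - nested.loglik), 0.0)
    return LRTRecord(statistic=stat, df=df, p=float(chi2.sf(stat, df)))


def fit_submodel(fit: FitResult, constraints: Mapping[str, float], **kwargs) -> FitResult:
    """Refit with extra fixed quantities (for the LRT battery)."""
    ctx = fit._ctx
    fixed = dict(ctx.base_fixed)
    fixed.update(constraints)
    layout = _Layout(ctx.prep.n_covariates, ctx.disease, fixed, ctx.free_disease_h2)
    nll = _make_nll(ctx.prep, ctx.disease, layout)
    n_starts = kwargs.get("n_starts", 3)
    best = _multi_start(nll, layout, ctx.mle_natural, n_starts, ctx.seed)
    nat = layout.unpack(best.x)
    estimates = {
        "h2": nat["h2"], "c2": nat["c2"], "e2": nat["e2"],
        "rg": nat["rg"], "rc": nat["rc"], "re": nat["re"],
        "mu": nat["mu"], "total_variance": nat["V"],
    }
    return FitResult(
        estimates=estimates,
        beta=nat["beta"],
        loglik=float(-best.fun),
        convergence={"success": bool(best.success), "message": str(best.message)},
        n_pairs_used=ctx.prep.n_pairs_used,
        fixed=fixed,
        disease=ctx.disease,
        _ctx=_FitContext(
            prep=ctx.prep,
            disease=ctx.disease,
            base_fixed=fixed,
            free_disease_h2=ctx.free_disease_h2,
            mle_natural=nat,
            seed=ctx.seed,
        ),
    )
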