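"""Phenotypic-correlation decomposition and the four endophenotype criteria.

The total phenotypic correlation between a cognitive measure and a
disease liability splits into additive-genetic, shared-environment and
unique-environment parts:

    rph_a = rg * sqrt(h2_x * h2_d)
    rph_c = rc * sqrt(c2_x * c2_d)
    rph_e = re * sqrt(e2_x * e2_d)
    rph   = rph_a + rph_c + rph_e

A measure qualifies as an endophenotype when (1) its within-twin
cross-trait correlation is significant, (2) its heritability is
significant and exceeds 10%, (3) its genetic correlation with the
liability is significant, and (4) rph_a is significant.  "Significant"
means the 95% CI excludes zero.  Failing criterion 1 short-circuits: the
measure is excluded from the genetic stage.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from .correlation_models import CorrelationSet
from .estimation import FitResult

__all__ = [
    "Decomposition",
    "CriteriaResult",
    "decompose_rph",
    "genetic_sharing",
    "evaluate_endophenotype",
    "round_half_away",
]

H2_THRESHOLD = 0.10


def round_half_away(x: float, ndigits: int = 2) -> float:
    """Round half away from zero (printed-table convention)."""
    factor = 10.0**ndigits
    return math.copysign(math.floor(abs(x) * factor + 0.5) / factor, x)


@dataclass
class Decomposition:
    rph_a: float
    rph_c: float
    rph_e: float
    rph: float
    ci: dict[str, tuple[float, float]] = field(default_factory=dict)
    ci_flags: dict[str, dict] = field(default_factory=dict)

    def significant(self, name: str) -> bool | None:
        if name not in self.ci:
            return None
        lo, hi = self.ci[name]
        return bool(lo > 0.0 or hi < 0.0)


def decompose_rph(
    rg: float,
    rc: float,
    re: float,
    h2_x: float,
    c2_x: float,
    e2_x: float,
    h2_d: float,
    c2_d: float,
    e2_d: float,
) -> Decomposition:
    """Split the phenotypic correlation into A/C/E contributions."""
    for label, (h2, c2, e2) in (("cognitive", (h2_x, c2_x, e2_x)),
                                ("disease", (h2_d, c2_d, e2_d))):
        if min(h2, c2, e2) < 0:
            raise ValueError(f"negative {label} variance proportion")
        if abs(h2 + c2 + e2 - 1.0) > 1e-8:
            raise ValueError(f"{label} variance proportions must sum to 1")
    for name, r in (("rg", rg), ("rc", rc), ("re", re)):
        if abs(r) > 1.0:
            raise ValueError(f"{name} outside [-1, 1]")
    rph_a = rg * math.sqrt(h2_x * h2_d)
    rph_c = rc * math.sqrt(c2_x * c2_d)
    rph_e = re * math.sqrt(e2_x * e2_d)
    return Decomposition(rph_a=rph_a, rph_c=rph_c, rph_e=rph_e,
                         rph=rph_a + rph_c + rph_e)


def decompose_fit(fit: FitResult) -> Decomposition:
    """Decomposition of a fitted bivariate ACE model, with profile CIs
    carried over where the fit computed them."""
    est = fit.estimates
    d = fit.disease
    dec = decompose_rph(
        est["rg"], est["rc"], est["re"], est["h2"], est["c2"], est["e2"],
        d.h2, d.c2, d.e2,
    )
    for name in ("rph_a", "rph_e"):
        if name in fit.ci:
            dec.ci[name] = fit.ci[name]
            dec.ci_flags[name] = fit.ci_flags.get(name, {})
    if d.c2 == 0.0:
        # rc structurally unidentified: rph_c is exactly 0 by convention
        dec.ci["rph_c"] = (0.0, 0.0)
        dec.ci_flags["rph_c"] = {"fixed_structural": True}
    return dec


def genetic_sharing(rg: float) -> int:
    """Percent of heritability shared: 100*rg^2, nearest integer."""
    if abs(rg) > 1.0:
        raise ValueError("rg outside [-1, 1]")
    return int(round_half_away(100.0 * rg * rg, 0))


@dataclass
class CriteriaResult:
    c1_phenotypic: bool | None
    c2_heritability: bool | None
    c3_rg: bool | None
    c4_rph_a: bool | None
    is_endophenotype: bool
    h2_significant: bool | None = None
    h2_above_threshold: bool | None = None
    excluded_at_c1: bool = False


def _ci_excludes_zero(ci: tuple[float, float] | None) -> bool | None:
    if ci is None:
        return None
    lo, hi = ci
    return bool(lo > 0.0 or hi < 0.0)


def evaluate_endophenotype(
    corr: CorrelationSet | None,
    fit: FitResult | None,
    dec: Decomposition | None,
) -> CriteriaResult:
    """Apply the four criteria; indeterminate inputs fail the conjunction.

    ``fit`` and ``dec`` may be None when criterion 1 already failed and
    the genetic stage was skipped.
    """
    c1 = corr.significant("r_wtct") if corr is not None else None
    if c1 is not True:
        return CriteriaResult(
            c1_phenotypic=c1, c2_heritability=None, c3_rg=None, c4_rph_a=None,
            is_endophenotype=False, excluded_at_c1=True,
        )

    h2_sig = _ci_excludes_zero(fit.ci.get("h2")) if fit is not None else None
    h2_above = (fit.estimates["h2"] > H2_THRESHOLD) if fit is not None else None
    c2 = None if (h2_sig is None or h2_above is None) else (h2_sig and h2_above)
    c3 = _ci_excludes_zero(fit.ci.get("rg")) if fit is not None else None
    c4 = dec.significant("rph_a") if dec is not None else None

    is_endo = all(flag is True for flag in (c2, c3, c4))
    return CriteriaResult(
        c1_phenotypic=True,
        c2_heritability=c2,
        c3_rg=c3,
        c4_rph_a=c4,
        is_endophenotype=is_endo,
        h2_significant=h2_sig,
        h2_above_threshold=h2_above,
    )
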