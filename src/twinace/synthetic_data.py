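"""Twin/sibling cohort simulator matching the analysis model exactly.

Latent structure per pair and trait block (cognition x, liability d):

* A factors correlate ``R_A`` across members and ``rg`` across traits,
* C factors are shared within a pair and correlate ``rc`` across traits,
* E factors are member-specific and correlate ``re`` across traits.

Affection is ``liability > tau``.  Covariates shift the cognitive mean
only.  The ascertainment scheme is stratified pair selection: requested
numbers of concordant-affected, discordant and screened control pairs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .core_data import Dataset, MemberRecord, PairRecord
from .liability_model import BivariateACEParams, DiseaseModel, kinship_coefficient

__all__ = ["SimConfig", "simulate_population", "ascertain_study_sample",
           "paper_like_composition"]


@dataclass(frozen=True)
class CovariateEffects:
    """Linear effects on the cognitive mean (age/education are centred)."""

    age: float = 0.0
    sex: float = 0.0
    education: float = 0.0
    centre: Mapping[str, float] = field(default_factory=dict)


@dataclass(frozen=True)
class SimConfig:
    n_pairs: Mapping[str, int]          # per zygosity class, e.g. {"MZ": 500, ...}
    truth: BivariateACEParams
    disease: DiseaseModel
    seed: int
    measure_name: str = "score"
    phenotype_name: str = "SZ"
    covariate_effects: CovariateEffects = CovariateEffects()
    centre_proportions: Mapping[str, float] = field(
        default_factory=lambda: {"A": 1.0}
    )
    missing_measure_rate: float = 0.0
    missing_affection_rate: float = 0.0
    generate_covariates: bool = True
    ascertainment: str = "population"   # or "proband_selected"
    target_composition: Mapping[str, int] | None = None

    def __post_init__(self) -> None:
        if any(n < 0 for n in self.n_pairs.values()):
            raise ValueError("pair counts must be non-negative")
        total = sum(self.centre_proportions.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError("centre proportions must sum to 1")
        if self.seed is None:
            raise ValueError("seed is mandatory")


def _check_feasible(cfg: SimConfig) -> None:
    """Reject cross-trait correlation structures that are not PSD."""
    from .liability_model import expected_pair_covariance

    for zyg in cfg.n_pairs:
        expected_pair_covariance(cfg.truth, cfg.disease, kinship_coefficient(zyg))


def _corr2(rng: np.random.Generator, r: float, n: int) -> np.ndarray:
    """n draws of a 2-vector with unit variances and correlation r."""
    z = rng.standard_normal((n, 2))
    out = np.empty_like(z)
    out[:, 0] = z[:, 0]
    out[:, 1] = r * z[:, 0] + np.sqrt(max(1.0 - r * r, 0.0)) * z[:, 1]
    return out


def simulate_population(cfg: SimConfig) -> Dataset:
    """Draw a population (non-ascertained) twin/sibling cohort."""
    _check_feasible(cfg)
    rng = np.random.default_rng(cfg.seed)
    t = cfg.truth
    d = cfg.disease
    tau = d.tau
    sd_x = np.array([t.a_x, t.c_x, t.e_x])
    sd_d = np.sqrt(np.array([d.h2, d.c2, d.e2]))
    eff = cfg.covariate_effects
    centres = sorted(cfg.centre_proportions)
    centre_p = np.array([cfg.centre_proportions[c] for c in centres])

    pairs = []
    counter = 0
    for zyg in sorted(cfg.n_pairs):
        n = cfg.n_pairs[zyg]
        if n == 0:
            continue
        r_a = kinship_coefficient(zyg)

        # A: shared + member-specific mixture reproduces the Kronecker structure
        a_shared = _corr2(rng, t.rg, n)
        a_ind = [_corr2(rng, t.rg, n) for _ in range(2)]
        a = [
            np.sqrt(r_a) * a_shared + np.sqrt(1.0 - r_a) * a_ind[j]
            for j in range(2)
        ]
        c_shared = _corr2(rng, t.rc, n)
        c = [c_shared, c_shared]
        e = [_corr2(rng, t.re, n) for _ in range(2)]

        y = np.empty((n, 2))
        liab = np.empty((n, 2))
        for j in range(2):
            y[:, j] = t.mu + sd_x[0] * a[j][:, 0] + sd_x[1] * c[j][:, 0] + sd_x[2] * e[j][:, 0]
            liab[:, j] = sd_d[0] * a[j][:, 1] + sd_d[1] * c[j][:, 1] + sd_d[2] * e[j][:, 1]

        if cfg.generate_covariates:
            age1 = rng.uniform(16.0, 65.0, n)
            if zyg == "SIB":
                age2 = np.clip(
                    age1 + rng.choice([-1.0, 1.0], n) * rng.normal(3.6, 3.0, n),
                    16.0, 65.0,
                )
            else:
                age2 = age1
            sex1 = rng.integers(0, 2, n)
            sex2 = sex1 if zyg == "MZ" else rng.integers(0, 2, n)
            edu = np.clip(rng.normal(13.0, 2.5, (n, 2)), 6.0, 22.0)
            centre = rng.choice(centres, n, p=centre_p)
            ages = np.column_stack([age1, age2])
            sexes = np.column_stack([sex1, sex2])
            # effects are defined on centred age/education (means 40.5 / 13)
            for j in range(2):
                y[:, j] += (
                    eff.age * (ages[:, j] - 40.5)
                    + eff.sex * sexes[:, j]
                    + eff.education * (edu[:, j] - 13.0)
                )
            y += np.array(
                [eff.centre.get(c0, 0.0) for c0 in centre]
            )[:, None]
        else:
            ages = sexes = edu = None
            centre = [None] * n

        affected = (liab > tau).astype(int)
        miss_y = rng.random((n, 2)) < cfg.missing_measure_rate
        miss_d = rng.random((n, 2)) < cfg.missing_affection_rate

        for i in range(n):
            members = []
            for j in range(2):
                members.append(
                    MemberRecord(
                        member_index=j + 1,
                        affected={
                            cfg.phenotype_name: None
                            if miss_d[i, j]
                            else int(affected[i, j])
                        },
                        cognitive_scores={
                            cfg.measure_name: None if miss_y[i, j] else float(y[i, j])
                        },
                        age=None if ages is None else float(ages[i, j]),
                        sex=None if sexes is None else int(sexes[i, j]),
                        education=None if edu is None else float(edu[i, j]),
                        centre=centre[i],
                    )
                )
            pairs.append(
                PairRecord(
                    pair_id=f"{zyg}{counter:06d}",
                    zygosity=zyg,
                    members=tuple(members),
                )
            )
            counter += 1

    return Dataset(
        pairs=tuple(pairs),
        measure_names=(cfg.measure_name,),
        phenotype_names=(cfg.phenotype_name,),
    )


def classify_pair(pair: PairRecord, phenotype: str) -> str | None:
    """'concordant' / 'discordant' / 'control' for complete pairs, else None."""
    flags = [m.affected.get(phenotype) for m in pair.members]
    if len(flags) != 2 or any(f is None for f in flags):
        return None
    total = sum(flags)
    return {0: "control", 1: "discordant", 2: "concordant"}[total]


def ascertain_study_sample(pop: Dataset, cfg: SimConfig) -> Dataset:
    """Stratified selection of concordant / discordant / control pairs."""
    targets = dict(cfg.target_composition or {})
    unknown = set(targets) - {"concordant", "discordant", "control"}
    if unknown:
        raise ValueError(f"unknown strata {sorted(unknown)}")
    rng = np.random.default_rng(cfg.seed + 1)
    by_stratum: dict[str, list[PairRecord]] = {
        "concordant": [], "discordant": [], "control": []
    }
    for pair in pop.pairs:
        cls = classify_pair(pair, cfg.phenotype_name)
        if cls is not None:
            by_stratum[cls].append(pair)

    chosen: list[PairRecord] = []
    for stratum in ("concordant", "discordant", "control"):
        want = int(targets.get(stratum, 0))
        have = by_stratum[stratum]
        if want > len(have):
            raise ValueError(
                f"insufficient {stratum} pairs: need {want}, have {len(have)}"
            )
        idx = rng.choice(len(have), size=want, replace=False)
        chosen.extend(have[i] for i in sorted(idx))

    chosen.sort(key=lambda p: p.pair_id)
    return Dataset(
        pairs=tuple(chosen),
        measure_names=pop.measure_names,
        phenotype_names=pop.phenotype_names,
    )


def paper_like_composition(scale: float = 1.0) -> dict[str, int]:
    """Study-like stratified pair composition (~460 pairs at scale 1).

    Roughly: a majority of screened control pairs, a large discordant
    stratum and a modest concordant stratum.
    """
    base = {"concordant": 55, "discordant": 130, "control": 280}
    return {k: max(int(round(v * scale)), 1) for k, v in base.items()}
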