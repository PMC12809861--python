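"""Pair-structured twin/sibling cohort data: records, I/O, filters, covariates.

One CSV row per individual.  Required columns are ``pair_id``,
``member_index`` and ``zygosity``; everything else (affection flags,
cognitive measures, covariates) is optional and missing cells stay
missing — they are never coerced to zero.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

VALID_ZYGOSITIES = ("MZ", "DZ", "SIB")

#: column names understood without a schema mapping
REQUIRED_COLUMNS = ("pair_id", "member_index", "zygosity")
COVARIATE_COLUMNS = ("age", "sex", "education", "centre")


class DataError(ValueError):
    """Structural problem in an input table (duplicates, bad codes...)."""


def _opt_float(value) -> float | None:
    if value is None:
        return None
    if isinstance(value, str):
        value = value.strip()
        if value in ("", "NA"):
            return None
        value = float(value)
    if isinstance(value, float) and math.isnan(value):
        return None
    return float(value)


def _opt_binary(value, column: str) -> int | None:
    v = _opt_float(value)
    if v is None:
        return None
    if v not in (0.0, 1.0):
        raise DataError(f"column {column!r}: expected 0/1 or missing, got {value!r}")
    return int(v)


@dataclass(frozen=True)
class MemberRecord:
    """One individual within a pair."""

    member_index: int
    affected: Mapping[str, int | None] = field(default_factory=dict)
    cognitive_scores: Mapping[str, float | None] = field(default_factory=dict)
    age: float | None = None
    sex: int | None = None
    education: float | None = None
    centre: str | None = None

    def __post_init__(self) -> None:
        if self.member_index not in (1, 2):
            raise DataError(f"member_index must be 1 or 2, got {self.member_index}")
        for name, flag in self.affected.items():
            if flag is not None and flag not in (0, 1):
                raise DataError(f"affection {name!r} must be 0/1 or missing")

    def has_data(self) -> bool:
        """True when at least one affection flag or cognitive score is observed."""
        return any(v is not None for v in self.affected.values()) or any(
            v is not None for v in self.cognitive_scores.values()
        )


@dataclass(frozen=True)
class PairRecord:
    pair_id: str
    zygosity: str
    members: tuple[MemberRecord, ...]

    def __post_init__(self) -> None:
        if self.zygosity not in VALID_ZYGOSITIES:
            raise DataError(
                f"pair {self.pair_id}: unknown zygosity {self.zygosity!r} "
                f"(expected one of {VALID_ZYGOSITIES})"
            )
        if len(self.members) > 2:
            raise DataError(f"pair {self.pair_id}: more than two members")
        idx = [m.member_index for m in self.members]
        if len(set(idx)) != len(idx):
            raise DataError(f"pair {self.pair_id}: duplicate member_index")

    def member(self, index: int) -> MemberRecord | None:
        for m in self.members:
            if m.member_index == index:
                return m
        return None


@dataclass(frozen=True)
class Dataset:
    pairs: tuple[PairRecord, ...]
    measure_names: tuple[str, ...]
    phenotype_names: tuple[str, ...]

    def __post_init__(self) -> None:
        ids = [p.pair_id for p in self.pairs]
        if len(set(ids)) != len(ids):
            raise DataError("pair_ids are not unique")
        for p in self.pairs:
            for m in p.members:
                unknown = set(m.cognitive_scores) - set(self.measure_names)
                if unknown:
                    raise DataError(
                        f"pair {p.pair_id}: unknown measures {sorted(unknown)}"
                    )

    @property
    def n_pairs(self) -> int:
        return len(self.pairs)

    @property
    def n_members(self) -> int:
        return sum(len(p.members) for p in self.pairs)

    def members(self) -> Iterable[tuple[PairRecord, MemberRecord]]:
        for p in self.pairs:
            for m in p.members:
                yield p, m


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def _affection_columns(columns: Sequence[str]) -> dict[str, str]:
    """Map phenotype name -> column for columns named ``affected_<name>``."""
    out = {}
    for col in columns:
        if col.startswith("affected_"):
            out[col[len("affected_"):].upper()] = col
    return out


def read_dataset(
    path,
    schema: Mapping[str, str] | None = None,
    measure_columns: Sequence[str] | None = None,
) -> Dataset:
    """Read a one-row-per-individual CSV into a :class:`Dataset`.

    Parameters
    ----------
    path:
        CSV file path.
    schema:
        Optional mapping from canonical column names (``pair_id`` ...)
        to the actual column names in the file.
    measure_columns:
        Columns holding cognitive scores.  Defaults to every column not
        otherwise recognised (id/zygosity/affection/covariates).
    """
    df = pd.read_csv(path, dtype={"pair_id": str}, na_values=["NA"], keep_default_na=True)
    if schema:
        df = df.rename(columns={v: k for k, v in schema.items()})
    for col in REQUIRED_COLUMNS:
        if col not in df.columns:
            raise DataError(f"missing required column {col!r}")

    dup = df.duplicated(subset=["pair_id", "member_index"])
    if dup.any():
        row = df[dup].iloc[0]
        raise DataError(
            f"duplicate (pair_id={row['pair_id']}, member_index={row['member_index']})"
        )

    aff_cols = _affection_columns(df.columns)
    if measure_columns is None:
        known = set(REQUIRED_COLUMNS) | set(COVARIATE_COLUMNS) | set(aff_cols.values())
        measure_columns = [c for c in df.columns if c not in known]

    pairs = []
    for pair_id, grp in df.groupby("pair_id", sort=True):
        zygosities = grp["zygosity"].unique()
        if len(zygosities) != 1:
            raise DataError(f"pair {pair_id}: inconsistent zygosity codes")
        members = []
        for _, row in grp.iterrows():
            members.append(
                MemberRecord(
                    member_index=int(row["member_index"]),
                    affected={
                        name: _opt_binary(row[col], col) for name, col in aff_cols.items()
                    },
                    cognitive_scores={
                        c: _opt_float(row[c]) for c in measure_columns
                    },
                    age=_opt_float(row.get("age")),
                    sex=None if _opt_float(row.get("sex")) is None else int(row["sex"]),
                    education=_opt_float(row.get("education")),
                    centre=None if pd.isna(row.get("centre")) else str(row["centre"]),
                )
            )
        members.sort(key=lambda m: m.member_index)
        pairs.append(PairRecord(pair_id=str(pair_id), zygosity=str(zygosities[0]), members=tuple(members)))

    return Dataset(
        pairs=tuple(pairs),
        measure_names=tuple(measure_columns),
        phenotype_names=tuple(sorted(aff_cols)),
    )


def to_frame(ds: Dataset) -> pd.DataFrame:
    """Flatten a Dataset back to the one-row-per-individual table."""
    rows = []
    for p, m in ds.members():
        row: dict = {
            "pair_id": p.pair_id,
            "member_index": m.member_index,
            "zygosity": p.zygosity,
        }
        for name in ds.phenotype_names:
            row[f"affected_{name.lower()}"] = m.affected.get(name)
        for name in ds.measure_names:
            row[name] = m.cognitive_scores.get(name)
        row["age"] = m.age
        row["sex"] = m.sex
        row["education"] = m.education
        row["centre"] = m.centre
        rows.append(row)
    return pd.DataFrame(rows)


def write_dataset(ds: Dataset, path) -> None:
    to_frame(ds).to_csv(path, index=False, na_rep="")


# ---------------------------------------------------------------------------
# Inclusion filters
# ---------------------------------------------------------------------------

def apply_inclusion_filters(
    ds: Dataset,
    min_iq: float = 70.0,
    age_range: tuple[float, float] = (16.0, 65.0),
    iq_measure: str = "iq",
) -> tuple[Dataset, dict[str, int]]:
    """Drop members failing IQ / age inclusion rules; keep their co-twin.

    Returns the filtered dataset and an exclusion log counting removed
    members by reason (``iq``, ``age``).  A member failing both rules is
    counted once, under ``iq``.  Members with the relevant field missing
    are retained.
    """
    log = {"iq": 0, "age": 0}
    new_pairs = []
    for p in ds.pairs:
        kept = []
        for m in p.members:
            iq = m.cognitive_scores.get(iq_measure)
            if iq is not None and iq < min_iq:
                log["iq"] += 1
                continue
            if m.age is not None and not (age_range[0] <= m.age <= age_range[1]):
                log["age"] += 1
                continue
            kept.append(m)
        if kept:
            new_pairs.append(replace(p, members=tuple(kept)))
    out = Dataset(
        pairs=tuple(new_pairs),
        measure_names=ds.measure_names,
        phenotype_names=ds.phenotype_names,
    )
    return out, log


def write_exclusion_log(log: Mapping[str, int], path) -> None:
    with open(path, "w") as fh:
        json.dump({**log, "total": int(sum(log.values()))}, fh, indent=2, sort_keys=True)


# ---------------------------------------------------------------------------
# Covariate encoding
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CovariateEncoder:
    """Design-matrix builder: centred age/education, 0/1 sex, K-1 centre dummies.

    Centering constants and the centre level set are frozen at fit time so
    that the same encoding can be re-applied to new members.
    """

    age_mean: float
    education_mean: float
    centre_levels: tuple[str, ...]  # non-reference levels, fixed order
    reference_centre: str | None

    @property
    def names(self) -> tuple[str, ...]:
        return ("age", "sex", "education") + tuple(
            f"centre[{c}]" for c in self.centre_levels
        )

    def encode_member(self, m: MemberRecord) -> np.ndarray:
        """Row of covariate values; missing covariates encode as 0 (mean)."""
        row = np.zeros(3 + len(self.centre_levels))
        if m.age is not None:
            row[0] = m.age - self.age_mean
        if m.sex is not None:
            row[1] = float(m.sex)
        if m.education is not None:
            row[2] = m.education - self.education_mean
        if m.centre is not None:
            if m.centre != self.reference_centre and m.centre not in self.centre_levels:
                raise DataError(f"unseen centre label {m.centre!r}")
            for k, c in enumerate(self.centre_levels):
                if m.centre == c:
                    row[3 + k] = 1.0
        return row


def encode_covariates(
    ds: Dataset, reference_centre: str | None = None
) -> tuple[CovariateEncoder, dict[tuple[str, int], np.ndarray]]:
    """Build the member-level design.

    Returns the fitted encoder plus a mapping
    ``(pair_id, member_index) -> covariate row``.
    """
    ages = [m.age for _, m in ds.members() if m.age is not None]
    edus = [m.education for _, m in ds.members() if m.education is not None]
    centres = sorted({m.centre for _, m in ds.members() if m.centre is not None})
    if reference_centre is None:
        reference_centre = centres[0] if centres else None
    elif centres and reference_centre not in centres:
        raise DataError(f"reference centre {reference_centre!r} not in data")
    enc = CovariateEncoder(
        age_mean=float(np.mean(ages)) if ages else 0.0,
        education_mean=float(np.mean(edus)) if edus else 0.0,
        centre_levels=tuple(c for c in centres if c != reference_centre),
        reference_centre=reference_centre,
    )
    design = {
        (p.pair_id, m.member_index): enc.encode_member(m) for p, m in ds.members()
    }
    return enc, design
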