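"""Candidate-pair construction (blocking) and per-pair comparison vectors.

The candidate-pair space is either the full cross product of the two
registers or the union of within-block cross products for a blocking key
(conventionally the baby's date of birth, so each day of episode data is
examined against the cohort at a time).  Records missing the key may be
paired against the whole opposite register (``compare_all``, the default —
they must stay reachable) or dropped.

Each candidate pair yields a comparison vector: per included field the
outcome is agree (1), disagree (0) or missing (either value absent).
Comparators are exact equality; there is no fuzzy matching.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Mapping

import numpy as np
import pandas as pd

from perilink.records import RECORD_FIELDS, RecordSet

COMPARATORS = ("exact", "date_exact", "category_exact")

#: Outcome encoding in the bulk matrix.
AGREE, DISAGREE, MISSING = 1.0, 0.0, np.nan


@dataclass(frozen=True)
class FieldSpec:
    """One matching variable and how to compare it."""

    name: str
    comparator: str = "exact"
    include: bool = True

    def __post_init__(self) -> None:
        if self.name not in RECORD_FIELDS:
            raise ValueError(f"{self.name!r} is not a record field")
        if self.comparator not in COMPARATORS:
            raise ValueError(f"unknown comparator {self.comparator!r}")


def default_specs(fields: list[str]) -> list[FieldSpec]:
    """Exact-equality specs for the given field names."""
    return [FieldSpec(f) for f in fields]


@dataclass
class PairIndex:
    """Candidate pairs between the two registers.

    ``pairs`` has columns ``cohort_id`` and ``episode_id`` (plus ``block``
    for audit when blocking was used); ``total_possible`` is the full
    cross-product size |cohort|·|episodes|.
    """

    pairs: pd.DataFrame
    blocking_key: str | None
    total_possible: int

    def __len__(self) -> int:
        return len(self.pairs)


def all_pairs(cohort: RecordSet, episodes: RecordSet) -> PairIndex:
    """Full cross-product pair index (no blocking)."""
    a = cohort.ids.to_numpy()
    b = episodes.ids.to_numpy()
    pairs = pd.DataFrame(
        {
            "cohort_id": np.repeat(a, len(b)),
            "episode_id": np.tile(b, len(a)),
        }
    )
    return PairIndex(pairs, blocking_key=None, total_possible=len(a) * len(b))


def block_pairs(
    cohort: RecordSet,
    episodes: RecordSet,
    key: str = "date_of_birth",
    missing_policy: str = "compare_all",
) -> PairIndex:
    """Pair records sharing a blocking-key value.

    Records missing the key are crossed with the entire opposite register
    under ``missing_policy="compare_all"`` or left unpaired under
    ``"drop"``.  The result has no duplicate pairs.
    """
    if key not in RECORD_FIELDS:
        raise ValueError(f"{key!r} is not a record field")
    if missing_policy not in ("compare_all", "drop"):
        raise ValueError(f"unknown missing_policy {missing_policy!r}")

    ca = cohort.df[[cohort.id_field, key]].rename(
        columns={cohort.id_field: "cohort_id", key: "block"}
    )
    ep = episodes.df[[episodes.id_field, key]].rename(
        columns={episodes.id_field: "episode_id", key: "block"}
    )
    matched = ca.dropna(subset=["block"]).merge(
        ep.dropna(subset=["block"]), on="block", how="inner"
    )[["cohort_id", "episode_id", "block"]]

    parts = [matched]
    if missing_policy == "compare_all":
        miss_c = ca.loc[ca["block"].isna(), "cohort_id"].to_numpy()
        if len(miss_c):
            parts.append(
                pd.DataFrame(
                    {
                        "cohort_id": np.repeat(miss_c, len(episodes)),
                        "episode_id": np.tile(episodes.ids.to_numpy(), len(miss_c)),
                        "block": pd.NaT if key in ("date_of_birth",) else np.nan,
                    }
                )
            )
        miss_e = ep.loc[ep["block"].isna(), "episode_id"].to_numpy()
        if len(miss_e):
            parts.append(
                pd.DataFrame(
                    {
                        "cohort_id": np.tile(cohort.ids.to_numpy(), len(miss_e)),
                        "episode_id": np.repeat(miss_e, len(cohort)),
                        "block": pd.NaT if key in ("date_of_birth",) else np.nan,
                    }
                )
            )
    pairs = pd.concat(parts, ignore_index=True).drop_duplicates(
        subset=["cohort_id", "episode_id"], keep="first"
    )
    return PairIndex(
        pairs.reset_index(drop=True),
        blocking_key=key,
        total_possible=len(cohort) * len(episodes),
    )


@dataclass
class ComparisonVector:
    """Per-field agree/disagree/missing outcomes for one candidate pair.

    ``outcomes`` maps field name to 1 (agree), 0 (disagree) or None
    (missing: either value absent).
    """

    pair: tuple
    outcomes: dict

    def __getitem__(self, fld: str):
        return self.outcomes[fld]


@dataclass
class ComparisonVectors:
    """Bulk container: one row per pair, one column per included field.

    ``matrix`` is float with 1.0 agree / 0.0 disagree / NaN missing, the
    form all three scorers consume.
    """

    pairs: pd.DataFrame  # columns cohort_id, episode_id
    fields: list[str]
    matrix: np.ndarray

    def __len__(self) -> int:
        return len(self.pairs)

    def __iter__(self) -> Iterator[ComparisonVector]:
        cid = self.pairs["cohort_id"].to_numpy()
        eid = self.pairs["episode_id"].to_numpy()
        for i in range(len(self)):
            out = {
                f: (None if np.isnan(v) else int(v))
                for f, v in zip(self.fields, self.matrix[i])
            }
            yield ComparisonVector(pair=(cid[i], eid[i]), outcomes=out)

    def to_frame(self) -> pd.DataFrame:
        out = self.pairs.copy()
        for j, f in enumerate(self.fields):
            out[f] = self.matrix[:, j]
        return out


def _value(rec: Mapping, fld: str):
    v = rec.get(fld) if hasattr(rec, "get") else rec[fld]
    if v is None or (isinstance(v, float) and np.isnan(v)) or v is pd.NaT or v is pd.NA:
        return None
    return v


def compare_pair(a: Mapping, b: Mapping, specs: list[FieldSpec]) -> ComparisonVector:
    """Compare one record pair field by field.

    Outcome per field: missing if either value is missing; agree if the
    comparator deems the values equal; disagree otherwise.
    """
    included = [s for s in specs if s.include]
    if not included:
        raise ValueError("no included fields to compare")
    out: dict = {}
    for s in included:
        va, vb = _value(a, s.name), _value(b, s.name)
        if va is None or vb is None:
            out[s.name] = None
        else:
            out[s.name] = int(va == vb)
    ida = a.get("id", None) if hasattr(a, "get") else None
    idb = b.get("id", None) if hasattr(b, "get") else None
    return ComparisonVector(pair=(ida, idb), outcomes=out)


def compare_pairs(
    cohort: RecordSet,
    episodes: RecordSet,
    index: PairIndex,
    specs: list[FieldSpec],
) -> ComparisonVectors:
    """Vectorised comparison of every pair in ``index``."""
    included = [s for s in specs if s.include]
    if not included:
        raise ValueError("no included fields to compare")
    fields = [s.name for s in included]

    cdf = cohort.df.set_index(cohort.id_field)
    edf = episodes.df.set_index(episodes.id_field)
    crows = cdf.loc[index.pairs["cohort_id"]]
    erows = edf.loc[index.pairs["episode_id"]]

    n = len(index.pairs)
    matrix = np.full((n, len(fields)), np.nan)
    for j, f in enumerate(fields):
        va = crows[f].to_numpy() if f in crows else np.full(n, np.nan, dtype=object)
        vb = erows[f].to_numpy() if f in erows else np.full(n, np.nan, dtype=object)
        ma = pd.isna(va)
        mb = pd.isna(vb)
        ok = ~(ma | mb)
        eq = np.zeros(n, dtype=bool)
        eq[ok] = va[ok] == vb[ok]
        col = matrix[:, j]
        col[ok] = eq[ok].astype(float)
    return ComparisonVectors(
        pairs=index.pairs[["cohort_id", "episode_id"]].reset_index(drop=True),
        fields=fields,
        matrix=matrix,
    )
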