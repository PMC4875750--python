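"""Threshold tabulation, candidate merging and iterative clerical review.

Cut-off tables show, per candidate threshold, how many scored pairs lie
strictly above it and how many distinct identifiers from each register
they involve — the information used to pick a review threshold.  Candidate
pairs retained from several algorithm runs are merged into one set of
unique pairs, then resolved by an iterative review: a confirmed pair
removes every other candidate sharing either identifier, and rounds
alternate between grouping by cohort and by episode identifier until a
round confirms nothing.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd


def _as_frame(sps) -> pd.DataFrame:
    """Accept a DataFrame or an iterable of ScoredPair-like objects."""
    if isinstance(sps, pd.DataFrame):
        return sps
    return pd.DataFrame(
        [
            {
                "cohort_id": s.cohort_id,
                "episode_id": s.episode_id,
                "weight": s.weight,
                "algorithm": getattr(s, "algorithm", ""),
            }
            for s in sps
        ],
        columns=["cohort_id", "episode_id", "weight", "algorithm"],
    )


def threshold_table(
    sps, cutoffs, sizes: tuple[int, int]
) -> pd.DataFrame:
    """Tabulate pair and unique-identifier counts above each cutoff.

    Inclusion is strict (weight > cutoff).  ``sizes`` is (n_cohort,
    n_episodes), the denominators of the percentage columns (2 dp).
    """
    cutoffs = list(cutoffs)
    if cutoffs != sorted(cutoffs):
        raise ValueError("cutoffs must be sorted ascending")
    df = _as_frame(sps)
    n_cohort, n_episodes = sizes
    rows = []
    for c in cutoffs:
        above = df[df["weight"] > c]
        ncu = above["cohort_id"].nunique()
        neu = above["episode_id"].nunique()
        rows.append(
            {
                "cutoff": c,
                "n_pairs": len(above),
                "n_cohort_ids": ncu,
                "pct_cohort": round(100.0 * ncu / n_cohort, 2) if n_cohort else float("nan"),
                "n_episode_ids": neu,
                "pct_episodes": round(100.0 * neu / n_episodes, 2) if n_episodes else float("nan"),
            }
        )
    return pd.DataFrame(rows)


def unique_matches(sps, cutoff: float) -> int:
    """Pairs above the cutoff whose two identifiers each occur exactly once
    among the pairs above the cutoff — the uniquely matched pairs."""
    df = _as_frame(sps)
    above = df[df["weight"] > cutoff]
    if above.empty:
        return 0
    c_once = above["cohort_id"].map(above["cohort_id"].value_counts()) == 1
    e_once = above["episode_id"].map(above["episode_id"].value_counts()) == 1
    return int((c_once & e_once).sum())


def merge_candidates(runs) -> pd.DataFrame:
    """Union of candidate pairs across algorithm runs.

    Each pair appears once; per-run weights are kept in columns named
    ``weight_<algorithm>`` (or ``weight_<i>`` for unlabelled runs) for
    review display.
    """
    frames = []
    for i, run in enumerate(runs):
        df = _as_frame(run)
        if "algorithm" in df.columns and df["algorithm"].nunique() == 1 and len(df):
            label = str(df["algorithm"].iloc[0]) or str(i)
        else:
            label = str(i)
        dedup = (
            df[["cohort_id", "episode_id", "weight"]]
            .groupby(["cohort_id", "episode_id"], as_index=False)["weight"]
            .max()  # a pair scored twice in one run keeps its best weight
        )
        frames.append(dedup.rename(columns={"weight": f"weight_{label}"}))
    if not frames:
        return pd.DataFrame(columns=["cohort_id", "episode_id"])
    out = frames[0]
    for f in frames[1:]:
        out = out.merge(f, on=["cohort_id", "episode_id"], how="outer")
    weight_cols = [c for c in out.columns if c.startswith("weight_")]
    out["max_weight"] = out[weight_cols].max(axis=1)
    return out.sort_values(
        ["max_weight", "cohort_id", "episode_id"], ascending=[False, True, True]
    ).reset_index(drop=True)


@dataclass
class ReviewResult:
    """Outcome of an iterative clerical review."""

    confirmed: set          # accepted (cohort_id, episode_id) pairs; 1:1
    unresolved: set         # candidates the oracle could not decide
    rejected: set           # candidates the oracle declared non-matches
    removed: set = field(default_factory=set)  # dropped because a confirmed pair shared an id
    rounds: int = 0
    complete: bool = True   # False when max_rounds was exhausted

    def __post_init__(self) -> None:
        confirmed_c = {c for c, _ in self.confirmed}
        confirmed_e = {e for _, e in self.confirmed}
        if len(confirmed_c) != len(self.confirmed) or len(confirmed_e) != len(self.confirmed):
            raise ValueError("confirmed pairs are not a 1:1 matching")
        for c, e in self.unresolved:
            if c in confirmed_c or e in confirmed_e:
                raise ValueError("unresolved pair shares an id with a confirmed pair")


def clerical_review(candidates, oracle, max_rounds: int = 25) -> ReviewResult:
    """Resolve candidate pairs by iterative adjudication.

    ``candidates`` is a DataFrame (cohort_id, episode_id, optional weight
    columns) or an iterable of pairs.  ``oracle`` is a callable mapping a
    pair to True (match), False (non-match) or None (cannot tell); a
    :class:`~perilink.synthetic.TruthMap` supplies one via ``.oracle()``.

    Pairs are visited in descending weight order (ties broken by
    identifiers); rounds alternate between cohort-grouped and
    episode-grouped views of the remaining duplicates.  Confirming a pair
    removes every other candidate sharing either of its identifiers.  The
    procedure stops when a round confirms nothing (or after
    ``max_rounds``, flagged incomplete); whatever remains undecided is
    returned unresolved.
    """
    if isinstance(candidates, pd.DataFrame):
        df = candidates.copy()
        weight_cols = [c for c in df.columns if c.startswith("weight") or c == "max_weight"]
        if weight_cols:
            df["_order"] = -df[weight_cols].max(axis=1).fillna(float("-inf"))
        else:
            df["_order"] = 0.0
        ordered = [
            (r.cohort_id, r.episode_id)
            for r in df.sort_values(
                ["_order", "cohort_id", "episode_id"]
            ).itertuples()
        ]
    else:
        ordered = sorted({tuple(p) for p in candidates})

    remaining: list[tuple] = list(dict.fromkeys(ordered))
    confirmed: set = set()
    rejected: set = set()
    removed: set = set()
    taken_c: set = set()
    taken_e: set = set()

    rounds = 0
    complete = True
    while remaining:
        if rounds >= max_rounds:
            complete = False
            break
        group_by_cohort = rounds % 2 == 0
        rounds += 1
        confirmed_this_round = 0

        # group the remaining candidates by one register's identifier and
        # review each group's rows in candidate order
        keyfn = (lambda p: p[0]) if group_by_cohort else (lambda p: p[1])
        groups: dict = {}
        for p in remaining:
            groups.setdefault(keyfn(p), []).append(p)

        still: list[tuple] = []
        decided_true: set = set()
        for key in sorted(groups, key=str):
            for p in groups[key]:
                if p[0] in taken_c or p[1] in taken_e:
                    removed.add(p)
                    continue
                verdict = oracle(p)
                if verdict is True:
                    confirmed.add(p)
                    decided_true.add(p)
                    taken_c.add(p[0])
                    taken_e.add(p[1])
                    confirmed_this_round += 1
                elif verdict is False:
                    rejected.add(p)
                else:
                    still.append(p)
        # propagate removals into the kept list
        remaining = []
        for p in still:
            if p[0] in taken_c or p[1] in taken_e:
                removed.add(p)
            else:
                remaining.append(p)
        if confirmed_this_round == 0:
            break

    return ReviewResult(
        confirmed=confirmed,
        unresolved=set(remaining),
        rejected=rejected,
        removed=removed,
        rounds=rounds,
        complete=complete,
    )
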