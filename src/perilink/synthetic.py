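"""Synthetic paired registers with a known truth map.

The generator emulates the statistical structure that probabilistic
linkage between a birth cohort and routine hospital episodes assumes,
without any real patient data:

* a configurable number of true matches, each cohort record paired with at
  most one episode record (a partial 1:1 matching);
* per-field agreement among true matches with probability m — a
  disagreeing field is resampled from the field's value distribution
  excluding the true value, so chance re-agreement is negligible;
* chance agreement among non-matches with probability ≈ u, controlled by
  the collision probability of the per-field value distribution (one
  common value plus a uniform remainder, skewed to hit the requested u
  exactly whenever the field's realistic domain allows it);
* per-field, per-register missingness, injected independently;
* exact-duplicate episode rows with fresh identifiers;
* jointly implausible birthweight/gestation combinations (marginally valid
  values, e.g. < 500 g recorded at term) at a configurable rate;
* a live/still/unknown vital status per subject for birth-count
  accounting.

Outputs are byte-identical for identical configuration and seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field as dc_field
from typing import NamedTuple

import numpy as np
import pandas as pd

from perilink.linkage import ProbabilityTable
from perilink.records import RecordSet

logger = logging.getLogger(__name__)

ETHNICITIES = [
    "White British",
    "White other",
    "Black Caribbean",
    "Black African",
    "Indian",
    "Pakistani",
    "Bangladeshi",
    "Chinese",
    "Mixed",
    "Other",
]
DELIVERY_METHODS = [
    "spontaneous vertex",
    "emergency caesarean",
    "elective caesarean",
    "forceps",
    "ventouse",
    "breech",
    "breech extraction",
    "induced",
    "spontaneous other",
    "other",
]

#: Per-field domain sizes and renderers from integer codes to values.
_EPOCH = pd.Timestamp("1995-01-01")
FIELD_DOMAINS: dict = {
    "date_of_birth": (365, lambda c: _EPOCH + pd.to_timedelta(c, unit="D")),
    "mother_dob": (10000, lambda c: pd.Timestamp("1955-01-01") + pd.to_timedelta(c, unit="D")),
    "discharge_date": (500, lambda c: _EPOCH + pd.to_timedelta(c, unit="D")),
    "date_of_death": (365, lambda c: _EPOCH + pd.to_timedelta(c, unit="D")),
    "sex": (2, lambda c: np.array(["male", "female"], dtype=object)[c]),
    "gestational_age": (26, lambda c: c + 20),
    "birth_weight": (4201, lambda c: c + 400),
    "birth_order": (8, lambda c: c + 1),
    "n_babies": (8, lambda c: c + 1),
    "n_previous_pregnancies": (12, lambda c: c),
    "maternal_age": (20, lambda c: c + 16),
    "ethnicity": (10, lambda c: np.array(ETHNICITIES, dtype=object)[c]),
    "delivery_method": (10, lambda c: np.array(DELIVERY_METHODS, dtype=object)[c]),
    "postcode": (1000, lambda c: np.array([f"PC{i:04d}" for i in range(1000)], dtype=object)[c]),
}

#: Vital-status proportions (live, still, unknown) among births at the
#: margins of viability, as routine hospital data record them.
VITAL_PROPORTIONS = {"live": 0.716, "still": 0.246, "unknown": 0.038}

#: Per-register, per-field missingness presets emulating the two epochs'
#: routine-data completeness (cohort registers are near-complete; episode
#: registers lose a quarter to a half of several clinical fields; a rate
#: of 1.0 marks a field the register simply did not collect).
MISSINGNESS_PRESETS = {
    "1995": {
        "cohort": {
            "discharge_date": 0.5584,
            "date_of_death": 0.4012,
            "delivery_method": 0.0015,
            "maternal_age": 0.0060,
            "postcode": 1.0,
        },
        "episodes": {
            "date_of_birth": 0.0153,
            "gestational_age": 0.2850,
            "sex": 0.0045,
            "discharge_date": 0.0294,
            "date_of_death": 0.9929,
            "birth_weight": 0.2652,
            "birth_order": 0.4356,
            "delivery_method": 0.2919,
            "n_babies": 0.2648,
            "ethnicity": 0.8045,
            "maternal_age": 0.3736,
            "mother_dob": 1.0,
            "postcode": 1.0,
            "n_previous_pregnancies": 1.0,
        },
    },
    "2006": {
        "cohort": {
            "gestational_age": 0.0025,
            "sex": 0.0033,
            "birth_weight": 0.0095,
            "n_previous_pregnancies": 0.0367,
            "postcode": 0.0004,
            "mother_dob": 1.0,
            "maternal_age": 0.0029,
        },
        "episodes": {
            "date_of_birth": 0.0068,
            "gestational_age": 0.5323,
            "sex": 0.0051,
            "birth_weight": 0.4561,
            "birth_order": 0.3557,
            "n_babies": 0.3317,
            "n_previous_pregnancies": 0.9797,
            "postcode": 0.4600,
            "mother_dob": 0.4330,
            "maternal_age": 0.4330,
            "discharge_date": 1.0,
            "date_of_death": 1.0,
            "delivery_method": 1.0,
            "ethnicity": 1.0,
        },
    },
}


def missingness_preset(epoch: str) -> dict:
    """Per-register missingness rates for a study epoch ('1995' or '2006')."""
    try:
        return {k: dict(v) for k, v in MISSINGNESS_PRESETS[epoch].items()}
    except KeyError:
        raise ValueError(f"unknown epoch {epoch!r}") from None


class TruthMap:
    """The known set of true (cohort_id, episode_id) matches; 1:1."""

    def __init__(self, pairs) -> None:
        pairs = frozenset(tuple(p) for p in pairs)
        cids = [c for c, _ in pairs]
        eids = [e for _, e in pairs]
        if len(set(cids)) != len(cids) or len(set(eids)) != len(eids):
            raise ValueError("truth map is not a 1:1 matching")
        self.pairs = pairs

    def __len__(self) -> int:
        return len(self.pairs)

    def __contains__(self, pair) -> bool:
        return tuple(pair) in self.pairs

    def __eq__(self, other) -> bool:
        return isinstance(other, TruthMap) and self.pairs == other.pairs

    def oracle(self, complete: bool = True):
        """A clerical-review oracle: True for truth pairs, False (complete)
        or None (partial: no opinion) otherwise."""
        def verdict(pair):
            if tuple(pair) in self.pairs:
                return True
            return False if complete else None

        return verdict

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            sorted(self.pairs), columns=["cohort_id", "episode_id"]
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "TruthMap":
        return cls(zip(df["cohort_id"], df["episode_id"]))


@dataclass
class SyntheticConfig:
    """Study conditions for one synthetic linkage exercise.

    Defaults reproduce the 1995 epoch's structure at full scale: a cohort
    of 668 babies against 486,705 episode records, full cohort overlap
    (every cohort baby has exactly one true episode counterpart), the
    a-priori m/u table, epoch-1995 missingness and a small rate of
    implausible birthweight/gestation injections.  Scale down n_cohort /
    n_episodes (keeping their ratio if the blocking load matters) for
    quick experiments.
    """

    n_cohort: int = 668
    n_episodes: int = 486705
    n_true_matches: int = 668
    probability_table: ProbabilityTable | None = None
    missingness_rates: dict | None = None  # {"cohort": {...}, "episodes": {...}}
    discordance_rate: float = 0.004
    duplicate_rate: float = 0.0
    vital_proportions: dict | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_true_matches > min(self.n_cohort, self.n_episodes):
            raise ValueError(
                "n_true_matches exceeds the smaller register "
                f"({self.n_true_matches} > {min(self.n_cohort, self.n_episodes)})"
            )
        for r in (self.discordance_rate, self.duplicate_rate):
            if not (0.0 <= r <= 1.0):
                raise ValueError(f"rate {r} outside [0, 1]")
        if self.missingness_rates:
            for reg in self.missingness_rates.values():
                for f, r in reg.items():
                    if not (0.0 <= r <= 1.0):
                        raise ValueError(f"missingness rate {f}={r} outside [0, 1]")
        if self.probability_table is None:
            from perilink.presets import BEST_GUESS

            self.probability_table = BEST_GUESS


@dataclass
class GenerationLog:
    """What the generator actually did (for audit and duplicate tracking)."""

    seed: int
    effective_u: dict = dc_field(default_factory=dict)
    duplicates: list = dc_field(default_factory=list)  # (new_id, original_id)
    discordant_ids: dict = dc_field(default_factory=dict)  # register -> list of ids


class SyntheticResult(NamedTuple):
    cohort: RecordSet
    episodes: RecordSet
    truth: TruthMap
    log: GenerationLog


def _category_probs(D: int, u: float) -> np.ndarray:
    """A D-category distribution whose collision probability is u.

    One common category with probability q and the remaining D-1 sharing
    1-q uniformly; q solves q² + (1-q)²/(D-1) = u.  The minimum attainable
    collision is 1/D (uniform); a request below that floor falls back to
    uniform.
    """
    if u <= 1.0 / D:
        return np.full(D, 1.0 / D)
    disc = 1.0 - D + u * D * (D - 1)
    q = (1.0 + np.sqrt(disc)) / D
    probs = np.full(D, (1.0 - q) / (D - 1))
    probs[0] = q
    return probs


def _sample_field(rng: np.random.Generator, n: int, probs: np.ndarray) -> np.ndarray:
    return rng.choice(len(probs), size=n, p=probs)


def _perturb(rng: np.random.Generator, true_codes: np.ndarray, probs: np.ndarray) -> np.ndarray:
    """Resample each code from the distribution excluding its true value."""
    out = _sample_field(rng, len(true_codes), probs)
    clash = out == true_codes
    tries = 0
    while clash.any():
        out[clash] = _sample_field(rng, int(clash.sum()), probs)
        clash = out == true_codes
        tries += 1
        if tries > 10000:  # unreachable for any non-degenerate distribution
            raise RuntimeError("perturbation failed to move off the true value")
    return out


def generate_linked_datasets(cfg: SyntheticConfig) -> SyntheticResult:
    """Generate (cohort, episodes, truth map, log) under ``cfg``.

    Field values are integer codes drawn from per-field distributions whose
    collision probability matches the table's u (exactly, where the
    realistic domain permits; the attainable values are reported in the
    log's ``effective_u``).  Each true-match episode copies its cohort
    record's value per field with probability m and otherwise perturbs it;
    unmatched episode records are drawn independently.  Birth order is
    folded into [1, n_babies] so every record satisfies the plurality
    invariant.
    """
    rng = np.random.default_rng(cfg.seed)
    pt = cfg.probability_table
    fields = [f for f in FIELD_DOMAINS if f in pt.m]
    log = GenerationLog(seed=cfg.seed)

    probs = {}
    for f in fields:
        D, _render = FIELD_DOMAINS[f]
        u = float(pt.u[f])
        probs[f] = _category_probs(D, u)
        log.effective_u[f] = float(np.sum(probs[f] ** 2))
        if u < 1.0 / D - 1e-12:
            logger.info(
                "field %s: requested u=%.4g below the 1/%d domain floor; using %.4g",
                f, u, D, log.effective_u[f],
            )

    cohort_codes = {f: _sample_field(rng, cfg.n_cohort, probs[f]) for f in fields}

    # Truth pairs: the first n_true_matches cohort records (order is
    # immaterial; ids are assigned after shuffling below).
    matched_idx = rng.choice(cfg.n_cohort, size=cfg.n_true_matches, replace=False)
    episode_codes = {f: _sample_field(rng, cfg.n_episodes, probs[f]) for f in fields}
    for f in fields:
        true_vals = cohort_codes[f][matched_idx]
        keep = rng.random(cfg.n_true_matches) < float(pt.m[f])
        vals = true_vals.copy()
        if (~keep).any():
            vals[~keep] = _perturb(rng, true_vals[~keep], probs[f])
        episode_codes[f][: cfg.n_true_matches] = vals
    # Scatter matched episodes through the register.
    episode_order = rng.permutation(cfg.n_episodes)
    for f in fields:
        episode_codes[f] = episode_codes[f][episode_order]
    matched_episode_pos = np.empty(cfg.n_episodes, dtype=int)
    matched_episode_pos[episode_order] = np.arange(cfg.n_episodes)
    # position in the final register of original slot i:
    episode_pos_of_slot = matched_episode_pos

    cohort_ids = np.array([f"C{i:06d}" for i in range(cfg.n_cohort)], dtype=object)
    episode_ids = np.array([f"E{i:07d}" for i in range(cfg.n_episodes)], dtype=object)
    truth = TruthMap(
        (cohort_ids[ci], episode_ids[episode_pos_of_slot[slot]])
        for slot, ci in enumerate(matched_idx)
    )

    vp = cfg.vital_proportions or VITAL_PROPORTIONS
    statuses = np.array(list(vp), dtype=object)
    pvec = np.array([vp[s] for s in statuses], dtype=float)
    pvec = pvec / pvec.sum()
    cohort_vital = rng.choice(statuses, size=cfg.n_cohort, p=pvec)
    episode_vital = rng.choice(statuses, size=cfg.n_episodes, p=pvec)
    # matched episodes share their subject's status
    episode_vital[episode_pos_of_slot[np.arange(cfg.n_true_matches)]] = cohort_vital[
        matched_idx
    ]

    def render(codes: dict, ids: np.ndarray, vital: np.ndarray) -> pd.DataFrame:
        data = {"id": ids}
        cols = dict(codes)
        if "birth_order" in cols and "n_babies" in cols:
            nb = cols["n_babies"] + 1  # rendered value
            cols = dict(cols)
            cols["birth_order"] = cols["birth_order"] % nb  # code in [0, nb)
        for f, c in cols.items():
            data[f] = FIELD_DOMAINS[f][1](c)
        data["vital_status"] = vital
        return pd.DataFrame(data)

    cohort_df = render(cohort_codes, cohort_ids, cohort_vital)
    episodes_df = render(episode_codes, episode_ids, episode_vital)

    cohort = RecordSet(cohort_df, "cohort")
    episodes = RecordSet(episodes_df, "episodes")

    if cfg.discordance_rate > 0:
        episodes = inject_discordance(
            episodes, cfg.discordance_rate, seed=int(rng.integers(2**31)), log=log
        )

    if cfg.missingness_rates:
        cohort = inject_missingness(
            cohort, cfg.missingness_rates.get("cohort", {}), seed=int(rng.integers(2**31))
        )
        episodes = inject_missingness(
            episodes,
            cfg.missingness_rates.get("episodes", {}),
            seed=int(rng.integers(2**31)),
        )

    if cfg.duplicate_rate > 0:
        n_dup = int(round(cfg.duplicate_rate * len(episodes)))
        if n_dup:
            pick = rng.choice(len(episodes), size=n_dup, replace=False)
            dup = episodes.df.iloc[pick].copy()
            new_ids = np.array(
                [f"E{cfg.n_episodes + i:07d}" for i in range(n_dup)], dtype=object
            )
            log.duplicates = list(zip(new_ids, dup["id"].to_numpy()))
            dup["id"] = new_ids
            episodes = RecordSet(
                pd.concat([episodes.df, dup], ignore_index=True), "episodes"
            )

    return SyntheticResult(cohort, episodes, truth, log)


def inject_missingness(rs: RecordSet, rates: dict, seed: int) -> RecordSet:
    """Independently blank each field value with its per-field rate."""
    rng = np.random.default_rng(seed)
    df = rs.df.copy()
    for f, rate in rates.items():
        if not (0.0 <= rate <= 1.0):
            raise ValueError(f"missingness rate {f}={rate} outside [0, 1]")
        if f not in df.columns or rate == 0.0:
            continue
        blank = rng.random(len(df)) < rate
        if pd.api.types.is_datetime64_any_dtype(df[f]):
            df.loc[blank, f] = pd.NaT
        elif pd.api.types.is_integer_dtype(df[f]):
            df[f] = df[f].astype("Int64")
            df.loc[blank, f] = pd.NA
        else:
            df[f] = df[f].astype(object)
            df.loc[blank, f] = np.nan
    return RecordSet(df, rs.register_label, rs.id_field)


#: The implausible joint region used by the injector: a birth weight below
#: 500 g recorded together with a gestational age at or beyond 35 weeks.
IMPLAUSIBLE_BW = (400, 499)
IMPLAUSIBLE_GA = (35, 45)


def inject_discordance(
    rs: RecordSet, rate: float, seed: int, log: GenerationLog | None = None
) -> RecordSet:
    """Make a fraction of records jointly implausible on weight × gestation.

    Selected records (among those with both fields present) get a birth
    weight under 500 g together with a gestational age of 35 weeks or
    more — each value marginally valid, the combination clinically
    impossible, as transcription slips in routine data produce.
    """
    if not (0.0 <= rate <= 1.0):
        raise ValueError(f"rate {rate} outside [0, 1]")
    df = rs.df.copy()
    if rate == 0.0 or "birth_weight" not in df.columns or "gestational_age" not in df.columns:
        return RecordSet(df, rs.register_label, rs.id_field)
    rng = np.random.default_rng(seed)
    eligible = df["birth_weight"].notna() & df["gestational_age"].notna()
    hit = eligible & (rng.random(len(df)) < rate)
    n = int(hit.sum())
    if n:
        df.loc[hit, "birth_weight"] = rng.integers(
            IMPLAUSIBLE_BW[0], IMPLAUSIBLE_BW[1] + 1, size=n
        )
        df.loc[hit, "gestational_age"] = rng.integers(
            IMPLAUSIBLE_GA[0], IMPLAUSIBLE_GA[1] + 1, size=n
        )
        if log is not None:
            log.discordant_ids[rs.register_label] = df.loc[hit, rs.id_field].tolist()
    return RecordSet(df, rs.register_label, rs.id_field)
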