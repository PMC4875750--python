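"""Shipped m/u parameter sets for the perinatal linkage exercise.

Two named probability tables are provided:

``best_guess``
    A priori estimates of each matching variable's agreement probability
    among true matches (m) and chance-agreement probability among
    non-matches (u), set before any linkage was run.  Note the u of
    0.00274 ≈ 1/365 for date of birth and the deliberately uninformative
    fields (m = u) whose weights vanish.

``dattani``
    Estimates adapted from a prior national linkage between hospital
    episode data and birth-notification records (Dattani et al.),
    supplemented with adjusted a-priori values for date of death and
    delivery method, for which that exercise had no information.  Fields
    with no usable prior estimate (discharge date, maternal age, mother's
    date of birth, number of previous pregnancies) are absent from this
    table; runs wanting them fall back to the best-guess values.
"""

from __future__ import annotations

from perilink.linkage import EpiLinkSpec, ProbabilityTable

BEST_GUESS = ProbabilityTable(
    m={
        "date_of_birth": 0.90,
        "gestational_age": 0.80,
        "sex": 0.999,
        "discharge_date": 0.20,
        "date_of_death": 0.20,
        "birth_weight": 0.60,
        "birth_order": 0.87,
        "delivery_method": 0.80,
        "ethnicity": 0.20,
        "maternal_age": 0.95,
        "mother_dob": 0.90,
        "postcode": 0.90,
        "n_previous_pregnancies": 0.60,
        "n_babies": 0.95,
    },
    u={
        "date_of_birth": 0.00274,
        "gestational_age": 0.02,
        "sex": 0.49,
        "discharge_date": 0.002,
        "date_of_death": 0.00274,
        "birth_weight": 0.001,
        "birth_order": 0.95,
        "delivery_method": 0.80,
        "ethnicity": 0.10,
        "maternal_age": 0.05,
        "mother_dob": 0.0001,
        "postcode": 0.001,
        "n_previous_pregnancies": 0.90,
        "n_babies": 0.95,
    },
)

DATTANI = ProbabilityTable(
    m={
        "date_of_birth": 0.7405,
        "gestational_age": 0.4941,
        "sex": 0.7208,
        "date_of_death": 0.30,
        "birth_weight": 0.7405,
        "birth_order": 0.8153,
        "delivery_method": 0.67,
        "ethnicity": 0.7308,
        "postcode": 0.9291,
        "n_babies": 0.8153,
    },
    u={
        "date_of_birth": 0.0015,
        "gestational_age": 0.0494,
        "sex": 0.0062,
        "date_of_death": 0.002,
        "birth_weight": 0.0074,
        "birth_order": 0.0033,
        "delivery_method": 0.1,
        "ethnicity": 0.095,
        "postcode": 0.065,
        "n_babies": 0.0033,
    },
)

PRESETS = {"best_guess": BEST_GUESS, "dattani": DATTANI}


def get_preset(name: str) -> ProbabilityTable:
    """Look up a shipped probability table by name."""
    try:
        return PRESETS[name]
    except KeyError:
        raise ValueError(
            f"unknown preset {name!r}; available: {sorted(PRESETS)}"
        ) from None


def epilink_spec_from_table(pt: ProbabilityTable) -> EpiLinkSpec:
    """Identify EpiLink's a-priori factors with an m/u table.

    EpiLink wants, per field, an error rate e (chance the recorded value is
    wrong) and an average value frequency f (chance two unrelated records
    collide on the value).  A natural identification with the
    Fellegi–Sunter quantities is e = 1 - m and f = u, which makes the field
    weight log2((1-e)/f) = log2(m/u) — the agreement weight in bits.  Both
    factors are thereby fixed in advance rather than estimated from the
    data being linked.
    """
    return EpiLinkSpec(
        error_rate={f: 1.0 - float(m) for f, m in pt.m.items()},
        avg_frequency={f: float(u) for f, u in pt.u.items()},
    )
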