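"""Frozen published reference values shared by the test modules.

PUBLISHED_WEIGHTS holds, per shipped parameter preset and field, the
per-field log-weights as the source table prints them (as strings, so each
comparison can use half a unit in the last printed decimal place).
"""

PUBLISHED_WEIGHTS = [
    ("best_guess", "date_of_birth", "5.794", "-2.30"),
    ("best_guess", "gestational_age", "3.689", "-1.589"),
    ("best_guess", "sex", "0.7123", "-6.2344"),
    ("best_guess", "discharge_date", "4.6052", "-0.2211"),
    ("best_guess", "date_of_death", "4.2904", "-0.2204"),
    ("best_guess", "birth_weight", "6.3969", "-0.9153"),
    ("best_guess", "birth_order", "-0.08797", "0.95551"),
    ("best_guess", "delivery_method", "0", "0"),
    ("best_guess", "ethnicity", "0.6931", "-0.1178"),
    ("best_guess", "maternal_age", "2.944", "-2.944"),
    ("best_guess", "mother_dob", "9.105", "-2.302"),
    ("best_guess", "postcode", "6.802", "-2.302"),
    ("best_guess", "n_previous_pregnancies", "-0.4055", "1.3863"),
    ("best_guess", "n_babies", "0", "0"),
    ("dattani", "date_of_birth", "6.202", "-1.347"),
    ("dattani", "gestational_age", "2.3028", "-0.6308"),
    ("dattani", "sex", "4.756", "-1.270"),
    ("dattani", "date_of_death", "5.0106", "-0.3547"),
    ("dattani", "birth_weight", "4.606", "-1.342"),
    ("dattani", "birth_order", "5.510", "-1.686"),
    ("dattani", "delivery_method", "1.902", "-1.003"),
    ("dattani", "ethnicity", "2.040", "-1.212"),
    ("dattani", "postcode", "2.660", "-2.579"),
    ("dattani", "n_babies", "5.510", "-1.686"),
]


def printed_tolerance(printed: str) -> float:
    """Half a unit in the last printed decimal place."""
    decimals = len(printed.split(".")[1]) if "." in printed else 0
    return 0.5 * 10.0 ** (-decimals) + 1e-12
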