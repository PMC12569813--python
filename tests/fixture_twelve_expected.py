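"""Frozen expected values for the 12-tree fixture.

Derived once from the first-principles implementation in
tests/oracles.py (derive_indexes); the derivation is re-run by the
acceptance suite to confirm the frozen numbers have not drifted.
"""

PER_TREE = {
    1: {
        "W": 0.25,
        "U": 0.16666666666666666,
        "Mc": 0.3554421768707483,
        "S": 0.5,
        "CI": 0.1924551285435531,
    },
    2: {
        "W": 0.25,
        "U": 0.25,
        "Mc": 0.1375,
        "S": 0.5,
        "CI": 0.41184405519539247,
    },
    3: {
        "W": 0.5,
        "U": 0.6,
        "Mc": 0.5177777777777778,
        "S": 0.26666666666666666,
        "CI": 2.6080011683125712,
    },
    4: {
        "W": 0.25,
        "U": 0.0,
        "Mc": 0.09277777777777779,
        "S": 0.5333333333333333,
        "CI": 0.13692553516481537,
    },
    5: {
        "W": 0.5,
        "U": 0.6,
        "Mc": 0.6422222222222222,
        "S": 0.6,
        "CI": 3.534374783740436,
    },
    6: {
        "W": 0.25,
        "U": 1.0,
        "Mc": 0.0,
        "S": 0.3333333333333333,
        "CI": 1.30214469021705,
    },
    7: {
        "W": 0.5,
        "U": 1.0,
        "Mc": 0.5194444444444444,
        "S": 0.0,
        "CI": 18.728496869087923,
    },
    8: {
        "W": 0.75,
        "U": 0.3333333333333333,
        "Mc": 0.22569444444444442,
        "S": 0.4444444444444444,
        "CI": 0.5559445718759602,
    },
    9: {
        "W": 0.75,
        "U": 0.5,
        "Mc": 0.4444444444444444,
        "S": 0.3333333333333333,
        "CI": 0.3507397281762676,
    },
    10: {
        "W": 0.75,
        "U": 0.5,
        "Mc": 0.1375,
        "S": 0.5,
        "CI": 0.43780614278258234,
    },
    11: {
        "W": 1.0,
        "U": 0.5,
        "Mc": 0.4444444444444444,
        "S": 0.3333333333333333,
        "CI": 0.565510159973318,
    },
}

MEANS = {
    "W": 0.5227272727272727,
    "U": 0.4954545454545455,
    "Mc": 0.3197497938569368,
    "S": 0.39494949494949494,
    "CI": 2.620385712097261,
}

STDS = {
    "W_abs": 0.14286883541287584,
    "U": 0.2971319902855565,
    "Mc": 0.20101686296287752,
    "S": 0.15971099293779695,
    "CI": 5.199510367523708,
}

L_OBJECTIVE = 1.4983886626199168
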