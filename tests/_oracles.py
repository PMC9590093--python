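"""Independent naive implementations of the rhythm metrics, used as oracles.

These follow the IV/IS definitions with explicit Python loops and the same
available-case deletion rules, but share no code with the package's vectorized
implementations.
"""

import math


def iv_oracle(values):
    """Naive intradaily variability with pairwise deletion of absent hours."""
    valid = [v for v in values if not math.isnan(v)]
    n_used = len(valid)
    xbar = sum(valid) / n_used
    denom = sum((v - xbar) ** 2 for v in valid)
    num = 0.0
    m = 0
    for i in range(1, len(values)):
        a, b = values[i - 1], values[i]
        if not (math.isnan(a) or math.isnan(b)):
            num += (b - a) ** 2
            m += 1
    if denom == 0.0 or m == 0:
        return float("nan")
    return n_used * num / (m * denom)


def is_oracle(values, hour_of_day, hours_per_day):
    """Naive interdaily stability with empty hour-of-day bins dropped."""
    valid_idx = [i for i, v in enumerate(values) if not math.isnan(v)]
    n_used = len(valid_idx)
    xbar = sum(values[i] for i in valid_idx) / n_used
    denom = sum((values[i] - xbar) ** 2 for i in valid_idx)
    num = 0.0
    p_used = 0
    for h in range(1, hours_per_day + 1):
        bin_vals = [values[i] for i in valid_idx if hour_of_day[i] == h]
        if bin_vals:
            p_used += 1
            bh = sum(bin_vals) / len(bin_vals)
            num += (bh - xbar) ** 2
    if denom == 0.0 or p_used == 0:
        return float("nan")
    return n_used * num / (p_used * denom)
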