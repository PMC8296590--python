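import numpy as np
import pandas as pd


def make_table(stage_names, drug, event, ages=None):
    """Small report table from parallel per-report lists."""
    n = len(stage_names)
    return pd.DataFrame(
        {
            "report_id": [f"R{i}" for i in range(n)],
            "age_years": ages if ages is not None else [10.0] * n,
            "nichd_stage": list(stage_names),
            "drug": np.asarray(drug, dtype=np.int8),
            "event": np.asarray(event, dtype=np.int8),
        }
    )


def table_from_counts(a, b, c, d, stage="infancy"):
    """Report table whose single-stage 2x2 counts are exactly (a, b, c, d)."""
    drug = [1] * (a + c) + [0] * (b + d)
    event = [1] * a + [0] * c + [1] * b + [0] * d
    return make_table([stage] * (a + b + c + d), drug, event)


def brute_force_prr(table, stage):
    """Independent PRR oracle: count raw rows, apply the printed formula."""
    sub = table[table["nichd_stage"] == stage]
    a = len(sub[(sub.drug == 1) & (sub.event == 1)])
    b = len(sub[(sub.drug == 0) & (sub.event == 1)])
    c = len(sub[(sub.drug == 1) & (sub.event == 0)])
    d = len(sub[(sub.drug == 0) & (sub.event == 0)])
    if a + c == 0:
        return float("nan"), "nan"
    if a == 0:
        return 0.0, "zero"
    if b == 0:
        return float("inf"), "infinite"
    return (a / (a + c)) / (b / (b + d)), "finite"
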