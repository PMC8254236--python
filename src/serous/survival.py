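"""Survival association of altered gene expression.

Patients are split into "altered" and "unaltered" groups per gene by a
z-score against a diploid reference population: z = (x - median of diploid
expression) / SD of diploid expression, altered iff |z| >= 2 (both
directions pooled).  Group survival is compared with Kaplan-Meier curves
and a two-group logrank test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test


@dataclass
class AlteredCall:
    patient_id: str
    gene_id: str
    z: float
    altered: bool


def altered_set(table: pd.DataFrame, gene: str, threshold: float = 2.0,
                center: str = "median") -> list[AlteredCall]:
    """Z-score every patient's expression of ``gene`` against the diploid
    reference and call |z| >= threshold altered.

    The reference center is the diploid median (``center='mean'`` switches
    to the mean); the denominator is the diploid sample SD.  At least two
    diploid patients with non-identical expression are required.
    """
    if gene not in table.columns:
        raise KeyError(f"gene {gene!r} not in survival table")
    diploid = table.loc[table["diploid"] == 1, gene].to_numpy(dtype=float)
    if diploid.size < 2:
        raise ValueError("need >= 2 diploid patients for the reference")
    sd = diploid.std(ddof=1)
    if sd == 0:
        raise ValueError("diploid reference SD is zero")
    c = float(np.median(diploid)) if center == "median" else float(diploid.mean())
    calls = []
    for row in table.itertuples():
        z = (float(getattr(row, gene)) - c) / sd
        calls.append(AlteredCall(str(row.patient_id), gene, z,
                                 bool(abs(z) >= threshold)))
    return calls


def km_estimate(times, events) -> pd.DataFrame:
    """Product-limit survival curve; columns (time, survival)."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    if (times < 0).any():
        raise ValueError("negative survival times")
    kmf = KaplanMeierFitter()
    kmf.fit(times, events)
    sf = kmf.survival_function_
    return pd.DataFrame({"time": sf.index.to_numpy(dtype=float),
                         "survival": sf.iloc[:, 0].to_numpy(dtype=float)})


def logrank(times_a, events_a, times_b, events_b) -> tuple[float, float]:
    """Two-group logrank test; returns (chi-square statistic, p).

    When neither group has any event the test is degenerate and (0, 1) is
    returned.
    """
    ta, ea = np.asarray(times_a, float), np.asarray(events_a, int)
    tb, eb = np.asarray(times_b, float), np.asarray(events_b, int)
    if ta.size == 0 or tb.size == 0:
        raise ValueError("both groups must be non-empty")
    if ea.sum() + eb.sum() == 0:
        return 0.0, 1.0
    res = logrank_test(ta, tb, event_observed_A=ea, event_observed_B=eb)
    stat, p = float(res.test_statistic), float(res.p_value)
    if not np.isfinite(stat):
        return 0.0, 1.0
    return stat, min(p, 1.0)


def survival_association(table: pd.DataFrame, gene: str,
                         threshold: float = 2.0,
                         center: str = "median") -> dict:
    """End-to-end association of one gene's altered expression with survival.

    Returns the altered calls, KM curves for the altered/unaltered groups,
    and the logrank (statistic, p).
    """
    calls = altered_set(table, gene, threshold=threshold, center=center)
    altered_ids = {c.patient_id for c in calls if c.altered}
    mask = table["patient_id"].astype(str).isin(altered_ids)
    if mask.all() or not mask.any():
        raise ValueError(
            f"gene {gene!r}: altered split is degenerate "
            f"({int(mask.sum())}/{len(mask)} altered)")
    a, b = table[mask], table[~mask]
    stat, p = logrank(a["time"], a["event"], b["time"], b["event"])
    return {
        "calls": calls,
        "n_altered": int(mask.sum()),
        "km_altered": km_estimate(a["time"], a["event"]),
        "km_unaltered": km_estimate(b["time"], b["event"]),
        "statistic": stat,
        "p": p,
    }
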