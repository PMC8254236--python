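"""Differential-expression statistics.

Implements the discovery contrast between tumor groups: the intersection
filter that drops genes missing in any sample, the pooled-variance two-sample
Student's t-test (computable either from raw vectors or from per-group
(mean, SD, n) summary triples), the signed fold-change convention in which a
ratio below 1 is replaced by its negative reciprocal so that |FC| >= 1, DEG
selection at a nominal alpha, and the Mann-Whitney U comparison used for
stage-wise validation.

No multiple-testing correction is applied for selection (the discovery
cohorts are very small); Benjamini-Hochberg q-values are reported alongside
for reference.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io import ExpressionMatrix


@dataclass
class GroupSummary:
    """Per-gene per-group sufficient statistics (sample SD, denominator n-1)."""

    gene_id: str
    group: str
    mean: float
    sd: float
    n: int

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError(f"{self.gene_id}/{self.group}: n={self.n} < 2")
        if self.sd < 0:
            raise ValueError(f"{self.gene_id}/{self.group}: negative SD")

    @classmethod
    def from_values(cls, gene_id, group, values) -> "GroupSummary":
        v = np.asarray(values, dtype=float)
        if v.size < 2:
            raise ValueError(f"{gene_id}/{group}: need >= 2 values")
        return cls(gene_id, group, float(v.mean()), float(v.std(ddof=1)), v.size)


@dataclass
class DEGRecord:
    gene_id: str
    fold_change: float
    t: float
    df: int
    p: float
    q: float
    direction: str  # up/down in group 2
    degenerate: bool = False


def intersection_filter(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Keep only genes observed (non-missing) in every sample, order preserved."""
    keep = matrix.values.notna().all(axis=1)
    if not keep.any():
        raise ValueError("no gene is present in all samples")
    return ExpressionMatrix(matrix.values.loc[keep].copy(), dict(matrix.groups))


def fold_change(m1: float, m2: float, pseudocount: float | None = None) -> float:
    """Signed fold change of group-1 over group-2 mean.

    The ratio r = m1/m2 is reported as-is when r >= 1 and as -1/r otherwise,
    so the magnitude is always >= 1 and the sign encodes direction.  With
    ``pseudocount`` set, epsilon is added to both means before forming the
    ratio; otherwise a zero mean is an error.
    """
    if pseudocount is not None:
        m1, m2 = m1 + pseudocount, m2 + pseudocount
    if m2 <= 0 or m1 <= 0:
        raise ValueError(
            f"non-positive group mean (m1={m1}, m2={m2}); pass a pseudocount")
    r = m1 / m2
    return r if r >= 1 else -1.0 / r


def ttest_pooled(summary_1: GroupSummary, summary_2: GroupSummary,
                 welch: bool = False) -> tuple[float, float, float]:
    """Two-sample Student's t-test from summary statistics.

    Returns (t, df, two-tailed p).  The default is the pooled-variance test
    with df = n1 + n2 - 2; ``welch=True`` switches to the unequal-variance
    form with Welch-Satterthwaite df.  Degenerate zero-variance input yields
    (0, df, 1) when the means agree and (+/-inf, df, 0) when they differ.
    """
    m1, s1, n1 = summary_1.mean, summary_1.sd, summary_1.n
    m2, s2, n2 = summary_2.mean, summary_2.sd, summary_2.n
    if welch:
        v1, v2 = s1**2 / n1, s2**2 / n2
        se2 = v1 + v2
        df = (se2**2 / (v1**2 / (n1 - 1) + v2**2 / (n2 - 1))
              if se2 > 0 else float(n1 + n2 - 2))
    else:
        sp2 = ((n1 - 1) * s1**2 + (n2 - 1) * s2**2) / (n1 + n2 - 2)
        se2 = sp2 * (1 / n1 + 1 / n2)
        df = float(n1 + n2 - 2)
    if se2 == 0:
        if m1 == m2:
            return 0.0, df, 1.0
        return float(np.copysign(np.inf, m1 - m2)), df, 0.0
    t = (m1 - m2) / np.sqrt(se2)
    p = 2.0 * stats.t.sf(abs(t), df)
    return float(t), df, float(p)


def ttest_raw(values_1, values_2, welch: bool = False) -> tuple[float, float, float]:
    """Pooled t-test from raw vectors; agrees with the summary path to 1e-10."""
    s1 = GroupSummary.from_values("_", "a", values_1)
    s2 = GroupSummary.from_values("_", "b", values_2)
    return ttest_pooled(s1, s2, welch=welch)


def _bh_qvalues(p: np.ndarray) -> np.ndarray:
    n = len(p)
    order = np.argsort(p, kind="stable")
    ranked = p[order] * n / np.arange(1, n + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(n)
    q[order] = np.clip(ranked, 0, 1)
    return q


def select_degs(matrix: ExpressionMatrix, group_1: str, group_2: str,
                alpha: float = 0.05,
                pseudocount: float | None = None) -> list[DEGRecord]:
    """Genes differing between two groups at nominal p < alpha.

    Records are sorted by |fold change| descending (ties broken by gene id);
    the fold change is mean(group 1) / mean(group 2) under the signed
    convention.  BH q-values over all tested genes are reported but play no
    role in selection.
    """
    filt = intersection_filter(matrix)
    cols_1 = filt.samples_in(group_1)
    cols_2 = filt.samples_in(group_2)
    if len(cols_1) < 2 or len(cols_2) < 2:
        raise ValueError("both groups need >= 2 samples")
    rows = []
    for gene in filt.gene_ids:
        v1 = filt.values.loc[gene, cols_1].to_numpy(dtype=float)
        v2 = filt.values.loc[gene, cols_2].to_numpy(dtype=float)
        t, df, p = ttest_raw(v1, v2)
        fc = fold_change(float(v1.mean()), float(v2.mean()), pseudocount)
        rows.append((gene, fc, t, df, p))
    pvals = np.array([r[4] for r in rows])
    qvals = _bh_qvalues(pvals)
    records = [
        DEGRecord(gene, fc, t, int(df), p, q,
                  direction="down" if fc > 0 else "up",
                  degenerate=not np.isfinite(t))
        for (gene, fc, t, df, p), q in zip(rows, qvals)
        if p < alpha
    ]
    records.sort(key=lambda r: (-abs(r.fold_change), r.gene_id))
    return records


def degs_to_frame(records: list[DEGRecord]) -> pd.DataFrame:
    return pd.DataFrame([{
        "gene": r.gene_id,
        "fold_change": round(r.fold_change, 2),
        "t": r.t, "df": r.df, "p": r.p, "q": r.q,
        "direction": r.direction,
    } for r in records])


def mannwhitney_stage(matrix: ExpressionMatrix, gene: str,
                      group_a: str, group_b: str,
                      method: str = "auto") -> tuple[float, float]:
    """Two-sided Mann-Whitney U comparison of one gene between two groups.

    ``method='auto'`` uses the exact null distribution when the combined
    sample size is <= 20 and there are no ties, and the tie-corrected normal
    approximation otherwise.  All-tied input returns p = 1.
    """
    va = matrix.values.loc[gene, matrix.samples_in(group_a)].to_numpy(dtype=float)
    vb = matrix.values.loc[gene, matrix.samples_in(group_b)].to_numpy(dtype=float)
    return mannwhitney_values(va, vb, method=method)


def mannwhitney_values(values_a, values_b, method: str = "auto") -> tuple[float, float]:
    va = np.asarray(values_a, dtype=float)
    vb = np.asarray(values_b, dtype=float)
    if va.size == 0 or vb.size == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([va, vb])
    if np.all(pooled == pooled[0]):
        return float(va.size * vb.size / 2), 1.0
    has_ties = len(np.unique(pooled)) < pooled.size
    if method == "auto":
        method = "exact" if (pooled.size <= 20 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(va, vb, alternative="two-sided", method=method)
    return float(res.statistic), float(min(res.pvalue, 1.0))
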