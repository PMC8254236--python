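"""Reproducible simulation experiments over the pipeline.

These drivers wire the synthetic generators to the analysis modules at
fixed, desk-scale problem sizes: the signature-classification cohort, the
end-to-end planted-motif recovery run, and the null calibrations of every
test statistic.  Both the validation test suite and the reproduction script
call them, so the measured quantities come from one code path.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from . import classify, go5t, motifs, simulate, survival
from .deg import mannwhitney_values, ttest_raw

#: reduced hyperparameter grid for desk-scale nested-CV runs
SMALL_GRID = {"min_samples_split": [2, 8], "max_depth": [4, None]}


# ---------------------------------------------------------------------------
# signature classification on a synthetic validation-sized cohort
# ---------------------------------------------------------------------------

def validation_cohort(seed: int, n_sbt: int = 18, n_hgsoc: int = 267):
    """Two-class cohort shaped like the microarray validation set (18 SBT vs
    267 HGSOC) with per-gene group distributions taken from the published
    discovery summary statistics."""
    effects, _ = simulate.discovery_effects("sbt_vs_hgsoc")
    return simulate.simulate_expression(
        effects, [("SBT", n_sbt), ("HGSOC", n_hgsoc)], seed=seed)


def signature_cv_accuracy(seed: int, model: str = "rf",
                          n_estimators: int = 100,
                          grid: dict | None = None) -> float:
    """Nested-CV mean accuracy of the 11-gene signature on one cohort draw."""
    em = validation_cohort(seed)
    X = em.values.to_numpy(dtype=float).T
    y = np.array([em.groups[s] for s in em.sample_ids])
    report = classify.nested_cv(X, y, model=model, seed=seed,
                                grid=grid or SMALL_GRID,
                                n_estimators=n_estimators)
    return report.mean_accuracy


def permuted_label_cv_accuracy(seed: int, n_samples: int = 60,
                               n_genes: int = 5) -> float:
    """Nested-CV accuracy of a decision tree on pure-noise features with
    randomly assigned balanced labels; chance level is 0.5."""
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n_samples, n_genes))
    y = rng.permutation(np.repeat(["a", "b"], n_samples // 2))
    report = classify.nested_cv(X, y, model="dt", seed=seed)
    return report.mean_accuracy


# ---------------------------------------------------------------------------
# end-to-end planted-motif recovery
# ---------------------------------------------------------------------------

def _known_motif(rng, motif_id: str, length: int | None = None):
    """Synthetic stand-in for a curated TF motif: length ~14, dominant-base
    frequency ~0.95 per column with Dirichlet jitter."""
    L = int(rng.integers(10, 17)) if length is None else length
    return simulate.random_pwm(rng, L, sharpness=0.95, concentration=100.0,
                               motif_id=motif_id)


def motif_recovery_trial(seed: int, n_foreground: int = 20,
                         n_decoys: int = 49, fg_coverage: float = 0.85,
                         bg_coverage: float = 0.10,
                         promoter_length: int = 2000,
                         p_threshold: float = 1e-5,
                         n_null: int = 10_000) -> dict:
    """One seed of the planted-motif pipeline experiment.

    A source PWM is planted at the given coverages among decoy candidates;
    the pipeline scans, RF-ranks, coverage-filters (regime A) and matches
    the planted candidate back to a database containing its source.
    Returns per-seed diagnostics including an overall ``success`` flag
    (retained by the filter, top-20 under both criteria, match p < 0.001).
    """
    rng = np.random.default_rng(seed)
    planted = _known_motif(rng, "planted", length=14)
    decoys = [_known_motif(rng, f"decoy{i:02d}") for i in range(n_decoys)]
    db = [planted] + [_known_motif(rng, f"known{i}", length=14)
                      for i in range(9)]
    fg, bg, _ = simulate.simulate_promoters(
        [(planted, fg_coverage, bg_coverage)], n_foreground=n_foreground,
        promoter_length=promoter_length, seed=seed)
    seqs = {**{f"fg::{k}": v for k, v in fg.items()},
            **{f"bg::{k}": v for k, v in bg.items()}}
    occ = motifs.scan_pwm(seqs, [planted] + decoys, p_threshold=p_threshold)
    labels = pd.Series({name: name.split("::")[0] for name in seqs})
    ranking = motifs.rf_rank_motifs(occ, labels, k=20, seed=seed)
    kept = motifs.coverage_filter(ranking, "A", motifs=[planted] + decoys,
                                  seed=seed)
    row = ranking.set_index("motif").loc["planted"]
    match = motifs.match_motif(planted, db, n_null=n_null, seed=seed)
    retained = "planted" in set(kept["motif"])
    top20 = bool(row["gini_rank"] <= 20 and row["infogain_rank"] <= 20)
    matched = match is not None and match.p < 1e-3
    return {
        "success": bool(retained and top20 and matched),
        "retained": retained,
        "c_fg": float(row["c_fg"]),
        "c_bg": float(row["c_bg"]),
        "gini_rank": int(row["gini_rank"]),
        "infogain_rank": int(row["infogain_rank"]),
        "match_p": float(match.p) if match is not None else 1.0,
        "n_kept": int(len(kept)),
    }


# ---------------------------------------------------------------------------
# null calibrations
# ---------------------------------------------------------------------------

def ttest_null_pvalues(seed: int, n_reps: int = 500, n1: int = 4,
                       n2: int = 7) -> np.ndarray:
    """Pooled-t p-values for draws from one normal population."""
    rng = np.random.default_rng(seed)
    out = np.empty(n_reps)
    for i in range(n_reps):
        out[i] = ttest_raw(rng.normal(10, 3, n1), rng.normal(10, 3, n2))[2]
    return out


def mannwhitney_null_pvalues(seed: int, n_reps: int = 500,
                             n_per_group: int = 10) -> np.ndarray:
    rng = np.random.default_rng(seed)
    out = np.empty(n_reps)
    for i in range(n_reps):
        out[i] = mannwhitney_values(rng.normal(size=n_per_group),
                                    rng.normal(size=n_per_group))[1]
    return out


def go5t_null_pvalues(seed: int, n_reps: int = 500, n_genes: int = 100,
                      term_size: int = 20) -> np.ndarray:
    """P-value of one randomly annotated term per replicate under a matrix
    with no term-linked expression shift."""
    rng = np.random.default_rng(seed)
    out = np.empty(n_reps)
    for i in range(n_reps):
        genes = [f"g{j}" for j in range(n_genes)]
        values = pd.DataFrame(
            rng.lognormal(2.0, 1.0, size=(n_genes, 3)),
            index=genes, columns=["s1", "s2", "s3"])
        em = simulate.ExpressionMatrix(values, {s: "G" for s in values.columns})
        members = rng.choice(n_genes, size=term_size, replace=False)
        annotation = simulate.GOAnnotation(
            {genes[j]: {"GO:TEST"} for j in members}, {})
        records = go5t.go5t_scan(em, annotation, "G")
        out[i] = records[0].p
    return out


def logrank_null_pvalues(seed: int, n_reps: int = 500,
                         n: int = 60) -> np.ndarray:
    """Logrank p-values for random splits of exchangeable survival data."""
    rng = np.random.default_rng(seed)
    out = np.empty(n_reps)
    for i in range(n_reps):
        times = rng.exponential(20.0, n)
        events = (rng.random(n) < 0.7).astype(int)
        half = n // 2
        idx = rng.permutation(n)
        a, b = idx[:half], idx[half:]
        out[i] = survival.logrank(times[a], events[a], times[b], events[b])[1]
    return out


def logrank_power(seed: int, n_reps: int = 100, n: int = 200,
                  log_hr: float = 2.0) -> float:
    """Fraction of replicates detecting a planted hazard split at p<0.05."""
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_reps):
        group = rng.random(n) < 0.5
        rate = np.where(group, 0.05 * np.exp(log_hr), 0.05)
        times = rng.exponential(1.0 / rate)
        events = np.ones(n, dtype=int)
        _, p = survival.logrank(times[group], events[group],
                                times[~group], events[~group])
        hits += p < 0.05
    return hits / n_reps


def fpr(pvalues, alpha: float = 0.05) -> float:
    p = np.asarray(pvalues, dtype=float)
    return float((p < alpha).mean())


def binomial_interval(n: int, p0: float = 0.05,
                      confidence: float = 0.99) -> tuple[float, float]:
    """Normal-approximation binomial interval for an observed proportion."""
    z = stats.norm.ppf(0.5 + confidence / 2)
    half = z * np.sqrt(p0 * (1 - p0) / n)
    return max(0.0, p0 - half), min(1.0, p0 + half)
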