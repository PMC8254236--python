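"""Synthetic data generators with known ground truth.

Every input the pipeline consumes can be generated here: FPKM-like
expression matrices whose per-gene per-group moments match configurable
targets (including the published discovery-cohort summary statistics),
foreground/background promoter sets with motif sites planted at chosen
coverage fractions, survival tables with expression-linked exponential
hazards, GO annotations with expression-shifted planted terms, and a generic
beta-value matrix for methylation-style site selection.

All generators are bit-reproducible under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import BASES, ExpressionMatrix, GOAnnotation, MotifPWM, reverse_complement
from . import tables

#: discovery-cohort design: 4 SBTs, 3 stage II + 4 stage III HGSOCs
DISCOVERY_GROUPS = {
    "sbt_vs_hgsoc": [("SBT", 4), ("HGSOC", 7)],
    "stage2_vs_stage3": [("STAGE2", 3), ("STAGE3", 4)],
}


@dataclass
class SimulationConfig:
    """Bundle of generator settings for the CLI `simulate` subcommand."""

    seed: int = 0
    n_genes: int = 100
    groups: list = field(default_factory=lambda: [("SBT", 4), ("HGSOC", 7)])
    effects: dict = field(default_factory=dict)  # gene -> {group: (mean, sd)}
    match_moments: bool = False
    promoter_length: int = 2000
    n_foreground: int = 20
    background_ratio: int = 4  # background set is 4x the foreground size
    base_composition: tuple = (0.25, 0.25, 0.25, 0.25)
    baseline_hazard: float = 0.05
    hazard_coefs: dict = field(default_factory=dict)  # gene -> log-hazard per SD
    censoring_rate: float = 0.3


# ---------------------------------------------------------------------------
# expression
# ---------------------------------------------------------------------------

def _truncated_normal(rng, mean, sd, size):
    """Draw from a normal truncated at zero (rejection; exact for sd=0)."""
    if sd == 0:
        if mean < 0:
            raise ValueError("sd=0 with negative mean cannot satisfy x >= 0")
        return np.full(size, float(mean))
    out = rng.normal(mean, sd, size)
    for _ in range(1000):
        neg = out < 0
        if not neg.any():
            return out
        out[neg] = rng.normal(mean, sd, int(neg.sum()))
    raise RuntimeError("truncated-normal rejection failed to converge")


def _match_moments_draw(rng, mean, sd, n, max_tries=1000):
    """Base draw affinely rescaled to hit (mean, sd) exactly, all values >= 0.

    Truncated-normal base draws are used while the target mean/SD ratio
    allows it; for strongly skewed targets (low mean, high SD — a nearly
    silent gene with bursts) the base switches to a right-skewed gamma whose
    population mean/SD ratio sits below the target's, which keeps the
    rescaled minimum non-negative.  Residual infeasible draws are retried,
    then values within 1e-9 of zero are clipped to exactly zero.
    """
    if n < 2:
        raise ValueError("match_moments needs n >= 2 per group (SD undefined)")
    if sd == 0:
        return np.full(n, float(mean))
    if mean <= 0:
        raise ValueError(f"mean={mean} with sd={sd} > 0 cannot be non-negative")
    ratio = mean / sd
    for attempt in range(max_tries):
        if ratio >= 1.5 and attempt < max_tries // 2:
            x = _truncated_normal(rng, mean, sd, n)
        else:
            shape = max(0.5 * ratio * ratio, 0.02)
            x = rng.gamma(shape, 1.0, n)
        xc = x - x.mean()
        s = xc.std(ddof=1)
        if s == 0:
            continue
        y = mean + xc * (sd / s)
        if y.min() >= -1e-9:
            return np.clip(y, 0.0, None)
    raise RuntimeError(
        f"could not realize non-negative sample with mean={mean}, sd={sd}, "
        f"n={n} after {max_tries} tries")


def simulate_expression(effects: dict, groups, seed: int = 0,
                        match_moments: bool = False) -> ExpressionMatrix:
    """Draw an FPKM-like matrix from per-gene per-group (mean, sd) targets.

    Parameters
    ----------
    effects
        ``{gene: {group: (mean, sd)}}``; every gene must cover every group.
    groups
        Sequence of ``(group_name, n_samples)``.
    match_moments
        If True, each gene/group cell block is affinely rescaled so the
        realized sample mean and SD (ddof=1) equal the targets exactly.
    """
    rng = np.random.default_rng(seed)
    sample_ids, labels = [], {}
    for gname, n in groups:
        if n < 2:
            raise ValueError(f"group {gname!r}: n={n} < 2")
        for i in range(n):
            sid = f"{gname}_{i + 1}"
            sample_ids.append(sid)
            labels[sid] = gname
    data = np.empty((len(effects), len(sample_ids)))
    genes = list(effects)
    for gi, gene in enumerate(genes):
        col = 0
        for gname, n in groups:
            mean, sd = effects[gene][gname]
            if sd < 0:
                raise ValueError(f"{gene}/{gname}: negative SD")
            if match_moments:
                vals = _match_moments_draw(rng, mean, sd, n)
            else:
                vals = _truncated_normal(rng, mean, sd, n)
            data[gi, col:col + n] = vals
            col += n
    values = pd.DataFrame(data, index=genes, columns=sample_ids)
    return ExpressionMatrix(values, labels)


def discovery_effects(comparison: str) -> tuple[dict, list]:
    """Effect table and group design replaying the published discovery cohort."""
    pairs = tables.summary_pairs(comparison)
    g1, g2 = tables.COMPARISON_GROUPS[comparison]
    effects = {
        row.gene: {g1: (row.m1, row.s1), g2: (row.m2, row.s2)}
        for row in pairs.itertuples()
    }
    return effects, DISCOVERY_GROUPS[comparison]


def simulate_discovery_cohort(comparison: str = "sbt_vs_hgsoc", seed: int = 0,
                              match_moments: bool = True,
                              n_null_genes: int = 0,
                              null_mean: float = 20.0,
                              null_sd: float = 8.0) -> ExpressionMatrix:
    """Synthetic stand-in for the discovery RNA-seq cohort.

    Regenerates per-gene values from the published (mean, SD, n) triples,
    optionally padded with expression-matched null genes that have no group
    difference.
    """
    effects, groups = discovery_effects(comparison)
    for i in range(n_null_genes):
        effects[f"NULL{i + 1:04d}"] = {g: (null_mean, null_sd) for g, _ in groups}
    return simulate_expression(effects, groups, seed=seed,
                               match_moments=match_moments)


# ---------------------------------------------------------------------------
# promoters
# ---------------------------------------------------------------------------

def _random_sequences(rng, n, length, base_composition, prefix):
    comp = np.asarray(base_composition, dtype=float)
    if abs(comp.sum() - 1.0) > 1e-9:
        raise ValueError("base composition must sum to 1")
    idx = rng.choice(4, size=(n, length), p=comp)
    lut = np.array(list(BASES))
    return {f"{prefix}{i + 1:03d}": "".join(lut[idx[i]]) for i in range(n)}


def _sample_site(rng, motif: MotifPWM) -> str:
    cols = [rng.choice(4, p=motif.matrix[i] / motif.matrix[i].sum())
            for i in range(len(motif))]
    return "".join(BASES[c] for c in cols)


def simulate_promoters(motif_plants, n_foreground: int = 20,
                       background_ratio: int = 4,
                       promoter_length: int = 2000,
                       base_composition=(0.25, 0.25, 0.25, 0.25),
                       seed: int = 0):
    """Foreground/background promoter sets with planted motif sites.

    ``motif_plants`` is a list of ``(MotifPWM, fg_fraction, bg_fraction)``.
    For each motif, a PWM-sampled site is inserted on a uniformly chosen
    strand at a uniform position in exactly ``round(fraction * n)`` sequences
    of each set.  Returns ``(fg_seqs, bg_seqs, truth)`` where ``truth`` is a
    DataFrame with columns (set, sequence, motif, position, strand).
    """
    rng = np.random.default_rng(seed)
    n_background = background_ratio * n_foreground
    fg = _random_sequences(rng, n_foreground, promoter_length, base_composition, "fg")
    bg = _random_sequences(rng, n_background, promoter_length, base_composition, "bg")
    truth_rows = []
    for motif, f_fg, f_bg in motif_plants:
        if not (0 <= f_fg <= 1 and 0 <= f_bg <= 1):
            raise ValueError(f"{motif.motif_id}: coverage fractions must be in [0,1]")
        if len(motif) > promoter_length:
            raise ValueError(f"motif {motif.motif_id} longer than promoter")
        for role, seqs, frac in (("fg", fg, f_fg), ("bg", bg, f_bg)):
            names = list(seqs)
            k = int(round(frac * len(names)))
            chosen = rng.choice(len(names), size=k, replace=False)
            for ci in chosen:
                name = names[ci]
                site = _sample_site(rng, motif)
                strand = "+" if rng.random() < 0.5 else "-"
                inserted = site if strand == "+" else reverse_complement(site)
                pos = int(rng.integers(0, promoter_length - len(motif) + 1))
                s = seqs[name]
                seqs[name] = s[:pos] + inserted + s[pos + len(motif):]
                truth_rows.append((role, name, motif.motif_id, pos, strand))
    truth = pd.DataFrame(truth_rows,
                         columns=["set", "sequence", "motif", "position", "strand"])
    return fg, bg, truth


# ---------------------------------------------------------------------------
# survival
# ---------------------------------------------------------------------------

def simulate_survival(expression: ExpressionMatrix,
                      hazard_coefs: dict | None = None,
                      baseline_hazard: float = 0.05,
                      censoring_rate: float = 0.3,
                      diploid_fraction: float | None = None,
                      seed: int = 0) -> pd.DataFrame:
    """Exponential survival times with expression-linked hazards.

    The per-patient hazard is ``baseline * exp(sum_g beta_g * z_g)`` over the
    coefficient genes (z-scored across patients).  Censoring is independent
    exponential, scaled so the expected censored fraction equals
    ``censoring_rate``; rate 1 censors everything.  Patients whose total
    planted log-hazard contribution is zero are flagged diploid, unless
    ``diploid_fraction`` forces a random diploid subset.
    """
    if baseline_hazard <= 0:
        raise ValueError("baseline hazard must be positive")
    if not 0 <= censoring_rate <= 1:
        raise ValueError("censoring rate must be in [0,1]")
    hazard_coefs = hazard_coefs or {}
    rng = np.random.default_rng(seed)
    patients = expression.sample_ids
    n = len(patients)
    loghaz = np.zeros(n)
    planted = np.zeros(n)
    for gene, beta in hazard_coefs.items():
        x = expression.values.loc[gene].to_numpy(dtype=float)
        sd = x.std(ddof=1)
        z = (x - x.mean()) / sd if sd > 0 else np.zeros(n)
        loghaz += beta * z
        planted += np.abs(beta * z)
    rate = baseline_hazard * np.exp(loghaz)
    t_event = rng.exponential(1.0 / rate)
    if censoring_rate >= 1.0:
        time, event = t_event, np.zeros(n, dtype=int)
    elif censoring_rate == 0.0:
        time, event = t_event, np.ones(n, dtype=int)
    else:
        c_rate = rate * censoring_rate / (1.0 - censoring_rate)
        t_cens = rng.exponential(1.0 / c_rate)
        time = np.minimum(t_event, t_cens)
        event = (t_event <= t_cens).astype(int)
    if diploid_fraction is None:
        diploid = (planted < 1e-12).astype(int)
    else:
        diploid = np.zeros(n, dtype=int)
        k = int(round(diploid_fraction * n))
        diploid[rng.choice(n, size=k, replace=False)] = 1
    table = pd.DataFrame({
        "patient_id": patients,
        "time": time,
        "event": event,
        "diploid": diploid,
    })
    for gene in expression.gene_ids:
        table[gene] = expression.values.loc[gene].to_numpy(dtype=float)
    return table


# ---------------------------------------------------------------------------
# GO annotations
# ---------------------------------------------------------------------------

def simulate_go_annotation(expression: ExpressionMatrix,
                           n_terms: int = 30,
                           genes_per_term: int = 15,
                           planted: list | None = None,
                           seed: int = 0) -> tuple[GOAnnotation, ExpressionMatrix]:
    """Random GO annotation (tree-shaped DAG) with optional planted terms.

    ``planted`` is a list of ``(term_id, delta_log2, n_genes)``: each planted
    term gets a dedicated random gene set whose expression is multiplied by
    ``2**delta`` (a shift of delta in log2 units).  Returns the annotation
    and the (possibly shifted) matrix; an empty plant spec leaves the matrix
    unchanged.
    """
    rng = np.random.default_rng(seed)
    genes = expression.gene_ids
    planted = planted or []
    term_ids = [f"GO:{i + 1:07d}" for i in range(n_terms)]
    parents: dict[str, set] = {}
    for i in range(1, n_terms):  # random tree rooted at the first term
        parents[term_ids[i]] = {term_ids[int(rng.integers(0, i))]}
    gene2terms: dict[str, set] = {}
    for term in term_ids:
        size = min(genes_per_term, len(genes))
        chosen = rng.choice(len(genes), size=size, replace=False)
        for gi in chosen:
            gene2terms.setdefault(genes[gi], set()).add(term)
    values = expression.values.copy()
    for term, delta, size in planted:
        if size > len(genes):
            raise ValueError(f"planted term {term!r} larger than gene universe")
        chosen = rng.choice(len(genes), size=size, replace=False)
        members = [genes[gi] for gi in chosen]
        for g in members:
            gene2terms.setdefault(g, set()).add(term)
        if term not in term_ids:
            parents[term] = {term_ids[0]}
            term_ids.append(term)
        values.loc[members] = values.loc[members] * (2.0 ** delta)
    annotation = GOAnnotation(gene2terms, parents)
    return annotation, ExpressionMatrix(values, dict(expression.groups))


# ---------------------------------------------------------------------------
# methylation-style beta values
# ---------------------------------------------------------------------------

def simulate_beta_matrix(n_sites: int = 1000, n_samples: int = 20,
                         seed: int = 0) -> pd.DataFrame:
    """Generic beta-value matrix (sites x samples, values in [0,1]) with
    site-specific Beta distributions; used by site-selection tests."""
    rng = np.random.default_rng(seed)
    a = rng.uniform(0.5, 5.0, n_sites)
    b = rng.uniform(0.5, 5.0, n_sites)
    data = rng.beta(a[:, None], b[:, None], size=(n_sites, n_samples))
    return pd.DataFrame(data,
                        index=[f"cg{i + 1:06d}" for i in range(n_sites)],
                        columns=[f"s{j + 1:03d}" for j in range(n_samples)])


def random_pwm(rng, length: int = 12, sharpness: float = 0.9,
               motif_id: str = "motif", concentration: float = 50.0) -> MotifPWM:
    """Random sharp PWM mimicking a curated TF motif.

    Each column has one dominant base whose probability averages
    ``sharpness`` (defaults give ~1.3 bits/column); column probabilities are
    Dirichlet-jittered so no two columns are exactly equal, as in empirical
    frequency matrices.
    """
    dominant = rng.integers(0, 4, size=length)
    mat = np.empty((length, 4))
    for i in range(length):
        alpha = np.full(4, (1.0 - sharpness) / 3.0 * concentration)
        alpha[dominant[i]] = sharpness * concentration
        mat[i] = rng.dirichlet(alpha)
    return MotifPWM(motif_id, mat)
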