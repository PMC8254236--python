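"""Promoter motif discovery, ranking and filtering.

The regulatory-analysis pipeline: extract strand-aware 2-kb promoters,
scan them with PWMs using log-odds scores whose hit threshold comes from an
exact dynamic-programming null distribution under a 0-order background
(FIMO-style), rank motifs by random-forest importance under both the Gini
and information-gain split criteria, retain the union of the top-k motifs
per criterion, apply foreground/background coverage filters, match retained
motifs to a known-motif database by mean per-column Euclidean distance with
an empirical column-shuffle null (TOMTOM-style), and count ChIP-seq binding
site intervals overlapping promoters.

A simple k-mer seed discovery stands in for external de-novo discovery
tools: any candidate PWM list can be supplied instead.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from sklearn.ensemble import RandomForestClassifier

from .io import BASES, GenomicInterval, MotifPWM, reverse_complement

_LUT = np.full(256, 4, dtype=np.int8)
for _i, _b in enumerate("ACGT"):
    _LUT[ord(_b)] = _i

DEFAULT_P_THRESHOLD = 1e-4  # FIMO's documented default
COVERAGE_REGIMES = {"A": (0.50, 0.35), "B": (0.80, 0.35)}


def encode_sequence(seq: str) -> np.ndarray:
    """A,C,G,T -> 0..3; N -> 4."""
    return _LUT[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


# ---------------------------------------------------------------------------
# promoter extraction
# ---------------------------------------------------------------------------

@dataclass
class PromoterSet:
    sequences: dict[str, str]
    role: str = "foreground"
    width: int = 2000
    truncated: set = field(default_factory=set)


def extract_promoters(tss, genome: dict[str, str], width: int = 2000) -> PromoterSet:
    """Strand-aware upstream sequences of length ``width``.

    ``tss`` is a list of GenomicInterval points whose ``start`` is the TSS
    position t: plus strand yields the forward sequence of [t-width, t),
    minus strand the reverse complement of [t, t+width).  Promoters running
    off a chromosome edge are truncated and flagged; a TSS on a missing
    chromosome or entirely off the contig is an error.
    """
    out: dict[str, str] = {}
    truncated: set = set()
    for iv in tss:
        if iv.chrom not in genome:
            raise KeyError(f"TSS {iv.name!r}: chromosome {iv.chrom!r} not in genome")
        contig = genome[iv.chrom]
        t = iv.start
        if not 0 <= t <= len(contig):
            raise ValueError(f"TSS {iv.name!r} at {t} outside {iv.chrom} "
                             f"(length {len(contig)})")
        if iv.strand == "+":
            lo, hi = max(0, t - width), t
            seq = contig[lo:hi]
        else:
            lo, hi = t, min(len(contig), t + width)
            seq = reverse_complement(contig[lo:hi])
        if len(seq) == 0:
            raise ValueError(f"TSS {iv.name!r}: promoter entirely off contig")
        if len(seq) < width:
            truncated.add(iv.name)
        out[iv.name] = seq
    return PromoterSet(out, width=width, truncated=truncated)


# ---------------------------------------------------------------------------
# PWM scanning with an exact DP null
# ---------------------------------------------------------------------------

def estimate_background(sequences) -> np.ndarray:
    """0-order base composition of the scanned set (N excluded)."""
    counts = np.zeros(4)
    for seq in (sequences.values() if isinstance(sequences, dict) else sequences):
        enc = encode_sequence(seq)
        counts += np.bincount(enc[enc < 4], minlength=4)
    if counts.sum() == 0:
        raise ValueError("no unambiguous bases in the scanned set")
    return counts / counts.sum()


def logodds_matrix(motif: MotifPWM, background) -> np.ndarray:
    """Per-column log2 odds of the motif vs the background model."""
    bg = np.asarray(background, dtype=float)
    if (motif.matrix == 0).any() and motif.pseudocount == 0:
        raise ValueError(
            f"motif {motif.motif_id!r}: zero probability with zero "
            f"pseudocount gives infinite log-odds")
    return np.log2(motif.matrix / bg)


def discretize_logodds(lo: np.ndarray, n_bins: int = 1000):
    """Round a log-odds matrix onto an integer grid of ~n_bins steps.

    Returns (integer matrix, step size).  All null-distribution and scan
    arithmetic runs on this grid so DP tails and window scores agree
    exactly.
    """
    span = float(lo.max() - lo.min())
    step = span / n_bins if span > 0 else 1.0
    return np.round(lo / step).astype(np.int64), step


def null_score_distribution(int_matrix: np.ndarray, background):
    """Exact null pmf of the total window score under the background model.

    Dynamic program: convolve the per-column score distributions of an
    i.i.d. background window.  Returns (scores, pmf, tail) where ``tail[i]``
    is P(S >= scores[i]).
    """
    bg = np.asarray(background, dtype=float)
    dist = np.ones(1)  # delta at score 0
    offset = 0  # dist[i] = P(sum == offset + i)
    for col in int_matrix:
        new_lo = offset + int(col.min())
        new_hi = offset + len(dist) - 1 + int(col.max())
        new = np.zeros(new_hi - new_lo + 1)
        for base in range(4):
            shift = int(col[base]) + offset - new_lo
            new[shift:shift + len(dist)] += bg[base] * dist
        dist, offset = new, new_lo
    scores = np.arange(offset, offset + len(dist))
    tail = np.cumsum(dist[::-1])[::-1]
    return scores, dist, tail


def score_threshold(motif: MotifPWM, background, p_threshold: float,
                    n_bins: int = 1000):
    """Smallest integer window score whose null tail is < p_threshold.

    Returns (int_matrix, step, threshold); threshold is None when no
    achievable score is that rare (the motif can never produce a hit).
    """
    lo = logodds_matrix(motif, background)
    int_matrix, step = discretize_logodds(lo, n_bins)
    scores, _, tail = null_score_distribution(int_matrix, background)
    below = tail < p_threshold
    if not below.any():
        return int_matrix, step, None
    return int_matrix, step, int(scores[np.argmax(below)])


@dataclass
class OccurrenceMatrix:
    """Binary promoters x motifs presence matrix with per-cell best hits."""

    presence: pd.DataFrame  # int8, promoters x motifs
    best: dict              # (promoter, motif) -> (score_bits, position, strand)
    p_threshold: float
    background: np.ndarray


def _window_scores(enc: np.ndarray, int_matrix: np.ndarray) -> np.ndarray:
    """Total discretized score of every window; NaN for N-containing windows."""
    L = int_matrix.shape[0]
    n_win = len(enc) - L + 1
    if n_win <= 0:
        return np.full(0, np.nan)
    windows = np.lib.stride_tricks.sliding_window_view(enc, L)
    valid = (windows < 4).all(axis=1)
    safe = np.where(windows < 4, windows, 0)
    scores = int_matrix[np.arange(L), safe].sum(axis=1).astype(float)
    scores[~valid] = np.nan
    return scores


def scan_pwm(promoters, motifs, p_threshold: float = DEFAULT_P_THRESHOLD,
             background=None, n_bins: int = 1000) -> OccurrenceMatrix:
    """Scan promoter sequences with PWMs on both strands.

    A promoter/motif cell is 1 iff at least one window's log-odds score has
    an exact null p-value below ``p_threshold`` under the 0-order background
    (estimated from the scanned set unless supplied).  Windows containing N
    are skipped.  Reverse-strand hits are found by scanning with the
    reverse-complement matrix; reported positions index the forward strand.
    """
    seqs = promoters.sequences if isinstance(promoters, PromoterSet) else promoters
    if background is None:
        background = estimate_background(seqs)
    names = list(seqs)
    max_len = max(len(m) for m in motifs)
    # concatenate all sequences with N runs between them: windows crossing a
    # boundary contain N and are skipped, so one vectorized pass per motif
    # and strand scores every promoter at once
    sep = np.full(max_len, 4, dtype=np.int8)
    pieces, starts, lengths = [], [], []
    pos = 0
    for name in names:
        enc = encode_sequence(seqs[name])
        starts.append(pos)
        lengths.append(len(enc))
        pieces.extend([enc, sep])
        pos += len(enc) + len(sep)
    big = np.concatenate(pieces[:-1]) if pieces else np.zeros(0, dtype=np.int8)
    presence = pd.DataFrame(0, index=names, columns=[m.motif_id for m in motifs],
                            dtype=np.int8)
    best: dict = {}
    for motif in motifs:
        int_fwd, step, thr = score_threshold(motif, background, p_threshold, n_bins)
        if thr is None:
            continue
        L = len(motif)
        for strand, mat in (("+", int_fwd), ("-", int_fwd[::-1, ::-1])):
            scores = _window_scores(big, mat)
            scores = np.where(np.isnan(scores), -np.inf, scores)
            for name, s0, n in zip(names, starts, lengths):
                seg = scores[s0:s0 + n - L + 1]
                if seg.size == 0:
                    continue
                i = int(np.argmax(seg))
                if seg[i] >= thr:
                    prev = best.get((name, motif.motif_id))
                    if prev is None or seg[i] * step > prev[0]:
                        best[(name, motif.motif_id)] = (float(seg[i]) * step, i, strand)
                    presence.loc[name, motif.motif_id] = 1
    return OccurrenceMatrix(presence, best, p_threshold, np.asarray(background))


# ---------------------------------------------------------------------------
# RF ranking, coverage and accuracy
# ---------------------------------------------------------------------------

def coverage(presence: pd.DataFrame, labels: pd.Series) -> pd.DataFrame:
    """Per-motif foreground/background coverage = class-wise column means."""
    labels = labels.loc[presence.index]
    fg = presence[labels == "fg"].mean(axis=0)
    bg = presence[labels == "bg"].mean(axis=0)
    return pd.DataFrame({"c_fg": fg, "c_bg": bg})


def single_motif_accuracy(presence: pd.DataFrame, motif_id: str,
                          labels: pd.Series) -> float:
    """Accuracy of the one-motif rule: call foreground iff the motif occurs."""
    labels = labels.loc[presence.index]
    pred_fg = presence[motif_id] == 1
    correct = (pred_fg & (labels == "fg")) | (~pred_fg & (labels == "bg"))
    return float(correct.mean())


def rf_rank_motifs(occ: OccurrenceMatrix | pd.DataFrame, labels: pd.Series,
                   k: int = 20, seed: int = 0,
                   n_estimators: int = 500) -> pd.DataFrame:
    """Rank motifs by RF mean-decrease-in-impurity importance.

    Two forests are fit on the binary occurrence matrix, one per split
    criterion (Gini impurity; entropy / information gain).  The retained set
    is the union of the top-k motifs under each criterion.  Ties in
    importance break by motif id.  Returns one row per motif with both
    importances, both 1-based ranks, class coverages, single-motif accuracy
    and a ``kept`` flag.
    """
    presence = occ.presence if isinstance(occ, OccurrenceMatrix) else occ
    labels = pd.Series(labels).loc[presence.index]
    if set(labels.unique()) != {"fg", "bg"}:
        raise ValueError("labels must contain both 'fg' and 'bg'")
    n_motifs = presence.shape[1]
    if k > n_motifs:
        k = n_motifs
    X = presence.to_numpy(dtype=float)
    y = (labels == "fg").to_numpy(dtype=int)
    rng = np.random.default_rng(seed)
    importances = {}
    for crit, col in (("gini", "gini"), ("entropy", "infogain")):
        forest = RandomForestClassifier(
            n_estimators=n_estimators, criterion=crit,
            random_state=int(rng.integers(2**31)), n_jobs=1)
        forest.fit(X, y)
        importances[col] = pd.Series(forest.feature_importances_,
                                     index=presence.columns)
    cov = coverage(presence, labels)
    out = pd.DataFrame({
        "motif": presence.columns,
        "gini_importance": importances["gini"].values,
        "infogain_importance": importances["infogain"].values,
        "c_fg": cov["c_fg"].values,
        "c_bg": cov["c_bg"].values,
        "accuracy": [single_motif_accuracy(presence, m, labels)
                     for m in presence.columns],
    }).set_index("motif")
    for col in ("gini", "infogain"):
        order = sorted(out.index, key=lambda m: (-out.loc[m, f"{col}_importance"], m))
        out.loc[order, f"{col}_rank"] = np.arange(1, n_motifs + 1)
        out[f"{col}_rank"] = out[f"{col}_rank"].astype(int)
    out["kept"] = (out["gini_rank"] <= k) | (out["infogain_rank"] <= k)
    return out.reset_index()


def coverage_filter(rankings: pd.DataFrame, regime: str = "A",
                    motifs: list[MotifPWM] | None = None,
                    match_p: float = 1e-3, n_null: int = 2000,
                    seed: int = 0) -> pd.DataFrame:
    """Coverage filtering of the retained motifs.

    Regime A keeps motifs with c_fg >= 0.50 and c_bg <= 0.35; regime B with
    c_fg >= 0.80 and c_bg <= 0.35.  When PWMs are supplied, near-duplicate
    survivors (pairwise Euclidean match p < ``match_p``) are deduplicated,
    dropping the motif with the lower foreground coverage.
    """
    if regime not in COVERAGE_REGIMES:
        raise ValueError(f"unknown regime {regime!r}; expected 'A' or 'B'")
    fg_min, bg_max = COVERAGE_REGIMES[regime]
    df = rankings[rankings["kept"]] if "kept" in rankings else rankings
    df = df[(df["c_fg"] >= fg_min) & (df["c_bg"] <= bg_max)].copy()
    if motifs is not None and len(df) > 1:
        by_id = {m.motif_id: m for m in motifs}
        order = df.sort_values(["c_fg", "motif"],
                               ascending=[False, True])["motif"].tolist()
        dropped: set = set()
        for i, a in enumerate(order):
            if a in dropped:
                continue
            for b in order[i + 1:]:
                if b in dropped or a not in by_id or b not in by_id:
                    continue
                match = match_motif(by_id[b], [by_id[a]], n_null=n_null, seed=seed)
                if match is not None and match.p < match_p:
                    dropped.add(b)  # b has lower (or tied-later) c_fg
        df = df[~df["motif"].isin(dropped)]
    return df.reset_index(drop=True)


# ---------------------------------------------------------------------------
# motif similarity matching (Euclidean, empirical column-shuffle null)
# ---------------------------------------------------------------------------

@dataclass
class MotifMatch:
    query: str
    target: str
    offset: int
    orientation: str  # + or -
    distance: float
    p: float


def _alignment_distances(qmat: np.ndarray, tmats: np.ndarray,
                         min_overlap: int = 4) -> np.ndarray:
    """Best mean per-column Euclidean distance of a query against a batch of
    equal-length target matrices, over all offsets and both orientations.

    ``tmats`` has shape (n, Lt, 4).  Returns shape (n,) of best distances
    (inf where no alignment reaches the overlap minimum).
    """
    n, Lt, _ = tmats.shape
    Lq = qmat.shape[0]
    best = np.full(n, np.inf)
    for tm in (tmats, tmats[:, ::-1, ::-1]):
        for off in range(-(Lt - min_overlap), Lq - min_overlap + 1):
            q_lo, q_hi = max(0, off), min(Lq, off + Lt)
            if q_hi - q_lo < min_overlap:
                continue
            t_lo = q_lo - off
            q_slice = qmat[q_lo:q_hi]
            t_slice = tm[:, t_lo:t_lo + (q_hi - q_lo)]
            d = np.sqrt(((q_slice[None] - t_slice) ** 2).sum(axis=2)).mean(axis=1)
            best = np.minimum(best, d)
    return best


def _best_alignment(qmat: np.ndarray, tmat: np.ndarray, min_overlap: int = 4):
    """Best (distance, offset, orientation) of query vs a single target."""
    Lq, Lt = qmat.shape[0], tmat.shape[0]
    best = (np.inf, 0, "+")
    for orient, tm in (("+", tmat), ("-", tmat[::-1, ::-1])):
        for off in range(-(Lt - min_overlap), Lq - min_overlap + 1):
            q_lo, q_hi = max(0, off), min(Lq, off + Lt)
            if q_hi - q_lo < min_overlap:
                continue
            t_lo = q_lo - off
            d = float(np.sqrt(
                ((qmat[q_lo:q_hi] - tm[t_lo:t_lo + (q_hi - q_lo)]) ** 2)
                .sum(axis=1)).mean())
            if d < best[0]:
                best = (d, off, orient)
    return best


def match_motif(query: MotifPWM, db: list[MotifPWM], n_null: int = 10_000,
                seed: int = 0, min_overlap: int = 4) -> MotifMatch | None:
    """Best database match of a query PWM with an empirical p-value.

    The distance is the mean per-column Euclidean distance over the best
    ungapped alignment (both orientations, overlap >= ``min_overlap``).  The
    null pool consists of ``n_null`` column-shuffled database motifs (which
    preserves per-column sharpness); the reported p uses the add-one rule
    p = (1 + #{null <= observed}) / (n_null + 1).  Returns None when no
    alignment reaches the overlap minimum for any database motif.
    """
    if not db:
        raise ValueError("empty motif database")
    qmat = query.matrix
    best = None
    for target in db:
        d, off, orient = _best_alignment(qmat, target.matrix, min_overlap)
        if np.isfinite(d) and (best is None or d < best.distance):
            best = MotifMatch(query.motif_id, target.motif_id, off, orient,
                              d, p=1.0)
    if best is None:
        return None
    rng = np.random.default_rng(seed)
    null_dists = []
    by_len: dict[int, list[np.ndarray]] = {}
    for i in range(n_null):
        src = db[i % len(db)].matrix
        perm = rng.permutation(src.shape[0])
        by_len.setdefault(src.shape[0], []).append(src[perm])
    for L, mats in by_len.items():
        null_dists.append(_alignment_distances(qmat, np.stack(mats), min_overlap))
    null = np.concatenate(null_dists)
    null = null[np.isfinite(null)]
    best.p = float((1 + (null <= best.distance + 1e-12).sum()) / (len(null) + 1))
    return best


# ---------------------------------------------------------------------------
# TF binding-site interval overlap
# ---------------------------------------------------------------------------

def count_tfbs_overlaps(promoters: list[GenomicInterval],
                        tfbs: dict[str, list[GenomicInterval]]) -> pd.DataFrame:
    """Per-TF count of promoters overlapped by at least one binding site.

    Overlap is half-open interval intersection; each promoter counts once
    per TF.  A TF whose sites share no chromosome with any promoter raises
    an error naming the offending chromosomes.  Output is ranked by count
    descending, ties by TF name.
    """
    trees: dict[str, IntervalTree] = {}
    prom_chroms = set()
    for i, iv in enumerate(promoters):
        trees.setdefault(iv.chrom, IntervalTree()).addi(iv.start, iv.end, i)
        prom_chroms.add(iv.chrom)
    rows = []
    for tf in sorted(tfbs):
        sites = tfbs[tf]
        site_chroms = {s.chrom for s in sites}
        if sites and not site_chroms & prom_chroms:
            raise ValueError(
                f"TF {tf!r}: no shared chromosomes with promoters "
                f"(sites on {sorted(site_chroms)}, promoters on "
                f"{sorted(prom_chroms)})")
        hit: set = set()
        for s in sites:
            if s.chrom in trees:
                hit |= {h.data for h in trees[s.chrom].overlap(s.start, s.end)}
        rows.append({"tf": tf, "n_promoters": len(hit)})
    out = pd.DataFrame(rows)
    if len(out):
        out = out.sort_values(["n_promoters", "tf"],
                              ascending=[False, True]).reset_index(drop=True)
    return out


# ---------------------------------------------------------------------------
# k-mer seed discovery
# ---------------------------------------------------------------------------

def _kmer_presence(seqs: dict[str, str], k: int) -> np.ndarray:
    """Per-sequence presence (either strand) of every k-mer; shape (n, 4^k)."""
    n = len(seqs)
    pres = np.zeros((n, 4 ** k), dtype=bool)
    weights = 4 ** np.arange(k - 1, -1, -1)
    for si, seq in enumerate(seqs.values()):
        for s in (seq, reverse_complement(seq)):
            enc = encode_sequence(s)
            if len(enc) < k:
                continue
            win = np.lib.stride_tricks.sliding_window_view(enc, k)
            valid = (win < 4).all(axis=1)
            ids = (win[valid] * weights).sum(axis=1)
            pres[si, np.unique(ids)] = True
    return pres


def _decode_kmer(idx: int, k: int) -> str:
    out = []
    for _ in range(k):
        out.append(BASES[idx % 4])
        idx //= 4
    return "".join(reversed(out))


def kmer_seed_discovery(fg: dict[str, str], bg: dict[str, str], k: int = 6,
                        n_seeds: int = 5,
                        pseudocount: float = 0.5) -> tuple[list[MotifPWM], pd.DataFrame]:
    """Rank k-mers by a binomial z-score of foreground vs background
    per-sequence presence and extend the top seeds into PWMs.

    The PWM for a seed averages all foreground windows within Hamming
    distance 1 of the seed (reverse-strand occurrences are complemented into
    motif orientation), with a pseudocount.  Returns (pwms, table) where the
    table lists every k-mer's presence fractions and z-score.
    """
    if not fg or not bg:
        raise ValueError("foreground and background sets must be non-empty")
    min_len = min(len(s) for s in list(fg.values()) + list(bg.values()))
    if k > min_len:
        raise ValueError(f"k={k} exceeds shortest sequence length {min_len}")
    p_fg = _kmer_presence(fg, k).mean(axis=0)
    p_bg = _kmer_presence(bg, k).mean(axis=0)
    n1, n2 = len(fg), len(bg)
    pooled = (p_fg * n1 + p_bg * n2) / (n1 + n2)
    var = pooled * (1 - pooled) * (1 / n1 + 1 / n2)
    with np.errstate(invalid="ignore", divide="ignore"):
        z = np.where(var > 0, (p_fg - p_bg) / np.sqrt(var), 0.0)
    kmers = [_decode_kmer(i, k) for i in range(4 ** k)]
    table = pd.DataFrame({"kmer": kmers, "p_fg": p_fg, "p_bg": p_bg, "z": z})
    table = table.sort_values(["z", "kmer"],
                              ascending=[False, True]).reset_index(drop=True)
    pwms = []
    for kmer in table["kmer"].head(n_seeds):
        seed_enc = encode_sequence(kmer)
        rc_enc = encode_sequence(reverse_complement(kmer))
        counts = np.full((k, 4), pseudocount)
        for seq in fg.values():
            enc = encode_sequence(seq)
            if len(enc) < k:
                continue
            win = np.lib.stride_tricks.sliding_window_view(enc, k)
            valid = (win < 4).all(axis=1)
            win = win[valid]
            fwd = win[(win != seed_enc).sum(axis=1) <= 1]
            for w in fwd:
                counts[np.arange(k), w] += 1
            rev = win[(win != rc_enc).sum(axis=1) <= 1]
            for w in rev:
                counts[np.arange(k), (3 - w)[::-1]] += 1
        pwms.append(MotifPWM(f"seed_{kmer}",
                             counts / counts.sum(axis=1, keepdims=True),
                             pseudocount=pseudocount))
    return pwms, table
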