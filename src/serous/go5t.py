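"""GO enrichment by the tree-travel / transform / t-test ("5T") scheme.

For each GO term, genes annotated to the term (after propagating
annotations up the is_a DAG) form the in-group and all remaining expressed
genes the out-group; a pooled two-sample t-test compares the transformed
per-gene mean expression of the two sets within a chosen sample group.  No
gene-set overlap statistics (Fisher, GSEA) are involved: the statistic
operates directly on expression values.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from .deg import _bh_qvalues, ttest_raw
from .io import ExpressionMatrix, GOAnnotation

log = logging.getLogger(__name__)


@dataclass
class GOEnrichmentRecord:
    term: str
    n_in: int
    n_out: int
    t: float
    df: float
    p: float
    q: float
    delta: float  # in-group minus out-group mean, transformed units


def tree_travel(annotation: GOAnnotation) -> dict[str, set]:
    """Propagate annotations to ancestors: each gene becomes annotated to
    every term reachable from its direct terms via is_a edges.

    Raises on a cyclic DAG, naming one edge of the cycle.
    """
    g = nx.DiGraph()
    g.add_nodes_from(annotation.terms())
    for child, parents in annotation.term_parents.items():
        for parent in parents:
            g.add_edge(child, parent)
    try:
        cycle = nx.find_cycle(g)
        raise ValueError(f"GO DAG contains a cycle through edge {cycle[0]}")
    except nx.NetworkXNoCycle:
        pass
    ancestors = {term: nx.descendants(g, term) for term in g.nodes}
    propagated: dict[str, set] = {}
    for gene, terms in annotation.gene2terms.items():
        full = set(terms)
        for term in terms:
            full |= ancestors.get(term, set())
        propagated[gene] = full
    return propagated


def go5t_scan(matrix: ExpressionMatrix, annotation: GOAnnotation,
              group: str, transform: bool = True,
              min_in_group: int = 2) -> list[GOEnrichmentRecord]:
    """Per-term in-group vs out-group t-test on per-gene mean expression.

    Only expressed genes (mean FPKM > 0 within the queried sample group)
    enter the universe.  ``transform`` applies log2(x+1) to the per-gene
    means before testing.  Terms with fewer than ``min_in_group`` expressed
    in-group genes, or an empty out-group, are skipped with a log notice.
    Records are sorted by p ascending, ties by term id.
    """
    samples = matrix.samples_in(group)
    means = matrix.values[samples].mean(axis=1)
    means = means[means > 0]
    if transform:
        means = np.log2(means + 1.0)
    universe = set(means.index)
    propagated = tree_travel(annotation)
    term2genes: dict[str, set] = {}
    for gene, terms in propagated.items():
        if gene in universe:
            for term in terms:
                term2genes.setdefault(term, set()).add(gene)
    rows = []
    for term in sorted(term2genes):
        in_genes = term2genes[term]
        out_genes = universe - in_genes
        if len(in_genes) < min_in_group or len(out_genes) < 2:
            log.info("skipping %s: n_in=%d, n_out=%d",
                     term, len(in_genes), len(out_genes))
            continue
        v_in = means.loc[sorted(in_genes)].to_numpy()
        v_out = means.loc[sorted(out_genes)].to_numpy()
        t, df, p = ttest_raw(v_in, v_out)
        rows.append((term, len(in_genes), len(out_genes), t, df, p,
                     float(v_in.mean() - v_out.mean())))
    if not rows:
        return []
    qvals = _bh_qvalues(np.array([r[5] for r in rows]))
    records = [
        GOEnrichmentRecord(term, n_in, n_out, t, df, p, q, delta)
        for (term, n_in, n_out, t, df, p, delta), q in zip(rows, qvals)
    ]
    records.sort(key=lambda r: (r.p, r.term))
    return records


def enrichment_to_frame(records) -> pd.DataFrame:
    return pd.DataFrame([{
        "term": r.term, "n_in": r.n_in, "n_out": r.n_out,
        "t": r.t, "df": r.df, "p": r.p, "q": r.q, "delta": r.delta,
    } for r in records])
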