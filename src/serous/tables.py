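"""Published per-group summary statistics for the discovery cohort.

The package ships the printed group means, standard deviations and sample
sizes for the 11 genes separating serous borderline tumors (SBT, n=4) from
high-grade serous ovarian cancers (HGSOC, n=7), and the 17 genes separating
stage II (n=3) from stage III (n=4) HGSOC, together with the published
signed fold changes and t-test p-values.  These triples drive the worked
examples and the synthetic discovery cohort.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

COMPARISONS = ("sbt_vs_hgsoc", "stage2_vs_stage3")

# (group1, group2) per comparison; fold change is mean(group1)/mean(group2)
COMPARISON_GROUPS = {
    "sbt_vs_hgsoc": ("SBT", "HGSOC"),
    "stage2_vs_stage3": ("STAGE2", "STAGE3"),
}


def load_discovery_summary(comparison: str | None = None) -> pd.DataFrame:
    """Long-format summary table: gene, comparison, group, mean, sd, n,
    printed_fc, printed_p (one row per gene per group)."""
    with resources.files("serous.data").joinpath("deg_summary.tsv").open() as fh:
        df = pd.read_csv(fh, sep="\t")
    if comparison is not None:
        if comparison not in COMPARISONS:
            raise KeyError(f"unknown comparison {comparison!r}; "
                           f"expected one of {COMPARISONS}")
        df = df[df["comparison"] == comparison].reset_index(drop=True)
    return df


def summary_pairs(comparison: str) -> pd.DataFrame:
    """Wide per-gene table for one comparison.

    Columns: gene, m1, s1, n1, m2, s2, n2, printed_fc, printed_p, where
    group 1/2 follow :data:`COMPARISON_GROUPS` order.
    """
    g1, g2 = COMPARISON_GROUPS[comparison]
    df = load_discovery_summary(comparison)
    a = df[df["group"] == g1].set_index("gene")
    b = df[df["group"] == g2].set_index("gene")
    out = pd.DataFrame({
        "m1": a["mean"], "s1": a["sd"], "n1": a["n"].astype(int),
        "m2": b["mean"], "s2": b["sd"], "n2": b["n"].astype(int),
        "printed_fc": a["printed_fc"], "printed_p": a["printed_p"],
    })
    # preserve the published (fold-change-sorted) row order
    order = [g for g in df["gene"].unique()]
    return out.loc[order].reset_index(names="gene")
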