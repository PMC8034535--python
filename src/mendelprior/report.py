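"""Ranked-term summary: top-k table twin plus a best-effort dot plot
(y: term names in rank order, x: overlap gene count, point size: gene ratio,
colour: empirical p)."""

from __future__ import annotations

import pandas as pd

from .errors import ValidationError


def render_top_terms(
    results: list,
    k: int = 50,
    table_path=None,
    figure_path=None,
) -> pd.DataFrame:
    """Top-k most significant terms in reporting order. The table is always
    written when a path is given; the figure is best-effort and never raises."""
    if k <= 0:
        raise ValidationError("k must be positive", code="bad_k")
    top = results[:k]
    df = pd.DataFrame(
        {
            "rank": range(1, len(top) + 1),
            "term_id": [r.term_id for r in top],
            "term_name": [r.term_name for r in top],
            "n_genes_in_intervals": [r.n_genes_in_intervals for r in top],
            "n_genome_annotated": [r.n_genome_annotated for r in top],
            "gene_ratio": [round(r.gene_ratio, 6) for r in top],
            "empirical_p": [r.empirical_p for r in top],
            "corrected_p": [r.corrected_p for r in top],
        }
    )
    if table_path is not None:
        df.to_csv(table_path, sep="\t", index=False)
    if figure_path is not None and len(df):
        try:
            _plot(df, figure_path)
        except Exception:  # pragma: no cover - plotting must never fail a run
            pass
    return df


def _plot(df: pd.DataFrame, figure_path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    n = len(df)
    fig, ax = plt.subplots(figsize=(8, max(3, 0.25 * n + 1.5)))
    y = range(n, 0, -1)
    sizes = 40 + 260 * df["gene_ratio"].to_numpy()
    sc = ax.scatter(
        df["n_genes_in_intervals"], list(y),
        s=sizes, c=df["empirical_p"], cmap="viridis_r",
        edgecolors="black", linewidths=0.3,
    )
    ax.set_yticks(list(y))
    ax.set_yticklabels(df["term_name"], fontsize=7)
    ax.set_xlabel("genes overlapping term in tested intervals")
    fig.colorbar(sc, ax=ax, label="empirical p-value")
    fig.tight_layout()
    fig.savefig(figure_path, dpi=120)
    plt.close(fig)
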