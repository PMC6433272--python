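"""Cross-species gene mapping for probes designed against the human genome.

Significant probes carry hg19 gene symbols; a gene is usable in the dog only
when it has both a homolog (shared ancestry, genome-browser inference) and
an ortholog (speciation-derived counterpart, Ensembl-style inference) in the
canine assembly. The mapping is driven by a static ortholog table so runs
are reproducible without live database queries.

Gene direction: a gene's hyper/hypo call is the direction of its
minimum-p probe; ties break by larger \\|logFC\\|, then lexicographic probe id.
"""

from __future__ import annotations

import pandas as pd


def map_genes(
    significant: pd.DataFrame, ortholog_table: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Summarise significant probes per gene, keeping dual-flagged genes.

    Parameters
    ----------
    significant : DataFrame
        MVP table indexed by probe id with columns ``gene``, ``p_value``,
        ``logFC``, ``direction``.
    ortholog_table : DataFrame
        Columns ``human_gene``, ``homolog`` (bool), ``ortholog`` (bool),
        ``dog_gene`` (nonempty iff both flags true).

    Returns
    -------
    (summaries, unmapped)
        ``summaries``: one row per mapped gene with the dog symbol, best
        (minimum) p, that probe's direction and logFC, and probe count.
        ``unmapped``: genes dropped, with the failing flag as reason
        ('absent', 'no_homolog', 'no_ortholog', or 'no_homolog+no_ortholog').
    """
    if ortholog_table["human_gene"].duplicated().any():
        dups = ortholog_table.loc[ortholog_table["human_gene"].duplicated(), "human_gene"]
        raise ValueError(f"duplicate human gene symbols in ortholog table: {sorted(set(dups))[:5]}")
    sig = significant.dropna(subset=["gene"])
    sig = sig[sig["gene"] != ""]
    lut = ortholog_table.set_index("human_gene")

    summaries, unmapped = [], []
    for gene, probes in sig.groupby("gene", sort=True):
        if gene not in lut.index:
            unmapped.append({"human_gene": gene, "reason": "absent"})
            continue
        row = lut.loc[gene]
        homolog, ortholog = bool(row["homolog"]), bool(row["ortholog"])
        if not (homolog and ortholog):
            reasons = []
            if not homolog:
                reasons.append("no_homolog")
            if not ortholog:
                reasons.append("no_ortholog")
            unmapped.append({"human_gene": gene, "reason": "+".join(reasons)})
            continue
        # order: p ascending, then |logFC| descending, then probe id
        ordered = probes.assign(_abs=probes["logFC"].abs())
        ordered = ordered.sort_index(kind="stable")
        ordered = ordered.sort_values("_abs", ascending=False, kind="stable")
        ordered = ordered.sort_values("p_value", kind="stable")
        top = ordered.iloc[0]
        summaries.append(
            {
                "dog_gene": row["dog_gene"],
                "human_gene": gene,
                "best_p": float(top["p_value"]),
                "direction": top["direction"],
                "logFC": float(top["logFC"]),
                "n_probes": len(probes),
            }
        )
    return (
        pd.DataFrame(summaries, columns=["dog_gene", "human_gene", "best_p", "direction", "logFC", "n_probes"]),
        pd.DataFrame(unmapped, columns=["human_gene", "reason"]),
    )


def direction_census(summaries: pd.DataFrame) -> tuple[int, int]:
    """Count (hypermethylated, hypomethylated) genes in the case group."""
    if len(summaries) == 0:
        return (0, 0)
    n_hyper = int((summaries["direction"] == "hyper").sum())
    n_hypo = int((summaries["direction"] == "hypo").sum())
    return (n_hyper, n_hypo)
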