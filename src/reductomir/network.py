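"""ReductomiR tier calls, the bipartite miRNA-mRNA network, and ORA.

A "reductomiR" is an induced, ARE-bearing miRNA; tiers nest:

    induced              pooled-contrast log2FC > 0 with p < threshold
    are_demir            induced AND >= 1 promoter ARE hit
    dose_reductomir      are_demir AND significant in the dose contrast
    effector_reductomir  dose_reductomir AND >= 1 consensus target among
                         the suppressed DEGs

The bipartite network connects miRNAs to their consensus targets with edge
weight equal to the number of supporting evidence sources. Over-representation
analysis is the exact hypergeometric upper tail against user-supplied gene
sets with Benjamini-Hochberg adjustment; the enrichment ratio is the
percentage of a set's (universe-restricted) members present in the query.
"""

from __future__ import annotations

import warnings
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .core_io import GeneSetCollection, write_tsv

__all__ = [
    "TIERS",
    "call_reductomirs",
    "reductomir_summary",
    "build_network",
    "network_to_edge_frame",
    "write_network",
    "ora",
]

TIERS = ("none", "are_demir", "dose_reductomir", "effector_reductomir")


def call_reductomirs(
    pooled_de: pd.DataFrame,
    dose_de: pd.DataFrame,
    are_counts: Mapping[str, int] | pd.Series,
    interactions: pd.DataFrame,
    suppressed_degs: Sequence[str],
    p_threshold: float = 0.05,
    use_adjusted: bool = False,
) -> tuple[pd.DataFrame, dict]:
    """Assign the nested reductomiR tier to every miRNA in the pooled table.

    Returns (calls, summary). ``calls`` has one row per miRNA with the
    evidence columns and the highest tier reached; ``summary`` reports nested
    tier counts and the percentage of dose reductomiRs that are effectors
    (rounded to the nearest integer).
    """
    pcol = "qvalue_bonferroni" if use_adjusted else "pvalue"
    are_counts = pd.Series(dict(are_counts), dtype=float) if not isinstance(
        are_counts, pd.Series
    ) else are_counts
    supp = set(suppressed_degs)
    kept = interactions[interactions["target_id"].isin(supp)]
    n_targets = kept.groupby("mirna_id")["target_id"].nunique()

    dose_p = dose_de.set_index("feature_id")[pcol]
    rows = []
    for _, row in pooled_de.iterrows():
        mid = row["feature_id"]
        p = row[pcol]
        induced = bool(row["log2FC"] > 0 and np.isfinite(p) and p < p_threshold)
        n_are = int(are_counts.get(mid, 0))
        pd_dose = dose_p.get(mid, np.nan)
        dose_responsive = bool(np.isfinite(pd_dose) and pd_dose < p_threshold)
        nt = int(n_targets.get(mid, 0))
        if induced and n_are >= 1:
            if dose_responsive:
                tier = "effector_reductomir" if nt >= 1 else "dose_reductomir"
            else:
                tier = "are_demir"
        else:
            tier = "none"
        rows.append(
            {
                "mirna_id": mid,
                "induced": induced,
                "are_count": n_are,
                "dose_responsive": dose_responsive,
                "n_targets": nt,
                "tier": tier,
            }
        )
    calls = pd.DataFrame(
        rows,
        columns=["mirna_id", "induced", "are_count", "dose_responsive", "n_targets", "tier"],
    )
    return calls, reductomir_summary(calls)


def reductomir_summary(calls: pd.DataFrame) -> dict:
    """Nested tier counts and effector coverage of the dose tier (percent)."""
    tier = calls["tier"]
    n_eff = int((tier == "effector_reductomir").sum())
    n_dose = n_eff + int((tier == "dose_reductomir").sum())
    n_are = n_dose + int((tier == "are_demir").sum())
    coverage = int(round(100.0 * n_eff / n_dose)) if n_dose else 0
    return {
        "n_mirnas": int(len(calls)),
        "n_induced": int(calls["induced"].sum()),
        "n_are_demir": n_are,
        "n_dose_reductomir": n_dose,
        "n_effector_reductomir": n_eff,
        "effector_coverage_pct": coverage,
    }


def build_network(interactions: pd.DataFrame) -> nx.Graph:
    """Bipartite miRNA-mRNA graph with evidence-count edge weights.

    miRNA nodes carry ``bipartite=0``, targets ``bipartite=1``; an identifier
    appearing on both sides is a namespace collision and raises.
    """
    mirnas = set(interactions["mirna_id"]) if len(interactions) else set()
    targets = set(interactions["target_id"]) if len(interactions) else set()
    overlap = mirnas & targets
    if overlap:
        raise ValueError(
            f"identifiers appear as both miRNA and target: {sorted(overlap)[:5]}"
        )
    g = nx.Graph()
    g.add_nodes_from(sorted(mirnas), bipartite=0, kind="miRNA")
    g.add_nodes_from(sorted(targets), bipartite=1, kind="mRNA")
    frame = interactions.sort_values(["mirna_id", "target_id"]) if len(interactions) else interactions
    for _, row in frame.iterrows():
        weight = int(row["n_sources"]) if "n_sources" in row else 1
        g.add_edge(row["mirna_id"], row["target_id"], weight=weight)
    for node in g.nodes:
        g.nodes[node]["degree"] = g.degree(node)
    return g


def network_to_edge_frame(g: nx.Graph) -> pd.DataFrame:
    rows = []
    for u, v, data in g.edges(data=True):
        mirna, target = (u, v) if g.nodes[u].get("bipartite") == 0 else (v, u)
        rows.append(
            {"mirna_id": mirna, "target_id": target, "weight": data.get("weight", 1)}
        )
    frame = pd.DataFrame(rows, columns=["mirna_id", "target_id", "weight"])
    return frame.sort_values(["mirna_id", "target_id"]).reset_index(drop=True)


def write_network(g: nx.Graph, graphml_path, edge_tsv_path) -> None:
    nx.write_graphml(g, graphml_path)
    write_tsv(network_to_edge_frame(g), edge_tsv_path)


def ora(
    query: Sequence[str],
    collection: GeneSetCollection,
    universe: Sequence[str],
) -> pd.DataFrame:
    """Hypergeometric over-representation of the query in each gene set.

    p = P(X >= k) for X ~ Hypergeometric(N, K, n) with N the universe size,
    K the (universe-restricted) set size, n the query size and k the overlap;
    BH adjustment across tested sets; results sorted by p. Query genes
    outside the universe are dropped with a warning; sets with no member in
    the universe are skipped.
    """
    universe_set = set(universe)
    if not universe_set:
        raise ValueError("empty universe")
    query_set = set(query)
    outside = query_set - universe_set
    if outside:
        warnings.warn(
            f"{len(outside)} query genes outside the universe were dropped"
        )
        query_set &= universe_set
    N, n = len(universe_set), len(query_set)
    rows = []
    for name, genes in collection.sets.items():
        members = set(genes) & universe_set
        K = len(members)
        if K == 0:
            warnings.warn(f"gene set {name!r} has no members in the universe; skipped")
            continue
        k = len(members & query_set)
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
        rows.append(
            {
                "set_name": name,
                "overlap": k,
                "set_size": K,
                "query_size": n,
                "universe_size": N,
                "pvalue": min(p, 1.0),
                "enrichment_ratio": 100.0 * k / K,
            }
        )
    result = pd.DataFrame(
        rows,
        columns=[
            "set_name",
            "overlap",
            "set_size",
            "query_size",
            "universe_size",
            "pvalue",
            "enrichment_ratio",
        ],
    )
    if len(result):
        result["qvalue_bh"] = multipletests(result["pvalue"], method="fdr_bh")[1]
    else:
        result["qvalue_bh"] = pd.Series(dtype=float)
    return result.sort_values("pvalue", kind="stable").reset_index(drop=True)
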