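"""End-to-end orchestration: counts -> DE -> Venn -> ARE scan -> targets -> tiers.

Mirrors the integrative analysis flow: differential expression of miRNA and
mRNA counts under the pooled (Tg vs NTg) and dose (TgH vs TgL) contrasts,
Venn classification, promoter ARE scanning of the miRNA loci, seed-match
target prediction of the induced miRNAs inside the suppressed transgene-dose
DEGs, cross-source consensus, and the nested reductomiR tier calls with the
bipartite network.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import pandas as pd

from . import classify, diffexpr, motif_scan, network, targeting
from .core_io import PWM, CountMatrix

__all__ = ["StudyResults", "run_de_pair", "run_study"]


@dataclass
class StudyResults:
    mirna_pooled: pd.DataFrame
    mirna_dose: pd.DataFrame
    mrna_pooled: pd.DataFrame
    mrna_dose: pd.DataFrame
    mirna_venn: pd.DataFrame
    mrna_venn: pd.DataFrame
    are_hits: list
    are_counts: pd.Series
    seed_sites: list
    consensus: pd.DataFrame
    linked: pd.DataFrame
    calls: pd.DataFrame
    summary: dict
    graph: nx.Graph
    induced_demirs: list[str]
    suppressed_degs: list[str]


def run_de_pair(cm: CountMatrix) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Size factors, shrunken dispersions, and both contrasts for one assay."""
    sf = diffexpr.estimate_size_factors(cm)
    disp = diffexpr.estimate_dispersions(cm, sf)
    pooled = diffexpr.wald_test(cm, sf, disp, contrast="pooled")
    dose = diffexpr.wald_test(cm, sf, disp, contrast="dose")
    return pooled, dose


def run_study(
    cm_mirna: CountMatrix,
    cm_mrna: CountMatrix,
    genome,
    annotations,
    mirna_seqs,
    utrs,
    pwm: PWM,
    external_predictions: pd.DataFrame | None = None,
    p_threshold: float = 0.05,
    window_size: int = 5000,
    min_relative_score: float = 0.8,
    k_min: int = 3,
) -> StudyResults:
    """Run the full discovery analysis and return every intermediate product.

    Suppressed DEGs are the transgene-dose mRNAs with negative pooled fold
    change; induced DEmiRs are pooled-significant miRNAs with positive fold
    change. Seed matching is restricted to that cross, as in a targeted
    follow-up of the suppressed subset.
    """
    mi_pooled, mi_dose = run_de_pair(cm_mirna)
    mr_pooled, mr_dose = run_de_pair(cm_mrna)

    mi_venn = classify.venn_classify(mi_pooled, mi_dose, p_threshold=p_threshold)
    mr_venn = classify.venn_classify(mr_pooled, mr_dose, p_threshold=p_threshold)

    induced = list(
        mi_pooled.loc[
            (mi_pooled["pvalue"] < p_threshold) & (mi_pooled["log2FC"] > 0),
            "feature_id",
        ]
    )
    suppressed = list(
        mr_venn.loc[
            (mr_venn["subset"] == "transgene_dose") & (mr_venn["lfc_pooled"] < 0),
            "feature_id",
        ]
    )

    windows = motif_scan.extract_promoters(annotations, genome, window_size=window_size)
    hits = motif_scan.scan(windows, pwm, min_relative_score=min_relative_score)
    are_counts, _bearing, _total = motif_scan.count_ares(
        hits, demirs=list(cm_mirna.feature_ids)
    )

    mirna_subset = {m: mirna_seqs[m] for m in induced if m in mirna_seqs}
    utr_subset = {g: utrs[g] for g in suppressed if g in utrs}
    sites = targeting.find_seed_sites(mirna_subset, utr_subset)
    evidence = [targeting.seed_sites_to_predictions(sites)]
    if external_predictions is not None:
        evidence.append(external_predictions[["mirna_id", "target_id", "source"]])
    cons = targeting.consensus(pd.concat(evidence, ignore_index=True), k_min=k_min)
    linked = targeting.link_to_suppressed(cons, suppressed, induced)

    calls, summary = network.call_reductomirs(
        mi_pooled,
        mi_dose,
        are_counts,
        cons,
        suppressed,
        p_threshold=p_threshold,
    )
    graph = network.build_network(linked)

    return StudyResults(
        mirna_pooled=mi_pooled,
        mirna_dose=mi_dose,
        mrna_pooled=mr_pooled,
        mrna_dose=mr_dose,
        mirna_venn=mi_venn,
        mrna_venn=mr_venn,
        are_hits=hits,
        are_counts=are_counts,
        seed_sites=sites,
        consensus=cons,
        linked=linked,
        calls=calls,
        summary=summary,
        graph=graph,
        induced_demirs=induced,
        suppressed_degs=suppressed,
    )
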