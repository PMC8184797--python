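"""Canonical miRNA seed-match target prediction and cross-source consensus.

A miRNA's seed is nucleotides 2-8 of the mature sequence. Canonical 3'UTR
sites are exact reverse complements of (parts of) the seed, graded
8mer > 7mer-m8 > 7mer-A1 > 6mer:

    8mer     rc(nt 2-8) followed by A
    7mer-m8  rc(nt 2-8)
    7mer-A1  rc(nt 2-7) followed by A
    6mer     rc(nt 2-7)

At any one seed-match locus only the highest grade is reported. The consensus
combiner takes prediction tables from arbitrary evidence sources (external
algorithm exports plus the internal matcher) and keeps (miRNA, target) pairs
supported by at least ``k_min`` distinct sources.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .core_io import read_fasta, revcomp

__all__ = [
    "SeedSite",
    "SITE_TYPES",
    "find_seed_sites",
    "seed_sites_to_frame",
    "seed_sites_to_predictions",
    "consensus",
    "link_to_suppressed",
]

SITE_TYPES = ("8mer", "7mer-m8", "7mer-A1", "6mer")


@dataclass(frozen=True)
class SeedSite:
    mirna_id: str
    target_id: str
    site_type: str
    utr_offset: int  # 0-based offset of the site's 5'-most UTR base
    matched_seq: str


def _normalize(seq: str) -> str:
    return seq.upper().replace("U", "T")


def find_seed_sites(
    mirna_seqs: Mapping[str, str] | str | Path,
    utrs: Mapping[str, str] | str | Path,
    site_types: Sequence[str] = SITE_TYPES,
) -> list[SeedSite]:
    """Exhaustively locate canonical seed-match sites of each miRNA in each UTR.

    Inputs may be mappings or FASTA paths; U is normalized to T. miRNAs
    shorter than 8 nt are skipped with a warning. For every occurrence of the
    6mer core rc(nt 2-7), the flanking bases decide the grade, so lower-grade
    calls at the same locus are naturally subsumed by the highest grade.
    Output is sorted by (miRNA, target, offset).
    """
    if not isinstance(mirna_seqs, Mapping):
        mirna_seqs = read_fasta(mirna_seqs)
    if not isinstance(utrs, Mapping):
        utrs = read_fasta(utrs)
    wanted = set(site_types)
    unknown = wanted - set(SITE_TYPES)
    if unknown:
        raise ValueError(f"unknown site types: {sorted(unknown)}")

    # concatenate UTRs with an impossible-separator pad so one C-level string
    # search per miRNA covers every UTR
    utr_ids = list(utrs)
    pad = "X" * 10
    seqs = [_normalize(utrs[u]) for u in utr_ids]
    big = pad.join(seqs)
    starts = np.empty(len(utr_ids), dtype=np.int64)
    pos = 0
    for i, s in enumerate(seqs):
        starts[i] = pos
        pos += len(s) + len(pad)
    lengths = np.array([len(s) for s in seqs], dtype=np.int64)

    sites: list[SeedSite] = []
    for mid in mirna_seqs:
        seq = _normalize(mirna_seqs[mid])
        if len(seq) < 8:
            warnings.warn(f"miRNA {mid} shorter than 8 nt; skipped")
            continue
        rc7 = revcomp(seq[1:8])  # rc of nt 2-8; rc7[1:] is rc of nt 2-7
        core = rc7[1:]
        m8_base = rc7[0]
        p = big.find(core)
        while p != -1:
            u = int(np.searchsorted(starts, p, side="right") - 1)
            local = p - int(starts[u])
            if local + 6 <= int(lengths[u]):  # not straddling the pad
                utr = seqs[u]
                has_m8 = local > 0 and utr[local - 1] == m8_base
                has_a1 = local + 6 < len(utr) and utr[local + 6] == "A"
                if has_m8 and has_a1:
                    stype, off, matched = "8mer", local - 1, rc7 + "A"
                elif has_m8:
                    stype, off, matched = "7mer-m8", local - 1, rc7
                elif has_a1:
                    stype, off, matched = "7mer-A1", local, core + "A"
                else:
                    stype, off, matched = "6mer", local, core
                if stype in wanted:
                    sites.append(SeedSite(mid, utr_ids[u], stype, off, matched))
            p = big.find(core, p + 1)
    sites.sort(key=lambda s: (s.mirna_id, s.target_id, s.utr_offset))
    return sites


def seed_sites_to_frame(sites: Iterable[SeedSite]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "mirna_id": s.mirna_id,
                "target_id": s.target_id,
                "site_type": s.site_type,
                "utr_offset": s.utr_offset,
                "matched_seq": s.matched_seq,
            }
            for s in sites
        ],
        columns=["mirna_id", "target_id", "site_type", "utr_offset", "matched_seq"],
    )


def seed_sites_to_predictions(
    sites: Iterable[SeedSite], source: str = "internal-seed"
) -> pd.DataFrame:
    """Collapse seed sites into one evidence row per (miRNA, target) pair.

    The internal matcher contributes at most one source per pair regardless of
    how many sites it found.
    """
    frame = seed_sites_to_frame(sites)
    pairs = frame[["mirna_id", "target_id"]].drop_duplicates()
    return pairs.assign(source=source).reset_index(drop=True)


def consensus(predictions: pd.DataFrame, k_min: int = 3) -> pd.DataFrame:
    """Keep (miRNA, target) pairs supported by >= k_min distinct sources.

    ``predictions`` needs columns mirna_id, target_id, source; duplicate
    (mirna, target, source) rows are deduplicated before counting. Returns a
    DataFrame with n_sources and the sorted comma-joined source list, ordered
    by (mirna_id, target_id).
    """
    required = {"mirna_id", "target_id", "source"}
    missing = required - set(predictions.columns)
    if missing:
        raise ValueError(f"prediction table missing columns: {sorted(missing)}")
    dedup = predictions[["mirna_id", "target_id", "source"]].drop_duplicates()
    grouped = (
        dedup.groupby(["mirna_id", "target_id"], sort=True)["source"]
        .agg(lambda s: sorted(s))
        .reset_index()
    )
    grouped["n_sources"] = grouped["source"].str.len()
    grouped["sources"] = grouped["source"].str.join(",")
    kept = grouped.loc[grouped["n_sources"] >= k_min, ["mirna_id", "target_id", "n_sources", "sources"]]
    return kept.reset_index(drop=True)


def link_to_suppressed(
    interactions: pd.DataFrame,
    suppressed_degs: Sequence[str],
    induced_demirs: Sequence[str],
) -> pd.DataFrame:
    """Restrict consensus interactions to induced miRNAs and suppressed targets.

    The returned frame's ``attrs`` carry the distinct miRNA and target counts.
    """
    supp = set(suppressed_degs)
    ind = set(induced_demirs)
    kept = interactions[
        interactions["mirna_id"].isin(ind) & interactions["target_id"].isin(supp)
    ].reset_index(drop=True)
    kept.attrs["n_mirnas"] = int(kept["mirna_id"].nunique())
    kept.attrs["n_targets"] = int(kept["target_id"].nunique())
    return kept
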