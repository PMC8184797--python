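"""Promoter-window extraction and strand-aware PWM scanning for ARE motifs.

Windows default to the 5,000 bp strictly upstream of the annotated TSS,
strand-aware and truncated at chromosome edges. Match scores are summed
log2(p/background) ("log-odds, bits"); hits are reported above a relative
score threshold, where relative score rescales [min_score, max_score] of the
matrix to [0, 1]. Overlapping hits are all retained.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .core_io import PWM, FeatureAnnotation, revcomp

__all__ = [
    "PromoterWindow",
    "MotifHit",
    "extract_promoters",
    "scan",
    "count_ares",
    "hits_to_frame",
    "write_hits_bed",
]

_CODE = np.full(256, 4, dtype=np.int8)
for _i, _b in enumerate("ACGT"):
    _CODE[ord(_b)] = _i
    _CODE[ord(_b.lower())] = _i


@dataclass(frozen=True)
class PromoterWindow:
    """Upstream window of a feature, oriented 5'->3' toward the TSS."""

    feature_id: str
    chrom: str
    start: int  # genomic, 0-based half-open
    end: int
    strand: str  # strand of the parent feature
    sequence: str

    def __post_init__(self) -> None:
        if len(self.sequence) != self.end - self.start:
            raise ValueError(
                f"window sequence length {len(self.sequence)} != interval "
                f"size {self.end - self.start} for {self.feature_id}"
            )


@dataclass(frozen=True)
class MotifHit:
    """A single PWM match inside a promoter window."""

    feature_id: str
    offset: int  # 0-based within the window
    chrom: str
    start: int  # genomic interval of the match
    end: int
    strand: str  # strand of the match relative to the reference
    score: float  # log-odds, bits
    rel_score: float  # (score - min) / (max - min), in [0, 1]
    matched_seq: str  # as read on the match strand (aligns with the PWM)


def _fetch(genome, chrom: str, start: int, end: int) -> str:
    if isinstance(genome, Mapping):
        return genome[chrom][start:end]
    return str(genome[chrom][start:end])  # pyfaidx.Fasta


def _chrom_len(genome, chrom: str) -> int:
    return len(genome[chrom])


def extract_promoters(
    annotations: Iterable[FeatureAnnotation],
    genome,
    window_size: int = 5000,
    downstream_extension: int = 0,
) -> list[PromoterWindow]:
    """Extract upstream promoter windows, strand-aware and edge-truncated.

    ``genome`` is a mapping of chrom -> sequence or a ``pyfaidx.Fasta``. On
    the + strand the window is [tss - window_size, tss); on the - strand it is
    [tss + 1, tss + 1 + window_size) reverse-complemented, so the returned
    sequence always reads 5'->3' toward the TSS. ``downstream_extension``
    extends the window past the TSS into the feature.
    """
    if isinstance(genome, (str, Path)):
        import pyfaidx

        genome = pyfaidx.Fasta(str(genome))
    windows: list[PromoterWindow] = []
    for ann in annotations:
        try:
            clen = _chrom_len(genome, ann.chrom)
        except KeyError:
            raise KeyError(f"chromosome {ann.chrom!r} missing from genome")
        tss = ann.tss
        if ann.strand == "+":
            start, end = tss - window_size, tss + downstream_extension
        else:
            start, end = tss + 1 - downstream_extension, tss + 1 + window_size
        tstart, tend = max(0, start), min(clen, end)
        if tend <= tstart:
            warnings.warn(f"window for {ann.feature_id} lies entirely off-chromosome")
            windows.append(
                PromoterWindow(ann.feature_id, ann.chrom, tstart, tstart, ann.strand, "")
            )
            continue
        if (tstart, tend) != (start, end):
            warnings.warn(
                f"window for {ann.feature_id} truncated to [{tstart}, {tend})"
            )
        seq = _fetch(genome, ann.chrom, tstart, tend).upper()
        if ann.strand == "-":
            seq = revcomp(seq)
        windows.append(
            PromoterWindow(ann.feature_id, ann.chrom, tstart, tend, ann.strand, seq)
        )
    return windows


def _window_scores(codes: np.ndarray, lodds: np.ndarray) -> np.ndarray:
    """Scores of every offset of a length-L matrix along an encoded sequence.

    ``lodds`` has an appended 5th row of -inf so any N in a window sinks its
    score; hence N-containing offsets can never be reported as hits.
    """
    L = lodds.shape[1]
    aug = np.vstack([lodds, np.full((1, L), -np.inf)])
    if len(codes) < L:
        return np.empty(0)
    view = np.lib.stride_tricks.sliding_window_view(codes, L)
    with np.errstate(invalid="ignore"):
        return aug[view, np.arange(L)].sum(axis=1)


def scan(
    windows: Iterable[PromoterWindow],
    pwm: PWM,
    min_relative_score: float = 0.8,
    both_strands: bool = True,
) -> list[MotifHit]:
    """Scan windows with the PWM on one or both strands.

    Every offset is scored; all hits with relative score >= the threshold are
    reported (overlaps retained), sorted by (feature, offset). Windows shorter
    than the matrix yield no hits. Reverse-strand matches are located by
    scanning with the reverse-complemented matrix, so offsets refer to the
    forward window coordinate of the site's leftmost base.
    """
    lodds = pwm.log_odds()
    lodds_rc = lodds[[3, 2, 1, 0], :][:, ::-1]
    span = pwm.max_score - pwm.min_score
    L = pwm.length
    hits: list[MotifHit] = []
    for w in windows:
        if len(w.sequence) < L:
            continue
        codes = _CODE[np.frombuffer(w.sequence.encode(), dtype=np.uint8)]
        strands = [("+", lodds)] + ([("-", lodds_rc)] if both_strands else [])
        found: list[tuple[int, str, float]] = []
        for strand, mat in strands:
            scores = _window_scores(codes, mat)
            rel = (scores - pwm.min_score) / span
            for off in np.flatnonzero(rel >= min_relative_score):
                found.append((int(off), strand, float(scores[off])))
        for off, strand, score in sorted(found):
            seq = w.sequence[off : off + L]
            if strand == "-":
                seq = revcomp(seq)
            # map window offset to genomic coordinates
            if w.strand == "+":
                gstart = w.start + off
                gstrand = strand
            else:
                gstart = w.end - off - L
                gstrand = "-" if strand == "+" else "+"
            hits.append(
                MotifHit(
                    feature_id=w.feature_id,
                    offset=off,
                    chrom=w.chrom,
                    start=gstart,
                    end=gstart + L,
                    strand=gstrand,
                    score=score,
                    rel_score=(score - pwm.min_score) / span,
                    matched_seq=seq,
                )
            )
    return hits


def count_ares(
    hits: Iterable[MotifHit], demirs: Sequence[str] | None = None
) -> tuple[pd.Series, list[str], int]:
    """Per-feature hit counts, the ARE-bearing feature list, and the total.

    If ``demirs`` is given, the count vector covers exactly those features
    (zero-filled); otherwise it covers features with at least one hit.
    """
    counts: dict[str, int] = {}
    for h in hits:
        counts[h.feature_id] = counts.get(h.feature_id, 0) + 1
    if demirs is not None:
        series = pd.Series({f: counts.get(f, 0) for f in demirs}, dtype=int)
    else:
        series = pd.Series(counts, dtype=int)
    series.index.name = "feature_id"
    series.name = "n_ares"
    bearing = sorted(series.index[series > 0])
    return series.sort_index(), bearing, int(series.sum())


def hits_to_frame(hits: Iterable[MotifHit]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "feature_id": h.feature_id,
                "chrom": h.chrom,
                "start": h.start,
                "end": h.end,
                "strand": h.strand,
                "offset": h.offset,
                "score": h.score,
                "rel_score": h.rel_score,
                "matched_seq": h.matched_seq,
            }
            for h in hits
        ],
        columns=[
            "feature_id",
            "chrom",
            "start",
            "end",
            "strand",
            "offset",
            "score",
            "rel_score",
            "matched_seq",
        ],
    )


def write_hits_bed(hits: Iterable[MotifHit], path) -> None:
    """BED6 output: name = feature_id, score = relative score x 1000."""
    with open(path, "w", encoding="utf-8") as fh:
        for h in hits:
            fh.write(
                f"{h.chrom}\t{h.start}\t{h.end}\t{h.feature_id}\t"
                f"{int(round(h.rel_score * 1000))}\t{h.strand}\n"
            )
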