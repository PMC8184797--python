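"""Data model and readers/writers for every external format the pipeline touches.

All genomic coordinates are 0-based, half-open (BED convention) internally;
GFF3 input is converted on read. The TSS of a minus-strand feature is
``end - 1`` under this convention. Count matrices must contain raw integer
counts: normalized inputs are rejected rather than silently accepted, because
median-of-ratios size-factor estimation assumes raw counts.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO, motifs
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "SampleDesign",
    "CountMatrix",
    "FeatureAnnotation",
    "PWM",
    "GeneSetCollection",
    "read_design",
    "read_count_matrix",
    "read_annotations",
    "read_pwm",
    "read_gmt",
    "read_fasta",
    "write_design",
    "write_count_matrix",
    "write_bed",
    "write_gmt",
    "write_fasta",
    "write_tsv",
    "revcomp",
]

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")
ALPHABET = "ACGT"


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (N-safe)."""
    return seq.translate(_COMPLEMENT)[::-1]


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass
class SampleDesign:
    """Sample sheet for a dose design: group labels with integer dose codes.

    ``dose_code`` encodes the ordinal transgene dose (e.g. NTg=0, TgL=1,
    TgH=2; or WT=0, KO=1). The group -> dose_code mapping must be a bijection.
    """

    frame: pd.DataFrame  # columns: sample_id, group, dose_code

    def __post_init__(self) -> None:
        required = {"sample_id", "group", "dose_code"}
        missing = required - set(self.frame.columns)
        if missing:
            raise ValueError(f"design table missing columns: {sorted(missing)}")
        if self.frame["sample_id"].duplicated().any():
            dups = self.frame.loc[self.frame["sample_id"].duplicated(), "sample_id"]
            raise ValueError(f"duplicate sample_ids in design: {list(dups)}")
        codes = self.frame.groupby("group", observed=True)["dose_code"].nunique()
        if (codes != 1).any():
            raise ValueError("dose_code is not constant within a group")
        mapping = self.group_dose_map
        if len(set(mapping.values())) != len(mapping):
            raise ValueError("group -> dose_code mapping is not a bijection")
        if (self.frame["dose_code"] < 0).any():
            raise ValueError("dose_code must be >= 0")
        self.frame = self.frame.reset_index(drop=True)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.frame["sample_id"])

    @property
    def groups(self) -> pd.Series:
        return self.frame.set_index("sample_id")["group"]

    @property
    def dose_codes(self) -> pd.Series:
        return self.frame.set_index("sample_id")["dose_code"]

    @property
    def group_dose_map(self) -> dict[str, int]:
        return dict(
            self.frame.drop_duplicates("group").set_index("group")["dose_code"]
        )

    def samples_in_group(self, group: str) -> list[str]:
        return list(self.frame.loc[self.frame["group"] == group, "sample_id"])

    def require_min_group_size(self, n: int = 2) -> None:
        sizes = self.frame.groupby("group", observed=True).size()
        small = sizes[sizes < n]
        if len(small):
            raise ValueError(
                f"groups with fewer than {n} samples: {dict(small)}"
            )


@dataclass
class CountMatrix:
    """Raw integer counts, features x samples, aligned to a SampleDesign."""

    counts: pd.DataFrame  # index: feature_id, columns: sample_id, int dtype
    design: SampleDesign
    feature_kind: str = "mRNA"  # {"miRNA", "mRNA"}

    def __post_init__(self) -> None:
        if self.feature_kind not in {"miRNA", "mRNA"}:
            raise ValueError(f"unknown feature_kind: {self.feature_kind!r}")
        if self.counts.index.duplicated().any():
            dups = self.counts.index[self.counts.index.duplicated()]
            raise ValueError(f"duplicate feature_ids: {list(dups[:5])}")
        design_samples = self.design.sample_ids
        extra = set(self.counts.columns) - set(design_samples)
        if extra:
            raise ValueError(f"samples in counts absent from design: {sorted(extra)}")
        missing = set(design_samples) - set(self.counts.columns)
        if missing:
            raise ValueError(f"design samples absent from counts: {sorted(missing)}")
        values = self.counts.to_numpy()
        if not np.issubdtype(values.dtype, np.integer):
            flat = np.asarray(values, dtype=float)
            if np.any(~np.isfinite(flat)) or np.any(flat != np.round(flat)):
                bad = np.argwhere(flat != np.round(flat))
                if len(bad):
                    i, j = bad[0]
                    raise ValueError(
                        "non-integer count at feature "
                        f"{self.counts.index[i]!r}, sample {self.counts.columns[j]!r}"
                    )
                raise ValueError("non-finite count values")
            values = flat.astype(np.int64)
        if (values < 0).any():
            i, j = np.argwhere(values < 0)[0]
            raise ValueError(
                f"negative count at feature {self.counts.index[i]!r}, "
                f"sample {self.counts.columns[j]!r}"
            )
        # column order follows the design order
        self.counts = pd.DataFrame(
            values.astype(np.int64), index=self.counts.index, columns=self.counts.columns
        )[design_samples]

    @property
    def feature_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def values(self) -> np.ndarray:
        return self.counts.to_numpy()


@dataclass(frozen=True)
class FeatureAnnotation:
    """Genomic interval of a feature, 0-based half-open, with derived TSS."""

    feature_id: str
    chrom: str
    start: int
    end: int
    strand: str

    def __post_init__(self) -> None:
        if self.strand not in {"+", "-"}:
            raise ValueError(f"unknown strand {self.strand!r} for {self.feature_id}")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval [{self.start}, {self.end}) for {self.feature_id}"
            )

    @property
    def tss(self) -> int:
        """Transcription start: ``start`` on +, ``end - 1`` on - (half-open)."""
        return self.start if self.strand == "+" else self.end - 1


@dataclass
class PWM:
    """Position probability matrix over A,C,G,T with background frequencies.

    ``probs`` is 4 x L, rows in A,C,G,T order; every column sums to 1 and all
    entries are strictly positive after pseudocount regularization. Match
    scores are summed log2 odds against the background.
    """

    probs: np.ndarray
    background: np.ndarray = field(
        default_factory=lambda: np.full(4, 0.25)
    )
    pseudocount: float = 1.0
    name: str = "motif"

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=float)
        self.background = np.asarray(self.background, dtype=float)
        if self.probs.ndim != 2 or self.probs.shape[0] != 4:
            raise ValueError("PWM probability matrix must be 4 x L")
        if not np.allclose(self.probs.sum(axis=0), 1.0, atol=1e-9):
            raise ValueError("PWM columns must each sum to 1")
        if (self.probs <= 0).any():
            raise ValueError("PWM entries must be strictly positive (use a pseudocount)")
        if not np.isclose(self.background.sum(), 1.0, atol=1e-9):
            raise ValueError("background must sum to 1")

    @property
    def length(self) -> int:
        return self.probs.shape[1]

    def log_odds(self) -> np.ndarray:
        """4 x L matrix of log2(p / background)."""
        return np.log2(self.probs / self.background[:, None])

    @property
    def max_score(self) -> float:
        return float(self.log_odds().max(axis=0).sum())

    @property
    def min_score(self) -> float:
        return float(self.log_odds().min(axis=0).sum())

    def consensus(self) -> str:
        return "".join(ALPHABET[i] for i in self.probs.argmax(axis=0))

    def sample(self, rng: np.random.Generator, n: int = 1) -> list[str]:
        """Draw n sequences column-wise from the position probabilities."""
        out = []
        for _ in range(n):
            idx = [rng.choice(4, p=self.probs[:, j]) for j in range(self.length)]
            out.append("".join(ALPHABET[i] for i in idx))
        return out


@dataclass
class GeneSetCollection:
    """Named gene sets (GMT-style) with an optional explicit universe."""

    sets: dict[str, list[str]]
    universe: list[str] | None = None
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, genes in self.sets.items():
            if not genes:
                raise ValueError(f"gene set {name!r} is empty")
            if len(set(genes)) != len(genes):
                raise ValueError(f"gene set {name!r} has duplicate members")


# ---------------------------------------------------------------------------
# Readers
# ---------------------------------------------------------------------------


def read_design(path: str | Path) -> SampleDesign:
    frame = pd.read_csv(path, sep="\t", comment="#", dtype={"sample_id": str})
    return SampleDesign(frame[["sample_id", "group", "dose_code"]])


def read_count_matrix(
    path: str | Path,
    design_path: str | Path | None = None,
    *,
    design: SampleDesign | None = None,
    feature_kind: str = "mRNA",
) -> tuple[CountMatrix, SampleDesign]:
    """Read a TSV count matrix (first column feature_id) plus its design table.

    Columns are reordered to design order; non-integer or negative cells are
    hard errors that name the offending row and column.
    """
    if design is None:
        if design_path is None:
            raise ValueError("either design_path or design must be given")
        design = read_design(design_path)
    table = pd.read_csv(path, sep="\t", comment="#", index_col=0)
    table.index = table.index.astype(str)
    cm = CountMatrix(counts=table, design=design, feature_kind=feature_kind)
    return cm, design


def _parse_gff3_attributes(attr: str) -> dict[str, str]:
    out: dict[str, str] = {}
    for item in attr.strip().split(";"):
        if "=" in item:
            k, v = item.split("=", 1)
            out[k.strip()] = v.strip()
    return out


def read_annotations(
    path: str | Path, fmt: str | None = None
) -> list[FeatureAnnotation]:
    """Read BED6 or GFF3 feature annotations into the internal convention.

    BED is already 0-based half-open; GFF3 (1-based inclusive) is converted by
    ``start -= 1``. Format is inferred from the extension unless ``fmt`` is
    one of ``"bed"`` or ``"gff3"``.
    """
    path = Path(path)
    if fmt is None:
        suffix = path.suffix.lower()
        if suffix == ".bed":
            fmt = "bed"
        elif suffix in {".gff", ".gff3"}:
            fmt = "gff3"
        else:
            raise ValueError(
                f"cannot infer annotation format from {path.name!r}; pass fmt="
            )
    records: list[FeatureAnnotation] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if fmt == "bed":
                if len(fields) < 6:
                    raise ValueError(f"{path.name}:{lineno}: BED6 needs 6 fields")
                chrom, start, end, name, _score, strand = fields[:6]
                start_i, end_i = int(start), int(end)
            else:
                if len(fields) < 9:
                    raise ValueError(f"{path.name}:{lineno}: GFF3 needs 9 fields")
                chrom, _src, _type, start, end, _score, strand, _phase, attrs = fields[:9]
                start_i, end_i = int(start) - 1, int(end)
                parsed = _parse_gff3_attributes(attrs)
                name = parsed.get("ID") or parsed.get("Name") or f"feature_{lineno}"
            if start_i >= end_i:
                raise ValueError(
                    f"{path.name}:{lineno}: empty or inverted interval "
                    f"[{start_i}, {end_i})"
                )
            records.append(
                FeatureAnnotation(
                    feature_id=name, chrom=chrom, start=start_i, end=end_i, strand=strand
                )
            )
    return records


def _parse_meme_probabilities(path: Path) -> tuple[np.ndarray, str]:
    """Read the first letter-probability matrix of a MEME minimal file.

    Rows in the file are motif positions over the A,C,G,T alphabet; the
    returned matrix is 4 x L.
    """
    name = path.stem
    rows: list[list[float]] = []
    width = None
    with open(path) as fh:
        in_matrix = False
        for line in fh:
            stripped = line.strip()
            if stripped.startswith("MOTIF"):
                parts = stripped.split()
                if len(parts) > 1:
                    name = parts[1]
            if stripped.startswith("letter-probability matrix"):
                in_matrix = True
                if "w=" in stripped.replace(" ", ""):
                    compact = stripped.replace(" ", "")
                    width = int(compact.split("w=")[1].split("nsites")[0].strip("= "))
                continue
            if in_matrix:
                if not stripped:
                    if rows:
                        break
                    continue
                values = stripped.split()
                if len(values) != 4:
                    break
                rows.append([float(v) for v in values])
                if width is not None and len(rows) == width:
                    break
    if not rows:
        raise ValueError(f"no letter-probability matrix found in {path}")
    return np.array(rows, dtype=float).T, name


def _looks_like_probabilities(matrix: np.ndarray) -> bool:
    return bool(np.all(matrix <= 1.0 + 1e-9) and np.allclose(matrix.sum(axis=0), 1.0, atol=1e-6))


def read_pwm(
    path: str | Path,
    pseudocount: float = 1.0,
    background: Sequence[float] = (0.25, 0.25, 0.25, 0.25),
) -> PWM:
    """Read a JASPAR count matrix or a MEME minimal motif into a PWM.

    Count matrices are converted with p = (n + pseudocount * bg) / (N + pseudocount)
    per column; probability matrices pass through up to renormalization (with
    the pseudocount applied only if a column contains exact zeros).
    """
    path = Path(path)
    background = np.asarray(background, dtype=float)
    fmt = "minimal" if path.suffix.lower() in {".meme", ".txt"} else "jaspar"
    if fmt == "minimal":
        # the MEME letter-probability block is read directly: round-tripping
        # through nsites-scaled integer counts would corrupt the probabilities
        counts, name = _parse_meme_probabilities(path)
    else:
        with open(path) as fh:
            motif = motifs.parse(fh, fmt)[0]
        counts = np.array([list(motif.counts[base]) for base in ALPHABET], dtype=float)
        name = getattr(motif, "matrix_id", None) or motif.name or path.stem
    if counts.shape[0] != 4 or counts.size == 0:
        raise ValueError("PWM must have 4 rows (A, C, G, T)")
    if (counts < 0).any():
        raise ValueError("negative entries in motif matrix")
    if _looks_like_probabilities(counts):
        probs = counts / counts.sum(axis=0, keepdims=True)
        if (probs == 0).any():
            if pseudocount <= 0:
                raise ValueError("zero column entry with pseudocount 0")
            probs = (probs + pseudocount * background[:, None]) / (1.0 + pseudocount)
    else:
        totals = counts.sum(axis=0)
        if np.any((totals + pseudocount) <= 0) or (
            pseudocount <= 0 and np.any(totals == 0)
        ):
            raise ValueError("zero column in count matrix with pseudocount 0")
        probs = (counts + pseudocount * background[:, None]) / (totals + pseudocount)
        if (probs <= 0).any():
            raise ValueError(
                "zero column entry survives pseudocount; increase pseudocount"
            )
    return PWM(probs=probs, background=background, pseudocount=pseudocount, name=str(name))


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Read a GMT gene-set file; duplicate members are deduplicated with a warning."""
    sets: dict[str, list[str]] = {}
    descriptions: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                warnings.warn(f"GMT line {lineno}: fewer than 3 fields, skipped")
                continue
            name, desc, *genes = fields
            genes = [g for g in genes if g]
            if not genes:
                warnings.warn(f"GMT set {name!r} has no genes, skipped")
                continue
            unique = list(dict.fromkeys(genes))
            if len(unique) != len(genes):
                warnings.warn(f"GMT set {name!r}: duplicate genes deduplicated")
            sets[name] = unique
            descriptions[name] = desc
    if not sets:
        raise ValueError(f"no usable gene sets in {path}")
    return GeneSetCollection(sets=sets, descriptions=descriptions)


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a (small) FASTA into an ordered dict of uppercase sequences."""
    return {
        rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")
    }


# ---------------------------------------------------------------------------
# Writers (all UTF-8, tab-separated, '#'-prefixed header comments)
# ---------------------------------------------------------------------------


def write_tsv(
    frame: pd.DataFrame, path: str | Path, comments: Iterable[str] = (), index: bool = False
) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for c in comments:
            fh.write(f"# {c}\n")
        frame.to_csv(fh, sep="\t", index=index)


def write_design(design: SampleDesign, path: str | Path, comments: Iterable[str] = ()) -> None:
    write_tsv(design.frame, path, comments=comments)


def write_count_matrix(cm: CountMatrix, path: str | Path, comments: Iterable[str] = ()) -> None:
    frame = cm.counts.copy()
    frame.index.name = "feature_id"
    write_tsv(frame, path, comments=comments, index=True)


def write_bed(annotations: Iterable[FeatureAnnotation], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for a in annotations:
            fh.write(f"{a.chrom}\t{a.start}\t{a.end}\t{a.feature_id}\t0\t{a.strand}\n")


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for name, genes in collection.sets.items():
            desc = collection.descriptions.get(name, "")
            fh.write("\t".join([name, desc, *genes]) + "\n")


def write_fasta(sequences: Mapping[str, str], path: str | Path) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences.items()
    ]
    SeqIO.write(records, str(path), "fasta")
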