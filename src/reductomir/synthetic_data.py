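"""Synthetic study generator: counts, sequences and a ground-truth manifest.

Emulates a three-genotype transgene dose design (NTg / TgL / TgH) of the kind
used to study cardiac reductive stress: miRNA and mRNA counts are negative
binomial with a 1/mean dispersion trend, a subset of features carries
transgene-only, transgene-dose or dose-only effects, a nested subset of
induced dose-responsive miRNAs ("reductomiRs") receives planted antioxidant
response element (ARE) motif instances in its promoter, and a set of mRNAs is
suppressed in proportion to the summed induction of the miRNAs that target
them, with exactly complementary seed sites planted in their 3'UTRs. Every
planted effect is recorded in a TruthManifest so downstream recovery is
measurable without any external data.

Features carrying planted effects are drawn from the detectably expressed
part of the baseline distribution (mean above ``expressed_floor``), mirroring
the fact that differential-expression candidates in a real study are by
construction detectable; effects planted on near-zero counts would be
untestable at any sample size.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .core_io import (
    PWM,
    CountMatrix,
    FeatureAnnotation,
    SampleDesign,
    revcomp,
    write_bed,
    write_count_matrix,
    write_design,
    write_fasta,
    write_tsv,
)

__all__ = [
    "SimulationConfig",
    "TruthManifest",
    "SimulatedSequences",
    "simulate_counts",
    "simulate_sequences",
    "simulate_predictions",
    "synthetic_are_pwm",
    "PREDICTION_SOURCES",
]

# Algorithm names used as synthetic evidence-source labels in generated
# prediction tables (the consensus combiner treats sources as opaque strings).
PREDICTION_SOURCES = (
    "DIANA-microT",
    "ElMMo",
    "MicroCosm",
    "miRanda",
    "miRDB",
    "PicTar",
    "PITA",
    "TargetScan",
)

_DNA = np.array(list("ACGT"))


@dataclass
class SimulationConfig:
    """Parameters of the synthetic study; defaults mirror the study design.

    Effect sizes are in log2 units. Transgene-dose features scale linearly
    with dose code (TgL gets delta/2, TgH gets delta); dose-only features get
    opposite-sign +/- delta/2 in TgL and TgH so the pooled effect is ~0;
    suppressed mRNA targets decrease by gamma per unit of summed induction of
    their planted targeting miRNAs.
    """

    n_mirna: int = 800
    n_mrna: int = 4000
    mirna_group_sizes: dict = field(
        default_factory=lambda: {"NTg": 3, "TgL": 3, "TgH": 3}
    )
    mrna_group_sizes: dict = field(
        default_factory=lambda: {"NTg": 4, "TgL": 3, "TgH": 3}
    )
    dose_map: dict = field(default_factory=lambda: {"NTg": 0, "TgL": 1, "TgH": 2})
    baseline_meanlog: float = 5.0
    baseline_sdlog: float = 2.0
    a0: float = 0.05  # asymptotic dispersion
    a1: float = 5.0  # mean-dependent dispersion term: alpha = a1/mu + a0
    disp_noise_sd: float = 0.3  # lognormal noise around the dispersion trend
    delta: float = 2.0  # log2 effect size
    frac_transgene_only: float = 0.12
    frac_transgene_dose: float = 0.03
    frac_dose_only: float = 0.05
    gamma: float = 0.5  # mRNA suppression per unit summed miRNA induction
    size_factor_range: tuple[float, float] = (0.7, 1.3)
    expressed_floor: float = 200.0  # min baseline mean for planted features
    # nested reductomiR structure (study-scale defaults)
    n_are_bearing: int = 40  # induced miRNAs with planted promoter AREs
    n_reductomir: int = 22  # ... of which dose-responsive (transgene-dose)
    n_effector: int = 19  # ... of which with suppressed consensus targets
    n_suppressed_targets: int = 61  # mRNAs suppressed via planted seed sites
    mirnas_per_target: tuple[int, int] = (2, 4)  # inclusive range
    promoter_length: int = 5000
    utr_length_range: tuple[int, int] = (500, 2000)
    n_are_per_reductomir: tuple[int, int] = (1, 3)  # inclusive range
    seed: int = 0

    def validate(self) -> None:
        fracs = (
            self.frac_transgene_only,
            self.frac_transgene_dose,
            self.frac_dose_only,
        )
        if any(f < 0 or f > 1 for f in fracs) or sum(fracs) > 1:
            raise ValueError("class fractions must lie in [0, 1] and sum to <= 1")
        if self.delta < 0:
            raise ValueError("effect size delta must be >= 0")
        if self.gamma < 0:
            raise ValueError("suppression coupling gamma must be >= 0")
        if not (self.n_effector <= self.n_reductomir <= self.n_are_bearing):
            raise ValueError("need n_effector <= n_reductomir <= n_are_bearing")
        if self.promoter_length < 1:
            raise ValueError("promoter_length must be positive")
        if self.utr_length_range[0] > self.utr_length_range[1]:
            raise ValueError("invalid utr_length_range")
        for k in self.dose_map.values():
            if k < 0:
                raise ValueError("dose codes must be >= 0")


@dataclass
class TruthManifest:
    """Ground truth of every planted effect, site and tier."""

    features: pd.DataFrame  # per feature: class, true LFCs, tier flags
    are_sites: pd.DataFrame  # mirna_id, offset, strand, site_seq
    seed_sites: pd.DataFrame  # mirna_id, target_id, site_type, utr_offset, site_seq
    size_factors: pd.DataFrame | None = None  # assay, sample_id, true s_j
    config: SimulationConfig | None = None

    def mirnas(self) -> pd.DataFrame:
        return self.features[self.features["kind"] == "miRNA"]

    def mrnas(self) -> pd.DataFrame:
        return self.features[self.features["kind"] == "mRNA"]

    def true_effectors(self) -> list[str]:
        f = self.features
        return list(f.loc[(f["kind"] == "miRNA") & f["is_effector"], "feature_id"])

    def true_reductomirs(self) -> list[str]:
        f = self.features
        return list(f.loc[(f["kind"] == "miRNA") & f["is_reductomir"], "feature_id"])

    def true_suppressed_targets(self) -> list[str]:
        f = self.features
        return list(f.loc[f["is_suppressed_target"], "feature_id"])

    def save(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_tsv(self.features, outdir / "truth_features.tsv")
        write_tsv(self.are_sites, outdir / "truth_are_sites.tsv")
        write_tsv(self.seed_sites, outdir / "truth_seed_sites.tsv")
        if self.config is not None:
            cfg = asdict(self.config)
            cfg["mirnas_per_target"] = list(cfg["mirnas_per_target"])
            with open(outdir / "truth_config.json", "w") as fh:
                json.dump(cfg, fh, indent=1, default=str)


def _make_design(group_sizes: dict, dose_map: dict) -> SampleDesign:
    rows = []
    for group, n in group_sizes.items():
        for i in range(1, n + 1):
            rows.append(
                {"sample_id": f"{group}_{i}", "group": group, "dose_code": dose_map[group]}
            )
    return SampleDesign(pd.DataFrame(rows))


def _assign_classes(
    rng: np.random.Generator,
    n: int,
    baselines: np.ndarray,
    config: SimulationConfig,
    reserved: np.ndarray | None = None,
) -> np.ndarray:
    """Assign true classes, drawing planted features from the expressed pool."""
    classes = np.array(["null"] * n, dtype=object)
    n_only = round(config.frac_transgene_only * n)
    n_dose_both = round(config.frac_transgene_dose * n)
    n_dose_only = round(config.frac_dose_only * n)
    eligible = np.flatnonzero(
        (baselines >= config.expressed_floor)
        & (classes == "null")
        & (~reserved if reserved is not None else True)
    )
    needed = n_only + n_dose_both + n_dose_only
    if needed > len(eligible):
        raise ValueError(
            f"only {len(eligible)} features above expressed_floor="
            f"{config.expressed_floor} but {needed} planted features requested"
        )
    chosen = rng.choice(eligible, size=needed, replace=False)
    classes[chosen[:n_only]] = "transgene_only"
    classes[chosen[n_only : n_only + n_dose_both]] = "transgene_dose"
    classes[chosen[n_only + n_dose_both :]] = "dose_only"
    return classes


def _nb_sample(
    rng: np.random.Generator, mu: np.ndarray, alpha: np.ndarray
) -> np.ndarray:
    """NB draws with variance mu + alpha mu^2 (Poisson limit for tiny alpha)."""
    alpha = np.broadcast_to(np.atleast_1d(alpha)[:, None], mu.shape)
    out = np.empty(mu.shape, dtype=np.int64)
    tiny = alpha < 1e-6
    if tiny.any():
        out[tiny] = rng.poisson(mu[tiny])
    big = ~tiny
    if big.any():
        r = 1.0 / alpha[big]
        p = r / (r + mu[big])
        out[big] = rng.negative_binomial(r, p)
    return out


def simulate_counts(
    config: SimulationConfig,
) -> tuple[CountMatrix, CountMatrix, TruthManifest]:
    """Generate miRNA and mRNA count matrices and the ground-truth manifest.

    Counts are NB(mean = s_j * q_i * 2^lfc(group_j), dispersion alpha_i) with
    alpha_i = (a1 / q_i + a0) * lognormal noise and size factors s_j uniform
    over ``size_factor_range``. Fixed ``config.seed`` gives bit-identical
    output on repeated calls.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)

    mirna_ids = [f"miR-sim-{i:04d}" for i in range(1, config.n_mirna + 1)]
    mrna_ids = [f"gene-sim-{i:04d}" for i in range(1, config.n_mrna + 1)]

    base_mi = rng.lognormal(config.baseline_meanlog, config.baseline_sdlog, config.n_mirna)
    base_mr = rng.lognormal(config.baseline_meanlog, config.baseline_sdlog, config.n_mrna)

    cls_mi = _assign_classes(rng, config.n_mirna, base_mi, config)
    # signs: +1 induced, -1 suppressed
    sign_mi = rng.choice([-1.0, 1.0], size=config.n_mirna)

    # nested reductomiR structure among induced miRNAs (capped by class counts)
    td_idx = np.flatnonzero(cls_mi == "transgene_dose")
    to_idx = np.flatnonzero(cls_mi == "transgene_only")
    n_reduct = min(config.n_reductomir, len(td_idx))
    n_are_only = min(config.n_are_bearing - n_reduct, len(to_idx))
    reduct_idx = rng.choice(td_idx, size=n_reduct, replace=False) if n_reduct else np.array([], int)
    are_only_idx = (
        rng.choice(to_idx, size=n_are_only, replace=False) if n_are_only else np.array([], int)
    )
    sign_mi[reduct_idx] = 1.0  # reductomiRs are induced by definition
    sign_mi[are_only_idx] = 1.0
    n_eff = min(config.n_effector, n_reduct)
    effector_idx = (
        rng.choice(reduct_idx, size=n_eff, replace=False) if n_eff else np.array([], int)
    )

    # mRNA classes; suppressed targets are reserved from the null pool first
    supp_pool = np.flatnonzero(base_mr >= config.expressed_floor)
    n_supp = min(config.n_suppressed_targets, len(supp_pool)) if n_eff else 0
    supp_idx = (
        rng.choice(supp_pool, size=n_supp, replace=False) if n_supp else np.array([], int)
    )
    reserved = np.zeros(config.n_mrna, dtype=bool)
    reserved[supp_idx] = True
    cls_mr = _assign_classes(rng, config.n_mrna, base_mr, config, reserved=reserved)
    sign_mr = rng.choice([-1.0, 1.0], size=config.n_mrna)

    # planted bipartite truth: each suppressed target gets 2-4 effector miRNAs,
    # round-robin so every effector has at least one target
    lo, hi = config.mirnas_per_target
    pair_rows: list[dict] = []
    target_effectors: dict[int, list[int]] = {}
    for j, t in enumerate(supp_idx):
        k = int(rng.integers(lo, hi + 1))
        k = min(k, n_eff)
        first = effector_idx[j % n_eff]
        others = [i for i in effector_idx if i != first]
        picked = [first] + (
            list(rng.choice(others, size=k - 1, replace=False)) if k > 1 else []
        )
        target_effectors[int(t)] = [int(i) for i in picked]

    # true LFCs per group (log2, relative to NTg)
    def _lfcs(cls: np.ndarray, sign: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        lfc_l = np.zeros(len(cls))
        lfc_h = np.zeros(len(cls))
        only = cls == "transgene_only"
        lfc_l[only] = sign[only] * config.delta
        lfc_h[only] = sign[only] * config.delta
        dose = cls == "transgene_dose"
        lfc_l[dose] = sign[dose] * config.delta / 2.0
        lfc_h[dose] = sign[dose] * config.delta
        donly = cls == "dose_only"
        lfc_l[donly] = sign[donly] * config.delta / 2.0
        lfc_h[donly] = -sign[donly] * config.delta / 2.0
        return lfc_l, lfc_h

    lfc_l_mi, lfc_h_mi = _lfcs(cls_mi, sign_mi)
    lfc_l_mr, lfc_h_mr = _lfcs(cls_mr, sign_mr)

    # suppression coupling: deterministic in the mean
    for t, mirs in target_effectors.items():
        cls_mr[t] = "transgene_dose"
        lfc_l_mr[t] = -config.gamma * float(np.sum(lfc_l_mi[mirs]))
        lfc_h_mr[t] = -config.gamma * float(np.sum(lfc_h_mi[mirs]))

    sf_rows: list[dict] = []

    def _simulate_assay(
        ids: list[str],
        base: np.ndarray,
        lfc_l: np.ndarray,
        lfc_h: np.ndarray,
        group_sizes: dict,
        kind: str,
    ) -> CountMatrix:
        design = _make_design(group_sizes, config.dose_map)
        s = rng.uniform(*config.size_factor_range, size=len(design.sample_ids))
        sf_rows.extend(
            {"assay": kind, "sample_id": sid, "size_factor": float(s[j])}
            for j, sid in enumerate(design.sample_ids)
        )
        alpha = (config.a1 / base + config.a0) * rng.lognormal(
            0.0, config.disp_noise_sd, len(base)
        )
        lfc_by_dose = {0: np.zeros(len(base)), 1: lfc_l, 2: lfc_h}
        mu = np.empty((len(base), len(design.sample_ids)))
        for j, sid in enumerate(design.sample_ids):
            dose = int(design.dose_codes[sid])
            mu[:, j] = s[j] * base * 2.0 ** lfc_by_dose[dose]
        counts = _nb_sample(rng, mu, alpha)
        frame = pd.DataFrame(counts, index=ids, columns=design.sample_ids)
        frame.index.name = "feature_id"
        return CountMatrix(counts=frame, design=design, feature_kind=kind)

    cm_mi = _simulate_assay(
        mirna_ids, base_mi, lfc_l_mi, lfc_h_mi, config.mirna_group_sizes, "miRNA"
    )
    cm_mr = _simulate_assay(
        mrna_ids, base_mr, lfc_l_mr, lfc_h_mr, config.mrna_group_sizes, "mRNA"
    )

    is_are = np.zeros(config.n_mirna, dtype=bool)
    is_are[reduct_idx] = True
    is_are[are_only_idx] = True
    is_reduct = np.zeros(config.n_mirna, dtype=bool)
    is_reduct[reduct_idx] = True
    is_eff = np.zeros(config.n_mirna, dtype=bool)
    is_eff[effector_idx] = True
    tier = np.array(["none"] * config.n_mirna, dtype=object)
    tier[are_only_idx] = "are_demir"
    tier[reduct_idx] = "dose_reductomir"
    tier[effector_idx] = "effector_reductomir"

    is_supp = np.zeros(config.n_mrna, dtype=bool)
    is_supp[list(target_effectors)] = True

    features = pd.concat(
        [
            pd.DataFrame(
                {
                    "feature_id": mirna_ids,
                    "kind": "miRNA",
                    "true_class": cls_mi,
                    "lfc_tgl": lfc_l_mi,
                    "lfc_tgh": lfc_h_mi,
                    "baseline_mean": base_mi,
                    "is_are_bearing": is_are,
                    "is_reductomir": is_reduct,
                    "is_effector": is_eff,
                    "is_suppressed_target": False,
                    "true_tier": tier,
                }
            ),
            pd.DataFrame(
                {
                    "feature_id": mrna_ids,
                    "kind": "mRNA",
                    "true_class": cls_mr,
                    "lfc_tgl": lfc_l_mr,
                    "lfc_tgh": lfc_h_mr,
                    "baseline_mean": base_mr,
                    "is_are_bearing": False,
                    "is_reductomir": False,
                    "is_effector": False,
                    "is_suppressed_target": is_supp,
                    "true_tier": "none",
                }
            ),
        ],
        ignore_index=True,
    )

    pair_rows = [
        {"mirna_id": mirna_ids[m], "target_id": mrna_ids[t]}
        for t, mirs in target_effectors.items()
        for m in mirs
    ]
    seed_sites = pd.DataFrame(
        pair_rows, columns=["mirna_id", "target_id"]
    ).assign(site_type="", utr_offset=-1, site_seq="")

    manifest = TruthManifest(
        features=features,
        are_sites=pd.DataFrame(columns=["mirna_id", "offset", "strand", "site_seq"]),
        seed_sites=seed_sites,
        size_factors=pd.DataFrame(sf_rows),
        config=config,
    )
    return cm_mi, cm_mr, manifest


# ---------------------------------------------------------------------------
# Sequences
# ---------------------------------------------------------------------------


@dataclass
class SimulatedSequences:
    """Synthetic genome contigs, annotations, UTRs and mature miRNA sequences."""

    genome: dict[str, str]
    annotations: list[FeatureAnnotation]
    promoter_windows: dict[str, str]  # feature_id -> upstream window (TSS-oriented)
    utrs: dict[str, str]
    mirna_seqs: dict[str, str]

    def save(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_fasta(self.genome, outdir / "genome.fa")
        write_bed(self.annotations, outdir / "mirna_loci.bed")
        write_fasta(self.utrs, outdir / "utrs.fa")
        write_fasta(self.mirna_seqs, outdir / "mirna_mature.fa")


def synthetic_are_pwm(peak: float = 0.97, name: str = "synthetic-ARE") -> PWM:
    """A synthetic, sharply peaked ARE-like probability matrix (16 columns).

    This is NOT a published Nrf2-binding matrix: it is a stand-in with the
    TGAC...GC ARE core embedded in its consensus, peaked enough that sites
    sampled from it score above the default scan threshold while uniform
    background rarely does.
    """
    consensus = "ATGACTCAGCAGTCAT"
    off = (1.0 - peak) / 3.0
    probs = np.full((4, len(consensus)), off)
    for j, base in enumerate(consensus):
        probs["ACGT".index(base), j] = peak
    return PWM(probs=probs, background=np.full(4, 0.25), name=name)


def _random_dna(rng: np.random.Generator, length: int) -> np.ndarray:
    return _DNA[rng.integers(0, 4, size=length)]


def _place_nonoverlapping(
    rng: np.random.Generator,
    n: int,
    site_len: int,
    seq_len: int,
    taken: list[tuple[int, int]],
    max_tries: int = 200,
) -> list[int]:
    offsets: list[int] = []
    for _ in range(n):
        for _try in range(max_tries):
            off = int(rng.integers(0, seq_len - site_len + 1))
            span = (off, off + site_len)
            if all(span[1] <= a or span[0] >= b for a, b in taken):
                taken.append(span)
                offsets.append(off)
                break
        else:
            raise ValueError(
                "could not place non-overlapping sites; use a longer promoter/UTR"
            )
    return offsets


def simulate_sequences(
    config: SimulationConfig,
    manifest: TruthManifest,
    pwm: PWM | None = None,
    mirna_seqs: dict[str, str] | None = None,
) -> SimulatedSequences:
    """Generate promoters, UTRs and mature miRNAs with planted sites.

    Background promoters and UTRs are i.i.d. uniform DNA. For every
    ARE-bearing miRNA, 1-3 sites sampled column-wise from the PWM are planted
    at non-overlapping offsets on random strands of its promoter window; for
    every planted (miRNA, target) pair an exactly seed-complementary 8mer,
    7mer-m8 or 7mer-A1 site is planted in the target 3'UTR (with guard bases
    so the planted grade is not accidentally upgraded). All plants are
    recorded in the manifest.
    """
    pwm = pwm or synthetic_are_pwm()
    if pwm.length > config.promoter_length:
        raise ValueError("PWM longer than the promoter window")
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 20210607]))
    feats = manifest.features
    mirnas = feats.loc[feats["kind"] == "miRNA", "feature_id"].tolist()
    mrnas = feats.loc[feats["kind"] == "mRNA", "feature_id"].tolist()
    are_bearing = set(feats.loc[feats["is_are_bearing"], "feature_id"])

    if mirna_seqs is None:
        mirna_seqs = {
            m: "".join(_random_dna(rng, 22)).replace("T", "U") for m in mirnas
        }

    feat_len = 100
    genome: dict[str, str] = {}
    annotations: list[FeatureAnnotation] = []
    windows: dict[str, str] = {}
    are_rows: list[dict] = []
    W = config.promoter_length
    lo_are, hi_are = config.n_are_per_reductomir
    for m in mirnas:
        window = _random_dna(rng, W)
        if m in are_bearing:
            n_sites = int(rng.integers(lo_are, hi_are + 1))
            taken: list[tuple[int, int]] = []
            offsets = _place_nonoverlapping(rng, n_sites, pwm.length, W, taken)
            for off in offsets:
                site = pwm.sample(rng, 1)[0]
                strand = "+" if rng.random() < 0.5 else "-"
                planted = site if strand == "+" else revcomp(site)
                window[off : off + pwm.length] = list(planted)
                are_rows.append(
                    {"mirna_id": m, "offset": off, "strand": strand, "site_seq": site}
                )
        window_str = "".join(window)
        windows[m] = window_str
        chrom = f"chr_{m}"
        strand = "+" if rng.random() < 0.5 else "-"
        if strand == "+":
            # [window][feature]: TSS at W, upstream window = [0, W)
            contig = window_str + "".join(_random_dna(rng, feat_len))
            annotations.append(
                FeatureAnnotation(m, chrom, W, W + feat_len, "+")
            )
        else:
            # [feature][revcomp(window)]: TSS at feat_len-1, window = [feat_len, feat_len+W)
            contig = "".join(_random_dna(rng, feat_len)) + revcomp(window_str)
            annotations.append(FeatureAnnotation(m, chrom, 0, feat_len, "-"))
        genome[chrom] = contig

    # UTRs with planted seed sites
    utr_lens = {
        g: int(rng.integers(config.utr_length_range[0], config.utr_length_range[1] + 1))
        for g in mrnas
    }
    utr_arrays = {g: _random_dna(rng, utr_lens[g]) for g in mrnas}
    taken_by_utr: dict[str, list[tuple[int, int]]] = {g: [] for g in mrnas}
    site_rows: list[dict] = []
    type_choices = np.array(["8mer", "7mer-m8", "7mer-A1"])
    type_probs = np.array([0.5, 0.3, 0.2])
    for _, row in manifest.seed_sites.iterrows():
        m, g = row["mirna_id"], row["target_id"]
        seq = mirna_seqs[m].replace("U", "T").upper()
        seed7 = seq[1:8]  # miRNA nt 2-8
        rc7 = revcomp(seed7)
        site_type = str(rng.choice(type_choices, p=type_probs))
        utr = utr_arrays[g]
        # reserve the site plus one guard base on each side
        off = _place_nonoverlapping(
            rng, 1, 10, len(utr), taken_by_utr[g]
        )[0] + 1
        non_a = [b for b in "CGT"]
        not_m8 = [b for b in "ACGT" if b != rc7[0]]
        if site_type == "8mer":
            site = rc7 + "A"
            utr[off : off + 8] = list(site)
            report_off = off
        elif site_type == "7mer-m8":
            site = rc7
            utr[off : off + 7] = list(site)
            utr[off + 7] = rng.choice(non_a)  # guard: no accidental 8mer
            report_off = off
        else:  # 7mer-A1
            site = rc7[1:] + "A"
            utr[off : off + 7] = list(site)
            utr[off - 1] = rng.choice(not_m8)  # guard: no accidental m8 match
            report_off = off
        site_rows.append(
            {
                "mirna_id": m,
                "target_id": g,
                "site_type": site_type,
                "utr_offset": report_off,
                "site_seq": site,
            }
        )

    manifest.are_sites = pd.DataFrame(
        are_rows, columns=["mirna_id", "offset", "strand", "site_seq"]
    )
    manifest.seed_sites = pd.DataFrame(
        site_rows, columns=["mirna_id", "target_id", "site_type", "utr_offset", "site_seq"]
    )
    utrs = {g: "".join(utr_arrays[g]) for g in mrnas}
    return SimulatedSequences(
        genome=genome,
        annotations=annotations,
        promoter_windows=windows,
        utrs=utrs,
        mirna_seqs=mirna_seqs,
    )


def simulate_predictions(
    config: SimulationConfig,
    manifest: TruthManifest,
    n_noise: int = 300,
    min_sources_planted: int = 3,
) -> pd.DataFrame:
    """Synthetic external target-prediction table (mirna, target, source).

    Planted pairs are supported by 3-8 of the named algorithms; noise pairs by
    1-2, so a >= 3-source consensus keeps the planted structure and discards
    most noise. Emulates a multi-algorithm compilation without network access.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 40]))
    feats = manifest.features
    mirnas = feats.loc[feats["kind"] == "miRNA", "feature_id"].to_numpy()
    mrnas = feats.loc[feats["kind"] == "mRNA", "feature_id"].to_numpy()
    rows: list[dict] = []
    planted = manifest.seed_sites[["mirna_id", "target_id"]].drop_duplicates()
    planted_set = set(map(tuple, planted.to_numpy()))
    for m, t in planted_set:
        k = int(rng.integers(min_sources_planted, len(PREDICTION_SOURCES) + 1))
        for src in rng.choice(PREDICTION_SOURCES, size=k, replace=False):
            rows.append({"mirna_id": m, "target_id": t, "source": src})
    made = 0
    while made < n_noise and len(mirnas) and len(mrnas):
        m = str(rng.choice(mirnas))
        t = str(rng.choice(mrnas))
        if (m, t) in planted_set:
            continue
        k = int(rng.integers(1, 3))
        for src in rng.choice(PREDICTION_SOURCES, size=k, replace=False):
            rows.append({"mirna_id": m, "target_id": t, "source": src})
        made += 1
    return pd.DataFrame(rows, columns=["mirna_id", "target_id", "source"])


def save_study(
    outdir: str | Path,
    cm_mirna: CountMatrix,
    cm_mrna: CountMatrix,
    manifest: TruthManifest,
    sequences: SimulatedSequences | None = None,
    predictions: pd.DataFrame | None = None,
) -> None:
    """Write every synthetic artifact as plain-text files under ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seed = manifest.config.seed if manifest.config else "NA"
    header = [f"synthetic study, seed={seed}"]
    write_count_matrix(cm_mirna, outdir / "mirna_counts.tsv", comments=header)
    write_count_matrix(cm_mrna, outdir / "mrna_counts.tsv", comments=header)
    write_design(cm_mirna.design, outdir / "mirna_design.tsv")
    write_design(cm_mrna.design, outdir / "mrna_design.tsv")
    manifest.save(outdir)
    if sequences is not None:
        sequences.save(outdir)
    if predictions is not None:
        write_tsv(predictions, outdir / "predictions.tsv")
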