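"""Genomic bookkeeping rules for spike-in ChIP-seq style analyses.

Implements the classification conventions used around acute-depletion
chromatin experiments: spike-in normalization factors, relative-change
differential classes (20 % for histone marks, 30 % for transcription
factors), rank-based H2A.Z level classes, nucleosome fragility ratios,
rescue calls between cell lines, turnover time-course groups, methylation
margins, strand-aware promoter/enhancer/nucleosome-window annotation and
six-cluster z-score k-means.  Coordinates are BED-style 0-based half-open
throughout; overlap means at least one shared base pair.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from sklearn.cluster import KMeans

__all__ = [
    "GenomicInterval",
    "RegulatoryAnnotation",
    "spike_in_factors",
    "classify_differential",
    "classify_h2az_levels",
    "fragility",
    "rescued_peaks",
    "turnover_groups",
    "classify_methylation",
    "annotate_regulatory",
    "zscore_cluster",
    "read_bed",
    "write_bed",
]

PROMOTER_UP = 1000      # bp upstream of the TSS
PROMOTER_DOWN = 500     # bp downstream
TSS_NUC_HALF = 20       # TSS-nucleosome half-window
FLANK_NUC = 400         # -1/+1 nucleosome window width


@dataclass(frozen=True)
class GenomicInterval:
    chrom: str
    start: int
    end: int
    name: str = "."
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValueError(f"{self.name}: start must be < end "
                             f"({self.start} >= {self.end})")


def read_bed(path) -> list:
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            out.append(GenomicInterval(
                chrom=f[0], start=int(f[1]), end=int(f[2]),
                name=f[3] if len(f) > 3 else ".",
                strand=f[5] if len(f) > 5 else ".",
            ))
    return out


def write_bed(intervals, path) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.name}\t0\t{iv.strand}\n")


# ---------------------------------------------------------------------------
# spike-in normalization


def spike_in_factors(counts: dict) -> dict:
    """Per-sample scaling factors equalizing spike-in read counts.

    Every sample is brought down to the sample with the fewest
    spike-in-mapped reads: factor_s = min(counts) / counts_s, so factors
    lie in (0, 1] and the minimum-count sample keeps factor 1.
    """
    for sample, c in counts.items():
        if c <= 0:
            raise ValueError(f"sample {sample!r} has non-positive spike-in "
                             f"count {c}")
    m = min(counts.values())
    return {s: m / c for s, c in counts.items()}


# ---------------------------------------------------------------------------
# per-peak classification rules

DIFF_THRESHOLDS = {"histone": 0.20, "tf": 0.30}


def classify_differential(score_ctrl, score_treat, mark_class: str,
                          pseudocount: float = 0.5):
    """Up/stable/down call from the relative change versus control.

    r = (treat - ctrl) / (ctrl + pseudocount); |r| at or above the class
    threshold (20 % histone marks, 30 % TFs) is up or down by sign.
    Vectorized over aligned score arrays.
    """
    if mark_class not in DIFF_THRESHOLDS:
        raise ValueError(f"unknown mark_class {mark_class!r}; "
                         f"expected one of {sorted(DIFF_THRESHOLDS)}")
    thr = DIFF_THRESHOLDS[mark_class]
    ctrl = np.asarray(score_ctrl, dtype=float)
    treat = np.asarray(score_treat, dtype=float)
    if np.any(ctrl < 0) or np.any(treat < 0):
        raise ValueError("scores must be non-negative")
    r = (treat - ctrl) / (ctrl + pseudocount)
    out = np.where(r >= thr, "up", np.where(r <= -thr, "down", "stable"))
    return out if out.ndim else out.item()


H2AZ_CLASSES = ("No", "Low", "Intermediate", "High")


def classify_h2az_levels(scores) -> np.ndarray:
    """Rank-based H2A.Z level classes.

    The 3 % lowest-scoring nucleosomes are "No"; the rest of the bottom
    quartile is "Low"; the top quartile is "High"; everything between is
    "Intermediate".  Ties are broken by stable input order, so any
    monotone transform of the scores leaves the classes unchanged.
    """
    s = np.asarray(scores, dtype=float)
    n = len(s)
    if n == 0:
        raise ValueError("empty score vector")
    if n < 34:
        raise ValueError(f"need >= 34 scores so every class is non-empty, got {n}")
    order = np.argsort(s, kind="stable")
    ranks = np.empty(n, dtype=int)
    ranks[order] = np.arange(n)
    n_no = int(np.floor(0.03 * n))
    n_low = int(np.floor(0.25 * n))
    n_high_start = int(np.floor(0.75 * n))
    out = np.full(n, "Intermediate", dtype=object)
    out[ranks < n_no] = "No"
    out[(ranks >= n_no) & (ranks < n_low)] = "Low"
    out[ranks >= n_high_start] = "High"
    return out.astype(str)


def fragility(mnlow_score, mnhigh_score, pseudocount: float | None = None):
    """Nucleosome fragility: MNase-low over MNase-high signal ratio.

    A zero MNase-high score yields NaN unless a pseudocount is supplied,
    in which case it is added to the denominator only when needed.
    """
    low = np.asarray(mnlow_score, dtype=float)
    high = np.asarray(mnhigh_score, dtype=float)
    if pseudocount is None:
        with np.errstate(divide="ignore", invalid="ignore"):
            out = np.where(high > 0, low / np.where(high > 0, high, 1.0), np.nan)
    else:
        denom = np.where(high > 0, high, pseudocount)
        out = low / denom
    return out if out.ndim else float(out)


def rescued_peaks(wt_ctrl, wt_iaa, cd_ctrl, cd_iaa, margin: float = 0.10,
                  rule: str = "methods"):
    """Call peaks whose depletion-induced loss is rescued in the mutant line.

    ``rule="methods"``: loss = ctrl - IAA per line; a peak is rescued when
    the catalytic-dead line loses more than (1 + margin) times the
    wild-type loss and its loss is positive.  ``rule="results"``: rescued
    when the catalytic-dead IAA score stays within ``margin`` of its own
    control (score retained despite depletion).
    """
    arrs = [np.asarray(a, dtype=float) for a in (wt_ctrl, wt_iaa, cd_ctrl, cd_iaa)]
    n = {a.shape for a in arrs}
    if len(n) != 1:
        raise ValueError(f"misaligned peak score vectors: shapes {sorted(n)}")
    wt_c, wt_i, cd_c, cd_i = arrs
    if rule == "methods":
        d_wt = wt_c - wt_i
        d_cd = cd_c - cd_i
        out = (d_cd > (1.0 + margin) * d_wt) & (d_cd > 0)
    elif rule == "results":
        out = np.abs(cd_i - cd_c) <= margin * cd_c
    else:
        raise ValueError(f"unknown rescue rule {rule!r}")
    return out if out.ndim else bool(out)


TURNOVER_TIMEPOINTS = (0, 2, 4, 6, 8)   # hours


def turnover_groups(series, loss_threshold: float = 0.5):
    """Assign each peak the earliest depletion timepoint losing >= half its signal.

    ``series`` is an (n_peaks, 5) array of scores at 0, 2, 4, 6, 8 h.
    L(t) = 1 - s(t)/s(0); the group is the earliest t with L >= 0.5
    ("2h" ... "8h"), or "stable" if never reached.
    """
    s = np.atleast_2d(np.asarray(series, dtype=float))
    if s.shape[1] != len(TURNOVER_TIMEPOINTS):
        raise ValueError(f"expected scores at {TURNOVER_TIMEPOINTS} h")
    if np.any(s[:, 0] <= 0):
        raise ValueError("zero baseline score")
    loss = 1.0 - s / s[:, :1]
    out = np.full(len(s), "stable", dtype=object)
    for t, name in zip(reversed(TURNOVER_TIMEPOINTS[1:]),
                       [f"{h}h" for h in reversed(TURNOVER_TIMEPOINTS[1:])]):
        idx = TURNOVER_TIMEPOINTS.index(t)
        out[loss[:, idx] >= loss_threshold] = name
    out = out.astype(str)
    return out if np.asarray(series).ndim == 2 else out[0]


def classify_methylation(pct_ctrl, pct_treat, margin: float = 5.0):
    """Hyper/hypo/stable methylation call with an inclusive margin.

    Percentages are on [0, 100]; a change of at least ``margin``
    percentage points in either direction is hyper- or hypomethylated.
    """
    c = np.asarray(pct_ctrl, dtype=float)
    t = np.asarray(pct_treat, dtype=float)
    if np.any((c < 0) | (c > 100)) or np.any((t < 0) | (t > 100)):
        raise ValueError("methylation percentages must lie in [0, 100]")
    d = t - c
    out = np.where(d >= margin, "hyper", np.where(d <= -margin, "hypo", "stable"))
    return out if out.ndim else out.item()


# ---------------------------------------------------------------------------
# regulatory annotation


@dataclass
class RegulatoryAnnotation:
    """Strand-aware promoter/enhancer classes and TSS nucleosome windows."""

    promoters: list = field(default_factory=list)           # all promoter windows
    promoter_classes: dict = field(default_factory=dict)    # name -> class
    enhancers: dict = field(default_factory=dict)           # class -> intervals
    tss_nucleosome: list = field(default_factory=list)
    minus1_nucleosome: list = field(default_factory=list)
    plus1_nucleosome: list = field(default_factory=list)

    def promoter_set(self, cls: str) -> list:
        return [p for p in self.promoters if self.promoter_classes.get(p.name) == cls]


def _tree(intervals) -> dict:
    trees: dict = {}
    for iv in intervals:
        trees.setdefault(iv.chrom, IntervalTree()).addi(iv.start, iv.end, iv)
    return trees


def _overlaps(trees: dict, iv: GenomicInterval) -> bool:
    t = trees.get(iv.chrom)
    return bool(t is not None and t.overlap(iv.start, iv.end))


def annotate_regulatory(
    tss: list,
    h3k4me3=(), h3k27me3=(), h3k27ac=(), h3k4me1=(),
    enhancer_candidates=(),
) -> RegulatoryAnnotation:
    """Build promoter, enhancer and nucleosome-window annotations.

    Promoters span 1 kb upstream to 500 bp downstream of each TSS,
    strand-aware; they are active (H3K4me3 without repressive marks),
    bivalent (H3K4me3 and H3K27me3) or inactive (H3K27me3 only).  Outside
    promoters, enhancers are active (H3K27ac and H3K4me1), poised
    (H3K4me1 and H3K27me3) or inactive (candidate regions with neither;
    requires ``enhancer_candidates``).  The TSS-nucleosome window is
    TSS +-20 bp and the -1/+1 nucleosome windows are the 400 bp
    immediately upstream/downstream of it, strand-aware.  Overlap is
    >= 1 bp; TSS records must carry a strand.
    """
    k4me3 = _tree(h3k4me3)
    k27me3 = _tree(h3k27me3)
    k27ac = _tree(h3k27ac)
    k4me1 = _tree(h3k4me1)

    ann = RegulatoryAnnotation()
    for t in tss:
        if t.strand not in ("+", "-"):
            raise ValueError(f"TSS {t.name!r} lacks a strand")
        pos = t.start
        if t.strand == "+":
            prom = GenomicInterval(t.chrom, pos - PROMOTER_UP, pos + PROMOTER_DOWN,
                                   name=t.name, strand=t.strand)
            minus1 = GenomicInterval(t.chrom, pos - TSS_NUC_HALF - FLANK_NUC,
                                     pos - TSS_NUC_HALF, name=t.name, strand=t.strand)
            plus1 = GenomicInterval(t.chrom, pos + TSS_NUC_HALF,
                                    pos + TSS_NUC_HALF + FLANK_NUC,
                                    name=t.name, strand=t.strand)
        else:
            prom = GenomicInterval(t.chrom, pos - PROMOTER_DOWN, pos + PROMOTER_UP,
                                   name=t.name, strand=t.strand)
            minus1 = GenomicInterval(t.chrom, pos + TSS_NUC_HALF,
                                     pos + TSS_NUC_HALF + FLANK_NUC,
                                     name=t.name, strand=t.strand)
            plus1 = GenomicInterval(t.chrom, pos - TSS_NUC_HALF - FLANK_NUC,
                                    pos - TSS_NUC_HALF, name=t.name, strand=t.strand)
        tssnuc = GenomicInterval(t.chrom, pos - TSS_NUC_HALF, pos + TSS_NUC_HALF,
                                 name=t.name, strand=t.strand)

        has_k4 = _overlaps(k4me3, prom)
        has_k27 = _overlaps(k27me3, prom)
        if has_k4 and has_k27:
            cls = "bivalent"
        elif has_k4:
            cls = "active"
        elif has_k27:
            cls = "inactive"
        else:
            cls = "unmarked"
        ann.promoters.append(prom)
        ann.promoter_classes[t.name] = cls
        ann.tss_nucleosome.append(tssnuc)
        ann.minus1_nucleosome.append(minus1)
        ann.plus1_nucleosome.append(plus1)

    prom_tree = _tree(ann.promoters)
    ann.enhancers = {"active": [], "poised": [], "inactive": []}
    for iv in h3k27ac:
        if not _overlaps(prom_tree, iv) and _overlaps(k4me1, iv):
            ann.enhancers["active"].append(iv)
    for iv in h3k4me1:
        if not _overlaps(prom_tree, iv) and _overlaps(k27me3, iv):
            ann.enhancers["poised"].append(iv)
    for iv in enhancer_candidates:
        if not _overlaps(prom_tree, iv) and not _overlaps(k4me1, iv):
            ann.enhancers["inactive"].append(iv)
    return ann


def assign_context(occurrences, annotation: RegulatoryAnnotation):
    """Label motif occurrences as promoter / enhancer / other by overlap.

    An occurrence overlapping both a promoter and an enhancer is assigned
    promoter (promoters take precedence; a warning notes how often this
    happened).
    """
    from .motifs import MotifOccurrence

    prom_tree = _tree(annotation.promoters)
    enh_tree = _tree([iv for ivs in annotation.enhancers.values() for iv in ivs])
    out = []
    n_both = 0
    for o in occurrences:
        iv = GenomicInterval(o.chrom, o.start, o.end, name=o.motif)
        in_p = _overlaps(prom_tree, iv)
        in_e = _overlaps(enh_tree, iv)
        if in_p and in_e:
            n_both += 1
        ctx = "promoter" if in_p else ("enhancer" if in_e else "other")
        out.append(MotifOccurrence(o.motif, o.chrom, o.start, o.end,
                                   strand=o.strand, context=ctx))
    if n_both:
        warnings.warn(f"{n_both} occurrences overlapped both a promoter and "
                      f"an enhancer; assigned promoter", stacklevel=2)
    return out


# ---------------------------------------------------------------------------
# clustering


def zscore_cluster(matrix, k: int = 6, seed: int = 0, n_restarts: int = 10):
    """K-means on per-row z-scores across samples.

    Rows (features) are standardized across columns (samples); rows with
    zero variance are dropped with a warning and receive label -1.
    Euclidean k-means with ``n_restarts`` initializations keeps the best
    inertia; deterministic for a fixed seed.  Labels are identifiable only
    up to permutation.
    """
    x = np.asarray(matrix, dtype=float)
    if isinstance(matrix, pd.DataFrame):
        x = matrix.to_numpy(dtype=float)
    sd = x.std(axis=1)
    keep = sd > 0
    if keep.sum() < k:
        raise ValueError(f"need at least {k} rows with nonzero variance, "
                         f"got {int(keep.sum())}")
    if not keep.all():
        warnings.warn(f"dropping {int((~keep).sum())} constant rows", stacklevel=2)
    z = (x[keep] - x[keep].mean(axis=1, keepdims=True)) / sd[keep, None]
    km = KMeans(n_clusters=k, n_init=n_restarts, random_state=seed)
    sub = km.fit_predict(z)
    labels = np.full(len(x), -1, dtype=int)
    labels[keep] = sub
    return labels
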