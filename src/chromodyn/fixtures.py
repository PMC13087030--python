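"""Deterministic synthetic inputs for every pipeline stage.

``make_genomic_fixture`` plants differential, rescue, turnover and
methylation classes into a peak table together with spike-in counts, BED
annotations and toy position-frequency matrices, so classifier recovery
can be asserted exactly.  ``make_toy_complex`` builds a ring of
DNA-labelled pseudo-atoms with an optional occluding blob for testing the
probe sweep against geometric expectations.  ``make_synthetic_nucleosome``
assembles a coarse nucleosome-remodeler bead model at realistic
dimensions; it is a synthetic stand-in, not a deposited structure.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .chromatin import GenomicInterval
from .motifs import PWM
from .sasa import AtomSet

__all__ = [
    "PlantedClasses",
    "GenomicFixture",
    "make_genomic_fixture",
    "make_toy_complex",
    "make_synthetic_nucleosome",
]


@dataclass(frozen=True)
class PlantedClasses:
    """Fractions and effect sizes of planted peak classes.

    Fractions apply to the differential classes and must sum to <= 1
    (the remainder is stable).  Effects are relative score changes upon
    treatment; ``down_effect=0.5`` halves the score.
    """

    frac_up: float = 0.2
    frac_down: float = 0.2
    up_effect: float = 0.6          # score gain of "up" peaks
    down_effect: float = 0.5        # score loss of "down" peaks
    frac_rescued: float = 0.3       # among "down" peaks
    frac_hyper: float = 0.1
    frac_hypo: float = 0.1

    def __post_init__(self) -> None:
        if self.frac_up + self.frac_down > 1 + 1e-12:
            raise ValueError("class fractions must sum to <= 1")
        for name in ("frac_up", "frac_down", "frac_rescued",
                     "frac_hyper", "frac_hypo"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.frac_hyper + self.frac_hypo > 1 + 1e-12:
            raise ValueError("methylation fractions must sum to <= 1")


@dataclass
class GenomicFixture:
    peaks: pd.DataFrame                 # chrom,start,end,peak_id,<samples>,labels
    tss: list
    mark_peaks: dict                    # mark -> list of GenomicInterval
    spike_counts: dict
    pwms: list
    turnover: pd.DataFrame              # peak_id x timepoint scores + label
    methylation: pd.DataFrame
    truth: dict = field(default_factory=dict)


def make_genomic_fixture(n_peaks: int = 200,
                         planted: PlantedClasses | None = None,
                         seed: int = 0) -> GenomicFixture:
    """Generate a peak table with exactly realized planted classes.

    Every label in the output is exact by construction: "down" peaks lose
    ``down_effect`` of their control score upon treatment, rescued peaks
    lose 1.5x the wild-type loss in the catalytic-dead line, turnover
    groups reach 50 % loss exactly at their planted timepoint, and
    methylation classes shift by twice the 5-point margin.  Byte-identical
    for a fixed seed.
    """
    if n_peaks < 1:
        raise ValueError("n_peaks must be >= 1")
    planted = planted or PlantedClasses()
    rng = np.random.default_rng(seed)

    n_up = int(round(planted.frac_up * n_peaks))
    n_down = int(round(planted.frac_down * n_peaks))
    labels = np.array(["up"] * n_up + ["down"] * n_down
                      + ["stable"] * (n_peaks - n_up - n_down))

    starts = np.sort(rng.choice(np.arange(1, 10**6), size=n_peaks, replace=False)) * 100
    widths = rng.integers(200, 800, size=n_peaks)
    ctrl = rng.uniform(5.0, 50.0, size=n_peaks)
    treat = ctrl.copy()
    treat[labels == "up"] = ctrl[labels == "up"] * (1 + planted.up_effect)
    treat[labels == "down"] = ctrl[labels == "down"] * (1 - planted.down_effect)
    # stable peaks wiggle well inside the 20 % band
    n_stable = int((labels == "stable").sum())
    treat[labels == "stable"] = ctrl[labels == "stable"] * rng.uniform(
        0.95, 1.05, size=n_stable)

    # rescue: among down peaks, rescued ones lose 1.5x the wt loss in the
    # catalytic-dead line; the rest lose the same as wt
    down_idx = np.flatnonzero(labels == "down")
    n_resc = int(round(planted.frac_rescued * len(down_idx)))
    rescued = np.zeros(n_peaks, dtype=bool)
    rescued[down_idx[:n_resc]] = True
    cd_ctrl = ctrl.copy()
    cd_iaa = treat.copy()
    wt_loss = ctrl - treat
    cd_iaa[rescued] = cd_ctrl[rescued] - 1.5 * wt_loss[rescued]

    peaks = pd.DataFrame({
        "chrom": "chr1",
        "start": starts,
        "end": starts + widths,
        "peak_id": [f"peak_{i:05d}" for i in range(n_peaks)],
        "wt_ctrl": ctrl,
        "wt_iaa": treat,
        "cd_ctrl": cd_ctrl,
        "cd_iaa": cd_iaa,
        "label_differential": labels,
        "label_rescued": rescued,
    })

    # turnover time series: group g reaches 50 % loss exactly at its time
    groups = rng.choice(["2h", "4h", "6h", "8h", "stable"], size=n_peaks,
                        p=[0.72, 0.1, 0.05, 0.05, 0.08])
    tp = np.array([0, 2, 4, 6, 8])
    base = rng.uniform(10, 40, size=n_peaks)
    series = np.empty((n_peaks, 5))
    for i, g in enumerate(groups):
        if g == "stable":
            frac = np.array([1.0, 0.9, 0.85, 0.8, 0.75])
        else:
            t50 = int(g[:-1])
            # linear decay hitting 40 % retained at t50, floor at 0.2
            frac = np.clip(1.0 - 0.6 * tp / t50, 0.2, 1.0)
            frac[tp < t50] = np.maximum(frac[tp < t50], 0.55)
            frac[0] = 1.0
        series[i] = base[i] * frac
    turnover = pd.DataFrame(series, columns=[f"t{t}h" for t in tp])
    turnover.insert(0, "peak_id", peaks["peak_id"])
    turnover["label_turnover"] = groups

    # methylation margins: hyper/hypo shift by 2x the 5-point margin
    n_hyper = int(round(planted.frac_hyper * n_peaks))
    n_hypo = int(round(planted.frac_hypo * n_peaks))
    meth_lab = np.array(["hyper"] * n_hyper + ["hypo"] * n_hypo
                        + ["stable"] * (n_peaks - n_hyper - n_hypo))
    rng.shuffle(meth_lab)
    m_ctrl = rng.uniform(20, 70, size=n_peaks)
    m_treat = m_ctrl.copy()
    m_treat[meth_lab == "hyper"] += 10.0
    m_treat[meth_lab == "hypo"] -= 10.0
    m_treat[meth_lab == "stable"] += rng.uniform(-3, 3, size=(meth_lab == "stable").sum())
    methylation = pd.DataFrame({
        "peak_id": peaks["peak_id"],
        "pct_ctrl": m_ctrl,
        "pct_treat": np.clip(m_treat, 0, 100),
        "label_methylation": meth_lab,
    })

    # TSS and mark peaks realizing one promoter of each class
    tss = [
        GenomicInterval("chr2", 100000, 100001, "gene_active", "+"),
        GenomicInterval("chr2", 200000, 200001, "gene_bivalent", "-"),
        GenomicInterval("chr2", 300000, 300001, "gene_inactive", "+"),
        GenomicInterval("chr2", 400000, 400001, "gene_unmarked", "-"),
    ]
    mark_peaks = {
        "H3K4me3": [GenomicInterval("chr2", 99800, 100200, "k4_a"),
                    GenomicInterval("chr2", 199800, 200200, "k4_b")],
        "H3K27me3": [GenomicInterval("chr2", 199900, 200100, "k27_b"),
                     GenomicInterval("chr2", 299900, 300100, "k27_c"),
                     GenomicInterval("chr2", 510000, 510400, "k27_e")],
        "H3K27ac": [GenomicInterval("chr2", 500000, 500500, "ac_e")],
        "H3K4me1": [GenomicInterval("chr2", 500100, 500600, "me1_e"),
                    GenomicInterval("chr2", 510100, 510500, "me1_p")],
    }

    spike_counts = {"wt_ctrl": 100000, "wt_iaa": 200000,
                    "cd_ctrl": 125000, "cd_iaa": 160000}

    pwms = [
        PWM("uniform", np.ones((4, 2))),
        PWM("perfect_cg", np.array([[0, 0], [1, 0], [0, 1], [0, 0]], float)),
        PWM("random_8mer", rng.integers(1, 50, size=(4, 8)).astype(float)),
    ]

    return GenomicFixture(
        peaks=peaks, tss=tss, mark_peaks=mark_peaks,
        spike_counts=spike_counts, pwms=pwms,
        turnover=turnover, methylation=methylation,
        truth={
            "differential": labels,
            "rescued": rescued,
            "turnover": groups,
            "methylation": meth_lab,
        },
    )


def _bead_set(coords, radius, chain, res_name) -> AtomSet:
    coords = np.asarray(coords, dtype=float)
    n = len(coords)
    return AtomSet(
        coords=coords,
        radii=np.full(n, float(radius)),
        elements=np.array(["C"] * n),
        chains=np.array([chain] * n),
        res_names=np.array([res_name] * n),
        res_ids=np.arange(1, n + 1),
    )


def _concat(a: AtomSet, b: AtomSet) -> AtomSet:
    return AtomSet(
        coords=np.vstack([a.coords, b.coords]),
        radii=np.concatenate([a.radii, b.radii]),
        elements=np.concatenate([a.elements, b.elements]),
        chains=np.concatenate([a.chains, b.chains]),
        res_names=np.concatenate([a.res_names, b.res_names]),
        res_ids=np.concatenate([a.res_ids, b.res_ids]),
    )


def make_toy_complex(ring_radius: float = 30.0, n_dna_atoms: int = 60,
                     occluder: tuple | None = None,
                     bead_radius: float = 2.0) -> tuple:
    """A DNA-labelled pseudo-atom ring, free and with an occluding blob.

    ``occluder`` is ``(center, radius)`` in Å; ``None`` returns identical
    free and bound sets.  The default occluder placement used in tests —
    centred on the ring at (ring_radius, 0, 0) with radius
    ring_radius * sqrt(2) — swallows exactly the half of the ring with
    x > 0, so the free/bound accessibility ratio is close to 2.
    Deterministic geometry, no randomness.
    """
    if n_dna_atoms < 3:
        raise ValueError("n_dna_atoms must be >= 3")
    if ring_radius <= 0 or bead_radius <= 0:
        raise ValueError("degenerate geometry: radii must be positive")
    theta = 2.0 * math.pi * np.arange(n_dna_atoms) / n_dna_atoms
    ring = np.column_stack([ring_radius * np.cos(theta),
                            ring_radius * np.sin(theta),
                            np.zeros(n_dna_atoms)])
    free = _bead_set(ring, bead_radius, "D", "DA")
    if occluder is None:
        bound = _bead_set(ring, bead_radius, "D", "DA")
        return free, bound
    center, radius = occluder
    if radius <= 0:
        raise ValueError("degenerate geometry: occluder radius must be positive")
    blob = _bead_set(np.asarray(center, float)[None, :], radius, "R", "BLB")
    bound = _concat(_bead_set(ring, bead_radius, "D", "DA"), blob)
    return free, bound


def make_synthetic_nucleosome(n_bp: int = 147, remodeler: bool = True) -> tuple:
    """Synthetic coarse-grained nucleosome, with and without a remodeler blob.

    This is a geometric stand-in for a cryo-EM remodeler-nucleosome
    structure, not derived from any deposited model.  DNA is a 1.65-turn
    superhelix of radius 42 Å (one 10 Å bead per basepair, residue name
    DA), the histone core a 35 Å bead cluster (chain H), and the
    remodeler — when present — a lobed ~1 MDa blob (chain R) engaging one
    face of the nucleosome and its wrapped DNA, as a large ATPase complex
    does.  Returns ``(free, bound)``: free = DNA + histone core, bound
    adds the remodeler.
    """
    helix_r = 42.0
    pitch = 25.0
    turns = 1.65
    t = np.linspace(0, turns * 2 * math.pi, n_bp)
    dna = np.column_stack([
        helix_r * np.cos(t),
        helix_r * np.sin(t),
        pitch * t / (2 * math.pi) - pitch * turns / 2,
    ])
    dna_set = _bead_set(dna, 10.0, "I", "DA")

    core = _bead_set(np.array([[0.0, 0.0, 0.0]]), 35.0, "H", "HIS")
    free = _concat(dna_set, core)

    if not remodeler:
        return free, _concat(dna_set, core)

    # remodeler: a chain of large beads arched over one nucleosome face,
    # clamping the DNA gyres on that side
    arc = np.linspace(-0.9 * math.pi / 2, 0.9 * math.pi / 2, 9)
    lobe_centers = np.column_stack([
        95.0 * np.cos(arc),
        95.0 * np.sin(arc),
        np.full(len(arc), 15.0),
    ])
    near = np.column_stack([
        70.0 * np.cos(arc[::2]),
        70.0 * np.sin(arc[::2]),
        np.full(len(arc[::2]), -5.0),
    ])
    blob = _bead_set(np.vstack([lobe_centers, near]), 32.0, "R", "BLB")
    bound = _concat(free, blob)
    return free, bound
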