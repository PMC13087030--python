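"""Motif-level statistics: CpG content, promoter/enhancer preference, pioneer-TF tally.

The CpG score quantifies how much of a motif's information sits on a CG
dinucleotide, weighting each adjacent C→G position pair by its column
totals relative to the matrix mean; motifs scoring above 6 are treated as
CpG-containing.  The P/E score is the fraction of genomic occurrences of a
motif falling in promoters among those falling in promoters or enhancers.
The pioneer-TF tally compares how often up- and down-regulated motifs
belong to a curated pioneer-factor list, with an exact two-sided test.
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd
from scipy.stats import fisher_exact

from Bio import motifs as bio_motifs

__all__ = [
    "PWM",
    "MotifOccurrence",
    "PFMParseError",
    "read_jaspar_pfm",
    "write_jaspar_pfm",
    "cpg_score",
    "has_cpg",
    "pe_score",
    "score_table",
    "ptf_tally",
    "PtfTally",
]

BASES = ("A", "C", "G", "T")


class PFMParseError(ValueError):
    pass


@dataclass(frozen=True)
class PWM:
    """Position frequency matrix: raw counts per base per position.

    Counts are kept exactly as distributed (no pseudocounts, no
    normalization); every score here is invariant to a uniform positive
    rescaling of the whole matrix.
    """

    name: str
    counts: np.ndarray          # shape (4, N), rows ordered A, C, G, T

    def __post_init__(self) -> None:
        c = np.asarray(self.counts, dtype=float)
        object.__setattr__(self, "counts", c)
        if c.ndim != 2 or c.shape[0] != 4 or c.shape[1] < 1:
            raise PFMParseError(f"motif {self.name!r}: counts must be 4 x N")
        if np.any(c < 0) or not np.all(np.isfinite(c)):
            raise PFMParseError(f"motif {self.name!r}: negative or non-finite counts")
        if np.any(c.sum(axis=0) <= 0):
            raise PFMParseError(f"motif {self.name!r}: all-zero position")

    @property
    def length(self) -> int:
        return self.counts.shape[1]


@dataclass(frozen=True)
class MotifOccurrence:
    """One genomic occurrence of a motif with its regulatory context."""

    motif: str
    chrom: str
    start: int
    end: int
    strand: str = "+"
    context: str = "other"      # promoter | enhancer | other

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValueError(f"{self.motif}: start must be < end")
        if self.context not in ("promoter", "enhancer", "other"):
            raise ValueError(f"unknown context {self.context!r}")


def _validate_block(name: str, text_block: str) -> None:
    """Pre-check a raw JASPAR block so malformed rows name their motif."""
    rows = {}
    for line in text_block.strip().splitlines():
        line = line.strip()
        if not line or line.startswith(">"):
            continue
        base = line[0].upper()
        body = line[1:].strip().strip("[]")
        rows[base] = len(body.split())
    if set(rows) != set(BASES):
        raise PFMParseError(
            f"motif {name!r}: expected rows A, C, G, T, found {sorted(rows)}")
    if len(set(rows.values())) != 1:
        raise PFMParseError(
            f"motif {name!r}: unequal row lengths {rows}")


def read_jaspar_pfm(source) -> list:
    """Parse JASPAR-format PFM text into :class:`PWM` objects.

    ``source`` may be a path or an open text handle.  Raw counts are kept;
    unequal row lengths or missing base rows raise :class:`PFMParseError`
    naming the offending motif.
    """
    if hasattr(source, "read"):
        text = source.read()
    else:
        with open(source) as fh:
            text = fh.read()

    # split into per-motif blocks so errors can name the motif
    blocks = []
    current_name, current_lines = None, []
    for line in text.splitlines():
        if line.startswith(">"):
            if current_name is not None:
                blocks.append((current_name, "\n".join(current_lines)))
            current_name = line[1:].strip().split()[0] if line[1:].strip() else "?"
            current_lines = [line]
        elif current_name is not None:
            current_lines.append(line)
    if current_name is not None:
        blocks.append((current_name, "\n".join(current_lines)))
    if not blocks:
        raise PFMParseError("no motif blocks found (expected '>' headers)")

    out = []
    for name, block in blocks:
        _validate_block(name, block)
        try:
            parsed = bio_motifs.parse(io.StringIO(block + "\n"), "jaspar")
        except Exception as exc:  # noqa: BLE001 - re-raise with motif context
            raise PFMParseError(f"motif {name!r}: {exc}") from exc
        for m in parsed:
            counts = np.array([m.counts[b] for b in BASES], dtype=float)
            out.append(PWM(name=m.name or name, counts=counts))
    return out


def write_jaspar_pfm(pwms: Iterable[PWM], path) -> None:
    with open(path, "w") as fh:
        for p in pwms:
            fh.write(f">{p.name}\n")
            for i, b in enumerate(BASES):
                vals = " ".join(f"{v:g}" for v in p.counts[i])
                fh.write(f"{b} [ {vals} ]\n")


def cpg_score(pwm: PWM) -> float:
    """CpG score of a motif.

    With column totals T_i = sum_b Score(b)_i and matrix mean m over all
    4N entries, each adjacent position pair contributes
    P(C)_i * P(G)_{i+1} * (T_i + T_{i+1}) / m; a single-position motif
    scores 0 (empty sum).  The score is invariant to scaling the whole
    matrix by a positive constant and is orientation-sensitive (no
    reverse-complementing is performed).
    """
    c = pwm.counts
    totals = c.sum(axis=0)
    if np.any(totals <= 0):
        raise PFMParseError(f"motif {pwm.name!r}: all-zero position")
    mean_all = c.mean()
    p_c = c[1] / totals
    p_g = c[2] / totals
    weight = totals / mean_all
    if pwm.length < 2:
        return 0.0
    return float(np.sum(p_c[:-1] * p_g[1:] * (weight[:-1] + weight[1:])))


def has_cpg(pwm: PWM, threshold: float = 6.0) -> bool:
    """Whether the motif is considered to contain a CpG (score strictly > 6)."""
    return cpg_score(pwm) > threshold


def pe_score(occurrences: Iterable[MotifOccurrence]) -> float:
    """Promoter-vs-enhancer score: mean of the promoter indicator.

    Occurrences in promoters count 1, in enhancers 0; occurrences in other
    contexts are excluded.  Raises if no promoter or enhancer occurrence
    exists (the score is undefined).
    """
    vals = [1.0 if o.context == "promoter" else 0.0
            for o in occurrences if o.context in ("promoter", "enhancer")]
    if not vals:
        raise ValueError("P/E score undefined: no promoter or enhancer occurrences")
    return float(np.mean(vals))


def score_table(pwms: Iterable[PWM],
                occurrences: dict | None = None) -> pd.DataFrame:
    """Per-motif summary table: CpG score, CpG call and, when genomic
    occurrences are supplied (motif name -> occurrence list), the P/E score."""
    rows = []
    occurrences = occurrences or {}
    for p in pwms:
        score = cpg_score(p)
        occ = occurrences.get(p.name)
        pe = None
        if occ:
            try:
                pe = pe_score(occ)
            except ValueError:
                pe = float("nan")
        rows.append({"motif": p.name, "cpg_score": score,
                     "has_cpg": score > 6.0, "pe_score": pe})
    return pd.DataFrame(rows)


@dataclass
class PtfTally:
    """Pioneer-factor composition of up- and down-regulated motif sets."""

    up_ptf: int
    up_total: int
    down_ptf: int
    down_total: int
    p_value: float

    @property
    def up_proportion(self) -> float:
        return self.up_ptf / self.up_total

    @property
    def down_proportion(self) -> float:
        return self.down_ptf / self.down_total

    @property
    def table(self) -> np.ndarray:
        return np.array([[self.up_ptf, self.up_total - self.up_ptf],
                         [self.down_ptf, self.down_total - self.down_ptf]])


def ptf_tally(up_motifs: set, down_motifs: set, ptf_list: set) -> PtfTally:
    """Count pioneer TFs among up- and down-regulated motifs.

    Returns the per-set proportions, the 2x2 contingency table and the
    two-sided exact hypergeometric (Fisher) p-value.
    """
    up, down, ptfs = set(up_motifs), set(down_motifs), set(ptf_list)
    if up & down:
        raise ValueError(f"up and down sets overlap: {sorted(up & down)}")
    if not up or not down:
        raise ValueError("up and down sets must both be non-empty")
    t = PtfTally(
        up_ptf=len(up & ptfs), up_total=len(up),
        down_ptf=len(down & ptfs), down_total=len(down),
        p_value=float("nan"),
    )
    t.p_value = float(fisher_exact(t.table, alternative="two-sided")[1])
    return t
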