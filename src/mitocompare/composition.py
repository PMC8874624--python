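"""Base composition, strand skews and the GC12-vs-GC3s neutrality plot.

Strand skews follow the Perna & Kocher convention,
AT skew = (A - T)/(A + T) and GC skew = (G - C)/(G + C), computed on the
majority strand (whole genome) or on concatenated protein-coding genes in
coding orientation.  The neutrality plot regresses GC12 (pooled GC fraction
at codon positions 1+2 over the 13 PCGs) on GC3s (pooled position-3 GC); a
slope near 1 indicates composition driven by mutation pressure rather than
position-specific selection.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .mitio import MitoGenome


@dataclass(frozen=True)
class CompositionStats:
    genome_id: str
    a: int
    c: int
    g: int
    t: int
    scope: str = "majority_strand"
    at_defined: bool = True
    gc_defined: bool = True

    @property
    def total(self) -> int:
        return self.a + self.c + self.g + self.t

    @property
    def at_content(self) -> float:
        return (self.a + self.t) / self.total

    @property
    def gc_content(self) -> float:
        return (self.g + self.c) / self.total

    @property
    def at_skew(self) -> float:
        return (self.a - self.t) / (self.a + self.t) if self.a + self.t else 0.0

    @property
    def gc_skew(self) -> float:
        return (self.g - self.c) / (self.g + self.c) if self.g + self.c else 0.0


@dataclass(frozen=True)
class NeutralityPoint:
    genome_id: str
    gc12: float
    gc3s: float

    def __post_init__(self):
        if not (0 <= self.gc12 <= 1 and 0 <= self.gc3s <= 1):
            raise ValueError("GC fractions must lie in [0, 1]")


class UndefinedStatisticError(ValueError):
    """Raised when a composition statistic has an empty denominator."""


def base_stats(
    sequence: str, genome_id: str = "", scope: str = "majority_strand"
) -> CompositionStats:
    """Exact base counts and skews; N and other ambiguity codes are excluded."""
    if not sequence:
        raise ValueError("empty sequence")
    counts = Counter(sequence.upper())
    a, c, g, t = counts["A"], counts["C"], counts["G"], counts["T"]
    if a + c + g + t == 0:
        raise UndefinedStatisticError(
            f"{genome_id or 'sequence'}: no unambiguous bases"
        )
    return CompositionStats(
        genome_id=genome_id, a=a, c=c, g=g, t=t, scope=scope,
        at_defined=(a + t) > 0, gc_defined=(g + c) > 0,
    )


def codon_position_gc(
    pcg_sequences: dict[str, str], genome_id: str = "", drop_terminal: bool = True
) -> NeutralityPoint:
    """Pooled GC at codon positions 1+2 (GC12) and position 3 (GC3s).

    Codons are pooled over all genes (weighting each gene by its codon
    count).  The terminal codon of each gene is dropped before counting, and
    a gene whose length is not a codon multiple is rejected by name.
    """
    gc12_n = gc12_d = gc3_n = gc3_d = 0
    for gene, seq in pcg_sequences.items():
        seq = seq.upper()
        if len(seq) % 3:
            raise ValueError(f"{genome_id or '?'}: gene {gene} is out of frame")
        codons = [seq[i:i + 3] for i in range(0, len(seq), 3)]
        if drop_terminal and codons:
            codons = codons[:-1]
        for codon in codons:
            for pos, base in enumerate(codon):
                if base not in "ACGT":
                    continue
                if pos < 2:
                    gc12_d += 1
                    gc12_n += base in "GC"
                else:
                    gc3_d += 1
                    gc3_n += base in "GC"
    if gc12_d == 0 or gc3_d == 0:
        raise UndefinedStatisticError(f"{genome_id or '?'}: no codons to count")
    return NeutralityPoint(genome_id, gc12_n / gc12_d, gc3_n / gc3_d)


def neutrality_regression(
    points: list[NeutralityPoint],
) -> tuple[float, float, float]:
    """OLS of GC12 on GC3s over genomes: (slope, intercept, Pearson R)."""
    if len(points) < 3:
        raise ValueError("neutrality regression needs at least 3 genomes")
    x = np.array([p.gc3s for p in points])
    y = np.array([p.gc12 for p in points])
    if np.ptp(x) == 0:
        raise ValueError("degenerate fit: GC3s constant across genomes")
    res = stats.linregress(x, y)
    return float(res.slope), float(res.intercept), float(res.rvalue)


def genome_composition(genome: MitoGenome) -> list[CompositionStats]:
    """Majority-strand and concatenated-PCG composition for one genome.

    PCG-scope statistics are computed on coding-orientation sequences, so
    minority-strand genes are reverse-complemented before counting.
    """
    out = [base_stats(genome.sequence, genome.id, "majority_strand")]
    pcgs = genome.pcg_sequences()
    if pcgs:
        out.append(base_stats("".join(pcgs.values()), genome.id, "PCGs_concatenated"))
    return out


def composition_report(genomes: list[MitoGenome]) -> pd.DataFrame:
    """One row per genome x scope, plus GC12/GC3s where PCGs are present."""
    rows = []
    for genome in genomes:
        neutrality = None
        pcgs = genome.pcg_sequences()
        if pcgs:
            neutrality = codon_position_gc(pcgs, genome.id)
        for cs in genome_composition(genome):
            rows.append({
                "genome_id": cs.genome_id,
                "scope": cs.scope,
                "A": cs.a, "C": cs.c, "G": cs.g, "T": cs.t,
                "at_content": cs.at_content,
                "gc_content": cs.gc_content,
                "at_skew": cs.at_skew,
                "gc_skew": cs.gc_skew,
                "gc12": neutrality.gc12 if neutrality else float("nan"),
                "gc3s": neutrality.gc3s if neutrality else float("nan"),
                "n_missing_genes": len(genome.missing_genes),
            })
    return pd.DataFrame(rows)
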