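"""Codon-usage bias: RSCU, effective number of codons and correspondence analysis.

All statistics are computed under the invertebrate mitochondrial code
(NCBI table 5), whose synonymous-family structure is twelve 2-fold, six
4-fold, one 6-fold (Leu) and one 8-fold (Ser) family over 62 sense codons —
Met (ATR) and Trp (TGR) are 2-fold here, unlike under the standard code.

The observed effective number of codons (ENc) is Wright's statistic
generalized to that family structure; the expected-ENc curve under pure
GC3s-driven mutation pressure,

    ENc* = 2 + GC3s + 29 / (GC3s + (1 - GC3s)**2),

is evaluated exactly in the form the comparative-mitogenomics literature
prints it (note the un-squared first denominator term, unlike Wright's
original curve; its constants also assume the standard-code family layout).
It serves as the conventional no-selection reference curve.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genes import (
    sense_codons,
    stop_codons,
    synonymous_families,
    translate_codon,
)
from .mitio import MitoGenome


@dataclass
class CodonCounts:
    """Sense-codon counts for one genome; stop codons tallied separately."""

    genome_id: str
    counts: dict[str, int] = field(default_factory=dict)
    stop_counts: dict[str, int] = field(default_factory=dict)

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    def get(self, codon: str) -> int:
        return self.counts.get(codon, 0)


def count_codons(
    gene_sequences: dict[str, str], genome_id: str = "", drop_terminal: bool = True
) -> CodonCounts:
    """Tally codons over in-frame gene sequences, dropping each terminal codon.

    Codons containing ambiguity codes are skipped.  Internal stop codons are
    recorded under ``stop_counts`` rather than silently discarded.
    """
    cc = CodonCounts(genome_id)
    stops = stop_codons()
    for gene, seq in gene_sequences.items():
        seq = seq.upper().replace("U", "T")
        if len(seq) % 3:
            raise ValueError(f"{genome_id or '?'}: gene {gene} is out of frame")
        codons = [seq[i:i + 3] for i in range(0, len(seq), 3)]
        if drop_terminal and codons:
            codons = codons[:-1]
        for codon in codons:
            if any(b not in "ACGT" for b in codon):
                continue
            if codon in stops:
                cc.stop_counts[codon] = cc.stop_counts.get(codon, 0) + 1
            else:
                cc.counts[codon] = cc.counts.get(codon, 0) + 1
    return cc


# --- RSCU --------------------------------------------------------------------

@dataclass(frozen=True)
class RSCUTable:
    genome_id: str
    rscu: dict[str, float]
    undefined_families: tuple[str, ...] = ()


def rscu(counts: CodonCounts) -> RSCUTable:
    """Relative synonymous codon usage: count / family mean.

    For a family of size s with total n, RSCU(c) = count(c) * s / n, so the
    family sums to s; families with zero usage are reported as undefined
    (their codons carry RSCU 0 and the amino acid is listed).
    """
    values: dict[str, float] = {}
    undefined: list[str] = []
    for aa, family in synonymous_families().items():
        n = sum(counts.get(c) for c in family)
        if n == 0:
            undefined.append(aa)
            for c in family:
                values[c] = 0.0
        else:
            s = len(family)
            for c in family:
                values[c] = counts.get(c) * s / n
    return RSCUTable(counts.genome_id, values, tuple(undefined))


def amino_acid_usage(counts: CodonCounts) -> dict[str, float]:
    """Fraction of codons per amino acid (sums to 1)."""
    if counts.total == 0:
        raise ValueError(f"{counts.genome_id}: no codons counted")
    usage = {aa: 0.0 for aa in synonymous_families()}
    for codon, n in counts.counts.items():
        usage[translate_codon(codon)] += n
    return {aa: n / counts.total for aa, n in usage.items()}


# --- effective number of codons ---------------------------------------------

def enc_expected(gc3s: float) -> float:
    """Expected ENc under mutation pressure alone at a given GC3s."""
    if not 0.0 <= gc3s <= 1.0:
        raise ValueError(f"GC3s must be in [0, 1], got {gc3s}")
    return 2.0 + gc3s + 29.0 / (gc3s + (1.0 - gc3s) ** 2)


def enc_observed(counts: CodonCounts) -> float:
    """Wright's ENc over the table-5 family structure, clamped to [20, 62].

    Per-family homozygosity uses the bias-corrected estimator
    F = (n * sum(p^2) - 1) / (n - 1); families with n < 2 are omitted and
    each size class contributes (number of families in class) / mean(F).
    A size class with no usable family is dropped and the statistic rescaled
    by the full/used sense-codon ratio.
    """
    by_size: dict[int, list[float]] = {}
    class_sizes: dict[int, int] = {}
    for family in synonymous_families().values():
        s = len(family)
        class_sizes[s] = class_sizes.get(s, 0) + 1
        n = sum(counts.get(c) for c in family)
        if n < 2:
            continue
        sum_p2 = sum((counts.get(c) / n) ** 2 for c in family)
        f_hat = (n * sum_p2 - 1.0) / (n - 1.0)
        by_size.setdefault(s, []).append(f_hat)

    if not by_size:
        raise ValueError(f"{counts.genome_id}: no family has >= 2 codons")

    enc = 0.0
    codons_used = 0
    for s, n_families in class_sizes.items():
        fs = by_size.get(s)
        if not fs:
            continue
        f_bar = sum(fs) / len(fs)
        # an all-identical tiny family can yield F <= 0; floor at 1/s (uniform)
        f_bar = max(f_bar, 1.0 / s)
        enc += n_families / f_bar
        codons_used += n_families * s
    n_sense = len(sense_codons())
    if codons_used < n_sense:
        enc *= n_sense / codons_used
    return float(min(max(enc, 20.0), float(n_sense)))


# --- correspondence analysis -------------------------------------------------

@dataclass(frozen=True)
class CoaResult:
    """Chi-square-metric correspondence analysis of a non-negative table."""

    eigenvalues: np.ndarray          # principal inertias per axis
    total_inertia: float
    axis_fractions: np.ndarray       # eigenvalues / total inertia
    row_coords: pd.DataFrame         # genomes, principal coordinates
    col_coords: pd.DataFrame         # codons / amino acids, principal coords
    degenerate: bool = False


def correspondence_analysis(table: pd.DataFrame) -> CoaResult:
    """CA of a genomes x variables table via SVD of standardized residuals.

    Total inertia equals the Pearson chi-square statistic of the table
    divided by its grand total; axis fractions sum to 1.  Row and column
    coordinates are returned in principal normalization.
    """
    X = np.asarray(table, dtype=float)
    if (X < 0).any():
        raise ValueError("correspondence analysis requires non-negative input")
    keep_rows = X.sum(axis=1) > 0
    keep_cols = X.sum(axis=0) > 0
    X = X[np.ix_(keep_rows, keep_cols)]
    if X.size == 0:
        raise ValueError("table is empty after removing all-zero rows/columns")
    row_ix = table.index[keep_rows]
    col_ix = table.columns[keep_cols]

    grand = X.sum()
    P = X / grand
    r = P.sum(axis=1)
    c = P.sum(axis=0)
    expected = np.outer(r, c)
    S = (P - expected) / np.sqrt(expected)
    U, sv, Vt = np.linalg.svd(S, full_matrices=False)
    k = min(X.shape) - 1  # trivial dimension removed
    sv = sv[:k]
    eig = sv ** 2
    total = float(eig.sum())
    if total <= 1e-14:
        zeros = np.zeros((len(row_ix), max(k, 1)))
        axes = [f"Axis{i + 1}" for i in range(max(k, 1))]
        return CoaResult(
            eigenvalues=np.zeros(max(k, 1)),
            total_inertia=0.0,
            axis_fractions=np.zeros(max(k, 1)),
            row_coords=pd.DataFrame(zeros, index=row_ix, columns=axes),
            col_coords=pd.DataFrame(
                np.zeros((len(col_ix), max(k, 1))), index=col_ix, columns=axes
            ),
            degenerate=True,
        )
    row_coords = (U[:, :k] / np.sqrt(r)[:, None]) * sv
    col_coords = (Vt[:k].T / np.sqrt(c)[:, None]) * sv
    axes = [f"Axis{i + 1}" for i in range(k)]
    return CoaResult(
        eigenvalues=eig,
        total_inertia=total,
        axis_fractions=eig / total,
        row_coords=pd.DataFrame(row_coords, index=row_ix, columns=axes),
        col_coords=pd.DataFrame(col_coords, index=col_ix, columns=axes),
    )


def rscu_matrix(
    tables: list[RSCUTable], codon_filter: str = "codonw"
) -> pd.DataFrame:
    """Genomes x codons RSCU matrix for CA input.

    ``codon_filter='codonw'`` drops stop codons and the codons of Met and
    Trp (the amino acids CodonW-style analyses exclude); ``'all'`` keeps
    every sense codon.
    """
    if codon_filter == "codonw":
        cols = [c for c in sense_codons() if translate_codon(c) not in ("M", "W")]
    elif codon_filter == "all":
        cols = list(sense_codons())
    else:
        raise ValueError(f"unknown codon filter {codon_filter!r}")
    return pd.DataFrame(
        [[t.rscu.get(c, 0.0) for c in cols] for t in tables],
        index=[t.genome_id for t in tables],
        columns=cols,
    )


def aa_usage_matrix(counts_list: list[CodonCounts]) -> pd.DataFrame:
    """Genomes x 20 amino-acid usage fractions."""
    aas = list(synonymous_families())
    return pd.DataFrame(
        [[amino_acid_usage(cc)[aa] for aa in aas] for cc in counts_list],
        index=[cc.genome_id for cc in counts_list],
        columns=aas,
    )


def codon_usage_report(genomes: list[MitoGenome]) -> pd.DataFrame:
    """Per-genome ENc, GC3s and expected ENc over concatenated PCGs."""
    from .composition import codon_position_gc

    rows = []
    for genome in genomes:
        pcgs = genome.pcg_sequences()
        if not pcgs:
            continue
        cc = count_codons(pcgs, genome.id)
        gc3s = codon_position_gc(pcgs, genome.id).gc3s
        rows.append({
            "genome_id": genome.id,
            "n_codons": cc.total,
            "gc3s": gc3s,
            "enc_observed": enc_observed(cc),
            "enc_expected": enc_expected(gc3s),
        })
    return pd.DataFrame(rows)
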