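"""Counting-based per-site dN-dS (SLAC-style) on a fixed tree.

For every codon site, ancestral codons are reconstructed by parsimony
(Sankoff over the observed codon states, unit cost per codon change, all
co-optimal labelings enumerated or uniformly sampled).  Substitutions on
each branch are decomposed into single-nucleotide steps averaged over all
shortest paths between the two codons (paths through stop codons excluded),
giving observed synonymous/nonsynonymous counts OS and ON.  The expected
(potential) site counts ES and EN are Nei-Gojobori fractions of each branch's
parent codon summed over branches.  Each site is then tested with a two-sided
extended (continuous) binomial: is ON out of ON+OS compatible with the
neutral expectation EN/(EN+ES)?

This is a deliberate counting approximation of the likelihood-ancestor SLAC
procedure: maximum-likelihood ancestors are replaced by parsimony with
averaging over co-optimal labelings, and branch lengths play no role once
the ancestors are fixed.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from functools import lru_cache
from itertools import permutations

import dendropy
import numpy as np
import pandas as pd
from Bio import SeqIO
from scipy.special import betainc

from .genes import stop_codons, translate_codon


class StopCodonError(ValueError):
    pass


class TaxonMismatchError(ValueError):
    pass


# --- alignment container -----------------------------------------------------

@dataclass
class CodonAlignment:
    """In-frame codon alignment: taxa x codon sites, bound to table 5."""

    taxa: list[str]
    columns: list[tuple[str, ...]]  # each tuple has one codon per taxon
    code: int = 5
    internal_stop_sites: list[int] = field(default_factory=list)

    def __post_init__(self):
        for col in self.columns:
            if len(col) != len(self.taxa):
                raise ValueError("ragged codon column")
        if not self.internal_stop_sites:
            stops = stop_codons()
            self.internal_stop_sites = [
                i for i, col in enumerate(self.columns)
                if any(c in stops for c in col)
            ]

    @property
    def n_sites(self) -> int:
        return len(self.columns)

    @classmethod
    def from_sequences(cls, sequences: dict[str, str], code: int = 5):
        taxa = list(sequences)
        lengths = {len(s) for s in sequences.values()}
        if len(lengths) != 1:
            raise ValueError("alignment rows differ in length")
        (length,) = lengths
        if length % 3:
            raise ValueError("alignment length is not a codon multiple")
        rows = [sequences[t].upper().replace("U", "T") for t in taxa]
        columns = [
            tuple(row[i:i + 3] for row in rows) for i in range(0, length, 3)
        ]
        return cls(taxa=taxa, columns=columns, code=code)

    @classmethod
    def from_fasta(cls, path_or_handle, code: int = 5):
        if isinstance(path_or_handle, str) and "\n" in path_or_handle:
            path_or_handle = io.StringIO(path_or_handle)
        records = list(SeqIO.parse(path_or_handle, "fasta"))
        if not records:
            raise ValueError("no sequences in FASTA input")
        return cls.from_sequences({r.id: str(r.seq) for r in records}, code)

    def row(self, taxon: str) -> str:
        i = self.taxa.index(taxon)
        return "".join(col[i] for col in self.columns)


# --- potential (expected) sites ---------------------------------------------

_BASES = "ACGT"


@lru_cache(maxsize=None)
def potential_sites(codon: str) -> tuple[float, float]:
    """Nei-Gojobori potential synonymous/nonsynonymous sites of a codon.

    The fraction of the 9 single-nucleotide neighbors that are synonymous,
    scaled to 3 sites.  Mutations to stop codons are treated as inadmissible
    and dropped from the neighbor set, so syn + nonsyn < 3 for codons with
    stop neighbors -- consistent with their exclusion from substitution
    paths in the observed counts.
    """
    codon = codon.upper()
    if codon in stop_codons():
        raise StopCodonError(f"potential_sites of stop codon {codon}")
    aa = translate_codon(codon)
    syn = nonsyn = 0
    for pos in range(3):
        for base in _BASES:
            if base == codon[pos]:
                continue
            neighbor = codon[:pos] + base + codon[pos + 1:]
            if neighbor in stop_codons():
                continue
            if translate_codon(neighbor) == aa:
                syn += 1
            else:
                nonsyn += 1
    return (syn / 3.0, nonsyn / 3.0)


@lru_cache(maxsize=None)
def _path_counts(parent: str, child: str) -> tuple[float, float]:
    """Mean (syn, nonsyn) step counts over shortest mutational paths.

    All orderings of the differing positions are enumerated; paths whose
    intermediates are stop codons are excluded and the mean renormalized
    (if every path crosses a stop, the exclusion is waived).
    """
    diff = [i for i in range(3) if parent[i] != child[i]]
    if not diff:
        return (0.0, 0.0)
    stops = stop_codons()
    valid: list[tuple[int, int]] = []
    fallback: list[tuple[int, int]] = []
    for order in permutations(diff):
        current = parent
        syn = nonsyn = 0
        through_stop = False
        for pos in order:
            nxt = current[:pos] + child[pos] + current[pos + 1:]
            if nxt in stops:
                through_stop = True
            if translate_codon_safe(current) == translate_codon_safe(nxt):
                syn += 1
            else:
                nonsyn += 1
            current = nxt
        (fallback if through_stop else valid).append((syn, nonsyn))
    paths = valid or fallback
    return (
        sum(p[0] for p in paths) / len(paths),
        sum(p[1] for p in paths) / len(paths),
    )


def translate_codon_safe(codon: str) -> str:
    return "*" if codon in stop_codons() else translate_codon(codon)


# --- parsimony ancestors -----------------------------------------------------

class _TreeIndex:
    """Postorder-indexed rooted view of a dendropy tree for fast per-site DP."""

    def __init__(self, tree: dendropy.Tree):
        self.nodes = list(tree.postorder_node_iter())
        self.index = {id(n): i for i, n in enumerate(self.nodes)}
        self.children = [
            [self.index[id(c)] for c in n.child_nodes()] for n in self.nodes
        ]
        self.leaf_taxon = {
            i: n.taxon.label for i, n in enumerate(self.nodes) if n.is_leaf()
        }
        self.root = len(self.nodes) - 1
        # (parent, child) pairs over all edges
        self.edges = [
            (i, c) for i, ch in enumerate(self.children) for c in ch
        ]

    def check_taxa(self, taxa: list[str]):
        tree_taxa = set(self.leaf_taxon.values())
        missing = sorted(set(taxa) - tree_taxa)
        extra = sorted(tree_taxa - set(taxa))
        if missing or extra:
            raise TaxonMismatchError(
                f"tree/alignment mismatch; alignment-only: {missing}, "
                f"tree-only: {extra}"
            )


def index_tree(tree: dendropy.Tree) -> _TreeIndex:
    return _TreeIndex(tree)


def parsimony_ancestors(
    tree_index: _TreeIndex,
    site_column: dict[str, str],
    max_labelings: int = 64,
    seed: int = 0,
) -> tuple[list[dict[int, str]], int]:
    """Minimal-change ancestral codons over the observed states of one site.

    Returns (labelings, min_changes) where each labeling maps internal node
    index -> codon.  All co-optimal labelings are returned when there are at
    most ``max_labelings``; otherwise that many are drawn uniformly without
    enumeration, using a seeded generator.
    """
    ti = tree_index
    states = sorted(set(site_column.values()))
    k = len(states)
    state_ix = {s: i for i, s in enumerate(states)}
    n = len(ti.nodes)
    INF = 10 ** 9
    cost = np.zeros((n, k), dtype=np.int64)
    nopt = np.ones((n, k), dtype=float)  # number of optimal sub-labelings

    for i in range(n):
        if i in ti.leaf_taxon:
            observed = site_column[ti.leaf_taxon[i]]
            for j in range(k):
                cost[i, j] = 0 if states[j] == observed else INF
            continue
        for j in range(k):
            total = 0
            ways = 1.0
            for c in ti.children[i]:
                child_costs = cost[c] + (np.arange(k) != j)
                m = child_costs.min()
                total += int(m)
                ways *= nopt[c][child_costs == m].sum()
            cost[i, j] = total
            nopt[i, j] = ways

    root_costs = cost[ti.root]
    best = int(root_costs.min())
    total_labelings = nopt[ti.root][root_costs == best].sum()

    rng = np.random.default_rng(seed)
    sample = total_labelings > max_labelings

    def draw_root() -> int:
        opts = np.flatnonzero(root_costs == best)
        if not sample:
            return -1  # unused
        w = nopt[ti.root][opts]
        return int(rng.choice(opts, p=w / w.sum()))

    def assign_down(i: int, j: int, labeling: dict[int, str]):
        """Sample child states uniformly among minimizers (stack-based)."""
        stack = [(i, j)]
        while stack:
            node, s = stack.pop()
            labeling[node] = states[s]
            for c in ti.children[node]:
                child_costs = cost[c] + (np.arange(k) != s)
                m = child_costs.min()
                opts = np.flatnonzero(child_costs == m)
                w = nopt[c][opts]
                pick = int(rng.choice(opts, p=w / w.sum()))
                stack.append((c, pick))

    labelings: list[dict[int, str]] = []
    if sample:
        for _ in range(max_labelings):
            lab: dict[int, str] = {}
            assign_down(ti.root, draw_root(), lab)
            labelings.append(lab)
        return labelings, best

    # exhaustive enumeration by recursive backtracking
    def expand(i: int, j: int) -> list[dict[int, str]]:
        partial = [{i: states[j]}]
        for c in ti.children[i]:
            child_costs = cost[c] + (np.arange(k) != j)
            m = child_costs.min()
            sub: list[dict[int, str]] = []
            for jj in np.flatnonzero(child_costs == m):
                sub.extend(expand(c, int(jj)))
            partial = [{**p, **s} for p in partial for s in sub]
        return partial

    for j in np.flatnonzero(root_costs == best):
        labelings.extend(expand(ti.root, int(j)))
    return labelings, best


# --- per-site counting and the site test -------------------------------------

@dataclass(frozen=True)
class SiteSelectionRecord:
    site_index: int
    ES: float
    EN: float
    OS: float
    ON: float
    dS: float
    dN: float
    dn_minus_ds: float
    p_value: float
    site_class: str  # positive / negative / ns


def count_site_substitutions(
    tree_index: _TreeIndex,
    site_column: dict[str, str],
    labelings: list[dict[int, str]],
) -> tuple[float, float, float, float]:
    """(OS, ON, ES, EN) for a site, averaged over co-optimal labelings."""
    ti = tree_index
    os_sum = on_sum = es_sum = en_sum = 0.0
    for labeling in labelings:
        full = dict(labeling)
        for i, taxon in ti.leaf_taxon.items():
            full[i] = site_column[taxon]
        for parent, child in ti.edges:
            p_codon, c_codon = full[parent], full[child]
            es, en = potential_sites(p_codon)
            es_sum += es
            en_sum += en
            if p_codon != c_codon:
                s, ns = _path_counts(p_codon, c_codon)
                os_sum += s
                on_sum += ns
    m = len(labelings)
    return os_sum / m, on_sum / m, es_sum / m, en_sum / m


def extended_binomial_pvalue(x: float, n: float, p: float) -> float:
    """Two-sided p-value for x successes in n trials at success rate p.

    Continuous extension of the binomial via the regularized incomplete
    beta function, valid for fractional x and n (the averaged counts).
    """
    if n <= 0:
        return 1.0
    if not 0.0 < p < 1.0:
        return 1.0
    x = min(max(x, 0.0), n)
    lower = 1.0 if n - x <= 0 else float(betainc(n - x, x + 1.0, 1.0 - p))
    upper = 1.0 if x <= 0 else float(betainc(x, n - x + 1.0, p))
    return float(min(1.0, 2.0 * min(lower, upper)))


@dataclass
class SlacResult:
    records: list[SiteSelectionRecord]
    global_dnds: float | None  # None when no synonymous change was counted
    n_positive: int
    n_negative: int
    alpha: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [{
                "site": r.site_index, "OS": r.OS, "ON": r.ON,
                "ES": r.ES, "EN": r.EN, "dS": r.dS, "dN": r.dN,
                "dn_minus_ds": r.dn_minus_ds, "p_value": r.p_value,
                "class": r.site_class,
            } for r in self.records]
        )


def slac_site_test(
    alignment: CodonAlignment,
    tree: dendropy.Tree,
    alpha: float = 0.1,
    max_labelings: int = 64,
    seed: int = 0,
) -> SlacResult:
    """Per-site dN-dS classification and global dN/dS over all sites.

    Sites with no counted substitution get p = 1 by convention.  The global
    ratio is (sum ON / sum EN) / (sum OS / sum ES); it is None (flagged) when
    the alignment yields no synonymous substitutions at all.
    """
    ti = index_tree(tree)
    ti.check_taxa(alignment.taxa)
    records: list[SiteSelectionRecord] = []
    tot_os = tot_on = tot_es = tot_en = 0.0
    stops = stop_codons()
    for site, col in enumerate(alignment.columns):
        column = {
            t: c for t, c in zip(alignment.taxa, col)
            if c not in stops and all(b in "ACGT" for b in c)
        }
        if len(column) < 2:
            records.append(
                SiteSelectionRecord(site, 0, 0, 0, 0, 0, 0, 0, 1.0, "ns")
            )
            continue
        if len(column) < len(alignment.taxa):
            # codons with gaps/ambiguity/stops are dropped for this site;
            # reconstruct on the subtree induced by the remaining taxa
            sub_ti = _induced_index(tree, set(column))
        else:
            sub_ti = ti
        labelings, _ = parsimony_ancestors(
            sub_ti, column, max_labelings=max_labelings, seed=seed + site
        )
        os_, on_, es_, en_ = count_site_substitutions(sub_ti, column, labelings)
        tot_os += os_
        tot_on += on_
        tot_es += es_
        tot_en += en_
        ds = os_ / es_ if es_ > 0 else 0.0
        dn = on_ / en_ if en_ > 0 else 0.0
        diff = dn - ds
        p = (
            1.0 if os_ + on_ == 0
            else extended_binomial_pvalue(on_, on_ + os_, en_ / (en_ + es_))
        )
        if p <= alpha and diff > 0:
            cls = "positive"
        elif p <= alpha and diff < 0:
            cls = "negative"
        else:
            cls = "ns"
        records.append(
            SiteSelectionRecord(site, es_, en_, os_, on_, ds, dn, diff, p, cls)
        )
    global_dnds: float | None = None
    if tot_os > 0 and tot_es > 0 and tot_en > 0:
        global_dnds = (tot_on / tot_en) / (tot_os / tot_es)
    return SlacResult(
        records=records,
        global_dnds=global_dnds,
        n_positive=sum(r.site_class == "positive" for r in records),
        n_negative=sum(r.site_class == "negative" for r in records),
        alpha=alpha,
    )


def _induced_index(tree: dendropy.Tree, keep: set[str]) -> _TreeIndex:
    sub = tree.extract_tree_with_taxa_labels(labels=keep)
    return _TreeIndex(sub)
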