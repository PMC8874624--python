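"""Synthetic annotated mitogenomes, codon alignments and trees with planted truth.

The generator emulates the statistical regime of parasitoid-wasp
mitochondrial genomes: ~15-16 kb circular molecules carrying the canonical
37 genes, majority-strand A+T content above 80% with a negative GC skew,
tRNA-cluster shuffles and transpositions layered onto the ancestral insect
gene order, and protein-coding sequences evolved under strong purifying
selection (dN/dS around 0.13) with transition and AT mutation bias.  Every
output records the ground truth needed to score the downstream inferences.

All randomness flows through a single integer seed into numpy Generator
streams, so a fixed seed gives byte-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import dendropy
import numpy as np
from scipy.linalg import expm

from .genes import (
    ANCESTRAL_INSECT_ORDER,
    gene_category,
    sense_codons,
    stop_codons,
)
from .mitio import GeneFeature, GeneOrder, MitoGenome
from .selection import CodonAlignment

Element = tuple[str, int]


@dataclass(frozen=True)
class SimulationConfig:
    """Study-condition defaults for the synthetic cohort.

    at_content/gc_skew target the majority strand (>0.80 A+T, negative GC
    skew); omega and kappa parameterize the codon substitution process
    (strong purifying selection, mild transition bias); branch_mean is the
    expected branch length in substitutions per codon site.
    """

    n_genomes: int = 104
    at_content: float = 0.82
    gc_skew: float = -0.2
    at_skew: float = 0.0
    omega: float = 0.13
    kappa: float = 2.0
    n_tips: int = 16
    n_codons: int = 2000
    branch_mean: float = 0.03
    seed: int = 0

    def __post_init__(self):
        if not 0 < self.at_content < 1:
            raise ValueError("at_content must be in (0, 1)")
        if self.omega <= 0:
            raise ValueError("omega must be positive")


@dataclass
class TruthTable:
    """Planted ground truth accompanying each simulated dataset."""

    gene_orders: dict[str, GeneOrder] = field(default_factory=dict)
    event_logs: dict[str, list[tuple]] = field(default_factory=dict)
    type_of_genome: dict[str, int] = field(default_factory=dict)
    omega: float | None = None
    kappa: float | None = None
    tree_newick: str | None = None


# --- nucleotide / codon target distributions ---------------------------------

def nucleotide_frequencies(config: SimulationConfig) -> dict[str, float]:
    """Majority-strand A/C/G/T frequencies hitting the composition targets."""
    at, gc = config.at_content, 1.0 - config.at_content
    return {
        "A": at * (1 + config.at_skew) / 2,
        "T": at * (1 - config.at_skew) / 2,
        "G": gc * (1 + config.gc_skew) / 2,
        "C": gc * (1 - config.gc_skew) / 2,
    }


def _codon_distribution(freqs: dict[str, float]) -> tuple[list[str], np.ndarray]:
    """Sense-codon sampling distribution = product of site frequencies."""
    codons = list(sense_codons())
    w = np.array([freqs[a] * freqs[b] * freqs[c] for a, b, c in codons])
    return codons, w / w.sum()


# --- gene-order simulation ---------------------------------------------------

def _apply_event(elements: tuple[Element, ...], event: tuple) -> tuple[Element, ...]:
    """Apply one planted event; events are primitive block edits.

    ('swap_adjacent', a, b): exchange two neighboring genes (a shuffle);
    ('move', (genes...), target): excise a block and reinsert after target;
    ('invert', (genes...)): flip strands and reverse the block in place.
    """
    names = [g for g, _ in elements]
    kind = event[0]
    if kind == "swap_adjacent":
        _, a, b = event
        i, j = names.index(a), names.index(b)
        lst = list(elements)
        lst[i], lst[j] = lst[j], lst[i]
        return tuple(lst)
    if kind == "move":
        _, genes, target = event
        if target in genes:
            raise ValueError("move target inside moved block")
        block = [el for el in elements if el[0] in genes]
        if len(block) != len(genes):
            missing = set(genes) - {g for g, _ in elements}
            raise ValueError(f"event names absent genes: {sorted(missing)}")
        rest = [el for el in elements if el[0] not in genes]
        k = next(i for i, (g, _) in enumerate(rest) if g == target)
        return tuple(rest[:k + 1] + block + rest[k + 1:])
    if kind == "invert":
        _, genes = event
        idx = [i for i, g in enumerate(names) if g in genes]
        if len(idx) != len(genes) or idx != list(range(idx[0], idx[-1] + 1)):
            raise ValueError("invert block must be present and contiguous")
        lst = list(elements)
        lst[idx[0]:idx[-1] + 1] = [
            (g, -s) for g, s in reversed(lst[idx[0]:idx[-1] + 1])
        ]
        return tuple(lst)
    raise ValueError(f"unknown event kind {kind!r}")


def apply_events(
    order: GeneOrder, events: list[tuple], genome_id: str | None = None
) -> GeneOrder:
    elements = order.elements
    for event in events:
        elements = _apply_event(elements, event)
    return GeneOrder(genome_id or order.genome_id, elements, order.circular)


R1_EVENTS = [
    ("swap_adjacent", "trnC", "trnY"),
    ("move", ("trnM",), "rrnS"),  # trnM to the front of trnI-trnQ
]

TRNL2_TRANSPOSITION = [("move", ("trnL2",), "rrnS")]


def _random_events(rng: np.random.Generator, n_events: int) -> list[tuple]:
    """Draw tRNA-level rearrangement events (shuffles, moves, inversions)."""
    trnas = [g for g, _ in ANCESTRAL_INSECT_ORDER if gene_category(g) == "tRNA"]
    all_names = [g for g, _ in ANCESTRAL_INSECT_ORDER]
    events: list[tuple] = []
    for _ in range(n_events):
        kind = rng.choice(["swap_adjacent", "move", "invert"], p=[0.5, 0.35, 0.15])
        gene = str(rng.choice(trnas))
        if kind == "swap_adjacent":
            i = all_names.index(gene)
            neighbor = all_names[(i + 1) % len(all_names)]
            events.append(("swap_adjacent", gene, neighbor))
        elif kind == "move":
            target = str(rng.choice([g for g in all_names if g != gene]))
            events.append(("move", (gene,), target))
        else:
            events.append(("invert", (gene,)))
    return events


def simulate_gene_orders(
    config: SimulationConfig,
    n_types: int = 38,
    events_per_type: tuple[int, int] = (1, 4),
) -> tuple[list[GeneOrder], TruthTable]:
    """Sample ``n_genomes`` gene orders from ``n_types`` planted distinct orders.

    Type 0 is always the ancestral order itself and type 1 the hallmark
    double-shuffle; further types stack 1-4 random tRNA events, re-drawn
    until all planted signatures are pairwise distinct.  Every type gets at
    least one genome; remaining genomes are assigned uniformly.
    """
    from .rearrangement import canonicalize  # local import: avoid cycle

    if n_types > config.n_genomes:
        raise ValueError("more planted types than genomes")
    rng = np.random.default_rng(config.seed)
    ancestral = GeneOrder("ancestral", ANCESTRAL_INSECT_ORDER)

    planted: list[list[tuple]] = [[]]
    if n_types >= 2:
        planted.append(list(R1_EVENTS))
    signatures = {canonicalize(apply_events(ancestral, ev, f"t{i}")).key
                  for i, ev in enumerate(planted)}
    while len(planted) < n_types:
        n_ev = int(rng.integers(events_per_type[0], events_per_type[1] + 1))
        events = _random_events(rng, n_ev)
        try:
            order = apply_events(ancestral, events, "candidate")
        except ValueError:
            continue
        key = canonicalize(order).key
        if key in signatures:
            continue
        signatures.add(key)
        planted.append(events)

    assignment = list(range(n_types))
    assignment += [
        int(rng.integers(0, n_types))
        for _ in range(config.n_genomes - n_types)
    ]
    rng.shuffle(assignment)

    truth = TruthTable()
    orders = []
    for i, type_ix in enumerate(assignment):
        gid = f"genome{i:03d}"
        order = apply_events(ancestral, planted[type_ix], gid)
        orders.append(order)
        truth.gene_orders[gid] = order
        truth.event_logs[gid] = planted[type_ix]
        truth.type_of_genome[gid] = type_ix
    return orders, truth


# --- tree simulation ---------------------------------------------------------

def simulate_tree(
    n_tips: int, branch_mean: float, rng: np.random.Generator
) -> dendropy.Tree:
    """Random binary topology by successive pairing, exponential branch lengths."""
    labels = [f"taxon{i:02d}" for i in range(n_tips)]
    newicks = list(labels)
    while len(newicks) > 1:
        i, j = sorted(rng.choice(len(newicks), size=2, replace=False))
        bi = rng.exponential(branch_mean)
        bj = rng.exponential(branch_mean)
        merged = f"({newicks[i]}:{bi:.6f},{newicks[j]}:{bj:.6f})"
        newicks = [s for k, s in enumerate(newicks) if k not in (i, j)]
        newicks.append(merged)
    return dendropy.Tree.get(data=newicks[0] + ";", schema="newick")


# --- codon alignment simulation ----------------------------------------------

_TRANSITIONS = {("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")}


def _mg94_matrix(config: SimulationConfig) -> tuple[list[str], np.ndarray, np.ndarray]:
    """Muse-Gaut-style codon rate matrix and its root distribution.

    Single-nucleotide exchanges at rate pi(target) * kappa^[transition]
    * omega^[nonsynonymous]; multi-nucleotide exchanges and stops excluded.
    Scaled so branch lengths are expected substitutions per codon site at
    stationarity.
    """
    from .genes import translate_codon

    codons = list(sense_codons())
    freqs = nucleotide_frequencies(config)
    n = len(codons)
    pos = {c: i for i, c in enumerate(codons)}
    Q = np.zeros((n, n))
    for i, ci in enumerate(codons):
        for p in range(3):
            for b in "ACGT":
                if b == ci[p]:
                    continue
                cj = ci[:p] + b + ci[p + 1:]
                if cj in stop_codons():
                    continue
                rate = freqs[b]
                if (ci[p], b) in _TRANSITIONS:
                    rate *= config.kappa
                if translate_codon(ci) != translate_codon(cj):
                    rate *= config.omega
                Q[i, pos[cj]] = rate
    np.fill_diagonal(Q, -Q.sum(axis=1))
    _, codon_w = _codon_distribution(freqs)
    scale = -(codon_w * np.diag(Q)).sum()
    return codons, Q / scale, codon_w


def simulate_codon_alignment(
    config: SimulationConfig, tree: dendropy.Tree | None = None
) -> tuple[CodonAlignment, TruthTable, dendropy.Tree]:
    """Evolve independent codon sites along a tree under the MG94-style model."""
    rng = np.random.default_rng(config.seed)
    if tree is None:
        tree = simulate_tree(config.n_tips, config.branch_mean, rng)
    codons, Q, root_w = _mg94_matrix(config)
    n_codons = config.n_codons

    states: dict[int, np.ndarray] = {}
    root = tree.seed_node
    states[id(root)] = rng.choice(len(codons), size=n_codons, p=root_w)
    transition_cache: dict[float, np.ndarray] = {}
    for node in tree.preorder_node_iter():
        if node is root:
            continue
        t = float(node.edge.length or 0.0)
        if t not in transition_cache:
            transition_cache[t] = (
                np.eye(len(codons)) if t == 0.0 else expm(Q * t)
            )
        P = transition_cache[t]
        parent_states = states[id(node.parent_node)]
        cum = P.cumsum(axis=1)
        u = rng.random(n_codons)
        child = np.empty(n_codons, dtype=np.int64)
        for s in np.unique(parent_states):
            mask = parent_states == s
            child[mask] = np.searchsorted(cum[s], u[mask])
        states[id(node)] = child

    sequences = {
        leaf.taxon.label: "".join(
            codons[s] for s in states[id(leaf)]
        )
        for leaf in tree.leaf_node_iter()
    }
    alignment = CodonAlignment.from_sequences(sequences)
    truth = TruthTable(
        omega=config.omega,
        kappa=config.kappa,
        tree_newick=tree.as_string(schema="newick").strip(),
    )
    return alignment, truth, tree


# --- whole-genome simulation -------------------------------------------------

# Round per-gene lengths (nt) in the range typical of insect mitogenomes.
GENE_LENGTHS = {
    "cox1": 1536, "cox2": 684, "cox3": 786, "cob": 1140,
    "nad1": 942, "nad2": 1020, "nad3": 351, "nad4": 1341,
    "nad4l": 291, "nad5": 1716, "nad6": 522, "atp6": 678, "atp8": 159,
    "rrnS": 800, "rrnL": 1320,
}
TRNA_LENGTH = 66
CONTROL_REGION_LENGTH = 1000
SPACER_MAX = 3


def _random_cds(
    n_codons: int, freqs: dict[str, float], rng: np.random.Generator
) -> str:
    codons, w = _codon_distribution(freqs)
    body = rng.choice(len(codons), size=n_codons - 1, p=w)
    return "".join(codons[i] for i in body) + "TAA"


def _random_nt(n: int, freqs: dict[str, float], rng: np.random.Generator) -> str:
    bases = np.array(list("ACGT"))
    p = np.array([freqs[b] for b in "ACGT"])
    return "".join(rng.choice(bases, size=n, p=p / p.sum()))


_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def _revcomp(s: str) -> str:
    return s.translate(_COMPLEMENT)[::-1]


def simulate_mitogenome(
    order: GeneOrder, config: SimulationConfig, rng: np.random.Generator
) -> MitoGenome:
    """One annotated circular genome realizing a planted gene order.

    Majority-strand composition targets apply everywhere: genes on the
    minority strand are generated against the complemented target so the
    assembled majority strand still hits it.  PCGs are stop-free random
    codon strings ending in TAA; no real homology is embedded.
    """
    freqs = nucleotide_frequencies(config)
    comp_freqs = {
        "A": freqs["T"], "T": freqs["A"], "C": freqs["G"], "G": freqs["C"]
    }
    parts: list[str] = []
    features: list[GeneFeature] = []
    pos = 0
    for gene, strand in order.elements:
        cat = gene_category(gene)
        gene_freqs = freqs if strand == +1 else comp_freqs
        if cat == "PCG":
            seq = _random_cds(GENE_LENGTHS[gene] // 3, gene_freqs, rng)
        elif cat == "tRNA":
            seq = _random_nt(TRNA_LENGTH, gene_freqs, rng)
        else:
            seq = _random_nt(GENE_LENGTHS[gene], gene_freqs, rng)
        if strand == -1:
            seq = _revcomp(seq)
        features.append(GeneFeature(gene, cat, pos, pos + len(seq), strand))
        parts.append(seq)
        pos += len(seq)
        spacer = int(rng.integers(0, SPACER_MAX + 1))
        if spacer:
            parts.append(_random_nt(spacer, freqs, rng))
            pos += spacer
    cr = _random_nt(CONTROL_REGION_LENGTH, freqs, rng)
    features.append(
        GeneFeature("control_region", "control_region", pos, pos + len(cr), +1)
    )
    parts.append(cr)
    return MitoGenome(
        id=order.genome_id,
        sequence="".join(parts),
        features=features,
        circular=True,
    )


def simulate_mitogenomes(
    config: SimulationConfig, n_types: int = 38
) -> tuple[list[MitoGenome], TruthTable]:
    """A cohort of annotated genomes over planted gene-order types."""
    orders, truth = simulate_gene_orders(config, n_types=n_types)
    rng = np.random.default_rng(config.seed + 1)
    genomes = [simulate_mitogenome(order, config, rng) for order in orders]
    return genomes, truth


def with_seed(config: SimulationConfig, seed: int) -> SimulationConfig:
    return replace(config, seed=seed)
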