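"""Circular signed gene-order comparison, rearrangement typing and tree mapping.

Gene orders are compared as signed circular permutations of the 37 canonical
mitochondrial genes against the ancestral insect (pancrustacean) ground
pattern.  Orders equal up to rotation or whole-molecule reflection share a
canonical signature; distinct signatures define rearrangement types
(R-labels).  Against the ancestral reference, displaced blocks are classified
as tRNA-cluster shuffles (local), transpositions (remote), inversions
(strand-flipping in place) or inverse transpositions, with a greedy
longest-kept-backbone decomposition whose replay provably reproduces the
observed order.  Shared derived order features (e.g. trnL2 relocated next to
the trnM-trnI-trnQ cluster) can be mapped onto a phylogeny to test whether
they mark clades.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import dendropy
import pandas as pd

from .genes import ANCESTRAL_INSECT_ORDER, CANONICAL_GENES, gene_category
from .mitio import GeneOrder

ANCHOR_GENE = "cox1"

Element = tuple[str, int]


def ancestral_order() -> GeneOrder:
    """The built-in 37-gene ancestral insect gene order."""
    return GeneOrder("ancestral_insect", ANCESTRAL_INSECT_ORDER)


# --- canonical signatures ----------------------------------------------------

@dataclass(frozen=True)
class OrderSignature:
    key: str
    missing: tuple[str, ...]

    def __str__(self) -> str:
        return self.key


def _reflect(elements: tuple[Element, ...]) -> tuple[Element, ...]:
    return tuple((g, -s) for g, s in reversed(elements))


def _rotate_to(elements: tuple[Element, ...], anchor: str) -> tuple[Element, ...]:
    names = [g for g, _ in elements]
    i = names.index(anchor)
    return elements[i:] + elements[:i]


def canonicalize(order: GeneOrder) -> OrderSignature:
    """Rotation- and reflection-invariant signature of a circular order.

    The order is rotated to start at cox1 (or the lexicographically smallest
    present gene) and reflected, if needed, so the anchor lies on the +
    strand; missing canonical genes are recorded in the mask.
    """
    if not order.elements:
        raise ValueError("empty gene order")
    present = order.genes
    anchor = ANCHOR_GENE if ANCHOR_GENE in present else min(present)
    elements = order.elements
    anchor_strand = next(s for g, s in elements if g == anchor)
    if anchor_strand == -1:
        elements = _reflect(elements)
    elements = _rotate_to(elements, anchor)
    key = "|".join(f"{g}{'+' if s > 0 else '-'}" for g, s in elements)
    missing = tuple(sorted(set(CANONICAL_GENES) - present))
    return OrderSignature(key=key, missing=missing)


def canonical_elements(order: GeneOrder) -> tuple[Element, ...]:
    """The element tuple underlying :func:`canonicalize`."""
    sig_elements = []
    for token in canonicalize(order).key.split("|"):
        sig_elements.append((token[:-1], +1 if token[-1] == "+" else -1))
    return tuple(sig_elements)


# --- breakpoint distance -----------------------------------------------------

def _adjacency_set(elements: tuple[Element, ...]) -> set[tuple[Element, Element]]:
    adj = set()
    n = len(elements)
    for i in range(n):
        a, b = elements[i], elements[(i + 1) % n]
        forward = (a, b)
        backward = ((b[0], -b[1]), (a[0], -a[1]))
        adj.add(min(forward, backward))
    return adj


def breakpoint_distance(a: GeneOrder, b: GeneOrder) -> int:
    """Signed circular adjacencies of ``a`` absent from ``b`` (shared genes)."""
    shared = a.genes & b.genes
    if len(shared) < 2:
        raise ValueError("breakpoint distance needs >= 2 shared genes")
    ea = a.restricted_to(shared).elements
    eb = b.restricted_to(shared).elements
    return len(_adjacency_set(ea) - _adjacency_set(eb))


# --- event inference ---------------------------------------------------------

@dataclass(frozen=True)
class EventCall:
    """One inferred rearrangement event explaining part of an observed order."""

    kind: str  # shuffle | transposition | inversion | inverse_transposition
    genes: tuple[str, ...]
    donor_context: tuple[str | None, str | None]     # reference neighbors
    acceptor_context: tuple[str | None, str | None]  # observed neighbors
    strand_changed: bool
    displacement: int


def _lcs_keep(obs: list[Element], ref: list[Element]) -> set[str]:
    """Gene names of one longest common subsequence (deterministic)."""
    n, m = len(obs), len(ref)
    L = [[0] * (m + 1) for _ in range(n + 1)]
    for i in range(n - 1, -1, -1):
        for j in range(m - 1, -1, -1):
            if obs[i] == ref[j]:
                L[i][j] = 1 + L[i + 1][j + 1]
            else:
                L[i][j] = max(L[i + 1][j], L[i][j + 1])
    keep: set[str] = set()
    i = j = 0
    while i < n and j < m:
        if obs[i] == ref[j]:
            keep.add(obs[i][0])
            i += 1
            j += 1
        elif L[i + 1][j] >= L[i][j + 1]:
            i += 1
        else:
            j += 1
    return keep


def _home_cluster(gene: str, ref: list[Element]) -> set[str]:
    """Genes of the maximal tRNA run containing ``gene`` in the reference.

    For non-tRNA genes the cluster is the gene itself: protein-coding and
    rRNA genes have no shuffling neighborhood.
    """
    names = [g for g, _ in ref]
    cluster = {gene}
    if gene_category(gene) != "tRNA":
        return cluster
    i = names.index(gene)
    n = len(names)
    j = (i - 1) % n
    while gene_category(names[j]) == "tRNA" and len(cluster) < n:
        cluster.add(names[j])
        j = (j - 1) % n
    j = (i + 1) % n
    while gene_category(names[j]) == "tRNA" and len(cluster) < n:
        cluster.add(names[j])
        j = (j + 1) % n
    return cluster


def infer_events(
    observed: GeneOrder, reference: GeneOrder | None = None
) -> list[EventCall]:
    """Greedy minimal-event explanation of an observed order vs a reference.

    A longest backbone of genes in common signed order is kept; each
    reference-contiguous run of displaced genes becomes one event,
    classified by whether its strand flipped and where it re-inserted:
    within its home tRNA cluster (or barely displaced) it is a shuffle,
    further afield a transposition; strand-flipped in place an inversion,
    strand-flipped and remote an inverse transposition.  The inferred list
    replays exactly onto the reference; its length is an upper bound on the
    true minimal event count.
    """
    reference = reference or ancestral_order()
    shared = observed.genes & reference.genes
    if len(shared) < 2:
        raise ValueError("event inference needs >= 2 shared genes")
    ref = list(canonical_elements(reference.restricted_to(shared)))
    obs_base = canonical_elements(observed.restricted_to(shared))

    # choose the rotation of the observed circle best aligned with the
    # reference linearization (largest kept backbone; ties -> smallest shift)
    best_keep: set[str] = set()
    best_obs: list[Element] = list(obs_base)
    for shift in range(len(obs_base)):
        rotated = list(obs_base[shift:] + obs_base[:shift])
        keep = _lcs_keep(rotated, ref)
        if len(keep) > len(best_keep):
            best_keep, best_obs = keep, rotated
    obs, keep = best_obs, best_keep

    ref_names = [g for g, _ in ref]
    ref_sign = dict(ref)
    n = len(ref)

    # maximal runs of displaced genes, in observed order
    runs: list[list[Element]] = []
    current: list[Element] = []
    for el in obs:
        if el[0] in keep:
            if current:
                runs.append(current)
                current = []
        else:
            current.append(el)
    if current:
        runs.append(current)

    # split each run so every block is contiguous in the reference (and
    # consistently oriented) -- one block then corresponds to one event
    def _ref_contiguous(prev: Element, el: Element) -> bool:
        i, j = ref_names.index(prev[0]), ref_names.index(el[0])
        forward = (i + 1) % n == j
        backward = (i - 1) % n == j
        prev_flipped = prev[1] != ref_sign[prev[0]]
        el_flipped = el[1] != ref_sign[el[0]]
        if forward and not prev_flipped and not el_flipped:
            return True
        return backward and prev_flipped and el_flipped

    blocks: list[list[Element]] = []
    for run in runs:
        block = [run[0]]
        for prev, el in zip(run, run[1:]):
            if _ref_contiguous(prev, el):
                block.append(el)
            else:
                blocks.append(block)
                block = [el]
        blocks.append(block)

    events: list[EventCall] = []
    for block in blocks:
        genes = tuple(g for g, _ in block)
        strand_changed = any(s != ref_sign[g] for g, s in block)
        first = genes[0]
        ref_pos = ref_names.index(first)
        obs_pos = next(i for i, (g, _) in enumerate(obs) if g == first)
        # observed neighbors (acceptor context)
        left = obs[obs_pos - 1][0] if obs_pos > 0 else obs[-1][0]
        right_i = obs_pos + len(block)
        right = obs[right_i][0] if right_i < len(obs) else obs[0][0]
        # reference neighbors (donor context)
        dleft = ref_names[(ref_pos - 1) % n]
        dright = ref_names[(ref_pos + len(block)) % n]
        # displacement: circular index shift of the block's leading gene
        ins = ref_names.index(left) if left in ref_names else 0
        raw = abs(ref_pos - ins)
        displacement = min(raw, n - raw)
        # local move = reinserted inside the block's home tRNA cluster (or
        # barely displaced); anything further afield is a transposition
        home = _home_cluster(first, ref)
        local = bool({left, right} & home) or displacement <= 2
        if strand_changed and displacement <= 1:
            kind = "inversion"
        elif strand_changed:
            kind = "inverse_transposition"
        elif local:
            kind = "shuffle"
        else:
            kind = "transposition"
        events.append(
            EventCall(
                kind=kind,
                genes=genes,
                donor_context=(dleft, dright),
                acceptor_context=(left, right),
                strand_changed=strand_changed,
                displacement=displacement,
            )
        )

    _check_replay(obs, ref, keep, blocks)
    return events


def _check_replay(
    obs: list[Element],
    ref: list[Element],
    keep: set[str],
    blocks: list[list[Element]],
):
    """Re-apply the block moves to the reference backbone; must match observed."""
    replay = [el for el in ref if el[0] in keep]
    for block in blocks:
        first = block[0][0]
        obs_pos = next(i for i, (g, _) in enumerate(obs) if g == first)
        if obs_pos == 0:
            replay = list(block) + replay
        else:
            left = obs[obs_pos - 1][0]
            j = next(i for i, (g, _) in enumerate(replay) if g == left)
            replay = replay[:j + 1] + list(block) + replay[j + 1:]
    if replay != obs:  # pragma: no cover - indicates an algorithmic bug
        raise RuntimeError("event replay failed to reproduce the observed order")


# --- typing (catalog) --------------------------------------------------------

# The hallmark double-shuffle order: trnW-trnC-trnY shuffled to trnW-trnY-trnC
# and trnI-trnQ-trnM shuffled to trnM-trnI-trnQ, on the ancestral background.
def r1_order() -> GeneOrder:
    swap = {"trnI": ("trnM", +1), "trnQ": ("trnI", +1), "trnM": ("trnQ", -1),
            "trnC": ("trnY", -1), "trnY": ("trnC", -1)}
    elements = tuple(swap.get(g, (g, s)) for g, s in ANCESTRAL_INSECT_ORDER)
    return GeneOrder("R1_reference", elements)


@dataclass
class RearrangementType:
    label: str
    signature: OrderSignature
    members: list[str]
    events: list[EventCall] = field(default_factory=list)
    breakpoints: int = 0
    is_partial: bool = False
    ambiguous: bool = False


@dataclass
class RearrangementCatalog:
    types: list[RearrangementType]

    @property
    def n_types(self) -> int:
        return len(self.types)

    def label_of(self, genome_id: str) -> str:
        for t in self.types:
            if genome_id in t.members:
                return t.label
        raise KeyError(genome_id)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [{
                "label": t.label,
                "n_members": len(t.members),
                "members": ",".join(t.members),
                "breakpoints_vs_ancestral": t.breakpoints,
                "n_events": len(t.events),
                "events": ";".join(
                    f"{e.kind}({','.join(e.genes)})" for e in t.events
                ),
                "partial": t.is_partial,
                "ambiguous": t.ambiguous,
            } for t in self.types]
        )


def classify_types(
    orders: list[GeneOrder], reference: GeneOrder | None = None
) -> RearrangementCatalog:
    """Group gene orders into rearrangement types by canonical signature.

    Partial orders (missing genes) join a unique complete type whose
    projection onto their gene set matches; multi-match partials stay
    separate and are flagged ambiguous.  Labels follow first appearance in
    the input, except that the hallmark double-shuffle signature is always
    labelled R1 when present.
    """
    if not orders:
        raise ValueError("no gene orders given")
    reference = reference or ancestral_order()

    groups: dict[str, dict] = {}
    for order in orders:
        sig = canonicalize(order)
        g = groups.setdefault(
            sig.key, {"sig": sig, "members": [], "order": order}
        )
        g["members"].append(order.genome_id)

    complete = [g for g in groups.values() if not g["sig"].missing]
    partial = [g for g in groups.values() if g["sig"].missing]

    merged: list[dict] = list(complete)
    for g in partial:
        present = g["order"].genes
        matches = [
            c for c in complete
            if canonicalize(c["order"].restricted_to(present)).key == g["sig"].key
        ]
        if len(matches) == 1:
            matches[0]["members"].extend(g["members"])
            matches[0]["absorbed_partial"] = True
        else:
            g["ambiguous"] = len(matches) > 1
            merged.append(g)

    r1_key = canonicalize(r1_order()).key
    merged.sort(key=lambda g: (g["sig"].key != r1_key,))  # stable: R1 first

    types = []
    for i, g in enumerate(merged, start=1):
        order = g["order"]
        types.append(
            RearrangementType(
                label=f"R{i}",
                signature=g["sig"],
                members=sorted(g["members"]),
                events=infer_events(order, reference),
                breakpoints=breakpoint_distance(order, reference),
                is_partial=bool(g["sig"].missing),
                ambiguous=g.get("ambiguous", False),
            )
        )
    return RearrangementCatalog(types)


# --- mapping onto a phylogeny ------------------------------------------------

def _has_run(order: GeneOrder, run: tuple[str, ...]) -> bool:
    names = [g for g, _ in canonical_elements(order)]
    n = len(names)
    for i in range(n):
        window = [names[(i + k) % n] for k in range(len(run))]
        if tuple(window) == run or tuple(reversed(window)) == run:
            return True
    return False


def _adjacent(order: GeneOrder, a: str, b: set[str]) -> bool:
    names = [g for g, _ in order.elements]
    if a not in names:
        return False
    n = len(names)
    i = names.index(a)
    return names[(i - 1) % n] in b or names[(i + 1) % n] in b


#: Named derived gene-order features worth mapping onto trees.
DERIVED_FEATURES = {
    "wyc_shuffle": lambda o: _has_run(o, ("trnW", "trnY", "trnC")),
    "miq_shuffle": lambda o: _has_run(o, ("trnM", "trnI", "trnQ")),
    "trnL2_at_miq_cluster": lambda o: _adjacent(
        o, "trnL2", {"trnM", "trnI", "trnQ"}
    ),
}


def map_types_on_tree(
    catalog: RearrangementCatalog,
    tree: dendropy.Tree,
    orders: list[GeneOrder] | None = None,
    features: dict | None = None,
) -> pd.DataFrame:
    """Smallest clades containing each type's (and feature's) carriers.

    A marker is a clean synapomorphy when the most recent common ancestor of
    its carriers contains no non-carrier tip.  Rows cover every
    rearrangement type and, when the underlying orders are supplied, each
    named derived feature.
    """
    tree.is_rooted = True  # clade queries treat the seed node as root
    tip_labels = {leaf.taxon.label for leaf in tree.leaf_node_iter()}
    members = {m for t in catalog.types for m in t.members}
    unknown = sorted(members - tip_labels)
    if unknown:
        raise ValueError(f"catalog members missing from tree: {unknown}")
    rows = []

    def mrca_row(marker: str, carriers: set[str]) -> dict:
        unknown = sorted(carriers - tip_labels)
        if unknown:
            raise ValueError(f"{marker}: carriers not in tree: {unknown}")
        if len(carriers) == 1:
            clade_tips = set(carriers)
        else:
            mrca = tree.mrca(taxon_labels=sorted(carriers))
            clade_tips = {
                leaf.taxon.label for leaf in mrca.leaf_iter()
            }
        outside = sorted(clade_tips - carriers)
        return {
            "marker": marker,
            "n_carriers": len(carriers),
            "clade_size": len(clade_tips),
            "synapomorphy": not outside,
            "non_carriers_in_clade": ",".join(outside),
            "carriers": ",".join(sorted(carriers)),
        }

    for t in catalog.types:
        rows.append(mrca_row(f"type:{t.label}", set(t.members)))

    if orders is not None:
        feats = features or DERIVED_FEATURES
        for name, predicate in feats.items():
            carriers = {
                o.genome_id for o in orders
                if o.genome_id in tip_labels and predicate(o)
            }
            if carriers:
                rows.append(mrca_row(f"feature:{name}", carriers))
    return pd.DataFrame(rows)
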