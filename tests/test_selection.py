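"""Counting-based dN-dS: potential sites, parsimony ancestors, site test.

The heart of this file is an exhaustive oracle that enumerates every
possible ancestral codon assignment and every substitution path with its
own (deliberately naive) code, and checks the production implementation
against it on all small instances.
"""

from itertools import permutations, product

import dendropy
import numpy as np
import pytest
from scipy.stats import binom

from mitocompare.genes import stop_codons, translate_codon
from mitocompare.selection import (
    CodonAlignment,
    StopCodonError,
    TaxonMismatchError,
    count_site_substitutions,
    extended_binomial_pvalue,
    index_tree,
    parsimony_ancestors,
    potential_sites,
    slac_site_test,
)
from mitocompare.synthetic_data import SimulationConfig, simulate_codon_alignment


# --- potential sites ---------------------------------------------------------

def test_potential_sites_phe():
    syn, nonsyn = potential_sites("TTT")
    assert syn == pytest.approx(1 / 3)
    assert nonsyn == pytest.approx(8 / 3)


def test_potential_sites_four_fold_val():
    syn, nonsyn = potential_sites("GTT")
    assert syn == pytest.approx(1.0)
    assert nonsyn == pytest.approx(2.0)


def test_potential_sites_conservation():
    from mitocompare.genes import sense_codons

    stops = stop_codons()
    for codon in sense_codons():
        has_stop_neighbor = any(
            codon[:p] + b + codon[p + 1:] in stops
            for p in range(3) for b in "ACGT" if b != codon[p]
        )
        syn, nonsyn = potential_sites(codon)
        if has_stop_neighbor:
            assert syn + nonsyn < 3
        else:
            assert syn + nonsyn == pytest.approx(3.0)


def test_potential_sites_rejects_stop():
    with pytest.raises(StopCodonError):
        potential_sites("TAA")


# --- parsimony ---------------------------------------------------------------

def test_invariant_column_has_zero_changes(four_taxon_tree):
    ti = index_tree(four_taxon_tree)
    labelings, changes = parsimony_ancestors(
        ti, {t: "ATG" for t in "ABCD"}
    )
    assert changes == 0
    assert len(labelings) == 1
    assert set(labelings[0].values()) == {"ATG"}


def test_single_internal_change(four_taxon_tree):
    ti = index_tree(four_taxon_tree)
    column = {"A": "AAA", "B": "AAA", "C": "AAG", "D": "AAG"}
    _, changes = parsimony_ancestors(ti, column)
    assert changes == 1


def test_tied_labelings_share_minimal_cost(four_taxon_tree):
    ti = index_tree(four_taxon_tree)
    column = {"A": "AAA", "B": "AAG", "C": "AAA", "D": "AAG"}
    labelings, changes = parsimony_ancestors(ti, column)
    assert len(labelings) > 1
    for lab in labelings:
        full = dict(lab)
        for i, taxon in ti.leaf_taxon.items():
            full[i] = column[taxon]
        observed_changes = sum(
            full[p] != full[c] for p, c in ti.edges
        )
        assert observed_changes == changes


def test_taxon_mismatch_lists_offenders(four_taxon_tree):
    aln = CodonAlignment.from_sequences({"A": "AAA", "B": "AAA", "X": "AAA"})
    with pytest.raises(TaxonMismatchError, match="X"):
        slac_site_test(aln, four_taxon_tree)


# --- branch counting ---------------------------------------------------------

def two_taxon_tree():
    return dendropy.Tree.get(data="(A:1,B:1);", schema="newick")


def test_synonymous_single_step_branch():
    ti = index_tree(two_taxon_tree())
    column = {"A": "AAA", "B": "AAG"}  # Lys -> Lys
    labelings, _ = parsimony_ancestors(ti, column)
    os_, on_, es_, en_ = count_site_substitutions(ti, column, labelings)
    assert os_ == pytest.approx(1.0)
    assert on_ == pytest.approx(0.0)
    assert es_ > 0 and en_ > 0


def test_two_step_branch_averages_paths():
    # TTT -> CTC: via CTT (nonsyn then syn) or TTC (syn then nonsyn)
    ti = index_tree(two_taxon_tree())
    column = {"A": "TTT", "B": "CTC"}
    labelings, _ = parsimony_ancestors(ti, column)
    os_, on_, _, _ = count_site_substitutions(ti, column, labelings)
    assert os_ == pytest.approx(1.0)
    assert on_ == pytest.approx(1.0)


# --- exhaustive oracle -------------------------------------------------------

def _oracle_translate(codon):
    return "*" if codon in ("TAA", "TAG") else translate_codon(codon)


def _oracle_potential(codon):
    syn = nonsyn = 0
    for p in range(3):
        for b in "ACGT":
            if b == codon[p]:
                continue
            nb = codon[:p] + b + codon[p + 1:]
            if _oracle_translate(nb) == "*":
                continue
            if _oracle_translate(nb) == _oracle_translate(codon):
                syn += 1
            else:
                nonsyn += 1
    return (syn / 3, nonsyn / 3)


def _oracle_paths(a, b):
    diff = [i for i in range(3) if a[i] != b[i]]
    ok, through_stop = [], []
    for order in permutations(diff):
        cur, syn, nonsyn, bad = a, 0, 0, False
        for p in order:
            nxt = cur[:p] + b[p] + cur[p + 1:]
            bad = bad or _oracle_translate(nxt) == "*"
            if _oracle_translate(cur) == _oracle_translate(nxt):
                syn += 1
            else:
                nonsyn += 1
            cur = nxt
        (through_stop if bad else ok).append((syn, nonsyn))
    paths = ok or through_stop
    return (
        sum(p[0] for p in paths) / len(paths),
        sum(p[1] for p in paths) / len(paths),
    )


def _oracle_site(tree, column):
    """Enumerate every ancestral assignment; average counts over optima."""
    nodes = list(tree.postorder_node_iter())
    internal = [n for n in nodes if not n.is_leaf()]
    states = sorted(set(column.values()))
    edges = [
        (n.parent_node, n) for n in nodes if n.parent_node is not None
    ]

    def codon_of(node, assignment):
        if node.is_leaf():
            return column[node.taxon.label]
        return assignment[internal.index(node)]

    best, optima = None, []
    for assignment in product(states, repeat=len(internal)):
        changes = sum(
            codon_of(p, assignment) != codon_of(c, assignment) for p, c in edges
        )
        if best is None or changes < best:
            best, optima = changes, [assignment]
        elif changes == best:
            optima.append(assignment)

    os_ = on_ = es_ = en_ = 0.0
    for assignment in optima:
        for p, c in edges:
            cp, cc = codon_of(p, assignment), codon_of(c, assignment)
            s_pot, n_pot = _oracle_potential(cp)
            es_ += s_pot
            en_ += n_pot
            if cp != cc:
                s, n = _oracle_paths(cp, cc)
                os_ += s
                on_ += n
    m = len(optima)
    return os_ / m, on_ / m, es_ / m, en_ / m


@pytest.mark.parametrize("n_taxa, seed", [(2, 0), (3, 1), (4, 2), (4, 3), (4, 4)])
def test_site_counts_match_exhaustive_oracle(n_taxa, seed):
    rng = np.random.default_rng(seed)
    newick = {
        2: "(A:1,B:1);",
        3: "((A:1,B:1):1,C:1);",
        4: "((A:1,B:1):1,(C:1,D:1):1);",
    }[n_taxa]
    tree = dendropy.Tree.get(data=newick, schema="newick")
    ti = index_tree(tree)
    from mitocompare.genes import sense_codons

    pool = list(sense_codons())
    taxa = "ABCD"[:n_taxa]
    for _ in range(10):  # 10 codon sites per instance
        # skew choices so some sites are invariant and some multi-state
        k = int(rng.integers(1, 4))
        choices = [pool[int(i)] for i in rng.integers(0, len(pool), size=k)]
        column = {t: choices[int(rng.integers(0, k))] for t in taxa}
        labelings, _ = parsimony_ancestors(ti, column)
        got = count_site_substitutions(ti, column, labelings)
        want = _oracle_site(tree, column)
        assert got == pytest.approx(want, abs=1e-9)


# --- extended binomial -------------------------------------------------------

def test_extended_binomial_matches_doubling_convention_at_integers():
    for n, x, p in [(10, 2, 0.5), (8, 8, 0.3), (5, 0, 0.7), (20, 13, 0.4)]:
        lower = binom.cdf(x, n, p)
        upper = 1 - binom.cdf(x - 1, n, p)
        expected = min(1.0, 2 * min(lower, upper))
        assert extended_binomial_pvalue(x, n, p) == pytest.approx(expected, abs=1e-12)


def test_extended_binomial_degenerate_inputs():
    assert extended_binomial_pvalue(0, 0, 0.5) == 1.0
    assert extended_binomial_pvalue(1.5, 3.2, 0.0) == 1.0


# --- full site test ----------------------------------------------------------

def test_invariant_alignment_flagged(four_taxon_tree):
    aln = CodonAlignment.from_sequences({t: "ATGATG" for t in "ABCD"})
    res = slac_site_test(aln, four_taxon_tree)
    assert all(r.p_value == 1.0 and r.site_class == "ns" for r in res.records)
    assert res.global_dnds is None


def test_single_synonymous_difference_two_taxa():
    aln = CodonAlignment.from_sequences({"A": "AAAATG", "B": "AAGATG"})
    res = slac_site_test(aln, two_taxon_tree())
    site = res.records[0]
    assert site.dS > 0
    assert site.dN == 0
    assert site.dn_minus_ds < 0


def test_near_zero_omega_conserves_amino_acids():
    # with omega ~ 0 every realized substitution is synonymous, so each
    # site stays within one synonymous family across all tips
    config = SimulationConfig(
        omega=1e-9, n_tips=6, n_codons=150, branch_mean=0.3, seed=4
    )
    aln, _, tree = simulate_codon_alignment(config)
    for col in aln.columns:
        assert len({translate_codon(c) for c in col}) == 1
    res = slac_site_test(aln, tree)
    assert sum(r.OS for r in res.records) > 0
    assert res.global_dnds < 0.05


def test_zero_branch_lengths_give_invariant_alignment():
    config = SimulationConfig(n_tips=5, n_codons=60, branch_mean=0.0, seed=6)
    # exponential(0) draws are all zero
    aln, _, tree = simulate_codon_alignment(config)
    assert all(len(set(col)) == 1 for col in aln.columns)


def test_approximate_size_control_under_neutrality():
    config = SimulationConfig(omega=1.0, n_tips=12, n_codons=500, seed=8)
    aln, _, tree = simulate_codon_alignment(config)
    res = slac_site_test(aln, tree, alpha=0.1)
    significant = res.n_positive + res.n_negative
    assert significant / aln.n_sites <= 0.15
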