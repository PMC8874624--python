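import dendropy
import pytest

from mitocompare.mitio import GeneOrder
from mitocompare.rearrangement import ancestral_order
from mitocompare.synthetic_data import SimulationConfig


@pytest.fixture
def ancestral() -> GeneOrder:
    return ancestral_order()


def home_trna_cluster(gene: str, names: list[str]) -> set[str]:
    """Maximal run of tRNA genes around ``gene`` (singleton for non-tRNAs)."""
    cluster = {gene}
    if not gene.startswith("trn"):
        return cluster
    n = len(names)
    i = names.index(gene)
    j = (i - 1) % n
    while names[j].startswith("trn"):
        cluster.add(names[j])
        j = (j - 1) % n
    j = (i + 1) % n
    while names[j].startswith("trn"):
        cluster.add(names[j])
        j = (j + 1) % n
    return cluster


def remote_targets(gene: str, names: list[str], min_dist: int = 5) -> list[str]:
    """Insertion targets that put ``gene`` clearly outside its home cluster."""
    n = len(names)
    i = names.index(gene)
    home = home_trna_cluster(gene, names)
    out = []
    for j, target in enumerate(names):
        if target == gene:
            continue
        successor = names[(j + 1) % n] if names[(j + 1) % n] != gene else names[(j + 2) % n]
        if target in home or successor in home:
            continue
        if min(abs(j - i), n - abs(j - i)) < min_dist:
            continue
        out.append(target)
    return out


@pytest.fixture
def small_config() -> SimulationConfig:
    return SimulationConfig(n_genomes=10, n_tips=6, n_codons=120, seed=11)


@pytest.fixture
def four_taxon_tree() -> dendropy.Tree:
    return dendropy.Tree.get(data="((A:1,B:1):1,(C:1,D:1):1);", schema="newick")


def genbank_record(
    locus: str = "TESTGENOME",
    length: int = 2000,
    features: str = "",
    sequence: str | None = None,
) -> str:
    """Minimal hand-written GenBank flat-file text for parser tests."""
    seq = sequence or ("ATGAAATTTCCCGGG" * (length // 15 + 1))[:length]
    lines = [
        f"LOCUS       {locus}             {len(seq)} bp    DNA     circular INV 01-JAN-2020",
        f"DEFINITION  {locus} mitochondrion.",
        "FEATURES             Location/Qualifiers",
        f"     source          1..{len(seq)}",
    ]
    lines.extend(features.rstrip("\n").split("\n") if features else [])
    lines.append("ORIGIN")
    for i in range(0, len(seq), 60):
        chunk = seq[i:i + 60].lower()
        blocks = " ".join(chunk[j:j + 10] for j in range(0, len(chunk), 10))
        lines.append(f"{i + 1:>9} {blocks}")
    lines.append("//")
    return "\n".join(lines) + "\n"
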