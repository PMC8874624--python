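"""End-to-end orchestration: genomes + optional tree/alignment -> report bundle.

Stages run in a fixed order (composition, codon usage + CA, saturation,
selection, rearrangement); stages whose inputs are absent are skipped with a
logged notice, and a failure in one stage does not stop independent stages.
Outputs are plain TSV files plus a manifest with SHA-256 checksums, so a
re-run on identical inputs is byte-identical and verifiable.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import codon_usage, composition, rearrangement, saturation, selection
from .mitio import (
    GeneOrder,
    MitoGenome,
    extract_gene_order,
    parse_mitogenome,
    read_gene_order_table,
    read_tree,
    write_gene_order_table,
)

log = logging.getLogger("mitocompare")


@dataclass
class RunManifest:
    """Inputs, parameters and output checksums of one pipeline run."""

    genome_dir: str | None = None
    gene_order_table: str | None = None
    alignment_fasta: str | None = None
    tree_newick: str | None = None
    out_dir: str = "mitocompare_out"
    alpha: float = 0.1
    coa_filter: str = "codonw"
    strata: tuple[str, ...] = saturation.STRATA
    seed: int = 0
    checksums: dict[str, str] = field(default_factory=dict)

    @classmethod
    def from_toml(cls, path: str) -> "RunManifest":
        import tomllib

        with open(path, "rb") as fh:
            data = tomllib.load(fh)
        known = {k: v for k, v in data.items() if k in cls.__dataclass_fields__}
        if "strata" in known:
            known["strata"] = tuple(known["strata"])
        return cls(**known)

    def save(self, path: Path):
        payload = {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in self.__dict__.items()
        }
        path.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write(df: pd.DataFrame, path: Path, manifest: RunManifest):
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")
    manifest.checksums[path.name] = _sha256(path)
    log.info("wrote %s (%d rows)", path.name, len(df))


def load_genomes(genome_dir: str) -> list[MitoGenome]:
    """Parse every .gb/.gbk/.genbank file in a directory, sorted by name."""
    paths = sorted(
        p for p in Path(genome_dir).iterdir()
        if p.suffix.lower() in (".gb", ".gbk", ".genbank")
    )
    return [parse_mitogenome(p.read_text()) for p in paths]


def run_all(manifest: RunManifest) -> dict[str, object]:
    """Execute all applicable stages; returns the in-memory results bundle."""
    out = Path(manifest.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    results: dict[str, object] = {}
    errors: dict[str, str] = {}

    genomes: list[MitoGenome] = []
    orders: list[GeneOrder] = []
    if manifest.genome_dir:
        genomes = load_genomes(manifest.genome_dir)
        orders = [extract_gene_order(g) for g in genomes]
        log.info("stage=load genomes=%d", len(genomes))
    elif manifest.gene_order_table:
        orders = read_gene_order_table(manifest.gene_order_table)
        log.info("stage=load gene_orders=%d", len(orders))

    tree = read_tree(manifest.tree_newick) if manifest.tree_newick else None

    if genomes:
        try:
            df = composition.composition_report(genomes)
            _write(df, out / "composition.tsv", manifest)
            results["composition"] = df
            points = [
                composition.codon_position_gc(g.pcg_sequences(), g.id)
                for g in genomes if g.pcg_sequences()
            ]
            if len(points) >= 3:
                slope, intercept, r = composition.neutrality_regression(points)
                results["neutrality"] = {
                    "slope": slope, "intercept": intercept, "r": r,
                }
                _write(
                    pd.DataFrame([results["neutrality"]]),
                    out / "neutrality.tsv", manifest,
                )
        except Exception as exc:
            errors["composition"] = str(exc)

        try:
            counts = [
                codon_usage.count_codons(g.pcg_sequences(), g.id)
                for g in genomes if g.pcg_sequences()
            ]
            tables = [codon_usage.rscu(c) for c in counts]
            _write(
                codon_usage.rscu_matrix(tables, "all").reset_index(names="genome_id"),
                out / "rscu.tsv", manifest,
            )
            _write(
                codon_usage.aa_usage_matrix(counts).reset_index(names="genome_id"),
                out / "aa_usage.tsv", manifest,
            )
            enc_df = codon_usage.codon_usage_report(genomes)
            _write(enc_df, out / "enc.tsv", manifest)
            results["codon_usage"] = enc_df
            if len(counts) >= 3:
                coa = codon_usage.correspondence_analysis(
                    codon_usage.rscu_matrix(tables, manifest.coa_filter)
                )
                results["coa_rscu"] = coa
                _write(
                    coa.row_coords.reset_index(names="genome_id"),
                    out / "coa_rscu_rows.tsv", manifest,
                )
                _write(
                    pd.DataFrame({
                        "axis": [f"Axis{i+1}" for i in range(len(coa.eigenvalues))],
                        "eigenvalue": coa.eigenvalues,
                        "fraction": coa.axis_fractions,
                        "total_inertia": coa.total_inertia,
                    }),
                    out / "coa_rscu_inertia.tsv", manifest,
                )
        except Exception as exc:
            errors["codon_usage"] = str(exc)

        try:
            concat = {
                g.id: "".join(g.pcg_sequences().values())
                for g in genomes if g.pcg_sequences()
            }
            lengths = {len(s) for s in concat.values()}
            if len(concat) >= 2 and len(lengths) == 1:
                dist = saturation.all_pairwise(concat, manifest.strata)
                _write(dist, out / "saturation_distances.tsv", manifest)
                _write(
                    saturation.saturation_report(dist),
                    out / "saturation_fits.tsv", manifest,
                )
                results["saturation"] = dist
            else:
                log.info("stage=saturation skipped: unaligned PCG lengths")
        except Exception as exc:
            errors["saturation"] = str(exc)

    if manifest.alignment_fasta and tree is not None:
        try:
            aln = selection.CodonAlignment.from_fasta(manifest.alignment_fasta)
            res = selection.slac_site_test(
                aln, tree, alpha=manifest.alpha, seed=manifest.seed
            )
            _write(res.to_frame(), out / "selection_sites.tsv", manifest)
            results["selection"] = res
            log.info(
                "stage=selection sites=%d dnds=%s", aln.n_sites, res.global_dnds
            )
        except Exception as exc:
            errors["selection"] = str(exc)
    elif manifest.alignment_fasta:
        log.info("stage=selection skipped: no tree given")

    if len(orders) >= 2:
        try:
            catalog = rearrangement.classify_types(orders)
            _write(catalog.to_frame(), out / "rearrangement_types.tsv", manifest)
            _write(write_gene_order_table(orders), out / "gene_orders.tsv", manifest)
            results["rearrangement"] = catalog
            if tree is not None:
                tips = {l.taxon.label for l in tree.leaf_node_iter()}
                if all(m in tips for t in catalog.types for m in t.members):
                    _write(
                        rearrangement.map_types_on_tree(catalog, tree, orders),
                        out / "clade_markers.tsv", manifest,
                    )
        except Exception as exc:
            errors["rearrangement"] = str(exc)
    else:
        log.info("stage=rearrangement skipped: fewer than 2 gene orders")

    for stage, message in errors.items():
        log.error("stage=%s failed: %s", stage, message)
    results["errors"] = errors
    manifest.save(out / "manifest.json")
    return results
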