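"""Reading, validation and nomenclature normalization for annotated mitogenomes.

GenBank flat files are read and written through Biopython; internally all
coordinates are 0-based half-open (GenBank's 1-based inclusive convention is
converted on the way in and restored on the way out).  Gene labels from
heterogeneous annotation practice (``ND2``, ``cytochrome c oxidase subunit I``,
``tRNA-Leu (TAA)`` ...) are mapped onto a single canonical vocabulary so gene
orders from different submitters are comparable.
"""

from __future__ import annotations

import io
import re
from dataclasses import dataclass, field

import dendropy
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqFeature import FeatureLocation, SeqFeature
from Bio.SeqRecord import SeqRecord

from .genes import (
    _CR_SYNONYMS,
    _PCG_SYNONYMS,
    _RRNA_SYNONYMS,
    _TRNA_BY_AA,
    AMINO_ACID_THREE_TO_ONE,
    CANONICAL_GENES,
    CONTROL_REGION,
    LEU_SER_ANTICODONS,
    gene_category,
)


class UnknownGeneError(ValueError):
    """An annotation label could not be mapped to a canonical gene id."""


class GenBankParseError(ValueError):
    """The record text is not a parseable GenBank flat file."""


@dataclass(frozen=True)
class GeneFeature:
    """One located gene on a mitogenome.

    Coordinates are 0-based half-open on the stored (majority) strand;
    strand +1 is the majority strand, -1 the minority strand.
    """

    name: str
    category: str
    start: int
    end: int
    strand: int

    def __post_init__(self):
        if self.name != CONTROL_REGION and self.name not in CANONICAL_GENES:
            raise ValueError(f"non-canonical gene name: {self.name!r}")
        if gene_category(self.name) != self.category:
            raise ValueError(
                f"category {self.category!r} inconsistent with name {self.name!r}"
            )
        if not 0 <= self.start < self.end:
            raise ValueError(f"bad coordinates {self.start}..{self.end}")
        if self.strand not in (+1, -1):
            raise ValueError(f"strand must be +1/-1, got {self.strand}")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class MitoGenome:
    """An annotated (usually circular) mitochondrial genome."""

    id: str
    sequence: str
    features: list[GeneFeature]
    circular: bool = True
    warnings: list[str] = field(default_factory=list)

    def __post_init__(self):
        seen: set[str] = set()
        for f in self.features:
            if f.name == CONTROL_REGION:
                continue
            if f.name in seen:
                raise ValueError(f"{self.id}: duplicate gene {f.name}")
            seen.add(f.name)
            if f.end > len(self.sequence):
                raise ValueError(
                    f"{self.id}: feature {f.name} end {f.end} beyond "
                    f"sequence length {len(self.sequence)}"
                )

    @property
    def gene_names(self) -> set[str]:
        return {f.name for f in self.features if f.name != CONTROL_REGION}

    @property
    def missing_genes(self) -> set[str]:
        return set(CANONICAL_GENES) - self.gene_names

    @property
    def is_complete(self) -> bool:
        return not self.missing_genes

    def feature_sequence(self, feature: GeneFeature) -> str:
        """Nucleotide sequence of a feature in coding orientation."""
        sub = self.sequence[feature.start:feature.end]
        if feature.strand == -1:
            sub = str(Seq(sub).reverse_complement())
        return sub

    def gene_sequence(self, name: str) -> str:
        for f in self.features:
            if f.name == name:
                return self.feature_sequence(f)
        raise KeyError(f"{self.id}: gene {name} not annotated")

    def pcg_sequences(self) -> dict[str, str]:
        """Coding-orientation sequences of all annotated protein-coding genes."""
        return {
            f.name: self.feature_sequence(f)
            for f in sorted(self.features, key=lambda f: f.start)
            if f.category == "PCG"
        }


@dataclass(frozen=True)
class GeneOrder:
    """Signed (circular) permutation of canonical gene names for one genome."""

    genome_id: str
    elements: tuple[tuple[str, int], ...]
    circular: bool = True

    def __post_init__(self):
        names = [g for g, _ in self.elements]
        if len(names) != len(set(names)):
            raise ValueError(f"{self.genome_id}: repeated gene in order")
        if len(names) > 37:
            raise ValueError(f"{self.genome_id}: more than 37 genes")

    @property
    def genes(self) -> set[str]:
        return {g for g, _ in self.elements}

    @property
    def is_partial(self) -> bool:
        return len(self.elements) < 37

    def restricted_to(self, genes: set[str]) -> "GeneOrder":
        return GeneOrder(
            self.genome_id,
            tuple(e for e in self.elements if e[0] in genes),
            self.circular,
        )


# --- nomenclature ------------------------------------------------------------

_SQUASH_RE = re.compile(r"[^A-Z0-9]")
# "tRNA-Leu", "tRNA Ser2" (separator required so "trnA" stays Ala)
_TRNA_LONG_RE = re.compile(r"^T?RNA[-_ ]+([A-Z]{3}|[A-Z])[-_ ]?([12])?$")
# "trnL1", "trnW", "trnL" (anticodon stripped beforehand)
_TRNA_SHORT_RE = re.compile(r"^TRN[-_ ]?([A-Z])([12])?$")
_ANTICODON_RE = re.compile(r"\(([ACGTU]{3})\)", re.IGNORECASE)


def normalize_gene_name(raw: str, anticodon: str | None = None) -> str:
    """Map an annotation label to a canonical gene id.

    ``anticodon`` (if given, e.g. from an /anticodon qualifier) disambiguates
    the duplicated Leu and Ser tRNAs; a parenthesized triplet inside the label
    is used otherwise, and a trailing 1/2 on the isotype letter as a last
    resort.  Raises :class:`UnknownGeneError` for unmappable labels.
    """
    if not raw or not raw.strip():
        raise UnknownGeneError("empty annotation label")
    label = raw.strip()
    upper = label.upper()

    m = _ANTICODON_RE.search(label)
    if anticodon is None and m:
        anticodon = m.group(1)
    if anticodon is not None:
        anticodon = anticodon.upper().replace("U", "T")

    core = upper.split("(")[0].strip().rstrip("-_ ")
    tm = _TRNA_LONG_RE.match(core) or _TRNA_SHORT_RE.match(core)
    if tm:
        spec, suffix = tm.group(1), tm.group(2) or ""
        if len(spec) == 3:
            three_letter = {k.upper(): v for k, v in AMINO_ACID_THREE_TO_ONE.items()}
            if spec not in three_letter:
                raise UnknownGeneError(f"{raw!r}: unknown amino acid {spec!r}")
            aa = three_letter[spec]
        else:
            aa = spec
        if aa in _TRNA_BY_AA:
            return _TRNA_BY_AA[aa]
        if aa in "LS":
            if anticodon and anticodon in LEU_SER_ANTICODONS:
                iso = LEU_SER_ANTICODONS[anticodon]
                if iso[3] == aa:
                    return iso
                raise UnknownGeneError(
                    f"{raw!r}: anticodon {anticodon} contradicts isotype {aa}"
                )
            if suffix in ("1", "2"):
                return f"trn{aa}{suffix}"
            raise UnknownGeneError(
                f"{raw!r}: tRNA-{aa} needs an anticodon or 1/2 suffix"
            )
        raise UnknownGeneError(f"{raw!r}: unrecognized tRNA isotype {spec!r}")

    squashed = _SQUASH_RE.sub("", upper)
    for table in (_PCG_SYNONYMS, _RRNA_SYNONYMS, _CR_SYNONYMS):
        if squashed in table:
            return table[squashed]
    raise UnknownGeneError(f"cannot map annotation label {raw!r}")


# --- GenBank I/O -------------------------------------------------------------

_FEATURE_TYPES = {"CDS": "PCG", "tRNA": "tRNA", "rRNA": "rRNA"}


def parse_mitogenome(record_text: str) -> MitoGenome:
    """Parse one GenBank flat-file record into a :class:`MitoGenome`.

    CDS/tRNA/rRNA features are mapped to canonical gene ids; a feature whose
    label cannot be mapped is skipped with a recorded warning, not an error.
    D-loop/misc features labelled as control region are kept as such.
    """
    try:
        record = SeqIO.read(io.StringIO(record_text), "genbank")
    except Exception as exc:  # Biopython raises bare ValueError subclasses
        raise GenBankParseError(f"unparseable GenBank record: {exc}") from exc
    if len(record.seq) == 0:
        raise GenBankParseError(f"{record.id}: record has no sequence block")

    circular = record.annotations.get("topology", "circular") == "circular"
    features: list[GeneFeature] = []
    warnings: list[str] = []
    for feat in record.features:
        if feat.type in ("D-loop", "misc_feature"):
            label = " ".join(feat.qualifiers.get("note", [""]))
            try:
                if normalize_gene_name(label) == CONTROL_REGION:
                    features.append(
                        GeneFeature(
                            CONTROL_REGION, "control_region",
                            int(feat.location.start), int(feat.location.end),
                            +1 if (feat.location.strand or 1) >= 0 else -1,
                        )
                    )
            except UnknownGeneError:
                pass
            continue
        if feat.type not in _FEATURE_TYPES:
            continue
        anticodon = None
        for q in feat.qualifiers.get("anticodon", []):
            am = re.search(r"seq\s*:\s*([acgtu]{3})", q, re.IGNORECASE)
            am = am or re.fullmatch(r"\s*([ACGTUacgtu]{3})\s*", q)
            if am:
                anticodon = am.group(1)
        name = None
        last_err = None
        for key in ("gene", "product", "note"):
            for label in feat.qualifiers.get(key, []):
                try:
                    name = normalize_gene_name(label, anticodon=anticodon)
                    break
                except UnknownGeneError as exc:
                    last_err = exc
            if name:
                break
        if name is None:
            warnings.append(
                f"skipped {feat.type} at {feat.location}: {last_err or 'no label'}"
            )
            continue
        start, end = int(feat.location.start), int(feat.location.end)
        strand = +1 if (feat.location.strand or 1) >= 0 else -1
        features.append(GeneFeature(name, gene_category(name), start, end, strand))

    genome = MitoGenome(
        id=record.name or record.id,
        sequence=str(record.seq).upper(),
        features=features,
        circular=circular,
        warnings=warnings,
    )
    for missing in sorted(genome.missing_genes):
        genome.warnings.append(f"gene {missing} not annotated")
    return genome


def write_genbank(genome: MitoGenome) -> str:
    """Render a MitoGenome back to GenBank flat-file text (round-trip safe)."""
    record = SeqRecord(
        Seq(genome.sequence),
        id=genome.id,
        name=genome.id[:16].replace(" ", "_"),
        description=f"{genome.id} mitochondrial genome",
        annotations={
            "molecule_type": "DNA",
            "topology": "circular" if genome.circular else "linear",
        },
    )
    type_of = {"PCG": "CDS", "tRNA": "tRNA", "rRNA": "rRNA",
               "control_region": "misc_feature"}
    for f in sorted(genome.features, key=lambda f: f.start):
        qualifiers = {"gene": [f.name]}
        if f.name == CONTROL_REGION:
            qualifiers = {"note": ["control region"]}
        record.features.append(
            SeqFeature(
                FeatureLocation(f.start, f.end, strand=f.strand),
                type=type_of[f.category],
                qualifiers=qualifiers,
            )
        )
    out = io.StringIO()
    SeqIO.write(record, out, "genbank")
    return out.getvalue()


# --- gene order --------------------------------------------------------------

def extract_gene_order(genome: MitoGenome) -> GeneOrder:
    """Gene order by start coordinate; control region excluded."""
    feats = [f for f in genome.features if f.name != CONTROL_REGION]
    if len(feats) < 2:
        raise ValueError(f"{genome.id}: need at least 2 named features")
    feats.sort(key=lambda f: f.start)
    return GeneOrder(
        genome_id=genome.id,
        elements=tuple((f.name, f.strand) for f in feats),
        circular=genome.circular,
    )


def read_gene_order_table(path_or_buf) -> list[GeneOrder]:
    """Read gene orders from TSV (genome_id, position, gene, strand)."""
    df = pd.read_csv(path_or_buf, sep="\t")
    required = {"genome_id", "position", "gene", "strand"}
    if not required <= set(df.columns):
        raise ValueError(f"gene-order table needs columns {sorted(required)}")
    orders = []
    for gid, grp in df.groupby("genome_id", sort=False):
        grp = grp.sort_values("position")
        orders.append(
            GeneOrder(str(gid), tuple(zip(grp["gene"], grp["strand"].astype(int))))
        )
    return orders


def write_gene_order_table(orders: list[GeneOrder]) -> pd.DataFrame:
    rows = [
        {"genome_id": o.genome_id, "position": i, "gene": g, "strand": s}
        for o in orders
        for i, (g, s) in enumerate(o.elements)
    ]
    return pd.DataFrame(rows, columns=["genome_id", "position", "gene", "strand"])


def read_tree(source: str, schema: str = "newick") -> dendropy.Tree:
    """Load a phylogeny from Newick text or a file path."""
    if "(" in source:
        return dendropy.Tree.get(data=source, schema=schema)
    return dendropy.Tree.get(path=source, schema=schema)
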