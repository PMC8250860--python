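"""Readers and writers for the formats the pipeline touches.

Genomes arrive as annotation (GFF3, CDS features with ID attributes) plus
protein FASTA keyed by the same IDs — the layout produced by common
prokaryotic annotation pipelines. Coordinates follow GFF3: 1-based,
inclusive on both ends. Protein sequences are always taken from the
companion FASTA, never re-translated; embedded ``##FASTA`` nucleotide
blocks are skipped.
"""

from __future__ import annotations

import csv
import urllib.parse
from dataclasses import dataclass, field

from Bio import SeqIO

TRAIT_LABELS = ("stalk", "dread", "amorphous")
#: The trait screen is always binary: stalk vs everything else.
POSITIVE_LABEL = "stalk"


class GenomeParseError(ValueError):
    """Malformed or inconsistent genome input."""


@dataclass(frozen=True)
class GeneRecord:
    """One annotated CDS with coordinates and its protein sequence."""

    gene_id: str
    genome_id: str
    contig_id: str
    start: int
    end: int
    strand: str
    locus_rank: int
    protein_seq: str
    product: str = "hypothetical protein"

    def __post_init__(self):
        if self.start < 1 or self.end < self.start:
            raise GenomeParseError(
                f"{self.gene_id}: bad coordinates {self.start}..{self.end}"
            )
        if self.strand not in ("+", "-"):
            raise GenomeParseError(f"{self.gene_id}: bad strand {self.strand!r}")
        if not self.protein_seq:
            raise GenomeParseError(f"{self.gene_id}: empty protein sequence")
        if self.locus_rank < 0:
            raise GenomeParseError(f"{self.gene_id}: negative locus_rank")

    def __len__(self) -> int:
        return len(self.protein_seq)


@dataclass
class Genome:
    """An ordered collection of genes over one or more contigs."""

    genome_id: str
    genes: list[GeneRecord]
    n_contigs: int = 0

    def __post_init__(self):
        contigs = []
        for g in self.genes:
            if g.genome_id != self.genome_id:
                raise GenomeParseError(
                    f"gene {g.gene_id} carries genome_id {g.genome_id!r}, "
                    f"expected {self.genome_id!r}"
                )
            if g.contig_id not in contigs:
                contigs.append(g.contig_id)
        if not self.n_contigs:
            self.n_contigs = max(len(contigs), 1)
        ids = [g.gene_id for g in self.genes]
        if len(set(ids)) != len(ids):
            dupe = next(i for i in ids if ids.count(i) > 1)
            raise GenomeParseError(f"duplicate gene_id {dupe!r} in {self.genome_id}")

    def __iter__(self):
        return iter(self.genes)

    def __len__(self) -> int:
        return len(self.genes)

    def by_contig(self) -> dict[str, list[GeneRecord]]:
        out: dict[str, list[GeneRecord]] = {}
        for g in self.genes:
            out.setdefault(g.contig_id, []).append(g)
        return out

    def gene_index(self) -> dict[str, GeneRecord]:
        return {g.gene_id: g for g in self.genes}


def _parse_attributes(raw: str) -> dict[str, str]:
    out = {}
    for part in raw.strip().split(";"):
        if not part:
            continue
        key, _, val = part.partition("=")
        out[key.strip()] = urllib.parse.unquote(val.strip())
    return out


def load_genome(gff_path, faa_path, genome_id: str) -> Genome:
    """Load a GFF3 + protein-FASTA pair into a :class:`Genome`.

    CDS features are cross-referenced to FASTA records by their ``ID``
    attribute; a CDS whose protein is missing from the FASTA is an error
    naming the offending ID. ``locus_rank`` is assigned per contig in
    coordinate order.
    """
    proteins = {rec.id: str(rec.seq) for rec in SeqIO.parse(str(faa_path), "fasta")}

    raw: list[tuple[str, int, int, str, str, str]] = []
    with open(gff_path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if line.startswith("##FASTA"):
                break
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise GenomeParseError(f"{gff_path}:{lineno}: expected 9 columns")
            if fields[2] != "CDS":
                continue
            try:
                start, end = int(fields[3]), int(fields[4])
            except ValueError:
                raise GenomeParseError(
                    f"{gff_path}:{lineno}: non-integer coordinates"
                ) from None
            if end < start:
                raise GenomeParseError(
                    f"{gff_path}:{lineno}: end < start ({end} < {start})"
                )
            attrs = _parse_attributes(fields[8])
            if "ID" not in attrs:
                raise GenomeParseError(f"{gff_path}:{lineno}: CDS without ID attribute")
            raw.append((fields[0], start, end, fields[6],
                        attrs["ID"], attrs.get("product", "hypothetical protein")))

    genes: list[GeneRecord] = []
    contig_order = []
    for contig in [c for c, *_ in raw]:
        if contig not in contig_order:
            contig_order.append(contig)
    for contig in contig_order:
        on_contig = sorted((r for r in raw if r[0] == contig), key=lambda r: (r[1], r[2]))
        for rank, (ctg, start, end, strand, gid, product) in enumerate(on_contig):
            if gid not in proteins:
                raise GenomeParseError(
                    f"CDS {gid!r} in {gff_path} has no protein in {faa_path}"
                )
            genes.append(GeneRecord(
                gene_id=gid, genome_id=genome_id, contig_id=ctg,
                start=start, end=end, strand=strand, locus_rank=rank,
                protein_seq=proteins[gid], product=product,
            ))
    return Genome(genome_id=genome_id, genes=genes)


def write_genome(genome: Genome, gff_path, faa_path) -> None:
    """Write a Genome back out as a GFF3 + protein FASTA pair."""
    with open(gff_path, "w") as gff:
        gff.write("##gff-version 3\n")
        for g in genome.genes:
            product = urllib.parse.quote(g.product, safe=" .,:_-/()'")
            gff.write(
                f"{g.contig_id}\tstalkscan\tCDS\t{g.start}\t{g.end}\t.\t{g.strand}\t0\t"
                f"ID={g.gene_id};product={product}\n"
            )
    with open(faa_path, "w") as faa:
        for g in genome.genes:
            faa.write(f">{g.gene_id} {g.product}\n")
            for i in range(0, len(g.protein_seq), 60):
                faa.write(g.protein_seq[i:i + 60] + "\n")


@dataclass
class TraitTable:
    """Genome -> trait label map with the derived binary grouping."""

    assignments: dict[str, str]
    positives: set[str] = field(init=False)
    negatives: set[str] = field(init=False)

    def __post_init__(self):
        for gid, label in self.assignments.items():
            if label not in TRAIT_LABELS:
                raise ValueError(
                    f"unknown trait label {label!r} for {gid!r}; "
                    f"allowed: {', '.join(TRAIT_LABELS)}"
                )
        self.positives = {g for g, t in self.assignments.items() if t == POSITIVE_LABEL}
        self.negatives = set(self.assignments) - self.positives


def read_trait_table(path) -> TraitTable:
    """Read a two-column TSV (genome_id <TAB> trait)."""
    assignments: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ValueError(f"{path}:{lineno}: expected genome_id<TAB>trait")
            gid, trait = parts
            if gid == "genome_id":  # optional header
                continue
            if gid in assignments:
                raise ValueError(f"{path}:{lineno}: duplicate genome_id {gid!r}")
            assignments[gid] = trait
    if not assignments:
        raise ValueError(f"{path}: empty trait table")
    return TraitTable(assignments)


def write_trait_table(table: TraitTable, path) -> None:
    with open(path, "w") as fh:
        fh.write("genome_id\ttrait\n")
        for gid in sorted(table.assignments):
            fh.write(f"{gid}\t{table.assignments[gid]}\n")


def read_cog_table(path) -> dict[str, str]:
    """Read gene_id -> COG category letters (possibly several, e.g. 'KT')."""
    out: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ValueError(f"{path}:{lineno}: expected gene_id<TAB>categories")
            if parts[0] == "gene_id":
                continue
            out[parts[0]] = parts[1]
    return out


def write_presence_absence(pan, path) -> None:
    """Presence/absence CSV: family_id, n_genomes, n_genes, one column per genome.

    Paralogous members within one genome are semicolon-joined; absent cells
    are empty.
    """
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["family_id", "n_genomes", "n_genes"] + list(pan.genomes))
        for fam in pan.families:
            row = [fam.family_id, fam.n_genomes(), fam.n_genes()]
            for gid in pan.genomes:
                row.append(";".join(fam.members.get(gid, [])))
            writer.writerow(row)


def read_presence_absence(path) -> tuple[list[str], dict[str, dict[str, list[str]]]]:
    """Reload a presence/absence CSV: (genome order, family -> members)."""
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        header = next(reader)
        genomes = header[3:]
        fams: dict[str, dict[str, list[str]]] = {}
        for row in reader:
            members = {}
            for gid, cell in zip(genomes, row[3:]):
                if cell:
                    members[gid] = cell.split(";")
            fams[row[0]] = members
    return genomes, fams


def newick_string(tree) -> str:
    """Render a dendrogram (see :mod:`stalkscan.aai`) as Newick.

    Branch lengths are height differences between a node and its parent;
    leaf names containing whitespace or Newick punctuation are quoted.
    """

    def needs_quote(name: str) -> bool:
        return any(c in name for c in " \t()[]:;,'")

    def fmt_name(name: str) -> str:
        if needs_quote(name):
            return "'" + name.replace("'", "''") + "'"
        return name

    def render(node, parent_height: float) -> str:
        length = parent_height - node.height
        if node.is_leaf():
            return f"{fmt_name(node.name)}:{length:.6g}"
        inner = ",".join(render(c, node.height) for c in node.children)
        return f"({inner}):{length:.6g}"

    root = tree
    if root.is_leaf():
        return f"{fmt_name(root.name)}:0;"
    inner = ",".join(render(c, root.height) for c in root.children)
    return f"({inner});"


def write_newick(tree, path) -> None:
    with open(path, "w") as fh:
        fh.write(newick_string(tree) + "\n")
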