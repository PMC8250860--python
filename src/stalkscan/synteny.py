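"""Cassette detection and cross-genome gene-order conservation.

A cassette is a maximal run of genes of interest along one contig where at
most ``max_gap`` non-member genes intervene between consecutive members.
Shared synteny holds when every genome's family-order signature equals a
reference signature or its reversal (clusters are compared
strand-normalized; per-gene strand is reported but not part of the
signature). Genomes whose members fall into several cassettes are reported
as fragmented rather than failed.
"""

from __future__ import annotations

from dataclasses import dataclass

from .genome_io import GeneRecord, Genome


@dataclass
class Cassette:
    genome_id: str
    contig_id: str
    gene_ids: list[str]
    locus_ranks: list[int]
    family_ids: list[str]
    max_gap: int

    def __len__(self) -> int:
        return len(self.gene_ids)

    def signature(self) -> tuple[str, ...]:
        return tuple(self.family_ids)


def find_cassettes(
    gene_ids: set[str],
    genome: Genome,
    max_gap: int = 1,
    family_of: dict[str, str] | None = None,
) -> list[Cassette]:
    """Maximal member runs per contig with <= max_gap intervening genes."""
    unknown = gene_ids - {g.gene_id for g in genome.genes}
    if unknown:
        raise ValueError(
            f"gene ids not in genome {genome.genome_id}: {', '.join(sorted(unknown))}"
        )
    family_of = family_of or {}
    out: list[Cassette] = []
    for contig_id, genes in genome.by_contig().items():
        members = [g for g in genes if g.gene_id in gene_ids]
        if not members:
            continue
        members.sort(key=lambda g: g.locus_rank)
        run: list[GeneRecord] = [members[0]]
        for g in members[1:]:
            if g.locus_rank - run[-1].locus_rank <= max_gap + 1:
                run.append(g)
            else:
                out.append(_cassette(genome.genome_id, contig_id, run,
                                     max_gap, family_of))
                run = [g]
        out.append(_cassette(genome.genome_id, contig_id, run, max_gap, family_of))
    return out


def _cassette(genome_id, contig_id, run, max_gap, family_of) -> Cassette:
    return Cassette(
        genome_id=genome_id, contig_id=contig_id,
        gene_ids=[g.gene_id for g in run],
        locus_ranks=[g.locus_rank for g in run],
        family_ids=[family_of.get(g.gene_id, "?") for g in run],
        max_gap=max_gap,
    )


@dataclass
class SyntenyReport:
    """Order-conservation verdict over one cassette per genome."""

    reference: tuple[str, ...]
    signatures: dict[str, tuple[str, ...]]
    orientation: dict[str, str]            # forward / reverse / divergent
    fragmented: list[str]                  # genomes with >1 cassette
    is_shared: bool


def shared_synteny(cassettes: dict[str, list[Cassette]]) -> SyntenyReport:
    """Compare family-order signatures across genomes, up to full reversal.

    The reference is the signature of the lexicographically first genome
    carrying exactly one cassette. ``is_shared`` requires every
    single-cassette genome to match the reference forward or reversed;
    fragmented genomes are listed separately and do not veto sharing.
    """
    singles = {g: cs[0] for g, cs in cassettes.items() if len(cs) == 1}
    fragmented = sorted(g for g, cs in cassettes.items() if len(cs) > 1)
    if not singles:
        return SyntenyReport(reference=(), signatures={}, orientation={},
                             fragmented=fragmented, is_shared=False)
    ref_genome = min(singles)
    reference = singles[ref_genome].signature()
    signatures: dict[str, tuple[str, ...]] = {}
    orientation: dict[str, str] = {}
    shared = True
    for g, cas in sorted(singles.items()):
        sig = cas.signature()
        signatures[g] = sig
        if sig == reference:
            orientation[g] = "forward"
        elif sig == tuple(reversed(reference)):
            orientation[g] = "reverse"
        else:
            orientation[g] = "divergent"
            shared = False
    return SyntenyReport(reference=reference, signatures=signatures,
                         orientation=orientation, fragmented=fragmented,
                         is_shared=shared)


def neighborhood(
    genome: Genome, cassette: Cassette, k: int = 5
) -> tuple[list[GeneRecord], list[GeneRecord]]:
    """Up to k flanking genes on each side of a cassette, in locus order."""
    contig_genes = sorted(
        (g for g in genome.genes if g.contig_id == cassette.contig_id),
        key=lambda g: g.locus_rank,
    )
    lo = min(cassette.locus_ranks)
    hi = max(cassette.locus_ranks)
    upstream = [g for g in contig_genes if lo - k <= g.locus_rank < lo]
    downstream = [g for g in contig_genes if hi < g.locus_rank <= hi + k]
    return upstream, downstream


def write_synteny_report(
    report: SyntenyReport, cassettes: dict[str, list[Cassette]], path
) -> None:
    """TSV stand-in for a synteny plot: one row per genome and cassette."""
    with open(path, "w") as fh:
        fh.write("genome_id\tcontig_id\tfamily_order\torientation\tfragmented\t"
                 "gene_ids\n")
        for g in sorted(cassettes):
            frag = "true" if g in report.fragmented else "false"
            for cas in cassettes[g]:
                fh.write("\t".join([
                    g, cas.contig_id, "|".join(cas.family_ids),
                    report.orientation.get(g, ""), frag,
                    ";".join(cas.gene_ids),
                ]) + "\n")
        fh.write(f"#is_shared\t{str(report.is_shared).lower()}\n")
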