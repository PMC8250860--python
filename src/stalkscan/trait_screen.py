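"""The core inference: gene families unique to the trait-positive group.

A family is trait-unique at a given clustering threshold when it has at
least one member in every trait-positive genome and no member in any
trait-negative genome. Absence means zero members at that threshold — no
secondary sensitive re-search; :func:`distant_homolog_search` exists
precisely to recover sub-threshold homologs afterwards.

The coverage filter flags families containing short members (e.g. a gene
split across contigs) instead of deleting them.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .align import ScoringScheme, align_pair, blosum62
from .genome_io import Genome, TraitTable
from .pangenome import PanConfig, PanGenome, build_pangenomes_sweep


@dataclass
class TraitUniqueSet:
    """Trait-unique families at one threshold, with coverage flags."""

    threshold: float
    family_ids: list[str]
    gene_count: int
    coverage_pass: dict[str, bool] = field(default_factory=dict)

    def flagged(self) -> list[str]:
        return [f for f, ok in self.coverage_pass.items() if not ok]


@dataclass(frozen=True)
class HomologHit:
    family_id: str
    genome_id: str
    gene_id: str
    pid: float
    coverage: float


def screen_matrix(
    pan: PanGenome, positives: set[str], negatives: set[str]
) -> list[str]:
    """Families present in every positive genome and absent from all negatives."""
    presence = pan.matrix > 0
    pos = [g for g in pan.genomes if g in positives]
    neg = [g for g in pan.genomes if g in negatives]
    mask = presence.loc[pos].all(axis=0) & ~presence.loc[neg].any(axis=0)
    return sorted(mask.index[mask])


def trait_unique_families(pan: PanGenome, traits: TraitTable) -> TraitUniqueSet:
    """Extract families shared by all positives and absent in all negatives."""
    missing = [g for g in pan.genomes if g not in traits.assignments]
    if missing:
        raise ValueError(f"genomes missing from trait table: {', '.join(missing)}")
    fams = screen_matrix(pan, traits.positives, traits.negatives)
    # hard invariant: no selected family touches a negative genome
    for fid in fams:
        members = pan.family_by_id(fid).members
        assert not (set(members) & traits.negatives), \
            f"family {fid} unexpectedly has members in a negative genome"
    gene_count = sum(pan.family_by_id(f).n_genes() for f in fams)
    return TraitUniqueSet(threshold=pan.threshold, family_ids=fams,
                          gene_count=gene_count)


def coverage_filter(
    tus: TraitUniqueSet, pan: PanGenome, min_cov: float = 70.0,
    scheme: ScoringScheme | None = None,
) -> TraitUniqueSet:
    """Flag families whose members do not mutually cover the longest member.

    A family passes when every member aligned to the family's longest
    member reaches ``min_cov`` mutual coverage. Failures are flagged, not
    dropped.
    """
    scheme = scheme or blosum62()
    flags: dict[str, bool] = {}
    for fid in tus.family_ids:
        fam = pan.family_by_id(fid)
        ref = pan.gene_records[fam.representative].protein_seq
        ok = True
        for gid in fam.all_gene_ids():
            if gid == fam.representative:
                continue
            st = align_pair(pan.gene_records[gid].protein_seq, ref, scheme)
            if st.query_cov < min_cov or st.subject_cov < min_cov:
                ok = False
                break
        flags[fid] = ok
    return TraitUniqueSet(threshold=tus.threshold, family_ids=list(tus.family_ids),
                          gene_count=tus.gene_count, coverage_pass=flags)


def distant_homolog_search(
    tus: TraitUniqueSet,
    pan: PanGenome,
    outgroups: list[Genome],
    floor_pid: float = 20.0,
    ceiling_pid: float = 40.0,
    min_cov: float = 50.0,
    scheme: ScoringScheme | None = None,
) -> list[HomologHit]:
    """Best sub-threshold homolog of each trait-unique family per outgroup.

    Reports one hit per (family, outgroup genome): the best-identity gene
    with ``floor_pid <= pid < ceiling_pid`` and mutual coverage >= min_cov.
    """
    scheme = scheme or blosum62()
    hits: list[HomologHit] = []
    for fid in tus.family_ids:
        fam = pan.family_by_id(fid)
        ref = pan.gene_records[fam.representative].protein_seq
        for genome in outgroups:
            best: HomologHit | None = None
            for gene in genome.genes:
                st = align_pair(ref, gene.protein_seq, scheme)
                cov = min(st.query_cov, st.subject_cov)
                if not (floor_pid <= st.pid < ceiling_pid) or cov < min_cov:
                    continue
                if best is None or st.pid > best.pid or (
                    st.pid == best.pid and gene.gene_id < best.gene_id
                ):
                    best = HomologHit(family_id=fid, genome_id=genome.genome_id,
                                      gene_id=gene.gene_id, pid=st.pid, coverage=cov)
            if best is not None:
                hits.append(best)
    return hits


@dataclass
class SweepResult:
    """Per-threshold screens plus the deduplicated union over a range."""

    sets: dict[float, TraitUniqueSet]
    pans: dict[float, PanGenome]
    union_range: tuple[float, float]
    union_gene_ids: list[str]
    union_family_count: int

    @property
    def union_gene_count(self) -> int:
        return len(self.union_gene_ids)


def threshold_sweep(
    genomes: list[Genome],
    traits: TraitTable,
    thresholds: list[float],
    config: PanConfig | None = None,
    scheme: ScoringScheme | None = None,
    union_range: tuple[float, float] = (30.0, 80.0),
    min_cov: float = 70.0,
) -> SweepResult:
    """One pan-genome + trait screen per threshold, with a union report.

    The union deduplicates member *genes* across thresholds inside
    ``union_range`` (inclusive); the family count is the number of
    distinct member-gene sets contributing.
    """
    pans = build_pangenomes_sweep(genomes, list(thresholds), config, scheme)
    sets: dict[float, TraitUniqueSet] = {}
    union_genes: set[str] = set()
    union_fams: set[frozenset] = set()
    for t in thresholds:
        tus = trait_unique_families(pans[t], traits)
        tus = coverage_filter(tus, pans[t], min_cov, scheme)
        sets[t] = tus
        if union_range[0] <= t <= union_range[1]:
            for fid in tus.family_ids:
                genes = frozenset(pans[t].family_by_id(fid).all_gene_ids())
                union_fams.add(genes)
                union_genes |= genes
    return SweepResult(
        sets=sets, pans=pans, union_range=union_range,
        union_gene_ids=sorted(union_genes), union_family_count=len(union_fams),
    )


def write_trait_report(tus: TraitUniqueSet, pan: PanGenome, path) -> None:
    """TSV: family_id, n_genes, coverage flag, per-genome member gene ids."""
    with open(path, "w") as fh:
        fh.write("family_id\tn_genes\tcoverage_pass\t"
                 + "\t".join(pan.genomes) + "\n")
        for fid in tus.family_ids:
            fam = pan.family_by_id(fid)
            flag = tus.coverage_pass.get(fid)
            cells = [";".join(fam.members.get(g, [])) for g in pan.genomes]
            fh.write(f"{fid}\t{fam.n_genes()}\t"
                     f"{'' if flag is None else str(flag).lower()}\t"
                     + "\t".join(cells) + "\n")


def write_union_report(result: SweepResult, path) -> None:
    with open(path, "w") as fh:
        fh.write("# trait-unique union over thresholds "
                 f"{result.union_range[0]:g}-{result.union_range[1]:g}\n")
        fh.write(f"# families: {result.union_family_count}\t"
                 f"genes: {result.union_gene_count}\n")
        fh.write("gene_id\n")
        for gid in result.union_gene_ids:
            fh.write(gid + "\n")
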