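"""Synthetic annotated genome communities with a machine-readable truth ledger.

The generator emits genome sets with the statistical structure the
trait screen assumes: a shared core gene pool, patterned accessory genes,
strain-specific genes, a planted trait-linked syntenic gene cluster at
mid-range conservation with an adjacent conserved neighbor cassette,
near-miss decoy families (present in all trait-positives plus one
negative), optional sub-threshold distant homologs in "dread" negatives,
and an optional split-gene artifact (one cluster gene divided across two
contigs of one positive genome).

Divergence is substitution-only so identity targets are exact and coverage
stays ~100%; the split-gene artifact is the only coverage perturbation.
Family members share conserved 4-residue termini so that free-end-gap
alignment cannot trim the sequence ends and shift realized identities.

Everything is driven by one seed; two runs with the same config produce
byte-identical output files.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field, asdict

import numpy as np

from .align import blosum62
from .genome_io import GeneRecord, Genome, TraitTable, write_genome, write_trait_table

_STANDARD = "ACDEFGHIKLMNPQRSTVWY"
_ANCHOR = 4  # conserved residues kept at each end of family sequences

COG_LETTERS = "JAKLBDYVTMNZWUOCGEFHIPQRS"
ENRICHED_CATEGORY = "M"


@dataclass(frozen=True)
class SynthConfig:
    """Shape of the generated community (defaults at desk-test scale)."""

    n_positive: int = 11
    n_negative: int = 5
    n_dread: int = 2                 # negatives labeled "dread" (rest amorphous)
    n_core: int = 150
    n_accessory: int = 60
    accessory_presence: float = 0.5
    n_unique_per_genome: int = 5
    cluster_size: int = 6
    cluster_identity: tuple[float, float] = (55.0, 75.0)   # pairwise targets
    neighbor_size: int = 5
    n_decoys: int = 3
    core_identity: tuple[float, float] = (55.0, 90.0)
    accessory_identity: tuple[float, float] = (55.0, 90.0)
    dread_mode: bool = False
    distant_identity: tuple[float, float] = (26.0, 36.0)   # pairwise to members
    split_gene: bool = False
    median_len: float = 300.0
    sigma_len: float = 0.35
    min_len: int = 120
    seed: int = 42

    def __post_init__(self):
        for lo, hi in (self.cluster_identity, self.core_identity,
                       self.accessory_identity, self.distant_identity):
            if not (0 < lo <= hi <= 100):
                raise ValueError("identity targets must lie in (0, 100]")
        if min(self.n_positive, self.n_negative, self.n_core) < 0:
            raise ValueError("counts must be >= 0")


@dataclass
class PlantedFamily:
    """Truth-ledger entry for one generated family."""

    label: str
    kind: str                        # core/accessory/unique/cluster/neighbor/decoy
    target_pid: float | None
    members: dict[str, list[str]]    # genome_id -> gene_ids
    realized_pairwise_min: float | None = None
    realized_pairwise_mean: float | None = None

    def presence(self) -> set[str]:
        return set(self.members)


@dataclass
class DistantHomolog:
    family_label: str
    genome_id: str
    gene_id: str
    realized_pid_min: float
    realized_pid_max: float


@dataclass
class SynthTruth:
    """Everything needed to score the pipeline without re-alignment."""

    families: dict[str, PlantedFamily]
    cluster_labels: list[str]
    neighbor_labels: list[str]
    decoy_labels: list[str]
    distant_homologs: list[DistantHomolog]
    cassette_gene_ids: dict[str, list[str]]   # positive genome -> ordered cluster genes
    split_gene: dict | None                   # {genome, family_label, fragment_ids}
    trait: dict[str, str]                     # genome -> label
    enriched_category: str = ENRICHED_CATEGORY
    cog: dict[str, str] = field(default_factory=dict)

    def positives(self) -> set[str]:
        return {g for g, t in self.trait.items() if t == "stalk"}

    def negatives(self) -> set[str]:
        return {g for g, t in self.trait.items() if t != "stalk"}

    def trait_unique_labels(self) -> set[str]:
        """Planted families present in every positive and no negative."""
        pos, neg = self.positives(), self.negatives()
        return {
            lab for lab, fam in self.families.items()
            if pos <= fam.presence() and not (fam.presence() & neg)
        }

    def to_json(self) -> str:
        payload = asdict(self)
        return json.dumps(payload, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "SynthTruth":
        d = json.loads(text)
        d["families"] = {k: PlantedFamily(**v) for k, v in d["families"].items()}
        d["distant_homologs"] = [DistantHomolog(**v) for v in d["distant_homologs"]]
        return cls(**d)


# ---------------------------------------------------------------------------
# sequence-level primitives
# ---------------------------------------------------------------------------

def random_protein(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list(_STANDARD), size=length))


def _draw_length(rng: np.random.Generator, cfg: SynthConfig) -> int:
    n = int(rng.lognormal(mean=np.log(cfg.median_len), sigma=cfg.sigma_len))
    return max(cfg.min_len, n)


def _blosum_weights() -> dict[str, np.ndarray]:
    """Replacement distribution per residue, softmax of BLOSUM62 scores."""
    scheme = blosum62()
    from .align import ALPHABET
    out = {}
    for i, a in enumerate(_STANDARD):
        ai = ALPHABET.index(a)
        w = np.zeros(len(_STANDARD))
        for j, b in enumerate(_STANDARD):
            if b == a:
                continue
            w[j] = np.exp(scheme.matrix[ai, ALPHABET.index(b)] / 2.0)
        out[a] = w / w.sum()
    return out


_WEIGHTS = None


def _replacement(rng: np.random.Generator, residue: str) -> str:
    global _WEIGHTS
    if _WEIGHTS is None:
        _WEIGHTS = _blosum_weights()
    w = _WEIGHTS.get(residue)
    if w is None:  # non-standard letter: replace uniformly
        return rng.choice(list(_STANDARD))
    return _STANDARD[rng.choice(len(_STANDARD), p=w)]


def mutate_to_identity(seq: str, target_pid: float, seed: int) -> tuple[str, float]:
    """Substitution-only divergence to a target ungapped identity.

    Exactly ``round(n * (1 - target/100))`` interior positions are replaced
    by a different residue drawn from a BLOSUM62-favored distribution; the
    4 terminal residues at each end are never touched so that end-trimming
    alignment reproduces the realized identity. Deterministic under seed.
    """
    if not 0 < target_pid <= 100:
        raise ValueError("target_pid must be in (0, 100]")
    n = len(seq)
    m = int(round(n * (1.0 - target_pid / 100.0)))
    if m == 0:
        return seq, 100.0
    interior = np.arange(_ANCHOR, n - _ANCHOR)
    if m > interior.size:
        raise ValueError(
            f"target {target_pid}% needs {m} mutations but only "
            f"{interior.size} interior positions are available"
        )
    rng = np.random.default_rng(seed)
    pos = rng.choice(interior, size=m, replace=False)
    chars = list(seq)
    for p in sorted(pos):
        chars[p] = _replacement(rng, seq[p])
    return "".join(chars), 100.0 * (n - m) / n


def ungapped_identity(a: str, b: str) -> float:
    """Position-wise percent identity of two equal-length sequences."""
    if len(a) != len(b):
        raise ValueError("sequences differ in length")
    same = sum(1 for x, y in zip(a, b) if x == y)
    return 100.0 * same / len(a)


def _block_sites(n: int, c: float, rng: np.random.Generator) -> np.ndarray:
    """Scramble-site layout in blocks, leaving conserved runs >= 8 residues.

    Alternating conserved/scrambled blocks (instead of uniformly scattered
    sites) guarantee that any two family members share many intact 4-mers,
    so the k-mer prescreen can never lose a planted homolog pair. The
    4-residue termini always fall in conserved blocks.
    """
    target = int(round((1.0 - c) * n))
    if target <= 0:
        return np.empty(0, dtype=int)
    sites: list[int] = []
    pos = max(_ANCHOR, 8)  # leading conserved block covers the anchor
    while len(sites) < target and pos < n - _ANCHOR:
        lc = int(rng.integers(8, 15))
        # inflate the scrambled share to offset the conserved end margins
        ratio = (1.0 - c) / max(c, 0.05) * n / max(n - 12, 1)
        ls = max(1, int(round(lc * ratio)))
        ls = min(ls, target - len(sites))
        end = min(pos + ls, n - _ANCHOR)
        sites.extend(range(pos, end))
        pos = end + lc
    return np.asarray(sites, dtype=int)


def diversify_family(
    base: str, k: int, target_pid: float, rng: np.random.Generator
) -> tuple[list[str], np.ndarray]:
    """Derive k member sequences whose pairwise identity is ~target_pid.

    A fixed set of interior sites (laid out in blocks, see
    :func:`_block_sites`) is scrambled independently per member with
    uniform residues; the rest stay at the base residue, so pairwise
    identity concentrates tightly around the target: with conserved
    fraction c, pairwise = c + (1 - c)/20 + O(1/sqrt(n)). Returns
    (members, realized pairwise identity matrix in percent).
    """
    n = len(base)
    c = min(max(target_pid / 100.0, 0.0), 1.0)
    sites = _block_sites(n, c, rng)
    # per site, hand every member a *distinct* non-base residue (possible
    # for k <= 19): scrambled sites then never match between members, so
    # pairwise identity is exactly (n - len(sites)) / n up to rounding
    site_residues = []
    for p in sites:
        choices = [r for r in _STANDARD if r != base[p]]
        perm = rng.permutation(len(choices))
        site_residues.append([choices[i] for i in perm])
    members = []
    for mi in range(k):
        chars = list(base)
        for si, p in enumerate(sites):
            options = site_residues[si]
            chars[p] = options[mi % len(options)]
        members.append("".join(chars))
    realized = np.full((k, k), 100.0)
    for i in range(k):
        for j in range(i + 1, k):
            realized[i, j] = realized[j, i] = ungapped_identity(members[i], members[j])
    return members, realized


def _distant_homolog(
    base: str, scramble_sites: np.ndarray, target_pid: float, rng: np.random.Generator
) -> str:
    """A sequence at ~target pairwise identity to diversify_family members.

    The homolog keeps the base residue at scrambled sites (members carry
    non-base residues there, so these positions never match) and keeps
    only the fraction of conserved sites needed to land pairwise identity
    to every member near the target; broken conserved sites get a non-base
    residue and so never match either. The identity to each member is
    therefore (kept conserved sites) / n, the same for all members.
    """
    n = len(base)
    conserved = np.setdiff1d(np.arange(_ANCHOR, n - _ANCHOR), scramble_sites)
    # the 2 * _ANCHOR terminal residues always match and sit outside `conserved`
    kept_needed = target_pid / 100.0 * n - 2 * _ANCHOR
    keep = min(max(kept_needed / max(conserved.size, 1), 0.0), 1.0)
    n_break = int(round((1.0 - keep) * conserved.size))
    broken = rng.choice(conserved, size=n_break, replace=False)
    chars = list(base)
    for p in broken:
        options = [r for r in _STANDARD if r != base[int(p)]]
        chars[int(p)] = options[int(rng.integers(0, len(options)))]
    return "".join(chars)


# ---------------------------------------------------------------------------
# community assembly
# ---------------------------------------------------------------------------

def _genome_ids(cfg: SynthConfig) -> tuple[list[str], dict[str, str]]:
    pos = [f"S{i + 1:02d}" for i in range(cfg.n_positive)]
    n_dread = min(cfg.n_dread, cfg.n_negative)
    neg = [f"D{i + 1:02d}" for i in range(n_dread)]
    neg += [f"A{i + 1:02d}" for i in range(cfg.n_negative - n_dread)]
    trait = {g: "stalk" for g in pos}
    trait.update({g: "dread" for g in neg if g.startswith("D")})
    trait.update({g: "amorphous" for g in neg if g.startswith("A")})
    return pos + neg, trait


MAX_CONTIG_NT = 20_000_000


def generate_community(cfg: SynthConfig) -> tuple[list[Genome], SynthTruth]:
    """Build the community and its truth ledger. Deterministic under cfg.seed."""
    rng = np.random.default_rng(cfg.seed)
    genome_ids, trait = _genome_ids(cfg)
    positives = [g for g in genome_ids if trait[g] == "stalk"]
    negatives = [g for g in genome_ids if trait[g] != "stalk"]
    dreads = [g for g in negatives if g.startswith("D")]

    families: dict[str, PlantedFamily] = {}
    # per genome: list of (family_label, sequence) in arbitrary pre-layout order
    pool: dict[str, list[tuple[str, str]]] = {g: [] for g in genome_ids}
    # contiguous block reserved for neighbor cassette + cluster, per positive
    block: dict[str, list[tuple[str, str]]] = {g: [] for g in positives}

    def plant(label: str, kind: str, carriers: list[str], target: float,
              block_of: dict | None = None) -> tuple[str, np.ndarray]:
        base = random_protein(rng, _draw_length(rng, cfg))
        seqs, realized = diversify_family(base, len(carriers), target, rng)
        members = {}
        for g, s in zip(carriers, seqs):
            dest = block_of[g] if block_of is not None else pool[g]
            dest.append((label, s))
            members[g] = []  # gene ids filled in at layout time
        off = np.triu_indices(len(carriers), k=1)
        fam = PlantedFamily(
            label=label, kind=kind, target_pid=target, members=members,
            realized_pairwise_min=float(realized[off].min()) if off[0].size else None,
            realized_pairwise_mean=float(realized[off].mean()) if off[0].size else None,
        )
        families[label] = fam
        return base, realized

    # --- core families (all genomes)
    for i in range(cfg.n_core):
        t = rng.uniform(*cfg.core_identity)
        plant(f"core{i + 1:04d}", "core", genome_ids, t)

    # --- accessory families: patterned presence, never exactly the positive set
    clades = [positives[: len(positives) // 2], positives[len(positives) // 2:],
              negatives]
    for i in range(cfg.n_accessory):
        carriers: set[str] = set()
        for clade in clades:
            if rng.random() < cfg.accessory_presence:
                carriers |= set(clade)
        for g in genome_ids:
            if rng.random() < 0.15:
                carriers.add(g)
        carriers_l = [g for g in genome_ids if g in carriers]
        if len(carriers_l) < 2:
            carriers_l = sorted(rng.choice(genome_ids, size=2, replace=False))
        if set(carriers_l) == set(positives) or len(carriers_l) == len(genome_ids):
            # keep the trait pattern reserved for the planted cluster
            carriers_l = [g for g in carriers_l if g != carriers_l[-1]]
        t = rng.uniform(*cfg.accessory_identity)
        plant(f"acc{i + 1:04d}", "accessory", carriers_l, t)

    # --- strain-specific singletons
    for g in genome_ids:
        for i in range(cfg.n_unique_per_genome):
            label = f"uniq_{g}_{i + 1:02d}"
            seq = random_protein(rng, _draw_length(rng, cfg))
            pool[g].append((label, seq))
            families[label] = PlantedFamily(
                label=label, kind="unique", target_pid=None, members={g: []},
            )

    # --- decoys: all positives plus exactly one negative
    for i in range(cfg.n_decoys):
        neg = negatives[int(rng.integers(0, len(negatives)))]
        t = rng.uniform(*cfg.accessory_identity)
        plant(f"decoy{i + 1:02d}", "decoy", positives + [neg], t)

    # --- neighbor cassette: conserved in every genome, adjacent to the
    #     cluster only in positives
    neighbor_labels = []
    for i in range(cfg.neighbor_size):
        label = f"nbr{i + 1:02d}"
        neighbor_labels.append(label)
        t = rng.uniform(60.0, 90.0)
        base = random_protein(rng, _draw_length(rng, cfg))
        seqs, realized = diversify_family(base, len(genome_ids), t, rng)
        members = {}
        for g, s in zip(genome_ids, seqs):
            if g in positives:
                block[g].append((label, s))
            else:
                pool[g].append((label, s))
            members[g] = []
        off = np.triu_indices(len(genome_ids), k=1)
        families[label] = PlantedFamily(
            label=label, kind="neighbor", target_pid=t, members=members,
            realized_pairwise_min=float(realized[off].min()),
            realized_pairwise_mean=float(realized[off].mean()),
        )

    # --- the trait-linked cluster, contiguous and order-conserved
    cluster_labels = []
    cluster_bases: list[tuple[str, np.ndarray, float]] = []
    for i in range(cfg.cluster_size):
        label = f"sfx{i + 1:02d}"
        cluster_labels.append(label)
        t = rng.uniform(*cfg.cluster_identity)
        base, _realized = plant(label, "cluster", positives, t, block_of=block)
        # recover the scramble sites for distant-homolog construction
        member_seqs = [s for (lab, s) in block[positives[0]] if lab == label]
        cluster_bases.append((base, t, member_seqs[0]))

    # --- distant homologs in dread genomes (below the screen band)
    distant: list[DistantHomolog] = []
    distant_seqs: dict[str, list[tuple[str, str]]] = {g: [] for g in dreads}
    if cfg.dread_mode and dreads:
        for label, (base, _t, _m) in zip(cluster_labels, cluster_bases):
            fam = families[label]
            member_seqs = []
            for g in positives:
                member_seqs.extend(s for (lab, s) in block[g] if lab == label)
            scramble_sites = np.flatnonzero(
                [any(m[i] != base[i] for m in member_seqs) for i in range(len(base))]
            )
            for g in dreads:
                t_h = rng.uniform(*cfg.distant_identity)
                hom = _distant_homolog(base, scramble_sites, t_h, rng)
                pids = [ungapped_identity(hom, m) for m in member_seqs]
                distant_seqs[g].append((f"hom_{label}", hom))
                distant.append(DistantHomolog(
                    family_label=label, genome_id=g, gene_id="",
                    realized_pid_min=float(min(pids)),
                    realized_pid_max=float(max(pids)),
                ))

    # ------------------------------------------------------------------
    # layout: shuffle the pool, pick contigs, insert the planted block
    # ------------------------------------------------------------------
    genomes: list[Genome] = []
    cassette_gene_ids: dict[str, list[str]] = {}
    split_info: dict | None = None

    for g in genome_ids:
        entries = list(pool[g])
        if g in dreads:
            # the homolog block stays contiguous, mirroring a degraded cluster
            entries = entries + [("__dread_block__", "")]
        order = rng.permutation(len(entries))
        entries = [entries[i] for i in order]
        flat: list[tuple[str, str]] = []
        for lab, s in entries:
            if lab == "__dread_block__":
                flat.extend(distant_seqs[g])
            else:
                flat.append((lab, s))

        n_contigs = int(rng.integers(1, 4))
        force_split = cfg.split_gene and g == positives[0]
        if force_split:
            n_contigs = max(n_contigs, 2)
        cuts = sorted(rng.choice(len(flat) + 1, size=n_contigs - 1, replace=False)) \
            if n_contigs > 1 else []
        contigs: list[list[tuple[str, str]]] = []
        prev = 0
        for c in cuts + [len(flat)]:
            contigs.append(flat[prev:c])
            prev = c

        if g in positives:
            blk = list(block[g])
            if force_split:
                # fragment the first cluster gene onto the last contig
                lab0, seq0 = next(e for e in blk if e[0] == cluster_labels[0])
                blk = [e for e in blk if e[0] != cluster_labels[0]]
                half = len(seq0) // 2
                frag_a = (f"{lab0}__frag1", seq0[:half])
                frag_b = (f"{lab0}__frag2", seq0[half:])
                contigs[-1].extend([frag_a, frag_b])
            insert_at = int(rng.integers(0, len(contigs[0]) + 1))
            contigs[0] = contigs[0][:insert_at] + blk + contigs[0][insert_at:]

        genes: list[GeneRecord] = []
        counter = 0
        label_of_gene: list[tuple[str, str]] = []
        for ci, contig in enumerate(contigs):
            contig_id = f"{g}_c{ci + 1}"
            pos_nt = 1
            for rank, (lab, seq) in enumerate(contig):
                counter += 1
                gid = f"{g}_{counter:05d}"
                start = pos_nt + int(rng.integers(20, 200))
                end = start + 3 * len(seq) + 2
                if end > MAX_CONTIG_NT:
                    raise ValueError(
                        f"genome {g} exceeds the {MAX_CONTIG_NT} nt contig budget"
                    )
                strand = "+" if rng.random() < 0.5 else "-"
                genes.append(GeneRecord(
                    gene_id=gid, genome_id=g, contig_id=contig_id,
                    start=start, end=end, strand=strand, locus_rank=rank,
                    protein_seq=seq,
                    product=("hypothetical protein" if lab.startswith(("sfx", "uniq"))
                             else f"synthetic {lab} protein"),
                ))
                label_of_gene.append((lab, gid))
                pos_nt = end + 1
        genomes.append(Genome(genome_id=g, genes=genes))

        # back-fill gene ids into the truth ledger
        for lab, gid in label_of_gene:
            if lab.endswith(("__frag1", "__frag2")):
                root = lab.rsplit("__", 1)[0]
                families[root].members.setdefault(g, []).append(gid)
                if split_info is None:
                    split_info = {"genome": g, "family_label": root, "fragment_ids": []}
                split_info["fragment_ids"].append(gid)
            elif lab.startswith("hom_"):
                root = lab[len("hom_"):]
                for d in distant:
                    if d.family_label == root and d.genome_id == g:
                        d.gene_id = gid
            elif lab in families:
                families[lab].members.setdefault(g, []).append(gid)
        if g in positives:
            cassette_gene_ids[g] = [
                gid for lab, gid in label_of_gene
                if lab in cluster_labels
                or lab.rsplit("__", 1)[0] in cluster_labels
            ]

    # --- random COG categories with one enriched category in the cluster
    cog: dict[str, str] = {}
    for genome in genomes:
        for gene in genome.genes:
            if rng.random() < 0.15:
                continue  # unassigned
            cog[gene.gene_id] = COG_LETTERS[int(rng.integers(0, len(COG_LETTERS)))]
    for lab in cluster_labels + neighbor_labels:
        for gids in families[lab].members.values():
            for gid in gids:
                if rng.random() < 0.9:
                    cog[gid] = ENRICHED_CATEGORY

    truth = SynthTruth(
        families=families,
        cluster_labels=cluster_labels,
        neighbor_labels=neighbor_labels,
        decoy_labels=[lab for lab, f in families.items() if f.kind == "decoy"],
        distant_homologs=distant,
        cassette_gene_ids=cassette_gene_ids,
        split_gene=split_info,
        trait=trait,
        cog=cog,
    )
    return genomes, truth


def make_proteome_pair(
    identities: list[float], seed: int = 0, length: int = 300
) -> tuple[Genome, Genome, list[float]]:
    """Two genomes whose i-th genes diverge at exactly identities[i] percent.

    The realized (recorded) identities are returned; they equal what
    full alignment recovers because divergence is substitution-only with
    conserved termini. Used as the exactness oracle for AAI.
    """
    rng = np.random.default_rng(seed)
    genes_a, genes_b, realized = [], [], []
    pos = 1
    for i, t in enumerate(identities):
        seq = random_protein(rng, length)
        mut, r = mutate_to_identity(seq, t, seed=int(rng.integers(0, 2**31)))
        realized.append(r)
        start = pos + 50
        end = start + 3 * length + 2
        for genes, gid, s in ((genes_a, f"GA_{i + 1:04d}", seq),
                              (genes_b, f"GB_{i + 1:04d}", mut)):
            genes.append(GeneRecord(
                gene_id=gid, genome_id=gid[:2], contig_id=f"{gid[:2]}_c1",
                start=start, end=end, strand="+", locus_rank=i, protein_seq=s,
            ))
        pos = end + 1
    return (Genome("GA", genes_a), Genome("GB", genes_b), realized)


# ---------------------------------------------------------------------------
# file emission
# ---------------------------------------------------------------------------

def emit_files(genomes: list[Genome], truth: SynthTruth, out_dir,
               force: bool = False) -> None:
    """Write genomes/<id>.gff3 + .faa, traits.tsv, cogs.tsv and truth.json."""
    out_dir = str(out_dir)
    if os.path.isdir(out_dir) and os.listdir(out_dir) and not force:
        raise FileExistsError(f"refusing to write into non-empty {out_dir!r}")
    gdir = os.path.join(out_dir, "genomes")
    os.makedirs(gdir, exist_ok=True)
    for genome in genomes:
        write_genome(genome,
                     os.path.join(gdir, f"{genome.genome_id}.gff3"),
                     os.path.join(gdir, f"{genome.genome_id}.faa"))
    write_trait_table(TraitTable(dict(truth.trait)),
                      os.path.join(out_dir, "traits.tsv"))
    with open(os.path.join(out_dir, "cogs.tsv"), "w") as fh:
        fh.write("gene_id\tcategories\n")
        for gid in sorted(truth.cog):
            fh.write(f"{gid}\t{truth.cog[gid]}\n")
    with open(os.path.join(out_dir, "truth.json"), "w") as fh:
        fh.write(truth.to_json())


def load_community(out_dir) -> tuple[list[Genome], TraitTable, SynthTruth]:
    """Reload an emitted community through the standard readers."""
    from .genome_io import load_genome, read_trait_table

    gdir = os.path.join(str(out_dir), "genomes")
    genomes = []
    for fn in sorted(os.listdir(gdir)):
        if fn.endswith(".gff3"):
            gid = fn[:-5]
            genomes.append(load_genome(
                os.path.join(gdir, fn), os.path.join(gdir, f"{gid}.faa"), gid
            ))
    traits = read_trait_table(os.path.join(str(out_dir), "traits.tsv"))
    with open(os.path.join(str(out_dir), "truth.json")) as fh:
        truth = SynthTruth.from_json(fh.read())
    return genomes, traits, truth
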