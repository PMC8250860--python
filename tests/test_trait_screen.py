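"""Trait-unique family extraction, coverage filter, distant homologs, sweep."""

import numpy as np
import pytest

from conftest import truth_gene_sets
from stalkscan.genome_io import TraitTable
from stalkscan.pangenome import build_pangenome
from stalkscan.simulate import SynthConfig, generate_community
from stalkscan.trait_screen import (
    coverage_filter,
    distant_homolog_search,
    screen_matrix,
    threshold_sweep,
    trait_unique_families,
)

SPLIT_CFG = SynthConfig(
    n_positive=5, n_negative=3, n_dread=1, n_core=15, n_accessory=8,
    n_unique_per_genome=2, n_decoys=2, cluster_size=4, neighbor_size=2,
    median_len=250.0, split_gene=True, seed=11,
)

DREAD_CFG = SynthConfig(
    n_positive=5, n_negative=3, n_dread=2, n_core=15, n_accessory=8,
    n_unique_per_genome=2, n_decoys=1, cluster_size=3, neighbor_size=2,
    median_len=250.0, dread_mode=True, seed=13,
)


@pytest.fixture(scope="module")
def split_run():
    genomes, truth = generate_community(SPLIT_CFG)
    pan = build_pangenome(genomes, 50.0)
    traits = TraitTable(dict(truth.trait))
    return genomes, truth, pan, traits


@pytest.fixture(scope="module")
def dread_run():
    genomes, truth = generate_community(DREAD_CFG)
    pan = build_pangenome(genomes, 50.0)
    traits = TraitTable(dict(truth.trait))
    return genomes, truth, pan, traits


class TestTraitUniqueFamilies:
    def test_exact_planted_recovery(self, default_pan50, default_community,
                                    default_traits):
        _, truth = default_community
        tus = trait_unique_families(default_pan50, default_traits)
        gene_sets = truth_gene_sets(truth)
        got = {frozenset(default_pan50.family_by_id(f).all_gene_ids())
               for f in tus.family_ids}
        want = {gene_sets[lab] for lab in truth.cluster_labels}
        assert got == want

    def test_decoys_excluded(self, default_pan50, default_community,
                             default_traits):
        _, truth = default_community
        tus = trait_unique_families(default_pan50, default_traits)
        gene_sets = truth_gene_sets(truth)
        got = {frozenset(default_pan50.family_by_id(f).all_gene_ids())
               for f in tus.family_ids}
        for lab in truth.decoy_labels:
            assert gene_sets[lab] not in got

    def test_family_touching_one_negative_excluded(self, small_pan50,
                                                   small_community):
        genomes, truth = small_community
        traits = TraitTable(dict(truth.trait))
        tus = trait_unique_families(small_pan50, traits)
        for fid in tus.family_ids:
            members = set(small_pan50.family_by_id(fid).members)
            assert not (members & traits.negatives)
            assert traits.positives <= members

    def test_missing_genome_label_raises(self, small_pan50, small_community):
        _, truth = small_community
        partial = dict(truth.trait)
        partial.pop(sorted(partial)[0])
        with pytest.raises(ValueError, match="missing"):
            trait_unique_families(small_pan50, TraitTable(partial))

    def test_monotone_in_positive_set(self, small_pan50, small_community):
        """Dropping a positive genome can only grow the screened set."""
        _, truth = small_community
        traits = TraitTable(dict(truth.trait))
        base = set(screen_matrix(small_pan50, traits.positives, traits.negatives))
        for g in sorted(traits.positives):
            reduced = set(screen_matrix(small_pan50, traits.positives - {g},
                                        traits.negatives))
            assert base <= reduced


class TestCoverageFilter:
    def test_full_length_families_pass(self, default_pan50, default_community,
                                       default_traits):
        tus = trait_unique_families(default_pan50, default_traits)
        tus = coverage_filter(tus, default_pan50, min_cov=70)
        assert all(tus.coverage_pass.values())
        assert tus.flagged() == []

    def test_split_gene_family_flagged(self, split_run):
        """The family carrying the two-contig split gene is the one flagged."""
        _, truth, pan, traits = split_run
        tus = trait_unique_families(pan, traits)
        tus = coverage_filter(tus, pan, min_cov=70)
        split_genes = set(truth.split_gene["fragment_ids"])
        flagged = tus.flagged()
        assert len(flagged) == 1
        members = set(pan.family_by_id(flagged[0]).all_gene_ids())
        assert split_genes <= members

    def test_constructed_fragment_flagged(self, small_community):
        """A family with a 45%-length member fails a 70% coverage check."""
        from stalkscan.align import align_pair
        from stalkscan.pangenome import GeneFamily, PanGenome
        from stalkscan.simulate import random_protein
        from stalkscan.genome_io import GeneRecord
        import pandas as pd

        rng = np.random.default_rng(0)
        full = random_protein(rng, 300)
        frag = full[: int(0.45 * len(full))]
        recs = {}
        for gid, seq, genome in (("g_full", full, "A"), ("g_frag", frag, "B")):
            recs[gid] = GeneRecord(gene_id=gid, genome_id=genome, contig_id="c",
                                   start=1, end=3 * len(seq) + 3, strand="+",
                                   locus_rank=0, protein_seq=seq)
        fam = GeneFamily(family_id="F1", members={"A": ["g_full"],
                                                  "B": ["g_frag"]},
                         representative="g_full")
        mat = pd.DataFrame([[1], [1]], index=["A", "B"], columns=["F1"])
        pan = PanGenome(threshold=50.0, families=[fam], genomes=["A", "B"],
                        matrix=mat, gene_records=recs)
        from stalkscan.trait_screen import TraitUniqueSet

        tus = TraitUniqueSet(threshold=50.0, family_ids=["F1"], gene_count=2)
        out = coverage_filter(tus, pan, min_cov=70)
        assert out.coverage_pass["F1"] is False
        assert align_pair(frag, full).subject_cov < 50


class TestDistantHomologs:
    def test_dread_homologs_found_in_band(self, dread_run):
        genomes, truth, pan, traits = dread_run
        tus = trait_unique_families(pan, traits)
        assert len(tus.family_ids) == len(truth.cluster_labels)
        dreads = [g for g in genomes
                  if truth.trait[g.genome_id] == "dread"]
        hits = distant_homolog_search(tus, pan, dreads,
                                      floor_pid=20, ceiling_pid=40)
        # one hit per (cluster family, dread genome)
        assert len(hits) == len(truth.cluster_labels) * len(dreads)
        planted = {(d.genome_id, d.gene_id) for d in truth.distant_homologs}
        for h in hits:
            assert (h.genome_id, h.gene_id) in planted
            assert 20 <= h.pid < 40
            assert h.coverage >= 50

    def test_empty_when_nothing_above_floor(self, default_pan50,
                                            default_community, default_traits):
        """Unrelated outgroup proteins never reach a 28% floor at >=50% cov
        (random semiglobal alignments plateau in the low twenties)."""
        genomes, truth = default_community
        tus = trait_unique_families(default_pan50, default_traits)
        outgroups = [g for g in genomes if g.genome_id in default_traits.negatives]
        hits = distant_homolog_search(tus, default_pan50, outgroups,
                                      floor_pid=28, ceiling_pid=40)
        assert hits == []

    def _mini_pan(self, family_seq):
        import pandas as pd

        from stalkscan.genome_io import GeneRecord
        from stalkscan.pangenome import GeneFamily, PanGenome

        rec = GeneRecord(gene_id="fam_rep", genome_id="P1", contig_id="c",
                         start=1, end=3 * len(family_seq) + 3, strand="+",
                         locus_rank=0, protein_seq=family_seq)
        fam = GeneFamily(family_id="F1", members={"P1": ["fam_rep"]},
                         representative="fam_rep")
        mat = pd.DataFrame([[1]], index=["P1"], columns=["F1"])
        return PanGenome(threshold=50.0, families=[fam], genomes=["P1"],
                         matrix=mat, gene_records={"fam_rep": rec})

    def test_ceiling_excludes_45pct_homolog(self):
        """A homolog at ~45% identity is invisible with ceiling 40 but
        reported once the ceiling is raised."""
        from stalkscan.genome_io import GeneRecord, Genome
        from stalkscan.simulate import mutate_to_identity, random_protein
        from stalkscan.trait_screen import TraitUniqueSet

        rng = np.random.default_rng(17)
        fam_seq = random_protein(rng, 300)
        hom, realized = mutate_to_identity(fam_seq, 45.0, seed=5)
        out = Genome("OG", [GeneRecord(
            gene_id="OG_1", genome_id="OG", contig_id="c", start=1,
            end=3 * len(hom) + 3, strand="+", locus_rank=0, protein_seq=hom)])
        pan = self._mini_pan(fam_seq)
        tus = TraitUniqueSet(threshold=50.0, family_ids=["F1"], gene_count=1)
        below = distant_homolog_search(tus, pan, [out],
                                       floor_pid=30, ceiling_pid=40)
        assert below == []
        above = distant_homolog_search(tus, pan, [out],
                                       floor_pid=30, ceiling_pid=50)
        assert len(above) == 1
        assert above[0].pid == pytest.approx(realized)


@pytest.fixture(scope="module")
def sweep_run():
    cfg = SynthConfig(
        n_positive=5, n_negative=3, n_dread=1, n_core=12, n_accessory=6,
        n_unique_per_genome=2, n_decoys=1, cluster_size=3, neighbor_size=2,
        cluster_identity=(60.0, 62.0), median_len=250.0, seed=21,
    )
    genomes, truth = generate_community(cfg)
    traits = TraitTable(dict(truth.trait))
    sweep = threshold_sweep(genomes, traits, [40.0, 50.0, 60.0, 80.0, 90.0],
                            union_range=(40.0, 80.0))
    return truth, sweep


class TestThresholdSweep:
    def test_found_at_low_absent_at_high(self, sweep_run):
        truth, sweep = sweep_run
        gene_sets = truth_gene_sets(truth)
        cluster_sets = {gene_sets[lab] for lab in truth.cluster_labels}
        for t in (40.0, 50.0):
            got = {frozenset(sweep.pans[t].family_by_id(f).all_gene_ids())
                   for f in sweep.sets[t].family_ids}
            assert cluster_sets <= got, f"cluster missing at {t}"
        for t in (80.0, 90.0):
            got = {frozenset(sweep.pans[t].family_by_id(f).all_gene_ids())
                   for f in sweep.sets[t].family_ids}
            assert not (cluster_sets & got), f"cluster must be absent at {t}"

    def test_union_counts(self, sweep_run):
        truth, sweep = sweep_run
        gene_sets = truth_gene_sets(truth)
        cluster_genes = set().union(*(gene_sets[lab]
                                      for lab in truth.cluster_labels))
        assert cluster_genes <= set(sweep.union_gene_ids)

    def test_full_identity_cluster_found_everywhere(self):
        cfg = SynthConfig(
            n_positive=4, n_negative=2, n_dread=1, n_core=8, n_accessory=4,
            n_unique_per_genome=1, n_decoys=1, cluster_size=2, neighbor_size=1,
            cluster_identity=(100.0, 100.0), median_len=220.0, seed=23,
        )
        genomes, truth = generate_community(cfg)
        traits = TraitTable(dict(truth.trait))
        sweep = threshold_sweep(genomes, traits, [30.0, 60.0, 90.0])
        gene_sets = truth_gene_sets(truth)
        cluster_sets = {gene_sets[lab] for lab in truth.cluster_labels}
        for t, tus in sweep.sets.items():
            got = {frozenset(sweep.pans[t].family_by_id(f).all_gene_ids())
                   for f in tus.family_ids}
            assert cluster_sets <= got


def test_reports_written(tmp_path, default_pan50, default_community,
                         default_traits):
    from stalkscan.trait_screen import write_trait_report

    tus = trait_unique_families(default_pan50, default_traits)
    tus = coverage_filter(tus, default_pan50)
    path = tmp_path / "report.tsv"
    write_trait_report(tus, default_pan50, path)
    lines = path.read_text().strip().splitlines()
    assert len(lines) == 1 + len(tus.family_ids)
    header = lines[0].split("\t")
    assert header[:3] == ["family_id", "n_genes", "coverage_pass"]
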