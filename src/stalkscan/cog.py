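"""COG category distribution per pan-genome subdivision and enrichment.

Assignments are consumed as a gene -> category-letters table (a gene may
carry several single-letter categories and then contributes to each).
Enrichment is a two-sided Fisher exact test on the 2x2 table
(in-subdivision with/without category vs out-subdivision with/without),
with Benjamini-Hochberg correction across the categories tested in one
call. The gene universe for every table is the set of assigned genes
present in the pan-genome.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .pangenome import PanGenome, Partition

COG_CATEGORIES = "JAKLBDYVTMNZWUOXCGEFHIPQRS"

SUBDIVISIONS = ("core", "accessory", "unique")


@dataclass(frozen=True)
class EnrichmentResult:
    category: str
    subdivision: str
    a: int   # in subdivision, with category
    b: int   # in subdivision, without
    c: int   # outside subdivision, with category
    d: int   # outside, without
    odds_ratio: float
    p_value: float
    q_value: float = float("nan")
    degenerate: bool = False


def _gene_subdivision(pan: PanGenome, partition: Partition) -> dict[str, str]:
    sub_of_family = {}
    for name in SUBDIVISIONS:
        for fid in getattr(partition, name):
            sub_of_family[fid] = name
    out = {}
    for fam in pan.families:
        sub = sub_of_family[fam.family_id]
        for gid in fam.all_gene_ids():
            out[gid] = sub
    return out


@dataclass
class CategoryDistribution:
    by_subdivision: pd.DataFrame   # categories x subdivisions, counts
    fractions: pd.DataFrame        # column-normalized
    by_genome: pd.DataFrame        # categories x genomes, counts


def category_distribution(
    assign: dict[str, str], partition: Partition, pan: PanGenome
) -> CategoryDistribution:
    """Category counts per subdivision and per genome (multi-letter genes
    count once per category)."""
    sub_of_gene = _gene_subdivision(pan, partition)
    cats = sorted(set("".join(assign.values())) or {"-"})
    by_sub = pd.DataFrame(0, index=cats, columns=list(SUBDIVISIONS))
    genome_of = {gid: rec.genome_id
                 for gid, rec in pan.gene_records.items()}
    by_genome = pd.DataFrame(0, index=cats, columns=list(pan.genomes))
    for gid, letters in assign.items():
        sub = sub_of_gene.get(gid)
        if sub is None:
            continue
        for letter in letters:
            by_sub.loc[letter, sub] += 1
            by_genome.loc[letter, genome_of[gid]] += 1
    colsum = by_sub.sum(axis=0).replace(0, 1)
    return CategoryDistribution(
        by_subdivision=by_sub, fractions=by_sub / colsum, by_genome=by_genome
    )


def fisher_2x2(a: int, b: int, c: int, d: int) -> tuple[float, float, bool]:
    """Two-sided Fisher exact; degenerate margins give OR nan, p 1.0."""
    if (a + b == 0) or (c + d == 0) or (a + c == 0) or (b + d == 0):
        return float("nan"), 1.0, True
    odds, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
    return float(odds), float(p), False


def bh_correct(pvals: list[float]) -> list[float]:
    """Benjamini-Hochberg q-values (monotone, always >= p)."""
    n = len(pvals)
    order = np.argsort(pvals, kind="stable")
    q = np.empty(n)
    running = 1.0
    for rank_from_end, idx in enumerate(reversed(order)):
        rank = n - rank_from_end
        running = min(running, pvals[idx] * n / rank)
        q[idx] = running
    return [float(max(qv, pv)) for qv, pv in zip(q, pvals)]


def enrichment_test(
    assign: dict[str, str], partition: Partition, pan: PanGenome,
    category: str, subdivision: str = "accessory",
) -> EnrichmentResult:
    """Fisher test of one category in one subdivision (no correction)."""
    return _enrichment(assign, partition, pan, [category], subdivision)[0]


def enrichment_table(
    assign: dict[str, str], partition: Partition, pan: PanGenome,
    subdivision: str = "accessory",
) -> list[EnrichmentResult]:
    """Fisher tests for every observed category, BH-corrected jointly."""
    cats = sorted(set("".join(assign.values())))
    return _enrichment(assign, partition, pan, cats, subdivision)


def _enrichment(assign, partition, pan, categories, subdivision):
    if subdivision not in SUBDIVISIONS:
        raise ValueError(f"subdivision must be one of {SUBDIVISIONS}")
    sub_of_gene = _gene_subdivision(pan, partition)
    universe = [gid for gid in assign if gid in sub_of_gene]
    results = []
    for cat in categories:
        a = b = c = d = 0
        for gid in universe:
            inside = sub_of_gene[gid] == subdivision
            has = cat in assign[gid]
            if inside and has:
                a += 1
            elif inside:
                b += 1
            elif has:
                c += 1
            else:
                d += 1
        odds, p, degenerate = fisher_2x2(a, b, c, d)
        results.append(EnrichmentResult(
            category=cat, subdivision=subdivision,
            a=a, b=b, c=c, d=d, odds_ratio=odds, p_value=p,
            degenerate=degenerate,
        ))
    qvals = bh_correct([r.p_value for r in results])
    results = [
        EnrichmentResult(**{**r.__dict__, "q_value": q})
        for r, q in zip(results, qvals)
    ]
    return results


def write_enrichment_report(results: list[EnrichmentResult], path) -> None:
    with open(path, "w") as fh:
        fh.write("category\tsubdivision\ta\tb\tc\td\todds_ratio\tp\tq\tdegenerate\n")
        for r in results:
            fh.write(
                f"{r.category}\t{r.subdivision}\t{r.a}\t{r.b}\t{r.c}\t{r.d}\t"
                f"{r.odds_ratio:.6g}\t{r.p_value:.6g}\t{r.q_value:.6g}\t"
                f"{str(r.degenerate).lower()}\n"
            )
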