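"""End-to-end orchestration: simulate -> discover -> build refs -> assign ->
classify -> date, with all intermediate products exposed for inspection.

The stages mirror the analysis workflow the package implements:

1. SNP discovery: parental and allopolyploid reads are mapped to the
   surrogate reference at low stringency and variants are called and
   classified into diagnostic ancestry classes (LD assignment included).
2. Reference construction: parent-like references are built, informative
   regions derived from the discriminating positions, non-informative
   sequence masked, and under-covered/under-informative genes culled.
3. Expression: allopolyploid fragments are homeolog-assigned at zero
   mismatches; parental reads are counted on their own masked references;
   RPM, Fisher/q statistics and DE calls computed.
4. Fate: nine categories, four outcomes, dominance, EDE, loss candidates,
   physical clusters, independence proportions.
5. Dating: upper bound from the recovered shortest-branch SNP count, the
   masked informative length, and the configured mutation rate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import pandas as pd

from . import expression, fate, refs as refs_mod, snp
from .dating import DatingInputs, date_upper_bound, shortest_branch_snps
from .seqmap import KmerIndex
from .simulate import SimConfig, SimData, simulate_experiment


@dataclass
class Thresholds:
    """All tunable thresholds of the analysis stages."""

    k_discovery: int = 9
    max_mismatch_frac: float = 0.10  # low-stringency discovery bound
    min_cov_parent: int = 5
    min_alt_frac_parent: float = 0.9
    min_alt_reads_allo: int = 3
    min_alt_frac_allo: float = 0.1
    min_links: int = 3
    max_conflict_frac: float = 0.05
    k_assign: int = 31
    min_parent_reads: int = 5
    min_informative_len: int = 150
    fold_de: float = 2.0
    q_thresh: float = 0.05
    fold_ede: float = 50.0
    min_ede_reads: int = 5
    mu: float = 1e-9

    def max_mismatch(self, read_length: int) -> int:
        return math.ceil(self.max_mismatch_frac * read_length)


@dataclass
class PipelineResult:
    sim: SimData
    classified: pd.DataFrame
    class_counts: pd.Series
    refs: refs_mod.HomeologReferenceSet
    cull_report: pd.DataFrame
    informative_length: int
    count_table: expression.CountTable
    table: pd.DataFrame
    fates: pd.DataFrame
    outcome_props: pd.Series
    loss_totals: dict
    clusters: list
    independence: dict = field(default_factory=dict)
    dating: dict = field(default_factory=dict)


def discover_snps(sim: SimData, th: Thresholds):
    """Low-stringency discovery mapping, variant calling and classification."""
    cfg = sim.config
    index = KmerIndex(sim.genes.seqs, k=th.k_discovery)
    mm = th.max_mismatch(cfg.read_length)

    def pooled_mapped(sample: str):
        mapped = []
        offset = 0
        for rs in sim.reads[sample]:
            part = snp.map_library(rs.reads1, index, mm, reads2=rs.reads2)
            for mr in part:
                mr.fragment += offset
            mapped.extend(part)
            offset += len(rs)
        return mapped

    mapped_p1 = pooled_mapped("p1")
    mapped_p2 = pooled_mapped("p2")
    mapped_allo = pooled_mapped("allo")

    pile_p1 = snp.pileup(mapped_p1, sim.genes.seqs)
    pile_p2 = snp.pileup(mapped_p2, sim.genes.seqs)
    pile_allo = snp.pileup(mapped_allo, sim.genes.seqs)

    var_p1 = snp.call_parent_variants(
        pile_p1, sim.genes.seqs, th.min_cov_parent, th.min_alt_frac_parent
    )
    var_p2 = snp.call_parent_variants(
        pile_p2, sim.genes.seqs, th.min_cov_parent, th.min_alt_frac_parent
    )
    var_allo = snp.call_allo_variants(
        pile_allo, sim.genes.seqs, th.min_alt_reads_allo, th.min_alt_frac_allo
    )
    classified = snp.classify_snps(var_p1, var_p2, var_allo)
    classified = snp.assign_allo_unique_by_ld(
        mapped_allo, classified, th.min_links, th.max_conflict_frac
    )
    return classified, mapped_allo


def build_references(sim: SimData, classified: pd.DataFrame, th: Thresholds):
    """Reference substitution, informative-region masking; culling comes after
    parent counting (it needs parent read counts on the masked references)."""
    refs = refs_mod.build_homeolog_references(sim.genes.seqs, classified)
    refs_mod.annotate_informative(refs, sim.config.read_length)
    refs_mod.mask_noninformative(refs)
    return refs


def run(cfg: SimConfig | None = None, thresholds: Thresholds | None = None) -> PipelineResult:
    """Run the complete analysis on a synthetic experiment."""
    cfg = cfg or SimConfig()
    th = thresholds or Thresholds()
    sim = simulate_experiment(cfg)

    classified, _ = discover_snps(sim, th)
    counts = snp.class_counts(classified)
    refs = build_references(sim, classified, th)

    # provisional count of parental reads on the masked references (all genes)
    # to drive culling, then the final count table on retained genes only
    all_genes = sorted(refs)
    idx_p1 = KmerIndex(refs.sequences("P1"), k=th.k_assign)
    idx_p2 = KmerIndex(refs.sequences("P2"), k=th.k_assign)
    p1_counts = sum(
        (expression.count_parent_reads(rs, idx_p1, all_genes)[0] for rs in sim.reads["p1"]),
        pd.Series(0, index=all_genes),
    )
    p2_counts = sum(
        (expression.count_parent_reads(rs, idx_p2, all_genes)[0] for rs in sim.reads["p2"]),
        pd.Series(0, index=all_genes),
    )
    parent_counts = pd.DataFrame(
        {"gene_id": all_genes, "p1_reads": p1_counts.values, "p2_reads": p2_counts.values}
    )
    cull_report = refs_mod.cull_genes(
        refs, parent_counts, th.min_parent_reads, th.min_informative_len
    )
    L = refs.cumulative_informative_length

    ct = expression.build_count_table(
        refs, sim.reads["p1"], sim.reads["p2"], sim.reads["allo"], k=th.k_assign
    )
    table = expression.expression_table(ct, th.fold_de, th.q_thresh)
    fates = fate.classify_fates(table, th.min_ede_reads, th.fold_ede)
    props = fate.outcome_proportions(fates)
    _, loss_totals = fate.loss_candidates(
        table[["count_h1", "count_h2"]].rename(
            columns={"count_h1": "allo_P1", "count_h2": "allo_P2"}
        )
    )
    retained = pd.Series(
        {g: refs[g].retained for g in refs}, name="retained"
    )
    clusters = fate.cluster_ede(sim.genes.coords, fates["ede"], retained)
    independence = fate.independence_proportions(fates)

    S = shortest_branch_snps(counts)
    dating = (
        date_upper_bound(DatingInputs(S=S, L=L, mu=th.mu)) if S >= 0 and L > 0 else {}
    )

    return PipelineResult(
        sim=sim,
        classified=classified,
        class_counts=counts,
        refs=refs,
        cull_report=cull_report,
        informative_length=L,
        count_table=ct,
        table=table,
        fates=fates,
        outcome_props=props,
        loss_totals=loss_totals,
        clusters=clusters,
        independence=independence,
        dating=dating,
    )
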