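"""Variant calling against the surrogate reference and diagnostic classification.

SNPs called from the two parents and the allopolyploid against the shared
surrogate gene models are partitioned into ancestry classes: ``ancestral``
(present in parent1, parent2 and the allopolyploid — substitutions on the
reference strain's own branch), ``p1_unique``/``p2_unique`` (parent-private,
absent from the allopolyploid), ``p1_shared``/``p2_shared`` (one parent plus
the allopolyploid — the homeolog-diagnostic classes), and allopolyploid-only
variants, which are post-hybridization candidates assigned to a subgenome by
read-level linkage with the diagnostic classes where possible.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._seq import revcomp
from .seqmap import Hit, KmerIndex, best_gene_hit

logger = logging.getLogger(__name__)

CLASSES = (
    "ancestral",
    "p1_unique",
    "p2_unique",
    "p1_shared",
    "p2_shared",
    "allo_p1",
    "allo_p2",
    "allo_unclassified",
)
ALLO_UNIQUE_CLASSES = ("allo_p1", "allo_p2", "allo_unclassified")
BASE_CODE = {b: i for i, b in enumerate("ACGTN")}


@dataclass
class MappedRead:
    """One uniquely placed read: fragment id, aligned bases, and its hit."""

    fragment: int
    aligned: np.ndarray  # bases in target orientation
    hit: Hit


def map_library(
    reads1: np.ndarray,
    index: KmerIndex,
    max_mismatch: int,
    reads2: np.ndarray | None = None,
    gene_of: dict[str, str] | None = None,
) -> list[MappedRead]:
    """Map a library (mates mapped independently, sharing a fragment id).

    Reads whose equal-best hits span more than one gene are discarded to
    avoid paralog-inflated variant evidence.
    """
    out: list[MappedRead] = []
    mates = (reads1,) if reads2 is None else (reads1, reads2)
    n = reads1.shape[0]
    for frag in range(n):
        for mate in mates:
            read = mate[frag]
            hit = best_gene_hit(index.map_read(read, max_mismatch), gene_of)
            if hit is None:
                continue
            aligned = revcomp(read) if hit.strand == "-" else read
            out.append(MappedRead(frag, aligned, hit))
    return out


def pileup(
    mapped: list[MappedRead], targets: dict[str, np.ndarray]
) -> dict[str, np.ndarray]:
    """Per-gene (4, L) base-count matrices from uniquely mapped reads."""
    piles: dict[str, np.ndarray] = {}
    for mr in mapped:
        t = mr.hit.target_id
        target = targets[t]
        L = len(mr.aligned)
        if mr.hit.position < 0 or mr.hit.position + L > len(target):
            raise ValueError(f"alignment beyond bounds of target {t}")
        arr = piles.get(t)
        if arr is None:
            arr = piles[t] = np.zeros((4, len(target)), dtype=np.int32)
        cols = np.arange(mr.hit.position, mr.hit.position + L)
        valid = mr.aligned < 4
        np.add.at(arr, (mr.aligned[valid], cols[valid]), 1)
    return piles


def _best_alt(counts: np.ndarray, ref: np.ndarray):
    """Top non-reference allele per position, with tie detection."""
    L = counts.shape[1]
    tmp = counts.copy()
    tmp[ref, np.arange(L)] = -1
    best_alt = tmp.argmax(axis=0)
    best_n = tmp.max(axis=0)
    tie = (tmp == best_n).sum(axis=0) > 1
    return best_alt, best_n, tie


def _calls_frame(gene, ref, best_alt, best_n, cov, mask) -> pd.DataFrame:
    pos = np.flatnonzero(mask)
    return pd.DataFrame(
        {
            "gene_id": gene,
            "position": pos,
            "ref": ["ACGT"[b] for b in ref[pos]],
            "alt": ["ACGT"[b] for b in best_alt[pos]],
            "ref_count": counts_at(cov, ref, pos),
            "alt_count": best_n[pos],
        }
    )


def counts_at(counts: np.ndarray, ref: np.ndarray, pos: np.ndarray) -> np.ndarray:
    return counts[ref[pos], pos]


def call_parent_variants(
    piles: dict[str, np.ndarray],
    reference: dict[str, np.ndarray],
    min_cov: int = 5,
    min_alt_frac: float = 0.9,
) -> pd.DataFrame:
    """Haploid variant calls: near-fixed alternate alleles at covered sites.

    A site is called when coverage >= min_cov and the single best alternate
    allele reaches min_alt_frac of the coverage (ties between alternates
    yield no call).  The fraction is below 1.0 to tolerate sequencing error.
    """
    frames = []
    for gene in sorted(piles):
        counts = piles[gene]
        ref = reference[gene]
        cov = counts.sum(axis=0)
        best_alt, best_n, tie = _best_alt(counts, ref)
        mask = (cov >= min_cov) & (best_n >= min_alt_frac * cov) & (best_n > 0) & ~tie
        frames.append(_calls_frame(gene, ref, best_alt, best_n, counts, mask))
    return _cat(frames)


def call_allo_variants(
    piles: dict[str, np.ndarray],
    reference: dict[str, np.ndarray],
    min_alt_reads: int = 3,
    min_alt_frac: float = 0.1,
) -> pd.DataFrame:
    """Mixed-sample variant calls retaining heterozygous-like sites.

    The alternate fraction threshold is far below 0.5 because homeolog
    expression bias skews allele fractions: a site may legitimately carry
    both a reference-like and an alternate-like homeolog allele, and the
    minor homeolog of a 4-fold biased gene contributes only ~20% of reads,
    so the threshold must sit safely below that share.  The absolute
    read floor keeps sequencing error from producing false calls.
    """
    frames = []
    for gene in sorted(piles):
        counts = piles[gene]
        ref = reference[gene]
        cov = counts.sum(axis=0)
        best_alt, best_n, tie = _best_alt(counts, ref)
        with np.errstate(invalid="ignore", divide="ignore"):
            frac = np.where(cov > 0, best_n / np.maximum(cov, 1), 0.0)
        mask = (best_n >= min_alt_reads) & (frac >= min_alt_frac) & ~tie
        frames.append(_calls_frame(gene, ref, best_alt, best_n, counts, mask))
    return _cat(frames)


def _cat(frames: list[pd.DataFrame]) -> pd.DataFrame:
    cols = ["gene_id", "position", "ref", "alt", "ref_count", "alt_count"]
    frames = [f for f in frames if len(f)]
    if not frames:
        return pd.DataFrame(columns=cols)
    return pd.concat(frames, ignore_index=True)[cols]


def classify_snps(
    var_p1: pd.DataFrame, var_p2: pd.DataFrame, var_allo: pd.DataFrame
) -> pd.DataFrame:
    """Partition variants into diagnostic ancestry classes.

    Presence/absence across the three samples determines the class; variants
    seen in both parents but undetected in the allopolyploid go to a
    ``parent_shared_residual`` bin (they cannot be used for reference
    substitution); sites with conflicting alternate alleles across samples
    are excluded as ``multiallelic``.
    """

    def keyed(df: pd.DataFrame) -> set[tuple]:
        return set(zip(df["gene_id"], df["position"], df["alt"]))

    k1, k2, ka = keyed(var_p1), keyed(var_p2), keyed(var_allo)
    all_keys = k1 | k2 | ka
    refs: dict[tuple, str] = {}
    for df in (var_p1, var_p2, var_allo):
        for g, p, r in zip(df["gene_id"], df["position"], df["ref"]):
            refs[(g, p)] = r
    # multi-allelic: more than one alt allele observed at a site
    alts_by_site: dict[tuple, set] = {}
    for g, p, a in all_keys:
        alts_by_site.setdefault((g, p), set()).add(a)
    multi = {site for site, alts in alts_by_site.items() if len(alts) > 1}
    if multi:
        logger.warning("excluded %d multi-allelic sites", len(multi))

    rows = []
    for g, p, a in sorted(all_keys):
        in1, in2, ina = (g, p, a) in k1, (g, p, a) in k2, (g, p, a) in ka
        if (g, p) in multi:
            cls = "multiallelic"
        elif in1 and in2 and ina:
            cls = "ancestral"
        elif in1 and ina:
            cls = "p1_shared"
        elif in2 and ina:
            cls = "p2_shared"
        elif in1 and in2:
            cls = "parent_shared_residual"
        elif in1:
            cls = "p1_unique"
        elif in2:
            cls = "p2_unique"
        else:
            cls = "allo_unclassified"
        rows.append((g, p, refs[(g, p)], a, cls))
    return pd.DataFrame(rows, columns=["gene_id", "position", "ref", "alt", "cls"])


def assign_allo_unique_by_ld(
    mapped_allo: list[MappedRead],
    classified: pd.DataFrame,
    min_links: int = 3,
    max_conflict_frac: float = 0.05,
) -> pd.DataFrame:
    """Assign allopolyploid-private SNPs to a subgenome by read linkage.

    For each unclassified variant, fragments (mate pairs count once) that
    carry its alternate allele and also cover at least one homeolog-
    diagnostic site cast a vote: the alternate allele of a p1_shared site —
    or the reference allele of a p2_shared site — identifies the parent-1
    subgenome, and symmetrically for parent 2.  A variant is reclassified
    when at least ``min_links`` voting fragments agree at a
    ``1 - max_conflict_frac`` supermajority.
    """
    out = classified.copy()
    unc = out[out["cls"] == "allo_unclassified"]
    if not len(unc):
        return out
    diag = out[out["cls"].isin(("p1_shared", "p2_shared"))]
    diag_by_gene = {
        g: (
            grp["position"].to_numpy(),
            np.array([BASE_CODE[b] for b in grp["alt"]], dtype=np.uint8),
            np.array([BASE_CODE[b] for b in grp["ref"]], dtype=np.uint8),
            (grp["cls"] == "p1_shared").to_numpy(),
        )
        for g, grp in diag.groupby("gene_id")
    }
    reads_by_gene: dict[str, list[MappedRead]] = {}
    for mr in mapped_allo:
        reads_by_gene.setdefault(mr.hit.target_id, []).append(mr)

    for idx, row in unc.iterrows():
        g = row["gene_id"]
        reads = reads_by_gene.get(g, [])
        if g not in diag_by_gene or not reads:
            continue
        dpos, dalt, dref, dis_p1 = diag_by_gene[g]
        p, alt_code = int(row["position"]), BASE_CODE[row["alt"]]
        carriers = {
            mr.fragment
            for mr in reads
            if mr.hit.position <= p < mr.hit.position + len(mr.aligned)
            and mr.aligned[p - mr.hit.position] == alt_code
        }
        if not carriers:
            continue
        frag_reads: dict[int, list[MappedRead]] = {}
        for mr in reads:
            if mr.fragment in carriers:
                frag_reads.setdefault(mr.fragment, []).append(mr)
        votes = {"P1": 0, "P2": 0}
        for frs in frag_reads.values():
            v1 = v2 = 0
            for mr in frs:
                lo, hi = mr.hit.position, mr.hit.position + len(mr.aligned)
                sel = np.flatnonzero((dpos >= lo) & (dpos < hi))
                for si in sel:
                    b = mr.aligned[dpos[si] - lo]
                    if b == dalt[si]:
                        v1 += dis_p1[si]
                        v2 += not dis_p1[si]
                    elif b == dref[si]:
                        v2 += dis_p1[si]
                        v1 += not dis_p1[si]
            if v1 and not v2:
                votes["P1"] += 1
            elif v2 and not v1:
                votes["P2"] += 1
        n = votes["P1"] + votes["P2"]
        if n >= min_links:
            for side, cls in (("P1", "allo_p1"), ("P2", "allo_p2")):
                if votes[side] >= (1.0 - max_conflict_frac) * n:
                    out.at[idx, "cls"] = cls
                    break
    return out


def class_counts(classified: pd.DataFrame) -> pd.Series:
    """Counts per diagnostic class, with the allo-unique roll-up total."""
    counts = classified["cls"].value_counts()
    out = pd.Series({c: int(counts.get(c, 0)) for c in CLASSES})
    out["allo_unique"] = sum(out[c] for c in ALLO_UNIQUE_CLASSES)
    for extra in ("parent_shared_residual", "multiallelic"):
        out[extra] = int(counts.get(extra, 0))
    return out


def sharing_summary(n_allo_total: int, n_allo_unique: int, n_ld_assigned: int) -> dict:
    """Bookkeeping percentages for allopolyploid SNP ancestry.

    ``pct_shared_with_parents`` is the share of allopolyploid SNPs also seen
    in at least one parent; ``pct_ld_assignable`` the share of the new
    (post-hybridization) SNPs that linkage could place on a subgenome.
    """
    if n_allo_total <= 0:
        raise ValueError("n_allo_total must be positive")
    return {
        "pct_shared_with_parents": 100.0 * (n_allo_total - n_allo_unique) / n_allo_total,
        "pct_ld_assignable": (
            100.0 * n_ld_assigned / n_allo_unique if n_allo_unique else float("nan")
        ),
    }


def marker_ancestry(
    piles: dict[str, np.ndarray],
    marker_sites: pd.DataFrame,
    min_total: int = 5,
) -> pd.DataFrame:
    """Per-marker ancestry verdict from parental allele counts at its sites.

    ``marker_sites`` columns: marker, gene_id, position, p1_base, p2_base.
    A marker is 'sole-P1' when every site shows only parent-1 alleles among
    informative reads (and at least ``min_total`` informative reads overall),
    symmetrically 'sole-P2'; otherwise 'mixed' or 'insufficient'.
    """
    rows = []
    for marker, grp in marker_sites.groupby("marker"):
        n1 = n2 = 0
        for _, r in grp.iterrows():
            counts = piles.get(r["gene_id"])
            if counts is None:
                continue
            n1 += int(counts[BASE_CODE[r["p1_base"]], int(r["position"])])
            n2 += int(counts[BASE_CODE[r["p2_base"]], int(r["position"])])
        if n1 + n2 < min_total:
            verdict = "insufficient"
        elif n2 == 0:
            verdict = "sole-P1"
        elif n1 == 0:
            verdict = "sole-P2"
        else:
            verdict = "mixed"
        rows.append((marker, n1, n2, verdict))
    return pd.DataFrame(rows, columns=["marker", "p1_reads", "p2_reads", "verdict"])


# ---------------------------------------------------------------------------
# VCF export (v4 subset: CHROM=gene_id, 1-based POS, INFO CLASS=...)

def write_vcf(classified: pd.DataFrame, gene_lengths: dict[str, int], path) -> None:
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##INFO=<ID=CLASS,Number=1,Type=String,Description="Diagnostic class">\n')
        for g in sorted(gene_lengths):
            fh.write(f"##contig=<ID={g},length={gene_lengths[g]}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        ordered = classified.sort_values(["gene_id", "position"])
        for _, r in ordered.iterrows():
            fh.write(
                f"{r['gene_id']}\t{int(r['position']) + 1}\t.\t{r['ref']}\t{r['alt']}"
                f"\t.\tPASS\tCLASS={r['cls']}\n"
            )


def read_vcf(path) -> pd.DataFrame:
    import pysam

    rows = []
    with pysam.VariantFile(str(path)) as vf:
        for rec in vf:
            rows.append(
                (
                    rec.chrom,
                    rec.pos - 1,
                    rec.ref,
                    rec.alts[0],
                    rec.info["CLASS"],
                )
            )
    return pd.DataFrame(rows, columns=["gene_id", "position", "ref", "alt", "cls"])
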