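"""Homeolog-specific reference construction, informative-region masking, culling.

Two parallel reference gene sets are derived from the surrogate reference by
substituting classified SNP alleles: the parent-1-like reference receives
{ancestral, p1_shared, allo_p1} alleles, the parent-2-like reference
{ancestral, p2_shared, allo_p2}.  Positions where the two references differ
are the discriminating positions; only reads overlapping one can ever be
homeolog-assigned, so the informative region of a gene is the union of
read-length windows around them.  Everything else is hard-masked to 'N',
and genes with thin parental evidence or short informative footprints are
culled before expression analysis.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._seq import N
from .snp import BASE_CODE

logger = logging.getLogger(__name__)

P1_CLASSES = ("ancestral", "p1_shared", "allo_p1")
P2_CLASSES = ("ancestral", "p2_shared", "allo_p2")


@dataclass
class GeneRefs:
    """Per-gene homeolog pair with discriminating/informative annotation."""

    p1_like: np.ndarray
    p2_like: np.ndarray
    disc_positions: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=int))
    intervals: list[tuple[int, int]] = field(default_factory=list)
    informative_length: int = 0
    retained: bool = True
    cull_reason: str = ""


class HomeologReferenceSet(dict):
    """gene_id -> GeneRefs mapping with convenience accessors."""

    def sequences(self, side: str, retained_only: bool = False) -> dict[str, np.ndarray]:
        attr = "p1_like" if side == "P1" else "p2_like"
        return {
            g: getattr(r, attr)
            for g, r in self.items()
            if not retained_only or r.retained
        }

    @property
    def cumulative_informative_length(self) -> int:
        return sum(r.informative_length for r in self.values() if r.retained)


def build_homeolog_references(
    reference: dict[str, np.ndarray], classified: pd.DataFrame
) -> HomeologReferenceSet:
    """Substitute classified alleles into parallel parent-like references.

    Parent-unique and unassigned allopolyploid alleles are NOT applied: the
    former are absent from the allopolyploid, the latter have unknown
    subgenome.  Conflicting substitutions targeting the same side of one
    site exclude that site (logged).
    """
    refs = HomeologReferenceSet(
        (g, GeneRefs(p1_like=seq.copy(), p2_like=seq.copy()))
        for g, seq in reference.items()
    )
    usable = classified[classified["cls"].isin(set(P1_CLASSES) | set(P2_CLASSES))]
    dropped = 0
    for (g, p), grp in usable.groupby(["gene_id", "position"]):
        if g not in refs:
            continue
        p = int(p)
        p1_alleles = {a for a, c in zip(grp["alt"], grp["cls"]) if c in P1_CLASSES}
        p2_alleles = {a for a, c in zip(grp["alt"], grp["cls"]) if c in P2_CLASSES}
        if len(p1_alleles) > 1 or len(p2_alleles) > 1:
            dropped += 1
            continue
        if p1_alleles:
            refs[g].p1_like[p] = BASE_CODE[p1_alleles.pop()]
        if p2_alleles:
            refs[g].p2_like[p] = BASE_CODE[p2_alleles.pop()]
    if dropped:
        logger.warning("excluded %d sites with conflicting substitutions", dropped)
    for r in refs.values():
        r.disc_positions = np.flatnonzero(r.p1_like != r.p2_like)
    return refs


def informative_regions(
    disc_positions: np.ndarray, read_length: int, gene_length: int
) -> tuple[list[tuple[int, int]], int]:
    """Merged union of read-length windows around discriminating positions.

    A full-length read can cover position p only if it starts within
    ``[p - (read_length - 1), p]``, so the reachable footprint of p is
    ``[p - (read_length - 1), p + read_length)`` clipped to the gene.
    """
    if read_length < 1:
        raise ValueError("read_length must be >= 1")
    intervals: list[tuple[int, int]] = []
    for p in np.sort(np.asarray(disc_positions, dtype=int)):
        lo = max(int(p) - (read_length - 1), 0)
        hi = min(int(p) + read_length, gene_length)
        if intervals and lo <= intervals[-1][1]:
            intervals[-1] = (intervals[-1][0], max(intervals[-1][1], hi))
        else:
            intervals.append((lo, hi))
    length = sum(hi - lo for lo, hi in intervals)
    return intervals, length


def annotate_informative(refs: HomeologReferenceSet, read_length: int) -> None:
    for r in refs.values():
        r.intervals, r.informative_length = informative_regions(
            r.disc_positions, read_length, len(r.p1_like)
        )


def mask_noninformative(refs: HomeologReferenceSet) -> int:
    """Hard-mask positions outside informative intervals in both references.

    Returns L, the cumulative haploid informative length over retained genes
    (the denominator of the dating calculation).
    """
    for r in refs.values():
        keep = np.zeros(len(r.p1_like), dtype=bool)
        for lo, hi in r.intervals:
            keep[lo:hi] = True
        r.p1_like[~keep] = N
        r.p2_like[~keep] = N
    return refs.cumulative_informative_length


def cull_genes(
    refs: HomeologReferenceSet,
    parent_counts: pd.DataFrame,
    min_parent_reads: int = 5,
    min_informative_len: int = 150,
) -> pd.DataFrame:
    """Apply the retention rules and record the reason for each culled gene.

    ``parent_counts`` columns: gene_id, p1_reads, p2_reads.  A gene is
    retained iff both parental read counts reach ``min_parent_reads`` and
    the informative footprint reaches ``min_informative_len`` (both bounds
    inclusive).
    """
    pc = parent_counts.set_index("gene_id")
    rows = []
    for g, r in refs.items():
        c1 = int(pc["p1_reads"].get(g, 0))
        c2 = int(pc["p2_reads"].get(g, 0))
        reasons = []
        if c1 < min_parent_reads or c2 < min_parent_reads:
            reasons.append("low_parent_expression")
        if r.informative_length < min_informative_len:
            reasons.append("short_informative")
        r.retained = not reasons
        r.cull_reason = ";".join(reasons)
        rows.append((g, c1, c2, r.informative_length, r.retained, r.cull_reason))
    return pd.DataFrame(
        rows,
        columns=["gene_id", "p1_reads", "p2_reads", "informative_length", "retained", "reason"],
    )
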