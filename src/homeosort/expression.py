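"""Zero-mismatch homeolog read assignment and expression statistics.

Allopolyploid fragments are mapped separately against the two masked
homeolog references; a fragment is counted for one homeolog of one gene only
when it aligns full-length with zero mismatches there and nowhere on the
other reference.  Because non-informative sequence is masked to 'N', a read
can only be assigned where it overlaps a discriminating position, and any
sequencing error renders a read unassignable rather than misassigned.

Statistics follow count-based RNA-seq practice: reads-per-million
normalization per assigned library, a fixed-orientation fold ratio
(parent-2 side over parent-1 side), Fisher's exact test on pooled counts,
and Storey-Tibshirani q-values.  Differential expression throughout requires
both significance (q below threshold) and at least a 2-fold difference.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .refs import HomeologReferenceSet
from .seqmap import KmerIndex
from .simulate import ReadSet

SOURCES = ("P1_ortholog", "P2_ortholog", "allo_P1", "allo_P2")


@dataclass
class CountTable:
    """Per-gene read counts for the four sources across replicates."""

    counts: pd.DataFrame  # index gene_id; columns MultiIndex (source, replicate)
    tallies: pd.DataFrame  # index (source, replicate); assigned/ambiguous/unassigned

    def pooled(self, source: str) -> pd.Series:
        """Replicate-summed counts for one source."""
        return self.counts[source].sum(axis=1)

    def library_total(self, source: str) -> int:
        """Total assigned reads of a source, pooled over replicates."""
        return int(self.tallies.loc[source, "assigned"].sum())


def _zero_mm_genes(index: KmerIndex, read: np.ndarray) -> set[str]:
    return {h.target_id for h in index.map_read(read, max_mismatch=0)}


def assign_reads(
    readset: ReadSet,
    index_p1: KmerIndex,
    index_p2: KmerIndex,
    gene_ids: list[str],
) -> tuple[pd.DataFrame, dict, pd.DataFrame]:
    """Assign allopolyploid fragments to homeologs at zero mismatches.

    Returns (per-gene counts for both homeologs, tally dict, per-fragment
    assignment table).  A fragment whose mates disagree, that matches both
    references, or that matches more than one gene is ambiguous; a fragment
    with no zero-mismatch match anywhere is unassigned.
    """
    c1 = dict.fromkeys(gene_ids, 0)
    c2 = dict.fromkeys(gene_ids, 0)
    tally = {"assigned": 0, "ambiguous": 0, "unassigned": 0}
    rows = []
    mates = [readset.reads1] + ([readset.reads2] if readset.reads2 is not None else [])
    n = readset.reads1.shape[0]
    for i in range(n):
        g1: set[str] | None = None
        g2: set[str] | None = None
        any1 = any2 = False
        for mate in mates:
            h1 = _zero_mm_genes(index_p1, mate[i])
            h2 = _zero_mm_genes(index_p2, mate[i])
            any1 |= bool(h1)
            any2 |= bool(h2)
            g1 = h1 if g1 is None else (g1 & h1)
            g2 = h2 if g2 is None else (g2 & h2)
        if not any1 and not any2:
            verdict = "unassigned"
        elif any1 and any2:
            verdict = "ambiguous"
        elif any1:
            verdict = ("P1", g1.pop()) if len(g1) == 1 else "ambiguous"
        else:
            verdict = ("P2", g2.pop()) if len(g2) == 1 else "ambiguous"
        if isinstance(verdict, tuple):
            side, gene = verdict
            (c1 if side == "P1" else c2)[gene] += 1
            tally["assigned"] += 1
            rows.append((i, side, gene))
        else:
            tally[verdict] += 1
            rows.append((i, verdict, ""))
    counts = pd.DataFrame(
        {"allo_P1": pd.Series(c1), "allo_P2": pd.Series(c2)}
    ).rename_axis("gene_id")
    detail = pd.DataFrame(rows, columns=["fragment", "assignment", "gene_id"])
    return counts, tally, detail


def count_parent_reads(
    readset: ReadSet, index: KmerIndex, gene_ids: list[str]
) -> tuple[pd.Series, dict]:
    """Count parental reads against the parent's own masked reference.

    Same zero-mismatch full-length rule; reads matching more than one gene
    are discarded as ambiguous.
    """
    counts = dict.fromkeys(gene_ids, 0)
    tally = {"assigned": 0, "ambiguous": 0, "unassigned": 0}
    for i in range(readset.reads1.shape[0]):
        genes = _zero_mm_genes(index, readset.reads1[i])
        if not genes:
            tally["unassigned"] += 1
        elif len(genes) > 1:
            tally["ambiguous"] += 1
        else:
            counts[genes.pop()] += 1
            tally["assigned"] += 1
    return pd.Series(counts, name="reads").rename_axis("gene_id"), tally


def build_count_table(
    refs: HomeologReferenceSet,
    parent1_reads: list[ReadSet],
    parent2_reads: list[ReadSet],
    allo_reads: list[ReadSet],
    k: int = 31,
) -> CountTable:
    """Run all assignments over replicates and assemble the count table."""
    retained = sorted(g for g, r in refs.items() if r.retained)
    seq_p1 = {g: refs[g].p1_like for g in retained}
    seq_p2 = {g: refs[g].p2_like for g in retained}
    index_p1 = KmerIndex(seq_p1, k=k)
    index_p2 = KmerIndex(seq_p2, k=k)

    cols, data, tall = [], [], []
    for rep, rs in enumerate(parent1_reads):
        c, t = count_parent_reads(rs, index_p1, retained)
        cols.append(("P1_ortholog", rep)), data.append(c), tall.append(
            (("P1_ortholog", rep), t)
        )
    for rep, rs in enumerate(parent2_reads):
        c, t = count_parent_reads(rs, index_p2, retained)
        cols.append(("P2_ortholog", rep)), data.append(c), tall.append(
            (("P2_ortholog", rep), t)
        )
    for rep, rs in enumerate(allo_reads):
        cc, t, _ = assign_reads(rs, index_p1, index_p2, retained)
        for side in ("allo_P1", "allo_P2"):
            cols.append((side, rep)), data.append(cc[side])
        t1 = {k_: (v if k_ != "assigned" else int(cc["allo_P1"].sum())) for k_, v in t.items()}
        t2 = {k_: (v if k_ != "assigned" else int(cc["allo_P2"].sum())) for k_, v in t.items()}
        tall.append((("allo_P1", rep), t1))
        tall.append((("allo_P2", rep), t2))
    counts = pd.concat(data, axis=1)
    counts.columns = pd.MultiIndex.from_tuples(cols, names=["source", "replicate"])
    tallies = pd.DataFrame(
        {key: t for key, t in tall}
    ).T.rename_axis(["source", "replicate"])
    return CountTable(counts=counts, tallies=tallies)


# ---------------------------------------------------------------------------
# statistics

def rpm_normalize(count, library_total):
    """Reads per million of the assigned library."""
    if np.any(np.asarray(library_total) <= 0):
        raise ValueError("library_total must be > 0")
    return np.asarray(count, dtype=float) * 1e6 / np.asarray(library_total, dtype=float)


def fold_difference(rpm_a: float, rpm_b: float) -> tuple[float, float, str]:
    """Fixed-orientation fold (side b over side a) plus symmetric magnitude.

    Returns (fold, magnitude, flag); flag is 'ok', 'one_sided' (one zero) or
    'undefined' (both zero).
    """
    if rpm_a < 0 or rpm_b < 0:
        raise ValueError("RPM values must be >= 0")
    if rpm_a == 0 and rpm_b == 0:
        return float("nan"), float("nan"), "undefined"
    if rpm_a == 0:
        return float("inf"), float("inf"), "one_sided"
    if rpm_b == 0:
        return 0.0, float("inf"), "one_sided"
    f = rpm_b / rpm_a
    return f, max(f, 1.0 / f), "ok"


def fisher_de(count_a: int, count_b: int, total_a: int, total_b: int) -> float:
    """Two-sided Fisher exact p for one gene's counts in two libraries."""
    if min(count_a, count_b, total_a, total_b) < 0:
        raise ValueError("negative values")
    if count_a > total_a or count_b > total_b:
        raise ValueError("totals must be >= counts")
    table = [[count_a, total_a - count_a], [count_b, total_b - count_b]]
    return float(stats.fisher_exact(table, alternative="two-sided")[1])


def qvalues(pvals) -> tuple[np.ndarray, float]:
    """Storey-Tibshirani q-values with smoother-based pi0 estimation.

    pi0(lambda) over the grid {0, 0.05, ..., 0.95} is smoothed with a cubic
    polynomial evaluated at lambda = 0.95 and clipped to (0, 1]; q-values
    are the usual step-up minimum of pi0 * m * p_(j) / j, monotone in p.
    """
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value list")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    lam = np.arange(0.0, 0.96, 0.05)
    pi0_lam = np.array([(p > L).sum() / (m * (1.0 - L)) for L in lam])
    if m < 8:
        pi0 = 1.0
    else:
        coef = np.polyfit(lam, pi0_lam, 3)
        pi0 = float(np.polyval(coef, 0.95))
    pi0 = min(max(pi0, 1.0 / m), 1.0)

    order = np.argsort(p, kind="mergesort")
    ranked = p[order]
    q_ranked = pi0 * m * ranked / np.arange(1, m + 1)
    q_ranked = np.minimum.accumulate(q_ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_ranked, 1.0)
    return q, pi0


def call_de(
    fold_magnitude: float, q: float, fold_thresh: float = 2.0, q_thresh: float = 0.05
) -> bool:
    """Differential expression: significance AND the biological fold criterion."""
    if np.isnan(fold_magnitude):
        return False
    return bool(fold_magnitude >= fold_thresh and q < q_thresh)


def _comparison(
    counts_a: pd.Series,
    counts_b: pd.Series,
    total_a: int,
    total_b: int,
    fold_thresh: float,
    q_thresh: float,
    prefix: str,
) -> pd.DataFrame:
    """Fisher + q + fold DE machinery for one pair of pooled libraries.

    Orientation: b over a (the parent-2 side is always the numerator).
    """
    rpm_a = rpm_normalize(counts_a, total_a)
    rpm_b = rpm_normalize(counts_b, total_b)
    folds, mags, flags = zip(
        *(fold_difference(a, b) for a, b in zip(rpm_a, rpm_b))
    )
    pv = np.array(
        [
            fisher_de(int(a), int(b), total_a, total_b)
            for a, b in zip(counts_a, counts_b)
        ]
    )
    qv, _ = qvalues(pv)
    de = np.array(
        [call_de(mg, q, fold_thresh, q_thresh) for mg, q in zip(mags, qv)]
    )
    direction = np.where(
        ~de, "equal", np.where(np.asarray(folds) > 1.0, "b_higher", "a_higher")
    )
    return pd.DataFrame(
        {
            f"rpm_a_{prefix}": rpm_a,
            f"rpm_b_{prefix}": rpm_b,
            f"fold_{prefix}": folds,
            f"foldmag_{prefix}": mags,
            f"flag_{prefix}": flags,
            f"p_{prefix}": pv,
            f"q_{prefix}": qv,
            f"de_{prefix}": de,
            f"dir_{prefix}": direction,
        },
        index=counts_a.index,
    )


def expression_table(
    ct: CountTable, fold_thresh: float = 2.0, q_thresh: float = 0.05
) -> pd.DataFrame:
    """Per-gene expression records for all comparisons the fate logic needs.

    Replicates are summed before testing.  Comparisons (a, b): parents
    (P1 ortholog, P2 ortholog); homeologs (allo P1, allo P2); combined
    homeolog expression vs each parent; each homeolog vs its own ortholog.
    """
    cp1 = ct.pooled("P1_ortholog")
    cp2 = ct.pooled("P2_ortholog")
    ch1 = ct.pooled("allo_P1")
    ch2 = ct.pooled("allo_P2")
    tp1 = ct.library_total("P1_ortholog")
    tp2 = ct.library_total("P2_ortholog")
    th1 = ct.library_total("allo_P1")
    th2 = ct.library_total("allo_P2")
    comb = ch1 + ch2
    tcomb = th1 + th2

    parts = [
        pd.DataFrame(
            {"count_p1": cp1, "count_p2": cp2, "count_h1": ch1, "count_h2": ch2}
        ),
        _comparison(cp1, cp2, tp1, tp2, fold_thresh, q_thresh, "parent"),
        _comparison(ch1, ch2, th1, th2, fold_thresh, q_thresh, "homeolog"),
        _comparison(cp1, comb, tp1, tcomb, fold_thresh, q_thresh, "comb_vs_p1"),
        _comparison(cp2, comb, tp2, tcomb, fold_thresh, q_thresh, "comb_vs_p2"),
        _comparison(cp1, ch1, tp1, th1, fold_thresh, q_thresh, "h1_vs_o1"),
        _comparison(cp2, ch2, tp2, th2, fold_thresh, q_thresh, "h2_vs_o2"),
    ]
    out = pd.concat(parts, axis=1)
    for comp in ("parent", "homeolog"):
        out[f"state_{comp}"] = np.select(
            [out[f"dir_{comp}"] == "b_higher", out[f"dir_{comp}"] == "a_higher"],
            ["P2_higher", "P1_higher"],
            default="equal",
        )
    return out.rename_axis("gene_id")


def log_ratio_columns(table: pd.DataFrame, pseudocount: float = 0.5) -> pd.DataFrame:
    """Heat-map-style log2 ratio export (pseudocounted, never infinite).

    Columns mirror the four panels used for extreme-expression inspection:
    homeolog ratio in the allopolyploid, ortholog ratio in the parents, and
    each homeolog against its own ortholog.
    """

    def lr(a, b):
        return np.log2((b + pseudocount) / (a + pseudocount))

    return pd.DataFrame(
        {
            "log2_homeolog": lr(table["rpm_a_homeolog"], table["rpm_b_homeolog"]),
            "log2_parent": lr(table["rpm_a_parent"], table["rpm_b_parent"]),
            "log2_h1_vs_o1": lr(table["rpm_a_h1_vs_o1"], table["rpm_b_h1_vs_o1"]),
            "log2_h2_vs_o2": lr(table["rpm_a_h2_vs_o2"], table["rpm_b_h2_vs_o2"]),
        },
        index=table.index,
    )
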