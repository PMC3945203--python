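"""Expression-fate classification of retained genes.

Each gene's parental state (which ortholog is higher, or equal) and
allopolyploid state (which homeolog is higher, or equal) place it in one of
nine categories, grouped into four outcomes: parental expression
inheritance (pattern unchanged), homeolog expression blending (parental
difference lost), homeolog expression bias (difference gained), and
homeolog expression reversal (difference flipped).  On top of that the
module flags expression-level dominance and its driving homeolog, extreme
differential expression (EDE), gene-loss candidates, physical EDE clusters,
and the regulatory-independence trichotomy.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .expression import call_de

STATES = ("equal", "P1_higher", "P2_higher")
OUTCOMES = ("inheritance", "blending", "bias", "reversal")

# (parent state, allo state) -> (nine-category code, outcome)
NINE_CATEGORIES = {
    ("equal", "equal"): (1, "inheritance"),
    ("P1_higher", "P1_higher"): (2, "inheritance"),
    ("P2_higher", "P2_higher"): (3, "inheritance"),
    ("P1_higher", "equal"): (4, "blending"),
    ("P2_higher", "equal"): (5, "blending"),
    ("equal", "P1_higher"): (6, "bias"),
    ("equal", "P2_higher"): (7, "bias"),
    ("P1_higher", "P2_higher"): (8, "reversal"),
    ("P2_higher", "P1_higher"): (9, "reversal"),
}


@dataclass
class EdeCluster:
    supercontig: str
    gene_ids: list[str]

    @property
    def size(self) -> int:
        return len(self.gene_ids)


def classify_nine(parent_state: str, allo_state: str) -> tuple[int, str]:
    """Nine-category code and outcome group for one gene."""
    if parent_state not in STATES or allo_state not in STATES:
        raise ValueError(f"unknown state: {parent_state!r}/{allo_state!r}")
    return NINE_CATEGORIES[(parent_state, allo_state)]


def outcome_proportions(fates: pd.DataFrame) -> pd.Series:
    """Fraction of classified genes per outcome group (sums to 1)."""
    frac = fates["outcome"].value_counts(normalize=True)
    return pd.Series({o: float(frac.get(o, 0.0)) for o in OUTCOMES})


def dominance_classify(row: pd.Series) -> str:
    """Expression-level dominance bin for one parent-DE gene.

    Combined homeolog expression is compared to each parent with the same
    fold + q machinery; indistinguishable from the high parent while
    different from the low parent is dominant_high, the converse
    dominant_low, anything else intermediate.
    """
    if row["state_parent"] == "equal":
        raise ValueError("dominance is defined only for parent-DE genes")
    high_is_p2 = row["state_parent"] == "P2_higher"
    de_vs_high = row["de_comb_vs_p2"] if high_is_p2 else row["de_comb_vs_p1"]
    de_vs_low = row["de_comb_vs_p1"] if high_is_p2 else row["de_comb_vs_p2"]
    if not de_vs_high and de_vs_low:
        return "dominant_high"
    if de_vs_high and not de_vs_low:
        return "dominant_low"
    return "intermediate"


def dominance_driver(row: pd.Series, dominance: str) -> str:
    """Did the non-dominant parent's homeolog change vs its own ortholog?"""
    if dominance not in ("dominant_high", "dominant_low"):
        return "not_applicable"
    high_is_p2 = row["state_parent"] == "P2_higher"
    # the dominant parent is the one the combined level matches
    dominant_is_p2 = high_is_p2 if dominance == "dominant_high" else not high_is_p2
    changed = row["de_h1_vs_o1"] if dominant_is_p2 else row["de_h2_vs_o2"]
    return "non_dominant_changed" if changed else "non_dominant_unchanged"


def find_ede(
    count_h1: int,
    count_h2: int,
    rpm_h1: float,
    rpm_h2: float,
    min_reads: int = 5,
    fold_thresh: float = 50.0,
) -> str:
    """Extreme differential expression flag for one gene.

    Among genes with at least ``min_reads`` allopolyploid reads: zero reads
    from exactly one homeolog is ``one_sided``; otherwise an RPM ratio of
    ``fold_thresh`` or more in either direction is ``fold50``.
    """
    if count_h1 + count_h2 < min_reads:
        return "none"
    if (count_h1 == 0) != (count_h2 == 0):
        return "one_sided"
    if rpm_h1 > 0 and rpm_h2 > 0:
        mag = max(rpm_h1 / rpm_h2, rpm_h2 / rpm_h1)
        if mag >= fold_thresh:
            return "fold50"
    return "none"


def loss_candidates(counts: pd.DataFrame) -> tuple[pd.Series, dict]:
    """Gene-loss candidate flags from raw homeolog counts (no read floor).

    (0, 0) -> both_silent; (>0, 0) -> P2_only (the silent side names the
    flag); (0, >0) -> P1_only.  Returns per-gene flags and summary totals,
    including the detection rate (share of genes with any homeolog read).
    """
    h1 = counts["allo_P1"]
    h2 = counts["allo_P2"]
    flags = pd.Series(
        np.select(
            [(h1 == 0) & (h2 == 0), (h1 > 0) & (h2 == 0), (h1 == 0) & (h2 > 0)],
            ["both_silent", "P2_only", "P1_only"],
            default="none",
        ),
        index=counts.index,
        name="loss_candidate",
    )
    n = len(flags)
    vc = flags.value_counts()
    totals = {k: int(vc.get(k, 0)) for k in ("both_silent", "P1_only", "P2_only")}
    totals["total_candidates"] = sum(totals.values())
    totals["n_genes"] = n
    totals["detection_rate_pct"] = 100.0 * (n - totals["both_silent"]) / n if n else float("nan")
    return flags, totals


def cluster_ede(
    coords: pd.DataFrame, ede_flags: pd.Series, retained: pd.Series
) -> list[EdeCluster]:
    """Maximal runs of >= 2 physically adjacent EDE genes per supercontig.

    Genes culled from the analysis carry no expression information and are
    transparent: they do not break a run.  Retained non-EDE genes do.
    """
    clusters: list[EdeCluster] = []
    for sc, grp in coords.sort_values(["supercontig", "start"]).groupby("supercontig"):
        run: list[str] = []
        for gid in grp["gene_id"]:
            if not bool(retained.get(gid, False)):
                continue  # culled genes are transparent
            if ede_flags.get(gid, "none") != "none":
                run.append(gid)
            else:
                if len(run) >= 2:
                    clusters.append(EdeCluster(sc, run))
                run = []
        if len(run) >= 2:
            clusters.append(EdeCluster(sc, run))
    return clusters


def clustered_fraction(clusters: list[EdeCluster], n_ede: int) -> float:
    """Percentage of EDE genes falling inside physical clusters."""
    if n_ede == 0:
        return float("nan")
    return 100.0 * sum(c.size for c in clusters) / n_ede


def independence_proportions(
    fates: pd.DataFrame, treatment: str = "exclude_unbiased"
) -> dict:
    """Regulatory-independence trichotomy since the parental speciation.

    Genes inheriting *biased* expression have evolved fully independent
    regulation; bias genes partial independence; blending genes none.
    Genes unbiased in both parents and allopolyploid are handled per
    ``treatment``: excluded from the denominator, counted as independent, or
    counted as non-independent.  Reversal genes are reported separately.
    """
    if treatment not in (
        "exclude_unbiased",
        "unbiased_as_independent",
        "unbiased_as_nonindependent",
    ):
        raise ValueError(f"unknown treatment {treatment!r}")
    biased_inherit = int(((fates["outcome"] == "inheritance") & (fates["nine_category"] != 1)).sum())
    unbiased = int((fates["nine_category"] == 1).sum())
    partial = int((fates["outcome"] == "bias").sum())
    none = int((fates["outcome"] == "blending").sum())
    reversal = int((fates["outcome"] == "reversal").sum())

    full = biased_inherit
    if treatment == "unbiased_as_independent":
        full += unbiased
    elif treatment == "unbiased_as_nonindependent":
        none += unbiased
    denom = full + partial + none
    if treatment == "exclude_unbiased":
        pass  # unbiased genes simply do not enter the denominator
    if denom == 0:
        props = (float("nan"),) * 3
    else:
        props = (full / denom, partial / denom, none / denom)
    return {
        "full": props[0],
        "partial": props[1],
        "none": props[2],
        "n_reversal_excluded": reversal,
        "treatment": treatment,
    }


def classify_fates(
    table: pd.DataFrame,
    min_ede_reads: int = 5,
    ede_fold: float = 50.0,
) -> pd.DataFrame:
    """Full per-gene fate calls from an expression table.

    Adds nine-category code, outcome, dominance class and driver, EDE flag
    and loss-candidate flag for every gene in the table.
    """
    recs = []
    for gid, row in table.iterrows():
        cat, outcome = classify_nine(row["state_parent"], row["state_homeolog"])
        if row["state_parent"] != "equal":
            dom = dominance_classify(row)
            driver = dominance_driver(row, dom)
        else:
            dom, driver = "not_applicable", "not_applicable"
        ede = find_ede(
            int(row["count_h1"]),
            int(row["count_h2"]),
            row["rpm_a_homeolog"],
            row["rpm_b_homeolog"],
            min_reads=min_ede_reads,
            fold_thresh=ede_fold,
        )
        recs.append((gid, row["state_parent"], row["state_homeolog"], cat, outcome, dom, driver, ede))
    fates = pd.DataFrame(
        recs,
        columns=[
            "gene_id",
            "state_parent",
            "state_homeolog",
            "nine_category",
            "outcome",
            "dominance",
            "driver",
            "ede",
        ],
    ).set_index("gene_id")
    counts = table[["count_h1", "count_h2"]].rename(
        columns={"count_h1": "allo_P1", "count_h2": "allo_P2"}
    )
    flags, _ = loss_candidates(counts)
    fates["loss_candidate"] = flags
    return fates
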