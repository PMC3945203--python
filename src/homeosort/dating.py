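"""Molecular dating of the hybridization event from lineage-specific SNPs.

Parent-private SNP counts accumulate along each parental branch since the
allopolyploid lineage split off; under a molecular clock the count S on the
*shortest* parental branch, over the cumulative haploid informative length
L and mutation rate mu, bounds the hybridization time from above:
T = S / (L * mu).  No lower bound is possible from these data — every
parent-private SNP may predate or postdate hybridization.
"""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class DatingInputs:
    """S: SNPs on the shortest parental branch; L: masked informative bp;
    mu: substitutions per site per year."""

    S: int
    L: int
    mu: float

    def __post_init__(self) -> None:
        if self.S < 0:
            raise ValueError("S must be >= 0")
        if self.L <= 0:
            raise ValueError("L must be > 0")
        if self.mu <= 0:
            raise ValueError("mu must be > 0")


def date_upper_bound(inputs: DatingInputs) -> dict:
    """Upper bound T = S / (L * mu), with a headline value rounded to the
    nearest 100,000 years."""
    t = inputs.S / (inputs.L * inputs.mu)
    return {
        "S": inputs.S,
        "L": inputs.L,
        "mu": inputs.mu,
        "T_years": t,
        "T_report": int(round(t / 100_000.0) * 100_000),
        "bound": "upper",
    }


def shortest_branch_snps(class_counts) -> int:
    """Pick S automatically as min(p1_unique, p2_unique)."""
    return int(min(class_counts["p1_unique"], class_counts["p2_unique"]))
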