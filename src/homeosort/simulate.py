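"""Synthetic allopolyploid transcriptome generator with ground truth.

The generator emulates the study design the rest of the pipeline assumes:
a surrogate reference gene set (a well-annotated relative of both parents),
two haploid parental transcriptomes at strongly asymmetric divergence from
that reference (one close, one roughly an order of magnitude farther), and
an allopolyploid that carries the union of the two parental subgenomes plus
private post-hybridization substitutions and clustered single-subgenome gene
deletions.  Expression fates (inheritance / blending / bias / reversal) are
drawn per gene from configurable proportions, and sequencing reads are
emitted with a per-read ground-truth sidecar so every downstream stage can
be scored exactly.

All randomness flows from one master seed through named per-stage child
generators (see :func:`homeosort._seq.stage_rng`), so a fixed seed gives
byte-identical outputs and individual stages are reproducible in isolation.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from ._seq import decode, encode, random_seq, stage_rng

LINEAGES = ("ancestral", "p1_branch", "p2_branch", "allo_p1_branch", "allo_p2_branch")
FATES = ("inheritance", "blending", "bias", "reversal")

SUBGENOME_SEP = "::"


def transcript_id(gene_id: str, subgenome: str) -> str:
    return f"{gene_id}{SUBGENOME_SEP}{subgenome}"


def split_transcript_id(tid: str) -> tuple[str, str]:
    gene, _, sub = tid.partition(SUBGENOME_SEP)
    return gene, sub


@dataclass
class SimConfig:
    """Parameters of one synthetic experiment.

    Divergences and post-hybridization rates are substitutions per site on
    the respective branch; ``fate_proportions`` are weights for
    (inheritance, blending, bias, reversal); ``library_sizes`` are reads
    (fragments when paired) per replicate for (parent1, parent2,
    allopolyploid).  Parents are sequenced single-end, the allopolyploid
    paired-end when ``paired`` is set, mirroring the study design the
    pipeline targets.
    """

    n_genes: int = 300
    gene_length_mean: float = 1200.0
    gene_length_sd: float = 250.0
    min_gene_length: int = 300
    genes_per_supercontig: int = 25
    intergenic_gap: int = 500
    divergence_ancestral: float = 0.0015
    divergence_close: float = 0.004
    divergence_far: float = 0.03
    post_hyb_subs_p1: float = 5e-4
    post_hyb_subs_p2: float = 5e-4
    n_deletion_clusters: int = 2
    deletion_cluster_size: int = 3
    fate_proportions: tuple[float, float, float, float] = (0.561, 0.251, 0.156, 0.032)
    inheritance_bias_frac: float = 0.25
    bias_log2_effect: float = 2.0
    expr_log2_mean: float = 6.0
    expr_log2_sd: float = 1.5
    library_sizes: tuple[int, int, int] = (60_000, 60_000, 120_000)
    n_replicates: int = 2
    read_length: int = 100
    paired: bool = True
    fragment_length: int = 250
    error_rate: float = 0.001
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 1:
            raise ValueError("n_genes must be >= 1")
        if self.gene_length_mean <= 0 or self.min_gene_length <= 0:
            raise ValueError("gene lengths must be positive")
        rates = (
            self.divergence_ancestral,
            self.divergence_close,
            self.divergence_far,
            self.post_hyb_subs_p1,
            self.post_hyb_subs_p2,
            self.error_rate,
        )
        if any(not (0.0 <= r < 1.0) for r in rates):
            raise ValueError("all per-site rates must lie in [0, 1)")
        if any(w < 0 for w in self.fate_proportions) or sum(self.fate_proportions) <= 0:
            raise ValueError("fate_proportions must be nonnegative with positive sum")
        if self.bias_log2_effect <= 0:
            raise ValueError("bias_log2_effect must be > 0")
        if self.n_genes < self.n_deletion_clusters * self.deletion_cluster_size:
            raise ValueError("deletion clusters do not fit into the gene set")
        if any(n < 0 for n in self.library_sizes):
            raise ValueError("library sizes must be >= 0")

    @property
    def fate_probs(self) -> np.ndarray:
        w = np.asarray(self.fate_proportions, dtype=float)
        return w / w.sum()

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, sort_keys=True)


@dataclass
class GeneSet:
    """Surrogate reference: transcript sequences plus supercontig layout."""

    ids: list[str]
    seqs: dict[str, np.ndarray]
    coords: pd.DataFrame  # gene_id, supercontig, start, end, strand

    def length(self, gene_id: str) -> int:
        return len(self.seqs[gene_id])

    @property
    def total_length(self) -> int:
        return sum(len(s) for s in self.seqs.values())


@dataclass
class Genomes:
    """Per-lineage transcript sequences (deleted genes absent from a dict)."""

    parent1: dict[str, np.ndarray]
    parent2: dict[str, np.ndarray]
    allo_p1: dict[str, np.ndarray]
    allo_p2: dict[str, np.ndarray]


@dataclass
class ReadSet:
    """Reads for one library plus the per-read truth-of-origin sidecar."""

    reads1: np.ndarray  # (n, read_length) uint8
    reads2: np.ndarray | None  # mate 2 for paired libraries
    origins: pd.DataFrame  # read_index, transcript, start, strand

    def __len__(self) -> int:
        return self.reads1.shape[0]


@dataclass
class SimTruth:
    variants: pd.DataFrame  # gene_id, position, ref, alt, lineage
    expression: pd.DataFrame  # per-gene fates, rhos and expression levels
    deletions: pd.DataFrame  # gene_id, subgenome, cluster_id


@dataclass
class SimData:
    config: SimConfig
    genes: GeneSet
    genomes: Genomes
    truth: SimTruth
    reads: dict[str, list[ReadSet]] = field(default_factory=dict)


def simulate_gene_set(cfg: SimConfig) -> GeneSet:
    """Draw random transcript sequences and lay them out on supercontigs.

    Coordinates are 0-based half-open, genes in order separated by a fixed
    intergenic gap; they exist solely to support physical-cluster analysis.
    """
    rng = stage_rng(cfg.seed, "gene_set")
    lengths = np.maximum(
        np.round(rng.normal(cfg.gene_length_mean, cfg.gene_length_sd, cfg.n_genes)),
        cfg.min_gene_length,
    ).astype(int)
    ids = [f"g{i + 1:05d}" for i in range(cfg.n_genes)]
    seqs = {gid: random_seq(rng, int(L)) for gid, L in zip(ids, lengths)}

    rows = []
    for i, (gid, L) in enumerate(zip(ids, lengths)):
        sc = f"sc{i // cfg.genes_per_supercontig + 1:03d}"
        rank = i % cfg.genes_per_supercontig
        start = rank * (cfg.intergenic_gap + int(cfg.gene_length_mean)) + (
            0 if rank == 0 else 0
        )
        # genes are laid out end-to-end with a fixed gap; start positions are
        # recomputed from cumulative gene lengths within the supercontig
        rows.append([gid, sc, rank, int(L)])
    coords = pd.DataFrame(rows, columns=["gene_id", "supercontig", "rank", "length"])
    starts = []
    for sc, grp in coords.groupby("supercontig", sort=False):
        pos = 0
        for L in grp["length"]:
            starts.append(pos)
            pos += int(L) + cfg.intergenic_gap
    coords["start"] = starts
    coords["end"] = coords["start"] + coords["length"]
    coords["strand"] = "+"
    coords = coords[["gene_id", "supercontig", "start", "end", "strand"]]
    return GeneSet(ids=ids, seqs=seqs, coords=coords)


def _mutate(
    rng: np.random.Generator, length: int, rates: dict[str, float]
) -> dict[str, np.ndarray]:
    """Draw disjoint substitution position sets, one per branch.

    Counts per branch are Binomial(length, rate); positions are then taken
    from a single permutation of the sites so that no site mutates on more
    than one branch (the bi-allelic-per-lineage simplification).
    """
    counts = {br: rng.binomial(length, r) for br, r in rates.items()}
    if sum(counts.values()) > length:
        raise ValueError("substitution rates too high for gene length")
    perm = rng.permutation(length)
    out, i = {}, 0
    for br in rates:  # insertion order fixed by LINEAGES
        n = counts[br]
        out[br] = np.sort(perm[i : i + n])
        i += n
    return out


def evolve_lineages(genes: GeneSet, cfg: SimConfig) -> tuple[Genomes, pd.DataFrame]:
    """Place substitutions on the five branches of the lineage tree.

    The ancestral branch is shared by both parents and the allopolyploid;
    each parent has a private branch; each allopolyploid subgenome has a
    private post-hybridization branch on top of its parent's sequence.
    """
    rng = stage_rng(cfg.seed, "lineages")
    rates = {
        "ancestral": cfg.divergence_ancestral,
        "p1_branch": cfg.divergence_close,
        "p2_branch": cfg.divergence_far,
        "allo_p1_branch": cfg.post_hyb_subs_p1,
        "allo_p2_branch": cfg.post_hyb_subs_p2,
    }
    parent1, parent2, allo1, allo2 = {}, {}, {}, {}
    recs: list[tuple[str, int, str, str, str]] = []
    for gid in genes.ids:
        ref = genes.seqs[gid]
        pos_by_branch = _mutate(rng, len(ref), rates)
        alts: dict[str, np.ndarray] = {}
        for br, pos in pos_by_branch.items():
            alt = (ref[pos] + rng.integers(1, 4, size=len(pos)).astype(np.uint8)) % 4
            alts[br] = alt
            for p, a in zip(pos.tolist(), alt.tolist()):
                recs.append((gid, p, "ACGTN"[ref[p]], "ACGTN"[a], br))
        p1 = ref.copy()
        for br in ("ancestral", "p1_branch"):
            p1[pos_by_branch[br]] = alts[br]
        p2 = ref.copy()
        for br in ("ancestral", "p2_branch"):
            p2[pos_by_branch[br]] = alts[br]
        a1 = p1.copy()
        a1[pos_by_branch["allo_p1_branch"]] = alts["allo_p1_branch"]
        a2 = p2.copy()
        a2[pos_by_branch["allo_p2_branch"]] = alts["allo_p2_branch"]
        parent1[gid], parent2[gid], allo1[gid], allo2[gid] = p1, p2, a1, a2
    variants = pd.DataFrame(
        recs, columns=["gene_id", "position", "ref", "alt", "lineage"]
    )
    return Genomes(parent1, parent2, allo1, allo2), variants


def apply_deletions(
    genomes: Genomes, genes: GeneSet, cfg: SimConfig
) -> tuple[Genomes, pd.DataFrame]:
    """Delete clustered runs of adjacent genes from one subgenome each.

    Each cluster is a run of ``deletion_cluster_size`` genes adjacent on one
    supercontig, removed from exactly one allopolyploid subgenome (mimicking
    a single large genomic deletion).  Clusters never overlap.
    """
    rng = stage_rng(cfg.seed, "deletions")
    recs = []
    if cfg.n_deletion_clusters > 0:
        order = genes.coords.sort_values(["supercontig", "start"])
        taken: set[str] = set()
        by_sc = {sc: list(grp["gene_id"]) for sc, grp in order.groupby("supercontig")}
        scs = [sc for sc, g in by_sc.items() if len(g) >= cfg.deletion_cluster_size]
        if not scs:
            raise ValueError("no supercontig can hold a deletion cluster")
        for ci in range(cfg.n_deletion_clusters):
            for _ in range(1000):
                sc = scs[rng.integers(len(scs))]
                gl = by_sc[sc]
                s = int(rng.integers(0, len(gl) - cfg.deletion_cluster_size + 1))
                run = gl[s : s + cfg.deletion_cluster_size]
                if not taken.intersection(run):
                    break
            else:
                raise ValueError("could not place non-overlapping deletion clusters")
            taken.update(run)
            sub = "P1" if rng.random() < 0.5 else "P2"
            target = genomes.allo_p1 if sub == "P1" else genomes.allo_p2
            for gid in run:
                del target[gid]
                recs.append((gid, sub, ci))
    deletions = pd.DataFrame(recs, columns=["gene_id", "subgenome", "cluster_id"])
    return genomes, deletions


def assign_expression_fates(
    genes: GeneSet, cfg: SimConfig, deletions: pd.DataFrame | None = None
) -> pd.DataFrame:
    """Sample per-gene fate categories and set true expression levels.

    rho_P = log2(parent2/parent1 ortholog expression); rho_H = the same for
    the allopolyploid homeologs.  inheritance: rho_H = rho_P with rho_P in
    {0, +-effect}; blending: |rho_P| = effect, rho_H = 0; bias: rho_P = 0,
    |rho_H| = effect; reversal: rho_H = -rho_P with |rho_P| = effect.  Total
    allopolyploid expression is the parental mean; deleted homeologs get
    zero expression regardless of category.
    """
    rng = stage_rng(cfg.seed, "fates")
    n = cfg.n_genes
    e = cfg.bias_log2_effect
    cats = rng.choice(len(FATES), size=n, p=cfg.fate_probs)
    signs = np.where(rng.random(n) < 0.5, 1.0, -1.0)
    rho_p = np.zeros(n)
    rho_h = np.zeros(n)
    inherit_biased = rng.random(n) < cfg.inheritance_bias_frac
    for i, c in enumerate(cats):
        fate = FATES[c]
        if fate == "inheritance":
            rho_p[i] = signs[i] * e if inherit_biased[i] else 0.0
            rho_h[i] = rho_p[i]
        elif fate == "blending":
            rho_p[i], rho_h[i] = signs[i] * e, 0.0
        elif fate == "bias":
            rho_p[i], rho_h[i] = 0.0, signs[i] * e
        else:  # reversal
            rho_p[i] = signs[i] * e
            rho_h[i] = -rho_p[i]
    base = np.exp2(rng.normal(cfg.expr_log2_mean, cfg.expr_log2_sd, n))
    p1 = base * np.exp2(-rho_p / 2)
    p2 = base * np.exp2(rho_p / 2)
    total = (p1 + p2) / 2.0
    h1 = total / (1.0 + np.exp2(rho_h))
    h2 = total - h1
    df = pd.DataFrame(
        {
            "gene_id": genes.ids,
            "category": [FATES[c] for c in cats],
            "rho_parent": rho_p,
            "rho_homeolog": rho_h,
            "expr_p1": p1,
            "expr_p2": p2,
            "expr_allo_p1": h1,
            "expr_allo_p2": h2,
            "deleted_p1": False,
            "deleted_p2": False,
        }
    )
    if deletions is not None and len(deletions):
        for _, row in deletions.iterrows():
            col = "deleted_p1" if row["subgenome"] == "P1" else "deleted_p2"
            df.loc[df["gene_id"] == row["gene_id"], col] = True
        df.loc[df["deleted_p1"], "expr_allo_p1"] = 0.0
        df.loc[df["deleted_p2"], "expr_allo_p2"] = 0.0
    return df


def simulate_reads(
    transcripts: dict[str, np.ndarray],
    expression: dict[str, float],
    n_reads: int,
    cfg: SimConfig,
    rng: np.random.Generator,
    paired: bool = False,
) -> ReadSet:
    """Draw a sequencing library from weighted transcripts with truth sidecar.

    Fragments are multinomial across transcripts with weight expression x
    effective length, positions uniform, strands fair, and i.i.d. base
    errors at ``error_rate``.  Paired mode emits proper FR mate pairs from a
    single fragment.
    """
    rl = cfg.read_length
    tids = [t for t in transcripts if expression.get(t, 0.0) > 0]
    if n_reads > 0:
        short = [t for t in tids if len(transcripts[t]) < rl]
        if short:
            raise ValueError(f"read_length {rl} exceeds transcript length for {short[0]}")
    spans = {t: min(cfg.fragment_length, len(transcripts[t])) if paired else rl for t in tids}
    w = np.array(
        [expression[t] * (len(transcripts[t]) - spans[t] + 1) for t in tids], dtype=float
    )
    r1_parts, r2_parts, origin_parts = [], [], []
    if n_reads > 0 and w.sum() > 0:
        counts = rng.multinomial(n_reads, w / w.sum())
        for t, c in zip(tids, counts):
            if c == 0:
                continue
            seq = transcripts[t]
            span = spans[t]
            starts = rng.integers(0, len(seq) - span + 1, size=c)
            minus = rng.random(c) < 0.5
            frags = seq[starts[:, None] + np.arange(span)]
            comp = np.array([3, 2, 1, 0, 4], dtype=np.uint8)
            frags[minus] = comp[frags[minus]][:, ::-1]
            r1 = frags[:, :rl].copy()
            if paired:
                r2 = comp[frags[:, span - rl :]][:, ::-1].copy()
            else:
                r2 = None
            for arr in (r1,) if r2 is None else (r1, r2):
                if cfg.error_rate > 0:
                    err = rng.random(arr.shape) < cfg.error_rate
                    arr[err] = (arr[err] + rng.integers(1, 4, size=int(err.sum()))) % 4
            r1_parts.append(r1)
            if paired:
                r2_parts.append(r2)
            origin_parts.append(
                pd.DataFrame(
                    {
                        "transcript": t,
                        "start": starts,
                        "strand": np.where(minus, "-", "+"),
                    }
                )
            )
    if r1_parts:
        reads1 = np.concatenate(r1_parts)
        reads2 = np.concatenate(r2_parts) if paired else None
        origins = pd.concat(origin_parts, ignore_index=True)
    else:
        reads1 = np.empty((0, rl), dtype=np.uint8)
        reads2 = np.empty((0, rl), dtype=np.uint8) if paired else None
        origins = pd.DataFrame(columns=["transcript", "start", "strand"])
    origins.insert(0, "read_index", np.arange(len(origins)))
    return ReadSet(reads1=reads1, reads2=reads2, origins=origins)


def simulate_experiment(cfg: SimConfig) -> SimData:
    """Run the full generator: gene set, lineages, deletions, fates, reads."""
    genes = simulate_gene_set(cfg)
    genomes, variants = evolve_lineages(genes, cfg)
    genomes, deletions = apply_deletions(genomes, genes, cfg)
    expression = assign_expression_fates(genes, cfg, deletions)
    truth = SimTruth(variants=variants, expression=expression, deletions=deletions)

    expr = expression.set_index("gene_id")
    data = SimData(config=cfg, genes=genes, genomes=genomes, truth=truth)
    lib_p1, lib_p2, lib_allo = cfg.library_sizes

    p1_tx = {transcript_id(g, "P1"): s for g, s in genomes.parent1.items()}
    p1_ex = {transcript_id(g, "P1"): float(expr.at[g, "expr_p1"]) for g in genomes.parent1}
    p2_tx = {transcript_id(g, "P2"): s for g, s in genomes.parent2.items()}
    p2_ex = {transcript_id(g, "P2"): float(expr.at[g, "expr_p2"]) for g in genomes.parent2}
    al_tx = {transcript_id(g, "P1"): s for g, s in genomes.allo_p1.items()}
    al_tx.update({transcript_id(g, "P2"): s for g, s in genomes.allo_p2.items()})
    al_ex = {transcript_id(g, "P1"): float(expr.at[g, "expr_allo_p1"]) for g in genomes.allo_p1}
    al_ex.update(
        {transcript_id(g, "P2"): float(expr.at[g, "expr_allo_p2"]) for g in genomes.allo_p2}
    )

    data.reads = {"p1": [], "p2": [], "allo": []}
    for rep in range(cfg.n_replicates):
        rng1 = stage_rng(cfg.seed, f"reads_p1_rep{rep}")
        rng2 = stage_rng(cfg.seed, f"reads_p2_rep{rep}")
        rnga = stage_rng(cfg.seed, f"reads_allo_rep{rep}")
        data.reads["p1"].append(simulate_reads(p1_tx, p1_ex, lib_p1, cfg, rng1, paired=False))
        data.reads["p2"].append(simulate_reads(p2_tx, p2_ex, lib_p2, cfg, rng2, paired=False))
        data.reads["allo"].append(
            simulate_reads(al_tx, al_ex, lib_allo, cfg, rnga, paired=cfg.paired)
        )
    return data


# ---------------------------------------------------------------------------
# text-format export helpers (used by the CLI)

def write_fasta(seqs: dict[str, np.ndarray], path) -> None:
    from Bio import SeqIO
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord

    records = [SeqRecord(Seq(decode(arr)), id=name, description="") for name, arr in seqs.items()]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path) -> dict[str, np.ndarray]:
    from Bio import SeqIO

    return {rec.id: encode(str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")}


def phred_char(error_rate: float) -> str:
    q = min(int(round(-10 * math.log10(max(error_rate, 1e-6)))), 40)
    return chr(33 + q)


def write_fastq(readset: ReadSet, prefix, error_rate: float) -> list[str]:
    """Write a ReadSet as one (single-end) or two (paired) FASTQ files."""
    qc = phred_char(error_rate)
    paths = []
    mates = [readset.reads1] + ([readset.reads2] if readset.reads2 is not None else [])
    for mi, arr in enumerate(mates, start=1):
        path = f"{prefix}_R{mi}.fastq" if len(mates) > 1 else f"{prefix}.fastq"
        with open(path, "w") as fh:
            qual = qc * arr.shape[1] if arr.size else ""
            for i in range(arr.shape[0]):
                fh.write(f"@r{i}/{mi}\n{decode(arr[i])}\n+\n{qual}\n")
        paths.append(path)
    return paths


def read_fastq(path, rl: int | None = None) -> np.ndarray:
    import pysam

    seqs = [encode(e.sequence) for e in pysam.FastxFile(str(path))]
    if not seqs:
        return np.empty((0, rl or 0), dtype=np.uint8)
    return np.vstack(seqs)
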