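"""Minimal self-contained read mapper: k-mer seeded, ungapped, mismatch-bounded.

The pipeline's discrimination between homeologs is SNP-based, and its
simulated data contain no indels, so ungapped full-length alignment is
sufficient and lets the pipeline run with no external aligner.  Reads are
partitioned into ``floor(len/k)`` non-overlapping seeds; by the pigeonhole
principle every alignment with at most ``max_mismatch`` mismatches admits an
exact seed whenever ``floor(len/k) > max_mismatch``, which makes the mapper
complete in that regime (asserted against a brute-force oracle in the test
suite).  Externally produced alignments can be imported from SAM instead.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from ._seq import N, revcomp

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class Hit:
    """An ungapped full-length alignment of a read on a target."""

    target_id: str
    position: int  # 0-based offset of the read start on the target
    strand: str  # '+' or '-'
    mismatches: int


class KmerIndex:
    """Exact k-mer index over a set of target sequences.

    Targets are encoded uint8 arrays; k-mers containing 'N' are not indexed
    (masked reference stretches are therefore unreachable by seeds, and 'N'
    never matches during verification either).
    """

    def __init__(self, targets: dict[str, np.ndarray], k: int = 13):
        if not targets:
            raise ValueError("targets must be nonempty")
        if k < 8:
            raise ValueError("seed length k must be >= 8")
        if k > 31:
            raise ValueError("seed length k must be <= 31 (64-bit k-mer codes)")
        shortest = min(len(t) for t in targets.values())
        if k > shortest:
            raise ValueError(f"k={k} exceeds shortest target length {shortest}")
        self.k = int(k)
        # store targets sorted by id so mapping is independent of insertion order
        self.targets: dict[str, np.ndarray] = {
            tid: np.ascontiguousarray(targets[tid], dtype=np.uint8)
            for tid in sorted(targets)
        }
        self._pow = (4 ** np.arange(self.k, dtype=np.uint64))[::-1].copy()
        self._index: dict[int, list[tuple[str, int]]] = {}
        for tid, seq in self.targets.items():
            if len(seq) < self.k:
                continue
            win = np.lib.stride_tricks.sliding_window_view(seq, self.k)
            codes = win.astype(np.uint64) @ self._pow
            has_n = np.convolve((seq == N).astype(np.int32), np.ones(self.k, np.int32))[
                self.k - 1 : len(seq)
            ]
            for pos in np.flatnonzero(has_n == 0):
                self._index.setdefault(int(codes[pos]), []).append((tid, int(pos)))

    def _code(self, kmer: np.ndarray) -> int | None:
        if (kmer == N).any():
            return None
        return int(kmer.astype(np.uint64) @ self._pow)

    def lookup(self, kmer: np.ndarray) -> list[tuple[str, int]]:
        """Posting list for one k-mer (encoded uint8 array of length k)."""
        code = self._code(kmer)
        if code is None:
            return []
        return self._index.get(code, [])

    def map_read(self, read: np.ndarray, max_mismatch: int = 0) -> list[Hit]:
        """Return all full-length ungapped hits with <= max_mismatch mismatches.

        Both strands are searched.  Completeness holds when
        ``floor(len(read)/k) > max_mismatch`` (pigeonhole seeding).
        """
        if len(read) == 0:
            raise ValueError("empty read")
        hits: list[Hit] = []
        seen: set[tuple[str, int, str]] = set()
        for strand, seq in (("+", read), ("-", revcomp(read))):
            L = len(seq)
            n_seeds = L // self.k
            for si in range(n_seeds):
                off = si * self.k
                code = self._code(seq[off : off + self.k])
                if code is None:
                    continue
                for tid, tpos in self._index.get(code, ()):
                    start = tpos - off
                    target = self.targets[tid]
                    if start < 0 or start + L > len(target):
                        continue
                    sig = (tid, start, strand)
                    if sig in seen:
                        continue
                    seen.add(sig)
                    mm = int(np.count_nonzero(target[start : start + L] != seq))
                    if mm <= max_mismatch:
                        hits.append(Hit(tid, start, strand, mm))
        hits.sort(key=lambda h: (h.mismatches, h.target_id, h.position, h.strand))
        return hits


def best_gene_hit(
    hits: list[Hit], gene_of: dict[str, str] | None = None
) -> Hit | None:
    """Resolve a hit list to a single best gene, or None when ambiguous.

    Hits at the equal best mismatch count that fall on more than one gene
    discard the read (avoids paralog-inflated evidence); ties within one
    gene keep the first hit and count the gene once.
    """
    if not hits:
        return None
    best_mm = hits[0].mismatches
    best = [h for h in hits if h.mismatches == best_mm]
    genes = {gene_of[h.target_id] if gene_of else h.target_id for h in best}
    if len(genes) > 1:
        return None
    return best[0]


def brute_force_map(
    targets: dict[str, np.ndarray], read: np.ndarray, max_mismatch: int
) -> list[Hit]:
    """All-offsets exhaustive scan; the independent oracle for map_read."""
    out = []
    for strand, seq in (("+", read), ("-", revcomp(read))):
        L = len(seq)
        for tid in sorted(targets):
            t = targets[tid]
            if len(t) < L:
                continue
            windows = np.lib.stride_tricks.sliding_window_view(t, L)
            mms = (windows != seq).sum(axis=1)
            for start in np.flatnonzero(mms <= max_mismatch):
                out.append(Hit(tid, int(start), strand, int(mms[start])))
    out.sort(key=lambda h: (h.mismatches, h.target_id, h.position, h.strand))
    return out


# ---------------------------------------------------------------------------
# SAM import/export (ungapped subset)

def write_sam(
    hits: list[tuple[str, np.ndarray, Hit]], targets: dict[str, np.ndarray], path
) -> None:
    """Write (read_name, read_seq, Hit) records as SAM v1 with NM tags."""
    import pysam

    from ._seq import decode

    tids = sorted(targets)
    header = {
        "HD": {"VN": "1.6", "SO": "unknown"},
        "SQ": [{"SN": t, "LN": len(targets[t])} for t in tids],
    }
    lut = {t: i for i, t in enumerate(tids)}
    with pysam.AlignmentFile(str(path), "w", header=header) as fh:
        for name, read, hit in hits:
            a = pysam.AlignedSegment(fh.header)
            a.query_name = name
            seq = revcomp(read) if hit.strand == "-" else read
            a.query_sequence = decode(seq)
            a.flag = 16 if hit.strand == "-" else 0
            a.reference_id = lut[hit.target_id]
            a.reference_start = hit.position  # pysam is 0-based internally
            a.mapping_quality = 255
            a.cigarstring = f"{len(read)}M"
            a.set_tag("NM", hit.mismatches)
            fh.write(a)


def read_sam(path) -> tuple[list[tuple[str, np.ndarray, Hit]], int]:
    """Read ungapped SAM records; indel CIGARs are skipped with a warning.

    Returns (records, n_skipped).  SAM 1-based coordinates arrive 0-based
    through pysam's reference_start, matching the internal convention.
    """
    import pysam

    from ._seq import encode

    out: list[tuple[str, np.ndarray, Hit]] = []
    skipped = 0
    with pysam.AlignmentFile(str(path), "r") as fh:
        for a in fh:
            if a.is_unmapped:
                continue
            if any(op not in (0, 7, 8) for op, _ in (a.cigartuples or [])):
                skipped += 1
                continue
            strand = "-" if a.is_reverse else "+"
            seq = encode(a.query_sequence)
            if strand == "-":
                seq = revcomp(seq)  # store read in original orientation
            nm = int(a.get_tag("NM")) if a.has_tag("NM") else 0
            out.append(
                (a.query_name, seq, Hit(a.reference_name, a.reference_start, strand, nm))
            )
    if skipped:
        logger.warning("skipped %d SAM records with indel CIGARs (ungapped model)", skipped)
    return out, skipped
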