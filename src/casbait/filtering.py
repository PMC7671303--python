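"""Read preprocessing: adapter + quality trimming, contaminant removal,
overlap merging of mate pairs.

These are the optional steps run before seed finding. Trimming removes
3' sequencing adapters and then low-quality ends (Mott running-sum
rule); cleaning additionally drops reads that share any canonical k-mer
with a contaminant reference (e.g. host DNA in a microbiome sample);
merging fuses mate pairs whose 3' ends overlap, recomputing qualities
in the overlap.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

from .core_io import ReadRecord, read_fasta, revcomp

__all__ = [
    "FilterConfig",
    "TRUSEQ_ADAPTERS",
    "trim_read",
    "clean_reads",
    "merge_pair",
    "filter_reads",
]

# Illumina TruSeq universal adapter 3' sequences (read-through targets).
TRUSEQ_ADAPTERS = (
    "AGATCGGAAGAGCACACGTCTGAACTCCAGTCA",
    "AGATCGGAAGAGCGTCGTGTAGGGAAAGAGTGT",
)

_ADAPTER_SEED = 12  # exact prefix seed length for adapter location


@dataclass
class FilterConfig:
    mode: str = "off"  # off | trim | clean
    adapters: tuple[str, ...] = TRUSEQ_ADAPTERS
    qual_cutoff: int = 10
    min_len: int = 50
    contaminant_refs: str | Path | None = None
    contam_k: int = 21
    merge_min_overlap: int = 20
    merge_max_mismatch_rate: float = 0.05

    def __post_init__(self) -> None:
        if self.mode not in ("off", "trim", "clean"):
            raise ValueError(f"bad filter mode {self.mode!r}")
        if self.mode == "clean" and self.contaminant_refs is None:
            raise ValueError("mode='clean' requires contaminant_refs")
        if not 0 < self.merge_max_mismatch_rate < 1:
            raise ValueError("merge_max_mismatch_rate must be in (0, 1)")


def _find_adapter(seq: str, adapter: str) -> int | None:
    """Leftmost position where the adapter starts in seq, or None.

    The adapter's first 12 bases must match exactly; the rest of the
    adapter (as far as it fits in the read) may mismatch at most once
    per 8 aligned bases.
    """
    seed = adapter[:_ADAPTER_SEED]
    start = seq.find(seed)
    while start != -1:
        aligned = min(len(adapter), len(seq) - start)
        mismatches = sum(
            1 for k in range(aligned) if seq[start + k] != adapter[k]
        )
        if mismatches <= aligned // 8:
            return start
        start = seq.find(seed, start + 1)
    return None


def _mott_window(qual: str, cutoff: int) -> tuple[int, int]:
    """Maximal-sum contiguous window of (Q - cutoff); returns [start, end).

    Ties go to the leftmost, then longest, window. An all-negative
    read yields the empty window (0, 0).
    """
    best_sum = 0
    best = (0, 0)
    run_sum = 0
    run_start = 0
    for i, ch in enumerate(qual):
        run_sum += (ord(ch) - 33) - cutoff
        if run_sum <= 0:
            run_sum = 0
            run_start = i + 1
        elif run_sum > best_sum or (
            run_sum == best_sum and run_start == best[0]
        ):
            best_sum = run_sum
            best = (run_start, i + 1)
    return best


def trim_read(r: ReadRecord, cfg: FilterConfig) -> ReadRecord | None:
    """Adapter- and quality-trim one read; None means dropped.

    The leftmost 3' adapter hit and everything downstream of it are
    removed first, then the Mott maximal-quality window is kept. Reads
    shorter than cfg.min_len afterwards are dropped.
    """
    if r.qual is None:
        raise ValueError(f"read {r.id!r} has no qualities; cannot trim")
    seq, qual = r.seq, r.qual
    cut = len(seq)
    for adapter in cfg.adapters:
        pos = _find_adapter(seq, adapter)
        if pos is not None and pos < cut:
            cut = pos
    seq, qual = seq[:cut], qual[:cut]
    start, end = _mott_window(qual, cfg.qual_cutoff)
    seq, qual = seq[start:end], qual[start:end]
    if len(seq) < cfg.min_len:
        return None
    return ReadRecord(r.id, seq, qual, r.pair_role, r.mate_id)


def canonical_kmers(seq: str, k: int) -> set[str]:
    """Canonical (lexicographic min of strand pair) k-mers, N-free."""
    out: set[str] = set()
    for i in range(len(seq) - k + 1):
        kmer = seq[i : i + k]
        if "N" in kmer:
            continue
        rc = revcomp(kmer)
        out.add(kmer if kmer <= rc else rc)
    return out


def _contaminant_index(cfg: FilterConfig) -> set[str]:
    entries = read_fasta(cfg.contaminant_refs)
    index: set[str] = set()
    for _, seq in entries:
        index |= canonical_kmers(seq, cfg.contam_k)
    return index


def clean_reads(reads: list[ReadRecord], cfg: FilterConfig) -> list[ReadRecord]:
    """Drop reads sharing >=1 canonical contam_k-mer with any contaminant
    reference; input order is otherwise preserved."""
    if cfg.mode != "clean":
        raise ValueError("clean_reads requires cfg.mode == 'clean'")
    index = _contaminant_index(cfg)
    kept = []
    for r in reads:
        if canonical_kmers(r.seq, cfg.contam_k) & index:
            continue
        kept.append(r)
    return kept


def merge_pair(
    f: ReadRecord, r: ReadRecord, cfg: FilterConfig
) -> ReadRecord | None:
    """Merge a mate pair by its best ungapped 3' overlap, or None.

    The reverse mate is reverse-complemented, then every overlap length
    o >= merge_min_overlap between the forward read's suffix and the
    reversed mate's prefix is scored by match count; overlaps whose
    mismatch rate exceeds merge_max_mismatch_rate are rejected. Ties in
    score break toward the longer overlap. In the merged overlap,
    agreeing bases take the max quality and disagreements take the
    higher-quality base with quality |Q1 - Q2|.
    """
    rseq = revcomp(r.seq)
    rqual = r.qual[::-1] if r.qual is not None else "I" * len(rseq)
    fqual = f.qual if f.qual is not None else "I" * len(f.seq)
    best: tuple[int, int] | None = None  # (score, overlap)
    max_o = min(len(f.seq), len(rseq))
    for o in range(cfg.merge_min_overlap, max_o + 1):
        fs = f.seq[len(f.seq) - o :]
        rs = rseq[:o]
        mism = sum(
            1
            for x, y in zip(fs, rs)
            if x != y or x == "N"
        )
        if mism / o > cfg.merge_max_mismatch_rate:
            continue
        score = o - mism
        if best is None or score > best[0] or (score == best[0] and o > best[1]):
            best = (score, o)
    if best is None:
        return None
    o = best[1]
    head_seq, head_q = f.seq[: len(f.seq) - o], fqual[: len(f.seq) - o]
    tail_seq, tail_q = rseq[o:], rqual[o:]
    mid_seq = []
    mid_q = []
    for k in range(o):
        fb, fq = f.seq[len(f.seq) - o + k], ord(fqual[len(f.seq) - o + k]) - 33
        rb, rq = rseq[k], ord(rqual[k]) - 33
        if fb == rb:
            mid_seq.append(fb)
            mid_q.append(max(fq, rq))
        else:
            mid_seq.append(fb if fq >= rq else rb)
            mid_q.append(abs(fq - rq))
    merged_seq = head_seq + "".join(mid_seq) + tail_seq
    merged_q = head_q + "".join(chr(q + 33) for q in mid_q) + tail_q
    return ReadRecord(f.id, merged_seq, merged_q, "merged", r.id)


def filter_reads(
    fwd: list[ReadRecord],
    rev: list[ReadRecord] | None,
    cfg: FilterConfig,
) -> tuple[list[ReadRecord], dict[str, int]]:
    """Run the configured preprocessing over a read set.

    Paired inputs are paired by record order. Returns the surviving
    records (merged pairs become one record; unmerged mates are both
    retained) and a tally of what happened to the inputs.
    """
    stats = {"input": len(fwd) + (len(rev) if rev else 0), "dropped": 0, "merged_pairs": 0, "contaminant": 0}
    if cfg.mode == "off":
        out = list(fwd) + (list(rev) if rev else [])
        stats["kept"] = len(out)
        return out, stats
    if rev is not None and len(rev) != len(fwd):
        raise ValueError("paired files have different record counts")

    def _trim_list(reads):
        out = []
        for r in reads:
            t = trim_read(r, cfg)
            if t is None:
                stats["dropped"] += 1
            out.append(t)
        return out

    tf = _trim_list(fwd)
    tr = _trim_list(rev) if rev is not None else None

    survivors: list[ReadRecord] = []
    if tr is None:
        survivors = [r for r in tf if r is not None]
    else:
        for a, b in zip(tf, tr):
            if a is not None and b is not None:
                m = merge_pair(a, b, cfg)
                if m is not None:
                    survivors.append(m)
                    stats["merged_pairs"] += 1
                    continue
            if a is not None:
                survivors.append(a)
            if b is not None:
                survivors.append(b)

    if cfg.mode == "clean":
        before = len(survivors)
        survivors = clean_reads(survivors, cfg)
        stats["contaminant"] = before - len(survivors)
    stats["kept"] = len(survivors)
    return survivors, stats
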