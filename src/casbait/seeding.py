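"""Initial seed-read discovery.

Three modes, combinable within one run: protein mode translates each
read's most likely frame and scores it against Cas family profile HMMs;
DNA mode finds reads containing a known CRISPR repeat at high identity;
user-defined mode takes an explicit read subset. The union of seed ids
becomes cycle 0 of the recruitment expansion.
"""

from __future__ import annotations

import logging

from .core_io import ReadPool, ReadRecord, read_fasta, read_fastq, revcomp
from .profiles import FrameCall, ProfileHMM, best_frame, viterbi_bits

__all__ = ["protein_seed_search", "dna_seed_search", "load_user_seeds"]

log = logging.getLogger(__name__)


def protein_seed_search(
    reads: list[ReadRecord],
    hmms: list[ProfileHMM],
    min_aa: int = 20,
    default_bits: float = 15.0,
) -> set[str]:
    """Ids of reads whose best-frame translation scores at or above
    threshold against at least one profile.

    The threshold is each model's gathering cutoff when the profile
    file provides one, else `default_bits`.
    """
    if not hmms:
        raise ValueError("protein_seed_search requires at least one profile")
    seeds: set[str] = set()
    for r in reads:
        call = best_frame(r, min_aa=min_aa)
        if call is None:
            continue
        for h in hmms:
            if viterbi_bits(call.peptide, h) >= h.threshold(default_bits):
                seeds.add(r.id)
                break
    return seeds


def _best_containment(read: str, ref: str, min_ref_cov: float) -> tuple[float, int]:
    """Best ungapped placement of ref within read (one strand).

    Terminal read overhangs are free; the reference may hang off a read
    end as long as >= min_ref_cov of it is aligned. Returns
    (identity over aligned reference columns, aligned columns);
    (0.0, 0) when no placement reaches the coverage floor.
    """
    lr, lf = len(read), len(ref)
    best_ident, best_cols = 0.0, 0
    min_cols = max(1, int(-(-min_ref_cov * lf // 1)))  # ceil
    for off in range(-(lf - 1), lr):
        a = max(0, off)
        b = min(lr, off + lf)
        cols = b - a
        if cols < min_cols:
            continue
        matches = 0
        for i in range(a, b):
            rb = read[i]
            fb = ref[i - off]
            if rb == fb and rb != "N":
                matches += 1
        ident = matches / cols
        if ident > best_ident or (ident == best_ident and cols > best_cols):
            best_ident, best_cols = ident, cols
    return best_ident, best_cols


def dna_seed_search(
    reads: list[ReadRecord],
    refs: list[tuple[str, str]] | str,
    min_identity: float = 0.95,
    min_ref_cov: float = 0.9,
) -> set[str]:
    """Ids of reads containing one of the reference sequences (e.g.
    CRISPR direct repeats) at >= min_identity over >= min_ref_cov of the
    reference, on either strand.

    `refs` is a FASTA path or a list of (name, sequence) pairs.
    References longer than a read are skipped for that read.
    """
    entries = read_fasta(refs) if isinstance(refs, str) else list(refs)
    if not entries:
        raise ValueError("dna_seed_search requires at least one reference")
    seeds: set[str] = set()
    for r in reads:
        for _, ref in entries:
            if len(ref) > len(r.seq):
                continue
            hit = False
            for strand_seq in (ref, revcomp(ref)):
                ident, cols = _best_containment(r.seq, strand_seq, min_ref_cov)
                if cols and ident >= min_identity:
                    hit = True
                    break
            if hit:
                seeds.add(r.id)
                break
    return seeds


def load_user_seeds(path, pool: ReadPool) -> set[str]:
    """Resolve a user-supplied FASTA/FASTQ of seed reads against the pool.

    Entries whose id is a pool read id match by id; other entries match
    any pool read with the identical sequence on either strand. Logs a
    warning and returns the empty set when nothing matches.
    """
    with open(path) as fh:
        first = fh.read(1)
    if first == "@":
        entries = [(rec.id, rec.seq) for rec in read_fastq(path)]
    else:
        entries = read_fasta(path)

    by_seq: dict[str, list[str]] = {}
    for rec in pool.records():
        by_seq.setdefault(rec.seq, []).append(rec.id)

    seeds: set[str] = set()
    for name, seq in entries:
        if name in pool:
            seeds.add(name)
            continue
        seq = seq.upper()
        for variant in (seq, revcomp(seq)):
            for rid in by_seq.get(variant, ()):
                seeds.add(rid)
    if not seeds:
        log.warning("user seed file %s matched no reads in the pool", path)
    return seeds
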