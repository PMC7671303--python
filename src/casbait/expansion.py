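"""Iterative read-subset expansion.

The core recruitment step: starting from the seed reads, each cycle
recruits every still-unrecruited read that overlaps a frontier read at
high identity, then uses the newly recruited reads as the next
frontier. Recruited reads leave the searchable pool, so the search
shrinks every cycle and no read is tested against the same frontier
twice. The result after c cycles equals a breadth-first traversal of
radius c over the read-overlap graph.

Overlap identity is computed by semi-global alignment with terminal
gaps free on both reads (the only identity definition under which two
staggered, partially overlapping reads can reach 95%): identity =
matches / aligned columns, both counted over the overlap only.

A shared-canonical-k-mer prefilter (k = 15) restricts the quadratic
alignment work to plausible pairs. k = 15 is the largest seed length
that cannot miss a qualifying pair: an alignment with >= 50 overlap
columns at >= 95% identity has at most floor(columns/20) non-match
events, and by pigeonhole its longest exact stretch has at least
ceil(matches / (events + 1)) >= 15 bases, shared exactly by both reads.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from ._align import encode, encode_rc, overlap_align
from .core_io import ReadPool

__all__ = [
    "ExpansionConfig",
    "ExpansionTrace",
    "overlap_identity",
    "recruit_cycle",
    "expand",
]

log = logging.getLogger(__name__)

PREFILTER_K = 15


@dataclass
class ExpansionConfig:
    cycles: int = 5
    min_identity: float = 0.95
    min_overlap: int = 50
    strands: str = "both"

    def __post_init__(self) -> None:
        if self.cycles < 0:
            raise ValueError("cycles must be >= 0")
        if not 0 < self.min_identity <= 1:
            raise ValueError("min_identity must be in (0, 1]")
        if self.min_overlap < 16:
            raise ValueError("min_overlap must be >= 16")
        if self.strands != "both":
            raise ValueError("only strands='both' is supported")


@dataclass
class ExpansionTrace:
    """Per-cycle recruitment counts: (cycle, newly recruited, cumulative).
    Cycle 0 is the seed set."""

    rows: list[tuple[int, int, int]] = field(default_factory=list)

    def add(self, cycle: int, new: int) -> None:
        cum = (self.rows[-1][2] if self.rows else 0) + new
        self.rows.append((cycle, new, cum))

    def cumulative(self) -> list[int]:
        return [r[2] for r in self.rows]

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("cycle\tnew\tcumulative\n")
            for cycle, new, cum in self.rows:
                fh.write(f"{cycle}\t{new}\t{cum}\n")


def overlap_identity(a: str, b: str, cfg: ExpansionConfig | None = None) -> tuple[float, int]:
    """Identity and length of the best overlap between two reads.

    Both orientations of b are tried; the higher-scoring one wins and
    ties go to the forward strand. Returns (matches / aligned columns,
    aligned columns), terminal gaps excluded. N never matches.
    """
    if not a or not b:
        raise ValueError("overlap_identity requires non-empty sequences")
    ea = encode(a)
    sf, mf, cf = overlap_align(ea, encode(b))
    sr, mr, cr = overlap_align(ea, encode_rc(b))
    if sr > sf:
        matches, cols = mr, cr
    else:
        matches, cols = mf, cf
    if cols == 0:
        return 0.0, 0
    return matches / cols, cols


def _passes(a: str, b: str, cfg: ExpansionConfig) -> bool:
    ident, cols = overlap_identity(a, b, cfg)
    return cols >= cfg.min_overlap and ident >= cfg.min_identity


class _KmerIndex:
    """Canonical k-mer -> read ids, over the unrecruited pool."""

    def __init__(self, pool: ReadPool, k: int = PREFILTER_K):
        from .filtering import canonical_kmers

        self.k = k
        self.pool = pool
        self._kmers = canonical_kmers
        self.index: dict[str, set[str]] = {}
        for rid in pool.unrecruited_ids():
            self._insert(rid)

    def _insert(self, rid: str) -> None:
        for km in self._kmers(self.pool[rid].seq, self.k):
            self.index.setdefault(km, set()).add(rid)

    def remove(self, rid: str) -> None:
        for km in self._kmers(self.pool[rid].seq, self.k):
            ids = self.index.get(km)
            if ids is not None:
                ids.discard(rid)

    def candidates(self, seq: str) -> set[str]:
        out: set[str] = set()
        for km in self._kmers(seq, self.k):
            hits = self.index.get(km)
            if hits:
                out |= hits
        return out


def recruit_cycle(
    frontier: set[str],
    pool: ReadPool,
    cfg: ExpansionConfig,
    cycle: int = 1,
    _index: _KmerIndex | None = None,
) -> set[str]:
    """One expansion cycle: recruit every unrecruited read overlapping a
    frontier read at >= (min_identity, min_overlap), relabelling it
    recruited@cycle in the pool.

    The frontier must already be out of the searchable pool.
    """
    unrec = set(pool.unrecruited_ids())
    if frontier & unrec:
        raise ValueError("frontier reads must already be removed from the pool")
    index = _index if _index is not None else _KmerIndex(pool)
    newly: set[str] = set()
    for fid in sorted(frontier):
        fseq = pool[fid].seq
        for cid in sorted(index.candidates(fseq)):
            if cid in newly or pool.label(cid) != "unrecruited":
                continue
            if _passes(pool[cid].seq, fseq, cfg):
                newly.add(cid)
                index.remove(cid)
    pool.recruit(newly, cycle)
    return newly


def expand(
    seeds: set[str], pool: ReadPool, cfg: ExpansionConfig | None = None
) -> tuple[set[str], ExpansionTrace]:
    """Run the full seed expansion: label seeds as cycle 0, then run
    cfg.cycles recruitment cycles, each using the previous cycle's
    newly recruited reads as the frontier.

    Returns the union of all recruited ids and the per-cycle trace.
    An empty seed set short-circuits with a warning.
    """
    cfg = cfg or ExpansionConfig()
    trace = ExpansionTrace()
    if not seeds:
        log.warning("no seed reads; expansion skipped")
        trace.add(0, 0)
        return set(), trace
    missing = seeds - set(pool.ids)
    if missing:
        raise KeyError(f"seed ids not in pool: {sorted(missing)[:5]}")

    pool.recruit(seeds, 0)
    trace.add(0, len(seeds))
    index = _KmerIndex(pool)  # built over unrecruited reads only
    recruited = set(seeds)
    frontier = set(seeds)
    for c in range(1, cfg.cycles + 1):
        newly = (
            recruit_cycle(frontier, pool, cfg, cycle=c, _index=index)
            if frontier
            else set()
        )
        trace.add(c, len(newly))
        recruited |= newly
        frontier = newly
    return recruited, trace
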