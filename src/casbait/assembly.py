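"""Desk-scale targeted de Bruijn assembler.

Built for the recruited read subset (thousands of reads spanning a few
kilobases), not whole genomes: a canonical de Bruijn graph at a single
fixed k, abundance-filtered to drop sequencing-error k-mers, tip
clipping for error dead-ends, bubble popping for error branches that
rejoin, and maximal unambiguous paths emitted as contigs.

meta=True keeps singleton k-mers (the metagenome setting, where a
low-abundance organism may contribute little coverage).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import edlib

from .core_io import ReadRecord, revcomp

__all__ = ["Contig", "assemble"]

log = logging.getLogger(__name__)

_ACGT = "ACGT"

# Default k. It must comfortably exceed natural CRISPR direct-repeat
# lengths (23-37 nt): two repeat copies whose (k-1)-mer contexts match
# by chance collapse into one graph node and break the contig mid-array.
# k = 41 leaves >= 12 discriminating flank bases against a 28 nt repeat
# while short-read data (>= 100 nt) still covers each position with
# dozens of k-mers.
DEFAULT_K = 41


@dataclass(frozen=True)
class Contig:
    id: str
    seq: str
    mean_cov: float

    def __post_init__(self) -> None:
        if self.mean_cov <= 0:
            raise ValueError(f"{self.id}: mean coverage must be positive")

    @property
    def length(self) -> int:
        return len(self.seq)

    def fasta_header(self) -> str:
        return f"{self.id} len={self.length} cov={self.mean_cov:.1f}"


def _canon(s: str) -> str:
    rc = revcomp(s)
    return s if s <= rc else rc


def _count_kmers(reads, k: int) -> dict[str, int]:
    counts: dict[str, int] = {}
    for r in reads:
        seq = r.seq
        for i in range(len(seq) - k + 1):
            km = seq[i : i + k]
            if "N" in km:
                continue
            km = _canon(km)
            counts[km] = counts.get(km, 0) + 1
    return counts


class _Graph:
    def __init__(self, counts: dict[str, int], k: int):
        self.counts = counts
        self.k = k

    def succs(self, s: str) -> list[str]:
        out = []
        core = s[1:]
        for b in _ACGT:
            t = core + b
            if _canon(t) in self.counts:
                out.append(t)
        return out

    def preds(self, s: str) -> list[str]:
        out = []
        core = s[:-1]
        for b in _ACGT:
            t = b + core
            if _canon(t) in self.counts:
                out.append(t)
        return out


@dataclass
class _Unitig:
    path: list[str]  # oriented k-mers
    seq: str
    cov: float
    preds: list[str]
    succs: list[str]

    @property
    def kmers(self) -> list[str]:
        return [_canon(s) for s in self.path]


def _walk_unitigs(g: _Graph) -> list[_Unitig]:
    starts: list[str] = []
    for km in sorted(g.counts):
        for s in (km, revcomp(km)):
            p = g.preds(s)
            if len(p) != 1 or len(g.succs(p[0])) != 1:
                starts.append(s)

    visited: set[str] = set()
    unitigs: list[_Unitig] = []

    def _extend(start: str) -> list[str]:
        path = [start]
        visited.add(_canon(start))
        cur = start
        while True:
            nxt = g.succs(cur)
            if len(nxt) != 1:
                break
            t = nxt[0]
            if len(g.preds(t)) != 1 or _canon(t) in visited:
                break
            path.append(t)
            visited.add(_canon(t))
            cur = t
        return path

    for s in starts:
        if _canon(s) in visited:
            continue
        path = _extend(s)
        unitigs.append(_finish(g, path))
    # pure cycles have no boundary k-mer; start them anywhere (sorted order)
    for km in sorted(g.counts):
        if km not in visited:
            unitigs.append(_finish(g, _extend(km)))
    return unitigs


def _finish(g: _Graph, path: list[str]) -> _Unitig:
    seq = path[0] + "".join(s[-1] for s in path[1:])
    cov = sum(g.counts[_canon(s)] for s in path) / len(path)
    return _Unitig(
        path=path,
        seq=seq,
        cov=cov,
        preds=g.preds(path[0]),
        succs=g.succs(path[-1]),
    )


def _clip_tips(g: _Graph, unitigs: list[_Unitig]) -> int:
    """Remove short dead-end unitigs that lose to a competing branch.

    A tip is a unitig dangling at exactly one end and shorter than 2k.
    It is clipped only when its attachment junction offers a better
    continuation: a branch that is not itself a dead end, or a competing
    dead end that is longer / better covered. A short dead end that is
    the sole continuation of the graph (the genuine boundary of the
    covered region) is kept; clipping it would eat the assembly inward
    from every coverage edge that carries a nearby sequencing error.
    """
    info: dict[str, tuple[_Unitig, str]] = {}
    for u in unitigs:
        info[u.path[0]] = (u, "fwd")
        info[revcomp(u.path[-1])] = (u, "rev")

    def tail_dangles(u: _Unitig, orient: str) -> bool:
        return (not u.succs) if orient == "fwd" else (not u.preds)

    def rank(u: _Unitig) -> tuple[int, float, str]:
        return (len(u.seq), u.cov, min(u.seq, revcomp(u.seq)))

    to_remove: list[_Unitig] = []
    for u in unitigs:
        if u.preds and not u.succs:
            first, junction_preds = u.path[0], u.preds
        elif u.succs and not u.preds:
            first = revcomp(u.path[-1])
            junction_preds = [revcomp(x) for x in u.succs]
        else:
            continue
        if len(u.seq) >= 2 * g.k:
            continue
        clip = False
        for p in junction_preds:
            for s in g.succs(p):
                if s == first:
                    continue
                alt = info.get(s)
                if alt is None or alt[0] is u:
                    continue
                au, aorient = alt
                if not tail_dangles(au, aorient) or rank(au) > rank(u):
                    clip = True
        if clip:
            to_remove.append(u)

    for u in to_remove:
        for km in u.kmers:
            g.counts.pop(km, None)
    return len(to_remove)


def _pop_bubbles(g: _Graph, unitigs: list[_Unitig], max_edits: int = 3) -> int:
    """Collapse parallel unitigs sharing both flanking junction k-mers
    whose sequences differ by <= max_edits; the higher-coverage branch
    survives."""
    groups: dict[tuple[str, str], list[tuple[_Unitig, str]]] = {}
    for u in unitigs:
        if len(u.preds) != 1 or len(u.succs) != 1:
            continue
        fwd_key = (u.preds[0], u.succs[0])
        rev_key = (revcomp(u.succs[0]), revcomp(u.preds[0]))
        if fwd_key <= rev_key:
            groups.setdefault(fwd_key, []).append((u, u.seq))
        else:
            groups.setdefault(rev_key, []).append((u, revcomp(u.seq)))
    removed = 0
    for key in sorted(groups):
        members = groups[key]
        if len(members) < 2:
            continue
        members.sort(key=lambda us: (-us[0].cov, us[1]))
        keeper_seq = members[0][1]
        for u, oriented in members[1:]:
            d = edlib.align(oriented, keeper_seq, task="distance")["editDistance"]
            if 0 <= d <= max_edits:
                for km in u.kmers:
                    g.counts.pop(km, None)
                removed += 1
    return removed


def _simplify(g: _Graph) -> None:
    for _ in range(100):
        unitigs = _walk_unitigs(g)
        changed = _clip_tips(g, unitigs)
        unitigs = _walk_unitigs(g) if changed else unitigs
        changed += _pop_bubbles(g, unitigs)
        if not changed or not g.counts:
            return


def _drop_low_coverage(g: _Graph, factor: float = 0.25) -> int:
    """Remove unitigs whose coverage sits far below the graph's
    length-weighted mean: residual error paths (pairs of reads sharing
    a substitution) that neither tip clipping nor pairwise bubble
    popping resolves when several of them interleave."""
    unitigs = _walk_unitigs(g)
    total = sum(len(u.seq) for u in unitigs)
    if not total:
        return 0
    wmean = sum(u.cov * len(u.seq) for u in unitigs) / total
    cutoff = factor * wmean
    removed = 0
    for u in unitigs:
        if u.cov < cutoff:
            for km in u.kmers:
                g.counts.pop(km, None)
            removed += 1
    return removed


def assemble(
    reads: list[ReadRecord],
    k: int = DEFAULT_K,
    min_count: int = 2,
    meta: bool = False,
) -> list[Contig]:
    """Assemble reads into contigs.

    k must be odd (canonical k-mers need a strand-unambiguous form).
    k-mers seen fewer than min_count times are dropped before graph
    construction (min_count is forced to 1 when meta=True); tips
    shorter than 2k are clipped and near-identical bubbles (<= 3 edits)
    are popped, keeping the higher-coverage branch. Contigs come back
    in their lexicographically smaller strand, longest first, as
    contig_1..contig_n. Identical read multisets give identical output
    regardless of input order.
    """
    if not reads:
        raise ValueError("assemble requires a non-empty read list")
    if k % 2 == 0 or k < 3:
        raise ValueError("k must be odd and >= 3")
    effective_min = 1 if meta else min_count
    counts = _count_kmers((r for r in reads if len(r.seq) >= k), k)
    counts = {km: c for km, c in counts.items() if c >= effective_min}
    if not counts:
        log.warning("no k-mer passed min_count=%d; no contigs", effective_min)
        return []

    g = _Graph(counts, k)
    _simplify(g)
    if g.counts and _drop_low_coverage(g):
        _simplify(g)
    if not g.counts:
        log.warning("graph emptied during simplification; no contigs")
        return []

    unitigs = _walk_unitigs(g)
    finals = []
    for u in unitigs:
        seq = u.seq
        rc = revcomp(seq)
        finals.append((seq if seq <= rc else rc, u.cov))
    finals.sort(key=lambda sc: (-len(sc[0]), sc[0]))
    return [
        Contig(id=f"contig_{i + 1}", seq=seq, mean_cov=cov)
        for i, (seq, cov) in enumerate(finals)
    ]
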