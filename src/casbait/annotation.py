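"""Annotation of assembled contigs: cas genes, CRISPR arrays, operons.

Gene calling is deliberately simple (maximal ATG/GTG/TTG-to-stop ORFs
scored against the profile set); CRISPR arrays are found by a
periodic-seed detector in the CRT style: an exact 8-mer recurring at a
period compatible with repeat-plus-spacer unit sizes anchors a
candidate, whose repeat boundaries are then grown column-by-column
while the units agree. An array whose spacers are all identical copies
of one another is flagged suspicious: real spacers record distinct
acquisition events, and a perfectly duplicated unit is the signature of
an assembly artifact rather than biology.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path

from Bio.Seq import Seq

from .assembly import Contig
from .core_io import revcomp
from .profiles import ProfileHMM, viterbi_bits

__all__ = [
    "CasGeneCall",
    "CrisprArrayCall",
    "OperonCall",
    "find_orfs",
    "annotate_cas",
    "detect_crispr_arrays",
    "group_and_type",
    "write_annotations",
]

STARTS = ("ATG", "GTG", "TTG")
STOPS = ("TAA", "TAG", "TGA")

# CRT-style detector parameters
ARRAY_SEED = 8
PERIOD_MIN, PERIOD_MAX = 48, 115
COLUMN_AGREEMENT = 0.8
MIN_REPEATS = 3
REPEAT_LEN = (23, 55)
SPACER_LEN = (25, 60)


@dataclass(frozen=True)
class CasGeneCall:
    """One cas gene call: an ORF scored above threshold by a family
    profile. Coordinates are 1-based inclusive on the forward strand."""

    contig_id: str
    start: int
    end: int
    strand: str
    family: str
    bits: float

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError("start must be <= end")
        if (self.end - self.start + 1) % 3 != 0:
            raise ValueError("cas gene span must be a whole number of codons")
        if self.strand not in "+-":
            raise ValueError(f"bad strand {self.strand!r}")


@dataclass(frozen=True)
class CrisprArrayCall:
    """A repeat-spacer array. spacers holds (sequence, start, end)."""

    contig_id: str
    start: int
    end: int
    repeat_consensus: str
    repeats: tuple[tuple[int, int], ...]
    spacers: tuple[tuple[str, int, int], ...]
    suspicious_duplicate: bool

    def __post_init__(self) -> None:
        if len(self.spacers) != len(self.repeats) - 1:
            raise ValueError("|spacers| must equal |repeats| - 1")
        if not REPEAT_LEN[0] <= len(self.repeat_consensus) <= REPEAT_LEN[1]:
            raise ValueError("repeat length out of range")
        prev_end = 0
        for s, e in self.repeats:
            if s <= prev_end:
                raise ValueError("repeats must be ordered and non-overlapping")
            prev_end = e
        for seq, _, _ in self.spacers:
            if not SPACER_LEN[0] <= len(seq) <= SPACER_LEN[1]:
                raise ValueError("spacer length out of range")


@dataclass(frozen=True)
class OperonCall:
    contig_id: str
    genes: tuple[CasGeneCall, ...]
    type_label: str

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValueError("operon requires at least one gene")

    @property
    def families(self) -> tuple[str, ...]:
        return tuple(g.family for g in self.genes)


def _orfs_one_strand(seq: str):
    """Maximal start-to-stop ORFs on one strand: (start0, end0_excl, peptide)."""
    L = len(seq)
    for frame in range(3):
        start_codon: int | None = None
        for i in range(frame, L - 2, 3):
            codon = seq[i : i + 3]
            if codon in STOPS:
                if start_codon is not None:
                    yield start_codon, i + 3, seq[start_codon:i]
                start_codon = None
            elif start_codon is None and codon in STARTS:
                start_codon = i


def find_orfs(contig: Contig, min_aa: int = 60) -> list[tuple[int, int, str, str]]:
    """All maximal ATG/GTG/TTG-to-stop ORFs with >= min_aa codons before
    the stop, on both strands.

    Returns (start, end, strand, peptide) with 1-based inclusive
    forward-strand coordinates spanning start codon through stop codon.
    """
    seq = contig.seq
    L = len(seq)
    out: list[tuple[int, int, str, str]] = []
    for a, b, nt in _orfs_one_strand(seq):
        if len(nt) // 3 >= min_aa:
            out.append((a + 1, b, "+", str(Seq(nt).translate(table=11))))
    for a, b, nt in _orfs_one_strand(revcomp(seq)):
        if len(nt) // 3 >= min_aa:
            out.append((L - b + 1, L - a, "-", str(Seq(nt).translate(table=11))))
    out.sort()
    return out


def annotate_cas(
    contigs: list[Contig],
    hmms: list[ProfileHMM],
    min_aa: int = 60,
    default_bits: float = 15.0,
) -> list[CasGeneCall]:
    """Score every ORF against every profile; emit one call per ORF whose
    best score clears its model's threshold (ties -> alphabetical model
    name). Overlapping ORFs are not resolved against each other."""
    calls: list[CasGeneCall] = []
    for contig in contigs:
        for start, end, strand, pep in find_orfs(contig, min_aa=min_aa):
            best: tuple[float, str] | None = None
            for h in hmms:
                score = viterbi_bits(pep, h)
                if score < h.threshold(default_bits):
                    continue
                if best is None or score > best[0] or (
                    score == best[0] and h.name < best[1]
                ):
                    best = (score, h.name)
            if best is not None:
                calls.append(
                    CasGeneCall(contig.id, start, end, strand, best[1], best[0])
                )
    return calls


def _column_agreement(seq: str, positions: list[int]) -> tuple[float, str]:
    counts = Counter(seq[p] for p in positions)
    mc = max(counts.values())
    base = min(b for b, c in counts.items() if c == mc)
    return mc / len(positions), base


def _refine_array(seq: str, starts: list[int], period: int) -> CrisprArrayCall | None:
    """Grow repeat boundaries around the anchored 8-mers while the unit
    columns agree, capped so each spacer keeps its minimum length."""
    n = len(starts)
    L = len(seq)
    max_repeat = min(REPEAT_LEN[1], period - SPACER_LEN[0])
    d_left = 0
    while ARRAY_SEED + d_left < max_repeat:
        cols = [s - d_left - 1 for s in starts]
        if cols[0] < 0:
            break
        frac, _ = _column_agreement(seq, cols)
        if frac < COLUMN_AGREEMENT:
            break
        d_left += 1
    d_right = 0
    while ARRAY_SEED + d_left + d_right < max_repeat:
        cols = [s + ARRAY_SEED + d_right for s in starts]
        if cols[-1] >= L:
            break
        frac, _ = _column_agreement(seq, cols)
        if frac < COLUMN_AGREEMENT:
            break
        d_right += 1

    rep_len = d_left + ARRAY_SEED + d_right
    spacer_len = period - rep_len
    if not REPEAT_LEN[0] <= rep_len <= REPEAT_LEN[1]:
        return None
    if not SPACER_LEN[0] <= spacer_len <= SPACER_LEN[1]:
        return None
    rep_starts = [s - d_left for s in starts]
    if rep_starts[0] < 0 or rep_starts[-1] + rep_len > L:
        return None
    repeats = tuple((rs + 1, rs + rep_len) for rs in rep_starts)
    spacers = []
    for rs in rep_starts[:-1]:
        a = rs + rep_len
        b = rs + period
        spacers.append((seq[a:b], a + 1, b))
    consensus = "".join(
        _column_agreement(seq, [rs + j for rs in rep_starts])[1]
        for j in range(rep_len)
    )
    spacer_seqs = [s[0] for s in spacers]
    suspicious = len(spacer_seqs) >= 2 and len(set(spacer_seqs)) == 1
    return CrisprArrayCall(
        contig_id="",
        start=repeats[0][0],
        end=repeats[-1][1],
        repeat_consensus=consensus,
        repeats=repeats,
        spacers=tuple(spacers),
        suspicious_duplicate=suspicious,
    )


def detect_crispr_arrays(contig: Contig) -> list[CrisprArrayCall]:
    """Find repeat-spacer arrays on one contig.

    An exact ARRAY_SEED-mer recurring at a period of 48-115 nt anchors a
    chain of units; the chain is extended through every unit repeating
    at that period, the repeat boundary is refined by column agreement,
    and the candidate is accepted with >= 3 repeats and in-range
    repeat/spacer lengths.
    """
    seq = contig.seq
    L = len(seq)
    arrays: list[CrisprArrayCall] = []
    next_free = 0
    i = 0
    while i <= L - ARRAY_SEED:
        if i < next_free:
            i = next_free
            continue
        km = seq[i : i + ARRAY_SEED]
        if "N" in km:
            i += 1
            continue
        hit = None
        for period in range(PERIOD_MIN, PERIOD_MAX + 1):
            if i + period + ARRAY_SEED > L:
                break
            if seq[i + period : i + period + ARRAY_SEED] != km:
                continue
            # the triggering 8-mer may straddle a repeat boundary and
            # recur at only some units; slide the anchor nearby and keep
            # the longest chain so the column vote sees every unit
            starts = None
            for j in range(max(0, i - ARRAY_SEED + 1), i + ARRAY_SEED):
                if j + period + ARRAY_SEED > L:
                    break
                kmj = seq[j : j + ARRAY_SEED]
                if "N" in kmj or seq[j + period : j + period + ARRAY_SEED] != kmj:
                    continue
                chain = [j]
                s = j - period
                while s >= 0 and seq[s : s + ARRAY_SEED] == kmj:
                    chain.insert(0, s)
                    s -= period
                s = chain[-1] + period
                while s + ARRAY_SEED <= L and seq[s : s + ARRAY_SEED] == kmj:
                    chain.append(s)
                    s += period
                if starts is None or len(chain) > len(starts):
                    starts = chain
            if starts is None or len(starts) < MIN_REPEATS:
                continue
            cand = _refine_array(seq, starts, period)
            if cand is not None:
                hit = CrisprArrayCall(
                    contig_id=contig.id,
                    start=cand.start,
                    end=cand.end,
                    repeat_consensus=cand.repeat_consensus,
                    repeats=cand.repeats,
                    spacers=cand.spacers,
                    suspicious_duplicate=cand.suspicious_duplicate,
                )
                break
        if hit is not None:
            arrays.append(hit)
            next_free = hit.end  # 1-based end == 0-based position after array
            i = next_free
        else:
            i += 1
    return arrays


# minimal subtype signatures over called family names
_SIGNATURES = (
    ("TypeIF", lambda f: {"csy1", "csy2", "csy3"} <= f),
    ("TypeIE", lambda f: {"cse1", "cse2"} <= f),
    ("TypeIC", lambda f: len({"cas8c", "cas5c", "cas7c"} & f) >= 2),
    ("TypeU", lambda f: len({"csf1", "csf2", "csf3", "csf4"} & f) >= 2),
)


def classify_operon(families) -> str:
    fams = {f.lower() for f in families}
    for label, rule in _SIGNATURES:
        if rule(fams):
            return label
    return "unclassified"


def group_and_type(
    genes: list[CasGeneCall],
    arrays: list[CrisprArrayCall],
    max_gap: int = 500,
) -> tuple[list[OperonCall], list[CrisprArrayCall]]:
    """Group same-contig cas genes within max_gap of a neighbour into
    operons, label each by its family signature, and report the arrays
    on contigs carrying no cas gene at all as isolated."""
    by_contig: dict[str, list[CasGeneCall]] = {}
    for g in genes:
        by_contig.setdefault(g.contig_id, []).append(g)

    operons: list[OperonCall] = []
    for contig_id in sorted(by_contig):
        members = sorted(by_contig[contig_id], key=lambda g: (g.start, g.end))
        cluster: list[CasGeneCall] = [members[0]]
        for g in members[1:]:
            if g.start - cluster[-1].end <= max_gap:
                cluster.append(g)
            else:
                operons.append(
                    OperonCall(contig_id, tuple(cluster), classify_operon(c.family for c in cluster))
                )
                cluster = [g]
        operons.append(
            OperonCall(contig_id, tuple(cluster), classify_operon(c.family for c in cluster))
        )

    gene_contigs = set(by_contig)
    isolated = [a for a in arrays if a.contig_id not in gene_contigs]
    return operons, isolated


def _gff_escape(v: str) -> str:
    return v.replace(";", "%3B").replace("=", "%3D").replace(",", "%2C")


def write_annotations(
    contigs: list[Contig],
    genes: list[CasGeneCall],
    arrays: list[CrisprArrayCall],
    operons: list[OperonCall],
    out_dir,
    min_contig: int = 500,
    filename: str = "annotations.gff3",
) -> Path:
    """Collate calls into a GFF3 file (1-based inclusive coordinates).

    Contigs shorter than min_contig are skipped entirely, along with
    every feature on them. Feature types: CDS (cas genes), repeat_region
    (arrays) with child direct_repeat and binding_site (spacer) rows.
    Records are sorted by contig id then start.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    path = out_dir / filename

    kept = {c.id: c for c in contigs if c.length >= min_contig}
    operon_type: dict[tuple[str, int, int, str], str] = {}
    for op in operons:
        for g in op.genes:
            operon_type[(g.contig_id, g.start, g.end, g.family)] = op.type_label

    rows: list[tuple[str, int, int, str]] = []  # (contig, start, -prio, line)
    gene_n = 0
    array_n = 0
    for g in sorted(genes, key=lambda g: (g.contig_id, g.start, g.end)):
        if g.contig_id not in kept:
            continue
        gene_n += 1
        optype = operon_type.get((g.contig_id, g.start, g.end, g.family), "unclassified")
        attrs = (
            f"ID=cas_{gene_n};family={_gff_escape(g.family)};"
            f"bits={g.bits:.1f};operon_type={optype}"
        )
        rows.append(
            (
                g.contig_id,
                g.start,
                0,
                f"{g.contig_id}\tcasbait\tCDS\t{g.start}\t{g.end}\t"
                f"{g.bits:.1f}\t{g.strand}\t0\t{attrs}",
            )
        )
    for a in sorted(arrays, key=lambda a: (a.contig_id, a.start)):
        if a.contig_id not in kept:
            continue
        array_n += 1
        aid = f"crispr_{array_n}"
        suspicious = "true" if a.suspicious_duplicate else "false"
        attrs = (
            f"ID={aid};n_repeats={len(a.repeats)};n_spacers={len(a.spacers)};"
            f"suspicious={suspicious};repeat_consensus={a.repeat_consensus}"
        )
        rows.append(
            (
                a.contig_id,
                a.start,
                0,
                f"{a.contig_id}\tcasbait\trepeat_region\t{a.start}\t{a.end}\t"
                f".\t+\t.\t{attrs}",
            )
        )
        for j, (s, e) in enumerate(a.repeats, 1):
            rows.append(
                (
                    a.contig_id,
                    s,
                    1,
                    f"{a.contig_id}\tcasbait\tdirect_repeat\t{s}\t{e}\t.\t+\t.\t"
                    f"ID={aid}_repeat_{j};Parent={aid}",
                )
            )
        for j, (spseq, s, e) in enumerate(a.spacers, 1):
            rows.append(
                (
                    a.contig_id,
                    s,
                    1,
                    f"{a.contig_id}\tcasbait\tbinding_site\t{s}\t{e}\t.\t+\t.\t"
                    f"ID={aid}_spacer_{j};Parent={aid};Name=spacer;"
                    f"sequence={spseq}",
                )
            )

    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for cid in sorted(kept):
            fh.write(f"##sequence-region {cid} 1 {kept[cid].length}\n")
        for _, _, _, line in sorted(rows, key=lambda r: (r[0], r[1], r[2], r[3])):
            fh.write(line + "\n")
    return path
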