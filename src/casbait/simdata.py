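"""Synthetic data with planted ground truth.

Generates bacterial-genome-like sequences carrying a planted cas operon
(genes reverse-translated from the bundled demo profiles' consensus
peptides) and a CRISPR repeat-spacer array, then error-bearing paired
short reads whose ids encode their true origin interval
(genome:start:end:strand:serial). Because every read carries its own
truth coordinates, recruitment completeness can be evaluated exactly
and without any mapping step: per-cycle locus coverage is computed
straight from the truth intervals.

The error model is substitution-only: an indel model would make
assembler behaviour (bubbles, tips) and recruitment behaviour hard to
attribute separately in tests.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .core_io import ReadRecord, revcomp, write_fastq
from .resources import demo_profile_map

__all__ = [
    "PlantedLocus",
    "CoverageReport",
    "make_genome",
    "make_background",
    "make_reads",
    "make_metagenome",
    "default_metagenome",
    "coverage_report",
    "parse_origin",
]

_BASES = np.array(list("ACGT"))
_STOPS = ("TAA", "TAG", "TGA")

# codon table 11 back-translation choices (no stop codons appear)
_CODONS: dict[str, tuple[str, ...]] = {
    "A": ("GCT", "GCC", "GCA", "GCG"),
    "C": ("TGT", "TGC"),
    "D": ("GAT", "GAC"),
    "E": ("GAA", "GAG"),
    "F": ("TTT", "TTC"),
    "G": ("GGT", "GGC", "GGA", "GGG"),
    "H": ("CAT", "CAC"),
    "I": ("ATT", "ATC", "ATA"),
    "K": ("AAA", "AAG"),
    "L": ("TTA", "TTG", "CTT", "CTC", "CTA", "CTG"),
    "M": ("ATG",),
    "N": ("AAT", "AAC"),
    "P": ("CCT", "CCC", "CCA", "CCG"),
    "Q": ("CAA", "CAG"),
    "R": ("CGT", "CGC", "CGA", "CGG", "AGA", "AGG"),
    "S": ("TCT", "TCC", "TCA", "TCG", "AGT", "AGC"),
    "T": ("ACT", "ACC", "ACA", "ACG"),
    "V": ("GTT", "GTC", "GTA", "GTG"),
    "W": ("TGG",),
    "Y": ("TAT", "TAC"),
}


@dataclass(frozen=True)
class PlantedLocus:
    """Ground truth for one planted CRISPR-cas locus (1-based inclusive)."""

    genome_id: str
    start: int
    end: int
    genes: tuple[tuple[str, int, int, str], ...]  # (family, start, end, strand)
    repeat: str | None
    spacers: tuple[str, ...]
    array_start: int | None = None
    array_end: int | None = None
    array_genome_id: str | None = None


@dataclass(frozen=True)
class CoverageReport:
    """Per-cycle locus coverage from recruited reads.

    rows: (cycle, mean coverage, percent of all-mappable-read coverage,
    gap count, gap lengths); gaps are maximal zero-coverage runs.
    """

    rows: tuple[tuple[int, float, float, int, tuple[int, ...]], ...]

    def percents(self) -> list[float]:
        return [r[2] for r in self.rows]

    def gap_counts(self) -> list[int]:
        return [r[3] for r in self.rows]

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("cycle\tmean_cov\tpct_of_mappable\tgaps\tgap_lengths\n")
            for cycle, mc, pct, gc, gl in self.rows:
                fh.write(
                    f"{cycle}\t{mc:.2f}\t{pct:.2f}\t{gc}\t"
                    + ",".join(map(str, gl))
                    + "\n"
                )


def _random_dna(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(_BASES, size=n))


def _reverse_translate(rng: np.random.Generator, peptide: str) -> str:
    return "".join(_CODONS[a][rng.integers(len(_CODONS[a]))] for a in peptide)


def make_background(bg_len: int, rng_seed: int, genome_id: str = "bg") -> tuple[str, str]:
    """A featureless i.i.d. uniform background genome."""
    rng = np.random.default_rng(rng_seed)
    return genome_id, _random_dna(rng, bg_len)


def make_genome(
    bg_len: int,
    operon_spec: list[str],
    array_spec: tuple[int, int, int] | None,
    rng_seed: int,
    genome_id: str = "g1",
    isolated_array: bool = False,
    identical_spacers: bool = False,
) -> tuple[list[tuple[str, str]], PlantedLocus]:
    """Plant a cas operon and (optionally) a CRISPR array in a random
    background.

    Genes are reverse-translations of the bundled demo profiles'
    consensus peptides, placed in operon_spec order with 20-200 nt
    intergenic gaps; the array follows the operon (or sits on a second
    replicon when isolated_array is set). Fully reproducible from
    rng_seed. Returns FASTA entries plus the truth record.
    """
    if bg_len < 20_000:
        raise ValueError("bg_len must be >= 20 kb")
    if not operon_spec:
        raise ValueError("operon_spec must name at least one gene family")
    rng = np.random.default_rng(rng_seed)
    profiles = demo_profile_map()

    pieces: list[str] = []
    genes: list[tuple[str, int, int, str]] = []
    pos = 0  # 0-based length of locus built so far
    for fam in operon_spec:
        if fam not in profiles:
            raise ValueError(f"unknown demo family {fam!r}")
        cds = _reverse_translate(rng, profiles[fam].consensus_peptide())
        cds += _STOPS[rng.integers(3)]
        genes.append((fam, pos + 1, pos + len(cds), "+"))
        pieces.append(cds)
        pos += len(cds)
        gap = int(rng.integers(20, 201))
        pieces.append(_random_dna(rng, gap))
        pos += gap

    array_seq = ""
    repeat = None
    spacers: tuple[str, ...] = ()
    arr_start_rel = arr_end_rel = None
    if array_spec is not None:
        n_rep, rep_len, sp_len = array_spec
        if n_rep < 2:
            raise ValueError("an array needs at least 2 repeats")
        repeat = _random_dna(rng, rep_len)
        if identical_spacers:
            sp = _random_dna(rng, sp_len)
            spacer_list = [sp] * (n_rep - 1)
        else:
            # distinct spacers whose boundary bases do not all agree:
            # if every spacer started (or ended) with the same base the
            # repeat/spacer decomposition of the planted array would be
            # ambiguous (that column belongs equally well to the repeat)
            # and the truth record ill-posed
            while True:
                spacer_list = []
                while len(spacer_list) < n_rep - 1:
                    sp = _random_dna(rng, sp_len)
                    if sp not in spacer_list:
                        spacer_list.append(sp)
                firsts = {sp[0] for sp in spacer_list}
                lasts = {sp[-1] for sp in spacer_list}
                if n_rep <= 2 or (len(firsts) > 1 and len(lasts) > 1):
                    break
        spacers = tuple(spacer_list)
        array_seq = repeat + "".join(sp + repeat for sp in spacer_list)
        if not isolated_array:
            arr_start_rel = pos
            pieces.append(array_seq)
            pos += len(array_seq)
            arr_end_rel = pos

    if array_spec is not None and not isolated_array:
        locus_seq = "".join(pieces)
    else:
        # no in-place array: the locus ends at the last gene (drop the
        # trailing intergenic gap)
        locus_seq = "".join(pieces)[: genes[-1][2]]
        pos = len(locus_seq)

    if pos + 2000 > bg_len:
        raise ValueError("planted locus does not fit in bg_len")
    offset = bg_len // 3  # 0-based insertion point
    background = _random_dna(rng, bg_len - pos)
    genome = background[:offset] + locus_seq + background[offset:]

    shift = offset  # 0-based shift of locus coordinates
    genes_abs = tuple(
        (fam, s + shift, e + shift, strand) for fam, s, e, strand in genes
    )
    locus_start = genes_abs[0][1]
    if arr_start_rel is not None:
        array_start = arr_start_rel + shift + 1
        array_end = arr_end_rel + shift
        locus_end = array_end
        array_gid = genome_id
    else:
        array_start = array_end = None
        array_gid = None
        locus_end = genes_abs[-1][2]

    entries = [(genome_id, genome)]
    if isolated_array and array_spec is not None:
        repl_id = f"{genome_id}_repl2"
        repl_len = max(6000, len(array_seq) + 4000)
        repl_bg = _random_dna(rng, repl_len - len(array_seq))
        cut = repl_len // 3
        repl = repl_bg[:cut] + array_seq + repl_bg[cut:]
        entries.append((repl_id, repl))
        array_start = cut + 1
        array_end = cut + len(array_seq)
        array_gid = repl_id

    locus = PlantedLocus(
        genome_id=genome_id,
        start=locus_start,
        end=locus_end,
        genes=genes_abs,
        repeat=repeat,
        spacers=spacers,
        array_start=array_start,
        array_end=array_end,
        array_genome_id=array_gid,
    )
    return entries, locus


def _mutate(rng: np.random.Generator, seq: str, err_rate: float) -> tuple[str, str]:
    """Apply substitution errors; returns (sequence, phred+33 qualities).

    Correct bases get Q38; substituted bases get Q drawn from [2, 20].
    """
    arr = np.array(list(seq))
    qual = np.full(len(seq), 38 + 33, dtype=np.uint8)
    errs = np.flatnonzero(rng.random(len(seq)) < err_rate)
    for i in errs:
        choices = [b for b in "ACGT" if b != arr[i]]
        arr[i] = choices[rng.integers(3)]
        qual[i] = int(rng.integers(2, 21)) + 33
    return "".join(arr), qual.tobytes().decode("ascii")


def _sample_pairs(
    rng: np.random.Generator,
    gid: str,
    seq: str,
    n_pairs: int,
    read_len: int,
    insert_mu: int,
    err_rate: float,
    serial_start: int = 0,
) -> tuple[list[ReadRecord], list[ReadRecord]]:
    L = len(seq)
    fwd_out: list[ReadRecord] = []
    rev_out: list[ReadRecord] = []
    for j in range(n_pairs):
        isize = int(round(rng.normal(insert_mu, insert_mu * 0.1)))
        isize = max(read_len, min(isize, L))
        start = int(rng.integers(0, L - isize + 1))  # 0-based fragment start
        frag = seq[start : start + isize]
        flip = bool(rng.integers(2))  # fragment drawn from the minus strand
        if flip:
            frag = revcomp(frag)
        r1 = frag[:read_len]
        r2 = revcomp(frag[isize - read_len :])
        if not flip:
            c1 = (start + 1, start + read_len, "+")
            c2 = (start + isize - read_len + 1, start + isize, "-")
        else:
            c1 = (start + isize - read_len + 1, start + isize, "-")
            c2 = (start + 1, start + read_len, "+")
        s1, q1 = _mutate(rng, r1, err_rate)
        s2, q2 = _mutate(rng, r2, err_rate)
        serial = serial_start + j
        id1 = f"{gid}:{c1[0]}:{c1[1]}:{c1[2]}:p{serial}/1"
        id2 = f"{gid}:{c2[0]}:{c2[1]}:{c2[2]}:p{serial}/2"
        fwd_out.append(ReadRecord(id1, s1, q1, "fwd", id2))
        rev_out.append(ReadRecord(id2, s2, q2, "rev", id1))
    return fwd_out, rev_out


def make_reads(
    genome: list[tuple[str, str]] | tuple[str, str],
    coverage: float = 30,
    read_len: int = 150,
    paired: bool = True,
    insert_mu: int = 300,
    err_rate: float = 0.01,
    rng_seed: int = 0,
    out_prefix: str | Path | None = None,
) -> tuple[list[ReadRecord], list[ReadRecord] | None]:
    """Simulate uniform shotgun reads over a genome (one or more replicons).

    Paired mode yields coverage * length / (2 * read_len) pairs per
    replicon. Read ids encode the truth origin of each mate. When
    out_prefix is given, FASTQ files <prefix>_1.fastq / _2.fastq (or
    <prefix>.fastq single-end) are written as well.
    """
    entries = [genome] if isinstance(genome, tuple) else list(genome)
    rng = np.random.default_rng(rng_seed)
    fwd: list[ReadRecord] = []
    rev: list[ReadRecord] = []
    for gid, seq in entries:
        if read_len >= len(seq):
            raise ValueError("read_len must be shorter than the genome")
        if paired:
            n_pairs = int(round(coverage * len(seq) / (2 * read_len)))
            f, r = _sample_pairs(
                rng, gid, seq, n_pairs, read_len, insert_mu, err_rate
            )
            fwd.extend(f)
            rev.extend(r)
        else:
            n = int(round(coverage * len(seq) / read_len))
            for j in range(n):
                start = int(rng.integers(0, len(seq) - read_len + 1))
                sub = seq[start : start + read_len]
                flip = bool(rng.integers(2))
                strand = "-" if flip else "+"
                if flip:
                    sub = revcomp(sub)
                s, q = _mutate(rng, sub, err_rate)
                fwd.append(
                    ReadRecord(
                        f"{gid}:{start + 1}:{start + read_len}:{strand}:s{j}",
                        s,
                        q,
                        "single",
                    )
                )
    if out_prefix is not None:
        out_prefix = Path(out_prefix)
        if paired:
            write_fastq(fwd, out_prefix.with_name(out_prefix.name + "_1.fastq"))
            write_fastq(rev, out_prefix.with_name(out_prefix.name + "_2.fastq"))
        else:
            write_fastq(fwd, out_prefix.with_name(out_prefix.name + ".fastq"))
    return fwd, (rev if paired else None)


def make_metagenome(
    genomes: list[list[tuple[str, str]] | tuple[str, str]],
    abundances: list[float],
    total_reads: int,
    rng_seed: int,
    read_len: int = 150,
    insert_mu: int = 300,
    err_rate: float = 0.01,
) -> tuple[list[ReadRecord], list[ReadRecord]]:
    """Pool paired reads from several genomes at given weights.

    Pair counts per genome are multinomial in the abundance weights;
    the pooled pairs are shuffled deterministically (mates stay in
    step across the two returned lists).
    """
    if len(genomes) != len(abundances):
        raise ValueError("genomes and abundances differ in length")
    weights = np.asarray(abundances, dtype=float)
    if weights.sum() <= 0:
        raise ValueError("at least one abundance must be positive")
    rng = np.random.default_rng(rng_seed)
    n_pairs_total = total_reads // 2
    per_genome = rng.multinomial(n_pairs_total, weights / weights.sum())
    fwd: list[ReadRecord] = []
    rev: list[ReadRecord] = []
    for genome, n_pairs in zip(genomes, per_genome):
        entries = [genome] if isinstance(genome, tuple) else list(genome)
        lens = np.array([len(s) for _, s in entries], dtype=float)
        per_entry = rng.multinomial(n_pairs, lens / lens.sum())
        for (gid, seq), n_e in zip(entries, per_entry):
            f, r = _sample_pairs(
                rng, gid, seq, int(n_e), read_len, insert_mu, err_rate
            )
            fwd.extend(f)
            rev.extend(r)
    order = rng.permutation(len(fwd))
    return [fwd[i] for i in order], [rev[i] for i in order]


# The default study conditions: a three-genome community, one genome
# carrying a type I-F-like operon plus a 4-repeat array, 30x combined
# depth, 150 nt pairs, 1% substitution errors. Repeat/spacer sizes are
# the type I-F norms (28 nt direct repeats, 32 nt spacers).
DEFAULT_OPERON = ("cas1", "cas3_cas2", "csy1", "csy2", "csy3", "cas6")
DEFAULT_ARRAY = (4, 28, 32)


def default_genomes(rng_seed: int):
    """The three community members of the reference metagenome: one
    20 kb genome with the planted type I-F-like locus, two featureless
    20 kb backgrounds."""
    entries, locus = make_genome(
        20_000, list(DEFAULT_OPERON), DEFAULT_ARRAY, rng_seed, genome_id="g1"
    )
    bg2 = make_background(20_000, rng_seed + 1, "g2")
    bg3 = make_background(20_000, rng_seed + 2, "g3")
    return [entries, [bg2], [bg3]], locus


def default_metagenome(
    rng_seed: int,
) -> tuple[list[ReadRecord], list[ReadRecord], PlantedLocus]:
    """The package's reference synthetic metagenome: 3 x 20 kb genomes,
    one planted type I-F-like locus, ~30x depth each, 1% error."""
    genomes, locus = default_genomes(rng_seed)
    fwd, rev = make_metagenome(
        genomes,
        [1.0, 1.0, 1.0],
        total_reads=12_000,
        rng_seed=rng_seed + 3,
    )
    return fwd, rev, locus


def parse_origin(read_id: str) -> tuple[str, int, int, str]:
    parts = read_id.split(":")
    if len(parts) < 5:
        raise ValueError(f"read id {read_id!r} carries no truth origin")
    gid = ":".join(parts[:-4])
    start, end, strand = parts[-4], parts[-3], parts[-2]
    return gid, int(start), int(end), strand


def _gaps(cov: np.ndarray) -> tuple[int, tuple[int, ...]]:
    lengths = []
    run = 0
    for v in cov:
        if v == 0:
            run += 1
        elif run:
            lengths.append(run)
            run = 0
    if run:
        lengths.append(run)
    return len(lengths), tuple(lengths)


def coverage_report(
    recruited_ids_per_cycle: list[set[str]],
    all_read_ids: list[str],
    locus: PlantedLocus,
) -> CoverageReport:
    """Evaluate recruitment completeness over the planted locus.

    recruited_ids_per_cycle[c] is the cumulative recruited id set
    through cycle c. Mappable reads are those whose truth interval
    overlaps the locus; percentages are relative to the coverage all
    mappable reads give together.
    """
    span = locus.end - locus.start + 1

    def clipped(read_id: str) -> tuple[int, int] | None:
        gid, s, e, _ = parse_origin(read_id)
        if gid != locus.genome_id:
            return None
        a = max(s, locus.start)
        b = min(e, locus.end)
        if a > b:
            return None
        return a - locus.start, b - locus.start + 1  # half-open, locus-relative

    mappable: dict[str, tuple[int, int]] = {}
    for rid in all_read_ids:
        iv = clipped(rid)
        if iv is not None:
            mappable[rid] = iv
    if not mappable:
        raise ValueError("no read originates from the locus; wrong locus or ids")

    all_cov = np.zeros(span, dtype=np.int64)
    for a, b in mappable.values():
        all_cov[a:b] += 1
    all_mean = all_cov.mean()

    rows = []
    for cycle, ids in enumerate(recruited_ids_per_cycle):
        cov = np.zeros(span, dtype=np.int64)
        for rid in ids:
            iv = mappable.get(rid)
            if iv is not None:
                cov[iv[0] : iv[1]] += 1
        pct = 100.0 * cov.mean() / all_mean
        gap_count, gap_lengths = _gaps(cov)
        rows.append((cycle, float(cov.mean()), float(pct), gap_count, gap_lengths))
    return CoverageReport(tuple(rows))
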