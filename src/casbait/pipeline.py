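"""End-to-end orchestration: filter -> seed -> expand -> assemble -> annotate.

This is the library entry point behind the command-line interface. The
stages are individually optional (mirroring the tool's flag surface);
every run writes recruited.fastq, expansion_trace.tsv, a run manifest
with parameter values and input checksums, and (unless disabled)
contigs.fasta and annotations.gff3.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

from . import annotation as ann
from . import resources
from .assembly import Contig, assemble
from .core_io import (
    ReadPool,
    ReadRecord,
    read_fastq,
    restore_qualities,
    write_fasta,
    write_fastq,
)
from .expansion import ExpansionConfig, ExpansionTrace, expand
from .filtering import FilterConfig, filter_reads
from .profiles import parse_hmm
from .seeding import dna_seed_search, load_user_seeds, protein_seed_search

__all__ = ["PipelineConfig", "RunResult", "run_pipeline"]

log = logging.getLogger("casbait")


@dataclass
class PipelineConfig:
    # inputs: exactly one of single or (fwd and rev)
    single: str | None = None
    fwd: str | None = None
    rev: str | None = None
    out_dir: str = "casbait_out"
    # filtering
    trim: bool = False
    clean: bool = False
    contaminant_ref: str | None = None
    # seeding
    protein: bool = True
    hmm: str | None = None  # HMMER3 file; None -> bundled demo set
    hmm_bits: float = 15.0
    nucl: bool = False
    query: str | None = None  # repeat FASTA for DNA mode
    user_seed: bool = False
    define: str | None = None  # user seed reads
    # expansion
    cycles: int = 5
    match: float = 95.0  # percent identity
    min_overlap: int = 50
    mate_rescue: bool = True
    # assembly
    noassembly: bool = False
    meta: bool = False
    asm_k: int = 41
    # annotation
    noannotate: bool = False
    min_contig: int = 500
    # interface parity; execution is single-process
    cpu: int = 1
    mem: int | None = None

    def validate(self) -> None:
        paired = self.fwd is not None and self.rev is not None
        if bool(self.single) == paired or (self.fwd is None) != (self.rev is None):
            raise ValueError(
                "provide exactly one of single-end input or a fwd/rev pair"
            )
        if self.clean and self.contaminant_ref is None:
            raise ValueError("cleaning requires a contaminant reference FASTA")
        if self.nucl and self.query is None:
            raise ValueError("DNA seed mode requires a query FASTA")
        if self.user_seed and self.define is None:
            raise ValueError("user-defined seed mode requires a seed read file")
        if not (self.protein or self.nucl or self.user_seed):
            raise ValueError("all seed modes are disabled; nothing to search for")
        if not 0 < self.match <= 100:
            raise ValueError("match must be a percentage in (0, 100]")


@dataclass
class RunResult:
    out_dir: Path
    seeds: set[str]
    recruited: set[str]
    trace: ExpansionTrace
    recruited_per_cycle: list[set[str]]
    contigs: list[Contig] = field(default_factory=list)
    genes: list = field(default_factory=list)
    arrays: list = field(default_factory=list)
    operons: list = field(default_factory=list)
    isolated_arrays: list = field(default_factory=list)


def _md5(path: str) -> str:
    h = hashlib.md5()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _load_inputs(cfg: PipelineConfig):
    if cfg.single:
        return read_fastq(cfg.single, "single"), None
    fwd = read_fastq(cfg.fwd, "fwd")
    rev = read_fastq(cfg.rev, "rev")
    if len(fwd) != len(rev):
        raise ValueError("fwd and rev files hold different record counts")
    # pair by record order; disambiguate ids shared between the mates
    out_f, out_r = [], []
    for a, b in zip(fwd, rev):
        ida, idb = a.id, b.id
        if ida == idb:
            ida, idb = f"{a.id}/1", f"{b.id}/2"
        out_f.append(ReadRecord(ida, a.seq, a.qual, "fwd", idb))
        out_r.append(ReadRecord(idb, b.seq, b.qual, "rev", ida))
    return out_f, out_r


def _original_ids(recruited: set[str], pool: ReadPool) -> set[str]:
    """Expand recruited ids to the original read ids they stand for
    (a merged record stands for both of its mates)."""
    out: set[str] = set()
    for rid in recruited:
        rec = pool[rid]
        out.add(rid)
        if rec.pair_role == "merged" and rec.mate_id is not None:
            out.add(rec.mate_id)
    return out


def _rescue_mates(ids: set[str], pool: ReadPool) -> set[str]:
    out = set(ids)
    for rid in ids:
        mate = pool[rid].mate_id
        if mate is not None:
            out.add(mate)
    return out


def run_pipeline(cfg: PipelineConfig) -> RunResult:
    """Run the targeted assembly pipeline and write its outputs.

    Returns a RunResult with the in-memory stage products; see the
    output directory for recruited.fastq, contigs.fasta,
    annotations.gff3, expansion_trace.tsv, run_log and manifest.json.
    """
    cfg.validate()
    out_dir = Path(cfg.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    handler = logging.FileHandler(out_dir / "run_log")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    root = logging.getLogger("casbait")
    root.addHandler(handler)
    if root.level > logging.INFO or root.level == logging.NOTSET:
        root.setLevel(logging.INFO)
    try:
        return _run(cfg, out_dir)
    finally:
        handler.close()
        root.removeHandler(handler)


def _run(cfg: PipelineConfig, out_dir: Path) -> RunResult:
    inputs = [p for p in (cfg.single, cfg.fwd, cfg.rev) if p]
    manifest = {
        "parameters": {
            k: v for k, v in vars(cfg).items() if not k.startswith("_")
        },
        "inputs": {p: _md5(p) for p in inputs},
    }
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)

    log.info("loading reads from %s", ", ".join(inputs))
    fwd, rev = _load_inputs(cfg)

    mode = "clean" if cfg.clean else ("trim" if cfg.trim else "off")
    fcfg = FilterConfig(mode=mode, contaminant_refs=cfg.contaminant_ref)
    records, fstats = filter_reads(fwd, rev, fcfg)
    log.info("filtering (%s): %s", mode, fstats)

    pool = ReadPool(records)

    seeds: set[str] = set()
    if cfg.protein:
        hmms = parse_hmm(cfg.hmm) if cfg.hmm else list(resources.demo_profiles())
        prot = protein_seed_search(records, hmms, default_bits=cfg.hmm_bits)
        log.info("protein mode: %d seed reads (%d profiles)", len(prot), len(hmms))
        seeds |= prot
    if cfg.nucl:
        dna = dna_seed_search(records, cfg.query)
        log.info("DNA mode: %d seed reads", len(dna))
        seeds |= dna
    if cfg.user_seed:
        usr = load_user_seeds(cfg.define, pool)
        log.info("user-defined mode: %d seed reads", len(usr))
        seeds |= usr
    log.info("combined seed set: %d reads", len(seeds))

    xcfg = ExpansionConfig(
        cycles=cfg.cycles,
        min_identity=cfg.match / 100.0,
        min_overlap=cfg.min_overlap,
    )
    recruited, trace = expand(seeds, pool, xcfg)
    trace.to_tsv(out_dir / "expansion_trace.tsv")
    per_cycle: list[set[str]] = []
    running: set[str] = set()
    for c in range(len(trace.rows)):
        running |= set(pool.recruited_ids(c))
        per_cycle.append(set(running))
    log.info(
        "expansion: %d reads recruited over %d cycles", len(recruited), cfg.cycles
    )

    result = RunResult(
        out_dir=out_dir,
        seeds=seeds,
        recruited=recruited,
        trace=trace,
        recruited_per_cycle=per_cycle,
    )
    if not seeds:
        log.warning("no seeds found; stopping before assembly")
        write_fastq([], out_dir / "recruited.fastq")
        return result

    assembly_ids = (
        _rescue_mates(recruited, pool) if cfg.mate_rescue else set(recruited)
    )
    original_ids = _original_ids(assembly_ids, pool)
    originals = restore_qualities(original_ids, inputs if cfg.single is None else cfg.single)
    write_fastq(originals, out_dir / "recruited.fastq")
    log.info("recruited.fastq: %d reads with original qualities", len(originals))

    if cfg.noassembly:
        return result

    contigs = assemble(originals, k=cfg.asm_k, meta=cfg.meta)
    write_fasta(
        [(c.fasta_header(), c.seq) for c in contigs], out_dir / "contigs.fasta"
    )
    result.contigs = contigs
    log.info("assembly: %d contigs", len(contigs))

    if cfg.noannotate:
        return result

    big = [c for c in contigs if c.length >= cfg.min_contig]
    hmms = parse_hmm(cfg.hmm) if cfg.hmm else list(resources.demo_profiles())
    genes = ann.annotate_cas(big, hmms, default_bits=cfg.hmm_bits)
    arrays = [a for c in big for a in ann.detect_crispr_arrays(c)]
    operons, isolated = ann.group_and_type(genes, arrays)
    ann.write_annotations(
        contigs, genes, arrays, operons, out_dir, min_contig=cfg.min_contig
    )
    result.genes, result.arrays = genes, arrays
    result.operons, result.isolated_arrays = operons, isolated
    log.info(
        "annotation: %d cas genes, %d arrays (%d isolated), %d operons",
        len(genes),
        len(arrays),
        len(isolated),
        len(operons),
    )
    return result
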