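"""Find a CRISPR array that has no cas genes near it.

Arrays unlinked to cas operons are invisible to protein-mode seeding:
no read near them translates to a Cas protein. DNA mode seeds the
recruitment from reads containing a known direct repeat instead. Here
the array sits on its own replicon; DNA-mode seeds recruit its
neighbourhood, the subset assembles, and the array is reported as
isolated because its contig carries no cas gene.
"""

from casbait import annotation as ann
from casbait.assembly import assemble
from casbait.core_io import ReadPool, revcomp
from casbait.expansion import ExpansionConfig, expand
from casbait.resources import demo_profiles
from casbait.seeding import dna_seed_search
from casbait.simdata import make_genome, make_reads

entries, locus = make_genome(
    20_000, ["cas1", "cas3_cas2", "csy1", "csy2", "csy3", "cas6"],
    (4, 28, 32), rng_seed=11, isolated_array=True,
)
print(f"replicons: {[gid for gid, _ in entries]}; array on {locus.array_genome_id}")

fwd, rev = make_reads(entries, coverage=30, rng_seed=12)
reads = fwd + rev
seeds = dna_seed_search(reads, [("repeat", locus.repeat)])
print(f"DNA mode: {len(seeds)} reads contain the repeat at >= 95% identity")

pool = ReadPool(reads)
recruited, _ = expand(seeds, pool, ExpansionConfig(cycles=5))
by_id = {r.id: r for r in reads}
contigs = assemble([by_id[i] for i in sorted(recruited)])
big = [c for c in contigs if c.length >= 500]

genes = ann.annotate_cas(big, list(demo_profiles()))
arrays = [a for c in big for a in ann.detect_crispr_arrays(c)]
operons, isolated = ann.group_and_type(genes, arrays)

print(f"assembled {len(big)} contig(s) >= 500 bp; {len(genes)} cas genes, "
      f"{len(arrays)} array(s), {len(isolated)} isolated")
for a in isolated:
    got = tuple(s[0] for s in a.spacers)
    match = got == locus.spacers or tuple(
        revcomp(s) for s in reversed(got)
    ) == locus.spacers  # the contig may be reported on the other strand
    print(f"isolated array on {a.contig_id}: {len(a.repeats)} repeats; "
          f"planted spacers recovered exactly: {match}")
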