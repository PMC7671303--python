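"""Simulate a metagenome with a planted cas locus and watch read
recruitment saturate it cycle by cycle.

Builds the reference synthetic community (three 20 kb genomes, one
carrying a type I-F-like operon and a CRISPR array, ~30x combined
depth, 1% substitution errors), finds protein-mode seed reads with the
bundled demo profiles, runs five recruitment cycles and reports what
fraction of the locus-derived reads each cycle captured.
"""

from casbait.core_io import ReadPool
from casbait.expansion import ExpansionConfig, expand
from casbait.resources import demo_profiles
from casbait.seeding import protein_seed_search
from casbait.simdata import coverage_report, default_metagenome

fwd, rev, locus = default_metagenome(rng_seed=1)
reads = fwd + rev
print(f"{len(reads)} reads; planted locus {locus.genome_id}:{locus.start}-{locus.end}")

seeds = protein_seed_search(reads, list(demo_profiles()))
print(f"protein mode found {len(seeds)} seed reads (reads translating to "
      "Cas-profile hits)")

pool = ReadPool(reads)
recruited, trace = expand(seeds, pool, ExpansionConfig(cycles=5))

per_cycle, running = [], set()
for c, _, _ in trace.rows:
    running |= set(pool.recruited_ids(c))
    per_cycle.append(set(running))
report = coverage_report(per_cycle, [r.id for r in reads], locus)

print("\ncycle  new_reads  cumulative  %of_mappable_cov  gaps")
for (c, new, cum), row in zip(trace.rows, report.rows):
    print(f"{c:5d}  {new:9d}  {cum:10d}  {row[2]:16.1f}  {row[3]}")
print(
    f"\n{len(recruited)} of {len(reads)} reads recruited "
    f"({100 * len(recruited) / len(reads):.1f}% of the dataset). Seeds alone "
    "leave coverage gaps over the array and intergenic regions; each cycle "
    "pulls in overlapping neighbours until the locus is fully covered."
)
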