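import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")

FLAGSHIP_SEED = 7


@pytest.fixture(scope="session")
def flagship():
    """One full run of the pipeline stages on the reference synthetic
    metagenome, shared by the end-to-end tests."""
    from casbait.core_io import ReadPool
    from casbait.expansion import ExpansionConfig, expand
    from casbait.resources import demo_profiles
    from casbait.seeding import protein_seed_search
    from casbait.assembly import assemble
    from casbait import annotation as ann
    from casbait.simdata import coverage_report, default_genomes, make_metagenome

    genomes, locus = default_genomes(FLAGSHIP_SEED)
    fwd, rev = make_metagenome(
        genomes, [1.0, 1.0, 1.0], total_reads=12_000, rng_seed=FLAGSHIP_SEED + 3
    )
    reads = fwd + rev
    by_id = {r.id: r for r in reads}
    seeds = protein_seed_search(reads, list(demo_profiles()))
    pool = ReadPool(reads)
    recruited, trace = expand(seeds, pool, ExpansionConfig())

    per_cycle, running = [], set()
    for c in range(len(trace.rows)):
        running |= set(pool.recruited_ids(c))
        per_cycle.append(set(running))
    report = coverage_report(per_cycle, [r.id for r in reads], locus)

    assembly_ids = set(recruited)
    for rid in recruited:
        mate = by_id[rid].mate_id
        if mate is not None:
            assembly_ids.add(mate)
    contigs = assemble([by_id[i] for i in sorted(assembly_ids)])

    big = [c for c in contigs if c.length >= 500]
    profiles = list(demo_profiles())
    genes = ann.annotate_cas(big, profiles)
    arrays = [a for c in big for a in ann.detect_crispr_arrays(c)]
    operons, isolated = ann.group_and_type(genes, arrays)

    return {
        "genomes": genomes,
        "locus": locus,
        "reads": reads,
        "by_id": by_id,
        "seeds": seeds,
        "pool": pool,
        "recruited": recruited,
        "trace": trace,
        "per_cycle": per_cycle,
        "report": report,
        "contigs": contigs,
        "genes": genes,
        "arrays": arrays,
        "operons": operons,
        "isolated": isolated,
    }


@pytest.fixture()
def rng():
    return np.random.default_rng(20_240_101)
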