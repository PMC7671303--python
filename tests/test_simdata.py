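import numpy as np
import pytest

from casbait.core_io import revcomp
from casbait.simdata import (
    DEFAULT_ARRAY,
    DEFAULT_OPERON,
    coverage_report,
    make_background,
    make_genome,
    make_metagenome,
    make_reads,
    parse_origin,
)


class TestMakeGenome:
    def test_construction_contract(self):
        entries, locus = make_genome(20_000, list(DEFAULT_OPERON), (4, 30, 34), 7)
        assert len(entries) == 1
        gid, seq = entries[0]
        assert len(seq) == 20_000
        assert len(locus.genes) == 6
        assert [g[0] for g in locus.genes] == list(DEFAULT_OPERON)
        assert len(locus.spacers) == 3 and len(set(locus.spacers)) == 3
        # truth features actually sit at their coordinates
        n_rep, rep_len, sp_len = 4, 30, 34
        assert seq[locus.array_start - 1 : locus.array_start - 1 + rep_len] == locus.repeat
        assert locus.start <= locus.array_start <= locus.end == locus.array_end
        for fam, s, e, strand in locus.genes:
            assert locus.start <= s <= e <= locus.end
            assert (e - s + 1) % 3 == 0

    def test_same_seed_is_byte_identical(self):
        a, _ = make_genome(20_000, list(DEFAULT_OPERON), DEFAULT_ARRAY, 3)
        b, _ = make_genome(20_000, list(DEFAULT_OPERON), DEFAULT_ARRAY, 3)
        assert a == b

    def test_single_repeat_is_an_error(self):
        with pytest.raises(ValueError):
            make_genome(20_000, ["cas1"], (1, 30, 34), 0)

    def test_too_small_background_is_an_error(self):
        with pytest.raises(ValueError):
            make_genome(5_000, ["cas1"], (4, 30, 34), 0)

    def test_isolated_array_lands_on_second_replicon(self):
        entries, locus = make_genome(
            20_000, ["cas1", "cas6"], (4, 28, 32), 5, isolated_array=True
        )
        assert len(entries) == 2
        repl_id, repl_seq = entries[1]
        assert locus.array_genome_id == repl_id
        assert (
            repl_seq[locus.array_start - 1 : locus.array_start - 1 + 28]
            == locus.repeat
        )
        # the main locus ends at the last gene
        assert locus.end == locus.genes[-1][2]

    def test_identical_spacers_mode(self):
        _, locus = make_genome(
            20_000, ["cas1"], (4, 28, 32), 9, identical_spacers=True
        )
        assert len(set(locus.spacers)) == 1


class TestMakeReads:
    def test_paired_read_count_formula(self):
        g = make_background(20_000, 1)
        fwd, rev = make_reads(g, coverage=30, read_len=150, paired=True, rng_seed=2)
        assert len(fwd) == len(rev) == 2000  # 30*20000/(2*150)
        assert all(len(r.seq) == 150 for r in fwd + rev)

    def test_zero_error_rate_reads_are_exact_substrings(self):
        gid, seq = make_background(20_000, 4)
        fwd, rev = make_reads((gid, seq), coverage=2, err_rate=0.0, rng_seed=5)
        for r in fwd + rev:
            g, s, e, strand = parse_origin(r.id)
            sub = seq[s - 1 : e]
            assert r.seq == (sub if strand == "+" else revcomp(sub))
            assert set(r.qual) == {chr(38 + 33)}

    def test_errors_get_low_qualities(self):
        gid, seq = make_background(20_000, 4)
        fwd, _ = make_reads((gid, seq), coverage=2, err_rate=0.05, rng_seed=6)
        mismatch_quals, match_quals = [], []
        for r in fwd:
            g, s, e, strand = parse_origin(r.id)
            truth = seq[s - 1 : e] if strand == "+" else revcomp(seq[s - 1 : e])
            for got, want, q in zip(r.seq, truth, r.qual):
                (match_quals if got == want else mismatch_quals).append(ord(q) - 33)
        assert mismatch_quals and max(mismatch_quals) <= 20
        assert set(match_quals) == {38}

    def test_same_seed_identical_output(self):
        g = make_background(20_000, 1)
        a = make_reads(g, coverage=3, rng_seed=9)
        b = make_reads(g, coverage=3, rng_seed=9)
        assert [(r.id, r.seq, r.qual) for r in a[0]] == [
            (r.id, r.seq, r.qual) for r in b[0]
        ]


class TestMakeMetagenome:
    def test_multinomial_proportions(self):
        gs = [make_background(20_000, s, f"g{s}") for s in (1, 2, 3)]
        fwd, rev = make_metagenome(gs, [1, 1, 2], total_reads=8000, rng_seed=0)
        assert len(fwd) + len(rev) == 8000
        counts = {}
        for r in fwd:
            gid = parse_origin(r.id)[0]
            counts[gid] = counts.get(gid, 0) + 2  # mate comes with it
        assert abs(counts["g1"] - 2000) < 200
        assert abs(counts["g2"] - 2000) < 200
        assert abs(counts["g3"] - 4000) < 250

    def test_zero_weight_genome_gets_no_reads(self):
        gs = [make_background(20_000, 1, "a"), make_background(20_000, 2, "b")]
        fwd, _ = make_metagenome(gs, [1, 0], total_reads=2000, rng_seed=1)
        assert {parse_origin(r.id)[0] for r in fwd} == {"a"}

    def test_all_zero_weights_error(self):
        gs = [make_background(20_000, 1)]
        with pytest.raises(ValueError):
            make_metagenome(gs, [0], total_reads=100, rng_seed=1)

    def test_mates_stay_in_step_after_shuffle(self):
        gs = [make_background(20_000, s, f"g{s}") for s in (1, 2)]
        fwd, rev = make_metagenome(gs, [1, 1], total_reads=1000, rng_seed=3)
        for f, r in zip(fwd, rev):
            assert f.mate_id == r.id and r.mate_id == f.id


class TestCoverageReport:
    @pytest.fixture()
    def truth(self):
        _, locus = make_genome(20_000, list(DEFAULT_OPERON), DEFAULT_ARRAY, 7)
        span = locus.end - locus.start + 1
        ids = []
        pos = locus.start - 120
        i = 0
        while pos < locus.end + 50:
            ids.append(f"g1:{pos}:{pos + 149}:+:x{i}")
            pos += 40
            i += 1
        ids += [f"g2:{j * 100 + 1}:{j * 100 + 150}:+:y{j}" for j in range(30)]
        mappable = [
            rid for rid in ids
            if parse_origin(rid)[0] == "g1"
            and parse_origin(rid)[1] <= locus.end
            and parse_origin(rid)[2] >= locus.start
        ]
        return locus, ids, mappable

    def test_full_recruitment_is_100_percent_no_gaps(self, truth):
        locus, ids, mappable = truth
        rep = coverage_report([set(mappable)], ids, locus)
        assert rep.rows[0][2] == pytest.approx(100.0)
        assert rep.rows[0][3] == 0

    def test_empty_recruitment_is_one_locus_wide_gap(self, truth):
        locus, ids, mappable = truth
        rep = coverage_report([set()], ids, locus)
        cycle0 = rep.rows[0]
        assert cycle0[2] == 0.0
        assert cycle0[3] == 1
        assert cycle0[4] == (locus.end - locus.start + 1,)

    def test_every_second_read_is_about_half(self, truth):
        locus, ids, mappable = truth
        half = set(mappable[::2])
        rep = coverage_report([half], ids, locus)
        # direct computation on the truth intervals
        import numpy as np

        span = locus.end - locus.start + 1
        cov_all = np.zeros(span)
        cov_half = np.zeros(span)
        for rid in mappable:
            _, s, e, _ = parse_origin(rid)
            a, b = max(s, locus.start) - locus.start, min(e, locus.end) - locus.start + 1
            cov_all[a:b] += 1
            if rid in half:
                cov_half[a:b] += 1
        assert rep.rows[0][2] == pytest.approx(100 * cov_half.mean() / cov_all.mean())
        assert 35 < rep.rows[0][2] < 65

    def test_percentages_non_decreasing_with_cumulative_sets(self, truth):
        locus, ids, mappable = truth
        sets = [set(mappable[:k]) for k in (5, 15, len(mappable))]
        rep = coverage_report(sets, ids, locus)
        pcts = rep.percents()
        assert pcts == sorted(pcts)

    def test_locus_without_reads_is_an_error(self, truth):
        locus, ids, _ = truth
        foreign = [i for i in ids if parse_origin(i)[0] != "g1"]
        with pytest.raises(ValueError):
            coverage_report([set()], foreign, locus)
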