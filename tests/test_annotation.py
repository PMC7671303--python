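import numpy as np
import pytest

from casbait.annotation import (
    CasGeneCall,
    CrisprArrayCall,
    annotate_cas,
    classify_operon,
    detect_crispr_arrays,
    find_orfs,
    group_and_type,
    write_annotations,
)
from casbait.assembly import Contig
from casbait.core_io import revcomp
from casbait.resources import make_profile
from casbait.simdata import _reverse_translate

STOP_RICH = "ATTAATTAACTA"  # stops every few codons, all six frames


def _dna(rng, n):
    return "".join(rng.choice(list("ACGT"), size=n))


def _flank(n):
    return (STOP_RICH * (n // len(STOP_RICH) + 1))[:n]


def _gene(rng, peptide):
    return _reverse_translate(rng, peptide) + "TAA"


class TestFindOrfs:
    def test_single_plus_strand_gene(self, rng):
        pep = "M" + "".join(rng.choice(list("ACDEFGHIKLNPQRSTVWY"), size=299))
        gene = _gene(rng, pep)
        left = _flank(300)
        contig = Contig("c", left + gene + _flank(300), 1.0)
        orfs = [o for o in find_orfs(contig, min_aa=60) if o[2] == "+"]
        assert len(orfs) == 1
        start, end, strand, got_pep = orfs[0]
        assert (start, end) == (301, 300 + len(gene))
        assert got_pep == pep

    def test_minus_strand_coordinates(self, rng):
        pep = "M" + "".join(rng.choice(list("ACDEFGHIKLNPQRSTVWY"), size=199))
        gene = _gene(rng, pep)
        left = _flank(240)
        seq = left + revcomp(gene) + _flank(240)
        orfs = [o for o in find_orfs(Contig("c", seq, 1.0), min_aa=60) if o[2] == "-"]
        # manual coordinate oracle: the gene occupies [241, 240+len] on
        # the forward strand, read on the minus strand (other minus-frame
        # ORFs inside the gene body may exist and are not suppressed)
        assert (241, 240 + len(gene), "-", pep) in orfs

    def test_all_n_contig_has_no_orfs(self):
        assert find_orfs(Contig("c", "N" * 600, 1.0)) == []

    def test_span_is_codon_multiple(self, rng):
        contig = Contig("c", _dna(rng, 3000), 1.0)
        for start, end, _, pep in find_orfs(contig, min_aa=20):
            assert (end - start + 1) % 3 == 0
            assert end <= contig.length
            assert "*" not in pep


class TestAnnotateCas:
    def test_planted_gene_called_with_right_family(self, rng):
        pep = "M" + "".join(rng.choice(list("ACDEFGHIKLNPQRSTVWY"), size=149))
        hmm = make_profile("cas1_toy", pep)
        seq = _flank(240) + _gene(rng, pep) + _flank(240)
        calls = annotate_cas([Contig("c", seq, 1.0)], [hmm])
        assert len(calls) == 1
        call = calls[0]
        assert call.family == "cas1_toy" and call.strand == "+"
        assert call.bits > 100

    def test_random_contig_yields_nothing(self, rng):
        hmm = make_profile("cas1_toy", "M" + "K" * 99)
        calls = annotate_cas([Contig("c", _dna(rng, 4000), 1.0)], [hmm])
        assert calls == []

    def test_overlapping_orfs_both_called(self, rng):
        # two genes on opposite strands over the same span: no overlap
        # resolution is attempted
        pep_a = "M" + "".join(rng.choice(list("ACDEFGHIKLNPQRSTVW"), size=99))
        hmm_a = make_profile("fam_a", pep_a)
        gene = _gene(rng, pep_a)
        rc_orf_pep = None
        seq = _flank(240) + gene + revcomp(gene) + _flank(240)
        calls = annotate_cas([Contig("c", seq, 1.0)], [hmm_a])
        strands = {c.strand for c in calls}
        assert len(calls) >= 2 and strands == {"+", "-"}


def _array_seq(rng, n_rep=4, rep_len=30, sp_len=34, identical=False):
    repeat = _dna(rng, rep_len)
    if identical:
        spacers = [_dna(rng, sp_len)] * (n_rep - 1)
    else:
        while True:
            spacers = [_dna(rng, sp_len) for _ in range(n_rep - 1)]
            if len(set(spacers)) != n_rep - 1:
                continue
            if n_rep <= 3 or (
                len({s[0] for s in spacers}) > 1 and len({s[-1] for s in spacers}) > 1
            ):
                break
    seq = repeat + "".join(s + repeat for s in spacers)
    return seq, repeat, spacers


class TestCrisprDetector:
    def test_planted_array_recovered_exactly(self, rng):
        seq, repeat, spacers = _array_seq(rng)
        contig = Contig("c", _dna(rng, 2000) + seq + _dna(rng, 2000), 1.0)
        arrays = detect_crispr_arrays(contig)
        assert len(arrays) == 1
        a = arrays[0]
        assert a.repeat_consensus == repeat
        assert [s[0] for s in a.spacers] == spacers
        assert len(a.repeats) == 4 and len(a.spacers) == 3
        assert not a.suspicious_duplicate
        assert a.start == 2001 and a.end == 2000 + len(seq)

    def test_random_contigs_have_no_arrays(self):
        for seed in range(20):
            rng = np.random.default_rng(3000 + seed)
            assert detect_crispr_arrays(Contig("c", _dna(rng, 5000), 1.0)) == []

    def test_identical_spacers_flagged_suspicious(self, rng):
        seq, _, _ = _array_seq(rng, identical=True)
        contig = Contig("c", _dna(rng, 1000) + seq + _dna(rng, 1000), 1.0)
        arrays = detect_crispr_arrays(contig)
        assert len(arrays) == 1
        assert arrays[0].suspicious_duplicate

    def test_spacer_repeat_count_identity(self, rng):
        for n_rep in (3, 4, 6):
            seq, _, _ = _array_seq(rng, n_rep=n_rep)
            contig = Contig("c", _dna(rng, 800) + seq + _dna(rng, 800), 1.0)
            for a in detect_crispr_arrays(contig):
                assert len(a.spacers) == len(a.repeats) - 1

    def test_two_repeats_do_not_qualify(self, rng):
        seq, _, _ = _array_seq(rng, n_rep=2)
        contig = Contig("c", _dna(rng, 800) + seq + _dna(rng, 800), 1.0)
        assert detect_crispr_arrays(contig) == []


def _gene_call(contig, start, end, family, strand="+"):
    return CasGeneCall(contig, start, end, strand, family, 100.0)


def _array_call(contig, start=1000):
    repeats = tuple((start + i * 64, start + i * 64 + 27) for i in range(4))
    spacers = tuple(
        ("A" * 36, start + i * 64 + 28, start + i * 64 + 63) for i in range(3)
    )
    return CrisprArrayCall(contig, repeats[0][0], repeats[-1][1], "G" * 28,
                           repeats, spacers, False)


class TestGroupAndType:
    def test_type_if_signature_from_full_operon(self):
        fams = ["cas1", "cas3_cas2", "csy1", "csy2", "csy3", "cas6"]
        genes = [
            _gene_call("c1", 1 + i * 1000, 900 + i * 1000, f) for i, f in enumerate(fams)
        ]
        operons, _ = group_and_type(genes, [], max_gap=500)
        assert len(operons) == 1
        assert operons[0].type_label == "TypeIF"
        assert operons[0].families == tuple(fams)

    @pytest.mark.parametrize(
        "families,label",
        [
            (["cas2", "cas1", "cas6", "cas5", "cas7", "cse2", "cse1", "cas3"], "TypeIE"),
            (["cas2", "cas1", "cas4", "cas7c", "cas8c", "cas5c", "cas3"], "TypeIC"),
            (["csf4", "csf1", "csf2", "csf3"], "TypeU"),
            (["cas1", "cas2"], "unclassified"),
            (["csy1", "csy2", "csy3", "cse1", "cse2"], "TypeIF"),  # precedence
        ],
    )
    def test_signature_classification(self, families, label):
        assert classify_operon(families) == label

    def test_gap_splits_operons(self):
        genes = [
            _gene_call("c1", 1, 900, "cas1"),
            _gene_call("c1", 1201, 2100, "cas2"),
            _gene_call("c1", 4201, 5100, "cas6"),  # 2.1 kb gap upstream
        ]
        operons, _ = group_and_type(genes, [], max_gap=500)
        assert [len(o.genes) for o in operons] == [2, 1]

    def test_isolation_is_per_contig(self):
        genes = [_gene_call("c1", 1, 900, "cas1")]
        arrays = [_array_call("c1"), _array_call("c2")]
        _, isolated = group_and_type(genes, arrays)
        assert [a.contig_id for a in isolated] == ["c2"]


class TestWriteAnnotations:
    @pytest.fixture()
    def calls(self):
        contigs = [Contig("c1", "A" * 6000, 12.0), Contig("tiny", "A" * 300, 5.0)]
        fams = ["cas1", "cas3_cas2", "csy1", "csy2", "csy3", "cas6"]
        genes = [
            _gene_call("c1", 1 + i * 900, 850 + i * 900 + 2, f)
            for i, f in enumerate(fams)
        ]
        arrays = [_array_call("c1", 5500), _array_call("tiny", 10)]
        operons, _ = group_and_type(genes, arrays)
        return contigs, genes, arrays, operons

    def test_feature_counts(self, tmp_path, calls):
        contigs, genes, arrays, operons = calls
        path = write_annotations(contigs, genes, arrays, operons, tmp_path)
        lines = [l for l in path.read_text().splitlines() if not l.startswith("#")]
        types = [l.split("\t")[2] for l in lines]
        assert types.count("CDS") == 6
        assert types.count("repeat_region") == 1  # 'tiny' is skipped
        assert types.count("direct_repeat") == 4
        assert types.count("binding_site") == 3

    def test_short_contigs_skipped_entirely(self, tmp_path, calls):
        contigs, genes, arrays, operons = calls
        path = write_annotations(
            contigs, genes, arrays, operons, tmp_path, min_contig=10_000
        )
        body = [l for l in path.read_text().splitlines() if not l.startswith("#")]
        assert body == []
        assert path.read_text().startswith("##gff-version 3")

    def test_round_trip_through_gff_reader(self, tmp_path, calls):
        gffutils = pytest.importorskip("gffutils")
        contigs, genes, arrays, operons = calls
        path = write_annotations(contigs, genes, arrays, operons, tmp_path)
        db = gffutils.create_db(
            str(path), ":memory:", force=True, keep_order=True,
            merge_strategy="create_unique",
        )
        cds = list(db.features_of_type("CDS"))
        assert [(f.start, f.end) for f in cds] == [(g.start, g.end) for g in genes]
        assert [f.attributes["family"][0] for f in cds] == [g.family for g in genes]
        rep = next(db.features_of_type("repeat_region"))
        assert rep.attributes["n_spacers"] == ["3"]
        assert len(list(db.children(rep, featuretype="direct_repeat"))) == 4
        spacer_rows = list(db.children(rep, featuretype="binding_site"))
        assert len(spacer_rows) == 3
        # coordinates never exceed the contig
        for f in db.all_features():
            assert f.end <= 6000

    def test_coordinates_sorted(self, tmp_path, calls):
        contigs, genes, arrays, operons = calls
        path = write_annotations(contigs, genes, arrays, operons, tmp_path)
        rows = [l.split("\t") for l in path.read_text().splitlines() if "\t" in l]
        keys = [(r[0], int(r[3])) for r in rows]
        assert keys == sorted(keys)
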