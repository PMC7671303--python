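import math

import numpy as np
import pytest

from casbait.core_io import ReadRecord
from casbait.profiles import (
    AMINO_ALPHABET,
    AMINO_BACKGROUND,
    ProfileHMM,
    best_frame,
    encode_peptide,
    parse_hmm,
    viterbi_bits,
    write_hmm,
)
from casbait.resources import demo_profiles, make_profile

from _oracles import viterbi_enumerate

LN2 = math.log(2.0)


def _toy_hmm_text(name, match_probs, ga=None):
    """Compose a minimal HMMER3 ASCII model from per-state emission
    probability dicts (missing residues share the remainder equally)."""
    lines = [
        "HMMER3/f [toy]",
        f"NAME  {name}",
        f"LENG  {len(match_probs)}",
        "ALPH  amino",
    ]
    if ga is not None:
        lines.append(f"GA    {ga:.2f} {ga:.2f};")
    lines += [
        "HMM          " + "  ".join(AMINO_ALPHABET),
        "            m->m     m->i     m->d     i->m     i->i     d->m     d->d",
        "          " + " ".join("2.99573" for _ in range(20)),  # node-0 inserts
        "          0.01005 5.29832 5.29832 0.69315 0.69315 0.00000 *",
    ]
    uniform = " ".join("2.99573" for _ in range(20))  # p = 1/20
    trans = "0.10536 2.99573 2.99573 0.69315 0.69315 0.35667 1.20397"
    for k, probs in enumerate(match_probs, 1):
        rest = (1.0 - sum(probs.values())) / (20 - len(probs))
        vals = []
        for aa in AMINO_ALPHABET:
            p = probs.get(aa, rest)
            vals.append("*" if p <= 0 else f"{-math.log(p):.5f}")
        lines.append(f"{k:7d}   " + " ".join(vals) + f"{k:7d} x - - -")
        lines.append("          " + uniform)
        lines.append("          " + trans)
    lines.append("//")
    return "\n".join(lines) + "\n"


class TestParseHmm:
    def test_emission_conversion_matches_hand_formula(self, tmp_path):
        probs = [{"A": 0.5}, {"W": 0.7}, {"C": 0.25, "Y": 0.25}]
        p = tmp_path / "toy.hmm"
        p.write_text(_toy_hmm_text("toy1", probs))
        (hmm,) = parse_hmm(p)
        assert hmm.M == 3 and hmm.name == "toy1"
        bg = dict(zip(AMINO_ALPHABET, AMINO_BACKGROUND))
        # bits = log2(p / background), from the file's -ln(p) encoding
        assert hmm.match_emit[0, AMINO_ALPHABET.index("A")] == pytest.approx(
            math.log2(0.5 / bg["A"]), abs=2e-4
        )
        assert hmm.match_emit[1, AMINO_ALPHABET.index("W")] == pytest.approx(
            math.log2(0.7 / bg["W"]), abs=2e-4
        )
        # transitions are plain log2 probabilities
        assert hmm.transitions[0, 0] == pytest.approx(math.log2(0.9), abs=2e-4)
        # insert emissions written at background-ish 1/20
        assert hmm.insert_emit[0, 0] == pytest.approx(
            math.log2(0.05 / bg["A"]), abs=2e-4
        )

    def test_multiple_models_and_ga(self, tmp_path):
        text = _toy_hmm_text("m1", [{"A": 0.5}] * 2, ga=21.5) + _toy_hmm_text(
            "m2", [{"C": 0.5}] * 4
        )
        p = tmp_path / "two.hmm"
        p.write_text(text)
        models = parse_hmm(p)
        assert [m.name for m in models] == ["m1", "m2"]
        assert [m.M for m in models] == [2, 4]
        assert models[0].threshold_bits == 21.5
        assert models[1].threshold_bits is None
        assert models[1].threshold(default=9.0) == 9.0

    def test_truncated_model_is_hard_error(self, tmp_path):
        text = _toy_hmm_text("trunc", [{"A": 0.5}] * 3)
        p = tmp_path / "trunc.hmm"
        p.write_text(text.replace("//\n", ""))
        with pytest.raises(ValueError, match="trunc"):
            parse_hmm(p)

    def test_missing_leng_is_hard_error(self, tmp_path):
        text = _toy_hmm_text("noleng", [{"A": 0.5}])
        p = tmp_path / "noleng.hmm"
        p.write_text("\n".join(l for l in text.splitlines() if not l.startswith("LENG")) + "\n")
        with pytest.raises(ValueError, match="noleng"):
            parse_hmm(p)

    def test_bad_magic(self, tmp_path):
        p = tmp_path / "bad.hmm"
        p.write_text("NOT A PROFILE\n")
        with pytest.raises(ValueError, match="magic"):
            parse_hmm(p)

    def test_round_trip_against_pyhmmer(self, tmp_path):
        """Our writer + parser agree with an independent HMMER3 reader."""
        pyhmmer = pytest.importorskip("pyhmmer")
        p = tmp_path / "demo.hmm"
        profiles = list(demo_profiles())[:3]
        write_hmm(profiles, p)
        ours = parse_hmm(p)
        with pyhmmer.plan7.HMMFile(str(p)) as fh:
            theirs = list(fh)
        names = [
            h.name.decode() if isinstance(h.name, bytes) else h.name for h in theirs
        ]
        assert names == [h.name for h in ours]
        assert [h.M for h in theirs] == [h.M for h in ours]
        for mine, ref in zip(ours, theirs):
            ref_probs = np.asarray(ref.match_emissions)[1:, :20]  # row 0 is node 0
            mine_probs = mine.null * np.exp2(mine.match_emit[:, :20])
            assert np.allclose(mine_probs, ref_probs, atol=1e-4)


class TestBestFrame:
    def test_clean_plus_one_orf(self, rng):
        aas = [a for a in AMINO_ALPHABET if a != "M"]
        pep = "M" + "".join(rng.choice(aas, size=39))
        from casbait.simdata import _reverse_translate

        nt = _reverse_translate(rng, pep)
        call = best_frame(ReadRecord("r", nt))
        assert call is not None
        assert call.frame == 1
        assert call.peptide == pep

    def test_short_stretches_return_none(self):
        # stops within every 4 codons in all six frames of this motif
        seq = ("ATTAATTAACTA" * 6)[:60]
        assert best_frame(ReadRecord("r", seq), min_aa=20) is None

    def test_tie_breaks_toward_first_frame(self):
        # poly-C translates stop-free in all six frames; +1 and -1 tie
        # at 20 codons and +1 must win
        call = best_frame(ReadRecord("r", "C" * 60))
        assert call.frame == 1
        assert call.peptide == "P" * 20


class TestViterbi:
    def test_consensus_scores_as_hand_sum(self):
        hmm = make_profile("toy", "MKVWY")
        pep = hmm.consensus_peptide()
        expected = hmm.entry_bits + sum(
            hmm.match_emit[k, AMINO_ALPHABET.index(a)] for k, a in enumerate(pep)
        ) + 4 * hmm.transitions[0, 0]
        assert viterbi_bits(pep, hmm) == pytest.approx(expected, abs=1e-9)

    def test_single_state_model_scores_one_residue(self):
        hmm = make_profile("one", "W")
        # M = 1: entry is log2(2/2) = 0, so the score is the emission
        assert viterbi_bits("W", hmm) == pytest.approx(
            hmm.match_emit[0, AMINO_ALPHABET.index("W")]
        )

    def test_non_canonical_letters_emit_background(self):
        hmm = make_profile("toy", "MKV")
        assert viterbi_bits("X", hmm) == pytest.approx(hmm.entry_bits)

    @staticmethod
    def _random_toy(rng, M):
        me = np.zeros((M, 21))
        ie = np.zeros((M, 21))
        me[:, :20] = rng.normal(0.0, 2.0, (M, 20))
        ie[:, :20] = rng.normal(0.0, 0.5, (M, 20))
        tr = rng.normal(-1.0, 0.7, (M, 7))
        return ProfileHMM(
            name=f"rand{M}", M=M, match_emit=me, insert_emit=ie,
            transitions=tr, null=AMINO_BACKGROUND.copy(),
        )

    def test_matches_exhaustive_enumeration(self, rng):
        """Viterbi equals the brute-force all-paths maximum (the full
        100-trial sweep runs with the end-to-end tests)."""
        for _ in range(30):
            M = int(rng.integers(1, 5))
            L = int(rng.integers(1, 7))
            hmm = self._random_toy(rng, M)
            pep = "".join(rng.choice(list(AMINO_ALPHABET), size=L))
            expected = viterbi_enumerate(list(encode_peptide(pep)), hmm)
            assert viterbi_bits(pep, hmm) == pytest.approx(expected, abs=1e-9)

    def test_padding_never_decreases_score(self, rng):
        hmm = make_profile("toy", "MKVWYACD")
        core = "KVWYA"
        base = viterbi_bits(core, hmm)
        for _ in range(10):
            pad_l = "".join(rng.choice(list(AMINO_ALPHABET), size=int(rng.integers(0, 6))))
            pad_r = "".join(rng.choice(list(AMINO_ALPHABET), size=int(rng.integers(0, 6))))
            assert viterbi_bits(pad_l + core + pad_r, hmm) >= base - 1e-9
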