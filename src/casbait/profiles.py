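"""Protein profile HMMs: parsing, six-frame translation, local Viterbi.

Profiles are read from HMMER3 ASCII files (the carrier format for Cas
protein family models). Emissions are converted from the file's
negative-natural-log probabilities into bit log-odds against the
standard amino-acid background, and reads are scored by a uni-local
Viterbi pass (free entry into and exit from any match state), so a
short read translating to a fragment of a Cas protein still scores.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from Bio.Seq import Seq

from ._align import viterbi_local
from .core_io import ReadRecord, revcomp

__all__ = [
    "AMINO_ALPHABET",
    "AMINO_BACKGROUND",
    "ProfileHMM",
    "FrameCall",
    "parse_hmm",
    "write_hmm",
    "best_frame",
    "viterbi_bits",
]

AMINO_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"
_AA_INDEX = {a: i for i, a in enumerate(AMINO_ALPHABET)}

# Swissprot 50.8 amino-acid background frequencies (the standard null
# used by profile search tools).
AMINO_BACKGROUND = np.array(
    [
        0.0787945, 0.0151600, 0.0535222, 0.0668298, 0.0397062,
        0.0695071, 0.0229198, 0.0590092, 0.0594422, 0.0963728,
        0.0237718, 0.0414386, 0.0482904, 0.0395639, 0.0540978,
        0.0683364, 0.0540687, 0.0673417, 0.0114135, 0.0304133,
    ]
)

_LN2 = math.log(2.0)
_NEG = -1e30

# transition column order in HMMER3 files and in ProfileHMM.transitions
TRANSITIONS = ("m->m", "m->i", "m->d", "i->m", "i->i", "d->m", "d->d")


@dataclass
class ProfileHMM:
    """A protein family profile in bit log-odds form.

    match_emit / insert_emit are (M, 21): 20 canonical residue columns
    plus a zero column for non-canonical letters (they emit at
    background). transitions is (M, 7) in TRANSITIONS order, row k
    holding the transitions out of node k+1. threshold_bits is the
    model's gathering cutoff when the file provides one, else None and
    a run-level default applies.
    """

    name: str
    M: int
    match_emit: np.ndarray
    insert_emit: np.ndarray
    transitions: np.ndarray
    null: np.ndarray
    threshold_bits: float | None = None
    consensus: str | None = None

    def __post_init__(self) -> None:
        if self.M < 1:
            raise ValueError(f"profile {self.name!r}: M must be >= 1")
        for arr, cols in ((self.match_emit, 21), (self.insert_emit, 21)):
            if arr.shape != (self.M, cols):
                raise ValueError(f"profile {self.name!r}: bad emission shape {arr.shape}")
        if not np.isfinite(self.match_emit[:, :20]).all():
            raise ValueError(f"profile {self.name!r}: non-finite match emissions")

    def threshold(self, default: float = 15.0) -> float:
        return self.threshold_bits if self.threshold_bits is not None else default

    @property
    def entry_bits(self) -> float:
        """Plan7 uniform local-entry score: log2 of 2 / (M * (M + 1)).

        Paid once per alignment; without it every local alignment would
        start for free and a handful of chance consensus matches in a
        random peptide would cross any workable bit threshold.
        """
        return math.log2(2.0 / (self.M * (self.M + 1)))

    def consensus_peptide(self) -> str:
        """Highest-scoring residue per match state."""
        if self.consensus is not None:
            return self.consensus
        idx = np.argmax(self.match_emit[:, :20], axis=1)
        return "".join(AMINO_ALPHABET[i] for i in idx)


@dataclass(frozen=True)
class FrameCall:
    """The most likely reading frame of a read: the frame holding the
    longest stop-free translated stretch."""

    read_id: str
    frame: int  # one of +1,+2,+3,-1,-2,-3
    peptide: str

    def __post_init__(self) -> None:
        if "*" in self.peptide:
            raise ValueError("FrameCall peptide contains a stop")


def _nll_to_prob(tok: str) -> float:
    if tok == "*":
        return 0.0
    return math.exp(-float(tok))


def _prob_to_bits(p: float, null: float = 1.0) -> float:
    if p <= 0.0:
        return _NEG
    return math.log2(p / null)


def parse_hmm(path) -> list[ProfileHMM]:
    """Parse every model in a HMMER3 ASCII profile file.

    Stored negative-log probabilities become bit log-odds against
    AMINO_BACKGROUND (emissions) or plain log2 probabilities
    (transitions). A model missing its HMM table, LENG line or closing
    '//' is a hard error naming the model.
    """
    with open(path) as fh:
        lines = fh.read().splitlines()
    if not lines or not lines[0].startswith("HMMER3"):
        raise ValueError(f"{path}: not a HMMER3 file (bad magic)")

    profiles: list[ProfileHMM] = []
    i = 0
    n = len(lines)
    while i < n:
        while i < n and not lines[i].startswith("HMMER3"):
            if lines[i].strip():
                raise ValueError(f"{path}: unexpected content between models at line {i + 1}")
            i += 1
        if i >= n:
            break
        i += 1
        name = None
        leng = None
        ga = None
        header_ok = False
        while i < n:
            line = lines[i]
            if line.startswith("HMM "):
                header_ok = True
                break
            tok = line.split()
            if tok:
                if tok[0] == "NAME":
                    name = tok[1]
                elif tok[0] == "LENG":
                    leng = int(tok[1])
                elif tok[0] == "GA":
                    ga = float(tok[1])
            i += 1
        label = name or f"model #{len(profiles) + 1}"
        if not header_ok:
            raise ValueError(f"{path}: {label}: missing HMM table header")
        if name is None:
            raise ValueError(f"{path}: model #{len(profiles) + 1}: missing NAME line")
        if leng is None:
            raise ValueError(f"{path}: {label}: missing LENG line")
        i += 2  # skip the symbol line and the transition-order line
        # optional COMPO line, then node-0 insert emissions + transitions
        if i < n and lines[i].split() and lines[i].split()[0] == "COMPO":
            i += 1
        i += 2  # node 0 insert emissions, node 0 (begin) transitions

        bg_bits_den = AMINO_BACKGROUND  # null frequencies
        me = np.zeros((leng, 21))
        ie = np.zeros((leng, 21))
        tr = np.full((leng, 7), _NEG)
        closed = False
        k = 0
        while i < n:
            line = lines[i].strip()
            if line == "//":
                closed = True
                i += 1
                break
            if k >= leng:
                raise ValueError(f"{path}: {label}: more nodes than LENG={leng}")
            tok = line.split()
            if int(tok[0]) != k + 1:
                raise ValueError(f"{path}: {label}: expected node {k + 1}, got {tok[0]}")
            for a in range(20):
                me[k, a] = _prob_to_bits(_nll_to_prob(tok[1 + a]), bg_bits_den[a])
            itok = lines[i + 1].split()
            for a in range(20):
                ie[k, a] = _prob_to_bits(_nll_to_prob(itok[a]), bg_bits_den[a])
            ttok = lines[i + 2].split()
            for t in range(7):
                tr[k, t] = _prob_to_bits(_nll_to_prob(ttok[t]))
            i += 3
            k += 1
        if not closed:
            raise ValueError(f"{path}: {label}: truncated model (missing '//')")
        if k != leng:
            raise ValueError(f"{path}: {label}: {k} nodes found, LENG says {leng}")
        profiles.append(
            ProfileHMM(
                name=name,
                M=leng,
                match_emit=me,
                insert_emit=ie,
                transitions=tr,
                null=AMINO_BACKGROUND.copy(),
                threshold_bits=ga,
            )
        )
    if not profiles:
        raise ValueError(f"{path}: no models found")
    return profiles


def write_hmm(profiles: list[ProfileHMM], path) -> None:
    """Write profiles as a HMMER3/f ASCII file (inverse of parse_hmm)."""

    def fmt(p: float) -> str:
        if p <= 0.0:
            return "*"
        return f"{-math.log(p):.5f}"

    with open(path, "w") as fh:
        for prof in profiles:
            cons = prof.consensus_peptide()
            fh.write("HMMER3/f [casbait profile]\n")
            fh.write(f"NAME  {prof.name}\n")
            fh.write(f"LENG  {prof.M}\n")
            fh.write("ALPH  amino\n")
            fh.write("STATS LOCAL MSV      -9.0  0.7\n")
            fh.write("STATS LOCAL VITERBI  -9.0  0.7\n")
            fh.write("STATS LOCAL FORWARD  -9.0  0.7\n")
            if prof.threshold_bits is not None:
                fh.write(f"GA    {prof.threshold_bits:.2f} {prof.threshold_bits:.2f};\n")
            fh.write("HMM          " + "        ".join(AMINO_ALPHABET) + "\n")
            fh.write(
                "            m->m     m->i     m->d     i->m     i->i     d->m     d->d\n"
            )
            ins0 = " ".join(fmt(b) for b in prof.null)
            fh.write(f"          {ins0}\n")
            # begin-state transitions: B->M1 nearly certain
            fh.write(
                "          "
                + " ".join(fmt(p) for p in (0.99, 0.005, 0.005, 0.5, 0.5, 1.0, 0.0))
                + "\n"
            )
            for k in range(prof.M):
                mp = prof.null * np.exp2(prof.match_emit[k, :20])
                ip = prof.null * np.exp2(prof.insert_emit[k, :20])
                tp = np.exp2(np.maximum(prof.transitions[k], -1e6))
                tp[prof.transitions[k] <= _NEG / 2] = 0.0
                fh.write(
                    f"{k + 1:7d}   "
                    + " ".join(fmt(p) for p in mp)
                    + f"{k + 1:7d} {cons[k].lower()} - - -\n"
                )
                fh.write("          " + " ".join(fmt(p) for p in ip) + "\n")
                fh.write("          " + " ".join(fmt(p) for p in tp) + "\n")
            fh.write("//\n")


_STOP_TABLE = 11  # bacterial/archaeal code


def _frames(seq: str):
    rc = revcomp(seq)
    for f in (1, 2, 3):
        yield f, seq[f - 1 :]
    for f in (1, 2, 3):
        yield -f, rc[f - 1 :]


def best_frame(r: ReadRecord, min_aa: int = 20) -> FrameCall | None:
    """Pick the reading frame with the longest stop-free translated
    stretch; None if the best stretch is shorter than min_aa.

    Ties break toward the first frame in the order +1,+2,+3,-1,-2,-3.
    """
    best: tuple[int, int, str] | None = None  # (length, order, peptide)
    order = 0
    for frame, sub in _frames(r.seq):
        sub = sub[: len(sub) - len(sub) % 3]
        if not sub:
            order += 1
            continue
        pep = str(Seq(sub).translate(table=_STOP_TABLE))
        stretch = max(pep.split("*"), key=len) if pep else ""
        if best is None or len(stretch) > best[0]:
            best = (len(stretch), order, stretch)
            best_frame_id = frame
        order += 1
    if best is None or best[0] < min_aa:
        return None
    return FrameCall(r.id, best_frame_id, best[2])


def encode_peptide(peptide: str) -> np.ndarray:
    return np.array(
        [_AA_INDEX.get(a, 20) for a in peptide.upper()], dtype=np.int64
    )


def viterbi_bits(peptide: str, hmm: ProfileHMM) -> float:
    """Maximum bit log-odds over all local alignments of the peptide to
    the profile (uni-local: one alignment, Plan7 uniform local entry,
    free exit). Non-canonical letters emit at background (0 bits)."""
    if not peptide:
        raise ValueError("empty peptide")
    pep = encode_peptide(peptide)
    return float(
        viterbi_local(
            pep,
            np.ascontiguousarray(hmm.match_emit, dtype=np.float64),
            np.ascontiguousarray(hmm.insert_emit, dtype=np.float64),
            np.ascontiguousarray(hmm.transitions, dtype=np.float64),
            hmm.entry_bits,
        )
    )
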