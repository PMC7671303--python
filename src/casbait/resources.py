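"""Bundled demonstration resources.

A small set of synthetic Cas-family protein profiles and CRISPR repeat
sequences, generated deterministically from a fixed internal seed so
the package is self-contained and testable offline. They are synthetic
stand-ins shaped like the real resources (a type I-F/I-E cas gene
complement and short direct repeats); production runs should supply
real profile collections and repeat references via the -hmm / -query
options, which are drop-in replacements.

Each demo profile has strongly peaked match emissions (consensus
residue probability 0.9, the rest spread proportionally to background),
so reads covering >= 20 codons of a consensus-derived gene score far
above the 15-bit default acceptance threshold while random background
reads stay below it (a flatter profile would let 50-aa random peptides
chain enough lucky matches locally to cross 15 bits).
"""

from __future__ import annotations

import functools

import numpy as np

from .profiles import AMINO_ALPHABET, AMINO_BACKGROUND, ProfileHMM

__all__ = [
    "DEMO_FAMILIES",
    "demo_profiles",
    "demo_profile_map",
    "demo_repeats",
    "write_demo_hmm",
    "write_demo_repeats",
    "make_profile",
]

_SEED = 740_331  # fixed: demo resources are part of the package surface

# family name -> match-state count (loosely proportional to the real
# protein lengths; cas3_cas2 models the type I-F Cas3-Cas2 fusion)
DEMO_FAMILIES = {
    "cas1": 120,
    "cas3_cas2": 260,
    "csy1": 150,
    "csy2": 120,
    "csy3": 130,
    "cas6": 100,
    "cse1": 140,
    "cse2": 90,
}

_CONS_P = 0.9  # probability mass on the consensus residue

# transition probabilities shared by every demo node
_T = (0.97, 0.015, 0.015, 0.5, 0.5, 0.7, 0.3)


def make_profile(name: str, consensus: str, threshold_bits: float | None = None) -> ProfileHMM:
    """Build a peaked profile around a consensus peptide."""
    M = len(consensus)
    me = np.zeros((M, 21))
    ie = np.zeros((M, 21))
    tr = np.zeros((M, 7))
    bg = AMINO_BACKGROUND
    for k, aa in enumerate(consensus):
        c = AMINO_ALPHABET.index(aa)
        probs = bg * ((1.0 - _CONS_P) / (1.0 - bg[c]))
        probs[c] = _CONS_P
        me[k, :20] = np.log2(probs / bg)
        ie[k, :20] = 0.0  # inserts emit at background
        tr[k] = np.log2(_T)
    return ProfileHMM(
        name=name,
        M=M,
        match_emit=me,
        insert_emit=ie,
        transitions=tr,
        null=bg.copy(),
        threshold_bits=threshold_bits,
        consensus=consensus,
    )


@functools.lru_cache(maxsize=1)
def _consensus_peptides() -> dict[str, str]:
    rng = np.random.default_rng(_SEED)
    aas = list(AMINO_ALPHABET)
    out = {}
    for name, M in DEMO_FAMILIES.items():
        pep = "M" + "".join(rng.choice(aas, size=M - 1))
        out[name] = pep
    return out


@functools.lru_cache(maxsize=1)
def demo_profiles() -> tuple[ProfileHMM, ...]:
    return tuple(
        make_profile(name, pep) for name, pep in _consensus_peptides().items()
    )


def demo_profile_map() -> dict[str, ProfileHMM]:
    return {p.name: p for p in demo_profiles()}


@functools.lru_cache(maxsize=1)
def demo_repeats() -> tuple[tuple[str, str], ...]:
    """Synthetic direct-repeat references (name, sequence), 28-40 nt."""
    rng = np.random.default_rng(_SEED + 1)
    bases = list("ACGT")
    out = []
    for i, length in enumerate((28, 29, 30, 32, 36, 40)):
        seq = "".join(rng.choice(bases, size=length))
        out.append((f"demo_repeat_{i + 1}", seq))
    return tuple(out)


def write_demo_hmm(path) -> None:
    from .profiles import write_hmm

    write_hmm(list(demo_profiles()), path)


def write_demo_repeats(path) -> None:
    from .core_io import write_fasta

    write_fasta(demo_repeats(), path)
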