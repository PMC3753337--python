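"""Small DNA-string utilities shared across modules."""

from __future__ import annotations

import numpy as np

BASES = "ACGT"
_BASE_BYTES = np.frombuffer(b"ACGT", dtype="S1")
_COMP_TABLE = str.maketrans("ACGTacgt", "TGCAtgca")

#: IUPAC nucleotide codes -> set of concrete bases.
IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT",
    "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG",
    "N": "ACGT",
}


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (case preserved)."""
    return seq.translate(_COMP_TABLE)[::-1]


def random_dna(rng: np.random.Generator, length: int, p=None) -> str:
    """Random DNA string with base probabilities ``p`` in ACGT order."""
    idx = rng.choice(4, size=length, p=p)
    return _BASE_BYTES[idx].tobytes().decode("ascii")


def base_frequencies(seqs) -> np.ndarray:
    """Empirical ACGT frequencies over one string or an iterable of strings."""
    if isinstance(seqs, str):
        seqs = [seqs]
    counts = np.zeros(4, dtype=np.int64)
    for s in seqs:
        arr = np.frombuffer(s.encode("ascii"), dtype="S1")
        for i, b in enumerate(_BASE_BYTES):
            counts[i] += int(np.count_nonzero(arr == b))
    total = counts.sum()
    if total == 0:
        raise ValueError("empty sequence set")
    return counts / total


def gc_fraction(seq: str) -> float:
    if not seq:
        raise ValueError("empty sequence")
    return (seq.count("G") + seq.count("C")) / len(seq)


def match_probability(freqs) -> float:
    """Per-position probability that two independent bases agree: sum f_x^2."""
    f = np.asarray(freqs, dtype=float)
    return float(np.dot(f, f))


def iupac_to_regex(pattern: str) -> str:
    """Translate an IUPAC pattern into a plain regex character-class string."""
    parts = []
    for ch in pattern.upper():
        try:
            bases = IUPAC[ch]
        except KeyError:
            raise ValueError(f"invalid IUPAC code {ch!r} in pattern {pattern!r}")
        parts.append(bases if len(bases) == 1 else f"[{bases}]")
    return "".join(parts)


def iupac_matches(code: str, base: str) -> bool:
    return base in IUPAC[code]
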