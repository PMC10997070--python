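"""Low-level DNA string helpers shared across modules."""

from __future__ import annotations

import numpy as np

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

#: index order used for all 4-state numerics
NUC_ORDER = "ACGT"
_NUC_INDEX = {c: i for i, c in enumerate(NUC_ORDER)}

#: IUPAC one-letter ambiguity codes other than N
AMBIGUOUS = set("RYSWKMBDHV")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (N-safe)."""
    return seq.translate(_COMPLEMENT)[::-1]


def complement_base(base: str) -> str:
    return base.translate(_COMPLEMENT)


def seq_to_array(seq: str) -> np.ndarray:
    """Encode a DNA string as an array of single characters."""
    return np.frombuffer(seq.encode("ascii"), dtype="S1").astype("U1")


def array_to_seq(arr: np.ndarray) -> str:
    return "".join(arr.tolist())


def encode_states(seq: str) -> np.ndarray:
    """Map A,C,G,T -> 0..3 and everything else (gap, N, ambiguity) -> 4."""
    out = np.full(len(seq), 4, dtype=np.int8)
    for base, idx in _NUC_INDEX.items():
        out[np.frombuffer(seq.encode("ascii"), dtype="S1") == base.encode()] = idx
    return out


def decode_states(states: np.ndarray) -> str:
    lookup = np.array(list(NUC_ORDER + "N"), dtype="U1")
    return "".join(lookup[states].tolist())


def sanitize(seq: str) -> tuple[str, int]:
    """Uppercase and map non-N ambiguity codes to N.

    Returns the cleaned sequence and the number of replaced characters.
    """
    seq = seq.upper()
    n_replaced = sum(seq.count(c) for c in AMBIGUOUS)
    if n_replaced:
        seq = seq.translate(str.maketrans({c: "N" for c in AMBIGUOUS}))
    return seq, n_replaced
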