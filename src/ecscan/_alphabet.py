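"""Internal RNA alphabet and encodings.

The internal alphabet is RNA over {A,C,G,U,N,-}.  DNA input is converted on
read (T -> U); IUPAC ambiguity codes other than N are mapped to N; '.' and
'~' gap glyphs are normalised to '-'.
"""

import numpy as np

RESIDUES = "ACGUN-"
A, C, G, U, N_CODE, GAP = range(6)

_ENC = np.full(256, -1, dtype=np.int8)
for _i, _ch in enumerate(RESIDUES):
    _ENC[ord(_ch)] = _i

_COMPLEMENT = {"A": "U", "C": "G", "G": "C", "U": "A", "N": "N", "-": "-"}

_AMBIGUOUS = set("RYSWKMBDHV")


def normalize(raw):
    """Uppercase, T->U, ambiguity codes -> N, './~' -> '-'.

    Raises ValueError on characters outside the IUPAC nucleotide set.
    """
    out = []
    for ch in raw.upper():
        if ch == "T":
            ch = "U"
        elif ch in ".~":
            ch = "-"
        elif ch in _AMBIGUOUS:
            ch = "N"
        if ch not in RESIDUES:
            raise ValueError(f"unexpected residue character {ch!r}")
        out.append(ch)
    return "".join(out)


def encode(seq):
    """Residue string -> int8 codes (A,C,G,U,N,- -> 0..5)."""
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    codes = _ENC[arr]
    if (codes < 0).any():
        bad = chr(int(arr[np.argmax(codes < 0)]))
        raise ValueError(f"unencodable residue {bad!r}; call normalize() first")
    return codes


def decode(codes):
    return "".join(RESIDUES[c] for c in codes)


def reverse_complement(seq):
    return "".join(_COMPLEMENT[ch] for ch in reversed(seq))


# Canonical pair types, in fixed order.
PAIR_NAMES = ("AU", "CG", "GC", "GU", "UA", "UG")

# 4x4 lookup (A,C,G,U) -> pair-type index, -1 if not canonical.
PAIR_TYPE = np.full((6, 6), -1, dtype=np.int8)
for _t, _p in enumerate(PAIR_NAMES):
    PAIR_TYPE[RESIDUES.index(_p[0]), RESIDUES.index(_p[1])] = _t


def can_pair(x, y):
    """True if encoded residues x, y form a canonical (incl. wobble) pair."""
    return x < 4 and y < 4 and PAIR_TYPE[x, y] >= 0
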