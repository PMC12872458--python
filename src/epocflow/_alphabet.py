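"""Amino-acid alphabet shared by the alignment and likelihood machinery."""

import numpy as np

# PAML / dat-file residue order.
AA = "ARNDCQEGHILKMFPSTWYV"
N_STATES = 20
AA_INDEX = {a: i for i, a in enumerate(AA)}

GAP_CHARS = frozenset("-.")
# Ambiguity codes treated as fully missing data.
MISSING_CHARS = frozenset("XBZJUO*?")


def encode_sequence(seq: str) -> np.ndarray:
    """Encode residues as ints 0..19; gaps/ambiguity become -1 (missing).

    Raises ValueError on characters outside the amino-acid alphabet,
    gap characters and recognised ambiguity codes.
    """
    out = np.empty(len(seq), dtype=np.int64)
    for i, ch in enumerate(seq):
        c = ch.upper()
        idx = AA_INDEX.get(c)
        if idx is not None:
            out[i] = idx
        elif c in GAP_CHARS or c in MISSING_CHARS:
            out[i] = -1
        else:
            raise ValueError(f"unknown residue {ch!r} at position {i}")
    return out
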