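"""Character-state alphabets and ambiguity-code semantics.

Three data types are supported: DNA (4 states, order ACGT), amino acids
(20 states, PAML order ARNDCQEGHILKMFPSTWYV) and binary characters
(2 states, order 01).  Each character maps to the set of states it is
compatible with; a gap or fully unknown code maps to the full state set.
The same tables drive tip conditional-likelihood encodings (0/1 vectors)
and parsimony bitmasks.
"""

from __future__ import annotations

import numpy as np

DNA = "DNA"
AA = "AA"
BINARY = "BINARY"

DNA_STATES = "ACGT"
AA_STATES = "ARNDCQEGHILKMFPSTWYV"
BIN_STATES = "01"

_DNA_CODES = {
    "A": "A", "C": "C", "G": "G", "T": "T", "U": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG",
    "N": "ACGT", "-": "ACGT", "?": "ACGT", ".": "ACGT", "O": "ACGT",
}

_AA_CODES = {c: c for c in AA_STATES}
_AA_CODES.update({
    "B": "DN", "Z": "EQ", "J": "IL",
    "X": AA_STATES, "?": AA_STATES, "-": AA_STATES, "*": AA_STATES,
    ".": AA_STATES,
})

_BIN_CODES = {"0": "0", "1": "1", "-": "01", "?": "01", ".": "01"}


class DataTypeInfo:
    """Alphabet of one data type plus derived encoding tables."""

    def __init__(self, name: str, states: str, codes: dict[str, str]):
        self.name = name
        self.states = states
        self.n_states = len(states)
        self.codes = codes
        idx = {s: i for i, s in enumerate(states)}
        # character -> 0/1 compatibility vector over states
        self.tip_vectors: dict[str, np.ndarray] = {}
        # character -> bitmask over states (for parsimony)
        self.bitmasks: dict[str, int] = {}
        for char, compat in codes.items():
            vec = np.zeros(self.n_states)
            mask = 0
            for s in compat:
                vec[idx[s]] = 1.0
                mask |= 1 << idx[s]
            self.tip_vectors[char] = vec
            self.bitmasks[char] = mask
        self.full_mask = (1 << self.n_states) - 1
        self.state_index = idx

    def is_valid(self, char: str) -> bool:
        return char in self.codes

    def is_missing(self, char: str) -> bool:
        """True when the character carries no state information (gap/unknown)."""
        return len(self.codes[char]) == self.n_states

    def __repr__(self) -> str:  # pragma: no cover
        return f"DataTypeInfo({self.name})"


DATA_TYPES: dict[str, DataTypeInfo] = {
    DNA: DataTypeInfo(DNA, DNA_STATES, _DNA_CODES),
    AA: DataTypeInfo(AA, AA_STATES, _AA_CODES),
    BINARY: DataTypeInfo(BINARY, BIN_STATES, _BIN_CODES),
}


def get_type(name: str) -> DataTypeInfo:
    try:
        return DATA_TYPES[name.upper()]
    except KeyError:
        raise ValueError(f"unknown data type: {name!r}") from None
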