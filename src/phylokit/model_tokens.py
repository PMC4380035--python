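"""Model-specification tokens used in partition files and on the CLI.

A token is a base model optionally followed by modifiers, e.g. ``GTR+G``,
``WAG+G4``, ``BIN+ASC``, ``HKY+PSR``.  DNA base models are the named
classics or an explicit rate-linkage string in restricted-growth form over
the exchangeability slots (AC, AG, AT, CG, CT, GT); e.g. ``010010`` is the
HKY/K80 linkage (transitions vs transversions).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

from .states import AA, BINARY, DNA

AA_MODEL_NAMES = (
    "DAYHOFF", "DCMUT", "JTT", "MTREV", "WAG", "RTREV", "CPREV", "VT",
    "BLOSUM62", "MTMAM", "LG", "MTART", "MTZOA", "PMB", "HIVB", "HIVW",
    "JTTDCMUT", "FLU",
)

# named DNA models as (linkage restricted-growth string, frequency mode)
DNA_NAMED = {
    "JC": ("000000", "equal"),
    "JC69": ("000000", "equal"),
    "F81": ("000000", "empirical"),
    "K80": ("010010", "equal"),
    "HKY": ("010010", "empirical"),
    "HKY85": ("010010", "empirical"),
    "GTR": ("012345", "empirical"),
}

_RGS_RE = re.compile(r"^[0-5]{6}$")


def is_linkage_string(tok: str) -> bool:
    """Valid restricted-growth string over the six exchangeability slots."""
    if not _RGS_RE.match(tok):
        return False
    top = -1
    for ch in tok:
        d = int(ch)
        if d > top + 1:
            return False
        top = max(top, d)
    return True


@dataclass
class ModelSpec:
    """Parsed model token."""

    base: str                      # canonical base token
    data_type: str                 # DNA | AA | BINARY
    linkage: str | None = None     # restricted-growth string (DNA only)
    freq_mode: str = "empirical"   # equal | empirical | model | ml
    gamma: bool = False
    gamma_categories: int = 4
    psr: bool = False
    psr_categories: int = 4
    ascertainment: bool = False

    def __str__(self) -> str:
        s = self.base
        if self.gamma:
            s += "+G" if self.gamma_categories == 4 else f"+G{self.gamma_categories}"
        if self.psr:
            s += "+PSR"
        if self.ascertainment:
            s += "+ASC"
        return s


def parse_model_token(token: str) -> ModelSpec:
    parts = token.strip().upper().split("+")
    base = parts[0]
    if base in DNA_NAMED:
        linkage, fmode = DNA_NAMED[base]
        spec = ModelSpec(base, DNA, linkage=linkage, freq_mode=fmode)
    elif base == "DNA":
        linkage, fmode = DNA_NAMED["GTR"]
        spec = ModelSpec("GTR", DNA, linkage=linkage, freq_mode=fmode)
    elif is_linkage_string(base):
        spec = ModelSpec(base, DNA, linkage=base, freq_mode="empirical")
    elif base in AA_MODEL_NAMES:
        spec = ModelSpec(base, AA, freq_mode="model")
    elif base in ("BIN", "BINARY"):
        spec = ModelSpec("BIN", BINARY, freq_mode="empirical")
    else:
        raise ValueError(f"unknown model token: {token!r}")
    for mod in parts[1:]:
        if mod.startswith("G"):
            spec.gamma = True
            if mod[1:]:
                spec.gamma_categories = int(mod[1:])
        elif mod.startswith("PSR"):
            spec.psr = True
            if mod[3:]:
                spec.psr_categories = int(mod[3:])
        elif mod == "ASC":
            spec.ascertainment = True
        elif mod in ("FO", "FML"):
            spec.freq_mode = "ml"
        elif mod == "FC":
            spec.freq_mode = "empirical"
        elif mod == "FQ":
            spec.freq_mode = "equal"
        else:
            raise ValueError(f"unknown model modifier: +{mod}")
    if spec.gamma and spec.psr:
        raise ValueError("a partition cannot use both +G and +PSR")
    return spec


def known_model_token(token: str) -> bool:
    try:
        parse_model_token(token)
        return True
    except ValueError:
        return False


def model_token_data_type(token: str) -> str:
    return parse_model_token(token).data_type
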