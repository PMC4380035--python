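"""Alignment containers, FASTA/PHYLIP readers and writers, partition
schemes, and site-pattern compression.

An :class:`Alignment` is a taxa-by-sites character matrix.  For likelihood
work it is compressed per partition into a :class:`PatternAlignment`:
identical site columns collapse into one pattern with an integer weight, so
the pruning recursion runs once per unique column instead of once per site.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np

from .states import AA, BINARY, DNA, DataTypeInfo, get_type


class AlignmentError(ValueError):
    """Malformed alignment, partition file, or inconsistent inputs."""


@dataclass
class Alignment:
    """Uncompressed character matrix; rows are taxa, columns are sites."""

    taxon_names: list[str]
    data: list[str]  # one upper-cased string per taxon

    def __post_init__(self) -> None:
        if len(self.taxon_names) != len(self.data):
            raise AlignmentError("taxon count does not match row count")
        if len(self.taxon_names) != len(set(self.taxon_names)):
            dup = sorted({n for n in self.taxon_names if self.taxon_names.count(n) > 1})
            raise AlignmentError(f"duplicate taxon name(s): {dup}")
        if any(not n for n in self.taxon_names):
            raise AlignmentError("empty taxon name")
        if not self.data or not self.data[0]:
            raise AlignmentError("alignment has no sites")
        n = len(self.data[0])
        for name, row in zip(self.taxon_names, self.data):
            if len(row) != n:
                raise AlignmentError(
                    f"unequal sequence lengths: {name!r} has {len(row)}, expected {n}"
                )

    @property
    def n_taxa(self) -> int:
        return len(self.taxon_names)

    @property
    def n_sites(self) -> int:
        return len(self.data[0])

    def validate_characters(self, scheme: "PartitionScheme") -> None:
        for part in scheme.partitions:
            dt = get_type(part.data_type)
            for name, row in zip(self.taxon_names, self.data):
                for site in part.sites:
                    ch = row[site]
                    if not dt.is_valid(ch):
                        raise AlignmentError(
                            f"invalid {dt.name} character {ch!r} at taxon {name!r},"
                            f" site {site + 1}"
                        )


@dataclass
class Partition:
    """One partition: a name, data type, model spec token, and its sites."""

    name: str
    data_type: str
    model_spec: str
    site_ranges: list[tuple[int, int, int]]  # 1-based (start, end, stride)

    @property
    def sites(self) -> list[int]:
        """0-based site indices, in ascending order."""
        out: list[int] = []
        for start, end, stride in self.site_ranges:
            out.extend(range(start - 1, end, stride))
        return sorted(out)


@dataclass
class PartitionScheme:
    partitions: list[Partition]

    def validate(self, n_sites: int) -> None:
        seen: dict[int, str] = {}
        for part in self.partitions:
            for s in part.sites:
                if s < 0 or s >= n_sites:
                    raise AlignmentError(
                        f"partition {part.name!r}: site {s + 1} beyond alignment"
                        f" length {n_sites}"
                    )
                if s in seen:
                    raise AlignmentError(
                        f"site {s + 1} assigned to both {seen[s]!r} and {part.name!r}"
                    )
                seen[s] = part.name
        missing = [s + 1 for s in range(n_sites) if s not in seen]
        if missing:
            head = ", ".join(map(str, missing[:5]))
            raise AlignmentError(f"sites not covered by any partition: {head}"
                                 + ("..." if len(missing) > 5 else ""))


@dataclass
class PatternPartition:
    """Compressed patterns for one partition."""

    partition: Partition
    patterns: list[str]          # one string per taxon? no: per pattern, chars across taxa
    weights: np.ndarray          # positive ints, one per pattern
    pattern_to_sites: list[list[int]]  # original 0-based site indices per pattern

    @property
    def n_patterns(self) -> int:
        return len(self.patterns)


@dataclass
class PatternAlignment:
    """Per-partition site-pattern compression of an alignment.

    ``parts[k].patterns[p]`` is the column string (one character per taxon,
    in ``taxon_names`` order) of pattern ``p`` of partition ``k``.
    """

    taxon_names: list[str]
    parts: list[PatternPartition]
    n_sites: int

    @property
    def n_taxa(self) -> int:
        return len(self.taxon_names)


# ---------------------------------------------------------------------------
# FASTA

def parse_fasta(text: str) -> Alignment:
    names: list[str] = []
    seqs: list[str] = []
    current: list[str] | None = None
    for line in text.splitlines():
        line = line.strip()
        if not line:
            continue
        if line.startswith(">"):
            name = line[1:].strip()
            if not name:
                raise AlignmentError("empty FASTA header")
            names.append(name)
            current = []
            seqs.append("")
            continue
        if current is None:
            raise AlignmentError("sequence data before first FASTA header")
        seqs[-1] += line.upper().replace(" ", "")
    if len(names) < 2:
        raise AlignmentError("FASTA must contain at least 2 records")
    if any(not s for s in seqs):
        empty = names[seqs.index("")]
        raise AlignmentError(f"empty FASTA record: {empty!r}")
    return Alignment(names, seqs)


def write_fasta(aln: Alignment, width: int = 70) -> str:
    lines = []
    for name, seq in zip(aln.taxon_names, aln.data):
        lines.append(f">{name}")
        for i in range(0, len(seq), width):
            lines.append(seq[i:i + width])
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# PHYLIP (relaxed names, sequential or interleaved)

def parse_phylip(text: str) -> Alignment:
    lines = [ln.rstrip() for ln in text.splitlines() if ln.strip()]
    if not lines:
        raise AlignmentError("empty PHYLIP input")
    header = lines[0].split()
    if len(header) != 2:
        raise AlignmentError(f"bad PHYLIP header: {lines[0]!r}")
    try:
        n_taxa, n_sites = int(header[0]), int(header[1])
    except ValueError:
        raise AlignmentError(f"bad PHYLIP header: {lines[0]!r}") from None
    body = lines[1:]
    if len(body) < n_taxa:
        raise AlignmentError(f"header promises {n_taxa} taxa, body has {len(body)} lines")

    names: list[str] = []
    seqs: list[str] = []
    # first block: name + sequence fragment
    for ln in body[:n_taxa]:
        parts = ln.split(None, 1)
        if len(parts) == 1:
            name, frag = parts[0], ""
        else:
            name, frag = parts
        names.append(name)
        seqs.append(frag.replace(" ", "").upper())
    if len(set(names)) != n_taxa:
        dup = sorted({n for n in names if names.count(n) > 1})
        raise AlignmentError(f"duplicate taxon name(s): {dup}")
    # subsequent interleaved blocks: bare sequence fragments, cycling taxa
    for i, ln in enumerate(body[n_taxa:]):
        seqs[i % n_taxa] += ln.replace(" ", "").upper()
    for name, s in zip(names, seqs):
        if len(s) != n_sites:
            raise AlignmentError(
                f"taxon {name!r}: {len(s)} characters, header promises {n_sites}"
            )
    return Alignment(names, seqs)


def write_phylip(aln: Alignment) -> str:
    width = max(len(n) for n in aln.taxon_names) + 2
    lines = [f"{aln.n_taxa} {aln.n_sites}"]
    for name, seq in zip(aln.taxon_names, aln.data):
        lines.append(f"{name:<{width}}{seq}")
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# Partition files (RAxML-style dialect): "MODEL, name = 1-500, 600-700\2"

_RANGE_RE = re.compile(r"^(\d+)(?:-(\d+))?(?:\\(\d+))?$")

# tokens recognized in the MODEL field; anything else is an error
from .model_tokens import known_model_token, model_token_data_type  # noqa: E402


def parse_partition_file(text: str, n_sites: int) -> PartitionScheme:
    parts: list[Partition] = []
    for lineno, raw in enumerate(text.splitlines(), 1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "," not in line or "=" not in line:
            raise AlignmentError(f"partition line {lineno}: expected 'MODEL, name = ranges'")
        model_tok, rest = line.split(",", 1)
        model_tok = model_tok.strip()
        if not known_model_token(model_tok):
            raise AlignmentError(f"partition line {lineno}: unknown model token {model_tok!r}")
        name, ranges_str = rest.split("=", 1)
        name = name.strip()
        if not name:
            raise AlignmentError(f"partition line {lineno}: empty partition name")
        ranges: list[tuple[int, int, int]] = []
        for tok in ranges_str.split(","):
            tok = tok.strip()
            m = _RANGE_RE.match(tok)
            if not m:
                raise AlignmentError(f"partition line {lineno}: bad range {tok!r}")
            start = int(m.group(1))
            end = int(m.group(2)) if m.group(2) else start
            stride = int(m.group(3)) if m.group(3) else 1
            if start < 1 or end < start or stride < 1:
                raise AlignmentError(f"partition line {lineno}: bad range {tok!r}")
            ranges.append((start, end, stride))
        parts.append(Partition(name, model_token_data_type(model_tok), model_tok, ranges))
    if not parts:
        raise AlignmentError("partition file contains no partitions")
    scheme = PartitionScheme(parts)
    scheme.validate(n_sites)
    return scheme


def detect_data_type(aln: Alignment) -> str:
    """DNA if >= 90% of informative characters are in {A,C,G,T,U}, else AA."""
    nuc = 0
    total = 0
    dna = get_type(DNA)
    for row in aln.data:
        for ch in row:
            if ch in "-?.":
                continue
            total += 1
            if ch in "ACGTUN":
                nuc += 1
    if total == 0:
        raise AlignmentError("alignment contains only missing data")
    if nuc / total >= 0.9:
        return DNA
    aa = get_type(AA)
    if all(aa.is_valid(ch) for row in aln.data for ch in row):
        return AA
    raise AlignmentError("cannot auto-detect data type (neither DNA nor AA)")


def default_scheme(aln: Alignment, model_spec: str | None = None) -> PartitionScheme:
    """Single partition over all sites.

    With an explicit model token the data type follows the token;
    otherwise it is auto-detected and a default model assigned."""
    if model_spec is None:
        dt = detect_data_type(aln)
        model_spec = "GTR" if dt == DNA else "LG"
    else:
        dt = model_token_data_type(model_spec)
    return PartitionScheme(
        [Partition("p1", dt, model_spec, [(1, aln.n_sites, 1)])]
    )


# ---------------------------------------------------------------------------
# Pattern compression

def compress_patterns(aln: Alignment, scheme: PartitionScheme) -> PatternAlignment:
    """Collapse identical site columns within each partition.

    Likelihood on (patterns, weights) equals likelihood on raw sites because
    sites are modelled i.i.d.; this is purely a computational device.
    """
    scheme.validate(aln.n_sites)
    aln.validate_characters(scheme)
    # map U -> T in DNA partitions at compression time so downstream code
    # only ever sees the canonical code set
    parts: list[PatternPartition] = []
    for part in scheme.partitions:
        dt = get_type(part.data_type)
        seen: dict[str, int] = {}
        patterns: list[str] = []
        weights: list[int] = []
        pattern_sites: list[list[int]] = []
        for site in part.sites:
            col = "".join(row[site] for row in aln.data)
            if dt.name == DNA:
                col = col.replace("U", "T")
            idx = seen.get(col)
            if idx is None:
                seen[col] = len(patterns)
                patterns.append(col)
                weights.append(1)
                pattern_sites.append([site])
            else:
                weights[idx] += 1
                pattern_sites[idx].append(site)
        parts.append(
            PatternPartition(part, patterns, np.asarray(weights, dtype=np.int64),
                             pattern_sites)
        )
    return PatternAlignment(list(aln.taxon_names), parts, aln.n_sites)


def tip_clv_matrix(pp: PatternPartition, taxon_index: int, dt: DataTypeInfo) -> np.ndarray:
    """(n_patterns, n_states) 0/1 compatibility matrix for one taxon."""
    out = np.empty((pp.n_patterns, dt.n_states))
    for p, col in enumerate(pp.patterns):
        out[p] = dt.tip_vectors[col[taxon_index]]
    return out


def tip_bitmask_vector(pp: PatternPartition, taxon_index: int, dt: DataTypeInfo) -> np.ndarray:
    """(n_patterns,) parsimony state-set bitmasks for one taxon."""
    return np.array([dt.bitmasks[col[taxon_index]] for col in pp.patterns],
                    dtype=np.uint32)
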