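"""IUPAC consensus scanning of promoter fragments and paralog comparison.

Motifs are written as IUPAC consensus strings (``CANNTG``) with optional
fixed-length repeats (``CCW{6}GG``).  Scanning reports every match on both
strands in forward-strand 0-based half-open coordinates; palindromic matches
that cover the same span are collapsed to a single hit.  The paralog
comparison splits the motif names observed in two promoters into shared and
exclusive sets — the pattern of interest when asking whether duplicated genes
have diverged in their cis-regulatory repertoire.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from dupsel.core_io import SequenceRecord

IUPAC = {
    "A": "A",
    "C": "C",
    "G": "G",
    "T": "T",
    "R": "AG",
    "Y": "CT",
    "S": "CG",
    "W": "AT",
    "K": "GT",
    "M": "AC",
    "B": "CGT",
    "D": "AGT",
    "H": "ACT",
    "V": "ACG",
    "N": "ACGT",
}

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")


@dataclass(frozen=True)
class MotifDefinition:
    name: str
    consensus: str
    source: str = ""

    def __post_init__(self) -> None:
        if not self.consensus:
            raise ValueError("motif consensus must be non-empty")


@dataclass(frozen=True)
class MotifHit:
    sequence_id: str
    motif_name: str
    start: int
    end: int
    strand: str
    matched_text: str


@dataclass(frozen=True)
class MotifComparison:
    pair: tuple[str, str]
    counts_a: dict[str, int]
    counts_b: dict[str, int]
    shared_motif_names: frozenset[str]
    exclusive_to_a: frozenset[str]
    exclusive_to_b: frozenset[str]


def _expand_repeats(consensus: str) -> str:
    """Expand X{n} fixed-repeat notation: CCW{6}GG -> CCWWWWWWGG."""

    def repl(m: re.Match) -> str:
        return m.group(1) * int(m.group(2))

    return re.sub(r"([A-Za-z])\{(\d+)\}", repl, consensus)


def expanded_length(consensus: str) -> int:
    return len(_expand_repeats(consensus))


def reverse_complement(consensus: str) -> str:
    return _expand_repeats(consensus).upper().translate(_COMPLEMENT)[::-1]


def compile_motif(definition: MotifDefinition) -> re.Pattern:
    """Regex matcher recognizing exactly the IUPAC-consistent sequences."""
    expanded = _expand_repeats(definition.consensus).upper()
    parts = []
    for ch in expanded:
        if ch not in IUPAC:
            raise ValueError(
                f"illegal IUPAC code {ch!r} in motif {definition.name!r}"
            )
        allowed = IUPAC[ch]
        parts.append(allowed if len(allowed) == 1 else f"[{allowed}]")
    return re.compile("".join(parts))


def _scan_one_strand(seq: str, pattern: re.Pattern):
    """All (possibly overlapping) match starts via a lookahead scan."""
    probe = re.compile(f"(?=({pattern.pattern}))")
    return [(m.start(), m.group(1)) for m in probe.finditer(seq)]


def scan_motifs(
    seq: SequenceRecord, motifs: Iterable[MotifDefinition]
) -> list[MotifHit]:
    """All motif matches on both strands, in forward coordinates.

    Minus-strand hits of a motif are found by scanning the forward sequence
    with the reverse-complemented consensus, so reported coordinates always
    index the forward strand.  Identical (span, motif) matches on both
    strands (palindromes) are reported once, on the plus strand.
    """
    hits: dict[tuple[int, int, str], MotifHit] = {}
    s = seq.residues
    for motif in motifs:
        fwd = compile_motif(motif)
        for start, text in _scan_one_strand(s, fwd):
            key = (start, start + len(text), motif.name)
            hits[key] = MotifHit(
                sequence_id=seq.id,
                motif_name=motif.name,
                start=start,
                end=start + len(text),
                strand="+",
                matched_text=text,
            )
        rc = compile_motif(
            MotifDefinition(name=motif.name, consensus=reverse_complement(motif.consensus))
        )
        for start, text in _scan_one_strand(s, rc):
            key = (start, start + len(text), motif.name)
            if key in hits:
                continue  # palindrome: already reported on +
            hits[key] = MotifHit(
                sequence_id=seq.id,
                motif_name=motif.name,
                start=start,
                end=start + len(text),
                strand="-",
                matched_text=text,
            )
    return sorted(hits.values(), key=lambda h: (h.start, h.motif_name, h.strand))


def compare_paralog_promoters(
    hits_a: Sequence[MotifHit], hits_b: Sequence[MotifHit]
) -> MotifComparison:
    """Shared vs exclusive motif names (with counts) between two promoters."""
    counts_a: dict[str, int] = {}
    counts_b: dict[str, int] = {}
    for h in hits_a:
        counts_a[h.motif_name] = counts_a.get(h.motif_name, 0) + 1
    for h in hits_b:
        counts_b[h.motif_name] = counts_b.get(h.motif_name, 0) + 1
    names_a, names_b = set(counts_a), set(counts_b)
    id_a = hits_a[0].sequence_id if hits_a else "a"
    id_b = hits_b[0].sequence_id if hits_b else "b"
    return MotifComparison(
        pair=(id_a, id_b),
        counts_a=counts_a,
        counts_b=counts_b,
        shared_motif_names=frozenset(names_a & names_b),
        exclusive_to_a=frozenset(names_a - names_b),
        exclusive_to_b=frozenset(names_b - names_a),
    )


def load_motifs(path: str | Path | None = None) -> list[MotifDefinition]:
    """Load motif definitions from a TSV (name, consensus[, source]).

    With no path, the packaged default set of plant light-signaling and
    ripening cis-elements is returned.
    """
    if path is None:
        source = resources.files("dupsel.data").joinpath("default_motifs.tsv")
        text = source.read_text()
    else:
        text = Path(path).read_text()
    motifs = []
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) < 2:
            raise ValueError(f"malformed motif line: {line!r}")
        motifs.append(
            MotifDefinition(
                name=fields[0],
                consensus=fields[1],
                source=fields[2] if len(fields) > 2 else "",
            )
        )
    return motifs


def default_motifs() -> list[MotifDefinition]:
    return load_motifs(None)


def hits_to_frame(hits: Sequence[MotifHit]) -> pd.DataFrame:
    """Hits as a BED6-compatible DataFrame (chrom, start, end, name, score,
    strand) plus the matched text."""
    return pd.DataFrame(
        {
            "chrom": [h.sequence_id for h in hits],
            "start": [h.start for h in hits],
            "end": [h.end for h in hits],
            "name": [h.motif_name for h in hits],
            "score": [0] * len(hits),
            "strand": [h.strand for h in hits],
            "matched_text": [h.matched_text for h in hits],
        }
    )
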