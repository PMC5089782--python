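"""Sequence containers, genetic code, and FASTA I/O.

Everything downstream (distances, site models, simulators) works on
:class:`CodonAlignment`, an in-frame alignment from which every codon column
containing a gap, an ambiguous base, or a stop codon has been removed whole —
the only reading-frame-safe way to strip alignment gaps before counting
synonymous and non-synonymous changes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Data import CodonTable
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

NUCLEOTIDES = "ACGT"
GAP = "-"


@dataclass(frozen=True, eq=False)
class GeneticCode:
    """A codon translation table plus the degeneracy bookkeeping Nc needs.

    Attributes
    ----------
    name:
        Human-readable table name.
    codon_to_aa:
        Map of all 64 codons to one-letter amino acids, with ``*`` for stops.
    sense_codons:
        The non-stop codons in lexicographic order (61 under the standard
        code).
    degeneracy_families:
        Map amino acid -> size of its synonymous codon family
        (1, 2, 3, 4 or 6 under the standard code).
    """

    name: str
    codon_to_aa: dict[str, str]
    sense_codons: tuple[str, ...] = field(init=False)
    degeneracy_families: dict[str, int] = field(init=False)

    def __post_init__(self) -> None:
        if len(self.codon_to_aa) != 64:
            raise ValueError(
                f"genetic code must map all 64 codons, got {len(self.codon_to_aa)}"
            )
        sense = tuple(c for c in sorted(self.codon_to_aa) if self.codon_to_aa[c] != "*")
        families: dict[str, int] = {}
        for codon in sense:
            aa = self.codon_to_aa[codon]
            families[aa] = families.get(aa, 0) + 1
        object.__setattr__(self, "sense_codons", sense)
        object.__setattr__(self, "degeneracy_families", families)

    @property
    def stop_codons(self) -> tuple[str, ...]:
        return tuple(c for c in sorted(self.codon_to_aa) if self.codon_to_aa[c] == "*")

    def is_stop(self, codon: str) -> bool:
        return self.codon_to_aa[codon] == "*"

    def translate(self, codon: str) -> str:
        return self.codon_to_aa[codon]


def _standard_code() -> GeneticCode:
    table = CodonTable.unambiguous_dna_by_id[1]
    mapping = dict(table.forward_table)
    for stop in table.stop_codons:
        mapping[stop] = "*"
    return GeneticCode(name="Standard", codon_to_aa=mapping)


#: The standard nuclear genetic code (61 sense codons, 3 stops).
STANDARD_CODE = _standard_code()


@dataclass(frozen=True)
class SequenceRecord:
    """A named sequence; residues are always stored uppercase."""

    id: str
    residues: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("sequence id must be non-empty")
        object.__setattr__(self, "residues", self.residues.upper())

    def __len__(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class CodonAlignment:
    """An in-frame alignment with gap/ambiguous/stop codon columns removed.

    Construct via :func:`build_codon_alignment`; direct construction assumes
    the invariants (equal lengths, length divisible by 3, no gaps, no N, no
    stop codons) already hold.
    """

    records: tuple[SequenceRecord, ...]
    n_codons: int
    source_gap_policy: str = "complete_deletion"

    @property
    def ids(self) -> tuple[str, ...]:
        return tuple(r.id for r in self.records)

    def record(self, seq_id: str) -> SequenceRecord:
        for r in self.records:
            if r.id == seq_id:
                return r
        raise KeyError(f"sequence id {seq_id!r} not in alignment")

    def codon(self, seq_index: int, codon_index: int) -> str:
        s = self.records[seq_index].residues
        return s[3 * codon_index : 3 * codon_index + 3]

    def codon_column(self, codon_index: int) -> tuple[str, ...]:
        return tuple(self.codon(i, codon_index) for i in range(len(self.records)))


def read_fasta(path: str | Path) -> list[SequenceRecord]:
    """Read a FASTA file into :class:`SequenceRecord` objects.

    The id is the header token up to the first whitespace; the remainder is
    kept as the description. Residues are uppercased. Raises on an empty file
    and on duplicate ids.
    """
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate sequence id {rec.id!r} in {path}")
        seen.add(rec.id)
        desc = rec.description
        if desc.startswith(rec.id):
            desc = desc[len(rec.id) :].strip()
        records.append(SequenceRecord(id=rec.id, residues=str(rec.seq), description=desc))
    if not records:
        raise ValueError(f"no sequences in {path}")
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path) -> None:
    """Write records as FASTA wrapped at 60 columns."""
    bio_records = [
        SeqRecord(Seq(r.residues), id=r.id, description=r.description) for r in records
    ]
    SeqIO.write(bio_records, str(path), "fasta")


def _is_clean_codon(codon: str) -> bool:
    return all(base in NUCLEOTIDES for base in codon)


def build_codon_alignment(
    records: Sequence[SequenceRecord], code: GeneticCode = STANDARD_CODE
) -> CodonAlignment:
    """Assemble an in-frame codon alignment by complete deletion.

    Any codon column in which any sequence carries a gap, an ambiguous base,
    or a stop codon is removed whole (all three sites together), which keeps
    the reading frame of every sequence intact.
    """
    if len(records) < 2:
        raise ValueError("codon alignment needs at least 2 sequences")
    length = len(records[0])
    for r in records:
        if len(r) != length:
            raise ValueError(
                f"aligned sequences must have equal length; {r.id!r} has "
                f"{len(r)}, expected {length}"
            )
    if length % 3 != 0:
        raise ValueError(f"alignment length {length} is not divisible by 3")

    kept: list[int] = []
    for col in range(length // 3):
        codons = [r.residues[3 * col : 3 * col + 3] for r in records]
        if all(_is_clean_codon(c) and not code.is_stop(c) for c in codons):
            kept.append(col)
    if not kept:
        raise ValueError("no codon columns retained after complete deletion")

    new_records = tuple(
        SequenceRecord(
            id=r.id,
            residues="".join(r.residues[3 * col : 3 * col + 3] for col in kept),
            description=r.description,
        )
        for r in records
    )
    return CodonAlignment(records=new_records, n_codons=len(kept))


def translate_alignment(
    aln: CodonAlignment, code: GeneticCode = STANDARD_CODE
) -> list[SequenceRecord]:
    """Translate each sequence of the alignment; output length = n_codons."""
    out = []
    for r in aln.records:
        aa = "".join(
            code.translate(r.residues[3 * i : 3 * i + 3]) for i in range(aln.n_codons)
        )
        out.append(SequenceRecord(id=r.id, residues=aa, description=r.description))
    return out
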