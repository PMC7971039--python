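"""Reading, writing and validation of sequences and interaction pair tables.

FASTA I/O is delegated to Biopython; this module adds alphabet validation,
explicit RNA->DNA conversion and the pair-table join that the rest of the
pipeline consumes.
"""

from __future__ import annotations

import csv
import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

DNA_ALPHABET = frozenset("ACGT")
RNA_ALPHABET = frozenset("ACGU")
PROTEIN_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWY")

_ALPHABETS = {
    "dna": DNA_ALPHABET,
    "rna": RNA_ALPHABET,
    "protein": PROTEIN_ALPHABET,
}


class SequenceValidationError(ValueError):
    """A residue outside the declared alphabet, or an empty sequence."""


class FastaParseError(ValueError):
    """Structurally malformed FASTA input."""


class PairTableError(ValueError):
    """Invalid pair table: unknown ids, bad labels or duplicate pairs."""


@dataclass(frozen=True)
class NucleotideSequence:
    """A validated DNA (or, pre-conversion, RNA) sequence."""

    id: str
    residues: str

    def __len__(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class ProteinSequence:
    """A validated protein sequence over the 20 standard one-letter codes."""

    id: str
    residues: str

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def L(self) -> int:
        return len(self.residues)


@dataclass
class InteractionDataset:
    """Labelled (aptamer, protein) pairs joined to their sequences."""

    pairs: list[tuple[str, str, int]]
    aptamers: dict[str, NucleotideSequence]
    proteins: dict[str, ProteinSequence]

    def __post_init__(self) -> None:
        seen: set[tuple[str, str]] = set()
        for apt_id, prot_id, label in self.pairs:
            if apt_id not in self.aptamers:
                raise PairTableError(f"unknown aptamer id {apt_id!r}")
            if prot_id not in self.proteins:
                raise PairTableError(f"unknown protein id {prot_id!r}")
            if label not in (0, 1):
                raise PairTableError(
                    f"label for pair ({apt_id!r}, {prot_id!r}) must be 0 or 1, got {label!r}"
                )
            key = (apt_id, prot_id)
            if key in seen:
                raise PairTableError(f"duplicate pair ({apt_id!r}, {prot_id!r})")
            seen.add(key)

    def __len__(self) -> int:
        return len(self.pairs)

    @property
    def labels(self) -> list[int]:
        return [label for _, _, label in self.pairs]


def _validate(seq_id: str, residues: str, alphabet: frozenset[str]) -> None:
    if not residues:
        raise SequenceValidationError(f"sequence {seq_id!r} is empty")
    for pos, ch in enumerate(residues):
        if ch not in alphabet:
            raise SequenceValidationError(
                f"sequence {seq_id!r}: invalid residue {ch!r} at position {pos}"
            )


def read_fasta(path: str | Path, alphabet: str) -> list[NucleotideSequence] | list[ProteinSequence]:
    """Read a FASTA file, validating every record against *alphabet*.

    Record ids are the header token up to the first whitespace. Lowercase
    residues are uppercased. Duplicate ids are rejected. RNA records keep
    their U residues; conversion to DNA is a separate, explicit step
    (:func:`rna_to_dna`).
    """
    if alphabet not in _ALPHABETS:
        raise ValueError(f"alphabet must be one of {sorted(_ALPHABETS)}, got {alphabet!r}")
    letters = _ALPHABETS[alphabet]
    cls = ProteinSequence if alphabet == "protein" else NucleotideSequence

    path = Path(path)
    text = path.read_text()
    stripped = text.lstrip()
    if stripped and not stripped.startswith(">"):
        first_bad = next(
            i + 1 for i, line in enumerate(text.splitlines()) if line.strip()
        )
        raise FastaParseError(f"{path}: line {first_bad}: expected '>' header before sequence data")

    records = []
    seen_ids: set[str] = set()
    with path.open() as handle:
        for rec in SeqIO.parse(handle, "fasta"):
            residues = str(rec.seq).upper()
            _validate(rec.id, residues, letters)
            if rec.id in seen_ids:
                raise FastaParseError(f"{path}: duplicate record id {rec.id!r}")
            seen_ids.add(rec.id)
            records.append(cls(id=rec.id, residues=residues))
    if not records and stripped:
        raise FastaParseError(f"{path}: no FASTA records parsed")
    return records


def write_fasta(path: str | Path, sequences: Iterable[NucleotideSequence | ProteinSequence]) -> None:
    """Write sequences as FASTA, wrapped at 60 columns."""
    records = [SeqRecord(Seq(s.residues), id=s.id, description="") for s in sequences]
    with Path(path).open("w") as handle:
        SeqIO.write(records, handle, "fasta")


def rna_to_dna(seq: NucleotideSequence) -> NucleotideSequence:
    """Replace every U with T. Idempotent; DNA input passes through."""
    residues = seq.residues
    if not set(residues) <= (RNA_ALPHABET | DNA_ALPHABET):
        bad = sorted(set(residues) - (RNA_ALPHABET | DNA_ALPHABET))
        raise SequenceValidationError(f"sequence {seq.id!r}: invalid residues {bad}")
    return NucleotideSequence(id=seq.id, residues=residues.replace("U", "T"))


def read_pair_table(
    path: str | Path,
    aptamers: Mapping[str, NucleotideSequence] | Sequence[NucleotideSequence],
    proteins: Mapping[str, ProteinSequence] | Sequence[ProteinSequence],
) -> InteractionDataset:
    """Read a delimited aptamer_id/protein_id/label table and join to sequences.

    The delimiter (tab or comma) is sniffed from the header line. Row order is
    preserved. Every referenced id must exist; labels must be 0 or 1; duplicate
    pairs are rejected.
    """
    apt_map = _as_map(aptamers)
    prot_map = _as_map(proteins)

    text = Path(path).read_text()
    header_line = text.splitlines()[0] if text.strip() else ""
    delimiter = "\t" if "\t" in header_line else ","
    reader = csv.DictReader(io.StringIO(text), delimiter=delimiter)
    required = {"aptamer_id", "protein_id", "label"}
    if reader.fieldnames is None or not required <= set(reader.fieldnames):
        raise PairTableError(
            f"{path}: header must contain columns {sorted(required)}, got {reader.fieldnames}"
        )

    pairs: list[tuple[str, str, int]] = []
    for lineno, row in enumerate(reader, start=2):
        raw_label = (row["label"] or "").strip()
        if raw_label not in ("0", "1"):
            raise PairTableError(f"{path}: line {lineno}: label must be 0 or 1, got {raw_label!r}")
        pairs.append((row["aptamer_id"].strip(), row["protein_id"].strip(), int(raw_label)))

    return InteractionDataset(pairs=pairs, aptamers=apt_map, proteins=prot_map)


def write_pair_table(path: str | Path, dataset: InteractionDataset) -> None:
    with Path(path).open("w", newline="") as handle:
        writer = csv.writer(handle)
        writer.writerow(["aptamer_id", "protein_id", "label"])
        writer.writerows(dataset.pairs)


def _as_map(seqs):
    if isinstance(seqs, Mapping):
        return dict(seqs)
    return {s.id: s for s in seqs}
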