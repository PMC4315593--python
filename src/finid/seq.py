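"""Nucleotide sequences, taxon labels and the COI-registered reference library.

Sequences are stored uppercase over the IUPAC alphabet (plus the gap
``-``); ``U`` is mapped to ``T`` on ingest and any other character is
rejected rather than silently converted. The reference library holds
equal-length alignment rows together with a single ``coordinate_offset``:
the 1-based COI position of the first alignment column. All public
interfaces speak COI coordinates (1-based, inclusive), never raw column
indices.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO

from .errors import AlphabetError, CoordinateError, FastaParseError, InputError
from .iupac import ALPHABET

#: The eight shark species listed on CITES Appendix II.
CITES_SPECIES: frozenset[str] = frozenset({
    "Rhincodon typus",
    "Cetorhinus maximus",
    "Carcharodon carcharias",
    "Carcharhinus longimanus",
    "Sphyrna lewini",
    "Sphyrna zygaena",
    "Sphyrna mokarran",
    "Lamna nasus",
})


@dataclass(frozen=True)
class TaxonLabel:
    """A genus/species annotation; the CITES flag is derived, never asserted.

    ``cites_listed`` is true exactly for the eight Appendix-II shark
    species; a constructor argument contradicting that is an error.
    """

    genus: str
    species: str = ""
    cites_listed: bool | None = None

    def __post_init__(self):
        if self.species and not self.genus:
            raise InputError(f"species {self.species!r} set without a genus")
        derived = self.binomial in CITES_SPECIES
        if self.cites_listed is None:
            object.__setattr__(self, "cites_listed", derived)
        elif self.cites_listed != derived:
            raise InputError(
                f"cites_listed={self.cites_listed} contradicts the Appendix-II "
                f"list for {self.binomial!r}"
            )

    @property
    def binomial(self) -> str:
        return f"{self.genus} {self.species}".strip()


@dataclass(frozen=True)
class NucSequence:
    """An IUPAC nucleotide string with an id and optional taxon label."""

    id: str
    bases: str
    label: TaxonLabel | None = None

    def __post_init__(self):
        if not self.id:
            raise InputError("sequence id must be non-empty")
        norm = self.bases.upper().replace("U", "T")
        bad = set(norm) - ALPHABET
        if bad:
            raise AlphabetError(
                f"record {self.id!r} contains non-IUPAC characters {sorted(bad)}"
            )
        object.__setattr__(self, "bases", norm)

    def __len__(self) -> int:
        return len(self.bases)

    def with_label(self, label: TaxonLabel | None) -> "NucSequence":
        return NucSequence(self.id, self.bases, label)


@dataclass
class ReferenceLibrary:
    """Equal-length, taxon-labelled alignment rows registered to COI coordinates.

    ``coordinate_offset`` is the 1-based COI position of alignment column 0.
    """

    records: list[NucSequence]
    coordinate_offset: int = 1

    def __post_init__(self):
        if self.coordinate_offset < 1:
            raise InputError("coordinate_offset must be >= 1")
        if not self.records:
            raise InputError("reference library must contain at least one record")
        lengths = {len(r) for r in self.records}
        if len(lengths) > 1:
            raise InputError(f"records have unequal lengths {sorted(lengths)}")
        ids = [r.id for r in self.records]
        if len(set(ids)) != len(ids):
            dup = next(i for i in ids if ids.count(i) > 1)
            raise InputError(f"duplicate record id {dup!r} in library")
        for r in self.records:
            if r.label is None:
                raise InputError(f"record {r.id!r} has no taxon label")

    def __len__(self) -> int:
        return len(self.records)

    @property
    def alignment_length(self) -> int:
        return len(self.records[0])

    @property
    def coi_range(self) -> tuple[int, int]:
        """Inclusive COI positions covered by the alignment columns."""
        return (self.coordinate_offset,
                self.coordinate_offset + self.alignment_length - 1)

    def species(self) -> list[str]:
        """Distinct binomials, in first-appearance order."""
        seen: dict[str, None] = {}
        for r in self.records:
            seen.setdefault(r.label.binomial, None)
        return list(seen)

    def records_for(self, binomial: str) -> list[NucSequence]:
        return [r for r in self.records if r.label.binomial == binomial]

    def column(self, coi_position: int) -> int:
        """Alignment column index of a 1-based COI position."""
        lo, hi = self.coi_range
        if not lo <= coi_position <= hi:
            raise CoordinateError(
                f"COI position {coi_position} outside registered range [{lo},{hi}]"
            )
        return coi_position - self.coordinate_offset


def read_fasta(path: str | Path) -> list[NucSequence]:
    """Read a FASTA file into NucSequences.

    The first whitespace-delimited token of the description is the id; if
    the remainder looks like ``Genus species`` it becomes the taxon label.
    Empty records and duplicate ids are parse errors naming the record.
    """
    path = Path(path)
    if not path.exists():
        raise FastaParseError(f"no such FASTA file: {path}")
    out: list[NucSequence] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if not rec.id:
            raise FastaParseError(f"record without an id in {path}")
        if rec.id in seen:
            raise FastaParseError(f"duplicate record id {rec.id!r} in {path}")
        seen.add(rec.id)
        bases = str(rec.seq)
        if not bases:
            raise FastaParseError(f"record {rec.id!r} in {path} has an empty sequence")
        label = _parse_description_label(rec.description, rec.id)
        try:
            out.append(NucSequence(rec.id, bases, label))
        except AlphabetError as exc:
            raise FastaParseError(str(exc)) from exc
    if not out:
        raise FastaParseError(f"no FASTA records in {path}")
    return out


def _parse_description_label(description: str, rec_id: str) -> TaxonLabel | None:
    rest = description[len(rec_id):].strip() if description.startswith(rec_id) else ""
    tokens = rest.split()
    if len(tokens) >= 2 and tokens[0][:1].isupper() and tokens[1][:1].islower():
        return TaxonLabel(genus=tokens[0], species=tokens[1])
    return None


def write_fasta(path: str | Path, records: Iterable[NucSequence]) -> None:
    """Write records one-per-line (no wrapping), preserving order and labels."""
    with open(path, "w") as fh:
        for rec in records:
            desc = f" {rec.label.binomial}" if rec.label else ""
            fh.write(f">{rec.id}{desc}\n{rec.bases}\n")


def read_taxon_table(path: str | Path) -> dict[str, TaxonLabel]:
    """Read the sidecar taxon TSV: ``id<TAB>genus<TAB>species<TAB>cites_listed``."""
    labels: dict[str, TaxonLabel] = {}
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        required = {"id", "genus", "species"}
        if reader.fieldnames is None or not required <= set(reader.fieldnames):
            raise InputError(f"taxon table {path} must have columns id, genus, species")
        for row in reader:
            flag = row.get("cites_listed")
            cites = None if flag in (None, "") else flag.strip().lower() in ("1", "true", "yes")
            labels[row["id"]] = TaxonLabel(row["genus"], row["species"], cites)
    return labels


def write_taxon_table(path: str | Path, records: Sequence[NucSequence]) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["id", "genus", "species", "cites_listed"])
        for rec in records:
            lab = rec.label
            w.writerow([rec.id, lab.genus if lab else "", lab.species if lab else "",
                        str(bool(lab and lab.cites_listed)).lower()])


def load_library(fasta_path: str | Path, taxa_path: str | Path | None = None,
                 coordinate_offset: int = 1) -> ReferenceLibrary:
    """Assemble a ReferenceLibrary from FASTA (+ optional taxon TSV override)."""
    records = read_fasta(fasta_path)
    if taxa_path is not None:
        overrides = read_taxon_table(taxa_path)
        records = [r.with_label(overrides.get(r.id, r.label)) for r in records]
    return ReferenceLibrary(records, coordinate_offset)


def slice_by_coi_positions(seq: NucSequence, library: ReferenceLibrary,
                           start: int, end: int) -> NucSequence:
    """Subsequence whose first base sits at COI ``start`` and last at ``end``.

    ``seq`` must be a full-length alignment row of ``library``; positions
    are 1-based and inclusive.
    """
    if start > end:
        raise CoordinateError(f"start {start} > end {end}")
    if len(seq) != library.alignment_length:
        raise InputError(
            f"sequence {seq.id!r} length {len(seq)} does not match the "
            f"alignment length {library.alignment_length}"
        )
    i, j = library.column(start), library.column(end)
    return NucSequence(seq.id, seq.bases[i:j + 1], seq.label)
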