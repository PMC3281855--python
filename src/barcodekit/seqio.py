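"""Sequence and taxonomy I/O.

Reads aligned FASTA and a five-rank taxonomy table (TSV) and joins them into
a validated :class:`Dataset`. Sequences are stored uppercase over the DNA
alphabet ('U' is mapped to 'T' on read); IUPAC ambiguity codes and gap
characters are retained and handled downstream by pairwise deletion.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import ParseError, ValidationError

__all__ = [
    "Marker",
    "SpecimenRecord",
    "Dataset",
    "read_fasta",
    "write_fasta",
    "read_taxonomy",
    "write_taxonomy",
    "build_dataset",
    "TAXONOMY_COLUMNS",
]

#: Exact header expected in the taxonomy TSV, in order.
TAXONOMY_COLUMNS = ["specimen_id", "species", "genus", "family", "order", "class"]

#: Rank columns (most to least specific), with "class" stored as "class_".
RANKS = ["species", "genus", "family", "order", "class_"]

IUPAC_CHARS = frozenset("ACGTNRYSWKMBDHV-")


class Marker(str, enum.Enum):
    """Supported marker loci. COI and cytb are protein-coding."""

    COI = "COI"
    CYTB = "cytb"
    RRNA_16S = "16S"
    RRNA_18S = "18S"

    @property
    def is_coding(self) -> bool:
        return self in (Marker.COI, Marker.CYTB)

    @classmethod
    def parse(cls, value: "Marker | str") -> "Marker":
        if isinstance(value, Marker):
            return value
        for m in cls:
            if m.value.lower() == str(value).lower():
                return m
        raise ValidationError(
            f"unknown marker {value!r}; expected one of "
            + ", ".join(m.value for m in cls)
        )


@dataclass(frozen=True)
class SpecimenRecord:
    """One sequenced specimen with its five-rank taxonomy."""

    specimen_id: str
    sequence: str
    marker: Marker
    species: str
    genus: str
    family: str
    order: str
    class_: str

    def __post_init__(self) -> None:
        if not self.specimen_id:
            raise ValidationError("specimen_id must be non-empty")
        if not self.sequence:
            raise ValidationError(f"{self.specimen_id}: sequence must be non-empty")
        bad = set(self.sequence) - IUPAC_CHARS
        if bad:
            raise ValidationError(
                f"{self.specimen_id}: invalid sequence characters {sorted(bad)}"
            )
        for rank in RANKS:
            if not getattr(self, rank):
                raise ValidationError(f"{self.specimen_id}: empty {rank} rank")


@dataclass
class Dataset:
    """An ordered collection of specimens, optionally aligned.

    ``alignment_length`` is set iff all sequences have equal length; the
    rRNA markers may legitimately carry it unset when lengths vary.
    """

    records: list[SpecimenRecord]
    alignment_length: int | None = field(default=None)

    def __post_init__(self) -> None:
        if len(self.records) < 2:
            raise ValidationError("a dataset requires at least 2 records")
        ids = [r.specimen_id for r in self.records]
        dupes = {i for i in ids if ids.count(i) > 1}
        if dupes:
            raise ValidationError(f"duplicate specimen ids: {sorted(dupes)}")
        lengths = {len(r.sequence) for r in self.records}
        if self.alignment_length is None and len(lengths) == 1:
            self.alignment_length = lengths.pop()
        elif self.alignment_length is not None and lengths != {self.alignment_length}:
            raise ValidationError(
                f"alignment_length={self.alignment_length} but sequence "
                f"lengths are {sorted(lengths)}"
            )
        _check_rank_nesting(self.taxonomy)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    @property
    def ids(self) -> list[str]:
        return [r.specimen_id for r in self.records]

    @property
    def sequences(self) -> dict[str, str]:
        return {r.specimen_id: r.sequence for r in self.records}

    @property
    def taxonomy(self) -> pd.DataFrame:
        """Per-specimen rank table indexed by specimen_id."""
        return pd.DataFrame(
            {rank: [getattr(r, rank) for r in self.records] for rank in RANKS},
            index=pd.Index(self.ids, name="specimen_id"),
        )

    @property
    def marker(self) -> Marker:
        markers = {r.marker for r in self.records}
        if len(markers) != 1:
            raise ValidationError(f"mixed markers in dataset: {sorted(m.value for m in markers)}")
        return markers.pop()

    def subset(self, keep_ids: Iterable[str]) -> "Dataset":
        keep = set(keep_ids)
        return Dataset([r for r in self.records if r.specimen_id in keep])


def _check_rank_nesting(tax: pd.DataFrame) -> None:
    """Each taxon must map to exactly one parent taxon (species→genus, …)."""
    for child, parent in zip(RANKS[:-1], RANKS[1:]):
        parents = tax.groupby(child)[parent].nunique()
        offenders = parents[parents > 1].index.tolist()
        if offenders:
            raise ValidationError(
                f"inconsistent taxonomy: {child} {offenders} mapped to "
                f"multiple {parent} values"
            )


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    """Read a FASTA file into an ordered list of (id, sequence) pairs.

    Sequences are uppercased, 'U' becomes 'T', and wrapped lines are joined.
    Duplicate ids, an empty file, or a file not starting with a header are
    parse errors naming the offending line.
    """
    path = Path(path)
    with open(path) as fh:
        lines = fh.read().splitlines()
    first_content = next(
        ((i + 1, ln) for i, ln in enumerate(lines) if ln.strip()), None
    )
    if first_content is None:
        raise ParseError(f"{path}: empty FASTA file")
    lineno, line = first_content
    if not line.lstrip().startswith(">"):
        raise ParseError(f"{path}, line {lineno}: expected FASTA header, got {line!r}")

    out: list[tuple[str, str]] = []
    seen: set[str] = set()
    with open(path) as fh:
        for rec in SeqIO.parse(fh, "fasta"):
            if not rec.id:
                raise ParseError(f"{path}: FASTA header with empty id")
            if rec.id in seen:
                raise ParseError(f"{path}: duplicate FASTA id {rec.id!r}")
            seen.add(rec.id)
            out.append((rec.id, str(rec.seq).upper().replace("U", "T")))
    return out


def write_fasta(path: str | Path, records: Sequence[tuple[str, str]] | Dataset,
                width: int = 70) -> None:
    """Write (id, sequence) pairs (or a Dataset) as wrapped FASTA."""
    if isinstance(records, Dataset):
        records = [(r.specimen_id, r.sequence) for r in records]
    seq_records = [SeqRecord(Seq(s), id=i, description="") for i, s in records]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(seq_records)


def read_taxonomy(path: str | Path) -> pd.DataFrame:
    """Read the taxonomy TSV into a rank table indexed by specimen_id.

    Schema is fixed: ``specimen_id  species  genus  family  order  class``
    (tab-separated, exactly this header). Rank nesting is verified: a species
    under two genera, a genus under two families, etc. is an error.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if list(df.columns) != TAXONOMY_COLUMNS:
        raise ParseError(
            f"{path}: taxonomy header must be exactly {TAXONOMY_COLUMNS}, "
            f"got {list(df.columns)}"
        )
    if df.empty:
        raise ParseError(f"{path}: taxonomy table has no rows")
    empties = df[(df == "").any(axis=1)]
    if not empties.empty:
        rows = (empties.index + 2).tolist()  # +2: header line + 1-based
        raise ValidationError(f"{path}: empty taxonomy fields on lines {rows}")
    if df["specimen_id"].duplicated().any():
        dupes = df.loc[df["specimen_id"].duplicated(), "specimen_id"].tolist()
        raise ValidationError(f"{path}: duplicate specimen ids {dupes}")
    tax = df.rename(columns={"class": "class_"}).set_index("specimen_id")
    _check_rank_nesting(tax)
    return tax


def write_taxonomy(path: str | Path, taxonomy: pd.DataFrame | Dataset) -> None:
    if isinstance(taxonomy, Dataset):
        taxonomy = taxonomy.taxonomy
    out = taxonomy.rename(columns={"class_": "class"}).reset_index()
    out.to_csv(path, sep="\t", index=False)


def build_dataset(
    fasta: Sequence[tuple[str, str]],
    taxonomy: pd.DataFrame,
    marker: Marker | str,
) -> Dataset:
    """Join FASTA records with the taxonomy table into a Dataset.

    Every FASTA id must be present in the taxonomy; unmatched ids are an
    error naming them. ``alignment_length`` is set iff all sequences are
    equal length.
    """
    marker = Marker.parse(marker)
    missing = [sid for sid, _ in fasta if sid not in taxonomy.index]
    if missing:
        raise ValidationError(
            f"FASTA ids absent from taxonomy: {sorted(missing)}"
        )
    records = [
        SpecimenRecord(
            specimen_id=sid,
            sequence=seq,
            marker=marker,
            **{rank: taxonomy.at[sid, rank] for rank in RANKS},
        )
        for sid, seq in fasta
    ]
    return Dataset(records)


def load_dataset(fasta_path: str | Path, taxonomy_path: str | Path,
                 marker: Marker | str) -> Dataset:
    """Convenience wrapper: read both files and join."""
    return build_dataset(read_fasta(fasta_path), read_taxonomy(taxonomy_path), marker)
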