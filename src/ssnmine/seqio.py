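"""Sequence records, FASTA I/O and metadata tables.

Defines the record model every other module consumes.  Residues are
uppercase amino acids over the 20 canonical letters plus ``X``
(unknown); the ambiguity codes B/Z/U/O that appear in translated
transcriptome assemblies are mapped to ``X`` with a warning rather than
silently dropped, because dropped residues would bias downstream length
filters.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Optional, Sequence

import pandas as pd
from Bio import SeqIO as _BioSeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioSeqRecord

#: the 20 canonical amino acids, in lexicographic order.
AMINO20 = "ACDEFGHIKLMNPQRSTVWY"

#: 20 canonical amino acids + X (unknown residue).
ALPHABET = AMINO20 + "X"
_ALPHABET_SET = frozenset(ALPHABET)

#: Ambiguity / rare codes folded into X on input.
_AMBIGUOUS = {"B": "X", "Z": "X", "U": "X", "O": "X", "J": "X"}


@dataclass(frozen=True)
class SeqRecord:
    """One protein sequence with identifier and optional metadata.

    Attributes
    ----------
    id : str
        Unique identifier (first whitespace-delimited header token).
    residues : str
        Uppercase amino-acid string over :data:`ALPHABET`.
    description : str
        Full FASTA header (minus ``>``), retained for reports.
    species, clade : str, optional
        Taxonomic annotations.
    label : str, optional
        Product-category label; only characterised reference sequences
        carry one.
    """

    id: str
    residues: str
    description: str = ""
    species: Optional[str] = None
    clade: Optional[str] = None
    label: Optional[str] = None

    def __post_init__(self) -> None:
        bad = next((i for i, c in enumerate(self.residues) if c not in _ALPHABET_SET), None)
        if bad is not None:
            raise ValueError(
                f"record {self.id!r}: non-alphabet residue {self.residues[bad]!r} at position {bad + 1}"
            )

    @property
    def length(self) -> int:
        """Number of residues."""
        return len(self.residues)

    @property
    def is_reference(self) -> bool:
        """True iff the record carries a product-category label."""
        return self.label is not None


def _clean_residues(raw: str, rec_id: str) -> str:
    seq = str(raw).upper()
    # stop characters stripped from the end only; internal '*' is an error
    seq = seq.rstrip("*")
    if any(c in _AMBIGUOUS for c in seq):
        folded = sorted({c for c in seq if c in _AMBIGUOUS})
        warnings.warn(
            f"record {rec_id!r}: ambiguity code(s) {','.join(folded)} mapped to X",
            stacklevel=3,
        )
        seq = "".join(_AMBIGUOUS.get(c, c) for c in seq)
    return seq


def read_fasta(path: str | Path) -> list[SeqRecord]:
    """Read a protein FASTA file into a list of :class:`SeqRecord`.

    Ids are the first whitespace-delimited token of each header; the
    full header is kept as ``description``.  Residues are uppercased and
    trailing ``*`` stop characters stripped.  Duplicate ids and
    non-alphabet residues are hard errors; an empty file yields an
    empty list.
    """
    records: list[SeqRecord] = []
    seen: set[str] = set()
    for bio in _BioSeqIO.parse(str(path), "fasta"):
        if bio.id in seen:
            raise ValueError(f"duplicate sequence id {bio.id!r} in {path}")
        seen.add(bio.id)
        residues = _clean_residues(str(bio.seq), bio.id)
        records.append(SeqRecord(id=bio.id, residues=residues, description=bio.description))
    return records


def write_fasta(records: Iterable[SeqRecord], path: str | Path, width: int = 60) -> None:
    """Write records to FASTA, preserving id, description and order."""
    bio_records = [
        _BioSeqRecord(Seq(r.residues), id=r.id, description=r.description.partition(" ")[2] if r.description.startswith(r.id) else r.description)
        for r in records
    ]
    with open(path, "w") as fh:
        writer = _BioSeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(bio_records)


@dataclass
class MetadataTable:
    """Per-sequence metadata keyed by id.

    Wraps a :class:`pandas.DataFrame` with mandatory column ``id`` and
    optional ``species``, ``clade``, ``label``.  Unknown columns are
    preserved but ignored.
    """

    frame: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(columns=["id"]))

    def __post_init__(self) -> None:
        if "id" not in self.frame.columns:
            raise ValueError("metadata table requires an 'id' column")
        ids = self.frame["id"]
        if ids.duplicated().any():
            dup = ids[ids.duplicated()].iloc[0]
            raise ValueError(f"duplicate id {dup!r} in metadata table")
        self.frame = self.frame.set_index("id", drop=False)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "MetadataTable":
        """Load a tab-separated table with a header row; columns matched by name."""
        return cls(pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False).replace({"": None}))

    def to_tsv(self, path: str | Path) -> None:
        self.frame.to_csv(path, sep="\t", index=False)

    def get(self, rec_id: str) -> Optional[dict]:
        if rec_id not in self.frame.index:
            return None
        row = self.frame.loc[rec_id]
        out = {}
        for col in ("species", "clade", "label"):
            if col in self.frame.columns:
                val = row[col]
                out[col] = None if val is None or (isinstance(val, float) and pd.isna(val)) else str(val)
            else:
                out[col] = None
        return out

    @property
    def ids(self) -> list[str]:
        return list(self.frame["id"])

    def __len__(self) -> int:
        return len(self.frame)


def attach_metadata(records: Sequence[SeqRecord], table: MetadataTable) -> list[SeqRecord]:
    """Return records enriched with species/clade/label from *table*.

    Records absent from the table pass through unchanged.  Table rows
    with no matching record are reported as warnings, never errors.
    The operation is idempotent.
    """
    record_ids = {r.id for r in records}
    orphans = [i for i in table.ids if i not in record_ids]
    if orphans:
        warnings.warn(
            f"{len(orphans)} metadata row(s) match no record (e.g. {orphans[0]!r})",
            stacklevel=2,
        )
    out = []
    for rec in records:
        meta = table.get(rec.id)
        if meta is None:
            out.append(rec)
        else:
            out.append(
                replace(
                    rec,
                    species=meta["species"] if meta["species"] is not None else rec.species,
                    clade=meta["clade"] if meta["clade"] is not None else rec.clade,
                    label=meta["label"] if meta["label"] is not None else rec.label,
                )
            )
    return out
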