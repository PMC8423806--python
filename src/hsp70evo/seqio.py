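"""Sequence, alignment and metadata IO.

The pipeline works on three plain-text inputs: protein FASTA, CDS FASTA and a
multiple protein alignment (aligned FASTA or Clustal), plus a TSV metadata
table carrying the annotations (species, localization, inducibility, clade,
accession) that in a real study come from the literature.  This module reads
and writes those formats and implements reference-anchored alignment trimming,
the step used to discard misannotated terminal extensions before substitution-
rate analysis.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import AlignIO, SeqIO

AMINO_ACIDS = set("ACDEFGHIKLMNPQRSTVWY")
PROTEIN_ALPHABET = AMINO_ACIDS | {"X"}
NUCLEOTIDE_ALPHABET = set("ACGTN")
GAP = "-"


class Localization(str, enum.Enum):
    CYTOSOL = "cytosol"
    ER = "ER"
    MITOCHONDRIA = "mitochondria"
    UNKNOWN = "unknown"


class Inducibility(str, enum.Enum):
    INDUCIBLE = "inducible"
    CONSTITUTIVE = "constitutive"
    UNKNOWN = "unknown"


_LOCALIZATION_ALIASES = {
    "cytosol": Localization.CYTOSOL,
    "cytosolic": Localization.CYTOSOL,
    "er": Localization.ER,
    "endoplasmic reticulum": Localization.ER,
    "mitochondria": Localization.MITOCHONDRIA,
    "mitochondrial": Localization.MITOCHONDRIA,
    "unknown": Localization.UNKNOWN,
    "": Localization.UNKNOWN,
}

_INDUCIBILITY_ALIASES = {
    "inducible": Inducibility.INDUCIBLE,
    "constitutive": Inducibility.CONSTITUTIVE,
    "unknown": Inducibility.UNKNOWN,
    "": Inducibility.UNKNOWN,
}


@dataclass
class ProteinRecord:
    """One amino-acid sequence with its annotations.

    The sequence is gap-free, non-empty and restricted to the 20 standard
    residues plus ``X``.  Inducibility defaults to unknown: many family
    members have never been assayed for stress induction.
    """

    id: str
    sequence: str
    species: str = ""
    localization: Localization = Localization.UNKNOWN
    inducibility: Inducibility = Inducibility.UNKNOWN
    clade: str | None = None
    accession: str | None = None

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("protein record requires a non-empty id")
        if not self.sequence:
            raise ValueError(f"protein record {self.id!r} has an empty sequence")
        for pos, ch in enumerate(self.sequence, start=1):
            if ch not in PROTEIN_ALPHABET:
                raise ValueError(
                    f"illegal character {ch!r} at position {pos} in protein "
                    f"record {self.id!r}"
                )


@dataclass
class CodingRecord:
    """A coding sequence (CDS) matched by id to a :class:`ProteinRecord`.

    Length/frame consistency with the protein is *not* enforced here; it is
    checked by ``kaks.validate_cds`` so that frame-shifted database records
    (a real failure mode of automated annotations) can be carried through the
    pipeline, flagged, and excluded only from the substitution-rate stage.
    """

    id: str
    cds: str
    frame_shifted: bool = False

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("coding record requires a non-empty id")
        if not self.cds:
            raise ValueError(f"coding record {self.id!r} has an empty CDS")
        for pos, ch in enumerate(self.cds, start=1):
            if ch not in NUCLEOTIDE_ALPHABET:
                raise ValueError(
                    f"illegal character {ch!r} at position {pos} in coding "
                    f"record {self.id!r}"
                )


@dataclass
class MultipleAlignment:
    """A rectangular protein alignment: ordered ids and gapped rows."""

    ids: list[str]
    rows: list[str]

    def __post_init__(self) -> None:
        if len(self.ids) != len(self.rows):
            raise ValueError("ids and rows differ in length")
        if len(set(self.ids)) != len(self.ids):
            raise ValueError("duplicate row ids in alignment")
        if self.rows:
            ncol = len(self.rows[0])
            for rid, row in zip(self.ids, self.rows):
                if len(row) != ncol:
                    raise ValueError(
                        f"ragged alignment: row {rid!r} has length {len(row)}, "
                        f"expected {ncol}"
                    )

    @property
    def ncol(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    def row(self, rid: str) -> str:
        try:
            return self.rows[self.ids.index(rid)]
        except ValueError:
            raise KeyError(f"row id {rid!r} not in alignment") from None

    def ungapped(self, rid: str) -> str:
        return self.row(rid).replace(GAP, "")

    def slice_columns(self, start: int, stop: int) -> "MultipleAlignment":
        """Column slice with python half-open 0-based semantics."""
        return MultipleAlignment(list(self.ids), [r[start:stop] for r in self.rows])


@dataclass
class MetadataTable:
    """Per-id annotations, one row per sequence."""

    table: pd.DataFrame

    COLUMNS = ("id", "species", "phylum", "localization", "inducibility", "clade", "accession")

    def annotations(self, rid: str) -> dict:
        hit = self.table[self.table["id"] == rid]
        if hit.empty:
            raise KeyError(f"id {rid!r} not in metadata table")
        return hit.iloc[0].to_dict()

    def annotate(self, records: Iterable[ProteinRecord]) -> list[ProteinRecord]:
        """Return copies of *records* with metadata columns filled in."""
        out = []
        for rec in records:
            try:
                row = self.annotations(rec.id)
            except KeyError:
                out.append(rec)
                continue
            out.append(
                replace(
                    rec,
                    species=row["species"] or rec.species,
                    localization=Localization(row["localization"]),
                    inducibility=Inducibility(row["inducibility"]),
                    clade=row["clade"] if row["clade"] else rec.clade,
                    accession=row["accession"] if row["accession"] else rec.accession,
                )
            )
        return out

    def clade_map(self) -> dict[str, str]:
        return {
            r["id"]: r["clade"]
            for _, r in self.table.iterrows()
            if r["clade"]
        }


def _check_unique_ids(ids: Sequence[str], what: str) -> None:
    seen: set[str] = set()
    for rid in ids:
        if rid in seen:
            raise ValueError(f"duplicate id {rid!r} in {what}")
        seen.add(rid)


def read_fasta(path: str | Path, kind: str = "protein") -> list[ProteinRecord] | list[CodingRecord]:
    """Read a FASTA file into protein or coding records.

    The id is the header token up to the first whitespace (GenBank-style);
    the remainder of the header is a free-text description and is ignored.
    """
    if kind not in ("protein", "nucleotide"):
        raise ValueError(f"kind must be 'protein' or 'nucleotide', got {kind!r}")
    path = Path(path)
    records: list = []
    ids: list[str] = []
    for entry in SeqIO.parse(str(path), "fasta"):
        seq = str(entry.seq).upper()
        if kind == "protein":
            records.append(ProteinRecord(id=entry.id, sequence=seq))
        else:
            records.append(CodingRecord(id=entry.id, cds=seq))
        ids.append(entry.id)
    _check_unique_ids(ids, str(path))
    return records


def write_fasta(records: Iterable[ProteinRecord | CodingRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for rec in records:
            seq = rec.sequence if isinstance(rec, ProteinRecord) else rec.cds
            fh.write(f">{rec.id}\n{seq}\n")


def read_metadata_table(path: str | Path) -> MetadataTable:
    """Read the TSV metadata table, normalizing enums case-insensitively.

    Missing localization/inducibility cells default to ``unknown``; an
    unrecognized enum token is an error naming the row and the value.
    """
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    missing = [c for c in MetadataTable.COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"metadata table {path} lacks columns: {missing}")
    _check_unique_ids(list(df["id"]), f"metadata table {path}")
    locs, inds = [], []
    for i, row in df.iterrows():
        loc_token = row["localization"].strip().lower()
        if loc_token not in _LOCALIZATION_ALIASES:
            raise ValueError(
                f"row {i + 1} (id {row['id']!r}): unknown localization "
                f"{row['localization']!r}"
            )
        ind_token = row["inducibility"].strip().lower()
        if ind_token not in _INDUCIBILITY_ALIASES:
            raise ValueError(
                f"row {i + 1} (id {row['id']!r}): unknown inducibility "
                f"{row['inducibility']!r}"
            )
        locs.append(_LOCALIZATION_ALIASES[loc_token].value)
        inds.append(_INDUCIBILITY_ALIASES[ind_token].value)
    df["localization"] = locs
    df["inducibility"] = inds
    return MetadataTable(df)


def write_metadata_table(meta: MetadataTable, path: str | Path) -> None:
    meta.table.to_csv(path, sep="\t", index=False)


def read_alignment(path: str | Path) -> MultipleAlignment:
    """Read an aligned FASTA or Clustal file.

    The format is sniffed from the first non-blank line.  Ragged rows are an
    error naming the offending row.
    """
    path = Path(path)
    with open(path) as fh:
        first = ""
        for line in fh:
            if line.strip():
                first = line
                break
    if first.startswith(">"):
        entries = list(SeqIO.parse(str(path), "fasta"))
        ids = [e.id for e in entries]
        rows = [str(e.seq).upper() for e in entries]
        _check_unique_ids(ids, str(path))
        if rows:
            ncol = len(rows[0])
            for rid, row in zip(ids, rows):
                if len(row) != ncol:
                    raise ValueError(
                        f"ragged alignment in {path}: row {rid!r} has length "
                        f"{len(row)}, expected {ncol}"
                    )
        return MultipleAlignment(ids, rows)
    aln = AlignIO.read(str(path), "clustal")
    return MultipleAlignment([r.id for r in aln], [str(r.seq).upper() for r in aln])


def write_alignment(aln: MultipleAlignment, path: str | Path) -> None:
    with open(path, "w") as fh:
        for rid, row in zip(aln.ids, aln.rows):
            fh.write(f">{rid}\n{row}\n")


def reference_window_columns(
    aln: MultipleAlignment, reference_id: str, start: int, end: int
) -> tuple[int, int]:
    """Half-open column range spanned by reference residues start..end.

    Positions are 1-based residue indices in the *ungapped* reference row and
    the window is inclusive at both ends; columns where the reference carries
    a gap between the two endpoint residues fall inside the range.
    """
    ref = aln.row(reference_id)
    residue_cols = [i for i, ch in enumerate(ref) if ch != GAP]
    nres = len(residue_cols)
    if not 1 <= start <= end:
        raise ValueError(f"invalid window {start}..{end}")
    if end > nres:
        raise ValueError(
            f"window end {end} beyond ungapped length {nres} of reference "
            f"{reference_id!r}"
        )
    return residue_cols[start - 1], residue_cols[end - 1] + 1


def trim_to_reference_window(
    aln: MultipleAlignment, reference_id: str, start: int, end: int
) -> MultipleAlignment:
    """Trim all rows to the columns spanned by reference residues start..end.

    This mirrors the practice of restricting analysis to the well-annotated
    core of the family (for real data, human HSPA1A/HSPA1B residues 6-616);
    see :func:`reference_window_columns` for the coordinate conventions.
    """
    lo, hi = reference_window_columns(aln, reference_id, start, end)
    return aln.slice_columns(lo, hi)
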