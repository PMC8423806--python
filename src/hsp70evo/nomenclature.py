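"""Phylogeny-aware HSP70 family nomenclature.

Historic names ("HSP70" vs "HSC70") encode presumed inducibility, which does
not track the gene phylogeny.  The scheme implemented here names members by
what is actually stable: HSP70 + subcellular localization (c / m / er) +
lineage letter (A, B, ... from the phylogeny) + copy number within the
organism + inducibility suffix (i / c) only when it is experimentally known.
HSP70cA1i is the first cytosolic Lineage-A copy of a species, inducible;
HSP70mA1 a mitochondrial member of unknown inducibility.  Gene symbols are
the lowercased protein names (hsp70cb2i, hsp70era1).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping

from .seqio import Inducibility, Localization

logger = logging.getLogger(__name__)

LOCALIZATION_CODES = {"c": Localization.CYTOSOL, "m": Localization.MITOCHONDRIA,
                      "er": Localization.ER}
CODE_OF_LOCALIZATION = {v: k for k, v in LOCALIZATION_CODES.items()}
SUFFIX_OF_INDUCIBILITY = {Inducibility.INDUCIBLE: "i", Inducibility.CONSTITUTIVE: "c",
                          Inducibility.UNKNOWN: ""}


@dataclass(frozen=True)
class NomenclatureName:
    """Structured HSP70 name: localization code, lineage, copy, suffix."""

    code: str  # c | m | er
    lineage: str  # single uppercase letter
    copy: int
    suffix: str = ""  # i | c | ""

    def __post_init__(self) -> None:
        if self.code not in LOCALIZATION_CODES:
            raise ValueError(f"invalid localization code {self.code!r}")
        if len(self.lineage) != 1 or not self.lineage.isalpha() or not self.lineage.isupper():
            raise ValueError(f"invalid lineage letter {self.lineage!r}")
        if self.copy < 1:
            raise ValueError(f"copy number must be >= 1, got {self.copy}")
        if self.suffix not in ("", "i", "c"):
            raise ValueError(f"invalid inducibility suffix {self.suffix!r}")

    @property
    def protein(self) -> str:
        return f"HSP70{self.code}{self.lineage}{self.copy}{self.suffix}"

    @property
    def gene(self) -> str:
        return self.protein.lower()


def compose_name(code: str, lineage: str, copy: int, suffix: str = "") -> NomenclatureName:
    """Build a validated name from its parts ('' suffix = inducibility unknown)."""
    return NomenclatureName(code=code, lineage=lineage.upper(), copy=copy, suffix=suffix)


def parse_name(text: str) -> NomenclatureName:
    """Case-insensitive parse of a protein or gene form name.

    'er' is consumed greedily before the single-letter codes, so hsp70era1
    is (er, A, 1) and not an error.  Unparseable input raises with the
    1-based position where parsing failed.
    """
    low = text.lower()
    pos = 0
    if not low.startswith("hsp70"):
        raise ValueError(f"cannot parse {text!r}: expected 'HSP70' at position 1")
    pos = 5
    if low.startswith("er", pos):
        code = "er"
        pos += 2
    elif pos < len(low) and low[pos] in ("c", "m"):
        code = low[pos]
        pos += 1
    else:
        raise ValueError(
            f"cannot parse {text!r}: expected localization code c/m/er at "
            f"position {pos + 1}"
        )
    if pos >= len(low) or not low[pos].isalpha():
        raise ValueError(
            f"cannot parse {text!r}: expected lineage letter at position {pos + 1}"
        )
    lineage = low[pos].upper()
    pos += 1
    digits = ""
    while pos < len(low) and low[pos].isdigit():
        digits += low[pos]
        pos += 1
    if not digits:
        raise ValueError(
            f"cannot parse {text!r}: expected copy number at position {pos + 1}"
        )
    suffix = ""
    if pos < len(low):
        if low[pos] in ("i", "c") and pos == len(low) - 1:
            suffix = low[pos]
            pos += 1
        else:
            raise ValueError(
                f"cannot parse {text!r}: unexpected trailing text at position {pos + 1}"
            )
    return NomenclatureName(code=code, lineage=lineage, copy=int(digits), suffix=suffix)


def assign_names(
    records: Iterable,
    lineages: Mapping[str, str] | None = None,
) -> dict[str, NomenclatureName]:
    """Assign names to annotated records (ProteinRecord-like objects).

    Copy numbers count up per (species, localization, lineage) group in input
    order.  Organelle members default to lineage A — only one mitochondrial
    and one ER lineage are known, and reserving the letter keeps room for
    novel ones.  Records without a localization are skipped with a warning.
    *lineages* overrides per-id lineage letters (e.g. from a CladeMap).
    """
    lineages = lineages or {}
    counters: dict[tuple[str, str, str], int] = {}
    out: dict[str, NomenclatureName] = {}
    for rec in records:
        loc = rec.localization
        if loc == Localization.UNKNOWN:
            logger.warning("record %s has unknown localization; skipped", rec.id)
            continue
        code = CODE_OF_LOCALIZATION[loc]
        lineage = lineages.get(rec.id) or rec.clade or ""
        if loc != Localization.CYTOSOL and (not lineage or len(lineage) != 1):
            lineage = "A"
        if len(lineage) != 1 or not lineage.isalpha():
            logger.warning("record %s has no usable lineage label (%r); skipped",
                           rec.id, lineage)
            continue
        lineage = lineage.upper()
        key = (rec.species, code, lineage)
        counters[key] = counters.get(key, 0) + 1
        out[rec.id] = NomenclatureName(
            code=code, lineage=lineage, copy=counters[key],
            suffix=SUFFIX_OF_INDUCIBILITY[rec.inducibility],
        )
    return out


def names_table(names: Mapping[str, NomenclatureName], records=None):
    """TSV-ready table: id, species, proposed protein and gene names."""
    import pandas as pd

    by_id = {r.id: r for r in records} if records else {}
    rows = []
    for rid, name in names.items():
        rec = by_id.get(rid)
        rows.append(
            {
                "id": rid,
                "species": rec.species if rec else "",
                "protein_name": name.protein,
                "gene_name": name.gene,
                "localization": LOCALIZATION_CODES[name.code].value,
                "lineage": name.lineage,
                "copy": name.copy,
                "inducibility_suffix": name.suffix,
            }
        )
    return pd.DataFrame(rows)
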