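"""Synthetic HSP70-like gene families with known truth.

The generator emulates the structure the analysis assumes for a metazoan
HSP70 family: ancient duplications produce one mitochondrial, one ER and two
(or more) cytosolic lineages (A and B), each lineage then tracking a shared
species tree.  Coding sequences evolve along the gene tree under a two-class
scheme — synonymous changes at a per-branch expected rate, nonsynonymous
changes at omega times that — so the dN/dS contrast between lineages is a
controlled dial the estimation stage must recover.  Diagnostic features are
injected at lineage ancestors and frozen against further mutation, mirroring
the conservation of real diagnostic residues: C-terminal EEVD (cytosolic) or
KDEL (ER), the N-terminal localization signature variants, and the
Lineage-A serine insertion in the ATPase domain.  Optional post-hoc noise
and frame-shift injections produce the degenerate records the pipeline must
tolerate, and every injected degeneracy is recorded in a ledger.

All randomness flows from one explicit seed; a fixed configuration yields
byte-identical output files.
"""

from __future__ import annotations

import string
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from .kaks import (CODON_TO_AA, SENSE_CODONS, STOP_CODONS, _position_site_fractions,
                   translate_codon)
from .motif_classify import default_signatures
from .seqio import (CodingRecord, Inducibility, Localization, MetadataTable,
                    MultipleAlignment, ProteinRecord, write_alignment, write_fasta,
                    write_metadata_table)

NUCLEOTIDES = "ACGT"

#: deterministic codon per amino acid (first sense codon in lexicographic order)
PREFERRED_CODON: dict[str, str] = {}
for _c in SENSE_CODONS:
    PREFERRED_CODON.setdefault(CODON_TO_AA[_c], _c)

#: 0-based codon offset of the N-terminal signature window in simulated genes
NTERM_OFFSET = 8
#: codon index at which the Lineage-A serine is inserted
SERINE_INSERT_AT = 100
SERINE_CODON = "AGC"
SERINE_FLANK = 5

_ORGANELLE_LOCALIZATION = {"mito": Localization.MITOCHONDRIA, "ER": Localization.ER}
_LINEAGE_TAG = {"mito": "mt", "ER": "er"}


@dataclass
class SimulationConfig:
    """Study conditions for one simulated family.

    ``stem_ks`` is the expected synonymous divergence on each duplication
    stem branch and ``crown_ks`` the root-to-tip synonymous divergence within
    each lineage's species tree, so a typical inter-lineage pair accumulates
    path Ks near 1 — divergent enough to be informative, below saturation.
    Per-lineage omega defaults put Lineage A (inducible) under weaker
    purifying selection (0.2) than Lineage B and the organelle lineages
    (0.05), the regime the family is observed in (omega well below 1).
    """

    seed: int = 0
    n_species: int = 3
    n_cytosolic_lineages: int = 2
    organelle_lineages: tuple[str, ...] = ("mito", "ER")
    omega: dict[str, float] = field(
        default_factory=lambda: {"A": 0.2, "B": 0.05, "mito": 0.05, "ER": 0.05}
    )
    backbone_omega: float = 0.05
    stem_ks: float = 0.15
    crown_ks: float = 0.25
    n_codons: int = 200
    inject_cterm: bool = True
    inject_nterm: bool = True
    inject_serine: bool = True
    noise: float = 0.0
    n_frameshift: int = 0

    def __post_init__(self) -> None:
        if self.n_codons < 50:
            raise ValueError("need at least 50 codons")
        if not 0 <= self.noise <= 1:
            raise ValueError("noise must be a probability")
        if self.n_cytosolic_lineages < 1:
            raise ValueError("need at least one cytosolic lineage")
        for name, w in self.omega.items():
            if w < 0:
                raise ValueError(f"omega for {name} must be >= 0")
        if self.inject_serine and self.n_cytosolic_lineages < 2:
            raise ValueError(
                "serine insertion needs Lineage A plus a reference lineage B"
            )
        if self.inject_serine and self.n_codons < SERINE_INSERT_AT + SERINE_FLANK + 1:
            raise ValueError("sequence too short for the serine insertion window")

    @property
    def cytosolic_lineages(self) -> tuple[str, ...]:
        return tuple(string.ascii_uppercase[: self.n_cytosolic_lineages])

    def omega_of(self, lineage: str) -> float:
        return self.omega.get(lineage, self.backbone_omega)


@dataclass
class SimulatedFamily:
    """A simulated family plus every ground truth the pipeline estimates."""

    config: SimulationConfig
    proteins: list[ProteinRecord]
    codings: list[CodingRecord]
    alignment: MultipleAlignment
    tree_newick: str
    clades: dict[str, str]
    localization: dict[str, Localization]
    inducibility: dict[str, Inducibility]
    ledger: list[dict]

    @property
    def ids(self) -> list[str]:
        return [p.id for p in self.proteins]

    def metadata(self) -> MetadataTable:
        rows = []
        for idx, rec in enumerate(self.proteins, start=1):
            rows.append(
                {
                    "id": rec.id,
                    "species": rec.species,
                    "phylum": "Synthetica",
                    "localization": self.localization[rec.id].value,
                    "inducibility": self.inducibility[rec.id].value,
                    "clade": self.clades[rec.id],
                    "accession": f"SYN{idx:04d}",
                }
            )
        return MetadataTable(pd.DataFrame(rows, columns=list(MetadataTable.COLUMNS)))

    def to_files(self, outdir: str | Path) -> dict[str, Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "proteins": outdir / "proteins.fasta",
            "cds": outdir / "cds.fasta",
            "alignment": outdir / "alignment.fasta",
            "tree": outdir / "tree.nwk",
            "metadata": outdir / "metadata.tsv",
        }
        write_fasta(self.proteins, paths["proteins"])
        write_fasta(self.codings, paths["cds"])
        write_alignment(self.alignment, paths["alignment"])
        paths["tree"].write_text(self.tree_newick + "\n")
        write_metadata_table(self.metadata(), paths["metadata"])
        return paths


# ---------------------------------------------------------------------------
# species tree


def _random_topology(rng: np.random.Generator, leaves: list[str]):
    if len(leaves) == 1:
        return leaves[0]
    order = list(leaves)
    rng.shuffle(order)
    k = int(rng.integers(1, len(order)))
    return (_random_topology(rng, order[:k]), _random_topology(rng, order[k:]))


def _depths(node, depth=0, out=None):
    out = out if out is not None else {}
    out[id(node)] = depth
    if isinstance(node, tuple):
        for child in node:
            _depths(child, depth + 1, out)
    return out


# ---------------------------------------------------------------------------
# sequence evolution


def _evolve_branch(codons: list[str], t: float, omega: float,
                   masked: frozenset[int], rng: np.random.Generator) -> list[str]:
    """One pass of the two-class substitution scheme along a branch.

    Per codon position the synonymous-change probability is t times the
    position's synonymous site fraction; nonsynonymous changes occur at
    omega times the corresponding nonsynonymous mass.  Stops are never
    created and masked codons are frozen.
    """
    out = list(codons)
    for idx in range(len(out)):
        if idx in masked:
            continue
        codon = out[idx]
        for pos in range(3):
            fractions = _position_site_fractions(codon)
            s_p = fractions[pos]
            syn_alts, nonsyn_alts = [], []
            for nt in NUCLEOTIDES:
                if nt == codon[pos]:
                    continue
                alt = codon[:pos] + nt + codon[pos + 1:]
                if alt in STOP_CODONS:
                    continue
                if CODON_TO_AA[alt] == CODON_TO_AA[codon]:
                    syn_alts.append(alt)
                else:
                    nonsyn_alts.append(alt)
            p_syn = t * s_p if syn_alts else 0.0
            p_non = t * omega * (1.0 - s_p) if nonsyn_alts else 0.0
            u = rng.random()
            if u < p_syn:
                codon = syn_alts[int(rng.integers(len(syn_alts)))]
            elif u < p_syn + p_non:
                codon = nonsyn_alts[int(rng.integers(len(nonsyn_alts)))]
        out[idx] = codon
    return out


def _encode(residues: str) -> list[str]:
    return [PREFERRED_CODON[aa] for aa in residues]


def _overwrite_window(codons: list[str], offset: int, residues: dict[int, str]) -> None:
    """Write window-position -> residue map (1-based positions) at *offset*."""
    for pos, aa in residues.items():
        codons[offset + pos - 1] = PREFERRED_CODON[aa]


# ---------------------------------------------------------------------------
# family simulation


def simulate_family(config: SimulationConfig) -> SimulatedFamily:
    """Simulate one family under *config*; see the module docstring."""
    rng = np.random.default_rng(config.seed)
    signatures = default_signatures()
    n = config.n_codons
    species = [f"sp{i + 1}" for i in range(config.n_species)]

    # --- root sequence and frozen sites
    root = [SENSE_CODONS[int(rng.integers(len(SENSE_CODONS)))] for _ in range(n)]
    masked: set[int] = set()
    if config.inject_nterm:
        consensus = signatures.consensus_window(Localization.CYTOSOL)
        for i, aa in enumerate(consensus):
            root[NTERM_OFFSET + i] = PREFERRED_CODON[aa]
        masked.update(range(NTERM_OFFSET, NTERM_OFFSET + len(consensus)))
    if config.inject_cterm:
        masked.update(range(n - 4, n))
        for i, aa in enumerate("GSSA"):  # neutral root terminus, set per lineage below
            root[n - 4 + i] = PREFERRED_CODON[aa]
    if config.inject_serine:
        masked.update(range(SERINE_INSERT_AT - SERINE_FLANK, SERINE_INSERT_AT + SERINE_FLANK))
    frozen = frozenset(masked)

    # --- lineage layout and per-lineage edits applied at the lineage ancestor
    cytosolic = config.cytosolic_lineages
    lineages = list(cytosolic) + list(config.organelle_lineages)

    def lineage_edit(lineage: str, codons: list[str]) -> list[str]:
        codons = list(codons)
        if lineage in cytosolic:
            if config.inject_cterm:
                codons[-4:] = _encode("EEVD")
        elif lineage == "ER":
            if config.inject_cterm:
                codons[-4:] = _encode("KDEL")
            if config.inject_nterm:
                _overwrite_window(codons, NTERM_OFFSET, {8: "K", 9: "N", 11: "R", 23: "I"})
        elif lineage == "mito":
            if config.inject_nterm:
                mito = {pos: sorted(allowed)[0] if len(allowed) > 1 else next(iter(allowed))
                        for pos, allowed in signatures.allowed[Localization.MITOCHONDRIA].items()}
                # use the first paper-listed variant for multi-residue positions
                mito.update({11: "T", 12: "P", 13: "K", 21: "S"})
                _overwrite_window(codons, NTERM_OFFSET, mito)
        return codons

    # --- evolve: root -> cytosolic/organelle ancestors -> lineage crowns
    def tag(lineage: str) -> str:
        return _LINEAGE_TAG.get(lineage, f"c{lineage}")

    leaf_codons: dict[str, list[str]] = {}
    newick_parts: list[str] = []

    cyt_anc = _evolve_branch(root, config.stem_ks, config.backbone_omega, frozen, rng)
    org_anc = _evolve_branch(root, config.stem_ks, config.backbone_omega, frozen, rng)

    for lineage in lineages:
        base = cyt_anc if lineage in cytosolic else org_anc
        anc = _evolve_branch(base, config.stem_ks, config.omega_of(lineage), frozen, rng)
        anc = lineage_edit(lineage, anc)
        topo = _random_topology(rng, list(species))
        depth = _depths(topo)
        max_depth = max(depth.values()) or 1

        def height(node) -> float:
            if not isinstance(node, tuple):
                return 0.0
            return config.crown_ks * (1.0 - depth[id(node)] / max_depth)

        def descend(node, codons, parent_h) -> str:
            h = height(node)
            length = parent_h - h
            evolved = _evolve_branch(codons, length, config.omega_of(lineage), frozen, rng)
            if isinstance(node, tuple):
                parts = [descend(child, evolved, h) for child in node]
                return f"({','.join(parts)}):{length:.6f}"
            leaf_id = f"{node}_{tag(lineage)}"
            leaf_codons[leaf_id] = evolved
            return f"{leaf_id}:{length:.6f}"

        crown = descend(topo, anc, config.crown_ks)
        # stem from the family root down to this lineage's crown ancestor
        stem = 2 * config.stem_ks
        newick_parts.append(f"{crown[:crown.rfind(':')]}:{stem:.6f}"
                            if crown.startswith("(") else f"{crown.split(':')[0]}:{stem:.6f}")

    tree_newick = f"({','.join(newick_parts)});"

    # --- materialize aligned rows (serine insertion column for Lineage A)
    ids = sorted(leaf_codons)
    aligned_rows: dict[str, list[str]] = {}
    for rid in ids:
        codons = leaf_codons[rid]
        if config.inject_serine:
            cells = list(codons[:SERINE_INSERT_AT])
            if rid.endswith("_cA"):
                cells.append(SERINE_CODON)
            else:
                cells.append("---")
            cells.extend(codons[SERINE_INSERT_AT:])
        else:
            cells = list(codons)
        aligned_rows[rid] = cells

    ledger: list[dict] = []

    # --- post-hoc noise (may hit any column, including motif sites)
    if config.noise > 0:
        for rid in ids:
            cells = aligned_rows[rid]
            hits = 0
            for k, cell in enumerate(cells):
                if cell == "---":
                    continue
                if rng.random() < config.noise:
                    aa = CODON_TO_AA[cell]
                    others = [c for c in SENSE_CODONS if CODON_TO_AA[c] != aa]
                    cells[k] = others[int(rng.integers(len(others)))]
                    hits += 1
            if hits:
                ledger.append({"id": rid, "type": "noise", "n_substitutions": hits})

    # --- records
    def lineage_of(rid: str) -> str:
        suffix = rid.rsplit("_", 1)[1]
        for lin in lineages:
            if suffix == tag(lin):
                return lin
        raise AssertionError(rid)

    localization: dict[str, Localization] = {}
    inducibility: dict[str, Inducibility] = {}
    clades: dict[str, str] = {}
    proteins: list[ProteinRecord] = []
    codings: list[CodingRecord] = []

    frameshift_ids = set()
    if config.n_frameshift:
        pick = rng.choice(len(ids), size=min(config.n_frameshift, len(ids)), replace=False)
        frameshift_ids = {ids[int(i)] for i in sorted(pick)}

    for rid in ids:
        lin = lineage_of(rid)
        sp = rid.rsplit("_", 1)[0]
        loc = _ORGANELLE_LOCALIZATION.get(lin, Localization.CYTOSOL)
        if lin == "A":
            ind = Inducibility.INDUCIBLE
        elif lin in cytosolic:
            ind = Inducibility.CONSTITUTIVE
        else:
            ind = Inducibility.UNKNOWN
        cells = aligned_rows[rid]
        protein = "".join(translate_codon(c) for c in cells if c != "---")
        cds = "".join(c for c in cells if c != "---") + "TAA"
        if rid in frameshift_ids:
            pos = len(cds) // 2
            cds = cds[:pos] + "A" + cds[pos:]
            ledger.append({"id": rid, "type": "frame_shift", "position": pos + 1})
        localization[rid] = loc
        inducibility[rid] = ind
        clades[rid] = lin
        proteins.append(
            ProteinRecord(id=rid, sequence=protein, species=sp, localization=loc,
                          inducibility=ind, clade=lin)
        )
        codings.append(CodingRecord(id=rid, cds=cds, frame_shifted=rid in frameshift_ids))

    alignment = MultipleAlignment(
        ids=list(ids),
        rows=["".join("-" if c == "---" else translate_codon(c) for c in aligned_rows[rid])
              for rid in ids],
    )
    return SimulatedFamily(
        config=config, proteins=proteins, codings=codings, alignment=alignment,
        tree_newick=tree_newick, clades=clades, localization=localization,
        inducibility=inducibility, ledger=ledger,
    )


def fixture_small_family() -> SimulatedFamily:
    """The canonical seed-0 fixture: 3 species x {cytA, cytB, mito, ER}."""
    return simulate_family(SimulationConfig())
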