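"""Pairwise Ka/Ks estimation on codon alignments.

The substitution-rate stage asks whether clades of the HSP70 family differ in
purifying-selection pressure.  It needs four pieces, all implemented here:

* CDS validation — frame-shifted or mistranslated database records (one
  rotifer CDS in the motivating dataset carries an insertion plus a deletion
  that shift the frame) are detected and excluded from rate estimation;
* back-translation of a protein alignment onto its coding sequences, giving
  a codon alignment;
* Nei–Gojobori (1986) counting: synonymous/nonsynonymous site counts per
  codon (stop-avoiding changes renormalized, so S + N = 3 exactly) and
  pairwise difference counts with multi-hit codons averaged over all
  substitution orderings that avoid stop codons, followed by Jukes–Cantor
  multiple-hit correction d = -(3/4)·ln(1 - 4p/3);
* saturation filtering (Ks beyond a threshold, or outside the correction
  domain, is meaningless) and pooling of inter-clade pair ratios per clade.

Ka/Ks (omega) < 1 indicates purifying selection; the family sits deep in
that regime, so the interesting signal is *how far* below 1 each clade is.
"""

from __future__ import annotations

import itertools
import statistics
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from Bio.Data import CodonTable
from Bio.Seq import Seq

from .seqio import GAP, CodingRecord, MultipleAlignment, ProteinRecord

_STANDARD = CodonTable.unambiguous_dna_by_id[1]
STOP_CODONS = frozenset(_STANDARD.stop_codons)
CODON_TO_AA: dict[str, str] = dict(_STANDARD.forward_table)
CODON_TO_AA.update({c: "*" for c in STOP_CODONS})
SENSE_CODONS = tuple(sorted(set(CODON_TO_AA) - STOP_CODONS))
NUCLEOTIDES = "ACGT"
GAP_CODON = "---"


def translate_codon(codon: str) -> str:
    """One-letter translation; codons containing N translate to X."""
    if "N" in codon:
        return "X"
    return CODON_TO_AA[codon]


# ---------------------------------------------------------------------------
# CDS validation and back-translation


@dataclass
class CdsValidation:
    """Outcome of checking a CDS against its protein sequence."""

    id: str
    ok: bool
    reason: str = ""  # frame_shift | translation_mismatch
    codon_index: int | None = None  # 1-based first offending codon
    message: str = ""


def strip_terminal_stop(cds: str) -> str:
    if len(cds) % 3 == 0 and cds[-3:] in STOP_CODONS:
        return cds[:-3]
    return cds


def validate_cds(protein: ProteinRecord, coding: CodingRecord) -> CdsValidation:
    """Check length/frame and translation agreement between protein and CDS.

    OK iff the CDS (terminal stop removed) is exactly 3x the protein length
    and every codon translates to the protein residue (X on either side
    matches anything).  Length mismatches are reported as frame shifts; the
    first mismatching codon is named otherwise.
    """
    if protein.id != coding.id:
        raise ValueError(f"id mismatch: {protein.id!r} vs {coding.id!r}")
    cds = strip_terminal_stop(coding.cds)
    if len(cds) != 3 * len(protein.sequence):
        return CdsValidation(
            id=protein.id, ok=False, reason="frame_shift",
            message=(
                f"CDS length {len(cds)} (stop removed) != 3 x protein length "
                f"{len(protein.sequence)}"
            ),
        )
    for k in range(len(protein.sequence)):
        codon = cds[3 * k:3 * k + 3]
        aa = translate_codon(codon)
        expected = protein.sequence[k]
        if aa == "X" or expected == "X":
            continue
        if aa != expected:
            return CdsValidation(
                id=protein.id, ok=False, reason="translation_mismatch",
                codon_index=k + 1,
                message=f"codon {k + 1} ({codon}) translates to {aa}, protein has {expected}",
            )
    return CdsValidation(id=protein.id, ok=True)


@dataclass
class CodonAlignment:
    """Aligned codons: one 3-mer (or ``---``) per protein alignment column."""

    ids: list[str]
    rows: list[list[str]]

    def __post_init__(self) -> None:
        if len(self.ids) != len(self.rows):
            raise ValueError("ids and rows differ in length")
        if self.rows:
            ncod = len(self.rows[0])
            for rid, row in zip(self.ids, self.rows):
                if len(row) != ncod:
                    raise ValueError(f"ragged codon alignment at row {rid!r}")
                for cell in row:
                    if cell != GAP_CODON and (
                        len(cell) != 3 or any(ch not in "ACGTN" for ch in cell)
                    ):
                        raise ValueError(f"bad codon cell {cell!r} in row {rid!r}")

    @property
    def ncodons(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    def row(self, rid: str) -> list[str]:
        return self.rows[self.ids.index(rid)]

    def slice_columns(self, start: int, stop: int) -> "CodonAlignment":
        """Codon-column slice with python half-open 0-based semantics."""
        return CodonAlignment(list(self.ids), [r[start:stop] for r in self.rows])

    def to_protein_alignment(self) -> MultipleAlignment:
        prot_rows = [
            "".join(GAP if cell == GAP_CODON else translate_codon(cell) for cell in row)
            for row in self.rows
        ]
        return MultipleAlignment(list(self.ids), prot_rows)


def backtranslate(aln: MultipleAlignment, coding: Mapping[str, CodingRecord],
                  proteins: Mapping[str, ProteinRecord] | None = None) -> CodonAlignment:
    """Map a protein alignment onto its CDSs, producing a codon alignment.

    Every row must pass :func:`validate_cds` against its ungapped protein
    sequence; failures abort with the offending ids so frame-shifted records
    are excluded upstream rather than silently mistranslated.
    """
    failures = []
    for rid in aln.ids:
        if rid not in coding:
            failures.append((rid, "no CDS"))
            continue
        prot = (proteins[rid] if proteins and rid in proteins
                else ProteinRecord(id=rid, sequence=aln.ungapped(rid)))
        check = validate_cds(prot, coding[rid])
        if not check.ok:
            failures.append((rid, check.reason))
    if failures:
        raise ValueError(f"CDS validation failed for: {failures}")
    rows = []
    for rid in aln.ids:
        cds = strip_terminal_stop(coding[rid].cds)
        cells, k = [], 0
        for ch in aln.row(rid):
            if ch == GAP:
                cells.append(GAP_CODON)
            else:
                cells.append(cds[3 * k:3 * k + 3])
                k += 1
        rows.append(cells)
    return CodonAlignment(list(aln.ids), rows)


# ---------------------------------------------------------------------------
# NG86 counting


def _position_site_fractions(codon: str) -> list[float]:
    """Synonymous site fraction at each codon position.

    Each position offers three single-nucleotide changes; changes that create
    a stop codon are skipped and the synonymous fraction is renormalized over
    the remaining ones, so every position contributes exactly one site and
    S + N = 3 for all sense codons.
    """
    fractions = []
    aa = CODON_TO_AA[codon]
    for pos in range(3):
        syn = nonstop = 0
        for nt in NUCLEOTIDES:
            if nt == codon[pos]:
                continue
            alt = codon[:pos] + nt + codon[pos + 1:]
            if alt in STOP_CODONS:
                continue
            nonstop += 1
            if CODON_TO_AA[alt] == aa:
                syn += 1
        fractions.append(syn / nonstop if nonstop else 0.0)
    return fractions


def ng86_site_counts(codon: str) -> tuple[float, float]:
    """(S, N) site counts for one codon; (0, 0) for stop or N-containing codons."""
    if "N" in codon or codon in STOP_CODONS:
        return 0.0, 0.0
    s = sum(_position_site_fractions(codon))
    return s, 3.0 - s


def _pathway_differences(codon_a: str, codon_b: str) -> tuple[float, float] | None:
    """(synonymous, nonsynonymous) differences between two sense codons.

    Multi-nucleotide differences are averaged over all orderings of the
    single-nucleotide steps; orderings that pass through a stop codon are
    excluded and the remaining ones reweighted.  None when every pathway is
    blocked by stop codons.
    """
    diff_positions = [p for p in range(3) if codon_a[p] != codon_b[p]]
    if not diff_positions:
        return 0.0, 0.0
    syn_totals, nonsyn_totals = [], []
    for order in itertools.permutations(diff_positions):
        current = codon_a
        syn = nonsyn = 0
        blocked = False
        for pos in order:
            nxt = current[:pos] + codon_b[pos] + current[pos + 1:]
            if nxt in STOP_CODONS:
                blocked = True
                break
            if CODON_TO_AA[nxt] == CODON_TO_AA[current]:
                syn += 1
            else:
                nonsyn += 1
            current = nxt
        if not blocked:
            syn_totals.append(syn)
            nonsyn_totals.append(nonsyn)
    if not syn_totals:
        return None
    return (sum(syn_totals) / len(syn_totals), sum(nonsyn_totals) / len(nonsyn_totals))


def jukes_cantor(p: float) -> float:
    """JC multiple-hit correction; requires p < 3/4."""
    if p >= 0.75:
        raise ValueError(f"proportion {p} outside Jukes-Cantor domain [0, 3/4)")
    return -0.75 * np.log1p(-4.0 * p / 3.0)


@dataclass
class KaKsPair:
    """Pairwise substitution-rate estimate between two aligned CDSs."""

    id_i: str
    id_j: str
    ka: float | None = None
    ks: float | None = None
    ratio: float | None = None
    valid: bool = False
    reason: str = ""  # saturated | undefined_correction | too_few_sites | frame_shift | zero_ks
    n_codons: int = 0

    @property
    def key(self) -> tuple[str, str]:
        return tuple(sorted((self.id_i, self.id_j)))


def _comparable_codon(cell: str) -> bool:
    return cell != GAP_CODON and "N" not in cell and cell not in STOP_CODONS


def ng86_pairwise(aln: CodonAlignment, id_i: str, id_j: str,
                  min_codons: int = 10) -> KaKsPair:
    """NG86 Ka/Ks for one pair of codon-alignment rows.

    Only columns where both cells are gap-free, N-free and non-stop are
    compared (columns whose every substitution pathway crosses a stop codon
    are likewise dropped).  Proportions of differences per site are corrected
    with Jukes–Cantor; a proportion at or beyond 3/4 cannot be corrected and
    invalidates the pair, as do fewer than *min_codons* comparable columns.
    """
    row_i, row_j = aln.row(id_i), aln.row(id_j)
    s_i = s_j = 0.0
    sd = nd = 0.0
    n_comp = 0
    for a, b in zip(row_i, row_j):
        if not (_comparable_codon(a) and _comparable_codon(b)):
            continue
        path = _pathway_differences(a, b)
        if path is None:
            continue
        sa, _ = ng86_site_counts(a)
        sb, _ = ng86_site_counts(b)
        s_i += sa
        s_j += sb
        sd += path[0]
        nd += path[1]
        n_comp += 1
    pair = KaKsPair(id_i=id_i, id_j=id_j, n_codons=n_comp)
    if n_comp < min_codons:
        pair.reason = "too_few_sites"
        return pair
    s_sites = 0.5 * (s_i + s_j)
    n_sites = 3.0 * n_comp - s_sites
    ps = sd / s_sites if s_sites > 0 else 0.0
    pn = nd / n_sites if n_sites > 0 else 0.0
    if ps >= 0.75 or pn >= 0.75:
        pair.reason = "undefined_correction"
        return pair
    pair.ks = float(jukes_cantor(ps))
    pair.ka = float(jukes_cantor(pn))
    pair.valid = True
    if pair.ks > 0:
        pair.ratio = pair.ka / pair.ks
    return pair


def pairwise_kaks_matrix(aln: CodonAlignment, min_codons: int = 10) -> list[KaKsPair]:
    """NG86 estimates for all unordered row pairs, in lexicographic id order."""
    if len(aln.ids) < 2:
        raise ValueError("need at least 2 rows")
    out = []
    for id_i, id_j in itertools.combinations(sorted(aln.ids), 2):
        out.append(ng86_pairwise(aln, id_i, id_j, min_codons=min_codons))
    return out


def filter_saturated(pairs: Iterable[KaKsPair], ks_max: float = 3.0
                     ) -> tuple[list[KaKsPair], list[KaKsPair]]:
    """Split pairs into (retained, excluded) by the saturation rule.

    Retained pairs are valid with 0 < Ks <= ks_max; everything else is
    excluded with its reason preserved (saturated for Ks > ks_max, zero_ks
    for Ka/Ks undefined at Ks = 0).
    """
    retained, excluded = [], []
    for pair in pairs:
        if not pair.valid:
            excluded.append(pair)
        elif pair.ks > ks_max:
            pair.reason = "saturated"
            pair.valid = False
            excluded.append(pair)
        elif pair.ks <= 0:
            pair.reason = "zero_ks"
            pair.valid = False
            excluded.append(pair)
        else:
            retained.append(pair)
    return retained, excluded


@dataclass
class CladeKaKsSummary:
    """Pooled Ka/Ks ratios for one clade (inter-clade pairs only)."""

    clade: str
    values: list[float]

    @property
    def count(self) -> int:
        return len(self.values)

    @property
    def mean(self) -> float:
        return statistics.fmean(self.values) if self.values else float("nan")

    @property
    def median(self) -> float:
        return statistics.median(self.values) if self.values else float("nan")


def clade_pool(retained: Iterable[KaKsPair], clades: Mapping[str, str]
               ) -> list[CladeKaKsSummary]:
    """Pool each inter-clade pair's ratio into both endpoint clades.

    Intra-clade pairs are excluded; a pooled id without a clade is an error.
    Summaries are ordered by clade label.
    """
    pools: dict[str, list[float]] = {}
    for pair in retained:
        for rid in (pair.id_i, pair.id_j):
            if rid not in clades:
                raise KeyError(f"id {rid!r} has no clade assignment")
        ci, cj = clades[pair.id_i], clades[pair.id_j]
        if ci == cj or pair.ratio is None:
            continue
        pools.setdefault(ci, []).append(pair.ratio)
        pools.setdefault(cj, []).append(pair.ratio)
    return [CladeKaKsSummary(clade=c, values=pools[c]) for c in sorted(pools)]


def pairs_to_table(pairs: Iterable[KaKsPair]):
    """Long-format table (id_i, id_j, ka, ks, ratio, valid, reason, n_codons)."""
    import pandas as pd

    return pd.DataFrame(
        [
            {
                "id_i": p.id_i, "id_j": p.id_j, "ka": p.ka, "ks": p.ks,
                "ratio": p.ratio, "valid": p.valid, "reason": p.reason,
                "n_codons": p.n_codons,
            }
            for p in pairs
        ]
    )
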