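"""Sequence-signature computations for subcellular-localization calls.

Metazoan HSP70 family members carry two independent localization signals that
survive deep divergence:

* a short region near the N terminus (after any signal peptide) whose residues
  differ systematically between cytosolic, ER and mitochondrial members —
  relative to the cytosolic consensus, ER members show Q8K, H9N, K11R and T23I,
  while mitochondrial members differ at most window positions (Y1N, G5A, F7M,
  Q8E, H9G, G10K, K11T/Q/V, V12P/A, E13K/R, I14V, I15L, A16E, D17A, Q18E,
  N21S/A/M);
* the classical C-terminal tetrapeptides: EEVD (cytosolic) and HDEL/KDEL
  (ER retention).

The RARFEEL motif, once proposed as cytosol-specific, also occurs in
ER-clade members; it is therefore detected and reported but never used for
the label.  A third diagnostic — an extra serine inserted in the ATPase
domain — marks cytosolic Lineage A and is detected against a Lineage-B
reference row in an alignment.

This module also provides the positional-profile (sequence logo) arithmetic:
per-column residue frequencies and information content in bits.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .seqio import AMINO_ACIDS, GAP, Localization, MultipleAlignment

LOG2_20 = math.log2(20.0)

#: residues used at window positions that carry no diagnostic signal, shared
#: by every localization consensus so they never discriminate
_NEUTRAL_CONTEXT = {2: "S", 3: "G", 4: "I", 6: "P", 19: "V", 20: "T", 22: "F"}

DEFAULT_WINDOW_LENGTH = 23
DEFAULT_SEARCH_LIMIT = 90
DEFAULT_VOTE_MARGIN = 2

CTERM_MOTIFS = ("EEVD", "HDEL", "KDEL")
RARFEEL = "RARFEEL"


# ---------------------------------------------------------------------------
# signature table


@dataclass
class SignatureTable:
    """Allowed residues per (1-based window position, localization)."""

    window_length: int
    allowed: dict[Localization, dict[int, frozenset[str]]]

    @property
    def positions(self) -> list[int]:
        """Union of signature positions across localizations, sorted."""
        out: set[int] = set()
        for table in self.allowed.values():
            out.update(table)
        return sorted(out)

    def union_allowed(self, position: int) -> frozenset[str]:
        out: set[str] = set()
        for table in self.allowed.values():
            out.update(table.get(position, ()))
        return frozenset(out)

    def consensus_window(self, localization: Localization) -> str:
        """A full-length consensus string for one localization.

        Signature positions take the first listed allowed residue; positions
        without signal take a neutral context residue shared by all three
        consensi, so consensus strings differ exactly at diagnostic sites.
        """
        table = self.allowed[localization]
        chars = []
        for pos in range(1, self.window_length + 1):
            if pos in table:
                chars.append(sorted(table[pos])[0] if len(table[pos]) > 1 else next(iter(table[pos])))
            else:
                chars.append(_NEUTRAL_CONTEXT.get(pos, "A"))
        return "".join(chars)


def load_signature_table(path: str | Path | None = None,
                         window_length: int = DEFAULT_WINDOW_LENGTH) -> SignatureTable:
    """Load the signature TSV (position, localization, residues).

    With no *path*, the packaged default table is used.
    """
    if path is None:
        src = resources.files("hsp70evo.data").joinpath("signatures.tsv")
        df = pd.read_csv(src.open(), sep="\t", dtype=str)
    else:
        df = pd.read_csv(path, sep="\t", dtype=str)
    allowed: dict[Localization, dict[int, frozenset[str]]] = {}
    for _, row in df.iterrows():
        loc = Localization(row["localization"])
        pos = int(row["position"])
        if not 1 <= pos <= window_length:
            raise ValueError(f"signature position {pos} outside window 1..{window_length}")
        allowed.setdefault(loc, {})[pos] = frozenset(row["residues"])
    return SignatureTable(window_length=window_length, allowed=allowed)


_DEFAULT_SIGNATURES: SignatureTable | None = None


def default_signatures() -> SignatureTable:
    global _DEFAULT_SIGNATURES
    if _DEFAULT_SIGNATURES is None:
        _DEFAULT_SIGNATURES = load_signature_table()
    return _DEFAULT_SIGNATURES


# ---------------------------------------------------------------------------
# logo arithmetic


@dataclass
class MotifProfile:
    """Per-column residue frequencies and information content of a window.

    ``frequencies[i]`` maps residues to probabilities summing to 1 (over the
    residues observed in column i, gaps ignored); ``information[i]`` is
    log2(20) - H(col) in bits, or NaN for an all-gap column.
    """

    length: int
    frequencies: list[dict[str, float]]
    information: list[float]

    def majority(self, position: int) -> tuple[str | None, float]:
        """(majority residue, its frequency) at a 1-based position."""
        freqs = self.frequencies[position - 1]
        if not freqs:
            return None, 0.0
        res = max(sorted(freqs), key=lambda r: freqs[r])
        return res, freqs[res]


def column_profile(rows: Sequence[str]) -> MotifProfile:
    """Build a :class:`MotifProfile` from equal-length aligned window rows."""
    if not rows:
        raise ValueError("no rows")
    length = len(rows[0])
    for row in rows:
        if len(row) != length:
            raise ValueError("rows have unequal lengths")
    frequencies: list[dict[str, float]] = []
    information: list[float] = []
    for col in range(length):
        counts: dict[str, int] = {}
        for row in rows:
            ch = row[col]
            if ch == GAP:
                continue
            if ch not in AMINO_ACIDS:
                continue  # X and other wildcards carry no positional signal
            counts[ch] = counts.get(ch, 0) + 1
        total = sum(counts.values())
        if total == 0:
            frequencies.append({})
            information.append(float("nan"))
            continue
        freqs = {res: n / total for res, n in counts.items()}
        entropy = -sum(p * math.log2(p) for p in freqs.values() if p > 0)
        frequencies.append(freqs)
        information.append(LOG2_20 - entropy)
    return MotifProfile(length=length, frequencies=frequencies, information=information)


def discriminating_positions(profile_a: MotifProfile, profile_b: MotifProfile,
                             threshold: float = 0.7) -> set[int]:
    """1-based positions whose majority residues differ, both above *threshold*."""
    if profile_a.length != profile_b.length:
        raise ValueError(
            f"profile lengths differ: {profile_a.length} vs {profile_b.length}"
        )
    out: set[int] = set()
    for pos in range(1, profile_a.length + 1):
        res_a, freq_a = profile_a.majority(pos)
        res_b, freq_b = profile_b.majority(pos)
        if res_a is None or res_b is None:
            continue
        if res_a != res_b and freq_a > threshold and freq_b > threshold:
            out.add(pos)
    return out


# ---------------------------------------------------------------------------
# N-terminal window location and scoring


def locate_nterm_window(sequence: str, signature: SignatureTable | None = None,
                        search_limit: int = DEFAULT_SEARCH_LIMIT,
                        min_match_fraction: float = 0.5) -> int | None:
    """Best-match offset of the signature window within the N-terminal region.

    Scans 0-based offsets up to *search_limit* (the region after any signal
    peptide but still near the N terminus), scoring each placement by matches
    to the union of all localization consensi at signature positions.  Returns
    None when even the best placement matches fewer than *min_match_fraction*
    of scored positions.
    """
    signature = signature or default_signatures()
    wlen = signature.window_length
    if len(sequence) < wlen:
        return None
    positions = signature.positions
    n_scored = len(positions)
    best_offset, best_score = None, -1
    last = min(search_limit, len(sequence) - wlen)
    for offset in range(last + 1):
        score = 0
        for pos in positions:
            if sequence[offset + pos - 1] in signature.union_allowed(pos):
                score += 1
        if score > best_score:
            best_offset, best_score = offset, score
    if best_score < min_match_fraction * n_scored:
        return None
    return best_offset


def score_nterm_window(sequence: str, signature: SignatureTable | None = None,
                       offset: int | None = None) -> dict[Localization, int]:
    """Votes per localization from the located N-terminal window.

    Each signature position casts one vote for every localization whose
    allowed residue set contains the observed residue; shared positions vote
    for all matching localizations.  All-zero votes when no window is found.
    """
    signature = signature or default_signatures()
    votes = {loc: 0 for loc in signature.allowed}
    if offset is None:
        offset = locate_nterm_window(sequence, signature)
    if offset is None:
        return votes
    for loc, table in signature.allowed.items():
        for pos, allowed in table.items():
            idx = offset + pos - 1
            if idx < len(sequence) and sequence[idx] in allowed:
                votes[loc] += 1
    return votes


def detect_cterm_motif(sequence: str) -> tuple[str, bool]:
    """(C-terminal motif or 'none', RARFEEL-anywhere flag).

    The motif is matched exactly against the final four residues; RARFEEL is
    searched anywhere but is informational only.
    """
    if not sequence:
        raise ValueError("empty sequence")
    tail = sequence[-4:]
    motif = tail if tail in CTERM_MOTIFS else "none"
    return motif, RARFEEL in sequence


_MOTIF_LABEL = {"EEVD": Localization.CYTOSOL, "HDEL": Localization.ER, "KDEL": Localization.ER}


@dataclass
class LocalizationCall:
    """Classifier verdict with its per-evidence breakdown."""

    label: Localization
    votes: dict[Localization, int]
    cterm_motif: str  # EEVD / HDEL / KDEL / none
    rarfeel: bool
    note: str = ""


def classify_localization(sequence: str, signature: SignatureTable | None = None,
                          vote_margin: int = DEFAULT_VOTE_MARGIN) -> LocalizationCall:
    """Combine C-terminal motif and N-terminal signature votes into a label.

    The C-terminal motif, when present, sets the label (EEVD -> cytosol,
    HDEL/KDEL -> ER); otherwise the N-terminal vote winner decides if it
    leads by at least *vote_margin* votes; conflicts between the two streams
    are resolved in favor of the motif and recorded in the note; with neither
    stream decisive the call is unknown.
    """
    signature = signature or default_signatures()
    motif, rarfeel = detect_cterm_motif(sequence)
    votes = score_nterm_window(sequence, signature)
    ranked = sorted(votes.items(), key=lambda kv: (-kv[1], kv[0].value))
    nterm_label: Localization | None = None
    if ranked and ranked[0][1] > 0:
        if len(ranked) == 1 or ranked[0][1] - ranked[1][1] >= vote_margin:
            nterm_label = ranked[0][0]
    note = ""
    if motif != "none":
        label = _MOTIF_LABEL[motif]
        if nterm_label is not None and nterm_label != label:
            note = (
                f"conflict: C-terminal {motif} says {label.value}, N-terminal "
                f"votes favor {nterm_label.value}; motif wins"
            )
    elif nterm_label is not None:
        label = nterm_label
    else:
        label = Localization.UNKNOWN
        note = "no C-terminal motif and no decisive N-terminal vote"
    return LocalizationCall(label=label, votes=votes, cterm_motif=motif,
                            rarfeel=rarfeel, note=note)


# ---------------------------------------------------------------------------
# Lineage-A serine insertion


@dataclass
class SerineFlag:
    """Status of the Lineage-A ATPase-domain serine insertion for one row."""

    status: str  # serine_present | substituted | absent | undetermined
    residue: str | None = None  # observed residue when substituted
    column: int | None = None  # 0-based alignment column of the insertion


def detect_lineageA_serine(aln: MultipleAlignment, reference_id: str,
                           flank: int = 5) -> dict[str, SerineFlag]:
    """Detect the Lineage-A serine insertion against a Lineage-B reference.

    The diagnostic column is an alignment column where the reference (which
    lacks the insertion) carries a gap and the *flank* columns on either side
    match the query exactly — the ATPase-domain context is conserved enough
    for exact flank matching.  Rows showing S there are serine_present,
    another residue is substituted (the residue is reported, e.g. alanine),
    a gap is absent; if no row anchors a diagnostic column, every row is
    undetermined.
    """
    ref = aln.row(reference_id)
    candidates = [i for i, ch in enumerate(ref) if ch == GAP]
    results: dict[str, SerineFlag] = {}
    for rid, row in zip(aln.ids, aln.rows):
        if rid == reference_id:
            continue
        found: SerineFlag | None = None
        for col in candidates:
            lo, hi = col - flank, col + flank + 1
            if lo < 0 or hi > len(ref):
                continue
            if ref[lo:col] != row[lo:col] or ref[col + 1:hi] != row[col + 1:hi]:
                continue
            ch = row[col]
            if ch == GAP:
                found = SerineFlag("absent", column=col)
            elif ch == "S":
                found = SerineFlag("serine_present", column=col)
            else:
                found = SerineFlag("substituted", residue=ch, column=col)
            break
        results[rid] = found if found is not None else SerineFlag("undetermined")
    if all(flag.status in ("undetermined", "absent") and flag.column is None
           for flag in results.values()):
        results = {rid: SerineFlag("undetermined") for rid in results}
    return results


def classification_report(records, signature: SignatureTable | None = None,
                          vote_margin: int = DEFAULT_VOTE_MARGIN) -> pd.DataFrame:
    """Classify each record; tabulate label, motif, votes and RARFEEL."""
    signature = signature or default_signatures()
    rows = []
    for rec in records:
        call = classify_localization(rec.sequence, signature, vote_margin)
        row = {
            "id": rec.id,
            "label": call.label.value,
            "cterm_motif": call.cterm_motif,
            "rarfeel": call.rarfeel,
            "note": call.note,
        }
        for loc, n in sorted(call.votes.items(), key=lambda kv: kv[0].value):
            row[f"votes_{loc.value}"] = n
        rows.append(row)
    return pd.DataFrame(rows)
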