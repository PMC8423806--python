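"""Independent brute-force oracles used by the test suite.

Everything here is written from definitions, independently of the package
implementation: its own genetic-code table, explicit enumeration of
substitution pathways, and explicit ranking for rank statistics.
"""

from __future__ import annotations

import itertools
import math

# standard genetic code, written out
GENETIC_CODE = {
    "AAA": "K", "AAC": "N", "AAG": "K", "AAT": "N", "ACA": "T", "ACC": "T", "ACG": "T", "ACT": "T",
    "AGA": "R", "AGC": "S", "AGG": "R", "AGT": "S", "ATA": "I", "ATC": "I", "ATG": "M", "ATT": "I",
    "CAA": "Q", "CAC": "H", "CAG": "Q", "CAT": "H", "CCA": "P", "CCC": "P", "CCG": "P", "CCT": "P",
    "CGA": "R", "CGC": "R", "CGG": "R", "CGT": "R", "CTA": "L", "CTC": "L", "CTG": "L", "CTT": "L",
    "GAA": "E", "GAC": "D", "GAG": "E", "GAT": "D", "GCA": "A", "GCC": "A", "GCG": "A", "GCT": "A",
    "GGA": "G", "GGC": "G", "GGG": "G", "GGT": "G", "GTA": "V", "GTC": "V", "GTG": "V", "GTT": "V",
    "TAA": "*", "TAC": "Y", "TAG": "*", "TAT": "Y", "TCA": "S", "TCC": "S", "TCG": "S", "TCT": "S",
    "TGA": "*", "TGC": "C", "TGG": "W", "TGT": "C", "TTA": "L", "TTC": "F", "TTG": "L", "TTT": "F",
}
STOPS = {c for c, aa in GENETIC_CODE.items() if aa == "*"}
SENSE = sorted(c for c in GENETIC_CODE if c not in STOPS)


def oracle_site_counts(codon: str) -> tuple[float, float]:
    """(S, N) by direct enumeration of the nine single-nucleotide changes,
    skipping stop-creating changes and renormalizing per position."""
    if "N" in codon or codon in STOPS:
        return 0.0, 0.0
    s_total = 0.0
    for pos in range(3):
        syn = nonstop = 0
        for nt in "ACGT":
            if nt == codon[pos]:
                continue
            alt = codon[:pos] + nt + codon[pos + 1:]
            if alt in STOPS:
                continue
            nonstop += 1
            if GENETIC_CODE[alt] == GENETIC_CODE[codon]:
                syn += 1
        s_total += syn / nonstop if nonstop else 0.0
    return s_total, 3.0 - s_total


def oracle_codon_differences(a: str, b: str) -> tuple[float, float] | None:
    """(Sd, Nd) averaged over all stop-free substitution orderings, or None
    when every ordering passes through a stop codon."""
    positions = [p for p in range(3) if a[p] != b[p]]
    if not positions:
        return 0.0, 0.0
    results = []
    for order in itertools.permutations(positions):
        cur, syn, non, ok = a, 0, 0, True
        for pos in order:
            nxt = cur[:pos] + b[pos] + cur[pos + 1:]
            if nxt in STOPS:
                ok = False
                break
            if GENETIC_CODE[nxt] == GENETIC_CODE[cur]:
                syn += 1
            else:
                non += 1
            cur = nxt
        if ok:
            results.append((syn, non))
    if not results:
        return None
    return (sum(r[0] for r in results) / len(results),
            sum(r[1] for r in results) / len(results))


def oracle_ng86(row_a: list[str], row_b: list[str], min_codons: int = 1):
    """Full NG86-with-JC estimate from scratch.

    Returns a dict with keys valid, reason, ka, ks mirroring the pairwise
    contract: comparable codons only (gap-free, N-free, non-stop, at least
    one stop-free pathway), averaged site counts, JC correction with domain
    check at 3/4.
    """

    def comparable(cell: str) -> bool:
        return cell != "---" and "N" not in cell and cell not in STOPS

    s_sites_a = s_sites_b = sd = nd = 0.0
    n_comp = 0
    for a, b in zip(row_a, row_b):
        if not (comparable(a) and comparable(b)):
            continue
        diffs = oracle_codon_differences(a, b)
        if diffs is None:
            continue
        sa, _ = oracle_site_counts(a)
        sb, _ = oracle_site_counts(b)
        s_sites_a += sa
        s_sites_b += sb
        sd += diffs[0]
        nd += diffs[1]
        n_comp += 1
    if n_comp < min_codons:
        return {"valid": False, "reason": "too_few_sites", "ka": None, "ks": None}
    s_bar = 0.5 * (s_sites_a + s_sites_b)
    n_bar = 3.0 * n_comp - s_bar
    ps = sd / s_bar if s_bar > 0 else 0.0
    pn = nd / n_bar if n_bar > 0 else 0.0
    if ps >= 0.75 or pn >= 0.75:
        return {"valid": False, "reason": "undefined_correction", "ka": None, "ks": None}
    jc = lambda p: -0.75 * math.log(1.0 - 4.0 * p / 3.0)
    return {"valid": True, "reason": "", "ka": jc(pn), "ks": jc(ps)}


def oracle_kruskal_wallis_h(groups) -> float:
    """H by explicit average ranking of the pooled sample, with tie correction."""
    pooled = [(x, gi) for gi, g in enumerate(groups) for x in g]
    values = sorted(x for x, _ in pooled)
    n = len(values)
    # average rank per value
    rank_of: dict[float, float] = {}
    i = 0
    while i < n:
        j = i
        while j < n and values[j] == values[i]:
            j += 1
        avg = (i + 1 + j) / 2.0
        rank_of[values[i]] = avg
        i = j
    h = 0.0
    for gi, g in enumerate(groups):
        rg = sum(rank_of[x] for x in g)
        h += rg * rg / len(g)
    h = 12.0 / (n * (n + 1)) * h - 3.0 * (n + 1)
    ties = 0.0
    for v in set(values):
        t = values.count(v)
        ties += t ** 3 - t
    denom = 1.0 - ties / (n ** 3 - n)
    return 0.0 if denom == 0 else h / denom


def additive_distances_from_tree(children, lengths, leaves):
    """Pairwise leaf distances by explicit path summation on a parent map.

    *children*: dict node -> list of child nodes; *lengths*: dict node ->
    branch length above it; *leaves*: list of leaf node names.
    """
    parent = {}
    for node, kids in children.items():
        for k in kids:
            parent[k] = node

    def path_to_root(x):
        out = []
        while x in parent:
            out.append(x)
            x = parent[x]
        out.append(x)
        return out

    dist = {}
    for a, b in itertools.combinations(leaves, 2):
        pa, pb = path_to_root(a), path_to_root(b)
        sa = set(pa)
        mrca = next(x for x in pb if x in sa)
        d = sum(lengths[x] for x in pa[: pa.index(mrca)])
        d += sum(lengths[x] for x in pb[: pb.index(mrca)])
        dist[frozenset((a, b))] = d
    return dist
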