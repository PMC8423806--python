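#!/usr/bin/env python
"""Estimate pairwise Ka/Ks, filter saturated pairs and pool per clade.

Back-translates the protein alignment onto the CDSs (frame-shifted records
would be excluded here), runs NG86 counting with Jukes-Cantor correction on
every sequence pair, drops pairs with saturated or uncorrectable Ks, and
pools inter-clade ratios into per-clade distributions.  Writes
results/kaks_pairs.tsv and results/clade_pools.tsv.
"""

from pathlib import Path

import pandas as pd

from hsp70evo.kaks import (backtranslate, clade_pool, filter_saturated,
                           pairs_to_table, pairwise_kaks_matrix, validate_cds)
from hsp70evo.seqio import read_alignment, read_fasta

RESULTS = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    aln = read_alignment(RESULTS / "family" / "alignment.fasta")
    proteins = {r.id: r for r in read_fasta(RESULTS / "family" / "proteins.fasta",
                                            kind="protein")}
    coding = {r.id: r for r in read_fasta(RESULTS / "family" / "cds.fasta",
                                          kind="nucleotide")}
    clades = dict(pd.read_csv(RESULTS / "clades.tsv", sep="\t").values)

    bad = [rid for rid in aln.ids if not validate_cds(proteins[rid], coding[rid]).ok]
    keep = [rid for rid in aln.ids if rid not in bad]
    if bad:
        print(f"excluded from rate estimation (CDS validation): {', '.join(bad)}")
    sub = type(aln)(keep, [aln.row(r) for r in keep])

    codon_aln = backtranslate(sub, coding)
    pairs = pairwise_kaks_matrix(codon_aln)
    retained, excluded = filter_saturated(pairs)
    pairs_to_table(pairs).to_csv(RESULTS / "kaks_pairs.tsv", sep="\t", index=False)

    summaries = clade_pool(retained, clades)
    pool_rows = []
    for s in summaries:
        pool_rows.extend({"clade": s.clade, "ratio": r} for r in s.values)
    pd.DataFrame(pool_rows).to_csv(RESULTS / "clade_pools.tsv", sep="\t", index=False)

    print(f"{len(pairs)} pairs computed, {len(retained)} retained "
          f"({len(excluded)} saturated/invalid)")
    for s in summaries:
        print(f"  clade {s.clade}: n={s.count}, mean Ka/Ks={s.mean:.4f}, "
              f"median={s.median:.4f}")
    print(f"wrote {RESULTS / 'kaks_pairs.tsv'} and {RESULTS / 'clade_pools.tsv'}")


if __name__ == "__main__":
    main()
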