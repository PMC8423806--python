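#!/usr/bin/env python
"""Assign phylogeny-aware names to every classified family member.

Names follow HSP70 + localization code (c/m/er) + lineage letter + copy
number within the organism + inducibility suffix (i/c, omitted when
unknown), with gene symbols as the lowercased protein names.  Writes
results/proposed_names.tsv.
"""

from pathlib import Path

import pandas as pd

from hsp70evo.nomenclature import assign_names, names_table
from hsp70evo.seqio import read_fasta, read_metadata_table

RESULTS = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    records = read_metadata_table(RESULTS / "family" / "metadata.tsv").annotate(
        read_fasta(RESULTS / "family" / "proteins.fasta", kind="protein")
    )
    clades = dict(pd.read_csv(RESULTS / "clades.tsv", sep="\t").values)
    names = assign_names(records, lineages=clades)
    table = names_table(names, records)
    table.to_csv(RESULTS / "proposed_names.tsv", sep="\t", index=False)

    print(f"named {len(names)} of {len(records)} records")
    for _, row in table.head(12).iterrows():
        print(f"  {row['id']:>10} -> {row['protein_name']} / {row['gene_name']}")
    print(f"wrote {RESULTS / 'proposed_names.tsv'}")


if __name__ == "__main__":
    main()
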