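"""End-to-end orchestration: trim -> classify -> tree/clades -> Ka/Ks -> stats -> names.

One call wires the library stages together on file inputs and writes every
intermediate plus a run manifest.  Frame-shifted CDS records (detected by
validate_cds) are excluded from the substitution-rate stage but retained in
classification, matching how a frame-shifted database record should be
handled: its protein annotation is still informative, its codon-level rates
are not.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .clade_stats import StatsReport, clade_comparison_report
from .kaks import (backtranslate, clade_pool, filter_saturated, pairs_to_table,
                   pairwise_kaks_matrix, validate_cds)
from .lineage_phylo import (assign_clades, midpoint_root, neighbor_joining,
                            protein_distance_matrix, read_tree, write_tree)
from .motif_classify import (classification_report, default_signatures,
                             detect_lineageA_serine)
from .nomenclature import assign_names, names_table
from .seqio import (Localization, MultipleAlignment, read_alignment, read_fasta,
                    read_metadata_table, reference_window_columns,
                    write_alignment)

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Inputs and knobs for one pipeline run.

    The trim window is applied only when a reference id is given; for real
    family data the canonical choice is the human HSPA1A/HSPA1B residues
    6-616, the well-annotated core of the alignment.
    """

    protein_fasta: str
    cds_fasta: str
    alignment: str
    metadata: str
    tree: str | None = None
    reference_id: str | None = None
    trim_window: tuple[int, int] = (6, 616)
    ks_max: float = 3.0
    vote_margin: int = 2
    serine_reference_id: str | None = None
    outdir: str = "pipeline_out"

    def validate_paths(self) -> None:
        for label in ("protein_fasta", "cds_fasta", "alignment", "metadata"):
            path = getattr(self, label)
            if not Path(path).exists():
                raise FileNotFoundError(f"{label} file not found: {path}")
        if self.tree and not Path(self.tree).exists():
            raise FileNotFoundError(f"tree file not found: {self.tree}")


@dataclass
class RunReport:
    manifest: dict
    stats: StatsReport | None
    outputs: dict[str, Path] = field(default_factory=dict)


def run_pipeline(config: PipelineConfig) -> RunReport:
    config.validate_paths()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    outputs: dict[str, Path] = {}
    manifest: dict = {"version": __version__, "config": {
        k: (list(v) if isinstance(v, tuple) else v)
        for k, v in vars(config).items()
    }}

    def emit(name: str, frame: pd.DataFrame) -> None:
        path = outdir / f"{name}.tsv"
        frame.to_csv(path, sep="\t", index=False)
        outputs[name] = path

    # --- load
    proteins = read_fasta(config.protein_fasta, kind="protein")
    codings = {r.id: r for r in read_fasta(config.cds_fasta, kind="nucleotide")}
    aln = read_alignment(config.alignment)
    meta = read_metadata_table(config.metadata)
    proteins = meta.annotate(proteins)
    by_id = {p.id: p for p in proteins}
    manifest["n_sequences"] = len(proteins)
    logger.info("loaded %d proteins, %d CDS, alignment %dx%d",
                len(proteins), len(codings), len(aln.ids), aln.ncol)

    # --- trim (the codon alignment is sliced to the same columns later)
    full_aln = aln
    window = None
    if config.reference_id:
        window = reference_window_columns(aln, config.reference_id,
                                          *config.trim_window)
        aln = aln.slice_columns(*window)
        logger.info("trimmed alignment to reference window %s: %d columns",
                    config.trim_window, aln.ncol)
    write_alignment(aln, outdir / "alignment_trimmed.fasta")
    outputs["alignment_trimmed"] = outdir / "alignment_trimmed.fasta"
    manifest["alignment_columns"] = aln.ncol

    # --- classification (all records, frame-shifted included)
    report = classification_report(proteins, vote_margin=config.vote_margin)
    serine_ref = config.serine_reference_id
    if serine_ref:
        flags = detect_lineageA_serine(aln, serine_ref)
        report["serine_status"] = [
            (flags[rid].status if rid in flags else "reference") for rid in report["id"]
        ]
    emit("localization", report)

    # --- tree and clades
    if config.tree:
        tree = read_tree(config.tree)
    else:
        dm = protein_distance_matrix(aln, model="poisson")
        tree = neighbor_joining(dm)
    write_tree(tree, outdir / "tree.nwk")
    outputs["tree"] = outdir / "tree.nwk"
    seed_clades = meta.clade_map()
    if not seed_clades:
        raise ValueError("metadata table carries no clade seed labels")
    clades = assign_clades(midpoint_root(tree), seed_clades)
    emit("clades", pd.DataFrame(sorted(clades.items()), columns=["id", "clade"]))
    manifest["n_clades"] = len(set(clades.values()))

    # --- CDS validation: exclude frame-shifted records from the rate stage
    validations = []
    rate_ids = []
    for rid in aln.ids:
        if rid not in codings:
            validations.append({"id": rid, "ok": False, "reason": "missing_cds",
                                "message": "no CDS record"})
            continue
        check = validate_cds(by_id[rid], codings[rid])
        validations.append({"id": rid, "ok": check.ok, "reason": check.reason,
                            "message": check.message})
        if check.ok:
            rate_ids.append(rid)
    emit("cds_validation", pd.DataFrame(validations))
    manifest["n_rate_sequences"] = len(rate_ids)
    logger.info("CDS validation: %d/%d records usable for rates",
                len(rate_ids), len(aln.ids))

    # --- Ka/Ks: back-translate full rows (CDS frame), then slice the window
    rate_aln = MultipleAlignment(rate_ids, [full_aln.row(r) for r in rate_ids])
    codon_aln = backtranslate(rate_aln, codings)
    if window is not None:
        codon_aln = codon_aln.slice_columns(*window)
    pairs = pairwise_kaks_matrix(codon_aln)
    retained, excluded = filter_saturated(pairs, ks_max=config.ks_max)
    emit("kaks_pairs", pairs_to_table(pairs))
    emit("kaks_retained", pairs_to_table(retained))
    manifest["pairs_computed"] = len(pairs)
    manifest["pairs_retained"] = len(retained)
    logger.info("Ka/Ks: %d pairs computed, %d retained after saturation filter",
                len(pairs), len(retained))

    # --- clade pooling and statistics
    summaries = clade_pool(retained, clades)
    emit("clade_pools", pd.DataFrame(
        [{"clade": s.clade, "count": s.count, "mean": s.mean, "median": s.median}
         for s in summaries]
    ))
    manifest["pooled_values"] = sum(s.count for s in summaries)
    stats = None
    nonempty = [s for s in summaries if s.count > 0]
    if len(nonempty) >= 2:
        stats = clade_comparison_report(nonempty)
        for name, frame in stats.to_tables().items():
            emit(f"stats_{name}", frame.reset_index()
                 if name in ("pairwise_adjusted_p", "effect_sizes") else frame)
        (outdir / "stats_summary.txt").write_text(stats.to_text() + "\n")
        outputs["stats_summary"] = outdir / "stats_summary.txt"
        manifest["kw_chi_squared"] = stats.kw_statistic
        manifest["kw_df"] = stats.kw_df
        manifest["kw_p"] = stats.kw_p
        manifest["clades_tested"] = len(nonempty)
        logger.info("stats: KW chi-squared %.3f (df=%d, p=%.3g) over %d clades",
                    stats.kw_statistic, stats.kw_df, stats.kw_p, len(nonempty))

    # --- nomenclature
    names = assign_names(proteins, lineages=clades)
    emit("proposed_names", names_table(names, proteins))
    manifest["n_named"] = len(names)

    manifest_path = outdir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    outputs["manifest"] = manifest_path
    return RunReport(manifest=manifest, stats=stats, outputs=outputs)
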