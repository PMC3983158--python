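"""End-to-end pipeline: simulate -> identify -> motifs -> structure ->
phylo -> dupl -> kaks -> expr, with per-stage TSV outputs, a consolidated
summary and a manifest.

Every stage is deterministic given the configuration seed, so two runs of
the same configuration produce byte-identical output bundles. A stage
failure aborts the run with the stage name and cause; outputs of earlier
stages are kept and listed in the manifest.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping, Optional

import pandas as pd

from . import expression as expr_mod
from . import identify as identify_mod
from .duplication import (
    DEFAULT_MAX_INTERVENING,
    DEFAULT_TANDEM_MAX_GAP,
    call_duplications,
    chromosome_map,
    classify_duplication,
)
from .io import (
    SeqRecord,
    SeqRecordSet,
    write_expression_tsv,
    write_fasta,
    write_gff3,
)
from .kaks import DEFAULT_LAMBDAS, analyze_pair
from .motifs import architecture_table
from .phylo import bootstrap_support, progressive_align
from .simulate import SimConfig, generate_family_genome
from .structure import intron_stats
from .tree import write_newick

__all__ = ["PipelineConfig", "run_pipeline"]


@dataclass(frozen=True)
class PipelineConfig:
    """All thresholds and conditions for one pipeline run."""

    sim: SimConfig = field(default_factory=SimConfig)
    species_code: str = "Zm"
    min_score: float = identify_mod.DEFAULT_MIN_SCORE
    min_coverage: float = 0.8
    min_identity: float = 0.8
    tandem_max_gap: int = DEFAULT_TANDEM_MAX_GAP
    max_intervening: int = DEFAULT_MAX_INTERVENING
    bootstrap_reps: int = 1000
    divergence_threshold: float = expr_mod.DEFAULT_DIVERGENCE_THRESHOLD
    lambdas: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_LAMBDAS)
    )
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("min_coverage", "min_identity", "divergence_threshold"):
            value = getattr(self, name)
            if not 0 < value <= 1:
                raise ValueError(f"{name} must lie in (0, 1]")
        if self.bootstrap_reps < 1:
            raise ValueError("bootstrap_reps must be >= 1")

    @staticmethod
    def from_dict(data: Mapping) -> "PipelineConfig":
        data = dict(data)
        sim = SimConfig(**{
            **data.pop("sim", {}),
            **({"seed": data["seed"]} if "seed" in data else {}),
        })
        return PipelineConfig(sim=sim, **data)


def _fmt(x: float) -> float:
    return float(f"{x:.6g}")


def run_pipeline(config: PipelineConfig, outdir: str | Path) -> dict:
    """Execute all stages; returns the summary dict (also written as JSON)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: list[dict] = []
    summary: dict = {"seed": config.seed}

    def emit(stage: str, filename: str) -> Path:
        manifest.append({"stage": stage, "file": filename})
        return outdir / filename

    stage = "simulate"
    try:
        cds, proteins, models, expr_matrix, truth = generate_family_genome(
            config.sim
        )
        write_fasta(cds, emit(stage, "cds.fna"))
        write_fasta(proteins, emit(stage, "proteins.faa"))
        write_gff3(models, emit(stage, "genes.gff3"))
        write_expression_tsv(expr_matrix, emit(stage, "expression.tsv"))
        queries = SeqRecordSet([SeqRecord("seed1", truth.ancestor_protein)])
        write_fasta(queries, emit(stage, "queries.faa"))
        truth_rows = pd.DataFrame(
            [
                {
                    "gene_a": p.gene_a,
                    "gene_b": p.gene_b,
                    "pair_type": p.pair_type,
                    "omega": p.omega,
                    "target_ks": p.target_ks,
                    "realized_ks": _fmt(p.realized_ks),
                }
                for p in truth.duplicate_pairs
            ]
        )
        truth_rows.to_csv(emit(stage, "ground_truth.tsv"), sep="\t", index=False)

        stage = "identify"
        candidates, name_table = identify_mod.identify_family(
            queries,
            proteins,
            models,
            species_code=config.species_code,
            min_score=config.min_score,
        )
        cand_table = pd.DataFrame(
            [
                {
                    "gene_id": c.gene_id,
                    "best_query": c.best_query_id,
                    "score": _fmt(c.alignment_score),
                    "motifs_found": c.motif_types_found,
                    "confirmed": c.confirmed,
                }
                for c in candidates
            ]
        )
        cand_table.to_csv(emit(stage, "candidates.tsv"), sep="\t", index=False)
        name_table.to_csv(emit(stage, "names.tsv"), sep="\t", index=False)
        family_ids = [c.gene_id for c in candidates]
        names = dict(zip(name_table["gene_id"], name_table["name"]))
        summary["family_size"] = len(family_ids)

        stage = "motifs"
        family_proteins = proteins.subset(family_ids)
        arch = architecture_table(family_proteins)
        arch.to_csv(emit(stage, "architecture.tsv"), sep="\t")

        stage = "structure"
        family_models = [m for m in models if m.gene_id in family_ids]
        records, struct_summary = intron_stats(family_models)
        pd.DataFrame(
            [
                {
                    "gene_id": r.gene_id,
                    "intron_count": r.intron_count,
                    "cds_span": r.total_cds_span,
                }
                for r in records
            ]
        ).to_csv(emit(stage, "structure.tsv"), sep="\t", index=False)
        summary["modal_intron_count"] = struct_summary.get("modal_introns")
        summary["modal_intron_fraction"] = struct_summary.get("modal_fraction")

        stage = "phylo"
        aln = progressive_align(family_proteins)
        tree, boot_info = bootstrap_support(
            aln, n_reps=config.bootstrap_reps, seed=config.seed
        )
        write_newick(tree, emit(stage, "tree.nwk"))
        summary["bootstrap"] = boot_info

        stage = "dupl"
        family_cds = cds.subset(family_ids)
        events = call_duplications(
            family_cds,
            min_coverage=config.min_coverage,
            min_identity=config.min_identity,
        )
        events = [
            classify_duplication(
                e, models, config.tandem_max_gap, config.max_intervening
            )
            for e in events
        ]
        pd.DataFrame(
            [
                {
                    "gene_a": e.gene_a,
                    "gene_b": e.gene_b,
                    "coverage": _fmt(e.coverage),
                    "identity": _fmt(e.identity),
                    "dup_type": e.dup_type,
                    "cluster": e.cluster,
                }
                for e in events
            ]
        ).to_csv(emit(stage, "events.tsv"), sep="\t", index=False)
        chromosome_map(models, names).to_csv(
            emit(stage, "chromosome_map.tsv"), sep="\t", index=False
        )
        summary["duplication_events"] = {
            "total": len(events),
            "tandem": sum(e.dup_type == "tandem" for e in events),
            "segmental": sum(e.dup_type == "segmental" for e in events),
        }

        stage = "kaks"
        kaks_rows = []
        for e in events:
            result = analyze_pair(
                cds[e.gene_a].residues,
                cds[e.gene_b].residues,
                species_code=config.species_code,
                lambdas=config.lambdas,
            )
            kaks_rows.append(
                {
                    "gene_a": e.gene_a,
                    "gene_b": e.gene_b,
                    "S": _fmt(result.S),
                    "N": _fmt(result.N),
                    "sd": _fmt(result.sd),
                    "nd": _fmt(result.nd),
                    "Ka": None if result.Ka is None else _fmt(result.Ka),
                    "Ks": None if result.Ks is None else _fmt(result.Ks),
                    "ratio": None if result.ratio is None else _fmt(result.ratio),
                    "selection": result.selection_class,
                    "T_mya": None if result.T_mya is None else _fmt(result.T_mya),
                }
            )
        kaks_table = pd.DataFrame(
            kaks_rows,
            columns=[
                "gene_a", "gene_b", "S", "N", "sd", "nd",
                "Ka", "Ks", "ratio", "selection", "T_mya",
            ],
        )
        kaks_table.to_csv(emit(stage, "kaks.tsv"), sep="\t", index=False)
        summary["kaks"] = {
            "pairs": len(kaks_rows),
            "max_ratio": _fmt(max((r["ratio"] for r in kaks_rows
                                   if r["ratio"] is not None), default=0.0)),
            "ks_range": [
                _fmt(min((r["Ks"] for r in kaks_rows if r["Ks"] is not None),
                         default=0.0)),
                _fmt(max((r["Ks"] for r in kaks_rows if r["Ks"] is not None),
                         default=0.0)),
            ],
        }

        stage = "expr"
        logged = expr_mod.log_transform(expr_matrix)
        dist = expr_mod.correlation_distance(logged)
        dendro = expr_mod.average_linkage(dist)
        labels = expr_mod.cut_clusters(dendro, k=2)
        pd.DataFrame(
            {"gene_id": expr_matrix.gene_ids, "cluster": labels}
        ).to_csv(emit(stage, "expression_clusters.tsv"), sep="\t", index=False)
        present = [
            e for e in events
            if e.gene_a in expr_matrix.gene_ids and e.gene_b in expr_matrix.gene_ids
        ]
        report = expr_mod.pair_expression_divergence(
            present, expr_matrix, threshold=config.divergence_threshold
        )
        report.to_csv(emit(stage, "expression_divergence.tsv"), sep="\t",
                      index=False, float_format="%.6g")
        summary["expression_divergent_pairs"] = int(report["divergent"].sum())
    except Exception as exc:
        (outdir / "manifest.json").write_text(
            json.dumps(manifest, indent=1, sort_keys=True) + "\n"
        )
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    (outdir / "manifest.json").write_text(
        json.dumps(manifest, indent=1, sort_keys=True) + "\n"
    )
    (outdir / "summary.json").write_text(
        json.dumps(summary, indent=1, sort_keys=True) + "\n"
    )
    return summary
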