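"""End-to-end orchestration: simulate -> call -> filter -> virtual -> cluster.

`run_pipeline` writes every stage artifact plus a machine-readable run
manifest (parameters, seed, package version, SHA-256 digest of each output)
so a run can be reproduced and verified byte-for-byte.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .cascades import (
    cascade_report,
    filter_robust_induced,
    filter_robust_repressed,
    filter_tissue_induced,
    filter_tissue_repressed,
)
from .clustering import ClusterConfig, MarkerSet, ProfileMatrix, cluster_profiles
from .io import (
    write_comparison_manifest,
    write_comparison_table,
    write_json,
    write_regulation_matrix,
    write_study_matrix,
    write_virt_records,
)
from .regulation import CallConfig, assemble_matrix
from .simulate import (
    StudySimConfig,
    SyntheticConfig,
    generate_comparisons,
    generate_study_matrix,
)
from .virtual import build_virtual_dataset, summarize_dataset

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_pipeline"]


@dataclass
class PipelineConfig:
    out_dir: Path
    seed: int = 0
    synthetic: SyntheticConfig | None = None
    study_sim: StudySimConfig | None = None
    call: CallConfig = field(default_factory=CallConfig)
    cluster: ClusterConfig = field(default_factory=ClusterConfig)
    markers: MarkerSet = field(default_factory=MarkerSet)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the full synthetic pipeline; returns the run manifest."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    syn = config.synthetic or SyntheticConfig(seed=config.seed)
    sim = config.study_sim or StudySimConfig(seed=config.seed)

    roots_tables, seedlings_tables, truth = generate_comparisons(syn)
    truth.to_csv(out / "truth_classes.tsv", sep="\t")
    for tissue, tables in (("roots", roots_tables), ("seedlings", seedlings_tables)):
        write_comparison_manifest([t.comparison for t in tables], out / f"{tissue}_manifest.tsv")
        for table in tables:
            write_comparison_table(table, out / f"{tissue}_{table.comparison.comparison_id}.tsv")

    roots = assemble_matrix(roots_tables, config.call)
    seedlings = assemble_matrix(seedlings_tables, config.call)
    write_regulation_matrix(roots, out / "roots_calls.tsv", out / "roots_mask.tsv")
    write_regulation_matrix(seedlings, out / "seedlings_calls.tsv", out / "seedlings_mask.tsv")

    robust_ind = filter_robust_induced(roots, seedlings)
    robust_rep = filter_robust_repressed(roots, seedlings)
    cascade_results = {
        "robust_induced": robust_ind,
        "robust_repressed": robust_rep,
        "roots_induced": filter_tissue_induced(roots, robust_set=robust_ind.final_set),
        "seedlings_induced": filter_tissue_induced(seedlings, robust_set=robust_ind.final_set),
        "roots_repressed": filter_tissue_repressed(roots, robust_set=robust_rep.final_set),
        "seedlings_repressed": filter_tissue_repressed(seedlings, robust_set=robust_rep.final_set),
    }
    cascade_summary = {}
    for name, result in cascade_results.items():
        report = cascade_report(result)
        pd.Series(sorted(result.final_set), name="gene_id").to_csv(
            out / f"cascade_{name}_genes.tsv", sep="\t", index=False
        )
        cascade_summary[name] = {
            "input_size": report["input_size"],
            "survivor_counts": report["survivor_counts"],
            "attrition": report["attrition"],
            "n_final": len(result.final_set),
            "n_subtracted": len(result.subtracted),
        }
    write_json(cascade_summary, out / "cascade_summary.json")

    study_matrix, study_truth = generate_study_matrix(sim)
    study_truth.to_csv(out / "truth_directions.tsv", sep="\t")
    write_study_matrix(study_matrix, out / "study_matrix.tsv", out / "study_manifest.tsv")
    ranked = build_virtual_dataset(study_matrix)
    write_virt_records(ranked, out / "virtual_dataset.tsv")
    write_json(summarize_dataset(ranked), out / "virtual_summary.json")

    # profile clustering on the concatenated per-tissue log2fc profiles
    profile_cols = {}
    for tissue, tables in (("roots", roots_tables), ("seedlings", seedlings_tables)):
        for table in tables:
            col = table.data.set_index("gene_id")["log2fc"]
            profile_cols[table.comparison.comparison_id] = col
    profiles = ProfileMatrix(pd.DataFrame(profile_cols))
    assignment = cluster_profiles(profiles, config.cluster, seed=config.seed)
    assignment.to_csv(out / "cluster_assignment.tsv", sep="\t")

    artifacts = sorted(p.name for p in out.iterdir() if p.is_file() and p.name != "run_manifest.json")
    manifest = {
        "package_version": __version__,
        "seed": config.seed,
        "parameters": {
            "n_genes": syn.n_genes,
            "effect_log2fc": syn.effect_log2fc,
            "noise_sd": syn.noise_sd,
            "fc_threshold": config.call.fc_threshold,
            "p_threshold": config.call.p_threshold,
            "study_n_genes": sim.n_genes,
            "study_n_studies": sim.n_studies,
            "study_consistency": sim.consistency,
        },
        "outputs": {name: _sha256(out / name) for name in artifacts},
    }
    write_json(manifest, out / "run_manifest.json")
    logger.info("pipeline complete: %d artifacts in %s", len(artifacts), out)
    return manifest
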