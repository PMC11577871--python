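"""End-to-end orchestration: QC -> delineation -> pangenome -> typing -> BGC tests.

``run_pipeline`` either loads the study inputs from files or generates a
synthetic study, then runs every downstream stage and writes a report
bundle (TSV tables, Newick tree, JSON summary, MANIFEST).  Runs are fully
deterministic given the configured seeds; the summary JSON is byte-stable
across reruns of the same configuration.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Any

import numpy as np

from . import __version__
from .delineation import (
    ClusterPartition,
    DelineationConfig,
    cluster_by_threshold,
    consensus_check,
    dedup,
)
from .pangenome import (
    PartitionThresholds,
    accumulation_curves,
    classify_genes,
    core_fraction,
    fit_heaps,
    type_core,
)
from .rmlst import cluster_monophyly, concat_distance, diagnostic_positions, nj_tree
from .stats import bgc_frequency_table
from .synthgen import StudyConfig, SyntheticStudy, generate_study

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline"]


class PipelineError(RuntimeError):
    """A stage-tagged pipeline failure."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class PipelineConfig:
    """Inputs, thresholds and seeds for one pipeline run.

    When ``ani_path`` is None a synthetic study is generated from
    ``study_config``; otherwise the listed files are loaded.
    """

    outdir: str = "panspecies_out"
    ani_path: str | None = None
    dddh_path: str | None = None
    pam_path: str | None = None
    loci_dir: str | None = None
    bgc_path: str | None = None
    study_config: StudyConfig = field(default_factory=StudyConfig)
    delineation: DelineationConfig = field(default_factory=DelineationConfig)
    thresholds: PartitionThresholds = field(default_factory=PartitionThresholds)
    n_permutations: int = 100
    heaps_seed: int = 7
    use_dddh: bool = True


def _config_hash(config: PipelineConfig) -> str:
    d = asdict(config)
    d.pop("outdir", None)  # hash the scientific config, not the run location
    blob = json.dumps(d, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def _load_or_generate(config: PipelineConfig) -> SyntheticStudy | Any:
    from .io import read_count_table, read_matrix_tsv, read_roary_pam
    from .rmlst import MarkerAlignment

    if config.ani_path is None:
        return generate_study(config.study_config)

    class _Loaded:
        pass

    study = _Loaded()
    study.ani = read_matrix_tsv(config.ani_path, measure="ANI")
    if config.use_dddh:
        if config.dddh_path is None:
            raise PipelineError("load", "dDDH checks enabled but no dDDH matrix given")
        study.dddh = read_matrix_tsv(config.dddh_path, measure="dDDH")
    else:
        study.dddh = None
    study.pam_full = read_roary_pam(config.pam_path) if config.pam_path else None
    study.marker_alignments = []
    if config.loci_dir:
        for p in sorted(Path(config.loci_dir).glob("*.fasta")):
            study.marker_alignments.append(MarkerAlignment.from_fasta(p))
    study.bgc_table = read_count_table(config.bgc_path) if config.bgc_path else None
    study.truth = None
    study.genome_ids = study.ani.ids
    return study


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage and write the report bundle; returns the summary dict."""
    from .io import (
        write_labels_tsv,
        write_ledger_tsv,
        write_matrix_tsv,
    )

    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: list[str] = []
    summary: dict = {
        "tool": "panspecies",
        "version": __version__,
        "config_hash": _config_hash(config),
        "seeds": {
            "study": config.study_config.seed,
            "heaps": config.heaps_seed,
        },
    }

    def _stage(name):
        def deco(fn):
            try:
                fn()
                manifest.append(f"{name}\tok")
            except PipelineError:
                manifest.append(f"{name}\tfailed")
                _write_manifest()
                raise
            except Exception as exc:  # tag unexpected failures with the stage
                manifest.append(f"{name}\tfailed")
                _write_manifest()
                raise PipelineError(name, str(exc)) from exc

        return deco

    def _write_manifest():
        with open(out / "MANIFEST", "w") as fh:
            fh.write("\n".join(manifest) + "\n")

    state: dict[str, Any] = {}

    @_stage("load")
    def _load():
        state["study"] = _load_or_generate(config)
        if config.ani_path is None:
            state["study"].write_all(out / "study")

    study = state["study"]

    @_stage("delineation")
    def _delineate():
        p_ani = cluster_by_threshold(
            study.ani, config.delineation.ani_species_threshold
        )
        state["p_ani"] = p_ani
        if study.dddh is not None:
            p_dddh = cluster_by_threshold(
                study.dddh, config.delineation.dddh_species_threshold
            )
            rep = consensus_check(p_ani, p_dddh)
            summary["consensus"] = {
                "ari": rep.ari,
                "discordant": rep.discordant,
            }
        summary["n_clusters"] = p_ani.n_clusters
        summary["cluster_sizes"] = {
            str(c): s for c, s in p_ani.cluster_sizes().items()
        }
        write_labels_tsv(p_ani, out / "clusters.tsv")

    @_stage("dedup")
    def _dedup():
        if study.dddh is None:
            state["kept"] = list(study.ani.ids)
            return
        gene_counts = (
            study.pam_full.genes_per_genome() if study.pam_full is not None else None
        )
        kept, ledger = dedup(
            study.ani,
            study.dddh,
            state["p_ani"],
            config.delineation,
            gene_counts=gene_counts,
        )
        state["kept"] = kept
        write_ledger_tsv(ledger, out / "exclusions.tsv")
        summary["dedup"] = {
            "removed": sorted(ledger.removed_ids()),
            "kept": len(kept),
        }

    @_stage("pangenome")
    def _pangenome():
        if study.pam_full is None:
            return
        kept = state["kept"]
        partition = state["p_ani"].subset(kept)
        state["partition_kept"] = partition
        per_cluster = {}
        heaps_rows = []
        cores = {}
        for c in sorted(set(partition.labels.values())):
            members = partition.members(c)
            pam_c = study.pam_full.subset_genomes(members).drop_absent_genes()
            part = classify_genes(pam_c, config.thresholds)
            cores[c] = part.core_genes
            info = {
                "counts": part.counts,
                "core_fraction": round(core_fraction(part), 1),
            }
            if len(members) >= 2:
                curves = accumulation_curves(
                    pam_c, config.n_permutations, seed=config.heaps_seed + c
                )
                hf = fit_heaps(curves)
                info["heaps"] = {
                    "kappa": hf.kappa,
                    "alpha": hf.alpha,
                    "alpha_sd": hf.alpha_sd,
                    "openness": hf.openness,
                }
                heaps_rows.append((c, hf))
            per_cluster[str(c)] = info
        summary["pangenome"] = per_cluster
        if len(cores) >= 2:
            fam = type_core(cores)
            summary["type_core"] = {
                "common": len(fam.common),
                "type_core_counts": {
                    str(c): len(s) for c, s in fam.type_core.items()
                },
            }
            with open(out / "venn.json", "w") as fh:
                json.dump(fam.venn, fh, indent=2, sort_keys=True)
        with open(out / "heaps.tsv", "w") as fh:
            fh.write("cluster\tkappa\talpha\talpha_sd\topenness\n")
            for c, hf in heaps_rows:
                fh.write(
                    f"{c}\t{hf.kappa:.4f}\t{hf.alpha:.4f}\t{hf.alpha_sd:.4f}"
                    f"\t{hf.openness}\n"
                )

    @_stage("typing")
    def _typing():
        if not study.marker_alignments:
            return
        labels = state["p_ani"]
        reports = {}
        for aln in study.marker_alignments:
            rep = diagnostic_positions(aln, labels)
            reports[aln.name] = {
                "unresolved_pairs": sorted(map(list, rep.unresolved_pairs)),
                "n_diagnostic_columns": len(rep.columns),
            }
        summary["typing"] = {"loci": reports}
        dm = concat_distance(study.marker_alignments)
        tree = nj_tree(dm)
        tree.write(str(out / "rmlst.nwk"))
        mono = cluster_monophyly(tree, labels)
        summary["typing"]["monophyletic"] = {str(c): bool(v) for c, v in mono.items()}

    @_stage("bgc")
    def _bgc():
        if study.bgc_table is None:
            return
        rows = bgc_frequency_table(study.bgc_table, state["p_ani"])
        with open(out / "bgc_tests.tsv", "w") as fh:
            clusters = sorted(set(state["p_ani"].labels.values()))
            head = "\t".join(
                f"c{c}_producers\tc{c}_size\tc{c}_pct" for c in clusters
            )
            fh.write(f"metabolite\t{head}\tp_value\tflag\n")
            for r in rows:
                cells = "\t".join(
                    f"{r.per_cluster[c][0]}\t{r.per_cluster[c][1]}\t{r.per_cluster[c][2]:.2f}"
                    for c in clusters
                )
                flag = "" if r.significant else "ns"
                fh.write(f"{r.metabolite}\t{cells}\t{r.p_value:.6g}\t{flag}\n")
        summary["bgc"] = {
            r.metabolite: {"p": r.p_value, "significant": r.significant}
            for r in rows
        }

    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
    manifest.append("summary\tok")
    _write_manifest()
    return summary
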