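"""End-to-end orchestration: filtered PSMs -> quant matrices -> HPS ->
networks/modules -> operons -> rescued ORFs -> annotation profiles.

Every stage writes a plain-text artifact into the output directory and the
run ends with a manifest JSON recording the seed, per-artifact row counts
and content hashes, so reruns with identical config are byte-stable.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import annotate as annotate_mod
from . import coexpress, hps, operons, orf_rescue, quantify, synthetic_data
from .io_formats import PsmRecord, fdr_filter, qc_filter_samples, write_fasta, write_psm_table

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and offending input."""


@dataclass
class PipelineConfig:
    out_dir: str = "protscape_out"
    seed: int = 0
    synthetic_preset: str | None = "small"
    fdr: float = 0.01
    min_unique_peptides: int = 1000
    sparcc_threshold: float = 0.3
    sparcc_iterations: int = 20
    operon_gap: int = 100
    support_min_samples: int = 2
    support_min_spectra: int = 2
    support_min_fraction: float = 0.5
    novelty_identity: float = 0.70
    coverage: float = 0.80
    module_dominance: float = 0.75
    min_clique: int = 3

    def __post_init__(self) -> None:
        if not 0 < self.fdr < 1:
            raise ValueError("fdr must be in (0,1)")
        if not 0 < self.coverage <= 1:
            raise ValueError("coverage must be in (0,1]")
        if not 0 < self.novelty_identity <= 1:
            raise ValueError("novelty_identity must be in (0,1]")
        if self.operon_gap < 0 or self.min_unique_peptides < 0:
            raise ValueError("thresholds must be non-negative")

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        return cls(**yaml.safe_load(Path(path).read_text()))


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _count_rows(path: Path) -> int:
    try:
        with path.open("rb") as handle:
            return sum(1 for _ in handle)
    except OSError:
        return -1


def run_full_analysis(config: PipelineConfig) -> Path:
    """Run every stage on a synthetic community; returns the artifact dir."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, Path] = {}

    def _stage(name: str):
        logger.info("stage: %s", name)

    # -- synthetic inputs ---------------------------------------------------
    _stage("simulate")
    try:
        if config.synthetic_preset != "small":
            raise PipelineError(f"simulate: unknown synthetic preset {config.synthetic_preset!r}")
        community = synthetic_data.generate_community(synthetic_data.small_config(seed=config.seed))
        simulated = synthetic_data.simulate_psms(community)
        syn_paths = community.write(out / "synthetic")
        syn_paths.update(simulated.write(out / "synthetic"))
        artifacts.update({f"synthetic/{k}": v for k, v in syn_paths.items()})
    except PipelineError:
        raise
    except Exception as exc:  # noqa: BLE001 - stage boundary
        raise PipelineError(f"simulate: {exc}") from exc

    # -- PSM filtering ------------------------------------------------------
    _stage("filter")
    try:
        by_sample: dict[str, list[PsmRecord]] = {}
        for rec in simulated.records:
            by_sample.setdefault(rec.sample_id, []).append(rec)
        kept: list[PsmRecord] = []
        for sample in sorted(by_sample):
            sample_kept, _thr = fdr_filter(by_sample[sample], fdr=config.fdr)
            kept.extend(sample_kept)
        kept_samples = qc_filter_samples(kept, min_unique_peptides=config.min_unique_peptides)
        kept = [r for r in kept if r.sample_id in kept_samples]
        path = out / "filtered_psms.tsv"
        write_psm_table(sorted(kept, key=lambda r: (r.sample_id, r.spectrum_id)), path)
        artifacts["filtered_psms"] = path
        if not kept:
            manifest_path = _write_manifest(out, config, artifacts)
            logger.warning("all samples discarded by QC (min_unique_peptides=%d); stopping after filter",
                           config.min_unique_peptides)
            print(f"protscape: all samples discarded at QC (min_unique_peptides="
                  f"{config.min_unique_peptides}); pipeline stopped after the filter stage")
            return out
    except PipelineError:
        raise
    except Exception as exc:  # noqa: BLE001
        raise PipelineError(f"filter: {exc}") from exc

    # -- quantification -----------------------------------------------------
    _stage("quantify")
    try:
        genome_map = dict(community.protein_genome)
        matrix, dropped = quantify.quantify_genomes(kept, genome_map,
                                                    proteome_size_aa=community.proteome_size_aa)
        normalized = quantify.normalize(matrix)
        quant_dir = out / "quant"
        quant_dir.mkdir(exist_ok=True)
        matrix.to_tsv(quant_dir / "genome_counts_raw.tsv")
        normalized.to_tsv(quant_dir / "genome_counts_normalized.tsv")
        prot_counts = quantify.protein_counts(kept)
        prot_counts.sort_index().to_csv(quant_dir / "protein_counts.tsv", sep="\t", index_label="protein_id")
        artifacts["quant/raw"] = quant_dir / "genome_counts_raw.tsv"
        artifacts["quant/normalized"] = quant_dir / "genome_counts_normalized.tsv"
        artifacts["quant/proteins"] = quant_dir / "protein_counts.tsv"
        logger.info("quantify: %d shared spectra dropped", dropped)
    except Exception as exc:  # noqa: BLE001
        raise PipelineError(f"quantify: {exc}") from exc

    # -- host phenotype specificity ----------------------------------------
    _stage("hps")
    try:
        totals = pd.Series(matrix.total_identified_spectra, dtype=float)
        depth_norm = prot_counts.div(totals[prot_counts.columns], axis=1)
        table = hps.hps_table(depth_norm, simulated.manifest)
        hps_dir = out / "hps"
        hps_dir.mkdir(exist_ok=True)
        table.to_csv(hps_dir / "hps.tsv", sep="\t", index=False, float_format="%.6f")
        summary = hps.genome_hps_summary(table, community.protein_genome)
        summary.to_csv(hps_dir / "genome_summary.tsv", sep="\t", index=False, float_format="%.6f")
        artifacts["hps/table"] = hps_dir / "hps.tsv"
        artifacts["hps/summary"] = hps_dir / "genome_summary.tsv"
    except Exception as exc:  # noqa: BLE001
        raise PipelineError(f"hps: {exc}") from exc

    # -- co-expression networks + modules -----------------------------------
    _stage("network")
    try:
        net_dir = out / "network"
        net_dir.mkdir(exist_ok=True)
        module_tables = []
        for genome in sorted(set(genome_map.values())):
            members = sorted(p for p, g in community.protein_genome.items()
                             if g == genome and p in prot_counts.index)
            if len(members) < 2:
                continue
            expressed_samples = [s for s in prot_counts.columns
                                 if matrix.counts.at[genome, s] > 0]
            if len(expressed_samples) < 3:
                continue
            sub = prot_counts.loc[members, expressed_samples]
            sub = sub[sub.sum(axis=1) > 0]
            if len(sub) < 2:
                continue
            corr = coexpress.sparcc(sub, n_iterations=config.sparcc_iterations)
            network = coexpress.build_network(corr, threshold=config.sparcc_threshold)
            network.to_edge_list(net_dir / f"{genome}_edges.tsv")
            artifacts[f"network/{genome}_edges"] = net_dir / f"{genome}_edges.tsv"
            modules = coexpress.extract_modules(network, min_clique=config.min_clique)
            for module in modules:
                phenotype, fractions = coexpress.assign_module_phenotype(
                    module, sub, simulated.manifest, dominance=config.module_dominance)
                module.phenotype = phenotype
                module.phenotype_fractions = fractions
            mt = coexpress.modules_to_table(modules)
            mt.insert(0, "genome_id", genome)
            module_tables.append(mt)
        all_modules = (pd.concat(module_tables, ignore_index=True) if module_tables
                       else pd.DataFrame(columns=["genome_id", "module_id", "protein_id", "role", "phenotype"]))
        all_modules.to_csv(net_dir / "modules.tsv", sep="\t", index=False)
        artifacts["network/modules"] = net_dir / "modules.tsv"
    except Exception as exc:  # noqa: BLE001
        raise PipelineError(f"network: {exc}") from exc

    # -- operons ------------------------------------------------------------
    _stage("operons")
    try:
        candidates = operons.cluster_genes(community.genes, max_gap=config.operon_gap)
        supported, unsupported = operons.filter_spectral_support(
            candidates, prot_counts,
            min_samples=config.support_min_samples,
            min_spectra=config.support_min_spectra,
            min_fraction=config.support_min_fraction,
        )
        op_dir = out / "operons"
        op_dir.mkdir(exist_ok=True)
        operons.write_operon_csv([*supported, *unsupported], op_dir / "operons.csv")
        artifacts["operons/csv"] = op_dir / "operons.csv"
    except Exception as exc:  # noqa: BLE001
        raise PipelineError(f"operons: {exc}") from exc

    # -- ORF rescue ---------------------------------------------------------
    _stage("rescue")
    try:
        db = orf_rescue.six_frame_translate(community.contigs)
        rescued = orf_rescue.rescue_orfs(simulated.novel_peptides, db)
        contig_genome = {cid: cid.split("_")[0] for cid in community.contigs}
        kept_orfs = []
        for orf in rescued:
            genome = contig_genome[orf.contig_id]
            same_genome_proteins = {p: aa for p, aa in community.proteome.items()
                                    if community.protein_genome[p] == genome}
            if orf_rescue.novelty_filter(orf, same_genome_proteins,
                                         min_identity=config.novelty_identity):
                kept_orfs.append(orf)
        kept_orfs = orf_rescue.classify_all(kept_orfs, community.genes, community.contig_lengths)
        rescue_dir = out / "rescue"
        rescue_dir.mkdir(exist_ok=True)
        orf_rescue.write_rescued_gff3(kept_orfs, rescue_dir / "rescued.gff3",
                                      contig_lengths=community.contig_lengths)
        write_fasta({orf.orf_id.replace("|", "_"): orf.aa_sequence for orf in kept_orfs},
                    rescue_dir / "rescued.fasta")
        artifacts["rescue/gff3"] = rescue_dir / "rescued.gff3"
        artifacts["rescue/fasta"] = rescue_dir / "rescued.fasta"
    except Exception as exc:  # noqa: BLE001
        raise PipelineError(f"rescue: {exc}") from exc

    # -- annotation profiles ------------------------------------------------
    _stage("annotate")
    try:
        rng = np.random.default_rng([config.seed, 99])
        letters = "CEGHIJKLMNOPQTUV"
        hits = []
        for protein in sorted(community.proteome):
            if rng.random() < 0.6:
                hits.append(annotate_mod.CogHit(
                    query=protein,
                    cog_id=f"COG{int(rng.integers(1000, 6000)):04d}",
                    categories=letters[int(rng.integers(len(letters)))],
                    domain_coverage=float(rng.uniform(0.3, 1.0)),
                    e_value=float(10 ** rng.uniform(-10, 0)),
                ))
        assignments = annotate_mod.filter_cog_hits(hits, all_proteins=community.proteome)
        profiles = {}
        for genome in sorted(set(genome_map.values())):
            spectra = {p: float(prot_counts.loc[p].sum())
                       for p in prot_counts.index
                       if community.protein_genome.get(p) == genome}
            if any(v > 0 for v in spectra.values()):
                profiles[genome] = annotate_mod.cog_category_profile(spectra, assignments)
        ann_dir = out / "annotation"
        ann_dir.mkdir(exist_ok=True)
        profile_frame = pd.DataFrame(profiles).fillna(0.0).sort_index()
        profile_frame.to_csv(ann_dir / "cog_profiles.tsv", sep="\t", index_label="category",
                             float_format="%.6f")
        artifacts["annotation/profiles"] = ann_dir / "cog_profiles.tsv"
    except Exception as exc:  # noqa: BLE001
        raise PipelineError(f"annotate: {exc}") from exc

    _write_manifest(out, config, artifacts)
    return out


def _write_manifest(out: Path, config: PipelineConfig, artifacts: dict[str, Path]) -> Path:
    manifest = {
        "seed": config.seed,
        "config": dataclasses.asdict(config),
        "artifacts": {
            name: {"path": str(path.relative_to(out)), "rows": _count_rows(path), "sha256": _sha256(path)}
            for name, path in sorted(artifacts.items())
        },
    }
    path = out / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return path
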