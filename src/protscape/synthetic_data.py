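"""Synthetic microbial communities with complete ground truth.

Generates contigs, gene models, predicted proteomes and per-sample PSM
tables that exercise every downstream stage: multi-genome communities with
shared peptides, phenotype-structured expression, planted operons, planted
hidden ORFs absent from the GFF (on opposite strands, shifted frames or in
intergenic space), co-expressed protein blocks, and two-Gaussian
target/decoy score mixtures.

All randomness flows from a single integer seed; per-stage substreams are
derived with fixed offsets, so identical (config, seed) pairs give
byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
from Bio.Seq import Seq

from .io_formats import (
    GeneModel,
    PsmRecord,
    SampleManifest,
    write_fasta,
    write_gff3,
    write_manifest,
    write_psm_table,
)

logger = logging.getLogger(__name__)

AA_ALPHABET = "ACDEFGHILMNPQSTVWY"  # K/R added separately as cleavage sites
STOP_CODONS = {"TAA", "TAG", "TGA"}
_CODONS_BY_AA: dict[str, list[str]] = {}
for _b1 in "TCAG":
    for _b2 in "TCAG":
        for _b3 in "TCAG":
            _codon = _b1 + _b2 + _b3
            if _codon in STOP_CODONS:
                continue
            _aa = str(Seq(_codon).translate(table=11))
            _CODONS_BY_AA.setdefault(_aa, []).append(_codon)

HIDDEN_CLASSES = ("opposite_strand", "same_strand_diff_frame", "no_overlap")

# RNG substream offsets
_STAGE_LAYOUT = 1
_STAGE_EXPRESSION = 2
_STAGE_PSM = 3
_STAGE_DECOY = 4
_STAGE_HIDDEN = 5


@dataclass
class CommunityConfig:
    n_genomes: int = 3
    contigs_per_genome: int = 2
    genes_per_contig: int = 12
    gene_length_aa: tuple[int, int] = (60, 150)
    n_operons_per_contig: int = 2
    operon_size_range: tuple[int, int] = (3, 5)
    intra_operon_gap: tuple[int, int] = (20, 80)
    inter_run_gap: tuple[int, int] = (150, 300)
    n_hidden_orfs: int = 3
    hidden_orf_classes: tuple[str, ...] = HIDDEN_CLASSES
    hidden_orf_length_aa: tuple[int, int] = (30, 60)
    phenotypes: tuple[str, ...] = ("healthy", "CD", "AL", "UC")
    n_samples_per_phenotype: int = 5
    genome_abundance: tuple[float, ...] | None = None
    abundance_sigma: float = 0.4
    counts_scale: float = 0.05
    nb_dispersion: float = 5.0
    coexpression_block_size: int = 5
    n_coexpression_blocks: int = 1
    block_sigma: float = 1.2
    rho_true: float = 0.8
    n_specific_per_phenotype: int = 2
    specific_boost: float = 3.0
    shared_genes_per_pair: int = 0
    min_peptide_len: int = 7
    max_peptide_len: int = 40
    missed_cleavages: int = 2
    n_decoys_per_sample: int = 50
    target_score: tuple[float, float] = (30.0, 4.0)
    decoy_score: tuple[float, float] = (15.0, 4.0)
    hidden_orf_psms: int = 3
    hidden_orf_evidence_samples: int = 2
    emit_hidden_evidence: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_genomes", "contigs_per_genome", "genes_per_contig", "n_samples_per_phenotype"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0 <= self.rho_true < 1:
            raise ValueError("rho_true must be in [0, 1)")
        unknown = set(self.hidden_orf_classes) - set(HIDDEN_CLASSES)
        if unknown:
            raise ValueError(f"unknown hidden-ORF classes: {sorted(unknown)}")
        if self.genome_abundance is not None and len(self.genome_abundance) != self.n_genomes:
            raise ValueError("genome_abundance length must equal n_genomes")


@dataclass
class HiddenOrf:
    genome_id: str
    contig_id: str
    strand: str
    start: int
    end: int  # includes the stop codon
    aa_sequence: str
    relation: str


@dataclass
class PlantedOperon:
    contig_id: str
    strand: str
    gene_ids: tuple[str, ...]
    start: int
    end: int


@dataclass
class GroundTruth:
    genome_abundance: dict[str, dict[str, float]] = field(default_factory=dict)  # sample -> genome -> value
    operons: list[PlantedOperon] = field(default_factory=list)
    hidden_orfs: list[HiddenOrf] = field(default_factory=list)
    coexpression_blocks: list[tuple[str, ...]] = field(default_factory=list)
    phenotype_specific: dict[str, tuple[str, ...]] = field(default_factory=dict)
    shared_gene_pairs: list[tuple[str, str]] = field(default_factory=list)


@dataclass
class Community:
    config: CommunityConfig
    contigs: dict[str, str]
    genes: list[GeneModel]
    proteome: dict[str, str]
    protein_genome: dict[str, str]
    truth: GroundTruth

    @property
    def contig_lengths(self) -> dict[str, int]:
        return {cid: len(seq) for cid, seq in self.contigs.items()}

    @property
    def proteome_size_aa(self) -> dict[str, int]:
        sizes: dict[str, int] = {}
        for protein, aa in self.proteome.items():
            genome = self.protein_genome[protein]
            sizes[genome] = sizes.get(genome, 0) + len(aa)
        return sizes

    def write(self, outdir: str | Path) -> dict[str, Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "contigs": outdir / "contigs.fasta",
            "genes": outdir / "genes.gff3",
            "proteome": outdir / "proteome.fasta",
            "truth": outdir / "truth.json",
        }
        write_fasta(dict(sorted(self.contigs.items())), paths["contigs"])
        write_gff3(sorted(self.genes, key=lambda g: (g.contig_id, g.start)), paths["genes"],
                   contig_lengths=self.contig_lengths)
        write_fasta(dict(sorted(self.proteome.items())), paths["proteome"])
        paths["truth"].write_text(json.dumps(_truth_to_json(self.truth), indent=2, sort_keys=True) + "\n")
        return paths


def _truth_to_json(truth: GroundTruth) -> dict:
    return {
        "genome_abundance": truth.genome_abundance,
        "operons": [dataclasses.asdict(o) for o in truth.operons],
        "hidden_orfs": [dataclasses.asdict(h) for h in truth.hidden_orfs],
        "coexpression_blocks": [list(b) for b in truth.coexpression_blocks],
        "phenotype_specific": {k: list(v) for k, v in truth.phenotype_specific.items()},
        "shared_gene_pairs": [list(p) for p in truth.shared_gene_pairs],
    }


# ---------------------------------------------------------------------------
# Sequence helpers
# ---------------------------------------------------------------------------

def tryptic_peptides(protein: str, min_len: int = 7, max_len: int = 40, missed_cleavages: int = 2) -> list[str]:
    """Tryptic digestion: cleave after K/R unless followed by P."""
    sites = [i + 1 for i in range(len(protein) - 1) if protein[i] in "KR" and protein[i + 1] != "P"]
    bounds = [0, *sites, len(protein)]
    peptides = []
    for i in range(len(bounds) - 1):
        for j in range(i + 1, min(i + 2 + missed_cleavages, len(bounds))):
            pep = protein[bounds[i]:bounds[j]]
            if min_len <= len(pep) <= max_len:
                peptides.append(pep)
    return peptides


def _random_protein(rng: np.random.Generator, length: int) -> str:
    """Random aa sequence with K/R sprinkled every ~10 residues (leading M)."""
    residues = ["M"]
    for i in range(1, length):
        if i % 10 == 9:
            residues.append(rng.choice(["K", "R"]))
        else:
            residues.append(AA_ALPHABET[rng.integers(len(AA_ALPHABET))])
    return "".join(residues)


def _encode(rng: np.random.Generator, protein: str) -> str:
    """Back-translate with random synonymous codons (leading aa forced ATG)."""
    codons = ["ATG"]
    for aa in protein[1:]:
        options = _CODONS_BY_AA[aa]
        codons.append(options[rng.integers(len(options))])
    return "".join(codons)


def _random_dna(rng: np.random.Generator, length: int) -> str:
    return "".join("ACGT"[i] for i in rng.integers(0, 4, size=length))


def _revcomp(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


def _has_internal_stop(dna: str) -> bool:
    return any(dna[i:i + 3] in STOP_CODONS for i in range(0, len(dna) - 2, 3))


# ---------------------------------------------------------------------------
# Community generation
# ---------------------------------------------------------------------------

def _make_hidden_block(rng: np.random.Generator, config: CommunityConfig) -> tuple[str, str]:
    """DNA block 'TAA' + ATG..body..TAA, and its protein sequence."""
    length = int(rng.integers(config.hidden_orf_length_aa[0], config.hidden_orf_length_aa[1] + 1))
    while True:
        protein = _random_protein(rng, length)
        if tryptic_peptides(protein, config.min_peptide_len, config.max_peptide_len,
                            config.missed_cleavages):
            break
    orf_dna = _encode(rng, protein) + "TAA"
    return "TAA" + orf_dna, protein


def _build_host_with_hidden(
    rng: np.random.Generator,
    config: CommunityConfig,
    relation: str,
) -> tuple[str, str, str, int, int]:
    """A host gene embedding a hidden ORF.

    Returns (host_dna, host_protein, hidden_protein, hidden offset within
    host_dna, hidden span). For ``opposite_strand`` the block is embedded
    reverse-complemented; for ``same_strand_diff_frame`` it is placed one
    base off the host's codon grid. Rejection sampling keeps the host's own
    reading frame stop-free.
    """
    for _ in range(500):
        block, hidden_protein = _make_hidden_block(rng, config)
        orf_len = len(block) - 3  # hidden interval length (incl. its stop)
        if relation == "opposite_strand":
            embed = _revcomp(block)
            # within the embed, the hidden ORF occupies the first orf_len bases
            # (revcomp reverses the upstream-stop + orf layout)
            hidden_rel, pad = 0, 0
        elif relation == "same_strand_diff_frame":
            embed = block + _random_dna(rng, 2)  # +2 restores codon parity after +1 shift
            hidden_rel, pad = 3, 1  # skip the upstream TAA; 1-base frame shift
        else:
            raise ValueError(relation)

        flank1_aa = _random_protein(rng, int(rng.integers(10, 20)))
        flank2_aa = _random_protein(rng, int(rng.integers(10, 20)))
        f1 = _encode(rng, flank1_aa) + _random_dna(rng, pad)
        f2 = _random_dna(rng, (3 - (len(f1) + len(embed)) % 3) % 3) + _encode(rng, flank2_aa)
        body = f1 + embed + f2
        host_dna = body + "TAA"
        if _has_internal_stop(host_dna[:-3]):
            continue
        host_protein = str(Seq(host_dna[:-3]).translate(table=11))
        if "*" in host_protein:
            continue
        hidden_offset = len(f1) + hidden_rel
        if relation == "same_strand_diff_frame":
            # the shifted-frame copy must still read cleanly where it lies
            region = host_dna[hidden_offset:hidden_offset + orf_len]
            if _has_internal_stop(region[:-3]):
                continue
        return host_dna, host_protein, hidden_protein, hidden_offset, orf_len
    raise RuntimeError(f"could not construct hidden-ORF host for class {relation}")


def generate_community(config: CommunityConfig) -> Community:
    """Build contigs, gene models and proteome with planted structures."""
    rng = np.random.default_rng([config.seed, _STAGE_LAYOUT])
    contigs: dict[str, str] = {}
    genes: list[GeneModel] = []
    proteome: dict[str, str] = {}
    protein_genome: dict[str, str] = {}
    truth = GroundTruth()

    # shared-gene planning: consecutive genome pairs (0,1), (2,3), ... with
    # the receiver's first slots on contig 0 re-encoding the donor's protein
    duplicate_plan: dict[tuple[int, int, int], str] = {}  # (genome, contig, slot) -> donor protein id
    if config.shared_genes_per_pair > 0:
        for gi in range(0, config.n_genomes - 1, 2):
            for slot in range(min(config.shared_genes_per_pair, config.genes_per_contig)):
                duplicate_plan[(gi + 1, 0, slot)] = f"g{gi:02d}_c0_p{slot:03d}"

    for gi in range(config.n_genomes):
        genome_id = f"g{gi:02d}"
        hidden_queue = [config.hidden_orf_classes[k % len(config.hidden_orf_classes)]
                        for k in range(config.n_hidden_orfs)]
        for ci in range(config.contigs_per_genome):
            contig_id = f"{genome_id}_c{ci}"
            parts: list[str] = []
            pos = 0
            gene_index = 0

            # plan runs: operons first, then singletons
            sizes: list[int] = []
            remaining = config.genes_per_contig
            for _ in range(config.n_operons_per_contig):
                k = int(rng.integers(config.operon_size_range[0], config.operon_size_range[1] + 1))
                if remaining - k < 0:
                    break
                sizes.append(k)
                remaining -= k
            runs = sizes + [1] * remaining
            order = rng.permutation(len(runs))
            runs = [runs[i] for i in order]

            for run_size in runs:
                gap = int(rng.integers(config.inter_run_gap[0], config.inter_run_gap[1] + 1))
                parts.append(_random_dna(rng, gap))
                pos += gap

                # occasionally drop a hidden intergenic ORF into the gap
                if hidden_queue and hidden_queue[0] == "no_overlap" and rng.random() < 0.6:
                    hidden_queue.pop(0)
                    block, hidden_protein = _make_hidden_block(rng, config)
                    h_strand = "+" if rng.random() < 0.5 else "-"
                    if h_strand == "+":
                        parts.append(block)
                        h_start = pos + 3
                        h_end = pos + len(block)
                    else:
                        parts.append(_revcomp(block))
                        h_start = pos
                        h_end = pos + len(block) - 3
                    truth.hidden_orfs.append(HiddenOrf(
                        genome_id=genome_id, contig_id=contig_id, strand=h_strand,
                        start=h_start, end=h_end, aa_sequence=hidden_protein,
                        relation="no_overlap"))
                    pos += len(block)
                    tail = int(rng.integers(config.inter_run_gap[0], config.inter_run_gap[1] + 1))
                    parts.append(_random_dna(rng, tail))
                    pos += tail

                strand = "+" if rng.random() < 0.5 else "-"
                run_genes: list[GeneModel] = []
                for k in range(run_size):
                    if k > 0:
                        intra = int(rng.integers(config.intra_operon_gap[0], config.intra_operon_gap[1] + 1))
                        parts.append(_random_dna(rng, intra))
                        pos += intra
                    gene_id = f"{contig_id}_p{gene_index:03d}"
                    gene_index += 1

                    donor = duplicate_plan.get((gi, ci, gene_index - 1))
                    overlap_class = None
                    if (donor is None and hidden_queue and hidden_queue[0] in
                            {"opposite_strand", "same_strand_diff_frame"} and rng.random() < 0.5):
                        overlap_class = hidden_queue.pop(0)

                    if donor is not None:
                        protein = proteome[donor]
                        dna = _encode(rng, protein) + "TAA"
                        truth.shared_gene_pairs.append((donor, gene_id))
                    elif overlap_class is not None and strand == "+":
                        dna, protein, hidden_protein, h_off, h_span = _build_host_with_hidden(
                            rng, config, overlap_class)
                        h_strand = "-" if overlap_class == "opposite_strand" else "+"
                        h_start = pos + h_off  # offset is within the host gene DNA
                        truth.hidden_orfs.append(HiddenOrf(
                            genome_id=genome_id, contig_id=contig_id, strand=h_strand,
                            start=h_start, end=h_start + h_span,
                            aa_sequence=hidden_protein, relation=overlap_class))
                    else:
                        if overlap_class is not None:
                            hidden_queue.insert(0, overlap_class)  # retry on a + strand gene
                        length = int(rng.integers(config.gene_length_aa[0], config.gene_length_aa[1] + 1))
                        while True:
                            protein = _random_protein(rng, length)
                            if tryptic_peptides(protein, config.min_peptide_len,
                                                config.max_peptide_len, config.missed_cleavages):
                                break
                        dna = _encode(rng, protein) + "TAA"

                    if strand == "+":
                        parts.append(dna)
                    else:
                        parts.append(_revcomp(dna))
                    gene = GeneModel(gene_id=gene_id, contig_id=contig_id,
                                     start=pos, end=pos + len(dna), strand=strand, source="FGS")
                    pos += len(dna)
                    run_genes.append(gene)
                    genes.append(gene)
                    proteome[gene_id] = protein
                    protein_genome[gene_id] = genome_id

                if run_size >= 2:
                    truth.operons.append(PlantedOperon(
                        contig_id=contig_id, strand=strand,
                        gene_ids=tuple(g.gene_id for g in run_genes),
                        start=min(g.start for g in run_genes),
                        end=max(g.end for g in run_genes)))

            tail = int(rng.integers(config.inter_run_gap[0], config.inter_run_gap[1] + 1))
            parts.append(_random_dna(rng, tail))
            contigs[contig_id] = "".join(parts)

        # any hidden ORFs that never found a host fall back to intergenic space
        for relation in hidden_queue:
            contig_id = f"{genome_id}_c0"
            block, hidden_protein = _make_hidden_block(rng, config)
            base = len(contigs[contig_id])
            contigs[contig_id] += _random_dna(rng, 60) + block + _random_dna(rng, 60)
            h_start = base + 60 + 3
            truth.hidden_orfs.append(HiddenOrf(
                genome_id=genome_id, contig_id=contig_id, strand="+",
                start=h_start, end=h_start + len(block) - 3,
                aa_sequence=hidden_protein, relation="no_overlap"))
            if relation != "no_overlap":
                logger.warning("hidden ORF of class %s placed intergenically (no host slot)", relation)

    # planted co-expression blocks and phenotype-specific sets, per genome
    for gi in range(config.n_genomes):
        genome_id = f"g{gi:02d}"
        members = sorted(p for p, g in protein_genome.items() if g == genome_id)
        cursor = 0
        for _ in range(config.n_coexpression_blocks):
            block = tuple(members[cursor:cursor + config.coexpression_block_size])
            cursor += config.coexpression_block_size
            if len(block) >= 2:
                truth.coexpression_blocks.append(block)
        for phenotype in config.phenotypes:
            chosen = tuple(members[cursor:cursor + config.n_specific_per_phenotype])
            cursor += config.n_specific_per_phenotype
            if chosen:
                existing = truth.phenotype_specific.get(phenotype, ())
                truth.phenotype_specific[phenotype] = existing + chosen

    return Community(config=config, contigs=contigs, genes=genes, proteome=proteome,
                     protein_genome=protein_genome, truth=truth)


# ---------------------------------------------------------------------------
# PSM simulation
# ---------------------------------------------------------------------------

@dataclass
class SimulatedPsms:
    records: list[PsmRecord]
    manifest: SampleManifest
    novel_peptides: dict[str, dict[str, int]]  # peptide -> sample -> PSM count
    counts: dict[str, dict[str, int]]  # protein -> sample -> true spectral count

    def write(self, outdir: str | Path) -> dict[str, Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths: dict[str, Path] = {"manifest": outdir / "manifest.csv",
                                  "novel_peptides": outdir / "novel_peptides.tsv"}
        write_manifest(self.manifest, paths["manifest"])
        psm_dir = outdir / "psms"
        psm_dir.mkdir(exist_ok=True)
        by_sample: dict[str, list[PsmRecord]] = {}
        for rec in self.records:
            by_sample.setdefault(rec.sample_id, []).append(rec)
        for sample in sorted(by_sample):
            path = psm_dir / f"{sample}.tsv"
            write_psm_table(by_sample[sample], path)
            paths[f"psms/{sample}"] = path
        with paths["novel_peptides"].open("w") as handle:
            handle.write("peptide\tsample_id\tpsm_count\n")
            for peptide in sorted(self.novel_peptides):
                for sample in sorted(self.novel_peptides[peptide]):
                    handle.write(f"{peptide}\t{sample}\t{self.novel_peptides[peptide][sample]}\n")
        return paths


def read_novel_peptides(path: str | Path) -> dict[str, dict[str, int]]:
    out: dict[str, dict[str, int]] = {}
    with Path(path).open() as handle:
        header = handle.readline()
        if not header.startswith("peptide"):
            raise ValueError(f"{path}: unexpected novel-peptide header")
        for line in handle:
            peptide, sample, count = line.rstrip("\n").split("\t")
            out.setdefault(peptide, {})[sample] = int(count)
    return out


def _nb_counts(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    """Negative-binomial draws with target means (Poisson when dispersion=inf)."""
    mean = np.asarray(mean, dtype=float)
    out = np.zeros_like(mean, dtype=np.int64)
    positive = mean > 0
    if not positive.any():
        return out
    if np.isinf(dispersion):
        out[positive] = rng.poisson(mean[positive])
        return out
    p = dispersion / (dispersion + mean[positive])
    out[positive] = rng.negative_binomial(dispersion, p)
    return out


def simulate_psms(community: Community) -> SimulatedPsms:
    """Draw per-sample spectral counts and materialize PSM records."""
    config = community.config
    truth = community.truth
    rng_expr = np.random.default_rng([config.seed, _STAGE_EXPRESSION])
    rng_psm = np.random.default_rng([config.seed, _STAGE_PSM])
    rng_decoy = np.random.default_rng([config.seed, _STAGE_DECOY])
    rng_hidden = np.random.default_rng([config.seed, _STAGE_HIDDEN])

    genomes = sorted({g for g in community.protein_genome.values()})
    if config.genome_abundance is not None:
        base_abundance = dict(zip(genomes, config.genome_abundance))
    else:
        base_abundance = {g: float(v) for g, v in
                          zip(genomes, rng_expr.lognormal(0.0, 0.8, size=len(genomes)))}

    samples: list[tuple[str, str]] = []
    for phenotype in config.phenotypes:
        for k in range(config.n_samples_per_phenotype):
            samples.append((f"{phenotype}_s{k:02d}", phenotype))
    manifest = SampleManifest(phenotypes={sid: ph for sid, ph in samples})

    block_of: dict[str, int] = {}
    for b_idx, block in enumerate(truth.coexpression_blocks):
        for protein in block:
            block_of[protein] = b_idx
    specific_of: dict[str, str] = {}
    for phenotype, proteins in truth.phenotype_specific.items():
        for protein in proteins:
            specific_of[protein] = phenotype

    proteins = sorted(community.proteome)
    lengths = np.array([len(community.proteome[p]) for p in proteins], dtype=float)
    peptide_pools = {
        p: tryptic_peptides(community.proteome[p], config.min_peptide_len,
                            config.max_peptide_len, config.missed_cleavages)
        for p in proteins
    }
    # peptide -> accession set over the predicted proteome
    peptide_index: dict[str, set[str]] = {}
    for protein in proteins:
        for pep in set(peptide_pools[protein]):
            peptide_index.setdefault(pep, set()).add(protein)

    sigma_b = config.block_sigma * np.sqrt(config.rho_true)
    sigma_e = config.block_sigma * np.sqrt(1.0 - config.rho_true)

    records: list[PsmRecord] = []
    counts_out: dict[str, dict[str, int]] = {}
    mu_t, sd_t = config.target_score
    mu_d, sd_d = config.decoy_score

    for sample_id, phenotype in samples:
        noise = rng_expr.lognormal(0.0, config.abundance_sigma, size=len(genomes))
        abundance = {g: base_abundance[g] * float(n) for g, n in zip(genomes, noise)}
        truth.genome_abundance[sample_id] = dict(sorted(abundance.items()))

        block_factor = rng_expr.normal(0.0, 1.0, size=max(len(truth.coexpression_blocks), 1))

        means = np.zeros(len(proteins))
        for idx, protein in enumerate(proteins):
            genome = community.protein_genome[protein]
            mean = abundance[genome] * lengths[idx] * config.counts_scale
            target = specific_of.get(protein)
            if target is not None:
                mean = mean * config.specific_boost if target == phenotype else 0.0
            b_idx = block_of.get(protein)
            if b_idx is not None and mean > 0:
                z = sigma_b * block_factor[b_idx] + sigma_e * rng_expr.normal()
                mean *= np.exp(z - config.block_sigma ** 2 / 2.0)
            means[idx] = mean

        counts = _nb_counts(rng_expr, means, config.nb_dispersion)
        spectrum_no = 0
        for idx, protein in enumerate(proteins):
            c = int(counts[idx])
            if c == 0:
                continue
            counts_out.setdefault(protein, {})[sample_id] = c
            pool = peptide_pools[protein]
            choices = rng_psm.integers(0, len(pool), size=c)
            scores = rng_psm.normal(mu_t, sd_t, size=c)
            for pep_i, score in zip(choices, scores):
                peptide = pool[int(pep_i)]
                records.append(PsmRecord(
                    spectrum_id=f"{sample_id}.{spectrum_no:06d}",
                    sample_id=sample_id,
                    peptide=peptide,
                    accessions=frozenset(peptide_index[peptide]),
                    score=float(score),
                    is_decoy=False,
                ))
                spectrum_no += 1

        decoy_scores = rng_decoy.normal(mu_d, sd_d, size=config.n_decoys_per_sample)
        for d_idx, score in enumerate(decoy_scores):
            peptide = _random_protein(rng_decoy, 12)[1:]  # drop forced leading M
            records.append(PsmRecord(
                spectrum_id=f"{sample_id}.decoy{d_idx:04d}",
                sample_id=sample_id,
                peptide=peptide,
                accessions=frozenset({f"XXX_{d_idx:04d}"}),
                score=float(score),
                is_decoy=True,
            ))

    novel: dict[str, dict[str, int]] = {}
    if config.emit_hidden_evidence:
        sample_ids = [sid for sid, _ in samples]
        for orf in truth.hidden_orfs:
            pool = tryptic_peptides(orf.aa_sequence, config.min_peptide_len,
                                    config.max_peptide_len, config.missed_cleavages)
            pool = [p for p in pool if p not in peptide_index] or pool
            peptide = pool[int(rng_hidden.integers(0, len(pool)))]
            picks = rng_hidden.choice(len(sample_ids),
                                      size=min(config.hidden_orf_evidence_samples, len(sample_ids)),
                                      replace=False)
            for s_idx in sorted(int(i) for i in picks):
                novel.setdefault(peptide, {})[sample_ids[s_idx]] = config.hidden_orf_psms

    return SimulatedPsms(records=records, manifest=manifest, novel_peptides=novel,
                         counts=counts_out)


def small_config(seed: int = 0, **overrides) -> CommunityConfig:
    """The 'small' preset: 3 genomes x 20 samples, generated in seconds."""
    defaults = dict(
        n_genomes=3,
        contigs_per_genome=2,
        genes_per_contig=12,
        phenotypes=("healthy", "CD", "AL", "UC"),
        n_samples_per_phenotype=5,
        seed=seed,
    )
    defaults.update(overrides)
    return CommunityConfig(**defaults)
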