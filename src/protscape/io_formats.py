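"""Readers/writers for the formats the pipeline touches, plus PSM- and
sample-level filtering.

Coordinates are 0-based half-open internally; GFF3 I/O converts to and from
the 1-based closed convention of the format.
"""

from __future__ import annotations

import csv
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

DEFAULT_DECOY_PREFIX = "XXX_"


class FormatError(ValueError):
    """Raised when an input file does not conform to its expected layout."""


@dataclass(frozen=True)
class PsmRecord:
    """One peptide-spectrum match.

    ``accessions`` holds every protein (or genome) identifier the peptide
    matched; a record is *unique* when those accessions all live in a single
    genome. ``score`` is oriented so that higher is better.
    """

    spectrum_id: str
    sample_id: str
    peptide: str
    accessions: frozenset[str]
    score: float
    is_decoy: bool = False

    def __post_init__(self) -> None:
        if len(self.peptide) < 6:
            raise ValueError(f"peptide too short (<6 aa): {self.peptide!r}")
        if not self.accessions:
            raise ValueError("PsmRecord requires at least one accession")


@dataclass(frozen=True)
class GeneModel:
    """A predicted protein-coding gene in 0-based half-open coordinates."""

    gene_id: str
    contig_id: str
    start: int
    end: int
    strand: str
    source: str = "other"

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid interval [{self.start},{self.end}) for {self.gene_id}")
        if self.strand not in {"+", "-"}:
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")

    def frame(self, contig_length: int | None = None) -> int:
        """Reading-frame phase in {0,1,2}.

        For minus-strand genes the phase is anchored at the contig 3' end and
        therefore needs the contig length.
        """
        if self.strand == "+":
            return self.start % 3
        if contig_length is None:
            raise ValueError("contig_length required for minus-strand frame")
        return (contig_length - self.end) % 3

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class PsmDialect:
    """Column-name map for PSM TSV tables.

    Defaults match the MSGF+ TSV shape. ``higher_is_better=False`` flips the
    sign of the parsed score so the in-memory convention (higher = better)
    always holds.
    """

    spectrum_id: str = "SpecID"
    sample_id: str = "SampleID"
    peptide: str = "Peptide"
    protein: str = "Protein"
    score: str = "Score"
    accession_sep: str = ";"
    decoy_prefix: str = DEFAULT_DECOY_PREFIX
    higher_is_better: bool = True

    @property
    def required_columns(self) -> tuple[str, ...]:
        return (self.spectrum_id, self.sample_id, self.peptide, self.protein, self.score)


def read_psm_table(path: str | Path, dialect: PsmDialect | None = None) -> list[PsmRecord]:
    """Parse a PSM TSV into :class:`PsmRecord` objects.

    Malformed rows (empty accession field, short peptide, unparsable score)
    are skipped with a warning that carries the 1-based line number.
    """
    dialect = dialect or PsmDialect()
    path = Path(path)
    records: list[PsmRecord] = []
    with path.open(newline="") as handle:
        reader = csv.DictReader(handle, delimiter="\t")
        if reader.fieldnames is None:
            logger.warning("empty PSM table: %s", path)
            return records
        missing = [c for c in dialect.required_columns if c not in reader.fieldnames]
        if missing:
            raise FormatError(f"{path}: missing required column(s): {', '.join(missing)}")
        for lineno, row in enumerate(reader, start=2):
            raw_acc = (row[dialect.protein] or "").strip()
            accessions = frozenset(a for a in raw_acc.split(dialect.accession_sep) if a)
            if not accessions:
                logger.warning("%s line %d: empty accession field, row skipped", path, lineno)
                continue
            try:
                score = float(row[dialect.score])
            except (TypeError, ValueError):
                logger.warning("%s line %d: unparsable score, row skipped", path, lineno)
                continue
            if not dialect.higher_is_better:
                score = -score
            peptide = row[dialect.peptide].strip().upper()
            if len(peptide) < 6:
                logger.warning("%s line %d: peptide shorter than 6 aa, row skipped", path, lineno)
                continue
            is_decoy = all(a.startswith(dialect.decoy_prefix) for a in accessions)
            records.append(
                PsmRecord(
                    spectrum_id=row[dialect.spectrum_id],
                    sample_id=row[dialect.sample_id],
                    peptide=peptide,
                    accessions=accessions,
                    score=score,
                    is_decoy=is_decoy,
                )
            )
    return records


def write_psm_table(records: Iterable[PsmRecord], path: str | Path, dialect: PsmDialect | None = None) -> None:
    dialect = dialect or PsmDialect()
    path = Path(path)
    with path.open("w", newline="") as handle:
        writer = csv.writer(handle, delimiter="\t", lineterminator="\n")
        writer.writerow(dialect.required_columns)
        for rec in records:
            score = rec.score if dialect.higher_is_better else -rec.score
            writer.writerow(
                [
                    rec.spectrum_id,
                    rec.sample_id,
                    rec.peptide,
                    dialect.accession_sep.join(sorted(rec.accessions)),
                    repr(score),
                ]
            )


# ---------------------------------------------------------------------------
# PSM-level and sample-level filters
# ---------------------------------------------------------------------------

def fdr_filter(
    records: Sequence[PsmRecord],
    fdr: float = 0.01,
    level: str = "psm",
) -> tuple[list[PsmRecord], float]:
    """Target-decoy FDR filtering.

    Finds the lowest score threshold ``t`` such that
    ``#decoys(score >= t) / #targets(score >= t) <= fdr`` and returns the
    target records at or above it (decoys are never returned). ``level`` may
    be ``"psm"`` (default) or ``"peptide"``: at peptide level each distinct
    peptide is represented by its best-scoring record when estimating the
    threshold, and every record of a passing peptide is kept.
    """
    if not 0 < fdr < 1:
        raise ValueError(f"fdr must be in (0,1), got {fdr}")
    if level not in {"psm", "peptide"}:
        raise ValueError(f"level must be 'psm' or 'peptide', got {level!r}")

    if level == "peptide":
        best: dict[tuple[str, bool], PsmRecord] = {}
        for rec in records:
            key = (rec.peptide, rec.is_decoy)
            cur = best.get(key)
            if cur is None or rec.score > cur.score:
                best[key] = rec
        pool: Sequence[PsmRecord] = list(best.values())
    else:
        pool = records

    targets = sorted((r.score for r in pool if not r.is_decoy), reverse=True)
    decoys = sorted((r.score for r in pool if r.is_decoy), reverse=True)
    if not targets:
        logger.warning("fdr_filter: no target records")
        return [], math.inf

    # Scan candidate thresholds (distinct scores, descending) and keep the
    # lowest threshold whose decoy/target ratio is still <= fdr.
    import bisect

    neg_targets = [-s for s in targets]  # ascending
    neg_decoys = [-s for s in decoys]
    threshold = math.inf
    for t in sorted({r.score for r in pool}, reverse=True):
        n_t = bisect.bisect_right(neg_targets, -t)
        n_d = bisect.bisect_right(neg_decoys, -t)
        if n_t > 0 and n_d / n_t <= fdr:
            threshold = t
    if math.isinf(threshold):
        logger.warning("fdr_filter: FDR %.3g unattainable, returning empty set", fdr)
        return [], math.inf

    if level == "peptide":
        passing = {r.peptide for r in pool if not r.is_decoy and r.score >= threshold}
        kept = [r for r in records if not r.is_decoy and r.peptide in passing]
    else:
        kept = [r for r in records if not r.is_decoy and r.score >= threshold]
    return kept, threshold


def qc_filter_samples(
    records: Sequence[PsmRecord],
    min_unique_peptides: int = 1000,
) -> set[str]:
    """Sample QC: keep samples with >= ``min_unique_peptides`` distinct peptides."""
    peptides: dict[str, set[str]] = {}
    for rec in records:
        peptides.setdefault(rec.sample_id, set()).add(rec.peptide)
    return {s for s, peps in peptides.items() if len(peps) >= min_unique_peptides}


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(sequences: Mapping[str, str], path: str | Path) -> None:
    records = [SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences.items()]
    SeqIO.write(records, str(path), "fasta")


# ---------------------------------------------------------------------------
# GFF3
# ---------------------------------------------------------------------------

def read_gff3(path: str | Path) -> tuple[list[GeneModel], dict[str, int]]:
    """Read CDS features from a GFF3 file.

    Returns the gene models (0-based half-open) and the contig lengths found
    in ``##sequence-region`` directives.
    """
    genes: list[GeneModel] = []
    contig_lengths: dict[str, int] = {}
    with Path(path).open() as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("##sequence-region"):
                parts = line.split()
                if len(parts) >= 4:
                    contig_lengths[parts[1]] = int(parts[3])
                continue
            if line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise FormatError(f"{path} line {lineno}: expected 9 GFF columns, got {len(fields)}")
            contig, source, ftype, start1, end1, _score, strand, _phase, attrs = fields
            if ftype not in {"CDS", "gene"}:
                continue
            attributes = dict(
                kv.split("=", 1) for kv in attrs.split(";") if "=" in kv
            )
            gene_id = attributes.get("ID") or attributes.get("Name")
            if gene_id is None:
                raise FormatError(f"{path} line {lineno}: feature without ID attribute")
            genes.append(
                GeneModel(
                    gene_id=gene_id,
                    contig_id=contig,
                    start=int(start1) - 1,
                    end=int(end1),
                    strand=strand,
                    source=source,
                )
            )
    return genes, contig_lengths


def write_gff3(
    genes: Iterable[GeneModel],
    path: str | Path,
    contig_lengths: Mapping[str, int] | None = None,
    extra_attributes: Mapping[str, Mapping[str, str]] | None = None,
) -> None:
    """Write gene models as GFF3 CDS features (1-based closed on disk)."""
    extra_attributes = extra_attributes or {}
    with Path(path).open("w") as handle:
        handle.write("##gff-version 3\n")
        if contig_lengths:
            for contig in sorted(contig_lengths):
                handle.write(f"##sequence-region {contig} 1 {contig_lengths[contig]}\n")
        for gene in genes:
            attrs = {"ID": gene.gene_id}
            attrs.update(extra_attributes.get(gene.gene_id, {}))
            attr_str = ";".join(f"{k}={v}" for k, v in attrs.items())
            handle.write(
                "\t".join(
                    [
                        gene.contig_id,
                        gene.source,
                        "CDS",
                        str(gene.start + 1),
                        str(gene.end),
                        ".",
                        gene.strand,
                        "0",
                        attr_str,
                    ]
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# Sample manifest
# ---------------------------------------------------------------------------

@dataclass
class SampleManifest:
    """sample_id -> phenotype, with optional fraction->sample merging."""

    phenotypes: dict[str, str] = field(default_factory=dict)
    fraction_of: dict[str, str] = field(default_factory=dict)

    def phenotype_of(self, sample_id: str) -> str:
        sample_id = self.resolve(sample_id)
        try:
            return self.phenotypes[sample_id]
        except KeyError:
            raise KeyError(f"sample {sample_id!r} not present in manifest") from None

    def resolve(self, sample_id: str) -> str:
        """Map a fraction id to its parent sample (identity otherwise)."""
        return self.fraction_of.get(sample_id, sample_id)

    @property
    def samples(self) -> list[str]:
        return sorted(self.phenotypes)

    @property
    def vocabulary(self) -> list[str]:
        return sorted(set(self.phenotypes.values()))

    def validate_samples(self, sample_ids: Iterable[str]) -> None:
        missing = sorted({self.resolve(s) for s in sample_ids} - set(self.phenotypes))
        if missing:
            raise FormatError(f"samples absent from manifest: {', '.join(missing)}")


def read_manifest(path: str | Path) -> SampleManifest:
    manifest = SampleManifest()
    with Path(path).open(newline="") as handle:
        reader = csv.DictReader(handle)
        if reader.fieldnames is None or "sample_id" not in reader.fieldnames or "phenotype" not in reader.fieldnames:
            raise FormatError(f"{path}: manifest needs columns sample_id,phenotype")
        for row in reader:
            sid = row["sample_id"].strip()
            parent = (row.get("fraction_of") or "").strip()
            if parent:
                manifest.fraction_of[sid] = parent
            else:
                manifest.phenotypes[sid] = row["phenotype"].strip()
    return manifest


def write_manifest(manifest: SampleManifest, path: str | Path) -> None:
    with Path(path).open("w", newline="") as handle:
        writer = csv.writer(handle, lineterminator="\n")
        writer.writerow(["sample_id", "phenotype", "fraction_of"])
        for sid in sorted(manifest.phenotypes):
            writer.writerow([sid, manifest.phenotypes[sid], ""])
        for frac in sorted(manifest.fraction_of):
            writer.writerow([frac, "", manifest.fraction_of[frac]])


# ---------------------------------------------------------------------------
# Function-annotation hit tables
# ---------------------------------------------------------------------------

def read_hit_table(path: str | Path) -> "pd.DataFrame":
    """Read a DIAMOND/BLAST-like hit table with a domain-length column.

    Expected tab-separated columns: query, subject_id, categories, align_len,
    domain_len, evalue. ``domain_coverage`` is derived as align_len/domain_len.
    """
    import pandas as pd

    df = pd.read_csv(path, sep="\t", dtype={"query": str, "subject_id": str, "categories": str})
    required = {"query", "subject_id", "align_len", "domain_len", "evalue"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing hit-table column(s): {', '.join(sorted(missing))}")
    df["domain_coverage"] = df["align_len"] / df["domain_len"]
    return df
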