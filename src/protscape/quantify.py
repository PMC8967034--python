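"""Spectral-count quantification of genomes.

Identified spectra are assigned to genomes in two passes: spectra whose
peptides are unique to one genome are counted directly, then multi-genome
spectra are fractionally allocated in proportion to each sharer's unique
count in the same sample. Sharers with zero unique spectra receive nothing;
if no sharer has unique support the spectrum is dropped and tallied.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .io_formats import PsmRecord

logger = logging.getLogger(__name__)


@dataclass
class SpectralCountMatrix:
    """Genomes (or proteins) x samples count matrix with quant metadata."""

    counts: pd.DataFrame
    proteome_size_aa: dict[str, int] = field(default_factory=dict)
    total_identified_spectra: dict[str, int] = field(default_factory=dict)
    normalized: bool = False

    def __post_init__(self) -> None:
        if (self.counts.values < 0).any():
            raise ValueError("spectral counts must be non-negative")

    def to_tsv(self, path: str | Path) -> None:
        self.counts.sort_index(axis=0).sort_index(axis=1).to_csv(path, sep="\t", index_label="id")
        sidecar = {
            "normalized": self.normalized,
            "proteome_size_aa": dict(sorted(self.proteome_size_aa.items())),
            "total_identified_spectra": dict(sorted(self.total_identified_spectra.items())),
        }
        Path(str(path) + ".meta.json").write_text(json.dumps(sidecar, indent=2, sort_keys=True) + "\n")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "SpectralCountMatrix":
        counts = pd.read_csv(path, sep="\t", index_col="id")
        counts.index.name = None
        counts.columns.name = None
        meta_path = Path(str(path) + ".meta.json")
        meta = json.loads(meta_path.read_text()) if meta_path.exists() else {}
        return cls(
            counts=counts,
            proteome_size_aa=meta.get("proteome_size_aa", {}),
            total_identified_spectra=meta.get("total_identified_spectra", {}),
            normalized=meta.get("normalized", False),
        )


@dataclass
class SharedSpectrum:
    sample_id: str
    genomes: frozenset[str]


def assign_unique(
    records: Sequence[PsmRecord],
    genome_map: Mapping[str, str],
) -> tuple[dict[tuple[str, str], float], list[SharedSpectrum]]:
    """First-pass assignment of uniquely mapping spectra.

    Returns ``{(genome, sample): unique count}`` and the pool of multi-genome
    spectra left for :func:`allocate_shared`. Accessions missing from
    ``genome_map`` raise with the full orphan list.
    """
    orphans = sorted({a for r in records for a in r.accessions if a not in genome_map})
    if orphans:
        raise KeyError(f"accessions absent from genome map: {', '.join(orphans[:20])}"
                       + (f" (+{len(orphans) - 20} more)" if len(orphans) > 20 else ""))
    unique: dict[tuple[str, str], float] = {}
    shared: list[SharedSpectrum] = []
    for rec in records:
        genomes = frozenset(genome_map[a] for a in rec.accessions)
        if len(genomes) == 1:
            key = (next(iter(genomes)), rec.sample_id)
            unique[key] = unique.get(key, 0.0) + 1.0
        else:
            shared.append(SharedSpectrum(sample_id=rec.sample_id, genomes=genomes))
    return unique, shared


def allocate_shared(
    shared: Iterable[SharedSpectrum],
    unique: Mapping[tuple[str, str], float],
) -> tuple[dict[tuple[str, str], float], int]:
    """Weighted allocation of multi-mapped spectra.

    Each shared spectrum is split over its genomes in proportion to their
    unique counts in the same sample. Returns the fractional allocations and
    the number of dropped spectra (all sharers at zero unique support).
    """
    allocated: dict[tuple[str, str], float] = {}
    dropped = 0
    for spectrum in shared:
        weights = {g: unique.get((g, spectrum.sample_id), 0.0) for g in spectrum.genomes}
        total = sum(weights.values())
        if total == 0:
            dropped += 1
            continue
        for g, w in weights.items():
            if w > 0:
                key = (g, spectrum.sample_id)
                allocated[key] = allocated.get(key, 0.0) + w / total
    return allocated, dropped


def quantify_genomes(
    records: Sequence[PsmRecord],
    genome_map: Mapping[str, str],
    proteome_size_aa: Mapping[str, int] | None = None,
) -> tuple[SpectralCountMatrix, int]:
    """Full genome quantification: unique assignment + shared allocation.

    Returns the raw count matrix and the number of dropped shared spectra.
    ``total_identified_spectra`` is the per-sample count of all input records.
    """
    unique, shared = assign_unique(records, genome_map)
    allocated, dropped = allocate_shared(shared, unique)

    totals: dict[str, int] = {}
    for rec in records:
        totals[rec.sample_id] = totals.get(rec.sample_id, 0) + 1

    combined: dict[tuple[str, str], float] = dict(unique)
    for key, value in allocated.items():
        combined[key] = combined.get(key, 0.0) + value

    genomes = sorted(set(genome_map.values()))
    samples = sorted(totals)
    counts = pd.DataFrame(0.0, index=genomes, columns=samples)
    for (g, s), v in combined.items():
        counts.at[g, s] = v
    matrix = SpectralCountMatrix(
        counts=counts,
        proteome_size_aa=dict(proteome_size_aa or {}),
        total_identified_spectra=totals,
    )
    return matrix, dropped


def normalize(matrix: SpectralCountMatrix) -> SpectralCountMatrix:
    """Depth- and proteome-size-normalized counts.

    value' = (value / proteome_size_aa * 1e6) / total_identified_spectra.
    """
    if matrix.normalized:
        raise ValueError("matrix is already normalized")
    missing = [g for g in matrix.counts.index if g not in matrix.proteome_size_aa]
    if missing:
        raise ValueError(f"missing proteome sizes for: {', '.join(missing[:10])}")
    zero = [g for g in matrix.counts.index if matrix.proteome_size_aa[g] == 0]
    if zero:
        raise ValueError(f"proteome size 0 for: {', '.join(zero[:10])}")
    missing_totals = [s for s in matrix.counts.columns if s not in matrix.total_identified_spectra]
    if missing_totals:
        raise ValueError(f"missing per-sample spectra totals for: {', '.join(missing_totals[:10])}")

    sizes = pd.Series({g: float(matrix.proteome_size_aa[g]) for g in matrix.counts.index})
    totals = pd.Series({s: float(matrix.total_identified_spectra[s]) for s in matrix.counts.columns})
    values = matrix.counts.div(sizes, axis=0).mul(1e6).div(totals, axis=1)
    return SpectralCountMatrix(
        counts=values,
        proteome_size_aa=dict(matrix.proteome_size_aa),
        total_identified_spectra=dict(matrix.total_identified_spectra),
        normalized=True,
    )


def protein_counts(records: Sequence[PsmRecord]) -> pd.DataFrame:
    """Protein x sample spectral counts.

    Spectra matching several proteins are split equally among them, keeping
    per-sample column sums equal to the number of spectra.
    """
    counts: dict[tuple[str, str], float] = {}
    samples: set[str] = set()
    for rec in records:
        samples.add(rec.sample_id)
        share = 1.0 / len(rec.accessions)
        for acc in rec.accessions:
            key = (acc, rec.sample_id)
            counts[key] = counts.get(key, 0.0) + share
    proteins = sorted({p for p, _ in counts})
    frame = pd.DataFrame(0.0, index=proteins, columns=sorted(samples))
    for (p, s), v in counts.items():
        frame.at[p, s] = v
    return frame
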