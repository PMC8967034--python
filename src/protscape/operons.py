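"""Operon candidate inference from gene adjacency and spectral support.

Candidates are maximal runs of same-contig, same-strand genes whose
consecutive intergenic gaps stay within a base-pair threshold; runs of one
gene are not operons. Spectral support partitions candidates by a
half-the-members rule on per-gene sample evidence.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .io_formats import GeneModel

logger = logging.getLogger(__name__)

DEFAULT_MAX_GAP = 100


@dataclass
class OperonCandidate:
    contig_id: str
    strand: str
    gene_ids: tuple[str, ...]
    start: int
    end: int
    supported: bool | None = None
    evidenced_members: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if len(self.gene_ids) < 2:
            raise ValueError("an operon candidate needs >= 2 member genes")

    @property
    def span(self) -> int:
        return self.end - self.start

    @property
    def size(self) -> int:
        return len(self.gene_ids)


def cluster_genes(genes: Sequence[GeneModel], max_gap: int = DEFAULT_MAX_GAP) -> list[OperonCandidate]:
    """Cluster same-contig/strand genes with intergenic gaps <= ``max_gap``.

    Overlapping same-strand genes are treated as gap 0 (with a warning).
    Single-gene runs are discarded.
    """
    candidates: list[OperonCandidate] = []
    by_group: dict[tuple[str, str], list[GeneModel]] = {}
    for gene in genes:
        by_group.setdefault((gene.contig_id, gene.strand), []).append(gene)

    for (contig, strand) in sorted(by_group):
        ordered = sorted(by_group[(contig, strand)], key=lambda g: (g.start, g.end))
        run: list[GeneModel] = [ordered[0]]
        for gene in ordered[1:]:
            gap = gene.start - run[-1].end
            if gap < 0:
                logger.warning(
                    "overlapping same-strand genes %s/%s on %s; gap treated as 0",
                    run[-1].gene_id, gene.gene_id, contig,
                )
                gap = 0
            if gap <= max_gap:
                run.append(gene)
            else:
                if len(run) >= 2:
                    candidates.append(_candidate_from_run(contig, strand, run))
                run = [gene]
        if len(run) >= 2:
            candidates.append(_candidate_from_run(contig, strand, run))
    return candidates


def _candidate_from_run(contig: str, strand: str, run: list[GeneModel]) -> OperonCandidate:
    return OperonCandidate(
        contig_id=contig,
        strand=strand,
        gene_ids=tuple(g.gene_id for g in run),
        start=min(g.start for g in run),
        end=max(g.end for g in run),
    )


def filter_spectral_support(
    candidates: Iterable[OperonCandidate],
    counts: pd.DataFrame,
    min_samples: int = 2,
    min_spectra: int = 2,
    min_fraction: float = 0.5,
) -> tuple[list[OperonCandidate], list[OperonCandidate]]:
    """Partition candidates into (supported, unsupported).

    A member gene is *evidenced* when it has >= ``min_spectra`` spectra in
    each of >= ``min_samples`` samples; a candidate is supported when the
    evidenced fraction of its members reaches ``min_fraction``.
    """
    supported: list[OperonCandidate] = []
    unsupported: list[OperonCandidate] = []
    for cand in candidates:
        evidenced = []
        for gene_id in cand.gene_ids:
            if gene_id in counts.index:
                n_samples = int((counts.loc[gene_id] >= min_spectra).sum())
            else:
                n_samples = 0
            if n_samples >= min_samples:
                evidenced.append(gene_id)
        flag = len(evidenced) / cand.size >= min_fraction
        labeled = OperonCandidate(
            contig_id=cand.contig_id,
            strand=cand.strand,
            gene_ids=cand.gene_ids,
            start=cand.start,
            end=cand.end,
            supported=flag,
            evidenced_members=tuple(evidenced),
        )
        (supported if flag else unsupported).append(labeled)
    return supported, unsupported


# ---------------------------------------------------------------------------
# Comparison against external operon predictions
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class OperonInterval:
    contig_id: str
    start: int
    end: int

    @property
    def span(self) -> int:
        return self.end - self.start


def _overlap_length(a: OperonInterval, b: OperonInterval) -> int:
    if a.contig_id != b.contig_id:
        return 0
    return max(0, min(a.end, b.end) - max(a.start, b.start))


def _matches(a: OperonInterval, b: OperonInterval, criterion: str) -> bool:
    ov = _overlap_length(a, b)
    if ov == 0:
        return False
    smaller = min(a.span, b.span)
    if criterion == "region70":
        return ov / smaller > 0.70
    if criterion == "half_smaller":
        return ov >= 0.5 * smaller
    raise ValueError(f"unknown overlap criterion: {criterion!r}")


def operon_overlap(
    list_a: Sequence[OperonInterval | OperonCandidate],
    list_b: Sequence[OperonInterval | OperonCandidate],
    criterion: str = "region70",
) -> tuple[list[tuple[int, int]], float]:
    """Greedy 1:1 matching of two operon lists.

    Pairs are formed by descending overlap length (ties: leftmost interval of
    list_a, then of list_b); each operon participates in at most one pair.
    Returns the matched index pairs and the fraction of list_a matched.
    """
    a_iv = [OperonInterval(x.contig_id, x.start, x.end) for x in list_a]
    b_iv = [OperonInterval(x.contig_id, x.start, x.end) for x in list_b]
    scored = []
    for i, a in enumerate(a_iv):
        for j, b in enumerate(b_iv):
            if _matches(a, b, criterion):
                scored.append((-_overlap_length(a, b), a.start, b.start, i, j))
    scored.sort()
    used_a: set[int] = set()
    used_b: set[int] = set()
    pairs: list[tuple[int, int]] = []
    for _neg_ov, _sa, _sb, i, j in scored:
        if i in used_a or j in used_b:
            continue
        pairs.append((i, j))
        used_a.add(i)
        used_b.add(j)
    agreement = len(pairs) / len(a_iv) if a_iv else 0.0
    return sorted(pairs), agreement


# ---------------------------------------------------------------------------
# CSV I/O
# ---------------------------------------------------------------------------

def write_operon_csv(candidates: Iterable[OperonCandidate], path: str | Path) -> None:
    with Path(path).open("w", newline="") as handle:
        writer = csv.writer(handle, lineterminator="\n")
        writer.writerow(["contig", "strand", "start", "end", "gene_ids", "supported", "evidenced_members"])
        for cand in candidates:
            writer.writerow(
                [
                    cand.contig_id,
                    cand.strand,
                    cand.start,
                    cand.end,
                    "|".join(cand.gene_ids),
                    "" if cand.supported is None else str(cand.supported).lower(),
                    "|".join(cand.evidenced_members),
                ]
            )


def read_operon_csv(path: str | Path) -> list[OperonCandidate]:
    out: list[OperonCandidate] = []
    with Path(path).open(newline="") as handle:
        for row in csv.DictReader(handle):
            supported = {"true": True, "false": False, "": None}[row.get("supported", "")]
            out.append(
                OperonCandidate(
                    contig_id=row["contig"],
                    strand=row["strand"],
                    gene_ids=tuple(row["gene_ids"].split("|")),
                    start=int(row["start"]),
                    end=int(row["end"]),
                    supported=supported,
                    evidenced_members=tuple(x for x in row.get("evidenced_members", "").split("|") if x),
                )
            )
    return out


def read_external_operons(path: str | Path) -> list[OperonInterval]:
    """Ingest an external operon list (e.g. fgenesB-style CSV) with
    contig,start,end columns."""
    out: list[OperonInterval] = []
    with Path(path).open(newline="") as handle:
        for row in csv.DictReader(handle):
            out.append(OperonInterval(row["contig"], int(row["start"]), int(row["end"])))
    return out
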