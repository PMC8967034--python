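"""Recovery of protein-coding ORFs missed by gene predictors.

A six-frame translation of each contig serves as the search space: novel
peptides (identified spectra whose peptides are absent from the predicted
proteome) are located in the frame translations, the surrounding
stop-bounded ORF is extracted and mapped back to genomic coordinates,
candidates re-discovering predicted proteins are filtered out by local
alignment, and the survivors are classified by their positional relation to
the predicted gene models.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

from Bio import Align
from Bio.Align import substitution_matrices
from Bio.Seq import Seq

from .io_formats import GeneModel, write_gff3

logger = logging.getLogger(__name__)

START_CODONS = ("ATG", "GTG", "TTG")
FRAMES = (1, 2, 3, -1, -2, -3)


def _translate(dna: str) -> str:
    """Bacterial-code translation; stops rendered '*', N-codons 'X'."""
    trimmed = dna[: len(dna) - len(dna) % 3]
    if not trimmed:
        return ""
    return str(Seq(trimmed).translate(table=11))


@dataclass
class SixFrameDb:
    """Per-contig six-frame translations with exact coordinate maps."""

    contigs: dict[str, str]
    frames: dict[tuple[str, int], str] = field(init=False)

    def __post_init__(self) -> None:
        self.frames = {}
        for contig_id, seq in self.contigs.items():
            seq = seq.upper()
            rc = str(Seq(seq).reverse_complement())
            for k in (1, 2, 3):
                self.frames[(contig_id, k)] = _translate(seq[k - 1 :])
                self.frames[(contig_id, -k)] = _translate(rc[k - 1 :])

    def contig_length(self, contig_id: str) -> int:
        return len(self.contigs[contig_id])

    def codon(self, contig_id: str, frame: int, aa_index: int) -> str:
        """The DNA codon (in reading orientation) behind one aa position."""
        offset = abs(frame) - 1
        if frame > 0:
            seq = self.contigs[contig_id].upper()
        else:
            seq = str(Seq(self.contigs[contig_id].upper()).reverse_complement())
        return seq[offset + 3 * aa_index : offset + 3 * aa_index + 3]

    def genomic_interval(self, contig_id: str, frame: int, aa_start: int, aa_end: int) -> tuple[int, int]:
        """Map an aa slice [aa_start, aa_end) of a frame to genomic coords."""
        offset = abs(frame) - 1
        length = self.contig_length(contig_id)
        if frame > 0:
            return offset + 3 * aa_start, offset + 3 * aa_end
        return length - offset - 3 * aa_end, length - offset - 3 * aa_start


@dataclass
class RescuedOrf:
    contig_id: str
    strand: str
    frame: int
    start: int
    end: int
    aa_sequence: str
    peptides: dict[str, int] = field(default_factory=dict)
    start_missing: bool = False
    relation: str | None = None
    cluster_id: str | None = None
    annotation: str | None = None

    def __post_init__(self) -> None:
        if "*" in self.aa_sequence:
            raise ValueError("rescued ORF contains an internal stop")
        if (self.end - self.start) % 3 != 0:
            raise ValueError("rescued ORF interval length not divisible by 3")
        for peptide in self.peptides:
            if peptide not in self.aa_sequence:
                raise ValueError(f"supporting peptide {peptide!r} not in ORF sequence")

    @property
    def psm_count(self) -> int:
        return sum(self.peptides.values())

    @property
    def orf_id(self) -> str:
        return f"{self.contig_id}|{self.frame:+d}|{self.start}-{self.end}"


# ---------------------------------------------------------------------------
# Top-genome selection
# ---------------------------------------------------------------------------

def select_top_genomes(totals: Mapping[str, float], coverage: float = 0.80) -> list[str]:
    """Smallest descending-count prefix of genomes reaching ``coverage``."""
    if not 0 < coverage <= 1:
        raise ValueError("coverage must be in (0, 1]")
    positive = [(g, c) for g, c in totals.items() if c > 0]
    if not positive:
        return []
    grand = sum(c for _, c in positive)
    ordered = sorted(positive, key=lambda gc: (-gc[1], gc[0]))
    selected: list[str] = []
    cumulative = 0.0
    for genome, count in ordered:
        selected.append(genome)
        cumulative += count
        if cumulative / grand >= coverage:
            break
    return selected


# ---------------------------------------------------------------------------
# ORF extraction
# ---------------------------------------------------------------------------

def six_frame_translate(contigs: Mapping[str, str]) -> SixFrameDb:
    return SixFrameDb(contigs=dict(contigs))


def _segment_bounds(frame_aa: str, position: int) -> tuple[int, int]:
    """Stop-bounded segment [start, end) containing aa ``position``."""
    seg_start = frame_aa.rfind("*", 0, position) + 1
    nxt = frame_aa.find("*", position)
    seg_end = len(frame_aa) if nxt == -1 else nxt
    return seg_start, seg_end


def extract_orf(
    db: SixFrameDb,
    contig_id: str,
    frame: int,
    peptide_position: int,
    min_length_aa: int = 20,
) -> RescuedOrf | None:
    """ORF surrounding a peptide occurrence at ``peptide_position`` (aa index).

    The ORF runs from the 5'-most ATG/GTG/TTG at-or-upstream of the peptide
    within the stop-bounded segment to the segment's stop codon (the genomic
    interval includes the stop codon when present). With no start codon the
    ORF begins at the segment start and is flagged ``start_missing``.
    """
    frame_aa = db.frames[(contig_id, frame)]
    assert frame_aa[peptide_position] != "*", "peptide cannot sit on a stop"
    seg_start, seg_end = _segment_bounds(frame_aa, peptide_position)

    orf_start_aa = None
    for a in range(seg_start, peptide_position + 1):
        if db.codon(contig_id, frame, a) in START_CODONS:
            orf_start_aa = a
            break
    start_missing = orf_start_aa is None
    if start_missing:
        orf_start_aa = seg_start

    aa_sequence = frame_aa[orf_start_aa:seg_end]
    if len(aa_sequence) < min_length_aa:
        return None
    has_stop = seg_end < len(frame_aa)
    coord_end_aa = seg_end + 1 if has_stop else seg_end
    start, end = db.genomic_interval(contig_id, frame, orf_start_aa, coord_end_aa)
    return RescuedOrf(
        contig_id=contig_id,
        strand="+" if frame > 0 else "-",
        frame=frame,
        start=start,
        end=end,
        aa_sequence=aa_sequence,
        start_missing=start_missing,
    )


def rescue_orfs(
    novel_peptides: Mapping[str, Mapping[str, int]],
    db: SixFrameDb,
    min_length_aa: int = 20,
) -> list[RescuedOrf]:
    """Locate novel peptides in the six-frame DB and extract their ORFs.

    ``novel_peptides`` maps peptide -> {sample: psm count}. Peptides landing
    in the same segment are merged onto one ORF with pooled PSM counts.
    """
    orfs: dict[tuple[str, int, int, int], RescuedOrf] = {}
    for peptide in sorted(novel_peptides):
        total_psms = sum(novel_peptides[peptide].values())
        for (contig_id, frame), frame_aa in sorted(db.frames.items()):
            pos = frame_aa.find(peptide)
            while pos != -1:
                orf = extract_orf(db, contig_id, frame, pos, min_length_aa=min_length_aa)
                if orf is not None:
                    key = (contig_id, frame, orf.start, orf.end)
                    if key not in orfs:
                        orfs[key] = orf
                    orfs[key].peptides[peptide] = orfs[key].peptides.get(peptide, 0) + total_psms
                pos = frame_aa.find(peptide, pos + 1)
    return [orfs[k] for k in sorted(orfs)]


# ---------------------------------------------------------------------------
# Novelty filtering (re-discovery removal)
# ---------------------------------------------------------------------------

def _make_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -11.0
    aligner.extend_gap_score = -1.0
    return aligner


_ALIGNER = _make_aligner()


def alignment_identity(a: str, b: str, min_alignment_aa: int = 20) -> float:
    """Local-alignment identity of two protein sequences.

    Identity = identical aligned columns / length of the shorter sequence;
    0.0 when the best local alignment covers fewer than ``min_alignment_aa``
    columns.
    """
    if not a or not b:
        return 0.0
    alignments = _ALIGNER.align(a, b)
    if len(alignments) == 0:
        return 0.0
    best = alignments[0]
    matches = 0
    columns = 0
    for (a0, a1), (b0, b1) in zip(*best.aligned):
        columns += a1 - a0
        matches += sum(1 for x, y in zip(a[a0:a1], b[b0:b1]) if x == y)
    if columns < min_alignment_aa:
        return 0.0
    return matches / min(len(a), len(b))


def novelty_filter(
    candidate: RescuedOrf,
    predicted_proteome: Mapping[str, str],
    min_identity: float = 0.70,
    min_alignment_aa: int = 20,
    keep_rediscoveries: bool = False,
) -> bool:
    """True when the candidate should be kept.

    By default a candidate matching any predicted protein at >=
    ``min_identity`` is considered a re-discovery and dropped;
    ``keep_rediscoveries`` inverts the decision (keeping only re-discovered
    ORFs, the literal high-identity filter direction).
    """
    rediscovered = any(
        alignment_identity(candidate.aa_sequence, prot, min_alignment_aa) >= min_identity
        for prot in predicted_proteome.values()
    )
    return rediscovered if keep_rediscoveries else not rediscovered


# ---------------------------------------------------------------------------
# Relation classification
# ---------------------------------------------------------------------------

def classify_orf_relation(
    orf: RescuedOrf,
    genes: Sequence[GeneModel],
    contig_lengths: Mapping[str, int],
    prefer: str = "same_strand_diff_frame",
) -> str:
    """Relation of a rescued ORF to the predicted genes of its contig.

    Classes: ``same_strand_diff_frame`` (>=1 bp overlap with a same-strand
    gene in another frame), ``opposite_strand`` (overlap with an
    other-strand gene), ``no_overlap``. When both occur, ``prefer`` wins.
    """
    if prefer not in {"same_strand_diff_frame", "opposite_strand"}:
        raise ValueError(f"invalid precedence class: {prefer!r}")
    contig_len = contig_lengths[orf.contig_id]
    orf_frame = orf.start % 3 if orf.strand == "+" else (contig_len - orf.end) % 3

    same_strand_diff_frame = False
    opposite = False
    for gene in genes:
        if gene.contig_id != orf.contig_id:
            continue
        if min(gene.end, orf.end) - max(gene.start, orf.start) < 1:
            continue
        if gene.strand != orf.strand:
            opposite = True
        elif gene.frame(contig_len) != orf_frame:
            same_strand_diff_frame = True
    if same_strand_diff_frame and opposite:
        return prefer
    if same_strand_diff_frame:
        return "same_strand_diff_frame"
    if opposite:
        return "opposite_strand"
    return "no_overlap"


def classify_all(
    orfs: Iterable[RescuedOrf],
    genes: Sequence[GeneModel],
    contig_lengths: Mapping[str, int],
    prefer: str = "same_strand_diff_frame",
) -> list[RescuedOrf]:
    return [
        replace(orf, relation=classify_orf_relation(orf, genes, contig_lengths, prefer))
        for orf in orfs
    ]


# ---------------------------------------------------------------------------
# ORF grouping
# ---------------------------------------------------------------------------

def cluster_orfs(orfs: Sequence[RescuedOrf], min_identity: float = 0.70) -> list[list[RescuedOrf]]:
    """Single-linkage groups of ORFs by pairwise aa identity.

    Only groups with >= 2 members are reported; ungrouped ORFs stay
    singletons (not returned).
    """
    n = len(orfs)
    parent = list(range(n))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            if alignment_identity(orfs[i].aa_sequence, orfs[j].aa_sequence) >= min_identity:
                parent[find(i)] = find(j)

    groups: dict[int, list[RescuedOrf]] = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(orfs[i])
    result = [sorted(g, key=lambda o: o.orf_id) for g in groups.values() if len(g) >= 2]
    return sorted(result, key=lambda g: (-len(g), g[0].orf_id))


# ---------------------------------------------------------------------------
# Export
# ---------------------------------------------------------------------------

def write_rescued_gff3(
    orfs: Sequence[RescuedOrf],
    path,
    contig_lengths: Mapping[str, int] | None = None,
) -> None:
    genes = []
    attributes = {}
    for idx, orf in enumerate(sorted(orfs, key=lambda o: o.orf_id), start=1):
        gene_id = f"rescued_{idx:05d}"
        genes.append(
            GeneModel(
                gene_id=gene_id,
                contig_id=orf.contig_id,
                start=orf.start,
                end=orf.end,
                strand=orf.strand,
                source="rescue",
            )
        )
        attributes[gene_id] = {
            "rescued": "true",
            "relation": orf.relation or "unclassified",
            "psm_count": str(orf.psm_count),
        }
    write_gff3(genes, path, contig_lengths=contig_lengths, extra_attributes=attributes)
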