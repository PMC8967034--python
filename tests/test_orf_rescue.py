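import numpy as np
import pytest
from Bio.Seq import Seq

from protscape.io_formats import GeneModel
from protscape.orf_rescue import (
    RescuedOrf,
    alignment_identity,
    classify_all,
    classify_orf_relation,
    cluster_orfs,
    extract_orf,
    novelty_filter,
    rescue_orfs,
    select_top_genomes,
    six_frame_translate,
)
from protscape.synthetic_data import generate_community, simulate_psms, small_config


class TestSelectTopGenomes:
    def test_cumulative_cut(self):
        totals = {"a": 50, "b": 30, "c": 15, "d": 5}
        assert select_top_genomes(totals, coverage=0.80) == ["a", "b"]

    def test_single_genome(self):
        assert select_top_genomes({"a": 42}, coverage=0.80) == ["a"]

    def test_full_coverage_takes_all_nonzero(self):
        totals = {"a": 5, "b": 3, "c": 0}
        assert select_top_genomes(totals, coverage=1.0) == ["a", "b"]

    def test_empty(self):
        assert select_top_genomes({}, coverage=0.8) == []
        assert select_top_genomes({"a": 0}, coverage=0.8) == []


class TestSixFrame:
    def test_plus_one(self):
        db = six_frame_translate({"c": "ATGGCC"})
        assert db.frames[("c", 1)] == "MA"

    def test_minus_one_is_revcomp_translation(self):
        db = six_frame_translate({"c": "ATGGCC"})
        assert db.frames[("c", -1)] == "GH"  # translate("GGCCAT")

    def test_stop_renders_star(self):
        db = six_frame_translate({"c": "ATGTAAGCC"})
        assert db.frames[("c", 1)] == "M*A"

    def test_n_codon_gives_x(self):
        db = six_frame_translate({"c": "ATGNNNGCC"})
        assert db.frames[("c", 1)] == "MXA"

    def test_short_sequence(self):
        db = six_frame_translate({"c": "AT"})
        assert db.frames[("c", 1)] == ""

    def test_revcomp_symmetry(self):
        rng = np.random.default_rng(17)
        for _ in range(20):
            seq = "".join("ACGT"[i] for i in rng.integers(0, 4, size=int(rng.integers(30, 120))))
            fwd = six_frame_translate({"c": seq})
            rev = six_frame_translate({"c": str(Seq(seq).reverse_complement())})
            forward_set = {fwd.frames[("c", k)] for k in (1, 2, 3)}
            rev_minus_set = {rev.frames[("c", -k)] for k in (1, 2, 3)}
            assert forward_set == rev_minus_set

    def test_coordinate_round_trip(self):
        rng = np.random.default_rng(3)
        seq = "".join("ACGT"[i] for i in rng.integers(0, 4, size=99))
        db = six_frame_translate({"c": seq})
        for frame in (1, 2, 3, -1, -2, -3):
            aa = db.frames[("c", frame)]
            for a in range(len(aa)):
                start, end = db.genomic_interval("c", frame, a, a + 1)
                assert end - start == 3
                codon = seq[start:end]
                if frame < 0:
                    codon = str(Seq(codon).reverse_complement())
                assert codon == db.codon("c", frame, a)


class TestExtractOrf:
    def test_start_missing_at_segment_start(self):
        # frame +1 segment with no ATG/GTG/TTG before the peptide
        protein = "CCCCCCCCIDEAWQNSSTHC"  # no start-codon residues up front
        dna = "".join({"C": "TGC", "I": "ATC", "D": "GAT", "E": "GAA", "A": "GCA",
                       "W": "TGG", "Q": "CAA", "N": "AAC", "S": "AGC", "T": "ACA",
                       "H": "CAC"}[aa] for aa in protein) + "TAA"
        db = six_frame_translate({"c": dna})
        pos = db.frames[("c", 1)].find("IDEAWQNSS")
        orf = extract_orf(db, "c", 1, pos, min_length_aa=5)
        assert orf is not None
        assert orf.start_missing
        assert orf.start == 0

    def test_two_peptides_same_segment_one_orf(self, community, simulated):
        db = six_frame_translate(community.contigs)
        orf = community.truth.hidden_orfs[0]
        from protscape.synthetic_data import tryptic_peptides

        peps = tryptic_peptides(orf.aa_sequence)[:2]
        novel = {p: {"s1": 1} for p in peps}
        rescued = rescue_orfs(novel, db)
        intervals = {(o.contig_id, o.start, o.end) for o in rescued}
        assert (orf.contig_id, orf.start, orf.end) in intervals
        target = [o for o in rescued if (o.contig_id, o.start, o.end) ==
                  (orf.contig_id, orf.start, orf.end)]
        assert len(target) == 1
        assert set(target[0].peptides) == set(peps)

    def test_min_length_filter(self):
        dna = "TAA" + "ATG" + "GCA" * 5 + "TAA"
        db = six_frame_translate({"c": dna})
        pos = db.frames[("c", 1)].find("MAAAAA")
        assert extract_orf(db, "c", 1, pos, min_length_aa=20) is None


class TestPlantedRecovery:
    @pytest.mark.parametrize("seed", [1, 2, 7])
    def test_recall_one_exact_intervals_and_classes(self, seed):
        community = generate_community(small_config(seed=seed))
        simulated = simulate_psms(community)
        db = six_frame_translate(community.contigs)
        rescued = rescue_orfs(simulated.novel_peptides, db)
        rescued = classify_all(rescued, community.genes, community.contig_lengths)
        truth = {(h.contig_id, h.strand, h.start, h.end): h.relation
                 for h in community.truth.hidden_orfs}
        found = {(o.contig_id, o.strand, o.start, o.end): o.relation for o in rescued}
        for key, relation in truth.items():
            assert key in found, f"planted ORF not recovered: {key}"
            assert found[key] == relation
        assert len(found) == len(truth)  # no hallucinated ORFs

    def test_no_evidence_no_rescue(self):
        community = generate_community(small_config(seed=7, emit_hidden_evidence=False))
        simulated = simulate_psms(community)
        db = six_frame_translate(community.contigs)
        assert rescue_orfs(simulated.novel_peptides, db) == []


def _orf(aa, contig="c", start=0):
    return RescuedOrf(contig_id=contig, strand="+", frame=1,
                      start=start, end=start + 3 * len(aa), aa_sequence=aa)


class TestNoveltyFilter:
    def test_identical_is_dropped(self):
        aa = "MSTENLIKQWERTASDFGHKLCVNMTYPQASDF"
        assert not novelty_filter(_orf(aa), {"p1": aa})

    def test_unrelated_is_kept(self):
        rng = np.random.default_rng(0)
        a = "".join("ACDEFGHIKLMNPQRSTVWY"[i] for i in rng.integers(0, 20, 60))
        b = "".join("ACDEFGHIKLMNPQRSTVWY"[i] for i in rng.integers(0, 20, 60))
        assert novelty_filter(_orf(a), {"p1": b})

    def test_sixty_nine_percent_boundary_kept(self):
        rng = np.random.default_rng(1)
        base = list("".join("ACDEFGHIKLMNPQRSTVWY"[i] for i in rng.integers(0, 20, 100)))
        mutant = list(base)
        # mutate 31 interior positions -> at most 69 identities over min length 100
        for pos in rng.choice(np.arange(10, 90), size=31, replace=False):
            current = mutant[pos]
            options = [c for c in "ACDEFGHIKLMNPQRSTVWY" if c != current]
            mutant[pos] = options[int(rng.integers(len(options)))]
        identity = alignment_identity("".join(base), "".join(mutant))
        assert identity <= 0.69
        assert novelty_filter(_orf("".join(base)), {"p1": "".join(mutant)})

    def test_inverted_direction_flag(self):
        aa = "MSTENLIKQWERTASDFGHKLCVNMTYPQASDF"
        assert novelty_filter(_orf(aa), {"p1": aa}, keep_rediscoveries=True)


class TestClassification:
    def test_minus_orf_inside_plus_gene(self):
        genes = [GeneModel("g", "c", 100, 400, "+")]
        orf = RescuedOrf("c", "-", -1, 150, 300, "A" * 50)
        assert classify_orf_relation(orf, genes, {"c": 1000}) == "opposite_strand"

    def test_same_strand_shifted_frame(self):
        genes = [GeneModel("g", "c", 99, 399, "+")]  # frame 0
        orf = RescuedOrf("c", "+", 2, 100, 250, "A" * 50)  # frame 1
        assert classify_orf_relation(orf, genes, {"c": 1000}) == "same_strand_diff_frame"

    def test_intergenic_desert(self):
        genes = [GeneModel("g", "c", 600, 900, "+")]
        orf = RescuedOrf("c", "+", 1, 0, 150, "A" * 50)
        assert classify_orf_relation(orf, genes, {"c": 1000}) == "no_overlap"

    def test_precedence_configurable(self):
        genes = [GeneModel("plus", "c", 99, 399, "+"), GeneModel("minus", "c", 120, 300, "-")]
        orf = RescuedOrf("c", "+", 2, 100, 250, "A" * 50)
        assert classify_orf_relation(orf, genes, {"c": 1000}) == "same_strand_diff_frame"
        assert classify_orf_relation(orf, genes, {"c": 1000},
                                     prefer="opposite_strand") == "opposite_strand"


class TestClusterOrfs:
    def test_identical_sequences_one_group(self):
        aa = "MSTENLIKQWERTASDFGHKLCVNMTYPQASDF"
        orfs = [_orf(aa, start=3 * i * len(aa)) for i in range(3)]
        groups = cluster_orfs(orfs)
        assert len(groups) == 1 and len(groups[0]) == 3

    def test_dissimilar_no_groups(self):
        rng = np.random.default_rng(0)
        orfs = [_orf("".join("ACDEFGHIKLMNPQRSTVWY"[i] for i in rng.integers(0, 20, 50)),
                     start=200 * k) for k in range(4)]
        assert cluster_orfs(orfs) == []

    def test_homolog_family_recovered(self):
        rng = np.random.default_rng(8)
        base = "".join("ACDEFGHIKLMNPQRSTVWY"[i] for i in rng.integers(0, 20, 60))
        family = []
        for k in range(12):
            seq = list(base)
            for pos in rng.choice(np.arange(5, 55), size=9, replace=False):  # 85% identity
                options = [c for c in "ACDEFGHIKLMNPQRSTVWY" if c != seq[pos]]
                seq[pos] = options[int(rng.integers(len(options)))]
            family.append(_orf("".join(seq), start=k * 600))
        groups = cluster_orfs(family, min_identity=0.7)
        assert len(groups) == 1
        assert len(groups[0]) == 12
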