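from collections import Counter

import pytest

from phagecomp.codon_trna import (
    STANDARD_CODE,
    CodonUsageProfile,
    TRNAComplement,
    codon_counts,
    per_gene_codon_counts,
    random_usage,
    rank_genes_by_target_codons,
    rare_codon_report,
    synonymous_usage,
    trna_complement,
    truncate3,
    usage_table,
)
from phagecomp.errors import ValidationError
from phagecomp.genome_model import GeneFeature, GenomeRecord


class TestGeneticCode:
    def test_sixty_four_codons(self):
        assert len(STANDARD_CODE.codon_to_aa) + len(STANDARD_CODE.stop_codons) == 64

    def test_family_sizes_sum_to_61(self):
        assert sum(STANDARD_CODE.family_size.values()) == 61

    def test_leucine_has_six_codons(self):
        assert STANDARD_CODE.family_size["L"] == 6

    def test_methionine_single(self):
        assert STANDARD_CODE.family_size["M"] == 1


class TestCodonCounts:
    def test_single_cds_stop_excluded(self):
        p = codon_counts(["ATGAAATAG"])
        assert p.counts == Counter({"AUG": 1, "AAA": 1})

    def test_frameshift_skipped_with_warning(self, caplog):
        with caplog.at_level("WARNING"):
            p = codon_counts(["ATGAAATAG", "ATGAAATA"])
        assert p.n_skipped == 1
        assert p.counts == Counter({"AUG": 1, "AAA": 1})

    def test_hand_counted_pair(self):
        p = codon_counts(["ATGTTATAA"] * 2)
        assert p.counts == Counter({"AUG": 2, "UUA": 2})

    def test_empty_set_errors(self):
        with pytest.raises(ValidationError):
            codon_counts([])

    def test_internal_stop_flagged_not_fatal(self):
        p = codon_counts(["ATGTAAAAATAG"])
        assert p.n_internal_stops == 1
        assert p.counts["UAA"] == 1

    def test_additivity(self):
        a = codon_counts(["ATGTTATAA", "ATGCCCTAA"])
        b = codon_counts(["ATGGGGTAA"])
        both = codon_counts(["ATGTTATAA", "ATGCCCTAA", "ATGGGGTAA"])
        assert a.counts + b.counts == both.counts


class TestSynonymousUsage:
    def test_methionine_always_one(self):
        usage = synonymous_usage({"AUG": 7})
        assert usage["AUG"] == 1.0

    def test_quarter_leucine(self):
        # Leu family counts {UUA:1, CUG:3}; usage(UUA) = 1/4
        usage = synonymous_usage({"UUA": 1, "CUG": 3})
        assert usage["UUA"] == 0.25

    def test_family_sums_to_one(self):
        counts = {"UUA": 3, "UUG": 2, "CUU": 5, "CUC": 1, "CUA": 7, "CUG": 2}
        usage = synonymous_usage(counts)
        assert sum(usage[c] for c in counts) == pytest.approx(1.0, abs=1e-9)

    def test_zero_count_family_omitted(self):
        usage = synonymous_usage({"AUG": 1})
        assert "UUA" not in usage


class TestRandomUsage:
    def test_table_values(self):
        ru = random_usage()
        assert truncate3(ru["UUA"]) == 0.166  # Leu, six codons
        assert truncate3(ru["CCA"]) == 0.25  # Pro, four
        assert truncate3(ru["AAC"]) == 0.5  # Asn, two
        assert truncate3(ru["AUG"]) == 1.0  # Met, one

    def test_sums_to_one_per_family(self):
        ru = random_usage()
        for aa, codons in STANDARD_CODE.family.items():
            assert sum(ru[c] for c in codons) == pytest.approx(1.0, abs=1e-9)


class TestTruncate:
    def test_truncates_not_rounds(self):
        assert truncate3(1 / 6) == 0.166
        assert truncate3(0.9999) == 0.999


class TestTrnaComplement:
    def test_reverse_complement_decoding(self):
        assert TRNAComplement.decode("UAA") == "UUA"
        assert TRNAComplement.decode("CAU") == "AUG"

    def test_planted_set_nine_determined(self):
        antis = ["UAA", "UAG", "CAU", "GUU", "UGG", "UGG", "UCU", "UGA", "UGU", "UAC"]
        feats = [
            GeneFeature(f"t{i}", "g", i * 100, i * 100 + 75, "+", "tRNA",
                        attributes={"anticodon": a})
            for i, a in enumerate(antis)
        ]
        comp = trna_complement(feats)
        assert comp.n_determined == 10
        assert comp.anticodon_counts["UGG"] == 2

    def test_undetermined_counted(self):
        feats = [
            GeneFeature("t1", "g", 0, 75, "+", "tRNA", attributes={"anticodon": "UAA"}),
            GeneFeature("t2", "g", 100, 175, "+", "tRNA", product="pseudo tRNA"),
        ]
        comp = trna_complement(feats)
        assert comp.n_determined == 1
        assert comp.n_undetermined == 1

    def test_amino_acid_count(self):
        # Pro (UGG twice) and Leu (UAA, UAG) doubled: 7 distinct amino acids
        antis = ["UAA", "UAG", "CAU", "GUU", "UGG", "UGG", "UCU", "UGU", "UAC"]
        feats = [
            GeneFeature(f"t{i}", "g", i * 100, i * 100 + 75, "+", "tRNA",
                        attributes={"anticodon": a})
            for i, a in enumerate(antis)
        ]
        comp = trna_complement(feats)
        assert len(comp.amino_acids()) == 7


def _profile(counts, source="x"):
    p = CodonUsageProfile(source_id=source)
    p.counts = Counter(counts)
    p.n_cds = 1
    return p


class TestRareCodonReport:
    def _phage_trnas(self):
        c = TRNAComplement(source_id="phage")
        c.anticodon_counts = Counter({"UAA": 1, "GUU": 1})  # decode UUA, AAC
        return c

    def test_rare_flagged(self):
        host = _profile({"UUA": 3, "CUG": 997, "AAC": 85, "AAU": 15})
        phage = _profile({"UUA": 50, "CUG": 50, "AAC": 10, "AAU": 10})
        report = rare_codon_report(phage, host, self._phage_trnas())
        row = report.set_index("codon").loc["UUA"]
        assert row["rare_host"]  # 0.003 < 0.166
        assert row["host_usage"] == pytest.approx(0.003)

    def test_asparagine_exception_not_rare(self):
        host = _profile({"UUA": 3, "CUG": 997, "AAC": 85, "AAU": 15})
        phage = _profile({"UUA": 1, "AAC": 1})
        report = rare_codon_report(phage, host, self._phage_trnas())
        row = report.set_index("codon").loc["AAC"]
        assert not row["rare_host"]  # 0.85 >= 0.5

    def test_equal_to_baseline_not_rare(self):
        host = _profile({"AAC": 1, "AAU": 1})  # usage exactly 0.5 = baseline
        phage = _profile({"AAC": 1})
        trnas = TRNAComplement(source_id="p")
        trnas.anticodon_counts = Counter({"GUU": 1})
        report = rare_codon_report(phage, host, trnas)
        assert not report.set_index("codon").loc["AAC"]["rare_host"]

    def test_host_trna_absent_flag(self):
        host = _profile({"UUA": 1, "AAC": 1, "AAU": 1})
        phage = _profile({"UUA": 1})
        host_trnas = TRNAComplement(source_id="h")
        host_trnas.anticodon_counts = Counter({"GUU": 1})  # decodes AAC only
        trnas = TRNAComplement(source_id="p")
        trnas.anticodon_counts = Counter({"UAA": 1, "GUU": 1})
        report = rare_codon_report(phage, host, trnas, host_trnas).set_index("codon")
        assert report.loc["UUA"]["host_trna_absent"]
        assert not report.loc["AAC"]["host_trna_absent"]


class TestUsageTable:
    def test_truncated_display(self):
        phage = _profile({"UUA": 1, "UUG": 5})
        host = _profile({"UUA": 1, "UUG": 2})
        trnas = TRNAComplement(source_id="p")
        trnas.anticodon_counts = Counter({"UAA": 1})
        table = usage_table(phage, host, trnas).set_index("codon")
        assert table.loc["UUA"]["random_usage"] == 0.166
        assert table.loc["UUA"]["phage_usage"] == truncate3(1 / 6)


class TestRankGenes:
    def test_score_fraction(self):
        counts = {"g1": Counter({"UUA": 4, "CUG": 6} | {f"GC{c}": 5 for c in "AU"}) ,
                  "g2": Counter({"CUG": 40})}
        frame = rank_genes_by_target_codons(counts, {"UUA"}, min_codons=10)
        row = frame.set_index("gene_id").loc["g1"]
        assert row["score"] == pytest.approx(4 / 20)

    def test_order_by_score(self):
        counts = {
            "low": Counter({"UUA": 4, "CUG": 36}),
            "high": Counter({"UUA": 16, "CUG": 24}),
        }
        frame = rank_genes_by_target_codons(counts, {"UUA"})
        assert list(frame["gene_id"]) == ["high", "low"]

    def test_min_codons_excludes_short(self):
        counts = {"short": Counter({"UUA": 5}), "long": Counter({"UUA": 5, "CUG": 45})}
        frame = rank_genes_by_target_codons(counts, {"UUA"}, min_codons=30)
        assert list(frame["gene_id"]) == ["long"]

    def test_empty_target_errors(self):
        with pytest.raises(ValidationError):
            rank_genes_by_target_codons({"g": Counter({"UUA": 40})}, set())

    def test_enriched_gene_ranks_first_in_simulation(self):
        import numpy as np

        rng = np.random.default_rng(42)
        sense = STANDARD_CODE.sense_codons
        targets = {"UUA", "CCA"}
        background = [c for c in sense]
        counts = {}
        for i in range(50):
            draws = rng.choice(background, size=200)
            counts[f"bg{i:02d}"] = Counter(draws.tolist())
        # enrich one gene to ~3x the background target-codon frequency
        enriched = rng.choice(background, size=200).tolist()
        base_freq = 2 / len(sense)
        n_extra = int(3 * base_freq * 200)
        enriched[:n_extra] = ["UUA"] * (n_extra // 2) + ["CCA"] * (n_extra - n_extra // 2)
        counts["enriched"] = Counter(enriched)
        frame = rank_genes_by_target_codons(counts, targets)
        assert frame.iloc[0]["gene_id"] == "enriched"


class TestPerGeneCounts:
    def test_counts_per_gene(self):
        g = GenomeRecord("g", "ATGTTATAAATGCCCTAA")
        feats = [
            GeneFeature("a", "g", 0, 9, "+", "CDS"),
            GeneFeature("b", "g", 9, 18, "+", "CDS"),
        ]
        counts = per_gene_codon_counts(g, feats)
        assert counts["a"] == Counter({"AUG": 1, "UUA": 1})
        assert counts["b"] == Counter({"AUG": 1, "CCC": 1})
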