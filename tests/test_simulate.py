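"""The forward simulator: parental panels, hybridization events, reads."""

import numpy as np
import pytest

from reticulator.amplicon import revcomp
from reticulator.simulate import (
    DEFAULT_FORWARD_PRIMER,
    DEFAULT_REVERSE_PRIMER,
    HybridEvent,
    LocusConfig,
    make_barcodes,
    simulate_hybridization,
    simulate_parental_panel,
    simulate_reads,
)


class TestParentalPanel:
    def test_minimal_panel(self):
        panel = simulate_parental_panel(2, seed=1)
        assert len(panel.taxa) == 2
        assert panel.cp_haplotype("P1") != panel.cp_haplotype("P2")
        groups = set(panel.group_map.values())
        assert groups == {"A", "B"}

    def test_seven_taxa_all_nuclear_alleles_distinct(self):
        panel = simulate_parental_panel(7, seed=42)
        for locus in panel.nuclear_loci:
            seqs = [
                panel.allele_sequences[(t, locus.locus_id)] for t in panel.taxa
            ]
            flat = [s for tup in seqs for s in tup]
            assert len(set(flat)) == len(flat)

    def test_deterministic_for_seed(self):
        a = simulate_parental_panel(7, seed=42)
        b = simulate_parental_panel(7, seed=42)
        assert a.allele_sequences == b.allele_sequences
        assert a.group_map == b.group_map

    def test_too_few_parents_rejected(self):
        with pytest.raises(ValueError, match="at least two parents"):
            simulate_parental_panel(1, seed=0)

    def test_zero_length_locus_rejected(self):
        with pytest.raises(ValueError, match="length"):
            LocusConfig("L", "biparental", 0)

    def test_exactly_one_maternal_locus_required(self):
        loci = [LocusConfig("a", "biparental", 10), LocusConfig("b", "biparental", 10)]
        with pytest.raises(ValueError, match="maternal"):
            simulate_parental_panel(2, loci=loci, seed=0)

    def test_within_group_divergence_gives_two_alleles(self):
        panel = simulate_parental_panel(2, seed=3, within_group_divergence=2)
        locus = panel.nuclear_loci[0].locus_id
        seqs = panel.allele_sequences[("P1", locus)]
        assert len(seqs) == 2 and seqs[0] != seqs[1]


class TestHybridization:
    def _panel(self):
        return simulate_parental_panel(3, seed=9)

    def test_diploid_cross_is_heterozygous_with_maternal_cp(self):
        panel = self._panel()
        samples, truth = simulate_hybridization(
            panel, [HybridEvent("P1", "P2")], seed=1,
            samples_per_event=1, parent_samples=1,
        )
        child = [s for s in samples if s.taxon_name.startswith("H1")][0]
        assert child.ploidy == 2
        assert child.cp_sequence == panel.cp_haplotype("P1")
        for locus in panel.nuclear_loci:
            assert len(set(child.alleles[locus.locus_id])) == 2

    def test_unreduced_maternal_gamete_gives_triploid(self):
        panel = self._panel()
        samples, _ = simulate_hybridization(
            panel,
            [HybridEvent("P1", "P2", maternal_gamete="unreduced")],
            seed=1, samples_per_event=1, parent_samples=0,
        )
        child = samples[0]
        assert child.ploidy == 3
        for locus in panel.nuclear_loci:
            assert len(child.alleles[locus.locus_id]) == 3

    def test_selfing_reproduces_parent_genotype(self):
        panel = self._panel()
        samples, _ = simulate_hybridization(
            panel, [HybridEvent("P1", "P1")], seed=1,
            samples_per_event=1, parent_samples=1,
        )
        parent = [s for s in samples if s.taxon_name == "P1"][0]
        child = [s for s in samples if s.taxon_name.startswith("H1")][0]
        assert child.alleles == parent.alleles
        assert child.cp_sequence == parent.cp_sequence

    def test_apogamous_vs_sexual_spore_counts(self):
        panel = self._panel()
        samples, _ = simulate_hybridization(
            panel,
            [HybridEvent("P1", "P2", child_mode="sexual"),
             HybridEvent("P1", "P3", child_mode="apogamous")],
            seed=1, samples_per_event=1, parent_samples=0,
        )
        assert samples[0].spore_count == 64 and samples[0].mode == "sexual"
        assert samples[1].spore_count == 32 and samples[1].mode == "apogamous"

    def test_unknown_taxon_rejected(self):
        with pytest.raises(ValueError, match="unknown taxon"):
            simulate_hybridization(self._panel(), [HybridEvent("P1", "P9")], seed=1)

    def test_double_unreduced_rejected(self):
        event = HybridEvent("P1", "P2", maternal_gamete="unreduced",
                            paternal_gamete="unreduced")
        with pytest.raises(ValueError, match="ploidy"):
            simulate_hybridization(self._panel(), [event], seed=1)

    def test_conservation_invariants_across_events(self):
        """cpDNA strictly maternal; child alleles are exactly the gamete
        union; ploidy equals the contributed copy count."""
        panel = simulate_parental_panel(4, seed=2)
        events = [
            HybridEvent("P1", "P2"),
            HybridEvent("P3", "P1", maternal_gamete="unreduced"),
            HybridEvent("P2", "P4", paternal_gamete="unreduced"),
        ]
        samples, truth = simulate_hybridization(panel, events, seed=5,
                                                samples_per_event=2)
        by_taxon = {}
        for s in samples:
            by_taxon.setdefault(s.taxon_name, []).append(s)
        for event, (child_taxon, pair) in zip(events, truth.parent_pairs.items()):
            assert pair == (event.maternal_taxon, event.paternal_taxon)
            for child in by_taxon[child_taxon]:
                assert child.cp_sequence == panel.cp_haplotype(event.maternal_taxon)
                assert child.ploidy == event.child_ploidy
                for locus in panel.nuclear_loci:
                    copies = child.alleles[locus.locus_id]
                    assert len(copies) == event.child_ploidy
                    for seq in set(copies):
                        origin = truth.allele_origin[(child_taxon, locus.locus_id, seq)]
                        assert origin in pair


class TestReads:
    def _setup(self, error_rate=0.0, depth=50, seed=4):
        panel = simulate_parental_panel(2, seed=8)
        samples, _ = simulate_hybridization(
            panel, [HybridEvent("P1", "P2")], seed=2,
            samples_per_event=1, parent_samples=0,
        )
        barcodes = make_barcodes([s.sample_id for s in samples], seed=3)
        reads = simulate_reads(samples, depth, error_rate, barcodes, seed=seed,
                               loci=["Knox3"])
        return panel, samples, barcodes, reads

    def test_zero_noise_reads_equal_source_allele(self):
        panel, samples, barcodes, reads = self._setup()
        child = samples[0]
        sources = set(child.alleles["Knox3"])
        prefix_len = 8 + len(DEFAULT_FORWARD_PRIMER)
        suffix_len = len(DEFAULT_REVERSE_PRIMER)
        for read in reads:
            insert = read.sequence[prefix_len:-suffix_len]
            assert insert in sources
            assert read.sequence[:8] == barcodes[child.sample_id]
            assert read.sequence.endswith(revcomp(DEFAULT_REVERSE_PRIMER))

    def test_read_counts_reproducible_for_seed(self):
        _, _, _, first = self._setup(seed=4)
        _, _, _, second = self._setup(seed=4)
        assert [(r.read_id, r.sequence) for r in first] == [
            (r.read_id, r.sequence) for r in second
        ]

    def test_error_rate_matches_binomial_expectation(self):
        error_rate = 0.005
        panel, samples, _, reads = self._setup(error_rate=error_rate, depth=600)
        child = samples[0]
        sources = set(child.alleles["Knox3"])
        length = len(next(iter(sources)))
        prefix_len = 8 + len(DEFAULT_FORWARD_PRIMER)
        suffix_len = len(DEFAULT_REVERSE_PRIMER)
        mismatches = []
        for read in reads:
            insert = read.sequence[prefix_len:-suffix_len]
            best = min(
                sum(a != b for a, b in zip(insert, src)) for src in sources
            )
            mismatches.append(best)
        assert len(mismatches) >= 1000
        expected = length * error_rate
        se = np.sqrt(length * error_rate * (1 - error_rate) / len(mismatches))
        assert abs(np.mean(mismatches) - expected) < 3 * se + 0.02

    def test_duplicate_barcodes_rejected(self):
        panel, samples, _, _ = self._setup()
        bad = {samples[0].sample_id: "AAAAAAAA", "other": "AAAAAAAA"}
        with pytest.raises(ValueError, match="duplicate barcode"):
            simulate_reads(samples, 10, 0.0, bad, seed=1)

    def test_barcodes_unique_and_8_bases(self):
        barcodes = make_barcodes([f"s{i}" for i in range(50)], seed=0)
        assert len(set(barcodes.values())) == 50
        assert all(len(b) == 8 for b in barcodes.values())
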