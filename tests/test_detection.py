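"""Detection channels, filters, Venn accounting, sensitivity scan, dedup."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from phagescreen import detection
from phagescreen.alignment import random_protein
from phagescreen.records import ARGCandidate, GenomeRecord, ReferenceProtein


def _candidate(pid="P|0", identity=50.0, qcov=90.0, product="hypothetical protein"):
    return ARGCandidate(
        protein_id=pid,
        phage_id=pid.split("|")[0],
        gene_index=int(pid.split("|")[1]),
        channels={"homology"},
        best_family="dfrA",
        mechanism="target replacement",
        best_identity_pct=identity,
        best_qcov_pct=qcov,
        product=product,
    )


class TestChannelRules:
    """Boundary semantics of the quoted thresholds (closed vs strict)."""

    def test_homology_boundaries(self):
        assert detection.passes_homology(1e-5, 60.0)  # both at boundary: kept
        assert not detection.passes_homology(2e-5, 80.0)  # E just beyond
        assert not detection.passes_homology(1e-9, 59.9)  # qcov just below

    def test_domain_boundaries(self):
        assert detection.passes_domain(40.0, 1e-5)
        assert not detection.passes_domain(39.9, 1e-12)
        assert not detection.passes_domain(80.0, 2e-5)

    def test_reported_boundaries(self):
        assert detection.passes_reported(92.0, 88.0)
        assert not detection.passes_reported(92.0, 80.0)
        assert not detection.passes_reported(89.9, 100.0)
        assert detection.passes_reported(90.0, 85.0)  # closed at both


class TestChannelsOnCohort:
    def test_homology_recovers_high_identity_plants(self, small_cohort):
        """Planted homologs at >= 70% identity all pass the lenient channel."""
        truth = small_cohort.truth
        high = {
            f"{a['phage_id']}|{a['gene_index']}"
            for a in truth.planted_args
            if a["achieved_identity"] >= 70
        }
        assert high
        hits = detection.channel_homology(small_cohort.proteins, small_cohort.refdb)
        assert high <= set(hits)

    def test_homology_precision_on_cohort(self, small_cohort):
        hits = detection.channel_homology(small_cohort.proteins, small_cohort.refdb)
        planted = small_cohort.truth.planted_gene_ids()
        false_pos = set(hits) - planted
        assert len(false_pos) / max(len(hits), 1) <= 0.05

    def test_domain_channel_requires_calibration(self, rng):
        from phagescreen.profiles import make_profile

        prof = make_profile([random_protein(30, rng) for _ in range(3)])
        with pytest.raises(Exception):
            detection.channel_domain({"P|0": random_protein(100, rng)}, [prof])

    def test_structure_identical_sequence_similarity_one(self, small_cohort):
        ref = small_cohort.refdb[0]
        centroids = {ref.family: detection.kmer_vector(ref.sequence)}
        hits = detection.channel_structure({"P|0": ref.sequence}, centroids, 0.0)
        assert hits["P|0"][0].similarity == pytest.approx(1.0)

    def test_structure_own_family_beats_others(self, small_cohort):
        centroids = detection.build_family_centroids(small_cohort.refdb)
        ref = small_cohort.refdb[0]
        hits = detection.channel_structure({"P|0": ref.sequence}, centroids, 0.0)
        assert hits["P|0"][0].family == ref.family


class TestMergeAndVenn:
    def test_three_way_example(self, small_cohort):
        refdb = small_cohort.refdb
        sh = detection.StructureHit
        hits_s = {"P|1": [sh("P|1", "dfrA", 0.9)]}
        hits_d = {
            "P|1": [detection.DomainHit("P|1", "dfrA", 50, 1e-9, 100)],
            "P|2": [detection.DomainHit("P|2", "thyA", 50, 1e-9, 100)],
        }
        cands, venn = detection.merge_channels({}, hits_d, hits_s, refdb)
        assert len(cands) == 2
        assert venn["DS"] == 1 and venn["D"] == 1 and venn["HDS"] == 0

    @settings(max_examples=50, deadline=None)
    @given(
        h=st.sets(st.integers(0, 12)),
        d=st.sets(st.integers(0, 12)),
        s=st.sets(st.integers(0, 12)),
    )
    def test_venn_regions_partition_union(self, small_cohort, h, d, s):
        mk = lambda ids, hit: {f"P|{i}": [hit(f"P|{i}")] for i in ids}
        hits_h = {}
        hits_d = mk(d, lambda p: detection.DomainHit(p, "dfrA", 50, 1e-9, 100))
        hits_s = mk(s, lambda p: detection.StructureHit(p, "dfrA", 0.9))
        # homology entries need AlignmentHit objects; reuse domain-only merge
        # with h folded into d and s via an extra structure channel is not
        # equivalent, so drive homology with minimal AlignmentHit instances
        from phagescreen.alignment import AlignmentHit

        hits_h = {
            f"P|{i}": [
                AlignmentHit(f"P|{i}", "REF000A", 100, 30, 1e-9, 95, 95, 1, 10, 1, 10)
            ]
            for i in h
        }
        cands, venn = detection.merge_channels(
            hits_h, hits_d, hits_s, small_cohort.refdb
        )
        assert sum(venn.values()) == len(h | d | s) == len(cands)
        assert venn["HDS"] == len(h & d & s)

    def test_disjoint_channels_empty_triple(self, small_cohort):
        from phagescreen.alignment import AlignmentHit

        hits_h = {
            "P|0": [AlignmentHit("P|0", "REF000A", 100, 30, 1e-9, 95, 95, 1, 10, 1, 10)]
        }
        hits_d = {"P|1": [detection.DomainHit("P|1", "dfrA", 50, 1e-9, 100)]}
        _, venn = detection.merge_channels(hits_h, hits_d, {}, small_cohort.refdb)
        assert venn["HDS"] == 0 and venn["H"] == 1 and venn["D"] == 1


class TestBlacklist:
    def test_regulator_removed(self):
        cands = [
            _candidate("P|0", product="ARG transcriptional regulator"),
            _candidate("P|1", product="dihydrofolate reductase"),
        ]
        kept = detection.blacklist_filter(cands, ["regulator"])
        assert [c.protein_id for c in kept] == ["P|1"]

    def test_empty_keyword_list_is_identity(self):
        cands = [_candidate("P|0"), _candidate("P|1")]
        assert detection.blacklist_filter(cands, []) == cands

    def test_unmatched_keyword_is_identity(self):
        cands = [_candidate("P|0", product="porin")]
        assert detection.blacklist_filter(cands, ["regulator"]) == cands

    def test_match_is_case_insensitive(self):
        cands = [_candidate("P|0", product="Transcriptional REGULATOR")]
        assert detection.blacklist_filter(cands, ["regulator"]) == []


class TestSensitivityScan:
    def test_planted_identities_counted_per_cutoff(self):
        cands = [
            _candidate("P|0", identity=35),
            _candidate("P|1", identity=55),
            _candidate("P|2", identity=95),
        ]
        lifestyles = {"P": "lytic"}
        scan = detection.sensitivity_scan(cands, lifestyles, cutoffs=(30, 50, 90))
        assert list(scan["total"]) == [3, 2, 1]
        assert list(scan["lytic"]) == [3, 2, 1]

    def test_cutoff_zero_counts_everything(self):
        cands = [_candidate(f"P|{i}", identity=10 * i) for i in range(5)]
        scan = detection.sensitivity_scan(cands, {"P": "lytic"}, cutoffs=(0,))
        assert scan["total"][0] == 5

    def test_counts_monotone_non_increasing(self, small_pipeline):
        scan = small_pipeline.tables["sensitivity_scan"]
        totals = list(scan["total"])
        assert all(a >= b for a, b in zip(totals, totals[1:]))


class TestDedup:
    def _genome(self, name, acc, seq):
        return GenomeRecord(id=acc, name=name, accession=acc, sequence=seq)

    def test_identical_same_name_collapsed(self, rng):
        from phagescreen.alignment import random_nucleotide

        seq = random_nucleotide(2000, rng)
        out = detection.dedup_genomes(
            [self._genome("phage X", "ACC2", seq), self._genome("phage X", "ACC1", seq)]
        )
        assert [g.accession for g in out] == ["ACC1"]

    def test_divergent_same_name_both_kept(self, rng):
        from phagescreen.alignment import random_nucleotide

        out = detection.dedup_genomes(
            [
                self._genome("phage X", "ACC1", random_nucleotide(2000, rng)),
                self._genome("phage X", "ACC2", random_nucleotide(2000, rng)),
            ]
        )
        assert len(out) == 2

    def test_mutant_dropped(self, rng):
        from phagescreen.alignment import random_nucleotide

        out = detection.dedup_genomes(
            [
                self._genome("phage X mutant", "ACC1", random_nucleotide(500, rng)),
                self._genome("phage Y", "ACC2", random_nucleotide(500, rng)),
            ]
        )
        assert [g.name for g in out] == ["phage Y"]

    def test_same_sequence_different_names_kept(self, rng):
        from phagescreen.alignment import random_nucleotide

        seq = random_nucleotide(1000, rng)
        out = detection.dedup_genomes(
            [self._genome("phage X", "ACC1", seq), self._genome("phage Y", "ACC2", seq)]
        )
        assert len(out) == 2
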