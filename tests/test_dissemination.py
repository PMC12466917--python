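"""Seeded nucleotide search, dissemination calls, pseudo-lysogeny flag."""

import dataclasses

import numpy as np
import pytest

from phagescreen.alignment import random_nucleotide, revcomp
from phagescreen.dissemination import (
    call_dissemination,
    nt_search,
    passes_dissemination,
    pseudolysogeny_flag,
    whole_genome_similarity,
)
from phagescreen.records import GenomeRecord

from .oracles import local_score_nt


def _plant(rng, gene_len=300, replicon_len=3000, sub_rate=0.0):
    """Random replicon with a (possibly mutated) gene copy planted inside.

    The first 16 bases stay intact so the copy is always seedable even for
    short genes, matching the long high-identity genes the screen targets.
    """
    gene = random_nucleotide(gene_len, rng)
    copy = list(gene)
    if sub_rate > 0:
        n_sub = int(round(gene_len * sub_rate))
        for pos in rng.choice(np.arange(16, gene_len), size=n_sub, replace=False):
            copy[pos] = "ACGT"[(("ACGT".index(copy[pos])) + 1 + int(rng.integers(3))) % 4]
    copy = "".join(copy)
    pad = min(200, max(0, (replicon_len - gene_len) // 4))
    at = int(rng.integers(pad, max(pad + 1, replicon_len - gene_len - pad)))
    backbone = random_nucleotide(replicon_len, rng)
    replicon = backbone[:at] + copy + backbone[at:]
    return gene, replicon


class TestNtSearch:
    def test_exact_copy_full_identity_and_coverage(self, rng):
        gene, replicon = _plant(rng)
        hits = nt_search(gene, replicon)
        assert hits
        assert hits[0].identity_pct == 100.0
        assert hits[0].query_coverage_pct == 100.0

    def test_substituted_copy_identity_in_band(self, rng):
        gene, replicon = _plant(rng, sub_rate=0.05)
        hits = nt_search(gene, replicon)
        best = hits[0]
        assert 93.0 <= best.identity_pct <= 97.0
        assert best.query_coverage_pct > 90.0

    def test_absent_gene_no_passing_hits(self, rng):
        gene = random_nucleotide(300, rng)
        replicon = random_nucleotide(3000, rng)
        hits = nt_search(gene, replicon)
        assert not any(
            passes_dissemination(h.identity_pct, h.query_coverage_pct) for h in hits
        )

    def test_minus_strand_copy_found(self, rng):
        gene, replicon = _plant(rng)
        hits = nt_search(gene, revcomp(replicon))
        assert hits and hits[0].identity_pct == 100.0
        assert hits[0].strand == "-"

    def test_strand_symmetry_of_decision(self, rng):
        gene, replicon = _plant(rng, sub_rate=0.05)
        h1 = nt_search(gene, replicon)[0]
        h2 = nt_search(gene, revcomp(replicon))[0]
        assert passes_dissemination(
            h1.identity_pct, h1.query_coverage_pct
        ) == passes_dissemination(h2.identity_pct, h2.query_coverage_pct)

    def test_score_matches_bruteforce_dp_on_planted_pairs(self, rng):
        """Seeded aligner equals full Smith–Waterman on seedable pairs."""
        for _ in range(30):
            gene, replicon = _plant(
                rng, gene_len=int(rng.integers(60, 120)), replicon_len=200,
                sub_rate=float(rng.uniform(0, 0.06)),
            )
            hits = nt_search(gene, replicon)
            assert hits
            assert hits[0].raw_score == local_score_nt(gene, replicon)

    def test_short_gene_rejected(self, rng):
        with pytest.raises(ValueError):
            nt_search("ACGTACGT", random_nucleotide(100, rng))


class TestDisseminationRule:
    def test_boundary_strictness(self):
        assert not passes_dissemination(90.0, 100.0)  # identity exactly 90: rejected
        assert not passes_dissemination(100.0, 90.0)  # coverage exactly 90: rejected
        assert passes_dissemination(90.01, 90.01)

    def test_planted_copies_recovered(self, small_cohort):
        truth = small_cohort.truth
        genes = {gid: small_cohort.gene_nt[gid] for gid in truth.planted_gene_ids()}
        source = dict(
            zip(small_cohort.pool_meta["replicon_id"], small_cohort.pool_meta["source"])
        )
        summary = call_dissemination(genes, small_cohort.pool, source)
        called = {c.gene_id for c in summary.calls if c.disseminated}
        assert called == set(truth.disseminated_gene_ids)

    def test_phage_derived_hits_do_not_count(self, small_cohort):
        """Genes of pseudolysogenised phages hit the plasmid copy but keep
        verified_origin = phage-derived, so they are not disseminated."""
        truth = small_cohort.truth
        pl_phages = set()
        meta = small_cohort.pool_meta.set_index("replicon_id")
        for rid in truth.pseudolysogen_replicon_ids:
            rep = next(r for r in small_cohort.pool if r.id == rid)
            src = next(p for p in small_cohort.phages if p.sequence == rep.sequence)
            pl_phages.add(src.id)
        candidate_genes = {
            gid: small_cohort.gene_nt[gid]
            for gid in small_cohort.gene_nt
            if gid.split("|")[0] in pl_phages
            and gid not in set(truth.disseminated_gene_ids)
        }
        if not candidate_genes:
            pytest.skip("no pseudolysogen genes outside the disseminated set")
        source = dict(zip(meta.index, meta["source"]))
        summary = call_dissemination(candidate_genes, small_cohort.pool, source)
        for call in summary.calls:
            assert not call.disseminated
            if call.hits:
                assert call.verified_origin == "phage-derived"


class TestWholeGenomeSimilarity:
    def test_identical_sequences(self, rng):
        s = random_nucleotide(5000, rng)
        ident, cov = whole_genome_similarity(s, s)
        assert ident == pytest.approx(100.0, abs=0.5)
        assert cov == pytest.approx(100.0, abs=0.5)

    def test_partial_copy_low_coverage(self, rng):
        s = random_nucleotide(6000, rng)
        half = s[:3000]
        ident, cov = whole_genome_similarity(s, half + random_nucleotide(100, rng))
        assert cov < 60.0

    def test_unrelated_sequences_no_coverage(self, rng):
        a, b = random_nucleotide(4000, rng), random_nucleotide(4000, rng)
        _, cov = whole_genome_similarity(a, b)
        assert cov < 5.0


class TestPseudolysogeny:
    def test_planted_pseudolysogen_flagged(self, small_pipeline):
        truth = small_pipeline.cohort.truth
        assert (
            small_pipeline.summary["pseudolysogenic_plasmids"]
            == truth.pseudolysogen_replicon_ids
        )

    def test_replication_gene_blocks_flag(self, small_cohort):
        truth = small_cohort.truth
        rid = truth.pseudolysogen_replicon_ids[0]
        rep = next(r for r in small_cohort.pool if r.id == rid)
        from phagescreen.records import GeneFeature

        with_rep = dataclasses.replace(
            rep,
            genes=rep.genes
            + [GeneFeature(len(rep.genes), 1, 30, "+", "replication initiator protein")],
        )
        assert not pseudolysogeny_flag(with_rep, small_cohort.phages)

    def test_unrelated_plasmid_not_flagged(self, small_cohort, rng):
        plasmid = GenomeRecord(
            id="X", name="x", accession="X", sequence=random_nucleotide(8000, rng)
        )
        assert not pseudolysogeny_flag(plasmid, small_cohort.phages)
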