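"""Liftover: identity transfer, rearrangement cases, scoring, reconciliation."""

import pytest
from Bio.Seq import reverse_complement

import synphen as sp
from synphen.liftover import Candidate, GeneModel, global_score
from conftest import synteny_map


class TestCoordinateMap:
    def test_identity_map_on_identical_genomes(self, identical_pair):
        cmap, chains = synteny_map(identical_pair)
        assert len(chains) == 1
        for p in [0, 1, 4_999, 9_999]:
            hit = cmap.map_position("reference", p)
            assert (hit.qry_id, hit.pos, hit.strand, hit.approximate) == \
                ("scaffold_1", p, "+", False)

    def test_insertion_shifts_downstream_positions(self):
        # one 100 bp insertion planted between two anchor regions
        pair = sp.simulate_genome_pair(10_000, 2, 0.0, 0.0, 0, 0, 1, seed=2)
        ref = pair.reference
        ins_at = 5_000
        derived = {"scaffold_1": ref[:ins_at] + "N" * 0 + _novel(100) + ref[ins_at:]}
        anchors = sp.find_anchors({"reference": ref}, derived, k=20)
        cmap = sp.build_coordinate_map(sp.filter_chains(sp.build_chains(anchors)))
        before = cmap.map_position("reference", 1_000)
        after = cmap.map_position("reference", 6_000)
        assert before.pos == 1_000
        assert after.pos == 6_100

    def test_deleted_segment_is_unmapped(self):
        pair = sp.simulate_genome_pair(20_000, 2, 0.0, 0.0, 0, 0, 1, seed=3)
        ref = pair.reference
        derived = {"scaffold_1": ref[:4_000] + ref[15_000:]}  # 11 kb deletion
        anchors = sp.find_anchors({"reference": ref}, derived, k=20)
        cmap = sp.build_coordinate_map(sp.filter_chains(sp.build_chains(anchors)))
        assert cmap.map_position("reference", 9_000) is None

    def test_overlapping_chains_rejected(self, identical_pair):
        anchors = sp.find_anchors({"reference": identical_pair.reference},
                                  identical_pair.derived_scaffolds, k=20)
        chains = sp.build_chains(anchors)
        with pytest.raises(ValueError, match="filter"):
            sp.build_coordinate_map(chains + chains)


def _novel(n, seed=99):
    import numpy as np
    rng = np.random.default_rng(seed)
    return "".join(rng.choice(list("ACGT"), size=n))


class TestProjectGene:
    def test_identity_projection(self, identical_pair):
        cmap, _ = synteny_map(identical_pair)
        for g in identical_pair.genes:
            cand = sp.project_gene(g, cmap)
            assert (cand.seq_id, cand.start, cand.end, cand.strand) == \
                ("scaffold_1", g.start, g.end, g.strand)
            assert not cand.approximate and not cand.disrupted

    def test_gene_in_inverted_block_flips_strand(self):
        # the inversion must exceed the 10 kb gap allowance so that chains
        # cannot bridge across it
        for seed in range(50):
            pair = sp.simulate_genome_pair(40_000, 10, 0.0, 0.0, 1, 0, 1, seed=seed,
                                           rearrangement_len=(11_000, 15_000))
            inv = next(e for e in pair.event_log if e.kind == "inversion")
            s, e = inv.interval
            inside = [g for g in pair.genes if s <= g.start and g.end <= e]
            if inside:
                break
        else:
            pytest.fail("no seed placed a gene inside the inversion")
        cmap, _ = synteny_map(pair)
        for g in inside:
            cand = sp.project_gene(g, cmap)
            im = pair.gene_images[g.gene_id]
            assert cand.strand == im.strand != g.strand
            assert (cand.start, cand.end) == (im.start, im.end)

    def test_gene_spanning_breakpoint_is_disrupted(self):
        for seed in range(50):
            pair = sp.simulate_genome_pair(40_000, 10, 0.0, 0.0, 0, 1, 1, seed=seed,
                                           rearrangement_len=(11_000, 15_000))
            broken = [g for g in pair.genes if pair.gene_images[g.gene_id].disrupted]
            if broken:
                break
        else:
            pytest.fail("no seed produced a breakpoint through a gene")
        cmap, _ = synteny_map(pair)
        for g in broken:
            cand = sp.project_gene(g, cmap)
            assert cand is None or cand.disrupted


class TestRealignAndSelect:
    def test_identity_realignment_scores_perfect(self, identical_pair):
        cmap, _ = synteny_map(identical_pair)
        g = identical_pair.genes[0]
        cand = sp.realign_gene(g, identical_pair.derived_scaffolds, cmap)
        assert (cand.start, cand.end, cand.strand) == (g.start, g.end, g.strand)
        assert cand.cds == g.cds
        assert global_score(cand.cds, g.cds) == len(g.cds)

    def test_two_substitutions_drop_score_by_four(self, identical_pair):
        # match +1 / mismatch -1: each substitution costs (match - mismatch) = 2
        g = identical_pair.genes[0]
        mutated = list(g.cds)
        for off in (10, 20):  # keep codons sense: swap within purines
            mutated[off] = "C" if mutated[off] != "C" else "G"
        score = global_score("".join(mutated), g.cds)
        assert score == len(g.cds) - 4

    def test_realignment_restores_boundary_lost_in_gap(self):
        # engineer a projected start boundary that falls in an inter-anchor
        # gap whose target side is shorter than its reference side: a 60 bp
        # upstream deletion plus scattered substitutions in the gene's first
        # 60 bp (first codon positions, so no stops arise). The clamped
        # projection truncates the gene; realignment recovers the full-length
        # ORF through the mismatches and must win the score comparison.
        pair = sp.simulate_genome_pair(20_000, 3, 0.0, 0.0, 0, 0, 1, seed=6)
        g = next(g for g in pair.genes if g.strand == "+")
        ref = pair.reference
        mutated = list(ref)
        for off in range(6, 60, 9):  # first codon positions within the CDS
            p = g.start + off
            mutated[p] = "C" if mutated[p] != "C" else "G"
        derived = {"scaffold_1": "".join(mutated[: g.start - 62] + mutated[g.start - 2:])}
        anchors = sp.find_anchors({"reference": ref}, derived, k=20)
        cmap = sp.build_coordinate_map(sp.filter_chains(sp.build_chains(anchors)))
        proj = sp.project_gene(g, cmap)
        assert proj.approximate and proj.end - proj.start < g.length
        res = sp.lift_gene(g, derived, cmap)
        assert res.method == "realignment"
        assert res.end - res.start == g.length

    def test_tie_goes_to_projection(self):
        proj = Candidate("projection", "s", 0, 9, "+", "ATGAAATAA")
        realn = Candidate("realignment", "s", 0, 9, "+", "ATGAAATAA")
        res = sp.select_mapping(proj, realn, "ATGAAATAA")
        assert res.method == "projection"
        assert res.alignment_score == 9

    def test_only_projection_present(self):
        proj = Candidate("projection", "s", 0, 9, "+", "ATGAAATAA")
        res = sp.select_mapping(proj, None, "ATGAAATAA")
        assert res.method == "projection" and res.status == "mapped"

    def test_both_absent_is_unmapped(self):
        res = sp.select_mapping(None, None, "ATGAAATAA")
        assert res.status == "unmapped" and res.alignment_score is None

    def test_truncated_projection_loses_to_full_realignment(self):
        full = "ATG" + "GGCTTAGCA" * 20 + "TAA"
        proj = Candidate("projection", "s", 0, 10, "+", full[:len(full) - 60])
        realn = Candidate("realignment", "s", 0, 10, "+", full)
        res = sp.select_mapping(proj, realn, full)
        assert res.method == "realignment"


class TestRecovery:
    def test_identity_liftover_returns_all_genes_unchanged(self, identical_pair):
        cmap, _ = synteny_map(identical_pair)
        results = sp.lift_genes(identical_pair.genes,
                                identical_pair.derived_scaffolds, cmap)
        for g, r in zip(identical_pair.genes, results):
            assert r.status == "mapped"
            assert r.method == "projection"
            assert (r.seq_id, r.start, r.end, r.strand) == \
                ("scaffold_1", g.start, g.end, g.strand)

    def test_95pct_exact_recovery_on_mutated_pair(self, rearranged_pair):
        pair = rearranged_pair  # sub_rate 0.01, inversion + translocation
        cmap, _ = synteny_map(pair)
        results = {r.gene_id: r for r in
                   sp.lift_genes(pair.genes, pair.derived_scaffolds, cmap)}
        intact = [g for g in pair.genes if pair.gene_images[g.gene_id].intact]
        assert len(intact) >= 8
        exact = 0
        for g in intact:
            im = pair.gene_images[g.gene_id]
            r = results[g.gene_id]
            if (r.seq_id, r.start, r.end, r.strand) == \
                    (im.scaffold, im.start, im.end, im.strand):
                exact += 1
        assert exact / len(intact) >= 0.95

    def test_score_monotone_under_substitutions(self, identical_pair):
        g = identical_pair.genes[1]
        prev = global_score(g.cds, g.cds)
        cds = list(g.cds)
        for i, off in enumerate(range(7, 100, 13)):
            cds[off] = {"A": "C", "C": "A", "G": "T", "T": "G"}[cds[off]]
            score = global_score("".join(cds), g.cds)
            assert score <= prev
            prev = score


class TestReconcileOrfs:
    def _results(self, genes):
        return [sp.LiftoverResult(g.gene_id, "projection", g.seq_id, g.start,
                                  g.end, g.strand, 100.0, "mapped")
                for g in genes]

    def test_identical_lists_fully_merge(self):
        genes = [GeneModel("g1", "s", 100, 400, "+"), GeneModel("g2", "s", 600, 900, "-")]
        out = sp.reconcile_orfs(self._results(genes), [GeneModel(f"ab{i}", g.seq_id,
                                g.start, g.end, g.strand) for i, g in enumerate(genes)])
        assert len(out) == 2
        assert all(g.product == "merged:mapped+ab_initio" for g in out)
        assert [g.gene_id for g in out] == ["g1", "g2"]

    def test_nonoverlapping_orf_retained_as_novel(self):
        mapped = self._results([GeneModel("g1", "s", 100, 400, "+")])
        novel = GeneModel("orf9", "s", 5_000, 5_300, "+")
        out = sp.reconcile_orfs(mapped, [novel])
        products = {g.gene_id: g.product for g in out}
        assert products["orf9"] == "ab_initio_only"

    def test_reciprocal_overlap_merge_uses_mapped_coordinates(self):
        mapped = self._results([GeneModel("g1", "s", 1_000, 2_000, "+")])
        # 60%/55% reciprocal overlap, same strand
        ab = GeneModel("ab1", "s", 1_400, 2_490, "+")
        out = sp.reconcile_orfs(mapped, [ab], min_reciprocal_overlap=0.5)
        assert len(out) == 1
        assert (out[0].gene_id, out[0].start, out[0].end) == ("g1", 1_000, 2_000)

    def test_opposite_strand_never_merges(self):
        mapped = self._results([GeneModel("g1", "s", 1_000, 2_000, "+")])
        ab = GeneModel("ab1", "s", 1_000, 2_000, "-")
        out = sp.reconcile_orfs(mapped, [ab])
        assert len(out) == 2


class TestFindOrfs:
    def test_finds_planted_genes(self, identical_pair):
        # the finder reports the longest ORF per stop-to-stop segment, so a
        # chance upstream in-frame ATG may extend a planted gene; the reported
        # ORF must share the gene's stop boundary and contain it
        orfs = sp.find_orfs({"reference": identical_pair.reference}, min_len=300)
        for g in identical_pair.genes:
            anchored = [
                o for o in orfs
                if o.strand == g.strand and o.start <= g.start and o.end >= g.end
                and (o.end == g.end if g.strand == "+" else o.start == g.start)
            ]
            assert len(anchored) == 1
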