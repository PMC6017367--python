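import numpy as np
import pytest

import famchar as fc
from famchar import align
from famchar.mining import DomainHit, assign_names, filter_candidates
from famchar.models import FamcharError, GeneModel


class TestBuildProfile:
    def test_single_ungapped_sequence_full_width(self):
        aln = {"a": "ACDEFGHIKL", "#ann": "..*......."}
        prof = fc.build_profile(aln, pseudocount=1.0)
        assert prof.consensus_length == 10
        assert prof.active_site_column == 2
        assert prof.consensus == "ACDEFGHIKL"

    def test_duplicate_sequences_idempotent(self):
        ann = {"#ann": "*" + "." * 9}
        one = fc.build_profile({"a": "ACDEFGHIKL", **ann})
        two = fc.build_profile({"a": "ACDEFGHIKL", "b": "ACDEFGHIKL", **ann})
        np.testing.assert_allclose(one.matrix, two.matrix)

    def test_ragged_alignment_rejected(self):
        with pytest.raises(FamcharError, match="ragged"):
            fc.build_profile({"a": "ACDE", "b": "ACD", "#ann": "*..."})

    def test_consensus_outscores_shuffles(self, seed_profile):
        """The seed consensus must beat 1000 shuffles of itself (shuffle oracle)."""
        cons = align.encode(seed_profile.consensus)
        cons_score, _, _ = align.local_align(cons, seed_profile.matrix)
        rng = np.random.default_rng(0)
        best_shuffle = max(
            align.local_align(rng.permutation(cons), seed_profile.matrix)[0]
            for _ in range(1000))
        assert cons_score > best_shuffle


class TestLocalAlignment:
    def test_gapless_score_equals_bruteforce(self):
        """With prohibitive gap costs the DP must equal exhaustive gapless search."""
        rng = np.random.default_rng(5)
        for _ in range(10):
            ncols = int(rng.integers(5, 21))
            profile = rng.normal(0, 2, size=(ncols, 20))
            seq = rng.integers(0, 20, size=int(rng.integers(10, 61)))
            score, _, _ = align.local_align(seq, profile, gap_open=1e9, gap_ext=1e9)
            best = 0.0
            for qstart in range(len(seq)):          # all start/end pairs, all phases
                for cstart in range(ncols):
                    total = 0.0
                    for k in range(min(len(seq) - qstart, ncols - cstart)):
                        total += profile[cstart + k, seq[qstart + k]]
                        best = max(best, total)
            assert score == pytest.approx(best, abs=1e-9)

    def test_empty_inputs_score_zero(self):
        assert align.local_align(np.array([], dtype=np.int64), np.zeros((3, 20)))[0] == 0.0


class TestScanProteome:
    def test_empty_proteome_empty_hits(self, seed_profile):
        assert fc.scan_proteome(seed_profile, {}, n_shuffles=50) == []

    def test_implanted_domain_span_recovered(self, seed_profile):
        rng = np.random.default_rng(9)
        aa = list("ACDEFGHIKLMNPQRSTVWY")
        cons = fc.DEFAULT_CONSENSUS
        prot = "".join(rng.choice(aa, 49)) + cons + "".join(rng.choice(aa, 40))
        fill = {f"bg{i}": "".join(rng.choice(aa, 200)) for i in range(5)}
        hits = fc.scan_proteome(seed_profile, {"target": prot, **fill},
                                seed=1, n_shuffles=300)
        (hit,) = [h for h in hits if h.gene_id == "target"]
        assert abs(hit.target_span[0] - 50) <= 3
        assert abs(hit.target_span[1] - (49 + len(cons))) <= 3
        assert hit.coverage > 0.9

    def test_decoy_proteome_rarely_hits(self, seed_profile):
        rng = np.random.default_rng(17)
        aa = list("ACDEFGHIKLMNPQRSTVWY")
        decoys = {f"d{i}": "".join(rng.choice(aa, 250)) for i in range(200)}
        hits = fc.scan_proteome(seed_profile, decoys, e_cutoff=0.01,
                                seed=2, n_shuffles=500)
        assert len(hits) <= 2

    def test_bad_symbols_skip_record_with_warning(self, seed_profile):
        with pytest.warns(UserWarning, match="skipped"):
            hits = fc.scan_proteome(seed_profile, {"bad": "ACDEX"}, n_shuffles=50)
        assert hits == []

    def test_lower_cutoff_never_adds_hits(self, small_genome, seed_profile):
        loose = fc.scan_proteome(seed_profile, small_genome.bundle.proteins,
                                 e_cutoff=0.01, seed=3, n_shuffles=300)
        strict = fc.scan_proteome(seed_profile, small_genome.bundle.proteins,
                                  e_cutoff=0.0001, seed=3, n_shuffles=300)
        assert {h.gene_id for h in strict} <= {h.gene_id for h in loose}


class TestConfirmBySimilarity:
    def test_identity_retained_random_dropped(self, seed_profile):
        rng = np.random.default_rng(13)
        aa = list("ACDEFGHIKLMNPQRSTVWY")
        ref = fc.DEFAULT_CONSENSUS
        proteins = {"same": ref, "rand": "".join(rng.choice(aa, len(ref)))}
        hits = [DomainHit(g, 100.0, 1e-10, (1, len(ref)), (1, 150), 1.0)
                for g in proteins]
        # a random sequence scores far below an identical one; threshold between
        kept = fc.confirm_by_similarity(hits, proteins, {"r1": ref}, bit_threshold=100)
        assert [h.gene_id for h in kept] == ["same"]

    def test_zero_threshold_keeps_everything(self, seed_profile):
        proteins = {"a": "ACDEFGHIKL" * 5}
        hits = [DomainHit("a", 10.0, 1e-3, (1, 50), (1, 50), 1.0)]
        assert fc.confirm_by_similarity(hits, proteins, {"r": "ACDEFGHIKL"}, 0.0) == hits

    def test_empty_hits_ok(self):
        assert fc.confirm_by_similarity([], {}, {"r": "ACD"}, 10) == []


def _hit(gene, coverage):
    return DomainHit(gene, 50.0, 1e-6, (1, 100), (1, 100), coverage)


class TestFilterCandidates:
    def test_bookkeeping_is_conserved(self, small_genome, seed_profile):
        hits = fc.scan_proteome(seed_profile, small_genome.bundle.proteins,
                                seed=5, n_shuffles=300)
        cs = fc.filter_candidates(hits, small_genome.bundle.proteins)
        assert len(cs.accepted) + len(cs.removed_incomplete) + len(cs.removed_redundant) \
            == len(hits)
        assert not (set(cs.accepted) & set(cs.removed_incomplete))
        assert not (set(cs.accepted) & set(cs.removed_redundant))

    def test_all_identical_keeps_one(self):
        proteins = {f"g{i}": "ACDEFGHIKL" * 10 for i in range(5)}
        cs = fc.filter_candidates([_hit(g, 1.0) for g in proteins], proteins)
        assert len(cs.accepted) == 1
        assert len(cs.removed_redundant) == 4
        assert cs.accepted == ["g0"]  # lexicographic tie-break among equals

    def test_empty_input(self):
        cs = fc.filter_candidates([], {})
        assert cs.accepted == [] and cs.hits == []

    def test_raising_coverage_never_adds_accepted(self):
        rng = np.random.default_rng(1)
        aa = list("ACDEFGHIKLMNPQRSTVWY")
        proteins = {f"g{i}": "".join(rng.choice(aa, 120)) for i in range(8)}
        hits = [_hit(g, float(rng.uniform(0.3, 1.0))) for g in proteins]
        prev = None
        for cov in (0.3, 0.5, 0.7, 0.9):
            acc = set(fc.filter_candidates(hits, proteins, min_coverage=cov).accepted)
            if prev is not None:
                assert acc <= prev
            prev = acc


class TestAssignNames:
    def make(self, gid, scaffold, start):
        return GeneModel(gid, scaffold, start, start + 99, "+", ((start, start + 99),))

    def test_orders_by_position(self):
        models = {"x": self.make("x", "scaffold1", 500),
                  "y": self.make("y", "scaffold1", 100)}
        assert fc.assign_names(["x", "y"], models, "FAM") == {"FAM1": "y", "FAM2": "x"}

    def test_natural_scaffold_ordering(self):
        models = {"a": self.make("a", "scaffold10", 100),
                  "b": self.make("b", "scaffold2", 100)}
        names = fc.assign_names(["a", "b"], models, "FAM")
        assert names == {"FAM1": "b", "FAM2": "a"}

    def test_single_gene(self):
        models = {"a": self.make("a", "s1", 5)}
        assert fc.assign_names(["a"], models, "P") == {"P1": "a"}

    def test_missing_model_is_an_error(self):
        with pytest.raises(FamcharError, match="ghost"):
            fc.assign_names(["ghost"], {}, "FAM")


class TestRecovery:
    def test_mine_family_accepts_implants_rejects_decoys(self, small_genome, seed_profile):
        b = small_genome.bundle
        models = {g.gene_id: g for g in b.genes}
        cs = fc.mine_family(seed_profile, b.proteins, models, prefix="FAM",
                            seed=5, n_shuffles=300)
        truth = small_genome.manifest.set_index("gene_id").category.to_dict()
        accepted_cats = {truth[g] for g in cs.accepted}
        assert "decoy" not in accepted_cats
        assert "incomplete" not in accepted_cats
        # every complete-domain implant is accounted for: accepted or redundant
        complete = {g for g, c in truth.items() if c in ("true", "redundant")}
        assert complete == set(cs.accepted) | set(cs.removed_redundant)
        assert len(cs.names) == len(cs.accepted)

    def test_uev_flags_match_manifest(self, small_genome, seed_profile):
        b = small_genome.bundle
        models = {g.gene_id: g for g in b.genes}
        cs = fc.mine_family(seed_profile, b.proteins, models, seed=5, n_shuffles=300)
        members = fc.characterize_family(cs, b.proteins, models, profile=seed_profile)
        truth = small_genome.manifest.set_index("gene_id").uev.to_dict()
        assert all(m.uev == truth[m.locus_id] for m in members)
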