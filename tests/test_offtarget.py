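"""Off-target search, distance null analysis, and overlap annotation."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from oracle_offtarget import brute_force_sites
from triomut.core_io import FormatError, GenomeSequence, SampleCall, VariantRecord
from triomut.offtarget import (
    CIBand,
    GuideQuery,
    OffTargetSite,
    annotate_variant_site_overlap,
    ci_band,
    consensus_sites,
    distance_analysis,
    ks_compare,
    nearest_distances,
    predict_offtargets,
    revcomp,
    sample_null_positions,
)


def random_genome(rng, length=5_000, name="chr1"):
    seq = "".join(rng.choice(list("ACGT"), size=length))
    return GenomeSequence("rand", {name: seq}, {name: True})


def site_keys(sites):
    return sorted((s.chrom, s.start, s.strand, s.mismatch_total, s.mismatch_seed)
                  for s in sites)


class TestGuideQuery:
    def test_validation(self):
        with pytest.raises(ValueError):
            GuideQuery("g", "ACGT")  # not 20 nt
        with pytest.raises(ValueError):
            GuideQuery("g", "A" * 20, pam_pattern="NGGG")
        with pytest.raises(ValueError):
            GuideQuery("g", "A" * 20, max_mismatch_total=1, max_seed_mismatch=2)


class TestPredict:
    def test_planted_exact_site_found(self):
        rng = np.random.default_rng(0)
        guide = GuideQuery("g1", "".join(rng.choice(list("ACGT"), size=20)))
        g = random_genome(rng, 10_000)
        seq = list(g.sequences["chr1"])
        seq[4000:4023] = list(guide.protospacer + "TGG")
        genome = GenomeSequence("p", {"chr1": "".join(seq)}, {"chr1": True})
        sites = predict_offtargets(genome, guide)
        exact = [s for s in sites if s.mismatch_total == 0]
        assert [(s.start, s.strand) for s in exact] == [(4000, "+")]
        assert site_keys(sites) == brute_force_sites(genome.sequences, guide)

    def test_zero_budget_without_match_is_empty(self):
        rng = np.random.default_rng(1)
        guide = GuideQuery(
            "g", "".join(rng.choice(list("ACGT"), size=20)),
            max_mismatch_total=0, max_seed_mismatch=0,
        )
        assert predict_offtargets(random_genome(rng, 3_000), guide) == []

    def test_n_bases_never_match(self):
        guide = GuideQuery("g", "A" * 20, max_mismatch_total=0, max_seed_mismatch=0)
        genome = GenomeSequence(
            "n", {"chr1": "A" * 19 + "N" + "AGG" + "A" * 5}, {"chr1": True}
        )
        assert predict_offtargets(genome, guide) == []
        # and an N inside the PAM fails even the N pattern position
        genome2 = GenomeSequence(
            "n2", {"chr1": "A" * 20 + "NGG" + "A" * 5}, {"chr1": True}
        )
        assert predict_offtargets(genome2, guide) == []

    def test_empty_genome_rejected(self):
        with pytest.raises(FormatError):
            predict_offtargets(
                GenomeSequence("e", {}, {}), GuideQuery("g", "A" * 20)
            )

    @pytest.mark.parametrize("seed", range(6))
    def test_oracle_equivalence_randomized(self, seed):
        rng = np.random.default_rng(seed)
        genome = random_genome(rng, 8_000)
        guide = GuideQuery(
            f"g{seed}",
            "".join(rng.choice(list("ACGT"), size=20)),
            pam_pattern=rng.choice(["NGG", "NRG"]),
            max_mismatch_total=int(rng.integers(3, 7)),
            max_seed_mismatch=int(rng.integers(0, 3)),
        )
        assert site_keys(predict_offtargets(genome, guide)) == brute_force_sites(
            genome.sequences, guide
        )

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(
        seq=st.text(alphabet="ACGTN", min_size=40, max_size=300),
        proto=st.text(alphabet="ACGT", min_size=20, max_size=20),
        budget=st.integers(min_value=0, max_value=8),
        seed_budget=st.integers(min_value=0, max_value=3),
    )
    def test_oracle_equivalence_property(self, seq, proto, budget, seed_budget):
        guide = GuideQuery(
            "h", proto, max_mismatch_total=max(budget, seed_budget),
            max_seed_mismatch=seed_budget,
        )
        genome = GenomeSequence("h", {"c": seq}, {"c": True})
        assert site_keys(predict_offtargets(genome, guide)) == brute_force_sites(
            genome.sequences, guide
        )

    def test_strand_symmetry(self):
        rng = np.random.default_rng(5)
        genome = random_genome(rng, 6_000)
        flipped = GenomeSequence(
            "rc", {"chr1": revcomp(genome.sequences["chr1"])}, {"chr1": True}
        )
        guide = GuideQuery(
            "g", "".join(rng.choice(list("ACGT"), size=20)),
            max_mismatch_total=6, max_seed_mismatch=2,
        )
        fwd = predict_offtargets(genome, guide)
        rev = predict_offtargets(flipped, guide)
        L = len(genome.sequences["chr1"])
        mapped = sorted(
            ("chr1", L - s.end, {"+": "-", "-": "+"}[s.strand],
             s.mismatch_total, s.mismatch_seed)
            for s in rev
        )
        assert mapped == site_keys(fwd)

    def test_budget_nesting(self):
        rng = np.random.default_rng(9)
        genome = random_genome(rng, 20_000)
        proto = "".join(rng.choice(list("ACGT"), size=20))
        prev: set = set()
        for m in range(0, 7):
            guide = GuideQuery(
                "g", proto, max_mismatch_total=m, max_seed_mismatch=min(m, 2)
            )
            keys = {s.key for s in predict_offtargets(genome, guide)}
            assert prev <= keys
            prev = keys


class TestConsensus:
    def test_identity_disjoint_and_nesting(self):
        rng = np.random.default_rng(3)
        genome = random_genome(rng, 30_000)
        proto = "".join(rng.choice(list("ACGT"), size=20))
        loose = predict_offtargets(
            genome, GuideQuery("g", proto, max_mismatch_total=6, max_seed_mismatch=3)
        )
        strict = predict_offtargets(
            genome, GuideQuery("g", proto, max_mismatch_total=4, max_seed_mismatch=2)
        )
        assert consensus_sites(loose, loose) == loose
        assert consensus_sites(loose, []) == []
        # nested budgets: the consensus is exactly the stricter list's keys
        assert {s.key for s in consensus_sites(loose, strict)} == {
            s.key for s in strict
        }


def mksite(start, chrom="chr1", strand="+", guide="g"):
    return OffTargetSite(
        chrom=chrom, start=start, end=start + 20, strand=strand,
        mismatch_total=1, mismatch_seed=0, matched_sequence="", guide_name=guide,
    )


class TestDistances:
    def test_inside_interval_is_zero(self):
        d, _ = nearest_distances([("chr1", 225)], [mksite(220)])
        assert d == [0]

    def test_hand_arithmetic(self):
        d, _ = nearest_distances([("chr1", 100)], [mksite(220)])
        assert d == [120]
        # downstream side: distance to the last base of [220, 240)
        d, _ = nearest_distances([("chr1", 300)], [mksite(220)])
        assert d == [300 - 239]

    def test_least_distance_over_many_sites(self):
        sites = [mksite(s) for s in (50, 400, 1000)]
        d, _ = nearest_distances([("chr1", 380)], sites)
        assert d == [20]
        perm, _ = nearest_distances([("chr1", 380)], list(reversed(sites)))
        assert perm == d

    def test_chromosome_without_sites_excluded(self):
        d, n_exc = nearest_distances(
            [("chr1", 10), ("chr2", 10)], [mksite(100)]
        )
        assert len(d) == 1 and n_exc == 1

    def test_empty_sites_error(self):
        with pytest.raises(ValueError):
            nearest_distances([("chr1", 10)], [])


class TestNullSampling:
    POOL = [("chr1", i * 7) for i in range(500)] + [("chr2", i * 3) for i in range(250)]

    def test_deterministic_per_seed(self):
        a = sample_null_positions(self.POOL, 100, seed=5)
        b = sample_null_positions(self.POOL, 100, seed=5)
        assert a == b
        assert a != sample_null_positions(self.POOL, 100, seed=6)

    def test_without_replacement_full_draw_is_the_pool(self):
        assert sample_null_positions(
            self.POOL, len(self.POOL), seed=0, replace=False
        ) == self.POOL

    def test_composition_matches_pool(self):
        sample = sample_null_positions(self.POOL, 30_000, seed=1)
        frac = sum(1 for c, _ in sample if c == "chr1") / len(sample)
        assert frac == pytest.approx(500 / 750, abs=0.02)

    def test_empty_pool_error(self):
        with pytest.raises(ValueError):
            sample_null_positions([], 10, seed=0)


class TestKS:
    def test_identical_samples(self):
        x = list(range(100))
        stat, p = ks_compare(x, x)
        assert stat == 0.0 and p == 1.0

    def test_statistic_bounded(self):
        rng = np.random.default_rng(0)
        stat, _ = ks_compare(rng.normal(size=50), rng.normal(5, 1, size=50))
        assert 0.0 <= stat <= 1.0

    def test_empty_error(self):
        with pytest.raises(ValueError):
            ks_compare([], [1.0])


class TestCIBand:
    NULL = list(np.random.default_rng(2).integers(0, 10_000, size=400).astype(float))

    def test_deterministic_per_seed(self):
        a = ci_band(self.NULL, seed=3)
        b = ci_band(self.NULL, seed=3)
        assert np.array_equal(a.lower, b.lower) and np.array_equal(a.upper, b.upper)

    def test_band_contains_ecdf_and_monotone_level(self):
        band = ci_band(self.NULL, level=0.95, seed=0)
        full = ci_band(self.NULL, level=1.0, seed=0)
        assert np.all(full.lower <= band.lower + 1e-12)
        assert np.all(band.upper <= full.upper + 1e-12)

    def test_band_narrows_with_larger_null(self):
        rng = np.random.default_rng(4)
        small = list(rng.exponential(1000, size=100))
        large = list(rng.exponential(1000, size=10_000))
        w_small = np.mean(ci_band(small, seed=0).upper - ci_band(small, seed=0).lower)
        w_large = np.mean(ci_band(large, seed=0).upper - ci_band(large, seed=0).lower)
        assert w_large < w_small

    def test_empty_error(self):
        with pytest.raises(ValueError):
            ci_band([])


class TestAnalysisAndOverlap:
    def test_distance_analysis_end_to_end(self):
        rng = np.random.default_rng(6)
        sites = [mksite(int(s)) for s in rng.integers(0, 50_000, size=20)]
        pool = [("chr1", int(p)) for p in rng.integers(0, 50_000, size=500)]
        observed = pool[:40]
        res = distance_analysis(observed, pool, sites, n_null=2_000, seed=1)
        assert len(res.null) == 2_000
        assert 0.0 <= res.ks_statistic <= 1.0
        assert 0.0 <= res.p_value <= 1.0
        assert isinstance(res.band, CIBand)

    def test_variant_overlap_boundaries(self):
        call = {"O": SampleCall("AB", 30, (40, 0, 25), 0.02)}
        inside = VariantRecord("chr1", 231, "A", "G", calls=call)  # 0-based 230
        before = VariantRecord("chr1", 220, "A", "G", calls=call)  # 0-based 219
        after = VariantRecord("chr1", 241, "A", "G", calls=call)  # 0-based 240
        ann, per_guide = annotate_variant_site_overlap(
            [inside, before, after], [mksite(220)]
        )
        assert set(ann) == {inside.key}
        assert per_guide == {"g": 1}

    def test_zero_sites_zero_annotations(self):
        call = {"O": SampleCall("AB", 30, (40, 0, 25), 0.02)}
        v = VariantRecord("chr1", 231, "A", "G", calls=call)
        ann, per_guide = annotate_variant_site_overlap([v], [])
        assert ann == {} and per_guide == {}
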