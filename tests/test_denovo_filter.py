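"""Filter cascade: stage predicates, trace behavior, and ground-truth recall."""

from __future__ import annotations

import itertools

import pytest

from triomut.core_io import (
    KnownVariantDatabase,
    SampleCall,
    TrioContext,
    VariantRecord,
)
from triomut.denovo_filter import (
    FilterCriteria,
    intersect_callsets,
    run_cascade,
    stage_cohort_unique,
    stage_depth,
    stage_known_db,
    stage_pl,
    stage_review,
    stage_softclip,
)

TRIO = TrioContext("S", "D", "O", ("S", "D", "O", "X"))
CRIT = FilterCriteria()

GOOD_OFF = dict(genotype="AB", depth=30, pl=(40, 0, 25), softclip_fraction=0.02)
GOOD_PAR = dict(genotype="AA", depth=30, pl=(0, 60, 90), softclip_fraction=0.02)


def mkvar(pos=100, **overrides):
    """A variant that passes every stage unless a role call is overridden."""
    calls = {
        "S": SampleCall(**GOOD_PAR),
        "D": SampleCall(**GOOD_PAR),
        "O": SampleCall(**GOOD_OFF),
        "X": SampleCall(**GOOD_PAR),
    }
    for sid, kwargs in overrides.items():
        base = dict(GOOD_OFF if sid == "O" else GOOD_PAR)
        base.update(kwargs)
        calls[sid] = SampleCall(**base)
    return VariantRecord("chr1", pos, "A", "G", calls=calls)


class TestCohortUnique:
    def test_private_het_kept(self):
        assert stage_cohort_unique({mkvar()}, TRIO) == {mkvar()}

    def test_parental_carrier_removed(self):
        v = mkvar(S=dict(genotype="AB"))
        assert stage_cohort_unique({v}, TRIO) == set()

    def test_non_trio_cohort_carrier_removed(self):
        v = mkvar(X=dict(genotype="BB"))
        assert stage_cohort_unique({v}, TRIO) == set()

    def test_offspring_homref_removed(self):
        v = mkvar(O=dict(genotype="AA", pl=(0, 60, 90)))
        assert stage_cohort_unique({v}, TRIO) == set()


class TestKnownDb:
    def test_empty_db_identity(self):
        s = {mkvar(p) for p in range(1, 20)}
        assert stage_known_db(s, KnownVariantDatabase(frozenset())) == s

    def test_constructed_overlap(self):
        s = {mkvar(p) for p in range(1, 101)}
        db = KnownVariantDatabase(
            frozenset(("chr1", p, "A", "G") for p in range(1, 38))
        )
        assert len(stage_known_db(s, db)) == 63

    def test_superset_db_empties(self):
        s = {mkvar(p) for p in range(1, 10)}
        db = KnownVariantDatabase(frozenset(v.key for v in s))
        assert stage_known_db(s, db) == set()


class TestDepth:
    @pytest.mark.parametrize(
        "ds,dd,do,kept",
        [
            (11, 30, 20, False),  # parent below 12
            (12, 12, 20, True),  # parent exactly at 12 passes
            (20, 21, 4, False),  # 4 < 41/10: allelic imbalance
            (20, 20, 4, True),  # exactly one tenth of the parental sum passes
            (20, 20, 3, False),
        ],
    )
    def test_boundaries(self, ds, dd, do, kept):
        v = mkvar(S=dict(depth=ds), D=dict(depth=dd), O=dict(depth=do))
        out = stage_depth({v}, TRIO, CRIT)
        assert (v in out) is kept


class TestPL:
    def test_textbook_pattern_kept(self):
        assert stage_pl({mkvar()}, TRIO, CRIT) == {mkvar()}

    def test_weak_offspring_homref_evidence_removed(self):
        v = mkvar(O=dict(pl=(15, 0, 25)))
        assert stage_pl({v}, TRIO, CRIT) == set()

    def test_weak_parent_het_evidence_removed(self):
        v = mkvar(D=dict(pl=(0, 12, 80)))
        assert stage_pl({v}, TRIO, CRIT) == set()

    def test_boundary_is_strict(self):
        # ">20" means 20 itself fails; 21 passes
        assert stage_pl({mkvar(O=dict(pl=(20, 0, 25)))}, TRIO, CRIT) == set()
        v = mkvar(O=dict(pl=(21, 0, 1)))
        assert stage_pl({v}, TRIO, CRIT) == {v}

    def test_non_normalized_pl_excluded_with_warning(self):
        v = mkvar(S=dict(pl=(5, 40, 90)))
        with pytest.warns(UserWarning, match="non-normalized"):
            assert stage_pl({v}, TRIO, CRIT) == set()


class TestSoftclip:
    @pytest.mark.parametrize("scf,kept", [(0.05, True), (0.10, True), (0.15, False)])
    def test_bound(self, scf, kept):
        v = mkvar(O=dict(softclip_fraction=scf))
        assert (v in stage_softclip({v}, TRIO, CRIT)) is kept

    def test_constructed_fractions(self):
        vs = {mkvar(p, O=dict(softclip_fraction=0.2 if p <= 6 else 0.03))
              for p in range(1, 21)}
        assert len(stage_softclip(vs, TRIO, CRIT)) == 14

    def test_missing_scf_passes_with_warning(self):
        v = mkvar(O=dict(softclip_fraction=None))
        with pytest.warns(UserWarning, match="missing soft-clip"):
            assert stage_softclip({v}, TRIO, CRIT) == {v}


class TestReview:
    def test_isolated_snv_unflagged(self, toy_genome):
        v = VariantRecord("chr1", 25, "T", "C", calls=mkvar().calls)
        survivors, ann = stage_review({v}, toy_genome, CRIT)
        assert survivors == {v}
        assert ann[v.key] == ()

    def test_homopolymer_flagged(self, toy_genome):
        # chrT has a 12-bp T run starting at 1-based position 11
        v = VariantRecord("chrT", 16, "T", "C", calls=mkvar().calls)
        _, ann = stage_review({v}, toy_genome, CRIT)
        assert "homopolymer" in ann[v.key]

    def test_ambiguous_base_proximity_flagged(self, toy_genome):
        # chrT has NNN at 1-based positions 33-35
        v = VariantRecord("chrT", 30, "T", "A", calls=mkvar().calls)
        _, ann = stage_review({v}, toy_genome, CRIT)
        assert "ambiguous_base" in ann[v.key]

    def test_cluster_flagged_and_strict_mode_removes(self, toy_genome):
        a = VariantRecord("chr1", 20, "T", "C", calls=mkvar().calls)
        b = VariantRecord("chr1", 24, "T", "G", calls=mkvar().calls)
        survivors, ann = stage_review({a, b}, toy_genome, CRIT)
        assert survivors == {a, b}  # non-destructive by default
        assert all("variant_cluster" in ann[v.key] for v in (a, b))
        strict, _ = stage_review({a, b}, toy_genome, CRIT, strict=True)
        assert strict == set()


class TestCascade:
    def test_empty_inputs_zero_trace(self, clean_sim):
        trio = clean_sim.trios[0]
        res = run_cascade(
            set(), set(), trio, clean_sim.db, CRIT, clean_sim.genome
        )
        assert all(n == 0 for _, n in res.trace.stages)
        assert res.candidates == []

    @pytest.mark.parametrize("vclass", ["SNV", "INDEL"])
    def test_recall_of_planted_denovo_is_total(self, clean_sim, vclass):
        truth_of = (
            clean_sim.truth.denovo_snv_keys
            if vclass == "SNV"
            else clean_sim.truth.denovo_indel_keys
        )
        for trio in clean_sim.trios:
            res = run_cascade(
                clean_sim.caller_a, clean_sim.caller_b, trio, clean_sim.db,
                CRIT, clean_sim.genome, vclass=vclass,
            )
            assert {c.variant.key for c in res.candidates} == truth_of(
                trio.offspring_id
            )
            assert res.trace.is_monotone()
            assert res.mu_alpha == len(truth_of(trio.offspring_id))

    def test_artifacts_all_removed_and_trace_monotone(self, artifact_sim):
        for trio in artifact_sim.trios:
            res = run_cascade(
                artifact_sim.caller_a, artifact_sim.caller_b, trio,
                artifact_sim.db, CRIT, artifact_sim.genome,
            )
            found = {c.variant.key for c in res.candidates}
            assert found == artifact_sim.truth.denovo_snv_keys(trio.offspring_id)
            planted = artifact_sim.truth.artifact_keys[trio.offspring_id]
            for keys in planted.values():
                assert not (keys & found)
            assert res.trace.is_monotone()

    def test_brute_force_predicate_equivalence(self, artifact_sim):
        """The staged cascade equals an all-at-once per-variant predicate."""
        sim = artifact_sim
        crit = CRIT
        for trio in sim.trios:
            res = run_cascade(
                sim.caller_a, sim.caller_b, trio, sim.db, crit, sim.genome
            )
            keys_b = {v.key for v in sim.caller_b}
            expected = set()
            for v in sim.caller_a:
                if v.vclass != "SNV" or v.key not in keys_b or v.key in sim.db:
                    continue
                s, d, o = (v.calls.get(x) for x in trio.role_ids)
                others = [
                    v.calls[x] for x in trio.cohort_ids
                    if x != trio.offspring_id and x in v.calls
                ]
                if o.genotype not in ("AB", "BB"):
                    continue
                if any(c.genotype in ("AB", "BB") for c in others):
                    continue
                if s.depth < 12 or d.depth < 12 or 10 * o.depth < s.depth + d.depth:
                    continue
                if not (s.pl[0] == 0 and s.pl[1] > 20 and s.pl[2] > 20):
                    continue
                if not (d.pl[0] == 0 and d.pl[1] > 20 and d.pl[2] > 20):
                    continue
                if not (o.pl[0] > 20 and o.pl[1] == 0 and o.pl[2] > 0):
                    continue
                if o.softclip_fraction is not None and o.softclip_fraction > 0.10:
                    continue
                expected.add(v.key)
            assert {c.variant.key for c in res.candidates} == expected

    def test_stage_order_does_not_change_final_set(self, artifact_sim):
        sim = artifact_sim
        trio = sim.trios[0]
        base = intersect_callsets(
            {v for v in sim.caller_a if v.vclass == "SNV"},
            {v for v in sim.caller_b if v.vclass == "SNV"},
        )
        stages = [
            lambda s: stage_cohort_unique(s, trio),
            lambda s: stage_known_db(s, sim.db),
            lambda s: stage_depth(s, trio, CRIT),
            lambda s: stage_pl(s, trio, CRIT),
            lambda s: stage_softclip(s, trio, CRIT),
        ]
        reference = None
        for perm in itertools.permutations(range(5)):
            current = set(base)
            for i in perm:
                current = stages[i](current)
            keys = {v.key for v in current}
            if reference is None:
                reference = keys
            assert keys == reference

    def test_bad_vclass_rejected(self, clean_sim):
        with pytest.raises(ValueError):
            run_cascade(
                set(), set(), clean_sim.trios[0], clean_sim.db, CRIT,
                clean_sim.genome, vclass="CNV",
            )
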