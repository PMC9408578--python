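import dataclasses

import numpy as np
import pytest

from lmecg import (
    CollateralStatus,
    CulpritGroup,
    FinePattern,
    MainPattern,
    Sex,
    builtin_criteria,
    classify_fine,
    classify_main,
    default_spec,
    depressed_lead_count,
    generate_exact,
    generate_sampled,
    realize_record,
    validate_spec,
)
from lmecg.cohort import GenerationError

GROUPS = list(CulpritGroup)

# published per-group criterion-row counts, canonical group order
TABLE1_ROWS = {
    "nstemi": (39, 83, 12, 6, 14, 7),
    "avr_isolated": (11, 53, 5, 4, 8, 7),
    "avr_v1": (5, 26, 4, 2, 3, 0),
    "avr_avl": (23, 4, 3, 0, 3, 0),
    "stemi": (45, 6, 73, 92, 77, 98),
    "v1_v5": (1, 1, 35, 42, 0, 0),
    "v2_v5": (1, 0, 0, 2, 0, 0),
    "i_avl_v1_v5": (14, 3, 32, 21, 0, 0),
    "i_avl_v2_v5": (29, 2, 6, 5, 0, 0),
    "inferior": (0, 0, 0, 2, 65, 98),
    "hdavb": (0, 0, 0, 1, 1, 13),
    "rbbb": (5, 1, 7, 10, 1, 3),
    "lbbb": (1, 0, 1, 1, 1, 0),
    "lafb": (31, 11, 7, 13, 3, 0),
    "avr_avl_lafb": (5, 1, 1, 0, 0, 0),
    "i_avl_v2_v5_lafb": (16, 0, 1, 0, 0, 0),
    "bifascicular": (14, 0, 1, 0, 0, 0),
    "avr_avl_bifascicular": (6, 0, 0, 0, 0, 0),
    "i_avl_v2_v5_bifascicular": (6, 0, 0, 0, 0, 0),
}

TABLE2_CELLS = {  # (collateral, non-collateral) within the LM group
    "avr_isolated": (10, 1),
    "avr_v1": (4, 1),
    "avr_avl": (20, 3),
    "stemi": (0, 45),
    "lafb": (7, 24),
    "rbbb": (2, 3),
    "bifascicular": (5, 9),
}


class TestDefaultSpec:
    def test_group_sizes(self, study_spec):
        assert [g.n for g in study_spec.groups] == [84, 89, 85, 98, 91, 105]
        for g in study_spec.groups:
            assert sum(c for c, _ in g.rows) == g.n

    def test_lm_archetype_allocation(self, study_spec):
        lm = study_spec.group_spec(CulpritGroup.LM_OCCLUSION)
        by_fine = {}
        for count, arch in lm.rows:
            by_fine[arch.fine] = by_fine.get(arch.fine, 0) + count
        assert by_fine[FinePattern.P_I_AVL_V2_V5] == 29
        assert by_fine[FinePattern.P_I_AVL_V1_V5] == 14
        assert by_fine[FinePattern.P_AVR_AVL] == 13
        assert by_fine[FinePattern.P_AVR] == 11
        assert by_fine[FinePattern.P_I_AVL_AVR] == 8
        assert by_fine[FinePattern.P_AVR_V1] == 5
        assert by_fine[FinePattern.P_AVR_AVL_PARTIAL_PRECORDIAL] == 2

    def test_subocclusion_nstemi_from_allocation(self, study_spec):
        sub = study_spec.group_spec(CulpritGroup.LM_SUBOCCLUSION)
        from lmecg import FINE_TO_MAIN

        nstemi = sum(
            c for c, a in sub.rows
            if FINE_TO_MAIN[a.fine] is not MainPattern.STEMI
        )
        assert nstemi == 83

    def test_validate_spec_all_pass(self, study_spec):
        results = validate_spec(study_spec)
        failures = [r for r in results if not r.ok]
        assert failures == []
        assert len(results) > 100

    def test_validate_spec_detects_injected_defects(self, study_spec):
        lm = study_spec.group_spec(CulpritGroup.LM_OCCLUSION)
        # drop one STEMI archetype record: STEMI sum 44 != 45
        rows = tuple(
            ((c - 1, a) if i == 0 else (c, a))
            for i, (c, a) in enumerate(lm.rows)
        )
        broken = dataclasses.replace(lm, rows=rows)
        spec = dataclasses.replace(
            study_spec,
            groups=tuple(broken if g is lm else g for g in study_spec.groups),
        )
        names = {r.name for r in validate_spec(spec) if not r.ok}
        assert any("STEMI" in n for n in names)
        with pytest.raises(GenerationError):
            generate_exact(spec)


class TestExactGeneration:
    def test_counts(self, exact_cohort):
        assert len(exact_cohort) == 552
        sizes = [sum(r.group is g for r in exact_cohort) for g in GROUPS]
        assert sizes == [84, 89, 85, 98, 91, 105]

    @pytest.mark.parametrize("criterion", sorted(TABLE1_ROWS))
    def test_reclassification_reproduces_every_table_row(
        self, exact_cohort, criterion
    ):
        reg = builtin_criteria()
        counts = tuple(
            sum(reg[criterion](r) for r in exact_cohort if r.group is g)
            for g in GROUPS
        )
        assert counts == TABLE1_ROWS[criterion]

    def test_collateral_cross_tabulation(self, exact_cohort):
        reg = builtin_criteria()
        lm = [r for r in exact_cohort if r.group is CulpritGroup.LM_OCCLUSION]
        coll = [r for r in lm if r.collateral is not CollateralStatus.NONE]
        non = [r for r in lm if r.collateral is CollateralStatus.NONE]
        assert (len(coll), len(non)) == (34, 50)
        for name, (want_coll, want_non) in TABLE2_CELLS.items():
            assert sum(reg[name](r) for r in coll) == want_coll, name
            assert sum(reg[name](r) for r in non) == want_non, name

    def test_collateral_territory_allocation(self, exact_cohort):
        reg = builtin_criteria()
        lm = [r for r in exact_cohort if r.group is CulpritGroup.LM_OCCLUSION]
        avr_avl_lad = sum(
            reg["avr_avl"](r)
            and r.collateral is CollateralStatus.LAD_TERRITORY
            for r in lm
        )
        assert avr_avl_lad == 15  # 15/23 = 65% of aVR+aVL records
        avr_both = sum(
            classify_fine(r) is FinePattern.P_AVR
            and r.collateral is CollateralStatus.BOTH
            for r in lm
        )
        assert avr_both == 8

    def test_sex_and_mortality_margins(self, exact_cohort):
        males = [sum(r.sex is Sex.MALE for r in exact_cohort if r.group is g)
                 for g in GROUPS]
        assert males == [73, 61, 63, 74, 69, 84]
        died = [sum(bool(r.died_in_hospital) for r in exact_cohort
                    if r.group is g) for g in GROUPS]
        assert died == [37, 10, 8, 4, 1, 1]

    def test_deterministic_under_seed(self, study_spec):
        a = generate_exact(study_spec, seed=3)
        b = generate_exact(study_spec, seed=3)
        assert a == b
        c = generate_exact(study_spec, seed=4)
        assert a != c

    def test_avr_pattern_records_show_diffuse_depression(self, exact_cohort):
        avr = [r for r in exact_cohort
               if classify_fine(r) in (FinePattern.P_AVR, FinePattern.P_AVR_V1)]
        assert avr
        assert all(depressed_lead_count(r, 0.5) >= 7 for r in avr)

    def test_collateral_only_on_lm_records(self, exact_cohort):
        for r in exact_cohort:
            if r.group is not CulpritGroup.LM_OCCLUSION:
                assert r.collateral is None
            else:
                assert r.collateral is not None

    def test_qrs_within_bounds(self, exact_cohort):
        assert all(40 <= r.qrs_ms <= 300 for r in exact_cohort)


class TestSampledGeneration:
    def test_deterministic_and_small_n(self, study_spec):
        a = generate_sampled(study_spec, 5, seed=11)
        b = generate_sampled(study_spec, 5, seed=11)
        assert a == b
        tiny = generate_sampled(study_spec, 1, seed=11)
        assert len(tiny) == 6
        with pytest.raises(ValueError):
            generate_sampled(study_spec, 0, seed=11)

    def test_proportions_and_qrs_converge(self, study_spec):
        # large-n draw for the two groups under test, single record elsewhere
        n = 20_000
        sizes = {g: 1 for g in GROUPS}
        sizes[CulpritGroup.LM_OCCLUSION] = n
        sizes[CulpritGroup.LM_SUBOCCLUSION] = n
        cohort = generate_sampled(study_spec, sizes, seed=2024)
        from lmecg import model1

        lm = [r for r in cohort if r.group is CulpritGroup.LM_OCCLUSION]
        frac = sum(model1(r) for r in lm) / len(lm)
        assert frac == pytest.approx(52 / 84, abs=0.015)
        sub_qrs = np.array([r.qrs_ms for r in cohort
                            if r.group is CulpritGroup.LM_SUBOCCLUSION])
        assert sub_qrs.mean() == pytest.approx(93, abs=4 * 13 / np.sqrt(n))
        assert sub_qrs.std(ddof=1) == pytest.approx(13, rel=0.05)


class TestRealize:
    def test_round_trip_for_every_archetype(self, study_spec, rng):
        for gspec in study_spec.groups:
            for _, arch in gspec.rows:
                for sex in (Sex.MALE, Sex.FEMALE):
                    r = realize_record(arch, sex, rng)
                    assert classify_fine(r) is arch.fine  # checked inside too

    def test_partial_precordial_realisation_band(self, study_spec, rng):
        lm = study_spec.group_spec(CulpritGroup.LM_OCCLUSION)
        arch = next(
            a for _, a in lm.rows
            if a.fine is FinePattern.P_AVR_AVL_PARTIAL_PRECORDIAL
        )
        for _ in range(20):
            r = realize_record(arch, Sex.MALE, rng)
            from lmecg import Lead

            assert 0.5 <= r.st[Lead.V2] <= 1.7
            assert classify_main(r) is MainPattern.AVR_AVL_PATTERN
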