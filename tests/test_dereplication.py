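"""Exogenous-component detection, route merging and final filtration."""

import numpy as np
import pytest

from isoderep.chem_core import MolecularFormula, ReactionKind, mz_from_formula
from isoderep.dereplication import (
    ComponentRecord,
    FilterCriteria,
    SampleSet,
    aggregate_descriptors,
    component_table,
    detect_exogenous,
    final_filter,
    merge_routes,
)
from isoderep.series_detect import FunctionalDescriptor
from isoderep.synthetic import (
    GroundTruth,
    generate_mixture,
    simulate_label_spectrum,
    simulate_sample_set,
    simulate_tag_experiments,
)


def _record(formula, routes=("parenteral",), in_ref=True, support=2, descriptor=None):
    return ComponentRecord(
        formula=formula,
        routes=frozenset(routes),
        in_labeled_ref=in_ref,
        support={r: support for r in routes},
        descriptor=descriptor,
    )


def _distinct_formulas(n, seed=0):
    rng = np.random.default_rng(seed)
    from isoderep.synthetic import _sample_formula

    out, seen = [], set()
    while len(out) < n:
        f = _sample_formula(rng, (150.0, 800.0))
        if f not in seen:
            seen.add(f)
            out.append(f)
    return out


class TestDetectExogenous:
    def test_clean_planted_recovery(self):
        truth = generate_mixture(20, seed=3)
        study = simulate_sample_set(
            truth, background_n=50, seed=3, n_decoys=0, mz_jitter_sd=0.0,
            efficiency=1.0, route_overlap=1.0, n_labeled=3,
        )
        recs = detect_exogenous(study.sample_set, "parenteral")
        assert {r.formula for r in recs} == set(truth.formulas)
        assert all(r.in_labeled_ref for r in recs)

    def test_admin_identical_to_control_yields_nothing(self):
        truth = generate_mixture(10, seed=4)
        study = simulate_sample_set(truth, background_n=50, seed=4, n_decoys=0)
        ss = study.sample_set
        identical = SampleSet(
            control=ss.labeled_admin["parenteral"],
            labeled_admin={"parenteral": ss.labeled_admin["parenteral"]},
            labeled_ref=ss.labeled_ref,
        )
        assert detect_exogenous(identical, "parenteral") == []

    def test_unlabeled_presence_in_control_does_not_mask(self):
        # the control shows the same compound as a bare peak; exogeneity is
        # decided by the D-series, not by peak presence
        truth = generate_mixture(5, seed=5)
        unlabeled = [
            simulate_label_spectrum(truth, ReactionKind.HD_EXCHANGE, efficiency=0.0,
                                    seed=9, sample_id="control_1")
        ]
        labeled = [
            simulate_label_spectrum(truth, ReactionKind.HD_EXCHANGE, efficiency=1.0,
                                    seed=10, sample_id="parenteral_1")
        ]
        ss = SampleSet(control=unlabeled, labeled_admin={"parenteral": labeled},
                       labeled_ref=labeled)
        recs = detect_exogenous(ss, "parenteral")
        assert {r.formula for r in recs} == set(truth.formulas)

    def test_missing_route_raises(self):
        truth = generate_mixture(5, seed=6)
        study = simulate_sample_set(truth, background_n=20, seed=6, n_decoys=0)
        ss = SampleSet(control=study.sample_set.control,
                       labeled_admin={"parenteral": study.sample_set.labeled_admin["parenteral"]},
                       labeled_ref=study.sample_set.labeled_ref)
        with pytest.raises(ValueError):
            detect_exogenous(ss, "oral")


class TestMergeRoutes:
    def test_disjoint_union(self):
        fs = _distinct_formulas(7)
        a = [_record(f, ("parenteral",)) for f in fs[:3]]
        b = [_record(f, ("oral",)) for f in fs[3:]]
        assert len(merge_routes({"parenteral": a, "oral": b})) == 7

    def test_identical_sets_get_both_routes(self):
        fs = _distinct_formulas(5)
        merged = merge_routes(
            {
                "parenteral": [_record(f, ("parenteral",)) for f in fs],
                "oral": [_record(f, ("oral",)) for f in fs],
            }
        )
        assert len(merged) == 5
        assert all(r.routes == frozenset(("parenteral", "oral")) for r in merged)

    def test_inclusion_exclusion_bookkeeping(self):
        # route lists of sizes 448 and 312 sharing 116 formulas merge to 644
        fs = _distinct_formulas(448 + 312 - 116, seed=1)
        parenteral = [_record(f, ("parenteral",)) for f in fs[:448]]
        oral = [_record(f, ("oral",)) for f in fs[448 - 116:]]
        assert len(oral) == 312
        merged = merge_routes({"parenteral": parenteral, "oral": oral})
        assert len(merged) == 644
        both = [r for r in merged if len(r.routes) == 2]
        assert len(both) == 116

    def test_idempotent_and_commutative(self):
        fs = _distinct_formulas(6)
        a = [_record(f, ("parenteral",)) for f in fs[:4]]
        b = [_record(f, ("oral",)) for f in fs[2:]]
        m1 = merge_routes({"parenteral": a, "oral": b})
        m2 = merge_routes({"oral": b, "parenteral": a})
        assert [(r.formula, r.routes) for r in m1] == [(r.formula, r.routes) for r in m2]
        again = merge_routes({"parenteral": m1, "oral": []})
        assert [(r.formula, r.routes) for r in again] == [(r.formula, r.routes) for r in m1]

    def test_descriptor_conflict_flagged(self):
        f = _distinct_formulas(1)[0]
        da = FunctionalDescriptor(f, n_cooh=1)
        db = FunctionalDescriptor(f, n_cooh=2)
        merged = merge_routes(
            {
                "parenteral": [_record(f, ("parenteral",), descriptor=da)],
                "oral": [_record(f, ("oral",), descriptor=db)],
            }
        )
        assert merged[0].descriptor_conflict


class TestFinalFilter:
    def test_low_support_removed(self):
        f = _distinct_formulas(1)[0]
        res = final_filter([_record(f, support=1)], FilterCriteria(min_support=2))
        assert not res.retained and res.attrition["min_support"] == 1

    def test_missing_from_labeled_ref_removed(self):
        f = _distinct_formulas(1)[0]
        res = final_filter([_record(f, in_ref=False)])
        assert not res.retained and res.attrition["labeled_ref"] == 1

    def test_counts_after_rule_application(self):
        fs = _distinct_formulas(10)
        recs = [_record(f) for f in fs]
        # violate one criterion in each of four records
        recs[0] = _record(fs[0], support=1)
        recs[1] = _record(fs[1], in_ref=False)
        recs[2] = _record(MolecularFormula(c=20, h=4, o=2))  # H/C 0.2 < 0.3
        recs[3] = _record(MolecularFormula(c=8, h=2, o=2), support=1)
        res = final_filter(recs)
        assert len(res.retained) == 6
        assert sum(res.attrition.values()) == 4

    def test_output_subset_and_conjunctive(self):
        fs = _distinct_formulas(12, seed=2)
        recs = [
            _record(f, support=1 + (i % 3), in_ref=(i % 4 != 0))
            for i, f in enumerate(fs)
        ]
        loose = final_filter(recs, FilterCriteria(min_support=None, require_labeled_ref=False))
        tight = final_filter(recs, FilterCriteria(min_support=2, require_labeled_ref=True))
        keys = lambda rr: {r.formula for r in rr.retained}
        assert keys(tight) <= keys(loose) <= {r.formula for r in recs}


class TestAggregateDescriptors:
    def test_completeness_fraction_planted(self):
        truth = generate_mixture(12, seed=7)
        records = [_record(c.formula) for c in truth.compounds]
        # run all three structural tags but drop 1/3 of compounds from the
        # bromination experiment: those records stay incomplete
        subset = GroundTruth(compounds=truth.compounds[4:], seed=0, params={})
        tags = simulate_tag_experiments(truth, seed=8, n_decoys=0, mz_jitter_sd=0.0)
        tags[ReactionKind.BROMINATION] = [
            simulate_label_spectrum(subset, ReactionKind.BROMINATION, seed=9,
                                    sample_id="tag_bromination")
        ]
        annotated = aggregate_descriptors(records, tags)
        by_f = truth.by_formula()
        for rec in annotated:
            c = by_f[rec.formula]
            assert rec.descriptor is not None
            assert rec.descriptor.n_carbonyl == c.n_carbonyl

    def test_descriptors_match_planted_truth(self):
        truth = generate_mixture(15, seed=9)
        records = [_record(c.formula) for c in truth.compounds]
        tags = simulate_tag_experiments(truth, seed=10, n_decoys=0, mz_jitter_sd=0.0)
        annotated = aggregate_descriptors(records, tags)
        by_f = truth.by_formula()
        exact = 0
        for rec in annotated:
            c = by_f[rec.formula]
            d = rec.descriptor
            if (
                d.n_cooh == c.n_cooh
                and d.n_carbonyl == c.n_carbonyl
                and d.is_aromatic == c.is_aromatic
                and d.n_exchangeable == c.n_exchangeable
            ):
                exact += 1
        assert exact >= 14  # only mass-coincidence chains may disturb one

    def test_bromination_absent_marks_incomplete(self):
        truth = generate_mixture(6, seed=11)
        records = [_record(c.formula) for c in truth.compounds]
        tags = simulate_tag_experiments(
            truth, seed=12,
            reactions=(ReactionKind.DEUTEROMETHYLATION, ReactionKind.REDUCTION),
            n_decoys=0, mz_jitter_sd=0.0,
        )
        annotated = aggregate_descriptors(records, tags)
        assert all(r.descriptor.is_aromatic is None for r in annotated)
        assert not any(r.complete for r in annotated)


def test_component_table_columns(default_pipeline_result):
    _, _, final = default_pipeline_result
    df = component_table(final.retained)
    assert {"formula", "routes", "n_cooh", "n_carbonyl", "aromatic", "complete"} <= set(
        df.columns
    )
    assert len(df) == len(final.retained)
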