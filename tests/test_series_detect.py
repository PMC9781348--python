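"""Series extraction, chemistry-rule filtration and descriptor folding."""

import numpy as np
import pytest

from conftest import brute_force_series, random_spectrum
from isoderep.chem_core import MolecularFormula, ReactionKind
from isoderep.formula_assign import Assignment, assign_formulas
from isoderep.series_detect import (
    DescriptorConsistencyError,
    FunctionalDescriptor,
    LabelSeries,
    SeriesRules,
    descriptors_from_series,
    detect_series,
    filter_series,
    series_table,
)
from isoderep.spectra_io import Peak, Spectrum
from isoderep.synthetic import generate_mixture, simulate_label_spectrum


def _as_chains(series):
    return [
        (round(s.base_peak.mz, 9), [(k, round(p.mz, 9)) for k, p in s.members])
        for s in series
    ]


def _oracle_chains(spectrum, reaction, tol, k_max):
    return [
        (round(base, 9), [(k, round(m, 9)) for k, m in members])
        for base, members in brute_force_series(spectrum, reaction, tol, k_max)
    ]


class TestDetect:
    def test_empty_spectrum(self):
        assert detect_series(Spectrum.from_peaks("e", []), ReactionKind.HD_EXCHANGE) == []

    def test_three_peak_hd_chain(self):
        spec = Spectrum.from_peaks(
            "c", [(121.0295, 1.0), (122.0358, 1.0), (123.0421, 1.0)]
        )
        series = detect_series(spec, ReactionKind.HD_EXCHANGE, tol_mz=0.0003)
        assert len(series) == 1
        assert series[0].base_peak.mz == pytest.approx(121.0295)
        assert series[0].max_k == 2
        assert _as_chains(series) == _oracle_chains(spec, ReactionKind.HD_EXCHANGE, 0.0003, 12)

    def test_gap_outside_tolerance(self):
        # spacing 1.00700 misses the H/D shift 1.00628 by 7.2e-4 > 3e-4
        spec = Spectrum.from_peaks("g", [(100.0, 1.0), (101.0070, 1.0)])
        assert detect_series(spec, ReactionKind.HD_EXCHANGE, tol_mz=0.0003) == []

    def test_chain_reported_once_under_lowest_base(self):
        delta = ReactionKind.HD_EXCHANGE.delta_da
        spec = Spectrum.from_peaks(
            "c", [(200.0, 1), (200.0 + delta, 1), (200.0 + 2 * delta, 1)]
        )
        series = detect_series(spec, ReactionKind.HD_EXCHANGE)
        assert len(series) == 1 and series[0].base_peak.mz == 200.0

    @pytest.mark.parametrize("reaction", list(ReactionKind))
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_oracle_equivalence_random(self, reaction, seed):
        rng = np.random.default_rng(seed)
        spec = random_spectrum(rng, 150, planted_chains=8, reaction=reaction)
        got = _as_chains(detect_series(spec, reaction, 0.0003, 6))
        want = _oracle_chains(spec, reaction, 0.0003, 6)
        assert got == want

    def test_tolerance_monotonicity(self):
        # exact chain spacings: shrinking the tolerance can only drop
        # coincidental series, never create new ones
        rng = np.random.default_rng(5)
        spec = random_spectrum(
            rng, 200, planted_chains=10, reaction=ReactionKind.HD_EXCHANGE, jitter_sd=0.0
        )
        counts = [
            len(detect_series(spec, ReactionKind.HD_EXCHANGE, tol))
            for tol in (3e-4, 2e-4, 1e-4, 5e-5)
        ]
        assert counts == sorted(counts, reverse=True)

    def test_planted_full_recovery_no_noise(self):
        truth = generate_mixture(20, seed=8)
        spec = simulate_label_spectrum(truth, ReactionKind.HD_EXCHANGE, efficiency=1.0, seed=1)
        series = detect_series(spec, ReactionKind.HD_EXCHANGE)
        by_base = {round(s.base_peak.mz, 4): s.max_k for s in series}
        from isoderep.chem_core import mz_from_formula

        for comp in truth.compounds:
            assert by_base[round(mz_from_formula(comp.formula), 4)] == comp.n_exchangeable


class TestFilter:
    def _series(self, reaction, base_mz, max_k):
        members = [(0, Peak(base_mz, 1.0))] + [
            (k, Peak(base_mz + k * reaction.delta_da, 1.0)) for k in range(1, max_k + 1)
        ]
        return LabelSeries(reaction=reaction, base_peak=Peak(base_mz, 1.0), members=members)

    def _assignment(self, base_mz, formula):
        return {base_mz: Assignment(Peak(base_mz, 1.0), formula, 0.0)}

    def test_deuteromethylation_overruns_oxygen_budget(self):
        f = MolecularFormula(c=7, h=6, o=2)  # one possible COOH
        s = self._series(ReactionKind.DEUTEROMETHYLATION, 121.0295, 3)
        res = filter_series([s], self._assignment(121.0295, f))
        assert not res.retained
        assert res.rejected[0][1].startswith("infeasible")

    def test_hd_within_hydrogen_count_retained(self):
        f = MolecularFormula(c=7, h=6, o=2)
        s = self._series(ReactionKind.HD_EXCHANGE, 121.0295, 2)
        res = filter_series([s], self._assignment(121.0295, f))
        assert len(res.retained) == 1
        assert res.retained[0].base_formula == f

    def test_unassigned_base_rejected(self):
        s = self._series(ReactionKind.HD_EXCHANGE, 121.0295, 2)
        res = filter_series([s], {})
        assert not res.retained and res.rejected[0][1] == "unassigned-base"

    def test_labeled_base_rejected(self):
        f = MolecularFormula(c=7, h=4, o=2, d=2)
        s = self._series(ReactionKind.HD_EXCHANGE, 123.0421, 1)
        res = filter_series([s], self._assignment(123.0421, f))
        assert not res.retained and res.rejected[0][1] == "labeled-base"

    def test_rule_override(self):
        f = MolecularFormula(c=7, h=6, o=2)
        s = self._series(ReactionKind.HD_EXCHANGE, 121.0295, 2)
        rules = SeriesRules(overrides={ReactionKind.HD_EXCHANGE: lambda _f, k: k <= 1})
        res = filter_series([s], self._assignment(121.0295, f), rules)
        assert not res.retained


class TestDescriptors:
    def test_all_three_tags(self):
        f = MolecularFormula(c=10, h=10, o=6)
        mk = TestFilter()._series
        series = {
            ReactionKind.DEUTEROMETHYLATION: mk(ReactionKind.DEUTEROMETHYLATION, 100.0, 2),
            ReactionKind.REDUCTION: mk(ReactionKind.REDUCTION, 100.0, 1),
            ReactionKind.BROMINATION: mk(ReactionKind.BROMINATION, 100.0, 1),
        }
        d = descriptors_from_series(f, series)
        assert (d.n_cooh, d.n_carbonyl, d.is_aromatic) == (2, 1, True)
        assert d.complete

    def test_reduction_run_but_absent_reports_zero(self):
        f = MolecularFormula(c=10, h=10, o=6)
        d = descriptors_from_series(
            f, {ReactionKind.REDUCTION: None}, experiments_run=[ReactionKind.REDUCTION]
        )
        assert d.n_carbonyl == 0
        assert d.n_cooh is None and d.is_aromatic is None

    def test_no_experiments_all_unknown(self):
        d = descriptors_from_series(MolecularFormula(c=10, h=10, o=6), {})
        assert d.n_cooh is None and d.n_carbonyl is None
        assert d.is_aromatic is None and d.n_exchangeable is None
        assert not d.complete

    def test_mismatched_base_formula_raises(self):
        mk = TestFilter()._series
        s = mk(ReactionKind.HD_EXCHANGE, 100.0, 1)
        s.base_formula = MolecularFormula(c=5, h=8, o=2)
        with pytest.raises(DescriptorConsistencyError):
            descriptors_from_series(
                MolecularFormula(c=10, h=10, o=6), {ReactionKind.HD_EXCHANGE: s}
            )

    def test_invariants_enforced(self):
        f = MolecularFormula(c=10, h=10, o=4)
        with pytest.raises(DescriptorConsistencyError):
            FunctionalDescriptor(f, n_cooh=3)  # exceeds floor(O/2)
        with pytest.raises(DescriptorConsistencyError):
            FunctionalDescriptor(f, n_cooh=2, n_carbonyl=1)  # O budget overrun
        with pytest.raises(DescriptorConsistencyError):
            FunctionalDescriptor(f, n_exchangeable=11)


def test_series_table_export():
    spec = Spectrum.from_peaks("t", [(121.0295, 1.0), (122.0358, 1.0)])
    series = detect_series(spec, ReactionKind.HD_EXCHANGE)
    res = filter_series(series, assign_formulas(spec))
    df = series_table(res.retained)
    assert list(df.columns) == ["base_mz", "formula", "reaction", "max_k", "member_mzs"]
    assert df.iloc[0]["formula"] == "C7H6O2"
    assert df.iloc[0]["max_k"] == 1
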