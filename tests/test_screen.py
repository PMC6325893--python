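"""Cohort screening: reference null, ranking, size classes, determinism."""

import warnings

import numpy as np
import pytest
from scipy import stats as sps

from sizedist import (
    ReferenceNull,
    ScreenConfig,
    SizeHistogram,
    SyntheticSpec,
    classify_size,
    rank_deviants,
    reference_null,
    rows_to_frame,
    screen_cohort,
    simulate_cohort,
)
from sizedist.distfit import FitResult
from sizedist.histogram_io import ValidationError
from sizedist.screen import ScreenRow, base_strain_id

REF = ReferenceNull(3.8277, 0.078949)


def _gamma_fit(shape, rate):
    return FitResult("gamma", {"shape": shape, "rate": rate}, 0.0, 1000, True)


def _light_config(**kw):
    base = dict(bootstrap_B=None, fit_gengamma=False, reference=REF, master_seed=0)
    base.update(kw)
    return ScreenConfig(**base)


class TestReferenceNull:
    def test_two_wildtype_haploid_fits_average(self):
        ref = reference_null([_gamma_fit(3.651767, 0.074363), _gamma_fit(4.003634, 0.083534)])
        assert ref.shape == pytest.approx(3.8277005, abs=1e-7)
        assert ref.rate == pytest.approx(0.0789485, abs=1e-7)

    def test_single_fit_identity(self):
        ref = reference_null([_gamma_fit(5.0, 0.06)])
        assert (ref.shape, ref.rate) == (5.0, 0.06)

    def test_mean_of_identical_fits_unchanged(self):
        ref = reference_null([_gamma_fit(5.0, 0.06)] * 4)
        assert (ref.shape, ref.rate) == (5.0, 0.06)

    def test_empty_and_mixed_family_rejected(self):
        with pytest.raises(ValidationError):
            reference_null([])
        with pytest.raises(ValidationError, match="gamma"):
            reference_null([_gamma_fit(5, 0.06), FitResult("weibull", {"shape": 2, "scale": 100}, 0, 1000, True)])

    def test_unconverged_fit_rejected(self):
        bad = FitResult("gamma", {"shape": 5, "rate": 0.06}, 0.0, 1000, converged=False)
        with pytest.raises(ValidationError, match="converged"):
            reference_null([bad])


@pytest.fixture(scope="module")
def null_cohort_rows():
    """A 40-strain cohort simulated entirely from the reference null,
    screened once with the full per-strain pipeline (B=199)."""
    spec = SyntheticSpec(classes={"wildtype_gamma": (40, {})}, master_seed=7)
    cohort, _ = simulate_cohort(spec)
    cfg = ScreenConfig(bootstrap_B=199, fit_gengamma=False, reference=REF, master_seed=7)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return cohort, screen_cohort(cohort, cfg)


class TestScreenCohort:
    def test_master_seed_determinism(self, null_cohort_rows):
        cohort, rows = null_cohort_rows
        cfg = ScreenConfig(bootstrap_B=199, fit_gengamma=False, reference=REF, master_seed=7)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            again = screen_cohort(cohort, cfg)
        assert rows_to_frame(again).equals(rows_to_frame(rows))

    def test_cohort_order_does_not_change_per_strain_results(self, null_cohort_rows):
        cohort, rows = null_cohort_rows
        cfg = ScreenConfig(bootstrap_B=199, fit_gengamma=False, reference=REF, master_seed=7)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            shuffled = screen_cohort(cohort[::-1], cfg)
        a = rows_to_frame(rows).set_index("strain").sort_index()
        b = rows_to_frame(shuffled).set_index("strain").sort_index()
        assert a.equals(b)

    def test_rows_in_input_order_with_permutation_ranks(self, null_cohort_rows):
        cohort, rows = null_cohort_rows
        assert [r.strain_id for r in rows] == [h.strain_id for h in cohort]
        assert sorted(r.deviant_rank for r in rows) == list(range(1, len(rows) + 1))

    def test_composite_and_fixed_statistics_positively_coupled(self, null_cohort_rows):
        _, rows = null_cohort_rows
        rho = sps.spearmanr([r.gamma_ad for r in rows], [r.fixed_null_ad for r in rows]).statistic
        assert rho > 0

    def test_failed_strain_recorded_not_fatal(self):
        # nearly all mass in one bin: the n=1000 resample is almost surely
        # degenerate (all values equal), so the fit must fail in-row
        h = SizeHistogram("BAD", [10.0, 20.0], [1e-12, 1.0])
        ok = SizeHistogram("OK", np.linspace(10, 100, 10), np.full(10, 0.1))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            rows = screen_cohort([h, ok], _light_config())
        by_id = {r.strain_id: r for r in rows}
        assert by_id["BAD"].status.startswith("failed")
        assert by_id["OK"].status == "ok"
        # failed strains rank last
        assert by_id["BAD"].deviant_rank == 2

    def test_wild_type_ids_build_the_reference(self):
        spec = SyntheticSpec(classes={"wildtype_gamma": (6, {})}, master_seed=3)
        cohort, _ = simulate_cohort(spec)
        cfg = ScreenConfig(
            bootstrap_B=None, fit_gengamma=False, master_seed=3,
            wild_type_ids=("WILDTYPE_GAMMA000", "WILDTYPE_GAMMA001"),
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            rows = screen_cohort(cohort, cfg)
        assert all(np.isfinite(r.fixed_null_ad) for r in rows)

    def test_missing_reference_specification_is_actionable(self):
        spec = SyntheticSpec(classes={"wildtype_gamma": (2, {})}, master_seed=1)
        cohort, _ = simulate_cohort(spec)
        with pytest.raises(ValidationError, match="wild_type_ids"):
            screen_cohort(cohort, ScreenConfig(reference=None, wild_type_ids=()))

    def test_null_cohort_fixed_null_rejection_rate_near_nominal(self):
        """Strains simulated from the reference null itself are rejected at
        roughly the nominal 1% rate."""
        n_rej = n_tot = 0
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            for seed in range(6):
                spec = SyntheticSpec(classes={"wildtype_gamma": (500, {})}, master_seed=seed)
                cohort, _ = simulate_cohort(spec)
                rows = screen_cohort(cohort, _light_config(master_seed=seed, families=("gamma",)))
                n_rej += sum(r.fixed_null_p < 0.01 for r in rows)
                n_tot += len(rows)
        assert 0.003 <= n_rej / n_tot <= 0.03


class TestRankDeviants:
    def _rows(self, stats_by_id):
        rows = []
        for sid, stat in stats_by_id.items():
            r = ScreenRow(strain_id=sid)
            r.fixed_null_ad = stat
            r.median_fl = 50.0
            rows.append(r)
        return rows

    def test_full_ordering_matches_independent_sort(self):
        rng = np.random.default_rng(0)
        stats_by_id = {f"Y{i:04d}": float(v) for i, v in enumerate(rng.exponential(2, 30))}
        dev = rank_deviants(self._rows(stats_by_id), 30)
        expected = sorted(stats_by_id, key=lambda s: (-stats_by_id[s], s))
        assert [r.strain_id for r in dev.rows] == expected

    def test_replicates_collapse_to_unique_strains(self):
        rows = self._rows({"YBR123C": 50.0, "YBR123C-2": 40.0, "YAL001C": 30.0})
        dev = rank_deviants(rows, 3)
        assert len(dev.rows) == 3
        assert dev.strain_ids == ("YBR123C", "YAL001C")

    def test_k_exceeding_rows_rejected(self):
        with pytest.raises(ValidationError):
            rank_deviants(self._rows({"A": 1.0}), 2)

    def test_ties_break_by_strain_id(self):
        dev = rank_deviants(self._rows({"B": 1.0, "A": 1.0, "C": 1.0}), 2)
        assert [r.strain_id for r in dev.rows] == ["A", "B"]


def test_base_strain_id_strips_replicate_suffix():
    assert base_strain_id("YBR123C-2") == "YBR123C"
    assert base_strain_id("YBR123C.10") == "YBR123C"
    assert base_strain_id("YBR123C") == "YBR123C"


class TestClassifySize:
    def _rows(self, medians):
        rows = []
        for i, m in enumerate(medians):
            r = ScreenRow(strain_id=f"Y{i:04d}")
            r.median_fl = float(m)
            rows.append(r)
        return rows

    def test_exact_tail_counts(self):
        rows = self._rows(np.arange(1, 101))
        classify_size(rows, 0.05)
        classes = [r.size_class for r in rows]
        assert classes.count("lge") == 5 and classes.count("whi") == 5
        assert {r.strain_id for r in rows if r.size_class == "lge"} == {f"Y{i:04d}" for i in range(95, 100)}

    def test_all_equal_medians_still_deterministic(self):
        rows = self._rows([42.0] * 10)
        classify_size(rows, 0.1)
        lge = [r.strain_id for r in rows if r.size_class == "lge"]
        whi = [r.strain_id for r in rows if r.size_class == "whi"]
        assert lge == ["Y0000"] and whi == ["Y0001"]  # tie-break by strain id

    def test_missing_medians_rejected(self):
        rows = self._rows([1, 2, 3])
        rows[1].median_fl = float("nan")
        with pytest.raises(ValidationError, match="missing"):
            classify_size(rows, 0.1)

    def test_invalid_tail_fraction(self):
        with pytest.raises(ValidationError):
            classify_size(self._rows([1, 2]), 0.6)

    def test_size_shifted_mutants_land_in_lge(self):
        """Spike-in construction: strains with shifted (larger) sizes are
        classified as lge."""
        spec = SyntheticSpec(
            classes={"wildtype_gamma": (18, {}), "shifted_gamma": (2, {"shift": 1.8})},
            master_seed=5,
        )
        cohort, labels = simulate_cohort(spec)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            rows = screen_cohort(cohort, _light_config(master_seed=5, tail_q=0.1, families=("gamma",)))
        lge = {r.strain_id for r in rows if r.size_class == "lge"}
        assert lge == set(labels[labels["class"] == "shifted_gamma"].strain)
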