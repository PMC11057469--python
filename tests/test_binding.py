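import numpy as np
import pytest

from dsfbind import (
    BindingFit,
    DosePoint,
    DoseResponseSeries,
    FitError,
    NotBiphasicError,
    OccupancySeries,
    ParameterError,
    aggregate_replicates,
    biphasic_occupancy,
    build_delta_tm_series,
    classify_binder,
    fit_hill,
    fit_single_site,
    hill_model,
    nonbinding_fit,
    single_site_model,
)
from dsfbind.plate_io import AnnotatedCurve
from dsfbind.synthetic import ALBUMIN_PRESETS, simulate_melt_curve

from conftest import grouped_curves


def make_series(conc, values, value_kind="delta_tm", replicate=None):
    points = tuple(
        DosePoint(float(c), float(v), 1 if replicate is None else replicate[i])
        for i, (c, v) in enumerate(zip(conc, values))
    )
    return DoseResponseSeries(protein="P", ligand="L", points=points,
                              value_kind=value_kind)


def isotherm_series(kd=0.79, dtm_max=13.0, n_conc=8, replicates=(1,)):
    conc = kd * np.logspace(-1, 1, n_conc)
    points = []
    for rep in replicates:
        for c in conc:
            points.append(DosePoint(float(c), float(single_site_model(c, dtm_max, kd)), rep))
    return DoseResponseSeries(protein="HSA", ligand="PFOA", points=tuple(points))


def annotated(tm, role, conc, rep, protein="HSA", well="A1", plate="p1"):
    preset = ALBUMIN_PRESETS[protein]
    curve = simulate_melt_curve(preset, tm, noise_sd=0.0)
    return AnnotatedCurve(curve=curve, well=well, protein=protein, ligand="L",
                          concentration_mM=conc, role=role, replicate=rep,
                          plate_id=plate)


class TestBuildDeltaTmSeries:
    def test_delta_is_sample_minus_vehicle_mean(self):
        curves = [
            annotated(71.3, "vehicle", 0.0, 1, well="A1"),
            annotated(74.3, "sample", 1.0, 1, well="A2"),
        ]
        series = build_delta_tm_series(curves)
        assert len(series) == 1
        assert series.points[0].value == pytest.approx(3.0, abs=0.1)

    def test_vehicle_baseline_is_mean_of_vehicle_wells(self):
        curves = [
            annotated(71.2, "vehicle", 0.0, 1, well="A1"),
            annotated(71.4, "vehicle", 0.0, 2, well="A2"),
            annotated(71.3, "sample", 1.0, 1, well="A3"),
        ]
        series = build_delta_tm_series(curves)
        assert series.points[0].value == pytest.approx(0.0, abs=0.1)

    def test_missing_vehicle_on_plate_names_plate(self):
        curves = [annotated(74.3, "sample", 1.0, 1, well="A2", plate="plate9")]
        from dsfbind.errors import PlateValidationError

        with pytest.raises(PlateValidationError, match="plate9"):
            build_delta_tm_series(curves)

    def test_simulated_plate_matches_truth(self, hsa_single_site_plate):
        plate, pmap, truth = hsa_single_site_plate
        series = build_delta_tm_series(grouped_curves(plate, pmap))
        true_tm = {w["well"]: w["true_tm_C"] for w in truth.wells if "true_tm_C" in w}
        tm0 = truth.protein["tm0_C"]
        by_conc = {}
        for w in truth.wells:
            if "true_tm_C" in w and w["concentration_mM"] > 0:
                by_conc[w["concentration_mM"]] = w["true_tm_C"] - tm0
        for p in series.points:
            # within 2x the grid-refinement tolerance (0.15 deg C)
            assert p.value == pytest.approx(by_conc[p.concentration_mM], abs=0.3)


class TestFitSingleSite:
    def test_noiseless_recovery_to_four_significant_digits(self):
        series = isotherm_series(kd=0.79, dtm_max=13.0)
        fit = fit_single_site(series)
        assert fit.kd_mM == pytest.approx(0.79, rel=5e-4)
        assert fit.dtm_max_C == pytest.approx(13.0, rel=5e-4)
        assert fit.model == "single_site"

    def test_model_identities(self):
        assert single_site_model(0.0, 13.0, 0.79) == 0.0
        assert single_site_model(0.79, 13.0, 0.79) == pytest.approx(13.0 / 2)

    def test_replicate_mean_and_sem_reported(self):
        rng = np.random.default_rng(3)
        conc = 0.79 * np.logspace(-1, 1, 8)
        points = []
        for rep in range(1, 7):
            for c in conc:
                points.append(DosePoint(float(c),
                                        float(single_site_model(c, 13.0, 0.79))
                                        + rng.normal(0, 0.3), rep))
        series = DoseResponseSeries(protein="HSA", ligand="PFOA",
                                    points=tuple(points))
        fit = fit_single_site(series)
        assert fit.n_replicates == 6
        assert fit.kd_se_mM > 0
        assert fit.kd_mM == pytest.approx(0.79, rel=0.2)
        assert 0.9 < fit.r2 <= 1.0

    def test_scale_consistency(self):
        base = isotherm_series(kd=0.6, dtm_max=9.0)
        k = 7.5
        scaled = DoseResponseSeries(
            protein="P", ligand="L",
            points=tuple(DosePoint(p.concentration_mM * k, p.value, p.replicate)
                         for p in base.points),
        )
        f1, f2 = fit_single_site(base), fit_single_site(scaled)
        assert f2.kd_mM == pytest.approx(f1.kd_mM * k, rel=1e-6)
        assert f2.dtm_max_C == pytest.approx(f1.dtm_max_C, rel=1e-6)

    def test_too_few_concentrations_rejected(self):
        series = make_series([0.1, 0.3, 1.0], [1.0, 2.0, 3.0])
        with pytest.raises(ParameterError, match="4 distinct"):
            fit_single_site(series)

    def test_destabilizing_ligand_flagged(self):
        series = isotherm_series(kd=0.5, dtm_max=-6.0)
        fit = fit_single_site(series)
        assert fit.destabilizing
        assert "destabilizing" in fit.notes

    def test_agrees_with_lmfit_oracle(self):
        lmfit = pytest.importorskip("lmfit")
        rng = np.random.default_rng(7)
        conc = np.repeat(0.79 * np.logspace(-1, 1, 8), 3)
        vals = single_site_model(conc, 13.0, 0.79) + rng.normal(0, 0.3, conc.size)
        series = DoseResponseSeries(
            protein="P", ligand="L",
            points=tuple(DosePoint(float(c), float(v), 1)
                         for c, v in zip(conc, vals)),
        )
        fit = fit_single_site(series)
        model = lmfit.Model(lambda c, dtm_max, kd: dtm_max * c / (kd + c))
        ref = model.fit(vals, c=conc, dtm_max=10.0, kd=1.0)
        assert fit.kd_mM == pytest.approx(ref.params["kd"].value, rel=1e-4)
        assert fit.dtm_max_C == pytest.approx(ref.params["dtm_max"].value, rel=1e-4)


class TestClassifyBinder:
    def test_small_shifts_are_nonbinding(self):
        series = make_series([0.1, 0.3, 1.0, 3.0], [0.1, -0.3, 0.2, 0.25])
        assert not classify_binder(series)
        fit = nonbinding_fit(series)
        assert fit.model == "nonbinding"

    def test_published_smallest_binder_shift_classifies_binding(self):
        # 3.53 deg C is the smallest max shift among bound congeners
        series = make_series([0.1, 0.3, 1.0, 3.0], [0.5, 1.2, 2.5, 3.53])
        assert classify_binder(series)

    def test_zero_threshold_classifies_everything_binding(self):
        series = make_series([0.1, 0.3], [0.0001, 0.0002])
        assert classify_binder(series, min_shift_C=0.0)


class TestBiphasicOccupancy:
    def test_equal_mixture_gives_half_occupancy(self, bsa_biphasic_plate):
        plate, pmap, truth = bsa_biphasic_plate
        occ = biphasic_occupancy(grouped_curves(plate, pmap))
        k_half = truth.binding["k_half_mM"]
        at_khalf = [p.value for p in occ.points
                    if p.concentration_mM == pytest.approx(k_half, rel=1e-6)]
        assert at_khalf
        assert np.mean(at_khalf) == pytest.approx(0.5, abs=0.05)

    def test_tracks_true_occupancy(self, bsa_biphasic_plate):
        plate, pmap, truth = bsa_biphasic_plate
        occ = biphasic_occupancy(grouped_curves(plate, pmap))
        truth_occ = {
            (w["well"]): w["true_occupancy"]
            for w in truth.wells if "baseline_tm_C" in w
        }
        well_occ = {}
        for c, p in zip([c for c in grouped_curves(plate, pmap) if c.role == "sample"],
                        [p for p in occ.points if p.concentration_mM > 0]):
            well_occ[c.well] = p.value
        for well, phi in truth_occ.items():
            if well in well_occ:
                assert well_occ[well] == pytest.approx(phi, abs=0.05)

    def test_monophasic_group_raises(self, hsa_single_site_plate):
        plate, pmap, _ = hsa_single_site_plate
        with pytest.raises(NotBiphasicError):
            biphasic_occupancy(grouped_curves(plate, pmap))

    def test_occupancy_monotone_after_averaging(self, bsa_biphasic_plate):
        plate, pmap, _ = bsa_biphasic_plate
        occ = biphasic_occupancy(grouped_curves(plate, pmap))
        conc, means = occ.to_series().mean_by_concentration()
        assert np.all(np.diff(means) >= -1e-9)


class TestFitHill:
    def test_noiseless_recovery_to_three_significant_digits(self):
        conc = 0.6 * np.logspace(-1, 1, 12)
        points = [DosePoint(0.0, 0.0, 1)] + [
            DosePoint(float(c), float(hill_model(c, 0.6, 3.5)), 1) for c in conc
        ]
        series = OccupancySeries(protein="BSA", ligand="PFOS", points=tuple(points))
        fit = fit_hill(series)
        assert fit.kd_mM == pytest.approx(0.6, rel=5e-3)
        assert fit.hill_h == pytest.approx(3.5, rel=5e-3)
        assert fit.model == "hill"

    def test_hill_one_reduces_to_single_site_shape(self):
        c = np.logspace(-2, 2, 30)
        np.testing.assert_allclose(hill_model(c, 0.7, 1.0),
                                   single_site_model(c, 1.0, 0.7), rtol=1e-12)

    def test_midpoint_identity(self):
        for h in (0.5, 1.0, 2.0, 3.5):
            assert hill_model(0.42, 0.42, h) == pytest.approx(0.5)

    def test_insufficient_span_rejected(self):
        points = tuple(DosePoint(float(c), 0.3 + 0.01 * i, 1)
                       for i, c in enumerate([0.1, 0.2, 0.4, 0.8]))
        series = DoseResponseSeries(protein="P", ligand="L", points=points,
                                    value_kind="occupancy")
        with pytest.raises(ParameterError, match="span"):
            fit_hill(series)


class TestAggregateReplicates:
    def _fit(self, kd, dtm=10.0):
        return BindingFit(protein="HSA", ligand="PFOS", model="single_site",
                          kd_mM=kd, dtm_max_C=dtm, n_replicates=1)

    def test_mean_and_sem(self):
        agg = aggregate_replicates([self._fit(0.60), self._fit(0.64)])
        assert agg.kd_mM == pytest.approx(0.62)
        assert agg.kd_se_mM == pytest.approx(0.02)
        assert agg.n_replicates == 2

    def test_single_fit_rejected(self):
        with pytest.raises(ParameterError):
            aggregate_replicates([self._fit(0.6)])

    def test_identical_replicates_have_zero_sem(self):
        agg = aggregate_replicates([self._fit(0.5)] * 3)
        assert agg.kd_se_mM == 0.0

    def test_mixed_models_rejected(self):
        hill = BindingFit(protein="HSA", ligand="PFOS", model="hill",
                          kd_mM=0.6, hill_h=3.5, n_replicates=1)
        with pytest.raises(ParameterError, match="mixed models"):
            aggregate_replicates([self._fit(0.6), hill])
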