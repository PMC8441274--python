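"""Curve reduction: segmentation, drift, unloading fit, contact mechanics,
loading decomposition, energies and specimen aggregation."""

import math
import warnings

import numpy as np
import pandas as pd
import pytest
from scipy.stats import spearmanr

from ossindent import (
    IndentationCurve,
    IndentationModel,
    IndenterSpec,
    MaterialTruth,
    aggregate_specimen,
    correct_drift,
    decompose_loading,
    fit_unloading,
    indentation_energies,
    oliver_pharr,
    segment_curve,
)
from ossindent.indentation import PhaseError, max_point
from ossindent.protocols import MN_NM2_PER_GPA
from ossindent.synthetic import generate_curve

from conftest import sneddon_cone_curve


# ---------------------------------------------------------------------- phases


@pytest.mark.parametrize("seed", [0, 1, 2])
def test_segmentation_matches_generator_boundaries(realistic_truth, protocol, seed):
    curve = generate_curve(realistic_truth, protocol, seed=seed)
    seg = segment_curve(curve, protocol)
    found = seg.meta["phase_bounds"]
    true = curve.meta["true_boundaries"]
    for key in ("loading_end", "hold_end", "unloading_end"):
        assert abs(found[key] - true[key]) <= 2
    # phases contiguous and in protocol order
    labels = pd.Series(seg.phase)
    order = labels[labels.ne(labels.shift())].tolist()
    assert order == ["loading", "hold", "unloading", "drift_hold"]


def test_segmentation_rejects_monotone_ramp():
    t = np.linspace(0, 10, 200)
    with pytest.raises(PhaseError, match="unloading"):
        segment_curve(IndentationCurve(t, 0.25 * t, 50.0 * t))


def test_segmentation_zero_duration_hold(clean_truth):
    from ossindent.protocols import IndentationProtocol

    proto = IndentationProtocol(hold_s=0.0, drift_hold_s=20.0)
    curve = generate_curve(clean_truth, proto, seed=3)
    seg = segment_curve(curve, proto)
    assert seg.phase_mask("hold").sum() <= 1
    assert seg.phase_mask("unloading").sum() >= 10


# ------------------------------------------------------------------ drift


def test_drift_rate_recovered_within_10pct(protocol):
    truth = MaterialTruth(E_s=16.2, H_true=1.178, creep_amp=5.0,
                          drift_rate=0.05, noise_sd=1.0)
    curve = generate_curve(truth, protocol, seed=11)
    corrected = correct_drift(segment_curve(curve, protocol))
    rate = corrected.meta["drift_rate_nm_per_s"]
    assert rate == pytest.approx(0.05, rel=0.10)


def test_zero_drift_leaves_properties_unchanged(clean_curve, protocol):
    seg = segment_curve(clean_curve, protocol)
    res_corr = IndentationModel(clean_curve).fit(drift_correction=True)
    res_raw = IndentationModel(clean_curve).fit(drift_correction=False)
    assert res_corr.properties.E == pytest.approx(res_raw.properties.E, rel=1e-3)
    assert res_corr.properties.H == pytest.approx(res_raw.properties.H, rel=1e-3)


def test_short_drift_hold_warns_and_skips(clean_truth):
    from ossindent.protocols import IndentationProtocol

    proto = IndentationProtocol(drift_hold_s=10.0)  # shorter than exclusion
    curve = generate_curve(clean_truth, proto, seed=5)
    seg = segment_curve(curve, proto)
    with pytest.warns(UserWarning, match="no drift correction"):
        out = correct_drift(seg)
    assert out.meta["drift_rate_nm_per_s"] is None
    np.testing.assert_array_equal(out.depth, seg.depth)


# ------------------------------------------------------------- unloading fit


def test_unloading_fit_recovers_exact_power_law(clean_curve, protocol):
    seg = segment_curve(clean_curve, protocol)
    fit = fit_unloading(seg)
    true = clean_curve.meta["unload_pars"]
    assert fit.m == pytest.approx(true["m"], rel=1e-4)
    assert fit.h_f == pytest.approx(true["h_f"], rel=1e-4)
    assert fit.B == pytest.approx(true["B"], rel=1e-3)
    assert fit.S == pytest.approx(true["S"], rel=1e-4)


def test_linear_unloading_gives_stiffness_equal_slope():
    # loading parabola to (500, 2.0) then straight unloading, slope B
    B = 0.008  # mN/nm
    h_l = np.linspace(0, 500, 600)[1:]
    P_l = 2.0 * (h_l / 500.0) ** 2
    P_u = np.linspace(2.0, 0.2, 300)[1:]
    h_u = 500.0 - (2.0 - P_u) / B
    t = np.arange(h_l.size + P_u.size, dtype=float)
    phase = np.array(["loading"] * h_l.size + ["unloading"] * P_u.size,
                     dtype=object)
    curve = IndentationCurve(
        t, np.concatenate([P_l, P_u]), np.concatenate([h_l, h_u]), phase=phase
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # m sits at its lower bound
        fit = fit_unloading(curve)
    assert fit.S == pytest.approx(B, rel=1e-3)


def test_unloading_stiffness_median_error_under_noise(realistic_truth, protocol):
    """1% depth noise, 100 curves: median relative error of S < 3%."""
    errs = []
    for seed in range(100):
        curve = generate_curve(realistic_truth, protocol, seed=seed)
        S_true = curve.meta["unload_pars"]["S"]
        seg = correct_drift(segment_curve(curve, protocol))
        errs.append(abs(fit_unloading(seg).S / S_true - 1.0))
    assert np.median(errs) < 0.03


# ------------------------------------------------------------- Oliver-Pharr


def test_rigid_indenter_limit_E_equals_Er(clean_curve, protocol):
    seg = segment_curve(clean_curve, protocol)
    fit = fit_unloading(seg)
    rigid = IndenterSpec(E_i=1e12)
    E_r, E, *_ = oliver_pharr(fit, rigid, nu_s=0.0)
    assert E == pytest.approx(E_r, rel=1e-6)


def test_area_coefficient_scaling_law(clean_curve, protocol):
    seg = segment_curve(clean_curve, protocol)
    fit = fit_unloading(seg)
    base = IndenterSpec()
    doubled = IndenterSpec(area_coeffs=(49.0,))
    E_r1, _, _, A1, Hc1 = oliver_pharr(fit, base)
    E_r2, _, _, A2, Hc2 = oliver_pharr(fit, doubled)
    assert Hc2 == pytest.approx(Hc1 / 2.0, rel=1e-12)
    assert E_r2 == pytest.approx(E_r1 / math.sqrt(2.0), rel=1e-12)


def test_sneddon_cone_reduction_recovers_Er(cone_indenter):
    curve = sneddon_cone_curve(E_r_gpa=20.0)
    res = IndentationModel(curve, indenter=cone_indenter).fit(
        drift_correction=False
    )
    assert res.properties.E_r == pytest.approx(20.0, rel=0.01)


# ------------------------------------------------------- loading decomposition


def test_decomposition_round_trip_exact(clean_curve, protocol, indenter):
    seg = segment_curve(clean_curve, protocol)
    fit = fit_unloading(seg)
    E_r, *_ = oliver_pharr(fit, indenter)
    H = decompose_loading(seg, E_r, indenter)
    assert H == pytest.approx(1.178, rel=1e-3)


def test_pure_elastic_loading_reports_no_plasticity(cone_indenter):
    curve = sneddon_cone_curve(E_r_gpa=20.0)
    res = IndentationModel(curve, indenter=cone_indenter).fit(
        drift_correction=False
    )
    assert math.isinf(res.properties.H)
    assert any("no measurable plasticity" in w for w in res.warnings)


def test_halving_H_true_halves_recovered_H(protocol, indenter):
    rec = []
    for H_true in (1.6, 0.8):
        truth = MaterialTruth(E_s=16.2, H_true=H_true, creep_amp=0.0,
                              drift_rate=0.0, noise_sd=0.0)
        curve = generate_curve(truth, protocol, seed=9)
        rec.append(IndentationModel(curve).fit().properties.H)
    assert rec[1] == pytest.approx(rec[0] / 2.0, rel=0.02)


def test_superelastic_loading_rejected(protocol, indenter):
    # a loading branch stiffer than the elastic limit is non-physical
    curve = sneddon_cone_curve(E_r_gpa=20.0)
    seg = segment_curve(curve, protocol)
    with pytest.raises(ValueError, match="non-physical"):
        decompose_loading(seg, E_r=10.0, indenter=cone_ind())


def cone_ind():
    from ossindent.protocols import CONE_EPSILON

    return IndenterSpec(epsilon=CONE_EPSILON)


# ----------------------------------------------------------------- energies


def triangle_curve() -> IndentationCurve:
    """P rises linearly to 2 mN at 500 nm, unloads linearly to (250 nm, 0)."""
    n = 400
    h_l = np.linspace(0, 500, n)
    P_l = np.linspace(0, 2.0, n)
    h_u = np.linspace(500, 250, n)[1:]
    P_u = np.linspace(2.0, 0.0, n)[1:]
    t = np.arange(2 * n - 1, dtype=float)
    phase = np.array(["loading"] * n + ["unloading"] * (n - 1), dtype=object)
    return IndentationCurve(
        t, np.concatenate([P_l, P_u]), np.concatenate([h_l, h_u]), phase=phase
    )


def test_triangle_energies_exact():
    U_total, Ue, Up = indentation_energies(triangle_curve())
    assert U_total == pytest.approx(500.0, abs=1e-9)
    assert Ue == pytest.approx(250.0, abs=1e-9)
    assert Up == pytest.approx(250.0, abs=1e-9)


def test_energy_partition_identity(realistic_truth, protocol):
    for seed in range(5):
        curve = generate_curve(realistic_truth, protocol, seed=seed)
        seg = correct_drift(segment_curve(curve, protocol))
        U_total, Ue, Up = indentation_energies(seg)
        assert Up == pytest.approx(U_total - Ue, abs=1e-12)
        assert U_total > 0 and Ue > 0


def test_elastic_retrace_has_negligible_plastic_energy():
    U_total, Ue, Up = indentation_energies(
        segment_curve(sneddon_cone_curve(20.0))
    )
    assert abs(Up) < 0.01 * U_total


# ------------------------------------------------------------- aggregation


def _props_frame(values, trabecula=None):
    df = pd.DataFrame({"E": values, "Hc": values, "H": values,
                       "Ue": values, "Up": values})
    if trabecula is not None:
        df["trabecula"] = trabecula
    return df


def test_identical_sites_aggregate_to_value_with_zero_sd():
    agg = aggregate_specimen(_props_frame([2.5] * 60), "cortical")
    assert agg["E_mean"] == pytest.approx(2.5)
    assert agg["E_sd"] == pytest.approx(0.0)
    assert agg["n_valid"] == 60


def test_cancellous_mean_of_trabecula_means():
    rng = np.random.default_rng(0)
    values, trabs = [], []
    for i, mean in enumerate([1.0, 2.0, 3.0, 4.0, 5.0]):
        values.extend(mean + rng.normal(0, 1e-6, 12))
        trabs.extend([f"T{i + 1}"] * 12)
    agg = aggregate_specimen(_props_frame(values, trabs), "cancellous")
    assert agg["E_mean"] == pytest.approx(3.0, abs=1e-5)


def test_unbalanced_trabecula_contributes_one_mean():
    # trabecula T1 has 6 sites at 10; T2 has 12 sites at 1 -> mean (10+1)/2
    values = [10.0] * 6 + [1.0] * 12
    trabs = ["T1"] * 6 + ["T2"] * 12
    agg = aggregate_specimen(_props_frame(values, trabs), "cancellous")
    assert agg["E_mean"] == pytest.approx(5.5)


def test_failed_sites_excluded_and_counted():
    vals = [2.0, 2.0, np.nan, 2.0]
    agg = aggregate_specimen(_props_frame(vals), "cortical")
    assert agg["n_valid"] == 3 and agg["n_failed"] == 1
    empty = aggregate_specimen(_props_frame([np.nan, np.nan]), "cortical")
    assert empty["missing"]


# --------------------------------------------------------------- invariants


def test_modulus_monotonicity(protocol):
    """Recovered S and E increase with generating E_s (rho > 0.95)."""
    Es = np.linspace(10, 30, 5)
    S_rec, E_rec = [], []
    for i, E_s in enumerate(Es):
        truth = MaterialTruth(E_s=E_s, H_true=1.178, creep_amp=5.0,
                              drift_rate=0.05, noise_sd=5.0)
        res = IndentationModel(generate_curve(truth, protocol, seed=i)).fit()
        S_rec.append(res.properties.S)
        E_rec.append(res.properties.E)
    assert spearmanr(Es, S_rec).statistic > 0.95
    assert spearmanr(Es, E_rec).statistic > 0.95


def test_unit_round_trip_is_lossless(clean_curve):
    """mN/nm -> N/m -> mN/nm leaves every property bit-identical to 1e-9."""
    base = IndentationModel(clean_curve).fit().properties
    converted = IndentationCurve(
        clean_curve.time,
        (clean_curve.load * 1e-3) / 1e-3,       # mN -> N -> mN
        (clean_curve.depth * 1e-9) / 1e-9,      # nm -> m -> nm
    )
    other = IndentationModel(converted).fit().properties
    for name in ("E", "Hc", "H", "Ue", "Up", "S", "E_r"):
        assert getattr(other, name) == pytest.approx(
            getattr(base, name), rel=1e-9
        )
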