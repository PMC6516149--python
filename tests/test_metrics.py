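"""Bioenergetic metric arithmetic, ATP-rate partitioning, trace
normalization and group statistics."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mitoflux import metrics as mx


def make_series(plateaus, ecar=None, cycles=3):
    """A synthetic well with exact per-phase plateaus (no noise)."""
    times, ocr, ec, phase = [], [], [], []
    inj = {"oligomycin": 20.0, "fccp": 40.0, "antimycin_a": 60.0}
    starts = [0.0, 20.0, 40.0, 60.0]
    names = ["baseline", "oligomycin", "fccp", "antimycin_a"]
    for t0, nm in zip(starts, names):
        for k in range(cycles):
            times.append(t0 + 5.0 * (k + 1))
            ocr.append(plateaus[nm])
            if ecar is not None:
                ec.append(ecar[nm])
    return mx.PlateSeries(well="w0", group="WT", time_min=np.array(times),
                          ocr=np.array(ocr),
                          ecar=np.array(ec) if ecar is not None else None,
                          injections=inj)


def test_stress_test_arithmetic_on_printed_example():
    """Plateaus (120, 50, 160, 20) with non-mito subtraction give the
    canonical metric values."""
    s = make_series({"baseline": 120.0, "oligomycin": 50.0,
                     "fccp": 160.0, "antimycin_a": 20.0})
    m = mx.compute_ocr_metrics(s)
    assert m.basal == pytest.approx(100.0)
    assert m.atp_synthesis == pytest.approx(70.0)
    assert m.h_leak == pytest.approx(30.0)
    assert m.maximal == pytest.approx(140.0)
    assert m.spare_capacity == pytest.approx(40.0)
    assert m.coupling_efficiency == pytest.approx(0.70)
    assert m.rcr_basal == pytest.approx(100.0 / 30.0)
    assert m.rcr_max == pytest.approx(140.0 / 30.0)


def test_simulation_style_plateaus_without_subtraction():
    m = mx.ocr_metrics_from_plateaus(100.0, 30.0, 150.0,
                                     subtract_nonmito=False)
    assert m.atp_synthesis == pytest.approx(70.0)
    assert m.h_leak == pytest.approx(30.0)
    assert m.spare_capacity == pytest.approx(50.0)
    assert m.coupling_efficiency == pytest.approx(0.70)
    assert m.rcr_max == pytest.approx(5.0)


def test_flat_trace_gives_zero_atp_synthesis_and_spare():
    s = make_series({k: 80.0 for k in
                     ("baseline", "oligomycin", "fccp", "antimycin_a")})
    m = mx.compute_ocr_metrics(s)
    assert m.atp_synthesis == 0.0
    assert m.spare_capacity == 0.0


@settings(max_examples=200, deadline=None)
@given(basal=st.floats(1.0, 500.0), oligo=st.floats(0.5, 500.0),
       fccp=st.floats(0.5, 900.0), antia=st.floats(0.0, 100.0))
def test_metric_identities_hold_on_any_plateaus(basal, oligo, fccp, antia):
    """basal = ATP synthesis + leak and spare = maximal - basal hold exactly
    whenever no clipping fires."""
    m = mx.ocr_metrics_from_plateaus(basal, oligo, fccp, antia)
    if not m.flags:
        assert m.basal == pytest.approx(m.atp_synthesis + m.h_leak, abs=1e-9)
        assert m.spare_capacity == pytest.approx(m.maximal - m.basal, abs=1e-9)
        assert m.basal >= 0 and m.h_leak >= 0 and m.maximal >= 0


def test_negative_subtracted_values_clip_with_flag():
    m = mx.ocr_metrics_from_plateaus(10.0, 5.0, 12.0, 20.0)
    assert "basal_clipped_negative" in m.flags
    assert m.basal == 0.0


def test_missing_phase_yields_flagged_empty_metrics():
    s = make_series({"baseline": 100.0, "oligomycin": 40.0,
                     "fccp": 150.0, "antimycin_a": 20.0})
    s.injections.pop("fccp")
    m = mx.compute_ocr_metrics(s)
    assert m.basal is None
    assert any(f.startswith("missing_phases") for f in m.flags)


def test_ecar_metrics_and_ratio():
    s = make_series(
        {"baseline": 120.0, "oligomycin": 50.0, "fccp": 160.0,
         "antimycin_a": 20.0},
        ecar={"baseline": 10.0, "oligomycin": 14.0, "fccp": 14.0,
              "antimycin_a": 14.0})
    m = mx.compute_ecar_metrics(s)
    assert m.basal_ecar == pytest.approx(10.0)
    assert m.maximal_glycolysis == pytest.approx(14.0)
    assert m.glycolytic_reserve == pytest.approx(4.0)
    # ratio uses mitochondrial basal OCR (120 - 20) over basal ECAR
    assert m.ocr_ecar_ratio == pytest.approx(10.0)


def test_atp_rate_total_proton_production_is_division():
    s = make_series(
        {"baseline": 0.0, "oligomycin": 0.0, "fccp": 0.0, "antimycin_a": 0.0},
        ecar={"baseline": 10.0, "oligomycin": 10.0, "fccp": 10.0,
              "antimycin_a": 10.0})
    rates = mx.compute_atp_rates(s, buffering_power=0.1)
    # all-zero OCR -> everything glycolytic: 10 / 0.1 = 100 pmol H+/min
    assert rates["basal"].atp_glycolytic == pytest.approx(100.0)
    assert rates["basal"].atp_total == pytest.approx(100.0)


def test_atp_rates_additive_and_linear():
    ocr = {"baseline": 120.0, "oligomycin": 50.0, "fccp": 160.0,
           "antimycin_a": 20.0}
    ecar = {"baseline": 10.0, "oligomycin": 14.0, "fccp": 14.0,
            "antimycin_a": 14.0}
    r1 = mx.compute_atp_rates(make_series(ocr, ecar), buffering_power=0.1)
    for phase in ("basal", "oligomycin"):
        m = r1[phase]
        assert m.atp_total == pytest.approx(m.atp_glycolytic + m.atp_oxidative)
    # uniform 2x scaling of OCR and ECAR doubles every rate
    ocr2 = {k: 2 * v for k, v in ocr.items()}
    ecar2 = {k: 2 * v for k, v in ecar.items()}
    r2 = mx.compute_atp_rates(make_series(ocr2, ecar2), buffering_power=0.1)
    for phase in ("basal", "oligomycin"):
        assert r2[phase].atp_total == pytest.approx(2 * r1[phase].atp_total)
        assert r2[phase].atp_glycolytic == pytest.approx(
            2 * r1[phase].atp_glycolytic)


def test_atp_rates_require_valid_inputs():
    s = make_series({"baseline": 100.0, "oligomycin": 40.0, "fccp": 150.0,
                     "antimycin_a": 20.0},
                    ecar={"baseline": 10.0, "oligomycin": 14.0, "fccp": 14.0,
                          "antimycin_a": 14.0})
    with pytest.raises(ValueError):
        mx.compute_atp_rates(s, buffering_power=0.0)


# ---------------------------------------------------------------------------
# imaging traces
# ---------------------------------------------------------------------------

def make_trace(signal, drugs, dt=1.0):
    t = np.arange(len(signal)) * dt
    return mx.ImagingTrace(cell="c0", group="WT", time_min=t,
                           signal=np.asarray(signal, dtype=float),
                           drugs=drugs)


def test_constant_trace_normalizes_to_one():
    tr = make_trace([100.0] * 40, {"oligomycin": 10.0})
    nt = mx.normalize_trace(tr)
    assert np.allclose(nt.normalized, 1.0)
    assert nt.fold_changes["oligomycin"] == pytest.approx(1.0)
    assert nt.stable


def test_step_trace_fold_change():
    sig = [100.0] * 10 + [150.0] * 40
    tr = make_trace(sig, {"fccp": 10.0})
    nt = mx.normalize_trace(tr, readout_delay_min=20.0)
    assert nt.fold_changes["fccp"] == pytest.approx(1.5)


def test_unstable_baseline_flagged():
    sig = np.concatenate([np.linspace(100, 140, 10), np.full(30, 140.0)])
    tr = make_trace(list(sig), {"fccp": 10.0})
    nt = mx.normalize_trace(tr, slope_tol_pct_per_min=0.5)
    assert not nt.stable
    assert "unstable_baseline" in nt.flags


def test_too_few_baseline_points_rejected():
    tr = make_trace([100.0] * 30, {"fccp": 1.5})
    with pytest.raises(ValueError):
        mx.normalize_trace(tr)


def test_post_drug_slope_measures_ramp():
    sig = [100.0] * 10 + list(100 + 4.0 * np.arange(1, 31))
    tr = make_trace(sig, {"rotenone": 10.0})
    slope = mx.post_drug_slope(tr, "rotenone", window_min=5.0)
    assert slope == pytest.approx(0.04, rel=1e-6)  # 4 a.u./min on baseline 100


# ---------------------------------------------------------------------------
# group statistics
# ---------------------------------------------------------------------------

def test_identical_groups_show_no_change():
    df = pd.DataFrame({"group": ["a"] * 5 + ["b"] * 5,
                       "m": [3.0] * 10})
    out = mx.group_compare(df, ["m"])
    row = out.iloc[0]
    assert row["percent_change"] == 0.0
    assert row.p_ttest == pytest.approx(1.0)
    assert row.p_ranksum == pytest.approx(1.0)


def test_ttest_power_matches_analytic_at_n50():
    """Empirical rejection rate over seeded replicates matches the analytic
    two-sample power within Monte-Carlo error."""
    from statsmodels.stats.power import TTestIndPower

    rng = np.random.default_rng(777)
    n, d = 50, 0.5
    want = TTestIndPower().power(effect_size=d, nobs1=n, ratio=1.0,
                                 alpha=0.05)
    reps = 4000
    hits = 0
    for _ in range(reps):
        df = pd.DataFrame({
            "group": ["a"] * n + ["b"] * n,
            "m": np.concatenate([rng.normal(0, 1, n), rng.normal(d, 1, n)])})
        hits += mx.group_compare(df, ["m"]).iloc[0].p_ttest < 0.05
    emp = hits / reps
    se = np.sqrt(want * (1 - want) / reps)
    assert abs(emp - want) < 4 * se


def test_group_compare_rejects_degenerate_groups():
    df = pd.DataFrame({"group": ["a", "b", "b"], "m": [1.0, 2.0, 3.0]})
    with pytest.raises(ValueError):
        mx.group_compare(df, ["m"])


def test_plate_tidy_roundtrip():
    s = make_series({"baseline": 100.0, "oligomycin": 40.0, "fccp": 150.0,
                     "antimycin_a": 20.0},
                    ecar={"baseline": 10.0, "oligomycin": 14.0, "fccp": 14.0,
                          "antimycin_a": 14.0})
    df = mx.plates_to_tidy([s])
    back = mx.plates_from_tidy(df, s.injections)
    assert len(back) == 1
    assert np.allclose(back[0].ocr, s.ocr)
    assert np.allclose(back[0].ecar, s.ecar)


def test_wide_plate_reader_matches_tidy():
    s = make_series({"baseline": 100.0, "oligomycin": 40.0, "fccp": 150.0,
                     "antimycin_a": 20.0})
    wide = pd.DataFrame({"time_min": s.time_min, "WT/w0": s.ocr})
    wells = mx.plates_from_wide(wide, s.injections)
    assert wells[0].group == "WT" and wells[0].well == "w0"
    m1 = mx.compute_ocr_metrics(wells[0])
    m2 = mx.compute_ocr_metrics(s)
    assert m1.maximal == pytest.approx(m2.maximal)
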