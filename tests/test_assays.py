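"""Electrophysiology and flux metrics against generator ground truth."""

import numpy as np
import pytest

from pipgate.assays import (
    CurrentTrace,
    FluxTrace,
    ProtocolEvent,
    ba_sensitive_current,
    current_density,
    fit_single_exponential,
    fractional_activation,
    fractional_inhibition,
    percent_change_vs_basal,
    relative_flux,
)
from pipgate.errors import FitError, TraceError
from pipgate.synthetic import EphysSimConfig, FluxSimConfig, generate_ephys_trace, generate_flux_trace


def _step_trace(levels, seg_len=100, dt=0.1, events=None):
    current = np.concatenate([np.full(seg_len, v) for v in levels])
    times = dt * np.arange(current.size)
    return CurrentTrace(times=times, current=current, holding_mV=-100,
                        events=events or [])


# ---------------------------------------------------------------------------
# Ba-sensitive current and density


def test_ba_sensitive_trivial_levels():
    tr = _step_trace([-10.0, 0.0], events=[ProtocolEvent(10.0, "Ba_on")])
    assert ba_sensitive_current(tr) == pytest.approx(-10.0)
    tr2 = _step_trace([-5.0, -5.0], events=[ProtocolEvent(10.0, "Ba_on")])
    assert ba_sensitive_current(tr2) == pytest.approx(0.0)


def test_ba_sensitive_missing_epoch_errors():
    tr = _step_trace([-10.0, 0.0])
    with pytest.raises(TraceError, match="Ba_on"):
        ba_sensitive_current(tr)


def test_ba_sensitive_recovers_programmed_value():
    cfg = EphysSimConfig(protocol="inhibition", ba_sensitive_pA=-200.0,
                         noise_sigma_pA=2.0, seed=81)
    trace, truth = generate_ephys_trace(cfg, pulse_duration_ms=300.0)
    # basal epoch has >= 100 samples; sigma 2 pA -> +/- 1 pA comfortably
    assert ba_sensitive_current(trace) == pytest.approx(-200.0, abs=1.0)


def test_current_density_scale_and_errors():
    assert current_density(-2322.0, 10.0) == pytest.approx(-232.2)
    assert current_density(0.0, 12.0) == 0.0
    with pytest.raises(TraceError):
        current_density(-100.0, 0.0)


def test_current_density_recovered_on_synthetic_cohort():
    vals = []
    for seed in range(8):
        cfg = EphysSimConfig(protocol="inhibition", noise_sigma_pA=2.0, seed=seed)
        trace, truth = generate_ephys_trace(cfg, pulse_duration_ms=300.0)
        vals.append(
            current_density(ba_sensitive_current(trace), trace.capacitance_pF)
        )
    expected = -500.0 / 10.0
    assert np.mean(vals) == pytest.approx(expected, abs=0.2)


# ---------------------------------------------------------------------------
# Percent change vs basal


def test_percent_change_trivial_cases():
    events = [
        ProtocolEvent(10.0, "drug_on", name="MPD"),
        ProtocolEvent(20.0, "drug_off", name="MPD"),
        ProtocolEvent(30.0, "Ba_on"),
    ]
    # drug abolishes exactly the Ba-sensitive component -> -100%
    tr = _step_trace([-100.0, -20.0, -100.0, -20.0], events=events)
    assert percent_change_vs_basal(tr, "MPD") == pytest.approx(-100.0)
    # drug epoch equals basal -> 0%
    tr0 = _step_trace([-100.0, -100.0, -100.0, -20.0], events=events)
    assert percent_change_vs_basal(tr0, "MPD") == pytest.approx(0.0)


def test_percent_change_recovers_programmed_inhibition():
    cfg = EphysSimConfig(protocol="drug", noise_sigma_pA=2.0, seed=82)
    trace, truth = generate_ephys_trace(cfg)
    assert percent_change_vs_basal(trace, truth["drug"]) == pytest.approx(
        truth["percent_change"], abs=1.5
    )


def test_percent_change_zero_denominator_errors():
    events = [
        ProtocolEvent(10.0, "drug_on", name="MPD"),
        ProtocolEvent(20.0, "drug_off", name="MPD"),
        ProtocolEvent(30.0, "Ba_on"),
    ]
    tr = _step_trace([-20.0, -10.0, -20.0, -20.0], events=events)
    with pytest.raises(TraceError, match="denominator"):
        percent_change_vs_basal(tr, "MPD")


# ---------------------------------------------------------------------------
# Exponential fits


def test_noiseless_exponential_recovered_exactly():
    t = np.linspace(0, 120, 600)
    tau = 25.0
    current = -150.0 + (-500.0 + 150.0) * np.exp(-t / tau)
    fit = fit_single_exponential(t, current)
    assert fit.tau == pytest.approx(tau, abs=1e-4)
    assert fit.asymptote == pytest.approx(-150.0, abs=1e-6)
    assert not fit.tau_at_bound


def test_fit_recovery_error_scales_with_noise():
    rng = np.random.default_rng(83)
    t = np.linspace(0, 150, 1500)
    tau = 35.8
    clean = -100.0 - 400.0 * np.exp(-t / tau)
    errs = []
    for sigma in (2.0, 20.0):
        taus = [
            fit_single_exponential(
                t, clean + rng.normal(0, sigma, t.size)
            ).tau
            for _ in range(20)
        ]
        errs.append(np.std(taus))
    assert errs[1] > 3 * errs[0]  # error grows roughly in proportion to sigma


def test_fit_requires_minimum_samples():
    with pytest.raises(TraceError, match="10 samples"):
        fit_single_exponential(np.arange(5.0), np.arange(5.0))


def test_fit_flat_segment_errors():
    with pytest.raises(FitError, match="flat"):
        fit_single_exponential(np.arange(20.0), np.zeros(20))


def test_median_tau_recovery_within_five_percent():
    """Parameter-recovery study: 50 seeded noisy replicates per arm at
    noise sigma = 5% of span."""
    recovered = {"depletion": [], "recovery": []}
    for seed in range(50):
        cfg = EphysSimConfig(protocol="recovery", noise_sigma_pA=0.05 * 350.0,
                             seed=seed)
        trace, truth = generate_ephys_trace(cfg)
        for arm in ("depletion", "recovery"):
            t0, t1 = truth[f"{arm}_segment"]
            m = (trace.times >= t0) & (trace.times < t1)
            recovered[arm].append(
                fit_single_exponential(trace.times[m], trace.current[m], arm).tau
            )
    assert np.median(recovered["depletion"]) == pytest.approx(24.9, rel=0.05)
    assert np.median(recovered["recovery"]) == pytest.approx(35.8, rel=0.05)


# ---------------------------------------------------------------------------
# Fractional inhibition


def test_fractional_inhibition_trivial_extremes():
    events = [
        ProtocolEvent(10.0, "vsp_pulse", duration_ms=300.0),
        ProtocolEvent(20.0, "Ba_on"),
    ]
    # post equals Ba level -> 1.0
    tr = _step_trace([-100.0, -20.0, -20.0], events=events)
    assert float(fractional_inhibition(tr, 300.0)) == pytest.approx(1.0)
    # post equals pre -> 0.0
    tr0 = _step_trace([-100.0, -100.0, -20.0], events=events)
    assert float(fractional_inhibition(tr0, 300.0)) == pytest.approx(0.0)


def test_fractional_inhibition_clipping_flag():
    events = [
        ProtocolEvent(10.0, "vsp_pulse", duration_ms=300.0),
        ProtocolEvent(20.0, "Ba_on"),
    ]
    # post overshoots past the Ba level -> clip at 1.1 and flag
    tr = _step_trace([-100.0, 30.0, -20.0], events=events)
    result = fractional_inhibition(tr, 300.0)
    assert float(result) == pytest.approx(1.1)
    assert result.out_of_range


def test_fractional_inhibition_recovers_programmed_value():
    cfg = EphysSimConfig(protocol="inhibition", noise_sigma_pA=0.02 * 350.0, seed=84)
    trace, truth = generate_ephys_trace(cfg, pulse_duration_ms=300.0)
    value = fractional_inhibition(trace, 300.0)
    assert float(value) == pytest.approx(0.70, abs=0.02)
    assert not value.out_of_range


def test_fractional_inhibition_affine_invariance():
    cfg = EphysSimConfig(protocol="inhibition", noise_sigma_pA=1.0, seed=85)
    trace, _ = generate_ephys_trace(cfg, pulse_duration_ms=300.0)
    scaled = CurrentTrace(
        times=trace.times,
        current=3.7 * trace.current + 42.0,
        holding_mV=trace.holding_mV,
        capacitance_pF=trace.capacitance_pF,
        events=trace.events,
    )
    assert float(fractional_inhibition(scaled, 300.0)) == pytest.approx(
        float(fractional_inhibition(trace, 300.0)), abs=1e-12
    )


# ---------------------------------------------------------------------------
# Flux metrics


def test_relative_flux_trivial_extremes():
    # no quench after lipid, full quench only after valinomycin -> ~0
    trace, _ = generate_flux_trace(FluxSimConfig(true_relative_flux=0.0,
                                                 noise_fraction=0.0, seed=86))
    assert relative_flux(trace) == pytest.approx(0.0, abs=0.01)
    # lipid quench reaching the valinomycin floor -> ~1
    trace, _ = generate_flux_trace(FluxSimConfig(true_relative_flux=1.0,
                                                 noise_fraction=0.0, seed=86))
    assert relative_flux(trace) == pytest.approx(1.0, abs=0.01)


def test_relative_flux_recovers_half_with_noise():
    vals = [
        relative_flux(
            generate_flux_trace(
                FluxSimConfig(true_relative_flux=0.5, noise_fraction=0.01, seed=s)
            )[0]
        )
        for s in range(5)
    ]
    assert np.mean(vals) == pytest.approx(0.50, abs=0.02)


def test_relative_flux_affine_invariance():
    trace, _ = generate_flux_trace(FluxSimConfig(true_relative_flux=0.6, seed=87))
    scaled = FluxTrace(
        times=trace.times,
        fluorescence=2.5 * trace.fluorescence + 30.0,
        events=trace.events,
    )
    assert relative_flux(scaled) == pytest.approx(relative_flux(trace), abs=1e-12)


def test_relative_flux_short_trace_errors():
    trace, _ = generate_flux_trace(FluxSimConfig(seed=88))
    cut = trace.times < trace.event_time("valinomycin")
    with pytest.raises(TraceError):
        FluxTrace(times=trace.times[cut], fluorescence=trace.fluorescence[cut],
                  events=trace.events[:2]).event_time("valinomycin")
    short = FluxTrace(
        times=trace.times[:400], fluorescence=trace.fluorescence[:400],
        events=[trace.events[0], trace.events[1],
                ProtocolEvent(trace.times[399], "valinomycin")],
    )
    with pytest.raises(TraceError, match="needs"):
        relative_flux(short)


def test_flux_event_order_enforced():
    with pytest.raises(TraceError, match="order"):
        FluxSimConfig(t_cccp_s=200.0, t_lipid_s=100.0)
    times = np.arange(0.0, 2000.0, 2.0)
    with pytest.raises(TraceError):
        FluxTrace(times=times, fluorescence=np.ones_like(times),
                  events=[ProtocolEvent(500.0, "CCCP"),
                          ProtocolEvent(100.0, "lipid", name="x"),
                          ProtocolEvent(1500.0, "valinomycin")])


def test_fractional_activation_formula_and_errors():
    assert fractional_activation(0.05, 0.05, 0.9) == pytest.approx(0.0)
    assert fractional_activation(0.9, 0.05, 0.9) == pytest.approx(1.0)
    assert fractional_activation(0.39, 0.05, 0.90) == pytest.approx(0.4)
    with pytest.raises(TraceError):
        fractional_activation(0.5, 0.9, 0.9)


def test_fractional_activation_recovered_from_traces():
    """A PI(5)P-like condition programmed at 0.4 of the PI(4,5)P2 response."""
    leak, full, fa_true = 0.05, 0.90, 0.4
    rf_x = leak + fa_true * (full - leak)

    def mean_flux(rf, base_seed):
        return np.mean([
            relative_flux(
                generate_flux_trace(
                    FluxSimConfig(true_relative_flux=rf, noise_fraction=0.01,
                                  seed=base_seed + s)
                )[0]
            )
            for s in range(4)
        ])

    fa = fractional_activation(
        mean_flux(rf_x, 100), mean_flux(leak, 200), mean_flux(full, 300)
    )
    assert fa == pytest.approx(fa_true, abs=0.03)
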