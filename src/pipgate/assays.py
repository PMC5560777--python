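"""Electrophysiology normalizations, Dr-Vsp kinetics, and flux quantification.

Sign conventions: inward currents are negative.  The Ba2+-sensitive current
is basal minus the current remaining in barium block (so it is negative for
an inward basal current).  Fractional inhibition and fractional activation
are normalised ratios, invariant under affine rescaling (gain/offset) of
the raw signal.  "Steady state" is the mean of the last 20% of an epoch.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.optimize import curve_fit

from .errors import FitError, TraceError


@dataclass(frozen=True)
class ProtocolEvent:
    """One annotated protocol event on a trace.

    ``kind`` is one of drug_on, drug_off, Ba_on, Ba_off, vsp_pulse (current
    traces) or CCCP, lipid, valinomycin, vehicle (flux traces); ``name``
    optionally identifies the drug/lipid; ``duration_ms`` applies to
    vsp_pulse events.
    """

    time: float
    kind: str
    name: str | None = None
    duration_ms: float | None = None


_CURRENT_EVENT_KINDS = {"drug_on", "drug_off", "Ba_on", "Ba_off", "vsp_pulse"}
_FLUX_EVENT_KINDS = {"CCCP", "lipid", "valinomycin", "vehicle"}


@dataclass
class CurrentTrace:
    """Whole-cell current recording (s, pA) with protocol annotations."""

    times: np.ndarray
    current: np.ndarray
    holding_mV: float
    capacitance_pF: float | None = None
    events: list[ProtocolEvent] = field(default_factory=list)

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.current = np.asarray(self.current, dtype=float)
        if self.times.shape != self.current.shape:
            raise TraceError("times and current must have equal length")
        if self.times.size > 1 and not np.all(np.diff(self.times) > 0):
            raise TraceError("times must be strictly increasing")
        self.events = sorted(self.events, key=lambda e: e.time)
        for e in self.events:
            if e.kind not in _CURRENT_EVENT_KINDS:
                raise TraceError(f"unknown event kind {e.kind!r}")
            if not (self.times[0] <= e.time <= self.times[-1]):
                raise TraceError(f"event {e.kind} at {e.time}s outside trace range")


@dataclass
class FluxTrace:
    """ACMA fluorescence trace (s, arbitrary units) with addition events."""

    times: np.ndarray
    fluorescence: np.ndarray
    events: list[ProtocolEvent] = field(default_factory=list)

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.fluorescence = np.asarray(self.fluorescence, dtype=float)
        if self.times.shape != self.fluorescence.shape:
            raise TraceError("times and fluorescence must have equal length")
        if self.times.size > 1 and not np.all(np.diff(self.times) > 0):
            raise TraceError("times must be strictly increasing")
        self.events = sorted(self.events, key=lambda e: e.time)
        for e in self.events:
            if e.kind not in _FLUX_EVENT_KINDS:
                raise TraceError(f"unknown event kind {e.kind!r}")
        order = [e.kind for e in self.events if e.kind in ("CCCP", "lipid", "vehicle", "valinomycin")]
        required = ["CCCP", "valinomycin"]
        for r in required:
            if r not in order:
                raise TraceError(f"flux trace missing {r} event")
        t_cccp = self.event_time("CCCP")
        t_lip = self._lipid_time()
        t_val = self.event_time("valinomycin")
        if not (t_cccp < t_lip < t_val):
            raise TraceError("events must be ordered CCCP < lipid/vehicle < valinomycin")

    def event_time(self, kind: str) -> float:
        for e in self.events:
            if e.kind == kind:
                return e.time
        raise TraceError(f"no {kind} event on trace")

    def _lipid_time(self) -> float:
        for e in self.events:
            if e.kind in ("lipid", "vehicle"):
                return e.time
        raise TraceError("no lipid or vehicle event on trace")


@dataclass
class ExpFitResult:
    """Single-exponential fit I(t) = I_inf + (I0 - I_inf) exp(-(t-t0)/tau)."""

    tau: float  # s
    amplitude: float  # I0 - I_inf, pA
    asymptote: float  # I_inf, pA
    residual_rms: float
    fit_window: tuple[float, float]
    tau_at_bound: bool = False

    def __post_init__(self):
        if self.tau <= 0:
            raise FitError("tau must be positive")


# ---------------------------------------------------------------------------
# Epoch bookkeeping


def _epoch_slice(trace: CurrentTrace, t_start: float, t_stop: float) -> np.ndarray:
    mask = (trace.times >= t_start) & (trace.times < t_stop)
    idx = np.flatnonzero(mask)
    if idx.size == 0:
        raise TraceError(f"no samples in epoch [{t_start}, {t_stop}) s")
    return idx


def _steady_mean(
    trace: CurrentTrace, t_start: float, t_stop: float, steady_fraction: float
) -> float:
    idx = _epoch_slice(trace, t_start, t_stop)
    n_tail = max(int(round(idx.size * steady_fraction)), 1)
    return float(trace.current[idx[-n_tail:]].mean())


def _event_bounds(trace: CurrentTrace, kind: str, **match) -> tuple[float, float, ProtocolEvent]:
    """(epoch start, epoch end, event) for the epoch opened by an event kind."""
    for i, e in enumerate(trace.events):
        if e.kind != kind:
            continue
        if match.get("name") is not None and e.name != match["name"]:
            continue
        if match.get("duration_ms") is not None and e.duration_ms != match["duration_ms"]:
            continue
        t_end = trace.times[-1] + np.finfo(float).eps
        for later in trace.events[i + 1:]:
            t_end = later.time
            break
        return e.time, t_end, e
    raise TraceError(f"no {kind} event matching {match} on trace")


def _pre_event_bounds(trace: CurrentTrace, event: ProtocolEvent) -> tuple[float, float]:
    """Epoch immediately preceding an event: from the previous event (or start)."""
    t_start = trace.times[0]
    for e in trace.events:
        if e.time < event.time:
            t_start = e.time
    return t_start, event.time


def _ba_steady(trace: CurrentTrace, steady_fraction: float) -> float:
    t0, t1, _ = _event_bounds(trace, "Ba_on")
    return _steady_mean(trace, t0, t1, steady_fraction)


# ---------------------------------------------------------------------------
# Current metrics


def ba_sensitive_current(trace: CurrentTrace, steady_fraction: float = 0.2) -> float:
    """Ba2+-sensitive basal current: steady basal minus steady current in Ba2+.

    The basal epoch runs from the start of the trace to the first event;
    steady values are the mean of the last ``steady_fraction`` of each epoch.
    """
    if not any(e.kind == "Ba_on" for e in trace.events):
        raise TraceError("trace has no Ba_on event")
    first_event_t = trace.events[0].time
    basal = _steady_mean(trace, trace.times[0], first_event_t, steady_fraction)
    ba = _ba_steady(trace, steady_fraction)
    return basal - ba


def current_density(current_pA: float, capacitance_pF: float) -> float:
    """Current density in pA/pF; sign preserved."""
    if capacitance_pF <= 0:
        raise TraceError("capacitance must be positive")
    return current_pA / capacitance_pF


def percent_change_vs_basal(
    trace: CurrentTrace, drug_label: str, steady_fraction: float = 0.2
) -> float:
    """Percent change of the drug steady state relative to the Ba2+ basal.

    100 x (mean(drug) - mean(basal)) / (mean(basal) - mean(Ba)); for inward
    (negative) currents a drug that inhibits gives a negative percentage,
    and one that abolishes exactly the Ba2+-sensitive component gives -100%.
    """
    t0, t1, e = _event_bounds(trace, "drug_on", name=drug_label)
    drug = _steady_mean(trace, t0, t1, steady_fraction)
    p0, p1 = _pre_event_bounds(trace, e)
    basal = _steady_mean(trace, p0, p1, steady_fraction)
    ba = _ba_steady(trace, steady_fraction)
    denom = basal - ba
    if denom == 0:
        raise TraceError("zero Ba2+-sensitive denominator")
    return 100.0 * (drug - basal) / denom


def fit_single_exponential(
    times: np.ndarray,
    current: np.ndarray,
    direction: str | None = None,
    max_nfev: int = 10000,
) -> ExpFitResult:
    """Bounded least-squares fit of a single exponential to a trace segment.

    Initialisation: the asymptote from the mean of the last 10% of samples,
    the starting value from the first sample, and tau from the time the
    signal first covers 63% of its span.  ``direction`` ("depletion" or
    "recovery") is annotation only; the model is symmetric.
    """
    times = np.asarray(times, dtype=float)
    current = np.asarray(current, dtype=float)
    if times.size < 10:
        raise TraceError("exponential fit needs at least 10 samples")
    t0 = times[0]
    i_inf0 = float(current[-max(times.size // 10, 1):].mean())
    i0 = float(current[0])
    span = i0 - i_inf0
    if span == 0:
        raise FitError("flat segment: no span to fit")
    frac = (current - i_inf0) / span
    below = np.flatnonzero(frac <= np.exp(-1.0))
    tau0 = float(times[below[0]] - t0) if below.size else float(times[-1] - t0) / 2
    tau0 = max(tau0, float(np.diff(times).min()))

    def model(t, tau, i0_, iinf):
        return iinf + (i0_ - iinf) * np.exp(-(t - t0) / tau)

    t_total = float(times[-1] - t0)
    tau_lo, tau_hi = t_total * 1e-6, t_total * 1e3
    try:
        popt, _ = curve_fit(
            model,
            times,
            current,
            p0=[tau0, i0, i_inf0],
            bounds=([tau_lo, -np.inf, -np.inf], [tau_hi, np.inf, np.inf]),
            max_nfev=max_nfev,
        )
    except RuntimeError as exc:
        raise FitError(
            f"exponential fit did not converge in {max_nfev} evaluations "
            f"(init tau={tau0:.3g}s, span={span:.3g} pA): {exc}"
        ) from exc
    tau, i0_fit, iinf_fit = (float(v) for v in popt)
    resid = current - model(times, *popt)
    at_bound = bool(
        np.isclose(tau, tau_lo, rtol=1e-3) or np.isclose(tau, tau_hi, rtol=1e-3)
    )
    return ExpFitResult(
        tau=tau,
        amplitude=i0_fit - iinf_fit,
        asymptote=iinf_fit,
        residual_rms=float(np.sqrt(np.mean(resid**2))),
        fit_window=(float(times[0]), float(times[-1])),
        tau_at_bound=at_bound,
    )


class FlaggedFraction(float):
    """A float carrying an out-of-range flag (report range clipping)."""

    out_of_range: bool = False

    def __new__(cls, value: float, out_of_range: bool = False):
        obj = super().__new__(cls, value)
        obj.out_of_range = out_of_range
        return obj


def fractional_inhibition(
    trace: CurrentTrace, pulse_duration_ms: float, steady_fraction: float = 0.2
) -> FlaggedFraction:
    """Fractional inhibition of the steady-state basal current by a Vsp pulse.

    (mean(pre) - mean(post)) / (mean(pre) - mean(Ba)), where pre and post
    are the steady segments flanking the vsp_pulse event of the given
    duration.  The report is clipped to [-0.1, 1.1] with an out-of-range
    flag.  A post level equal to the Ba2+ level gives 1.0; no change gives 0.
    """
    t0, t1, e = _event_bounds(trace, "vsp_pulse", duration_ms=pulse_duration_ms)
    post = _steady_mean(trace, t0, t1, steady_fraction)
    p0, p1 = _pre_event_bounds(trace, e)
    pre = _steady_mean(trace, p0, p1, steady_fraction)
    ba = _ba_steady(trace, steady_fraction)
    denom = pre - ba
    if denom == 0:
        raise TraceError("zero Ba2+-sensitive denominator")
    frac = (pre - post) / denom
    clipped = min(max(frac, -0.1), 1.1)
    return FlaggedFraction(clipped, out_of_range=(frac != clipped))


# ---------------------------------------------------------------------------
# Flux metrics


def _median_at(trace: FluxTrace, t: float, values: np.ndarray, k: int = 5) -> float:
    """k-point median of a signal around the sample nearest to time t."""
    i = int(np.argmin(np.abs(trace.times - t)))
    half = k // 2
    lo, hi = max(i - half, 0), min(i + half + 1, values.size)
    return float(np.median(values[lo:hi]))


def relative_flux(
    trace: FluxTrace, quench_time_s: float = 900.0, smooth_points: int = 5
) -> float:
    """Relative K+ flux from an ACMA quench trace.

    With F_hat = F / F_basal (basal = mean fluorescence before CCCP), the
    metric is the fluorescence decrease over ``quench_time_s`` after lipid
    (or vehicle) addition, normalised to the maximal valinomycin-defined
    quench: (F_hat(t_lipid) - F_hat(t_lipid + 900 s)) /
    (F_hat(pre-valinomycin) - min F_hat(post-valinomycin)).  Time-point
    values use a small running median for noise robustness.
    """
    t_lip = trace._lipid_time()
    t_val = trace.event_time("valinomycin")
    t_cccp = trace.event_time("CCCP")
    if trace.times[-1] < t_lip + quench_time_s:
        raise TraceError(
            f"trace ends {trace.times[-1]:.0f}s, needs >= {quench_time_s:.0f}s "
            "past lipid addition"
        )
    basal_mask = trace.times < t_cccp
    if not basal_mask.any():
        raise TraceError("no samples before CCCP for basal fluorescence")
    f_basal = float(trace.fluorescence[basal_mask].mean())
    if f_basal <= 0:
        raise TraceError("basal fluorescence must be positive")
    fhat = trace.fluorescence / f_basal
    f_at_lipid = _median_at(trace, t_lip, fhat, smooth_points)
    f_after = _median_at(trace, t_lip + quench_time_s, fhat, smooth_points)
    pre_val = _median_at(trace, t_val, fhat, smooth_points)
    post_mask = trace.times > t_val
    if not post_mask.any():
        raise TraceError("no samples after valinomycin")
    f_min = float(fhat[post_mask].min())
    denom = pre_val - f_min
    if denom == 0:
        raise TraceError("zero valinomycin quench: cannot normalise")
    return (f_at_lipid - f_after) / denom


def fractional_activation(
    flux_x: float, flux_vehicle: float, flux_pip2: float
) -> float:
    """Lipid-evoked flux normalised to PI(4,5)P2 after leak subtraction."""
    denom = flux_pip2 - flux_vehicle
    if denom <= 0:
        raise TraceError("PI(4,5)P2 flux must exceed vehicle flux")
    return (flux_x - flux_vehicle) / denom
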