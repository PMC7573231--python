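"""High-resolution respirometry analysis for SUIT titration runs.

Converts annotated oxygen-concentration traces into per-state steady
fluxes, applies baseline correction and the cytochrome-c membrane
integrity check, aggregates runs into per-sample state sets with
OXPHOS-anchored standardization, and computes respiratory control ratios
and paired pre/post comparisons.

Units: oxygen concentration is nmol O2 ml^-1; all fluxes are
pmol O2 s^-1 mg^-1 (tissue wet mass).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
from scipy import stats
from scipy.signal import savgol_filter

from .errors import (
    ClippingWarning,
    InsufficientDataError,
    MissingBaselineError,
    NoVarianceError,
    QCWarning,
    UndefinedRatioError,
    ValidationError,
)
from .protocols import (
    REPEATED_STATES,
    SINGLE_STATES,
    VALID_AGENTS,
    SuitProtocol,
)

__all__ = [
    "TitrationEvent",
    "OxygenTrace",
    "SteadyState",
    "FluxSeries",
    "RunStates",
    "SampleStateSet",
    "RespiratoryRatios",
    "PairedComparison",
    "compute_flux",
    "detect_steady_states",
    "baseline_correct",
    "cytc_test",
    "check_oxygen_window",
    "run_states",
    "aggregate_sample",
    "respiratory_ratios",
    "paired_compare",
    "O2_WINDOW",
    "CYTC_FAIL_THRESHOLD",
]

#: Closed oxygen-concentration operating window, nmol ml^-1.
O2_WINDOW = (250.0, 400.0)
#: Fractional flux increase after cytochrome c above which a run fails QC
#: (strictly greater than).
CYTC_FAIL_THRESHOLD = 0.10


# ---------------------------------------------------------------------------
# domain types


@dataclass(frozen=True)
class TitrationEvent:
    """A chamber addition (or reoxygenation marker) at time ``t`` seconds."""

    t: float
    agent: str
    target_conc: float | None = None
    unit: str | None = None

    def __post_init__(self) -> None:
        if self.agent not in VALID_AGENTS:
            raise ValidationError(f"unknown titration agent {self.agent!r}")

    @property
    def is_reox(self) -> bool:
        return self.agent == "REOX"


@dataclass
class OxygenTrace:
    """A raw chamber time series with titration-event annotations."""

    run_id: str
    animal_id: str
    timepoint: str
    protocol_id: str
    t: np.ndarray  # seconds
    conc: np.ndarray  # nmol O2 ml^-1
    chamber_volume: float  # ml
    tissue_mass: float  # mg
    events: list[TitrationEvent] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.conc = np.asarray(self.conc, dtype=float)
        if self.t.ndim != 1 or self.t.shape != self.conc.shape:
            raise ValidationError("t and conc must be 1-d arrays of equal length")
        if self.t.size >= 2 and not np.all(np.diff(self.t) > 0):
            raise ValidationError(f"{self.run_id}: time not strictly increasing")
        if self.chamber_volume <= 0:
            raise ValidationError(f"{self.run_id}: chamber_volume must be > 0")
        if self.tissue_mass <= 0:
            raise ValidationError(f"{self.run_id}: tissue_mass must be > 0")
        if np.any(self.conc < 0):
            raise ValidationError(f"{self.run_id}: negative oxygen concentration")
        if self.timepoint not in ("pre", "post"):
            raise ValidationError(f"{self.run_id}: timepoint must be pre|post")
        self.events = sorted(self.events, key=lambda e: e.t)

    @property
    def titrations(self) -> list[TitrationEvent]:
        """Events that add an agent (reoxygenation markers excluded)."""
        return [e for e in self.events if not e.is_reox]

    @property
    def reox_times(self) -> list[float]:
        return [e.t for e in self.events if e.is_reox]

    @property
    def span(self) -> float:
        return float(self.t[-1] - self.t[0]) if self.t.size else 0.0


@dataclass(frozen=True)
class SteadyState:
    """A detected steady-state flux for one protocol step."""

    state_label: str
    flux: float  # pmol O2 s^-1 mg^-1; NaN when no window qualified
    window: tuple[float, float] | None = None
    slope_residual: float = math.nan  # flux change per second in the window
    baseline_corrected: bool = False
    qc_flags: tuple[str, ...] = ()

    @property
    def missing(self) -> bool:
        return not math.isfinite(self.flux)


@dataclass(frozen=True)
class FluxSeries:
    """Per-time oxygen flux; NaN marks intervals masked around reoxygenation."""

    t: np.ndarray
    flux: np.ndarray  # pmol O2 s^-1 mg^-1
    masked_intervals: tuple[tuple[float, float], ...] = ()


@dataclass
class RunStates:
    """Per-run state fluxes after QC, keyed by state label."""

    protocol_id: str
    states: dict[str, float]
    cytc_pass: bool = True

    @property
    def excluded(self) -> bool:
        return not self.cytc_pass


@dataclass
class SampleStateSet:
    """Per animal x timepoint respiratory-state summary.

    ``mean_*`` states are arithmetic means over all contributing runs;
    ``std_*`` states are single measures standardized to the sample-mean
    OXPHOS.  The two leak estimates (Ln, LOmy) are deliberately kept
    distinct and never pooled.
    """

    animal_id: str
    timepoint: str
    mean_Ln: float = math.nan
    mean_OXPHOS: float = math.nan
    mean_ETS: float = math.nan
    std_LOmy: float = math.nan
    std_CI: float = math.nan
    std_CII: float = math.nan
    cytc_pass: bool = True
    excluded: bool = False
    n_runs: int = 0

    def get(self, name: str) -> float:
        mapping = {
            "Ln": self.mean_Ln,
            "OXPHOS": self.mean_OXPHOS,
            "ETS": self.mean_ETS,
            "LOmy": self.std_LOmy,
            "CI": self.std_CI,
            "CII": self.std_CII,
        }
        return mapping[name]


@dataclass(frozen=True)
class RespiratoryRatios:
    """Control ratios derived from a SampleStateSet."""

    SCR_CI: float
    SCR_CII: float
    CCR_Ln: float
    FCR: float


@dataclass(frozen=True)
class PairedComparison:
    """Two-sided paired t-test summary (difference = post - pre)."""

    t: float
    p: float
    mean_diff: float
    n: int
    alpha: float = 0.05

    @property
    def significant(self) -> bool:
        return self.p < self.alpha


# ---------------------------------------------------------------------------
# flux estimation


def _reox_intervals(
    reox_times: Iterable[float], pad: float
) -> tuple[tuple[float, float], ...]:
    return tuple((rt - pad, rt + pad) for rt in reox_times)


def _local_slope_nonuniform(
    t: np.ndarray, y: np.ndarray, half: float
) -> np.ndarray:
    """Derivative by local quadratic fit; handles irregular sampling."""
    slope = np.empty_like(y)
    for i, ti in enumerate(t):
        sel = (t >= ti - half) & (t <= ti + half)
        n = int(sel.sum())
        if n < 3:
            raise InsufficientDataError(
                f"fewer than 3 samples in the smoothing window at t={ti:.1f}s"
            )
        order = 2 if n > 3 else 1
        coeffs = np.polyfit(t[sel] - ti, y[sel], order)
        slope[i] = coeffs[-2]
    return slope


def _segment_slope(t: np.ndarray, conc: np.ndarray, window: float) -> np.ndarray:
    """Slope within one smooth (event-free) segment."""
    n = t.size
    out = np.full(n, np.nan)
    if n < 3:
        return out
    dt = np.diff(t)
    if np.allclose(dt, dt[0], rtol=1e-6, atol=1e-9):
        step = float(dt[0])
        npts = max(3, int(round(window / step)) | 1)
        if npts > n:
            npts = (n - 1) if (n - 1) % 2 else n - 2
            npts = max(npts, 3)
        out[:] = savgol_filter(
            conc, npts, polyorder=2, deriv=1, delta=step, mode="interp"
        )
    else:
        out[:] = _local_slope_nonuniform(t, conc, window / 2.0)
    return out


def compute_flux(trace: OxygenTrace, smoothing_window: float = 20.0) -> FluxSeries:
    """Estimate mass-specific oxygen flux from a concentration trace.

    flux(t) = -d[O2]/dt x chamber_volume / tissue_mass.  The slope is a
    local quadratic (Savitzky-Golay) fit over ``smoothing_window``
    seconds, computed independently within each inter-event segment so
    that titration discontinuities never bleed into neighbouring
    plateaus.  Samples within ``smoothing_window`` of a reoxygenation
    event are additionally masked NaN (the concentration jump makes the
    derivative meaningless there).
    """
    if trace.t.size < 3:
        raise InsufficientDataError(f"{trace.run_id}: trace has < 3 samples")
    if smoothing_window <= 0 or smoothing_window >= trace.span:
        raise ValidationError("smoothing_window must be in (0, trace span)")
    med_dt = float(np.median(np.diff(trace.t)))
    if smoothing_window < 3 * med_dt:
        raise InsufficientDataError(
            f"{trace.run_id}: fewer than 3 samples per smoothing window"
        )

    cuts = sorted({e.t for e in trace.events})
    edges = [trace.t[0] - 1.0] + cuts + [trace.t[-1] + 1.0]
    slope = np.full(trace.t.size, np.nan)
    for lo, hi in zip(edges[:-1], edges[1:]):
        sel = (trace.t >= lo) & (trace.t < hi)
        if sel.any():
            slope[sel] = _segment_slope(
                trace.t[sel], trace.conc[sel], smoothing_window
            )

    # nmol ml^-1 s^-1 x ml / mg -> nmol s^-1 mg^-1 -> x1000 pmol
    flux = -slope * trace.chamber_volume / trace.tissue_mass * 1000.0

    masked = _reox_intervals(trace.reox_times, smoothing_window)
    for lo, hi in masked:
        flux[(trace.t >= lo) & (trace.t <= hi)] = np.nan
    return FluxSeries(t=trace.t.copy(), flux=flux, masked_intervals=masked)


# ---------------------------------------------------------------------------
# steady-state detection


def _window_ok(t: np.ndarray, flux: np.ndarray, tol: float) -> tuple[bool, float, float]:
    """Stability test on one candidate window: |slope| <= tol * |mean flux|."""
    mean = float(np.mean(flux))
    if t.size >= 2:
        slope = float(np.polyfit(t - t[0], flux, 1)[0])
    else:
        slope = 0.0
    floor = max(abs(mean), 1e-12)
    return abs(slope) <= tol * floor, mean, slope


def detect_steady_states(
    flux_series: FluxSeries,
    events: Sequence[TitrationEvent],
    protocol: SuitProtocol,
    stability_tol: float = 0.02,
    window: float = 60.0,
) -> list[SteadyState]:
    """Assign one steady state per protocol step from an annotated flux series.

    Within each inter-event segment a fixed-length window slides backward
    from the segment end; the first (i.e. latest) window whose flux slope
    magnitude is at most ``stability_tol`` x the window-mean flux is
    accepted and its mean reported.  Windows never overlap masked
    (reoxygenation) intervals.  A step with no qualifying window is
    reported with NaN flux and a QC flag, never dropped.
    """
    events = sorted(events, key=lambda e: e.t)
    # agents added at the same instant form a single titration step
    titration_times: list[float] = []
    for e in events:
        if e.is_reox:
            continue
        if not titration_times or e.t > titration_times[-1]:
            titration_times.append(e.t)
    t, flux = flux_series.t, flux_series.flux
    t_end = float(t[-1])

    # segment boundaries: baseline runs from trace start to first titration
    bounds: list[tuple[str, float, float]] = []
    first_t = titration_times[0] if titration_times else t_end
    bounds.append(("baseline", float(t[0]), float(first_t)))
    n_steps = len(protocol.titration_steps)
    for i, ev_t in enumerate(titration_times[:n_steps]):
        nxt = titration_times[i + 1] if i + 1 < len(titration_times) else t_end
        bounds.append((protocol.titration_steps[i].state, float(ev_t), float(nxt)))

    out: list[SteadyState] = []
    for state, seg_lo, seg_hi in bounds:
        found = None
        hi = seg_hi
        while hi - window >= seg_lo:
            lo = hi - window
            # half-open: the sample at hi belongs to the next segment's fit
            sel = (t >= lo) & (t < hi)
            wt, wf = t[sel], flux[sel]
            if wt.size >= 3 and not np.any(np.isnan(wf)):
                ok, mean, slope = _window_ok(wt, wf, stability_tol)
                if ok:
                    found = SteadyState(
                        state_label=state,
                        flux=mean,
                        window=(lo, hi),
                        slope_residual=slope,
                    )
                    break
            hi -= max(window / 10.0, float(np.median(np.diff(t))))
        if found is None:
            found = SteadyState(
                state_label=state, flux=math.nan, qc_flags=("no_steady_state",)
            )
        out.append(found)
    return out


def baseline_correct(
    states: Sequence[SteadyState],
    baseline_flux: float | None = None,
    run_id: str = "<run>",
) -> list[SteadyState]:
    """Subtract the chamber baseline flux from every non-baseline state.

    Negative corrected fluxes are clipped to zero with a warning
    (baseline noise can push small leak states below zero; negative
    respiration is non-physical).
    """
    if baseline_flux is None:
        base = next((s for s in states if s.state_label == "baseline"), None)
        if base is None or base.missing:
            raise MissingBaselineError(f"run {run_id}: no baseline steady state")
        baseline_flux = base.flux

    out: list[SteadyState] = []
    for s in states:
        if s.state_label == "baseline" or s.missing:
            out.append(replace(s, baseline_corrected=True))
            continue
        corrected = s.flux - baseline_flux
        flags = s.qc_flags
        if corrected < 0:
            warnings.warn(
                f"run {run_id}: {s.state_label} corrected flux "
                f"{corrected:.3g} < 0 clipped to 0",
                ClippingWarning,
                stacklevel=2,
            )
            corrected = 0.0
            flags = flags + ("clipped_negative",)
        out.append(
            replace(s, flux=corrected, baseline_corrected=True, qc_flags=flags)
        )
    return out


def cytc_test(flux_before: float, flux_after: float) -> bool:
    """Cytochrome-c membrane-integrity check.

    Returns True (pass) unless the flux increase after cytochrome c
    exceeds 10% of the pre-addition flux — strictly greater than, so an
    exact 10% bump still passes.
    """
    if flux_before <= 0:
        raise UndefinedRatioError(
            f"cytc_test undefined for flux_before={flux_before}"
        )
    return bool((flux_after - flux_before) / flux_before <= CYTC_FAIL_THRESHOLD)


def check_oxygen_window(
    trace: OxygenTrace,
    lo: float = O2_WINDOW[0],
    hi: float = O2_WINDOW[1],
) -> list[tuple[float, float]]:
    """Intervals (after the first event) where [O2] leaves [lo, hi].

    Bounds are closed; excursions are reported as warnings-level QC
    information and never exclude a run.
    """
    start = trace.events[0].t if trace.events else float(trace.t[0])
    sel = trace.t >= start
    t, conc = trace.t[sel], trace.conc[sel]
    bad = (conc < lo) | (conc > hi)
    intervals: list[tuple[float, float]] = []
    i = 0
    n = bad.size
    while i < n:
        if bad[i]:
            j = i
            while j + 1 < n and bad[j + 1]:
                j += 1
            intervals.append((float(t[i]), float(t[j])))
            i = j + 1
        else:
            i += 1
    return intervals


# ---------------------------------------------------------------------------
# aggregation and comparison


def run_states(
    protocol: SuitProtocol, states: Sequence[SteadyState], run_id: str = "<run>"
) -> RunStates:
    """Collapse detected steady states of one run into a QC'd state map.

    The cytochrome-c check compares the flux of the step preceding the
    CytC titration with the flux right after it; a failing run is marked
    excluded and contributes no states downstream.
    """
    by_label: dict[str, float] = {}
    ordered = [s for s in states if s.state_label != "baseline"]
    cytc_pass = True
    prev: SteadyState | None = None
    for s in ordered:
        if s.state_label == "cytc_check":
            if prev is not None and not prev.missing and not s.missing:
                cytc_pass = cytc_test(prev.flux, s.flux)
            continue
        if s.state_label != "none" and not s.missing:
            by_label[s.state_label] = s.flux
        prev = s if not s.missing else prev
    return RunStates(protocol.protocol_id, by_label, cytc_pass=cytc_pass)


def aggregate_sample(
    runs: Sequence[RunStates], animal_id: str = "", timepoint: str = "pre"
) -> SampleStateSet:
    """Aggregate per-protocol runs into a per-sample state set.

    Repeatedly measured states (Ln, OXPHOS, ETS) are arithmetic means
    over all non-excluded runs measuring them; OXPHOS is pooled across
    all protocols.  Single-measure states X (LOmy, CI, CII) are
    standardized to the sample-mean OXPHOS:

        std_X = (X_run / OXPHOS_run) x mean_OXPHOS

    i.e. the fractional reduction from OXPHOS in the measuring run,
    re-expressed on the sample's average OXPHOS scale.
    """
    usable = [r for r in runs if not r.excluded]
    out = SampleStateSet(animal_id=animal_id, timepoint=timepoint)
    out.n_runs = len(usable)
    if not usable:
        out.excluded = True
        out.cytc_pass = False
        return out

    means: dict[str, float] = {}
    for state in REPEATED_STATES:
        vals = [r.states[state] for r in usable if state in r.states]
        means[state] = float(np.mean(vals)) if vals else math.nan
    out.mean_Ln = means["Ln"]
    out.mean_OXPHOS = means["OXPHOS"]
    out.mean_ETS = means["ETS"]

    for state in SINGLE_STATES:
        vals = []
        for r in usable:
            if state not in r.states:
                continue
            oxphos_run = r.states.get("OXPHOS")
            if oxphos_run is None or not math.isfinite(oxphos_run) or oxphos_run <= 0:
                continue  # OXPHOS missing in the measuring run -> X missing
            vals.append(r.states[state] / oxphos_run * out.mean_OXPHOS)
        std = float(np.mean(vals)) if vals else math.nan
        setattr(out, f"std_{state}", std)
    return out


def respiratory_ratios(s: SampleStateSet) -> RespiratoryRatios:
    """Substrate, coupling and flux control ratios for one sample."""
    if not (math.isfinite(s.mean_OXPHOS) and s.mean_OXPHOS > 0):
        raise UndefinedRatioError(
            f"{s.animal_id}/{s.timepoint}: mean OXPHOS must be > 0 for "
            "SCR_CI, SCR_CII and CCR_Ln"
        )
    if not (math.isfinite(s.mean_ETS) and s.mean_ETS > 0):
        raise UndefinedRatioError(
            f"{s.animal_id}/{s.timepoint}: mean ETS must be > 0 for FCR"
        )
    ratios = RespiratoryRatios(
        SCR_CI=s.std_CI / s.mean_OXPHOS,
        SCR_CII=s.std_CII / s.mean_OXPHOS,
        CCR_Ln=s.mean_Ln / s.mean_OXPHOS,
        FCR=s.mean_OXPHOS / s.mean_ETS,
    )
    for name in ("CCR_Ln", "FCR"):
        v = getattr(ratios, name)
        if math.isfinite(v) and not (0 < v <= 1):
            warnings.warn(
                f"{s.animal_id}/{s.timepoint}: {name}={v:.3g} outside (0, 1]",
                QCWarning,
                stacklevel=2,
            )
    return ratios


def paired_compare(
    pre: Sequence[float], post: Sequence[float], alpha: float = 0.05
) -> PairedComparison:
    """Two-sided paired t-test of post vs pre, paired by position.

    Pairs with any missing (NaN) member are dropped listwise.  All-equal
    differences give an undefined t statistic and raise
    :class:`NoVarianceError`.
    """
    pre = np.asarray(pre, dtype=float)
    post = np.asarray(post, dtype=float)
    if pre.shape != post.shape:
        raise ValidationError("pre and post must have equal length")
    keep = ~(np.isnan(pre) | np.isnan(post))
    pre, post = pre[keep], post[keep]
    n = int(pre.size)
    if n < 2:
        raise InsufficientDataError(f"need >= 2 complete pairs, got {n}")
    diffs = post - pre
    if np.ptp(diffs) == 0:
        raise NoVarianceError("paired differences have zero variance")
    res = stats.ttest_rel(post, pre)
    return PairedComparison(
        t=float(res.statistic),
        p=float(res.pvalue),
        mean_diff=float(np.mean(diffs)),
        n=n,
        alpha=alpha,
    )
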