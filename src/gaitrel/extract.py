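"""Gait-variable extraction from six-sensor IMU sessions.

Pipeline (mirroring how an evaluator works through a recording):

1. :func:`calibrate_orientation` — initial tilt from the gravity vector during
   the 10 s standstill, plus a gyro-bias estimate.
2. :func:`integrate_orientation` — sagittal/coronal segment angle by
   trapezoidal integration of the bias-corrected rotation velocity.
3. :func:`segment_strides` — stride boundaries at successive maxima of the
   left-hind retraction excursion (the zero point).
4. :func:`select_window` — the longest steady run of strides (coefficient of
   variation of stride duration below threshold), at least five strides.
5. :func:`representative_stride` — the stride minimizing the summed squared
   difference against all other strides in the window.
6. :func:`limb_phasing` (circular cross-correlation of lateromedial rotation
   velocity), :func:`temporal_variables`, :func:`spatial_variables`,
   :func:`symmetry_index` — the 19 analysed variables.

:func:`extract_record` composes the stages into one
:class:`~gaitrel.containers.GaitVariableRecord`.
"""

from __future__ import annotations

import numpy as np
from scipy.integrate import cumulative_trapezoid
from scipy.signal import detrend as _linear_detrend
from scipy.signal import find_peaks

from .containers import (
    GaitVariableRecord,
    IMUSession,
    OrientationSeries,
    PLACEMENT_LIMB,
    SensorStream,
    StrideSeries,
)
from .errors import (
    CalibrationError,
    EventDetectionError,
    ParameterError,
    PhaseError,
    SegmentationError,
    SelectionError,
)

#: Default resampling grid per stride cycle (1% resolution).
N_GRID = 100


# ---------------------------------------------------------------------------
# calibration and orientation
# ---------------------------------------------------------------------------

def calibrate_orientation(stream: SensorStream, standstill_window: tuple):
    """Initial tilt (sagittal, coronal; degrees) and gyro bias from standstill.

    The mean accelerometer vector over the window is taken as the gravity
    direction: sagittal tilt about the lateromedial x axis moves gravity into
    the y component, coronal tilt about y moves it into x.

    Returns ``((sagittal_deg, coronal_deg), bias)`` where ``bias`` is the
    mean 3-axis gyro vector (deg/s) over the window.
    """
    lo, hi = standstill_window
    if (hi - lo) < stream.sample_rate:  # need at least one second
        raise CalibrationError("standstill window shorter than 1 s")
    acc = stream.accel[lo:hi].mean(axis=0)
    norm = np.linalg.norm(acc)
    if norm < 0.5:  # gravity should be near 1 g
        raise CalibrationError(f"degenerate gravity vector (|a| = {norm:.3f} g)")
    ax, ay, az = acc
    sagittal = np.degrees(np.arctan2(-ay, np.hypot(ax, az)))
    coronal = np.degrees(np.arctan2(ax, -az))
    bias = stream.gyro[lo:hi].mean(axis=0)
    return (float(sagittal), float(coronal)), bias


def integrate_orientation(
    stream: SensorStream, tilt=(0.0, 0.0), bias=None
) -> OrientationSeries:
    """Integrate rotation velocity into sagittal/coronal angles (degrees).

    ``angle(t) = tilt + cumulative trapezoidal integral of (gyro - bias)``
    about the respective axis.  Per-stride detrending is applied later, once
    stride boundaries are known (see :func:`detrend_per_stride`).
    """
    if bias is None:
        bias = np.zeros(3)
    bias = np.asarray(bias, dtype=float)
    dt = 1.0 / stream.sample_rate
    sag = tilt[0] + cumulative_trapezoid(stream.gyro[:, 0] - bias[0], dx=dt, initial=0.0)
    cor = tilt[1] + cumulative_trapezoid(stream.gyro[:, 1] - bias[1], dx=dt, initial=0.0)
    return OrientationSeries(sag, cor, stream.sample_rate)


def detrend_per_stride(angle: np.ndarray, boundaries: np.ndarray) -> np.ndarray:
    """Remove per-stride linear drift by matching stride-boundary values.

    Within each stride the line connecting the angle at the two boundaries
    (which may be fractional sample positions) is subtracted, keeping the
    starting value.  This exactly cancels a constant gyro-bias ramp while
    leaving a periodic signal untouched.
    """
    angle = np.asarray(angle, dtype=float)
    boundaries = np.asarray(boundaries, dtype=float)
    out = angle.copy()
    idx = np.arange(len(angle))
    vals = np.interp(boundaries, idx, angle)
    for (b0, b1), (v0, v1) in zip(
        zip(boundaries[:-1], boundaries[1:]), zip(vals[:-1], vals[1:])
    ):
        s0, s1 = int(np.ceil(b0)), int(np.ceil(b1))
        out[s0:s1] -= (v1 - v0) * (idx[s0:s1] - b0) / (b1 - b0)
    return out


# ---------------------------------------------------------------------------
# stride segmentation
# ---------------------------------------------------------------------------

def _detect_retraction_maxima(angle: np.ndarray) -> np.ndarray:
    """Per-cycle extrema of the sagittal angle in the retraction sense.

    Retraction is the positive sagittal direction, so the events are maxima
    of the (linearly detrended) angle series.  A two-pass peak search
    enforces a minimum separation of half the median period.
    """
    a = _linear_detrend(np.asarray(angle, dtype=float))
    span = a.max() - a.min()
    if span < 1e-9:
        raise SegmentationError("flat angle series: no cycle events")
    peaks, _ = find_peaks(a, prominence=0.25 * span)
    if len(peaks) < 2:
        raise SegmentationError(f"only {len(peaks)} cycle events detected")
    min_sep = max(1, int(0.5 * np.median(np.diff(peaks))))
    peaks, _ = find_peaks(a, prominence=0.25 * span, distance=min_sep)
    if len(peaks) < 2:
        raise SegmentationError("fewer than 2 cycle events after separation filter")
    return peaks


def _refine_extrema(angle: np.ndarray, peaks: np.ndarray) -> np.ndarray:
    """Sub-sample extremum locations by parabolic interpolation around each peak."""
    refined = peaks.astype(float)
    for i, m in enumerate(peaks):
        if 0 < m < len(angle) - 1:
            y0, y1, y2 = angle[m - 1], angle[m], angle[m + 1]
            denom = y0 - 2 * y1 + y2
            if abs(denom) > 1e-12:
                delta = 0.5 * (y0 - y2) / denom
                if abs(delta) <= 1:
                    refined[i] = m + delta
    return refined


def resample_cycles(signal: np.ndarray, boundaries: np.ndarray, n_grid: int = N_GRID) -> np.ndarray:
    """Resample each half-open stride ``[b_i, b_{i+1})`` to ``n_grid`` points."""
    signal = np.asarray(signal, dtype=float)
    sample_idx = np.arange(len(signal))
    boundaries = np.asarray(boundaries, dtype=float)
    out = np.empty((len(boundaries) - 1, n_grid))
    grid = np.arange(n_grid) / n_grid
    for i, (b0, b1) in enumerate(zip(boundaries[:-1], boundaries[1:])):
        out[i] = np.interp(b0 + (b1 - b0) * grid, sample_idx, signal)
    return out


def segment_strides(stream: SensorStream, n_grid: int = N_GRID) -> StrideSeries:
    """Segment a sensor stream into strides at retraction zero-point events.

    The lateromedial rotation velocity is integrated to a sagittal angle and
    boundaries are placed at successive per-cycle retraction extrema.
    """
    orient = integrate_orientation(stream)
    boundaries = _detect_retraction_maxima(orient.sagittal_angle)
    durations = np.diff(boundaries) / stream.sample_rate
    angle = detrend_per_stride(orient.sagittal_angle, boundaries)
    cycles = {
        "gyro_x": resample_cycles(stream.gyro[:, 0], boundaries, n_grid),
        "sagittal_angle": resample_cycles(angle, boundaries, n_grid),
    }
    return StrideSeries(boundaries, durations, cycles, stream.sample_rate)


# ---------------------------------------------------------------------------
# window selection and representative stride
# ---------------------------------------------------------------------------

def select_window(
    series,
    min_strides: int = 5,
    cv_threshold: float = 0.05,
    manual: tuple | None = None,
) -> tuple:
    """Select the steady-state analysis window (half-open stride index range).

    Automatic mode returns the longest contiguous run of strides whose
    stride-duration coefficient of variation is at most ``cv_threshold``
    (earliest run on ties); ramp strides are excluded because they violate
    the CV bound.  Raises :class:`SelectionError` if the best run holds fewer
    than ``min_strides`` strides (the minimum-five-strides rule).  Manual mode
    validates an explicit range against the same rules.
    """
    durations = series.durations if isinstance(series, StrideSeries) else np.asarray(series, float)
    s = len(durations)
    if s == 0:
        raise SelectionError("empty stride series")

    csum = np.concatenate([[0.0], np.cumsum(durations)])
    csum2 = np.concatenate([[0.0], np.cumsum(durations**2)])

    def cv(i, j):
        k = j - i
        m = (csum[j] - csum[i]) / k
        var = max((csum2[j] - csum2[i]) / k - m * m, 0.0)
        return np.sqrt(var) / m if m > 0 else np.inf

    if manual is not None:
        i, j = manual
        if not (0 <= i < j <= s):
            raise SelectionError(f"manual window {manual} out of range for {s} strides")
        if j - i < min_strides:
            raise SelectionError(f"manual window holds {j - i} < {min_strides} strides")
        if cv(i, j) > cv_threshold:
            raise SelectionError("manual window exceeds the stride-duration CV threshold")
        return (i, j)

    best = (0, 0)
    for i in range(s):
        for j in range(i + max(best[1] - best[0], 1) + 1, s + 1):
            if cv(i, j) <= cv_threshold and j - i > best[1] - best[0]:
                best = (i, j)
    if best[1] - best[0] == 0:
        best = (0, 1)  # a single stride always has zero CV
    # exclude residual ramp strides at the window edges: trim strides whose
    # duration deviates from the window median by more than 4%
    lo, hi = best
    med = np.median(durations[lo:hi])
    while hi - lo > min_strides and abs(durations[lo] - med) > 0.04 * med:
        lo += 1
    while hi - lo > min_strides and abs(durations[hi - 1] - med) > 0.04 * med:
        hi -= 1
    best = (lo, hi)
    if best[1] - best[0] < min_strides:
        raise SelectionError(
            f"no steady run of >= {min_strides} strides (best: {best[1] - best[0]})"
        )
    return best


def representative_stride(cycles, window: tuple | None = None) -> int:
    """Index of the stride most representative of the window.

    ``cycles`` is one ``(n_strides, n_grid)`` array or a sequence/dict of such
    arrays (one per channel or sensor, pooled by summing).  Returns the
    absolute stride index minimizing ``sum_j sum_grid (cycle_i - cycle_j)^2``;
    ties resolve to the lowest index.
    """
    if isinstance(cycles, dict):
        channels = list(cycles.values())
    elif isinstance(cycles, np.ndarray):
        channels = [cycles]
    else:
        channels = list(cycles)
    if not channels:
        raise ParameterError("no cycle channels given")
    s = channels[0].shape[0]
    lo, hi = (0, s) if window is None else window
    if hi - lo < 2:
        raise ParameterError("representative stride needs a window of >= 2 strides")
    ssd = np.zeros(hi - lo)
    for x in channels:
        xw = np.asarray(x, dtype=float)[lo:hi]
        gram = xw @ xw.T
        sq = np.diag(gram)
        ssd += (sq[:, None] + sq[None, :] - 2.0 * gram).sum(axis=1)
    return lo + int(np.argmin(ssd))


# ---------------------------------------------------------------------------
# per-variable operations
# ---------------------------------------------------------------------------

def limb_phasing(cycles: dict, reference: str = "LH") -> dict:
    """Phase lag of each limb's cycle vs the reference, in percent of stride.

    Circular cross-correlation of the lateromedial rotation-velocity cycles on
    the common grid; the phase is the argmax lag scaled to percent, in
    [0, 100).  The reference limb maps to exactly 0.
    """
    if reference not in cycles:
        raise ParameterError(f"reference limb {reference!r} missing from cycles")
    ref = np.asarray(cycles[reference], dtype=float)
    n = len(ref)
    ref = ref - ref.mean()
    if np.allclose(ref, 0):
        raise PhaseError("zero-variance reference cycle")
    fref = np.fft.rfft(ref)
    phases = {}
    for limb, cyc in cycles.items():
        if limb == reference:
            phases[limb] = 0.0
            continue
        x = np.asarray(cyc, dtype=float)
        if len(x) != n:
            raise ParameterError("all cycles must share the grid length")
        x = x - x.mean()
        if np.allclose(x, 0):
            raise PhaseError(f"zero-variance cycle for limb {limb!r}")
        corr = np.fft.irfft(np.conj(fref) * np.fft.rfft(x), n)
        m = int(np.argmax(corr))
        # sub-grid lag via parabolic interpolation of the correlation peak
        y0, y1, y2 = corr[(m - 1) % n], corr[m], corr[(m + 1) % n]
        denom = y0 - 2 * y1 + y2
        delta = 0.5 * (y0 - y2) / denom if abs(denom) > 1e-12 else 0.0
        if abs(delta) > 1:
            delta = 0.0
        phases[limb] = float(((m + delta) % n) * 100.0 / n)
    return phases


def classify_gait(phases: dict) -> str:
    """Classify limb phasing (percent of stride, LH reference) as walk/trot/unknown.

    Trot: diagonal pairs move together — RF near the LH zero point, LF near
    RH, and RH half a stride from LH.  Walk: the four events are near-evenly
    spaced (circular gaps 25% +- 10%).  Anything else is unknown.
    """
    try:
        lf, rf, rh = (float(phases[k]) for k in ("LF", "RF", "RH"))
    except KeyError as exc:
        raise ParameterError(f"missing limb phase: {exc}") from exc

    def circ(a, b=0.0):
        d = abs((a - b) % 100.0)
        return min(d, 100.0 - d)

    if circ(rh, 50.0) <= 10.0 and circ(rf, 0.0) <= 20.0 and circ(lf, rh) <= 20.0:
        return "trot"
    events = np.sort(np.mod([0.0, lf, rf, rh], 100.0))
    gaps = np.diff(np.concatenate([events, [events[0] + 100.0]]))
    if np.all(np.abs(gaps - 25.0) <= 10.0):
        return "walk"
    return "unknown"


def _event_from_velocity(vel_cycle: np.ndarray, kind: str) -> float | None:
    """Sub-grid event timing from the rotation-velocity zero crossing.

    The angle extremum coincides with a velocity zero crossing: downward
    (+ to -) at the retraction maximum, upward at the protraction minimum.
    The crossing adjacent to the largest velocity excursion is taken (spurious
    noise crossings in flat regions have small neighbours) and linearly
    interpolated.  Returns percent of stride, or None when no crossing exists.
    """
    v = np.asarray(vel_cycle, dtype=float)
    n = len(v)
    nxt = np.roll(v, -1)
    if kind == "retraction":
        cand = np.nonzero((v > 0) & (nxt <= 0))[0]
    else:
        cand = np.nonzero((v < 0) & (nxt >= 0))[0]
    if len(cand) == 0:
        return None
    w = max(2, n // 8)
    scores = []
    for i in cand:
        ring = np.arange(i - w, i + w + 1) % n
        scores.append(np.max(np.abs(v[ring])))
    i = int(cand[int(np.argmax(scores))])
    denom = v[i] - nxt[i]
    frac = v[i] / denom if abs(denom) > 1e-12 else 0.0
    event = (i + frac) % n
    # refine by extrapolating the shallow (near-linear) side of the crossing
    # to its zero: interpolation through the steep swing spike biases the
    # naive crossing, the shallow approach does not
    if n >= 24:
        rel_left = np.arange(-8, -2)
        rel_right = np.arange(3, 9)
        v_left = v[(i + rel_left) % n]
        v_right = v[(i + rel_right) % n]
        rel, vals = (
            (rel_left, v_left)
            if np.abs(v_left).mean() <= np.abs(v_right).mean()
            else (rel_right, v_right)
        )
        slope, icept = np.polyfit(rel, vals, 1)
        if abs(slope) > 1e-12:
            root = -icept / slope
            if abs(root) <= 3.0:
                event = (i + root) % n
    return float(event * 100.0 / n)


def temporal_variables(angle_cycle: np.ndarray, durations=None, velocity_cycle=None) -> dict:
    """Pro/retraction event percents (and stride duration) from an angle cycle.

    Retraction is the positive-angle extremum (the zero-point direction),
    protraction the negative one; each event percent is the extremum grid
    index scaled to percent of stride.  When ``velocity_cycle`` is supplied
    the events are refined to the corresponding velocity zero crossings,
    which localizes flat angle extrema far better than the raw argmax.
    ``durations`` (seconds, over the selected window) yields the mean stride
    duration.
    """
    cyc = np.asarray(angle_cycle, dtype=float)
    if cyc.max() - cyc.min() < 1e-9:
        raise EventDetectionError("flat cycle: no pro/retraction events")
    n = len(cyc)
    out = {
        "retraction": float(np.argmax(cyc) * 100.0 / n),
        "protraction": float(np.argmin(cyc) * 100.0 / n),
    }
    if velocity_cycle is not None:
        for kind in ("retraction", "protraction"):
            refined = _event_from_velocity(velocity_cycle, kind)
            if refined is not None:
                out[kind] = refined
    if durations is not None:
        out["stride_duration"] = float(np.mean(durations))
    return out


def recode_protraction(p: float) -> float:
    """Fold late-cycle protraction percents to distance from cycle end.

    A maximal-protraction timing of 98% of the stride is equivalent to 2%
    (96% to 4%, 94% to 6%): values above 50 map to ``100 - p``.
    """
    if not (0 <= p < 100):
        raise ParameterError(f"percent {p} outside [0, 100)")
    return float(100.0 - p) if p > 50.0 else float(p)


def spatial_variables(
    angle: np.ndarray,
    boundaries: np.ndarray,
    window: tuple,
    detrend: bool = True,
) -> float:
    """Mean per-stride range of motion (max - min, degrees) over the window."""
    lo, hi = window
    if hi - lo < 1:
        raise ParameterError("empty window")
    a = detrend_per_stride(np.asarray(angle, float), boundaries) if detrend else np.asarray(angle, float)
    b = np.asarray(boundaries, dtype=float)
    roms = []
    for i in range(lo, hi):
        s0, s1 = int(np.ceil(b[i])), int(np.ceil(b[i + 1]))
        seg = a[s0:s1]
        hi_val = _refine_extremum_value(seg, int(np.argmax(seg)), "max")
        lo_val = _refine_extremum_value(seg, int(np.argmin(seg)), "min")
        roms.append(hi_val - lo_val)
    return float(np.mean(roms))


def _refine_extremum_value(seg: np.ndarray, m: int, sense: str) -> float:
    """Sub-sample extremum value by a parabola fitted on the shallow side.

    Limb-cycle apexes are kinked (steep on one side, flat on the other); a
    parabola through both sides overshoots, so the fit uses the apex sample
    plus the two neighbours on the flatter side, which is locally quadratic.
    """
    n = len(seg)
    if not (0 < m < n - 1):
        return float(seg[m])
    drop_left = abs(seg[m] - seg[m - 1])
    drop_right = abs(seg[m] - seg[m + 1])
    step = 1 if drop_right <= drop_left else -1
    if not (0 <= m + 2 * step < n):
        return float(seg[m])
    x = np.array([0.0, step, 2.0 * step])
    y = seg[[m, m + step, m + 2 * step]].astype(float)
    c2, c1, c0 = np.polyfit(x, y, 2)
    if abs(c2) < 1e-12:
        return float(seg[m])
    vx = -c1 / (2 * c2)
    # only trust a vertex between the apex sample and its first neighbour
    if (sense == "max" and c2 < 0 or sense == "min" and c2 > 0) and 0 <= vx * step <= 1:
        return float(c0 + c1 * vx + c2 * vx * vx)
    return float(seg[m])


def symmetry_index(left: float, right: float) -> float:
    """Left/right asymmetry: |left - right| / mean(left, right) * 100."""
    mean = 0.5 * (left + right)
    if mean <= 0:
        raise ParameterError("symmetry index undefined for non-positive mean")
    return float(abs(left - right) / mean * 100.0)


# ---------------------------------------------------------------------------
# end-to-end record extraction
# ---------------------------------------------------------------------------

#: Sensors feeding the temporal event variables (variable suffix -> placement).
_EVENT_SENSORS = {
    "mt_L": "LH_mt",
    "mt_R": "RH_mt",
    "mc_L": "LF_mc",
    "mc_R": "RF_mc",
}

#: Limb-phasing sensors (limb -> placement of its cannon sensor).
_PHASING_SENSORS = {"LH": "LH_mt", "RH": "RH_mt", "LF": "LF_mc", "RF": "RF_mc"}


def extract_record(
    session: IMUSession,
    evaluator_id: str = "E1",
    repetition: int = 1,
    evaluator_type: str = "",
    min_strides: int = 5,
    cv_threshold: float = 0.05,
    window="auto",
    rng: np.random.Generator | None = None,
    n_grid: int = N_GRID,
) -> GaitVariableRecord:
    """Run the full extraction pipeline on one session.

    ``window`` is ``"auto"`` (steady-run selection, optionally jittered within
    the steady region by ``rng`` to emulate an evaluator's manual choice) or
    an explicit half-open stride range.  Raises :class:`SelectionError` when
    no steady trot window of at least ``min_strides`` strides exists.
    """
    fs = session.sample_rate

    # calibrate + integrate every sensor
    orientations = {}
    for placement, stream in session.streams.items():
        tilt, bias = calibrate_orientation(stream, session.standstill_window)
        orientations[placement] = integrate_orientation(stream, tilt, bias)

    # segment on the left-hind metatarsal sensor (the zero-point definition)
    lh_angle = orientations["LH_mt"].sagittal_angle
    boundaries = _detect_retraction_maxima(lh_angle)
    # sub-sample zero-point refinement: durations and cycle grids use the
    # parabolic-interpolated event times, sample-level ops the integer indices
    refined = _refine_extrema(_linear_detrend(lh_angle), boundaries)
    durations = np.diff(refined) / fs

    if window == "auto":
        lo, hi = select_window(durations, min_strides=min_strides, cv_threshold=cv_threshold)
        if rng is not None:  # evaluator-specific sub-window within the steady run
            length = int(rng.integers(min_strides, hi - lo + 1))
            start = int(rng.integers(lo, hi - length + 1))
            lo, hi = start, start + length
    else:
        lo, hi = select_window(durations, min_strides=min_strides, cv_threshold=cv_threshold, manual=tuple(window))

    # resampled cycles per sensor over all strides (refined boundaries shared)
    vel_cycles = {
        p: resample_cycles(session.streams[p].gyro[:, 0], refined, n_grid)
        for p in session.streams
    }
    rep = representative_stride(list(vel_cycles.values()), (lo, hi))

    phases = limb_phasing({limb: vel_cycles[p][rep] for limb, p in _PHASING_SENSORS.items()})
    gait = classify_gait(phases)
    if gait != "trot":
        raise SelectionError(f"selected window is not trot (classified {gait!r})")

    values = {
        "stride_duration": float(np.mean(durations[lo:hi])),
        "limb_phasing_LF": phases["LF"],
        "limb_phasing_RF": phases["RF"],
        "limb_phasing_RH": phases["RH"],
    }

    # temporal events, measured within each limb's own cycle.  The measured
    # LH retraction crossing re-references all events to the true zero point,
    # cancelling any sub-sample bias of the detected stride boundaries.
    lh_vel_mean = vel_cycles["LH_mt"][lo:hi].mean(axis=0)
    lh_zero = _event_from_velocity(lh_vel_mean, "retraction")
    zero_offset = 0.0 if lh_zero is None else ((lh_zero + 50.0) % 100.0) - 50.0
    for suffix, placement in _EVENT_SENSORS.items():
        angle = detrend_per_stride(orientations[placement].sagittal_angle, refined)
        cyc = resample_cycles(angle, refined, n_grid)[rep]
        vel_mean = vel_cycles[placement][lo:hi].mean(axis=0)
        events = temporal_variables(cyc, velocity_cycle=vel_mean)
        limb = PLACEMENT_LIMB[placement]
        shift = phases[limb] + zero_offset
        prot = (events["protraction"] - shift) % 100.0
        values[f"protraction_{suffix}"] = recode_protraction(prot)
        if suffix.startswith("mt"):
            values[f"retraction_{suffix}"] = (events["retraction"] - shift) % 100.0

    # spatial ROM per sensor/plane
    rom_map = {
        "rom_sag_hock_L": ("L_tibia", "sagittal_angle"),
        "rom_sag_hock_R": ("R_tibia", "sagittal_angle"),
        "rom_sag_fore_cannon_L": ("LF_mc", "sagittal_angle"),
        "rom_sag_fore_cannon_R": ("RF_mc", "sagittal_angle"),
        "rom_cor_fore_cannon_L": ("LF_mc", "coronal_angle"),
        "rom_cor_fore_cannon_R": ("RF_mc", "coronal_angle"),
        "rom_cor_hind_cannon_L": ("LH_mt", "coronal_angle"),
        "rom_cor_hind_cannon_R": ("RH_mt", "coronal_angle"),
    }
    for name, (placement, plane) in rom_map.items():
        angle = getattr(orientations[placement], plane)
        values[name] = spatial_variables(angle, refined, (lo, hi))

    values["symmetry_hock"] = symmetry_index(values["rom_sag_hock_L"], values["rom_sag_hock_R"])

    return GaitVariableRecord(
        horse_id=session.horse_id,
        surface=session.surface,
        evaluator_id=evaluator_id,
        evaluator_type=evaluator_type,
        repetition=repetition,
        n_strides_evaluated=hi - lo,
        values=values,
    )
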