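"""Synthetic data generation: IMU trot sessions and gait-variable tables.

Two kinds of synthetic data are produced, matching the two stages of the
analysis:

* :func:`simulate_session` builds a six-sensor inertial recording of one horse
  (standstill calibration prefix, walk segments, acceleration/deceleration
  ramps and a steady trot segment) from a :class:`HorseKinematicProfile` whose
  fields are the ground truth that the extraction stage must recover.

* :func:`simulate_variable_table` draws a balanced horse x evaluator x
  repetition gait-variable table directly under the additive random-effects
  model ``Y_ijk = mu + a_i + b_j + e_ijk`` (evaluator effect ``a``, horse
  effect ``b``, repetition error ``e``), the model the reliability statistics
  assume.

Population defaults are anchored to treadmill trot kinematics of sound
warmblood horses: stride duration 0.731 s and limb phases (relative to the
left-hind zero point) of 63.097% (LF), 13.654% (RF) and 49.460% (RH).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._waveform import cycle_waveform
from .containers import (
    LIMBS,
    PLACEMENT_LIMB,
    PLACEMENT_SEGMENT,
    PLACEMENTS,
    IMUSession,
    SensorStream,
    VARIABLE_COLUMNS,
)
from .errors import ParameterError

#: Four-beat lateral-sequence walk: footfall-cycle offsets per limb (% of stride).
WALK_PHASES = {"LH": 0.0, "RF": 25.0, "RH": 50.0, "LF": 75.0}

#: Walk stride duration used for walk segments and ramp interpolation (s).
WALK_STRIDE_DURATION = 1.1

# Within-cycle timing template shared by all limb segments: maximal retraction
# defines the limb's cycle zero; maximal protraction sits 94.778% into the
# cycle (so the recoded protraction percent is 5.222).
_DEFAULT_PROTRACTION_OFFSET = 94.778

_DEFAULT_SAGITTAL_ROM = {
    "hock_L": 42.093,
    "hock_R": 37.160,
    "fore_cannon_L": 85.107,
    "fore_cannon_R": 86.177,
    "hind_cannon_L": 60.0,
    "hind_cannon_R": 60.0,
}

_DEFAULT_CORONAL_ROM = {
    "fore_cannon_L": 12.920,
    "fore_cannon_R": 20.567,
    "hind_cannon_L": 13.816,
    "hind_cannon_R": 14.317,
    "hock_L": 5.0,
    "hock_R": 5.0,
}

#: Default between-horse standard deviations for profile draws.
DEFAULT_BETWEEN_HORSE_SD = {
    "stride_duration": 0.022,
    "limb_phasing_LF": 0.733,
    "limb_phasing_RF": 1.073,
    "limb_phasing_RH": 0.835,
    "protraction_offset": 2.1,
    "speed": 0.33,
    "sagittal_rom.hock_L": 3.278,
    "sagittal_rom.hock_R": 3.169,
    "sagittal_rom.fore_cannon_L": 1.582,
    "sagittal_rom.fore_cannon_R": 4.055,
    "sagittal_rom.hind_cannon_L": 3.0,
    "sagittal_rom.hind_cannon_R": 3.0,
    "coronal_rom.fore_cannon_L": 5.954,
    "coronal_rom.fore_cannon_R": 8.100,
    "coronal_rom.hind_cannon_L": 3.119,
    "coronal_rom.hind_cannon_R": 3.682,
    "coronal_rom.hock_L": 1.0,
    "coronal_rom.hock_R": 1.0,
}


@dataclass
class HorseKinematicProfile:
    """Ground-truth trot kinematics of one horse.

    ``limb_phases`` holds the cycle offset of LF/RF/RH relative to the
    left-hind zero point (maximal LH retraction); LH is implicitly 0.
    ``protraction_events`` / ``retraction_events`` are within-own-cycle
    positions (percent of stride) of the maximal pro/retraction of the segment
    carried by each limb.  ROM maps are keyed by anatomical segment.
    """

    horse_id: str = "H01"
    stride_duration: float = 0.731
    limb_phases: dict = field(
        default_factory=lambda: {"LF": 63.097, "RF": 13.654, "RH": 49.460}
    )
    protraction_events: dict = field(
        default_factory=lambda: {limb: _DEFAULT_PROTRACTION_OFFSET for limb in LIMBS}
    )
    retraction_events: dict = field(default_factory=lambda: {limb: 0.0 for limb in LIMBS})
    sagittal_rom: dict = field(default_factory=lambda: dict(_DEFAULT_SAGITTAL_ROM))
    coronal_rom: dict = field(default_factory=lambda: dict(_DEFAULT_CORONAL_ROM))
    speed: float = 3.3

    def __post_init__(self) -> None:
        if self.stride_duration <= 0:
            raise ParameterError("stride_duration must be > 0")
        for m in (self.limb_phases, self.protraction_events, self.retraction_events):
            for limb, val in m.items():
                if not (0 <= val < 100):
                    raise ParameterError(f"percent for {limb} outside [0, 100): {val}")
        for m in (self.sagittal_rom, self.coronal_rom):
            for seg, val in m.items():
                if val <= 0:
                    raise ParameterError(f"ROM for {seg} must be > 0")


@dataclass
class SessionProtocol:
    """Recording-session layout and sensor-noise settings.

    The session is: ``standstill_duration`` s of standstill (gravity
    calibration), a leading walk segment, ``ramp_strides`` acceleration
    strides whose duration interpolates linearly from walk to trot, the steady
    trot segment of ``n_trot_strides`` strides, a deceleration ramp and a
    trailing walk segment.
    """

    surface: str = "treadmill"
    n_trot_strides: int = 25
    walk_segments: tuple = (2.0, 2.0)
    ramp_strides: int = 3
    sample_rate: float = 102.4
    noise_sd_gyro: float = 2.0
    noise_sd_accel: float = 0.02
    gyro_bias: float = 0.0
    standstill_duration: float = 10.0
    seed: int = 0
    waveform: str = "asymmetric"  # or "sinusoid"
    walk_stride_duration: float = WALK_STRIDE_DURATION

    def __post_init__(self) -> None:
        if self.n_trot_strides < 1:
            raise ParameterError("n_trot_strides must be >= 1")
        if self.sample_rate <= 0:
            raise ParameterError("sample_rate must be > 0")
        if self.standstill_duration < 0:
            raise ParameterError("standstill_duration must be >= 0")
        if self.noise_sd_gyro < 0 or self.noise_sd_accel < 0:
            raise ParameterError("noise standard deviations must be >= 0")
        if self.ramp_strides < 0:
            raise ParameterError("ramp_strides must be >= 0")


def simulate_horse_profile(
    population_means: HorseKinematicProfile | None = None,
    between_horse_sd: dict | None = None,
    seed: int = 0,
    horse_id: str | None = None,
) -> HorseKinematicProfile:
    """Draw one horse's profile as population mean + Normal(0, sd) per variable.

    The protraction-offset perturbation is shared across limbs so that all
    limb segments keep a common within-cycle timing template (which makes
    cross-correlation limb phasing exact on noise-free data).
    """
    pop = population_means if population_means is not None else HorseKinematicProfile()
    sds = dict(DEFAULT_BETWEEN_HORSE_SD)
    if between_horse_sd is not None:
        sds.update(between_horse_sd)
    for key, sd in sds.items():
        if sd < 0:
            raise ParameterError(f"negative sd for {key}")
    rng = np.random.default_rng(np.random.SeedSequence(seed))

    stride = max(pop.stride_duration + rng.normal(0, sds.get("stride_duration", 0.0)), 0.05)
    phases = {
        limb: float(np.mod(pop.limb_phases[limb] + rng.normal(0, sds.get(f"limb_phasing_{limb}", 0.0)), 100.0))
        for limb in ("LF", "RF", "RH")
    }
    dq = rng.normal(0, sds.get("protraction_offset", 0.0))
    # keep both waveform arcs at least 5% of the cycle (>= 3.5 samples at
    # 102.4 Hz) so the drawn profile stays resolvable at the sensor rate
    retr = dict(pop.retraction_events)
    prot = {}
    for limb in LIMBS:
        arc = np.clip(np.mod(pop.protraction_events[limb] - retr[limb] + dq, 100.0), 5.0, 95.0)
        prot[limb] = float(np.mod(retr[limb] + arc, 100.0))
    sag = {
        seg: max(float(pop.sagittal_rom[seg] + rng.normal(0, sds.get(f"sagittal_rom.{seg}", 0.0))), 1e-3)
        for seg in sorted(pop.sagittal_rom)
    }
    cor = {
        seg: max(float(pop.coronal_rom[seg] + rng.normal(0, sds.get(f"coronal_rom.{seg}", 0.0))), 1e-3)
        for seg in sorted(pop.coronal_rom)
    }
    speed = max(pop.speed + rng.normal(0, sds.get("speed", 0.0)), 0.1)
    return HorseKinematicProfile(
        horse_id=horse_id if horse_id is not None else pop.horse_id,
        stride_duration=float(stride),
        limb_phases=phases,
        protraction_events=prot,
        retraction_events=retr,
        sagittal_rom=sag,
        coronal_rom=cor,
        speed=float(speed),
    )


def _stride_plan(profile: HorseKinematicProfile, protocol: SessionProtocol):
    """Sequence of (gait, duration_s) strides making up the moving part."""
    walk_d = protocol.walk_stride_duration
    trot_d = profile.stride_duration
    segs = tuple(protocol.walk_segments)
    lead = segs[0] if len(segs) >= 1 else 0.0
    trail = segs[1] if len(segs) >= 2 else 0.0
    plan: list[tuple[str, float]] = []

    def walk_block(duration):
        n = int(np.ceil(duration / walk_d)) if duration > 0 else 0
        plan.extend(("walk", walk_d) for _ in range(n))

    walk_block(lead)
    r = protocol.ramp_strides
    for k in range(1, r + 1):  # accelerate: walk -> trot
        plan.append(("trot", walk_d + (trot_d - walk_d) * k / (r + 1)))
    plan.extend(("trot", trot_d) for _ in range(protocol.n_trot_strides))
    for k in range(r, 0, -1):  # decelerate: trot -> walk
        plan.append(("trot", walk_d + (trot_d - walk_d) * k / (r + 1)))
    walk_block(trail)
    return plan


def _gravity_accel(sagittal_deg: np.ndarray, coronal_deg: np.ndarray) -> np.ndarray:
    """Gravity in the sensor frame for tilt about x (sagittal) then y (coronal)."""
    th = np.deg2rad(sagittal_deg)
    ps = np.deg2rad(coronal_deg)
    return np.stack(
        [np.sin(ps) * np.cos(th), -np.sin(th), -np.cos(ps) * np.cos(th)], axis=1
    )


def simulate_session(profile: HorseKinematicProfile, protocol: SessionProtocol) -> IMUSession:
    """Generate a six-sensor IMU session for one horse.

    Each sensor's lateromedial gyro channel (x) is the analytic time
    derivative of a periodic sagittal-angle waveform whose extrema sit at the
    programmed pro/retraction cycle positions and whose peak-to-peak range is
    the programmed sagittal ROM; the coronal channel (y) is analogous with a
    sinusoidal waveform.  The accelerometer reports gravity rotated by the
    instantaneous segment tilt.  Gaussian sensor noise and an optional
    constant gyro bias are added per sample.
    """
    fs = protocol.sample_rate
    plan = _stride_plan(profile, protocol)
    durs = np.array([d for _, d in plan])
    gaits = np.array([g for g, _ in plan])
    starts = np.concatenate([[0.0], np.cumsum(durs)])
    total = protocol.standstill_duration + starts[-1]
    n = int(round(total * fs))
    t = np.arange(n) / fs
    n_still = int(round(protocol.standstill_duration * fs))
    moving = slice(n_still, n)
    tm = t[moving] - protocol.standstill_duration

    idx = np.clip(np.searchsorted(starts, tm, side="right") - 1, 0, len(durs) - 1)
    frac = (tm - starts[idx]) / durs[idx]
    # cycle clock starts mid-cycle so that boundary events are interior extrema
    c = np.mod(50.0 + 100.0 * (idx + frac), 100.0)
    cdot = 100.0 / durs[idx]  # percent of cycle per second
    is_walk = gaits[idx] == "walk"

    ss = np.random.SeedSequence(protocol.seed)
    rngs = {p: np.random.default_rng(child) for p, child in zip(PLACEMENTS, ss.spawn(len(PLACEMENTS)))}

    streams = {}
    for placement in PLACEMENTS:
        limb = PLACEMENT_LIMB[placement]
        seg = PLACEMENT_SEGMENT[placement]
        phase = 0.0 if limb == "LH" else profile.limb_phases[limb]
        rom_sag = profile.sagittal_rom[seg]
        rom_cor = profile.coronal_rom.get(seg, 0.0)

        sag = np.zeros(len(tm))
        sag_vel = np.zeros(len(tm))
        cor = np.zeros(len(tm))
        cor_vel = np.zeros(len(tm))

        # retraction is the positive sagittal direction: the waveform maximum
        # sits at the limb's retraction event, the minimum at protraction
        trot_max = np.mod(phase + profile.retraction_events[limb], 100.0)
        trot_min = np.mod(phase + profile.protraction_events[limb], 100.0)
        w, dw = cycle_waveform(c[~is_walk], trot_min, trot_max, kind=protocol.waveform)
        sag[~is_walk] = rom_sag * w
        sag_vel[~is_walk] = rom_sag * dw * cdot[~is_walk]
        walk_min = WALK_PHASES[limb] + 50.0
        w, dw = cycle_waveform(c[is_walk], walk_min, walk_min + 50.0, kind="sinusoid")
        sag[is_walk] = rom_sag * w
        sag_vel[is_walk] = rom_sag * dw * cdot[is_walk]

        if rom_cor > 0:
            cor_min = np.mod(trot_min + 25.0, 100.0)
            w, dw = cycle_waveform(c, cor_min, cor_min + 50.0, kind="sinusoid")
            cor = rom_cor * w
            cor_vel = rom_cor * dw * cdot

        sag_full = np.zeros(n)
        cor_full = np.zeros(n)
        sag_full[moving] = sag
        cor_full[moving] = cor
        gyro = np.zeros((n, 3))
        gyro[moving, 0] = sag_vel
        gyro[moving, 1] = cor_vel
        accel = _gravity_accel(sag_full, cor_full)

        rng = rngs[placement]
        gyro = gyro + protocol.gyro_bias
        if protocol.noise_sd_gyro > 0:
            gyro = gyro + rng.normal(0, protocol.noise_sd_gyro, (n, 3))
        if protocol.noise_sd_accel > 0:
            accel = accel + rng.normal(0, protocol.noise_sd_accel, (n, 3))
        streams[placement] = SensorStream(placement, fs, gyro, accel)

    return IMUSession(
        horse_id=profile.horse_id,
        surface=protocol.surface,
        streams=streams,
        standstill_window=(0, n_still),
        truth=profile,
    )


def expected_variables(profile: HorseKinematicProfile) -> dict:
    """The 19 gait-variable values a perfect extraction should report.

    Phases are relative to the LH zero point; temporal pro/retraction events
    are within-own-cycle positions with protraction stored recoded.
    """
    from .extract import recode_protraction, symmetry_index

    retr_lh = profile.retraction_events["LH"]

    def phase(limb):
        return float(np.mod(profile.limb_phases[limb] + profile.retraction_events[limb] - retr_lh, 100.0))

    def own_prot(limb):
        return recode_protraction(
            float(np.mod(profile.protraction_events[limb] - profile.retraction_events[limb], 100.0))
        )

    out = {
        "stride_duration": profile.stride_duration,
        "limb_phasing_LF": phase("LF"),
        "limb_phasing_RF": phase("RF"),
        "limb_phasing_RH": phase("RH"),
        "protraction_mt_L": own_prot("LH"),
        "protraction_mt_R": own_prot("RH"),
        "protraction_mc_L": own_prot("LF"),
        "protraction_mc_R": own_prot("RF"),
        "retraction_mt_L": 0.0,
        "retraction_mt_R": 0.0,
        "rom_sag_hock_L": profile.sagittal_rom["hock_L"],
        "rom_sag_hock_R": profile.sagittal_rom["hock_R"],
        "rom_sag_fore_cannon_L": profile.sagittal_rom["fore_cannon_L"],
        "rom_sag_fore_cannon_R": profile.sagittal_rom["fore_cannon_R"],
        "rom_cor_fore_cannon_L": profile.coronal_rom["fore_cannon_L"],
        "rom_cor_fore_cannon_R": profile.coronal_rom["fore_cannon_R"],
        "rom_cor_hind_cannon_L": profile.coronal_rom["hind_cannon_L"],
        "rom_cor_hind_cannon_R": profile.coronal_rom["hind_cannon_R"],
        "symmetry_hock": symmetry_index(profile.sagittal_rom["hock_L"], profile.sagittal_rom["hock_R"]),
    }
    assert set(out) == set(VARIABLE_COLUMNS)
    return out


@dataclass
class TableSimSpec:
    """Design and variance parameters for direct gait-variable-table simulation.

    Defaults mirror the study design: J = 10 horses, I = 6 evaluators (three
    experienced, three inexperienced), K = 3 repetitions, 180 rows per
    surface.  ``grand_mean`` and the three variance components may be scalars
    (applied to every variable) or dicts keyed by variable name.
    """

    n_horses: int = 10
    n_evaluators: int = 6
    n_repetitions: int = 3
    evaluator_types: dict | None = None
    variables: tuple = ("value",)
    grand_mean: float | dict = 0.0
    sigma2_horse: float | dict = 0.9
    sigma2_evaluator: float | dict = 0.05
    sigma2_repetition: float | dict = 0.05
    type_effect: float | dict = 0.0
    surface: str = "treadmill"
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_horses, self.n_evaluators, self.n_repetitions) < 1:
            raise ParameterError("I, J, K must all be >= 1")
        for name in ("sigma2_horse", "sigma2_evaluator", "sigma2_repetition"):
            val = getattr(self, name)
            vals = val.values() if isinstance(val, dict) else [val]
            if any(v < 0 for v in vals):
                raise ParameterError(f"{name} must be >= 0")

    @property
    def n(self) -> int:
        return self.n_horses * self.n_evaluators * self.n_repetitions

    def evaluator_ids(self):
        return [f"E{i + 1}" for i in range(self.n_evaluators)]

    def types(self):
        if self.evaluator_types is not None:
            return dict(self.evaluator_types)
        half = self.n_evaluators // 2
        ids = self.evaluator_ids()
        return {e: ("experienced" if i < half else "inexperienced") for i, e in enumerate(ids)}


def _per_variable(value, variable):
    return value[variable] if isinstance(value, dict) else value


def simulate_variable_table(spec: TableSimSpec) -> pd.DataFrame:
    """Simulate a balanced table under ``Y_ijk = mu + a_i + b_j + e_ijk``.

    ``a_i ~ N(0, sigma2_evaluator)`` (evaluator), ``b_j ~ N(0, sigma2_horse)``
    (horse), ``e_ijk ~ N(0, sigma2_repetition)``; experienced evaluators get
    ``type_effect`` added.  Deterministic given ``spec.seed``.
    """
    I, J, K = spec.n_evaluators, spec.n_horses, spec.n_repetitions
    rng = np.random.default_rng(np.random.SeedSequence(spec.seed))
    ev_ids = spec.evaluator_ids()
    types = spec.types()
    horse_ids = [f"H{j + 1:02d}" for j in range(J)]
    exp_mask = np.array([types[e] == "experienced" for e in ev_ids], dtype=float)

    data = {}
    for var in spec.variables:
        mu = _per_variable(spec.grand_mean, var)
        s2h = _per_variable(spec.sigma2_horse, var)
        s2e = _per_variable(spec.sigma2_evaluator, var)
        s2r = _per_variable(spec.sigma2_repetition, var)
        shift = _per_variable(spec.type_effect, var)
        a = rng.normal(0, np.sqrt(s2e), I)
        b = rng.normal(0, np.sqrt(s2h), J)
        e = rng.normal(0, np.sqrt(s2r), (I, J, K))
        y = mu + a[:, None, None] + b[None, :, None] + e + (shift * exp_mask)[:, None, None]
        data[var] = y.ravel()

    index = pd.MultiIndex.from_product(
        [ev_ids, horse_ids, range(1, K + 1)], names=["evaluator_id", "horse_id", "repetition"]
    ).to_frame(index=False)
    out = pd.DataFrame(
        {
            "horse_id": index["horse_id"],
            "surface": spec.surface,
            "evaluator_id": index["evaluator_id"],
            "evaluator_type": index["evaluator_id"].map(types),
            "repetition": index["repetition"],
        }
    )
    for var in spec.variables:
        out[var] = data[var]
    return out
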