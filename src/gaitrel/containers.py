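"""Core data containers shared by the simulator, the extraction pipeline and the
reliability statistics.

The package works with six extremity-mounted inertial sensors per horse:
metacarpal sensors on both forelimbs (``LF_mc``, ``RF_mc``), metatarsal sensors
on both hindlimbs (``LH_mt``, ``RH_mt``) and one sensor on each tibia
(``L_tibia``, ``R_tibia``).  Each sensor records a 3-axis gyroscope (deg/s) and
a 3-axis accelerometer (g).  The sensor frame is right-handed with

* ``x`` — lateromedial axis (sagittal-plane rotation happens about x),
* ``y`` — craniocaudal axis (coronal-plane rotation about y),
* ``z`` — proximodistal axis; gravity is ``(0, 0, -1)`` g at zero tilt.

Nineteen gait variables are analysed per (horse, surface, repetition,
evaluator) cell; the lists below fix their canonical column names and order.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ParameterError

#: Valid sensor placements (mc = metacarpus, mt = metatarsus).
PLACEMENTS = ("LF_mc", "RF_mc", "LH_mt", "RH_mt", "L_tibia", "R_tibia")

#: Limb labels; LH is the phase reference (zero point at maximal LH retraction).
LIMBS = ("LH", "RH", "LF", "RF")

#: Sensor placement -> limb whose cycle drives it.
PLACEMENT_LIMB = {
    "LF_mc": "LF",
    "RF_mc": "RF",
    "LH_mt": "LH",
    "RH_mt": "RH",
    "L_tibia": "LH",
    "R_tibia": "RH",
}

#: Sensor placement -> anatomical segment key used for range-of-motion maps.
PLACEMENT_SEGMENT = {
    "LF_mc": "fore_cannon_L",
    "RF_mc": "fore_cannon_R",
    "LH_mt": "hind_cannon_L",
    "RH_mt": "hind_cannon_R",
    "L_tibia": "hock_L",
    "R_tibia": "hock_R",
}

TEMPORAL_VARIABLES = (
    "stride_duration",
    "limb_phasing_LF",
    "limb_phasing_RF",
    "limb_phasing_RH",
    "protraction_mt_L",
    "protraction_mt_R",
    "protraction_mc_L",
    "protraction_mc_R",
    "retraction_mt_L",
    "retraction_mt_R",
)

SPATIAL_VARIABLES = (
    "rom_sag_hock_L",
    "rom_sag_hock_R",
    "rom_sag_fore_cannon_L",
    "rom_sag_fore_cannon_R",
    "rom_cor_fore_cannon_L",
    "rom_cor_fore_cannon_R",
    "rom_cor_hind_cannon_L",
    "rom_cor_hind_cannon_R",
    "symmetry_hock",
)

#: The 19 analysed gait variables, in report order.
VARIABLE_COLUMNS = TEMPORAL_VARIABLES + SPATIAL_VARIABLES

#: Metadata columns of a gait-variable table.
TABLE_META_COLUMNS = ("horse_id", "surface", "evaluator_id", "evaluator_type", "repetition")


@dataclass
class SensorStream:
    """One sensor's synchronous gyro + accelerometer time series.

    Parameters
    ----------
    placement : str
        One of :data:`PLACEMENTS`.
    sample_rate : float
        Sampling frequency in Hz (the study hardware samples at 102.4 Hz).
    gyro : ndarray, shape (n, 3)
        Angular velocity in deg/s, axes (x, y, z) as defined above.
    accel : ndarray, shape (n, 3)
        Specific force in g.
    """

    placement: str
    sample_rate: float
    gyro: np.ndarray
    accel: np.ndarray

    def __post_init__(self) -> None:
        if self.placement not in PLACEMENTS:
            raise ParameterError(f"unknown placement {self.placement!r}")
        if self.sample_rate <= 0:
            raise ParameterError("sample_rate must be > 0")
        self.gyro = np.asarray(self.gyro, dtype=float)
        self.accel = np.asarray(self.accel, dtype=float)
        if self.gyro.shape != self.accel.shape or self.gyro.ndim != 2 or self.gyro.shape[1] != 3:
            raise ParameterError("gyro and accel must both have shape (n, 3)")

    @property
    def n_samples(self) -> int:
        return self.gyro.shape[0]

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.sample_rate


@dataclass
class IMUSession:
    """A six-sensor recording of one horse on one surface."""

    horse_id: str
    surface: str
    streams: dict  # placement -> SensorStream
    standstill_window: tuple  # (start, stop) sample indices, half-open
    truth: object | None = None  # optional HorseKinematicProfile payload

    def __post_init__(self) -> None:
        if set(self.streams) != set(PLACEMENTS):
            raise ParameterError("a session needs exactly the six standard placements")
        counts = {s.n_samples for s in self.streams.values()}
        rates = {s.sample_rate for s in self.streams.values()}
        if len(counts) != 1 or len(rates) != 1:
            raise ParameterError("all streams must share sample count and sample rate")

    @property
    def sample_rate(self) -> float:
        return next(iter(self.streams.values())).sample_rate

    @property
    def n_samples(self) -> int:
        return next(iter(self.streams.values())).n_samples


@dataclass
class StrideSeries:
    """Detected stride boundaries and per-stride resampled cycles.

    ``boundaries`` are sample indices of successive left-hind zero-point events
    (maximal LH metatarsal retraction); stride ``i`` spans the half-open sample
    window ``[boundaries[i], boundaries[i+1])``.  ``cycles`` maps a channel
    label to an array of shape ``(n_strides, n_grid)`` holding each stride
    resampled to a fixed grid.
    """

    boundaries: np.ndarray
    durations: np.ndarray
    cycles: dict = field(default_factory=dict)
    sample_rate: float = 102.4

    def __post_init__(self) -> None:
        self.boundaries = np.asarray(self.boundaries, dtype=int)
        self.durations = np.asarray(self.durations, dtype=float)
        if np.any(np.diff(self.boundaries) <= 0):
            raise ParameterError("stride boundaries must be strictly increasing")
        if len(self.durations) != len(self.boundaries) - 1:
            raise ParameterError("need exactly one duration per stride")
        if np.any(self.durations <= 0):
            raise ParameterError("stride durations must be positive")

    @property
    def n_strides(self) -> int:
        return len(self.durations)


@dataclass
class OrientationSeries:
    """Integrated segment orientation (degrees) for one sensor."""

    sagittal_angle: np.ndarray
    coronal_angle: np.ndarray
    sample_rate: float
    detrend_mode: str = "none"  # "none" | "per_stride"


@dataclass
class GaitVariableRecord:
    """The 19 analysed variables for one (horse, surface, repetition, evaluator) cell.

    ``values`` is keyed by :data:`VARIABLE_COLUMNS`; protraction variables are
    stored recoded (late-cycle events mapped to distance from cycle end).
    """

    horse_id: str
    surface: str
    evaluator_id: str
    repetition: int
    n_strides_evaluated: int
    values: dict
    evaluator_type: str = ""

    def __post_init__(self) -> None:
        missing = [v for v in VARIABLE_COLUMNS if v not in self.values]
        if missing:
            raise ParameterError(f"record is missing variables: {missing}")
        if self.n_strides_evaluated < 5:
            raise ParameterError("records require at least five evaluated strides")
        for name in VARIABLE_COLUMNS:
            val = self.values[name]
            if name.startswith(("limb_phasing", "protraction", "retraction")):
                if not (0 <= val < 100):
                    raise ParameterError(f"{name}={val} outside [0, 100)")
            if name.startswith("rom_") and val < 0:
                raise ParameterError(f"{name} must be >= 0")

    def as_row(self) -> dict:
        row = {
            "horse_id": self.horse_id,
            "surface": self.surface,
            "evaluator_id": self.evaluator_id,
            "evaluator_type": self.evaluator_type,
            "repetition": self.repetition,
            "n_strides_evaluated": self.n_strides_evaluated,
        }
        row.update({v: self.values[v] for v in VARIABLE_COLUMNS})
        return row
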