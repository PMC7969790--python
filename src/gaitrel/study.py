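"""Study orchestration: blinding, evaluator emulation and end-to-end runs.

The emulated study follows the published design: per surface, one recording
per horse is copied ``copies_per_horse`` times and blinded behind opaque ids;
every evaluator analyses every blinded item, choosing their own steady-state
window (emulated by an evaluator-and-item-specific seed that jitters the
window inside the steady region); unblinding restores (horse, copy) identity
and the full factorial table (I evaluators x J horses x K copies) feeds the
reliability analysis.
"""

from __future__ import annotations

import pathlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from .containers import TABLE_META_COLUMNS, VARIABLE_COLUMNS
from .errors import ParameterError
from .extract import extract_record
from .reliability import ReliabilityReport, reliability_report
from .simulate import (
    HorseKinematicProfile,
    SessionProtocol,
    simulate_horse_profile,
    simulate_session,
)

#: Per-surface population stride durations (s) for the default study.
SURFACE_STRIDE_DURATION = {"treadmill": 0.731, "soft": 0.707, "hard": 0.698}
#: Per-surface trot speed (m/s); hard-surface speed was not recorded in the
#: field protocol, so the soft-surface natural speed is reused.
SURFACE_SPEED = {"treadmill": 3.3, "soft": 3.51, "hard": 3.51}


@dataclass
class StudyDesign:
    """Blinding/copying design of the reliability study."""

    surfaces: tuple = ("treadmill", "soft", "hard")
    horses_per_surface: int = 10
    copies_per_horse: int = 3
    evaluators: tuple = (
        ("E1", "experienced"),
        ("E2", "experienced"),
        ("E3", "experienced"),
        ("E4", "inexperienced"),
        ("E5", "inexperienced"),
        ("E6", "inexperienced"),
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.horses_per_surface, self.copies_per_horse, len(self.evaluators), len(self.surfaces)) < 1:
            raise ParameterError("all design counts must be >= 1")

    @property
    def evaluator_types(self) -> dict:
        return dict(self.evaluators)


def blind_copies(sessions: dict, design: StudyDesign, seed: int | None = None):
    """Duplicate and blind each horse's session.

    ``sessions`` maps horse id -> session (one surface), or is an iterable of
    ``(horse_id, session)`` pairs.  Each session is copied
    ``copies_per_horse`` times; the copies are shuffled and assigned opaque
    zero-padded sequential ids.  Returns ``(blinded, key)`` where ``blinded``
    is a list of ``(blinded_id, session)`` and ``key`` maps blinded id ->
    (horse id, copy index).  Deterministic given the seed.
    """
    pairs = list(sessions.items()) if isinstance(sessions, dict) else list(sessions)
    horses = [h for h, _ in pairs]
    if len(set(horses)) != len(horses):
        raise ParameterError("duplicate horse ids")
    sessions = dict(pairs)
    items = [(h, c) for h in horses for c in range(1, design.copies_per_horse + 1)]
    rng = np.random.default_rng(np.random.SeedSequence(design.seed if seed is None else seed))
    order = rng.permutation(len(items))
    width = max(2, len(str(len(items))))
    blinded = []
    key = {}
    for rank, pos in enumerate(order):
        horse, copy = items[pos]
        bid = f"B{rank + 1:0{width}d}"
        blinded.append((bid, sessions[horse]))
        key[bid] = (horse, copy)
    return blinded, key


def unblind(key: dict, blinded_id: str):
    """Inverse of :func:`blind_copies` for a single id."""
    return key[blinded_id]


@dataclass
class StudyConfig:
    """Everything a full end-to-end run needs."""

    design: StudyDesign = field(default_factory=StudyDesign)
    population: HorseKinematicProfile = field(default_factory=HorseKinematicProfile)
    between_horse_sd: dict | None = None
    n_trot_strides: int = 25
    noise_sd_gyro: float = 2.0
    noise_sd_accel: float = 0.02
    gyro_bias: float = 0.0
    min_strides: int = 5
    cv_threshold: float = 0.05
    mode: str = "paper"
    seed: int = 0
    # force every evaluator to the same window choice (degenerate design in
    # which the between-evaluator variance component is exactly zero)
    identical_evaluator_windows: bool = False


@dataclass
class StudyReport:
    """Output of :func:`run_study`: the response table, per-surface reliability
    frames, blinding keys and the seed log."""

    table: pd.DataFrame
    report: ReliabilityReport
    keys: dict  # surface -> blinding key
    seeds: dict

    def write(self, out_dir) -> list:
        out_dir = pathlib.Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        paths = []
        table_path = out_dir / "gait_variables.csv"
        from .io import write_blinding_key, write_table

        write_table(self.table, table_path)
        paths.append(table_path)
        paths.extend(self.report.to_csv(out_dir))
        for surface, key in self.keys.items():
            p = out_dir / f"blinding_key_{surface}.csv"
            write_blinding_key(key, p)
            paths.append(p)
        log = out_dir / "run.yaml"
        with open(log, "w") as fh:
            yaml.safe_dump({"seeds": self.seeds}, fh, sort_keys=True)
        paths.append(log)
        return paths


def _child_seed(root: int, *key: int) -> np.random.SeedSequence:
    return np.random.SeedSequence(entropy=root, spawn_key=tuple(key))


def run_study(config: StudyConfig | None = None) -> StudyReport:
    """Simulate, blind, extract per evaluator, unblind and analyse.

    Per surface: draw one kinematic profile per horse, record one session per
    horse, blind J*K copies, have each evaluator extract every blinded item
    with their own window choice, unblind, and assemble the I*J*K response
    table feeding :func:`~gaitrel.reliability.reliability_report`.
    """
    config = config or StudyConfig()
    design = config.design
    rows = []
    keys = {}
    seeds = {"root": config.seed}
    for s_idx, surface in enumerate(design.surfaces):
        pop = HorseKinematicProfile(
            horse_id="POP",
            stride_duration=SURFACE_STRIDE_DURATION.get(surface, config.population.stride_duration),
            limb_phases=dict(config.population.limb_phases),
            protraction_events=dict(config.population.protraction_events),
            retraction_events=dict(config.population.retraction_events),
            sagittal_rom=dict(config.population.sagittal_rom),
            coronal_rom=dict(config.population.coronal_rom),
            speed=SURFACE_SPEED.get(surface, config.population.speed),
        )
        sessions = {}
        for j in range(design.horses_per_surface):
            horse_id = f"H{j + 1:02d}"
            profile_seed = _child_seed(config.seed, s_idx, 0, j)
            profile = simulate_horse_profile(
                pop,
                config.between_horse_sd,
                seed=profile_seed.generate_state(1)[0] % (2**31),
                horse_id=horse_id,
            )
            protocol = SessionProtocol(
                surface=surface,
                n_trot_strides=config.n_trot_strides,
                noise_sd_gyro=config.noise_sd_gyro,
                noise_sd_accel=config.noise_sd_accel,
                gyro_bias=config.gyro_bias,
                seed=int(_child_seed(config.seed, s_idx, 1, j).generate_state(1)[0] % (2**31)),
            )
            sessions[horse_id] = simulate_session(profile, protocol)
        blind_seed = int(_child_seed(config.seed, s_idx, 2).generate_state(1)[0] % (2**31))
        blinded, key = blind_copies(sessions, design, seed=blind_seed)
        keys[surface] = key
        seeds[f"blinding_{surface}"] = blind_seed

        for e_idx, (evaluator_id, evaluator_type) in enumerate(design.evaluators):
            for b_idx, (blinded_id, session) in enumerate(blinded):
                window_key = 0 if config.identical_evaluator_windows else e_idx
                window_rng = np.random.default_rng(_child_seed(config.seed, s_idx, 3, window_key, b_idx))
                record = extract_record(
                    session,
                    evaluator_id=evaluator_id,
                    evaluator_type=evaluator_type,
                    min_strides=config.min_strides,
                    cv_threshold=config.cv_threshold,
                    rng=window_rng,
                )
                horse_id, copy = unblind(key, blinded_id)
                record.horse_id = horse_id
                record.repetition = copy
                rows.append(record.as_row())

    table = pd.DataFrame(rows)
    table = table.sort_values(["surface", "evaluator_id", "horse_id", "repetition"]).reset_index(drop=True)
    report = reliability_report(table, mode=config.mode, variables=list(VARIABLE_COLUMNS))
    return StudyReport(table=table, report=report, keys=keys, seeds=seeds)
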