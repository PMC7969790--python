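"""Rater-reliability statistics for balanced horse x evaluator x repetition tables.

The response model is the additive two-way crossed random-effects ANOVA

    Y_ijk = mu + a_i + b_j + e_ijk,

with evaluator effect ``a_i`` (i = 1..I), horse effect ``b_j`` (j = 1..J) and
repetition error ``e_ijk`` (k = 1..K); repetition and interaction variation
are pooled into the error term.  Mean squares from this ANOVA yield variance
components, from which

    ICC_inter = s2_H / (s2_H + s2_E + s2_R)            (between-evaluator)
    ICC_intra = (s2_H + s2_E) / (s2_H + s2_E + s2_R)   (within-evaluator)
    VPC_x     = s2_x / (s2_H + s2_E + s2_R)            (variance partitioning)

Two variance-component modes are provided.  ``paper`` divides the mean-square
differences by J (horses) and I (evaluators) — at the study design (I = 6,
J = 10) these are the published divisors 10 and 6.  ``balanced`` uses the
expected-mean-square divisors I*K and J*K, which make the estimator
consistent and is the mode used for parameter-recovery checks.

The module exposes both a functional surface (:func:`anova_mean_squares`,
:func:`variance_components`, :func:`icc`, :func:`vpc`,
:func:`experience_effect`, :func:`describe`, :func:`reliability_report`) and a
statsmodels-style model object: build a :class:`ReliabilityAnova` from data,
call :meth:`~ReliabilityAnova.fit`, and read estimates off the returned
:class:`ReliabilityAnovaResults` (or print ``results.summary()``).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .containers import SPATIAL_VARIABLES, TEMPORAL_VARIABLES, VARIABLE_COLUMNS
from .errors import DesignError, ParameterError, UndefinedVarianceError


@dataclass
class MeanSquares:
    """ANOVA mean squares and degrees of freedom for the additive model."""

    ms_horse: float
    ms_evaluator: float
    ms_error: float
    df_horse: int
    df_evaluator: int
    df_error: int
    n: int

    @property
    def n_evaluators(self) -> int:
        return self.df_evaluator + 1

    @property
    def n_horses(self) -> int:
        return self.df_horse + 1

    @property
    def n_repetitions(self) -> int:
        return self.n // (self.n_evaluators * self.n_horses)


@dataclass
class VarianceComponents:
    """Estimated variance components (negative estimates truncated to zero)."""

    sigma2_horse: float
    sigma2_evaluator: float
    sigma2_repetition: float
    mode: str = "paper"

    @property
    def total(self) -> float:
        return self.sigma2_horse + self.sigma2_evaluator + self.sigma2_repetition


def _as_array(table, variable=None):
    """Coerce input to a (I, J, K) response array.

    Accepts an ndarray already shaped (I, J, K), or a DataFrame with
    ``evaluator_id``/``horse_id``/``repetition`` columns and ``variable``.
    Returns ``(y, evaluator_ids)``.
    """
    if isinstance(table, np.ndarray):
        if table.ndim != 3:
            raise DesignError("response array must have shape (I, J, K)")
        return table.astype(float), None
    df = table
    if variable is None:
        raise ParameterError("variable name required for DataFrame input")
    evaluators = sorted(df["evaluator_id"].unique())
    horses = sorted(df["horse_id"].unique())
    reps = sorted(df["repetition"].unique())
    expected = len(evaluators) * len(horses) * len(reps)
    if len(df) != expected:
        raise DesignError(f"unbalanced table: {len(df)} rows, expected {expected}")
    pivot = df.set_index(["evaluator_id", "horse_id", "repetition"])[variable]
    if pivot.index.duplicated().any():
        raise DesignError("duplicate (evaluator, horse, repetition) cells")
    try:
        y = pivot.unstack("repetition").loc[
            pd.MultiIndex.from_product([evaluators, horses])
        ].to_numpy().reshape(len(evaluators), len(horses), len(reps))
    except KeyError as exc:
        raise DesignError("unbalanced table: missing cells") from exc
    if np.isnan(y).any():
        raise DesignError("unbalanced table: missing cells")
    return y, evaluators


def anova_mean_squares(table, variable: str | None = None) -> MeanSquares:
    """Mean squares of the additive model ``Y = mu + a_i + b_j + e``.

    ``SS_Horse = I*K * sum_j (ybar_j - ybar)^2``,
    ``SS_Evaluator = J*K * sum_i (ybar_i - ybar)^2``,
    ``SS_Error = SS_Total - SS_Horse - SS_Evaluator`` with
    ``df_error = n - 1 - (I-1) - (J-1)``.
    """
    y, _ = _as_array(table, variable)
    I, J, K = y.shape
    n = I * J * K
    grand = y.mean()
    ss_total = float(((y - grand) ** 2).sum())
    ss_horse = float(I * K * ((y.mean(axis=(0, 2)) - grand) ** 2).sum())
    ss_eval = float(J * K * ((y.mean(axis=(1, 2)) - grand) ** 2).sum())
    ss_error = max(ss_total - ss_horse - ss_eval, 0.0)
    df_h, df_e = J - 1, I - 1
    df_err = n - 1 - df_h - df_e
    if df_h < 1 or df_e < 1 or df_err < 1:
        raise DesignError("design too small for the additive ANOVA")
    return MeanSquares(
        ms_horse=ss_horse / df_h,
        ms_evaluator=ss_eval / df_e,
        ms_error=ss_error / df_err,
        df_horse=df_h,
        df_evaluator=df_e,
        df_error=df_err,
        n=n,
    )


def variance_components(ms: MeanSquares, mode: str = "paper") -> VarianceComponents:
    """Variance components from mean squares.

    ``paper``: s2_H = (MS_H - MS_err) / J, s2_E = (MS_E - MS_err) / I (the
    published divisors, 10 and 6 at the study design); ``balanced``:
    divisors I*K and J*K (expected mean squares).  s2_R = MS_err in both.
    Negative estimates are truncated to zero.
    """
    I, J, K = ms.n_evaluators, ms.n_horses, ms.n_repetitions
    if mode == "paper":
        div_h, div_e = J, I
    elif mode == "balanced":
        div_h, div_e = I * K, J * K
    else:
        raise ParameterError(f"unknown mode {mode!r}")
    return VarianceComponents(
        sigma2_horse=max((ms.ms_horse - ms.ms_error) / div_h, 0.0),
        sigma2_evaluator=max((ms.ms_evaluator - ms.ms_error) / div_e, 0.0),
        sigma2_repetition=max(ms.ms_error, 0.0),
        mode=mode,
    )


def icc(components: VarianceComponents) -> tuple:
    """(ICC interclass, ICC intraclass) from variance components."""
    total = components.total
    if total <= 0:
        raise UndefinedVarianceError("total variance is zero: ICC undefined")
    inter = components.sigma2_horse / total
    intra = (components.sigma2_horse + components.sigma2_evaluator) / total
    return float(inter), float(intra)


def vpc(components: VarianceComponents) -> tuple:
    """(VPC horse, VPC evaluator, VPC repetition); the triplet sums to one."""
    total = components.total
    if total <= 0:
        raise UndefinedVarianceError("total variance is zero: VPC undefined")
    return (
        float(components.sigma2_horse / total),
        float(components.sigma2_evaluator / total),
        float(components.sigma2_repetition / total),
    )


def experience_effect(table, variable: str | None = None, evaluator_types=None) -> tuple:
    """F test of evaluator experience (evaluator nested in type).

    The type contrast is tested against between-evaluator-within-type
    variation: ``F = MS_Type / MS_Evaluator(Type)`` on (T-1, I-T) degrees of
    freedom (T = number of types).  Returns ``(F, p)``.

    ``evaluator_types`` maps evaluator id -> type; for DataFrame input it
    defaults to the table's ``evaluator_type`` column.
    """
    y, evaluators = _as_array(table, variable)
    if evaluator_types is None:
        if not isinstance(table, pd.DataFrame) or "evaluator_type" not in table:
            raise ParameterError("evaluator_types required")
        evaluator_types = (
            table.drop_duplicates("evaluator_id").set_index("evaluator_id")["evaluator_type"].to_dict()
        )
    if evaluators is None:
        evaluators = list(range(y.shape[0]))
    types = np.array([evaluator_types[e] for e in evaluators])
    levels = sorted(set(types))
    t = len(levels)
    counts = {lv: int((types == lv).sum()) for lv in levels}
    if t < 2 or min(counts.values()) < 2:
        raise DesignError(f"each evaluator type needs >= 2 evaluators (got {counts})")
    I, J, K = y.shape
    ev_means = y.mean(axis=(1, 2))
    grand = ev_means.mean()
    ss_type = 0.0
    ss_within = 0.0
    for lv in levels:
        sel = ev_means[types == lv]
        ss_type += J * K * len(sel) * (sel.mean() - grand) ** 2
        ss_within += J * K * ((sel - sel.mean()) ** 2).sum()
    df_type, df_within = t - 1, I - t
    ms_within = ss_within / df_within
    if ms_within <= 0:
        raise UndefinedVarianceError("no between-evaluator variation within types")
    f = (ss_type / df_type) / ms_within
    p = float(stats.f.sf(f, df_type, df_within))
    return float(f), p


def describe(values, variable: str | None = None) -> tuple:
    """Descriptives ``(mean, sd, median, iqr)``.

    Sample sd (n-1 denominator); IQR = Q3 - Q1 with linear-interpolation
    quantiles.
    """
    if isinstance(values, pd.DataFrame):
        values = values[variable]
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise ParameterError("describe needs at least 2 values")
    q1, q3 = np.percentile(x, [25, 75], method="linear")
    return (
        float(x.mean()),
        float(x.std(ddof=1)),
        float(np.median(x)),
        float(q3 - q1),
    )


# ---------------------------------------------------------------------------
# model / results objects
# ---------------------------------------------------------------------------

class ReliabilityAnova:
    """Reliability model for one response variable on a balanced table.

    Parameters
    ----------
    y : ndarray, shape (I, J, K)
        Responses indexed by (evaluator, horse, repetition).
    evaluator_types : dict, optional
        Evaluator id (or index) -> type label; enables the experience test.

    Use :meth:`from_dataframe` to build the model from a long-format
    gait-variable table.
    """

    def __init__(self, y: np.ndarray, evaluator_ids=None, evaluator_types=None, name: str = "value"):
        y = np.asarray(y, dtype=float)
        if y.ndim != 3:
            raise DesignError("y must have shape (I, J, K)")
        self.y = y
        self.evaluator_ids = list(evaluator_ids) if evaluator_ids is not None else list(range(y.shape[0]))
        self.evaluator_types = evaluator_types
        self.name = name

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, variable: str) -> "ReliabilityAnova":
        y, evaluators = _as_array(df, variable)
        types = None
        if "evaluator_type" in df and df["evaluator_type"].astype(str).str.len().gt(0).any():
            types = df.drop_duplicates("evaluator_id").set_index("evaluator_id")["evaluator_type"].to_dict()
        return cls(y, evaluator_ids=evaluators, evaluator_types=types, name=variable)

    def fit(self, mode: str = "paper") -> "ReliabilityAnovaResults":
        ms = anova_mean_squares(self.y)
        components = variance_components(ms, mode=mode)
        try:
            icc_inter, icc_intra = icc(components)
            vpcs = vpc(components)
        except UndefinedVarianceError:
            icc_inter = icc_intra = np.nan
            vpcs = (np.nan, np.nan, np.nan)
        descriptives = describe(self.y.ravel())
        exp_f = exp_p = None
        if self.evaluator_types is not None:
            try:
                exp_f, exp_p = experience_effect(
                    self.y, evaluator_types={i: self.evaluator_types[e] for i, e in enumerate(self.evaluator_ids)}
                )
            except UndefinedVarianceError:
                exp_f, exp_p = np.nan, np.nan
        return ReliabilityAnovaResults(
            model=self,
            mode=mode,
            mean_squares=ms,
            components=components,
            icc_inter=icc_inter,
            icc_intra=icc_intra,
            vpc_horse=vpcs[0],
            vpc_evaluator=vpcs[1],
            vpc_repetition=vpcs[2],
            descriptives=descriptives,
            experience_F=exp_f,
            experience_p=exp_p,
        )


@dataclass
class ReliabilityAnovaResults:
    """Fitted reliability estimates for one variable."""

    model: ReliabilityAnova
    mode: str
    mean_squares: MeanSquares
    components: VarianceComponents
    icc_inter: float
    icc_intra: float
    vpc_horse: float
    vpc_evaluator: float
    vpc_repetition: float
    descriptives: tuple  # (mean, sd, median, iqr)
    experience_F: float | None = None
    experience_p: float | None = None

    def summary(self) -> str:
        ms = self.mean_squares
        mean, sd, median, iqr = self.descriptives
        lines = [
            f"Reliability ANOVA results [{self.model.name}] (mode={self.mode})",
            "=" * 58,
            f"design: I={ms.n_evaluators} evaluators, J={ms.n_horses} horses, "
            f"K={ms.n_repetitions} repetitions (n={ms.n})",
            f"descriptives: mean={mean:.3f} sd={sd:.3f} median={median:.3f} iqr={iqr:.3f}",
            f"mean squares: horse={ms.ms_horse:.4g} (df {ms.df_horse}), "
            f"evaluator={ms.ms_evaluator:.4g} (df {ms.df_evaluator}), "
            f"error={ms.ms_error:.4g} (df {ms.df_error})",
            f"variance components: horse={self.components.sigma2_horse:.4g}, "
            f"evaluator={self.components.sigma2_evaluator:.4g}, "
            f"repetition={self.components.sigma2_repetition:.4g}",
            f"ICC interclass={self.icc_inter:.3f}  ICC intraclass={self.icc_intra:.3f}",
            f"VPC horse={self.vpc_horse:.3f}  evaluator={self.vpc_evaluator:.3f}  "
            f"repetition={self.vpc_repetition:.3f}",
        ]
        if self.experience_p is not None:
            lines.append(f"evaluator experience: F={self.experience_F:.3f}, p={self.experience_p:.4f}")
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# per-surface report
# ---------------------------------------------------------------------------

class ReliabilityReport:
    """Per-surface reliability tables (one row per variable + mean-ICC rows)."""

    def __init__(self, frames: dict, mode: str):
        self.frames = frames  # surface -> DataFrame
        self.mode = mode

    def to_csv(self, out_dir, prefix: str = "reliability") -> list:
        import pathlib

        out_dir = pathlib.Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        paths = []
        for surface, frame in self.frames.items():
            path = out_dir / f"{prefix}_{surface}.csv"
            frame.to_csv(path, index=False, float_format="%.6g")
            paths.append(path)
        return paths


def reliability_report(table: pd.DataFrame, mode: str = "paper", variables=None) -> ReliabilityReport:
    """Full reliability analysis, one block per surface.

    For every surface x variable: descriptives, mean squares, variance
    components, inter/intraclass ICC, VPCs and the evaluator-experience
    p-value; plus mean-ICC rows over temporal, spatial and all variables.
    Variables with zero total variance are reported as NaN with a note and do
    not abort the run.
    """
    if variables is None:
        variables = [v for v in VARIABLE_COLUMNS if v in table.columns]
        if not variables:
            variables = [
                c
                for c in table.columns
                if c not in ("horse_id", "surface", "evaluator_id", "evaluator_type", "repetition", "n_strides_evaluated")
            ]
    if not len(table):
        raise DesignError("empty table")
    frames = {}
    for surface, sub in table.groupby("surface", sort=True):
        rows = []
        for var in variables:
            model = ReliabilityAnova.from_dataframe(sub, var)
            res = model.fit(mode=mode)
            mean, sd, median, iqr = res.descriptives
            rows.append(
                {
                    "variable": var,
                    "kind": "temporal" if var in TEMPORAL_VARIABLES else (
                        "spatial" if var in SPATIAL_VARIABLES else "other"
                    ),
                    "mean": mean,
                    "sd": sd,
                    "median": median,
                    "iqr": iqr,
                    "ms_horse": res.mean_squares.ms_horse,
                    "ms_evaluator": res.mean_squares.ms_evaluator,
                    "ms_error": res.mean_squares.ms_error,
                    "sigma2_horse": res.components.sigma2_horse,
                    "sigma2_evaluator": res.components.sigma2_evaluator,
                    "sigma2_repetition": res.components.sigma2_repetition,
                    "icc_inter": res.icc_inter,
                    "icc_intra": res.icc_intra,
                    "vpc_horse": res.vpc_horse,
                    "vpc_evaluator": res.vpc_evaluator,
                    "vpc_repetition": res.vpc_repetition,
                    "experience_p": res.experience_p if res.experience_p is not None else np.nan,
                    "note": "" if np.isfinite(res.icc_inter) else "undefined ICC (zero total variance)",
                }
            )
        frame = pd.DataFrame(rows)
        summary_rows = []
        for label, sel in (
            ("mean_icc_temporal", frame["kind"] == "temporal"),
            ("mean_icc_spatial", frame["kind"] == "spatial"),
            ("mean_icc_total", frame["kind"].isin(["temporal", "spatial", "other"])),
        ):
            if sel.any():
                summary_rows.append(
                    {
                        "variable": label,
                        "kind": "summary",
                        "icc_inter": frame.loc[sel, "icc_inter"].mean(),
                        "icc_intra": frame.loc[sel, "icc_intra"].mean(),
                    }
                )
        frames[surface] = pd.concat([frame, pd.DataFrame(summary_rows)], ignore_index=True)
    return ReliabilityReport(frames, mode)
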