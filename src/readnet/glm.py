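"""ROI-level general linear model for block designs.

Design matrices pair canonical-HRF-convolved condition boxcars with a
discrete-cosine high-pass set and an intercept; estimation is ordinary
least squares per ROI, with contrast t-statistics and a group-level
two-sample comparison of contrast effects.  Autocorrelation modeling is
deliberately omitted: at ~80 volumes an AR fit is poorly conditioned and
the downstream network analysis never consumes GLM residual variances.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.special import gammaln

from .synthetic import RoiTimeSeriesSet, StimulusSchedule

__all__ = [
    "canonical_hrf",
    "convolved_regressor",
    "dct_highpass_basis",
    "DesignMatrix",
    "build_design_matrix",
    "GlmFit",
    "fit_glm",
    "contrast_t",
    "group_activation_ttest",
    "global_signal_regressor",
]

OVERSAMPLING = 16

# Conventional double-gamma parameters: response delay 6 s, undershoot
# delay 16 s, unit dispersions, response:undershoot amplitude ratio 6.
HRF_RESPONSE_DELAY = 6.0
HRF_UNDERSHOOT_DELAY = 16.0
HRF_RESPONSE_DISPERSION = 1.0
HRF_UNDERSHOOT_DISPERSION = 1.0
HRF_RATIO = 6.0
HRF_LENGTH_S = 32.0


def _gamma_pdf(t: np.ndarray, shape: float, scale: float) -> np.ndarray:
    # evaluated directly to keep t=0 exactly zero for shape > 1
    out = np.zeros_like(t, dtype=float)
    pos = t > 0
    tp = t[pos]
    out[pos] = np.exp(
        (shape - 1) * np.log(tp) - tp / scale - gammaln(shape) - shape * np.log(scale)
    )
    return out


def canonical_hrf(tr_s: float, duration_s: float = HRF_LENGTH_S) -> np.ndarray:
    """Canonical double-gamma hemodynamic response sampled every `tr_s`.

    Positive response peaking near 5 s, negative undershoot at 1/6
    amplitude centered near 16 s, peak-normalized to a maximum of 1.
    """
    if tr_s <= 0:
        raise ValueError("tr_s must be positive")
    if duration_s < HRF_LENGTH_S:
        raise ValueError(f"duration_s must be >= {HRF_LENGTH_S}")
    t = np.arange(0, duration_s, tr_s)
    h = _gamma_pdf(
        t, HRF_RESPONSE_DELAY / HRF_RESPONSE_DISPERSION, HRF_RESPONSE_DISPERSION
    ) - _gamma_pdf(
        t, HRF_UNDERSHOOT_DELAY / HRF_UNDERSHOOT_DISPERSION, HRF_UNDERSHOOT_DISPERSION
    ) / HRF_RATIO
    return h / h.max()


def convolved_regressor(
    schedule: StimulusSchedule, condition: str, drop_dummies: bool = True
) -> np.ndarray:
    """Condition boxcar convolved with the canonical HRF, sampled at the TR.

    The boxcar is built on a 16x-oversampled grid, convolved, then
    decimated at volume onsets; optionally the dummy volumes are dropped.
    """
    dt = schedule.tr_s / OVERSAMPLING
    box = schedule.boxcar(condition, dt)
    hrf = canonical_hrf(dt)
    reg = np.convolve(box, hrf)[: box.size]
    reg = reg[::OVERSAMPLING][: schedule.n_volumes]
    return reg[schedule.n_dummy :] if drop_dummies else reg


def dct_highpass_basis(n_volumes: int, tr_s: float, cutoff_s: float) -> np.ndarray:
    """Discrete-cosine drift columns with periods longer than `cutoff_s`.

    K = floor(2 * D / cutoff) columns for run duration D = n_volumes * tr_s;
    an infinite cutoff yields an empty basis.
    """
    if cutoff_s <= 0:
        raise ValueError("cutoff_s must be positive")
    if not np.isfinite(cutoff_s):
        return np.empty((n_volumes, 0))
    duration = n_volumes * tr_s
    k_max = int(np.floor(2 * duration / cutoff_s))
    n = np.arange(n_volumes)
    cols = [
        np.cos(np.pi * k * (2 * n + 1) / (2 * n_volumes)) for k in range(1, k_max + 1)
    ]
    return np.column_stack(cols) if cols else np.empty((n_volumes, 0))


@dataclass(frozen=True)
class DesignMatrix:
    matrix: np.ndarray  # [n_volumes_analyzed, n_regressors]
    names: tuple[str, ...]
    tr_s: float

    def __post_init__(self) -> None:
        if self.matrix.shape[1] != len(self.names):
            raise ValueError("column count does not match names")

    @property
    def n_volumes(self) -> int:
        return self.matrix.shape[0]

    def column(self, name: str) -> np.ndarray:
        return self.matrix[:, self.names.index(name)]

    def contrast_vector(self, weights: dict[str, float]) -> np.ndarray:
        c = np.zeros(len(self.names))
        for name, w in weights.items():
            c[self.names.index(name)] = w
        return c

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix, columns=list(self.names))


def _collinear_columns(x: np.ndarray, names: tuple[str, ...]) -> list[str]:
    bad = []
    for j in range(1, x.shape[1]):
        sub = x[:, : j + 1]
        if np.linalg.matrix_rank(sub) < j + 1:
            bad.append(names[j])
    return bad


def build_design_matrix(
    schedule: StimulusSchedule,
    nuisance: np.ndarray | None = None,
    nuisance_names: tuple[str, ...] | None = None,
    hp_cutoff_s: float = 128.0,
    include_instruction: bool = True,
) -> DesignMatrix:
    """Assemble [task, instruction, nuisance..., dct..., intercept].

    The instruction period gets its own regressor so the 2-s cue before
    each block does not bias the task boxcar.  High-pass drift columns are
    computed over the analyzed run.  Raises if the result is rank
    deficient, naming the collinear columns.
    """
    cols = [convolved_regressor(schedule, "task")]
    names = ["task"]
    if include_instruction:
        cols.append(convolved_regressor(schedule, "instruction"))
        names.append("instruction")
    n = schedule.n_volumes_analyzed
    if nuisance is not None:
        nuisance = np.atleast_2d(np.asarray(nuisance, dtype=float))
        if nuisance.shape[0] != n:
            nuisance = nuisance.T
        if nuisance.shape[0] != n:
            raise ValueError(
                f"nuisance rows ({nuisance.shape}) do not match {n} analyzed volumes"
            )
        if nuisance_names is None:
            nuisance_names = tuple(
                f"nuisance_{i + 1}" for i in range(nuisance.shape[1])
            )
        cols.extend(nuisance.T)
        names.extend(nuisance_names)
    dct = dct_highpass_basis(n, schedule.tr_s, hp_cutoff_s)
    cols.extend(dct.T)
    names.extend(f"dct_{k + 1}" for k in range(dct.shape[1]))
    cols.append(np.ones(n))
    names.append("intercept")
    x = np.column_stack(cols)
    if np.linalg.matrix_rank(x) < x.shape[1]:
        bad = _collinear_columns(x, tuple(names))
        raise ValueError(f"design matrix is rank deficient; collinear columns: {bad}")
    return DesignMatrix(x, tuple(names), schedule.tr_s)


@dataclass(frozen=True)
class GlmFit:
    betas: np.ndarray  # [n_regressors, n_rois]
    residual_variance: np.ndarray  # [n_rois]
    dof_resid: int
    roi_labels: tuple[str, ...]


def fit_glm(ts: RoiTimeSeriesSet, design: DesignMatrix) -> GlmFit:
    """Ordinary least squares, one fit per ROI (shared design)."""
    x = design.matrix
    if ts.n_volumes != x.shape[0]:
        raise ValueError(
            f"time series has {ts.n_volumes} volumes, design {x.shape[0]} rows"
        )
    rank = np.linalg.matrix_rank(x)
    dof = x.shape[0] - rank
    if dof <= 0:
        raise ValueError("no residual degrees of freedom")
    y = ts.data.T  # [n_volumes, n_rois]
    betas, *_ = np.linalg.lstsq(x, y, rcond=None)
    rss = np.sum((y - x @ betas) ** 2, axis=0)
    return GlmFit(betas, rss / dof, dof, ts.roi_labels)


def contrast_t(
    fit: GlmFit, design: DesignMatrix, contrast: np.ndarray | dict[str, float]
) -> pd.DataFrame:
    """Per-ROI contrast effect, t-statistic and two-sided p.

    Zero-residual-variance ROIs (exact interpolation) are flagged: t is
    +/-inf with p = 0 when the effect is nonzero, and 0/1 otherwise.
    """
    if isinstance(contrast, dict):
        c = design.contrast_vector(contrast)
    else:
        c = np.asarray(contrast, dtype=float)
    if c.size != len(design.names):
        raise ValueError("contrast length does not match the design")
    x = design.matrix
    effect = c @ fit.betas
    var_factor = float(c @ np.linalg.pinv(x.T @ x) @ c)
    se = np.sqrt(fit.residual_variance * var_factor)
    # exact interpolation leaves residual variance at rounding level, not
    # literally zero; flag relative to the effect's own scale
    zero_var = se**2 <= 1e-20 * np.maximum(effect**2, np.finfo(float).tiny)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(zero_var, np.sign(effect) * np.inf, effect / np.where(se, se, 1))
    t = np.where(zero_var & (effect == 0), 0.0, t)
    if np.any(zero_var & (effect != 0)):
        warnings.warn("zero residual variance with nonzero effect: t set to +/-inf")
    p = np.where(
        np.isinf(t), 0.0, 2 * sps.t.sf(np.abs(np.where(np.isinf(t), 0, t)), fit.dof_resid)
    )
    p = np.where(zero_var & (effect == 0), 1.0, p)
    return pd.DataFrame(
        {
            "roi": list(fit.roi_labels),
            "effect": effect,
            "t": t,
            "p": p,
            "zero_variance": zero_var,
        }
    )


def group_activation_ttest(
    effects_a: pd.DataFrame | np.ndarray,
    effects_b: pd.DataFrame | np.ndarray,
    roi_labels: tuple[str, ...] | None = None,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Two-sample pooled-variance t per ROI on subjects' contrast effects.

    Inputs are [n_subjects, n_rois] arrays (or DataFrames whose columns are
    ROIs).  Bonferroni family = number of ROIs.
    """
    from .stats import two_sample_t  # local import: stats depends on nothing here

    if isinstance(effects_a, pd.DataFrame):
        roi_labels = tuple(effects_a.columns)
        effects_a = effects_a.to_numpy()
    if isinstance(effects_b, pd.DataFrame):
        if roi_labels is not None and tuple(effects_b.columns) != roi_labels:
            raise ValueError("groups have different ROI sets")
        effects_b = effects_b.to_numpy()
    effects_a = np.asarray(effects_a, dtype=float)
    effects_b = np.asarray(effects_b, dtype=float)
    if effects_a.shape[1] != effects_b.shape[1]:
        raise ValueError("groups have different ROI sets")
    if roi_labels is None:
        roi_labels = tuple(f"ROI_{i + 1:03d}" for i in range(effects_a.shape[1]))
    t, df, p = two_sample_t(effects_a, effects_b)
    m = len(roi_labels)
    return pd.DataFrame(
        {
            "roi": list(roi_labels),
            "mean_a": effects_a.mean(axis=0),
            "sd_a": effects_a.std(axis=0, ddof=1),
            "mean_b": effects_b.mean(axis=0),
            "sd_b": effects_b.std(axis=0, ddof=1),
            "t": t,
            "df": df,
            "p": p,
            "significant_uncorrected": p < alpha,
            "significant_bonferroni": p < alpha / m,
            "family_size": m,
        }
    )


def global_signal_regressor(ts: RoiTimeSeriesSet) -> np.ndarray:
    """Mean signal across ROIs, centered — the optional global-signal
    nuisance column (used by the GLM stage, off by default for networks)."""
    g = ts.data.mean(axis=0)
    return g - g.mean()
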