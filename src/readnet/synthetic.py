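"""Synthetic two-group, two-session block-design BOLD cohorts at ROI resolution.

The generator emulates the structure a whole-brain functional-network study
of child readers assumes: two groups of 16 subjects, two task sessions
(phonological and orthographic judgment), 90 AAL parcels sampled every
TR = 2 s over a run of four 26-s experimental blocks interleaved with 12-s
fixation blocks, plus behavioral score tables.  ROI signals are drawn from
a module-structured multivariate normal (community-structured correlation),
with an HRF-convolved task waveform added to a designated subset of
"active" ROIs and optional white measurement noise on top.  A per-session
correlation perturbation applied to one group injects a detectable
network-topology difference into exactly one session.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from importlib import resources
from typing import Sequence

import numpy as np
import pandas as pd

GROUPS = ("good", "poor")
SESSIONS = ("phonological", "orthographic")
CONDITIONS = ("task", "instruction", "fixation")

__all__ = [
    "GROUPS",
    "SESSIONS",
    "Event",
    "StimulusSchedule",
    "GroupEffect",
    "BehaviorParams",
    "SyntheticCohortSpec",
    "RoiTimeSeriesSet",
    "aal_labels",
    "make_block_design",
    "module_assignments",
    "active_rois",
    "target_correlation",
    "simulate_subject_timeseries",
    "simulate_behavior",
    "simulate_cohort",
    "subject_seed",
]


def aal_labels() -> tuple[str, ...]:
    """The 90 cortical/subcortical AAL parcel names, in atlas order."""
    text = resources.files("readnet.data").joinpath("aal90.txt").read_text()
    labels = tuple(line.strip() for line in text.splitlines() if line.strip())
    if len(labels) != 90:
        raise RuntimeError("packaged AAL label list is corrupt")
    return labels


@dataclass(frozen=True)
class Event:
    onset_s: float
    duration_s: float
    condition: str

    def __post_init__(self) -> None:
        if self.condition not in CONDITIONS:
            raise ValueError(f"unknown condition {self.condition!r}")
        if self.duration_s <= 0:
            raise ValueError("event duration must be positive")


@dataclass(frozen=True)
class StimulusSchedule:
    """A block-design run: non-overlapping events tiling [0, total_duration_s)."""

    events: tuple[Event, ...]
    tr_s: float
    n_dummy: int

    def __post_init__(self) -> None:
        if self.tr_s <= 0:
            raise ValueError("tr_s must be positive")
        if not self.events:
            raise ValueError("schedule has no events")
        prev_end = 0.0
        for ev in self.events:
            if ev.onset_s < prev_end - 1e-9:
                raise ValueError("events overlap or are unsorted")
            prev_end = ev.onset_s + ev.duration_s
        total = self.total_duration_s
        if abs(total / self.tr_s - round(total / self.tr_s)) > 1e-9:
            raise ValueError(
                f"tr_s={self.tr_s} does not evenly divide total duration {total}"
            )
        if not 0 <= self.n_dummy < self.n_volumes:
            raise ValueError("n_dummy must be in [0, n_volumes)")

    @property
    def total_duration_s(self) -> float:
        return sum(ev.duration_s for ev in self.events)

    @property
    def n_volumes(self) -> int:
        return int(round(self.total_duration_s / self.tr_s))

    @property
    def n_volumes_analyzed(self) -> int:
        return self.n_volumes - self.n_dummy

    @property
    def analyzed_duration_s(self) -> float:
        return self.n_volumes_analyzed * self.tr_s

    def condition_intervals(self, condition: str) -> list[tuple[float, float]]:
        """(onset, offset) pairs, in seconds from run start, for one condition."""
        return [
            (ev.onset_s, ev.onset_s + ev.duration_s)
            for ev in self.events
            if ev.condition == condition
        ]

    def boxcar(self, condition: str, dt_s: float) -> np.ndarray:
        """Indicator of `condition` sampled at step dt_s over the full run."""
        n = int(round(self.total_duration_s / dt_s))
        t = np.arange(n) * dt_s
        out = np.zeros(n)
        for on, off in self.condition_intervals(condition):
            out[(t >= on - 1e-9) & (t < off - 1e-9)] = 1.0
        return out

    def analyzed_volume_mask(self, condition: str) -> np.ndarray:
        """Boolean mask over analyzed volumes whose acquisition time falls in
        `condition` blocks (volume timestamped at its onset)."""
        t = (np.arange(self.n_volumes) * self.tr_s)[self.n_dummy :]
        mask = np.zeros(t.size, dtype=bool)
        for on, off in self.condition_intervals(condition):
            mask |= (t >= on - 1e-9) & (t < off - 1e-9)
        return mask


def make_block_design(
    tr_s: float = 2.0,
    n_blocks: int = 4,
    instruction_s: float = 2.0,
    n_trials: int = 8,
    trial_s: float = 3.0,
    fixation_s: float = 12.0,
    n_dummy: int = 3,
) -> StimulusSchedule:
    """Block-design run with fixation flanking every experimental block
    (F E F E ... E F).

    Defaults mirror the acquisition the generator emulates: four blocks of
    a 2-s instruction plus eight 3-s trials (26 s each) interleaved with
    12-s fixation, TR 2 s, three dummy volumes — 164 s, 82 volumes,
    79 analyzed.
    """
    if n_blocks < 1 or n_trials < 1:
        raise ValueError("n_blocks and n_trials must be positive integers")
    if min(tr_s, instruction_s, trial_s, fixation_s) <= 0:
        raise ValueError("all durations must be positive")
    if n_dummy < 0:
        raise ValueError("n_dummy must be non-negative")
    task_s = n_trials * trial_s
    events: list[Event] = []
    t = 0.0
    for _ in range(n_blocks):
        events.append(Event(t, fixation_s, "fixation"))
        t += fixation_s
        events.append(Event(t, instruction_s, "instruction"))
        t += instruction_s
        events.append(Event(t, task_s, "task"))
        t += task_s
    events.append(Event(t, fixation_s, "fixation"))
    return StimulusSchedule(tuple(events), tr_s=tr_s, n_dummy=n_dummy)


@dataclass(frozen=True)
class GroupEffect:
    """Within-module correlation offset applied to one group in one session."""

    delta_within_r: float = 0.15
    group: str = "poor"
    session: str = "orthographic"

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ValueError(f"group must be one of {GROUPS}")
        if self.session not in SESSIONS:
            raise ValueError(f"session must be one of {SESSIONS}")


@dataclass(frozen=True)
class BehaviorParams:
    reading_mean: float
    reading_sd: float
    raven_mean: float
    raven_sd: float


#: Printed cohort summary statistics for the two reading groups.
DEFAULT_BEHAVIOR = {
    "good": BehaviorParams(115.75, 13.57, 68.44, 15.78),
    "poor": BehaviorParams(35.63, 13.59, 75.0, 16.73),
}


@dataclass(frozen=True)
class SyntheticCohortSpec:
    """Everything that determines a synthetic cohort, including the seed.

    Cohort generation is a pure function of this object: same spec, same
    cohort, bit for bit.
    """

    n_per_group: int = 16
    n_rois: int = 90
    n_modules: int = 6
    within_module_r: float = 0.3
    between_module_r: float = 0.1
    group_effect: GroupEffect = field(default_factory=GroupEffect)
    activation_amplitude: float = 1.0
    noise_sd: float = 0.5
    behavior: dict[str, BehaviorParams] = field(
        default_factory=lambda: dict(DEFAULT_BEHAVIOR)
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_group < 1:
            raise ValueError("n_per_group must be >= 1")
        if self.n_rois < 2 or self.n_modules < 1 or self.n_modules > self.n_rois:
            raise ValueError("need 2 <= n_modules <= n_rois")
        for r in (self.within_module_r, self.between_module_r):
            if not -1 < r < 1:
                raise ValueError("module correlations must lie in (-1, 1)")
        perturbed = self.within_module_r + self.group_effect.delta_within_r
        if not -1 < perturbed < 1:
            raise ValueError("perturbed within-module correlation leaves (-1, 1)")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if set(self.behavior) != set(GROUPS):
            raise ValueError(f"behavior must have entries for {GROUPS}")


@dataclass(frozen=True)
class RoiTimeSeriesSet:
    """One subject-session's ROI-by-volume BOLD matrix (dummies removed)."""

    subject_id: str
    group: str
    session: str
    data: np.ndarray  # [n_rois, n_volumes_analyzed]
    tr_s: float
    roi_labels: tuple[str, ...]

    def __post_init__(self) -> None:
        data = np.asarray(self.data, dtype=float)
        object.__setattr__(self, "data", data)
        if data.ndim != 2:
            raise ValueError("data must be a 2-D [ROI x volume] matrix")
        if data.shape[0] != len(self.roi_labels):
            raise ValueError(
                f"{data.shape[0]} rows but {len(self.roi_labels)} ROI labels"
            )
        if not np.all(np.isfinite(data)):
            raise ValueError("data contains non-finite values")

    @property
    def n_rois(self) -> int:
        return self.data.shape[0]

    @property
    def n_volumes(self) -> int:
        return self.data.shape[1]


def module_assignments(n_rois: int, n_modules: int) -> np.ndarray:
    """Contiguous, near-equal-size module labels for each ROI (0-based)."""
    sizes = np.full(n_modules, n_rois // n_modules)
    sizes[: n_rois % n_modules] += 1
    return np.repeat(np.arange(n_modules), sizes)


def active_rois(n_rois: int, n_modules: int) -> np.ndarray:
    """Task-responsive ROI indices: the first ROI of each module."""
    modules = module_assignments(n_rois, n_modules)
    return np.array([int(np.argmax(modules == m)) for m in range(n_modules)])


def _repair_psd(corr: np.ndarray, floor: float = 1e-8) -> np.ndarray:
    """Clip eigenvalues at `floor` and rescale to unit diagonal."""
    vals, vecs = np.linalg.eigh(corr)
    if vals.min() >= floor:
        return corr
    warnings.warn(
        "perturbed correlation matrix is not positive semidefinite; "
        "repairing by eigenvalue clipping",
        stacklevel=3,
    )
    vals = np.clip(vals, floor, None)
    fixed = (vecs * vals) @ vecs.T
    d = np.sqrt(np.diag(fixed))
    fixed = fixed / np.outer(d, d)
    np.fill_diagonal(fixed, 1.0)
    vmin = np.linalg.eigvalsh(fixed).min()
    if vmin < -1e-10:
        raise ValueError("covariance repair failed")
    return fixed


def target_correlation(
    spec: SyntheticCohortSpec, group: str, session: str
) -> np.ndarray:
    """The ROI correlation matrix the correlated-noise process targets.

    Within-module entries take `within_module_r` (plus `delta_within_r`
    when the group/session match the spec's group_effect); between-module
    entries take `between_module_r`; unit diagonal.  Repaired to PSD by
    eigenvalue clipping if the perturbation breaks it.
    """
    modules = module_assignments(spec.n_rois, spec.n_modules)
    same = modules[:, None] == modules[None, :]
    corr = np.where(same, spec.within_module_r, spec.between_module_r).astype(float)
    eff = spec.group_effect
    if group == eff.group and session == eff.session and eff.delta_within_r != 0:
        corr[same] += eff.delta_within_r
    np.fill_diagonal(corr, 1.0)
    if np.any(np.abs(corr[~np.eye(spec.n_rois, dtype=bool)]) >= 1):
        raise ValueError("perturbed correlations leave (-1, 1)")
    return _repair_psd(corr)


def _task_regressor(schedule: StimulusSchedule, include_dummies: bool) -> np.ndarray:
    # HRF-convolved task boxcar over the full run; imported lazily to keep
    # module load order simple.
    from .glm import convolved_regressor

    reg = convolved_regressor(schedule, "task", drop_dummies=False)
    return reg if include_dummies else reg[schedule.n_dummy :]


def simulate_subject_timeseries(
    spec: SyntheticCohortSpec,
    schedule: StimulusSchedule,
    group: str,
    session: str,
    subject_seed: int,
    subject_id: str | None = None,
    roi_labels: Sequence[str] | None = None,
    _chol: np.ndarray | None = None,
) -> RoiTimeSeriesSet:
    """Draw one subject-session: task signal + correlated + white noise.

    The full run (dummy volumes included) is simulated, then the first
    ``schedule.n_dummy`` volumes are discarded, so downstream stages never
    see the pre-steady-state period.
    """
    if group not in GROUPS or session not in SESSIONS:
        raise ValueError(f"group/session must be in {GROUPS} x {SESSIONS}")
    rng = np.random.default_rng(subject_seed)
    if _chol is None:
        _chol = np.linalg.cholesky(
            target_correlation(spec, group, session) + 1e-10 * np.eye(spec.n_rois)
        )
    n_vol = schedule.n_volumes
    data = _chol @ rng.standard_normal((spec.n_rois, n_vol))
    if spec.noise_sd > 0:
        data += spec.noise_sd * rng.standard_normal((spec.n_rois, n_vol))
    if spec.activation_amplitude != 0:
        task = _task_regressor(schedule, include_dummies=True)
        data[active_rois(spec.n_rois, spec.n_modules)] += (
            spec.activation_amplitude * task
        )
    data = data[:, schedule.n_dummy :]
    if roi_labels is None:
        roi_labels = (
            aal_labels()
            if spec.n_rois == 90
            else tuple(f"ROI_{i + 1:03d}" for i in range(spec.n_rois))
        )
    return RoiTimeSeriesSet(
        subject_id=subject_id or f"{group}_{subject_seed}",
        group=group,
        session=session,
        data=data,
        tr_s=schedule.tr_s,
        roi_labels=tuple(roi_labels),
    )


def subject_seed(cohort_seed: int, group: str, session: str, index: int) -> int:
    """Deterministic per-subject-session seed.

    Derived with numpy's SeedSequence from (cohort seed, group index,
    session index, subject index) so subjects are independent but the whole
    cohort is reproducible from one integer.
    """
    ss = np.random.SeedSequence(
        [int(cohort_seed), GROUPS.index(group), SESSIONS.index(session), int(index)]
    )
    return int(ss.generate_state(1, dtype=np.uint32)[0]) % (2**31)


def simulate_behavior(spec: SyntheticCohortSpec) -> pd.DataFrame:
    """Behavioral table: reading and Raven scores, normal per group."""
    rng = np.random.default_rng(
        np.random.SeedSequence([int(spec.seed), 7_654_321]).generate_state(1)
    )
    rows = []
    for group in GROUPS:
        bp = spec.behavior[group]
        reading = rng.normal(bp.reading_mean, bp.reading_sd, spec.n_per_group)
        raven = rng.normal(bp.raven_mean, bp.raven_sd, spec.n_per_group)
        for i in range(spec.n_per_group):
            rows.append(
                {
                    "subject_id": f"{group}{i + 1:03d}",
                    "group": group,
                    "reading_score": reading[i],
                    "raven_score": raven[i],
                }
            )
    return pd.DataFrame(rows)


def simulate_cohort(
    spec: SyntheticCohortSpec, schedule: StimulusSchedule | None = None
) -> tuple[list[RoiTimeSeriesSet], pd.DataFrame]:
    """Generate the full cohort: 2 groups x n_per_group x 2 sessions.

    Returns the time-series sets (group-major, subject-major, session-minor
    order) and the behavioral table.
    """
    if schedule is None:
        schedule = make_block_design()
    if spec.n_rois == 90:
        labels = aal_labels()
    else:
        labels = tuple(f"ROI_{i + 1:03d}" for i in range(spec.n_rois))
    sets: list[RoiTimeSeriesSet] = []
    for group in GROUPS:
        for i in range(spec.n_per_group):
            for session in SESSIONS:
                chol = _cohort_chol(spec, group, session)
                sets.append(
                    simulate_subject_timeseries(
                        spec,
                        schedule,
                        group,
                        session,
                        subject_seed(spec.seed, group, session, i),
                        subject_id=f"{group}{i + 1:03d}",
                        roi_labels=labels,
                        _chol=chol,
                    )
                )
    return sets, simulate_behavior(spec)


_CHOL_CACHE: dict[tuple, np.ndarray] = {}


def _cohort_chol(spec: SyntheticCohortSpec, group: str, session: str) -> np.ndarray:
    key = (
        spec.n_rois,
        spec.n_modules,
        spec.within_module_r,
        spec.between_module_r,
        spec.group_effect,
        group,
        session,
    )
    if key not in _CHOL_CACHE:
        if len(_CHOL_CACHE) > 64:
            _CHOL_CACHE.clear()
        _CHOL_CACHE[key] = np.linalg.cholesky(
            target_correlation(spec, group, session) + 1e-10 * np.eye(spec.n_rois)
        )
    return _CHOL_CACHE[key]


def null_spec(spec: SyntheticCohortSpec | None = None, **overrides) -> SyntheticCohortSpec:
    """A copy of `spec` (default spec if None) with the group effect zeroed."""
    base = spec or SyntheticCohortSpec()
    return replace(
        base, group_effect=replace(base.group_effect, delta_within_r=0.0), **overrides
    )
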