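"""Monte-Carlo calibration experiments for the group-comparison pipeline.

Two reusable experiments: a type-I-error / t-distribution calibration of
the full simulate -> correlate -> threshold -> metric -> t-test chain under
a null generator (no group effect), and a session-specific detection
(power) experiment under the injected within-module-correlation effect.
Both run the real pipeline stages end to end on each simulated cohort.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .pipeline import cohort_connectivity, cohort_metric_table
from .stats import compare_global_metrics
from .synthetic import SyntheticCohortSpec, make_block_design, null_spec, simulate_cohort

__all__ = ["TypeOneResult", "type_one_error_experiment",
           "DetectionResult", "session_detection_experiment"]

#: Metrics used in calibration runs: the non-normalized global metrics,
#: whose null distributions need no rewired reference networks.
CALIBRATION_METRICS = ("Cp", "Lp", "E_glob", "E_loc")


@dataclass(frozen=True)
class TypeOneResult:
    t_values: np.ndarray  # pooled over cohorts and metrics
    df: int
    rejection_rate: float  # fraction of uncorrected-significant rows
    ks_statistic: float  # empirical t distribution vs Student(df)
    n_cohorts: int


def type_one_error_experiment(
    n_cohorts: int = 200,
    n_per_group: int = 16,
    sparsity: float = 0.10,
    alpha: float = 0.05,
    seed: int = 0,
    metrics: tuple[str, ...] = CALIBRATION_METRICS,
) -> TypeOneResult:
    """Null calibration: group-effect-free cohorts through the full chain.

    Each cohort is simulated with the group effect zeroed, carried through
    connectivity, thresholding at a single sparsity, and the global-metric
    two-sample t-tests.  Reported: the pooled t-values across cohorts and
    metrics, the uncorrected rejection fraction at `alpha`, and the
    Kolmogorov-Smirnov distance to Student's t with 2*n_per_group - 2 df.
    """
    schedule = make_block_design()
    cohort_seeds = np.random.SeedSequence([seed, 101]).generate_state(n_cohorts)
    t_all: list[np.ndarray] = []
    reject: list[np.ndarray] = []
    for k in range(n_cohorts):
        spec = null_spec(
            SyntheticCohortSpec(n_per_group=n_per_group, seed=int(cohort_seeds[k]) % (2**31))
        )
        sets, _ = simulate_cohort(spec, schedule)
        zmats = cohort_connectivity(sets)
        table = cohort_metric_table(zmats, [sparsity], metrics_wanted=metrics)
        cmp_table = compare_global_metrics(table, metrics=metrics, alpha=alpha)
        t_all.append(cmp_table["t"].to_numpy())
        reject.append(cmp_table["significant_uncorrected"].to_numpy())
    t_values = np.concatenate(t_all)
    df = 2 * n_per_group - 2
    ks = sps.kstest(t_values, sps.t(df).cdf).statistic
    return TypeOneResult(
        t_values=t_values,
        df=df,
        rejection_rate=float(np.concatenate(reject).mean()),
        ks_statistic=float(ks),
        n_cohorts=n_cohorts,
    )


@dataclass(frozen=True)
class DetectionResult:
    orthographic_rate: float  # replicates with a corrected-significant Cp row
    phonological_rate: float  # ditto in the unaffected session (false alarms)
    joint_success_rate: float  # detect in orthographic AND clean phonological
    n_replicates: int
    per_replicate: pd.DataFrame


def session_detection_experiment(
    n_replicates: int = 100,
    n_per_group: int = 16,
    delta_within_r: float = 0.15,
    alpha: float = 0.05,
    seed: int = 0,
) -> DetectionResult:
    """Power experiment for the session-specific clustering difference.

    The generator injects `delta_within_r` into the poor group's
    orthographic session only; each replicate runs the full ladder
    (10 sparsities) and asks whether any Cp row is Bonferroni-significant
    per session (family = ladder length).  The headline pattern is
    detection in the orthographic session with a clean phonological
    session.
    """
    schedule = make_block_design()
    rep_seeds = np.random.SeedSequence([seed, 202]).generate_state(n_replicates)
    rows = []
    for k in range(n_replicates):
        base = SyntheticCohortSpec(n_per_group=n_per_group, seed=int(rep_seeds[k]) % (2**31))
        spec = dataclasses.replace(
            base,
            group_effect=dataclasses.replace(
                base.group_effect, delta_within_r=delta_within_r
            ),
        )
        sets, _ = simulate_cohort(spec, schedule)
        zmats = cohort_connectivity(sets)
        table = cohort_metric_table(zmats, _ladder(), metrics_wanted=("Cp",))
        cmp_table = compare_global_metrics(table, metrics=("Cp",), alpha=alpha)
        sig = cmp_table[cmp_table["significant_bonferroni"]]
        rows.append(
            {
                "replicate": k,
                "orthographic_hit": bool((sig["session"] == "orthographic").any()),
                "phonological_hit": bool((sig["session"] == "phonological").any()),
            }
        )
    per = pd.DataFrame(rows)
    orth = per["orthographic_hit"].mean()
    phon = per["phonological_hit"].mean()
    joint = (per["orthographic_hit"] & ~per["phonological_hit"]).mean()
    return DetectionResult(
        orthographic_rate=float(orth),
        phonological_rate=float(phon),
        joint_success_rate=float(joint),
        n_replicates=n_replicates,
        per_replicate=per,
    )


def _ladder() -> list[float]:
    from .connectivity import default_sparsities

    return default_sparsities()
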