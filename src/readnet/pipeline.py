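"""End-to-end orchestration: simulate/load -> GLM -> networks -> metrics
-> group comparisons, from a single validated config.

Every stage writes its artifacts under the output directory so stages can
be re-run independently, and a fixed (config, seed) pair reproduces
byte-identical tables.
"""

from __future__ import annotations

import dataclasses
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from . import glm, io, metrics, stats
from .connectivity import (
    default_sparsities,
    roi_correlation_matrix,
    threshold_by_sparsity,
)
from .synthetic import (
    GROUPS,
    SESSIONS,
    RoiTimeSeriesSet,
    StimulusSchedule,
    SyntheticCohortSpec,
    make_block_design,
    simulate_cohort,
)

logger = logging.getLogger("readnet")

__all__ = [
    "PipelineConfig",
    "run_pipeline",
    "cohort_connectivity",
    "cohort_metric_table",
    "cohort_nodal_table",
    "cohort_glm_effects",
    "plot_metric_vs_sparsity",
]


@dataclass(frozen=True)
class PipelineConfig:
    """Resolved configuration for a full pipeline run."""

    simulate: SyntheticCohortSpec | None = field(
        default_factory=SyntheticCohortSpec
    )
    manifest: str | None = None  # alternative to simulate
    sparsity_min: float = 0.05
    sparsity_max: float = 0.50
    sparsity_step: float = 0.05
    nodal_sparsity: float = 0.05
    n_null: int = 100
    alpha: float = 0.05
    group_order: tuple[str, str] = ("good", "poor")
    seed: int = 0
    run_glm: bool = True
    global_signal_in_glm: bool = True
    task_blocks_only: bool = False

    def __post_init__(self) -> None:
        if (self.simulate is None) == (self.manifest is None):
            raise ValueError("exactly one of simulate/manifest must be set")
        default_sparsities(self.sparsity_min, self.sparsity_max, self.sparsity_step)
        if not 0 < self.nodal_sparsity <= 1:
            raise ValueError("nodal_sparsity must be in (0, 1]")
        if self.n_null < 0:
            raise ValueError("n_null must be >= 0")
        if not 0 < self.alpha <= 1:
            raise ValueError("alpha must be in (0, 1]")
        if tuple(sorted(self.group_order)) != tuple(sorted(GROUPS)):
            raise ValueError(f"group_order must be a permutation of {GROUPS}")

    @property
    def sparsities(self) -> list[float]:
        return default_sparsities(
            self.sparsity_min, self.sparsity_max, self.sparsity_step
        )

    def to_yaml(self, path: Path | str) -> None:
        payload = dataclasses.asdict(self)
        if self.simulate is not None:
            payload["simulate"]["behavior"] = {
                g: dataclasses.asdict(bp) for g, bp in self.simulate.behavior.items()
            }
        with open(path, "w") as fh:
            yaml.safe_dump(payload, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path: Path | str) -> "PipelineConfig":
        from .synthetic import BehaviorParams, GroupEffect

        with open(path) as fh:
            payload = yaml.safe_load(fh)
        sim = payload.get("simulate")
        if sim is not None:
            if "group_effect" in sim and sim["group_effect"] is not None:
                sim["group_effect"] = GroupEffect(**sim["group_effect"])
            if "behavior" in sim and sim["behavior"] is not None:
                sim["behavior"] = {
                    g: BehaviorParams(**bp) for g, bp in sim["behavior"].items()
                }
            payload["simulate"] = SyntheticCohortSpec(**sim)
        if "group_order" in payload:
            payload["group_order"] = tuple(payload["group_order"])
        return cls(**payload)


def cohort_connectivity(
    ts_sets: Sequence[RoiTimeSeriesSet],
    task_blocks_only: bool = False,
    schedule: StimulusSchedule | None = None,
):
    """Fisher-z connectivity per subject-session.

    With `task_blocks_only`, correlations are restricted to volumes
    acquired inside task blocks (requires the schedule).
    """
    volumes = None
    if task_blocks_only:
        if schedule is None:
            raise ValueError("task_blocks_only requires the stimulus schedule")
        volumes = schedule.analyzed_volume_mask("task")
    return [roi_correlation_matrix(ts, volumes=volumes) for ts in ts_sets]


def cohort_metric_table(
    z_matrices,
    sparsities: Sequence[float],
    n_null: int = 0,
    seed: int | None = None,
    metrics_wanted: tuple[str, ...] | None = None,
) -> pd.DataFrame:
    """Long table: one row per subject-session-sparsity of global metrics."""
    rows = []
    ss = np.random.SeedSequence(seed)
    for zc, child in zip(z_matrices, ss.spawn(len(z_matrices))):
        net_seeds = child.generate_state(len(sparsities), dtype=np.uint32)
        for s, net_seed in zip(sparsities, net_seeds):
            net = threshold_by_sparsity(zc, s)
            row = {
                "subject_id": zc.subject_id,
                "group": zc.group,
                "session": zc.session,
                "sparsity": s,
            }
            row.update(
                metrics.compute_global_metrics(
                    net, n_null=n_null, seed=int(net_seed), metrics=metrics_wanted
                )
            )
            rows.append(row)
    return pd.DataFrame(rows)


def cohort_nodal_table(z_matrices, sparsity: float) -> pd.DataFrame:
    """Long nodal table (degree, betweenness) at a single sparsity."""
    rows = []
    for zc in z_matrices:
        net = threshold_by_sparsity(zc, sparsity)
        nodal = metrics.compute_nodal_metrics(net)
        for k, node in enumerate(net.node_labels):
            rows.append(
                {
                    "subject_id": zc.subject_id,
                    "group": zc.group,
                    "session": zc.session,
                    "sparsity": sparsity,
                    "node": node,
                    "degree": int(nodal["degree"][k]),
                    "betweenness": float(nodal["betweenness"][k]),
                }
            )
    return pd.DataFrame(rows)


def isolated_node_counts(z_matrices, sparsity: float) -> pd.DataFrame:
    """Per subject-session count of degree-0 nodes at one sparsity.

    Surfaced because at the sparsest threshold some nodes are typically
    disconnected, which qualifies any nodal comparison run there.
    """
    rows = []
    for zc in z_matrices:
        net = threshold_by_sparsity(zc, sparsity)
        rows.append(
            {
                "subject_id": zc.subject_id,
                "session": zc.session,
                "sparsity": sparsity,
                "isolated_nodes": int((net.degree == 0).sum()),
            }
        )
    return pd.DataFrame(rows)


def cohort_glm_effects(
    ts_sets: Sequence[RoiTimeSeriesSet],
    schedule: StimulusSchedule,
    global_signal: bool = True,
    contrast: dict[str, float] | None = None,
) -> dict[str, dict[str, pd.DataFrame]]:
    """Per-session, per-group [n_subjects x n_rois] contrast-effect frames.

    The default contrast is task vs implicit fixation baseline
    ({"task": 1}).  The global-signal regressor is ON here by default (it
    belongs to the activation analysis, not to network construction).
    """
    contrast = contrast or {"task": 1.0}
    out: dict[str, dict[str, pd.DataFrame]] = {}
    for session in SESSIONS:
        out[session] = {}
        for group in GROUPS:
            members = [
                ts for ts in ts_sets if ts.session == session and ts.group == group
            ]
            if not members:
                continue
            effects = {}
            for ts in members:
                if global_signal:
                    design = glm.build_design_matrix(
                        schedule,
                        nuisance=glm.global_signal_regressor(ts)[:, None],
                        nuisance_names=("global_signal",),
                    )
                else:
                    design = glm.build_design_matrix(schedule)
                fit = glm.fit_glm(ts, design)
                result = glm.contrast_t(fit, design, contrast)
                effects[ts.subject_id] = result["effect"].to_numpy()
            frame = pd.DataFrame.from_dict(
                effects, orient="index", columns=list(members[0].roi_labels)
            )
            out[session][group] = frame
    return out


def run_pipeline(config: PipelineConfig, outdir: Path | str) -> Path:
    """Run every stage and write all artifacts under `outdir`.

    Artifacts: resolved config, cohort TSVs (simulate mode), per-subject
    z-matrices, metrics.tsv, nodal.tsv, comparison tables, isolated-node
    counts, behavioral comparison (simulate mode), and run.log.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log_path = outdir / "run.log"
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    try:
        config.to_yaml(outdir / "config_resolved.yaml")
        import networkx
        import scipy

        from . import __version__

        logger.info(
            "readnet %s | numpy %s scipy %s pandas %s networkx %s",
            __version__, np.__version__, scipy.__version__, pd.__version__,
            networkx.__version__,
        )
        logger.info("seed=%s sparsities=%s n_null=%s", config.seed, config.sparsities,
                    config.n_null)
        schedule = make_block_design()
        behavior = None
        if config.simulate is not None:
            stage = "simulate"
            spec = dataclasses.replace(config.simulate, seed=config.seed)
            ts_sets, behavior = simulate_cohort(spec, schedule)
            io.write_cohort(ts_sets, behavior, outdir / "cohort")
            logger.info("simulated %d subject-sessions", len(ts_sets))
        else:
            stage = "load"
            ts_sets = io.read_timeseries_manifest(config.manifest)
            logger.info("loaded %d subject-sessions", len(ts_sets))

        if config.run_glm:
            stage = "glm"
            effects = cohort_glm_effects(
                ts_sets, schedule, global_signal=config.global_signal_in_glm
            )
            for session in effects:
                groups = effects[session]
                if len(groups) == 2:
                    a = groups[config.group_order[0]]
                    b = groups[config.group_order[1]]
                    table = glm.group_activation_ttest(a, b, alpha=config.alpha)
                    io.write_comparison_table(
                        table,
                        outdir / f"activation_comparison_{session}.tsv",
                        {"group_order": ",".join(config.group_order),
                         "alpha": config.alpha, "session": session},
                    )
            logger.info("glm stage complete")

        stage = "connectivity"
        zmats = cohort_connectivity(
            ts_sets, task_blocks_only=config.task_blocks_only, schedule=schedule
        )
        conndir = outdir / "connectivity"
        conndir.mkdir(exist_ok=True)
        for zc in zmats:
            io.write_z_matrix(zc, conndir / f"{zc.subject_id}_{zc.session}_z.tsv")
        logger.info("wrote %d connectivity matrices", len(zmats))

        stage = "metrics"
        metric_table = cohort_metric_table(
            zmats, config.sparsities, n_null=config.n_null, seed=config.seed
        )
        metric_table.to_csv(
            outdir / "metrics.tsv", sep="\t", index=False, float_format=io.FLOAT_FMT
        )
        nodal_table = cohort_nodal_table(zmats, config.nodal_sparsity)
        nodal_table.to_csv(
            outdir / "nodal.tsv", sep="\t", index=False, float_format=io.FLOAT_FMT
        )
        isolated_node_counts(zmats, config.nodal_sparsity).to_csv(
            outdir / "isolated_nodes.tsv", sep="\t", index=False
        )
        logger.info("metrics stage complete (%d rows)", len(metric_table))

        stage = "compare"
        global_cmp = stats.compare_global_metrics(
            metric_table, group_order=config.group_order, alpha=config.alpha
        )
        io.write_comparison_table(global_cmp, outdir / "global_comparison.tsv")
        nodal_cmp = stats.compare_nodal(
            nodal_table, group_order=config.group_order, alpha=config.alpha
        )
        io.write_comparison_table(nodal_cmp, outdir / "nodal_comparison.tsv")
        if behavior is not None:
            behav_cmp = stats.compare_behavior(
                behavior, group_order=config.group_order, alpha=config.alpha
            )
            io.write_comparison_table(behav_cmp, outdir / "behavior_comparison.tsv")
        logger.info("comparison stage complete")

        stage = "report"
        _write_report(outdir, config, metric_table, global_cmp, nodal_cmp)
    except Exception as exc:
        logger.exception("pipeline failed in stage %r", stage)
        raise RuntimeError(f"pipeline failed in stage {stage!r}: {exc}") from exc
    finally:
        logger.removeHandler(handler)
        handler.close()
    return outdir


def _write_report(outdir, config, metric_table, global_cmp, nodal_cmp) -> None:
    lines = ["readnet pipeline summary", "=" * 30]
    lines.append(f"seed: {config.seed}")
    n_ss = len(metric_table[["subject_id", "session"]].drop_duplicates())
    lines.append(f"subject-sessions: {n_ss}")
    lines.append(f"metric rows: {len(metric_table)}")
    sig = global_cmp[global_cmp["significant_bonferroni"]]
    lines.append(f"Bonferroni-significant global rows: {len(sig)}")
    for _, row in sig.iterrows():
        lines.append(
            f"  {row['target']} @ session={row['session']} "
            f"sparsity={row['sparsity']:.2f}: t={row['t']:.3f} p={row['p']:.4g}"
        )
    nsig = nodal_cmp[nodal_cmp["significant_bonferroni"]]
    lines.append(f"Bonferroni-significant nodal rows: {len(nsig)}")
    (outdir / "report.txt").write_text("\n".join(lines) + "\n")


def plot_metric_vs_sparsity(
    metric_table: pd.DataFrame, metric: str, session: str, path: Path | str
) -> None:
    """Group-mean metric-vs-sparsity line plot with SD band."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 3.5))
    sess = metric_table[metric_table["session"] == session]
    for group in GROUPS:
        sub = sess[sess["group"] == group]
        agg = sub.groupby("sparsity")[metric].agg(["mean", "std"])
        ax.plot(agg.index, agg["mean"], marker="o", label=group)
        ax.fill_between(
            agg.index, agg["mean"] - agg["std"], agg["mean"] + agg["std"], alpha=0.2
        )
    ax.set_xlabel("sparsity")
    ax.set_ylabel(metric)
    ax.set_title(f"{metric} ({session})")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
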