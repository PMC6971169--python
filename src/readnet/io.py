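"""Text-based I/O: time-series TSVs, manifests, matrices and stat tables.

All tabular artifacts are plain TSV/CSV so runs diff cleanly and tables
round-trip byte-identically under a fixed seed.  Comparison tables carry a
commented header block recording group ordering, alpha and family sizes.
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .connectivity import ZConnectivityMatrix
from .synthetic import GROUPS, SESSIONS, RoiTimeSeriesSet, aal_labels

__all__ = [
    "write_timeseries_tsv",
    "read_timeseries_tsv",
    "write_cohort",
    "read_timeseries_manifest",
    "write_matrix_tsv",
    "read_matrix_tsv",
    "write_comparison_table",
    "write_edge_list",
    "extract_roi_timeseries",
]

FLOAT_FMT = "%.10g"


def write_timeseries_tsv(ts: RoiTimeSeriesSet, path: Path | str) -> None:
    """One row per ROI (index = label), one column per volume."""
    frame = pd.DataFrame(
        ts.data,
        index=list(ts.roi_labels),
        columns=[f"vol_{i:03d}" for i in range(ts.n_volumes)],
    )
    frame.index.name = "roi"
    frame.to_csv(path, sep="\t", float_format=FLOAT_FMT)


def read_timeseries_tsv(
    path: Path | str,
    subject_id: str,
    group: str,
    session: str,
    tr_s: float,
    expected_labels: Sequence[str] | None = None,
) -> RoiTimeSeriesSet:
    frame = pd.read_csv(path, sep="\t", index_col=0)
    labels = tuple(frame.index)
    if expected_labels is not None and labels != tuple(expected_labels):
        raise ValueError(
            f"{path}: has {len(labels)} ROI rows; expected the "
            f"{len(tuple(expected_labels))} packaged atlas labels in order"
        )
    return RoiTimeSeriesSet(
        subject_id=subject_id,
        group=group,
        session=session,
        data=frame.to_numpy(float),
        tr_s=tr_s,
        roi_labels=labels,
    )


def write_cohort(
    ts_sets: Sequence[RoiTimeSeriesSet],
    behavior: pd.DataFrame,
    outdir: Path | str,
) -> Path:
    """Write per-subject TSVs plus manifest.csv and behavior.csv."""
    outdir = Path(outdir)
    tsdir = outdir / "timeseries"
    tsdir.mkdir(parents=True, exist_ok=True)
    rows = []
    for ts in ts_sets:
        fname = f"{ts.subject_id}_{ts.session}.tsv"
        write_timeseries_tsv(ts, tsdir / fname)
        rows.append(
            {
                "subject_id": ts.subject_id,
                "group": ts.group,
                "session": ts.session,
                "file": f"timeseries/{fname}",
                "tr_s": ts.tr_s,
            }
        )
    pd.DataFrame(rows).to_csv(outdir / "manifest.csv", index=False)
    behavior.to_csv(outdir / "behavior.csv", index=False, float_format=FLOAT_FMT)
    return outdir / "manifest.csv"


def read_timeseries_manifest(
    path: Path | str, expected_n_rois: int | None = 90
) -> list[RoiTimeSeriesSet]:
    """Load a cohort from a manifest CSV (subject_id, group, session, file).

    Shapes are validated against the packaged 90-label AAL list when
    `expected_n_rois` is 90 (set None to accept any parcellation).
    Errors name the offending manifest row.
    """
    path = Path(path)
    manifest = pd.read_csv(path)
    required = {"subject_id", "group", "session", "file"}
    if missing := required - set(manifest.columns):
        raise ValueError(f"manifest missing column(s) {sorted(missing)}")
    if manifest.empty:
        raise ValueError("no subjects in manifest")
    expected_labels = (
        aal_labels() if expected_n_rois == 90 else None
    )
    seen: set[tuple[str, str]] = set()
    out = []
    for idx, row in manifest.iterrows():
        where = f"manifest row {idx + 1}"
        if row["group"] not in GROUPS:
            raise ValueError(f"{where}: unknown group {row['group']!r}")
        if row["session"] not in SESSIONS:
            raise ValueError(f"{where}: unknown session {row['session']!r}")
        key = (row["subject_id"], row["session"])
        if key in seen:
            raise ValueError(f"{where}: duplicate subject/session {key}")
        seen.add(key)
        fpath = path.parent / row["file"]
        if not fpath.exists():
            raise FileNotFoundError(f"{where}: file not found: {fpath}")
        try:
            ts = read_timeseries_tsv(
                fpath,
                subject_id=row["subject_id"],
                group=row["group"],
                session=row["session"],
                tr_s=float(row.get("tr_s", 2.0)),
                expected_labels=expected_labels,
            )
        except ValueError as err:
            raise ValueError(f"{where}: {err}") from err
        if expected_n_rois is not None and ts.n_rois != expected_n_rois:
            raise ValueError(
                f"{where}: {fpath} has {ts.n_rois} rows, expected {expected_n_rois}"
            )
        out.append(ts)
    return out


def write_matrix_tsv(
    matrix: np.ndarray, labels: Sequence[str], path: Path | str
) -> None:
    frame = pd.DataFrame(matrix, index=list(labels), columns=list(labels))
    frame.index.name = "roi"
    frame.to_csv(path, sep="\t", float_format=FLOAT_FMT)


def read_matrix_tsv(path: Path | str) -> tuple[np.ndarray, tuple[str, ...]]:
    frame = pd.read_csv(path, sep="\t", index_col=0)
    return frame.to_numpy(float), tuple(frame.index)


def write_z_matrix(zc: ZConnectivityMatrix, path: Path | str) -> None:
    write_matrix_tsv(zc.z, zc.roi_labels, path)


def write_comparison_table(
    table: pd.DataFrame, path: Path | str, extra_meta: dict | None = None
) -> None:
    """TSV with a '#'-commented header recording the table's conventions."""
    meta = {
        "group_order": ",".join(table.attrs.get("group_order", ())),
        "alpha": table.attrs.get("alpha", ""),
        "sign_convention": "t = mean_a - mean_b over group_order",
    }
    meta.update(extra_meta or {})
    with open(path, "w") as fh:
        for key, val in meta.items():
            fh.write(f"# {key}: {val}\n")
        table.to_csv(fh, sep="\t", index=False, float_format=FLOAT_FMT)


def write_edge_list(net, path: Path | str, labeled: bool = True) -> None:
    """Edge list (node_i <tab> node_j), by label or 0-based index."""
    with open(path, "w") as fh:
        for i, j in net.edge_list():
            if labeled:
                fh.write(f"{net.node_labels[i]}\t{net.node_labels[j]}\n")
            else:
                fh.write(f"{i}\t{j}\n")


def write_viewer_files(net, prefix: Path | str) -> tuple[Path, Path]:
    """Plain-text node/edge files in the layout brain-surface viewers read.

    `<prefix>.edge` is the dense N x N adjacency, tab-separated, no
    header; `<prefix>.node` has one row per node: x, y, z, size, color,
    label.  No parcel coordinates ship with this package, so x/y/z are
    written as zeros (viewers substitute their own atlas coordinates);
    size encodes degree and color is constant.
    """
    prefix = Path(prefix)
    edge_path = prefix.with_suffix(".edge")
    node_path = prefix.with_suffix(".node")
    np.savetxt(edge_path, net.adjacency, fmt="%d", delimiter="\t")
    degree = net.degree
    with open(node_path, "w") as fh:
        for label, k in zip(net.node_labels, degree):
            fh.write(f"0\t0\t0\t{int(k)}\t1\t{label}\n")
    return node_path, edge_path


def extract_roi_timeseries(
    nifti_path: Path | str,
    atlas_path: Path | str,
    subject_id: str,
    group: str,
    session: str,
    tr_s: float,
    labels: Sequence[str] | None = None,
) -> RoiTimeSeriesSet:
    """Mean signal per labeled parcel from a 4-D NIfTI (import utility).

    Atlas voxels labeled 1..K define the parcels; label k maps to row
    k-1.  Requires nibabel; real scanner data never ships with this
    package, so this path is exercised only on synthetic volumes.
    """
    import nibabel as nib

    img = np.asanyarray(nib.load(str(nifti_path)).dataobj, dtype=float)
    atlas = np.asanyarray(nib.load(str(atlas_path)).dataobj)
    atlas = np.rint(atlas).astype(int)
    if img.ndim != 4:
        raise ValueError("expected a 4-D functional image")
    if atlas.shape != img.shape[:3]:
        raise ValueError("atlas and functional image grids differ")
    n_rois = int(atlas.max())
    if n_rois < 1:
        raise ValueError("atlas contains no labeled parcels")
    data = np.empty((n_rois, img.shape[3]))
    flat = img.reshape(-1, img.shape[3])
    aflat = atlas.ravel()
    for k in range(1, n_rois + 1):
        sel = aflat == k
        if not sel.any():
            raise ValueError(f"atlas label {k} has no voxels")
        data[k - 1] = flat[sel].mean(axis=0)
    if labels is None:
        labels = tuple(f"ROI_{i + 1:03d}" for i in range(n_rois))
    return RoiTimeSeriesSet(
        subject_id=subject_id,
        group=group,
        session=session,
        data=data,
        tr_s=tr_s,
        roi_labels=tuple(labels),
    )
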