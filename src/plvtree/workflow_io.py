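"""File formats, configuration and the end-to-end analysis driver.

Everything on disk is inspectable text: epochs, matrices, trees and metric
tables are tab-separated values with labelled headers; configuration,
provenance and cohort manifests are JSON.  SNIRF (HDF5) continuous input is
supported read-only.

``run_pipeline`` chains the full analysis for a cohort on disk: per-subject
tPLV matrix and spanning tree, per-group group tree and occurrence table,
cohort-level statistics and reference-tree overlap, plus a provenance
record.  With a fixed seed and config the outputs are byte-identical across
reruns.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .connectivity import (
    BASELINE_WINDOW,
    POST_WINDOW,
    ConnectivityMatrix,
    analytic_signal,
    gplv,
    normalize_plv,
    plv,
    tplv_matrix,
)
from .graph_metrics import (
    GLOBAL_METRIC_NAMES,
    global_metrics,
    occurrence,
    overlap,
)
from .group_stats import CONTROL, PATIENT, SubjectRecord, clinical_table, group_table
from .mst import TreeGraph, group_tree, kruskal_max_tree
from .preprocess import ContinuousRecording, EpochSet, EpochWindow

logger = logging.getLogger(__name__)

_FLOAT_FMT = "%.12g"


@dataclass
class RunConfig:
    """Pipeline parameters; defaults are the reference analysis settings.

    Band edges 0.01-0.15 Hz; 2/4/12/2-s epoch geometry; [-4, -1) s baseline;
    [0, 12) s post-stimulus averaging; 25% occurrence display threshold.
    """

    input_dir: str | Path = "."
    out_dir: str | Path = "results"
    band: tuple[float, float] = (0.01, 0.15)
    filter_order: int = 4
    window: EpochWindow = field(default_factory=EpochWindow)
    baseline: tuple[float, float] = BASELINE_WINDOW
    post: tuple[float, float] = POST_WINDOW
    occurrence_threshold: float = 0.25
    ecc_variant: str = "range"
    group_mst: bool = True
    seed: int = 0

    def to_json(self) -> dict:
        d = asdict(self)
        d["input_dir"] = str(self.input_dir)
        d["out_dir"] = str(self.out_dir)
        return d


# ---------------------------------------------------------------------------
# epoch files


def write_epochs(path: str | Path, epochs: EpochSet) -> None:
    """Write an EpochSet as TSV: header comments + (trial, sample) rows."""
    path = Path(path)
    win = epochs.window
    with open(path, "w") as fh:
        fh.write(f"# fs={epochs.fs!r}\n")
        fh.write(f"# margin={win.margin!r} pre={win.pre!r} post={win.post!r}\n")
        cols = "\t".join(["trial", "sample"] + list(epochs.channel_labels))
        fh.write(cols + "\n")
        for trial in range(epochs.n_trials):
            block = epochs.data[trial].T  # (sample, channel)
            for s in range(block.shape[0]):
                row = "\t".join(_FLOAT_FMT % v for v in block[s])
                fh.write(f"{trial}\t{s}\t{row}\n")


def read_epochs(path: str | Path) -> EpochSet:
    path = Path(path)
    meta: dict[str, float] = {}
    header = None
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                header = line.rstrip("\n").split("\t")
                break
            for token in line[1:].split():
                key, _, value = token.partition("=")
                meta[key] = float(value)
    if header is None:
        raise ValueError("epoch file has no header row")
    raw_labels = [c for c in header if c not in ("trial", "sample")]
    if len(set(raw_labels)) != len(raw_labels):
        dupes = sorted({c for c in raw_labels if raw_labels.count(c) > 1})
        raise ValueError(f"duplicate channel labels in header: {dupes}")
    frame = pd.read_csv(path, sep="\t", comment="#")
    labels = [c for c in frame.columns if c not in ("trial", "sample")]
    win = EpochWindow(margin=meta["margin"], pre=meta["pre"], post=meta["post"])
    n_trials = int(frame["trial"].max()) + 1
    n_samples = int(frame["sample"].max()) + 1
    if len(frame) != n_trials * n_samples:
        raise ValueError(f"ragged epoch file: {len(frame)} rows, expected "
                         f"{n_trials} trials x {n_samples} samples")
    data = (
        frame[labels].to_numpy().reshape(n_trials, n_samples, len(labels))
    ).transpose(0, 2, 1)
    return EpochSet(data=data, fs=meta["fs"], channel_labels=labels, window=win)


# ---------------------------------------------------------------------------
# matrices


def write_matrix(path: str | Path, conn: ConnectivityMatrix) -> None:
    """Labelled TSV plus a JSON sidecar with averaging metadata."""
    path = Path(path)
    frame = pd.DataFrame(conn.matrix, index=conn.channel_labels,
                         columns=conn.channel_labels)
    frame.to_csv(path, sep="\t", float_format=_FLOAT_FMT)
    meta = {"m_samples": conn.m_samples, "n_trials": conn.n_trials}
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(meta, indent=1))


def read_matrix(path: str | Path) -> ConnectivityMatrix:
    path = Path(path)
    frame = pd.read_csv(path, sep="\t", index_col=0)
    labels = [str(c) for c in frame.columns]
    if len(set(labels)) != len(labels):
        dupes = sorted({c for c in labels if labels.count(c) > 1})
        raise ValueError(f"duplicate channel labels: {dupes}")
    if [str(i) for i in frame.index] != labels:
        raise ValueError("row labels do not match column labels")
    matrix = frame.to_numpy(dtype=float)
    if matrix.shape[0] != matrix.shape[1]:
        raise ValueError("matrix is not square")
    if not np.allclose(matrix, matrix.T):
        ij = np.argwhere(~np.isclose(matrix, matrix.T))
        raise ValueError(f"matrix is asymmetric (first mismatch at {ij[0] + 1})")
    meta_path = path.with_suffix(path.suffix + ".json")
    meta = json.loads(meta_path.read_text()) if meta_path.exists() else {}
    return ConnectivityMatrix(
        matrix=matrix, channel_labels=labels,
        m_samples=int(meta.get("m_samples", 0)),
        n_trials=int(meta.get("n_trials", 0)),
    )


# ---------------------------------------------------------------------------
# trees


def write_tree(path: str | Path, tree: TreeGraph) -> None:
    """Edge list TSV with a label-ordering comment (round-trip safe)."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("# labels=" + ",".join(tree.channel_labels) + "\n")
        fh.write("channel_a\tchannel_b\n")
        for a, b in tree.edges:
            fh.write(f"{tree.channel_labels[a]}\t{tree.channel_labels[b]}\n")


def read_tree(path: str | Path) -> TreeGraph:
    path = Path(path)
    lines = path.read_text().splitlines()
    if not lines or not lines[0].startswith("# labels="):
        raise ValueError("tree file missing '# labels=' header (line 1)")
    labels = lines[0].split("=", 1)[1].split(",")
    if len(set(labels)) != len(labels):
        dupes = sorted({c for c in labels if labels.count(c) > 1})
        raise ValueError(f"duplicate channel labels: {dupes}")
    index = {lab: i for i, lab in enumerate(labels)}
    edges = []
    for lineno, line in enumerate(lines[2:], start=3):
        if not line.strip():
            continue
        parts = line.split("\t")
        if len(parts) != 2:
            raise ValueError(f"malformed edge row at line {lineno}")
        try:
            edges.append((index[parts[0]], index[parts[1]]))
        except KeyError as exc:
            raise ValueError(f"unknown channel {exc} at line {lineno}") from None
    return TreeGraph(n_nodes=len(labels), edges=tuple(edges), channel_labels=labels)


def write_tree_adjacency(path: str | Path, tree: TreeGraph) -> None:
    frame = pd.DataFrame(tree.adjacency, index=tree.channel_labels,
                         columns=tree.channel_labels)
    frame.to_csv(path, sep="\t")


def write_tree_graphml(path: str | Path, tree: TreeGraph) -> None:
    """Optional GraphML export for external graph viewers."""
    import networkx as nx

    g = nx.relabel_nodes(tree.to_networkx(),
                         dict(enumerate(tree.channel_labels)))
    nx.write_graphml(g, str(path))


# ---------------------------------------------------------------------------
# cohorts

def save_cohort(
    cohort: list[tuple[EpochSet, SubjectRecord]], directory: str | Path,
    config_echo: dict | None = None, seed: int | None = None,
) -> Path:
    """Write per-subject epoch files plus a JSON manifest; returns manifest path."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    subjects = []
    for epochs, record in cohort:
        fname = f"{record.subject_id}_epochs.tsv"
        write_epochs(directory / fname, epochs)
        subjects.append(
            {
                "subject_id": record.subject_id,
                "group": record.group,
                "disease_duration": record.disease_duration,
                "alsfrs_r": record.alsfrs_r,
                "clinical_score": record.clinical_score,
                "coupling_kappa": record.coupling_kappa,
                "epochs_file": fname,
            }
        )
    manifest = {"seed": seed, "config": config_echo or {}, "subjects": subjects}
    path = directory / "manifest.json"
    path.write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return path


def load_cohort(directory: str | Path) -> list[tuple[EpochSet, SubjectRecord]]:
    directory = Path(directory)
    manifest = json.loads((directory / "manifest.json").read_text())
    cohort = []
    for entry in manifest["subjects"]:
        epochs = read_epochs(directory / entry["epochs_file"])
        record = SubjectRecord(
            subject_id=entry["subject_id"],
            group=entry["group"],
            disease_duration=entry.get("disease_duration", float("nan")),
            alsfrs_r=entry.get("alsfrs_r"),
            clinical_score=entry.get("clinical_score", float("nan")),
            coupling_kappa=entry.get("coupling_kappa", float("nan")),
        )
        cohort.append((epochs, record))
    return cohort


# ---------------------------------------------------------------------------
# SNIRF (read-only, minimal)


def read_snirf(path: str | Path) -> ContinuousRecording:
    """Read a continuous recording from a SNIRF (HDF5) file.

    Minimal reader: uses ``/nirs/data1/dataTimeSeries`` and ``.../time`` and
    collects stimulus onsets from every ``/nirs/stim*`` group.  Channel
    labels fall back to measurement-list indices.
    """
    import h5py

    with h5py.File(path, "r") as fh:
        nirs = fh["nirs"] if "nirs" in fh else fh["nirs1"]
        data = nirs["data1"]
        samples = np.asarray(data["dataTimeSeries"], dtype=float)
        time = np.asarray(data["time"], dtype=float).ravel()
        if time.size == 2:  # [start, dt] convention
            fs = 1.0 / time[1]
        else:
            fs = 1.0 / float(np.median(np.diff(time)))
        onsets = []
        for key in sorted(k for k in nirs.keys() if k.startswith("stim")):
            stim_data = np.atleast_2d(np.asarray(nirs[key]["data"], dtype=float))
            if stim_data.size:
                onsets.extend(stim_data[:, 0].tolist())
        labels = [f"CH{i + 1:02d}" for i in range(samples.shape[1])]
    return ContinuousRecording(samples=samples, fs=fs, channel_labels=labels,
                               onsets=np.sort(np.asarray(onsets)))


# ---------------------------------------------------------------------------
# end-to-end driver


@dataclass
class PipelineResult:
    """In-memory bundle mirroring the files ``run_pipeline`` writes."""

    records: list[SubjectRecord]
    matrices: dict[str, ConnectivityMatrix]
    trees: dict[str, TreeGraph]
    metrics_table: pd.DataFrame
    stats_table: pd.DataFrame
    clinical_stats: pd.DataFrame | None
    group_trees: dict[str, TreeGraph]
    reference_tree: TreeGraph
    provenance: dict


def subject_connectivity(
    epochs: EpochSet,
    baseline: tuple[float, float] = BASELINE_WINDOW,
    post: tuple[float, float] = POST_WINDOW,
) -> ConnectivityMatrix:
    """Epochs -> phases -> PLV -> zPLV -> tPLV adjacency for one subject."""
    return tplv_matrix(normalize_plv(plv(analytic_signal(epochs)),
                                     baseline=baseline), post=post)


def analyze_cohort(
    cohort: list[tuple[EpochSet, SubjectRecord]], config: RunConfig | None = None
) -> PipelineResult:
    """Run connectivity, tree extraction, metrics and statistics in memory."""
    cfg = config or RunConfig()
    records: list[SubjectRecord] = []
    matrices: dict[str, ConnectivityMatrix] = {}
    trees: dict[str, TreeGraph] = {}
    for epochs, record in cohort:
        conn = subject_connectivity(epochs, baseline=cfg.baseline, post=cfg.post)
        tree = kruskal_max_tree(conn)
        record.metrics = global_metrics(tree, gplv=gplv(conn),
                                        ecc_variant=cfg.ecc_variant)
        matrices[record.subject_id] = conn
        trees[record.subject_id] = tree
        records.append(record)

    control_ids = [r.subject_id for r in records if r.group == CONTROL]
    patient_ids = [r.subject_id for r in records if r.group == PATIENT]
    group_trees: dict[str, TreeGraph] = {}
    if cfg.group_mst:
        for name, ids in ((CONTROL, control_ids), (PATIENT, patient_ids)):
            if ids:
                group_trees[name] = group_tree([matrices[i] for i in ids])
    # Reference tree: from the control-group average connectivity.
    reference = group_tree([matrices[i] for i in control_ids])

    rows = []
    for r in records:
        row = {"subject_id": r.subject_id, "group": r.group}
        row.update(r.metrics.as_dict())
        sim = overlap(trees[r.subject_id], reference)
        row["overlap_percent"] = sim.overlap_percent
        rows.append(row)
    metrics_table = pd.DataFrame(rows)

    stats = group_table(records, GLOBAL_METRIC_NAMES)
    # overlap lives in the metrics table, not GlobalMetrics; append its test
    try:
        from .group_stats import mannwhitney

        x = metrics_table.loc[metrics_table.group == PATIENT, "overlap_percent"]
        y = metrics_table.loc[metrics_table.group == CONTROL, "overlap_percent"]
        ov = mannwhitney(x.to_numpy(), y.to_numpy())
        stats = pd.concat(
            [
                stats,
                pd.DataFrame(
                    [{
                        "metric": "overlap_percent",
                        "control_mean": y.mean(), "control_sd": y.std(ddof=1),
                        "patient_mean": x.mean(), "patient_sd": x.std(ddof=1),
                        "u_statistic": ov.statistic, "p_value": ov.p_value,
                        "method": ov.method,
                    }]
                ),
            ],
            ignore_index=True,
        )
    except ValueError:
        logger.warning("skipping overlap group test (insufficient subjects)")

    clinical = None
    n_patients = sum(1 for r in records if r.group == PATIENT)
    if n_patients >= 4:
        clinical = clinical_table(records)

    provenance = {
        "package_version": __version__,
        "config": cfg.to_json(),
        "seed": cfg.seed,
        "n_subjects": len(records),
        "m_samples": next(iter(matrices.values())).m_samples if matrices else None,
    }
    return PipelineResult(
        records=records, matrices=matrices, trees=trees,
        metrics_table=metrics_table, stats_table=stats, clinical_stats=clinical,
        group_trees=group_trees, reference_tree=reference, provenance=provenance,
    )


def run_pipeline(config: RunConfig) -> PipelineResult:
    """Load a cohort from ``config.input_dir`` and write the analysis bundle."""
    cohort = load_cohort(config.input_dir)
    result = analyze_cohort(cohort, config)
    out = Path(config.out_dir)
    (out / "subjects").mkdir(parents=True, exist_ok=True)
    for sid, conn in result.matrices.items():
        write_matrix(out / "subjects" / f"{sid}_tplv.tsv", conn)
        write_tree(out / "subjects" / f"{sid}_mst.tsv", result.trees[sid])
    for name, tree in result.group_trees.items():
        write_tree(out / f"group_mst_{name}.tsv", tree)
    write_tree(out / "reference_mst.tsv", result.reference_tree)
    for name in (CONTROL, PATIENT):
        grp = [result.trees[r.subject_id] for r in result.records if r.group == name]
        if grp:
            occ = occurrence(grp, threshold=config.occurrence_threshold)
            occ.hub_frame().to_csv(out / f"hub_occurrence_{name}.tsv", sep="\t",
                                   index=False, float_format=_FLOAT_FMT)
            occ.edge_frame().to_csv(out / f"edge_occurrence_{name}.tsv", sep="\t",
                                    index=False, float_format=_FLOAT_FMT)
    result.metrics_table.to_csv(out / "metrics.tsv", sep="\t", index=False,
                                float_format=_FLOAT_FMT)
    result.stats_table.to_csv(out / "group_stats.tsv", sep="\t", index=False,
                              float_format=_FLOAT_FMT)
    if result.clinical_stats is not None:
        result.clinical_stats.to_csv(out / "clinical_stats.tsv", sep="\t",
                                     index=False, float_format=_FLOAT_FMT)
    (out / "provenance.json").write_text(
        json.dumps(result.provenance, indent=1, sort_keys=True)
    )
    return result
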