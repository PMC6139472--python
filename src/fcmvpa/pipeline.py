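"""End-to-end orchestration: configuration, stage runners, manifests.

Three stages mirror the analysis: ``run_simulate`` writes a synthetic
cohort (4D NIfTI + BIDS-style events TSV per subject), ``run_connectivity``
turns each subject's run into its 120 edge features, ``run_classify``
performs the incremental-feature SVM analysis with its permutation null
and writes the curve, results JSON, and the Table-style edge report.

All randomness flows from one master seed: the simulation derives
per-subject seeds from ``sim_seed`` and the permutation null uses
``seed`` directly.  Every stage archives its exact configuration and the
SHA-256 of every file it wrote, so a rerun with the same config is
verifiable bit-for-bit on the deterministic stages.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .classify import (
    ClassificationCurve,
    CohortFeatureMatrix,
    edge_report,
    find_peak,
    incremental_curve,
    permutation_null,
    rank_features,
)
from .connectivity import (
    NodeSignalSet,
    canonical_hrf,
    connectivity_features,
    lower_triangle_pairs,
    make_psych_factor,
    ppi_node_series,
)
from .nodes import extract_block, node_table_to_specs, read_node_table, write_node_table
from .simulate import SimCohortConfig, default_affine, iter_cohort

logger = logging.getLogger("fcmvpa")

__all__ = ["PipelineConfig", "run_simulate", "run_connectivity", "run_classify", "run_report"]


@dataclass
class PipelineConfig:
    """One flat, serializable configuration for the whole workflow.

    Precedence when assembled by the CLI: command-line flags > config
    file > these defaults.  A run's config is archived verbatim in its
    output manifest.
    """

    # paths
    cohort_dir: str = "cohort"
    node_table: str | None = None  # default: <cohort_dir>/nodes.csv
    out_dir: str = "results"
    # protocol
    tr: float = 2.0
    n_volumes: int = 360
    # simulation
    n_ctrl: int = 27
    n_pp: int = 25
    n_old_items: int = 120
    n_new_items: int = 60
    trial_duration_s: float = 4.0
    base_rho: float = 0.1
    noise_sd: float = 0.5
    drift_amplitude: float = 1.0
    signal_scale: float = 1.0
    grid_shape: tuple[int, int, int] = (64, 64, 32)
    voxel_size: float = 3.0
    effect_edges: tuple[tuple[tuple[int, int], float], ...] = ()
    sim_seed: int = 0
    # analysis
    lam: float | str = "gcv"
    hrf_peak_delay: float = 6.0
    hrf_undershoot_delay: float = 16.0
    hrf_peak_dispersion: float = 1.0
    hrf_undershoot_dispersion: float = 1.0
    hrf_ratio: float = 6.0
    hrf_length: float = 32.0
    ranking_method: str = "ttest"
    nested_ranking: bool = False
    svm_C: float = 1.0
    standardize: bool = False
    n_perm: int = 2000
    seed: int = 0
    # reports
    write_node_signals: bool = False
    write_matrix: bool = False
    make_plot: bool = True
    force: bool = False

    def validate(self) -> list[str]:
        """Collect every violated field (empty list means valid)."""
        errors = []
        if self.tr <= 0:
            errors.append(f"tr must be positive (got {self.tr})")
        if self.n_volumes < 1:
            errors.append(f"n_volumes must be >= 1 (got {self.n_volumes})")
        if self.n_ctrl < 0 or self.n_pp < 0:
            errors.append(f"group sizes must be non-negative (got {self.n_ctrl}, {self.n_pp})")
        if self.trial_duration_s <= 0:
            errors.append("trial_duration_s must be positive")
        total_s = (self.n_old_items + self.n_new_items) * self.trial_duration_s
        if total_s > self.n_volumes * self.tr:
            errors.append(
                f"run too short: trials need {total_s} s, run is {self.n_volumes * self.tr} s"
            )
        if not -1 < self.base_rho < 1:
            errors.append(f"base_rho must lie in (-1, 1) (got {self.base_rho})")
        for (i, j), delta in self.effect_edges:
            if not -1 < self.base_rho + delta < 1:
                errors.append(f"effect edge ({i},{j}): base_rho+delta outside (-1, 1)")
        if self.noise_sd < 0:
            errors.append("noise_sd must be non-negative")
        if isinstance(self.lam, str) and self.lam != "gcv":
            errors.append(f"lam must be a number or 'gcv' (got {self.lam!r})")
        if not isinstance(self.lam, str) and self.lam < 0:
            errors.append("lam must be non-negative")
        if self.ranking_method not in ("ttest", "svm_weight"):
            errors.append(f"unknown ranking_method {self.ranking_method!r}")
        if self.svm_C <= 0:
            errors.append("svm_C must be positive")
        if self.n_perm < 0:
            errors.append("n_perm must be non-negative")
        return errors

    def require_valid(self) -> None:
        errors = self.validate()
        if errors:
            raise ValueError(
                "invalid configuration:\n" + "\n".join(f"  - {e}" for e in errors)
            )

    # -- (de)serialization ---------------------------------------------------

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["grid_shape"] = list(self.grid_shape)
        d["effect_edges"] = [
            [[int(i), int(j)], float(delta)] for (i, j), delta in self.effect_edges
        ]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        d = dict(d)
        if "grid_shape" in d:
            d["grid_shape"] = tuple(int(v) for v in d["grid_shape"])
        if "effect_edges" in d:
            d["effect_edges"] = tuple(
                ((int(e[0][0]), int(e[0][1])), float(e[1])) for e in d["effect_edges"]
            )
        return cls(**d)

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_file(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    # -- derived objects -----------------------------------------------------

    def sim_config(self, node_centers=None, node_names=None) -> SimCohortConfig:
        return SimCohortConfig(
            n_ctrl=self.n_ctrl,
            n_pp=self.n_pp,
            n_volumes=self.n_volumes,
            tr_seconds=self.tr,
            n_old_items=self.n_old_items,
            n_new_items=self.n_new_items,
            trial_duration_s=self.trial_duration_s,
            node_centers=node_centers,
            node_names=node_names,
            effect_edges=self.effect_edges,
            base_rho=self.base_rho,
            noise_sd=self.noise_sd,
            drift_amplitude=self.drift_amplitude,
            signal_scale=self.signal_scale,
            grid_shape=self.grid_shape,
            voxel_size=self.voxel_size,
            seed=self.sim_seed,
        )

    def hrf(self):
        return canonical_hrf(
            self.tr,
            peak_delay=self.hrf_peak_delay,
            undershoot_delay=self.hrf_undershoot_delay,
            peak_dispersion=self.hrf_peak_dispersion,
            undershoot_dispersion=self.hrf_undershoot_dispersion,
            ratio=self.hrf_ratio,
            length=self.hrf_length,
        )


# ---------------------------------------------------------------------------
# Manifests
# ---------------------------------------------------------------------------


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def write_run_manifest(
    out_dir: Path, stage: str, config: PipelineConfig, files: list[Path], extra: dict | None = None
) -> dict:
    cfg_json = json.dumps(config.to_dict(), sort_keys=True)
    manifest = {
        "stage": stage,
        "fcmvpa_version": __version__,
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S%z"),
        "config": config.to_dict(),
        "config_sha256": hashlib.sha256(cfg_json.encode()).hexdigest(),
        "files": {str(p.relative_to(out_dir)): _sha256(p) for p in sorted(files)},
    }
    if extra:
        manifest.update(extra)
    with open(out_dir / f"manifest_{stage}.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest


# ---------------------------------------------------------------------------
# Stage: simulate
# ---------------------------------------------------------------------------


def run_simulate(config: PipelineConfig, node_table_df: pd.DataFrame | None = None) -> dict:
    """Generate the synthetic cohort and write it under ``cohort_dir``.

    Per subject: ``sub-XXX/sub-XXX_bold.nii.gz`` and a BIDS-style
    ``sub-XXX_events.tsv`` (onset, duration, trial_type).  Cohort-level:
    ``participants.tsv``, ``nodes.csv`` (both coordinate spaces filled,
    RAS+ mm, 0-based voxel convention), and a manifest with all
    parameters and per-subject seeds.
    """
    import nibabel as nib

    config.require_valid()
    cohort = Path(config.cohort_dir)
    cohort.mkdir(parents=True, exist_ok=True)

    centers = names = None
    if node_table_df is not None:
        specs_df = node_table_df
        affine = default_affine(config.grid_shape, config.voxel_size)
        specs = node_table_to_specs(specs_df, affine, config.grid_shape)
        centers = tuple(s.center_mni for s in specs)
        names = tuple(s.name for s in specs)
    sim = config.sim_config(node_centers=centers, node_names=names)

    nodes = sim.node_specs()
    nodes_df = pd.DataFrame(
        {
            "name": [n.name for n in nodes],
            "x": [n.center_mni[0] for n in nodes],
            "y": [n.center_mni[1] for n in nodes],
            "z": [n.center_mni[2] for n in nodes],
            "space": "MNI",
        }
    )
    write_node_table(nodes_df, cohort / "nodes.csv")

    written = [cohort / "nodes.csv"]
    rows = []
    logger.info(
        "simulating %d CTRL + %d PP subjects (grid %s, noise_sd %.3g, seed %d)",
        sim.n_ctrl, sim.n_pp, sim.grid_shape, sim.noise_sd, sim.seed,
    )
    for sub in iter_cohort(sim):
        sdir = cohort / sub.subject_id
        sdir.mkdir(exist_ok=True)
        img = nib.Nifti1Image(sub.bold_run, sub.affine)
        img.header.set_zooms((config.voxel_size,) * 3 + (config.tr,))
        bold_path = sdir / f"{sub.subject_id}_bold.nii.gz"
        nib.save(img, bold_path)
        events_path = sdir / f"{sub.subject_id}_events.tsv"
        sub.events.to_csv(events_path, sep="\t", index=False)
        rows.append({"subject_id": sub.subject_id, "group": sub.group_label, "seed": sub.seed})
        written += [bold_path, events_path]
    participants = pd.DataFrame(rows)
    participants.to_csv(cohort / "participants.tsv", sep="\t", index=False)
    written.append(cohort / "participants.tsv")
    return write_run_manifest(
        cohort, "simulate", config, written, extra={"sim_config": sim.to_manifest_dict()}
    )


# ---------------------------------------------------------------------------
# Stage: connectivity
# ---------------------------------------------------------------------------


def subject_features_path(out_dir: Path, subject_id: str) -> Path:
    return out_dir / "features" / f"{subject_id}_features.csv"


def run_connectivity(config: PipelineConfig) -> dict:
    """Node extraction + PPI + connectivity features for every subject.

    Subjects whose feature file already exists are skipped unless
    ``force``; per-subject failures are collected and summarized at the
    end without aborting the run.
    """
    import nibabel as nib

    config.require_valid()
    cohort = Path(config.cohort_dir)
    out = Path(config.out_dir)
    (out / "features").mkdir(parents=True, exist_ok=True)

    participants_path = cohort / "participants.tsv"
    if not participants_path.exists():
        raise FileNotFoundError(f"no subjects found: {participants_path} is missing")
    participants = pd.read_csv(participants_path, sep="\t")
    if participants.empty:
        raise ValueError(f"no subjects found in {participants_path}")

    node_csv = Path(config.node_table) if config.node_table else cohort / "nodes.csv"
    nodes_df = read_node_table(node_csv)
    hrf = config.hrf()
    logger.info(
        "connectivity: %d subjects, nodes=%s, lam=%s, HRF(peak=%gs, undershoot=%gs, ratio=%g)",
        len(participants), node_csv, config.lam,
        config.hrf_peak_delay, config.hrf_undershoot_delay, config.hrf_ratio,
    )

    written, errors, n_skipped = [], {}, 0
    specs = None
    for row in participants.itertuples(index=False):
        sid = row.subject_id
        feat_path = subject_features_path(out, sid)
        if feat_path.exists() and not config.force:
            n_skipped += 1
            continue
        try:
            bold_path = cohort / sid / f"{sid}_bold.nii.gz"
            events_path = cohort / sid / f"{sid}_events.tsv"
            img = nib.load(bold_path)
            if specs is None:
                specs = node_table_to_specs(nodes_df, img.affine, img.shape[:3])
            events = pd.read_csv(events_path, sep="\t")
            data = np.asarray(img.get_fdata(), dtype=np.float32)
            psych = make_psych_factor(events, config.n_volumes, config.tr)
            signals = np.vstack(
                [
                    ppi_node_series(
                        extract_block(data, spec, tr=config.tr), psych, hrf, lam=config.lam
                    )
                    for spec in specs
                ]
            )
            sigset = NodeSignalSet(sid, signals, tuple(s.name for s in specs))
            feats = connectivity_features(sigset)
            pd.DataFrame({"edge": feats.edge_names, "r": feats.values}).to_csv(
                feat_path, index=False
            )
            written.append(feat_path)
            if config.write_node_signals:
                p = out / "features" / f"{sid}_node_signals.csv"
                pd.DataFrame(signals.T, columns=sigset.node_names).to_csv(p, index=False)
                written.append(p)
            if config.write_matrix:
                p = out / "features" / f"{sid}_matrix.csv"
                pd.DataFrame(
                    feats.matrix, index=sigset.node_names, columns=sigset.node_names
                ).to_csv(p)
                written.append(p)
        except (OSError, ValueError) as exc:
            errors[sid] = str(exc)
            logger.error("subject %s failed: %s", sid, exc)
    if errors:
        logger.warning("connectivity finished with %d failed subjects: %s",
                       len(errors), sorted(errors))
    if n_skipped:
        logger.info("skipped %d subjects with existing features (use force to redo)", n_skipped)
    return write_run_manifest(
        out, "connectivity", config, written,
        extra={"n_skipped": n_skipped, "errors": errors},
    )


# ---------------------------------------------------------------------------
# Stage: classify
# ---------------------------------------------------------------------------


def load_cohort_features(config: PipelineConfig) -> CohortFeatureMatrix:
    """Assemble the subjects x features matrix from per-subject CSVs."""
    cohort = Path(config.cohort_dir)
    out = Path(config.out_dir)
    participants = pd.read_csv(cohort / "participants.tsv", sep="\t")
    rows, labels, ids = [], [], []
    edge_names = None
    for row in participants.itertuples(index=False):
        path = subject_features_path(out, row.subject_id)
        if not path.exists():
            raise FileNotFoundError(f"missing features for {row.subject_id}: {path}")
        df = pd.read_csv(path)
        if edge_names is None:
            edge_names = tuple(df["edge"])
        rows.append(df["r"].to_numpy())
        labels.append(row.group)
        ids.append(row.subject_id)
    X = np.vstack(rows)
    n_nodes = int(round((1 + np.sqrt(1 + 8 * X.shape[1])) / 2))
    pairs = tuple(lower_triangle_pairs(n_nodes))
    return CohortFeatureMatrix(
        X=X, labels=np.array(labels), edge_pairs=pairs,
        edge_names=edge_names, subject_ids=tuple(ids),
    )


def run_classify(config: PipelineConfig) -> dict:
    """Ranking, incremental LOOCV curve, permutation null, peak, edge report."""
    config.require_valid()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    data = load_cohort_features(config)
    logger.info(
        "classify: %d subjects (%d CTRL / %d PP), %d features; "
        "ranking=%s (ties -> lower edge index), C=%g, standardize=%s, n_perm=%d, seed=%d",
        data.n_subjects, int(np.sum(data.labels == "CTRL")), int(np.sum(data.labels == "PP")),
        data.n_features, config.ranking_method, config.svm_C, config.standardize,
        config.n_perm, config.seed,
    )

    ranking = rank_features(data, method=config.ranking_method, C=config.svm_C)
    curve = incremental_curve(
        data, ranking, C=config.svm_C, nested=config.nested_ranking,
        ranking_method=config.ranking_method,
    )
    if config.n_perm > 0:
        null_mean, null_sd = permutation_null(
            data, ranking_method=config.ranking_method, n_perm=config.n_perm,
            seed=config.seed, C=config.svm_C,
        )
        curve.null_mean, curve.null_sd = null_mean, null_sd
        curve.n_permutations = config.n_perm
    else:
        logger.warning("n_perm=0: writing the accuracy curve without null columns")

    peak_k, peak_accuracy = find_peak(curve.accuracy)
    report = edge_report(data, ranking, peak_k)

    curve_path = out / "curve.csv"
    curve.to_frame().to_csv(curve_path, index=False)
    report_path = out / "edge_report.csv"
    report_out = report.copy()
    report_out["mean_r_CTRL"] = report_out["mean_r_CTRL"].round(2)
    report_out["mean_r_PP"] = report_out["mean_r_PP"].round(2)
    report_out.to_csv(report_path, index=False)

    n_ctrl = int(np.sum(data.labels == "CTRL"))
    n_pp = int(np.sum(data.labels == "PP"))
    results = {
        "peak_k": int(peak_k),
        "peak_accuracy": float(peak_accuracy),
        "accuracy_all_features": float(curve.accuracy[-1]),
        "n_subjects": data.n_subjects,
        "n_features": data.n_features,
        "n_perm": int(config.n_perm),
        "seed": int(config.seed),
        "chance_level": 0.5,
        "majority_class_proportion": max(n_ctrl, n_pp) / data.n_subjects,
        "ranking_method": config.ranking_method,
        "svm_C": config.svm_C,
    }
    results_path = out / "results.json"
    with open(results_path, "w") as fh:
        json.dump(results, fh, indent=2)
    written = [curve_path, report_path, results_path]
    if config.make_plot:
        written.append(_plot_curve(curve, out))
    return write_run_manifest(out, "classify", config, written, extra={"results": results})


def _plot_curve(curve: ClassificationCurve, out: Path) -> Path:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 4.5))
    ax.plot(curve.k, curve.accuracy, "k-", lw=2, label="LOOCV accuracy")
    if curve.null_mean is not None:
        ax.errorbar(
            curve.k, curve.null_mean, yerr=curve.null_sd, fmt="k--", lw=0.8,
            ecolor="0.7", elinewidth=0.6, label=f"permutation null (n={curve.n_permutations})",
        )
    ax.axvline(curve.peak_k, color="r", ls=":", lw=1)
    ax.set_xlabel("number of connectivity features included")
    ax.set_ylabel("classification accuracy")
    ax.set_ylim(0, 1.05)
    ax.legend(loc="lower right", frameon=False)
    ax.set_title(f"peak accuracy {curve.peak_accuracy:.2f} at k={curve.peak_k}")
    fig.tight_layout()
    path = out / "accuracy_curve.png"
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path


def run_report(config: PipelineConfig) -> dict:
    """Regenerate the edge report and plot from saved features + curve."""
    out = Path(config.out_dir)
    curve_df = pd.read_csv(out / "curve.csv")
    curve = ClassificationCurve(
        k=curve_df["k"].to_numpy(),
        accuracy=curve_df["accuracy"].to_numpy(),
        null_mean=curve_df["null_mean"].to_numpy() if "null_mean" in curve_df else None,
        null_sd=curve_df["null_sd"].to_numpy() if "null_sd" in curve_df else None,
    )
    data = load_cohort_features(config)
    ranking = rank_features(data, method=config.ranking_method, C=config.svm_C)
    report = edge_report(data, ranking, curve.peak_k)
    report_path = out / "edge_report.csv"
    report_out = report.copy()
    report_out["mean_r_CTRL"] = report_out["mean_r_CTRL"].round(2)
    report_out["mean_r_PP"] = report_out["mean_r_PP"].round(2)
    report_out.to_csv(report_path, index=False)
    written = [report_path]
    if config.make_plot:
        written.append(_plot_curve(curve, out))
    return write_run_manifest(out, "report", config, written)
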