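"""End-to-end workflow: configuration, stage chaining, manifest and audit files.

``run_pipeline`` chains ingest -> preprocess -> phenospace -> ranking on a
feature table + plate map, writing every intermediate table as CSV plus a
JSON manifest (config hash, seed, per-stage row counts, output content
hashes, library versions, accumulated warnings). Re-running the same
configuration on the same inputs reproduces byte-identical outputs; the
manifest deliberately contains no timestamps or absolute paths so two runs
of the same analysis in different directories produce identical manifests.
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__, ingest, phenospace, preprocess, ranking, synthetic
from .errors import ConfigError, StageError

log = logging.getLogger("thetascreen")

NEGCTRL_LABEL = "DMSO 0.1%"
POSCTRL_LABEL = "staurosporine 0.3 µM"

#: config fields excluded from the manifest's config hash (filesystem-specific)
_PATH_FIELDS = ("feature_table", "plate_map", "outdir", "exclusion_list")


@dataclass
class PipelineConfig:
    """All knobs of the end-to-end analysis.

    Defaults are the screening constants used throughout the package:
    correlation cutoff 0.9 and variance cutoff 1e-5 for feature selection,
    activity cutoff at 2 SD of compound distances, 0.1% DMSO negative and
    0.3 uM staurosporine positive controls.
    """

    feature_table: str = "cells.csv"
    plate_map: str = "platemap.csv"
    outdir: str = "results"
    dialect: str = "generic"
    qc_enabled: bool = True
    sat_max: float = 0.2
    focus_min: float | None = None
    corr_threshold: float = 0.9
    var_threshold: float = 1e-5
    norm_center: str = "median"
    variance_prop: float = 0.9
    k_sd: float = 2.0
    zprime_space: str = "feature"  # "feature" or "pc"
    theta_mode: str = "2d"  # "2d" or "kd"
    top_n: int | None = None
    exclusion_list: str | None = None
    seed: int = 0
    negctrl_label: str = NEGCTRL_LABEL
    posctrl_label: str = POSCTRL_LABEL

    def validate(self) -> None:
        ingest.get_dialect(self.dialect)
        if self.zprime_space not in ("feature", "pc"):
            raise ConfigError("zprime_space must be 'feature' or 'pc'")
        if self.theta_mode not in ("2d", "kd"):
            raise ConfigError("theta_mode must be '2d' or 'kd'")
        if self.norm_center not in ("median", "mean"):
            raise ConfigError("norm_center must be 'median' or 'mean'")
        if not 0 < self.variance_prop <= 1:
            raise ConfigError("variance_prop must lie in (0, 1]")
        for name in ("corr_threshold", "var_threshold", "k_sd", "sat_max"):
            if float(getattr(self, name)) < 0:
                raise ConfigError(f"{name} must be >= 0")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        d = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigError(f"unknown pipeline config keys {sorted(unknown)}")
        return cls(**d)

    def analysis_hash(self) -> str:
        """Hash of the analysis parameters (paths excluded)."""
        d = {k: v for k, v in self.to_dict().items() if k not in _PATH_FIELDS}
        blob = json.dumps(d, sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


class _Run:
    """Collects stage stats, warnings and output files for the manifest."""

    def __init__(self, outdir: Path):
        self.outdir = outdir
        self.stages: list[dict] = []
        self.outputs: list[str] = []
        self.warnings: list[str] = []

    def stage(self, name: str, n_in: int, n_out: int) -> None:
        self.stages.append({"name": name, "n_rows_in": int(n_in), "n_rows_out": int(n_out)})
        log.info("stage %-18s rows in=%d out=%d", name, n_in, n_out)

    def write(self, name: str, df: pd.DataFrame) -> None:
        path = self.outdir / name
        df.to_csv(path, index=False)
        self.outputs.append(name)

    def manifest(self, config: PipelineConfig, status: str = "ok", failed_stage: str | None = None) -> dict:
        m = {
            "config": {k: v for k, v in config.to_dict().items() if k not in _PATH_FIELDS},
            "config_hash": config.analysis_hash(),
            "seed": config.seed,
            "status": status,
            "failed_stage": failed_stage,
            "stages": self.stages,
            "outputs": {n: _sha256(self.outdir / n) for n in sorted(self.outputs)},
            "warnings": self.warnings,
            "versions": _versions(),
        }
        (self.outdir / ("manifest.json" if status == "ok" else "manifest.failed.json")).write_text(
            json.dumps(m, indent=2, sort_keys=True, default=str) + "\n"
        )
        return m


def _versions() -> dict[str, str]:
    import numpy, scipy
    return {
        "thetascreen": __version__,
        "numpy": numpy.__version__,
        "scipy": scipy.__version__,
        "pandas": pd.__version__,
    }


class _WarningCapture(logging.Handler):
    def __init__(self, sink: list[str]):
        super().__init__(level=logging.WARNING)
        self.sink = sink

    def emit(self, record: logging.LogRecord) -> None:
        self.sink.append(record.getMessage())


def run_pipeline(
    config: PipelineConfig,
    feature_table: pd.DataFrame | None = None,
    layout: pd.DataFrame | None = None,
) -> dict:
    """Execute the full analysis and return the run manifest.

    ``feature_table``/``layout`` can be passed in memory to skip re-reading
    the CSVs named in the config. Any stage error aborts the run with a
    :class:`StageError`; outputs written so far are hashed into a
    ``manifest.failed.json`` marker.
    """
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    run = _Run(outdir)
    capture = _WarningCapture(run.warnings)
    log.addHandler(capture)
    stage = "ingest.read"
    try:
        if feature_table is None:
            feature_table = ingest.read_feature_table(config.feature_table, config.dialect)
        if layout is None:
            layout = ingest.read_plate_map(config.plate_map)
        run.stage(stage, 0, len(feature_table))

        stage = "ingest.qc"
        thresholds = ingest.QCThresholds(sat_max=config.sat_max, focus_min=config.focus_min)
        cells, qc_report = ingest.qc_filter_images(
            feature_table, thresholds, layout=layout, enabled=config.qc_enabled
        )
        run.write("qc_report.csv", qc_report.removed)
        run.stage(stage, len(feature_table), len(cells))

        stage = "ingest.aggregate"
        images = ingest.aggregate_to_image_median(cells)
        wells = ingest.aggregate_to_well(images)
        wells = ingest.join_layout(wells, layout)
        run.write("well_profiles.csv", wells)
        run.stage(stage, len(cells), len(wells))

        stage = "preprocess.select_features"
        selected, fs_report = preprocess.select_features(
            wells, corr_threshold=config.corr_threshold, var_threshold=config.var_threshold
        )
        run.write("feature_selection.csv", fs_report.to_frame())
        run.stage(stage, len(ingest.feature_columns(wells)), len(fs_report.retained))

        stage = "preprocess.normalize"
        normed = preprocess.normalize_to_dmso(selected, center=config.norm_center)
        run.write("normalized_profiles.csv", normed.data)
        run.write("normalization_constants.csv", normed.constants)
        run.stage(stage, len(selected), len(normed.data))

        stage = "phenospace.pca"
        model = phenospace.fit_pca(normed, variance_prop=config.variance_prop)
        loadings = model.loadings.reset_index()
        loadings.attrs = {}
        run.write("pc_model.csv", loadings)
        run.write(
            "pc_variance.csv",
            pd.DataFrame(
                {
                    "component": [f"pc_{i + 1}" for i in range(len(model.variance_fractions))],
                    "variance_fraction": model.variance_fractions,
                    "retained": [i < model.k for i in range(len(model.variance_fractions))],
                }
            ),
        )
        centered = phenospace.project_and_center(model, normed)
        run.write("pc_coordinates.csv", centered.data)
        run.stage(stage, len(normed.data), model.k)

        stage = "phenospace.activity"
        activity = phenospace.call_activity(centered, k_sd=config.k_sd)
        pan_active, counts = phenospace.filter_pan_active(activity)
        run.write("activity.csv", activity)
        run.write(
            "active_counts.csv",
            counts.rename("n_active").reset_index(),
        )
        run.stage(stage, len(activity), len(pan_active))

        stage = "phenospace.zprime"
        z_table = centered if config.zprime_space == "pc" else normed
        zscores = phenospace.multivariate_zprime(z_table)
        run.write(
            "zprime.csv",
            pd.DataFrame(sorted(zscores.items()), columns=["cell_line", "zprime"]),
        )
        run.stage(stage, len(zscores), len(zscores))

        stage = "tccs.theta"
        theta = ranking.compute_theta(centered, activity=activity)
        run.write("theta.csv", theta)
        run.stage(stage, len(centered.data), len(theta))

        stage = "tccs.delta_theta"
        delta = ranking.delta_theta_table(theta, mode=config.theta_mode)
        run.write("delta_theta.csv", delta)
        run.stage(stage, len(theta), len(delta))

        stage = "rank.rank_product"
        delta_active = delta[delta["compound"].isin(set(pan_active))]
        ranked = ranking.rank_product(delta_active)
        run.write("ranked_pairs.csv", ranked)
        exclude = (
            ranking.read_exclusion_list(config.exclusion_list) if config.exclusion_list else None
        )
        hits = ranking.build_hit_list(
            ranked, active_compounds=pan_active, top_n=config.top_n, exclude=exclude
        )
        run.write("hit_list.csv", hits)
        run.stage(stage, len(delta_active), len(hits))
    except Exception as exc:
        run.manifest(config, status="failed", failed_stage=stage)
        raise StageError(stage, exc) from exc
    finally:
        log.removeHandler(capture)
    return run.manifest(config)


def simulate(config: synthetic.ScreenSimConfig | str | Path, outdir: str | Path) -> dict[str, Path]:
    """Generate a synthetic screen (optionally from a YAML config) onto disk."""
    if not isinstance(config, synthetic.ScreenSimConfig):
        config = synthetic.ScreenSimConfig.from_dict(
            yaml.safe_load(Path(config).read_text()) or {}
        )
    config.validate()
    cells, layout, gt = synthetic.generate_screen(config)
    return synthetic.write_screen(outdir, cells, layout, gt, config)
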