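"""Synthetic multi-cell-line Cell Painting-like screens with known ground truth.

Real high-content screens of this kind image a panel of morphologically
distinct cell lines treated with a compound library in 96- or 384-well
plates, with vehicle (0.1% DMSO) negative controls and 0.3 uM staurosporine
positive controls on every plate. No such raw data ships with this package;
instead this module draws per-cell feature tables from a generative model
whose ground truth (which compounds are active, and the angle between two
cell lines' phenotypic response directions) is known exactly, so every
downstream stage can be tested quantitatively.

Generative model, per cell line c and feature f:

    cell value = ( mu_cf  +  s_cf * [ effect_f + (W_c z)_f + eps_f ] ) * g_pf

* mu_c is a distinct basal morphology mean vector per cell line and s_c a
  per-feature baseline-SD scale, so raw cell lines are well separated.
* W_c z + eps is correlated low-rank noise (about 10 latent factors plus
  unit diagonal noise, in SD units). The two strongest factors lie along a
  fixed orthonormal 2-D plane (e1, e2) of standardized feature space shared
  by all cell lines, so that plane is the top-2 principal plane of the
  standardized baseline covariance.
* effect is the compound effect in baseline-SD units: magnitude m times the
  unit direction cos(phi) e1 + sin(phi) e2. Inactive compounds have m = 0.
  By default a compound's in-plane angle phi is shared across cell lines
  (no divergence); entries in ``divergence_spec`` plant a chosen angular
  divergence between a pair of cell lines. Positive-control wells get a
  fixed large "staurosporine-like" in-plane effect shared within a line.
* g_p is a multiplicative per-plate, per-feature technical effect that the
  plate-wise DMSO normalization stage is expected to remove.

Effects are applied on the raw scale before plate effects. All randomness
flows from ``ScreenSimConfig.seed``; the same config yields bit-identical
output.
"""
from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import ingest
from .errors import ConfigError, LayoutError, UnknownReferenceError
from .ingest import IMAGE, OBJECT, PLATE, QC_FOCUS, QC_SATURATION, WELL

NEG_COMPOUND = "DMSO"
POS_COMPOUND = "staurosporine"
NEG_CONC = "0.1 %"
POS_CONC = "0.3 uM"
TREATMENT_CONC = "1 uM"

_PLATE_GEOMETRY = {96: (8, 12), 384: (16, 24)}

# latent-factor scales of the standardized baseline covariance: the first two
# (in-plane) dominate so the planted plane is the top-2 principal plane
_PLANE_FACTOR_SCALES = (2.5, 2.2)
_N_MINOR_FACTORS = 8
_MINOR_SCALE_RANGE = (0.4, 1.2)
_POSCTRL_MAGNITUDE = 12.0


def well_names(plate_format: int) -> list[str]:
    """Row-major well names ("A01", "A02", ...) for a plate format."""
    try:
        n_rows, n_cols = _PLATE_GEOMETRY[plate_format]
    except KeyError:
        raise ConfigError(f"plate_format must be one of {sorted(_PLATE_GEOMETRY)}") from None
    rows = [chr(ord("A") + i) for i in range(n_rows)]
    return [f"{r}{c:02d}" for r in rows for c in range(1, n_cols + 1)]


@dataclass
class ScreenSimConfig:
    """Parameters of a simulated screen.

    Defaults emulate the full study design: 8 cell lines x 1280 compounds at
    a single 1 uM concentration in 384-well plates, 340 features per cell,
    DMSO negative and staurosporine positive control wells on every plate.
    """

    n_cell_lines: int = 8
    n_compounds: int = 1280
    n_replicates: int = 1
    plate_format: int = 384
    n_features: int = 340
    n_fields_per_well: int = 1
    cells_per_image_range: tuple[int, int] = (8, 14)
    frac_inactive: float = 0.4
    effect_magnitude_range: tuple[float, float] = (2.0, 6.0)
    #: (compound id, (cell line a, cell line b), planted angle in degrees)
    divergence_spec: list[tuple[str, tuple[str, str], float]] = field(default_factory=list)
    #: optional explicit control wells per plate: {"negctrl": [...], "posctrl": [...]}
    control_layout: dict[str, list[str]] | None = None
    #: optional explicit set of active compound ids (overrides frac_inactive)
    active_compounds: list[str] | None = None
    plate_effect_sd: float = 0.1
    qc_fail_rate: float = 0.0
    seed: int = 0

    @property
    def cell_line_names(self) -> list[str]:
        return [f"CL{i + 1:02d}" for i in range(self.n_cell_lines)]

    @property
    def compound_names(self) -> list[str]:
        return [f"CPD{i + 1:04d}" for i in range(self.n_compounds)]

    def control_wells(self) -> tuple[list[str], list[str]]:
        """(negctrl wells, posctrl wells) per plate."""
        wells = well_names(self.plate_format)
        n_rows, n_cols = _PLATE_GEOMETRY[self.plate_format]
        if self.control_layout is not None:
            neg = list(self.control_layout.get("negctrl", []))
            pos = list(self.control_layout.get("posctrl", []))
        else:  # first column DMSO, last column staurosporine
            neg = [w for w in wells if int(w[1:]) == 1]
            pos = [w for w in wells if int(w[1:]) == n_cols]
        unknown = (set(neg) | set(pos)) - set(wells)
        if unknown:
            raise LayoutError(f"control wells not on a {self.plate_format}-well plate: {sorted(unknown)}")
        if set(neg) & set(pos):
            raise LayoutError("negctrl and posctrl well sets overlap")
        if len(neg) < 2 or len(pos) < 2:
            raise LayoutError("every plate needs >= 2 negctrl and >= 2 posctrl wells")
        return neg, pos

    def validate(self) -> None:
        for name in ("n_cell_lines", "n_compounds", "n_replicates", "n_features", "n_fields_per_well"):
            if int(getattr(self, name)) < 1:
                raise ConfigError(f"{name} must be >= 1")
        if self.plate_format not in _PLATE_GEOMETRY:
            raise ConfigError(f"plate_format must be one of {sorted(_PLATE_GEOMETRY)}")
        lo, hi = self.cells_per_image_range
        if not (1 <= lo <= hi):
            raise ConfigError("cells_per_image_range must satisfy 1 <= min <= max")
        for name in ("frac_inactive", "qc_fail_rate"):
            v = float(getattr(self, name))
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} must lie in [0, 1]")
        mlo, mhi = self.effect_magnitude_range
        if mlo < 0 or mhi < mlo:
            raise ConfigError("effect_magnitude_range must satisfy 0 <= min <= max")
        if self.plate_effect_sd < 0:
            raise ConfigError("plate_effect_sd must be >= 0")
        compounds = set(self.compound_names)
        lines = set(self.cell_line_names)
        for cpd, (a, b), angle in self.divergence_spec:
            if cpd not in compounds:
                raise UnknownReferenceError(f"divergence_spec names unknown compound {cpd!r}")
            if a not in lines or b not in lines:
                raise UnknownReferenceError(f"divergence_spec names unknown cell line in {(a, b)}")
            if a == b:
                raise ConfigError(f"divergence_spec pair for {cpd!r} must name two distinct lines")
            if not 0.0 <= float(angle) <= 180.0:
                raise ConfigError("planted angles must lie in [0, 180] degrees")
        if self.active_compounds is not None:
            unknown = set(self.active_compounds) - compounds
            if unknown:
                raise UnknownReferenceError(f"active_compounds names unknown compounds {sorted(unknown)}")
        self.control_wells()

    # --- (de)serialization -------------------------------------------------
    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["cells_per_image_range"] = list(self.cells_per_image_range)
        d["effect_magnitude_range"] = list(self.effect_magnitude_range)
        d["divergence_spec"] = [[c, [a, b], float(t)] for c, (a, b), t in self.divergence_spec]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ScreenSimConfig":
        d = dict(d)
        if "cells_per_image_range" in d:
            d["cells_per_image_range"] = tuple(d["cells_per_image_range"])
        if "effect_magnitude_range" in d:
            d["effect_magnitude_range"] = tuple(d["effect_magnitude_range"])
        if "divergence_spec" in d:
            d["divergence_spec"] = [(c, (a, b), float(t)) for c, (a, b), t in d["divergence_spec"]]
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigError(f"unknown simulation config keys {sorted(unknown)}")
        return cls(**d)


@dataclass
class GroundTruth:
    """Planted truth emitted alongside a simulated screen.

    ``effects`` has one row per compound x cell line with the effect
    magnitude (baseline-SD units), the in-plane angle phi (degrees) and the
    active flag; ``plane`` holds the orthonormal basis (e1, e2) of the
    planted plane in standardized feature space. Effect vectors are in
    baseline-SD units.
    """

    plane: np.ndarray  # (2, n_features)
    effects: pd.DataFrame  # compound, cell_line, magnitude, phi_deg, active
    posctrl_effects: pd.DataFrame  # cell_line, magnitude, phi_deg
    qc_failed_images: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=[PLATE, WELL, IMAGE, "mode"])
    )

    def __post_init__(self) -> None:
        eff = self.effects
        bad = (eff["magnitude"] == 0) != (~eff["active"])
        if bad.any():
            raise ValueError("ground truth violated: magnitude 0 <=> active False")
        self._eff = eff.set_index(["compound", "cell_line"])

    def effect_vector(self, compound: str, cell_line: str) -> np.ndarray:
        """Effect vector in baseline-SD units (zeros if inactive)."""
        row = self._eff.loc[(compound, cell_line)]
        m, phi = float(row["magnitude"]), np.deg2rad(float(row["phi_deg"]))
        return m * (np.cos(phi) * self.plane[0] + np.sin(phi) * self.plane[1])

    def true_delta_theta(self, compound: str, line_a: str, line_b: str) -> float:
        """Planted angular divergence in degrees, symmetric, in [0, 180]."""
        if line_a == line_b:
            return 0.0
        pa = float(self._eff.loc[(compound, line_a), "phi_deg"])
        pb = float(self._eff.loc[(compound, line_b), "phi_deg"])
        d = abs(pa - pb) % 360.0
        return min(d, 360.0 - d)

    def active_set(self) -> set[str]:
        by_cpd = self.effects.groupby("compound")["active"].all()
        return set(by_cpd.index[by_cpd])


def build_layout(config: ScreenSimConfig) -> pd.DataFrame:
    """Plate map for the whole screen (one plate series per line x replicate)."""
    neg_wells, pos_wells = config.control_wells()
    treatment_wells = [w for w in well_names(config.plate_format) if w not in set(neg_wells) | set(pos_wells)]
    if not treatment_wells:
        raise LayoutError("control layout leaves no treatment wells")
    per_plate = len(treatment_wells)
    compounds = config.compound_names
    rows = []
    for line in config.cell_line_names:
        for rep in range(1, config.n_replicates + 1):
            for p0 in range(0, config.n_compounds, per_plate):
                plate = f"{line}-R{rep}-P{p0 // per_plate + 1:02d}"
                chunk = compounds[p0 : p0 + per_plate]
                for w in neg_wells:
                    rows.append((plate, w, NEG_COMPOUND, NEG_CONC, "negctrl", line, rep))
                for w in pos_wells:
                    rows.append((plate, w, POS_COMPOUND, POS_CONC, "posctrl", line, rep))
                for w, cpd in zip(treatment_wells, chunk):
                    rows.append((plate, w, cpd, TREATMENT_CONC, "treatment", line, rep))
    return pd.DataFrame(
        rows, columns=[PLATE, WELL, "compound", "conc", "role", "cell_line", "replicate"]
    )


def _orthonormal_plane(rng: np.random.Generator, n_features: int) -> np.ndarray:
    q, _ = np.linalg.qr(rng.standard_normal((n_features, 2)))
    return q.T  # (2, n_features), orthonormal rows


def _draw_ground_truth(config: ScreenSimConfig, rng: np.random.Generator) -> GroundTruth:
    nf = config.n_features
    plane = _orthonormal_plane(rng, nf)
    lines = config.cell_line_names
    compounds = config.compound_names

    pos_rows = []
    for line in lines:
        pos_rows.append((line, _POSCTRL_MAGNITUDE, float(rng.uniform(0.0, 360.0))))
    posctrl = pd.DataFrame(pos_rows, columns=["cell_line", "magnitude", "phi_deg"])

    if config.active_compounds is not None:
        active = np.array([c in set(config.active_compounds) for c in compounds])
        _ = rng.random(config.n_compounds)  # keep stream layout stable
    else:
        active = rng.random(config.n_compounds) >= config.frac_inactive
    lo, hi = config.effect_magnitude_range
    magnitudes = np.where(active, rng.uniform(lo, hi, config.n_compounds), 0.0)
    active = active & (magnitudes > 0)  # magnitude 0 <=> inactive, even if lo == 0
    base_phi = rng.uniform(0.0, 360.0, config.n_compounds)

    phi = {(c, ln): float(base_phi[i]) for i, c in enumerate(compounds) for ln in lines}
    for cpd, (a, b), angle in config.divergence_spec:
        phi[(cpd, b)] = (phi[(cpd, a)] + float(angle)) % 360.0

    eff_rows = []
    for i, c in enumerate(compounds):
        for ln in lines:
            eff_rows.append((c, ln, float(magnitudes[i]), phi[(c, ln)], bool(active[i])))
    effects = pd.DataFrame(
        eff_rows, columns=["compound", "cell_line", "magnitude", "phi_deg", "active"]
    )
    return GroundTruth(plane=plane, effects=effects, posctrl_effects=posctrl)


def generate_screen(
    config: ScreenSimConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, GroundTruth]:
    """Simulate a screen: per-cell feature table, plate map and ground truth.

    Deterministic in ``config.seed``: identical configs give bit-identical
    tables.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    nf = config.n_features
    feat_names = [f"f{i + 1:04d}" for i in range(nf)]
    layout = build_layout(config)
    gt = _draw_ground_truth(config, rng)
    e1, e2 = gt.plane
    pos_by_line = gt.posctrl_effects.set_index("cell_line")

    k_minor = _N_MINOR_FACTORS
    lo_c, hi_c = config.cells_per_image_range

    chunks: list[pd.DataFrame] = []
    for line in config.cell_line_names:
        mu = rng.uniform(8.0, 16.0, nf)
        s = rng.uniform(0.5, 2.0, nf)
        minors = rng.standard_normal((nf, k_minor))
        minors /= np.linalg.norm(minors, axis=0)
        minor_scales = rng.uniform(*_MINOR_SCALE_RANGE, k_minor)
        W = np.column_stack(
            [_PLANE_FACTOR_SCALES[0] * e1, _PLANE_FACTOR_SCALES[1] * e2, minors * minor_scales]
        )  # (nf, 2 + k_minor)

        sub = layout.loc[layout["cell_line"] == line]
        m_pos = float(pos_by_line.loc[line, "magnitude"])
        phi_pos = float(pos_by_line.loc[line, "phi_deg"])
        eff_line = gt.effects.loc[
            gt.effects["cell_line"] == line, ["compound", "magnitude", "phi_deg"]
        ]

        for plate, pw in sub.groupby(PLATE, sort=False):
            g = np.exp(rng.normal(0.0, config.plate_effect_sd, nf))
            n_wells = len(pw)
            # effect matrix in SD units, one row per well
            merged = pw.merge(eff_line, on="compound", how="left")
            m = merged["magnitude"].to_numpy()
            phi = merged["phi_deg"].to_numpy()
            is_pos = (merged["role"] == "posctrl").to_numpy()
            is_neg = (merged["role"] == "negctrl").to_numpy()
            m = np.where(is_pos, m_pos, np.where(is_neg, 0.0, m))
            phi = np.deg2rad(np.where(is_pos, phi_pos, np.where(is_neg, 0.0, phi)))
            E = (m * np.cos(phi))[:, None] * e1 + (m * np.sin(phi))[:, None] * e2
            n_images = config.n_fields_per_well
            cells_per_image = rng.integers(lo_c, hi_c + 1, size=(n_wells, n_images))
            cells_per_well = cells_per_image.sum(axis=1)
            total = int(cells_per_well.sum())
            well_idx = np.repeat(np.arange(n_wells), cells_per_well)

            Z = rng.standard_normal((total, W.shape[1]))
            eps = rng.standard_normal((total, nf))
            sd_units = E[well_idx] + Z @ W.T + eps
            raw = (mu + s * sd_units) * g

            image_of_cell = np.concatenate(
                [np.repeat(np.arange(1, n_images + 1), cells_per_image[i]) for i in range(n_wells)]
            )
            object_id = np.concatenate([np.arange(1, n + 1) for n in cells_per_image.reshape(-1)])
            sat = rng.uniform(0.0, 0.05, (n_wells, n_images))
            focus = np.clip(rng.normal(100.0, 5.0, (n_wells, n_images)), 1.0, None)

            df = pd.DataFrame(raw, columns=feat_names)
            df.insert(0, PLATE, plate)
            df.insert(1, WELL, pw[WELL].to_numpy()[well_idx])
            df.insert(2, IMAGE, image_of_cell)
            df.insert(3, OBJECT, object_id)
            df.insert(4, QC_SATURATION, sat[well_idx, image_of_cell - 1])
            df.insert(5, QC_FOCUS, focus[well_idx, image_of_cell - 1])
            chunks.append(df)

    cells = pd.concat(chunks, ignore_index=True)
    if config.qc_fail_rate > 0:
        cells, flagged = inject_qc_failures(cells, config, ground_truth=gt)
    return cells, layout, gt


def inject_qc_failures(
    table: pd.DataFrame,
    config: ScreenSimConfig,
    ground_truth: GroundTruth | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Degrade a qc_fail_rate fraction of images past the default QC cutoffs.

    Flagged images get either a saturated-pixel fraction in [0.5, 1.0]
    ("saturation" mode) or a focus score in [0, 2] ("focus" mode). Returns
    the modified table and the flagged-image table; the latter is also
    stored on ``ground_truth`` when given.
    """
    rate = float(config.qc_fail_rate)
    flagged = pd.DataFrame(columns=[PLATE, WELL, IMAGE, "mode"])
    if rate == 0:
        if ground_truth is not None:
            ground_truth.qc_failed_images = flagged
        return table, flagged

    rng = np.random.default_rng((int(config.seed) * 7919 + 13) % (2**31))
    images = (
        table[[PLATE, WELL, IMAGE]]
        .drop_duplicates()
        .sort_values([PLATE, WELL, IMAGE], kind="stable")
        .reset_index(drop=True)
    )
    hit = rng.random(len(images)) < rate
    mode = np.where(rng.random(len(images)) < 0.5, "saturation", "focus")
    flagged = images.loc[hit].copy()
    flagged["mode"] = mode[hit]
    flagged["_sat"] = np.where(
        flagged["mode"] == "saturation", rng.uniform(0.5, 1.0, len(flagged)), np.nan
    )
    flagged["_foc"] = np.where(
        flagged["mode"] == "focus", rng.uniform(0.0, 2.0, len(flagged)), np.nan
    )

    table = table.merge(flagged, on=[PLATE, WELL, IMAGE], how="left")
    table[QC_SATURATION] = table["_sat"].fillna(table[QC_SATURATION])
    table[QC_FOCUS] = table["_foc"].fillna(table[QC_FOCUS])
    table = table.drop(columns=["mode", "_sat", "_foc"])
    flagged = flagged.drop(columns=["_sat", "_foc"]).reset_index(drop=True)
    if ground_truth is not None:
        ground_truth.qc_failed_images = flagged
    return table, flagged


# --- on-disk form ----------------------------------------------------------

def write_screen(
    outdir: str | Path,
    cells: pd.DataFrame,
    layout: pd.DataFrame,
    ground_truth: GroundTruth,
    config: ScreenSimConfig,
) -> dict[str, Path]:
    """Write a simulated screen as CSVs + a YAML config echo.

    The per-cell table uses the ingest module's "generic" dialect, so the
    output is directly consumable by the analysis pipeline.
    """
    import pyarrow as pa
    import pyarrow.csv as pacsv

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "cells": outdir / "cells.csv",
        "platemap": outdir / "platemap.csv",
        "ground_truth_effects": outdir / "ground_truth_effects.csv",
        "ground_truth_posctrl": outdir / "ground_truth_posctrl.csv",
        "ground_truth_plane": outdir / "ground_truth_plane.csv",
        "ground_truth_qc": outdir / "ground_truth_qc.csv",
        "config": outdir / "sim_config.yaml",
    }
    # pyarrow writes large float tables much faster than pandas
    pacsv.write_csv(pa.Table.from_pandas(cells, preserve_index=False), paths["cells"])
    layout.to_csv(paths["platemap"], index=False)
    ground_truth.effects.to_csv(paths["ground_truth_effects"], index=False)
    ground_truth.posctrl_effects.to_csv(paths["ground_truth_posctrl"], index=False)
    pd.DataFrame(ground_truth.plane, index=["e1", "e2"]).to_csv(paths["ground_truth_plane"])
    ground_truth.qc_failed_images.to_csv(paths["ground_truth_qc"], index=False)
    paths["config"].write_text(yaml.safe_dump(config.to_dict(), sort_keys=True))
    return paths


def load_ground_truth(outdir: str | Path) -> GroundTruth:
    outdir = Path(outdir)
    plane = pd.read_csv(outdir / "ground_truth_plane.csv", index_col=0).to_numpy()
    effects = pd.read_csv(outdir / "ground_truth_effects.csv")
    posctrl = pd.read_csv(outdir / "ground_truth_posctrl.csv")
    qc = pd.read_csv(outdir / "ground_truth_qc.csv")
    if qc.empty:
        qc = pd.DataFrame(columns=[PLATE, WELL, IMAGE, "mode"])
    return GroundTruth(plane=plane, effects=effects, posctrl_effects=posctrl, qc_failed_images=qc)
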