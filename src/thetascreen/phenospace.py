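"""Shared principal-component phenotype space, activity calls and assay quality.

After plate-wise DMSO standardization all cell lines' profiles live on a
common scale, so a single PCA (computed on the data matrix *without*
re-centering or re-scaling — standardization already did both) defines a
shared phenotype space. The number of retained components is the smallest
k whose cumulative variance fraction reaches a chosen proportion. The
space is then translated so the per-component median of the negative
controls (the control centroid) sits at the origin.

A compound's phenotypic strength in a cell line is its l1 distance from
the control centroid; compounds within ``k_sd`` (default 2) standard
deviations of zero — the SD taken over all compound distances in that cell
line — are called inactive. Assay robustness is scored with a multivariate
Z' factor: control wells are projected onto the axis joining the negative-
and positive-control centroids and the classical Z' = 1 - 3(sd_pos +
sd_neg)/|mu_pos - mu_neg| is evaluated on the projections.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import PipelineError
from .ingest import PLATE, WELL, feature_columns

log = logging.getLogger("thetascreen")

PC_PREFIX = "pc_"
ANNOT_COLS = (PLATE, WELL, "compound", "conc", "role", "cell_line", "replicate")


def pc_columns(df: pd.DataFrame) -> list[str]:
    cols = [c for c in df.columns if c.startswith(PC_PREFIX)]
    return sorted(cols, key=lambda c: int(c[len(PC_PREFIX):]))


@dataclass
class PCModel:
    """Uncentered-PCA loadings and the retained-component rule."""

    loadings: pd.DataFrame  # features x components (pc_1, pc_2, ...)
    variance_fractions: np.ndarray
    k: int  # retained component count
    variance_prop: float

    @property
    def features(self) -> list[str]:
        return list(self.loadings.index)


def components_for_variance(variance_fractions: np.ndarray, variance_prop: float) -> int:
    """Smallest k whose cumulative variance fraction reaches the target."""
    cum = np.cumsum(variance_fractions)
    # tolerate float round-off at the boundary
    k = int(np.searchsorted(cum, variance_prop - 1e-12) + 1)
    return min(k, len(variance_fractions))


def fit_pca(table, variance_prop: float = 0.9) -> PCModel:
    """PCA of the profile matrix with no re-centering or re-scaling.

    ``table`` is a :class:`~thetascreen.preprocess.NormalizedProfileTable`
    or its DataFrame. Variance fractions are singular-value energies of the
    raw matrix; components beyond its numerical rank carry zero variance
    and are never retained. Loadings signs are fixed by making each
    vector's largest-magnitude element positive.
    """
    df = getattr(table, "data", table)
    feats = feature_columns(df)
    if len(df) < 2 or len(feats) < 2:
        raise PipelineError("PCA needs at least 2 wells and 2 features")
    if not 0 < variance_prop <= 1:
        raise PipelineError("variance_prop must lie in (0, 1]")
    X = df[feats].to_numpy(dtype=float)
    _, s, vt = np.linalg.svd(X, full_matrices=False)
    tol = s[0] * max(X.shape) * np.finfo(float).eps if len(s) else 0.0
    rank = int((s > tol).sum())
    s, vt = s[:rank], vt[:rank]
    energies = s**2
    fractions = energies / energies.sum()

    # deterministic sign convention
    flip = np.sign(vt[np.arange(rank), np.abs(vt).argmax(axis=1)])
    vt = vt * flip[:, None]

    k = components_for_variance(fractions, variance_prop)
    loadings = pd.DataFrame(
        vt.T, index=pd.Index(feats, name="feature"),
        columns=[f"{PC_PREFIX}{i + 1}" for i in range(rank)],
    )
    return PCModel(loadings=loadings, variance_fractions=fractions, k=k, variance_prop=variance_prop)


@dataclass
class CenteredPCTable:
    """Well coordinates in retained PC space, negctrl centroid at the origin."""

    data: pd.DataFrame  # annotations + pc_1..pc_k
    offset: np.ndarray  # the negctrl per-component median that was subtracted
    k: int

    def coords(self) -> np.ndarray:
        return self.data[pc_columns(self.data)].to_numpy(dtype=float)


def project_and_center(model: PCModel, table, layout: pd.DataFrame | None = None) -> CenteredPCTable:
    """Project profiles onto the retained components and center on the controls.

    The per-component median of the negative-control rows is subtracted
    from every row, placing the control centroid exactly at the origin.
    """
    from .ingest import join_layout

    df = getattr(table, "data", table)
    if "role" not in df.columns:
        if layout is None:
            raise PipelineError("profiles carry no 'role' column and no layout was given")
        df = join_layout(df, layout)
    feats = feature_columns(df)
    if feats != model.features:
        raise PipelineError(
            "profile feature columns do not match the PC model "
            f"({len(feats)} vs {len(model.features)})"
        )
    L = model.loadings.to_numpy()[:, : model.k]
    scores = df[feats].to_numpy(dtype=float) @ L

    neg = (df["role"] == "negctrl").to_numpy()
    if not neg.any():
        raise PipelineError("no negative-control rows to center on")
    offset = np.median(scores[neg], axis=0)
    scores = scores - offset

    keep = [c for c in ANNOT_COLS if c in df.columns]
    pc_frame = pd.DataFrame(
        scores, columns=[f"{PC_PREFIX}{i + 1}" for i in range(model.k)]
    )
    out = pd.concat([df[keep].reset_index(drop=True), pc_frame], axis=1)
    return CenteredPCTable(data=out, offset=offset, k=model.k)


# --- activity calling ------------------------------------------------------

def call_activity(table: CenteredPCTable, k_sd: float = 2.0) -> pd.DataFrame:
    """Call compound activity per cell line from l1 distances to the origin.

    Compound-level coordinates are the per-component median over that
    compound's wells (across replicates). The activity threshold is
    ``k_sd`` times the SD (n-1 denominator) of all compound distances in
    the cell line. Returns one row per compound x cell line with columns
    compound, cell_line, l1_distance, threshold, active.
    """
    df = table.data
    pcs = pc_columns(df)
    records = []
    for line, g in df[df["role"] == "treatment"].groupby("cell_line", sort=True):
        coords = g.groupby("compound", sort=True)[pcs].median()
        if len(coords) < 3:
            raise PipelineError(
                f"cell line {line!r} has {len(coords)} compounds; "
                "need >= 3 for a stable distance SD"
            )
        d = np.abs(coords.to_numpy()).sum(axis=1)
        threshold = k_sd * float(np.std(d, ddof=1))
        for cpd, dist in zip(coords.index, d):
            records.append((cpd, line, float(dist), threshold, bool(dist > threshold)))
    return pd.DataFrame(
        records, columns=["compound", "cell_line", "l1_distance", "threshold", "active"]
    )


def filter_pan_active(
    activity: pd.DataFrame, cell_lines: list[str] | None = None
) -> tuple[list[str], pd.Series]:
    """Compounds active in *every* cell line, plus per-line active counts.

    A compound missing an activity record for some screened line is
    excluded with a warning. Returns (sorted pan-active compound list,
    per-cell-line active counts).
    """
    lines = cell_lines or sorted(activity["cell_line"].unique())
    counts = (
        activity[activity["active"]].groupby("cell_line")["compound"].count()
        .reindex(lines, fill_value=0)
    )
    flags = activity.pivot(index="compound", columns="cell_line", values="active")
    missing = flags.index[flags[lines].isna().any(axis=1)] if set(lines) <= set(flags.columns) else flags.index
    if set(lines) - set(flags.columns):
        log.warning("no activity records at all for lines %s", sorted(set(lines) - set(flags.columns)))
        return [], counts
    if len(missing):
        log.warning("%d compounds lack activity records in some cell line; excluded", len(missing))
        flags = flags.drop(index=missing)
    pan = flags.index[flags[lines].all(axis=1)]
    return sorted(pan), counts


# --- assay quality ---------------------------------------------------------

def zprime(mu_neg: float, sd_neg: float, mu_pos: float, sd_pos: float) -> float:
    """Classical Z' factor; -inf when the control means coincide."""
    sep = abs(mu_pos - mu_neg)
    if sep == 0:
        return float("-inf")
    return 1.0 - 3.0 * (sd_pos + sd_neg) / sep


def _zprime_projected(neg: np.ndarray, pos: np.ndarray) -> float:
    axis = np.median(pos, axis=0) - np.median(neg, axis=0)
    norm = np.linalg.norm(axis)
    if norm == 0:
        log.warning("Z': control centroids coincide; score undefined (-inf)")
        return float("-inf")
    axis = axis / norm
    pn, pp = neg @ axis, pos @ axis
    return zprime(pn.mean(), pn.std(ddof=1), pp.mean(), pp.std(ddof=1))


def multivariate_zprime(table, value_cols: list[str] | None = None) -> dict[str, float]:
    """Multivariate Z' per cell line plus a pooled score.

    Control wells are projected onto the axis joining the negative- and
    positive-control per-column medians; Z' is computed on the 1-D
    projections. ``table`` may be a normalized profile table (feature
    space, the default reporting space) or a centered PC table. The pooled
    score concatenates all lines' (already per-plate-normalized) control
    wells and uses one common axis.
    """
    df = getattr(table, "data", table)
    if value_cols is None:
        value_cols = pc_columns(df) or feature_columns(df)
    ctrl = df[df["role"].isin(["negctrl", "posctrl"])]
    scores: dict[str, float] = {}
    for line, g in ctrl.groupby("cell_line", sort=True):
        neg = g.loc[g["role"] == "negctrl", value_cols].to_numpy(dtype=float)
        pos = g.loc[g["role"] == "posctrl", value_cols].to_numpy(dtype=float)
        if len(neg) < 2 or len(pos) < 2:
            raise PipelineError(f"cell line {line!r} needs >= 2 wells per control class")
        scores[str(line)] = _zprime_projected(neg, pos)
    scores["pooled"] = _zprime_projected(
        ctrl.loc[ctrl["role"] == "negctrl", value_cols].to_numpy(dtype=float),
        ctrl.loc[ctrl["role"] == "posctrl", value_cols].to_numpy(dtype=float),
    )
    return scores


def plot_controls_scatter(table: CenteredPCTable, path=None):
    """PC1/PC2 scatter of wells colored by control role (QC figure)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    df = table.data
    fig, ax = plt.subplots(figsize=(5, 4))
    colors = {"treatment": "0.7", "negctrl": "tab:blue", "posctrl": "tab:red"}
    for role, g in df.groupby("role"):
        ax.scatter(g[f"{PC_PREFIX}1"], g[f"{PC_PREFIX}2"], s=6, alpha=0.6,
                   c=colors.get(role, "k"), label=role)
    ax.set_xlabel("PC1")
    ax.set_ylabel("PC2")
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig
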