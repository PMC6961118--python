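"""Feature selection and plate-wise control-based normalization.

Morphologically distinct cell lines cannot be compared on raw CellProfiler
features: each line has its own basal morphology and each plate its own
technical scale. The remedy used here is the standard one in image-based
profiling — select an informative, non-redundant feature set once for the
whole screen, then standardize every feature plate-by-plate against the
vehicle (DMSO) wells of that plate, so that all profiles are expressed as
deviations from the local vehicle response.

Feature selection (on pooled well profiles, columns in alphabetical order):

1. drop features with variance < ``var_threshold`` (default 1e-5) or zero;
2. greedily break up feature pairs with \\|Pearson r\\| > ``corr_threshold``
   (default 0.9): within an offending pair, the feature with the larger
   mean \\|r\\| against all other features is removed (ties alphabetical),
   until no retained pair exceeds the threshold.

Normalization, per plate and per feature:

    x' = x / median(DMSO x)          (guarded: shift instead of divide when
                                      the DMSO median is ~0)
    z  = (x' - center(DMSO x')) / SD(DMSO x')

``center`` is the DMSO median by default, which pins the per-plate DMSO
feature median at exactly 0 with DMSO SD exactly 1; ``center="mean"`` gives
classical z-scores against the DMSO mean instead. Features whose DMSO SD is
zero on any plate are dropped with a warning. Missing values are imputed
with the plate DMSO median before the transform.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import LayoutError, PipelineError
from .ingest import PLATE, feature_columns, join_layout

log = logging.getLogger("thetascreen")


@dataclass
class FeatureSelectionReport:
    #: (kept feature, removed feature, |r|) per correlation-based removal
    removed_by_correlation: list[tuple[str, str, float]] = field(default_factory=list)
    #: (feature, variance) per variance-based removal
    removed_by_variance: list[tuple[str, float]] = field(default_factory=list)
    retained: list[str] = field(default_factory=list)

    def removed_features(self) -> set[str]:
        return {r for _, r, _ in self.removed_by_correlation} | {
            f for f, _ in self.removed_by_variance
        }

    def to_frame(self) -> pd.DataFrame:
        rows = [("variance", f, "", v) for f, v in self.removed_by_variance]
        rows += [("correlation", rm, kept, r) for kept, rm, r in self.removed_by_correlation]
        return pd.DataFrame(rows, columns=["filter", "removed", "kept_partner", "value"])


def select_features(
    table: pd.DataFrame,
    corr_threshold: float = 0.9,
    var_threshold: float = 1e-5,
) -> tuple[pd.DataFrame, FeatureSelectionReport]:
    """Drop uninformative and redundant feature columns from well profiles.

    Deterministic given the (alphabetical) column order, and idempotent.
    Raises :class:`PipelineError` if fewer than 2 features survive.
    """
    feats = feature_columns(table)
    if len(table) < 2:
        raise PipelineError("feature selection needs at least 2 wells")
    report = FeatureSelectionReport()

    variances = table[feats].var(ddof=1)
    low = variances.isna() | (variances < var_threshold)
    report.removed_by_variance = [(f, float(variances[f])) for f in feats if low[f]]
    feats = [f for f in feats if not low[f]]
    if len(feats) < 2:
        raise PipelineError("fewer than 2 features survive the variance filter")

    corr = table[feats].corr().abs().to_numpy()
    np.fill_diagonal(corr, 0.0)
    corr = np.nan_to_num(corr)
    mean_abs = corr.mean(axis=1)  # fixed redundancy score per feature
    alive = np.ones(len(feats), dtype=bool)
    while True:
        sub = np.where(alive[:, None] & alive[None, :], corr, 0.0)
        i, j = np.unravel_index(np.argmax(sub), sub.shape)
        r = sub[i, j]
        if r <= corr_threshold:
            break
        # remove the more redundant member; ties -> alphabetically later name
        if (mean_abs[i], feats[i]) >= (mean_abs[j], feats[j]):
            rm, kept = i, j
        else:
            rm, kept = j, i
        alive[rm] = False
        report.removed_by_correlation.append((feats[kept], feats[rm], float(r)))

    report.retained = [f for f, a in zip(feats, alive) if a]
    if len(report.retained) < 2:
        raise PipelineError("fewer than 2 features survive correlation pruning")
    keep_cols = [c for c in table.columns if c not in set(feature_columns(table)) or c in set(report.retained)]
    return table[keep_cols].copy(), report


@dataclass
class NormalizedProfileTable:
    """Plate-wise DMSO-standardized well profiles plus audit constants."""

    data: pd.DataFrame
    #: long-form per-plate constants: plate, feature, dmso_median, dmso_center, dmso_sd, guarded
    constants: pd.DataFrame
    dropped_features: list[str] = field(default_factory=list)


def normalize_to_dmso(
    table: pd.DataFrame,
    layout: pd.DataFrame | None = None,
    center: str = "median",
    guard_scale: float = 1e-9,
) -> NormalizedProfileTable:
    """Standardize well profiles against each plate's DMSO wells.

    ``table`` must carry a ``role`` column (or pass ``layout`` to join it).
    See the module docstring for the transform. Raises
    :class:`LayoutError` if any plate has fewer than 2 DMSO wells.
    """
    if center not in ("median", "mean"):
        raise PipelineError(f"center must be 'median' or 'mean', got {center!r}")
    if "role" not in table.columns:
        if layout is None:
            raise LayoutError("table has no 'role' column and no layout was given")
        table = join_layout(table, layout)

    feats = feature_columns(table)
    pooled_sd = table[feats].std(ddof=1)
    guard_eps = guard_scale * (pooled_sd + 1.0)

    out = table.copy()
    const_rows = []
    dropped: set[str] = set()
    for plate, g in table.groupby(PLATE, sort=True):
        is_dmso = (g["role"] == "negctrl").to_numpy()
        if is_dmso.sum() < 2:
            raise LayoutError(f"plate {plate!r} has fewer than 2 negctrl wells")
        X = g[feats].to_numpy(dtype=float)
        med = np.nanmedian(X[is_dmso], axis=0)
        # impute missing raw values with the plate DMSO median
        X = np.where(np.isnan(X), med, X)
        divide = np.abs(med) >= guard_eps.to_numpy()
        xprime = np.where(divide, X / np.where(divide, med, 1.0), X - med)
        dm = xprime[is_dmso]
        ctr = np.median(dm, axis=0) if center == "median" else dm.mean(axis=0)
        sd = dm.std(axis=0, ddof=1)
        zero_sd = ~(sd > 0)
        dropped.update(np.array(feats)[zero_sd])
        sd_safe = np.where(zero_sd, 1.0, sd)
        out.loc[g.index, feats] = (xprime - ctr) / sd_safe
        for fi, f in enumerate(feats):
            const_rows.append(
                (plate, f, float(med[fi]), float(ctr[fi]), float(sd[fi]), not bool(divide[fi]))
            )

    constants = pd.DataFrame(
        const_rows,
        columns=[PLATE, "feature", "dmso_median", "dmso_center", "dmso_sd", "guarded"],
    )
    if dropped:
        log.warning(
            "normalize_to_dmso: dropping %d features with zero DMSO SD on some plate: %s",
            len(dropped), sorted(dropped)[:10],
        )
        out = out.drop(columns=sorted(dropped))
    return NormalizedProfileTable(
        data=out, constants=constants, dropped_features=sorted(dropped)
    )
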