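"""Theta comparative cell scoring: theta, delta-theta and rank-product ranking.

Each active compound's phenotypic displacement in a cell line is reduced
to a direction: theta is the angle of its (PC1, PC2) coordinates measured
counter-clockwise from the positive PC1 axis, in degrees in [0, 360). For
a pair of cell lines treated with the same compound, delta-theta is the
wrap-around angular difference min(|a - b|, 360 - |a - b|) in [0, 180]:
0 means the two lines respond in the same phenotypic direction, 180 in
opposite directions. An optional k-dimensional variant measures the angle
between the full retained-coordinate vectors, arccos of their cosine
similarity.

Hits are ranked across replicates with a rank product: within each
replicate, rank 1 goes to the largest delta-theta (average ranks on ties);
an item's rank product is the geometric mean of its per-replicate ranks,
and the final hit list ascends in rank product, so compound-cell-line
pairs that diverge consistently across replicates come out on top.

Directions are only meaningful for compounds that actually moved the
phenotype: theta is flagged undefined for compounds below a magnitude
floor or called inactive, and such records are excluded from ranking.
"""
from __future__ import annotations

import logging
from itertools import combinations
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .errors import PipelineError
from .phenospace import CenteredPCTable, pc_columns

log = logging.getLogger("thetascreen")

PAIR_COLS = ["compound", "cell_line_a", "cell_line_b"]


def theta_degrees(pc1, pc2) -> np.ndarray:
    """Counter-clockwise angle from the +PC1 axis, degrees in [0, 360)."""
    return np.degrees(np.arctan2(pc2, pc1)) % 360.0


def delta_theta(theta_a: float, theta_b: float) -> float:
    """Wrap-around angular difference in degrees, in [0, 180]."""
    d = abs(float(theta_a) - float(theta_b)) % 360.0
    return min(d, 360.0 - d)


def compute_theta(
    table: CenteredPCTable,
    activity: pd.DataFrame | None = None,
    magnitude_floor: float = 0.0,
) -> pd.DataFrame:
    """Per compound x cell line x replicate: theta, magnitude and coordinates.

    Coordinates are per-component medians over the group's wells. theta is
    set to missing (undefined) when the (PC1, PC2) magnitude is below
    ``magnitude_floor`` or, if ``activity`` records are given, when the
    compound is inactive in that cell line — an unreliable direction is
    worse than none.
    """
    df = table.data
    pcs = pc_columns(df)
    if len(pcs) < 2:
        raise PipelineError("theta needs at least 2 retained principal components")
    grouped = (
        df[df["role"] == "treatment"]
        .groupby(["compound", "cell_line", "replicate"], sort=True)[pcs]
        .median()
        .reset_index()
    )
    p1 = grouped[pcs[0]].to_numpy()
    p2 = grouped[pcs[1]].to_numpy()
    grouped["magnitude"] = np.hypot(p1, p2)
    grouped["theta_deg"] = theta_degrees(p1, p2)

    defined = grouped["magnitude"] >= magnitude_floor
    if activity is not None:
        act = activity.set_index(["compound", "cell_line"])["active"]
        key = pd.MultiIndex.from_frame(grouped[["compound", "cell_line"]])
        defined &= act.reindex(key).fillna(False).to_numpy()
    grouped.loc[~defined, "theta_deg"] = np.nan
    n_undef = int((~defined).sum())
    if n_undef:
        log.info("theta undefined for %d compound x line x replicate groups", n_undef)
    return grouped


def delta_theta_table(theta: pd.DataFrame, mode: str = "2d") -> pd.DataFrame:
    """Delta-theta per compound x unordered cell-line pair x replicate.

    ``mode="2d"`` uses the wrap-around difference of the 2-D thetas;
    ``mode="kd"`` uses the angle between the full coordinate vectors
    (arccos of cosine similarity). Rows where either side is undefined get
    a missing delta-theta (they are excluded from ranking and counted).
    """
    if mode not in ("2d", "kd"):
        raise PipelineError(f"theta mode must be '2d' or 'kd', got {mode!r}")
    pcs = [c for c in theta.columns if c.startswith("pc_")]
    lines = sorted(theta["cell_line"].unique())
    frames = []
    for a, b in combinations(lines, 2):
        ta = theta[theta["cell_line"] == a]
        tb = theta[theta["cell_line"] == b]
        m = ta.merge(tb, on=["compound", "replicate"], suffixes=("_a", "_b"))
        if m.empty:
            continue
        defined = m["theta_deg_a"].notna() & m["theta_deg_b"].notna()
        if mode == "2d":
            d = np.abs(m["theta_deg_a"] - m["theta_deg_b"]) % 360.0
            dt = np.minimum(d, 360.0 - d)
        else:
            va = m[[f"{c}_a" for c in pcs]].to_numpy(dtype=float)
            vb = m[[f"{c}_b" for c in pcs]].to_numpy(dtype=float)
            na = np.linalg.norm(va, axis=1)
            nb = np.linalg.norm(vb, axis=1)
            ok = (na > 0) & (nb > 0)
            cos = np.where(ok, (va * vb).sum(axis=1) / np.where(ok, na * nb, 1.0), np.nan)
            dt = np.degrees(np.arccos(np.clip(cos, -1.0, 1.0)))
        out = pd.DataFrame(
            {
                "compound": m["compound"],
                "cell_line_a": a,
                "cell_line_b": b,
                "replicate": m["replicate"],
                "delta_theta_deg": np.where(defined, dt, np.nan),
            }
        )
        frames.append(out)
    if not frames:
        raise PipelineError("need at least 2 cell lines with theta records")
    result = pd.concat(frames, ignore_index=True)
    n_missing = int(result["delta_theta_deg"].isna().sum())
    if n_missing:
        log.info("delta-theta undefined for %d records (excluded from ranking)", n_missing)
    return result


def rank_product(delta: pd.DataFrame) -> pd.DataFrame:
    """Rank-product ordering of compound x cell-line-pair items over replicates.

    Within each replicate rank 1 is the largest delta-theta, ties receive
    average (fractional) ranks. Items missing from any replicate (absent
    or undefined) are excluded and logged. The final order ascends in rank
    product, breaking ties by larger mean delta-theta, then by item id.
    Per-replicate ranks are retained in ``rank_rep_*`` columns.
    """
    d = delta.dropna(subset=["delta_theta_deg"])
    if d.empty:
        raise PipelineError("no defined delta-theta records to rank")
    reps = sorted(d["replicate"].unique())
    wide = d.pivot_table(
        index=PAIR_COLS, columns="replicate", values="delta_theta_deg", aggfunc="mean"
    )
    complete = wide.notna().all(axis=1)
    if (~complete).any():
        log.warning(
            "rank_product: excluding %d items missing in some replicate", int((~complete).sum())
        )
        wide = wide.loc[complete]
    if wide.empty:
        raise PipelineError("no items present in every replicate")

    ranks = pd.DataFrame(index=wide.index)
    for r in reps:
        ranks[f"rank_rep_{r}"] = rankdata(-wide[r].to_numpy(), method="average")
    rp = np.prod(ranks.to_numpy(), axis=1) ** (1.0 / len(reps))

    out = wide.mean(axis=1).rename("mean_delta_theta_deg").reset_index()
    out = out.join(ranks.reset_index(drop=True))
    out["rank_product"] = rp
    out = out.sort_values(
        by=["rank_product", "mean_delta_theta_deg"] + PAIR_COLS,
        ascending=[True, False, True, True, True],
        kind="stable",
    ).reset_index(drop=True)
    out.insert(0, "final_rank", np.arange(1, len(out) + 1))
    return out


def read_exclusion_list(path: str | Path) -> list[str]:
    """Plain-text exclusion list: one compound id per line, '#' comments."""
    lines = Path(path).read_text().splitlines()
    return [ln.strip() for ln in lines if ln.strip() and not ln.lstrip().startswith("#")]


def build_hit_list(
    ranked: pd.DataFrame,
    active_compounds: list[str] | None = None,
    top_n: int | None = None,
    exclude: list[str] | None = None,
) -> pd.DataFrame:
    """Final hit table, restricted to pan-active compounds, re-ranked, truncated.

    ``exclude`` supports the manual mechanism-of-action triage step: listed
    compounds are dropped (unknown ids warn and are ignored) and ranks are
    recomputed before truncating to ``top_n``.
    """
    hits = ranked.copy()
    if active_compounds is not None:
        hits = hits[hits["compound"].isin(set(active_compounds))]
    if exclude:
        unknown = set(exclude) - set(ranked["compound"])
        if unknown:
            log.warning("exclusion list names unknown compounds %s; ignored", sorted(unknown))
        hits = hits[~hits["compound"].isin(set(exclude))]
    hits = hits.sort_values("final_rank", kind="stable").reset_index(drop=True)
    hits["final_rank"] = np.arange(1, len(hits) + 1)
    if top_n is not None:
        hits = hits.head(top_n)
    cols = ["final_rank", "compound", "cell_line_a", "cell_line_b",
            "mean_delta_theta_deg", "rank_product"]
    extra = [c for c in hits.columns if c not in cols]
    return hits[cols + extra]
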