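"""Differential quantification of delta-mass clusters between groups.

Abundance is measured by normalized spectral counts: for each cluster (or
residue-level key) and each technical replicate, the number of member
observations per 10^4 filtered PSMs; the three technical replicates of a
biological sample are then averaged, leaving one value per biological
sample.  Group comparison is a two-tailed Student t-test (pooled variance; a Welch
variant is available) across the biological samples, with the ratio computed
on pseudocount-adjusted group means.  A cluster is called significant only when all three gates hold:
R^2 > 0.5 for its Gaussian regression, a greater-than-twofold change in
either direction, and p < 0.05.  No multiple-testing correction is applied
by default (a Benjamini-Hochberg option exists but is off), matching the
raw-p significance rule.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DataError

NORMALIZATION_SCALE = 1e4  # observations per 10^4 filtered PSMs


def quantify(member_obs: pd.DataFrame, totals: pd.DataFrame,
             scale: float = NORMALIZATION_SCALE) -> pd.DataFrame:
    """Normalized spectral counts per biological sample for one key.

    ``totals`` must hold the filtered-PSM count per (group, bio_replicate,
    tech_replicate); every technical replicate contributes a count (0 when
    the key was not observed), scaled to per-``scale``-PSM units, and the
    technical replicates of each biological sample are averaged.
    """
    if (totals["total"] <= 0).any():
        bad = totals.loc[totals["total"] <= 0].iloc[0]
        raise DataError(
            f"replicate {bad['group']}/bio{bad['bio_replicate']}/"
            f"tech{bad['tech_replicate']} has zero filtered PSMs")
    counts = (member_obs.groupby(["group", "bio_replicate", "tech_replicate"])
              .size().rename("count").reset_index()) if len(member_obs) else \
        pd.DataFrame(columns=["group", "bio_replicate", "tech_replicate", "count"])
    merged = totals.merge(counts, on=["group", "bio_replicate", "tech_replicate"],
                          how="left").fillna({"count": 0})
    merged["normalized"] = merged["count"] / merged["total"] * scale
    out = (merged.groupby(["group", "bio_replicate"])["normalized"]
           .mean().rename("normalized_count").reset_index())
    return out


def compare_groups(control: np.ndarray, ischemia: np.ndarray,
                   pseudocount: float = 0.5, test: str = "student"):
    """Ratio and two-tailed t-test p-value between the two groups.

    ratio = (mean_ischemia + pseudocount) / (mean_control + pseudocount);
    p is a two-tailed Student t-test across the biological-sample values
    (pooled variance by default, ``test="welch"`` for unequal-variance).  Degenerate
    inputs follow fixed conventions: both groups all-zero -> (1, 1),
    flagged uninformative; zero variance in both groups -> p = 1 when the
    means agree, p = 0 otherwise.

    Returns (ratio, p_value, uninformative).
    """
    c = np.asarray(control, dtype=float)
    i = np.asarray(ischemia, dtype=float)
    if len(c) < 2 or len(i) < 2:
        raise DataError("compare_groups needs >= 2 biological samples per group")
    if not (c.any() or i.any()):
        return 1.0, 1.0, True
    mc, mi = c.mean(), i.mean()
    ratio = (mi + pseudocount) / (mc + pseudocount)
    if c.std() == 0 and i.std() == 0:
        return float(ratio), 1.0 if mc == mi else 0.0, False
    res = stats.ttest_ind(i, c, equal_var=(test != "welch"))
    p = float(res.pvalue)
    if not np.isfinite(p):
        p = 1.0
    return float(ratio), p, False


def flag_significant(ratio: float, p_value: float, r2: float,
                     fold: float = 2.0, alpha: float = 0.05,
                     min_r2: float = 0.5) -> bool:
    """Three-condition significance rule: R^2 > 0.5 AND (> fold change in
    either direction) AND p < alpha."""
    return bool(r2 > min_r2 and (ratio > fold or ratio < 1.0 / fold) and p_value < alpha)


def _differential_frame(rows: list[dict]) -> pd.DataFrame:
    cols = ["key", "cluster_id", "mean_control", "mean_ischemia", "ratio",
            "p_value", "r2", "significant", "direction", "uninformative"]
    df = pd.DataFrame(rows) if rows else pd.DataFrame(columns=cols)
    return df


def differential_clusters(clusters, obs: pd.DataFrame, totals: pd.DataFrame,
                          pseudocount: float = 0.5, test: str = "student",
                          fdr_correct: bool = False) -> pd.DataFrame:
    """Cluster-level differential table: one row per delta-mass cluster."""
    rows = []
    for c in clusters:
        quant = quantify(obs.iloc[c.members], totals)
        ctl = quant.loc[quant["group"] == "control", "normalized_count"].to_numpy()
        isc = quant.loc[quant["group"] == "ischemia", "normalized_count"].to_numpy()
        ratio, p, uninf = compare_groups(ctl, isc, pseudocount, test)
        rows.append({
            "key": c.cluster_id, "cluster_id": c.cluster_id,
            "mean_control": float(ctl.mean()), "mean_ischemia": float(isc.mean()),
            "ratio": ratio, "p_value": p, "r2": c.r2,
            "significant": flag_significant(ratio, p, c.r2),
            "direction": "up" if ratio > 1 else "down",
            "uninformative": uninf,
        })
    df = _differential_frame(rows)
    if fdr_correct and len(df):
        df = _apply_bh(df)
    return df


def differential_residues(clusters, obs: pd.DataFrame, totals: pd.DataFrame,
                          pseudocount: float = 0.5, test: str = "student",
                          fdr_correct: bool = False) -> pd.DataFrame:
    """Residue-level differential table: one row per unique
    (protein, position, residue, cluster)."""
    rows = []
    for c in clusters:
        members = obs.iloc[c.members]
        for (pid, pos, res), sub in members.groupby(
                ["protein_id", "protein_position", "residue"], sort=True):
            quant = quantify(sub, totals)
            ctl = quant.loc[quant["group"] == "control", "normalized_count"].to_numpy()
            isc = quant.loc[quant["group"] == "ischemia", "normalized_count"].to_numpy()
            ratio, p, uninf = compare_groups(ctl, isc, pseudocount, test)
            rows.append({
                "key": f"{pid}:{pos}:{res}:{c.cluster_id}",
                "cluster_id": c.cluster_id,
                "protein_id": pid, "protein_position": int(pos), "residue": res,
                "delta_mass": c.peak,
                "mean_control": float(ctl.mean()), "mean_ischemia": float(isc.mean()),
                "ratio": ratio, "p_value": p, "r2": c.r2,
                "significant": flag_significant(ratio, p, c.r2),
                "direction": "up" if ratio > 1 else "down",
                "uninformative": uninf,
            })
    df = pd.DataFrame(rows) if rows else pd.DataFrame(
        columns=["key", "cluster_id", "protein_id", "protein_position", "residue",
                 "delta_mass", "mean_control", "mean_ischemia", "ratio", "p_value",
                 "r2", "significant", "direction", "uninformative"])
    if fdr_correct and len(df):
        df = _apply_bh(df)
    return df


def _apply_bh(df: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """Benjamini-Hochberg adjusted p-values; significance gates on q."""
    p = df["p_value"].to_numpy()
    order = np.argsort(p)
    m = len(p)
    q = np.empty(m)
    prev = 1.0
    for rank_from_top in range(m - 1, -1, -1):
        i = order[rank_from_top]
        prev = min(prev, p[i] * m / (rank_from_top + 1))
        q[i] = prev
    df = df.assign(q_value=q)
    df["significant"] = [
        flag_significant(r, qv, r2)
        for r, qv, r2 in zip(df["ratio"], df["q_value"], df["r2"])]
    return df


def residue_level_report(residue_diff: pd.DataFrame) -> pd.DataFrame:
    """Figure-style points: one per unique significant (protein, position,
    cluster), carrying position, residue, delta mass, ratio and direction,
    sorted by protein then position."""
    cols = ["protein_id", "protein_position", "residue", "delta_mass",
            "ratio", "direction", "cluster_id"]
    if residue_diff.empty:
        return pd.DataFrame(columns=cols)
    sig = residue_diff.loc[residue_diff["significant"]]
    points = (sig[cols].drop_duplicates(subset=["protein_id", "protein_position",
                                                "cluster_id"])
              .sort_values(["protein_id", "protein_position"], kind="stable")
              .reset_index(drop=True))
    return points


def protein_frequency_table(points: pd.DataFrame) -> pd.DataFrame:
    """Per-protein unique-ncAA frequencies by regulation direction.

    freq counts unique (position, cluster) pairs; a protein appears once per
    direction in which it has any significant ncAA.
    """
    cols = ["protein_id", "direction", "freq"]
    if points.empty:
        return pd.DataFrame(columns=cols)
    uniq = points.drop_duplicates(subset=["protein_id", "protein_position",
                                          "cluster_id"])
    freq = (uniq.groupby(["protein_id", "direction"])
            .size().rename("freq").reset_index())
    return freq.sort_values(["protein_id", "direction"], kind="stable").reset_index(drop=True)


def table1_layout(freq: pd.DataFrame) -> pd.DataFrame:
    """Two-column (up | down) layout of the per-protein frequencies."""
    if freq.empty:
        return pd.DataFrame(columns=["protein_id", "freq_up", "freq_down"])
    wide = freq.pivot_table(index="protein_id", columns="direction",
                            values="freq", fill_value=0).reset_index()
    wide.columns.name = None
    for d in ("up", "down"):
        if d not in wide.columns:
            wide[d] = 0
    return wide.rename(columns={"up": "freq_up", "down": "freq_down"})[
        ["protein_id", "freq_up", "freq_down"]]
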