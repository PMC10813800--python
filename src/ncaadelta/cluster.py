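"""Delta-mass windowing, Gaussian-mixture clustering and peak regression.

Observed delta masses are first grouped into 1-Da windows [n - 0.5, n + 0.5)
for n in [-200, 1000].  Within each window, a Gaussian mixture is fitted for
a range of component counts and the count is chosen by the Bayesian
information criterion (reported negated, so that larger values indicate the
stronger model).  Components must then survive three constraints before they
are accepted as delta-mass clusters:

1. peak half-width > 1 ppm — the fitted SD, expressed in ppm of the member
   PSMs' median peptide monoisotopic mass (instrument mass error scales with
   precursor mass, so a width below 1 ppm is narrower than physics allows
   and indicates a degenerate, duplicate-valued artifact);
2. peak distance > 2 peak widths — components closer than twice the larger
   SD are over-split and are merged by refitting the window with one fewer
   component;
3. cluster size > 20 members.

Each surviving component is then individually fitted with a Gaussian
regression on its binned delta masses, yielding the reported peak value
(clustered delta mass), standard deviation, and goodness-of-fit R^2.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit
from sklearn.mixture import GaussianMixture

log = logging.getLogger(__name__)

WINDOW_MIN = -200
WINDOW_MAX = 1000
SD_FLOOR = 1e-5  # Da; prevents singular components on duplicate-valued deltas


@dataclass
class ClusterParams:
    """Tunables of the window-clustering stage."""

    max_k: int = 5
    min_cluster_size: int = 20     # strict: size must exceed this
    min_half_width_ppm: float = 1.0
    merge_width_factor: float = 2.0
    bin_width: float = 0.001       # Da, histogram bins for the regression
    window_min: int = WINDOW_MIN
    window_max: int = WINDOW_MAX


@dataclass
class MixtureComponent:
    mean: float
    sd: float
    weight: float
    members: np.ndarray = field(repr=False)  # indices into the window's observations

    @property
    def size(self) -> int:
        return len(self.members)


@dataclass
class WindowFitResult:
    """Mixture fit of one 1-Da window: BIC trace and selected components."""

    window_n: int
    k_candidates: list[int]
    bic_per_k: list[float]  # negated sklearn BIC: larger = stronger model
    k_selected: int
    components: list[MixtureComponent]


@dataclass
class DeltaCluster:
    """One accepted delta-mass cluster with its regression diagnostics."""

    cluster_id: str
    window_n: int
    peak: float
    sd: float
    r2: float
    size: int
    members: np.ndarray = field(repr=False)  # row positions in the observation table
    residue_composition: dict[str, float] = field(default_factory=dict)
    dominant_residue: str = ""
    dominant_fraction: float = 0.0
    half_width_ppm: float = np.nan
    median_peptide_mass: float = np.nan
    degenerate: bool = False

    def as_row(self) -> dict:
        return {
            "cluster_id": self.cluster_id,
            "window_n": self.window_n,
            "peak": self.peak,
            "sd": self.sd,
            "r2": self.r2,
            "size": self.size,
            "dominant_residue": self.dominant_residue,
            "dominant_fraction": self.dominant_fraction,
            "half_width_ppm": self.half_width_ppm,
        }


def assign_windows(obs: pd.DataFrame, window_min: int = WINDOW_MIN,
                   window_max: int = WINDOW_MAX) -> pd.DataFrame:
    """Attach the 1-Da window index n (interval [n-0.5, n+0.5), half-open).

    Observations outside [window_min - 0.5, window_max + 0.5) are excluded
    and reported; the survivors are returned with a ``window_n`` column.
    """
    n = np.floor(obs["delta_mass_raw"].to_numpy() + 0.5).astype(int)
    in_range = (n >= window_min) & (n <= window_max)
    n_out = int((~in_range).sum())
    if n_out:
        log.warning("assign_windows: %d observation(s) outside [%d, %d] Da excluded",
                    n_out, window_min, window_max)
    out = obs.loc[in_range].copy()
    out["window_n"] = n[in_range]
    return out


def _fit_gmm(x: np.ndarray, k: int, seed: int) -> GaussianMixture:
    return GaussianMixture(
        n_components=k, covariance_type="full", reg_covar=SD_FLOOR ** 2,
        n_init=10, init_params="k-means++", random_state=seed,
        tol=1e-3, max_iter=200,
    ).fit(x.reshape(-1, 1))


def _components_from(gmm: GaussianMixture, x: np.ndarray) -> list[MixtureComponent]:
    labels = gmm.predict(x.reshape(-1, 1))
    comps = []
    order = np.argsort(gmm.means_.ravel())
    for c in order:
        members = np.nonzero(labels == c)[0]
        sd = max(float(np.sqrt(gmm.covariances_[c].ravel()[0])), SD_FLOOR)
        comps.append(MixtureComponent(
            mean=float(gmm.means_[c, 0]), sd=sd,
            weight=float(gmm.weights_[c]), members=members))
    return comps


def fit_window_gmm(deltas: np.ndarray, window_n: int, max_k: int = 5,
                   seed: int = 0, min_per_component: int = 20) -> WindowFitResult:
    """Fit Gaussian mixtures for k = 1..min(max_k, n_obs // 20) (at least
    k = 1) and select k by BIC; ties break toward fewer components.

    Each observation is assigned to its maximum-responsibility component.
    Deterministic for a fixed seed.  Requires >= 2 observations.
    """
    x = np.asarray(deltas, dtype=float)
    if len(x) < 2:
        raise ValueError(f"window {window_n}: need >= 2 observations, got {len(x)}")
    if max_k < 1:
        raise ValueError("max_k must be >= 1")
    k_hi = max(1, min(max_k, len(x) // min_per_component))
    ks, bics, gmms = [], [], []
    for k in range(1, k_hi + 1):
        gmm = _fit_gmm(x, k, seed)
        ks.append(k)
        bics.append(-float(gmm.bic(x.reshape(-1, 1))))  # larger = stronger
        gmms.append(gmm)
    best = int(np.argmax(bics))  # first max -> smallest k on ties
    return WindowFitResult(
        window_n=window_n, k_candidates=ks, bic_per_k=bics,
        k_selected=ks[best], components=_components_from(gmms[best], x))


def gaussian_regression(deltas: np.ndarray, bin_width: float = 0.001):
    """Least-squares Gaussian fit to the binned delta masses.

    Histograms the members at ``bin_width``, fits amplitude/mean/SD to the
    bin counts and returns (peak, sd, r2) with r2 = 1 - SS_res/SS_tot over
    bins (clipped to [0, 1]).  Degenerate inputs (fewer than 3 occupied
    bins) or a non-convergent fit fall back to the sample mean and a floored
    sample SD with r2 = 0, flagging the cluster unfit.
    """
    x = np.asarray(deltas, dtype=float)
    if len(x) < 21:
        raise ValueError(f"gaussian_regression needs >= 21 members, got {len(x)}")
    mean, std = float(np.mean(x)), float(np.std(x))
    fallback = (mean, max(std, SD_FLOOR), 0.0)
    lo, hi = x.min() - bin_width, x.max() + bin_width
    edges = np.arange(lo, hi + bin_width, bin_width)
    if len(edges) < 4:
        return fallback
    counts, edges = np.histogram(x, bins=edges)
    centers = (edges[:-1] + edges[1:]) / 2
    if int((counts > 0).sum()) < 3:
        return fallback

    def gauss(t, a, mu, sigma):
        return a * np.exp(-0.5 * ((t - mu) / sigma) ** 2)

    try:
        popt, _ = curve_fit(
            gauss, centers, counts,
            p0=(float(counts.max()), mean, max(std, bin_width / 2)),
            bounds=([0.0, lo, SD_FLOOR], [np.inf, hi, hi - lo + bin_width]),
            maxfev=10000)
    except RuntimeError:
        return fallback
    fitted = gauss(centers, *popt)
    ss_res = float(np.sum((counts - fitted) ** 2))
    ss_tot = float(np.sum((counts - counts.mean()) ** 2))
    if ss_tot == 0:
        return fallback
    r2 = float(np.clip(1.0 - ss_res / ss_tot, 0.0, 1.0))
    return float(popt[1]), float(abs(popt[2])), r2


def apply_cluster_constraints(fit: WindowFitResult, deltas: np.ndarray,
                              peptide_masses: np.ndarray,
                              params: ClusterParams | None = None,
                              seed: int = 0) -> list[DeltaCluster]:
    """Constrain mixture components and regress the survivors.

    First, adjacent components whose mean separation is <= ``merge_width_factor``
    times the larger SD are merged by refitting the window with k - 1
    components (repeated until no pair violates).  Then components with
    size <= ``min_cluster_size`` or fitted half-width <= ``min_half_width_ppm``
    (SD in ppm of the members' median peptide mass) are dropped.  Survivors
    get Gaussian-regression diagnostics and become :class:`DeltaCluster`s.
    Cluster ids are assigned by :func:`cluster_observations`.
    """
    params = params or ClusterParams()
    x = np.asarray(deltas, dtype=float)
    pm = np.asarray(peptide_masses, dtype=float)
    comps = sorted(fit.components, key=lambda c: c.mean)
    k = len(comps)
    while k > 1:
        too_close = any(
            (b.mean - a.mean) <= params.merge_width_factor * max(a.sd, b.sd)
            for a, b in zip(comps[:-1], comps[1:]))
        if not too_close:
            break
        k -= 1
        comps = sorted(_components_from(_fit_gmm(x, k, seed), x),
                       key=lambda c: c.mean)
    clusters = []
    for comp in comps:
        if comp.size <= params.min_cluster_size:
            continue
        med_mass = float(np.median(pm[comp.members]))
        half_width_ppm = comp.sd / med_mass * 1e6
        if half_width_ppm <= params.min_half_width_ppm:
            continue
        peak, sd, r2 = gaussian_regression(x[comp.members], params.bin_width)
        clusters.append(DeltaCluster(
            cluster_id="", window_n=fit.window_n,
            peak=peak, sd=sd, r2=r2, size=comp.size, members=comp.members,
            half_width_ppm=half_width_ppm, median_peptide_mass=med_mass,
            degenerate=(r2 == 0.0)))
    return clusters


def cluster_observations(obs: pd.DataFrame, params: ClusterParams | None = None,
                         seed: int = 0):
    """Run the full windowing + clustering stage over an observation table.

    Returns (clusters, report): accepted clusters with ids C0001..., whose
    ``members`` index rows of ``obs`` (positional), and a per-window report
    of BIC traces and skip diagnostics.
    """
    params = params or ClusterParams()
    obs = obs.reset_index(drop=True)
    windowed = assign_windows(obs, params.window_min, params.window_max)
    report = {"windows": {}, "n_out_of_range": len(obs) - len(windowed)}
    clusters: list[DeltaCluster] = []
    for n, sub in windowed.groupby("window_n", sort=True):
        idx = sub.index.to_numpy()
        if len(idx) <= params.min_cluster_size:
            report["windows"][int(n)] = {"n_obs": len(idx), "skipped": "too few observations"}
            continue
        deltas = sub["delta_mass_raw"].to_numpy()
        fit = fit_window_gmm(deltas, int(n), params.max_k, seed,
                             min_per_component=params.min_cluster_size)
        found = apply_cluster_constraints(fit, deltas,
                                          sub["peptide_mass"].to_numpy(),
                                          params, seed)
        for c in found:
            c.members = idx[c.members]  # window-local -> table positions
            residues = obs.loc[c.members, "residue"]
            comp = (residues.value_counts() / len(residues))
            c.residue_composition = comp.to_dict()
            c.dominant_residue = comp.index[0]
            c.dominant_fraction = float(comp.iloc[0])
        clusters.extend(found)
        report["windows"][int(n)] = {
            "n_obs": len(idx),
            "k_candidates": fit.k_candidates,
            "bic_per_k": fit.bic_per_k,
            "k_selected": fit.k_selected,
            "n_clusters_accepted": len(found),
        }
    for i, c in enumerate(sorted(clusters, key=lambda c: (c.window_n, c.peak)), 1):
        c.cluster_id = f"C{i:04d}"
    clusters.sort(key=lambda c: c.cluster_id)
    return clusters, report


def cluster_table(clusters) -> pd.DataFrame:
    cols = ["cluster_id", "window_n", "peak", "sd", "r2", "size",
            "dominant_residue", "dominant_fraction", "half_width_ppm"]
    if not clusters:
        return pd.DataFrame(columns=cols)
    return pd.DataFrame([c.as_row() for c in clusters])[cols]
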