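"""Per-species establishment-class profiles and gap-statistic K-means.

Each species is summarised by a 4-vector ordered (Y1978, Y2003, Y2011,
Y2014): the mean, over the sites of each deer-establishment class, of a
site-level statistic — summed plot cover, mean damage grade, or mean
per-sample read proportion. K-means groups species with similar profile
shapes; the number of clusters is chosen by the gap statistic, comparing
log within-cluster dispersion with its expectation under uniform reference
data drawn over each dimension's observed range.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

from .datamodel import CLASS_ORDER, CoverageTable, EstablishmentClass, ReadTable, Site
from .barcoding import proportions

__all__ = [
    "ClusteringOutcome",
    "build_profiles",
    "scale_profiles",
    "kmeans",
    "gap_statistic",
    "cluster_profiles",
]

PROFILE_COLUMNS = [c.name for c in CLASS_ORDER]


@dataclass
class ClusteringOutcome:
    chosen_k: int
    labels: pd.Series  # species -> 1..k
    centers: np.ndarray  # k x 4, on the scaled axes
    W_k: np.ndarray  # within-cluster dispersion for k = 1..kmax
    gap: np.ndarray
    s_k: np.ndarray
    scale: str
    profiles: pd.DataFrame  # unscaled species x class profiles

    @property
    def cluster_profiles(self) -> pd.DataFrame:
        """Mean unscaled profile of each cluster (for interpretation)."""
        return self.profiles.groupby(self.labels).mean()


def _sites_by_class(sites: dict[str, Site]) -> dict[EstablishmentClass, list[str]]:
    by = {c: [] for c in CLASS_ORDER}
    for sid, site in sites.items():
        by[site.establishment].append(sid)
    empty = [c.name for c, ss in by.items() if not ss]
    if empty:
        raise ValueError(f"establishment class(es) without sites: {empty}")
    return by


def build_profiles(
    source: str,
    data,
    sites: dict[str, Site],
    presence_filter: bool = True,
) -> pd.DataFrame:
    """Species x class profile matrix from one evidence stream.

    source='coverage': ``data`` is a CoverageTable; the site statistic is
    cover summed over the 20 plots, and a site where the species was not
    recorded contributes 0.  source='mdg': ``data`` is the species x site
    MDG matrix; unsampled cells are excluded from the class mean (absence of
    a survey is not absence of damage).  source='reads': ``data`` is a
    ReadTable; per-sample proportions are averaged within a site, then over
    the sites of each class; the presence filter is not applied (all
    detected taxa are retained).

    ``presence_filter`` keeps only species observed in at least one site of
    every establishment class.
    """
    by_class = _sites_by_class(sites)

    if source == "coverage":
        if not isinstance(data, CoverageTable):
            raise TypeError("coverage source expects a CoverageTable")
        site_mat = data.site_totals()  # site x species, zeros where absent
        site_mat = site_mat.reindex(index=sorted(sites), fill_value=0)
        prof = {}
        for cls in CLASS_ORDER:
            prof[cls.name] = site_mat.loc[by_class[cls]].mean(axis=0)
        profiles = pd.DataFrame(prof)
        if presence_filter:
            keep = pd.Series(True, index=profiles.index)
            for cls in CLASS_ORDER:
                present = (site_mat.loc[by_class[cls]] > 0).any(axis=0)
                keep &= present
            profiles = profiles.loc[keep]
    elif source == "mdg":
        mat = data  # species x site, NaN = unsampled
        prof = {}
        for cls in CLASS_ORDER:
            cols = [s for s in by_class[cls] if s in mat.columns]
            prof[cls.name] = mat[cols].mean(axis=1) if cols else np.nan
        profiles = pd.DataFrame(prof)
        if presence_filter:
            keep = pd.Series(True, index=profiles.index)
            for cls in CLASS_ORDER:
                cols = [s for s in by_class[cls] if s in mat.columns]
                keep &= mat[cols].notna().any(axis=1) if cols else False
            profiles = profiles.loc[keep]
        profiles = profiles.fillna(0.0)
    elif source == "reads":
        if not isinstance(data, ReadTable):
            raise TypeError("reads source expects a ReadTable")
        prop = proportions(data)
        site_of = pd.Series({s: data.sample_sites[s] for s in prop.index})
        site_means = prop.groupby(site_of).mean()  # site x taxon
        prof = {}
        for cls in CLASS_ORDER:
            rows = [s for s in by_class[cls] if s in site_means.index]
            if not rows:
                raise ValueError(f"no fecal samples in class {cls.name}")
            prof[cls.name] = site_means.loc[rows].mean(axis=0)
        profiles = pd.DataFrame(prof)
    else:
        raise ValueError(f"unknown profile source: {source!r}")

    profiles = profiles[PROFILE_COLUMNS].sort_index()
    profiles.index.name = "species_id"
    return profiles.astype(float)


def scale_profiles(profiles: pd.DataFrame, mode: str = "max") -> pd.DataFrame:
    """Scale each species' 4-vector before clustering.

    'max' divides by the row maximum so clusters capture the shape of
    variation across classes rather than overall abundance; 'z' row
    z-scores; 'raw' leaves values untouched. All-zero (or constant, for
    'z') rows map to zeros.
    """
    X = profiles.to_numpy(dtype=float)
    if mode == "raw":
        out = X
    elif mode == "max":
        m = X.max(axis=1, keepdims=True)
        out = np.divide(X, m, out=np.zeros_like(X), where=m > 0)
    elif mode == "z":
        mu = X.mean(axis=1, keepdims=True)
        sd = X.std(axis=1, keepdims=True)
        out = np.divide(X - mu, sd, out=np.zeros_like(X), where=sd > 0)
    else:
        raise ValueError(f"unknown scaling mode: {mode!r}")
    return pd.DataFrame(out, index=profiles.index, columns=profiles.columns)


def kmeans(
    X: np.ndarray, k: int, seed: int | None = None, n_init: int = 10
) -> tuple[np.ndarray, np.ndarray, float]:
    """K-means (k-means++ starts, best of n_init by within-cluster SS).

    Returns (labels 0..k-1, centers, W = total within-cluster sum of
    squares)."""
    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    if not 1 <= k <= n:
        raise ValueError(f"k must lie in 1..{n}, got {k}")
    if k == 1:
        center = X.mean(axis=0, keepdims=True)
        w = float(((X - center) ** 2).sum())
        return np.zeros(n, dtype=int), center, w
    km = KMeans(n_clusters=k, n_init=n_init, random_state=_seed32(seed)).fit(X)
    return km.labels_, km.cluster_centers_, float(km.inertia_)


def _seed32(seed):
    return None if seed is None else int(np.random.default_rng(seed).integers(2**31 - 1))


def gap_statistic(
    X: np.ndarray,
    kmax: int = 6,
    B: int = 50,
    seed: int | None = None,
    n_init: int = 10,
) -> tuple[int, np.ndarray, np.ndarray, np.ndarray]:
    """Choose the cluster count by the gap statistic.

    Gap(k) = mean_b log W*_kb - log W_k over B uniform reference sets drawn
    over each dimension's observed range; s_k = sd_b(log W*_kb) *
    sqrt(1 + 1/B). The chosen k is the smallest with
    Gap(k) >= Gap(k+1) - s_{k+1} (kmax if none qualifies).

    Returns (chosen_k, W_k, gap, s_k) with arrays indexed k = 1..kmax.
    """
    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    if not 1 <= kmax < n:
        raise ValueError("kmax must satisfy 1 <= kmax < n")
    if B < 10:
        raise ValueError("B must be at least 10")
    if np.allclose(X, X[0]):
        return 1, np.zeros(kmax), np.zeros(kmax), np.zeros(kmax)

    rng = np.random.default_rng(seed)
    lo, hi = X.min(axis=0), X.max(axis=0)

    log_w = np.empty(kmax)
    for k in range(1, kmax + 1):
        _, _, w = kmeans(X, k, seed=rng.integers(2**31 - 1), n_init=n_init)
        log_w[k - 1] = np.log(max(w, 1e-300))

    log_w_ref = np.empty((B, kmax))
    for b in range(B):
        ref = rng.uniform(lo, hi, size=X.shape)
        for k in range(1, kmax + 1):
            _, _, w = kmeans(ref, k, seed=rng.integers(2**31 - 1), n_init=n_init)
            log_w_ref[b, k - 1] = np.log(max(w, 1e-300))

    gap = log_w_ref.mean(axis=0) - log_w
    s_k = log_w_ref.std(axis=0, ddof=0) * np.sqrt(1 + 1 / B)

    chosen = kmax
    for k in range(1, kmax):
        if gap[k - 1] >= gap[k] - s_k[k]:
            chosen = k
            break
    return chosen, np.exp(log_w), gap, s_k


def cluster_profiles(
    profiles: pd.DataFrame,
    kmax: int = 6,
    B: int = 50,
    seed: int | None = None,
    scale: str = "max",
    k: int | None = None,
    n_init: int = 10,
) -> ClusteringOutcome:
    """Scale profiles, pick k by the gap statistic (unless fixed), and
    cluster. Cluster labels run 1..k."""
    scaled = scale_profiles(profiles, scale)
    X = scaled.to_numpy()
    kmax_eff = min(kmax, len(profiles) - 1) if len(profiles) > 1 else 1
    if k is None:
        chosen, W_k, gap, s_k = gap_statistic(X, kmax=kmax_eff, B=B, seed=seed, n_init=n_init)
    else:
        chosen = k
        W_k = np.array([kmeans(X, kk, seed=seed, n_init=n_init)[2] for kk in range(1, kmax_eff + 1)])
        gap = np.full(kmax_eff, np.nan)
        s_k = np.full(kmax_eff, np.nan)
    labels, centers, _ = kmeans(X, chosen, seed=seed, n_init=n_init)
    return ClusteringOutcome(
        chosen_k=chosen,
        labels=pd.Series(labels + 1, index=profiles.index, name="cluster"),
        centers=centers,
        W_k=np.asarray(W_k),
        gap=gap,
        s_k=s_k,
        scale=scale,
        profiles=profiles,
    )
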