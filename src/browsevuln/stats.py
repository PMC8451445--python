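"""Community statistics used across the three analysis arms.

All multivariate tests operate on Bray-Curtis dissimilarities. PERMANOVA
partitions the distance matrix's sums of squares for a single factor and
obtains its p-value by permuting group labels — optionally restricted to
within-stratum shuffles when observations are blocked (here: fecal samples
blocked by site). Ordination is non-metric MDS minimising Kruskal stress-1.
Spatial structure is screened with distance-based Moran's eigenvector maps
(dbMEM). Univariate responses (species richness, Shannon diversity, read
proportions) are compared across establishment classes with GLMs and
likelihood-ratio tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, sparse, stats as sps
from scipy.special import gammaln
from scipy.spatial.distance import pdist, squareform
from scipy.sparse.csgraph import minimum_spanning_tree
from sklearn.isotonic import IsotonicRegression
from sklearn.manifold import smacof
import statsmodels.api as sm

from .datamodel import CoverageTable

__all__ = [
    "DistanceMatrix",
    "PermanovaResult",
    "OrdinationResult",
    "GlmFit",
    "richness",
    "shannon",
    "bray_curtis",
    "permutation_indices",
    "permanova",
    "permdisp",
    "kruskal_stress1",
    "nmds",
    "dbmem",
    "dbmem_test",
    "glm_fit",
    "lrt",
    "glmm_poisson_laplace",
]


# ---------------------------------------------------------------------------
# containers


@dataclass
class DistanceMatrix:
    """Symmetric dissimilarity matrix with item labels."""

    values: np.ndarray
    labels: list[str]

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("distance matrix must be square")
        if not np.allclose(v, v.T):
            raise ValueError("distance matrix must be symmetric")
        if not np.allclose(np.diag(v), 0):
            raise ValueError("distance matrix must have a zero diagonal")
        self.values = v
        self.labels = [str(x) for x in self.labels]
        if len(self.labels) != v.shape[0]:
            raise ValueError("label count must match matrix size")

    def __len__(self) -> int:
        return self.values.shape[0]


@dataclass
class PermanovaResult:
    pseudo_F: float
    R2: float
    p_value: float
    n_permutations: int
    scheme: str


@dataclass
class OrdinationResult:
    coords: np.ndarray
    stress: float
    n_starts: int
    converged: bool
    labels: list[str] = field(default_factory=list)


@dataclass
class GlmFit:
    params: np.ndarray
    llf: float
    family: str
    link: str
    df_model: int
    nobs: int


# ---------------------------------------------------------------------------
# diversity


def richness(coverage: CoverageTable, site_id: str) -> int:
    """Number of species recorded in any plot of the site."""
    sub = coverage.df[coverage.df["site_id"] == site_id]
    return int(sub["species_id"].nunique())


def shannon(coverage: CoverageTable, site_id: str) -> float:
    """Shannon-Wiener H' (natural log) on summed plot cover per species."""
    sub = coverage.df[coverage.df["site_id"] == site_id]
    if sub.empty:
        raise ValueError(f"site {site_id}: no records, Shannon undefined")
    totals = sub.groupby("species_id")["coverage"].sum().to_numpy(dtype=float)
    p = totals / totals.sum()
    return float(-(p * np.log(p)).sum())


# ---------------------------------------------------------------------------
# dissimilarity


def bray_curtis(abundance: pd.DataFrame) -> DistanceMatrix:
    """Bray-Curtis dissimilarity between rows: sum|x-y| / sum(x+y)."""
    X = abundance.to_numpy(dtype=float)
    if (X < 0).any():
        raise ValueError("Bray-Curtis needs non-negative abundances")
    row_sums = X.sum(axis=1)
    zero = np.flatnonzero(row_sums == 0)
    if len(zero) >= 2:
        raise ValueError(
            f"rows {list(abundance.index[zero])} are all zero; their mutual "
            "dissimilarity is undefined"
        )
    D = squareform(pdist(X, metric="braycurtis"))
    return DistanceMatrix(D, list(abundance.index.astype(str)))


# ---------------------------------------------------------------------------
# PERMANOVA and dispersion


def permutation_indices(
    n: int,
    n_perm: int,
    rng: np.random.Generator,
    strata: np.ndarray | None = None,
) -> np.ndarray:
    """(n_perm, n) permutation index arrays; with strata, each permutation
    rearranges positions only inside their own stratum."""
    if strata is None:
        return np.array([rng.permutation(n) for _ in range(n_perm)])
    strata = np.asarray(strata)
    out = np.tile(np.arange(n), (n_perm, 1))
    for s in np.unique(strata):
        pos = np.flatnonzero(strata == s)
        for b in range(n_perm):
            out[b, pos] = pos[rng.permutation(len(pos))]
    return out


def _ss_partition(sq: np.ndarray, labels: np.ndarray) -> tuple[float, float]:
    """(SS_total, SS_within) from the squared-distance matrix via the
    Gower identity SS = sum of squared within-set distances / set size."""
    n = sq.shape[0]
    ss_total = sq.sum() / (2 * n)
    ss_within = 0.0
    for g in np.unique(labels):
        idx = np.flatnonzero(labels == g)
        ss_within += sq[np.ix_(idx, idx)].sum() / (2 * len(idx))
    return ss_total, ss_within


def permanova(
    D: DistanceMatrix,
    groups,
    strata=None,
    n_perm: int = 999,
    seed: int | None = None,
    exhaustive: bool = False,
) -> PermanovaResult:
    """One-factor PERMANOVA with optional restricted (within-block)
    permutations.

    pseudo-F = (SS_between/(a-1)) / (SS_within/(n-a)); R^2 = SS_between /
    SS_total; p = (1 + #{F_perm >= F_obs}) / (1 + n_perm). With
    ``exhaustive=True`` (n <= 8, no strata) every one of the n! label
    permutations is evaluated and p = #{F_perm >= F_obs} / n!, the identity
    permutation included.
    """
    labels = np.asarray(groups)
    n = len(D)
    if len(labels) != n:
        raise ValueError("one group label per item required")
    uniq = np.unique(labels)
    a = len(uniq)
    if a < 2:
        raise ValueError("PERMANOVA needs at least two groups")
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    strata_arr = None if strata is None else np.asarray(strata)
    if strata_arr is not None and len(strata_arr) != n:
        raise ValueError("one stratum per item required")

    sq = D.values**2
    ss_total, ss_within = _ss_partition(sq, labels)
    ss_between = ss_total - ss_within
    f_obs = (ss_between / (a - 1)) / (ss_within / (n - a))
    r2 = ss_between / ss_total

    if exhaustive:
        if strata_arr is not None:
            raise ValueError("exhaustive enumeration does not support strata")
        if n > 8:
            raise ValueError("exhaustive enumeration is limited to n <= 8")
        import itertools

        count = total = 0
        for perm in itertools.permutations(range(n)):
            _, ss_w = _ss_partition(sq, labels[list(perm)])
            f_perm = ((ss_total - ss_w) / (a - 1)) / (ss_w / (n - a))
            count += f_perm >= f_obs - 1e-12
            total += 1
        return PermanovaResult(
            float(f_obs), float(r2), count / total, total, "exhaustive"
        )

    rng = np.random.default_rng(seed)
    perms = permutation_indices(n, n_perm, rng, strata_arr)
    count = 0
    for perm in perms:
        _, ss_w = _ss_partition(sq, labels[perm])
        ss_b = ss_total - ss_w
        f_perm = (ss_b / (a - 1)) / (ss_w / (n - a))
        if f_perm >= f_obs - 1e-12:
            count += 1
    p = (1 + count) / (1 + n_perm)
    scheme = "free" if strata_arr is None else "within-strata"
    return PermanovaResult(float(f_obs), float(r2), float(p), n_perm, scheme)


def _pcoa_axes(D: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Eigen-decomposition of the Gower-centred matrix -1/2 J D^2 J.

    Returns (eigenvalues desc, eigenvectors as columns)."""
    n = D.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    G = -0.5 * J @ (D**2) @ J
    w, V = np.linalg.eigh((G + G.T) / 2)
    order = np.argsort(w)[::-1]
    return w[order], V[:, order]


def permdisp(
    D: DistanceMatrix,
    groups,
    n_perm: int = 999,
    seed: int | None = None,
) -> tuple[float, float]:
    """Test homogeneity of multivariate dispersion around group centroids.

    Items are embedded by principal coordinates; axes with negative
    eigenvalues act as imaginary components, so the squared distance to a
    centroid is the real-part contribution minus the imaginary-part one
    (clipped at zero). A one-way F on those distances is assessed by
    permuting the distances across groups.
    """
    labels = np.asarray(groups)
    n = len(D)
    w, V = _pcoa_axes(D.values)
    keep = np.abs(w) > 1e-10 * max(1.0, np.abs(w).max())
    w, V = w[keep], V[:, keep]
    axes = V * np.sqrt(np.abs(w))
    is_real = w > 0

    z = np.empty(n)
    for g in np.unique(labels):
        idx = np.flatnonzero(labels == g)
        centroid = axes[idx].mean(axis=0)
        diff2 = (axes[idx] - centroid) ** 2
        d2 = diff2[:, is_real].sum(axis=1) - diff2[:, ~is_real].sum(axis=1)
        z[idx] = np.sqrt(np.clip(d2, 0, None))

    def anova_f(values: np.ndarray) -> float:
        grand = values.mean()
        ssb = sum(
            len(idx) * (values[idx].mean() - grand) ** 2
            for g in np.unique(labels)
            for idx in [np.flatnonzero(labels == g)]
        )
        ssw = sum(
            ((values[idx] - values[idx].mean()) ** 2).sum()
            for g in np.unique(labels)
            for idx in [np.flatnonzero(labels == g)]
        )
        a = len(np.unique(labels))
        # sums of squares at machine-noise scale mean "no signal", not a
        # huge (or tiny) F from a ratio of rounding errors
        scale = (values**2).mean() + 1e-300
        if ssb <= 1e-12 * scale:
            return 0.0
        if ssw <= 1e-12 * scale:
            return np.inf
        return (ssb / (a - 1)) / (ssw / (n - a))

    f_obs = anova_f(z)
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        if anova_f(z[rng.permutation(n)]) >= f_obs - 1e-12:
            count += 1
    return float(f_obs), (1 + count) / (1 + n_perm)


# ---------------------------------------------------------------------------
# NMDS


def kruskal_stress1(D: DistanceMatrix, coords: np.ndarray) -> float:
    """Kruskal stress-1 of a configuration against observed dissimilarities:
    sqrt(sum (dhat - d*)^2 / sum dhat^2), with d* the isotonic regression of
    configuration distances on the observed ranks (primary tie treatment)."""
    obs = squareform(D.values, checks=False)
    dhat = pdist(coords)
    iso = IsotonicRegression()
    dstar = iso.fit_transform(obs, dhat)
    denom = (dhat**2).sum()
    if denom == 0:
        return 0.0
    return float(np.sqrt(((dhat - dstar) ** 2).sum() / denom))


def nmds(
    D: DistanceMatrix,
    k: int = 2,
    n_starts: int = 20,
    max_iter: int = 300,
    tol: float = 1e-7,
    seed: int | None = None,
) -> OrdinationResult:
    """Non-metric MDS in k dimensions, best of ``n_starts`` runs.

    The first start is the metric principal-coordinate configuration; the
    remaining starts jitter it with Gaussian noise. Each run uses SMACOF
    majorisation with monotone (isotonic) regression of distances on ranks;
    the reported stress is Kruskal stress-1 of the best configuration.
    """
    n = len(D)
    if n < k + 1:
        raise ValueError("need at least k+1 items for a k-dimensional NMDS")
    w, V = _pcoa_axes(D.values)
    base = V[:, :k] * np.sqrt(np.clip(w[:k], 0, None))
    rng = np.random.default_rng(seed)
    scale = max(base.std(), 1e-6)

    best: tuple[float, np.ndarray, bool] | None = None
    for s in range(n_starts):
        init = base if s == 0 else base + rng.normal(0, 0.3 * scale, size=base.shape)
        coords, _, n_iter = smacof(
            D.values,
            metric=False,
            n_components=k,
            init=init,
            n_init=1,
            max_iter=max_iter,
            eps=tol,
            normalized_stress=True,
            return_n_iter=True,
        )
        stress = kruskal_stress1(D, coords)
        converged = n_iter < max_iter
        if best is None or stress < best[0]:
            best = (stress, coords, converged)
    stress, coords, converged = best
    return OrdinationResult(coords, float(stress), n_starts, converged, list(D.labels))


# ---------------------------------------------------------------------------
# dbMEM


def dbmem(coords: np.ndarray) -> tuple[pd.DataFrame, np.ndarray]:
    """Distance-based Moran's eigenvector maps from planar coordinates.

    The inter-site distance matrix is truncated at the longest edge of its
    minimum spanning tree; larger distances are replaced by four times the
    threshold. Principal coordinates of the truncated matrix with positive
    eigenvalues are the spatial eigenvectors (broad- to fine-scale).
    """
    coords = np.asarray(coords, dtype=float)
    n = coords.shape[0]
    if n < 3:
        raise ValueError("dbMEM needs at least three sites")
    D = squareform(pdist(coords))
    if (D[np.triu_indices(n, 1)] == 0).any():
        raise ValueError("duplicate coordinates are not allowed")
    mst = minimum_spanning_tree(sparse.csr_matrix(D))
    threshold = mst.toarray().max()
    Dt = np.where(D > threshold, 4 * threshold, D)
    np.fill_diagonal(Dt, 0)
    w, V = _pcoa_axes(Dt)
    pos = w > 1e-9 * np.abs(w).max()
    vectors = pd.DataFrame(
        V[:, pos], columns=[f"MEM{i + 1}" for i in range(int(pos.sum()))]
    )
    return vectors, w[pos]


def dbmem_test(
    vectors: pd.DataFrame,
    response,
    coords: np.ndarray | None = None,
    n_perm: int = 999,
    seed: int | None = None,
) -> pd.DataFrame:
    """Permutation test of each spatial eigenvector against a response.

    For a univariate response the response is first detrended (OLS residuals
    on the x,y coordinates when given) and each vector's squared correlation
    with the residuals is compared with its permutation distribution. For a
    DistanceMatrix response the statistic is the fraction of the
    Gower-centred matrix's total sum of squares explained by the vector.
    """
    rng = np.random.default_rng(seed)
    out = []
    if isinstance(response, DistanceMatrix):
        n = len(response)
        J = np.eye(n) - np.ones((n, n)) / n
        G = -0.5 * J @ (response.values**2) @ J
        trace = np.trace(G)
        for name in vectors.columns:
            v = vectors[name].to_numpy()
            v = (v - v.mean()) / np.linalg.norm(v - v.mean())
            r2 = float(v @ G @ v / trace)
            count = 0
            for _ in range(n_perm):
                p = rng.permutation(n)
                if v @ G[np.ix_(p, p)] @ v / trace >= r2 - 1e-12:
                    count += 1
            out.append({"vector": name, "R2": r2, "p_value": (1 + count) / (1 + n_perm)})
    else:
        y = np.asarray(response, dtype=float)
        if coords is not None:
            X = sm.add_constant(np.asarray(coords, dtype=float))
            y = y - X @ np.linalg.lstsq(X, y, rcond=None)[0]
        y = y - y.mean()
        ss_y = (y**2).sum()
        for name in vectors.columns:
            v = vectors[name].to_numpy()
            v = v - v.mean()
            r2 = float((v @ y) ** 2 / ((v**2).sum() * ss_y))
            count = 0
            for _ in range(n_perm):
                yp = y[rng.permutation(len(y))]
                if (v @ yp) ** 2 / ((v**2).sum() * ss_y) >= r2 - 1e-12:
                    count += 1
            out.append({"vector": name, "R2": r2, "p_value": (1 + count) / (1 + n_perm)})
    return pd.DataFrame(out)


# ---------------------------------------------------------------------------
# GLM / LRT


_FAMILIES = {
    ("poisson", "log"): lambda: sm.families.Poisson(),
    ("gaussian", "identity"): lambda: sm.families.Gaussian(),
    ("gaussian", "log"): lambda: sm.families.Gaussian(sm.families.links.Log()),
}


def _design(groups, covariate=None) -> np.ndarray:
    cols = [np.ones(len(np.asarray(groups)))]
    if groups is not None:
        g = pd.Series(groups).astype("category")
        dummies = pd.get_dummies(g, drop_first=True).to_numpy(dtype=float)
        if dummies.size:
            cols.append(dummies)
    if covariate is not None:
        cols.append(np.asarray(covariate, dtype=float).reshape(len(cols[0]), -1))
    return np.column_stack(cols)


def glm_fit(
    y,
    groups=None,
    covariate=None,
    family: str = "poisson",
    link: str | None = None,
) -> GlmFit:
    """Fit a one-factor GLM (optionally with a covariate) by IRLS.

    Supported: poisson/log, gaussian/identity, gaussian/log. ``groups=None``
    fits the intercept-only null model.
    """
    y = np.asarray(y, dtype=float)
    link = link or ("log" if family == "poisson" else "identity")
    if (family, link) not in _FAMILIES:
        raise ValueError(f"unsupported family/link: {family}/{link}")
    if groups is None and covariate is None:
        X = np.ones((len(y), 1))
    else:
        X = _design(groups if groups is not None else np.zeros(len(y)), covariate)
    model = sm.GLM(y, X, family=_FAMILIES[(family, link)]())
    res = model.fit(maxiter=100, tol=1e-10)
    if not res.converged:
        raise RuntimeError("GLM did not converge in 100 IRLS iterations")
    return GlmFit(
        params=np.asarray(res.params),
        llf=float(res.llf),
        family=family,
        link=link,
        df_model=int(res.df_model),
        nobs=len(y),
    )


def lrt(full: GlmFit, null: GlmFit) -> tuple[float, int, float]:
    """Likelihood-ratio test of nested GLMs against the chi-square."""
    chi2 = max(0.0, 2.0 * (full.llf - null.llf))
    df = full.df_model - null.df_model
    if df < 1:
        raise ValueError("full model must have more parameters than the null")
    p = float(sps.chi2.sf(chi2, df))
    return float(chi2), df, p


# ---------------------------------------------------------------------------
# Poisson GLMM with Laplace approximation (fidelity mode)


def glmm_poisson_laplace(y, groups, sites) -> dict:
    """Poisson GLMM with a per-site random intercept, fitted by maximising
    the Laplace-approximated marginal likelihood.

    Returns fixed effects (treatment coding over establishment classes),
    the random-intercept standard deviation, and the marginal
    log-likelihood. With zero true between-site variance the fit shrinks to
    the plain GLM.
    """
    y = np.asarray(y, dtype=float)
    X = _design(groups)
    site_codes, site_idx = np.unique(np.asarray(sites), return_inverse=True)
    n_sites = len(site_codes)
    if n_sites < 2:
        raise ValueError("need at least two sites for a random intercept")

    def site_mode(eta_fixed_s, y_s, var):
        # Newton iterations on h(b) = sum(y*(eta+b) - exp(eta+b)) - b^2/(2 var)
        b = 0.0
        for _ in range(50):
            mu = np.exp(eta_fixed_s + b)
            grad = (y_s - mu).sum() - b / var
            hess = -mu.sum() - 1.0 / var
            step = grad / hess
            b -= step
            if abs(step) < 1e-10:
                break
        return b

    def neg_marginal_ll(theta):
        beta, log_sd = theta[:-1], theta[-1]
        var = np.exp(2 * log_sd) + 1e-12
        eta_fixed = X @ beta
        ll = 0.0
        for s in range(n_sites):
            mask = site_idx == s
            b = site_mode(eta_fixed[mask], y[mask], var)
            mu = np.exp(eta_fixed[mask] + b)
            h = (y[mask] * np.log(np.clip(mu, 1e-300, None)) - mu).sum() - b**2 / (2 * var)
            curv = mu.sum() + 1.0 / var
            ll += h - 0.5 * np.log(var * curv)
        ll -= gammaln(y + 1).sum()  # Poisson normalising constant
        return -ll

    start_glm = glm_fit(y, groups, family="poisson")
    x0 = np.concatenate([start_glm.params, [np.log(0.3)]])
    res = optimize.minimize(neg_marginal_ll, x0, method="Nelder-Mead",
                            options={"maxiter": 2000, "xatol": 1e-8, "fatol": 1e-8})
    if not res.success:
        raise RuntimeError(f"GLMM did not converge: {res.message}")
    beta = res.x[:-1]
    sd = float(np.exp(res.x[-1]))
    return {"beta": beta, "sd_site": sd, "llf": -float(res.fun)}
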