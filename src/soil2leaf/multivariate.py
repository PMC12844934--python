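"""Multivariate structure discovery: PCA + varimax, Ward HCA, stepwise LDA.

All three methods operate on an observations x variables matrix (sites or
trees in rows).  Variables are z-scored by default because concentrations,
indices and ratios live on wildly different scales; raw-covariance mode is
available for homogeneous inputs.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

__all__ = [
    "PcaResult",
    "HcaResult",
    "LdaResult",
    "pca_fit",
    "varimax_rotate",
    "hca_ward",
    "lda_stepwise",
]


def _as_matrix(data) -> np.ndarray:
    x = np.asarray(data, dtype=float)
    if x.ndim != 2:
        raise ValueError("data must be 2-D (observations x variables)")
    if np.isnan(x).any():
        raise ValueError("missing values not allowed; impute or drop first")
    return x


def _standardize(x: np.ndarray) -> np.ndarray:
    sd = x.std(axis=0, ddof=1)
    if (sd == 0).any():
        bad = np.where(sd == 0)[0].tolist()
        raise ValueError(f"constant variables at columns {bad}")
    return (x - x.mean(axis=0)) / sd


def _orient_columns(mat: np.ndarray) -> np.ndarray:
    """Flip column signs so the largest-magnitude entry of each is positive."""
    out = mat.copy()
    for j in range(out.shape[1]):
        i = int(np.argmax(np.abs(out[:, j])))
        if out[i, j] < 0:
            out[:, j] = -out[:, j]
    return out


# ---------------------------------------------------------------------------
# PCA with varimax
# ---------------------------------------------------------------------------


@dataclass
class PcaResult:
    eigenvalues: np.ndarray  # all, descending
    explained_pct: np.ndarray  # all components, pre-rotation
    loadings: np.ndarray  # variables x retained components
    scores: np.ndarray  # observations x retained components
    rotation: str
    components: np.ndarray  # variables x retained eigenvectors (unrotated)
    rotated_ssq_pct: np.ndarray | None = None  # per-factor SSQ share after rotation
    mean_: np.ndarray = field(default_factory=lambda: np.array([]))


def pca_fit(
    data,
    standardize: bool = True,
    rotate: str = "none",
    n_components: int | None = None,
) -> PcaResult:
    """Eigendecomposition of the covariance matrix of (optionally z-scored) data.

    Loadings are eigenvectors scaled by sqrt(eigenvalue); with
    ``rotate='varimax'`` the retained loading block is rotated (Kaiser
    normalized) and per-factor variance re-reported as rotated sums of
    squared loadings.
    """
    x = _as_matrix(data)
    n, p = x.shape
    if n < 2:
        raise ValueError("need at least 2 observations")
    if standardize:
        x = _standardize(x)
    mean = x.mean(axis=0)
    xc = x - mean
    cov = np.cov(xc, rowvar=False, ddof=1)
    cov = np.atleast_2d(cov)
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals = np.clip(evals[order], 0.0, None)
    evecs = evecs[:, order]
    rank = int(np.linalg.matrix_rank(cov))
    if n_components is None:
        n_components = min(rank, p)
    if n_components > rank:
        raise ValueError(f"n_components={n_components} exceeds rank {rank}")
    evecs = _orient_columns(evecs)
    keep = evecs[:, :n_components]
    lam = evals[:n_components]
    loadings = keep * np.sqrt(lam)
    scores = xc @ keep
    total = evals.sum()
    explained = 100.0 * evals / total if total > 0 else np.zeros_like(evals)
    rotated_pct = None
    if rotate == "varimax" and n_components >= 2:
        loadings = varimax_rotate(loadings, kaiser=True)
        loadings = _orient_columns(loadings)
        # scores consistent with rotated loadings (least-squares projection)
        scores = xc @ np.linalg.pinv(loadings.T)
        ssq = (loadings**2).sum(axis=0)
        rotated_pct = 100.0 * ssq / total if total > 0 else np.zeros_like(ssq)
    elif rotate not in ("none", "varimax"):
        raise ValueError(f"unknown rotation {rotate!r}")
    return PcaResult(
        eigenvalues=evals,
        explained_pct=explained,
        loadings=loadings,
        scores=scores,
        rotation=rotate if n_components >= 2 else "none",
        components=keep,
        rotated_ssq_pct=rotated_pct,
        mean_=mean,
    )


def varimax_rotate(
    loadings,
    kaiser: bool = False,
    tol: float = 1e-6,
    max_sweeps: int = 1000,
) -> np.ndarray:
    """Orthogonal varimax rotation by iterative pairwise angle optimization.

    Returns ``loadings @ R`` with R orthogonal.  ``kaiser`` normalizes rows by
    communality before rotation and restores them after.  A single-column
    input is returned unchanged.
    """
    lam = np.array(loadings, dtype=float)
    if lam.ndim != 2:
        raise ValueError("loadings must be a matrix")
    p, m = lam.shape
    if m < 2:
        return lam.copy()
    comm = np.sqrt((lam**2).sum(axis=1))
    if kaiser:
        safe = np.where(comm > 0, comm, 1.0)
        lam = lam / safe[:, None]
    for _ in range(max_sweeps):
        max_angle = 0.0
        for j, l in itertools.combinations(range(m), 2):
            x, y = lam[:, j], lam[:, l]
            u = x * x - y * y
            v = 2.0 * x * y
            a, b = u.sum(), v.sum()
            c = (u * u - v * v).sum()
            d = 2.0 * (u * v).sum()
            num = d - 2.0 * a * b / p
            den = c - (a * a - b * b) / p
            phi = 0.25 * math.atan2(num, den)
            if abs(phi) > 1e-15:
                cs, sn = math.cos(phi), math.sin(phi)
                xj = cs * x + sn * y
                yl = -sn * x + cs * y
                lam[:, j], lam[:, l] = xj, yl
            max_angle = max(max_angle, abs(phi))
        if max_angle < tol:
            break
    if kaiser:
        lam = lam * np.where(comm > 0, comm, 1.0)[:, None]
    return lam


# ---------------------------------------------------------------------------
# Ward hierarchical clustering
# ---------------------------------------------------------------------------


@dataclass
class HcaResult:
    merge_history: list[tuple[int, int, float, int]]  # (a, b, height, new size)
    n_obs: int
    labels: list[str]

    def labels_at(self, k: int) -> np.ndarray:
        """Flat cluster assignment (0..k-1) after cutting to k clusters."""
        if not (1 <= k <= self.n_obs):
            raise ValueError(f"k must be in [1, {self.n_obs}]")
        parent = list(range(self.n_obs + len(self.merge_history)))

        def find(i: int) -> int:
            while parent[i] != i:
                parent[i] = parent[parent[i]]
                i = parent[i]
            return i

        for step, (a, b, _, _) in enumerate(self.merge_history[: self.n_obs - k]):
            new = self.n_obs + step
            parent[find(a)] = new
            parent[find(b)] = new
        roots = {}
        out = np.empty(self.n_obs, dtype=int)
        for i in range(self.n_obs):
            r = find(i)
            if r not in roots:
                roots[r] = len(roots)
            out[i] = roots[r]
        return out


def hca_ward(data, standardize: bool = True, labels=None) -> HcaResult:
    """Agglomerative Ward clustering via the Lance-Williams update.

    Squared Euclidean distances are maintained internally; reported heights
    are on the (unsquared) distance scale, matching standard dendrograms.
    Merged cluster ids follow the convention original points = 0..n-1, the
    cluster formed at step t = n + t.
    """
    x = _as_matrix(data)
    n = x.shape[0]
    if n < 2:
        raise ValueError("need at least 2 observations")
    if labels is None:
        labels = [str(i) for i in range(n)]
    if len(set(labels)) != n:
        raise ValueError("duplicate observation ids")
    if standardize:
        x = _standardize(x)

    d2 = ((x[:, None, :] - x[None, :, :]) ** 2).sum(axis=2)
    active: dict[int, int] = {i: 1 for i in range(n)}  # id -> size
    index: dict[int, int] = {i: i for i in range(n)}  # id -> row in d2
    merges: list[tuple[int, int, float, int]] = []
    next_id = n
    for _ in range(n - 1):
        ids = sorted(active)
        best = None
        for ai, bi in itertools.combinations(ids, 2):
            dd = d2[index[ai], index[bi]]
            if best is None or dd < best[0] - 1e-15:
                best = (dd, ai, bi)
        dd, ai, bi = best
        na, nb = active[ai], active[bi]
        merges.append((ai, bi, math.sqrt(max(dd, 0.0)), na + nb))
        ra, rb = index[ai], index[bi]
        # Lance-Williams Ward update into row ra
        for ci in ids:
            if ci in (ai, bi):
                continue
            rc, nc = index[ci], active[ci]
            new = ((na + nc) * d2[ra, rc] + (nb + nc) * d2[rb, rc] - nc * dd) / (
                na + nb + nc
            )
            d2[ra, rc] = d2[rc, ra] = new
        del active[ai], active[bi], index[ai], index[bi]
        active[next_id] = na + nb
        index[next_id] = ra
        next_id += 1
    return HcaResult(merge_history=merges, n_obs=n, labels=[str(x) for x in labels])


# ---------------------------------------------------------------------------
# stepwise LDA
# ---------------------------------------------------------------------------


@dataclass
class LdaResult:
    selected_vars: list[int]
    wilks_lambda_path: list[float]
    discriminant_axes: np.ndarray  # selected variables x functions
    scores: np.ndarray  # observations x functions
    group_centroids: np.ndarray  # groups x functions
    loadings: np.ndarray  # structure coefficients, selected variables x functions
    groups_: list
    status: str = "ok"


def _sscp(x: np.ndarray, g: np.ndarray):
    """Within-group and total sums-of-squares-and-cross-products matrices."""
    grand = x.mean(axis=0)
    t = (x - grand).T @ (x - grand)
    w = np.zeros_like(t)
    for lvl in np.unique(g):
        xg = x[g == lvl]
        cg = xg - xg.mean(axis=0)
        w += cg.T @ cg
    return w, t


def _wilks(w: np.ndarray, t: np.ndarray, idx: list[int]) -> float:
    sub = np.ix_(idx, idx)
    sign_t, logdet_t = np.linalg.slogdet(t[sub])
    sign_w, logdet_w = np.linalg.slogdet(w[sub])
    if sign_t <= 0 or sign_w <= 0:
        return np.nan
    return float(np.exp(logdet_w - logdet_t))


def lda_stepwise(
    data, groups, alpha_enter: float = 0.05, standardize: bool = True
) -> LdaResult:
    """Forward stepwise discriminant analysis driven by Wilks' lambda.

    At each step the candidate minimizing the overall lambda enters if its
    partial F-to-enter, F = ((n-g-p)/(g-1)) * (lambda_p/lambda_{p+1} - 1),
    is significant at ``alpha_enter``.  Axes come from the eigenvectors of
    W^-1 B on the selected variables, scaled so scores have identity pooled
    within-group covariance.
    """
    x = _as_matrix(data)
    g = np.asarray(groups)
    if g.shape[0] != x.shape[0]:
        raise ValueError("groups length must match observations")
    levels, g_codes = np.unique(g, return_inverse=True)
    ngroups = len(levels)
    if ngroups < 2:
        raise ValueError("need at least 2 groups")
    for lvl in range(ngroups):
        if (g_codes == lvl).sum() < 2:
            raise ValueError(f"group {levels[lvl]!r} has fewer than 2 observations")
    if standardize:
        x = _standardize(x)
    n, p = x.shape
    w, t = _sscp(x, g_codes)

    selected: list[int] = []
    lam_path: list[float] = []
    lam_prev = 1.0
    while True:
        p_sel = len(selected)
        if n - ngroups - p_sel <= 0:
            break
        best = None
        for cand in range(p):
            if cand in selected:
                continue
            lam = _wilks(w, t, selected + [cand])
            if np.isnan(lam) or lam <= 0:
                continue
            if best is None or lam < best[0]:
                best = (lam, cand)
        if best is None:
            break
        lam_new, cand = best
        f_enter = ((n - ngroups - p_sel) / (ngroups - 1)) * (lam_prev / lam_new - 1.0)
        p_val = float(sps.f.sf(f_enter, ngroups - 1, n - ngroups - p_sel))
        if p_val >= alpha_enter:
            break
        selected.append(cand)
        lam_path.append(lam_new)
        lam_prev = lam_new

    if not selected:
        empty = np.zeros((0, 0))
        return LdaResult(
            selected_vars=[],
            wilks_lambda_path=[],
            discriminant_axes=empty,
            scores=np.zeros((n, 0)),
            group_centroids=np.zeros((ngroups, 0)),
            loadings=empty,
            groups_=list(levels),
            status="no variable passed the entry criterion",
        )

    idx = np.ix_(selected, selected)
    w_sel = w[idx]
    b_sel = (t - w)[idx]
    try:
        m = np.linalg.solve(w_sel, b_sel)
    except np.linalg.LinAlgError as exc:
        raise ValueError(
            "singular within-group matrix; reduce the variable set"
        ) from exc
    evals, evecs = np.linalg.eig(m)
    evals, evecs = np.real(evals), np.real(evecs)
    order = np.argsort(evals)[::-1]
    n_funcs = min(ngroups - 1, len(selected))
    axes = evecs[:, order[:n_funcs]]
    # scale: unit pooled within-group variance of each score
    w_cov = w_sel / (n - ngroups)
    for j in range(axes.shape[1]):
        a = axes[:, j]
        s = math.sqrt(a @ w_cov @ a)
        if s > 0:
            axes[:, j] = a / s
    axes = _orient_columns(axes)
    xs = x[:, selected]
    scores = (xs - xs.mean(axis=0)) @ axes
    centroids = np.vstack([scores[g_codes == lvl].mean(axis=0) for lvl in range(ngroups)])
    # structure coefficients: pooled within-group correlations of vars vs scores
    sd_vars = np.sqrt(np.diag(w_cov))
    loadings = np.zeros((len(selected), n_funcs))
    for j in range(n_funcs):
        cov_vs = w_cov @ axes[:, j]  # within-group cov(var, score); score sd = 1
        loadings[:, j] = cov_vs / sd_vars
    return LdaResult(
        selected_vars=selected,
        wilks_lambda_path=lam_path,
        discriminant_axes=axes,
        scores=scores,
        group_centroids=centroids,
        loadings=loadings,
        groups_=list(levels),
    )
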