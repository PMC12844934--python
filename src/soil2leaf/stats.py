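"""Univariate inference: Welch ANOVA, Games-Howell post hoc, correlations.

The studentized-range tail probability needed by Games-Howell is computed by
direct Gauss-Legendre quadrature of the classical double-integral form rather
than delegated to a library, so the implementation can be cross-checked
against ``scipy.stats.studentized_range`` as an independent oracle.
Documented tolerance of the quadrature: ~1e-6 for p in (1e-8, 1).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import special, stats as sps

from .core import star_code

__all__ = [
    "WelchAnovaResult",
    "PairwiseComparison",
    "CorrelationMatrix",
    "welch_anova",
    "games_howell",
    "correlation_matrix",
    "studentized_range_sf",
    "strength_label",
]


# ---------------------------------------------------------------------------
# studentized range distribution
# ---------------------------------------------------------------------------

_GL_CACHE: dict[int, tuple[np.ndarray, np.ndarray]] = {}


def _gl_nodes(n: int) -> tuple[np.ndarray, np.ndarray]:
    if n not in _GL_CACHE:
        _GL_CACHE[n] = np.polynomial.legendre.leggauss(n)
    return _GL_CACHE[n]


def _range_cdf_given_scale(w: np.ndarray, k: int, n_inner: int = 160) -> np.ndarray:
    """P(range of k standard normals <= w), vectorized over w >= 0."""
    w = np.asarray(w, dtype=float)
    out = np.zeros_like(w)
    pos = w > 0
    if not pos.any():
        return out
    wv = w[pos][:, None]
    x, wt = _gl_nodes(n_inner)
    lo, hi = -8.5, 8.5 + wv  # integrand negligible outside
    z = (hi + lo) / 2 + (hi - lo) / 2 * x[None, :]
    half = (hi - lo) / 2
    phi = np.exp(-0.5 * z * z) / math.sqrt(2 * math.pi)
    inner = special.ndtr(z) - special.ndtr(z - wv)
    integrand = phi * np.power(inner, k - 1)
    out[pos] = k * (half[:, 0] * (integrand * wt[None, :]).sum(axis=1))
    return np.clip(out, 0.0, 1.0)


def studentized_range_sf(q: float, k: int, df: float, n_outer: int = 120) -> float:
    """Upper-tail probability of the studentized range with k groups, df dof.

    Integrates over the distribution of the scale estimate
    s = sqrt(chi2_df / df); ``df = inf`` skips the outer integral.
    """
    if q <= 0:
        return 1.0
    if k < 2:
        raise ValueError("k must be >= 2")
    if not np.isfinite(df):
        return float(1.0 - _range_cdf_given_scale(np.array([q]), k)[0])
    if df <= 0:
        raise ValueError("df must be positive")
    # density of s: C * s^(df-1) * exp(-df s^2 / 2), in log space for stability
    log_c = (df / 2) * math.log(df) - special.gammaln(df / 2) - (df / 2 - 1) * math.log(2)
    s_hi = 1.0 + 12.0 / math.sqrt(df)
    x, wt = _gl_nodes(n_outer)
    s = s_hi / 2 * (x + 1.0)
    half = s_hi / 2
    with np.errstate(divide="ignore"):
        log_dens = log_c + (df - 1) * np.log(s) - df * s * s / 2
    dens = np.exp(log_dens)
    cdf = float(np.sum(wt * dens * _range_cdf_given_scale(q * s, k)) * half)
    return float(np.clip(1.0 - cdf, 0.0, 1.0))


# ---------------------------------------------------------------------------
# Welch ANOVA
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class WelchAnovaResult:
    f_stat: float
    df1: float
    df2: float
    p: float


def _check_groups(groups: Sequence[Sequence[float]]) -> list[np.ndarray]:
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    for i, a in enumerate(arrays):
        if a.size < 2:
            raise ValueError(f"group {i} has fewer than 2 observations")
        if a.var(ddof=1) == 0:
            raise ValueError(f"group {i} has zero variance; statistic undefined")
    return arrays

def welch_anova(groups: Sequence[Sequence[float]]) -> WelchAnovaResult:
    """One-way ANOVA robust to unequal variances (Welch 1951 statistic)."""
    arrays = _check_groups(groups)
    k = len(arrays)
    n = np.array([a.size for a in arrays], dtype=float)
    m = np.array([a.mean() for a in arrays])
    v = np.array([a.var(ddof=1) for a in arrays])
    w = n / v
    sw = w.sum()
    grand = (w * m).sum() / sw
    num = ((w * (m - grand) ** 2).sum()) / (k - 1)
    lam = ((1 - w / sw) ** 2 / (n - 1)).sum()  # heterogeneity correction
    den = 1 + 2 * (k - 2) / (k * k - 1) * lam
    f = num / den
    df1 = k - 1
    df2 = (k * k - 1) / (3 * lam)
    p = float(sps.f.sf(f, df1, df2))
    return WelchAnovaResult(f_stat=float(f), df1=float(df1), df2=float(df2), p=p)


# ---------------------------------------------------------------------------
# Games-Howell
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PairwiseComparison:
    group_a: str
    group_b: str
    mean_diff: float
    se: float
    df: float
    q_stat: float
    p: float
    sig_code: str


def games_howell(
    groups: Sequence[Sequence[float]],
    labels: Sequence[str] | None = None,
) -> list[PairwiseComparison]:
    """All pairwise comparisons with unequal-variance control.

    For each pair: t = |diff| / sqrt(vi/ni + vj/nj), Welch-Satterthwaite df,
    and p from the studentized range at q = t * sqrt(2) with k groups.
    """
    arrays = _check_groups(groups)
    k = len(arrays)
    if labels is None:
        labels = [f"G{i + 1}" for i in range(k)]
    if len(labels) != k:
        raise ValueError("labels length must match number of groups")
    out = []
    for i, j in itertools.combinations(range(k), 2):
        a, b = arrays[i], arrays[j]
        vi, vj = a.var(ddof=1), b.var(ddof=1)
        ni, nj = a.size, b.size
        se = math.sqrt(vi / ni + vj / nj)
        diff = a.mean() - b.mean()
        df = (vi / ni + vj / nj) ** 2 / (
            (vi / ni) ** 2 / (ni - 1) + (vj / nj) ** 2 / (nj - 1)
        )
        q = abs(diff) / se * math.sqrt(2.0)
        p = studentized_range_sf(q, k, df)
        out.append(
            PairwiseComparison(
                group_a=str(labels[i]),
                group_b=str(labels[j]),
                mean_diff=float(diff),
                se=float(se),
                df=float(df),
                q_stat=float(q),
                p=float(p),
                sig_code=star_code(min(max(p, 0.0), 1.0)),
            )
        )
    return out


# ---------------------------------------------------------------------------
# correlation matrices
# ---------------------------------------------------------------------------


def strength_label(r: float) -> str:
    """Conventional strength categories for |r| (none/weak/moderate/strong)."""
    if np.isnan(r):
        return "undefined"
    a = abs(r)
    if a > 0.6:
        return "strong"
    if a >= 0.4:
        return "moderate"
    if a >= 0.2:
        return "weak"
    return "none"


@dataclass(frozen=True)
class CorrelationMatrix:
    variables: list[str]
    r: np.ndarray
    p: np.ndarray
    strength: np.ndarray  # object array of labels
    method: str

    def stars(self) -> np.ndarray:
        flat = [
            "" if np.isnan(p) else star_code(p).replace("ns", "")
            for p in self.p.ravel()
        ]
        return np.array(flat, dtype=object).reshape(self.p.shape)


def _midranks(x: np.ndarray) -> np.ndarray:
    return sps.rankdata(x, method="average")


def correlation_matrix(
    data, variables: Sequence[str] | None = None, method: str = "pearson"
) -> CorrelationMatrix:
    """Pairwise-complete correlation matrix with two-tailed t-test p-values.

    ``data`` is observations x variables (array or DataFrame).  Spearman is
    computed as Pearson on midranks.  Constant variables get NaN r/p.
    """
    if method not in ("pearson", "spearman"):
        raise ValueError(f"unknown method {method!r}")
    if hasattr(data, "columns"):
        if variables is None:
            variables = [str(c) for c in data.columns]
        mat = np.asarray(data, dtype=float)
    else:
        mat = np.asarray(data, dtype=float)
        if variables is None:
            variables = [f"V{i + 1}" for i in range(mat.shape[1])]
    nvar = mat.shape[1]
    r = np.full((nvar, nvar), np.nan)
    p = np.full((nvar, nvar), np.nan)
    np.fill_diagonal(r, 1.0)
    np.fill_diagonal(p, 0.0)
    for i in range(nvar):
        for j in range(i + 1, nvar):
            mask = ~(np.isnan(mat[:, i]) | np.isnan(mat[:, j]))
            x, y = mat[mask, i], mat[mask, j]
            n = x.size
            if n < 3:
                raise ValueError(
                    f"fewer than 3 complete observations for pair "
                    f"({variables[i]}, {variables[j]})"
                )
            if method == "spearman":
                x, y = _midranks(x), _midranks(y)
            sx, sy = x.std(ddof=1), y.std(ddof=1)
            if sx == 0 or sy == 0:
                continue  # constant variable: undefined correlation
            rij = float(np.cov(x, y, ddof=1)[0, 1] / (sx * sy))
            rij = min(max(rij, -1.0), 1.0)
            if abs(rij) == 1.0:
                pij = 0.0
            else:
                t = rij * math.sqrt((n - 2) / (1 - rij * rij))
                pij = float(2 * sps.t.sf(abs(t), n - 2))
            r[i, j] = r[j, i] = rij
            p[i, j] = p[j, i] = pij
    strength = np.array([strength_label(v) for v in r.ravel()], dtype=object).reshape(r.shape)
    return CorrelationMatrix(
        variables=list(variables), r=r, p=p, strength=strength, method=method
    )
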