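"""Pairwise and conditional dependencies of the motif models.

Sample and analytic Pearson correlations, first-order (and higher-order)
partial correlations, their exact algebraic limits as one node's noise scale
grows without bound, and the exact t-test for (partial) Pearson correlation
used as the conditional-independence test throughout the package.

All analytic quantities are derived from the implied covariance
Sigma = (I-B)^-1 D (I-B)^-T of the linear SEM: correlations by
normalisation, partial correlations from the precision matrix
(rho_ij.rest = -Omega_ij / sqrt(Omega_ii Omega_jj), which for three nodes is
the first-order partial correlation).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from typing import Iterable, Mapping

import numpy as np
import sympy as sp
from scipy import stats

from .motif_models import (
    MOTIF_EDGES,
    MOTIF_NODES,
    ExpressionMatrix,
    LinearMotif,
    MotifKind,
    implied_covariance,
)

__all__ = [
    "DependencyProfile",
    "CITestResult",
    "AsymptoticProfile",
    "sample_correlation",
    "sample_partial_correlation",
    "analytic_dependencies",
    "asymptotic_limits",
    "ci_test",
    "partial_correlation_from_matrix",
    "CorrelationTester",
]

PROFILE_FIELDS = ("rho_xy", "rho_xz", "rho_yz", "rho_xy_z", "rho_xz_y", "rho_yz_x")


@dataclass(frozen=True)
class DependencyProfile:
    """The six dependency measures of a three-node system.

    ``rho_ab`` are pairwise Pearson correlations; ``rho_ab_c`` is the partial
    correlation of a and b given the third variable c.
    """

    rho_xy: float
    rho_xz: float
    rho_yz: float
    rho_xy_z: float
    rho_xz_y: float
    rho_yz_x: float

    def as_dict(self) -> dict[str, float]:
        return {f: getattr(self, f) for f in PROFILE_FIELDS}

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, f) for f in PROFILE_FIELDS])


@dataclass(frozen=True)
class AsymptoticProfile:
    """Limit profile plus flags marking entries that stay parameter-dependent."""

    profile: DependencyProfile
    parameter_dependent: Mapping[str, bool] = field(default_factory=dict)


@dataclass(frozen=True)
class CITestResult:
    """Outcome of the exact t-test for a (partial) Pearson correlation."""

    r: float
    statistic: float
    df: int
    p_value: float
    independent: bool
    conditioning_set: tuple[str, ...]

    def as_dict(self) -> dict:
        return {
            "r": self.r,
            "statistic": self.statistic,
            "df": self.df,
            "p_value": self.p_value,
            "independent": self.independent,
            "conditioning_set": list(self.conditioning_set),
        }


def sample_correlation(x: np.ndarray, y: np.ndarray) -> float:
    """Pearson product-moment correlation of two equal-length vectors."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D vectors of equal length")
    if x.size < 3:
        raise ValueError("need at least 3 observations")
    xc = x - x.mean()
    yc = y - y.mean()
    sx = np.sqrt(xc @ xc)
    sy = np.sqrt(yc @ yc)
    if sx == 0 or sy == 0:
        raise ValueError("correlation undefined for a constant vector")
    return float(np.clip((xc @ yc) / (sx * sy), -1.0, 1.0))


def sample_partial_correlation(x: np.ndarray, y: np.ndarray, given: np.ndarray) -> float:
    """First-order partial correlation rho_xy.z via the recursion formula."""
    rxy = sample_correlation(x, y)
    rxz = sample_correlation(x, given)
    ryz = sample_correlation(y, given)
    denom = (1.0 - rxz**2) * (1.0 - ryz**2)
    if denom <= 0:
        raise ValueError("degenerate conditioning: |corr with conditioning variable| = 1")
    return float(np.clip((rxy - rxz * ryz) / np.sqrt(denom), -1.0, 1.0))


def _profile_from_covariance(sigma: np.ndarray) -> DependencyProfile:
    d = np.sqrt(np.diag(sigma))
    corr = sigma / np.outer(d, d)
    prec = np.linalg.inv(sigma)
    pd_ = np.sqrt(np.diag(prec))
    pcorr = -prec / np.outer(pd_, pd_)
    return DependencyProfile(
        rho_xy=float(corr[0, 1]),
        rho_xz=float(corr[0, 2]),
        rho_yz=float(corr[1, 2]),
        rho_xy_z=float(pcorr[0, 1]),
        rho_xz_y=float(pcorr[0, 2]),
        rho_yz_x=float(pcorr[1, 2]),
    )


def analytic_dependencies(model: LinearMotif) -> DependencyProfile:
    """Exact population dependencies of a motif model (no sampling)."""
    return _profile_from_covariance(implied_covariance(model))


def sample_dependencies(data: ExpressionMatrix) -> DependencyProfile:
    """The six sample dependencies of a 3-column expression matrix."""
    if data.p != 3:
        raise ValueError("sample_dependencies expects exactly 3 variables")
    cov = np.cov(data.values, rowvar=False)
    return _profile_from_covariance(cov)


# ---------------------------------------------------------------------------
# Exact algebraic limits (Table-1 style asymptotics), via sympy
# ---------------------------------------------------------------------------

@lru_cache(maxsize=None)
def _symbolic_limits(kind: MotifKind, limit_node: str):
    """Limits of the six dependencies as the noise scale at limit_node -> oo.

    Returns a list of (sympy expression in (a, s_f1, s_f2), field name) where
    the remaining symbols are the coupling and the two finite noise scales.
    """
    a = sp.symbols("a", positive=True)
    scales = {n: sp.symbols(f"s_{n}", positive=True) for n in MOTIF_NODES}
    t = sp.symbols("t", positive=True)
    scales[limit_node] = t

    B = sp.zeros(3, 3)
    idx = {n: i for i, n in enumerate(MOTIF_NODES)}
    for parent, child in MOTIF_EDGES[kind]:
        B[idx[child], idx[parent]] = a
    A = (sp.eye(3) - B).inv()
    D = sp.diag(*[scales[n] ** 2 for n in MOTIF_NODES])
    sigma = A * D * A.T
    prec = sigma.inv()

    def corr(i, j):
        return sigma[i, j] / sp.sqrt(sigma[i, i] * sigma[j, j])

    def pcorr(i, j):
        return -prec[i, j] / sp.sqrt(prec[i, i] * prec[j, j])

    exprs = [corr(0, 1), corr(0, 2), corr(1, 2), pcorr(0, 1), pcorr(0, 2), pcorr(1, 2)]
    limits = [sp.simplify(sp.limit(sp.simplify(e), t, sp.oo)) for e in exprs]
    return tuple(limits), (a, scales)


def asymptotic_limits(
    kind: MotifKind | str,
    limit_node: str,
    coupling: float = 1.0,
    finite_scales: tuple[float, float] | None = None,
) -> AsymptoticProfile:
    """Componentwise limits of the dependency profile as one noise scale -> oo.

    ``limit_node`` is 'y' or 'z'; ``finite_scales`` are the noise scales of
    the two remaining nodes in (x, y, z) order with the limit node skipped.
    Entries whose limit still depends on the coupling or the finite scales
    are evaluated at the supplied values and flagged ``parameter_dependent``.
    """
    kind = MotifKind(kind)
    if limit_node not in ("y", "z"):
        raise ValueError("limit_node must be 'y' or 'z'")
    if finite_scales is None:
        finite_scales = (1.0, 1.0)
    limits, (a, scales) = _symbolic_limits(kind, limit_node)
    finite_nodes = [n for n in MOTIF_NODES if n != limit_node]
    subs = {a: sp.Rational(coupling) if float(coupling).is_integer() else sp.Float(coupling)}
    for node, value in zip(finite_nodes, finite_scales):
        subs[scales[node]] = sp.Float(value)
    values: dict[str, float] = {}
    flags: dict[str, bool] = {}
    for name, expr in zip(PROFILE_FIELDS, limits):
        flags[name] = bool(expr.free_symbols)
        values[name] = float(expr.subs(subs))
    return AsymptoticProfile(DependencyProfile(**values), flags)


# ---------------------------------------------------------------------------
# Conditional-independence test
# ---------------------------------------------------------------------------

def partial_correlation_from_matrix(
    corr: np.ndarray, i: int, j: int, cond: Iterable[int]
) -> float:
    """Partial correlation of variables i, j given ``cond``, from a correlation
    matrix, via inversion of the relevant submatrix (any conditioning order)."""
    cond = list(cond)
    if not cond:
        return float(corr[i, j])
    idx = [i, j] + cond
    sub = corr[np.ix_(idx, idx)]
    try:
        prec = np.linalg.inv(sub)
    except np.linalg.LinAlgError as exc:
        raise ValueError("singular conditioning covariance") from exc
    denom = prec[0, 0] * prec[1, 1]
    if denom <= 0:
        raise ValueError("singular conditioning covariance")
    return float(np.clip(-prec[0, 1] / np.sqrt(denom), -1.0, 1.0))


def _t_test(r: float, n: int, k: int) -> tuple[float, int, float]:
    """Exact t-test for a (partial) Pearson correlation with |S| = k."""
    df = n - 2 - k
    if df < 1:
        raise ValueError(f"insufficient sample size: n={n} with |S|={k} leaves df={df}")
    r = float(np.clip(r, -1.0, 1.0))
    if abs(r) >= 1.0:
        return np.inf if r > 0 else -np.inf, df, 0.0
    t = r * np.sqrt(df / (1.0 - r * r))
    p = 2.0 * stats.t.sf(abs(t), df)
    return float(t), df, float(min(p, 1.0))


class CorrelationTester:
    """Gaussian conditional-independence tests against one dataset.

    Computes the sample correlation matrix once; every test then only needs
    the inversion of a small submatrix, which keeps bootstrap loops cheap.
    """

    def __init__(self, data: ExpressionMatrix, alpha: float = 0.01):
        if not 0.0 < alpha < 1.0:
            raise ValueError("significance level must be in (0, 1)")
        self.names = list(data.variable_names)
        self._index = {name: i for i, name in enumerate(self.names)}
        sd = data.values.std(axis=0)
        if np.any(sd == 0):
            bad = self.names[int(np.argmin(sd))]
            raise ValueError(f"constant column {bad!r}: correlation undefined")
        self.corr = np.corrcoef(data.values, rowvar=False)
        self.n = data.n
        self.alpha = alpha

    def test(self, x: str, y: str, S: Iterable[str] = ()) -> CITestResult:
        S = tuple(S)
        if x == y or x in S or y in S:
            raise ValueError("x, y and the conditioning set must be distinct")
        if self.n <= len(S) + 3:
            raise ValueError(
                f"insufficient sample size n={self.n} for conditioning-set size {len(S)}"
            )
        r = partial_correlation_from_matrix(
            self.corr, self._index[x], self._index[y], [self._index[s] for s in S]
        )
        t, df, p = _t_test(r, self.n, len(S))
        return CITestResult(
            r=r, statistic=t, df=df, p_value=p, independent=p > self.alpha, conditioning_set=S
        )


def ci_test(
    data: ExpressionMatrix,
    x: str,
    y: str,
    S: Iterable[str] = (),
    alpha: float = 0.01,
) -> CITestResult:
    """Exact t-test for the (partial) Pearson correlation of x and y given S.

    t = r sqrt(df / (1 - r^2)) with df = n - 2 - |S|; two-sided p-value from
    the t distribution; ``independent`` iff p > alpha.
    """
    return CorrelationTester(data, alpha).test(x, y, S)
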