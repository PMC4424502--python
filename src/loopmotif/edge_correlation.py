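"""Edge scoring: Pearson correlation and distance correlation with significance.

Every candidate regulatory edge is scored on matched n-point expression
profiles with two complementary dependence measures:

* Pearson's rho = cov(X, Y) / (sd(X) sd(Y)), sensitive to linear dependence,
  with a two-sided p-value from t = r * sqrt((n - 2) / (1 - r^2)) on n - 2
  degrees of freedom.
* Distance correlation (dCor), which is zero iff X and Y are independent.
  Pairwise distance matrices a_jk = |x_j - x_k| and b_jk = |y_j - y_k| are
  double-centered (row mean and column mean subtracted, grand mean added
  back); dCov^2 is the mean elementwise product of the centered matrices and
  dCor = dCov / sqrt(dVar_x dVar_y), defined as 0 when a variance term
  vanishes.  Its p-value comes from a permutation test — exact enumeration
  of all n! pairings when n! is small (n <= 7 by default), seeded
  Monte-Carlo otherwise.

An edge is *significant* when either test's p-value is <= alpha (the OR
rule; AND is available), unless a profile is constant, which is always
non-significant.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from itertools import permutations

import numpy as np
from scipy import stats

__all__ = [
    "EdgeStats",
    "pearson",
    "distance_correlation",
    "permutation_pvalue",
    "score_edge",
]

EXACT_PERMUTATION_LIMIT = 5040  # enumerate all n! pairings while n! <= this (n <= 7)


@dataclass(frozen=True)
class EdgeStats:
    """Correlation summary for one directed edge candidate."""

    source: str
    target: str
    edge_class: str
    n: int
    r: float
    p_pearson: float
    dcor: float
    p_dcor: float
    significant: bool


def _as_vector(x, name: str) -> np.ndarray:
    v = np.asarray(x, dtype=float).ravel()
    if not np.isfinite(v).all():
        raise ValueError(f"{name} contains non-finite values")
    return v


def pearson(x, y) -> tuple[float, float]:
    """Sample Pearson r and two-sided t-based p-value.

    Degenerate input (either vector constant) yields r = 0, p = 1.
    """
    x = _as_vector(x, "x")
    y = _as_vector(y, "y")
    if x.size != y.size:
        raise ValueError(f"length mismatch: {x.size} vs {y.size}")
    n = x.size
    if n < 3:
        raise ValueError("Pearson test needs n >= 3")
    xc = x - x.mean()
    yc = y - y.mean()
    sx = math.sqrt((xc @ xc))
    sy = math.sqrt((yc @ yc))
    if sx == 0.0 or sy == 0.0:
        return 0.0, 1.0
    r = float(np.clip((xc @ yc) / (sx * sy), -1.0, 1.0))
    if abs(r) == 1.0:
        return r, 0.0
    t = r * math.sqrt((n - 2) / (1.0 - r * r))
    p = 2.0 * stats.t.sf(abs(t), df=n - 2)
    return r, float(min(p, 1.0))


def _centered_distances(v: np.ndarray) -> np.ndarray:
    d = np.abs(v[:, None] - v[None, :])
    return d - d.mean(axis=0) - d.mean(axis=1)[:, None] + d.mean()


def distance_correlation(x, y) -> float:
    """Sample distance correlation in [0, 1]; 0 when either variable is constant."""
    x = _as_vector(x, "x")
    y = _as_vector(y, "y")
    if x.size != y.size:
        raise ValueError(f"length mismatch: {x.size} vs {y.size}")
    if x.size < 2:
        raise ValueError("distance correlation needs n >= 2")
    A = _centered_distances(x)
    B = _centered_distances(y)
    dvar_x = (A * A).mean()
    dvar_y = (B * B).mean()
    if dvar_x <= 0.0 or dvar_y <= 0.0:
        return 0.0
    dcov2 = max((A * B).mean(), 0.0)
    return float(min(math.sqrt(dcov2 / math.sqrt(dvar_x * dvar_y)), 1.0))


def _statistic(name: str):
    if name == "dcor":
        return distance_correlation
    if name == "pearson_abs":
        return lambda x, y: abs(pearson(x, y)[0])
    raise ValueError(f"unknown permutation statistic {name!r}")


def permutation_pvalue(
    statistic: str,
    x,
    y,
    n_perm: int = 1999,
    seed: int | None = None,
    exact_limit: int = EXACT_PERMUTATION_LIMIT,
) -> float:
    """Permutation p-value for dependence between x and y.

    Exact when n! <= ``exact_limit``: p = #{stat(perm) >= stat(obs)} / n!
    over all permutations of y (the identity is one of them, so p >= 1/n!).
    Otherwise Monte-Carlo with the +1 correction p = (1 + #{>=}) / (1 + n_perm).
    """
    x = _as_vector(x, "x")
    y = _as_vector(y, "y")
    if x.size != y.size:
        raise ValueError(f"length mismatch: {x.size} vs {y.size}")
    n = x.size
    if n < 3:
        raise ValueError("permutation test needs n >= 3")
    stat = _statistic(statistic)
    observed = stat(x, y)
    tol = 1e-12
    if math.factorial(n) <= exact_limit:
        hits = sum(stat(x, np.array(p)) >= observed - tol for p in permutations(y))
        return hits / math.factorial(n)
    if n_perm < 100:
        warnings.warn(f"n_perm={n_perm} is small for a Monte-Carlo permutation test")
    rng = np.random.default_rng(seed)
    hits = sum(
        stat(x, rng.permutation(y)) >= observed - tol for _ in range(n_perm)
    )
    return (1 + hits) / (1 + n_perm)


def score_edge(
    source: str,
    target: str,
    edge_class: str,
    profiles: dict[str, np.ndarray],
    alpha: float = 0.05,
    combine: str = "or",
    positive_only: bool = False,
    n_perm: int = 1999,
    seed: int | None = None,
) -> EdgeStats:
    """Score one edge on matched profiles and decide significance.

    ``combine`` selects the rule joining the two tests ("or" / "and");
    ``positive_only`` additionally requires r > 0.  Constant profiles on
    either side are never significant.
    """
    for eid in (source, target):
        if eid not in profiles:
            raise KeyError(f"no matched profile for entity {eid!r}")
    if combine not in ("or", "and"):
        raise ValueError("combine must be 'or' or 'and'")
    x = np.asarray(profiles[source], dtype=float)
    y = np.asarray(profiles[target], dtype=float)
    r, p_r = pearson(x, y)
    d = distance_correlation(x, y)
    degenerate = x.std() == 0.0 or y.std() == 0.0
    if degenerate:
        p_d = 1.0
    else:
        p_d = permutation_pvalue("dcor", x, y, n_perm=n_perm, seed=seed)
    if combine == "or":
        sig = (p_r <= alpha) or (p_d <= alpha)
    else:
        sig = (p_r <= alpha) and (p_d <= alpha)
    if degenerate:
        sig = False
    if positive_only and r <= 0.0:
        sig = False
    return EdgeStats(
        source=source,
        target=target,
        edge_class=edge_class,
        n=int(x.size),
        r=r,
        p_pearson=p_r,
        dcor=d,
        p_dcor=p_d,
        significant=bool(sig),
    )
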