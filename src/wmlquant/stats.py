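"""Group and correlation statistics for lesion and volumetric measures.

The layer mirrors a two-group neuroimaging study design: ANCOVA with a
log10 gate for transformable data, Freedman-Lane permutation GLMs for
data that stay non-Gaussian, Bonferroni correction across regions,
partial Spearman rank correlations, a two-way repeated-measures design
with hemisphere as the within-subject factor, and — voxel-wise on binary
lesion maps — the Liebermeister quasi-exact 2x2 test with a presence
mask and max-statistic permutation familywise-error control.

All stochastic procedures take an explicit seed and reproduce exactly.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from itertools import permutations as iter_permutations

import numpy as np
import pandas as pd
from scipy import stats as sps

EXHAUSTIVE_LIMIT = 50_000


@dataclass
class TestResult:
    """One statistical comparison."""

    method: str
    statistic: float
    df: tuple | None
    p: float
    p_adjusted: float | None = None
    adjustment: str = "none"
    n_permutations: int | None = None
    seed: int | None = None
    extras: dict = field(default_factory=dict)

    def as_row(self) -> dict:
        return {
            "method": self.method,
            "statistic": self.statistic,
            "df": "" if self.df is None else ",".join(str(d) for d in self.df),
            "p": self.p,
            "p_adjusted": "" if self.p_adjusted is None else self.p_adjusted,
            "adjustment": self.adjustment,
            "n_permutations": "" if self.n_permutations is None else self.n_permutations,
            "seed": "" if self.seed is None else self.seed,
            **self.extras,
        }


# ---------------------------------------------------------------------------
# design-matrix helpers


def _as_numeric(col: pd.Series) -> np.ndarray:
    if col.dtype == object or isinstance(col.dtype, pd.CategoricalDtype):
        levels = sorted(col.astype(str).unique())
        if len(levels) > 2:
            raise ValueError(f"column {col.name!r} has >2 levels; dummy-code it first")
        return (col.astype(str) == levels[-1]).to_numpy(float)
    return col.to_numpy(float)


def _design(table: pd.DataFrame, group: str, covariates,
            extra_cols=()) -> tuple[np.ndarray, np.ndarray, list]:
    """Full design [1 | group | covariates]; listwise-deletes rows missing
    any design or response (``extra_cols``) value."""
    cols = [group] + list(covariates)
    sub = table[cols + list(extra_cols)].dropna()[cols]
    dropped = len(table) - len(sub)
    if dropped:
        warnings.warn(f"{dropped} rows dropped for missing data", UserWarning)
    X = np.column_stack([np.ones(len(sub))] +
                        [_as_numeric(sub[c]) for c in cols])
    names = ["intercept"] + cols
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        bad = [n for i, n in enumerate(names)
               if np.linalg.matrix_rank(np.delete(X, i, axis=1)) == rank]
        raise ValueError(f"rank-deficient design; collinear columns: {bad}")
    return X, sub.index.to_numpy(), names


def _ols_t(X: np.ndarray, y: np.ndarray, j: int):
    """t statistic for coefficient j of an OLS fit (plain linear algebra)."""
    n, p = X.shape
    dof = n - p
    if dof < 1:
        raise ValueError(f"too few observations ({n}) for {p} design columns")
    XtX_inv = np.linalg.inv(X.T @ X)
    beta = XtX_inv @ (X.T @ y)
    resid = y - X @ beta
    sigma2 = float(resid @ resid) / dof
    se = math.sqrt(max(sigma2 * XtX_inv[j, j], 0.0))
    if se == 0:
        raise ValueError("response has no residual variance")
    return float(beta[j] / se), dof


# ---------------------------------------------------------------------------
# gaussianity gate


def gaussianity_gate(y, covariates=None, alpha: float = 0.05) -> str:
    """Decide the analysis route for one response variable.

    Shapiro-Wilk on the OLS residuals of ``y ~ covariates`` (intercept
    only when no covariates): pass -> ``"none"`` (plain ANCOVA); else if
    all values are positive, test log10(y) the same way -> ``"log10"``;
    otherwise ``"permutation"``.  Fewer than 8 observations force the
    permutation route.
    """
    y = np.asarray(y, float)
    if covariates is None:
        Z = np.ones((len(y), 1))
    else:
        Z = np.column_stack([np.ones(len(y)), np.asarray(covariates, float)])
    if len(y) < 8:
        warnings.warn("n < 8: forcing the permutation route", UserWarning)
        return "permutation"

    def _resid_normal(v):
        resid = v - Z @ np.linalg.lstsq(Z, v, rcond=None)[0]
        if np.ptp(resid) == 0:
            return False
        return sps.shapiro(resid).pvalue > alpha

    if _resid_normal(y):
        return "none"
    if np.min(y) > 0 and _resid_normal(np.log10(y)):
        return "log10"
    return "permutation"


# ---------------------------------------------------------------------------
# ANCOVA


def ancova(table: pd.DataFrame, response: str, group: str, covariates=(),
           transform: str = "none") -> TestResult:
    """ANCOVA group test: partial F (1 numerator df) for the group term in
    an OLS of the (optionally log10-transformed) response on group plus
    covariates, with exact p from the F distribution."""
    X, idx, names = _design(table, group, covariates, extra_cols=(response,))
    y = table.loc[idx, response].to_numpy(float)
    if transform == "log10":
        if np.min(y) <= 0:
            raise ValueError("log10 transform requires strictly positive data")
        y = np.log10(y)
    elif transform != "none":
        raise ValueError(f"unknown transform {transform!r}")
    if np.ptp(y) == 0:
        raise ValueError("response has no variance")
    t, dof = _ols_t(X, y, j=1)
    F = t * t
    p = float(sps.f.sf(F, 1, dof))
    return TestResult(method="ancova" if transform == "none" else "ancova_log10",
                      statistic=F, df=(1, dof), p=p,
                      extras={"response": response, "transform": transform,
                              "n_used": len(idx)})


# ---------------------------------------------------------------------------
# Freedman-Lane permutation GLM


def permutation_glm(table: pd.DataFrame, response: str, group: str, covariates=(),
                    n_permutations: int = 10_000, seed: int = 0,
                    exhaustive: str = "auto") -> TestResult:
    """Two-sided permutation test for the group term of a GLM.

    The observed statistic is the OLS t for the group coefficient.  The
    null is built by the Freedman-Lane scheme: residuals of the reduced
    (covariates-only) model are permuted, added back to the reduced
    fit, and the full model is re-fit to each permuted response.  With
    ``exhaustive='auto'`` all n! residual orderings are enumerated when
    that count is at most 50,000 (p is then exact: the proportion of
    orderings, identity included, with |t*| >= |t|); otherwise
    ``n_permutations`` random permutations give
    p = (1 + #{|t*| >= |t|}) / (1 + n_permutations).
    """
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    X, idx, names = _design(table, group, covariates, extra_cols=(response,))
    y = table.loc[idx, response].to_numpy(float)
    if np.ptp(y) == 0:
        raise ValueError("response has no variance")
    n, p_cols = X.shape
    t_obs, dof = _ols_t(X, y, j=1)

    Z = np.delete(X, 1, axis=1)                      # reduced model
    beta_r = np.linalg.lstsq(Z, y, rcond=None)[0]
    fitted_r = Z @ beta_r
    resid_r = y - fitted_r

    use_exhaustive = (exhaustive is True or
                      (exhaustive == "auto" and math.factorial(n) <= EXHAUSTIVE_LIMIT))
    if use_exhaustive:
        perms = np.array(list(iter_permutations(range(n))))
    else:
        rng = np.random.default_rng(seed)
        perms = np.array([rng.permutation(n) for _ in range(n_permutations)])

    Ystar = fitted_r[None, :] + resid_r[perms]       # (B, n)
    XtX_inv = np.linalg.inv(X.T @ X)
    A = XtX_inv @ X.T                                # (p, n)
    B = A @ Ystar.T                                  # (p, B)
    resid = Ystar.T - X @ B                          # (n, B)
    sigma2 = (resid ** 2).sum(axis=0) / (n - p_cols)
    se = np.sqrt(np.clip(sigma2 * XtX_inv[1, 1], 1e-300, None))
    t_star = B[1] / se

    eps = 1e-12 * max(1.0, abs(t_obs))
    exceed = np.abs(t_star) >= abs(t_obs) - eps
    if use_exhaustive:
        p = float(exceed.mean())
        n_perm_done = len(perms)
    else:
        p = float((1 + exceed.sum()) / (1 + n_permutations))
        n_perm_done = n_permutations
    return TestResult(method="perm_glm", statistic=t_obs, df=(dof,), p=p,
                      n_permutations=n_perm_done, seed=None if use_exhaustive else seed,
                      extras={"response": response, "scheme": "freedman-lane",
                              "exhaustive": bool(use_exhaustive), "n_used": n})


def bonferroni(p_values, m: int | None = None) -> np.ndarray:
    """Bonferroni adjustment: min(1, m * p); m defaults to len(p_values)."""
    p = np.asarray(p_values, float)
    m = int(m) if m is not None else p.size
    if m < 1:
        raise ValueError("m must be >= 1")
    return np.minimum(1.0, m * p)


# ---------------------------------------------------------------------------
# partial Spearman


def partial_spearman(table: pd.DataFrame, x: str, y: str, covariates=()) -> TestResult:
    """Partial Spearman rank correlation of x and y given covariates.

    Both variables are rank-transformed (average ranks for ties),
    OLS-residualised on the covariates, and Pearson-correlated; p comes
    from the t approximation with df = n - #covariates - 2.
    """
    cols = [x, y] + list(covariates)
    sub = table[cols].dropna()
    n = len(sub)
    k = len(covariates)
    if n < k + 4:
        raise ValueError("too few complete observations for a partial correlation")
    xv = sub[x].to_numpy(float)
    yv = sub[y].to_numpy(float)
    if np.ptp(xv) == 0 or np.ptp(yv) == 0:
        return TestResult(method="spearman_partial", statistic=float("nan"),
                          df=None, p=float("nan"),
                          extras={"note": "constant variable", "n_used": n})
    rx = sps.rankdata(xv)
    ry = sps.rankdata(yv)
    Z = np.column_stack([np.ones(n)] + [_as_numeric(sub[c]) for c in covariates])
    ex = rx - Z @ np.linalg.lstsq(Z, rx, rcond=None)[0]
    ey = ry - Z @ np.linalg.lstsq(Z, ry, rcond=None)[0]
    denom = math.sqrt(float(ex @ ex) * float(ey @ ey))
    r = float(ex @ ey) / denom if denom > 0 else float("nan")
    dof = n - k - 2
    r_cl = min(max(r, -0.999999999999), 0.999999999999)
    t = r_cl * math.sqrt(dof / (1.0 - r_cl * r_cl))
    p = float(2.0 * sps.t.sf(abs(t), dof))
    return TestResult(method="spearman_partial", statistic=r, df=(dof,), p=p,
                      extras={"x": x, "y": y, "n_used": n})


# ---------------------------------------------------------------------------
# repeated-measures ANCOVA (2 within-levels)


def rm_ancova(table: pd.DataFrame, left: str, right: str, group: str,
              covariates=()) -> dict:
    """Two-way repeated-measures ANCOVA with hemisphere within-subject.

    Mixed between-within decomposition for a two-level within factor:
    the between-subject (group) effect is tested on subject sums, the
    within-subject effects on subject differences — hemisphere as the
    intercept of the difference model (group effect-coded +-1/2,
    covariates mean-centred, so the intercept is the unweighted average
    hemisphere effect) and the hemisphere x group interaction as its
    group term.  Returns F tests keyed ``group``, ``hemisphere``,
    ``interaction``.
    """
    X, idx, names = _design(table, group, covariates, extra_cols=(left, right))
    L = table.loc[idx, left].to_numpy(float)
    R = table.loc[idx, right].to_numpy(float)
    s = L + R
    d = R - L
    n, p_cols = X.shape
    dof = n - p_cols

    def _f_test(Xd, v, j, tag):
        # handle the degenerate perfect-fit case (e.g. a constant
        # hemisphere difference) explicitly: the residual variance is 0,
        # so a non-zero effect is certain and a zero effect absent
        XtX_inv = np.linalg.inv(Xd.T @ Xd)
        beta = XtX_inv @ (Xd.T @ v)
        resid = v - Xd @ beta
        dd = n - p_cols
        ss_res = float(resid @ resid)
        scale = float(v @ v) + 1e-300
        if ss_res <= 1e-20 * scale:
            certain = abs(beta[j]) > 1e-10 * math.sqrt(scale / n)
            return TestResult(method="rm_ancova",
                              statistic=float("inf") if certain else 0.0,
                              df=(1, dd), p=0.0 if certain else 1.0,
                              extras={"term": tag, "degenerate": True})
        se = math.sqrt(ss_res / dd * XtX_inv[j, j])
        F = (beta[j] / se) ** 2
        return TestResult(method="rm_ancova", statistic=float(F), df=(1, dd),
                          p=float(sps.f.sf(F, 1, dd)), extras={"term": tag})

    out = {"group": _f_test(X, s, 1, "group")}
    # within-stratum design: effect-coded group, centred covariates
    Xw = X.copy()
    g = X[:, 1]
    Xw[:, 1] = np.where(g > 0.5, 0.5, -0.5)
    for j in range(2, p_cols):
        Xw[:, j] = X[:, j] - X[:, j].mean()
    out["hemisphere"] = _f_test(Xw, d, 0, "hemisphere")
    out["interaction"] = _f_test(Xw, d, 1, "interaction")
    return out


# ---------------------------------------------------------------------------
# Liebermeister 2x2 test


def liebermeister(a: int, b: int, c: int, d: int) -> tuple[float, float]:
    """Liebermeister quasi-exact test for a 2x2 table.

    Rows are groups; ``a``/``b`` are group-1 successes/failures and
    ``c``/``d`` group-2's.  With independent uniform-prior Beta
    posteriors p1 ~ Beta(a+1, b+1), p2 ~ Beta(c+1, d+1), the one-sided p
    is Pr(p1 <= p2), evaluated in closed form as the one-sided
    hypergeometric tail of the table with the concordant diagonal
    incremented (a+1, b, c, d+1); the two-sided p doubles the smaller
    tail, capped at 1.
    """
    for v in (a, b, c, d):
        if v < 0 or int(v) != v:
            raise ValueError("cell counts must be non-negative integers")
    a, b, c, d = int(a), int(b), int(c), int(d)
    # Pr(p1 <= p2) = P[Hypergeom(M=n+2, K=a+b+1, N=a+c+1) >= a+1]
    M = a + b + c + d + 2
    one_sided = float(sps.hypergeom.sf(a, M, a + b + 1, a + c + 1))
    two_sided = min(1.0, 2.0 * min(one_sided, 1.0 - one_sided))
    return one_sided, two_sided


def _liebermeister_p_table(n1: int, n2: int) -> np.ndarray:
    """Two-sided Liebermeister p for every (a, c) with fixed group sizes."""
    p = np.empty((n1 + 1, n2 + 1))
    for a in range(n1 + 1):
        for c in range(n2 + 1):
            p[a, c] = liebermeister(a, n1 - a, c, n2 - c)[1]
    return p


# ---------------------------------------------------------------------------
# voxel-wise lesion analysis with max-statistic permutation FWE


@dataclass
class VoxelwiseResult:
    p_map: np.ndarray               # raw two-sided Liebermeister p (1 outside mask)
    p_fwe_map: np.ndarray           # max-statistic corrected p (1 outside mask)
    mask: np.ndarray
    n_in_mask: int
    presence_threshold: int
    n_permutations: int
    seed: int


def voxelwise_lesion_test(maps, groups, presence_min: float = 0.10,
                          n_permutations: int = 1000, seed: int = 0) -> VoxelwiseResult:
    """Voxel-wise two-group comparison of binary lesion maps.

    Analysis is restricted to voxels lesioned in at least
    ceil(presence_min * N) subjects.  Each in-mask voxel gets a two-sided
    Liebermeister p; familywise error is controlled by permuting group
    labels, recording each permutation's most extreme voxel statistic
    (smallest p), and ranking the observed statistics against that null:
    p_fwe(v) = (1 + #{min_b p*_b <= p_v}) / (1 + n_permutations).
    """
    data = np.stack([np.asarray(getattr(m, "data", m), dtype=np.uint8) for m in maps])
    N = data.shape[0]
    groups = np.asarray(groups)
    levels = sorted(pd.unique(groups).tolist())
    if len(levels) != 2:
        raise ValueError("exactly two groups required")
    g1 = groups == levels[0]
    n1, n2 = int(g1.sum()), int(N - g1.sum())

    presence_threshold = int(np.ceil(presence_min * N))
    flat = data.reshape(N, -1)
    presence = flat.sum(axis=0)
    mask_flat = presence >= presence_threshold
    shape = data.shape[1:]
    mask = mask_flat.reshape(shape)
    if not mask_flat.any():
        ones = np.ones(shape)
        return VoxelwiseResult(p_map=ones, p_fwe_map=ones.copy(), mask=mask,
                               n_in_mask=0, presence_threshold=presence_threshold,
                               n_permutations=n_permutations, seed=seed)

    sub = flat[:, mask_flat].astype(np.int64)        # (N, V)
    total = sub.sum(axis=0)
    p_lut = _liebermeister_p_table(n1, n2)

    a_obs = sub[g1].sum(axis=0)
    c_obs = total - a_obs
    p_obs = p_lut[a_obs, c_obs]

    rng = np.random.default_rng(seed)
    sel = np.zeros((n_permutations, N), dtype=np.int64)
    for b in range(n_permutations):
        sel[b, rng.permutation(N)[:n1]] = 1
    a_perm = sel @ sub                               # (B, V)
    c_perm = total[None, :] - a_perm
    p_perm = p_lut[a_perm, c_perm]
    min_p = p_perm.min(axis=1)                       # (B,)

    p_fwe = (1 + (min_p[:, None] <= p_obs[None, :]).sum(axis=0)) / (1 + n_permutations)

    p_map = np.ones(shape)
    p_map[mask] = p_obs
    p_fwe_map = np.ones(shape)
    p_fwe_map[mask] = p_fwe
    return VoxelwiseResult(p_map=p_map, p_fwe_map=p_fwe_map, mask=mask,
                           n_in_mask=int(mask_flat.sum()),
                           presence_threshold=presence_threshold,
                           n_permutations=n_permutations, seed=seed)
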