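"""Nested linear mixed model for log10 follicle densities.

The model for the transformed density of section *l* in fragment *k* of
ovary *j* within ewe *i* is

    y_ijkl = mu + ewe_i + ovary_j(i) [+ treatment] + f_k(ij) + e_l(ijk)

with fixed ewe / ovary-within-ewe / treatment effects, a random fragment
intercept f ~ N(0, sigma2_fragment), and a section-level residual
e ~ N(0, sigma2_section).  Estimation is by REML (statsmodels MixedLM,
polished on an explicit profile restricted log-likelihood); an
expected-mean-squares moments estimator for balanced tables is provided as
an independent cross-check.  Fixed factors are tested with F statistics
using containment denominator degrees of freedom (fragments minus the rank
of the fragment-level fixed design), which for balanced two-group designs
reproduces the exact between-fragment test.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import linalg, optimize, stats

from .errors import DataError, FitError, ParameterError

__all__ = [
    "ModelSpec",
    "VarianceComponents",
    "FixedEffectTest",
    "FitResult",
    "fit_mixed_model",
    "estimate_components_moments",
    "variance_proportions",
    "test_fixed_effect",
]


@dataclass(frozen=True)
class ModelSpec:
    """What to fit: response column, ordered fixed factors, random factor.

    Ovary labels are interpreted within their ewe and fragment labels within
    their ovary (nesting by composite labels).
    """

    response: str = "y"
    fixed_factors: tuple[str, ...] = ("ewe_id", "ovary_id")
    random_factor: str = "fragment_id"
    nesting: Mapping[str, tuple[str, ...]] = field(
        default_factory=lambda: {
            "ovary_id": ("ewe_id",),
            "fragment_id": ("ewe_id", "ovary_id"),
        }
    )

    def nested_label(self, table: pd.DataFrame, factor: str) -> pd.Series:
        """Composite label realizing the nesting (e.g. ewe1/ov2/frag3)."""
        parents = self.nesting.get(factor, ())
        cols = [table[p].astype(str) for p in parents] + [table[factor].astype(str)]
        out = cols[0]
        for c in cols[1:]:
            out = out + "/" + c
        return out


@dataclass
class VarianceComponents:
    """Fragment / section variance decomposition on the log10 scale."""

    sigma2_fragment: float
    sigma2_section: float
    se_fragment: float = float("nan")
    se_section: float = float("nan")
    truncated: bool = False

    def __post_init__(self) -> None:
        if self.sigma2_fragment < 0 or self.sigma2_section < 0:
            raise ParameterError("variance components must be >= 0")

    @property
    def total(self) -> float:
        return self.sigma2_fragment + self.sigma2_section


@dataclass(frozen=True)
class FixedEffectTest:
    statistic: float  # F statistic of the joint contrast
    df_num: int
    df_den: float
    pvalue: float
    pvalue_chi2: float  # large-sample Wald chi-square p for reference


@dataclass
class FitResult:
    params: pd.Series
    se: pd.Series
    tests: dict[str, FixedEffectTest]
    vc: VarianceComponents
    loglike: float
    converged: bool
    method: str
    n_obs: int
    n_fragments: int

    def to_dict(self) -> dict:
        return {
            "fixed_effects": {
                name: {"estimate": float(est), "se": float(self.se[name])}
                for name, est in self.params.items()
            },
            "tests": {
                f: {
                    "F": t.statistic,
                    "df_num": t.df_num,
                    "df_den": t.df_den,
                    "pvalue": t.pvalue,
                    "pvalue_chi2": t.pvalue_chi2,
                }
                for f, t in self.tests.items()
            },
            "variance_components": {
                "sigma2_fragment": float(self.vc.sigma2_fragment),
                "sigma2_section": float(self.vc.sigma2_section),
                "se_fragment": float(self.vc.se_fragment),
                "se_section": float(self.vc.se_section),
                "truncated": bool(self.vc.truncated),
            },
            "loglike": float(self.loglike),
            "converged": bool(self.converged),
            "method": self.method,
            "n_obs": int(self.n_obs),
            "n_fragments": int(self.n_fragments),
        }


# ---------------------------------------------------------------------------
# design construction
# ---------------------------------------------------------------------------


def _build_design(table: pd.DataFrame, spec: ModelSpec):
    """Full-rank fixed design (treatment coding, nested dummies) + term map."""
    n = len(table)
    cols = [np.ones(n)]
    names = ["Intercept"]
    terms: dict[str, list[int]] = {}
    for factor in spec.fixed_factors:
        if factor not in table.columns:
            raise DataError(f"factor column '{factor}' missing from table")
        label = spec.nested_label(table, factor)
        parents = spec.nesting.get(factor, ())
        idx: list[int] = []
        if parents:
            # drop the first level within each parent cell
            parent_key = table[list(parents)].astype(str).agg("/".join, axis=1)
            for cell in sorted(parent_key.unique()):
                in_cell = parent_key == cell
                levels = sorted(label[in_cell].unique())
                for lev in levels[1:]:
                    idx.append(len(cols))
                    cols.append((label == lev).to_numpy(float))
                    names.append(f"{factor}[{lev}]")
        else:
            levels = sorted(label.unique())
            for lev in levels[1:]:
                idx.append(len(cols))
                cols.append((label == lev).to_numpy(float))
                names.append(f"{factor}[{lev}]")
        terms[factor] = idx
    X = np.column_stack(cols)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise FitError("singular fixed-effects design (aliased factor levels)")
    return X, names, terms


def _fragment_codes(table: pd.DataFrame, spec: ModelSpec) -> np.ndarray:
    label = spec.nested_label(table, spec.random_factor)
    # same fragment id under two ovaries must resolve to distinct labels;
    # composite labels guarantee that, but a fragment spread over ovaries
    # after labelling indicates corrupt input
    codes, _ = pd.factorize(label, sort=True)
    return codes


# ---------------------------------------------------------------------------
# explicit REML profile log-likelihood (block compound-symmetry covariance)
# ---------------------------------------------------------------------------


def _reml_quantities(theta, y, X, codes, n_frag):
    """GLS pieces under V = s2s·I + s2f·(block J); Woodbury per fragment."""
    s2f, s2s = max(theta[0], 0.0), theta[1]
    n, p = X.shape
    counts = np.bincount(codes, minlength=n_frag).astype(float)
    Sx = np.zeros((n_frag, p))
    np.add.at(Sx, codes, X)
    Sy = np.bincount(codes, weights=y, minlength=n_frag)
    c = s2f / (s2s * (s2s + counts * s2f))
    XtVX = X.T @ X / s2s - Sx.T @ (c[:, None] * Sx)
    XtVy = X.T @ y / s2s - Sx.T @ (c * Sy)
    ytVy = y @ y / s2s - np.sum(c * Sy**2)
    logdetV = float(np.sum((counts - 1.0) * math.log(s2s) + np.log(s2s + counts * s2f)))
    return XtVX, XtVy, ytVy, logdetV


def _reml_loglik(theta, y, X, codes, n_frag) -> float:
    s2f, s2s = theta
    if s2s <= 0 or s2f < 0:
        return -np.inf
    n, p = X.shape
    XtVX, XtVy, ytVy, logdetV = _reml_quantities(theta, y, X, codes, n_frag)
    try:
        cf = linalg.cho_factor(XtVX)
    except linalg.LinAlgError:
        return -np.inf
    beta = linalg.cho_solve(cf, XtVy)
    quad = ytVy - beta @ XtVy
    logdetXtVX = 2.0 * float(np.sum(np.log(np.diag(cf[0]))))
    return -0.5 * (logdetV + logdetXtVX + quad + (n - p) * math.log(2 * math.pi))


def _gls_fit(theta, y, X, codes, n_frag):
    XtVX, XtVy, _, _ = _reml_quantities(theta, y, X, codes, n_frag)
    cov = linalg.inv(XtVX)
    beta = cov @ XtVy
    return beta, cov


def _component_ses(theta, y, X, codes, n_frag):
    """Standard errors from the numeric Hessian of the REML log-likelihood."""

    def ll(t):
        return _reml_loglik(t, y, X, codes, n_frag)

    h = [max(1e-6, 1e-4 * abs(t)) for t in theta]
    # keep all finite-difference points inside the feasible region
    theta = (max(theta[0], 2 * h[0]), max(theta[1], 2 * h[1]))
    H = np.empty((2, 2))
    for a in range(2):
        for b in range(a, 2):
            ta = np.array(theta, float)
            pts = []
            for sa in (1, -1):
                for sb in (1, -1):
                    t = ta.copy()
                    t[a] += sa * h[a]
                    t[b] += sb * h[b]
                    pts.append(sa * sb * ll(t))
            H[a, b] = H[b, a] = sum(pts) / (4 * h[a] * h[b])
    try:
        cov = linalg.inv(-H)
        ses = np.sqrt(np.clip(np.diag(cov), 0.0, None))
    except (linalg.LinAlgError, ValueError):
        ses = np.array([np.nan, np.nan])
    return float(ses[0]), float(ses[1])


# ---------------------------------------------------------------------------
# public estimators
# ---------------------------------------------------------------------------


def fit_mixed_model(table: pd.DataFrame, spec: ModelSpec | None = None) -> FitResult:
    """REML fit of the nested mixed model.

    Deterministic given the data.  Degenerate tables (all responses equal)
    return zero components and null tests rather than failing.
    """
    spec = spec or ModelSpec()
    if spec.response not in table.columns:
        raise DataError(f"response column '{spec.response}' missing")
    y = table[spec.response].to_numpy(float)
    if np.isnan(y).any():
        raise DataError("missing values in response")
    codes = _fragment_codes(table, spec)
    n_frag = int(codes.max()) + 1 if len(codes) else 0
    frag_sizes = np.bincount(codes)
    if n_frag < 2 or (frag_sizes >= 2).sum() < 2:
        raise DataError("need >= 2 fragments with >= 2 sections each")
    X, names, terms = _build_design(table, spec)
    n, p = X.shape

    if np.ptp(y) == 0.0:
        params = pd.Series(np.r_[y[0], np.zeros(p - 1)], index=names)
        se = pd.Series(np.zeros(p), index=names)
        tests = {
            f: FixedEffectTest(0.0, max(len(ix), 1), float(n - p), 1.0, 1.0)
            for f, ix in terms.items()
        }
        vc = VarianceComponents(0.0, 0.0)
        return FitResult(params, se, tests, vc, math.inf, True, "degenerate", n, n_frag)

    # fragment-level design rank decides containment df for the F tests
    frag_level = np.array(
        [all(np.ptp(X[codes == k, j]) == 0 for k in range(n_frag)) for j in range(p)]
    )

    theta0, sm_converged, method = _initial_fit(y, X, codes, n_frag)
    theta, ll = _polish(theta0, y, X, codes, n_frag)
    # a finite polished optimum (possibly on the s2f = 0 boundary) is a
    # valid REML solution even when the initial iterative fit flagged
    # non-convergence at the boundary
    converged = sm_converged or bool(np.isfinite(ll))
    truncated = theta[0] <= 1e-10
    if truncated:
        theta = (0.0, theta[1])
    se_f, se_s = _component_ses(
        (max(theta[0], 1e-8), theta[1]), y, X, codes, n_frag
    )
    vc = VarianceComponents(
        sigma2_fragment=theta[0],
        sigma2_section=theta[1],
        se_fragment=float("nan") if truncated else se_f,
        se_section=se_s,
        truncated=truncated,
    )

    beta, cov = _gls_fit((theta[0], max(theta[1], 1e-12)), y, X, codes, n_frag)
    params = pd.Series(beta, index=names)
    se = pd.Series(np.sqrt(np.diag(cov)), index=names)

    p_frag_level = int(frag_level.sum())
    tests: dict[str, FixedEffectTest] = {}
    for factor, ix in terms.items():
        if not ix:
            raise FitError(f"factor '{factor}' has a single level; no contrast to test")
        L = np.zeros((len(ix), p))
        for r, j in enumerate(ix):
            L[r, j] = 1.0
        Lb = L @ beta
        M = L @ cov @ L.T
        stat = float(Lb @ linalg.solve(M, Lb, assume_a="pos"))
        q = len(ix)
        if all(frag_level[j] for j in ix):
            df_den = float(n_frag - p_frag_level)
        else:
            df_den = float(n - p - n_frag + 1)
        df_den = max(df_den, 1.0)
        tests[factor] = FixedEffectTest(
            statistic=stat / q,
            df_num=q,
            df_den=df_den,
            pvalue=float(stats.f.sf(stat / q, q, df_den)),
            pvalue_chi2=float(stats.chi2.sf(stat, q)),
        )

    return FitResult(params, se, tests, vc, ll, converged, method, n, n_frag)


def _initial_fit(y, X, codes, n_frag):
    """statsmodels MixedLM REML fit; moment-based fallback on failure."""
    from statsmodels.regression.mixed_linear_model import MixedLM

    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = MixedLM(y, X, groups=codes).fit(reml=True)
        s2f = float(np.asarray(res.cov_re).ravel()[0])
        s2s = float(res.scale)
        return (max(s2f, 0.0), max(s2s, 1e-12)), bool(res.converged), "reml"
    except Exception:
        v = float(np.var(y, ddof=1))
        return (v / 2, v / 2), False, "reml-fallback"


def _polish(theta0, y, X, codes, n_frag):
    """Tighten the REML optimum on the explicit profile log-likelihood."""

    def nll(t):
        return -_reml_loglik(t, y, X, codes, n_frag)

    best = optimize.minimize(
        nll,
        x0=np.array(theta0, float),
        method="Nelder-Mead",
        options={"xatol": 1e-12, "fatol": 1e-12, "maxiter": 2000},
    )
    candidates = [(nll(theta0), tuple(theta0))]
    if best.success or best.fun < candidates[0][0]:
        t = (max(best.x[0], 0.0), max(best.x[1], 1e-12))
        candidates.append((nll(t), t))
    # the boundary solution matters when the interior optimum has s2f < 0
    bnd = optimize.minimize_scalar(
        lambda s: nll((0.0, s)),
        bracket=None,
        bounds=(1e-10, 10 * (theta0[0] + theta0[1]) + 1.0),
        method="bounded",
        options={"xatol": 1e-12},
    )
    candidates.append((bnd.fun, (0.0, float(bnd.x))))
    fun, theta = min(candidates, key=lambda c: c[0])
    return theta, -fun


def estimate_components_moments(
    table: pd.DataFrame,
    spec: ModelSpec | None = None,
    cell_factors: tuple[str, ...] | None = None,
) -> VarianceComponents:
    """Expected-mean-squares (ANOVA) estimator on a balanced nested table.

    Within each (ewe, ovary, group) cell with F fragments of S sections:
    sigma2_section-hat = MS_within, sigma2_fragment-hat =
    (MS_between − MS_within)/S truncated at 0; cells pooled by degrees of
    freedom.  Serves as an independent oracle for :func:`fit_mixed_model`.
    """
    spec = spec or ModelSpec()
    if spec.response not in table.columns:
        raise DataError(f"response column '{spec.response}' missing")
    cell_factors = cell_factors or tuple(
        f for f in (*spec.fixed_factors, "group") if f in table.columns
    )
    frag = spec.nested_label(table, spec.random_factor)
    work = table.assign(_frag=frag)

    sizes = work.groupby("_frag")[spec.response].size()
    if sizes.nunique() != 1 or sizes.iloc[0] < 2:
        raise DataError(
            "unbalanced table (unequal sections per fragment): use fit_mixed_model"
        )
    S = int(sizes.iloc[0])

    cells = (
        work.groupby(list(cell_factors), sort=True) if cell_factors else [((), work)]
    )
    ssw = ssb = 0.0
    dfw = dfb = 0
    for _, cell in cells:
        frag_groups = cell.groupby("_frag")[spec.response]
        F = frag_groups.ngroups
        if F < 2:
            raise DataError("each cell needs >= 2 fragments for the moments estimator")
        means = frag_groups.mean()
        ssw += float(((cell[spec.response] - means.reindex(cell["_frag"]).to_numpy()) ** 2).sum())
        dfw += F * (S - 1)
        ssb += float(S * ((means - means.mean()) ** 2).sum())
        dfb += F - 1
    ms_within = ssw / dfw
    ms_between = ssb / dfb
    s2f = (ms_between - ms_within) / S
    return VarianceComponents(
        sigma2_fragment=max(s2f, 0.0),
        sigma2_section=ms_within,
        truncated=s2f < 0.0,
    )


def variance_proportions(
    vc: VarianceComponents | tuple[float, float],
) -> tuple[float, float]:
    """Percent of total variance at the fragment and section levels.

    Accepts a :class:`VarianceComponents` or a bare ``(sigma2_fragment,
    sigma2_section)`` pair; returns ``(prop_fragment, prop_section)`` in
    percent.  Use :func:`variance_proportion_ses` for delta-method SEs.
    """
    if not isinstance(vc, VarianceComponents):
        vc = VarianceComponents(*vc)
    if vc.total <= 0:
        raise ParameterError("both components zero: proportions undefined")
    pf = 100.0 * vc.sigma2_fragment / vc.total
    return pf, 100.0 - pf


def variance_proportion_ses(vc: VarianceComponents) -> tuple[float, float]:
    """First-order delta-method SEs of the two variance proportions.

    With p_f = 100·s2f/(s2f+s2s) the gradient is 100/(total²)·(s2s, −s2f),
    and p_s = 100 − p_f, so (treating the component estimates as
    independent) both proportions share the same standard error.
    """
    if vc.total <= 0:
        raise ParameterError("both components zero: proportions undefined")
    g_f = 100.0 * vc.sigma2_section / vc.total**2
    g_s = 100.0 * vc.sigma2_fragment / vc.total**2
    var = (g_f * vc.se_fragment) ** 2 + (g_s * vc.se_section) ** 2
    se = math.sqrt(var)
    return se, se


def test_fixed_effect(fit: FitResult, factor: str) -> float:
    """p-value of the joint contrast for one fixed factor."""
    if factor not in fit.tests:
        raise ParameterError(
            f"factor '{factor}' not in fit (have {sorted(fit.tests)})"
        )
    return fit.tests[factor].pvalue
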