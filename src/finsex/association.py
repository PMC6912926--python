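"""ANCOVA of pigmentation intensity on treatment, sex and polynomial body
size, with backward elimination, studentized-residual outlier filtering,
and Tukey–Kramer least-squares means.

The response is the cohort-level z-transformed SVM score difference (the
pigmentation-intensity statistic).  The full model contains the fixed
factors treatment (alpha_i) and sex (beta_j), their interaction, and a body
size covariate x (weight in g or length in mm) as polynomial terms up to
degree 3 together with their interactions with each factor:

    y_ijk = mu + alpha_i + beta_j + (alpha beta)_ij
            + sum_k b_k x^k + sum_k c_k beta_j x^k + sum_k d_k alpha_i x^k
            + eps_ijk .

Backward elimination removes, one at a time, the least significant term
whose removal respects marginality (no term is dropped while a kept term
contains it), refitting until every removable term passes the stay
threshold.  Outliers are flagged by externally studentized residuals
(leave-one-out variance) and removed in a single pass followed by one
refit.  Factors use sum-to-zero coding and covariates are mean-centered
before raising to powers (collinearity control); both are internal and do
not appear in reported quantities.  LS-means are estimable-function
predictions at the covariate grand mean with Tukey–Kramer adjusted pairwise
p-values from the studentized range distribution.

The same machinery, without a covariate, provides the two-way ANOVA used
for body weight and length themselves.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from scipy.stats import studentized_range
from statsmodels.stats.outliers_influence import OLSInfluence

# Sum-to-zero codes for the two-level factors, by sorted level order.
_GROUP_CODE = {"control": 1.0, "treatment": -1.0}
_SEX_CODE = {"F": 1.0, "M": -1.0}


class AliasingError(ValueError):
    """Design matrix is rank-deficient; the message names aliased terms."""


@dataclass(frozen=True)
class Term:
    """One model term: a named design column with its marginality parents."""

    name: str
    parents: tuple[str, ...] = ()


@dataclass(frozen=True)
class AncovaSpec:
    """Specification of the full (pre-elimination) intensity model.

    ``covariate`` is a column name ("body_weight_g" or "total_length_mm"),
    or None for the pure two-way ANOVA.  ``alpha_stay`` is the F-test
    p-value a term must beat to stay during backward elimination.
    """

    response: str = "z"
    covariate: Optional[str] = "body_weight_g"
    max_poly_degree: int = 3
    alpha_stay: float = 0.05
    include_treatment_covariate: bool = True

    def __post_init__(self) -> None:
        if self.covariate is not None and self.max_poly_degree not in (1, 2, 3):
            raise ValueError("max_poly_degree must be 1, 2 or 3")
        if not 0.0 < self.alpha_stay < 1.0:
            raise ValueError("alpha_stay must lie in (0, 1)")

    def terms(self) -> list[Term]:
        """Full term list in deterministic order (the elimination tie-break)."""
        out = [
            Term("Intercept"),
            Term("treatment"),
            Term("sex"),
            Term("treatment:sex", parents=("treatment", "sex")),
        ]
        if self.covariate is None:
            return out
        for k in range(1, self.max_poly_degree + 1):
            parents = (f"x^{k - 1}",) if k >= 2 else ()
            out.append(Term(f"x^{k}", parents=parents))
        for k in range(1, self.max_poly_degree + 1):
            parents = ["sex", f"x^{k}"]
            if k >= 2:
                parents.append(f"sex:x^{k - 1}")
            out.append(Term(f"sex:x^{k}", parents=tuple(parents)))
        if self.include_treatment_covariate:
            for k in range(1, self.max_poly_degree + 1):
                parents = ["treatment", f"x^{k}"]
                if k >= 2:
                    parents.append(f"treatment:x^{k - 1}")
                out.append(Term(f"treatment:x^{k}", parents=tuple(parents)))
        return out


@dataclass
class AncovaFit:
    """A fitted (possibly reduced) intensity model.

    Holds the kept terms, the statsmodels OLS result, the term-wise
    extra-sum-of-squares ANOVA table, and enough bookkeeping (covariate
    center, data) to build estimable functions for LS-means.
    """

    spec: AncovaSpec
    data: pd.DataFrame
    terms: list[Term]
    center: float
    result: object  # statsmodels RegressionResults
    anova_table: pd.DataFrame = field(default_factory=pd.DataFrame)

    @property
    def term_names(self) -> list[str]:
        return [t.name for t in self.terms]

    @property
    def coefficients(self) -> pd.Series:
        return pd.Series(self.result.params, index=self.term_names)

    @property
    def residuals(self) -> np.ndarray:
        return np.asarray(self.result.resid)

    def ids(self) -> list[str]:
        return [str(v) for v in self.data["id"]]


# -- design construction ----------------------------------------------------


def _term_column(
    term: Term, data: pd.DataFrame, covariate: Optional[str], center: float
) -> np.ndarray:
    n = len(data)
    g = data["group"].map(_GROUP_CODE).to_numpy(dtype=float)
    s = data["true_sex"].map(_SEX_CODE).to_numpy(dtype=float)
    if np.isnan(g).any():
        raise ValueError("group must be 'control' or 'treatment'")
    if np.isnan(s).any():
        raise ValueError("true_sex must be 'M' or 'F'")
    xc = None
    if covariate is not None:
        xc = data[covariate].to_numpy(dtype=float) - center
    name = term.name
    if name == "Intercept":
        return np.ones(n)
    if name == "treatment":
        return g
    if name == "sex":
        return s
    if name == "treatment:sex":
        return g * s
    if name.startswith("x^"):
        return xc ** int(name[2:])
    if name.startswith("sex:x^"):
        return s * xc ** int(name[6:])
    if name.startswith("treatment:x^"):
        return g * xc ** int(name[12:])
    raise ValueError(f"unknown term {name!r}")


def build_design(
    data: pd.DataFrame, terms: Sequence[Term], covariate: Optional[str], center: float
) -> np.ndarray:
    X = np.column_stack(
        [_term_column(t, data, covariate, center) for t in terms]
    )
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        aliased = _aliased_terms(X, [t.name for t in terms])
        raise AliasingError(f"design is rank-deficient; aliased terms: {aliased}")
    return X


def _aliased_terms(X: np.ndarray, names: list[str]) -> list[str]:
    _, R = np.linalg.qr(X)
    diag = np.abs(np.diag(R))
    tol = diag.max() * max(X.shape) * np.finfo(float).eps
    return [names[i] for i in np.flatnonzero(diag < tol)]


def fit_terms(
    spec: AncovaSpec,
    data: pd.DataFrame,
    terms: Sequence[Term],
    center: Optional[float] = None,
) -> AncovaFit:
    """OLS fit of the given terms; computes the term-wise ANOVA table."""
    data = data.reset_index(drop=True)
    y = data[spec.response].to_numpy(dtype=float)
    if spec.covariate is not None:
        xvals = data[spec.covariate].to_numpy(dtype=float)
        if np.ptp(xvals) == 0:
            raise ValueError(f"covariate {spec.covariate!r} is degenerate (constant)")
        if center is None:
            center = float(xvals.mean())
    else:
        center = 0.0
    counts = data.groupby(["group", "true_sex"]).size()
    for g in data["group"].unique():
        for s in data["true_sex"].unique():
            if counts.get((g, s), 0) < 2:
                raise ValueError(
                    f"need >= 2 observations per treatment-by-sex cell; cell ({g}, {s}) "
                    f"has {counts.get((g, s), 0)}"
                )
    X = build_design(data, terms, spec.covariate, center)
    result = sm.OLS(y, X).fit()
    fit = AncovaFit(
        spec=spec, data=data, terms=list(terms), center=center, result=result
    )
    fit.anova_table = _anova_table(fit, X, y)
    return fit


def _anova_table(fit: AncovaFit, X: np.ndarray, y: np.ndarray) -> pd.DataFrame:
    """Extra-sum-of-squares (drop-one-term) F-tests for each non-intercept term."""
    rss_full = float(fit.result.ssr)
    df_full = int(fit.result.df_resid)
    rows = []
    for i, term in enumerate(fit.terms):
        if term.name == "Intercept":
            continue
        Xr = np.delete(X, i, axis=1)
        rss_r = float(sm.OLS(y, Xr).fit().ssr)
        q = 1
        if df_full <= 0 or rss_full <= 0:
            F, p = np.inf, 0.0
        else:
            F = ((rss_r - rss_full) / q) / (rss_full / df_full)
            p = float(stats.f.sf(F, q, df_full))
        rows.append({"term": term.name, "df": q, "F": F, "p": p})
    return pd.DataFrame(rows)


def fit_full(spec: AncovaSpec, data: pd.DataFrame) -> AncovaFit:
    """Fit the full polynomial ANCOVA design defined by ``spec``."""
    return fit_terms(spec, data, spec.terms())


# -- backward elimination ---------------------------------------------------


def _removable(terms: list[Term]) -> list[Term]:
    kept = {t.name for t in terms}
    blocked = set()
    for t in terms:
        blocked.update(p for p in t.parents if p in kept)
    return [t for t in terms if t.name != "Intercept" and t.name not in blocked]


def backward_eliminate(fit: AncovaFit, alpha_stay: Optional[float] = None) -> AncovaFit:
    """Iteratively drop the least significant removable term.

    At each step the removable term (one no kept term contains) with the
    largest drop-one F-test p-value above ``alpha_stay`` is removed and the
    model refitted; ties break by reverse term order (later terms first),
    which is deterministic.  May reduce to the intercept-only model.
    """
    alpha = fit.spec.alpha_stay if alpha_stay is None else alpha_stay
    current = fit
    while True:
        removable = {t.name for t in _removable(current.terms)}
        if not removable:
            return current
        tab = current.anova_table
        cand = tab[tab["term"].isin(removable)]
        worst_p = cand["p"].max()
        if not worst_p > alpha:
            return current
        # reverse term order among ties: highest-order terms leave first
        ties = set(cand.loc[cand["p"] == worst_p, "term"])
        for t in reversed(current.terms):
            if t.name in ties:
                drop = t.name
                break
        new_terms = [t for t in current.terms if t.name != drop]
        current = fit_terms(current.spec, current.data, new_terms, center=current.center)


# -- outlier filtering ------------------------------------------------------


def studentized_outliers(fit: AncovaFit, threshold: float = 3.0) -> list[str]:
    """Ids with |externally studentized residual| > threshold.

    Externally studentized residuals use the leave-one-out error variance,
    matching regression influence diagnostics.  Raises on (near-)saturated
    models where the statistic is undefined.
    """
    if fit.result.df_resid < 2:
        raise ValueError("model is (nearly) saturated; studentized residuals undefined")
    y = np.asarray(fit.result.model.endog)
    if fit.result.ssr <= 1e-10 * (np.abs(y).max() ** 2 + 1e-30):
        return []  # exact fit: all residuals are numerical zero
    with np.errstate(divide="ignore", invalid="ignore"):
        r = np.asarray(OLSInfluence(fit.result).resid_studentized_external)
    r = np.nan_to_num(r)  # exact-fit (zero-residual) observations are not outliers
    ids = fit.ids()
    return [ids[i] for i in np.flatnonzero(np.abs(r) > threshold)]


def filter_outliers_and_refit(
    fit: AncovaFit, threshold: float = 3.0
) -> tuple[AncovaFit, list[str]]:
    """Single-pass outlier filter: flag, drop, refit once."""
    flagged = studentized_outliers(fit, threshold)
    if not flagged:
        return fit, []
    keep = ~fit.data["id"].astype(str).isin(flagged)
    refit = fit_terms(fit.spec, fit.data[keep], fit.terms, center=fit.center)
    return refit, flagged


# -- LS-means ---------------------------------------------------------------


def _contrast_row(
    fit: AncovaFit, group: str, sex: str, at: Optional[float]
) -> np.ndarray:
    """Estimable-function row L for one factor cell at covariate value ``at``."""
    xc = 0.0 if at is None else float(at) - fit.center
    g = _GROUP_CODE[group]
    s = _SEX_CODE[sex]
    row = []
    for t in fit.terms:
        name = t.name
        if name == "Intercept":
            row.append(1.0)
        elif name == "treatment":
            row.append(g)
        elif name == "sex":
            row.append(s)
        elif name == "treatment:sex":
            row.append(g * s)
        elif name.startswith("x^"):
            row.append(xc ** int(name[2:]))
        elif name.startswith("sex:x^"):
            row.append(s * xc ** int(name[6:]))
        elif name.startswith("treatment:x^"):
            row.append(g * xc ** int(name[12:]))
        else:
            raise ValueError(f"non-estimable term {name!r}")
    return np.asarray(row)


def _compact_letters(names: list[str], nonsig: set[tuple[str, str]]) -> dict[str, str]:
    """Compact letter display: maximal cliques of the nonsignificance graph."""
    k = len(names)
    adj = {(a, b) for a, b in nonsig} | {(b, a) for a, b in nonsig}
    cliques = []
    for size in range(k, 0, -1):
        for combo in itertools.combinations(range(k), size):
            if all((names[a], names[b]) in adj for a, b in itertools.combinations(combo, 2)):
                cset = set(combo)
                if not any(cset <= c for c in cliques):
                    cliques.append(cset)
    cliques.sort(key=lambda c: min(c))
    letters = {n: "" for n in names}
    for letter, clique in zip("abcdefghij", cliques):
        for i in sorted(clique):
            letters[names[i]] += letter
    return letters


def ls_means(
    fit: AncovaFit,
    at: Optional[float] = None,
    by: tuple[str, ...] = ("group", "true_sex"),
) -> pd.DataFrame:
    """Least-squares means per factor cell, with Tukey–Kramer pairwise tests.

    Covariate terms are evaluated at the covariate grand mean by default or
    at a caller-supplied raw value ``at``.  Returns one row per cell with
    the estimate, its SE from the coefficient covariance, and a
    compact-letter display; attaches the adjusted pairwise p-values as the
    ``pairwise_p`` attribute in ``DataFrame.attrs``.
    """
    levels = {
        "group": sorted(fit.data["group"].unique()),
        "true_sex": sorted(fit.data["true_sex"].unique()),
    }
    cells = list(itertools.product(*(levels[f] for f in by)))
    beta = np.asarray(fit.result.params)
    V = np.asarray(fit.result.cov_params())
    df_resid = float(fit.result.df_resid)

    def cell_L(cell: tuple[str, ...]) -> np.ndarray:
        assign = dict(zip(by, cell))
        if "group" in assign and "true_sex" in assign:
            return _contrast_row(fit, assign["group"], assign["true_sex"], at)
        # marginal LS-mean: average the cell rows over the absent factor
        if "group" in assign:
            rows = [_contrast_row(fit, assign["group"], s, at) for s in levels["true_sex"]]
        else:
            rows = [_contrast_row(fit, g, assign["true_sex"], at) for g in levels["group"]]
        return np.mean(rows, axis=0)

    Ls = [cell_L(c) for c in cells]
    names = ["*".join(c) for c in cells]
    est = np.array([L @ beta for L in Ls])
    se = np.array([np.sqrt(L @ V @ L) for L in Ls])

    k = len(cells)
    pairs: dict[tuple[str, str], float] = {}
    nonsig: set[tuple[str, str]] = set()
    for i, j in itertools.combinations(range(k), 2):
        Ld = Ls[i] - Ls[j]
        sed = float(np.sqrt(Ld @ V @ Ld))
        tstat = abs(float(Ld @ beta)) / sed if sed > 0 else np.inf
        p = float(studentized_range.sf(tstat * np.sqrt(2.0), k, df_resid))
        pairs[(names[i], names[j])] = p
        if p > 0.05:
            nonsig.add((names[i], names[j]))
    letters = _compact_letters(names, nonsig)

    out = pd.DataFrame({"cell": names, "estimate": est, "se": se})
    out["letters"] = [letters[n] for n in names]
    out.attrs["pairwise_p"] = pairs
    out.attrs["at"] = at
    return out


def sex_specific_slopes(fit: AncovaFit, conf: float = 0.95) -> pd.DataFrame:
    """Linear covariate slope per sex at the covariate grand mean.

    The derivative of the fitted surface with respect to x at the grand
    mean involves only the degree-1 terms: slope_sex = b(x) + code(sex) *
    b(sex:x) (+ treatment terms averaged out).  Returns estimate, SE and a
    confidence interval per sex.
    """
    beta = np.asarray(fit.result.params)
    V = np.asarray(fit.result.cov_params())
    names = fit.term_names
    tcrit = stats.t.ppf(0.5 + conf / 2, fit.result.df_resid)
    rows = []
    for sex, code in _SEX_CODE.items():
        L = np.zeros(len(names))
        for i, n in enumerate(names):
            if n == "x^1":
                L[i] = 1.0
            elif n == "sex:x^1":
                L[i] = code
            # treatment:x^1 averages to 0 across balanced groups
        est = float(L @ beta)
        se = float(np.sqrt(L @ V @ L))
        rows.append(
            {
                "true_sex": sex,
                "slope": est,
                "se": se,
                "ci_low": est - tcrit * se,
                "ci_high": est + tcrit * se,
            }
        )
    return pd.DataFrame(rows)


# -- two-way ANOVA for body size -------------------------------------------

SizeAnovaFit = AncovaFit


def fit_size_anova(data: pd.DataFrame, response: str) -> AncovaFit:
    """Two-way treatment-by-sex ANOVA for body weight or total length."""
    spec = AncovaSpec(response=response, covariate=None)
    return fit_terms(spec, data, spec.terms())


# -- synthetic responses for recovery studies -------------------------------


def simulate_intensity_data(
    n_per_cell: int,
    mu: float = 0.0,
    treatment_effect: float = 0.0,
    sex_effect: float = 0.0,
    interaction: float = 0.0,
    b1: float = 0.0,
    b2: float = 0.0,
    noise_sd: float = 1.0,
    weight_means: Optional[dict] = None,
    weight_sd: float = 0.07,
    seed: int = 0,
) -> pd.DataFrame:
    """Draw a balanced cohort whose z follows the final intensity model.

    z = mu + a*g + b*s + ab*g*s + b1*xc + b2*s*xc + N(0, noise_sd), with g
    and s the sum-to-zero treatment and sex codes and xc the body-weight
    deviation from the overall mean.  Used by parameter-recovery and
    elimination power studies; generating coefficients are directly
    comparable to the fitted sum-coded parameters.
    """
    from finsex.simulate import DEFAULT_WEIGHT_MEANS

    wm = weight_means or DEFAULT_WEIGHT_MEANS
    grand = float(np.mean(list(wm.values())))
    rng = np.random.default_rng(seed)
    rows = []
    i = 0
    for group in ("control", "treatment"):
        for sex in ("M", "F"):
            g, s = _GROUP_CODE[group], _SEX_CODE[sex]
            w = rng.normal(wm[(group, sex)], weight_sd, size=n_per_cell)
            xc = w - grand
            z = (
                mu
                + treatment_effect * g
                + sex_effect * s
                + interaction * g * s
                + b1 * xc
                + b2 * s * xc
                + rng.normal(0.0, noise_sd, size=n_per_cell)
            )
            for j in range(n_per_cell):
                rows.append(
                    {
                        "id": f"sim{i:05d}",
                        "group": group,
                        "true_sex": sex,
                        "body_weight_g": float(w[j]),
                        "z": float(z[j]),
                    }
                )
                i += 1
    return pd.DataFrame(rows)
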