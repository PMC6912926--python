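"""Classifier-vs-truth agreement (phi coefficient) and logit-link
sex-ratio modelling.

The phi coefficient of a 2x2 contingency table,

    phi = (n11 n22 - n12 n21) / sqrt(r1 r2 c1 c2),

equals the Pearson correlation of the two binary indicator variables and
lies in [-1, 1].  Sex ratios per treatment group are modelled as Bernoulli
outcomes with a logit link, logit(pi_i) = eta_i = mu + alpha_i; group
LS-means are estimated on the logit scale and back-transformed with the
inverse link pi = exp(eta) / (1 + exp(eta)).  Pairwise group contrasts are
tested on the logit scale with a Tukey–Kramer adjustment (which reduces to
the unadjusted two-sided test when there are two groups).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import statsmodels.api as sm
from scipy.stats import studentized_range


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Counts of (true, predicted) sex pairs.

    n11: true M predicted M, n12: true M predicted F,
    n21: true F predicted M, n22: true F predicted F.
    """

    n11: int
    n12: int
    n21: int
    n22: int

    def __post_init__(self) -> None:
        cells = (self.n11, self.n12, self.n21, self.n22)
        if any(c < 0 for c in cells):
            raise ValueError("counts must be nonnegative")
        if sum(cells) == 0:
            raise ValueError("table is empty")

    @property
    def total(self) -> int:
        return self.n11 + self.n12 + self.n21 + self.n22

    def margins(self) -> tuple[int, int, int, int]:
        """(row1, row2, col1, col2) sums: true M/F counts, predicted M/F counts."""
        return (
            self.n11 + self.n12,
            self.n21 + self.n22,
            self.n11 + self.n21,
            self.n12 + self.n22,
        )


def confusion(truth: Sequence[str], predicted: Sequence[str]) -> ContingencyTable2x2:
    """Tabulate true-vs-predicted sex labels ("M"/"F") into a 2x2 table."""
    t = np.asarray(truth)
    p = np.asarray(predicted)
    if t.shape != p.shape or t.size == 0:
        raise ValueError("truth and predicted must be equal-length, nonempty")
    bad = set(np.unique(np.concatenate([t, p]))) - {"M", "F"}
    if bad:
        raise ValueError(f"labels must be 'M' or 'F', got extras {sorted(bad)}")
    return ContingencyTable2x2(
        n11=int(((t == "M") & (p == "M")).sum()),
        n12=int(((t == "M") & (p == "F")).sum()),
        n21=int(((t == "F") & (p == "M")).sum()),
        n22=int(((t == "F") & (p == "F")).sum()),
    )


def phi(table: ContingencyTable2x2) -> float:
    """Mean-square contingency (phi) coefficient of a 2x2 table.

    Raises on any zero margin (a silent 0 would corrupt agreement
    summaries); phi = +1 is perfect agreement, -1 perfect disagreement.
    """
    r1, r2, c1, c2 = table.margins()
    if min(r1, r2, c1, c2) == 0:
        raise ValueError(f"phi undefined: zero margin in table {table}")
    num = table.n11 * table.n22 - table.n12 * table.n21
    return float(num / np.sqrt(float(r1) * r2 * c1 * c2))


@dataclass
class SexRatioFit:
    """Logit-scale group LS-means and back-transformed male proportions."""

    groups: tuple[str, ...]
    eta: np.ndarray          # logit-scale LS-means
    se: np.ndarray           # standard errors of eta
    pi: np.ndarray           # back-transformed male probabilities
    contrast_p: dict[tuple[str, str], float]  # Tukey–Kramer adjusted

    def percent_male(self) -> np.ndarray:
        return 100.0 * self.pi


def fit_sex_ratio(
    successes: Sequence[int],
    totals: Sequence[int],
    groups: Sequence[str] | None = None,
) -> SexRatioFit:
    """Fit the one-factor Bernoulli logit GLM to per-group male counts.

    For this saturated model the fitted probability equals the group
    proportion and SE(eta_i) = sqrt(1 / (n_i p_i (1 - p_i))); the fit is by
    maximum likelihood (IRLS).  Groups with p = 0 or 1 are separated: their
    eta is +/-inf with unbounded SE, reported with a warning.
    """
    succ = np.asarray(successes, dtype=float)
    tot = np.asarray(totals, dtype=float)
    if succ.shape != tot.shape or succ.ndim != 1 or succ.size == 0:
        raise ValueError("successes and totals must be equal-length 1-D")
    if (tot <= 0).any():
        raise ValueError("totals must be > 0")
    if ((succ < 0) | (succ > tot)).any():
        raise ValueError("successes must lie in [0, total]")
    k = succ.size
    names = tuple(groups) if groups is not None else tuple(f"g{i}" for i in range(k))

    p_hat = succ / tot
    eta = np.empty(k)
    se = np.empty(k)
    finite = (p_hat > 0) & (p_hat < 1)
    if not finite.all():
        warnings.warn(
            "complete separation in groups "
            f"{[names[i] for i in np.flatnonzero(~finite)]}: eta unbounded",
            RuntimeWarning,
            stacklevel=2,
        )
    eta[~finite] = np.where(p_hat[~finite] > 0.5, np.inf, -np.inf)
    se[~finite] = np.inf
    if finite.any():
        idx = np.flatnonzero(finite)
        exog = np.eye(k)[idx][:, idx]  # cell-means coding over finite groups
        endog = np.column_stack([succ[idx], tot[idx] - succ[idx]])
        with warnings.catch_warnings():
            # the saturated cell-means fit has zero deviance and zero
            # residual df by construction; statsmodels warns about both
            warnings.simplefilter("ignore", RuntimeWarning)
            warnings.filterwarnings("ignore", message=".*[Pp]erfect separation.*")
            res = sm.GLM(endog, exog, family=sm.families.Binomial()).fit(
                tol=1e-14, maxiter=200
            )
        eta[idx] = res.params
        se[idx] = res.bse
    pi = np.where(np.isfinite(eta), 1.0 / (1.0 + np.exp(-np.clip(eta, -500, 500))), p_hat)

    contrast_p: dict[tuple[str, str], float] = {}
    for i in range(k):
        for j in range(i + 1, k):
            if np.isfinite(se[i]) and np.isfinite(se[j]):
                zstat = abs(eta[i] - eta[j]) / np.sqrt(se[i] ** 2 + se[j] ** 2)
                # Tukey–Kramer on the logit scale; infinite df (asymptotic z).
                p = float(studentized_range.sf(zstat * np.sqrt(2.0), k, np.inf))
            else:
                p = np.nan
            contrast_p[(names[i], names[j])] = p
    return SexRatioFit(groups=names, eta=eta, se=se, pi=pi, contrast_p=contrast_p)


def agreement_report(
    truth: Sequence[str], predicted: Sequence[str], group: Sequence[str] | None = None
) -> dict:
    """JSON-ready agreement summary: per-group tables, phi, proportions, GLM."""
    truth = np.asarray(truth)
    predicted = np.asarray(predicted)
    grp = np.asarray(group) if group is not None else np.full(truth.shape, "all")
    report: dict = {"groups": {}}
    names, succ, tot = [], [], []
    for g in sorted(set(grp)):
        mask = grp == g
        table = confusion(truth[mask], predicted[mask])
        entry: dict = {
            "table": {"n11": table.n11, "n12": table.n12, "n21": table.n21, "n22": table.n22},
            "n": table.total,
            "pct_male_true": 100.0 * (table.n11 + table.n12) / table.total,
            "pct_male_predicted": 100.0 * (table.n11 + table.n21) / table.total,
        }
        try:
            entry["phi"] = phi(table)
        except ValueError as exc:
            entry["phi"] = None
            entry["phi_error"] = str(exc)
        report["groups"][g] = entry
        names.append(g)
        succ.append(table.n11 + table.n12)
        tot.append(table.total)
    if len(names) > 1:
        fit = fit_sex_ratio(succ, tot, groups=names)
        report["sex_ratio_glm"] = {
            "groups": list(fit.groups),
            "eta": fit.eta.tolist(),
            "se": fit.se.tolist(),
            "pct_male": fit.percent_male().tolist(),
            "contrast_p": {f"{a}|{b}": p for (a, b), p in fit.contrast_p.items()},
        }
    return report
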