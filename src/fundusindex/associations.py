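"""Association analyses between the fundus sex index and covariates.

Reproduces the downstream statistics of the index workflow: Pearson and
Spearman correlations of the index with body height and axial length
(overall and within each sex), Mann-Whitney comparisons of the covariates
between sexes, bidirectional stepwise multiple regression for axial length
(entry p < 0.05, removal p >= 0.10, the defaults of the classic clinical
statistics packages), and an ordinary least-squares regression of the index
on height and sex.  Both correlation flavors are always reported.
Significance is flagged at p < 0.001 (large-sample convention).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .errors import CollinearityError, DataError, JoinError, UndefinedValueError

SIGNIFICANCE_LEVEL = 0.001


def correlate(x, y, method: str = "pearson") -> tuple[float, float]:
    """Correlation coefficient and two-sided p (t approximation).

    Spearman's rho is Pearson's r on midranks.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise DataError("correlation needs two aligned vectors of length >= 3")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise DataError("correlation inputs must be finite")
    if np.std(x) == 0 or np.std(y) == 0:
        raise UndefinedValueError("correlation undefined for a zero-variance vector")
    if method == "pearson":
        result = stats.pearsonr(x, y)
    elif method == "spearman":
        result = stats.spearmanr(x, y)
    else:
        raise DataError(f"unknown correlation method {method!r}")
    return float(result.statistic), float(result.pvalue)


def mann_whitney(group_a, group_b) -> tuple[float, float]:
    """Mann-Whitney U (pairs with a > b plus half the ties) and two-sided p.

    p uses the normal approximation with tie correction and no continuity
    correction; when every pair is tied the variance vanishes and p = 1.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise DataError("Mann-Whitney requires two non-empty groups")
    with np.errstate(invalid="ignore", divide="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        result = stats.mannwhitneyu(
            a, b, alternative="two-sided", method="asymptotic", use_continuity=False
        )
    p = float(result.pvalue)
    if not np.isfinite(p):  # all observations tied: no evidence either way
        p = 1.0
    return float(result.statistic), p


def _ols(y: np.ndarray, X: np.ndarray):
    """Least squares with t-test p-values; X excludes the intercept column."""
    n = len(y)
    A = np.column_stack([np.ones(n), X])
    k = A.shape[1]
    coef, _, rank, _ = np.linalg.lstsq(A, y, rcond=None)
    if rank < k:
        raise CollinearityError("design matrix is rank deficient")
    resid = y - A @ coef
    df = n - k
    if df <= 0:
        raise DataError("not enough observations for the requested model")
    s2 = resid @ resid / df
    cov = s2 * np.linalg.inv(A.T @ A)
    se = np.sqrt(np.diag(cov))
    with np.errstate(divide="ignore", invalid="ignore"):
        tvals = coef / se
    pvals = 2.0 * stats.t.sf(np.abs(tvals), df)
    return coef, se, pvals


@dataclass
class StepwiseResult:
    selected: list[str]
    coef: dict[str, float]
    std_coef: dict[str, float]
    pvalues: dict[str, float]
    intercept: float


def stepwise_regression(
    response,
    candidates: pd.DataFrame,
    p_enter: float = 0.05,
    p_remove: float = 0.10,
) -> StepwiseResult:
    """Bidirectional stepwise OLS selection for a continuous response.

    Forward step: add the candidate whose coefficient has the smallest
    p-value, if below p_enter.  Backward step: drop any included variable
    whose p-value has risen to p_remove or above.  Deterministic given the
    data; an empty selection returns the intercept-only model.
    """
    y = np.asarray(response, dtype=float)
    if candidates.shape[0] != len(y):
        raise DataError("response and candidate table have different lengths")
    if candidates.shape[0] <= candidates.shape[1]:
        raise DataError("need more observations than candidate variables")
    names = list(candidates.columns)
    data = candidates.to_numpy(dtype=float)

    tss = float(((y - y.mean()) ** 2).sum())
    selected: list[str] = []
    while True:
        changed = False
        # stop once the current model is numerically exact (zero residual
        # variance makes further t-tests meaningless)
        if selected:
            cols = [names.index(v) for v in selected]
            A = np.column_stack([np.ones(len(y)), data[:, cols]])
            coef, _, _, _ = np.linalg.lstsq(A, y, rcond=None)
            rss = float(((y - A @ coef) ** 2).sum())
            if rss <= 1e-10 * tss:
                break
        # forward
        best_name, best_p = None, None
        for name in names:
            if name in selected:
                continue
            cols = [names.index(v) for v in selected + [name]]
            try:
                _, _, pvals = _ols(y, data[:, cols])
            except CollinearityError:
                continue
            p_new = pvals[-1]  # p of the newly added variable
            if best_p is None or p_new < best_p:
                best_name, best_p = name, p_new
        if best_name is not None and best_p < p_enter:
            selected.append(best_name)
            changed = True
        # backward
        while selected:
            cols = [names.index(v) for v in selected]
            _, _, pvals = _ols(y, data[:, cols])
            worst = int(np.argmax(pvals[1:]))
            if pvals[1:][worst] >= p_remove:
                selected.pop(worst)
                changed = True
            else:
                break
        if not changed:
            break

    if not selected:
        return StepwiseResult(
            selected=[], coef={}, std_coef={}, pvalues={}, intercept=float(y.mean())
        )
    cols = [names.index(v) for v in selected]
    coef, _, pvals = _ols(y, data[:, cols])
    sy = y.std(ddof=1)
    std_coef = {
        v: float(coef[j + 1] * data[:, names.index(v)].std(ddof=1) / sy)
        for j, v in enumerate(selected)
    }
    return StepwiseResult(
        selected=selected,
        coef={v: float(coef[j + 1]) for j, v in enumerate(selected)},
        std_coef=std_coef,
        pvalues={v: float(pvals[j + 1]) for j, v in enumerate(selected)},
        intercept=float(coef[0]),
    )


def regress_index_on_height_sex(index, height, sex) -> dict:
    """OLS of the index on body height and sex (female = 1); standardized
    coefficients are coef * SD(x) / SD(y)."""
    y = np.asarray(index, dtype=float)
    h = np.asarray(height, dtype=float)
    sex = np.asarray(sex)
    if len(y) < 10:
        raise DataError("regression needs at least 10 subjects")
    s = np.where(sex == "female", 1.0, np.where(sex == "male", 0.0, np.nan))
    if np.isnan(s).any():
        s = sex.astype(float)
    if np.std(h) == 0 or np.std(s) == 0 or np.std(y) == 0:
        raise CollinearityError("a regression variable is constant")
    X = sm.add_constant(np.column_stack([h, s]))
    fit = sm.OLS(y, X).fit()
    sy = y.std(ddof=1)
    return {
        "intercept": float(fit.params[0]),
        "height": {
            "coef": float(fit.params[1]),
            "std_coef": float(fit.params[1] * h.std(ddof=1) / sy),
            "p": float(fit.pvalues[1]),
        },
        "sex": {
            "coef": float(fit.params[2]),
            "std_coef": float(fit.params[2] * s.std(ddof=1) / sy),
            "p": float(fit.pvalues[2]),
        },
    }


@dataclass
class AssociationReport:
    """Correlation, group-difference and regression tables of one cohort."""

    correlations: pd.DataFrame
    group_tests: pd.DataFrame
    index_on_height_sex: dict
    stepwise: dict | None = None

    def to_dict(self) -> dict:
        payload = {
            "correlations": self.correlations.to_dict(orient="records"),
            "group_tests": self.group_tests.to_dict(orient="records"),
            "index_on_height_sex": self.index_on_height_sex,
        }
        if self.stepwise is not None:
            payload["stepwise_axial_length"] = {
                group: (
                    {
                        "selected": res.selected,
                        "coef": res.coef,
                        "std_coef": res.std_coef,
                        "pvalues": res.pvalues,
                        "intercept": res.intercept,
                    }
                    if res is not None
                    else None
                )
                for group, res in self.stepwise.items()
            }
        return payload

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=1, sort_keys=True, allow_nan=True)

    def to_markdown(self) -> str:
        lines = ["# Fundus sex index association report", "", "## Correlations", ""]
        lines.append(self.correlations.to_string(index=False))
        lines += ["", "## Sex differences (Mann-Whitney U)", ""]
        lines.append(self.group_tests.to_string(index=False))
        lines += ["", "## Index ~ height + sex (OLS, standardized coefficients)", ""]
        for term in ("height", "sex"):
            entry = self.index_on_height_sex[term]
            lines.append(
                f"- {term}: std coef {entry['std_coef']:+.3f} (p = {entry['p']:.3g})"
            )
        if self.stepwise is not None:
            lines += ["", "## Stepwise regression for axial length", ""]
            for group, res in self.stepwise.items():
                if res is None:
                    lines.append(f"- {group}: not computable (too few subjects)")
                    continue
                chosen = (
                    ", ".join(
                        f"{v} ({res.std_coef[v]:+.3f})" for v in res.selected
                    )
                    or "(intercept only)"
                )
                lines.append(f"- {group}: {chosen}")
        return "\n".join(lines) + "\n"


_CORR_VARIABLES = (("fundus_sex_index", "height_cm"), ("fundus_sex_index", "axial_length_mm"))
_GROUP_VARIABLES = ("age", "height_cm", "axial_length_mm", "fundus_sex_index")


def build_report(
    index: pd.DataFrame,
    covariates: pd.DataFrame,
    features: pd.DataFrame | None = None,
) -> AssociationReport:
    """Assemble the full association report from an index table and covariates.

    index needs columns subject_id and fundus_sex_index; covariates the
    simulate-stage schema.  If a 42-parameter feature table (indexed by
    subject_id) is supplied, stepwise regression of axial length on the
    index plus all parameters is run overall and within each sex.
    """
    idx_ids = set(index["subject_id"])
    cov_ids = set(covariates["subject_id"])
    if idx_ids != cov_ids:
        raise JoinError(idx_ids.symmetric_difference(cov_ids))
    merged = covariates.merge(
        index[["subject_id", "fundus_sex_index"]], on="subject_id", how="inner"
    ).sort_values("subject_id").reset_index(drop=True)
    merged = merged.dropna(subset=["fundus_sex_index", "height_cm", "axial_length_mm"])

    rows = []
    groups = {
        "all": merged,
        "male": merged[merged["sex"] == "male"],
        "female": merged[merged["sex"] == "female"],
    }
    for (var_x, var_y) in _CORR_VARIABLES:
        for group, frame in groups.items():
            for method in ("pearson", "spearman"):
                row = {
                    "pair": f"{var_x}~{var_y}",
                    "subgroup": group,
                    "method": method,
                    "n": len(frame),
                }
                try:
                    r, p = correlate(frame[var_x], frame[var_y], method=method)
                    row.update(r=r, p=p, significant=bool(p < SIGNIFICANCE_LEVEL))
                except (DataError, UndefinedValueError):
                    row.update(r=np.nan, p=np.nan, significant=False)
                rows.append(row)
    correlations = pd.DataFrame(rows)

    men = merged[merged["sex"] == "male"]
    women = merged[merged["sex"] == "female"]
    test_rows = []
    for variable in _GROUP_VARIABLES:
        if variable not in merged.columns:
            continue
        u, p = mann_whitney(men[variable], women[variable])
        test_rows.append(
            {
                "variable": variable,
                "U": u,
                "p": p,
                "significant": bool(p < SIGNIFICANCE_LEVEL),
                "mean_male": float(men[variable].mean()),
                "mean_female": float(women[variable].mean()),
            }
        )
    group_tests = pd.DataFrame(test_rows)

    height_sex = regress_index_on_height_sex(
        merged["fundus_sex_index"], merged["height_cm"], merged["sex"]
    )

    stepwise = None
    if features is not None:
        feat = features.loc[merged["subject_id"]].reset_index(drop=True)
        candidates = pd.concat(
            [merged[["fundus_sex_index"]].reset_index(drop=True), feat], axis=1
        )
        stepwise = {}
        for group, frame in groups.items():
            sel = frame.index
            try:
                stepwise[group] = stepwise_regression(
                    frame["axial_length_mm"].to_numpy(),
                    candidates.loc[sel].reset_index(drop=True),
                )
            except DataError:  # subgroup smaller than the candidate count
                stepwise[group] = None
    return AssociationReport(
        correlations=correlations,
        group_tests=group_tests,
        index_on_height_sex=height_sex,
        stepwise=stepwise,
    )
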