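"""Genotype comparison of per-fish summaries.

Each kinematic parameter is compared between the two genotypes with a
linear mixed model — a fixed genotype effect and a random intercept per
clutch — tested by a 1-df Type II Wald chi-square.  A variance-
stabilising transform (none / log / sqrt) is chosen automatically by
residual skewness.  Within an analysis family (escape: 8 parameters,
forward swims: 6, routine turns: 6) the raw p-values are multiplied by
the effective number of independent tests

    Meff = 1 + (k - 1) * (1 - Vcorr / k),

where ``Vcorr`` is the sample variance (denominator k - 1) of the
eigenvalues of the parameters' Spearman rank-correlation matrix: k
independent parameters give Meff = k (a Bonferroni factor), perfectly
correlated parameters give Meff = 1 (no correction).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.api as sm
from statsmodels.tools.sm_exceptions import ConvergenceWarning

from .errors import ComparisonError

__all__ = ["MeffResult", "ComparisonResult", "choose_transform",
           "fit_genotype_model", "compute_meff", "adjust_pvalues",
           "compare_groups", "ANALYSES"]

#: parameter columns of the fish-summary table per analysis family
ANALYSES: dict[str, list[str]] = {
    "escape": ["esc_distance_mm", "esc_duration_s", "esc_speed_mm_s",
               "esc_n_osc", "esc_tbf_hz", "esc_latency_ms", "esc_cbend_deg",
               "esc_counterbend_deg"],
    "forward": ["fwd_distance_mm", "fwd_duration_s", "fwd_speed_mm_s",
                "fwd_median_bend_deg", "fwd_n_osc", "fwd_tbf_hz"],
    "turn": ["turn_distance_mm", "turn_duration_s", "turn_speed_mm_s",
             "turn_median_bend_deg", "turn_n_osc", "turn_tbf_hz"],
    "boutrate": ["bout_rate_hz"],
}


@dataclass
class MeffResult:
    """Effective number of independent tests for one analysis family."""

    k: int
    eigenvalues: np.ndarray
    vcorr: float
    meff: float


@dataclass
class ComparisonResult:
    """Genotype comparison of a single kinematic parameter."""

    parameter: str
    transform: str                    # "none" | "log" | "sqrt"
    wald_chi2: float
    p_raw: float
    meff: float
    p_adj: float
    group_means: dict = field(default_factory=dict)   # genotype -> (mean, sem)
    n: dict = field(default_factory=dict)             # genotype -> n fish


_TRANSFORMS = {
    "none": lambda x: x,
    "log": np.log,
    "sqrt": np.sqrt,
}


def choose_transform(values: np.ndarray, groups: np.ndarray) -> str:
    """Pick the transform minimising |skewness| of the within-group
    residuals.

    ``log`` is only eligible for strictly positive data, ``sqrt`` for
    non-negative data.
    """
    values = np.asarray(values, dtype=float)
    candidates = ["none"]
    if np.all(values >= 0):
        candidates.append("sqrt")
    if np.all(values > 0):
        candidates.append("log")
    best, best_skew = "none", np.inf
    for name in candidates:
        t = _TRANSFORMS[name](values)
        resid = t - pd.Series(t).groupby(pd.Series(groups)).transform("mean")
        skew = abs(float(sps.skew(resid)))
        if skew < best_skew - 1e-12:
            best, best_skew = name, skew
    return best


def fit_genotype_model(summaries: pd.DataFrame, parameter: str,
                       transform: str = "none") -> tuple[float, float]:
    """Wald chi-square (1 df) and raw p for the genotype fixed effect.

    Fits ``transform(parameter) ~ genotype + (1 | clutch)`` by REML.  A
    degenerate clutch variance (or a failed mixed fit) falls back to the
    marginal ordinary-least-squares model, which the mixed model equals
    in that limit, so a finite statistic is always returned.
    """
    df = summaries[["genotype", "clutch", parameter]].dropna()
    genotypes = df["genotype"].unique()
    if len(genotypes) != 2:
        raise ComparisonError(
            f"{parameter}: need exactly two genotypes, found {list(genotypes)}")
    if df["clutch"].nunique() < 2:
        raise ComparisonError(f"{parameter}: need at least two clutches")
    y = _TRANSFORMS[transform](df[parameter].to_numpy(dtype=float))
    x = (df["genotype"] == genotypes[1]).to_numpy(dtype=float)
    work = pd.DataFrame({"y": y, "g": x, "clutch": df["clutch"].to_numpy()})
    chi2 = None
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ConvergenceWarning)
            warnings.simplefilter("ignore", RuntimeWarning)
            warnings.simplefilter("ignore", UserWarning)
            model = sm.MixedLM.from_formula("y ~ g", groups="clutch", data=work)
            fit = model.fit(reml=True)
        se = float(fit.bse_fe["g"])
        if np.isfinite(se) and se > 0:
            chi2 = float((fit.fe_params["g"] / se) ** 2)
    except (np.linalg.LinAlgError, ValueError):
        chi2 = None
    if chi2 is None:  # boundary/degenerate fit: marginal model
        ols = sm.OLS(work["y"], sm.add_constant(work["g"])).fit()
        chi2 = float((ols.params["g"] / ols.bse["g"]) ** 2)
    return chi2, float(sps.chi2.sf(chi2, df=1))


def compute_meff(matrix: pd.DataFrame | np.ndarray) -> MeffResult:
    """Meff from a fish x parameter matrix.

    Spearman rank correlation -> eigenvalues -> Vcorr (sample variance,
    denominator k - 1) -> Meff = 1 + (k - 1)(1 - Vcorr / k).  Rows with
    missing values are dropped; a constant column has no rank variance
    and raises :class:`ComparisonError` naming it.
    """
    df = pd.DataFrame(matrix)
    df = df.dropna()
    k = df.shape[1]
    if k < 1:
        raise ComparisonError("need at least one parameter")
    if k == 1:
        return MeffResult(k=1, eigenvalues=np.array([1.0]), vcorr=0.0, meff=1.0)
    if df.shape[0] < k + 1:
        raise ComparisonError(
            f"need at least k+1={k + 1} complete fish, have {df.shape[0]}")
    for col in df.columns:
        if df[col].nunique() <= 1:
            raise ComparisonError(
                f"parameter {col!r} is constant: rank correlation undefined")
    rho, _ = sps.spearmanr(df.to_numpy())
    if np.ndim(rho) == 0:  # scipy returns a scalar for k = 2
        rho = np.array([[1.0, float(rho)], [float(rho), 1.0]])
    eig = np.linalg.eigvalsh(rho)
    vcorr = float(np.var(eig, ddof=1))
    meff = 1.0 + (k - 1) * (1.0 - vcorr / k)
    return MeffResult(k=k, eigenvalues=eig[::-1], vcorr=vcorr,
                      meff=float(np.clip(meff, 1.0, k)))


def adjust_pvalues(p_raw, meff: float):
    """Meff multiplicity adjustment: ``min(1, p * meff)`` elementwise."""
    if meff < 1.0:
        raise ValueError("meff must be >= 1")
    return np.minimum(1.0, np.asarray(p_raw, dtype=float) * meff)


def compare_groups(summaries: pd.DataFrame, analysis: str = "forward",
                   parameters: list[str] | None = None,
                   ) -> list[ComparisonResult]:
    """Run one analysis family on a fish-summary table.

    QC-failing fish are excluded; a shared Meff is computed from the
    family's fish x parameter matrix (single-parameter families use
    Meff = 1); each parameter is transformed, mixed-model tested and
    Meff-adjusted.  Group means +- SEM are reported on the original
    scale.
    """
    if parameters is None:
        try:
            parameters = ANALYSES[analysis]
        except KeyError:
            raise ComparisonError(f"unknown analysis {analysis!r}") from None
    use = summaries
    if "qc_pass" in use.columns and analysis in ("forward", "turn", "boutrate"):
        use = use[use["qc_pass"].astype(bool)]
    missing = [p for p in parameters if p not in use.columns]
    if missing:
        raise ComparisonError(f"summary table lacks columns {missing}")
    meff = (compute_meff(use[parameters]).meff if len(parameters) > 1 else 1.0)
    results = []
    for parameter in parameters:
        sub = use.dropna(subset=[parameter])
        transform = choose_transform(sub[parameter].to_numpy(),
                                     sub["genotype"].to_numpy())
        chi2, p_raw = fit_genotype_model(sub, parameter, transform)
        means = {}
        ns = {}
        for g, grp in sub.groupby("genotype"):
            v = grp[parameter].to_numpy(dtype=float)
            means[g] = (float(v.mean()),
                        float(v.std(ddof=1) / np.sqrt(len(v))) if len(v) > 1
                        else float("nan"))
            ns[g] = int(len(v))
        results.append(ComparisonResult(
            parameter=parameter, transform=transform, wald_chi2=chi2,
            p_raw=p_raw, meff=meff,
            p_adj=float(adjust_pvalues(p_raw, meff)),
            group_means=means, n=ns))
    return results


def results_table(results: list[ComparisonResult]) -> pd.DataFrame:
    """Flatten comparison results into a report table."""
    rows = []
    for r in results:
        row = {"parameter": r.parameter, "transform": r.transform,
               "wald_chi2": r.wald_chi2, "p_raw": r.p_raw, "meff": r.meff,
               "p_adj": r.p_adj}
        for g, (mean, sem) in r.group_means.items():
            row[f"mean_{g}"] = mean
            row[f"sem_{g}"] = sem
            row[f"n_{g}"] = r.n[g]
        rows.append(row)
    return pd.DataFrame(rows)
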