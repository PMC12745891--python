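"""Protocol-comparison statistics.

Two layers mirror the study designs they serve:

* Parameter sweeps (repeated scans per tested parameter value) are compared
  with Welch's heteroscedastic one-way ANOVA followed by Games-Howell
  pairwise tests, with eta-squared and Cohen's f effect sizes. Replicate
  scans are treated as independent measurements.
* Patient-derived waveform comparisons use a linear mixed-effects model with
  a fixed effect per protocol (relative to a reference protocol) and a random
  intercept per waveform, absorbing the inter-waveform amplitude variability.

Welch's ANOVA and Games-Howell are computed directly from the textbook
formulas (scipy supplies the F and studentized-range distributions); the LMM
is fit by REML via statsmodels.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import DegenerateVarianceError

#: significance star convention used in the figures
STAR_LEVELS = ((0.001, "***"), (0.01, "**"), (0.05, "*"))


def significance_stars(p: float) -> str:
    for level, stars in STAR_LEVELS:
        if p < level:
            return stars
    return ""


@dataclass(frozen=True)
class EffectSizes:
    """ANOVA effect sizes; ``cohens_f = sqrt(eta2 / (1 - eta2))``."""

    eta_squared: float

    def __post_init__(self):
        if not 0 <= self.eta_squared < 1:
            raise ValueError("eta_squared must be in [0, 1)")

    @property
    def cohens_f(self) -> float:
        return float(np.sqrt(self.eta_squared / (1 - self.eta_squared)))


def effect_sizes(eta_squared: float) -> EffectSizes:
    """Validate eta-squared and derive Cohen's f."""
    return EffectSizes(float(eta_squared))


@dataclass(frozen=True)
class WelchAnovaResult:
    F: float
    df1: float
    df2: float
    p: float
    effects: EffectSizes


def _groups(table: pd.DataFrame, dv: str, group_by: str) -> list[np.ndarray]:
    groups = [g[dv].to_numpy(dtype=float) for _, g in table.groupby(group_by, observed=True)]
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    for g in groups:
        if len(g) < 2:
            raise ValueError("every group needs at least 2 replicates")
        if np.var(g, ddof=1) <= 0:
            raise DegenerateVarianceError("zero within-group variance")
    return groups


def welch_anova(table: pd.DataFrame, group_by: str, dv: str = "displacement") -> WelchAnovaResult:
    """Welch's heteroscedastic one-way ANOVA with eta-squared.

    Eta-squared uses the classical between/total sum-of-squares decomposition
    (the convention when reported alongside Welch's F).
    """
    groups = _groups(table, dv, group_by)
    k = len(groups)
    n = np.array([len(g) for g in groups], dtype=float)
    m = np.array([g.mean() for g in groups])
    v = np.array([g.var(ddof=1) for g in groups])
    w = n / v
    W = w.sum()
    mw = (w * m).sum() / W
    num = (w * (m - mw) ** 2).sum() / (k - 1)
    lam = ((1 - w / W) ** 2 / (n - 1)).sum()  # Satterthwaite-type term
    den = 1 + 2 * (k - 2) / (k**2 - 1) * lam
    F = float(num / den)
    df1 = k - 1
    df2 = float((k**2 - 1) / (3 * lam))
    p = float(sps.f.sf(F, df1, df2))

    allv = np.concatenate(groups)
    grand = allv.mean()
    ss_between = (n * (m - grand) ** 2).sum()
    ss_total = ((allv - grand) ** 2).sum()
    eta2 = float(ss_between / ss_total) if ss_total > 0 else 0.0
    return WelchAnovaResult(F, df1, df2, p, EffectSizes(min(eta2, 1 - 1e-12)))


def games_howell(table: pd.DataFrame, group_by: str, dv: str = "displacement") -> pd.DataFrame:
    """Games-Howell pairwise comparisons (studentized-range adjustment).

    Returns one row per unordered pair with the mean difference, its SE,
    the Welch-Satterthwaite df, the adjusted p-value and significance stars.
    """
    _groups(table, dv, group_by)  # validation
    names = []
    arrays = []
    for name, g in table.groupby(group_by, observed=True):
        names.append(name)
        arrays.append(g[dv].to_numpy(dtype=float))
    k = len(names)
    rows = []
    for i in range(k):
        for j in range(i + 1, k):
            a, b = arrays[i], arrays[j]
            na, nb = len(a), len(b)
            va, vb = a.var(ddof=1), b.var(ddof=1)
            se2 = va / na + vb / nb
            diff = a.mean() - b.mean()
            t = diff / np.sqrt(se2)
            df = se2**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
            p = float(sps.studentized_range.sf(np.abs(t) * np.sqrt(2), k, df))
            rows.append(
                {
                    "A": names[i],
                    "B": names[j],
                    "mean_diff": float(diff),
                    "se": float(np.sqrt(se2)),
                    "t": float(t),
                    "df": float(df),
                    "p_adj": min(p, 1.0),
                    "stars": significance_stars(p),
                }
            )
    return pd.DataFrame(rows)


@dataclass
class LmmResult:
    """Fixed effects of each condition relative to the reference protocol."""

    table: pd.DataFrame  # condition, estimate, se, ci_low, ci_high, p, stars
    reference: str
    random_effect_var: float
    converged: bool

    def estimate(self, condition: str) -> float:
        return float(self.table.set_index("condition").loc[condition, "estimate"])


def lmm_compare(
    table: pd.DataFrame,
    reference_protocol: str,
    dv: str = "displacement",
    protocol_col: str = "protocol",
    waveform_col: str = "waveform_id",
    ground_truth_col: str = "ground_truth_pp",
    include_waveform_mean: bool = True,
) -> LmmResult:
    """Mixed-effects comparison of protocols against a reference.

    Fits ``dv ~ C(protocol)`` with a random intercept per waveform (REML).
    When ``include_waveform_mean`` is set and a ground-truth column is
    present, the programmed mean amplitude of each waveform enters as a
    pseudo-condition ``waveform_mean``, so its fixed effect reports how far
    the reference protocol sits from the programmed motion.

    On a singular/non-converged fit the function falls back to a
    per-waveform paired summary and flags ``converged=False``.
    """
    import statsmodels.formula.api as smf

    df = table[[protocol_col, waveform_col, dv]].copy()
    if include_waveform_mean and ground_truth_col in table.columns:
        gt = (
            table[[waveform_col, ground_truth_col]]
            .drop_duplicates(waveform_col)
            .rename(columns={ground_truth_col: dv})
        )
        gt[protocol_col] = "waveform_mean"
        df = pd.concat([df, gt[[protocol_col, waveform_col, dv]]], ignore_index=True)

    levels = [x for x in df[protocol_col].unique() if x != reference_protocol]
    if reference_protocol not in set(df[protocol_col]):
        raise ValueError(f"reference protocol {reference_protocol!r} not in table")

    formula = f"{dv} ~ C({protocol_col}, Treatment(reference='{reference_protocol}'))"
    converged = True
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = smf.mixedlm(formula, df, groups=df[waveform_col])
            fit = model.fit(reml=True)
        if not np.all(np.isfinite(fit.bse)):
            raise ValueError("singular fit")
        rows = []
        for lev in levels:
            key = f"C({protocol_col}, Treatment(reference='{reference_protocol}'))[T.{lev}]"
            est, se, p = fit.params[key], fit.bse[key], fit.pvalues[key]
            rows.append((lev, est, se, p))
        re_var = float(np.asarray(fit.cov_re).ravel()[0])
    except Exception:
        converged = False
        warnings.warn("mixed model failed to converge; using paired per-waveform summary", stacklevel=2)
        ref_means = df[df[protocol_col] == reference_protocol].groupby(waveform_col)[dv].mean()
        rows = []
        for lev in levels:
            lev_means = df[df[protocol_col] == lev].groupby(waveform_col)[dv].mean()
            paired = (lev_means - ref_means).dropna()
            est = paired.mean()
            se = paired.std(ddof=1) / np.sqrt(len(paired)) if len(paired) > 1 else np.nan
            p = float(sps.ttest_1samp(paired, 0).pvalue) if len(paired) > 1 else np.nan
            rows.append((lev, est, se, p))
        re_var = float("nan")

    out = pd.DataFrame(rows, columns=["condition", "estimate", "se", "p"])
    out["ci_low"] = out["estimate"] - 1.96 * out["se"]
    out["ci_high"] = out["estimate"] + 1.96 * out["se"]
    out["stars"] = [significance_stars(p) if np.isfinite(p) else "" for p in out["p"]]
    out = out[["condition", "estimate", "se", "ci_low", "ci_high", "p", "stars"]]
    return LmmResult(out, reference_protocol, re_var, converged)
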