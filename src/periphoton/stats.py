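"""Inferential layer: mixed-effects model on AUCs, rm-ANOVA, effect sizes.

The headline model is a linear mixed-effects model on the windowed AUC
values,

    AUC ~ stress * social * timepoint + (1 | mouse)

with all main effects, two- and three-way interactions as fixed effects and
a random intercept per mouse, estimated by REML with Wald z tests per
coefficient. Factors use treatment (dummy) coding with reference levels
pre-stress, non-aggressive target and the baseline window, so e.g. the
``timepoint[after]`` coefficient is the after-minus-baseline contrast at the
reference levels of the other factors.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf
from scipy import stats as sps
from statsmodels.stats.anova import AnovaRM, anova_lm
from statsmodels.tools.sm_exceptions import ConvergenceWarning

__all__ = [
    "LMMResult",
    "EffectSize",
    "fit_auc_lmm",
    "rm_anova",
    "cohens_d",
    "log_transform_vigilance",
    "two_way_anova_planned",
    "normality_diagnostics",
]

LMM_FORMULA = (
    "auc ~ C(stress, Treatment('pre')) * C(social, Treatment('non-aggressive'))"
    " * C(timepoint, Treatment('baseline'))"
)


def _clean_term(term: str) -> str:
    """'C(stress, Treatment('pre'))[T.post]' -> 'stress[post]'."""
    out = re.sub(r"C\((\w+),\s*Treatment\([^)]*\)\)\[T\.([^\]]+)\]", r"\1[\2]", term)
    return out


@dataclass
class LMMResult:
    """Per-term Wald table and fit metadata for the AUC mixed model."""

    terms: pd.DataFrame  # index: cleaned term; columns: beta, se, z, p
    n_obs: int
    n_groups: int
    converged: bool
    random_intercept_var: float
    formula: str = LMM_FORMULA

    def term(self, name: str) -> pd.Series:
        """Look up one fixed-effect row, e.g. ``term('timepoint[after]')``."""
        if name not in self.terms.index:
            raise KeyError(
                f"no term {name!r}; available: {list(self.terms.index)}"
            )
        return self.terms.loc[name]


def fit_auc_lmm(auc_table: pd.DataFrame, subject_col: str = "mouse") -> LMMResult:
    """Fit the three-factor mixed model with a random intercept per mouse.

    Requires >= 2 mice and every factor present with >= 2 levels. Singular or
    non-converged fits are flagged in the result, not raised — the Wald table
    is still returned with a warning state.
    """
    df = auc_table.copy()
    required = {subject_col, "stress", "social", "timepoint", "auc"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"AUC table missing columns: {sorted(missing)}")
    if df[subject_col].nunique() < 2:
        raise ValueError("mixed model needs >= 2 mice")
    for col, min_levels in (("stress", 2), ("social", 2), ("timepoint", 2)):
        if df[col].nunique() < min_levels:
            raise ValueError(f"factor {col!r} needs >= {min_levels} levels")
    model = smf.mixedlm(LMM_FORMULA, data=df, groups=df[subject_col])
    # when the random-intercept variance sits on the zero boundary some
    # optimizers hit a singular Hessian; fall through a method chain
    fit = None
    caught: list[warnings.WarningMessage] = []
    for method in ("lbfgs", "powell", "nm"):
        try:
            with warnings.catch_warnings(record=True) as caught:
                warnings.simplefilter("always")
                fit = model.fit(reml=True, method=method)
            break
        except np.linalg.LinAlgError:
            continue
    if fit is None:
        raise RuntimeError("mixed model failed under every optimizer")
    converged = bool(getattr(fit, "converged", True)) and not any(
        issubclass(w.category, ConvergenceWarning) for w in caught
    )
    fe = fit.fe_params
    terms = pd.DataFrame({
        "beta": fe.values,
        "se": fit.bse_fe.values,
        "z": (fe / fit.bse_fe).values,
    }, index=[_clean_term(t) for t in fe.index])
    terms["p"] = 2 * sps.norm.sf(np.abs(terms["z"]))
    return LMMResult(
        terms=terms,
        n_obs=len(df),
        n_groups=df[subject_col].nunique(),
        converged=converged,
        random_intercept_var=float(np.asarray(fit.cov_re).ravel()[0]),
    )


def rm_anova(
    table: pd.DataFrame,
    dv: str,
    within: tuple[str, ...] = ("stress", "social"),
    subject: str = "mouse",
) -> pd.DataFrame:
    """Repeated-measures ANOVA with within-subject error terms.

    Multiple observations per (subject, cell) are averaged first; a missing
    cell is an error naming the (subject, condition) cell. Returns a table
    with F, df_num, df_den and p per effect (main effects and interaction).
    """
    cell = table.groupby([subject, *within], observed=True)[dv].mean().reset_index()
    levels = [sorted(cell[f].unique()) for f in within]
    for subj in sorted(cell[subject].unique()):
        sub = cell[cell[subject] == subj]
        have = set(map(tuple, sub[list(within)].itertuples(index=False)))
        for combo in _product(levels):
            if combo not in have:
                raise ValueError(
                    f"missing cell: subject {subj!r}, "
                    + ", ".join(f"{f}={v!r}" for f, v in zip(within, combo))
                )
    res = AnovaRM(cell, depvar=dv, subject=subject, within=list(within)).fit()
    tab = res.anova_table.rename(columns={
        "F Value": "F", "Num DF": "df_num", "Den DF": "df_den", "Pr > F": "p",
    })
    tab.index = [i.replace(":", " x ") for i in tab.index]
    tab = tab[["F", "df_num", "df_den", "p"]].copy()
    # degenerate guard: an effect whose numerator sum of squares vanishes
    # (response identical across its levels) is 0/0 in the within-subject
    # strata; report F = 0, p = 1 instead of numerical noise
    if len(within) == 2:
        cube = _cell_cube(cell, dv, within, subject)
        ss = _effect_numerator_ss(cube, within)
        total = float(np.sum((cube - cube.mean()) ** 2))
        for eff in tab.index:
            if ss[eff] <= 1e-12 * max(total, 1e-30):
                tab.loc[eff, ["F", "p"]] = 0.0, 1.0
    return tab


def _cell_cube(cell, dv, within, subject):
    levels = [sorted(cell[f].unique()) for f in within]
    subjects = sorted(cell[subject].unique())
    cube = np.empty((len(subjects), len(levels[0]), len(levels[1])))
    idx = cell.set_index([subject, *within])[dv]
    for i, s in enumerate(subjects):
        for a, la in enumerate(levels[0]):
            for b, lb in enumerate(levels[1]):
                cube[i, a, b] = idx.loc[(s, la, lb)]
    return cube


def _effect_numerator_ss(y: np.ndarray, within) -> dict:
    S, A, B = y.shape
    g = y.mean()
    m_a, m_b, m_ab = y.mean(axis=(0, 2)), y.mean(axis=(0, 1)), y.mean(axis=0)
    return {
        within[0]: S * B * float(np.sum((m_a - g) ** 2)),
        within[1]: S * A * float(np.sum((m_b - g) ** 2)),
        f"{within[0]} x {within[1]}": S * float(
            np.sum((m_ab - m_a[:, None] - m_b[None, :] + g) ** 2)),
    }


def _product(levels):
    out = [()]
    for lv in levels:
        out = [c + (v,) for c in out for v in lv]
    return out


@dataclass(frozen=True)
class EffectSize:
    """Cohen's d with the group summaries behind it."""

    d: float
    mean_a: float
    mean_b: float
    pooled_sd: float
    n_a: int
    n_b: int


def cohens_d(group_a, group_b) -> EffectSize:
    """d = (mean_a - mean_b) / pooled SD, with (n-1)-weighted pooled SD."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs n >= 2")
    na, nb = len(a), len(b)
    pooled = np.sqrt(
        ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2)
    )
    if pooled == 0:
        raise ValueError("zero pooled SD: effect size undefined")
    return EffectSize(
        d=float((a.mean() - b.mean()) / pooled),
        mean_a=float(a.mean()), mean_b=float(b.mean()),
        pooled_sd=float(pooled), n_a=na, n_b=nb,
    )


def log_transform_vigilance(values) -> np.ndarray:
    """log(x + 1) on vigilance durations (seconds).

    The +1 s offset keeps zero-vigilance sessions defined; the transform
    corrects the heterogeneous variance typical of duration data.
    """
    v = np.asarray(values, dtype=float)
    if np.any(v < 0):
        raise ValueError("vigilance durations must be non-negative")
    return np.log1p(v)


def two_way_anova_planned(
    table: pd.DataFrame,
    dv: str,
    factors: tuple[str, str] = ("sex", "treatment"),
    planned: list[tuple[dict, dict]] | None = None,
) -> dict:
    """Two-way between-subjects ANOVA plus planned pairwise comparisons.

    The omnibus table is a type-II ANOVA on ``dv ~ A * B``. Planned
    comparisons are Welch-corrected two-sample t tests between row subsets
    selected by column->value dicts; being planned, they are reported
    uncorrected and are not gated on the omnibus test.
    """
    a, b = factors
    model = smf.ols(f"{dv} ~ C({a}) * C({b})", data=table).fit()
    omnibus = anova_lm(model, typ=2)
    comparisons = []
    for sel_a, sel_b in planned or []:
        ga = _select(table, sel_a)[dv].to_numpy()
        gb = _select(table, sel_b)[dv].to_numpy()
        t, p = sps.ttest_ind(ga, gb, equal_var=False)
        comparisons.append({
            "a": sel_a, "b": sel_b, "t": float(t), "p": float(p),
            "d": cohens_d(ga, gb).d,
        })
    return {"omnibus": omnibus, "planned": comparisons}


def _select(df: pd.DataFrame, sel: dict) -> pd.DataFrame:
    mask = np.ones(len(df), dtype=bool)
    for col, val in sel.items():
        mask &= (df[col] == val).to_numpy()
    return df[mask]


def normality_diagnostics(values) -> dict:
    """Shapiro-Wilk normality check, emitted as a diagnostic (never a gate)."""
    v = np.asarray(values, dtype=float)
    w, p = sps.shapiro(v)
    return {"shapiro_w": float(w), "shapiro_p": float(p), "n": len(v)}


def variance_diagnostics(*groups) -> dict:
    """Fligner-Killeen homogeneity-of-variance check (diagnostic only)."""
    stat, p = sps.fligner(*groups)
    return {"fligner_stat": float(stat), "fligner_p": float(p)}
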