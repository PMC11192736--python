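"""Mixed-effects inference on per-trial coordination outcomes.

Each outcome (Fisher-z rho, coherence, %REC, MaxLine, gaze proportion) is
modelled with a linear mixed-effects model: fixed effects for the design
factors (coordination: 0 = spontaneous, 1 = intentional; avatar gaze:
0 = direct, 1 = averted), at most one questionnaire score (LSAS or AQ) and
optionally the participant-gaze proportion, plus a by-participant random
intercept. Models are fit by REML through statsmodels' MixedLM.

Degrees of freedom: the backend has no Satterthwaite approximation, so
t-tests use residual degrees of freedom (nobs minus the number of fixed
parameters); the choice is recorded in ``ModelResult.df_method``.
Interactions are decomposed with simple slopes (continuous moderators at
mean +/- 1 SD) and Tukey-adjusted pairwise contrasts of estimated marginal
means (studentised-range distribution; Bonferroni available as an
alternative).
"""
from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import FitError, ImputationError, ModelSpecError

log = logging.getLogger(__name__)

__all__ = [
    "ModelSpec",
    "ModelResult",
    "impute_subscale_mean",
    "center_predictors",
    "fit_lmm",
    "simple_slopes",
    "pairwise_contrasts",
]

QUESTIONNAIRES = ("lsas", "aq")


@dataclass(frozen=True)
class ModelSpec:
    """Specification of one mixed model.

    ``fixed`` is a formula right-hand side over columns of the study table
    (e.g. ``"lsas_c * gaze_code * coord_code"``). At most one questionnaire
    measure may appear; the random structure is fixed to a by-participant
    intercept.
    """

    outcome: str
    fixed: str
    groups: str = "participant_id"
    name: str = ""

    def validate(self, table: pd.DataFrame) -> None:
        if self.outcome not in table.columns:
            raise ModelSpecError(f"outcome {self.outcome!r} not in table")
        if self.groups not in table.columns:
            raise ModelSpecError(f"grouping column {self.groups!r} not in table")
        present = [q for q in QUESTIONNAIRES
                   if any(tok.startswith(q) for tok in _formula_tokens(self.fixed))]
        if len(present) > 1:
            raise ModelSpecError(
                "at most one questionnaire measure per model; found "
                f"{present}"
            )
        for tok in _formula_tokens(self.fixed):
            if tok not in table.columns:
                raise ModelSpecError(f"fixed-effect column {tok!r} not in table")


def _formula_tokens(rhs: str) -> list[str]:
    out = []
    for raw in rhs.replace("*", "+").replace(":", "+").split("+"):
        tok = raw.strip()
        if tok and tok != "1" and tok not in out:
            out.append(tok)
    return out


@dataclass
class ModelResult:
    """Tidy coefficient table plus everything contrasts/slopes need."""

    terms: pd.DataFrame  # columns: term, estimate, se, df, t, p
    cov: pd.DataFrame  # covariance of the fixed estimates
    resid_df: float
    df_method: str
    re_var: float  # by-participant intercept variance
    resid_var: float
    llf: float
    converged: bool
    singular: bool
    nobs: int
    spec: ModelSpec = None
    data: pd.DataFrame = None  # model frame (rows actually used)

    @property
    def params(self) -> pd.Series:
        return self.terms.set_index("term")["estimate"]

    def summary_text(self) -> str:
        lines = [
            f"Model: {self.spec.outcome} ~ {self.spec.fixed}",
            f"Random: ~1 | {self.spec.groups}   (REML, df = {self.df_method})",
            f"nobs = {self.nobs}, groups var = {self.re_var:.5g}, "
            f"residual var = {self.resid_var:.5g}, logLik = {self.llf:.3f}",
            f"converged = {self.converged}, singular = {self.singular}",
            "",
            self.terms.to_string(index=False, float_format=lambda v: f"{v: .5g}"),
        ]
        return "\n".join(lines)


def impute_subscale_mean(
    items: pd.DataFrame, subscales: dict[str, list[str]]
) -> pd.DataFrame:
    """Replace missing questionnaire items with the respondent's mean of the
    observed items in the same subscale.

    Raises :class:`ImputationError` if a respondent has an entire subscale
    missing (there is nothing to impute from).
    """
    out = items.copy()
    for name, cols in subscales.items():
        missing_cols = [c for c in cols if c not in out.columns]
        if missing_cols:
            raise ModelSpecError(f"subscale {name!r}: unknown items {missing_cols}")
        block = out[cols]
        all_missing = block.isna().all(axis=1)
        if all_missing.any():
            who = list(out.index[all_missing])
            raise ImputationError(
                f"subscale {name!r} entirely missing for respondent(s) {who}"
            )
        means = block.mean(axis=1)
        for c in cols:
            out[c] = out[c].fillna(means)
    return out


def center_predictors(
    table: pd.DataFrame, columns: list[str], suffix: str = "_c"
) -> tuple[pd.DataFrame, dict[str, float]]:
    """Mean-centre the listed columns, adding ``<col>_c`` versions.

    Returns the augmented table and the centring constants (needed to map
    conditional effects back to the raw scales).
    """
    out = table.copy()
    centers: dict[str, float] = {}
    for col in columns:
        if not pd.api.types.is_numeric_dtype(out[col]):
            raise TypeError(f"column {col!r} is not numeric")
        mu = float(out[col].mean())
        centers[col] = mu
        out[col + suffix] = out[col] - mu
    return out, centers


def _degenerate_fit(frame: pd.DataFrame, spec: ModelSpec) -> ModelResult:
    """Closed-form result for a zero-variance outcome: both variance
    components are zero and the model is a perfect (singular) fit."""
    import statsmodels.formula.api as smf

    log.warning("zero-variance outcome %r: singular fit", spec.outcome)
    ols = smf.ols(f"{spec.outcome} ~ {spec.fixed}", data=frame).fit()
    beta = ols.params.to_numpy()
    names = list(ols.params.index)
    k = len(names)
    resid_df = float(len(frame) - k)
    terms = pd.DataFrame({
        "term": names, "estimate": beta, "se": 0.0, "df": resid_df,
        "t": np.nan, "p": np.nan,
    })
    cov = pd.DataFrame(np.zeros((k, k)), index=names, columns=names)
    return ModelResult(
        terms=terms, cov=cov, resid_df=resid_df, df_method="residual",
        re_var=0.0, resid_var=0.0, llf=np.nan, converged=True, singular=True,
        nobs=len(frame), spec=spec, data=frame,
    )


def fit_lmm(table: pd.DataFrame, spec: ModelSpec) -> ModelResult:
    """REML fit of a by-participant random-intercept model."""
    import statsmodels.formula.api as smf

    spec.validate(table)
    cols = [spec.outcome, spec.groups] + _formula_tokens(spec.fixed)
    frame = table[list(dict.fromkeys(cols))].dropna().reset_index(drop=True)
    if len(frame) < 2:
        raise ModelSpecError("fewer than 2 complete rows")
    formula = f"{spec.outcome} ~ {spec.fixed}"
    if float(frame[spec.outcome].var()) == 0.0:
        return _degenerate_fit(frame, spec)
    singular = False
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        model = smf.mixedlm(formula, data=frame, groups=frame[spec.groups])
        try:
            fit = model.fit(reml=True)
        except np.linalg.LinAlgError as exc:
            raise FitError(f"mixed-model fit failed: {exc}") from exc
    for w in caught:
        if "singular" in str(w.message).lower() or "boundary" in str(w.message).lower():
            singular = True
    re_var = float(np.asarray(fit.cov_re).ravel()[0])
    if re_var < 1e-8 * max(float(fit.scale), 1e-30):
        # variance component on the boundary: a singular fit, not a failure
        singular = True
    if singular:
        log.warning("singular fit for %s ~ %s (random-intercept variance ~ 0)",
                    spec.outcome, spec.fixed)
    if not fit.converged and not singular:
        raise FitError(
            f"optimizer did not converge for {formula}; trace: {fit.summary()}"
        )
    if not np.all(np.isfinite(fit.fe_params.to_numpy())):
        raise FitError(f"non-finite fixed-effect estimates for {formula}")

    fe_names = list(fit.fe_params.index)
    k = len(fe_names)
    resid_df = float(len(frame) - k)
    est = fit.fe_params.to_numpy()
    cov = pd.DataFrame(
        np.asarray(fit.cov_params())[:k, :k], index=fe_names, columns=fe_names
    )
    se = np.sqrt(np.diag(cov.to_numpy()))
    tval = est / se
    pval = 2 * stats.t.sf(np.abs(tval), resid_df)
    terms = pd.DataFrame({
        "term": fe_names, "estimate": est, "se": se,
        "df": resid_df, "t": tval, "p": pval,
    })
    return ModelResult(
        terms=terms, cov=cov, resid_df=resid_df, df_method="residual",
        re_var=re_var, resid_var=float(fit.scale), llf=float(fit.llf),
        converged=bool(fit.converged), singular=singular, nobs=len(frame),
        spec=spec, data=frame,
    )


# ---------------------------------------------------------------------------
# interaction decomposition


def _term_components(term: str) -> list[str]:
    return [] if term == "Intercept" else term.split(":")


def _reference_values(result: ModelResult, at: dict | None) -> dict[str, float]:
    """Value assigned to every model variable when not otherwise pinned:
    its sample mean in the model frame (centred covariates -> ~0)."""
    values = {}
    for term in result.terms["term"]:
        for comp in _term_components(term):
            if comp not in values:
                values[comp] = float(result.data[comp].mean())
    if at:
        for key, val in at.items():
            if key not in values:
                raise ModelSpecError(f"'at' variable {key!r} not in the model")
            values[key] = float(val)
    return values


def _is_binary(col: pd.Series) -> bool:
    return set(pd.unique(col.dropna())) <= {0, 1}


def simple_slopes(
    result: ModelResult,
    focal: str,
    moderator: str,
    levels: dict[str, float] | None = None,
    at: dict | None = None,
) -> pd.DataFrame:
    """Conditional slope of ``focal`` at chosen levels of ``moderator``.

    For a continuous moderator the default levels are mean - SD, mean, and
    mean + SD ("low" / "medium" / "high"); for a 0/1 factor both levels.
    Other variables appearing in interactions with the focal predictor are
    held at their sample means unless pinned via ``at``.
    """
    term_list = list(result.terms["term"])
    slope_terms = [t for t in term_list if focal in _term_components(t)]
    if not slope_terms:
        raise ModelSpecError(f"focal predictor {focal!r} not in the model")
    if not any(moderator in _term_components(t) for t in slope_terms):
        raise ModelSpecError(
            f"moderator {moderator!r} does not interact with {focal!r}"
        )
    if levels is None:
        col = result.data[moderator]
        if _is_binary(col):
            levels = {f"{moderator}=0": 0.0, f"{moderator}=1": 1.0}
        else:
            m, s = float(col.mean()), float(col.std())
            levels = {"low (M-SD)": m - s, "medium (M)": m, "high (M+SD)": m + s}

    base = _reference_values(result, at)
    beta = result.params.to_numpy()
    cov = result.cov.to_numpy()
    rows = []
    for label, value in levels.items():
        values = dict(base, **{moderator: float(value)})
        L = np.zeros(len(term_list))
        for i, term in enumerate(term_list):
            comps = _term_components(term)
            if focal not in comps:
                continue
            others = [c for c in comps if c != focal]
            L[i] = float(np.prod([values[c] for c in others])) if others else 1.0
        est = float(L @ beta)
        se = float(np.sqrt(L @ cov @ L))
        tval = est / se if se > 0 else np.nan
        pval = 2 * stats.t.sf(abs(tval), result.resid_df)
        rows.append({
            "focal": focal, "moderator": moderator, "level": label,
            "moderator_value": value, "estimate": est, "se": se,
            "df": result.resid_df, "t": tval, "p": pval,
        })
    return pd.DataFrame(rows)


def pairwise_contrasts(
    result: ModelResult,
    factors: list[str],
    adjust: str = "tukey",
) -> pd.DataFrame:
    """Tukey-adjusted pairwise comparisons of estimated marginal means.

    Cells are the crossing of the listed 0/1-coded factors; covariates not
    listed are held at their sample means. ``adjust`` is ``"tukey"``
    (studentised range), ``"bonferroni"``, or ``"none"``.
    """
    if adjust not in ("tukey", "bonferroni", "none"):
        raise ModelSpecError(f"unknown adjustment {adjust!r}")
    term_list = list(result.terms["term"])
    model_vars = {c for t in term_list for c in _term_components(t)}
    for f in factors:
        if f not in model_vars:
            raise ModelSpecError(f"factor {f!r} not in the model")
        if not _is_binary(result.data[f]):
            raise ModelSpecError(f"factor {f!r} is not 0/1 coded")

    base = _reference_values(result, None)
    beta = result.params.to_numpy()
    cov = result.cov.to_numpy()

    def design_row(cell: dict[str, float]) -> np.ndarray:
        values = dict(base, **cell)
        row = np.zeros(len(term_list))
        for i, term in enumerate(term_list):
            comps = _term_components(term)
            row[i] = float(np.prod([values[c] for c in comps])) if comps else 1.0
        return row

    cells = [dict(zip(factors, combo))
             for combo in itertools.product([0.0, 1.0], repeat=len(factors))]
    labels = [", ".join(f"{k}={int(v)}" for k, v in cell.items()) for cell in cells]
    k_cells = len(cells)
    rows = []
    for (i, ci), (j, cj) in itertools.combinations(enumerate(cells), 2):
        L = design_row(ci) - design_row(cj)
        est = float(L @ beta)
        se = float(np.sqrt(L @ cov @ L))
        tval = est / se if se > 0 else np.nan
        p_raw = 2 * stats.t.sf(abs(tval), result.resid_df)
        if adjust == "tukey":
            p_adj = float(stats.studentized_range.sf(
                abs(tval) * np.sqrt(2.0), k_cells, result.resid_df))
        elif adjust == "bonferroni":
            n_comp = k_cells * (k_cells - 1) // 2
            p_adj = min(1.0, p_raw * n_comp)
        else:
            p_adj = p_raw
        rows.append({
            "contrast": f"({labels[i]}) - ({labels[j]})",
            "estimate": est, "se": se, "df": result.resid_df, "t": tval,
            "p_unadjusted": p_raw, "p_adjusted": p_adj, "adjust": adjust,
        })
    return pd.DataFrame(rows)
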