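"""Group inference battery.

Covariate-adjusted OLS with interaction pruning, paired and Welch t-tests
with Cohen's d, a BIC-approximate Bayes factor for null evidence, and
Bonferroni adjustment for the two-test brain-behavior case.

Conventions
-----------
* Models are ordinary least squares with listwise deletion.  Interaction
  terms are fitted first; every interaction with p >= prune_alpha is
  dropped and the model refitted without them.
* With ``standardize`` on, continuous variables (outcome and regressors
  with more than two distinct values) are z-scored before fitting and
  interactions are products of the standardized columns; raw-scale
  coefficients are reported alongside (`beta_raw`, `se_raw`).  t, p and d
  for interaction terms are invariant to this choice; main-effect terms
  become simple effects at the sample mean, the usual centered-interaction
  reading.
* Cohen's d for a regression term is computed from its t statistic as
  d = 2t / sqrt(df_resid) (configurable to a partial-correlation variant).
* Welch t and its Cohen's d are signed group2 - group1 and accept either
  raw samples or printed summary statistics; d uses the pooled SD with
  (n-1) weights.
* BF01 ~ exp((BIC_alt - BIC_null) / 2) approximates a default-prior
  Bayesian regression; it preserves the direction and order of magnitude
  of null evidence, not any particular prior's exact value.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .containers import ModelResult
from .errors import AnalysisError, ConfigError, DataError

#: Fixed codes for binary factors so signs are stable across runs.
FACTOR_CODES: dict[str, dict[str, int]] = {
    "group": {"NT": 0, "ASD": 1},
    "sex": {"M": 0, "F": 1},
}

DEFAULT_COVARIATES = ("mean_fd", "age", "sex", "fsiq", "site")


@dataclass
class ModelSpec:
    outcome: str
    predictors: list[str] = field(default_factory=list)
    covariates: list[str] = field(default_factory=lambda: list(DEFAULT_COVARIATES))
    interactions: list[tuple[str, str]] = field(default_factory=list)
    prune_alpha: float = 0.05
    standardize: bool = True
    d_formula: str = "from_t"  # or "partial_r"

    def __post_init__(self) -> None:
        if not (0 < self.prune_alpha < 1):
            raise ConfigError("prune_alpha must lie in (0, 1)")


@dataclass
class TTestResult:
    t: float
    df: float
    p: float
    d: float
    mean_diff: float
    ci95: tuple[float, float] | None = None
    n1: int | None = None
    n2: int | None = None


def encode_factors(table: pd.DataFrame) -> pd.DataFrame:
    """Return a copy with string factor columns coded 0/1.

    'group' and 'sex' use the fixed codes above; any other object column
    with exactly two levels is coded by sorted order (first level = 0).
    """
    out = table.copy()
    for col in out.columns:
        if out[col].dtype == object or isinstance(out[col].dtype, pd.CategoricalDtype):
            levels = sorted(out[col].dropna().unique())
            codes = FACTOR_CODES.get(col)
            if codes is None:
                if len(levels) != 2:
                    raise DataError(
                        f"factor column {col!r} has {len(levels)} levels; "
                        "only binary factors are supported"
                    )
                codes = {levels[0]: 0, levels[1]: 1}
            out[col] = out[col].map(codes).astype(float)
    return out


def _is_binary(x: np.ndarray) -> bool:
    return np.unique(x[np.isfinite(x)]).size <= 2


def _build_design(
    data: pd.DataFrame, spec: ModelSpec, interactions: list[tuple[str, str]],
    standardize: bool,
) -> tuple[pd.Series, pd.DataFrame]:
    cols = {}
    y = data[spec.outcome].astype(float)
    if standardize and not _is_binary(y.to_numpy()):
        y = (y - y.mean()) / y.std(ddof=0)
    for name in list(spec.predictors) + list(spec.covariates):
        x = data[name].astype(float)
        if standardize and not _is_binary(x.to_numpy()):
            x = (x - x.mean()) / x.std(ddof=0)
        cols[name] = x
    for a, b in interactions:
        cols[f"{a}:{b}"] = cols[a] * cols[b]
    X = pd.DataFrame(cols, index=data.index)
    X.insert(0, "const", 1.0)
    return y, X


def _fit_ols(y: pd.Series, X: pd.DataFrame):
    if np.linalg.matrix_rank(X.to_numpy()) < X.shape[1]:
        raise AnalysisError("design matrix is rank deficient")
    return sm.OLS(y.to_numpy(), X).fit()


def _term_d(t: float, df_resid: float, partial: bool = False) -> float:
    if partial:
        r = t / np.sqrt(t**2 + df_resid)
        return float(2 * r / np.sqrt(1 - r**2))
    return float(2 * t / np.sqrt(df_resid))


def fit_pruned_linear_model(spec: ModelSpec, table: pd.DataFrame) -> ModelResult:
    """OLS with interaction pruning; see module docstring for conventions."""
    used = [spec.outcome] + list(spec.predictors) + list(spec.covariates)
    missing = [c for c in used if c not in table.columns]
    if missing:
        raise DataError(f"table lacks columns {missing}")
    data = encode_factors(table[used]).dropna()
    n = len(data)
    n_terms = 1 + len(spec.predictors) + len(spec.covariates) + len(spec.interactions)
    if n < n_terms + 2:
        raise AnalysisError(f"n = {n} too small for {n_terms} terms")

    interactions = list(spec.interactions)
    if interactions:
        y, X = _build_design(data, spec, interactions, spec.standardize)
        fit = _fit_ols(y, X)
        pvals = fit.pvalues
        kept = [
            (a, b) for a, b in interactions
            if pvals[f"{a}:{b}"] < spec.prune_alpha
        ]
        pruned = [f"{a}:{b}" for a, b in interactions if (a, b) not in kept]
    else:
        kept, pruned = [], []

    y, X = _build_design(data, spec, kept, spec.standardize)
    fit = _fit_ols(y, X)
    y_raw, X_raw = _build_design(data, spec, kept, standardize=False)
    fit_raw = _fit_ols(y_raw, X_raw)

    partial = spec.d_formula == "partial_r"
    terms = pd.DataFrame(
        {
            "beta": fit.params,
            "se": fit.bse,
            "t": fit.tvalues,
            "p": fit.pvalues,
            "d": [_term_d(t, fit.df_resid, partial) for t in fit.tvalues],
            "beta_raw": fit_raw.params,
            "se_raw": fit_raw.bse,
        }
    )
    return ModelResult(
        terms=terms,
        n=n,
        pruned=pruned,
        family="ols",
        bic=float(fit_raw.bic),
        r_squared=float(fit.rsquared),
    )


def paired_t(x, y) -> TTestResult:
    """Classical paired t-test on differences x - y (pairwise complete)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise DataError("paired samples must have equal length")
    keep = np.isfinite(x) & np.isfinite(y)
    d = x[keep] - y[keep]
    n = d.size
    if n < 3:
        raise AnalysisError("paired t-test needs at least 3 complete pairs")
    sd = d.std(ddof=1)
    if sd == 0:
        raise AnalysisError("zero-variance differences; paired t undefined")
    se = sd / np.sqrt(n)
    t = d.mean() / se
    df = n - 1
    p = 2 * stats.t.sf(abs(t), df)
    crit = stats.t.ppf(0.975, df)
    return TTestResult(
        t=float(t),
        df=float(df),
        p=float(p),
        d=float(d.mean() / sd),
        mean_diff=float(d.mean()),
        ci95=(float(d.mean() - crit * se), float(d.mean() + crit * se)),
        n1=n,
        n2=n,
    )


def welch_t_from_summary(
    m1: float, sd1: float, n1: int, m2: float, sd2: float, n2: int
) -> TTestResult:
    """Welch t with Satterthwaite df from printed summary statistics.

    Signed group2 - group1; Cohen's d uses the (n-1)-weighted pooled SD.
    """
    if n1 < 2 or n2 < 2:
        raise AnalysisError("each group needs n >= 2")
    if sd1 <= 0 or sd2 <= 0:
        raise AnalysisError("degenerate variance; Welch t undefined")
    v1, v2 = sd1**2 / n1, sd2**2 / n2
    se = np.sqrt(v1 + v2)
    t = (m2 - m1) / se
    df = (v1 + v2) ** 2 / (v1**2 / (n1 - 1) + v2**2 / (n2 - 1))
    p = 2 * stats.t.sf(abs(t), df)
    pooled = np.sqrt(((n1 - 1) * sd1**2 + (n2 - 1) * sd2**2) / (n1 + n2 - 2))
    return TTestResult(
        t=float(t),
        df=float(df),
        p=float(p),
        d=float((m2 - m1) / pooled),
        mean_diff=float(m2 - m1),
        n1=n1,
        n2=n2,
    )


def welch_t(x, y) -> TTestResult:
    """Welch t from raw samples (delegates to the summary form)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    x = x[np.isfinite(x)]
    y = y[np.isfinite(y)]
    return welch_t_from_summary(
        x.mean(), x.std(ddof=1), x.size, y.mean(), y.std(ddof=1), y.size
    )


def bf01_from_bic(bic_null: float, bic_alt: float) -> float:
    """BF01 ~ exp((BIC_alt - BIC_null) / 2): evidence for the null model."""
    return float(np.exp((bic_alt - bic_null) / 2.0))


def bf01_null_evidence(
    model_null: ModelResult, model_alt: ModelResult
) -> float:
    """Null-evidence Bayes factor for nested models fitted on the same rows."""
    if model_null.n != model_alt.n:
        raise AnalysisError("models must be fitted on identical rows")
    if model_null.n <= 1:
        raise AnalysisError("BIC undefined for n <= 1")
    if len(model_null.terms) >= len(model_alt.terms):
        raise AnalysisError("null model must be nested in the alternative")
    return bf01_from_bic(model_null.bic, model_alt.bic)


def bonferroni(p_values, k: int | None = None, alpha: float = 0.05):
    """Bonferroni correction: (adjusted alpha, adjusted p-values)."""
    p = np.asarray(list(p_values), dtype=float)
    if k is None:
        k = p.size
    if k < 1:
        raise ConfigError("k must be >= 1")
    return alpha / k, np.minimum(1.0, p * k)


# ---------------------------------------------------------------------------
# The preregistered hypothesis battery


@dataclass
class BatteryResult:
    models: dict[str, ModelResult]
    ttests: dict[str, TTestResult]
    bayes: dict[str, float]
    bonferroni_alpha: float
    bonferroni_adjusted: dict[str, float]

    def to_frame(self) -> pd.DataFrame:
        """Flat one-row-per-term table across all models and t-tests."""
        rows = []
        for name, res in self.models.items():
            for term, row in res.terms.iterrows():
                rows.append(
                    {
                        "analysis": name,
                        "term": term,
                        "beta": row["beta"],
                        "se": row["se"],
                        "t": row["t"],
                        "p": row["p"],
                        "d": row["d"],
                        "n": res.n,
                    }
                )
        for name, res in self.ttests.items():
            rows.append(
                {
                    "analysis": name,
                    "term": "difference",
                    "beta": res.mean_diff,
                    "se": np.nan,
                    "t": res.t,
                    "p": res.p,
                    "d": res.d,
                    "n": res.n1,
                }
            )
        return pd.DataFrame(rows)


def battery_model_specs(prune_alpha: float = 0.05, standardize: bool = True
                        ) -> dict[str, ModelSpec]:
    """The fixed model list: group models for IRC and reference similarity,
    specialization-similarity association models, and brain-behavior
    models (MASC, AQ, EQ, event magnitude) with group interactions."""
    def spec(outcome, predictors, interactions):
        return ModelSpec(
            outcome=outcome,
            predictors=predictors,
            interactions=interactions,
            prune_alpha=prune_alpha,
            standardize=standardize,
        )

    return {
        "irc_within_tom_group": spec("within_tom_z", ["group"], [("group", "site")]),
        "irc_within_pain_group": spec("within_pain_z", ["group"], [("group", "site")]),
        "irc_across_group": spec("across_z", ["group"], [("group", "site")]),
        "sim_nt_tom_group": spec("sim_nt_tom_z", ["group"], [("group", "site")]),
        "sim_nt_pain_group": spec("sim_nt_pain_z", ["group"], [("group", "site")]),
        "spec_sim_tom": spec(
            "sim_nt_tom_z",
            ["within_tom_z", "across_z", "group"],
            [("group", "within_tom_z"), ("group", "across_z")],
        ),
        "spec_sim_pain": spec(
            "sim_nt_pain_z",
            ["within_pain_z", "across_z", "group"],
            [("group", "within_pain_z"), ("group", "across_z")],
        ),
        "behavior_masc_irc": spec(
            "within_tom_z", ["masc", "group"], [("group", "masc")]
        ),
        "behavior_aq_irc": spec("within_tom_z", ["aq", "group"], [("group", "aq")]),
        "behavior_eq_pain": spec("within_pain_z", ["eq", "group"], [("group", "eq")]),
        "behavior_masc_t04": spec(
            "masc", ["t04_magnitude", "group"], [("group", "t04_magnitude")]
        ),
    }


#: analyses in the bundle: 11 models + 6 t-tests
BATTERY_SIZE = 17


def run_hypothesis_battery(
    data: pd.DataFrame,
    prune_alpha: float = 0.05,
    standardize: bool = True,
    null_evidence_models: tuple[str, ...] = (
        "irc_within_pain_group",
        "irc_across_group",
        "sim_nt_pain_group",
    ),
) -> BatteryResult:
    """Run the full preregistered analysis set on a joined metrics+cohort
    table (one row per subject).

    t-tests: per network, paired within- vs across-group similarity inside
    each group, and Welch within-group similarity NT vs ASD.  Bayes factors
    (BF01 for dropping the group term) are attached to the hypothesized-null
    models whenever their group term has p > 0.05.  The MASC/AQ pair of
    brain-behavior tests gets a Bonferroni-adjusted alpha of 0.025.
    """
    specs = battery_model_specs(prune_alpha, standardize)
    models = {name: fit_pruned_linear_model(s, data) for name, s in specs.items()}

    ttests: dict[str, TTestResult] = {}
    for net in ("tom", "pain"):
        for grp in ("NT", "ASD"):
            sel = data["group"] == grp
            ttests[f"hetero_paired_{grp.lower()}_{net}"] = paired_t(
                data.loc[sel, f"within_group_{net}_z"],
                data.loc[sel, f"across_group_{net}_z"],
            )
        ttests[f"hetero_welch_{net}"] = welch_t(
            data.loc[data["group"] == "NT", f"within_group_{net}_z"],
            data.loc[data["group"] == "ASD", f"within_group_{net}_z"],
        )

    bayes: dict[str, float] = {}
    for name in null_evidence_models:
        res = models[name]
        if "group" not in res.terms.index or res.term("group")["p"] <= 0.05:
            continue
        spec = specs[name]
        null_spec = ModelSpec(
            outcome=spec.outcome,
            predictors=[p for p in spec.predictors if p != "group"],
            covariates=spec.covariates,
            interactions=[],  # group interactions cannot survive without group
            prune_alpha=spec.prune_alpha,
            standardize=spec.standardize,
        )
        kept_inter = [
            i for i in spec.interactions
            if f"{i[0]}:{i[1]}" not in res.pruned and "group" not in i
        ]
        null_spec.interactions = kept_inter
        alt_spec = ModelSpec(
            outcome=spec.outcome,
            predictors=spec.predictors,
            covariates=spec.covariates,
            interactions=[
                i for i in spec.interactions if f"{i[0]}:{i[1]}" not in res.pruned
            ],
            prune_alpha=spec.prune_alpha,
            standardize=spec.standardize,
        )
        null_fit = fit_pruned_linear_model(null_spec, data)
        alt_fit = fit_pruned_linear_model(alt_spec, data)
        bayes[name] = bf01_null_evidence(null_fit, alt_fit)

    masc_p = models["behavior_masc_irc"].term("masc")["p"]
    aq_p = models["behavior_aq_irc"].term("aq")["p"]
    adj_alpha, adj_p = bonferroni([masc_p, aq_p], k=2)
    result = BatteryResult(
        models=models,
        ttests=ttests,
        bayes=bayes,
        bonferroni_alpha=adj_alpha,
        bonferroni_adjusted={
            "behavior_masc_irc": float(adj_p[0]),
            "behavior_aq_irc": float(adj_p[1]),
        },
    )
    assert len(result.models) + len(result.ttests) == BATTERY_SIZE
    return result
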