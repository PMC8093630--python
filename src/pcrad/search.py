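"""Exhaustive covariate-subset model search with dual cross-validated AUC.

Every non-empty subset of a variable group (a categorical covariate's dummy
columns enter and leave together) is fitted with one of three classifiers —
logistic regression (Logit), linear support-vector regression on the 0/1
outcome (SVR) or random forest (RF) — and scored by the average of two
cross-validated AUCs: leave-one-out and one seeded partition into folds of
size two ("30-fold" at n = 60).  Classifier hyperparameters (SVR cost, RF
tree count) are tuned once on the full-group LOOCV model and frozen.

Each model gets a DeLong confidence interval and a Mason-Graham p-value
against AUC = 0.5 from its pooled leave-one-out scores; p-values are
Benjamini-Hochberg adjusted across all models evaluated in one search run.
The report ranks models, keeps the best six, computes per-covariate inclusion
frequencies over the best six, and aggregates the full-data logistic
coefficients of covariate j over all fitted subsets as

    m_j = sum_i m_ij / sigma_ij^2  /  sum_i 1 / sigma_ij

(the published formula; the textbook inverse-variance weighting
sum_i m_ij/sigma_ij^2 / sum_i 1/sigma_ij^2 is available via
``aggregation="inverse_variance"``).  |m_j| > 1 is read as a relevant
positive/negative association with pCR.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from . import _fastfit, roc

__all__ = [
    "VariableGroup",
    "ModelSpec",
    "FitResult",
    "ModelPerformance",
    "SearchReport",
    "ExhaustiveSubsetSearch",
    "encode_dummies",
    "standard_groups",
    "tune_hyperparameters",
    "cv_scores",
    "evaluate_model",
    "run_group_search",
    "aggregate_coefficients",
    "SVR_COST_GRID",
    "RF_TREES_GRID",
]

SVR_COST_GRID: tuple[float, ...] = tuple(2.0**k for k in range(-5, 7, 2))  # 2^-5 .. 2^5
RF_TREES_GRID: tuple[int, ...] = (100, 250, 500, 1000)

# Reference-level dummy coding producing the published design-column names.
# References: Grade 2, HER2 Neg, Shape R, Margin S, IntEnh RE, Curve {I, II},
# Type U.
_DUMMY_CODING: dict[str, list[tuple[str, str]]] = {
    "Grade": [("Grade_3", "3")],
    "HER2": [("HER2", "Pos")],
    "Shape": [("Shape_I", "I"), ("Shape_O", "O")],
    "Margin": [("Margin_I", "I")],
    "IntEnh": [("IntEnh_E", "E"), ("IntEnh_O", "O")],
    "Curve": [("Curve_III", "III")],
    "Type": [("Type_MC", "MC"), ("Type_MF", "MF")],
}
_ALLOWED_LEVELS: dict[str, set[str]] = {
    "Grade": {"2", "3"},
    "HER2": {"Pos", "Neg"},
    "Shape": {"I", "O", "R"},
    "Margin": {"I", "S"},
    "IntEnh": {"E", "O", "RE"},
    "Curve": {"I", "II", "III"},
    "Type": {"MC", "MF", "U"},
}

_G1 = ("Age", "ADC", "PET_SUV", "Grade", "Shape", "Margin", "IntEnh", "Curve", "Type")
_RAD = ("F1", "F2", "F3", "F4", "F5")
_HIST = ("Ki67", "ER", "PgR", "HER2")


@dataclass(frozen=True)
class VariableGroup:
    """A named set of candidate covariates for the subset search."""

    name: str
    members: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError("variable group must not be empty")


def standard_groups() -> dict[str, VariableGroup]:
    """The five standard variable groups: G1, Rad, Hist, NoRad, All."""
    return {
        "G1": VariableGroup("G1", _G1),
        "Rad": VariableGroup("Rad", _RAD),
        "Hist": VariableGroup("Hist", _HIST),
        "NoRad": VariableGroup("NoRad", _G1 + _HIST),
        "All": VariableGroup("All", _G1 + _RAD + _HIST),
    }


def encode_dummies(table: pd.DataFrame) -> tuple[pd.DataFrame, dict[str, list[str]]]:
    """Reference-level dummy encoding of the categorical covariates.

    Returns the numeric design matrix (categorical columns replaced in place
    by their dummy columns) and a map from original covariate name to its
    design columns.  Unseen category levels raise an error.
    """
    design: dict[str, np.ndarray] = {}
    name_map: dict[str, list[str]] = {}
    for col in table.columns:
        if col in _DUMMY_CODING:
            values = table[col].astype(str).to_numpy()
            unseen = set(values) - _ALLOWED_LEVELS[col]
            if unseen:
                raise ValueError(f"unseen level(s) {sorted(unseen)} in covariate '{col}'")
            cols = []
            for dummy_name, level in _DUMMY_CODING[col]:
                design[dummy_name] = (values == level).astype(float)
                cols.append(dummy_name)
            name_map[col] = cols
        else:
            design[col] = pd.to_numeric(table[col]).to_numpy(dtype=float)
            name_map[col] = [col]
    return pd.DataFrame(design, index=table.index), name_map


@dataclass(frozen=True)
class ModelSpec:
    """One candidate model: classifier + covariate subset (+ hyperparameters)."""

    classifier: str  # logit | svr | rf
    subset: tuple[str, ...]
    hyperparameters: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.classifier not in ("logit", "svr", "rf"):
            raise ValueError(f"unknown classifier '{self.classifier}'")
        if not self.subset:
            raise ValueError("subset must be non-empty")


@dataclass(frozen=True)
class FitResult:
    """Full-data logistic fit of one subset: coefficients and standard errors
    per dummy-encoded design column (standardized scale, log-odds per sd)."""

    names: tuple[str, ...]
    coefficients: np.ndarray
    standard_errors: np.ndarray
    converged: bool
    intercept: float = 0.0


@dataclass(frozen=True)
class ModelPerformance:
    auc_loo: float
    auc_30fold: float
    ci: tuple[float, float]
    p_raw: float
    p_adj: float | None = None

    @property
    def auc_mean(self) -> float:
        return 0.5 * (self.auc_loo + self.auc_30fold)


@dataclass
class SearchReport:
    """Ranked outcome of one group search."""

    group: str
    classifier: str
    hyperparameters: dict
    models: list[tuple[ModelSpec, ModelPerformance]]  # ranked, best first
    best6: list[tuple[ModelSpec, ModelPerformance]]
    frequency: dict[str, float]  # best-6 inclusion frequency per covariate
    m_agg: dict[str, float]  # aggregated logistic coefficient per design column
    mean_p_adj_best6: float
    n_evaluated: int
    truncated: bool
    seed: int
    aggregation: str

    def to_dict(self) -> dict:
        def model_entry(spec, perf):
            return {
                "subset": list(spec.subset),
                "auc_loo": perf.auc_loo,
                "auc_30fold": perf.auc_30fold,
                "auc_mean": perf.auc_mean,
                "ci": list(perf.ci),
                "p_raw": perf.p_raw,
                "p_adj": perf.p_adj,
            }

        return {
            "group": self.group,
            "classifier": self.classifier,
            "hyperparameters": self.hyperparameters,
            "n_evaluated": self.n_evaluated,
            "truncated": self.truncated,
            "seed": self.seed,
            "aggregation": self.aggregation,
            "best6": [model_entry(s, p) for s, p in self.best6],
            "frequency": self.frequency,
            "m_agg": self.m_agg,
            "mean_p_adj_best6": self.mean_p_adj_best6,
            "models": [model_entry(s, p) for s, p in self.models],
        }


def _fold_ids(n: int, scheme: str, seed: int) -> tuple[np.ndarray, int]:
    if scheme == "loo":
        return np.arange(n, dtype=np.int64), n
    if scheme == "30fold":
        # one fixed seeded partition into folds of size 2 (leave-two-out)
        rng = np.random.default_rng(np.random.SeedSequence((seed, 2)))
        perm = rng.permutation(n)
        ids = np.empty(n, dtype=np.int64)
        ids[perm] = np.arange(n) // 2
        return ids, int(ids.max()) + 1
    raise ValueError(f"unknown scheme '{scheme}'")


def _design_for_subset(design: pd.DataFrame, name_map, subset) -> np.ndarray:
    cols = [c for cov in subset for c in name_map[cov]]
    return np.ascontiguousarray(design[cols].to_numpy(dtype=float))


def _sklearn_cv_scores(X, y, fold_ids, n_folds, classifier, hyper, seed):
    from sklearn.ensemble import RandomForestClassifier
    from sklearn.preprocessing import StandardScaler
    from sklearn.svm import SVR

    scores = np.empty(len(y), dtype=float)
    for f in range(n_folds):
        test = fold_ids == f
        train = ~test
        scaler = StandardScaler().fit(X[train])
        Xtr, Xte = scaler.transform(X[train]), scaler.transform(X[test])
        if classifier == "svr":
            model = SVR(kernel="linear", C=hyper.get("cost", 1.0))
            model.fit(Xtr, y[train].astype(float))
            scores[test] = model.predict(Xte)
        else:  # rf
            model = RandomForestClassifier(
                n_estimators=int(hyper.get("n_trees", 500)), random_state=seed
            )
            model.fit(Xtr, y[train].astype(int))
            proba = model.predict_proba(Xte)
            scores[test] = proba[:, 1] if model.classes_[-1] == 1 else 1.0 - proba[:, 0]
    return scores


def cv_scores(X: np.ndarray, y: np.ndarray, classifier: str, scheme: str,
              seed: int, hyperparameters: dict | None = None,
              warm_start: np.ndarray | None = None) -> np.ndarray:
    """Out-of-fold continuous scores for one design matrix.

    Logit returns out-of-fold predicted probabilities, SVR the raw regression
    output on the 0/1 outcome, RF the out-of-fold positive-class vote
    fraction.  Per-fold standardization is fitted on the training folds only.
    ``warm_start`` optionally seeds the per-fold Newton iterations with a
    full-data coefficient vector (intercept first, standardized scale).
    """
    X = np.ascontiguousarray(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float).ravel()
    hyper = hyperparameters or {}
    fold_ids, n_folds = _fold_ids(len(y), scheme, seed)
    if classifier == "logit":
        scores, ok = _fastfit.cv_logit_scores(X, y, fold_ids, n_folds, warm_start)
        if not ok:
            warnings.warn("one or more logistic CV fits were quasi-separated", stacklevel=2)
        return scores
    return _sklearn_cv_scores(X, y, fold_ids, n_folds, classifier, hyper, seed)


def full_logit_fit(X: np.ndarray, y: np.ndarray, names: tuple[str, ...]) -> FitResult:
    """Full-data logistic fit on standardized columns, with standard errors.

    Standard errors come from the inverse observed information at the MLE;
    quasi-separated or singular fits are flagged not converged.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    sd[sd == 0] = 1.0
    Xd = np.column_stack([np.ones(len(y)), (X - mu) / sd])
    beta, conv = _fastfit.newton_logit(np.ascontiguousarray(Xd), y)
    pr = 1.0 / (1.0 + np.exp(-np.clip(Xd @ beta, -500, 500)))
    w = pr * (1.0 - pr)
    info = (Xd * w[:, None]).T @ Xd
    try:
        cov = np.linalg.inv(info)
        with np.errstate(invalid="ignore"):
            se = np.sqrt(np.diag(cov)[1:])
        if not np.all(np.isfinite(se)) or np.any(se <= 0):
            conv = False
    except np.linalg.LinAlgError:
        se = np.full(X.shape[1], np.nan)
        conv = False
    return FitResult(tuple(names), beta[1:], se, bool(conv), float(beta[0]))


def tune_hyperparameters(table: pd.DataFrame, group: VariableGroup, classifier: str,
                         seed: int = 0, grid=None) -> dict:
    """Grid-search one hyperparameter on the full-group LOOCV model.

    SVR tunes the cost over 2^-5..2^5 (odd powers), RF the tree count over
    {100, 250, 500, 1000}; the chosen value is frozen for the whole search.
    Ties go to the smallest value.  Logit has no hyperparameter.
    """
    if classifier == "logit":
        return {}
    design, name_map = encode_dummies(table.drop(columns=["pCR"]))
    y = table["pCR"].to_numpy(dtype=float)
    X = _design_for_subset(design, name_map, group.members)
    key = "cost" if classifier == "svr" else "n_trees"
    values = sorted(set(grid if grid is not None else
                        (SVR_COST_GRID if classifier == "svr" else RF_TREES_GRID)))
    best_val, best_auc = None, -np.inf
    for v in values:
        scores = cv_scores(X, y, classifier, "loo", seed, {key: v})
        a = roc.auc(scores, y)
        if a > best_auc:
            best_val, best_auc = v, a
    return {key: best_val}


def evaluate_model(spec: ModelSpec, table: pd.DataFrame, seed: int = 0,
                   ci_level: float = 0.95) -> ModelPerformance:
    """Dual-CV AUC plus DeLong CI and Mason-Graham p on the pooled LOO scores."""
    design, name_map = encode_dummies(table.drop(columns=["pCR"]))
    y = table["pCR"].to_numpy(dtype=float)
    X = _design_for_subset(design, name_map, spec.subset)
    return _evaluate(X, y, spec, seed, ci_level)


def _evaluate(X, y, spec, seed, ci_level, warm_start=None) -> ModelPerformance:
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        loo = cv_scores(X, y, spec.classifier, "loo", seed, spec.hyperparameters, warm_start)
        k30 = cv_scores(X, y, spec.classifier, "30fold", seed, spec.hyperparameters, warm_start)
        return ModelPerformance(
            auc_loo=roc.auc(loo, y),
            auc_30fold=roc.auc(k30, y),
            ci=roc.auc_ci(loo, y, ci_level),
            p_raw=roc.mason_graham_p(loo, y),
        )


def aggregate_coefficients(fits: list[FitResult], aggregation: str = "printed") -> dict[str, float]:
    """Aggregate per-column logistic coefficients over many subset fits.

    ``printed`` uses m_j = sum m_ij/sigma_ij^2 / sum 1/sigma_ij (the published
    weighting); ``inverse_variance`` the textbook
    sum m_ij/sigma_ij^2 / sum 1/sigma_ij^2.  Columns absent from every
    converged fit get NaN.
    """
    if aggregation not in ("printed", "inverse_variance"):
        raise ValueError(f"unknown aggregation '{aggregation}'")
    num: dict[str, float] = {}
    den: dict[str, float] = {}
    for fit in fits:
        if not fit.converged:
            continue
        for name, m, s in zip(fit.names, fit.coefficients, fit.standard_errors):
            num[name] = num.get(name, 0.0) + m / s**2
            den[name] = den.get(name, 0.0) + (1.0 / s if aggregation == "printed" else 1.0 / s**2)
    out = {}
    for name in num:
        out[name] = num[name] / den[name] if den.get(name, 0.0) > 0 else float("nan")
    return out


def _enumerate_subsets(members: tuple[str, ...], cap: int, seed: int):
    """All non-empty subsets, or a seeded uniform sample of ``cap`` of them."""
    total = 2 ** len(members) - 1
    if total <= cap:
        masks = range(1, total + 1)
        truncated = False
    else:
        rng = np.random.default_rng(np.random.SeedSequence((seed, 3)))
        masks = rng.choice(total, size=cap, replace=False) + 1
        truncated = True
    subsets = [
        tuple(m for i, m in enumerate(members) if mask >> i & 1) for mask in masks
    ]
    return subsets, truncated


class ExhaustiveSubsetSearch(BaseEstimator):
    """Exhaustive (or capped random) covariate-subset search for one group.

    Parameters
    ----------
    group : name of a standard group (G1/Rad/Hist/NoRad/All) or "custom".
    members : explicit covariate tuple (required when group="custom").
    classifier : "logit", "svr" or "rf".
    subset_cap : maximum number of subsets evaluated; beyond it a seeded
        uniform sample of subsets is drawn and the report flags truncation.
    seed : drives the 30-fold partition, subset sampling and RF randomness.
    aggregation : coefficient aggregation variant ("printed" default).

    Fitted attributes
    -----------------
    report_ : :class:`SearchReport`; also ``ranking_``, ``best6_``,
    ``frequencies_``, ``m_agg_``, ``hyperparameters_``.
    """

    def __init__(self, group: str = "All", members: tuple[str, ...] | None = None,
                 classifier: str = "logit", subset_cap: int = 2**14, seed: int = 0,
                 ci_level: float = 0.95, aggregation: str = "printed",
                 hyperparameters: dict | None = None):
        self.group = group
        self.members = members
        self.classifier = classifier
        self.subset_cap = subset_cap
        self.seed = seed
        self.ci_level = ci_level
        self.aggregation = aggregation
        self.hyperparameters = hyperparameters

    def _resolve_members(self, columns) -> tuple[str, ...]:
        if self.members is not None:
            members = tuple(self.members)
        else:
            groups = standard_groups()
            if self.group not in groups:
                raise ValueError(f"unknown group '{self.group}' and no explicit members")
            members = groups[self.group].members
        missing = [m for m in members if m not in columns]
        if missing:
            raise ValueError(f"group members missing from table: {missing}")
        return members

    def fit(self, X: pd.DataFrame, y=None):
        table = pd.DataFrame(X).copy()
        if y is not None:
            table["pCR"] = np.asarray(y).astype(int)
        if "pCR" not in table.columns:
            raise ValueError("outcome column 'pCR' is required")
        if table.isna().any().any():
            raise ValueError("missing values are not allowed in the search")
        members = self._resolve_members(table.columns)

        design, name_map = encode_dummies(table.drop(columns=["pCR"]))
        yv = table["pCR"].to_numpy(dtype=float)
        if self.hyperparameters is not None:
            hyper = dict(self.hyperparameters)
        else:
            hyper = tune_hyperparameters(table, VariableGroup(self.group, members),
                                         self.classifier, self.seed)

        subsets, truncated = _enumerate_subsets(members, self.subset_cap, self.seed)
        design_np = np.ascontiguousarray(design.to_numpy(dtype=float))
        col_index = {c: i for i, c in enumerate(design.columns)}
        evaluated: list[tuple[ModelSpec, ModelPerformance]] = []
        fits: list[FitResult] = []
        for subset in subsets:
            spec = ModelSpec(self.classifier, subset, hyper)
            cols = tuple(c for cov in subset for c in name_map[cov])
            Xs = np.ascontiguousarray(design_np[:, [col_index[c] for c in cols]])
            fit = full_logit_fit(Xs, yv, cols)
            fits.append(fit)
            warm = None
            if self.classifier == "logit":
                if fit.converged:
                    warm = np.concatenate([[fit.intercept], fit.coefficients])
                else:
                    # quasi-separated subset: warm-start CV folds from a
                    # ridge-stabilized full-data fit instead
                    mu = Xs.mean(axis=0)
                    sd = Xs.std(axis=0)
                    sd[sd == 0] = 1.0
                    Xd = np.ascontiguousarray(
                        np.column_stack([np.ones(len(yv)), (Xs - mu) / sd])
                    )
                    warm, _ = _fastfit.newton_logit(Xd, yv, 30, 1e-8, None, 1e-3)
            perf = _evaluate(Xs, yv, spec, self.seed, self.ci_level, warm)
            evaluated.append((spec, perf))

        adj = roc.benjamini_hochberg([p.p_raw for _, p in evaluated])
        evaluated = [
            (s, ModelPerformance(p.auc_loo, p.auc_30fold, p.ci, p.p_raw, float(a)))
            for (s, p), a in zip(evaluated, adj)
        ]
        evaluated.sort(key=lambda sp: (-sp[1].auc_mean, len(sp[0].subset), sp[0].subset))
        best6 = evaluated[: min(6, len(evaluated))]
        freq = {
            m: float(np.mean([m in s.subset for s, _ in best6])) for m in members
        }
        m_agg = aggregate_coefficients(fits, self.aggregation)

        self.hyperparameters_ = hyper
        self.ranking_ = evaluated
        self.best6_ = best6
        self.frequencies_ = freq
        self.m_agg_ = m_agg
        self.report_ = SearchReport(
            group=self.group,
            classifier=self.classifier,
            hyperparameters=hyper,
            models=evaluated,
            best6=best6,
            frequency=freq,
            m_agg=m_agg,
            mean_p_adj_best6=float(np.mean([p.p_adj for _, p in best6])),
            n_evaluated=len(evaluated),
            truncated=truncated,
            seed=self.seed,
            aggregation=self.aggregation,
        )
        return self


def run_group_search(table: pd.DataFrame, group: VariableGroup | str,
                     classifier: str = "logit", subset_cap: int = 2**14,
                     seed: int = 0, **kwargs) -> SearchReport:
    """Run one group search and return its :class:`SearchReport`."""
    if isinstance(group, VariableGroup):
        est = ExhaustiveSubsetSearch(group=group.name, members=group.members,
                                     classifier=classifier, subset_cap=subset_cap,
                                     seed=seed, **kwargs)
    else:
        est = ExhaustiveSubsetSearch(group=group, classifier=classifier,
                                     subset_cap=subset_cap, seed=seed, **kwargs)
    return est.fit(table).report_
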