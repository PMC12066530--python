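"""Severity classification: screening, CV tuning, learners, stacking, FIRM.

The training protocol mirrors the evaluation design of the assessment
pipeline: a recording-level stratified 75/25 split, removal of highly
inter-correlated predictors (|Spearman rho| > 0.9, keeping in each
correlated group the predictor most correlated with the outcome), 10-fold
cross-validated hyperparameter search over space-filling (maximin Latin
hypercube) candidate sets within fixed ranges, mean logarithmic loss as the
tuning criterion, probability-averaging of the ten fold models of each
kind, a non-negatively weighted stack of the averaged models, and FIRM
(feature importance ranking measure) importances for the winning model.

Model kinds: polynomial-kernel SVM, elastic-net penalized proportional-odds
ordinal regression, random forest, kernel-weighted k nearest neighbors, and
the stacked ensemble.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize, sparse
from scipy.sparse.csgraph import connected_components
from scipy.special import expit
from sklearn.calibration import CalibratedClassifierCV
from sklearn.ensemble import RandomForestClassifier
from sklearn.impute import SimpleImputer
from sklearn.model_selection import StratifiedGroupKFold, StratifiedKFold
from sklearn.neighbors import KNeighborsClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

log = logging.getLogger(__name__)

MODEL_KINDS = ("svm_poly", "ordinal_elasticnet", "random_forest", "knn")

KNN_KERNELS = ("rectangular", "triangular", "epanechnikov", "biweight",
               "triweight", "cosine", "inverse", "gaussian", "rank")


# ---------------------------------------------------------------------------
# splitting and screening

def stratified_split(table: pd.DataFrame, test_fraction: float = 0.25,
                     seed: int = 0) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Recording-level stratified train/test split.

    All utterances of one recording land on the same side; within each
    severity class the share of recordings assigned to the test side is
    ``test_fraction`` up to rounding.
    """
    rng = np.random.default_rng(seed)
    rec_label = table.groupby("recording_id")["label"].first()
    test_recs: list[str] = []
    for cls, recs in rec_label.groupby(rec_label):
        ids = np.array(sorted(recs.index))
        if ids.size < 4:
            raise ValueError(f"class {cls} has fewer than 4 recordings")
        rng.shuffle(ids)
        n_test = int(round(test_fraction * ids.size))
        test_recs.extend(ids[:n_test])
    mask = table["recording_id"].isin(test_recs)
    return table[~mask].reset_index(drop=True), table[mask].reset_index(drop=True)


def filter_correlated(X: pd.DataFrame, y: Sequence[int],
                      rho_threshold: float = 0.9
                      ) -> tuple[pd.DataFrame, dict[str, str]]:
    """Drop predictors that are highly inter-correlated.

    Connected components of the graph with edges |Spearman rho| >
    ``rho_threshold`` are each represented by the member with the highest
    |Spearman rho| against the outcome; the mapping dropped -> kept is
    returned.  Constant predictors correlate as 0 (logged).
    """
    cols = list(X.columns)
    vals = X.to_numpy(dtype=float)
    y = np.asarray(y, dtype=float)
    # rank-transform once, then Pearson on ranks == Spearman
    ranks = np.empty_like(vals)
    for j in range(vals.shape[1]):
        col = vals[:, j]
        finite = np.isfinite(col)
        r = np.full(col.shape, np.nan)
        r[finite] = pd.Series(col[finite]).rank().to_numpy()
        ranks[:, j] = r
    with np.errstate(invalid="ignore"):
        ranks_f = np.where(np.isfinite(ranks), ranks,
                           np.nanmean(ranks, axis=0))
        sd = ranks_f.std(axis=0)
        constant = sd < 1e-12
        if constant.any():
            log.info("constant predictors treated as rho=0: %s",
                     [cols[j] for j in np.flatnonzero(constant)])
        z = (ranks_f - ranks_f.mean(axis=0)) / np.where(constant, 1.0, sd)
        z[:, constant] = 0.0
        corr = z.T @ z / z.shape[0]
    adj = sparse.csr_matrix(np.abs(corr) > rho_threshold)
    n_comp, comp = connected_components(adj, directed=False)
    y_rank = pd.Series(y).rank().to_numpy()
    zy = (y_rank - y_rank.mean())
    zy_sd = zy.std()
    rho_y = np.abs(z.T @ (zy / (zy_sd if zy_sd > 0 else 1.0))) / z.shape[0]
    keep: list[int] = []
    mapping: dict[str, str] = {}
    for cidx in range(n_comp):
        members = np.flatnonzero(comp == cidx)
        best = members[np.argmax(rho_y[members])]
        keep.append(best)
        for m in members:
            if m != best:
                mapping[cols[m]] = cols[best]
    keep.sort()
    return X.iloc[:, keep], mapping


def mean_log_loss(proba: np.ndarray, truth: Sequence[int]) -> float:
    """Mean negative log probability of the true class (clipped at 1e-15)."""
    proba = np.asarray(proba, dtype=float)
    truth = np.asarray(truth)
    if np.any(np.abs(proba.sum(axis=1) - 1.0) > 1e-6):
        raise ValueError("probability rows must sum to 1")
    p = np.clip(proba[np.arange(truth.size), truth], 1e-15, 1.0)
    return float(-np.mean(np.log(p)))


# ---------------------------------------------------------------------------
# hyperparameter candidate design

@dataclass
class ParamRange:
    lo: float
    hi: float
    scale: str = "linear"   # linear | log | int
    choices: tuple | None = None


def default_grid(kind: str) -> dict[str, ParamRange]:
    """Tuning ranges for each model kind (fixed search-space bounds)."""
    if kind == "svm_poly":
        return {"cost": ParamRange(9.96e-4, 31.6, "log")}
    if kind == "ordinal_elasticnet":
        return {"reg_total": ParamRange(0.0, 0.998, "linear"),
                "l1_ratio": ParamRange(6.7e-4, 0.999, "log")}
    if kind == "random_forest":
        return {"n_trees": ParamRange(1, 2000, "int"),
                "mtry": ParamRange(1, 74, "int"),
                "min_node": ParamRange(2, 40, "int")}
    if kind == "knn":
        return {"n_neighbors": ParamRange(1, 15, "int"),
                "kernel": ParamRange(0, 0, choices=KNN_KERNELS),
                "minkowski_p": ParamRange(1.0, 2.0, "linear")}
    raise ValueError(f"unknown model kind {kind!r}")


@dataclass
class TuningGrid:
    kind: str
    ranges: dict[str, ParamRange]
    n_candidates: int = 1000
    seed: int = 0


def _lhs_unit(n: int, d: int, rng: np.random.Generator) -> np.ndarray:
    u = np.empty((n, d))
    for j in range(d):
        u[:, j] = (rng.permutation(n) + rng.uniform(size=n)) / n
    return u


def space_filling_candidates(grid: TuningGrid,
                             n_designs: int = 10) -> list[dict]:
    """Space-filling candidate set: maximin Latin hypercube over the ranges.

    ``n_designs`` LHS draws are generated and the one maximizing the
    minimum pairwise distance (in the unit cube) is kept.  Log-scaled
    dimensions are sampled uniformly in log space; integer dimensions are
    rounded; categorical dimensions cycle through their options.
    """
    rng = np.random.default_rng(grid.seed)
    cont = [(name, pr) for name, pr in grid.ranges.items() if pr.choices is None]
    n, d = grid.n_candidates, max(1, len(cont))
    best_u, best_score = None, -np.inf
    for _ in range(n_designs):
        u = _lhs_unit(n, d, rng)
        if n > 1:
            dists = np.linalg.norm(u[:, None, :] - u[None, :, :], axis=-1)
            np.fill_diagonal(dists, np.inf)
            score = dists.min()
        else:
            score = 0.0
        if score > best_score:
            best_u, best_score = u, score
    out = []
    for i in range(n):
        cand: dict = {}
        for j, (name, pr) in enumerate(cont):
            x = best_u[i, j]
            if pr.scale == "log":
                v = float(np.exp(np.log(pr.lo) + x * (np.log(pr.hi) - np.log(pr.lo))))
            else:
                v = float(pr.lo + x * (pr.hi - pr.lo))
            if pr.scale == "int":
                v = int(np.clip(round(v), pr.lo, pr.hi))
            cand[name] = v
        out.append(cand)
    for name, pr in grid.ranges.items():
        if pr.choices is not None:
            idx = rng.permutation(n) % len(pr.choices)
            for i in range(n):
                out[i][name] = pr.choices[idx[i]]
    return out


# ---------------------------------------------------------------------------
# learners

class _KnnKernelWeights:
    """kknn-style kernel weighting of neighbor distances (picklable)."""

    def __init__(self, kernel: str):
        if kernel not in KNN_KERNELS:
            raise ValueError(f"unknown kNN kernel {kernel!r}")
        self.kernel = kernel

    def __call__(self, dist: np.ndarray) -> np.ndarray:
        kernel = self.kernel
        d = np.asarray(dist, dtype=float)
        scale = d.max(axis=1, keepdims=True)
        scale[scale == 0] = 1.0
        x = np.clip(d / (scale * (1 + 1e-9)), 0.0, 1.0)
        if kernel == "rectangular":
            w = np.ones_like(x)
        elif kernel == "triangular":
            w = 1 - x
        elif kernel == "epanechnikov":
            w = 1 - x ** 2
        elif kernel == "biweight":
            w = (1 - x ** 2) ** 2
        elif kernel == "triweight":
            w = (1 - x ** 2) ** 3
        elif kernel == "cosine":
            w = np.cos(np.pi * x / 2)
        elif kernel == "inverse":
            w = 1.0 / np.maximum(x, 1e-6)
        elif kernel == "gaussian":
            w = np.exp(-0.5 * (3 * x) ** 2)
        elif kernel == "rank":
            w = np.argsort(np.argsort(d, axis=1), axis=1).astype(float)
            w = w.shape[1] - w
        w = np.maximum(w, 1e-9)
        return w


class OrdinalElasticNet:
    """Proportional-odds ordinal regression with an elastic-net penalty.

    P(y <= j | x) = sigmoid(theta_j - w.x); the negative log likelihood is
    minimized with penalty reg_total * (l1_ratio * |w|_1 + (1 - l1_ratio)/2
    * |w|_2^2) (L1 smoothed for the quasi-Newton solver).  Inputs are
    standardized internally.
    """

    def __init__(self, reg_total: float = 0.0, l1_ratio: float = 0.5,
                 n_classes: int = 3):
        self.reg_total = reg_total
        self.l1_ratio = l1_ratio
        self.n_classes = n_classes
        self.classes_ = np.arange(n_classes)

    def _nll(self, params, X, y):
        p = X.shape[1]
        w = params[:p]
        # strictly increasing thresholds via cumulative softplus spacing
        raw = params[p:]
        theta = np.cumsum(np.concatenate([[raw[0]], np.log1p(np.exp(raw[1:]))]))
        eta = X @ w
        cum = expit(theta[None, :] - eta[:, None])          # (n, K-1)
        cum = np.hstack([np.zeros((X.shape[0], 1)), cum,
                         np.ones((X.shape[0], 1))])
        probs = np.clip(np.diff(cum, axis=1), 1e-12, 1.0)
        nll = -np.mean(np.log(probs[np.arange(y.size), y]))
        lam, alpha = self.reg_total, self.l1_ratio
        pen = lam * (alpha * np.sum(np.sqrt(w ** 2 + 1e-8))
                     + 0.5 * (1 - alpha) * np.sum(w ** 2))
        return nll + pen

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        self._mu = X.mean(axis=0)
        self._sd = X.std(axis=0)
        self._sd[self._sd == 0] = 1.0
        Z = (X - self._mu) / self._sd
        p = Z.shape[1]
        x0 = np.zeros(p + self.n_classes - 1)
        x0[p] = -1.0
        x0[p + 1:] = np.log(np.e - 1)  # softplus(.) = 1 spacing
        res = optimize.minimize(self._nll, x0, args=(Z, y), method="L-BFGS-B",
                                options={"maxiter": 500})
        self._params = res.x
        return self

    def predict_proba(self, X):
        X = np.asarray(X, dtype=float)
        Z = (X - self._mu) / self._sd
        p = Z.shape[1]
        w = self._params[:p]
        raw = self._params[p:]
        theta = np.cumsum(np.concatenate([[raw[0]], np.log1p(np.exp(raw[1:]))]))
        cum = expit(theta[None, :] - (Z @ w)[:, None])
        cum = np.hstack([np.zeros((Z.shape[0], 1)), cum,
                         np.ones((Z.shape[0], 1))])
        probs = np.maximum(np.diff(cum, axis=1), 1e-12)
        return probs / probs.sum(axis=1, keepdims=True)

    def predict(self, X):
        return np.argmax(self.predict_proba(X), axis=1)


class _SkWrapper:
    """Imputation (+ optional scaling) around an sklearn classifier, with a
    fixed 3-class probability layout."""

    def __init__(self, est, scale: bool, n_classes: int = 3):
        steps = [("imp", SimpleImputer(strategy="median"))]
        if scale:
            steps.append(("sc", StandardScaler()))
        steps.append(("est", est))
        self.pipe = Pipeline(steps)
        self.n_classes = n_classes

    def fit(self, X, y):
        self.pipe.fit(np.asarray(X, dtype=float), np.asarray(y))
        return self

    def predict_proba(self, X):
        p = self.pipe.predict_proba(np.asarray(X, dtype=float))
        seen = self.pipe.named_steps["est"].classes_
        out = np.zeros((p.shape[0], self.n_classes))
        out[:, np.asarray(seen, dtype=int)] = p
        return out

    def predict(self, X):
        return np.argmax(self.predict_proba(X), axis=1)


def make_model(kind: str, params: dict, n_features: int, n_train: int,
               seed: int = 0):
    """Instantiate an untrained model of the given kind."""
    if kind == "svm_poly":
        svc = SVC(kernel="poly", degree=3, C=params["cost"], gamma="scale",
                  random_state=seed)
        est = CalibratedClassifierCV(svc, method="sigmoid", cv=3,
                                     ensemble=False)
        return _SkWrapper(est, scale=True)
    if kind == "ordinal_elasticnet":
        om = OrdinalElasticNet(params["reg_total"], params["l1_ratio"])
        return _ImputedOrdinal(om)
    if kind == "random_forest":
        mtry = int(min(params["mtry"], n_features))
        est = RandomForestClassifier(
            n_estimators=int(params["n_trees"]), max_features=mtry,
            min_samples_split=int(params["min_node"]),
            random_state=seed, n_jobs=1)
        return _SkWrapper(est, scale=False)
    if kind == "knn":
        k = int(min(params["n_neighbors"], max(1, n_train - 1)))
        est = KNeighborsClassifier(
            n_neighbors=k, p=params.get("minkowski_p", 2.0),
            weights=_KnnKernelWeights(params.get("kernel", "rectangular")))
        return _SkWrapper(est, scale=True)
    raise ValueError(f"unknown model kind {kind!r}")


class _ImputedOrdinal:
    def __init__(self, inner: OrdinalElasticNet):
        self.inner = inner
        self.imp = SimpleImputer(strategy="median")

    def fit(self, X, y):
        self.inner.fit(self.imp.fit_transform(np.asarray(X, dtype=float)), y)
        return self

    def predict_proba(self, X):
        return self.inner.predict_proba(
            self.imp.transform(np.asarray(X, dtype=float)))

    def predict(self, X):
        return np.argmax(self.predict_proba(X), axis=1)


# ---------------------------------------------------------------------------
# tuning, averaging, stacking

@dataclass
class TunedModel:
    kind: str
    params: dict
    fold_models: list
    fold_losses: list[float]
    cv_loss: float
    oof_proba: np.ndarray   # out-of-fold probabilities on the training rows


def tune_cv(kind: str, X, y, grid: TuningGrid | None = None,
            k: int = 10, seed: int = 0,
            n_candidates: int | None = None, groups=None) -> TunedModel:
    """CV hyperparameter search on mean log loss.

    Folds are stratified by label; when ``groups`` (recording ids) are
    given, all utterances of a recording stay in one fold so that
    hyperparameter selection cannot exploit speaker identity — labels are
    assigned per recording, so leaking a speaker across the fold boundary
    would reward memorization rather than generalization.  Every candidate
    is fitted on each train-fold and scored on its holdout; the candidate
    with the lowest mean holdout log loss wins and its per-fold fits are
    returned.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    n_classes = 3
    if X.shape[0] < k * n_classes:
        raise ValueError("too few training rows for the fold count")
    if grid is None:
        grid = TuningGrid(kind, default_grid(kind),
                          n_candidates=n_candidates or 1000, seed=seed)
    elif n_candidates is not None:
        grid.n_candidates = n_candidates
    candidates = space_filling_candidates(grid)

    def make_folds(rs):
        if groups is not None:
            skf = StratifiedGroupKFold(n_splits=k, shuffle=True,
                                       random_state=rs)
            return list(skf.split(X, y, groups))
        skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=rs)
        return list(skf.split(X, y))

    folds = make_folds(seed)
    for tr, ho in folds:
        if len(np.unique(y[tr])) < n_classes:
            folds = make_folds(seed + 1)
            for tr2, _ in folds:
                if len(np.unique(y[tr2])) < n_classes:
                    raise ValueError("degenerate fold: missing class")
            break
    best = None
    for cand in candidates:
        fits, losses = [], []
        oof = np.zeros((y.size, n_classes))
        for tr, ho in folds:
            m = make_model(kind, cand, X.shape[1], tr.size, seed)
            m.fit(X[tr], y[tr])
            p = m.predict_proba(X[ho])
            losses.append(mean_log_loss(p, y[ho]))
            oof[ho] = p
            fits.append(m)
        cv = float(np.mean(losses))
        if best is None or cv < best.cv_loss:
            best = TunedModel(kind, cand, fits, losses, cv, oof)
    return best


class AveragedModel:
    """Arithmetic mean of the fold models' class probabilities."""

    def __init__(self, kind: str, fold_models: list):
        if len(fold_models) < 2:
            raise ValueError("need at least 2 fold models to average")
        self.kind = kind
        self.fold_models = fold_models

    def predict_proba(self, X):
        return np.mean([m.predict_proba(X) for m in self.fold_models], axis=0)

    def predict(self, X):
        return np.argmax(self.predict_proba(X), axis=1)


def average_fold_models(tuned: TunedModel) -> AveragedModel:
    return AveragedModel(tuned.kind, tuned.fold_models)


class StackedEnsemble:
    """Convex (non-negative, sum-1) weighting of base-model probabilities."""

    def __init__(self, base_models: dict[str, AveragedModel],
                 weights: np.ndarray):
        self.kind = "ensemble"
        self.base_models = base_models
        self.weights = weights

    def predict_proba(self, X):
        probs = [m.predict_proba(X) for m in self.base_models.values()]
        return np.tensordot(self.weights, np.array(probs), axes=1)

    def predict(self, X):
        return np.argmax(self.predict_proba(X), axis=1)


def stack_ensemble(tuned: dict[str, TunedModel], y_train,
                   seed: int = 0) -> StackedEnsemble:
    """Stack the averaged base models by their out-of-fold strengths.

    Weights minimize the log loss of the convex combination of the models'
    out-of-fold probabilities on the training rows; a failed optimization
    falls back to uniform weights (logged).
    """
    if len(tuned) < 2:
        raise ValueError("need at least 2 base models to stack")
    kinds = list(tuned)
    y = np.asarray(y_train)
    P = np.array([tuned[k].oof_proba for k in kinds])   # (m, n, 3)

    def loss(w):
        w = np.maximum(w, 0)
        s = w.sum()
        if s <= 0:
            return np.log(3.0)
        mix = np.tensordot(w / s, P, axes=1)
        return mean_log_loss(mix / mix.sum(axis=1, keepdims=True), y)

    m = len(kinds)
    res = optimize.minimize(loss, np.full(m, 1.0 / m), method="SLSQP",
                            bounds=[(0, 1)] * m,
                            constraints=[{"type": "eq",
                                          "fun": lambda w: w.sum() - 1}])
    if res.success and np.isfinite(res.fun):
        w = np.maximum(res.x, 0)
        w /= w.sum()
    else:
        log.warning("stacking optimization failed; uniform weights used")
        w = np.full(m, 1.0 / m)
    averaged = {k: average_fold_models(tuned[k]) for k in kinds}
    return StackedEnsemble(averaged, w)


# ---------------------------------------------------------------------------
# FIRM importance

def firm_importance(model, X, n_bins: int = 10,
                    feature_names: Sequence[str] | None = None
                    ) -> dict[str, float]:
    """Feature importance ranking measure via quantile-bin clamping.

    For predictor j the conditional expected model output q_j(b) is
    estimated by clamping column j to the median of quantile bin b for all
    reference rows and averaging the predicted class probabilities; the
    importance is the standard deviation of q_j across bins (the root of
    the mean squared change of the model output), averaged over classes.
    Constant predictors get importance 0.
    """
    X = np.asarray(X, dtype=float)
    if X.shape[0] < 50:
        raise ValueError("need >= 50 reference rows for FIRM")
    names = (list(feature_names) if feature_names is not None
             else [f"x{j}" for j in range(X.shape[1])])
    out: dict[str, float] = {}
    for j, name in enumerate(names):
        col = X[:, j]
        finite = col[np.isfinite(col)]
        if finite.size == 0 or np.all(finite == finite[0]):
            out[name] = 0.0
            continue
        edges = np.quantile(finite, np.linspace(0, 1, n_bins + 1))
        qs = []
        for b in range(n_bins):
            sel = finite[(finite >= edges[b]) & (finite <= edges[b + 1])]
            if sel.size == 0:
                continue
            Xc = X.copy()
            Xc[:, j] = np.median(sel)
            qs.append(model.predict_proba(Xc).mean(axis=0))
        if len(qs) < 2:
            out[name] = 0.0
            continue
        qs = np.array(qs)                      # (bins, classes)
        out[name] = float(np.mean(np.std(qs, axis=0)))
    return out


# ---------------------------------------------------------------------------
# single-predictor baseline

def baseline_f0sd_model(X_f0sd, y) -> _ImputedOrdinal:
    """Ordinal-regression baseline with utterance-wide f0 SD as the only
    predictor (the field's traditional dysprosody proxy)."""
    X = np.asarray(X_f0sd, dtype=float).reshape(-1, 1)
    m = _ImputedOrdinal(OrdinalElasticNet(reg_total=0.0, l1_ratio=0.5))
    return m.fit(X, np.asarray(y))
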