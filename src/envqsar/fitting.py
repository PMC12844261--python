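"""Model development: collinearity screen, forward-stepwise MLR, validation
metrics, boosted-tree and neural-network ensembles, and sensitivity analysis.

Estimators follow scikit-learn conventions (``fit``/``predict``, parameters in
``__init__``, fitted attributes with a trailing underscore) and accept pandas
DataFrames so that descriptor names travel with the data. Module-level
functions (:func:`tolerance_screen`, :func:`forward_stepwise_mlr`,
:func:`loo_q2`, :func:`rmse_pred`, :func:`fit_boosted_trees`,
:func:`fit_ann_ensemble`, :func:`gsa`, :func:`run_protocol`) are thin wrappers
over the estimator classes for pipeline-style use.

Validation metrics
------------------
R² and adjusted R² are reported on the training split; Q² is the
leave-one-out cross-validated R², ``1 - PRESS/TSS``, where PRESS sums squared
prediction errors with each training row in turn held out and the model refit
on the remaining rows (computed here through the exact hat-matrix identity
for ordinary least squares); RMSE_pred is the root-mean-square prediction
error on the held-out test split.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Any, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.ensemble import GradientBoostingRegressor
from sklearn.neural_network import MLPRegressor
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler

from .core import EnvQsarError, FittedMLR, PropertyModelSpec, ReferenceDataset

__all__ = [
    "ScreenResult",
    "tolerance_screen",
    "ForwardStepwiseMLR",
    "forward_stepwise_mlr",
    "loo_q2",
    "rmse_pred",
    "BoostedTreeModel",
    "fit_boosted_trees",
    "AnnEnsemble",
    "fit_ann_ensemble",
    "gsa",
    "ProtocolConfig",
    "ProtocolBundle",
    "run_protocol",
    "DEFAULT_CANDIDATES",
]

#: Default candidate descriptor sets per property (the published term sets).
DEFAULT_CANDIDATES: dict[str, tuple[str, ...]] = {
    "logKoc": ("nRot", "nHet", "nRing", "PAMPA", "logS", "logP"),
    "logBCF": ("nRot", "MaxRing", "PAMPA", "logS", "logD"),
    "logKpuu": ("TPSA", "nHet", "Fsp3", "MDCK"),
}

#: Extra candidates used only by the boosted-tree stage.
BT_EXTRA_CANDIDATES: dict[str, tuple[str, ...]] = {"logKpuu": ("logVDss",)}


# ---------------------------------------------------------------------------
# collinearity screen
# ---------------------------------------------------------------------------


@dataclass
class ScreenResult:
    """Outcome of the pairwise tolerance (collinearity) screen."""

    retained: list[str]
    flagged_pairs: list[tuple[str, str, float]]  # (a, b, tolerance)
    dropped: list[str]
    degenerate: list[str]


def _resolve_xy(table, candidates, split="train"):
    if isinstance(table, ReferenceDataset):
        cands = list(candidates) if candidates is not None else None
        if cands is None:
            raise EnvQsarError("candidate descriptor list required")
        return table.frame(cands, split)
    X = table
    if candidates is not None:
        X = X[list(candidates)]
    return X, None


def tolerance_screen(
    table,
    candidates: Sequence[str] | None = None,
    cutoff: float = 0.1,
    y: pd.Series | None = None,
) -> ScreenResult:
    """Flag collinear descriptor pairs by tolerance and drop one per pair.

    Tolerance between two candidates is ``1 - r**2`` of their Pearson
    correlation on the training rows; a pair with tolerance below ``cutoff``
    (default 0.1, i.e. |r| > ~0.949) is collinear. From each flagged pair the
    member with the smaller absolute correlation to the response is dropped;
    ties drop the later candidate in input order. Zero-variance candidates
    are degenerate and dropped with a warning.

    ``table`` may be a :class:`~envqsar.core.ReferenceDataset` (the training
    split is used) or a DataFrame with ``y`` given separately.
    """
    X, y_ds = _resolve_xy(table, candidates)
    if y is None:
        y = y_ds
    cols = list(X.columns)
    if len(X) < 3:
        raise EnvQsarError("tolerance screen needs at least 3 training rows")

    degenerate = [c for c in cols if np.std(X[c].to_numpy()) == 0.0]
    if degenerate:
        warnings.warn(
            f"zero-variance candidate(s) dropped: {degenerate}", stacklevel=2
        )
    live = [c for c in cols if c not in degenerate]

    resp_corr: dict[str, float] = {}
    if y is not None:
        yv = np.asarray(y, dtype=float)
        for c in live:
            xv = X[c].to_numpy(dtype=float)
            r = np.corrcoef(xv, yv)[0, 1] if np.std(yv) > 0 else 0.0
            resp_corr[c] = abs(r) if np.isfinite(r) else 0.0

    flagged: list[tuple[str, str, float]] = []
    dropped: set[str] = set(degenerate)
    order = {c: i for i, c in enumerate(cols)}
    for i, a in enumerate(live):
        for b in live[i + 1 :]:
            r = np.corrcoef(X[a].to_numpy(float), X[b].to_numpy(float))[0, 1]
            tol = 1.0 - r * r
            if tol < cutoff:
                flagged.append((a, b, tol))
                if a in dropped or b in dropped:
                    continue
                if resp_corr:
                    ca, cb = resp_corr[a], resp_corr[b]
                    if ca < cb:
                        dropped.add(a)
                    elif cb < ca:
                        dropped.add(b)
                    else:  # tie: drop the later in input order
                        dropped.add(b if order[b] > order[a] else a)
                else:
                    dropped.add(b if order[b] > order[a] else a)
    retained = [c for c in cols if c not in dropped]
    return ScreenResult(
        retained=retained,
        flagged_pairs=flagged,
        dropped=sorted(dropped, key=order.get),
        degenerate=degenerate,
    )


# ---------------------------------------------------------------------------
# forward stepwise MLR
# ---------------------------------------------------------------------------


def _ols(Xmat: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, float]:
    """Least-squares fit with intercept column already included; returns
    (coefficients, residual sum of squares)."""
    beta, _, rank, _ = np.linalg.lstsq(Xmat, y, rcond=None)
    if rank < Xmat.shape[1]:
        raise EnvQsarError("design matrix is rank-deficient")
    resid = y - Xmat @ beta
    return beta, float(resid @ resid)


class ForwardStepwiseMLR(RegressorMixin, BaseEstimator):
    """Forward-stepwise multiple linear regression with partial-F entry.

    Starting from the intercept-only model, each step adds the candidate with
    the largest partial F statistic, provided its p-value is below
    ``p_enter``; the search stops when no remaining candidate qualifies.
    There is no removal step (pure forward selection). Ties break on the
    larger F, then input order. The final model is refit by ordinary least
    squares to obtain coefficient standard errors.

    Parameters
    ----------
    p_enter : float, default 0.05
        Entry threshold on the partial-F p-value.

    Attributes
    ----------
    selected_ : list of str
        Descriptors in order of entry.
    intercept_, coef_ : float, ndarray
        Final OLS fit; ``coef_`` aligns with ``selected_``.
    se_, intercept_se_ : ndarray, float
        Standard errors of the final fit.
    step_trace_ : list of (name, F, cumulative R²)
        One entry per accepted step; cumulative R² is non-decreasing.
    r2_, r2_adj_ : float
        Training-set coefficient of determination and its adjusted form.
    """

    def __init__(self, p_enter: float = 0.05):
        self.p_enter = p_enter

    def fit(self, X: pd.DataFrame, y) -> "ForwardStepwiseMLR":
        X = pd.DataFrame(X)
        yv = np.asarray(y, dtype=float)
        n = len(yv)
        candidates = list(X.columns)
        if n <= len(candidates) + 2:
            raise EnvQsarError(
                f"need n_train > n_candidates + 2 ({n} rows, {len(candidates)} candidates)"
            )
        self.feature_names_in_ = np.asarray(candidates, dtype=object)
        self.n_features_in_ = len(candidates)

        ybar = yv.mean()
        tss = float(((yv - ybar) ** 2).sum())
        selected: list[str] = []
        trace: list[tuple[str, float, float]] = []
        ones = np.ones((n, 1))
        rss_current = tss

        while True:
            remaining = [c for c in candidates if c not in selected]
            if not remaining:
                break
            best: tuple[float, float, str] | None = None  # (F, p, name)
            p_new = len(selected) + 2  # intercept + selected + candidate
            dof = n - p_new
            for c in remaining:
                cols = [X[s].to_numpy(float) for s in selected] + [
                    X[c].to_numpy(float)
                ]
                Xmat = np.hstack([ones] + [col[:, None] for col in cols])
                try:
                    _, rss_new = _ols(Xmat, yv)
                except EnvQsarError as exc:
                    raise EnvQsarError(
                        f"design matrix rank-deficient when entering {c!r} "
                        f"after {selected}"
                    ) from exc
                if rss_new <= 0:
                    F = np.inf
                else:
                    F = (rss_current - rss_new) / (rss_new / dof)
                pval = float(stats.f.sf(F, 1, dof)) if np.isfinite(F) else 0.0
                if best is None or F > best[0]:
                    best = (F, pval, c)
            F, pval, name = best
            if pval >= self.p_enter:
                break
            selected.append(name)
            cols = [X[s].to_numpy(float)[:, None] for s in selected]
            _, rss_current = _ols(np.hstack([ones] + cols), yv)
            r2 = 1.0 - rss_current / tss if tss > 0 else 1.0
            trace.append((name, float(F), float(r2)))

        # final OLS refit (with SEs) on the selected set
        import statsmodels.api as sm

        design = sm.add_constant(
            X[selected].to_numpy(float) if selected else np.empty((n, 0)),
            has_constant="add",
        )
        ols_fit = sm.OLS(yv, design).fit()
        params = np.asarray(ols_fit.params, dtype=float)
        bse = np.asarray(ols_fit.bse, dtype=float)
        self.selected_ = selected
        self.intercept_ = float(params[0])
        self.coef_ = params[1:]
        self.intercept_se_ = float(bse[0])
        self.se_ = bse[1:]
        self.step_trace_ = trace
        k = len(selected)
        self.r2_ = float(1.0 - rss_current / tss) if tss > 0 else 1.0
        self.r2_adj_ = (
            float(1.0 - (1.0 - self.r2_) * (n - 1) / (n - k - 1))
            if n - k - 1 > 0
            else np.nan
        )
        self.n_samples_ = n
        return self

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        X = pd.DataFrame(X)
        Xsel = X[self.selected_].to_numpy(float) if self.selected_ else np.empty(
            (len(X), 0)
        )
        return self.intercept_ + Xsel @ self.coef_

    def coefficients(self) -> dict[str, float]:
        return dict(zip(self.selected_, map(float, self.coef_)))

    def standard_errors(self) -> dict[str, float]:
        return dict(zip(self.selected_, map(float, self.se_)))


def forward_stepwise_mlr(
    table: ReferenceDataset,
    candidates: Sequence[str],
    p_enter: float = 0.05,
    with_q2: bool = True,
) -> FittedMLR:
    """Run forward-stepwise MLR on a reference dataset's training split.

    Returns a :class:`~envqsar.core.FittedMLR` with the step trace, training
    R²/adjusted R², leave-one-out Q², and test-set RMSE of prediction (when a
    test split exists).
    """
    X_tr, y_tr = table.frame(candidates, "train")
    est = ForwardStepwiseMLR(p_enter=p_enter).fit(X_tr, y_tr)
    q2 = loo_q2(est, X_tr, y_tr) if with_q2 and est.selected_ else None
    sizes = table.split_sizes()
    rmse = None
    if sizes.get("test", 0) > 0:
        X_te, y_te = table.frame(candidates, "test")
        rmse = rmse_pred(est, X_te, y_te)
    return FittedMLR(
        property=table.property,
        intercept=est.intercept_,
        coefficients=est.coefficients(),
        standard_errors=est.standard_errors(),
        intercept_se=est.intercept_se_,
        step_trace=est.step_trace_,
        r2=est.r2_,
        r2_adj=est.r2_adj_,
        q2=q2,
        rmse_pred=rmse,
        n_train=sizes.get("train", 0),
        n_test=sizes.get("test", 0),
    )


# ---------------------------------------------------------------------------
# validation metrics
# ---------------------------------------------------------------------------


def _term_names(model) -> list[str]:
    if isinstance(model, ForwardStepwiseMLR):
        return list(model.selected_)
    if isinstance(model, PropertyModelSpec):
        return list(model.terms)
    if isinstance(model, FittedMLR):
        return list(model.coefficients)
    if isinstance(model, (list, tuple)):
        return list(model)
    raise TypeError(f"cannot extract term names from {type(model).__name__}")


def loo_q2(model, X: pd.DataFrame, y) -> float:
    """Leave-one-out cross-validated Q² = 1 - PRESS/TSS on the given rows.

    The model contributes only its *term set*; an OLS model on those terms is
    refit with each row held out in turn. The PRESS statistic is evaluated
    through the exact hat-matrix identity ``e_i / (1 - h_ii)``, which equals
    the naive n-refit loop for ordinary least squares.
    """
    terms = _term_names(model)
    X = pd.DataFrame(X)
    yv = np.asarray(y, dtype=float)
    n = len(yv)
    if n < 5:
        raise EnvQsarError("Q² needs at least 5 training rows")
    Xmat = np.hstack([np.ones((n, 1)), X[terms].to_numpy(float)])
    beta, _, rank, _ = np.linalg.lstsq(Xmat, yv, rcond=None)
    if rank < Xmat.shape[1]:
        raise EnvQsarError("Q²: design matrix singular")
    resid = yv - Xmat @ beta
    # hat diagonal via QR for numerical stability
    Q, _ = np.linalg.qr(Xmat)
    h = np.einsum("ij,ij->i", Q, Q)
    near_one = np.where(h > 1.0 - 1e-10)[0]
    if near_one.size:
        raise EnvQsarError(
            f"Q²: leave-one-out refit singular for row index {int(near_one[0])}"
        )
    press = float(((resid / (1.0 - h)) ** 2).sum())
    tss = float(((yv - yv.mean()) ** 2).sum())
    if tss == 0:
        raise EnvQsarError("Q² undefined: response has zero variance")
    return 1.0 - press / tss


def rmse_pred(model, X_test: pd.DataFrame, y_test) -> float:
    """Root-mean-square error of the model's predictions on a test split."""
    yv = np.asarray(y_test, dtype=float)
    if len(yv) == 0:
        raise EnvQsarError("test split is empty")
    if isinstance(model, PropertyModelSpec):
        preds = np.array([model.predict(row) for _, row in pd.DataFrame(X_test).iterrows()])
    elif isinstance(model, FittedMLR):
        preds = np.array(
            [model.as_spec().predict(row) for _, row in pd.DataFrame(X_test).iterrows()]
        )
    else:
        preds = np.asarray(model.predict(X_test), dtype=float)
    return float(np.sqrt(np.mean((preds - yv) ** 2)))


# ---------------------------------------------------------------------------
# boosted trees
# ---------------------------------------------------------------------------


class BoostedTreeModel(RegressorMixin, BaseEstimator):
    """Gradient-boosted regression trees with normalised relative importances.

    A squared-error-loss boosting ensemble; after fitting,
    ``relative_importances_`` rescales the impurity-based feature importances
    so the largest equals exactly 1, the convention used when ranking QSAR
    descriptors by relative importance.
    """

    def __init__(
        self,
        n_trees: int = 200,
        depth: int = 3,
        learning_rate: float = 0.05,
        seed: int = 0,
    ):
        self.n_trees = n_trees
        self.depth = depth
        self.learning_rate = learning_rate
        self.seed = seed

    def fit(self, X: pd.DataFrame, y) -> "BoostedTreeModel":
        X = pd.DataFrame(X)
        yv = np.asarray(y, dtype=float)
        if np.std(yv) == 0:
            raise EnvQsarError("degenerate response: constant y")
        if self.n_trees < 1 or self.depth < 1 or self.learning_rate <= 0:
            raise ValueError("invalid boosted-tree parameters")
        self.feature_names_in_ = np.asarray(list(X.columns), dtype=object)
        self.n_features_in_ = X.shape[1]
        self.model_ = GradientBoostingRegressor(
            loss="squared_error",
            n_estimators=self.n_trees,
            max_depth=self.depth,
            learning_rate=self.learning_rate,
            random_state=self.seed,
        ).fit(X.to_numpy(float), yv)
        raw = self.model_.feature_importances_
        top = raw.max()
        rel = raw / top if top > 0 else raw
        self.relative_importances_ = {
            name: float(v)
            for name, v in sorted(
                zip(X.columns, rel), key=lambda kv: kv[1], reverse=True
            )
        }
        self.r2_train_ = float(self.model_.score(X.to_numpy(float), yv))
        return self

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        return self.model_.predict(pd.DataFrame(X)[list(self.feature_names_in_)].to_numpy(float))


def fit_boosted_trees(
    table: ReferenceDataset,
    candidates: Sequence[str],
    params: Mapping[str, Any] | None = None,
):
    """Fit a boosted-tree ensemble on the training split.

    Returns ``(model, relative_importances, r2_train, rmse_pred)``;
    importances are normalised to a maximum of 1.
    """
    params = dict(params or {})
    X_tr, y_tr = table.frame(candidates, "train")
    model = BoostedTreeModel(
        n_trees=params.get("n_trees", 200),
        depth=params.get("depth", 3),
        learning_rate=params.get("learning_rate", 0.05),
        seed=params.get("seed", 0),
    ).fit(X_tr, y_tr)
    rmse = None
    if table.split_sizes().get("test", 0) > 0:
        X_te, y_te = table.frame(candidates, "test")
        rmse = rmse_pred(model, X_te, y_te)
    return model, model.relative_importances_, model.r2_train_, rmse


# ---------------------------------------------------------------------------
# neural-network ensemble
# ---------------------------------------------------------------------------


class AnnEnsemble(RegressorMixin, BaseEstimator):
    """Reduced automated network search over single-hidden-layer perceptrons.

    ``n_train_nets`` candidate multilayer perceptrons are trained with a
    quasi-Newton (L-BFGS) optimiser and sum-of-squares loss, each with a
    randomly drawn hidden-layer size and activation function; the
    ``n_retain`` networks with the highest validation-set correlation are
    retained. Inputs are standardised inside each network's pipeline.
    ``predict`` averages the retained networks. Quality is reported as
    Pearson correlation per data split, the conventional metric for such
    network ensembles. A candidate network that fails to train is discarded
    with a log entry, never fatally.
    """

    _ACTIVATIONS = ("identity", "logistic", "tanh")

    def __init__(
        self,
        n_train_nets: int = 50,
        n_retain: int = 5,
        hidden_range: tuple[int, int] = (2, 12),
        activations: tuple[str, ...] = _ACTIVATIONS,
        seed: int = 0,
        max_iter: int = 400,
        val_fraction: float = 0.15,
    ):
        self.n_train_nets = n_train_nets
        self.n_retain = n_retain
        self.hidden_range = hidden_range
        self.activations = activations
        self.seed = seed
        self.max_iter = max_iter
        self.val_fraction = val_fraction

    def fit(self, X, y, X_val=None, y_val=None) -> "AnnEnsemble":
        X = pd.DataFrame(X)
        yv = np.asarray(y, dtype=float)
        rng = np.random.default_rng(self.seed)
        if X_val is None:
            # carve an internal validation subset when none is supplied
            n = len(yv)
            idx = rng.permutation(n)
            n_val = max(1, int(round(self.val_fraction * n)))
            val_idx, tr_idx = idx[:n_val], idx[n_val:]
            X_val, y_val = X.iloc[val_idx], yv[val_idx]
            X, yv = X.iloc[tr_idx], yv[tr_idx]
        else:
            X_val = pd.DataFrame(X_val)
            y_val = np.asarray(y_val, dtype=float)
        self.feature_names_in_ = np.asarray(list(X.columns), dtype=object)
        self.n_features_in_ = X.shape[1]

        lo, hi = self.hidden_range
        candidates = []
        self.training_log_: list[str] = []
        for i in range(self.n_train_nets):
            hidden = int(rng.integers(lo, hi + 1))
            act = str(rng.choice(list(self.activations)))
            net_seed = int(rng.integers(0, 2**31 - 1))
            net = Pipeline(
                [
                    ("scale", StandardScaler()),
                    (
                        "mlp",
                        MLPRegressor(
                            hidden_layer_sizes=(hidden,),
                            activation=act,
                            solver="lbfgs",
                            max_iter=self.max_iter,
                            random_state=net_seed,
                        ),
                    ),
                ]
            )
            try:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    net.fit(X.to_numpy(float), yv)
                pred_tr = net.predict(X.to_numpy(float))
                pred_val = net.predict(X_val.to_numpy(float))
                if not (np.all(np.isfinite(pred_tr)) and np.all(np.isfinite(pred_val))):
                    raise FloatingPointError("non-finite predictions")
            except Exception as exc:  # noqa: BLE001 — any training failure is logged
                self.training_log_.append(
                    f"net {i} (hidden={hidden}, activation={act}) discarded: {exc}"
                )
                continue
            corr_tr = _safe_corr(pred_tr, yv)
            corr_val = _safe_corr(pred_val, y_val)
            candidates.append(
                {
                    "index": i,
                    "hidden": hidden,
                    "activation": act,
                    "seed": net_seed,
                    "net": net,
                    "corr_train": corr_tr,
                    "corr_validation": corr_val,
                }
            )
        if not candidates:
            raise EnvQsarError("no candidate network trained successfully")
        candidates.sort(key=lambda c: (-c["corr_validation"], c["index"]))
        self.retained_ = candidates[: self.n_retain]
        return self

    def predict(self, X) -> np.ndarray:
        Xm = pd.DataFrame(X)[list(self.feature_names_in_)].to_numpy(float)
        return np.mean([c["net"].predict(Xm) for c in self.retained_], axis=0)

    def split_correlations(self, X, y) -> list[float]:
        """Pearson correlation of each retained network on the given rows."""
        Xm = pd.DataFrame(X)[list(self.feature_names_in_)].to_numpy(float)
        yv = np.asarray(y, dtype=float)
        return [_safe_corr(c["net"].predict(Xm), yv) for c in self.retained_]

    def architectures(self) -> list[tuple[int, str]]:
        return [(c["hidden"], c["activation"]) for c in self.retained_]


def _safe_corr(a: np.ndarray, b: np.ndarray) -> float:
    if np.std(a) == 0 or np.std(b) == 0:
        return 0.0
    return float(np.corrcoef(a, b)[0, 1])


def fit_ann_ensemble(
    table: ReferenceDataset,
    candidates: Sequence[str],
    params: Mapping[str, Any] | None = None,
) -> AnnEnsemble:
    """Train the network ensemble using the dataset's three-way split.

    When the dataset has a ``validation`` split it is used for network
    retention; otherwise a validation subset is carved from the training rows.
    """
    params = dict(params or {})
    X_tr, y_tr = table.frame(candidates, "train")
    kwargs = {}
    if table.split_sizes().get("validation", 0) > 0:
        X_val, y_val = table.frame(candidates, "validation")
        kwargs = {"X_val": X_val, "y_val": y_val}
    est = AnnEnsemble(
        n_train_nets=params.get("n_train_nets", 50),
        n_retain=params.get("n_retain", 5),
        hidden_range=tuple(params.get("hidden_range", (2, 12))),
        activations=tuple(params.get("activations", AnnEnsemble._ACTIVATIONS)),
        seed=params.get("seed", 0),
        max_iter=params.get("max_iter", 400),
    )
    return est.fit(X_tr, y_tr, **kwargs)


# ---------------------------------------------------------------------------
# global sensitivity analysis
# ---------------------------------------------------------------------------


def gsa(
    model,
    X: pd.DataFrame,
    y,
    means: Mapping[str, float] | None = None,
) -> dict[str, float]:
    """Global sensitivity scores: SSR with a variable ablated over full SSR.

    A variable is ablated by replacing its column with its training mean
    (``means[name]`` when supplied, else the column mean of ``X``) without
    refitting; the score for variable ``v`` is ``SSR(ablated) / SSR(full)``.
    Scores at or below 1 mean the model performs no worse without the
    variable; large scores mark variables the model depends on. Returned
    sorted descending. If the full model has zero residual error the scores
    are reported as ``inf`` with a warning.
    """
    X = pd.DataFrame(X)
    yv = np.asarray(y, dtype=float)
    full = np.asarray(model.predict(X), dtype=float)
    ssr_full = float(((yv - full) ** 2).sum())
    scores: dict[str, float] = {}
    for col in X.columns:
        Xa = X.copy()
        Xa[col] = means[col] if means is not None else X[col].mean()
        pred = np.asarray(model.predict(Xa), dtype=float)
        ssr = float(((yv - pred) ** 2).sum())
        if ssr_full == 0.0:
            scores[col] = 1.0 if ssr == 0.0 else np.inf
        else:
            scores[col] = ssr / ssr_full
    if ssr_full == 0.0 and any(np.isinf(v) for v in scores.values()):
        warnings.warn(
            "full model has zero residual error; GSA scores reported as inf",
            stacklevel=2,
        )
    return dict(sorted(scores.items(), key=lambda kv: kv[1], reverse=True))


# ---------------------------------------------------------------------------
# end-to-end protocol
# ---------------------------------------------------------------------------


@dataclass
class ProtocolConfig:
    """Configuration for the full modelling protocol.

    ``candidates`` defaults to the published term set for the dataset's
    property; the boosted-tree stage for log Kp,uu additionally considers
    the volume of distribution (logVDss).
    """

    candidates: tuple[str, ...] | None = None
    p_enter: float = 0.05
    tolerance_cutoff: float = 0.1
    bt: dict = field(default_factory=dict)
    ann: dict = field(default_factory=dict)
    seed: int = 0


@dataclass
class ProtocolBundle:
    """Everything the modelling protocol produces for one property."""

    property: str
    screen: ScreenResult
    mlr: FittedMLR
    bt_model: BoostedTreeModel
    bt_importance: dict[str, float]
    bt_r2_train: float
    bt_rmse_pred: float | None
    ann: AnnEnsemble
    ann_correlations: dict[str, list[float]]
    gsa_report: dict[str, float]

    def summary(self) -> dict:
        return {
            "property": self.property,
            "screen_retained": list(self.screen.retained),
            "mlr": {
                "intercept": self.mlr.intercept,
                "coefficients": self.mlr.coefficients,
                "standard_errors": self.mlr.standard_errors,
                "r2": self.mlr.r2,
                "r2_adj": self.mlr.r2_adj,
                "q2": self.mlr.q2,
                "rmse_pred": self.mlr.rmse_pred,
                "step_trace": [list(t) for t in self.mlr.step_trace],
            },
            "bt": {
                "relative_importances": self.bt_importance,
                "r2_train": self.bt_r2_train,
                "rmse_pred": self.bt_rmse_pred,
            },
            "ann": {
                "architectures": self.ann.architectures(),
                "correlations": self.ann_correlations,
            },
            "gsa": self.gsa_report,
        }

    def summary_json(self) -> str:
        return json.dumps(self.summary(), indent=2, default=float)


def run_protocol(
    table: ReferenceDataset,
    config: ProtocolConfig | None = None,
) -> ProtocolBundle:
    """Run the complete modelling protocol on one reference dataset.

    Stages: collinearity screen on the candidate descriptors; forward
    stepwise MLR with Q² and test RMSE; boosted-tree regression with relative
    importances (with logVDss added to the log Kp,uu candidate pool); a
    neural-network ensemble on the stepwise-selected variables; and global
    sensitivity analysis of the ensemble on the training rows. Fully
    deterministic under ``config.seed``.
    """
    config = config or ProtocolConfig()
    candidates = (
        config.candidates
        if config.candidates is not None
        else DEFAULT_CANDIDATES.get(table.property)
    )
    if not candidates:
        raise EnvQsarError(
            f"no candidate descriptors configured for property {table.property!r}"
        )
    X_tr, y_tr = table.frame(candidates, "train")
    screen = tolerance_screen(X_tr, cutoff=config.tolerance_cutoff, y=y_tr)
    mlr = forward_stepwise_mlr(table, screen.retained, p_enter=config.p_enter)

    bt_cands = list(screen.retained) + [
        c
        for c in BT_EXTRA_CANDIDATES.get(table.property, ())
        if c not in screen.retained
    ]
    bt_params = {"seed": config.seed, **config.bt}
    bt_model, bt_imp, bt_r2, bt_rmse = fit_boosted_trees(table, bt_cands, bt_params)

    ann_cands = mlr.coefficients.keys() if mlr.coefficients else screen.retained
    ann_cands = list(ann_cands)
    ann_params = {"seed": config.seed, **config.ann}
    ann = fit_ann_ensemble(table, ann_cands, ann_params)
    ann_corr: dict[str, list[float]] = {}
    for label in ("train", "test", "validation"):
        if table.split_sizes().get(label, 0) > 1:
            Xs, ys = table.frame(ann_cands, label)
            ann_corr[label] = ann.split_correlations(Xs, ys)

    Xg, yg = table.frame(ann_cands, "train")
    gsa_report = gsa(ann, Xg, yg)

    return ProtocolBundle(
        property=table.property,
        screen=screen,
        mlr=mlr,
        bt_model=bt_model,
        bt_importance=bt_imp,
        bt_r2_train=bt_r2,
        bt_rmse_pred=bt_rmse,
        ann=ann,
        ann_correlations=ann_corr,
        gsa_report=gsa_report,
    )
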