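"""Regression utilities: least-squares fits, repeated train/test greedy
forward feature selection with SCR prioritization, and correlation
helpers."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps


class RankDeficientError(ValueError):
    pass


def _design(X: np.ndarray) -> np.ndarray:
    return np.column_stack([np.ones(X.shape[0]), X])


def fit_ols(X: np.ndarray, y: np.ndarray, column_names=None):
    """Ordinary least squares with intercept.

    Returns ``(coefficients, r_squared)`` where ``coefficients[0]`` is the
    intercept.  Rank deficiency raises :class:`RankDeficientError` naming
    suspect columns.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.ndim == 1:
        X = X[:, None]
    y = np.asarray(y, dtype=float)
    n, m = X.shape
    if n <= m:
        raise ValueError(f"need more rows ({n}) than columns ({m})")
    A = _design(X)
    rank = np.linalg.matrix_rank(A)
    if rank < A.shape[1]:
        names = column_names or [f"x{i}" for i in range(m)]
        # crude collinearity report: columns whose removal restores rank
        bad = [
            names[i]
            for i in range(m)
            if np.linalg.matrix_rank(np.delete(A, i + 1, axis=1)) == rank
        ]
        raise RankDeficientError(f"collinear columns: {bad or names}")
    coef, *_ = np.linalg.lstsq(A, y, rcond=None)
    return coef, r_squared(A @ coef, y)


def r_squared(pred: np.ndarray, y: np.ndarray) -> float:
    ss_res = float(np.sum((y - pred) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0:
        return 0.0
    return 1.0 - ss_res / ss_tot


def predict(coef: np.ndarray, X: np.ndarray) -> np.ndarray:
    return _design(np.atleast_2d(np.asarray(X, float))) @ coef


@dataclass
class SelectionResult:
    """Outcome of repeated-split greedy forward selection."""

    features: list[str]
    scr: dict[str, int]                  # sum of selection ranks; low = good
    ranked: list[str]                    # ascending SCR (ties by name)
    orders: list[list[str]]              # per-repetition selection orders
    r2_train: np.ndarray                 # (n_rep, max_features)
    r2_test: np.ndarray

    def report_frame(self) -> pd.DataFrame:
        m = len(self.features)
        times = {f: 0 for f in self.features}
        ranksum = {f: 0 for f in self.features}
        for order in self.orders:
            for i, f in enumerate(order, start=1):
                times[f] += 1
                ranksum[f] += i
        return pd.DataFrame(
            {
                "feature": self.ranked,
                "scr": [self.scr[f] for f in self.ranked],
                "times_selected": [times[f] for f in self.ranked],
                "mean_rank_when_selected": [
                    ranksum[f] / times[f] if times[f] else np.nan
                    for f in self.ranked
                ],
            }
        )


def forward_select(
    table: pd.DataFrame,
    y: np.ndarray,
    n_rep: int = 100,
    train_frac: float = 2 / 3,
    max_features: int | None = None,
    rng: np.random.Generator | None = None,
    select_on: str = "test",
) -> SelectionResult:
    """Repeated train/test greedy forward selection.

    Per repetition: a random ``train_frac`` split; the first feature
    maximizes R-squared and each subsequent feature maximizes the
    R-squared increase, evaluated on the held-out test set by default
    (``select_on="train"`` switches to in-sample selection).  A feature
    selected ``i``-th in a repetition contributes ``i`` to its SCR;
    features not selected in a repetition contribute ``M + 1``.  The
    final ranking sorts SCR ascending (ties by feature name).
    """
    if n_rep < 1:
        raise ValueError("n_rep must be >= 1")
    if select_on not in ("test", "train"):
        raise ValueError("select_on must be 'test' or 'train'")
    if table.isna().any().any():
        raise ValueError("feature table contains missing values")
    rng = rng or np.random.default_rng()
    features = list(table.columns)
    M = len(features)
    X = table.to_numpy(dtype=float)
    y = np.asarray(y, dtype=float)
    n = X.shape[0]
    n_train = int(round(train_frac * n))
    if n_train < 2 or n - n_train < 2:
        raise ValueError("not enough rows for the train/test split")
    cap = min(max_features or 15, M, n_train - 2)

    scr = {f: 0 for f in features}
    orders: list[list[str]] = []
    r2_train = np.full((n_rep, cap), np.nan)
    r2_test = np.full((n_rep, cap), np.nan)
    for rep in range(n_rep):
        idx = rng.permutation(n)
        tr, te = idx[:n_train], idx[n_train:]
        chosen: list[int] = []
        best_score = -np.inf
        for step in range(cap):
            cand_best, cand_score, cand_tr = -1, -np.inf, np.nan
            for c in range(M):
                if c in chosen:
                    continue
                cols = chosen + [c]
                try:
                    coef, r2tr = fit_ols(X[np.ix_(tr, cols)], y[tr])
                except RankDeficientError:
                    continue
                r2te = r_squared(predict(coef, X[np.ix_(te, cols)]), y[te])
                score = r2te if select_on == "test" else r2tr
                if score > cand_score + 1e-12 or (
                    cand_best >= 0
                    and abs(score - cand_score) <= 1e-12
                    and features[c] < features[cand_best]
                ):
                    cand_best, cand_score, cand_tr = c, score, r2tr
            if cand_best < 0:
                break
            chosen.append(cand_best)
            best_score = cand_score
            r2_train[rep, step] = cand_tr
            r2_test[rep, step] = (
                cand_score if select_on == "test"
                else r_squared(
                    predict(
                        fit_ols(X[np.ix_(tr, chosen)], y[tr])[0],
                        X[np.ix_(te, chosen)],
                    ),
                    y[te],
                )
            )
        order = [features[c] for c in chosen]
        orders.append(order)
        picked = set(chosen)
        for i, c in enumerate(chosen, start=1):
            scr[features[c]] += i
        for c in range(M):
            if c not in picked:
                scr[features[c]] += M + 1
    ranked = sorted(features, key=lambda f: (scr[f], f))
    return SelectionResult(features, scr, ranked, orders, r2_train, r2_test)


def evaluate_ranked(
    table: pd.DataFrame,
    y: np.ndarray,
    ranked: list[str],
    k_max: int | None = None,
) -> pd.DataFrame:
    """Full-table fit with the top-k ranked features for k = 1..k_max;
    returns Pearson/Spearman correlation curves between prediction and
    objective."""
    y = np.asarray(y, dtype=float)
    k_max = k_max or len(ranked)
    rows = []
    for k in range(1, k_max + 1):
        cols = ranked[:k]
        X = table[cols].to_numpy(dtype=float)
        try:
            coef, r2 = fit_ols(X, y, column_names=cols)
            pred = predict(coef, X)
            pear = float(sps.pearsonr(pred, y).statistic)
            spear = float(sps.spearmanr(pred, y).statistic)
        except (RankDeficientError, ValueError):
            r2, pear, spear = np.nan, np.nan, np.nan
        rows.append(
            {"k": k, "r2": r2, "pearson": pear, "spearman": spear}
        )
    return pd.DataFrame(rows)


def partial_spearman(
    x: np.ndarray,
    y: np.ndarray,
    controls: np.ndarray | None = None,
) -> float:
    """Spearman correlation of x and y after regressing the (ranked)
    controls out of both."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 4:
        raise ValueError("x and y must be equal-length with >= 4 points")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant input: correlation undefined")
    rx = sps.rankdata(x)
    ry = sps.rankdata(y)
    if controls is None or (
        hasattr(controls, "__len__") and len(controls) == 0
    ):
        return float(sps.pearsonr(rx, ry).statistic)
    C = np.atleast_2d(np.asarray(controls, dtype=float))
    if C.shape[0] == x.size and C.ndim == 2:
        pass
    elif C.shape[1] == x.size:
        C = C.T
    else:
        raise ValueError("controls must have the same number of rows as x")
    RC = np.column_stack([sps.rankdata(c) for c in C.T])
    A = _design(RC)
    res_x = rx - A @ np.linalg.lstsq(A, rx, rcond=None)[0]
    res_y = ry - A @ np.linalg.lstsq(A, ry, rcond=None)[0]
    if np.allclose(res_x, 0) or np.allclose(res_y, 0):
        return 0.0
    return float(sps.pearsonr(res_x, res_y).statistic)
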