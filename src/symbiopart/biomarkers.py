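"""Caste biomarker selection by L1-penalized logistic regression.

Features are log2(TMM + 1) expression values, standardized per transcript;
the response is the binary caste label (soldier = 1).  The lasso path is
fit by cyclic coordinate descent on the iteratively reweighted quadratic
approximation of the logistic deviance,

    minimize (1/n) * sum_i deviance_i(beta0, beta) + lambda * ||beta||_1,

warm-started along a decreasing lambda grid, with the penalty chosen by
stratified k-fold cross-validation.  A positive coefficient marks a
soldier-biased transcript, a negative one a worker-biased transcript.

With 20 samples and hundreds of features the selected set is unstable;
the report therefore records the selection frequency of each transcript
across CV folds rather than claiming uniqueness.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .expression import SOLDIER

_P_CLAMP = 1e-5


@dataclass
class LassoFit:
    """A fitted regularization path plus the CV-selected solution."""

    feature_names: list[str]
    means: np.ndarray              # standardization means/scales
    scales: np.ndarray
    lambdas: np.ndarray            # decreasing grid
    coefs: np.ndarray              # (n_lambda, n_features), standardized scale
    intercepts: np.ndarray
    cv_deviance: np.ndarray | None = None
    cv_se: np.ndarray | None = None
    selected_lambda: float | None = None
    selection_freq: dict[str, float] = field(default_factory=dict)

    @property
    def selected_index(self) -> int:
        return int(np.argmin(np.abs(self.lambdas - self.selected_lambda)))

    def nonzero(self, index: int | None = None) -> dict[str, float]:
        """Nonzero coefficients (standardized scale) at the selected lambda."""
        i = self.selected_index if index is None else index
        beta = self.coefs[i]
        return {name: float(b) for name, b in zip(self.feature_names, beta)
                if b != 0.0}


def _objective(X: np.ndarray, y: np.ndarray, beta0: float,
               beta: np.ndarray, lam: float) -> float:
    eta = beta0 + X @ beta
    # numerically stable logistic negative log-likelihood / n
    nll = np.mean(np.logaddexp(0.0, eta) - y * eta)
    return nll + lam * np.abs(beta).sum()


def _soft(x: float, t: float) -> float:
    return np.sign(x) * max(abs(x) - t, 0.0)


def _fit_single_lambda(X: np.ndarray, y: np.ndarray, lam: float,
                       beta0: float, beta: np.ndarray,
                       tol: float = 1e-7, max_outer: int = 100
                       ) -> tuple[float, np.ndarray]:
    """IRLS + cyclic coordinate descent, warm-started at (beta0, beta).

    A step-halving safeguard keeps the penalized objective non-increasing
    across outer sweeps.
    """
    n, p = X.shape
    beta = beta.copy()
    obj = _objective(X, y, beta0, beta, lam)
    for _ in range(max_outer):
        eta = beta0 + X @ beta
        prob = np.clip(1.0 / (1.0 + np.exp(-eta)), _P_CLAMP, 1 - _P_CLAMP)
        w = prob * (1 - prob)
        z = eta + (y - prob) / w
        # coordinate descent on the weighted least-squares surrogate
        b0_new, b_new = beta0, beta.copy()
        for _ in range(200):
            max_delta = 0.0
            r = z - (b0_new + X @ b_new)
            b0_prev = b0_new
            b0_new = b0_new + np.sum(w * r) / np.sum(w)
            r -= b0_new - b0_prev
            for j in range(p):
                xj = X[:, j]
                num = np.sum(w * xj * (r + xj * b_new[j])) / n
                den = np.sum(w * xj * xj) / n
                bj = _soft(num, lam) / den
                delta = bj - b_new[j]
                if delta != 0.0:
                    r -= xj * delta
                    b_new[j] = bj
                    max_delta = max(max_delta, abs(delta))
            if max_delta < tol:
                break
        # step-halving: the IRLS surrogate may overshoot the true objective
        step = 1.0
        for _ in range(30):
            b0_try = beta0 + step * (b0_new - beta0)
            b_try = beta + step * (b_new - beta)
            obj_try = _objective(X, y, b0_try, b_try, lam)
            if obj_try <= obj + 1e-12:
                break
            step /= 2
        else:
            break  # no improving step: converged
        moved = max(abs(b0_try - beta0), np.max(np.abs(b_try - beta),
                                                initial=0.0))
        beta0, beta, obj = b0_try, b_try, obj_try
        if moved < tol:
            break
    return beta0, beta


def standardize(X: np.ndarray, names: list[str]
                ) -> tuple[np.ndarray, np.ndarray, np.ndarray, list[str]]:
    """Column-standardize, dropping constant columns."""
    means = X.mean(axis=0)
    scales = X.std(axis=0)
    keep = scales > 0
    Xs = (X[:, keep] - means[keep]) / scales[keep]
    kept = [n for n, k in zip(names, keep) if k]
    return Xs, means[keep], scales[keep], kept


def lambda_max(X: np.ndarray, y: np.ndarray) -> float:
    """Smallest penalty at which all coefficients are zero."""
    n = X.shape[0]
    return float(np.max(np.abs(X.T @ (y - y.mean()))) / n)


def lambda_grid(X: np.ndarray, y: np.ndarray, n_lambda: int = 50,
                ratio: float = 0.01) -> np.ndarray:
    lmax = lambda_max(X, y)
    return np.geomspace(lmax, ratio * lmax, n_lambda)


def lasso_logistic_path(X: np.ndarray, y: np.ndarray,
                        lambdas: np.ndarray,
                        feature_names: list[str] | None = None,
                        standardized: bool = True) -> LassoFit:
    """Fit the penalized logistic path over a decreasing lambda grid.

    *X* must already be standardized column-wise unless
    ``standardized=False``, in which case it is standardized here.
    """
    y = np.asarray(y, dtype=float)
    if set(np.unique(y)) - {0.0, 1.0}:
        raise ValueError("y must be binary 0/1")
    if X.shape[0] < 4:
        raise ValueError("need at least 4 samples")
    names = feature_names or [f"f{j}" for j in range(X.shape[1])]
    if standardized:
        means = np.zeros(X.shape[1])
        scales = np.ones(X.shape[1])
    else:
        X, means, scales, names = standardize(np.asarray(X, float), names)

    lambdas = np.sort(np.asarray(lambdas, dtype=float))[::-1]
    n_lambda = lambdas.size
    coefs = np.zeros((n_lambda, X.shape[1]))
    intercepts = np.zeros(n_lambda)
    beta0 = float(np.log(y.mean() / (1 - y.mean()))) \
        if 0 < y.mean() < 1 else 0.0
    beta = np.zeros(X.shape[1])
    for i, lam in enumerate(lambdas):
        beta0, beta = _fit_single_lambda(X, y, lam, beta0, beta)
        intercepts[i] = beta0
        coefs[i] = beta
    return LassoFit(names, means, scales, lambdas, coefs, intercepts)


def _stratified_folds(y: np.ndarray, k: int,
                      rng: np.random.Generator) -> list[np.ndarray]:
    """Fold index arrays with class proportions preserved."""
    folds: list[list[int]] = [[] for _ in range(k)]
    for cls in np.unique(y):
        idx = np.flatnonzero(y == cls)
        rng.shuffle(idx)
        for i, sample in enumerate(idx):
            folds[i % k].append(sample)
    out = [np.sort(np.array(f)) for f in folds]
    for f in out:
        if len(np.unique(y[f])) < 2 and len(f) > 0 and len(np.unique(y)) > 1:
            raise ValueError("a CV fold contains a single class; "
                             "reduce k or rebalance")
    return out


def cv_select_lambda(X: np.ndarray, y: np.ndarray, k: int = 10,
                     seed: int = 0, lambdas: np.ndarray | None = None,
                     rule: str = "min") -> LassoFit:
    """Cross-validated penalty selection (rule "min" or "1se").

    Fits the full-data path, then per-fold paths on the same grid; the
    selected lambda minimizes mean held-out deviance ("min") or is the
    largest lambda within one standard error of that minimum ("1se").
    Also records per-feature selection frequency across folds at the
    chosen lambda.
    """
    y = np.asarray(y, dtype=float)
    if k > len(y):
        raise ValueError("k exceeds sample count")
    if lambdas is None:
        lambdas = lambda_grid(X, y)
    fit = lasso_logistic_path(X, y, lambdas)
    rng = np.random.default_rng(seed)
    folds = _stratified_folds(y, k, rng)

    dev = np.zeros((k, lambdas.size))
    fold_nonzero = []
    for fi, val_idx in enumerate(folds):
        train = np.setdiff1d(np.arange(len(y)), val_idx)
        f = lasso_logistic_path(X[train], y[train], lambdas)
        eta = f.intercepts[:, None] + f.coefs @ X[val_idx].T
        yv = y[val_idx]
        dev[fi] = 2 * np.mean(np.logaddexp(0.0, eta) - yv[None, :] * eta,
                              axis=1)
        fold_nonzero.append(f)
    mean_dev = dev.mean(axis=0)
    se_dev = dev.std(axis=0, ddof=1) / np.sqrt(k)
    i_min = int(np.argmin(mean_dev))
    if rule == "min":
        i_sel = i_min
    elif rule == "1se":
        thresh = mean_dev[i_min] + se_dev[i_min]
        within = np.flatnonzero(mean_dev <= thresh)
        i_sel = int(within[0])  # grid is decreasing: first = largest lambda
    else:
        raise ValueError(f"unknown rule {rule!r}")

    fit.cv_deviance = mean_dev
    fit.cv_se = se_dev
    fit.selected_lambda = float(fit.lambdas[i_sel])
    freq: dict[str, float] = {}
    for f in fold_nonzero:
        for name in f.nonzero(i_sel):
            freq[name] = freq.get(name, 0.0) + 1.0 / k
    fit.selection_freq = freq
    return fit


def fit_biomarkers(tmm: pd.DataFrame, castes: pd.Series, seed: int,
                   k: int = 10, log_transform: bool = True,
                   rule: str = "min") -> LassoFit:
    """Convenience wrapper: TMM matrix -> standardized features -> CV lasso."""
    samples = list(tmm.columns)
    X = tmm.T.to_numpy(dtype=float)
    if log_transform:
        X = np.log2(X + 1.0)
    y = (castes.loc[samples] == SOLDIER).to_numpy(dtype=float)
    Xs, means, scales, names = standardize(X, list(tmm.index))
    fit = cv_select_lambda(Xs, y, k=k, seed=seed)
    fit.means, fit.scales, fit.feature_names = means, scales, names
    return fit


def report_biomarkers(fit: LassoFit, calls: dict, de_results: list,
                      tmm: pd.DataFrame, castes: pd.Series) -> pd.DataFrame:
    """Biomarker report: one row per nonzero-coefficient transcript.

    Columns: putative source, lasso coefficient, average worker and
    soldier TMM, DET flag joined from the differential-abundance results,
    and cross-fold selection frequency.
    """
    from .diffabund import NS

    det = {r.transcript: r.status != NS for r in de_results}
    worker_samples = [s for s in tmm.columns if castes[s] != SOLDIER]
    soldier_samples = [s for s in tmm.columns if castes[s] == SOLDIER]
    rows = []
    for name, coef in sorted(fit.nonzero().items()):
        call = calls.get(name)
        rows.append({
            "transcript": name,
            "putative_source": call.source if call else "unclear",
            "coefficient": coef,
            "avg_worker_tmm": float(tmm.loc[name, worker_samples].mean()),
            "avg_soldier_tmm": float(tmm.loc[name, soldier_samples].mean()),
            "det": "yes" if det.get(name, False) else "no",
            "selection_freq": fit.selection_freq.get(name, 0.0),
        })
    cols = ["transcript", "putative_source", "coefficient", "avg_worker_tmm",
            "avg_soldier_tmm", "det", "selection_freq"]
    return pd.DataFrame(rows, columns=cols)


def biomarker_consistency(report: pd.DataFrame,
                          host_label: str = "termite") -> dict[str, int]:
    """Summary counts over a biomarker report.

    Returns the number of rows, the number flagged DET, the number of
    host-source DET rows, and the number whose coefficient sign agrees
    with the direction of the caste TMM means (positive coefficient iff
    soldier mean exceeds worker mean).
    """
    det = report["det"].astype(str).str.lower() == "yes"
    sign_ok = ((report["coefficient"] > 0)
               == (report["avg_soldier_tmm"] > report["avg_worker_tmm"]))
    return {
        "n_rows": int(len(report)),
        "n_det": int(det.sum()),
        "n_host_det": int((det & (report["putative_source"]
                                  == host_label)).sum()),
        "n_sign_consistent": int(sign_ok.sum()),
    }
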