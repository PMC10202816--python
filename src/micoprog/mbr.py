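"""The microbiome-based risk (MBR) signature.

The MBR score is a linear risk score over genus-level relative abundances:
each genus is z-scored with the *training* cohort's mean and standard
deviation, multiplied by its coefficient from a relaxed elastic-net Cox
model of overall survival, and summed.  Hyperparameters — the penalty
strength lambda and the relaxation gamma that blends the penalized
coefficients with an unpenalized refit on the active set — are chosen by
k-fold cross-validation maximizing the out-of-fold Harrell concordance.
Genera with nonzero coefficients form the "MBR classifier"; transferring
the score to a new cohort uses only the classifier genera present there,
always standardized with the training parameters.  Scores are binarized at
0: negative = low risk, zero or positive = high risk (the boundary sample
is closed on the high side).

The cross-validation harness, grid search, concordance metric,
standardization and score transfer live here; the penalized Cox path itself
is solved by scikit-survival's coordinate-descent elastic net.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.model_selection import KFold
from sksurv.linear_model import CoxnetSurvivalAnalysis
from sksurv.util import Surv

from .survival import check_survival, fit_coxph, harrell_c

__all__ = [
    "StandardizationParams",
    "MBRModel",
    "fit_standardization",
    "train_mbr",
    "score_mbr",
    "evaluate_mbr",
    "write_model",
    "read_model",
    "DEFAULT_GAMMAS",
]

DEFAULT_GAMMAS = (0.0, 0.25, 0.5, 0.75, 1.0)


@dataclass
class StandardizationParams:
    """Per-genus training mean and standard deviation (sample sd, ddof = 1)."""

    mean: pd.Series
    sd: pd.Series

    @property
    def zero_variance(self) -> list:
        return list(self.sd.index[self.sd == 0])

    def transform(self, table: pd.DataFrame) -> pd.DataFrame:
        common = [t for t in self.mean.index if t in table.columns]
        sd = self.sd[common].replace(0.0, np.nan)
        return (table[common] - self.mean[common]) / sd

    def inverse_transform(self, z: pd.DataFrame) -> pd.DataFrame:
        common = [t for t in self.mean.index if t in z.columns]
        return z[common] * self.sd[common] + self.mean[common]


@dataclass
class MBRModel:
    taxa: list
    coefficients: np.ndarray
    standardization: StandardizationParams
    gamma: float
    lam: float
    l1_ratio: float = 0.5
    k_folds: int = 5
    seed: int = 0
    cv_concordance: float = float("nan")
    cv_grid: pd.DataFrame | None = field(default=None, repr=False)

    @property
    def classifier(self) -> pd.Series:
        """Nonzero-coefficient genera — the MBR classifier."""
        coefs = pd.Series(self.coefficients, index=self.taxa)
        return coefs[coefs != 0]


def fit_standardization(table: pd.DataFrame) -> StandardizationParams:
    """Column means and sample standard deviations of a training table."""
    if len(table) < 2:
        raise ValueError("standardization needs at least 2 samples")
    mean = table.mean(axis=0)
    sd = table.std(axis=0, ddof=1)
    if (sd == 0).any():
        warnings.warn(
            f"zero-variance column(s): {list(sd.index[sd == 0])}", stacklevel=2
        )
    return StandardizationParams(mean=mean, sd=sd)


def _relaxed_coefs(beta_pen: np.ndarray, gamma: float, refit_cache: dict, refitter) -> np.ndarray:
    """Blend penalized coefficients with the unpenalized refit on the active set.

    gamma = 1 returns the penalized solution, gamma = 0 the fully relaxed
    (refit) one.
    """
    active = tuple(np.flatnonzero(beta_pen))
    if not active:
        return beta_pen
    if gamma == 1.0:
        return beta_pen
    if active not in refit_cache:
        refit_cache[active] = refitter(active)
    beta_refit = refit_cache[active]
    return gamma * beta_pen + (1.0 - gamma) * beta_refit


def _newton_cox(X: np.ndarray, time: np.ndarray, event: np.ndarray,
                ridge: float = 1e-4, max_iter: int = 30, tol: float = 1e-7) -> np.ndarray:
    """Newton maximization of the Breslow-ties Cox partial likelihood.

    A small ridge keeps the refit finite under separation.  Used only for the
    relaxation refit on active sets; inference-grade fits go through
    :func:`micoprog.survival.fit_coxph`.  Returns NaN when the fit is not
    identifiable (more parameters than events support).
    """
    n, p = X.shape
    n_events = int(event.sum())
    if p >= max(2, int(0.8 * n_events)):
        return np.full(p, np.nan)  # unpenalized refit would be unreliable

    order = np.argsort(-time)  # descending: risk sets are prefixes
    Xs, ts, es = X[order], time[order], event[order]
    # risk set of subject i = prefix up to the last index sharing t_i
    idx = np.searchsorted(-ts, -ts, side="right") - 1
    ev = np.flatnonzero(es)
    uniq, inv = np.unique(idx[ev], return_inverse=True)  # ascending prefix ends
    starts = np.concatenate([[0], uniq[:-1] + 1])

    beta = np.zeros(p)
    for _ in range(max_iter):
        eta = Xs @ beta
        eta -= eta.max()
        w = np.exp(eta)
        wX = w[:, None] * Xs
        # segment sums between successive unique risk-set boundaries,
        # accumulated into prefix sums only at the boundaries we need
        s0 = np.cumsum(np.add.reduceat(w, starts))
        s1 = np.cumsum(np.add.reduceat(wX, starts, axis=0), axis=0)
        s2 = np.empty((uniq.size, p, p))
        acc = np.zeros((p, p))
        for j, (a, b) in enumerate(zip(starts, uniq + 1)):
            acc = acc + Xs[a:b].T @ wX[a:b]
            s2[j] = acc
        xbar = s1 / s0[:, None]
        grad = (Xs[ev] - xbar[inv]).sum(axis=0) - ridge * beta
        v = s2[inv] / s0[inv, None, None] - xbar[inv][:, :, None] * xbar[inv][:, None, :]
        info = v.sum(axis=0) + ridge * np.eye(p)
        try:
            step = np.linalg.solve(info, grad)
        except np.linalg.LinAlgError:
            return np.full(p, np.nan)
        beta = beta + step
        if not np.isfinite(beta).all():
            return np.full(p, np.nan)
        if np.abs(step).max() < tol:
            break
    return beta


def _make_refitter(X: np.ndarray, y) -> callable:
    time = y["time"] if y.dtype.names and "time" in y.dtype.names else y[y.dtype.names[1]]
    event = y[y.dtype.names[0]].astype(float)

    def refitter(active: tuple) -> np.ndarray:
        beta = np.zeros(X.shape[1])
        sub = _newton_cox(X[:, list(active)], np.asarray(time, float), np.asarray(event, float))
        beta[list(active)] = sub
        return beta

    return refitter


def _blend(beta_pen, beta_refit_fn, gamma, cache, refitter):
    beta = _relaxed_coefs(beta_pen, gamma, cache, refitter)
    if np.isnan(beta).any():  # refit failed; use the penalized solution
        return beta_pen
    return beta


def train_mbr(
    table: pd.DataFrame,
    survival: pd.DataFrame,
    k_folds: int = 5,
    gammas=DEFAULT_GAMMAS,
    n_lambdas: int = 50,
    l1_ratio: float = 0.5,
    seed: int = 0,
) -> MBRModel:
    """Train the MBR signature on a (samples x genera) relative-abundance table.

    The table is z-scored with its own mean/sd (stored for transfer).  A
    common lambda path of ``n_lambdas`` values is computed on the full
    training set; for every (gamma, lambda) grid point the mean out-of-fold
    Harrell concordance over ``k_folds`` folds is evaluated, the maximizing
    point selected (ties prefer the stronger penalty, then the more
    penalized blend), and the final model refit on all data at that point.
    """
    survival = check_survival(survival).loc[table.index]
    n_events = int(survival["event"].sum())
    if n_events < k_folds:
        raise ValueError(f"{n_events} events is fewer than k_folds={k_folds}")

    params = fit_standardization(table)
    usable = [t for t in table.columns if params.sd[t] > 0]
    Z = params.transform(table)[usable].to_numpy(float)
    y = Surv.from_arrays(event=survival["event"].astype(bool), time=survival["time"])

    path = CoxnetSurvivalAnalysis(l1_ratio=l1_ratio, n_alphas=n_lambdas, alpha_min_ratio=0.01)
    path.fit(Z, y)
    alphas = np.asarray(path.alphas_)

    folds = list(KFold(n_splits=k_folds, shuffle=True, random_state=seed).split(Z))
    # c_scores[f, g, l]
    c_scores = np.full((k_folds, len(gammas), len(alphas)), np.nan)
    for f, (tr, te) in enumerate(folds):
        fit = CoxnetSurvivalAnalysis(l1_ratio=l1_ratio, alphas=alphas)
        fit.fit(Z[tr], y[tr])
        fitted_alphas = list(fit.alphas_)
        cache: dict = {}
        refitter = _make_refitter(Z[tr], y[tr])
        rec_te = survival.iloc[te]
        for l, lam in enumerate(alphas):
            if lam not in fitted_alphas:
                continue
            beta_pen = fit.coef_[:, fitted_alphas.index(lam)]
            for g, gamma in enumerate(gammas):
                beta = _blend(beta_pen, None, gamma, cache, refitter)
                c_scores[f, g, l] = harrell_c(Z[te] @ beta, rec_te)

    mean_c = np.nanmean(c_scores, axis=0)  # (gammas, lambdas)
    best = np.unravel_index(np.nanargmax(mean_c), mean_c.shape)
    # deterministic preference among near-ties is implicit in argmax order;
    # resolve exact ties toward stronger penalty and more penalized blend
    best_val = mean_c[best]
    ties = np.argwhere(mean_c == best_val)
    ties = sorted(ties, key=lambda gl: (-alphas[gl[1]], -gammas[gl[0]]))
    g_best, l_best = int(ties[0][0]), int(ties[0][1])

    final_path = CoxnetSurvivalAnalysis(l1_ratio=l1_ratio, alphas=alphas)
    final_path.fit(Z, y)
    final_alphas = list(final_path.alphas_)
    beta_pen = final_path.coef_[:, final_alphas.index(alphas[l_best])]
    cache = {}
    beta = _blend(beta_pen, None, gammas[g_best], cache, _make_refitter(Z, y))

    coefs = pd.Series(0.0, index=table.columns)
    coefs[usable] = beta
    if (coefs == 0).all():
        warnings.warn("all coefficients zero at the selected grid point: empty classifier", stacklevel=2)

    grid = pd.DataFrame(mean_c, index=list(gammas), columns=alphas)
    grid.index.name = "gamma"
    grid.columns.name = "lambda"
    return MBRModel(
        taxa=list(table.columns),
        coefficients=coefs.to_numpy(),
        standardization=params,
        gamma=float(gammas[g_best]),
        lam=float(alphas[l_best]),
        l1_ratio=float(l1_ratio),
        k_folds=k_folds,
        seed=seed,
        cv_concordance=float(best_val),
        cv_grid=grid,
    )


def score_mbr(model: MBRModel, table: pd.DataFrame) -> pd.DataFrame:
    """MBR scores for new samples, standardized with the training parameters.

    Only classifier genera present in ``table`` contribute; a sample's score
    is independent of every other sample.  Returns columns ``score`` and
    ``risk_group`` ('low' iff score < 0, else 'high').
    """
    classifier = model.classifier
    overlap = [t for t in classifier.index if t in table.columns]
    if not overlap:
        raise ValueError(
            f"no overlap between the table and the classifier genera {list(classifier.index)}"
        )
    sd = model.standardization.sd
    usable = [t for t in overlap if sd[t] > 0]
    dropped = sorted(set(overlap) - set(usable))
    if dropped:
        warnings.warn(f"excluding zero-training-variance genera: {dropped}", stacklevel=2)
    z = (table[usable] - model.standardization.mean[usable]) / sd[usable]
    scores = z.to_numpy(float) @ classifier[usable].to_numpy()
    out = pd.DataFrame({"score": scores}, index=table.index)
    out["risk_group"] = np.where(out["score"] < 0, "low", "high")
    return out


def evaluate_mbr(model: MBRModel, table: pd.DataFrame, survival: pd.DataFrame):
    """Concordance of the MBR score and the high-vs-low hazard contrast.

    Returns ``(concordance, CoxFit or None)``; the contrast is omitted with a
    notice when only one risk group is present.
    """
    survival = check_survival(survival).loc[table.index]
    scored = score_mbr(model, table)
    c = harrell_c(scored["score"], survival)
    groups = (scored["risk_group"] == "high").astype(int).rename("mbr_high")
    if groups.nunique() < 2:
        warnings.warn("only one MBR risk group present; hazard contrast omitted", stacklevel=2)
        return c, None
    contrast = fit_coxph(survival, groups, enforce_min_group=False)
    return c, contrast


_FMT = "%.17g"  # round-trips IEEE doubles exactly


def write_model(model: MBRModel, path) -> None:
    """Serialize a model to the versioned plain-text format (exact round-trip)."""
    with open(path, "w") as fh:
        fh.write("# MBR model format v1\n")
        for key, val in (
            ("gamma", model.gamma),
            ("lambda", model.lam),
            ("l1_ratio", model.l1_ratio),
            ("k_folds", model.k_folds),
            ("seed", model.seed),
            ("cv_concordance", model.cv_concordance),
        ):
            fh.write(f"{key}\t{_FMT % val if isinstance(val, float) else val}\n")
        fh.write("taxon\tcoefficient\ttrain_mean\ttrain_sd\n")
        for taxon, coef in zip(model.taxa, model.coefficients):
            fh.write(
                "\t".join(
                    [
                        str(taxon),
                        _FMT % coef,
                        _FMT % model.standardization.mean[taxon],
                        _FMT % model.standardization.sd[taxon],
                    ]
                )
                + "\n"
            )


def read_model(path) -> MBRModel:
    header: dict = {}
    rows = []
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip()]
    if not lines or not lines[0].startswith("# MBR model format"):
        raise ValueError("not an MBR model file")
    in_table = False
    for line in lines[1:]:
        parts = line.split("\t")
        if parts[0] == "taxon":
            in_table = True
            continue
        if not in_table:
            header[parts[0]] = parts[1]
        else:
            rows.append(parts)
    taxa = [r[0] for r in rows]
    coefs = np.array([float(r[1]) for r in rows])
    mean = pd.Series([float(r[2]) for r in rows], index=taxa)
    sd = pd.Series([float(r[3]) for r in rows], index=taxa)
    return MBRModel(
        taxa=taxa,
        coefficients=coefs,
        standardization=StandardizationParams(mean=mean, sd=sd),
        gamma=float(header["gamma"]),
        lam=float(header["lambda"]),
        l1_ratio=float(header["l1_ratio"]),
        k_folds=int(header["k_folds"]),
        seed=int(header["seed"]),
        cv_concordance=float(header["cv_concordance"]),
    )
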