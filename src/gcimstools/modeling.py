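"""Classification and feature ranking with PLS-DA.

The modeling stage mirrors standard chemometric practice for wide,
collinear data: a deterministic Kennard–Stone split into calibration and
external-validation subsets, autoscaling on calibration statistics, an
advisory robust-PCA outlier screen, a PLS1 discriminant model (class coded
0/1, NIPALS) whose number of latent variables is chosen by bootstrapped
out-of-bag classification rate, VIP scores for feature ranking, and
uncertainty estimates: a Clopper–Pearson interval for the classification
rate, a binormal (per-class Gaussian) interval for the AUC, and a label
permutation test for significance.

VIP scores are the weighted sum of squared PLS weights, weighted by the
Y-block variance captured per latent variable:

    VIP_j = sqrt( p * sum_a SSY_a w_aj^2 / sum_a SSY_a )

with unit-norm weight vectors; the mean of the squared VIPs is exactly 1,
which is why VIP > 1 conventionally marks influential variables.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from scipy.spatial.distance import cdist

__all__ = [
    "SplitPlan", "Scaler", "PLSDAModel", "PerfReport",
    "kennard_stone_split", "autoscale_fit", "autoscale_apply",
    "rpca_outliers", "plsda_fit", "plsda_predict", "select_n_lv_bootstrap",
    "vip_scores", "classification_rate", "auc_with_ci", "permutation_test",
    "vip_concordance", "peak_vip_from_matrix", "peak_vip_from_ric",
    "evaluate_features",
]

logger = logging.getLogger(__name__)


@dataclass
class SplitPlan:
    calibration: np.ndarray
    validation: np.ndarray


def kennard_stone_split(X: np.ndarray, calibration_fraction: float = 0.66
                        ) -> SplitPlan:
    """Deterministic max-min (Kennard–Stone) calibration/validation split.

    Seeds with the two mutually most distant samples, then repeatedly adds
    the sample whose minimum distance to the selected set is largest, until
    ``ceil(fraction * n)`` samples are selected.  Ties break on the lowest
    sample index, making the plan reproducible and permutation-equivariant.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    n = X.shape[0]
    if not 0 < calibration_fraction < 1:
        raise ValueError("calibration_fraction must be in (0, 1)")
    if n < 4:
        raise ValueError("need at least 4 samples to split")
    selected = _maxmin_select(X, int(np.ceil(calibration_fraction * n)))
    return SplitPlan(calibration=np.array(selected),
                     validation=np.array(sorted(set(range(n)) - set(selected))))


def _maxmin_select(X: np.ndarray, n_sel: int) -> list[int]:
    """Kennard–Stone max-min selection order (ties to the lowest index)."""
    n = X.shape[0]
    d = cdist(X, X)
    i, j = np.unravel_index(np.argmax(d), d.shape)
    selected = [min(i, j), max(i, j)]
    remaining = [k for k in range(n) if k not in selected]
    while len(selected) < n_sel and remaining:
        dmin = d[np.ix_(remaining, selected)].min(axis=1)
        selected.append(remaining.pop(int(np.argmax(dmin))))
    return selected[:max(n_sel, 2)]


def kennard_stone_split_stratified(X: np.ndarray, y: np.ndarray,
                                   calibration_fraction: float = 0.66
                                   ) -> SplitPlan:
    """Kennard–Stone applied within each class, then merged.

    Plain max-min selection on strongly clustered two-class data can sweep
    nearly all of the more dispersed class into calibration and leave a
    single-class validation set; stratifying guarantees both subsets
    contain both classes while keeping the selection deterministic.
    """
    y = np.asarray(y)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    cal, val = [], []
    for cls in np.unique(y):
        idx = np.flatnonzero(y == cls)
        if idx.size < 2:
            raise ValueError(f"class {cls} has fewer than 2 samples")
        # keep at least one validation sample per class
        n_cal = min(int(np.ceil(calibration_fraction * idx.size)),
                    idx.size - 1)
        sel = _maxmin_select(X[idx], max(n_cal, 1))
        cal.extend(idx[sel])
        val.extend(np.delete(idx, sel))
    return SplitPlan(calibration=np.array(sorted(cal)),
                     validation=np.array(sorted(val)))


@dataclass
class Scaler:
    mean: np.ndarray
    sd: np.ndarray
    zero_sd: np.ndarray  # flagged constant features


def autoscale_fit(Xcal: np.ndarray) -> Scaler:
    """Column mean/SD from calibration data; constant columns are flagged."""
    Xcal = np.atleast_2d(np.asarray(Xcal, dtype=float))
    if Xcal.shape[0] < 2:
        raise ValueError("need at least 2 calibration samples")
    mean = Xcal.mean(axis=0)
    sd = Xcal.std(axis=0, ddof=1)
    zero = sd <= 0
    sd = np.where(zero, 1.0, sd)
    return Scaler(mean=mean, sd=sd, zero_sd=zero)


def autoscale_apply(scaler: Scaler, X: np.ndarray) -> np.ndarray:
    """Autoscale with calibration statistics; constant features map to 0."""
    Xs = (np.atleast_2d(np.asarray(X, dtype=float)) - scaler.mean) / scaler.sd
    Xs[:, scaler.zero_sd] = 0.0
    return Xs


def rpca_outliers(X: np.ndarray, n_components: int = 2,
                  cutoff_quantile: float = 0.975) -> np.ndarray:
    """Advisory robust-PCA outlier screen.

    Columns are robustly standardized (median, scaled MAD); PCA via SVD;
    samples are flagged when their score distance exceeds the chi-square
    cutoff or their orthogonal distance exceeds a normal-approximation
    cutoff on OD^(2/3).  Flagged samples are reported, never removed.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    n, p = X.shape
    if n < 5:
        raise ValueError("need at least 5 samples")
    med = np.median(X, axis=0)
    mad = np.median(np.abs(X - med), axis=0) * 1.4826
    mad = np.where(mad <= 0, 1.0, mad)
    Z = (X - med) / mad
    k = min(n_components, n - 1, p)
    U, S, Vt = np.linalg.svd(Z - Z.mean(axis=0), full_matrices=False)
    scores = U[:, :k] * S[:k]
    scale = np.median(np.abs(scores - np.median(scores, axis=0)), axis=0) * 1.4826
    scale = np.where(scale <= 0, 1.0, scale)
    sd = np.sqrt(((scores / scale) ** 2).sum(axis=1))
    sd_cut = np.sqrt(stats.chi2.ppf(cutoff_quantile, df=k))
    resid = Z - Z.mean(axis=0) - scores @ Vt[:k]
    od2 = np.einsum("ij,ij->i", resid, resid)
    df = max(p - k, 1)
    # robust residual scale from the median of OD^2 ~ sigma^2 chi2_df
    sigma2 = np.median(od2) / stats.chi2.ppf(0.5, df)
    od_cut2 = sigma2 * stats.chi2.ppf(cutoff_quantile, df)
    return np.flatnonzero((sd > sd_cut) | (od2 > od_cut2))


@dataclass
class PLSDAModel:
    """Fitted PLS1 discriminant model (class coded 0/1)."""
    weights: np.ndarray     # (p, A), unit-norm columns
    x_loadings: np.ndarray  # (p, A)
    y_loadings: np.ndarray  # (A,)
    coef: np.ndarray        # (p,) regression vector on autoscaled X
    y_mean: float
    n_components: int
    ssy: np.ndarray         # (A,) Y-variance captured per component
    scaler: Scaler | None = None


def plsda_fit(X: np.ndarray, y: np.ndarray, n_components: int) -> PLSDAModel:
    """NIPALS PLS1 on autoscaled X against the centered 0/1 class code.

    Deflates X per component; if the requested complexity exceeds the data
    rank the model is truncated with a warning.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float)
    if set(np.unique(y)) - {0.0, 1.0}:
        raise ValueError("labels must be coded 0/1")
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present")
    n, p = X.shape
    y_mean = float(y.mean())
    Xa = X.copy()
    yc = y - y_mean
    W, P, q, ssy = [], [], [], []
    for _ in range(n_components):
        w = Xa.T @ yc
        nw = np.linalg.norm(w)
        if nw < 1e-12 * max(1.0, np.abs(Xa).max()):
            warnings.warn(
                f"rank exhausted: truncating at {len(W)} components",
                stacklevel=2)
            break
        w /= nw
        t = Xa @ w
        tt = float(t @ t)
        if tt < 1e-300:
            break
        pl = Xa.T @ t / tt
        qa = float(yc @ t / tt)
        Xa = Xa - np.outer(t, pl)
        yc = yc - qa * t
        W.append(w)
        P.append(pl)
        q.append(qa)
        ssy.append(qa * qa * tt)
    if not W:
        raise ValueError("could not extract any latent variable")
    W = np.column_stack(W)
    P = np.column_stack(P)
    q = np.array(q)
    ssy = np.array(ssy)
    coef = W @ np.linalg.solve(P.T @ W, q)
    return PLSDAModel(weights=W, x_loadings=P, y_loadings=q, coef=coef,
                      y_mean=y_mean, n_components=W.shape[1], ssy=ssy)


def plsda_predict(model: PLSDAModel, X: np.ndarray,
                  threshold: float = 0.5) -> tuple[np.ndarray, np.ndarray]:
    """Continuous scores and 0/1 class calls (threshold on the 0/1 code)."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] != model.coef.size:
        raise ValueError(
            f"feature count {X.shape[1]} != model {model.coef.size}")
    scores = model.y_mean + X @ model.coef
    return scores, (scores >= threshold).astype(int)


def _coef_for_truncation(model: PLSDAModel, a: int) -> np.ndarray:
    W, P, q = model.weights[:, :a], model.x_loadings[:, :a], model.y_loadings[:a]
    return W @ np.linalg.solve(P.T @ W, q)


def select_n_lv_bootstrap(X: np.ndarray, y: np.ndarray, max_lv: int = 10,
                          n_boot: int = 200, seed=None) -> int:
    """Choose the number of latent variables by bootstrapped out-of-bag
    classification rate; ties go to the simpler model.

    Each resample is drawn with replacement from the calibration rows
    (redrawn, with a log note, if a class is missing or no row is left out
    of bag); one model at maximal complexity is fitted per resample and
    evaluated at every truncation.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float)
    n = X.shape[0]
    max_lv = max(1, min(max_lv, n - 2, X.shape[1]))
    rng = np.random.default_rng(seed)
    cr_sums = np.zeros(max_lv)
    counts = np.zeros(max_lv)
    redraws = 0
    for _ in range(n_boot):
        for _attempt in range(100):
            idx = rng.integers(0, n, size=n)
            oob = np.setdiff1d(np.arange(n), idx)
            if oob.size and len(np.unique(y[idx])) == 2:
                break
            redraws += 1
        else:
            continue
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = plsda_fit(X[idx], y[idx], max_lv)
        for a in range(1, model.n_components + 1):
            coef = _coef_for_truncation(model, a)
            pred = (model.y_mean + X[oob] @ coef) >= 0.5
            cr_sums[a - 1] += float(np.mean(pred == (y[oob] == 1)))
            counts[a - 1] += 1
    if redraws:
        logger.info("bootstrap LV selection redrew %d degenerate resamples",
                    redraws)
    mean_cr = np.where(counts > 0, cr_sums / np.maximum(counts, 1), -np.inf)
    # argmax returns the first (fewest-LV) maximizer
    return int(np.argmax(np.round(mean_cr, 12))) + 1


def vip_scores(model: PLSDAModel) -> np.ndarray:
    """Variable importance in projection; mean of squared scores is 1."""
    w2 = model.weights ** 2
    ssy = model.ssy
    p = model.weights.shape[0]
    return np.sqrt(p * (w2 @ ssy) / ssy.sum())


def classification_rate(calls: np.ndarray, truth: np.ndarray,
                        alpha: float = 0.05) -> tuple[float, tuple[float, float]]:
    """Proportion correct with an exact Clopper–Pearson interval."""
    calls = np.asarray(calls).astype(int)
    truth = np.asarray(truth).astype(int)
    if calls.size == 0 or calls.shape != truth.shape:
        raise ValueError("calls and truth must be nonempty and congruent")
    n = calls.size
    k = int(np.sum(calls == truth))
    cr = k / n
    lo = 0.0 if k == 0 else float(stats.beta.ppf(alpha / 2, k, n - k + 1))
    hi = 1.0 if k == n else float(stats.beta.ppf(1 - alpha / 2, k + 1, n - k))
    return cr, (lo, hi)


def auc_with_ci(scores: np.ndarray, truth: np.ndarray, alpha: float = 0.05
                ) -> tuple[float, tuple[float, float]]:
    """Empirical (Mann–Whitney) AUC with a binormal confidence interval.

    The interval assumes Gaussian per-class score distributions: with
    separation ``d = (mu1 - mu0) / sqrt(s0^2 + s1^2)`` the binormal AUC is
    ``Phi(d)``; a delta-method standard error on ``d`` is propagated
    through ``Phi`` and the interval clipped to [0, 1].
    """
    scores = np.asarray(scores, dtype=float)
    truth = np.asarray(truth).astype(int)
    s0, s1 = scores[truth == 0], scores[truth == 1]
    if s0.size == 0 or s1.size == 0:
        raise ValueError("both classes must be present")
    # empirical AUC = normalized Mann-Whitney U
    auc = (np.sum(s1[:, None] > s0[None, :])
           + 0.5 * np.sum(s1[:, None] == s0[None, :])) / (s0.size * s1.size)
    m0, m1 = s0.mean(), s1.mean()
    v0 = s0.var(ddof=1) if s0.size > 1 else 0.0
    v1 = s1.var(ddof=1) if s1.size > 1 else 0.0
    ssum = v0 + v1
    if ssum <= 0:
        return float(auc), (float(auc), float(auc))
    d = (m1 - m0) / np.sqrt(ssum)
    var_delta = v0 / s0.size + v1 / s1.size
    var_ssum = (2 * v0 ** 2 / max(s0.size - 1, 1)
                + 2 * v1 ** 2 / max(s1.size - 1, 1))
    var_d = var_delta / ssum + (m1 - m0) ** 2 * var_ssum / (4 * ssum ** 3)
    z = stats.norm.ppf(1 - alpha / 2)
    se = np.sqrt(max(var_d, 0.0))
    lo, hi = stats.norm.cdf(d - z * se), stats.norm.cdf(d + z * se)
    return float(auc), (float(np.clip(lo, 0, 1)), float(np.clip(hi, 0, 1)))


def binormal_auc(mu0: float, mu1: float, sd0: float, sd1: float) -> float:
    """Closed-form binormal AUC, Phi((mu1-mu0)/sqrt(sd0^2+sd1^2))."""
    return float(stats.norm.cdf((mu1 - mu0) / np.hypot(sd0, sd1)))


def permutation_test(pipeline, X: np.ndarray, y: np.ndarray,
                     n_perm: int = 1000, seed=None) -> float:
    """Label-permutation significance of the observed classification rate.

    ``pipeline(X, y) -> CR`` is any callable running the modeling chain and
    returning the statistic; the p-value is
    ``(1 + #{perm CR >= observed}) / (n_perm + 1)``.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    y = np.asarray(y)
    rng = np.random.default_rng(seed)
    observed = pipeline(X, y)
    count = 0
    for _ in range(n_perm):
        count += pipeline(X, rng.permutation(y)) >= observed - 1e-12
    return (1 + count) / (n_perm + 1)


def vip_concordance(vip_a: np.ndarray, vip_b: np.ndarray,
                    threshold: float = 1.0) -> float:
    """Fraction of features whose binary importance (VIP > threshold)
    agrees between two per-peak VIP vectors."""
    a = np.asarray(vip_a, dtype=float)
    b = np.asarray(vip_b, dtype=float)
    if a.shape != b.shape or a.size == 0:
        raise ValueError("VIP vectors must be nonempty and congruent")
    return float(np.mean((a > threshold) == (b > threshold)))


def peak_vip_from_matrix(vip_flat: np.ndarray, shape: tuple[int, int],
                         tr_indices, td_indices,
                         window: tuple[int, int] = (5, 10)) -> np.ndarray:
    """Map a full-matrix VIP vector to peaks: maximum VIP within the
    assignment window around each peak's representative cell."""
    vip2d = np.asarray(vip_flat, dtype=float).reshape(shape)
    wtr, wtd = window
    out = np.empty(len(tr_indices))
    for i, (r, d) in enumerate(zip(tr_indices, td_indices)):
        r0, r1 = max(0, r - wtr), min(shape[0], r + wtr + 1)
        d0, d1 = max(0, d - wtd), min(shape[1], d + wtd + 1)
        if r0 >= r1 or d0 >= d1:
            raise ValueError(f"peak ({r}, {d}) outside the matrix grid")
        out[i] = vip2d[r0:r1, d0:d1].max()
    return out


def peak_vip_from_ric(vip_ric: np.ndarray, tr_indices) -> np.ndarray:
    """Map a RIC VIP vector to peaks: the VIP at each peak's retention
    index.  Where several ions co-elute, the RIC point is attributed to the
    highest-intensity ion; co-eluting minor ions inherit the same value."""
    vip_ric = np.asarray(vip_ric, dtype=float)
    tr = np.asarray(tr_indices, dtype=int)
    if np.any((tr < 0) | (tr >= vip_ric.size)):
        raise ValueError("peak retention index outside the RIC")
    return vip_ric[tr]


@dataclass
class PerfReport:
    """External-validation performance of one feature-extraction method."""
    cr: float
    cr_ci: tuple[float, float]
    auc: float
    auc_ci: tuple[float, float]
    n_components: int
    permutation_p: float | None = None
    n_validation: int = 0
    outlier_flags: list = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "cr": self.cr, "cr_ci": list(self.cr_ci),
            "auc": self.auc, "auc_ci": list(self.auc_ci),
            "n_components": self.n_components,
            "permutation_p": self.permutation_p,
            "n_validation": self.n_validation,
            "outlier_flags": [int(i) for i in self.outlier_flags],
        }


def evaluate_features(X: np.ndarray, y: np.ndarray,
                      calibration_fraction: float = 0.66,
                      max_lv: int = 10, n_boot: int = 200,
                      n_perm: int = 0, reselect_lv: bool = False,
                      stratify: bool = True,
                      seed=None) -> tuple[PerfReport, np.ndarray, PLSDAModel]:
    """Full modeling chain for one feature matrix.

    Kennard–Stone split → autoscale on calibration → bootstrap LV choice →
    PLS-DA fit → external-validation CR/AUC with intervals → optional
    permutation test (split fixed, labels permuted before splitting;
    ``reselect_lv`` reruns the LV selection inside each permutation).
    Returns the report, the VIP vector and the fitted model (with its
    scaler attached).
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y).astype(int)
    ss = np.random.SeedSequence(seed) if not isinstance(seed, np.random.SeedSequence) else seed
    s_lv, s_perm = ss.spawn(2)
    plan = (kennard_stone_split_stratified(X, y, calibration_fraction)
            if stratify else kennard_stone_split(X, calibration_fraction))
    cal, val = plan.calibration, plan.validation
    scaler = autoscale_fit(X[cal])
    Xc = autoscale_apply(scaler, X[cal])
    Xv = autoscale_apply(scaler, X[val])
    try:
        outliers = rpca_outliers(Xc)
    except ValueError:
        outliers = np.array([], dtype=int)
    n_lv = (select_n_lv_bootstrap(Xc, y[cal], max_lv=max_lv, n_boot=n_boot,
                                  seed=s_lv)
            if max_lv > 1 else 1)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = plsda_fit(Xc, y[cal], n_lv)
    model.scaler = scaler
    scores, calls = plsda_predict(model, Xv)
    cr, cr_ci = classification_rate(calls, y[val])
    auc, auc_ci = auc_with_ci(scores, y[val])
    vip = vip_scores(model)

    p_value = None
    if n_perm > 0:
        def stat(_X, y_perm):
            yp = np.asarray(y_perm).astype(int)
            sc = autoscale_fit(_X[cal])
            Xc_p = autoscale_apply(sc, _X[cal])
            if len(np.unique(yp[cal])) < 2:
                return 0.0
            if reselect_lv:
                a = select_n_lv_bootstrap(Xc_p, yp[cal], max_lv=max_lv,
                                          n_boot=n_boot, seed=s_lv)
            else:
                a = n_lv
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                mod = plsda_fit(Xc_p, yp[cal], a)
            _, prd = plsda_predict(mod, autoscale_apply(sc, _X[val]))
            return float(np.mean(prd == yp[val]))
        p_value = permutation_test(stat, X, y, n_perm=n_perm,
                                   seed=np.random.default_rng(s_perm))

    report = PerfReport(cr=cr, cr_ci=cr_ci, auc=auc, auc_ci=auc_ci,
                        n_components=model.n_components,
                        permutation_p=p_value, n_validation=val.size,
                        outlier_flags=list(outliers))
    return report, vip, model
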