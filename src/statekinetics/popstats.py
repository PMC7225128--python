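"""Population-level statistics for the transcriptome analyses.

Differential expression uses the two-sided Wilcoxon rank-sum test on
log-normalized expression with pre-test filters (absolute log
fold-change >= 0.15, expressed in >= 10% of cells) and Bonferroni
correction over the genes actually tested. Per-gene AUROC equals the
rank-sum U statistic normalized by n1*n2. Overdispersion uses the
difference-from-the-median (DM) of log10 CV^2, and the
population-divergence estimate is a classifier-based density-ratio KL.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold


def rank_sum_de(
    expr_a: np.ndarray,
    expr_b: np.ndarray,
    gene_ids: list[str] | None = None,
    min_lfc: float = 0.15,
    min_frac: float = 0.10,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Wilcoxon rank-sum differential expression with pre-test filters.

    ``expr_a``/``expr_b`` are genes x cells log-normalized expression
    for the two populations (>= 3 cells each). Genes with
    |mean log difference| < ``min_lfc`` or expressed (value > 0) in
    fewer than ``min_frac`` of cells in both groups are filtered before
    testing; Bonferroni multiplies by the number of genes tested.
    """
    A = np.atleast_2d(np.asarray(expr_a, dtype=float))
    B = np.atleast_2d(np.asarray(expr_b, dtype=float))
    if A.shape[0] != B.shape[0]:
        raise ValueError("groups must share the gene axis")
    if A.shape[1] < 3 or B.shape[1] < 3:
        raise ValueError("each group needs >= 3 cells")
    genes = gene_ids if gene_ids is not None else [f"g{i}" for i in range(A.shape[0])]

    lfc = A.mean(axis=1) - B.mean(axis=1)
    frac_a = (A > 0).mean(axis=1)
    frac_b = (B > 0).mean(axis=1)
    pass_lfc = np.abs(lfc) >= min_lfc
    pass_frac = np.maximum(frac_a, frac_b) >= min_frac
    tested = pass_lfc & pass_frac
    m = int(tested.sum())

    pvals = np.full(A.shape[0], np.nan)
    statv = np.full(A.shape[0], np.nan)
    flags = np.zeros(A.shape[0], dtype=bool)
    for g in np.flatnonzero(tested):
        a, b = A[g], B[g]
        if np.ptp(a) == 0 and np.ptp(b) == 0 and a[0] == b[0]:
            pvals[g], statv[g], flags[g] = 1.0, np.nan, True
            continue
        res = stats.mannwhitneyu(a, b, alternative="two-sided", method="auto")
        statv[g], pvals[g] = res.statistic, res.pvalue
    adj = np.minimum(pvals * m, 1.0)
    return pd.DataFrame(
        {
            "gene_id": genes,
            "statistic": statv,
            "p": pvals,
            "p_bonferroni": adj,
            "log_fold_change": lfc,
            "frac_expressing_a": frac_a,
            "frac_expressing_b": frac_b,
            "pass_lfc_filter": pass_lfc,
            "pass_frac_filter": pass_frac,
            "tested": tested,
            "constant_flag": flags,
            "significant": tested & (adj < alpha),
        }
    )


def gene_auroc(expr_g: np.ndarray, labels: np.ndarray) -> float:
    """AUROC of a single-gene threshold classifier.

    Computed from rank sums: AUROC = U / (n1 * n2) with ties counted
    0.5, where U is the Mann-Whitney statistic of the positive class.
    """
    x = np.asarray(expr_g, dtype=float)
    y = np.asarray(labels).astype(bool)
    n1, n0 = int(y.sum()), int((~y).sum())
    if n1 == 0 or n0 == 0:
        raise ValueError("both classes must be present")
    ranks = stats.rankdata(x)
    u = ranks[y].sum() - n1 * (n1 + 1) / 2.0
    return float(u / (n1 * n0))


def dm_overdispersion(
    expr: np.ndarray,
    gene_ids: list[str] | None = None,
    mean_min: float = 0.1,
    window: int = 50,
) -> pd.DataFrame:
    """Difference-from-the-median overdispersion scores.

    Genes with mean expression below ``mean_min`` are excluded (NaN).
    Passing genes are ordered by log10 mean; DM = log10 CV^2 minus the
    running median of log10 CV^2 over ``window`` genes at comparable
    mean (window shrinks at the ends).
    """
    X = np.atleast_2d(np.asarray(expr, dtype=float))
    genes = gene_ids if gene_ids is not None else [f"g{i}" for i in range(X.shape[0])]
    mean = X.mean(axis=1)
    var = X.var(axis=1, ddof=1)
    keep = mean >= mean_min
    if keep.sum() < window:
        raise ValueError(
            f"window={window} exceeds the {int(keep.sum())} genes passing the mean filter"
        )
    dm = np.full(X.shape[0], np.nan)
    with np.errstate(invalid="ignore", divide="ignore"):
        log_cv2 = np.log10(var / mean**2)
    idx = np.flatnonzero(keep)
    order = idx[np.argsort(np.log10(mean[idx]), kind="stable")]
    vals = log_cv2[order]
    half = window // 2
    n = len(order)
    for i in range(n):
        lo = max(0, i - half)
        hi = min(n, i + half + 1)
        dm[order[i]] = vals[i] - np.median(vals[lo:hi])
    return pd.DataFrame(
        {"gene_id": genes, "mean": mean, "cv2": var / np.maximum(mean, 1e-300) ** 2,
         "dm": dm, "filtered": ~keep}
    )


@dataclass
class DivergenceEstimate:
    kl: float
    accuracy: float
    n_a: int
    n_b: int
    seed: int

    def to_dict(self) -> dict:
        return dict(self.__dict__)


def kl_divergence(
    xa: np.ndarray,
    xb: np.ndarray,
    n_folds: int = 2,
    clip: float = 1e-6,
    seed: int = 0,
    classifier: str = "logistic",
) -> DivergenceEstimate:
    """Classifier-based density-ratio estimate of KL(A || B) in nats.

    A probabilistic classifier is cross-fitted to discriminate samples
    of A from B; the density ratio at x is
    r(x) = [p(A|x) / (1 - p(A|x))] * (n_B / n_A) with probabilities
    clipped to [clip, 1-clip], and KL(A||B) is the mean of log r over
    held-out A points.
    """
    XA = np.atleast_2d(np.asarray(xa, dtype=float))
    XB = np.atleast_2d(np.asarray(xb, dtype=float))
    if XA.ndim == 2 and XA.shape[0] == 1 and XA.size > 1:
        XA = XA.T
    if XB.ndim == 2 and XB.shape[0] == 1 and XB.size > 1:
        XB = XB.T
    n_a, n_b = len(XA), len(XB)
    if n_a < 50 or n_b < 50:
        raise ValueError("each sample needs >= 50 points")
    X = np.vstack([XA, XB])
    keep = X.std(axis=0) > 0
    if not keep.all():
        warnings.warn("dropping degenerate constant features")
        X = X[:, keep]
    y = np.concatenate([np.ones(n_a), np.zeros(n_b)])

    if classifier == "logistic":
        def make_clf():
            return LogisticRegression(max_iter=1000)
    elif classifier == "gbm":
        from sklearn.ensemble import HistGradientBoostingClassifier

        def make_clf():
            return HistGradientBoostingClassifier(random_state=seed)
    else:
        raise ValueError(f"unknown classifier {classifier!r}")

    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    log_r = np.empty(0)
    correct = 0
    for train, test in skf.split(X, y):
        clf = make_clf()
        clf.fit(X[train], y[train])
        p = np.clip(clf.predict_proba(X[test])[:, 1], clip, 1.0 - clip)
        n_a_tr = y[train].sum()
        n_b_tr = len(train) - n_a_tr
        r = p / (1.0 - p) * (n_b_tr / n_a_tr)
        held_a = y[test] == 1
        log_r = np.concatenate([log_r, np.log(r[held_a])])
        correct += ((p > 0.5) == y[test].astype(bool)).sum()
    return DivergenceEstimate(
        kl=float(log_r.mean()),
        accuracy=float(correct / len(y)),
        n_a=n_a,
        n_b=n_b,
        seed=seed,
    )


def incorporation_wald(
    outcome: np.ndarray | tuple,
    group: np.ndarray | None = None,
) -> dict:
    """Logistic regression Wald test for a binary incorporation outcome.

    Accepts either per-cell arrays (outcome, group) or a tuple
    ((successes_a, total_a), (successes_b, total_b)). Returns the odds
    ratio for group membership, the Wald z and its two-sided p. Perfect
    separation is flagged and the odds ratio then comes from an
    L2-penalized fit with p reported as NaN.
    """
    import statsmodels.api as sm

    if group is None:
        (sa, ta), (sb, tb) = outcome  # counts-by-group form
        y = np.concatenate(
            [np.ones(sa), np.zeros(ta - sa), np.ones(sb), np.zeros(tb - sb)]
        )
        g = np.concatenate([np.ones(ta), np.zeros(tb)])
    else:
        y = np.asarray(outcome, dtype=float)
        g = pd.get_dummies(pd.Series(np.asarray(group)), drop_first=True).to_numpy(
            float
        )[:, 0]
    if np.ptp(y) == 0:
        raise ValueError("outcome has no variation")
    X = sm.add_constant(g)
    rates = [y[g == v].mean() for v in np.unique(g)]
    separated = any(r in (0.0, 1.0) for r in rates)
    if not separated:
        fit = sm.Logit(y, X).fit(disp=0)
        coef = float(fit.params[1])
        return {
            "odds_ratio": float(np.exp(coef)),
            "coef": coef,
            "wald_z": float(fit.tvalues[1]),
            "p": float(fit.pvalues[1]),
            "separation": False,
        }
    warnings.warn("perfect separation detected; using penalized fallback")
    clf = LogisticRegression(C=1.0, max_iter=1000)
    clf.fit(g.reshape(-1, 1), y)
    coef = float(clf.coef_[0, 0])
    return {
        "odds_ratio": float(np.exp(coef)),
        "coef": coef,
        "wald_z": float("nan"),
        "p": float("nan"),
        "separation": True,
    }
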