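"""Cell-behavior feature extraction, state clustering and transition statistics.

Features are computed per track inside a fixed analysis window
(default 10-35 h of recording). Behavior states are found by Ward
hierarchical clustering of z-scored features; a group's state-transition
magnitude is the Euclidean norm of its mean displacement vector in a
common behavior PCA between the earlier and later halves of the window.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage

logger = logging.getLogger(__name__)

FEATURE_NAMES = [
    "total_distance",
    "net_distance",
    "net_total_ratio",
    "mean_speed",
    "max_speed",
    "min_speed",
    "linearity",
    "progressivity",
    "mean_turn_angle_cos",
    "time_moving_fraction",
]


def _track_features(
    pos: np.ndarray, frame_interval: float, move_threshold: float
) -> dict[str, float]:
    """Feature vector for one track (n_frames x 2, um)."""
    steps = np.diff(pos, axis=0)
    step_len = np.linalg.norm(steps, axis=1)
    total = float(step_len.sum())
    net = float(np.linalg.norm(pos[-1] - pos[0]))
    speeds = step_len / frame_interval  # um/min
    x, y = pos[:, 0], pos[:, 1]
    vx, vy = x.var(), y.var()
    if vx > 0 and vy > 0:
        linearity = float(np.corrcoef(x, y)[0, 1] ** 2)
    elif total > 0:
        linearity = 1.0  # axis-aligned straight line
    else:
        linearity = 0.0
    dist_from_origin = np.linalg.norm(pos - pos[0], axis=1)
    if np.ptp(dist_from_origin) > 0:
        progressivity = float(
            stats.spearmanr(np.arange(len(pos)), dist_from_origin).statistic
        )
    else:
        progressivity = 0.0
    moving = step_len > 0
    if moving[:-1].sum() and (moving[:-1] & moving[1:]).any():
        both = moving[:-1] & moving[1:]
        a, b = steps[:-1][both], steps[1:][both]
        cosines = (a * b).sum(axis=1) / (
            np.linalg.norm(a, axis=1) * np.linalg.norm(b, axis=1)
        )
        mean_cos = float(cosines.mean())
    else:
        mean_cos = 0.0
    return {
        "total_distance": total,
        "net_distance": net,
        "net_total_ratio": net / total if total > 0 else 0.0,
        "mean_speed": float(speeds.mean()),
        "max_speed": float(speeds.max()),
        "min_speed": float(speeds.min()),
        "linearity": linearity,
        "progressivity": progressivity,
        "mean_turn_angle_cos": mean_cos,
        "time_moving_fraction": float((step_len > move_threshold).mean()),
    }


def extract_features(
    tracks,
    move_threshold: float = 0.5,
    window: Optional[tuple[float, float]] = None,
    n_subwindows: int = 1,
) -> pd.DataFrame:
    """Behavior features per cell (and per sub-window when requested).

    ``move_threshold`` is in um/frame. With ``n_subwindows`` > 1 the
    analysis window is split into equal spans and a feature vector is
    returned per (cell, sub-window); the result carries a ``subwindow``
    column. Tracks too short for the window raise per-cell log entries
    and are excluded.
    """
    pos_all = tracks.window_slice(window)
    n_frames = pos_all.shape[1]
    if n_frames < 3 * n_subwindows:
        raise ValueError("window too short for the requested sub-windows")
    bounds = np.linspace(0, n_frames, n_subwindows + 1).astype(int)
    rows = []
    for ci in range(pos_all.shape[0]):
        for wi in range(n_subwindows):
            seg = pos_all[ci, bounds[wi] : bounds[wi + 1]]
            if len(seg) < 3:
                logger.warning("cell %s: segment too short, excluded", ci)
                continue
            feats = _track_features(seg, tracks.frame_interval, move_threshold)
            feats["cell_index"] = ci
            feats["cell_id"] = tracks.cell_ids[ci]
            feats["subwindow"] = wi
            rows.append(feats)
    df = pd.DataFrame(rows)
    return df[["cell_id", "cell_index", "subwindow"] + FEATURE_NAMES]


def zscore_features(features: pd.DataFrame) -> pd.DataFrame:
    """Center each feature to mean 0 and scale to variance 1 over the
    population; constant features are left at 0."""
    X = features[FEATURE_NAMES]
    sd = X.std(ddof=0)
    sd = sd.where(sd > 0, 1.0)
    out = features.copy()
    out[FEATURE_NAMES] = (X - X.mean()) / sd
    return out


def cluster_behavior(
    features: pd.DataFrame, k: int = 3
) -> tuple[np.ndarray, np.ndarray]:
    """Ward-linkage hierarchical clustering of z-scored features cut at k.

    Labels (1..k) are ordered by ascending cluster-mean mean_speed, so
    cluster 1 is the least motile state. Returns (labels, linkage matrix).
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    if len(features) < k:
        raise ValueError("need at least k cells")
    Z = zscore_features(features)[FEATURE_NAMES].to_numpy()
    link = linkage(Z, method="ward", metric="euclidean")
    raw = fcluster(link, t=k, criterion="maxclust")
    speed = features["mean_speed"].to_numpy()
    order = np.argsort(
        [speed[raw == c].mean() for c in np.unique(raw)], kind="stable"
    )
    relabel = {int(np.unique(raw)[old]): new + 1 for new, old in enumerate(order)}
    return np.array([relabel[c] for c in raw]), link


@dataclass
class BehaviorStateSpace:
    """Z-scored features, their PCA, cluster labels, and per-cell
    transition vectors (later-half coordinates minus earlier-half)."""

    features: pd.DataFrame  # per (cell, subwindow) raw features
    zscored: pd.DataFrame
    pca_coords: np.ndarray  # rows aligned with `features`
    labels: Optional[np.ndarray]  # per cell, from full-window clustering
    transitions: np.ndarray  # n_cells x d


def build_state_space(
    tracks,
    k: int = 3,
    d: int = 2,
    move_threshold: float = 0.5,
    window: Optional[tuple[float, float]] = None,
) -> BehaviorStateSpace:
    """Full-window clustering plus half-window transition vectors.

    Features from the two window halves are z-scored and embedded in one
    common PCA (dimension ``d``); each cell's transition vector is its
    later-half position minus its earlier-half position in that space.
    """
    full = extract_features(tracks, move_threshold, window, n_subwindows=1)
    labels, _ = cluster_behavior(full, k=k) if len(full) >= k else (None, None)
    halves = extract_features(tracks, move_threshold, window, n_subwindows=2)
    z = zscore_features(halves)
    X = z[FEATURE_NAMES].to_numpy()
    Xc = X - X.mean(axis=0)
    _, _, Vt = np.linalg.svd(Xc, full_matrices=False)
    load = Vt[:d].T
    for j in range(d):
        i_max = np.argmax(np.abs(load[:, j]))
        if load[i_max, j] < 0:
            load[:, j] = -load[:, j]
    coords = Xc @ load
    early = coords[z["subwindow"].to_numpy() == 0]
    late = coords[z["subwindow"].to_numpy() == 1]
    if len(early) == 0 or len(late) == 0:
        raise ValueError("transitions undefined: need two sub-windows")
    transitions = late - early
    return BehaviorStateSpace(halves, z, coords, labels, transitions)


def transition_magnitude(
    transitions: np.ndarray,
    group_mask: Optional[np.ndarray] = None,
    n_boot: int = 1000,
    ci: float = 0.95,
    seed: int = 0,
) -> dict:
    """Euclidean norm of the group's mean transition vector, with a
    percentile bootstrap confidence interval."""
    vecs = np.asarray(transitions, dtype=float)
    if group_mask is not None:
        vecs = vecs[np.asarray(group_mask, dtype=bool)]
    if vecs.ndim != 2 or len(vecs) < 2:
        raise ValueError("need >= 2 cells with transition vectors")
    mag = float(np.linalg.norm(vecs.mean(axis=0)))
    rng = np.random.default_rng(seed)
    n = len(vecs)
    boots = np.empty(n_boot)
    for b in range(n_boot):
        idx = rng.integers(0, n, n)
        boots[b] = np.linalg.norm(vecs[idx].mean(axis=0))
    alpha = (1.0 - ci) / 2.0
    lo, hi = np.quantile(boots, [alpha, 1.0 - alpha])
    return {"magnitude": mag, "ci_low": float(lo), "ci_high": float(hi), "n": n}


def state_preference_test(
    labels: np.ndarray,
    age: np.ndarray,
    covariate: Optional[np.ndarray] = None,
) -> dict:
    """Age x behavior-cluster preference statistics.

    A chi-square test (no continuity correction) on the age x cluster
    contingency table; when expected counts hit zero a Fisher exact test
    on the 2x2 collapse (cluster 1 vs rest) is used and flagged. With a
    covariate (e.g. LRC status), a logistic regression of cluster-1
    membership on age + covariate adds a Wald p for the age term.
    """
    labels = np.asarray(labels)
    age = np.asarray(age)
    if len(labels) != len(age):
        raise ValueError("labels and age must align")
    table = pd.crosstab(age, labels)
    if (table.to_numpy().sum(axis=1) == 0).any():
        raise ValueError("every age group needs at least one cell")
    expected = stats.contingency.expected_freq(table.to_numpy())
    out: dict = {"table": table}
    if (expected == 0).any():
        in_c1 = labels == np.min(labels)
        t22 = pd.crosstab(age, in_c1).to_numpy()
        _, p = stats.fisher_exact(t22)
        out.update(chi2=float("nan"), p=float(p), df=None, exact_fallback=True)
    else:
        chi2, p, dof, _ = stats.chi2_contingency(table, correction=False)
        out.update(chi2=float(chi2), p=float(p), df=int(dof), exact_fallback=False)
    if covariate is not None:
        import statsmodels.api as sm

        y = (labels == np.min(labels)).astype(float)
        ages = pd.get_dummies(pd.Series(age), drop_first=True).to_numpy(float)
        covs = pd.get_dummies(pd.Series(np.asarray(covariate)), drop_first=True).to_numpy(float)
        X = sm.add_constant(np.hstack([ages, covs]))
        fit = sm.Logit(y, X).fit(disp=0)
        out["age_coef"] = float(fit.params[1])
        out["age_p"] = float(fit.pvalues[1])
    return out


def feature_age_comparison(
    features: pd.DataFrame, age: np.ndarray
) -> pd.DataFrame:
    """Per-feature two-tailed t-tests between ages with Holm-Bonferroni
    correction."""
    from statsmodels.stats.multitest import multipletests

    age = np.asarray(age)
    groups = np.unique(age)
    if len(groups) != 2:
        raise ValueError("expected exactly two age groups")
    rows = []
    for f in FEATURE_NAMES:
        a = features.loc[age == groups[0], f]
        b = features.loc[age == groups[1], f]
        t, p = stats.ttest_ind(a, b)
        rows.append({"feature": f, "t": float(t), "p": float(p),
                     "mean_diff": float(a.mean() - b.mean())})
    df = pd.DataFrame(rows)
    df["p_holm"] = multipletests(df["p"], method="holm")[1]
    return df
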