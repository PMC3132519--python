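"""Minimum-Redundancy Maximum-Relevance feature ranking.

Ranks the 33 features by greedy forward selection: the first pick maximises
mutual information (MI) with the class label; each subsequent pick maximises
relevance minus mean redundancy with the already-selected set (the MID,
difference, form; the MIQ quotient form is available by flag).  Continuous
features are discretised to three levels at mean +/- k*sigma before MI
estimation.

Because patch-based properties (intensity, orientation) contribute one
feature per patch position, individual positions of a single property are
scattered through the ranked list; the grouped-relevance rule counts how
often each property group appears among the top-K ranks and flags groups
whose members dominate there, indicating the whole 3x3 patch of that
property should enter the feature vector.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .features import FeatureMatrix, FEATURE_GROUPS, N_FEATURES

GROUP_SIZES = {"intensity": 9, "orientation": 18, "statistic": 6}


def discretize(features, k: float = 0.5) -> np.ndarray:
    """Map each column to 3 levels split at mean - k*std and mean + k*std.

    Level 0: below mean - k*std; 1: middle; 2: above mean + k*std.  A
    constant column maps to a single level (1).  Deterministic.
    """
    X = features.values if isinstance(features, FeatureMatrix) else np.asarray(features, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    mean = X.mean(axis=0)
    std = X.std(axis=0)
    const = std <= 1e-12 * np.maximum(1.0, np.abs(mean))
    lo = np.where(const, -np.inf, mean - k * std)
    hi = np.where(const, np.inf, mean + k * std)
    out = np.ones(X.shape, dtype=np.int8)
    out[X < lo] = 0
    out[X > hi] = 2
    return out


def mutual_information(x, y) -> float:
    """Empirical plug-in mutual information in bits (0 log 0 = 0)."""
    x = np.asarray(x).ravel()
    y = np.asarray(y).ravel()
    if x.size != y.size:
        raise ValueError("length mismatch")
    xv, xi = np.unique(x, return_inverse=True)
    yv, yi = np.unique(y, return_inverse=True)
    joint = np.zeros((xv.size, yv.size))
    np.add.at(joint, (xi, yi), 1.0)
    joint /= x.size
    px = joint.sum(axis=1, keepdims=True)
    py = joint.sum(axis=0, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = joint * np.log2(joint / (px * py))
    return float(np.nansum(terms))


@dataclass
class FeatureRanking:
    """Greedy mRMR ordering of feature columns.

    ``order`` holds 1-based feature indices in feature-vector column order,
    from most to least valuable; ``relevance``/``redundancy`` are the MI
    with the label and the mean MI with previously selected features at the
    step each index was picked.
    """

    order: np.ndarray        # 1-based indices, a permutation of 1..n
    relevance: np.ndarray
    redundancy: np.ndarray
    groups: tuple

    def to_frame(self) -> pd.DataFrame:
        from .features import FEATURE_NAMES

        names = [FEATURE_NAMES[i - 1] if len(self.groups) == N_FEATURES else str(i)
                 for i in self.order]
        return pd.DataFrame(
            {
                "rank": np.arange(1, self.order.size + 1),
                "feature_index": self.order,
                "feature_name": names,
                "group": [self.groups[i - 1] for i in self.order],
                "relevance": self.relevance,
                "redundancy": self.redundancy,
            }
        )


def mrmr_rank(
    features,
    labels,
    K: Optional[int] = None,
    scheme: str = "MID",
    groups: Optional[tuple] = None,
) -> FeatureRanking:
    """Greedy mRMR ranking of a discrete feature matrix against labels.

    Parameters
    ----------
    features : (N, n_features) discrete matrix (see :func:`discretize`)
    labels : binary vector
    K : number of features to rank (default all)
    scheme : 'MID' (relevance - mean redundancy) or 'MIQ' (quotient)
    groups : per-column property labels; defaults to the 33-feature groups
        when the column count matches.

    Ties are broken toward the lower column index.
    """
    X = np.asarray(features)
    y = np.asarray(labels).ravel()
    n_feat = X.shape[1]
    if K is None:
        K = n_feat
    if K < 1 or K > n_feat:
        raise ValueError(f"K must lie in [1, {n_feat}]")
    if scheme not in ("MID", "MIQ"):
        raise ValueError("scheme must be 'MID' or 'MIQ'")
    if groups is None:
        groups = FEATURE_GROUPS if n_feat == N_FEATURES else tuple(["feature"] * n_feat)

    relevance_all = np.array([mutual_information(X[:, j], y) for j in range(n_feat)])
    selected: list = []
    rel_out, red_out = [], []
    pairwise = {}  # cached MI between feature columns

    remaining = list(range(n_feat))
    for _ in range(K):
        best_j, best_score, best_red = None, -np.inf, 0.0
        for j in remaining:
            if selected:
                reds = []
                for s in selected:
                    key = (min(j, s), max(j, s))
                    if key not in pairwise:
                        pairwise[key] = mutual_information(X[:, j], X[:, s])
                    reds.append(pairwise[key])
                red = float(np.mean(reds))
            else:
                red = 0.0
            if scheme == "MID":
                score = relevance_all[j] - red
            else:
                score = relevance_all[j] / (red + 1e-12)
            if score > best_score:  # strict: ties keep the lower index
                best_j, best_score, best_red = j, score, red
        selected.append(best_j)
        remaining.remove(best_j)
        rel_out.append(relevance_all[best_j])
        red_out.append(best_red)

    return FeatureRanking(
        order=np.asarray(selected) + 1,
        relevance=np.asarray(rel_out),
        redundancy=np.asarray(red_out),
        groups=tuple(groups),
    )


def grouped_relevance(ranking: FeatureRanking, K: int, flag_fraction: float = 0.5) -> pd.DataFrame:
    """Per-property-group frequency among the top-K ranked features.

    For each group the table reports its member count in the top K, the
    fraction of the group that represents, and the enrichment relative to
    the group's share of all features (count/K divided by size/total).  A
    group is flagged "include whole 3x3 property" when its top-K count
    exceeds ``flag_fraction`` of the group size.
    """
    if K < 1 or K > ranking.order.size:
        raise ValueError(f"K must lie in [1, {ranking.order.size}]")
    top = ranking.order[:K]
    group_names = sorted(set(ranking.groups), key=list(ranking.groups).index)
    total = len(ranking.groups)
    rows = []
    for g in group_names:
        size = sum(1 for gg in ranking.groups if gg == g)
        count = int(sum(1 for i in top if ranking.groups[i - 1] == g))
        rows.append(
            {
                "group": g,
                "group_size": size,
                "top_k_count": count,
                "fraction_of_group": count / size,
                "enrichment": (count / K) / (size / total),
                "include_whole_patch": count > flag_fraction * size,
            }
        )
    return pd.DataFrame(rows).set_index("group")


class MRMRRanker(BaseEstimator):
    """Estimator wrapper: fit(X, y) ranks feature columns by mRMR.

    Parameters
    ----------
    K : number of features to rank (default: all columns)
    scheme : 'MID' or 'MIQ'
    discretize_k : the k in the mean +/- k*sigma 3-level discretisation

    Attributes
    ----------
    ranking_ : FeatureRanking
    order_ : 1-based ranked feature indices
    """

    def __init__(self, K: Optional[int] = None, scheme: str = "MID", discretize_k: float = 0.5):
        self.K = K
        self.scheme = scheme
        self.discretize_k = discretize_k

    def fit(self, X, y):
        Xd = discretize(X, k=self.discretize_k)
        self.ranking_ = mrmr_rank(Xd, y, K=self.K, scheme=self.scheme)
        self.order_ = self.ranking_.order
        return self
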