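"""MAP cluster/regime labeling and label-matched accuracy scoring.

A mixture likelihood is invariant to permutations of cluster labels and, within
each cluster, of regime labels; accuracies are therefore computed after an
optimal one-to-one matching of estimated to true labels (Hungarian assignment
on the confusion matrix).  Regimes are matched within matched clusters because
regimes are cluster-specific objects in this model.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import linear_sum_assignment

from .em import FitResult
from .model import PanelData, Parameters, posterior_cluster, posterior_regime

__all__ = [
    "Labeling",
    "classify",
    "match_labels",
    "apply_matching",
    "accuracy",
    "matched_accuracy",
    "permute_parameters",
    "match_parameters",
]


@dataclass
class Labeling:
    """Hard cluster/regime assignments; labels are 1-based.

    ``cluster`` has length N_p with values in 1..K; ``regime`` is N_p x N_t
    with values in 1..R.
    """

    cluster: np.ndarray
    regime: np.ndarray

    def __post_init__(self) -> None:
        self.cluster = np.asarray(self.cluster, dtype=int)
        self.regime = np.atleast_2d(np.asarray(self.regime, dtype=int))
        if self.cluster.ndim != 1 or self.regime.shape[0] != self.cluster.size:
            raise ValueError("cluster and regime dimensions disagree")
        if self.cluster.min() < 1 or self.regime.min() < 1:
            raise ValueError("labels are 1-based")


def classify(fit: FitResult, data: PanelData) -> Labeling:
    """MAP labels: cluster_i = argmax_k tau_ik, regime_ij = argmax_r under the
    subject's MAP cluster.  Argmax ties break to the smallest index."""
    tau = posterior_cluster(data, fit.params)
    cluster = tau.argmax(axis=1)
    regime = np.empty((data.n_subjects, data.n_times), dtype=int)
    for i in range(data.n_subjects):
        g = posterior_regime(data.values[i], data.grid, fit.params, int(cluster[i]))
        regime[i] = g.argmax(axis=1) + 1
    return Labeling(cluster + 1, regime)


def _best_permutation(confusion: np.ndarray) -> np.ndarray:
    """perm[est] = truth maximizing the matched total of a confusion matrix
    whose rows index estimated labels and columns true labels."""
    rows, cols = linear_sum_assignment(-confusion)
    perm = np.empty(confusion.shape[0], dtype=int)
    perm[rows] = cols
    return perm


def match_labels(truth: Labeling, est: Labeling, K: int, R: int):
    """Optimal label matching between an estimated and a true Labeling.

    Returns ``(cluster_perm, regime_perms)`` where ``cluster_perm[k]`` is the
    0-based true cluster matched to 0-based estimated cluster k, and
    ``regime_perms[k][r]`` the true regime matched to estimated regime r of
    estimated cluster k.  Regime confusions are accumulated over cells of
    subjects whose matched estimated cluster agrees with their true cluster;
    clusters with no such cells keep the identity permutation.
    """
    tc, ec = truth.cluster - 1, est.cluster - 1
    conf = np.zeros((K, K))
    for k_est in range(K):
        for k_true in range(K):
            conf[k_est, k_true] = np.sum((ec == k_est) & (tc == k_true))
    cluster_perm = _best_permutation(conf)

    regime_perms = []
    for k_est in range(K):
        mask = (ec == k_est) & (tc == cluster_perm[k_est])
        rconf = np.zeros((R, R))
        if mask.any():
            tr = truth.regime[mask] - 1
            er = est.regime[mask] - 1
            for r_est in range(R):
                for r_true in range(R):
                    rconf[r_est, r_true] = np.sum((er == r_est) & (tr == r_true))
            regime_perms.append(_best_permutation(rconf))
        else:
            regime_perms.append(np.arange(R))
    return cluster_perm, regime_perms


def apply_matching(est: Labeling, cluster_perm: np.ndarray, regime_perms) -> Labeling:
    """Relabel an estimated Labeling into the true label space."""
    ec = est.cluster - 1
    new_cluster = cluster_perm[ec] + 1
    new_regime = np.empty_like(est.regime)
    for i in range(ec.size):
        new_regime[i] = regime_perms[ec[i]][est.regime[i] - 1] + 1
    return Labeling(new_cluster, new_regime)


def accuracy(truth: Labeling, est: Labeling, observed_mask: np.ndarray | None = None) -> dict:
    """Fraction of correctly labeled subjects / observed cells.

    ``est`` must already be in the true label space (see ``apply_matching``).
    Regime accuracy is pooled over all (subject, time) cells whose
    ``observed_mask`` entry is True — i.e. cells available before imputation.
    """
    if observed_mask is None:
        observed_mask = np.ones(truth.regime.shape, dtype=bool)
    cluster_acc = float(np.mean(truth.cluster == est.cluster))
    agree = (truth.regime == est.regime)[observed_mask]
    regime_acc = float(np.mean(agree)) if agree.size else float("nan")
    # per-subject-first average, reported alongside the pooled convention
    per_subj = [
        float(np.mean((truth.regime[i] == est.regime[i])[observed_mask[i]]))
        for i in range(truth.cluster.size)
        if observed_mask[i].any()
    ]
    return {
        "cluster_acc": cluster_acc,
        "regime_acc": regime_acc,
        "regime_acc_subject_mean": float(np.mean(per_subj)) if per_subj else float("nan"),
    }


def matched_accuracy(
    truth: Labeling, est: Labeling, K: int, R: int,
    observed_mask: np.ndarray | None = None,
) -> dict:
    """Accuracy after optimal label matching (permutation-invariant)."""
    perm, rperms = match_labels(truth, est, K, R)
    return accuracy(truth, apply_matching(est, perm, rperms), observed_mask)


def permute_parameters(params: Parameters, cluster_perm: np.ndarray, regime_perms) -> Parameters:
    """Reorder clusters/regimes of a Parameters object into the true label
    space and re-pin the reference regime's logistic row at zero.

    The logistic coefficients are identified only up to subtraction of the
    reference row, so after reordering regimes the row that lands on the
    reference slot is subtracted from all rows of that cluster.
    """
    K, R = params.n_clusters, params.n_regimes
    alpha = np.empty_like(params.alpha)
    omega = np.empty_like(params.omega)
    beta = np.empty_like(params.beta)
    sigma2 = np.empty_like(params.sigma2)
    for k_est in range(K):
        k_true = cluster_perm[k_est]
        alpha[k_true] = params.alpha[k_est]
        inv = np.empty(R, dtype=int)          # inv[true] = est
        inv[np.asarray(regime_perms[k_est])] = np.arange(R)
        om = params.omega[k_est][inv]
        omega[k_true] = om - om[-1][None, :]  # re-pin reference at zero
        beta[k_true] = params.beta[k_est][inv]
        sigma2[k_true] = params.sigma2[k_est][inv]
    return Parameters(alpha, omega, beta, sigma2, params.spec)


def match_parameters(
    fit: FitResult, data: PanelData, truth: Labeling
) -> Parameters:
    """Label-match a fit's parameters to simulation truth via MAP labels."""
    est = classify(fit, data)
    K, R = fit.spec.n_clusters, fit.spec.n_regimes
    perm, rperms = match_labels(truth, est, K, R)
    return permute_parameters(fit.params, perm, rperms)
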