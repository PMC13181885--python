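"""Alpha diversity, Bray-Curtis dissimilarity, principal-coordinates
ordination and PERMANOVA.

Diversity estimators follow the standard amplicon/metagenome conventions:
observed species is the count of taxa with positive abundance, Shannon is
-sum(p ln p) in natural log by default, and Chao1 is the nonparametric
richness estimator from singleton/doubleton counts, bias-corrected by
default:

    Chao1_bc      = S_obs + F1 (F1 - 1) / (2 (F2 + 1))
    Chao1_classic = S_obs + F1^2 / (2 F2)        (F2 > 0)

PCoA is classical metric scaling: Gower double-centering of the squared
distance matrix followed by eigendecomposition.  Negative eigenvalues —
the signature of a non-Euclidean dissimilarity such as Bray-Curtis — are
returned, never silently dropped.

PERMANOVA partitions the squared distances into among- and within-group
sums of squares and tests the pseudo-F statistic

    F = (SS_among / (g - 1)) / (SS_within / (N - g))

by permuting sample labels; p = (1 + #{F* >= F}) / (1 + n_perm).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform


@dataclass
class OrdinationResult:
    coordinates: np.ndarray       # samples x axes
    eigenvalues: np.ndarray       # all eigenvalues, descending
    proportion_explained: np.ndarray
    has_negative_eigenvalues: bool


@dataclass
class PermanovaResult:
    pseudo_f: float
    p_value: float
    n_permutations: int
    seed: int | None


def alpha_diversity(counts, base: float | None = None,
                    chao1_bias_corrected: bool = True) -> dict:
    """Observed species, Shannon index and Chao1 for one count vector.

    ``base`` switches the Shannon logarithm (natural log when None).
    Classic Chao1 (F1^2 / 2 F2) is available with
    ``chao1_bias_corrected=False``; it falls back to the bias-corrected
    form when there are no doubletons.
    """
    c = np.asarray(counts, dtype=float)
    if (c < 0).any():
        raise ValueError("negative counts")
    total = c.sum()
    if total == 0:
        raise ValueError("all-zero count vector")
    observed = int((c > 0).sum())
    p = c[c > 0] / total
    shannon = float(-(p * np.log(p)).sum())
    if base is not None:
        shannon /= math.log(base)
    f1 = int((c == 1).sum())
    f2 = int((c == 2).sum())
    if chao1_bias_corrected or f2 == 0:
        chao1 = observed + f1 * (f1 - 1) / (2.0 * (f2 + 1))
    else:
        chao1 = observed + f1 ** 2 / (2.0 * f2)
    return {"observed": observed, "shannon": shannon, "chao1": float(chao1)}


def alpha_diversity_table(matrix: pd.DataFrame, **kwargs) -> pd.DataFrame:
    """Alpha diversity per sample for a taxa x samples count frame."""
    rows = {s: alpha_diversity(matrix[s].to_numpy(), **kwargs)
            for s in matrix.columns}
    return pd.DataFrame(rows).T.rename_axis("sample")


def bray_curtis(matrix) -> np.ndarray:
    """Pairwise Bray-Curtis distances for a samples x taxa matrix.

    d(x, y) = sum |x_i - y_i| / sum (x_i + y_i), in [0, 1] for
    non-negative data.
    """
    x = np.asarray(matrix, dtype=float)
    if (x < 0).any():
        raise ValueError("negative abundances")
    sums = x.sum(axis=1)
    if (sums == 0).any():
        bad = int(np.argmax(sums == 0))
        raise ValueError(f"sample at row {bad} has zero total abundance")
    return squareform(pdist(x, metric="braycurtis"))


def pcoa(distances, k: int | None = None) -> OrdinationResult:
    """Classical (metric) multidimensional scaling of a distance matrix.

    Coordinates are returned only for axes with positive eigenvalues;
    negative eigenvalues are kept in ``eigenvalues`` and flagged.
    Proportions explained are relative to the sum of positive eigenvalues.
    """
    d = np.asarray(distances, dtype=float)
    n = d.shape[0]
    if d.shape != (n, n) or not np.allclose(d, d.T, atol=1e-8):
        raise ValueError("distance matrix must be square symmetric")
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (d ** 2) @ j
    evals, evecs = np.linalg.eigh(b)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    pos = evals > max(1e-10, 1e-10 * abs(evals).max(initial=1.0))
    coords = evecs[:, pos] * np.sqrt(evals[pos])
    if k is not None:
        coords = coords[:, :k]
    pos_sum = evals[pos].sum()
    prop = np.where(evals > 0, evals / pos_sum, 0.0) if pos_sum > 0 \
        else np.zeros_like(evals)
    return OrdinationResult(coordinates=coords, eigenvalues=evals,
                            proportion_explained=prop,
                            has_negative_eigenvalues=bool(
                                (evals < -1e-8 * max(1.0, abs(evals).max()))
                                .any()))


def _pseudo_f(d2: np.ndarray, labels: np.ndarray) -> float:
    """Anderson's pseudo-F from a squared distance matrix and labels."""
    n = len(labels)
    groups = np.unique(labels)
    g = len(groups)
    ss_total = d2[np.triu_indices(n, 1)].sum() / n
    ss_within = 0.0
    for grp in groups:
        idx = np.flatnonzero(labels == grp)
        if len(idx) > 1:
            sub = d2[np.ix_(idx, idx)]
            ss_within += sub[np.triu_indices(len(idx), 1)].sum() / len(idx)
    ss_among = ss_total - ss_within
    return (ss_among / (g - 1)) / (ss_within / (n - g))


def permanova(distances, groups, n_perm: int = 999,
              seed: int | None = None,
              exhaustive: bool = False) -> PermanovaResult:
    """Permutational multivariate ANOVA on a distance matrix.

    With ``exhaustive=True`` every distinct label permutation is
    enumerated (only sensible for very small designs) and the p-value is
    exact; otherwise ``n_perm`` random permutations are drawn from the
    generator seeded with ``seed``.
    """
    d = np.asarray(distances, dtype=float)
    labels = np.asarray(groups)
    uniq, counts = np.unique(labels, return_counts=True)
    if len(uniq) < 2:
        raise ValueError("need >= 2 groups")
    if (counts < 2).any():
        raise ValueError("every group needs >= 2 samples")
    if not exhaustive and n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    d2 = d ** 2
    f_obs = _pseudo_f(d2, labels)
    if exhaustive:
        perms = itertools.permutations(labels)
        hits = total = 0
        for perm in perms:
            total += 1
            if _pseudo_f(d2, np.asarray(perm)) >= f_obs - 1e-12:
                hits += 1
        # the identity permutation is included in the enumeration
        return PermanovaResult(pseudo_f=f_obs, p_value=hits / total,
                               n_permutations=total, seed=None)
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        perm = rng.permutation(labels)
        if _pseudo_f(d2, perm) >= f_obs - 1e-12:
            hits += 1
    p = (1 + hits) / (1 + n_perm)
    return PermanovaResult(pseudo_f=f_obs, p_value=p,
                           n_permutations=n_perm, seed=seed)
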