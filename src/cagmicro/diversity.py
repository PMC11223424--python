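"""Alpha diversity, Bray-Curtis dissimilarity, PCoA, and PERMANOVA.

Alpha indices follow the standard estimators: bias-corrected Chao1
(S_obs + F1(F1-1)/(2(F2+1))), ACE with the conventional rare/abundant cutoff
of 10, Shannon entropy in nats by default (Pielou then normalizes by
ln S_obs), and Simpson in the Gini-Simpson form 1 - sum p_i^2. Chao1 and ACE
are computed by scikit-bio; the remainder are direct formula evaluations.

PERMANOVA is a one-way pseudo-F test on the distance matrix. When the design
admits no more distinct label assignments than the permutation budget (the
two-group case), the permutation distribution is enumerated exactly and the
p-value is the exact tail fraction; otherwise Monte Carlo permutations give
p = (c + 1) / (B + 1).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from skbio.diversity import alpha as _skb_alpha

from .data_io import AbundanceTable, DataError

ALPHA_INDICES = ("ACE", "Chao1", "Observed", "Pielou", "Shannon", "Simpson")


# ---------------------------------------------------------------------------
# alpha diversity

def alpha_index(counts, index_name: str, log_base: float | None = None) -> float:
    """Compute one alpha-diversity index for a single sample's count vector.

    ``log_base`` switches the Shannon/Pielou logarithm (default: natural log).
    Richness estimators (Chao1, ACE, Observed) require integer counts.
    """
    c = np.asarray(counts, dtype=float)
    if c.ndim != 1 or (c < 0).any():
        raise DataError("alpha_index expects a 1-D non-negative count vector")
    total = c.sum()
    if total <= 0:
        raise DataError("alpha_index requires a positive total count")
    name = index_name.lower()
    if name in ("chao1", "ace", "observed"):
        if not np.allclose(c, np.round(c)):
            raise DataError(f"{index_name} requires integer counts")
        ci = np.round(c).astype(np.int64)
        if name == "observed":
            return float((ci > 0).sum())
        if name == "chao1":
            return float(_skb_alpha.chao1(ci, bias_corrected=True))
        return float(_skb_alpha.ace(ci, rare_threshold=10))
    p = c[c > 0] / total
    if name == "shannon":
        h = float(-(p * np.log(p)).sum())
        return h / np.log(log_base) if log_base else h
    if name == "simpson":  # Gini-Simpson
        return float(1.0 - (p ** 2).sum())
    if name == "pielou":
        s_obs = (c > 0).sum()
        if s_obs < 2:
            raise DataError("Pielou evenness needs at least 2 observed taxa")
        return float(-(p * np.log(p)).sum() / np.log(s_obs))
    raise DataError(f"unknown alpha index {index_name!r}")


def alpha_table(t: AbundanceTable, indices=ALPHA_INDICES) -> pd.DataFrame:
    """Per-sample alpha indices (samples × indices) on a counts table."""
    if t.kind != "counts":
        raise DataError("alpha diversity is computed on counts")
    rows = {s: {ix: alpha_index(t.data[s].to_numpy(), ix) for ix in indices}
            for s in t.samples}
    return pd.DataFrame.from_dict(rows, orient="index").loc[t.samples, list(indices)]


# ---------------------------------------------------------------------------
# distances

@dataclass(frozen=True)
class DistanceMatrix:
    """Symmetric pairwise dissimilarities with sample (or genus) ids."""

    ids: tuple[str, ...]
    d: np.ndarray

    def __post_init__(self) -> None:
        d = np.asarray(self.d, dtype=float)
        if d.shape != (len(self.ids), len(self.ids)):
            raise DataError("distance matrix shape does not match ids")
        if not np.allclose(d, d.T, atol=1e-12):
            raise DataError("distance matrix is not symmetric")
        if not np.allclose(np.diag(d), 0.0, atol=1e-12):
            raise DataError("distance matrix diagonal is not zero")
        object.__setattr__(self, "d", d)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.d, index=list(self.ids), columns=list(self.ids))


def bray_curtis(t: AbundanceTable) -> DistanceMatrix:
    """Bray-Curtis dissimilarity between sample columns: sum|x-y| / sum(x+y)."""
    if t.kind == "counts":
        raise DataError("bray_curtis expects relative abundances (use to_relative)")
    x = t.values().T  # samples × taxa
    if x.shape[0] < 2:
        raise DataError("need at least 2 samples")
    d = squareform(pdist(x, metric="braycurtis"))
    return DistanceMatrix(tuple(t.samples), d)


# ---------------------------------------------------------------------------
# ordination

@dataclass(frozen=True)
class OrdinationResult:
    ids: tuple[str, ...]
    coordinates: pd.DataFrame           # samples × retained axes
    eigenvalues: np.ndarray             # all eigenvalues, descending
    proportion_explained: np.ndarray    # over the positive eigenvalues
    negative_eigenvalues: np.ndarray


def pcoa(dm: DistanceMatrix, n_axes: int | None = None) -> OrdinationResult:
    """Classical scaling (PCoA): Gower-center -D^2/2, eigendecompose.

    Coordinates are built from positive eigenvalues only; negative
    eigenvalues (non-Euclidean input) are reported, not silently dropped.
    """
    d = dm.d
    n = d.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (d ** 2) @ j
    evals, evecs = np.linalg.eigh((b + b.T) / 2)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    tol = max(1.0, np.abs(evals).max(initial=1.0)) * 1e-12
    pos = evals > tol
    n_pos = int(pos.sum())
    if n_axes is None:
        n_axes = n_pos
    elif n_axes > n_pos:
        import warnings
        warnings.warn(f"requested {n_axes} axes but only {n_pos} positive eigenvalues; truncating")
        n_axes = n_pos
    coords = evecs[:, :n_axes] * np.sqrt(np.maximum(evals[:n_axes], 0.0))
    cols = [f"PCo{i + 1}" for i in range(n_axes)]
    prop = (evals[pos] / evals[pos].sum()) if n_pos else np.zeros(0)
    return OrdinationResult(
        ids=dm.ids,
        coordinates=pd.DataFrame(coords, index=list(dm.ids), columns=cols),
        eigenvalues=evals,
        proportion_explained=prop,
        negative_eigenvalues=evals[evals < -tol],
    )


# ---------------------------------------------------------------------------
# PERMANOVA

@dataclass(frozen=True)
class PermanovaResult:
    pseudo_F: float
    p_value: float
    n_permutations: int
    seed: int | None
    exhaustive: bool = False


def _pseudo_f(d2: np.ndarray, group_indices: list[np.ndarray], n: int, a: int) -> float:
    ss_total = d2[np.triu_indices(n, k=1)].sum() / n
    ss_within = 0.0
    for idx in group_indices:
        sub = d2[np.ix_(idx, idx)]
        ss_within += sub.sum() / (2 * len(idx))
    ss_between = ss_total - ss_within
    if ss_within <= 0:
        return np.inf
    return (ss_between / (a - 1)) / (ss_within / (n - a))


def permanova(dm: DistanceMatrix, labels, n_perm: int = 999,
              seed: int | None = None, strata=None) -> PermanovaResult:
    """One-way PERMANOVA on a distance matrix.

    Labels are permuted freely by default. ``strata`` (e.g. patient ids)
    restricts permutations to within each stratum — the paired-design
    variant, where tissue labels are shuffled within a patient only.
    """
    labels = np.asarray(labels)
    n = len(dm.ids)
    if labels.shape[0] != n:
        raise DataError("labels length does not match distance matrix")
    groups, inverse = np.unique(labels, return_inverse=True)
    a = len(groups)
    if a < 2:
        raise DataError("PERMANOVA needs at least 2 groups")
    sizes = np.bincount(inverse)
    d2 = dm.d ** 2
    obs_idx = [np.flatnonzero(inverse == g) for g in range(a)]
    f_obs = _pseudo_f(d2, obs_idx, n, a)

    if strata is not None:
        strata = np.asarray(strata)
        if strata.shape[0] != n:
            raise DataError("strata length does not match distance matrix")
        rng = np.random.default_rng(seed)
        stratum_idx = [np.flatnonzero(strata == s) for s in np.unique(strata)]
        count = 0
        for _ in range(n_perm):
            perm = np.arange(n)
            for idx in stratum_idx:
                perm[idx] = idx[rng.permutation(len(idx))]
            perm_inv = inverse[perm]
            idxs = [np.flatnonzero(perm_inv == g) for g in range(a)]
            count += _pseudo_f(d2, idxs, n, a) >= f_obs - 1e-12
        p = (count + 1) / (n_perm + 1)
        return PermanovaResult(float(f_obs), p, n_perm, seed, exhaustive=False)

    # exact enumeration of distinct assignments when affordable (2 groups)
    if a == 2 and comb(n, int(sizes[0])) <= n_perm:
        total = comb(n, int(sizes[0]))
        count = 0
        all_idx = np.arange(n)
        for chosen in combinations(range(n), int(sizes[0])):
            idx0 = np.array(chosen)
            idx1 = np.setdiff1d(all_idx, idx0, assume_unique=True)
            f = _pseudo_f(d2, [idx0, idx1], n, a)
            if f >= f_obs - 1e-12:
                count += 1
        return PermanovaResult(float(f_obs), count / total, total, seed, exhaustive=True)

    rng = np.random.default_rng(seed)
    # vectorized Monte Carlo: indicator matrices per group over B permutations
    perms = np.argsort(rng.random((n_perm, n)), axis=1)  # random permutations
    perm_labels = inverse[perms]                          # (B, n)
    ss_total = d2[np.triu_indices(n, k=1)].sum() / n
    ss_within = np.zeros(n_perm)
    for g in range(a):
        m = (perm_labels == g).astype(float)              # (B, n)
        ss_within += ((m @ d2) * m).sum(axis=1) / (2 * sizes[g])
    ss_between = ss_total - ss_within
    with np.errstate(divide="ignore", invalid="ignore"):
        f_perm = (ss_between / (a - 1)) / (ss_within / (n - a))
    count = int(np.sum(f_perm >= f_obs - 1e-12))
    p = (count + 1) / (n_perm + 1)
    return PermanovaResult(float(f_obs), p, n_perm, seed, exhaustive=False)
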