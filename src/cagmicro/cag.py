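"""Co-abundance group (CAG) construction and sample stratification.

This is the core procedure: genera abundant in both tissue compartments are
clustered into co-abundance groups by Ward-linkage hierarchical clustering on
a correlation- or composition-based dissimilarity; samples are then profiled
by summed CAG abundance and themselves Ward-clustered into sample groups;
finally tissue contrasts are run per CAG, with a re-analysis that excludes a
dominant sample group.

Ward linkage is implemented in the ward.D2 convention: the Lance-Williams
recurrence is applied to squared input dissimilarities and merge heights are
the square roots of the merged cost. This matters on non-Euclidean input
(e.g. 1 - Spearman rho), where ward.D1 gives different trees. Ties are broken
deterministically toward the pair containing the lowest leaf index, so
dendrograms are bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .data_io import AbundanceTable, DataError, TISSUES
from .diff_abundance import TestResult, mann_whitney, wilcoxon_signed_rank
from .diversity import DistanceMatrix, bray_curtis


# ---------------------------------------------------------------------------
# genus filter

@dataclass(frozen=True)
class GenusFilterResult:
    retained: tuple[str, ...]
    threshold: float
    mode: str
    group_means: pd.DataFrame = field(repr=False)  # genera × tissue mean rel. abundance


def filter_genera(t: AbundanceTable, meta: pd.DataFrame, threshold: float = 0.001,
                  mode: str = "both_groups") -> GenusFilterResult:
    """Retain genera whose mean relative abundance strictly exceeds ``threshold``.

    ``mode="both_groups"``: the mean must exceed the threshold within the
    tumor samples and within the normal samples (conjunctive reading);
    ``"either_group"``: in at least one tissue; ``"overall"``: pooled mean.
    """
    if t.kind != "relative":
        raise DataError("filter_genera expects a relative table")
    if mode not in ("both_groups", "either_group", "overall"):
        raise DataError(f"unknown filter mode {mode!r}")
    tissue = meta.loc[t.samples, "tissue"]
    means = {}
    for tis in TISSUES:
        cols = tissue.index[tissue == tis]
        if len(cols) == 0:
            raise DataError(f"no samples in tissue group {tis}")
        means[tis] = t.data.loc[:, cols].mean(axis=1)
    gm = pd.DataFrame(means)
    if mode == "both_groups":
        keep = (gm > threshold).all(axis=1)
    elif mode == "either_group":
        keep = (gm > threshold).any(axis=1)
    else:
        keep = t.data.mean(axis=1) > threshold
    return GenusFilterResult(tuple(gm.index[keep]), threshold, mode, gm)


# ---------------------------------------------------------------------------
# genus-genus dissimilarity

def _spearman_matrix(x: np.ndarray) -> np.ndarray:
    """Pairwise Spearman correlation between the rows of x (always a matrix,
    even for 2 rows where scipy returns a scalar); unit diagonal."""
    rho = stats.spearmanr(x, axis=1)[0]
    if np.ndim(rho) == 0:
        rho = np.array([[1.0, float(rho)], [float(rho), 1.0]])
    rho = np.asarray(rho, dtype=float)
    np.fill_diagonal(rho, 1.0)
    return rho


def genus_distance(t: AbundanceTable, retained, mode: str = "spearman") -> DistanceMatrix:
    """Dissimilarity between genus abundance profiles across samples.

    ``spearman``: d = 1 - Spearman rho (range [0, 2]); ``bray_curtis``:
    Bray-Curtis between genus profiles each normalized to sum 1.
    """
    retained = list(retained)
    if len(t.samples) < 3:
        raise DataError("genus_distance needs at least 3 samples")
    x = t.data.loc[retained, :].to_numpy(dtype=float)  # genera × samples
    if mode == "spearman":
        const = np.all(x == x[:, [0]], axis=1)
        if const.any():
            bad = retained[int(np.argmax(const))]
            raise DataError(f"genus {bad!r} has a constant profile (zero rank variance)")
        d = 1.0 - _spearman_matrix(x)
        np.fill_diagonal(d, 0.0)
        d = np.clip((d + d.T) / 2, 0.0, 2.0)
        return DistanceMatrix(tuple(retained), d)
    if mode == "bray_curtis":
        sums = x.sum(axis=1, keepdims=True)
        if (sums <= 0).any():
            bad = retained[int(np.argmax(sums[:, 0] <= 0))]
            raise DataError(f"genus {bad!r} has zero total abundance")
        prof = x / sums
        sub = AbundanceTable(pd.DataFrame(prof.T, index=t.samples, columns=retained),
                             kind="fraction")
        return bray_curtis(sub)
    raise DataError(f"unknown genus distance mode {mode!r}")


# ---------------------------------------------------------------------------
# Ward clustering

@dataclass(frozen=True)
class Dendrogram:
    """Agglomeration result over n leaves, scipy linkage convention.

    ``merges`` is an (n-1, 4) array: each row (id_a, id_b, height, size)
    merges clusters id_a < n+step into a new cluster with id n+step. Heights
    are ward.D2 merge costs and are non-decreasing.
    """

    labels: tuple[str, ...]
    merges: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.merges, dtype=float)
        if m.shape != (len(self.labels) - 1, 4):
            raise DataError("merge list must have n-1 rows of 4")
        object.__setattr__(self, "merges", m)

    @property
    def n_leaves(self) -> int:
        return len(self.labels)

    def to_newick(self) -> str:
        """Newick string with branch lengths = parent height - child height."""
        n = self.n_leaves
        height = {i: 0.0 for i in range(n)}
        node = {i: lab.replace(" ", "_") for i, lab in enumerate(self.labels)}
        for step, (a, b, h, _size) in enumerate(self.merges):
            a, b = int(a), int(b)
            la = max(h - height[a], 0.0)
            lb = max(h - height[b], 0.0)
            node[n + step] = f"({node[a]}:{la:.6g},{node[b]}:{lb:.6g})"
            height[n + step] = h
        return node[n + len(self.merges) - 1] + ";" if n > 1 else node[0] + ";"


def ward_cluster(dm: DistanceMatrix) -> Dendrogram:
    """Agglomerate by Ward linkage (ward.D2) with deterministic tie-breaking.

    The Lance-Williams update is applied to squared dissimilarities; among
    equal-cost candidate merges the pair whose smallest member leaf indices
    are lexicographically lowest is merged first.
    """
    n = len(dm.ids)
    if n < 2:
        raise DataError("ward_cluster needs at least 2 items")
    s = dm.d.astype(float) ** 2          # current squared dissimilarities
    np.fill_diagonal(s, np.inf)
    ids = np.arange(n)                   # cluster ids in scipy convention
    sizes = np.ones(n)
    merges = np.empty((n - 1, 4))
    for step in range(n - 1):
        m = s.shape[0]
        # each cluster occupies the slot of its smallest leaf, so the first
        # flattened argmin over the upper triangle is the lowest-index tie-break
        iu = np.triu_indices(m, k=1)
        flat = s[iu]
        k = int(np.argmin(flat))
        i, j = int(iu[0][k]), int(iu[1][k])
        cost = flat[k]
        height = float(np.sqrt(cost))
        new_size = sizes[i] + sizes[j]
        merges[step] = (ids[i], ids[j], height, new_size)
        # Lance-Williams ward update into position i
        others = np.array([k_ for k_ in range(m) if k_ not in (i, j)], dtype=int)
        if len(others):
            upd = ((sizes[i] + sizes[others]) * s[i, others]
                   + (sizes[j] + sizes[others]) * s[j, others]
                   - sizes[others] * cost) / (new_size + sizes[others])
            s[i, others] = upd
            s[others, i] = upd
        s[i, i] = np.inf
        s = np.delete(np.delete(s, j, axis=0), j, axis=1)
        sizes[i] = new_size
        sizes = np.delete(sizes, j)
        ids[i] = n + step
        ids = np.delete(ids, j)
    return Dendrogram(tuple(dm.ids), merges)


def cut_tree(dn: Dendrogram, k: int) -> dict[str, int]:
    """Cut the dendrogram into k clusters (undo the last k-1 merges).

    Returns label -> cluster number in 1..k, clusters numbered by their
    smallest leaf index (deterministic).
    """
    n = dn.n_leaves
    if not 1 <= k <= n:
        raise DataError(f"k={k} out of range 1..{n}")
    parent = list(range(2 * n - 1))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for step in range(n - 1 - (k - 1)):
        a, b, _, _ = dn.merges[step]
        new = n + step
        parent[find(int(a))] = new
        parent[find(int(b))] = new
    roots: dict[int, list[int]] = {}
    for leaf in range(n):
        roots.setdefault(find(leaf), []).append(leaf)
    clusters = sorted(roots.values(), key=lambda leaves: min(leaves))
    out: dict[str, int] = {}
    for num, leaves in enumerate(clusters, start=1):
        for leaf in leaves:
            out[dn.labels[leaf]] = num
    return out


# ---------------------------------------------------------------------------
# CAG model and sample grouping

@dataclass(frozen=True)
class CagModel:
    assignment: dict[str, str]   # genus -> "CAG1".."CAGk"
    k: int
    dendrogram: Dendrogram
    distance_mode: str

    def members(self, cag: str) -> list[str]:
        return [g for g, c in self.assignment.items() if c == cag]

    @property
    def cags(self) -> list[str]:
        return [f"CAG{i}" for i in range(1, self.k + 1)]


def build_cag_model(t: AbundanceTable, meta: pd.DataFrame, k: int = 4,
                    threshold: float = 0.001, filter_mode: str = "both_groups",
                    distance_mode: str = "spearman") -> CagModel:
    """Filter genera, cluster them, and cut into k co-abundance groups."""
    filt = filter_genera(t, meta, threshold=threshold, mode=filter_mode)
    if len(filt.retained) < k:
        raise DataError(f"only {len(filt.retained)} genera pass the filter; cannot form {k} CAGs")
    dm = genus_distance(t, filt.retained, mode=distance_mode)
    dn = ward_cluster(dm)
    numbers = cut_tree(dn, k)
    assignment = {g: f"CAG{c}" for g, c in numbers.items()}
    return CagModel(assignment, k, dn, distance_mode)


def cag_profiles(t: AbundanceTable, model: CagModel) -> AbundanceTable:
    """Per-sample CAG abundance: sum of member-genus relative abundances.

    Columns are NOT renormalized (they sum to at most 1), so printed medians
    stay comparable to per-genus relative abundances.
    """
    if t.kind == "counts":
        raise DataError("cag_profiles expects relative abundances")
    rows = {}
    for cag in model.cags:
        members = model.members(cag)
        if not members:
            raise DataError(f"{cag} has no member genera")
        missing = [g for g in members if g not in t.data.index]
        if missing:
            raise DataError(f"model genera absent from table: {missing[:5]}")
        rows[cag] = t.data.loc[members, :].sum(axis=0)
    prof = pd.DataFrame(rows).T.loc[model.cags, t.samples]
    return AbundanceTable(prof, kind="fraction")


@dataclass(frozen=True)
class SampleGrouping:
    assignment: dict[str, int]   # sample -> group number 1..g
    g: int
    composition: pd.DataFrame    # groups × {TT, NT} counts
    dendrogram: Dendrogram

    def members(self, group: int) -> list[str]:
        return [s for s, grp in self.assignment.items() if grp == group]


def cluster_samples(profiles: AbundanceTable, g: int, meta: pd.DataFrame) -> SampleGrouping:
    """Ward-cluster samples on Bray-Curtis distances between CAG profiles."""
    if g < 1 or g > len(profiles.samples):
        raise DataError(f"g={g} out of range")
    dm = bray_curtis(profiles)
    dn = ward_cluster(dm)
    assignment = cut_tree(dn, g)
    tissue = meta.loc[profiles.samples, "tissue"]
    comp = pd.DataFrame(0, index=range(1, g + 1), columns=list(TISSUES))
    for s, grp in assignment.items():
        comp.loc[grp, tissue[s]] += 1
    comp.index.name = "group"
    return SampleGrouping(assignment, g, comp, dn)


# ---------------------------------------------------------------------------
# tissue contrasts

def compare_cag_abundance(profiles: AbundanceTable, meta: pd.DataFrame,
                          paired: bool = False) -> list[TestResult]:
    """Per-CAG tumor-vs-normal contrast (Mann-Whitney; Wilcoxon when paired).

    Medians are reported per tissue on the percent scale. The paired variant
    uses within-patient tumor-minus-normal differences and keeps only
    patients with both tissues present.
    """
    tissue = meta.loc[profiles.samples, "tissue"]
    tt = tissue.index[tissue == "TT"]
    nt = tissue.index[tissue == "NT"]
    if len(tt) == 0 or len(nt) == 0:
        raise DataError("both tissues must be present")
    out = []
    for cag in profiles.taxa:
        row = profiles.data.loc[cag]
        x, y = row[tt].to_numpy(), row[nt].to_numpy()
        if paired:
            pat = meta.loc[profiles.samples, "patient_id"]
            tt_by_pat = {pat[s]: row[s] for s in tt}
            nt_by_pat = {pat[s]: row[s] for s in nt}
            common = sorted(set(tt_by_pat) & set(nt_by_pat))
            diffs = np.array([tt_by_pat[p] - nt_by_pat[p] for p in common])
            res = wilcoxon_signed_rank(diffs, feature=cag)
        else:
            res = mann_whitney(x, y, feature=cag)
        medians = {"TT": float(np.median(x) * 100), "NT": float(np.median(y) * 100)}
        out.append(TestResult(cag, res.test, res.statistic, res.p_value, medians,
                              n=res.n, extra={"median_scale": "percent"}))
    return out


def cag_correlation(profiles: AbundanceTable) -> pd.DataFrame:
    """Pairwise Spearman correlation among CAG abundance profiles."""
    rho = _spearman_matrix(profiles.values())
    return pd.DataFrame(rho, index=profiles.taxa, columns=profiles.taxa)


def pick_dominant_group(profiles: AbundanceTable, grouping: SampleGrouping,
                        cag: str = "CAG1", share: float = 0.90) -> int | None:
    """Heuristic for the exclusion step: the group whose mean ``cag`` share of
    the total CAG profile exceeds ``share`` (None if no group qualifies)."""
    totals = profiles.data.sum(axis=0)
    frac = profiles.data.loc[cag] / totals.where(totals > 0, np.nan)
    for grp in range(1, grouping.g + 1):
        members = grouping.members(grp)
        if members and float(frac[members].mean()) > share:
            return grp
    return None


def exclude_group_and_recompute(profiles: AbundanceTable, grouping: SampleGrouping,
                                exclude_id: int, meta: pd.DataFrame,
                                paired: bool = False):
    """Drop one sample group and re-run the tissue contrasts and CAG correlations."""
    if exclude_id not in range(1, grouping.g + 1):
        raise DataError(f"group {exclude_id} not in grouping")
    drop = set(grouping.members(exclude_id))
    keep = [s for s in profiles.samples if s not in drop]
    sub = profiles.select_samples(keep)
    tissue = meta.loc[keep, "tissue"]
    if (tissue == "TT").sum() == 0 or (tissue == "NT").sum() == 0:
        raise DataError("exclusion empties a tissue class")
    contrasts = compare_cag_abundance(sub, meta, paired=paired)
    corr = cag_correlation(sub)
    return contrasts, corr
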