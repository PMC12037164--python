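"""Cluster-based permutation inference.

Forward-versus-backward contrasts are tested with a dependent-samples
cluster permutation t-test: per-bin paired t statistics are thresholded at
the two-sided critical value for the cluster-forming alpha (0.01), maximal
connected sets of suprathreshold bins form clusters separately for each
sign, cluster mass is the summed statistic, and the null distribution is
the maximal |cluster mass| over random within-subject condition sign
flips.  Group differences are tested with a cluster permutation
mixed-design 2x3 ANOVA (modality within subjects, listening group between
subjects) with effect-specific permutation schemes, plus parametric
single-bin ANOVAs and post hoc paired / Welch t-tests.

Following the two-sided convention of the major cluster-permutation
toolboxes, positive and negative clusters are formed separately and a
cluster is called significant at level ``alpha`` when its permutation
p-value is at most ``alpha / 2`` (t-test) or ``alpha`` (one-sided F).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import sparse, stats

__all__ = ["Cluster", "ClusterResult", "AnovaResult", "chain_adjacency",
           "grid_product_adjacency", "cluster_perm_ttest",
           "cluster_perm_mixed_anova", "point_anova", "posthoc_tests"]


@dataclass
class Cluster:
    members: np.ndarray     # bin indices
    mass: float             # summed statistic over members
    p: float                # permutation p-value
    sign: int               # +1 / -1 (F clusters: +1)


@dataclass
class ClusterResult:
    clusters: list
    stat_map: np.ndarray
    threshold: float
    cluster_alpha: float
    n_perm: int
    seed: int
    two_sided: bool = True

    def significant(self, alpha: float = 0.05) -> list:
        """Clusters significant at family-wise level ``alpha`` (the
        per-sign criterion is alpha/2 for two-sided tests)."""
        crit = alpha / 2 if self.two_sided else alpha
        return [c for c in self.clusters if c.p <= crit]


@dataclass
class AnovaResult:
    """Per-effect F maps, degrees of freedom and clusters, plus the post
    hoc table."""

    effects: dict
    posthoc: pd.DataFrame | None = None
    n_perm: int = 0
    cluster_alpha: float = 0.01
    seed: int = 0


# ---------------------------------------------------------------------------
# adjacency and clustering
# ---------------------------------------------------------------------------

def chain_adjacency(n: int) -> sparse.csr_matrix:
    """1-D chain adjacency over ``n`` ordered bins."""
    i = np.arange(n - 1)
    rows = np.concatenate([i, i + 1])
    cols = np.concatenate([i + 1, i])
    return sparse.csr_matrix((np.ones(rows.size), (rows, cols)), shape=(n, n))


def grid_product_adjacency(n_freq: int,
                           spatial: sparse.spmatrix | None = None,
                           n_space: int = 1) -> sparse.csr_matrix:
    """Graph product of the frequency chain with a spatial neighbor graph
    (default: a chain over ``n_space`` ordered channels).  Bin index is
    ``space * n_freq + freq``."""
    if spatial is None:
        spatial = chain_adjacency(n_space)
    f_adj = chain_adjacency(n_freq)
    eye_f = sparse.identity(n_freq, format="csr")
    eye_s = sparse.identity(spatial.shape[0], format="csr")
    return (sparse.kron(eye_s, f_adj) + sparse.kron(spatial, eye_f)).tocsr()


def _cluster_sets(mask: np.ndarray,
                  adjacency: sparse.spmatrix | None) -> list[np.ndarray]:
    """Connected suprathreshold sets; chain adjacency when ``None``."""
    if not mask.any():
        return []
    idx = np.flatnonzero(mask)
    if adjacency is None:
        splits = np.where(np.diff(idx) > 1)[0] + 1
        return np.split(idx, splits)
    sub = adjacency[idx][:, idx]
    n_comp, labels = sparse.csgraph.connected_components(sub, directed=False)
    return [idx[labels == c] for c in range(n_comp)]


def _max_mass(stat: np.ndarray, threshold: float,
              adjacency: sparse.spmatrix | None, two_sided: bool) -> float:
    best = 0.0
    for members in _cluster_sets(stat > threshold, adjacency):
        best = max(best, float(stat[members].sum()))
    if two_sided:
        for members in _cluster_sets(-stat > threshold, adjacency):
            best = max(best, float(-stat[members].sum()))
    return best


def _observed_clusters(stat: np.ndarray, threshold: float,
                       adjacency: sparse.spmatrix | None,
                       two_sided: bool) -> list[Cluster]:
    out = []
    for members in _cluster_sets(stat > threshold, adjacency):
        out.append(Cluster(members=members, mass=float(stat[members].sum()),
                           p=np.nan, sign=+1))
    if two_sided:
        for members in _cluster_sets(-stat > threshold, adjacency):
            out.append(Cluster(members=members,
                               mass=float(stat[members].sum()), p=np.nan,
                               sign=-1))
    return out


def _attach_pvalues(clusters: list[Cluster], null: np.ndarray) -> None:
    n_perm = null.size
    for c in clusters:
        c.p = float((1 + np.sum(null >= abs(c.mass))) / (1 + n_perm))
    clusters.sort(key=lambda c: c.p)


# ---------------------------------------------------------------------------
# dependent-samples cluster permutation t-test
# ---------------------------------------------------------------------------

def _paired_t(diffs: np.ndarray, flips: np.ndarray) -> np.ndarray:
    """Paired t maps for sign-flip matrices.  ``diffs`` is (n_sub, n_bins),
    ``flips`` is (n_perm, n_sub) of +/-1; returns (n_perm, n_bins).

    Sign flips leave the per-bin second moment unchanged, so the permuted
    variance follows from the permuted mean alone.
    """
    n = diffs.shape[0]
    m = flips @ diffs / n
    e2 = np.mean(diffs ** 2, axis=0)
    var = np.maximum(e2[None, :] - m ** 2, 0.0) * n / (n - 1)
    with np.errstate(invalid="ignore", divide="ignore"):
        t = m / np.sqrt(var / n)
    return np.nan_to_num(t)


def cluster_perm_ttest(data: np.ndarray,
                       adjacency: sparse.spmatrix | None = None,
                       cluster_alpha: float = 0.01,
                       n_perm: int = 1000,
                       seed: int | np.random.Generator = 0) -> ClusterResult:
    """Dependent-samples cluster permutation t-test.

    Parameters
    ----------
    data : ndarray
        Either (n_subjects, 2, n_bins) condition pairs, from which
        forward-minus-backward differences are formed, or already
        differenced (n_subjects, n_bins).
    adjacency : sparse matrix, optional
        Bin neighborhood; ``None`` means a 1-D chain over the bin order.
    cluster_alpha : float
        Cluster-forming threshold as a two-sided p-value (default 0.01).
    n_perm : int
        Number of random within-subject sign flips (the observed labeling
        is included in the null, so the minimum attainable p is
        ``1 / (1 + n_perm)``).
    """
    data = np.asarray(data, dtype=float)
    if data.ndim == 3:
        if data.shape[1] != 2:
            raise ValueError("expected exactly 2 conditions")
        diffs = data[:, 0] - data[:, 1]
    elif data.ndim == 2:
        diffs = data
    else:
        raise ValueError("data must be (subjects, 2, bins) or (subjects, bins)")
    n_sub, n_bins = diffs.shape
    if n_sub < 2:
        raise ValueError("at least 2 subjects required")
    if adjacency is not None and adjacency.shape[0] != n_bins:
        raise ValueError(
            f"adjacency is {adjacency.shape[0]} bins but data has {n_bins}")
    if n_perm < 100:
        warnings.warn(f"n_perm={n_perm} gives a coarse p-value resolution",
                      UserWarning)
    rng = np.random.default_rng(seed)
    threshold = float(stats.t.ppf(1 - cluster_alpha / 2, df=n_sub - 1))

    t_obs = _paired_t(diffs, np.ones((1, n_sub)))[0]
    clusters = _observed_clusters(t_obs, threshold, adjacency, two_sided=True)

    flips = rng.choice([-1.0, 1.0], size=(n_perm, n_sub))
    t_perm = _paired_t(diffs, flips)
    null = np.fromiter(
        (_max_mass(t_perm[p], threshold, adjacency, True)
         for p in range(n_perm)), dtype=float, count=n_perm)
    _attach_pvalues(clusters, null)
    return ClusterResult(clusters=clusters, stat_map=t_obs,
                         threshold=threshold, cluster_alpha=cluster_alpha,
                         n_perm=n_perm,
                         seed=seed if isinstance(seed, int) else -1)


# ---------------------------------------------------------------------------
# mixed-design 2 x k ANOVA
# ---------------------------------------------------------------------------

def _group_onehot(groups: np.ndarray) -> tuple[np.ndarray, np.ndarray, list]:
    labels = list(dict.fromkeys(groups))
    G = np.stack([groups == g for g in labels]).astype(float)  # (k, N)
    return G, G.sum(axis=1), labels


def _mixed_anova_maps(y: np.ndarray, G: np.ndarray,
                      n_g: np.ndarray) -> dict:
    """Split-plot sums of squares per bin.

    ``y`` is (N, 2, B): N subjects, 2 within-subject modality levels.
    Between-subject factor from the one-hot ``G`` (k, N).  Returns F maps
    and degrees of freedom for the group, modality and interaction effects.
    """
    N = y.shape[0]
    k = G.shape[0]
    s = y.mean(axis=1)           # (N, B) subject means
    d = y[:, 0] - y[:, 1]        # (N, B) modality differences
    mu = s.mean(axis=0)          # (B,)
    mean_g = (G @ s) / n_g[:, None]            # (k, B)
    ss_group = 2.0 * np.sum(n_g[:, None] * (mean_g - mu) ** 2, axis=0)
    ss_subj = 2.0 * np.sum((s - G.T @ mean_g) ** 2, axis=0)
    dbar = d.mean(axis=0)
    dbar_g = (G @ d) / n_g[:, None]
    ss_mod = N * dbar ** 2 / 2.0
    ss_int = np.sum(n_g[:, None] * (dbar_g - dbar) ** 2, axis=0) / 2.0
    ss_ew = np.sum((d - G.T @ dbar_g) ** 2, axis=0) / 2.0
    dfd = N - k
    with np.errstate(invalid="ignore", divide="ignore"):
        f_group = (ss_group / (k - 1)) / (ss_subj / dfd)
        f_mod = ss_mod / (ss_ew / dfd)
        f_int = (ss_int / (k - 1)) / (ss_ew / dfd)
    return {
        "group": (np.nan_to_num(f_group), k - 1, dfd),
        "modality": (np.nan_to_num(f_mod), 1, dfd),
        "interaction": (np.nan_to_num(f_int), k - 1, dfd),
    }


def cluster_perm_mixed_anova(contrasts: np.ndarray, groups,
                             adjacency: sparse.spmatrix | None = None,
                             cluster_alpha: float = 0.01,
                             n_perm: int = 1000,
                             seed: int | np.random.Generator = 0,
                             modality_names: tuple = ("envelope", "lip"),
                             ) -> AnovaResult:
    """Cluster permutation mixed 2 x k ANOVA on condition contrasts.

    ``contrasts`` is (n_subjects, 2 modalities, n_bins); ``groups`` gives
    one between-subject label per subject.  Permutation schemes: the group
    effect permutes group labels across subjects; the modality effect flips
    modality within subjects; the interaction flips modality within
    subjects under fixed groups (an approximate scheme — exact permutation
    for interactions does not exist).  Cluster mass is summed F over
    connected bins exceeding the critical F at ``cluster_alpha``.
    """
    y = np.asarray(contrasts, dtype=float)
    if y.ndim == 2:
        y = y[:, :, None]
    if y.ndim != 3 or y.shape[1] != 2:
        raise ValueError("contrasts must be (subjects, 2 modalities, bins)")
    groups = np.asarray(groups)
    G, n_g, labels = _group_onehot(groups)
    if np.any(n_g < 2):
        raise ValueError("every group needs at least 2 subjects")
    N, _, B = y.shape
    rng = np.random.default_rng(seed)
    maps = _mixed_anova_maps(y, G, n_g)
    d = y[:, 0] - y[:, 1]

    effects = {}
    for name, (f_obs, dfn, dfd) in maps.items():
        thr = float(stats.f.ppf(1 - cluster_alpha, dfn, dfd))
        clusters = _observed_clusters(f_obs, thr, adjacency, two_sided=False)
        null = np.empty(n_perm)
        if name == "group":
            for p in range(n_perm):
                perm = rng.permutation(N)
                f_p = _mixed_anova_maps(y[perm], G, n_g)["group"][0]
                null[p] = _max_mass(f_p, thr, adjacency, False)
        else:
            flips = rng.choice([-1.0, 1.0], size=(n_perm, N))
            for p in range(n_perm):
                d_p = flips[p][:, None] * d
                y_p = np.stack([d_p / 2.0, -d_p / 2.0], axis=1) \
                    + y.mean(axis=1, keepdims=True)
                f_p = _mixed_anova_maps(y_p, G, n_g)[name][0]
                null[p] = _max_mass(f_p, thr, adjacency, False)
        _attach_pvalues(clusters, null)
        effects[name] = {"F": f_obs, "dfn": dfn, "dfd": dfd,
                         "threshold": thr,
                         "result": ClusterResult(
                             clusters=clusters, stat_map=f_obs, threshold=thr,
                             cluster_alpha=cluster_alpha, n_perm=n_perm,
                             seed=seed if isinstance(seed, int) else -1,
                             two_sided=False)}
    post = posthoc_tests(y.mean(axis=2), groups,
                         modality_names=modality_names)
    return AnovaResult(effects=effects, posthoc=post, n_perm=n_perm,
                       cluster_alpha=cluster_alpha,
                       seed=seed if isinstance(seed, int) else -1)


def point_anova(values: np.ndarray, groups,
                modality_names: tuple = ("envelope", "lip")) -> AnovaResult:
    """Parametric mixed 2 x k ANOVA at a single bin / ROI value.

    ``values`` is (n_subjects, 2 modalities); returns per-effect F,
    degrees of freedom and parametric p, plus the post hoc table.
    """
    y = np.asarray(values, dtype=float)
    if y.ndim != 2 or y.shape[1] != 2:
        raise ValueError("values must be (subjects, 2 modalities)")
    groups = np.asarray(groups)
    G, n_g, labels = _group_onehot(groups)
    if np.any(n_g < 2):
        raise ValueError("every group needs at least 2 subjects")
    maps = _mixed_anova_maps(y[:, :, None], G, n_g)
    effects = {}
    for name, (f_map, dfn, dfd) in maps.items():
        f = float(f_map[0])
        effects[name] = {"F": f, "dfn": dfn, "dfd": dfd,
                         "p": float(stats.f.sf(f, dfn, dfd))}
    post = posthoc_tests(y, groups, modality_names=modality_names)
    return AnovaResult(effects=effects, posthoc=post)


def posthoc_tests(values: np.ndarray, groups,
                  modality_names: tuple = ("envelope", "lip")
                  ) -> pd.DataFrame:
    """Post hoc table for the mixed design.

    Within-subject comparison: paired t between the two modalities across
    all subjects.  Between-group comparisons: Welch t (Satterthwaite
    fractional degrees of freedom) on the subject modality means and on the
    modality difference (the interaction contrast).  All p-values
    two-sided and uncorrected.
    """
    y = np.asarray(values, dtype=float)
    if y.ndim != 2 or y.shape[1] != 2:
        raise ValueError("values must be (subjects, 2 modalities)")
    groups = np.asarray(groups)
    labels = list(dict.fromkeys(groups))
    rows = []

    def add(comparison, variant, res):
        df = float(getattr(res, "df", np.nan))
        rows.append({"comparison": comparison, "variant": variant,
                     "t": float(res.statistic), "df": df,
                     "p": float(res.pvalue)})

    a, b = y[:, 0], y[:, 1]
    if np.allclose(a, b):
        rows.append({"comparison": f"{modality_names[0]} vs "
                                   f"{modality_names[1]}",
                     "variant": "paired", "t": 0.0,
                     "df": float(y.shape[0] - 1), "p": 1.0})
    else:
        add(f"{modality_names[0]} vs {modality_names[1]}", "paired",
            stats.ttest_rel(a, b))
    mean_vals = y.mean(axis=1)
    diff_vals = a - b
    for i in range(len(labels)):
        for j in range(i + 1, len(labels)):
            gi, gj = labels[i], labels[j]
            mi, mj = mean_vals[groups == gi], mean_vals[groups == gj]
            di, dj = diff_vals[groups == gi], diff_vals[groups == gj]
            if mi.std() == 0 and mj.std() == 0:
                warnings.warn(f"zero-variance cells in {gi} vs {gj}",
                              UserWarning)
                rows.append({"comparison": f"{gi} vs {gj}",
                             "variant": "welch", "t": np.nan, "df": np.nan,
                             "p": np.nan})
            else:
                add(f"{gi} vs {gj}", "welch",
                    stats.ttest_ind(mi, mj, equal_var=False))
            if di.std() > 0 or dj.std() > 0:
                add(f"{gi} vs {gj} ({modality_names[0]}-{modality_names[1]})",
                    "welch-interaction",
                    stats.ttest_ind(di, dj, equal_var=False))
    return pd.DataFrame(rows)
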