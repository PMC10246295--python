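"""Ancestry matching: genetic PCs, cluster assignment, and greedy
selection of external controls for cases.

Cases define the PC space (PCA of the standardized common-variant
dosage matrix after LD pruning); controls are projected into it and
matched greedily to their nearest case neighbours in top-PC Euclidean
distance, each control used at most once, up to a configurable ratio
per case and within a caliper. The effective sample size
``4 / (1/n_cases + 1/n_controls)`` summarizes the power of the
resulting unbalanced design.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree
from sklearn.cluster import KMeans

from .architecture import effective_sample_size
from .errors import ConfigurationError

__all__ = [
    "PCModel",
    "MatchResult",
    "ld_prune",
    "compute_pcs",
    "project",
    "assign_clusters",
    "match_controls",
    "effective_sample_size",
]


@dataclass
class PCModel:
    """Principal components of a standardized dosage matrix.

    ``loadings`` maps standardized dosages at ``variant_idx`` to PC
    coordinates; ``means`` / ``stds`` are the standardization constants,
    so any sample set can be projected into the same space.
    """

    loadings: np.ndarray  # (n_kept_variants, k)
    eigenvalues: np.ndarray  # (k,)
    variant_idx: np.ndarray  # columns of the source matrix used
    means: np.ndarray
    stds: np.ndarray
    coords: np.ndarray  # (n_samples, k) of the fitting samples


@dataclass
class MatchResult:
    selected_controls: list[str]
    case_clusters: dict[str, int]
    per_cluster_counts: dict[int, tuple[int, int]]  # cluster -> (cases, ctrls)
    effective_n: int
    dropped_clusters: list[int] = field(default_factory=list)


def ld_prune(dosages: np.ndarray, r2_threshold: float = 0.2,
             window: int = 50) -> np.ndarray:
    """Indices of variants surviving windowed r^2 pruning.

    Scans left to right; a variant is dropped when its squared
    correlation with any kept variant in the trailing window exceeds
    the threshold. Constant columns are dropped outright.
    """
    d = np.asarray(dosages, dtype=float)
    sd = d.std(axis=0)
    keep: list[int] = []
    centered = d - d.mean(axis=0)
    for j in range(d.shape[1]):
        if sd[j] == 0:
            continue
        ok = True
        for i in keep[-window:]:
            r = float(centered[:, i] @ centered[:, j]) / (
                len(d) * sd[i] * sd[j])
            if r * r > r2_threshold:
                ok = False
                break
        if ok:
            keep.append(j)
    return np.array(keep, dtype=int)


def compute_pcs(dosages: np.ndarray, n_components: int,
                maf_min: float = 0.05, r2_threshold: float = 0.2) -> PCModel:
    """Top principal components of the standardized genotype matrix.

    Deterministic up to sign; the sign of each component is fixed by
    making its largest-magnitude loading positive.
    """
    d = np.asarray(dosages, dtype=float)
    n = d.shape[0]
    if n < 2:
        raise ConfigurationError("need at least two samples for PCA")
    af = d.mean(axis=0) / 2.0
    maf = np.minimum(af, 1 - af)
    common = np.where(maf >= maf_min)[0]
    if common.size == 0:
        raise ConfigurationError("no variants pass the MAF filter")
    pruned = ld_prune(d[:, common], r2_threshold)
    idx = common[pruned]
    sub = d[:, idx]
    means = sub.mean(axis=0)
    stds = sub.std(axis=0)
    stds[stds == 0] = 1.0
    Z = (sub - means) / stds
    rank = min(n - 1, len(idx))
    if n_components > rank:
        raise ConfigurationError(
            f"requested {n_components} components but rank is {rank}")
    U, S, Vt = np.linalg.svd(Z, full_matrices=False)
    V = Vt[:n_components].T  # (variants, k)
    # sign convention
    for k in range(n_components):
        j = np.argmax(np.abs(V[:, k]))
        if V[j, k] < 0:
            V[:, k] = -V[:, k]
    eigs = (S[:n_components] ** 2) / max(n - 1, 1)
    coords = Z @ V
    return PCModel(V, eigs, idx, means, stds, coords)


def project(model: PCModel, dosages: np.ndarray) -> np.ndarray:
    """Project new samples into an existing PC space."""
    sub = np.asarray(dosages, dtype=float)[:, model.variant_idx]
    Z = (sub - model.means) / model.stds
    return Z @ model.loadings


def assign_clusters(coords: np.ndarray, k: int,
                    seed: int = 0) -> np.ndarray:
    """K-means cluster labels on PC coordinates (seeded, deterministic)."""
    km = KMeans(n_clusters=k, n_init=10, random_state=seed)
    return km.fit_predict(coords)


def match_controls(
    case_coords: np.ndarray,
    control_coords: np.ndarray,
    case_ids: list[str],
    control_ids: list[str],
    max_ratio: int = 4,
    caliper: float | None = None,
    k_clusters: int | None = None,
    seed: int = 0,
) -> MatchResult:
    """Greedy nearest-neighbour selection of controls for cases.

    Controls must already be projected into the case PC space. Matching
    proceeds in rounds: in each round every case (in lexicographic
    sample-id order, for determinism) claims its nearest unused control
    within the caliper. The default caliper is the mean plus two SDs of
    the pairwise case-case distance: wide enough to keep essentially all
    controls drawn from the cases' own ancestry mixture, while excluding
    populations displaced by many SDs. Clusters (k-means on case PCs when
    ``k_clusters`` is given) that end up with zero matched controls are
    dropped from the report with a warning.
    """
    import logging

    log = logging.getLogger(__name__)
    if len(case_coords) == 0 or len(control_coords) == 0:
        raise ConfigurationError("empty case or control set")
    case_coords = np.asarray(case_coords, dtype=float)
    control_coords = np.asarray(control_coords, dtype=float)

    if caliper is None:
        rng = np.random.default_rng(seed)
        n = len(case_coords)
        take = min(n, 500)
        sel = rng.choice(n, take, replace=False)
        from scipy.spatial.distance import pdist
        dists = pdist(case_coords[sel])
        caliper = (float(dists.mean() + 2.0 * dists.std())
                   if len(dists) else np.inf)

    case_order = np.argsort(np.asarray(case_ids))
    used = np.zeros(len(control_coords), dtype=bool)
    selected: list[int] = []
    assigned_to: dict[int, list[int]] = {i: [] for i in range(len(case_ids))}
    tree = cKDTree(control_coords)
    k_query = min(len(control_coords), max_ratio * 8 + 8)
    dist_all, nbr_all = tree.query(case_coords, k=k_query)
    dist_all = np.atleast_2d(dist_all)
    nbr_all = np.atleast_2d(nbr_all)

    for _round in range(max_ratio):
        any_match = False
        for ci in case_order:
            picked = -1
            for d, j in zip(dist_all[ci], nbr_all[ci]):
                if d > caliper:
                    break
                if not used[j]:
                    picked = int(j)
                    break
            if picked < 0:
                # fall back to a fresh query over unused controls
                free = np.where(~used)[0]
                if free.size:
                    diff = control_coords[free] - case_coords[ci]
                    dd = np.sqrt((diff * diff).sum(axis=1))
                    order = np.lexsort((np.asarray(control_ids)[free], dd))
                    jbest = order[0]
                    if dd[jbest] <= caliper:
                        picked = int(free[jbest])
            if picked >= 0:
                used[picked] = True
                selected.append(picked)
                assigned_to[ci].append(picked)
                any_match = True
        if not any_match:
            break

    # cluster bookkeeping
    if k_clusters is not None and len(case_coords) >= k_clusters:
        labels = assign_clusters(case_coords, k_clusters, seed=seed)
    else:
        labels = np.zeros(len(case_coords), dtype=int)
    per_cluster: dict[int, tuple[int, int]] = {}
    dropped = []
    for c in sorted(set(labels.tolist())):
        cases_c = np.where(labels == c)[0]
        n_ctrl = sum(len(assigned_to[i]) for i in cases_c)
        if n_ctrl == 0:
            dropped.append(c)
            log.warning("cluster %d has zero matched controls; dropped", c)
        else:
            per_cluster[c] = (len(cases_c), n_ctrl)
    kept_cases = {i for c, _ in per_cluster.items()
                  for i in np.where(labels == c)[0]}
    case_clusters = {case_ids[i]: int(labels[i]) for i in kept_cases}

    sel_ids = sorted({control_ids[j] for j in selected})
    eff = effective_sample_size(max(len(kept_cases), 1), max(len(sel_ids), 1)) \
        if sel_ids else 0
    return MatchResult(sel_ids, case_clusters, per_cluster, eff, dropped)
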