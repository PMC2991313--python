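"""Voxel-wise group statistics.

Spatially normalized volumes are smoothed (FWHM = 3 x voxel size), compared
voxel-by-voxel with a pooled-variance two-sample t-test, and the resulting
signed p-maps are corrected for multiple testing (Benjamini-Hochberg FDR;
Bonferroni or permutation max-T FWE).  Significant voxels are grouped into
26-connected clusters and filtered by a minimum cluster size.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from skimage import measure

from .core import Volume
from .normalize import smooth_gaussian


@dataclass
class GroupData:
    """Normalized subject volumes with group labels and an analysis mask."""

    volumes: list[Volume]
    labels: list[str]  # "A" or "B" per volume
    analysis_mask: np.ndarray | None = None

    def __post_init__(self):
        if len(self.volumes) != len(self.labels):
            raise ValueError("one label per volume required")
        shapes = {v.shape for v in self.volumes}
        if len(shapes) != 1:
            raise ValueError("all volumes must share one grid")
        groups = set(self.labels)
        if groups != {"A", "B"}:
            raise ValueError("labels must contain exactly groups 'A' and 'B'")
        if min(self.labels.count("A"), self.labels.count("B")) < 2:
            raise ValueError("need at least two subjects per group")
        if self.analysis_mask is None:
            masks = [v.mask for v in self.volumes]
            if all(m is not None for m in masks):
                self.analysis_mask = np.logical_and.reduce(masks)
            else:
                self.analysis_mask = np.ones(self.volumes[0].shape, bool)
        if not self.analysis_mask.any():
            raise ValueError("analysis mask is empty")

    def arrays(self) -> tuple[np.ndarray, np.ndarray]:
        a = np.stack([v.voxels for v, l in zip(self.volumes, self.labels) if l == "A"])
        b = np.stack([v.voxels for v, l in zip(self.volumes, self.labels) if l == "B"])
        return a, b


@dataclass
class StatMaps:
    """t-map plus signed p-maps, corrections, and significant clusters."""

    t_map: np.ndarray
    df: int
    p_pos: np.ndarray  # one-sided, B > A
    p_neg: np.ndarray  # one-sided, B < A
    analysis_mask: np.ndarray
    degenerate_mask: np.ndarray
    q_fdr: np.ndarray | None = None
    p_fwe: np.ndarray | None = None
    cluster_labels: np.ndarray | None = None
    cluster_table: pd.DataFrame | None = None
    fdr_threshold: float | None = None
    fwe_threshold: float | None = None

    @property
    def p_two_sided(self) -> np.ndarray:
        p = 2.0 * np.minimum(self.p_pos, self.p_neg)
        return np.minimum(p, 1.0)


def smooth_group(data: GroupData, fwhm_factor: float = 3.0) -> GroupData:
    """Smooth every subject volume with FWHM = fwhm_factor x spacing."""
    if fwhm_factor == 0:
        return data
    out = []
    for v in data.volumes:
        fwhm = np.asarray(v.spacing) * fwhm_factor
        out.append(smooth_gaussian(v, fwhm))
    return GroupData(out, list(data.labels), data.analysis_mask.copy())


def _pooled_t(a: np.ndarray, b: np.ndarray):
    """Vectorized pooled-variance two-sample t along axis 0 of each stack.

    Returns (t, df, degenerate) where degenerate marks voxels with zero
    pooled variance.
    """
    na, nb = a.shape[0], b.shape[0]
    ma, mb = a.mean(axis=0), b.mean(axis=0)
    ssa = ((a - ma) ** 2).sum(axis=0)
    ssb = ((b - mb) ** 2).sum(axis=0)
    df = na + nb - 2
    sp2 = (ssa + ssb) / df
    degenerate = sp2 <= 0
    denom = np.sqrt(sp2 * (1.0 / na + 1.0 / nb))
    with np.errstate(invalid="ignore", divide="ignore"):
        t = (mb - ma) / denom
    t[degenerate] = 0.0
    return t, df, degenerate


def voxelwise_ttest(data: GroupData) -> StatMaps:
    """Pooled two-sample t at every in-mask voxel; t > 0 means B > A.

    Voxels with zero pooled variance are excluded from all maps (reported in
    ``degenerate_mask``) rather than assigned p = 1, so they do not bias the
    FDR correction's test count.
    """
    a, b = data.arrays()
    t, df, degenerate = _pooled_t(a, b)
    mask = data.analysis_mask & ~degenerate
    p_pos = np.ones_like(t)
    p_neg = np.ones_like(t)
    p_pos[mask] = sps.t.sf(t[mask], df)
    p_neg[mask] = sps.t.cdf(t[mask], df)
    t = np.where(mask, t, 0.0)
    return StatMaps(
        t_map=t,
        df=df,
        p_pos=p_pos,
        p_neg=p_neg,
        analysis_mask=mask,
        degenerate_mask=degenerate & data.analysis_mask,
    )


def fdr_bh(p: np.ndarray, mask: np.ndarray, q: float = 0.05):
    """Benjamini-Hochberg step-up over the in-mask p values.

    Returns ``(threshold, q_map)``: the largest p(k) with p(k) <= k q / m
    (None when no k qualifies) and the monotone step-up adjusted p values
    (1 outside the mask).
    """
    if not 0 < q < 1:
        raise ValueError("q must be in (0, 1)")
    pv = np.asarray(p, dtype=float)[mask]
    m = pv.size
    if m < 1:
        raise ValueError("mask selects no tests")
    order = np.argsort(pv, kind="stable")
    ranked = pv[order]
    ks = np.arange(1, m + 1)
    passing = ranked <= ks * q / m
    threshold = float(ranked[np.nonzero(passing)[0][-1]]) if passing.any() else None
    adj = np.minimum.accumulate((ranked * m / ks)[::-1])[::-1]
    adj = np.minimum(adj, 1.0)
    q_map = np.ones_like(np.asarray(p, dtype=float))
    flat = np.empty(m)
    flat[order] = adj
    q_map[mask] = flat
    return threshold, q_map


def bonferroni(p: np.ndarray, mask: np.ndarray, alpha: float = 0.05):
    """Bonferroni FWE: adjusted p = min(1, m p); threshold alpha/m."""
    m = int(np.count_nonzero(mask))
    p_fwe = np.ones_like(np.asarray(p, dtype=float))
    p_fwe[mask] = np.minimum(1.0, np.asarray(p, dtype=float)[mask] * m)
    return alpha / m, p_fwe


def _distinct_relabelings(na: int, nb: int, limit: int):
    """All index subsets of size na out of na+nb, capped at ``limit``."""
    combos = itertools.combinations(range(na + nb), na)
    return list(itertools.islice(combos, limit + 1))


def fwe_permutation_maxt(
    data: GroupData,
    t_maps: StatMaps,
    n_permutations: int = 1000,
    seed: int = 0,
):
    """Permutation max-T FWE-adjusted p values.

    Group labels are permuted (exhaustively when the number of distinct
    relabelings is at most ``n_permutations``, otherwise by seeded random
    draws); each permutation records the maximum |t| over the mask, and
    p_fwe(v) = (1 + #{max >= |t(v)|}) / (P + 1).  Exact and distribution-free
    under the group-exchangeability null.
    """
    a, b = data.arrays()
    pooled = np.concatenate([a, b], axis=0)
    na = a.shape[0]
    n = pooled.shape[0]
    mask = t_maps.analysis_mask

    combos = _distinct_relabelings(na, n - na, n_permutations)
    exhaustive = len(combos) <= n_permutations
    if exhaustive:
        assignments = combos
    else:
        rng = np.random.default_rng(seed)
        assignments = [
            tuple(np.sort(rng.choice(n, na, replace=False)))
            for _ in range(n_permutations)
        ]
    if len(assignments) < 10:
        import warnings

        warnings.warn("fewer than 10 distinct relabelings; permutation FWE "
                      "is uninformative", stacklevel=2)

    observed = np.abs(t_maps.t_map[mask])
    maxima = np.empty(len(assignments))
    for i, idx_a in enumerate(assignments):
        sel = np.zeros(n, bool)
        sel[list(idx_a)] = True
        t, _, degen = _pooled_t(pooled[sel], pooled[~sel])
        t = np.where(degen, 0.0, t)
        maxima[i] = np.abs(t[mask]).max()

    P = len(assignments)
    counts = (maxima[None, :] >= observed[:, None] - 1e-12).sum(axis=1)
    p_fwe = np.ones_like(t_maps.t_map)
    p_fwe[mask] = (1.0 + counts) / (P + 1.0)
    return p_fwe, maxima


def cluster_filter(
    significant: np.ndarray,
    min_cluster_size: int = 1,
    peak_stat: np.ndarray | None = None,
    connectivity: int = 26,
):
    """26-connected components of a suprathreshold map, size-filtered.

    Returns a labelled volume (labels renumbered 1..K by descending size)
    and a table with one row per surviving cluster: label, size, peak
    statistic, peak voxel index.
    """
    if min_cluster_size < 1:
        raise ValueError("min_cluster_size must be >= 1")
    conn = {6: 1, 18: 2, 26: 3}[connectivity]
    labels = measure.label(np.asarray(significant, bool), connectivity=conn)
    sizes = np.bincount(labels.ravel())
    rows = []
    for lab in range(1, labels.max() + 1):
        if sizes[lab] < min_cluster_size:
            labels[labels == lab] = 0
            continue
        rows.append((lab, int(sizes[lab])))
    rows.sort(key=lambda r: -r[1])
    out_labels = np.zeros_like(labels)
    table_rows = []
    for new, (old, size) in enumerate(rows, start=1):
        sel = labels == old
        out_labels[sel] = new
        if peak_stat is not None:
            stat = np.where(sel, np.abs(peak_stat), -np.inf)
            peak_idx = np.unravel_index(int(np.argmax(stat)), stat.shape)
            peak_val = float(peak_stat[peak_idx])
        else:
            peak_idx, peak_val = (0, 0, 0), float("nan")
        table_rows.append(
            {
                "label": new,
                "size": size,
                "peak_t": peak_val,
                "peak_i": int(peak_idx[0]),
                "peak_j": int(peak_idx[1]),
                "peak_k": int(peak_idx[2]),
            }
        )
    table = pd.DataFrame(
        table_rows, columns=["label", "size", "peak_t", "peak_i", "peak_j", "peak_k"]
    )
    return out_labels, table


def analyze_group(
    data: GroupData,
    fwhm_factor: float = 3.0,
    q_fdr: float = 0.05,
    alpha_fwe: float = 0.05,
    fwe_method: str = "bonferroni",
    min_cluster_size: int = 1,
    alpha_cluster: float | None = None,
    seed: int = 0,
) -> StatMaps:
    """Full statistics step: smooth, t-test, FDR + FWE, cluster filter.

    Clusters are formed from voxels whose two-sided FDR-adjusted p is below
    ``q_fdr`` (or whose uncorrected p is below ``alpha_cluster`` when
    given), then filtered by ``min_cluster_size``.
    """
    smoothed = smooth_group(data, fwhm_factor)
    maps = voxelwise_ttest(smoothed)
    p2 = maps.p_two_sided
    maps.fdr_threshold, maps.q_fdr = fdr_bh(p2, maps.analysis_mask, q_fdr)
    if fwe_method == "bonferroni":
        maps.fwe_threshold, maps.p_fwe = bonferroni(p2, maps.analysis_mask, alpha_fwe)
    elif fwe_method == "permutation":
        maps.p_fwe, _ = fwe_permutation_maxt(smoothed, maps, seed=seed)
        maps.fwe_threshold = alpha_fwe
    else:
        raise ValueError(f"unknown fwe_method {fwe_method!r}")
    if alpha_cluster is not None:
        sig = (p2 < alpha_cluster) & maps.analysis_mask
    else:
        sig = (maps.q_fdr < q_fdr) & maps.analysis_mask
    maps.cluster_labels, maps.cluster_table = cluster_filter(
        sig, min_cluster_size, peak_stat=maps.t_map
    )
    return maps
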