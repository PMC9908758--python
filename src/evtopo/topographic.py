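"""Topographic (microstate-style) analysis of evoked potentials.

The scalp potential map at each instant is treated as the unit of
analysis.  Periods of stable field topography are found by
atomize-and-agglomerate hierarchical clustering (AAHC) of the
group-average topography series; the retained template maps are then
"fitted" back to single-subject data by winner-take-all spatial
correlation, yielding per-map presence (duration) and field strength
(GFP) for factorial statistics.

Polarity convention: evoked potentials — correlations are signed and a
map and its inverse are distinct states.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import CONDITIONS, EvokedDataset

__all__ = [
    "gfp",
    "spatial_correlation",
    "gev",
    "aahc_cluster",
    "select_n_maps",
    "fit_templates",
    "select_window",
    "TemplateMapSet",
    "FittingResult",
    "WindowSelection",
]


def gfp(topo: np.ndarray, axis: int = -1) -> np.ndarray | float:
    """Global field power: population standard deviation over channels."""
    topo = np.asarray(topo, dtype=float)
    if topo.shape[axis] < 2:
        raise ValueError("GFP needs at least 2 channels")
    return np.std(topo, axis=axis)


def spatial_correlation(a: np.ndarray, b: np.ndarray) -> float:
    """Signed Pearson correlation of two topographies across channels."""
    a = np.asarray(a, dtype=float) - np.mean(a)
    b = np.asarray(b, dtype=float) - np.mean(b)
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        raise ValueError("spatial correlation undefined for zero-variance topography")
    return float(np.clip(a @ b / (na * nb), -1.0, 1.0))


def _normalize_rows(X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Centre rows (average reference) and scale to unit norm.

    Zero rows stay zero; their norm is returned as 0.
    """
    Xc = X - X.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(Xc, axis=1)
    out = np.zeros_like(Xc)
    nz = norms > 0
    out[nz] = Xc[nz] / norms[nz, None]
    return out, norms


def gev(data: np.ndarray, maps: np.ndarray, labels: np.ndarray) -> float:
    """Global explained variance of a labelled topography series.

    GEV = sum_t (GFP_t * corr(u_t, map_label(t)))^2 / sum_t GFP_t^2.
    """
    data = np.asarray(data, dtype=float)
    maps = np.asarray(maps, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if labels.shape[0] != data.shape[0]:
        raise ValueError("labels must cover all time points")
    Xn, _ = _normalize_rows(data)
    Mn, mnorm = _normalize_rows(maps)
    if (mnorm == 0).any():
        raise ValueError("zero-variance template map")
    g = gfp(data, axis=1)
    corr = np.einsum("tc,tc->t", Xn, Mn[labels])
    denom = float(np.sum(g**2))
    if denom == 0:
        return 0.0
    return float(np.sum((g * corr) ** 2) / denom)


@dataclass
class TemplateMapSet:
    """q cluster templates with the labelling of the input series.

    maps are unit-GFP (unit-norm after centring); labels are 0-based
    indices into ``maps``; ``segments`` lists maximal half-open runs
    ``(start, end, label)`` in sample indices of the clustered series.
    """

    q: int
    maps: np.ndarray = field(repr=False)
    labels: np.ndarray = field(repr=False)
    gev_total: float
    segments: list[tuple[int, int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not 0.0 <= self.gev_total <= 1.0 + 1e-12:
            raise ValueError("gev_total must be in [0, 1]")
        if self.labels.min() < 0 or self.labels.max() >= self.q:
            raise ValueError("labels out of range")
        if not self.segments:
            self.segments = _label_runs(self.labels)


def _label_runs(labels: np.ndarray) -> list[tuple[int, int, int]]:
    runs = []
    start = 0
    for t in range(1, len(labels) + 1):
        if t == len(labels) or labels[t] != labels[start]:
            runs.append((start, t, int(labels[start])))
            start = t
    return runs


def aahc_cluster(
    data: np.ndarray, q_range: range | list[int] | None = None
) -> dict[int, TemplateMapSet]:
    """Atomize-and-agglomerate hierarchical clustering of topographies.

    ``data`` is (T, n_channels), typically the group-average evoked
    concatenated over conditions.  Starting from one cluster per time
    point, the cluster contributing least to the global explained
    variance is atomized and each freed point reassigned to the
    remaining cluster with the highest (signed) spatial correlation;
    cluster templates are the GFP-weighted means of their members,
    renormalized.  Returns one TemplateMapSet per requested q.
    """
    X = np.asarray(data, dtype=float)
    if X.ndim != 2 or X.shape[0] == 0:
        raise ValueError("data must be a nonempty (T, n_channels) array")
    T, C = X.shape
    q_range = list(q_range) if q_range is not None else list(range(1, min(T, 20) + 1))
    if any(q < 1 or q > T for q in q_range):
        raise ValueError("q_range must lie within [1, T]")
    wanted = set(q_range)

    Xn, norms = _normalize_rows(X)
    g = gfp(X, axis=1)
    gfp_sq_total = float(np.sum(g**2))

    # cluster state: member lists and unit-norm templates
    members: list[list[int]] = [[t] for t in range(T)]
    templates = Xn.copy()
    labels = np.arange(T)

    def snapshot(q: int) -> TemplateMapSet:
        # compact labels in first-appearance order for determinism
        remap: dict[int, int] = {}
        lab = np.empty(T, dtype=int)
        for t in range(T):
            k = labels[t]
            if k not in remap:
                remap[k] = len(remap)
            lab[t] = remap[k]
        maps = np.zeros((q, C))
        for k, new in remap.items():
            maps[new] = templates[k]
        corr = np.einsum("tc,tc->t", Xn, maps[lab])
        total = float(np.sum((g * corr) ** 2) / gfp_sq_total) if gfp_sq_total else 0.0
        return TemplateMapSet(q=q, maps=maps, labels=lab, gev_total=min(total, 1.0))

    out: dict[int, TemplateMapSet] = {}
    active = list(range(T))
    if T in wanted:
        out[T] = snapshot(T)
    while len(active) > 1:
        act = np.array(active)
        corr = np.einsum("tc,tc->t", Xn, templates[labels])
        contrib_all = (g * corr) ** 2
        contrib = np.array([contrib_all[members[k]].sum() for k in act])
        k_min = act[int(np.argmin(contrib))]

        freed = members[k_min]
        active.remove(k_min)
        members[k_min] = []
        rest = np.array(active)
        # reassign each freed point to the best-correlated remaining template
        cmat = Xn[freed] @ templates[rest].T  # signed correlations
        best = rest[np.argmax(cmat, axis=1)]
        touched = set()
        for t, k in zip(freed, best):
            labels[t] = k
            members[k].append(t)
            touched.add(k)
        for k in touched:
            idx = members[k]
            w = (g[idx] * norms[idx])[:, None]  # GFP-weighted (signed) mean
            tpl = (w * Xn[idx]).sum(axis=0) if np.any(w) else X[idx].sum(axis=0)
            tpl = tpl - tpl.mean()
            n = np.linalg.norm(tpl)
            templates[k] = tpl / n if n > 0 else Xn[idx[0]]
        q = len(active)
        if q in wanted:
            out[q] = snapshot(q)
    return {q: out[q] for q in sorted(wanted) if q in out}


def select_n_maps(
    hierarchy: dict[int, TemplateMapSet], gev_threshold: float = 0.90
) -> tuple[int, dict[int, float]]:
    """Smallest q whose solution explains at least ``gev_threshold`` of the
    GFP-weighted variance; a modified Krzanowski-Lai score is returned
    alongside as an advisory diagnostic (never the operative selector).

    KL(q) = |DIFF(q)| / |DIFF(q+1)| with DIFF(q) = (q-1)^(2/p) W_(q-1)
    - q^(2/p) W_q, where W_q is the within-cluster dispersion of the
    normalized topographies (1 - gev as the dispersion proxy on the
    normalized scale).
    """
    if not hierarchy:
        raise ValueError("empty hierarchy")
    qs = sorted(hierarchy)
    gevs = {q: hierarchy[q].gev_total for q in qs}
    candidates = [q for q in qs if gevs[q] >= gev_threshold]
    if not candidates:
        q_star = qs[-1]
        warnings.warn(
            f"no solution reaches GEV >= {gev_threshold}; returning q={q_star}",
            stacklevel=2,
        )
    else:
        q_star = candidates[0]

    p = hierarchy[qs[0]].maps.shape[1]
    W = {q: max(1.0 - gevs[q], 0.0) for q in qs}
    diff = {
        q: (q - 1) ** (2.0 / p) * W[q - 1] - q ** (2.0 / p) * W[q]
        for q in qs
        if q - 1 in W
    }
    kl = {}
    for q in qs:
        if q in diff and q + 1 in diff and abs(diff[q + 1]) > 1e-15:
            kl[q] = abs(diff[q]) / abs(diff[q + 1])
    return q_star, kl


@dataclass
class FittingResult:
    """Per subject x condition x map presence and field strength.

    ``table`` columns: subject, condition, map, n_samples, duration_ms,
    mean_gfp_uv (NaN when a map wins no samples in a cell).
    """

    table: pd.DataFrame
    window_ms: tuple[float, float]
    sfreq: float


def fit_templates(
    evoked: EvokedDataset, maps: np.ndarray, window_ms: tuple[float, float]
) -> FittingResult:
    """Winner-take-all fitting of template maps to single-subject data.

    For every sample of the analysis window the template with the
    highest signed spatial correlation wins (ties break to the lowest
    map index).  Per cell and map: duration = won samples / sfreq, and
    the mean GFP over won samples.  Durations over maps sum exactly to
    the window length in every cell.
    """
    from .sources import window_samples

    maps = np.asarray(maps, dtype=float)
    Mn, mnorm = _normalize_rows(maps)
    if (mnorm == 0).any():
        raise ValueError("zero-variance template map")
    idx = window_samples(evoked.times, window_ms)
    rows = []
    for (subj, cond), wave in sorted(evoked.evoked.items()):
        seg = wave[:, idx].T  # (n_win, C)
        Xn, _ = _normalize_rows(seg)
        corr = Xn @ Mn.T
        winner = np.argmax(corr, axis=1)  # argmax takes the lowest index on ties
        g = gfp(seg, axis=1)
        for m in range(maps.shape[0]):
            won = winner == m
            n = int(won.sum())
            rows.append(
                {
                    "subject": subj,
                    "condition": cond,
                    "map": m,
                    "n_samples": n,
                    "duration_ms": n / evoked.sfreq * 1000.0,
                    "mean_gfp_uv": float(g[won].mean()) if n else np.nan,
                }
            )
    return FittingResult(
        table=pd.DataFrame(rows), window_ms=tuple(window_ms), sfreq=evoked.sfreq
    )


@dataclass
class WindowSelection:
    window_ms: tuple[float, float] | None
    segments_ms: list[tuple[float, float]]
    eligible_ms: list[tuple[float, float]]


def select_window(
    labels_by_condition: dict[str, np.ndarray],
    tct_p_by_condition: dict[str, np.ndarray],
    grand_gfp: np.ndarray,
    times_ms: np.ndarray,
    alpha: float = 0.05,
) -> WindowSelection:
    """Choose the analysis window from clustering segments and the TCT.

    Segments are the maximal runs between any condition's label change
    points.  The selected window is the part of the segment containing
    the global GFP maximum over which every sample is TCT-significant
    (p < alpha) in all conditions — i.e. the overlap of that stable-
    topography segment with the all-conditions consistency window
    around the peak.  Returns ``window_ms=None`` (with a warning) when
    the GFP peak itself is not consistent in all conditions.
    ``eligible_ms`` lists the segments that are consistent throughout.
    """
    conds = [c for c in CONDITIONS if c in labels_by_condition]
    if not conds:
        raise ValueError("no condition labels given")
    T = len(times_ms)
    lab = np.stack([np.asarray(labels_by_condition[c]) for c in conds])
    pmat = np.stack([np.asarray(tct_p_by_condition[c]) for c in conds])
    if lab.shape[1] != T or pmat.shape[1] != T:
        raise ValueError("labels, p-values and time base disagree in length")

    change = np.zeros(T, dtype=bool)
    change[0] = True
    change[1:] = (lab[:, 1:] != lab[:, :-1]).any(axis=0)
    starts = list(np.flatnonzero(change)) + [T]
    dt = float(np.median(np.diff(times_ms))) if T > 1 else 1.0

    def bounds(i0: int, i1: int) -> tuple[float, float]:
        end = times_ms[i1] if i1 < T else times_ms[-1] + dt
        return (float(times_ms[i0]), float(end))

    sig_all = (pmat < alpha).all(axis=0)
    segments, eligible = [], []
    t_peak = int(np.argmax(grand_gfp))
    window = None
    for i0, i1 in zip(starts[:-1], starts[1:]):
        b = bounds(i0, i1)
        segments.append(b)
        if sig_all[i0:i1].all():
            eligible.append(b)
        if i0 <= t_peak < i1 and sig_all[t_peak]:
            lo = t_peak
            while lo > i0 and sig_all[lo - 1]:
                lo -= 1
            hi = t_peak + 1
            while hi < i1 and sig_all[hi]:
                hi += 1
            window = bounds(lo, hi)
    if window is None:
        warnings.warn(
            "no clustering segment is topographically consistent in all "
            "conditions around the GFP peak; no window selected",
            stacklevel=2,
        )
    return WindowSelection(window_ms=window, segments_ms=segments, eligible_ms=eligible)
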