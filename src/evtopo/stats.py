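"""Permutation statistics for the 2x2 within-subject design.

Observed F statistics come from the classical repeated-measures
decomposition (each effect tested against its subject-by-effect
interaction, df = (1, n-1); for a 2x2 design this is the squared paired
t of the per-subject effect contrast).  The null distribution permutes
the four cell labels independently within each subject — the simplest
valid within-subject exchangeability scheme — and one shared schedule
serves all three effects (and, node-wise, all nodes, preserving spatial
coherence).  p = (1 + #{F_perm >= F_obs}) / (1 + n_permutations).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
import scipy.stats

from .containers import CONDITIONS, condition_factors
from .sources import CurrentDensityMap, SourceSpace

__all__ = [
    "EFFECTS",
    "AnovaResult",
    "ClusterResult",
    "cell_matrix",
    "rm_anova_2x2_f",
    "perm_rm_anova_2x2",
    "nodewise_anova",
    "spatial_cluster_filter",
    "posthoc_paired",
    "pearson_correlation",
]

EFFECTS = ("congruency", "synchrony", "interaction")

#: contrast weights over the canonical cell order (CS, CA, IS, IA)
_CONTRASTS = {
    "congruency": np.array([1.0, 1.0, -1.0, -1.0]) / 2.0,
    "synchrony": np.array([1.0, -1.0, 1.0, -1.0]) / 2.0,
    "interaction": np.array([1.0, -1.0, -1.0, 1.0]) / 2.0,
}


def cell_matrix(table: pd.DataFrame, outcome: str) -> tuple[list[str], np.ndarray]:
    """Subjects x 4 cell-value matrix in canonical condition order.

    Accepts tidy tables with either ``congruency``/``synchrony`` columns
    or a ``condition`` column.  Subjects with any missing value in the
    outcome are excluded listwise; structurally missing cells raise.
    """
    df = table.copy()
    if "condition" not in df.columns:
        df["condition"] = [
            f"{c}-{s}" for c, s in zip(df["congruency"], df["synchrony"])
        ]
    df["condition"].map(condition_factors)
    # structurally absent cells (no row at all) are a design error; explicit
    # NaN outcomes are tolerated and handled listwise below
    present = set(zip(df["subject"], df["condition"]))
    structurally = [
        (s, c)
        for s in sorted(df["subject"].unique())
        for c in CONDITIONS
        if (s, c) not in present
    ]
    if structurally:
        raise ValueError(f"incomplete design; missing cells: {structurally}")
    wide = df.pivot_table(
        index="subject", columns="condition", values=outcome, aggfunc="mean"
    )
    wide = wide.reindex(columns=list(CONDITIONS)).dropna(axis=0)
    if wide.empty:
        raise ValueError(f"no complete subjects for outcome {outcome!r}")
    return list(wide.index), wide.to_numpy(dtype=float)


def _contrast_f(Y: np.ndarray, w: np.ndarray) -> tuple[float, float]:
    """F and partial eta^2 for one df=1 within-subject contrast.

    With per-subject contrast scores c_s, SS_effect = n * mean(c)^2 and
    SS_error = sum (c_s - mean)^2 (on the contrast scale), giving
    F = n mean(c)^2 / var(c) and eta2p = SS_e / (SS_e + SS_err).
    """
    c = Y @ w
    n = c.size
    ss_eff = n * c.mean() ** 2
    ss_err = np.sum((c - c.mean()) ** 2)
    F = 0.0 if ss_err == 0 and ss_eff == 0 else ss_eff * (n - 1) / ss_err if ss_err > 0 else np.inf
    eta = ss_eff / (ss_eff + ss_err) if (ss_eff + ss_err) > 0 else 0.0
    return float(F), float(eta)


def rm_anova_2x2_f(Y: np.ndarray) -> dict[str, tuple[float, float]]:
    """Observed (F, partial eta^2) per effect for a (n, 4) cell matrix."""
    Y = np.asarray(Y, dtype=float)
    if Y.ndim != 2 or Y.shape[1] != 4:
        raise ValueError("cell matrix must be (n_subjects, 4)")
    if Y.shape[0] < 3:
        raise ValueError("repeated-measures ANOVA needs at least 3 subjects")
    return {name: _contrast_f(Y, w) for name, w in _CONTRASTS.items()}


def permutation_schedule(
    n_subjects: int, n_permutations: int, seed: int | None
) -> np.ndarray:
    """(n_permutations, n_subjects, 4) within-subject cell relabellings."""
    rng = np.random.default_rng(seed)
    return np.argsort(rng.random((n_permutations, n_subjects, 4)), axis=-1)


def _perm_f(Y: np.ndarray, schedule: np.ndarray) -> dict[str, np.ndarray]:
    """Null F per effect for every permutation of the schedule."""
    Yp = np.take_along_axis(Y[None, :, :], schedule, axis=2)  # (P, n, 4)
    n = Y.shape[0]
    out = {}
    for name, w in _CONTRASTS.items():
        c = Yp @ w  # (P, n)
        mean = c.mean(axis=1)
        ss_err = ((c - mean[:, None]) ** 2).sum(axis=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            F = n * mean**2 * (n - 1) / ss_err
        F[~np.isfinite(F)] = 0.0
        out[name] = F
    return out


@dataclass
class AnovaResult:
    """Permutation repeated-measures 2x2 ANOVA result for one outcome."""

    effects: dict[str, dict] = field(repr=False)
    n_subjects: int = 0
    n_permutations: int = 0
    seed: int | None = None
    outcome: str | None = None

    def __post_init__(self) -> None:
        pmin = 1.0 / (self.n_permutations + 1)
        for name, res in self.effects.items():
            if res["F"] < 0 or not pmin - 1e-12 <= res["p"] <= 1 + 1e-12:
                raise ValueError(f"invalid statistics for effect {name}")

    def __getitem__(self, effect: str) -> dict:
        return self.effects[effect]

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"effect": k, "df1": 1, "df2": self.n_subjects - 1, **v}
            for k, v in self.effects.items()
        ]
        return pd.DataFrame(rows)


def perm_rm_anova_2x2(
    table: pd.DataFrame,
    outcome: str,
    n_permutations: int = 10000,
    seed: int | None = None,
) -> AnovaResult:
    """Permutation 2x2 repeated-measures ANOVA on one outcome column."""
    subjects, Y = cell_matrix(table, outcome)
    obs = rm_anova_2x2_f(Y)
    schedule = permutation_schedule(len(subjects), n_permutations, seed)
    null = _perm_f(Y, schedule)
    effects = {}
    for name, (F, eta) in obs.items():
        p = (1.0 + np.sum(null[name] >= F - 1e-12)) / (1.0 + n_permutations)
        effects[name] = {"F": F, "p": float(p), "eta2p": eta}
    return AnovaResult(
        effects=effects,
        n_subjects=len(subjects),
        n_permutations=n_permutations,
        seed=seed,
        outcome=outcome,
    )


def nodewise_anova(
    maps: CurrentDensityMap,
    n_permutations: int = 1000,
    seed: int | None = None,
    chunk: int = 64,
) -> dict[str, dict[str, np.ndarray]]:
    """Per-node permutation 2x2 ANOVA on current density.

    All nodes share one permutation schedule, so the spatial structure
    of the null is coherent and a fixed seed yields an identical p-map.
    Returns effect -> {"F": (n_nodes,), "p": (n_nodes,)}.
    """
    subjects = sorted({s for s, _ in maps.density})
    data = np.stack(
        [np.stack([maps.density[(s, c)] for c in CONDITIONS], axis=1) for s in subjects]
    )  # (n_subj, n_nodes, 4)
    n, n_nodes, _ = data.shape
    schedule = permutation_schedule(n, n_permutations, seed)
    out = {e: {"F": np.zeros(n_nodes), "p": np.zeros(n_nodes)} for e in EFFECTS}
    for start in range(0, n_nodes, chunk):
        block = data[:, start : start + chunk, :]  # (n, B, 4)
        for name, w in _CONTRASTS.items():
            c_obs = block @ w  # (n, B)
            m = c_obs.mean(axis=0)
            ss_err = ((c_obs - m) ** 2).sum(axis=0)
            with np.errstate(divide="ignore", invalid="ignore"):
                F_obs = n * m**2 * (n - 1) / ss_err
            F_obs[~np.isfinite(F_obs)] = 0.0
            # null: (P, n, B)
            cp = np.einsum(
                "pnkb,k->pnb",
                np.take_along_axis(
                    block.transpose(0, 2, 1)[None], schedule[..., None], axis=2
                ),
                w,
            )
            mp = cp.mean(axis=1)
            ssp = ((cp - mp[:, None, :]) ** 2).sum(axis=1)
            with np.errstate(divide="ignore", invalid="ignore"):
                Fp = n * mp**2 * (n - 1) / ssp
            Fp[~np.isfinite(Fp)] = 0.0
            p = (1.0 + (Fp >= F_obs[None] - 1e-12).sum(axis=0)) / (1.0 + n_permutations)
            sl = slice(start, start + block.shape[1])
            out[name]["F"][sl] = F_obs
            out[name]["p"][sl] = p
    return out


@dataclass
class ClusterResult:
    """Connected components of sub-threshold nodes, filtered by extent."""

    clusters: list[dict]
    threshold_p: float
    min_size: int

    def retained(self) -> list[dict]:
        return [c for c in self.clusters if c["significant"]]


def spatial_cluster_filter(
    pmap: np.ndarray,
    fmap: np.ndarray,
    space: SourceSpace,
    threshold_p: float = 0.05,
    min_size: int = 17,
) -> ClusterResult:
    """Contiguity filter on a node-wise p-map.

    Connected components (under the source-space adjacency) of nodes
    with p < threshold_p; components smaller than ``min_size`` are
    reported but flagged non-significant.
    """
    pmap = np.asarray(pmap, dtype=float)
    fmap = np.asarray(fmap, dtype=float)
    if pmap.shape != (space.n_nodes,):
        raise ValueError("p-map length must match the source space")
    mask = pmap < threshold_p
    clusters: list[dict] = []
    if mask.any():
        sub = space.adjacency[mask][:, mask]
        n_comp, comp = sp.csgraph.connected_components(sub, directed=False)
        node_ids = np.flatnonzero(mask)
        for k in range(n_comp):
            members = node_ids[comp == k]
            clusters.append(
                {
                    "nodes": members.tolist(),
                    "size": int(members.size),
                    "mean_F": float(fmap[members].mean()),
                    "centroid_mm": space.nodes[members].mean(axis=0).tolist(),
                    "significant": bool(members.size >= min_size),
                }
            )
        clusters.sort(key=lambda c: -c["size"])
    return ClusterResult(clusters=clusters, threshold_p=threshold_p, min_size=min_size)


def posthoc_paired(
    table: pd.DataFrame, outcome: str, pairs: list[tuple[str, str]]
) -> pd.DataFrame:
    """Paired t tests with Cohen's d for condition contrasts.

    d = mean(diff) / SD(diff); p is the two-sided t probability.
    Reported uncorrected.
    """
    _, Y = cell_matrix(table, outcome)
    order = {c: i for i, c in enumerate(CONDITIONS)}
    rows = []
    for a, b in pairs:
        diff = Y[:, order[a]] - Y[:, order[b]]
        n = diff.size
        sd = diff.std(ddof=1)
        if sd == 0:
            t = 0.0 if diff.mean() == 0 else np.inf
        else:
            t = diff.mean() / (sd / np.sqrt(n))
        p = float(2 * scipy.stats.t.sf(abs(t), n - 1)) if np.isfinite(t) else 0.0
        d = diff.mean() / sd if sd > 0 else 0.0
        rows.append(
            {"pair": f"{a} vs {b}", "t": float(t), "df": n - 1, "p": p, "d": float(d)}
        )
    return pd.DataFrame(rows)


def pearson_correlation(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Sample Pearson r with the two-sided t-based p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need paired samples with n >= 3")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("correlation undefined for zero-variance input")
    r, p = scipy.stats.pearsonr(x, y)
    return float(r), float(p)
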