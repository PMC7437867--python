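"""Network populations and behavioural comparison statistics.

Linear centered kernel alignment (CKA) compares layer activations across
independently trained networks; a divisive hierarchical clustering check
asks whether a population splits into families; and the behavioural suite
computes RMSE, percent-of-scale, Pearson and partial correlations against
the observer panel, with a bootstrap rating baseline.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import linregress, pearsonr

from .slowfusion import (RELU_LAYERS, SlowFusionConfig, build_network,
                         collect_activations, train)

__all__ = [
    "ComparisonStats",
    "CKAResult",
    "linear_cka",
    "population_train",
    "network_cluster_check",
    "behavior_compare",
    "bootstrap_baseline",
    "rating_variance_explained",
    "partial_correlation",
]


def linear_cka(acts_a: np.ndarray, acts_b: np.ndarray) -> float:
    """Linear CKA between two activation matrices over shared stimuli.

    Columns are centred across observations ('cocktail blank'
    normalization); similarity is ||Xc^T Yc||_F^2 normalized by the
    within-matrix norms.  Invariant to orthogonal transforms and isotropic
    scaling; result in [0, 1].
    """
    X = np.asarray(acts_a, dtype=float)
    Y = np.asarray(acts_b, dtype=float)
    if X.shape[0] != Y.shape[0]:
        raise ValueError("activation matrices must share the stimulus axis")
    if X.shape[0] < 2:
        raise ValueError("CKA needs at least two stimuli")
    Xc = X - X.mean(axis=0)
    Yc = Y - Y.mean(axis=0)
    xx = np.linalg.norm(Xc.T @ Xc)
    yy = np.linalg.norm(Yc.T @ Yc)
    if xx == 0 or yy == 0:
        raise ValueError("all-zero activation matrix after centring; CKA undefined")
    xy = np.linalg.norm(Yc.T @ Xc) ** 2
    return float(xy / (xx * yy))


@dataclass
class CKAResult:
    """Per-layer pairwise CKA across a network population."""

    layers: tuple
    matrices: dict                # layer -> (n_nets, n_nets) similarity matrix

    def summary(self) -> pd.DataFrame:
        rows = []
        for layer in self.layers:
            m = self.matrices[layer]
            iu = np.triu_indices(m.shape[0], k=1)
            vals = m[iu]
            rows.append((layer, vals.mean(), np.percentile(vals, 1),
                         np.percentile(vals, 99)))
        return pd.DataFrame(rows, columns=["layer", "mean", "p01", "p99"])


def population_train(n_networks: int, config: SlowFusionConfig,
                     clips: np.ndarray, labels: np.ndarray,
                     probe_clips: np.ndarray, perceived_targets: np.ndarray,
                     base_seed: int = 0, epochs: int | None = None,
                     lr: float | None = None,
                     layers: tuple = RELU_LAYERS):
    """Train ``n_networks`` instances (different init + batch order, same
    data), compare them layer-wise with CKA on a shared probe set, and pick
    the representative network (lowest RMSE against perceived targets).

    Returns (networks, CKAResult, representative_index).
    """
    if n_networks < 2:
        raise ValueError("a population needs at least two networks")
    nets = []
    for i in range(n_networks):
        seed = int(np.random.SeedSequence([base_seed, i]).generate_state(1)[0] % (2**31))
        net = build_network(config, seed=seed)
        train(net, clips, labels, epochs=epochs, seed=seed + 1, lr=lr)
        nets.append(net)
    acts = {layer: [collect_activations(net, probe_clips, layer).layer_matrix()
                    for net in nets] for layer in layers}
    matrices = {}
    for layer in layers:
        m = np.eye(n_networks)
        for i in range(n_networks):
            for j in range(i + 1, n_networks):
                m[i, j] = m[j, i] = linear_cka(acts[layer][i], acts[layer][j])
        matrices[layer] = m
    rmses = [float(np.sqrt(np.mean((net.predict(probe_clips) - perceived_targets) ** 2)))
             for net in nets]
    rep = int(np.argmin(rmses))
    return nets, CKAResult(layers=tuple(layers), matrices=matrices), rep


# ---------------------------------------------------------------------------
# divisive hierarchical clustering check (DIANA-style)
# ---------------------------------------------------------------------------

def _diana_split(D: np.ndarray, members: np.ndarray):
    """Split one cluster by the classic divisive procedure: seed the
    splinter with the object of largest mean dissimilarity, then move
    objects whose mean dissimilarity to the splinter is smaller than to
    the remainder."""
    if len(members) < 2:
        return members, np.array([], dtype=int)
    sub = D[np.ix_(members, members)]
    splinter = [int(np.argmax(sub.mean(axis=1)))]
    rest = [i for i in range(len(members)) if i not in splinter]
    moved = True
    while moved and len(rest) > 1:
        moved = False
        gains = []
        for i in rest:
            d_rest = np.mean([sub[i, j] for j in rest if j != i])
            d_spl = np.mean([sub[i, j] for j in splinter])
            gains.append(d_rest - d_spl)
        k = int(np.argmax(gains))
        if gains[k] > 0:
            splinter.append(rest.pop(k))
            moved = True
    return members[np.array(rest, dtype=int)], members[np.array(splinter, dtype=int)]


def divisive_clustering(D: np.ndarray, n_clusters: int) -> np.ndarray:
    """DIANA-style divisive hierarchical clustering on a distance matrix."""
    clusters = [np.arange(D.shape[0])]
    while len(clusters) < n_clusters:
        diams = [D[np.ix_(c, c)].max() if len(c) > 1 else -1 for c in clusters]
        target = int(np.argmax(diams))
        if diams[target] <= 0:
            break
        c = clusters.pop(target)
        a, b = _diana_split(D, c)
        clusters.extend([a, b])
    labels = np.empty(D.shape[0], dtype=int)
    for ci, c in enumerate(clusters):
        labels[c] = ci
    return labels


def network_cluster_check(cka_matrix: np.ndarray, max_k: int | None = None,
                          silhouette_threshold: float = 0.25) -> dict:
    """Does a population of networks split into families?

    Takes a pairwise CKA similarity matrix, converts to 1 - CKA distances,
    runs divisive hierarchical clustering for k = 2..max_k, and evaluates
    silhouette and elbow (within-cluster dispersion) criteria.  Verdict
    ``"no significant clustering"`` when the best silhouette stays at or
    below the threshold.
    """
    from sklearn.metrics import silhouette_score

    S = np.asarray(cka_matrix, dtype=float)
    n = S.shape[0]
    if n < 3:
        raise ValueError("need at least three networks")
    if not np.allclose(S, S.T, atol=1e-8):
        raise ValueError("CKA matrix must be symmetric")
    D = 1.0 - S
    np.fill_diagonal(D, 0.0)
    D = np.clip(D, 0.0, None)
    if max_k is None:
        max_k = min(6, n - 1)
    sils, wss, labelings = {}, {}, {}
    for k in range(2, max_k + 1):
        labels = divisive_clustering(D, k)
        if len(np.unique(labels)) < 2:
            continue
        labelings[k] = labels
        sils[k] = float(silhouette_score(D, labels, metric="precomputed"))
        wss[k] = float(sum(D[np.ix_(c, c)].sum() / (2 * len(c))
                           for c in (np.flatnonzero(labels == u)
                                     for u in np.unique(labels))))
    best_k = max(sils, key=sils.get) if sils else None
    best_sil = sils.get(best_k, 0.0) if best_k else 0.0
    verdict = ("no significant clustering" if best_sil <= silhouette_threshold
               else f"{best_k} clusters detected")
    return {
        "verdict": verdict,
        "best_k": best_k,
        "silhouette": sils,
        "elbow_wss": wss,
        "labels": labelings.get(best_k),
    }


# ---------------------------------------------------------------------------
# behavioural statistics
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ComparisonStats:
    rmse: float                   # rating units
    rmse_percent: float           # % of the 16-step scale
    pearson_r: float
    partial_r_vs_human: float     # r(pred, human | physical)
    partial_r_vs_physical: float  # r(pred, physical | human)
    n: int


def partial_correlation(x: np.ndarray, y: np.ndarray, control: np.ndarray) -> float:
    """Pearson correlation of x and y after OLS-residualizing both on the
    control variable (with intercept)."""
    x, y, control = (np.asarray(v, dtype=float) for v in (x, y, control))
    if len(x) < 3:
        raise ValueError("partial correlation needs at least three observations")
    A = np.column_stack([np.ones(len(control)), control])
    rx = x - A @ np.linalg.lstsq(A, x, rcond=None)[0]
    ry = y - A @ np.linalg.lstsq(A, y, rcond=None)[0]
    return float(pearsonr(rx, ry).statistic)


def _average_over_variations(df: pd.DataFrame, value_cols) -> pd.DataFrame:
    return (df.groupby(["scene_class", "viscosity_step"])[list(value_cols)]
            .mean().reset_index())


def behavior_compare(predictions: np.ndarray, human_mean: np.ndarray,
                     physical: np.ndarray, specs=None,
                     average_over_variations: bool = True,
                     scale_steps: int = 16) -> ComparisonStats:
    """Prediction-vs-perception statistics.

    With ``average_over_variations`` (default, requires ``specs``), all
    three series are first averaged within (scene, viscosity step) cells.
    Reports RMSE to the human mean, percent of scale (RMSE / 16 x 100),
    Pearson r, and the two partial-correlation variants: r with the human
    mean controlling for physical truth, and r with physical truth
    controlling for the human mean.
    """
    p = np.asarray(predictions, dtype=float)
    h = np.asarray(human_mean, dtype=float)
    v = np.asarray(physical, dtype=float)
    if average_over_variations:
        if specs is None:
            raise ValueError("averaging over variations requires the design specs")
        df = pd.DataFrame({
            "scene_class": [s.scene_class for s in specs],
            "viscosity_step": [s.viscosity_step for s in specs],
            "p": p, "h": h, "v": v,
        })
        cell = _average_over_variations(df, ("p", "h", "v"))
        p, h, v = cell["p"].values, cell["h"].values, cell["v"].values
    rmse = float(np.sqrt(np.mean((p - h) ** 2)))
    return ComparisonStats(
        rmse=rmse,
        rmse_percent=rmse / scale_steps * 100.0,
        pearson_r=float(pearsonr(p, h).statistic),
        partial_r_vs_human=partial_correlation(p, h, v),
        partial_r_vs_physical=partial_correlation(p, v, h),
        n=len(p),
    )


def bootstrap_baseline(ratings: np.ndarray, human_mean: np.ndarray,
                       n_draws: int = 1000, seed: int = 0,
                       scheme: str = "pooled") -> dict:
    """Chance-level prediction baseline from resampled ratings.

    Each draw assigns every stimulus a rating sampled uniformly (with
    replacement) from the pooled empirical rating distribution
    (``scheme="pooled"``) or a permutation of the per-stimulus means
    (``scheme="permute"``); RMSE and Pearson r against the human mean are
    recorded per draw.
    """
    pool = np.asarray(ratings, dtype=float).ravel()
    h = np.asarray(human_mean, dtype=float)
    if pool.size == 0:
        raise ValueError("empty rating pool")
    if len(h) < 2:
        raise ValueError("need at least two stimuli")
    rng = np.random.default_rng(seed)
    rmses = np.empty(n_draws)
    rs = np.empty(n_draws)
    for i in range(n_draws):
        if scheme == "pooled":
            draw = rng.choice(pool, size=len(h), replace=True)
        elif scheme == "permute":
            draw = rng.permutation(h)
        else:
            raise ValueError(f"unknown bootstrap scheme {scheme!r}")
        rmses[i] = np.sqrt(np.mean((draw - h) ** 2))
        if np.std(draw) == 0 or np.std(h) == 0:
            rs[i] = 0.0
        else:
            rs[i] = pearsonr(draw, h).statistic
    return {
        "rmse_mean": float(rmses.mean()),
        "rmse": rmses,
        "r_mean": float(rs.mean()),
        "r": rs,
        "n_draws": n_draws,
    }


def rating_variance_explained(human_mean: np.ndarray,
                              physical: np.ndarray) -> float:
    """R-squared of a simple linear regression of mean rating on step."""
    lr = linregress(np.asarray(physical, float), np.asarray(human_mean, float))
    return float(lr.rvalue ** 2)
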