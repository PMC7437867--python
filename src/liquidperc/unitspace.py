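"""'Virtual electrophysiology': unit-level analyses.

Each convolutional unit is embedded in an 18-dimensional predictor space
(its unit RDM's Spearman correlation with each predictor RDM), clustered
by Louvain community detection on a k-nearest-neighbour graph, probed by
its extreme stimuli, causally tested by artificial lesions against
size-matched random-lesion nulls, and visualized by activation
maximization.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
from sklearn.manifold import TSNE
from sklearn.neighbors import NearestNeighbors

from . import _nn
from .rsa import RDM, compare_rdms, rdm_from_features
from .slowfusion import ActivationRecord, SlowFusionNet

__all__ = [
    "UnitProfiles",
    "ClusterAssignment",
    "LesionResult",
    "build_predictor_space",
    "cluster_units",
    "cluster_centre",
    "minmax_stimuli",
    "lesion_test",
    "activation_maximize",
    "embed_2d",
]


@dataclass
class UnitProfiles:
    """(n_units, n_predictors) Spearman correlations + bookkeeping."""

    correlations: np.ndarray
    unit_ids: np.ndarray
    predictor_names: tuple

    @property
    def n_units(self) -> int:
        return self.correlations.shape[0]


def build_predictor_space(records: "list[ActivationRecord]",
                          predictor_rdms: "dict[str, RDM]") -> UnitProfiles:
    """Correlate every conv unit's Euclidean RDM with each predictor RDM."""
    names = tuple(predictor_rdms)
    if not names:
        raise KeyError("no predictor RDMs supplied")
    profiles, ids = [], []
    for rec in records:
        for u in range(rec.n_units):
            resp = rec.responses[:, u, :]
            if np.all(resp == resp[0]):
                # dead/constant unit: its RDM is identically zero and rank
                # correlations are undefined; report zero correlations
                row = [0.0] * len(names)
            else:
                unit_rdm = rdm_from_features(resp, "euclidean")
                row = [compare_rdms(unit_rdm, predictor_rdms[nm]).spearman_r
                       for nm in names]
            profiles.append(row)
            ids.append(rec.unit_ids[u])
    return UnitProfiles(correlations=np.array(profiles, dtype=float),
                        unit_ids=np.array(ids), predictor_names=names)


@dataclass
class ClusterAssignment:
    labels: np.ndarray            # community id per unit
    unit_ids: np.ndarray
    k: int
    graph: nx.Graph
    centres: dict                 # community id -> unit id

    @property
    def n_clusters(self) -> int:
        return len(np.unique(self.labels))

    def members(self, cluster: int) -> np.ndarray:
        return self.unit_ids[self.labels == cluster]


def _knn_graph(X: np.ndarray, k: int) -> nx.Graph:
    """kNN graph (Euclidean) with inverse-distance weights in (0, 1]."""
    nn = NearestNeighbors(n_neighbors=k + 1).fit(X)
    dist, idx = nn.kneighbors(X)
    g = nx.Graph()
    g.add_nodes_from(range(len(X)))
    scale = np.median(dist[:, 1:]) + 1e-12
    for i in range(len(X)):
        for d, j in zip(dist[i, 1:], idx[i, 1:]):
            w = 1.0 / (1.0 + d / scale)
            if g.has_edge(i, j):
                g[i][j]["weight"] = max(g[i][j]["weight"], w)
            else:
                g.add_edge(i, j, weight=w)
    return g


def cluster_units(profiles: UnitProfiles, k: int | None = None,
                  resolution: float = 1.0, seed: int = 0) -> ClusterAssignment:
    """Louvain communities on the kNN graph in the full predictor space.

    ``k`` defaults to round(sqrt(n_units)) (k = 20 for the 420 conv units
    of the full-scale network).
    """
    X = profiles.correlations
    n = len(X)
    if k is None:
        k = int(round(np.sqrt(n)))
    if n <= k:
        raise ValueError(f"need more than k={k} units, got {n}")
    if np.allclose(X, X[0]):
        # degenerate geometry: identical profiles form a single community
        g = _knn_graph(X, k)
        assignment = ClusterAssignment(labels=np.zeros(n, dtype=int),
                                       unit_ids=profiles.unit_ids, k=k,
                                       graph=g, centres={})
        assignment.centres = cluster_centre(profiles, assignment)
        return assignment
    g = _knn_graph(X, k)
    comms = nx.community.louvain_communities(g, weight="weight",
                                             resolution=resolution, seed=seed)
    labels = np.empty(n, dtype=int)
    for ci, members in enumerate(sorted(comms, key=lambda s: -len(s))):
        for m in members:
            labels[m] = ci
    assignment = ClusterAssignment(labels=labels, unit_ids=profiles.unit_ids,
                                   k=k, graph=g, centres={})
    assignment.centres = cluster_centre(profiles, assignment)
    return assignment


def cluster_centre(profiles: UnitProfiles, assignment: ClusterAssignment) -> dict:
    """Centre of each cluster: the member with the largest mean graph weight
    to its co-members (absent edges count as weight 0; ties -> lowest id)."""
    centres = {}
    for c in np.unique(assignment.labels):
        members = np.flatnonzero(assignment.labels == c)
        if len(members) == 1:
            centres[int(c)] = int(profiles.unit_ids[members[0]])
            continue
        best, best_w = None, -np.inf
        for m in members:
            ws = [assignment.graph[m][o]["weight"]
                  for o in members if o != m and assignment.graph.has_edge(m, o)]
            mean_w = float(np.sum(ws)) / (len(members) - 1)
            uid = int(profiles.unit_ids[m])
            if mean_w > best_w or (mean_w == best_w and uid < best):
                best, best_w = uid, mean_w
        centres[int(c)] = best
    return centres


def minmax_stimuli(record: ActivationRecord, unit_index: int,
                   pooling: str = "sum") -> tuple[int, int, bool]:
    """Stimulus indices minimally/maximally driving a unit (pooled scalar
    response).  Returns (argmin, argmax, degenerate)."""
    pooled = record.pooled(pooling)[:, unit_index]
    degenerate = bool(np.all(pooled == pooled[0]))
    return int(np.argmin(pooled)), int(np.argmax(pooled)), degenerate


@dataclass(frozen=True)
class LesionResult:
    delta_lesion: float           # RMSE(lesioned) - RMSE(intact), rating units
    null_deltas: np.ndarray       # size-matched random lesions
    z: float
    n_null: int


def lesion_test(net: SlowFusionNet, unit_ids, clips: np.ndarray,
                targets: np.ndarray, n_null: int = 1000, seed: int = 0,
                candidate_units: np.ndarray | None = None) -> LesionResult:
    """Causal importance of a unit set against size-matched random lesions.

    z = (delta_lesion - mean(delta_null)) / sd(delta_null), where delta is
    the change in prediction RMSE against ``targets``.  Null draws are
    uniform subsets (without replacement within a draw) of the conv-unit
    registry (or ``candidate_units``).
    """
    unit_ids = np.atleast_1d(np.asarray(unit_ids, dtype=int))
    targets = np.asarray(targets, dtype=float)
    base_rmse = float(np.sqrt(np.mean((net.predict(clips) - targets) ** 2)))
    lesioned = net.lesioned(unit_ids)
    delta = float(np.sqrt(np.mean((lesioned.predict(clips) - targets) ** 2))) - base_rmse
    pool = (np.asarray(candidate_units) if candidate_units is not None
            else net.registry.conv_unit_ids())
    rng = np.random.default_rng(seed)
    nulls = np.empty(n_null)
    for i in range(n_null):
        draw = rng.choice(pool, size=len(unit_ids), replace=False)
        li = net.lesioned(draw)
        nulls[i] = float(np.sqrt(np.mean((li.predict(clips) - targets) ** 2))) - base_rmse
    sd = nulls.std()
    if sd == 0:
        if delta == 0 and np.all(nulls == 0):
            return LesionResult(delta_lesion=0.0, null_deltas=nulls, z=0.0,
                                n_null=n_null)
        raise ZeroDivisionError("null lesion distribution has zero spread; z undefined")
    z = (delta - nulls.mean()) / sd
    return LesionResult(delta_lesion=delta, null_deltas=nulls, z=float(z),
                        n_null=n_null)


def activation_maximize(net: SlowFusionNet, unit_id: int,
                        seed_clip: np.ndarray | None = None,
                        iterations: int = 2000, step: float = 0.05,
                        noise_sd: float = 0.05, pooling: str = "sum",
                        seed: int = 0):
    """Gradient ascent on the input clip maximizing a unit's pooled response.

    The seed image is the mean clip (or mid-gray) plus Gaussian white
    noise.  Returns (clip, trace, dead): the best-scoring clip (never
    worse than the seed), the activation trace, and a flag for
    zero-gradient (dead) units.
    """
    layer, ch = net.registry.locate(int(unit_id))
    c = net.config
    rng = np.random.default_rng(seed)
    if seed_clip is None:
        seed_clip = np.full((c.frames, c.height, c.width, c.channels), 0.5,
                            dtype=np.float32)
    x = np.clip(seed_clip + rng.normal(0, noise_sd, seed_clip.shape), 0, 1)
    x = x[None].astype(np.float32)

    def objective_and_grad(xb):
        pred, acts, cache = net.forward(xb, capture=(layer,))
        a = acts[layer]
        resp = a[:, ch] if a.ndim == 5 else a[:, ch, None]
        if pooling == "sum":
            obj = float(resp.sum())
            # gradient of the pooled objective w.r.t. the ReLU output is 1
            gact = np.ones_like(a)
        else:
            raise ValueError("only sum pooling is supported for maximization")
        mask = np.zeros_like(a)
        mask[:, ch] = 1.0
        gact *= mask
        gx = _activation_input_grad(net, cache, layer, gact)
        return obj, gx

    obj0, _ = objective_and_grad(x)
    best_x, best_obj = x.copy(), obj0
    trace = [obj0]
    for _ in range(iterations):
        obj, gx = objective_and_grad(x)
        gnorm = float(np.abs(gx).max())
        if gnorm == 0:
            if obj <= 0 and best_obj <= 0:
                return np.clip(seed_clip, 0, 1), np.array(trace), True
            break
        x = np.clip(x + step * gx / gnorm, 0.0, 1.0)
        obj, _ = objective_and_grad(x)
        trace.append(obj)
        if obj > best_obj:
            best_obj, best_x = obj, x.copy()
    return best_x[0], np.array(trace), False


def _activation_input_grad(net: SlowFusionNet, cache: dict, layer: str,
                           gact: np.ndarray) -> np.ndarray:
    """Backpropagate a gradient placed on a captured ReLU layer's
    activations to the input clip, reusing the forward caches."""
    c = net.config

    def stage_back_from_output(tag, gouts):
        """Gradient arriving at the pooled stage outputs."""
        mask = net.masks[{"s1": "relu1", "s2": "relu2", "s3": "relu3"}[tag]]
        gins = []
        for (conv, cc, rm, pc, xshape), go in zip(cache[tag], gouts):
            gr = _nn.maxpool_backward(go, pc)
            gr = gr * mask[None, :, None, None]
            gr = _nn.relu_backward(gr, rm)
            gins.append(conv.backward(gr, cc))
        return gins

    def stage_back_from_relu(tag, g_at_relu):
        """Gradient placed directly on the captured (post-mask) ReLU maps."""
        mask = net.masks[{"s1": "relu1", "s2": "relu2", "s3": "relu3"}[tag]]
        gins = []
        for (conv, cc, rm, pc, xshape), ga in zip(cache[tag], g_at_relu):
            gr = ga * mask[None, :, None, None]
            gr = _nn.relu_backward(gr, rm)
            gins.append(conv.backward(gr, cc))
        return gins

    g3 = g2 = None
    if layer == "relu4":
        g = gact * net.masks["relu4"][None, :]
        g = _nn.relu_backward(g, cache["rm4"])
        g = net.fc4.backward(g, cache["fc4"])
        g3 = stage_back_from_output("s3", [g.reshape(cache["flat_shape"])])
    elif layer == "relu3":
        g3 = stage_back_from_relu("s3", [gact[:, :, i] for i in range(gact.shape[2])])

    if g3 is not None:
        g2 = stage_back_from_output("s2", list(np.split(g3[0], c.n_pathways2, axis=1)))
    elif layer == "relu2":
        g2 = stage_back_from_relu("s2", [gact[:, :, i] for i in range(gact.shape[2])])

    if g2 is not None:
        g1outs = None
        for i, gi in enumerate(g2):
            parts = np.split(gi, c.n_fuse2, axis=1)
            if g1outs is None:
                g1outs = [np.zeros_like(parts[0]) for _ in range(c.n_pathways1)]
            for j, pj in enumerate(parts):
                g1outs[i + j] += pj
        g1 = stage_back_from_output("s1", g1outs)
    else:
        g1 = stage_back_from_relu("s1", [gact[:, :, i] for i in range(gact.shape[2])])

    gx = np.zeros((gact.shape[0], c.frames, c.height, c.width, c.channels),
                  dtype=np.float32)
    for i, gpi in enumerate(g1):
        n, fc_, h, w = gpi.shape
        gwin = gpi.reshape(n, c.t_extent1, c.channels, h, w).transpose(0, 1, 3, 4, 2)
        t0 = i * c.t_stride
        gx[:, t0:t0 + c.t_extent1] += gwin
    return gx


def embed_2d(profiles: UnitProfiles | np.ndarray, seed: int = 0,
             perplexity: float | None = None) -> np.ndarray:
    """t-SNE layout of unit profiles; visualization only, never clustering."""
    X = profiles.correlations if isinstance(profiles, UnitProfiles) else np.asarray(profiles)
    if len(X) < 3:
        raise ValueError("need at least three profiles to embed")
    if perplexity is None:
        perplexity = min(30.0, (len(X) - 1) / 3.0)
    ts = TSNE(n_components=2, random_state=seed, perplexity=perplexity,
              init="pca")
    return ts.fit_transform(X)
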