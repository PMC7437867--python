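"""'Virtual fMRI': layer-level analyses.

Layer RDMs (1 - Pearson over the concatenated unit maps of a ReLU layer)
are correlated with the 18 predictor RDMs; perceived viscosity is decoded
linearly from each layer; FC4 is retrained at reduced widths with the
convolutional prefix frozen (capacity compression); the frozen prefix is
transferred to scene classification; and stimulus activation spaces are
embedded in 2-D, optionally jointly with the controlled reference set.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.manifold import TSNE

from .rsa import RDM, compare_rdms, rdm_from_features, upper_triangle
from .slowfusion import (RELU_LAYERS, SlowFusionNet, collect_activations,
                         fit_linear_decoder, prefix_features, retrain_head,
                         retrain_scene_head)

__all__ = [
    "LayerProfile",
    "CapacityCurve",
    "layer_profile",
    "decoder_curve",
    "capacity_experiment",
    "scene_transfer_compare",
    "stimulus_embedding",
    "DEFAULT_WIDTHS",
]

DEFAULT_WIDTHS = (4096, 1024, 256, 64, 15, 8, 4, 2, 1)


@dataclass
class LayerProfile:
    layer: str
    correlations: dict            # predictor name -> Spearman r
    p_values: dict                # predictor name -> permutation p
    significant: dict             # predictor name -> p < alpha


def layer_profile(layer_matrix: np.ndarray, predictor_rdms: "dict[str, RDM]",
                  layer: str = "", n_permutations: int = 1000,
                  alpha: float = 0.05, seed: int = 0) -> LayerProfile:
    """Spearman correlations of a layer RDM with each predictor RDM.

    ``layer_matrix``: (n_stimuli, n_features) concatenated unit responses.
    The layer RDM uses the 1 - Pearson convention.  Two-sided significance
    comes from permuting stimulus labels of the layer RDM.
    """
    layer_rdm = rdm_from_features(layer_matrix, "one_minus_pearson")
    corrs, pvals, sig = {}, {}, {}
    rng = np.random.default_rng(seed)
    n = layer_rdm.n
    perms = [rng.permutation(n) for _ in range(n_permutations)]
    for name, prdm in predictor_rdms.items():
        r_obs = compare_rdms(layer_rdm, prdm).spearman_r
        corrs[name] = r_obs
        if n_permutations:
            null = np.empty(n_permutations)
            tri_p = prdm.triangle()
            from scipy.stats import spearmanr
            tri_l = layer_rdm.triangle()
            iu = np.triu_indices(n, k=1)
            lv = layer_rdm.values
            for b, perm in enumerate(perms):
                pm = lv[np.ix_(perm, perm)]
                x = pm[iu]
                ok = np.isfinite(x) & np.isfinite(tri_p)
                null[b] = spearmanr(x[ok], tri_p[ok]).statistic
            p = (1 + np.sum(np.abs(null) >= abs(r_obs))) / (1 + n_permutations)
        else:
            p = np.nan
        pvals[name] = float(p)
        sig[name] = bool(p < alpha)
    return LayerProfile(layer=layer, correlations=corrs, p_values=pvals,
                        significant=sig)


def decoder_curve(net: SlowFusionNet, clips: np.ndarray, targets: np.ndarray,
                  layers: tuple = RELU_LAYERS, epochs: int = 800,
                  test_fraction: float = 0.2, seed: int = 0) -> dict:
    """Held-out RMSE of a linear decoder per ReLU layer, plus the full
    network's RMSE on the same held-out split as reference."""
    rng = np.random.default_rng(seed)
    n = len(clips)
    order = rng.permutation(n)
    n_test = max(1, int(round(test_fraction * n)))
    test = order[:n_test]
    out = {}
    for layer in layers:
        rec = collect_activations(net, clips, layer)
        _, rmse = fit_linear_decoder(rec.layer_matrix(), targets,
                                     epochs=epochs, test_fraction=test_fraction,
                                     seed=seed)
        out[layer] = rmse
    preds = net.predict(clips)
    out["network"] = float(np.sqrt(np.mean((preds[test] - np.asarray(targets)[test]) ** 2)))
    return out


@dataclass
class CapacityCurve:
    widths: tuple
    rmses: dict                   # width -> list of per-repeat validation RMSEs
    best_width: int
    best_models: dict             # width -> best RetrainedHead

    def best_rmse(self, width: int) -> float:
        return float(np.min(self.rmses[width]))


def capacity_experiment(net: SlowFusionNet, clips: np.ndarray,
                        labels: np.ndarray, val_clips: np.ndarray,
                        val_targets: np.ndarray,
                        widths: tuple = DEFAULT_WIDTHS, repeats: int = 10,
                        epochs: int = 10, lr: float = 1e-2, seed: int = 0,
                        reference_width: int = 15) -> CapacityCurve:
    """Retrain FC4 at each width (frozen prefix), ``repeats`` times each.

    The prefix forward passes are computed once and shared.  The best run
    per width (validation RMSE against perceived targets) is kept; the
    ``reference_width`` variant is exported for downstream comparisons.
    """
    feats = (prefix_features(net, clips), prefix_features(net, val_clips))
    rmses, best_models = {}, {}
    for w in widths:
        model, rs = retrain_head(net, w, clips, labels, val_clips, val_targets,
                                 repeats=repeats, epochs=epochs, lr=lr,
                                 seed=seed, features=feats)
        rmses[w] = rs
        best_models[w] = model
    return CapacityCurve(widths=tuple(widths), rmses=rmses,
                         best_width=reference_width, best_models=best_models)


def scene_transfer_compare(net: SlowFusionNet, clips: np.ndarray,
                           scene_labels: np.ndarray, val_clips: np.ndarray,
                           val_labels: np.ndarray,
                           widths: tuple = (4096, 15), epochs: int = 8,
                           lr: float = 1e-2, seed: int = 0) -> dict:
    """Scene-classification transfer for full-width and compressed heads.

    Returns width -> (accuracy, mean one-vs-rest AUC, probability matrix).
    """
    feats = (prefix_features(net, clips), prefix_features(net, val_clips))
    out = {}
    for w in widths:
        acc, auc, pmat, _ = retrain_scene_head(
            net, clips, scene_labels, val_clips, val_labels, width=w,
            epochs=epochs, lr=lr, seed=seed, features=feats)
        out[w] = (acc, auc, pmat)
    return out


def stimulus_embedding(activations: np.ndarray,
                       reference_activations: np.ndarray | None = None,
                       seed: int = 0, perplexity: float | None = None
                       ) -> np.ndarray:
    """t-SNE of stimulus activation vectors, optionally jointly with the
    reference set (reference rows appended after the stimulus rows)."""
    X = np.asarray(activations, dtype=float)
    if reference_activations is not None:
        X = np.vstack([X, np.asarray(reference_activations, dtype=float)])
    if perplexity is None:
        perplexity = min(30.0, (len(X) - 1) / 3.0)
    return TSNE(n_components=2, random_state=seed, perplexity=perplexity,
                init="pca").fit_transform(X)
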