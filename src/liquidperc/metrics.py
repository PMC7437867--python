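"""The 18 predictor representations used to interpret network activity.

Fifteen image-computable metrics in four categories (motion, spatial
structure, lightness/colour, multi-feature) plus three high-level
predictors (physical viscosity step, perceived viscosity, scene class).
Each metric maps a 20x64x64x3 clip to a fixed-shape feature array; the
registry records names, categories and shapes.

Motion metrics are built on iterative Lucas-Kanade optical flow
(scikit-image).  Flow is evaluated only inside a liquid mask: the
textureless rendered background gives the flow estimator unconstrained
(noise-driven) solutions, so speeds outside the mask are zeroed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pywt
from scipy import ndimage
from skimage import color as skcolor
from skimage.feature import hog
from skimage.registration import optical_flow_ilk

__all__ = [
    "METRIC_NAMES",
    "MetricRegistry",
    "registry",
    "liquid_mask",
    "optical_flow",
    "flow_gradient",
    "freedman_diaconis_bins",
    "flow_hist",
    "power_spectrum",
    "local_contrast",
    "image_gradient",
    "colour_channels",
    "motion_energy",
    "sift_dense",
    "gist",
    "ps_texture",
    "high_level",
    "compute_image_metrics",
    "HighLevelPredictors",
]

METRIC_NAMES = (
    "of_speed", "of_gradient", "of_speed_hist", "of_gradient_hist",   # motion
    "im_power_spectra", "im_contrast", "im_gradient",                 # spatial
    "s_hsv", "l_lab", "a_lab", "b_lab",                               # lightness/colour
    "motion_energy", "sift", "gist", "texture",                       # multi-feature
    "viscosity", "perceived", "scene",                                # high-level
)

_CATEGORY = {
    "of_speed": "motion", "of_gradient": "motion",
    "of_speed_hist": "motion", "of_gradient_hist": "motion",
    "im_power_spectra": "spatial", "im_contrast": "spatial", "im_gradient": "spatial",
    "s_hsv": "lightness/colour", "l_lab": "lightness/colour",
    "a_lab": "lightness/colour", "b_lab": "lightness/colour",
    "motion_energy": "multi-feature", "sift": "multi-feature",
    "gist": "multi-feature", "texture": "multi-feature",
    "viscosity": "high-level", "perceived": "high-level", "scene": "high-level",
}

_REC709 = np.array([0.2126, 0.7152, 0.0722])


def _gray(clip: np.ndarray) -> np.ndarray:
    """(f, h, w, 3) -> (f, h, w) CIE luminance (Rec. 709 weights)."""
    return clip @ _REC709


@dataclass(frozen=True)
class MetricRegistry:
    """Names, categories, and per-stimulus feature shapes of the metrics."""

    shapes: dict

    @property
    def names(self) -> tuple:
        return METRIC_NAMES

    def category(self, name: str) -> str:
        return _CATEGORY[name]

    def shape(self, name: str):
        return self.shapes[name]

    def manifest(self):
        return [{"name": n, "category": _CATEGORY[n], "shape": self.shapes.get(n)}
                for n in METRIC_NAMES]


def registry(hist_bins: int | None = None) -> MetricRegistry:
    """Registry for 20-frame 64x64 input at default bank settings."""
    shapes = {
        "of_speed": (32, 32, 19),
        "of_gradient": (32, 32, 19),
        "of_speed_hist": (hist_bins, 19),
        "of_gradient_hist": (hist_bins, 19),
        "im_power_spectra": (33, 20),
        "im_contrast": (64, 64, 20),
        "im_gradient": (64, 64, 20),
        "s_hsv": (64, 64, 20),
        "l_lab": (64, 64, 20),
        "a_lab": (64, 64, 20),
        "b_lab": (64, 64, 20),
        "motion_energy": (_ME_BANK_SIZE, 20),
        "sift": (_SIFT_DIM, 20),
        "gist": (512, 20),
        "texture": (_TEXTURE_DIM, 20),
        "viscosity": (1,),
        "perceived": (1,),
        "scene": (1,),
    }
    return MetricRegistry(shapes=shapes)


# ---------------------------------------------------------------------------
# motion metrics
# ---------------------------------------------------------------------------

def liquid_mask(clip: np.ndarray, threshold: float = 0.08) -> np.ndarray:
    """Liquid-region mask: pixels whose time-averaged channel spread
    (a cheap saturation proxy) exceeds a threshold.  Flow is meaningful
    only where the liquid provides texture."""
    spread = (clip.max(axis=3) - clip.min(axis=3)).mean(axis=0)
    return spread > threshold


def optical_flow(clip: np.ndarray, mask: np.ndarray | None = None,
                 radius: int = 5, num_warp: int = 5,
                 frame_pairs: "list[int] | None" = None) -> np.ndarray:
    """Lucas-Kanade flow speed between consecutive frames -> (32, 32, n_pairs).

    Speeds outside the mask are zeroed, then block-averaged to 32x32.
    ``frame_pairs`` selects a subset of the 19 pairs (indices 1..19 of the
    later frame); default all.
    """
    if clip.shape[0] < 2:
        raise ValueError("optical flow needs at least two frames")
    g = _gray(clip)
    if mask is None:
        mask = liquid_mask(clip)
    if mask.shape != g.shape[1:]:
        raise ValueError("mask must match the frame size")
    pairs = frame_pairs if frame_pairs is not None else list(range(1, clip.shape[0]))
    out = np.zeros((32, 32, len(pairs)))
    for k, t in enumerate(pairs):
        v, u = optical_flow_ilk(g[t - 1], g[t], radius=radius, num_warp=num_warp)
        speed = np.hypot(u, v) * mask
        out[:, :, k] = speed.reshape(32, 2, 32, 2).mean(axis=(1, 3))
    return out


def flow_gradient(flow: np.ndarray) -> np.ndarray:
    """Magnitude of the spatial gradient of the flow speed, per pair."""
    gy, gx = np.gradient(flow, axis=(0, 1))
    return np.hypot(gx, gy)


def freedman_diaconis_bins(values: np.ndarray) -> int:
    """Freedman-Diaconis bin count for one stimulus' pooled values."""
    v = np.asarray(values).ravel()
    q75, q25 = np.percentile(v, [75, 25])
    iqr = q75 - q25
    if iqr <= 0:
        return 1
    width = 2 * iqr / len(v) ** (1 / 3)
    return max(1, int(np.ceil((v.max() - v.min()) / width)))


def shared_bin_count(flows: "list[np.ndarray]") -> int:
    """Set-level bin count: rounded mean of per-stimulus FD counts."""
    if not flows:
        raise ValueError("cannot estimate bins from an empty stimulus set")
    return int(round(np.mean([freedman_diaconis_bins(f) for f in flows])))


def flow_hist(flows: "list[np.ndarray]", n_bins: int | None = None
              ) -> tuple[np.ndarray, np.ndarray]:
    """Histograms of flow speed per temporal slice with shared bins.

    Returns (hists, edges): hists has shape (n_stimuli, n_bins, n_pairs);
    edges are shared over the pooled range of the whole set.
    """
    if not flows:
        raise ValueError("cannot histogram an empty stimulus set")
    if n_bins is None:
        n_bins = shared_bin_count(flows)
    lo = min(float(f.min()) for f in flows)
    hi = max(float(f.max()) for f in flows)
    if hi <= lo:
        hi = lo + 1e-12
    edges = np.linspace(lo, hi, n_bins + 1)
    out = np.zeros((len(flows), n_bins, flows[0].shape[2]))
    for i, f in enumerate(flows):
        for t in range(f.shape[2]):
            out[i, :, t], _ = np.histogram(f[:, :, t], bins=edges)
    return out, edges


# ---------------------------------------------------------------------------
# spatial structure
# ---------------------------------------------------------------------------

def power_spectrum(clip: np.ndarray) -> np.ndarray:
    """Rotationally averaged power spectrum per grayscale frame -> (33, 20)."""
    g = _gray(clip)
    f, h, w = g.shape
    fy = np.fft.fftfreq(h) * h
    fx = np.fft.fftfreq(w) * w
    r = np.round(np.hypot(fy[:, None], fx[None, :])).astype(int)
    n_bins = 33
    keep = r < n_bins
    out = np.zeros((n_bins, f))
    counts = np.bincount(r[keep], minlength=n_bins)
    for t in range(f):
        power = np.abs(np.fft.fft2(g[t])) ** 2
        sums = np.bincount(r[keep], weights=power[keep], minlength=n_bins)
        out[:, t] = sums / np.maximum(counts, 1)
    return out


def local_contrast(clip: np.ndarray) -> np.ndarray:
    """3x3 range filter (max - min) on the grayscale frames -> (64, 64, 20)."""
    g = _gray(clip)
    out = np.stack([ndimage.maximum_filter(fr, size=3) - ndimage.minimum_filter(fr, size=3)
                    for fr in g], axis=-1)
    return out


def image_gradient(clip: np.ndarray) -> np.ndarray:
    """Central-difference gradient magnitude per grayscale frame."""
    g = _gray(clip)
    out = np.zeros((g.shape[1], g.shape[2], g.shape[0]))
    for t in range(g.shape[0]):
        gy, gx = np.gradient(g[t])
        out[:, :, t] = np.hypot(gx, gy)
    return out


# ---------------------------------------------------------------------------
# lightness / colour
# ---------------------------------------------------------------------------

def colour_channels(clip: np.ndarray) -> dict[str, np.ndarray]:
    """S (HSV) and L*, a*, b* (CIE 1976, sRGB/D65) maps -> (64, 64, 20) each."""
    s, L, a, b = [], [], [], []
    for fr in clip:
        hsv = skcolor.rgb2hsv(fr)
        lab = skcolor.rgb2lab(fr)
        s.append(hsv[:, :, 1])
        L.append(lab[:, :, 0])
        a.append(lab[:, :, 1])
        b.append(lab[:, :, 2])
    return {
        "s_hsv": np.stack(s, axis=-1),
        "l_lab": np.stack(L, axis=-1),
        "a_lab": np.stack(a, axis=-1),
        "b_lab": np.stack(b, axis=-1),
    }


# ---------------------------------------------------------------------------
# multi-feature models
# ---------------------------------------------------------------------------

_ME_ORIENTS = 4
_ME_SFREQS = (2.0, 4.0)       # cycles per image (at 32 px working size)
_ME_TFREQS = (1.0, 3.0)       # cycles per clip window
_ME_GRID = 2
_ME_BANK_SIZE = _ME_ORIENTS * len(_ME_SFREQS) * len(_ME_TFREQS) * _ME_GRID * _ME_GRID


def _spatial_gabor_bank(size: int = 32):
    ys, xs = np.mgrid[0:size, 0:size] / size - 0.5
    bank = []
    for io in range(_ME_ORIENTS):
        th = np.pi * io / _ME_ORIENTS
        u = xs * np.cos(th) + ys * np.sin(th)
        v = -xs * np.sin(th) + ys * np.cos(th)
        for sf in _ME_SFREQS:
            env = np.exp(-(u ** 2 + v ** 2) / (2 * (0.6 / sf) ** 2))
            bank.append((env * np.cos(2 * np.pi * sf * u),
                         env * np.sin(2 * np.pi * sf * u)))
    return bank


_ME_BANK = None


def motion_energy(clip: np.ndarray) -> np.ndarray:
    """Rectified quadrature spatiotemporal Gabor filter-bank energies.

    Separable bank: spatial Gabor pairs (orientations x spatial
    frequencies) combined with temporal quadrature pairs over a sliding
    window, pooled on a coarse spatial grid -> (bank_size, 20).  The bank
    size is a configuration of this implementation, recorded in the
    registry (the full-scale model's wavelet count came from an external
    implementation's defaults).
    """
    global _ME_BANK
    if _ME_BANK is None:
        _ME_BANK = _spatial_gabor_bank()
    g = _gray(clip)
    f = g.shape[0]
    # downsample to the 32-px working size
    gs = g.reshape(f, 32, 2, 32, 2).mean(axis=(2, 4))
    twin = 8
    ts = np.arange(twin) - (twin - 1) / 2
    tenv = np.exp(-ts ** 2 / (2 * (twin / 4) ** 2))
    out = np.zeros((_ME_BANK_SIZE, f))
    # spatial quadrature responses per frame
    resp = []
    for even, odd in _ME_BANK:
        fe = np.fft.rfft2(even, s=(32, 32))
        fo = np.fft.rfft2(odd, s=(32, 32))
        fg = np.fft.rfft2(gs, s=(32, 32))
        re = np.fft.irfft2(fg * np.conj(fe), s=(32, 32))
        ro = np.fft.irfft2(fg * np.conj(fo), s=(32, 32))
        resp.append((re, ro))
    row = 0
    for re, ro in resp:
        for tf in _ME_TFREQS:
            tc = tenv * np.cos(2 * np.pi * tf * ts / twin)
            tsn = tenv * np.sin(2 * np.pi * tf * ts / twin)
            # temporal filtering with edge padding
            ee = ndimage.convolve1d(re, tc, axis=0, mode="nearest")
            eo = ndimage.convolve1d(re, tsn, axis=0, mode="nearest")
            oe = ndimage.convolve1d(ro, tc, axis=0, mode="nearest")
            oo = ndimage.convolve1d(ro, tsn, axis=0, mode="nearest")
            energy = (ee - oo) ** 2 + (eo + oe) ** 2
            # grid pooling
            pooled = energy.reshape(f, _ME_GRID, 32 // _ME_GRID,
                                    _ME_GRID, 32 // _ME_GRID).mean(axis=(2, 4))
            out[row:row + _ME_GRID * _ME_GRID] = pooled.reshape(f, -1).T
            row += _ME_GRID * _ME_GRID
    return out


_SIFT_DIM = None


def sift_dense(clip: np.ndarray) -> np.ndarray:
    """Dense gradient-orientation descriptors (HOG grid) per frame.

    A dense SIFT-style descriptor: 8-orientation histograms over an 8x8
    cell grid with 2x2 block normalization.  The descriptor length follows
    from these grid choices and is recorded in the registry.
    """
    global _SIFT_DIM
    g = _gray(clip)
    frames = []
    for fr in g:
        frames.append(hog(fr, orientations=8, pixels_per_cell=(8, 8),
                          cells_per_block=(2, 2), feature_vector=True))
    out = np.stack(frames, axis=-1)
    _SIFT_DIM = out.shape[0]
    return out


def _gist_bank(size: int = 64, n_scales: int = 4, n_orients: int = 8):
    fy = np.fft.fftfreq(size)[:, None]
    fx = np.fft.fftfreq(size)[None, :]
    rad = np.hypot(fy, fx) + 1e-9
    theta = np.arctan2(fy, fx)
    bank = []
    for s in range(n_scales):
        f0 = 0.25 / (2 ** s)
        for o in range(n_orients):
            th0 = np.pi * o / n_orients
            dth = np.angle(np.exp(1j * 2 * (theta - th0))) / 2
            tf = np.exp(-((np.log(rad / f0)) ** 2) / (2 * 0.35 ** 2)
                        - (dth ** 2) / (2 * (np.pi / n_orients / 1.2) ** 2))
            bank.append(tf)
    return bank


_GIST_BANK = None


def gist(clip: np.ndarray) -> np.ndarray:
    """GIST descriptor per frame: 32 log-Gabor filters (4 scales x 8
    orientations) pooled on a 4x4 grid -> (512, 20)."""
    global _GIST_BANK
    if _GIST_BANK is None:
        _GIST_BANK = _gist_bank()
    g = _gray(clip)
    f = g.shape[0]
    out = np.zeros((len(_GIST_BANK) * 16, f))
    F = np.fft.fft2(g, axes=(1, 2))
    row = 0
    for tf in _GIST_BANK:
        mag = np.abs(np.fft.ifft2(F * tf[None], axes=(1, 2)))
        pooled = mag.reshape(f, 4, 16, 4, 16).mean(axis=(2, 4))
        out[row:row + 16] = pooled.reshape(f, 16).T
        row += 16
    return out


_TEXTURE_DIM = None


def ps_texture(clip: np.ndarray, levels: int = 3) -> np.ndarray:
    """Texture-statistic descriptor per frame, in the spirit of
    parametric texture-synthesis models: marginal statistics of the image
    and of oriented wavelet subbands, subband magnitude means/variances,
    and cross-scale magnitude correlations, per colour channel luminance.
    Reduced statistic set sized for 64x64 input; length recorded in the
    registry."""
    global _TEXTURE_DIM
    g = _gray(clip)
    frames = []
    for fr in g:
        stats = [fr.mean(), fr.var(), _skew(fr), _kurt(fr), fr.min(), fr.max()]
        coeffs = pywt.wavedec2(fr, "db2", level=levels)
        prev_mags = None
        for lev in coeffs[1:]:
            mags = []
            for band in lev:                     # (cH, cV, cD)
                stats += [band.var(), _skew(band), _kurt(band)]
                m = np.abs(band)
                stats += [m.mean(), m.var()]
                mags.append(m)
            if prev_mags is not None:
                for m_prev, m_cur in zip(prev_mags, mags):
                    a = ndimage.zoom(m_prev, np.array(m_cur.shape) / np.array(m_prev.shape),
                                     order=1)
                    c = np.corrcoef(a.ravel(), m_cur.ravel())[0, 1]
                    stats.append(0.0 if not np.isfinite(c) else c)
            prev_mags = mags
        low = coeffs[0]
        stats += [low.mean(), low.var(), _skew(low), _kurt(low)]
        frames.append(np.array(stats))
    out = np.stack(frames, axis=-1)
    _TEXTURE_DIM = out.shape[0]
    return out


def _skew(x: np.ndarray) -> float:
    x = x.ravel()
    sd = x.std()
    return float(np.mean((x - x.mean()) ** 3) / sd ** 3) if sd > 0 else 0.0


def _kurt(x: np.ndarray) -> float:
    x = x.ravel()
    sd = x.std()
    return float(np.mean((x - x.mean()) ** 4) / sd ** 4) if sd > 0 else 0.0


# ---------------------------------------------------------------------------
# high-level predictors
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class HighLevelPredictors:
    """Single-value predictors: physical step, perceived mean rating, scene."""

    viscosity: np.ndarray     # (n,) physical step, 1..16 linear
    perceived: np.ndarray     # (n,) mean observer rating, 1..16
    scene: np.ndarray         # (n,) scene class labels


def high_level(specs, mean_ratings) -> HighLevelPredictors:
    """Assemble the three high-level predictors for a design.

    ``mean_ratings``: DataFrame from `stimgen.simulate_observers` (or any
    frame keyed by the design columns with a ``mean_rating`` column).
    """
    import pandas as pd

    key_cols = ["scene_class", "viscosity_step", "scene_variation", "optical_variation"]
    table = mean_ratings.set_index(key_cols)["mean_rating"]
    perceived = []
    for s in specs:
        if s.key not in table.index:
            raise KeyError(f"no rating for stimulus {s.key}")
        perceived.append(float(table.loc[s.key]))
    return HighLevelPredictors(
        viscosity=np.array([s.viscosity_step for s in specs], dtype=float),
        perceived=np.array(perceived),
        scene=np.array([s.scene_class for s in specs], dtype=float),
    )


# ---------------------------------------------------------------------------
# batch driver
# ---------------------------------------------------------------------------

def compute_image_metrics(clips: np.ndarray, flow_kwargs: dict | None = None
                          ) -> dict[str, np.ndarray]:
    """All 15 image-computable metrics for a clip batch.

    Returns a dict of per-stimulus feature arrays (first axis = stimulus).
    Histogram metrics use the set-level shared Freedman-Diaconis bins.
    """
    flow_kwargs = flow_kwargs or {}
    flows = [optical_flow(c, **flow_kwargs) for c in clips]
    grads = [flow_gradient(f) for f in flows]
    sh, _ = flow_hist(flows)
    gh, _ = flow_hist(grads)
    feats: dict[str, list | np.ndarray] = {
        "of_speed": np.stack(flows),
        "of_gradient": np.stack(grads),
        "of_speed_hist": sh,
        "of_gradient_hist": gh,
    }
    per_clip = {name: [] for name in
                ("im_power_spectra", "im_contrast", "im_gradient",
                 "s_hsv", "l_lab", "a_lab", "b_lab",
                 "motion_energy", "sift", "gist", "texture")}
    for c in clips:
        per_clip["im_power_spectra"].append(power_spectrum(c))
        per_clip["im_contrast"].append(local_contrast(c))
        per_clip["im_gradient"].append(image_gradient(c))
        cc = colour_channels(c)
        for k, v in cc.items():
            per_clip[k].append(v)
        per_clip["motion_energy"].append(motion_energy(c))
        per_clip["sift"].append(sift_dense(c))
        per_clip["gist"].append(gist(c))
        per_clip["texture"].append(ps_texture(c))
    for k, v in per_clip.items():
        feats[k] = np.stack(v)
    return feats
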