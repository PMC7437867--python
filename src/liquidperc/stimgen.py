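"""Synthetic liquid stimuli and observer ratings.

The study conditions are a factorial design of scene class x viscosity step
x scene variation x optical variation.  Each cell is a 20-frame 64x64 RGB
clip (nominal 30 fps) cut from the tail of a longer 2-D particle simulation
whose motion statistics depend monotonically on a dynamic-viscosity
parameter drawn from a 16-step log-spaced scale (0.001-10 Pa.s).  A
synthetic observer panel rates each clip on the 1-16 linear scale with
scene-dependent accuracy and inter-observer noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

__all__ = [
    "ViscosityScale",
    "StimulusSpec",
    "DesignSummary",
    "ObserverModel",
    "make_design",
    "viscosity_value",
    "simulate_movie",
    "make_reference_set",
    "simulate_observers",
    "FRAMES",
    "HEIGHT",
    "WIDTH",
]

FRAMES = 20
HEIGHT = 64
WIDTH = 64
SIM_STEPS = 120          # internal simulation length; last FRAMES are rendered
N_SCENES = 10
DT = 1.0 / 30.0


@dataclass(frozen=True)
class ViscosityScale:
    """16-step logarithmic dynamic-viscosity scale with linear 1..16 labels."""

    n_steps: int = 16
    min_visc: float = 0.001   # Pa.s
    max_visc: float = 10.0    # Pa.s

    def value(self, step: int) -> float:
        if not 1 <= step <= self.n_steps:
            raise ValueError(f"viscosity step {step} outside 1..{self.n_steps}")
        frac = (step - 1) / (self.n_steps - 1)
        return self.min_visc * (self.max_visc / self.min_visc) ** frac

    def values(self) -> np.ndarray:
        return np.array([self.value(s) for s in range(1, self.n_steps + 1)])


def viscosity_value(step: int, scale: ViscosityScale | None = None) -> float:
    """Dynamic viscosity (Pa.s) of a linear step label on the log scale."""
    return (scale or ViscosityScale()).value(step)


@dataclass(frozen=True)
class StimulusSpec:
    scene_class: int        # 1..10
    viscosity_step: int     # 1..16
    scene_variation: int    # >= 1
    optical_variation: int  # >= 1
    seed: int               # deterministic function of the tuple + global seed

    @property
    def key(self) -> tuple[int, int, int, int]:
        return (self.scene_class, self.viscosity_step,
                self.scene_variation, self.optical_variation)


@dataclass(frozen=True)
class DesignSummary:
    n_stimuli: int
    n_unique_simulations: int
    n_frames: int


def _spec_seed(global_seed: int, *key: int) -> int:
    ss = np.random.SeedSequence([int(global_seed), *[int(k) for k in key]])
    return int(ss.generate_state(1)[0])


def make_design(n_scenes: int = 10, n_viscosities: int = 16,
                n_scene_variations: int = 5, n_optical_variations: int = 1,
                global_seed: int = 0) -> tuple[list[StimulusSpec], DesignSummary]:
    """Enumerate the factorial design, scene-major ordering."""
    for name, v in [("n_scenes", n_scenes), ("n_viscosities", n_viscosities),
                    ("n_scene_variations", n_scene_variations),
                    ("n_optical_variations", n_optical_variations)]:
        if v < 1:
            raise ValueError(f"invalid design: {name}={v} must be >= 1")
    specs = []
    for sc in range(1, n_scenes + 1):
        for st in range(1, n_viscosities + 1):
            for sv in range(1, n_scene_variations + 1):
                for ov in range(1, n_optical_variations + 1):
                    specs.append(StimulusSpec(
                        sc, st, sv, ov, _spec_seed(global_seed, sc, st, sv, ov)))
    summary = DesignSummary(
        n_stimuli=len(specs),
        n_unique_simulations=n_scenes * n_viscosities * n_scene_variations,
        n_frames=len(specs) * FRAMES,
    )
    return specs, summary


# ---------------------------------------------------------------------------
# Scene templates: emitter geometry and forces for ten liquid interactions.
# Each template also places a distinctive static occluder so scene identity
# carries a visual signature independent of the liquid.
# ---------------------------------------------------------------------------

_SCENE_NAMES = {
    1: "pour", 2: "rain", 3: "stir", 4: "dip", 5: "spray",
    6: "splash", 7: "fountain", 8: "waterfall", 9: "drip", 10: "wave",
}


def _template(scene_class: int) -> dict:
    if scene_class not in _SCENE_NAMES:
        raise KeyError(f"unknown scene class {scene_class}; templates defined for 1..10")
    name = _SCENE_NAMES[scene_class]
    base = dict(name=name, emit_rate=4, emit_speed=0.8, occluder=None, swirl=0.0,
                osc=0.0, burst=False)
    if name == "pour":
        base.update(origin=(0.25, 0.08), spread=0.015, direction=(0.25, 1.0),
                    occluder=(0.70, 0.05, 0.12, 0.25))
    elif name == "rain":
        base.update(origin=(0.5, 0.04), spread=0.45, direction=(0.0, 1.0),
                    emit_rate=6, occluder=(0.42, 0.40, 0.16, 0.05))
    elif name == "stir":
        base.update(origin=(0.5, 0.35), spread=0.10, direction=(0.0, 0.4),
                    swirl=3.0, occluder=(0.47, 0.05, 0.06, 0.30))
    elif name == "dip":
        base.update(origin=(0.5, 0.55), spread=0.20, direction=(0.0, 0.2),
                    osc=2.0, occluder=(0.35, 0.15, 0.30, 0.08))
    elif name == "spray":
        base.update(origin=(0.08, 0.15), spread=0.02, direction=(1.0, 0.35),
                    emit_speed=1.3, occluder=(0.08, 0.05, 0.10, 0.10))
    elif name == "splash":
        base.update(origin=(0.5, 0.80), spread=0.06, direction=(0.0, -1.4),
                    emit_speed=1.2, burst=True, occluder=(0.10, 0.70, 0.08, 0.20))
    elif name == "fountain":
        base.update(origin=(0.5, 0.88), spread=0.04, direction=(0.0, -1.8),
                    emit_speed=2.2, emit_rate=6, occluder=(0.44, 0.80, 0.12, 0.12))
    elif name == "waterfall":
        base.update(origin=(0.88, 0.06), spread=0.10, direction=(-0.1, 1.0),
                    emit_rate=6, occluder=(0.80, 0.30, 0.15, 0.06))
    elif name == "drip":
        base.update(origin=(0.3, 0.06), spread=0.005, emit_rate=1,
                    direction=(0.0, 1.0), occluder=(0.60, 0.12, 0.25, 0.05))
    elif name == "wave":
        base.update(origin=(0.5, 0.70), spread=0.35, direction=(0.0, 0.0),
                    emit_rate=6, osc=4.0, occluder=(0.05, 0.40, 0.06, 0.35))
    return base


def scene_templates() -> dict[int, dict]:
    return {sc: _template(sc) for sc in range(1, N_SCENES + 1)}


# viscosity -> dynamics mapping (monotone log-linear law):
#   lam in [0, 1] indexes the log-viscosity scale position;
#   velocity damping rate grows with lam (runny liquids keep momentum),
#   cohesive attraction grows with lam (thick liquids clump),
#   emission speed shrinks with lam (thick liquids pour slowly).
def _dynamics_params(step: int, scale: ViscosityScale) -> dict:
    lam = (step - 1) / (scale.n_steps - 1)
    return dict(
        lam=lam,
        damp_rate=1.5 + 8.0 * lam,      # 1/s
        cohesion=1.0 * lam,             # 1/s^2 toward local centroid
        speed_factor=1.0 / (1.0 + 2.0 * lam),
        motion_scale=1.0 / (1.0 + 4.0 * lam),  # overdamped time scaling
        gravity=1.2,                    # scene units / s^2
    )


def _nuisance_params(global_seed: int, spec: StimulusSpec, canonical: bool):
    """Scene nuisance (emitter/geometry) and optics (palette/noise) draws.

    The scene-nuisance stream is keyed without the viscosity step or optical
    index, so one scene variation shares emitter settings across the whole
    viscosity scale; the optics stream is keyed without the viscosity step,
    so palettes are constant across steps within a variation.
    """
    if canonical:
        scene_n = dict(origin_jitter=(0.0, 0.0), speed_jitter=1.0, size_jitter=1.0)
        optics = dict(
            liquid_rgb=np.array([0.25, 0.45, 0.85]),
            bg_top=0.85, bg_bot=0.55, occ_gray=0.25, noise_sd=0.0,
        )
        return scene_n, optics
    rng_s = np.random.default_rng(
        _spec_seed(global_seed, 101, spec.scene_class, spec.scene_variation))
    scene_n = dict(
        origin_jitter=tuple(rng_s.uniform(-0.06, 0.06, size=2)),
        speed_jitter=rng_s.uniform(0.7, 1.3),
        size_jitter=rng_s.uniform(0.8, 1.2),
    )
    rng_o = np.random.default_rng(
        _spec_seed(global_seed, 202, spec.scene_class, spec.scene_variation,
                   spec.optical_variation))
    hue = rng_o.uniform(0, 1)
    import colorsys
    liquid_rgb = np.array(colorsys.hsv_to_rgb(hue, rng_o.uniform(0.4, 0.9),
                                              rng_o.uniform(0.5, 0.95)))
    optics = dict(
        liquid_rgb=liquid_rgb,
        bg_top=rng_o.uniform(0.6, 0.95),
        bg_bot=rng_o.uniform(0.35, 0.65),
        occ_gray=rng_o.uniform(0.1, 0.4),
        noise_sd=rng_o.uniform(0.002, 0.010),
    )
    return scene_n, optics


def _simulate_particles(spec: StimulusSpec, tpl: dict, dyn: dict, scene_n: dict,
                        rng: np.random.Generator) -> list[np.ndarray]:
    """Run the 2-D particle simulation; return per-step position arrays."""
    max_p = tpl["emit_rate"] * SIM_STEPS + 400
    pos = np.zeros((max_p, 2))
    vel = np.zeros((max_p, 2))
    n_active = 0
    ox = tpl["origin"][0] + scene_n["origin_jitter"][0]
    oy = tpl["origin"][1] + scene_n["origin_jitter"][1]
    d = np.array(tpl["direction"], dtype=float)
    emit_speed = tpl["emit_speed"] * scene_n["speed_jitter"] * dyn["speed_factor"]
    spread = tpl["spread"] * scene_n["size_jitter"]
    retention = np.exp(-dyn["damp_rate"] * DT)
    frames_pos = []

    def burst(n0: int) -> None:
        nonlocal n_active
        if n_active + n0 > max_p:
            return
        sl = slice(n_active, n_active + n0)
        pos[sl, 0] = ox + rng.uniform(-spread, spread, n0)
        pos[sl, 1] = oy + rng.uniform(-0.02, 0.02, n0)
        ang = rng.uniform(-1.3, 1.3, n0)
        vel[sl, 0] = emit_speed * np.sin(ang)
        vel[sl, 1] = d[1] * emit_speed * np.abs(np.cos(ang))
        n_active += n0

    for t in range(SIM_STEPS):
        if tpl["burst"]:
            if t % 50 == 0:
                burst(80)
        else:
            k = tpl["emit_rate"]
            if tpl["name"] == "drip" and t % 4 != 0:
                k = 0
            if k and n_active + k <= max_p:
                sl = slice(n_active, n_active + k)
                pos[sl, 0] = ox + rng.uniform(-spread, spread, k)
                pos[sl, 1] = oy + rng.uniform(-0.01, 0.01, k)
                vel[sl] = d * emit_speed + rng.normal(0, 0.08, (k, 2))
                n_active += k
        p = pos[:n_active]
        v = vel[:n_active]
        if n_active:
            v[:, 1] += dyn["gravity"] * DT
            if tpl["swirl"]:
                rel = p - np.array([0.5, 0.55])
                v[:, 0] += -tpl["swirl"] * rel[:, 1] * DT * dyn["speed_factor"]
                v[:, 1] += tpl["swirl"] * rel[:, 0] * DT * dyn["speed_factor"]
            if tpl["osc"]:
                v[:, 0] += 0.8 * np.sin(tpl["osc"] * t * DT * 2 * np.pi) * DT * 30
            if dyn["cohesion"] and n_active > 3:
                v += dyn["cohesion"] * (p.mean(axis=0) - p) * DT
            v *= retention
            p += v * DT * dyn["motion_scale"]
            # container walls and floor; impacts splash back with jitter
            # proportional to impact speed, so runny liquids stay agitated
            for axis, lo, hi in ((0, 0.03, 0.97), (1, 0.02, 0.92)):
                low = p[:, axis] < lo
                high = p[:, axis] > hi
                p[low, axis] = lo
                p[high, axis] = hi
                hit = low | high
                if np.any(hit):
                    impact = np.abs(v[hit, axis])
                    v[hit, axis] *= -0.5
                    v[hit, 1 - axis] += rng.normal(0, 0.6, hit.sum()) * impact
        if t >= SIM_STEPS - FRAMES:
            frames_pos.append(p.copy())
    return frames_pos


def _render(frames_pos: list[np.ndarray], tpl: dict, optics: dict,
            rng: np.random.Generator) -> np.ndarray:
    clip = np.zeros((FRAMES, HEIGHT, WIDTH, 3), dtype=np.float64)
    ramp = np.linspace(optics["bg_top"], optics["bg_bot"], HEIGHT)[:, None]
    bg = np.repeat(ramp, WIDTH, axis=1)
    occ = tpl["occluder"]
    for f, p in enumerate(frames_pos):
        frame = np.repeat(bg[:, :, None], 3, axis=2).copy()
        if occ is not None:
            x0, y0, w, h = occ
            r0, r1 = int(y0 * HEIGHT), int((y0 + h) * HEIGHT)
            c0, c1 = int(x0 * WIDTH), int((x0 + w) * WIDTH)
            frame[r0:r1, c0:c1, :] = optics["occ_gray"]
        if len(p):
            hist, _, _ = np.histogram2d(p[:, 1], p[:, 0], bins=(HEIGHT, WIDTH),
                                        range=[[0, 1], [0, 1]])
            dens = gaussian_filter(hist, sigma=1.3)
            alpha = 1.0 - np.exp(-7.0 * dens)
            frame = frame * (1 - alpha[:, :, None]) + optics["liquid_rgb"] * alpha[:, :, None]
        if optics["noise_sd"]:
            frame = frame + rng.normal(0, optics["noise_sd"], frame.shape)
        clip[f] = frame
    return np.clip(clip, 0.0, 1.0).astype(np.float32)


def simulate_movie(spec: StimulusSpec, scale: ViscosityScale | None = None,
                   global_seed: int = 0, canonical: bool = False) -> np.ndarray:
    """Render one 20x64x64x3 clip for a stimulus specification.

    The clip is the tail of a longer (120-step) internal particle
    simulation; the same spec and global seed reproduce it bit-exactly.
    """
    scale = scale or ViscosityScale()
    tpl = _template(spec.scene_class)
    dyn = _dynamics_params(spec.viscosity_step, scale)
    scene_n, optics = _nuisance_params(global_seed, spec, canonical)
    rng = np.random.default_rng(spec.seed)
    frames_pos = _simulate_particles(spec, tpl, dyn, scene_n, rng)
    render_rng = np.random.default_rng(
        _spec_seed(global_seed, 303, *spec.key, spec.viscosity_step))
    return _render(frames_pos, tpl, optics, render_rng)


def simulate_design(specs: list[StimulusSpec], scale: ViscosityScale | None = None,
                    global_seed: int = 0) -> np.ndarray:
    """Render every spec in a design; returns (n, 20, 64, 64, 3)."""
    return np.stack([simulate_movie(s, scale, global_seed) for s in specs])


def make_reference_set(scale: ViscosityScale | None = None, global_seed: int = 0
                       ) -> tuple[list[StimulusSpec], np.ndarray]:
    """The controlled reference set: scenes x viscosity steps, all nuisance
    parameters held at canonical values (one clip per cell, 160 at defaults)."""
    scale = scale or ViscosityScale()
    specs = []
    clips = []
    for sc in range(1, N_SCENES + 1):
        for st in range(1, scale.n_steps + 1):
            spec = StimulusSpec(sc, st, 0, 0, _spec_seed(global_seed, sc, st, 0, 0))
            specs.append(spec)
            clips.append(simulate_movie(spec, scale, global_seed, canonical=True))
    return specs, np.stack(clips)


# ---------------------------------------------------------------------------
# Observer model
# ---------------------------------------------------------------------------

# Per-scene response distortions (gain, compressive exponent, bias, extra
# noise multiplier).  Calibrated once so that, with the default noise terms,
# the panel lands in the regime of the behavioural data being emulated
# (true-step R^2 on mean ratings ~ 0.68; individual-vs-mean RMSE ~ 12% of
# the 16-step scale).  Scenes differ in rating quality by construction.
_SCENE_GAIN = {1: 1.00, 2: 0.88, 3: 0.80, 4: 0.42, 5: 1.00,
               6: 0.45, 7: 0.85, 8: 0.70, 9: 0.55, 10: 0.92}
_SCENE_GAMMA = {1: 1.00, 2: 1.35, 3: 0.70, 4: 0.45, 5: 1.05,
                6: 2.10, 7: 0.85, 8: 1.60, 9: 0.55, 10: 1.10}
_SCENE_BIAS = {1: 0.0, 2: -0.8, 3: 1.2, 4: 3.5, 5: 0.0,
               6: 2.5, 7: 0.6, 8: -1.0, 9: 2.8, 10: 0.3}
_SCENE_NOISE = {1: 0.8, 2: 1.1, 3: 1.0, 4: 1.5, 5: 0.8,
                6: 1.6, 7: 1.0, 8: 1.2, 9: 1.3, 10: 1.0}


@dataclass(frozen=True)
class ObserverModel:
    """Synthetic rating panel with scene-dependent accuracy.

    Mean rating for scene s at step v is
    ``1 + 15 * gain_s * ((v-1)/15) ** gamma_s + bias_s`` plus an observer
    bias (SD ``observer_bias_sd``) and trial noise (SD ``trial_noise_sd``
    times the scene noise multiplier), clipped to [1, 16].  With unit
    gains/exponents and all bias and noise terms zero the panel is the
    identity on the step scale.
    """

    n_observers: int = 16
    observer_bias_sd: float = 1.4
    trial_noise_sd: float = 3.8
    scene_gain: dict = field(default_factory=lambda: dict(_SCENE_GAIN))
    scene_gamma: dict = field(default_factory=lambda: dict(_SCENE_GAMMA))
    scene_bias: dict = field(default_factory=lambda: dict(_SCENE_BIAS))
    scene_noise: dict = field(default_factory=lambda: dict(_SCENE_NOISE))

    @classmethod
    def noiseless(cls, n_observers: int = 16) -> "ObserverModel":
        unit = {s: 1.0 for s in range(1, N_SCENES + 1)}
        zero = {s: 0.0 for s in range(1, N_SCENES + 1)}
        return cls(n_observers=n_observers, observer_bias_sd=0.0,
                   trial_noise_sd=0.0, scene_gain=dict(unit),
                   scene_gamma=dict(unit), scene_bias=dict(zero),
                   scene_noise=dict(zero))

    def mean_response(self, scene: int, step: float, n_steps: int = 16) -> float:
        g = self.scene_gain.get(scene, 1.0)
        gam = self.scene_gamma.get(scene, 1.0)
        b = self.scene_bias.get(scene, 0.0)
        frac = (step - 1) / (n_steps - 1)
        return 1.0 + (n_steps - 1) * g * frac ** gam + b


def simulate_observers(specs: list[StimulusSpec], scale: ViscosityScale | None = None,
                       model: ObserverModel | None = None, seed: int = 0
                       ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """One rating per observer per stimulus, plus the per-stimulus mean table.

    Returns ``(records, means)``: records with columns (observer_id,
    scene_class, viscosity_step, scene_variation, optical_variation,
    rating); means indexed like the design with a ``mean_rating`` column.
    """
    if not specs:
        raise ValueError("design is empty")
    scale = scale or ViscosityScale()
    model = model or ObserverModel()
    if model.n_observers < 1:
        raise ValueError("observer model needs at least one observer")
    rng = np.random.default_rng(seed)
    obs_bias = rng.normal(0.0, model.observer_bias_sd, model.n_observers)
    rows = []
    for spec in specs:
        mu = model.mean_response(spec.scene_class, spec.viscosity_step, scale.n_steps)
        noise_sd = model.trial_noise_sd * model.scene_noise.get(spec.scene_class, 1.0)
        noise = (rng.normal(0.0, noise_sd, model.n_observers) if noise_sd > 0
                 else np.zeros(model.n_observers))
        ratings = np.clip(mu + obs_bias + noise, 1.0, scale.n_steps)
        for i in range(model.n_observers):
            rows.append((i + 1, *spec.key, float(ratings[i])))
    records = pd.DataFrame(rows, columns=[
        "observer_id", "scene_class", "viscosity_step",
        "scene_variation", "optical_variation", "rating"])
    means = (records.groupby(["scene_class", "viscosity_step",
                              "scene_variation", "optical_variation"])["rating"]
             .mean().rename("mean_rating").reset_index())
    return records, means
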