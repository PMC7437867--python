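"""Shared fixtures.

The expensive end-to-end fixture (`trained_session`) generates the
desk-scale stimulus set, simulates the observer panel, and trains the
reduced slow-fusion network once per session; the parameter-recovery and
scaled-down replication suites all read from it.
"""

from __future__ import annotations

import numpy as np
import pytest

from liquidperc import slowfusion as sf
from liquidperc import stimgen as sg

# Reduced desk-scale architecture/optimizer settings used across the suite.
DESK_CONFIG = dict(channels1=12, channels2=12, channels3=12, fc4=32,
                   stride1=4, pool1=2, pool2=1, pool3=1, dropout=0.0,
                   batch_size=16, momentum=0.8, l2=4e-9, max_grad_norm=1.0)
DESK_LR = 1e-2
DESK_EPOCHS = 30
GLOBAL_SEED = 11


@pytest.fixture(scope="session")
def tiny_cfg():
    """Very small network for fast unit tests."""
    return sf.SlowFusionConfig(channels1=6, channels2=6, channels3=6, fc4=8,
                               stride1=4, pool1=2, pool2=1, pool3=1,
                               dropout=0.0, batch_size=8, momentum=0.8)


@pytest.fixture(scope="session")
def small_clipset():
    """16 clips spanning 2 scenes x 4 viscosity steps x 2 variations."""
    specs, _ = sg.make_design(2, 4, 2, 1, global_seed=3)
    clips = np.stack([sg.simulate_movie(s, global_seed=3) for s in specs])
    return specs, clips


@pytest.fixture(scope="session")
def trained_session():
    """Desk-scale study: ~1,920 clips, observer panel, 30-epoch training."""
    specs, _ = sg.make_design(10, 16, 12, 1, global_seed=GLOBAL_SEED)
    clips = np.stack([sg.simulate_movie(s, global_seed=GLOBAL_SEED)
                      for s in specs])
    labels = np.array([s.viscosity_step for s in specs], dtype=np.float32)
    records, means = sg.simulate_observers(specs, seed=GLOBAL_SEED)
    mtab = means.set_index(["scene_class", "viscosity_step", "scene_variation",
                            "optical_variation"])["mean_rating"]
    perceived = np.array([float(mtab.loc[s.key]) for s in specs])

    rng = np.random.default_rng(0)
    order = rng.permutation(len(clips))
    val, tr = order[:320], order[320:]
    cfg = sf.SlowFusionConfig(**DESK_CONFIG)
    net = sf.build_network(cfg, seed=1)
    history = sf.train(net, clips[tr], labels[tr], clips[val], labels[val],
                       perceived[val], epochs=DESK_EPOCHS, seed=2, lr=DESK_LR)
    return {
        "specs": specs,
        "clips": clips,
        "labels": labels,
        "records": records,
        "perceived": perceived,
        "train_idx": tr,
        "val_idx": val,
        "net": net,
        "config": cfg,
        "history": history,
    }
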