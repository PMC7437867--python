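"""Unit-level analyses: predictor space, clustering, lesions, maximization."""

import numpy as np
import pytest
from sklearn.metrics import adjusted_rand_score

from liquidperc import rsa, slowfusion as sf, stimgen as sg, unitspace as us


def make_profiles(X, ids=None):
    return us.UnitProfiles(correlations=np.asarray(X, float),
                           unit_ids=np.asarray(ids if ids is not None
                                               else np.arange(len(X))),
                           predictor_names=tuple(f"p{i}" for i in range(X.shape[1])))


@pytest.fixture(scope="module")
def blobs():
    rng = np.random.default_rng(0)
    a = rng.normal(0, 0.1, (50, 18))
    b = rng.normal(0, 0.1, (50, 18)) + 1.0     # 10 sigma separation
    return np.vstack([a, b]), np.array([0] * 50 + [1] * 50)


class TestPredictorSpace:
    def test_profile_count_and_self_match(self, small_clipset):
        specs, clips = small_clipset
        net = sf.build_network(sf.SlowFusionConfig(
            channels1=6, channels2=6, channels3=6, fc4=8, stride1=4,
            pool1=2, pool2=1, pool3=1, dropout=0.0), seed=0)
        records = [sf.collect_activations(net, clips, l)
                   for l in ("relu1", "relu2", "relu3")]
        # predictors: physical step + a synthetic predictor equal to one
        # unit's own responses (self-match construction)
        steps = np.array([s.viscosity_step for s in specs], float)
        self_feat = records[0].responses[:, 2, :]
        prdms = {
            "viscosity": rsa.rdm_from_features(steps[:, None]),
            "self": rsa.rdm_from_features(self_feat),
        }
        profiles = us.build_predictor_space(records, prdms)
        assert profiles.n_units == 18     # 6 + 6 + 6 conv units
        idx_self = list(profiles.predictor_names).index("self")
        assert profiles.correlations[2, idx_self] >= 0.99
        assert np.all(np.abs(profiles.correlations) <= 1.0 + 1e-9)

    def test_shuffled_control_unit_uncorrelated(self, small_clipset):
        specs, clips = small_clipset
        rng = np.random.default_rng(1)
        steps = np.array([s.viscosity_step for s in specs], float)
        prdm = {"viscosity": rsa.rdm_from_features(steps[:, None])}
        corrs = []
        for _ in range(20):
            fake = rng.permutation(np.linspace(0, 1, len(specs)))[:, None]
            rec = sf.ActivationRecord(layer="relu1",
                                      responses=fake[:, None, :],
                                      unit_ids=np.array([0]))
            p = us.build_predictor_space([rec], prdm)
            corrs.append(p.correlations[0, 0])
        assert np.all(np.abs(corrs) <= 0.35)
        assert abs(np.mean(corrs)) <= 0.1

    def test_missing_predictors_rejected(self):
        with pytest.raises(KeyError):
            us.build_predictor_space([], {})


class TestClustering:
    def test_default_k_rule(self):
        assert int(round(np.sqrt(420))) == 20

    def test_planted_blobs_recovered(self, blobs):
        X, truth = blobs
        assign = us.cluster_units(make_profiles(X), seed=0)
        assert assign.n_clusters == 2
        assert adjusted_rand_score(truth, assign.labels) == 1.0

    def test_recovery_across_seeds(self, blobs):
        """ARI >= 0.9 for well-separated blobs over ten seeds."""
        X, truth = blobs
        for seed in range(10):
            assign = us.cluster_units(make_profiles(X), seed=seed)
            assert adjusted_rand_score(truth, assign.labels) >= 0.9

    def test_identical_profiles_single_community(self):
        X = np.tile(np.linspace(0, 1, 18), (30, 1))
        assign = us.cluster_units(make_profiles(X), k=5, seed=0)
        assert assign.n_clusters == 1

    def test_too_few_units(self):
        X = np.random.default_rng(0).random((5, 18))
        with pytest.raises(ValueError):
            us.cluster_units(make_profiles(X), k=10)

    def test_every_unit_assigned_once(self, blobs):
        X, _ = blobs
        assign = us.cluster_units(make_profiles(X), seed=0)
        assert len(assign.labels) == len(X)
        assert set(assign.centres) == set(np.unique(assign.labels))


class TestCentres:
    def test_singleton_cluster_centre(self):
        X = np.vstack([np.zeros(18), np.ones(18) * 5, np.ones(18) * 5.1])
        profiles = make_profiles(X, ids=[10, 11, 12])
        assign = us.cluster_units(profiles, k=1, seed=0)
        for c, members in ((c, assign.members(c)) for c in assign.centres):
            if len(members) == 1:
                assert assign.centres[c] == members[0]

    def test_centre_maximizes_mean_weight(self):
        # three units on a line: the middle one is closest to both others
        X = np.zeros((3, 18))
        X[0, 0], X[1, 0], X[2, 0] = 0.0, 1.0, 2.0
        profiles = make_profiles(X, ids=[7, 8, 9])
        assign = us.cluster_units(profiles, k=2, seed=0)
        assert assign.n_clusters == 1
        assert assign.centres[0] == 8

    def test_centre_membership(self, blobs):
        X, _ = blobs
        profiles = make_profiles(X)
        assign = us.cluster_units(profiles, seed=0)
        for c, centre in assign.centres.items():
            assert centre in assign.members(c)


class TestMinMax:
    def test_luminance_ordered_argmax(self):
        # a unit responding to mean luminance: brightest stimulus wins
        lum = np.linspace(0.1, 0.9, 10)
        rec = sf.ActivationRecord(layer="relu1",
                                  responses=lum[:, None, None] * np.ones((10, 1, 4)),
                                  unit_ids=np.array([0]))
        lo, hi, degenerate = us.minmax_stimuli(rec, 0)
        assert (lo, hi, degenerate) == (0, 9, False)

    def test_constant_unit_degenerate(self):
        rec = sf.ActivationRecord(layer="relu1",
                                  responses=np.ones((5, 1, 3)),
                                  unit_ids=np.array([0]))
        assert us.minmax_stimuli(rec, 0)[2] is True

    def test_argmax_invariant_to_rescaling(self):
        rng = np.random.default_rng(0)
        resp = rng.random((8, 1, 5))
        rec = sf.ActivationRecord(layer="relu1", responses=resp,
                                  unit_ids=np.array([0]))
        rec2 = sf.ActivationRecord(layer="relu1", responses=3.5 * resp,
                                   unit_ids=np.array([0]))
        assert us.minmax_stimuli(rec, 0)[:2] == us.minmax_stimuli(rec2, 0)[:2]


@pytest.fixture(scope="module")
def toy_setup():
    """Tiny trained net + eval clips; targets are its own predictions
    so the intact model is exactly calibrated."""
    cfg = sf.SlowFusionConfig(channels1=6, channels2=6, channels3=6, fc4=8,
                              stride1=4, pool1=2, pool2=1, pool3=1,
                              dropout=0.0, batch_size=8, momentum=0.8)
    net = sf.build_network(cfg, seed=5)
    rng = np.random.default_rng(2)
    clips = rng.random((24, 20, 64, 64, 3)).astype(np.float32)
    y = np.linspace(1, 16, 24).astype(np.float32)
    sf.train(net, clips, y, epochs=20, seed=0, lr=3e-3)
    return net, clips, net.predict(clips)


class TestLesionTest:

    def test_planted_critical_unit(self, toy_setup):
        """One hand-planted critical unit among 50 redundant ones: z >= 3."""
        _, clips, _ = toy_setup
        cfg = sf.SlowFusionConfig(channels1=6, channels2=6, channels3=51,
                                  fc4=8, stride1=4, pool1=2, pool2=1, pool3=1,
                                  dropout=0.0)
        planted = sf.build_network(cfg, seed=5)
        # rewire FC4 + output so the prediction reads (almost) only stage-3
        # channel 2; the other 50 stage-3 units are redundant by construction
        ch = 2
        flat_per_ch = planted.flat_dim // cfg.channels3
        planted.fc4.W[:] = 0.001
        planted.fc4.W[0, ch * flat_per_ch:(ch + 1) * flat_per_ch] = 1.0
        planted.out.W[:] = 0.01
        planted.out.W[0, 0] = 1.0
        targets = planted.predict(clips)
        relu3_ids = planted.registry.unit_ids("relu3")
        critical = int(relu3_ids[ch])
        res = us.lesion_test(planted, [critical], clips, targets,
                             n_null=100, seed=0, candidate_units=relu3_ids)
        assert res.z >= 3.0

    def test_redundant_units_low_z(self, toy_setup):
        net, clips, targets = toy_setup
        rng = np.random.default_rng(3)
        pool = net.registry.conv_unit_ids()
        zs = []
        for seed in range(10):
            uid = rng.choice(pool)
            res = us.lesion_test(net, [uid], clips, targets, n_null=60, seed=seed)
            zs.append(res.z)
        assert np.mean(np.abs(np.array(zs)) <= 2.0) >= 0.9

    def test_null_reproducible(self, toy_setup):
        net, clips, targets = toy_setup
        a = us.lesion_test(net, [1], clips, targets, n_null=20, seed=4)
        b = us.lesion_test(net, [1], clips, targets, n_null=20, seed=4)
        assert np.array_equal(a.null_deltas, b.null_deltas)

    def test_empty_lesion_delta_zero(self, toy_setup):
        net, clips, targets = toy_setup
        res = us.lesion_test(net, np.array([], dtype=int)[:0].reshape(0),
                             clips, targets, n_null=20, seed=0)
        assert res.delta_lesion == pytest.approx(0.0)


@pytest.fixture(scope="module")
def maxim_net():
    cfg = sf.SlowFusionConfig(channels1=6, channels2=6, channels3=6, fc4=8,
                              stride1=4, pool1=2, pool2=1, pool3=1,
                              dropout=0.0)
    return sf.build_network(cfg, seed=9)


class TestActivationMaximization:

    def test_default_iteration_budget(self):
        import inspect
        sig = inspect.signature(us.activation_maximize)
        assert sig.parameters["iterations"].default == 2000

    def test_activation_never_below_seed(self, maxim_net):
        for uid in (0, int(maxim_net.registry.unit_ids("relu3")[0])):
            clip, trace, dead = us.activation_maximize(maxim_net, uid,
                                                       iterations=30, seed=1)
            if not dead:
                assert trace.max() >= trace[0]

    def test_improves_over_seed(self, maxim_net):
        uid = int(maxim_net.registry.unit_ids("relu1")[1])
        clip, trace, dead = us.activation_maximize(maxim_net, uid,
                                                   iterations=50, seed=2)
        assert not dead
        assert trace.max() > trace[0]

    def test_deterministic(self, maxim_net):
        a = us.activation_maximize(maxim_net, 0, iterations=10, seed=3)
        b = us.activation_maximize(maxim_net, 0, iterations=10, seed=3)
        assert np.array_equal(a[0], b[0])

    def test_dead_unit_flagged(self, maxim_net):
        import copy
        dead_net = sf.lesion_units(maxim_net, [2])
        clip, trace, dead = us.activation_maximize(dead_net, 2, iterations=5,
                                                   seed=0)
        assert dead


class TestEmbedding:
    def test_row_count_and_determinism(self):
        rng = np.random.default_rng(0)
        X = rng.random((40, 18))
        a = us.embed_2d(make_profiles(X), seed=1)
        b = us.embed_2d(make_profiles(X), seed=1)
        assert a.shape == (40, 2)
        assert np.array_equal(a, b)

    def test_duplicate_profiles_near_coincident(self):
        rng = np.random.default_rng(1)
        X = rng.random((30, 18))
        X[7] = X[3]
        emb = us.embed_2d(make_profiles(X), seed=0)
        d_dup = np.linalg.norm(emb[7] - emb[3])
        from scipy.spatial.distance import pdist
        assert d_dup <= np.percentile(pdist(emb), 5)

    def test_too_few_profiles(self):
        with pytest.raises(ValueError):
            us.embed_2d(make_profiles(np.ones((2, 18))))
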