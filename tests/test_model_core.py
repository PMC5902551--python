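import numpy as np
import pytest

from editnet import (
    CandidateSNV,
    ClassLabel,
    Component,
    EnsembleNet,
    EnsembleSpec,
    IndividualNet,
    IndividualNetSpec,
    MotifModel,
    ScoreTriple,
    SingleCellModule,
    SingleCellModuleSpec,
    TrainingConfig,
    assemble_model,
    average_probabilities,
    balanced_bootstrap,
    call_editing_sites,
    derive_seed,
    generate_dataset,
    kfold_split,
    load_model,
    position_importance,
    roc_auc,
    save_model,
    score_candidates,
    train_component,
    train_ensemble,
    train_individual_net,
)
from editnet.model_core import crop_centre
from editnet.sequence_windows import SequenceWindow, one_hot_encode

from conftest import desk_config

FAST = TrainingConfig(epochs=10)


def toy_net(input_flank, seed):
    """A deterministic untrained net with fixed random weights."""
    rng = np.random.default_rng(seed)
    dims = [(2 * input_flank + 1) * 4, 8, 3]
    weights = [rng.normal(size=(a, b)) for a, b in zip(dims, dims[1:])]
    biases = [rng.normal(size=b) for b in dims[1:]]
    return IndividualNet(IndividualNetSpec(input_flank, (8,), seed=seed), weights, biases)


def random_windows(n, flank, seed):
    rng = np.random.default_rng(seed)
    return rng.integers(0, 2, size=(n, 2 * flank + 1, 4)).astype(np.float32)


# ---------------------------------------------------------------------------
# Sampling
# ---------------------------------------------------------------------------

class TestBalancedBootstrap:
    def test_exactly_equal_class_counts(self):
        y = np.array([0] * 1000 + [1] * 5000 + [2] * 20000)
        idx = balanced_bootstrap(y, 1000, seed=3)
        assert idx.size == 3000
        assert np.bincount(y[idx]).tolist() == [1000, 1000, 1000]

    def test_single_draw_per_class(self):
        y = np.array([0, 1, 2, 2])
        assert balanced_bootstrap(y, 1, seed=0).size == 3

    def test_seed_reproducibility(self):
        y = np.array([0] * 10 + [1] * 10 + [2] * 10)
        a = balanced_bootstrap(y, 5, seed=42)
        b = balanced_bootstrap(y, 5, seed=42)
        assert np.array_equal(a, b)
        assert not np.array_equal(a, balanced_bootstrap(y, 5, seed=43))

    def test_absent_class_named(self):
        with pytest.raises(ValueError, match="SNP"):
            balanced_bootstrap(np.array([0, 0, 2]), 2, seed=0)


class TestKFold:
    def test_partition_properties(self):
        y = np.array(([0] * 40) + ([1] * 35) + ([2] * 25))
        folds = kfold_split(y, 5, seed=1)
        assert len(folds) == 5
        all_test = np.concatenate([te for _, te in folds])
        assert sorted(all_test) == list(range(100))
        for _, te in folds:
            assert te.size == 20
            # class proportions within ±1 of the global 8/7/5 split
            counts = np.bincount(y[te], minlength=3)
            assert np.all(np.abs(counts - np.array([8, 7, 5])) <= 1)

    def test_reproducible(self):
        y = np.repeat([0, 1, 2], 10)
        a = kfold_split(y, 2, seed=9)
        b = kfold_split(y, 2, seed=9)
        assert all(np.array_equal(x[1], y2[1]) for x, y2 in zip(a, b))

    def test_k_bounds(self):
        with pytest.raises(ValueError):
            kfold_split(np.array([0, 1, 2]), 1, seed=0)


# ---------------------------------------------------------------------------
# Nets and averaging
# ---------------------------------------------------------------------------

class TestIndividualNet:
    def test_input_dimensions_by_scale(self):
        assert IndividualNetSpec(input_flank=50).input_dim == 404
        assert IndividualNetSpec(input_flank=20).input_dim == 164

    def test_trained_first_layer_shape_and_simplex(self):
        X = random_windows(60, 4, seed=0)
        y = np.repeat([0, 1, 2], 20)
        net = train_individual_net(X, y, IndividualNetSpec(4, (12,), seed=1), FAST)
        assert net.weights[0].shape == ((2 * 4 + 1) * 4, 12)
        p = net.predict_proba(X)
        assert np.allclose(p.sum(axis=1), 1.0, atol=1e-9)

    def test_deterministic_given_seed(self):
        X = random_windows(60, 3, seed=0)
        y = np.repeat([0, 1, 2], 20)
        spec = IndividualNetSpec(3, (8,), seed=7)
        a = train_individual_net(X, y, spec, FAST)
        b = train_individual_net(X, y, spec, FAST)
        assert all(np.array_equal(w1, w2) for w1, w2 in zip(a.weights, b.weights))

    def test_missing_class_errors(self):
        X = random_windows(10, 3, seed=0)
        with pytest.raises(ValueError, match="missing"):
            train_individual_net(X, np.zeros(10, dtype=int), IndividualNetSpec(3, (8,)), FAST)

    def test_empty_training_set_errors(self):
        with pytest.raises(ValueError):
            train_individual_net(np.zeros((0, 7, 4)), np.zeros(0, dtype=int),
                                 IndividualNetSpec(3, (8,)), FAST)


class TestAveraging:
    def test_componentwise_mean(self):
        out = average_probabilities([(0.2, 0.3, 0.5), (0.4, 0.1, 0.5)])
        assert out == pytest.approx((0.3, 0.2, 0.5))

    def test_singleton_and_copies(self):
        t = (0.1, 0.2, 0.7)
        assert average_probabilities([t]) == pytest.approx(t)
        assert average_probabilities([t] * 5) == pytest.approx(t)

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            average_probabilities([])

    def test_hierarchy_average_equals_flat_leaf_mean(self):
        """Averaging members then modules equals the equal-weight mean over
        all leaves when module sizes match (2×2 toy hierarchy)."""
        nets = [toy_net(3, s) for s in range(4)]
        X = random_windows(5, 3, seed=9)
        comp = Component([
            # modules built as single-scale, two-member ensembles
            SingleCellModule({3: EnsembleNet(nets[:2])}),
            SingleCellModule({3: EnsembleNet(nets[2:])}),
        ])
        flat = np.mean([n.predict_proba(X) for n in nets], axis=0)
        assert np.allclose(comp.predict_proba(X), flat, atol=1e-12)


# ---------------------------------------------------------------------------
# Hierarchy structure
# ---------------------------------------------------------------------------

class TestHierarchy:
    def test_ensemble_member_count_and_distinct_weights(self):
        X = random_windows(90, 3, seed=1)
        y = np.repeat([0, 1, 2], 30)
        spec = EnsembleSpec(n_members=3, member_spec=IndividualNetSpec(3, (8,)))
        ens = train_ensemble(X, y, spec, FAST, seed=0)
        assert len(ens.members) == 3
        w0 = [m.weights[0] for m in ens.members]
        assert not np.array_equal(w0[0], w0[1])

    def test_single_member_ensemble_equals_member(self):
        X = random_windows(60, 3, seed=2)
        y = np.repeat([0, 1, 2], 20)
        spec = EnsembleSpec(n_members=1, member_spec=IndividualNetSpec(3, (8,)))
        ens = train_ensemble(X, y, spec, FAST, seed=0)
        assert np.allclose(ens.predict_proba(X), ens.members[0].predict_proba(X))

    def test_module_scales_and_crop_symmetry(self, trained_module):
        assert set(trained_module.scales) == {25, 10}
        assert sum(len(e.members) for e in trained_module.scale_ensembles.values()) == 4

    def test_crop_keeps_centre_base(self):
        X = random_windows(4, 10, seed=3)
        cropped = crop_centre(X, 4)
        assert cropped.shape == (4, 9, 4)
        assert np.array_equal(cropped[:, 4, :], X[:, 10, :])

    def test_window_narrower_than_scale_errors(self):
        with pytest.raises(ValueError, match="narrower"):
            crop_centre(random_windows(2, 3, seed=0), 5)

    def test_component_order_invariance(self):
        nets = [toy_net(2, s) for s in range(2)]
        mods = [SingleCellModule({2: EnsembleNet([n])}) for n in nets]
        X = random_windows(6, 2, seed=5)
        a = Component(mods).predict_proba(X)
        b = Component(mods[::-1]).predict_proba(X)
        assert np.allclose(a, b)

    def test_component_needs_gold_sets(self):
        with pytest.raises(ValueError):
            train_component([], SingleCellModuleSpec(scales=(3,)), FAST)

    def test_assemble_symmetry_and_degeneracy(self):
        nets = [toy_net(2, s) for s in range(2)]
        comps = [Component([SingleCellModule({2: EnsembleNet([n])})]) for n in nets]
        X = random_windows(6, 2, seed=6)
        ab = assemble_model(comps[0], comps[1]).predict_proba(X)
        ba = assemble_model(comps[1], comps[0]).predict_proba(X)
        assert np.allclose(ab, ba)
        same = assemble_model(comps[0], comps[0])
        assert np.allclose(same.predict_proba(X), comps[0].predict_proba(X))
        solo = assemble_model(comps[0], None)
        assert np.allclose(solo.predict_proba(X), comps[0].predict_proba(X))

    def test_assemble_requires_compatible_scales(self):
        c1 = Component([SingleCellModule({2: EnsembleNet([toy_net(2, 0)])})])
        c2 = Component([SingleCellModule({3: EnsembleNet([toy_net(3, 0)])})])
        with pytest.raises(ValueError, match="scales"):
            assemble_model(c1, c2)

    def test_simplex_at_every_level(self, trained_module):
        X = random_windows(20, 25, seed=8)
        for level in [trained_module,
                      next(iter(trained_module.scale_ensembles.values())),
                      next(iter(trained_module.scale_ensembles.values())).members[0],
                      Component([trained_module])]:
            p = level.predict_proba(X)
            assert np.allclose(p.sum(axis=1), 1.0, atol=1e-9)
            assert (p >= 0).all()


# ---------------------------------------------------------------------------
# Scoring and calling
# ---------------------------------------------------------------------------

def make_windows(n, flank):
    snv = CandidateSNV("c1", 1000, "A", "G")
    seq = "ACGT" * flank + "A" * (2 * flank + 1 - 4 * flank) if flank == 0 else None
    windows = []
    for i in range(n):
        s = ("ACGT" * (flank + 1))[: 2 * flank + 1]
        windows.append(SequenceWindow(snv, flank, s, one_hot_encode(s)))
    return windows


class TestScoring:
    def test_empty_and_order_and_determinism(self, trained_module):
        assert score_candidates(trained_module, []) == []
        windows = make_windows(3, 25)
        scores = score_candidates(trained_module, windows)
        assert len(scores) == 3
        assert scores[0] == scores[1] == scores[2]  # identical windows
        assert sum(scores[0]) == pytest.approx(1.0, abs=1e-9)

    def test_too_narrow_windows_error(self, trained_module):
        with pytest.raises(ValueError, match="narrower"):
            score_candidates(trained_module, make_windows(2, 10))

    def test_call_cutoff_extremes(self):
        cands = [CandidateSNV("c1", i + 1, "A", "G") for i in range(3)]
        scores = [ScoreTriple(0.8, 0.1, 0.1), ScoreTriple(0.5, 0.3, 0.2),
                  ScoreTriple(0.2, 0.4, 0.4)]
        assert call_editing_sites(scores, cands, 1.0) == []
        assert len(call_editing_sites(scores, cands, 0.0)) == 3
        # strict comparison: exactly-at-cutoff is excluded
        assert [s.snv.pos for s in call_editing_sites(scores, cands, 0.5)] == [1]

    def test_call_invalid_cutoff(self):
        with pytest.raises(ValueError):
            call_editing_sites([], [], 1.5)


# ---------------------------------------------------------------------------
# Serialization and seeds
# ---------------------------------------------------------------------------

class TestSerialization:
    def test_bit_exact_reload(self, trained_module, tmp_path):
        path = tmp_path / "model.npz"
        save_model(trained_module, path)
        reloaded = load_model(path)
        X = random_windows(10, 25, seed=1)
        assert np.array_equal(reloaded.predict_proba(X), trained_module.predict_proba(X))

    def test_manifest_tamper_detected(self, trained_module, tmp_path):
        import json
        path = tmp_path / "model.npz"
        save_model(trained_module, path)
        with np.load(path) as data:
            payload = json.loads(bytes(data["__manifest__"]).decode())
            arrays = {k: data[k] for k in data.files if k != "__manifest__"}
        payload["spec_hash"] = "0" * 64
        blob = np.frombuffer(json.dumps(payload, sort_keys=True).encode(), dtype=np.uint8)
        np.savez_compressed(path, __manifest__=blob, **arrays)
        with pytest.raises(ValueError, match="integrity"):
            load_model(path)


class TestSeeds:
    def test_derivation_deterministic_and_bounded(self):
        assert derive_seed(1, 2, 3) == derive_seed(1, 2, 3)
        assert derive_seed(1, 2, 3) != derive_seed(1, 2, 4)
        assert 0 <= derive_seed(2**20, 5) < 2**31


# ---------------------------------------------------------------------------
# Level-wise behaviour on planted signal
# ---------------------------------------------------------------------------

def _editing_auc(model, X, y):
    return roc_auc(model.predict_proba(X)[:, 0], (y == int(ClassLabel.EDITING)).astype(int))


def test_component_auc_at_least_module_mean_auc():
    """Averaging single-cell modules into a component does not hurt mean
    discrimination on planted-signal data (level-wise improvement)."""
    comp_aucs, mod_aucs = [], []
    spec = SingleCellModuleSpec(scales=(10,), n_members=1, hidden_sizes=(16,))
    for seed in range(5):
        ds = generate_dataset(desk_config(150, seed=100 + seed, flank=10),
                              MotifModel(decay_halfwidth=8, signal_strength=0.9),
                              n_gold_sets=3)
        sets = ds.gold_set_arrays()
        (X_test, y_test), train_sets = sets[-1], sets[:-1]
        comp = train_component(train_sets, spec, FAST, seed=seed)
        comp_aucs.append(_editing_auc(comp, X_test, y_test))
        mod_aucs.append(np.mean([_editing_auc(m, X_test, y_test) for m in comp.modules]))
    assert np.mean(comp_aucs) >= np.mean(mod_aucs) - 0.01


# ---------------------------------------------------------------------------
# Position importance
# ---------------------------------------------------------------------------

class TestPositionImportance:
    def test_null_labels_give_near_zero_scores(self, trained_module, split_arrays):
        _, _, X_test, y_test = split_arrays
        rng = np.random.default_rng(0)
        y_null = rng.permutation(y_test)
        imp = position_importance(trained_module, X_test, y_null, n_repeats=3, seed=1)
        assert imp.shape == (51,)
        assert imp.max() < 0.06

    def test_gini_importance_peaks_at_planted_signal(self, split_arrays):
        X, y, _, _ = split_arrays
        imp = position_importance(None, X, y, n_repeats=1, seed=2, method="gini")
        assert imp.shape == (51,)
        assert (imp >= 0).all()
        assert abs(int(np.argmax(imp)) - 25) <= 2

    def test_invalid_arguments(self, split_arrays):
        X, y, _, _ = split_arrays
        with pytest.raises(ValueError):
            position_importance(None, X, y, n_repeats=0)
        with pytest.raises(ValueError):
            position_importance(None, X, y, method="nope")


def test_full_model_combines_both_components():
    """Training with m separate and m pooled gold sets yields 2m modules,
    and the combined prediction is the mean of the two components."""
    from editnet import train_full_model
    rng = np.random.default_rng(12)
    spec = SingleCellModuleSpec(scales=(3,), n_members=1, hidden_sizes=(8,))
    sets = [(random_windows(60, 3, seed=s), np.repeat([0, 1, 2], 20)) for s in range(4)]
    model = train_full_model(sets[:2], sets[2:], spec, FAST, seed=1)
    assert len(model.separate.modules) == 2
    assert len(model.pooled.modules) == 2
    X = random_windows(5, 3, seed=0)
    mean = (model.separate.predict_proba(X) + model.pooled.predict_proba(X)) / 2
    assert np.allclose(model.predict_proba(X), mean)
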