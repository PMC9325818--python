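import numpy as np
import pytest

from salqsar.chem import parse_smiles
from salqsar.data import chronological_split
from salqsar.evaluate import auroc
from salqsar.gcnn import (
    GCNNConfig,
    GraphConvClassifier,
    _forward,
    adjacency,
    conv_unit,
    featurize_atoms,
)
from salqsar.synth import GeneratorSpec, generate_dataset


class TestFeaturize:
    def test_methane_carbon(self):
        row = featurize_atoms(parse_smiles("C"))[0]
        assert row[0] == 1.0  # carbon one-hot
        assert row[10] == 1.0  # degree 0
        assert row[22] == 1.0  # 4 implicit hydrogens
        assert row[23] == 0.0  # not in ring

    def test_benzene_carbons_identical(self):
        feats = featurize_atoms(parse_smiles("c1ccccc1"))
        assert np.ptp(feats, axis=0).max() == 0.0

    def test_quaternary_ammonium_charge(self):
        g = parse_smiles("C[N+](C)(C)C")
        feats = featurize_atoms(g)
        n_idx = next(i for i, a in enumerate(g.atoms) if a.element == "N")
        assert feats[n_idx, 16] == 1.0  # formal charge field


class TestConvUnit:
    def test_three_atom_path_hand_example(self):
        # path 0-1-2, scalar features [1,2,3], W_self=W_nbr=1, b=0
        feats = np.array([[1.0], [2.0], [3.0]])
        adj = np.array([[0, 1, 0], [1, 0, 1], [0, 1, 0]], dtype=float)
        w = np.array([[1.0]])
        conv, pooled = conv_unit(feats, adj, w, w, np.zeros(1))
        assert conv.ravel().tolist() == [3.0, 6.0, 5.0]
        assert pooled.ravel().tolist() == [6.0, 6.0, 6.0]

    def test_isolated_atom_reduces_to_dense_relu(self):
        feats = np.array([[2.0, -1.0]])
        adj = np.zeros((1, 1))
        w_self = np.array([[1.0, -1.0], [0.5, 0.5]])
        conv, pooled = conv_unit(feats, adj, w_self, np.ones((2, 2)), np.zeros(2))
        expected = np.maximum(feats @ w_self, 0.0)
        np.testing.assert_allclose(conv, expected)
        np.testing.assert_allclose(pooled, expected)

    def test_identical_connected_atoms_symmetric(self):
        feats = np.array([[1.0, 2.0], [1.0, 2.0]])
        adj = np.array([[0.0, 1.0], [1.0, 0.0]])
        rng = np.random.default_rng(3)
        conv, pooled = conv_unit(
            feats, adj, rng.normal(size=(2, 4)), rng.normal(size=(2, 4)), np.zeros(4)
        )
        np.testing.assert_allclose(conv[0], conv[1])
        np.testing.assert_allclose(pooled[0], pooled[1])

    def test_width_mismatch_raises(self):
        with pytest.raises(ValueError):
            conv_unit(np.ones((2, 3)), np.zeros((2, 2)), np.ones((4, 4)),
                      np.ones((4, 4)), np.zeros(4))


class TestEncode:
    def test_saliency_shape_and_fingerprint_length(self, random_model):
        g = parse_smiles("CC(C)CC(=O)NC1CCCC1")  # 12 heavy atoms
        tensor, fp = random_model.encode(g)
        assert tensor.values.shape == (12, 128)
        assert fp.shape == (128,)

    def test_tanh_of_column_sums_is_fingerprint(self, random_model, tiny_molecules):
        for smiles in tiny_molecules:
            tensor, fp = random_model.encode(parse_smiles(smiles))
            np.testing.assert_allclose(
                np.tanh(tensor.values.sum(axis=0)), fp, atol=1e-6
            )
            assert (tensor.values >= 0).all()

    def test_permutation_equivariance(self, random_model):
        g = parse_smiles("CCOc1ccccc1N")
        feats = featurize_atoms(g)
        adj = adjacency(g)
        rng = np.random.default_rng(7)
        perm = rng.permutation(g.n_atom)
        base = _forward(feats, adj, random_model.params_)
        permuted = _forward(
            feats[perm], adj[np.ix_(perm, perm)], random_model.params_
        )
        np.testing.assert_allclose(
            permuted["saliency"], base["saliency"][perm], atol=1e-9
        )
        np.testing.assert_allclose(
            permuted["fingerprint"], base["fingerprint"], atol=1e-6
        )

    def test_receptive_field_on_chain(self, random_model):
        # each conv unit sees 2 bonds (conv + neighborhood pooling), so
        # three units depend on atoms at most 6 bonds away
        g = parse_smiles("C" * 16)
        feats = featurize_atoms(g)
        adj = adjacency(g)
        base = _forward(feats, adj, random_model.params_)["saliency"]
        modified = feats.copy()
        modified[7:] = 0.0  # atoms >= 7 bonds from atom 0
        out = _forward(modified, adj, random_model.params_)["saliency"]
        np.testing.assert_allclose(out[0], base[0], atol=1e-9)


class TestPredict:
    def test_zero_head_gives_half(self, random_model):
        import copy

        model = GraphConvClassifier(conv_sizes=(36, 50, 16))
        model.params_ = copy.deepcopy(random_model.params_)
        model.params_["Wh2"] = np.zeros_like(model.params_["Wh2"])
        model.params_["bh2"] = np.zeros(2)
        model.classes_ = np.array([0, 1])
        assert model.predict_one(parse_smiles("CCO")) == pytest.approx(0.5)

    def test_probabilities_sum_to_one(self, random_model, tiny_molecules):
        probs = random_model.predict_proba(tiny_molecules)
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-12)


class TestTraining:
    def test_learns_planted_motif(self):
        ds = generate_dataset(GeneratorSpec(n=250, seed=21))
        model = GraphConvClassifier(
            conv_sizes=(16, 16, 16), epochs=12, seed=0
        )
        model.fit(ds.df["smiles"].tolist(), ds.df["label"].to_numpy())
        assert model.history_[-1]["train_auc"] > 0.95
        assert len(model.history_) == 12

    def test_huge_l2_shrinks_weights(self):
        ds = generate_dataset(GeneratorSpec(n=60, seed=3))
        norms = {}
        for l2 in (0.0, 1e6):
            m = GraphConvClassifier(conv_sizes=(8, 8, 8), epochs=3, l2=l2, seed=0)
            m.fit(ds.df["smiles"].tolist(), ds.df["label"].to_numpy())
            norms[l2] = sum(float((v**2).sum()) for v in m.params_.values())
        assert norms[1e6] < norms[0.0]

    def test_same_seed_identical_history(self):
        ds = generate_dataset(GeneratorSpec(n=60, seed=3))
        histories = []
        for _ in range(2):
            m = GraphConvClassifier(conv_sizes=(8, 8, 8), epochs=2, seed=9)
            m.fit(ds.df["smiles"].tolist(), ds.df["label"].to_numpy())
            histories.append(m.history_)
        assert histories[0] == histories[1]

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            GraphConvClassifier(epochs=1).fit(["C", "CC"], [1, 1])

    def test_chronological_test_auc_on_planted_motif(self, trained_tiny_model, small_dataset):
        model, split = trained_tiny_model
        test = small_dataset.subset(list(split.test_ids))
        scores = model.predict_proba(test.df["smiles"].tolist())[:, 1]
        assert auroc(test.df["label"].to_numpy(), scores) >= 0.9


class TestPersistence:
    def test_save_load_roundtrip(self, trained_tiny_model, tmp_path):
        model, _ = trained_tiny_model
        path = tmp_path / "model.zip"
        model.save(path)
        loaded = GraphConvClassifier.load(path)
        assert loaded.conv_sizes == tuple(model.conv_sizes)
        probes = ["CCO", "c1ccccc1", "CC(=O)NS(=O)(=O)c1ccccc1"]
        np.testing.assert_allclose(
            loaded.predict_proba(probes), model.predict_proba(probes)
        )

    def test_sklearn_params_roundtrip(self):
        model = GraphConvClassifier(l2=0.01, epochs=7)
        params = model.get_params()
        clone = GraphConvClassifier(**params)
        assert clone.get_params() == params
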