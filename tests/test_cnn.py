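"""CNN encoding, architecture invariants, training, and attribution."""

import numpy as np
import pytest

from secscreen.features import SecretabilityDataset, auroc, make_folds
from secscreen.nn import (
    CNNConfig,
    SecretabilityCNN,
    aggregate_attributions,
    build_model,
    decode_one_hot,
    ensemble_average,
    integrated_gradients,
    normalize_contributions,
    one_hot_encode,
)
from secscreen.nn.attribution import AttributionMap
from secscreen.nn.autograd import Tensor
from secscreen.nn.model import train_cnn, train_single

SMALL = dict(n_filters=(6, 6, 6), dense=8, gru_hidden=6)


class TestOneHot:
    def test_rows_and_round_trip(self):
        x = one_hot_encode("ACDW")
        assert x.shape == (4, 20)
        assert (x.sum(axis=1) == 1).all()
        assert decode_one_hot(x) == "ACDW"

    def test_unknown_residue_zero_row(self):
        x = one_hot_encode("AXA")
        assert x[1].sum() == 0
        assert decode_one_hot(x) == "AXA"


class TestArchitecture:
    def test_scalar_probability_for_any_length(self):
        model = build_model(CNNConfig(seed=0, **SMALL))
        for length in (15, 50, 137):
            x = one_hot_encode("ACDEFGHIKLMNPQRSTVWY" * 7)[:length]
            p = model.forward(x[None]).data
            assert p.shape == (1,)
            assert 0 <= p[0] <= 1

    def test_global_max_invariant_to_zero_padding(self):
        model = build_model(CNNConfig(seed=1, **SMALL))
        pep = "MKTAYIAKQRQISFVKSHFSRQLEERLGLIEVQ" * 2
        x = one_hot_encode(pep)
        padded = np.concatenate([x, np.zeros((17, 20))], axis=0)
        assert model.forward(x[None]).data[0] == pytest.approx(
            model.forward(padded[None]).data[0]
        )

    def test_kmax_with_k1_equals_global_max(self):
        x = one_hot_encode("ACDEFGHIKLMNPQRSTVWY" * 3)
        gmax = SecretabilityCNN(CNNConfig(seed=2, **SMALL, pooling="global_max"))
        k1 = SecretabilityCNN(CNNConfig(seed=2, **SMALL, pooling="kmax", kmax_k=1))
        assert gmax.forward(x[None]).data[0] == pytest.approx(
            k1.forward(x[None]).data[0]
        )

    @pytest.mark.parametrize("strategy", ["global_max", "kmax", "bigru", "pad_truncate"])
    def test_all_length_strategies_run_batched(self, strategy):
        model = SecretabilityCNN(CNNConfig(seed=3, **SMALL, pooling=strategy))
        probs = model.predict_proba(
            ["ACDEFGHIKLMNPQRSTVWY" * 3, "MKTAYIAKQRQISFVKSHFS" * 4]
        )
        assert probs.shape == (2,)
        assert np.isfinite(probs).all()

    def test_invalid_strategy_rejected(self):
        with pytest.raises(ValueError):
            CNNConfig(pooling="avg")

    def test_forward_gradient_matches_finite_differences(self):
        model = build_model(CNNConfig(seed=4, **SMALL))
        pep = "ACDEFGHIKLMNPQRSTVWYMKTAYIAKQRQISFV"
        x = one_hot_encode(pep)
        xt = Tensor(x[None], requires_grad=True)
        model.forward(xt).sum().backward()
        rng = np.random.default_rng(0)
        eps = 1e-6
        for _ in range(8):
            i, j = int(rng.integers(0, len(pep))), int(rng.integers(0, 20))
            xp, xm = x.copy(), x.copy()
            xp[i, j] += eps
            xm[i, j] -= eps
            num = (
                model.forward(xp[None]).data[0] - model.forward(xm[None]).data[0]
            ) / (2 * eps)
            assert num == pytest.approx(xt.grad[0, i, j], abs=1e-6)


class TestTraining:
    def _toy(self, n=160, seed=0):
        rng = np.random.default_rng(seed)
        peps, labels = [], []
        for i in range(n):
            lab = i % 2
            pool = list("DE" * 5 + "GSTANQ") if lab else list("LIVF" * 3 + "GSTANQ")
            peps.append("".join(rng.choice(pool, size=52)))
            labels.append(lab)
        return peps, np.array(labels)

    def test_separable_toy_learns(self):
        peps, labels = self._toy(seed=1)
        model = train_single(peps, labels, CNNConfig(seed=1, epochs=10, **SMALL))
        assert auroc(labels, model.predict_proba(peps)) > 0.9

    def test_shuffled_labels_stay_near_chance_out_of_sample(self):
        peps, labels = self._toy(n=200, seed=2)
        rng = np.random.default_rng(2)
        labels = rng.permutation(labels)
        model = train_single(
            peps[:150], labels[:150], CNNConfig(seed=2, epochs=4, **SMALL)
        )
        score = auroc(labels[150:], model.predict_proba(peps[150:]))
        assert 0.3 <= score <= 0.7

    def test_training_deterministic_given_seed(self):
        peps, labels = self._toy(n=60, seed=3)
        cfg = CNNConfig(seed=3, epochs=2, **SMALL)
        p1 = train_single(peps, labels, cfg).predict_proba(peps)
        p2 = train_single(peps, labels, cfg).predict_proba(peps)
        assert np.array_equal(p1, p2)

    def test_fold_models_and_oof_alignment(self):
        peps, labels = self._toy(n=120, seed=4)
        ds = SecretabilityDataset(
            [f"k{i}" for i in range(120)], peps, labels,
            [f"G{i % 12}" for i in range(120)],
        )
        folds = make_folds(ds, k=4, seed=4)
        models, oof = train_cnn(ds, folds, CNNConfig(seed=4, epochs=2, **SMALL))
        assert len(models) == 4
        assert not oof.isna().any()


class TestEnsembleAverage:
    def test_mean_and_identity(self):
        assert ensemble_average([0.2], [0.8])[0] == pytest.approx(0.5)
        assert ensemble_average([0.4, 0.6], [0.4, 0.6]).tolist() == [0.4, 0.6]

    def test_complementary_models_do_not_hurt(self):
        rng = np.random.default_rng(5)
        y = rng.integers(0, 2, size=500)
        # two noisy views of the label with independent errors
        a = np.clip(y + rng.normal(0, 0.6, 500), 0, 1)
        b = np.clip(y + rng.normal(0, 0.6, 500), 0, 1)
        best = max(auroc(y, a), auroc(y, b))
        assert auroc(y, ensemble_average(a, b)) >= best - 0.02


class TestIntegratedGradients:
    def test_input_equal_to_baseline_gives_zero(self):
        model = build_model(CNNConfig(seed=6, **SMALL))
        pep = "ACDEFGHIKLMNPQRSTVWY"
        x = one_hot_encode(pep)
        amap = integrated_gradients(model, pep, baseline=x.copy())
        assert np.allclose(amap.contributions, 0)

    def test_linear_model_closed_form(self):
        # for a linear model F(x) = w . x, IG = w * (x - x') exactly, for
        # any number of integration steps
        rng = np.random.default_rng(7)
        w = rng.normal(0, 0.3, size=(30, 20))

        class Linear:
            def forward(self, xt, valid=None, train=False):
                t = xt if isinstance(xt, Tensor) else Tensor(xt)
                return (
                    t.reshape(t.shape[0], 600) @ Tensor(w.reshape(600, 1))
                ).reshape(t.shape[0])

        pep = "ACDEFGHIKLMNPQRSTVWYACDEFGHIKL"
        x = one_hot_encode(pep)
        expected = (w * x).sum(axis=1)
        for m in (1, 5, 50):
            amap = integrated_gradients(Linear(), pep, m=m, max_m=m)
            assert np.allclose(amap.contributions, expected)
            assert amap.completeness_residual < 1e-9

    def test_completeness_on_trained_model(self):
        model = build_model(CNNConfig(seed=8, **SMALL))
        rng = np.random.default_rng(8)
        for _ in range(5):
            pep = "".join(
                rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), size=int(rng.integers(20, 80)))
            )
            amap = integrated_gradients(model, pep)
            gap = abs(amap.model_output - amap.baseline_output)
            assert amap.completeness_residual <= 0.02 * gap + 1e-12


class TestNormalizationAndAggregation:
    def _map(self, key, pep, contributions):
        return AttributionMap(
            key=key, peptide=pep, contributions=np.asarray(contributions, float),
            model_output=0.8, baseline_output=0.5, m=50, completeness_residual=0.0,
        )

    def test_single_map_scaled_to_100(self):
        maps = normalize_contributions([self._map("a", "ACDE", [10, -20, 15, 5])])
        assert np.abs(maps[0].contributions).sum() == pytest.approx(100)

    def test_mean_of_sums_is_100(self):
        maps = normalize_contributions(
            [
                self._map("a", "AC", [30, -20]),       # sum |.| = 50
                self._map("b", "DE", [100, 50]),        # sum |.| = 150
            ]
        )
        sums = [np.abs(m.contributions).sum() for m in maps]
        assert np.mean(sums) == pytest.approx(100)
        # already-balanced pair is left unchanged (global factor 1)
        assert maps[0].contributions.tolist() == [30, -20]

    def test_all_zero_maps_rejected(self):
        with pytest.raises(ValueError):
            normalize_contributions([self._map("a", "AC", [0, 0])])

    def test_per_aa_single_residue_type(self):
        maps = [self._map("a", "AAAA", [1.0, 2.0, 3.0, 4.0])]
        table = aggregate_attributions(maps, "per_aa")
        assert table.loc["A", "mean_contribution"] == pytest.approx(2.5)
        assert np.isnan(table.loc["C", "mean_contribution"])

    def test_region20_one_residue_per_bin(self):
        pep = "ACDEFGHIKLMNPQRSTVWY"
        maps = [self._map("a", pep, np.arange(20, dtype=float))]
        table = aggregate_attributions(maps, "per_region20")
        for i, aa in enumerate(pep):
            assert table.loc[aa, f"region_{i}"] == pytest.approx(float(i))

    def test_grouping_matches_brute_force_oracle(self):
        rng = np.random.default_rng(9)
        maps = []
        for k in range(6):
            pep = "".join(rng.choice(list("ACDEFG"), size=int(rng.integers(10, 40))))
            maps.append(self._map(f"m{k}", pep, rng.normal(size=len(pep))))
        table = aggregate_attributions(maps, "per_region20")
        buckets: dict[tuple[str, int], list[float]] = {}
        for mp in maps:
            L = len(mp.peptide)
            for i, (aa, c) in enumerate(zip(mp.peptide, mp.contributions)):
                buckets.setdefault((aa, min(20 * i // L, 19)), []).append(c)
        for (aa, b), vals in buckets.items():
            assert table.loc[aa, f"region_{b}"] == pytest.approx(np.mean(vals))
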