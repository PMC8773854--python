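"""Model builders, parameter audit, cost calculator, structural invariants."""

import numpy as np
import pytest

from mbeeg import (
    EEGNetBranchConfig,
    MultibranchModelSpec,
    ShallowBranchConfig,
    SpecError,
    ValidationError,
    build_model,
    conv_multiplication_count,
    count_trainable_parameters,
    describe_model,
    eegnet_spec,
    mbeegnet_spec,
    mbshallow_spec,
    shallow_spec,
)


def eegnet_branch_param_oracle(f1, ke, e, d=2, f2=None, sep=16):
    """Closed-form per-layer hand count for one EEGNet-style branch."""
    f2 = f2 or 2 * f1
    return {
        "temporal": ke * f1,
        "bn1": 2 * f1,
        "depthwise": e * f1 * d,
        "bn2": 2 * f1 * d,
        "sep_depthwise": sep * f1 * d,
        "sep_pointwise": f1 * d * f2,
        "bn3": 2 * f2,
    }


class TestParameterAudit:
    def test_first_branch_contributes_472(self):
        oracle = eegnet_branch_param_oracle(f1=4, ke=16, e=22)
        assert sum(oracle.values()) == 472
        audit = count_trainable_parameters(mbeegnet_spec())
        branch0 = sum(c for name, _, c in audit.entries if name.startswith("branch0/"))
        assert branch0 == 472

    def test_canonical_model_total_matches_branchwise_oracle(self):
        """Audit equals the independent closed-form enumeration per layer."""
        audit = count_trainable_parameters(mbeegnet_spec())
        expected = 0
        for f1, ke in ((4, 16), (8, 32), (16, 64)):
            expected += sum(eegnet_branch_param_oracle(f1, ke, 22).values())
        flat = sum(2 * f1 * 17 for f1 in (4, 8, 16))  # F2 x floor(floor(1125/8)/8)
        expected += flat * 4 + 4  # dense weights + bias
        assert audit.total == expected == 8908

    def test_audit_total_equals_entry_sum(self):
        audit = count_trainable_parameters(mbshallow_spec())
        assert audit.total == sum(c for _, _, c in audit.entries)
        # every shape entry is consistent with its count
        for name, shape, count in audit.entries:
            assert int(np.prod(shape)) == count, name

    def test_audit_counts_match_model_variables(self):
        """The audit enumerates exactly the model's trainable arrays."""
        model = build_model(eegnet_spec())
        audit = count_trainable_parameters(model)
        assert audit.total == sum(p.value.size for p in model.params())
        assert len(audit.entries) == len(model.params())

    def test_single_dense_model_oracle(self):
        # a dense layer 10 -> 4 with bias has 44 parameters
        from mbeeg.nn import Dense

        d = Dense(10, 4)
        assert sum(p.value.size for p in d.params()) == 44


class TestMultiplicationCount:
    @pytest.mark.parametrize("filters,dims,positions,expected", [
        (10, (8, 1, 1), 100, 8000),     # temporal 1-D bank
        (10, (1, 22, 1), 21, 4620),     # spatial 1-D bank
        (10, (8, 22, 3), 100, 528000),  # one dense 3-D bank
    ])
    def test_worked_examples(self, filters, dims, positions, expected):
        assert conv_multiplication_count(filters, dims, positions) == expected

    def test_factorized_pair_total(self):
        total = (conv_multiplication_count(10, (8, 1, 1), 100)
                 + conv_multiplication_count(10, (1, 22, 1), 21))
        assert total == 12620
        assert total < conv_multiplication_count(10, (8, 22, 3), 100)

    def test_invalid_arguments_rejected(self):
        with pytest.raises(ValidationError):
            conv_multiplication_count(0, (8, 1, 1), 100)
        with pytest.raises(ValidationError):
            conv_multiplication_count(10, (8, 0, 1), 100)
        with pytest.raises(ValidationError):
            conv_multiplication_count(10, (8, 1), 100)


class TestBuildModel:
    def test_outputs_are_probabilities(self, rng):
        model = build_model(mbeegnet_spec(n_samples=250), seed=0)
        x = rng.standard_normal((5, 22, 250)).astype(np.float32)
        p = model.predict_proba(x)
        assert np.all(p >= 0)
        np.testing.assert_allclose(p.sum(axis=1), 1.0, atol=1e-6)

    def test_branch_flatten_lengths(self):
        """Each EEGNet branch flattens to F2 x 17 for 1125 samples."""
        model = build_model(mbeegnet_spec(), seed=0)
        x = np.zeros((2, 22, 1125), dtype=np.float32)
        outs = [br.forward(x, training=False) for br in model.branches]
        assert [o.shape[1] for o in outs] == [8 * 17, 16 * 17, 32 * 17]

    def test_shallow_pooled_length(self, rng):
        """KE=25 with pool 75/15 gives 69 pooled samples: floor((1101-75)/15)+1."""
        spec = shallow_spec(kernel=25)
        model = build_model(spec, seed=0)
        x = rng.standard_normal((2, 22, 1125)).astype(np.float32)
        out = model.branches[0].forward(x, training=False)
        assert out.shape[1] == 40 * 69

    def test_kernel_exceeding_samples_rejected(self):
        with pytest.raises(SpecError):
            mbeegnet_spec(n_samples=32).validate()

    def test_pool_collapse_rejected(self):
        spec = MultibranchModelSpec(
            "shallow", (ShallowBranchConfig(kernel=5, pool_length=500, pool_stride=100),),
            4, 500, 4)
        with pytest.raises(SpecError):
            build_model(spec)

    def test_heterogeneous_branch_families_rejected(self):
        spec = MultibranchModelSpec(
            "eegnet", (EEGNetBranchConfig(4, 16, 0.0), ShallowBranchConfig(kernel=5)),
            22, 1125, 4)
        with pytest.raises(SpecError):
            spec.validate()

    def test_single_branch_equals_mb_with_one_branch(self, rng):
        """A 1-branch multibranch spec with branch-2 settings is the EEGNet baseline."""
        single = build_model(eegnet_spec(n_filters=8, kernel=32, dropout_rate=0.1), seed=3)
        mb1 = build_model(
            MultibranchModelSpec("eegnet", (EEGNetBranchConfig(8, 32, 0.1),), 22, 1125, 4),
            seed=3)
        assert [type(l).__name__ for l in single.branches[0].layers] == \
               [type(l).__name__ for l in mb1.branches[0].layers]
        x = rng.standard_normal((3, 22, 1125)).astype(np.float32)
        np.testing.assert_array_equal(single.predict_proba(x), mb1.predict_proba(x))

    def test_class_permutation_equivariance(self, rng):
        """Permuting dense-layer class columns permutes probabilities identically."""
        model = build_model(eegnet_spec(n_samples=250), seed=1)
        x = rng.standard_normal((4, 22, 250)).astype(np.float32)
        p = model.predict_proba(x)
        perm = np.array([2, 0, 3, 1])
        model.head.w.value[...] = model.head.w.value[:, perm]
        model.head.b.value[...] = model.head.b.value[perm]
        p2 = model.predict_proba(x)
        np.testing.assert_allclose(p2, p[:, perm], atol=1e-6)

    def test_inference_is_deterministic_and_batch_invariant(self, rng):
        model = build_model(mbeegnet_spec(n_samples=375), seed=2)
        x = rng.standard_normal((6, 22, 375)).astype(np.float32)
        # dropout off at inference: repeated calls identical
        np.testing.assert_array_equal(model.predict_proba(x), model.predict_proba(x))
        # single-trial vs batched predictions agree (running-stats BN)
        single = np.concatenate([model.predict_proba(x[i : i + 1]) for i in range(6)])
        np.testing.assert_allclose(model.predict_proba(x), single, atol=1e-5)


class TestDescribeModel:
    def test_summary_total_matches_audit(self):
        text = describe_model(mbeegnet_spec())
        assert "8908" in text.split("total")[-1]

    def test_single_branch_summary_has_no_concatenation(self):
        text = describe_model(eegnet_spec())
        assert "concatenated" not in text

    def test_describe_is_deterministic(self):
        spec = mbshallow_spec()
        assert describe_model(spec) == describe_model(spec)


class TestSpecSerialization:
    def test_roundtrip_through_plain_dict(self):
        from mbeeg import spec_from_config, spec_to_config

        for spec in (mbeegnet_spec(), mbshallow_spec(), eegnet_spec(n_filters=6, kernel=24)):
            back = spec_from_config(spec_to_config(spec))
            assert back == spec

    def test_roundtrip_survives_json(self):
        import json

        from mbeeg import spec_from_config, spec_to_config

        spec = mbeegnet_spec(n_channels=44, n_samples=1125)
        back = spec_from_config(json.loads(json.dumps(spec_to_config(spec))))
        assert back == spec
        assert count_trainable_parameters(back).total == count_trainable_parameters(spec).total

    def test_bad_family_rejected(self):
        from mbeeg import spec_from_config

        with pytest.raises(SpecError):
            spec_from_config({"family": "mlp", "branches": [], "n_channels": 1,
                              "n_samples": 1, "n_classes": 2})
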