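"""Assembly of the radiologist / context / practitioner blocks."""

import numpy as np
import pytest

from climat import nn
from climat.features import CovariateSchema, TokenSequence
from climat.model import ClimatConfig, ClimatModel
from climat.synthetic import PatientRecord, TrajectoryConfig, generate_cohort


def build_model(records, T, n_classes, image_shape, seed=0, **cfg_kwargs):
    schema = CovariateSchema().fit(records)
    config = ClimatConfig(**{"depth_p": 2, "backbone_width": 8, **cfg_kwargs})
    return ClimatModel(
        config, T, n_classes, schema, image_shape, np.random.default_rng(seed)
    )


@pytest.fixture(scope="module")
def cohort_2d():
    cfg = TrajectoryConfig(
        n_subjects=6, T=4, n_classes_per_task=(5,) * 5, seed=3, noise_sd=0.0
    )
    return generate_cohort(cfg)


@pytest.fixture(scope="module")
def cohort_3d():
    cfg = TrajectoryConfig(
        n_subjects=3,
        T=1,
        n_classes_per_task=(3, 3),
        image_size=(32, 32, 32),
        seed=4,
    )
    return generate_cohort(cfg)


class TestForwardShapes:
    def test_2d_full_pipeline_shapes(self, cohort_2d):
        model = build_model(cohort_2d, 4, [5] * 5, (64, 64))
        out = model.forward(cohort_2d[0])
        assert out.f0R.shape == (5,)
        assert len(out.f) == 5
        assert all(ft.shape == (5,) for ft in out.f)

    def test_3d_input_and_k1(self, cohort_3d):
        model = build_model(cohort_3d, 1, [3, 3], (32, 32, 32), n_cls=1)
        out = model.forward(cohort_3d[0])
        assert len(out.f) == 2 and out.f0R.shape == (3,)
        assert out.imaging_attention[0].shape == (2, 2, 2)

    def test_practitioner_sequence_length(self, cohort_2d):
        model = build_model(cohort_2d, 4, [5] * 5, (64, 64))
        images, covs = model._encode_records(cohort_2d[:2])
        out = model.forward_arrays(images, covs)
        # P sees K CLS tokens + the N+1 radiologist states
        assert out["state_p"].hidden.shape[1] == model.K + model.N + 1

    def test_sequence_fusion_path(self, cohort_2d):
        model = build_model(cohort_2d, 4, [5] * 5, (64, 64), fusion="sequence")
        images, covs = model._encode_records(cohort_2d[:2])
        out = model.forward_arrays(images, covs)
        assert out["state_p"].hidden.shape[1] == model.K + model.N + 2
        assert len(out["f"]) == 5

    def test_separate_heads_allow_varying_class_counts(self, cohort_2d):
        records = [
            PatientRecord(
                r.subject_id, r.image, r.covariates,
                [min(int(y), 3) if m else y for y, m in zip(r.targets, r.target_mask)],
                r.target_mask,
            )
            for r in cohort_2d
        ]
        model = build_model(records, 4, [5, 4, 4, 3, 3], (64, 64), head_mode="separate")
        out = model.forward(records[0])
        assert [ft.shape[0] for ft in out.f] == [5, 4, 4, 3, 3]

    def test_common_head_rejects_varying_class_counts(self, cohort_2d):
        with pytest.raises(ValueError, match="common"):
            build_model(cohort_2d, 4, [5, 4, 4, 3, 3], (64, 64), head_mode="common")

    def test_invalid_k_rejected(self, cohort_2d):
        with pytest.raises(ValueError):
            build_model(cohort_2d, 4, [5] * 5, (64, 64), n_cls=3)

    def test_missing_image_rejected(self, cohort_2d):
        rec = cohort_2d[0]
        broken = PatientRecord(
            rec.subject_id, np.zeros((8, 8)), rec.covariates, rec.targets, rec.target_mask
        )
        broken.image = None
        model = build_model(cohort_2d, 4, [5] * 5, (64, 64))
        with pytest.raises(ValueError, match="image"):
            model.forward(broken)


class TestBlockSemantics:
    def test_average_pooling_oracle(self, cohort_2d):
        model = build_model(cohort_2d, 4, [5] * 5, (64, 64))
        images, covs = model._encode_records(cohort_2d[:2])
        tokens = model.image_encoder(images)
        state, f0R = model.radiologist_forward(tokens)
        pooled = state.hidden.data.mean(axis=1)  # independent mean recomputation
        expected = model.head_r(nn.Tensor(pooled)).data
        assert np.allclose(f0R.data, expected, atol=1e-12)

    def test_context_residual_identity(self, cohort_2d):
        model = build_model(cohort_2d, 4, [5] * 5, (64, 64))
        for block in model.encoder_c.blocks:
            block.proj.weight.data[:] = 0
            block.proj.bias.data[:] = 0
            block.fc2.weight.data[:] = 0
            block.fc2.bias.data[:] = 0
        images, covs = model._encode_records(cohort_2d[:1])
        clin = nn.concat(
            [enc(arr).reshape(1, 1, model.config.cm)
             for enc, arr in zip(model.scalar_encoders, covs)],
            axis=1,
        )
        _, h_c0 = model.context_forward(TokenSequence(tokens=clin, modality_tag="non-imaging"))
        expected = model.encoder_c.cls.data[0] + model.encoder_c.pos.data[0]
        assert np.allclose(h_c0.data[0], expected, atol=1e-12)

    def test_cls_token_routing_under_residual_identity(self, cohort_2d):
        """With P's residual branches zeroed, CLS token t feeds only horizon t."""
        model = build_model(cohort_2d, 4, [5] * 5, (64, 64))
        for block in model.encoder_p.blocks:
            block.proj.weight.data[:] = 0
            block.proj.bias.data[:] = 0
            block.fc2.weight.data[:] = 0
            block.fc2.bias.data[:] = 0
        images, covs = model._encode_records(cohort_2d[:1])
        # non-constant perturbation (layer norm is invariant to constant shifts)
        bump = np.random.default_rng(7).normal(size=model.width_p)
        with nn.no_grad():
            base = [ft.data.copy() for ft in model.forward_arrays(images, covs)["f"]]
            model.encoder_p.cls.data[2] += bump  # perturb CLS token of horizon 2
            pert = [ft.data.copy() for ft in model.forward_arrays(images, covs)["f"]]
        for t in range(5):
            changed = not np.allclose(base[t], pert[t])
            assert changed == (t == 2)

    def test_cls_perturbation_reaches_own_horizon_in_full_model(self, cohort_2d):
        model = build_model(cohort_2d, 4, [5] * 5, (64, 64))
        images, covs = model._encode_records(cohort_2d[:1])
        bump = np.random.default_rng(9).normal(size=model.width_p) * 0.5
        with nn.no_grad():
            base = model.forward_arrays(images, covs)["f"][1].data.copy()
            model.encoder_p.cls.data[1] += bump
            pert = model.forward_arrays(images, covs)["f"][1].data.copy()
        assert not np.allclose(base, pert)


class TestAttention:
    def test_clinical_weights_normalized(self, cohort_2d):
        model = build_model(cohort_2d, 4, [5] * 5, (64, 64))
        imaging, clinical = model.extract_attention(cohort_2d[0], t=1)
        assert clinical.shape == (4,)
        assert np.all(clinical >= 0)
        assert clinical.sum() == pytest.approx(1.0)

    def test_imaging_map_folds_to_feature_grid(self, cohort_2d):
        model = build_model(cohort_2d, 4, [5] * 5, (64, 64))
        imaging, _ = model.extract_attention(cohort_2d[0], t=0)
        assert imaging.shape == (2, 2)  # 64/32 per axis
        assert imaging.sum() == pytest.approx(1.0)

    def test_head_averaging_oracle(self, cohort_2d):
        model = build_model(cohort_2d, 4, [5] * 5, (64, 64))
        images, covs = model._encode_records(cohort_2d[:1])
        with nn.no_grad():
            out = model.forward_arrays(images, covs)
        maps, clin = model._attention_from_states(out["state_c"], out["state_p"], out["grid"])
        # independent recomputation: mean of per-head rows, then renormalize
        per_head = out["state_c"].attention[-1].data[0]  # (H, S, S)
        row = np.mean([per_head[h, 0, 1:5] for h in range(per_head.shape[0])], axis=0)
        assert np.allclose(clin[0], row / row.sum(), atol=1e-12)

    def test_horizon_out_of_range(self, cohort_2d):
        model = build_model(cohort_2d, 4, [5] * 5, (64, 64))
        with pytest.raises(IndexError):
            model.extract_attention(cohort_2d[0], t=9)


def test_end_to_end_gradients_finite(cohort_2d):
    from climat.losses import consistency_loss, prognosis_loss, total_loss

    model = build_model(cohort_2d, 4, [5] * 5, (64, 64))
    images, covs = model._encode_records(cohort_2d[:3])
    out = model.forward_arrays(images, covs)
    labels = np.array([[int(y) if m else 0 for y, m in zip(r.targets, r.target_mask)]
                       for r in cohort_2d[:3]])
    mask = np.array([r.target_mask for r in cohort_2d[:3]])
    loss = total_loss(
        prognosis_loss(out["f"], labels, mask, np.ones(5)),
        consistency_loss(out["f0R"], out["f"][0]),
        0.5,
    )
    loss.backward()
    for name, p in model.named_parameters():
        assert p.grad is None or np.all(np.isfinite(p.grad)), name
        assert p.grad is not None, f"no gradient reached {name}"
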