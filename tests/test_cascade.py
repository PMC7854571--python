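"""Cascade orchestration: pre-training, fine-tuning, composed inference."""

import numpy as np
import pytest

from cryocdae.autoencoder import ConvDenoisingAutoencoder
from cryocdae.cascade import CascadeDenoiser, denoise, finetune, pretrain
from cryocdae.metrics import equalize_stack, psnr
from cryocdae.stack import ImageStack

SMALL_BLOCK = dict(channels=4, epochs=2, random_state=0)


def _small_cascade(**kwargs) -> CascadeDenoiser:
    params = dict(
        block=ConvDenoisingAutoencoder(**SMALL_BLOCK),
        k_neighbors=3,
        random_state=1,
    )
    params.update(kwargs)
    return CascadeDenoiser(**params)


@pytest.fixture(scope="module")
def fitted(tiny_datasets):
    tiers, test = tiny_datasets
    model = _small_cascade(enhance=False)
    model.fit([t.pixels for t in tiers])
    return model, tiers, test


class TestPretrain:
    def test_wrong_tier_count_rejected(self, tiny_datasets):
        tiers, _ = tiny_datasets
        with pytest.raises(ValueError, match="tiers"):
            _small_cascade().fit([t.pixels for t in tiers[:3]])

    def test_misaligned_tiers_rejected(self, tiny_datasets):
        tiers, _ = tiny_datasets
        bad = [t.pixels for t in tiers]
        bad[1] = bad[1][:-2]
        with pytest.raises(ValueError, match="misaligned"):
            _small_cascade().fit(bad)

    def test_each_block_loss_decreases(self, fitted):
        model, _, _ = fitted
        for blk in model.blocks_:
            assert blk.loss_history_[-1] < blk.loss_history_[0]

    def test_blocks_are_independent_of_each_other(self, fitted, tiny_datasets):
        """Block j depends only on tiers (j, j+1): retraining one alone matches."""
        model, tiers, _ = fitted
        solo = ConvDenoisingAutoencoder(**SMALL_BLOCK)
        solo.set_params(random_state=model.random_state * 1000 + 1)
        solo.fit(tiers[1].pixels, tiers[2].pixels)
        x = tiers[1].pixels[:4]
        assert np.array_equal(model.blocks_[1].transform(x), solo.transform(x))


class TestFineTune:
    def test_requires_pretraining(self, tiny_datasets):
        _, test = tiny_datasets
        with pytest.raises(RuntimeError):
            _small_cascade().fine_tune(test.pixels)

    def test_zero_epoch_finetune_is_identity_on_weights(self, fitted):
        model, tiers, test = fitted
        frozen = CascadeDenoiser(**{**model.get_params(deep=False), "finetune_epochs": 0})
        frozen.blocks_ = model.blocks_
        record = frozen.fine_tune(test.pixels)
        manual = test.pixels
        for blk in model.blocks_:
            manual = blk.transform(manual)
        assert np.array_equal(record.final, manual)
        assert all(len(h) == 0 for h in record.loss_histories)

    def test_record_stages_recompute_consistently(self, fitted):
        model, _, test = fitted
        work = CascadeDenoiser(**model.get_params(deep=False))
        work.blocks_ = model.blocks_
        record = work.fine_tune(test.pixels)
        assert np.array_equal(record.stages[1], work.finetuned_blocks_[0].transform(test.pixels))
        assert len(record.stages) == 4
        assert all(s.shape == test.pixels.shape for s in record.stages)

    @pytest.mark.parametrize("mode", ["block1_fixed", "per_block"])
    def test_both_target_modes_run(self, fitted, mode):
        model, _, test = fitted
        work = CascadeDenoiser(**{**model.get_params(deep=False), "target_mode": mode})
        work.blocks_ = model.blocks_
        record = work.fine_tune(test.pixels)
        assert record.final.shape == test.pixels.shape

    def test_functional_wrappers(self, tiny_datasets):
        from cryocdae.autoencoder import BlockSpec, TrainConfig

        tiers, test = tiny_datasets
        model = pretrain(
            tiers, spec=BlockSpec(channels=4), cfg=TrainConfig(epochs=1), seed=3
        )
        model.set_params(k_neighbors=3)
        model, record = finetune(model, test, cfg=TrainConfig(epochs=1))
        out = denoise(model, test)
        assert out.pixels.shape == test.pixels.shape
        assert np.array_equal(out.labels, test.labels)
        assert record.final is not None


class TestDenoise:
    def test_composition_equals_manual_chain_plus_equalization(self, fitted):
        model, _, test = fitted
        enhanced = CascadeDenoiser(**{**model.get_params(deep=False), "enhance": True})
        enhanced.blocks_ = model.blocks_
        enhanced.finetuned_blocks_ = None
        out = enhanced.transform(test.pixels)
        manual = test.pixels
        for blk in model.blocks_:
            manual = blk.transform(manual)
        manual = equalize_stack(ImageStack(manual)).pixels
        assert np.allclose(out, manual, atol=1e-6)

    def test_deterministic_across_calls(self, fitted):
        model, _, test = fitted
        assert np.array_equal(model.transform(test.pixels), model.transform(test.pixels))

    def test_enhance_false_returns_raw_cascade_output(self, fitted):
        model, _, test = fitted
        out = model.transform(test.pixels)  # enhance=False in fixture
        manual = test.pixels
        for blk in model.blocks_:
            manual = blk.transform(manual)
        assert np.array_equal(out, manual)

    def test_near_identity_blocks_on_constant_stack(self):
        const = np.full((128, 16, 16), 0.5, dtype=np.float32)
        tiers = [const] * 4
        model = CascadeDenoiser(
            block=ConvDenoisingAutoencoder(
                channels=8, epochs=20, learning_rate=1e-2, batch_size=16, random_state=0
            ),
            enhance=False,
            random_state=2,
        )
        model.fit(tiers)
        out = model.transform(const[:4])
        assert np.abs(out - const[:4]).max() < 0.05


class TestProgressiveDenoising:
    def test_denoising_gain_and_stagewise_psnr(self, tiny_datasets):
        """Pre-trained cascade beats raw noisy input on held-out data."""
        tiers, test = tiny_datasets
        model = CascadeDenoiser(
            block=ConvDenoisingAutoencoder(channels=8, epochs=8, learning_rate=3e-3, random_state=0),
            k_neighbors=5,
            enhance=False,
            random_state=4,
        )
        model.fit([t.pixels for t in tiers])
        record = model.fine_tune(test.pixels)
        clean = test.clean_ref.pixels
        stage_db = [psnr(clean, s).mean_db for s in record.stages]
        assert stage_db[-1] > stage_db[0]
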