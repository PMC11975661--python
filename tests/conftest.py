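import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_phantom_config():
    """A fast 64x64 phantom configuration used across modules."""
    from dsca.phantom import PhantomConfig

    return PhantomConfig(image_size=64, n_patients=3, seed=11)


@pytest.fixture(scope="session")
def toy_disk_shards():
    """Separable toy task: noise-free disks, 64x64, patient-grouped shards."""
    from dsca.io_prep import normalize_image, SliceRecord
    from dsca.phantom import PhantomConfig, generate_phantom

    config = PhantomConfig(image_size=64, perturb_amplitude=0.0, noise_sigma=0.0,
                           area_range_mm2=(80.0, 200.0), seed=21)
    def shard(patients, slices):
        pairs = []
        for p in patients:
            for s in range(slices):
                sample = generate_phantom(config, p, s)
                rec = SliceRecord(image=normalize_image(sample.image),
                                  patient_id=sample.patient_id,
                                  slice_id=sample.slice_id,
                                  pixel_spacing_mm=sample.pixel_spacing_mm)
                pairs.append((rec, sample.mask))
        return pairs

    return shard(["A", "B", "C", "D"], 4), shard(["E", "F"], 3)


@pytest.fixture(scope="session")
def random_mask_pairs():
    """Seeded random binary mask pairs for statistics oracle checks."""
    rng = np.random.default_rng(99)
    pairs = []
    for _ in range(20):
        shape = (rng.integers(4, 12), rng.integers(4, 12))
        truth = (rng.random(shape) > 0.6).astype(np.float32)
        pred = (rng.random(shape) > 0.6).astype(np.float32)
        pairs.append((pred, truth))
    return pairs
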