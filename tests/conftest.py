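import numpy as np
import pytest

from autoctr import phantom as ph
from autoctr import preprocess as pp
from autoctr import unet as un


def make_measurement_table(n: int = 100, delta: float = 0.03,
                           noise: float = 0.005, seed: int = 11):
    """Synthetic observer table: four concordant humans and a model whose
    CTR is shifted down by ``delta`` — large versus the per-observer noise
    but small versus the between-image spread, so group tests detect the
    shift while rank correlation stays high."""
    import pandas as pd

    rng = np.random.default_rng(seed)
    true_ctr = rng.normal(0.50, 0.03, n)
    true_ttd = rng.normal(200.0, 10.0, n)
    rows = []
    for i in range(n):
        sid = f"im{i:03d}"
        for obs in ("OBS1", "OBS2", "OBS3", "OBS4"):
            c = true_ctr[i] + rng.normal(0, noise)
            t = true_ttd[i] + rng.normal(0, 2.0)
            rows.append(dict(source_id=sid, observer=obs, tcd=c * t,
                             ttd=t, ctr=c, time_s=rng.uniform(10, 20),
                             projection="PA"))
        c_ai = true_ctr[i] - delta + rng.normal(0, noise)
        t_ai = true_ttd[i] - 8.0 + rng.normal(0, 2.0)
        rows.append(dict(source_id=sid, observer="AI", tcd=c_ai * t_ai,
                         ttd=t_ai, ctr=c_ai, time_s=0.005, projection="PA"))
    return pd.DataFrame(rows)


@pytest.fixture(scope="session")
def measurement_table():
    return make_measurement_table()


@pytest.fixture(scope="session")
def phantom_training_run():
    """Train the small phantom model once per session.

    64 training phantoms + 16 validation phantoms at 128x128, a
    three-level/base-8 U-Net, 15 epochs of Adam at the default learning
    rate, no augmentation, fully seed-pinned.  Shared by the training,
    inference, and evaluation tests.
    """
    truths = ph.generate_dataset(80, seed=42, canvas=(128, 128))
    images = np.stack([t.image for t in truths])
    masks = np.stack([t.mask.stacked() for t in truths]).astype(np.float32)
    stats = pp.fit_normalizer(images[:64])
    x = pp.standardize(images, stats).astype(np.float32)

    cfg = un.UNetConfig(input_shape=(128, 128, 1), n_levels=3, base_filters=8)
    model = un.build_unet(cfg, rng=np.random.default_rng(7))
    tcfg = un.TrainingConfig(epochs=15, batch_size=8, seed=7)
    history = un.train(model, (x[:64], masks[:64]), (x[64:], masks[64:]), tcfg)
    return {
        "model": model,
        "history": history,
        "x_train": x[:64], "masks_train": masks[:64],
        "x_val": x[64:], "masks_val": masks[64:],
        "truths": truths,
        "stats": stats,
    }
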