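import numpy as np
import pytest
from PIL import Image

from lcnet.dataio import ImageRecord, Label
from lcnet.preprocess import standardize
from lcnet.synthgen import SynthSpec, generate_dataset


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_synth_set():
    """24 base images + 2 exact duplicates, raw 192x192 renders."""
    return generate_dataset(SynthSpec(n_per_class=12, duplicate_rate=0.1, seed=3))


@pytest.fixture(scope="session")
def preprocessed_records(small_synth_set):
    """The small synthetic set standardized to 128x128."""
    records, _ = small_synth_set
    return [
        ImageRecord(r.id, standardize(r.pixels), r.label, r.split) for r in records
    ]


@pytest.fixture
def disk_dataset(tmp_path):
    """A tiny on-disk dataset: PNG files plus a manifest CSV."""
    rng = np.random.default_rng(7)
    rows = ["image_path,label"]
    for i in range(4):
        label = "MEL" if i % 2 == 0 else "BEN"
        px = rng.integers(0, 256, size=(32, 32, 3), dtype=np.uint8)
        path = tmp_path / f"img_{i}.png"
        Image.fromarray(px).save(path)
        rows.append(f"{path},{label}")
    manifest = tmp_path / "manifest.csv"
    manifest.write_text("\n".join(rows) + "\n")
    return manifest


def make_record(pixels: np.ndarray, label=Label.BEN, rec_id="r0") -> ImageRecord:
    return ImageRecord(id=rec_id, pixels=pixels, label=label)
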