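import numpy as np
import pytest

from vaefusion.synthetic_data import SyntheticConfig, generate


@pytest.fixture(scope="session")
def tiny_dataset(tmp_path_factory):
    """A small clean synthetic dataset (no uncertain/missing/single-view)."""
    root = tmp_path_factory.mktemp("tiny")
    config = SyntheticConfig(n_patients=12, image_size=32, seed=7,
                             positive_fraction=0.5)
    manifest = generate(config, root)
    return {"root": root, "manifest": manifest, "config": config}


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def write_manifest(path, rows):
    """Write a CheXpert-dialect manifest from (path, view, proj, label) tuples."""
    header = "Path,Sex,Age,Frontal/Lateral,AP/PA/Lateral,Pneumonia\n"
    lines = [f"{p},Unknown,60,{view},{proj},{label}" for p, view, proj, label in rows]
    path.write_text(header + "\n".join(lines) + "\n")
    return path
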