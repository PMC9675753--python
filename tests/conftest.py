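import numpy as np
import pytest

from myofiberquant.synthetic import ArtifactSpec, SectionSpec, generate_section


@pytest.fixture(scope="session")
def small_scene():
    """A 768x768 px section with default parameters (including artifacts)."""
    return generate_section(SectionSpec(seed=42, width_px=768, height_px=768))


@pytest.fixture(scope="session")
def clean_scene():
    """A 1024x1024 px artifact-free section, used by reconstruction tests."""
    spec = SectionSpec(
        seed=7,
        width_px=1024,
        height_px=1024,
        artifact_spec=ArtifactSpec(n_dark_blobs=0, n_tears=0),
    )
    return generate_section(spec)


def random_blob_scene(rng, n_masks=12, size=140):
    """Random disjoint-ish circular blobs as a LabelImage (test helper)."""
    from myofiberquant.imaging import LabelImage

    arr = np.zeros((size, size), dtype=np.int32)
    for lab in range(1, n_masks + 1):
        r, c = rng.integers(10, size - 10, 2)
        rad = int(rng.integers(3, 9))
        yy, xx = np.ogrid[-rad : rad + 1, -rad : rad + 1]
        m = yy**2 + xx**2 <= rad**2
        arr[r - rad : r + rad + 1, c - rad : c + rad + 1][m] = lab
    return LabelImage(arr)
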