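import numpy as np
import pytest

from tasselkit import AnnotationSet, BBox, ImageSpec, TasselCategory


@pytest.fixture(scope="session")
def uav_frame() -> ImageSpec:
    """Full-resolution UAV frame at the default GSD."""
    return ImageSpec(8192, 5460, 0.25)


@pytest.fixture(scope="session")
def desk_frame() -> ImageSpec:
    return ImageSpec(2048, 2048, 0.25)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


def make_random_annotations(
    rng: np.random.Generator,
    img: ImageSpec,
    n_boxes: int,
    image_id: str = "rand",
) -> AnnotationSet:
    boxes = []
    for _ in range(n_boxes):
        w = float(rng.uniform(10, 200))
        h = float(rng.uniform(10, 200))
        cx = float(rng.uniform(w / 2, img.width_px - w / 2))
        cy = float(rng.uniform(h / 2, img.height_px - h / 2))
        cat = TasselCategory(int(rng.integers(0, 3)))
        boxes.append(BBox(cat, cx, cy, w, h))
    return AnnotationSet(image_id=image_id, image_spec=img, boxes=tuple(boxes))
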