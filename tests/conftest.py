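import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from sphereq.io_formats import ChannelImage

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


def make_image(arr, dtype_max=255, label="x"):
    dtype = np.uint8 if dtype_max == 255 else np.uint16
    return ChannelImage(
        pixels=np.asarray(arr, dtype=dtype), dtype_max=dtype_max, channel_label=label
    )


def disk_bool(shape, center, radius):
    rr, cc = np.ogrid[: shape[0], : shape[1]]
    return (rr - center[0]) ** 2 + (cc - center[1]) ** 2 <= radius**2


def flood_fill_components(mask):
    """Brute-force 8-connected component labeling oracle (BFS)."""
    mask = np.asarray(mask, bool)
    labels = np.zeros(mask.shape, dtype=int)
    nxt = 0
    for sr in range(mask.shape[0]):
        for sc in range(mask.shape[1]):
            if not mask[sr, sc] or labels[sr, sc]:
                continue
            nxt += 1
            stack = [(sr, sc)]
            labels[sr, sc] = nxt
            while stack:
                r, c = stack.pop()
                for dr in (-1, 0, 1):
                    for dc in (-1, 0, 1):
                        nr, nc = r + dr, c + dc
                        if (
                            0 <= nr < mask.shape[0]
                            and 0 <= nc < mask.shape[1]
                            and mask[nr, nc]
                            and not labels[nr, nc]
                        ):
                            labels[nr, nc] = nxt
                            stack.append((nr, nc))
    return labels


def canonical_labels(labels):
    """Relabel a label image by first-occurrence order for comparison."""
    labels = np.asarray(labels)
    out = np.zeros_like(labels)
    mapping = {}
    flat = labels.ravel()
    res = out.ravel()
    for i, v in enumerate(flat):
        if v == 0:
            continue
        if v not in mapping:
            mapping[v] = len(mapping) + 1
        res[i] = mapping[v]
    return out


@pytest.fixture(scope="session")
def small_field():
    """One small spheroid field with ~40 nuclei, shared across tests."""
    from sphereq.synthetic import SynthesisParams, generate_stack

    params = SynthesisParams(
        seed=11,
        image_shape=(256, 320),
        n_spheroids=1,
        spheroid_radius_range=(95.0, 110.0),
        n_nuclei_per_spheroid=40,
    )
    return generate_stack(params)
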