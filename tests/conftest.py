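import numpy as np
import pytest

from glymphoquant.simulate import ImageSimParams, simulate_if_image


@pytest.fixture(scope="session")
def noiseless_image_factory():
    """Factory for small noiseless simulated images with ground truth."""

    def make(enrichment: float = 3.0, seed: int = 7, n_vessels: int = 5):
        params = ImageSimParams(
            height=160,
            width=160,
            n_vessels=n_vessels,
            vessel_radius=6,
            ring_width=3,
            perivascular_enrichment=enrichment,
            noise_sd=0.0,
            seed=seed,
        )
        return simulate_if_image(params)

    return make


def brute_force_index(plane: np.ndarray, m_pv: float) -> float:
    """Independent per-pixel counter for the polarization index."""
    below = 0
    total = 0
    for row in np.asarray(plane, dtype=float):
        for value in row:
            total += 1
            if value < m_pv:
                below += 1
    return 100.0 * below / total
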