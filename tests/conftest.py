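"""Shared fixtures and helpers for the octoseg test suite."""

from __future__ import annotations

import numpy as np
import pytest

from octoseg.types import BoundarySet, BScan, LabelMask


def random_monotone_boundaries(
    rng: np.random.Generator, height_px: int, width_px: int, image_id: str = ""
) -> BoundarySet:
    """Three random ordered traces strictly inside the image."""
    lo = rng.uniform(0.05, 0.25)
    mid = rng.uniform(lo + 0.1, 0.6)
    hi = rng.uniform(mid + 0.1, 0.9)
    jitter = lambda: rng.normal(0.0, 0.02 * height_px, size=width_px)  # noqa: E731
    ilm = np.clip(lo * height_px + jitter(), 0, height_px - 1)
    cc = np.clip(mid * height_px + jitter(), 0, height_px - 1)
    csi = np.clip(hi * height_px + jitter(), 0, height_px - 1)
    cc = np.maximum(cc, ilm)
    csi = np.maximum(csi, cc)
    return BoundarySet(ilm=ilm, cc=cc, csi=csi, height_px=height_px, image_id=image_id)


def random_mask(rng: np.random.Generator, height_px: int, width_px: int) -> LabelMask:
    return LabelMask(labels=rng.integers(0, 4, size=(height_px, width_px)))


def gray_scan(height_px: int = 8, width_px: int = 6, value: float = 0.5, **kw) -> BScan:
    return BScan(pixels=np.full((height_px, width_px), value), **kw)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)


@pytest.fixture
def small_phantoms():
    """Six small phantoms with ground-truth boundaries (cached per test)."""
    from octoseg.phantom import PhantomConfig, generate_phantoms

    cfg = PhantomConfig(
        width_px=64,
        height_px=64,
        n_images=6,
        boundary_wave_amplitude_px=1.0,
        cc_band_px=1,
        seed=77,
    )
    return generate_phantoms(cfg)
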