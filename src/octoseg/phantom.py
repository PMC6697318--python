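"""Synthetic OCT-like phantoms and simulated human graders.

The phantom generator emulates the gross axial reflectivity profile of a
posterior-segment B-scan: a dark vitreous, a bright retina, a thin dark
choriocapillaris band just below the retina–choroid boundary, a textured
choroid and a somewhat brighter sclera, all separated by smooth curved
boundaries and degraded by multiplicative speckle (a gamma-distributed
surrogate with unit mean, as is standard for coherent imaging noise).

Simulated graders redraw the true boundary lines with a per-line constant
bias plus smooth (spatially correlated) jitter, mimicking humans who draw
continuous lines rather than making independent per-column errors.  The
choroid–sclera interface (CSI) is given the largest default jitter because it
is the hardest line to delineate; per-group default magnitudes (laymen >
expert ophthalmologists > reading-center experts) are package defaults for
synthetic benchmarking, not estimates of any real grader population.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from . import io as oio
from .types import BoundarySet, BScan, DeviceKind, ValidationError

__all__ = [
    "PhantomConfig",
    "GraderProfile",
    "BenchmarkFixture",
    "DEFAULT_GROUP_SIGMAS",
    "generate_phantoms",
    "simulate_grader",
    "build_benchmark_fixture",
]


@dataclass
class PhantomConfig:
    """Parameters of the synthetic B-scan generator.

    ``boundary_mean_depths`` are the ILM/CC/CSI mean positions as fractions of
    image height; ``boundary_wave_amplitude_px`` and ``boundary_wave_count``
    control the smooth sinusoidal curvature of the boundaries;
    ``layer_mean_intensities`` are the vitreous/retina/choroid/sclera mean
    reflectivities; ``speckle_shape`` is the gamma shape parameter of the
    unit-mean multiplicative speckle (larger = cleaner image).
    """

    width_px: int = 384
    height_px: int = 496
    n_images: int = 10
    boundary_mean_depths: tuple[float, float, float] = (0.15, 0.45, 0.70)
    boundary_wave_amplitude_px: float = 8.0
    boundary_wave_count: float = 2.0
    layer_mean_intensities: tuple[float, float, float, float] = (0.05, 0.60, 0.35, 0.55)
    speckle_shape: float = 8.0
    cc_band_px: int = 4
    cc_band_intensity: float = 0.12
    choroid_texture_amplitude: float = 0.08
    device_kind: DeviceKind = DeviceKind.SD
    id_prefix: str = "phantom"
    seed: int = 0

    def __post_init__(self) -> None:
        d = self.boundary_mean_depths
        if not (0.0 < d[0] < d[1] < d[2] < 1.0):
            raise ValidationError(
                "boundary_mean_depths must be strictly increasing in (0, 1)"
            )
        if any(not 0.0 <= m <= 1.0 for m in self.layer_mean_intensities):
            raise ValidationError("layer_mean_intensities must lie in [0, 1]")
        if self.speckle_shape <= 0:
            raise ValidationError("speckle_shape must be positive")
        if self.width_px < 2 or self.height_px < 4:
            raise ValidationError("phantom geometry too small")


#: Synthetic default jitter magnitudes (ilm, cc, csi) in pixels per grader
#: group: laymen (L) > expert ophthalmologists (EO) > reading center (RC),
#: with the CSI always the noisiest line.
DEFAULT_GROUP_SIGMAS: dict[str, tuple[float, float, float]] = {
    "L": (2.0, 3.0, 9.0),
    "EO": (1.2, 1.8, 5.0),
    "RC": (0.8, 1.2, 3.0),
}


@dataclass
class GraderProfile:
    """A simulated grader: per-line jitter sigma and bias, plus smoothness."""

    name: str
    group: str = "EO"  # one of L / EO / RC
    boundary_sigma_px: tuple[float, float, float] = (1.2, 1.8, 5.0)
    bias_px: tuple[float, float, float] = (0.0, 0.0, 0.0)
    smoothness_scale_px: float = 40.0
    seed: int = 0

    def __post_init__(self) -> None:
        if any(s < 0 for s in self.boundary_sigma_px):
            raise ValidationError("boundary_sigma_px must be non-negative")
        if self.smoothness_scale_px <= 0:
            raise ValidationError("smoothness_scale_px must be positive")
        if self.group not in ("L", "EO", "RC"):
            raise ValidationError("group must be one of L, EO, RC")


def _boundary_traces(
    rng: np.random.Generator, config: PhantomConfig
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Draw three smooth, strictly ordered boundary traces."""
    w, h = config.width_px, config.height_px
    x = np.arange(w, dtype=np.float64) / max(w - 1, 1)
    traces = []
    for depth in config.boundary_mean_depths:
        trace = np.full(w, depth * h)
        # fundamental + half-amplitude second harmonic, random phase/frequency
        for harmonic, amp_frac in ((1.0, 1.0), (2.0, 0.5)):
            amp = config.boundary_wave_amplitude_px * amp_frac * rng.uniform(0.6, 1.0)
            freq = config.boundary_wave_count * harmonic * rng.uniform(0.7, 1.3)
            phase = rng.uniform(0.0, 2.0 * np.pi)
            trace = trace + amp * np.sin(2.0 * np.pi * freq * x + phase)
        traces.append(trace)
    ilm, cc, csi = traces
    if (cc - ilm).min() <= 0 or (csi - cc).min() <= 0:
        raise ValidationError(
            "boundary_wave_amplitude_px too large: generated boundaries cross"
        )
    if ilm.min() < 0 or csi.max() > h - 1:
        raise ValidationError(
            "boundary waves leave the image; reduce amplitude or recenter depths"
        )
    return ilm, cc, csi


def _render(
    rng: np.random.Generator, boundaries: BoundarySet, config: PhantomConfig
) -> np.ndarray:
    """Render the layered reflectivity image for a set of true boundaries."""
    from .compartments import lines_to_mask, round_half_up

    h, w = config.height_px, config.width_px
    mask = lines_to_mask(boundaries, h, w)
    base = np.asarray(config.layer_mean_intensities, dtype=np.float64)[mask.labels]

    # dark choriocapillaris analogue: thin band just below the CC boundary
    if config.cc_band_px > 0:
        cc_rows = round_half_up(boundaries.cc)
        rows = np.arange(h)[:, None]
        band = (rows > cc_rows[None, :]) & (rows <= cc_rows[None, :] + config.cc_band_px)
        base = np.where(band, config.cc_band_intensity, base)

    # low-frequency texture inside the choroid
    if config.choroid_texture_amplitude > 0:
        tex = gaussian_filter(rng.standard_normal((h, w)), sigma=6.0)
        tex /= max(tex.std(), 1e-12)
        base = base + config.choroid_texture_amplitude * tex * (mask.labels == 2)

    speckle = rng.gamma(config.speckle_shape, 1.0 / config.speckle_shape, size=(h, w))
    return np.clip(base * speckle, 0.0, 1.0)


def generate_phantoms(config: PhantomConfig) -> list[tuple[BScan, BoundarySet]]:
    """Generate ``config.n_images`` (image, true-boundaries) pairs.

    Fully reproducible: the same config (including seed) yields bit-identical
    output.
    """
    rng = np.random.default_rng(config.seed)
    out = []
    for i in range(config.n_images):
        image_id = f"{config.id_prefix}-{i:03d}"
        ilm, cc, csi = _boundary_traces(rng, config)
        boundaries = BoundarySet(
            ilm=ilm, cc=cc, csi=csi, height_px=config.height_px, image_id=image_id
        )
        pixels = _render(rng, boundaries, config)
        scan = BScan(
            pixels=pixels,
            device_kind=config.device_kind,
            id=image_id,
        )
        out.append((scan, boundaries))
    return out


def _smooth_noise(
    rng: np.random.Generator, n: int, sigma: float, scale: float
) -> np.ndarray:
    """Stationary smooth Gaussian noise with pointwise std exactly ``sigma``.

    White noise is convolved with a Gaussian kernel of width ``scale`` that is
    normalized to unit L2 norm, so every output point is N(0, sigma^2) while
    neighbouring points are correlated over ~``scale`` columns.
    """
    if sigma == 0.0:
        return np.zeros(n)
    half = max(int(np.ceil(4.0 * scale)), 1)
    t = np.arange(-half, half + 1, dtype=np.float64)
    kernel = np.exp(-0.5 * (t / scale) ** 2)
    kernel /= np.linalg.norm(kernel)
    white = rng.standard_normal(n + 2 * half)
    return sigma * np.convolve(white, kernel, mode="valid")


def _sub_rng(seed: int, run_index: int, image_id: str) -> np.random.Generator:
    # stable across sessions: image id hashed with crc32 (not Python hash())
    return np.random.default_rng(
        np.random.SeedSequence([seed, run_index, zlib.crc32(image_id.encode())])
    )


def simulate_grader(
    truth: BoundarySet, profile: GraderProfile, run_index: int = 0
) -> BoundarySet:
    """One simulated annotation run: truth + bias + smooth correlated jitter.

    Deterministic given ``(profile.seed, run_index, truth.image_id)``.  The
    jittered lines are re-projected onto the ordering invariant by clamping
    (``cc <- max(cc, ilm)``, ``csi <- max(csi, cc)``) and clipped to the image.
    """
    rng = _sub_rng(profile.seed, run_index, truth.image_id)
    w, h = truth.width_px, truth.height_px
    lines = []
    for tr, sigma, bias in zip(
        truth.traces(), profile.boundary_sigma_px, profile.bias_px
    ):
        lines.append(
            tr + bias + _smooth_noise(rng, w, sigma, profile.smoothness_scale_px)
        )
    ilm, cc, csi = lines
    cc = np.maximum(cc, ilm)
    csi = np.maximum(csi, cc)
    ilm = np.clip(ilm, 0.0, h - 1)
    cc = np.clip(cc, ilm, h - 1)
    csi = np.clip(csi, cc, h - 1)
    return BoundarySet(ilm=ilm, cc=cc, csi=csi, height_px=h, image_id=truth.image_id)


@dataclass
class BenchmarkFixture:
    """The synthetic analogue of a 60-image multi-grader benchmark.

    30 SD-geometry + 30 SS-geometry phantoms with ground-truth boundaries,
    nine grader profiles (three per group L/EO/RC), and three simulated
    annotation runs per grader per image.
    """

    scans: list[BScan]
    ground_truth: dict[str, BoundarySet]
    profiles: list[GraderProfile]
    #: (grader_name, run_index in {1,2,3}, image_id) -> simulated annotation
    annotations: dict[tuple[str, int, str], BoundarySet] = field(default_factory=dict)

    @property
    def image_ids(self) -> list[str]:
        return [s.id for s in self.scans]

    def graders_in_group(self, group: str) -> list[str]:
        return [p.name for p in self.profiles if p.group == group]


def build_benchmark_fixture(
    seed: int,
    out_dir: str | Path | None = None,
    n_per_device: int = 30,
    graders_per_group: int = 3,
    n_runs: int = 3,
    sd_size: tuple[int, int] = (384, 496),
    ss_size: tuple[int, int] = (512, 992),
    group_sigmas: dict[str, tuple[float, float, float]] | None = None,
) -> BenchmarkFixture:
    """Build the synthetic benchmark bundle (optionally persisted to disk)."""
    group_sigmas = group_sigmas or DEFAULT_GROUP_SIGMAS
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0xB0B]))

    base = PhantomConfig()
    scans: list[BScan] = []
    ground_truth: dict[str, BoundarySet] = {}
    for device, (w, h) in (("SD", sd_size), ("SS", ss_size)):
        cfg = replace(
            base,
            width_px=w,
            height_px=h,
            n_images=n_per_device,
            device_kind=DeviceKind(device),
            id_prefix=f"bench-{device.lower()}",
            seed=int(rng.integers(2**31)),
            boundary_wave_amplitude_px=base.boundary_wave_amplitude_px * h / 496.0,
        )
        for scan, bset in generate_phantoms(cfg):
            scans.append(scan)
            ground_truth[scan.id] = bset

    profiles: list[GraderProfile] = []
    for group in ("L", "EO", "RC"):
        sigmas = np.asarray(group_sigmas[group], dtype=np.float64)
        for j in range(graders_per_group):
            bias = rng.normal(0.0, sigmas / 3.0)
            profiles.append(
                GraderProfile(
                    name=f"{group}{j + 1}",
                    group=group,
                    boundary_sigma_px=tuple(sigmas),
                    bias_px=tuple(bias),
                    seed=int(rng.integers(2**31)),
                )
            )

    annotations: dict[tuple[str, int, str], BoundarySet] = {}
    for profile in profiles:
        for run in range(1, n_runs + 1):
            for image_id, truth in ground_truth.items():
                annotations[(profile.name, run, image_id)] = simulate_grader(
                    truth, profile, run_index=run
                )

    fixture = BenchmarkFixture(
        scans=scans,
        ground_truth=ground_truth,
        profiles=profiles,
        annotations=annotations,
    )
    if out_dir is not None:
        _persist_fixture(fixture, Path(out_dir))
    return fixture


def _persist_fixture(fixture: BenchmarkFixture, out_dir: Path) -> None:
    (out_dir / "images").mkdir(parents=True, exist_ok=True)
    (out_dir / "annotations").mkdir(parents=True, exist_ok=True)
    rows = []
    for scan in fixture.scans:
        oio.write_bscan(scan, out_dir / "images" / f"{scan.id}.png")
        gt = fixture.ground_truth[scan.id]
        oio.write_annotation(gt, out_dir / "annotations" / f"{scan.id}__gt.json")
        rows.append(
            {
                "image_id": scan.id,
                "device_kind": scan.device_kind.value,
                "width_px": scan.width_px,
                "height_px": scan.height_px,
            }
        )
    for (grader, run, image_id), bset in fixture.annotations.items():
        oio.write_annotation(
            bset, out_dir / "annotations" / f"{image_id}__{grader}__run{run}.json"
        )
    pd.DataFrame(rows).to_csv(out_dir / "manifest.csv", index=False)
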