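"""4096-d image features and per-well vehicle normalization.

Raster-plot windows are summarized by a 4096-dimensional descriptor in
the style of a late fully connected layer (fc7) of a pretrained
object-recognition network.  Two backends share the contract:

``fixture``
    A deterministic, dependency-free extractor: the image is inverted
    (ink as signal), downsampled to 64 x 64, transformed to its 2-D
    log-amplitude spectrum, and passed through a fixed seeded Gaussian
    random projection to 4096 outputs.  The amplitude spectrum discards
    the phase of the burst pattern within the window — the same
    translation invariance a convolutional backbone acquires through
    pooling — while keeping burst rate, width and density linearly
    readable; the random projection approximately preserves that
    geometry in 4096 dimensions.
``alexnet``
    The reference pretrained backbone (fc7 activations of AlexNet).
    Loaded lazily; raises a descriptive error when torch/torchvision are
    not installed, naming the fixture backend as the remediation.

Differences in each well's initial state are removed by centering every
feature vector on the per-dimension mean of that same well's vehicle
windows ("vehicle normalization"); a z-score variant is available.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
from PIL import Image

from mearaster.rasterization import RasterImage

FEATURE_DIM = 4096
_FIXTURE_INPUT = 64  # fixture backend downsampling size
_FIXTURE_SPECTRUM_SHAPE = (_FIXTURE_INPUT, _FIXTURE_INPUT // 2 + 1)  # rfft2 of a real image
_FIXTURE_GRID = 16  # coarse ink-density grid appended to the spectrum
_FIXTURE_GRID_GAIN = 4.0  # puts the grid channel on the spectrum's scale

__all__ = ["FEATURE_DIM", "ExtractorSpec", "FeatureVector", "extract_features", "vehicle_normalize"]


@dataclass(frozen=True)
class ExtractorSpec:
    """Which backbone produces the 4096-d descriptor.

    ``layer_id`` names the fully connected layer tapped on the reference
    backbone (fc7, its 21st layer); the fixture backend ignores it.
    """

    backend_id: str = "fixture"
    layer_id: str = "fc7"
    input_size: int = 227
    weights_source: str = "pretrained"
    seed: int = 2022

    def __post_init__(self):
        if self.backend_id not in ("fixture", "alexnet"):
            raise ValueError(f"unknown backend {self.backend_id!r}")


@dataclass(frozen=True)
class FeatureVector:
    """4096 finite reals + provenance; ``normalized`` marks vehicle centering."""

    values: np.ndarray
    well_id: str
    compound: str
    concentration: float
    is_vehicle: bool
    window_index: int
    normalized: bool = False

    def __post_init__(self):
        v = np.asarray(self.values)
        if v.shape != (FEATURE_DIM,):
            raise ValueError(f"feature vector must have length {FEATURE_DIM}, got {v.shape}")
        if not np.all(np.isfinite(v)):
            raise ValueError("feature vector contains non-finite values")
        object.__setattr__(self, "values", v)


_projection_cache: dict[int, np.ndarray] = {}


def fixture_projection(seed: int) -> np.ndarray:
    """The fixture backend's fixed (spectrum -> 4096) Gaussian projection."""
    if seed not in _projection_cache:
        rng = np.random.default_rng(seed)
        d_in = _FIXTURE_SPECTRUM_SHAPE[0] * _FIXTURE_SPECTRUM_SHAPE[1] + _FIXTURE_GRID**2
        _projection_cache[seed] = rng.standard_normal((d_in, FEATURE_DIM)).astype(
            np.float32
        ) / np.sqrt(d_in)
    return _projection_cache[seed]


def fixture_descriptor(pixels: np.ndarray) -> np.ndarray:
    """The fixture backend's pre-projection descriptor of an image.

    Two channels of the ink-inverted image: the log1p amplitude of the
    2-D FFT of the 64 x 64 downsample (burst rhythm, width and density,
    invariant to where bursts fall inside the window) and a 16 x 16
    mean-ink grid (which electrode rows are active, and how dark).
    """
    pil = Image.fromarray(pixels, mode="L")
    x = 1.0 - np.asarray(
        pil.resize((_FIXTURE_INPUT, _FIXTURE_INPUT), Image.BILINEAR), dtype=np.float32
    ) / 255.0
    spectrum = np.log1p(np.abs(np.fft.rfft2(x))).ravel()
    grid = 1.0 - np.asarray(
        pil.resize((_FIXTURE_GRID, _FIXTURE_GRID), Image.BILINEAR), dtype=np.float32
    ).ravel() / 255.0
    return np.concatenate([spectrum, _FIXTURE_GRID_GAIN * grid]).astype(np.float32)


def _extract_fixture(img: RasterImage, spec: ExtractorSpec) -> np.ndarray:
    d = fixture_descriptor(img.pixels)
    return (d @ fixture_projection(spec.seed)).astype(np.float64)


def _extract_alexnet(img: RasterImage, spec: ExtractorSpec) -> np.ndarray:
    try:
        import torch  # noqa: F401
        import torchvision  # noqa: F401
    except ImportError as exc:
        raise RuntimeError(
            "the 'alexnet' backend requires torch and torchvision; install them "
            "or use ExtractorSpec(backend_id='fixture') for the deterministic "
            "dependency-free extractor"
        ) from exc
    import torch
    from torchvision import models, transforms

    model = models.alexnet(weights=models.AlexNet_Weights.IMAGENET1K_V1)
    model.eval()
    # grayscale raster replicated to 3 channels; standard ImageNet statistics
    pil = Image.fromarray(img.pixels, mode="L").convert("RGB")
    prep = transforms.Compose(
        [
            transforms.Resize((spec.input_size, spec.input_size)),
            transforms.ToTensor(),
            transforms.Normalize([0.485, 0.456, 0.406], [0.229, 0.224, 0.225]),
        ]
    )
    with torch.no_grad():
        x = prep(pil).unsqueeze(0)
        feats = model.features(x)
        feats = model.avgpool(feats).flatten(1)
        # fc7 = second Linear of the classifier head (4096 outputs)
        h = feats
        for layer in model.classifier[:5]:
            h = layer(h)
    return h.squeeze(0).numpy().astype(np.float64)


def extract_features(img: RasterImage, spec: ExtractorSpec | None = None) -> FeatureVector:
    """4096-d descriptor of one raster image; pure and deterministic."""
    spec = spec or ExtractorSpec()
    if spec.backend_id == "fixture":
        values = _extract_fixture(img, spec)
    else:
        values = _extract_alexnet(img, spec)
    c = img.condition
    return FeatureVector(
        values=values,
        well_id=img.well_id,
        compound=c.compound,
        concentration=c.concentration,
        is_vehicle=c.is_vehicle,
        window_index=img.window_index,
    )


def vehicle_normalize(
    features: Sequence[FeatureVector],
    vehicle_features: Sequence[FeatureVector],
    mode: str = "center",
    eps: float = 1e-8,
) -> list[FeatureVector]:
    """Center each vector on the well's vehicle mean (per dimension).

    All inputs must come from the same well.  ``mode='zscore'``
    additionally divides by the vehicle per-dimension s.d. + eps.
    After centering, the mean of the normalized vehicle vectors is the
    zero vector (to floating tolerance), so the operation is idempotent
    on vehicle sets.
    """
    if not vehicle_features:
        raise ValueError("no vehicle features supplied for normalization")
    if mode not in ("center", "zscore"):
        raise ValueError("mode must be 'center' or 'zscore'")
    wells = {f.well_id for f in features} | {f.well_id for f in vehicle_features}
    if len(wells) > 1:
        raise ValueError(f"cross-well normalization attempted: wells {sorted(wells)}")
    veh = np.stack([f.values for f in vehicle_features])
    mean = veh.mean(axis=0)
    if mode == "zscore":
        sd = veh.std(axis=0) + eps
        return [replace(f, values=(f.values - mean) / sd, normalized=True) for f in features]
    return [replace(f, values=f.values - mean, normalized=True) for f in features]
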