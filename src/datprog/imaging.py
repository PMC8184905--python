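"""Stage 1 — spatiotemporal feature extraction from two-timepoint imaging.

Three extraction routes, mirroring the ensemble design:

1. a convolutional LSTM applied directly to the Year-0/Year-1 DaTscan
   volume sequence (provenance ``convlstm_datscan``);
2. a frozen 2D convolutional backbone applied to axial maximum intensity
   projections of each scan, followed by an LSTM over the two embeddings
   (provenances ``backbone_vgg16`` ... ``backbone_inceptionv3``);
3. an LSTM over the two striatal-binding-ratio quadruples, the
   semi-quantitative imaging measures (provenance ``semiquant_lstm``).

Because true ImageNet-pre-trained weights cannot be assumed available, the
named backbones default to a "stub": a small convolutional network with
fixed seed-derived weights and the same interface.  Backbone parameters are
frozen always; all extractors here are deterministic seed-initialized
networks whose parameters are never updated during training, acting as
fixed random-projection feature maps (the trainable part of the pipeline is
the Stage-3 fusion head).
"""

from __future__ import annotations

import dataclasses
import json
import zlib
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from skimage.transform import resize as _sk_resize

from . import _nn
from .cohort import PatientRecord, StriatalVolume

__all__ = [
    "PROVENANCES",
    "BACKBONE_NAMES",
    "FeatureVector",
    "BackboneId",
    "ExtractorSpec",
    "BackboneWeightsError",
    "max_intensity_projection",
    "prepare_backbone_input",
    "convlstm_features",
    "backbone_lstm_features",
    "semiquant_lstm_features",
    "extract_all_imaging",
    "ImagingExtractor",
]

BACKBONE_NAMES = ("vgg16", "resnet50", "densenet121", "inceptionv3")
PROVENANCES = (
    "convlstm_datscan",
    "semiquant_lstm",
    "backbone_vgg16",
    "backbone_resnet50",
    "backbone_densenet121",
    "backbone_inceptionv3",
    "all_imagenet",
    "updrs_lstm",
    "clinical",
)
_STUB_EMBED = 16


class BackboneWeightsError(RuntimeError):
    """Raised when true pre-trained backbone weights are requested."""


@dataclass
class FeatureVector:
    """A fixed-length feature vector tagged with the extractor that made it."""

    provenance: str
    values: np.ndarray

    def __post_init__(self):
        if self.provenance not in PROVENANCES:
            raise ValueError(f"unknown provenance {self.provenance!r}")
        v = np.asarray(self.values, dtype=np.float64).ravel()
        if not np.all(np.isfinite(v)):
            raise ValueError("feature values must be finite")
        self.values = v

    @property
    def length(self) -> int:
        return self.values.size


@dataclass(frozen=True)
class BackboneId:
    """Identity of a frozen 2D backbone.

    ``pretrained=False`` (the default) uses stub weights derived
    deterministically from the backbone name, so the pipeline runs with no
    weight download; requesting ``pretrained=True`` raises, since ImageNet
    weights are not bundled.
    """

    name: str = "stub"
    input_size: tuple[int, int] = (64, 64)
    pretrained: bool = False

    def __post_init__(self):
        if self.name not in BACKBONE_NAMES + ("stub",):
            raise ValueError(f"unknown backbone {self.name!r}")
        if any(s < 8 for s in self.input_size):
            raise ValueError("backbone input_size components must be >= 8")
        object.__setattr__(self, "input_size", tuple(int(s) for s in self.input_size))

    @property
    def frozen(self) -> bool:
        return True


@dataclass(frozen=True)
class ExtractorSpec:
    """Architecture hyperparameters of the Stage-1/Stage-2 extractors."""

    conv_filters: int = 8
    conv_kernel: tuple[int, int, int] = (3, 3, 3)
    lstm_hidden: int = 16
    output_width: int = 16
    seed: int = 0

    def __post_init__(self):
        if min(self.conv_filters, self.lstm_hidden, self.output_width) < 1:
            raise ValueError("widths must be positive")
        if len(self.conv_kernel) != 3 or any(k < 1 or k % 2 == 0 for k in self.conv_kernel):
            raise ValueError("conv_kernel must be three odd positive integers")
        object.__setattr__(self, "conv_kernel", tuple(int(k) for k in self.conv_kernel))

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "ExtractorSpec":
        d = json.loads(Path(path).read_text())
        d["conv_kernel"] = tuple(d["conv_kernel"])
        return cls(**d)


# ---------------------------------------------------------------------------
# deterministic 2D preprocessing
# ---------------------------------------------------------------------------


def max_intensity_projection(volume: StriatalVolume | np.ndarray, axis: int = 2) -> np.ndarray:
    """Project a 3D volume to 2D by taking the maximum along the axial
    (inferior-superior) axis; each output pixel is the brightest voxel of
    its transaxial column."""
    a = volume.intensities if isinstance(volume, StriatalVolume) else np.asarray(volume)
    if a.ndim != 3:
        raise ValueError("expected a 3D volume")
    return a.max(axis=axis)


def prepare_backbone_input(mip: np.ndarray, backbone: BackboneId) -> np.ndarray:
    """Adapt a grayscale MIP to a backbone's input: rescale intensities to
    [0, 1] (a constant image maps to 0.5 everywhere), resize bilinearly to
    the backbone's input size, and replicate across 3 channels."""
    m = np.asarray(mip, dtype=np.float64)
    if m.ndim != 2 or np.any(m < 0):
        raise ValueError("MIP must be a nonnegative 2D image")
    lo, hi = m.min(), m.max()
    m = np.full_like(m, 0.5) if hi == lo else (m - lo) / (hi - lo)
    if m.shape != backbone.input_size:
        m = _sk_resize(
            m, backbone.input_size, order=1, mode="edge",
            anti_aliasing=False, preserve_range=True,
        )
    return np.broadcast_to(m, (3,) + m.shape).copy()


# ---------------------------------------------------------------------------
# parameter construction
# ---------------------------------------------------------------------------


def _backbone_seed(backbone: BackboneId, spec: ExtractorSpec) -> int:
    return int((spec.seed * 1000003 + zlib.crc32(backbone.name.encode())) % (2**31 - 1))


def init_convlstm_params(spec: ExtractorSpec) -> dict:
    rng = np.random.default_rng(spec.seed)
    return {
        "cell": _nn.init_convlstm(rng, 1, spec.conv_filters, spec.conv_kernel),
        "proj": _nn.init_linear(rng, spec.conv_filters, spec.output_width),
    }


def init_semiquant_params(spec: ExtractorSpec) -> dict:
    rng = np.random.default_rng(spec.seed + 1)
    return {
        "lstm": _nn.init_lstm(rng, 4, spec.lstm_hidden),
        "proj": _nn.init_linear(rng, spec.lstm_hidden, spec.output_width),
    }


def init_backbone_params(backbone: BackboneId, spec: ExtractorSpec) -> dict:
    """Build the frozen backbone embedding net plus its LSTM/projection.

    Stub weights are derived from (spec.seed, backbone name); requesting true
    pre-trained weights raises, with instructions.
    """
    if backbone.pretrained:
        raise BackboneWeightsError(
            f"pre-trained ImageNet weights for {backbone.name!r} are not bundled; "
            "construct BackboneId(pretrained=False) to use deterministic stub "
            "weights, or load weights through your own deep-learning runtime"
        )
    rng = np.random.default_rng(_backbone_seed(backbone, spec))
    return {
        "cnn": _nn.init_stub_cnn(rng, in_channels=3, width=_STUB_EMBED),
        "lstm": _nn.init_lstm(rng, _STUB_EMBED, spec.lstm_hidden),
        "proj": _nn.init_linear(rng, spec.lstm_hidden, spec.output_width),
    }


# ---------------------------------------------------------------------------
# feature extraction (per-record ops delegate to batched kernels)
# ---------------------------------------------------------------------------


def _convlstm_batch(x: np.ndarray, spec: ExtractorSpec, params: dict) -> np.ndarray:
    """x: (B, 2, 1, X, Y, Z) -> (B, output_width); final hidden state is
    globally average-pooled then linearly projected."""
    h = _nn.convlstm_forward(x, params["cell"])
    pooled = h.mean(axis=tuple(range(2, h.ndim)))
    return _nn.linear_forward(pooled, params["proj"])


def convlstm_features(
    volumes: list[StriatalVolume], spec: ExtractorSpec, params: dict
) -> FeatureVector:
    """Convolutional-LSTM features from the ordered [Y0, Y1] volume pair."""
    if len(volumes) != 2:
        raise ValueError("expected exactly two timepoints")
    if volumes[0].shape != volumes[1].shape:
        raise ValueError("timepoint volumes must share a shape")
    x = np.stack([v.intensities.astype(np.float64) for v in volumes])[None, :, None]
    return FeatureVector("convlstm_datscan", _convlstm_batch(x, spec, params)[0])


def _backbone_batch(
    mips: np.ndarray, backbone: BackboneId, spec: ExtractorSpec, params: dict
) -> np.ndarray:
    """mips: (B, 2, H, W) -> (B, output_width)."""
    embeds = []
    for t in range(2):
        imgs = np.stack([prepare_backbone_input(m, backbone) for m in mips[:, t]])
        embeds.append(_nn.stub_cnn_forward(imgs, params["cnn"]))
    seq = np.stack(embeds, axis=1)
    return _nn.linear_forward(_nn.lstm_forward(seq, params["lstm"]), params["proj"])


def backbone_lstm_features(
    mips: list[np.ndarray], backbone: BackboneId, spec: ExtractorSpec, params: dict
) -> FeatureVector:
    """Frozen-backbone + LSTM features from the ordered [Y0, Y1] MIP pair."""
    if len(mips) != 2:
        raise ValueError("expected exactly two MIPs")
    name = backbone.name if backbone.name in BACKBONE_NAMES else "vgg16"
    x = np.stack(mips)[None]
    return FeatureVector(f"backbone_{name}", _backbone_batch(x, backbone, spec, params)[0])


def _semiquant_batch(sbr: np.ndarray, spec: ExtractorSpec, params: dict) -> np.ndarray:
    """sbr: (B, 2, 4) -> (B, output_width)."""
    if np.any(sbr < 0):
        raise ValueError("SBR values must be >= 0")
    return _nn.linear_forward(_nn.lstm_forward(sbr, params["lstm"]), params["proj"])


def semiquant_lstm_features(sbr_seq, spec: ExtractorSpec, params: dict) -> FeatureVector:
    """LSTM features from the ordered [Y0, Y1] SBR quadruples."""
    if len(sbr_seq) != 2:
        raise ValueError("expected exactly two timepoints")
    x = np.stack([np.asarray(getattr(s, "as_array", lambda: s)(), dtype=np.float64) for s in sbr_seq])
    return FeatureVector("semiquant_lstm", _semiquant_batch(x[None], spec, params)[0])


# ---------------------------------------------------------------------------
# bundled extractor
# ---------------------------------------------------------------------------

IMAGING_PROVENANCES = (
    "convlstm_datscan",
    "semiquant_lstm",
    "backbone_vgg16",
    "backbone_resnet50",
    "backbone_densenet121",
    "backbone_inceptionv3",
)


class ImagingExtractor:
    """All Stage-1 extractors with their (frozen) parameters.

    Parameters are fully determined by the ExtractorSpec (including its
    seed) and the backbone list, so two extractors built from the same spec
    produce identical features.
    """

    def __init__(self, spec: ExtractorSpec, backbones: tuple[BackboneId, ...] | None = None):
        if backbones is None:
            backbones = tuple(BackboneId(name=n) for n in BACKBONE_NAMES)
        self.spec = spec
        self.backbones = tuple(backbones)
        self.convlstm_params = init_convlstm_params(spec)
        self.semiquant_params = init_semiquant_params(spec)
        self.backbone_params = {b.name: init_backbone_params(b, spec) for b in self.backbones}

    # batched extraction over a list of records -------------------------------

    def extract_batch(
        self, records: list[PatientRecord], request: set[str] | None = None
    ) -> dict[str, np.ndarray]:
        """Feature matrices (n, width) per requested provenance."""
        if request is None:
            request = set(IMAGING_PROVENANCES[:2]) | {
                f"backbone_{b.name}" for b in self.backbones
            }
        out: dict[str, np.ndarray] = {}
        if "convlstm_datscan" in request:
            x = np.stack(
                [
                    np.stack([r.volumes[tp].intensities.astype(np.float64) for tp in ("Y0", "Y1")])
                    for r in records
                ]
            )[:, :, None]
            out["convlstm_datscan"] = _convlstm_batch(x, self.spec, self.convlstm_params)
        if "semiquant_lstm" in request:
            sbr = np.stack(
                [np.stack([r.sbr[tp].as_array() for tp in ("Y0", "Y1")]) for r in records]
            )
            out["semiquant_lstm"] = _semiquant_batch(sbr, self.spec, self.semiquant_params)
        wanted = [b for b in self.backbones if f"backbone_{b.name}" in request]
        if wanted:
            mips = np.stack(
                [
                    np.stack([max_intensity_projection(r.volumes[tp]) for tp in ("Y0", "Y1")])
                    for r in records
                ]
            )
            for b in wanted:
                out[f"backbone_{b.name}"] = _backbone_batch(
                    mips, b, self.spec, self.backbone_params[b.name]
                )
        return out

    def extract(
        self, record: PatientRecord, request: set[str] | None = None
    ) -> dict[str, FeatureVector]:
        mats = self.extract_batch([record], request)
        return {prov: FeatureVector(prov, m[0]) for prov, m in mats.items()}

    def backbone_checksums(self) -> dict[str, str]:
        """Per-backbone parameter digests (to assert frozenness)."""
        return {
            name: _nn.params_checksum(
                {f"{part}.{k}": v for part, sub in p.items() for k, v in sub.items()}
            )
            for name, p in self.backbone_params.items()
        }


def extract_all_imaging(
    record: PatientRecord,
    extractor: ImagingExtractor,
    request: set[str] | None = None,
    include_all_imagenet: bool = False,
) -> dict[str, FeatureVector]:
    """Extract the requested imaging feature vectors for one record.

    With ``include_all_imagenet`` the concatenation of the four backbone
    vectors, in the fixed order vgg16, resnet50, densenet121, inceptionv3,
    is added under the key ``all_imagenet``.
    """
    feats = extractor.extract(record, request)
    if include_all_imagenet:
        parts = [feats[f"backbone_{n}"].values for n in BACKBONE_NAMES]
        feats["all_imagenet"] = FeatureVector("all_imagenet", np.concatenate(parts))
    return feats
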