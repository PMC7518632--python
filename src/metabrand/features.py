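"""Per-slice 2048-dim feature extraction and per-scan sequences.

Each 3-channel slice is summarized by a fixed-length activation vector
of 2048 values; the 80 sampled slices of a scan then form an ordered
80 x 2048 feature sequence (163,840 values per scan) consumed by the
sequence classifier.

Backbones are pluggable.  The default is a deterministic, weight-free
patch-statistics extractor that needs no downloads: the 224x224x3 slice
is partitioned into a 16x16 grid of 14x14 patches and each patch emits
8 statistics (per-channel mean and standard deviation, the max of the
channel-mean image, and mean squared gradient magnitude), giving
256 x 8 = 2048 features.  A pre-trained Inception-v3 ImageNet backbone
can be plugged in through the same interface when a deep-learning
runtime and its weights are available locally.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Iterable, Sequence

import numpy as np

from .branding import BrandedSlice, MarkerSet, brand_slice, MARKER_SHAPE
from .cohort import BinnedMetadata
from .enhancement import (
    ClaheParams,
    EnhancedSlice,
    NlMeansParams,
    PreparedVolume,
    enhance_edited_top,
    enhance_slice,
    select_slices,
)

__all__ = [
    "FEATURE_DIM",
    "SEQUENCE_LENGTH",
    "Backbone",
    "FeatureSequence",
    "surrogate_backbone",
    "pretrained_backbone",
    "enhance_volume",
    "scan_to_sequence",
    "FeatureStore",
    "BackboneUnavailableError",
]

FEATURE_DIM = 2048
SEQUENCE_LENGTH = 80
_GRID = 16  # 16x16 patches of 14x14 pixels
_PATCH = 224 // _GRID
_STATS = 8

INPUT_MODES = ("original", "branded", "widedeep")


class BackboneUnavailableError(RuntimeError):
    """A requested pre-trained backbone cannot be constructed here."""


@dataclass(frozen=True)
class Backbone:
    """A per-slice feature extractor with a fixed 2048-dim output."""

    name: str
    transform: Callable[[EnhancedSlice], np.ndarray]
    output_dim: int = FEATURE_DIM

    def __post_init__(self) -> None:
        if self.output_dim != FEATURE_DIM:
            raise ValueError(
                f"backbone {self.name!r} output_dim must be {FEATURE_DIM}, "
                f"got {self.output_dim}"
            )

    def __call__(self, slice_: EnhancedSlice) -> np.ndarray:
        vec = np.asarray(self.transform(slice_), dtype=np.float32).ravel()
        if vec.shape != (self.output_dim,):
            raise ValueError(
                f"backbone {self.name!r} returned {vec.shape}, "
                f"expected ({self.output_dim},)"
            )
        return vec


def _patch_statistics(slice_: EnhancedSlice) -> np.ndarray:
    x = slice_.channels.astype(np.float64) / 255.0  # (224, 224, 3)
    p = x.reshape(_GRID, _PATCH, _GRID, _PATCH, 3)
    mean = p.mean(axis=(1, 3))                      # (16, 16, 3)
    std = p.std(axis=(1, 3))                        # (16, 16, 3)
    gray = x.mean(axis=2)
    gmax = gray.reshape(_GRID, _PATCH, _GRID, _PATCH).max(axis=(1, 3))
    gy, gx = np.gradient(gray)
    energy = (gx * gx + gy * gy).reshape(_GRID, _PATCH, _GRID, _PATCH).mean(axis=(1, 3))
    feats = np.concatenate(
        [mean, std, gmax[..., None], energy[..., None]], axis=2
    )  # (16, 16, 8)
    return feats.reshape(FEATURE_DIM).astype(np.float32)


def surrogate_backbone() -> Backbone:
    """The deterministic patch-statistics extractor (no weights needed)."""
    return Backbone(name="surrogate", transform=_patch_statistics)


def pretrained_backbone(name: str = "inception_v3_imagenet") -> Backbone:
    """Global-average-pool activations of a pre-trained network.

    Requires an installed deep-learning runtime with locally available
    ImageNet weights; raises :class:`BackboneUnavailableError` otherwise
    (use :func:`surrogate_backbone` for a weight-free extractor).
    """
    if name != "inception_v3_imagenet":
        raise BackboneUnavailableError(f"unknown pre-trained backbone {name!r}")
    try:
        from tensorflow.keras.applications.inception_v3 import (  # type: ignore
            InceptionV3,
            preprocess_input,
        )
        import tensorflow as tf  # type: ignore
    except Exception as exc:
        raise BackboneUnavailableError(
            "inception_v3_imagenet requires tensorflow/keras with local "
            "ImageNet weights; use surrogate_backbone() for an offline, "
            "weight-free extractor"
        ) from exc

    model = InceptionV3(weights="imagenet", include_top=False, pooling="avg")

    def transform(slice_: EnhancedSlice) -> np.ndarray:
        img = tf.image.resize(
            slice_.channels.astype(np.float32)[None], (299, 299)
        ).numpy()
        return model.predict(preprocess_input(img), verbose=0)[0]

    return Backbone(name=name, transform=transform)


@dataclass(frozen=True)
class FeatureSequence:
    """Ordered 80 x 2048 activation features of one scan."""

    matrix: np.ndarray  # (80, 2048) float32
    participant_id: str = ""
    input_mode: str = "original"

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=np.float32)
        if m.shape != (SEQUENCE_LENGTH, FEATURE_DIM):
            raise ValueError(
                f"feature sequence must be ({SEQUENCE_LENGTH}, {FEATURE_DIM}), "
                f"got {m.shape}"
            )
        if not np.isfinite(m).all():
            raise ValueError("feature sequence contains non-finite values")
        if self.input_mode not in INPUT_MODES:
            raise ValueError(f"unknown input mode {self.input_mode!r}")
        object.__setattr__(self, "matrix", m)

    @property
    def flat_dim(self) -> int:
        return int(self.matrix.size)  # 163,840


def enhance_volume(
    volume: PreparedVolume,
    clahe_params: ClaheParams | None = None,
    nlm_params: NlMeansParams | None = None,
) -> list[EnhancedSlice]:
    """Enhanced 3-channel versions of the 80 selected slices."""
    return [
        enhance_slice(volume.slices[i], clahe_params, nlm_params)
        for i in select_slices(volume)
    ]


def scan_to_sequence(
    volume: PreparedVolume,
    backbone: Backbone,
    mode: str = "original",
    meta: BinnedMetadata | None = None,
    markers: MarkerSet | None = None,
    include: Iterable[str] | None = None,
    clahe_params: ClaheParams | None = None,
    nlm_params: NlMeansParams | None = None,
    participant_id: str = "",
    enhanced_original: Sequence[EnhancedSlice] | None = None,
) -> FeatureSequence:
    """Turn one scan into its 80 x 2048 feature sequence.

    ``mode="original"`` enhances and extracts each selected slice;
    ``mode="branded"`` first stamps the participant's covariate markers
    onto each slice.  When the original-mode enhanced slices of the same
    volume are already at hand they can be passed as
    ``enhanced_original``: branding only edits the top marker band, so
    the enhancement of a branded slice can be recomputed exactly from
    the original's (see :func:`metabrand.enhancement.enhance_edited_top`).
    """
    if mode not in ("original", "branded"):
        raise ValueError(f"scan_to_sequence mode must be original|branded, got {mode!r}")
    indices = select_slices(volume)
    if enhanced_original is not None and len(enhanced_original) != len(indices):
        raise ValueError(
            f"enhanced_original has {len(enhanced_original)} slices, "
            f"expected {len(indices)}"
        )
    rows = np.empty((SEQUENCE_LENGTH, FEATURE_DIM), dtype=np.float32)
    for step, idx in enumerate(indices):
        raw = volume.slices[idx]
        if mode == "branded":
            if meta is None or markers is None:
                raise ValueError("branded mode requires meta and markers")
            branded = brand_slice(raw, meta, markers, include).image
            if enhanced_original is not None:
                enhanced = enhance_edited_top(
                    branded, enhanced_original[step], MARKER_SHAPE[0],
                    clahe_params, nlm_params,
                )
            else:
                enhanced = enhance_slice(branded, clahe_params, nlm_params)
        else:
            if enhanced_original is not None:
                enhanced = enhanced_original[step]
            else:
                enhanced = enhance_slice(raw, clahe_params, nlm_params)
        rows[step] = backbone(enhanced)
    return FeatureSequence(matrix=rows, participant_id=participant_id, input_mode=mode)


class FeatureStore:
    """HDF5 cache of per-participant feature sequences.

    One dataset per participant under the root group, with ``mode``,
    ``backbone`` and ``marker_seed`` attributes.  A manifest CSV
    (``participant_id,label,feature_path``) can be written alongside.
    """

    def __init__(self, path: str | Path, mode: str = "a") -> None:
        import h5py

        self.path = Path(path)
        self._file = h5py.File(self.path, mode)

    def put(
        self,
        seq: FeatureSequence,
        backbone: str = "surrogate",
        marker_seed: int | None = None,
    ) -> None:
        if not seq.participant_id:
            raise ValueError("feature sequence needs a participant_id to be stored")
        if seq.participant_id in self._file:
            del self._file[seq.participant_id]
        ds = self._file.create_dataset(seq.participant_id, data=seq.matrix)
        ds.attrs["mode"] = seq.input_mode
        ds.attrs["backbone"] = backbone
        if marker_seed is not None:
            ds.attrs["marker_seed"] = int(marker_seed)

    def get(self, participant_id: str) -> FeatureSequence:
        if participant_id not in self._file:
            raise KeyError(f"no features stored for {participant_id!r}")
        ds = self._file[participant_id]
        return FeatureSequence(
            matrix=np.asarray(ds),
            participant_id=participant_id,
            input_mode=str(ds.attrs.get("mode", "original")),
        )

    @property
    def ids(self) -> list[str]:
        return sorted(self._file.keys())

    def write_manifest(self, labels: dict[str, str], path: str | Path) -> Path:
        import csv

        path = Path(path)
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["participant_id", "label", "feature_path"])
            for pid in self.ids:
                writer.writerow([pid, labels.get(pid, ""), f"{self.path}#{pid}"])
        return path

    def close(self) -> None:
        self._file.close()

    def __enter__(self) -> "FeatureStore":
        return self

    def __exit__(self, *exc) -> None:
        self.close()
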