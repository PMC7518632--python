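"""Volume preparation and the two extra "color" layers.

3D scans (DICOM series, NIfTI, or a directory of PNG slices) are
converted to ordered stacks of 8-bit 224x224 grayscale slices.  Each
slice is then expanded to three channels so a color-input convolutional
backbone can be applied to grayscale MRI: channel 0 keeps the original
slice, channel 1 is a contrast-intensified adaptation (CLAHE), and
channel 2 a denoised/blurred adaptation (non-local means).

Both enhancement operators are pure functions of their input: byte
identical outputs for byte-identical inputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from skimage.exposure import equalize_adapthist
from skimage.restoration import denoise_nl_means
from skimage.transform import resize

__all__ = [
    "SLICE_SHAPE",
    "MIN_DEPTH",
    "PreparedVolume",
    "ClaheParams",
    "NlMeansParams",
    "EnhancedSlice",
    "load_volume",
    "volume_from_array",
    "select_slices",
    "apply_clahe",
    "apply_nlmeans",
    "compose_rgb",
    "enhance_slice",
    "enhance_edited_top",
    "VolumeError",
]

SLICE_SHAPE = (224, 224)

# Slice sampling takes every second slice from index 8 up to and
# including 166 (0-based): 80 slices, so a scan needs >= 167 slices.
SLICE_START = 8
SLICE_STOP = 167
SLICE_STEP = 2
N_SELECTED_SLICES = 80
MIN_DEPTH = 167


class VolumeError(ValueError):
    """Raised for unreadable or malformed volumes."""


@dataclass(frozen=True)
class PreparedVolume:
    """Ordered 8-bit 224x224 slices of one scan."""

    slices: np.ndarray  # (depth, 224, 224) uint8
    source_format: str = "array"

    def __post_init__(self) -> None:
        arr = np.asarray(self.slices)
        if arr.ndim != 3 or arr.shape[1:] != SLICE_SHAPE:
            raise VolumeError(
                f"prepared volume must be (depth, 224, 224), got {arr.shape}"
            )
        if arr.dtype != np.uint8:
            raise VolumeError(f"prepared volume must be uint8, got {arr.dtype}")
        if arr.shape[0] < MIN_DEPTH:
            raise VolumeError(
                f"volume depth {arr.shape[0]} < required {MIN_DEPTH} "
                f"(slice sampling needs index {SLICE_STOP - 1})"
            )

    @property
    def depth(self) -> int:
        return int(self.slices.shape[0])


@dataclass(frozen=True)
class ClaheParams:
    """Contrast-limited adaptive histogram equalization settings.

    ``distribution_parameter`` applies only to non-uniform target
    histogram shapes; with the default uniform shape it is accepted and
    ignored.  ``clip_limit`` is the relative contrast-enhancement limit.
    """

    histogram_shape: str = "uniform"
    distribution_parameter: float = 0.4
    bins: int = 256
    clip_limit: float = 0.01
    output_range: str = "full"
    tiles: tuple[int, int] = (8, 8)


@dataclass(frozen=True)
class NlMeansParams:
    """Non-local means settings.

    ``filter_strength`` is a fraction of the 8-bit intensity range;
    ``kernel_ratio`` is the patch radius and ``window_ratio`` the search
    window radius, both in pixels (so 4/4 means 9x9 patches compared
    inside a 9x9 search window).
    """

    filter_strength: float = 0.05
    kernel_ratio: int = 4
    window_ratio: int = 4

    @property
    def influence_radius(self) -> int:
        """Rows/cols over which an edited pixel can affect the output."""
        return self.kernel_ratio + self.window_ratio


def _scale_to_uint8(volume: np.ndarray) -> np.ndarray:
    """Per-volume min-max scale to [0, 255]; constant volumes map to 0."""
    volume = np.asarray(volume, dtype=np.float64)
    lo, hi = float(volume.min()), float(volume.max())
    if hi == lo:
        return np.zeros(volume.shape, dtype=np.float64)
    return (volume - lo) * (255.0 / (hi - lo))


def _resize_slice(slice_f: np.ndarray) -> np.ndarray:
    if slice_f.shape == SLICE_SHAPE:
        return slice_f
    return resize(
        slice_f, SLICE_SHAPE, order=1, mode="edge",
        anti_aliasing=False, preserve_range=True,
    )


def volume_from_array(
    array: np.ndarray, source_format: str = "array"
) -> PreparedVolume:
    """Prepare a raw (depth, H, W) array: scale to 8-bit and resize."""
    array = np.asarray(array)
    if array.ndim != 3:
        raise VolumeError(f"expected a 3D array, got shape {array.shape}")
    scaled = _scale_to_uint8(array)
    slices = np.stack(
        [np.rint(_resize_slice(s)).astype(np.uint8) for s in scaled]
    )
    return PreparedVolume(slices=slices, source_format=source_format)


def load_volume(path: str | Path, format: str | None = None) -> PreparedVolume:
    """Load a scan from NIfTI, a DICOM series directory, or a PNG stack.

    Slices are ordered by acquisition index (NIfTI third axis, DICOM
    ``InstanceNumber``, or lexicographic file name), min-max scaled per
    volume to 8-bit, and bilinearly resampled to 224x224.
    """
    path = Path(path)
    if not path.exists():
        raise VolumeError(f"no such volume: {path}")
    fmt = format or _sniff_format(path)
    if fmt == "nifti":
        import nibabel as nib

        try:
            img = nib.load(str(path))
            data = np.asanyarray(img.dataobj).astype(np.float64)
        except Exception as exc:  # nibabel raises several types
            raise VolumeError(f"unreadable NIfTI file {path}: {exc}") from exc
        if data.ndim != 3:
            raise VolumeError(f"{path}: expected a 3D NIfTI, got shape {data.shape}")
        stack = np.moveaxis(data, 2, 0)  # slice index = third axis
        return volume_from_array(stack, source_format="NIfTI")
    if fmt == "dicom":
        import pydicom

        files = sorted(p for p in path.iterdir() if p.suffix.lower() in (".dcm", ".ima"))
        if not files:
            raise VolumeError(f"{path}: no DICOM files found")
        datasets = [pydicom.dcmread(str(f)) for f in files]
        datasets.sort(key=lambda d: int(getattr(d, "InstanceNumber", 0)))
        arrays = [d.pixel_array.astype(np.float64) for d in datasets]
        shapes = {a.shape for a in arrays}
        if len(shapes) != 1:
            raise VolumeError(f"{path}: inconsistent DICOM slice shapes {shapes}")
        return volume_from_array(np.stack(arrays), source_format="DICOM")
    if fmt == "png":
        import imageio.v3 as iio

        files = sorted(p for p in path.iterdir() if p.suffix.lower() == ".png")
        if not files:
            raise VolumeError(f"{path}: no PNG files found")
        arrays = []
        for f in files:
            a = np.asarray(iio.imread(f), dtype=np.float64)
            if a.ndim == 3:
                a = a.mean(axis=2)
            arrays.append(a)
        shapes = {a.shape for a in arrays}
        if len(shapes) != 1:
            raise VolumeError(f"{path}: inconsistent PNG slice shapes {shapes}")
        return volume_from_array(np.stack(arrays), source_format="PNG-stack")
    raise VolumeError(f"unrecognized volume format for {path}")


def _sniff_format(path: Path) -> str:
    name = path.name.lower()
    if name.endswith((".nii", ".nii.gz")):
        return "nifti"
    if path.is_dir():
        suffixes = {p.suffix.lower() for p in path.iterdir()}
        if ".dcm" in suffixes or ".ima" in suffixes:
            return "dicom"
        if ".png" in suffixes:
            return "png"
    raise VolumeError(f"cannot determine format of {path}")


def select_slices(volume: PreparedVolume | int) -> list[int]:
    """The 80 slice indices used to represent one scan.

    Every second slice from index 8 through 166 inclusive (0-based).
    """
    depth = volume if isinstance(volume, int) else volume.depth
    if depth < MIN_DEPTH:
        raise VolumeError(
            f"volume depth {depth} too small; slice sampling requires "
            f"depth >= {MIN_DEPTH}"
        )
    indices = list(range(SLICE_START, SLICE_STOP, SLICE_STEP))
    assert len(indices) == N_SELECTED_SLICES
    return indices


def _check_image(img: np.ndarray, op: str) -> np.ndarray:
    img = np.asarray(img)
    if img.ndim != 2:
        raise VolumeError(f"{op} expects a 2D image, got shape {img.shape}")
    if img.dtype != np.uint8:
        raise VolumeError(f"{op} expects an 8-bit (uint8) image, got {img.dtype}")
    return img


def apply_clahe(image: np.ndarray, params: ClaheParams | None = None) -> np.ndarray:
    """Contrast-limited adaptive histogram equalization of one slice.

    Tile grid per ``params.tiles`` (default 8x8), 256 bins, uniform
    target histogram, relative clip limit 0.01, output stretched to the
    full 8-bit range.  A constant image is returned unchanged (there is
    no contrast to redistribute).
    """
    params = params or ClaheParams()
    img = _check_image(image, "apply_clahe")
    if img.min() == img.max():
        return img.copy()
    kernel = (img.shape[0] // params.tiles[0], img.shape[1] // params.tiles[1])
    out = equalize_adapthist(
        img / 255.0, kernel_size=kernel, clip_limit=params.clip_limit,
        nbins=params.bins,
    )
    return np.rint(out * 255.0).astype(np.uint8)


def apply_nlmeans(image: np.ndarray, params: NlMeansParams | None = None) -> np.ndarray:
    """Non-local means denoising of one slice.

    Patch radius 4 (9x9 patches), search radius 4, smoothing strength
    0.05 of the intensity range; blockwise (fast-mode) averaging.
    """
    params = params or NlMeansParams()
    img = _check_image(image, "apply_nlmeans")
    out = denoise_nl_means(
        img / 255.0,
        patch_size=2 * params.kernel_ratio + 1,
        patch_distance=params.window_ratio,
        h=params.filter_strength,
        fast_mode=True,
    )
    return np.rint(out * 255.0).astype(np.uint8)


@dataclass(frozen=True)
class EnhancedSlice:
    """One slice's three channels: (original, CLAHE, NL-means)."""

    channels: np.ndarray  # (224, 224, 3) uint8

    def __post_init__(self) -> None:
        arr = np.asarray(self.channels)
        if arr.ndim != 3 or arr.shape[2] != 3 or arr.dtype != np.uint8:
            raise VolumeError(
                f"enhanced slice must be (H, W, 3) uint8, got {arr.dtype} {arr.shape}"
            )

    @property
    def original(self) -> np.ndarray:
        return self.channels[:, :, 0]

    @property
    def clahe(self) -> np.ndarray:
        return self.channels[:, :, 1]

    @property
    def nlmeans(self) -> np.ndarray:
        return self.channels[:, :, 2]


def compose_rgb(
    original: np.ndarray, clahe_img: np.ndarray, nlm_img: np.ndarray
) -> EnhancedSlice:
    """Stack the three layers into one 3-channel slice."""
    imgs = [np.asarray(a) for a in (original, clahe_img, nlm_img)]
    shapes = {a.shape for a in imgs}
    if len(shapes) != 1:
        raise VolumeError(f"channel shape mismatch: {sorted(shapes)}")
    return EnhancedSlice(channels=np.stack(imgs, axis=2).astype(np.uint8))


def enhance_slice(
    image: np.ndarray,
    clahe_params: ClaheParams | None = None,
    nlm_params: NlMeansParams | None = None,
) -> EnhancedSlice:
    """Original + CLAHE + NL-means channels for one slice."""
    img = _check_image(image, "enhance_slice")
    return compose_rgb(
        img, apply_clahe(img, clahe_params), apply_nlmeans(img, nlm_params)
    )


def enhance_edited_top(
    edited: np.ndarray,
    base_enhanced: EnhancedSlice,
    edited_rows: int,
    clahe_params: ClaheParams | None = None,
    nlm_params: NlMeansParams | None = None,
) -> EnhancedSlice:
    """Enhance a slice that differs from an already-enhanced one only in
    its top ``edited_rows`` rows (e.g. after marker branding).

    CLAHE is recomputed on the full edited slice (it is cheap and its
    tile interpolation spreads a top-band edit over several tile rows).
    Non-local means output at row r depends only on input rows within
    r +/- (kernel_ratio + window_ratio), so only the top
    ``edited_rows + influence`` rows can change: they are recomputed on
    a top strip tall enough that every recomputed pixel sees exactly the
    pixels it would see in a full-image pass, and the remaining rows are
    reused from ``base_enhanced``.  The result is bit-identical to
    ``enhance_slice(edited)``.
    """
    nlm_params = nlm_params or NlMeansParams()
    img = _check_image(edited, "enhance_edited_top")
    base = base_enhanced.channels
    if base.shape[:2] != img.shape:
        raise VolumeError("edited slice and base enhanced slice shapes differ")
    if not np.array_equal(img[edited_rows:], base[edited_rows:, :, 0]):
        raise VolumeError(
            "edited slice differs from the base outside the stated top rows"
        )
    influence = nlm_params.influence_radius
    affected = edited_rows + influence  # rows whose NL-means value may change
    strip_rows = min(img.shape[0], affected + influence)
    clahe_img = apply_clahe(img, clahe_params)
    nlm = base[:, :, 2].copy()
    strip = apply_nlmeans(img[:strip_rows], nlm_params)
    nlm[:affected] = strip[:affected]
    return compose_rgb(img, clahe_img, nlm)
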