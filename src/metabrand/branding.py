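"""Binary marker alphabet and slice branding.

Categorical participant covariates are fused into each 2D MRI slice by
overwriting small fixed rectangles ("markers") near the top edge of the
image with binary pixel patterns.  Each of the 15 covariate categories
owns one randomly generated 10x20 pattern of {0, 255} pixels; a
participant's five category patterns are stamped left to right into a
band starting at column 10, with a 5-pixel gap between consecutive
markers.  Marker ``i`` therefore occupies rows [0, 10) and columns
[10 + 25*i, 10 + 25*i + 20); with five variables the band ends at
column 130.

Patterns are drawn independently per category and resampled until every
pair of patterns belonging to the same variable differs in at least 60
of the 200 pixels, so one category can never be mistaken for another
even after moderate pixel corruption (e.g. by the downstream image
enhancement).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .cohort import BinnedMetadata, CATEGORY_ORDERS, Scheme, VARIABLE_ORDER, category_orders

__all__ = [
    "MARKER_SHAPE",
    "MARKER_BAND_START_COL",
    "MARKER_STRIDE",
    "MIN_WITHIN_VARIABLE_HAMMING",
    "MarkerPattern",
    "MarkerSet",
    "BrandedSlice",
    "build_marker_set",
    "marker_rectangle",
    "brand_slice",
    "brand_volume",
    "decode_markers",
    "BrandingError",
]

MARKER_SHAPE = (10, 20)  # rows x columns of one marker
MARKER_BAND_START_COL = 10
MARKER_GAP = 5
MARKER_STRIDE = MARKER_SHAPE[1] + MARKER_GAP  # 25 columns per variable slot
SLICE_SHAPE = (224, 224)
MIN_WITHIN_VARIABLE_HAMMING = 60  # of 200 pixels
DECODE_ABSENT_THRESHOLD = 30  # Hamming distance above which "absent"
_MAX_RESAMPLE_DRAWS = 10_000


class BrandingError(ValueError):
    """Raised for malformed slices or inconsistent marker sets."""


@dataclass(frozen=True)
class MarkerPattern:
    """One category's 10x20 binary pixel pattern."""

    variable: str
    category: str
    pixels: np.ndarray  # uint8, values in {0, 255}

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels, dtype=np.uint8)
        if px.shape != MARKER_SHAPE:
            raise BrandingError(
                f"marker for {self.variable}/{self.category} has shape "
                f"{px.shape}, expected {MARKER_SHAPE}"
            )
        if not np.isin(px, (0, 255)).all():
            raise BrandingError("marker pixels must be 0 or 255")
        if not ((px == 0).any() and (px == 255).any()):
            raise BrandingError("marker must contain both 0 and 255 pixels")
        object.__setattr__(self, "pixels", px)


def hamming(a: np.ndarray, b: np.ndarray) -> int:
    """Number of differing pixels between two equal-shape patterns."""
    return int(np.count_nonzero(np.asarray(a) != np.asarray(b)))


@dataclass(frozen=True)
class MarkerSet:
    """The full (variable, category) -> pattern alphabet.

    Exactly 15 patterns: one per category of the five binned variables.
    """

    patterns: Mapping[tuple[str, str], MarkerPattern]
    seed: int
    variable_order: tuple[str, ...] = VARIABLE_ORDER
    scheme: Scheme = Scheme.HNR

    def __post_init__(self) -> None:
        orders = category_orders(self.scheme)
        expected = {(v, c) for v in self.variable_order for c in orders[v]}
        if set(self.patterns) != expected:
            raise BrandingError(
                f"marker set must contain exactly the {len(expected)} "
                "(variable, category) pairs of the binning scheme"
            )
        for var in self.variable_order:
            cats = orders[var]
            for i in range(len(cats)):
                for j in range(i + 1, len(cats)):
                    d = hamming(
                        self.patterns[(var, cats[i])].pixels,
                        self.patterns[(var, cats[j])].pixels,
                    )
                    if d < MIN_WITHIN_VARIABLE_HAMMING:
                        raise BrandingError(
                            f"{var}: patterns {cats[i]!r}/{cats[j]!r} differ "
                            f"in only {d} pixels (< {MIN_WITHIN_VARIABLE_HAMMING})"
                        )

    def pattern(self, variable: str, category: str) -> MarkerPattern:
        try:
            return self.patterns[(variable, category)]
        except KeyError:
            raise BrandingError(
                f"no marker for variable {variable!r} category {category!r}"
            ) from None

    def to_json(self, path: str | Path | None = None) -> str:
        """Serialize to JSON (seed, order, flattened 0/1 patterns)."""
        payload = {
            "seed": self.seed,
            "scheme": self.scheme.value,
            "variable_order": list(self.variable_order),
            "patterns": {
                f"{v}|{c}": (p.pixels // 255).flatten().tolist()
                for (v, c), p in self.patterns.items()
            },
        }
        text = json.dumps(payload)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "MarkerSet":
        text = Path(source).read_text() if Path(str(source)).exists() else str(source)
        payload = json.loads(text)
        patterns = {}
        for key, flat in payload["patterns"].items():
            v, c = key.split("|", 1)
            px = (np.array(flat, dtype=np.uint8).reshape(MARKER_SHAPE)) * 255
            patterns[(v, c)] = MarkerPattern(variable=v, category=c, pixels=px)
        return cls(
            patterns=patterns,
            seed=int(payload["seed"]),
            variable_order=tuple(payload["variable_order"]),
            scheme=Scheme(payload.get("scheme", "HNR")),
        )


def build_marker_set(seed: int = 42, scheme: Scheme | str = Scheme.HNR) -> MarkerSet:
    """Generate the 15-pattern marker alphabet from a seed.

    Deterministic: the same seed always yields bit-identical patterns.
    Within each variable, patterns are redrawn (the newest one only)
    until all pairwise Hamming distances reach 60 pixels; random 200-bit
    patterns differ in ~100 pixels on average, so resampling is rare.
    """
    scheme = Scheme(scheme)
    rng = np.random.default_rng(seed)
    orders = category_orders(scheme)
    patterns: dict[tuple[str, str], MarkerPattern] = {}
    for var in VARIABLE_ORDER:
        accepted: list[np.ndarray] = []
        for cat in orders[var]:
            for attempt in range(_MAX_RESAMPLE_DRAWS):
                px = (rng.integers(0, 2, size=MARKER_SHAPE, dtype=np.uint8)) * 255
                if not ((px == 0).any() and (px == 255).any()):
                    continue
                if all(
                    hamming(px, prev) >= MIN_WITHIN_VARIABLE_HAMMING
                    for prev in accepted
                ):
                    break
            else:
                raise BrandingError(
                    f"could not draw a distinct marker for {var}/{cat} "
                    f"after {_MAX_RESAMPLE_DRAWS} attempts"
                )
            accepted.append(px)
            patterns[(var, cat)] = MarkerPattern(variable=var, category=cat, pixels=px)
    return MarkerSet(patterns=patterns, seed=int(seed), scheme=scheme)


def marker_rectangle(variable: str, variable_order: Sequence[str] = VARIABLE_ORDER):
    """Half-open (row, col) rectangle a variable's marker occupies."""
    i = list(variable_order).index(variable)
    col0 = MARKER_BAND_START_COL + MARKER_STRIDE * i
    return (0, MARKER_SHAPE[0]), (col0, col0 + MARKER_SHAPE[1])


@dataclass(frozen=True)
class BrandedSlice:
    """A 224x224 8-bit slice with markers stamped into the top band."""

    image: np.ndarray
    branded_variables: frozenset[str]

    def __post_init__(self) -> None:
        img = np.asarray(self.image)
        if img.shape != SLICE_SHAPE or img.dtype != np.uint8:
            raise BrandingError(
                f"branded slice must be uint8 {SLICE_SHAPE}, got "
                f"{img.dtype} {img.shape}"
            )


def _check_slice(img: np.ndarray, where: str = "slice") -> np.ndarray:
    img = np.asarray(img)
    if img.ndim != 2 or img.shape != SLICE_SHAPE:
        raise BrandingError(f"{where} must be 2D {SLICE_SHAPE}, got shape {img.shape}")
    if img.dtype != np.uint8:
        raise BrandingError(f"{where} must be 8-bit (uint8), got {img.dtype}")
    return img


def brand_slice(
    slice_image: np.ndarray,
    meta: BinnedMetadata,
    markers: MarkerSet,
    include: Iterable[str] | None = None,
) -> BrandedSlice:
    """Stamp the participant's markers onto one slice.

    ``include`` selects which variables to brand (default: all five);
    excluded variables' rectangles — and every pixel outside the band —
    are left untouched.  Branding is idempotent.
    """
    img = _check_slice(slice_image).copy()
    include_set = frozenset(markers.variable_order if include is None else include)
    unknown = include_set - set(markers.variable_order)
    if unknown:
        raise BrandingError(f"unknown variables to brand: {sorted(unknown)}")
    categories = meta.as_dict()
    for var in markers.variable_order:
        if var not in include_set:
            continue
        (r0, r1), (c0, c1) = marker_rectangle(var, markers.variable_order)
        img[r0:r1, c0:c1] = markers.pattern(var, categories[var]).pixels
    return BrandedSlice(image=img, branded_variables=include_set)


def brand_volume(
    slices: Sequence[np.ndarray],
    meta: BinnedMetadata,
    markers: MarkerSet,
    include: Iterable[str] | None = None,
) -> list[BrandedSlice]:
    """Brand every slice of a volume with the same (constant) markers."""
    out = []
    for idx, sl in enumerate(slices):
        try:
            out.append(brand_slice(sl, meta, markers, include))
        except BrandingError as exc:
            raise BrandingError(f"slice {idx}: {exc}") from exc
    return out


def decode_markers(
    branded: BrandedSlice | np.ndarray,
    markers: MarkerSet,
    absent_threshold: int = DECODE_ABSENT_THRESHOLD,
) -> dict[str, str | None]:
    """Read the markers back off a branded slice (validation aid).

    For each variable, returns the category whose pattern is nearest in
    Hamming distance to the observed band rectangle, or ``None``
    ("absent") when even the best match differs in more than
    ``absent_threshold`` of the 200 pixels.  Because same-variable
    patterns differ in >= 60 pixels, up to 29 corrupted pixels can never
    flip the decoded category.
    """
    img = branded.image if isinstance(branded, BrandedSlice) else _check_slice(branded)
    orders = category_orders(markers.scheme)
    decoded: dict[str, str | None] = {}
    for var in markers.variable_order:
        (r0, r1), (c0, c1) = marker_rectangle(var, markers.variable_order)
        region = img[r0:r1, c0:c1]
        best_cat, best_d = None, None
        for cat in orders[var]:
            d = hamming(region, markers.pattern(var, cat).pixels)
            if best_d is None or d < best_d:
                best_cat, best_d = cat, d
        decoded[var] = best_cat if best_d is not None and best_d <= absent_threshold else None
    return decoded
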