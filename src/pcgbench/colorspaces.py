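"""Registry of 150 three-channel color-space conversions for the random
color-filter augmentation.

Each entry maps a uint8 RGB image to another uint8 3-channel image that is
then reinterpreted as RGB. Entries are built from scikit-image color-space
conversions (with a fixed affine range-mapping per space so the result fills
[0, 255]), channel permutations, and channel inversions, plus their
compositions. The registry order is deterministic and versioned: entry 0 is
the identity.
"""

from __future__ import annotations

import itertools

import numpy as np
from skimage import color as skcolor

REGISTRY_VERSION = "1"
REGISTRY_SIZE = 150

# Fixed output ranges per target space: (low, high) per channel, used to map
# conversion output onto [0, 255] deterministically (no per-image scaling).
_SPACE_RANGES = {
    "hsv": [(0, 1), (0, 1), (0, 1)],
    "xyz": [(0, 0.9505), (0, 1.0), (0, 1.089)],
    "lab": [(0, 100), (-128, 127), (-128, 127)],
    "luv": [(0, 100), (-134, 220), (-140, 122)],
    "yuv": [(0, 1), (-0.436, 0.436), (-0.615, 0.615)],
    "yiq": [(0, 1), (-0.5957, 0.5957), (-0.5226, 0.5226)],
    "ypbpr": [(0, 1), (-0.5, 0.5), (-0.5, 0.5)],
    "ycbcr": [(16, 235), (16, 240), (16, 240)],
    "ydbdr": [(0, 1), (-1.333, 1.333), (-1.333, 1.333)],
    "rgbcie": [(-0.2, 1.2), (-0.2, 1.2), (-0.2, 1.2)],
    "hed": [(-1.0, 1.0), (-1.0, 1.0), (-1.0, 1.0)],
}

_FORWARD = {
    "hsv": skcolor.rgb2hsv,
    "xyz": skcolor.rgb2xyz,
    "lab": skcolor.rgb2lab,
    "luv": skcolor.rgb2luv,
    "yuv": skcolor.rgb2yuv,
    "yiq": skcolor.rgb2yiq,
    "ypbpr": skcolor.rgb2ypbpr,
    "ycbcr": skcolor.rgb2ycbcr,
    "ydbdr": skcolor.rgb2ydbdr,
    "rgbcie": skcolor.rgb2rgbcie,
    "hed": skcolor.rgb2hed,
}

_PERMUTATIONS = list(itertools.permutations(range(3)))  # identity first


def _to_space(img: np.ndarray, space: str) -> np.ndarray:
    """Convert uint8 RGB to `space` and affinely map onto uint8 [0,255]."""
    out = _FORWARD[space](img.astype(np.float64) / 255.0)
    lo = np.array([r[0] for r in _SPACE_RANGES[space]])
    hi = np.array([r[1] for r in _SPACE_RANGES[space]])
    scaled = (out - lo) / (hi - lo)
    return np.round(np.clip(scaled, 0.0, 1.0) * 255.0).astype(np.uint8)


def _permute(img: np.ndarray, perm) -> np.ndarray:
    return img[..., list(perm)]


def _invert(img: np.ndarray, mask) -> np.ndarray:
    out = img.copy()
    for c in range(3):
        if mask[c]:
            out[..., c] = 255 - out[..., c]
    return out


def _make_perm_invert(perm, mask):
    def f(img, _perm=perm, _mask=mask):
        return _invert(_permute(img, _perm), _mask)

    return f


def _make_space(space, perm, invert):
    def f(img, _space=space, _perm=perm, _inv=invert):
        out = _permute(_to_space(img, _space), _perm)
        if _inv:
            out = 255 - out
        return out

    return f


def build_registry() -> list[tuple[str, object]]:
    """Deterministic ordered list of exactly REGISTRY_SIZE (name, func) entries."""
    entries: list[tuple[str, object]] = []
    # 48 permutation/inversion filters on raw RGB; entry 0 is the identity.
    for perm in _PERMUTATIONS:
        for mask in itertools.product((False, True), repeat=3):
            name = "rgb-perm{}{}{}-inv{}".format(
                *perm, "".join("1" if m else "0" for m in mask)
            )
            entries.append((name, _make_perm_invert(perm, mask)))
    # 66 forward conversions x channel permutations, then 66 inverted copies.
    for invert in (False, True):
        for space in _FORWARD:
            for perm in _PERMUTATIONS:
                name = "{}-perm{}{}{}{}".format(space, *perm, "-inv" if invert else "")
                entries.append((name, _make_space(space, perm, invert)))
    assert len(entries) >= REGISTRY_SIZE
    return entries[:REGISTRY_SIZE]


_REGISTRY: list[tuple[str, object]] | None = None


def registry() -> list[tuple[str, object]]:
    global _REGISTRY
    if _REGISTRY is None:
        _REGISTRY = build_registry()
        if len(_REGISTRY) != REGISTRY_SIZE:
            raise RuntimeError("color-conversion registry has wrong size")
    return _REGISTRY
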