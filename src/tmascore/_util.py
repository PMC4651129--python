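"""Small shared helpers: disc structuring elements and seed derivation."""

from __future__ import annotations

from functools import lru_cache

import numpy as np

_CROSS = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], bool)
_SQUARE = np.ones((3, 3), bool)


@lru_cache(maxsize=None)
def disc_footprint(diameter_px: int) -> np.ndarray:
    """Disc-like structuring element of the given pixel diameter.

    Built as an alternating cross/square dilation chain starting from a
    single pixel, each step growing the diameter by two.  The result is an
    octagonal approximation of a Euclidean disc (exact for small diameters)
    with one key property a pixel-grid disc lacks: the footprints form a
    dilation chain, so they are nested and morphological openings with them
    are monotone in the diameter — which makes the Type-1 disagreement set
    grow monotonically with the assumed cell diameter.
    """
    from scipy import ndimage

    d = int(diameter_px)
    if d < 1:
        raise ValueError("diameter_px must be >= 1")
    fp = np.ones((1, 1), bool)
    for i in range((d - 1) // 2):
        fp = np.pad(fp, 1)
        fp = ndimage.binary_dilation(fp, structure=_CROSS if i % 2 == 0 else _SQUARE)
    fp.setflags(write=False)
    return fp


def spawn_seed(seed: int, *keys: int) -> int:
    """Derive a child seed (< 2**31) from a base seed and integer keys."""
    ss = np.random.SeedSequence([int(seed), *[int(k) for k in keys]])
    return int(ss.generate_state(1)[0] % (2**31))
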