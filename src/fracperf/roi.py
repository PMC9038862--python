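"""Pixel-set regions of interest (tumor-margin bands)."""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["MarginRoi"]


@dataclass
class MarginRoi:
    """Serpentine band of pixels at a lesion periphery.

    ``pixels`` is an (n, 2) integer array of (row, col) coordinates;
    ``source_frame`` records the timepoint index the band was drawn on, or
    "phantom" for simulated ground truth.
    """

    pixels: np.ndarray
    band_width: int = 1
    source_frame: int | str = "phantom"

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.int64).reshape(-1, 2)
        if len(self.pixels) == 0:
            raise ValueError("margin ROI must be nonempty")
        if self.band_width < 1:
            raise ValueError("band_width must be >= 1")
        # de-duplicate, canonical order: keeps set semantics deterministic
        self.pixels = np.unique(self.pixels, axis=0)

    def __len__(self) -> int:
        return len(self.pixels)

    def mask(self, shape: tuple[int, int]) -> np.ndarray:
        """Boolean mask of the ROI on an image grid of the given shape."""
        m = np.zeros(shape, dtype=bool)
        r, c = self.pixels[:, 0], self.pixels[:, 1]
        ok = (r >= 0) & (r < shape[0]) & (c >= 0) & (c < shape[1])
        m[r[ok], c[ok]] = True
        return m

    def to_rle(self) -> dict:
        """Run-length encoding (row, start_col, run_length) for plain-text I/O."""
        runs = []
        for r in np.unique(self.pixels[:, 0]):
            cols = np.sort(self.pixels[self.pixels[:, 0] == r, 1])
            start = prev = int(cols[0])
            for c in cols[1:]:
                if int(c) == prev + 1:
                    prev = int(c)
                else:
                    runs.append([int(r), start, prev - start + 1])
                    start = prev = int(c)
            runs.append([int(r), start, prev - start + 1])
        return {"format": "fracperf-roi-rle", "band_width": self.band_width,
                "source_frame": self.source_frame, "runs": runs}

    @classmethod
    def from_rle(cls, d: dict) -> "MarginRoi":
        pix = [(r, c0 + k) for r, c0, n in d["runs"] for k in range(n)]
        return cls(np.array(pix), d.get("band_width", 1),
                   d.get("source_frame", "phantom"))
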