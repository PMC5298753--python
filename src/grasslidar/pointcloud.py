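"""In-memory container for discrete lidar returns."""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import IntEnum

import numpy as np


class ClassLabel(IntEnum):
    """Return classification codes (ASPRS LAS convention).

    ``OTHER`` re-uses the LAS low-point/noise code 7 for isolated or
    below-surface outliers.
    """

    UNCLASSIFIED = 1
    GROUND = 2
    VEGETATION = 3
    OTHER = 7


@dataclass
class PointCloud:
    """Georeferenced discrete returns in planar projected coordinates.

    Coordinates are metres (``z`` is elevation); ``rel_height_cm`` is the
    height above the ground surface model in centimetres and is NaN until
    :func:`grasslidar.terrain.normalize_heights` has run.  Synthetic clouds
    carry truth attributes (``truth``, ``intercepted``, ``true_rel_h_cm``)
    so every downstream stage can be scored against a known answer.
    """

    x: np.ndarray
    y: np.ndarray
    z: np.ndarray
    return_number: np.ndarray = None
    classification: np.ndarray = None
    truth: np.ndarray | None = None
    intercepted: np.ndarray | None = None
    true_rel_h_cm: np.ndarray | None = None
    rel_height_cm: np.ndarray = None
    outside_gsm: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        self.z = np.asarray(self.z, dtype=float)
        n = self.x.size
        if self.y.size != n or self.z.size != n:
            raise ValueError("x, y, z must have equal length")
        if not (np.all(np.isfinite(self.x)) and np.all(np.isfinite(self.y))
                and np.all(np.isfinite(self.z))):
            raise ValueError("coordinates must be finite")
        if self.return_number is None:
            self.return_number = np.ones(n, dtype=np.uint8)
        else:
            self.return_number = np.asarray(self.return_number, dtype=np.uint8)
        if self.classification is None:
            self.classification = np.full(n, ClassLabel.UNCLASSIFIED, dtype=np.uint8)
        else:
            self.classification = np.asarray(self.classification, dtype=np.uint8)
        if self.rel_height_cm is None:
            self.rel_height_cm = np.full(n, np.nan)
        else:
            self.rel_height_cm = np.asarray(self.rel_height_cm, dtype=float)
        for name in ("truth", "intercepted", "true_rel_h_cm", "outside_gsm"):
            v = getattr(self, name)
            if v is not None:
                setattr(self, name, np.asarray(v))

    def __len__(self) -> int:
        return self.x.size

    @property
    def has_truth(self) -> bool:
        return self.truth is not None

    def copy(self) -> "PointCloud":
        def cp(a):
            return None if a is None else np.array(a, copy=True)

        return PointCloud(
            x=cp(self.x), y=cp(self.y), z=cp(self.z),
            return_number=cp(self.return_number),
            classification=cp(self.classification),
            truth=cp(self.truth), intercepted=cp(self.intercepted),
            true_rel_h_cm=cp(self.true_rel_h_cm),
            rel_height_cm=cp(self.rel_height_cm),
            outside_gsm=cp(self.outside_gsm),
        )

    def subset(self, mask: np.ndarray) -> "PointCloud":
        def take(a):
            return None if a is None else a[mask]

        return PointCloud(
            x=self.x[mask], y=self.y[mask], z=self.z[mask],
            return_number=self.return_number[mask],
            classification=self.classification[mask],
            truth=take(self.truth), intercepted=take(self.intercepted),
            true_rel_h_cm=take(self.true_rel_h_cm),
            rel_height_cm=self.rel_height_cm[mask],
            outside_gsm=take(self.outside_gsm),
        )

    def bounds(self) -> tuple[float, float, float, float]:
        """(xmin, ymin, xmax, ymax) of the returns."""
        if len(self) == 0:
            raise ValueError("empty cloud has no bounds")
        return (self.x.min(), self.y.min(), self.x.max(), self.y.max())
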