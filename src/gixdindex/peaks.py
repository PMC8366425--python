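"""Measured peak positions: (q_xy, q_z) tuples plus an optional specular peak."""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = ["Peak", "PeakList"]


@dataclass(frozen=True)
class Peak:
    """One reflection in the reciprocal-space map, components in A^-1.

    A peak with q_xy == 0 is a specular peak.
    """

    q_xy: float
    q_z: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.q_xy) and math.isfinite(self.q_z)):
            raise ValueError(f"non-finite peak position ({self.q_xy}, {self.q_z})")
        if self.q_xy < 0:
            raise ValueError(f"q_xy must be >= 0, got {self.q_xy}")

    @property
    def q_xyz(self) -> float:
        return math.hypot(self.q_xy, self.q_z)

    @property
    def is_specular(self) -> bool:
        return self.q_xy == 0.0


@dataclass(frozen=True)
class PeakList:
    """Ordered GIXD peaks (q_xy > 0) and an optional specular peak."""

    gixd: tuple[Peak, ...]
    specular: Peak | None = None

    def __post_init__(self) -> None:
        for p in self.gixd:
            if p.is_specular:
                raise ValueError("specular peak (q_xy = 0) belongs in the 'specular' slot")
        if self.specular is not None and not self.specular.is_specular:
            raise ValueError("specular peak must have q_xy = 0")

    def __len__(self) -> int:
        return len(self.gixd)

    @property
    def has_specular(self) -> bool:
        return self.specular is not None

    @property
    def q_spec(self) -> float | None:
        return None if self.specular is None else self.specular.q_z

    def arrays(self) -> tuple[np.ndarray, np.ndarray]:
        """(q_xy, q_z) of the GIXD peaks as float arrays."""
        q_xy = np.array([p.q_xy for p in self.gixd])
        q_z = np.array([p.q_z for p in self.gixd])
        return q_xy, q_z

    @staticmethod
    def from_rows(rows, specular_tol: float = 1e-12) -> "PeakList":
        """Build from (q_xy, q_z) rows; rows with |q_xy| <= tol are specular.

        With several specular rows the lowest-q_z one is used (higher specular
        orders are redundant for indexing) and a warning is emitted.
        """
        import warnings

        gixd: list[Peak] = []
        speculars: list[Peak] = []
        for q_xy, q_z in rows:
            if abs(q_xy) <= specular_tol:
                speculars.append(Peak(0.0, float(q_z)))
            else:
                gixd.append(Peak(float(q_xy), float(q_z)))
        specular = None
        if speculars:
            if len(speculars) > 1:
                warnings.warn(
                    f"{len(speculars)} specular rows found; using the lowest q_z",
                    stacklevel=2,
                )
            specular = min(speculars, key=lambda p: p.q_z)
        return PeakList(tuple(gixd), specular)
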