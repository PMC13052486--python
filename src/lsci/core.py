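"""Core containers: frames, stacks, ROI masks and acquisition metadata."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Iterator

import numpy as np


class LsciError(Exception):
    """Base class for all package errors."""


class InvalidInputError(LsciError, ValueError):
    """Raised when an input violates an operation's preconditions."""


class FormatError(LsciError, ValueError):
    """Raised when an on-disk file does not match the expected format."""


@dataclass
class StackMetadata:
    """Acquisition metadata carried alongside a frame stack.

    Defaults mirror a typical intraoperative acquisition: 5 ms exposure at
    40 frames per second.  ``processing_log`` is append-only; every pipeline
    stage records the operation name and its parameters so a run can be
    reproduced from the sidecar JSON alone.
    """

    exposure_ms: float = 5.0
    frame_rate_hz: float = 40.0
    bit_depth: int | None = None
    source: str = ""
    processing_log: list[dict[str, Any]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.exposure_ms <= 0:
            raise InvalidInputError(f"exposure_ms must be > 0, got {self.exposure_ms}")
        if self.frame_rate_hz <= 0:
            raise InvalidInputError(
                f"frame_rate_hz must be > 0, got {self.frame_rate_hz}"
            )

    def log(self, operation: str, **params: Any) -> None:
        """Append one processing step to the log."""
        self.processing_log.append({"operation": operation, "params": params})

    def to_dict(self) -> dict[str, Any]:
        return {
            "exposure_ms": self.exposure_ms,
            "frame_rate_hz": self.frame_rate_hz,
            "bit_depth": self.bit_depth,
            "source": self.source,
            "processing_log": self.processing_log,
        }

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "StackMetadata":
        return cls(
            exposure_ms=float(d.get("exposure_ms", 5.0)),
            frame_rate_hz=float(d.get("frame_rate_hz", 40.0)),
            bit_depth=d.get("bit_depth"),
            source=str(d.get("source", "")),
            processing_log=list(d.get("processing_log", [])),
        )


@dataclass
class SpeckleFrame:
    """One grayscale speckle image plus acquisition context.

    ``pixels`` is a 2-D nonnegative intensity grid (integer counts or float);
    ``exposure_ms`` is the camera integration time T during which scatterer
    motion blurs the speckle pattern.
    """

    pixels: np.ndarray
    exposure_ms: float = 5.0
    frame_index: int = 0
    bit_depth: int | None = None

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2:
            raise InvalidInputError(
                f"frame pixels must be 2-D, got shape {self.pixels.shape}"
            )
        if self.pixels.size == 0:
            raise InvalidInputError("frame pixels must be non-empty")
        if np.any(self.pixels < 0):
            raise InvalidInputError("frame pixels must be nonnegative")
        if self.exposure_ms <= 0:
            raise InvalidInputError(f"exposure_ms must be > 0, got {self.exposure_ms}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape  # type: ignore[return-value]


@dataclass
class SpeckleStack:
    """An ordered sequence of same-shaped speckle frames at a fixed rate.

    ``pixels`` has shape ``(n_frames, rows, cols)``.  ``frame_indices`` keeps
    the original acquisition indices so motion filtering can drop frames
    without renumbering.  ``sim_spec`` is set when the stack was produced by
    the simulator and enables exact field-level re-rendering (e.g. for motion
    injection).
    """

    pixels: np.ndarray
    metadata: StackMetadata = field(default_factory=StackMetadata)
    frame_indices: np.ndarray | None = None
    sim_spec: Any = None  # lsci.simulate.SimSpec, kept loose to avoid a cycle

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 3:
            raise InvalidInputError(
                f"stack pixels must be 3-D (n, rows, cols), got {self.pixels.shape}"
            )
        if self.pixels.shape[0] == 0:
            raise InvalidInputError("stack must contain at least one frame")
        if self.frame_indices is None:
            self.frame_indices = np.arange(self.pixels.shape[0])
        else:
            self.frame_indices = np.asarray(self.frame_indices)
            if self.frame_indices.shape != (self.pixels.shape[0],):
                raise InvalidInputError("frame_indices length must match frame count")

    def __len__(self) -> int:
        return int(self.pixels.shape[0])

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.pixels.shape[1:]  # type: ignore[return-value]

    def frame(self, i: int) -> SpeckleFrame:
        """Return frame ``i`` (positional) as a :class:`SpeckleFrame`."""
        return SpeckleFrame(
            pixels=self.pixels[i],
            exposure_ms=self.metadata.exposure_ms,
            frame_index=int(self.frame_indices[i]),
            bit_depth=self.metadata.bit_depth,
        )

    def __iter__(self) -> Iterator[SpeckleFrame]:
        for i in range(len(self)):
            yield self.frame(i)

    def select(self, positions: np.ndarray | list[int]) -> "SpeckleStack":
        """Sub-stack at the given positional indices, order preserved."""
        positions = np.asarray(positions, dtype=int)
        return SpeckleStack(
            pixels=self.pixels[positions],
            metadata=self.metadata,
            frame_indices=self.frame_indices[positions],
            sim_spec=self.sim_spec,
        )


@dataclass
class RoiMask:
    """Binary region of interest aligned pixel-for-pixel with the frame grid.

    Row-major, origin top-left, 0-based — the same convention as the frames.
    """

    mask: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 2:
            raise InvalidInputError(f"ROI mask must be 2-D, got {self.mask.shape}")
        if not self.mask.any():
            raise InvalidInputError("ROI mask must contain at least one pixel")

    @property
    def n_pixels(self) -> int:
        return int(self.mask.sum())
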