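"""Core container for ROI-averaged calcium fluorescence recordings.

A :class:`CalciumRecording` bundles the time x cell fluorescence matrix with
its sampling frequency, per-cell planar coordinates (micrometers), stable
cell identifiers, and optional named protocol intervals (e.g. the plateau
phase of a stimulation protocol).  All downstream stages — filtering,
binarization, similarity, network construction — operate on this container
or on arrays sliced out of it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .exceptions import ParameterError

__all__ = ["CalciumRecording", "Interval"]


@dataclass(frozen=True)
class Interval:
    """A named time window of a recording, in seconds from its start."""

    name: str
    start_s: float
    end_s: float

    def __post_init__(self) -> None:
        if not self.start_s < self.end_s:
            raise ParameterError(
                f"interval {self.name!r}: start ({self.start_s}) must be "
                f"strictly before end ({self.end_s})"
            )
        if self.start_s < 0:
            raise ParameterError(f"interval {self.name!r}: negative start")


@dataclass
class CalciumRecording:
    """ROI-averaged fluorescence traces for one imaged islet.

    Parameters
    ----------
    traces
        Fluorescence intensity, shape ``(n_frames, n_cells)``, arbitrary
        units.  Values must be finite.
    fs
        Sampling frequency in Hz, strictly positive.
    cell_ids
        Stable per-cell labels; defaults to ``"c000", "c001", ...``.
    coords
        Planar positions of the cells in micrometers, shape
        ``(n_cells, 2)``.  Optional: coordinate-free stages (filtering,
        similarity) work without them.
    intervals
        Optional named protocol windows.
    """

    traces: np.ndarray
    fs: float
    cell_ids: list[str] | None = None
    coords: np.ndarray | None = None
    intervals: list[Interval] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.traces = np.asarray(self.traces, dtype=float)
        if self.traces.ndim != 2:
            raise ParameterError("traces must be a 2-D (frames x cells) array")
        if not np.isfinite(self.traces).all():
            raise ParameterError("traces contain non-finite values")
        if not self.fs > 0:
            raise ParameterError(f"sampling frequency must be positive, got {self.fs}")
        if self.cell_ids is None:
            self.cell_ids = [f"c{i:03d}" for i in range(self.n_cells)]
        else:
            self.cell_ids = [str(c) for c in self.cell_ids]
        if len(self.cell_ids) != self.n_cells:
            raise ParameterError(
                f"{len(self.cell_ids)} cell_ids for {self.n_cells} trace columns"
            )
        if len(set(self.cell_ids)) != len(self.cell_ids):
            raise ParameterError("cell_ids must be unique")
        if self.coords is not None:
            self.coords = np.asarray(self.coords, dtype=float)
            if self.coords.shape != (self.n_cells, 2):
                raise ParameterError(
                    f"coords shape {self.coords.shape} does not match "
                    f"(n_cells, 2) = ({self.n_cells}, 2)"
                )
            if not np.isfinite(self.coords).all():
                raise ParameterError("coords contain non-finite values")
        for iv in self.intervals:
            if iv.end_s > self.duration_s + 0.5 / self.fs:
                raise ParameterError(
                    f"interval {iv.name!r} ends at {iv.end_s} s but the "
                    f"recording lasts {self.duration_s} s"
                )

    # ------------------------------------------------------------------
    @property
    def n_frames(self) -> int:
        return self.traces.shape[0]

    @property
    def n_cells(self) -> int:
        return self.traces.shape[1]

    @property
    def duration_s(self) -> float:
        """Recording length in seconds (n_frames / fs)."""
        return self.n_frames / self.fs

    @property
    def time_s(self) -> np.ndarray:
        """Frame times in seconds, starting at 0."""
        return np.arange(self.n_frames) / self.fs

    # ------------------------------------------------------------------
    def interval(self, name: str) -> Interval:
        for iv in self.intervals:
            if iv.name == name:
                return iv
        raise KeyError(f"no interval named {name!r}")

    def slice_time(self, start_s: float, end_s: float) -> "CalciumRecording":
        """Return a copy restricted to frames in ``[start_s, end_s)``."""
        i0 = int(np.floor(start_s * self.fs))
        i1 = int(np.ceil(end_s * self.fs))
        i0 = max(i0, 0)
        i1 = min(i1, self.n_frames)
        if i1 - i0 < 2:
            raise ParameterError(f"window [{start_s}, {end_s}) s selects < 2 frames")
        return CalciumRecording(
            traces=self.traces[i0:i1].copy(),
            fs=self.fs,
            cell_ids=list(self.cell_ids),
            coords=None if self.coords is None else self.coords.copy(),
        )

    def slice_interval(self, name: str) -> "CalciumRecording":
        iv = self.interval(name)
        return self.slice_time(iv.start_s, iv.end_s)

    def with_traces(self, traces: np.ndarray) -> "CalciumRecording":
        """Copy of this recording with ``traces`` replaced (same metadata)."""
        return CalciumRecording(
            traces=np.asarray(traces, dtype=float),
            fs=self.fs,
            cell_ids=list(self.cell_ids),
            coords=None if self.coords is None else self.coords.copy(),
            intervals=list(self.intervals),
        )
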