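"""Signal preprocessing: zero-phase band-pass filtering, smoothing,
binarization, and per-cell activity statistics.

Islet calcium dynamics contain two superimposed oscillatory components:
fast bursting (on the order of 1-5 per minute) that propagates through the
tissue as intercellular waves, and slow metabolic oscillations (about
0.1-0.2 per minute) that are coherent over long ranges.  The analysis
pipeline isolates either component with a zero-phase band-pass filter,
optionally smooths it, and turns the fast/oscillatory component into a
binary active/inactive raster from which the relative active time (duty
cycle) of every cell is read off.

Default frequency bands
-----------------------
========== ================== ==========================================
band       cutoffs (Hz)       intended use
========== ================== ==========================================
fast       0.05 - 2.0         bursting component in tissue slices
slow       0.001 - 0.07       slow metabolic component
oscillatory 0.005 - 0.25      isolated islets (drift removal + bursts)
========== ================== ==========================================
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

from .exceptions import InvalidFilterError, ParameterError, ShortSeriesError
from .recording import CalciumRecording

__all__ = [
    "BANDS",
    "FilterSpec",
    "BinarizedActivity",
    "bandpass_filter",
    "smooth",
    "binarize",
    "relative_active_time",
    "snr_screen",
]

logger = logging.getLogger(__name__)

#: Named default bands (low_cut, high_cut) in Hz.
BANDS: dict[str, tuple[float, float]] = {
    "fast": (0.05, 2.0),
    "slow": (0.001, 0.07),
    "oscillatory": (0.005, 0.25),
}


@dataclass(frozen=True)
class FilterSpec:
    """A band-pass specification.

    ``band_name`` is a free label ("fast", "slow", "oscillatory", "raw", or
    anything else); the cutoffs are what matters.  Use :meth:`named` for the
    package defaults.
    """

    band_name: str
    low_cut: float
    high_cut: float
    order: int = 2  # order of the underlying recursive filter section

    def __post_init__(self) -> None:
        if not (0 <= self.low_cut < self.high_cut):
            raise InvalidFilterError(
                f"need 0 <= low_cut < high_cut, got ({self.low_cut}, {self.high_cut})"
            )
        if self.order < 1:
            raise ParameterError("filter order must be >= 1")

    @classmethod
    def named(cls, band_name: str) -> "FilterSpec":
        """Return the default spec for a named band ('fast', 'slow',
        'oscillatory')."""
        try:
            lo, hi = BANDS[band_name]
        except KeyError:
            raise ParameterError(
                f"unknown band {band_name!r}; known: {sorted(BANDS)}"
            ) from None
        return cls(band_name, lo, hi)

    def validate_for(self, fs: float) -> None:
        if self.high_cut >= fs / 2:
            raise InvalidFilterError(
                f"high cutoff {self.high_cut} Hz is not below the Nyquist "
                f"frequency {fs / 2} Hz"
            )


@dataclass
class BinarizedActivity:
    """Binary active/inactive raster derived from a filtered recording.

    ``states`` has the same frames x cells shape as the source traces and
    contains only 0 and 1.  ``params`` records the binarization parameters;
    ``source_band`` records which oscillatory component was binarized.
    """

    states: np.ndarray
    fs: float
    cell_ids: list[str]
    params: dict = field(default_factory=dict)
    source_band: FilterSpec | None = None

    def __post_init__(self) -> None:
        self.states = np.asarray(self.states)
        uniq = np.unique(self.states)
        if not np.isin(uniq, (0, 1)).all():
            raise ParameterError("states must contain only 0 and 1")
        self.states = self.states.astype(np.uint8)

    @property
    def n_frames(self) -> int:
        return self.states.shape[0]

    @property
    def n_cells(self) -> int:
        return self.states.shape[1]


# ----------------------------------------------------------------------
# Filtering
# ----------------------------------------------------------------------

def _settling_len(sos: np.ndarray) -> int:
    # padlen used by sosfiltfilt; serves as the filter settling length
    return 3 * (2 * sos.shape[0] + 1)


def bandpass_filter(rec: CalciumRecording, spec: FilterSpec) -> CalciumRecording:
    """Band-pass every trace with a zero-phase (forward-backward) filter.

    A Butterworth band-pass of order ``spec.order`` is applied forwards and
    backwards (``sosfiltfilt``), doubling the effective order and cancelling
    the phase response exactly: an in-band sinusoid comes out with zero lag.
    DC and out-of-band components are attenuated.

    Raises
    ------
    InvalidFilterError
        If the cutoffs are incompatible with the sampling frequency.
    ShortSeriesError
        If the traces are shorter than three settling lengths of the filter.
    """
    spec.validate_for(rec.fs)
    sos = sps.butter(
        spec.order,
        [spec.low_cut, spec.high_cut],
        btype="bandpass",
        fs=rec.fs,
        output="sos",
    )
    need = 3 * _settling_len(sos)
    if rec.n_frames < need:
        raise ShortSeriesError(
            f"{rec.n_frames} frames, but the {spec.band_name} filter needs "
            f"at least {need}"
        )
    filtered = sps.sosfiltfilt(sos, rec.traces, axis=0)
    return rec.with_traces(filtered)


def smooth(traces: np.ndarray, window: int) -> np.ndarray:
    """Centered moving average (adjacency averaging) along the time axis.

    ``window`` must be a positive odd integer no longer than the traces.  At
    the boundaries the window shrinks to the available frames, so no padded
    values are fabricated.  ``window=1`` is the identity.
    """
    traces = np.asarray(traces, dtype=float)
    if window < 1 or window % 2 == 0:
        raise ParameterError(f"window must be a positive odd integer, got {window}")
    one_d = traces.ndim == 1
    if one_d:
        traces = traces[:, None]
    n = traces.shape[0]
    if window > n:
        raise ParameterError(f"window {window} exceeds trace length {n}")
    if window == 1:
        out = traces.copy()
    else:
        kernel = np.ones(window)
        sums = np.apply_along_axis(
            lambda c: np.convolve(c, kernel, mode="same"), 0, traces
        )
        counts = np.convolve(np.ones(n), kernel, mode="same")
        out = sums / counts[:, None]
    return out[:, 0] if one_d else out


# ----------------------------------------------------------------------
# Binarization
# ----------------------------------------------------------------------

def _hysteresis(x: np.ndarray, on_level: float, off_level: float) -> np.ndarray:
    """Schmitt-trigger binarization of one trace."""
    above_on = x >= on_level
    above_off = x >= off_level
    state = np.zeros(x.size, dtype=np.uint8)
    active = False
    for t in range(x.size):
        if not active:
            if above_on[t]:
                active = True
        else:
            if not above_off[t]:
                active = False
        state[t] = active
    return state


def _drop_short_events(state: np.ndarray, min_frames: int) -> np.ndarray:
    if min_frames <= 1:
        return state
    out = state.copy()
    t = 0
    n = out.size
    while t < n:
        if out[t]:
            t1 = t
            while t1 < n and out[t1]:
                t1 += 1
            if t1 - t < min_frames:
                out[t:t1] = 0
            t = t1
        else:
            t += 1
    return out


def binarize(
    rec: CalciumRecording,
    on_frac: float = 0.5,
    off_frac: float = 0.3,
    min_duration_s: float | None = None,
    spec: FilterSpec | None = None,
) -> BinarizedActivity:
    """Binarize a filtered oscillatory component into active/inactive states.

    Per cell, a robust amplitude scale is taken from the 10th-percentile
    baseline and 95th-percentile peak of the trace.  A frame becomes active
    when the signal rises above ``baseline + on_frac * (peak - baseline)``
    and stays active until it falls below
    ``baseline + off_frac * (peak - baseline)`` (hysteresis, so threshold
    chatter does not fragment events).  Events shorter than
    ``min_duration_s`` are removed; the default is two frames.

    Cells whose amplitude range does not exceed their high-frequency noise
    floor (estimated from the robust SD of the first difference) are marked
    all-inactive with a logged warning — binarizing pure noise would only
    create spurious events.
    """
    if not (0 < off_frac < on_frac < 1):
        raise ParameterError(
            f"need 0 < off_frac < on_frac < 1, got off={off_frac}, on={on_frac}"
        )
    if min_duration_s is None:
        min_frames = 2
        min_duration_s = min_frames / rec.fs
    else:
        if min_duration_s < 0:
            raise ParameterError("min_duration_s must be >= 0")
        min_frames = int(round(min_duration_s * rec.fs))

    states = np.zeros(rec.traces.shape, dtype=np.uint8)
    for j in range(rec.n_cells):
        x = rec.traces[:, j]
        base, peak = np.percentile(x, [10.0, 95.0])
        amp = peak - base
        # robust high-frequency noise SD from the first difference
        d = np.diff(x)
        sigma_hf = 1.4826 * np.median(np.abs(d - np.median(d))) / np.sqrt(2.0)
        floor = max(4.0 * sigma_hf, 1e-12 * max(1.0, abs(peak), abs(base)))
        if amp <= floor:
            logger.warning(
                "cell %s: amplitude %.3g below noise floor %.3g; marked inactive",
                rec.cell_ids[j], amp, floor,
            )
            continue
        on_level = base + on_frac * amp
        off_level = base + off_frac * amp
        states[:, j] = _drop_short_events(_hysteresis(x, on_level, off_level), min_frames)

    return BinarizedActivity(
        states=states,
        fs=rec.fs,
        cell_ids=list(rec.cell_ids),
        params={
            "on_frac": on_frac,
            "off_frac": off_frac,
            "min_duration_s": min_duration_s,
            "baseline_percentile": 10.0,
            "peak_percentile": 95.0,
        },
        source_band=spec,
    )


def relative_active_time(bin_act: BinarizedActivity) -> np.ndarray:
    """Fraction of frames each cell spends in the active state (duty cycle).

    Returns a length-``n_cells`` array of values in [0, 1].
    """
    return bin_act.states.mean(axis=0)


# ----------------------------------------------------------------------
# Optional quality screen
# ----------------------------------------------------------------------

def snr_screen(rec: CalciumRecording, spec: FilterSpec, min_snr: float = 2.0) -> np.ndarray:
    """Boolean mask of cells passing an automated signal-to-noise screen.

    SNR is defined as the robust oscillation amplitude of the band-passed
    trace (10th-95th percentile range) divided by the high-frequency
    residual SD (robust SD of the first difference of the raw trace).  The
    screen replaces manual visual rejection of artifact-laden cells; it is
    off by default in the pipeline.
    """
    filtered = bandpass_filter(rec, spec)
    keep = np.zeros(rec.n_cells, dtype=bool)
    for j in range(rec.n_cells):
        base, peak = np.percentile(filtered.traces[:, j], [10.0, 95.0])
        d = np.diff(rec.traces[:, j])
        sigma_hf = 1.4826 * np.median(np.abs(d - np.median(d))) / np.sqrt(2.0)
        keep[j] = (peak - base) > min_snr * max(sigma_hf, 1e-300)
    return keep
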