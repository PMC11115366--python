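"""Synthetic multicellular islet calcium recordings with ground truth.

The simulator emulates the features of islet [Ca2+] imaging that the
analysis pipeline is built to detect, at desk scale:

* cells packed in a planar disc with a minimum spacing (dart throwing);
* fast bursting (default period 20 s, i.e. 3 per minute) propagating as
  intercellular waves: each burst starts at a wave-initiator cell drawn
  from the outer 20% radius band, and every other cell activates after a
  delay equal to its distance from that initiator divided by the wave
  speed;
* heterogeneous per-cell duty cycles (burst duration = duty * period);
* a slow sinusoidal component (default period 400 s, i.e. 0.15 per
  minute) whose phase varies smoothly in space with a long correlation
  length, so it is coherent across the islet;
* calcium-indicator kinetics (events convolved with an exponential decay
  kernel) and additive Gaussian photon noise;
* optional asynchronous contaminant cells (e.g. non-beta cells) whose
  bursts occur at independent random times, untouched by the waves.

The wave model is geometric — activation delay proportional to distance —
rather than a biophysically coupled oscillator system; it reproduces the
qualitative structures the pipeline measures (distance-dependent fast
correlations, long-range slow coherence, duty-cycle/degree relation)
while remaining fast and fully deterministic given a seed.

Ground truth (event raster, duty cycles, initiator and asynchronous cell
identities) is returned alongside the recording so that every pipeline
stage can be validated against known answers.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

from .construct import FunctionalNetwork, geometric_network
from .exceptions import PackingError, ParameterError
from .recording import CalciumRecording

__all__ = ["IsletSimConfig", "SyntheticIslet", "generate_islet", "reference_geometric_truth"]


@dataclass(frozen=True)
class IsletSimConfig:
    """Parameters of the synthetic islet.

    Defaults place 100 cells in a 100 um disc and record 1200 s at 5 Hz,
    giving fast bursting at 3 min^-1 and slow oscillations at 0.15 min^-1 —
    inside the characteristic ranges of the two islet timescales (fast
    1-5 min^-1, slow 0.1-0.2 min^-1).
    """

    n_cells: int = 100
    disc_radius_um: float = 100.0
    min_spacing_um: float = 9.0
    fs: float = 5.0
    duration_s: float = 1200.0
    fast_period_s: float = 12.0
    fast_period_jitter_s: float = 1.0
    wave_speed_um_per_s: float = 80.0
    wave_jitter_sd_s: float = 1.5
    wave_jitter_corr_len_um: float = 40.0
    n_initiators: int = 3
    duty_mean: float = 0.3
    duty_sd: float = 0.1
    slow_period_s: float = 400.0
    slow_phase_corr_len_um: float = 300.0
    slow_phase_sd_rad: float = 0.3
    slow_phase_nugget_rad: float = 0.3
    slow_noise_sd: float = 0.3
    slow_noise_tau_s: float = 60.0
    amp_fast: float = 1.0
    amp_slow: float = 0.5
    kernel_tau_s: float = 0.2
    noise_sd: float = 0.05
    n_async_cells: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cells < 2:
            raise ParameterError("n_cells must be >= 2")
        if not 0 < self.duty_mean < 1:
            raise ParameterError("duty_mean must be in (0, 1)")
        if self.n_initiators < 1:
            raise ParameterError("n_initiators must be >= 1")
        if self.fs * self.duration_s < 100:
            raise ParameterError("need at least 100 frames (fs * duration)")
        if self.n_async_cells < 0 or self.n_async_cells >= self.n_cells:
            raise ParameterError("n_async_cells must be in [0, n_cells)")
        for name in (
            "disc_radius_um", "min_spacing_um", "fs", "duration_s",
            "fast_period_s", "wave_speed_um_per_s", "slow_period_s",
            "slow_phase_corr_len_um", "kernel_tau_s",
        ):
            if getattr(self, name) <= 0:
                raise ParameterError(f"{name} must be positive")


@dataclass
class SyntheticIslet:
    """A generated recording plus the ground truth used to make it."""

    recording: CalciumRecording
    truth_events: np.ndarray
    truth_duty: np.ndarray
    initiator_ids: list[str]
    async_ids: list[str]
    config: IsletSimConfig

    def __post_init__(self) -> None:
        if self.truth_events.shape != self.recording.traces.shape:
            raise ParameterError("truth_events shape does not match recording")
        if set(self.initiator_ids) & set(self.async_ids):
            raise ParameterError("initiators and async cells must be disjoint")


# ----------------------------------------------------------------------

def _place_cells(rng: np.random.Generator, cfg: IsletSimConfig) -> np.ndarray:
    """Dart-throwing placement in a disc with minimum spacing."""
    coords = np.empty((cfg.n_cells, 2))
    placed = 0
    misses = 0  # consecutive rejected darts
    while placed < cfg.n_cells:
        if misses >= 5000:
            raise PackingError(
                f"placed only {placed}/{cfg.n_cells} cells at spacing "
                f"{cfg.min_spacing_um} um in a {cfg.disc_radius_um} um disc"
            )
        r = cfg.disc_radius_um * np.sqrt(rng.uniform())
        theta = rng.uniform(0, 2 * np.pi)
        p = np.array([r * np.cos(theta), r * np.sin(theta)])
        if placed and (np.linalg.norm(coords[:placed] - p, axis=1) < cfg.min_spacing_um).any():
            misses += 1
            continue
        coords[placed] = p
        placed += 1
        misses = 0
    return coords


def _smooth_phase_field(
    rng: np.random.Generator, coords: np.ndarray, corr_len: float, sd: float
) -> np.ndarray:
    """Gaussian random field with squared-exponential spatial covariance."""
    d2 = ((coords[:, None, :] - coords[None, :, :]) ** 2).sum(-1)
    cov = sd**2 * np.exp(-d2 / (2 * corr_len**2))
    cov += 1e-9 * np.eye(len(coords))
    L = np.linalg.cholesky(cov)
    return L @ rng.standard_normal(len(coords))


def generate_islet(cfg: IsletSimConfig | None = None, **overrides) -> SyntheticIslet:
    """Generate a synthetic islet recording with known ground truth.

    All randomness flows from ``cfg.seed`` through per-stage substreams, so
    the same config gives bit-identical output.  Keyword overrides build a
    modified config from the defaults.
    """
    if cfg is None:
        cfg = IsletSimConfig(**overrides)
    elif overrides:
        cfg = IsletSimConfig(**{**asdict(cfg), **overrides})

    seeds = np.random.SeedSequence(cfg.seed).spawn(6)
    rng_place, rng_cells, rng_bursts, rng_slow, rng_async, rng_noise = (
        np.random.default_rng(s) for s in seeds
    )

    coords = _place_cells(rng_place, cfg)
    n = cfg.n_cells
    n_frames = int(round(cfg.fs * cfg.duration_s))
    cell_ids = [f"c{i:03d}" for i in range(n)]

    # roles: initiators from the outer 20% radius band, async cells from the rest
    radii = np.linalg.norm(coords, axis=1)
    outer = np.flatnonzero(radii >= 0.8 * cfg.disc_radius_um)
    if outer.size < cfg.n_initiators:
        outer = np.argsort(radii)[-max(cfg.n_initiators, 1):]
    initiators = rng_cells.choice(outer, size=cfg.n_initiators, replace=False)
    remaining = np.setdiff1d(np.arange(n), initiators)
    async_cells = (
        rng_cells.choice(remaining, size=cfg.n_async_cells, replace=False)
        if cfg.n_async_cells
        else np.array([], dtype=int)
    )
    async_mask = np.zeros(n, dtype=bool)
    async_mask[async_cells] = True

    duty = np.clip(
        rng_cells.normal(cfg.duty_mean, cfg.duty_sd, size=n), 0.1, 0.9
    )

    # --- fast component: waves from initiators -------------------------
    # conduction variability: per burst, a spatially smooth random delay
    # field is added to the geometric wave delay.  Neighboring cells share
    # the field value and stay tightly coordinated, while cells farther
    # apart than its correlation length accumulate independent delays —
    # including pairs equidistant from the initiator, which a purely
    # geometric wave would leave perfectly synchronous.
    d2 = ((coords[:, None, :] - coords[None, :, :]) ** 2).sum(-1)
    jitter_cov = np.exp(-d2 / (2 * cfg.wave_jitter_corr_len_um**2))
    jitter_cov += 1e-9 * np.eye(n)
    jitter_chol = cfg.wave_jitter_sd_s * np.linalg.cholesky(jitter_cov)

    events = np.zeros((n_frames, n), dtype=np.uint8)
    t_burst = 0.0
    burst_idx = 0
    while t_burst < cfg.duration_s:
        init = initiators[burst_idx % len(initiators)]
        wave_delay = np.linalg.norm(coords - coords[init], axis=1) / cfg.wave_speed_um_per_s
        conduction = jitter_chol @ rng_bursts.standard_normal(n)
        on = t_burst + np.maximum(wave_delay + conduction - conduction[init], 0.0)
        off = on + duty * cfg.fast_period_s
        for j in range(n):
            if async_mask[j]:
                continue
            i0 = int(np.ceil(on[j] * cfg.fs))
            i1 = int(np.ceil(off[j] * cfg.fs))
            if i0 < n_frames:
                events[i0:min(i1, n_frames), j] = 1
        jitter = rng_bursts.normal(0.0, cfg.fast_period_jitter_s)
        t_burst += max(cfg.fast_period_s + jitter, 0.5 * cfg.fast_period_s)
        burst_idx += 1

    # async cells: same duty, independent random burst times
    for j in async_cells:
        t = float(rng_async.uniform(0, cfg.fast_period_s))
        while t < cfg.duration_s:
            i0 = int(np.ceil(t * cfg.fs))
            i1 = int(np.ceil((t + duty[j] * cfg.fast_period_s) * cfg.fs))
            if i0 < n_frames:
                events[i0:min(i1, n_frames), j] = 1
            t += cfg.fast_period_s * float(rng_async.uniform(0.7, 1.3))

    # --- slow component -------------------------------------------------
    # phase = smooth long-range field (coherence across the islet) plus an
    # independent per-cell offset: each cell's metabolic oscillator sits
    # near the global rhythm but is not spatially organized, so slow-band
    # similarity is not ordered by distance
    phase = _smooth_phase_field(
        rng_slow, coords, cfg.slow_phase_corr_len_um, cfg.slow_phase_sd_rad
    ) + cfg.slow_phase_nugget_rad * rng_slow.standard_normal(n)
    t = np.arange(n_frames) / cfg.fs
    slow = 0.5 * (1 + np.sin(2 * np.pi * t[:, None] / cfg.slow_period_s + phase[None, :]))
    # per-cell idiosyncratic slow fluctuations (Ornstein-Uhlenbeck):
    # metabolic drift independent across cells.  Because the recording is
    # short relative to the slow timescale, these fluctuations leave
    # realistic finite-sample scatter in slow-band correlations.
    if cfg.slow_noise_sd > 0:
        rho_ou = np.exp(-1.0 / (cfg.slow_noise_tau_s * cfg.fs))
        innov_sd = cfg.slow_noise_sd * np.sqrt(1 - rho_ou**2)
        ou = np.empty((n_frames, n))
        ou[0] = cfg.slow_noise_sd * rng_slow.standard_normal(n)
        z = rng_slow.standard_normal((n_frames - 1, n))
        for ti in range(1, n_frames):
            ou[ti] = rho_ou * ou[ti - 1] + innov_sd * z[ti - 1]
        slow = slow + ou

    # --- indicator kinetics + noise -------------------------------------
    # first-order indicator response: rise and decay with time constant tau,
    # plateau at 1 during sustained activity
    tau_frames = cfg.kernel_tau_s * cfg.fs
    alpha = 1.0 - np.exp(-1.0 / tau_frames)
    klen = int(np.ceil(8 * tau_frames)) + 1
    kernel = alpha * np.exp(-np.arange(klen) / tau_frames)
    fast = np.empty((n_frames, n))
    for j in range(n):
        fast[:, j] = np.convolve(events[:, j].astype(float), kernel)[:n_frames]

    traces = (
        1.0
        + cfg.amp_fast * fast
        + cfg.amp_slow * slow
        + cfg.noise_sd * rng_noise.standard_normal((n_frames, n))
    )

    rec = CalciumRecording(traces=traces, fs=cfg.fs, cell_ids=cell_ids, coords=coords)
    return SyntheticIslet(
        recording=rec,
        truth_events=events,
        truth_duty=duty,
        initiator_ids=[cell_ids[i] for i in sorted(initiators)],
        async_ids=[cell_ids[i] for i in sorted(async_cells)],
        config=cfg,
    )


def reference_geometric_truth(islet: SyntheticIslet, target_kavg: float = 8.0) -> FunctionalNetwork:
    """Geometric network on the simulated coordinates — the stand-in for
    the islet's structural (gap-junctional) wiring."""
    return geometric_network(
        islet.recording.coords,
        cell_ids=list(islet.recording.cell_ids),
        mode="target_kavg",
        value=target_kavg,
    )
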