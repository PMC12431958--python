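"""Time-of-arrival permittivity reconstruction.

Image-formation chain: each path's frequency-domain transmission measurement
is brought to the time domain with an inverse chirp-Z transform evaluated on a
zoomed time window, the envelope peak gives the arrival time, the arrival-time
difference against an air reference of the same geometry yields a path-average
relative permittivity

    eps_r = (1 + c * dt / L)**2,        L = sqrt(d**2 + offset**2),

and each estimate is painted onto a disk footprint centred at the path's
mid-plane midpoint; overlapping footprints are averaged.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.signal import CZT

from .forward import FreqSweep, PathPair, PathSpectrum, reference_spectra
from .grid import C_MM_PER_NS, GridSpec

DEFAULT_TIME_WINDOW_NS = (0.0, 3.0)
DEFAULT_N_TIME_SAMPLES = 1024
DEFAULT_FOOTPRINT_RADIUS_MM = 6.0


@dataclass(frozen=True)
class TransformParams:
    """Zoomed time window for the inverse chirp-Z transform."""

    t_start_ns: float = DEFAULT_TIME_WINDOW_NS[0]
    t_stop_ns: float = DEFAULT_TIME_WINDOW_NS[1]
    n_samples: int = DEFAULT_N_TIME_SAMPLES

    def __post_init__(self) -> None:
        if self.t_stop_ns <= self.t_start_ns:
            raise ValueError("time window must have positive length")
        if self.n_samples < 8:
            raise ValueError("need at least 8 time samples")

    @property
    def times_ns(self) -> np.ndarray:
        return np.linspace(self.t_start_ns, self.t_stop_ns, self.n_samples)


@dataclass
class TimeSignal:
    """Real envelope signal on a uniform time grid."""

    times_ns: np.ndarray
    amplitude: np.ndarray
    pair_id: Optional[tuple[int, int]] = None
    peak_at_edge: bool = False


@dataclass
class PathPermittivity:
    """Per-path arrival-time difference and permittivity estimate."""

    pair: PathPair
    dt_ns: float
    epsilon: float
    clamped: bool = False  # negative dt (noise) clamped to eps_r = 1


@dataclass
class ReconImage:
    """Reconstructed permittivity map on the mid-plane grid."""

    grid: GridSpec
    epsilon_map: np.ndarray
    coverage: np.ndarray  # per-pixel count of contributing footprints
    separation_mm: float
    view: str = ""
    subject_id: str = ""
    metadata: dict = field(default_factory=dict)


def inverse_czt(
    values: np.ndarray,
    f0_ghz: float,
    df_ghz: float,
    t_start_ns: float,
    dt_ns: float,
    n_samples: int,
) -> np.ndarray:
    """Evaluate s(t_n) = sum_k S_k exp(+2j*pi*f_k*t_n) on a zoomed time grid.

    ``values`` may be 1D (one spectrum) or 2D (spectra stacked on axis 0);
    frequencies f_k = f0 + k*df, times t_n = t_start + n*dt.  Uses Bluestein's
    chirp-Z algorithm; on parameters degenerate to a uniform full-band grid
    (f0 = 0, dt = 1/(K*df), n_samples = K) this reduces to K times the inverse
    DFT.
    """
    values = np.asarray(values)
    k = values.shape[-1]
    w = np.exp(2j * np.pi * df_ghz * dt_ns)
    a = np.exp(-2j * np.pi * df_ghz * t_start_ns)
    out = CZT(n=k, m=n_samples, w=w, a=a)(values, axis=-1)
    if f0_ghz != 0.0:
        t = t_start_ns + dt_ns * np.arange(n_samples)
        out = out * np.exp(2j * np.pi * f0_ghz * t)
    return out


def _envelopes(spectra: np.ndarray, sweep: FreqSweep, params: TransformParams) -> np.ndarray:
    """Envelope |s(t)| for stacked spectra; the band is one-sided so the
    reconstruction is analytic and its magnitude is the envelope."""
    f = sweep.frequencies_ghz
    df = f[1] - f[0]
    t = params.times_ns
    dt = t[1] - t[0]
    out = inverse_czt(spectra, float(f[0]), float(df), float(t[0]), float(dt), params.n_samples)
    return np.abs(out) / sweep.n_points


def to_time_domain(
    spectrum: PathSpectrum,
    params: TransformParams = TransformParams(),
) -> TimeSignal:
    """Transform one spectrum to a time-domain envelope on the zoomed window."""
    env = _envelopes(spectrum.values[None, :], spectrum.sweep, params)[0]
    peak = int(np.argmax(env))
    pair_id = None
    if spectrum.pair is not None:
        pair_id = (spectrum.pair.tx_index, spectrum.pair.rx_index)
    edge = env.any() and peak in (0, params.n_samples - 1)
    return TimeSignal(params.times_ns, env, pair_id=pair_id, peak_at_edge=bool(edge))


def _refine_peaks(amplitude: np.ndarray, times: np.ndarray) -> np.ndarray:
    """Vectorised global-argmax arrival times with 3-point parabolic refinement.

    ``amplitude`` is (n_signals, n_times); returns (n_signals,) times in ns.
    """
    n = amplitude.shape[-1]
    idx = np.argmax(amplitude, axis=-1)
    dt = times[1] - times[0]
    t_peak = times[idx].astype(float)
    interior = (idx > 0) & (idx < n - 1)
    if interior.any():
        rows = np.nonzero(interior)[0]
        i = idx[rows]
        y0 = amplitude[rows, i - 1]
        y1 = amplitude[rows, i]
        y2 = amplitude[rows, i + 1]
        denom = y0 - 2 * y1 + y2
        shift = np.zeros_like(y1)
        ok = denom != 0
        shift[ok] = 0.5 * (y0 - y2)[ok] / denom[ok]
        # guard against a degenerate plateau throwing the vertex out of cell
        shift = np.clip(shift, -0.5, 0.5)
        t_peak[rows] = times[i] + shift * dt
    return t_peak


def estimate_arrival_time(signal: TimeSignal) -> float:
    """Arrival time (ns) of the global envelope maximum, parabolic-refined."""
    if not np.any(signal.amplitude):
        raise ValueError("no peak: signal is identically zero")
    return float(_refine_peaks(signal.amplitude[None, :], signal.times_ns)[0])


def estimate_path_permittivity(
    dt_ns: float, offset_mm: float, d_mm: float
) -> tuple[float, bool]:
    """Invert an arrival-time difference to a path-average permittivity.

    Returns (eps_r, clamped); negative dt (possible under noise) is clamped to
    the air value eps_r = 1 and flagged.
    """
    length = math.hypot(d_mm, offset_mm)
    if length <= 0:
        raise ValueError("path length must be positive")
    if dt_ns < 0:
        return 1.0, True
    return (1.0 + C_MM_PER_NS * dt_ns / length) ** 2, False


def _disk_pixels(grid: GridSpec, center_mm: tuple[float, float], radius_mm: float):
    """Pixel indices whose centres lie within the footprint disk."""
    x, y = grid.pixel_centers()
    cx, cy = center_mm
    ix = np.nonzero(np.abs(x - cx) <= radius_mm)[0]
    iy = np.nonzero(np.abs(y - cy) <= radius_mm)[0]
    if len(ix) == 0 or len(iy) == 0:
        return None
    xx, yy = np.meshgrid(x[ix], y[iy])
    inside = (xx - cx) ** 2 + (yy - cy) ** 2 <= radius_mm**2
    if not inside.any():
        return None
    jj, ii = np.nonzero(inside)
    return iy[jj], ix[ii]


def map_paths_to_image(
    estimates: Sequence[PathPermittivity],
    grid: GridSpec,
    footprint_radius_mm: float = DEFAULT_FOOTPRINT_RADIUS_MM,
    **metadata,
) -> ReconImage:
    """Paint per-path estimates onto disk footprints; overlaps averaged.

    Uncovered pixels are set to the air baseline 1.0 with coverage 0.
    """
    if len(estimates) == 0:
        raise ValueError("need at least one path estimate")
    acc = np.zeros(grid.shape)
    cov = np.zeros(grid.shape, dtype=int)
    for est in estimates:
        pix = _disk_pixels(grid, est.pair.midpoint_mm, footprint_radius_mm)
        if pix is None:
            continue
        iy, ix = pix
        acc[iy, ix] += est.epsilon
        cov[iy, ix] += 1
    eps = np.ones(grid.shape)
    covered = cov > 0
    eps[covered] = acc[covered] / cov[covered]
    sep = metadata.pop("separation_mm", 0.0)
    return ReconImage(
        grid=grid,
        epsilon_map=eps,
        coverage=cov,
        separation_mm=sep,
        view=metadata.pop("view", ""),
        subject_id=metadata.pop("subject_id", ""),
        metadata=metadata,
    )


def reconstruct_scan(
    spectra: np.ndarray,
    references: np.ndarray,
    pairs: Sequence[PathPair],
    d_mm: float,
    sweep: FreqSweep,
    grid: GridSpec,
    params: TransformParams = TransformParams(),
    footprint_radius_mm: float = DEFAULT_FOOTPRINT_RADIUS_MM,
    **metadata,
) -> ReconImage:
    """Full chain: spectra -> envelopes -> peak times -> eps_r -> image.

    ``spectra`` and ``references`` are (n_paths, n_points) complex arrays in
    path order; references must be air measurements at the same separation and
    per-path obliquity (see :func:`tmscan.forward.reference_spectra`).
    """
    if references is None:
        raise ValueError("missing reference measurements for this separation")
    spectra = np.atleast_2d(np.asarray(spectra))
    references = np.atleast_2d(np.asarray(references))
    if spectra.shape != references.shape or spectra.shape[0] != len(pairs):
        raise ValueError("spectra, references and pairs must align")
    t = params.times_ns
    env_meas = _envelopes(spectra, sweep, params)
    env_ref = _envelopes(references, sweep, params)
    t_meas = _refine_peaks(env_meas, t)
    t_ref = _refine_peaks(env_ref, t)
    estimates = []
    n_clamped = 0
    for pair, dt in zip(pairs, t_meas - t_ref):
        eps, clamped = estimate_path_permittivity(float(dt), pair.offset_mm, d_mm)
        n_clamped += clamped
        estimates.append(PathPermittivity(pair, float(dt), eps, clamped))
    metadata.setdefault("n_clamped", n_clamped)
    return map_paths_to_image(
        estimates, grid, footprint_radius_mm, separation_mm=d_mm, **metadata
    )


def reconstruct_phantom(
    phantom,
    pairs: Sequence[PathPair],
    sweep: FreqSweep,
    snr_db: float = math.inf,
    seed: int = 0,
    params: TransformParams = TransformParams(),
    footprint_radius_mm: float = DEFAULT_FOOTPRINT_RADIUS_MM,
) -> ReconImage:
    """Simulate a scan of ``phantom`` and reconstruct it (convenience wrapper)."""
    from .forward import simulate_scan_spectra

    d = phantom.separation_mm
    offsets = np.array([p.offset_mm for p in pairs])
    rng = np.random.default_rng(seed)
    seed_meas, seed_ref = (int(s) for s in rng.integers(0, 2**31 - 1, size=2))
    spectra = simulate_scan_spectra(phantom, list(pairs), sweep, snr_db=snr_db, seed=seed_meas)
    refs = reference_spectra(d, offsets, sweep, snr_db=snr_db, seed=seed_ref)
    return reconstruct_scan(
        spectra,
        refs,
        pairs,
        d,
        sweep,
        phantom.grid,
        params=params,
        footprint_radius_mm=footprint_radius_mm,
        view=phantom.view,
    )
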