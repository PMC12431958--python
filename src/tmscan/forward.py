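"""Antenna-array geometry and straight-ray forward simulation.

The scanner holds the breast between two planar antenna arrays: a transmitting
plate of 247 patch antennas above and a receiving plate of 240 antennas below,
separated by the plate distance d.  Each transmitter is measured against the
receivers laterally close to it, giving more than 2000 transmission paths over
the 21 cm x 16 cm aperture.

Propagation is modelled as a straight ray between the 3D antenna positions;
the delay is the line integral of sqrt(eps_r)/c along the ray, with the 2D
permittivity map assumed homogeneous through the plate gap.  Measured spectra
are ideal delays shaped by a raised-cosine band window, with optional complex
additive white Gaussian noise at a prescribed SNR.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.spatial import cKDTree

from .grid import C_MM_PER_NS, GridSpec
from .phantom import BreastPhantom

logger = logging.getLogger(__name__)

DEFAULT_PAIRING_RADIUS_MM = 25.0
#: transmit lattice 19 x 13 = 247, receive lattice 20 x 12 = 240
TX_LATTICE = (19, 13)
RX_LATTICE = (20, 12)


@dataclass(frozen=True)
class FreqSweep:
    """Uniform frequency sweep, GHz."""

    f_min_ghz: float = 0.1
    f_max_ghz: float = 8.0
    n_points: int = 201

    def __post_init__(self) -> None:
        if not 0 < self.f_min_ghz < self.f_max_ghz:
            raise ValueError("need 0 < f_min < f_max")
        if self.n_points < 2:
            raise ValueError("need at least 2 frequency points")

    @property
    def frequencies_ghz(self) -> np.ndarray:
        return np.linspace(self.f_min_ghz, self.f_max_ghz, self.n_points)


@dataclass(frozen=True)
class PathPair:
    """One transmitter-receiver pair."""

    tx_index: int
    rx_index: int
    tx_xy_mm: tuple[float, float]
    rx_xy_mm: tuple[float, float]

    @property
    def offset_mm(self) -> float:
        """Lateral (in-plane) offset between transmitter and receiver."""
        return math.hypot(
            self.rx_xy_mm[0] - self.tx_xy_mm[0], self.rx_xy_mm[1] - self.tx_xy_mm[1]
        )

    @property
    def midpoint_mm(self) -> tuple[float, float]:
        """Projection of the path centre onto the mid-plane."""
        return (
            0.5 * (self.tx_xy_mm[0] + self.rx_xy_mm[0]),
            0.5 * (self.tx_xy_mm[1] + self.rx_xy_mm[1]),
        )

    def path_length_mm(self, d_mm: float) -> float:
        """3D straight-segment length between the plates."""
        return math.hypot(d_mm, self.offset_mm)


@dataclass
class ArrayGeometry:
    """Planar transmit/receive lattices spanning the imaging extent."""

    tx_positions_mm: np.ndarray  # (247, 2)
    rx_positions_mm: np.ndarray  # (240, 2)
    plate_separation_mm: float
    pairing_radius_mm: float = DEFAULT_PAIRING_RADIUS_MM

    def __post_init__(self) -> None:
        if self.plate_separation_mm <= 0:
            raise ValueError("plate separation must be positive")
        if self.pairing_radius_mm <= 0:
            raise ValueError("pairing radius must be positive")


@dataclass
class PathSpectrum:
    """Complex transmission spectrum S(f) for one path."""

    pair: Optional[PathPair]
    sweep: FreqSweep
    values: np.ndarray  # complex, length n_points
    snr_db: float = math.inf
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.values) != self.sweep.n_points:
            raise ValueError("spectrum length does not match sweep")
        if not np.isfinite(self.values).all():
            raise ValueError("spectrum contains non-finite values")


def _lattice(extent_x: float, extent_y: float, nx: int, ny: int) -> np.ndarray:
    x = np.linspace(0.0, extent_x, nx)
    y = np.linspace(0.0, extent_y, ny)
    xx, yy = np.meshgrid(x, y)
    return np.column_stack([xx.ravel(), yy.ravel()])


def build_array(
    grid: GridSpec,
    d_mm: float,
    pairing_radius_mm: float = DEFAULT_PAIRING_RADIUS_MM,
) -> ArrayGeometry:
    """Regular 19x13 transmit and 20x12 receive lattices over the grid extent."""
    tx = _lattice(grid.width_mm, grid.height_mm, *TX_LATTICE)
    rx = _lattice(grid.width_mm, grid.height_mm, *RX_LATTICE)
    return ArrayGeometry(tx, rx, d_mm, pairing_radius_mm)


def enumerate_paths(geom: ArrayGeometry) -> list[PathPair]:
    """All Tx-Rx pairs with lateral offset within the pairing radius.

    Ordering is deterministic: transmitter-major, then receiver index.
    """
    tree = cKDTree(geom.rx_positions_mm)
    pairs: list[PathPair] = []
    lonely = 0
    for ti, txy in enumerate(geom.tx_positions_mm):
        partners = sorted(tree.query_ball_point(txy, geom.pairing_radius_mm))
        if not partners:
            lonely += 1
        for ri in partners:
            rxy = geom.rx_positions_mm[ri]
            pairs.append(PathPair(ti, ri, (float(txy[0]), float(txy[1])), (float(rxy[0]), float(rxy[1]))))
    if lonely:
        logger.warning("%d transmitters have no receiver within %.1f mm", lonely, geom.pairing_radius_mm)
    return pairs


def path_delays(
    phantom: BreastPhantom,
    pairs: list[PathPair],
    d_mm: Optional[float] = None,
    step_mm: Optional[float] = None,
) -> np.ndarray:
    """Straight-ray delays (ns) for many paths through one phantom.

    The 3D Tx->Rx segment is projected onto the 2D map; sqrt(eps_r) is sampled
    at a fixed step along the projection and averaged, then scaled by the true
    3D segment length: tau = (L3d / c) * mean(sqrt(eps_r)).
    """
    if d_mm is None:
        d_mm = phantom.separation_mm
    if step_mm is None:
        step_mm = phantom.grid.pixel_mm / 2.0
    sqrt_eps = np.sqrt(phantom.epsilon_map)
    out = np.empty(len(pairs))
    for k, pair in enumerate(pairs):
        tx = np.asarray(pair.tx_xy_mm)
        rx = np.asarray(pair.rx_xy_mm)
        lateral = float(np.hypot(*(rx - tx)))
        n = max(1, math.ceil(lateral / step_mm))
        u = (np.arange(n) + 0.5) / n
        pts = tx[None, :] + u[:, None] * (rx - tx)[None, :]
        iy, ix = phantom.grid.index_of(pts[:, 0], pts[:, 1])
        mean_slowness = sqrt_eps[iy, ix].mean()
        out[k] = math.hypot(d_mm, lateral) / C_MM_PER_NS * mean_slowness
    return out


def path_delay(
    phantom: BreastPhantom,
    pair: PathPair,
    d_mm: Optional[float] = None,
    step_mm: Optional[float] = None,
) -> float:
    """Delay (ns) of a single path; see :func:`path_delays`."""
    return float(path_delays(phantom, [pair], d_mm=d_mm, step_mm=step_mm)[0])


def band_window(sweep: FreqSweep) -> np.ndarray:
    """Raised-cosine (Hann) amplitude shaping over the swept band.

    The same window is applied to measurement and reference spectra so peak
    alignment in the time domain is unbiased.
    """
    return np.hanning(sweep.n_points + 2)[1:-1]


def _delay_spectrum(tau_ns: np.ndarray, sweep: FreqSweep) -> np.ndarray:
    f = sweep.frequencies_ghz
    window = band_window(sweep)
    return window[None, :] * np.exp(-2j * np.pi * f[None, :] * np.asarray(tau_ns)[:, None])


def _add_noise(values: np.ndarray, snr_db: float, rng: np.random.Generator) -> np.ndarray:
    if math.isinf(snr_db):
        return values
    power = float(np.mean(np.abs(values) ** 2))
    sigma2 = power / 10 ** (snr_db / 10.0)
    noise = rng.normal(scale=math.sqrt(sigma2 / 2.0), size=values.shape) + 1j * rng.normal(
        scale=math.sqrt(sigma2 / 2.0), size=values.shape
    )
    return values + noise


def simulate_scan_spectra(
    phantom: BreastPhantom,
    pairs: list[PathPair],
    sweep: FreqSweep,
    snr_db: float = math.inf,
    seed: int = 0,
    d_mm: Optional[float] = None,
) -> np.ndarray:
    """Complex spectra (n_paths, n_points) for all paths of one scan."""
    taus = path_delays(phantom, pairs, d_mm=d_mm)
    values = _delay_spectrum(taus, sweep)
    rng = np.random.default_rng(seed)
    return _add_noise(values, snr_db, rng)


def simulate_path_spectrum(
    phantom: BreastPhantom,
    pair: PathPair,
    sweep: FreqSweep,
    snr_db: float = math.inf,
    seed: int = 0,
    d_mm: Optional[float] = None,
) -> PathSpectrum:
    """Simulated transmission spectrum for a single path."""
    values = simulate_scan_spectra(phantom, [pair], sweep, snr_db=snr_db, seed=seed, d_mm=d_mm)[0]
    return PathSpectrum(pair, sweep, values, snr_db=snr_db, seed=seed)


def reference_spectra(
    d_mm: float,
    offsets_mm: np.ndarray,
    sweep: FreqSweep,
    snr_db: float = math.inf,
    seed: int = 0,
) -> np.ndarray:
    """Air-reference spectra for paths of given lateral offsets at separation d."""
    taus = np.hypot(d_mm, np.asarray(offsets_mm, dtype=float)) / C_MM_PER_NS
    values = _delay_spectrum(taus, sweep)
    rng = np.random.default_rng(seed)
    return _add_noise(values, snr_db, rng)


def simulate_reference(
    d_mm: float,
    sweep: FreqSweep,
    snr_db: float = math.inf,
    seed: int = 0,
    offset_mm: float = 0.0,
) -> PathSpectrum:
    """Reference measurement through air of the same thickness (and obliquity)."""
    if d_mm <= 0:
        raise ValueError("separation must be positive")
    values = reference_spectra(d_mm, np.array([offset_mm]), sweep, snr_db=snr_db, seed=seed)[0]
    return PathSpectrum(None, sweep, values, snr_db=snr_db, seed=seed)
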