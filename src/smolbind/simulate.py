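"""Synthetic single-molecule and binding data with known ground truth.

Four generators mirror the experimental modalities the analysis modules
consume:

* :func:`simulate_photobleach_trace` — background-corrected intensity time
  series of a 1–3 fluorophore spot bleaching in discrete steps under shot
  and read noise.
* :func:`simulate_tirfm_movie` — a sparse-spot TIRFM image stack (one
  2-D Gaussian per spot whose amplitude follows its bleaching trace),
  writable as 16-bit TIFF, with per-spot ground truth.
* :func:`simulate_force_curve` — an AFM approach/retract force–distance
  cycle with an optional specific sawtooth rupture and an optional
  near-contact nonspecific adhesion.
* :func:`simulate_binding_series` — steady-state 1:1 Langmuir responses or
  one-site competition curves.

Every generator takes an explicit seed (or an already-spawned
``numpy.random.Generator``); identical configuration and seed give
bit-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Optional, Sequence

import numpy as np
import pandas as pd
import tifffile
from pydantic import BaseModel, ConfigDict, Field, model_validator

from ._errors import ConfigError, PlacementError
from ._util import spawn_rng

__all__ = [
    "MovieConfig",
    "MovieGroundTruth",
    "ForceConfig",
    "BindingSimConfig",
    "IntensityTrace",
    "ForceCurve",
    "BindingSeries",
    "simulate_photobleach_trace",
    "simulate_tirfm_movie",
    "simulate_force_curve",
    "simulate_force_curves",
    "simulate_binding_series",
    "write_movie_tiff",
    "read_movie_tiff",
    "TWOFOLD_SERIES_UM",
]

#: Two-fold dilution series from 62.5 μM down to ~1.9 μM (six doses).
TWOFOLD_SERIES_UM = tuple(62.5 / 2**k for k in reversed(range(6)))


# --------------------------------------------------------------------------
# data containers shared with the analysis modules
# --------------------------------------------------------------------------

@dataclass
class IntensityTrace:
    """Background-corrected fluorescence time series of one spot."""

    values: np.ndarray
    frame_interval: float  # seconds per frame

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.frame_interval <= 0:
            raise ConfigError("frame_interval must be positive")

    def __len__(self) -> int:
        return self.values.size

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.values.size) * self.frame_interval


@dataclass
class ForceCurve:
    """One AFM force–distance cycle.

    Separations in nm, forces in pN (deflection already converted via
    F = k·d at parse/simulation time). Approach stored with decreasing
    separation (toward the surface), retract with increasing separation.
    Adhesive (pulling) forces are negative.
    """

    approach_separation: np.ndarray
    approach_force: np.ndarray
    retract_separation: np.ndarray
    retract_force: np.ndarray
    spring_constant: float  # N/m
    loading_rate: float  # pN/s
    curve_id: str = "curve"
    condition: str = ""
    baseline_corrected: bool = False
    contact_nm: Optional[float] = None

    def __post_init__(self) -> None:
        for name in ("approach_separation", "approach_force",
                     "retract_separation", "retract_force"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        if self.approach_separation.size == 0 or self.retract_separation.size == 0:
            raise ConfigError("force-curve segments must be non-empty")
        if self.spring_constant <= 0:
            raise ConfigError("spring_constant must be positive")


@dataclass
class BindingSeries:
    """Concentration–response pairs for equilibrium binding fits."""

    concentrations: np.ndarray  # μM (steady-state) or molar (competition)
    responses: np.ndarray  # response units or % specific binding
    mode: Literal["steady_state", "competition"] = "steady_state"
    replicate_ids: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.concentrations = np.asarray(self.concentrations, dtype=float)
        self.responses = np.asarray(self.responses, dtype=float)
        if self.concentrations.shape != self.responses.shape:
            raise ConfigError("concentrations and responses must align")
        if np.any(self.concentrations <= 0):
            raise ConfigError("concentrations must be strictly positive")

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {"concentration": self.concentrations, "response": self.responses}
        )
        if self.replicate_ids is not None:
            df["replicate"] = self.replicate_ids
        return df


# --------------------------------------------------------------------------
# configurations
# --------------------------------------------------------------------------

class MovieConfig(BaseModel):
    """Parameters of the TIRFM movie / trace generator.

    Intensities are photons per frame; ``background_level`` is photons per
    pixel per frame. The trace generator integrates over a 5×5-pixel
    aperture, so its shot-noise background is ``25 * background_level`` and
    its read noise ``5 * read_noise_sd`` (quadrature over 25 pixels).
    """

    model_config = ConfigDict(extra="forbid")

    n_frames: int = Field(250, ge=20)
    frame_rate: float = Field(10.0, gt=0)  # Hz
    image_size: tuple[int, int] = (256, 256)  # (rows, cols) pixels
    n_spots: int = Field(120, ge=0)
    psf_sigma: float = Field(1.3, gt=0)  # pixels
    fraction_monomer: float = Field(0.85, ge=0, le=1)
    fraction_dimer: float = Field(0.14, ge=0, le=1)
    fraction_trimer: float = Field(0.01, ge=0, le=1)
    unit_intensity: float = Field(600.0, gt=0)  # photons / fluorophore / frame
    bleach_rate: float = Field(0.2, gt=0)  # s^-1 per fluorophore
    background_level: float = Field(200.0, ge=0)  # photons / pixel / frame
    read_noise_sd: float = Field(10.0, ge=0)  # counts / pixel
    shot_noise: bool = True  # master switch for shot + read noise
    p_dark: float = Field(0.0, ge=0, le=1)  # immature (never fluorescent) GFP
    blink_off_rate: float = Field(0.0, ge=0)  # s^-1; 0 disables blinking
    blink_on_rate: float = Field(5.0, gt=0)  # s^-1 recovery when blinking on
    seed: int

    @model_validator(mode="after")
    def _check(self) -> "MovieConfig":
        total = self.fraction_monomer + self.fraction_dimer + self.fraction_trimer
        if abs(total - 1.0) > 1e-9:
            raise ConfigError(f"stoichiometry fractions must sum to 1 (got {total})")
        if min(self.image_size) < 16:
            raise ConfigError("image_size must be at least 16x16")
        return self

    @property
    def frame_interval(self) -> float:
        return 1.0 / self.frame_rate

    @property
    def fractions(self) -> np.ndarray:
        return np.array(
            [self.fraction_monomer, self.fraction_dimer, self.fraction_trimer]
        )


class ForceConfig(BaseModel):
    """Parameters of the AFM force-curve generator.

    Defaults mirror the untreated (control) condition: a soft 0.06 N/m
    cantilever loaded at 1e4 pN/s, ~21.7% of curves carrying one specific
    rupture with Gaussian force distribution centred at 49.5 pN, plus a
    nonspecific adhesion contaminant confined to within 5 nm of contact
    (specific ruptures occur beyond 10 nm, giving the specificity filter a
    well-separated target).
    """

    model_config = ConfigDict(extra="forbid")

    n_curves: int = Field(600, ge=1)
    spring_constant: float = Field(0.06, gt=0)  # N/m
    loading_rate: float = Field(1.0e4, gt=0)  # pN/s
    p_specific: float = Field(0.217, ge=0, le=1)
    specific_force_mean: float = Field(49.5, gt=0)  # pN
    specific_force_sd: float = Field(10.0, ge=0)  # pN
    p_nonspecific: float = Field(0.3, ge=0, le=1)
    nonspecific_force_mean: float = Field(80.0, gt=0)  # pN
    nonspecific_force_sd: float = Field(30.0, ge=0)  # pN
    noise_sd: float = Field(3.0, ge=0)  # pN
    points_per_segment: int = Field(400, ge=50)
    max_separation: float = Field(100.0, gt=0)  # nm
    min_separation: float = Field(-10.0)  # nm (indentation depth)
    rupture_sep_range: tuple[float, float] = (20.0, 45.0)  # nm from contact
    tether_stiffness: float = Field(3.0, gt=0)  # pN/nm loading slope
    baseline_offset_sd: float = Field(5.0, ge=0)  # pN
    baseline_slope_sd: float = Field(0.02, ge=0)  # pN/nm
    seed: int

    @model_validator(mode="after")
    def _check(self) -> "ForceConfig":
        lo, hi = self.rupture_sep_range
        if not (0 < lo < hi <= self.max_separation):
            raise ConfigError("rupture_sep_range must be within (0, max_separation]")
        if self.min_separation >= 0:
            raise ConfigError("min_separation must be negative (indentation)")
        return self


class BindingSimConfig(BaseModel):
    """Parameters of the binding-series generator."""

    model_config = ConfigDict(extra="forbid")

    mode: Literal["steady_state", "competition"] = "steady_state"
    true_KD: float = Field(15.9, gt=0)  # μM, steady-state mode
    true_logIC50: float = -4.16  # log10 molar, competition mode
    Rmax: float = Field(100.0, gt=0)  # response units
    concentrations: Optional[list[float]] = None
    noise_sd: float = Field(0.0, ge=0)  # response units (or % points)
    seed: int

    @model_validator(mode="after")
    def _check(self) -> "BindingSimConfig":
        if self.concentrations is not None:
            c = np.asarray(self.concentrations, dtype=float)
            if np.any(c <= 0):
                raise ConfigError("concentrations must be strictly positive")
            if np.unique(c).size != c.size:
                raise ConfigError("concentrations must be distinct")
        return self

    def resolved_concentrations(self) -> np.ndarray:
        if self.concentrations is not None:
            return np.asarray(self.concentrations, dtype=float)
        if self.mode == "steady_state":
            return np.asarray(TWOFOLD_SERIES_UM)
        # competition: 8 half-decade doses bracketing ~70 μM in molar units
        return 10.0 ** np.arange(-6.5, -2.4, 0.5)


# --------------------------------------------------------------------------
# photobleaching traces
# --------------------------------------------------------------------------

@dataclass
class MovieGroundTruth:
    """Per-spot truth for a simulated movie.

    ``bleach_frames[i]`` holds one sorted frame index per fluorophore of
    spot ``i``; a fluorophore that survives the whole movie is recorded
    with the sentinel ``n_frames`` (its trace is "incomplete").
    """

    centers: np.ndarray  # (n_spots, 2) float, (row, col), 0-based
    counts: np.ndarray  # (n_spots,) int in 1..3
    bleach_frames: list[np.ndarray] = field(default_factory=list)
    n_frames: int = 0

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i, (c, k, bf) in enumerate(
            zip(self.centers, self.counts, self.bleach_frames)
        ):
            rows.append(
                {
                    "spot": i,
                    "row": c[0],
                    "col": c[1],
                    "n_fluorophores": int(k),
                    "bleach_frames": ";".join(str(int(b)) for b in bf),
                }
            )
        return pd.DataFrame(rows)


def _draw_bleach_frames(
    n_fluorophores: int, config: MovieConfig, rng: np.random.Generator
) -> np.ndarray:
    """Exponential bleach times, truncated to the movie; survivors get the
    sentinel ``n_frames``."""
    t = rng.exponential(1.0 / config.bleach_rate, size=n_fluorophores)
    frames = np.floor(t * config.frame_rate).astype(int)
    frames = np.minimum(frames, config.n_frames)
    return np.sort(frames)


def _emission_matrix(
    bleach_frames: np.ndarray, config: MovieConfig, rng: np.random.Generator
) -> np.ndarray:
    """(n_fluorophores, n_frames) 0/1 emission indicator."""
    frames = np.arange(config.n_frames)
    on = frames[None, :] < bleach_frames[:, None]
    if config.p_dark > 0:
        dark = rng.random(bleach_frames.size) < config.p_dark
        on = on & ~dark[:, None]
    if config.blink_off_rate > 0:
        dt = config.frame_interval
        p_off = 1.0 - np.exp(-config.blink_off_rate * dt)
        p_on = 1.0 - np.exp(-config.blink_on_rate * dt)
        for i in range(on.shape[0]):
            state = True
            for f in range(config.n_frames):
                if not state:
                    on[i, f] = False
                state = (state and rng.random() >= p_off) or (
                    not state and rng.random() < p_on
                )
    return on.astype(float)


def _noiseless_signal(
    bleach_frames: np.ndarray, config: MovieConfig, rng: np.random.Generator
) -> np.ndarray:
    return config.unit_intensity * _emission_matrix(bleach_frames, config, rng).sum(
        axis=0
    )


def simulate_photobleach_trace(
    n_fluorophores: int,
    config: MovieConfig,
    rng: Optional[np.random.Generator] = None,
    bleach_frames: Optional[Sequence[int]] = None,
) -> tuple[IntensityTrace, np.ndarray]:
    """Simulate one background-corrected photobleaching trace.

    The noiseless signal is a sum of per-fluorophore step functions
    (``unit_intensity`` until that fluorophore's exponential bleach time,
    zero after). With ``shot_noise`` on, the photon count over the 5×5
    aperture is Poisson-distributed around signal + aperture background,
    the (known) background is subtracted back off, and Gaussian read
    noise is added.

    Returns the trace and the sorted ground-truth bleach frames
    (sentinel ``n_frames`` for fluorophores surviving the movie).
    """
    if not 1 <= n_fluorophores <= 3:
        raise ConfigError("n_fluorophores must be 1, 2 or 3")
    if rng is None:
        rng = spawn_rng(config.seed, 0)
    if bleach_frames is None:
        bleach_frames = _draw_bleach_frames(n_fluorophores, config, rng)
    else:
        bleach_frames = np.sort(np.asarray(bleach_frames, dtype=int))
        if bleach_frames.size != n_fluorophores:
            raise ConfigError("one bleach frame per fluorophore required")
        if bleach_frames.min() < 0 or bleach_frames.max() > config.n_frames:
            raise ConfigError("bleach frames must lie in [0, n_frames]")
    signal = _noiseless_signal(bleach_frames, config, rng)
    if config.shot_noise:
        bg = 25.0 * config.background_level
        counts = rng.poisson(signal + bg).astype(float)
        values = counts - bg + rng.normal(
            0.0, 5.0 * config.read_noise_sd, size=signal.size
        )
    else:
        values = signal
    return IntensityTrace(values, config.frame_interval), bleach_frames


# --------------------------------------------------------------------------
# TIRFM movies
# --------------------------------------------------------------------------

def _place_spots(
    config: MovieConfig, rng: np.random.Generator, max_tries: int = 20000
) -> np.ndarray:
    """Uniform random centers with a minimum pairwise separation.

    Separation floor is max(4·psf_sigma, 6 px) so that rendered spots do
    not overlap and the downstream 5-px spot-pair exclusion rarely fires;
    a 6-px margin keeps the 5×5 analysis region inside the image.
    """
    min_sep = max(4.0 * config.psf_sigma, 6.0)
    margin = 6.0
    h, w = config.image_size
    if h - 2 * margin <= 0 or w - 2 * margin <= 0:
        raise PlacementError("image too small for the placement margin")
    centers: list[np.ndarray] = []
    tries = 0
    while len(centers) < config.n_spots:
        tries += 1
        if tries > max_tries:
            raise PlacementError(
                f"could not place {config.n_spots} spots at separation "
                f">= {min_sep:.1f} px in a {h}x{w} image"
            )
        cand = np.array(
            [rng.uniform(margin, h - 1 - margin), rng.uniform(margin, w - 1 - margin)]
        )
        if all(np.hypot(*(cand - c)) >= min_sep for c in centers):
            centers.append(cand)
    return np.array(centers).reshape(config.n_spots, 2)


def _psf_patch(
    center: np.ndarray, sigma: float, half: int
) -> tuple[slice, slice, np.ndarray]:
    """Unit-flux Gaussian patch around an (integer-window) center."""
    r0, c0 = int(round(center[0])) - half, int(round(center[1])) - half
    rows = np.arange(r0, r0 + 2 * half + 1)
    cols = np.arange(c0, c0 + 2 * half + 1)
    gr = np.exp(-((rows - center[0]) ** 2) / (2 * sigma**2))
    gc = np.exp(-((cols - center[1]) ** 2) / (2 * sigma**2))
    patch = np.outer(gr, gc)
    patch /= 2.0 * np.pi * sigma**2  # unit total flux on the infinite plane
    return slice(r0, r0 + 2 * half + 1), slice(c0, c0 + 2 * half + 1), patch


def simulate_tirfm_movie(
    config: MovieConfig,
) -> tuple[np.ndarray, MovieGroundTruth]:
    """Simulate a sparse-spot single-channel TIRFM stack.

    Each spot is a 2-D Gaussian of width ``psf_sigma`` whose total flux per
    frame follows its simulated bleaching trace; the stack is returned as
    float64 photons (exact; use :func:`write_movie_tiff` for 16-bit TIFF).
    """
    rng = spawn_rng(config.seed, 1)
    centers = _place_spots(config, rng)
    counts = (
        rng.choice(np.array([1, 2, 3]), size=config.n_spots, p=config.fractions)
        if config.n_spots
        else np.empty(0, dtype=int)
    )
    h, w = config.image_size
    stack = np.full((config.n_frames, h, w), float(config.background_level))
    half = max(4, int(np.ceil(4 * config.psf_sigma)))
    truth = MovieGroundTruth(
        centers=centers,
        counts=np.asarray(counts, dtype=int),
        bleach_frames=[],
        n_frames=config.n_frames,
    )
    for i in range(config.n_spots):
        bf = _draw_bleach_frames(int(counts[i]), config, rng)
        truth.bleach_frames.append(bf)
        signal = _noiseless_signal(bf, config, rng)
        rs, cs, patch = _psf_patch(centers[i], config.psf_sigma, half)
        stack[:, rs, cs] += signal[:, None, None] * patch[None, :, :]
    if config.shot_noise:
        stack = rng.poisson(stack).astype(float)
        if config.read_noise_sd > 0:
            stack += config.read_noise_sd * rng.standard_normal(
                stack.shape, dtype=np.float32
            )
    return stack, truth


def write_movie_tiff(path, stack: np.ndarray) -> None:
    """Write a stack as single-channel 16-bit unsigned TIFF, one page per frame."""
    data = np.clip(np.round(stack), 0, 65535).astype(np.uint16)
    tifffile.imwrite(str(path), data, photometric="minisblack")


def read_movie_tiff(path) -> np.ndarray:
    return np.asarray(tifffile.imread(str(path)))


# --------------------------------------------------------------------------
# AFM force curves
# --------------------------------------------------------------------------

def simulate_force_curve(
    has_specific: bool,
    config: ForceConfig,
    rng: Optional[np.random.Generator] = None,
) -> tuple[ForceCurve, Optional[float]]:
    """Simulate one approach/retract force–distance cycle.

    The retract carries, when ``has_specific``, a single sawtooth rupture:
    the pulling force ramps linearly (tether stiffness) to the drawn
    rupture force at a separation in ``rupture_sep_range`` and then drops
    discontinuously to baseline. A nonspecific adhesion (probability
    ``p_nonspecific``) is confined to within 5 nm of the contact point.
    Returns the curve and the ground-truth specific rupture force (pN) or
    None.
    """
    if rng is None:
        rng = spawn_rng(config.seed, 2)
    n = config.points_per_segment
    sep = np.linspace(config.min_separation, config.max_separation, n)
    k_pn_per_nm = config.spring_constant * 1000.0  # (N/m)·nm -> pN

    contact = np.where(sep < 0, -k_pn_per_nm * sep, 0.0)

    retract = contact.copy()
    true_force: Optional[float] = None
    if has_specific:
        f_r = -1.0
        while f_r <= 0:  # Gaussian truncated at zero; forces are magnitudes
            f_r = rng.normal(config.specific_force_mean, config.specific_force_sd)
        s_r = rng.uniform(*config.rupture_sep_range)
        s_start = s_r - f_r / config.tether_stiffness
        ramp = (sep > s_start) & (sep <= s_r)
        retract[ramp] -= config.tether_stiffness * (sep[ramp] - s_start)
        true_force = float(f_r)
    if rng.random() < config.p_nonspecific:
        f_ns = abs(
            rng.normal(config.nonspecific_force_mean, config.nonspecific_force_sd)
        )
        s_ns = rng.uniform(2.0, 5.0)
        ramp = (sep > 0) & (sep <= s_ns)
        retract[ramp] -= f_ns * sep[ramp] / s_ns

    offset = rng.normal(0.0, config.baseline_offset_sd)
    slope = rng.normal(0.0, config.baseline_slope_sd)
    tilt = offset + slope * sep
    approach_f = contact + tilt
    retract_f = retract + tilt
    if config.noise_sd > 0:
        approach_f = approach_f + rng.normal(0.0, config.noise_sd, size=n)
        retract_f = retract_f + rng.normal(0.0, config.noise_sd, size=n)

    curve = ForceCurve(
        approach_separation=sep[::-1].copy(),
        approach_force=approach_f[::-1].copy(),
        retract_separation=sep,
        retract_force=retract_f,
        spring_constant=config.spring_constant,
        loading_rate=config.loading_rate,
    )
    return curve, true_force


def simulate_force_curves(
    config: ForceConfig, condition: str = ""
) -> tuple[list[ForceCurve], pd.DataFrame]:
    """Simulate a batch of curves; ``p_specific`` decides which carry a
    specific rupture. Returns the curves and a ground-truth table."""
    rng = spawn_rng(config.seed, 2)
    has = rng.random(config.n_curves) < config.p_specific
    curves, rows = [], []
    for i in range(config.n_curves):
        curve, f = simulate_force_curve(bool(has[i]), config, rng)
        curve.curve_id = f"{condition or 'curve'}_{i:05d}"
        curve.condition = condition
        curves.append(curve)
        rows.append(
            {"curve_id": curve.curve_id, "has_specific": bool(has[i]),
             "true_force_pN": f if f is not None else np.nan}
        )
    return curves, pd.DataFrame(rows)


# --------------------------------------------------------------------------
# binding series
# --------------------------------------------------------------------------

def langmuir_response(C: np.ndarray, Rmax: float, KD: float) -> np.ndarray:
    """1:1 steady-state binding isotherm R = Rmax·C/(KD + C)."""
    C = np.asarray(C, dtype=float)
    return Rmax * C / (KD + C)


def competition_response(C: np.ndarray, logIC50: float) -> np.ndarray:
    """One-site competition, unit slope, asymptotes fixed at 100/0 (%)."""
    C = np.asarray(C, dtype=float)
    return 100.0 / (1.0 + 10.0 ** (np.log10(C) - logIC50))


def simulate_binding_series(config: BindingSimConfig) -> BindingSeries:
    """Simulate a steady-state or competition concentration–response series."""
    rng = spawn_rng(config.seed, 3)
    C = config.resolved_concentrations()
    if config.mode == "steady_state":
        resp = langmuir_response(C, config.Rmax, config.true_KD)
    else:
        resp = competition_response(C, config.true_logIC50)
    if config.noise_sd > 0:
        resp = resp + rng.normal(0.0, config.noise_sd, size=C.size)
    return BindingSeries(C, resp, mode=config.mode)
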