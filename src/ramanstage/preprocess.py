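"""Spectral preprocessing: raw hyperspectral cube -> normalized spectrum table.

The chain, applied per FOV:

1. extract the 600-1800 cm**-1 fingerprint region,
2. despike every pixel spectrum with a Hampel filter (sliding-window median,
   3 x scaled-MAD rule),
3. Savitzky-Golay smoothing (window 9, order 5),
4. iterative modified polynomial baseline subtraction (degree 12, 100
   iterations of fit-then-clip-to-minimum),
5. 5 x 5 spatial binning (block means),
6. per-spectrum z-score standardization and Frobenius normalization.

All stages accept either a single spectrum or an (N, C) stack and are
vectorized over rows; the 12th-degree baseline fits run in an orthonormal
Legendre basis on the axis mapped to [-1, 1], which is mathematically the
same least-squares problem as a raw-polynomial fit but numerically stable.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd
from numpy.lib.stride_tricks import sliding_window_view
from scipy.signal import savgol_filter

from .axes import FINGERPRINT_HI, FINGERPRINT_LO, WavenumberAxis
from .synth import HyperspectralCube
from .table import SpectrumTable

#: Consistency factor turning a median absolute deviation into a Gaussian SD.
MAD_SCALE = 1.4826

_DEGENERATE_TOL = 1e-8


class DegenerateSpectrumError(ValueError):
    """A spectrum is (numerically) constant and cannot be standardized."""


def _as_float(x: np.ndarray) -> np.ndarray:
    """Coerce to a floating array, preserving float32 inputs."""
    x = np.asarray(x)
    return x if np.issubdtype(x.dtype, np.floating) else x.astype(float)


@dataclass(frozen=True)
class PreprocessConfig:
    fingerprint_lo: float = FINGERPRINT_LO
    fingerprint_hi: float = FINGERPRINT_HI
    hampel_halfwidth: int = 3
    hampel_nsigma: float = 3.0
    sg_window: int = 9
    sg_polyorder: int = 5
    baseline_order: int = 12
    baseline_iterations: int = 100
    bin_factor: int = 5
    normalization_order: str = "zscore_then_frobenius"
    normalization_scope: str = "spectrum"

    def __post_init__(self) -> None:
        if self.fingerprint_lo >= self.fingerprint_hi:
            raise ValueError("fingerprint_lo must be < fingerprint_hi")
        if self.sg_window % 2 == 0 or self.sg_window <= self.sg_polyorder:
            raise ValueError("sg_window must be odd and > sg_polyorder")
        if self.bin_factor < 1:
            raise ValueError("bin_factor must be >= 1")
        if self.baseline_order < 1 or self.baseline_iterations < 1:
            raise ValueError("baseline order and iterations must be >= 1")
        if self.hampel_halfwidth < 1 or self.hampel_nsigma <= 0:
            raise ValueError("invalid hampel parameters")
        if self.normalization_order not in (
            "zscore_then_frobenius",
            "frobenius_then_zscore",
        ):
            raise ValueError(f"unknown normalization_order {self.normalization_order!r}")
        if self.normalization_scope not in ("spectrum", "fov"):
            raise ValueError(f"unknown normalization_scope {self.normalization_scope!r}")


# ---------------------------------------------------------------------------
# stage 1: fingerprint extraction

def extract_fingerprint(
    cube: HyperspectralCube,
    lo: float = FINGERPRINT_LO,
    hi: float = FINGERPRINT_HI,
) -> HyperspectralCube:
    """Keep exactly the channels with lo <= wavenumber <= hi (closed)."""
    mask = cube.axis.window_mask(lo, hi)
    if not mask.any():
        raise ValueError(
            f"no channel of the axis falls inside [{lo}, {hi}] cm^-1"
        )
    return HyperspectralCube(
        intensities=cube.intensities[:, :, mask],
        axis=WavenumberAxis(cube.axis.values[mask]),
        line=cube.line,
        organoid_id=cube.organoid_id,
        stage_weeks=cube.stage_weeks,
        fov_id=cube.fov_id,
        pitch_um=cube.pitch_um,
    )


# ---------------------------------------------------------------------------
# stage 2: Hampel despiking

def _window_median_mad(block: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    med = np.median(block, axis=-1)
    mad = np.median(np.abs(block - med[..., None]), axis=-1)
    return med, mad


def remove_cosmic_rays(
    spectra: np.ndarray, halfwidth: int = 3, nsigma: float = 3.0
) -> np.ndarray:
    """Hampel filter along the channel axis.

    For each channel, the median and scaled MAD (sigma-hat = 1.4826 * MAD) of
    the window of ``2*halfwidth + 1`` channels (truncated at the spectrum
    edges) are computed; the value is replaced by the window median iff it
    deviates from it by more than ``nsigma * sigma-hat``.
    """
    if halfwidth < 1 or nsigma <= 0:
        raise ValueError("halfwidth must be >= 1 and nsigma > 0")
    x = _as_float(spectra)
    squeeze = x.ndim == 1
    X = np.atleast_2d(x)
    n, c = X.shape
    if c < 2:
        raise ValueError("spectrum must have at least 2 channels")

    med = np.empty_like(X)
    mad = np.empty_like(X)
    w = 2 * halfwidth + 1
    if c >= w:
        core = sliding_window_view(X, w, axis=1)
        med[:, halfwidth : c - halfwidth], mad[:, halfwidth : c - halfwidth] = (
            _window_median_mad(core)
        )
        edge = list(range(halfwidth)) + list(range(c - halfwidth, c))
    else:
        edge = list(range(c))
    for i in edge:  # truncated windows at the spectrum ends
        lo, hi = max(0, i - halfwidth), min(c, i + halfwidth + 1)
        med[:, i], mad[:, i] = _window_median_mad(X[:, lo:hi])

    outlier = np.abs(X - med) > nsigma * MAD_SCALE * mad
    out = np.where(outlier, med, X)
    return out[0] if squeeze else out


# ---------------------------------------------------------------------------
# stage 3: Savitzky-Golay smoothing

def sg_smooth(spectra: np.ndarray, window: int = 9, polyorder: int = 5) -> np.ndarray:
    """Least-squares polynomial smoothing; exact on polynomials <= polyorder.

    Edges are handled by fitting the polynomial on the truncated window
    (scipy's ``mode='interp'``).
    """
    if window % 2 == 0 or window <= polyorder:
        raise ValueError("window must be odd and > polyorder")
    x = _as_float(spectra)
    if x.shape[-1] < window:
        raise ValueError("spectrum shorter than the smoothing window")
    return savgol_filter(x, window, polyorder, axis=-1, mode="interp")


# ---------------------------------------------------------------------------
# stage 4: iterative modified polynomial baseline

def _legendre_q(axis: WavenumberAxis, order: int) -> np.ndarray:
    """Orthonormal basis (C x (order+1)) of degree-``order`` polynomials."""
    v = axis.values
    t = 2.0 * (v - v[0]) / (v[-1] - v[0]) - 1.0
    vand = np.polynomial.legendre.legvander(t, order)
    q, _ = np.linalg.qr(vand)
    return q


def baseline_subtract(
    spectra: np.ndarray,
    axis: WavenumberAxis,
    order: int = 12,
    iterations: int = 100,
) -> tuple[np.ndarray, np.ndarray]:
    """Iterative modified polynomial fitting (fit, clip to minimum, repeat).

    Starting from the spectrum itself, a degree-``order`` least-squares
    polynomial is fitted and the working spectrum replaced by the pointwise
    minimum of itself and the fit; after ``iterations`` rounds the final fit
    is the autofluorescence baseline estimate.  Peaks stick out above the
    baseline and are progressively excluded by the minimum operation.

    Returns ``(corrected, baseline)`` with ``corrected = spectra - baseline``.
    """
    if order < 1 or iterations < 1:
        raise ValueError("order and iterations must be >= 1")
    x = _as_float(spectra)
    squeeze = x.ndim == 1
    X = np.atleast_2d(x)
    if X.shape[1] != len(axis):
        raise ValueError("spectra and axis disagree on channel count")
    if X.shape[1] <= order:
        raise ValueError("fit is ill-posed: need more channels than the degree")

    q = _legendre_q(axis, order).astype(X.dtype, copy=False)
    working = X.copy()
    fit = working
    for _ in range(iterations):
        fit = (working @ q) @ q.T
        np.minimum(working, fit, out=working)
    corrected = X - fit
    if squeeze:
        return corrected[0], fit[0]
    return corrected, fit


# ---------------------------------------------------------------------------
# stage 5: spatial binning

def bin_spatial(cube: HyperspectralCube, factor: int = 5) -> HyperspectralCube:
    """Average non-overlapping factor x factor pixel blocks per channel."""
    binned = bin_blocks(cube.intensities, factor)
    return HyperspectralCube(
        intensities=binned,
        axis=cube.axis,
        line=cube.line,
        organoid_id=cube.organoid_id,
        stage_weeks=cube.stage_weeks,
        fov_id=cube.fov_id,
        pitch_um=cube.pitch_um * factor,
    )


def bin_blocks(block: np.ndarray, factor: int) -> np.ndarray:
    if factor < 1:
        raise ValueError("bin factor must be >= 1")
    h, w, c = block.shape
    if h % factor or w % factor:
        raise ValueError(
            f"spatial dimensions {h}x{w} not divisible by bin factor {factor}"
        )
    return block.reshape(h // factor, factor, w // factor, factor, c).mean(axis=(1, 3))


# ---------------------------------------------------------------------------
# stage 6: normalization

def zscore(spectra: np.ndarray) -> np.ndarray:
    """Per-spectrum standardization to mean 0, SD 1 across channels."""
    x = np.asarray(spectra, dtype=float)
    squeeze = x.ndim == 1
    X = np.atleast_2d(x)
    mean = X.mean(axis=1, keepdims=True)
    sd = X.std(axis=1, keepdims=True)
    floor = _DEGENERATE_TOL * np.maximum(1.0, np.abs(mean))
    if np.any(sd <= floor):
        raise DegenerateSpectrumError("constant spectrum cannot be z-scored")
    out = (X - mean) / sd
    return out[0] if squeeze else out


def frobenius_normalize(block: np.ndarray) -> np.ndarray:
    """Divide a spectrum (or matrix of spectra) by its Frobenius norm."""
    x = np.asarray(block, dtype=float)
    norm = float(np.linalg.norm(x))
    if norm == 0.0:
        raise DegenerateSpectrumError("zero block cannot be normalized")
    return x / norm


def _normalize_rows(X: np.ndarray) -> np.ndarray:
    norms = np.linalg.norm(X, axis=1, keepdims=True)
    if np.any(norms == 0.0):
        raise DegenerateSpectrumError("zero spectrum cannot be normalized")
    return X / norms


def normalize(
    X: np.ndarray,
    order: str = "zscore_then_frobenius",
    scope: str = "spectrum",
) -> np.ndarray:
    """Apply z-score and Frobenius normalization to an (N, C) block.

    z-scoring is always per spectrum; the Frobenius norm is taken per
    spectrum or over the whole block (one FOV) depending on ``scope``.
    """
    def frob(Y: np.ndarray) -> np.ndarray:
        return _normalize_rows(Y) if scope == "spectrum" else frobenius_normalize(Y)

    if order == "zscore_then_frobenius":
        return frob(zscore(X))
    if order == "frobenius_then_zscore":
        return zscore(frob(X))
    raise ValueError(f"unknown normalization order {order!r}")


# ---------------------------------------------------------------------------
# full pipeline

def preprocess_cube(
    cube: HyperspectralCube, config: PreprocessConfig = PreprocessConfig()
) -> HyperspectralCube:
    """Stages 1-5 on one cube: fingerprint, despike, smooth, baseline, bin."""
    fp = extract_fingerprint(cube, config.fingerprint_lo, config.fingerprint_hi)
    h, w, c = fp.shape
    # single precision is ample for raw detector counts and cuts the batch
    # despiking/fit cost several-fold; the binned output returns to float64
    spectra = fp.spectra().astype(np.float32)
    spectra = remove_cosmic_rays(spectra, config.hampel_halfwidth, config.hampel_nsigma)
    spectra = sg_smooth(spectra, config.sg_window, config.sg_polyorder)
    pre_norm = np.linalg.norm(spectra, axis=1)
    spectra, _ = baseline_subtract(
        spectra, fp.axis, config.baseline_order, config.baseline_iterations
    )
    # a spectrum that was (numerically) pure baseline has nothing left to
    # normalize; catch it here where the pre-subtraction scale is known.
    # 1e-4 sits well above single-precision fit roundoff (~1e-5 relative)
    # and well below any real peak-plus-noise residual (>= 1e-2 relative)
    post_norm = np.linalg.norm(spectra, axis=1)
    if np.any(post_norm <= 1e-4 * pre_norm):
        raise DegenerateSpectrumError(
            "spectrum is entirely baseline; nothing remains after subtraction"
        )
    corrected = HyperspectralCube(
        intensities=spectra.reshape(h, w, c).astype(np.float64),
        axis=fp.axis,
        line=fp.line,
        organoid_id=fp.organoid_id,
        stage_weeks=fp.stage_weeks,
        fov_id=fp.fov_id,
        pitch_um=fp.pitch_um,
    )
    return bin_spatial(corrected, config.bin_factor)


def preprocess_pipeline(
    cubes: Iterable[HyperspectralCube],
    config: PreprocessConfig = PreprocessConfig(),
) -> SpectrumTable:
    """Run the full chain over a study and stack the labelled rows."""
    blocks: list[np.ndarray] = []
    labels: list[dict] = []
    axis: WavenumberAxis | None = None
    for cube in cubes:
        cube_id = f"{cube.organoid_id}/{cube.fov_id}"
        try:
            binned = preprocess_cube(cube, config)
            rows = normalize(
                binned.spectra(),
                config.normalization_order,
                config.normalization_scope,
            )
        except Exception as exc:
            raise type(exc)(f"cube {cube_id}: {exc}") from exc
        if axis is None:
            axis = binned.axis
        elif binned.axis != axis:
            raise ValueError(f"cube {cube_id}: axis differs from previous cubes")
        blocks.append(rows)
        labels.extend(
            {
                "stage_weeks": cube.stage_weeks,
                "line": cube.line,
                "organoid_id": cube.organoid_id,
                "fov_id": f"{cube.organoid_id}/{cube.fov_id}",
            }
            for _ in range(rows.shape[0])
        )
    if axis is None:
        raise ValueError("no cubes to preprocess")
    return SpectrumTable(np.vstack(blocks), axis, pd.DataFrame(labels))
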