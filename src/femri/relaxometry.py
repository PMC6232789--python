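"""Pixel-wise monoexponential T2*/R2* relaxometry for multi-gradient-echo series.

The observable is a stack of magnitude images acquired at increasing echo
times TE.  Each pixel is modelled as

    S(TE) = S0 * exp(-R2* . TE)

with the effective transverse relaxation rate R2* = 1/T2*.  Iron deposits
shorten T2*, so R2* maps carry the iron contrast that the downstream
calibration converts to concentration maps.

Rates are stored in s^-1 while echo times are in ms; the unit conversion is
explicit in :func:`fit_monoexponential` (rates are fitted per ms and scaled
by 1000 on output).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .exceptions import InputError

__all__ = ["MGESeries", "R2StarMap", "fit_monoexponential", "t2star_map"]


@dataclass
class MGESeries:
    """Multi-echo magnitude image stack.

    Attributes
    ----------
    stack:
        Array of shape ``(n_echoes, rows, cols)``, arbitrary signal units,
        all values >= 0.
    echo_times:
        Echo times in ms, strictly increasing, one per stack plane.
    pixel_size:
        In-plane pixel size in mm.
    tr_s, flip_angle_deg:
        Acquisition metadata carried for provenance; unused by the fit.
    """

    stack: np.ndarray
    echo_times: np.ndarray
    pixel_size: float = 0.1
    tr_s: Optional[float] = None
    flip_angle_deg: Optional[float] = None

    def __post_init__(self) -> None:
        self.stack = np.asarray(self.stack, dtype=float)
        self.echo_times = np.asarray(self.echo_times, dtype=float)
        if self.stack.ndim != 3:
            raise InputError("stack must be (echoes, rows, cols)")
        if self.stack.shape[0] != self.echo_times.size:
            raise InputError(
                f"stack depth {self.stack.shape[0]} does not match "
                f"{self.echo_times.size} echo times"
            )
        if self.echo_times.size and (
            np.any(np.diff(self.echo_times) <= 0) or self.echo_times[0] <= 0
        ):
            raise InputError("echo times must be positive and strictly increasing")
        if np.any(self.stack < 0):
            raise InputError("magnitude stack must be non-negative")

    @property
    def shape(self) -> tuple[int, int]:
        return self.stack.shape[1:]


@dataclass
class R2StarMap:
    """Per-pixel monoexponential fit results.

    ``r2star`` is in s^-1 and is non-negative wherever ``fit_ok``;
    ``fit_ok`` is False for pixels excluded from, or failed by, the fit.
    """

    r2star: np.ndarray
    s0: np.ndarray
    fit_ok: np.ndarray
    rss: np.ndarray
    pixel_size: float = 0.1


def _loglinear(te: np.ndarray, sig: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Ordinary log-linear regression of ln S on TE, vectorized over pixels.

    ``sig`` has shape (n_echoes, n_pixels).  Returns (rate per ms, amplitude).
    """
    lns = np.log(np.clip(sig, 1e-300, None))
    te = te[:, None]
    n = te.shape[0]
    te_mean = te.mean()
    lns_mean = lns.mean(axis=0)
    sxx = float(np.sum((te - te_mean) ** 2))
    sxy = np.sum((te - te_mean) * (lns - lns_mean), axis=0)
    slope = sxy / sxx
    intercept = lns_mean - slope * te_mean
    return -slope, np.exp(intercept)


def _gauss_newton(
    te: np.ndarray,
    sig: np.ndarray,
    rate0: np.ndarray,
    amp0: np.ndarray,
    max_iter: int = 50,
    tol: float = 1e-12,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Damped Gauss-Newton refinement of (S0, rate) per pixel, vectorized.

    Levenberg-style damping: each pixel carries its own lambda, increased on
    rejected steps and decreased on accepted ones.  Returns (rate, amp, rss).
    """
    te = te[:, None]
    amp = amp0.copy()
    rate = rate0.copy()
    lam = np.full(rate.shape, 1e-3)

    def rss_of(a: np.ndarray, r: np.ndarray) -> np.ndarray:
        return np.sum((sig - a * np.exp(-r * te)) ** 2, axis=0)

    rss = rss_of(amp, rate)
    for _ in range(max_iter):
        model = amp * np.exp(-rate * te)
        resid = sig - model
        # Jacobian columns: d/dS0 = model/S0 (=exp(-r te)), d/dr = -te*model
        j1 = np.exp(-rate * te)
        j2 = -te * model
        h11 = np.sum(j1 * j1, axis=0)
        h12 = np.sum(j1 * j2, axis=0)
        h22 = np.sum(j2 * j2, axis=0)
        g1 = np.sum(j1 * resid, axis=0)
        g2 = np.sum(j2 * resid, axis=0)
        a11 = h11 * (1.0 + lam)
        a22 = h22 * (1.0 + lam)
        det = a11 * a22 - h12 * h12
        ok = np.abs(det) > 1e-300
        det_safe = np.where(ok, det, 1.0)
        da = np.where(ok, (g1 * a22 - g2 * h12) / det_safe, 0.0)
        dr = np.where(ok, (g2 * a11 - g1 * h12) / det_safe, 0.0)
        new_rss = rss_of(amp + da, rate + dr)
        accept = new_rss <= rss
        amp = np.where(accept, amp + da, amp)
        rate = np.where(accept, rate + dr, rate)
        lam = np.where(accept, lam / 3.0, lam * 10.0)
        improved = rss - np.where(accept, new_rss, rss)
        rss = np.where(accept, new_rss, rss)
        if np.max(improved) <= tol * np.maximum(np.max(rss), 1.0):
            break
    return rate, amp, rss


def fit_monoexponential(
    series: MGESeries,
    mask: Optional[np.ndarray] = None,
    min_signal_fraction: float = 0.05,
    method: str = "nls",
    max_iter: int = 50,
) -> R2StarMap:
    """Fit S(TE) = S0 exp(-R2* TE) pixel-wise over a mask.

    Parameters
    ----------
    series:
        The multi-echo stack.
    mask:
        Boolean raster of pixels to fit (default: all).
    min_signal_fraction:
        Pixels whose first-echo signal falls below this fraction of the
        masked 99th-percentile first-echo signal are excluded
        (``fit_ok=False``); screens out non-tissue noise pixels.
    method:
        ``"nls"`` (nonlinear least squares, log-linear initialized; default)
        or ``"loglin"`` (plain log-linear regression).

    Returns
    -------
    R2StarMap
        Rates in s^-1; negative fitted rates are clamped to 0 with
        ``fit_ok`` retained.
    """
    if series.echo_times.size < 3:
        raise InputError("at least 3 echoes are required for a stable fit")
    if not 0 <= min_signal_fraction < 1:
        raise InputError("min_signal_fraction must be in [0, 1)")
    if method not in ("nls", "loglin"):
        raise InputError(f"unknown fit method {method!r}")

    shape = series.shape
    if mask is None:
        mask = np.ones(shape, dtype=bool)
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != shape:
        raise InputError(f"mask shape {mask.shape} does not match stack {shape}")

    r2star = np.zeros(shape)
    s0 = np.zeros(shape)
    rss_map = np.zeros(shape)
    fit_ok = np.zeros(shape, dtype=bool)

    if not mask.any():
        return R2StarMap(r2star, s0, fit_ok, rss_map, series.pixel_size)

    first = series.stack[0]
    ref = np.percentile(first[mask], 99)
    fit_mask = mask & (first >= min_signal_fraction * ref)
    if not fit_mask.any():
        return R2StarMap(r2star, s0, fit_ok, rss_map, series.pixel_size)

    sig = series.stack[:, fit_mask]  # (echoes, n_pixels)
    te = series.echo_times  # ms
    rate, amp = _loglinear(te, sig)
    if method == "nls":
        rate, amp, rss = _gauss_newton(te, sig, rate, amp, max_iter=max_iter)
    else:
        rss = np.sum((sig - amp * np.exp(-rate * te[:, None])) ** 2, axis=0)

    rate = np.where(rate < 0, 0.0, rate)  # physical non-negativity
    r2star[fit_mask] = rate * 1000.0  # per-ms -> s^-1
    s0[fit_mask] = amp
    rss_map[fit_mask] = rss
    fit_ok[fit_mask] = True
    return R2StarMap(r2star, s0, fit_ok, rss_map, series.pixel_size)


def t2star_map(r2map: R2StarMap) -> np.ndarray:
    """T2* in ms per pixel: 1000 / R2*[s^-1].

    Pixels with R2* = 0 or ``fit_ok=False`` are undefined and returned as NaN.
    """
    defined = r2map.fit_ok & (r2map.r2star > 0)
    out = np.full(r2map.r2star.shape, np.nan)
    out[defined] = 1000.0 / r2map.r2star[defined]
    return out
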