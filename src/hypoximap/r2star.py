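"""Voxelwise R2* relaxometry from multi-echo gradient-echo magnitude data.

The signal model is mono-exponential, S(TE) = S0 exp(-TE * R2*), and
R2* is the reciprocal of T2*.  The default estimator is a weighted
log-linear regression of ln S on TE (weights proportional to S², the
first-order variance weighting for log-transformed data) refined by a
bounded 1-D nonlinear least-squares solve in which S0 is profiled out
in closed form.  Echoes near the Rician noise floor can be excluded
per voxel via an estimated background sigma.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .config import R2StarFitConfig


@dataclass
class R2StarFitMaps:
    """Fitted R2* (Hz), S0, residuals and flags; T2* = 1/R2*."""

    r2star: np.ndarray
    s0: np.ndarray
    rss: np.ndarray
    n_echoes_used: np.ndarray
    converged: np.ndarray
    method: str = "loglinear+nls"

    @property
    def t2star(self) -> np.ndarray:
        return 1.0 / self.r2star


def mege_signal(te_s, s0: float, r2star: float):
    """Gradient-echo decay S0 exp(-TE R2*); TE in seconds, R2* in Hz."""
    if r2star < 0:
        raise ValueError("R2* must be non-negative")
    te = np.asarray(te_s, dtype=float)
    if np.any(te < 0):
        raise ValueError("TE must be non-negative")
    return s0 * np.exp(-te * r2star)


def estimate_background_sigma(series: np.ndarray, corner: int = 8) -> float:
    """Estimate the Rician sigma from air-only corner patches.

    Background magnitude data are Rayleigh distributed with mean
    sigma*sqrt(pi/2); the estimate averages the four in-plane corners
    across all echoes.
    """
    c = corner
    patches = [series[:c, :c], series[:c, -c:], series[-c:, :c], series[-c:, -c:]]
    mean = float(np.mean([p.mean() for p in patches]))
    return mean / np.sqrt(np.pi / 2.0)


def _profiled_sse(signals: np.ndarray, te: np.ndarray, w: np.ndarray,
                  r2_grid: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """SSE over usable echoes for each R2* candidate, with S0 profiled.

    For fixed R2*, the optimal S0 is sum(s e)/sum(e²) over usable
    echoes (e = exp(-TE R2*)).  Returns (sse, s0) of shape (n, k).
    """
    e = np.exp(-r2_grid[:, :, None] * te[None, None, :])  # (n, k, nte)
    we = w[:, None, :] * e
    num = (we * signals[:, None, :]).sum(axis=2)
    den = (we * e).sum(axis=2)
    s0 = np.where(den > 0, num / np.maximum(den, 1e-300), 0.0)
    resid = s0[:, :, None] * e - signals[:, None, :]
    sse = (w[:, None, :] * resid**2).sum(axis=2)
    return sse, s0


def fit_r2star(signals: np.ndarray, echo_times_s, cfg: R2StarFitConfig | None = None
               ) -> R2StarFitMaps:
    """Fit R2* over the last axis of ``signals``.

    Non-positive echoes (and echoes below the configured noise floor)
    are dropped per voxel; voxels with fewer than ``cfg.min_echoes``
    usable echoes, or whose estimate pins to the lower R2* bound, are
    flagged as non-converged.
    """
    cfg = cfg or R2StarFitConfig()
    te = np.asarray(echo_times_s, dtype=float)
    sig = np.asarray(signals, dtype=float)
    if sig.shape[-1] != te.size:
        raise ValueError("last signal axis must match the echo-time list")
    if te.size < cfg.min_echoes:
        raise ValueError(f"need at least {cfg.min_echoes} echoes")
    out_shape = sig.shape[:-1]
    flat = sig.reshape(-1, te.size)
    n = flat.shape[0]

    floor = 0.0
    if cfg.noise_sigma is not None:
        floor = cfg.noise_floor_factor * cfg.noise_sigma
    usable = (flat > 0) & (flat >= floor)
    n_used = usable.sum(axis=1)
    ok = n_used >= cfg.min_echoes

    w = np.where(usable, flat**2, 0.0)  # log-domain variance weights
    y = np.log(np.clip(flat, 1e-300, None))
    wsum = np.maximum(w.sum(axis=1), 1e-300)
    xbar = (w * te[None, :]).sum(axis=1) / wsum
    ybar = (w * y).sum(axis=1) / wsum
    dx = te[None, :] - xbar[:, None]
    sxx = np.maximum((w * dx**2).sum(axis=1), 1e-300)
    slope = (w * dx * (y - ybar[:, None])).sum(axis=1) / sxx
    lo, hi = cfg.r2_bounds
    r2_ll = np.clip(-slope, lo, hi)
    s0_ll = np.exp(ybar - slope * xbar)

    r2 = r2_ll.copy()
    s0 = s0_ll.copy()
    if cfg.refine:
        # bounded 1-D solve around the log-linear estimate (log-spaced
        # coarse-to-fine grid with parabolic polish; S0 in closed form)
        g_lo = np.log(np.clip(r2_ll / 3.0, lo, hi))
        g_hi = np.log(np.clip(r2_ll * 3.0, lo, hi))
        g_hi = np.maximum(g_hi, g_lo + 1e-9)
        pts = 17
        t = np.linspace(0.0, 1.0, pts)
        uw = usable.astype(float)
        last = None
        for _ in range(4):
            grid = g_lo[:, None] + (g_hi - g_lo)[:, None] * t[None, :]
            sse, s0_grid = _profiled_sse(flat, te, uw, np.exp(grid))
            k = np.argmin(sse, axis=1)
            step = (g_hi - g_lo) / (pts - 1)
            center = g_lo + step * k
            last = (center, step, sse, s0_grid, k)
            g_lo, g_hi = center - step, center + step
        center, step, sse, s0_grid, k = last
        rows = np.arange(n)
        km, kp = np.clip(k - 1, 0, pts - 1), np.clip(k + 1, 0, pts - 1)
        a_, b_, c_ = sse[rows, km], sse[rows, k], sse[rows, kp]
        denom = a_ - 2 * b_ + c_
        shift = np.zeros(n)
        interior = (k > 0) & (k < pts - 1) & (denom > 0)
        shift[interior] = 0.5 * (a_[interior] - c_[interior]) / denom[interior]
        r2 = np.clip(np.exp(center + np.clip(shift, -1, 1) * step), lo, hi)
        sse_fin, s0_fin = _profiled_sse(flat, te, uw, r2[:, None])
        # keep the refinement only where it does not degrade the fit
        sse_ll, _ = _profiled_sse(flat, te, uw, r2_ll[:, None])
        worse = sse_fin[:, 0] > sse_ll[:, 0]
        r2 = np.where(worse, r2_ll, r2)
        s0 = np.where(worse, s0_ll, s0_fin[:, 0])

    at_floor = r2 <= lo * (1 + 1e-9)
    converged = ok & ~at_floor
    e = np.exp(-r2[:, None] * te[None, :])
    rss = np.where(usable, (s0[:, None] * e - flat) ** 2, 0.0).sum(axis=1)
    r2_out = np.where(ok, r2, np.nan)
    s0_out = np.where(ok, s0, np.nan)
    rss = np.where(ok, rss, np.nan)

    return R2StarFitMaps(
        r2star=r2_out.reshape(out_shape), s0=s0_out.reshape(out_shape),
        rss=rss.reshape(out_shape), n_echoes_used=n_used.reshape(out_shape),
        converged=converged.reshape(out_shape),
    )
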