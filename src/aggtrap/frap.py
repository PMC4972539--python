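"""Single-exponential FRAP recovery fitting.

After a focal bleach at ``t0`` the normalized intensity of a region
recovers as ``I(t) = plateau * (1 - exp(-(t - t0)/tau))``; ``tau`` is the
FRAP recovery lifetime.  Soluble pools recover within a second; stable
aggregates show recovery lifetimes far beyond any practical acquisition
window, so slow behaviour is reported as a classification (lower bound)
rather than a trustworthy point estimate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

__all__ = ["FrapFit", "fit_recovery"]


@dataclass(frozen=True)
class FrapFit:
    tau: float  # recovery lifetime (s)
    plateau: float  # recovered fraction (normalized intensity units)
    r_squared: float
    classification: str  # "fast" | "slow"
    converged: bool
    observation_window: float  # post-bleach span actually observed (s)
    message: str = ""


def _model(t, plateau, tau):
    return plateau * (1.0 - np.exp(-t / tau))


def fit_recovery(
    times: np.ndarray,
    intensities: np.ndarray,
    t0: float = 0.0,
    normalize: bool = True,
    slow_threshold: float | None = None,
) -> FrapFit:
    """Fit a single-exponential recovery to a FRAP time course.

    Parameters
    ----------
    times, intensities:
        The measured curve.  Samples at ``t < t0`` are treated as
        pre-bleach; at least 5 post-bleach samples are required and times
        must be strictly increasing.
    t0:
        Bleach time.
    normalize:
        Rescale so the pre-bleach mean is 1 and the post-bleach minimum is
        0 before fitting.  With no pre-bleach samples the post-bleach
        range is used instead.
    slow_threshold:
        Recovery lifetimes above this are classified ``"slow"``.  Default:
        the observed post-bleach window, i.e. a curve whose lifetime
        exceeds the acquisition is only bounded from below.
    """
    times = np.asarray(times, dtype=float)
    intensities = np.asarray(intensities, dtype=float)
    if times.ndim != 1 or times.shape != intensities.shape:
        raise ValueError("times and intensities must be matching 1D arrays")
    if np.any(np.diff(times) <= 0):
        raise ValueError("times must be strictly increasing")

    post = times >= t0
    t = times[post] - t0
    y = intensities[post].copy()
    if len(t) < 5:
        raise ValueError("need at least 5 post-bleach samples")

    window = float(t[-1])
    if slow_threshold is None:
        slow_threshold = window

    if normalize:
        pre = intensities[~post]
        hi = float(np.mean(pre)) if len(pre) else float(np.max(y))
        lo = float(np.min(y))
        if hi - lo <= 0:
            raise ValueError("degenerate intensity range; cannot normalize")
        y = (y - lo) / (hi - lo)

    # initialization: plateau from the last quartile, tau from the time the
    # curve first reaches half of that plateau
    plateau0 = float(np.mean(y[-max(len(y) // 4, 1) :]))
    if plateau0 <= 0:
        plateau0 = max(float(np.max(y)), 1e-6)
    above = np.nonzero(y >= 0.5 * plateau0)[0]
    tau0 = float(t[above[0]]) / np.log(2.0) if len(above) else window
    tau0 = min(max(tau0, 1e-6), 100.0 * window)

    try:
        popt, _ = curve_fit(
            _model,
            t,
            y,
            p0=(plateau0, tau0),
            bounds=((0.0, 1e-12), (np.inf, np.inf)),
            maxfev=10000,
        )
        plateau, tau = float(popt[0]), float(popt[1])
        converged = True
        message = ""
    except RuntimeError as exc:  # pragma: no cover - scipy failure path
        return FrapFit(
            tau=float("nan"),
            plateau=float("nan"),
            r_squared=float("nan"),
            classification="slow",
            converged=False,
            observation_window=window,
            message=str(exc),
        )

    resid = y - _model(t, plateau, tau)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - float(np.sum(resid**2)) / ss_tot if ss_tot > 0 else float("nan")
    return FrapFit(
        tau=tau,
        plateau=plateau,
        r_squared=r2,
        classification="slow" if tau > slow_threshold else "fast",
        converged=converged,
        observation_window=window,
        message=message,
    )
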