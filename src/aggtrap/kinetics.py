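"""Closed-form decoy-site kinetics of facilitated target search.

A transcription factor (TF) searching the nucleus alternates 3D diffusion
with transient binding events.  Binding sites come in two classes: ``N_s``
specific (cognate) sites with per-site association rate ``k_s`` and
residence time ``tau_s``, and ``N_ns`` non-specific decoy sites with
per-site rate ``k_ns`` and residence time ``tau_ns``.  Protein aggregates
act as a large additional reservoir of non-specific decoy sites, so the
model links the decoy load ``N_ns`` to the specific-site search time and
to how frequently any given specific site is sampled by the cell's
``N_TF`` TF copies.

All quantities are count-based (rates in 1/s per site); there is no
molarity conversion.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "KineticParams",
    "KineticDerived",
    "p_sb",
    "n_trials",
    "tau_3d",
    "tau_search",
    "sampling_interval",
    "sampling_frequency",
    "effective_kon",
    "derive",
    "decoy_response_curve",
]


@dataclass(frozen=True)
class KineticParams:
    """Rates, site counts and residence times of the two-class search model."""

    k_s: float = 1.0  # association rate to one specific site (1/s)
    k_ns: float = 1.0  # association rate to one non-specific site (1/s)
    n_s: float = 1.0  # specific sites per cell
    n_ns: float = 0.0  # non-specific (decoy) sites per cell
    n_tf: float = 1.0  # TF copies per cell
    tau_ns: float = 0.0  # non-specific residence time (s)
    tau_s: float = 0.0  # specific residence time (s)

    def __post_init__(self) -> None:
        for name in ("k_s", "k_ns", "n_s", "n_ns", "n_tf", "tau_ns", "tau_s"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    def replace(self, **kw) -> "KineticParams":
        return replace(self, **kw)


@dataclass(frozen=True)
class KineticDerived:
    """All derived search-kinetics quantities for one parameter set."""

    p_sb: float
    n_trials: float
    tau_3d: float
    tau_search: float
    t_sampling: float
    f_sampling: float


def _check_specific_flux(params: KineticParams) -> None:
    if params.k_s * params.n_s <= 0:
        raise ValueError("k_s * n_s must be positive for search-time quantities")


def p_sb(params: KineticParams) -> float:
    """Probability that a free TF's next binding event is to a specific site.

    ``P_sb = k_s N_s / (k_s N_s + k_ns N_ns)``.
    """
    denom = params.k_s * params.n_s + params.k_ns * params.n_ns
    if denom <= 0:
        raise ValueError("k_s*n_s + k_ns*n_ns must be positive")
    return params.k_s * params.n_s / denom


def n_trials(params: KineticParams) -> float:
    """Expected number of binding trials before a specific site is reached.

    ``N_trials = 1 + k_ns N_ns / (k_s N_s)`` (equal to ``1 / P_sb``).
    """
    _check_specific_flux(params)
    return 1.0 + params.k_ns * params.n_ns / (params.k_s * params.n_s)


def tau_3d(params: KineticParams) -> float:
    """Mean 3D-diffusion interval between two successive binding events.

    ``tau_3D = 1 / (k_s N_s + k_ns N_ns)``.
    """
    denom = params.k_s * params.n_s + params.k_ns * params.n_ns
    if denom <= 0:
        raise ValueError("k_s*n_s + k_ns*n_ns must be positive")
    return 1.0 / denom


def tau_search(params: KineticParams) -> float:
    """Mean total search time for one TF to reach a specific site.

    Two algebraically equivalent forms exist: the trial-sum form
    ``N_trials (tau_3D + tau_ns) - tau_ns`` and the expanded form
    ``1/(k_s N_s) + tau_ns k_ns N_ns / (k_s N_s)``.  Both are computed and
    their agreement asserted; the expanded form is returned.  The
    trial-sum form is evaluated with the excess-trial count factored out
    (``N_trials tau_3D + (N_trials - 1) tau_ns``) so the subtraction of
    ``tau_ns`` cannot catastrophically cancel for long residence times.
    """
    _check_specific_flux(params)
    excess = params.k_ns * params.n_ns / (params.k_s * params.n_s)  # N_trials - 1
    trial_form = (1.0 + excess) * tau_3d(params) + excess * params.tau_ns
    ksns = params.k_s * params.n_s
    expanded = 1.0 / ksns + params.tau_ns * params.k_ns * params.n_ns / ksns
    if not np.isclose(trial_form, expanded, rtol=1e-12, atol=0.0):
        raise AssertionError(
            f"search-time identity violated: {trial_form} != {expanded}"
        )
    return expanded


def sampling_interval(params: KineticParams) -> float:
    """Mean interval between visits of any TF copy to one given specific site.

    First-order approximation ``T_sampling = ((tau_search + tau_s) / N_TF) * N_s``:
    one TF completes a search-plus-residence cycle in ``tau_search + tau_s``
    and lands on one of the ``N_s`` sites; ``N_TF`` copies search in parallel.
    """
    if params.n_tf <= 0:
        raise ValueError("n_tf must be positive")
    return (tau_search(params) + params.tau_s) / params.n_tf * params.n_s


def sampling_frequency(params: KineticParams) -> float:
    """``F_sampling = 1 / T_sampling`` (visits per second per specific site)."""
    return 1.0 / sampling_interval(params)


def effective_kon(kon: float, tf_conc: float) -> float:
    """Apparent specific-site association rate at free-TF concentration ``tf_conc``.

    ``kon_eff = kon * [TF]``: permanent trapping of TF copies inside
    aggregates lowers the searching concentration and hence the apparent
    on-rate.
    """
    if kon < 0 or tf_conc < 0:
        raise ValueError("kon and tf_conc must be non-negative")
    return kon * tf_conc


def derive(params: KineticParams) -> KineticDerived:
    """Compute every derived quantity at once."""
    return KineticDerived(
        p_sb=p_sb(params),
        n_trials=n_trials(params),
        tau_3d=tau_3d(params),
        tau_search=tau_search(params),
        t_sampling=sampling_interval(params),
        f_sampling=sampling_frequency(params),
    )


def decoy_response_curve(
    params: KineticParams, n_ns_grid: Sequence[float]
) -> pd.DataFrame:
    """Search time and sampling frequency as functions of the decoy load.

    Returns one row per ``N_ns`` value with columns
    ``n_ns, p_sb, tau_search, t_sampling, f_sampling``.  For positive
    ``k_ns`` and ``tau_ns`` the search time increases and the sampling
    frequency decreases strictly with ``N_ns``.
    """
    rows = []
    for n_ns in n_ns_grid:
        p = params.replace(n_ns=float(n_ns))
        rows.append(
            {
                "n_ns": float(n_ns),
                "p_sb": p_sb(p),
                "tau_search": tau_search(p),
                "t_sampling": sampling_interval(p),
                "f_sampling": sampling_frequency(p),
            }
        )
    return pd.DataFrame(rows)
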