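"""Subharmonic structure of cluster tempi.

If tapping tempo is governed by an internal oscillator with base period T
(~4 Hz for T near 250 ms), cluster mean ITIs should sit near integer
multiples nT.  :func:`harmonic_fit` measures how closely a set of cluster
means does so; :func:`estimate_base_period` finds the T on a grid that
minimizes the mean absolute deviation (MAD) from the nearest allowed
multiple.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from tempoclust.datatypes import PAPER_MULTIPLIERS


@dataclass
class HarmonicFit:
    """Nearest-multiple decomposition of cluster mean tempi.

    ``deviations[i] = |cluster_means[i] - chosen_n[i] * T|`` with ``chosen_n``
    minimizing the deviation over ``allowed_n`` (ties broken toward the
    smaller multiplier).  ``mad`` is the mean deviation; ``mad_ms`` and
    ``deviations_ms`` are integer-rounded for reporting.
    """

    T: float
    allowed_n: tuple[int, ...]
    cluster_means: tuple[float, ...]
    chosen_n: tuple[int, ...]
    deviations: tuple[float, ...]
    mad: float
    dev_min: float
    dev_max: float

    @property
    def mad_ms(self) -> int:
        return int(round(self.mad))

    @property
    def deviations_ms(self) -> tuple[int, ...]:
        return tuple(int(round(d)) for d in self.deviations)

    def as_dict(self) -> dict:
        return {
            "base_period_ms": self.T,
            "allowed_multipliers": list(self.allowed_n),
            "cluster_means_ms": list(self.cluster_means),
            "chosen_multipliers": list(self.chosen_n),
            "deviations_ms": list(self.deviations),
            "mad_ms": self.mad,
            "mad_rounded_ms": self.mad_ms,
            "dev_min_ms": self.dev_min,
            "dev_max_ms": self.dev_max,
        }


def harmonic_fit(
    cluster_means: Sequence[float],
    T: float = 251.0,
    allowed_n: Sequence[int] = PAPER_MULTIPLIERS,
) -> HarmonicFit:
    """Deviation of each cluster mean from its nearest allowed multiple of T."""
    if T <= 0:
        raise ValueError("base period T must be positive")
    ns = sorted(set(int(n) for n in allowed_n))
    if not ns or ns[0] < 1:
        raise ValueError("allowed_n must be a non-empty set of positive integers")
    means = [float(m) for m in cluster_means]
    if any(m <= 0 for m in means):
        raise ValueError("cluster means must be positive")

    chosen, devs = [], []
    for m in means:
        # ns ascending, strict < : ties resolve to the smaller multiplier
        best = min(ns, key=lambda n: (abs(m - n * T), n))
        chosen.append(best)
        devs.append(abs(m - best * T))
    devs_arr = np.asarray(devs)
    return HarmonicFit(
        T=float(T),
        allowed_n=tuple(ns),
        cluster_means=tuple(means),
        chosen_n=tuple(chosen),
        deviations=tuple(devs),
        mad=float(devs_arr.mean()),
        dev_min=float(devs_arr.min()),
        dev_max=float(devs_arr.max()),
    )


def estimate_base_period(
    cluster_means: Sequence[float],
    allowed_n: Sequence[int] = PAPER_MULTIPLIERS,
    T_grid: tuple[float, float, float] = (200.0, 300.0, 0.5),
) -> tuple[float, HarmonicFit]:
    """Grid search for the base period minimizing the MAD; ties -> smallest T."""
    lo, hi, step = T_grid
    if step <= 0 or hi < lo:
        raise ValueError("invalid grid: need lo <= hi and step > 0")
    # include hi when it lands on the grid
    n_steps = int(np.floor((hi - lo) / step + 1e-9)) + 1
    best_T, best_fit = None, None
    for i in range(n_steps):
        T = lo + i * step
        fit = harmonic_fit(cluster_means, T=T, allowed_n=allowed_n)
        if best_fit is None or fit.mad < best_fit.mad - 1e-12:
            best_T, best_fit = T, fit
    return float(best_T), best_fit
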