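"""Run-trajectory diagnostics: heating-cycle counting and the
variance-versus-temperature profile.

A healthy biphasic run alternates between cooling stretches (score
climbing, temperature falling) and heating stretches (reversal phases);
each maximal run of consecutive reversal iterations counts as one
heating cycle.  On rugged landscapes explored with a blend of mutation
counts, the batch score variance typically peaks at an intermediate
temperature — the signature the controller exploits to balance
exploration and exploitation.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np

from .core import IterationRecord, OptimizerPhase

__all__ = ["count_heating_cycles", "sigma2_vs_temperature_peak"]


def count_heating_cycles(records: Sequence[IterationRecord]) -> int:
    """Number of maximal consecutive runs of the reversal (heating) phase."""
    cycles = 0
    in_heat = False
    for r in records:
        heating = r.phase is OptimizerPhase.PHASE_TRANSITION_REVERSAL
        if heating and not in_heat:
            cycles += 1
        in_heat = heating
    return cycles


def sigma2_vs_temperature_peak(
    records: Sequence[IterationRecord],
    n_bins: int = 12,
    transient_cutoff: int = 0,
) -> tuple[np.ndarray, np.ndarray, bool]:
    """Bin batch variance by log-temperature and locate its peak.

    Returns (bin-center temperatures, mean sigma^2 per occupied bin, and
    whether the argmax falls strictly inside the binned grid — i.e. the
    variance peaks at an intermediate temperature rather than at the
    hottest or coldest visited).
    """
    recs = [r for r in records if r.t > transient_cutoff]
    if len(recs) < n_bins:
        raise ValueError("not enough post-transient iterations to bin")
    T = np.array([r.T for r in recs])
    s2 = np.array([r.sigma**2 for r in recs])
    edges = np.linspace(np.log(T.min()) - 1e-12, np.log(T.max()) + 1e-12, n_bins + 1)
    which = np.clip(np.digitize(np.log(T), edges) - 1, 0, n_bins - 1)
    centers, means = [], []
    for b in range(n_bins):
        mask = which == b
        if mask.any():
            centers.append(np.exp(0.5 * (edges[b] + edges[b + 1])))
            means.append(s2[mask].mean())
    centers_arr = np.array(centers)
    means_arr = np.array(means)
    peak = int(means_arr.argmax())
    interior = 0 < peak < len(means_arr) - 1
    return centers_arr, means_arr, bool(interior)
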