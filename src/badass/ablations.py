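"""Ablated optimizer variants and an exhaustive-search oracle.

Two components make the optimizer more than simulated annealing: the
biphasic temperature controller (cooling/heating cycles driven by score
set points) and the dynamic per-mutation energies (re-estimated from all
scored sequences every iteration).  Each ablation disables exactly one of
them via a strategy flag on the shared main loop:

* ``pure_cooling`` — monotone ``T_{t+1} = alpha * T_t``; classical
  simulated-annealing-style cooling with no reheating.
* ``static_energies`` — q frozen at its post-initialization value; new
  scores never feed back into the sampler.
* ``full`` — the unmodified optimizer (identical to :func:`badass.core.run`).

:func:`exhaustive_search` enumerates and scores an entire k-mutation
shell, practical only at desk scale, providing ground-truth rankings for
tests.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import BadassConfig, RunResult, run
from .oracles import FitnessOracle
from .sequence_space import ReferenceSequence, VariantSpec, enumerate_shell, shell_size

__all__ = ["AblationConfig", "run_ablation", "exhaustive_search", "DEFAULT_ENUMERATION_CAP"]

DEFAULT_ENUMERATION_CAP = 1_000_000

_MODES = ("full", "pure_cooling", "static_energies")


@dataclass(frozen=True)
class AblationConfig:
    mode: str
    config: BadassConfig

    def __post_init__(self) -> None:
        if self.mode not in _MODES:
            raise ValueError(f"mode must be one of {_MODES}; got {self.mode!r}")


def run_ablation(
    oracle: FitnessOracle, ref: ReferenceSequence, ablation: AblationConfig
) -> RunResult:
    """Run the shared loop with the ablated component disabled."""
    return run(
        oracle,
        ref,
        ablation.config,
        update_energies=ablation.mode != "static_energies",
        biphasic=ablation.mode != "pure_cooling",
    )


def exhaustive_search(
    oracle: FitnessOracle,
    ref: ReferenceSequence,
    k: int,
    cap: int = DEFAULT_ENUMERATION_CAP,
    chunk: int = 8192,
) -> list[tuple[VariantSpec, float]]:
    """Score every variant of the exact-k shell, ranked by descending score.

    Ties are broken by the canonical mutation key, so the ranking is
    invariant to enumeration order.
    """
    size = shell_size(ref.L, k)
    if size > cap:
        raise ValueError(
            f"shell S_{k} for L={ref.L} holds {size} variants, above the cap of "
            f"{cap}; use a smaller L or k (or raise cap explicitly)"
        )
    variants: list[VariantSpec] = []
    scores: list[float] = []
    buf: list[VariantSpec] = []
    for v in enumerate_shell(ref, k):
        buf.append(v)
        if len(buf) == chunk:
            scores.extend(np.asarray(oracle.score_batch(buf), dtype=float))
            variants.extend(buf)
            buf = []
    if buf:
        scores.extend(np.asarray(oracle.score_batch(buf), dtype=float))
        variants.extend(buf)
    ranked = sorted(
        zip(variants, scores),
        key=lambda vs: (-vs[1], vs[0].canonical_key(ref)),
    )
    return [(v, float(s)) for v, s in ranked]
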