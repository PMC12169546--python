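"""Ranking, diversity metrics, and file output for optimization runs.

The metric suite mirrors what practitioners report for in-silico design
campaigns: the percentage of top-ranked sequences scoring above the
reference (wildtype), the scores at ranks 1 / 100 / 1,000, and the number
of distinct mutations and distinct mutated sites across the top set —
the latter two capturing how much diversity the optimizer retained while
chasing high scores.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import matplotlib
import numpy as np
import pandas as pd

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402

from .core import RunResult, ScoredSequence
from .oracles import AdditiveLandscape, landscape_to_json
from .sequence_space import ReferenceSequence, apply_mutations, parse_variant_string

__all__ = [
    "RankedResults",
    "DiversityMetrics",
    "rank_sequences",
    "diversity_metrics",
    "write_outputs",
    "read_designs_csv",
    "plot_traces",
    "run_log_frame",
]


@dataclass
class RankedResults:
    """Sequences sorted by (score desc, canonical key asc); no duplicates."""

    entries: list[ScoredSequence]
    top_n: int
    truncated_to_available: bool = False

    def __len__(self) -> int:
        return len(self.entries)


@dataclass
class DiversityMetrics:
    pct_better_than_ref: float
    best_score: float
    score_at_rank_100: float | None
    score_at_rank_1000: float | None
    unique_mutations: int
    unique_sites: int
    top_n: int
    n_counted: int = 0


def rank_sequences(result: RunResult, top_n: int) -> RankedResults:
    """Deterministic top-n ranking with canonical-key tie-break."""
    if top_n < 1:
        raise ValueError("top_n must be >= 1")
    ordered = sorted(result.sequences.values(), key=lambda s: (-s.score, s.key))
    truncated = top_n > len(ordered)
    return RankedResults(
        entries=ordered[: min(top_n, len(ordered))],
        top_n=top_n,
        truncated_to_available=truncated,
    )


def diversity_metrics(ranked: RankedResults, ref_score: float) -> DiversityMetrics:
    """Score and diversity summary of a ranked design set.

    ``pct_better_than_ref`` uses a strict inequality on the raw oracle
    score scale.  Rank-100/1000 scores are reported as absent (None) when
    fewer sequences exist.
    """
    if len(ranked) == 0:
        raise ValueError("ranked results are empty")
    scores = np.array([e.score for e in ranked.entries])
    mutations = {m for e in ranked.entries for m in e.variant.mutations}
    sites = {m.site for m in mutations}
    n = len(ranked)
    return DiversityMetrics(
        pct_better_than_ref=100.0 * float((scores > ref_score).sum()) / n,
        best_score=float(scores[0]),
        score_at_rank_100=float(scores[99]) if n >= 100 else None,
        score_at_rank_1000=float(scores[999]) if n >= 1000 else None,
        unique_mutations=len(mutations),
        unique_sites=len(sites),
        top_n=ranked.top_n,
        n_counted=n,
    )


def run_log_frame(result: RunResult) -> pd.DataFrame:
    """One row per iteration: t, mu, sigma, T, phase, new_seqs, unique_total."""
    return pd.DataFrame(
        {
            "t": [r.t for r in result.records],
            "mu": [r.mu for r in result.records],
            "sigma": [r.sigma for r in result.records],
            "T": [r.T for r in result.records],
            "phase": [r.phase.value for r in result.records],
            "new_seqs": [r.n_new for r in result.records],
            "unique_total": [r.unique_total for r in result.records],
        }
    )


def write_outputs(
    result: RunResult,
    ranked: RankedResults,
    metrics: DiversityMetrics,
    out_dir,
    landscape: AdditiveLandscape | None = None,
) -> dict[str, Path]:
    """Write the full artifact set for a run; byte-identical across reruns
    with the same seed and configuration.

    Files: designs.fasta, designs.csv, run_log.csv, metrics.json,
    config.json, and landscape.json when a synthetic landscape is given.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    ref = result.ref
    paths: dict[str, Path] = {}

    fasta = out / "designs.fasta"
    with open(fasta, "w") as fh:
        for rank, e in enumerate(ranked.entries, start=1):
            header = e.key if e.key else "reference"
            fh.write(f">{header} score={e.score!r} rank={rank}\n")
            fh.write(apply_mutations(ref, e.variant) + "\n")
    paths["designs.fasta"] = fasta

    designs = pd.DataFrame(
        {
            "rank": np.arange(1, len(ranked) + 1),
            "key": [e.key for e in ranked.entries],
            "k": [e.variant.k for e in ranked.entries],
            "score": [repr(e.score) for e in ranked.entries],
            "first_iteration": [e.first_iteration for e in ranked.entries],
        }
    )
    paths["designs.csv"] = out / "designs.csv"
    designs.to_csv(paths["designs.csv"], index=False)

    paths["run_log.csv"] = out / "run_log.csv"
    log = run_log_frame(result)
    log["mu"] = log["mu"].map(repr)
    log["sigma"] = log["sigma"].map(repr)
    log["T"] = log["T"].map(repr)
    log.to_csv(paths["run_log.csv"], index=False)

    paths["metrics.json"] = out / "metrics.json"
    with open(paths["metrics.json"], "w") as fh:
        json.dump(asdict(metrics), fh, indent=1, sort_keys=True)

    paths["config.json"] = out / "config.json"
    cfg = asdict(result.config)
    cfg["k_mixture"] = {str(k): v for k, v in cfg["k_mixture"].items()}
    cfg["reference"] = {"id": ref.id, "residues": ref.residues}
    cfg["n_unique_evaluations"] = result.n_unique_evaluations
    with open(paths["config.json"], "w") as fh:
        json.dump(cfg, fh, indent=1, sort_keys=True)

    if landscape is not None:
        paths["landscape.json"] = out / "landscape.json"
        with open(paths["landscape.json"], "w") as fh:
            json.dump(landscape_to_json(landscape), fh, indent=1)

    return paths


def read_designs_csv(path, ref: ReferenceSequence) -> RankedResults:
    """Round-trip loader for designs.csv."""
    df = pd.read_csv(path, keep_default_na=False)
    entries = [
        ScoredSequence(
            key=str(row.key),
            variant=parse_variant_string(str(row.key), ref),
            score=float(row.score),
            first_iteration=int(row.first_iteration),
        )
        for row in df.itertuples()
    ]
    return RankedResults(entries=entries, top_n=len(entries))


def plot_traces(
    run_log: pd.DataFrame,
    out_dir,
    mu_high: float | None = None,
    mu_low: float | None = None,
    transient_cutoff: int = 100,
) -> dict[str, Path]:
    """Diagnostic figures for a run log.

    (a) batch mean with a 1.96-sigma band versus iteration, with the set
    points and phase-transition markers; (b) batch mean and variance
    versus the sampling temperature, post-transient iterations only.
    """
    if len(run_log) < 2:
        raise ValueError("run log must contain at least 2 iterations")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    t = run_log["t"].to_numpy()
    mu = run_log["mu"].to_numpy(dtype=float)
    sigma = run_log["sigma"].to_numpy(dtype=float)

    fig, ax = plt.subplots(figsize=(7, 4))
    ax.plot(t, mu, lw=1.2, label="batch mean")
    ax.fill_between(t, mu - 1.96 * sigma, mu + 1.96 * sigma, alpha=0.25, label="±1.96σ")
    for level, name in ((mu_high, "μ_high"), (mu_low, "μ_low")):
        if level is not None:
            ax.axhline(level, ls="--", lw=0.8, color="gray")
            ax.annotate(name, (t[0], level), fontsize=8)
    phases = run_log["phase"].to_numpy()
    changes = np.nonzero(phases[1:] != phases[:-1])[0] + 1
    for c in changes:
        ax.axvline(t[c], color="red", lw=0.5, alpha=0.5)
    ax.set_xlabel("iteration")
    ax.set_ylabel("fitness score")
    ax.legend(loc="lower right", fontsize=8)
    paths["score_trace.png"] = out / "score_trace.png"
    fig.savefig(paths["score_trace.png"], dpi=120, bbox_inches="tight")
    plt.close(fig)

    post = run_log[run_log["t"] > transient_cutoff]
    if len(post) == 0:
        post = run_log
    fig, axes = plt.subplots(1, 2, figsize=(9, 3.5))
    axes[0].scatter(post["T"], post["mu"], s=8)
    axes[0].set_xlabel("temperature T")
    axes[0].set_ylabel("batch mean μ")
    axes[0].set_xscale("log")
    axes[1].scatter(post["T"], post["sigma"].to_numpy(dtype=float) ** 2, s=8)
    axes[1].set_xlabel("temperature T")
    axes[1].set_ylabel("batch variance σ²")
    axes[1].set_xscale("log")
    fig.tight_layout()
    paths["order_parameters.png"] = out / "order_parameters.png"
    fig.savefig(paths["order_parameters.png"], dpi=120, bbox_inches="tight")
    plt.close(fig)

    return paths
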