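"""Seed ensembles, channeling statistics, the channel occupancy histogram
and state comparison.

An ensemble runs one trajectory per seed (seeds derive independently from a
base seed, so results do not depend on execution order), classifies each as
reached / escaped / blocked, and aggregates fractions and travel times.
The occupancy histogram projects sampled indole midpoints onto the channel
axis and bins the arc-length coordinate into equal sections (72 by default,
spanning the α-active site to the β-active site).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .engine import (
    BDParams,
    OUTCOME_BLOCKED,
    OUTCOME_ESCAPED,
    OUTCOME_INVALID,
    OUTCOME_REACHED,
    TrajectoryResult,
    run_trajectory,
)
from .model import CGProtein, IndoleLigand

__all__ = [
    "EnsembleStats", "OccupancyHistogram", "EnsembleError",
    "trajectory_seed", "run_ensemble", "occupancy_histogram", "compare_states",
]


class EnsembleError(RuntimeError):
    """No valid trajectory in the ensemble."""


@dataclass
class EnsembleStats:
    """Aggregated outcome statistics over the valid trajectories of one
    ensemble (invalid starts are excluded and counted separately)."""

    n_trajectories: int
    fraction_reached: float
    fraction_escaped: float
    fraction_blocked: float
    mean_travel_time_ns: Optional[float]
    travel_time_sd_ns: Optional[float]
    n_invalid_start: int = 0
    outcomes: tuple[str, ...] = field(default=(), repr=False)
    travel_times_ns: tuple[float, ...] = field(default=(), repr=False)

    @classmethod
    def from_results(cls, results: Sequence[TrajectoryResult]) -> "EnsembleStats":
        valid = [r for r in results if r.outcome != OUTCOME_INVALID]
        n_invalid = len(results) - len(valid)
        if not valid:
            raise EnsembleError("every trajectory had an invalid start")
        n = len(valid)
        counts = {k: sum(r.outcome == k for r in valid)
                  for k in (OUTCOME_REACHED, OUTCOME_ESCAPED, OUTCOME_BLOCKED)}
        times = [r.travel_time_ns for r in valid if r.outcome == OUTCOME_REACHED]
        mean_t = float(np.mean(times)) if times else None
        sd_t = float(np.std(times, ddof=1)) if len(times) > 1 else (0.0 if times else None)
        return cls(
            n_trajectories=n,
            fraction_reached=counts[OUTCOME_REACHED] / n,
            fraction_escaped=counts[OUTCOME_ESCAPED] / n,
            fraction_blocked=counts[OUTCOME_BLOCKED] / n,
            mean_travel_time_ns=mean_t,
            travel_time_sd_ns=sd_t,
            n_invalid_start=n_invalid,
            outcomes=tuple(r.outcome for r in valid),
            travel_times_ns=tuple(times),
        )


@dataclass
class OccupancyHistogram:
    """Counts of sampled indole midpoints per equal-length channel section."""

    boundaries: np.ndarray          # (n_sections + 1,) arc-length edges, Å
    counts: np.ndarray              # (n_sections,) int
    clamped_low: int                # samples projecting before the α end
    clamped_high: int               # samples projecting past the β end

    @property
    def n_sections(self) -> int:
        return len(self.counts)

    @property
    def total_samples(self) -> int:
        return int(self.counts.sum())

    @property
    def fractions(self) -> np.ndarray:
        return self.counts / max(1, self.total_samples)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "section_index": np.arange(1, self.n_sections + 1),
            "arc_start_A": self.boundaries[:-1],
            "arc_end_A": self.boundaries[1:],
            "count": self.counts,
            "fraction": self.fractions,
        })


def trajectory_seed(base_seed: int, index: int) -> int:
    """Deterministic per-trajectory seed (< 2**31) derived from the base
    seed and the 1-based trajectory index."""
    return int(np.random.SeedSequence([base_seed, index]).generate_state(1)[0] & 0x7FFFFFFF)


def run_ensemble(protein: CGProtein, indole: IndoleLigand, params: BDParams,
                 n_seeds: int, base_seed: int = 0, keep_samples: bool = False,
                 ) -> tuple[EnsembleStats, pd.DataFrame, list[np.ndarray]]:
    """Run ``n_seeds`` independent trajectories and aggregate their outcomes.

    Returns (stats, per-trajectory table, list of sample arrays).  The
    per-trajectory table has columns seed, outcome, travel_time_ns, n_steps.
    """
    if n_seeds < 1:
        raise ValueError("n_seeds must be >= 1")
    results = []
    samples: list[np.ndarray] = []
    for k in range(1, n_seeds + 1):
        res = run_trajectory(protein, indole, params, trajectory_seed(base_seed, k))
        if keep_samples and res.samples is not None:
            samples.append(res.samples)
        res.samples = None
        results.append(res)
    table = pd.DataFrame({
        "seed": [r.seed for r in results],
        "outcome": [r.outcome for r in results],
        "travel_time_ns": [r.travel_time_ns for r in results],
        "n_steps": [r.n_steps for r in results],
    })
    return EnsembleStats.from_results(results), table, samples


def _project_onto_polyline(points: np.ndarray, axis: np.ndarray):
    """Arc-length coordinate of each point's nearest position on the
    polyline, plus the unclamped coordinate on the nearest segment (used to
    detect projections falling off either end)."""
    seg_a = axis[:-1]
    seg_v = axis[1:] - axis[:-1]
    seg_len = np.linalg.norm(seg_v, axis=1)
    if np.all(seg_len == 0):
        raise ValueError("degenerate channel axis (zero length)")
    arc0 = np.concatenate([[0.0], np.cumsum(seg_len)])

    # distances of every point to every segment
    diff = points[:, None, :] - seg_a[None, :, :]              # (N, S, 3)
    denom = np.where(seg_len == 0, 1.0, seg_len ** 2)
    t_raw = np.einsum("nsk,sk->ns", diff, seg_v) / denom       # unclamped
    t = np.clip(t_raw, 0.0, 1.0)
    proj = seg_a[None] + t[..., None] * seg_v[None]
    d2 = np.sum((points[:, None, :] - proj) ** 2, axis=2)
    nearest = np.argmin(d2, axis=1)
    idx = np.arange(len(points))
    s = arc0[nearest] + t[idx, nearest] * seg_len[nearest]
    s_raw = arc0[nearest] + t_raw[idx, nearest] * seg_len[nearest]
    return s, s_raw, arc0[-1]


def occupancy_histogram(samples, protein: CGProtein, n_sections: int = 72,
                        ) -> OccupancyHistogram:
    """Bin sampled indole midpoints into equal arc-length channel sections.

    ``samples`` is one array or a list of arrays with columns
    (time_ns, x1, y1, z1, x2, y2, z2) as produced by the propagator; the
    representative indole position is the two-bead midpoint.  Midpoints
    projecting beyond either end of the axis are clamped into the end
    sections and counted separately.
    """
    if isinstance(samples, (list, tuple)):
        if not samples:
            raise ValueError("no samples given")
        samples = np.vstack(samples)
    samples = np.asarray(samples, dtype=float)
    if samples.ndim != 2 or samples.shape[1] != 7 or len(samples) == 0:
        raise ValueError("samples must be a non-empty (N, 7) array")
    mid = 0.5 * (samples[:, 1:4] + samples[:, 4:7])
    s, s_raw, length = _project_onto_polyline(mid, protein.channel_axis)
    if length <= 0:
        raise ValueError("degenerate channel axis (zero length)")
    edges = np.linspace(0.0, length, n_sections + 1)
    bins = np.minimum((s / length * n_sections).astype(int), n_sections - 1)
    counts = np.bincount(bins, minlength=n_sections)
    return OccupancyHistogram(
        boundaries=edges,
        counts=counts,
        clamped_low=int(np.sum(s_raw < 0.0)),
        clamped_high=int(np.sum(s_raw > length)),
    )


def write_samples_xyz(samples: np.ndarray, path) -> None:
    """Write sampled indole positions as an XYZ trajectory (two pseudo-atoms
    per frame, comment line = time in ns)."""
    samples = np.asarray(samples, dtype=float)
    with open(path, "w") as fh:
        for row in samples:
            fh.write(f"2\ntime_ns {row[0]:.6f}\n")
            fh.write(f"P {row[1]:.4f} {row[2]:.4f} {row[3]:.4f}\n")
            fh.write(f"B {row[4]:.4f} {row[5]:.4f} {row[6]:.4f}\n")


def compare_states(stats: Sequence[tuple[str, EnsembleStats]],
                   n_boot: int = 1000, seed: int = 0) -> pd.DataFrame:
    """Rank conformational states by channeling success fraction.

    Returns a table sorted by ``fraction_reached`` (descending; ties keep
    the input order) with percentile bootstrap confidence intervals from
    resampling trajectories (``n_boot`` replicates).  The intervals are a
    package addition — an uncertainty label on the stochastic fractions.
    """
    if len(stats) < 2:
        raise ValueError("need at least two states to compare")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    rows = []
    for label, st in stats:
        outcomes = np.array([o == "reached" for o in st.outcomes], dtype=float)
        n = len(outcomes)
        boot = rng.choice(outcomes, size=(n_boot, n), replace=True).mean(axis=1)
        lo, hi = np.percentile(boot, [2.5, 97.5])
        rows.append({
            "state": label,
            "n": n,
            "fraction_reached": st.fraction_reached,
            "ci_low": float(lo),
            "ci_high": float(hi),
            "fraction_escaped": st.fraction_escaped,
            "fraction_blocked": st.fraction_blocked,
            "mean_travel_time_ns": st.mean_travel_time_ns,
        })
    out = pd.DataFrame(rows)
    return (out.sort_values("fraction_reached", ascending=False, kind="stable")
            .reset_index(drop=True))
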