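"""Derivative-based checkpoint selection and early stopping.

During a long training run, the loss and F-measure of checkpointed
models are evaluated every ``eval_period`` iterations, giving two series
on a regular iteration grid.  A checkpoint is worth considering once the
loss has stopped moving: the first grid point where both the first and
second finite differences of the loss stay inside ``[-epsilon,
epsilon]`` for a run of consecutive evaluations opens the selection
window (``k_s``).  The window closes (``k_e``) when the F-measure
derivatives similarly settle inside ``[-tau, tau]`` — at which point
training can stop early — or at the last evaluated iteration otherwise.
The selected checkpoint is the best-F-measure model inside the window,
ties broken toward the largest iteration count.

Derivatives are forward differences per grid step (not per raw
iteration), matching the resolution at which the series is observed;
``epsilon`` and ``tau`` are therefore bounds on the change per
evaluation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "TrainingTrace",
    "SelectionResult",
    "finite_derivatives",
    "find_stable_window",
    "early_stop_check",
    "select_model",
    "select_from_trace",
]


@dataclass
class TrainingTrace:
    """Loss and F-measure of checkpoints on a regular iteration grid."""

    iterations: np.ndarray
    loss: np.ndarray
    f_measure: np.ndarray

    def __post_init__(self) -> None:
        self.iterations = np.asarray(self.iterations, dtype=int)
        self.loss = np.asarray(self.loss, dtype=float)
        self.f_measure = np.asarray(self.f_measure, dtype=float)
        if not (len(self.iterations) == len(self.loss) == len(self.f_measure)):
            raise ValueError("iteration, loss and F-measure series must align")
        if np.any(np.diff(self.iterations) <= 0):
            raise ValueError("iterations must be strictly increasing")
        if np.any(self.loss < 0):
            raise ValueError("losses must be non-negative")
        if np.any((self.f_measure < 0) | (self.f_measure > 1)):
            raise ValueError("F-measures must lie in [0, 1]")

    def __len__(self) -> int:
        return len(self.iterations)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"iteration": self.iterations, "loss": self.loss, "f_measure": self.f_measure}
        )

    @classmethod
    def from_csv(cls, path: str) -> "TrainingTrace":
        df = pd.read_csv(path)
        return cls(df["iteration"].values, df["loss"].values, df["f_measure"].values)


@dataclass
class SelectionResult:
    ks: int            # window-opening iteration (loss stabilised)
    ke: int            # window-closing iteration (early stop or last)
    early_stopped: bool
    i_star: int        # selected checkpoint iteration

    def __post_init__(self) -> None:
        if not self.ks <= self.i_star <= self.ke:
            raise ValueError("selected iteration must lie inside [ks, ke]")


def finite_derivatives(series: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Forward first and second differences per grid step.

    ``first[i] = s[i+1] - s[i]`` (length n-1) and ``second[i] =
    first[i+1] - first[i]`` (length n-2), both aligned to the left point.
    """
    s = np.asarray(series, dtype=float)
    if s.size < 3:
        raise ValueError("need at least 3 evaluations for both derivatives")
    first = np.diff(s)
    second = np.diff(first)
    return first, second


def find_stable_window(
    first: np.ndarray,
    second: np.ndarray,
    bound: float,
    run_length: int = 3,
    start_index: int = 0,
) -> int | None:
    """Index of the first grid point (at or after ``start_index``) opening
    a run of ``run_length`` consecutive evaluations with both derivatives
    inside ``[-bound, bound]``; None when the series never settles."""
    if run_length < 1:
        raise ValueError("run_length must be >= 1")
    n = len(second)  # second is the shorter, index-aligned series
    ok = (np.abs(first[:n]) <= bound) & (np.abs(second) <= bound)
    run = 0
    for i in range(start_index, n):
        run = run + 1 if ok[i] else 0
        if run >= run_length:
            return i - run_length + 1
    return None


def early_stop_check(
    first: np.ndarray,
    second: np.ndarray,
    bound: float,
    run_length: int = 3,
    start_index: int = 0,
) -> int | None:
    """Same run detection applied to the F-measure derivatives; the caller
    falls back to the final iteration when this returns None."""
    return find_stable_window(first, second, bound, run_length, start_index)


def select_model(trace: TrainingTrace, ks: int, ke: int) -> int:
    """Best-F-measure checkpoint in the closed window [ks, ke]; ties go to
    the largest iteration."""
    mask = (trace.iterations >= ks) & (trace.iterations <= ke)
    if not mask.any():
        raise ValueError(f"empty selection window [{ks}, {ke}]")
    its = trace.iterations[mask]
    fs = trace.f_measure[mask]
    best = fs.max()
    return int(its[fs == best].max())


def select_from_trace(
    trace: TrainingTrace,
    epsilon: float = 0.003,
    tau: float = 0.1,
    run_length: int = 3,
) -> SelectionResult:
    """Full pipeline: derivatives -> stable-loss window start -> F-measure
    early stop (or last iteration) -> best checkpoint in the window.

    When the loss never stabilises the window opens at the final
    evaluation, so the most-trained checkpoint is returned.
    """
    w1, w2 = finite_derivatives(trace.loss)
    i1, i2 = finite_derivatives(trace.f_measure)
    ks_idx = find_stable_window(w1, w2, epsilon, run_length)
    ks = int(trace.iterations[ks_idx]) if ks_idx is not None else int(trace.iterations[-1])
    # the F-measure stability search only starts once the loss has settled
    ke_idx = early_stop_check(i1, i2, tau, run_length, start_index=ks_idx or 0)
    early = ke_idx is not None
    if early:
        # training halts at the evaluation where the run is confirmed: the
        # last of run_length stable points plus the two-evaluation lookahead
        # the second difference needs
        ke = int(trace.iterations[min(ke_idx + run_length + 1, len(trace) - 1)])
    else:
        ke = int(trace.iterations[-1])
    if ke < ks:
        ke = int(trace.iterations[-1])
        early = False
    i_star = select_model(trace, ks, ke)
    return SelectionResult(ks=ks, ke=ke, early_stopped=early, i_star=i_star)
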