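"""Trial-level quality control and reduction to the critical time window.

Trials whose electrooculogram exceeds a peak-amplitude threshold (strictly
greater than, default 100 microvolts) are rejected; each retained trial is
then reduced to its per-vertex mean current density over the analysis window
(default 150-250 ms, endpoints inclusive).  No baseline correction is applied
at the current-density stage.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from cortexlrp.synthdata import TrialSet

__all__ = ["WindowedTrialSet", "reject_by_eog", "window_average"]


@dataclass
class WindowedTrialSet:
    """Retained trials reduced to one value per vertex.

    data : (n_retained, n_vertices) mean current densities over the window
    subject_id, group : labels carried over from the retained trials
    rejected_trials : indices (into the original TrialSet) that were dropped
    window_ms : the averaging window actually used
    """

    data: np.ndarray
    subject_id: np.ndarray
    group: np.ndarray
    rejected_trials: np.ndarray
    window_ms: tuple[float, float]

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    def labels(self) -> np.ndarray:
        return (self.group == "patient").astype(np.int64)


def reject_by_eog(trials: TrialSet, threshold_uv: float = 100.0) -> np.ndarray:
    """Mask of trials to retain: peak |EOG| must not exceed the threshold.

    A trial is rejected iff max |eog(t)| > threshold (strict, so a peak of
    exactly the threshold is retained).  If the EOG channel is missing, all
    trials are retained with a warning.
    """
    if threshold_uv <= 0:
        raise ValueError("threshold must be positive")
    if trials.eog is None or trials.eog.size == 0:
        warnings.warn("no EOG channel; retaining all trials")
        return np.ones(trials.n_trials, dtype=bool)
    peak = np.abs(trials.eog).max(axis=1)
    return peak <= threshold_uv


def window_average(
    trials: TrialSet,
    t_start_ms: float = 150.0,
    t_end_ms: float = 250.0,
    retained: np.ndarray | None = None,
) -> WindowedTrialSet:
    """Average each retained trial over the window (inclusive endpoints).

    The window must lie inside the epoch; samples s with
    t_start <= t(s) <= t_end contribute with equal weight.
    """
    if t_start_ms >= t_end_ms:
        raise ValueError("t_start_ms must be < t_end_ms")
    t = trials.time_ms
    if t_start_ms < t[0] or t_end_ms > t[-1]:
        raise ValueError(
            f"window [{t_start_ms}, {t_end_ms}] ms outside epoch [{t[0]}, {t[-1]}] ms"
        )
    if retained is None:
        retained = trials.retained
    retained = np.asarray(retained, dtype=bool)

    in_win = (t >= t_start_ms) & (t <= t_end_ms)
    keep = np.flatnonzero(retained)
    data = trials.data[keep][:, :, in_win].mean(axis=2)
    return WindowedTrialSet(
        data=np.asarray(data, dtype=np.float64),
        subject_id=trials.subject_id[keep],
        group=trials.group[keep],
        rejected_trials=np.flatnonzero(~retained),
        window_ms=(t_start_ms, t_end_ms),
    )
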