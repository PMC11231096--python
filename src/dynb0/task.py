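"""Decision-making task events, hemodynamic response, and BOLD modulation.

Each trial: an offer appears; after 3-4 s the go-cue (frame moves); the
animal may respond within 1 s (probability ``p_respond``); a reward outcome
follows the response after 3.5-4.5 s; the next trial starts after a
3.5-4.5 s intertrial interval.

The HRF is a double-gamma with a configurable (fast, primate-like) peak; no
species-specific parameter set is assumed, so the shape is a knob.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import stats

REGRESSOR_NAMES = ("offer", "action_onset", "motor_response", "outcome")


@dataclass
class EventList:
    """Per-trial onsets in seconds. NaN marks absent response/outcome."""

    offer: np.ndarray
    gocue: np.ndarray
    responded: np.ndarray  # bool
    response: np.ndarray   # NaN where not responded
    outcome: np.ndarray    # NaN where not responded

    @property
    def n_trials(self) -> int:
        return len(self.offer)

    def onsets(self, regressor: str) -> np.ndarray:
        """Event onsets for a named GLM regressor (all amplitudes one)."""
        if regressor == "offer":
            return self.offer
        if regressor == "action_onset":
            return self.gocue
        if regressor == "motor_response":
            return self.gocue[self.responded]
        if regressor == "outcome":
            return self.outcome[self.responded]
        raise ValueError(f"unknown regressor: {regressor!r}")

    def write_ev_files(self, out_dir: str | Path, duration: float = 0.1) -> list[Path]:
        """Write one 3-column text file (onset, duration, amplitude) per regressor."""
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        paths = []
        for name in REGRESSOR_NAMES:
            ons = self.onsets(name)
            arr = np.column_stack([ons, np.full_like(ons, duration), np.ones_like(ons)])
            p = out_dir / f"{name}.txt"
            np.savetxt(p, arr, fmt="%.4f")
            paths.append(p)
        return paths


def make_task_events(n_trials: int, p_respond: float, seed: int, start: float = 4.0) -> EventList:
    """Generate a legal trial sequence (see module docstring for timing)."""
    if n_trials < 1:
        raise ValueError("need at least one trial")
    if not 0.0 <= p_respond <= 1.0:
        raise ValueError("p_respond must be a probability")
    rng = np.random.default_rng(seed)
    offer = np.empty(n_trials)
    gocue = np.empty(n_trials)
    responded = np.zeros(n_trials, dtype=bool)
    response = np.full(n_trials, np.nan)
    outcome = np.full(n_trials, np.nan)
    t = start
    for i in range(n_trials):
        offer[i] = t
        gocue[i] = offer[i] + rng.uniform(3.0, 4.0)
        if rng.uniform() < p_respond:
            responded[i] = True
            response[i] = gocue[i] + rng.uniform(0.2, 0.9)
            outcome[i] = response[i] + rng.uniform(3.5, 4.5)
            t = outcome[i] + rng.uniform(3.5, 4.5)
        else:
            t = gocue[i] + 1.0 + rng.uniform(3.5, 4.5)
    return EventList(offer, gocue, responded, response, outcome)


@dataclass(frozen=True)
class HRFParams:
    """Double-gamma HRF: response peaking at ``peak`` s with an undershoot."""

    peak: float = 3.0
    undershoot: float = 7.0
    ratio: float = 0.167
    shape: float = 5.0  # gamma shape for both lobes

    def evaluate(self, t: np.ndarray) -> np.ndarray:
        """HRF samples, normalized to unit peak."""
        t = np.asarray(t, dtype=float)
        a = self.shape
        h = stats.gamma.pdf(t, a, scale=self.peak / (a - 1))
        h = h - self.ratio * stats.gamma.pdf(t, a, scale=self.undershoot / (a - 1))
        peak = h.max()
        return h / peak if peak > 0 else h


def convolve_events(
    onsets: np.ndarray,
    t_eval: np.ndarray,
    hrf: HRFParams,
    duration: float = 0.1,
    amplitudes: np.ndarray | None = None,
    dt: float = 0.02,
) -> np.ndarray:
    """Boxcar (constant ``duration``) events convolved with the HRF.

    Returns the convolved regressor sampled at ``t_eval`` (seconds).
    """
    onsets = np.asarray(onsets, dtype=float)
    onsets = onsets[np.isfinite(onsets)]
    if onsets.size == 0:
        return np.zeros_like(np.asarray(t_eval, dtype=float))
    if amplitudes is None:
        amplitudes = np.ones_like(onsets)
    t_max = max(float(np.max(t_eval)), float(onsets.max())) + 40.0
    grid = np.arange(0.0, t_max + dt, dt)
    stick = np.zeros_like(grid)
    n_box = max(1, int(round(duration / dt)))
    for on, amp in zip(onsets, amplitudes):
        i0 = int(round(on / dt))
        stick[i0:i0 + n_box] += amp
    kernel = HRFParams.evaluate(hrf, np.arange(0.0, 32.0, dt))
    conv = np.convolve(stick, kernel)[: grid.size] * dt / duration
    return np.interp(t_eval, grid, conv)


def bold_timecourses(
    events: EventList,
    T: int,
    tr: float,
    hrf: HRFParams,
) -> dict[str, np.ndarray]:
    """Convolved regressor value at each frame time, per regressor name."""
    t_eval = np.arange(T) * tr
    return {name: convolve_events(events.onsets(name), t_eval, hrf) for name in REGRESSOR_NAMES}


def object_at_frame(
    phantom,
    events: EventList,
    hrf: HRFParams,
    t: int,
    tr: float,
    T: int | None = None,
    _timecourses: dict[str, np.ndarray] | None = None,
) -> np.ndarray:
    """Ground-truth complex object at frame ``t`` (0-based).

    Voxels in each activation region have their magnitude modulated by
    ``1 + activation_map * x_reg(t)`` where ``x_reg`` is the convolved
    regressor driving that region; all other voxels are frame-independent.
    """
    n_frames = T if T is not None else t + 1
    if not 0 <= t < max(n_frames, t + 1) or t < 0:
        raise ValueError("frame index out of range")
    if T is not None and t >= T:
        raise ValueError("frame index out of range")
    tc = _timecourses or bold_timecourses(events, t + 1, tr, hrf)
    mod = np.ones_like(phantom.activation_map)
    for _, (mask, reg) in phantom.activation_regions.items():
        mod[mask] = 1.0 + phantom.activation_map[mask] * tc[reg][t]
    return phantom.grid * mod
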