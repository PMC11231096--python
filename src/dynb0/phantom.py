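"""Digital phantom, coil sensitivities and dynamic field-perturbation timelines.

The phantom is a piecewise-smooth ellipse-based object with named tissue
masks that double as anatomical ROIs, plus a fractional BOLD activation map
concentrated in two disjoint regions (a posterior "visual" region driven by
stimulus presentation and a "motor" region driven by motor responses).

Dynamic off-resonance is modeled as a spatially linear field
``df(x, y) = c0 + cx*x + cy*y`` (Hz, with x/y in FOV units), whose effect at
echo time TE is a global phase ``phi0 = 2*pi*c0*TE`` plus a net k-space
translation ``(dkx, dky) = (cx*TE, cy*TE)`` in grid units.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .fourier import image_grids

# mask name -> (angular/band predicate id) ; ring sectors of the cortical ribbon
_ROI_NAMES = (
    "frontal",
    "motor",
    "somatosensory",
    "parietal",
    "occipital",
    "temporal",
    "deep_gm",
    "ventricles",
)


@dataclass
class Phantom:
    """Multi-slice complex object with tissue masks and BOLD amplitude map.

    grid : (n_slices, n, n) complex image, arbitrary signal units.
    tissue_masks : name -> (n_slices, n, n) boolean masks (ROI set).
    activation_map : (n_slices, n, n) fractional BOLD amplitude (e.g. 0.02).
    activation_regions : region name -> (mask, driving regressor name).
    """

    grid: np.ndarray
    tissue_masks: dict[str, np.ndarray]
    activation_map: np.ndarray
    activation_regions: dict[str, tuple[np.ndarray, str]]
    support: np.ndarray = field(default=None)  # type: ignore[assignment]

    @property
    def n_slices(self) -> int:
        return self.grid.shape[0]

    @property
    def n(self) -> int:
        return self.grid.shape[-1]


@dataclass
class CoilSensitivities:
    """Smooth complex receive sensitivities, shared across slices.

    maps : (n_coils, n, n) complex, normalized so the root-sum-of-squares
    over coils is 1 everywhere (hence within [0.5, 2] over the object).
    """

    maps: np.ndarray

    @property
    def n_coils(self) -> int:
        return self.maps.shape[0]

    def rss(self) -> np.ndarray:
        return np.sqrt(np.sum(np.abs(self.maps) ** 2, axis=0))


@dataclass(frozen=True)
class FieldState:
    """Spatially linear off-resonance: c0 (Hz), cx, cy (Hz per FOV)."""

    c0: float = 0.0
    cx: float = 0.0
    cy: float = 0.0

    def to_kspace(self, te: float) -> tuple[float, float, float]:
        """(phi0 [rad], dkx, dky [grid units]) equivalent at echo time."""
        return (2.0 * np.pi * self.c0 * te, self.cx * te, self.cy * te)

    @classmethod
    def from_kspace(cls, phi0: float, dkx: float, dky: float, te: float) -> "FieldState":
        return cls(phi0 / (2.0 * np.pi * te), dkx / te, dky / te)

    def is_zero(self) -> bool:
        return self.c0 == 0.0 and self.cx == 0.0 and self.cy == 0.0


@dataclass
class FieldTimeline:
    """One FieldState per frame; frame 0 is the (all-zero) reference."""

    states: list[FieldState]

    def __post_init__(self) -> None:
        if not self.states[0].is_zero():
            raise ValueError("first frame must be the zero-field reference")

    def __len__(self) -> int:
        return len(self.states)

    def __getitem__(self, t: int) -> FieldState:
        return self.states[t]

    def as_array(self) -> np.ndarray:
        return np.array([[s.c0, s.cx, s.cy] for s in self.states])

    @classmethod
    def from_array(cls, arr: np.ndarray) -> "FieldTimeline":
        return cls([FieldState(*row) for row in np.asarray(arr, dtype=float)])


def _ellipse(Y: np.ndarray, X: np.ndarray, cx: float, cy: float, ax: float, ay: float) -> np.ndarray:
    return ((X - cx) / ax) ** 2 + ((Y - cy) / ay) ** 2 <= 1.0


def make_phantom(
    n: int,
    n_slices: int,
    seed: int,
    activation_amplitude: float = 0.02,
) -> Phantom:
    """Build the ellipse-based multi-slice phantom.

    Deterministic for a fixed seed. The object is an outer ellipse (white
    matter), a cortical ribbon split into anatomically-named sectors, deep
    gray nuclei and ventricles, with smooth texture and a smooth low-order
    phase. Orientation: +y anterior, -y posterior.
    """
    if n % 2 != 0 or n < 32:
        raise ValueError("grid size n must be even and >= 32")
    rng = np.random.default_rng(seed)
    Y, X = image_grids(n)

    # slight seeded jitter of the outer geometry (different object per seed)
    ax0 = 0.40 * (1 + 0.03 * rng.standard_normal())
    ay0 = 0.34 * (1 + 0.03 * rng.standard_normal())

    grid = np.zeros((n_slices, n, n), dtype=complex)
    support = np.zeros((n_slices, n, n), dtype=bool)
    masks = {name: np.zeros((n_slices, n, n), dtype=bool) for name in _ROI_NAMES}
    act = np.zeros((n_slices, n, n))
    vis_mask = np.zeros((n_slices, n, n), dtype=bool)
    mot_mask = np.zeros((n_slices, n, n), dtype=bool)

    mid = (n_slices - 1) / 2.0
    for s in range(n_slices):
        sc = 1.0 - 0.04 * abs(s - mid)
        outer = _ellipse(Y, X, 0, 0, ax0 * sc, ay0 * sc)
        inner = _ellipse(Y, X, 0, 0, 0.72 * ax0 * sc, 0.72 * ay0 * sc)
        ring = outer & ~inner
        support[s] = outer

        mag = np.where(outer, 1.0, 0.0)
        mag[ring] = 1.2
        deep = _ellipse(Y, X, -0.10, 0.02, 0.07, 0.05) | _ellipse(Y, X, 0.10, 0.02, 0.07, 0.05)
        deep &= inner
        mag[deep] = 1.1
        vent = _ellipse(Y, X, -0.045, -0.05, 0.035, 0.06) | _ellipse(Y, X, 0.045, -0.05, 0.035, 0.06)
        vent &= inner & ~deep
        mag[vent] = 0.3

        # smooth seeded texture, confined to the object
        tex = ndimage.gaussian_filter(rng.standard_normal((n, n)), 2.0)
        tex /= max(np.abs(tex).max(), 1e-12)
        mag = mag * (1.0 + 0.05 * tex)
        mag[~outer] = 0.0

        # smooth low-order phase
        ph = 0.3 * (X + 0.5 * Y) + 0.4 * (X * Y) + 0.1 * rng.standard_normal() * (X**2 - Y**2)
        grid[s] = mag * np.exp(1j * ph)

        masks["frontal"][s] = ring & (Y > 0.16)
        masks["motor"][s] = ring & (Y > 0.06) & (Y <= 0.16)
        masks["somatosensory"][s] = ring & (np.abs(Y) <= 0.06)
        masks["parietal"][s] = ring & (Y < -0.06) & (Y >= -0.16)
        masks["occipital"][s] = ring & (Y < -0.16)
        masks["temporal"][s] = inner & (np.abs(X) > 0.22) & (np.abs(Y) <= 0.12)
        masks["deep_gm"][s] = deep
        masks["ventricles"][s] = vent

        # activation: posterior "visual/offer" blob and a blob in the motor
        # strip, disjoint by construction and inside the object
        vis = _ellipse(Y, X, 0.0, -0.26 * sc, 0.09, 0.05) & outer
        mot = _ellipse(Y, X, 0.29 * sc, 0.11 * sc, 0.07, 0.05) & outer
        mot &= ~vis
        act[s][vis] = activation_amplitude
        act[s][mot] = activation_amplitude
        vis_mask[s] = vis
        mot_mask[s] = mot

    regions = {"visual": (vis_mask, "offer"), "motor": (mot_mask, "motor_response")}
    return Phantom(grid=grid, tissue_masks=masks, activation_map=act,
                   activation_regions=regions, support=support)


def make_coil_maps(n_coils: int, n: int, seed: int) -> CoilSensitivities:
    """Smooth complex coil maps from Gaussian profiles on a ring of centers.

    Maps are normalized by their pointwise root-sum-of-squares, so the RSS
    is exactly 1 everywhere (trivially inside [0.5, 2] over the object).
    """
    if n_coils < 2:
        raise ValueError("parallel imaging requires at least 2 coils")
    rng = np.random.default_rng(seed)
    Y, X = image_grids(n)
    maps = np.empty((n_coils, n, n), dtype=complex)
    angles = 2 * np.pi * (np.arange(n_coils) + rng.uniform(0, 1)) / n_coils
    for c in range(n_coils):
        cx, cy = 0.58 * np.cos(angles[c]), 0.58 * np.sin(angles[c])
        r2 = (X - cx) ** 2 + (Y - cy) ** 2
        amp = np.exp(-r2 / (2 * 0.40**2))
        # smooth low-order complex phase with realistic ~one-cycle rolls
        # across the FOV (receive phase of off-center elements); the k-space
        # coil coupling that GRAPPA shift operators exploit lives here
        a, b, c2 = rng.uniform(-2 * np.pi, 2 * np.pi, size=3)
        ph = a * X + b * Y + c2 * X * Y + rng.uniform(-np.pi, np.pi)
        maps[c] = amp * np.exp(1j * ph)
    rss = np.sqrt(np.sum(np.abs(maps) ** 2, axis=0))
    maps /= rss[None]
    return CoilSensitivities(maps=maps)


def make_field_timeline(
    T: int,
    amp: tuple[float, float, float],
    model: str = "smooth",
    seed: int = 0,
) -> FieldTimeline:
    """Body-motion-like timeline of linear field perturbations.

    amp = (c0, cx, cy) maximum magnitudes in Hz / Hz-per-FOV.  Models:
    "smooth" (low-pass filtered noise), "step" (half-session offset),
    "spikes" (isolated excursions on ~5% of frames, the rest exactly zero).
    Frame 0 is always the zero reference and |coef| <= amp per channel.
    """
    if T < 2:
        raise ValueError("need at least 2 frames")
    amp = tuple(float(a) for a in amp)
    if any(a < 0 for a in amp):
        raise ValueError("amplitudes must be non-negative")
    if model not in ("smooth", "step", "spikes"):
        raise ValueError(f"unknown timeline model: {model!r}")
    rng = np.random.default_rng(seed)
    arr = np.zeros((T, 3))
    if model == "smooth":
        raw = ndimage.gaussian_filter1d(rng.standard_normal((T, 3)), sigma=5.0, axis=0)
        raw -= raw[0]
        peak = np.abs(raw).max(axis=0)
        peak[peak == 0] = 1.0
        arr = raw / peak * np.asarray(amp)
    elif model == "step":
        signs = rng.choice([-1.0, 1.0], size=3)
        arr[T // 2:] = signs * np.asarray(amp)
    else:  # spikes
        n_spk = max(1, int(round(0.05 * (T - 1))))
        idx = rng.choice(np.arange(1, T), size=n_spk, replace=False)
        vals = rng.uniform(0.5, 1.0, size=(n_spk, 3)) * rng.choice([-1.0, 1.0], size=(n_spk, 3))
        arr[idx] = vals * np.asarray(amp)
    arr[0] = 0.0
    return FieldTimeline.from_array(arr)
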