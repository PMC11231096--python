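"""Acquisition protocol and run configuration.

Defaults mirror the emulated awake-NHP SMS-EPI protocol where printed
(TE 25.4 ms, TR 1.282 s, MB = 2, in-plane R = 2, 120 mm FOV), scaled down in
matrix size, slice count and coil count so that full sessions simulate and
reconstruct in minutes on one CPU.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml


@dataclass
class Protocol:
    """Sequence and geometry parameters for the simulated acquisition.

    Attributes
    ----------
    n : matrix size (even); image grid is n x n.
    n_slices : total slices; must be a multiple of ``mb``.
    n_coils : receive channels.
    mb : multiband (SMS) factor.
    r : in-plane acceleration (every r-th phase-encode line acquired).
    te, tr : echo / repetition time in seconds.
    esp : effective echo spacing between consecutive acquired lines (s).
    fov_mm : field of view in mm (isotropic in-plane).
    slice_mm : slice thickness in mm.
    caipi : whether blipped-CAIPI inter-slice shifting is enabled.
    ghost_theta0, ghost_theta1 : even/odd readout phase error, constant term
        (rad) and linear term (rad per readout sample from center).
    sigma : complex Gaussian noise standard deviation per k-space sample
        (per real/imag component), in the same arbitrary units as the
        phantom signal after coil weighting.
    """

    n: int = 64
    n_slices: int = 4
    n_coils: int = 8
    mb: int = 2
    r: int = 2
    te: float = 0.0254
    tr: float = 1.282
    esp: float = 0.0006
    fov_mm: float = 120.0
    slice_mm: float = 2.0
    caipi: bool = True
    ghost_theta0: float = 0.1
    ghost_theta1: float = 0.05
    sigma: float = 0.0

    def __post_init__(self) -> None:
        if self.n % 2 != 0 or self.n < 32:
            raise ValueError("matrix size n must be even and >= 32")
        if self.n_slices % self.mb != 0:
            raise ValueError("n_slices must be a multiple of mb")
        if self.n % self.r != 0:
            raise ValueError("n must be divisible by r")

    # --- derived geometry -------------------------------------------------
    @property
    def n_lines(self) -> int:
        return self.n // self.r

    @property
    def n_groups(self) -> int:
        return self.n_slices // self.mb

    @property
    def voxel_mm(self) -> float:
        return self.fov_mm / self.n

    @property
    def acquired_ky(self) -> "np.ndarray":
        """Acquired phase-encode lines in grid units (DC = 0), every r-th."""
        import numpy as np

        return np.arange(-(self.n // 2), self.n // 2, self.r)

    def line_times(self) -> "np.ndarray":
        """Acquisition time of each acquired line relative to excitation.

        t_n = TE + (n - N_lines/2) * esp so that the k-space center line is
        sampled at the echo time.
        """
        import numpy as np

        n_l = self.n_lines
        return self.te + (np.arange(n_l) - n_l / 2) * self.esp

    def nav_times(self) -> "np.ndarray":
        """Navigator line times: three lines just before the echo train."""
        import numpy as np

        m = np.arange(3, 0, -1)  # acquired in order m = 3, 2, 1 before train
        return self.te - (self.n_lines / 2 + m) * self.esp

    def caipi_phase(self, ky: "np.ndarray", slice_in_group: int) -> "np.ndarray":
        """Blipped-CAIPI encoding phase for a slice at the given ky lines.

        The blip pattern alternates per *acquired* line, giving an
        inter-slice image shift of FOV/2 in the acquired (reduced) FOV,
        i.e. exp(i*2*pi*ky*s/(mb*r)) on the full grid.
        """
        import numpy as np

        if not self.caipi or self.mb == 1:
            return np.ones(np.shape(ky), dtype=complex)
        frac = slice_in_group / (self.mb * self.r)
        return np.exp(2j * np.pi * np.asarray(ky) * frac)

    def slice_groups(self) -> list[list[int]]:
        """SMS slice groups: slices separated by n_slices/mb are excited together."""
        g = self.n_groups
        return [[s + k * g for k in range(self.mb)] for s in range(g)]


@dataclass
class RunConfig:
    """All tunable parameters of a simulated study, serializable to YAML."""

    protocol: Protocol = field(default_factory=Protocol)
    # phantom / signal
    activation_amplitude: float = 0.02
    hrf_peak: float = 3.0
    hrf_undershoot: float = 7.0
    hrf_ratio: float = 0.167
    # task
    n_trials: int = 40
    p_respond: float = 0.8
    # field perturbation timeline
    field_model: str = "smooth"
    amp_c0: float = 10.0  # Hz
    amp_cx: float = 15.0  # Hz per FOV, readout
    amp_cy: float = 15.0  # Hz per FOV, phase-encode
    # session
    n_frames: int = 200
    snr: float = 30.0
    seed: int = 0
    # estimation / recon
    dky_bound: float = 0.75
    dky_tol: float = 0.005
    # analysis
    z_threshold: float = 3.1
    highpass_cutoff_s: float = 100.0
    smooth_fwhm_mm: float = 3.0

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "protocol" in d and isinstance(d["protocol"], dict):
            d["protocol"] = Protocol(**d["protocol"])
        return cls(**d)

    def save(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def load(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    def hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]
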