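"""Model configuration for the notochord G1/S transition wave model.

Physical defaults reflect the measured system: 2.5-min imaging frames, a 5 µm
cell diameter, a posterior elongation speed of 4/3 µm/min and a 30-min
segmentation clock, which together give 8 cells per somite width.
"""

from __future__ import annotations

from dataclasses import dataclass, replace


@dataclass(frozen=True)
class ModelConfig:
    """Parameters of the stochastic lattice model.

    Attributes
    ----------
    alpha_dt:
        Probability that a licensed G1 cell enters S phase within one frame
        (the per-frame transition probability, estimated ~0.11, used as 0.1).
    z:
        Wave step size in cells. ``z=1`` is the continuous wave; ``z=8`` steps
        one somite width every 30 min; ``z=16`` and ``z=24`` are the two- and
        three-fold periodic modes.
    L_c:
        Notochordal cell diameter in µm.
    lam:
        Posterior body-axis elongation speed in µm/min.
    dt:
        Imaging frame interval in minutes.
    T_som:
        Segmentation-clock period in minutes (reference only; the wave
        schedule is built from ``z``, ``L_c`` and ``lam``).
    n_cells:
        Lattice length (cells per notochord column).
    t_max:
        Number of frames simulated.
    seed:
        RNG seed; ``None`` draws fresh entropy.
    license_from_k0:
        If True the first ``z`` cells are licensed from frame 0 (wave step
        index starts at k=0 instead of k=1).
    """

    alpha_dt: float = 0.1
    z: int = 16
    L_c: float = 5.0
    lam: float = 4.0 / 3.0
    dt: float = 2.5
    T_som: float = 30.0
    n_cells: int = 100
    t_max: int = 120
    seed: int | None = None
    license_from_k0: bool = False

    def __post_init__(self) -> None:
        if not (0.0 < self.alpha_dt <= 1.0):
            raise ValueError(f"alpha_dt must be in (0, 1], got {self.alpha_dt}")
        if not (isinstance(self.z, (int,)) and self.z >= 1):
            raise ValueError(f"z must be a positive integer, got {self.z}")
        for name in ("L_c", "lam", "dt", "T_som"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0, got {getattr(self, name)}")
        for name in ("n_cells", "t_max"):
            v = getattr(self, name)
            if not (isinstance(v, int) and v >= 1):
                raise ValueError(f"{name} must be a positive integer, got {v}")
        if self.seed is not None and not isinstance(self.seed, int):
            raise ValueError(f"seed must be an integer or None, got {self.seed!r}")

    @property
    def somite_width_cells(self) -> float:
        """Number of cells spanning one somite width, T_som·λ/L_c (=8 here)."""
        return self.T_som * self.lam / self.L_c

    @property
    def step_interval_frames(self) -> float:
        """Frames between successive wave steps, L_c·z/(λ·Δt)."""
        return self.L_c * self.z / (self.lam * self.dt)

    @property
    def step_interval_minutes(self) -> float:
        """Minutes between successive wave steps, z·L_c/λ."""
        return self.z * self.L_c / self.lam

    def with_(self, **kwargs) -> "ModelConfig":
        """Return a copy with the given fields replaced."""
        return replace(self, **kwargs)
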