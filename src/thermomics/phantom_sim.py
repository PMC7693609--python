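"""Pennes bioheat phantom simulator.

Generates labeled synthetic thermal cohorts by explicit finite-difference
solution of the Pennes bioheat equation

    rho_t c_t dT/dt = div(k_t grad T) + omega_b c_b (T_a - T) + q_m

on a 2-D grid representing the frontal (skin-parallel) plane of the chest.
Symptomatic subjects carry a randomly placed tumor disc with elevated
metabolic heat generation q_m and locally elevated perfusion omega_b
(a vasodilation surrogate), which produces the thermal-heterogeneity
signal the downstream pipeline is built to detect.

Discretization: forward Euler in time with a conservative flux form of the
5-point Laplacian (harmonic-mean face conductivities) and zero-flux
(insulated Neumann) boundaries; an optional convective skin boundary
exchanges heat with an ambient temperature along the frame edge.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .errors import StabilityError, ValidationError

__all__ = [
    "TissueGrid",
    "ThermalSequence",
    "CohortRecord",
    "CohortConfig",
    "uniform_grid",
    "breast_masks",
    "tumor_phantom",
    "max_stable_dt",
    "simulate_pennes",
    "generate_cohort",
]

# Literature-typical soft-tissue constants (SI units).
RHO_TISSUE = 1050.0     # kg/m^3
C_TISSUE = 3600.0       # J/(kg K)
K_TISSUE = 0.48         # W/(m K)
C_BLOOD = 3617.0        # J/(kg K)
T_ARTERIAL = 37.0       # degC
OMEGA_NORMAL = 0.5      # kg/(m^3 s) perfusion mass-flow density
Q_M_NORMAL = 2.0e4      # W/m^3 metabolic heat, normal breast tissue
Q_M_TUMOR_RANGE = (1.0e5, 1.2e6)  # W/m^3, tumor metabolic heat range


def _as_field(value, shape) -> np.ndarray:
    arr = np.asarray(value, dtype=float)
    if arr.ndim == 0:
        return np.full(shape, float(arr))
    if arr.shape != tuple(shape):
        raise ValidationError(
            f"field shape {arr.shape} does not match grid shape {tuple(shape)}"
        )
    return arr.copy()


@dataclass
class TissueGrid:
    """Per-cell tissue properties on a rectangular grid.

    All per-cell fields accept scalars (broadcast) or (rows, cols) arrays.
    ``omega_b`` is the perfusion mass-flow density in kg/(m^3 s), i.e. the
    blood flow rate already multiplied by blood density, so the perfusion
    sink is ``omega_b * c_b * (T_a - T)`` in W/m^3.
    """

    shape: tuple[int, int]
    cell_size: float = 2.0e-3
    rho_t: np.ndarray | float = RHO_TISSUE
    c_t: np.ndarray | float = C_TISSUE
    k_t: np.ndarray | float = K_TISSUE
    omega_b: np.ndarray | float = OMEGA_NORMAL
    c_b: float = C_BLOOD
    T_a: float = T_ARTERIAL
    q_m: np.ndarray | float = Q_M_NORMAL
    breast_mask: np.ndarray | None = None
    tumor_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.shape = (int(self.shape[0]), int(self.shape[1]))
        for name in ("rho_t", "c_t", "k_t", "omega_b", "q_m"):
            setattr(self, name, _as_field(getattr(self, name), self.shape))
        if self.breast_mask is None:
            self.breast_mask = np.ones(self.shape, dtype=bool)
        else:
            self.breast_mask = np.asarray(self.breast_mask, dtype=bool).copy()
        if self.tumor_mask is None:
            self.tumor_mask = np.zeros(self.shape, dtype=bool)
        else:
            self.tumor_mask = np.asarray(self.tumor_mask, dtype=bool).copy()
        self.validate()

    def validate(self) -> None:
        if self.cell_size <= 0:
            raise ValidationError("cell_size must be positive")
        if self.c_b <= 0:
            raise ValidationError("blood specific heat c_b must be positive")
        m = self.breast_mask
        for name in ("rho_t", "c_t"):
            if np.any(getattr(self, name)[m] <= 0):
                raise ValidationError(f"{name} must be strictly positive in the breast ROI")
        for name in ("k_t", "omega_b", "q_m"):
            if np.any(getattr(self, name) < 0):
                raise ValidationError(f"{name} must be non-negative")
        if np.any(self.tumor_mask & ~self.breast_mask):
            raise ValidationError("tumor_mask must be contained in breast_mask")


@dataclass
class ThermalSequence:
    """A stack of temperature frames (degC) for one subject."""

    frames: np.ndarray                  # tau x rows x cols
    frame_interval: float = 15.0        # s
    subject_id: str = ""
    label: str = "healthy"              # {healthy, symptomatic}
    noise_sigma: float = 0.0            # degC

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if not np.issubdtype(self.frames.dtype, np.floating):
            self.frames = self.frames.astype(np.float64)
        if self.frames.ndim != 3 or self.frames.shape[0] < 1:
            raise ValidationError("frames must be a tau x rows x cols stack with tau >= 1")
        if not np.all(np.isfinite(self.frames)):
            raise ValidationError("frames contain non-finite values")
        if self.label not in ("healthy", "symptomatic"):
            raise ValidationError(f"unknown label {self.label!r}")

    @property
    def tau(self) -> int:
        return self.frames.shape[0]

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.frames.shape[1], self.frames.shape[2]


@dataclass
class CohortRecord:
    subject_id: str
    age: float
    family_history: str          # {none, diabetes, hypertensive, leukemia}
    hormone_therapy: bool
    label: str                   # {healthy, symptomatic}

    def __post_init__(self) -> None:
        if not (18 <= self.age <= 120):
            raise ValidationError(f"age {self.age} outside [18, 120]")
        if self.family_history not in ("none", "diabetes", "hypertensive", "leukemia"):
            raise ValidationError(f"unknown family_history {self.family_history!r}")
        if self.label not in ("healthy", "symptomatic"):
            raise ValidationError(f"unknown label {self.label!r}")


def uniform_grid(shape=(64, 64), **overrides) -> TissueGrid:
    """A homogeneous tissue grid with the default soft-tissue constants."""
    return TissueGrid(shape=shape, **overrides)


def breast_masks(shape) -> tuple[np.ndarray, np.ndarray]:
    """Left and right breast discs in the frontal plane (boolean masks)."""
    rows, cols = shape
    rr, cc = np.mgrid[0:rows, 0:cols]
    radius = 0.22 * cols
    left = (rr - 0.55 * rows) ** 2 + (cc - 0.28 * cols) ** 2 <= radius**2
    right = (rr - 0.55 * rows) ** 2 + (cc - 0.72 * cols) ** 2 <= radius**2
    return left, right


def tumor_phantom(
    shape=(64, 64),
    tumor_center=None,
    tumor_radius: float = 4.0,
    q_m_tumor: float = 6.0e5,
    q_m_normal: float = Q_M_NORMAL,
    omega_tumor_factor: float = 3.0,
    **overrides,
) -> TissueGrid:
    """Two-breast phantom with an optional tumor disc in the left breast.

    ``omega_tumor_factor`` scales perfusion inside the tumor (vasodilation
    surrogate). ``tumor_center`` defaults to the left-breast center.
    """
    rows, cols = shape
    left, right = breast_masks(shape)
    breast = left | right
    if tumor_center is None:
        tumor_center = (0.55 * rows, 0.28 * cols)
    rr, cc = np.mgrid[0:rows, 0:cols]
    tumor = (rr - tumor_center[0]) ** 2 + (cc - tumor_center[1]) ** 2 <= tumor_radius**2
    tumor &= breast
    q_m = np.full(shape, q_m_normal, dtype=float)
    q_m[tumor] = q_m_tumor
    omega = np.full(shape, overrides.pop("omega_b", OMEGA_NORMAL), dtype=float)
    omega[tumor] *= omega_tumor_factor
    return TissueGrid(
        shape=shape, q_m=q_m, omega_b=omega,
        breast_mask=breast, tumor_mask=tumor, **overrides,
    )


def max_stable_dt(grid: TissueGrid) -> float:
    """Largest admissible forward-Euler step for the diffusion term.

    dt_max = min over cells of rho c h^2 / (4 k); infinite for k == 0.
    """
    h2 = grid.cell_size**2
    with np.errstate(divide="ignore"):
        per_cell = grid.rho_t * grid.c_t * h2 / (4.0 * grid.k_t)
    return float(np.min(per_cell))


def _diffusion_flux(T: np.ndarray, k: np.ndarray, h: float) -> np.ndarray:
    """div(k grad T) in conservative flux form; zero-flux boundaries.

    Face conductivities are harmonic means, so heterogeneous (and zero)
    conductivities are handled and the insulated scheme conserves
    sum(rho c T) exactly up to roundoff.
    """
    div = np.zeros_like(T)
    # vertical faces (between columns)
    ksum = k[:, 1:] + k[:, :-1]
    kf = np.divide(2.0 * k[:, 1:] * k[:, :-1], ksum, out=np.zeros_like(ksum), where=ksum > 0)
    flux = kf * (T[:, 1:] - T[:, :-1]) / h
    div[:, :-1] += flux / h
    div[:, 1:] -= flux / h
    # horizontal faces (between rows)
    ksum = k[1:, :] + k[:-1, :]
    kf = np.divide(2.0 * k[1:, :] * k[:-1, :], ksum, out=np.zeros_like(ksum), where=ksum > 0)
    flux = kf * (T[1:, :] - T[:-1, :]) / h
    div[:-1, :] += flux / h
    div[1:, :] -= flux / h
    return div


def simulate_pennes(
    grid: TissueGrid,
    T0: np.ndarray | float,
    n_steps: int,
    dt: float,
    frame_interval: float | None = None,
    h_conv: float = 0.0,
    T_ambient: float = 22.0,
    subject_id: str = "",
    label: str = "healthy",
) -> ThermalSequence:
    """Integrate the Pennes equation and return sampled frames.

    Frames are recorded at t = 0 and every ``frame_interval`` seconds
    (default: every step). ``h_conv`` > 0 adds a convective heat loss
    h (T - T_ambient) / cell_size along the frame border (W/m^3
    equivalent for a one-cell-thick skin layer).

    Raises
    ------
    StabilityError
        if ``dt`` exceeds the explicit bound, naming the maximal
        admissible step.
    """
    grid.validate()
    if dt <= 0:
        raise ValidationError("dt must be positive")
    if n_steps < 0:
        raise ValidationError("n_steps must be non-negative")
    dt_max = max_stable_dt(grid)
    if dt > dt_max:
        raise StabilityError(
            f"dt={dt:g} s violates the explicit stability bound; "
            f"maximal admissible dt is {dt_max:.6g} s for this grid"
        )
    T = _as_field(T0, grid.shape)
    if not np.all(np.isfinite(T)):
        raise ValidationError("initial field T0 contains non-finite values")

    if frame_interval is None:
        record_every = 1
        frame_interval = dt
    else:
        record_every = max(1, int(round(frame_interval / dt)))

    rho_c = grid.rho_t * grid.c_t
    h = grid.cell_size
    border = np.zeros(grid.shape)
    if h_conv > 0:
        border[0, :] = border[-1, :] = border[:, 0] = border[:, -1] = h_conv / h

    frames = [T.copy()]
    for step in range(1, n_steps + 1):
        rate = _diffusion_flux(T, grid.k_t, h)
        rate += grid.omega_b * grid.c_b * (grid.T_a - T)
        rate += grid.q_m
        if h_conv > 0:
            rate -= border * (T - T_ambient)
        T = T + dt * rate / rho_c
        if step % record_every == 0:
            frames.append(T.copy())

    seq = ThermalSequence(
        frames=np.stack(frames),
        frame_interval=float(frame_interval),
        subject_id=subject_id,
        label=label,
    )
    if not np.all(np.isfinite(seq.frames)):
        raise ValidationError("simulation produced non-finite temperatures")
    return seq


# ---------------------------------------------------------------------------
# Cohort generation
# ---------------------------------------------------------------------------

@dataclass
class CohortConfig:
    """Stated world for the synthetic cohort.

    Defaults mirror the acquisition and population the pipeline targets:
    23 frames, 0.04 degC camera noise, tumor metabolic heat uniform in
    [1e5, 1.2e6] W/m^3 vs 2e4 W/m^3 normal, age median ~60, diabetes
    family history with probability 0.25, hormone therapy 0.183.
    """

    grid_shape: tuple[int, int] = (64, 64)
    cell_size: float = 2.0e-3
    tau: int = 23
    frame_interval: float = 15.0
    dt: float = 1.0
    T0: float = 30.0
    noise_sigma: float = 0.04
    q_m_normal: float = Q_M_NORMAL
    q_m_tumor_range: tuple[float, float] = Q_M_TUMOR_RANGE
    omega_normal: float = OMEGA_NORMAL
    omega_tumor_factor: float = 3.0
    tumor_radius_range: tuple[float, float] = (3.0, 6.0)
    age_mean: float = 60.0
    age_sd: float = 15.0
    p_family_history: dict = field(default_factory=lambda: {
        "none": 0.721, "diabetes": 0.25, "hypertensive": 0.024, "leukemia": 0.005,
    })
    p_hormone_therapy: float = 0.183


def _sample_record(rng: np.random.Generator, subject_id: str, label: str,
                   cfg: CohortConfig) -> CohortRecord:
    age = float(np.clip(np.round(rng.normal(cfg.age_mean, cfg.age_sd)), 18, 100))
    cats = list(cfg.p_family_history)
    probs = np.array([cfg.p_family_history[c] for c in cats])
    fh = cats[rng.choice(len(cats), p=probs / probs.sum())]
    ht = bool(rng.random() < cfg.p_hormone_therapy)
    return CohortRecord(subject_id=subject_id, age=age, family_history=fh,
                        hormone_therapy=ht, label=label)


def _simulate_subject(rng: np.random.Generator, subject_id: str, label: str,
                      cfg: CohortConfig) -> ThermalSequence:
    rows, cols = cfg.grid_shape
    if label == "symptomatic":
        q_tumor = rng.uniform(*cfg.q_m_tumor_range)
        radius = rng.uniform(*cfg.tumor_radius_range)
        # place the tumor uniformly inside a random breast disc, with margin
        side_c = 0.28 * cols if rng.random() < 0.5 else 0.72 * cols
        breast_r = 0.22 * cols
        ang = rng.uniform(0, 2 * np.pi)
        rad = (breast_r - radius - 1.0) * np.sqrt(rng.random())
        center = (0.55 * rows + rad * np.sin(ang), side_c + rad * np.cos(ang))
        grid = tumor_phantom(
            shape=cfg.grid_shape, tumor_center=center, tumor_radius=radius,
            q_m_tumor=q_tumor, q_m_normal=cfg.q_m_normal,
            omega_tumor_factor=cfg.omega_tumor_factor,
            omega_b=cfg.omega_normal, cell_size=cfg.cell_size,
        )
    else:
        grid = tumor_phantom(
            shape=cfg.grid_shape, tumor_radius=0.0, q_m_tumor=cfg.q_m_normal,
            q_m_normal=cfg.q_m_normal, omega_b=cfg.omega_normal,
            cell_size=cfg.cell_size,
        )
    n_steps = int(round((cfg.tau - 1) * cfg.frame_interval / cfg.dt))
    seq = simulate_pennes(
        grid, cfg.T0, n_steps, cfg.dt, frame_interval=cfg.frame_interval,
        subject_id=subject_id, label=label,
    )
    frames = seq.frames[: cfg.tau].astype(np.float32)
    if cfg.noise_sigma > 0:
        frames = frames + rng.normal(0.0, cfg.noise_sigma, frames.shape).astype(np.float32)
    return ThermalSequence(frames=frames, frame_interval=cfg.frame_interval,
                           subject_id=subject_id, label=label,
                           noise_sigma=cfg.noise_sigma)


def generate_cohort(
    n_healthy: int,
    n_symptomatic: int,
    seed: int,
    config: CohortConfig | None = None,
) -> tuple[list[ThermalSequence], list[CohortRecord]]:
    """Generate a labeled synthetic cohort, deterministically under ``seed``.

    Clinical covariates are sampled independently of the label (they carry
    no diagnostic signal by construction); the thermal signal lives in the
    tumor heat source and perfusion of symptomatic subjects.
    """
    if n_healthy < 0 or n_symptomatic < 0:
        raise ValidationError("cohort counts must be non-negative")
    cfg = config or CohortConfig()
    rng = np.random.default_rng(seed)
    sequences: list[ThermalSequence] = []
    records: list[CohortRecord] = []
    labels = ["healthy"] * n_healthy + ["symptomatic"] * n_symptomatic
    for i, label in enumerate(labels):
        sid = f"S{i:04d}"
        sequences.append(_simulate_subject(rng, sid, label, cfg))
        records.append(_sample_record(rng, sid, label, cfg))
    return sequences, records
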