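"""1-D Brownian toy model of steered ligand egress from a binding pocket.

The reaction coordinate x is the distance (Angstrom) of the ligand centre
from the bottom of the binding pocket.  The free-energy landscape is a
double well — a deep orthosteric well near x = 0 and a shallower
vestibule well around x = 16 A — built from two inverted Gaussians, with
flat bulk beyond a boundary (~30 A).  Overdamped (Euler-Maruyama)
dynamics:

    x_{n+1} = x_n + [D * F(x_n) / kT + v_steer] * dt + sqrt(2 D dt) * xi

where F = -dU/dx and v_steer is the drift contributed by the steering
schedule: during steered dissociation an acceleration inversely
proportional to the pocket distance, capped at ``cap`` (default 4000
nm/ns^2) and re-applied every ``apply_interval`` steps; during steered
association an acceleration proportional to 1/(scale - distance) directed
inward.  The acceleration is converted to drift velocity through a single
mobility constant, so absolute accelerations are schedule-relative and
not comparable to an all-atom simulation; the defaults are calibrated so
the escape threshold falls inside the schedule's working range and the
particle transiently pauses at the vestibule station on its way out.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from tandemsite.errors import NumericalError, ValidationError


@dataclass(frozen=True)
class SteeringSchedule:
    """Distance-dependent steering acceleration law.

    ``mode="dissociation"``: outward acceleration ``min(a0 / d, cap)``;
    ``mode="association"``: inward acceleration ``a0 / (scale - d)``,
    singular at ``d >= scale``.  The acceleration is recomputed every
    ``apply_interval`` integration steps and held constant in between.
    Units: nm/ns^2 for accelerations, Angstrom for ``scale``.
    """

    mode: str
    a0: float
    cap: float = 4000.0
    apply_interval: int = 100
    scale: float = 30.0

    def __post_init__(self) -> None:
        if self.mode not in ("dissociation", "association"):
            raise ValidationError("mode must be 'dissociation' or 'association'")
        if not self.a0 > 0:
            raise ValidationError("a0 must be > 0")
        if not self.cap > 0:
            raise ValidationError("cap must be > 0")
        if self.apply_interval < 1:
            raise ValidationError("apply_interval must be >= 1")


def steering_accel(schedule: SteeringSchedule, distance: float) -> float:
    """Signed steering acceleration at a pocket distance (nm/ns^2).

    Positive values point outward (dissociation), negative inward
    (association).
    """
    if schedule.mode == "dissociation":
        if distance <= 0:
            return schedule.cap
        return min(schedule.a0 / distance, schedule.cap)
    if distance >= schedule.scale:
        raise ValidationError(
            f"association schedule singular at distance {distance} >= "
            f"scale {schedule.scale}")
    return -schedule.a0 / (schedule.scale - distance)


@dataclass(frozen=True)
class PotentialLandscape:
    """Double-well potential along the pocket axis (energies in kT)."""

    well_positions: tuple = (0.0, 16.0)
    well_depths: tuple = (12.0, 4.0)
    well_widths: tuple = (2.0, 2.5)
    bulk_boundary: float = 30.0

    def __post_init__(self) -> None:
        if len(self.well_positions) != 2 or len(self.well_depths) != 2 \
                or len(self.well_widths) != 2:
            raise ValidationError("landscape needs exactly two wells")
        if self.well_positions[0] >= self.well_positions[1]:
            raise ValidationError("wells must be ordered along the coordinate")
        if any(d < 0 for d in self.well_depths):
            raise ValidationError("well depths must be >= 0")
        if any(w <= 0 for w in self.well_widths):
            raise ValidationError("well widths must be > 0")
        if self.bulk_boundary <= self.well_positions[1]:
            raise ValidationError("bulk boundary must lie beyond both wells")

    def energy(self, x):
        """U(x) in kT."""
        x = np.asarray(x, dtype=float)
        u = np.zeros_like(x)
        for pos, depth, width in zip(self.well_positions, self.well_depths,
                                     self.well_widths):
            u -= depth * np.exp(-((x - pos) ** 2) / (2.0 * width ** 2))
        return u

    def force(self, x):
        """-dU/dx in kT per Angstrom."""
        x = np.asarray(x, dtype=float)
        f = np.zeros_like(x)
        for pos, depth, width in zip(self.well_positions, self.well_depths,
                                     self.well_widths):
            f -= depth * (x - pos) / width ** 2 * np.exp(
                -((x - pos) ** 2) / (2.0 * width ** 2))
        return f

    @property
    def basin_divide(self) -> float:
        """Coordinate separating the orthosteric and vestibule basins."""
        return 0.5 * (self.well_positions[0] + self.well_positions[1])


@dataclass
class EscapeResult:
    """Outcome of a steered-escape run (one row per replica)."""

    record_steps: np.ndarray        # recorded step indices
    distances: np.ndarray           # (n_replicas, n_recorded) in Angstrom
    escaped: np.ndarray             # crossed the bulk boundary
    left_orthosteric: np.ndarray    # crossed the basin divide
    first_escape_step: np.ndarray   # -1 if never escaped
    residence: pd.DataFrame         # fractional time per region per replica

    @property
    def escape_probability(self) -> float:
        return float(np.mean(self.escaped))

    def to_csv(self, path) -> None:
        df = pd.DataFrame(self.distances.T, columns=[
            f"replica_{i}" for i in range(self.distances.shape[0])])
        df.insert(0, "step", self.record_steps)
        df.to_csv(path, index=False, float_format="%.6g")


def run_escape(landscape: PotentialLandscape,
               schedule: SteeringSchedule | None,
               n_steps: int,
               seed: int,
               n_replicas: int = 1,
               x0: float | None = None,
               diffusion: float = 0.1,
               dt: float = 0.01,
               steer_mobility: float = 1.5e-4,
               absorb_at_boundary: bool = True,
               reflect_lower: float = -5.0,
               record_every: int | None = None) -> EscapeResult:
    """Integrate overdamped Brownian dynamics under a steering schedule.

    Parameters
    ----------
    landscape, schedule
        Potential and steering law; ``schedule=None`` runs unsteered
        equilibrium dynamics.
    n_steps : int
        Number of Euler-Maruyama steps (positive).
    seed : int
        Seed for the noise stream (one substream per replica).
    n_replicas : int
        Independent trajectories integrated in parallel.
    x0 : float
        Starting coordinate; defaults to the orthosteric well bottom for
        dissociation runs and to just inside the bulk boundary for
        association runs.
    diffusion, dt
        Diffusion coefficient (A^2 per time unit) and step (time units).
    steer_mobility : float
        Drift velocity (A per time unit) contributed per unit steering
        acceleration (nm/ns^2); folds friction and mass into one constant.
    absorb_at_boundary : bool
        Freeze replicas once they cross the bulk boundary (escape);
        ``False`` reflects there instead (closed two-well system).
    """
    if n_steps < 1:
        raise ValidationError("n_steps must be >= 1")
    if dt <= 0 or diffusion <= 0:
        raise ValidationError("dt and diffusion must be > 0")
    associating = schedule is not None and schedule.mode == "association"
    if x0 is None:
        x0 = (landscape.bulk_boundary - 2.0 if associating
              else landscape.well_positions[0])
    interval = schedule.apply_interval if schedule is not None else n_steps
    record_every = record_every or max(1, n_steps // 2000)

    rng = np.random.default_rng(np.random.SeedSequence(seed))
    x = np.full(n_replicas, float(x0))
    frozen = np.zeros(n_replicas, dtype=bool)
    escaped = np.zeros(n_replicas, dtype=bool)
    left_orth = np.zeros(n_replicas, dtype=bool)
    first_escape = np.full(n_replicas, -1, dtype=int)
    region_steps = np.zeros((n_replicas, 3))  # orthosteric, vestibule, bulk
    well_steps = np.zeros((n_replicas, 2))    # within 1.5 widths of each well
    divide = landscape.basin_divide
    bulk = landscape.bulk_boundary
    noise_scale = math.sqrt(2.0 * diffusion * dt)
    v_steer = np.zeros(n_replicas)

    rec_steps, rec_x = [0], [x.copy()]
    for step in range(n_steps):
        if schedule is not None and step % interval == 0:
            d = np.maximum(x - landscape.well_positions[0], 1e-2)
            if schedule.mode == "dissociation":
                acc = np.minimum(schedule.a0 / d, schedule.cap)
            else:
                gap = schedule.scale - d
                if (gap <= 0).any():
                    raise ValidationError(
                        "association schedule singular: distance reached "
                        "the scale constant")
                acc = -schedule.a0 / gap
            v_steer = steer_mobility * acc
        drift = diffusion * landscape.force(x) + v_steer
        active = ~frozen
        x[active] = (x[active] + drift[active] * dt
                     + noise_scale * rng.standard_normal(active.sum()))
        if not np.isfinite(x).all() or np.abs(x).max() > 1e6:
            raise NumericalError(
                "integration unstable (coordinate blow-up): reduce dt")
        below = x < reflect_lower
        x[below] = 2 * reflect_lower - x[below]
        crossed = x >= bulk
        left_orth |= x >= divide
        newly = crossed & ~escaped
        first_escape[newly] = step
        escaped |= crossed
        if absorb_at_boundary:
            x[crossed] = bulk
            frozen |= crossed
        else:
            over = x > bulk
            x[over] = 2 * bulk - x[over]
        region = np.where(x < divide, 0, np.where(x < bulk, 1, 2))
        region_steps[np.arange(n_replicas), region] += 1
        for w, (pos, width) in enumerate(zip(landscape.well_positions,
                                             landscape.well_widths)):
            well_steps[:, w] += np.abs(x - pos) <= 0.5 * width
        if (step + 1) % record_every == 0 or step == n_steps - 1:
            rec_steps.append(step + 1)
            rec_x.append(x.copy())

    residence = pd.DataFrame(region_steps / n_steps,
                             columns=["orthosteric", "vestibule", "bulk"])
    # occupancy of narrow windows around the well bottoms (within half a
    # width), whose equilibrium ratio approaches exp(depth difference)
    residence["orthosteric_well"] = well_steps[:, 0] / n_steps
    residence["vestibule_well"] = well_steps[:, 1] / n_steps
    residence.insert(0, "replica", np.arange(n_replicas))
    return EscapeResult(
        record_steps=np.array(rec_steps),
        distances=np.array(rec_x).T,
        escaped=escaped,
        left_orthosteric=left_orth,
        first_escape_step=first_escape,
        residence=residence,
    )
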