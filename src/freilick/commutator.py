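"""Magnet-and-Hall-sensor ring encoder simulation and sector decoding.

A magnet glued to the tether cable rotates inside a ring of three Hall
sensors 120 degrees apart. Each sensor reads the cosine of the angular
offset between magnet and sensor axis (an idealized bipolar Hall response).
Combining the three readings reconstructs the magnet orientation among six
60-degree sectors; a stepper motor then counter-rotates the ring by whole
sectors so the cable never accumulates more than one sector of twist.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ParameterError

#: decoded-sector sentinel when the readings carry no direction information
INDETERMINATE = -1

SECTOR_DEG = 60.0
N_SECTORS = 6


@dataclass
class RingGeometry:
    """Angular positions of the three Hall sensors (degrees)."""

    sensor_positions_deg: tuple[float, float, float] = (0.0, 120.0, 240.0)

    def __post_init__(self) -> None:
        pos = np.mod(np.asarray(self.sensor_positions_deg, dtype=float), 360.0)
        if len(pos) != 3 or len(set(pos.tolist())) != 3:
            raise ParameterError("need 3 distinct sensor positions modulo 360")


def hall_readings(angle_deg: float, geometry: RingGeometry | None = None) -> np.ndarray:
    """Three direction-field readings for a magnet at ``angle_deg``.

    Sensor i reads ``cos(angle - position_i)``; the pattern is 360-degree
    periodic and rotating the magnet by 120 degrees cyclically permutes the
    readings.
    """
    if geometry is None:
        geometry = RingGeometry()
    pos = np.asarray(geometry.sensor_positions_deg, dtype=float)
    return np.cos(np.deg2rad(angle_deg - pos))


def sector_decode(readings, geometry: RingGeometry | None = None) -> int:
    """Decode the magnet sector (0..5) from the three Hall readings.

    The three cosine direction fields are combined into a phasor whose
    argument is the magnet angle; the sector is ``floor(angle / 60)``.
    Noise-free readings at angle theta decode to ``floor(theta/60) mod 6``.
    All-zero (or numerically negligible) readings are indeterminate.
    """
    if geometry is None:
        geometry = RingGeometry()
    r = np.asarray(readings, dtype=float)
    if r.shape != (3,):
        raise ParameterError("expected exactly 3 readings")
    phi = np.deg2rad(np.asarray(geometry.sensor_positions_deg, dtype=float))
    z_re = float(np.sum(r * np.cos(phi)))
    z_im = float(np.sum(r * np.sin(phi)))
    if np.hypot(z_re, z_im) < 1e-9:
        return INDETERMINATE
    angle = np.rad2deg(np.arctan2(z_im, z_re)) % 360.0
    return int(angle // SECTOR_DEG) % N_SECTORS


def decision_step(prev_sector: int, new_sector: int) -> int:
    """Motor command (-1, 0, +1 sector steps) from a sector transition.

    The command follows the shortest signed sector displacement, quantized
    to one sector per update; an indeterminate sector holds the motor.
    """
    if prev_sector == INDETERMINATE or new_sector == INDETERMINATE:
        return 0
    for s in (prev_sector, new_sector):
        if not 0 <= s < N_SECTORS:
            raise ParameterError(f"sector {s} outside 0..{N_SECTORS - 1}")
    d = (new_sector - prev_sector + N_SECTORS // 2) % N_SECTORS - N_SECTORS // 2
    return int(np.sign(d))


def decision_matrix() -> np.ndarray:
    """The full 6x6 command table implied by :func:`decision_step`."""
    return np.array([[decision_step(a, b) for b in range(N_SECTORS)]
                     for a in range(N_SECTORS)])


def simulate_tracking(
    angle_trajectory_deg,
    geometry: RingGeometry | None = None,
    noise_sigma: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Closed-loop tracking of a magnet trajectory by the sector decoder.

    At each step the sensors read the *relative* angle (magnet minus motor),
    the sector is decoded, and a sector transition commands the motor by one
    sector, keeping the residual cable twist within about one sector. Steps
    whose magnet rotation is at least one sector are flagged as aliased.

    Returns a log with magnet angle, readings, decoded sector, command and
    cumulative motor angle per step.
    """
    if geometry is None:
        geometry = RingGeometry()
    if noise_sigma < 0:
        raise ParameterError("noise_sigma must be non-negative")
    traj = np.asarray(angle_trajectory_deg, dtype=float)
    rng = np.random.default_rng(seed)
    motor = 0.0
    prev_sector = None
    rows = []
    prev_angle = traj[0] if traj.size else 0.0
    for k, angle in enumerate(traj):
        aliased = abs(angle - prev_angle) >= SECTOR_DEG
        rel = angle - motor
        r = hall_readings(rel, geometry)
        if noise_sigma > 0:
            r = r + rng.normal(0.0, noise_sigma, size=3)
        sector = sector_decode(r, geometry)
        if prev_sector is None or sector == INDETERMINATE:
            cmd = 0
        else:
            cmd = decision_step(prev_sector, sector)
        motor += cmd * SECTOR_DEG
        # after the corrective move, the magnet sits one sector back
        prev_sector = sector if sector == INDETERMINATE else (sector - cmd) % N_SECTORS
        rows.append({"step": k, "magnet_deg": angle, "h1": r[0], "h2": r[1],
                     "h3": r[2], "sector": sector, "command": cmd,
                     "motor_deg": motor, "twist_deg": angle - motor,
                     "aliased": aliased})
        prev_angle = angle
    return pd.DataFrame(rows)
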