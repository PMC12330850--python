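"""Sensor layouts on the unit sphere.

The reference layout is the 129-channel EGI HydroCel geodesic net used in
dense-array ssVEP work, with an occipital analysis pool of Oz (EGI sensor 75)
and its seven neighbours.  Positions are stored as unit vectors so that the
spherical-spline machinery (interpolation, surface Laplacian) can work with
inter-sensor cosines directly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: EGI HydroCel sensor numbers of Oz and its seven neighbours, pooled for
#: statistical analysis of the occipital ssVEP response.
OCCIPITAL_POOL_EGI = (70, 71, 72, 74, 75, 76, 82, 83)


@dataclass(frozen=True)
class SensorNet:
    """A named set of EEG sensors with unit-sphere positions.

    Parameters
    ----------
    sensor_ids : tuple of str
        Channel labels, e.g. ``("E1", ..., "E128", "Cz")``.
    positions : ndarray, shape (n_sensors, 3)
        Cartesian coordinates, each row of unit norm (tolerance 1e-9).
    occipital_pool : tuple of str
        Subset of ``sensor_ids`` averaged for pooled SNR statistics.
    """

    sensor_ids: tuple
    positions: np.ndarray
    occipital_pool: tuple = field(default=())

    def __post_init__(self):
        ids = tuple(self.sensor_ids)
        object.__setattr__(self, "sensor_ids", ids)
        pos = np.asarray(self.positions, dtype=float)
        if pos.shape != (len(ids), 3):
            raise ValueError(
                f"positions must have shape ({len(ids)}, 3), got {pos.shape}"
            )
        norms = np.linalg.norm(pos, axis=1)
        if not np.allclose(norms, 1.0, atol=1e-9):
            raise ValueError("sensor positions must lie on the unit sphere")
        object.__setattr__(self, "positions", pos)
        pool = tuple(self.occipital_pool)
        missing = [s for s in pool if s not in ids]
        if missing:
            raise ValueError(f"occipital_pool sensors not in net: {missing}")
        object.__setattr__(self, "occipital_pool", pool)

    @property
    def n_sensors(self) -> int:
        return len(self.sensor_ids)

    def index(self, sensor_id: str) -> int:
        try:
            return self.sensor_ids.index(sensor_id)
        except ValueError:
            raise KeyError(f"sensor {sensor_id!r} not in net") from None

    def pool_indices(self) -> np.ndarray:
        return np.array([self.index(s) for s in self.occipital_pool], dtype=int)

    # -- I/O -------------------------------------------------------------
    def to_file(self, path) -> None:
        """Write a whitespace-delimited ``name x y z`` electrode file."""
        with open(path, "w") as fh:
            fh.write("# name x y z (unit sphere)\n")
            fh.write("# pool: " + " ".join(self.occipital_pool) + "\n")
            for name, (x, y, z) in zip(self.sensor_ids, self.positions):
                fh.write(f"{name} {x:.12f} {y:.12f} {z:.12f}\n")

    @classmethod
    def from_file(cls, path) -> "SensorNet":
        ids, rows, pool = [], [], ()
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if line.startswith("# pool:"):
                    pool = tuple(line.split(":", 1)[1].split())
                    continue
                if not line or line.startswith("#"):
                    continue
                name, x, y, z = line.split()
                ids.append(name)
                rows.append([float(x), float(y), float(z)])
        return cls(tuple(ids), np.array(rows), pool)


def egi_hydrocel_129() -> SensorNet:
    """The 129-channel EGI HydroCel reference layout.

    Positions come from the standard montage shipped with MNE-Python and are
    radially projected onto the unit sphere.  The occipital pool is Oz (E75)
    plus seven neighbours (E70, E71, E72, E74, E76, E82, E83).
    """
    import mne

    montage = mne.channels.make_standard_montage("GSN-HydroCel-129")
    ch_pos = montage.get_positions()["ch_pos"]
    ids = tuple(montage.ch_names)
    pos = np.array([ch_pos[name] for name in ids])
    pos /= np.linalg.norm(pos, axis=1, keepdims=True)
    pool = tuple(f"E{k}" for k in OCCIPITAL_POOL_EGI)
    return SensorNet(ids, pos, pool)


def fibonacci_net(n_sensors: int, pool_size: int = 8) -> SensorNet:
    """A quasi-uniform n-sensor layout (Fibonacci sphere) for small fixtures.

    The pool is the ``pool_size`` sensors nearest an occipital reference
    direction, mimicking the Oz-centred analysis pool of the full net.
    """
    if n_sensors < pool_size:
        raise ValueError("need at least pool_size sensors")
    k = np.arange(n_sensors)
    phi = np.pi * (3.0 - np.sqrt(5.0)) * k
    z = 1.0 - 2.0 * (k + 0.5) / n_sensors
    r = np.sqrt(1.0 - z**2)
    pos = np.column_stack([r * np.cos(phi), r * np.sin(phi), z])
    ids = tuple(f"S{i + 1}" for i in range(n_sensors))
    occ = np.array([0.0, -0.7, -0.714])
    occ /= np.linalg.norm(occ)
    order = np.argsort(pos @ occ)[::-1]
    pool = tuple(ids[i] for i in sorted(order[:pool_size]))
    return SensorNet(ids, pos, pool)
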