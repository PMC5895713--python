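"""Oscillating-dipole forward model for a wave-type electric fish.

A wave-type weakly electric fish is modelled as an ideal current dipole of
time-varying strength ``I(t)`` lying in a horizontal plane.  In the far field
(``r >> d``, with ``d`` the dipole length) the potential at a point at distance
``r`` and angle ``theta`` from the dipole axis is

    Phi = K * I(t) * cos(theta) / r**2,       K = d / (4 * pi * sigma)

where ``sigma`` is the water conductivity; ``d`` and ``sigma`` are never needed
separately and are lumped into the single constant ``K``.  The discharge
current is well approximated by its first two harmonics,

    I(t) = A*cos(2*pi*f*t + psi) + gamma*A*cos(4*pi*f*t + xi).

The quantity the spatial tracker inverts is the *ideal observation vector*
``h(X)``: per-electrode signed amplitudes ``lambda_i = K*A*cos(theta_i)/r_i**2``
are differenced against a reference electrode and unit-normalized, which
removes every fish-specific constant (``K``, ``A``, ``gamma``) and leaves a
function of the dipole state ``X = (x, y, z, theta)`` alone.

Units: centimeters, seconds, Hz, radians.  ``z`` is measured downward from the
electrode plane (electrodes typically sit ~10 cm below the water surface), so
``z >= 0`` means "below the plane of the grid".
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml

__all__ = [
    "GridGeometry",
    "EODWaveform",
    "DipoleState",
    "DipoleSource",
    "ObservationVector",
    "instantaneous_current",
    "potential_at_point",
    "signed_amplitudes",
    "observation_map",
]

#: differenced vectors with norm below this are flagged degenerate
DEGENERATE_NORM = 1e-12

#: coplanarity tolerance for electrode grids (cm)
COPLANAR_TOL = 1.0


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GridGeometry:
    """Ordered electrode coordinates plus the reference-electrode choice.

    Parameters
    ----------
    electrodes
        ``(n, 3)`` array of electrode positions in cm, ordered; the ordering
        fixes the component order of every observation vector.
    reference_index
        Index of the electrode whose signal is subtracted from the others
        when forming the differenced observation vector.
    electrode_ids
        Optional string ids, used to align recording channels to electrodes.
    """

    electrodes: np.ndarray
    reference_index: int = -1
    electrode_ids: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        elec = np.asarray(self.electrodes, dtype=float)
        if elec.ndim != 2 or elec.shape[1] != 3:
            raise ValueError("electrodes must be an (n, 3) coordinate array")
        if elec.shape[0] < 3:
            raise ValueError("need at least 3 electrodes")
        if len(np.unique(elec, axis=0)) != elec.shape[0]:
            raise ValueError("electrode coordinates must be distinct")
        zspread = elec[:, 2].max() - elec[:, 2].min()
        if zspread > COPLANAR_TOL:
            raise ValueError(
                f"electrodes not coplanar within {COPLANAR_TOL} cm "
                f"(z spread {zspread:.3g} cm); the dipole plane is assumed "
                "parallel to the electrode plane"
            )
        ref = int(self.reference_index) % elec.shape[0]
        ids = tuple(self.electrode_ids) or tuple(
            f"E{i}" for i in range(elec.shape[0])
        )
        if len(ids) != elec.shape[0]:
            raise ValueError("electrode_ids length must match electrode count")
        object.__setattr__(self, "electrodes", elec)
        object.__setattr__(self, "reference_index", ref)
        object.__setattr__(self, "electrode_ids", ids)

    @property
    def n_electrodes(self) -> int:
        return self.electrodes.shape[0]

    @property
    def signal_indices(self) -> np.ndarray:
        """Indices of the (n-1) non-reference electrodes, in grid order."""
        n = self.n_electrodes
        return np.array([i for i in range(n) if i != self.reference_index])

    def xy_bounding_square(self) -> tuple[float, float, float, float]:
        """(xmin, xmax, ymin, ymax) of the outermost electrodes."""
        e = self.electrodes
        return e[:, 0].min(), e[:, 0].max(), e[:, 1].min(), e[:, 1].max()

    def contains_xy(self, x: float, y: float) -> bool:
        """Whether (x, y) lies within the closed square of outermost electrodes."""
        xmin, xmax, ymin, ymax = self.xy_bounding_square()
        return bool(xmin <= x <= xmax and ymin <= y <= ymax)

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "frame": {"units": "cm", "z_convention": "down from electrode plane"},
            "reference_index": int(self.reference_index),
            "electrodes": [
                {"id": eid, "x_cm": float(x), "y_cm": float(y), "z_cm": float(z)}
                for eid, (x, y, z) in zip(self.electrode_ids, self.electrodes)
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GridGeometry":
        recs = d["electrodes"]
        coords = np.array([[r["x_cm"], r["y_cm"], r["z_cm"]] for r in recs], float)
        ids = tuple(str(r["id"]) for r in recs)
        return cls(coords, int(d.get("reference_index", -1)), ids)

    def save(self, path: str | Path) -> None:
        path = Path(path)
        text = (
            json.dumps(self.to_dict(), indent=2)
            if path.suffix == ".json"
            else yaml.safe_dump(self.to_dict(), sort_keys=False)
        )
        path.write_text(text + "\n")

    @classmethod
    def load(cls, path: str | Path) -> "GridGeometry":
        path = Path(path)
        text = path.read_text()
        d = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
        return cls.from_dict(d)

    @classmethod
    def regular(
        cls,
        shape: tuple[int, int] = (3, 3),
        spacing: float = 30.0,
        origin: tuple[float, float] = (0.0, 0.0),
        z: float = 0.0,
        reference_index: int = -1,
    ) -> "GridGeometry":
        """A regular rows x cols planar grid (lab default: 3x3 at 30 cm)."""
        rows, cols = shape
        pts = [
            (origin[0] + c * spacing, origin[1] + r * spacing, z)
            for r in range(rows)
            for c in range(cols)
        ]
        return cls(np.array(pts, float), reference_index)


@dataclass(frozen=True)
class EODWaveform:
    """Two-harmonic electric organ discharge current waveform.

    ``f`` fundamental frequency (Hz); ``A`` fundamental amplitude (> 0,
    arbitrary units); ``gamma`` second-to-fundamental amplitude ratio;
    ``psi``/``xi`` fundamental / second-harmonic phases (rad).
    """

    f: float
    A: float = 1.0
    gamma: float = 0.25
    psi: float = 0.0
    xi: float = 0.0

    def __post_init__(self) -> None:
        if self.A <= 0:
            raise ValueError("fundamental amplitude A must be positive")
        if self.gamma < 0:
            raise ValueError("harmonic ratio gamma must be non-negative")
        if self.f <= 0:
            raise ValueError("fundamental frequency must be positive")


def _wrap_2pi(theta: float | np.ndarray):
    return np.mod(theta, 2.0 * math.pi)


@dataclass(frozen=True)
class DipoleState:
    """Dipole pose: position (cm) and planar orientation theta (rad).

    theta is measured counterclockwise from the +x axis of the grid frame;
    the dipole axis direction is (cos theta, sin theta, 0).
    """

    x: float
    y: float
    z: float
    theta: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "theta", float(_wrap_2pi(self.theta)))

    @property
    def position(self) -> np.ndarray:
        return np.array([self.x, self.y, self.z], float)

    @property
    def axis(self) -> np.ndarray:
        return np.array([math.cos(self.theta), math.sin(self.theta), 0.0])

    def as_array(self) -> np.ndarray:
        return np.array([self.x, self.y, self.z, self.theta], float)


@dataclass
class DipoleSource:
    """One fish: lumped field constant, waveform, and a pose trajectory.

    ``K = d/(4*pi*sigma)`` lumps the dipole length and water conductivity;
    its units are potential*cm^2 per unit current and it cancels out of every
    normalized observation.
    """

    source_id: str
    K: float
    waveform: EODWaveform
    times: np.ndarray = field(default_factory=lambda: np.array([0.0]))
    trajectory: list[DipoleState] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.K <= 0:
            raise ValueError("lumped constant K must be positive")
        self.times = np.asarray(self.times, float)
        if self.times.size > 1 and not np.all(np.diff(self.times) > 0):
            raise ValueError("trajectory timestamps must be strictly increasing")
        if self.trajectory and len(self.trajectory) != self.times.size:
            raise ValueError("trajectory length must match times length")

    def state_at(self, t: float) -> DipoleState:
        """Pose at time t by linear interpolation (theta via unwrap)."""
        if not self.trajectory:
            raise ValueError(f"source {self.source_id} has no trajectory")
        if len(self.trajectory) == 1:
            return self.trajectory[0]
        arr = np.array([s.as_array() for s in self.trajectory])
        th = np.unwrap(arr[:, 3])
        t = float(np.clip(t, self.times[0], self.times[-1]))
        x = np.interp(t, self.times, arr[:, 0])
        y = np.interp(t, self.times, arr[:, 1])
        z = np.interp(t, self.times, arr[:, 2])
        theta = np.interp(t, self.times, th)
        return DipoleState(x, y, z, theta)


@dataclass
class ObservationVector:
    """Reference-differenced, unit-normalized signed amplitudes at one window.

    ``values`` has one component per non-reference electrode in grid order.
    ``valid_mask`` marks which of those electrodes contributed; components of
    non-contributing electrodes are zero and the norm is taken over the valid
    components.  ``valid`` is False for degenerate or under-determined windows.
    """

    t: float
    values: np.ndarray
    valid_mask: np.ndarray
    valid: bool = True

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, float)
        self.valid_mask = np.asarray(self.valid_mask, bool)


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------

def instantaneous_current(waveform: EODWaveform, t: float | np.ndarray):
    """Two-harmonic discharge current I(t)."""
    w = waveform
    t = np.asarray(t, float)
    out = w.A * np.cos(2 * np.pi * w.f * t + w.psi) + w.gamma * w.A * np.cos(
        4 * np.pi * w.f * t + w.xi
    )
    return float(out) if out.ndim == 0 else out


def _geometry_factors(
    position: np.ndarray, theta: float | np.ndarray, points: np.ndarray
) -> np.ndarray:
    """cos(theta_i)/r_i^2 for each point; theta_i is the angle between the
    horizontal dipole axis and the full 3D displacement vector."""
    disp = points - position  # (n, 3)
    r2 = np.einsum("...ij,...ij->...i", disp, disp)
    if np.any(r2 <= 0):
        raise ValueError("evaluation point coincides with the dipole center")
    axis = np.stack(
        [np.cos(theta), np.sin(theta), np.zeros_like(np.asarray(theta, float))],
        axis=-1,
    )
    cos_ti = np.einsum("...ij,...j->...i", disp, axis) / np.sqrt(r2)
    return cos_ti / r2


def potential_at_point(
    source: DipoleSource,
    state: DipoleState,
    point: Sequence[float],
    t: float | np.ndarray,
):
    """Far-field potential of the oscillating dipole at one point.

    Phi = K * I(t) * cos(theta_pt) / r^2; r >> d is assumed, not checked.
    """
    g = _geometry_factors(state.position, state.theta, np.atleast_2d(np.asarray(point, float)))[0]
    out = source.K * g * instantaneous_current(source.waveform, t)
    return out


def signed_amplitudes(
    state: DipoleState, ka: float, grid: GridGeometry
) -> np.ndarray:
    """Per-electrode signed amplitudes lambda_i = K*A*cos(theta_i)/r_i^2.

    The sign is carried by cos(theta_i): electrodes on opposite sides of the
    dipole's perpendicular bisector plane receive opposite signs, which is the
    information the measured in-phase/antiphase grouping recovers.
    """
    return ka * _geometry_factors(state.position, state.theta, grid.electrodes)


def observation_map(
    state: DipoleState | np.ndarray,
    grid: GridGeometry,
    valid_mask: np.ndarray | None = None,
) -> ObservationVector | np.ndarray:
    """Ideal observation vector h(X): differenced, unit-normalized amplitudes.

    Fish-specific constants cancel, so K*A is set to 1.  When ``state`` is an
    ``(m, 4)`` array of states the result is an ``(m, n-1)`` array of h values
    (degenerate rows are returned as zero vectors); for a single
    ``DipoleState`` an :class:`ObservationVector` is returned, flagged invalid
    if the differenced vector is degenerate.

    ``valid_mask`` is a boolean mask over the non-reference electrodes; masked
    components are zeroed before normalization so the map matches observations
    in which some electrodes did not report.
    """
    single = isinstance(state, DipoleState)
    if single:
        arr = state.as_array()[None, :]
    else:
        arr = np.atleast_2d(np.asarray(state, float))
    lam = _geometry_factors(
        arr[:, None, :3], arr[:, 3], grid.electrodes[None, :, :]
    )  # (m, n)
    sig = grid.signal_indices
    diff = lam[:, sig] - lam[:, grid.reference_index, None]  # (m, n-1)
    if valid_mask is not None:
        diff = np.where(np.asarray(valid_mask, bool)[None, :], diff, 0.0)
    norm = np.linalg.norm(diff, axis=1)
    ok = norm > DEGENERATE_NORM
    h = np.zeros_like(diff)
    h[ok] = diff[ok] / norm[ok, None]
    if single:
        mask = (
            np.ones(sig.size, bool) if valid_mask is None
            else np.asarray(valid_mask, bool)
        )
        return ObservationVector(t=0.0, values=h[0], valid_mask=mask, valid=bool(ok[0]))
    return h
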