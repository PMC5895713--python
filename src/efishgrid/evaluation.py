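"""Validation machinery: pose errors, cumulative curves, and shuffled nulls.

Tracking output is scored against reference poses (simulation ground truth,
or video-tracked poses for real recordings) as *pose pairs*.  Position error
is the planar (x-y) Euclidean distance; orientation error is the minimal
circular difference, by default on the axial (mod-180 deg) scale since the
tracker estimates the dipole axis rather than the heading.  Pairs are
stratified by whether the reference position lies within the closed square
of the outermost electrodes — estimates degrade outside the grid.

Significance is assessed with a Monte-Carlo permutation (shuffle) test: the
reference poses are randomly permuted against the estimated poses many
times, the error statistics recomputed each time, and the true statistics
compared against the 0.001/0.999 quantiles of the shuffled distributions.
A true RMS error below the 0.001 quantile rejects the null hypothesis that
the tracking is no better than a random pairing of poses.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import permutations

import numpy as np
import pandas as pd

from .dipole_model import GridGeometry

__all__ = [
    "PosePair",
    "pose_error",
    "assign_strata",
    "cumulative_error_curve",
    "rmse",
    "shuffle_test",
    "pairs_from_tables",
]


@dataclass
class PosePair:
    """A reference pose and its corresponding estimated pose.

    Poses are ``(x_cm, y_cm, theta_rad)``.  ``stratum`` is ``"within_grid"``
    or ``"outside_grid"`` by the reference position.
    """

    reference: tuple[float, float, float]
    estimate: tuple[float, float, float]
    stratum: str = "within_grid"

    def __post_init__(self) -> None:
        vals = (*self.reference, *self.estimate)
        if not all(math.isfinite(v) for v in vals):
            raise ValueError("pose pair contains non-finite values")


def _angle_errors_deg(
    ref: np.ndarray, est: np.ndarray, angle_mode: str
) -> np.ndarray:
    period = math.pi if angle_mode == "axial" else 2 * math.pi
    d = np.mod(ref - est + period / 2, period) - period / 2
    return np.degrees(np.abs(d))


def pose_error(
    pair: PosePair, angle_mode: str = "axial"
) -> tuple[float, float]:
    """(planar position error in cm, orientation error in degrees)."""
    if angle_mode not in ("axial", "directed"):
        raise ValueError("angle_mode must be 'axial' or 'directed'")
    rx, ry, rth = pair.reference
    ex, ey, eth = pair.estimate
    pos = math.hypot(rx - ex, ry - ey)
    ang = float(
        _angle_errors_deg(np.array([rth]), np.array([eth]), angle_mode)[0]
    )
    return pos, ang


def assign_strata(pairs: list[PosePair], grid: GridGeometry) -> list[PosePair]:
    """Set each pair's stratum by whether its reference position falls inside
    the closed square of outermost electrode x-y coordinates."""
    for p in pairs:
        p.stratum = (
            "within_grid" if grid.contains_xy(p.reference[0], p.reference[1])
            else "outside_grid"
        )
    return pairs


def cumulative_error_curve(errors: np.ndarray) -> pd.DataFrame:
    """Empirical CDF of an error sample: columns ``threshold``, ``fraction``."""
    errors = np.asarray(errors, float)
    if errors.size == 0:
        raise ValueError("cumulative_error_curve needs at least one error")
    thr = np.sort(errors)
    frac = np.arange(1, thr.size + 1) / thr.size
    return pd.DataFrame({"threshold": thr, "fraction": frac})


def _errors(
    pairs: list[PosePair], angle_mode: str
) -> tuple[np.ndarray, np.ndarray]:
    ref = np.array([p.reference for p in pairs])
    est = np.array([p.estimate for p in pairs])
    pos = np.hypot(ref[:, 0] - est[:, 0], ref[:, 1] - est[:, 1])
    ang = _angle_errors_deg(ref[:, 2], est[:, 2], angle_mode)
    return pos, ang


def rmse(
    pairs: list[PosePair], component: str, angle_mode: str = "axial"
) -> float:
    """Root-mean-square position (cm) or angle (deg) error over pairs."""
    if not pairs:
        raise ValueError("rmse needs at least one pair")
    pos, ang = _errors(pairs, angle_mode)
    err = {"position": pos, "angle": ang}[component]
    return float(np.sqrt(np.mean(err**2)))


def _shuffled_rms(
    ref: np.ndarray,
    est: np.ndarray,
    iterations: int,
    angle_mode: str,
    rng: np.random.Generator,
    exhaustive: bool,
) -> tuple[np.ndarray, np.ndarray]:
    n = ref.shape[0]
    perms = (
        np.array(list(permutations(range(n))))
        if exhaustive
        else np.array([rng.permutation(n) for _ in range(iterations)])
    )
    rms_pos = np.empty(perms.shape[0])
    rms_ang = np.empty(perms.shape[0])
    for i, perm in enumerate(perms):
        r = ref[perm]
        pos = np.hypot(r[:, 0] - est[:, 0], r[:, 1] - est[:, 1])
        ang = _angle_errors_deg(r[:, 2], est[:, 2], angle_mode)
        rms_pos[i] = np.sqrt(np.mean(pos**2))
        rms_ang[i] = np.sqrt(np.mean(ang**2))
    return rms_pos, rms_ang


def shuffle_test(
    pairs: list[PosePair],
    iterations: int = 10_000,
    quantiles: tuple[float, float] = (0.001, 0.999),
    seed: int = 0,
    angle_mode: str = "axial",
    exhaustive: bool = False,
    cdf_grid: np.ndarray | None = None,
) -> dict:
    """Monte-Carlo permutation test of tracking performance.

    For each stratum (``within_grid``, ``outside_grid``, ``all``; strata with
    fewer than 2 pairs are skipped) the reference poses are permuted against
    the estimates ``iterations`` times (or over all n! permutations when
    ``exhaustive``), and per iteration the RMS position/angle errors and the
    cumulative error fractions on ``cdf_grid`` are recorded.

    Returns a dict per stratum with the true statistics, the shuffled RMS
    samples, their requested quantiles, a ``*_below_lower_quantile`` flag per
    component, and the mean/quantile bands of the shuffled cumulative curves.
    """
    if len(pairs) < 2:
        raise ValueError("shuffle_test needs at least 2 pose pairs")
    rng = np.random.default_rng(seed)
    strata: dict[str, list[PosePair]] = {"all": list(pairs)}
    for name in ("within_grid", "outside_grid"):
        sub = [p for p in pairs if p.stratum == name]
        strata[name] = sub

    out: dict[str, dict] = {}
    for name, sub in strata.items():
        if len(sub) < 2:
            continue
        ref = np.array([p.reference for p in sub])
        est = np.array([p.estimate for p in sub])
        true_pos, true_ang = _errors(sub, angle_mode)
        rms_pos, rms_ang = _shuffled_rms(
            ref, est, iterations, angle_mode, rng, exhaustive
        )
        res = {
            "n_pairs": len(sub),
            "true_rms_position": float(np.sqrt(np.mean(true_pos**2))),
            "true_rms_angle": float(np.sqrt(np.mean(true_ang**2))),
            "shuffled_rms_position": rms_pos,
            "shuffled_rms_angle": rms_ang,
            "rms_position_quantiles": {
                q: float(np.quantile(rms_pos, q)) for q in quantiles
            },
            "rms_angle_quantiles": {
                q: float(np.quantile(rms_ang, q)) for q in quantiles
            },
        }
        qlo = min(quantiles)
        res["position_below_lower_quantile"] = bool(
            res["true_rms_position"] < res["rms_position_quantiles"][qlo]
        )
        res["angle_below_lower_quantile"] = bool(
            res["true_rms_angle"] < res["rms_angle_quantiles"][qlo]
        )
        if cdf_grid is not None:
            grid_arr = np.asarray(cdf_grid, float)
            # shuffled cumulative error distribution on the grid
            n_show = min(200, iterations)
            fracs = np.empty((n_show, grid_arr.size))
            for i in range(n_show):
                perm = rng.permutation(len(sub))
                pos = np.hypot(
                    ref[perm, 0] - est[:, 0], ref[perm, 1] - est[:, 1]
                )
                fracs[i] = np.mean(pos[None, :] <= grid_arr[:, None], axis=1)
            res["cdf_grid"] = grid_arr
            res["shuffled_cdf_mean"] = fracs.mean(axis=0)
            res["shuffled_cdf_bands"] = {
                q: np.quantile(fracs, q, axis=0) for q in quantiles
            }
            res["true_cdf"] = np.mean(
                true_pos[None, :] <= grid_arr[:, None], axis=1
            )
        out[name] = res
    return out


def pairs_from_tables(
    truth: pd.DataFrame,
    poses: pd.DataFrame,
    grid: GridGeometry,
    time_tolerance: float = 0.125,
) -> list[PosePair]:
    """Join a ground-truth table and a pose-estimate table into pose pairs.

    ``truth`` needs columns ``t, x, y, theta`` (radians) and optionally
    ``source_id``; ``poses`` needs ``t, x, y, theta`` and optionally
    ``track_id`` and ``valid``.  Rows are matched per (source, track) on
    nearest time within ``time_tolerance`` seconds (default half a typical
    hop).  Strata are assigned from the grid geometry.
    """
    if "valid" in poses:
        poses = poses[poses["valid"].astype(bool)]
    pairs: list[PosePair] = []
    tt = truth.sort_values("t")
    for _, row in poses.iterrows():
        sub = tt
        if "source_id" in truth.columns and "track_id" in poses.columns:
            # single-truth-source tables pair with any track
            if truth["source_id"].nunique() > 1:
                sub = tt[tt["source_id"] == row["track_id"]]
                if sub.empty:
                    continue
        idx = (sub["t"] - row["t"]).abs().idxmin()
        tr = sub.loc[idx]
        if abs(tr["t"] - row["t"]) > time_tolerance:
            continue
        pairs.append(
            PosePair(
                reference=(float(tr["x"]), float(tr["y"]), float(tr["theta"])),
                estimate=(float(row["x"]), float(row["y"]), float(row["theta"])),
            )
        )
    return assign_strata(pairs, grid)
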