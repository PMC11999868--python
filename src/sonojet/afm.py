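"""Hertz-model fitting of AFM nanoindentation force curves.

A colloidal probe (sphere of radius Rbead) indents a soft substrate; on
the post-contact segment the force follows the Hertz contact law

    F = (4/3) E / (1 - theta^2) * sqrt(Rbead) * iota^(3/2)

with iota the indentation and theta the Poisson ratio (0.5 for an
incompressible gel).  The apparent compression elastic modulus E is
extracted per curve by a joint least-squares fit of (E, contact point,
force baseline); curves without a clear contact point are discarded.
Per-sample aggregation follows the median-per-location / mean-over-
locations / mean +- sd over samples convention.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

__all__ = [
    "ForceCurve",
    "HertzFit",
    "hertz_force",
    "fit_modulus",
    "aggregate_modulus",
    "read_force_curves",
    "write_force_curves",
]


@dataclass
class ForceCurve:
    """Approach segment of a force-displacement curve.

    displacement: probe position (m), strictly increasing towards the
    sample; force: cantilever force (N).  Metadata: bead radius (m),
    Poisson ratio, approach speed (m/s) and grouping labels.
    """

    displacement: np.ndarray
    force: np.ndarray
    Rbead: float = 5.0e-6
    theta: float = 0.5
    approach_speed: float = 1.0e-6
    location_id: str = "loc0"
    sample_id: str = "sample0"

    def __post_init__(self) -> None:
        self.displacement = np.asarray(self.displacement, dtype=float)
        self.force = np.asarray(self.force, dtype=float)
        if self.displacement.size != self.force.size:
            raise ValueError("displacement and force must have equal length")
        if np.any(np.diff(self.displacement) <= 0):
            raise ValueError("approach displacement must be strictly increasing")


@dataclass(frozen=True)
class HertzFit:
    """Result of a Hertz fit: apparent modulus E (Pa), contact point (m),
    force baseline (N), residual RMS (N) and a validity flag."""

    E: float
    contact_point: float
    baseline: float
    residual_rms: float
    valid: bool
    location_id: str = "loc0"
    sample_id: str = "sample0"


def hertz_force(iota, E: float, theta: float = 0.5, Rbead: float = 5.0e-6):
    """Hertz contact force for a sphere on an elastic half-space.

    Zero for negative indentation (pre-contact).
    """
    iota = np.asarray(iota, dtype=float)
    pref = (4.0 / 3.0) * E / (1.0 - theta**2) * math.sqrt(Rbead)
    return pref * np.where(iota > 0.0, iota, 0.0) ** 1.5


MIN_POST_CONTACT = 10


def fit_modulus(curve: ForceCurve, theta: float | None = None,
                Rbead: float | None = None,
                fit_baseline: bool = True) -> HertzFit:
    """Least-squares Hertz fit of one approach curve.

    E and the contact point (and, by default, a constant force baseline)
    are fitted jointly on the whole approach segment; the contact point is
    free rather than thresholded.  The fit is marked invalid when fewer
    than 10 samples lie past the fitted contact point or when the fitted
    post-contact force rise does not clearly exceed the residual noise
    (no clear contact point, e.g. a pure-baseline curve).
    """
    theta = curve.theta if theta is None else theta
    Rbead = curve.Rbead if Rbead is None else Rbead
    z = curve.displacement
    F = curve.force
    n = z.size
    if n < MIN_POST_CONTACT + 2:
        return HertzFit(math.nan, math.nan, math.nan, math.nan, False,
                        curve.location_id, curve.sample_id)

    b0 = float(np.median(F[: max(n // 5, 3)]))
    noise = float(np.std(F[: max(n // 5, 3)])) or 1e-15
    above = np.flatnonzero(F - b0 > 3.0 * noise)
    z0_guess = z[above[0]] if above.size else z[int(0.6 * n)]
    span = F[-1] - b0
    iota_end = max(z[-1] - z0_guess, (z[-1] - z[0]) * 1e-3)
    E_guess = max(span, noise) * (1.0 - theta**2) / (
        (4.0 / 3.0) * math.sqrt(Rbead) * iota_end**1.5
    )

    def model(p):
        logE, z0, b = p
        return b + hertz_force(z - z0, math.exp(logE), theta, Rbead)

    def resid(p):
        return model(p) - F

    p0 = [math.log(max(E_guess, 1e-3)), z0_guess, b0 if fit_baseline else b0]
    if fit_baseline:
        res = least_squares(resid, p0, method="lm", max_nfev=2000)
    else:
        res = least_squares(lambda p: model([p[0], p[1], b0]) - F,
                            p0[:2], method="lm", max_nfev=2000)
        res.x = np.append(res.x, b0)
    logE, z0, b = res.x
    E = math.exp(logE)
    rms = float(np.sqrt(np.mean(res.fun**2)))
    n_post = int(np.sum(z > z0))
    rise = float(F[-1] - b)
    valid = (
        n_post >= MIN_POST_CONTACT
        and np.isfinite(E)
        and E > 0
        and rise > 3.0 * max(rms, noise)
        and z[0] - (z[-1] - z[0]) < z0 < z[-1]
    )
    return HertzFit(E, float(z0), float(b), rms, bool(valid),
                    curve.location_id, curve.sample_id)


def aggregate_modulus(fits: list[HertzFit]) -> dict:
    """Hierarchical summary of apparent moduli.

    Per location: median over the grid points; per sample: mean over its
    locations; overall: mean +- sd over samples.  Invalid fits are
    dropped; empty groups are excluded.
    """
    rows = [
        {"sample_id": f.sample_id, "location_id": f.location_id, "E": f.E}
        for f in fits if f.valid
    ]
    if not rows:
        raise ValueError("no valid fits to aggregate")
    df = pd.DataFrame(rows)
    per_location = df.groupby(["sample_id", "location_id"])["E"].median()
    per_sample = per_location.groupby("sample_id").mean()
    return {
        "E_mean": float(per_sample.mean()),
        "E_sd": float(per_sample.std(ddof=1)) if per_sample.size > 1 else 0.0,
        "n_samples": int(per_sample.size),
        "per_sample": per_sample.to_dict(),
        "per_location": {f"{s}/{l}": v for (s, l), v in per_location.items()},
        "n_valid_fits": len(rows),
    }


def read_force_curves(path) -> list[ForceCurve]:
    """Read force curves from CSV with columns z_m, F_N, location_id,
    sample_id (one curve per (sample, location, curve_id) group; a
    curve_id column is optional for multiple curves per location)."""
    df = pd.read_csv(path)
    needed = {"z_m", "F_N", "location_id", "sample_id"}
    if not needed.issubset(df.columns):
        raise ValueError(f"force-curve CSV needs columns {sorted(needed)}")
    keys = ["sample_id", "location_id"]
    if "curve_id" in df.columns:
        keys.append("curve_id")
    curves = []
    for key, g in df.groupby(keys, sort=False):
        curves.append(
            ForceCurve(
                displacement=g["z_m"].to_numpy(),
                force=g["F_N"].to_numpy(),
                location_id=str(g["location_id"].iloc[0]),
                sample_id=str(g["sample_id"].iloc[0]),
            )
        )
    return curves


def write_force_curves(path, curves: list[ForceCurve]) -> None:
    frames = []
    for i, c in enumerate(curves):
        frames.append(pd.DataFrame({
            "z_m": c.displacement, "F_N": c.force,
            "location_id": c.location_id, "sample_id": c.sample_id,
            "curve_id": i,
        }))
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)
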