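"""End-to-end analysis pipelines over a structured run configuration.

Three reproductions are provided:

* :func:`run_case_study` - the paired low/high amplitude case study
  (radius dynamics, centroid translation, per-cycle impulse
  decomposition with substrate-to-ultrasound ratios);
* :func:`run_threshold_map` - minimum jetting pressure amplitude versus
  equilibrium radius, by bisection on the 1-um expansion threshold;
* :func:`run_stress_comparison` - the stress-mechanism comparison with
  peak table and dominance ratios.

Every run can emit a manifest (full config + seed + package version)
sufficient to reproduce its outputs bit-for-bit.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .acoustics import Medium, UltrasoundPulse, build_pulse
from .impulse import cycles_to_frame, zeta_per_cycle
from .radial_dynamics import (
    BubbleParams,
    EXPANSION_THRESHOLD,
    RadialCollapseError,
    ShellParams,
    expansion_metrics,
    solve_radial,
)
from .stress import JetParams, stress_report
from .translation_dynamics import CellLayer, solve_translation

__all__ = [
    "RunConfig",
    "run_case_study",
    "run_threshold_map",
    "run_stress_comparison",
    "jetting_threshold_pressure",
]


@dataclass
class RunConfig:
    """Validated configuration for the analysis pipelines."""

    medium: Medium = field(default_factory=Medium)
    bubble: BubbleParams = field(default_factory=BubbleParams)
    shell: ShellParams = field(default_factory=ShellParams)
    cell: CellLayer = field(default_factory=CellLayer)
    f_hz: float = 1.0e6
    n_cycles: int = 20
    ramp_cycles: float = 5.0
    angle_deg: float = 15.0
    envelope_file: str | None = None
    p_a_low: float = 60.0e3
    p_a_high: float = 160.0e3
    u_jet: float = 60.0
    u_stream: float = 0.1
    R_jet: float | None = None
    frame_rate: float = 1.0e7
    expansion_threshold: float = EXPANSION_THRESHOLD
    R0_grid: tuple[float, ...] = tuple(np.linspace(1.0e-6, 4.0e-6, 13))
    p_a_bounds: tuple[float, float] = (5.0e3, 400.0e3)
    bisect_tol: float = 1.0e3
    seed: int = 0

    def pulse(self, p_a: float) -> UltrasoundPulse:
        return build_pulse(
            self.f_hz, p_a, self.n_cycles, ramp_cycles=self.ramp_cycles,
            angle_deg=self.angle_deg, envelope_file=self.envelope_file,
        )

    def jet(self, R0: float | None = None) -> JetParams:
        if self.R_jet is not None:
            return JetParams(u_jet=self.u_jet, R_jet=self.R_jet)
        return JetParams.for_bubble(R0 or self.bubble.R0, u_jet=self.u_jet)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        kwargs = dict(raw)
        for key, typ in (("medium", Medium), ("bubble", BubbleParams),
                         ("shell", ShellParams), ("cell", CellLayer)):
            if key in kwargs and isinstance(kwargs[key], dict):
                kwargs[key] = typ(**kwargs[key])
        for key in ("R0_grid", "p_a_bounds"):
            if key in kwargs:
                kwargs[key] = tuple(kwargs[key])
        return cls(**kwargs)

    def to_dict(self) -> dict:
        def conv(obj):
            if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
                return {k: conv(v) for k, v in dataclasses.asdict(obj).items()}
            if isinstance(obj, (np.floating, np.integer)):
                return obj.item()
            if isinstance(obj, (tuple, list, np.ndarray)):
                return [conv(v) for v in obj]
            return obj
        return {f.name: conv(getattr(self, f.name))
                for f in dataclasses.fields(self)}

    def write_manifest(self, path: str | Path, extra: dict | None = None) -> None:
        manifest = {"config": self.to_dict(), "seed": self.seed,
                    "sonojet_version": __version__}
        if extra:
            manifest.update(extra)
        Path(path).write_text(json.dumps(manifest, indent=2))


def run_case_study(config: RunConfig, out_dir: str | Path | None = None) -> dict:
    """Paired low/high-amplitude case study.

    For each amplitude: radial solution, translation solution, per-cycle
    impulse table, expansion metrics and the per-cycle substrate-to-
    ultrasound impulse ratios.  Writes CSV tables and a manifest when
    ``out_dir`` is given.
    """
    results = {}
    for name, p_a in (("low", config.p_a_low), ("high", config.p_a_high)):
        pulse = config.pulse(p_a)
        radial = solve_radial(pulse, config.bubble, config.shell, config.medium)
        translation = solve_translation(radial, pulse, config.medium, config.cell)
        cycles = zeta_per_cycle(radial, translation, pulse, config.medium,
                                config.cell)
        metrics = expansion_metrics(radial)
        results[name] = {
            "radial": radial,
            "translation": translation,
            "cycles": cycles,
            "metrics": metrics,
            "ratio_sub_us": [c.ratio_sub_us for c in cycles],
        }
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for name, r in results.items():
            r["radial"].to_frame().to_csv(out / f"radial_{name}.csv", index=False)
            r["translation"].to_frame().to_csv(
                out / f"translation_{name}.csv", index=False)
            cycles_to_frame(r["cycles"]).to_csv(
                out / f"impulse_{name}.csv", index=False)
        summary = {
            name: {
                "max_expansion_m": r["metrics"]["max_expansion"],
                "accel_proxy_m_s2": r["metrics"]["accel_proxy"],
                "ultimate_compression": bool(r["translation"].ultimate_compression),
                "min_ratio_sub_us": float(np.min(r["ratio_sub_us"])),
                "max_ratio_sub_us": float(np.max(r["ratio_sub_us"])),
            }
            for name, r in results.items()
        }
        (out / "summary.json").write_text(json.dumps(summary, indent=2))
        config.write_manifest(out / "manifest.json")
    return results


def jetting_threshold_pressure(
    R0: float,
    config: RunConfig,
    threshold: float | None = None,
) -> float:
    """Minimum pressure amplitude whose maximum radial expansion reaches
    the jetting threshold, by bisection to ``config.bisect_tol`` (Pa).

    Returns NaN when the threshold is not reached within
    ``config.p_a_bounds`` (a radial-collapse failure counts as exceeding
    the threshold, since it can only occur far beyond it).
    """
    threshold = threshold if threshold is not None else config.expansion_threshold
    bubble = BubbleParams(R0=R0, gas_model=config.bubble.gas_model,
                          kappa=config.bubble.kappa)

    def reaches(p_a: float) -> bool:
        try:
            sol = solve_radial(config.pulse(p_a), bubble, config.shell,
                               config.medium)
        except RadialCollapseError:
            return True
        return float(np.max(sol.R)) - R0 >= threshold

    lo, hi = config.p_a_bounds
    if not reaches(hi):
        return float("nan")
    if reaches(lo):
        return lo
    while hi - lo > config.bisect_tol:
        mid = 0.5 * (lo + hi)
        if reaches(mid):
            hi = mid
        else:
            lo = mid
    return 0.5 * (lo + hi)


def run_threshold_map(config: RunConfig, out_dir: str | Path | None = None) -> dict:
    """Jetting-threshold pressure versus equilibrium radius.

    Bisects the pressure amplitude for each radius on ``config.R0_grid``
    and reports the minimum threshold and the radius where it occurs (the
    large-amplitude resonant size).
    """
    import pandas as pd

    rows = []
    for R0 in config.R0_grid:
        p_th = jetting_threshold_pressure(float(R0), config)
        rows.append({"R0_m": float(R0), "p_threshold_pa": p_th,
                     "reached": bool(np.isfinite(p_th))})
    df = pd.DataFrame(rows)
    ok = df[df["reached"]]
    i_min = ok["p_threshold_pa"].idxmin()
    result = {
        "table": df,
        "min_threshold_pa": float(ok.loc[i_min, "p_threshold_pa"]),
        "R0_at_min_m": float(ok.loc[i_min, "R0_m"]),
    }
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        df.to_csv(out / "threshold_map.csv", index=False)
        (out / "threshold_summary.json").write_text(json.dumps(
            {k: v for k, v in result.items() if k != "table"}, indent=2))
        config.write_manifest(out / "manifest.json")
    return result


def run_stress_comparison(config: RunConfig,
                          out_dir: str | Path | None = None) -> dict:
    """Stress-mechanism comparison for the high-amplitude case."""
    pulse = config.pulse(config.p_a_high)
    radial = solve_radial(pulse, config.bubble, config.shell, config.medium)
    translation = solve_translation(radial, pulse, config.medium, config.cell)
    series, table = stress_report(
        radial, translation, pulse, config.medium, config.jet(),
        u_stream=config.u_stream, frame_rate=config.frame_rate,
        expansion_threshold=config.expansion_threshold,
    )
    result = {"series": series, "table": table,
              "radial": radial, "translation": translation}
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        series.to_frame().to_csv(out / "stress_series.csv", index=False)
        (out / "stress_peaks.json").write_text(json.dumps(table, indent=2))
        config.write_manifest(out / "manifest.json")
    return result
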