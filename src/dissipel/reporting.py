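"""Report generation: DP(t) tables, energy-loss summaries, correlations.

CSV output uses 9 significant digits and a fixed row order so identical
inputs reproduce byte-identical files (regression-friendly).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import stats

from .bernoulli import MethodComparison
from .core import ValidationError
from .dissipation import PowerSeries

__all__ = ["pearson_r", "EnergyLossReport", "build_report"]

log = logging.getLogger("dissipel")


def pearson_r(x, y) -> float:
    """Pearson product-moment correlation of two equal-length samples (n >= 3)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 3:
        raise ValidationError("pearson_r needs two equal-length 1-D samples of length >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValidationError("undefined correlation: constant input")
    return float(stats.pearsonr(x, y).statistic)


@dataclass
class EnergyLossReport:
    """Collected outputs of one run: per-segment DP(t), ELs and comparisons."""

    dp_series: dict = field(default_factory=dict)  # region -> PowerSeries
    el_df: dict = field(default_factory=dict)  # region -> W
    el_be: float | None = None
    comparison: MethodComparison | None = None
    el_df_an: float | None = None
    el_be_an: float | None = None
    correlation_r: float | None = None

    def to_dict(self) -> dict:
        out = {
            "el_df_w": self.el_df,
            "el_be_w": self.el_be,
            "el_df_an_w": self.el_df_an,
            "el_be_an_w": self.el_be_an,
            "correlation_r": self.correlation_r,
        }
        if self.comparison is not None:
            c = self.comparison
            out["comparison"] = {
                "el_df_w": c.el_df,
                "el_be_w": c.el_be,
                "relative_difference": c.relative_difference,
                "sac_el_df_w": c.sac_el_df,
                "sac_el_be_w": c.sac_el_be,
                "sac_relative_difference": c.sac_relative_difference,
                "sac_discrepant": c.sac_discrepant,
            }
        return out


def _g9(v) -> str:
    return "" if v is None else f"{float(v):.9g}"


def build_report(output_dir, report: EnergyLossReport) -> Path:
    """Write report.json, dp_series.csv, energy_loss.csv and sac_comparison.csv.

    Returns the output directory.  Row order: segments in insertion order,
    times ascending — deterministic for identical inputs.
    """
    out = Path(output_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "report.json").write_text(json.dumps(report.to_dict(), indent=2, sort_keys=True) + "\n")

    lines = ["time_s,segment,dp_w"]
    for region, ps in report.dp_series.items():
        if not isinstance(ps, PowerSeries):
            raise ValidationError("dp_series values must be PowerSeries")
        for t, dp in zip(ps.times, ps.dp_values):
            lines.append(f"{_g9(t)},{region},{_g9(dp)}")
    (out / "dp_series.csv").write_text("\n".join(lines) + "\n")

    lines = ["region,el_df_w,el_be_w,rel_diff"]
    for region, el in report.el_df.items():
        if region == "domain" and report.comparison is not None:
            c = report.comparison
            lines.append(f"{region},{_g9(el)},{_g9(c.el_be)},{_g9(c.relative_difference)}")
        else:
            lines.append(f"{region},{_g9(el)},,")
    (out / "energy_loss.csv").write_text("\n".join(lines) + "\n")

    lines = ["quantity,value_w"]
    if report.el_df_an is not None:
        lines.append(f"el_df_an,{_g9(report.el_df_an)}")
    if report.el_be_an is not None:
        lines.append(f"el_be_an,{_g9(report.el_be_an)}")
    if report.el_df_an is not None and report.el_be_an is not None:
        lines.append(f"signed_difference,{_g9(report.el_df_an - report.el_be_an)}")
    (out / "sac_comparison.csv").write_text("\n".join(lines) + "\n")
    log.info("report written to %s", out)
    return out
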