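"""Validation statistics for a migration-measurement method.

Two study designs establish the method's error characteristics:

* **Precision** -- double measurements: repeated scans with *zero* true
  displacement (the phantom is removed from the gantry and replaced between
  scans).  Any measured motion is error; precision per axis is 1.96 x the
  sample standard deviation of those errors.
* **Accuracy** -- a motion stage imposes known single-axis displacements;
  accuracy per axis is 1.96 x the root-mean-square error between imposed
  and measured values.

Agreement is visualised with Bland-Altman constructions (pair mean vs
signed difference, bias and 1.96 SD limits of agreement), inter-observer
reproducibility with a variance-ratio F test about the expected zero error,
and normality with the Shapiro-Wilk test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .kinematics import AXES, MigrationResult, decompose, invert, recompose
from .registration import MeasureConfig, measure_migration
from .synthetic_phantom import (MotionStep, PhantomSpec, default_protocol,
                                render)

__all__ = [
    "ValidationTable",
    "BlandAltman",
    "precision",
    "accuracy",
    "mean_signed_error",
    "bland_altman",
    "observer_f_test",
    "normality_check",
    "run_precision_study",
    "run_accuracy_study",
]

_UNITS = {"tx": "mm", "ty": "mm", "tz": "mm",
          "rx": "deg", "ry": "deg", "rz": "deg"}


# --------------------------------------------------------------------------
# elementary statistics


def precision(errors) -> float:
    """1.96 x sample standard deviation (n-1 denominator) of signed
    double-measurement errors."""
    e = np.asarray(errors, dtype=float)
    if e.size < 2:
        raise ValueError("precision needs at least 2 errors")
    return 1.96 * float(np.std(e, ddof=1))


def accuracy(imposed, measured) -> float:
    """1.96 x root-mean-square error between imposed and measured values."""
    imp = np.asarray(imposed, dtype=float)
    mea = np.asarray(measured, dtype=float)
    if imp.shape != mea.shape:
        raise ValueError("imposed and measured must have equal length")
    if imp.size < 1:
        raise ValueError("accuracy needs at least one pair")
    return 1.96 * float(np.sqrt(np.mean((mea - imp) ** 2)))


def mean_signed_error(errors) -> float:
    e = np.asarray(errors, dtype=float)
    if e.size < 1:
        raise ValueError("empty error list")
    return float(np.mean(e))


@dataclass(frozen=True)
class BlandAltman:
    """Per-pair (mean, difference) points with bias and limits of agreement."""

    means: np.ndarray
    differences: np.ndarray  # measured - imposed
    bias: float
    loa_lower: float
    loa_upper: float


def bland_altman(imposed, measured) -> BlandAltman:
    """Bland-Altman construction: x = (imposed + measured)/2,
    y = measured - imposed; bias and bias +- 1.96 SD limits of agreement."""
    imp = np.asarray(imposed, dtype=float)
    mea = np.asarray(measured, dtype=float)
    if imp.shape != mea.shape:
        raise ValueError("imposed and measured must have equal length")
    if imp.size < 2:
        raise ValueError("Bland-Altman needs at least 2 pairs")
    diff = mea - imp
    bias = float(diff.mean())
    half = 1.96 * float(np.std(diff, ddof=1))
    return BlandAltman((imp + mea) / 2.0, diff, bias, bias - half, bias + half)


def bland_altman_plot(ba: BlandAltman, ax=None, label: str = ""):
    """Draw the agreement plot; returns the matplotlib axes."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    ax.scatter(ba.means, ba.differences, s=14)
    for y, style in ((ba.bias, "-"), (ba.loa_lower, "--"), (ba.loa_upper, "--")):
        ax.axhline(y, linestyle=style, color="grey")
    ax.set_xlabel(f"mean of imposed and measured {label}".strip())
    ax.set_ylabel("measured - imposed")
    return ax


def observer_f_test(errors_a, errors_b) -> tuple[float, float]:
    """Variance-ratio F test of two observers' errors about the expected
    zero error.

    Variances are mean squares about zero (no mean is estimated, honouring
    the zero-error null), F is the larger over the smaller, and the
    two-sided p comes from the F distribution with degrees of freedom
    ordered to match.  Identical inputs give F = 1, p = 1.
    """
    a = np.asarray(errors_a, dtype=float)
    b = np.asarray(errors_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each observer needs at least 2 errors")
    va = float(np.mean(a**2))
    vb = float(np.mean(b**2))
    if min(va, vb) == 0.0:
        raise ValueError("zero variance in denominator")
    if va >= vb:
        f, dfn, dfd = va / vb, a.size, b.size
    else:
        f, dfn, dfd = vb / va, b.size, a.size
    p = min(1.0, 2.0 * float(stats.f.sf(f, dfn, dfd)))
    return f, p


def normality_check(errors) -> tuple[float, float]:
    """Shapiro-Wilk W statistic and p-value (3 <= n <= 5000)."""
    e = np.asarray(errors, dtype=float)
    if not 3 <= e.size <= 5000:
        raise ValueError(f"Shapiro-Wilk supports 3 <= n <= 5000, got {e.size}")
    if np.ptp(e) == 0:
        raise ValueError("constant input has no distribution to test")
    res = stats.shapiro(e)
    return float(res.statistic), float(res.pvalue)


# --------------------------------------------------------------------------
# tables


@dataclass
class ValidationTable:
    """Signed errors for one axis with the derived summary statistics.

    For accuracy studies ``imposed``/``measured`` carry the raw pairs so
    Bland-Altman constructions can be rebuilt; for precision studies the
    errors are the double-measurement readings themselves (truth is zero).
    """

    axis: str
    errors: np.ndarray
    imposed: np.ndarray | None = None
    measured: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.errors = np.asarray(self.errors, dtype=float).reshape(-1)
        if self.errors.size < 2:
            raise ValueError("a validation table needs n >= 2 errors")

    @property
    def n(self) -> int:
        return self.errors.size

    @property
    def unit(self) -> str:
        return _UNITS[self.axis]

    def mean_signed_error(self) -> float:
        return mean_signed_error(self.errors)

    def sd(self) -> float:
        return float(np.std(self.errors, ddof=1))

    def precision(self) -> float:
        return precision(self.errors)

    def accuracy(self) -> float:
        return 1.96 * float(np.sqrt(np.mean(self.errors**2)))

    def bland_altman(self) -> BlandAltman:
        if self.imposed is None or self.measured is None:
            raise ValueError("no imposed/measured pairs stored on this table")
        return bland_altman(self.imposed, self.measured)


def tables_to_frame(tables: dict, kind: str) -> pd.DataFrame:
    """Summarise per-axis tables as a DataFrame (one row per axis)."""
    rows = []
    for axis in AXES:
        if axis not in tables:
            continue
        t = tables[axis]
        row = {"axis": axis, "unit": t.unit, "n": t.n,
               "mean_signed_error": t.mean_signed_error(), "sd": t.sd()}
        if kind == "precision":
            row["precision_1_96sd"] = t.precision()
        else:
            row["accuracy_1_96rms"] = t.accuracy()
        rows.append(row)
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# study harnesses


@dataclass
class StudyResult:
    tables: dict
    excluded_steps: list
    reports: list

    def to_frame(self, kind: str) -> pd.DataFrame:
        return tables_to_frame(self.tables, kind)


def _random_repositioning(rng: np.random.Generator, sd_mm: float,
                          sd_deg: float) -> MigrationResult:
    t = rng.normal(0.0, sd_mm, 3) if sd_mm > 0 else np.zeros(3)
    r = rng.normal(0.0, sd_deg, 3) if sd_deg > 0 else np.zeros(3)
    return MigrationResult(t[0], t[1], t[2], r[0], r[1], r[2])


def run_precision_study(spec: PhantomSpec, n_repeats: int = 9, seed: int = 0,
                        cfg: MeasureConfig | None = None,
                        reposition_sd_mm: float = 0.2,
                        reposition_sd_deg: float = 0.2) -> StudyResult:
    """Double-measurement precision study on the digital phantom.

    One reference scan is followed by ``n_repeats`` scans with zero imposed
    displacement, fresh noise, and a small random rigid repositioning of
    the whole phantom (it is "removed from the gantry and placed back").
    Each repeat is measured against the reference; per-axis 1.96 x SD of
    the readings is the precision.
    """
    if n_repeats < 2:
        raise ValueError("need at least 2 repeats")
    cfg = cfg or MeasureConfig.for_phantom(spec)
    rng = np.random.default_rng([seed, 917])
    reference = render(spec, noise_seed=[seed, 0])
    errors = {axis: [] for axis in AXES}
    excluded, reports = [], []
    for k in range(1, n_repeats + 1):
        pose = recompose(_random_repositioning(rng, reposition_sd_mm,
                                               reposition_sd_deg))
        scan = render(spec, global_pose=pose, noise_seed=[seed, k])
        report = measure_migration(reference, scan, cfg)
        reports.append(report)
        if not report.qc.acceptable:
            excluded.append((f"repeat_{k}", report.qc.flags))
            continue
        for axis, value in zip(AXES, report.result.as_array()):
            errors[axis].append(value)
    tables = {axis: ValidationTable(axis, v) for axis, v in errors.items()
              if len(v) >= 2}
    return StudyResult(tables, excluded, reports)


def expected_measurement(imposed: MigrationResult,
                         reference_point) -> MigrationResult:
    """Ground-truth reading for a phantom step.

    The rig moves the *markers* around a fixed implant, while the method
    reports implant motion relative to the markers -- the inverse transform
    -- decomposed about the measurement's reference point."""
    return decompose(invert(recompose(imposed)), reference_point)


def run_accuracy_study(spec: PhantomSpec,
                       protocol: list[MotionStep] | None = None,
                       seed: int = 0,
                       cfg: MeasureConfig | None = None) -> StudyResult:
    """Imposed-vs-measured accuracy study on the digital phantom.

    Renders one reference scan plus one target per protocol step (default:
    the full 17-translation + 15-rotation schedule), measures each pair,
    and tabulates per-axis signed errors against the ground-truth reading.
    Steps whose QC flags fire are excluded from the tables and listed, so a
    failed scan is bookkept rather than silently averaged in.
    """
    if protocol is None:
        protocol = (default_protocol("translations", spec.stage_centre)
                    + default_protocol("rotations", spec.stage_centre))
    if not protocol:
        raise ValueError("empty protocol")
    cfg = cfg or MeasureConfig.for_phantom(spec)
    reference = render(spec, noise_seed=[seed, 0])
    imposed = {axis: [] for axis in AXES}
    measured = {axis: [] for axis in AXES}
    excluded, reports = [], []
    for k, step in enumerate(protocol, start=1):
        displacement = recompose(step.imposed)
        scan = render(spec, displacement=displacement, noise_seed=[seed, k])
        report = measure_migration(reference, scan, cfg)
        reports.append(report)
        if not report.qc.acceptable:
            excluded.append((step.label, report.qc.flags))
            continue
        truth = expected_measurement(step.imposed,
                                     report.result.reference_point)
        for axis, m, t in zip(AXES, report.result.as_array(), truth.as_array()):
            imposed[axis].append(t)
            measured[axis].append(m)
    tables = {
        axis: ValidationTable(axis,
                              np.asarray(measured[axis]) - np.asarray(imposed[axis]),
                              imposed=np.asarray(imposed[axis]),
                              measured=np.asarray(measured[axis]))
        for axis in AXES if len(measured[axis]) >= 2
    }
    return StudyResult(tables, excluded, reports)
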