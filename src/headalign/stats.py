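"""Alignment quality metrics and the accompanying statistics.

Two assessment surfaces:

*Skull base* — millimetre deviations between the transformed right and
left cochlear points along y (anterior-posterior) and z (craniocaudal).
Perfect alignment is y and z deviations of 0; a method that aligns the
cochleas symmetrically drives both toward zero.

*Whole head* — signed per-plane angular deviations from the canonical
orientation, reported in whole degrees with clockwise misalignment
positive (the sign convention of standard radiological display:
e.g. an axial falx line tilted 4.64 degrees clockwise reads +5).
On phantoms the human raters are replaced by an analytic decomposition
of the residual rotation, but the signed/rounded reporting convention
is preserved so outputs stay in the same units as manual review.

Statistics: cohorts of deviations are compared with a two-sided
Wilcoxon signed-rank test on *absolute* deviations (signed clockwise /
counter-clockwise errors cancel in a mean and would mask
misalignment), gated by Shapiro-Wilk normality; inter-rater
reliability uses ICC(1,k) — one-way random effects, average of k
raters, absolute agreement — implemented from the one-way ANOVA mean
squares and cross-checked against an independent reference
implementation in the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .align import RigidTransform, decompose_rotation
from .errors import ConfigurationError, DegenerateStatisticsError
from .landmarks import LandmarkSet
from .phantom import MisalignmentSpec

__all__ = [
    "CochlearDeviation",
    "PlaneDeviations",
    "SummaryTable",
    "cochlear_deviation",
    "plane_deviation_from_truth",
    "signed_rounded_degrees",
    "paired_wilcoxon_abs",
    "shapiro_wilk_gate",
    "icc_1k",
    "summarize_deviations",
]


@dataclass(frozen=True)
class CochlearDeviation:
    """Per-subject |y| and |z| deviation (mm) between the two cochleas."""

    y_dev_mm: float
    z_dev_mm: float
    subject_id: str = ""

    def __post_init__(self) -> None:
        if self.y_dev_mm < 0 or self.z_dev_mm < 0:
            raise ConfigurationError("deviations are absolute and must be >= 0")


@dataclass(frozen=True)
class PlaneDeviations:
    """Signed per-plane angular deviation (degrees, clockwise positive)."""

    axial_deg: float
    sagittal_deg: float
    coronal_deg: float
    rounded: bool = False

    def round_whole(self) -> "PlaneDeviations":
        """Whole-degree reporting, half away from zero."""
        return PlaneDeviations(
            axial_deg=_round_half_away(self.axial_deg),
            sagittal_deg=_round_half_away(self.sagittal_deg),
            coronal_deg=_round_half_away(self.coronal_deg),
            rounded=True,
        )

    def as_array(self) -> np.ndarray:
        return np.array([self.axial_deg, self.sagittal_deg, self.coronal_deg])


def cochlear_deviation(landmarks: LandmarkSet, subject_id: str = "") -> CochlearDeviation:
    """Absolute y and z differences between the cochlear points."""
    d = landmarks.left_cochlea - landmarks.right_cochlea
    return CochlearDeviation(
        y_dev_mm=float(abs(d[1])), z_dev_mm=float(abs(d[2])), subject_id=subject_id
    )


def plane_deviation_from_truth(
    applied: "MisalignmentSpec | RigidTransform | np.ndarray",
    recovered: RigidTransform,
) -> PlaneDeviations:
    """Residual per-plane angles after alignment of a known misalignment.

    ``applied`` rotated the canonical phantom; ``recovered`` is the
    alignment the method then computed. Their composition is the
    residual rotation away from canonical, decomposed into axial
    (yaw, about z), sagittal (pitch, about x) and coronal (roll,
    about y) angles in the same z->x->y convention the alignment uses.
    Perfect recovery gives (0, 0, 0); no recovery at all returns the
    applied angles themselves.
    """
    if isinstance(applied, MisalignmentSpec):
        R_applied = applied.rotation_matrix()
    elif isinstance(applied, RigidTransform):
        R_applied = applied.rotation
    else:
        R_applied = np.asarray(applied, dtype=float)
    residual = recovered.rotation @ R_applied
    yaw, pitch, roll = decompose_rotation(residual)
    return PlaneDeviations(axial_deg=yaw, sagittal_deg=pitch, coronal_deg=roll)


def _round_half_away(x: float) -> int:
    return int(np.sign(x) * np.floor(abs(x) + 0.5))


def signed_rounded_degrees(angle_deg: float, direction: str) -> int:
    """Whole-degree signed reading of an angular misalignment.

    Clockwise misalignment is reported positive, counter-clockwise
    negative; magnitudes round half away from zero. E.g. 4.64 degrees
    clockwise -> +5; 5.26 degrees counter-clockwise -> -5.
    """
    if angle_deg < 0:
        raise ConfigurationError("angle magnitude must be >= 0")
    if direction not in ("clockwise", "counter-clockwise"):
        raise ConfigurationError(f"direction must be clockwise/counter-clockwise, got {direction!r}")
    sign = 1 if direction == "clockwise" else -1
    return sign * _round_half_away(angle_deg)


def paired_wilcoxon_abs(before, after) -> tuple[float, float]:
    """Two-sided Wilcoxon signed-rank test on |before| vs |after|.

    Zero paired differences are dropped (the classical Wilcoxon
    convention). Exact p-values where scipy's exact path applies
    (small n, no ties), normal approximation otherwise.
    """
    b = np.abs(np.asarray(before, dtype=float))
    a = np.abs(np.asarray(after, dtype=float))
    if b.shape != a.shape or b.ndim != 1:
        raise ConfigurationError("before/after must be equal-length 1D samples")
    if b.size < 5:
        raise ConfigurationError("need at least 5 pairs")
    if np.all(b == a):
        raise DegenerateStatisticsError("all paired differences are zero")
    res = sps.wilcoxon(b, a, zero_method="wilcox", alternative="two-sided", method="auto")
    return float(res.statistic), float(res.pvalue)


def shapiro_wilk_gate(sample, alpha: float = 0.05) -> bool:
    """True if the sample looks normal (Shapiro-Wilk p >= alpha).

    Steers cohort comparisons to the nonparametric signed-rank test
    when False. Degenerate (constant) samples are rejected.
    """
    x = np.asarray(sample, dtype=float)
    if x.size < 3:
        raise ConfigurationError("Shapiro-Wilk needs at least 3 observations")
    if np.ptp(x) == 0:
        raise DegenerateStatisticsError("constant sample: normality test undefined")
    return bool(sps.shapiro(x).pvalue >= alpha)


def icc_1k(matrix, confidence: float = 0.95) -> tuple[float, tuple[float, float]]:
    """ICC(1,k): one-way random effects, average-measures, absolute agreement.

    From the one-way ANOVA across subjects (rows) with raters (columns)
    as replicate measurements:

        ICC(1,k) = (MS_between - MS_within) / MS_between

    CI from F = MS_between / MS_within with (n-1, n(k-1)) df:
    lower = 1 - 1/(F / F_upper), upper = 1 - 1/(F * F_lower'),
    the standard one-way construction.
    """
    X = np.asarray(matrix, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2 or X.shape[1] < 2:
        raise ConfigurationError("rater matrix must be at least 2 subjects x 2 raters")
    if np.any(~np.isfinite(X)):
        raise ConfigurationError("rater matrix must have no missing cells")
    n, k = X.shape
    row_means = X.mean(axis=1)
    grand = X.mean()
    ms_between = k * np.sum((row_means - grand) ** 2) / (n - 1)
    ms_within = np.sum((X - row_means[:, None]) ** 2) / (n * (k - 1))
    if ms_between <= 0:
        raise DegenerateStatisticsError("no between-subject variance: ICC undefined")
    icc = (ms_between - ms_within) / ms_between

    alpha = 1.0 - confidence
    df1, df2 = n - 1, n * (k - 1)
    if ms_within == 0:
        return float(icc), (1.0, 1.0)
    f_obs = ms_between / ms_within
    f_lower = f_obs / sps.f.ppf(1 - alpha / 2, df1, df2)
    f_upper = f_obs * sps.f.ppf(1 - alpha / 2, df2, df1)
    return float(icc), (float(1 - 1 / f_lower), float(1 - 1 / f_upper))


@dataclass(frozen=True)
class SummaryTable:
    """Cohort summary of absolute deviations per condition, plus the
    paired Wilcoxon p-value between the two conditions (if paired)."""

    table: pd.DataFrame  # index: condition; columns: n, mean, median, sd, min, max
    p_value: float | None = None

    def to_text(self) -> str:
        lines = [self.table.to_string(float_format=lambda v: f"{v:.3f}")]
        if self.p_value is not None:
            lines.append(f"paired Wilcoxon p-value: {self.p_value:.3g}")
        return "\n".join(lines)

    def to_csv(self, path) -> None:
        self.table.to_csv(path)


def summarize_deviations(deviations: dict, paired: bool = True) -> SummaryTable:
    """Tabulate mean/median/SD/range of absolute deviations per condition.

    ``deviations`` maps condition name -> 1D sequence of deviations
    (mm or degrees; absolute values are taken). With ``paired`` and
    exactly two conditions of equal length, a paired Wilcoxon
    signed-rank p-value on the absolute deviations is attached.
    """
    if not deviations:
        raise ConfigurationError("no conditions given")
    rows = {}
    lengths = set()
    for cond, vals in deviations.items():
        v = np.abs(np.asarray(vals, dtype=float))
        if v.ndim != 1 or v.size < 2:
            raise ConfigurationError(f"condition {cond!r} needs >= 2 subjects")
        lengths.add(v.size)
        rows[cond] = {
            "n": v.size,
            "mean": v.mean(),
            "median": float(np.median(v)),
            "sd": v.std(ddof=1),
            "min": v.min(),
            "max": v.max(),
        }
    table = pd.DataFrame.from_dict(rows, orient="index")
    p_value = None
    if paired and len(deviations) == 2:
        if len(lengths) != 1:
            raise ConfigurationError("paired summary requires equal-length conditions")
        a, b = (np.asarray(v, dtype=float) for v in deviations.values())
        p_value = paired_wilcoxon_abs(a, b)[1]
    return SummaryTable(table=table, p_value=p_value)
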