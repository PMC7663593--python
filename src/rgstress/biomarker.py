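"""Subject-level RG conditioning and group-level curves and correlations.

Per subject the relative-gamma series is smoothed with a centred 19-point
moving average, resampled to a common 480-point grid, classified as a
direct or inverse responder by the MIST-vs-relax mean contrast, and (for
inverse responders) reflected about its own mean so that all subjects share
the same stress polarity before averaging.  Group curves are pointwise
grand averages with SEM; a 6th-degree polynomial fitted on a rescaled
abscissa summarises each curve, and curve similarity is quantified by the
Pearson correlation with a Fisher-z 95% confidence interval.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from numpy.polynomial import Polynomial
from scipy import stats as ss

from .spectral import RGSeries

__all__ = [
    "ResponderLabel",
    "GroupCurve",
    "PolyFit",
    "CorrelationResult",
    "smooth_moving_average",
    "resample_to_length",
    "classify_responder",
    "orient_rg",
    "grand_average_sem",
    "fit_poly6",
    "pcc_with_ci",
    "fisher_ci",
]


@dataclass(frozen=True)
class ResponderLabel:
    """Responder polarity and the decision statistic it came from.

    The statistic is mean(RG | MIST task) - mean(RG | relax); non-negative
    values (including ties) classify as direct.
    """

    polarity: str  # 'direct' | 'inverse'
    statistic: float


@dataclass
class GroupCurve:
    """Pointwise grand average and SEM of the oriented RG curves of a group."""

    mean: np.ndarray
    sem: np.ndarray
    n_subjects: int
    group: str = ""


@dataclass
class PolyFit:
    """Least-squares polynomial summary of a group curve."""

    degree: int
    coefficients: np.ndarray  # on the rescaled [-1, 1] abscissa
    fitted: np.ndarray


@dataclass(frozen=True)
class CorrelationResult:
    """Pearson correlation with a Fisher-z confidence interval."""

    pcc: float
    ci_low: float | None
    ci_up: float | None
    level: float
    n: int


def smooth_moving_average(rg: RGSeries, span: int = 19) -> RGSeries:
    """Centred moving average of odd ``span``; the window shrinks symmetrically
    at the edges so the output has the same length with no phase shift.

    A span of 19 two-second epochs smears any sharp transition over ~18 s on
    either side, which is why curve extrema lag their true onsets by roughly
    20 s.
    """
    if span < 1 or span % 2 == 0:
        raise ValueError(f"span must be odd and >= 1, got {span} (use e.g. 19 or 21)")
    x = np.asarray(rg.values, dtype=float)
    if not np.isfinite(x).all():
        raise ValueError("series contains missing values; interpolate first")
    n = len(x)
    h = (span - 1) // 2
    if h == 0:
        return replace(rg, values=x.copy(), smoothing_span=span)
    c = np.concatenate([[0.0], np.cumsum(x)])
    out = np.empty(n)
    for i in range(n):
        hi = min(h, i, n - 1 - i)
        out[i] = (c[i + hi + 1] - c[i - hi]) / (2 * hi + 1)
    return replace(rg, values=out, smoothing_span=span)


def resample_to_length(rg: RGSeries, target: int = 480) -> RGSeries:
    """Linear interpolation onto ``target`` equally spaced points.

    The new grid spans the original index range, so the endpoints are
    preserved and an input already at the target length is returned
    unchanged (up to floating point identity).
    """
    if target < 2:
        raise ValueError("target length must be >= 2")
    x = np.asarray(rg.values, dtype=float)
    n = len(x)
    if n < 2:
        raise ValueError("need at least 2 points to resample")
    if n == target:
        return replace(rg, resampled_length=target)
    new_idx = np.linspace(0, n - 1, target)
    values = np.interp(new_idx, np.arange(n), x)
    scale = target / n
    boundaries = {
        k: (int(round(s * scale)), int(round(e * scale)))
        for k, (s, e) in rg.epoch_boundaries.items()
    }
    return replace(rg, values=values, resampled_length=target, epoch_boundaries=boundaries)


def classify_responder(
    rg: RGSeries, boundaries: dict[str, tuple[int, int]] | None = None
) -> ResponderLabel:
    """Direct/inverse polarity from the MIST-task-minus-relax mean contrast.

    An automated surrogate for per-subject visual inspection: a subject
    whose RG is higher under the stressor than during relaxation responds
    directly; ties classify as direct.
    """
    b = boundaries if boundaries is not None else rg.epoch_boundaries
    for phase in ("MIST_TASK", "RELAX"):
        if phase not in b:
            raise ValueError(f"boundary map lacks {phase!r}")
        s, e = b[phase]
        if e <= s:
            raise ValueError(f"phase {phase!r} is empty")
    x = np.asarray(rg.values, dtype=float)
    task = x[slice(*b["MIST_TASK"])]
    relax = x[slice(*b["RELAX"])]
    delta = float(np.nanmean(task) - np.nanmean(relax))
    return ResponderLabel("direct" if delta >= 0 else "inverse", delta)


def orient_rg(rg: RGSeries, label: ResponderLabel) -> RGSeries:
    """Reflect inverse responders about their own mean; leave direct ones alone.

    Reflection (x -> 2*mean - x) preserves the location and scale of the
    series, so oriented direct and inverse subjects remain averageable; it
    is an involution, and applying it twice restores the input.
    """
    if label.polarity == "direct":
        return replace(rg, polarity="direct")
    x = np.asarray(rg.values, dtype=float)
    return replace(rg, values=2.0 * x.mean() - x, polarity="inverse")


def grand_average_sem(series: list[RGSeries], group: str = "") -> GroupCurve:
    """Pointwise mean and standard error across subjects."""
    if len(series) < 2:
        raise ValueError("need at least 2 subjects for a group curve")
    lengths = {len(s.values) for s in series}
    if len(lengths) > 1:
        raise ValueError(f"series lengths differ: {sorted(lengths)}")
    stack = np.vstack([s.values for s in series])
    mean = stack.mean(axis=0)
    sem = stack.std(axis=0, ddof=1) / np.sqrt(stack.shape[0])
    return GroupCurve(mean=mean, sem=sem, n_subjects=stack.shape[0], group=group)


def fit_poly6(y: np.ndarray, degree: int = 6) -> PolyFit:
    """Least-squares polynomial fit on an abscissa rescaled to [-1, 1].

    Rescaling keeps the degree-6 Vandermonde system well conditioned
    (raw indices 0..479 would be numerically hostile).
    """
    y = np.asarray(y, dtype=float)
    n = len(y)
    if n < degree + 1:
        raise ValueError(f"need at least {degree + 1} points for degree {degree}")
    p = Polynomial.fit(np.arange(n), y, degree)
    return PolyFit(degree=degree, coefficients=p.coef.copy(), fitted=p(np.arange(n)))


def fisher_ci(r: float, n: int, level: float = 0.95) -> tuple[float, float]:
    """Fisher-z confidence interval: tanh(atanh(r) +/- z* / sqrt(n - 3))."""
    if n < 4:
        raise ValueError("Fisher interval needs n >= 4")
    if abs(r) >= 1.0:
        return (r, r)
    zcrit = ss.norm.ppf(0.5 + level / 2.0)
    z = np.arctanh(r)
    hw = zcrit / np.sqrt(n - 3)
    return float(np.tanh(z - hw)), float(np.tanh(z + hw))


def pcc_with_ci(a: np.ndarray, b: np.ndarray, level: float = 0.95) -> CorrelationResult:
    """Pearson correlation of two equal-length curves with a Fisher-z CI.

    The interval treats the curve points as independent observations; the
    autocorrelation of smoothed/fitted curves is ignored, which makes the
    interval optimistic.  This is a documented caveat, not corrected for.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("curves must have equal length")
    n = len(a)
    if n < 4:
        raise ValueError("need n >= 4")
    if a.std() == 0 or b.std() == 0:
        raise ValueError("curve has zero variance")
    r = float(ss.pearsonr(a, b).statistic)
    lo, up = fisher_ci(r, n, level)
    return CorrelationResult(pcc=r, ci_low=lo, ci_up=up, level=level, n=n)
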