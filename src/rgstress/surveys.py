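"""Survey statistics: normality gate, exact Wilcoxon tests, and the
stress-vs-biomarker correlation at the four survey instants.

The self-perceived stress level (SPSL) is a 1-5 integer collected at four
instants: T1 before the first resting state, T2 right after the MIST, T3
90 s into relaxation and T4 at its end.  Because such data are discrete and
non-normal (the normality gate is a Lilliefors test with a seeded
Monte-Carlo null), phase and group contrasts use the Wilcoxon signed-rank
test: exact by enumeration of the signed-rank distribution (mid-ranks for
ties, zero differences discarded) for effective n <= 25, a tie-corrected
normal approximation above.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as ss

from .biomarker import CorrelationResult

logger = logging.getLogger(__name__)

__all__ = [
    "SPSLRecord",
    "TestResult",
    "InstantSummary",
    "INSTANTS",
    "lilliefors_test",
    "wilcoxon_signed_rank",
    "summarize_spsl",
    "rg_at_instants",
    "default_instant_epochs",
    "correlate_spsl_rg",
]

INSTANTS = ("T1", "T2", "T3", "T4")

EXACT_WILCOXON_MAX_N = 25


@dataclass(frozen=True)
class SPSLRecord:
    """One subject's four survey responses."""

    subject_id: str
    group: str
    responses: tuple[int, int, int, int]

    def __post_init__(self) -> None:
        if len(self.responses) != 4:
            raise ValueError("need exactly four responses T1..T4")
        if any(not (1 <= int(r) <= 5) for r in self.responses):
            raise ValueError("responses must be integers in [1, 5]")


@dataclass(frozen=True)
class TestResult:
    """Outcome of one hypothesis test at significance level ``alpha``."""

    method: str
    statistic: float
    p_value: float
    n: int
    alpha: float = 0.05
    notes: str = ""

    @property
    def significant(self) -> bool:
        return self.p_value < self.alpha


@dataclass
class InstantSummary:
    """Per group x instant SPSL mean/sd plus the test battery."""

    means: pd.DataFrame  # index: group, columns T1..T4
    sds: pd.DataFrame
    within_group: dict[tuple[str, str], TestResult]  # (group, 'T1-T2') -> result
    between_group: dict[str, TestResult]  # instant -> result
    normality: dict[str, TestResult | None] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# Lilliefors normality test
# ---------------------------------------------------------------------------


def _lilliefors_statistic(x: np.ndarray) -> float:
    """KS distance between the sample ECDF and a normal with estimated
    mean/sd (the composite-null variant of the KS statistic)."""
    n = x.shape[-1]
    z = np.sort(x, axis=-1)
    mu = z.mean(axis=-1, keepdims=True)
    sd = z.std(axis=-1, ddof=1, keepdims=True)
    cdf = ss.norm.cdf((z - mu) / sd)
    grid_hi = np.arange(1, n + 1) / n
    grid_lo = np.arange(0, n) / n
    d_plus = (grid_hi - cdf).max(axis=-1)
    d_minus = (cdf - grid_lo).max(axis=-1)
    return np.maximum(d_plus, d_minus)


def lilliefors_test(
    x, alpha: float = 0.05, mc_samples: int = 10000, seed: int = 0
) -> TestResult:
    """Lilliefors normality test with a seeded Monte-Carlo null.

    The null distribution of the statistic is simulated by drawing
    ``mc_samples`` standard-normal samples of the same size and computing
    the same statistic; the p-value is ``(1 + #{D_mc >= D}) / (mc + 1)``,
    bit-reproducible for a given seed.
    """
    x = np.asarray(x, dtype=float)
    n = len(x)
    if n < 4:
        raise ValueError("Lilliefors test needs n >= 4")
    if x.std(ddof=1) == 0:
        raise ValueError("sample is constant (sd = 0)")
    d = float(_lilliefors_statistic(x))
    rng = np.random.default_rng(seed)
    null = _lilliefors_statistic(rng.standard_normal((mc_samples, n)))
    p = (1 + int((null >= d).sum())) / (mc_samples + 1)
    return TestResult(
        method="lilliefors-mc", statistic=d, p_value=p, n=n, alpha=alpha,
        notes=f"monte-carlo null, {mc_samples} draws",
    )


# ---------------------------------------------------------------------------
# Wilcoxon signed-rank test
# ---------------------------------------------------------------------------


def _signed_rank_cdf_table(ranks2: np.ndarray) -> np.ndarray:
    """Exact distribution of the positive rank sum over all sign assignments.

    ``ranks2`` are the mid-ranks doubled so ties (.5 steps) become integers;
    returns ``counts[s] = #{sign patterns with doubled rank sum s}``.
    """
    total = int(ranks2.sum())
    counts = np.zeros(total + 1, dtype=float)
    counts[0] = 1.0
    for r in ranks2:
        r = int(r)
        shifted = np.zeros_like(counts)
        shifted[r:] = counts[: total + 1 - r]
        counts = counts + shifted
    return counts


def wilcoxon_signed_rank(x, y, alpha: float = 0.05) -> TestResult:
    """Two-sided Wilcoxon signed-rank test on paired samples.

    Zero differences are discarded (the effective n is reduced and noted);
    tied absolute differences receive mid-ranks.  For effective n <=
    ``EXACT_WILCOXON_MAX_N`` the p-value is exact, from the full null
    distribution of the rank sum over all 2^n sign assignments; larger
    samples use the normal approximation with tie correction and a 0.5
    continuity correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("paired samples must have equal length")
    if len(x) < 1:
        raise ValueError("need at least one pair")
    d = x - y
    nonzero = d != 0
    n_dropped = int((~nonzero).sum())
    d = d[nonzero]
    n = len(d)
    notes = f"{n_dropped} zero differences dropped" if n_dropped else ""
    if n == 0:
        return TestResult(
            method="wilcoxon-exact", statistic=0.0, p_value=1.0, n=0,
            alpha=alpha, notes=notes + "; all differences zero",
        )
    ranks = ss.rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    if n <= EXACT_WILCOXON_MAX_N:
        ranks2 = np.rint(2 * ranks).astype(int)
        counts = _signed_rank_cdf_table(ranks2)
        total = counts.sum()  # 2**n
        w2 = int(round(2 * w_plus))
        p_le = counts[: w2 + 1].sum() / total
        p_ge = counts[w2:].sum() / total
        p = min(1.0, 2.0 * min(p_le, p_ge))
        return TestResult(
            method="wilcoxon-exact", statistic=w_plus, p_value=p, n=n,
            alpha=alpha, notes=notes,
        )
    mu = n * (n + 1) / 4.0
    tie_sizes = np.unique(ranks, return_counts=True)[1]
    var = n * (n + 1) * (2 * n + 1) / 24.0 - ((tie_sizes**3 - tie_sizes).sum()) / 48.0
    z = (w_plus - mu - 0.5 * np.sign(w_plus - mu)) / np.sqrt(var)
    p = float(min(1.0, 2.0 * ss.norm.sf(abs(z))))
    return TestResult(
        method="wilcoxon-normal", statistic=w_plus, p_value=p, n=n,
        alpha=alpha, notes=(notes + "; tie-corrected normal approximation").strip("; "),
    )


# ---------------------------------------------------------------------------
# SPSL summaries (Fig. 7 / Tables 3-4 layout)
# ---------------------------------------------------------------------------


def spsl_frame(records: list[SPSLRecord]) -> pd.DataFrame:
    rows = [
        {"subject_id": r.subject_id, "group": r.group,
         **dict(zip(INSTANTS, r.responses))}
        for r in records
    ]
    return pd.DataFrame(rows)


def records_from_frame(df: pd.DataFrame) -> list[SPSLRecord]:
    return [
        SPSLRecord(
            subject_id=str(row["subject_id"]),
            group=str(row["group"]),
            responses=tuple(int(row[t]) for t in INSTANTS),
        )
        for _, row in df.iterrows()
    ]


def summarize_spsl(
    records: list[SPSLRecord] | pd.DataFrame,
    alpha: float = 0.05,
    lilliefors_seed: int = 0,
) -> InstantSummary:
    """Per-group SPSL means/sds and the full Wilcoxon test battery.

    Within each group, consecutive instants are compared pairwise
    (T1-T2, T2-T3, T3-T4); between groups, responses at each instant are
    compared by pairing subjects positionally (sorted subject order), which
    requires equal group sizes.  A Lilliefors normality gate is computed on
    each comparison's differences and reported alongside; the Wilcoxon test
    is always the decision test for this ordinal data.
    """
    df = records if isinstance(records, pd.DataFrame) else spsl_frame(records)
    groups = sorted(df["group"].unique())
    if len(groups) < 2:
        raise ValueError(f"need two groups, found {groups}")
    for g in groups:
        if (df["group"] == g).sum() < 2:
            raise ValueError(f"group {g!r} has fewer than 2 records")

    means = df.groupby("group")[list(INSTANTS)].mean()
    sds = df.groupby("group")[list(INSTANTS)].std(ddof=1)

    def _gate(diffs: np.ndarray, key: str) -> TestResult | None:
        try:
            return lilliefors_test(diffs, alpha=alpha, seed=lilliefors_seed)
        except ValueError as exc:
            logger.info("normality gate skipped for %s: %s", key, exc)
            return None

    within: dict[tuple[str, str], TestResult] = {}
    normality: dict[str, TestResult | None] = {}
    for g in groups:
        sub = df[df["group"] == g].sort_values("subject_id")
        for a, b in zip(INSTANTS[:-1], INSTANTS[1:]):
            key = f"{g}:{a}-{b}"
            xa = sub[a].to_numpy(dtype=float)
            xb = sub[b].to_numpy(dtype=float)
            within[(g, f"{a}-{b}")] = wilcoxon_signed_rank(xa, xb, alpha=alpha)
            normality[key] = _gate(xa - xb, key)

    g0 = df[df["group"] == groups[0]].sort_values("subject_id")
    g1 = df[df["group"] == groups[1]].sort_values("subject_id")
    if len(g0) != len(g1):
        raise ValueError(
            "between-group signed-rank comparison requires equal group sizes; "
            f"got {len(g0)} vs {len(g1)}"
        )
    between: dict[str, TestResult] = {}
    for t in INSTANTS:
        xa = g0[t].to_numpy(dtype=float)
        xb = g1[t].to_numpy(dtype=float)
        between[t] = wilcoxon_signed_rank(xa, xb, alpha=alpha)
        normality[f"between:{t}"] = _gate(xa - xb, f"between:{t}")

    return InstantSummary(
        means=means, sds=sds, within_group=within, between_group=between,
        normality=normality,
    )


# ---------------------------------------------------------------------------
# RG at the survey instants (Fig. 8 aggregation)
# ---------------------------------------------------------------------------


def default_instant_epochs(
    epoch_boundaries: dict[str, tuple[int, int]],
    t3_offset_epochs: int = 45,
) -> dict[str, int]:
    """Epoch indices of T1..T4 in the analysis window.

    T1 sits at the start of the window (the survey precedes RS1), T2 at the
    end of the MIST task, T3 90 s (45 epochs) into relaxation and T4 at the
    end of relaxation.
    """
    relax = epoch_boundaries["RELAX"]
    return {
        "T1": epoch_boundaries["RS1"][0],
        "T2": epoch_boundaries["MIST_TASK"][1],
        "T3": relax[0] + t3_offset_epochs,
        "T4": relax[1],
    }


def rg_at_instants(
    values: np.ndarray,
    instants: dict[str, int],
    half_window: int = 15,
) -> dict[str, float]:
    """Mean RG over the minute (30 epochs) centred on each instant.

    The window ``[i - half_window, i + half_window)`` is clipped at the
    series edges (logged); an instant outside the series is an error.
    """
    x = np.asarray(values, dtype=float)
    n = len(x)
    out = {}
    for name, i in instants.items():
        if not (0 <= i <= n):
            raise ValueError(f"instant {name} at epoch {i} outside series of {n}")
        lo, hi = max(0, i - half_window), min(n, i + half_window)
        if lo == 0 or hi == n:
            logger.info("window for %s clipped to [%d, %d)", name, lo, hi)
        out[name] = float(x[lo:hi].mean())
    return out


def correlate_spsl_rg(
    spsl_means: np.ndarray, rg_means: np.ndarray
) -> CorrelationResult:
    """Pearson correlation between mean SPSL and mean RG at T1..T4.

    With only four paired instants no confidence interval is meaningful
    (Fisher's interval needs n > 3 and would be vacuous); ci bounds are None.
    """
    a = np.asarray(spsl_means, dtype=float)
    b = np.asarray(rg_means, dtype=float)
    if a.shape != b.shape or len(a) != 4:
        raise ValueError("need exactly 4 paired instant means")
    if a.std() == 0 or b.std() == 0:
        raise ValueError("zero variance at the instants")
    r = float(ss.pearsonr(a, b).statistic)
    return CorrelationResult(pcc=r, ci_low=None, ci_up=None, level=0.95, n=4)
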