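"""Trial-level behavioral analysis of the polarity x probe-type design.

The central statistic is the *net negation interaction* (NetNegInt): the
reaction-time cost of the negative linguistic quantifier (``less`` - ``more``)
minus the cost of the negative comparison symbol (``<`` - ``>``).  A positive
NetNegInt isolates the processing cost of implicit logical negation from
generic symbol-reversal costs.  Inference on the 2 x 2 within-subject design
uses a repeated-measures ANOVA on log-transformed judgment times; for a 2 x 2
design the interaction F is algebraically the square of a paired t test on the
per-subject difference of differences, which the test-suite verifies.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import pingouin as pg
from scipy import stats

logger = logging.getLogger(__name__)

POLARITIES = ("positive", "negative")
PROBE_TYPES = ("linguistic", "symbolic")
#: the four condition cells in a fixed order: (polarity, probe_type)
CELLS = tuple((pol, pt) for pt in PROBE_TYPES for pol in POLARITIES)


# ---------------------------------------------------------------------------
# paired t test
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TTestResult:
    """Classical paired t test with df = n - 1.

    ``degenerate`` flags the zero-variance case: identical nonzero differences
    yield an infinite t (p = 0); identical zero differences yield t = 0, p = 1.
    """

    t: float
    df: int
    p: float
    tail: str
    degenerate: bool = False

    def __iter__(self):  # allow ``t, df, p = paired_t(...)``
        return iter((self.t, self.df, self.p))


def paired_t(a: Sequence[float], b: Sequence[float],
             tail: str = "two-sided") -> TTestResult:
    """Paired-sample t test of ``a`` vs ``b``.

    tail : 'two-sided', 'greater' (a > b) or 'less'.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("paired_t requires two equal-length 1-D vectors")
    n = a.size
    if n < 2:
        raise ValueError("paired_t requires at least 2 pairs")
    d = a - b
    sd = d.std(ddof=1)
    if sd == 0.0:
        m = d.mean()
        if m == 0.0:
            p = 1.0 if tail == "two-sided" else 0.5
            return TTestResult(0.0, n - 1, p, tail, degenerate=True)
        t = math.inf if m > 0 else -math.inf
        if tail == "two-sided":
            p = 0.0
        elif tail == "greater":
            p = 0.0 if m > 0 else 1.0
        else:
            p = 0.0 if m < 0 else 1.0
        logger.warning("paired_t: zero-variance nonzero-mean differences; "
                       "reporting infinite t")
        return TTestResult(t, n - 1, p, tail, degenerate=True)
    res = stats.ttest_rel(a, b, alternative=tail.replace("two-sided", "two-sided"))
    return TTestResult(float(res.statistic), n - 1, float(res.pvalue), tail)


# ---------------------------------------------------------------------------
# filtering and summaries
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FilterPolicy:
    """Trial-exclusion policy.

    correct_only
        Keep only correct responses (default).  The reported RT means of this
        kind of verification task conventionally exclude errors.
    rt_sd_cutoff
        If set, additionally drop trials with RT above the per-subject
        mean + cutoff * SD (computed on the rows surviving the accuracy
        filter).  Off by default.
    """

    correct_only: bool = True
    rt_sd_cutoff: float | None = None


REQUIRED_COLUMNS = ("subject", "polarity", "probe_type", "proportion",
                    "rt_ms", "correct")


def _check_table(trials: pd.DataFrame) -> None:
    missing = [c for c in REQUIRED_COLUMNS if c not in trials.columns]
    if missing:
        raise ValueError(f"trial table missing columns: {missing}")


def filter_trials(trials: pd.DataFrame,
                  policy: FilterPolicy = FilterPolicy()) -> pd.DataFrame:
    """Apply ``policy`` and return the surviving rows.

    Counts of removed rows are logged and stored in ``result.attrs['filter_log']``.
    Raises if any subject x polarity x probe-type cell becomes empty.
    """
    _check_table(trials)
    out = trials
    log: dict[str, int] = {}
    if policy.correct_only:
        keep = out["correct"].astype(bool)
        log["incorrect_removed"] = int((~keep).sum())
        out = out[keep]
    if policy.rt_sd_cutoff is not None:
        g = out.groupby("subject")["rt_ms"]
        thr = g.transform("mean") + policy.rt_sd_cutoff * g.transform(lambda s: s.std(ddof=1))
        keep = out["rt_ms"] <= thr
        log["rt_outliers_removed"] = int((~keep).sum())
        out = out[keep]
    counts = out.groupby(["subject", "polarity", "probe_type"], observed=True).size()
    expected = {(s, pol, pt) for s in trials["subject"].unique()
                for pol, pt in CELLS}
    empty = sorted(expected - set(counts.index))
    if empty:
        raise ValueError(f"empty cells after filtering: {empty[:5]}"
                         + ("..." if len(empty) > 5 else ""))
    logger.info("filter_trials removed %s", log)
    out = out.copy()
    out.attrs["filter_log"] = log
    return out


def condition_summary(trials: pd.DataFrame,
                      by_proportion: bool = False) -> pd.DataFrame:
    """Mean/SD/n of RT per condition cell (SD with n-1 denominator)."""
    _check_table(trials)
    keys = ["polarity", "probe_type"] + (["proportion"] if by_proportion else [])
    grp = trials.groupby(keys, observed=True)["rt_ms"]
    out = grp.agg(mean_rt_ms="mean", sd_ms=lambda s: s.std(ddof=1), n="size")
    out["sd_ms"] = out["sd_ms"].fillna(0.0)
    if (out["n"] < 1).any():
        raise ValueError("empty condition cell")
    return out


def subject_cell_means(trials: pd.DataFrame, log: bool = False) -> pd.DataFrame:
    """Per-subject mean (log-)RT for each of the four cells, wide format.

    Columns are (polarity, probe_type) tuples; raises if any subject lacks a
    cell, listing the offending subjects.
    """
    _check_table(trials)
    vals = trials.assign(y=np.log(trials["rt_ms"]) if log else trials["rt_ms"])
    wide = vals.pivot_table(index="subject", columns=["polarity", "probe_type"],
                            values="y", aggfunc="mean")
    missing = wide.columns.size < 4 or wide.isna().any(axis=1)
    if np.any(missing):
        bad = wide.index[wide.isna().any(axis=1)].tolist() if wide.columns.size == 4 \
            else wide.index.tolist()
        raise ValueError(f"subjects with missing condition cells: {bad}")
    return wide[list(CELLS)]


# ---------------------------------------------------------------------------
# NetNegInt
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class NetNegIntResult:
    """The net negation interaction in milliseconds.

    delta_ling = mean(less) - mean(more); delta_symb = mean(<) - mean(>);
    net = delta_ling - delta_symb.  ``per_subject`` holds the per-subject net
    values (on raw ms, the scale used for brain-behavior correlations).
    """

    delta_ling: float
    delta_symb: float
    net: float
    per_subject: np.ndarray = field(default_factory=lambda: np.empty(0))
    subjects: tuple = ()

    def __post_init__(self):
        assert abs(self.net - (self.delta_ling - self.delta_symb)) < 1e-9


def net_neg_int(data: pd.DataFrame | Mapping) -> NetNegIntResult:
    """NetNegInt from a trial table (per-subject vector form) or from a
    mapping of the four cell means (grand-mean form).

    The mapping form accepts keys ('negative','linguistic') etc., or the
    condition aliases 'less', 'more', '<', '>'.
    """
    if isinstance(data, pd.DataFrame):
        wide = subject_cell_means(data, log=False)
        d_ling = wide[("negative", "linguistic")] - wide[("positive", "linguistic")]
        d_symb = wide[("negative", "symbolic")] - wide[("positive", "symbolic")]
        per = (d_ling - d_symb).to_numpy()
        return NetNegIntResult(float(d_ling.mean()), float(d_symb.mean()),
                               float(d_ling.mean() - d_symb.mean()),
                               per, tuple(wide.index))
    alias = {"less": ("negative", "linguistic"), "more": ("positive", "linguistic"),
             "<": ("negative", "symbolic"), ">": ("positive", "symbolic")}
    means = {alias.get(k, k): v for k, v in dict(data).items()}
    try:
        dl = means[("negative", "linguistic")] - means[("positive", "linguistic")]
        ds = means[("negative", "symbolic")] - means[("positive", "symbolic")]
    except KeyError as exc:
        raise ValueError(f"missing condition cell: {exc}") from exc
    return NetNegIntResult(float(dl), float(ds), float(dl - ds))


# ---------------------------------------------------------------------------
# 2 x 2 repeated-measures ANOVA
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class EffectStat:
    F: float
    df1: int
    df2: int
    p: float


@dataclass(frozen=True)
class AnovaResult:
    """F/df/p for the Polarity and Probe-type main effects and their
    interaction in the 2 x 2 within-subject design."""

    polarity: EffectStat
    probe_type: EffectStat
    interaction: EffectStat

    def as_dict(self) -> dict:
        return {name: vars(getattr(self, name))
                for name in ("polarity", "probe_type", "interaction")}


def rm_anova_2x2(wide: pd.DataFrame) -> AnovaResult:
    """Two-way repeated-measures ANOVA on a subjects x 4-cells wide table.

    ``wide`` columns must be the (polarity, probe_type) cells of
    :data:`CELLS`.  Engine: :func:`pingouin.rm_anova`.
    """
    if wide.shape[0] < 2:
        raise ValueError("need at least 2 subjects")
    long = wide.stack([0, 1], future_stack=True).rename("y").reset_index()
    long.columns = ["subject", "polarity", "probe_type", "y"]
    import warnings as _warnings
    with _warnings.catch_warnings():
        # 0/0 F ratios of degenerate contrasts are handled below
        _warnings.simplefilter("ignore", RuntimeWarning)
        aov = pg.rm_anova(data=long, dv="y", within=["polarity", "probe_type"],
                          subject="subject", detailed=True)
    aov = aov.set_index("Source")
    ss_scale = max(float(aov["SS"].abs().max()), 1e-300)

    def eff(src: str) -> EffectStat:
        row = aov.loc[src]
        F, p = float(row["F"]), float(row["p_unc"])
        if float(row["SS"]) <= 1e-12 * ss_scale or not np.isfinite(F):
            # contrast identically zero for every subject: no effect
            F, p = 0.0, 1.0
        return EffectStat(F, int(row["ddof1"]), int(row["ddof2"]), p)

    return AnovaResult(polarity=eff("polarity"), probe_type=eff("probe_type"),
                       interaction=eff("polarity * probe_type"))


def rm_anova_2x2_log(trials: pd.DataFrame) -> AnovaResult:
    """Repeated-measures ANOVA on log judgment times.

    Cell means are taken per subject on natural-log RT (the transform
    stabilizes the right-skewed RT distribution; F and p are invariant to the
    log base).
    """
    return rm_anova_2x2(subject_cell_means(trials, log=True))
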