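"""Determinant-relevance analytics: CIBER summaries and Potential-for-Change.

CIBER (Confidence Interval-Based Estimation of Relevance) summarises each
sub-determinant item by (a) the distribution of its scores with an ultra-wide
99.99% confidence interval for the mean — how much room for improvement the
sample leaves — and (b) the 95% confidence interval of its zero-order Pearson
correlation with the behaviour measure.  An item is a promising intervention
target when it is associated with behaviour *and* its mean sits well below the
scale ceiling.  The approach is estimation-based: the wide intervals replace
significance testing, and no multiplicity correction is applied.

The two Potential-for-Change indices condense both panels into one number:

* ``PΔ1 = (max(x) - mean(x)) * r``  for ``r > 0`` (observed maximum), and
  ``(min(x) - mean(x)) * r`` for ``r < 0``; 0 when ``r = 0``.
* ``PΔ2`` replaces the observed extremum by the .95 (resp. .05) quantile and
  ``r`` by ``r²``: trimming and squaring make it less sensitive to outliers
  and to small correlation differences, hence more stable across samples.

Both use *observed* sample extrema/quantiles, not theoretical scale bounds.
Quantiles follow the linear-interpolation convention between order statistics
(numpy's default), which PΔ2 values depend on.

Planned missingness makes every statistic pairwise-complete; items with fewer
than ``min_pairs`` complete pairs are reported as insufficient rather than
silently dropped.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InsufficientDataError, UndefinedStatisticError
from .survey import ItemBank, ResponseRecord, distance_numeric

DEFAULT_MEAN_LEVEL = 0.9999
DEFAULT_R_LEVEL = 0.95
DEFAULT_MIN_PAIRS = 10


def mean_ci(
    scores, level: float = DEFAULT_MEAN_LEVEL
) -> tuple[float, float, float]:
    """Two-sided t-interval for the mean: ``(mean, low, high)``.

    Uses the t distribution with n−1 degrees of freedom.  A constant vector
    has zero standard error and returns a degenerate interval.
    """
    x = np.asarray(scores, dtype=float)
    x = x[~np.isnan(x)]
    n = x.size
    if n < 2:
        raise InsufficientDataError(f"mean_ci needs n >= 2, got {n}")
    if not (0 < level < 1):
        raise ValueError(f"confidence level must be in (0,1), got {level}")
    m = float(np.mean(x))
    sem = float(np.std(x, ddof=1) / math.sqrt(n))
    tcrit = float(stats.t.ppf(0.5 + level / 2.0, df=n - 1))
    return m, m - tcrit * sem, m + tcrit * sem


def correlation_ci(
    x, y, level: float = DEFAULT_R_LEVEL
) -> tuple[float, float, float]:
    """Pearson r with a Fisher-z confidence interval: ``(r, low, high)``.

    Pairwise-complete: pairs with a missing value in either vector are
    dropped.  Constant input is flagged undefined (raises), never reported as
    a silent zero.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have the same length")
    mask = ~(np.isnan(x) | np.isnan(y))
    x, y = x[mask], y[mask]
    n = x.size
    if n < 3:
        raise InsufficientDataError(f"correlation_ci needs n >= 3 complete pairs, got {n}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise UndefinedStatisticError("correlation undefined for constant input")
    r = float(np.clip(np.corrcoef(x, y)[0, 1], -1.0, 1.0))
    if abs(r) > 1.0 - 1e-12:  # snap exact linear dependence despite rounding
        r = math.copysign(1.0, r)
    # Fisher z: atanh(r) +/- z_crit / sqrt(n-3), back-transformed; at n = 3 the
    # half-width is infinite and the interval degenerates to (-1, 1)
    zcrit = float(stats.norm.ppf(0.5 + level / 2.0))
    z = np.arctanh(np.clip(r, -1 + 1e-15, 1 - 1e-15))
    half = zcrit / math.sqrt(n - 3) if n > 3 else math.inf
    lo, hi = float(np.tanh(z - half)), float(np.tanh(z + half))
    if r == 1.0:
        hi = 1.0
    if r == -1.0:
        lo = -1.0
    return r, lo, hi


def _pairwise(scores, behaviour):
    x = np.asarray(scores, dtype=float)
    y = np.asarray(behaviour, dtype=float)
    if x.shape != y.shape:
        raise ValueError("scores and behaviour must have the same length")
    mask = ~(np.isnan(x) | np.isnan(y))
    return x, y, mask


def _zero_order_r(scores, behaviour) -> tuple[float, np.ndarray]:
    x, y, mask = _pairwise(scores, behaviour)
    xp, yp = x[mask], y[mask]
    if xp.size < 3:
        raise InsufficientDataError(
            f"potential-for-change needs n >= 3 complete pairs, got {xp.size}"
        )
    if np.ptp(yp) == 0:
        raise UndefinedStatisticError("behaviour measure is constant; r undefined")
    if np.ptp(xp) == 0:
        # no spread in the item: no association and no room signal
        return 0.0, x[~np.isnan(x)]
    r = float(np.clip(np.corrcoef(xp, yp)[0, 1], -1.0, 1.0))
    return r, x[~np.isnan(x)]


def potential_for_change_1(scores, behaviour) -> float:
    """PΔ1: room to the observed extremum weighted by the correlation.

    The mean and extremum are taken over all observed item scores; the
    correlation over pairwise-complete (item, behaviour) pairs.
    """
    r, observed = _zero_order_r(scores, behaviour)
    if r == 0.0:
        return 0.0
    m = float(np.mean(observed))
    extremum = float(np.max(observed)) if r > 0 else float(np.min(observed))
    return (extremum - m) * r


def potential_for_change_2(
    scores, behaviour, upper_q: float = 0.95, lower_q: float = 0.05
) -> float:
    """PΔ2: room to the trimmed extremum weighted by the squared correlation.

    Computed as ``(trimmed extremum - mean) * r * |r|``: for ``r > 0`` this is
    exactly ``(q_.95 - mean) * r^2``; for ``r < 0`` the sign of r cancels the
    sign of the room term (as it does in PΔ1), so both branches yield a
    non-negative index of magnitude ``|room| * r^2``.
    """
    if not (0 < lower_q < upper_q < 1):
        raise ValueError(f"quantiles must satisfy 0 < lower < upper < 1, got "
                         f"({lower_q}, {upper_q})")
    r, observed = _zero_order_r(scores, behaviour)
    if r == 0.0:
        return 0.0
    m = float(np.mean(observed))
    q = upper_q if r > 0 else lower_q
    trimmed = float(np.quantile(observed, q, method="linear"))
    return (trimmed - m) * r * abs(r)


# --------------------------------------------------------------------------- #
# Cohort-level tables
# --------------------------------------------------------------------------- #

SUMMARY_COLUMNS = (
    "item_id",
    "behaviour",
    "construct",
    "sub_determinant",
    "n_scores",
    "n_pairs",
    "mean",
    "mean_ci_low",
    "mean_ci_high",
    "r",
    "r_ci_low",
    "r_ci_high",
    "pdelta1",
    "pdelta2",
    "selected",
)


@dataclass
class CiberResults:
    """Per-item CIBER summaries plus the three canonical orderings."""

    summaries: pd.DataFrame  # items with sufficient data, SUMMARY_COLUMNS
    insufficient: pd.DataFrame  # item_id, n_pairs, reason

    def sorted_by(self, key: str) -> pd.DataFrame:
        """One of the three report orders: 'pdelta1', 'pdelta2' or 'r'."""
        if key not in {"pdelta1", "pdelta2", "r"}:
            raise ValueError(f"sort key must be pdelta1, pdelta2 or r, got {key!r}")
        return self.summaries.sort_values(
            key, ascending=False, kind="mergesort"
        ).reset_index(drop=True)

    def orderings(self) -> dict[str, pd.DataFrame]:
        return {k: self.sorted_by(k) for k in ("pdelta1", "pdelta2", "r")}


def behaviour_vector(
    responses: list[ResponseRecord], behaviour_field: str = "distance_frequency"
) -> np.ndarray:
    """Numeric behaviour measure per respondent (NaN where undefined).

    The default is the ordinal distance-keeping item coded 1–5, with the
    "never in public places" answer treated as missing: someone who is never
    in public has no defined distance-keeping frequency.
    """
    if behaviour_field == "distance_frequency":
        return np.array(
            [distance_numeric(r.distance_frequency) for r in responses], dtype=float
        )
    values = []
    for r in responses:
        v = getattr(r, behaviour_field)
        values.append(float(getattr(v, "value", v)))
    return np.array(values, dtype=float)


def score_matrix(
    responses: list[ResponseRecord], item_ids: tuple[str, ...]
) -> pd.DataFrame:
    """Wide respondents x items score matrix (NaN = not presented/answered)."""
    data = np.full((len(responses), len(item_ids)), np.nan)
    col = {iid: j for j, iid in enumerate(item_ids)}
    for i, rec in enumerate(responses):
        for iid, score in rec.determinant_scores.items():
            j = col.get(iid)
            if j is not None:
                data[i, j] = score
    return pd.DataFrame(data, columns=list(item_ids))


def ciber_table(
    responses: list[ResponseRecord],
    bank: ItemBank,
    behaviour_field: str = "distance_frequency",
    min_pairs: int = DEFAULT_MIN_PAIRS,
    mean_level: float = DEFAULT_MEAN_LEVEL,
    r_level: float = DEFAULT_R_LEVEL,
    upper_q: float = 0.95,
    lower_q: float = 0.05,
) -> CiberResults:
    """CIBER summary for every bank item with enough pairwise-complete data.

    Items an insufficient number of respondents answered (fewer than
    ``min_pairs`` complete pairs with the behaviour measure) or with undefined
    statistics are listed in ``insufficient`` with a reason.  ``selected``
    is initialised via :func:`select_targets` with default thresholds.
    """
    import warnings

    y = behaviour_vector(responses, behaviour_field)
    answered = sorted({iid for r in responses for iid in r.determinant_scores})
    rows, skipped = [], []
    for iid in answered:
        item = bank[iid]
        x = np.array(
            [float(r.determinant_scores.get(iid, np.nan)) for r in responses]
        )
        n_scores = int(np.sum(~np.isnan(x)))
        n_pairs = int(np.sum(~(np.isnan(x) | np.isnan(y))))
        if n_pairs < max(min_pairs, 4):
            skipped.append((iid, n_pairs, "insufficient data"))
            continue
        try:
            m, mlo, mhi = mean_ci(x, level=mean_level)
            r, rlo, rhi = correlation_ci(x, y, level=r_level)
            pd1 = potential_for_change_1(x, y)
            pd2 = potential_for_change_2(x, y, upper_q=upper_q, lower_q=lower_q)
        except UndefinedStatisticError as exc:
            skipped.append((iid, n_pairs, str(exc)))
            continue
        except InsufficientDataError as exc:
            skipped.append((iid, n_pairs, str(exc)))
            continue
        rows.append(
            {
                "item_id": iid,
                "behaviour": item.behaviour.value,
                "construct": item.construct.value,
                "sub_determinant": item.sub_determinant,
                "n_scores": n_scores,
                "n_pairs": n_pairs,
                "mean": m,
                "mean_ci_low": mlo,
                "mean_ci_high": mhi,
                "r": r,
                "r_ci_low": rlo,
                "r_ci_high": rhi,
                "pdelta1": pd1,
                "pdelta2": pd2,
                "selected": False,
            }
        )
    summaries = pd.DataFrame(rows, columns=list(SUMMARY_COLUMNS))
    insufficient = pd.DataFrame(skipped, columns=["item_id", "n_pairs", "reason"])
    if summaries.empty:
        warnings.warn("no item meets the pairwise-complete threshold", stacklevel=2)
    else:
        scale_lo = np.array([bank[i].scale_min for i in summaries["item_id"]], float)
        scale_hi = np.array([bank[i].scale_max for i in summaries["item_id"]], float)
        summaries["selected"] = select_targets(summaries, scale_lo, scale_hi)
    return CiberResults(summaries=summaries, insufficient=insufficient)


def select_targets(
    summaries: pd.DataFrame,
    scale_min,
    scale_max,
    ceiling_fraction: float = 0.9,
    direction: str = "positive",
) -> np.ndarray:
    """Flag items worth targeting: associated with behaviour AND room to move.

    Association: the r confidence interval excludes 0 in the favourable
    direction (``direction`` = 'positive', 'negative' or 'either').  Room: the
    item mean lies below ``scale_min + ceiling_fraction * (scale_max -
    scale_min)`` — items already at the ceiling can correlate with behaviour
    yet offer nothing to change.
    """
    lo = summaries["r_ci_low"].to_numpy(dtype=float)
    hi = summaries["r_ci_high"].to_numpy(dtype=float)
    if direction == "positive":
        associated = lo > 0
    elif direction == "negative":
        associated = hi < 0
    elif direction == "either":
        associated = (lo > 0) | (hi < 0)
    else:
        raise ValueError(f"direction must be positive/negative/either, got {direction!r}")
    scale_min = np.asarray(scale_min, dtype=float)
    scale_max = np.asarray(scale_max, dtype=float)
    ceiling = scale_min + ceiling_fraction * (scale_max - scale_min)
    room = summaries["mean"].to_numpy(dtype=float) < ceiling
    return associated & room


# --------------------------------------------------------------------------- #
# Diamond plot
# --------------------------------------------------------------------------- #

def ciber_plot(
    results: CiberResults,
    responses: list[ResponseRecord],
    behaviour_field: str = "distance_frequency",
    seed: int = 0,
    order_by: str = "pdelta2",
):
    """Two-panel CIBER diamond plot.

    Left panel: each item's raw scores as a jittered strip with a diamond
    spanning the 99.99% mean CI.  Right panel: a diamond spanning the 95% CI
    of the correlation with behaviour, on a fixed [−1, 1] axis with a zero
    line.  Jitter is drawn from ``seed``, so the figure is deterministic.
    Returns a matplotlib Figure.
    """
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    if results.summaries.empty:
        raise InsufficientDataError("nothing to plot: no item summaries")
    table = results.sorted_by(order_by)
    rng = np.random.default_rng(seed)
    n_items = len(table)
    fig, (ax_left, ax_right) = plt.subplots(
        1, 2, figsize=(9, 0.9 * n_items + 1.5), sharey=True,
        gridspec_kw={"width_ratios": [2, 1]},
    )
    ys = np.arange(n_items)[::-1]  # top row = first item

    scores_by_item = {}
    for rec in responses:
        for iid, score in rec.determinant_scores.items():
            scores_by_item.setdefault(iid, []).append(score)

    for y_pos, (_, row) in zip(ys, table.iterrows()):
        raw = np.asarray(scores_by_item.get(row["item_id"], []), dtype=float)
        if raw.size:
            jitter = rng.uniform(-0.22, 0.22, size=raw.size)
            ax_left.plot(
                raw + rng.uniform(-0.1, 0.1, size=raw.size),
                y_pos + jitter,
                ".", color="0.6", markersize=2, alpha=0.4,
            )
        _diamond(ax_left, row["mean_ci_low"], row["mean_ci_high"], row["mean"],
                 y_pos, color="#2166ac")
        _diamond(ax_right, row["r_ci_low"], row["r_ci_high"], row["r"],
                 y_pos, color="#b2182b" if row["selected"] else "0.35")

    ax_left.set_yticks(ys)
    ax_left.set_yticklabels(table["item_id"])
    ax_left.set_xlabel("score (mean with 99.99% CI)")
    ax_right.set_xlim(-1, 1)
    ax_right.axvline(0.0, color="0.75", linewidth=0.8)
    ax_right.set_xlabel("correlation with behaviour (95% CI)")
    fig.tight_layout()
    return fig


def _diamond(ax, lo: float, hi: float, mid: float, y: float, color: str,
             half_height: float = 0.28) -> None:
    xs = [lo, mid, hi, mid, lo]
    ys = [y, y + half_height, y, y - half_height, y]
    ax.fill(xs, ys, color=color, alpha=0.85, linewidth=0)
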