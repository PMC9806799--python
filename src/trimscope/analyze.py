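"""Single-cell gating and Trim-Away knockdown estimation.

The central readouts:

* antibody-positivity gating against a no-delivery null distribution
  (threshold = a quantile of the null, default the 99th percentile);
* top-percentile filtering by delivery-marker intensity, the paper-style way
  of narrowing analysis to efficiently resealed cells;
* knockdown fraction 1 − mean(target | treated)/mean(target | control) — the
  ratio-of-means estimator matching western-blot densitometry aggregation —
  with a nonparametric bootstrap CI, in bulk / gated / percentile modes;
* condition comparisons by Welch's t-test (Holm-adjusted for many-to-one).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "GatingResult",
    "KnockdownEstimate",
    "gate_positive",
    "flag_died",
    "top_percentile_filter",
    "estimate_knockdown",
    "ratio_features",
    "separation_curve",
    "welch_test",
    "compare_many_to_one",
]


@dataclass(frozen=True)
class GatingResult:
    rule: str
    threshold: float
    positive: pd.Series = field(repr=False)  # aligned with the gated table's index
    positive_fraction: float = 0.0
    n_cells: int = 0
    null_source: str = "no-delivery control"

    def to_dict(self) -> dict:
        return {
            "rule": self.rule,
            "threshold": self.threshold,
            "positive_fraction": self.positive_fraction,
            "n_cells": self.n_cells,
            "null_source": self.null_source,
        }


@dataclass(frozen=True)
class KnockdownEstimate:
    mode: str
    fraction: float  # 1 - treated/control ratio of target means; <= 1
    ci_low: float
    ci_high: float
    n_treated: int
    n_control: int
    channel: str
    n_boot: int

    def to_dict(self) -> dict:
        return {
            "mode": self.mode,
            "fraction": self.fraction,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "n_treated": self.n_treated,
            "n_control": self.n_control,
            "channel": self.channel,
            "n_boot": self.n_boot,
        }


def usable(cells: pd.DataFrame) -> pd.DataFrame:
    """Drop flagged cells (border, registration-invalid, died) from analysis."""
    mask = np.ones(len(cells), dtype=bool)
    for col in ("flag_border", "flag_invalid", "flag_died"):
        if col in cells.columns:
            mask &= ~cells[col].to_numpy(bool)
    return cells.loc[mask]


def gate_positive(
    cells: pd.DataFrame,
    ab_column: str,
    null_cells: pd.DataFrame,
    rule: str = "quantile",
    q: float = 0.99,
    k_sd: float = 3.0,
    null_source: str = "no-delivery control",
) -> GatingResult:
    """Classify cells as antibody-positive against a null distribution.

    ``rule='quantile'``: threshold at the q-quantile of the null sample's
    delivery-marker means (default 0.99). ``rule='mean_sd'``: null mean +
    k_sd standard deviations.
    """
    if len(cells) == 0 or len(null_cells) == 0:
        raise ValueError("gate_positive requires nonempty cell and null tables")
    null_vals = null_cells[ab_column].to_numpy(float)
    if rule == "quantile":
        threshold = float(np.quantile(null_vals, q))
        rule_desc = f"quantile[{q}]"
    elif rule == "mean_sd":
        threshold = float(null_vals.mean() + k_sd * null_vals.std(ddof=1))
        rule_desc = f"mean+{k_sd}*sd"
    else:
        raise ValueError(f"unknown gating rule {rule!r}")
    positive = cells[ab_column] > threshold
    return GatingResult(
        rule=rule_desc,
        threshold=threshold,
        positive=positive,
        positive_fraction=float(positive.mean()),
        n_cells=int(len(cells)),
        null_source=null_source,
    )


def flag_died(
    cells: pd.DataFrame, pi_column: str, k_mad: float = 10.0, min_scale: float = 1.0
) -> pd.DataFrame:
    """Flag incompletely resealed cells by their propidium-iodide-like signal.

    Threshold = median + k_mad × (1.4826·MAD) of the per-cell PI means, with a
    floor on the scale so a noise-free field still thresholds sensibly. Adds a
    ``flag_died`` column; returns a copy.
    """
    vals = cells[pi_column].to_numpy(float)
    med = float(np.median(vals))
    mad = float(np.median(np.abs(vals - med)))
    scale = max(1.4826 * mad, min_scale)
    out = cells.copy()
    out["flag_died"] = vals > med + k_mad * scale
    return out


def top_percentile_filter(
    cells: pd.DataFrame,
    column: str,
    top_pct: float,
    by_condition: bool = True,
) -> pd.DataFrame:
    """Keep the cells in the top ``top_pct`` percent by ``column``.

    The cutoff is the (100 − top_pct) percentile computed within each
    condition (when a condition column is present); ties at the cutoff are
    included, so the subset may slightly exceed the nominal fraction.
    """
    if not 0 < top_pct <= 100:
        raise ValueError(f"top_pct must be in (0, 100], got {top_pct}")
    if top_pct == 100:
        return cells.copy()

    def _subset(df: pd.DataFrame) -> pd.DataFrame:
        cut = np.percentile(df[column].to_numpy(float), 100 - top_pct)
        return df.loc[df[column] >= cut]

    if by_condition and "condition" in cells.columns:
        parts = [
            _subset(grp) for _, grp in cells.groupby("condition", sort=True)
        ]
        return pd.concat(parts).sort_index()
    return _subset(cells)


def _subset_for_mode(
    table: pd.DataFrame,
    mode: str,
    target_column: str,
    positive: pd.Series | None,
    ab_column: str | None,
    top_pct: float | None,
) -> pd.DataFrame:
    if mode == "bulk":
        return table
    if mode == "gated":
        if positive is None:
            raise ValueError("gated mode needs the gating result's positive flags")
        return table.loc[positive.reindex(table.index, fill_value=False)]
    if mode == "percentile":
        if ab_column is None or top_pct is None:
            raise ValueError("percentile mode needs ab_column and top_pct")
        return top_percentile_filter(table, ab_column, top_pct, by_condition=False)
    raise ValueError(f"unknown mode {mode!r}")


def estimate_knockdown(
    treated: pd.DataFrame,
    control: pd.DataFrame,
    target_column: str,
    mode: str = "bulk",
    positive_treated: pd.Series | None = None,
    positive_control: pd.Series | None = None,
    ab_column: str | None = None,
    top_pct: float | None = None,
    n_boot: int = 1000,
    seed: int = 0,
) -> KnockdownEstimate:
    """Degradation fraction 1 − mean(target|treated)/mean(target|control).

    ``mode='bulk'`` uses all cells (the western-blot-equivalent readout),
    ``'gated'`` only antibody-positive cells, ``'percentile'`` the top
    ``top_pct`` percent by delivery marker. CI by seeded nonparametric
    bootstrap over cells (percentile method).
    """
    t = _subset_for_mode(treated, mode, target_column, positive_treated, ab_column, top_pct)
    c = _subset_for_mode(control, mode, target_column, positive_control, ab_column, top_pct)
    label = mode if mode != "percentile" else f"percentile-{top_pct:g}"
    if len(t) == 0 or len(c) == 0:
        raise ValueError(f"empty {'treated' if len(t) == 0 else 'control'} subset in mode {label}")
    tv = t[target_column].to_numpy(float)
    cv = c[target_column].to_numpy(float)
    c_mean = cv.mean()
    if c_mean <= 0:
        raise ValueError("control mean intensity must be positive")
    fraction = 1.0 - tv.mean() / c_mean

    rng = np.random.default_rng(seed)
    boots = np.empty(n_boot)
    for i in range(n_boot):
        bt = tv[rng.integers(0, len(tv), len(tv))]
        bc = cv[rng.integers(0, len(cv), len(cv))]
        boots[i] = 1.0 - bt.mean() / bc.mean()
    lo, hi = np.percentile(boots, [2.5, 97.5])
    return KnockdownEstimate(
        mode=label,
        fraction=float(fraction),
        ci_low=float(lo),
        ci_high=float(hi),
        n_treated=int(len(tv)),
        n_control=int(len(cv)),
        channel=target_column,
        n_boot=n_boot,
    )


def ratio_features(
    cells: pd.DataFrame, pairs: list[tuple[str, str]]
) -> pd.DataFrame:
    """Add per-cell intensity-ratio columns ``ratio_{num}_{den}`` (e.g.
    pAkt/Akt). Non-positive denominators yield missing values and a flag."""
    out = cells.copy()
    for num, den in pairs:
        for col in (num, den):
            if col not in out.columns:
                raise KeyError(f"unknown channel column {col!r}")
        d = out[den].to_numpy(float)
        n = out[num].to_numpy(float)
        bad = d <= 0
        ratio = np.where(bad, np.nan, n / np.where(bad, 1.0, d))
        out[f"ratio_{num}_{den}"] = ratio
        if bad.any():
            out[f"ratio_{num}_{den}_undefined"] = bad
    return out


def _smd(a: np.ndarray, b: np.ndarray) -> float:
    """Absolute standardized mean difference with the unweighted pooled SD."""
    sd = math.sqrt((a.var(ddof=1) + b.var(ddof=1)) / 2.0)
    if sd == 0:
        return 0.0
    return abs(a.mean() - b.mean()) / sd


def separation_curve(
    treated: pd.DataFrame,
    control: pd.DataFrame,
    feature: str,
    ab_column: str,
    percentiles: tuple[float, ...] = (100, 50, 25, 10, 5),
    stat: str = "smd",
    min_n: int = 20,
) -> pd.DataFrame:
    """Condition separation on ``feature`` as analysis narrows to the
    top-percentile delivery cells — the single-cell sharpening readout.

    For each level, both conditions are filtered to their own top percentile
    by the delivery marker, then a standardized separation (absolute SMD, or
    the two-sample Kolmogorov–Smirnov statistic) is computed. Levels with
    fewer than ``min_n`` cells in either arm are marked unreliable.
    """
    if len(percentiles) < 2:
        raise ValueError("need at least two percentile levels")
    rows = []
    for p in percentiles:
        t = top_percentile_filter(treated, ab_column, p, by_condition=False)
        c = top_percentile_filter(control, ab_column, p, by_condition=False)
        a = t[feature].dropna().to_numpy(float)
        b = c[feature].dropna().to_numpy(float)
        unreliable = len(a) < min_n or len(b) < min_n
        if stat == "smd":
            eff = _smd(a, b) if not unreliable else np.nan
        elif stat == "ks":
            eff = float(stats.ks_2samp(a, b).statistic) if not unreliable else np.nan
        else:
            raise ValueError(f"unknown stat {stat!r}")
        rows.append(
            {"top_pct": p, "effect_size": eff, "n_treated": len(a),
             "n_control": len(b), "unreliable": unreliable}
        )
    return pd.DataFrame(rows)


def welch_test(a, b) -> tuple[float, float, float]:
    """Welch's two-sample t-test: returns (t, Welch–Satterthwaite df, two-sided p)."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each sample needs n >= 2")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va == 0 and vb == 0:
        raise ValueError("degenerate samples: zero variance in both groups")
    res = stats.ttest_ind(a, b, equal_var=False)
    se2a, se2b = va / len(a), vb / len(b)
    df = (se2a + se2b) ** 2 / (se2a**2 / (len(a) - 1) + se2b**2 / (len(b) - 1))
    return float(res.statistic), float(df), float(res.pvalue)


def compare_many_to_one(
    groups: dict[str, np.ndarray], reference: np.ndarray
) -> pd.DataFrame:
    """Each group vs a shared reference by Welch's t with Holm family-wise
    adjustment (an approximation of Dunnett-style many-to-one testing)."""
    rows = []
    for name, vals in groups.items():
        t, df, p = welch_test(vals, reference)
        rows.append({"group": name, "t": t, "df": df, "p": p})
    out = pd.DataFrame(rows)
    order = np.argsort(out["p"].to_numpy())
    m = len(out)
    adj = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, (m - rank) * out["p"].iloc[idx])
        adj[idx] = min(running, 1.0)
    out["p_holm"] = adj
    return out
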