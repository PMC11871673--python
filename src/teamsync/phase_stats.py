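"""Phase-level synchrony comparisons (task-dependence analysis).

Per-dyad phase-averaged dtw/second values are compared between phases with
Wilcoxon signed-rank tests (exact two-sided p by enumeration up to n = 25,
normal approximation with continuity and tie corrections above), adjusted for
multiple comparisons with the Benjamini-Hochberg step-up procedure within
each metric's family, and accompanied by the matched-pairs rank-biserial
correlation r = (W+ - W-)/(W+ + W-) with Cohen-style magnitude labels
(0.1 / 0.3 / 0.5 boundaries, lower-inclusive).

Because lower dtw/second means higher synchrony, a positive r for the pair
(A, B) — dtw higher in A — is reported as higher physiological synchrony in B.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from statsmodels.stats.multitest import multipletests

from .types import PHASE_CATEGORIES, ValidationError

logger = logging.getLogger("teamsync")

EXACT_N_MAX = 25
ALPHA_DEFAULT = 0.05
MIN_PAIRS = 3


@dataclass(frozen=True)
class WilcoxonResult:
    n: int                 # pairs with nonzero difference
    w_plus: float
    w_minus: float
    p: float
    method: str            # "exact" | "approx" | "degenerate"


def wilcoxon_signed_rank(x, y) -> WilcoxonResult:
    """Two-sided Wilcoxon signed-rank test on paired samples.

    Pairs with a missing value are deleted pairwise; zero differences are
    discarded (Wilcoxon's convention).  |d| are ranked with midranks for ties.
    For n <= 25 the two-sided p is exact, computed by dynamic-programming
    enumeration of the 2^n sign assignments; beyond that a normal
    approximation with continuity and tie corrections is used.  All
    differences zero is degenerate: p = 1, W+ = 0.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValidationError("paired samples must have equal length")
    keep = np.isfinite(x) & np.isfinite(y)
    d = x[keep] - y[keep]
    d = d[d != 0]
    n = d.size
    if n == 0:
        return WilcoxonResult(0, 0.0, 0.0, 1.0, "degenerate")
    ranks = rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    w_minus = float(ranks[d < 0].sum())
    if n <= EXACT_N_MAX:
        p = _exact_two_sided_p(ranks, w_plus)
        return WilcoxonResult(n, w_plus, w_minus, p, "exact")
    p = _approx_two_sided_p(ranks, w_plus, d)
    return WilcoxonResult(n, w_plus, w_minus, p, "approx")


def _exact_two_sided_p(ranks: np.ndarray, w_plus: float) -> float:
    """Exact two-sided p over all sign assignments (midranks doubled to ints)."""
    r2 = np.rint(2 * ranks).astype(int)  # midranks are multiples of 1/2
    total = int(r2.sum())
    # counts[s] = number of sign assignments with doubled W+ equal to s
    counts = np.zeros(total + 1, dtype=float)
    counts[0] = 1.0
    for r in r2:
        counts[r:] += counts[: counts.size - r].copy()
    counts /= 2.0 ** ranks.size
    w2 = int(np.rint(2 * w_plus))
    p_low = counts[: w2 + 1].sum()
    p_high = counts[w2:].sum()
    return float(min(1.0, 2.0 * min(p_low, p_high)))


def _approx_two_sided_p(ranks: np.ndarray, w_plus: float, d: np.ndarray) -> float:
    from scipy.stats import norm

    n = d.size
    mu = n * (n + 1) / 4.0
    var = n * (n + 1) * (2 * n + 1) / 24.0
    _, tie_counts = np.unique(ranks, return_counts=True)
    var -= np.sum(tie_counts**3 - tie_counts) / 48.0
    if var <= 0:
        return 1.0
    diff = w_plus - mu
    z = (diff - 0.5 * np.sign(diff)) / np.sqrt(var)
    return float(min(1.0, 2.0 * norm.sf(abs(z))))


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (order-preserving, capped at 1)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any(~np.isfinite(p)) or np.any(p < 0) or np.any(p > 1):
        raise ValidationError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def rank_biserial(x, y) -> float:
    """Matched-pairs rank-biserial correlation r = (W+ - W-)/(W+ + W-).

    Uses the same midranks and zero-discarding as the signed-rank test.
    NaN (undefined) when all differences are zero.
    """
    res = wilcoxon_signed_rank(x, y)
    if res.n == 0:
        return np.nan
    return (res.w_plus - res.w_minus) / (res.w_plus + res.w_minus)


def classify_effect(r: float) -> str:
    """Cohen-style magnitude for |r|: <0.1 negligible, <0.3 small, <0.5 moderate, else large."""
    if not np.isfinite(r) or abs(r) > 1:
        raise ValidationError(f"effect size must be finite with |r| <= 1, got {r}")
    a = abs(r)
    if a < 0.1:
        return "negligible"
    if a < 0.3:
        return "small"
    if a < 0.5:
        return "moderate"
    return "large"


@dataclass
class PhaseComparison:
    metric: str
    phase_a: str
    phase_b: str
    n_pairs: int
    w_plus: float
    p_raw: float
    p_adj: float
    r_rb: float
    magnitude: str | None
    significant: bool
    higher_ps_phase: str | None  # phase with lower dtw/second, i.e. higher synchrony
    method: str
    summary: dict = field(default_factory=dict)  # per-phase median/SD of the paired values

    def to_dict(self) -> dict:
        return {
            "metric": self.metric, "phase_a": self.phase_a, "phase_b": self.phase_b,
            "n_pairs": self.n_pairs, "w_plus": self.w_plus,
            "p_raw": self.p_raw, "p_adj": self.p_adj,
            "r_rb": None if not np.isfinite(self.r_rb) else self.r_rb,
            "magnitude": self.magnitude, "significant": self.significant,
            "higher_ps_phase": self.higher_ps_phase, "method": self.method,
            "summary": self.summary,
        }


def _category_means(phase_avg: pd.DataFrame) -> pd.DataFrame:
    """Add pooled phase categories (baseline / pre / scenario) to a phase-average table."""
    frames = [phase_avg.assign(phase_key=phase_avg["phase"])]
    for cat, members in PHASE_CATEGORIES.items():
        sub = phase_avg[phase_avg["phase"].isin(members)]
        if sub.empty:
            continue
        pooled = (
            sub.groupby(["team_id", "dyad", "metric", "delta_s"], sort=True)["mean_dtw_per_second"]
            .mean()
            .reset_index()
            .assign(phase_key=cat)
        )
        frames.append(pooled)
    return pd.concat(frames, ignore_index=True)


def compare_phases(
    phase_avg: pd.DataFrame,
    phase_pairs: list[tuple[str, str]],
    *,
    metrics: list[str] | None = None,
    alpha: float = ALPHA_DEFAULT,
    family: str = "metric",
) -> list[PhaseComparison]:
    """Paired phase comparisons on a phase-average table (one row per dyad-phase).

    ``phase_pairs`` may name concrete phases (``street``) or pooled categories
    (``baseline``, ``pre``, ``scenario``).  BH adjustment is applied within
    each metric's family (``family="pooled"`` corrects across all metrics at
    once).  Comparisons with fewer than 3 complete dyad pairs are skipped with
    a warning.  Significance is flagged at adjusted p < alpha.
    """
    if family not in ("metric", "pooled"):
        raise ValidationError(f"unknown BH family {family!r}")
    table = _category_means(phase_avg)
    metrics = metrics or sorted(table["metric"].unique())
    comparisons: list[PhaseComparison] = []
    for metric in metrics:
        sub = table[table["metric"] == metric]
        wide = sub.pivot_table(index=["team_id", "dyad"], columns="phase_key",
                               values="mean_dtw_per_second", aggfunc="mean")
        for pa, pb in phase_pairs:
            if pa not in wide.columns or pb not in wide.columns:
                logger.warning("metric %s: phase pair (%s, %s) unavailable; skipped", metric, pa, pb)
                continue
            pair = wide[[pa, pb]].dropna()
            if len(pair) < MIN_PAIRS:
                logger.warning("metric %s: only %d complete pairs for (%s, %s); skipped",
                               metric, len(pair), pa, pb)
                continue
            x, y = pair[pa].to_numpy(), pair[pb].to_numpy()
            res = wilcoxon_signed_rank(x, y)
            r = rank_biserial(x, y)
            higher = None
            if np.isfinite(r) and r != 0:
                higher = pb if r > 0 else pa  # positive r: dtw higher in A => more synchrony in B
            comparisons.append(PhaseComparison(
                metric=metric, phase_a=pa, phase_b=pb, n_pairs=len(pair),
                w_plus=res.w_plus, p_raw=res.p, p_adj=np.nan,
                r_rb=r, magnitude=classify_effect(r) if np.isfinite(r) else None,
                significant=False, higher_ps_phase=higher, method=res.method,
                summary={
                    pa: {"median": float(np.median(x)), "sd": float(np.std(x, ddof=1))},
                    pb: {"median": float(np.median(y)), "sd": float(np.std(y, ddof=1))},
                },
            ))
    # multiplicity correction within the chosen family
    if family == "pooled":
        groups = {None: comparisons}
    else:
        groups = {}
        for c in comparisons:
            groups.setdefault(c.metric, []).append(c)
    for fam in groups.values():
        adj = bh_adjust([c.p_raw for c in fam])
        for c, pa in zip(fam, adj):
            c.p_adj = float(pa)
            c.significant = bool(pa < alpha)
    return comparisons
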