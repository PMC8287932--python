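"""Spearman rank-order correlation of cohort score tables.

Spearman's rho is the Pearson correlation of average ranks, so it is
invariant under strictly monotone transforms of either variable — which is
exactly why the log10(count + 0.5) display transform used for APOBEC burdens
is correlation-neutral.  Two-sided P values come from the t approximation
``t = rho * sqrt((n-2)/(1-rho^2))`` for n >= 10 and from exact enumeration
of all n! pairings for smaller n.  Significance is assessed at alpha = 0.05;
P values are reported raw (an optional Benjamini-Hochberg column is offered
but is an extra, not part of the original analysis convention).
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger("tcwsig")

ALPHA = 0.05
EXACT_N_MAX = 9  # exact permutation enumeration below this sample size


@dataclass(frozen=True)
class CorrelationResult:
    x_name: str
    y_name: str
    n: int
    rho: float
    p_value: float
    method: str  # tie handling + p-value approximation note


def _rho_of_ranks(rx: np.ndarray, ry: np.ndarray) -> float:
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    denom = math.sqrt(float(rx @ rx) * float(ry @ ry))
    if denom == 0.0:
        raise ValueError("undefined correlation: constant vector")
    return float(rx @ ry) / denom


def spearman(
    x, y, x_name: str = "x", y_name: str = "y"
) -> CorrelationResult:
    """Spearman rank correlation with a two-sided P value.

    Ties get average ranks; rho is the Pearson correlation of the ranks.
    Missing values are handled pairwise-complete.  Requires >= 3 complete
    pairs and non-constant vectors.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError(f"length mismatch: {x.shape} vs {y.shape}")
    keep = ~(np.isnan(x) | np.isnan(y))
    x, y = x[keep], y[keep]
    n = len(x)
    if n < 3:
        raise ValueError(f"need >= 3 pairwise-complete observations, got {n}")
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    rho = _rho_of_ranks(rx, ry)
    rho = float(np.clip(rho, -1.0, 1.0))
    if n <= EXACT_N_MAX:
        p = _exact_p(rx, ry, rho)
        method = "average ranks; exact permutation p"
    else:
        denom = 1.0 - rho * rho
        if denom <= 0.0:  # |rho| == 1: t statistic diverges
            p = 0.0
        else:
            t = rho * math.sqrt((n - 2) / denom)
            p = float(2.0 * stats.t.sf(abs(t), n - 2))
        method = "average ranks; t approximation p"
    p = min(p, 1.0)
    return CorrelationResult(x_name, y_name, n, rho, p, method)


def _exact_p(rx: np.ndarray, ry: np.ndarray, rho_obs: float) -> float:
    """Two-sided exact P: fraction of the n! pairings with |rho| >= |rho_obs|.

    Conditions on the observed tie patterns (rank vectors are fixed, only the
    pairing is permuted)."""
    n = len(rx)
    rxc = rx - rx.mean()
    ryc = ry - ry.mean()
    denom = math.sqrt(float(rxc @ rxc) * float(ryc @ ryc))
    perms = np.array(list(itertools.permutations(range(n))))
    rhos = (ryc[perms] @ rxc) / denom
    return float(np.mean(np.abs(rhos) >= abs(rho_obs) - 1e-12))


def filter_cohorts(
    cohorts: dict[str, pd.DataFrame], min_n: int = 100
) -> dict[str, pd.DataFrame]:
    """Keep cohorts with strictly more than ``min_n`` samples.

    The strict inequality mirrors the ">100 samples with available
    mutational data" selection rule: a cohort of exactly ``min_n`` samples
    is dropped.
    """
    kept = {name: t for name, t in cohorts.items() if len(t) > min_n}
    dropped = sorted(set(cohorts) - set(kept))
    for name in dropped:
        logger.info(
            "filter_cohorts: dropping %s (n=%d <= %d)", name, len(cohorts[name]), min_n
        )
    if not kept:
        raise ValueError(
            f"no cohorts retained: all have <= {min_n} samples ({list(cohorts)})"
        )
    return kept


def correlate_panel(
    table: pd.DataFrame,
    x_cols: list[str],
    y_cols: list[str],
    bh_adjust: bool = False,
) -> pd.DataFrame:
    """All pairwise Spearman correlations between two column sets.

    Returns a long-format frame (x, y, n, rho, p) in the requested order.
    ``bh_adjust`` appends a Benjamini-Hochberg column labelled ``p_bh`` as a
    clearly optional extra; raw P values remain the primary output.
    """
    missing = [c for c in [*x_cols, *y_cols] if c not in table.columns]
    if missing:
        raise KeyError(f"columns not in score table: {missing}")
    rows = []
    for xc in x_cols:
        for yc in y_cols:
            try:
                r = spearman(table[xc], table[yc], xc, yc)
            except ValueError as exc:
                raise ValueError(f"correlation failed for pair ({xc}, {yc}): {exc}")
            rows.append((r.x_name, r.y_name, r.n, r.rho, r.p_value))
    out = pd.DataFrame(rows, columns=["x", "y", "n", "rho", "p"])
    if bh_adjust:
        out["p_bh"] = stats.false_discovery_control(out["p"], method="bh")
    return out


def panel_matrix(panel: pd.DataFrame, value: str = "rho") -> pd.DataFrame:
    """Pivot a long-format panel into an x-by-y matrix (heatmap layout)."""
    return panel.pivot(index="x", columns="y", values=value)


def plot_score_scatter(
    table: pd.DataFrame,
    x: str = "hypsig",
    y: str = "log_shifted",
    path: str | None = None,
    title: str | None = None,
):
    """Scatter of a signature score against log-shifted APOBEC burden,
    annotated with the Spearman rho and P value."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    r = spearman(table[x], table[y], x, y)
    fig, ax = plt.subplots(figsize=(4.5, 4))
    ax.scatter(table[x], table[y], s=10, alpha=0.6, edgecolors="none")
    ax.set_xlabel(x)
    ax.set_ylabel(y)
    ax.set_title(title or f"rho={r.rho:.3f}, P={r.p_value:.2e} (n={r.n})")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig
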