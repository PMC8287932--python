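"""Quantification rules for the bench assays: foci-threshold cell
classification, replication-catastrophe co-positivity, nuclear-area
comparison, ddCt qPCR fold changes and deamination-gel quantification.

All operations consume tidy tabular inputs (one row per cell / Ct
measurement / gel lane); image segmentation and densitometry are upstream
and out of scope.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger("tcwsig")

# positive iff foci count strictly exceeds the threshold
DEFAULT_FOCI_THRESHOLDS = {"53BP1": 5, "RPA": 6}
MIN_CELLS_PER_CONDITION = 150  # warn below this counting depth

CONDITION_COL = "condition"


def classify_cells(
    cells: pd.DataFrame,
    channel: str,
    threshold: int | None = None,
    strict: bool = True,
) -> tuple[pd.Series, pd.DataFrame]:
    """Threshold foci counts into positive/negative cells.

    Defaults: 53BP1-positive iff count > 5; RPA-positive iff count > 6
    (strict inequalities).  Returns the per-cell boolean series and a
    per-condition summary with ``n_cells``, ``n_positive`` and
    ``pct_positive``; conditions counted at fewer than 150 cells trigger a
    warning.
    """
    if channel not in cells.columns:
        raise KeyError(f"unknown foci channel {channel!r}; columns: {list(cells.columns)}")
    if threshold is None:
        if channel not in DEFAULT_FOCI_THRESHOLDS:
            raise KeyError(f"no default threshold for channel {channel!r}")
        threshold = DEFAULT_FOCI_THRESHOLDS[channel]
    counts = cells[channel]
    if (counts < 0).any():
        raise ValueError(f"negative foci counts in channel {channel!r}")
    positive = counts > threshold if strict else counts >= threshold
    positive.name = f"{channel}_positive"
    summary = (
        cells.assign(_pos=positive)
        .groupby(CONDITION_COL, sort=False)
        .agg(n_cells=("_pos", "size"), n_positive=("_pos", "sum"))
        .reset_index()
    )
    summary["pct_positive"] = 100.0 * summary["n_positive"] / summary["n_cells"]
    low = summary[summary["n_cells"] < MIN_CELLS_PER_CONDITION]
    for row in low.itertuples(index=False):
        warnings.warn(
            f"condition {row.condition!r}: only {row.n_cells} cells counted "
            f"(< {MIN_CELLS_PER_CONDITION})",
            stacklevel=2,
        )
    return positive, summary


def replication_catastrophe_fraction(
    cells: pd.DataFrame,
    thresholds: dict[str, int] | None = None,
) -> pd.DataFrame:
    """Per-condition percentage of cells positive for both damage (53BP1)
    and replication-stress (RPA) foci — the replication-catastrophe readout.

    Double-positive = (53BP1 > 5) AND (RPA > 6) under the default
    thresholds.
    """
    thresholds = dict(DEFAULT_FOCI_THRESHOLDS, **(thresholds or {}))
    for channel in thresholds:
        if channel not in cells.columns:
            raise KeyError(f"missing foci channel {channel!r} in cell table")
    double = np.ones(len(cells), dtype=bool)
    for channel, thr in thresholds.items():
        pos, _ = classify_cells(cells, channel, thr)
        double &= pos.to_numpy()
    summary = (
        cells.assign(_dp=double)
        .groupby(CONDITION_COL, sort=False)
        .agg(n_cells=("_dp", "size"), n_double_positive=("_dp", "sum"))
        .reset_index()
    )
    summary["pct_double_positive"] = (
        100.0 * summary["n_double_positive"] / summary["n_cells"]
    )
    return summary


@dataclass(frozen=True)
class GroupComparison:
    """Group means +/- SEM and a two-sided test on nuclear areas."""

    groups: pd.DataFrame  # group, n, mean, sem
    statistic: float
    p_value: float
    test: str


def compare_nuclear_area(
    cells: pd.DataFrame,
    group_col: str | None = None,
    area_col: str = "nuclear_area",
    thresholds: dict[str, int] | None = None,
) -> GroupComparison:
    """Compare mean nuclear area between cell groups.

    By default the two groups are replication-catastrophe double-positive
    versus not (53BP1 > 5 AND RPA > 6).  Two groups are compared with a
    two-sided unpaired Welch t test — per-cell areas across damage groups
    are unpaired observations, so a paired test is not applicable; more than
    two groups use one-way ANOVA.
    """
    if area_col not in cells.columns:
        raise KeyError(f"missing area column {area_col!r}")
    work = cells.dropna(subset=[area_col]).copy()
    if group_col is None:
        thresholds = dict(DEFAULT_FOCI_THRESHOLDS, **(thresholds or {}))
        double = np.ones(len(work), dtype=bool)
        for channel, thr in thresholds.items():
            double &= (work[channel] > thr).to_numpy()
        work["_group"] = np.where(double, "double_positive", "negative")
        group_col = "_group"
    grouped = [
        (name, g[area_col].to_numpy()) for name, g in work.groupby(group_col, sort=False)
    ]
    for name, vals in grouped:
        if len(vals) < 2:
            raise ValueError(f"group {name!r} has fewer than 2 cells")
    rows = [
        (name, len(v), float(v.mean()), float(stats.sem(v))) for name, v in grouped
    ]
    groups = pd.DataFrame(rows, columns=["group", "n", "mean", "sem"])
    arrays = [v for _, v in grouped]
    if len(arrays) < 2:
        raise ValueError("need at least 2 groups to compare")
    if len(arrays) == 2:
        res = stats.ttest_ind(arrays[0], arrays[1], equal_var=False)
        test = "Welch two-sided unpaired t"
    else:
        res = stats.f_oneway(*arrays)
        test = "one-way ANOVA"
    return GroupComparison(groups, float(res.statistic), float(res.pvalue), test)


def ddct_fold_change(
    ct: pd.DataFrame,
    target_gene: str,
    control_gene: str = "18S",
    reference_condition: str = "normoxia",
) -> pd.DataFrame:
    """Relative expression by the ddCt method.

    Per biological replicate, dCt = Ct(target) - Ct(control) within each
    condition; ddCt = dCt(condition) - dCt(reference condition, same
    replicate); fold = 2^(-ddCt).  Folds are then averaged over replicates
    with SEM, so the reference condition's own fold is exactly 1 in every
    replicate.  ``ct`` columns: gene, condition, replicate, Ct.
    """
    required = {"gene", "condition", "replicate", "Ct"}
    if not required.issubset(ct.columns):
        raise ValueError(f"Ct table needs columns {sorted(required)}")
    if not np.isfinite(ct["Ct"]).all():
        raise ValueError("non-finite Ct values")

    def _ct(gene: str, condition: str, replicate) -> float:
        sel = ct[
            (ct["gene"] == gene)
            & (ct["condition"] == condition)
            & (ct["replicate"] == replicate)
        ]["Ct"]
        if sel.empty:
            raise ValueError(
                f"missing Ct for gene={gene!r} in (condition={condition!r}, "
                f"replicate={replicate!r})"
            )
        return float(sel.mean())  # technical replicates averaged

    conditions = list(dict.fromkeys(ct["condition"]))
    if reference_condition not in conditions:
        raise ValueError(f"reference condition {reference_condition!r} absent")
    replicates = [
        r.item() if hasattr(r, "item") else r for r in sorted(ct["replicate"].unique())
    ]
    rows = []
    for condition in conditions:
        folds = []
        for rep in replicates:
            dct = _ct(target_gene, condition, rep) - _ct(control_gene, condition, rep)
            dct_ref = _ct(target_gene, reference_condition, rep) - _ct(
                control_gene, reference_condition, rep
            )
            folds.append(2.0 ** -(dct - dct_ref))
        folds = np.asarray(folds)
        sem = float(stats.sem(folds)) if len(folds) > 1 else np.nan
        rows.append((condition, len(folds), float(folds.mean()), sem, list(folds)))
    return pd.DataFrame(
        rows, columns=["condition", "n_replicates", "fold_mean", "fold_sem", "folds"]
    )


def deamination_quant(
    lanes: pd.DataFrame, reference_condition: str = "normoxia"
) -> pd.DataFrame:
    """Quantify a deamination gel from substrate (S) and product (P) band
    intensities.

    Primary metric: mean product intensity per condition relative to the
    reference condition's mean product intensity (so the reference is
    exactly 1).  Secondary QC metric: per-lane product fraction P/(S+P),
    averaged per condition.  ``lanes`` columns: condition, replicate, S, P.
    """
    required = {"condition", "S", "P"}
    if not required.issubset(lanes.columns):
        raise ValueError(f"lane table needs columns {sorted(required)}")
    if ((lanes["S"] < 0) | (lanes["P"] < 0)).any():
        raise ValueError("negative band intensities")
    if ((lanes["S"] + lanes["P"]) <= 0).any():
        raise ValueError("lane with S + P == 0")
    ref = lanes[lanes["condition"] == reference_condition]
    if ref.empty:
        raise ValueError(f"reference condition {reference_condition!r} absent")
    ref_p = float(ref["P"].mean())
    if ref_p <= 0:
        raise ValueError("reference product intensity is zero")
    out = (
        lanes.assign(_frac=lanes["P"] / (lanes["S"] + lanes["P"]))
        .groupby("condition", sort=False)
        .agg(
            n_lanes=("P", "size"),
            mean_P=("P", "mean"),
            sem_P=("P", lambda v: stats.sem(v) if len(v) > 1 else np.nan),
            product_fraction=("_frac", "mean"),
        )
        .reset_index()
    )
    out["relative_product"] = out["mean_P"] / ref_p
    return out


@dataclass(frozen=True)
class TcwSite:
    """A TCW motif occurrence; ``pos`` is the 0-based offset of the motif's
    first base on the given strand's plus-coordinates."""

    pos: int
    strand: str  # "+" or "-"
    context: str  # the TCW triplet as read 5'->3' on that strand


def scan_tcw_sites(sequence: str, both_strands: bool = False) -> list[TcwSite]:
    """Locate TCW (T-C-[A|T]) motifs in a nucleotide sequence.

    Plus-strand sites are literal TCA/TCT matches; with ``both_strands``,
    minus-strand sites ([T|A]GA on the plus strand, i.e. TCW read on the
    complement) are included.  Used to verify deamination-substrate designs
    and by the synthetic cohort generator.
    """
    seq = sequence.upper()
    sites = []
    for i in range(len(seq) - 2):
        trip = seq[i : i + 3]
        if trip[0] == "T" and trip[1] == "C" and trip[2] in "AT":
            sites.append(TcwSite(i, "+", trip))
        if both_strands and trip[2] == "A" and trip[1] == "G" and trip[0] in "AT":
            # complement of [T|A]GA read 3'->5' is TC[A|T] on the minus strand
            comp = {"A": "T", "T": "A", "G": "C", "C": "G"}
            sites.append(TcwSite(i, "-", "".join(comp[b] for b in reversed(trip))))
    return sites


# the deamination-assay substrate: a single TCA site downstream of an
# internal abasic-site surrogate (N), FAM-labelled in the bench assay
DEAMINATION_SUBSTRATE = "ATTATTATTANTCAAATGGATTTATTTATTTATTTATTTATTT"
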