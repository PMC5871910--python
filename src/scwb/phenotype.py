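"""Cell gating and population statistics for scWB cohorts.

Gating follows the three-step marker logic: loading controls (actinin
and GAPDH) separate cells from debris and empty wells; pan-cytokeratin
separates epithelial cells; the HER2 band identifies HER2-positive
cells; the truncated-HER2 call comes from the isoform table.  Population
summaries report %Pos, the mean abundance among positives (AVG), the
staining score (AVG x %Pos), CV, and the max/min fold change.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "PopulationSummary",
    "GroupComparison",
    "gate_cells",
    "summarize_population",
    "remove_outliers",
    "empirical_pvalue",
    "copy_number",
    "compare_groups",
    "capture_probability",
]


@dataclass(frozen=True)
class PopulationSummary:
    n: int
    n_pos: int
    pos_fraction: float
    avg: float
    sd: float
    cv_percent: float
    staining: float
    fold_change: float


@dataclass(frozen=True)
class GroupComparison:
    test: str
    statistic: float
    p_value: float
    n_a: int
    n_b: int


def gate_cells(fit_table: pd.DataFrame, calls: pd.DataFrame | None = None,
               controls: tuple[str, str] = ("actinin", "GAPDH"),
               epithelial_marker: str = "panCK") -> pd.DataFrame:
    """One row per lane with gate flags and per-target abundances.

    is_cell: both loading controls pass QC.  is_epithelial: is_cell and
    the epithelial marker passes.  is_her2_pos: is_epithelial and the
    full-length HER2 band passes.  is_terbb2_pos: is_her2_pos and the
    lane's isoform call is truncated-positive.  Lanes missing a control
    trace are excluded (cannot be gated).
    """
    call_idx = (calls.set_index("lane_id") if calls is not None
                and len(calls) else None)
    rows = []
    for lane_id, grp in fit_table.groupby("lane_id", sort=True):
        by_target = {r["target"]: r for _, r in grp.iterrows()}
        if any(c not in by_target for c in controls):
            continue  # ungateable lane: required control not probed
        rec: dict = {"lane_id": lane_id}
        for tgt, r in by_target.items():
            rec[f"auc_{tgt}"] = r["auc"] if r["qc_pass"] else np.nan
            rec[f"qc_{tgt}"] = bool(r["qc_pass"])
        is_cell = all(by_target[c]["qc_pass"] for c in controls)
        is_epi = bool(is_cell and epithelial_marker in by_target
                      and by_target[epithelial_marker]["qc_pass"])
        is_her2 = bool(is_epi and "p185" in by_target
                       and by_target["p185"]["qc_pass"])
        is_terbb2 = False
        ratio = np.nan
        if call_idx is not None and lane_id in call_idx.index:
            c = call_idx.loc[lane_id]
            is_terbb2 = bool(is_her2 and c["has_terbb2"])
            ratio = c["ratio_t_over_p185"]
        elif "terbb2" in by_target:
            is_terbb2 = bool(is_her2 and by_target["terbb2"]["qc_pass"])
            if is_terbb2 and by_target["p185"]["qc_pass"]:
                ratio = by_target["terbb2"]["auc"] / by_target["p185"]["auc"]
        rec.update(is_cell=is_cell, is_epithelial=is_epi,
                   is_her2_pos=is_her2, is_terbb2_pos=is_terbb2,
                   ratio_t_over_p185=ratio)
        for num, den, out in (("p-ERK", "ERK", "ratio_perk_erk"),
                              ("p-rs6", "rs6", "ratio_prs6_rs6")):
            a, b = rec.get(f"auc_{num}"), rec.get(f"auc_{den}")
            rec[out] = (a / b if a is not None and b is not None
                        and np.isfinite(a) and np.isfinite(b) and b != 0
                        else np.nan)
        rows.append(rec)
    return pd.DataFrame(rows)


def summarize_population(cells: pd.DataFrame, target: str,
                         positive_col: str | None = None) -> PopulationSummary:
    """Population summary of one target's abundance.

    Positivity defaults to the target's own QC flag column qc_<target>.
    AVG/SD/CV/fold change are computed among positives only.
    """
    if len(cells) == 0:
        raise ValueError("no cells to summarize")
    pos_col = positive_col or f"qc_{target}"
    pos = cells[pos_col].fillna(False).astype(bool)
    vals = cells.loc[pos, f"auc_{target}"].dropna().to_numpy(dtype=float)
    n = len(cells)
    n_pos = int(pos.sum())
    frac = n_pos / n
    if len(vals) == 0:
        return PopulationSummary(n, n_pos, frac, np.nan, np.nan, np.nan,
                                 0.0, np.nan)
    avg = float(np.mean(vals))
    sd = float(np.std(vals, ddof=1)) if len(vals) > 1 else 0.0
    cv = 100.0 * sd / avg if avg != 0 else np.nan
    fold = float(vals.max() / vals.min()) if vals.min() > 0 else np.inf
    return PopulationSummary(n, n_pos, frac, avg, sd, cv, avg * frac, fold)


def remove_outliers(values, n_sd: float = 4.0) -> np.ndarray:
    """Single-pass outlier filter: drop x with |x - mean| > n_sd * SD.

    Mean and SD come from the full sample; the rule is applied once and
    not re-iterated.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 3:
        raise ValueError("need at least 3 values")
    mu = x.mean()
    sd = x.std(ddof=1)
    if sd == 0:
        return x.copy()
    return x[np.abs(x - mu) <= n_sd * sd]


def empirical_pvalue(observed: float, reference,
                     convention: str = "count") -> float:
    """Rank-based empirical p-value of one observation against references.

    "count": p = max(1, #{ref >= observed}) / n_ref (never exactly 0).
    "add_one": p = (#{ref >= observed} + 1) / (n_ref + 1).
    """
    ref = np.asarray(reference, dtype=float)
    if ref.size == 0:
        raise ValueError("reference set is empty")
    k = int(np.sum(ref >= observed))
    if convention == "count":
        return max(1, k) / ref.size
    if convention == "add_one":
        return (k + 1) / (ref.size + 1)
    raise ValueError(f"unknown convention {convention!r}")


def copy_number(ratio_t_over_p185: float,
                receptors_per_cell: float = 5e5) -> float:
    """Truncated-HER2 copies per cell from the abundance ratio.

    Scales the truncated/full-length AUC ratio by the assumed number of
    full-length HER2 receptors per cell (5e5 for BT474).
    """
    if ratio_t_over_p185 < 0:
        raise ValueError("ratio must be non-negative")
    return ratio_t_over_p185 * receptors_per_cell


def compare_groups(a, b, test: str,
                   alternative: str = "two-sided") -> GroupComparison:
    """Two-group comparison with the study's test battery.

    test: "mann-whitney" (two-tailed; exact for small tie-free samples,
    normal approximation with tie correction otherwise), "spearman"
    (rho with two-sided p), "f-variance" (variance-ratio F with the
    larger variance in the numerator, two-sided p), "paired-t"
    (one-tailed by default via ``alternative``).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 values")
    if test == "mann-whitney":
        res = sps.mannwhitneyu(a, b, alternative=alternative, method="auto")
        return GroupComparison(test, float(res.statistic), float(res.pvalue),
                               a.size, b.size)
    if test == "spearman":
        rho, p = sps.spearmanr(a, b)
        return GroupComparison(test, float(rho), float(p), a.size, b.size)
    if test == "f-variance":
        va, vb = np.var(a, ddof=1), np.var(b, ddof=1)
        if va >= vb:
            f, dfn, dfd = va / vb, a.size - 1, b.size - 1
        else:
            f, dfn, dfd = vb / va, b.size - 1, a.size - 1
        p = 2.0 * min(sps.f.sf(f, dfn, dfd), 1.0 - sps.f.sf(f, dfn, dfd))
        return GroupComparison(test, float(f), float(min(p, 1.0)),
                               a.size, b.size)
    if test == "paired-t":
        alt = "greater" if alternative == "two-sided" else alternative
        res = sps.ttest_rel(a, b, alternative=alt)
        return GroupComparison(test, float(res.statistic), float(res.pvalue),
                               a.size, b.size)
    raise ValueError(f"unknown test {test!r}")


def capture_probability(n_lanes: int, subpop_fraction: float,
                        k_min: int) -> float:
    """P(at least k_min subpopulation cells among n_lanes single cells).

    Exact binomial tail: X ~ Binomial(n_lanes, fraction), P(X >= k_min).
    Quantifies how many microwells are needed to capture a rare
    subpopulation (e.g. 1% truncated-HER2 cells).
    """
    if not 0.0 <= subpop_fraction <= 1.0:
        raise ValueError("fraction must be in [0, 1]")
    if k_min < 0 or k_min > n_lanes:
        raise ValueError("need 0 <= k_min <= n_lanes")
    if k_min == 0:
        return 1.0
    return float(sps.binom.sf(k_min - 1, n_lanes, subpop_fraction))
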