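"""Construct screening statistics: per-construct aggregation, many-to-one
comparison against the wild type, and phenotype classification.

Each construct's pulse-averaged kinetics (decay t_half, recovery tau,
inhibition ratio, affinity index) are summarized as mean +/- SEM, compared
to the wild-type group with a one-way ANOVA followed by a Dunnett-type
many-to-one test, and classified into phenotype flags at the p < 0.05
tier.  The Dunnett adjustment is computed by seeded parametric resampling
of the max-|t| null (pooled-variance t statistics against the control,
multiplicity handled by the maximum over comparators), which keeps the
procedure testable by Monte-Carlo calibration and handles unbalanced
groups directly.  Kinetic metrics are compared on the log scale
(strictly positive, right-skewed); the inhibition ratio on the natural
scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = ["ScreenResult", "aggregate", "compare_to_wt", "classify", "run_screen"]

METRICS = ("t_half_ms", "tau_s", "inhibition_ratio", "affinity_index")
LOG_METRICS = frozenset({"t_half_ms", "tau_s", "affinity_index"})
N_RESAMPLE = 50_000
ALPHA = 0.05

_null_cache: dict = {}


def aggregate(cells: pd.DataFrame, metrics=METRICS) -> pd.DataFrame:
    """Per-construct n / mean / SD / SEM for each metric.

    ``cells`` has one row per cell with a ``construct`` column.  SEM is
    SD/sqrt(n) and is reported as NaN for single-cell groups.
    """
    rows = []
    for label, g in cells.groupby("construct", sort=False):
        for m in metrics:
            x = g[m].dropna().to_numpy(dtype=float)
            n = x.size
            sd = float(np.std(x, ddof=1)) if n >= 2 else np.nan
            rows.append({
                "construct": label, "metric": m, "n": n,
                "mean": float(np.mean(x)) if n else np.nan,
                "sd": sd, "sem": sd / np.sqrt(n) if n >= 2 else np.nan,
            })
    return pd.DataFrame(rows)


def _maxt_null(sizes: tuple, n_resample: int, seed: int) -> np.ndarray:
    """Sorted null sample of max over comparators of |t_i| for group sizes
    (control first), under the global null of equal normal populations."""
    key = (sizes, n_resample, seed)
    if key in _null_cache:
        return _null_cache[key]
    rng = np.random.default_rng(seed)
    n0, rest = sizes[0], sizes[1:]
    df = sum(sizes) - len(sizes)
    maxt = np.zeros(n_resample)
    x0 = rng.normal(size=(n_resample, n0))
    m0 = x0.mean(axis=1)
    ss = ((x0 - m0[:, None]) ** 2).sum(axis=1)
    t_all = np.empty((len(rest), n_resample))
    ss_tot = ss.copy()
    means = []
    for i, ni in enumerate(rest):
        xi = rng.normal(size=(n_resample, ni))
        mi = xi.mean(axis=1)
        ss_tot += ((xi - mi[:, None]) ** 2).sum(axis=1)
        means.append(mi)
    sp2 = ss_tot / df
    for i, ni in enumerate(rest):
        t_all[i] = (means[i] - m0) / np.sqrt(sp2 * (1.0 / ni + 1.0 / n0))
    maxt = np.abs(t_all).max(axis=0)
    maxt.sort()
    _null_cache[key] = maxt
    return maxt


def compare_to_wt(cells: pd.DataFrame, wt_label: str = "WT", metrics=METRICS,
                  n_resample: int = N_RESAMPLE, seed: int = 0) -> pd.DataFrame:
    """ANOVA + Dunnett-type many-to-one p-values against the control group.

    Returns one row per (construct, metric) with the adjusted p-value and
    the metric-level ANOVA p.  Groups with fewer than 2 cells are skipped
    (insufficient replication, no p-value).
    """
    if wt_label not in set(cells["construct"]):
        raise ValueError(f"control group {wt_label!r} missing")
    rows = []
    for m in metrics:
        groups, labels = [], []
        for label, g in cells.groupby("construct", sort=False):
            x = g[m].dropna().to_numpy(dtype=float)
            if m in LOG_METRICS:
                if np.any(x <= 0):
                    continue
                x = np.log(x)
            if x.size >= 2:
                groups.append(x)
                labels.append(label)
        if wt_label not in labels or len(labels) < 2:
            continue
        i0 = labels.index(wt_label)
        x0 = groups[i0]
        comp = [(lb, x) for lb, x in zip(labels, groups) if lb != wt_label]

        anova_p = float(sps.f_oneway(*groups).pvalue) if all(
            np.std(g) > 0 for g in groups) else (
            1.0 if all(np.allclose(g, groups[0][0]) for g in groups) else np.nan)

        sizes = (x0.size,) + tuple(x.size for _, x in comp)
        df_err = sum(sizes) - len(sizes)
        sp2 = sum(((g - g.mean()) ** 2).sum() for g in [x0] + [x for _, x in comp]) / df_err
        null = _maxt_null(sizes, n_resample, seed)
        for (label, x) in comp:
            diff = x.mean() - x0.mean()
            if sp2 == 0:
                p = 1.0 if diff == 0 else 1.0 / (n_resample + 1)
                t_obs = 0.0 if diff == 0 else np.inf
            else:
                t_obs = diff / np.sqrt(sp2 * (1.0 / x.size + 1.0 / x0.size))
                n_ge = null.size - np.searchsorted(null, abs(t_obs), side="left")
                p = (1.0 + n_ge) / (n_resample + 1.0)
            rows.append({"construct": label, "metric": m, "t_stat": float(t_obs),
                         "p_dunnett": float(p), "p_anova": anova_p,
                         "mean_diff": float(diff)})
    return pd.DataFrame(rows)


FLAGS = ("faster_decay", "slower_decay", "faster_recovery", "slower_recovery",
         "reduced_inhibition", "potentiated", "no_current")


def classify(agg: pd.DataFrame, pvals: pd.DataFrame, wt_label: str = "WT",
             alpha: float = ALPHA, no_current_labels=()) -> pd.DataFrame:
    """Deterministic phenotype flags from (means, p-values).

    Direction comes from the sign of the mean difference to the wild type;
    a flag is set only when the corresponding Dunnett comparison is
    significant at ``alpha``.  ``no_current`` is never inferred — it is
    set only for labels explicitly listed (cells with no agonist
    response)."""
    wt_mean = {r["metric"]: r["mean"]
               for _, r in agg[agg["construct"] == wt_label].iterrows()}
    rows = []
    constructs = [c for c in agg["construct"].unique() if c != wt_label]
    for label in constructs:
        flags = {f: False for f in FLAGS}
        if label in no_current_labels:
            flags["no_current"] = True
        sub = pvals[pvals["construct"] == label] if len(pvals) else pvals
        mean = {r["metric"]: r["mean"]
                for _, r in agg[agg["construct"] == label].iterrows()}

        def sig(metric):
            if sub is None or not len(sub):
                return False
            r = sub[sub["metric"] == metric]
            return bool(len(r)) and float(r["p_dunnett"].iloc[0]) < alpha

        if sig("t_half_ms"):
            if mean["t_half_ms"] < wt_mean["t_half_ms"]:
                flags["faster_decay"] = True
            else:
                flags["slower_decay"] = True
        if sig("tau_s"):
            if mean["tau_s"] < wt_mean["tau_s"]:
                flags["faster_recovery"] = True
            else:
                flags["slower_recovery"] = True
        if sig("inhibition_ratio") and mean["inhibition_ratio"] > wt_mean["inhibition_ratio"]:
            if mean["inhibition_ratio"] > 1.0:
                flags["potentiated"] = True
            else:
                flags["reduced_inhibition"] = True
        rows.append({"construct": label, **flags})
    return pd.DataFrame(rows)


@dataclass
class ScreenResult:
    """Full screening output: aggregates, comparisons, flags, provenance."""

    aggregates: pd.DataFrame
    comparisons: pd.DataFrame
    flags: pd.DataFrame
    wt_label: str = "WT"
    seed: int = 0
    n_resample: int = N_RESAMPLE
    alpha: float = ALPHA
    notes: dict = field(default_factory=dict)

    def significance_tier(self, construct: str, metric: str) -> str:
        r = self.comparisons[(self.comparisons["construct"] == construct)
                             & (self.comparisons["metric"] == metric)]
        if not len(r):
            return ""
        p = float(r["p_dunnett"].iloc[0])
        return "**" if p < 0.01 else ("*" if p < 0.05 else "")


def run_screen(cells: pd.DataFrame, wt_label: str = "WT", seed: int = 0,
               n_resample: int = N_RESAMPLE, alpha: float = ALPHA,
               no_current_labels=()) -> ScreenResult:
    """Aggregate, compare to the wild type and classify in one call."""
    agg = aggregate(cells)
    wt_n = cells[cells["construct"] == wt_label].shape[0]
    if wt_n < 2:
        return ScreenResult(agg, pd.DataFrame(), pd.DataFrame(), wt_label, seed,
                            n_resample, alpha,
                            notes={"insufficient_replication":
                                   f"control has {wt_n} cell(s); no p-values"})
    pvals = compare_to_wt(cells, wt_label, n_resample=n_resample, seed=seed)
    flags = classify(agg, pvals, wt_label, alpha, no_current_labels)
    return ScreenResult(agg, pvals, flags, wt_label, seed, n_resample, alpha)
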