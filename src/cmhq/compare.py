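"""Method-comparison harness: ratios to a reference, stats, timing.

The evaluation design expresses every method's per-section microbleed
area and count as a ratio to a reference counting (ground truth for
synthetic stacks, or an expert's manual counts supplied as CSV), then
tests methods against the reference with one-way ANOVA plus Dunnett's
many-to-one comparison, reporting Shapiro-Wilk normality and
Brown-Forsythe variance-equality diagnostics alongside.

Group-level burden comparisons (e.g. young vs aged vs treated brains)
use the Kruskal-Wallis test with a rank-based many-to-one follow-up
(Dunn's z statistics against the control with Holm correction). Some
published workflows label this follow-up "Dunnett's post hoc" even after
a Kruskal-Wallis omnibus; the parametric Dunnett test does not apply to
ranks, so the rank-based Dunn analogue with a Dunnett-style contrast set
is what is computed here.
"""

from __future__ import annotations

import time
from contextlib import contextmanager
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DataError, StatisticsError

__all__ = [
    "ratio_to_reference",
    "compare_methods",
    "compare_groups",
    "dunn_many_to_one",
    "StageTimer",
    "ComparisonReport",
]

ALPHA = 0.05


def ratio_to_reference(method_results: pd.DataFrame,
                       reference_results: pd.DataFrame) -> pd.DataFrame:
    """Per-section area and count ratios of a method to the reference.

    Inputs carry columns ``section``, ``count``, ``area``. Sections where
    both the method and the reference report zero get ratio 1 (perfect
    agreement on absence); sections where the reference is zero but the
    method is not are flagged ``excluded`` (the ratio is undefined) and
    dropped from means, with the exclusion count reported downstream.
    """
    m = method_results.set_index("section")
    r = reference_results.set_index("section")
    if set(m.index) != set(r.index):
        raise DataError("method and reference section ids do not match")
    m = m.loc[r.index]
    rows = []
    for sec in r.index:
        rc, ra = float(r.loc[sec, "count"]), float(r.loc[sec, "area"])
        mc, ma = float(m.loc[sec, "count"]), float(m.loc[sec, "area"])
        row = {"section": sec, "excluded": False}
        if rc == 0 and mc == 0:
            row["count_ratio"] = 1.0
        elif rc == 0:
            row["count_ratio"] = np.inf
            row["excluded"] = True
        else:
            row["count_ratio"] = mc / rc
        if ra == 0 and ma == 0:
            row["area_ratio"] = 1.0
        elif ra == 0:
            row["area_ratio"] = np.inf
            row["excluded"] = True
        else:
            row["area_ratio"] = ma / ra
        rows.append(row)
    return pd.DataFrame(rows)


@dataclass
class ComparisonReport:
    """Per-method ratio summaries plus omnibus/post-hoc statistics."""

    summary: pd.DataFrame
    anova: dict = field(default_factory=dict)
    diagnostics: pd.DataFrame = None

    def to_json(self) -> dict:
        return {
            "summary": self.summary.to_dict(orient="records"),
            "anova": self.anova,
            "diagnostics": (self.diagnostics.to_dict(orient="records")
                            if self.diagnostics is not None else None),
        }


def _sem(x: np.ndarray) -> float:
    return float(np.std(x, ddof=1) / np.sqrt(len(x))) if len(x) > 1 else 0.0


def compare_methods(ratio_tables: dict, reference_name: str = "reference",
                    alpha: float = ALPHA) -> ComparisonReport:
    """ANOVA + Dunnett comparison of method ratios against the reference.

    ``ratio_tables`` maps method name to the output of
    :func:`ratio_to_reference`; the reference itself is represented by
    all-ones ratios. For each metric (area_ratio, count_ratio) a one-way
    ANOVA across methods is followed by Dunnett's test against the
    reference; Shapiro-Wilk and Brown-Forsythe diagnostics are attached.
    """
    if len(ratio_tables) < 2:
        raise StatisticsError("need >= 2 methods to compare")
    summary_rows, diag_rows, anova = [], [], {}
    for metric in ("area_ratio", "count_ratio"):
        samples = {}
        for name, tbl in ratio_tables.items():
            vals = tbl.loc[~tbl["excluded"], metric].to_numpy(float)
            if len(vals) < 3:
                raise StatisticsError(
                    f"method {name!r} has fewer than 3 usable sections")
            samples[name] = vals
        if reference_name not in samples:
            raise StatisticsError(
                f"reference {reference_name!r} missing from ratio tables")
        names = [n for n in samples if n != reference_name]
        f_stat, f_p = stats.f_oneway(*samples.values())
        anova[metric] = {"F": float(f_stat), "p": float(f_p)}
        try:
            # the reference sample is an exact-ones vector, so scipy warns
            # about zero variance in the control; that is expected here
            import warnings

            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                dn = stats.dunnett(*(samples[n] for n in names),
                                   control=samples[reference_name])
            dunnett_p = dict(zip(names, np.atleast_1d(dn.pvalue)))
        except ValueError:  # e.g. zero variance everywhere
            dunnett_p = {n: np.nan for n in names}
        for name in samples:
            vals = samples[name]
            tbl = ratio_tables[name]
            summary_rows.append({
                "method": name, "metric": metric,
                "mean": float(np.mean(vals)), "sem": _sem(vals),
                "n": int(len(vals)),
                "n_excluded": int(tbl["excluded"].sum()),
                "p_vs_reference": (1.0 if name == reference_name
                                   else float(dunnett_p[name])),
                "significant": (False if name == reference_name
                                else bool(dunnett_p[name] < alpha)),
            })
            if len(np.unique(vals)) > 1:
                sw = stats.shapiro(vals)
                diag_rows.append({"method": name, "metric": metric,
                                  "shapiro_W": float(sw.statistic),
                                  "shapiro_p": float(sw.pvalue)})
        groups = [v for v in samples.values() if len(np.unique(v)) > 0]
        try:
            bf = stats.levene(*groups, center="median")
            diag_rows.append({"method": "(all)", "metric": metric,
                              "brown_forsythe_W": float(bf.statistic),
                              "brown_forsythe_p": float(bf.pvalue)})
        except ValueError:
            pass
    return ComparisonReport(pd.DataFrame(summary_rows), anova,
                            pd.DataFrame(diag_rows))


def kruskal_exact_threshold() -> int:
    """Largest total N for which the exact permutation test is used."""
    return 12


def _kruskal_h(values: np.ndarray, sizes) -> float:
    """Tie-corrected Kruskal-Wallis H for concatenated group values."""
    n = len(values)
    ranks = stats.rankdata(values)
    h = 0.0
    pos = 0
    for sz in sizes:
        h += ranks[pos:pos + sz].sum() ** 2 / sz
        pos += sz
    h = 12.0 / (n * (n + 1)) * h - 3 * (n + 1)
    _, tie_counts = np.unique(values, return_counts=True)
    correction = 1.0 - (tie_counts ** 3 - tie_counts).sum() / (n ** 3 - n)
    return h / correction if correction > 0 else np.nan


def kruskal_wallis(samples: list) -> tuple:
    """Kruskal-Wallis omnibus test, exact for very small samples.

    With total N <= 12 the p-value is computed by enumerating every
    distinct assignment of the pooled observations to the group sizes
    (the chi-square approximation is useless there: at 3 groups of 3 it
    cannot drop below ~0.03 even for complete separation). Larger samples
    use the standard chi-square approximation.
    """
    samples = [np.asarray(s, float) for s in samples]
    sizes = [len(s) for s in samples]
    values = np.concatenate(samples)
    n = len(values)
    if n > kruskal_exact_threshold():
        h, p = stats.kruskal(*samples)
        return float(h), float(p)
    from itertools import combinations

    h_obs = _kruskal_h(values, sizes)
    # H depends only on how the pooled ranks split into groups, so the
    # ranks (and the tie correction) are computed once and every distinct
    # assignment is scored from rank sums alone.
    ranks = stats.rankdata(values)
    _, tie_counts = np.unique(values, return_counts=True)
    correction = 1.0 - (tie_counts ** 3 - tie_counts).sum() / (n ** 3 - n)
    const = 12.0 / (n * (n + 1))

    def h_of(rank_sums):
        h = const * sum(r * r / sz for r, sz in zip(rank_sums, sizes)) \
            - 3 * (n + 1)
        return h / correction if correction > 0 else np.nan

    count = total = 0

    def assignments(remaining, szs):
        if len(szs) == 1:
            yield [sum(ranks[i] for i in remaining)]
            return
        for combo in combinations(sorted(remaining), szs[0]):
            head = sum(ranks[i] for i in combo)
            for rest in assignments(remaining - set(combo), szs[1:]):
                yield [head] + rest

    for rank_sums in assignments(frozenset(range(n)), sizes):
        total += 1
        if h_of(rank_sums) >= h_obs - 1e-12:
            count += 1
    return float(h_obs), count / total


def dunn_many_to_one(groups: dict, control: str) -> pd.DataFrame:
    """Rank-based many-to-one comparisons after a Kruskal-Wallis omnibus.

    Dunn's z statistic per group vs the control, with tie correction and
    Holm-adjusted two-sided p-values.
    """
    names = list(groups)
    values = np.concatenate([np.asarray(groups[n], float) for n in names])
    sizes = {n: len(groups[n]) for n in names}
    n_total = len(values)
    ranks = stats.rankdata(values)
    mean_ranks, pos = {}, 0
    for n in names:
        mean_ranks[n] = ranks[pos:pos + sizes[n]].mean()
        pos += sizes[n]
    _, tie_counts = np.unique(values, return_counts=True)
    tie_term = (tie_counts ** 3 - tie_counts).sum() / (12.0 * (n_total - 1))
    rows = []
    others = [n for n in names if n != control]
    for n in others:
        se = np.sqrt((n_total * (n_total + 1) / 12.0 - tie_term)
                     * (1.0 / sizes[n] + 1.0 / sizes[control]))
        z = (mean_ranks[n] - mean_ranks[control]) / se if se > 0 else np.nan
        p = 2.0 * stats.norm.sf(abs(z)) if np.isfinite(z) else np.nan
        rows.append({"group": n, "z": float(z), "p_raw": float(p),
                     "direction": "higher" if z > 0 else "lower"})
    df = pd.DataFrame(rows)
    order = np.argsort(df["p_raw"].to_numpy())
    adj = np.empty(len(df))
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, (len(df) - rank) * df["p_raw"].iloc[idx])
        adj[idx] = min(running, 1.0)
    df["p_holm"] = adj
    return df


def compare_groups(quant_by_group: dict, control: str,
                   metrics=("area_fraction_pct", "density_per_mm2"),
                   alpha: float = ALPHA) -> dict:
    """Kruskal-Wallis across experimental groups on per-brain burden.

    ``quant_by_group`` maps group label to a DataFrame with one row per
    brain carrying the burden metrics. Returns the omnibus statistic and
    the many-to-one rank follow-up per metric.
    """
    if len(quant_by_group) < 2:
        raise StatisticsError("need >= 2 groups")
    for name, df in quant_by_group.items():
        if len(df) < 3:
            raise StatisticsError(f"group {name!r} has fewer than 3 brains")
    if control not in quant_by_group:
        raise StatisticsError(f"control group {control!r} missing")
    report = {}
    for metric in metrics:
        samples = {n: df[metric].to_numpy(float)
                   for n, df in quant_by_group.items()}
        h, p = kruskal_wallis(list(samples.values()))
        posthoc = dunn_many_to_one(samples, control)
        report[metric] = {
            "kruskal_H": float(h), "kruskal_p": float(p),
            "significant": bool(p < alpha),
            "posthoc": posthoc,
        }
    return report


class StageTimer:
    """Wall-clock capture per pipeline stage (execution, counting, ...).

    Absolute values are hardware-dependent and are reported, never
    asserted.
    """

    def __init__(self):
        self.records = []

    @contextmanager
    def stage(self, method: str, stage: str):
        t0 = time.perf_counter()
        try:
            yield
        finally:
            self.records.append({
                "method": method, "stage": stage,
                "seconds": time.perf_counter() - t0,
            })

    def report(self) -> pd.DataFrame:
        df = pd.DataFrame(self.records,
                          columns=["method", "stage", "seconds"])
        return df
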