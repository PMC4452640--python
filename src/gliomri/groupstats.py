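"""ROI summaries, percent-change statistics and Welch group comparisons.

The study design compares tumour-bearing against sham animals, separately
per sex, with every quantity reported as mean +/- SEM and the lesion
effect expressed as a relative change

    %Delta = (value_glioma - value_sham) / value_sham * 100 .

Group differences are tested with the unpaired two-tailed t test with
Welch's correction (no equal-variance assumption; Welch-Satterthwaite
degrees of freedom), which works both from raw per-subject values and
from printed (mean, SEM, n) summaries. Significance stars follow the
usual figure-legend convention: * 0.05, ** 0.01, *** 0.001, **** 0.0001.

Two aggregation modes exist for the percent change because published
group deltas are not always consistent with the ratio of published group
means: ``group-mean`` (the ratio of group means, the default) and
``per-subject`` (each glioma subject against the sham group mean, then
averaged). No multiple-testing correction is applied by default,
matching the source analysis; a Holm adjustment is available behind a
flag.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .volumes import ParametricMap, ROIMask

__all__ = [
    "RoiSummary",
    "GroupSummary",
    "DeltaPercent",
    "GroupComparison",
    "roi_summary",
    "mask_volume",
    "summarize_values",
    "percent_change",
    "welch_test",
    "significance_stars",
    "holm_adjust",
    "rer_day_night",
    "build_report",
]


@dataclass
class RoiSummary:
    """Mean and SEM of a parametric map over the valid voxels of one ROI."""

    mean: float
    sem: float
    n_voxels: int
    n_invalid: int


def roi_summary(pmap: ParametricMap, roi: ROIMask) -> RoiSummary:
    """Arithmetic mean and SEM over the valid ROI voxels.

    Invalid voxels are excluded from the statistics and counted in
    ``n_invalid``; an ROI with no valid voxel raises.
    """
    if roi.data.shape != pmap.data.shape:
        raise ValueError("ROI grid does not match the map")
    sel = roi.data & pmap.valid
    n = int(sel.sum())
    if n == 0:
        raise ValueError(f"ROI {roi.label!r} has no valid voxels")
    vals = pmap.data[sel]
    sem = float(vals.std(ddof=1) / np.sqrt(n)) if n > 1 else 0.0
    return RoiSummary(mean=float(vals.mean()), sem=sem, n_voxels=n,
                      n_invalid=int((roi.data & ~pmap.valid).sum()))


def mask_volume(roi: ROIMask) -> float:
    """ROI volume in mm^3 (voxel count times voxel volume)."""
    return roi.n_voxels * roi.voxel_volume


@dataclass
class GroupSummary:
    """One group's summary: label, n, mean, SEM and (optionally) the
    underlying per-subject values."""

    label: str
    n: int
    mean: float
    sem: float
    values: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.sem < 0:
            raise ValueError("SEM must be non-negative")
        if self.n < 2 and self.sem > 0:
            raise ValueError("SEM reported with n < 2")


def summarize_values(values, label: str = "") -> GroupSummary:
    """Mean +/- SEM summary of raw per-subject values."""
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ValueError("need at least two subjects to form a SEM")
    return GroupSummary(label=label, n=v.size, mean=float(v.mean()),
                        sem=float(v.std(ddof=1) / np.sqrt(v.size)), values=v)


@dataclass
class DeltaPercent:
    """A relative change (in %) with its propagated SEM."""

    delta: float
    sem: float
    mode: str = "group-mean"


def percent_change(glioma: GroupSummary, sham: GroupSummary,
                   mode: str = "group-mean") -> DeltaPercent:
    """Relative change of the glioma group against the sham group, in %.

    ``group-mean`` applies the ratio to the two group means, with the SEM
    from first-order error propagation of the ratio. ``per-subject``
    divides each glioma subject's value by the sham group mean and
    averages the resulting percentages (requires raw glioma values); its
    SEM combines the subject scatter with the propagated sham-mean
    uncertainty.
    """
    if sham.mean == 0:
        raise ValueError("sham mean is zero; percent change undefined")
    if mode == "group-mean":
        delta = (glioma.mean - sham.mean) / sham.mean * 100.0
        sem = 100.0 * np.sqrt(glioma.sem**2 / sham.mean**2
                              + glioma.mean**2 * sham.sem**2 / sham.mean**4)
        return DeltaPercent(delta=float(delta), sem=float(sem), mode=mode)
    if mode == "per-subject":
        if glioma.values is None:
            raise ValueError("per-subject mode needs raw glioma values")
        ratios = glioma.values / sham.mean * 100.0 - 100.0
        n = ratios.size
        sem_subjects = ratios.std(ddof=1) / np.sqrt(n) if n > 1 else 0.0
        sem_sham = 100.0 * glioma.mean * sham.sem / sham.mean**2
        return DeltaPercent(delta=float(ratios.mean()),
                            sem=float(np.hypot(sem_subjects, sem_sham)),
                            mode=mode)
    raise ValueError(f"unknown mode {mode!r}; use 'group-mean' or 'per-subject'")


def significance_stars(p: float) -> str:
    """Figure-legend stars: * <0.05, ** <0.01, *** <0.001, **** <0.0001."""
    for threshold, mark in ((1e-4, "****"), (1e-3, "***"), (1e-2, "**"),
                            (5e-2, "*")):
        if p < threshold:
            return mark
    return "ns"


@dataclass
class GroupComparison:
    """Welch test result between two groups."""

    t: float
    df: float
    p: float
    stars: str
    mean_diff: float


def welch_test(a: GroupSummary, b: GroupSummary) -> GroupComparison:
    """Unpaired two-tailed t test with Welch's correction.

    Works from (mean, SEM, n) summaries; when both groups carry raw
    values the summaries are recomputed from them, which makes raw mode
    and summary mode coincide exactly.

        t  = (mean_a - mean_b) / sqrt(SEM_a^2 + SEM_b^2)
        df = (SEM_a^2 + SEM_b^2)^2 /
             (SEM_a^4/(n_a - 1) + SEM_b^4/(n_b - 1))
    """
    if a.values is not None and b.values is not None:
        a = summarize_values(a.values, a.label)
        b = summarize_values(b.values, b.label)
    if a.n < 2 or b.n < 2:
        raise ValueError("each group needs n >= 2")
    va, vb = a.sem**2, b.sem**2
    if va + vb == 0:
        raise ValueError("both SEMs are zero; t undefined")
    t = (a.mean - b.mean) / np.sqrt(va + vb)
    df = (va + vb) ** 2 / (va**2 / (a.n - 1) + vb**2 / (b.n - 1))
    p = float(2.0 * stats.t.sf(abs(t), df))
    return GroupComparison(t=float(t), df=float(df), p=p,
                           stars=significance_stars(p),
                           mean_diff=float(a.mean - b.mean))


def _welch_or_degenerate(a: GroupSummary, b: GroupSummary) -> GroupComparison:
    """Welch test that tolerates a fully degenerate (zero-variance) pair,
    as produced by noiseless deterministic cohorts: no test is possible
    there, so t/df/p come back NaN with empty stars."""
    if a.sem == 0 and b.sem == 0:
        return GroupComparison(t=float("nan"), df=float("nan"),
                               p=float("nan"), stars="",
                               mean_diff=float(a.mean - b.mean))
    return welch_test(a, b)


def holm_adjust(pvals) -> np.ndarray:
    """Holm step-down adjusted p-values (optional; off by default)."""
    p = np.asarray(pvals, dtype=float)
    order = np.argsort(p)
    m = p.size
    adj = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, (m - rank) * p[idx])
        adj[idx] = min(1.0, running)
    return adj


# ---------------------------------------------------------------------------
# circadian RER aggregation


def rer_day_night(records: pd.DataFrame, mode: str = "per-subject"
                  ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Day/night RER group deltas and male-vs-female comparisons.

    ``records`` is tidy with columns subject, sex, condition, group,
    time_h, rer, light (one row per subject per 30-min bin) and must span
    at least one full light/dark cycle. Per subject, the RER is averaged
    within light and dark bins; tumour groups are then compared to the
    matching sham group with the percent-change statistic, and the sexes
    are compared per cycle with Welch's test on the per-subject deltas.

    Returns ``(deltas, comparisons)``: one row per (sex, cycle) with the
    group Delta% +/- SEM, and one row per cycle with the male-vs-female
    Welch test.
    """
    required = {"subject", "sex", "condition", "group", "time_h", "rer", "light"}
    missing = required - set(records.columns)
    if missing:
        raise ValueError(f"records missing columns: {sorted(missing)}")
    span = records.groupby("subject")["time_h"].agg(lambda s: s.max() - s.min())
    if (span < 24.0 - 1e-9).any():
        raise ValueError("records must span at least one full 24-h cycle")

    per_subject = (records
                   .assign(cycle=np.where(records["light"], "day", "night"))
                   .groupby(["group", "sex", "condition", "subject", "cycle"],
                            observed=True)["rer"].mean().reset_index())

    delta_rows = []
    per_subject_deltas: dict[tuple[str, str], np.ndarray] = {}
    for sex in sorted(per_subject.sex.unique()):
        for cycle in ("day", "night"):
            sel = per_subject[(per_subject.sex == sex)
                              & (per_subject.cycle == cycle)]
            glioma = sel[sel.condition == "tumour"]["rer"].to_numpy()
            sham = sel[sel.condition == "sham"]["rer"].to_numpy()
            if glioma.size < 2 or sham.size < 2:
                raise ValueError(f"group {sex}/{cycle} has fewer than 2 subjects")
            g = summarize_values(glioma, f"{sex}/tumour")
            s = summarize_values(sham, f"{sex}/sham")
            d = percent_change(g, s, mode=mode if mode != "per-subject"
                               else "per-subject")
            per_subject_deltas[(sex, cycle)] = glioma / s.mean * 100.0 - 100.0
            delta_rows.append((sex, cycle, d.delta, d.sem, g.n))
    deltas = pd.DataFrame(delta_rows,
                          columns=["sex", "cycle", "delta_pct", "sem", "n"])

    comp_rows = []
    for cycle in ("day", "night"):
        male = per_subject_deltas.get(("male", cycle))
        female = per_subject_deltas.get(("female", cycle))
        if male is None or female is None:
            continue
        cmp_ = _welch_or_degenerate(summarize_values(male, "male"),
                                    summarize_values(female, "female"))
        comp_rows.append((cycle, cmp_.t, cmp_.df, cmp_.p, cmp_.stars))
    comparisons = pd.DataFrame(comp_rows, columns=["cycle", "t", "df", "p", "stars"])
    return deltas, comparisons


# ---------------------------------------------------------------------------
# report tables


def _fmt_pm(mean: float, sem: float, digits: int = 4) -> str:
    return f"{mean:.{digits}g} ± {sem:.{3}g}"


def build_report(cohort: pd.DataFrame, mode: str = "group-mean",
                 holm: bool = False) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Summary and percent-change report tables for a quantified cohort.

    ``cohort`` is tidy per-subject data: columns subject, sex, condition,
    group, region, parameter, value. Returns

    * a summary table (one row per region/parameter, one column per group
      holding "mean +/- SEM" plus full-precision mean/SEM columns), and
    * a delta table: per sex/region/parameter the Delta% of tumour vs
      sham with SEM, and the male-vs-female Welch p with stars.

    All four groups must be present.
    """
    required_groups = {"male/tumour", "female/tumour", "male/sham", "female/sham"}
    present = set(cohort.group.unique()) if len(cohort) else set()
    missing = required_groups - present
    if missing:
        raise ValueError(f"cohort is missing groups: {sorted(missing)}")

    groups = ["male/tumour", "female/tumour", "male/sham", "female/sham"]
    summary_rows = []
    stats_cache: dict[tuple[str, str, str], GroupSummary] = {}
    for (region, parameter), block in cohort.groupby(["region", "parameter"],
                                                     observed=True, sort=False):
        row: dict[str, object] = {"region": region, "parameter": parameter}
        for group in groups:
            vals = block[block.group == group]["value"].to_numpy()
            if vals.size < 2:
                raise ValueError(f"group {group} has n < 2 for "
                                 f"({region}, {parameter})")
            summ = summarize_values(vals, group)
            stats_cache[(group, region, parameter)] = summ
            row[group] = _fmt_pm(summ.mean, summ.sem)
            row[f"{group}:mean"] = summ.mean
            row[f"{group}:sem"] = summ.sem
        summary_rows.append(row)
    summary = pd.DataFrame(summary_rows)

    delta_rows = []
    for (region, parameter) in summary[["region", "parameter"]].itertuples(index=False):
        deltas = {}
        for sex in ("male", "female"):
            g = stats_cache[(f"{sex}/tumour", region, parameter)]
            s = stats_cache[(f"{sex}/sham", region, parameter)]
            deltas[sex] = (percent_change(g, s, mode=mode), g, s)
        # male-vs-female on the per-subject delta distributions
        dm = deltas["male"][1].values / deltas["male"][2].mean * 100.0 - 100.0
        df_ = deltas["female"][1].values / deltas["female"][2].mean * 100.0 - 100.0
        cmp_ = _welch_or_degenerate(summarize_values(dm, "male"),
                                    summarize_values(df_, "female"))
        delta_rows.append({
            "region": region, "parameter": parameter,
            "delta_male": deltas["male"][0].delta,
            "sem_male": deltas["male"][0].sem,
            "delta_female": deltas["female"][0].delta,
            "sem_female": deltas["female"][0].sem,
            "t": cmp_.t, "df": cmp_.df, "p": cmp_.p, "stars": cmp_.stars,
        })
    delta = pd.DataFrame(delta_rows)
    if holm and len(delta):
        delta["p_holm"] = holm_adjust(delta["p"].to_numpy())
        delta["stars_holm"] = [significance_stars(p) for p in delta["p_holm"]]
    return summary, delta
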