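"""Per-patient volume metrics and recurrent-vs-non-recurrent group statistics.

The per-patient record collects, in mL: the total mandible volume Vm, the
whole-grid 56 Gy and PTV isodose volumes V56 and V-PTV, the mandibular
portions Vm56 and Vm-PTV, the resected volume VmR, and the residual
irradiated volumes after resection Vm56R and Vm-PTV-R — plus the same
quantities as percentages of Vm.

Group comparisons follow a normality-gated scheme: a Lilliefors-corrected
Kolmogorov–Smirnov test screens each group for normality; when both groups
pass, a pooled-variance two-sample t-test is used, otherwise the
Mann–Whitney U test (exact p when sample sizes permit and there are no ties,
tie-corrected normal approximation otherwise).
"""

from __future__ import annotations

import functools
from dataclasses import dataclass, field, fields as dataclass_fields

import numpy as np
import pandas as pd
from scipy import stats

from .core import BinaryVolume
from .resection import CorticalClassification, ResectionSpec, apply_resection
from .volumetrics import IsodoseVolume, intersect, volume_ml

__all__ = [
    "VolumeMetrics",
    "GroupComparison",
    "compute_metrics",
    "normality_test",
    "compare_groups",
    "tabulate_osteotomies",
    "cohort_report",
    "METRIC_FIELDS",
]


@dataclass
class VolumeMetrics:
    """All volume quantities for one patient, in mL and percent of Vm."""

    Vm: float
    V56: float
    V_PTV: float
    Vm56: float
    Vm_PTV: float
    VmR: float
    Vm56R: float
    Vm_PTV_R: float
    Vm56_over_Vm: float
    Vm_PTV_over_Vm: float
    VmR_over_Vm: float

    def validate(self, tol_ml: float = 1e-9, tol_pp: float = 0.5) -> None:
        """Check the internal consistency every record must satisfy."""
        checks = [
            ("Vm56 <= Vm", self.Vm56 <= self.Vm + tol_ml),
            ("Vm56 <= V56", self.Vm56 <= self.V56 + tol_ml),
            ("Vm_PTV <= Vm", self.Vm_PTV <= self.Vm + tol_ml),
            ("Vm56R <= Vm56", self.Vm56R <= self.Vm56 + tol_ml),
            ("Vm_PTV_R <= Vm_PTV", self.Vm_PTV_R <= self.Vm_PTV + tol_ml),
            ("VmR <= Vm", self.VmR <= self.Vm + tol_ml),
            ("all >= 0", all(getattr(self, f.name) >= -tol_ml for f in dataclass_fields(self))),
        ]
        for name, ok in checks:
            if not ok:
                raise ValueError(f"volume metrics violate invariant: {name} ({self})")
        for ratio_name, num in [
            ("Vm56_over_Vm", self.Vm56),
            ("Vm_PTV_over_Vm", self.Vm_PTV),
            ("VmR_over_Vm", self.VmR),
        ]:
            if self.Vm > 0:
                expected = 100.0 * num / self.Vm
                if abs(getattr(self, ratio_name) - expected) > tol_pp:
                    raise ValueError(
                        f"{ratio_name} = {getattr(self, ratio_name):.3f} does not "
                        f"recompute from mL fields ({expected:.3f})"
                    )

    def as_dict(self) -> dict[str, float]:
        return {f.name: getattr(self, f.name) for f in dataclass_fields(self)}


METRIC_FIELDS = [f.name for f in dataclass_fields(VolumeMetrics)]


def _region_mask(x) -> BinaryVolume:
    return x.region if isinstance(x, IsodoseVolume) else x


def compute_metrics(
    mandible: BinaryVolume,
    isodose56,
    ptv_region,
    resection_spec: ResectionSpec | None = None,
) -> VolumeMetrics:
    """Assemble the full per-patient volume record.

    ``isodose56`` and ``ptv_region`` may be :class:`IsodoseVolume` objects or
    raw masks; V56 and V-PTV are reported over the whole grid, their
    mandibular portions Vm56 and Vm-PTV after intersection with the mandible.
    With no resection the residual quantities equal their pre-operative
    counterparts' complements (VmR = 0, Vm56R = Vm56).
    """
    iso56 = _region_mask(isodose56)
    ptv = _region_mask(ptv_region)

    vm = volume_ml(mandible)
    vm56_mask = intersect(mandible, iso56)
    vmptv_mask = intersect(mandible, ptv)

    if resection_spec is not None:
        resected, residual = apply_resection(mandible, resection_spec)
        vmr = volume_ml(resected)
    else:
        residual = mandible
        vmr = 0.0

    vm56 = volume_ml(vm56_mask)
    vmptv = volume_ml(vmptv_mask)
    vm56r = volume_ml(intersect(residual, iso56))
    vmptvr = volume_ml(intersect(residual, ptv))

    def pct(x: float) -> float:
        return 100.0 * x / vm if vm > 0 else 0.0

    metrics = VolumeMetrics(
        Vm=vm,
        V56=volume_ml(iso56),
        V_PTV=volume_ml(ptv),
        Vm56=vm56,
        Vm_PTV=vmptv,
        VmR=vmr,
        Vm56R=vm56r,
        Vm_PTV_R=vmptvr,
        Vm56_over_Vm=pct(vm56),
        Vm_PTV_over_Vm=pct(vmptv),
        VmR_over_Vm=pct(vmr),
    )
    metrics.validate()
    return metrics


# --------------------------------------------------------------------------
# Normality gate and group comparison
# --------------------------------------------------------------------------

_LILLIEFORS_MC_DRAWS = 10_000
_LILLIEFORS_MC_SEED = 20080604  # fixed internal seed: the null table is a constant


def _ks_statistic_normal(x: np.ndarray) -> float:
    """KS distance of a standardized sample from the fitted normal."""
    n = len(x)
    z = np.sort((x - x.mean()) / x.std(ddof=1))
    cdf = stats.norm.cdf(z)
    upper = np.max(np.arange(1, n + 1) / n - cdf)
    lower = np.max(cdf - np.arange(0, n) / n)
    return float(max(upper, lower))


@functools.lru_cache(maxsize=64)
def _lilliefors_null(n: int) -> np.ndarray:
    """Monte-Carlo null distribution of the KS statistic with estimated
    mean/sd, for sample size n (sorted ascending)."""
    rng = np.random.default_rng(_LILLIEFORS_MC_SEED + n)
    draws = rng.standard_normal((_LILLIEFORS_MC_DRAWS, n))
    means = draws.mean(axis=1, keepdims=True)
    sds = draws.std(axis=1, ddof=1, keepdims=True)
    z = np.sort((draws - means) / sds, axis=1)
    cdf = stats.norm.cdf(z)
    i = np.arange(1, n + 1)
    upper = (i / n - cdf).max(axis=1)
    lower = (cdf - (i - 1) / n).max(axis=1)
    return np.sort(np.maximum(upper, lower))


def normality_test(sample) -> tuple[float, float]:
    """Lilliefors-corrected Kolmogorov–Smirnov normality test.

    One-sample KS against a normal with mean and standard deviation estimated
    from the sample; because the parameters are estimated, the plain KS null
    is anticonservative, so the p-value is taken from a seeded Monte-Carlo
    null distribution (10^4 draws, cached per sample size).

    Returns (KS statistic, p). Requires n >= 4 and nonzero variance.
    """
    x = np.asarray(sample, dtype=float)
    if len(x) < 4:
        raise ValueError(f"normality test needs n >= 4, got n = {len(x)}")
    if x.std(ddof=1) == 0:
        raise ValueError("normality test undefined for a constant sample")
    d = _ks_statistic_normal(x)
    null = _lilliefors_null(len(x))
    p = (1 + np.sum(null >= d)) / (len(null) + 1)
    return d, float(p)


@dataclass
class GroupComparison:
    """Two-group comparison of one metric."""

    metric: str
    group_labels: tuple[str, str]
    n: tuple[int, int]
    mean: tuple[float, float]
    min: tuple[float, float]
    max: tuple[float, float]
    test: str  # "t" or "MWW"
    statistic: float
    p: float
    normality_p: tuple[float | None, float | None] = (None, None)


def compare_groups(
    a,
    b,
    alpha: float = 0.05,
    metric: str = "",
    group_labels: tuple[str, str] = ("a", "b"),
    welch: bool = False,
) -> GroupComparison:
    """Compare two samples with a normality-gated test choice.

    Both samples pass the Lilliefors normality screen at ``alpha`` → Student's
    two-sample t-test (pooled variance by default, Welch with ``welch=True``);
    otherwise the Mann–Whitney U test. Groups too small for the normality
    screen (n < 4) are sent to Mann–Whitney directly. Two identical constant
    samples compare as p = 1, statistic 0.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs n >= 2")

    summary = dict(
        metric=metric,
        group_labels=group_labels,
        n=(len(a), len(b)),
        mean=(float(a.mean()), float(b.mean())),
        min=(float(a.min()), float(b.min())),
        max=(float(a.max()), float(b.max())),
    )

    if np.ptp(np.concatenate([a, b])) == 0:
        return GroupComparison(**summary, test="t", statistic=0.0, p=1.0)

    def _norm_p(x):
        if len(x) < 4 or x.std(ddof=1) == 0:
            return None
        return normality_test(x)[1]

    pa, pb = _norm_p(a), _norm_p(b)
    both_normal = pa is not None and pb is not None and pa > alpha and pb > alpha

    if both_normal:
        res = stats.ttest_ind(a, b, equal_var=not welch)
        test, statistic, p = "t", float(res.statistic), float(res.pvalue)
    else:
        res = stats.mannwhitneyu(a, b, alternative="two-sided", method="auto")
        test, statistic, p = "MWW", float(res.statistic), float(res.pvalue)
    return GroupComparison(**summary, test=test, statistic=statistic, p=p,
                           normality_p=(pa, pb))


def tabulate_osteotomies(
    classifications: list[CorticalClassification],
    groups: list[str] | None = None,
) -> pd.DataFrame:
    """Count osteotomy planes per cortical-involvement category.

    With ``groups`` given (one label per plane), returns a category x group
    cross-tabulation with row/column totals; otherwise a single 'total'
    column. Counts always sum to the number of planes.
    """
    categories = ["outside", "lingual_only", "buccal_only", "bicortical"]
    cats = [c.category for c in classifications]
    if groups is None:
        groups = ["total"] * len(cats)
    if not cats:
        return pd.DataFrame(
            {"total": [0] * len(categories)},
            index=pd.Index(categories, name="category"),
        )
    df = pd.DataFrame({"category": cats, "group": list(groups)})
    table = pd.crosstab(df["category"], df["group"]).reindex(categories, fill_value=0)
    table.columns.name = None
    table.index.name = "category"
    if list(table.columns) != ["total"]:
        table["total"] = table.sum(axis=1)
    return table.astype(int)


def cohort_report(
    metrics: pd.DataFrame,
    group_col: str = "group",
    alpha: float = 0.05,
) -> tuple[pd.DataFrame, list[GroupComparison]]:
    """Per-group mean/min/max summary plus a two-group comparison per metric.

    ``metrics`` must hold one row per patient with the VolumeMetrics columns
    and a group column with exactly two levels.
    """
    if group_col not in metrics.columns:
        raise ValueError(
            f"group column {group_col!r} not found; available: {list(metrics.columns)}"
        )
    levels = sorted(metrics[group_col].unique())
    if len(levels) < 2:
        raise ValueError(f"need at least two groups, got {levels}")
    if len(levels) > 2:
        raise ValueError(f"pairwise comparison expects exactly two groups, got {levels}")

    present = [c for c in METRIC_FIELDS if c in metrics.columns]
    rows = []
    for level in levels + ["all"]:
        sub = metrics if level == "all" else metrics[metrics[group_col] == level]
        for stat_name, fn in [("mean", np.mean), ("min", np.min), ("max", np.max)]:
            rows.append(
                {"group": level, "stat": stat_name, "n": len(sub)}
                | {c: float(fn(sub[c])) for c in present}
            )
    summary = pd.DataFrame(rows)

    ga = metrics[metrics[group_col] == levels[0]]
    gb = metrics[metrics[group_col] == levels[1]]
    comparisons = [
        compare_groups(
            ga[c].to_numpy(), gb[c].to_numpy(),
            alpha=alpha, metric=c, group_labels=(str(levels[0]), str(levels[1])),
        )
        for c in present
    ]
    return summary, comparisons
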