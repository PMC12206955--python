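"""Regional statistics, SAN/myocardium contrast metrics and method agreement.

Contrast between the SAN and remote myocardium is expressed as the relative
relaxation time difference, RRTD = 2 (T_SAN - T_myo) / (T_SAN + T_myo), and
for magnetization transfer as MTC = 2 (MTR_myo - MTR_SAN) / (MTR_SAN +
MTR_myo) (the SAN has the lower MTR, so both metrics are positive for the
SAN's fibrotic signature). Agreement between MRI- and histology-derived SAN
areas uses Pearson correlation and Bland-Altman bias / 95% limits of
agreement; group comparisons use an independent t-test and one-way ANOVA
with Benjamini-Hochberg correction across the declared comparison family.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import DegenerateInputError
from .phantom import LabelMap
from .relaxometry import ParameterMap
from .tissues import Tissue

__all__ = [
    "RegionStats",
    "ContrastResult",
    "AgreementResult",
    "TestResult",
    "region_stats",
    "rrtd",
    "mtc",
    "pearson_agreement",
    "bland_altman",
    "agreement",
    "independent_t",
    "anova_bh",
    "bh_adjust",
    "normality_check",
    "significance_stars",
]


@dataclass
class RegionStats:
    """Mean +/- SD of a mapped quantity over one region."""

    region: Tissue
    mean: float
    sd: float
    n_pixels: int
    area_mm2: float | None
    contrast: str
    units: str


@dataclass(frozen=True)
class ContrastResult:
    """A dimensionless SAN-vs-myocardium contrast value."""

    value: float
    san: float
    myocardium: float
    metric: str  # "RRTD" or "MTC"
    contrast: str = ""


@dataclass
class AgreementResult:
    """Paired-method comparison; correlation and/or Bland-Altman parts."""

    a: np.ndarray
    b: np.ndarray
    r_squared: float | None = None
    p_value: float | None = None
    slope: float | None = None
    intercept: float | None = None
    bias: float | None = None
    loa_low: float | None = None
    loa_high: float | None = None


@dataclass
class TestResult:
    statistic: float
    p_value: float
    p_adjusted: float | None = None
    test: str = ""
    groups: tuple[str, ...] = ()

    @property
    def stars(self) -> str:
        return significance_stars(
            self.p_adjusted if self.p_adjusted is not None else self.p_value
        )


def significance_stars(p: float) -> str:
    """Conventional significance stars: * < 0.05, ** < 0.01, *** < 0.001."""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def region_stats(
    labels: LabelMap,
    pmap: ParameterMap,
    regions: tuple[Tissue, ...] = (Tissue.MYOCARDIUM, Tissue.SAN, Tissue.EPICARDIUM),
) -> dict[Tissue, RegionStats]:
    """Mean, SD, pixel count and area per region over valid pixels."""
    out: dict[Tissue, RegionStats] = {}
    for cls in regions:
        m = labels.mask(cls) & pmap.valid
        if not m.any():
            continue
        vals = pmap.values[m]
        out[cls] = RegionStats(
            region=cls,
            mean=float(vals.mean()),
            sd=float(vals.std(ddof=1)) if vals.size > 1 else 0.0,
            n_pixels=int(vals.size),
            area_mm2=float(vals.size * labels.pixel_area_mm2),
            contrast=pmap.name,
            units=pmap.units,
        )
    return out


def rrtd(t_san: float, t_myo: float, contrast: str = "") -> ContrastResult:
    """Relative relaxation time difference, 2 (T_SAN - T_myo) / (T_SAN + T_myo)."""
    if t_san <= 0 or t_myo <= 0:
        raise ValueError("relaxation times must be positive")
    value = 2.0 * (t_san - t_myo) / (t_san + t_myo)
    return ContrastResult(value, t_san, t_myo, "RRTD", contrast)


def mtc(mtr_san: float, mtr_myo: float) -> ContrastResult:
    """MT contrast, 2 (MTR_myo - MTR_SAN) / (MTR_SAN + MTR_myo)."""
    if mtr_san <= 0 or mtr_myo <= 0:
        raise ValueError("MTR values must be positive")
    value = 2.0 * (mtr_myo - mtr_san) / (mtr_san + mtr_myo)
    return ContrastResult(value, mtr_san, mtr_myo, "MTC", "MTR")


def pearson_agreement(areas_a, areas_b) -> AgreementResult:
    """Pearson correlation of paired measurements, with the least-squares line.

    p is two-sided from the t distribution with n - 2 degrees of freedom.
    """
    a = np.asarray(areas_a, float)
    b = np.asarray(areas_b, float)
    if a.shape != b.shape or a.size < 3:
        raise ValueError("need >= 3 finite pairs of equal length")
    if not (np.isfinite(a).all() and np.isfinite(b).all()):
        raise ValueError("non-finite values in input")
    if a.std() == 0 or b.std() == 0:
        raise DegenerateInputError("zero variance in one of the inputs")
    res = stats.linregress(a, b)
    return AgreementResult(
        a=a,
        b=b,
        r_squared=float(res.rvalue**2),
        p_value=float(res.pvalue),
        slope=float(res.slope),
        intercept=float(res.intercept),
    )


def bland_altman(areas_a, areas_b) -> AgreementResult:
    """Bland-Altman bias and 95% limits of agreement, bias +/- 1.96 SD(a - b),
    with the SD taken over n - 1."""
    a = np.asarray(areas_a, float)
    b = np.asarray(areas_b, float)
    if a.shape != b.shape:
        raise ValueError("paired inputs differ in length")
    if a.size < 2:
        raise ValueError("need >= 2 pairs")
    d = a - b
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    return AgreementResult(
        a=a, b=b, bias=bias, loa_low=bias - 1.96 * sd, loa_high=bias + 1.96 * sd
    )


def agreement(areas_a, areas_b) -> AgreementResult:
    """Correlation and Bland-Altman agreement in one result."""
    pa = pearson_agreement(areas_a, areas_b)
    ba = bland_altman(areas_a, areas_b)
    pa.bias, pa.loa_low, pa.loa_high = ba.bias, ba.loa_low, ba.loa_high
    return pa


def independent_t(group_a, group_b, variant: str = "welch") -> TestResult:
    """Two-sided independent-samples t-test (Welch by default)."""
    a = np.asarray(group_a, float)
    b = np.asarray(group_b, float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs n >= 2")
    if variant not in ("welch", "pooled"):
        raise ValueError(f"unknown variant {variant!r}")
    if np.ptp(a) == 0 and np.ptp(b) == 0 and a[0] == b[0]:
        # two constant, equal groups: no difference, scipy would return NaN
        return TestResult(0.0, 1.0, test=f"t ({variant})")
    res = stats.ttest_ind(a, b, equal_var=(variant == "pooled"))
    return TestResult(float(res.statistic), float(res.pvalue), test=f"t ({variant})")


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    p = np.asarray(p_values, float)
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def anova_bh(
    groups: list[np.ndarray],
    labels: tuple[str, ...] | None = None,
    pairwise_family: list[tuple[int, int]] | None = None,
    variant: str = "welch",
) -> list[TestResult]:
    """One-way ANOVA followed by BH-corrected pairwise comparisons.

    The default comparison family tests every group against the first
    (reference) group, mirroring contrast comparisons that use RAFF2 as the
    reference. Returns the ANOVA result first, then one TestResult per
    family member carrying the BH-adjusted p.
    """
    arrs = [np.asarray(g, float) for g in groups]
    if len(arrs) < 2 or any(a.size < 2 for a in arrs):
        raise ValueError("need >= 2 groups with n >= 2 each")
    names = labels or tuple(f"group{i}" for i in range(len(arrs)))
    if all(np.allclose(a, arrs[0]) for a in arrs[1:]) and all(
        np.ptp(a) == 0 for a in arrs
    ):
        anova = TestResult(0.0, 1.0, test="anova", groups=names)
    else:
        f, p = stats.f_oneway(*arrs)
        anova = TestResult(float(f), float(p), test="anova", groups=names)
    family = pairwise_family or [(0, j) for j in range(1, len(arrs))]
    raw = []
    for i, j in family:
        raw.append(independent_t(arrs[i], arrs[j], variant=variant))
    adj = bh_adjust([t.p_value for t in raw])
    out = [anova]
    for (i, j), t, pa in zip(family, raw, adj):
        out.append(
            TestResult(
                t.statistic,
                t.p_value,
                p_adjusted=float(pa),
                test=t.test,
                groups=(names[i], names[j]),
            )
        )
    return out


def normality_check(sample) -> TestResult:
    """Shapiro-Wilk normality test (3 <= n <= 5000)."""
    x = np.asarray(sample, float)
    if not 3 <= x.size <= 5000:
        raise ValueError("Shapiro-Wilk requires 3 <= n <= 5000")
    if np.ptp(x) == 0:
        raise DegenerateInputError("constant sample has no defined W statistic")
    w, p = stats.shapiro(x)
    return TestResult(float(w), float(p), test="shapiro")
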