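"""Device-agreement statistics for method-comparison studies.

Implements the full validation protocol used when comparing a new activity
monitor against a criterion posture monitor on per-subject session totals:

* paired difference test (paired t when the differences pass a Shapiro-Wilk
  normality gate, Wilcoxon signed-rank otherwise);
* Pearson or Spearman correlation with a Fisher-z 95% CI (Pearson when both
  margins pass the normality gate);
* Lin's concordance correlation coefficient (CCC) with a Fisher-type z
  confidence interval and the McBride qualitative category;
* Bland-Altman mean bias and 95% limits of agreement (bias +/- 1.96 sd of
  the paired differences);
* TOST paired equivalence: the two devices are declared equivalent when the
  90% CI of the mean difference lies inside a symmetric equivalence region,
  by default +/-15% of the criterion mean, with an escalation scan over
  larger fractions in 5% increments.

The ``DeviceAgreement`` model / ``AgreementResults`` pair follows the
statsmodels convention: build the model from a long-format table of
per-subject paired minutes, call :meth:`DeviceAgreement.fit`, then read the
per-behavior statistics or ``summary()`` off the results object.  Composite
behaviors (stationary = sitting + standing, upright = standing + stepping,
recording = all three) are assembled per subject before analysis.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import asdict, dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .classifier import BEHAVIORS

__all__ = [
    "COMPOSITE_BEHAVIORS",
    "ALL_BEHAVIORS",
    "DegenerateDataError",
    "EquivalenceRegion",
    "DifferenceTest",
    "Correlation",
    "ConcordanceCC",
    "BlandAltman",
    "TostResult",
    "BehaviorAgreement",
    "difference_test",
    "correlation",
    "lin_ccc",
    "mcbride_category",
    "bland_altman",
    "tost_equivalence",
    "equivalence_verdict",
    "equivalence_region_for",
    "escalate_equivalence",
    "DeviceAgreement",
    "AgreementResults",
]

logger = logging.getLogger(__name__)

COMPOSITE_BEHAVIORS = ("stationary", "upright", "recording")
ALL_BEHAVIORS = BEHAVIORS + COMPOSITE_BEHAVIORS

_SHAPIRO_ALPHA = 0.05
_Z95 = stats.norm.ppf(0.975)
_LOA_MULTIPLIER = 1.96  # Bland-Altman convention


class DegenerateDataError(ValueError):
    """A statistic is undefined on this input (e.g. zero variance)."""


# ---------------------------------------------------------------------------
# Result containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class EquivalenceRegion:
    """Symmetric equivalence region for the mean paired difference."""

    half_width_min: float
    derivation: Literal["fraction_of_criterion", "absolute"] = "fraction_of_criterion"
    fraction: float | None = None
    behavior: str | None = None

    def __post_init__(self) -> None:
        if self.half_width_min <= 0:
            raise ValueError("half_width_min must be positive")
        if self.derivation == "fraction_of_criterion":
            if self.fraction is None or not (0.0 < self.fraction < 1.0):
                raise ValueError("fraction must lie in (0, 1)")


@dataclass(frozen=True)
class DifferenceTest:
    test: str                       # "paired_t", "wilcoxon" or "degenerate"
    statistic: float | None
    p_value: float | None
    normality_p: float | None = None


@dataclass(frozen=True)
class Correlation:
    method: str                     # "pearson" or "spearman"
    r: float
    ci_low: float
    ci_high: float


@dataclass(frozen=True)
class ConcordanceCC:
    ccc: float
    ci_low: float
    ci_high: float
    category: str


@dataclass(frozen=True)
class BlandAltman:
    mean_bias: float
    loa_lower: float
    loa_upper: float
    means: tuple[float, ...] = field(default=(), repr=False)
    differences: tuple[float, ...] = field(default=(), repr=False)


@dataclass(frozen=True)
class TostResult:
    ci90_low: float
    ci90_high: float
    half_width_min: float
    equivalent: bool


# ---------------------------------------------------------------------------
# Elementary operations
# ---------------------------------------------------------------------------

def _paired(x, y, min_pairs: int = 2) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("paired inputs must be one-dimensional and equal length")
    if x.size < min_pairs:
        raise ValueError(f"need at least {min_pairs} complete pairs; got {x.size}")
    if np.any(~np.isfinite(x)) or np.any(~np.isfinite(y)):
        raise ValueError("paired inputs must be finite")
    return x, y


def _is_normal(values: np.ndarray) -> tuple[bool, float | None]:
    """Shapiro-Wilk gate at alpha = 0.05; constant input counts as non-testable."""
    if values.size < 3 or np.ptp(values) == 0:
        return True, None
    p = float(stats.shapiro(values).pvalue)
    return p > _SHAPIRO_ALPHA, p


def difference_test(test, criterion) -> DifferenceTest:
    """Paired difference test with a normality gate on the differences.

    Differences that are all identical are flagged as degenerate rather than
    fabricating a p-value.
    """
    x, y = _paired(test, criterion)
    d = x - y
    if np.ptp(d) == 0:
        return DifferenceTest(test="degenerate", statistic=None, p_value=None)
    normal, p_norm = _is_normal(d)
    if normal:
        res = stats.ttest_rel(x, y)
        return DifferenceTest("paired_t", float(res.statistic), float(res.pvalue), p_norm)
    res = stats.wilcoxon(x, y)
    return DifferenceTest("wilcoxon", float(res.statistic), float(res.pvalue), p_norm)


def _fisher_ci(r: float, n: int) -> tuple[float, float]:
    if n <= 3 or abs(r) >= 1.0 - 1e-12:
        return r, r
    z = math.atanh(r)
    se = 1.0 / math.sqrt(n - 3)
    return math.tanh(z - _Z95 * se), math.tanh(z + _Z95 * se)


def correlation(test, criterion) -> Correlation:
    """Pearson (both margins normal) or Spearman correlation with 95% CI.

    The CI uses the Fisher z-transformation in either case.
    """
    x, y = _paired(test, criterion, min_pairs=3)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise DegenerateDataError("correlation undefined: a margin has zero variance")
    x_norm, _ = _is_normal(x)
    y_norm, _ = _is_normal(y)
    if x_norm and y_norm:
        r = float(stats.pearsonr(x, y).statistic)
        method = "pearson"
    else:
        r = float(stats.spearmanr(x, y).statistic)
        method = "spearman"
    lo, hi = _fisher_ci(r, x.size)
    return Correlation(method=method, r=r, ci_low=lo, ci_high=hi)


def lin_ccc(test, criterion) -> tuple[float, tuple[float, float]]:
    """Lin's concordance correlation coefficient with a Fisher-type 95% CI.

    The point estimate uses sample moments with 1/n scaling:

        ccc = 2 s_xy / (s_x^2 + s_y^2 + (mean_x - mean_y)^2)

    The CI applies the z-transformation with Lin's asymptotic variance.
    """
    x, y = _paired(test, criterion, min_pairs=3)
    n = x.size
    mx, my = float(np.mean(x)), float(np.mean(y))
    sx2 = float(np.mean((x - mx) ** 2))
    sy2 = float(np.mean((y - my) ** 2))
    sxy = float(np.mean((x - mx) * (y - my)))
    denom = sx2 + sy2 + (mx - my) ** 2
    if denom <= 0:
        raise DegenerateDataError("CCC undefined: both margins have zero variance")
    ccc = 2.0 * sxy / denom

    if sx2 <= 0 or sy2 <= 0 or abs(ccc) >= 1.0 - 1e-12 or n <= 2:
        return ccc, (ccc, ccc)
    r = sxy / math.sqrt(sx2 * sy2)
    if r == 0:
        return ccc, (ccc, ccc)
    u2 = (mx - my) ** 2 / math.sqrt(sx2 * sy2)
    one_m = 1.0 - ccc * ccc
    var_z = (
        (1.0 - r * r) * ccc * ccc / (one_m * r * r)
        + 2.0 * ccc**3 * (1.0 - ccc) * u2 / (r * one_m**2)
        - ccc**4 * u2 * u2 / (2.0 * r * r * one_m**2)
    ) / (n - 2)
    var_z = max(var_z, 0.0)
    z = math.atanh(ccc)
    half = _Z95 * math.sqrt(var_z)
    return ccc, (math.tanh(z - half), math.tanh(z + half))


#: McBride qualitative interpretation bands for the CCC.
_MCBRIDE_BANDS = (
    (0.99, "almost perfect"),
    (0.95, "substantial"),
    (0.90, "moderate"),
)


def mcbride_category(ccc: float) -> str:
    """Qualitative CCC band: poor < 0.90 <= moderate < 0.95 <= substantial
    < 0.99 <= almost perfect."""
    if not (-1.0 <= ccc <= 1.0):
        raise ValueError(f"CCC must lie in [-1, 1]; got {ccc!r}")
    for cut, name in _MCBRIDE_BANDS:
        if ccc >= cut:
            return name
    return "poor"


def bland_altman(test, criterion) -> BlandAltman:
    """Mean bias and 95% limits of agreement on paired differences.

    LoA = bias +/- 1.96 sd(differences) (sample sd, ddof=1); the per-subject
    (mean, difference) points are retained for plotting.
    """
    x, y = _paired(test, criterion)
    d = x - y
    bias = float(np.mean(d))
    sd = float(np.std(d, ddof=1))
    return BlandAltman(
        mean_bias=bias,
        loa_lower=bias - _LOA_MULTIPLIER * sd,
        loa_upper=bias + _LOA_MULTIPLIER * sd,
        means=tuple((x + y) / 2.0),
        differences=tuple(d),
    )


def equivalence_verdict(ci_low: float, ci_high: float, half_width: float) -> bool:
    """Equivalent iff the CI lies inside [-half_width, +half_width]."""
    return (ci_low >= -half_width - 1e-12) and (ci_high <= half_width + 1e-12)


def tost_equivalence(test, criterion, region: EquivalenceRegion | float) -> TostResult:
    """Two one-sided paired t tests via the 90% CI of the mean difference.

    With zero variance the CI collapses to the point estimate and the verdict
    is still defined.
    """
    x, y = _paired(test, criterion)
    half = region.half_width_min if isinstance(region, EquivalenceRegion) else float(region)
    if half <= 0:
        raise ValueError("equivalence half-width must be positive")
    d = x - y
    n = d.size
    m = float(np.mean(d))
    sd = float(np.std(d, ddof=1))
    if sd == 0:
        lo = hi = m
    else:
        se = sd / math.sqrt(n)
        tcrit = float(stats.t.ppf(0.95, n - 1))
        lo, hi = m - tcrit * se, m + tcrit * se
    return TostResult(lo, hi, half, equivalence_verdict(lo, hi, half))


def _round_half_up(x: float) -> float:
    return math.floor(x + 0.5)


def equivalence_region_for(
    criterion_values,
    fraction: float = 0.15,
    rounding: Literal["nearest", "none"] = "nearest",
    behavior: str | None = None,
) -> EquivalenceRegion:
    """Equivalence region of +/-(fraction x criterion mean) minutes.

    The half-width is rounded to the nearest whole minute by default
    (``rounding="none"`` keeps the raw product).  Raises if the criterion
    central tendency is not positive.
    """
    if not (0.0 < fraction < 1.0):
        raise ValueError("fraction must lie in (0, 1)")
    vals = np.asarray(criterion_values, dtype=float)
    if vals.size == 0:
        raise ValueError("criterion_values must be non-empty")
    center = float(np.mean(vals))
    if center <= 0:
        raise ValueError("criterion central tendency must be positive")
    half = fraction * center
    if rounding == "nearest":
        half = _round_half_up(half)
        if half <= 0:
            half = fraction * center  # too small to round; keep raw
    return EquivalenceRegion(
        half_width_min=float(half),
        derivation="fraction_of_criterion",
        fraction=fraction,
        behavior=behavior,
    )


def escalate_equivalence(
    test,
    criterion,
    start_fraction: float = 0.10,
    step: float = 0.05,
    max_fraction: float = 0.50,
    rounding: Literal["nearest", "none"] = "nearest",
) -> float | None:
    """Smallest fraction on the (start, start+step, ...) grid achieving
    equivalence, or None if none does up to ``max_fraction``."""
    if step <= 0:
        raise ValueError("step must be positive")
    if not (0.0 < start_fraction <= max_fraction < 1.0):
        raise ValueError("fractions must satisfy 0 < start <= max < 1")
    frac = start_fraction
    while frac <= max_fraction + 1e-9:
        region = equivalence_region_for(criterion, fraction=frac, rounding=rounding)
        if tost_equivalence(test, criterion, region).equivalent:
            return round(frac, 10)
        frac += step
    return None


# ---------------------------------------------------------------------------
# Model / Results
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BehaviorAgreement:
    """All agreement statistics for one behavior."""

    behavior: str
    n: int
    test_mean: float
    criterion_mean: float
    difference: DifferenceTest
    correlation: Correlation | None
    concordance: ConcordanceCC | None
    bland_altman: BlandAltman
    tost: TostResult
    region: EquivalenceRegion
    minimal_equivalent_fraction: float | None

    def to_dict(self) -> dict:
        d = {
            "behavior": self.behavior,
            "n": self.n,
            "test_mean": self.test_mean,
            "criterion_mean": self.criterion_mean,
            "difference": asdict(self.difference),
            "correlation": asdict(self.correlation) if self.correlation else None,
            "concordance": asdict(self.concordance) if self.concordance else None,
            "bland_altman": {
                "mean_bias": self.bland_altman.mean_bias,
                "loa_lower": self.bland_altman.loa_lower,
                "loa_upper": self.bland_altman.loa_upper,
            },
            "tost": asdict(self.tost),
            "region": asdict(self.region),
            "minimal_equivalent_fraction": self.minimal_equivalent_fraction,
        }
        return d


def _wide_pairs(data: pd.DataFrame) -> dict[str, pd.DataFrame]:
    """Split a long table into per-behavior frames of complete pairs,
    appending the per-subject composite behaviors."""
    required = {"subject_id", "behavior", "test_min", "criterion_min"}
    missing = required - set(data.columns)
    if missing:
        raise ValueError(f"paired data missing columns: {sorted(missing)}")
    bad = set(data["behavior"].unique()) - set(BEHAVIORS)
    if bad:
        raise ValueError(f"unknown behaviors in paired data: {sorted(bad)}")
    if (data[["test_min", "criterion_min"]] < 0).any().any():
        raise ValueError("minutes must be non-negative")
    if data.duplicated(["subject_id", "behavior"]).any():
        raise ValueError("duplicate (subject, behavior) rows in paired data")

    out: dict[str, pd.DataFrame] = {}
    for b in BEHAVIORS:
        sub = data[data["behavior"] == b][["subject_id", "test_min", "criterion_min"]]
        out[b] = sub.set_index("subject_id").sort_index()

    # composites from subjects with all three base behaviors
    common = out["sitting"].index
    for b in ("standing", "stepping"):
        common = common.intersection(out[b].index)
    sit, sta, ste = (out[b].loc[common] for b in BEHAVIORS)
    out["stationary"] = sit + sta
    out["upright"] = sta + ste
    out["recording"] = sit + sta + ste
    return out


class DeviceAgreement:
    """Agreement model comparing test-device totals against a criterion.

    Parameters
    ----------
    data : DataFrame
        Long format with columns ``subject_id, behavior, test_min,
        criterion_min``; behaviors restricted to sitting/standing/stepping.
        Composites are assembled internally per subject.
    fraction : float
        Equivalence-region fraction of the criterion mean (default 0.15).
    absolute_regions : dict, optional
        Per-behavior absolute half-widths (minutes) overriding the
        fraction-of-criterion rule, e.g. to apply externally pre-specified
        regions verbatim.
    region_rounding : {"nearest", "none"}
        Rounding policy for fraction-derived half-widths.
    """

    def __init__(
        self,
        data: pd.DataFrame,
        fraction: float = 0.15,
        absolute_regions: dict[str, float] | None = None,
        region_rounding: Literal["nearest", "none"] = "nearest",
        escalation_start: float = 0.05,
        escalation_step: float = 0.05,
        escalation_max: float = 0.50,
    ) -> None:
        self.data = data.copy()
        self.fraction = float(fraction)
        self.absolute_regions = dict(absolute_regions or {})
        self.region_rounding = region_rounding
        self.escalation = (escalation_start, escalation_step, escalation_max)
        self._pairs = _wide_pairs(self.data)

    @classmethod
    def from_dataframe(cls, data: pd.DataFrame, **kwargs) -> "DeviceAgreement":
        return cls(data, **kwargs)

    @classmethod
    def from_csv(cls, path, **kwargs) -> "DeviceAgreement":
        return cls(pd.read_csv(path), **kwargs)

    def region_for(self, behavior: str, criterion: np.ndarray) -> EquivalenceRegion:
        if behavior in self.absolute_regions:
            return EquivalenceRegion(
                half_width_min=float(self.absolute_regions[behavior]),
                derivation="absolute",
                behavior=behavior,
            )
        return equivalence_region_for(
            criterion, fraction=self.fraction, rounding=self.region_rounding,
            behavior=behavior,
        )

    def fit(self) -> "AgreementResults":
        behaviors: dict[str, BehaviorAgreement] = {}
        for b in ALL_BEHAVIORS:
            sub = self._pairs[b]
            if len(sub) < 2:
                logger.warning("behavior %r skipped: fewer than 2 complete pairs", b)
                continue
            x = sub["test_min"].to_numpy(dtype=float)
            y = sub["criterion_min"].to_numpy(dtype=float)
            try:
                corr = correlation(x, y)
            except (DegenerateDataError, ValueError):
                corr = None
            try:
                ccc, (lo, hi) = lin_ccc(x, y)
                conc = ConcordanceCC(ccc, lo, hi, mcbride_category(ccc))
            except (DegenerateDataError, ValueError):
                conc = None
            region = self.region_for(b, y)
            start, step, fmax = self.escalation
            behaviors[b] = BehaviorAgreement(
                behavior=b,
                n=len(sub),
                test_mean=float(np.mean(x)),
                criterion_mean=float(np.mean(y)),
                difference=difference_test(x, y),
                correlation=corr,
                concordance=conc,
                bland_altman=bland_altman(x, y),
                tost=tost_equivalence(x, y, region),
                region=region,
                minimal_equivalent_fraction=escalate_equivalence(
                    x, y, start_fraction=start, step=step, max_fraction=fmax,
                    rounding=self.region_rounding,
                ),
            )
        return AgreementResults(model=self, behaviors=behaviors)


class AgreementResults:
    """Fitted agreement statistics per behavior, with export helpers."""

    def __init__(self, model: DeviceAgreement | None, behaviors: dict[str, BehaviorAgreement]):
        self.model = model
        self.behaviors = behaviors

    def __getitem__(self, behavior: str) -> BehaviorAgreement:
        return self.behaviors[behavior]

    # -- presentation ------------------------------------------------------
    def summary(self) -> str:
        lines = [
            "Device agreement vs criterion (per-behavior session totals, minutes)",
            "=" * 78,
            f"{'behavior':<11}{'n':>3}{'bias':>8}{'LoA':>18}{'CCC':>6}  "
            f"{'category':<15}{'90% CI':>15}  {'equivalent':<10}",
            "-" * 78,
        ]
        for b, res in self.behaviors.items():
            ba = res.bland_altman
            ccc = f"{res.concordance.ccc:.2f}" if res.concordance else "--"
            cat = res.concordance.category if res.concordance else "--"
            lines.append(
                f"{b:<11}{res.n:>3}{ba.mean_bias:>8.2f}"
                f"{f'({ba.loa_lower:.2f}, {ba.loa_upper:.2f})':>18}"
                f"{ccc:>6}  {cat:<15}"
                f"{f'({res.tost.ci90_low:.1f}, {res.tost.ci90_high:.1f})':>15}  "
                f"{'yes' if res.tost.equivalent else 'no':<10}"
            )
        lines.append("-" * 78)
        lines.append(
            "equivalence: TOST 90% CI within +/- region half-width "
            "(default 15% of criterion mean)"
        )
        return "\n".join(lines)

    # -- serialization -----------------------------------------------------
    def to_dict(self) -> dict:
        return {b: res.to_dict() for b, res in self.behaviors.items()}

    def to_json(self, path=None, **meta) -> str:
        payload = {"behaviors": self.to_dict()}
        payload.update(meta)
        text = json.dumps(payload, indent=2, sort_keys=True)
        if path is not None:
            with open(path, "w", encoding="utf-8") as fh:
                fh.write(text + "\n")
        return text

    def to_frame(self) -> pd.DataFrame:
        """Flat one-row-per-(behavior, statistic) table."""
        rows = []
        for b, res in self.behaviors.items():
            flat = {
                "n": res.n,
                "test_mean": res.test_mean,
                "criterion_mean": res.criterion_mean,
                "difference_test": res.difference.test,
                "difference_p": res.difference.p_value,
                "correlation_method": res.correlation.method if res.correlation else None,
                "r": res.correlation.r if res.correlation else None,
                "r_ci_low": res.correlation.ci_low if res.correlation else None,
                "r_ci_high": res.correlation.ci_high if res.correlation else None,
                "ccc": res.concordance.ccc if res.concordance else None,
                "ccc_ci_low": res.concordance.ci_low if res.concordance else None,
                "ccc_ci_high": res.concordance.ci_high if res.concordance else None,
                "ccc_category": res.concordance.category if res.concordance else None,
                "mean_bias": res.bland_altman.mean_bias,
                "loa_lower": res.bland_altman.loa_lower,
                "loa_upper": res.bland_altman.loa_upper,
                "tost_ci90_low": res.tost.ci90_low,
                "tost_ci90_high": res.tost.ci90_high,
                "region_half_width": res.region.half_width_min,
                "equivalent": res.tost.equivalent,
                "minimal_equivalent_fraction": res.minimal_equivalent_fraction,
            }
            for stat, value in flat.items():
                rows.append({"behavior": b, "statistic": stat, "value": value})
        return pd.DataFrame(rows, columns=["behavior", "statistic", "value"])

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_json(cls, path) -> "AgreementResults":
        with open(path, encoding="utf-8") as fh:
            payload = json.load(fh)
        behaviors = {}
        for b, d in payload["behaviors"].items():
            behaviors[b] = BehaviorAgreement(
                behavior=d["behavior"],
                n=d["n"],
                test_mean=d["test_mean"],
                criterion_mean=d["criterion_mean"],
                difference=DifferenceTest(**d["difference"]),
                correlation=Correlation(**d["correlation"]) if d["correlation"] else None,
                concordance=ConcordanceCC(**d["concordance"]) if d["concordance"] else None,
                bland_altman=BlandAltman(**d["bland_altman"]),
                tost=TostResult(**d["tost"]),
                region=EquivalenceRegion(**d["region"]),
                minimal_equivalent_fraction=d["minimal_equivalent_fraction"],
            )
        return cls(model=None, behaviors=behaviors)

    # -- plotting ----------------------------------------------------------
    def plot_bland_altman(self, behavior: str, ax=None, path=None):
        """Bland-Altman scatter with bias and LoA reference lines."""
        import matplotlib
        if path is not None:
            matplotlib.use("Agg", force=False)
        import matplotlib.pyplot as plt

        res = self.behaviors[behavior]
        ba = res.bland_altman
        if ax is None:
            fig, ax = plt.subplots(figsize=(5, 4))
        else:
            fig = ax.figure
        ax.scatter(ba.means, ba.differences, s=20, color="tab:blue", alpha=0.7)
        ax.axhline(ba.mean_bias, color="k", lw=1.2, label=f"bias {ba.mean_bias:.2f}")
        for v in (ba.loa_lower, ba.loa_upper):
            ax.axhline(v, color="k", lw=0.8, ls="--")
        ax.set_xlabel("mean of devices (min)")
        ax.set_ylabel("test - criterion (min)")
        ax.set_title(f"Bland-Altman: {behavior}")
        ax.legend(loc="best", fontsize=8)
        if path is not None:
            fig.savefig(path, dpi=120, bbox_inches="tight")
            plt.close(fig)
        return ax
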