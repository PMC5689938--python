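"""Agreement statistics: Dice, mean-percentage differences, Bland-Altman
reproducibility limits, reproducibility classification, and ICC precision.

Conventions
-----------
* Per-case percentage difference uses the pair mean as denominator:
  ``d = (f_m - f_n) / ((f_m + f_n) / 2) * 100``; cases with a zero pair mean
  are excluded per feature and logged.
* ``|d_bar|`` is the absolute value of the *mean signed* difference (signed
  first, then absolute), as required for coherent Bland-Altman limits.
* Limits: ``URL = mean + 1.96 SD`` and ``LRL = mean - 1.96 SD`` with the
  sample SD (ddof=1) of the signed differences.
* A feature is *reproducible* iff ``|d_bar| <= 25`` and ``SD <= 35``; the
  level comes from ``m = max(|URL|, |LRL|)``: High for ``m <= 30`` (including
  ``m < 1``), Intermediate for ``30 < m <= 45``, Low for ``45 < m <= 50``,
  otherwise NR.  Band edges are inclusive.
* ICC is the two-way random-effects, absolute-agreement, single-measurement
  form with an F-based 95% CI; precision is the CI half-width x 100.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .volio import FeatureTable, ROIMask

__all__ = [
    "PairedDifferenceResult",
    "ICCResult",
    "ReproClass",
    "dice",
    "percentage_differences",
    "paired_differences",
    "classify_reproducibility",
    "icc_with_precision",
    "precision_from_ci",
    "inter_item_correlation",
    "icc2_single",
    "PARAMETER_COLUMNS",
]

logger = logging.getLogger(__name__)

Z_95 = 1.96

#: Study-parameter codes mapped to feature-table variant columns.
PARAMETER_COLUMNS = {"SM": "segmentation", "GL": "gray_level", "RA": "recon"}


# ---------------------------------------------------------------------------
# Dice
# ---------------------------------------------------------------------------


def dice(a: ROIMask, b: ROIMask) -> float:
    """Dice overlap ``2|A n B| / (|A| + |B|)`` of two aligned masks."""
    if a.shape != b.shape:
        raise ValueError(f"mask shapes differ: {a.shape} vs {b.shape}")
    na = int(a.values.sum())
    nb = int(b.values.sum())
    if na + nb == 0:
        raise ValueError("Dice undefined: both masks are empty")
    inter = int(np.logical_and(a.as_bool(), b.as_bool()).sum())
    return 2.0 * inter / (na + nb)


# ---------------------------------------------------------------------------
# Paired percentage differences and Bland-Altman limits
# ---------------------------------------------------------------------------


@dataclass
class PairedDifferenceResult:
    feature_name: str
    pair_label: str
    d: np.ndarray  # per-case signed percentage differences
    d_mean: float
    d_mean_abs: float
    sd: float
    lrl: float
    url: float
    n_cases: int
    n_excluded: int = 0


def percentage_differences(fm: np.ndarray, fn: np.ndarray) -> tuple[np.ndarray, int]:
    """Signed per-case percentage differences on the pair-mean scale.

    Returns the valid differences and the count of cases excluded for a zero
    pair-mean denominator.
    """
    fm = np.asarray(fm, dtype=float)
    fn = np.asarray(fn, dtype=float)
    if fm.shape != fn.shape:
        raise ValueError("paired value arrays must have equal length")
    mean = (fm + fn) / 2.0
    valid = mean != 0.0
    n_excluded = int((~valid).sum())
    d = (fm[valid] - fn[valid]) / mean[valid] * 100.0
    return d, n_excluded


def _summarize(feature: str, pair_label: str, d: np.ndarray, n_excluded: int) -> PairedDifferenceResult:
    if d.size == 0:
        raise ValueError(
            f"no valid cases for feature {feature!r}, pair {pair_label!r} "
            f"({n_excluded} excluded for zero pair mean)"
        )
    d_mean = float(d.mean())
    sd = float(d.std(ddof=1)) if d.size > 1 else 0.0
    return PairedDifferenceResult(
        feature_name=feature,
        pair_label=pair_label,
        d=d,
        d_mean=d_mean,
        d_mean_abs=abs(d_mean),
        sd=sd,
        lrl=d_mean - Z_95 * sd,
        url=d_mean + Z_95 * sd,
        n_cases=int(d.size),
        n_excluded=n_excluded,
    )


def _variant_column(table: FeatureTable, label) -> str:
    for col in ("segmentation", "gray_level", "recon"):
        if label in set(table.data[col].unique()):
            return col
    raise ValueError(f"variant label {label!r} not present in the feature table")


def paired_differences(
    table: FeatureTable,
    pair: tuple,
    variant_column: str | None = None,
) -> list[PairedDifferenceResult]:
    """Per-feature paired percentage differences between two variant labels.

    Cases are matched by ``case_id``; both labels must be present for every
    matched case (cases missing one arm are dropped with a log entry).
    """
    m_label, n_label = pair
    if variant_column is None:
        variant_column = _variant_column(table, m_label)
    wide = table.pivot(variant_column)
    if m_label not in wide.columns or n_label not in wide.columns:
        raise ValueError(f"pair {pair!r} not present in column {variant_column!r}")
    pair_label = f"{m_label}-{n_label}"
    out: list[PairedDifferenceResult] = []
    for feature, grp in wide.groupby(level="feature_name"):
        fm = grp[m_label].to_numpy()
        fn = grp[n_label].to_numpy()
        keep = ~(np.isnan(fm) | np.isnan(fn))
        dropped = int((~keep).sum())
        if dropped:
            logger.info(
                "feature %s pair %s: dropping %d case(s) missing one arm",
                feature, pair_label, dropped,
            )
        d, n_excluded = percentage_differences(fm[keep], fn[keep])
        if n_excluded:
            logger.info(
                "feature %s pair %s: excluded %d case(s) with zero pair mean",
                feature, pair_label, n_excluded,
            )
        out.append(_summarize(str(feature), pair_label, d, n_excluded))
    return out


# ---------------------------------------------------------------------------
# Reproducibility classification
# ---------------------------------------------------------------------------


@dataclass
class ReproClass:
    level: str  # High | Intermediate | Low | NR
    reproducible: bool  # |d_bar| <= 25 and SD <= 35 gate
    d_mean_abs: float
    sd: float
    limit_magnitude: float  # max(|URL|, |LRL|)


def classify_reproducibility(res: PairedDifferenceResult) -> ReproClass:
    """Classify a paired-difference result into High/Intermediate/Low/NR."""
    gate = res.d_mean_abs <= 25.0 and res.sd <= 35.0
    m = max(abs(res.url), abs(res.lrl))
    if not gate:
        level = "NR"
    elif m <= 30.0:  # limits below +/-1% are treated as High
        level = "High"
    elif m <= 45.0:
        level = "Intermediate"
    elif m <= 50.0:
        level = "Low"
    else:
        level = "NR"
    return ReproClass(
        level=level,
        reproducible=gate,
        d_mean_abs=res.d_mean_abs,
        sd=res.sd,
        limit_magnitude=m,
    )


# ---------------------------------------------------------------------------
# ICC and precision
# ---------------------------------------------------------------------------


@dataclass
class ICCResult:
    feature_name: str
    parameter: str
    icc: float
    ci_lb: float
    ci_ub: float
    precision: float
    n_cases: int
    n_raters: int


def precision_from_ci(ci_lb: float, ci_ub: float) -> float:
    """Half-width of a confidence interval, scaled by 100."""
    lo, hi = sorted((float(ci_lb), float(ci_ub)))
    return (hi - lo) / 2.0 * 100.0


def icc2_single(ratings: np.ndarray, alpha: float = 0.05) -> tuple[float, float, float]:
    """Two-way random, absolute agreement, single-rater ICC with F-based CI.

    ``ratings`` is a complete (cases x raters) matrix.  Follows the
    McGraw & Wong ICC(A,1) estimator and its Satterthwaite-style confidence
    bounds.  Degenerate inputs: zero within-case variance with case spread
    -> (1, 1, 1); zero between-case variance -> NaNs with a warning.
    """
    from scipy.stats import f as fdist

    y = np.asarray(ratings, dtype=float)
    if y.ndim != 2:
        raise ValueError("ratings must be a 2D (cases x raters) matrix")
    n, k = y.shape
    if n < 3 or k < 2:
        raise ValueError(f"ICC needs >= 3 cases and >= 2 raters, got {n} x {k}")

    between_spread = y.mean(axis=1).std()
    within_spread = np.abs(y - y.mean(axis=1, keepdims=True)).max()
    scale = max(np.abs(y).max(), 1.0)
    if between_spread <= 1e-12 * scale:
        warnings.warn("ICC undefined: zero between-case variance", stacklevel=2)
        return float("nan"), float("nan"), float("nan")
    if within_spread <= 1e-12 * scale:
        return 1.0, 1.0, 1.0

    grand = y.mean()
    row_means = y.mean(axis=1)
    col_means = y.mean(axis=0)
    msb = k * np.sum((row_means - grand) ** 2) / (n - 1)  # between cases
    msj = n * np.sum((col_means - grand) ** 2) / (k - 1)  # between raters
    sse = np.sum((y - row_means[:, None] - col_means[None, :] + grand) ** 2)
    mse = sse / ((n - 1) * (k - 1))

    icc = (msb - mse) / (msb + (k - 1) * mse + k * (msj - mse) / n)

    if mse <= 0:
        return float(icc), float(icc), float(icc)
    fj = msj / mse
    vn = (k - 1) * (n - 1) * (k * icc * fj + n * (1 + (k - 1) * icc) - k * icc) ** 2
    vd = (n - 1) * k**2 * icc**2 * fj**2 + (n * (1 + (k - 1) * icc) - k * icc) ** 2
    v = vn / vd
    f2u = fdist.ppf(1 - alpha / 2, n - 1, v)
    f2l = fdist.ppf(1 - alpha / 2, v, n - 1)
    lb = n * (msb - f2u * mse) / (
        f2u * (k * msj + (k * n - k - n) * mse) + n * msb
    )
    ub = n * (f2l * msb - mse) / (k * msj + (k * n - k - n) * mse + n * f2l * msb)
    lb, ub = sorted((float(lb), float(ub)))
    return float(icc), lb, ub


def icc_with_precision(
    table: FeatureTable,
    parameter: str,
    variant_column: str | None = None,
) -> list[ICCResult]:
    """Per-feature ICC(2,1) with 95% CI and precision across one parameter.

    ``parameter`` is one of ``SM``, ``GL``, ``RA`` (or an explicit variant
    column name via ``variant_column``).  Each variant level acts as a rater.
    """
    if variant_column is None:
        try:
            variant_column = PARAMETER_COLUMNS[parameter]
        except KeyError:
            raise ValueError(f"unknown parameter {parameter!r}; expected SM, GL or RA")
    wide = table.pivot(variant_column)
    out: list[ICCResult] = []
    for feature, grp in wide.groupby(level="feature_name"):
        mat = grp.dropna(axis=0).to_numpy()
        icc, lb, ub = icc2_single(mat)
        prec = precision_from_ci(lb, ub) if np.isfinite(lb) and np.isfinite(ub) else float("nan")
        out.append(
            ICCResult(
                feature_name=str(feature),
                parameter=parameter,
                icc=icc,
                ci_lb=lb,
                ci_ub=ub,
                precision=prec,
                n_cases=mat.shape[0],
                n_raters=mat.shape[1],
            )
        )
    return out


# ---------------------------------------------------------------------------
# Inter-item correlation (reference gray-level choice)
# ---------------------------------------------------------------------------


def inter_item_correlation(
    table: FeatureTable,
    reference_gl: int,
    other_gls: tuple[int, ...],
) -> pd.DataFrame:
    """Pearson correlation of each feature across cases between the reference
    gray level and each other level.  Constant vectors yield NaN with a log
    entry.  Returns a (feature x gray level) frame."""
    wide = table.pivot("gray_level")
    if reference_gl not in wide.columns:
        raise ValueError(f"reference gray level {reference_gl} not in table")
    rows = {}
    for feature, grp in wide.groupby(level="feature_name"):
        vals = {}
        ref = grp[reference_gl].to_numpy()
        for gl in other_gls:
            if gl not in grp.columns:
                raise ValueError(f"gray level {gl} not in table")
            other = grp[gl].to_numpy()
            keep = ~(np.isnan(ref) | np.isnan(other))
            r_, o_ = ref[keep], other[keep]
            if r_.size < 2 or r_.std() == 0 or o_.std() == 0:
                logger.info("feature %s: constant vector, IIC undefined for GL %s", feature, gl)
                vals[gl] = float("nan")
            else:
                vals[gl] = float(np.corrcoef(r_, o_)[0, 1])
        rows[str(feature)] = vals
    return pd.DataFrame.from_dict(rows, orient="index").sort_index()


# ---------------------------------------------------------------------------
# Optional plots
# ---------------------------------------------------------------------------


def bland_altman_plot(res: PairedDifferenceResult, fm: np.ndarray, fn: np.ndarray, path) -> None:
    """Write a Bland-Altman scatter (pair mean vs signed % difference)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    mean = (np.asarray(fm, float) + np.asarray(fn, float)) / 2.0
    valid = mean != 0
    d = (np.asarray(fm, float)[valid] - np.asarray(fn, float)[valid]) / mean[valid] * 100.0
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.scatter(mean[valid], d, s=18, alpha=0.8)
    for yv, style, lab in (
        (res.d_mean, "-", "mean"),
        (res.url, "--", "URL"),
        (res.lrl, "--", "LRL"),
    ):
        ax.axhline(yv, linestyle=style, color="gray")
        ax.annotate(lab, xy=(ax.get_xlim()[1], yv), fontsize=8)
    ax.set_xlabel("pair mean")
    ax.set_ylabel("difference (%)")
    ax.set_title(f"{res.feature_name} [{res.pair_label}]")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def reproducibility_heatmap(class_table: pd.DataFrame, path) -> None:
    """Color-coded (feature x pair) reproducibility map.

    ``class_table`` must have columns feature_name, pair_label, level.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    order = {"High": 3, "Intermediate": 2, "Low": 1, "NR": 0}
    piv = class_table.pivot_table(
        index="feature_name", columns="pair_label", values="level",
        aggfunc="first",
    )
    grid = piv.apply(lambda c: c.map(order)).to_numpy(dtype=float)
    fig, ax = plt.subplots(figsize=(1 + 0.55 * piv.shape[1], 1 + 0.16 * piv.shape[0]))
    im = ax.imshow(grid, aspect="auto", cmap="RdYlGn", vmin=0, vmax=3)
    ax.set_xticks(range(piv.shape[1]), piv.columns, rotation=45, ha="right", fontsize=7)
    ax.set_yticks(range(piv.shape[0]), piv.index, fontsize=6)
    fig.colorbar(im, ticks=[0, 1, 2, 3]).ax.set_yticklabels(["NR", "Low", "Interm.", "High"])
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
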