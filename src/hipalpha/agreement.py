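"""Agreement statistics for validating automatic against manual alpha angles.

Implements the battery used to compare two raters of the same hips:
Lin's concordance correlation coefficient (CCC) with a Fisher-z
confidence interval, Cohen's kappa with percentage agreement for the
binary cam classification, the mean absolute difference, and
Bland-Altman limits of agreement with outlier identification.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats

__all__ = [
    "AgreementStats",
    "concordance_correlation",
    "cohen_kappa_binary",
    "mean_absolute_difference",
    "bland_altman",
    "compute_agreement",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class AgreementStats:
    """Summary of agreement between two sets of paired alpha angles."""

    n: int
    ccc: float
    ccc_ci_low: float
    ccc_ci_high: float
    kappa: float
    percent_agreement: float
    mean_abs_diff: float
    mad_sd: float
    bland_altman_mean: float
    bland_altman_loa_low: float
    bland_altman_loa_high: float
    outlier_ids: tuple = field(default_factory=tuple)

    def to_dict(self) -> dict:
        d = {k: getattr(self, k) for k in (
            "n", "ccc", "ccc_ci_low", "ccc_ci_high", "kappa",
            "percent_agreement", "mean_abs_diff", "mad_sd",
            "bland_altman_mean", "bland_altman_loa_low",
            "bland_altman_loa_high",
        )}
        d["outlier_ids"] = list(self.outlier_ids)
        return d


def _paired(x, y) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D sequences of equal length")
    return x, y


def concordance_correlation(
    x: Sequence[float], y: Sequence[float], ci_level: float = 0.95
) -> tuple[float, float, float]:
    """Lin's concordance correlation coefficient with its Fisher-z CI.

    CCC = 2 s_xy / (s_x^2 + s_y^2 + (x̄ − ȳ)^2) with population (1/n)
    moments; it penalises both loss of correlation and location/scale
    shift, so CCC = 1 only for y == x.  The confidence interval applies
    the normal approximation to the Fisher z-transform of the CCC with
    Lin's asymptotic variance, then back-transforms.
    """
    x, y = _paired(x, y)
    n = len(x)
    if n < 3:
        raise ValueError("concordance correlation needs n >= 3 pairs")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("inputs must be finite")
    mx, my = x.mean(), y.mean()
    sx2 = float(np.var(x))  # population (1/n) moments, per Lin's estimator
    sy2 = float(np.var(y))
    sxy = float(np.mean((x - mx) * (y - my)))
    denom = sx2 + sy2 + (mx - my) ** 2
    if denom == 0.0:
        raise ValueError("CCC undefined: both sequences constant and equal")
    ccc = 2.0 * sxy / denom

    # Fisher-z CI with Lin's asymptotic variance of z = atanh(ccc)
    zcrit = stats.norm.ppf(0.5 + ci_level / 2.0)
    if sx2 == 0.0 or sy2 == 0.0 or abs(ccc) >= 1.0 - 1e-15:
        # degenerate: no sampling variability expressible on the z scale
        return float(ccc), float(ccc), float(ccc)
    r = sxy / math.sqrt(sx2 * sy2)
    u2 = (mx - my) ** 2 / math.sqrt(sx2 * sy2)
    one_m = 1.0 - ccc**2
    if r == 0.0:
        return float(ccc), -1.0, 1.0
    var_z = (
        (1.0 - r**2) * ccc**2 / (one_m * r**2)
        + 4.0 * ccc**3 * (1.0 - ccc) * u2 / (r * one_m**2)
        - 2.0 * ccc**4 * u2**2 / (r**2 * one_m**2)
    ) / (n - 2)
    var_z = max(var_z, 0.0)
    z = math.atanh(ccc)
    half = zcrit * math.sqrt(var_z)
    return float(ccc), float(math.tanh(z - half)), float(math.tanh(z + half))


def cohen_kappa_binary(a, b) -> tuple[float, float]:
    """Cohen's kappa and percentage agreement for two binary raters.

    kappa = (p_o − p_e) / (1 − p_e) from the 2x2 contingency table;
    percentage agreement is 100 p_o.  When chance agreement p_e is 1
    (both raters constant) kappa is undefined and returned as NaN.
    """
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    if a.shape != b.shape or a.ndim != 1 or len(a) == 0:
        raise ValueError("a and b must be equal-length non-empty sequences")
    n = len(a)
    po = float(np.mean(a == b))
    pa, pb = float(a.mean()), float(b.mean())
    pe = pa * pb + (1 - pa) * (1 - pb)
    if pe == 1.0:
        return float("nan"), 100.0 * po
    kappa = (po - pe) / (1.0 - pe)
    return float(kappa), 100.0 * po


def mean_absolute_difference(x, y) -> tuple[float, float]:
    """Mean and sample SD (n−1 denominator) of the absolute differences."""
    x, y = _paired(x, y)
    if len(x) < 2:
        raise ValueError("mean absolute difference needs n >= 2 pairs")
    d = np.abs(x - y)
    return float(d.mean()), float(d.std(ddof=1))


def bland_altman(x, y, ids=None, plot_path=None):
    """Bland-Altman limits of agreement and the outliers beyond them.

    Differences d = x − y; limits of agreement are mean(d) ± 1.96 sd(d)
    (sample SD).  Pairs with d strictly outside the limits are flagged
    by their id.  If ``plot_path`` is given, the standard plot
    (difference against pairwise mean) is written there.

    Returns ``(mean_diff, loa_low, loa_high, outlier_ids)``.
    """
    x, y = _paired(x, y)
    n = len(x)
    if n < 3:
        raise ValueError("Bland-Altman needs n >= 3 pairs")
    if ids is None:
        ids = list(range(n))
    if len(ids) != n:
        raise ValueError("ids must match the number of pairs")
    d = x - y
    mean_diff = float(d.mean())
    sd = float(d.std(ddof=1))
    loa_low = mean_diff - 1.96 * sd
    loa_high = mean_diff + 1.96 * sd
    outliers = tuple(
        ids[i] for i in range(n) if d[i] < loa_low or d[i] > loa_high
    )
    if plot_path is not None:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(6, 4.5))
        ax.scatter((x + y) / 2.0, d, s=12, alpha=0.7)
        for yv, style in ((mean_diff, "-"), (loa_low, "--"), (loa_high, "--")):
            ax.axhline(yv, linestyle=style, color="grey")
        ax.set_xlabel("mean of paired measures (degrees)")
        ax.set_ylabel("difference (degrees)")
        ax.set_title("Bland-Altman")
        fig.tight_layout()
        fig.savefig(plot_path, dpi=120)
        plt.close(fig)
    return mean_diff, loa_low, loa_high, outliers


def compute_agreement(
    x,
    y,
    ids=None,
    cam_threshold_deg: float = 60.0,
    ci_level: float = 0.95,
    plot_path=None,
) -> AgreementStats:
    """Full agreement battery between two paired alpha-angle series.

    Pairs with a missing (NaN) value in either series are dropped
    listwise before any statistic is computed; the drop count is logged.
    The cam classifications for kappa are derived from the angles at
    ``cam_threshold_deg``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D sequences of equal length")
    if ids is None:
        ids = list(range(len(x)))
    if len(ids) != len(x):
        raise ValueError("ids must match the number of pairs")
    keep = np.isfinite(x) & np.isfinite(y)
    n_dropped = int((~keep).sum())
    if n_dropped:
        log.info("dropping %d pairs with missing values", n_dropped)
    x, y = x[keep], y[keep]
    ids = [i for i, k in zip(ids, keep) if k]
    if len(x) < 3:
        raise ValueError("fewer than 3 complete pairs after dropping missing")

    ccc, lo, hi = concordance_correlation(x, y, ci_level=ci_level)
    kappa, pct = cohen_kappa_binary(
        x >= cam_threshold_deg, y >= cam_threshold_deg
    )
    mad, mad_sd = mean_absolute_difference(x, y)
    mean_d, loa_lo, loa_hi, outliers = bland_altman(
        x, y, ids=ids, plot_path=plot_path
    )
    return AgreementStats(
        n=len(x),
        ccc=ccc,
        ccc_ci_low=lo,
        ccc_ci_high=hi,
        kappa=kappa,
        percent_agreement=pct,
        mean_abs_diff=mad,
        mad_sd=mad_sd,
        bland_altman_mean=mean_d,
        bland_altman_loa_low=loa_lo,
        bland_altman_loa_high=loa_hi,
        outlier_ids=tuple(outliers),
    )
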