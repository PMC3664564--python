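"""qPCR standard-curve quantification and screening-vs-validation concordance.

Relative quantification follows the standard-curve method: a dilution series
of known quantities yields a least-squares line Ct = intercept +
slope * log10(quantity) (slope < 0; amplification efficiency
10^(-1/slope) - 1); unknown Ct values (technical triplicates averaged first)
are inverted on the curve and normalized to a reference assay measured the
same way.

Concordance between a screening platform and the validation assay is the
Spearman rank correlation of the matched values, with an empirical
probability from repeatedly permuting the association between the validation
and screening entries and recomputing rho (k permutations, +1 small-sample
correction) — a resampling scheme in the Westfall-Young spirit, reduced to
the single-statistic case.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .errors import ConfigurationError

__all__ = ["StandardCurve", "ConcordanceResult", "fit_standard_curve",
           "relative_quantity", "spearman_rho", "permutation_concordance",
           "mean_ct", "quantity_from_ct"]


@dataclass(frozen=True)
class StandardCurve:
    """Fitted dilution line Ct = intercept + slope * log10(quantity)."""

    slope: float       # Ct per log10(quantity); < 0 for a valid series
    intercept: float   # Ct at quantity 1
    r_squared: float
    efficiency: float  # 10^(-1/slope) - 1; 1.0 = perfect doubling


@dataclass
class ConcordanceResult:
    rho_observed: float
    k: int
    rho_permuted: np.ndarray
    p_empirical: float          # two-sided on |rho|, (+1)/(k+1)-corrected
    p_one_sided: float          # P(rho_perm >= rho_obs), same correction
    seed: int | None = None

    def __post_init__(self):
        lo = 1.0 / (self.k + 1)
        assert lo - 1e-12 <= self.p_empirical <= 1.0


def fit_standard_curve(dilution_quantities, ct_values) -> StandardCurve:
    """Least-squares Ct vs log10(quantity) line from >= 3 dilution points."""
    q = np.asarray(dilution_quantities, dtype=float)
    ct = np.asarray(ct_values, dtype=float)
    if q.size < 3 or ct.size != q.size:
        raise ConfigurationError(
            "need >= 3 matched dilution points to fit a standard curve")
    if (q <= 0).any():
        raise ConfigurationError("dilution quantities must be > 0")
    x = np.log10(q)
    if np.ptp(x) == 0:
        raise ConfigurationError("zero variance in log10(quantity)")
    res = stats.linregress(x, ct)
    if res.slope >= 0:
        raise ConfigurationError(
            f"standard-curve slope must be negative, got {res.slope:.4g}")
    r2 = float(res.rvalue ** 2)
    eff = float(10.0 ** (-1.0 / res.slope) - 1.0)
    return StandardCurve(float(res.slope), float(res.intercept), r2, eff)


def mean_ct(ct_replicates, drop_outliers: bool = False) -> float:
    """Aggregate technical replicates to one Ct (arithmetic mean).

    With ``drop_outliers`` and a replicate range > 1 Ct, the replicate
    farthest from the median is dropped before averaging.
    """
    ct = np.asarray(ct_replicates, dtype=float)
    if ct.size == 0:
        raise ConfigurationError("no Ct replicates")
    if drop_outliers and ct.size >= 3 and np.ptp(ct) > 1.0:
        med = np.median(ct)
        ct = np.delete(ct, int(np.argmax(np.abs(ct - med))))
    return float(ct.mean())


def quantity_from_ct(ct: float, curve: StandardCurve) -> float:
    """Invert the fitted line: quantity = 10^((intercept - Ct) / |slope|)."""
    return float(10.0 ** ((curve.intercept - ct) / abs(curve.slope)))


def relative_quantity(ct_target, curve_target: StandardCurve,
                      ct_reference, curve_reference: StandardCurve,
                      drop_outliers: bool = False) -> float:
    """Target quantity normalized to the reference assay.

    ``ct_target`` / ``ct_reference`` may be scalars or replicate arrays
    (replicates are averaged first).
    """
    qt = quantity_from_ct(mean_ct(np.atleast_1d(ct_target), drop_outliers),
                          curve_target)
    qr = quantity_from_ct(mean_ct(np.atleast_1d(ct_reference), drop_outliers),
                          curve_reference)
    if qr == 0:
        raise ConfigurationError("reference quantity is zero")
    return qt / qr


def spearman_rho(x_values, y_values) -> float:
    """Spearman rank correlation (Pearson correlation of midranks)."""
    x = np.asarray(x_values, dtype=float)
    y = np.asarray(y_values, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ConfigurationError("need equal-length vectors of size >= 3")
    if np.unique(x).size == 1 or np.unique(y).size == 1:
        raise ConfigurationError("zero rank variance; rho undefined")
    return float(stats.spearmanr(x, y).statistic)


def permutation_concordance(screening_values, validation_values,
                            k: int = 10_000,
                            seed: int | None = None) -> ConcordanceResult:
    """Empirical probability of the observed screening-validation rho.

    ``k`` uniform random permutations of the validation vector re-associate
    validation results with randomly picked screening results; rho is
    recomputed each time.  p_empirical = (#{|rho_perm| >= |rho_obs|} + 1) /
    (k + 1); the signed one-sided tail is reported alongside.  Deterministic
    for a fixed seed.
    """
    if k < 1:
        raise ConfigurationError("k must be >= 1")
    x = np.asarray(screening_values, dtype=float)
    y = np.asarray(validation_values, dtype=float)
    rho_obs = spearman_rho(x, y)
    rng = np.random.default_rng(seed)
    perm = np.empty(k)
    for i in range(k):
        perm[i] = stats.spearmanr(x, rng.permutation(y)).statistic
    p_two = (int((np.abs(perm) >= abs(rho_obs) - 1e-12).sum()) + 1) / (k + 1)
    p_one = (int((perm >= rho_obs - 1e-12).sum()) + 1) / (k + 1)
    return ConcordanceResult(rho_obs, k, perm, min(p_two, 1.0),
                             min(p_one, 1.0), seed)
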