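"""Inter-subject edge-weight variability and group comparison.

For each edge the coefficient of variation (CV) across subjects is the sample
standard deviation divided by the mean; its distribution over the
N(N-1)/2 edges is summarised by a log-normal fit, and two groups are compared
with a two-sided Mann-Whitney-Wilcoxon test (normal approximation with tie
correction, reported as a signed Z).

Note on pooling: edges are treated as exchangeable observations, so the MWW
degrees of freedom equal the edge count.  Edges of one cohort share subjects
and are therefore not independent; the resulting test is anticonservative and
should be read as a descriptive effect-size summary rather than a calibrated
hypothesis test.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import DataError, FitError
from .networks import Cohort

logger = logging.getLogger(__name__)


@dataclass
class LognormalFit:
    """Location/scale of a log-normal fit with uncertainties."""

    mu: float
    sigma: float
    mu_err: float
    sigma_err: float
    n: int
    method: str = "mle"

    def to_dict(self) -> dict:
        return {
            "mu": self.mu, "sigma": self.sigma,
            "mu_err": self.mu_err, "sigma_err": self.sigma_err,
            "n": self.n, "method": self.method,
        }


@dataclass
class MWWResult:
    """Signed-Z Mann-Whitney-Wilcoxon comparison (two-sided)."""

    Z: float
    p: float
    U: float
    n_x: int
    n_y: int

    def to_dict(self) -> dict:
        return {"Z": self.Z, "p": self.p, "U": self.U, "n_x": self.n_x, "n_y": self.n_y}


def coefficient_of_variation(cohort_or_stack) -> np.ndarray:
    """Per-edge coefficient of variation across subjects.

    Accepts a :class:`Cohort` or an (n_subjects, n, n) array of symmetric
    matrices.  Returns an (n, n) matrix with NaN on the diagonal; edges whose
    across-subject mean is zero are flagged NaN and counted in the log.
    Sample (ddof=1) standard deviation is used throughout, making the CV
    invariant to a global rescaling of all subjects' weights.
    """
    if isinstance(cohort_or_stack, Cohort):
        stack = cohort_or_stack.weight_stack()
    else:
        stack = np.asarray(cohort_or_stack, dtype=float)
    if stack.ndim != 3 or stack.shape[1] != stack.shape[2]:
        raise DataError(f"expected (n_subjects, n, n) stack, got shape {stack.shape}")
    if stack.shape[0] < 2:
        raise DataError("coefficient of variation needs >= 2 subjects")
    mean = stack.mean(axis=0)
    sd = stack.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        cv = sd / mean
    n = cv.shape[0]
    off = ~np.eye(n, dtype=bool)
    n_zero = int(np.count_nonzero((mean == 0) & off))
    if n_zero:
        logger.warning("%d edges with zero mean weight excluded from CV", n_zero)
    cv[mean == 0] = np.nan
    np.fill_diagonal(cv, np.nan)
    return cv


def offdiagonal_values(matrix: np.ndarray) -> np.ndarray:
    """Finite strict-upper-triangle values of a symmetric per-edge matrix."""
    m = np.asarray(matrix, dtype=float)
    vals = m[np.triu_indices(m.shape[0], 1)]
    return vals[np.isfinite(vals)]


def fit_lognormal(values, method: str = "mle", min_n: int = 30) -> LognormalFit:
    """Fit a log-normal to positive values.

    ``mle`` (default): mu and sigma are the mean and sample sd of the log
    values, with standard errors sigma/sqrt(n) and sigma/sqrt(2n).

    ``histogram``: least-squares fit of the log-normal density to a
    Freedman-Diaconis histogram (mirrors binned curve-fitting workflows that
    report curve-fit errors); falls back to MLE initialisation.
    """
    v = np.asarray(values, dtype=float)
    v = v[np.isfinite(v)]
    n_bad = int(np.count_nonzero(v <= 0))
    if n_bad:
        raise DataError(f"{n_bad} non-positive values: log-normal fit undefined")
    if v.size < min_n:
        raise DataError(f"need >= {min_n} values for a log-normal fit, got {v.size}")
    logs = np.log(v)
    mu = float(logs.mean())
    sigma = float(logs.std(ddof=1))
    if sigma == 0.0:
        warnings.warn("degenerate log-normal fit: all values equal", stacklevel=2)
        return LognormalFit(mu=mu, sigma=0.0, mu_err=0.0, sigma_err=0.0,
                            n=v.size, method=method)
    if method == "mle":
        return LognormalFit(
            mu=mu, sigma=sigma,
            mu_err=sigma / np.sqrt(v.size),
            sigma_err=sigma / np.sqrt(2 * v.size),
            n=v.size, method="mle",
        )
    if method != "histogram":
        raise DataError(f"unknown log-normal fit method {method!r}")

    from scipy.optimize import curve_fit

    density, edges = np.histogram(v, bins="fd", density=True)
    centers = (edges[:-1] + edges[1:]) / 2.0

    def pdf(x, m, s):
        return np.exp(-((np.log(x) - m) ** 2) / (2 * s**2)) / (x * s * np.sqrt(2 * np.pi))

    try:
        popt, pcov = curve_fit(pdf, centers, density, p0=[mu, sigma], maxfev=20000)
    except RuntimeError as exc:  # pragma: no cover
        raise FitError("histogram log-normal fit did not converge") from exc
    perr = np.sqrt(np.diag(pcov))
    return LognormalFit(
        mu=float(popt[0]), sigma=float(abs(popt[1])),
        mu_err=float(perr[0]), sigma_err=float(perr[1]),
        n=v.size, method="histogram",
    )


def mww_compare(x, y) -> MWWResult:
    """Two-sided Mann-Whitney-Wilcoxon test with signed Z.

    Z is positive when ``x`` tends to be larger than ``y``; the normal
    approximation with tie correction is used (no continuity correction) and
    p = 2 * Phi(-|Z|).  If every value is tied across both samples the result
    is Z = 0, p = 1 with a warning.
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.size == 0 or y.size == 0:
        raise DataError("both samples must be nonempty")
    nx, ny = x.size, y.size
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)
    u_x = float(ranks[:nx].sum() - nx * (nx + 1) / 2.0)
    mean_u = nx * ny / 2.0
    n = nx + ny
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(counts**3 - counts))
    var_u = nx * ny / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    if var_u <= 0:
        warnings.warn("all values tied across both samples", stacklevel=2)
        return MWWResult(Z=0.0, p=1.0, U=u_x, n_x=nx, n_y=ny)
    z = (u_x - mean_u) / np.sqrt(var_u)
    p = 2.0 * stats.norm.sf(abs(z))
    return MWWResult(Z=float(z), p=float(p), U=u_x, n_x=nx, n_y=ny)
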