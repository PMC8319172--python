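"""Nonlinear exponential fits shared by the percolation and allometry modules.

Both decay laws used in the analysis are fitted here by Levenberg-Marquardt /
trust-region least squares (``scipy.optimize.curve_fit``) with tight
tolerances, so that noiseless synthetic series are recovered essentially to
machine precision.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import curve_fit

from .errors import FitError

_TOL = 1e-12
_MAXFEV = 20000


def fit_exponential_decay(x, y):
    """Fit ``y = a * exp(-x / tau)`` with ``tau > 0``.

    Parameters are initialised at ``a = y[0]``, ``tau = 1``.

    Returns
    -------
    (a, tau, a_stderr, tau_stderr)

    Raises
    ------
    FitError
        If the optimiser fails to converge; the exception message carries the
        series so it can be inspected.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2:
        raise FitError("exponential decay fit needs at least 2 points")

    x0 = float(x[0])

    # fitted as y = y0 * exp(-(x - x[0]) / tau): the amplitude at the first
    # abscissa is well conditioned even when tau -> 0 (a series that drops to
    # zero after its first point), where the a-parametrisation diverges
    def model(t, y0, tau):
        return y0 * np.exp(-(t - x0) / tau)

    try:
        popt, pcov = curve_fit(
            model, x, y,
            p0=[y[0] if y[0] != 0 else 1.0, 1.0],
            bounds=([-np.inf, 1e-9], [np.inf, np.inf]),
            xtol=_TOL, ftol=_TOL, gtol=_TOL, maxfev=_MAXFEV,
        )
    except RuntimeError as exc:  # pragma: no cover - scipy non-convergence
        raise FitError(f"exponential decay fit did not converge on series {y.tolist()}") from exc
    y0, tau = popt
    perr = np.sqrt(np.diag(pcov))
    scale = np.exp(min(x0 / tau, 700.0))
    a = y0 * scale
    a_err = perr[0] * scale
    return a, tau, a_err, perr[1]


def fit_saturating_exponential(rank, eta):
    """Fit ``eta(rank) = (eta0 - eta_inf) * exp(-rank / sr) + eta_inf``.

    Parametrised internally as ``(eta_inf, delta, sr)`` with
    ``delta = eta0 - eta_inf >= 0`` so the constraint ``eta_inf <= eta0`` is a
    simple box bound.  Initialisation: ``eta_inf = 1``,
    ``delta = eta[0] - 1``, ``sr = 1``; bounds ``eta_inf >= 1``,
    ``delta >= 0``, ``sr > 0``.

    Returns
    -------
    (eta0, eta_inf, sr, sr_stderr)
    """
    rank = np.asarray(rank, dtype=float)
    eta = np.asarray(eta, dtype=float)
    if rank.size < 3:
        raise FitError("rank-decay fit needs at least 3 ranks (3 parameters)")

    def model(r, eta_inf, delta, sr):
        return delta * np.exp(-r / sr) + eta_inf

    p0 = [1.0, max(eta[0] - 1.0, 1e-3), 1.0]
    try:
        popt, pcov = curve_fit(
            model, rank, eta,
            p0=p0,
            bounds=([1.0, 0.0, 1e-12], [np.inf, np.inf, np.inf]),
            xtol=_TOL, ftol=_TOL, gtol=_TOL, maxfev=_MAXFEV,
        )
    except RuntimeError as exc:  # pragma: no cover
        raise FitError(f"rank-decay fit did not converge on series {eta.tolist()}") from exc
    eta_inf, delta, sr = popt
    sr_stderr = float(np.sqrt(pcov[2, 2]))
    return eta_inf + delta, eta_inf, sr, sr_stderr
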