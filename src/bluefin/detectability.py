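"""Probability of automated detection as a smooth function of SNR.

Each manual annotation yields a binary outcome -- 1 if any automated
detection (at the chosen threshold) matched it, 0 otherwise -- paired with
its measured band-limited SNR.  Per site, outcomes are modelled by a
binomial GAM with a logit link: a penalized cubic B-spline smooth of SNR
(basis dimension 10), with the penalty weight chosen on a deterministic
log-spaced grid by AIC (deviance + 2 * effective df, the UBRE/GCV-family
criterion appropriate for a binomial family with known scale).

Confidence bands use the Bayesian posterior covariance of the penalized fit,
``(X' W X + lambda * S)^{-1}``, the interval construction with good
across-the-function coverage for penalized regression splines; intervals are
formed on the link scale and mapped through the inverse logit, so they always
lie in (0, 1).

Single-class sites (every annotation detected, or none) leave the logistic
fit degenerate; by default they are modelled as a constant detection
probability with a Jeffreys binomial interval and flagged, or can be made a
hard error.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.special import expit
from scipy.stats import beta as beta_dist
from statsmodels.gam.api import BSplines, GLMGam

#: Penalty weights scanned when smoothing is selected.
ALPHA_GRID = tuple(10.0 ** np.arange(-1, 7))

#: How far (dB) beyond the observed SNR range the smooth may be evaluated.
EXTRAPOLATION_DB = 5.0


@dataclass(frozen=True)
class DetectionOutcome:
    """One annotation's fate under the automated detector."""

    snr_db: float
    detected: int
    site: str = ""

    def __post_init__(self) -> None:
        if not np.isfinite(self.snr_db):
            raise ValueError("snr_db must be finite")
        if self.detected not in (0, 1):
            raise ValueError("detected must be 0 or 1")


@dataclass(frozen=True)
class MarginalCurve:
    """Detection probability vs SNR with a 95% confidence band."""

    snr_db: np.ndarray
    probability: np.ndarray
    lower: np.ndarray
    upper: np.ndarray
    site: str = ""


class DetectabilityFit:
    """Penalized binomial GAM of detection probability against SNR for one site."""

    degenerate = False

    def __init__(self, snr_db: np.ndarray, detected: np.ndarray, site: str = ""):
        self.site = site
        self.snr_db = np.asarray(snr_db, dtype=float)
        self.detected = np.asarray(detected, dtype=float)
        x = self.snr_db[:, None]
        self._smoother = BSplines(
            x,
            df=[10],
            degree=[3],
            knot_kwds=[
                {
                    "lower_bound": self.snr_db.min() - EXTRAPOLATION_DB,
                    "upper_bound": self.snr_db.max() + EXTRAPOLATION_DB,
                }
            ],
        )
        const = np.ones((len(self.detected), 1))
        best = None
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            for alpha in ALPHA_GRID:
                gam = GLMGam(
                    self.detected,
                    exog=const,
                    smoother=self._smoother,
                    family=sm.families.Binomial(),
                    alpha=alpha,
                )
                res = gam.fit()
                if best is None or res.aic < best[0]:
                    best = (res.aic, alpha, gam, res)
        _, self.alpha, gam, self.result = best
        # Bayesian posterior covariance of the penalized fit
        X = gam.exog
        mu = self.result.fittedvalues
        w = np.clip(mu * (1.0 - mu), 1e-12, None)
        S = gam.penal.penalty_matrix(alpha=[self.alpha])
        self._cov = np.linalg.inv((X * w[:, None]).T @ X + S)

    def _design(self, grid: np.ndarray) -> np.ndarray:
        return np.column_stack(
            [np.ones(len(grid)), self._smoother.transform(grid[:, None])]
        )

    def predict(self, grid: np.ndarray) -> np.ndarray:
        return expit(self._design(np.asarray(grid, dtype=float)) @ self.result.params)

    def curve(self, grid: np.ndarray) -> MarginalCurve:
        grid = np.asarray(grid, dtype=float)
        X = self._design(grid)
        eta = X @ self.result.params
        sd = np.sqrt(np.einsum("ij,jk,ik->i", X, self._cov, X))
        eps = 1e-12  # keep saturated links inside the open unit interval
        return MarginalCurve(
            snr_db=grid,
            probability=np.clip(expit(eta), eps, 1 - eps),
            lower=np.clip(expit(eta - 1.96 * sd), eps, 1 - eps),
            upper=np.clip(expit(eta + 1.96 * sd), eps, 1 - eps),
            site=self.site,
        )


class DegenerateDetectabilityFit:
    """Constant-probability model for a single-class site.

    Probability is the Jeffreys posterior mean ``(k + 0.5) / (n + 1)`` with a
    Jeffreys 95% interval, so all-detected data predicts > 0.95 for any
    reasonably sized sample while staying inside (0, 1).
    """

    degenerate = True

    def __init__(self, snr_db: np.ndarray, detected: np.ndarray, site: str = ""):
        self.site = site
        self.snr_db = np.asarray(snr_db, dtype=float)
        self.detected = np.asarray(detected, dtype=float)
        n = len(self.detected)
        k = float(self.detected.sum())
        self._p = (k + 0.5) / (n + 1.0)
        self._lo = float(beta_dist.ppf(0.025, k + 0.5, n - k + 0.5))
        self._hi = float(beta_dist.ppf(0.975, k + 0.5, n - k + 0.5))

    def predict(self, grid: np.ndarray) -> np.ndarray:
        return np.full(len(np.asarray(grid)), self._p)

    def curve(self, grid: np.ndarray) -> MarginalCurve:
        grid = np.asarray(grid, dtype=float)
        n = len(grid)
        eps = 1e-12
        return MarginalCurve(
            snr_db=grid,
            probability=np.full(n, self._p),
            lower=np.full(n, np.clip(self._lo, eps, 1 - eps)),
            upper=np.full(n, np.clip(self._hi, eps, 1 - eps)),
            site=self.site,
        )


def _to_frame(
    outcomes: Sequence[DetectionOutcome] | pd.DataFrame,
) -> pd.DataFrame:
    if isinstance(outcomes, pd.DataFrame):
        frame = outcomes[["snr_db", "detected"]].copy()
        frame["site"] = outcomes["site"] if "site" in outcomes else ""
        return frame
    return pd.DataFrame(
        {
            "snr_db": [o.snr_db for o in outcomes],
            "detected": [o.detected for o in outcomes],
            "site": [o.site for o in outcomes],
        }
    )


def fit_detectability(
    outcomes: Sequence[DetectionOutcome] | pd.DataFrame,
    min_outcomes: int = 30,
    on_degenerate: str = "fit",
) -> Mapping[str, DetectabilityFit | DegenerateDetectabilityFit]:
    """Fit the detectability GAM separately for each site.

    Parameters
    ----------
    outcomes:
        DetectionOutcome records or a DataFrame with columns
        ``snr_db, detected, site``.
    min_outcomes:
        Minimum outcomes per site; smaller sites raise.
    on_degenerate:
        ``"fit"`` (default) fits a flagged constant-probability model for
        single-class sites; ``"raise"`` raises a ValueError naming the site.

    Returns
    -------
    dict mapping site id to its fitted model.
    """
    if on_degenerate not in ("fit", "raise"):
        raise ValueError("on_degenerate must be 'fit' or 'raise'")
    frame = _to_frame(outcomes)
    fits: dict[str, DetectabilityFit | DegenerateDetectabilityFit] = {}
    for site, group in frame.groupby("site", sort=True):
        if len(group) < min_outcomes:
            raise ValueError(
                f"site {site!r} has only {len(group)} outcomes "
                f"(need >= {min_outcomes})"
            )
        snr = group["snr_db"].to_numpy(dtype=float)
        det = group["detected"].to_numpy(dtype=float)
        if det.min() == det.max():
            if on_degenerate == "raise":
                raise ValueError(
                    f"site {site!r} has single-class outcomes "
                    f"(all detected={int(det[0])}); cannot fit a logistic smooth"
                )
            warnings.warn(
                f"site {site!r} has single-class outcomes; using a "
                "constant-probability model",
                stacklevel=2,
            )
            fits[str(site)] = DegenerateDetectabilityFit(snr, det, site=str(site))
        else:
            fits[str(site)] = DetectabilityFit(snr, det, site=str(site))
    return fits


def marginal_curve(
    fit: DetectabilityFit | DegenerateDetectabilityFit,
    grid: Iterable[float],
) -> MarginalCurve:
    """Detection-probability curve with 95% CI on an SNR grid (dB).

    The grid must stay within ``EXTRAPOLATION_DB`` of the observed SNR range.
    """
    grid = np.asarray(list(grid), dtype=float)
    if grid.size == 0:
        raise ValueError("SNR grid is empty")
    lo = fit.snr_db.min() - EXTRAPOLATION_DB
    hi = fit.snr_db.max() + EXTRAPOLATION_DB
    if grid.min() < lo or grid.max() > hi:
        raise ValueError(
            f"grid extends beyond [{lo:.1f}, {hi:.1f}] dB, more than "
            f"{EXTRAPOLATION_DB} dB outside the observed SNR range"
        )
    return fit.curve(grid)
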