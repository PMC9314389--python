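"""Maximum-likelihood SCR fitting, confidence intervals and model ranking.

The central objects follow the familiar model/results split:
:class:`SpatialCaptureRecapture` is built from a detection history, a
detector array and a model code, and its :meth:`fit` returns a
:class:`ScrResults` carrying estimates, standard errors, confidence
intervals, AICc and convergence diagnostics.  ``fit_scr`` and
``fit_with_autobuffer`` are convenience wrappers; ``rank_models``
produces the AICc comparison table used for model selection.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import expit, logit
from statsmodels.tools.numdiff import approx_fprime, approx_hess

from .core import (
    MODEL_CODES,
    HabitatMask,
    _LikelihoodEngine,
    build_mask,
)
from .data import CaptHist, DetectorArray
from .exceptions import (
    InsufficientDataError,
    NotComparableError,
    ParameterError,
)

#: convergence thresholds on the link scale
GRAD_TOL = 1e-4
LOGL_RELTOL = 1e-8

Z_95 = 1.959963984540054  # standard normal 97.5% quantile


def aicc(loglik: float, K: int, n: int) -> float:
    """Akaike Information Criterion with small-sample correction.

    ``-2 logL + 2K + 2K(K+1) / (n - K - 1)``, with n the number of
    detected individuals (the sample-size convention used for SCR).
    """
    if n <= K + 1:
        raise ParameterError(
            f"AICc undefined for n={n} <= K+1={K + 1} (too few individuals)"
        )
    return -2.0 * loglik + 2.0 * K + 2.0 * K * (K + 1) / (n - K - 1)


def rpsv(capthist: CaptHist, detectors: DetectorArray) -> float:
    """Bias-corrected root pooled spatial variance of detection locations.

    Per-individual centroids of detection coordinates; squared deviations
    pooled over both coordinates and all individuals, divided by
    ``2 * (n_detections - n_individuals)`` (the bias correction: each
    centroid absorbs one degree of freedom).  A crude scale proxy for
    sigma, used only to seed the buffer iteration.
    """
    order = [detectors.index(s) for s in capthist.detector_ids]
    xy = detectors.xy[order]
    num = 0.0
    dof = 0
    for i in range(capthist.n_individuals):
        occ, det = np.nonzero(capthist.incidence[i])
        pts = xy[det]
        if len(pts) < 2:
            continue
        dev = pts - pts.mean(axis=0)
        num += float((dev ** 2).sum())
        dof += len(pts) - 1
    if dof == 0 or num == 0.0:
        raise InsufficientDataError(
            "no spatial spread in detections; sigma scale cannot be seeded"
        )
    return float(np.sqrt(num / (2.0 * dof)))


def _check_sufficient(capthist: CaptHist):
    if capthist.n_individuals < 2:
        raise InsufficientDataError(
            f"{capthist.n_individuals} detected individual(s); at least 2 "
            "are required for a density estimate"
        )
    if capthist.n_spatial_redetections() < 1:
        raise InsufficientDataError(
            "no individual was detected at >= 2 detectors; the spatial "
            "scale parameter is not estimable from these data"
        )


class SpatialCaptureRecapture:
    """Spatial capture-recapture model for one survey's detection history.

    Parameters
    ----------
    capthist : CaptHist
        Binary individuals x occasions x detectors history.
    detectors : DetectorArray
        Station coordinates (planar metres); must contain every detector
        in ``capthist``.
    model : str
        Baseline-encounter model code: "0", "b", "bk", "B", "Bk" or "T".
    mask : HabitatMask, optional
        Integration mask; built from ``buffer``/``spacing`` when omitted.
    buffer : float, metres
        Mask buffer width (required when ``mask`` is not given).
    spacing : float, metres, optional
        Mask grid spacing; defaults to buffer/16.

    Examples
    --------
    >>> scr = SpatialCaptureRecapture(ch, detectors, model="bk", buffer=2000)
    >>> res = scr.fit()
    >>> res.estimates.loc["D", "estimate"]
    """

    def __init__(
        self,
        capthist: CaptHist,
        detectors: DetectorArray,
        model: str = "0",
        mask: Optional[HabitatMask] = None,
        buffer: Optional[float] = None,
        spacing: Optional[float] = None,
    ):
        if model not in MODEL_CODES:
            raise ParameterError(
                f"unknown model code {model!r}; expected one of {MODEL_CODES}"
            )
        _check_sufficient(capthist)
        if mask is None:
            if buffer is None:
                raise ParameterError("either mask or buffer must be given")
            mask = build_mask(detectors, buffer=buffer, spacing=spacing)
        self.capthist = capthist
        self.detectors = detectors
        self.model_code = model
        self.mask = mask
        self._engine = _LikelihoodEngine(capthist, detectors, mask, model)

    # -------------------------------------------------------------- API
    @property
    def n_parameters(self) -> int:
        return self._engine.n_parameters

    @property
    def param_names(self):
        return self._engine.param_names()

    def loglike(self, theta) -> float:
        """Log-likelihood at link-scale parameters ``theta``."""
        return self._engine.loglik(theta)

    def start_params(self) -> np.ndarray:
        """Deterministic starting values on the link scale.

        D0 = n / mask area, g0_0 = 0.025, sigma0 = half the mean
        nearest-detector spacing, beta1_0 = 0.
        """
        n = self.capthist.n_individuals
        D0 = max(n, 1) / self.mask.area_km2
        nnd = self.detectors.nearest_neighbour_distances()
        nnd = nnd[np.isfinite(nnd)]
        sigma0 = 0.5 * float(nnd.mean()) if nnd.size else self.mask.buffer / 4.0
        return self._engine.pack(np.log(D0), float(logit(0.025)), 0.0, np.log(sigma0))

    def fit(self, start: Optional[np.ndarray] = None, multistart: bool = False) -> "ScrResults":
        """Maximise the likelihood; returns a :class:`ScrResults`.

        Optimisation runs on the link scale (log D, logit g0, log sigma)
        with BFGS, falling back to a Nelder-Mead polish when the gradient
        norm exceeds the tolerance.  ``multistart=True`` adds two extra
        starts with sigma0 halved/doubled and keeps the best optimum.
        """
        starts = [self.start_params() if start is None else np.asarray(start, float)]
        if multistart:
            for f in (np.log(0.5), np.log(2.0)):
                s = starts[0].copy()
                s[-1] += f
                starts.append(s)

        neg = lambda th: -self._engine.loglik(th)
        best = None
        for x0 in starts:
            res = minimize(neg, x0, method="BFGS",
                           options={"gtol": 1e-6, "maxiter": 500})
            if not np.isfinite(res.fun):
                continue
            if best is None or res.fun < best.fun - 1e-12:
                best = res
        if best is None:
            raise InsufficientDataError(
                "likelihood is degenerate at every starting value"
            )
        theta = best.x
        ll = -best.fun
        # polish with Nelder-Mead if the gradient is not yet flat
        grad = approx_fprime(theta, self._engine.loglik, centered=True)
        if np.linalg.norm(grad) > GRAD_TOL:
            nm = minimize(neg, theta, method="Nelder-Mead",
                          options={"xatol": 1e-8, "fatol": 1e-10, "maxiter": 4000})
            if np.isfinite(nm.fun) and nm.fun <= best.fun + LOGL_RELTOL * abs(best.fun):
                theta, ll = nm.x, -nm.fun
                grad = approx_fprime(theta, self._engine.loglik, centered=True)

        grad_norm = float(np.linalg.norm(grad))
        converged = bool(grad_norm < GRAD_TOL)
        if not converged:
            warnings.warn(
                f"model {self.model_code!r}: optimiser did not reach gradient "
                f"tolerance (|grad| = {grad_norm:.3g})", stacklevel=2,
            )

        cov = self._covariance(theta)
        return ScrResults(model=self, params=np.asarray(theta, float), cov=cov,
                          loglik=float(ll), converged=converged,
                          grad_norm=grad_norm, buffer_used=self.mask.buffer)

    def _covariance(self, theta) -> np.ndarray:
        """Inverse observed information on the link scale (NaN if singular)."""
        p = len(theta)
        try:
            H = approx_hess(np.asarray(theta, float), self._engine.loglik)
            cov = np.linalg.inv(-H)
            if not np.all(np.isfinite(cov)) or np.any(np.diag(cov) <= 0):
                raise np.linalg.LinAlgError
            return cov
        except np.linalg.LinAlgError:
            warnings.warn(
                "observed information is singular; standard errors undefined",
                stacklevel=2,
            )
            return np.full((p, p), np.nan)


class ScrResults:
    """Fitted SCR model: estimates, uncertainty, AICc and diagnostics.

    Attributes
    ----------
    params, cov : link-scale MLE and covariance.
    loglik : maximised log-likelihood.
    K : number of estimated parameters (3 for the null model, else 4).
    n : number of detected individuals.
    aicc : small-sample-corrected AIC.
    estimates : DataFrame indexed by D / g0 / sigma (/ beta1) with
        natural-scale estimates, SEs and 95% confidence limits.  The D
        interval is lognormal-based, ``D * exp(±z * sqrt(log(1+CV^2)))``
        (asymmetric, respecting D > 0); g0 and sigma are Wald on the link
        scale, back-transformed.
    """

    def __init__(self, model, params, cov, loglik, converged, grad_norm, buffer_used):
        self.model = model
        self.model_code = model.model_code
        self.params = params
        self.cov = cov
        self.loglik = loglik
        self.converged = converged
        self.grad_norm = grad_norm
        self.buffer_used = float(buffer_used)
        self.K = model.n_parameters
        self.n = model.capthist.n_individuals
        if self.n > self.K + 1:
            self.aicc = aicc(loglik, self.K, self.n)
        else:
            warnings.warn(
                f"AICc undefined for n={self.n} detected individuals with "
                f"K={self.K}; reported as NaN", stacklevel=2,
            )
            self.aicc = np.nan
        self.param_names = model.param_names
        self.estimates = self._build_estimates()

    # -- back-transformed table -----------------------------------------
    def _build_estimates(self) -> pd.DataFrame:
        eng = self.model._engine
        logD, b0, b1, logsig = eng.unpack(self.params)
        se_link = np.sqrt(np.diag(self.cov))
        names = self.param_names
        se = dict(zip(names, se_link))

        rows = {}
        D = float(np.exp(logD))
        seD_link = se["log(D)"]
        seD = D * seD_link if np.isfinite(seD_link) else np.nan
        if np.isfinite(seD):
            cv = seD / D
            w = np.exp(Z_95 * np.sqrt(np.log1p(cv ** 2)))
            rows["D"] = (D, seD, D / w, D * w)
        else:
            rows["D"] = (D, np.nan, np.nan, np.nan)

        g0 = float(expit(b0))
        se0 = se["beta0(g0)"]
        rows["g0"] = (
            g0,
            g0 * (1 - g0) * se0 if np.isfinite(se0) else np.nan,
            float(expit(b0 - Z_95 * se0)) if np.isfinite(se0) else np.nan,
            float(expit(b0 + Z_95 * se0)) if np.isfinite(se0) else np.nan,
        )

        sig = float(np.exp(logsig))
        ses = se["log(sigma)"]
        rows["sigma"] = (
            sig,
            sig * ses if np.isfinite(ses) else np.nan,
            sig * np.exp(-Z_95 * ses) if np.isfinite(ses) else np.nan,
            sig * np.exp(Z_95 * ses) if np.isfinite(ses) else np.nan,
        )

        if self.model_code != "0":
            name = f"beta1({self.model_code})"
            seb = se[name]
            rows["beta1"] = (
                b1, seb,
                b1 - Z_95 * seb if np.isfinite(seb) else np.nan,
                b1 + Z_95 * seb if np.isfinite(seb) else np.nan,
            )

        return pd.DataFrame.from_dict(
            rows, orient="index", columns=["estimate", "se", "lcl", "ucl"]
        )

    @property
    def density(self) -> float:
        """Estimated density, animals per km^2."""
        return float(self.estimates.loc["D", "estimate"])

    @property
    def density_ci(self) -> tuple[float, float]:
        return (
            float(self.estimates.loc["D", "lcl"]),
            float(self.estimates.loc["D", "ucl"]),
        )

    def summary(self) -> str:
        ch = self.model.capthist
        lines = [
            "Spatial capture-recapture fit",
            "=" * 64,
            f"model: {self.model_code}    detected individuals: {self.n}    "
            f"occasions: {ch.n_occasions}    detectors: {ch.n_detectors}",
            f"mask: {self.model.mask.n_points} cells, spacing "
            f"{self.model.mask.spacing:.0f} m, buffer {self.buffer_used:.0f} m",
            f"logL = {self.loglik:.4f}    K = {self.K}    AICc = {self.aicc:.3f}",
            f"converged: {self.converged} (|grad| = {self.grad_norm:.2e})",
            "",
            self.estimates.to_string(float_format=lambda v: f"{v:.6g}"),
            "",
            "D: animals per km^2 (lognormal 95% CI); sigma in metres.",
        ]
        return "\n".join(lines)

    def __repr__(self):
        return (
            f"<ScrResults model={self.model_code} D={self.density:.3f} "
            f"AICc={self.aicc:.2f} converged={self.converged}>"
        )


def fit_scr(
    capthist: CaptHist,
    detectors: DetectorArray,
    model_code: str = "0",
    buffer: float = None,
    spacing: Optional[float] = None,
    **fit_kwargs,
) -> ScrResults:
    """Fit one SCR model with a fixed mask buffer."""
    scr = SpatialCaptureRecapture(
        capthist, detectors, model=model_code, buffer=buffer, spacing=spacing
    )
    return scr.fit(**fit_kwargs)


def fit_with_autobuffer(
    capthist: CaptHist,
    detectors: DetectorArray,
    model_code: str = "0",
    spacing_fraction: float = 1.0 / 16.0,
    rel_tol: float = 0.05,
    max_iter: int = 5,
    **fit_kwargs,
) -> ScrResults:
    """Fit with the buffer iterated to 4 x the estimated sigma.

    The integration buffer should be wide relative to the movement scale
    (4 sigma leaves a negligible tail of the half-normal outside the
    mask), but sigma is unknown before fitting.  The initial buffer is
    4 x RPSV (a data-based sigma proxy); each refit sets the buffer to
    4 sigma-hat until it changes by less than ``rel_tol`` (5%) or
    ``max_iter`` fits have run, in which case the last fit is returned
    with its convergence flag cleared.
    """
    buffer = 4.0 * rpsv(capthist, detectors)
    fit = None
    for _ in range(max_iter):
        fit = fit_scr(
            capthist, detectors, model_code,
            buffer=buffer, spacing=buffer * spacing_fraction, **fit_kwargs,
        )
        new_buffer = 4.0 * float(fit.estimates.loc["sigma", "estimate"])
        if abs(new_buffer - buffer) / buffer < rel_tol:
            return fit
        buffer = new_buffer
    warnings.warn(
        f"buffer did not stabilise within {max_iter} iterations "
        f"(last = {buffer:.0f} m); returning last fit", stacklevel=2,
    )
    fit.converged = False
    return fit


def rank_models(fits: Sequence[ScrResults]) -> pd.DataFrame:
    """AICc comparison table for fits of one detection history.

    Sorted ascending by AICc (ties broken by smaller K); ``delta_aicc``
    is relative to the best model and ``substantial_support`` flags the
    top model when the runner-up's delta exceeds 2.
    """
    fits = list(fits)
    if not fits:
        raise NotComparableError("no fits to rank")
    ns = {f.n for f in fits}
    if len(ns) > 1:
        raise NotComparableError(
            f"fits have differing numbers of individuals {sorted(ns)}; "
            "AICc values are not comparable"
        )
    if any(np.isnan(f.aicc) for f in fits):
        warnings.warn("some fits have undefined AICc (n too small); "
                      "they are ranked last", stacklevel=2)
    fits.sort(key=lambda f: (np.isnan(f.aicc), f.aicc, f.K))
    best = fits[0].aicc
    df = pd.DataFrame(
        {
            "model": [f.model_code for f in fits],
            "K": [f.K for f in fits],
            "loglik": [f.loglik for f in fits],
            "aicc": [f.aicc for f in fits],
            "delta_aicc": [f.aicc - best for f in fits],
            "density": [f.density for f in fits],
            "converged": [f.converged for f in fits],
        }
    )
    df["substantial_support"] = False
    if len(df) > 1 and df.loc[1, "delta_aicc"] > 2.0:
        df.loc[0, "substantial_support"] = True
    return df
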