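"""Spatial capture-recapture probability machinery.

The model: animals have latent activity centres ``s`` distributed as a
homogeneous Poisson process with intensity D (animals per km^2).  A
proximity detector k records an animal with centre s on occasion t with
probability

    p(s, t, k) = g0(i, t, k) * exp(-d(k, s)^2 / (2 sigma^2))

the half-normal detection function, where ``g0`` is the baseline encounter
probability (logit link) optionally shifted by a behavioural or time
covariate, and ``sigma`` (metres) sets the spatial scale of detection.
The likelihood integrates over possible centres on a discretised habitat
mask (a regular grid of points within a buffer of the detectors; the sum
over cells times cell area is the midpoint-rule integral).

Six baseline-encounter models are supported, identified by the codes used
throughout the SCR literature:

====  =========================================================
code  effect on g0
====  =========================================================
0     constant (null)
b     learned response: shift after the individual's first
      detection anywhere, persisting to the end of the survey
bk    site-specific learned response: shift at detector k after
      the individual's first detection at k
B     transient response: shift iff detected anywhere on the
      previous occasion
Bk    site-specific transient response: shift at k iff detected
      at k on the previous occasion
T     linear-in-time trend on the logit of g0 (centred occasion
      index)
====  =========================================================

The full likelihood treats the number of detected individuals n as
Poisson with mean Lambda = D * sum_s pdot(s) * a, where pdot(s) is the
probability an animal centred at s is detected at least once.  Because a
behavioural response can only start after a first detection, pdot uses
the baseline (pre-response) encounter probability; under T it uses the
time-varying g0(t).  Each detected animal contributes the mask-integrated
probability of its full history.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.special import expit, gammaln, logsumexp, logit

from .data import CaptHist, DetectorArray
from .exceptions import MaskError, ParameterError

MODEL_CODES = ("0", "b", "bk", "B", "Bk", "T")

#: default mask granularity: grid spacing as a fraction of the buffer.
#: At the conventional 4*sigma buffer this is sigma/4, comfortably finer
#: than the usual "spacing below sigma" rule of thumb for mask error.
DEFAULT_SPACING_FRACTION = 1.0 / 16.0


def halfnormal_p(d, g0, sigma) -> np.ndarray:
    """Half-normal detection probability ``g0 * exp(-d^2 / (2 sigma^2))``.

    Parameters
    ----------
    d : array-like, metres, >= 0
    g0 : baseline encounter probability in [0, 1]
    sigma : spatial detection parameter, metres, > 0
    """
    d = np.asarray(d, dtype=float)
    if np.any(d < 0):
        raise ParameterError("distances must be non-negative")
    if sigma <= 0:
        raise ParameterError(f"sigma must be > 0, got {sigma}")
    g0 = float(g0)
    if not 0.0 <= g0 <= 1.0:
        raise ParameterError(f"g0 must lie in [0, 1], got {g0}")
    out = g0 * np.exp(-(d ** 2) / (2.0 * sigma ** 2))
    return out if out.shape else float(out)


@dataclass(frozen=True)
class HabitatMask:
    """Discretised integration region for activity centres.

    points : (S, 2) array of cell centres (metres); spacing : grid step
    (metres); cell_area : spacing^2 in km^2; buffer : the buffer width
    (metres) used to clip the grid around the detectors.
    """

    points: np.ndarray
    spacing: float
    buffer: float

    @property
    def n_points(self) -> int:
        return self.points.shape[0]

    @property
    def cell_area_km2(self) -> float:
        return (self.spacing / 1000.0) ** 2

    @property
    def area_km2(self) -> float:
        return self.n_points * self.cell_area_km2

    def distances_to(self, xy: np.ndarray) -> np.ndarray:
        """(len(xy), S) Euclidean distance matrix, metres."""
        xy = np.atleast_2d(xy)
        return np.hypot(
            xy[:, 0][:, None] - self.points[None, :, 0],
            xy[:, 1][:, None] - self.points[None, :, 1],
        )


def build_mask(
    detectors: DetectorArray, buffer: float, spacing: Optional[float] = None
) -> HabitatMask:
    """Regular-grid habitat mask clipped to within ``buffer`` of a detector.

    ``spacing`` defaults to ``buffer * DEFAULT_SPACING_FRACTION``.  Grid
    lines pass through cell centres offset by half a spacing from the
    buffered bounding box edge, and a point is kept iff its Euclidean
    distance to the nearest detector is at most ``buffer`` (trap-buffer
    clipping).
    """
    if buffer <= 0:
        raise ParameterError(f"buffer must be > 0, got {buffer}")
    if spacing is None:
        spacing = buffer * DEFAULT_SPACING_FRACTION
    if spacing <= 0:
        raise ParameterError(f"spacing must be > 0, got {spacing}")
    if spacing > buffer:
        raise MaskError(
            f"mask spacing {spacing} exceeds buffer {buffer}; grid too "
            "coarse to represent the buffered region"
        )
    xmin, ymin, xmax, ymax = detectors.bounding_box()
    xs = np.arange(xmin - buffer + spacing / 2.0, xmax + buffer, spacing)
    ys = np.arange(ymin - buffer + spacing / 2.0, ymax + buffer, spacing)
    gx, gy = np.meshgrid(xs, ys)
    pts = np.column_stack([gx.ravel(), gy.ravel()])
    d = np.hypot(
        pts[:, 0][:, None] - detectors.xy[None, :, 0],
        pts[:, 1][:, None] - detectors.xy[None, :, 1],
    ).min(axis=1)
    pts = pts[d <= buffer]
    if pts.shape[0] == 0:
        raise MaskError("habitat mask is empty")
    return HabitatMask(points=pts, spacing=float(spacing), buffer=float(buffer))


@dataclass(frozen=True)
class ScrModel:
    """One parameterisation of the SCR model (a point in parameter space).

    D : density (animals per km^2, log link); g0 : baseline encounter
    probability (logit link, via beta0); sigma : metres (log link);
    beta1 : logit-scale covariate coefficient (response or time trend),
    required for every code except "0".
    """

    code: str
    D: float
    g0: float
    sigma: float
    beta1: Optional[float] = None

    def __post_init__(self):
        if self.code not in MODEL_CODES:
            raise ParameterError(f"unknown model code {self.code!r}")
        if self.D <= 0:
            raise ParameterError("D must be > 0")
        if self.sigma <= 0:
            raise ParameterError("sigma must be > 0")
        if not 0.0 < self.g0 < 1.0:
            raise ParameterError("g0 must lie in (0, 1)")
        if self.code != "0" and self.beta1 is None:
            raise ParameterError(f"model {self.code!r} requires beta1")

    @property
    def beta0(self) -> float:
        return float(logit(self.g0))

    @property
    def n_parameters(self) -> int:
        return 3 if self.code == "0" else 4


@dataclass
class CovariateState:
    """Behavioural/time covariate derived from a detection history.

    ``z[i, t, k]`` is the binary response covariate for individual i,
    occasion t (1-based t folded to 0-based axis), detector k, computed
    solely from detections strictly before occasion t; ``u[t]`` is the
    centred, scaled occasion index used by the time-trend model.
    """

    code: str
    z: np.ndarray  # (n, T, K) uint8
    u: np.ndarray  # (T,)


def behaviour_covariate(capthist: CaptHist, code: str) -> CovariateState:
    """Compute the encounter covariate state implied by ``code``.

    b : detected anywhere before t; bk : detected at k before t;
    B : detected anywhere at t-1; Bk : detected at k at t-1;
    T : u(t) = (t - (T_occ + 1)/2) / T_occ; 0 : all-zero.
    """
    if code not in MODEL_CODES:
        raise ParameterError(f"unknown model code {code!r}")
    y = capthist.incidence.astype(bool)
    n, T, K = y.shape
    z = np.zeros((n, T, K), dtype=np.uint8)
    if n and T > 1:
        if code == "b":
            prior = np.cumsum(y.any(axis=2), axis=1)[:, :-1] > 0  # (n, T-1)
            z[:, 1:, :] = prior[:, :, None]
        elif code == "bk":
            prior = np.cumsum(y, axis=1)[:, :-1, :] > 0  # (n, T-1, K)
            z[:, 1:, :] = prior
        elif code == "B":
            z[:, 1:, :] = y.any(axis=2)[:, :-1, None]
        elif code == "Bk":
            z[:, 1:, :] = y[:, :-1, :]
    t = np.arange(1, T + 1, dtype=float)
    u = (t - (T + 1) / 2.0) / T
    return CovariateState(code=code, z=z, u=u)


class _LikelihoodEngine:
    """Precomputed quantities for repeated likelihood evaluation.

    For the binary-response codes the per-individual history probability
    factorises over (detector, covariate value, outcome), so occasions are
    collapsed into the count table ``c[i, k, z, y]`` once and each
    evaluation reduces to four (n x K) @ (K x S) products.  The time-trend
    code cannot collapse occasions; there the all-zero-history term is
    shared across individuals and corrected at the (few) detected cells.
    """

    def __init__(self, capthist: CaptHist, detectors: DetectorArray,
                 mask: HabitatMask, code: str):
        if code not in MODEL_CODES:
            raise ParameterError(f"unknown model code {code!r}")
        if mask.n_points == 0:
            raise MaskError("habitat mask is empty")
        for sid in capthist.detector_ids:
            if sid not in detectors:
                raise ParameterError(f"capthist detector {sid!r} unknown")
        self.code = code
        self.capthist = capthist
        self.mask = mask
        order = [detectors.index(sid) for sid in capthist.detector_ids]
        self.det_xy = detectors.xy[order]
        self.dist = mask.distances_to(self.det_xy)  # (K, S)
        self.n, self.T, self.K = capthist.incidence.shape

        usage = detectors.usage
        if usage is not None:
            if usage.shape[1] != self.T:
                raise ParameterError(
                    f"usage has {usage.shape[1]} occasions, capthist has {self.T}"
                )
            self.active = usage[order].T.astype(bool)  # (T, K)
        else:
            self.active = np.ones((self.T, self.K), dtype=bool)

        y = capthist.incidence.astype(bool)
        if np.any(y & ~self.active[None, :, :]):
            raise ParameterError("detection recorded at an inactive (occasion, detector)")

        cov = behaviour_covariate(capthist, code)
        self.u = cov.u
        if code != "T":
            # c[i, k, z, y]: number of active occasions with covariate z and outcome y
            act = self.active.T[None, :, :]  # (1, K, T)
            zz = cov.z.transpose(0, 2, 1).astype(bool)  # (n, K, T)
            yy = y.transpose(0, 2, 1)  # (n, K, T)
            c = np.empty((self.n, self.K, 2, 2), dtype=float)
            for zv in (0, 1):
                for yv in (0, 1):
                    m = ((zz == zv) & (yy == yv)) & act
                    c[:, :, zv, yv] = m.sum(axis=2)
            self.counts = c
            self.active_per_k = self.active.sum(axis=0).astype(float)  # (K,)
        else:
            self.det_cells = np.argwhere(y)  # rows (i, t, k)

    # -- parameter vector <-> named values ------------------------------
    @property
    def n_parameters(self) -> int:
        return 3 if self.code == "0" else 4

    def param_names(self):
        names = ["log(D)", "beta0(g0)", "log(sigma)"]
        if self.code != "0":
            names.insert(2, f"beta1({self.code})")
        return names

    def unpack(self, theta):
        theta = np.asarray(theta, dtype=float)
        if theta.shape != (self.n_parameters,):
            raise ParameterError(
                f"expected {self.n_parameters} parameters for model "
                f"{self.code!r}, got {theta.shape}"
            )
        if self.code == "0":
            logD, b0, logsig = theta
            b1 = 0.0
        else:
            logD, b0, b1, logsig = theta
        return logD, b0, b1, logsig

    def pack(self, logD, b0, b1, logsig):
        if self.code == "0":
            return np.array([logD, b0, logsig])
        return np.array([logD, b0, b1, logsig])

    # -- likelihood ------------------------------------------------------
    def loglik(self, theta) -> float:
        logD, b0, b1, logsig = self.unpack(theta)
        D = np.exp(logD)
        sigma = np.exp(logsig)
        a = self.mask.cell_area_km2
        logh = -(self.dist ** 2) / (2.0 * sigma ** 2)  # (K, S)

        with np.errstate(divide="ignore", invalid="ignore"):
            if self.code != "T":
                g = np.array([expit(b0), expit(b0 + b1)])
                # log p and log (1-p) per covariate level, (2, K, S)
                lp = np.log(g)[:, None, None] + logh[None, :, :]
                lq = np.log1p(-np.exp(lp))
                # detected-animal terms
                logPr = np.zeros((self.n, self.mask.n_points))
                for zv in (0, 1):
                    logPr += self.counts[:, :, zv, 1] @ lp[zv]
                    logPr += self.counts[:, :, zv, 0] @ lq[zv]
                # pdot from baseline (pre-response) probabilities
                log_surv = self.active_per_k @ lq[0]  # (S,)
            else:
                g_t = expit(b0 + b1 * self.u)  # (T,)
                # log(1 - p) summed over active (t, k) per mask point
                lq_tk = np.log1p(-g_t[:, None, None] * np.exp(logh)[None, :, :])
                lq_tk = np.where(self.active[:, :, None], lq_tk, 0.0)
                log_surv = lq_tk.sum(axis=(0, 1))  # (S,)
                logPr = np.tile(log_surv, (self.n, 1))
                for i, t, k in self.det_cells:
                    logPr[i] += (np.log(g_t[t]) + logh[k]) - lq_tk[t, k]

            pdot = -np.expm1(log_surv)  # 1 - exp(log_surv), (S,)
            Lam = D * a * float(pdot.sum())
            ll = -Lam - gammaln(self.n + 1)
            if self.n:
                per = logsumexp(logPr, axis=1)  # log sum_s Pr(omega_i | s)
                if np.any(np.isneginf(per)):
                    return -np.inf
                ll += self.n * np.log(D * a) + float(per.sum())
        if np.isnan(ll):
            return -np.inf
        return float(ll)


def scr_loglik(
    capthist: CaptHist,
    detectors: DetectorArray,
    mask: HabitatMask,
    model: ScrModel,
) -> float:
    """Full SCR log-likelihood of ``capthist`` under ``model``.

    Number of detected animals Poisson with mean
    ``Lambda = D * sum_s pdot(s) * cell_area`` (pdot from baseline
    encounter probabilities, time-varying under code "T"); each detected
    animal contributes ``log(D * cell_area * sum_s Pr(history | s))``.
    Returns ``-inf`` (not an exception) when a detection has probability
    zero under the parameters.
    """
    eng = _LikelihoodEngine(capthist, detectors, mask, model.code)
    theta = eng.pack(
        np.log(model.D), model.beta0,
        0.0 if model.beta1 is None else model.beta1,
        np.log(model.sigma),
    )
    return eng.loglik(theta)
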