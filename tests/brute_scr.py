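"""Independent brute-force SCR likelihood oracle.

Evaluates the full likelihood by explicit enumeration: Lambda is the
density times the mask-summed probability of *any* non-null history,
obtained by enumerating every binary outcome over occasions x detectors;
each detected animal's term sums its history probability, computed with
plain Python loops (covariates recomputed from scratch per outcome),
over mask cells.  Deliberately shares no code with the package's
vectorised engine; feasible only for tiny instances.
"""

import itertools
import math

from scipy.special import expit


def brute_loglik(capthist, detectors, mask, model):
    a = mask.cell_area_km2
    T, K = capthist.incidence.shape[1], capthist.incidence.shape[2]
    code = model.code
    b0 = model.beta0
    b1 = model.beta1 or 0.0
    sig = model.sigma
    order = [detectors.index(s) for s in capthist.detector_ids]
    dists = mask.distances_to(detectors.xy[order])

    def g0(t, z):
        if code == "T":
            u = (t + 1 - (T + 1) / 2.0) / T
            return expit(b0 + b1 * u)
        return expit(b0 + b1 * z)

    def z_of(hist, t, k):
        if code == "b":
            return int(any(hist[tt][kk] for tt in range(t) for kk in range(K)))
        if code == "bk":
            return int(any(hist[tt][k] for tt in range(t)))
        if code == "B":
            return int(t > 0 and any(hist[t - 1]))
        if code == "Bk":
            return int(t > 0 and hist[t - 1][k])
        return 0

    def pr_hist(hist, s):
        p = 1.0
        for t in range(T):
            for k in range(K):
                pk = g0(t, z_of(hist, t, k)) * math.exp(
                    -dists[k, s] ** 2 / (2.0 * sig * sig)
                )
                p *= pk if hist[t][k] else (1.0 - pk)
        return p

    lam = 0.0
    for s in range(mask.n_points):
        for bits in itertools.product((0, 1), repeat=T * K):
            if not any(bits):
                continue
            hist = [list(bits[t * K:(t + 1) * K]) for t in range(T)]
            lam += pr_hist(hist, s)
    lam *= model.D * a

    ll = -lam - math.lgamma(capthist.n_individuals + 1)
    for i in range(capthist.n_individuals):
        hist = [
            [int(capthist.incidence[i, t, k]) for k in range(K)] for t in range(T)
        ]
        ll += math.log(
            model.D * a * sum(pr_hist(hist, s) for s in range(mask.n_points))
        )
    return ll
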