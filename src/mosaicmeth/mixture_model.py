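"""Two-component Gaussian decomposition of the CpG-score distribution.

Every genome's CpG-score histogram is decomposed into exactly two normal
components by expectation-maximisation on the binned data (bin midpoints
weighted by bin counts). The decomposition is *compulsory*: two
components are returned even when the empirical distribution looks
unimodal, because the minor, high-score component then captures the
small unmethylated fraction (CpG islands) of a globally methylated
genome.

The decision threshold between putatively methylated and unmethylated
windows is the barycenter of the decomposition: the mixing-weight
weighted mean of the two component means, i.e. the center of mass of the
fitted density. An unweighted midpoint variant is available for
comparison.

EM details: deterministic initialisation by splitting the distribution
at its weighted median; convergence on relative log-likelihood change;
a variance floor prevents a component collapsing onto a single bin.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import norm

from .cpg_metrics import ScoreHistogram

__all__ = [
    "GaussianComponent",
    "MixtureFit",
    "fit_two_gaussians",
    "fit_two_gaussians_raw",
    "barycenter",
    "mixture_density",
]

VARIANCE_FLOOR = 1e-6
WEIGHT_COLLAPSE = 1e-4
DEFAULT_TOL = 1e-8
DEFAULT_MAX_ITER = 2000


@dataclass
class GaussianComponent:
    weight: float
    mean: float
    sd: float


@dataclass
class MixtureFit:
    """Two fitted components sorted by mean, plus convergence info.

    ``low`` (smaller mean) is the putatively methylated component,
    ``high`` the putatively unmethylated one.
    """

    low: GaussianComponent
    high: GaussianComponent
    log_likelihood: float
    n_iterations: int
    converged: bool
    boundary: float
    log_likelihood_history: list[float] = field(default_factory=list, repr=False)

    def to_dict(self) -> dict:
        return {
            "low": {"weight": self.low.weight, "mean": self.low.mean, "sd": self.low.sd},
            "high": {"weight": self.high.weight, "mean": self.high.mean, "sd": self.high.sd},
            "boundary": self.boundary,
            "log_likelihood": self.log_likelihood,
            "n_iterations": self.n_iterations,
            "converged": self.converged,
        }

    def to_json(self, path=None) -> str:
        text = json.dumps(self.to_dict(), indent=2)
        if path is not None:
            with open(path, "wt") as fh:
                fh.write(text + "\n")
        return text


def _weighted_median(x: np.ndarray, w: np.ndarray) -> float:
    order = np.argsort(x)
    cw = np.cumsum(w[order])
    return float(x[order][np.searchsorted(cw, 0.5 * cw[-1])])


def _log_mixture_pdf(x, weights, means, sds):
    # log sum_c w_c phi(x; mu_c, sd_c), stable via logsumexp over 2 comps
    log_comp = np.stack(
        [np.log(weights[c]) + norm.logpdf(x, means[c], sds[c]) for c in range(2)]
    )
    m = log_comp.max(axis=0)
    return m + np.log(np.exp(log_comp - m).sum(axis=0)), log_comp


def _em(
    x: np.ndarray,
    w: np.ndarray,
    tol: float,
    max_iter: int,
    barycenter_mode: str,
) -> MixtureFit:
    n = w.sum()
    # deterministic init: split at the weighted median
    med = _weighted_median(x, w)
    lo_mask = x <= med
    if not lo_mask.any() or lo_mask.all():
        # all support on one side of the median value; split by index instead
        half = len(x) // 2
        lo_mask = np.zeros(len(x), dtype=bool)
        lo_mask[:half] = True
    means = np.empty(2)
    sds = np.empty(2)
    for c, mask in enumerate((lo_mask, ~lo_mask)):
        ww = w[mask]
        means[c] = np.average(x[mask], weights=ww)
        var = np.average((x[mask] - means[c]) ** 2, weights=ww)
        sds[c] = math.sqrt(max(var, VARIANCE_FLOOR))
    weights = np.array([0.5, 0.5])

    ll_history: list[float] = []
    converged = False
    collapsed = False
    ll = -np.inf
    it = 0
    for it in range(1, max_iter + 1):
        log_pdf, log_comp = _log_mixture_pdf(x, weights, means, sds)
        new_ll = float(np.sum(w * log_pdf))
        if ll_history and new_ll < ll_history[-1] - 1e-9 * abs(ll_history[-1]):
            raise AssertionError(
                f"EM log-likelihood decreased at iteration {it}: {ll_history[-1]} -> {new_ll}"
            )
        ll_history.append(new_ll)
        if it > 1 and abs(new_ll - ll) <= tol * abs(ll):
            converged = True
            ll = new_ll
            break
        ll = new_ll
        # E-step
        resp = np.exp(log_comp - log_pdf)  # (2, n_bins)
        # M-step with bin multiplicities
        nk = (resp * w).sum(axis=1)
        if nk.min() / n < WEIGHT_COLLAPSE:
            collapsed = True
            break
        weights = nk / n
        means = (resp * w * x).sum(axis=1) / nk
        for c in range(2):
            var = float((resp[c] * w * (x - means[c]) ** 2).sum() / nk[c])
            sds[c] = math.sqrt(max(var, VARIANCE_FLOOR))

    if collapsed:
        warnings.warn(
            "a mixture component's weight collapsed below "
            f"{WEIGHT_COLLAPSE}; returning the last parameters as non-converged",
            RuntimeWarning,
        )
        converged = False

    order = np.argsort(means)
    comps = [
        GaussianComponent(float(weights[c]), float(means[c]), float(sds[c])) for c in order
    ]
    fit = MixtureFit(
        low=comps[0],
        high=comps[1],
        log_likelihood=float(ll_history[-1]),
        n_iterations=it,
        converged=converged,
        boundary=math.nan,
        log_likelihood_history=ll_history,
    )
    fit.boundary = barycenter(fit, mode=barycenter_mode)
    return fit


def fit_two_gaussians(
    hist: ScoreHistogram,
    tol: float = DEFAULT_TOL,
    max_iter: int = DEFAULT_MAX_ITER,
    barycenter_mode: str = "weighted",
) -> MixtureFit:
    """Fit two Gaussians to a binned score distribution by EM.

    The likelihood treats each bin midpoint as a data point with the bin
    count as multiplicity, so the fit is invariant to rescaling all
    counts by a common factor. Raises on a distribution concentrated in
    fewer than two bins ("degenerate distribution").
    """
    counts = np.asarray(hist.counts, dtype=np.float64)
    nonempty = counts > 0
    if nonempty.sum() < 2:
        raise ValueError("degenerate distribution: fewer than 2 nonempty bins")
    if hist.n_windows < 100:
        warnings.warn(
            f"only {hist.n_windows} windows in histogram; fit may be unstable",
            RuntimeWarning,
        )
    x = hist.midpoints[nonempty]
    w = counts[nonempty]
    return _em(x, w, tol=tol, max_iter=max_iter, barycenter_mode=barycenter_mode)


def fit_two_gaussians_raw(
    scores,
    tol: float = DEFAULT_TOL,
    max_iter: int = DEFAULT_MAX_ITER,
    barycenter_mode: str = "weighted",
) -> MixtureFit:
    """EM on raw per-window scores (cross-check for the binned fit)."""
    scores = np.asarray(scores, dtype=np.float64)
    if np.unique(scores).size < 2:
        raise ValueError("degenerate distribution: fewer than 2 distinct scores")
    x, w = np.unique(scores, return_counts=True)
    return _em(x, w.astype(np.float64), tol=tol, max_iter=max_iter, barycenter_mode=barycenter_mode)


def barycenter(fit: MixtureFit, mode: str = "weighted") -> float:
    """Decision boundary between the two components.

    ``"weighted"`` (default): center of mass, ``w_lo*mu_lo + w_hi*mu_hi``.
    ``"midpoint"``: unweighted mean of the two component means.
    """
    if mode == "weighted":
        return fit.low.weight * fit.low.mean + fit.high.weight * fit.high.mean
    if mode == "midpoint":
        return 0.5 * (fit.low.mean + fit.high.mean)
    raise ValueError(f"unknown barycenter mode {mode!r}")


def mixture_density(fit: MixtureFit, x) -> np.ndarray:
    """Merged two-component density w1*phi1(x) + w2*phi2(x)."""
    x = np.asarray(x, dtype=np.float64)
    return fit.low.weight * norm.pdf(x, fit.low.mean, fit.low.sd) + fit.high.weight * norm.pdf(
        x, fit.high.mean, fit.high.sd
    )
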