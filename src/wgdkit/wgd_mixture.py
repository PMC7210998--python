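"""Univariate normal mixtures for dating duplication waves.

The corrected 4DTv distribution of paralog pairs is modelled as a mixture
of k normal components; expectation-maximisation is run from several
k-means++-style seeded starts, the component count and the equal- vs
unequal-variance family are selected by minimising

    BIC = -2 loglik + p ln n,   p = (k-1) + k + 1 (equal) or (k-1) + 2k,

and components are classified into small-scale-duplication (SSD) versus
WGD peaks by a mean threshold (the SSD peak of a 4DTv distribution sits
near zero, far below the oldest WGD waves).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np
from numba import njit

SD_FLOOR = 1e-4

_LOG_SQRT_2PI = 0.5 * np.log(2 * np.pi)


@njit(cache=True, fastmath=False)
def _em_core(x, means, sds, weights, equal_variance, tol, max_iter):
    """EM iterations for a 1-D normal mixture; returns the loglik trace."""
    n = x.shape[0]
    k = means.shape[0]
    history = np.empty(max_iter)
    log_w = np.log(weights)
    loglik = -np.inf
    n_iter = 0
    nk = np.empty(k)
    sum_x = np.empty(k)
    sum_sq = np.empty(k)
    logp = np.empty(k)
    for it in range(max_iter):
        for j in range(k):
            nk[j] = 0.0
            sum_x[j] = 0.0
            sum_sq[j] = 0.0
        new_loglik = 0.0
        for i in range(n):
            m = -1e308
            for j in range(k):
                z = (x[i] - means[j]) / sds[j]
                logp[j] = log_w[j] - np.log(sds[j]) - 0.5 * z * z - 0.9189385332046727
                if logp[j] > m:
                    m = logp[j]
            s = 0.0
            for j in range(k):
                logp[j] = np.exp(logp[j] - m)
                s += logp[j]
            new_loglik += m + np.log(s)
            for j in range(k):
                r = logp[j] / s
                nk[j] += r
                sum_x[j] += r * x[i]
                sum_sq[j] += r * x[i] * x[i]
        history[it] = new_loglik
        for j in range(k):
            means[j] = sum_x[j] / (nk[j] + 1e-300)
            sum_sq[j] = sum_sq[j] - nk[j] * means[j] * means[j]
            if sum_sq[j] < 0.0:
                sum_sq[j] = 0.0
        n_iter = it + 1
        if equal_variance:
            total = 0.0
            for j in range(k):
                total += sum_sq[j]
            sd = np.sqrt(total / n)
            if sd < 1e-4:
                sd = 1e-4
            for j in range(k):
                sds[j] = sd
        else:
            for j in range(k):
                sd = np.sqrt(sum_sq[j] / (nk[j] + 1e-300))
                if sd < 1e-4:
                    sd = 1e-4
                sds[j] = sd
        for j in range(k):
            weights[j] = nk[j] / n
            log_w[j] = np.log(weights[j] + 1e-300)
        if np.isfinite(loglik) and new_loglik - loglik < tol * (1.0 + abs(new_loglik)):
            loglik = new_loglik
            break
        loglik = new_loglik
    return weights, means, sds, loglik, history[:n_iter]


@dataclass(frozen=True)
class NormalMixtureModel:
    k: int
    weights: Tuple[float, ...]
    means: Tuple[float, ...]
    sds: Tuple[float, ...]
    loglik: float
    bic: float
    variance_mode: str  # "equal" | "unequal"
    n: int
    seed: int

    def n_parameters(self) -> int:
        if self.variance_mode == "equal":
            return (self.k - 1) + self.k + 1
        return (self.k - 1) + 2 * self.k

    def component_logpdf(self, values: np.ndarray) -> np.ndarray:
        """(n, k) matrix of log w_j + log N(x | mu_j, sd_j)."""
        x = np.asarray(values, dtype=float)[:, None]
        mu = np.asarray(self.means)[None, :]
        sd = np.asarray(self.sds)[None, :]
        w = np.asarray(self.weights)[None, :]
        return (
            np.log(w)
            - 0.5 * np.log(2 * np.pi)
            - np.log(sd)
            - 0.5 * ((x - mu) / sd) ** 2
        )


@dataclass(frozen=True)
class WGDPeakReport:
    """Mixture components split into SSD and WGD peaks, each (mean, sd, weight)."""

    ssd_peaks: Tuple[Tuple[float, float, float], ...]
    wgd_peaks: Tuple[Tuple[float, float, float], ...]

    @property
    def n_wgd(self) -> int:
        return len(self.wgd_peaks)


def _kmeanspp_centers(x: np.ndarray, k: int, rng: np.random.Generator) -> np.ndarray:
    centers = [x[rng.integers(len(x))]]
    for _ in range(k - 1):
        d2 = np.min((x[:, None] - np.array(centers)[None, :]) ** 2, axis=1)
        total = d2.sum()
        if total <= 0:
            centers.append(x[rng.integers(len(x))])
            continue
        centers.append(x[rng.choice(len(x), p=d2 / total)])
    return np.array(centers)


def _em_once(
    x: np.ndarray,
    k: int,
    equal_variance: bool,
    rng: np.random.Generator,
    tol: float,
    max_iter: int,
) -> Tuple[np.ndarray, np.ndarray, np.ndarray, float, List[float]]:
    n = len(x)
    means = np.sort(_kmeanspp_centers(x, k, rng))
    global_sd = max(float(x.std()), SD_FLOOR)
    sds = np.full(k, max(global_sd / k, SD_FLOOR))
    weights = np.full(k, 1.0 / k)

    weights, means, sds, loglik, history = _em_core(
        np.ascontiguousarray(x, dtype=np.float64),
        means.astype(np.float64),
        sds.astype(np.float64),
        weights.astype(np.float64),
        equal_variance,
        tol,
        max_iter,
    )
    return weights, means, sds, float(loglik), list(history)


def fit_normal_mixture(
    values: Sequence[float],
    k: int,
    variance_mode: str = "unequal",
    n_restarts: int = 20,
    seed: int = 0,
    tol: float = 1e-7,
    max_iter: int = 500,
    return_history: bool = False,
):
    """Fit a k-component univariate normal mixture by restarted EM.

    The best-log-likelihood restart is returned with components sorted by
    mean; standard deviations are floored at 1e-4 so degenerate spikes
    cannot absorb single points.  Deterministic under ``seed``.
    """
    x = np.asarray(values, dtype=float)
    if x.ndim != 1 or not np.all(np.isfinite(x)):
        raise ValueError("values must be a 1-D finite array")
    if len(x) <= k:
        raise ValueError(f"need more than k={k} observations, got {len(x)}")
    if float(x.std()) == 0.0:
        raise ValueError("all values identical: zero variance")
    if variance_mode not in ("equal", "unequal"):
        raise ValueError("variance_mode must be 'equal' or 'unequal'")

    rng = np.random.default_rng(seed)
    best = None
    best_history = None
    for _ in range(max(n_restarts, 1)):
        result = _em_once(x, k, variance_mode == "equal", rng, tol, max_iter)
        if best is None or result[3] > best[3]:
            best = result
            best_history = result[4]
    weights, means, sds, loglik, _ = best
    order = np.argsort(means)
    p = (k - 1) + k + 1 if variance_mode == "equal" else (k - 1) + 2 * k
    model = NormalMixtureModel(
        k=k,
        weights=tuple(float(w) for w in weights[order]),
        means=tuple(float(m) for m in means[order]),
        sds=tuple(float(s) for s in sds[order]),
        loglik=loglik,
        bic=-2.0 * loglik + p * np.log(len(x)),
        variance_mode=variance_mode,
        n=len(x),
        seed=seed,
    )
    if return_history:
        return model, best_history
    return model


def select_model_bic(
    values: Sequence[float],
    k_range: Sequence[int] = range(1, 9),
    variance_modes: Sequence[str] = ("equal", "unequal"),
    seed: int = 0,
    n_restarts: int = 3,
    tol: float = 1e-7,
    max_iter: int = 200,
) -> NormalMixtureModel:
    """Fit every (k, variance mode) pair and return the minimum-BIC model.

    The sweep uses fewer restarts and a tighter iteration cap than a single
    :func:`fit_normal_mixture` call: under-converged over-parameterised fits
    only lose likelihood, which the BIC penalty already disfavours.

    Ties break toward smaller k, then toward equal variance (the iteration
    order).  Individual fit failures are skipped with a warning.
    """
    best: Optional[NormalMixtureModel] = None
    for k in sorted(k_range):
        for mode in variance_modes:
            try:
                model = fit_normal_mixture(
                    values, k, variance_mode=mode,
                    n_restarts=1 if k == 1 else n_restarts,
                    seed=seed + 1009 * k, tol=tol, max_iter=max_iter,
                )
            except ValueError as exc:
                warnings.warn(f"mixture fit k={k} mode={mode} failed: {exc}")
                continue
            if best is None or model.bic < best.bic:
                best = model
    if best is None:
        raise ValueError("every mixture fit failed")
    return best


def classify_wgd_peaks(
    model: NormalMixtureModel, ssd_mean_threshold: float = 0.1
) -> WGDPeakReport:
    """Split mixture components into SSD (mean below threshold) and WGD peaks."""
    if model is None or model.k == 0:
        raise ValueError("cannot classify an empty model")
    ssd, wgd = [], []
    for w, m, s in zip(model.weights, model.means, model.sds):
        (ssd if m < ssd_mean_threshold else wgd).append((m, s, w))
    ssd.sort()
    wgd.sort()
    return WGDPeakReport(ssd_peaks=tuple(ssd), wgd_peaks=tuple(wgd))


def plot_mixture(values: Sequence[float], model: NormalMixtureModel, path) -> None:
    """Histogram of corrected 4DTv values with the fitted component curves."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    x = np.asarray(values, dtype=float)
    grid = np.linspace(x.min(), x.max(), 400)
    fig, ax = plt.subplots(figsize=(7, 4))
    ax.hist(x, bins=60, density=True, color="lightgrey", edgecolor="none")
    dens = np.exp(model.component_logpdf(grid))
    for j in range(model.k):
        ax.plot(grid, dens[:, j], label=f"mean {model.means[j]:.2f}")
    ax.plot(grid, dens.sum(axis=1), "k--", label="mixture")
    ax.set_xlabel("corrected 4DTv")
    ax.set_ylabel("density")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
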