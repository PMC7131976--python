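"""Finite von Mises mixtures for pointing directions.

Pointing directions pooled over participants for one origin->target trial
are modeled as a one- or two-component von Mises mixture on the circle.
Maximum-likelihood fits come from expectation-maximization with random
restarts; one versus two modes is decided by BIC, guarded by a minimum
component weight and a minimum separation between mode directions, so that
a shoulder or a few strays are not called a second mode. When a trial is
bimodal, the mode farther from the correct target direction is labeled the
systematic mode -- the signature of a distorted environment representation
rather than of noisy pointing.

Angles enter and leave in azimuth degrees; radians are internal.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.special import i0e, i1e, logsumexp

from .geometry import angular_error, normalize_azimuth, signed_angle_difference

__all__ = [
    "MixtureConfig",
    "MixtureComponent",
    "MixtureFit",
    "ConfidenceSector",
    "fit_vonmises_mixture",
    "select_modality",
    "mode_confidence_sector",
    "label_systematic_mode",
    "per_target_error_summary",
    "vonmises_mixture_logpdf",
]


@dataclass(frozen=True)
class MixtureConfig:
    """Tunable knobs of mixture fitting and modality selection.

    ``w_min`` and ``s_min`` implement the guard rails on calling a trial
    bimodal: both components must carry at least ``w_min`` of the mass and
    their mean directions must lie at least ``s_min`` degrees apart.
    """

    restarts: int = 20
    tol: float = 1e-8           # EM stop: log-likelihood gain per step
    max_iter: int = 500
    kappa_cap: float = 500.0    # near-degenerate clusters cap here
    w_min: float = 0.15
    s_min: float = 30.0         # degrees
    bootstrap_B: int = 1000


@dataclass(frozen=True)
class MixtureComponent:
    weight: float
    mean_deg: float
    kappa: float


@dataclass(frozen=True)
class ConfidenceSector:
    """Bootstrap percentile arc for one component's mean direction."""

    lo_deg: float     # arc start (azimuth); arc runs clockwise lo -> hi
    hi_deg: float
    width_deg: float
    level: float

    def contains(self, azimuth: float) -> bool:
        span = (self.hi_deg - self.lo_deg) % 360.0
        return (azimuth - self.lo_deg) % 360.0 <= span + 1e-9


@dataclass(frozen=True)
class MixtureFit:
    """A fitted von Mises mixture for one pointing trial."""

    k: int
    components: tuple[MixtureComponent, ...]
    log_likelihood: float
    bic: float
    n: int
    ll_trace: tuple[float, ...] = ()
    trial: tuple[int, int] | None = None
    verdict: str | None = None            # "unimodal" | "bimodal"
    sectors: tuple[ConfidenceSector, ...] | None = None
    systematic_index: int | None = None

    @property
    def weights(self) -> tuple[float, ...]:
        return tuple(c.weight for c in self.components)

    @property
    def means_deg(self) -> tuple[float, ...]:
        return tuple(c.mean_deg for c in self.components)

    @property
    def separation_deg(self) -> float:
        """Angular distance between the two mode directions (0 for K=1)."""
        if self.k == 1:
            return 0.0
        return angular_error(self.components[0].mean_deg,
                             self.components[1].mean_deg)

    def to_dict(self) -> dict:
        return {
            "trial": list(self.trial) if self.trial else None,
            "k": self.k,
            "n": self.n,
            "components": [
                {"weight": c.weight, "mean_deg": c.mean_deg, "kappa": c.kappa}
                for c in self.components
            ],
            "log_likelihood": self.log_likelihood,
            "bic": self.bic,
            "verdict": self.verdict,
            "systematic_index": self.systematic_index,
            "sectors": [
                {"lo_deg": s.lo_deg, "hi_deg": s.hi_deg,
                 "width_deg": s.width_deg, "level": s.level}
                for s in self.sectors
            ] if self.sectors is not None else None,
        }


# ---------------------------------------------------------------------------
# von Mises basics
# ---------------------------------------------------------------------------

def _log_i0(kappa: np.ndarray) -> np.ndarray:
    # i0e(k) = I0(k) * exp(-k), stable for large concentrations
    return np.log(i0e(kappa)) + kappa


def _vm_logpdf(theta: np.ndarray, mu: float, kappa: float) -> np.ndarray:
    return kappa * np.cos(theta - mu) - np.log(2 * np.pi) - _log_i0(np.asarray(kappa))


def vonmises_mixture_logpdf(theta_rad: np.ndarray,
                            fit: MixtureFit) -> np.ndarray:
    """Mixture log-density at angles in radians."""
    theta = np.asarray(theta_rad, dtype=float)
    parts = [np.log(c.weight) + _vm_logpdf(theta, np.radians(c.mean_deg), c.kappa)
             for c in fit.components]
    return logsumexp(np.stack(parts), axis=0)


def _kappa_from_rbar(rbar, cap: float):
    """Best-Fisher approximation to the ML concentration A1^-1(rbar)."""
    r = np.clip(np.asarray(rbar, dtype=float), 0.0, 1.0 - 1e-12)
    k = np.where(
        r < 0.53,
        2 * r + r**3 + 5 * r**5 / 6,
        np.where(r < 0.85,
                 -0.4 + 1.39 * r + 0.43 / np.maximum(1 - r, 1e-12),
                 1.0 / np.maximum(r**3 - 4 * r**2 + 3 * r, 1e-12)),
    )
    # Newton refinement on A1(kappa) = I1/I0 = rbar; the closed form alone
    # is approximate enough to break the EM ascent property near convergence
    k = np.maximum(k, 1e-8)
    with np.errstate(divide="ignore", invalid="ignore"):
        for _ in range(3):
            a1 = i1e(k) / i0e(k)
            da1 = 1.0 - a1 / k - a1 * a1
            step = np.where(np.abs(da1) > 1e-14, (r - a1) / da1, 0.0)
            k = np.clip(k + step, 1e-8, cap)
    out = np.where(np.asarray(rbar) >= 1.0 - 1e-12, cap, k)
    return float(out) if np.isscalar(rbar) else out


def _weighted_vm_mle(theta: np.ndarray, w: np.ndarray,
                     cap: float) -> tuple[float, float]:
    """Weighted mean direction and concentration."""
    wsum = w.sum()
    c = float(np.dot(w, np.cos(theta))) / wsum
    s = float(np.dot(w, np.sin(theta))) / wsum
    mu = float(np.arctan2(s, c))
    rbar = float(np.hypot(c, s))
    return mu, _kappa_from_rbar(rbar, cap)


# ---------------------------------------------------------------------------
# Fitting
# ---------------------------------------------------------------------------

def _fit_k1(theta: np.ndarray, cap: float) -> tuple[list, float, list[float]]:
    mu, kappa = _weighted_vm_mle(theta, np.ones_like(theta), cap)
    ll = float(_vm_logpdf(theta, mu, kappa).sum())
    return [(1.0, mu, kappa)], ll, [ll]


def _em_k2(theta: np.ndarray, init_mu: np.ndarray, init_kappa: np.ndarray,
           init_w: np.ndarray, config: MixtureConfig) -> tuple[list, float, list[float]]:
    """Two-component EM, run for a whole batch of restarts at once.

    ``init_mu``, ``init_kappa``, ``init_w`` have shape (R, 2) for R
    restarts; every restart is advanced in lock step until all have
    converged. Returns the best restart's components, log-likelihood and
    per-iteration log-likelihood trace.
    """
    mu = np.atleast_2d(init_mu).astype(float).copy()       # (R, 2)
    kappa = np.atleast_2d(init_kappa).astype(float).copy()
    w = np.atleast_2d(init_w).astype(float).copy()
    n = len(theta)
    cos_t, sin_t = np.cos(theta), np.sin(theta)            # (n,)
    traces: list[np.ndarray] = []
    ll = np.full(mu.shape[0], -np.inf)
    for _ in range(config.max_iter):
        # E-step: log responsibilities, (R, 2, n)
        cos_dev = (np.cos(mu)[:, :, None] * cos_t
                   + np.sin(mu)[:, :, None] * sin_t)
        log_r = (np.log(np.maximum(w, 1e-300))[:, :, None]
                 + kappa[:, :, None] * cos_dev
                 - np.log(2 * np.pi) - _log_i0(kappa)[:, :, None])
        norm = logsumexp(log_r, axis=1)                    # (R, n)
        new_ll = norm.sum(axis=1)                          # (R,)
        traces.append(new_ll)
        resp = np.exp(log_r - norm[:, None, :])
        # M-step
        nk = np.maximum(resp.sum(axis=2), 1e-12)           # (R, 2)
        w = nk / n
        c = resp @ cos_t                                   # (R, 2)
        s = resp @ sin_t
        mu = np.arctan2(s, c)
        kappa = _kappa_from_rbar(np.hypot(c, s) / nk, config.kappa_cap)
        done = np.all(np.isfinite(ll) & (new_ll - ll < config.tol))
        ll = new_ll
        if done:
            break
    best = int(np.argmax(ll))
    comps = [(float(w[best, j]), float(mu[best, j]), float(kappa[best, j]))
             for j in range(2)]
    trace = [float(t[best]) for t in traces]
    return comps, float(ll[best]), trace


def fit_vonmises_mixture(angles_deg, k: int, restarts: int | None = None,
                         seed: int = 0,
                         config: MixtureConfig | None = None,
                         trial: tuple[int, int] | None = None,
                         init: MixtureFit | None = None) -> MixtureFit:
    """Maximum-likelihood von Mises mixture with ``k`` in {1, 2}.

    K=1 has a closed-form solution. K=2 runs EM from ``restarts`` random
    initializations (component means drawn from the data, deterministic for
    a given ``seed``) and keeps the best log-likelihood. ``init`` warm-starts
    a single EM run from an existing fit instead (used by the bootstrap).

    Near-degenerate clusters hit the configured concentration cap
    (a warning is emitted); the EM log-likelihood trace is retained on the
    returned fit so monotonicity is checkable.
    """
    config = config or MixtureConfig()
    if restarts is None:
        restarts = config.restarts
    if k not in (1, 2):
        raise ValueError("k must be 1 or 2")
    angles = np.asarray(angles_deg, dtype=float)
    if angles.ndim != 1 or len(angles) < 5 * k:
        raise ValueError(f"need at least {5 * k} angles for k={k}, "
                         f"got {len(angles)}")
    theta = np.radians(angles % 360.0)

    if k == 1:
        comps, ll, trace = _fit_k1(theta, config.kappa_cap)
    elif init is not None:
        mu0 = np.radians([[c.mean_deg for c in init.components]])
        k0 = np.array([[c.kappa for c in init.components]])
        w0 = np.array([[c.weight for c in init.components]])
        comps, ll, trace = _em_k2(theta, mu0, k0, w0, config)
    else:
        rng = np.random.default_rng(seed)
        n_restarts = max(1, restarts)
        # component means seeded from the data itself: rotation-equivariant
        idx = np.stack([rng.choice(len(theta), size=2, replace=False)
                        for _ in range(n_restarts)])
        comps, ll, trace = _em_k2(
            theta, theta[idx], np.full((n_restarts, 2), 2.0),
            np.full((n_restarts, 2), 0.5), config)

    if any(c[2] >= config.kappa_cap - 1e-9 for c in comps):
        warnings.warn("concentration reached cap; near-degenerate cluster",
                      RuntimeWarning, stacklevel=2)
    n_params = 2 if k == 1 else 5
    bic = float(-2 * ll + n_params * np.log(len(theta)))
    components = tuple(
        MixtureComponent(weight=w_, mean_deg=normalize_azimuth(np.degrees(mu_)),
                         kappa=k_)
        for w_, mu_, k_ in comps
    )
    return MixtureFit(k=k, components=components, log_likelihood=ll, bic=bic,
                      n=len(theta), ll_trace=tuple(trace), trial=trial)


def select_modality(angles_deg, config: MixtureConfig | None = None,
                    seed: int = 0,
                    trial: tuple[int, int] | None = None) -> MixtureFit:
    """Decide unimodal versus bimodal for one trial's pooled directions.

    Fits both K=1 and K=2; the trial is declared bimodal only when the
    two-component fit wins on BIC *and* both weights reach ``w_min`` *and*
    the mode directions are at least ``s_min`` degrees apart. The returned
    fit is the selected model with its ``verdict`` field set.
    """
    config = config or MixtureConfig()
    angles = np.asarray(angles_deg, dtype=float)
    if len(angles) < 10:
        raise ValueError("need at least 10 angles to assess modality")
    fit1 = fit_vonmises_mixture(angles, 1, config=config, trial=trial)
    fit2 = fit_vonmises_mixture(angles, 2, seed=seed, config=config, trial=trial)
    bimodal = (
        fit2.bic < fit1.bic
        and min(fit2.weights) >= config.w_min
        and fit2.separation_deg >= config.s_min
    )
    chosen = fit2 if bimodal else fit1
    return replace(chosen, verdict="bimodal" if bimodal else "unimodal")


# ---------------------------------------------------------------------------
# Bootstrap confidence sectors
# ---------------------------------------------------------------------------

def mode_confidence_sector(angles_deg, fit: MixtureFit, level: float = 0.95,
                           B: int | None = None, seed: int = 0,
                           config: MixtureConfig | None = None) -> tuple[ConfidenceSector, ...]:
    """Percentile-bootstrap arcs for each component's mean direction.

    Resamples the angles with replacement, refits warm-started from ``fit``
    (components matched back to the original by nearest mean direction), and
    takes circular percentiles of the mean-direction deviations. Each arc is
    widened, if necessary, to contain its point estimate.
    """
    config = config or MixtureConfig()
    if B is None:
        B = config.bootstrap_B
    if B < 100:
        raise ValueError("need at least 100 bootstrap resamples")
    angles = np.asarray(angles_deg, dtype=float)
    rng = np.random.default_rng(seed)
    devs: list[list[float]] = [[] for _ in fit.components]
    fast = replace(config, max_iter=200)
    for _ in range(B):
        sample = angles[rng.integers(0, len(angles), size=len(angles))]
        try:
            refit = fit_vonmises_mixture(sample, fit.k, config=fast, init=fit)
        except ValueError:
            continue
        means = list(refit.means_deg)
        if fit.k == 2:
            # match bootstrap components to the original ones
            direct = (angular_error(means[0], fit.means_deg[0])
                      + angular_error(means[1], fit.means_deg[1]))
            crossed = (angular_error(means[1], fit.means_deg[0])
                       + angular_error(means[0], fit.means_deg[1]))
            if crossed < direct:
                means = means[::-1]
        for j, m in enumerate(means):
            devs[j].append(signed_angle_difference(m, fit.means_deg[j]))
    alpha = 1.0 - level
    sectors = []
    for j, comp in enumerate(fit.components):
        d = np.asarray(devs[j])
        lo = min(float(np.percentile(d, 100 * alpha / 2)), 0.0)
        hi = max(float(np.percentile(d, 100 * (1 - alpha / 2))), 0.0)
        sectors.append(ConfidenceSector(
            lo_deg=normalize_azimuth(comp.mean_deg + lo),
            hi_deg=normalize_azimuth(comp.mean_deg + hi),
            width_deg=hi - lo, level=level))
    return tuple(sectors)


def label_systematic_mode(fit: MixtureFit, correct_deg: float) -> int:
    """Index of the systematic mode of a bimodal fit.

    The systematic mode is the component whose mean direction deviates more
    from the correct pointing direction; the nearer mode is taken as noisy
    pointing at the true target. An exact tie is broken toward the
    lower-weight component (systematic errors are typically the minority
    regime), with a warning.
    """
    if fit.k != 2:
        raise ValueError("systematic-mode labeling requires a 2-component fit")
    d = [angular_error(c.mean_deg, correct_deg) for c in fit.components]
    if abs(d[0] - d[1]) < 1e-9:
        warnings.warn("modes equidistant from the correct direction; "
                      "labeling the lower-weight mode systematic",
                      RuntimeWarning, stacklevel=2)
        return int(np.argmin([c.weight for c in fit.components]))
    return int(np.argmax(d))


# ---------------------------------------------------------------------------
# Per-target error aggregation
# ---------------------------------------------------------------------------

def per_target_error_summary(records: pd.DataFrame) -> pd.DataFrame:
    """Distribution of participant-level mean pointing errors per target.

    Errors of one participant toward the same target are averaged first;
    the summary then describes the distribution of those participant means
    for every target location: mean, median, quartiles, and count.

    ``records`` needs columns ``participant``, ``target``, ``error_deg``.
    """
    if records.empty:
        raise ValueError("no pointing records")
    per_participant = (records.groupby(["target", "participant"], sort=True)
                       ["error_deg"].mean())
    g = per_participant.groupby("target")
    out = pd.DataFrame({
        "mean_error": g.mean(),
        "median_error": g.median(),
        "q1_error": g.quantile(0.25),
        "q3_error": g.quantile(0.75),
        "n_participants": g.size(),
    })
    return out.reset_index()
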