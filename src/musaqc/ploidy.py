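"""Ploidy inference from heterozygous-site allele frequencies.

At a heterozygous site of a ploidy-``p`` individual, the alternate allele
sits on ``k`` of ``p`` chromosome copies, so the fraction of reads carrying
it clusters around ``k/p``: one mode at 1/2 for diploids, modes at 1/3 and
2/3 for triploids, and at 1/4, 1/2, 3/4 for tetraploids.  The model family
is a Gaussian mixture over those frequencies with one component per
expected mode:

* *fixed* models (one per ploidy) pin the component means at the expected
  fractions and fit the mixture weights and a shared standard deviation;
* the *free* model additionally frees the three component means, serving
  as the reference fit every fixed model is compared against.

All fits are maximum likelihood via expectation-maximisation (EM).  For each
fixed model the delta log-likelihood ``logL(free) - logL(fixed)`` measures
how much is lost by pinning the means; the ploidy whose fixed model loses
the least (the lowest delta) is the inferred ploidy.  Deltas within a
BIC-scale margin of each other are treated as ties and resolved toward the
lower ploidy: the fixed models are nested (e.g. the tetraploid mean set
contains the diploid's), so a higher-ploidy model can always tie a lower
one and often edges it out by a few nats of overfitting, while genuine
ploidy signal separates models by orders of magnitude more.  Because the
free model is warm-started from every fixed model's solution (a fixed
model is a constrained special case of the free one), its likelihood can
never fall below theirs and every delta is non-negative up to optimiser
tolerance.

Gaussians are evaluated without truncation to (0, 1); for the standard
deviations that arise from read depths of 10x and up (sd <= 0.15) the mass
lost outside the interval is negligible, and ignoring it keeps the fixed
and free models exactly comparable.

Before fitting, frequencies can be de-noised: a free three-Gaussian mixture
plus a uniform(0, 1) background component is fitted, and sites assigned to
the background (posterior above a cutoff) are dropped.  This removes the
flat haze of allele frequencies produced by reads mis-mapped from
repetitive regions, which otherwise blurs the dosage modes.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Iterable, NamedTuple, Sequence

import numpy as np
from scipy.special import logsumexp

from .exceptions import InsufficientSitesError, InvalidParameterError
from .pileup import BASES, PileupColumn

logger = logging.getLogger(__name__)

__all__ = [
    "SiteFrequency",
    "PloidyFit",
    "PloidyModel",
    "PloidyResults",
    "extract_site_frequencies",
    "denoise",
    "fit_fixed_model",
    "fit_free_model",
    "infer_ploidy",
    "FIXED_MEANS",
]

FIXED_MEANS: dict[int, tuple[float, ...]] = {
    2: (0.5,),
    3: (1.0 / 3.0, 2.0 / 3.0),
    4: (0.25, 0.5, 0.75),
}
MODEL_NAMES = {2: "diploid", 3: "triploid", 4: "tetraploid"}

SD_FLOOR = 1e-4
_LOG_2PI = float(np.log(2.0 * np.pi))


class SiteFrequency(NamedTuple):
    chrom: str
    pos: int
    depth: int
    alt_fraction: float  # strictly in (0, 1)


def extract_site_frequencies(
    pileup: Sequence[PileupColumn],
    min_depth: int = 10,
    min_minor_reads: int = 3,
) -> list[SiteFrequency]:
    """Heterozygous-site allele frequencies from a pileup.

    A site qualifies when its two best-supported bases both have at least
    ``min_minor_reads`` reads and the top-two total meets ``min_depth``.
    The reported fraction is polarised against the reference: it is the
    fraction of the non-reference allele among the top-two base counts (so
    an AAB-type site reports near 1/3 and an ABB-type site near 2/3).  When
    neither top base is the reference, the minor fraction is reported.
    """
    freqs: list[SiteFrequency] = []
    for col in pileup:
        order = sorted(range(4), key=lambda i: (-col.base_counts[i], i))
        c1 = col.base_counts[order[0]]
        c2 = col.base_counts[order[1]]
        total = c1 + c2
        if c2 < min_minor_reads or c1 < min_minor_reads or col.depth < min_depth:
            continue
        top_bases = (BASES[order[0]], BASES[order[1]])
        if col.ref == top_bases[0]:
            frac = c2 / total
        elif col.ref == top_bases[1]:
            frac = c1 / total
        else:
            frac = c2 / total
        if 0.0 < frac < 1.0:
            freqs.append(SiteFrequency(col.chrom, col.pos, col.depth, frac))
    return freqs


def _as_array(freqs: Sequence[SiteFrequency] | Sequence[float] | np.ndarray) -> np.ndarray:
    if len(freqs) and isinstance(freqs[0], SiteFrequency):
        x = np.array([f.alt_fraction for f in freqs], dtype=float)
    else:
        x = np.asarray(freqs, dtype=float)
    if x.size and not ((x > 0) & (x < 1)).all():
        raise InvalidParameterError("allele frequencies must lie strictly in (0, 1)")
    return x


@dataclass
class PloidyFit:
    """One maximised mixture fit and its EM diagnostics."""

    model: str  # "diploid" | "triploid" | "tetraploid" | "free"
    log_likelihood: float
    weights: np.ndarray
    means: np.ndarray
    sd: float
    n_sites: int
    converged: bool
    n_iter: int
    loglik_trace: np.ndarray
    delta_loglik: float | None = None  # logL(free) - logL(this); None for free


def _log_gauss(x: np.ndarray, means: np.ndarray, sd: float) -> np.ndarray:
    z = (x[:, None] - means[None, :]) / sd
    return -0.5 * z * z - np.log(sd) - 0.5 * _LOG_2PI


def _em_gmm(
    x: np.ndarray,
    means: np.ndarray,
    weights: np.ndarray,
    sd: float,
    free_means: bool,
    tol: float,
    max_iter: int,
) -> tuple[np.ndarray, np.ndarray, float, float, bool, int, np.ndarray]:
    """Shared-sd Gaussian mixture EM; means optionally free.

    Returns (weights, means, sd, loglik, converged, n_iter, trace).  The
    trace holds the observed-data log-likelihood at the *start* of each
    iteration; EM guarantees it is non-decreasing.
    """
    n = x.size
    means = means.astype(float).copy()
    weights = weights.astype(float).copy()
    xcol = x[:, None]
    trace: list[float] = []
    converged = False
    it = 0
    prev = -np.inf
    ll = -np.inf
    for it in range(1, max_iter + 1):
        with np.errstate(divide="ignore"):
            log_comp = _log_gauss(x, means, sd) + np.log(weights)[None, :]
        m = log_comp.max(axis=1)
        p = np.exp(log_comp - m[:, None])
        mix = p.sum(axis=1)
        ll = float((m + np.log(mix)).sum())
        trace.append(ll)
        if ll - prev < tol and np.isfinite(prev):
            converged = True
            break
        prev = ll
        resp = p / mix[:, None]
        nk = resp.sum(axis=0)
        weights = nk / n
        if free_means:
            safe = nk > 1e-12
            means[safe] = (resp[:, safe] * xcol).sum(axis=0) / nk[safe]
        var = float((resp * (xcol - means[None, :]) ** 2).sum() / n)
        sd = np.sqrt(var)
        if sd < SD_FLOOR:
            warnings.warn(
                f"mixture standard deviation degenerated; floored at {SD_FLOOR}"
            )
            sd = SD_FLOOR
    # the trace entry for the final parameters is the converged likelihood
    return weights, means, sd, ll, converged, it, np.asarray(trace)


def _init_sd(x: np.ndarray, means: np.ndarray) -> float:
    resid = x[:, None] - means[None, :]
    nearest = np.abs(resid).argmin(axis=1)
    sd = float(np.sqrt(np.mean(resid[np.arange(x.size), nearest] ** 2)))
    return max(sd, 0.01)


def fit_fixed_model(
    freqs: Sequence[SiteFrequency] | np.ndarray,
    ploidy: int,
    tol: float = 1e-7,
    max_iter: int = 500,
    min_sites: int = 50,
) -> PloidyFit:
    """Fit the fixed-mean mixture for one ploidy (free weights, shared sd)."""
    if ploidy not in FIXED_MEANS:
        raise InvalidParameterError(f"ploidy must be one of {sorted(FIXED_MEANS)}")
    x = _as_array(freqs)
    if x.size < min_sites:
        raise InsufficientSitesError(
            f"need >= {min_sites} sites to fit, got {x.size}"
        )
    means = np.asarray(FIXED_MEANS[ploidy])
    weights = np.full(means.size, 1.0 / means.size)
    sd = _init_sd(x, means)
    w, m, s, ll, conv, it, trace = _em_gmm(
        x, means, weights, sd, free_means=False, tol=tol, max_iter=max_iter
    )
    return PloidyFit(
        model=MODEL_NAMES[ploidy],
        log_likelihood=ll,
        weights=w,
        means=m,
        sd=s,
        n_sites=x.size,
        converged=conv,
        n_iter=it,
        loglik_trace=trace,
    )


def _embed_fixed(fit: PloidyFit) -> tuple[np.ndarray, np.ndarray]:
    """Express a fixed fit as an equivalent 3-component initialisation.

    Components with fewer than three means are duplicated with split
    weights, which leaves the mixture density — and hence the
    log-likelihood — unchanged, so warm-starting the free model here
    guarantees it can only improve on the fixed fit.
    """
    means = list(fit.means)
    weights = list(fit.weights)
    while len(means) < 3:
        i = int(np.argmax(weights))
        means.append(means[i])
        weights[i] /= 2.0
        weights.append(weights[i])
    return np.asarray(means), np.asarray(weights)


def fit_free_model(
    freqs: Sequence[SiteFrequency] | np.ndarray,
    tol: float = 1e-7,
    max_iter: int = 500,
    min_sites: int = 50,
    n_restarts: int = 2,
    seed: int = 0,
    warm_starts: Iterable[PloidyFit] = (),
) -> PloidyFit:
    """Fit the free-mean 3-component mixture (weights, means, shared sd).

    Runs EM from several initialisations — the canonical tetraploid means,
    ``n_restarts`` seeded draws from the data quantiles, and an embedding of
    each fit in ``warm_starts`` — and keeps the best likelihood.
    """
    x = _as_array(freqs)
    if x.size < min_sites:
        raise InsufficientSitesError(
            f"need >= {min_sites} sites to fit, got {x.size}"
        )
    rng = np.random.default_rng(seed)
    inits: list[tuple[np.ndarray, np.ndarray, float]] = []
    base_means = np.asarray([0.25, 0.5, 0.75])
    inits.append((base_means, np.full(3, 1 / 3), _init_sd(x, base_means)))
    for _ in range(n_restarts):
        qs = np.sort(rng.uniform(0.05, 0.95, size=3))
        means = np.quantile(x, qs)
        inits.append((means, np.full(3, 1 / 3), _init_sd(x, means)))
    for fit in warm_starts:
        means, weights = _embed_fixed(fit)
        inits.append((means, weights, fit.sd))

    best: tuple | None = None
    for means, weights, sd in inits:
        w, m, s, ll, conv, it, trace = _em_gmm(
            x, means, weights, sd, free_means=True, tol=tol, max_iter=max_iter
        )
        if best is None or ll > best[3]:
            best = (w, m, s, ll, conv, it, trace)
    w, m, s, ll, conv, it, trace = best
    return PloidyFit(
        model="free",
        log_likelihood=ll,
        weights=w,
        means=m,
        sd=s,
        n_sites=x.size,
        converged=conv,
        n_iter=it,
        loglik_trace=trace,
    )


def denoise(
    freqs: Sequence[SiteFrequency],
    max_noise_posterior: float = 0.5,
    tol: float = 1e-4,
    max_iter: int = 2000,
    min_sites: int = 50,
) -> list[SiteFrequency]:
    """Drop sites attributed to a uniform mis-mapping background.

    Fits a free three-Gaussian + uniform(0, 1) mixture by EM and removes
    sites whose posterior probability of the uniform component exceeds
    ``max_noise_posterior``.  If EM fails to converge the input is returned
    unchanged with a warning — de-noising must never silently discard data.
    """
    freqs = list(freqs)
    x = _as_array(freqs)
    if x.size < min_sites:
        raise InsufficientSitesError(
            f"de-noising needs >= {min_sites} sites, got {x.size}"
        )
    means = np.asarray([0.25, 0.5, 0.75])
    weights = np.asarray([0.3, 0.3, 0.3])
    w_unif = 0.1
    sd = min(_init_sd(x, means), 0.15)
    prev = -np.inf
    converged = False
    for _ in range(max_iter):
        with np.errstate(divide="ignore"):
            log_comp = np.column_stack(
                [
                    _log_gauss(x, means, sd) + np.log(weights)[None, :],
                    np.full((x.size, 1), np.log(w_unif) if w_unif > 0 else -np.inf),
                ]
            )
        log_mix = logsumexp(log_comp, axis=1)
        ll = float(log_mix.sum())
        if ll - prev < tol and np.isfinite(prev):
            converged = True
            break
        prev = ll
        resp = np.exp(log_comp - log_mix[:, None])
        nk = resp.sum(axis=0)
        weights = nk[:3] / x.size
        w_unif = nk[3] / x.size
        safe = nk[:3] > 1e-12
        means[safe] = (resp[:, :3][:, safe] * x[:, None]).sum(axis=0) / nk[:3][safe]
        gauss_mass = resp[:, :3].sum()
        if gauss_mass > 1e-12:
            var = float(
                (resp[:, :3] * (x[:, None] - means[None, :]) ** 2).sum() / gauss_mass
            )
            sd = max(np.sqrt(var), SD_FLOOR)
    if not converged:
        warnings.warn("de-noising EM did not converge; returning input unchanged")
        return freqs
    with np.errstate(divide="ignore"):
        log_comp = np.column_stack(
            [
                _log_gauss(x, means, sd) + np.log(weights)[None, :],
                np.full((x.size, 1), np.log(w_unif) if w_unif > 0 else -np.inf),
            ]
        )
    post_unif = np.exp(log_comp[:, 3] - logsumexp(log_comp, axis=1))
    kept = [f for f, p in zip(freqs, post_unif) if p <= max_noise_posterior]
    logger.info("denoise: kept %d of %d sites", len(kept), len(freqs))
    return kept


class PloidyModel:
    """Gaussian-mixture model selection over ploidy levels 2, 3 and 4.

    Parameters
    ----------
    freqs
        Heterozygous-site allele frequencies (``SiteFrequency`` records or a
        plain array of values strictly inside (0, 1)).
    min_sites
        Minimum number of sites for a determinate fit; below this,
        :meth:`fit` returns an *undetermined* result rather than guessing.

    Examples
    --------
    >>> res = PloidyModel(freqs).fit(seed=1)
    >>> res.observed_ploidy
    3
    >>> print(res.summary())          # doctest: +SKIP
    """

    def __init__(
        self,
        freqs: Sequence[SiteFrequency] | np.ndarray,
        min_sites: int = 50,
    ):
        self.freqs = freqs
        self.x = _as_array(freqs)
        self.min_sites = min_sites

    def fit(
        self,
        seed: int = 0,
        tol: float = 1e-7,
        max_iter: int = 500,
        tie_tol: float | None = None,
    ) -> "PloidyResults":
        """Fit all fixed models and the free model; select the ploidy.

        ``tie_tol`` is the log-likelihood margin within which two fixed
        models are considered tied; ties are resolved toward the lower
        ploidy with a logged warning.  The default is ``ln(n_sites)`` — a
        BIC-scale parsimony margin.  The fixed models are nested (the
        tetraploid's mean set contains the diploid's), so a higher-ploidy
        model can always match a lower one and typically edges it out by a
        few nats of pure overfitting, whereas a genuinely better ploidy
        wins by hundreds to thousands of nats; differences on the order of
        the BIC penalty for the extra mixture weights carry no evidence.
        """
        n = self.x.size
        if n < self.min_sites:
            return PloidyResults(
                model=self, observed_ploidy=None, fits={}, tie_tol=0.0
            )
        if tie_tol is None:
            tie_tol = float(np.log(n))
        fits: dict[str, PloidyFit] = {}
        for p in (2, 3, 4):
            fits[MODEL_NAMES[p]] = fit_fixed_model(
                self.x, p, tol=tol, max_iter=max_iter, min_sites=self.min_sites
            )
        free = fit_free_model(
            self.x,
            tol=tol,
            max_iter=max_iter,
            min_sites=self.min_sites,
            seed=seed,
            warm_starts=fits.values(),
        )
        fits["free"] = free
        for p in (2, 3, 4):
            fit = fits[MODEL_NAMES[p]]
            fit.delta_loglik = free.log_likelihood - fit.log_likelihood

        best_p = 2
        for p in (3, 4):
            if (
                fits[MODEL_NAMES[p]].delta_loglik
                < fits[MODEL_NAMES[best_p]].delta_loglik - tie_tol
            ):
                best_p = p
        near = [
            p
            for p in (2, 3, 4)
            if abs(
                fits[MODEL_NAMES[p]].delta_loglik
                - fits[MODEL_NAMES[best_p]].delta_loglik
            )
            <= tie_tol
        ]
        if len(near) > 1:
            logger.warning(
                "ploidy models %s tied within %.3g nats; choosing the lowest (%d)",
                near,
                tie_tol,
                min(near),
            )
            best_p = min(near)
        return PloidyResults(
            model=self, observed_ploidy=best_p, fits=fits, tie_tol=tie_tol
        )


@dataclass
class PloidyResults:
    """Fitted mixture models and the selected ploidy.

    ``observed_ploidy`` is ``None`` when too few sites were available — an
    explicit *undetermined* outcome, never a silent default.
    """

    model: PloidyModel
    observed_ploidy: int | None
    fits: dict[str, PloidyFit]
    tie_tol: float

    @property
    def status(self) -> str:
        return "ok" if self.observed_ploidy is not None else "undetermined"

    def delta(self, name: str) -> float:
        return self.fits[name].delta_loglik

    def summary(self) -> str:
        """Per-model table in the shape of a likelihood-ratio report."""
        lines = [
            f"Ploidy inference on {self.model.x.size} heterozygous sites",
            f"{'model':<12}{'logL':>14}{'deltaLogL':>14}{'sd':>9}  weights",
        ]
        if not self.fits:
            lines.append("  (undetermined: too few sites)")
            return "\n".join(lines)
        for name in ("free", "diploid", "triploid", "tetraploid"):
            f = self.fits[name]
            delta = "" if f.delta_loglik is None else f"{f.delta_loglik:14.3f}"
            wstr = ", ".join(f"{w:.3f}" for w in f.weights)
            lines.append(
                f"{name:<12}{f.log_likelihood:14.3f}{delta:>14}{f.sd:9.4f}  [{wstr}]"
            )
        if self.observed_ploidy is not None:
            lines.append(f"inferred ploidy: {self.observed_ploidy}")
        return "\n".join(lines)


def infer_ploidy(
    freqs: Sequence[SiteFrequency] | np.ndarray,
    min_sites: int = 50,
    seed: int = 0,
    tol: float = 1e-7,
    max_iter: int = 500,
) -> tuple[int | None, dict[str, PloidyFit]]:
    """Functional wrapper: returns (observed_ploidy, fits).

    ``observed_ploidy`` is the ploidy whose fixed model has the lowest delta
    log-likelihood against the free model, or ``None`` (undetermined) with
    an empty fit table when fewer than ``min_sites`` sites are available.
    """
    res = PloidyModel(freqs, min_sites=min_sites).fit(
        seed=seed, tol=tol, max_iter=max_iter
    )
    return res.observed_ploidy, res.fits
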