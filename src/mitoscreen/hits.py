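"""Distribution-aware hit calling for plate screens.

A screen's normalized readouts may be unimodal (one biological population
plus measurement noise) or bimodal (non-responders vs candidate rescuers).
A pooled mean + 2 SD cutoff is only meaningful in the unimodal case: under
mixing, the pooled variance is inflated by the between-population spread.
This module fits one- and two-component Gaussian mixtures by
expectation-maximization, classifies the distribution shape by BIC and
component geometry, and applies the matching >= 2 SD hit rule:

* bimodal  -> threshold = mu_high + 2*sigma_high of the dominant
  (higher-mean) mixture component;
* unimodal -> threshold = pooled mean + 2 * pooled sample SD.

The EM implementation is self-contained and deterministic: the first
attempt initializes from median-split group moments, restarts (on variance
collapse) jitter the responsibilities with a seeded generator, and the
log-likelihood is asserted non-decreasing at every iteration.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict, field
from typing import Mapping, Sequence

import numpy as np
from scipy.special import logsumexp

from .qc import ScreenQCReport
from .screen import NormalizedValue

__all__ = [
    "MixtureFit",
    "ModalityAssessment",
    "HitCallResult",
    "NonConvergenceError",
    "MissingModelError",
    "fit_gmm",
    "assess_modality",
    "call_hits",
    "screen_report",
]

SD_FLOOR = 1e-4  # normalized-ratio units; EM variance-collapse guard
_LOG_2PI = float(np.log(2.0 * np.pi))


class NonConvergenceError(RuntimeError):
    """EM failed to converge after the allowed restarts."""


class MissingModelError(ValueError):
    """A bimodal hit call was requested without a converged k=2 fit."""


@dataclass
class MixtureFit:
    """Maximum-likelihood Gaussian mixture parameters with fit diagnostics.

    Components are ordered by ascending mean.  BIC = -2*loglik + p*ln(n)
    with p = 3k - 1 free parameters.
    """

    k: int
    weights: tuple[float, ...]
    means: tuple[float, ...]
    sds: tuple[float, ...]
    loglik: float
    bic: float
    n: int
    n_iter: int
    converged: bool
    seed: int
    n_restarts: int = 0

    @property
    def high(self) -> tuple[float, float, float]:
        """(weight, mean, sd) of the higher-mean component."""
        return self.weights[-1], self.means[-1], self.sds[-1]


def _loglik(x: np.ndarray, w: np.ndarray, mu: np.ndarray, sd: np.ndarray) -> tuple[float, np.ndarray]:
    """Total log-likelihood and per-point per-component log joint."""
    # log w_j + log N(x | mu_j, sd_j), shape (n, k)
    lj = (
        np.log(w)[None, :]
        - 0.5 * (_LOG_2PI + 2.0 * np.log(sd))[None, :]
        - 0.5 * ((x[:, None] - mu[None, :]) / sd[None, :]) ** 2
    )
    return float(np.sum(logsumexp(lj, axis=1))), lj


def _m_step(x: np.ndarray, resp: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    nk = resp.sum(axis=0)
    w = nk / len(x)
    mu = (resp * x[:, None]).sum(axis=0) / nk
    var = (resp * (x[:, None] - mu[None, :]) ** 2).sum(axis=0) / nk
    return w, mu, np.sqrt(var)


def _two_means_split(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Deterministic 1-D two-means partition (Lloyd iterations seeded at
    the 10th/90th percentiles).  Keeps the EM start aligned with cluster
    structure rather than sample density, so a minority component is
    isolated instead of being merged into a broad background class."""
    c = np.percentile(x, [10.0, 90.0]).astype(float)
    if c[0] == c[1]:
        med = np.median(x)
        lo, hi = x[x <= med], x[x > med]
        if hi.size == 0:
            srt = np.sort(x)
            lo, hi = srt[: x.size // 2], srt[x.size // 2 :]
        return lo, hi
    for _ in range(100):
        mid = 0.5 * (c[0] + c[1])
        lo, hi = x[x <= mid], x[x > mid]
        if lo.size == 0 or hi.size == 0:
            break
        new = np.array([lo.mean(), hi.mean()])
        if np.allclose(new, c):
            break
        c = new
    return lo, hi


def fit_gmm(
    values: Sequence[float],
    k: int = 2,
    seed: int = 0,
    tol: float = 1e-8,
    max_iter: int = 500,
    sd_floor: float = SD_FLOOR,
) -> MixtureFit:
    """Fit a k-component (k in {1, 2}) Gaussian mixture by EM.

    k=1 is the closed-form MLE (mean and 1/n-denominator SD).  k=2 starts
    from median-split group moments; a component whose SD collapses below
    ``sd_floor`` triggers a restart from seeded random responsibilities, up
    to 5 restarts before NonConvergenceError.
    """
    x = np.asarray(values, dtype=float)
    if k not in (1, 2):
        raise ValueError(f"k must be 1 or 2, got {k}")
    n = x.size
    if n < 10 * k:
        raise ValueError(f"need >= {10 * k} values for k={k}, got {n}")

    if k == 1:
        mu = float(np.mean(x))
        sd = max(float(np.std(x, ddof=0)), sd_floor)
        ll, _ = _loglik(x, np.array([1.0]), np.array([mu]), np.array([sd]))
        return MixtureFit(
            k=1,
            weights=(1.0,),
            means=(mu,),
            sds=(sd,),
            loglik=ll,
            bic=-2.0 * ll + 2.0 * np.log(n),
            n=n,
            n_iter=0,
            converged=True,
            seed=seed,
        )

    rng = np.random.default_rng(seed)
    for attempt in range(6):
        if attempt == 0:
            # deterministic start: 1-D two-means split, group moments
            lo, hi = _two_means_split(x)
            w = np.array([lo.size / n, hi.size / n])
            mu = np.array([lo.mean(), hi.mean()])
            sd = np.maximum([lo.std(), hi.std()], sd_floor)
        else:
            resp = rng.dirichlet([1.0, 1.0], size=n)
            w, mu, sd = _m_step(x, resp)
            sd = np.maximum(sd, sd_floor)

        ll_prev = -np.inf
        collapsed = False
        converged = False
        for it in range(1, max_iter + 1):
            ll, lj = _loglik(x, w, mu, sd)
            if ll < ll_prev - 1e-9 * max(1.0, abs(ll_prev)):
                raise AssertionError(
                    f"EM log-likelihood decreased: {ll_prev} -> {ll}"
                )
            resp = np.exp(lj - logsumexp(lj, axis=1, keepdims=True))
            w, mu, sd = _m_step(x, resp)
            if np.any(sd < sd_floor) or np.any(w < 1e-12):
                collapsed = True
                break
            if ll_prev > -np.inf and abs(ll - ll_prev) <= tol * abs(ll_prev):
                converged = True
                break
            ll_prev = ll
        if collapsed:
            continue
        ll, _ = _loglik(x, w, mu, sd)
        order = np.argsort(mu)
        w, mu, sd = w[order], mu[order], sd[order]
        return MixtureFit(
            k=2,
            weights=tuple(float(v) for v in w),
            means=tuple(float(v) for v in mu),
            sds=tuple(float(v) for v in sd),
            loglik=ll,
            bic=-2.0 * ll + 5.0 * np.log(n),
            n=n,
            n_iter=it,
            converged=converged,
            seed=seed,
            n_restarts=attempt,
        )
    raise NonConvergenceError("EM collapsed in all 5 restarts")


@dataclass
class ModalityAssessment:
    """Shape classification of a screen's value distribution.

    ``bimodal`` requires all three: BIC improvement of the two-component
    model over one component exceeding 10, smallest mixing weight >= 0.05,
    and component separation |mu2 - mu1| / max(sd1, sd2) >= 2.
    """

    label: str  # "bimodal" | "unimodal"
    delta_bic: float
    min_weight: float
    separation: float
    fit1: MixtureFit = field(repr=False)
    fit2: MixtureFit | None = field(repr=False)


def assess_modality(values: Sequence[float], seed: int = 0) -> ModalityAssessment:
    x = np.asarray(values, dtype=float)
    if x.size < 20:
        raise ValueError(f"need >= 20 values, got {x.size}")
    fit1 = fit_gmm(x, k=1, seed=seed)
    try:
        fit2 = fit_gmm(x, k=2, seed=seed)
    except NonConvergenceError:
        # persistent variance collapse: the data cannot support a second
        # component (e.g. near-degenerate samples) -> treat as unimodal
        return ModalityAssessment(
            label="unimodal",
            delta_bic=float("-inf"),
            min_weight=0.0,
            separation=0.0,
            fit1=fit1,
            fit2=None,
        )
    delta_bic = fit1.bic - fit2.bic
    min_w = min(fit2.weights)
    sep = abs(fit2.means[1] - fit2.means[0]) / max(fit2.sds)
    bimodal = delta_bic > 10.0 and min_w >= 0.05 and sep >= 2.0
    return ModalityAssessment(
        label="bimodal" if bimodal else "unimodal",
        delta_bic=delta_bic,
        min_weight=min_w,
        separation=sep,
        fit1=fit1,
        fit2=fit2,
    )


@dataclass
class HitCallResult:
    rule: str  # "gmm_component" | "pooled_sd"
    threshold: float
    reference_mean: float
    reference_sd: float
    pooled_mean: float
    pooled_sd: float
    hits: list[str]
    n_hits: int
    values: dict[str, float] = field(repr=False, default_factory=dict)


def call_hits(
    normalized: Sequence[NormalizedValue],
    assessment: ModalityAssessment,
    fit: MixtureFit | None = None,
) -> HitCallResult:
    """Apply the distribution-appropriate >= 2 SD hit rule.

    Bimodal screens use the dominant (higher-mean) component of the
    supplied converged k=2 fit; unimodal screens use the pooled sample
    mean and sample SD (ddof=1).  Hits are treatments whose replicate-
    aggregated value is >= threshold (inclusive).
    """
    vals = {v.treatment_id: v.aggregate for v in normalized}
    arr = np.array(list(vals.values()))
    pooled_mean = float(np.mean(arr))
    pooled_sd = float(np.std(arr, ddof=1))

    if assessment.label == "bimodal":
        if fit is None:
            fit = assessment.fit2
        if fit is None or fit.k != 2 or not fit.converged:
            raise MissingModelError("bimodal screen requires a converged k=2 fit")
        _, ref_mean, ref_sd = fit.high
        rule = "gmm_component"
    else:
        ref_mean, ref_sd = pooled_mean, pooled_sd
        rule = "pooled_sd"

    threshold = ref_mean + 2.0 * ref_sd
    hits = sorted(t for t, v in vals.items() if v >= threshold)
    return HitCallResult(
        rule=rule,
        threshold=threshold,
        reference_mean=ref_mean,
        reference_sd=ref_sd,
        pooled_mean=pooled_mean,
        pooled_sd=pooled_sd,
        hits=hits,
        n_hits=len(hits),
        values=vals,
    )


def screen_report(
    result: HitCallResult,
    qc: ScreenQCReport | None = None,
    assessment: ModalityAssessment | None = None,
) -> dict:
    """JSON-ready report: rule, threshold, fit diagnostics, hit list, QC.

    ``scatter`` carries (treatment index, value, is_hit) triples for the
    screen-overview scatter plot.
    """
    doc: dict = {
        "rule": result.rule,
        "threshold": result.threshold,
        "reference_mean": result.reference_mean,
        "reference_sd": result.reference_sd,
        "pooled_mean": result.pooled_mean,
        "pooled_sd": result.pooled_sd,
        "n_hits": result.n_hits,
        "hits": [
            {"treatment_id": t, "value": result.values[t]} for t in result.hits
        ],
    }
    if assessment is not None:
        doc["modality"] = {
            "label": assessment.label,
            "delta_bic": assessment.delta_bic,
            "min_weight": assessment.min_weight,
            "separation": assessment.separation,
        }
        if assessment.fit2 is not None:
            doc["modality"]["fit_k2"] = {
                "weights": assessment.fit2.weights,
                "means": assessment.fit2.means,
                "sds": assessment.fit2.sds,
                "converged": assessment.fit2.converged,
                "n_iter": assessment.fit2.n_iter,
            }
    if qc is not None:
        doc["qc"] = asdict(qc)
    hitset = set(result.hits)
    doc["scatter"] = [
        {"index": i, "treatment_id": t, "value": v, "hit": t in hitset}
        for i, (t, v) in enumerate(sorted(result.values.items()))
    ]
    return doc


def write_report_json(doc: Mapping, path) -> None:
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=2)
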