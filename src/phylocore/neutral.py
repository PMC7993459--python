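"""Sloan-style neutral community model fitting.

Under dispersal-limited neutral assembly, a taxon with metacommunity
relative abundance p has local relative abundance x ~ Beta(N*m*p,
N*m*(1-p)), with N the sample depth and m the migration (immigration)
rate. Its expected detection frequency across samples ("occupancy") is
therefore a function of p alone once N*m is known; m is estimated by
least squares between observed and predicted occupancies over taxa, and
per-taxon departures (occupancy above/below the neutral envelope) are
called from binomial confidence intervals.

Two detection models are provided: the Beta survival function above an
explicit relative-abundance detection limit d, and (the default) the exact
probability of observing at least one read when the Beta abundance is
multinomially sampled to depth N — the latter matches how counts are
actually generated and avoids the upward bias in m of the sharp-threshold
approximation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

from .containers import AbundanceTable, ValidationError

VERDICTS = ("neutral", "subset_departure", "global_departure", "undecidable")


def predicted_occupancy(p, N: float, m: float, d: float):
    """P(local relative abundance > d) under the neutral Beta model.

    Monotone increasing in p; equals 1 at d = 0 and tends to 0 (1) as
    p -> 0 (1). Accepts scalar or array p.
    """
    if not 0 < m <= 1:
        raise ValidationError("m must be in (0, 1]")
    if N < 1 or not 0 <= d < 1:
        raise ValidationError("need N >= 1 and 0 <= d < 1")
    p_arr = np.atleast_1d(np.asarray(p, dtype=float))
    if ((p_arr < 0) | (p_arr > 1)).any():
        raise ValidationError("p must be in [0, 1]")
    out = np.empty_like(p_arr)
    interior = (p_arr > 0) & (p_arr < 1)
    out[p_arr <= 0] = 0.0
    out[p_arr >= 1] = 1.0
    a = N * m * p_arr[interior]
    b = N * m * (1.0 - p_arr[interior])
    if d == 0:
        out[interior] = 1.0
    else:
        out[interior] = 1.0 - special.betainc(a, b, d)
    return out if np.ndim(p) else float(out[0])


def detection_probability(p, N: float, m: float):
    """Exact P(at least one read among N) under Beta abundance + multinomial reads.

    1 - E[(1-x)^N] with x ~ Beta(N*m*p, N*m*(1-p)), evaluated via log-Beta
    functions.
    """
    if not 0 < m <= 1:
        raise ValidationError("m must be in (0, 1]")
    p_arr = np.atleast_1d(np.asarray(p, dtype=float))
    out = np.empty_like(p_arr)
    interior = (p_arr > 0) & (p_arr < 1)
    out[p_arr <= 0] = 0.0
    out[p_arr >= 1] = 1.0
    a = N * m * p_arr[interior]
    b = N * m * (1.0 - p_arr[interior])
    out[interior] = 1.0 - np.exp(special.betaln(a, b + N) - special.betaln(a, b))
    return out if np.ndim(p) else float(out[0])


@dataclass
class NeutralFitResult:
    """Fitted migration rate, fit quality, per-taxon departure calls."""

    m_hat: float
    fit_quality: float
    per_taxon: pd.DataFrame  # p, occupancy, predicted, ci_low, ci_high, call
    verdict: str
    n_samples: int
    depth: float
    detection_limit: float | None
    boundary: bool = False

    @property
    def departing_taxa(self) -> list[str]:
        if self.per_taxon.empty:
            return []
        return list(self.per_taxon.index[self.per_taxon["call"] != "neutral"])

    @property
    def departing_fraction(self) -> float:
        if self.per_taxon.empty:
            return float("nan")
        return float((self.per_taxon["call"] != "neutral").mean())


def _predict(p: np.ndarray, N: float, m: float, d: float | None) -> np.ndarray:
    if d is None:
        return detection_probability(p, N, m)
    return predicted_occupancy(p, N, m, d)


def sloan_fit(
    table: AbundanceTable,
    detection_limit: float | None = None,
    ci_level: float = 0.95,
    neutral_frac: float = 0.05,
    global_frac: float = 0.5,
) -> NeutralFitResult:
    """Fit the neutral occupancy-abundance model to one metacommunity.

    m is chosen to minimize squared error between observed occupancy
    frequencies and the model prediction across taxa; per-taxon calls
    compare observed occupied-sample counts with a central binomial
    interval around the prediction. Verdict: ``neutral`` if fewer than
    ``neutral_frac`` of taxa depart, ``global_departure`` if at least
    ``global_frac`` depart or the fit explains nothing (R^2 < 0),
    ``subset_departure`` otherwise.
    """
    table = table.trim_zero_taxa()
    n_samples = len(table.samples)
    n_taxa = len(table.taxa)
    if n_samples < 5:
        raise ValidationError(f"need >= 5 samples, got {n_samples}")
    if n_taxa < 5:
        raise ValidationError(f"need >= 5 taxa with nonzero counts, got {n_taxa}")
    N = float(np.median(table.depths))
    p = table.mean_relative().to_numpy()
    occupied = (table.counts > 0).sum(axis=1)
    o = occupied / n_samples

    def sse(log_m: float) -> float:
        pred = _predict(p, N, float(np.exp(log_m)), detection_limit)
        return float(np.sum((o - pred) ** 2))

    res = optimize.minimize_scalar(
        sse, bounds=(np.log(1e-4), 0.0), method="bounded",
        options={"xatol": 1e-6},
    )
    m_hat = float(np.exp(res.x))
    boundary = m_hat >= 0.999 or m_hat <= 1.5e-4

    pred = _predict(p, N, m_hat, detection_limit)
    sst = float(np.sum((o - o.mean()) ** 2))
    fit_quality = 1.0 - res.fun / sst if sst > 0 else float("nan")

    # Per-taxon envelope: binomial sampling of occupancy around the
    # prediction, widened by the uncertainty the prediction inherits from
    # the estimated mean abundance (delta method; matters for rare taxa).
    lo_b, hi_b = stats.binom.interval(ci_level, n_samples, np.clip(pred, 0.0, 1.0))
    rel = table.relative().to_numpy()
    var_p = rel.var(axis=1, ddof=1) / n_samples
    h = np.maximum(p * 1e-3, 1e-9)
    grad = (
        _predict(np.clip(p + h, 0, 1), N, m_hat, detection_limit)
        - _predict(np.clip(p - h, 0, 1), N, m_hat, detection_limit)
    ) / (2 * h)
    z_ci = stats.norm.ppf(0.5 + ci_level / 2.0)
    sd_counts = np.sqrt(
        np.maximum(n_samples * pred * (1 - pred), 0.0)
        + (n_samples * grad) ** 2 * var_p
    )
    lo = np.minimum(lo_b, np.floor(n_samples * pred - z_ci * sd_counts))
    hi = np.maximum(hi_b, np.ceil(n_samples * pred + z_ci * sd_counts))
    lo = np.clip(lo, 0, n_samples)
    hi = np.clip(hi, 0, n_samples)
    call = np.where(occupied > hi, "above", np.where(occupied < lo, "below", "neutral"))
    per_taxon = pd.DataFrame(
        {
            "p": p,
            "occupancy": o,
            "predicted": pred,
            "ci_low": lo / n_samples,
            "ci_high": hi / n_samples,
            "call": call,
        },
        index=table.taxa,
    )

    frac = float((call != "neutral").mean())
    if not np.isnan(fit_quality) and fit_quality < 0:
        verdict = "global_departure"
    elif frac < neutral_frac:
        verdict = "neutral"
    elif frac < global_frac:
        verdict = "subset_departure"
    else:
        verdict = "global_departure"

    return NeutralFitResult(
        m_hat=m_hat,
        fit_quality=fit_quality,
        per_taxon=per_taxon,
        verdict=verdict,
        n_samples=n_samples,
        depth=N,
        detection_limit=detection_limit,
        boundary=boundary,
    )


def refit_excluding(
    table: AbundanceTable, exclude: list[str], **kwargs
) -> NeutralFitResult:
    """Re-run :func:`sloan_fit` with some taxa removed.

    With an empty exclusion list this is identical to ``sloan_fit``. If the
    exclusion leaves fewer than 5 taxa the result carries the
    ``undecidable`` verdict instead of raising.
    """
    sub = table.drop_taxa(list(exclude)) if exclude else table
    try:
        return sloan_fit(sub, **kwargs)
    except ValidationError:
        return NeutralFitResult(
            m_hat=float("nan"),
            fit_quality=float("nan"),
            per_taxon=pd.DataFrame(),
            verdict="undecidable",
            n_samples=len(sub.samples),
            depth=float(np.median(sub.depths)) if len(sub.samples) else float("nan"),
            detection_limit=kwargs.get("detection_limit"),
        )
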