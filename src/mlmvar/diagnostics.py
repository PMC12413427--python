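"""Convergence verdicts and the rerun protocol.

A replication counts as converged under the strict criterion when (1)
every monitored parameter has split-Rhat below 1.01, (2) minimum bulk and
tail effective sample sizes exceed 100 per chain, and (3) no divergent
transitions occurred.  The lenient criterion only requires Rhat < 1.05.
A strictly non-converged fit is rerun once with twice the number of
iterations (and a newly derived seed) and flagged as excluded if it still
fails.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import EstimationError
from .posterior import PosteriorDraws, PriorConfig, fit

RHAT_STRICT = 1.01
RHAT_LENIENT = 1.05
MIN_ESS_PER_CHAIN = 100.0


@dataclass
class ConvergenceVerdict:
    converged_strict: bool
    converged_lenient: bool
    failing_parameters: list = field(default_factory=list)
    rerun_count: int = 0
    excluded: bool = False


def assess(draws: PosteriorDraws) -> ConvergenceVerdict:
    """Apply the strict/lenient convergence criteria to a fitted model."""
    if draws.n_chains < 2:
        raise EstimationError("Rhat requires at least 2 chains")
    min_ess = MIN_ESS_PER_CHAIN * draws.n_chains
    failing = []
    rhat = np.asarray(draws.rhat, dtype=float)
    bad_rhat = ~np.isfinite(rhat) | (rhat >= RHAT_STRICT)
    for i in np.flatnonzero(bad_rhat):
        failing.append((draws.names[i], f"rhat={rhat[i]:.4f}"))
    for arr, label in ((draws.ess_bulk, "ess_bulk"), (draws.ess_tail, "ess_tail")):
        arr = np.asarray(arr, dtype=float)
        bad = ~np.isfinite(arr) | (arr <= min_ess)
        for i in np.flatnonzero(bad):
            failing.append((draws.names[i], f"{label}={arr[i]:.0f}"))
    n_div = int(np.asarray(draws.n_divergent).sum())
    if n_div > 0:
        failing.append(("(sampler)", f"divergences={n_div}"))
    lenient = bool(np.all(np.isfinite(rhat) & (rhat < RHAT_LENIENT)))
    strict = lenient and not failing and bool(np.all(rhat < RHAT_STRICT))
    return ConvergenceVerdict(
        converged_strict=strict,
        converged_lenient=lenient,
        failing_parameters=failing,
    )


def fit_with_rerun(
    spec,
    priors: PriorConfig | None,
    data,
    chains: int = 2,
    iterations: int = 4000,
    seed: int = 0,
    fitter=fit,
    **kwargs,
):
    """Fit, assess, and rerun once at double length on strict failure.

    Returns (draws, verdict).  The rerun uses a deterministically derived
    new seed; if the rerun still fails the strict criterion the verdict is
    flagged ``excluded`` (draws are retained for forensic use).
    """
    draws = fitter(spec, priors, data, chains=chains, iterations=iterations, seed=seed, **kwargs)
    verdict = assess(draws)
    if verdict.converged_strict:
        return draws, verdict
    rerun_seed = int((seed * 2654435761 + 97) % (2**31 - 1))
    draws = fitter(
        spec, priors, data, chains=chains, iterations=2 * iterations, seed=rerun_seed, **kwargs
    )
    verdict = assess(draws)
    verdict.rerun_count = 1
    verdict.excluded = not verdict.converged_strict
    return draws, verdict
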