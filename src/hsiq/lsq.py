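"""Iterative least-squares baseline for spectral parameter fitting.

Fits (log10 B, S, fm, a) to a measured diffuse reflectance spectrum by
bound-constrained nonlinear least squares on the spectrum-domain residual
against the lookup-backed forward model.  The blood volume is fitted on a
log10 scale for conditioning parity with the neural inverse model.  The
objective is mildly multimodal in (B, fm), so fitting is multi-start: the
range center plus randomized starts, keeping the best final objective.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

from .dataset import SamplingRanges, default_ranges
from .tissue import TissueParams

__all__ = ["FitResult", "fit_spectrum", "fit_batch"]


@dataclass(frozen=True)
class FitResult:
    """Outcome of one spectral fit."""

    params: TissueParams
    rmse: float
    iterations: int
    converged: bool
    objective_trace: np.ndarray  # best-so-far cost after each evaluation


def _bounds_from_ranges(ranges: SamplingRanges):
    lo = np.array([np.log10(ranges.B[0]), ranges.S[0], ranges.fm[0], ranges.a[0]])
    hi = np.array([np.log10(ranges.B[1]), ranges.S[1], ranges.fm[1], ranges.a[1]])
    return lo, hi


def fit_spectrum(
    spectrum: np.ndarray,
    forward,
    ranges: SamplingRanges | None = None,
    init: np.ndarray | None = None,
    n_starts: int = 3,
    seed: int = 0,
    xtol: float = 1e-8,
    ftol: float = 1e-10,
    max_nfev: int = 400,
) -> FitResult:
    """Fit one spectrum; ``forward`` must expose ``spectra_log(...)``.

    ``init``, when given, is a (log10B, S, fm, a) vector used as the first
    start; the remaining starts are the range center and uniform random
    points inside the bounds.
    """
    spectrum = np.asarray(spectrum, float).ravel()
    if not np.all(np.isfinite(spectrum)):
        raise ValueError("non-finite spectrum")
    ranges = ranges or default_ranges()
    lo, hi = _bounds_from_ranges(ranges)
    rng = np.random.default_rng(np.random.SeedSequence(seed))

    starts = []
    if init is not None:
        init = np.asarray(init, float)
        if np.any(init < lo) or np.any(init > hi):
            raise ValueError("init outside bounds")
        starts.append(init)
    starts.append(0.5 * (lo + hi))
    while len(starts) < max(n_starts, 1):
        starts.append(rng.uniform(lo, hi))
    starts = starts[: max(n_starts, 1)]

    trace = []

    def residuals(x):
        model = forward.spectra_log(x[0], x[1], x[2], x[3])[0]
        r = model - spectrum
        cost = float(r @ r)
        trace.append(min(cost, trace[-1]) if trace else cost)
        return r

    best = None
    total_nfev = 0
    for x0 in starts:
        sol = least_squares(
            residuals, x0, bounds=(lo, hi), method="trf",
            xtol=xtol, ftol=ftol, max_nfev=max_nfev,
        )
        total_nfev += sol.nfev
        if best is None or sol.cost < best.cost:
            best = sol

    n_bands = spectrum.size
    x = best.x
    return FitResult(
        params=TissueParams(float(10.0 ** x[0]), float(x[1]), float(x[2]),
                            float(x[3])),
        rmse=float(np.sqrt(2.0 * best.cost / n_bands)),
        iterations=int(total_nfev),
        converged=bool(best.success),
        objective_trace=np.asarray(trace),
    )


def fit_batch(
    spectra: np.ndarray,
    forward,
    ranges: SamplingRanges | None = None,
    seed: int = 0,
    **kwargs,
) -> list[FitResult]:
    """Fit many spectra with per-spectrum derived seeds."""
    spectra = np.atleast_2d(np.asarray(spectra, float))
    seeds = np.random.SeedSequence(seed).generate_state(spectra.shape[0])
    return [
        fit_spectrum(spec, forward, ranges, seed=int(s), **kwargs)
        for spec, s in zip(spectra, seeds)
    ]


def results_to_csv(results: list[FitResult], path):
    """One row per spectrum: parameters, RMSE, iterations, convergence."""
    with open(path, "w") as fh:
        fh.write("B,S,fm,a,rmse,iterations,converged\n")
        for r in results:
            p = r.params
            fh.write(
                f"{p.B:.6g},{p.S:.6g},{p.fm:.6g},{p.a:.6g},"
                f"{r.rmse:.6g},{r.iterations},{int(r.converged)}\n"
            )
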