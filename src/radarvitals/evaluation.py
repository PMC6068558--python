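"""Monte-Carlo benchmarking of the estimators.

Performance claims about stochastic optimizers are statements about
error *distributions*, so the harness repeats the full pipeline — draw a
scenario replicate, estimate, score — and summarizes each scored
component as an empirical CDF: P(error <= threshold) over replicates.
Replicates are seeded individually (draw seed ``master_seed + k``,
optimizer seed offset by 2**20 so the two never share a stream), which
makes results independent of execution order and embarrassingly
parallel.  A failed estimation (e.g. peak detection finding no peak) is
scored as +inf error rather than dropped, so the CDF stays an honest
fraction of *all* replicates.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
from joblib import Parallel, delayed

from .demodulation import arctangent_demod, magnitude_spectrum, peak_detect_rates
from .estimation import (
    EstimationResult,
    OptimizerSettings,
    ParameterBounds,
    estimate_ga,
    estimate_lsm,
    estimate_pso,
    estimation_error,
)
from .parallel_search import SubrangeScheme, parallel_pso_estimate
from .scenarios import Scenario, draw_scenario
from .signal_model import PhysioParams

__all__ = ["CDFResult", "run_benchmark", "cdf_at", "METHODS"]

METHODS = ("lsm", "ga", "pso", "pso_parallel", "peak_arctan")

#: Offset between a replicate's draw seed and its optimizer seed.
_OPT_SEED_OFFSET = 2**20


@dataclass(frozen=True)
class CDFResult:
    """Per-replicate errors and their empirical CDF for scored components.

    ``errors`` maps a component name to an array of per-replicate error
    values (percent, or component units where ``absolute_flags`` marks the
    true value as zero; +inf for outright failures).  ``estimates`` keeps
    the raw estimated values of the non-phase components for amplitude
    analyses (e.g. the apnea criterion on estimated mr).
    """

    errors: dict
    absolute_flags: dict
    estimates: dict
    metadata: dict = field(default_factory=dict)

    @property
    def n_replicates(self) -> int:
        return len(next(iter(self.errors.values())))

    def cdf_at(self, threshold: float, component: str = "fh") -> float:
        return cdf_at(self, threshold, component)

    def cdf_curve(self, component: str = "fh") -> tuple[np.ndarray, np.ndarray]:
        """Sorted finite thresholds and P(error <= threshold) at each."""
        err = np.asarray(self.errors[component], dtype=float)
        finite = np.sort(err[np.isfinite(err)])
        probs = np.searchsorted(np.sort(err), finite, side="right") / err.size
        return finite, probs

    def percentile(self, q: float, component: str = "fh") -> float:
        """The q-th percentile of the error distribution (inf-aware)."""
        err = np.asarray(self.errors[component], dtype=float)
        return float(np.percentile(err, q, method="higher"))

    def to_dict(self) -> dict:
        return {
            "errors": {k: np.asarray(v).tolist() for k, v in self.errors.items()},
            "absolute_flags": {
                k: np.asarray(v).astype(bool).tolist() for k, v in self.absolute_flags.items()
            },
            "estimates": {k: np.asarray(v).tolist() for k, v in self.estimates.items()},
            "metadata": self.metadata,
        }


def cdf_at(result: CDFResult, threshold: float, component: str = "fh") -> float:
    """Fraction of replicates with error <= threshold (percent units)."""
    if threshold < 0:
        raise ValueError("threshold must be nonnegative")
    err = np.asarray(result.errors[component], dtype=float)
    return float(np.mean(err <= threshold))


def _estimate_one(
    scenario: Scenario,
    replicate: int,
    method: str,
    domain: str,
    settings: OptimizerSettings,
    bounds: Optional[ParameterBounds],
    scheme: Optional[SubrangeScheme],
) -> tuple[PhysioParams, Optional[PhysioParams], Optional[EstimationResult]]:
    truth, sig = draw_scenario(scenario, replicate)
    cfg = scenario.radar_config
    opt_seed = scenario.master_seed + replicate + _OPT_SEED_OFFSET
    settings = replace(settings, seed=opt_seed)

    if method == "peak_arctan":
        spec = magnitude_spectrum(arctangent_demod(sig), sig.sample_rate)
        est = peak_detect_rates(spec)
        # a failed band search scores as +inf error for that rate only
        p = PhysioParams(
            mr=truth.mr,
            mh=truth.mh,
            fr=est.fr_hat if est.fr_ok else np.inf,
            fh=est.fh_hat if est.fh_ok else np.inf,
        )
        return truth, p, None
    if method == "lsm":
        res = estimate_lsm(sig, cfg, bounds, settings, domain=domain)
    elif method == "ga":
        res = estimate_ga(sig, cfg, bounds, settings, domain=domain)
    elif method == "pso":
        res = estimate_pso(sig, cfg, bounds, settings, domain=domain)
    elif method == "pso_parallel":
        res = parallel_pso_estimate(sig, cfg, scheme, settings, domain=domain)
    else:
        raise ValueError(f"unknown method {method!r}; expected one of {METHODS}")
    return truth, res.params, res


def run_benchmark(
    scenario: Scenario,
    method: str,
    domain: str = "time",
    settings: Optional[OptimizerSettings] = None,
    components: Sequence[str] = ("fh",),
    n_replicates: Optional[int] = None,
    bounds: Optional[ParameterBounds] = None,
    scheme: Optional[SubrangeScheme] = None,
    n_jobs: int = 1,
    verbose: bool = False,
) -> CDFResult:
    """Run a Monte-Carlo benchmark of one (scenario, method, domain) cell.

    Parameters
    ----------
    scenario
        The measurement conditions; ``n_replicates`` overrides its
        replicate count for desk-scale runs.
    method
        One of ``lsm``, ``ga``, ``pso``, ``pso_parallel`` or the direct
        spectral baseline ``peak_arctan`` (which ignores domain, settings,
        bounds and scheme).
    components
        Parameter names scored with the relative-percent error metric.
    bounds, scheme
        Search box for the single-box optimizers / subrange scheme for
        ``pso_parallel``; sensible defaults are used when omitted.
    n_jobs
        joblib workers for replicate-level parallelism; per-replicate
        seeding guarantees identical results for any value.
    """
    settings = settings or OptimizerSettings()
    n = n_replicates if n_replicates is not None else scenario.n_replicates
    if n_replicates is not None:
        scenario = scenario.with_(n_replicates=max(scenario.n_replicates, n_replicates))
    if method == "pso_parallel" and scheme is None:
        scheme = SubrangeScheme.default()

    tasks = (
        delayed(_estimate_one)(scenario, k, method, domain, settings, bounds, scheme)
        for k in range(n)
    )
    outcomes = Parallel(n_jobs=n_jobs, verbose=0)(tasks)

    comp_list = list(components)
    errors = {c: np.full(n, np.inf) for c in comp_list}
    flags = {c: np.zeros(n, dtype=bool) for c in comp_list}
    estimates = {c: np.full(n, np.nan) for c in ("mr", "mh", "fr", "fh")}
    costs = np.full(n, np.nan)
    for k, (truth, est, res) in enumerate(outcomes):
        if res is not None:
            costs[k] = res.final_cost
            if verbose:
                import sys

                print(
                    f"replicate {k}: seed={res.seed} cost={res.final_cost:.4g} "
                    f"converged={res.converged}",
                    file=sys.stderr,
                )
        if est is None:
            continue  # failure: errors stay +inf
        for c in comp_list:
            e = estimation_error(truth, est, c)
            errors[c][k] = e.value
            flags[c][k] = e.absolute
        for c in estimates:
            estimates[c][k] = getattr(est, c)

    metadata = {
        "scenario": scenario.to_dict(),
        "method": method,
        "domain": domain,
        "settings": settings.to_dict(),
        "n_replicates": n,
        "bounds": None if bounds is None else bounds.name,
        "scheme": None if scheme is None else [name for name, _ in scheme.boxes],
        "final_costs": costs.tolist(),
    }
    return CDFResult(errors=errors, absolute_flags=flags, estimates=estimates, metadata=metadata)
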