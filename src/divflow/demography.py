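"""SFS-based demographic inference for the two-population model ladder.

Fits each scenario (strict isolation through secondary contact with
asymmetric migration) to a folded joint SFS by maximising a Poisson
composite likelihood with analytically optimal theta scaling.  Expected
spectra come from the Monte Carlo structured-coalescent branch-length engine
(:mod:`divflow.simgen`), evaluated with common random numbers within one fit
so the objective is deterministic during optimisation.  The search combines
iterated conditional grid refinement over natural parameter pairs (global,
in log space with reflecting bounds) with a Nelder-Mead polish at high
replication; see :func:`fit_model`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize
from scipy.special import gammaln

from ._kernels import branch_length_sfs
from .models import (
    ConversionConstants,
    ConvertedParams,
    DemographicModel,
    SampleConfig,
    Scenario,
)
from .sfs import JointSFS, joint_sfs

__all__ = [
    "FitResult",
    "expected_sfs",
    "composite_loglik",
    "fit_model",
    "compare_models",
    "convert_units",
    "bootstrap_ci",
    "default_bounds",
]

MODEL_FLOOR = 1e-8  # floor for expected-SFS entries in the likelihood


def expected_sfs(
    model: DemographicModel,
    samples: SampleConfig,
    n_reps: int,
    seed: int,
    fold: bool = True,
    with_variance: bool = False,
) -> JointSFS:
    """Expected joint SFS per unit theta, optionally folded.

    With ``with_variance`` the returned spectrum carries a ``variance``
    attribute holding the per-cell Monte Carlo variance of the estimate
    (from 16 replicate batches, computed after folding so that the
    covariance of folded-together cells is handled exactly).  The
    likelihood uses it to cancel the model-dependent noise penalty.
    """
    if not with_variance:
        F = branch_length_sfs(samples.n1, samples.n2, model, n_reps, seed)
        spec = JointSFS(F, folded=False)
        return spec.fold() if fold else spec
    F, batches = branch_length_sfs(
        samples.n1, samples.n2, model, n_reps, seed, return_batches=True
    )
    spec = JointSFS(F, folded=False)
    if fold:
        from .sfs import fold_stack

        spec = spec.fold()
        stack = fold_stack(batches)
    else:
        stack = np.asarray(batches)
    B = stack.shape[0]
    var = stack.var(axis=0, ddof=1) / B if B > 1 else np.zeros_like(spec.data)
    spec.variance = var
    return spec


def composite_loglik(data: JointSFS, model: JointSFS) -> tuple[float, float]:
    """Poisson composite log-likelihood with optimal theta scaling.

    ``theta_hat = sum(data) / sum(model)`` over unmasked entries; the
    log-likelihood is ``sum(d * ln(theta_hat * m) - theta_hat * m - ln d!)``.
    Model entries are floored at a small positive value so that model-zero /
    data-positive cells contribute a large finite penalty rather than -inf.
    """
    if data.data.shape != model.data.shape:
        raise ValueError("data and model spectra have different shapes")
    if data.folded != model.folded:
        raise ValueError("data and model spectra differ in fold state")
    if not np.array_equal(data.mask, model.mask):
        raise ValueError("data and model spectra have different masks")
    keep = ~data.mask
    d = data.data[keep]
    m = model.data[keep]
    msum = m.sum()
    if msum <= 0:
        raise ValueError("model spectrum has no unmasked mass")
    theta_hat = float(d.sum() / msum)
    mm = theta_hat * np.maximum(m, MODEL_FLOOR)
    ll = float(np.sum(d * np.log(mm) - mm - gammaln(d + 1.0)))
    var = getattr(model, "variance", None)
    if var is not None:
        # cancel the leading-order Monte Carlo bias E[d ln m_hat] ~
        # d ln m - d Var(m_hat)/(2 m^2), which otherwise penalises models
        # whose spectra are estimated with more noise (long histories)
        rel = np.minimum(var[keep] / np.maximum(m, MODEL_FLOOR) ** 2, 1.0)
        ll += float(np.sum(d * rel) / 2.0)
    return ll, theta_hat


@dataclass
class FitResult:
    """Outcome of one multi-start composite-likelihood fit."""

    model: DemographicModel
    loglik: float
    theta_hat: float
    n_params: int
    starts: list[dict] = field(default_factory=list)
    converged: bool = True
    data_shape: tuple[int, int] | None = None

    @property
    def scenario(self) -> Scenario:
        return self.model.scenario

    def params_dict(self) -> dict[str, float]:
        return dict(zip(self.model.free_params, self.model.param_vector()))


#: Default (lower, upper) optimisation bounds per free parameter.
#: Ranges cover the plausible space for a pair of sister taxa under the
#: secondary-contact scenario: relative sizes within a factor ~20 of the
#: ancestral size, an isolation epoch that dominates the history (the
#: scenario's defining assumption), a contact epoch short relative to the
#: divergence, and scaled migration up to 2*N*m = 40.
DEFAULT_BOUNDS: dict[str, tuple[float, float]] = {
    "nu1": (0.08, 20.0),
    "nu2": (0.08, 20.0),
    "nu1_0": (0.08, 20.0),
    "nu2_0": (0.08, 20.0),
    "t_iso": (0.2, 20.0),
    "t_sc": (2e-3, 1.2),
    "m12": (0.2, 40.0),
    "m21": (0.2, 40.0),
    "m_sym": (0.2, 40.0),
}

#: Sign of each parameter in the coalescent scaling direction
#: (nu, T) -> (c nu, c T), M -> M / c, which leaves the sample SFS nearly
#: invariant except through the fixed ancestral size.  The likelihood valley
#: along this direction is searched explicitly during fitting.
_SCALING_SIGN = {
    "nu1": 1.0, "nu2": 1.0, "nu1_0": 1.0, "nu2_0": 1.0,
    "t_iso": 1.0, "t_sc": 1.0,
    "m12": -1.0, "m21": -1.0, "m_sym": -1.0,
}


def default_bounds(scenario: Scenario | str) -> list[tuple[float, float]]:
    from .models import FREE_PARAMS

    return [DEFAULT_BOUNDS[p] for p in FREE_PARAMS[Scenario(scenario)]]


def _reflect(x: np.ndarray, lo: np.ndarray, hi: np.ndarray) -> np.ndarray:
    """Fold unconstrained coordinates into [lo, hi] by reflection."""
    width = hi - lo
    y = np.mod(x - lo, 2.0 * width)
    y = np.where(y > width, 2.0 * width - y, y)
    return lo + y


def fit_model(
    data: JointSFS,
    scenario: Scenario | str,
    n_starts: int = 10,
    bounds: list[tuple[float, float]] | None = None,
    seed: int = 0,
    n_reps: int = 4000,
    n_reps_polish: int = 30_000,
    n_reps_local: int = 15_000,
    n_grid: int = 9,
    n_pass: int = 4,
    maxfev: int = 140,
    refine: bool = True,
    starts: list[np.ndarray] | None = None,
) -> FitResult:
    """Fit one scenario to a folded joint SFS by composite likelihood.

    The search runs in log-parameter space with reflecting ``bounds`` and a
    deterministic Monte Carlo objective (common random numbers: one
    simulation seed per stage of a fit), in two stages:

    1. *Iterated conditional grid refinement* (global): free parameters are
       grouped into natural pairs -- the two sizes, the two epoch durations,
       the two migration rates -- and each pass scans an ``n_grid x n_grid``
       log-grid over each pair (the other parameters held at the current
       optimum), jumps to the best cell, then line-searches along the
       coalescent scaling direction ``(nu, T) -> (c nu, c T), M -> M/c``,
       whose likelihood valley defeats purely local methods.  Grid spans
       halve each pass.  Scans use ``n_reps`` replicates per evaluation.
    2. *Polish*: Nelder-Mead from the grid optimum at ``n_reps_polish``
       replicates, where the Monte Carlo noise is small enough not to
       favour short-tree parameter regions.
    3. *Refine* (optional, default on): the valley's tilt is below the
       polish noise floor, so a wide scaling line search at ``4 x`` polish
       replication, pairwise re-scans and a short Nelder-Mead at ``2 x``
       polish replication crawl along the valley floor; the result is kept
       only if it is no worse at the highest replication.

    When explicit ``starts`` are given (natural-scale parameter vectors),
    stage 1 is skipped and Nelder-Mead runs from each start (used by the
    bootstrap, which refits from the MLE).
    """
    if not data.folded:
        raise ValueError("fit expects a folded data spectrum")
    scenario = Scenario(scenario)
    if bounds is None:
        bounds = default_bounds(scenario)
    lo = np.log(np.array([b[0] for b in bounds], dtype=float))
    hi = np.log(np.array([b[1] for b in bounds], dtype=float))
    if not (np.all(np.isfinite(lo)) and np.all(np.isfinite(hi)) and np.all(hi > lo)):
        raise ValueError("bounds must be finite, positive and ordered")
    ndim = len(lo)
    from .models import FREE_PARAMS

    param_names = FREE_PARAMS[scenario]
    if len(param_names) != ndim:
        raise ValueError(f"expected {len(param_names)} bounds for {scenario}")

    samples = SampleConfig(data.n1, data.n2)
    rng = np.random.default_rng(seed)
    sim_seed = int(rng.integers(2**31 - 1))  # CRN within the scan stage
    sim_seed_polish = int(rng.integers(2**31 - 1))

    def make_objective(reps: int, sseed: int):
        cache: dict[tuple, tuple[float, float]] = {}

        def objective(x) -> float:
            xr = _reflect(np.asarray(x, dtype=float), lo, hi)
            key = tuple(np.round(xr, 12))
            if key not in cache:
                model = DemographicModel.from_params(scenario, np.exp(xr))
                spec = expected_sfs(
                    model, samples, reps, sseed, fold=True, with_variance=True
                )
                cache[key] = composite_loglik(data, spec)
            return -cache[key][0]

        objective.cache = cache
        return objective

    trace: list[dict] = []
    obj_polish = make_objective(n_reps_polish, sim_seed_polish)
    obj_local = make_objective(n_reps_local, int(rng.integers(2**31 - 1)))

    if starts is not None:
        # local refits from supplied starts (bootstrap / warm starts)
        best_x, best_ll = None, -np.inf
        for k, s in enumerate(starts):
            x0 = np.clip(np.log(np.asarray(s, dtype=float)), lo, hi)
            simplex = np.vstack(
                [x0] + [x0 + 0.12 * np.eye(ndim)[i] for i in range(ndim)]
            )
            res = minimize(
                obj_polish, x0, method="Nelder-Mead",
                options={"maxfev": maxfev, "xatol": 1e-3, "fatol": 0.05,
                         "adaptive": True, "initial_simplex": simplex},
            )
            ll = -res.fun
            trace.append({"stage": "warm", "start": k, "loglik": ll,
                          "nfev": res.nfev, "converged": bool(res.success)})
            if ll > best_ll:
                best_x, best_ll = _reflect(res.x, lo, hi), ll
        x_best = best_x
    else:
        obj = make_objective(n_reps, sim_seed)
        sign = np.array([_SCALING_SIGN[p] for p in param_names])
        pairs = [tuple(range(i, min(i + 2, ndim))) for i in range(0, ndim, 2)]
        x = 0.5 * (lo + hi)
        span = (hi - lo) / 2.0
        for _p in range(n_pass):
            for pair in pairs:
                best_v, best_y = obj(x), x.copy()
                axes = [
                    np.linspace(max(lo[i], x[i] - span[i]),
                                min(hi[i], x[i] + span[i]), n_grid)
                    for i in pair
                ]
                if len(pair) == 2:
                    for a in axes[0]:
                        for b in axes[1]:
                            y = x.copy()
                            y[pair[0]] = a
                            y[pair[1]] = b
                            v = obj(y)
                            if v < best_v:
                                best_v, best_y = v, y
                else:
                    for a in axes[0]:
                        y = x.copy()
                        y[pair[0]] = a
                        v = obj(y)
                        if v < best_v:
                            best_v, best_y = v, y
                x = best_y
            cs = np.linspace(-0.7, 0.7, 11)
            vals = [obj(x + c * sign) for c in cs]
            x = _reflect(x + cs[int(np.argmin(vals))] * sign, lo, hi)
            span = np.maximum(span * 0.5, 0.12)
        trace.append({"stage": "grid", "loglik": -obj(x),
                      "params": np.exp(x).tolist()})

        simplex = np.vstack([x] + [x + 0.1 * np.eye(ndim)[i] for i in range(ndim)])
        res = minimize(
            obj_local, x, method="Nelder-Mead",
            options={"maxfev": maxfev, "xatol": 1e-3, "fatol": 0.05,
                     "adaptive": True, "initial_simplex": simplex},
        )
        x_best = _reflect(res.x, lo, hi)
        trace.append({"stage": "polish", "loglik": -res.fun, "nfev": res.nfev,
                      "converged": bool(res.success)})

        if refine:
            # The valley's tilt is only a few tens of log-likelihood units
            # over large displacements along the near-degenerate scaling
            # direction, so crawl along the curved valley floor at high
            # replication with the bias-corrected objective: a 2-D scan over
            # (scaling c) x (residual on the dominant time parameter) -- the
            # plane in which the floor curves -- then a local re-scan of the
            # epoch pair and a short Nelder-Mead; two rounds with shrinking
            # spans.
            obj_ref = make_objective(int(1.7 * n_reps_polish),
                                     int(rng.integers(2**31 - 1)))
            obj_guard = make_objective(4 * n_reps_polish,
                                       int(rng.integers(2**31 - 1)))
            t_name = "t_iso" if "t_iso" in param_names else "t_sc"
            et = np.eye(ndim)[param_names.index(t_name)]
            tpair = [i for i, p in enumerate(param_names)
                     if p in ("t_iso", "t_sc")]
            x = x_best
            prev = obj_ref(x)
            rounds = ((0.9, 0.35, 7, 7), (0.4, 0.2, 5, 5))
            for c_span, t_span, nc, nt in rounds:
                best_v, best_y = obj_ref(x), x.copy()
                for c in np.linspace(-c_span, c_span, nc):
                    for r in np.linspace(-t_span, t_span, nt):
                        y = _reflect(x + c * sign + r * et, lo, hi)
                        v = obj_ref(y)
                        if v < best_v:
                            best_v, best_y = v, y
                x = best_y
                best_v, best_y = obj_ref(x), x.copy()
                for a in np.linspace(max(lo[tpair[0]], x[tpair[0]] - 0.25),
                                     min(hi[tpair[0]], x[tpair[0]] + 0.25), 5):
                    bs = (
                        np.linspace(max(lo[tpair[1]], x[tpair[1]] - 0.25),
                                    min(hi[tpair[1]], x[tpair[1]] + 0.25), 5)
                        if len(tpair) == 2 else [None]
                    )
                    for b in bs:
                        y = x.copy()
                        y[tpair[0]] = a
                        if b is not None:
                            y[tpair[1]] = b
                        v = obj_ref(y)
                        if v < best_v:
                            best_v, best_y = v, y
                x = best_y
                lo2 = np.maximum(lo, x - 0.6)
                hi2 = np.minimum(hi, x + 0.6)

                def obj_local_box(z, _l=lo2, _h=hi2):
                    return obj_ref(_reflect(np.asarray(z, float), _l, _h))

                simplex = np.vstack(
                    [x] + [x + 0.08 * np.eye(ndim)[i] for i in range(ndim)]
                )
                res = minimize(
                    obj_local_box, x, method="Nelder-Mead",
                    options={"maxfev": 40, "xatol": 1e-3, "fatol": 0.05,
                             "adaptive": True, "initial_simplex": simplex},
                )
                x = _reflect(_reflect(np.asarray(res.x, float), lo2, hi2), lo, hi)
                cur = obj_ref(x)
                if prev - cur < 12.0:  # converged along the valley floor
                    break
                prev = cur
            # keep the refined point only if no worse at guard precision
            if obj_guard(x) <= obj_guard(x_best):
                x_best = x
            trace.append({"stage": "refine", "loglik": -obj_guard(x_best),
                          "params": np.exp(x_best).tolist()})

    ll = -obj_polish(x_best)
    theta = obj_polish.cache[tuple(np.round(x_best, 12))][1]
    params = np.exp(x_best)
    model = DemographicModel.from_params(scenario, params)
    return FitResult(
        model=model,
        loglik=ll,
        theta_hat=theta,
        n_params=len(params),
        starts=trace,
        converged=True,
        data_shape=data.data.shape,
    )



def compare_models(fits: list[FitResult]) -> list[FitResult]:
    """Rank fits of the same data by log-likelihood (ties: fewer parameters)."""
    if not fits:
        raise ValueError("no fits to compare")
    shapes = {f.data_shape for f in fits}
    if len(shapes) > 1:
        raise ValueError("fits were produced on different data spectra")
    return sorted(fits, key=lambda f: (-f.loglik, f.n_params))


def convert_units(fit: FitResult, consts: ConversionConstants) -> ConvertedParams:
    """Convert a fit from coalescent units to individuals and years.

    ``N_ref = theta_hat / (4 mu L_eff)``; sizes scale by ``nu``; times scale
    by ``2 N_ref`` generations times the generation time; migration rates
    are ``m_ij = M_ij / (2 N_ref)`` per generation.
    """
    if fit.theta_hat <= 0:
        raise ValueError("theta_hat must be > 0")
    m = fit.model
    N_ref = fit.theta_hat / (4.0 * consts.mu * consts.L_eff)
    years_per_unit = 2.0 * N_ref * consts.gen_time
    return ConvertedParams(
        N_ref=N_ref,
        N1=m.nu1 * N_ref,
        N2=m.nu2 * N_ref,
        T_div_years=m.t_div * years_per_unit,
        T_sc_years=m.t_sc * years_per_unit,
        m12=m.m12 / (2.0 * N_ref),
        m21=m.m21 / (2.0 * N_ref),
    )


def bootstrap_ci(
    data,
    scenario: Scenario | str,
    mle: FitResult,
    n_boot: int = 10,
    n_snps: int | None = None,
    seed: int = 0,
    n_reps: int = 20_000,
    ci: float = 0.95,
) -> dict:
    """Percentile bootstrap CIs by SNP resampling and one-start refits.

    ``data`` may be a :class:`JointSFS` or a genotype matrix (converted with
    :func:`divflow.sfs.joint_sfs`).  Each iteration draws ``n_snps`` SNPs
    i.i.d. with replacement (a multinomial resample of the spectrum),
    refolds, and refits the scenario from the MLE as the single start.
    Failed refits are recorded and excluded; if every refit fails an error
    is raised.
    """
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    if not isinstance(data, JointSFS):
        data = joint_sfs(data)
    spec = data if data.folded else data.fold()
    keep = ~spec.mask
    probs = spec.data[keep]
    total = probs.sum()
    if total <= 0:
        raise ValueError("empty data spectrum")
    probs = probs / total
    if n_snps is None:
        n_snps = int(round(total))

    rng = np.random.default_rng(seed)
    start = np.asarray(mle.model.param_vector(), dtype=float)
    param_names = list(mle.model.free_params)
    draws: list[dict] = []
    failures = 0
    for b in range(n_boot):
        counts = rng.multinomial(n_snps, probs)
        boot = JointSFS(np.zeros_like(spec.data), folded=True, mask=spec.mask.copy())
        boot.data[keep] = counts
        try:
            fit = fit_model(
                boot,
                scenario,
                bounds=None,
                seed=int(rng.integers(2**31 - 1)),
                n_reps=n_reps,
                n_reps_polish=n_reps,
                starts=[start],
            )
        except Exception:  # noqa: BLE001 - refit failure recorded, not fatal
            failures += 1
            continue
        rec = fit.params_dict()
        rec["theta_hat"] = fit.theta_hat
        rec["loglik"] = fit.loglik
        draws.append(rec)
    if not draws:
        raise RuntimeError("all bootstrap refits failed")
    alpha = (1.0 - ci) / 2.0
    intervals = {}
    for name in param_names + ["theta_hat"]:
        vals = np.array([d[name] for d in draws])
        intervals[name] = (
            float(np.quantile(vals, alpha)),
            float(np.quantile(vals, 1.0 - alpha)),
        )
    return {"intervals": intervals, "draws": draws, "n_failures": failures}
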