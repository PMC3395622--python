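"""Model fitting: cost functions, simulated annealing, quality control.

The fit minimises the weighted least-squares cost

    S(theta) = sum_t sum_i sum_a v_i^a(t) * (model - data)^2

over the free parameters of a circuit (OLS is the special case v = 1).
Goodness of fit is reported as the weight-independent root mean square
RMS = sqrt(sum (model - data)^2 / N_d), which is comparable across OLS/WLS
fits and datasets.

Global optimisation uses a serial adaptive Lam-schedule simulated annealer:
move scales adapt per coordinate and the temperature is steered so the
acceptance rate follows the Lam-Delosme target trajectory (a warm phase,
a long 0.44-acceptance plateau, and a cooling tail that ends in greedy
descent).  A differential-evolution backend (scipy) is available behind the
same contract.

Candidate solutions are screened automatically: solver sensitivity
(re-solving at tightened tolerances), brittleness (cost response to 0.1%
parameter perturbations), and expression-defect heuristics (missing domains,
ectopic domains, wrong domain order) replace the visual inspection used for
ensemble selection.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import differential_evolution, least_squares

from .circuit_model import CircuitParameters, DivisionSchedule
from .dataprep import ExpressionDataset
from .simulator import (
    SimulationError,
    StateMatrix,
    Trajectory,
    initial_conditions,
    sample_at,
    simulate,
)

__all__ = [
    "FitConfig",
    "FitResult",
    "QCReport",
    "QCThresholds",
    "CircuitObjective",
    "cost",
    "rms",
    "fit_lam_sa",
    "anneal",
    "qc_screen",
    "default_bounds",
]

#: Scale-free default parameter bounds on the x200 concentration scale.
DEFAULT_BOUNDS = {
    "W": (-0.3, 0.3),
    "E": (-0.3, 0.3),
    "R": (0.01, 30.0),
    "D": (0.0, 0.3),
    "lam": (0.005, 0.3),
    "h": (-5.0, 5.0),
}

#: Penalty cost per data point for failed simulations during optimisation.
PENALTY_PER_POINT = 1.0e6


def default_bounds(params: CircuitParameters, bounds: dict | None = None
                   ) -> np.ndarray:
    """(p, 2) bounds array aligned with the circuit's free parameters."""
    table = dict(DEFAULT_BOUNDS)
    if bounds:
        table.update(bounds)
    return np.array([table[block] for block, _ in params.free_entries()])


def default_schedule(dataset: ExpressionDataset) -> DivisionSchedule:
    """The standard gap-gene schedule when the dataset uses the standard time
    classes, otherwise a division-free schedule spanning the data times."""
    times = dataset.data_times
    if "C13" in times and "T8" in times:
        return DivisionSchedule(data_times=times)
    t_end = max(times.values())
    return DivisionSchedule(t_start=0.0, t_end=t_end, mitosis=None,
                            data_times=times)


class CircuitObjective:
    """Cost evaluation context binding a dataset, inputs and a circuit mask."""

    def __init__(self, dataset: ExpressionDataset, inputs,
                 template: CircuitParameters,
                 schedule: DivisionSchedule | None = None,
                 initial_state: StateMatrix | None = None,
                 solver_options: dict | None = None,
                 mode: str = "WLS"):
        if mode not in ("OLS", "WLS"):
            raise ValueError(f"mode must be OLS or WLS, got {mode!r}")
        self.dataset = dataset
        self.inputs = inputs
        self.template = template
        self.schedule = schedule or default_schedule(dataset)
        if initial_state is None:
            if "C13" in dataset.time_classes:
                initial_state = initial_conditions(dataset,
                                                   t0=self.schedule.t_start)
            else:
                lat = dataset.lattice_of(dataset.time_classes[0])
                initial_state = StateMatrix(
                    np.zeros((dataset.spec.n_genes, lat.n_nuclei)), lat,
                    self.schedule.t_start)
        self.initial_state = initial_state
        self.solver_options = solver_options
        self.mode = mode
        self.y = dataset.values
        self.v = dataset.weights if mode == "WLS" else np.ones(dataset.n_points)
        self.n_evals = 0

    @property
    def n_points(self) -> int:
        return self.dataset.n_points

    def params_from_vector(self, vec) -> CircuitParameters:
        return self.template.with_vector(vec)

    def simulate_params(self, params: CircuitParameters,
                        solver_options: dict | None = None) -> Trajectory:
        return simulate(params.spec, params, self.inputs, self.schedule,
                        self.initial_state,
                        solver_options or self.solver_options)

    def model_values(self, params: CircuitParameters,
                     solver_options: dict | None = None) -> np.ndarray:
        traj = self.simulate_params(params, solver_options)
        times = [self.dataset.data_times[tc] for tc in self.dataset.time_classes]
        return sample_at(traj, times)

    def residuals(self, params: CircuitParameters) -> np.ndarray:
        return self.model_values(params) - self.y

    def weighted_residuals(self, params: CircuitParameters) -> np.ndarray:
        return np.sqrt(self.v) * self.residuals(params)

    def cost_params(self, params: CircuitParameters) -> float:
        try:
            r = self.residuals(params)
        except (SimulationError, ValueError):
            return PENALTY_PER_POINT * self.n_points
        finally:
            self.n_evals += 1
        return float(np.sum(self.v * r * r))

    def cost_vector(self, vec) -> float:
        try:
            params = self.params_from_vector(vec)
        except ValueError:
            return PENALTY_PER_POINT * self.n_points
        return self.cost_params(params)

    def rms_params(self, params: CircuitParameters) -> float:
        if self.n_points == 0:
            raise ValueError("empty dataset: RMS undefined")
        r = self.residuals(params)
        return float(np.sqrt(np.sum(r * r) / self.n_points))


def cost(params: CircuitParameters, dataset: ExpressionDataset, inputs,
         mode: str = "WLS", **kwargs) -> float:
    """WLS (or OLS) cost of a circuit against a dataset.

    With all weights equal to 1 (mode OLS) this is the ordinary
    least-squares cost; a failed simulation yields a large finite penalty
    (PENALTY_PER_POINT per data point) so annealing can reject the move.
    """
    return CircuitObjective(dataset, inputs, params, mode=mode,
                            **kwargs).cost_params(params)


def rms(params: CircuitParameters, dataset: ExpressionDataset, inputs,
        **kwargs) -> float:
    """Root mean square of unweighted residuals; independent of weights."""
    return CircuitObjective(dataset, inputs, params, **kwargs).rms_params(params)


# ---------------------------------------------------------------------------
# Lam-schedule simulated annealing
# ---------------------------------------------------------------------------


@dataclass
class FitConfig:
    """Optimiser configuration.

    The Lam schedule steers the Metropolis acceptance rate along the
    classic target trajectory (warm start decaying to a 0.44 plateau, then
    a cooling tail); the final ``greedy_frac`` of moves accept improvements
    only.  Move scales adapt per coordinate toward the plateau acceptance.
    """

    mode: str = "WLS"
    optimizer: str = "lam_sa"       # "lam_sa", "de" or "trf_multistart"
    n_moves: int = 20000
    warmup: int = 200
    greedy_frac: float = 0.05       # final fraction of moves run greedily
    initial_scale: float = 0.25     # move scale as fraction of bound width
    acceptance_plateau: float = 0.44
    temperature_gain: float = 0.05
    scale_gain: float = 0.05
    trace_every: int = 200
    bounds: dict | None = None
    solver_options: dict | None = field(
        default_factory=lambda: {"rtol": 1e-4, "atol": 1e-6})
    de_maxiter: int = 60
    de_popsize: int = 12
    n_starts: int = 10              # restarts for the multistart backend
    polish: bool = True             # trust-region least-squares refinement
    polish_max_nfev: int = 800


@dataclass
class QCThresholds:
    """Acceptance thresholds for automated solution screening."""

    solver_sensitivity: float = 1.0   # max |Delta output| at tolerances / 10
    brittleness: float = 1.0          # max |Delta RMS| under 0.1% perturbation
    defect_low: float = 0.1           # "not expressed" fraction of slice max
    defect_high: float = 0.5          # "expressed" fraction of slice max


@dataclass
class QCReport:
    solver_sensitivity: float
    brittleness: float
    missing_domain: dict
    ectopic_domain: dict
    order_violation: dict
    passed: bool

    @property
    def any_defect(self) -> bool:
        return (any(self.missing_domain.values())
                or any(self.ectopic_domain.values())
                or any(self.order_violation.values()))


@dataclass
class FitResult:
    params: CircuitParameters
    cost: float
    rms: float
    mode: str
    seed: int
    trace: list                      # (iteration, temperature, cost)
    n_evals: int
    qc: QCReport | None = None
    objective: CircuitObjective | None = None

    def to_json_dict(self) -> dict:
        import json
        doc = {
            "mode": self.mode,
            "seed": self.seed,
            "cost": self.cost,
            "rms": self.rms,
            "n_evals": self.n_evals,
            "params": json.loads(self.params.to_json()),
            "trace_length": len(self.trace),
        }
        if self.qc is not None:
            doc["qc"] = {
                "solver_sensitivity": self.qc.solver_sensitivity,
                "brittleness": self.qc.brittleness,
                "passed": self.qc.passed,
            }
        return doc


def _lam_target(frac: float, plateau: float = 0.44) -> float:
    """Modified-Lam acceptance-rate target trajectory."""
    if frac < 0.15:
        return plateau + (1.0 - plateau) * 560.0 ** (-frac / 0.15)
    if frac < 0.65:
        return plateau
    return plateau * 440.0 ** (-(frac - 0.65) / 0.35)


def anneal(func, bounds, seed: int, config: FitConfig | None = None,
           x0=None):
    """Adaptive Lam-schedule simulated annealing on a bounded vector.

    Returns (x_best, f_best, trace).  Deterministic given the seed.
    """
    cfg = config or FitConfig()
    bounds = np.asarray(bounds, dtype=float)
    lo, hi = bounds[:, 0], bounds[:, 1]
    width = hi - lo
    p = len(bounds)
    rng = np.random.default_rng(seed)

    x = np.asarray(x0, dtype=float) if x0 is not None else lo + rng.random(p) * width
    fx = func(x)
    best_x, best_f = x.copy(), fx
    scales = np.full(p, cfg.initial_scale)

    # warm-up: Metropolis at a temperature from observed uphill steps
    deltas = []
    xw = x.copy()
    fw = fx
    n_acc_warm = 0
    for _ in range(max(cfg.warmup, 2 * p)):
        j = rng.integers(p)
        cand = xw.copy()
        cand[j] = np.clip(cand[j] + scales[j] * width[j] * rng.standard_normal(),
                          lo[j], hi[j])
        fc = func(cand)
        deltas.append(abs(fc - fw))
        if fc <= fw:
            xw, fw = cand, fc
            n_acc_warm += 1
            if fw < best_f:
                best_x, best_f = xw.copy(), fw
    T = max(float(np.mean(deltas)), 1e-12) * 3.0
    if n_acc_warm == 0:
        raise RuntimeError(
            "no accepted move during warm-up; widen the move scale "
            "(FitConfig.initial_scale) or check the objective"
        )
    x, fx = xw, fw

    acc_est = 1.0
    acc_coord = np.full(p, cfg.acceptance_plateau)
    trace = [(0, T, fx)]
    ema = 2.0 / 500.0
    for k in range(cfg.n_moves):
        frac = k / cfg.n_moves
        greedy = frac >= 1.0 - cfg.greedy_frac
        target = _lam_target(frac, cfg.acceptance_plateau)
        j = int(rng.integers(p))
        cand = x.copy()
        cand[j] = np.clip(cand[j] + scales[j] * width[j] * rng.standard_normal(),
                          lo[j], hi[j])
        fc = func(cand)
        if greedy:
            accept = fc <= fx
        else:
            accept = fc <= fx or rng.random() < np.exp(-(fc - fx) / T)
        if accept:
            x, fx = cand, fc
            if fx < best_f:
                best_x, best_f = x.copy(), fx
        acc_est += ema * ((1.0 if accept else 0.0) - acc_est)
        acc_coord[j] += 0.1 * ((1.0 if accept else 0.0) - acc_coord[j])
        if not greedy:
            T *= np.exp(-cfg.temperature_gain * (acc_est - target))
            T = max(T, 1e-300)
        scales[j] *= np.exp(
            cfg.scale_gain * (acc_coord[j] - cfg.acceptance_plateau))
        scales[j] = float(np.clip(scales[j], 1e-6, 2.0))
        if (k + 1) % cfg.trace_every == 0:
            trace.append((k + 1, T, fx))
    trace.append((cfg.n_moves, T, fx))
    return best_x, best_f, trace


def fit_lam_sa(dataset: ExpressionDataset, inputs, config: FitConfig,
               seed: int, template: CircuitParameters,
               schedule: DivisionSchedule | None = None,
               initial_state: StateMatrix | None = None) -> FitResult:
    """Fit a gene circuit to a dataset by global optimisation.

    ``template`` supplies the network spec and the parameter mask; its free
    entries are re-initialised uniformly within bounds from the seed.
    Deterministic given the seed.  ``config.optimizer`` selects the
    Lam-schedule annealer (default) or scipy differential evolution behind
    the same contract.
    """
    obj = CircuitObjective(dataset, inputs, template, schedule=schedule,
                           initial_state=initial_state,
                           solver_options=config.solver_options,
                           mode=config.mode)
    bounds = default_bounds(template, config.bounds)
    rng = np.random.default_rng(seed)
    x0 = bounds[:, 0] + rng.random(len(bounds)) * (bounds[:, 1] - bounds[:, 0])

    def weighted_residual_vec(vec):
        try:
            r = np.sqrt(obj.v) * (obj.model_values(obj.params_from_vector(vec))
                                  - obj.y)
        except (SimulationError, ValueError):
            return np.full(obj.n_points, np.sqrt(PENALTY_PER_POINT))
        return r

    def trf_refine(x_start):
        res = least_squares(
            weighted_residual_vec, x_start,
            bounds=(bounds[:, 0], bounds[:, 1]), method="trf",
            diff_step=1e-4, max_nfev=config.polish_max_nfev,
        )
        return res.x, float(2.0 * res.cost)

    if config.optimizer == "lam_sa":
        x_best, f_best, trace = anneal(obj.cost_vector, bounds, seed,
                                       config, x0=x0)
        if config.polish:
            x_ref, f_ref = trf_refine(x_best)
            if f_ref < f_best:
                x_best, f_best = x_ref, f_ref
            trace.append((config.n_moves, 0.0, f_best))
    elif config.optimizer == "de":
        res = differential_evolution(
            obj.cost_vector, bounds, seed=int(seed), maxiter=config.de_maxiter,
            popsize=config.de_popsize, tol=1e-8, polish=False, init="sobol",
        )
        x_best, f_best = res.x, float(res.fun)
        if config.polish:
            x_ref, f_ref = trf_refine(x_best)
            if f_ref < f_best:
                x_best, f_best = x_ref, f_ref
        trace = [(int(res.nit), 0.0, f_best)]
    elif config.optimizer == "trf_multistart":
        # seeded random restarts of bounded trust-region least squares
        x_best, f_best, trace = None, np.inf, []
        for k in range(config.n_starts):
            xs = x0 if k == 0 else (
                bounds[:, 0] + rng.random(len(bounds))
                * (bounds[:, 1] - bounds[:, 0]))
            x_ref, f_ref = trf_refine(xs)
            trace.append((k, 0.0, f_ref))
            if f_ref < f_best:
                x_best, f_best = x_ref, f_ref
    else:
        raise ValueError(f"unknown optimizer {config.optimizer!r}")

    params = obj.params_from_vector(x_best)
    final_cost = obj.cost_params(params)
    return FitResult(
        params=params, cost=final_cost, rms=obj.rms_params(params),
        mode=config.mode, seed=seed, trace=trace, n_evals=obj.n_evals,
        objective=obj,
    )


# ---------------------------------------------------------------------------
# Automated quality control
# ---------------------------------------------------------------------------


def _defect_flags(dataset: ExpressionDataset, model_by_tc: dict,
                  lo: float, hi: float):
    missing, ectopic, order = {}, {}, {}
    genes = dataset.spec.gap_genes
    for tc in dataset.time_classes:
        d = dataset.slice_matrix(tc)
        m = model_by_tc[tc]
        data_order, model_order = [], []
        for gi, gene in enumerate(genes):
            dmax = d[gi].max()
            if dmax <= 0:
                continue
            expressed = d[gi] > hi * dmax
            silent = d[gi] < lo * dmax
            missing[(gene, tc)] = bool(np.any(expressed & (m[gi] < lo * dmax)))
            ectopic[(gene, tc)] = bool(np.any(silent & (m[gi] > hi * dmax)))
            data_order.append((int(np.argmax(d[gi])), gene))
            model_order.append((int(np.argmax(m[gi])), gene))
        order[tc] = ([g for _, g in sorted(data_order)]
                     != [g for _, g in sorted(model_order)])
    return missing, ectopic, order


def qc_screen(fit: FitResult, dataset: ExpressionDataset | None = None,
              thresholds: QCThresholds | None = None) -> QCReport:
    """Screen a fitted circuit for numerical and patterning problems.

    Solver sensitivity re-solves at tolerances tightened by a factor of 10
    and reports the largest change in sampled model output.  Brittleness
    perturbs each free parameter by +-0.1% and reports the largest RMS
    change.  Defect heuristics flag, per gene and time class, domains
    missing from the model where the data show expression, ectopic model
    expression where the data are silent, and changes in the A-P order of
    the genes' expression maxima.
    """
    if fit.objective is None:
        raise ValueError("fit carries no objective context; refit or rebuild")
    obj = fit.objective
    dataset = dataset or obj.dataset
    thr = thresholds or QCThresholds()
    params = fit.params

    base = obj.model_values(params)
    opts = dict(obj.solver_options or {})
    tight = {**opts,
             "rtol": opts.get("rtol", 1e-6) / 10.0,
             "atol": opts.get("atol", 1e-8) / 10.0}
    sens = float(np.max(np.abs(obj.model_values(params, tight) - base)))

    rms0 = obj.rms_params(params)
    britt = 0.0
    vec = params.to_vector()
    for j in range(len(vec)):
        for sign in (-1.0, 1.0):
            pert = vec.copy()
            step = 1e-3 * (abs(pert[j]) if pert[j] != 0 else 1e-3)
            pert[j] += sign * step
            try:
                r = obj.rms_params(obj.params_from_vector(pert))
            except (SimulationError, ValueError):
                r = np.inf
            britt = max(britt, abs(r - rms0))

    model_by_tc = {}
    pos = 0
    for tc in dataset.time_classes:
        n = dataset.slice_matrix(tc).size
        model_by_tc[tc] = base[pos:pos + n].reshape(dataset.slice_matrix(tc).shape)
        pos += n
    missing, ectopic, order = _defect_flags(dataset, model_by_tc,
                                            thr.defect_low, thr.defect_high)

    report = QCReport(
        solver_sensitivity=sens,
        brittleness=britt,
        missing_domain=missing,
        ectopic_domain=ectopic,
        order_violation=order,
        passed=False,
    )
    report.passed = (sens <= thr.solver_sensitivity
                     and britt <= thr.brittleness
                     and not report.any_defect)
    return report
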