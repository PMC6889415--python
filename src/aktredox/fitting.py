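"""Genetic-algorithm parameter estimation for the Akt redox model.

Fitting minimizes an SEM-weighted sum of squared residuals between
simulated observables and time-course measurements, with an analytically
profiled linear scale factor for observables recorded in arbitrary units
(immunoblot or TIRF intensities). The optimizer is a real-coded genetic
algorithm over log10-transformed rate constants — tournament selection,
SBX crossover, Gaussian log-space mutation, elitism — optionally followed
by a Nelder-Mead polish of the winner. Several independent restarts are
kept and predictions are averaged across the best-fitted parameter sets,
reported as mean ± SEM over fits.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy.optimize import minimize

from .network import ParameterSet, ReactionNetwork
from .simulate import Protocol, SimulationError, simulate

logger = logging.getLogger(__name__)


@dataclass
class FitDataset:
    """Time-course training data: per (protocol, observable) means ± SEM.

    ``data`` columns: protocol_id, observable, time, mean, sem, n.
    ``protocols`` maps protocol_id to the :class:`Protocol` that produced
    it. ``scale_mode`` marks each observable ``"absolute"`` (compared
    directly) or ``"scaled"`` (arbitrary units; a linear scale factor is
    profiled out analytically).
    """

    data: pd.DataFrame
    protocols: dict
    scale_mode: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        required = {"protocol_id", "observable", "time", "mean", "sem", "n"}
        missing = required - set(self.data.columns)
        if missing:
            raise ValueError(f"dataset lacks columns {sorted(missing)}")
        if self.data.empty:
            raise ValueError("empty dataset")
        self.data = self.data.reset_index(drop=True)
        unknown = set(self.data["protocol_id"]) - set(self.protocols)
        if unknown:
            raise ValueError(f"no protocol supplied for ids {sorted(unknown)}")
        for pid, proto in self.protocols.items():
            sel = self.data["protocol_id"] == pid
            if sel.any() and self.data.loc[sel, "time"].max() > proto.horizon + 1e-9:
                raise ValueError(f"data time beyond horizon of protocol {pid!r}")

    def weights(self) -> np.ndarray:
        """1/SEM weights; non-positive or missing SEMs get the observable's
        median positive SEM (or 1 if none exists)."""
        sem = self.data["sem"].to_numpy(dtype=float).copy()
        for obs in self.data["observable"].unique():
            sel = (self.data["observable"] == obs).to_numpy()
            good = sem[sel] > 0
            fill = np.median(sem[sel][good]) if good.any() else 1.0
            bad = sel & ~(sem > 0)
            sem[bad] = fill
        return 1.0 / sem

    def to_csv(self, path: str | Path) -> None:
        self.data.to_csv(path, index=False)


def objective(
    params: ParameterSet,
    dataset: FitDataset,
    network: ReactionNetwork,
    rtol: float = 1e-6,
    atol: float = 1e-9,
) -> float:
    """SEM-weighted chi-square of the model against the dataset.

    For observables flagged ``"scaled"`` the data are mapped into model
    units by a linear factor profiled out analytically
    (``beta = sum(w^2 m y) / sum(w^2 y^2)``, minimizing
    ``sum(w^2 (m - beta y)^2)``), making the score invariant to the
    data's arbitrary units. Failed simulations score +inf.
    """
    w = dataset.weights()
    score = 0.0
    for pid, block in dataset.data.groupby("protocol_id", sort=False):
        proto = dataset.protocols[pid]
        try:
            tc = simulate(network, params, proto, rtol=rtol, atol=atol)
        except SimulationError as exc:
            logger.info("objective: simulation failed for %s (%s)", pid, exc)
            return np.inf
        for obs, sub in block.groupby("observable", sort=False):
            model = np.interp(sub["time"].to_numpy(), tc.time, tc.observable(obs))
            y = sub["mean"].to_numpy(dtype=float)
            wi = w[sub.index.to_numpy()]
            if dataset.scale_mode.get(obs, "absolute") == "scaled":
                denom = np.sum((wi * y) ** 2)
                beta = np.sum(wi**2 * model * y) / denom if denom > 0 else 1.0
                y = beta * y
            score += float(np.sum((wi * (model - y)) ** 2))
    return score


@dataclass
class GAConfig:
    population: int = 200
    generations: int = 500
    tournament_size: int = 3
    crossover_p: float = 0.9
    crossover_eta: float = 10.0
    mutation_p: float = 0.1
    mutation_sigma: float = 0.2
    elitism: int = 2
    polish: bool = True

    def __post_init__(self) -> None:
        if self.population < 2 or self.generations < 1:
            raise ValueError("population >= 2 and generations >= 1 required")
        if self.elitism >= self.population:
            raise ValueError("elitism must be smaller than the population")


@dataclass
class FitResult:
    params: ParameterSet
    objective: float
    trace: pd.DataFrame  # generation, best, mean
    seed: int
    bounds: dict
    fitted_names: list

    def to_file(self, path: str | Path) -> None:
        payload = {
            "objective": float(self.objective),
            "seed": int(self.seed),
            "fitted_names": list(self.fitted_names),
            "bounds": {k: [float(v[0]), float(v[1])] for k, v in self.bounds.items()},
            "rates": {k: float(v) for k, v in self.params.rates.items()},
            "totals": {
                "akt_total": self.params.akt_total,
                "ir_total": self.params.ir_total,
                "nox_total": self.params.nox_total,
                "sub_total": self.params.sub_total,
            },
            "dpi_ki": float(self.params.dpi_ki),
            "bcnu_af_reduction_factor": float(self.params.bcnu_af_reduction_factor),
            "trace": self.trace.to_dict(orient="list"),
        }
        Path(path).write_text(yaml.safe_dump(payload, sort_keys=True))

    @classmethod
    def from_file(cls, path: str | Path) -> "FitResult":
        payload = yaml.safe_load(Path(path).read_text())
        params = ParameterSet(
            rates=payload["rates"],
            dpi_ki=payload["dpi_ki"],
            bcnu_af_reduction_factor=payload["bcnu_af_reduction_factor"],
            **payload["totals"],
        )
        return cls(
            params=params,
            objective=payload["objective"],
            trace=pd.DataFrame(payload["trace"]),
            seed=payload["seed"],
            bounds={k: tuple(v) for k, v in payload["bounds"].items()},
            fitted_names=payload["fitted_names"],
        )


DEFAULT_LOG10_BOUNDS = (-4.0, 3.0)


def _sbx(parent_a, parent_b, lo, hi, eta, rng):
    """Simulated binary crossover, gene-wise."""
    u = rng.random(parent_a.shape)
    beta = np.where(u <= 0.5, (2 * u) ** (1 / (eta + 1)), (1 / (2 * (1 - u))) ** (1 / (eta + 1)))
    c1 = 0.5 * ((1 + beta) * parent_a + (1 - beta) * parent_b)
    c2 = 0.5 * ((1 - beta) * parent_a + (1 + beta) * parent_b)
    return np.clip(c1, lo, hi), np.clip(c2, lo, hi)


def ga_fit(
    dataset: FitDataset,
    network: ReactionNetwork,
    bounds: dict,
    ga_config: GAConfig | None = None,
    seed: int = 0,
    base_params: ParameterSet | None = None,
) -> FitResult:
    """Fit the rate constants named in ``bounds`` by a real-coded GA.

    ``bounds`` maps parameter names to positive (lo, hi) intervals; the
    search runs in log10 space. Parameters not named keep their
    ``base_params`` values. Deterministic for a fixed seed. Elitism keeps
    the best individuals, so the best-objective trace is non-increasing.
    """
    cfg = ga_config or GAConfig()
    if base_params is None:
        from .network import reference_parameters

        base_params = reference_parameters()
    names = list(bounds)
    for name, (lo_v, hi_v) in bounds.items():
        if not (lo_v > 0 and hi_v >= lo_v):
            raise ValueError(f"bounds for {name} must be positive with hi >= lo")
    lo = np.log10([bounds[n][0] for n in names])
    hi = np.log10([bounds[n][1] for n in names])
    rng = np.random.default_rng(seed)

    def make_params(x_log10) -> ParameterSet:
        return base_params.with_rates(**{n: 10.0**v for n, v in zip(names, x_log10)})

    def score(x_log10) -> float:
        return objective(make_params(x_log10), dataset, network)

    pop = lo + (hi - lo) * rng.random((cfg.population, len(names)))
    fitness = np.array([score(ind) for ind in pop])
    if not np.isfinite(fitness).any():
        raise RuntimeError(
            "all generation-0 individuals are infeasible; widen the bounds or check the model"
        )
    trace_rows = []
    for gen in range(cfg.generations):
        finite = fitness[np.isfinite(fitness)]
        trace_rows.append(
            {"generation": gen, "best": float(fitness.min()), "mean": float(finite.mean())}
        )
        elite_idx = np.argsort(fitness)[: cfg.elitism]
        children = [pop[i].copy() for i in elite_idx]
        while len(children) < cfg.population:
            # tournament selection
            parents = []
            for _ in range(2):
                contenders = rng.integers(0, cfg.population, cfg.tournament_size)
                parents.append(pop[contenders[np.argmin(fitness[contenders])]].copy())
            if rng.random() < cfg.crossover_p:
                parents = list(_sbx(parents[0], parents[1], lo, hi, cfg.crossover_eta, rng))
            for child in parents:
                mutate = rng.random(len(names)) < cfg.mutation_p
                child[mutate] += rng.normal(0, cfg.mutation_sigma, mutate.sum())
                np.clip(child, lo, hi, out=child)
                children.append(child)
        pop = np.array(children[: cfg.population])
        fitness = np.array([score(ind) for ind in pop])
    finite = fitness[np.isfinite(fitness)]
    trace_rows.append(
        {"generation": cfg.generations, "best": float(fitness.min()), "mean": float(finite.mean())}
    )
    best_x = pop[int(np.argmin(fitness))].copy()
    best_f = float(fitness.min())

    if cfg.polish and np.any(hi > lo):
        res = minimize(
            lambda x: score(np.clip(x, lo, hi)),
            best_x,
            method="Nelder-Mead",
            options={"xatol": 1e-6, "fatol": 1e-10, "maxfev": 2000},
        )
        x_pol = np.clip(res.x, lo, hi)
        f_pol = score(x_pol)
        if f_pol < best_f:
            best_x, best_f = x_pol, float(f_pol)
    return FitResult(
        params=make_params(best_x),
        objective=best_f,
        trace=pd.DataFrame(trace_rows),
        seed=seed,
        bounds=dict(bounds),
        fitted_names=names,
    )


def multi_start(
    dataset: FitDataset,
    network: ReactionNetwork,
    bounds: dict,
    ga_config: GAConfig | None = None,
    n_starts: int = 3,
    seeds=None,
    base_params: ParameterSet | None = None,
) -> list[FitResult]:
    """Independent GA restarts with distinct seeds, sorted by objective."""
    if n_starts < 1:
        raise ValueError("n_starts must be >= 1")
    if seeds is None:
        seeds = list(range(n_starts))
    seeds = list(seeds)[:n_starts]
    if len(set(seeds)) < len(seeds):
        warnings.warn("duplicate seeds supplied; restarts will be identical", stacklevel=2)
    results, failures = [], []
    for s in seeds:
        try:
            results.append(
                ga_fit(dataset, network, bounds, ga_config, seed=s, base_params=base_params)
            )
        except Exception as exc:  # noqa: BLE001 - per-start failures are collected
            logger.warning("restart seed %s failed: %s", s, exc)
            failures.append((s, exc))
    if not results:
        raise RuntimeError(f"all {len(seeds)} restarts failed; first error: {failures[0][1]}")
    return sorted(results, key=lambda r: r.objective)


def predict_averaged(
    fits: list[FitResult],
    network: ReactionNetwork,
    protocol: Protocol | None = None,
    pip3_scales=None,
    observables=("Akt_PM", "pAkt", "pSub"),
) -> pd.DataFrame:
    """Average predictions over independent best-fitted parameter sets.

    With ``protocol``: simulate it under each fit and average observables
    pointwise; with ``pip3_scales``: average the peak-recruitment
    dose-response instead. SEM = sd/sqrt(n_fits). Returns a tidy frame.
    """
    if len(fits) < 2:
        raise ValueError("need >= 2 fits to report an SEM")
    if (protocol is None) == (pip3_scales is None):
        raise ValueError("supply exactly one of protocol or pip3_scales")
    if protocol is not None:
        curves = {}
        for obs in observables:
            stack = []
            for fit in fits:
                tc = simulate(network, fit.params, protocol)
                stack.append(tc.observable(obs))
            curves[obs] = np.array(stack)
        rows = []
        grid = protocol.grid()
        for obs in observables:
            stack = curves[obs]
            rows.append(
                pd.DataFrame(
                    {
                        "time": grid,
                        "observable": obs,
                        "mean": stack.mean(axis=0),
                        "sem": stack.std(axis=0, ddof=1) / np.sqrt(len(fits)),
                    }
                )
            )
        return pd.concat(rows, ignore_index=True)
    from .simulate import pip3_dose_response

    stacks = []
    for fit in fits:
        df = pip3_dose_response(network, fit.params, pip3_scales)
        stacks.append(df.set_index(["pip3_scale", "condition"])["peak_akt_pm"])
    wide = pd.concat(stacks, axis=1)
    out = wide.mean(axis=1).rename("mean").to_frame()
    out["sem"] = wide.std(axis=1, ddof=1) / np.sqrt(len(fits))
    return out.reset_index()
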