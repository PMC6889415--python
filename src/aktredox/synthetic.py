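"""Seeded generators for every input the pipeline consumes.

The generators emulate the statistical structure of the study designs the
statistics assume, with known ground truth for recovery testing:

* multiplexed redox peptide matrices — four biological replicates per
  (treatment, time) condition, log-normal intensities, planted log2
  treatment effects, optional concordance of effects across the acute
  (2 h) and late (24 h) time points;
* label-free phosphoproteome matrices with condition-structured
  missingness — a stated fraction of features detected only under
  insulin (or only basal), the rest missing-not-at-random with a
  logistic intensity dependence;
* noisy time courses simulated from the mechanistic model under stated
  protocols, with replicate-level multiplicative noise summarised to
  mean ± SEM;
* Hill dose-response curves at the six spotted PIP3 amounts.

All randomness flows through a single integer seed per call; fixed seed
means bit-identical output (numpy Generator, PCG64).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit

from .assays import OVERLAY_DOSES_PMOL, DoseResponse, hill
from .fitting import FitDataset
from .matrix import OmicsMatrix
from .network import ParameterSet, ReactionNetwork
from .simulate import Protocol, SimulationError, simulate

BASELINE_LOG2_MEAN = 20.0
BASELINE_LOG2_SD = 2.0


# ---------------------------------------------------------------------------
# designs and missingness models
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MCAR:
    rate: float = 0.0


@dataclass(frozen=True)
class MNARLogistic:
    """P(missing) = expit(-slope * (log2 intensity - midpoint))."""

    midpoint: float = 16.0
    slope: float = 1.0


@dataclass(frozen=True)
class ConditionStructured:
    """A fraction of features present only under one condition; the rest
    follow the MNAR logistic model."""

    fraction: float = 0.1
    midpoint: float = 16.0
    slope: float = 1.0


@dataclass
class OmicsDesign:
    """Design of a synthetic features-by-samples experiment.

    ``groups`` lists (treatment, time) conditions; ``feature_effects``
    maps a group to a length-``n_features`` array of planted log2 effects
    (absent groups have zero effect). ``noise_sd`` is the log2-scale
    replicate noise.
    """

    n_features: int
    n_samples_per_group: int = 4
    groups: list = field(default_factory=list)
    feature_effects: dict = field(default_factory=dict)
    noise_sd: float = 0.3
    missing_model: object = MCAR(0.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_features < 1:
            raise ValueError("invalid design: n_features must be >= 1")
        if self.n_samples_per_group < 2:
            raise ValueError("invalid design: n_samples_per_group must be >= 2")
        if not self.noise_sd > 0:
            raise ValueError("invalid design: noise_sd must be > 0")
        if not self.groups:
            raise ValueError("invalid design: groups must be non-empty")
        if isinstance(self.missing_model, MCAR) and not 0 <= self.missing_model.rate < 1:
            raise ValueError("invalid design: MCAR rate must be in [0, 1)")
        if isinstance(self.missing_model, ConditionStructured) and not (
            0 <= self.missing_model.fraction <= 1
        ):
            raise ValueError("invalid design: condition-structured fraction must be in [0, 1]")
        for g, eff in self.feature_effects.items():
            if tuple(g) not in {tuple(x) for x in self.groups}:
                raise ValueError(f"invalid design: feature_effects group {g} not in groups")
            if len(np.atleast_1d(eff)) != self.n_features:
                raise ValueError(f"invalid design: feature_effects for {g} has wrong length")


def _sample_table(design: OmicsDesign) -> pd.DataFrame:
    rows = []
    for treatment, time in design.groups:
        for rep in range(1, design.n_samples_per_group + 1):
            rows.append(
                {
                    "sample_id": f"{treatment}_{time}_r{rep}".replace(" ", ""),
                    "treatment": treatment,
                    "time": time,
                    "replicate": rep,
                    "channel": f"tmt{len(rows) % 6 + 1}",
                }
            )
    return pd.DataFrame(rows)


def _log2_signal(design: OmicsDesign, rng: np.random.Generator) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Noise-free + noisy log2 intensities and the effect table."""
    features = [f"f{i:05d}" for i in range(design.n_features)]
    samples = _sample_table(design)
    baselines = rng.normal(BASELINE_LOG2_MEAN, BASELINE_LOG2_SD, design.n_features)
    effects = {
        tuple(g): np.asarray(design.feature_effects.get(tuple(g), np.zeros(design.n_features)))
        for g in map(tuple, design.groups)
    }
    log2 = np.empty((design.n_features, len(samples)))
    for j, row in samples.iterrows():
        g = (row["treatment"], row["time"])
        log2[:, j] = baselines + effects[g] + rng.normal(0, design.noise_sd, design.n_features)
    vals = pd.DataFrame(log2, index=features, columns=samples["sample_id"])
    eff_table = pd.DataFrame(
        {f"effect_{t}_{tm}".replace(" ", ""): effects[(t, tm)] for t, tm in map(tuple, design.groups)},
        index=features,
    )
    return vals, eff_table


def _apply_mcar(log2: pd.DataFrame, rate: float, rng) -> None:
    if rate > 0:
        mask = rng.random(log2.shape) < rate
        log2.values[mask] = np.nan


def _apply_mnar(log2: pd.DataFrame, midpoint: float, slope: float, rng) -> None:
    p_miss = expit(-slope * (log2.to_numpy() - midpoint))
    mask = rng.random(log2.shape) < p_miss
    log2.values[mask] = np.nan


# ---------------------------------------------------------------------------
# redox matrix
# ---------------------------------------------------------------------------

def generate_redox_matrix(
    design: OmicsDesign, acute_time: str = "2 h", late_time: str = "24 h"
) -> tuple[OmicsMatrix, pd.DataFrame]:
    """Redox peptide matrix with planted effects and ground truth.

    Returns the linear-scale matrix and a ground-truth table with per
    group effect columns plus ``differential`` (any non-zero effect) and
    ``concordant`` (same-sign non-zero effects at the acute and late time
    of the same treatment) flags.
    """
    rng = np.random.default_rng(design.seed)
    log2, eff_table = _log2_signal(design, rng)
    if isinstance(design.missing_model, MCAR):
        _apply_mcar(log2, design.missing_model.rate, rng)
    elif isinstance(design.missing_model, MNARLogistic):
        _apply_mnar(log2, design.missing_model.midpoint, design.missing_model.slope, rng)
    else:
        raise ValueError(
            "invalid design: missing_model for redox matrices must be MCAR or MNARLogistic"
        )
    matrix = OmicsMatrix(values=2.0**log2, samples=_sample_table(design), scale="linear")

    truth = eff_table.copy()
    truth["differential"] = (eff_table != 0).any(axis=1)
    concordant = np.zeros(design.n_features, dtype=bool)
    treatments = {t for t, _ in map(tuple, design.groups)}
    for t in treatments:
        acute = (t, acute_time)
        late = (t, late_time)
        if {acute, late} <= {tuple(g) for g in design.groups}:
            e1 = np.asarray(design.feature_effects.get(acute, np.zeros(design.n_features)))
            e2 = np.asarray(design.feature_effects.get(late, np.zeros(design.n_features)))
            concordant |= (e1 * e2) > 0
    truth["concordant"] = concordant
    truth.index.name = "feature_id"
    return matrix, truth


# ---------------------------------------------------------------------------
# phospho matrix
# ---------------------------------------------------------------------------

def generate_phospho_matrix(
    design: OmicsDesign, basal_label: str = "basal", insulin_label: str = "insulin"
) -> tuple[OmicsMatrix, pd.DataFrame]:
    """Phosphosite matrix with condition-structured (on/off) missingness.

    ``design.groups`` must contain both a ``basal``- and an
    ``insulin``-labelled treatment. Under a
    :class:`ConditionStructured` model, each feature is independently
    "insulin-only" with the stated probability: all basal cells missing,
    present in >= 2 insulin replicates. All other cells are thinned by
    the MNAR logistic model. Ground truth flags the insulin-only set.
    """
    treatments = {t for t, _ in map(tuple, design.groups)}
    missing_labels = {basal_label, insulin_label} - treatments
    if missing_labels:
        raise ValueError(f"design lacks treatment label(s) {sorted(missing_labels)}")
    rng = np.random.default_rng(design.seed)
    log2, eff_table = _log2_signal(design, rng)
    samples = _sample_table(design)
    model = design.missing_model
    if isinstance(model, ConditionStructured):
        insulin_only = rng.random(design.n_features) < model.fraction
        signal = log2.to_numpy().copy()  # pre-thinning values
        _apply_mnar(log2, model.midpoint, model.slope, rng)
        basal_cols = np.flatnonzero(samples["treatment"] == basal_label)
        insulin_cols = np.flatnonzero(samples["treatment"] == insulin_label)
        for i in np.flatnonzero(insulin_only):
            log2.iloc[i, basal_cols] = np.nan
            n_present = int(rng.integers(2, len(insulin_cols) + 1))
            present = rng.choice(insulin_cols, size=n_present, replace=False)
            log2.iloc[i, insulin_cols] = np.nan
            log2.iloc[i, present] = signal[i, present]
        # MNAR thinning can produce the on/off pattern by chance; restore one
        # cell in the empty condition so the pattern set is exactly the
        # planted one (both directions)
        arr = log2.to_numpy()
        for i in np.flatnonzero(~insulin_only):
            obs_b = ~np.isnan(arr[i, basal_cols])
            obs_i = ~np.isnan(arr[i, insulin_cols])
            if obs_i.sum() >= 2 and obs_b.sum() == 0:
                log2.iloc[i, basal_cols[0]] = signal[i, basal_cols[0]]
            elif obs_b.sum() >= 2 and obs_i.sum() == 0:
                log2.iloc[i, insulin_cols[0]] = signal[i, insulin_cols[0]]
    elif isinstance(model, MCAR):
        insulin_only = np.zeros(design.n_features, dtype=bool)
        _apply_mcar(log2, model.rate, rng)
    elif isinstance(model, MNARLogistic):
        insulin_only = np.zeros(design.n_features, dtype=bool)
        _apply_mnar(log2, model.midpoint, model.slope, rng)
    else:
        raise ValueError("invalid design: unknown missing_model")
    matrix = OmicsMatrix(values=2.0**log2, samples=samples, scale="linear")
    truth = eff_table.copy()
    truth["differential"] = (eff_table != 0).any(axis=1)
    truth["insulin_only"] = insulin_only
    truth.index.name = "feature_id"
    return matrix, truth


def insulin_only_pattern(
    matrix: OmicsMatrix,
    basal_label: str = "basal",
    insulin_label: str = "insulin",
    min_present: int = 2,
) -> np.ndarray:
    """Boolean flag per feature: observed in >= min_present insulin
    samples and in no basal sample."""
    obs = matrix.mask.to_numpy()
    basal = (matrix.samples["treatment"] == basal_label).to_numpy()
    insulin = (matrix.samples["treatment"] == insulin_label).to_numpy()
    return (obs[:, insulin].sum(axis=1) >= min_present) & (obs[:, basal].sum(axis=1) == 0)


# ---------------------------------------------------------------------------
# model time courses
# ---------------------------------------------------------------------------

def generate_timecourses(
    params: ParameterSet,
    protocols: list[Protocol],
    network: ReactionNetwork,
    times: np.ndarray | None = None,
    observables=("Akt_PM", "pAkt", "pSub"),
    noise_cv: float = 0.1,
    n_replicates: int = 4,
    seed: int = 0,
    scale_mode: str = "absolute",
) -> FitDataset:
    """Noisy replicate time courses simulated from the model.

    Each protocol is simulated, observables sampled at ``times``
    (default: every grid point from t = 0 on), and ``n_replicates``
    pseudo-replicates drawn with multiplicative Gaussian noise of the
    given coefficient of variation. Mean and SEM (= sd/sqrt(n), as
    experimental SEMs arise) per point are returned; with
    ``noise_cv = 0`` the dataset equals the noiseless simulation and the
    SEMs are zero.
    """
    if noise_cv < 0:
        raise ValueError("noise_cv must be >= 0")
    rng = np.random.default_rng(seed)
    rows = []
    for proto in protocols:
        try:
            tc = simulate(network, params, proto)
        except SimulationError as exc:
            raise SimulationError(f"protocol {proto.protocol_id!r}: {exc}") from exc
        t_sel = tc.time[tc.time >= 0] if times is None else np.asarray(times, dtype=float)
        for obs in observables:
            truth = np.interp(t_sel, tc.time, tc.observable(obs))
            if noise_cv > 0:
                reps = truth[None, :] * (
                    1.0 + noise_cv * rng.standard_normal((n_replicates, len(t_sel)))
                )
                mean = reps.mean(axis=0)
                sem = reps.std(axis=0, ddof=1) / np.sqrt(n_replicates)
            else:
                mean = truth
                sem = np.zeros_like(truth)
            rows.append(
                pd.DataFrame(
                    {
                        "protocol_id": proto.protocol_id,
                        "observable": obs,
                        "time": t_sel,
                        "mean": mean,
                        "sem": sem,
                        "n": n_replicates,
                    }
                )
            )
    data = pd.concat(rows, ignore_index=True)
    return FitDataset(
        data=data,
        protocols={p.protocol_id: p for p in protocols},
        scale_mode={obs: scale_mode for obs in observables},
    )


# ---------------------------------------------------------------------------
# Hill curves
# ---------------------------------------------------------------------------

def generate_hill_curve(
    ec50: float,
    hillslope: float,
    top: float = 1.0,
    bottom: float = 0.0,
    doses=OVERLAY_DOSES_PMOL,
    noise_sd: float = 0.0,
    seed: int = 0,
    condition: str = "other",
) -> DoseResponse:
    """Hill dose-response at the given doses plus additive Gaussian noise."""
    doses = np.asarray(doses, dtype=float)
    if not ec50 > 0:
        raise ValueError("ec50 must be > 0")
    if np.any(doses <= 0):
        raise ValueError("doses must be strictly positive")
    y = hill(doses, ec50, hillslope, top, bottom)
    if noise_sd > 0:
        y = y + np.random.default_rng(seed).normal(0, noise_sd, len(doses))
    return DoseResponse(doses=doses, responses=y, condition=condition)
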