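"""Synthetic dose-response data with the structure of sensillum recordings.

Emulates per-sensillum LFP dose-response tables: each neuron is driven by
its private odorant over a dilution series, with replicate pairs (default 9)
and additive homoscedastic Gaussian noise on the peak |LFP| in mV.  Ground
truth travels with the dataset so parameter-recovery experiments can score
themselves.  Also houses the morphometric helper that converts a measured
dendrite volume and length into a cylindrical surface area, and the
generate-then-fit recovery harness.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .circuit import ParameterError, SensillumModel
from .fit import DoseResponseDataset, FitConfig, FitFailureError, global_fit
from .simulate import dose_response

logger = logging.getLogger(__name__)

__all__ = [
    "DEFAULT_RECOVERY_X_GRID",
    "SyntheticSpec",
    "SyntheticDataset",
    "generate",
    "cylinder_lateral_area",
    "recovery_experiment",
    "RecoverySummary",
]

# dilution series 10^-8 .. 10^-2 in decade steps, the typical measured range
DEFAULT_RECOVERY_X_GRID = np.arange(-8.0, -1.0, 1.0)


@dataclass(frozen=True)
class SyntheticSpec:
    """Ground truth and sampling plan for one synthetic dataset.

    ``models`` maps sensillum name to its calibrated ground-truth circuit.
    Defaults: 9 replicate pairs and 0.5 mV noise, mirroring the replicate
    count and error-bar scale of typical sensillum dose-response data.
    """

    models: dict[str, SensillumModel]
    x_grid: np.ndarray = field(default_factory=lambda: DEFAULT_RECOVERY_X_GRID.copy())
    replicates: int = 9
    noise_sd: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.replicates < 1:
            raise ParameterError(f"replicates must be >= 1, got {self.replicates}")
        if self.noise_sd < 0:
            raise ParameterError(f"noise_sd must be >= 0, got {self.noise_sd}")
        if len(self.models) == 0:
            raise ParameterError("at least one ground-truth model is required")


@dataclass(frozen=True)
class SyntheticDataset:
    """Generated records plus the spec that produced them (the ground truth)."""

    frame: pd.DataFrame
    spec: SyntheticSpec

    def as_dataset(self) -> DoseResponseDataset:
        return DoseResponseDataset(self.frame)

    def truth_params(self) -> dict[str, float]:
        """Flat ground-truth parameter map keyed like fitted parameters."""
        out: dict[str, float] = {}
        first = next(iter(self.spec.models.values()))
        for name in ("E_A", "V_0", "rho_s", "rho_d0", "n", "g_max"):
            out[name] = float(getattr(first.common, name))
        for sens, model in self.spec.models.items():
            out[f"{sens}.k_od1"] = float(model.orn1.k_od)
            out[f"{sens}.k_od2"] = float(model.orn2.k_od)
            out[f"{sens}.A_d1"] = float(model.orn1.A_d)
            out[f"{sens}.A_d2"] = float(model.orn2.A_d)
        return out


def generate(spec: SyntheticSpec) -> SyntheticDataset:
    """Draw a synthetic dataset: noiseless model |LFP| plus i.i.d. Gaussian noise.

    Deterministic given ``spec.seed``; with ``noise_sd = 0`` every replicate
    equals the model value exactly.  Record count is
    ``len(models) * 2 * len(x_grid) * replicates``.
    """
    rng = np.random.default_rng(spec.seed)
    rows = []
    for sens in sorted(spec.models):
        model = spec.models[sens]
        for stimulated, orn in ((1, model.orn1), (2, model.orn2)):
            clean = dose_response(model, stimulated, x_grid=spec.x_grid).lfp
            noise = rng.normal(0.0, spec.noise_sd,
                               size=(spec.replicates, len(spec.x_grid)))
            for rep in range(spec.replicates):
                for j, x in enumerate(spec.x_grid):
                    rows.append((sens, orn.label, f"private_{orn.label}", float(x),
                                 rep + 1, float(clean[j] + noise[rep, j])))
    frame = pd.DataFrame(rows, columns=[
        "sensillum", "orn", "odorant", "x_log10_dilution", "replicate", "lfp_mV"])
    return SyntheticDataset(frame=frame, spec=spec)


def cylinder_lateral_area(volume: float, length: float) -> float:
    """Lateral surface of a cylinder from its volume and length, um^2.

    Outer dendrites are treated as cylinders whose radius follows from the
    measured volume: ``r = sqrt(V / (pi L))``, so ``A = 2 pi r L =
    2 sqrt(pi V L)``.
    """
    if volume <= 0 or length <= 0:
        raise ParameterError("cylinder volume and length must be > 0")
    return 2.0 * math.sqrt(math.pi * volume * length)


# ---------------------------------------------------------------------------
# Parameter-recovery harness
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RecoverySummary:
    """Per-parameter recovery statistics over repeated generate+fit runs."""

    table: pd.DataFrame          # parameter, truth, median_err, median_abs_err, ...
    n_seeds: int
    n_failures: int
    estimates: pd.DataFrame      # one row per (seed, parameter)


def recovery_experiment(spec: SyntheticSpec, fit_config: FitConfig,
                        n_seeds: int) -> RecoverySummary:
    """Repeatedly generate a dataset and fit it; score recovery per parameter.

    Child seeds are spawned deterministically from ``spec.seed``.  Scored
    parameters are the free ones (shared constants, every ``k_od``, and the
    dendrite areas of ratio-mode sensilla, including the implied ``A_d1``).
    Individual fit failures are recorded; more than 50% failures aborts the
    experiment.
    """
    if n_seeds < 1:
        raise ValueError("n_seeds must be >= 1")
    truth = generate(replace(spec, noise_sd=0.0)).truth_params()
    scored = list(fit_config.common_free)
    for sens in sorted(spec.models):
        scored += [f"{sens}.k_od1", f"{sens}.k_od2"]
        if fit_config.sensillum_mode(sens) == "ratio":
            scored += [f"{sens}.A_d1", f"{sens}.A_d2"]

    child_seeds = np.random.SeedSequence(spec.seed).generate_state(2 * n_seeds) % (2 ** 31)
    est_rows = []
    n_fail = 0
    for i in range(n_seeds):
        run_spec = replace(spec, seed=int(child_seeds[2 * i]))
        data = generate(run_spec).as_dataset()
        cfg = replace_config_seed(fit_config, int(child_seeds[2 * i + 1]))
        try:
            result = global_fit(data, cfg)
        except FitFailureError as exc:
            logger.warning("recovery run %d failed: %s", i, exc)
            n_fail += 1
            continue
        for name in scored:
            est_rows.append((i, name, truth[name], result.params[name]))
    if n_fail > n_seeds / 2:
        raise FitFailureError(f"{n_fail}/{n_seeds} recovery fits failed")

    est = pd.DataFrame(est_rows, columns=["seed_index", "parameter", "truth", "estimate"])
    est["error"] = est["estimate"] - est["truth"]
    est["rel_error"] = est["error"] / est["truth"].abs()

    summ = (est.groupby("parameter")
            .agg(truth=("truth", "first"),
                 median_err=("error", "median"),
                 median_abs_err=("error", lambda e: float(np.median(np.abs(e)))),
                 median_rel_err=("rel_error", "median"),
                 median_abs_rel_err=("rel_error", lambda e: float(np.median(np.abs(e)))),
                 n=("error", "count"))
            .reset_index())
    return RecoverySummary(table=summ, n_seeds=n_seeds, n_failures=n_fail,
                           estimates=est)


def replace_config_seed(cfg: FitConfig, seed: int) -> FitConfig:
    out = FitConfig(sensilla=cfg.sensilla, common_init=cfg.common_init,
                    common_free=cfg.common_free, common_bounds=dict(cfg.common_bounds),
                    k_od_bounds=cfg.k_od_bounds, A_d_bounds=cfg.A_d_bounds,
                    r_bounds=cfg.r_bounds, n_starts=cfg.n_starts, seed=seed,
                    weighting=cfg.weighting, jitter=cfg.jitter)
    return out
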