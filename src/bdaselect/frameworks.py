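"""Selection frameworks: single run, multi-run voting, bootstrap ensemble.

A single stochastic search returns a different wavelength set every time it
is seeded differently, which makes the selection hard to trust. Two
aggregation frameworks tame that randomness:

* **multi**: run the optimizer R times on the full dataset and keep the
  wavelengths chosen in at least a fraction ``vp`` (votes percentage) of
  the runs;
* **ensemble**: draw B bootstrap sample subsets (same-size resampling with
  replacement, duplicates removed — on average ~63.2% of distinct samples
  survive), run the optimizer once per subset, and vote the same way. The
  smaller subsets make each cost evaluation cheaper while the diversity of
  subsets supplies the variation that voting averages out.

Final masks from either voting framework are evaluated by cross-validated
RMSECV and R^2 on the *full* dataset so all three frameworks are compared
on the same footing. :func:`stability_report` and :func:`grid_experiment`
provide the repeat-based evaluation harness (mean/std of RMSECV over
repeats; iteration x swarm-size sweeps).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from itertools import combinations
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .dragonfly import BDAConfig, run_bda
from .fitness import FitnessConfig, FitnessValue, r2_cv, rmsecv
from .spectra import SpectraDataset, WavelengthMask

__all__ = [
    "VoteTally",
    "SelectionResult",
    "StabilityReport",
    "select_single",
    "aggregate_votes",
    "select_multi",
    "bootstrap_subset",
    "select_ensemble",
    "stability_report",
    "grid_experiment",
]

logger = logging.getLogger(__name__)

#: Default votes-percentage threshold: midpoint of the recommended 60-70% band.
DEFAULT_VP = 0.65


@dataclass
class VoteTally:
    """Per-channel vote counts over n_runs optimizer runs."""

    counts: np.ndarray
    n_runs: int
    vp_threshold: float

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=int)
        if not 0 < self.vp_threshold <= 1:
            raise ValueError("vp_threshold must be in (0, 1]")
        if np.any(self.counts < 0) or np.any(self.counts > self.n_runs):
            raise ValueError("vote counts must lie in [0, n_runs]")

    def mask_at(self, vp: float) -> WavelengthMask:
        """Channels selected in at least ``vp`` of the runs (inclusive)."""
        return WavelengthMask(
            (self.counts / self.n_runs >= vp - 1e-12).astype(np.int8)
        )


@dataclass
class SelectionResult:
    """Outcome of one framework invocation."""

    final_mask: WavelengthMask
    per_run_masks: list[WavelengthMask]
    per_run_costs: np.ndarray
    tally: VoteTally | None
    evaluation: FitnessValue | None
    r2: float | None
    provenance: dict


def _master_seeds(master_seed: int, n: int) -> np.ndarray:
    """Deterministic, distinct per-run seeds derived from a master seed."""
    return np.random.default_rng(master_seed).integers(0, 2**31 - 1, size=n)


def _evaluate_final(
    dataset: SpectraDataset,
    mask: WavelengthMask,
    fitness_config: FitnessConfig,
) -> tuple[FitnessValue | None, float | None]:
    if mask.n_selected == 0:
        return None, None
    return (
        rmsecv(dataset, mask, fitness_config),
        r2_cv(dataset, mask, fitness_config),
    )


def select_single(
    dataset: SpectraDataset,
    bda_config: BDAConfig,
    fitness_config: FitnessConfig | None = None,
) -> SelectionResult:
    """One optimizer run; the final mask is that run's best individual."""
    if fitness_config is None:
        fitness_config = FitnessConfig.for_dataset(dataset, rng=bda_config.seed)
    run = run_bda(dataset, fitness_config, bda_config)
    fit, r2 = _evaluate_final(dataset, run.best_mask, fitness_config)
    return SelectionResult(
        final_mask=run.best_mask,
        per_run_masks=[run.best_mask],
        per_run_costs=np.array([run.best_cost]),
        tally=None,
        evaluation=fit,
        r2=r2,
        provenance={
            "framework": "single",
            "seed": bda_config.seed,
            "max_iter": bda_config.max_iter,
            "n_dragonflies": bda_config.n_dragonflies,
            "n_latent": fitness_config.n_latent,
            "k_folds": fitness_config.k_folds,
            "trace": run.trace.tolist(),
        },
    )


def aggregate_votes(
    per_run_masks: Sequence[WavelengthMask],
    vp: float,
) -> tuple[VoteTally, WavelengthMask]:
    """Column-wise vote tally and the mask of channels reaching ``vp``."""
    if not per_run_masks:
        raise ValueError("need at least one mask to aggregate")
    lengths = {m.n_channels for m in per_run_masks}
    if len(lengths) != 1:
        raise ValueError("masks have unequal lengths")
    counts = np.sum([m.bits for m in per_run_masks], axis=0)
    tally = VoteTally(counts=counts, n_runs=len(per_run_masks), vp_threshold=vp)
    return tally, tally.mask_at(vp)


def select_multi(
    dataset: SpectraDataset,
    bda_config: BDAConfig,
    n_runs: int = 10,
    vp: float = DEFAULT_VP,
    master_seed: int = 0,
    n_latent: int = 2,
    k_folds: int = 5,
) -> SelectionResult:
    """R independent runs on the full dataset, aggregated by voting."""
    if n_runs < 2:
        raise ValueError("n_runs must be >= 2")
    seeds = _master_seeds(master_seed, n_runs)
    masks: list[WavelengthMask] = []
    costs = np.empty(n_runs)
    for i, seed in enumerate(seeds):
        cfg = replace(bda_config, seed=int(seed))
        fit_cfg = FitnessConfig.for_dataset(
            dataset, n_latent=n_latent, k_folds=k_folds, rng=int(seed)
        )
        run = run_bda(dataset, fit_cfg, cfg)
        masks.append(run.best_mask)
        costs[i] = run.best_cost
    tally, final = aggregate_votes(masks, vp)
    eval_cfg = FitnessConfig.for_dataset(
        dataset, n_latent=n_latent, k_folds=k_folds, rng=master_seed
    )
    if final.n_selected == 0:
        logger.warning(
            "no wavelength reached votes percentage %.0f%%; final mask is empty",
            100 * vp,
        )
    fit, r2 = _evaluate_final(dataset, final, eval_cfg)
    return SelectionResult(
        final_mask=final,
        per_run_masks=masks,
        per_run_costs=costs,
        tally=tally,
        evaluation=fit,
        r2=r2,
        provenance={
            "framework": "multi",
            "master_seed": master_seed,
            "run_seeds": seeds.tolist(),
            "n_runs": n_runs,
            "vp": vp,
            "max_iter": bda_config.max_iter,
            "n_dragonflies": bda_config.n_dragonflies,
            "n_latent": n_latent,
            "k_folds": k_folds,
        },
    )


def bootstrap_subset(
    dataset: SpectraDataset,
    rng: np.random.Generator,
    min_samples: int = 2,
    max_retries: int = 100,
) -> SpectraDataset:
    """Same-size resample with replacement, duplicates removed.

    The expected fraction of distinct samples retained is
    ``1 - (1 - 1/N)^N``, about 63.2% for large N. Redraws (bounded) if the
    deduplicated subset is smaller than ``min_samples``.
    """
    n = dataset.n_samples
    if n < 2:
        raise ValueError("need at least 2 samples to bootstrap")
    for _ in range(max_retries):
        idx = np.unique(rng.integers(0, n, size=n))
        if idx.size >= min_samples:
            return dataset.subset(idx)
    raise RuntimeError(
        f"could not draw a bootstrap subset of >= {min_samples} samples "
        f"in {max_retries} tries"
    )


def select_ensemble(
    dataset: SpectraDataset,
    bda_config: BDAConfig,
    n_runs: int = 10,
    vp: float = DEFAULT_VP,
    master_seed: int = 0,
    n_latent: int = 2,
    k_folds: int = 5,
    subset_fn: Callable[[SpectraDataset, np.random.Generator], SpectraDataset]
    | None = None,
) -> SelectionResult:
    """B bootstrap subsets, one optimizer run per subset, vote aggregation.

    Each run gets a fresh fold assignment sized to its subset; the final
    voted mask is evaluated on the full dataset. ``subset_fn`` can replace
    the bootstrap draw (mainly for testing degenerate cases).
    """
    if n_runs < 2:
        raise ValueError("n_runs must be >= 2")
    if subset_fn is None:
        subset_fn = lambda ds, rng: bootstrap_subset(ds, rng, min_samples=k_folds)
    seeds = _master_seeds(master_seed, n_runs)
    masks: list[WavelengthMask] = []
    costs = np.empty(n_runs)
    for i, seed in enumerate(seeds):
        rng = np.random.default_rng(int(seed))
        subset = subset_fn(dataset, rng)
        cfg = replace(bda_config, seed=int(seed))
        fit_cfg = FitnessConfig.for_dataset(
            subset, n_latent=n_latent, k_folds=k_folds, rng=rng
        )
        run = run_bda(subset, fit_cfg, cfg)
        masks.append(run.best_mask)
        costs[i] = run.best_cost
    tally, final = aggregate_votes(masks, vp)
    eval_cfg = FitnessConfig.for_dataset(
        dataset, n_latent=n_latent, k_folds=k_folds, rng=master_seed
    )
    if final.n_selected == 0:
        logger.warning(
            "no wavelength reached votes percentage %.0f%%; final mask is empty",
            100 * vp,
        )
    fit, r2 = _evaluate_final(dataset, final, eval_cfg)
    return SelectionResult(
        final_mask=final,
        per_run_masks=masks,
        per_run_costs=costs,
        tally=tally,
        evaluation=fit,
        r2=r2,
        provenance={
            "framework": "ensemble",
            "master_seed": master_seed,
            "run_seeds": seeds.tolist(),
            "n_runs": n_runs,
            "vp": vp,
            "max_iter": bda_config.max_iter,
            "n_dragonflies": bda_config.n_dragonflies,
            "n_latent": n_latent,
            "k_folds": k_folds,
        },
    )


@dataclass
class StabilityReport:
    """Repeat-to-repeat variability of a framework's final masks."""

    mean_rmsecv: float
    std_rmsecv: float
    selection_frequency: np.ndarray
    mean_jaccard: float  # extra diagnostic beyond the mean/std index
    n_repeats: int


def _jaccard(a: WavelengthMask, b: WavelengthMask) -> float:
    sa, sb = a.as_bool(), b.as_bool()
    union = np.count_nonzero(sa | sb)
    if union == 0:
        return 1.0
    return np.count_nonzero(sa & sb) / union


def stability_report(results: Sequence[SelectionResult]) -> StabilityReport:
    """Mean/std of final-mask RMSECV across repeats plus mask agreement.

    The primary stability index is the standard deviation of the final
    masks' cross-validated RMSECV over repeated framework invocations;
    per-channel selection frequency and mean pairwise Jaccard similarity
    of the final masks are added as diagnostics.
    """
    if len(results) < 2:
        raise ValueError("need at least 2 repeats")
    costs = np.array(
        [r.evaluation.rmsecv for r in results if r.evaluation is not None]
    )
    if costs.size < 2:
        raise ValueError("need at least 2 evaluated (non-empty) results")
    masks = [r.final_mask for r in results]
    freq = np.mean([m.bits for m in masks], axis=0)
    jac = (
        float(np.mean([_jaccard(a, b) for a, b in combinations(masks, 2)]))
        if len(masks) > 1
        else 1.0
    )
    return StabilityReport(
        mean_rmsecv=float(costs.mean()),
        std_rmsecv=float(costs.std(ddof=1)),
        selection_frequency=freq,
        mean_jaccard=jac,
        n_repeats=len(results),
    )


def grid_experiment(
    dataset: SpectraDataset,
    max_iter_values: Sequence[int],
    swarm_size_values: Sequence[int],
    repeats: int = 10,
    master_seed: int = 0,
    n_latent: int = 2,
    k_folds: int = 5,
) -> pd.DataFrame:
    """Mean single-run RMSECV over a (max_iter x swarm size) parameter grid.

    Returns a tidy DataFrame with columns ``max_iter``, ``n_dragonflies``
    and ``mean_rmsecv`` (mean best cost of ``repeats`` seeded single runs
    per cell), suitable for a heat-map of the budget/quality trade-off.
    """
    if not max_iter_values or not swarm_size_values:
        raise ValueError("grid value lists must be non-empty")
    rows = []
    seeds = _master_seeds(master_seed, repeats)
    for mi in max_iter_values:
        for nd in swarm_size_values:
            costs = []
            for seed in seeds:
                cfg = BDAConfig(max_iter=mi, n_dragonflies=nd, seed=int(seed))
                fit_cfg = FitnessConfig.for_dataset(
                    dataset, n_latent=n_latent, k_folds=k_folds, rng=int(seed)
                )
                costs.append(run_bda(dataset, fit_cfg, cfg).best_cost)
            rows.append(
                {
                    "max_iter": mi,
                    "n_dragonflies": nd,
                    "mean_rmsecv": float(np.mean(costs)),
                }
            )
    return pd.DataFrame(rows)
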