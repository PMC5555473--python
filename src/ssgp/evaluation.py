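"""Accuracy/bias metrics and the replicated scenario grid.

Accuracy is the Pearson correlation (in percent) between true and
estimated breeding values in the validation generation; bias is the
ordinary-least-squares slope of TBV regressed on (G)EBV, with 1 meaning
no bias.  ``run_replicates`` repeats a scenario over independent
simulation replicates and aggregates replicate means with their standard
errors, mirroring how the study's tables are constructed.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .model import fit_single_step, impute_marker_covariates
from .pblup import solve_pblup
from .pedigree import RelationshipOperator
from .simulation import PANELS, SimulationConfig, StudyDataset, simulate_study

__all__ = [
    "accuracy",
    "bias_slope",
    "ScenarioConfig",
    "EvaluationResult",
    "run_replicates",
    "evaluate_dataset",
    "study_grid",
]

log = logging.getLogger("ssgp")


def accuracy(tbv: np.ndarray, gebv: np.ndarray) -> float:
    """Pearson correlation of TBV and GEBV, in percent (NaN if degenerate)."""
    tbv = np.asarray(tbv, dtype=float)
    gebv = np.asarray(gebv, dtype=float)
    if tbv.shape != gebv.shape:
        raise ValueError("tbv and gebv must have the same shape")
    if np.std(tbv) == 0 or np.std(gebv) == 0:
        warnings.warn("zero variance in TBV or GEBV; accuracy undefined")
        return float("nan")
    return float(np.corrcoef(tbv, gebv)[0, 1] * 100.0)


def bias_slope(tbv: np.ndarray, gebv: np.ndarray) -> float:
    """OLS slope of TBV on GEBV (cov/var); 1 = unbiased, NaN if degenerate."""
    tbv = np.asarray(tbv, dtype=float)
    gebv = np.asarray(gebv, dtype=float)
    if tbv.shape != gebv.shape:
        raise ValueError("tbv and gebv must have the same shape")
    var = np.var(gebv)
    if var == 0:
        warnings.warn("zero variance in GEBV; slope undefined")
        return float("nan")
    return float(np.cov(tbv, gebv, ddof=1)[0, 1] / np.var(gebv, ddof=1))


@dataclass(frozen=True)
class ScenarioConfig:
    """One cell of the study grid, replicated over seeds.

    ``scale`` chooses the population size: ``"full"`` is the study design
    (4000 dams / 200 sires, 40,000 training phenotypes), ``"reduced"`` the
    desk-scale variant (800 dams / 40 sires, same 5% selected proportion).
    """

    n_loci: int = 200
    qtl_per_chrom: int = 5
    h2: float = 0.5
    mu_alpha: float = 0.2
    panels: tuple = ("qtl_plus_markers", "qtl_only", "markers_only")
    variants: tuple = ("JC", "J", "C", "N")
    include_pblup: bool = True
    n_replicates: int = 10
    master_seed: int = 1
    method: str = "mme"
    scale: str = "full"

    def simulation_config(self) -> SimulationConfig:
        base = SimulationConfig() if self.scale == "full" else SimulationConfig.reduced()
        return base.with_(
            n_loci=self.n_loci,
            qtl_per_chrom=self.qtl_per_chrom,
            h2=self.h2,
            mu_alpha=self.mu_alpha,
        )

    def replicate_seed(self, r: int) -> int:
        return (self.master_seed * 100_003 + 7919 * r) & 0x7FFFFFFF


@dataclass
class EvaluationResult:
    """Raw per-replicate metrics plus the mean +- SE aggregation."""

    results: pd.DataFrame
    config: ScenarioConfig | None = None
    failures: list = field(default_factory=list)

    def summary(self) -> pd.DataFrame:
        g = self.results.groupby(["panel", "variant"], sort=False)

        def se(x):
            x = x.dropna()
            return x.std(ddof=1) / np.sqrt(len(x)) if len(x) > 1 else np.nan

        out = g.agg(
            accuracy_mean=("accuracy", "mean"),
            accuracy_se=("accuracy", se),
            slope_mean=("slope", "mean"),
            slope_se=("slope", se),
            n_replicates=("replicate", "count"),
        ).reset_index()
        return out


def evaluate_dataset(
    dataset: StudyDataset,
    variants=("JC", "J", "C", "N"),
    panels=PANELS,
    include_pblup: bool = True,
    method: str = "mme",
    seed: int = 0,
) -> pd.DataFrame:
    """Fit the requested variants/panels to one dataset; metrics on G5.

    The relationship operator (with its cached nn-factorization) and the
    per-panel imputation solves are shared across variants.
    """
    operator = RelationshipOperator(dataset.pedigree, dataset.genotyped_ids)
    val = dataset.validation_mask
    tbv_val = dataset.tbv[val]
    rows = []
    for panel in panels:
        Mg_raw = dataset.observed_genotypes(panel)
        Mn_raw = impute_marker_covariates(operator, Mg_raw)
        for variant in variants:
            fit = fit_single_step(
                dataset,
                variant=variant,
                panel=panel,
                method=method,
                operator=operator,
                Mn_raw=Mn_raw,
                seed=seed,
            )
            g_val = fit.gebv[val]
            rows.append(
                {
                    "panel": panel,
                    "variant": variant,
                    "accuracy": accuracy(tbv_val, g_val),
                    "slope": bias_slope(tbv_val, g_val),
                    "mu_hat": fit.mu_hat,
                    "mu_g_hat": fit.mu_g_hat,
                }
            )
    if include_pblup:
        pfit = solve_pblup(dataset)
        u_val = pfit.u_hat[val]
        rows.append(
            {
                "panel": "no_genotypes",
                "variant": "PBLUP",
                "accuracy": accuracy(tbv_val, u_val),
                "slope": bias_slope(tbv_val, u_val),
                "mu_hat": pfit.mu_hat,
                "mu_g_hat": None,
            }
        )
    return pd.DataFrame(rows)


def run_replicates(config: ScenarioConfig) -> EvaluationResult:
    """Replicate a scenario: fresh simulation per replicate, all fits, G5
    metrics, aggregated as replicate means with SEs.

    A failed replicate is recorded and skipped with a warning; aggregation
    runs over the completed ones.
    """
    frames = []
    failures = []
    sim_config = config.simulation_config()
    for r in range(config.n_replicates):
        seed = config.replicate_seed(r)
        try:
            ds = simulate_study(sim_config, seed=seed)
            frame = evaluate_dataset(
                ds,
                variants=config.variants,
                panels=config.panels,
                include_pblup=config.include_pblup,
                method=config.method,
                seed=seed,
            )
        except Exception as e:  # noqa: BLE001 - replicate isolation
            log.warning("replicate %d (seed %d) failed: %s", r, seed, e)
            failures.append({"replicate": r, "seed": seed, "error": str(e)})
            continue
        frame.insert(0, "replicate", r)
        frame.insert(1, "seed", seed)
        frames.append(frame)
    if not frames:
        raise RuntimeError(f"all {config.n_replicates} replicates failed: {failures}")
    if failures:
        warnings.warn(f"{len(failures)} of {config.n_replicates} replicates failed")
    return EvaluationResult(
        results=pd.concat(frames, ignore_index=True), config=config, failures=failures
    )


def study_grid(
    master_seed: int = 1,
    n_replicates: int = 3,
    scale: str = "reduced",
    method: str = "mme",
) -> dict[str, EvaluationResult]:
    """The study's scenario grid: one entry per table-defining scenario.

    ``main``      : h2 = 0.5, mu_alpha = 0.2, all three panels, variants
                    JC/J/C/N + PBLUP (the accuracy/bias comparison).
    ``h2_01/03``  : same trait with h2 = 0.1 / 0.3, QTL+markers panel
                    (the heritability sweep).
    ``mu0_markers``: mu_alpha = 0, markers-only panel, adding the
                    observed-only-centering variants JC*/C* (the
                    single-step-GBLUP centering comparison).
    """
    base = dict(n_replicates=n_replicates, method=method, scale=scale)
    scenarios = {
        "main": ScenarioConfig(
            h2=0.5, mu_alpha=0.2, master_seed=master_seed, **base
        ),
        "h2_01": ScenarioConfig(
            h2=0.1,
            mu_alpha=0.2,
            panels=("qtl_plus_markers",),
            master_seed=master_seed + 1,
            **base,
        ),
        "h2_03": ScenarioConfig(
            h2=0.3,
            mu_alpha=0.2,
            panels=("qtl_plus_markers",),
            master_seed=master_seed + 2,
            **base,
        ),
        "mu0_markers": ScenarioConfig(
            h2=0.5,
            mu_alpha=0.0,
            panels=("markers_only",),
            variants=("JC", "J", "C", "N", "JCstar", "Cstar"),
            master_seed=master_seed + 3,
            **base,
        ),
    }
    return {name: run_replicates(cfg) for name, cfg in scenarios.items()}
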