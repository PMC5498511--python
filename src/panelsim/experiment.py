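"""Replicated scenario runs and accuracy-table reporting.

A scenario is one (QTL count, heritability) cell of the study grid.  Each
replicate draws a QTL architecture (optionally shared across replicates),
simulates the trait, splits the individuals into a training and a
validation half, builds the requested marker panels, fits the requested
whole-genome regression models on the training rows restricted to each
panel's columns, and records the validation-set correlation between
predictions and the configured truth (true genetic values by default;
phenotypes are recorded alongside).

Replicate seeds are derived from ``master_seed`` by a counter scheme —
SeedSequence(master_seed, replicate, stage, ...) — so every replicate and
every stage is independently reproducible and results do not depend on
execution order.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .ld_panels import PANEL_KINDS, build_panel, qtl_ld_scan
from .synthetic_data import GenotypePanel
from .trait_model import build_architecture, simulate_trait
from .wgr_models import MCMCSettings, accuracy, fit, predict_genetic_values

logger = logging.getLogger(__name__)

_STAGE_ARCH, _STAGE_TRAIT, _STAGE_SPLIT, _STAGE_PANEL, _STAGE_FIT = range(5)


def _derive_seed(master_seed: int, *counters: int) -> int:
    ss = np.random.SeedSequence((int(master_seed),) + tuple(int(c) for c in counters))
    return int(ss.generate_state(1)[0] % 2**31)


@dataclass(frozen=True)
class ScenarioConfig:
    """One cell of the simulation grid plus protocol knobs."""

    n_qtl: int
    h2: float
    panels: tuple[str, ...] = PANEL_KINDS
    models: tuple[str, ...] = ("bayesB",)
    n_replicates: int = 5
    train_size: int = 400
    resample_qtl_per_replicate: bool = True
    accuracy_truth: str = "genetic_value"
    effect_distribution: str = "standard_normal"
    ld_on_training: bool = False
    master_seed: int = 0
    mcmc: MCMCSettings = field(default_factory=MCMCSettings)

    def __post_init__(self) -> None:
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        if self.accuracy_truth not in ("genetic_value", "phenotype"):
            raise ValueError("accuracy_truth must be genetic_value or phenotype")
        unknown = set(self.panels) - set(PANEL_KINDS)
        if unknown:
            raise ValueError(f"unknown panel kinds {sorted(unknown)}")


@dataclass
class AccuracyTable:
    """Long-format per-replicate accuracies with summary helpers."""

    records: pd.DataFrame

    def summary(self) -> pd.DataFrame:
        """Mean and across-replicate sample SD per (n_qtl, h2, panel, model)."""
        grp = self.records.groupby(["n_qtl", "h2", "panel", "model"], sort=False)
        out = grp.agg(
            mean_accuracy=("accuracy", "mean"),
            sd_accuracy=("accuracy", lambda s: s.std(ddof=1) if len(s) > 1 else 0.0),
            n_replicates=("accuracy", "size"),
            panel_size=("panel_size", "first"),
        ).reset_index()
        return out

    def cell(self, n_qtl: int, h2: float, panel: str, model: str) -> tuple[float, float]:
        s = self.records
        sel = s[
            (s.n_qtl == n_qtl) & (s.h2 == h2) & (s.panel == panel) & (s.model == model)
        ]["accuracy"]
        if sel.empty:
            raise KeyError((n_qtl, h2, panel, model))
        sd = sel.std(ddof=1) if len(sel) > 1 else 0.0
        return float(sel.mean()), float(sd)

    def format_table(self, model: str = "bayesB") -> str:
        """Accuracy grid formatted like the study's comparison table."""
        lines = []
        s = self.summary()
        s = s[s.model == model]
        for (n_qtl, h2), block in s.groupby(["n_qtl", "h2"], sort=True):
            lines.append(f"QTL{n_qtl} (h2={h2:g})")
            for row in block.itertuples():
                sd = row.sd_accuracy if row.n_replicates > 1 else None
                lines.append(
                    f"  {row.panel} ({int(row.panel_size)} loci): "
                    f"{format_accuracy_cell(row.mean_accuracy, sd)}"
                )
        return "\n".join(lines)

    @staticmethod
    def concat(tables: list["AccuracyTable"]) -> "AccuracyTable":
        return AccuracyTable(
            pd.concat([t.records for t in tables], ignore_index=True)
        )


def split_train_validation(n: int, train_size: int, seed: int | None = None):
    """Disjoint uniform-random train/validation index sets covering 0..n-1."""
    if not (0 < train_size < n):
        raise ValueError(f"train_size must lie in (0, {n}), got {train_size}")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    return np.sort(perm[:train_size]), np.sort(perm[train_size:])


def format_accuracy_cell(mean: float, sd: float | None = None) -> str:
    """'0.94 (0.01)' cell style; SD omitted for single-replicate runs."""
    if sd is None:
        return f"{mean:.2f}"
    return f"{mean:.2f} ({sd:.2f})"


def run_replicate(
    panel_data: GenotypePanel, scenario: ScenarioConfig, replicate_index: int
) -> list[dict]:
    """Run one replicate; returns one record per (panel, model)."""
    n = panel_data.n_individuals
    ms = scenario.master_seed
    arch_rep = replicate_index if scenario.resample_qtl_per_replicate else 0
    try:
        if scenario.train_size >= n:
            raise ValueError(
                f"train_size {scenario.train_size} >= panel size {n}"
            )
        arch = build_architecture(
            panel_data,
            scenario.n_qtl,
            scenario.effect_distribution,
            seed=_derive_seed(ms, arch_rep, _STAGE_ARCH),
        )
        trait = simulate_trait(
            panel_data, arch, scenario.h2, seed=_derive_seed(ms, replicate_index, _STAGE_TRAIT)
        )
        train, val = split_train_validation(
            n, scenario.train_size, seed=_derive_seed(ms, replicate_index, _STAGE_SPLIT)
        )

        scan = None
        if any(k in ("mp2", "mp4", "mp6", "mp7") for k in scenario.panels):
            ld_source = (
                panel_data.subset_individuals(train)
                if scenario.ld_on_training
                else panel_data
            )
            scan = qtl_ld_scan(ld_source, arch.qtl_indices)

        records = []
        for k_idx, kind in enumerate(scenario.panels):
            mpanel = build_panel(
                kind,
                arch,
                panel_data,
                seed=_derive_seed(ms, replicate_index, _STAGE_PANEL, k_idx),
                ld_scan=scan,
            )
            X = panel_data.dosages[:, mpanel.locus_indices].astype(np.float64)
            X_tr, X_val = X[train], X[val]
            for m_idx, model in enumerate(scenario.models):
                kwargs = {}
                if model in ("bayesB", "bayesC"):
                    kwargs["settings"] = replace(
                        scenario.mcmc,
                        seed=_derive_seed(ms, replicate_index, _STAGE_FIT, k_idx, m_idx),
                    )
                fitted = fit(model, X_tr, trait.phenotypes[train], **kwargs)
                pred = predict_genetic_values(fitted, X_val)
                acc_g = accuracy(pred, trait.genetic_values[val])
                acc_y = accuracy(pred, trait.phenotypes[val])
                records.append(
                    {
                        "n_qtl": scenario.n_qtl,
                        "h2": scenario.h2,
                        "panel": kind,
                        "model": model,
                        "replicate": replicate_index,
                        "panel_size": mpanel.size,
                        "accuracy_genetic": acc_g,
                        "accuracy_phenotype": acc_y,
                        "accuracy": acc_g
                        if scenario.accuracy_truth == "genetic_value"
                        else acc_y,
                    }
                )
        return records
    except Exception as exc:
        raise RuntimeError(
            f"replicate {replicate_index} of scenario "
            f"(n_qtl={scenario.n_qtl}, h2={scenario.h2}) failed: {exc}"
        ) from exc


def run_scenario(panel_data: GenotypePanel, scenario: ScenarioConfig) -> AccuracyTable:
    """Run all replicates of one scenario and aggregate the accuracies."""
    records: list[dict] = []
    for rep in range(scenario.n_replicates):
        logger.info(
            "scenario n_qtl=%d h2=%.2f replicate %d/%d",
            scenario.n_qtl,
            scenario.h2,
            rep + 1,
            scenario.n_replicates,
        )
        records.extend(run_replicate(panel_data, scenario, rep))
    df = pd.DataFrame.from_records(records)
    order = {k: i for i, k in enumerate(PANEL_KINDS)}
    df = df.sort_values(
        ["n_qtl", "h2", "panel", "model", "replicate"],
        key=lambda s: s.map(order) if s.name == "panel" else s,
    ).reset_index(drop=True)
    return AccuracyTable(df)


def run_grid(
    panel_data: GenotypePanel,
    qtl_counts,
    heritabilities,
    base: ScenarioConfig,
) -> AccuracyTable:
    """Run the full (QTL count x heritability) grid under one base config."""
    tables = []
    for n_qtl in qtl_counts:
        for h2 in heritabilities:
            scenario = replace(base, n_qtl=n_qtl, h2=h2)
            tables.append(run_scenario(panel_data, scenario))
    return AccuracyTable.concat(tables)
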