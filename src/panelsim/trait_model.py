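"""Additive QTL architectures and quantitative-trait simulation.

A trait is controlled by ``n_qtl`` loci drawn uniformly from the panel,
each carrying an additive allele-substitution effect.  The true genetic
value of an individual is the dot product of its (column-centered) QTL
dosages with the effect vector; phenotypes add i.i.d. normal noise whose
variance is set from the *realized* genetic variance so that the nominal
narrow-sense heritability h2 = var(g) / (var(g) + sigma_e^2) holds exactly
in-sample.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .synthetic_data import MISSING, GenotypePanel

EFFECT_DISTRIBUTIONS = ("standard_normal", "gamma_signed")

# Shape/scale of the signed-gamma alternative: a leptokurtic effect-size
# distribution conventional in genomic-selection simulations.
_GAMMA_SHAPE = 0.4
_GAMMA_SCALE = 1.66


@dataclass(frozen=True)
class QTLArchitecture:
    """Sampled QTL locus indices and their additive effects."""

    qtl_indices: np.ndarray
    effects: np.ndarray
    effect_distribution: str = "standard_normal"
    seed: int | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "qtl_indices", np.asarray(self.qtl_indices, dtype=np.int64))
        object.__setattr__(self, "effects", np.asarray(self.effects, dtype=np.float64))
        if self.qtl_indices.size != np.unique(self.qtl_indices).size:
            raise ValueError("QTL indices must be unique")
        if self.effects.shape != self.qtl_indices.shape:
            raise ValueError("effects and qtl_indices length mismatch")

    @property
    def n_qtl(self) -> int:
        return self.qtl_indices.size


@dataclass(frozen=True)
class SimulatedTrait:
    """True genetic values g, residuals e, phenotypes y = g + e."""

    genetic_values: np.ndarray
    residuals: np.ndarray
    phenotypes: np.ndarray
    h2_nominal: float
    residual_variance: float


def sample_qtl(panel: GenotypePanel, n_qtl: int, seed: int | None = None) -> np.ndarray:
    """Uniform sample of ``n_qtl`` locus indices without replacement (sorted)."""
    if not (1 <= n_qtl <= panel.n_loci):
        raise ValueError(f"n_qtl must lie in [1, {panel.n_loci}], got {n_qtl}")
    rng = np.random.default_rng(seed)
    return np.sort(rng.choice(panel.n_loci, size=n_qtl, replace=False))


def sample_effects(
    n_qtl: int, distribution: str = "standard_normal", seed: int | None = None
) -> np.ndarray:
    """Additive allele-substitution effects for ``n_qtl`` loci."""
    if distribution not in EFFECT_DISTRIBUTIONS:
        raise ValueError(
            f"unknown effect distribution {distribution!r}; "
            f"choose from {EFFECT_DISTRIBUTIONS}"
        )
    rng = np.random.default_rng(seed)
    if n_qtl == 0:
        return np.empty(0)
    if distribution == "standard_normal":
        return rng.standard_normal(n_qtl)
    magnitudes = rng.gamma(_GAMMA_SHAPE, _GAMMA_SCALE, size=n_qtl)
    signs = rng.choice([-1.0, 1.0], size=n_qtl)
    return magnitudes * signs


def build_architecture(
    panel: GenotypePanel,
    n_qtl: int,
    distribution: str = "standard_normal",
    seed: int | None = None,
) -> QTLArchitecture:
    """Sample indices and effects together under one seed stream."""
    ss = np.random.SeedSequence(seed)
    s_idx, s_eff = (int(c.generate_state(1)[0] % 2**31) for c in ss.spawn(2))
    idx = sample_qtl(panel, n_qtl, seed=s_idx)
    eff = sample_effects(n_qtl, distribution, seed=s_eff)
    return QTLArchitecture(idx, eff, distribution, seed)


def simulate_trait(
    panel: GenotypePanel,
    arch: QTLArchitecture,
    h2: float,
    seed: int | None = None,
) -> SimulatedTrait:
    """Simulate phenotypes y = g + e at nominal heritability ``h2``.

    g is the centered QTL dosage submatrix times the effects; the residual
    standard deviation is computed from the realized var(g), so the sample
    genetic-to-phenotypic variance ratio equals h2 up to residual sampling
    noise only.  With h2 = 1 residuals are identically zero.
    """
    if not (0.0 < h2 <= 1.0):
        raise ValueError("h2 must lie in (0, 1]")
    idx = arch.qtl_indices
    if idx.size and idx.max() >= panel.n_loci:
        raise ValueError("QTL index out of panel bounds")
    X = panel.dosages[:, idx].astype(np.float64)
    X[panel.dosages[:, idx] == MISSING] = np.nan
    X -= np.nanmean(X, axis=0)
    g = np.nan_to_num(X) @ arch.effects
    var_g = g.var(ddof=1)
    if var_g <= 0:
        raise ValueError("genetic variance is zero (all QTL monomorphic?)")
    if h2 == 1.0:
        e = np.zeros_like(g)
        sigma2_e = 0.0
    else:
        sigma2_e = var_g * (1.0 - h2) / h2
        rng = np.random.default_rng(seed)
        e = np.sqrt(sigma2_e) * rng.standard_normal(g.size)
    return SimulatedTrait(
        genetic_values=g,
        residuals=e,
        phenotypes=g + e,
        h2_nominal=h2,
        residual_variance=float(sigma2_e),
    )
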