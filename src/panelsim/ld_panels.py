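"""Pairwise LD (r2) and construction of the seven QTL-anchored marker panels.

Panel definitions (q = number of QTL):

========  ==================================================================
mp1       the QTL loci themselves (ideal functional markers)
mp2       QTL plus, for each QTL, its highest-LD (HLD) marker
mp3       all genome-wide loci, QTL included (common practice)
mp4       one HLD marker per QTL, QTL themselves excluded
mp5       all loci minus the QTL
mp6       per QTL, two markers drawn at random from its 20 highest-r2 loci
mp7       mp6 plus one random marker per QTL ("rSNP", falsely representing
          a QTL)
========  ==================================================================

LD is the squared Pearson correlation of allele-dosage vectors (composite
r2, identical to haplotype r2 for fully inbred lines).  Panels are sets:
a marker serving as HLD for two QTL is kept once, so realized sizes can be
smaller than the nominal arithmetic.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .synthetic_data import MISSING, GenotypePanel
from .trait_model import QTLArchitecture

PANEL_KINDS = ("mp1", "mp2", "mp3", "mp4", "mp5", "mp6", "mp7")

#: number of top-r2 loci per QTL from which mp6 samples
TOP_LD_POOL = 20


@dataclass(frozen=True)
class MarkerPanel:
    """A named subset of panel loci with per-locus provenance."""

    name: str
    locus_indices: np.ndarray
    provenance: tuple[str, ...]
    seed: int | None = None

    def __post_init__(self) -> None:
        idx = np.asarray(self.locus_indices, dtype=np.int64)
        object.__setattr__(self, "locus_indices", idx)
        if idx.size != np.unique(idx).size:
            raise ValueError("panel locus indices must be unique")
        if len(self.provenance) != idx.size:
            raise ValueError("provenance length mismatch")

    @property
    def size(self) -> int:
        return self.locus_indices.size


def r2(x: np.ndarray, y: np.ndarray) -> float:
    """Squared Pearson correlation between two dosage vectors."""
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape or x.ndim != 1 or x.size < 2:
        raise ValueError("need two equal-length vectors of length >= 2")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("r2 undefined for a monomorphic locus")
    r = np.corrcoef(x, y)[0, 1]
    return float(min(r * r, 1.0))


def _standardized(panel: GenotypePanel) -> np.ndarray:
    """Columns centered and scaled to unit variance; monomorphic or
    missing-heavy columns become all-zero (flagged separately)."""
    X = panel.dosages.astype(np.float64)
    X[panel.dosages == MISSING] = np.nan
    mu = np.nanmean(X, axis=0)
    sd = np.nanstd(X, axis=0)
    safe = np.where(sd > 0, sd, 1.0)
    Z = (X - mu) / safe
    Z = np.nan_to_num(Z)
    Z[:, sd == 0] = 0.0
    return Z


def qtl_ld_scan(panel: GenotypePanel, qtl_indices: np.ndarray, chunk: int = 4096) -> np.ndarray:
    """r2 between every QTL column and every panel column.

    Returns a (n_qtl, n_loci) matrix; monomorphic candidate columns are
    encoded as -1 so they can never win an argmax.  Missing dosages are
    mean-imputed for this scan.
    """
    qtl_indices = np.asarray(qtl_indices, dtype=np.int64)
    Z = _standardized(panel)
    n = Z.shape[0]
    poly = Z.std(axis=0) > 0
    Zq = Z[:, qtl_indices]
    out = np.empty((qtl_indices.size, panel.n_loci))
    for start in range(0, panel.n_loci, chunk):
        stop = min(start + chunk, panel.n_loci)
        r = Zq.T @ Z[:, start:stop] / n
        out[:, start:stop] = np.minimum(r * r, 1.0)
    out[:, ~poly] = -1.0
    # round away float noise so exact ties resolve by the index rule
    np.round(out, 12, out=out)
    return out


def _eligible_mask(panel: GenotypePanel, qtl_index: int, excluded) -> np.ndarray:
    mask = np.ones(panel.n_loci, dtype=bool)
    mask[list(excluded)] = False
    mask[qtl_index] = False
    return mask


def hld_for_qtl(panel: GenotypePanel, qtl_index: int, excluded=()) -> int:
    """Index of the eligible locus with the highest r2 to the QTL column.

    Ties resolve to the lowest locus index; monomorphic loci are ineligible.
    """
    scores = qtl_ld_scan(panel, np.array([qtl_index]))[0]
    scores[~_eligible_mask(panel, qtl_index, excluded)] = -1.0
    best = int(np.argmax(scores))
    if scores[best] < 0:
        raise ValueError(f"no polymorphic candidate for QTL at index {qtl_index}")
    return best


def top_k_r2(panel: GenotypePanel, qtl_index: int, k: int, excluded=()) -> np.ndarray:
    """The k eligible loci with the largest r2 to the QTL, in descending
    order (ties by lowest index).  Returns fewer with a warning when the
    candidates are exhausted."""
    if k < 1:
        raise ValueError("k must be >= 1")
    scores = qtl_ld_scan(panel, np.array([qtl_index]))[0]
    scores[~_eligible_mask(panel, qtl_index, excluded)] = -1.0
    order = np.lexsort((np.arange(scores.size), -scores))
    order = order[scores[order] >= 0]
    if order.size == 0:
        raise ValueError(f"no polymorphic candidate for QTL at index {qtl_index}")
    if order.size < k:
        warnings.warn(
            f"only {order.size} eligible loci for QTL {qtl_index} (asked for {k})",
            stacklevel=2,
        )
    return order[:k]


def _dedup_with_provenance(indices: np.ndarray, tags: list[str]) -> tuple[np.ndarray, tuple[str, ...]]:
    """Sort, deduplicate; the first-listed tag wins for a duplicated locus."""
    seen: dict[int, str] = {}
    for i, t in zip(indices, tags):
        seen.setdefault(int(i), t)
    idx = np.array(sorted(seen), dtype=np.int64)
    return idx, tuple(seen[int(i)] for i in idx)


def build_panel(
    kind: str,
    arch: QTLArchitecture,
    panel: GenotypePanel,
    seed: int | None = None,
    ld_scan: np.ndarray | None = None,
) -> MarkerPanel:
    """Construct one of the mp1..mp7 marker panels.

    ``ld_scan`` may carry a precomputed ``qtl_ld_scan(panel,
    arch.qtl_indices)`` so several panels can share one scan.  ``seed``
    drives the random draws of mp6 and mp7 only.
    """
    if kind not in PANEL_KINDS:
        raise ValueError(f"unknown panel kind {kind!r}")
    qtl = arch.qtl_indices
    all_loci = np.arange(panel.n_loci, dtype=np.int64)
    qtl_set = set(qtl.tolist())

    if kind == "mp1":
        return MarkerPanel("mp1", np.sort(qtl), ("QTL",) * qtl.size, seed)
    if kind == "mp3":
        prov = tuple("QTL" if i in qtl_set else "genome_wide" for i in all_loci)
        return MarkerPanel("mp3", all_loci, prov, seed)
    if kind == "mp5":
        rest = np.setdiff1d(all_loci, qtl)
        return MarkerPanel("mp5", rest, ("genome_wide",) * rest.size, seed)

    if ld_scan is None:
        ld_scan = qtl_ld_scan(panel, qtl)
    scores = ld_scan.copy()
    scores[:, qtl] = -1.0  # QTL are never HLD candidates

    if kind in ("mp2", "mp4"):
        hld = _argmax_per_qtl(scores, qtl)
        if kind == "mp4":
            idx, prov = _dedup_with_provenance(hld, ["HLD"] * hld.size)
            return MarkerPanel("mp4", idx, prov, seed)
        idx, prov = _dedup_with_provenance(
            np.concatenate([qtl, hld]), ["QTL"] * qtl.size + ["HLD"] * hld.size
        )
        return MarkerPanel("mp2", idx, prov, seed)

    # mp6 / mp7
    rng = np.random.default_rng(seed)
    picks: list[int] = []
    for row in range(qtl.size):
        order = np.lexsort((np.arange(scores.shape[1]), -scores[row]))
        pool = order[scores[row][order] >= 0][:TOP_LD_POOL]
        take = min(2, pool.size)
        picks.extend(rng.choice(pool, size=take, replace=False).tolist())
    if kind == "mp6":
        idx, prov = _dedup_with_provenance(np.array(picks), ["HLDr2"] * len(picks))
        return MarkerPanel("mp6", idx, prov, seed)
    # mp7: mp6 plus one random non-QTL, non-mp6 marker per QTL
    forbidden = qtl_set | set(picks)
    candidates = np.array([i for i in all_loci if i not in forbidden])
    n_rsnp = min(qtl.size, candidates.size)
    rsnp = rng.choice(candidates, size=n_rsnp, replace=False)
    idx, prov = _dedup_with_provenance(
        np.concatenate([np.array(picks, dtype=np.int64), rsnp]),
        ["HLDr2"] * len(picks) + ["rSNP"] * n_rsnp,
    )
    return MarkerPanel("mp7", idx, prov, seed)


def _argmax_per_qtl(scores: np.ndarray, qtl: np.ndarray) -> np.ndarray:
    best = np.argmax(scores, axis=1)  # first max -> lowest-index tie-break
    if np.any(scores[np.arange(qtl.size), best] < 0):
        bad = int(qtl[np.argmax(scores[np.arange(qtl.size), best] < 0)])
        raise ValueError(f"no polymorphic HLD candidate for QTL at index {bad}")
    return best.astype(np.int64)
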