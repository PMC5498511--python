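"""Synthetic genotype panels for genomic-prediction simulation.

The generator emulates a large inbred (selfing) diversity panel such as a
soybean germplasm collection genotyped on a fixed SNP array: biallelic
markers with a U-shaped allele-frequency spectrum, blockwise linkage
disequilibrium decaying with distance, and population structure from
subpopulation-private founder haplotypes.

Each simulated individual is a hidden-Markov mosaic of founder haplotypes:
walking along a chromosome, the active founder template is exchanged for a
freshly drawn one with probability ``switch_rate`` per locus step.  Small
founder pools and low switch rates produce long stretches of shared
haplotype, hence strong local LD and a small effective number of
independently segregating segments (Me) — the quantity that governs
genome-wide prediction accuracy.  ``estimate_effective_segments`` measures
Me from the genomic relationship matrix so a configuration can be
calibrated against a target regime.
"""

from __future__ import annotations

import dataclasses
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Sentinel dosage for a missing genotype call.  All frequency computations
#: ignore entries equal to MISSING.
MISSING = -1

LOCUS_COLUMNS = ("locus_id", "chromosome", "position")


@dataclass(frozen=True)
class LocusMeta:
    """Metadata for one biallelic locus.

    Dosage counts copies of the alternate allele; position is 1-based.
    """

    locus_id: str
    chromosome: str
    position: int


@dataclass
class GenotypePanel:
    """An individuals x loci allele-dosage matrix with locus metadata.

    ``dosages`` is an integer matrix with entries in {0, 1, 2} or
    :data:`MISSING`.  ``loci`` is a DataFrame with columns
    ``locus_id, chromosome, position`` (1-based), positions strictly
    increasing within a chromosome.  ``inbred`` declares the panel fully
    homozygous (no dosage of 1), the natural coding for selfing species.
    """

    dosages: np.ndarray
    individual_ids: list[str]
    loci: pd.DataFrame
    inbred: bool = True

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages)
        if self.dosages.ndim != 2:
            raise ValueError("dosages must be a 2-D matrix")
        if not isinstance(self.loci, pd.DataFrame):
            self.loci = pd.DataFrame(
                [dataclasses.astuple(m) for m in self.loci], columns=list(LOCUS_COLUMNS)
            )
        missing_cols = set(LOCUS_COLUMNS) - set(self.loci.columns)
        if missing_cols:
            raise ValueError(f"loci missing columns {sorted(missing_cols)}")
        n, p = self.dosages.shape
        if len(self.individual_ids) != n:
            raise ValueError(
                f"{len(self.individual_ids)} individual ids for {n} matrix rows"
            )
        if len(self.loci) != p:
            raise ValueError(f"{len(self.loci)} locus records for {p} matrix columns")
        if self.loci["locus_id"].duplicated().any():
            dup = self.loci["locus_id"][self.loci["locus_id"].duplicated()].iloc[0]
            raise ValueError(f"duplicate locus_id {dup!r}")
        for chrom, grp in self.loci.groupby("chromosome", sort=False):
            pos = grp["position"].to_numpy()
            if np.any(np.diff(pos) <= 0):
                raise ValueError(f"positions not strictly increasing on {chrom}")
        observed = self.dosages[self.dosages != MISSING]
        if observed.size and (observed.min() < 0 or observed.max() > 2):
            raise ValueError("dosages must lie in {0,1,2} or MISSING")
        if self.inbred and np.any(self.dosages == 1):
            raise ValueError("inbred panel contains heterozygous dosage 1")
        self.loci = self.loci.reset_index(drop=True)

    @property
    def n_individuals(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_loci(self) -> int:
        return self.dosages.shape[1]

    def allele_frequencies(self) -> np.ndarray:
        """Alternate-allele frequency per locus, ignoring missing calls."""
        d = self.dosages
        obs = d != MISSING
        counts = np.where(obs, d, 0).sum(axis=0, dtype=np.int64)
        n_obs = obs.sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            freq = counts / (2.0 * n_obs)
        return freq

    def minor_allele_frequencies(self) -> np.ndarray:
        p = self.allele_frequencies()
        return np.minimum(p, 1.0 - p)

    def subset_loci(self, indices) -> "GenotypePanel":
        indices = np.asarray(indices)
        return GenotypePanel(
            dosages=self.dosages[:, indices].copy(),
            individual_ids=list(self.individual_ids),
            loci=self.loci.iloc[indices].reset_index(drop=True),
            inbred=self.inbred,
        )

    def subset_individuals(self, rows) -> "GenotypePanel":
        rows = np.asarray(rows)
        return GenotypePanel(
            dosages=self.dosages[rows, :].copy(),
            individual_ids=[self.individual_ids[i] for i in rows],
            loci=self.loci.copy(),
            inbred=self.inbred,
        )


@dataclass(frozen=True)
class GeneratorConfig:
    """Parameters of the founder-mosaic genotype generator.

    switch_rate is the per-locus-step probability of exchanging the active
    founder template; 1/switch_rate is therefore the mean haplotype-block
    length in loci.  structure_strength is the fraction of founder
    haplotypes private to a single subpopulation (0 = panmictic pool).
    """

    n_individuals: int = 800
    n_loci: int = 20_000
    n_founder_haplotypes: int = 6
    switch_rate: float = 0.0025
    n_subpopulations: int = 3
    structure_strength: float = 0.5
    maf_min: float = 0.05
    inbred: bool = True
    n_chromosomes: int = 20
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.switch_rate <= 1.0):
            raise ValueError("switch_rate must lie in [0, 1]")
        if not (0.0 <= self.maf_min < 0.5):
            raise ValueError("maf_min must lie in [0, 0.5)")
        if not (0.0 <= self.structure_strength <= 1.0):
            raise ValueError("structure_strength must lie in [0, 1]")
        for name in ("n_individuals", "n_loci", "n_subpopulations", "n_chromosomes"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")
        if self.n_founder_haplotypes < 2:
            raise ValueError("need at least 2 founder haplotypes")


def soybean_like_config(
    n_loci: int = 20_000, n_individuals: int = 800, seed: int = 0
) -> GeneratorConfig:
    """A configuration calibrated to a soybean-diversity-panel regime.

    The defaults target an effective segment number (Me) in the low
    hundreds for a full-size panel, with per-locus switch rate scaled so
    the expected number of haplotype blocks per genome (~50) does not
    depend on marker density.
    """
    switch_rate = min(1.0, 50.0 / n_loci)
    return GeneratorConfig(
        n_individuals=n_individuals,
        n_loci=n_loci,
        switch_rate=switch_rate,
        seed=seed,
    )


def _u_shaped_frequencies(rng: np.random.Generator, size: int, maf_min: float) -> np.ndarray:
    """Founder allele frequencies from a U-shaped (beta) spectrum truncated
    to [maf_min, 1 - maf_min] by rejection."""
    out = np.empty(size)
    filled = 0
    while filled < size:
        draw = rng.beta(0.4, 0.4, size=size - filled)
        keep = draw[(draw >= maf_min) & (draw <= 1.0 - maf_min)]
        out[filled : filled + keep.size] = keep
        filled += keep.size
    return out


def _mosaic_haplotypes(
    rng: np.random.Generator,
    founders: np.ndarray,
    allowed: list[np.ndarray],
    subpop_of: np.ndarray,
    switch_rate: float,
) -> np.ndarray:
    """One haplotype per individual as a founder mosaic along one chromosome.

    ``founders`` is (K, L) in {0,1}; ``allowed[k]`` lists the founder
    indices individuals of subpopulation k may copy from.
    """
    n = subpop_of.size
    L = founders.shape[1]
    switch = rng.random((n, L)) < switch_rate
    switch[:, 0] = True
    # Founder draw at every position; only positions with a switch are used.
    choice = np.empty((n, L), dtype=np.int32)
    for k, pool in enumerate(allowed):
        rows = np.where(subpop_of == k)[0]
        if rows.size:
            idx = rng.integers(0, pool.size, size=(rows.size, L))
            choice[rows] = pool[idx]
    # Forward-fill the template index from the last switch point.
    pos = np.where(switch, np.arange(L)[None, :], 0)
    last_switch = np.maximum.accumulate(pos, axis=1)
    template = np.take_along_axis(choice, last_switch, axis=1)
    return founders[template, np.arange(L)[None, :]]


def _founder_pools(
    rng: np.random.Generator, n_founders: int, n_subpops: int, structure_strength: float
) -> list[np.ndarray]:
    n_private = int(round(structure_strength * n_founders))
    order = rng.permutation(n_founders)
    private, shared = order[:n_private], order[n_private:]
    pools = []
    for k in range(n_subpops):
        own = private[k::n_subpops]
        pool = np.concatenate([own, shared])
        if pool.size == 0:
            raise ValueError(
                "subpopulation has no available founder haplotypes; "
                "lower structure_strength or add founders"
            )
        pools.append(np.sort(pool))
    return pools


def generate_panel(config: GeneratorConfig) -> GenotypePanel:
    """Generate a genotype panel under the founder-mosaic model.

    Candidate loci are simulated in excess, loci with minor-allele
    frequency below ``maf_min`` are discarded, and the first ``n_loci``
    survivors (in genome order) are returned, so the result always passes
    ``maf_filter(maf_min)``.  Identical configs yield bit-identical panels.
    """
    oversample = 1.5
    for attempt in range(4):
        rng = np.random.default_rng([config.seed, attempt])
        panel = _generate_once(config, rng, oversample)
        if panel is not None:
            return panel
        oversample *= 1.8
    raise RuntimeError(
        f"could not obtain {config.n_loci} loci with MAF >= {config.maf_min} "
        "after repeated attempts; lower maf_min or the locus count"
    )


def _generate_once(
    config: GeneratorConfig, rng: np.random.Generator, oversample: float
) -> GenotypePanel | None:
    n = config.n_individuals
    n_cand = int(np.ceil(config.n_loci * oversample))
    K = config.n_founder_haplotypes
    pools = _founder_pools(
        rng, K, config.n_subpopulations, config.structure_strength
    )
    subpop_of = np.arange(n) % config.n_subpopulations

    per_chrom = np.full(config.n_chromosomes, n_cand // config.n_chromosomes)
    per_chrom[: n_cand % config.n_chromosomes] += 1

    dosage_blocks = []
    meta_blocks = []
    for c, Lc in enumerate(per_chrom):
        if Lc == 0:
            continue
        freqs = _u_shaped_frequencies(rng, Lc, config.maf_min)
        founders = (rng.random((K, Lc)) < freqs[None, :]).astype(np.int8)
        h1 = _mosaic_haplotypes(rng, founders, pools, subpop_of, config.switch_rate)
        if config.inbred:
            dos = (2 * h1).astype(np.int8)
        else:
            h2 = _mosaic_haplotypes(rng, founders, pools, subpop_of, config.switch_rate)
            dos = (h1 + h2).astype(np.int8)
        dosage_blocks.append(dos)
        positions = 1 + 2000 * np.arange(Lc)
        meta_blocks.append(
            pd.DataFrame(
                {
                    "locus_id": [f"ss{c + 1:02d}_{p}" for p in positions],
                    "chromosome": f"Gm{c + 1:02d}",
                    "position": positions,
                }
            )
        )
    dosages = np.concatenate(dosage_blocks, axis=1)
    loci = pd.concat(meta_blocks, ignore_index=True)

    freq = np.where(dosages != MISSING, dosages, 0).sum(0) / (2.0 * n)
    maf = np.minimum(freq, 1.0 - freq)
    keep = np.where(maf >= config.maf_min)[0]
    if keep.size < config.n_loci:
        return None
    keep = keep[: config.n_loci]
    ids = [f"ind{i + 1:04d}" for i in range(n)]
    return GenotypePanel(
        dosages=np.ascontiguousarray(dosages[:, keep]),
        individual_ids=ids,
        loci=loci.iloc[keep].reset_index(drop=True),
        inbred=config.inbred,
    )


def maf_filter(panel: GenotypePanel, min_maf: float) -> GenotypePanel:
    """Drop loci whose minor-allele frequency is below ``min_maf``.

    A locus at exactly the threshold is retained (only frequencies *less
    than* the threshold are excluded).  Column order is preserved.
    """
    if panel.n_loci == 0:
        raise ValueError("empty panel")
    maf = panel.minor_allele_frequencies()
    keep = np.where(np.nan_to_num(maf, nan=-1.0) >= min_maf)[0]
    if keep.size == 0:
        raise ValueError(f"no loci with MAF >= {min_maf}")
    return panel.subset_loci(keep)


def drop_scaffold_loci(panel: GenotypePanel, chromosomes: list[str]) -> GenotypePanel:
    """Keep only loci on the whitelisted (anchored) chromosomes.

    Loci on unplaced scaffolds — any chromosome label outside the
    whitelist — are removed.
    """
    keep = np.where(panel.loci["chromosome"].isin(chromosomes).to_numpy())[0]
    if keep.size == 0:
        raise ValueError("no loci on whitelisted chromosomes")
    return panel.subset_loci(keep)


def impute_missing(panel: GenotypePanel, strategy: str = "haplotype_window", window: int = 2) -> GenotypePanel:
    """Replace missing dosages so no MISSING entries remain.

    ``column_mode`` substitutes the most frequent observed dosage at the
    locus (ties resolve to the lower dosage).  ``haplotype_window`` matches
    the individual's observed flanking dosages (up to ``window`` loci each
    side, same chromosome) against all complete individuals and substitutes
    the target dosage of the most frequent matching local haplotype,
    falling back to the column mode when no individual matches.
    """
    if strategy not in ("column_mode", "haplotype_window"):
        raise ValueError(f"unknown imputation strategy {strategy!r}")
    d = panel.dosages.copy()
    miss_r, miss_c = np.where(d == MISSING)
    if miss_r.size == 0:
        return panel
    chrom = panel.loci["chromosome"].to_numpy()
    for col in np.unique(miss_c):
        column = d[:, col]
        observed = column[column != MISSING]
        if observed.size == 0:
            raise ValueError(
                f"locus {panel.loci['locus_id'].iloc[col]!r} entirely missing"
            )
        vals, counts = np.unique(observed, return_counts=True)
        mode = int(vals[np.argmax(counts)])  # np.unique sorts: ties -> lower dosage
        rows = miss_r[miss_c == col]
        if strategy == "column_mode":
            d[rows, col] = mode
            continue
        lo, hi = col, col
        while lo > col - window and lo > 0 and chrom[lo - 1] == chrom[col]:
            lo -= 1
        while hi < col + window and hi + 1 < d.shape[1] and chrom[hi + 1] == chrom[col]:
            hi += 1
        flank_cols = [j for j in range(lo, hi + 1) if j != col]
        for i in rows:
            filled = _haplotype_window_value(d, i, col, flank_cols)
            d[i, col] = filled if filled is not None else mode
    return GenotypePanel(
        dosages=d,
        individual_ids=list(panel.individual_ids),
        loci=panel.loci.copy(),
        inbred=panel.inbred,
    )


def _haplotype_window_value(d, row, col, flank_cols) -> int | None:
    obs = [j for j in flank_cols if d[row, j] != MISSING]
    if not obs:
        return None
    donors = np.all(d[:, obs] == d[row, obs][None, :], axis=1) & (d[:, col] != MISSING)
    donors[row] = False
    values = d[donors, col]
    if values.size == 0:
        return None
    vals, counts = np.unique(values, return_counts=True)
    return int(vals[np.argmax(counts)])


def estimate_effective_segments(panel: GenotypePanel) -> float:
    """Effective number of independently segregating segments, Me.

    Computed as 1 / Var(off-diagonal entries of the centered-and-scaled
    genomic relationship matrix).  For L independent loci the off-diagonal
    variance is about 1/L, so Me tracks the locus count; LD and shared
    ancestry inflate the variance and shrink Me.  This is an approximation
    used to calibrate synthetic panels against a target prediction regime.
    """
    if panel.n_individuals < 2 or panel.n_loci < 2:
        raise ValueError("need at least 2 individuals and 2 loci")
    X = panel.dosages.astype(np.float64)
    X[panel.dosages == MISSING] = np.nan
    mu = np.nanmean(X, axis=0)
    sd = np.nanstd(X, axis=0)
    poly = sd > 0
    if poly.sum() < 2:
        raise ValueError("fewer than 2 polymorphic loci")
    W = (X[:, poly] - mu[poly]) / sd[poly]
    W = np.nan_to_num(W)
    G = W @ W.T / poly.sum()
    off = G[np.triu_indices_from(G, k=1)]
    v = off.var()
    if v <= 0:
        raise ValueError("zero off-diagonal variance (duplicated individuals?)")
    return float(1.0 / v)


# ---------------------------------------------------------------------------
# I/O: dosage TSV, VCF 4.x (GT only), HapMap diploid text
# ---------------------------------------------------------------------------

_TSV_NA = "NA"


def _encode_locus_header(row) -> str:
    return f"{row.locus_id}|{row.chromosome}|{row.position}"


def _decode_locus_headers(headers: list[str]) -> pd.DataFrame:
    ids, chroms, poss = [], [], []
    for i, h in enumerate(headers):
        parts = h.split("|")
        if len(parts) == 3 and parts[2].isdigit():
            ids.append(parts[0])
            chroms.append(parts[1])
            poss.append(int(parts[2]))
        else:
            ids.append(h)
            chroms.append("chr0")
            poss.append(i + 1)
    return pd.DataFrame({"locus_id": ids, "chromosome": chroms, "position": poss})


def write_genotypes(panel: GenotypePanel, path, format: str = "tsv") -> None:
    """Write a panel to ``tsv`` (lossless) or ``vcf`` (synthetic REF/ALT)."""
    path = Path(path)
    if format == "tsv":
        headers = [_encode_locus_header(r) for r in panel.loci.itertuples()]
        with open(path, "w") as fh:
            fh.write("individual_id\t" + "\t".join(headers) + "\n")
            for i, ind in enumerate(panel.individual_ids):
                row = [
                    _TSV_NA if v == MISSING else str(int(v))
                    for v in panel.dosages[i]
                ]
                fh.write(ind + "\t" + "\t".join(row) + "\n")
    elif format == "vcf":
        _write_vcf(panel, path)
    else:
        raise ValueError(f"unsupported output format {format!r}")


_GT_BY_DOSAGE = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}


def _write_vcf(panel: GenotypePanel, path: Path) -> None:
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=panelsim\n")
        for chrom in panel.loci["chromosome"].unique():
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(panel.individual_ids)
            + "\n"
        )
        for j, row in enumerate(panel.loci.itertuples()):
            gts = "\t".join(_GT_BY_DOSAGE[int(v)] for v in panel.dosages[:, j])
            fh.write(
                f"{row.chromosome}\t{row.position}\t{row.locus_id}\tA\tT\t.\t.\t.\tGT\t{gts}\n"
            )


def read_genotypes(path, format: str = "tsv") -> GenotypePanel:
    """Read a genotype matrix from ``vcf``, ``hapmap`` or ``tsv``.

    VCF dosage is the count of ALT alleles in GT (missing GT -> MISSING);
    multiallelic records are skipped with a warning.  HapMap diploid letter
    pairs are mapped against the record's two declared alleles.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.stat().st_size == 0:
        raise ValueError(f"{path} is empty")
    if format == "tsv":
        return _read_tsv(path)
    if format == "vcf":
        return _read_vcf(path)
    if format == "hapmap":
        return _read_hapmap(path)
    raise ValueError(f"unsupported input format {format!r}")


def _read_tsv(path: Path) -> GenotypePanel:
    try:
        df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise ValueError(f"malformed TSV {path}: {exc}") from exc
    if df.shape[1] == 0:
        raise ValueError(f"{path}: no locus columns")
    mat = np.full(df.shape, MISSING, dtype=np.int8)
    for j, colname in enumerate(df.columns):
        col = df.iloc[:, j]
        for i, v in enumerate(col):
            if pd.isna(v) or v == _TSV_NA:
                continue
            try:
                mat[i, j] = int(v)
            except ValueError as exc:
                raise ValueError(
                    f"{path} line {i + 2}: bad dosage {v!r} at {colname}"
                ) from exc
    loci = _decode_locus_headers(list(df.columns))
    inbred = not np.any(mat == 1)
    return GenotypePanel(
        dosages=mat,
        individual_ids=[str(x) for x in df.index],
        loci=loci,
        inbred=inbred,
    )


def _read_vcf(path: Path) -> GenotypePanel:
    from cyvcf2 import VCF

    try:
        vcf = VCF(str(path))
        samples = list(vcf.samples)
        rows = []
        meta = []
        for variant in vcf:
            if len(variant.ALT) != 1:
                warnings.warn(
                    f"skipping multiallelic record {variant.CHROM}:{variant.POS}",
                    stacklevel=2,
                )
                continue
            dos = np.full(len(samples), MISSING, dtype=np.int8)
            for i, gt in enumerate(variant.genotypes):
                alleles = [a for a in gt[:2] if a >= 0]
                if len(alleles) == 2:
                    dos[i] = sum(alleles)
            rows.append(dos)
            vid = variant.ID if variant.ID else f"{variant.CHROM}_{variant.POS}"
            meta.append((vid, variant.CHROM, variant.POS))
    except OSError as exc:
        raise ValueError(f"malformed VCF {path}: {exc}") from exc
    if not rows:
        raise ValueError(f"{path}: no usable biallelic records")
    mat = np.stack(rows, axis=1)
    loci = pd.DataFrame(meta, columns=list(LOCUS_COLUMNS))
    return GenotypePanel(
        dosages=mat,
        individual_ids=samples,
        loci=loci,
        inbred=not np.any(mat == 1),
    )


_HAPMAP_FIXED = 11  # rs# alleles chrom pos strand assembly# center protLSID assayLSID panelLSID QCcode


def _read_hapmap(path: Path) -> GenotypePanel:
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if len(header) <= _HAPMAP_FIXED:
            raise ValueError(f"{path} line 1: not a HapMap header")
        samples = header[_HAPMAP_FIXED:]
        rows, meta = [], []
        for lineno, line in enumerate(fh, start=2):
            fields = line.rstrip("\n").split("\t")
            if len(fields) != len(header):
                raise ValueError(f"{path} line {lineno}: wrong field count")
            alleles = fields[1].split("/")
            if len(alleles) != 2:
                raise ValueError(f"{path} line {lineno}: bad alleles {fields[1]!r}")
            ref, alt = alleles
            dos = np.full(len(samples), MISSING, dtype=np.int8)
            for i, call in enumerate(fields[_HAPMAP_FIXED:]):
                if len(call) != 2 or "N" in call:
                    continue
                if not set(call) <= {ref, alt}:
                    raise ValueError(
                        f"{path} line {lineno}: call {call!r} outside alleles {ref}/{alt}"
                    )
                dos[i] = call.count(alt)
            rows.append(dos)
            meta.append((fields[0], fields[2], int(fields[3])))
    if not rows:
        raise ValueError(f"{path}: no records")
    mat = np.stack(rows, axis=1)
    loci = pd.DataFrame(meta, columns=list(LOCUS_COLUMNS))
    return GenotypePanel(
        dosages=mat,
        individual_ids=samples,
        loci=loci,
        inbred=not np.any(mat == 1),
    )
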