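"""Genotype containers, simulators and format readers.

The package works on additive dosage matrices (samples x markers, entries in
{0, 1, 2}) for two kinds of panels: a *wild* diversity panel and an F2
*hybrid* panel produced by crossing wild accessions to a fixed, homozygous
cultivar parent.  The simulator emulates the structural features the method
depends on: blockwise linkage disequilibrium in the wild panel, Mendelian
F2 segregation in the hybrid panel, partial marker overlap between panels,
and a higher minor-allele frequency in wild than in hybrid material.

Dosage orientation: dosage counts the non-cultivar (alternate / wild)
allele, so the cultivar parent is dosage 0 everywhere.  Missing genotypes
are stored as ``MISSING`` (-1); the simulator never emits missing values,
but the readers admit them.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "MISSING",
    "GenotypeMatrix",
    "SimPopConfig",
    "simulate_wild_population",
    "simulate_f2_population",
    "read_vcf",
    "read_plink_raw",
    "write_plink_raw",
    "read_genotype_tsv",
    "write_genotype_tsv",
    "intersect_markers",
]

#: Sentinel for a missing dosage entry.
MISSING: int = -1

WILD = "wild"
HYBRID = "hybrid"


class GenotypeFormatError(ValueError):
    """Raised when an input genotype file violates the expected format."""


@dataclass
class GenotypeMatrix:
    """Samples x markers additive-dosage table with a population label.

    Parameters
    ----------
    sample_ids : ordered unique sample names, length ``n_samples``.
    marker_ids : ordered unique marker names, length ``n_markers``.
    dosage : integer array of shape ``(n_samples, n_markers)`` with entries
        in ``{0, 1, 2}`` or ``MISSING``.
    population : ``"wild"`` or ``"hybrid"``.
    """

    sample_ids: list[str]
    marker_ids: list[str]
    dosage: np.ndarray
    population: str

    def __post_init__(self) -> None:
        self.sample_ids = list(self.sample_ids)
        self.marker_ids = list(self.marker_ids)
        self.dosage = np.asarray(self.dosage, dtype=np.int16)
        if self.dosage.ndim != 2:
            raise ValueError("dosage must be a 2-D array")
        n, m = self.dosage.shape
        if n != len(self.sample_ids) or m != len(self.marker_ids):
            raise ValueError(
                f"dosage shape {self.dosage.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.marker_ids)} markers"
            )
        if len(set(self.sample_ids)) != n:
            raise ValueError("sample_ids are not unique")
        if len(set(self.marker_ids)) != m:
            raise ValueError("marker_ids are not unique")
        valid = np.isin(self.dosage, (0, 1, 2, MISSING))
        if not valid.all():
            bad = np.unique(self.dosage[~valid])
            raise ValueError(f"dosage entries outside {{0,1,2,{MISSING}}}: {bad}")
        if self.population not in (WILD, HYBRID):
            raise ValueError(f"population must be '{WILD}' or '{HYBRID}'")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_markers(self) -> int:
        return len(self.marker_ids)

    def dosage_float(self) -> np.ndarray:
        """Dosage as float64 with missing entries mapped to NaN."""
        out = self.dosage.astype(np.float64)
        out[self.dosage == MISSING] = np.nan
        return out

    def marker_index(self, marker_id: str) -> int:
        try:
            return self.marker_ids.index(marker_id)
        except ValueError:
            raise KeyError(f"marker {marker_id!r} not in matrix") from None

    def marker_dosage(self, marker_id: str) -> np.ndarray:
        return self.dosage[:, self.marker_index(marker_id)]

    def subset_markers(self, marker_ids: Sequence[str]) -> "GenotypeMatrix":
        idx = [self.marker_index(m) for m in marker_ids]
        return replace(self, marker_ids=list(marker_ids), dosage=self.dosage[:, idx])

    def subset_samples(self, indices: Sequence[int]) -> "GenotypeMatrix":
        idx = list(indices)
        return replace(
            self,
            sample_ids=[self.sample_ids[i] for i in idx],
            dosage=self.dosage[idx, :],
        )

    def allele_frequency(self) -> np.ndarray:
        """Per-marker alternate-allele frequency over non-missing entries."""
        d = self.dosage_float()
        with np.errstate(invalid="ignore"):
            return np.nanmean(d, axis=0) / 2.0

    def maf(self) -> np.ndarray:
        """Per-marker minor-allele frequency."""
        f = self.allele_frequency()
        return np.minimum(f, 1.0 - f)

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(self.dosage, index=self.sample_ids, columns=self.marker_ids)


@dataclass
class SimPopConfig:
    """Configuration for the wild / F2 panel simulator.

    Defaults emulate the Bari-like study conditions: 143 wild samples, a 140
    sample F2 panel, blockwise LD, wild minor-allele frequencies drawn
    uniformly from (0.1, 0.5), and full marker overlap at the post-filter
    scale.

    Attributes
    ----------
    ld_block_size : markers per linkage block; 1 means independent markers.
    ld_rho : latent Gaussian-copula correlation shared within a block.
    shared_marker_fraction : fraction of hybrid marker ids that keep the
        wild panel's ids; the rest are renamed as hybrid-private markers.
    alt_major_fraction : fraction of markers at which the non-cultivar
        allele is the *major* allele in the wild panel (frequency 1 - MAF
        rather than MAF).  Interspecific divergence makes such markers
        common; they segregate broadly in the F2 and are the natural
        trans-suppressor candidates.
    n_parent_lines : number of distinct wild accessions used as F2 parents.
    recomb_rate : per-adjacent-marker recombination probability within a
        block (adjacent blocks assort independently).
    """

    n_wild: int = 143
    n_hybrid: int = 140
    n_markers: int = 125
    ld_block_size: int = 1
    wild_maf_range: tuple[float, float] = (0.1, 0.5)
    shared_marker_fraction: float = 1.0
    seed: int = 0
    ld_rho: float = 0.8
    alt_major_fraction: float = 0.5
    n_parent_lines: int = 20
    recomb_rate: float = 0.05

    def validate(self) -> None:
        for name in ("n_wild", "n_hybrid", "n_markers", "ld_block_size", "n_parent_lines"):
            if int(getattr(self, name)) < 1:
                raise ValueError(f"{name} must be a positive count")
        lo, hi = self.wild_maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ValueError("wild_maf_range must lie within (0, 0.5]")
        if not (0.0 < self.shared_marker_fraction <= 1.0):
            raise ValueError("shared_marker_fraction must be in (0, 1]")
        if not (0.0 <= self.ld_rho < 1.0):
            raise ValueError("ld_rho must be in [0, 1)")
        if not (0.0 <= self.alt_major_fraction <= 1.0):
            raise ValueError("alt_major_fraction must be in [0, 1]")
        if not (0.0 <= self.recomb_rate <= 0.5):
            raise ValueError("recomb_rate must be in [0, 0.5]")


def _wild_haplotypes(cfg: SimPopConfig, rng: np.random.Generator) -> np.ndarray:
    """Draw 2*n_wild haplotypes with blockwise Gaussian-copula LD.

    Markers within an ``ld_block_size`` block share a latent block factor
    with loading sqrt(ld_rho), so within-block allele correlation exceeds
    between-block correlation; blocks are independent.
    """
    from scipy.stats import norm

    m = cfg.n_markers
    n_hap = 2 * cfg.n_wild
    freqs = rng.uniform(cfg.wild_maf_range[0], cfg.wild_maf_range[1], size=m)
    flip = rng.random(m) < cfg.alt_major_fraction
    freqs = np.where(flip, 1.0 - freqs, freqs)
    n_blocks = math.ceil(m / cfg.ld_block_size)
    block_of = np.repeat(np.arange(n_blocks), cfg.ld_block_size)[:m]
    z_block = rng.standard_normal((n_hap, n_blocks))
    eps = rng.standard_normal((n_hap, m))
    rho = cfg.ld_rho if cfg.ld_block_size > 1 else 0.0
    z = math.sqrt(rho) * z_block[:, block_of] + math.sqrt(1.0 - rho) * eps
    thresh = norm.ppf(freqs)
    hap = (z < thresh[None, :]).astype(np.int8)
    return hap, freqs


def simulate_wild_population(cfg: SimPopConfig) -> GenotypeMatrix:
    """Simulate a wild diversity panel with blockwise LD.

    Each individual is the sum of two haplotypes drawn from a Gaussian
    copula whose correlation structure is block-diagonal.  Marginal
    alternate-allele frequencies are uniform on ``wild_maf_range``.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    hap, _ = _wild_haplotypes(cfg, rng)
    dosage = hap[0::2] + hap[1::2]
    sample_ids = [f"wild_{i:04d}" for i in range(cfg.n_wild)]
    marker_ids = [f"m{j:05d}" for j in range(cfg.n_markers)]
    return GenotypeMatrix(sample_ids, marker_ids, dosage, WILD)


def _phase_naive(dosage_row: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Split one dosage vector into two haplotypes (random phase at hets)."""
    m = dosage_row.shape[0]
    h = np.zeros((2, m), dtype=np.int8)
    h[:, dosage_row == 2] = 1
    het = np.flatnonzero(dosage_row == 1)
    which = rng.integers(0, 2, size=het.size)
    h[which, het] = 1
    return h


def _gamete(hap_pair: np.ndarray, cfg: SimPopConfig, rng: np.random.Generator) -> np.ndarray:
    """One recombinant gamete from a pair of haplotypes.

    A Markov chain along the markers: switch strands with probability
    ``recomb_rate`` between adjacent markers inside a block and with
    probability 0.5 at block boundaries (blocks assort independently).
    """
    m = hap_pair.shape[1]
    switch_p = np.full(m, cfg.recomb_rate)
    switch_p[0] = 0.5  # initial strand uniform
    if cfg.ld_block_size < m:
        starts = np.arange(cfg.ld_block_size, m, cfg.ld_block_size)
        switch_p[starts] = 0.5
    switches = rng.random(m) < switch_p
    strand = np.cumsum(switches) % 2
    return hap_pair[strand, np.arange(m)]


def simulate_f2_population(wild: GenotypeMatrix, cfg: SimPopConfig) -> GenotypeMatrix:
    """Simulate an F2 hybrid panel from wild accessions x a fixed cultivar.

    ``n_parent_lines`` wild samples are drawn as parents; each F2 individual
    descends from one of them.  The cultivar parent is homozygous dosage 0
    everywhere, so the F1 carries one (recombinant) wild gamete and one null
    haplotype; selfing the F1 yields dosages that segregate 1:2:1 at
    markers where the transmitted wild allele is present.  Only
    ``shared_marker_fraction`` of the marker ids keep their wild-panel
    names; the rest are renamed as hybrid-private markers.
    """
    cfg.validate()
    if wild.n_samples == 0 or wild.n_markers == 0:
        raise ValueError("wild population is empty")
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 0xF2]))
    n_par = min(cfg.n_parent_lines, wild.n_samples)
    parent_rows = rng.choice(wild.n_samples, size=n_par, replace=False)
    parent_haps = [_phase_naive(wild.dosage[i], rng) for i in parent_rows]

    m = wild.n_markers
    dosage = np.zeros((cfg.n_hybrid, m), dtype=np.int16)
    assignment = rng.integers(0, n_par, size=cfg.n_hybrid)
    null_hap = np.zeros(m, dtype=np.int8)
    for i in range(cfg.n_hybrid):
        wild_gamete = _gamete(parent_haps[assignment[i]], cfg, rng)
        f1 = np.stack([wild_gamete, null_hap])
        dosage[i] = _gamete(f1, cfg, rng) + _gamete(f1, cfg, rng)

    marker_ids = list(wild.marker_ids)
    if cfg.shared_marker_fraction < 1.0:
        n_shared = max(1, int(round(cfg.shared_marker_fraction * m)))
        private = rng.choice(m, size=m - n_shared, replace=False)
        for rank, j in enumerate(sorted(private)):
            marker_ids[j] = f"hyb_{rank:05d}"
    sample_ids = [f"hyb_{i:04d}" for i in range(cfg.n_hybrid)]
    return GenotypeMatrix(sample_ids, marker_ids, dosage, HYBRID)


def read_vcf(path: str | Path, population: str = HYBRID) -> GenotypeMatrix:
    """Read diploid GT fields from a VCF into a dosage matrix.

    Dosage is the alternate-allele count; missing genotypes become
    ``MISSING``.  Multi-allelic records are rejected.
    """
    from cyvcf2 import VCF

    path = str(path)
    try:
        vcf = VCF(path, gts012=True)
    except Exception as exc:  # cyvcf2 raises bare OSError on bad files
        raise GenotypeFormatError(f"cannot open VCF {path}: {exc}") from exc
    samples = list(vcf.samples)
    marker_ids: list[str] = []
    rows: list[np.ndarray] = []
    for i, rec in enumerate(vcf, start=1):
        if len(rec.ALT) > 1:
            raise GenotypeFormatError(
                f"multi-allelic site at record {i} ({rec.CHROM}:{rec.POS}); "
                "split or filter multi-allelic variants first"
            )
        # gts012: 0/1/2 = alt dosage, 3 = missing
        g = np.asarray(rec.gt_types, dtype=np.int16)
        g[g == 3] = MISSING
        rows.append(g)
        vid = rec.ID if rec.ID not in (None, ".") else f"{rec.CHROM}:{rec.POS}"
        marker_ids.append(vid)
    dosage = (
        np.stack(rows, axis=1) if rows else np.zeros((len(samples), 0), dtype=np.int16)
    )
    return GenotypeMatrix(samples, marker_ids, dosage, population)


def read_plink_raw(path: str | Path, population: str = HYBRID) -> GenotypeMatrix:
    """Read a PLINK additive-dosage ``.raw``-style text table.

    Expects a whitespace-delimited header ``FID IID [PAT MAT SEX PHENOTYPE]
    marker...`` followed by one row per sample; marker entries are 0/1/2 or
    NA.  Samples are identified by their IID column.
    """
    path = Path(path)
    with path.open() as fh:
        header = fh.readline().split()
        if len(header) < 2 or header[0] != "FID" or header[1] != "IID":
            raise GenotypeFormatError(f"{path}: expected header starting 'FID IID'")
        meta_cols = 2
        for extra in ("PAT", "MAT", "SEX", "PHENOTYPE"):
            if len(header) > meta_cols and header[meta_cols] == extra:
                meta_cols += 1
        marker_ids = header[meta_cols:]
        sample_ids: list[str] = []
        rows: list[list[int]] = []
        for lineno, line in enumerate(fh, start=2):
            fields = line.split()
            if not fields:
                continue
            if len(fields) != len(header):
                raise GenotypeFormatError(
                    f"{path}:{lineno}: expected {len(header)} fields, got {len(fields)}"
                )
            sample_ids.append(fields[1])
            row = []
            for m_id, tok in zip(marker_ids, fields[meta_cols:]):
                if tok == "NA":
                    row.append(MISSING)
                elif tok in ("0", "1", "2"):
                    row.append(int(tok))
                else:
                    raise GenotypeFormatError(
                        f"{path}:{lineno}: marker {m_id} has dosage {tok!r}, "
                        "expected 0/1/2/NA"
                    )
            rows.append(row)
    dosage = (
        np.asarray(rows, dtype=np.int16)
        if rows
        else np.zeros((0, len(marker_ids)), dtype=np.int16)
    )
    return GenotypeMatrix(sample_ids, marker_ids, dosage, population)


def write_plink_raw(G: GenotypeMatrix, path: str | Path) -> None:
    """Write the PLINK additive-dosage dialect read by :func:`read_plink_raw`."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write("FID IID " + " ".join(G.marker_ids) + "\n")
        for i, sid in enumerate(G.sample_ids):
            toks = ["NA" if d == MISSING else str(int(d)) for d in G.dosage[i]]
            fh.write(f"{sid} {sid} " + " ".join(toks) + "\n")


def write_genotype_tsv(G: GenotypeMatrix, path: str | Path) -> None:
    """Write a samples x markers TSV with a marker-id header row."""
    G.to_dataframe().to_csv(path, sep="\t", index_label="sample_id")


def read_genotype_tsv(path: str | Path, population: str) -> GenotypeMatrix:
    import pandas as pd

    df = pd.read_csv(path, sep="\t", index_col=0)
    dosage = df.to_numpy()
    dosage = np.where(np.isnan(dosage.astype(float)), MISSING, dosage).astype(np.int16)
    return GenotypeMatrix(
        [str(s) for s in df.index], [str(m) for m in df.columns], dosage, population
    )


def intersect_markers(wild: GenotypeMatrix, hybrid: GenotypeMatrix) -> list[str]:
    """Marker ids present in both panels, in hybrid order.

    These shared markers are the candidate causal set and the space in
    which wild/hybrid genotype distances are computed.
    """
    if wild.n_markers == 0 or hybrid.n_markers == 0:
        raise ValueError("both genotype matrices must be non-empty")
    wild_set = set(wild.marker_ids)
    shared = [m for m in hybrid.marker_ids if m in wild_set]
    if not shared:
        raise ValueError("wild and hybrid panels share no markers")
    return shared
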