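"""Synthetic-data generators with known ground truth.

Every downstream analysis in the toolkit has a generator here that
produces inputs with the statistical structure the analysis assumes:

* a star-genealogy mitogenome cohort (one founder haplotype, independent
  Poisson mutations per descendant lineage, optional heteroplasmy) for
  the mutation-frequency colonization clock;
* per-SNP local-ancestry probability tracks containing introgressed
  blocks of known boundaries and copy numbers, in the shape of Hapmix
  HAPLOID-mode output;
* microsatellite genotypes drawn under Hardy–Weinberg equilibrium from
  stated allele frequencies;
* 2-D landmark configurations = group mean shape + isotropic landmark
  noise + nuisance rotation/translation/scale.

All generators are deterministic under a fixed seed; each accepts either
an integer seed or a ``numpy.random.Generator``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .mito import IUPAC_FOR_PAIR, MitoAlignment

__all__ = [
    "MitoSimTruth",
    "AncestrySimTruth",
    "simulate_mito_cohort",
    "simulate_ancestry_tracks",
    "simulate_microsat_genotypes",
    "simulate_landmarks",
]

NUCLEOTIDES = "ACGT"


def _rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


# ----------------------------------------------------------- mitogenomes

@dataclass
class MitoSimTruth:
    """Ground truth for a simulated star-genealogy mitogenome cohort."""

    founder_sequence: str
    per_genome_mutations: list  # (genome_id, 0-based position, derived base)
    heteroplasmic_positions: list  # (genome_id, 0-based position)
    control_region: tuple  # half-open [start, end), 0-based
    mu: float  # expected mutations per site per genome


def simulate_mito_cohort(
    founder_sequence: str,
    n_genomes: int,
    mu: float,
    control_region: tuple | None = None,
    heteroplasmy_prob: float = 0.0,
    seed=None,
    id_prefix: str = "SIM_",
) -> tuple[MitoAlignment, MitoSimTruth]:
    """Simulate a cohort descending from one founder haplotype.

    Each genome independently accumulates ``Poisson(mu * L)`` new point
    mutations at uniformly drawn positions (a position already hit in
    the same genome is re-drawn, i.e. infinite-sites within a lineage).
    With probability ``heteroplasmy_prob`` a mutation is emitted as a
    double peak: the sequence carries the two-base IUPAC code for
    {founder base, derived base}.
    """
    founder_sequence = founder_sequence.upper()
    if set(founder_sequence) - set(NUCLEOTIDES):
        bad = sorted(set(founder_sequence) - set(NUCLEOTIDES))
        raise ValueError(f"founder contains non-nucleotide characters: {bad}")
    if n_genomes < 1:
        raise ValueError("n_genomes must be >= 1")
    if mu < 0:
        raise ValueError("mu must be non-negative")
    if not 0 <= heteroplasmy_prob <= 1:
        raise ValueError("heteroplasmy_prob must be in [0, 1]")
    L = len(founder_sequence)
    if control_region is None:
        control_region = (L, L)
    cr_start, cr_end = control_region
    if not (0 <= cr_start <= cr_end <= L):
        raise ValueError("control_region outside sequence bounds")
    if cr_end - cr_start >= L:
        raise ValueError("founder must be longer than the control region")

    rng = _rng(seed)
    founder_arr = np.frombuffer(founder_sequence.encode(), dtype=np.uint8)
    sequences: dict[str, str] = {}
    mutations: list[tuple] = []
    heteroplasmies: list[tuple] = []
    width = max(2, len(str(n_genomes)))
    for g in range(n_genomes):
        gid = f"{id_prefix}{g + 1:0{width}d}"
        arr = founder_arr.copy()
        k = int(rng.poisson(mu * L))
        used: set[int] = set()
        for _ in range(k):
            pos = int(rng.integers(L))
            while pos in used:
                pos = int(rng.integers(L))
            used.add(pos)
            ref = founder_sequence[pos]
            derived = NUCLEOTIDES[
                (NUCLEOTIDES.index(ref) + 1 + int(rng.integers(3))) % 4
            ]
            mutations.append((gid, pos, derived))
            if rng.random() < heteroplasmy_prob:
                arr[pos] = ord(IUPAC_FOR_PAIR[frozenset((ref, derived))])
                heteroplasmies.append((gid, pos))
            else:
                arr[pos] = ord(derived)
        sequences[gid] = arr.tobytes().decode()

    alignment = MitoAlignment(sequences=sequences, control_region=control_region)
    truth = MitoSimTruth(
        founder_sequence=founder_sequence,
        per_genome_mutations=mutations,
        heteroplasmic_positions=heteroplasmies,
        control_region=control_region,
        mu=mu,
    )
    return alignment, truth


def random_founder(length: int, seed=None) -> str:
    """A uniform-random nucleotide string, handy as a simulation founder."""
    rng = _rng(seed)
    return "".join(rng.choice(list(NUCLEOTIDES), size=length))


# ------------------------------------------------------- ancestry tracks

@dataclass
class AncestrySimTruth:
    """Truth for simulated local-ancestry tracks.

    ``blocks`` are half-open bp intervals ``(chrom, start, end,
    haplotype_ids)`` where each haplotype id is ``(individual,
    haplotype)`` with haplotype in {1, 2}.
    """

    blocks: list
    chrom_lengths: dict
    n_individuals: int
    noise_sd: float = 0.0

    def __post_init__(self):
        if not 0 <= self.noise_sd < 0.5:
            raise ValueError("noise_sd must be in [0, 0.5)")
        valid = {
            (f"IND_{i + 1}", h)
            for i in range(self.n_individuals)
            for h in (1, 2)
        }
        for chrom, start, end, haps in self.blocks:
            if chrom not in self.chrom_lengths:
                raise ValueError(f"block on unknown chromosome {chrom!r}")
            if not (0 <= start < end <= self.chrom_lengths[chrom]):
                raise ValueError(f"block {chrom}:{start}-{end} out of bounds")
            if not set(haps) <= valid:
                raise ValueError(f"unknown haplotype ids in block: {haps}")

    def haplotype_ids(self):
        return [
            (f"IND_{i + 1}", h)
            for i in range(self.n_individuals)
            for h in (1, 2)
        ]


def simulate_ancestry_tracks(
    truth: AncestrySimTruth,
    snp_spacing: int,
    unknown_fraction: float = 0.0,
    seed=None,
) -> pd.DataFrame:
    """Emit a per-SNP source-A ancestry-probability table.

    SNPs sit on a regular grid (every ``snp_spacing`` bp, 1-based). The
    probability of carrying one source-A copy is drawn near 1 inside
    truth blocks (for the listed haplotypes) and near 0 outside, with
    Gaussian noise of the truth's ``noise_sd`` truncated to [0, 1]. A
    ``unknown_fraction`` of SNPs carries the literal unknown-ancestry
    code 9.
    """
    if snp_spacing <= 0:
        raise ValueError("snp_spacing must be positive")
    if not truth.chrom_lengths:
        raise ValueError("empty chromosome map")
    rng = _rng(seed)
    frames = []
    for chrom, length in truth.chrom_lengths.items():
        positions = np.arange(1, length + 1, snp_spacing, dtype=np.int64)
        for ind, hap in truth.haplotype_ids():
            base = np.zeros(len(positions))
            for bchrom, start, end, haps in truth.blocks:
                if bchrom == chrom and (ind, hap) in set(haps):
                    inside = (positions - 1 >= start) & (positions - 1 < end)
                    base[inside] = 1.0
            prob = base
            if truth.noise_sd > 0:
                prob = np.clip(
                    base + rng.normal(0.0, truth.noise_sd, len(positions)), 0, 1
                )
            if unknown_fraction > 0:
                prob = prob.copy()
                prob[rng.random(len(positions)) < unknown_fraction] = 9.0
            frames.append(
                pd.DataFrame(
                    {
                        "individual": ind,
                        "haplotype": hap,
                        "chrom": chrom,
                        "pos": positions,
                        "prob_sourceA": prob,
                    }
                )
            )
    return pd.concat(frames, ignore_index=True)


# --------------------------------------------------------- microsatellites

def simulate_microsat_genotypes(
    allele_freqs: dict,
    n_individuals: int,
    seed=None,
    missing_rate: float = 0.0,
    population: str = "SIM",
) -> pd.DataFrame:
    """Draw genotypes under Hardy–Weinberg from per-locus allele frequencies.

    ``allele_freqs`` maps locus name -> {allele (positive int): frequency};
    frequencies at each locus must sum to 1. Returns the long genotype
    table (population, individual, locus, allele1, allele2) with NaN for
    missing calls.
    """
    if n_individuals < 1:
        raise ValueError("n_individuals must be >= 1")
    rng = _rng(seed)
    rows = []
    for locus, freqs in allele_freqs.items():
        alleles = np.array(sorted(freqs), dtype=int)
        p = np.array([freqs[a] for a in alleles], dtype=float)
        if (p < 0).any():
            raise ValueError(f"negative allele frequency at locus {locus!r}")
        if (alleles <= 0).any():
            raise ValueError(f"alleles must be positive integers at {locus!r}")
        if not math.isclose(p.sum(), 1.0, abs_tol=1e-9):
            raise ValueError(f"frequencies at locus {locus!r} do not sum to 1")
        draws = rng.choice(alleles, size=(n_individuals, 2), p=p)
        miss = rng.random(n_individuals) < missing_rate
        for i in range(n_individuals):
            a1, a2 = (np.nan, np.nan) if miss[i] else (draws[i, 0], draws[i, 1])
            rows.append((population, f"IND_{i + 1}", locus, a1, a2))
    return pd.DataFrame(
        rows, columns=["population", "individual", "locus", "allele1", "allele2"]
    )


# --------------------------------------------------------------- landmarks

@dataclass
class LandmarkSimTruth:
    """Applied nuisance transform per specimen."""

    group: dict = field(default_factory=dict)
    rotation: dict = field(default_factory=dict)
    translation: dict = field(default_factory=dict)
    scale: dict = field(default_factory=dict)


def simulate_landmarks(
    mean_shapes: dict,
    n_per_group: int,
    landmark_noise_sd: float = 0.0,
    rotation_range: tuple = (0.0, 2 * math.pi),
    translation_range: tuple = (0.0, 0.0),
    scale_range: tuple = (1.0, 1.0),
    seed=None,
):
    """Simulate landmark configurations around group mean shapes.

    Each specimen is its group mean plus iid Gaussian landmark noise,
    then rotated, scaled and translated by nuisance parameters drawn
    uniformly from the given ranges. Returns ``(LandmarkSet, truth)``
    where the truth records group membership and the applied transform.
    """
    from .morpho import LandmarkSet

    if landmark_noise_sd < 0:
        raise ValueError("landmark_noise_sd must be non-negative")
    rng = _rng(seed)
    shapes = {g: np.asarray(m, dtype=float) for g, m in mean_shapes.items()}
    k = None
    for g, m in shapes.items():
        if m.ndim != 2 or m.shape[1] != 2:
            raise ValueError(f"mean shape for group {g!r} is not k x 2")
        if k is None:
            k = m.shape[0]
        elif m.shape[0] != k:
            raise ValueError("mean shapes have differing landmark counts")
        if np.allclose(m, m[0]):
            raise ValueError(f"degenerate mean shape for group {g!r}")

    coords, ids, groups = [], [], []
    truth = LandmarkSimTruth()
    for g in sorted(shapes):
        for i in range(n_per_group):
            sid = f"{g}_{i + 1:03d}"
            config = shapes[g] + rng.normal(0, landmark_noise_sd, (k, 2))
            theta = rng.uniform(*rotation_range)
            scale = rng.uniform(*scale_range)
            shift = rng.uniform(
                translation_range[0], translation_range[1], size=2
            )
            rot = np.array(
                [[math.cos(theta), -math.sin(theta)],
                 [math.sin(theta), math.cos(theta)]]
            )
            coords.append(scale * config @ rot.T + shift)
            ids.append(sid)
            groups.append(g)
            truth.group[sid] = g
            truth.rotation[sid] = theta
            truth.translation[sid] = shift
            truth.scale[sid] = scale
    return LandmarkSet(np.stack(coords), ids, groups), truth
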