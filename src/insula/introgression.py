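"""Local-ancestry post-processing: introgression blocks and copy counts.

Consumes per-SNP probabilities of carrying one haplotype copy from a
source population (the shape emitted by Hapmix in HAPLOID mode, with the
literal code 9 for unknown ancestry), thresholds them into per-haplotype
calls, merges consecutive introgressed SNPs into blocks, sweeps the
cohort's blocks into a piecewise-constant copy-number profile, and
summarizes genome fractions and fixed regions.

Block coordinates follow the resolution-honest convention: a block runs
from the first SNP of a run to the last SNP + 1 (half-open on 1-based
positions), so lengths never extend beyond observed support. BED output
converts to the standard 0-based half-open convention.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "UNKNOWN_CODE",
    "GenomeSummary",
    "call_introgressed_snps",
    "merge_blocks",
    "copy_count_profile",
    "genome_fraction",
    "fixed_regions",
    "blocks_to_bed",
    "profile_to_bedgraph",
]

UNKNOWN_CODE = 9.0
BLOCK_COLUMNS = ["individual", "haplotype", "chrom", "start", "end", "length"]

_SEX_CHROMS = {"X", "Y", "M", "MT", "chrX", "chrY", "chrM", "chrMT"}


def _validate_track(track: pd.DataFrame) -> None:
    prob = track["prob_sourceA"].to_numpy(dtype=float)
    bad = ~(((prob >= 0) & (prob <= 1)) | (prob == UNKNOWN_CODE))
    if bad.any():
        row = track.iloc[int(np.nonzero(bad)[0][0])]
        raise ValueError(
            "ancestry probability outside [0, 1] and != 9: "
            f"{row['individual']} hap{row['haplotype']} "
            f"{row['chrom']}:{row['pos']} prob={row['prob_sourceA']}"
        )
    for (ind, hap, chrom), grp in track.groupby(
        ["individual", "haplotype", "chrom"], sort=False
    ):
        pos = grp["pos"].to_numpy()
        if (np.diff(pos) <= 0).any():
            raise ValueError(
                f"positions not strictly increasing for {ind} hap{hap} {chrom}"
            )


def call_introgressed_snps(track: pd.DataFrame, threshold: float = 0.9) -> pd.DataFrame:
    """Threshold per-SNP source-A probabilities into introgression calls.

    Adds a nullable-boolean ``call`` column: True where ``prob_sourceA >=
    threshold``, False below, and NA (unknown) for the code-9 SNPs, which
    are neither introgressed nor non-introgressed.
    """
    if not 0 < threshold <= 1:
        raise ValueError("threshold must be in (0, 1]")
    _validate_track(track)
    out = track.copy()
    prob = out["prob_sourceA"].to_numpy(dtype=float)
    call = pd.array(prob >= threshold, dtype="boolean")
    call[prob == UNKNOWN_CODE] = pd.NA
    out["call"] = call
    return out


def merge_blocks(calls: pd.DataFrame, gap_policy: str = "bridge") -> pd.DataFrame:
    """Merge consecutive introgressed SNP calls into blocks per haplotype.

    A block is a maximal run of introgressed SNPs: start = position of
    the first SNP in the run, end = position of the last SNP + 1
    (half-open). A non-introgressed SNP always terminates a run.
    Unknown-ancestry SNPs bridge a run under the default
    ``gap_policy="bridge"`` (they never start or end one); with
    ``gap_policy="break"`` they terminate runs like a negative call.
    """
    if gap_policy not in ("bridge", "break"):
        raise ValueError(f"unknown gap_policy {gap_policy!r}")
    rows = []
    for (ind, hap, chrom), grp in calls.groupby(
        ["individual", "haplotype", "chrom"], sort=True
    ):
        grp = grp.sort_values("pos")
        pos = grp["pos"].to_numpy()
        call = grp["call"]
        run_start = None  # position of first True in the current run
        run_end = None  # position of last True seen
        for p, c in zip(pos, call):
            if c is pd.NA or (isinstance(c, float) and np.isnan(c)):
                if gap_policy == "break" and run_start is not None:
                    rows.append((ind, hap, chrom, run_start, run_end + 1))
                    run_start = None
                continue  # bridge: neither starts nor ends a run
            if c:
                if run_start is None:
                    run_start = p
                run_end = p
            else:
                if run_start is not None:
                    rows.append((ind, hap, chrom, run_start, run_end + 1))
                    run_start = None
        if run_start is not None:
            rows.append((ind, hap, chrom, run_start, run_end + 1))
    df = pd.DataFrame(
        rows, columns=["individual", "haplotype", "chrom", "start", "end"]
    )
    df["length"] = df["end"] - df["start"]
    return df


def copy_count_profile(blocks: pd.DataFrame) -> dict:
    """Sweep-line copy-number profile of the cohort's blocks.

    Returns ``{chrom: DataFrame(start, end, n_copies)}`` of maximal
    segments with constant copy number (zero-count segments omitted);
    breakpoints fall exactly at block boundaries. Overlapping blocks
    from the same haplotype violate the block invariant and are
    rejected.
    """
    for (ind, hap, chrom), grp in blocks.groupby(
        ["individual", "haplotype", "chrom"], sort=False
    ):
        g = grp.sort_values("start")
        if (g["start"].to_numpy()[1:] < g["end"].to_numpy()[:-1]).any():
            raise ValueError(
                f"overlapping blocks for haplotype {ind} hap{hap} on {chrom}"
            )
    profile = {}
    for chrom, grp in blocks.groupby("chrom", sort=True):
        events = np.concatenate(
            [
                np.stack([grp["start"].to_numpy(), np.ones(len(grp))], axis=1),
                np.stack([grp["end"].to_numpy(), -np.ones(len(grp))], axis=1),
            ]
        )
        order = np.lexsort((events[:, 1], events[:, 0]))
        events = events[order]
        segs = []
        count = 0
        prev = None
        for bp, delta in events:
            if prev is not None and bp > prev and count > 0:
                segs.append((int(prev), int(bp), int(count)))
            count += int(delta)
            prev = bp
        df = pd.DataFrame(segs, columns=["start", "end", "n_copies"])
        # merge touching segments with equal counts
        merged = []
        for row in df.itertuples(index=False):
            if merged and merged[-1][1] == row.start and merged[-1][2] == row.n_copies:
                merged[-1][1] = row.end
            else:
                merged.append([row.start, row.end, row.n_copies])
        profile[chrom] = pd.DataFrame(
            merged, columns=["start", "end", "n_copies"]
        )
    return profile


@dataclass
class GenomeSummary:
    """Genome fractions covered by >= k source-A copies, and fixed regions."""

    fractions: dict  # k -> total fraction over autosomes
    per_chrom: dict = field(default_factory=dict)  # chrom -> {k: fraction}
    denominator_bp: int = 0
    autosomes: list = field(default_factory=list)


def _autosomes(chrom_lengths: dict, autosomes=None) -> list:
    if autosomes is not None:
        return list(autosomes)
    return [c for c in chrom_lengths if c not in _SEX_CHROMS]


def genome_fraction(
    profile: dict,
    chrom_lengths: dict,
    min_copies: int = 1,
    max_copies: int | None = None,
    autosomes=None,
) -> GenomeSummary:
    """Fraction of the genome carrying at least k source-A haplotype copies.

    The denominator is the summed length of the autosomes (sex
    chromosomes are excluded unless an explicit ``autosomes`` list is
    given). Fractions are reported for every k from 1 to ``max_copies``
    (default: the largest observed copy number, or ``min_copies``).
    """
    unknown = set(profile) - set(chrom_lengths)
    if unknown:
        raise ValueError(f"profile chromosomes not in chrom_lengths: {sorted(unknown)}")
    autos = _autosomes(chrom_lengths, autosomes)
    denom = sum(chrom_lengths[c] for c in autos)
    if denom <= 0:
        raise ValueError("autosome length denominator is zero")
    observed_max = 0
    for chrom, segs in profile.items():
        if len(segs) and segs["end"].max() - 1 > chrom_lengths[chrom]:
            raise ValueError(f"block beyond end of chromosome {chrom}")
        if len(segs):
            observed_max = max(observed_max, int(segs["n_copies"].max()))
    kmax = max_copies if max_copies is not None else max(observed_max, min_copies)

    fractions = {}
    per_chrom: dict = {c: {} for c in autos}
    for k in range(1, kmax + 1):
        total = 0
        for chrom in autos:
            segs = profile.get(chrom)
            if segs is None or not len(segs):
                per_chrom[chrom][k] = 0.0
                continue
            covered = int(
                (segs.loc[segs["n_copies"] >= k, "end"]
                 - segs.loc[segs["n_copies"] >= k, "start"]).sum()
            )
            per_chrom[chrom][k] = covered / chrom_lengths[chrom]
            total += covered
        fractions[k] = total / denom
    return GenomeSummary(
        fractions=fractions,
        per_chrom=per_chrom,
        denominator_bp=denom,
        autosomes=autos,
    )


def fixed_regions(profile: dict, total_haplotypes: int) -> pd.DataFrame:
    """Maximal intervals where every sampled haplotype carries source-A
    ancestry (n_copies equal to the cohort's 2N)."""
    if total_haplotypes < 1:
        raise ValueError("total_haplotypes must be >= 1")
    rows = []
    for chrom in sorted(profile):
        segs = profile[chrom]
        fixed = segs[segs["n_copies"] == total_haplotypes]
        current = None
        for row in fixed.itertuples(index=False):
            if current is not None and row.start == current[2]:
                current[2] = row.end
            else:
                if current is not None:
                    rows.append(tuple(current))
                current = [chrom, row.start, row.end]
        if current is not None:
            rows.append(tuple(current))
    return pd.DataFrame(rows, columns=["chrom", "start", "end"])


def blocks_to_bed(blocks: pd.DataFrame) -> list:
    """Convert 1-based half-open block coordinates to BED intervals."""
    return [
        (row.chrom, int(row.start) - 1, int(row.end) - 1)
        for row in blocks.itertuples(index=False)
    ]


def profile_to_bedgraph(profile: dict) -> list:
    rows = []
    for chrom in sorted(profile):
        for row in profile[chrom].itertuples(index=False):
            rows.append((chrom, int(row.start) - 1, int(row.end) - 1,
                         float(row.n_copies)))
    return rows
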