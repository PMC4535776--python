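"""Mitochondrial mutation-frequency dating of an island colonization.

The clock assumes a star genealogy: every sampled mitogenome descends
independently from the single founder haplotype, so each base that
differs from the cohort consensus is a *new* mutation accumulated since
colonization. The per-nucleotide mutation frequency

    f = (number of counted mutation positions) / (n_genomes x counted bp)

is compared with a calibration point — an island of known colonization
age with a measured frequency — and the age follows by proportionality.
The hypervariable control region (D-loop) is excluded from both the
numerator and the denominator, and positions whose only evidence is a
heteroplasmic double peak are not counted when the same derived allele
is fixed elsewhere in the cohort (inherited, not new).

Coordinates are 1-based in every report, matching the genomic tables the
method is read against; internal arrays are 0-based half-open.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from functools import cached_property

import numpy as np
import pandas as pd

__all__ = [
    "MitoAlignment",
    "MutationCall",
    "CalibrationPoint",
    "ConservationMatrix",
    "AgeEstimate",
    "ConsensusError",
    "consensus",
    "call_new_mutations",
    "mutation_frequency",
    "estimate_age",
    "age_uncertainty",
    "conserved_positions",
    "calls_to_frame",
    "load_island_fixture",
    "DEFAULT_CONTROL_REGION",
    "KERGUELEN_CALIBRATION",
]

# Two-base IUPAC ambiguity codes, read as Sanger double peaks.
AMBIGUITY_PAIRS = {
    "R": ("A", "G"),
    "Y": ("C", "T"),
    "S": ("C", "G"),
    "W": ("A", "T"),
    "K": ("G", "T"),
    "M": ("A", "C"),
}
IUPAC_FOR_PAIR = {frozenset(v): k for k, v in AMBIGUITY_PAIRS.items()}
BASES = "ACGT"
GAP = "-"

# mm9 chrM: control region 15,423-16,299 (1-based), i.e. 877 bp of a
# 16,299 bp genome, leaving 15,422 counted bp. The exclusion itself is
# part of the method; the coordinates are an explicit, overridable config.
DEFAULT_CONTROL_REGION = (15422, 16299)
MM9_CHRM_LENGTH = 16299


class ConsensusError(ValueError):
    """A consensus column could not be resolved (tie or no unambiguous call)."""

    def __init__(self, column: int, message: str):
        self.column = column
        super().__init__(f"column {column + 1}: {message}")


@dataclass
class MitoAlignment:
    """Equal-length aligned mitogenomes with a control-region mask.

    ``sequences`` maps genome id to an uppercase nucleotide string; IUPAC
    two-base codes mark heteroplasmic double peaks. ``control_region`` is
    a half-open 0-based interval excluded from the dating clock.
    """

    sequences: dict
    control_region: tuple | None = None

    def __post_init__(self):
        lengths = {len(s) for s in self.sequences.values()}
        if len(lengths) > 1:
            raise ValueError(f"sequences have unequal lengths: {sorted(lengths)}")
        self.sequences = {k: v.upper() for k, v in self.sequences.items()}
        L = self.length
        if self.control_region is None:
            self.control_region = (L, L)
        start, end = self.control_region
        if not (0 <= start <= end <= L):
            raise ValueError("control_region outside alignment bounds")

    @property
    def length(self) -> int:
        return len(next(iter(self.sequences.values()))) if self.sequences else 0

    @property
    def n_genomes(self) -> int:
        return len(self.sequences)

    @property
    def counted_length(self) -> int:
        start, end = self.control_region
        return self.length - (end - start)

    @property
    def ids(self) -> list:
        return list(self.sequences)

    @cached_property
    def array(self) -> np.ndarray:
        """(n_genomes, length) uint8 view of the alignment (ASCII codes)."""
        return np.vstack(
            [
                np.frombuffer(s.encode(), dtype=np.uint8)
                for s in self.sequences.values()
            ]
        )

    def exclude(self, ids) -> "MitoAlignment":
        """Drop genomes by id (e.g. a known recent immigrant) before analysis."""
        ids = set(ids)
        missing = ids - set(self.sequences)
        if missing:
            raise KeyError(f"ids not in alignment: {sorted(missing)}")
        return MitoAlignment(
            sequences={k: v for k, v in self.sequences.items() if k not in ids},
            control_region=self.control_region,
        )


@dataclass
class MutationCall:
    """One derived variant position relative to the cohort consensus."""

    position: int  # 1-based
    consensus_base: str
    derived_base: str
    carriers: list  # genome ids fixed for the derived base
    heteroplasmic_carriers: list  # genome ids with a double peak
    annotation: str = ""
    counted: bool = True  # enters the frequency numerator


@dataclass
class CalibrationPoint:
    """A reference island: measured mutation frequency and known age."""

    frequency: float
    age: float

    def __post_init__(self):
        if self.frequency <= 0:
            raise ValueError("calibration frequency must be positive")
        if self.age <= 0:
            raise ValueError("calibration age must be positive")


# Kerguelen archipelago mice: 3.0e-5 per nucleotide, colonized ~200 years
# ago on historical records.
KERGUELEN_CALIBRATION = CalibrationPoint(frequency=3.0e-5, age=200.0)


@dataclass
class ConservationMatrix:
    """Bases carried by comparator species at the called positions."""

    positions: list
    species_bases: dict  # species -> {position: base}
    consensus_bases: dict  # position -> base

    def __post_init__(self):
        for species, bases in self.species_bases.items():
            missing = set(self.positions) - set(bases)
            if missing:
                raise ValueError(
                    f"species {species!r} lacks positions {sorted(missing)}"
                )

    def is_conserved(self, position: int) -> bool:
        if position not in self.consensus_bases:
            raise KeyError(f"position {position} not in conservation matrix")
        cons = self.consensus_bases[position]
        return all(
            bases[position] == cons for bases in self.species_bases.values()
        )


# ------------------------------------------------------------- consensus

def _weight_table() -> np.ndarray:
    W = np.zeros((256, 4))
    for i, b in enumerate(BASES):
        W[ord(b), i] = 1.0
    for code, (b1, b2) in AMBIGUITY_PAIRS.items():
        W[ord(code), BASES.index(b1)] = 0.5
        W[ord(code), BASES.index(b2)] = 0.5
    return W


_WEIGHTS = _weight_table()
_IS_BASE = np.zeros(256, dtype=bool)
for _b in BASES:
    _IS_BASE[ord(_b)] = True


def consensus(alignment: MitoAlignment) -> str:
    """Per-column strict-majority consensus of the cohort.

    Unambiguous bases count 1; two-base ambiguity codes (double peaks)
    contribute half weight to each constituent base. A column with no
    unambiguous call, or with a tied majority, is an error — ties are
    not broken silently.
    """
    if alignment.n_genomes < 2:
        raise ValueError("consensus requires at least 2 sequences")
    arr = alignment.array
    col_weights = _WEIGHTS[arr].sum(axis=0)  # (L, 4)
    has_base = _IS_BASE[arr].any(axis=0)
    if not has_base.all():
        col = int(np.nonzero(~has_base)[0][0])
        raise ConsensusError(col, "no unambiguous base calls")
    order = np.sort(col_weights, axis=1)
    ties = order[:, -1] == order[:, -2]
    if ties.any():
        col = int(np.nonzero(ties)[0][0])
        raise ConsensusError(col, "tied majority between bases")
    best = col_weights.argmax(axis=1)
    return "".join(BASES[i] for i in best)


# -------------------------------------------------------- mutation calls

def call_new_mutations(
    alignment: MitoAlignment,
    consensus_seq: str,
    annotations: dict | None = None,
) -> list:
    """Call every column where a genome departs from the consensus.

    Rules:

    * indel columns (any gap character) are excluded from point-mutation
      calls;
    * columns inside the control region are reported but flagged
      ``counted=False``;
    * a two-base ambiguity code containing the consensus base is a
      heteroplasmic carrier of the other base; a call whose only
      evidence is heteroplasmic (no genome fixed for the derived base)
      is flagged ``counted=False`` — the double-peak variant is treated
      as inherited when it is also fixed in another animal, and a
      position enters the count once regardless of heteroplasmic
      co-carriers.

    ``annotations`` optionally maps 1-based position to a region label.
    """
    if len(consensus_seq) != alignment.length:
        raise ValueError("consensus length does not match alignment")
    annotations = annotations or {}
    arr = alignment.array
    cons_arr = np.frombuffer(consensus_seq.upper().encode(), dtype=np.uint8)
    ids = alignment.ids
    cr_start, cr_end = alignment.control_region
    diff_cols = np.nonzero((arr != cons_arr[None, :]).any(axis=0))[0]

    calls: list[MutationCall] = []
    for col in diff_cols:
        column = arr[:, col]
        if (column == ord(GAP)).any():
            continue  # indel column: not a point mutation
        cons_base = consensus_seq[col]
        carriers: dict[str, list] = {}
        het: dict[str, list] = {}
        for gid, code in zip(ids, column):
            c = chr(code)
            if c == cons_base:
                continue
            if c in BASES:
                carriers.setdefault(c, []).append(gid)
            elif c in AMBIGUITY_PAIRS:
                pair = AMBIGUITY_PAIRS[c]
                for b in pair:
                    if b != cons_base:
                        het.setdefault(b, []).append(gid)
            # N and rarer codes carry no call
        pos1 = int(col) + 1
        in_cr = cr_start <= col < cr_end
        for derived in sorted(set(carriers) | set(het)):
            fixed = carriers.get(derived, [])
            calls.append(
                MutationCall(
                    position=pos1,
                    consensus_base=cons_base,
                    derived_base=derived,
                    carriers=fixed,
                    heteroplasmic_carriers=het.get(derived, []),
                    annotation=annotations.get(
                        pos1, "control_region" if in_cr else ""
                    ),
                    counted=bool(fixed) and not in_cr,
                )
            )
    return calls


def counted_positions(calls) -> list:
    """Distinct 1-based positions entering the frequency numerator."""
    return sorted({c.position for c in calls if c.counted})


def mutation_frequency(calls, n_genomes: int, counted_length: int) -> float:
    """Counted mutation positions per nucleotide sequenced.

    ``counted_length`` is the alignment length minus the control region;
    the denominator is ``n_genomes x counted_length`` (total nucleotides
    sequenced outside the D-loop).
    """
    if n_genomes < 1:
        raise ValueError("n_genomes must be >= 1")
    if counted_length <= 0:
        raise ValueError("counted_length must be positive")
    return len(counted_positions(calls)) / (n_genomes * counted_length)


# ------------------------------------------------------------ age estimate

@dataclass
class AgeEstimate:
    years: float  # rounded point estimate
    unrounded_years: float
    frequency_ratio: float
    rounding: str = "ratio"


def estimate_age(
    focal_frequency: float,
    calibration: CalibrationPoint,
    rounding: str = "ratio",
) -> AgeEstimate:
    """Calibrated colonization age from the focal mutation frequency.

    The unrounded age is ``calibration.age * focal / calibration.frequency``.
    ``rounding`` controls the point estimate:

    * ``"ratio"`` (default) — round the frequency ratio to the nearest
      integer before multiplying ("about two times as old");
    * ``"sigfig"`` — round the year value to 1 significant figure;
    * ``"none"`` — the unrounded value.
    """
    if focal_frequency < 0:
        raise ValueError("focal frequency must be non-negative")
    ratio = focal_frequency / calibration.frequency
    unrounded = calibration.age * ratio
    if rounding == "ratio":
        years = float(round(ratio)) * calibration.age
    elif rounding == "sigfig":
        years = _round_sigfig(unrounded, 1)
    elif rounding == "none":
        years = unrounded
    else:
        raise ValueError(f"unknown rounding mode {rounding!r}")
    return AgeEstimate(
        years=years,
        unrounded_years=unrounded,
        frequency_ratio=ratio,
        rounding=rounding,
    )


def _round_sigfig(x: float, ndigits: int) -> float:
    if x == 0:
        return 0.0
    from math import floor, log10

    return round(x, -int(floor(log10(abs(x)))) + (ndigits - 1))


def age_uncertainty(
    n_counted: int,
    n_genomes: int,
    counted_length: int,
    calibration: CalibrationPoint,
    n_boot: int = 10_000,
    seed=None,
    level: float = 0.95,
) -> tuple[float, float]:
    """Percentile interval for the age under Poisson resampling.

    The mutation count is resampled as Poisson(``n_counted``), each
    resample is mapped through the frequency and the (unrounded) age,
    and the central ``level`` percentile interval is returned. The
    interval is widened, if needed, to contain the point estimate.
    """
    if n_boot < 100:
        raise ValueError("n_boot must be >= 100")
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    counts = rng.poisson(n_counted, size=n_boot)
    freqs = counts / (n_genomes * counted_length)
    ages = calibration.age * freqs / calibration.frequency
    alpha = (1 - level) / 2
    lo, hi = np.quantile(ages, [alpha, 1 - alpha])
    point = estimate_age(
        n_counted / (n_genomes * counted_length), calibration
    ).years
    return (float(min(lo, point)), float(max(hi, point)))


# ------------------------------------------------------------ conservation

def conserved_positions(calls, matrix: ConservationMatrix) -> list:
    """Calls at positions where every comparator species matches consensus.

    With an empty species set every call is (vacuously) conserved. A call
    position absent from the matrix is an error naming the position.
    """
    out = []
    for call in calls:
        if call.position not in matrix.consensus_bases:
            raise KeyError(
                f"position {call.position} missing from conservation matrix"
            )
        if matrix.is_conserved(call.position):
            out.append(call)
    return out


def calls_to_frame(calls) -> pd.DataFrame:
    """Tabular view of mutation calls (TSV-ready)."""
    return pd.DataFrame(
        {
            "position": [c.position for c in calls],
            "consensus": [c.consensus_base for c in calls],
            "derived": [c.derived_base for c in calls],
            "carriers": [",".join(c.carriers) for c in calls],
            "heteroplasmic": [",".join(c.heteroplasmic_carriers) for c in calls],
            "counted": [c.counted for c in calls],
            "annotation": [c.annotation for c in calls],
        }
    )


# ---------------------------------------------------------------- fixture

COHORT_IDS = [
    "HG_01", "HG_02", "HG_03", "HG_05", "HG_06", "HG_08",
    "HG_10", "HG_11", "HG_12", "HG_13", "HG_14",
]
IMMIGRANT_ID = "HG_1450_2"
# Private derived positions (1-based) carried only by the recent immigrant;
# excluded from the cohort statistic by id before analysis.
_IMMIGRANT_PRIVATE_POSITIONS = (2001, 3001)


def load_mutation_table() -> pd.DataFrame:
    """The packaged island mutation table (10 positions, TSV)."""
    ref = importlib.resources.files("insula").joinpath(
        "data/heligoland_mtdna_mutations.tsv"
    )
    with importlib.resources.as_file(ref) as path:
        return pd.read_csv(path, sep="\t", comment="#")


def load_island_fixture(include_immigrant: bool = False):
    """Reconstruct the island cohort alignment from the packaged table.

    Returns ``(MitoAlignment, ConservationMatrix, annotations)``. The
    alignment holds the 11-genome cohort (plus the known recent
    immigrant when ``include_immigrant=True``): a deterministic synthetic
    mm9-length background carrying the tabulated consensus bases, with
    each animal's fixed and heteroplasmic derived calls applied. The
    background outside the tabulated positions is synthetic — only the
    tabulated columns carry information, which is exactly what the
    dating statistic consumes.
    """
    table = load_mutation_table()
    rng = np.random.default_rng(101)  # fixed: part of the fixture definition
    background = rng.choice(list(BASES), size=MM9_CHRM_LENGTH)
    cons = background.copy()
    for _, row in table.iterrows():
        cons[row.position - 1] = row.consensus

    sequences: dict[str, np.ndarray] = {
        gid: cons.copy() for gid in COHORT_IDS
    }
    for _, row in table.iterrows():
        idx = row.position - 1
        for gid in str(row.fixed_carriers).split(","):
            if gid and gid != ".":
                sequences[gid][idx] = row.derived
        for gid in str(row.het_carriers).split(","):
            if gid and gid != ".":
                sequences[gid][idx] = IUPAC_FOR_PAIR[
                    frozenset((row.consensus, row.derived))
                ]
    if include_immigrant:
        imm = cons.copy()
        for pos in _IMMIGRANT_PRIVATE_POSITIONS:
            ref_base = imm[pos - 1]
            imm[pos - 1] = BASES[(BASES.index(ref_base) + 1) % 4]
        sequences[IMMIGRANT_ID] = imm

    alignment = MitoAlignment(
        sequences={k: "".join(v) for k, v in sequences.items()},
        control_region=DEFAULT_CONTROL_REGION,
    )
    species_cols = ["Rat", "Human", "Orangutan", "Dog", "Horse", "Opossum"]
    matrix = ConservationMatrix(
        positions=list(table.position),
        species_bases={
            sp: dict(zip(table.position, table[sp])) for sp in species_cols
        },
        consensus_bases=dict(zip(table.position, table.consensus)),
    )
    annotations = dict(zip(table.position, table.region))
    return alignment, matrix, annotations
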