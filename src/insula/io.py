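"""Readers and writers for the formats the toolkit consumes and emits.

FASTA goes through Biopython; GML through networkx; BED/bedGraph, DOT,
TPS, GenePop and the tab-separated tables are small line-oriented formats
written directly. All genomic interval files follow the BED convention
(0-based, half-open); tabular reports use 1-based positions.
"""

from __future__ import annotations

import datetime
import json
import warnings
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "read_fasta",
    "write_fasta",
    "read_bed",
    "write_bed",
    "read_bedgraph",
    "write_bedgraph",
    "read_gml",
    "write_gml",
    "write_dot",
    "read_tps",
    "write_tps",
    "read_landmarks_tsv",
    "write_landmarks_tsv",
    "read_genepop",
    "read_ancestry_tsv",
    "write_ancestry_tsv",
    "read_chrom_sizes",
    "write_provenance",
]


# ---------------------------------------------------------------- FASTA

def read_fasta(path, uppercase: bool = True) -> dict[str, str]:
    """Read an (aligned) multi-FASTA into an ordered ``{id: sequence}`` map.

    Gaps and IUPAC ambiguity codes are preserved. Lowercase input is
    normalized to uppercase unless ``uppercase=False``.
    """
    records: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in records:
            raise ValueError(f"duplicate sequence identifier: {rec.id!r}")
        seq = str(rec.seq)
        records[rec.id] = seq.upper() if uppercase else seq
    if not records:
        raise ValueError(f"no FASTA records found in {path}")
    return records


def write_fasta(sequences: Mapping[str, str], path, width: int = 70) -> None:
    recs = [
        SeqRecord(Seq(seq), id=name, description="")
        for name, seq in sequences.items()
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(recs)


# ------------------------------------------------------ BED / bedGraph

def _check_and_sort_intervals(rows: list[tuple]) -> list[tuple]:
    for row in rows:
        chrom, start, end = row[0], int(row[1]), int(row[2])
        if end <= start:
            raise ValueError(
                f"interval end must exceed start: {chrom}:{start}-{end}"
            )
    ordered = sorted(rows, key=lambda r: (str(r[0]), int(r[1]), int(r[2])))
    if ordered != rows:
        warnings.warn("intervals were unsorted; sorted on write")
    return ordered


def write_bed(intervals: Iterable[Sequence], path, header: str | None = None) -> None:
    """Write 0-based half-open intervals as BED3(+name).

    Each interval is ``(chrom, start, end)`` or ``(chrom, start, end, name)``.
    Unsorted input is sorted with a warning; empty input yields a file with
    only the (optional) header.
    """
    rows = _check_and_sort_intervals([tuple(r) for r in intervals])
    with open(path, "w") as fh:
        if header:
            fh.write(f"#{header}\n")
        for row in rows:
            fh.write("\t".join(str(x) for x in row) + "\n")


def read_bed(path) -> list[tuple]:
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            row = [parts[0], int(parts[1]), int(parts[2])] + parts[3:]
            out.append(tuple(row))
    return out


def write_bedgraph(rows: Iterable[Sequence], path, header: str | None = None) -> None:
    """Write 4-column bedGraph rows ``(chrom, start, end, value)``."""
    rows = _check_and_sort_intervals([tuple(r) for r in rows])
    with open(path, "w") as fh:
        if header:
            fh.write(f"#{header}\n")
        for chrom, start, end, value in rows:
            fh.write(f"{chrom}\t{start}\t{end}\t{value:g}\n")


def read_bedgraph(path) -> list[tuple]:
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            chrom, start, end, value = line.split("\t")
            out.append((chrom, int(start), int(end), float(value)))
    return out


# ------------------------------------------------------------ GML / DOT

def write_gml(graph: nx.Graph, path) -> None:
    nx.write_gml(graph, str(path))


def read_gml(path) -> nx.Graph:
    return nx.read_gml(str(path))


def write_dot(graph: nx.Graph, path) -> None:
    """Minimal DOT export (node/edge attributes as plain key=value)."""

    def fmt_attrs(d: Mapping) -> str:
        if not d:
            return ""
        inner = ", ".join(f'{k}="{v}"' for k, v in d.items())
        return f" [{inner}]"

    with open(path, "w") as fh:
        fh.write("graph haplonet {\n")
        for node, data in graph.nodes(data=True):
            fh.write(f'  "{node}"{fmt_attrs(data)};\n')
        for u, v, data in graph.edges(data=True):
            fh.write(f'  "{u}" -- "{v}"{fmt_attrs(data)};\n')
        fh.write("}\n")


# ------------------------------------------------------------------ TPS

def read_tps(path) -> tuple[np.ndarray, list[str]]:
    """Read a TPS landmark file into ``(coords (n, k, 2), ids)``.

    Only LM, the coordinate lines and ID records are interpreted; SCALE
    and IMAGE lines are ignored.
    """
    specimens: list[np.ndarray] = []
    ids: list[str] = []
    current: list[list[float]] | None = None
    expected = 0
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            upper = line.upper()
            if upper.startswith("LM="):
                if current is not None:
                    specimens.append(np.asarray(current, dtype=float))
                    if len(ids) < len(specimens):
                        ids.append(f"specimen_{len(specimens)}")
                expected = int(line.split("=", 1)[1])
                current = []
            elif upper.startswith("ID="):
                ids.append(line.split("=", 1)[1])
            elif upper.startswith(("IMAGE=", "SCALE=")):
                continue
            else:
                if current is None:
                    raise ValueError("coordinate line before LM= record")
                x, y = line.split()[:2]
                current.append([float(x), float(y)])
    if current is not None:
        specimens.append(np.asarray(current, dtype=float))
        if len(ids) < len(specimens):
            ids.append(f"specimen_{len(specimens)}")
    if not specimens:
        raise ValueError(f"no TPS records found in {path}")
    shapes = {s.shape for s in specimens}
    if len(shapes) != 1:
        raise ValueError("TPS specimens have differing landmark counts")
    if expected and specimens[-1].shape[0] != expected:
        raise ValueError("LM= count does not match coordinate lines")
    return np.stack(specimens), ids


def write_tps(coords: np.ndarray, ids: Sequence[str], path) -> None:
    coords = np.asarray(coords, dtype=float)
    with open(path, "w") as fh:
        for config, name in zip(coords, ids):
            fh.write(f"LM={config.shape[0]}\n")
            for x, y in config:
                fh.write(f"{x:.10g} {y:.10g}\n")
            fh.write(f"ID={name}\n")


def read_landmarks_tsv(path) -> pd.DataFrame:
    """Long-format landmark table: specimen_id, group, landmark_index, x, y."""
    df = pd.read_csv(path, sep="\t", comment="#")
    required = {"specimen_id", "group", "landmark_index", "x", "y"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"landmark TSV missing columns: {sorted(missing)}")
    return df


def write_landmarks_tsv(coords, ids, groups, path) -> None:
    rows = []
    for config, sid, grp in zip(np.asarray(coords, dtype=float), ids, groups):
        for i, (x, y) in enumerate(config, start=1):
            rows.append((sid, grp, i, x, y))
    pd.DataFrame(
        rows, columns=["specimen_id", "group", "landmark_index", "x", "y"]
    ).to_csv(path, sep="\t", index=False)


# -------------------------------------------------------------- GenePop

def read_genepop(path) -> pd.DataFrame:
    """Parse a GenePop file into a long genotype table.

    Returns a DataFrame with columns (population, individual, locus,
    allele1, allele2); 2- or 3-digit allele coding is auto-detected and
    the all-zero code is treated as missing. Populations are named
    ``pop_1 ...`` in file order.
    """
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh]
    if not lines:
        raise ValueError(f"empty GenePop file: {path}")
    lines = lines[1:]  # title line
    loci: list[str] = []
    i = 0
    while i < len(lines) and lines[i].strip().lower() != "pop":
        chunk = lines[i].strip()
        if chunk:
            loci.extend(x.strip() for x in chunk.split(",") if x.strip())
        i += 1
    if not loci:
        raise ValueError("no locus names before first 'pop' line")
    rows = []
    pop_idx = 0
    while i < len(lines):
        if lines[i].strip().lower() == "pop":
            pop_idx += 1
            i += 1
            continue
        line = lines[i].strip()
        i += 1
        if not line:
            continue
        if "," not in line:
            raise ValueError(f"malformed GenePop individual line: {line!r}")
        name, geno = line.split(",", 1)
        fields = geno.split()
        if len(fields) != len(loci):
            raise ValueError(
                f"individual {name.strip()!r} has {len(fields)} genotypes "
                f"for {len(loci)} loci"
            )
        for locus, field in zip(loci, fields):
            width = len(field) // 2
            a1, a2 = int(field[:width]), int(field[width:])
            rows.append(
                (
                    f"pop_{pop_idx}",
                    name.strip(),
                    locus,
                    a1 if a1 else np.nan,
                    a2 if a2 else np.nan,
                )
            )
    return pd.DataFrame(
        rows, columns=["population", "individual", "locus", "allele1", "allele2"]
    )


# ------------------------------------------------------- ancestry / misc

ANCESTRY_COLUMNS = ["individual", "haplotype", "chrom", "pos", "prob_sourceA"]


def read_ancestry_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#")
    missing = set(ANCESTRY_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"ancestry TSV missing columns: {sorted(missing)}")
    return df


def write_ancestry_tsv(track: pd.DataFrame, path) -> None:
    track.loc[:, ANCESTRY_COLUMNS].to_csv(path, sep="\t", index=False)


def read_chrom_sizes(path) -> dict[str, int]:
    sizes: dict[str, int] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            chrom, size = line.split()[:2]
            sizes[chrom] = int(size)
    if not sizes:
        raise ValueError(f"no chromosome sizes found in {path}")
    return sizes


def write_provenance(outdir, command: str, params: Mapping, seed=None) -> Path:
    """Drop a provenance JSON next to a command's outputs.

    Records the tool version, timestamp, command name, the full parameter
    echo and the seed, which together suffice to re-run the command.
    """
    from . import __version__

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    payload = {
        "tool": "insula",
        "version": __version__,
        "timestamp": datetime.datetime.now().isoformat(timespec="seconds"),
        "command": command,
        "seed": seed,
        "parameters": {k: _jsonable(v) for k, v in params.items()},
    }
    path = outdir / "provenance.json"
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2)
        fh.write("\n")
    return path


def _jsonable(v):
    if isinstance(v, Path):
        return str(v)
    if isinstance(v, (np.integer, np.floating)):
        return v.item()
    if isinstance(v, (list, tuple)):
        return [_jsonable(x) for x in v]
    return v
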