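"""Readers/writers for the plain-text formats the pipeline touches.

Supported dialects: ms-style replicate blocks (positions as fractions of
the region length), selscan-style .hap/.map pairs, the per-site allele
frequency table consumed by the SFS scan, spectrum files, rate-map TSVs,
and YAML scenario snippets.  All files are UTF-8 with Unix newlines;
TSVs are tab-separated.  Physical positions are 1-based except in ms
blocks, whose native convention is fractional.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Optional, Sequence, TextIO, Union

import numpy as np

from .genome_model import RateMap
from .wf_engine import HaplotypeSample

__all__ = [
    "write_ms",
    "read_ms",
    "write_hap_map",
    "read_hap_map",
    "sample_from_hap_map",
    "write_freq_table",
    "read_freq_table",
    "write_spectrum",
    "read_spectrum",
    "write_rate_map",
    "read_rate_map",
    "write_layout",
    "read_layout",
    "config_digest",
]

PathLike = Union[str, Path]
_MS_DECIMALS = 12


def write_ms(
    samples: Sequence[HaplotypeSample], region_length: int, path: PathLike
) -> None:
    """Write samples as ms-dialect replicate blocks.

    Positions are bp / region_length, printed to 12 decimals; the
    round-trip through :func:`read_ms` is lossless up to that
    quantisation.
    """
    path = Path(path)
    with path.open("w", newline="\n") as fh:
        fh.write(f"ms {samples[0].n if samples else 0} {len(samples)}\n\n")
        for s in samples:
            fh.write("//\n")
            fh.write(f"segsites: {s.n_sites}\n")
            if s.n_sites:
                fracs = " ".join(
                    f"{p / region_length:.{_MS_DECIMALS}f}" for p in s.positions
                )
                fh.write(f"positions: {fracs}\n")
                for row in s.matrix:
                    fh.write("".join("1" if v else "0" for v in row) + "\n")
            fh.write("\n")


def read_ms(path: PathLike) -> list[tuple[np.ndarray, np.ndarray]]:
    """Read ms-dialect blocks as (positions_fraction, matrix) pairs."""
    blocks: list[tuple[np.ndarray, np.ndarray]] = []
    lines = Path(path).read_text().splitlines()
    i = 0
    while i < len(lines):
        if lines[i].strip() != "//":
            i += 1
            continue
        i += 1
        if i >= len(lines) or not lines[i].startswith("segsites:"):
            raise ValueError(f"{path}: malformed block, expected segsites line")
        seg = int(lines[i].split(":")[1])
        i += 1
        if seg == 0:
            blocks.append((np.empty(0), np.empty((0, 0), dtype=np.uint8)))
            continue
        if not lines[i].startswith("positions:"):
            raise ValueError(f"{path}: malformed block, expected positions line")
        pos = np.asarray([float(x) for x in lines[i].split(":")[1].split()])
        if pos.size != seg:
            raise ValueError(f"{path}: positions line does not match segsites")
        i += 1
        rows = []
        while i < len(lines) and lines[i].strip() and lines[i].strip() != "//":
            row = lines[i].strip()
            if len(row) != seg or set(row) - {"0", "1"}:
                raise ValueError(f"{path}: malformed haplotype row")
            rows.append([int(c) for c in row])
            i += 1
        blocks.append((pos, np.asarray(rows, dtype=np.uint8)))
    return blocks


def write_hap_map(
    sample: HaplotypeSample,
    chrom: str,
    path_stem: PathLike,
    recombination_map: Optional[RateMap] = None,
    fixed_r: float = 1e-8,
) -> tuple[Path, Path]:
    """Write selscan-style .hap (one haplotype per row, space-separated
    0/1) and 4-column .map (chrom, locus id, genetic position in
    Morgans, physical position in bp) files.

    Genetic positions come from cumulative integration of the
    recombination map when given, otherwise bp * fixed_r.
    """
    stem = Path(path_stem)
    hap_path = stem.with_suffix(".hap")
    map_path = stem.with_suffix(".map")
    with hap_path.open("w", newline="\n") as fh:
        for row in sample.matrix:
            fh.write(" ".join(str(int(v)) for v in row) + "\n")
    if recombination_map is not None:
        edges = np.asarray(recombination_map.block_edges, dtype=float)
        cum = recombination_map.cumulative_mass()
        blk = np.searchsorted(edges, sample.positions, side="right") - 1
        gpos = cum[blk] + (sample.positions - edges[blk]) * np.asarray(
            recombination_map.block_rates
        )[blk]
    else:
        gpos = sample.positions * fixed_r
    with map_path.open("w", newline="\n") as fh:
        for i, (p, g) in enumerate(zip(sample.positions, gpos), start=1):
            fh.write(f"{chrom}\tlocus{i}\t{g:.12g}\t{int(p)}\n")
    return hap_path, map_path


def read_hap_map(path_stem: PathLike) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Read a .hap/.map pair -> (matrix, physical positions, genetic
    positions)."""
    stem = Path(path_stem)
    matrix = np.loadtxt(stem.with_suffix(".hap"), dtype=np.uint8, ndmin=2)
    phys, gen = [], []
    for line in stem.with_suffix(".map").read_text().splitlines():
        if not line.strip():
            continue
        fields = line.split("\t")
        if len(fields) != 4:
            raise ValueError(f"{stem}.map: expected 4 tab-separated columns")
        gen.append(float(fields[2]))
        phys.append(int(fields[3]))
    phys_arr = np.asarray(phys, dtype=np.int64)
    if (np.diff(phys_arr) <= 0).any():
        raise ValueError(f"{stem}.map: physical positions must strictly increase")
    if matrix.size and matrix.shape[1] != phys_arr.size:
        raise ValueError(f"{stem}: .hap width does not match .map length")
    return matrix, phys_arr, np.asarray(gen)


def sample_from_hap_map(
    path_stem: PathLike,
    total_length: int,
    tau_label: str = "",
    focal_position: Optional[int] = None,
) -> HaplotypeSample:
    """Build a HaplotypeSample from a .hap/.map pair (no substitution
    records; the focal column is located by ``focal_position`` when
    given)."""
    matrix, phys, _ = read_hap_map(path_stem)
    bcol = None
    if focal_position is not None:
        hit = np.flatnonzero(phys == focal_position)
        bcol = int(hit[0]) if hit.size else None
    return HaplotypeSample(
        tau_label=tau_label,
        matrix=matrix,
        positions=phys,
        substitution_positions=np.empty(0, dtype=np.int64),
        balanced_col=bcol,
        total_length=int(total_length),
        generation=0,
        focal_position=focal_position,
    )


def write_freq_table(sample: HaplotypeSample, path: PathLike) -> None:
    """Per-site allele-frequency TSV: position, derived count k, sample
    size n, substitution flag; substitutions carry k = n."""
    k = sample.derived_counts()
    rows = [(int(p), int(c), sample.n, 0) for p, c in zip(sample.positions, k)]
    rows += [(int(p), sample.n, sample.n, 1) for p in sample.substitution_positions]
    rows.sort()
    seen = set()
    with Path(path).open("w", newline="\n") as fh:
        fh.write("position\tderived_count\tsample_size\tsubstitution\n")
        for p, c, n, flag in rows:
            if p in seen:
                raise ValueError(f"duplicate position {p}")
            seen.add(p)
            fh.write(f"{p}\t{c}\t{n}\t{flag}\n")


def read_freq_table(path: PathLike) -> tuple[np.ndarray, np.ndarray, int, np.ndarray]:
    """Read the frequency table -> (positions, derived counts, n,
    substitution flags)."""
    lines = Path(path).read_text().splitlines()
    if not lines or lines[0].split("\t")[0] != "position":
        raise ValueError(f"{path}: missing header")
    pos, k, flags = [], [], []
    n = None
    for line in lines[1:]:
        if not line.strip():
            continue
        p, c, nn, f = line.split("\t")
        pos.append(int(p))
        k.append(int(c))
        flags.append(int(f))
        if n is None:
            n = int(nn)
        elif n != int(nn):
            raise ValueError(f"{path}: mixed sample sizes")
    return (
        np.asarray(pos, dtype=np.int64),
        np.asarray(k, dtype=np.int64),
        int(n or 0),
        np.asarray(flags, dtype=np.int64),
    )


def write_spectrum(g: np.ndarray, path: PathLike) -> None:
    """Spectrum TSV: derived count k (1..n), probability."""
    with Path(path).open("w", newline="\n") as fh:
        fh.write("k\tprobability\n")
        for i, p in enumerate(np.asarray(g, dtype=float), start=1):
            fh.write(f"{i}\t{p:.12g}\n")


def read_spectrum(path: PathLike) -> np.ndarray:
    lines = Path(path).read_text().splitlines()
    vals = [float(line.split("\t")[1]) for line in lines[1:] if line.strip()]
    return np.asarray(vals)


def write_layout(layout, path: PathLike) -> None:
    """Chromosome-layout TSV: kind, start, end (1-based inclusive), with
    the balanced-site position recorded on a comment header line."""
    with Path(path).open("w", newline="\n") as fh:
        fh.write(f"# balanced_site_position={layout.balanced_site_position}\n")
        fh.write(f"# synonymous_rule={int(layout.synonymous_rule)}\n")
        fh.write("kind\tstart\tend\n")
        for kind, start, end in layout.elements:
            fh.write(f"{kind}\t{start}\t{end}\n")


def read_layout(path: PathLike):
    from .genome_model import ChromosomeLayout

    balanced = None
    synonymous = True
    elements = []
    for line in Path(path).read_text().splitlines():
        if line.startswith("# balanced_site_position="):
            balanced = int(line.split("=")[1])
        elif line.startswith("# synonymous_rule="):
            synonymous = bool(int(line.split("=")[1]))
        elif line and not line.startswith(("#", "kind")):
            kind, start, end = line.split("\t")
            elements.append((kind, int(start), int(end)))
    if balanced is None or not elements:
        raise ValueError(f"{path}: malformed layout file")
    return ChromosomeLayout(
        total_length=elements[-1][2],
        elements=tuple(elements),
        balanced_site_position=balanced,
        synonymous_rule=synonymous,
    )


def write_rate_map(rate_map: RateMap, path: PathLike) -> None:
    """Rate-map TSV: kind, start, end, rate (1-based inclusive blocks)."""
    with Path(path).open("w", newline="\n") as fh:
        fh.write("kind\tstart\tend\trate\n")
        for i, rate in enumerate(rate_map.block_rates):
            start = rate_map.block_edges[i]
            end = rate_map.block_edges[i + 1] - 1
            fh.write(f"{rate_map.kind}\t{start}\t{end}\t{rate:.12g}\n")


def read_rate_map(path: PathLike) -> RateMap:
    lines = Path(path).read_text().splitlines()
    kind = None
    edges: list[int] = []
    rates: list[float] = []
    for line in lines[1:]:
        if not line.strip():
            continue
        k, start, end, rate = line.split("\t")
        if kind is None:
            kind = k
            edges.append(int(start))
        rates.append(float(rate))
        edges.append(int(end) + 1)
    return RateMap(kind=kind or "mutation", block_edges=tuple(edges), block_rates=tuple(rates))


def config_digest(obj) -> str:
    """Stable sha256 digest of a JSON-serialisable config description."""
    payload = json.dumps(obj, sort_keys=True, default=str).encode()
    return hashlib.sha256(payload).hexdigest()[:16]
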