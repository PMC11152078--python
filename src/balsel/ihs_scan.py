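"""Extended haplotype homozygosity (EHH) and the integrated haplotype
score (iHS), evaluated at every SNP.

EHH at a target SNP is the probability that two randomly chosen
chromosomes carrying the core allele are identical at every site between
the core and the target.  iHH integrates the EHH curve (trapezoid over
physical position, stopping when EHH drops below a cutoff or the region
edge is reached); the unstandardised score is ln(iHH_ancestral /
iHH_derived), standardised within derived-allele-frequency bins so that
under neutrality scores are approximately standard normal.  The
detection score used for ROC construction is |standardised iHS|.

Truncated curves are retained (integration stops at the region edge) and
no low-frequency sites are excluded: any SNP with at least two carriers
of each allele is scored.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np

from .wf_engine import HaplotypeSample

__all__ = [
    "EhhCurve",
    "IhsScore",
    "ScanResult",
    "ehh",
    "integrated_ehh",
    "unstandardized_ihs",
    "standardize_ihs",
    "fit_standardization",
    "IhsStandardization",
    "ihs_scan",
    "ihs_scan_set",
]

EHH_CUTOFF = 0.05
BIN_WIDTH = 0.02
MIN_BIN_COUNT = 20


@dataclass
class EhhCurve:
    """EHH values at successive SNPs left and right of a core site.

    ``points`` is ordered by position and always includes (core position,
    1.0).  ``left_truncated`` / ``right_truncated`` flag sides that
    reached the region edge while still above the cutoff.
    """

    core_position: int
    core_allele: int
    points: list[tuple[int, float]]
    left_truncated: bool
    right_truncated: bool


@dataclass
class IhsScore:
    position: int
    derived_freq: float
    ihh_ancestral: float
    ihh_derived: float
    unstandardized: float
    standardized: float = float("nan")
    bin_id: int = -1


@dataclass
class ScanResult:
    """Per-SNP detection scores for one replicate sample."""

    method: str
    positions: np.ndarray
    scores: np.ndarray  # detection score (|standardised iHS| or CLR)
    extras: dict = field(default_factory=dict)

    @property
    def n_snps(self) -> int:
        return len(self.positions)


def _ehh_side(
    matrix: np.ndarray,
    positions: np.ndarray,
    carriers: np.ndarray,
    core_idx: int,
    direction: int,
    cutoff: float,
) -> tuple[list[tuple[int, float]], bool]:
    """Walk outward from the core refining the carrier partition.

    Returns curve points (excluding the core point) and a truncation flag
    (region edge reached with EHH still >= cutoff).
    """
    n_c = carriers.size
    denom = n_c * (n_c - 1) / 2.0
    group = np.zeros(n_c, dtype=np.int64)
    val = 1.0
    points: list[tuple[int, float]] = []
    j = core_idx + direction
    n_sites = positions.size
    sub = matrix[carriers]
    while 0 <= j < n_sites:
        col = sub[:, j]
        if col.min() != col.max():
            # refine: combine current group id with this column's allele
            _, group, counts = np.unique(
                group * 2 + col, return_inverse=True, return_counts=True
            )
            val = float((counts * (counts - 1) / 2.0).sum()) / denom
        points.append((int(positions[j]), val))
        if val < cutoff:
            return points, False
        j += direction
    return points, True  # ran off the region edge


def ehh(
    sample: HaplotypeSample,
    core_idx: int,
    allele: int,
    cutoff: float = EHH_CUTOFF,
) -> Optional[EhhCurve]:
    """EHH curve for one core allele at SNP index ``core_idx``; None when
    the allele has fewer than two carriers."""
    carriers = np.flatnonzero(sample.matrix[:, core_idx] == allele)
    if carriers.size < 2:
        return None
    left, left_trunc = _ehh_side(
        sample.matrix, sample.positions, carriers, core_idx, -1, cutoff
    )
    right, right_trunc = _ehh_side(
        sample.matrix, sample.positions, carriers, core_idx, +1, cutoff
    )
    core_point = (int(sample.positions[core_idx]), 1.0)
    points = list(reversed(left)) + [core_point] + right
    return EhhCurve(
        core_position=core_point[0],
        core_allele=allele,
        points=points,
        left_truncated=left_trunc,
        right_truncated=right_trunc,
    )


def integrated_ehh(curve: EhhCurve) -> float:
    """Trapezoidal integral of the EHH curve over physical position (bp),
    left plus right of the core."""
    pts = curve.points
    core = curve.core_position
    pos = np.asarray([p for p, _ in pts], dtype=float)
    val = np.asarray([v for _, v in pts], dtype=float)
    left = pos <= core
    right = pos >= core
    area = 0.0
    if left.sum() >= 2:
        area += np.trapezoid(val[left], pos[left])
    if right.sum() >= 2:
        area += np.trapezoid(val[right], pos[right])
    return float(area)


def unstandardized_ihs(ihh_a: float, ihh_d: float) -> float:
    """ln(iHH_ancestral / iHH_derived); NaN when either integral is 0."""
    if ihh_a <= 0 or ihh_d <= 0:
        return float("nan")
    return float(np.log(ihh_a / ihh_d))


def _merge_bins(bin_ids: np.ndarray, min_count: int) -> np.ndarray:
    """Merge occupied frequency bins with < min_count members into their
    nearest occupied neighbour (the adjacent occupied bin with fewer
    members; ties go left).  Returns relabelled bin ids."""
    ids = bin_ids.copy()
    while True:
        uniq, counts = np.unique(ids, return_counts=True)
        if uniq.size <= 1:
            break
        small = np.flatnonzero(counts < min_count)
        if small.size == 0:
            break
        i = small[np.argmin(counts[small])]
        left = i - 1 if i > 0 else None
        right = i + 1 if i < uniq.size - 1 else None
        if left is None:
            target = right
        elif right is None:
            target = left
        else:
            target = left if counts[left] <= counts[right] else right
        ids[ids == uniq[i]] = uniq[target]
    return ids


@dataclass
class IhsStandardization:
    """Frequency-binned standardisation reference: per merged bin, the
    mean and sample SD of the unstandardised score among the reference
    scores.  Fit on neutral (or scenario-pooled) data, then applied to
    any score set."""

    bin_width: float
    merge_map: dict  # raw bin index -> merged bin id
    stats: dict  # merged bin id -> (mean, sd)

    def assign_bin(self, freq: float) -> int:
        nb = int(round(1.0 / self.bin_width))
        rb = min(int(freq / self.bin_width), nb - 1)
        if rb in self.merge_map:
            return self.merge_map[rb]
        known = np.asarray(sorted(self.merge_map))
        nearest = int(known[np.argmin(np.abs(known - rb))])
        return self.merge_map[nearest]

    def apply(self, raw: float, freq: float) -> tuple[float, int]:
        b = self.assign_bin(freq)
        mu, sd = self.stats.get(b, (np.nan, np.nan))
        if not np.isfinite(sd) or sd <= 0:
            return float("nan"), b
        return (raw - mu) / sd, b


def fit_standardization(
    scores: Sequence[tuple[float, float]],
    bin_width: float = BIN_WIDTH,
    min_bin_count: int = MIN_BIN_COUNT,
) -> IhsStandardization:
    """Fit bin means/SDs on (unstandardised score, derived frequency)
    reference pairs; underfilled bins are merged with their nearest
    neighbour."""
    if len(scores) < 2:
        raise ValueError("need at least 2 scores to standardise")
    raw = np.asarray([s for s, _ in scores], dtype=float)
    freq = np.asarray([f for _, f in scores], dtype=float)
    bins = np.minimum((freq / bin_width).astype(np.int64), int(1 / bin_width) - 1)
    merged = _merge_bins(bins, min_bin_count)
    merge_map = {int(rb): int(mb) for rb, mb in zip(bins, merged)}
    stats = {}
    for b in np.unique(merged):
        idx = np.flatnonzero(merged == b)
        if idx.size < 2:
            continue
        stats[int(b)] = (float(raw[idx].mean()), float(raw[idx].std(ddof=1)))
    return IhsStandardization(bin_width=bin_width, merge_map=merge_map, stats=stats)


def standardize_ihs(
    scores: Sequence[tuple[float, float]],
    bin_width: float = BIN_WIDTH,
    min_bin_count: int = MIN_BIN_COUNT,
    reference: Optional[IhsStandardization] = None,
) -> list[IhsScore]:
    """Standardise (unstandardised score, derived frequency) pairs within
    derived-frequency bins: subtract the bin mean, divide by the bin
    sample SD (n-1 denominator).  With ``reference`` the bin statistics
    come from an external (e.g. neutral) score set."""
    ref = reference or fit_standardization(scores, bin_width, min_bin_count)
    out = []
    for raw, freq in scores:
        z, b = ref.apply(float(raw), float(freq))
        out.append(
            IhsScore(
                position=-1,
                derived_freq=float(freq),
                ihh_ancestral=float("nan"),
                ihh_derived=float("nan"),
                unstandardized=float(raw),
                standardized=z,
                bin_id=b,
            )
        )
    return out


def _unstandardized_scan(
    sample: HaplotypeSample, cutoff: float
) -> list[IhsScore]:
    scores = []
    m = sample.matrix
    n = sample.n
    k = m.sum(axis=0, dtype=np.int64)
    for j in range(sample.n_sites):
        if k[j] < 2 or n - k[j] < 2:
            continue  # needs >= 2 carriers of each allele
        curve_d = ehh(sample, j, 1, cutoff)
        curve_a = ehh(sample, j, 0, cutoff)
        if curve_d is None or curve_a is None:
            continue
        ihh_d = integrated_ehh(curve_d)
        ihh_a = integrated_ehh(curve_a)
        u = unstandardized_ihs(ihh_a, ihh_d)
        if not np.isfinite(u):
            continue
        scores.append(
            IhsScore(
                position=int(sample.positions[j]),
                derived_freq=float(k[j]) / n,
                ihh_ancestral=ihh_a,
                ihh_derived=ihh_d,
                unstandardized=u,
            )
        )
    return scores


def ihs_scan_set(
    samples: Sequence[HaplotypeSample],
    cutoff: float = EHH_CUTOFF,
    bin_width: float = BIN_WIDTH,
    min_bin_count: int = MIN_BIN_COUNT,
    reference_samples: Optional[Sequence[HaplotypeSample]] = None,
    reference: Optional[IhsStandardization] = None,
) -> list[ScanResult]:
    """Scan a set of replicate samples, pooling scores across replicates
    for frequency-bin standardisation (pooling keeps the bins stable at
    realistic replicate counts).  Detection score = |standardised iHS|.

    With ``reference_samples`` the bin statistics are fit on that set
    instead (e.g. matched neutral replicates, approximating the
    genome-wide expectation that standardisation presumes; without it, a
    scenario whose every replicate carries a sweep would standardise the
    signal away)."""
    per_rep = [_unstandardized_scan(s, cutoff) for s in samples]
    flat = [(sc.unstandardized, sc.derived_freq) for rep in per_rep for sc in rep]
    if reference is None and reference_samples is not None:
        ref_flat = [
            (sc.unstandardized, sc.derived_freq)
            for s in reference_samples
            for sc in _unstandardized_scan(s, cutoff)
        ]
        reference = fit_standardization(ref_flat, bin_width, min_bin_count)
    results = []
    if len(flat) >= 2 or (flat and reference is not None):
        standardized = standardize_ihs(
            flat, bin_width, min_bin_count, reference=reference
        )
    else:
        standardized = [None] * len(flat)
    i = 0
    for sample, rep in zip(samples, per_rep):
        positions, scores, extras_raw, extras_freq = [], [], [], []
        for sc in rep:
            std = standardized[i]
            i += 1
            if std is None or not np.isfinite(std.standardized):
                continue
            positions.append(sc.position)
            scores.append(abs(std.standardized))
            extras_raw.append(sc.unstandardized)
            extras_freq.append(sc.derived_freq)
        results.append(
            ScanResult(
                method="ihs",
                positions=np.asarray(positions, dtype=np.int64),
                scores=np.asarray(scores, dtype=float),
                extras={
                    "unstandardized": np.asarray(extras_raw),
                    "derived_freq": np.asarray(extras_freq),
                },
            )
        )
    return results


def ihs_scan(sample: HaplotypeSample, **kwargs) -> ScanResult:
    """Scan a single sample (standardisation across its own SNPs)."""
    return ihs_scan_set([sample], **kwargs)[0]
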