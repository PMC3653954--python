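"""Common genetic map for microsatellite anchors and SNPs, plus marker cleaning.

Linkage panels carry genetic positions (cM) for their microsatellites; GWAS
SNPs carry only physical positions (bp).  To place both marker types on one
map, a SNP between two microsatellite anchors receives a genetic position by
linear interpolation of the flanking anchors' genetic interval in proportion
to physical distance; beyond the first or last anchor on a chromosome the
1 cM ≈ 1 Mb convention extrapolates.

Before mapping, markers are cleaned: microsatellites without a physical
position are unusable as anchors; SNPs with minor allele frequency ≤ 5% are
poorly inferred and dropped; SNPs within 1,000 bp of a retained
microsatellite are dropped to avoid local LD with the anchor itself.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import pandas as pd

__all__ = [
    "MarkerAnchor",
    "MarkerRecord",
    "interpolate_genetic_position",
    "clean_markers",
    "build_common_map",
    "CM_PER_BP_FLANK",
]

# chromosome-end convention: 1 cM per megabase
CM_PER_BP_FLANK = 1.0e-6


@dataclass(frozen=True)
class MarkerAnchor:
    """A microsatellite with known genetic (cM) and physical (bp) position."""

    name: str
    chromosome: str
    gm: float
    pm: int

    def __post_init__(self) -> None:
        if self.pm < 0:
            raise ValueError(f"anchor {self.name!r}: physical position {self.pm} < 0")


@dataclass(frozen=True)
class MarkerRecord:
    """A marker awaiting cleaning/mapping; ``kind`` is 'microsatellite' or 'snp'."""

    name: str
    chromosome: str
    pm: Optional[int]
    kind: str
    maf: Optional[float] = None
    gm: Optional[float] = None

    def __post_init__(self) -> None:
        if self.kind not in ("microsatellite", "snp"):
            raise ValueError(f"marker {self.name!r}: unknown kind {self.kind!r}")
        if self.maf is not None and not 0.0 <= self.maf <= 0.5:
            raise ValueError(f"marker {self.name!r}: maf={self.maf!r} outside [0, 0.5]")


def _check_anchors(anchors: Sequence[MarkerAnchor]) -> None:
    if not anchors:
        raise ValueError("anchor list is empty")
    for left, right in zip(anchors, anchors[1:]):
        if right.pm <= left.pm:
            raise ValueError(
                f"anchors not strictly increasing in physical position: "
                f"{left.name} (pm={left.pm}) then {right.name} (pm={right.pm})"
            )
        if right.gm < left.gm:
            raise ValueError(
                f"anchors decreasing in genetic position: "
                f"{left.name} (gm={left.gm}) then {right.name} (gm={right.gm})"
            )


def interpolate_genetic_position(
    pm_snp: int, anchors: Sequence[MarkerAnchor]
) -> float:
    """Genetic position (cM) of a SNP at physical position ``pm_snp``.

    Between two anchors: linear interpolation of the anchors' genetic interval
    by relative physical distance.  Before the first / after the last anchor:
    1 cM per Mb from that anchor.  At an anchor's physical position the
    anchor's own genetic position is returned.
    """
    _check_anchors(anchors)
    first, last = anchors[0], anchors[-1]
    if pm_snp <= first.pm:
        return first.gm - (first.pm - pm_snp) * CM_PER_BP_FLANK
    if pm_snp >= last.pm:
        return last.gm + (pm_snp - last.pm) * CM_PER_BP_FLANK
    for left, right in zip(anchors, anchors[1:]):
        if left.pm <= pm_snp <= right.pm:
            frac = (pm_snp - left.pm) / (right.pm - left.pm)
            return left.gm + frac * (right.gm - left.gm)
    raise AssertionError("unreachable: pm_snp not bracketed")  # pragma: no cover


def clean_markers(
    markers: Iterable[MarkerRecord],
    maf_cutoff: float = 0.05,
    flank_bp: int = 1000,
) -> Tuple[List[MarkerRecord], Dict[str, int]]:
    """Apply the cleaning rules; returns (retained markers, exclusion report).

    Exclusion reasons, applied in order (a marker is counted under the first
    that fires):

    1. ``missing_position`` — microsatellite without a physical position;
    2. ``low_maf`` — SNP with MAF ≤ ``maf_cutoff`` (boundary inclusive);
    3. ``near_microsatellite`` — SNP within ``flank_bp`` (inclusive) of a
       retained microsatellite on the same chromosome.
    """
    markers = list(markers)
    report = {"missing_position": 0, "low_maf": 0, "near_microsatellite": 0}

    retained_ms: List[MarkerRecord] = []
    for m in markers:
        if m.kind == "microsatellite":
            if m.pm is None:
                report["missing_position"] += 1
            else:
                retained_ms.append(m)
    ms_by_chrom: Dict[str, List[int]] = {}
    for m in retained_ms:
        ms_by_chrom.setdefault(m.chromosome, []).append(m.pm)  # type: ignore[arg-type]

    retained: List[MarkerRecord] = list(retained_ms)
    for m in markers:
        if m.kind != "snp":
            continue
        if m.pm is None:
            report["missing_position"] += 1
            continue
        if m.maf is not None and m.maf <= maf_cutoff:
            report["low_maf"] += 1
            continue
        near = any(
            abs(m.pm - ms_pm) <= flank_bp for ms_pm in ms_by_chrom.get(m.chromosome, ())
        )
        if near:
            report["near_microsatellite"] += 1
            continue
        retained.append(m)
    return retained, report


def build_common_map(
    microsatellites: Iterable[MarkerRecord],
    snps: Iterable[MarkerRecord],
) -> pd.DataFrame:
    """Unified per-chromosome map of microsatellite anchors and SNPs.

    Inputs are assumed cleaned.  Every SNP gains a genetic position by
    interpolation against its chromosome's anchors; the output frame has
    columns (chromosome, name, kind, gm, pm) sorted by (chromosome, gm, pm).

    Raises ``ValueError`` if some chromosome has SNPs but no anchor.
    """
    anchors_by_chrom: Dict[str, List[MarkerAnchor]] = {}
    for m in microsatellites:
        if m.pm is None or m.gm is None:
            raise ValueError(f"microsatellite {m.name!r} lacks a position; clean first")
        anchors_by_chrom.setdefault(m.chromosome, []).append(
            MarkerAnchor(m.name, m.chromosome, m.gm, m.pm)
        )
    for chrom, anchor_list in anchors_by_chrom.items():
        anchor_list.sort(key=lambda a: a.pm)
        _check_anchors(anchor_list)

    snps = list(snps)
    orphan = sorted({s.chromosome for s in snps} - set(anchors_by_chrom))
    if orphan:
        raise ValueError(f"chromosomes with SNPs but no microsatellite anchor: {orphan}")

    rows = []
    for chrom, anchor_list in anchors_by_chrom.items():
        for a in anchor_list:
            rows.append((chrom, a.name, "microsatellite", a.gm, a.pm))
    for s in snps:
        gm = interpolate_genetic_position(s.pm, anchors_by_chrom[s.chromosome])  # type: ignore[arg-type]
        rows.append((s.chromosome, s.name, "snp", gm, s.pm))
    frame = pd.DataFrame(rows, columns=["chromosome", "name", "kind", "gm", "pm"])
    return frame.sort_values(["chromosome", "gm", "pm"], kind="mergesort").reset_index(
        drop=True
    )
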