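"""Fragment-analysis peak tables and reduction to allele pairs.

Input is the sized-peak table a capillary/gel genotyping package exports:
one row per detected peak with sample id, tissue (tumor or normal), marker,
fragment size in bp and peak height in relative fluorescence units. For each
sample x marker x tissue the peaks inside the marker's expected product-size
window are reduced to one or two allele peaks; a heterozygote shows two major
peaks, a homozygote one.
"""
from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .panel import MicrosatelliteMarker, Panel

__all__ = [
    "PeakRecord",
    "AllelePair",
    "PeakTableError",
    "read_peak_table",
    "write_peak_table",
    "extract_alleles",
    "PEAK_TABLE_COLUMNS",
    "TISSUES",
]

TISSUES = ("tumor", "normal")
PEAK_TABLE_COLUMNS = ("sample_id", "tissue", "marker", "size_bp", "height")

#: Minimum fraction of the major peak's height a second peak must reach to
#: call the constitutional genotype heterozygous.
DEFAULT_HET_MIN_FRACTION = 0.20
#: Minimum spacing between the two candidate allele peaks, bp. Guards against
#: counting a stutter shoulder as a second allele on dinucleotide repeats.
DEFAULT_MIN_ALLELE_SPACING_BP = 2.0


class PeakTableError(ValueError):
    """Invalid peak-table content (vocabulary, sign, or structure)."""


@dataclass(frozen=True)
class PeakRecord:
    sample_id: str
    tissue: str
    marker: str
    size_bp: float
    height: float

    def __post_init__(self) -> None:
        if self.tissue not in TISSUES:
            raise PeakTableError(
                f"tissue {self.tissue!r} not one of {TISSUES}"
            )
        if not self.size_bp > 0:
            raise PeakTableError(f"size_bp must be > 0, got {self.size_bp}")
        if not self.height > 0:
            raise PeakTableError(f"height must be > 0, got {self.height}")


@dataclass(frozen=True)
class AllelePair:
    """One or two quantified allele peaks for a sample x marker x tissue.

    ``allele1`` is always the shorter fragment. A homozygote carries a single
    allele: ``allele2_size_bp`` and ``h2`` are ``None``.
    """

    sample_id: str
    tissue: str
    marker: str
    allele1_size_bp: float
    h1: float
    allele2_size_bp: float | None = None
    h2: float | None = None

    def __post_init__(self) -> None:
        if (self.allele2_size_bp is None) != (self.h2 is None):
            raise ValueError("allele2_size_bp and h2 must both be set or both absent")
        if not self.h1 > 0:
            raise ValueError("h1 must be > 0")
        if self.allele2_size_bp is not None:
            if not self.h2 > 0:
                raise ValueError("h2 must be > 0")
            if not self.allele1_size_bp < self.allele2_size_bp:
                raise ValueError("allele1 must be the shorter fragment")

    @property
    def heterozygous(self) -> bool:
        return self.allele2_size_bp is not None

    @property
    def zygosity(self) -> str:
        return "heterozygous" if self.heterozygous else "homozygous"

    @property
    def sizes(self) -> tuple[float, ...]:
        if self.heterozygous:
            return (self.allele1_size_bp, self.allele2_size_bp)
        return (self.allele1_size_bp,)


def read_peak_table(
    path: str | Path,
    panel: Panel | None = None,
    *,
    ignore_unknown_markers: bool = False,
) -> list[PeakRecord]:
    """Parse a peak-table CSV into :class:`PeakRecord` rows.

    Row count is preserved (no filtering happens here). With ``panel`` given,
    marker names are validated against it; unknown markers raise unless
    ``ignore_unknown_markers`` is set, in which case their rows are dropped.
    """
    df = pd.read_csv(path, dtype={"sample_id": str})
    missing = [c for c in PEAK_TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise PeakTableError(f"{path}: missing column(s) {missing}")
    records: list[PeakRecord] = []
    for i, row in enumerate(df.itertuples(index=False), start=2):
        if panel is not None and row.marker not in panel:
            if ignore_unknown_markers:
                continue
            raise PeakTableError(
                f"{path}: row {i}: unknown marker {row.marker!r} "
                f"(panel: {panel.marker_names})"
            )
        try:
            records.append(
                PeakRecord(
                    sample_id=str(row.sample_id),
                    tissue=str(row.tissue),
                    marker=str(row.marker),
                    size_bp=float(row.size_bp),
                    height=float(row.height),
                )
            )
        except (PeakTableError, ValueError) as exc:
            raise PeakTableError(f"{path}: row {i}: {exc}") from None
    return records


def write_peak_table(records: Iterable[PeakRecord], path: str | Path) -> None:
    df = pd.DataFrame(
        [(r.sample_id, r.tissue, r.marker, r.size_bp, r.height) for r in records],
        columns=list(PEAK_TABLE_COLUMNS),
    )
    df.to_csv(path, index=False)


def extract_alleles(
    peaks: Sequence[PeakRecord],
    marker: MicrosatelliteMarker,
    het_min_fraction: float = DEFAULT_HET_MIN_FRACTION,
    min_allele_spacing_bp: float = DEFAULT_MIN_ALLELE_SPACING_BP,
) -> AllelePair | None:
    """Reduce the peaks of one sample x marker x tissue to an allele pair.

    Peaks outside the marker's [size_min_bp, size_max_bp] window are
    discarded. The tallest surviving peak is the major allele; the tallest
    peak at least ``min_allele_spacing_bp`` away is the candidate minor
    allele, accepted iff its height is >= ``het_min_fraction`` times the
    major height. Returns ``None`` when no peak falls in the window
    (no amplification — propagated as a missing call downstream).

    Height ties are broken toward the shorter fragment so the reduction is
    deterministic and independent of input row order.
    """
    if not 0 < het_min_fraction <= 1:
        raise ValueError("het_min_fraction must be in (0, 1]")
    if min_allele_spacing_bp < 0:
        raise ValueError("min_allele_spacing_bp must be >= 0")
    ids = {(p.sample_id, p.tissue, p.marker) for p in peaks}
    if len(ids) > 1:
        raise ValueError(f"peaks span multiple sample/tissue/marker groups: {sorted(ids)}")
    surviving = [p for p in peaks if marker.contains_size(p.size_bp)]
    if not surviving:
        return None
    surviving.sort(key=lambda p: (-p.height, p.size_bp))
    major = surviving[0]
    minor = next(
        (p for p in surviving[1:] if abs(p.size_bp - major.size_bp) >= min_allele_spacing_bp),
        None,
    )
    if minor is not None and minor.height >= het_min_fraction * major.height:
        first, second = sorted((major, minor), key=lambda p: p.size_bp)
        return AllelePair(
            sample_id=major.sample_id,
            tissue=major.tissue,
            marker=major.marker,
            allele1_size_bp=first.size_bp,
            h1=first.height,
            allele2_size_bp=second.size_bp,
            h2=second.height,
        )
    return AllelePair(
        sample_id=major.sample_id,
        tissue=major.tissue,
        marker=major.marker,
        allele1_size_bp=major.size_bp,
        h1=major.height,
    )
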