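"""Cohort summaries of a call matrix.

Three aggregation levels:

* per sample — the fractional allele loss (FAL) index, the number of loci
  with LOH over the number of informative loci examined;
* per marker — LOH frequency among samples informative at that marker;
* per region — a sample counts as informative for a region when at least
  one of the region's markers is informative in its blood DNA, and as an
  LOH case when at least one of those markers shows LOH.

Exclusive-LOH patterns (loss confined to one region, none detected in the
others) are computed over all studied samples.
"""
from __future__ import annotations

from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP
from typing import Iterable, Sequence

import pandas as pd

from .calls import LOH, NG, CallMatrix, GenotypeCall
from .panel import Panel, canonical_region

__all__ = [
    "SampleSummary",
    "RegionSummary",
    "MarkerSummary",
    "fal_index",
    "region_summary",
    "marker_loh_frequency",
    "exclusive_loh_fraction",
    "sample_table",
    "region_table",
    "marker_table",
    "round_fal",
]


@dataclass(frozen=True)
class SampleSummary:
    sample_id: str
    n_informative: int
    n_loh: int

    @property
    def fal(self) -> float | None:
        """LOH loci / informative loci; undefined with no informative locus."""
        if self.n_informative == 0:
            return None
        return self.n_loh / self.n_informative


@dataclass(frozen=True)
class RegionSummary:
    region: str
    n_studied: int
    n_informative: int
    n_loh: int

    @property
    def informative_fraction(self) -> float | None:
        return None if self.n_studied == 0 else self.n_informative / self.n_studied

    @property
    def loh_fraction(self) -> float | None:
        return None if self.n_informative == 0 else self.n_loh / self.n_informative


@dataclass(frozen=True)
class MarkerSummary:
    marker: str
    n_informative: int
    n_loh: int

    @property
    def loh_fraction(self) -> float | None:
        return None if self.n_informative == 0 else self.n_loh / self.n_informative


def round_fal(fal: float | None, digits: int = 3) -> str:
    """Half-up presentation rounding; full precision is kept internally."""
    if fal is None:
        return "NA"
    q = Decimal(1).scaleb(-digits)
    return str(Decimal(repr(fal)).quantize(q, rounding=ROUND_HALF_UP).normalize())


def fal_index(calls: Iterable[GenotypeCall] | Sequence[str], sample_id: str | None = None) -> SampleSummary:
    """Fractional allele loss for one sample's calls.

    Accepts either :class:`GenotypeCall` objects or bare status tokens.
    ``ni`` and ``missing`` loci are excluded from the denominator.
    """
    statuses: list[str] = []
    sid = sample_id
    for c in calls:
        if isinstance(c, GenotypeCall):
            statuses.append(c.status)
            if sid is None:
                sid = c.sample_id
        else:
            statuses.append(c)
    n_informative = sum(1 for s in statuses if s in (LOH, NG))
    n_loh = sum(1 for s in statuses if s == LOH)
    return SampleSummary(sid or "", n_informative, n_loh)


def _region_markers(panel: Panel, region: str) -> list[str]:
    names = panel.markers_in_region(region)
    if not names:
        raise ValueError(f"region {region!r} has no markers")
    return names


def region_summary(matrix: CallMatrix, panel: Panel, region: str) -> RegionSummary:
    """Region-level informativeness and LOH incidence over the cohort."""
    region = canonical_region(region)
    names = [m for m in _region_markers(panel, region) if m in matrix.marker_names]
    if not names:
        raise ValueError(f"matrix has no markers for region {region!r}")
    n_informative = 0
    n_loh = 0
    for sid in matrix.sample_ids:
        statuses = [matrix.get(sid, m).status for m in names]
        if any(s in (LOH, NG) for s in statuses):
            n_informative += 1
        if any(s == LOH for s in statuses):
            n_loh += 1
    return RegionSummary(region, len(matrix.sample_ids), n_informative, n_loh)


def marker_loh_frequency(matrix: CallMatrix, marker: str) -> MarkerSummary:
    """LOH count, informative count and their ratio for a single marker."""
    if marker not in matrix.marker_names:
        raise ValueError(f"marker {marker!r} not in matrix ({matrix.marker_names})")
    statuses = [c.status for c in matrix.marker_calls(marker)]
    return MarkerSummary(
        marker,
        n_informative=sum(1 for s in statuses if s in (LOH, NG)),
        n_loh=sum(1 for s in statuses if s == LOH),
    )


def region_has_loh(matrix: CallMatrix, panel: Panel, region: str, sample_id: str) -> bool:
    names = _region_markers(panel, canonical_region(region))
    return any(
        matrix.get(sample_id, m).status == LOH
        for m in names
        if m in matrix.marker_names
    )


def exclusive_loh_fraction(
    matrix: CallMatrix,
    panel: Panel,
    target_region: str,
    other_regions: Sequence[str] | None = None,
) -> float:
    """Fraction of ALL studied samples with LOH confined to ``target_region``.

    Numerator: samples with >=1 LOH call among the target region's markers
    and no LOH call in any other region (informativeness elsewhere is not
    required). Denominator: every sample in the matrix.
    """
    target_region = canonical_region(target_region)
    if other_regions is None:
        other_regions = [r for r in panel.regions if r != target_region]
    other_regions = [canonical_region(r) for r in other_regions]
    overlap = set()
    target_set = set(_region_markers(panel, target_region))
    for r in other_regions:
        overlap |= target_set & set(_region_markers(panel, r))
    if overlap or target_region in other_regions:
        raise ValueError(f"target and other regions overlap: {sorted(overlap) or target_region}")
    n = sum(
        1
        for sid in matrix.sample_ids
        if region_has_loh(matrix, panel, target_region, sid)
        and not any(region_has_loh(matrix, panel, r, sid) for r in other_regions)
    )
    return n / len(matrix.sample_ids)


def sample_table(matrix: CallMatrix) -> pd.DataFrame:
    """Per-sample FAL table (columns sample_id, n_informative, n_loh, fal)."""
    rows = []
    for sid in matrix.sample_ids:
        s = fal_index(matrix.sample_calls(sid))
        rows.append((sid, s.n_informative, s.n_loh, s.fal))
    return pd.DataFrame(rows, columns=["sample_id", "n_informative", "n_loh", "fal"])


def region_table(matrix: CallMatrix, panel: Panel) -> pd.DataFrame:
    """Per-region incidence table mirroring the cohort summary layout."""
    rows = []
    for region in panel.regions:
        s = region_summary(matrix, panel, region)
        rows.append(
            (
                region,
                s.n_informative,
                s.n_studied,
                s.informative_fraction,
                s.n_loh,
                s.loh_fraction,
            )
        )
    return pd.DataFrame(
        rows,
        columns=[
            "region",
            "n_informative",
            "n_studied",
            "informative_fraction",
            "n_loh",
            "loh_fraction",
        ],
    )


def marker_table(matrix: CallMatrix, panel: Panel | None = None) -> pd.DataFrame:
    markers = panel.marker_names if panel is not None else matrix.marker_names
    rows = []
    for mk in markers:
        if mk not in matrix.marker_names:
            continue
        s = marker_loh_frequency(matrix, mk)
        rows.append((mk, s.n_informative, s.n_loh, s.loh_fraction))
    return pd.DataFrame(rows, columns=["marker", "n_informative", "n_loh", "loh_fraction"])
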