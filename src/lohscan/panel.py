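"""Microsatellite marker panel: definitions, region index, file I/O.

A panel is the ordered set of short-tandem-repeat loci genotyped in both
tumor and matched normal DNA. Each marker carries its chromosomal region,
an optional candidate gene, primer sequences, the fluorescent dye used for
fragment detection, and the expected PCR product-size window in base pairs.
The default panel covers three regions implicated in homologous-recombination
DNA repair: 15q14-21.1 (RAD51), 17q21.31 (BRCA1) and 13q12.3-13.1 (BRCA2),
with seven markers partitioned 3/2/2.
"""
from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

__all__ = [
    "MicrosatelliteMarker",
    "Panel",
    "PanelError",
    "load_default_panel",
    "load_panel",
    "REGION_ALIASES",
    "STUDY_REGIONS",
]

STUDY_REGIONS = ("15q14-21.1", "17q21.31", "13q12.3-13.1")

#: Alternate spellings accepted on input and normalized to the canonical label.
REGION_ALIASES: Mapping[str, str] = {"13q12-13": "13q12.3-13.1"}

VALID_DYES = ("6-FAM", "TET")

_PANEL_FIELDS = (
    "name",
    "region",
    "gene",
    "position_bp",
    "forward_primer",
    "reverse_primer",
    "dye",
    "size_min_bp",
    "size_max_bp",
)


class PanelError(ValueError):
    """Malformed panel definition or unknown marker/region lookup."""


def canonical_region(region: str) -> str:
    return REGION_ALIASES.get(region, region)


@dataclass(frozen=True)
class MicrosatelliteMarker:
    """One panel locus.

    ``position_bp`` is the genomic position as annotated at design time and
    is provenance metadata only — no computation uses it.
    """

    name: str
    region: str
    gene: str | None
    position_bp: int
    forward_primer: str
    reverse_primer: str
    dye: str
    size_min_bp: int
    size_max_bp: int

    def __post_init__(self) -> None:
        object.__setattr__(self, "region", canonical_region(self.region))
        if not self.name:
            raise PanelError("marker name must be non-empty")
        if self.size_min_bp >= self.size_max_bp:
            raise PanelError(
                f"{self.name}: size_min_bp ({self.size_min_bp}) must be < "
                f"size_max_bp ({self.size_max_bp})"
            )
        for label, seq in (("forward", self.forward_primer), ("reverse", self.reverse_primer)):
            if not seq or set(seq) - set("ACGT"):
                raise PanelError(f"{self.name}: {label} primer {seq!r} is not a plain ACGT string")
        if self.dye not in VALID_DYES:
            raise PanelError(f"{self.name}: dye {self.dye!r} not one of {VALID_DYES}")

    def contains_size(self, size_bp: float) -> bool:
        return self.size_min_bp <= size_bp <= self.size_max_bp


@dataclass(frozen=True)
class Panel:
    """Ordered marker collection with a region → markers index."""

    markers: tuple[MicrosatelliteMarker, ...]
    _by_name: dict[str, MicrosatelliteMarker] = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        names = [m.name for m in self.markers]
        if len(set(names)) != len(names):
            dupes = sorted({n for n in names if names.count(n) > 1})
            raise PanelError(f"duplicate marker names: {dupes}")
        object.__setattr__(self, "_by_name", {m.name: m for m in self.markers})

    def __iter__(self):
        return iter(self.markers)

    def __len__(self) -> int:
        return len(self.markers)

    @property
    def marker_names(self) -> list[str]:
        return [m.name for m in self.markers]

    @property
    def regions(self) -> list[str]:
        seen: list[str] = []
        for m in self.markers:
            if m.region not in seen:
                seen.append(m.region)
        return seen

    @property
    def region_index(self) -> dict[str, list[str]]:
        idx: dict[str, list[str]] = {}
        for m in self.markers:
            idx.setdefault(m.region, []).append(m.name)
        return idx

    def get(self, name: str) -> MicrosatelliteMarker:
        try:
            return self._by_name[name]
        except KeyError:
            raise PanelError(
                f"unknown marker {name!r}; panel has {self.marker_names}"
            ) from None

    def __contains__(self, name: str) -> bool:
        return name in self._by_name

    def markers_in_region(self, region: str) -> list[str]:
        """Marker names of ``region`` in panel order."""
        region = canonical_region(region)
        idx = self.region_index
        if region not in idx:
            raise PanelError(
                f"unknown region {region!r}; panel regions are {sorted(idx)}"
            )
        return idx[region]

    def to_file(self, path: str | Path) -> None:
        with open(path, "w", newline="", encoding="utf-8") as fh:
            writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
            writer.writerow(_PANEL_FIELDS)
            for m in self.markers:
                writer.writerow(
                    [
                        m.name,
                        m.region,
                        m.gene or "",
                        m.position_bp,
                        m.forward_primer,
                        m.reverse_primer,
                        m.dye,
                        m.size_min_bp,
                        m.size_max_bp,
                    ]
                )


def markers_in_region(panel: Panel, region: str) -> list[str]:
    """Module-level convenience mirroring :meth:`Panel.markers_in_region`."""
    return panel.markers_in_region(region)


def _parse_rows(rows: Iterable[dict], source: str) -> Panel:
    markers = []
    for lineno, row in enumerate(rows, start=2):
        missing = [f for f in _PANEL_FIELDS if row.get(f) in (None, "") and f != "gene"]
        if missing:
            raise PanelError(f"{source}: line {lineno}: missing field(s) {missing}")
        try:
            markers.append(
                MicrosatelliteMarker(
                    name=row["name"].strip(),
                    region=row["region"].strip(),
                    gene=(row.get("gene") or "").strip() or None,
                    position_bp=int(row["position_bp"]),
                    forward_primer=row["forward_primer"].strip(),
                    reverse_primer=row["reverse_primer"].strip(),
                    dye=row["dye"].strip(),
                    size_min_bp=int(row["size_min_bp"]),
                    size_max_bp=int(row["size_max_bp"]),
                )
            )
        except (PanelError, ValueError) as exc:
            raise PanelError(f"{source}: line {lineno}: {exc}") from None
    if not markers:
        raise PanelError(f"{source}: no markers defined")
    return Panel(tuple(markers))


def load_panel(path: str | Path) -> Panel:
    """Load a panel from a tab-separated file (see ``data/panel.tsv`` format)."""
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        if reader.fieldnames is None or "name" not in reader.fieldnames:
            raise PanelError(f"{path}: missing header row with a 'name' column")
        return _parse_rows(reader, str(path))


def load_default_panel() -> Panel:
    """The packaged seven-marker RAD51/BRCA1/BRCA2-region panel."""
    ref = resources.files("lohscan.data").joinpath("panel.tsv")
    with resources.as_file(ref) as path:
        return load_panel(path)
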