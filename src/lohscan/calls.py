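"""Allelic-imbalance LOH calling from paired tumor/normal allele peaks.

For a constitutionally heterozygous locus the tumor-to-normal allele ratio

    R = (T1 * N2) / (T2 * N1)

compares the shorter-allele peak heights (T1, N1) and longer-allele peak
heights (T2, N2) between tumor (T) and matched normal (N) tissue. R near 1
means both alleles are retained in balance; loss of heterozygosity (LOH) is
called when one allele is completely lost or reduced by at least 50%
relative to the other, i.e. R <= 0.5 or R >= 2.0 with the boundary
inclusive. A locus homozygous in normal DNA is non-informative (``ni``):
allelic loss is unobservable there. Per sample x marker the call status is
one of LOH, NG (heterozygous without LOH), ni, or missing (a tissue failed
to amplify).
"""
from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
import yaml

from .panel import Panel
from .peaks import (
    AllelePair,
    PeakRecord,
    extract_alleles,
    DEFAULT_HET_MIN_FRACTION,
    DEFAULT_MIN_ALLELE_SPACING_BP,
)

__all__ = [
    "LOH",
    "NG",
    "NI",
    "MISSING",
    "STATUSES",
    "GenotypeCall",
    "CallMatrix",
    "CallingConfig",
    "AlleleMismatchError",
    "CallMatrixError",
    "allele_ratio",
    "call_marker",
    "call_all",
    "read_call_matrix",
    "write_call_matrix",
]

LOH = "LOH"
NG = "NG"
NI = "ni"
MISSING = "missing"
STATUSES = (LOH, NG, NI, MISSING)

#: Token used for ``missing`` in call-matrix files.
_NA_TOKEN = "NA"
_FAL_COLUMN_NAMES = {"fal", "fal_index"}


class AlleleMismatchError(ValueError):
    """Tumor allele sizes do not match the constitutional alleles.

    Raised when a tumor allele cannot be assigned to either normal allele
    within the size bin — possible sample mix-up or microsatellite
    instability, which this caller flags but does not score.
    """


class CallMatrixError(ValueError):
    """Invalid call-matrix file content."""


@dataclass(frozen=True)
class CallingConfig:
    """Single source of truth for the calling policy.

    ``lower_ratio``/``upper_ratio`` bound the no-loss band of the allele
    ratio (boundary values are called LOH). ``size_bin_bp`` is the maximum
    sizing discrepancy allowed when pairing tumor alleles with normal
    alleles. The remaining knobs parameterize peak-to-allele reduction
    (see :func:`lohscan.peaks.extract_alleles`).
    """

    lower_ratio: float = 0.5
    upper_ratio: float = 2.0
    het_min_fraction: float = DEFAULT_HET_MIN_FRACTION
    min_allele_spacing_bp: float = DEFAULT_MIN_ALLELE_SPACING_BP
    size_bin_bp: float = 1.0

    def __post_init__(self) -> None:
        if not 0 < self.lower_ratio < 1:
            raise ValueError("lower_ratio must be in (0, 1)")
        if self.upper_ratio <= 1:
            raise ValueError("upper_ratio must be > 1")
        if self.size_bin_bp < 0:
            raise ValueError("size_bin_bp must be >= 0")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "CallingConfig":
        with open(path, encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - {f for f in cls.__dataclass_fields__}
        if unknown:
            raise ValueError(f"{path}: unknown config key(s) {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)


@dataclass(frozen=True)
class GenotypeCall:
    sample_id: str
    marker: str
    status: str
    ratio: float | None = None

    def __post_init__(self) -> None:
        if self.status not in STATUSES:
            raise ValueError(f"status {self.status!r} not one of {STATUSES}")
        if self.status in (NI, MISSING) and self.ratio is not None:
            raise ValueError(f"status {self.status} cannot carry a ratio")
        if self.ratio is not None and not self.ratio > 0:
            raise ValueError("ratio, when present, must be > 0")

    @property
    def informative(self) -> bool:
        return self.status in (LOH, NG)


def allele_ratio(t1: float, t2: float, n1: float, n2: float) -> float:
    """Tumor/normal allele peak-height ratio ``(T1*N2)/(T2*N1)``.

    Subscript 1 is the shorter-length allele, 2 the longer, in both tissues.
    All four heights must be positive; complete loss of one allele is
    handled by :func:`call_marker`, not here.
    """
    for name, v in (("t1", t1), ("t2", t2), ("n1", n1), ("n2", n2)):
        if not v > 0:
            raise ValueError(f"{name} must be > 0, got {v}")
    return (t1 * n2) / (t2 * n1)


def _match_allele(size: float, normal_sizes: Sequence[float], bin_bp: float) -> int | None:
    """Index of the normal allele within ``bin_bp`` of ``size`` (closest wins)."""
    best, best_d = None, None
    for i, ns in enumerate(normal_sizes):
        d = abs(size - ns)
        if d <= bin_bp and (best_d is None or d < best_d):
            best, best_d = i, d
    return best


def call_marker(
    normal: AllelePair | None,
    tumor: AllelePair | None,
    config: CallingConfig = CallingConfig(),
) -> GenotypeCall:
    """Score one sample x marker from its normal and tumor allele pairs.

    Informativeness is decided by the normal (blood) genotype alone: a
    homozygous normal is ``ni`` regardless of the tumor. For heterozygous
    normals, a tumor retaining a single normal allele is LOH by complete
    loss (no ratio); a tumor retaining both is called by the allele ratio
    against the inclusive thresholds. A missing tissue yields ``missing``.
    """
    if normal is None and tumor is None:
        raise ValueError("at least one tissue must be identified")
    ref = normal if normal is not None else tumor
    sample_id, marker = ref.sample_id, ref.marker
    if normal is not None and tumor is not None:
        if (normal.sample_id, normal.marker) != (tumor.sample_id, tumor.marker):
            raise ValueError(
                f"tissue mismatch: normal is {(normal.sample_id, normal.marker)}, "
                f"tumor is {(tumor.sample_id, tumor.marker)}"
            )
    if normal is None or tumor is None:
        return GenotypeCall(sample_id, marker, MISSING)
    if not normal.heterozygous:
        return GenotypeCall(sample_id, marker, NI)

    n_sizes = normal.sizes
    n_heights = (normal.h1, normal.h2)
    matches = [_match_allele(s, n_sizes, config.size_bin_bp) for s in tumor.sizes]
    if any(m is None for m in matches) or len(set(matches)) != len(matches):
        raise AlleleMismatchError(
            f"{sample_id}/{marker}: tumor allele sizes {tumor.sizes} do not pair "
            f"with normal alleles {n_sizes} within ±{config.size_bin_bp} bp "
            "(possible sample mix-up or microsatellite instability)"
        )
    if not tumor.heterozygous:
        # One constitutional allele absent from the tumor: loss.
        return GenotypeCall(sample_id, marker, LOH, ratio=None)
    t_heights = [None, None]
    for t_height, m in zip((tumor.h1, tumor.h2), matches):
        t_heights[m] = t_height
    ratio = allele_ratio(t_heights[0], t_heights[1], n_heights[0], n_heights[1])
    status = LOH if (ratio <= config.lower_ratio or ratio >= config.upper_ratio) else NG
    return GenotypeCall(sample_id, marker, status, ratio=ratio)


@dataclass
class CallMatrix:
    """Sample x marker grid of genotype calls.

    ``flags`` records cells the caller set to ``missing`` because tumor and
    normal alleles could not be paired (mix-up/instability flags).
    """

    sample_ids: list[str]
    marker_names: list[str]
    calls: dict[tuple[str, str], GenotypeCall]
    flags: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        for sid in self.sample_ids:
            for mk in self.marker_names:
                if (sid, mk) not in self.calls:
                    raise CallMatrixError(f"no call for sample {sid!r} x marker {mk!r}")

    def get(self, sample_id: str, marker: str) -> GenotypeCall:
        return self.calls[(sample_id, marker)]

    def sample_calls(self, sample_id: str) -> list[GenotypeCall]:
        return [self.calls[(sample_id, mk)] for mk in self.marker_names]

    def marker_calls(self, marker: str) -> list[GenotypeCall]:
        return [self.calls[(sid, marker)] for sid in self.sample_ids]

    @property
    def shape(self) -> tuple[int, int]:
        return (len(self.sample_ids), len(self.marker_names))

    def to_dataframe(self) -> pd.DataFrame:
        data = {
            mk: [self.calls[(sid, mk)].status for sid in self.sample_ids]
            for mk in self.marker_names
        }
        return pd.DataFrame(data, index=pd.Index(self.sample_ids, name="sample_id"))

    @classmethod
    def from_status_grid(
        cls,
        sample_ids: Sequence[str],
        marker_names: Sequence[str],
        grid: Mapping[tuple[str, str], str] | Sequence[Sequence[str]],
    ) -> "CallMatrix":
        """Build a matrix from bare status tokens (no ratios)."""
        calls: dict[tuple[str, str], GenotypeCall] = {}
        if isinstance(grid, Mapping):
            lookup = lambda s, m: grid[(s, m)]  # noqa: E731
        else:
            rows = {s: list(r) for s, r in zip(sample_ids, grid)}
            lookup = lambda s, m: rows[s][list(marker_names).index(m)]  # noqa: E731
        for sid in sample_ids:
            for mk in marker_names:
                calls[(sid, mk)] = GenotypeCall(sid, mk, lookup(sid, mk))
        return cls(list(sample_ids), list(marker_names), calls)


def call_all(
    peak_records: Iterable[PeakRecord],
    panel: Panel,
    config: CallingConfig = CallingConfig(),
) -> CallMatrix:
    """Call every sample x panel-marker cell from a peak table.

    Samples are taken in order of first appearance. Cells lacking tumor or
    normal amplification are ``missing``; cells whose tumor alleles cannot
    be paired with the normal alleles are ``missing`` and flagged.
    """
    grouped: dict[tuple[str, str, str], list[PeakRecord]] = {}
    sample_order: list[str] = []
    for rec in peak_records:
        if rec.sample_id not in sample_order:
            sample_order.append(rec.sample_id)
        grouped.setdefault((rec.sample_id, rec.marker, rec.tissue), []).append(rec)
    if not sample_order:
        raise ValueError("no peak records supplied")

    calls: dict[tuple[str, str], GenotypeCall] = {}
    flags: list[str] = []
    for sid in sample_order:
        for mk in panel.marker_names:
            marker = panel.get(mk)
            pairs = {}
            for tissue in ("normal", "tumor"):
                recs = grouped.get((sid, mk, tissue), [])
                pairs[tissue] = (
                    extract_alleles(
                        recs,
                        marker,
                        het_min_fraction=config.het_min_fraction,
                        min_allele_spacing_bp=config.min_allele_spacing_bp,
                    )
                    if recs
                    else None
                )
            if pairs["normal"] is None and pairs["tumor"] is None:
                calls[(sid, mk)] = GenotypeCall(sid, mk, MISSING)
                continue
            try:
                calls[(sid, mk)] = call_marker(pairs["normal"], pairs["tumor"], config)
            except AlleleMismatchError as exc:
                flags.append(str(exc))
                calls[(sid, mk)] = GenotypeCall(sid, mk, MISSING)
    return CallMatrix(sample_order, panel.marker_names, calls, flags)


def write_call_matrix(
    matrix: CallMatrix, path: str | Path, *, include_fal: bool = False
) -> None:
    """Write the matrix as CSV (tokens LOH/NG/ni/NA, one marker per column).

    With ``include_fal`` a trailing fractional-allele-loss column is added
    for human inspection; it is recomputed, never trusted, on read.
    """
    df = matrix.to_dataframe().replace(MISSING, _NA_TOKEN)
    if include_fal:
        from .summarize import fal_index  # local import: summarize depends on calls

        fal = []
        for sid in matrix.sample_ids:
            s = fal_index(matrix.sample_calls(sid))
            fal.append("" if s.fal is None else f"{s.fal:.6g}")
        df["fal"] = fal
    df.to_csv(path)


def read_call_matrix(path: str | Path, panel: Panel | None = None) -> CallMatrix:
    """Read a call-matrix CSV; any FAL column is ignored and recomputed later."""
    df = pd.read_csv(path, dtype=str).fillna(_NA_TOKEN)
    if df.columns[0] != "sample_id":
        raise CallMatrixError(f"{path}: first column must be 'sample_id', got {df.columns[0]!r}")
    df = df.set_index("sample_id")
    df = df[[c for c in df.columns if c.lower() not in _FAL_COLUMN_NAMES]]
    markers = list(df.columns)
    if panel is not None:
        unknown = [m for m in markers if m not in panel]
        if unknown:
            raise CallMatrixError(f"{path}: unknown marker column(s) {unknown}")
        markers = [m for m in panel.marker_names if m in df.columns]
        df = df[markers]
    token_map = {LOH: LOH, NG: NG, NI: NI, _NA_TOKEN: MISSING}
    calls: dict[tuple[str, str], GenotypeCall] = {}
    sample_ids = [str(s) for s in df.index]
    for sid, row in zip(sample_ids, df.itertuples(index=False)):
        for mk, token in zip(markers, row):
            if token not in token_map:
                raise CallMatrixError(
                    f"{path}: sample {sid!r}, marker {mk!r}: unknown token {token!r} "
                    f"(accepted: {sorted(token_map)})"
                )
            calls[(sid, mk)] = GenotypeCall(sid, mk, token_map[token])
    return CallMatrix(sample_ids, markers, calls)
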