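"""Synthetic paired tumor/normal cohorts with known LOH truth.

The generator emulates the data-generating situation the analysis assumes:
each patient carries at most one deletion event per chromosomal region
(shared by the region's markers), observable only at markers where the
patient is constitutionally heterozygous. Tumor peak heights are a
purity-weighted mixture of tumor-cell and contaminating normal-cell allele
copies under multiplicative lognormal noise; a clinical covariate table is
drawn alongside, with PSA density optionally linked to regional LOH so
association tests can be exercised with a known effect (or a known null).

Default rates are calibrated to the reference cohort: region-wise
informativeness of about 0.80/0.60/0.70 and LOH incidence among informative
cases of 0.575/0.23/0.40 for 15q14-21.1, 17q21.31 and 13q12.3-13.1.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from importlib import resources
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from .assoc import GroupingRule, default_rules
from .calls import CallMatrix, GenotypeCall, LOH, NG, NI, read_call_matrix
from .panel import Panel, load_default_panel
from .peaks import PeakRecord, write_peak_table

__all__ = [
    "SimulationConfig",
    "SimulatedCohort",
    "simulate_cohort",
    "expected_ratio",
    "load_reference_cohort",
]

# Per-marker heterozygosity defaults solve 1-(1-h)^k = target region
# informativeness (k markers/region; targets 0.80, 0.60, 0.70).
_DEFAULT_HET_PROB = {
    "15q14-21.1": 1.0 - 0.20 ** (1.0 / 3.0),  # ~0.415
    "17q21.31": 1.0 - math.sqrt(0.40),        # ~0.368
    "13q12.3-13.1": 1.0 - math.sqrt(0.30),    # ~0.452
}
_DEFAULT_LOH_PROB = {"15q14-21.1": 0.575, "17q21.31": 0.23, "13q12.3-13.1": 0.40}

_GLEASON_VALUES = (4, 6, 7, 8, 9, 10)
_GLEASON_PROBS = (0.04, 0.18, 0.36, 0.22, 0.18, 0.02)
_STAGE_VALUES = ("T1", "T2", "T3", "T4")
_STAGE_PROBS = (0.24, 0.28, 0.24, 0.24)


def expected_ratio(purity: float, completeness: float) -> float:
    """Noiseless allele ratio a caller observes for a true LOH event.

    With tumor-cell fraction ``purity`` and a fraction ``completeness`` of
    the lost allele remaining in tumor cells, the lost allele's copy
    fraction relative to the retained allele is
    ``(1 - purity) + purity * completeness``.
    """
    if not 0 < purity <= 1:
        raise ValueError("purity must be in (0, 1]")
    if not 0 <= completeness < 1:
        raise ValueError("completeness must be in [0, 1)")
    return (1.0 - purity) + purity * completeness


@dataclass(frozen=True)
class SimulationConfig:
    """Cohort-generator settings.

    ``het_prob`` and ``loh_prob`` map region label -> probability;
    ``tumor_purity`` is the tumor-cell fraction of the biopsy;
    ``loss_completeness`` the fraction of the lost allele remaining in
    tumor cells (0 = complete somatic loss); ``peak_cv`` the coefficient
    of variation of multiplicative lognormal peak noise; a positive
    ``stutter_fraction`` adds a -2 bp shoulder peak at that height
    fraction. ``psad_odds_ratio`` links P(PSAD >= 0.15) to regional LOH
    (1 = null); ``psad_high_prob`` is the no-LOH baseline.
    """

    n_patients: int = 50
    het_prob: Mapping[str, float] = field(default_factory=lambda: dict(_DEFAULT_HET_PROB))
    loh_prob: Mapping[str, float] = field(default_factory=lambda: dict(_DEFAULT_LOH_PROB))
    tumor_purity: float = 0.7
    loss_completeness: float = 0.0
    peak_height_mean: float = 2000.0
    peak_cv: float = 0.1
    stutter_fraction: float = 0.0
    psad_odds_ratio: float = 1.0
    psad_high_prob: float = 0.84
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 1:
            raise ValueError("n_patients must be >= 1")
        for name, probs in (("het_prob", self.het_prob), ("loh_prob", self.loh_prob)):
            for region, p in probs.items():
                if not 0 <= p <= 1:
                    raise ValueError(f"{name}[{region!r}] must be in [0, 1], got {p}")
        expected_ratio(self.tumor_purity, self.loss_completeness)  # domain check
        if self.peak_cv < 0:
            raise ValueError("peak_cv must be >= 0")
        if not 0 <= self.stutter_fraction < 1:
            raise ValueError("stutter_fraction must be in [0, 1)")
        if self.psad_odds_ratio <= 0:
            raise ValueError("psad_odds_ratio must be > 0")
        if not 0 < self.psad_high_prob < 1:
            raise ValueError("psad_high_prob must be in (0, 1)")

    def to_yaml(self, path: str | Path) -> None:
        data = asdict(self)
        data["het_prob"] = dict(self.het_prob)
        data["loh_prob"] = dict(self.loh_prob)
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationConfig":
        with open(path, encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)


@dataclass
class SimulatedCohort:
    peaks: list[PeakRecord]
    truth: CallMatrix
    clinical: pd.DataFrame
    config: SimulationConfig

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_peak_table(self.peaks, outdir / "peaks.csv")
        from .calls import write_call_matrix

        write_call_matrix(self.truth, outdir / "truth_calls.csv", include_fal=True)
        self.clinical.to_csv(outdir / "clinical.csv", index=False)
        self.config.to_yaml(outdir / "config.yaml")


def _lognormal_factor(rng: np.random.Generator, cv: float) -> float:
    """Unit-mean multiplicative noise with the requested CV."""
    if cv == 0:
        return 1.0
    sigma = math.sqrt(math.log(1.0 + cv * cv))
    return float(rng.lognormal(mean=-0.5 * sigma * sigma, sigma=sigma))


def _validate_panel(config: SimulationConfig, panel: Panel) -> None:
    for region in panel.regions:
        if region not in config.het_prob or region not in config.loh_prob:
            raise ValueError(f"config lacks het_prob/loh_prob for region {region!r}")
    for m in panel:
        n_grid = int((m.size_max_bp - m.size_min_bp) // 2) + 1
        if n_grid < 2:
            raise ValueError(
                f"{m.name}: size window [{m.size_min_bp}, {m.size_max_bp}] too "
                "narrow for two distinct alleles on a 2 bp grid"
            )


def simulate_cohort(
    config: SimulationConfig = SimulationConfig(), panel: Panel | None = None
) -> SimulatedCohort:
    """Draw a full synthetic cohort: peak table, truth calls, clinical table.

    A fixed ``config.rng_seed`` makes the cohort byte-identical on disk.
    Truth statuses ignore purity and noise: ``ni`` where the constitutional
    genotype is homozygous, else LOH/NG by the latent region event.
    """
    if panel is None:
        panel = load_default_panel()
    _validate_panel(config, panel)
    rng = np.random.default_rng(config.rng_seed)
    width = max(3, len(str(config.n_patients)))
    sample_ids = [f"P{i + 1:0{width}d}" for i in range(config.n_patients)]

    lost_fraction = expected_ratio(config.tumor_purity, config.loss_completeness)
    peaks: list[PeakRecord] = []
    calls: dict[tuple[str, str], GenotypeCall] = {}
    region_event: dict[tuple[str, str], bool] = {}

    def emit(sid: str, tissue: str, marker: str, size: float, height_frac: float) -> None:
        if height_frac <= 0:
            return
        h = config.peak_height_mean * height_frac * _lognormal_factor(rng, config.peak_cv)
        peaks.append(PeakRecord(sid, tissue, marker, float(size), h))
        if config.stutter_fraction > 0:
            peaks.append(
                PeakRecord(
                    sid, tissue, marker, float(size) - 2.0, h * config.stutter_fraction
                )
            )

    for sid in sample_ids:
        for region in panel.regions:
            region_event[(sid, region)] = bool(rng.random() < config.loh_prob[region])
        for m in panel:
            grid = np.arange(m.size_min_bp, m.size_max_bp + 1e-9, 2.0)
            het = bool(rng.random() < config.het_prob[m.region])
            event = region_event[(sid, m.region)]
            if het:
                sizes = np.sort(rng.choice(grid, size=2, replace=False))
                lost_idx = int(rng.integers(2)) if event else -1
                # normal tissue: balanced constitutional alleles
                for size in sizes:
                    emit(sid, "normal", m.name, size, 1.0)
                for i, size in enumerate(sizes):
                    emit(sid, "tumor", m.name, size, lost_fraction if i == lost_idx else 1.0)
                status = LOH if event else NG
            else:
                size = float(rng.choice(grid))
                emit(sid, "normal", m.name, size, 2.0)
                emit(sid, "tumor", m.name, size, 2.0)
                status = NI
            calls[(sid, m.name)] = GenotypeCall(sid, m.name, status)

    truth = CallMatrix(sample_ids, panel.marker_names, calls)
    clinical = _simulate_clinical(config, panel, rng, sample_ids, region_event)
    return SimulatedCohort(peaks, truth, clinical, config)


def _simulate_clinical(
    config: SimulationConfig,
    panel: Panel,
    rng: np.random.Generator,
    sample_ids: list[str],
    region_event: Mapping[tuple[str, str], bool],
) -> pd.DataFrame:
    """Clinical covariates with ranges typical of a prostate-biopsy cohort.

    Only PSA density is linked to LOH (latent deletion in 15q14-21.1 or
    13q12.3-13.1) through ``psad_odds_ratio``; everything else is drawn
    independently of the genotypes, so the generator is an exact null for
    those variables.
    """
    psad_regions = [r for r in ("15q14-21.1", "13q12.3-13.1") if r in panel.regions]
    base_logit = math.log(config.psad_high_prob / (1.0 - config.psad_high_prob))
    rows = []
    for sid in sample_ids:
        age = int(round(min(86.0, max(55.0, rng.normal(71.2, 8.6)))))
        psat = float(min(1489.0, max(4.58, rng.lognormal(math.log(17.37), 1.1))))
        psaf = float(min(0.79, max(0.05, rng.lognormal(math.log(0.16), 0.5))))
        has_loh = any(region_event[(sid, r)] for r in psad_regions)
        logit = base_logit + (math.log(config.psad_odds_ratio) if has_loh else 0.0)
        p_high = 1.0 / (1.0 + math.exp(-logit))
        if rng.random() < p_high:
            psad = float(min(56.4, 0.15 * math.exp(rng.exponential(1.2))))
        else:
            psad = float(rng.uniform(0.08, 0.1499))
        volume = float(min(191.0, max(20.7, rng.lognormal(math.log(47.25), 0.45))))
        gleason = int(rng.choice(_GLEASON_VALUES, p=_GLEASON_PROBS))
        stage = str(rng.choice(_STAGE_VALUES, p=_STAGE_PROBS))
        rows.append((sid, age, round(psat, 2), round(psaf, 3), round(psad, 4), round(volume, 1), gleason, stage))
    return pd.DataFrame(
        rows,
        columns=[
            "sample_id",
            "age",
            "psat",
            "psaf_ratio",
            "psad",
            "prostate_volume",
            "gleason",
            "stage",
        ],
    )


def load_reference_cohort() -> tuple[CallMatrix, list[GroupingRule]]:
    """The packaged 50-patient reference call matrix and the study's
    stratification rules.

    The matrix ships statuses only; FAL indices and all summaries are
    recomputed downstream. Per-sample clinical values are not part of the
    fixture (only stratum definitions are), so the second element carries
    the grouping rules rather than a clinical table.
    """
    ref = resources.files("lohscan.data").joinpath("reference_calls_50.csv")
    with resources.as_file(ref) as path:
        matrix = read_call_matrix(path, panel=load_default_panel())
    return matrix, default_rules()
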