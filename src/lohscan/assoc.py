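"""Clinicopathological association testing for regional LOH and FAL.

The cohort's clinical covariates (age, total PSA, free/total PSA ratio, PSA
density, prostate volume, Gleason score, T stage) are split into the study's
strata; regional LOH status (>=1 LOH marker among a region's informative
markers) is cross-tabulated against each stratification and tested with
Fisher's exact test — computed here by full enumeration of all tables with
the observed margins (point-probability two-sided rule, log-factorial
arithmetic), which for a stratification with more than two levels is the
Freeman–Halton extension. FAL distributions across strata are compared with
the exact/asymptotic Mann–Whitney U test or the Kruskal–Wallis test, and
monotone association and trend with Spearman rank correlation and ordinary
least squares.

All tests are implemented in-package to the conventions documented on each
function; they are cross-checked against independent references in the test
suite.
"""
from __future__ import annotations

import logging
import math
import re
from dataclasses import dataclass
from itertools import combinations
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import chi2 as chi2_dist
from scipy.stats import norm as norm_dist
from scipy.stats import rankdata
from scipy.stats import t as t_dist

from .calls import LOH, NG, CallMatrix
from .panel import Panel, canonical_region
from .summarize import fal_index, region_has_loh

__all__ = [
    "ContingencyTable2x2",
    "GroupingRule",
    "default_rules",
    "read_clinical_table",
    "dichotomize",
    "loh_contingency",
    "fisher_exact",
    "fisher_exact_2x2",
    "fisher_table_log_probs",
    "mann_whitney_u",
    "kruskal_wallis",
    "spearman_rho",
    "linear_regression",
    "association_report",
    "fal_association",
    "CLINICAL_COLUMNS",
]

logger = logging.getLogger("lohscan.assoc")

CLINICAL_COLUMNS = (
    "sample_id",
    "age",
    "psat",
    "psaf_ratio",
    "psad",
    "prostate_volume",
    "gleason",
    "stage",
)

_STAGE_RE = re.compile(r"^T([1-4])$")

#: Log-probability slack when collecting tables "at most as probable as
#: observed" — absorbs float rounding in the log-factorial sums.
_LOG_P_EPS = 1e-7


# ---------------------------------------------------------------------------
# Clinical records and stratification
# ---------------------------------------------------------------------------

def read_clinical_table(path: str | Path) -> pd.DataFrame:
    """Read and validate the clinical covariate CSV.

    Missing values are permitted (empty cells); offending non-missing values
    raise with the sample id.
    """
    df = pd.read_csv(path, dtype={"sample_id": str, "stage": str})
    missing = [c for c in CLINICAL_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing clinical column(s) {missing}")
    df = df[list(CLINICAL_COLUMNS)].copy()
    for _, row in df.iterrows():
        sid = row["sample_id"]
        for col in ("age", "psat", "psad", "prostate_volume"):
            v = row[col]
            if pd.notna(v) and not v > 0:
                raise ValueError(f"{path}: sample {sid}: {col} must be > 0, got {v}")
        if pd.notna(row["psaf_ratio"]) and not 0 < row["psaf_ratio"] <= 1:
            raise ValueError(f"{path}: sample {sid}: psaf_ratio must be in (0, 1]")
        if pd.notna(row["gleason"]) and not 2 <= row["gleason"] <= 10:
            raise ValueError(f"{path}: sample {sid}: gleason must be in [2, 10]")
        if pd.notna(row["stage"]) and not _STAGE_RE.match(str(row["stage"])):
            raise ValueError(f"{path}: sample {sid}: stage must be T1..T4")
    return df


@dataclass(frozen=True)
class GroupingRule:
    """Ordered stratification of one clinical variable at fixed cut points.

    ``boundary_to_upper`` controls where a value equal to a cut lands; the
    study's dichotomies all read ">= cut" (boundary up) while its three-level
    total-PSA split reads "> cut" (boundary down).
    """

    variable: str
    cuts: tuple[float, ...]
    labels: tuple[str, ...]
    boundary_to_upper: bool = True

    def __post_init__(self) -> None:
        if len(self.labels) != len(self.cuts) + 1:
            raise ValueError("need exactly len(cuts)+1 labels")
        if list(self.cuts) != sorted(set(self.cuts)):
            raise ValueError("cuts must be strictly increasing")
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("labels must be unique")

    def assign(self, value: float) -> str:
        for i, cut in enumerate(self.cuts):
            if value < cut or (not self.boundary_to_upper and value == cut):
                return self.labels[i]
        return self.labels[-1]


def default_rules() -> list[GroupingRule]:
    """The study's stratifications of the clinical covariates."""
    return [
        GroupingRule("age", (72,), ("<72", ">=72")),
        GroupingRule("psat", (10, 20), ("4-10", ">10-20", ">20"), boundary_to_upper=False),
        GroupingRule("psaf_ratio", (0.16,), ("<0.16", ">=0.16")),
        GroupingRule("psad", (0.15,), ("<0.15", ">=0.15")),
        GroupingRule("prostate_volume", (50,), ("<50", ">=50")),
        GroupingRule("gleason", (7,), ("<7", ">=7")),
        GroupingRule("stage", (3,), ("T1-T2", "T3-T4")),
    ]


def dichotomize(clinical: pd.DataFrame, rule: GroupingRule) -> dict[str, str]:
    """Map sample_id -> stratum label under ``rule``; missing values dropped."""
    if rule.variable not in clinical.columns:
        raise ValueError(
            f"unknown variable {rule.variable!r}; clinical columns are "
            f"{list(clinical.columns)}"
        )
    values = clinical.set_index("sample_id")[rule.variable]
    groups: dict[str, str] = {}
    n_missing = 0
    for sid, v in values.items():
        if pd.isna(v):
            n_missing += 1
            continue
        if rule.variable == "stage":
            v = int(_STAGE_RE.match(str(v)).group(1))
        groups[str(sid)] = rule.assign(float(v))
    if n_missing:
        logger.info("%s: %d sample(s) with missing values excluded", rule.variable, n_missing)
    return groups


# ---------------------------------------------------------------------------
# Contingency tables
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ContingencyTable2x2:
    """Counts a..d: rows = clinical strata, columns = (LOH, no LOH)."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("counts must be non-negative")

    @property
    def total(self) -> int:
        return self.a + self.b + self.c + self.d

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]], dtype=np.int64)


def loh_contingency(
    matrix: CallMatrix,
    panel: Panel,
    region: str,
    groups: Mapping[str, str],
    labels: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Strata x (LOH, NG) counts over region-informative, grouped samples.

    Rows follow ``labels`` (or first-appearance order); every label appears
    even if no informative sample falls in it. Row sums give the informative
    count I per stratum, so I = N + LOH holds by construction.
    """
    region = canonical_region(region)
    region_markers = set(panel.markers_in_region(region)) & set(matrix.marker_names)
    if labels is None:
        seen: list[str] = []
        for sid in matrix.sample_ids:
            g = groups.get(sid)
            if g is not None and g not in seen:
                seen.append(g)
        labels = seen
    counts = {lab: {"LOH": 0, "NG": 0} for lab in labels}
    for sid in matrix.sample_ids:
        lab = groups.get(sid)
        if lab is None:
            continue
        if lab not in counts:
            raise ValueError(f"sample {sid}: group {lab!r} not in labels {list(labels)}")
        statuses = [matrix.get(sid, m).status for m in matrix.marker_names if m in region_markers]
        if not any(s in (LOH, NG) for s in statuses):
            continue  # not informative for this region
        if any(s == LOH for s in statuses):
            counts[lab]["LOH"] += 1
        else:
            counts[lab]["NG"] += 1
    return pd.DataFrame(
        [[counts[lab]["LOH"], counts[lab]["NG"]] for lab in labels],
        index=pd.Index(labels, name="stratum"),
        columns=["LOH", "NG"],
    )


# ---------------------------------------------------------------------------
# Fisher's exact test (r x 2, point-probability two-sided rule)
# ---------------------------------------------------------------------------

def _log_hypergeom(table: np.ndarray) -> float:
    """Log multivariate hypergeometric probability of an r x c table given
    its margins: log( prod r_i! prod c_j! / (N! prod n_ij!) )."""
    rows = table.sum(axis=1)
    cols = table.sum(axis=0)
    n = int(table.sum())
    lp = -math.lgamma(n + 1)
    lp += sum(math.lgamma(int(r) + 1) for r in rows)
    lp += sum(math.lgamma(int(c) + 1) for c in cols)
    lp -= sum(math.lgamma(int(x) + 1) for x in table.ravel())
    return lp


def _iter_first_columns(row_sums: Sequence[int], col1: int):
    """All first-column count vectors consistent with the margins."""
    r = len(row_sums)

    def rec(i: int, remaining: int, prefix: tuple[int, ...]):
        if i == r - 1:
            if 0 <= remaining <= row_sums[i]:
                yield prefix + (remaining,)
            return
        tail_capacity = sum(row_sums[i + 1 :])
        lo = max(0, remaining - tail_capacity)
        hi = min(row_sums[i], remaining)
        for x in range(lo, hi + 1):
            yield from rec(i + 1, remaining - x, prefix + (x,))

    yield from rec(0, col1, ())


def fisher_table_log_probs(table) -> tuple[float, list[float]]:
    """(observed log-probability, log-probabilities of every table with the
    observed margins). The exponentials of the second element sum to 1."""
    obs = np.asarray(getattr(table, "as_array", lambda: table)(), dtype=np.int64)
    if obs.ndim != 2 or obs.shape[1] != 2:
        raise ValueError("expected an r x 2 table")
    if obs.min() < 0:
        raise ValueError("counts must be non-negative")
    if obs.sum() == 0:
        raise ValueError("empty table: no observations to test")
    row_sums = [int(x) for x in obs.sum(axis=1)]
    col1 = int(obs[:, 0].sum())
    obs_lp = _log_hypergeom(obs)
    lps = []
    for first_col in _iter_first_columns(row_sums, col1):
        t = np.column_stack([first_col, np.asarray(row_sums) - np.asarray(first_col)])
        lps.append(_log_hypergeom(t))
    return obs_lp, lps


def fisher_exact(table) -> float:
    """Two-sided Fisher exact p for an r x 2 table.

    Sums the point probabilities of every table with the observed margins
    whose probability does not exceed the observed table's (the
    point-probability rule). For r > 2 this is the Freeman–Halton test.
    A table with a zero row or column admits a single configuration and
    returns p = 1.
    """
    obs_lp, lps = fisher_table_log_probs(table)
    p = sum(math.exp(lp) for lp in lps if lp <= obs_lp + _LOG_P_EPS)
    return min(p, 1.0)


def fisher_exact_2x2(table) -> float:
    """Two-sided Fisher exact p for a 2 x 2 table (see :func:`fisher_exact`)."""
    obs = np.asarray(getattr(table, "as_array", lambda: table)(), dtype=np.int64)
    if obs.shape != (2, 2):
        raise ValueError(f"expected a 2x2 table, got shape {obs.shape}")
    return fisher_exact(obs)


# ---------------------------------------------------------------------------
# Rank tests, correlation, regression
# ---------------------------------------------------------------------------

def _tie_term(values: np.ndarray) -> float:
    """sum over tie groups of (t^3 - t)."""
    _, counts = np.unique(values, return_counts=True)
    return float(np.sum(counts.astype(float) ** 3 - counts))


def mann_whitney_u(
    x: Sequence[float], y: Sequence[float], exact_max_n: int = 12
) -> tuple[float, float]:
    """Two-sided Mann–Whitney U test; returns (min(U_x, U_y), p).

    With at most ``exact_max_n`` observations in total and no ties the p
    value is exact, by complete enumeration of the rank assignments;
    otherwise the normal approximation with tie-corrected variance and a
    0.5 continuity correction is used. Two identical samples (zero variance
    overall) give p = 1 by convention.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must be non-empty")
    nx, ny = x.size, y.size
    combined = np.concatenate([x, y])
    if np.all(combined == combined[0]):
        return (nx * ny / 2.0, 1.0)
    ranks = rankdata(combined)
    u_x = float(np.sum(ranks[:nx]) - nx * (nx + 1) / 2.0)
    u_y = nx * ny - u_x
    u = min(u_x, u_y)
    n = nx + ny
    has_ties = len(np.unique(combined)) < n
    if n <= exact_max_n and not has_ties:
        total = math.comb(n, nx)
        all_ranks = range(1, n + 1)
        extreme = 0
        hi = nx * ny - u
        for subset in combinations(all_ranks, nx):
            u_s = sum(subset) - nx * (nx + 1) / 2.0
            if u_s <= u or u_s >= hi:
                extreme += 1
        return (u, min(1.0, extreme / total))
    mu = nx * ny / 2.0
    var = nx * ny / 12.0 * ((n + 1) - _tie_term(combined) / (n * (n - 1)))
    if var <= 0:
        return (u, 1.0)
    z = (u - mu + 0.5) / math.sqrt(var)  # u <= mu, so z <= ~0
    return (u, min(1.0, 2.0 * float(norm_dist.cdf(z))))


def kruskal_wallis(groups: Sequence[Sequence[float]]) -> tuple[float, float]:
    """Kruskal–Wallis H with tie correction; p from chi-square, k-1 df."""
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if len(arrays) < 2 or any(a.size == 0 for a in arrays):
        raise ValueError("need >=2 non-empty groups")
    combined = np.concatenate(arrays)
    n = combined.size
    if np.all(combined == combined[0]):
        return (0.0, 1.0)
    ranks = rankdata(combined)
    h = 0.0
    start = 0
    for a in arrays:
        r_sum = float(np.sum(ranks[start : start + a.size]))
        h += r_sum**2 / a.size
        start += a.size
    h = 12.0 / (n * (n + 1)) * h - 3 * (n + 1)
    correction = 1.0 - _tie_term(combined) / (n**3 - n)
    if correction <= 0:
        return (0.0, 1.0)
    h /= correction
    return (h, float(chi2_dist.sf(h, len(arrays) - 1)))


def spearman_rho(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Spearman rank correlation (mid-ranks for ties) with t-approximation p.

    Raises if either variable is constant after ranking (rho undefined).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need >=3 paired observations")
    rx, ry = rankdata(x), rankdata(y)
    if np.ptp(rx) == 0 or np.ptp(ry) == 0:
        raise ValueError("rank correlation undefined: a variable is constant")
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    rho = float(np.sum(rx * ry) / math.sqrt(np.sum(rx**2) * np.sum(ry**2)))
    rho = max(-1.0, min(1.0, rho))
    n = x.size
    if abs(rho) == 1.0:
        return (rho, 0.0)
    t = rho * math.sqrt((n - 2) / (1 - rho**2))
    return (rho, 2.0 * float(t_dist.sf(abs(t), n - 2)))


def linear_regression(x: Sequence[float], y: Sequence[float]) -> tuple[float, float, float]:
    """Ordinary least squares y = a + b*x; returns (slope, intercept, p_slope).

    The slope p value is the two-sided t test with n-2 degrees of freedom.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need >=3 paired observations")
    sxx = float(np.sum((x - x.mean()) ** 2))
    if sxx == 0:
        raise ValueError("x is constant: slope undefined")
    slope = float(np.sum((x - x.mean()) * (y - y.mean())) / sxx)
    intercept = float(y.mean() - slope * x.mean())
    resid = y - (intercept + slope * x)
    n = x.size
    sse = float(np.sum(resid**2))
    if sse == 0:
        return (slope, intercept, 0.0)
    se = math.sqrt(sse / (n - 2) / sxx)
    t = slope / se
    return (slope, intercept, 2.0 * float(t_dist.sf(abs(t), n - 2)))


# ---------------------------------------------------------------------------
# Report assembly
# ---------------------------------------------------------------------------

def _bh_qvalues(pvals: Sequence[float]) -> list[float]:
    p = np.asarray(pvals, dtype=float)
    order = np.argsort(p)
    m = p.size
    q = np.empty(m)
    running = 1.0
    for rank_from_top, idx in enumerate(order[::-1]):
        i = m - rank_from_top  # 1-based rank of this p value
        running = min(running, p[idx] * m / i)
        q[idx] = running
    return q.tolist()


def association_report(
    matrix: CallMatrix,
    panel: Panel,
    clinical: pd.DataFrame,
    rules: Sequence[GroupingRule] | None = None,
    regions: Sequence[str] | None = None,
    alpha: float = 0.05,
    fdr: bool = False,
) -> pd.DataFrame:
    """Region x clinical-variable association battery.

    For every region and stratification rule, counts informative (I),
    no-loss (N) and LOH samples per stratum and tests the strata x LOH
    table with the exact test of :func:`fisher_exact` (Freeman–Halton for
    three or more strata). One p value per region x variable, repeated on
    each stratum row; ``significant`` flags p < ``alpha``. With ``fdr``
    a Benjamini–Hochberg q-value column is appended (off by default —
    the primary analysis reports unadjusted exact p values).
    """
    if rules is None:
        rules = default_rules()
    if regions is None:
        regions = panel.regions
    known = set(matrix.sample_ids)
    missing_ids = sorted(set(clinical["sample_id"].astype(str)) - known)
    if missing_ids:
        logger.info("%d clinical sample(s) absent from call matrix: %s", len(missing_ids), missing_ids)
    rows = []
    pvals = []
    for region in regions:
        region = canonical_region(region)
        for rule in rules:
            groups = dichotomize(clinical, rule)
            groups = {sid: g for sid, g in groups.items() if sid in known}
            table = loh_contingency(matrix, panel, region, groups, labels=rule.labels)
            p = fisher_exact(table.to_numpy())
            pvals.append(p)
            for lab in rule.labels:
                loh_n = int(table.loc[lab, "LOH"])
                ng_n = int(table.loc[lab, "NG"])
                rows.append(
                    {
                        "region": region,
                        "variable": rule.variable,
                        "stratum": lab,
                        "I": loh_n + ng_n,
                        "N": ng_n,
                        "LOH": loh_n,
                        "p": p,
                        "significant": p < alpha,
                    }
                )
    report = pd.DataFrame(rows)
    if fdr and not report.empty:
        # one q per region x variable, expanded to stratum rows
        qmap = dict(zip(range(len(pvals)), _bh_qvalues(pvals)))
        idx = 0
        q_col = []
        for region in regions:
            for rule in rules:
                q_col.extend([qmap[idx]] * len(rule.labels))
                idx += 1
        report["q"] = q_col
    return report


def fal_association(
    matrix: CallMatrix,
    clinical: pd.DataFrame,
    rules: Sequence[GroupingRule] | None = None,
) -> pd.DataFrame:
    """Compare FAL distributions across clinical strata.

    Two strata: Mann–Whitney U; three or more (with data): Kruskal–Wallis.
    Samples with undefined FAL (no informative locus) are excluded.
    """
    if rules is None:
        rules = default_rules()
    fal_by_sample = {}
    for sid in matrix.sample_ids:
        s = fal_index(matrix.sample_calls(sid))
        if s.fal is not None:
            fal_by_sample[sid] = s.fal
    rows = []
    for rule in rules:
        groups = dichotomize(clinical, rule)
        by_label = {
            lab: [fal_by_sample[sid] for sid, g in groups.items() if g == lab and sid in fal_by_sample]
            for lab in rule.labels
        }
        filled = [lab for lab in rule.labels if by_label[lab]]
        if len(filled) < 2:
            rows.append({"variable": rule.variable, "test": "none", "stat": math.nan, "p": math.nan})
            continue
        if len(filled) == 2:
            stat, p = mann_whitney_u(by_label[filled[0]], by_label[filled[1]])
            test = "mann-whitney"
        else:
            stat, p = kruskal_wallis([by_label[lab] for lab in filled])
            test = "kruskal-wallis"
        rows.append({"variable": rule.variable, "test": test, "stat": stat, "p": p})
    return pd.DataFrame(rows)
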