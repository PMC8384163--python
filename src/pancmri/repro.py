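"""Multisite reproducibility statistics.

Works on a long-format *measure table* — one record per (subject, site,
measure) with a numeric value or a missing marker — the in-memory form of a
traveling-subject study.  Provides accuracy vs reference (percent
difference), per-subject across-site coefficients of variation and their
unweighted average, Friedman's rank test across scanners with post-hoc
pairwise Wilcoxon rank-sum tests, and the inter-individual vs inter-assay
variance decomposition.

Conventions (all deliberate, all visible in the outputs):

* CV uses the n-1 sample standard deviation.
* Missing cells are dropped pairwise per statistic, never imputed; every
  statistic reports its effective n.
* Friedman requires complete blocks; subjects missing any site for a
  measure are excluded from that measure's test.
* The pairwise test is the unpaired rank-sum (exact distribution when both
  groups have <= 10 tie-free observations, else the normal approximation
  with tie correction); a paired signed-rank alternative is available via
  ``paired=True``.
* Post-hoc p-values are reported raw by default; ``holm=True`` applies the
  Holm step-down correction.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "load_measure_table",
    "load_volunteer_table",
    "load_phantom_table",
    "percent_difference",
    "coefficient_of_variation",
    "average_cv",
    "friedman_across_sites",
    "pairwise_rank_tests",
    "variance_components",
    "VarianceComponents",
    "FriedmanResult",
    "InsufficientDataError",
]

TABLE_COLUMNS = ("subject", "site", "measure", "value")


class InsufficientDataError(ValueError):
    """Too few non-missing observations for the requested statistic."""


def load_measure_table(path: str | Path) -> pd.DataFrame:
    """Read a long-format measure table CSV (subject, site, measure, value);
    empty value cells mean missing."""
    df = pd.read_csv(path, dtype={"subject": str, "site": str, "measure": str})
    missing_cols = [c for c in TABLE_COLUMNS if c not in df.columns]
    if missing_cols:
        raise ValueError(f"{path}: measure table lacks columns {missing_cols}")
    df["value"] = pd.to_numeric(df["value"], errors="coerce")
    dup = df.duplicated(subset=["subject", "site", "measure"])
    if dup.any():
        raise ValueError(f"{path}: duplicate (subject, site, measure) records")
    return df[list(TABLE_COLUMNS)]


def _packaged_csv(name: str) -> pd.DataFrame:
    with resources.as_file(resources.files("pancmri.data") / name) as p:
        return load_measure_table(p)


def load_volunteer_table() -> pd.DataFrame:
    """Packaged five-volunteer x four-site reproducibility table."""
    return _packaged_csv("multisite_volunteers.csv")


def load_phantom_table() -> tuple[pd.DataFrame, dict]:
    """Packaged five-site phantom table and its reference values.

    Returns (table, references) where the table uses the phantom id as the
    ``subject`` column and references maps measure -> reference value for
    the measures with calibrated standards (volume, four T1 vials).
    """
    table = _packaged_csv("multisite_phantom.csv")
    with resources.as_file(resources.files("pancmri.data") / "multisite_phantom_refs.csv") as p:
        refs_df = pd.read_csv(p)
    references = dict(zip(refs_df["measure"], refs_df["reference"].astype(float)))
    return table, references


def percent_difference(measured: float, reference: float) -> float:
    """|measured - reference| / reference x 100."""
    if reference <= 0:
        raise ValueError("reference value must be positive")
    return abs(measured - reference) / reference * 100.0


def coefficient_of_variation(values) -> float:
    """Sample SD (n-1) over non-missing values, divided by their mean, x 100."""
    v = np.asarray(pd.to_numeric(pd.Series(list(values)), errors="coerce"), dtype=float)
    v = v[np.isfinite(v)]
    if v.size < 2:
        raise InsufficientDataError(f"CV needs >= 2 non-missing values, got {v.size}")
    mean = v.mean()
    if mean == 0:
        raise InsufficientDataError("CV undefined for zero mean")
    return float(np.std(v, ddof=1) / mean * 100.0)


def _measure_pivot(table: pd.DataFrame, measure: str) -> pd.DataFrame:
    sub = table[table["measure"] == measure]
    if sub.empty:
        raise InsufficientDataError(f"no records for measure {measure!r}")
    return sub.pivot(index="subject", columns="site", values="value")


def average_cv(table: pd.DataFrame, measure: str, warnings: list | None = None) -> float:
    """Unweighted mean of per-subject across-site CVs for one measure.

    Subjects with fewer than two non-missing sites are excluded (recorded in
    ``warnings`` when a list is supplied); all excluded is an error.
    """
    pivot = _measure_pivot(table, measure)
    cvs = []
    for subject, row in pivot.iterrows():
        try:
            cvs.append(coefficient_of_variation(row.values))
        except InsufficientDataError:
            if warnings is not None:
                warnings.append(f"{measure}: subject {subject} excluded (<2 sites)")
    if not cvs:
        raise InsufficientDataError(f"{measure}: no subject has >= 2 non-missing sites")
    return float(np.mean(cvs))


@dataclass(frozen=True)
class FriedmanResult:
    statistic: float
    p_value: float
    n_complete_blocks: int
    n_sites: int


def friedman_across_sites(table: pd.DataFrame, measure: str) -> FriedmanResult:
    """Friedman chi-square on within-subject ranks across sites.

    Sites that never measured the assay are not part of the comparison and
    are dropped first; incomplete blocks (subjects missing any remaining
    site) are then dropped and counted.  Ties receive average ranks with the
    standard tie correction; a table in which every block is fully tied has
    no rank information and returns statistic 0, p = 1.
    """
    pivot = _measure_pivot(table, measure).dropna(axis=1, how="all").dropna(axis=0, how="any")
    n, k = pivot.shape
    if n < 2 or k < 2:
        raise InsufficientDataError(
            f"{measure}: Friedman needs >= 2 complete blocks over >= 2 sites (got {n}x{k})"
        )
    data = pivot.to_numpy()
    ranks = np.apply_along_axis(sps.rankdata, 1, data)
    rank_sums = ranks.sum(axis=0)
    chi2 = 12.0 / (n * k * (k + 1)) * np.sum(rank_sums**2) - 3.0 * n * (k + 1)
    # tie correction (Conover): divide by 1 - sum(t^3 - t) / (n k (k^2 - 1))
    tie_term = 0.0
    for row in data:
        _, counts = np.unique(row, return_counts=True)
        tie_term += float(np.sum(counts**3 - counts))
    denom = 1.0 - tie_term / (n * k * (k**2 - 1))
    if denom <= 0:  # every block fully tied: no evidence of a site effect
        return FriedmanResult(0.0, 1.0, n, k)
    chi2 /= denom
    p = float(sps.chi2.sf(chi2, k - 1))
    return FriedmanResult(float(chi2), p, n, k)


def _rank_sum_test(x: np.ndarray, y: np.ndarray, paired: bool) -> tuple[float, float]:
    if paired:
        d = x - y
        if np.all(d == 0):
            return 0.0, 1.0
        res = sps.wilcoxon(x, y, zero_method="wilcox", method="auto")
        return float(res.statistic), float(res.pvalue)
    if np.array_equal(np.sort(x), np.sort(y)) and np.unique(np.concatenate([x, y])).size == 1:
        # all observations identical: rank variance is zero
        return float(len(x) * len(y) / 2.0), 1.0
    has_ties = np.unique(np.concatenate([x, y])).size < len(x) + len(y)
    method = "exact" if (len(x) <= 10 and len(y) <= 10 and not has_ties) else "asymptotic"
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.statistic), float(min(res.pvalue, 1.0))


def pairwise_rank_tests(
    table: pd.DataFrame,
    measure: str,
    paired: bool = False,
    holm: bool = False,
) -> pd.DataFrame:
    """Post-hoc two-sided rank tests for every pair of sites.

    Returns a DataFrame with columns (site_a, site_b, statistic, p_value,
    n_a, n_b, note); pairs with fewer than two values per site are flagged
    in ``note`` and carry NaN statistics while other pairs are still
    computed.  ``paired=True`` switches to the signed-rank test on subjects
    observed at both sites.
    """
    pivot = _measure_pivot(table, measure)
    sites = list(pivot.columns)
    rows = []
    for a, b in itertools.combinations(sites, 2):
        if paired:
            both = pivot[[a, b]].dropna()
            x, y = both[a].to_numpy(), both[b].to_numpy()
            n_a = n_b = len(both)
        else:
            x = pivot[a].dropna().to_numpy()
            y = pivot[b].dropna().to_numpy()
            n_a, n_b = len(x), len(y)
        if min(n_a, n_b) < 2:
            rows.append(dict(site_a=a, site_b=b, statistic=np.nan, p_value=np.nan,
                             n_a=n_a, n_b=n_b, note="insufficient data"))
            continue
        stat, p = _rank_sum_test(x, y, paired)
        rows.append(dict(site_a=a, site_b=b, statistic=stat, p_value=p,
                         n_a=n_a, n_b=n_b, note=""))
    out = pd.DataFrame(rows)
    if holm:
        out["p_holm"] = _holm(out["p_value"].to_numpy())
    return out


def _holm(p: np.ndarray) -> np.ndarray:
    adj = np.full(p.shape, np.nan)
    ok = np.isfinite(p)
    ps = p[ok]
    order = np.argsort(ps)
    m = ps.size
    running = 0.0
    stepped = np.empty(m)
    for rank, idx in enumerate(order):
        running = max(running, (m - rank) * ps[idx])
        stepped[idx] = min(running, 1.0)
    adj[ok] = stepped
    return adj


@dataclass(frozen=True)
class VarianceComponents:
    """Inter-individual vs inter-assay decomposition for one measure."""

    measure: str
    grand_mean: float
    inter_individual_sd: float  # sample SD of per-subject means
    inter_assay_sd: float       # mean of per-subject across-site sample SDs
    n_subjects: int
    per_subject_mean: dict = field(default_factory=dict)
    per_subject_sd: dict = field(default_factory=dict)


def variance_components(table: pd.DataFrame, measure: str) -> VarianceComponents:
    """Mean/SD construction of between-subject vs within-subject spread.

    inter_assay_sd averages each subject's across-site sample SD;
    inter_individual_sd is the sample SD of subject means; the grand mean is
    the mean of subject means.  Subjects need >= 2 sites; >= 2 subjects are
    required overall.
    """
    pivot = _measure_pivot(table, measure)
    means, sds = {}, {}
    for subject, row in pivot.iterrows():
        vals = row.dropna().to_numpy()
        if vals.size < 2:
            continue
        means[subject] = float(vals.mean())
        sds[subject] = float(np.std(vals, ddof=1))
    if len(means) < 2:
        raise InsufficientDataError(
            f"{measure}: variance components need >= 2 subjects with >= 2 sites"
        )
    subject_means = np.array(list(means.values()))
    return VarianceComponents(
        measure=measure,
        grand_mean=float(subject_means.mean()),
        inter_individual_sd=float(np.std(subject_means, ddof=1)),
        inter_assay_sd=float(np.mean(list(sds.values()))),
        n_subjects=len(means),
        per_subject_mean=means,
        per_subject_sd=sds,
    )
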