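"""rRNA/rDNA relative-activity analysis.

The per-taxon ratio of rRNA-based to rDNA-based relative abundance is used as
a proxy for relative metabolic activity: in a log-log scatter of the two
abundances, points above the 1:1 line (ratio > 1, strictly) are classified
active. The ratio is regressed on rDNA abundance (both log10) by ordinary
least squares, pooling records across sampling events within a group; the
residuals of that fit are then attributed to environmental factors by simple
standardized regressions and by permutation importance around a random-forest
regressor.

Taxon/sample pairs where either abundance is zero are excluded from every
ratio computation (no pseudocounts by default; a pseudocount mode exists for
sensitivity analysis).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .io import EnvTable, RelAbundanceTable, SamplePair, ValidationError

logger = logging.getLogger("phycoactivity")

LINEAGE_RANKS = ("kingdom", "phylum", "class", "order", "family", "genus")


@dataclass(frozen=True)
class ActivityRecord:
    """One (taxon, paired sample) observation with both abundances positive."""

    taxon_id: str
    pair_key: str
    date: object
    condition: str
    rdna_prop: float
    rrna_prop: float

    def __post_init__(self) -> None:
        if self.rdna_prop <= 0 or self.rrna_prop <= 0:
            raise ValidationError(
                f"activity record requires positive proportions "
                f"(taxon {self.taxon_id}, pair {self.pair_key})"
            )

    @property
    def ratio(self) -> float:
        return self.rrna_prop / self.rdna_prop

    @property
    def log10_ratio(self) -> float:
        return math.log10(self.ratio)

    @property
    def log10_rdna(self) -> float:
        return math.log10(self.rdna_prop)

    @property
    def active(self) -> bool:
        return self.ratio > 1.0  # strictly above the 1:1 line


@dataclass(frozen=True)
class RegressionFit:
    """OLS fit of log10(rRNA/rDNA ratio) on log10(rDNA abundance)."""

    group: str
    slope: float
    intercept: float
    r2: float
    n: int
    residuals: np.ndarray
    records: tuple[ActivityRecord, ...]
    constant_response: bool = False


@dataclass(frozen=True)
class EnvAttribution:
    factor: str
    slope: float
    correlation: float
    p: float
    importance: float = float("nan")
    rank: int = 0


# ---------------------------------------------------------------------------
# record construction
# ---------------------------------------------------------------------------


def compute_activity(rdna: RelAbundanceTable, rrna: RelAbundanceTable,
                     pairs: Sequence[SamplePair],
                     pseudocount: float | None = None) -> list[ActivityRecord]:
    """Build activity records for every (taxon, pair) with both abundances > 0.

    ``pseudocount``, if given, is added to both proportions before the zero
    filter (sensitivity mode); by default zero pairs are simply excluded.
    """
    if list(rdna.taxon_ids) != list(rrna.taxon_ids):
        raise ValidationError("rDNA and rRNA tables must share the taxon axis")
    records: list[ActivityRecord] = []
    n_excluded = 0
    eps = pseudocount or 0.0
    for pair in pairs:
        a = rdna.data[pair.rdna_sample_id].to_numpy(float) + eps
        b = rrna.data[pair.rrna_sample_id].to_numpy(float) + eps
        keep = (a > 0) & (b > 0)
        n_excluded += int((~keep).sum())
        for i in np.flatnonzero(keep):
            records.append(ActivityRecord(
                taxon_id=rdna.taxon_ids[i],
                pair_key=pair.pair_key,
                date=pair.date,
                condition=pair.condition,
                rdna_prop=float(a[i]),
                rrna_prop=float(b[i]),
            ))
    logger.info("compute_activity: %d records kept, %d zero pairs excluded",
                len(records), n_excluded)
    return records


def records_to_frame(records: Sequence[ActivityRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "taxon_id": [r.taxon_id for r in records],
            "pair_key": [r.pair_key for r in records],
            "date": [r.date for r in records],
            "condition": [r.condition for r in records],
            "rdna_prop": [r.rdna_prop for r in records],
            "rrna_prop": [r.rrna_prop for r in records],
            "ratio": [r.ratio for r in records],
            "log10_ratio": [r.log10_ratio for r in records],
            "log10_rdna": [r.log10_rdna for r in records],
            "active": [r.active for r in records],
        }
    )


def split_host_nonhost(records: Sequence[ActivityRecord],
                       taxonomy: Mapping[str, str],
                       host_label: str) -> tuple[list[ActivityRecord], list[ActivityRecord]]:
    """Partition records into host (lineage contains ``host_label``) and the rest."""
    missing = sorted({r.taxon_id for r in records} - set(taxonomy))
    if missing:
        raise ValidationError(f"taxa missing from taxonomy: {missing}")
    host = [r for r in records if host_label in taxonomy[r.taxon_id]]
    nonhost = [r for r in records if host_label not in taxonomy[r.taxon_id]]
    return host, nonhost


# ---------------------------------------------------------------------------
# abundance-activity regression
# ---------------------------------------------------------------------------


def fit_abundance_activity(records: Sequence[ActivityRecord],
                           group: str = "all") -> RegressionFit:
    """OLS of log10(ratio) on log10(rDNA abundance), pooled over all records."""
    if len(records) < 10:
        raise ValidationError(f"regression needs >= 10 records, got {len(records)}")
    x = np.array([r.log10_rdna for r in records])
    y = np.array([r.log10_ratio for r in records])
    if np.ptp(x) == 0:
        raise ValidationError("zero variance in log10 rDNA abundance")
    if np.ptp(y) == 0:
        # constant response (e.g. every ratio exactly 1): slope 0 by convention
        return RegressionFit(group=group, slope=0.0, intercept=float(y[0]) if y[0] != 0 else 0.0,
                             r2=0.0, n=len(records), residuals=np.zeros(len(records)),
                             records=tuple(records), constant_response=True)
    model = sm.OLS(y, sm.add_constant(x)).fit()
    return RegressionFit(
        group=group,
        slope=float(model.params[1]),
        intercept=float(model.params[0]),
        r2=float(model.rsquared),
        n=len(records),
        residuals=np.asarray(model.resid),
        records=tuple(records),
    )


# ---------------------------------------------------------------------------
# environmental attribution of residuals
# ---------------------------------------------------------------------------


def _event_key(record: ActivityRecord, env: EnvTable) -> tuple:
    if "condition" in env.data.columns:
        return (str(record.date), record.condition)
    return (str(record.date),)


def _env_design(fit: RegressionFit, env: EnvTable) -> tuple[pd.DataFrame, np.ndarray, list[tuple]]:
    """Per-record factor matrix aligned with fit.residuals, plus event keys."""
    cache: dict[tuple, pd.Series] = {}
    rows = []
    keys = []
    for rec in fit.records:
        key = _event_key(rec, env)
        if key not in cache:
            cache[key] = env.lookup(*key)
        rows.append(cache[key])
        keys.append(key)
    design = pd.DataFrame(rows).reset_index(drop=True)
    return design, np.asarray(fit.residuals), keys


def residual_env_regression(fit: RegressionFit, env: EnvTable) -> list[EnvAttribution]:
    """Simple linear regression of fit residuals on each standardized factor.

    Residuals are first averaged per sampling event: environmental factors
    only vary at event resolution, and records within one sample share a
    compositional normalizer, so regressing thousands of per-record
    residuals would pseudo-replicate the sample-level signal and inflate
    significance. Factors are z-scored across events before fitting so
    slopes are comparable across units; constant factors are skipped with a
    warning.
    """
    design, resid, keys = _env_design(fit, env)
    frame = design.copy()
    frame["__resid__"] = resid
    frame["__event__"] = ["|".join(map(str, k)) for k in keys]
    events = frame.groupby("__event__", sort=False).mean(numeric_only=True)
    out: list[EnvAttribution] = []
    for factor in env.factors:
        vals = events[factor].to_numpy(float)
        if np.ptp(vals) == 0:
            logger.warning("factor %s constant across events; skipped", factor)
            continue
        z = (vals - vals.mean()) / vals.std(ddof=0)
        res = stats.linregress(z, events["__resid__"].to_numpy(float))
        out.append(EnvAttribution(
            factor=factor,
            slope=float(res.slope),
            correlation=float(res.rvalue),
            p=float(res.pvalue),
        ))
    return out


def rank_env_importance(fit: RegressionFit, env: EnvTable,
                        n_repeats: int = 30, seed: int | None = None,
                        n_estimators: int = 200) -> list[EnvAttribution]:
    """Permutation importance of environmental factors for the fit residuals.

    Residuals are averaged per sampling event (environmental factors only
    vary at event resolution) and a random-forest regressor is fitted to the
    event-level means; importance is the mean decrease in R^2 when one factor
    is permuted, over ``n_repeats`` shuffles. Significance per factor is a
    one-sided t test of the repeated importances against zero. Returns every
    factor with importance rank 1..n_factors (1 = most important).
    """
    from sklearn.ensemble import RandomForestRegressor
    from sklearn.inspection import permutation_importance

    design, resid, keys = _env_design(fit, env)
    factors = [f for f in env.factors if np.ptp(design[f].to_numpy(float)) > 0]
    if len(factors) < 2:
        raise ValidationError("permutation importance needs >= 2 varying factors")
    df = design[factors].copy()
    df["__event__"] = ["|".join(map(str, k)) for k in keys]
    df["__resid__"] = resid
    events = df.groupby("__event__", sort=False, as_index=False).mean(numeric_only=True)
    x = events[factors].to_numpy(float)
    y = events["__resid__"].to_numpy(float)
    if len(y) < len(factors) + 2:
        raise ValidationError(
            f"need more sampling events ({len(y)}) than factors + 2 ({len(factors) + 2})"
        )
    x = (x - x.mean(axis=0)) / x.std(axis=0, ddof=0)
    rng = np.random.default_rng(seed)
    rf_seed = int(rng.integers(2**31 - 1))
    pi_seed = int(rng.integers(2**31 - 1))
    forest = RandomForestRegressor(n_estimators=n_estimators, random_state=rf_seed)
    forest.fit(x, y)
    imp = permutation_importance(forest, x, y, n_repeats=n_repeats, random_state=pi_seed)
    order = np.argsort(imp.importances_mean)[::-1]
    ranks = np.empty(len(factors), dtype=int)
    ranks[order] = np.arange(1, len(factors) + 1)
    out = []
    simple = {a.factor: a for a in residual_env_regression(fit, env)}
    for i, factor in enumerate(factors):
        reps = imp.importances[i]
        if reps.std(ddof=1) > 0:
            t = stats.ttest_1samp(reps, 0.0, alternative="greater")
            p_imp = float(t.pvalue)
        else:
            p_imp = 1.0 if reps.mean() <= 0 else 0.0
        base = simple.get(factor)
        out.append(EnvAttribution(
            factor=factor,
            slope=base.slope if base else float("nan"),
            correlation=base.correlation if base else float("nan"),
            p=p_imp,
            importance=float(imp.importances_mean[i]),
            rank=int(ranks[i]),
        ))
    out.sort(key=lambda a: a.rank)
    return out


# ---------------------------------------------------------------------------
# taxon-group activity profiles
# ---------------------------------------------------------------------------


def lineage_rank(lineage: str, rank: str) -> str:
    """Extract one rank from a semicolon-separated lineage string."""
    parts = [p.strip() for p in lineage.split(";")]
    try:
        idx = LINEAGE_RANKS.index(rank)
    except ValueError as exc:
        raise ValueError(f"unknown rank {rank!r}; use one of {LINEAGE_RANKS}") from exc
    if idx >= len(parts):
        return "unclassified"
    return parts[idx] or "unclassified"


def taxon_activity_profile(records: Sequence[ActivityRecord],
                           taxonomy: Mapping[str, str],
                           rank: str = "order",
                           group_by: str = "date",
                           aggregation: str = "sum_ratio") -> pd.DataFrame:
    """Ratio distributions of taxon groups (e.g. orders) across dates/conditions.

    ``aggregation="sum_ratio"`` (default) first collapses each group within a
    sample pair to the ratio of summed proportions, then summarises those
    per-pair ratios; ``"mean_ratio"`` averages the per-taxon ratios instead.
    Returns one row per (group taxon, group_by value) with median and
    quartiles of the ratio plus the group's mean rDNA-based abundance.
    """
    if group_by not in ("date", "condition"):
        raise ValueError("group_by must be 'date' or 'condition'")
    if aggregation not in ("sum_ratio", "mean_ratio"):
        raise ValueError("aggregation must be 'sum_ratio' or 'mean_ratio'")
    frame = records_to_frame(records)
    if frame.empty:
        raise ValidationError("no activity records to profile")
    missing = sorted(set(frame["taxon_id"]) - set(taxonomy))
    if missing:
        raise ValidationError(f"taxa missing from taxonomy: {missing}")
    frame["group_taxon"] = [lineage_rank(taxonomy[t], rank) for t in frame["taxon_id"]]

    per_pair = (
        frame.groupby(["group_taxon", "pair_key", group_by], sort=False)
        .agg(rdna_sum=("rdna_prop", "sum"), rrna_sum=("rrna_prop", "sum"),
             mean_ratio=("ratio", "mean"), n_records=("ratio", "size"))
        .reset_index()
    )
    if aggregation == "sum_ratio":
        per_pair["group_ratio"] = per_pair["rrna_sum"] / per_pair["rdna_sum"]
    else:
        per_pair["group_ratio"] = per_pair["mean_ratio"]

    prof = (
        per_pair.groupby(["group_taxon", group_by], sort=False)
        .agg(
            ratio_median=("group_ratio", "median"),
            ratio_q1=("group_ratio", lambda v: float(np.quantile(v, 0.25))),
            ratio_q3=("group_ratio", lambda v: float(np.quantile(v, 0.75))),
            rdna_abundance_mean=("rdna_sum", "mean"),
            n_pairs=("group_ratio", "size"),
            n_records=("n_records", "sum"),
        )
        .reset_index()
    )
    return prof


def pair_group_ratios(records: Sequence[ActivityRecord],
                      taxonomy: Mapping[str, str], rank: str,
                      group_taxon: str,
                      aggregation: str = "sum_ratio") -> pd.DataFrame:
    """Per-pair ratios of one taxon group, for downstream paired tests.

    Returns columns pair_key, date, condition, group_ratio.
    """
    frame = records_to_frame(records)
    frame["group_taxon"] = [lineage_rank(taxonomy[t], rank) for t in frame["taxon_id"]]
    sub = frame[frame["group_taxon"] == group_taxon]
    if sub.empty:
        raise ValidationError(f"no records for group {group_taxon!r}")
    per_pair = (
        sub.groupby(["pair_key", "date", "condition"], sort=False)
        .agg(rdna_sum=("rdna_prop", "sum"), rrna_sum=("rrna_prop", "sum"),
             mean_ratio=("ratio", "mean"))
        .reset_index()
    )
    if aggregation == "sum_ratio":
        per_pair["group_ratio"] = per_pair["rrna_sum"] / per_pair["rdna_sum"]
    else:
        per_pair["group_ratio"] = per_pair["mean_ratio"]
    return per_pair[["pair_key", "date", "condition", "group_ratio"]]
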