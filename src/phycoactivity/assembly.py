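"""Phylogenetic null-model analysis of community assembly (betaMNTD / betaNTI).

betaMNTD is the abundance-weighted mean phylogenetic (patristic) distance
between each taxon in one community and its nearest relative in the other
community, averaged over both directions:

    betaMNTD(A, B) = 1/2 [ sum_i f_i(A) min_j d(i, j in B)
                         + sum_j f_j(B) min_i d(j, i in A) ]

with f the within-community relative abundances over taxa present in that
community; a taxon shared by both communities contributes a nearest-taxon
distance of zero. The null model shuffles taxon labels across all tips of
the (pruned) phylogeny — community structure (abundances and occupancy) is
preserved, phylogenetic positions are randomized — the "taxa labels" shuffle
of the Stegen/Picante approach. betaNTI is the standardized effect size of
the observed betaMNTD against 999 such randomizations; betaNTI < -2 infers
homogeneous selection, betaNTI > 2 heterogeneous selection, and values
between -2 and 2 a stochastic assembly process.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import CountTable, Phylogeny, ValidationError

logger = logging.getLogger("phycoactivity")

PROCESSES = ("homogeneous_selection", "stochastic", "heterogeneous_selection")


@dataclass(frozen=True)
class PhyloDistances:
    """Patristic (tip-to-tip path length) distances between taxa."""

    taxon_ids: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, float)
        object.__setattr__(self, "values", v)
        object.__setattr__(self, "taxon_ids", tuple(self.taxon_ids))
        if not np.allclose(v, v.T):
            raise ValidationError("patristic matrix must be symmetric")
        if not np.allclose(np.diag(v), 0):
            raise ValidationError("patristic matrix diagonal must be zero")

    def index_of(self, taxa) -> np.ndarray:
        pos = {t: i for i, t in enumerate(self.taxon_ids)}
        missing = [t for t in taxa if t not in pos]
        if missing:
            raise ValidationError(f"taxa not in distance matrix: {missing}")
        return np.array([pos[t] for t in taxa], dtype=int)


@dataclass(frozen=True)
class BNTIResult:
    sample_a: str
    sample_b: str
    observed_bmntd: float
    null_mean: float
    null_sd: float
    bnti: float            # NaN when the null distribution is degenerate
    process: str | None

    @staticmethod
    def classify(bnti: float) -> str | None:
        if np.isnan(bnti):
            return None
        if bnti < -2:
            return "homogeneous_selection"
        if bnti > 2:
            return "heterogeneous_selection"
        return "stochastic"


def patristic_distances(tree: Phylogeny, taxa=None) -> PhyloDistances:
    """Tip-to-tip path-length distances, optionally restricted to ``taxa``."""
    tip_names = [t.name for t in tree.tips()]
    if taxa is not None:
        missing = sorted(set(taxa) - set(tip_names))
        if missing:
            raise ValidationError(f"taxa missing from tree: {missing}")
    dm = tree.tip_tip_distances()
    order = list(dm.ids)
    if taxa is not None:
        idx = [order.index(t) for t in taxa]
        return PhyloDistances(tuple(taxa), dm.data[np.ix_(idx, idx)])
    return PhyloDistances(tuple(order), np.asarray(dm.data, float))


def beta_mntd(comm_a, comm_b, d: PhyloDistances) -> float:
    """Abundance-weighted beta mean nearest-taxon distance between two communities.

    ``comm_a``/``comm_b`` are mappings taxon -> abundance (or pandas Series);
    only taxa with positive abundance participate, and weights are
    renormalized within each community.
    """
    a = pd.Series(comm_a, dtype=float)
    b = pd.Series(comm_b, dtype=float)
    a, b = a[a > 0], b[b > 0]
    if a.empty or b.empty:
        raise ValidationError("betaMNTD requires non-empty communities")
    ia = d.index_of(a.index)
    ib = d.index_of(b.index)
    fa = a.to_numpy() / a.sum()
    fb = b.to_numpy() / b.sum()
    sub = d.values[np.ix_(ia, ib)]
    return 0.5 * (float(fa @ sub.min(axis=1)) + float(fb @ sub.min(axis=0)))


def _bmntd_from_indices(idx_a, fa, idx_b, fb, dist) -> float:
    sub = dist[np.ix_(idx_a, idx_b)]
    return 0.5 * (float(fa @ sub.min(axis=1)) + float(fb @ sub.min(axis=0)))


def bnti(table: CountTable, tree: Phylogeny, n_null: int = 999,
         seed: int | None = None, pairs=None,
         exclude_taxa=None) -> list[BNTIResult]:
    """betaNTI for sample pairs of a count table against the tip-shuffle null.

    The phylogeny is pruned to the taxa present (nonzero total) in the table;
    every such taxon must be a tip. ``pairs`` is an iterable of sample-id
    pairs; by default all within-table pairs are analysed.
    ``exclude_taxa`` removes taxa (e.g. host cyanobacterial ASVs) before the
    analysis, renormalizing the remaining community.
    """
    if n_null < 99:
        raise ValueError("n_null must be at least 99")
    if exclude_taxa:
        table = table.drop_taxa(exclude_taxa)
    totals = table.data.sum(axis=1)
    present = list(totals.index[totals > 0])
    if not present:
        raise ValidationError("no taxa with nonzero counts")
    tip_names = {t.name for t in tree.tips()}
    missing = sorted(set(present) - tip_names)
    if missing:
        raise ValidationError(f"taxa absent from the phylogeny: {missing}")
    pruned = tree.shear(present)
    d = patristic_distances(pruned, present)
    data = table.data.loc[present]

    if pairs is None:
        pairs = list(itertools.combinations(table.sample_ids, 2))

    # community index sets and weights in pruned-taxon coordinates
    comms: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for s in table.sample_ids:
        col = data[s].to_numpy(float)
        idx = np.flatnonzero(col > 0)
        if len(idx) == 0:
            continue
        comms[s] = (idx, col[idx] / col[idx].sum())

    usable = []
    for sa, sb in pairs:
        if sa not in comms or sb not in comms:
            logger.warning("pair (%s, %s) has an empty community; skipped", sa, sb)
            continue
        usable.append((sa, sb))

    dist = d.values
    n_taxa = len(present)
    observed = {
        (sa, sb): _bmntd_from_indices(*comms[sa], *comms[sb], dist)
        for sa, sb in usable
    }

    rng = np.random.default_rng(seed)
    nulls = {pair: np.empty(n_null) for pair in usable}
    for k in range(n_null):
        perm = rng.permutation(n_taxa)
        pdist = dist[np.ix_(perm, perm)]
        for pair in usable:
            (ia, fa), (ib, fb) = comms[pair[0]], comms[pair[1]]
            nulls[pair][k] = _bmntd_from_indices(ia, fa, ib, fb, pdist)

    results = []
    for sa, sb in usable:
        null = nulls[(sa, sb)]
        mu, sd = float(null.mean()), float(null.std(ddof=1))
        if sd == 0:
            logger.warning("degenerate null distribution for pair (%s, %s)", sa, sb)
            z = float("nan")
        else:
            z = (observed[(sa, sb)] - mu) / sd
        results.append(BNTIResult(
            sample_a=sa, sample_b=sb,
            observed_bmntd=observed[(sa, sb)],
            null_mean=mu, null_sd=sd, bnti=z,
            process=BNTIResult.classify(z),
        ))
    return results


def classify_processes(results, grouping=None) -> pd.DataFrame:
    """Fraction of sample pairs assigned to each assembly process.

    ``grouping`` maps either sample ids or (sample_a, sample_b) pairs to a
    group label (e.g. condition); pairs whose two samples map to different
    groups are labelled "mixed". Returns one row per group with per-process
    fractions summing to 1 over classified pairs.
    """
    results = list(results)
    if not results:
        raise ValidationError("no betaNTI results to classify")

    def group_of(r: BNTIResult) -> str:
        if grouping is None:
            return "all"
        if (r.sample_a, r.sample_b) in grouping:
            return str(grouping[(r.sample_a, r.sample_b)])
        ga, gb = grouping.get(r.sample_a), grouping.get(r.sample_b)
        if ga is None or gb is None:
            raise ValidationError(f"no group for pair ({r.sample_a}, {r.sample_b})")
        return str(ga) if ga == gb else "mixed"

    rows = []
    frame = pd.DataFrame({
        "group": [group_of(r) for r in results],
        "process": [r.process for r in results],
    })
    for group, sub in frame.groupby("group", sort=False):
        classified = sub.dropna(subset=["process"])
        n = len(classified)
        row = {"group": group, "n_pairs": n,
               "n_undefined": int(len(sub) - n)}
        for proc in PROCESSES:
            row[f"frac_{proc}"] = float((classified["process"] == proc).mean()) if n else float("nan")
        rows.append(row)
    return pd.DataFrame(rows)
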