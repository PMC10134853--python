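"""Synthetic paired rDNA/rRNA amplicon data with known ground truth.

The generator emulates the structures the analysis stages assume:

* a lognormal rank-abundance curve with smooth date-driven turnover, and a
  designated host clade (a single subtree, standing in for the bloom-forming
  cyanobacterium) receiving a fixed share of the abundance mass;
* a power-law (linear in log-log) relationship between the per-taxon
  rRNA/rDNA activity ratio and rDNA abundance, modulated by environmental
  covariates and lognormal noise:
  log10 ratio = alpha + beta * log10(abundance) + sum_f gamma_f z_f + eps;
* multinomial sequencing of both molecules at a fixed read depth, so zero
  inflation arises naturally from finite sampling rather than an explicit
  zero parameter;
* environmental covariates as seasonal sinusoids plus noise on realistic
  measurement scales (the generative model consumes their z-scores);
* Yule phylogenies with either trait-based (selection) or neutral community
  assembly for null-model testing.

Every artifact is a pure function of the configuration, including its seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io import (
    CONDITIONS,
    CountTable,
    EnvTable,
    Phylogeny,
    SampleMetadata,
    tree_from_newick,
)

HOST_LINEAGE = "Bacteria;Cyanobacteria;Cyanophyceae;Chroococcales;Microcystaceae;Microcystis"
_PHYCO_LINEAGES = (
    "Bacteria;Bacteroidota;Flavobacteriia;Flavobacteriales;Flavobacteriaceae;Flavobacterium",
    "Bacteria;Proteobacteria;Betaproteobacteria;Burkholderiales;Comamonadaceae;Hydrogenophaga",
    "Bacteria;Proteobacteria;Alphaproteobacteria;Sphingomonadales;Sphingomonadaceae;Sphingomonas",
    "Bacteria;Proteobacteria;Alphaproteobacteria;Rhodobacterales;Rhodobacteraceae;Rhodobacter",
    "Bacteria;Bacteroidota;Chitinophagia;Chitinophagales;Chitinophagaceae;Sediminibacterium",
    "Bacteria;Verrucomicrobiota;Verrucomicrobiae;Verrucomicrobiales;Rubritaleaceae;Luteolibacter",
)


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the paired-amplicon generative model."""

    n_taxa: int = 300
    n_dates: int = 17
    conditions: tuple[str, ...] = CONDITIONS
    depth: int = 21160                 # reads per library after rarefaction
    rank_meanlog: float = 0.0          # lognormal rank-abundance location
    rank_sdlog: float = 1.5            # lognormal rank-abundance spread
    turnover_sd: float = 1.0           # per-taxon seasonal loading spread
    activity_slope: float = -0.6       # beta: d log10(ratio) / d log10(abundance)
    activity_intercept: float = 0.0    # alpha
    env_effects: Mapping[str, float] = field(default_factory=dict)  # gamma per factor
    noise_sd: float = 0.3              # sigma of the log10-ratio noise
    host_fraction: float = 0.75        # abundance share of the host clade
    assembly_mode: str = "neutral"     # {selection, neutral}
    selection_strength: float = 0.2    # filter leakiness; smaller = stricter
    n_communities: int = 15            # assembly-scenario communities
    community_richness: int = 40       # taxa per assembly-scenario community
    community_evenness_sdlog: float = 0.3  # within-community lognormal spread (scenarios)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.depth <= 0:
            raise ValueError("depth must be positive")
        if self.n_taxa < 10:
            raise ValueError("n_taxa must be >= 10")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if not 0.0 <= self.host_fraction < 1.0:
            raise ValueError("host_fraction must lie in [0, 1)")
        if self.assembly_mode not in ("selection", "neutral"):
            raise ValueError(f"unknown assembly_mode {self.assembly_mode!r}")
        unknown = [c for c in self.conditions if c not in CONDITIONS]
        if unknown:
            raise ValueError(f"unknown conditions: {unknown}")


@dataclass(frozen=True)
class SimTruth:
    """Ground-truth parameters and latent states of a simulated dataset."""

    config: SimConfig
    host_taxa: tuple[str, ...] = ()
    taxonomy: Mapping[str, str] = field(default_factory=dict)
    true_log10_abund: pd.DataFrame | None = None   # taxa x pair events
    true_log10_ratio: pd.DataFrame | None = None   # taxa x pair events
    env_z: pd.DataFrame | None = None              # events x factors, standardized
    selected_clade: tuple[str, ...] = ()           # assembly scenarios

    def generative_r2(self, records=None) -> float:
        """Empirical R^2 of log10 ratio on log10 abundance in the latent model.

        With ``records`` (taxon_id/pair_key observations, e.g. the output of
        the activity computation) the latent values are restricted to those
        (taxon, sample-pair) cells, so the quantity is comparable to a fit on
        the same observations; otherwise the full latent grid is used.
        """
        if records is None:
            x = self.true_log10_abund.to_numpy().ravel()
            y = self.true_log10_ratio.to_numpy().ravel()
        else:
            x = np.array([self.true_log10_abund.at[r.taxon_id, r.pair_key] for r in records])
            y = np.array([self.true_log10_ratio.at[r.taxon_id, r.pair_key] for r in records])
        return float(np.corrcoef(x, y)[0, 1] ** 2)


# ---------------------------------------------------------------------------
# phylogeny
# ---------------------------------------------------------------------------


class _Node:
    __slots__ = ("children", "length", "birth", "name")

    def __init__(self, birth: float) -> None:
        self.children: list[_Node] = []
        self.length = 0.0
        self.birth = birth
        self.name = ""

    def newick(self) -> str:
        if not self.children:
            return f"{self.name}:{self.length:.10g}"
        inner = ",".join(c.newick() for c in self.children)
        return f"({inner}):{self.length:.10g}"


def simulate_tree(n_taxa: int, seed: int | np.random.SeedSequence) -> Phylogeny:
    """Yule (pure-birth) tree with exponential waiting times, tips ASV_0001..

    The process starts from a single lineage; with k extant lineages the next
    speciation waits an Exponential(k) time and splits a uniformly chosen
    lineage. Tip branches extend to the time of the (n+1)-th unrealized
    event, so the tree is ultrametric with strictly positive branch lengths.
    """
    if n_taxa < 3:
        raise ValueError("n_taxa must be >= 3")
    rng = np.random.default_rng(seed)
    t = 0.0
    root = _Node(0.0)
    active = [root]
    while len(active) < n_taxa:
        k = len(active)
        t += rng.exponential(1.0 / k)
        node = active.pop(rng.integers(k))
        node.length = t - node.birth
        children = [_Node(t), _Node(t)]
        node.children = children
        active.extend(children)
    t += rng.exponential(1.0 / n_taxa)
    for tip in active:
        tip.length = t - tip.birth
    # deterministic left-to-right tip labelling
    counter = [0]

    def label(node: _Node) -> None:
        if not node.children:
            counter[0] += 1
            node.name = f"ASV_{counter[0]:04d}"
        for c in node.children:
            label(c)

    label(root)
    newick = f"({','.join(c.newick() for c in root.children)});"
    return tree_from_newick(newick)


def _host_clade(tree: Phylogeny, target: int) -> tuple[str, ...]:
    """Tips of the internal clade whose size is closest to ``target``."""
    best, best_gap = None, None
    for node in tree.non_tips(include_self=False):
        tips = [t.name for t in node.tips()]
        gap = abs(len(tips) - target)
        if best_gap is None or gap < best_gap:
            best, best_gap = tips, gap
    return tuple(sorted(best))


def _most_isolated_clade(tree: Phylogeny, dmat: np.ndarray, taxa: Sequence[str],
                         lo: int, hi: int) -> tuple[str, ...]:
    """Clade of lo..hi tips maximizing (mean cross distance / mean within distance).

    This is the phylogenetically most coherent habitat-specialist pool the
    tree offers at that size, used as the target of the selection filter.
    """
    pos = {t: i for i, t in enumerate(taxa)}
    best, best_score = None, -np.inf
    for node in tree.non_tips(include_self=False):
        tips = [t.name for t in node.tips()]
        if not lo <= len(tips) <= hi:
            continue
        ci = np.array([pos[t] for t in tips])
        oi = np.setdiff1d(np.arange(len(taxa)), ci)
        within = dmat[np.ix_(ci, ci)][np.triu_indices(len(ci), 1)].mean()
        cross = dmat[np.ix_(ci, oi)].mean()
        if within > 0 and cross / within > best_score:
            best, best_score = tips, cross / within
    if best is None:
        raise ValueError(f"tree has no clade with {lo}..{hi} tips")
    return tuple(sorted(best))


# ---------------------------------------------------------------------------
# environmental covariates
# ---------------------------------------------------------------------------

# natural-scale factor models: (mean, seasonal amplitude, noise sd, per-condition offset)
_ENV_MODEL = {
    "WT":    (22.0, 6.0, 1.0, {"daytime": 1.0, "nighttime": -1.0, "anoxic": 0.0}),
    "pH":    (8.3, 0.4, 0.15, {"daytime": 0.3, "nighttime": -0.2, "anoxic": -0.4}),
    "Tur":   (40.0, 15.0, 6.0, {"daytime": 0.0, "nighttime": 0.0, "anoxic": 5.0}),
    "EC":    (320.0, 40.0, 15.0, {"daytime": 0.0, "nighttime": 0.0, "anoxic": 0.0}),
    "DO":    (8.0, 2.5, 1.0, {"daytime": 3.0, "nighttime": -2.0, "anoxic": -7.0}),
    "NO3_N": (0.6, 0.3, 0.08, {"daytime": 0.0, "nighttime": 0.05, "anoxic": -0.2}),
    "NO2_N": (0.06, 0.02, 0.01, {"daytime": 0.0, "nighttime": 0.0, "anoxic": 0.01}),
    "NH4_N": (0.4, 0.15, 0.06, {"daytime": -0.05, "nighttime": 0.05, "anoxic": 0.25}),
    "DIP":   (0.08, 0.03, 0.01, {"daytime": 0.0, "nighttime": 0.0, "anoxic": 0.02}),
}


def _simulate_env(dates: Sequence[str], conditions: Sequence[str],
                  rng: np.random.Generator) -> EnvTable:
    n = len(dates)
    phases = {f: rng.uniform(0, 2 * math.pi) for f in _ENV_MODEL}
    rows = []
    for si, date in enumerate(dates):
        season = 2 * math.pi * si / max(n - 1, 1)
        for cond in conditions:
            row = {"date": date, "condition": cond}
            for f, (mean, amp, sd, offsets) in _ENV_MODEL.items():
                val = mean + amp * math.sin(season + phases[f]) \
                    + offsets[cond] + rng.normal(0.0, sd)
                if f != "WT":
                    val = max(val, 0.01)  # concentrations / pH stay positive
                row[f] = val
            # DIN is the sum of the measured nitrogen species (real collinearity)
            row["DIN"] = row["NO3_N"] + row["NO2_N"] + row["NH4_N"]
            rows.append(row)
    return EnvTable(pd.DataFrame(rows))


def _standardize_env(env: EnvTable) -> pd.DataFrame:
    z = env.data[list(env.factors)].astype(float)
    z = (z - z.mean()) / z.std(ddof=0)
    keys = env.data["date"].astype(str) + "|" + env.data["condition"].astype(str)
    z.index = keys
    return z


# ---------------------------------------------------------------------------
# paired dataset
# ---------------------------------------------------------------------------


def _sample_dates(n_dates: int) -> list[str]:
    """Roughly fortnightly sampling dates spanning a May-November bloom season."""
    start = pd.Timestamp("2021-05-04")
    step = max(1, int(196 / max(n_dates - 1, 1)))
    return [(start + pd.Timedelta(days=step * i)).strftime("%Y-%m-%d")
            for i in range(n_dates)]


def simulate_paired_dataset(cfg: SimConfig) -> tuple[
        CountTable, CountTable, SampleMetadata, EnvTable, Phylogeny, SimTruth]:
    """Generate matched rDNA and rRNA count tables plus metadata, env, and tree."""
    ss = np.random.SeedSequence(cfg.seed)
    s_tree, s_abund, s_env, s_noise, s_counts = ss.spawn(5)

    tree = simulate_tree(cfg.n_taxa, s_tree)
    taxa = sorted(t.name for t in tree.tips())
    host_target = max(3, round(0.1 * cfg.n_taxa))
    host_taxa = _host_clade(tree, host_target) if cfg.host_fraction > 0 else ()
    is_host = np.array([t in set(host_taxa) for t in taxa])

    taxonomy = {}
    j = 0
    for t in taxa:
        if t in set(host_taxa):
            taxonomy[t] = HOST_LINEAGE
        else:
            taxonomy[t] = _PHYCO_LINEAGES[j % len(_PHYCO_LINEAGES)]
            j += 1

    rng_a = np.random.default_rng(s_abund)
    base = rng_a.normal(cfg.rank_meanlog, cfg.rank_sdlog, cfg.n_taxa)
    loading = rng_a.normal(0.0, cfg.turnover_sd, cfg.n_taxa)

    dates = _sample_dates(cfg.n_dates)
    env = _simulate_env(dates, cfg.conditions, np.random.default_rng(s_env))
    env_z = _standardize_env(env)
    unknown = set(cfg.env_effects) - set(env.factors)
    if unknown:
        raise ValueError(f"env_effects name unknown factors: {sorted(unknown)}")

    events = [(d, c) for d in dates for c in cfg.conditions]
    pair_keys = [f"d{di:02d}_{c}" for di, d in enumerate(dates) for c in cfg.conditions]

    rng_n = np.random.default_rng(s_noise)
    rng_c = np.random.default_rng(s_counts)

    abund = np.empty((cfg.n_taxa, len(events)))
    log_ratio = np.empty_like(abund)
    rdna_counts = np.empty((cfg.n_taxa, len(events)), dtype=np.int64)
    rrna_counts = np.empty_like(rdna_counts)

    for k, ((date, cond), pk) in enumerate(zip(events, pair_keys)):
        di = dates.index(date)
        season = math.sin(2 * math.pi * di / max(cfg.n_dates - 1, 1))
        log_a = base + loading * season
        w = np.exp(log_a)
        if cfg.host_fraction > 0 and is_host.any():
            a = np.empty(cfg.n_taxa)
            a[is_host] = cfg.host_fraction * w[is_host] / w[is_host].sum()
            a[~is_host] = (1 - cfg.host_fraction) * w[~is_host] / w[~is_host].sum()
        else:
            a = w / w.sum()
        env_term = sum(
            gamma * env_z.loc[f"{date}|{cond}", f]
            for f, gamma in cfg.env_effects.items()
        )
        # environmental modulation applies to the phycospheric (non-host)
        # community only: the host clade supplies the bulk of the rRNA pool,
        # so a host-independent effect remains identifiable after the
        # per-sample renormalization of sequencing proportions (an effect
        # shared by every taxon would cancel against the normalizer)
        eps = rng_n.normal(0.0, cfg.noise_sd, cfg.n_taxa)
        L = (cfg.activity_intercept + cfg.activity_slope * np.log10(a)
             + env_term * (~is_host) + eps)
        r = a * 10.0**L
        r /= r.sum()
        abund[:, k] = np.log10(a)
        log_ratio[:, k] = L
        rdna_counts[:, k] = rng_c.multinomial(cfg.depth, a)
        rrna_counts[:, k] = rng_c.multinomial(cfg.depth, r)

    rdna = CountTable(pd.DataFrame(rdna_counts, index=taxa,
                                   columns=[f"{pk}_rDNA" for pk in pair_keys]))
    rrna = CountTable(pd.DataFrame(rrna_counts, index=taxa,
                                   columns=[f"{pk}_rRNA" for pk in pair_keys]))

    meta_rows = []
    for (date, cond), pk in zip(events, pair_keys):
        for mol in ("rDNA", "rRNA"):
            meta_rows.append({
                "sample_id": f"{pk}_{mol}", "date": date, "condition": cond,
                "molecule": mol, "pair_key": pk,
            })
    meta = SampleMetadata(pd.DataFrame(meta_rows))

    truth = SimTruth(
        config=cfg,
        host_taxa=tuple(host_taxa),
        taxonomy=taxonomy,
        true_log10_abund=pd.DataFrame(abund, index=taxa, columns=pair_keys),
        true_log10_ratio=pd.DataFrame(log_ratio, index=taxa, columns=pair_keys),
        env_z=env_z,
    )
    return rdna, rrna, meta, env, tree, truth


# ---------------------------------------------------------------------------
# assembly scenarios
# ---------------------------------------------------------------------------


def simulate_assembly_scenario(mode: str, cfg: SimConfig) -> tuple[
        CountTable, Phylogeny, SimTruth]:
    """Communities assembled under clade-restricted selection or neutrally.

    Selection emulates consistent habitat filtering: one phylogenetically
    isolated clade (~20-40% of the taxon pool) is the shared species pool of
    every community; occupancy draws mostly from that clade, with a uniform
    immigration stream across the whole tree, and off-clade immigrants carry
    a strong abundance handicap so they stay rare. Because every community is
    filtered toward the same clade, pairwise phylogenetic turnover is far
    lower than the tip-shuffle null expects (homogeneous selection). Neutral:
    taxa are sampled uniformly at random with no handicap. Within-community
    abundances are lognormal in both modes; counts are multinomial at the
    configured depth.

    ``selection_strength`` sets the leakiness of the filter: the immigration
    share of occupancy draws is ``2 * selection_strength`` and the abundance
    handicap of off-clade taxa is ``selection_strength^2 / 40`` (defaults:
    0.4 and 1e-3 at selection_strength 0.2); 0 is a perfectly sealed clade.
    """
    if mode not in ("selection", "neutral"):
        raise ValueError(f"unknown mode {mode!r}")
    ss = np.random.SeedSequence(cfg.seed)
    s_tree, s_clade, s_comm = ss.spawn(3)
    tree = simulate_tree(cfg.n_taxa, s_tree)
    taxa = sorted(t.name for t in tree.tips())
    rng = np.random.default_rng(s_comm)

    n = len(taxa)
    clade: tuple[str, ...] = ()
    if mode == "selection":
        dmat = _patristic(tree, taxa)
        clade = _most_isolated_clade(tree, dmat, taxa,
                                     max(3, int(0.2 * n)), max(4, int(0.4 * n)))
        in_clade = np.isin(np.array(taxa), np.array(clade))
        imm = min(0.9, 2.0 * cfg.selection_strength)
        handicap_out = cfg.selection_strength**2 / 40.0
        pick = np.where(in_clade, 1.0, 0.0)
        pick = (1 - imm) * pick / pick.sum() + imm / n
        handicap = np.where(in_clade, 1.0, handicap_out)
    else:
        pick = np.full(n, 1.0 / n)
        handicap = np.ones(n)

    richness = min(cfg.community_richness, cfg.n_taxa)
    cols = {}
    for k in range(cfg.n_communities):
        chosen = rng.choice(n, size=richness, replace=False, p=pick)
        log_ab = rng.normal(0.0, cfg.community_evenness_sdlog, richness)
        p = np.exp(log_ab) * handicap[chosen]
        p /= p.sum()
        counts = np.zeros(n, dtype=np.int64)
        counts[chosen] = rng.multinomial(cfg.depth, p)
        cols[f"comm_{k:02d}"] = counts
    table = CountTable(pd.DataFrame(cols, index=taxa))
    truth = SimTruth(config=cfg, selected_clade=clade)
    return table, tree, truth


def _patristic(tree: Phylogeny, taxa: Sequence[str]) -> np.ndarray:
    dm = tree.tip_tip_distances()
    order = list(dm.ids)
    idx = [order.index(t) for t in taxa]
    return np.asarray(dm.data, float)[np.ix_(idx, idx)]
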