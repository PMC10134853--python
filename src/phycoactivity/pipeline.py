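"""End-to-end orchestration: ingest -> diversity -> activity -> association -> assembly.

A run is driven by a single :class:`RunConfig` (loadable from YAML). Every
stage writes TSV outputs into the run directory and appends to a JSON-lines
event log; a manifest records package version, seeds, and a parameter hash so
a rerun with the identical config reproduces identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import sys
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .activity import (
    compute_activity,
    fit_abundance_activity,
    rank_env_importance,
    records_to_frame,
    residual_env_regression,
    split_host_nonhost,
)
from .assembly import bnti, classify_processes
from .association import mantel, mrpp
from .diversity import DistanceMatrix, alpha_diversity_table, bray_curtis, pcoa
from .io import (
    CountTable,
    ValidationError,
    pair_samples,
    rarefy,
    read_count_table,
    read_env_table,
    read_metadata,
    read_tree,
    relative_abundance,
    write_count_table,
)

logger = logging.getLogger("phycoactivity")

STAGES = ("ingest", "diversity", "activity", "association", "assembly")


@dataclass
class RunConfig:
    rdna_counts: str = ""
    rrna_counts: str = ""
    tree: str = ""
    metadata: str = ""
    env: str = ""
    taxonomy: str = ""            # optional TSV: taxon_id <tab> lineage
    host_label: str = "Microcystis"
    rarefy_depth: int = 21160
    seed: int = 17
    n_perm: int = 999
    n_null: int = 999
    group_by: str = "condition"
    stages: tuple[str, ...] = STAGES
    out_dir: str = "phycoactivity_run"

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        if "stages" in raw:
            raw["stages"] = tuple(raw["stages"])
        return cls(**raw)

    def validate(self) -> None:
        required = {"rdna_counts": self.rdna_counts, "rrna_counts": self.rrna_counts,
                    "metadata": self.metadata}
        if "assembly" in self.stages:
            required["tree"] = self.tree
        if "activity" in self.stages:
            required["env"] = self.env
        for name, path in required.items():
            if not path:
                raise ValidationError(f"config field {name!r} is required for the enabled stages")
            if not Path(path).exists():
                raise ValidationError(f"{name} path does not exist: {path}")
        bad = [s for s in self.stages if s not in STAGES]
        if bad:
            raise ValidationError(f"unknown stages: {bad}")

    def param_hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


class _EventLog:
    def __init__(self, path: Path) -> None:
        self.path = path
        self.path.write_text("")

    def emit(self, event: str, **fields) -> None:
        rec = {"event": event, "time": time.strftime("%Y-%m-%dT%H:%M:%S"), **fields}
        with open(self.path, "a") as fh:
            fh.write(json.dumps(rec, default=str) + "\n")
        logger.info("%s %s", event, fields if fields else "")


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute the configured stages in order; returns the run manifest."""
    cfg.validate()
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log = _EventLog(out / "events.jsonl")
    manifest = {
        "version": __version__,
        "param_hash": cfg.param_hash(),
        "config": dataclasses.asdict(cfg),
        "stages": {},
    }
    state: dict = {}
    try:
        for stage in cfg.stages:
            log.emit("stage_start", stage=stage)
            t0 = time.time()
            _STAGE_FUNCS[stage](cfg, state, out, log)
            manifest["stages"][stage] = {"status": "complete",
                                         "seconds": round(time.time() - t0, 2)}
            log.emit("stage_complete", stage=stage)
    except Exception as exc:
        manifest["stages"][stage] = {"status": "failed", "error": str(exc)}
        (out / "FAILED").write_text(f"{stage}: {exc}\n")
        _write_manifest(manifest, out)
        raise
    _write_manifest(manifest, out)
    log.emit("run_complete", param_hash=manifest["param_hash"])
    return manifest


def _write_manifest(manifest: dict, out: Path) -> None:
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str, sort_keys=True)


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------


def _stage_ingest(cfg: RunConfig, state: dict, out: Path, log: _EventLog) -> None:
    rdna = read_count_table(cfg.rdna_counts, _fmt(cfg.rdna_counts))
    rrna = read_count_table(cfg.rrna_counts, _fmt(cfg.rrna_counts))
    meta = read_metadata(cfg.metadata)
    state["meta"] = meta
    state["rdna"] = rarefy(rdna, cfg.rarefy_depth, cfg.seed)
    state["rrna"] = rarefy(rrna, cfg.rarefy_depth, cfg.seed + 1)
    pairs = [
        p for p in pair_samples(meta)
        if p.rdna_sample_id in state["rdna"].sample_ids
        and p.rrna_sample_id in state["rrna"].sample_ids
    ]
    if not pairs:
        raise ValidationError("no complete rDNA/rRNA pairs survive rarefaction")
    state["pairs"] = pairs
    if cfg.env:
        state["env"] = read_env_table(cfg.env)
    if cfg.tree:
        state["tree"] = read_tree(cfg.tree)
    if cfg.taxonomy:
        tax = pd.read_csv(cfg.taxonomy, sep="\t", header=None,
                          names=["taxon_id", "lineage"], dtype=str)
        state["taxonomy"] = dict(zip(tax["taxon_id"], tax["lineage"]))
    write_count_table(state["rdna"], out / "rdna_rarefied.tsv")
    write_count_table(state["rrna"], out / "rrna_rarefied.tsv")
    log.emit("ingest_summary", n_pairs=len(pairs),
             rdna_samples=len(state["rdna"].sample_ids),
             rrna_samples=len(state["rrna"].sample_ids))


def _paired_bc(state: dict, molecule: str) -> DistanceMatrix:
    """Bray-Curtis between paired samples of one molecule, labelled by pair key."""
    table: CountTable = state[molecule.lower()]
    ids = [getattr(p, f"{molecule.lower()}_sample_id") for p in state["pairs"]]
    sub = table.select_samples(ids)
    renamed = sub.data.set_axis([p.pair_key for p in state["pairs"]], axis=1)
    return bray_curtis(CountTable(renamed))


def _stage_diversity(cfg: RunConfig, state: dict, out: Path, log: _EventLog) -> None:
    for molecule in ("rdna", "rrna"):
        table = state[molecule]
        alpha = alpha_diversity_table(table)
        alpha.to_csv(out / f"alpha_{molecule}.tsv", sep="\t")
        dm = bray_curtis(table)
        dm.to_frame().to_csv(out / f"braycurtis_{molecule}.tsv", sep="\t")
        state[f"bc_{molecule}"] = dm
        ord_ = pcoa(dm)
        ord_.coordinates.to_csv(out / f"pcoa_{molecule}.tsv", sep="\t")
        with open(out / f"pcoa_{molecule}_eigen.tsv", "w") as fh:
            fh.write("axis\teigenvalue\tproportion\n")
            for i, prop in enumerate(ord_.proportion_explained):
                fh.write(f"PCo{i + 1}\t{ord_.eigenvalues[i]:.6g}\t{prop:.6g}\n")
        log.emit("diversity_summary", molecule=molecule,
                 pcoa1_proportion=float(ord_.proportion_explained[0]))


def _stage_activity(cfg: RunConfig, state: dict, out: Path, log: _EventLog) -> None:
    rdna_rel = relative_abundance(state["rdna"])
    rrna_rel = relative_abundance(state["rrna"])
    records = compute_activity(rdna_rel, rrna_rel, state["pairs"])
    state["records"] = records
    records_to_frame(records).to_csv(out / "activity_records.tsv", sep="\t", index=False)

    groups = {"all": records}
    if "taxonomy" in state:
        host, nonhost = split_host_nonhost(records, state["taxonomy"], cfg.host_label)
        groups = {cfg.host_label: host, f"non-{cfg.host_label}": nonhost}

    fit_rows, env_rows = [], []
    for name, recs in groups.items():
        if len(recs) < 10:
            log.emit("activity_group_skipped", group=name, n=len(recs))
            continue
        fit = fit_abundance_activity(recs, group=name)
        state[f"fit_{name}"] = fit
        fit_rows.append({"group": name, "slope": fit.slope, "intercept": fit.intercept,
                         "r2": fit.r2, "n": fit.n})
        if "env" in state:
            for att in residual_env_regression(fit, state["env"]):
                env_rows.append({"group": name, "test": "regression", "factor": att.factor,
                                 "slope": att.slope, "r": att.correlation, "p": att.p,
                                 "importance": "", "rank": ""})
            for att in rank_env_importance(fit, state["env"], seed=cfg.seed):
                env_rows.append({"group": name, "test": "importance", "factor": att.factor,
                                 "slope": att.slope, "r": att.correlation, "p": att.p,
                                 "importance": att.importance, "rank": att.rank})
    pd.DataFrame(fit_rows).to_csv(out / "activity_fits.tsv", sep="\t", index=False)
    if env_rows:
        pd.DataFrame(env_rows).to_csv(out / "env_attribution.tsv", sep="\t", index=False)
    log.emit("activity_summary", n_records=len(records),
             groups={r["group"]: r["r2"] for r in fit_rows})


def _stage_association(cfg: RunConfig, state: dict, out: Path, log: _EventLog) -> None:
    rows = []
    bc_rdna = _paired_bc(state, "rdna")
    bc_rrna = _paired_bc(state, "rrna")
    res = mantel(bc_rdna, bc_rrna, n_perm=cfg.n_perm, seed=cfg.seed)
    rows.append({"test": "mantel_rdna_vs_rrna", "statistic": res.r, "p": res.p,
                 "n_perm": res.n_perm, "seed": cfg.seed})
    meta = {p.pair_key: p for p in state["pairs"]}
    conditions = [meta[k].condition for k in bc_rdna.sample_ids]
    dates = [str(meta[k].date) for k in bc_rdna.sample_ids]
    if len(set(conditions)) > 1:
        res = mrpp(bc_rdna, conditions, strata=dates, n_perm=cfg.n_perm, seed=cfg.seed)
        rows.append({"test": "mrpp_condition_strata_date", "statistic": res.statistic,
                     "p": res.p, "n_perm": cfg.n_perm, "seed": cfg.seed,
                     "A": res.extra["A"]})
    pd.DataFrame(rows).to_csv(out / "association_tests.tsv", sep="\t", index=False)
    log.emit("association_summary", tests=len(rows))


def _stage_assembly(cfg: RunConfig, state: dict, out: Path, log: _EventLog) -> None:
    table: CountTable = state["rdna"]
    results = bnti(table, state["tree"], n_null=cfg.n_null, seed=cfg.seed)
    per_pair = pd.DataFrame([
        {"sample_a": r.sample_a, "sample_b": r.sample_b,
         "obs_bmntd": r.observed_bmntd, "null_mean": r.null_mean,
         "null_sd": r.null_sd, "bnti": r.bnti, "process": r.process}
        for r in results
    ])
    per_pair.to_csv(out / "bnti_pairs.tsv", sep="\t", index=False)
    meta = state["meta"]
    grouping = None
    if cfg.group_by in meta.data.columns:
        grouping = dict(zip(meta.data["sample_id"], meta.data[cfg.group_by].astype(str)))
    summary = classify_processes(results, grouping)
    summary.to_csv(out / "assembly_summary.tsv", sep="\t", index=False)
    log.emit("assembly_summary", n_pairs=len(per_pair))


def _fmt(path) -> str:
    return "biom" if str(path).endswith(".biom") else "tsv"


_STAGE_FUNCS = {
    "ingest": _stage_ingest,
    "diversity": _stage_diversity,
    "activity": _stage_activity,
    "association": _stage_association,
    "assembly": _stage_assembly,
}


def configure_logging(verbose: bool = True) -> None:
    handler = logging.StreamHandler(sys.stderr)
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.handlers.clear()
    logger.addHandler(handler)
    logger.setLevel(logging.INFO if verbose else logging.WARNING)
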