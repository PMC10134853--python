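"""Ingest, validation, pairing, rarefaction, and normalisation of amplicon data.

Everything downstream (diversity, activity ratios, null models) consumes the
containers defined here: integer ASV count tables (taxa x samples), per-sample
relative-abundance tables, sample metadata describing the paired rDNA/rRNA
library design, per-sampling-event environmental measurements, and a rooted
phylogeny with branch lengths.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Literal, NamedTuple, Sequence

import h5py
import numpy as np
import pandas as pd
from skbio import TreeNode

logger = logging.getLogger("phycoactivity")

CONDITIONS = ("daytime", "nighttime", "anoxic")
MOLECULES = ("rDNA", "rRNA")
ENV_FACTORS = ("WT", "pH", "Tur", "EC", "DO", "NO3_N", "NO2_N", "NH4_N", "DIN", "DIP")


class FormatError(ValueError):
    """A file does not conform to the expected dialect."""


class ValidationError(ValueError):
    """Data violate a container invariant."""


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------


def _check_axes(index: pd.Index, columns: pd.Index) -> None:
    if len(index) == 0 or len(columns) == 0:
        raise ValidationError("table must have at least one taxon and one sample")
    if index.has_duplicates:
        dups = index[index.duplicated()].unique().tolist()
        raise ValidationError(f"duplicate taxon ids: {dups}")
    if columns.has_duplicates:
        dups = columns[columns.duplicated()].unique().tolist()
        raise ValidationError(f"duplicate sample ids: {dups}")


@dataclass(frozen=True)
class CountTable:
    """Integer ASV counts, taxa (rows) x samples (columns)."""

    data: pd.DataFrame

    def __post_init__(self) -> None:
        _check_axes(self.data.index, self.data.columns)
        values = self.data.to_numpy()
        if not np.issubdtype(values.dtype, np.integer):
            if not np.all(np.equal(np.mod(values, 1), 0)):
                raise ValidationError("counts must be integers")
            object.__setattr__(self, "data", self.data.astype(np.int64))
            values = self.data.to_numpy()
        if (values < 0).any():
            r, c = np.argwhere(values < 0)[0]
            raise ValidationError(
                f"negative count at taxon {self.data.index[r]!r}, "
                f"sample {self.data.columns[c]!r}"
            )

    @property
    def taxon_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def counts(self) -> np.ndarray:
        return self.data.to_numpy()

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def sample_sums(self) -> pd.Series:
        return self.data.sum(axis=0)

    def select_samples(self, sample_ids: Sequence[str]) -> "CountTable":
        missing = [s for s in sample_ids if s not in self.data.columns]
        if missing:
            raise ValidationError(f"unknown sample ids: {missing}")
        return CountTable(self.data.loc[:, list(sample_ids)])

    def drop_taxa(self, taxon_ids: Iterable[str]) -> "CountTable":
        keep = self.data.index.difference(pd.Index(taxon_ids), sort=False)
        return CountTable(self.data.loc[keep])


@dataclass(frozen=True)
class RelAbundanceTable:
    """Per-sample relative abundances; every column sums to 1."""

    data: pd.DataFrame

    def __post_init__(self) -> None:
        _check_axes(self.data.index, self.data.columns)
        sums = self.data.sum(axis=0)
        bad = sums[(sums - 1.0).abs() > 1e-9]
        if len(bad):
            raise ValidationError(
                f"sample columns do not sum to 1: {list(bad.index)}"
            )

    @property
    def taxon_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)


@dataclass(frozen=True)
class SampleMetadata:
    """One row per sequencing library of the paired rDNA/rRNA design.

    Columns: sample_id, date, condition in {daytime, nighttime, anoxic},
    molecule in {rDNA, rRNA}, pair_key linking the two libraries of one
    physical sample.
    """

    data: pd.DataFrame

    REQUIRED = ("sample_id", "date", "condition", "molecule", "pair_key")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.data.columns]
        if missing:
            raise ValidationError(f"metadata missing columns: {missing}")
        if self.data["sample_id"].duplicated().any():
            dups = self.data.loc[self.data["sample_id"].duplicated(), "sample_id"]
            raise ValidationError(f"duplicate sample ids in metadata: {list(dups)}")
        bad_cond = set(self.data["condition"]) - set(CONDITIONS)
        if bad_cond:
            raise ValidationError(f"unknown conditions: {sorted(bad_cond)}")
        bad_mol = set(self.data["molecule"]) - set(MOLECULES)
        if bad_mol:
            raise ValidationError(f"unknown molecules: {sorted(bad_mol)}")
        if self.data.duplicated(subset=["pair_key", "molecule"]).any():
            dups = self.data.loc[
                self.data.duplicated(subset=["pair_key", "molecule"]), "pair_key"
            ]
            raise ValidationError(
                f"duplicate (pair_key, molecule) combinations: {sorted(set(dups))}"
            )

    def row_for(self, sample_id: str) -> pd.Series:
        rows = self.data[self.data["sample_id"] == sample_id]
        if rows.empty:
            raise ValidationError(f"sample id {sample_id!r} not in metadata")
        return rows.iloc[0]


@dataclass(frozen=True)
class EnvTable:
    """Environmental measurements, one row per sampling event.

    Indexed by (date, condition) when a `condition` column is present,
    otherwise by date alone. Factors: WT, pH, Tur, EC, DO and dissolved
    nitrogen/phosphorus species.
    """

    data: pd.DataFrame
    factors: tuple[str, ...] = field(default=ENV_FACTORS)

    def __post_init__(self) -> None:
        if "date" not in self.data.columns:
            raise ValidationError("environmental table requires a 'date' column")
        present = [f for f in self.factors if f in self.data.columns]
        if not present:
            raise ValidationError(
                f"no recognised environmental factors among {list(self.data.columns)}"
            )
        object.__setattr__(self, "factors", tuple(present))
        if "pH" in self.data.columns:
            ph = self.data["pH"].to_numpy(float)
            if ((ph <= 0) | (ph >= 14)).any():
                raise ValidationError("pH values must lie in (0, 14)")
        conc = [f for f in present if f not in ("pH", "WT")]
        for f in conc:
            if (self.data[f].to_numpy(float) < 0).any():
                raise ValidationError(f"negative values in factor {f!r}")
        keys = ["date"] + (["condition"] if "condition" in self.data.columns else [])
        if self.data.duplicated(subset=keys).any():
            raise ValidationError("duplicate environmental rows for a sampling event")

    def lookup(self, date, condition: str | None = None) -> pd.Series:
        """Return the factor vector for one sampling event."""
        sub = self.data[self.data["date"].astype(str) == str(date)]
        if condition is not None and "condition" in self.data.columns:
            sub = sub[sub["condition"] == condition]
        if sub.empty:
            raise ValidationError(f"no environmental row for date {date!r}")
        return sub.iloc[0][list(self.factors)].astype(float)


Phylogeny = TreeNode  # rooted tree with branch lengths; alias for clarity


class SamplePair(NamedTuple):
    rdna_sample_id: str
    rrna_sample_id: str
    date: object
    condition: str
    pair_key: str


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

_BIOM_ATTRS = {
    "id": "No Table ID",
    "type": "OTU table",
    "format-url": "http://biom-format.org",
    "generated-by": "phycoactivity",
    "creation-date": "",
}


def read_count_table(path, format: Literal["tsv", "biom"] = "tsv") -> CountTable:
    """Read an ASV count table.

    TSV dialect: tab separated, first column taxon ids (a leading
    "#OTU ID"-style header cell is accepted), remaining columns samples,
    integer cells. BIOM: the HDF5-based 2.1 layout.
    """
    if format == "tsv":
        df = pd.read_csv(path, sep="\t", index_col=0, comment=None, dtype=str)
        df.index = df.index.astype(str)
        df.index.name = None  # "#OTU ID"-style header cell accepted, not kept
        try:
            numeric = df.apply(pd.to_numeric)
        except ValueError as exc:
            raise FormatError(f"non-numeric cell in {path}: {exc}") from exc
        arr = numeric.to_numpy()
        frac = np.mod(arr, 1) != 0
        if frac.any():
            r, c = np.argwhere(frac)[0]
            raise FormatError(
                f"non-integer cell at taxon {numeric.index[r]!r}, "
                f"sample {numeric.columns[c]!r} in {path}"
            )
        neg = arr < 0
        if neg.any():
            r, c = np.argwhere(neg)[0]
            raise FormatError(
                f"negative cell at taxon {numeric.index[r]!r}, "
                f"sample {numeric.columns[c]!r} in {path}"
            )
        return CountTable(numeric.astype(np.int64))
    if format == "biom":
        return _read_biom(path)
    raise ValueError(f"unknown format {format!r}")


def write_count_table(table: CountTable, path, format: Literal["tsv", "biom"] = "tsv") -> None:
    if format == "tsv":
        table.data.rename_axis("#OTU ID").to_csv(path, sep="\t")
    elif format == "biom":
        _write_biom(table, path)
    else:
        raise ValueError(f"unknown format {format!r}")


def _write_biom(table: CountTable, path) -> None:
    """Write the BIOM 2.1 HDF5 layout (CSR in observation/, CSC in sample/)."""
    from scipy import sparse

    mat = sparse.csr_matrix(table.counts.astype(float))
    csc = mat.tocsc()
    with h5py.File(path, "w") as h5:
        for k, v in _BIOM_ATTRS.items():
            h5.attrs[k] = v
        h5.attrs["format-version"] = [2, 1]
        h5.attrs["shape"] = list(table.shape)
        h5.attrs["nnz"] = int(mat.nnz)
        obs = h5.create_group("observation")
        obs.create_dataset(
            "ids", data=np.array(table.taxon_ids, dtype=h5py.string_dtype())
        )
        omat = obs.create_group("matrix")
        omat.create_dataset("data", data=mat.data)
        omat.create_dataset("indices", data=mat.indices.astype(np.int64))
        omat.create_dataset("indptr", data=mat.indptr.astype(np.int64))
        obs.create_group("metadata")
        obs.create_group("group-metadata")
        smp = h5.create_group("sample")
        smp.create_dataset(
            "ids", data=np.array(table.sample_ids, dtype=h5py.string_dtype())
        )
        smat = smp.create_group("matrix")
        smat.create_dataset("data", data=csc.data)
        smat.create_dataset("indices", data=csc.indices.astype(np.int64))
        smat.create_dataset("indptr", data=csc.indptr.astype(np.int64))
        smp.create_group("metadata")
        smp.create_group("group-metadata")


def _read_biom(path) -> CountTable:
    from scipy import sparse

    with h5py.File(path, "r") as h5:
        try:
            taxa = [t.decode() if isinstance(t, bytes) else str(t) for t in h5["observation/ids"][:]]
            samples = [s.decode() if isinstance(s, bytes) else str(s) for s in h5["sample/ids"][:]]
            g = h5["observation/matrix"]
            mat = sparse.csr_matrix(
                (g["data"][:], g["indices"][:], g["indptr"][:]),
                shape=(len(taxa), len(samples)),
            )
        except KeyError as exc:
            raise FormatError(f"{path} is not a BIOM 2.1 file: missing {exc}") from exc
    dense = np.asarray(mat.todense())
    return CountTable(pd.DataFrame(dense, index=taxa, columns=samples).astype(np.int64))


def read_tree(path) -> Phylogeny:
    """Read a rooted Newick phylogeny; every tip must carry a branch length."""
    try:
        tree = TreeNode.read(str(path), format="newick", convert_underscores=False)
    except Exception as exc:  # skbio raises its own parse error hierarchy
        raise FormatError(f"cannot parse Newick file {path}: {exc}") from exc
    return _validate_tree(tree)


def tree_from_newick(newick: str) -> Phylogeny:
    """Parse a Newick string (convenience; same validation as :func:`read_tree`)."""
    import io as _io

    try:
        tree = TreeNode.read(_io.StringIO(newick), format="newick",
                             convert_underscores=False)
    except Exception as exc:
        raise FormatError(f"cannot parse Newick string: {exc}") from exc
    return _validate_tree(tree)


def _validate_tree(tree: TreeNode) -> TreeNode:
    tips = list(tree.tips())
    names = [t.name for t in tips]
    if len(set(names)) != len(names):
        raise ValidationError("duplicate tip labels in tree")
    for node in tree.traverse(include_self=False):
        if node.length is None:
            if node.is_tip():
                raise ValidationError(
                    f"tip {node.name!r} has no branch length; branch lengths are required"
                )
            node.length = 0.0
        elif node.length < 0:
            raise ValidationError(
                f"negative branch length at node {node.name or '<internal>'!r}"
            )
    return tree


def read_metadata(path) -> SampleMetadata:
    return SampleMetadata(pd.read_csv(path, sep="\t", dtype=str))


def write_metadata(meta: SampleMetadata, path) -> None:
    meta.data.to_csv(path, sep="\t", index=False)


def read_env_table(path) -> EnvTable:
    df = pd.read_csv(path, sep="\t")
    df["date"] = df["date"].astype(str)
    return EnvTable(df)


def write_env_table(env: EnvTable, path) -> None:
    env.data.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# rarefaction & normalisation
# ---------------------------------------------------------------------------


def rarefy(table: CountTable, depth: int, seed: int | np.random.SeedSequence) -> CountTable:
    """Rarefy every sample to ``depth`` reads without replacement.

    Subsampling is multivariate hypergeometric, drawn once per sample from a
    seeded generator, so repeated calls with the same seed are identical.
    Samples with fewer than ``depth`` reads are dropped with a warning; a
    sample whose total equals ``depth`` is returned unchanged. Taxa that end
    up with zero total are retained so axes stay aligned across paired tables.
    """
    if depth <= 0:
        raise ValueError(f"rarefaction depth must be positive, got {depth}")
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    children = ss.spawn(len(table.sample_ids))
    cols = {}
    for child, sample in zip(children, table.sample_ids):
        counts = table.data[sample].to_numpy()
        total = int(counts.sum())
        if total < depth:
            logger.warning(
                "dropping sample %s: %d reads < rarefaction depth %d",
                sample, total, depth,
            )
            continue
        if total == depth:
            cols[sample] = counts
            continue
        rng = np.random.default_rng(child)
        cols[sample] = rng.multivariate_hypergeometric(counts, depth)
    if not cols:
        raise ValidationError(f"no sample reaches rarefaction depth {depth}")
    return CountTable(pd.DataFrame(cols, index=table.data.index).astype(np.int64))


def relative_abundance(table: CountTable) -> RelAbundanceTable:
    """Convert counts to per-sample proportions (columns sum to 1)."""
    sums = table.sample_sums()
    zero = sums[sums == 0]
    if len(zero):
        raise ValidationError(f"all-zero samples cannot be normalised: {list(zero.index)}")
    return RelAbundanceTable(table.data / sums)


def pair_samples(meta: SampleMetadata) -> list[SamplePair]:
    """Match rDNA and rRNA libraries of the same physical sample by pair_key.

    Pair keys with only one molecule are excluded with a logged warning.
    """
    pairs: list[SamplePair] = []
    for pair_key, grp in meta.data.groupby("pair_key", sort=False):
        mols = dict(zip(grp["molecule"], grp["sample_id"]))
        if set(mols) != set(MOLECULES):
            logger.warning(
                "pair_key %s has only %s; excluded from pairing",
                pair_key, sorted(mols),
            )
            continue
        row = grp.iloc[0]
        pairs.append(
            SamplePair(mols["rDNA"], mols["rRNA"], row["date"], row["condition"], str(pair_key))
        )
    return pairs
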