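"""Readers, writers and aligned-cohort assembly for the pipeline's file formats.

Three plain-text dialects are supported:

* **GMT** (MSigDB): one gene set per line, ``name<TAB>description<TAB>gene...``.
* **Omics matrices**: tab-separated gene-by-sample grids; first row holds sample
  identifiers, first column gene symbols, top-left cell empty or ``gene``.
* **Survival tables**: tab-separated with header ``sample<TAB>time<TAB>event``;
  time in days, event 1 = death/event observed, 0 = censored.

Gene and sample identifiers are opaque, case-sensitive strings: no symbol
aliasing or TCGA-barcode parsing is attempted. Missing values are errors.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

MODALITY_TAGS = ("GE", "CNV", "SPM", "METH", "other")
VALUE_KINDS = ("continuous", "binary")
ENDPOINT_TAGS = ("OS", "DFI")


class FormatError(ValueError):
    """A file violated one of the supported plain-text dialects."""


# ---------------------------------------------------------------------------
# domain containers
# ---------------------------------------------------------------------------


@dataclass
class OmicsMatrix:
    """Gene-by-sample value grid for one omics modality.

    Parameters
    ----------
    values : pandas.DataFrame
        Genes as the index, samples as columns. Binary matrices (somatic
        point mutations) are restricted to entries in {0, 1}.
    modality : str
        One of ``GE``, ``CNV``, ``SPM``, ``METH``, ``other``.
    value_kind : str
        ``continuous`` or ``binary``.
    """

    values: pd.DataFrame
    modality: str = "GE"
    value_kind: str = "continuous"

    def __post_init__(self) -> None:
        if self.modality not in MODALITY_TAGS:
            raise ValueError(f"unknown modality tag {self.modality!r}")
        if self.value_kind not in VALUE_KINDS:
            raise ValueError(f"unknown value kind {self.value_kind!r}")
        idx = self.values.index
        cols = self.values.columns
        if idx.has_duplicates:
            dup = idx[idx.duplicated()].unique().tolist()
            raise FormatError(f"duplicate gene symbols: {dup[:5]}")
        if cols.has_duplicates:
            dup = cols[cols.duplicated()].unique().tolist()
            raise FormatError(f"duplicate sample identifiers: {dup[:5]}")
        arr = self.values.to_numpy()
        if not np.issubdtype(arr.dtype, np.number):
            raise FormatError("omics matrix contains non-numeric cells")
        if np.isnan(arr).any():
            g, s = np.argwhere(np.isnan(arr))[0]
            raise FormatError(
                f"missing value at gene {idx[g]!r}, sample {cols[s]!r}; "
                "missing values are not supported"
            )
        if self.value_kind == "binary":
            bad = (arr != 0) & (arr != 1)
            if bad.any():
                g, s = np.argwhere(bad)[0]
                raise FormatError(
                    f"binary matrix has entry {arr[g, s]!r} not in {{0,1}} at "
                    f"gene {idx[g]!r}, sample {cols[s]!r}"
                )

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def subset_genes(self, genes: Sequence[str]) -> "OmicsMatrix":
        """Restrict to ``genes`` (kept in current matrix order)."""
        keep = [g for g in self.genes if g in set(genes)]
        return OmicsMatrix(self.values.loc[keep], self.modality, self.value_kind)

    def subset_samples(self, samples: Sequence[str]) -> "OmicsMatrix":
        return OmicsMatrix(self.values.loc[:, list(samples)], self.modality, self.value_kind)

    def write(self, path: str | Path) -> None:
        write_omics_matrix(self, path)


@dataclass
class SurvivalTable:
    """Right-censored survival records, one per sample.

    ``data`` is indexed by sample identifier with columns ``time`` (days,
    nonnegative) and ``event`` (1 = observed death/event, 0 = censored).
    """

    data: pd.DataFrame
    endpoint: str = "OS"

    def __post_init__(self) -> None:
        if self.endpoint not in ENDPOINT_TAGS:
            raise ValueError(f"unknown endpoint tag {self.endpoint!r}")
        if not {"time", "event"}.issubset(self.data.columns):
            raise FormatError("survival table requires 'time' and 'event' columns")
        if self.data.index.has_duplicates:
            dup = self.data.index[self.data.index.duplicated()].unique().tolist()
            raise FormatError(f"duplicate sample identifiers: {dup[:5]}")
        t = self.data["time"].to_numpy(dtype=float)
        e = self.data["event"].to_numpy(dtype=float)
        if np.isnan(t).any() or np.isnan(e).any():
            raise FormatError("missing value in survival table")
        if (t < 0).any():
            bad = self.data.index[t < 0][0]
            raise FormatError(f"negative survival time for sample {bad!r}")
        if not np.isin(e, (0.0, 1.0)).all():
            bad = self.data.index[~np.isin(e, (0.0, 1.0))][0]
            raise FormatError(f"event indicator outside {{0,1}} for sample {bad!r}")

    @property
    def samples(self) -> list[str]:
        return list(self.data.index)

    @property
    def time(self) -> np.ndarray:
        return self.data["time"].to_numpy(dtype=float)

    @property
    def event(self) -> np.ndarray:
        return self.data["event"].to_numpy(dtype=int)

    @property
    def n_events(self) -> int:
        return int(self.event.sum())

    def subset(self, samples: Sequence[str]) -> "SurvivalTable":
        return SurvivalTable(self.data.loc[list(samples)], self.endpoint)

    def to_structured(self) -> np.ndarray:
        """Return a scikit-survival style structured array (event, time)."""
        out = np.empty(len(self.data), dtype=[("event", "?"), ("time", "<f8")])
        out["event"] = self.event.astype(bool)
        out["time"] = self.time
        return out

    def write(self, path: str | Path) -> None:
        write_survival_table(self, path)


@dataclass
class PathwayCollection:
    """Named gene sets (Hallmark-style), preserving file order."""

    names: list[str]
    members: dict[str, tuple[str, ...]]
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(set(self.names)) != len(self.names):
            raise FormatError("duplicate pathway names")
        for name in self.names:
            if not self.members.get(name):
                raise FormatError(f"pathway {name!r} has no members")

    def __len__(self) -> int:
        return len(self.names)

    def __iter__(self):
        return iter(self.names)

    def __getitem__(self, name: str) -> tuple[str, ...]:
        return self.members[name]

    def gene_union(self) -> set[str]:
        out: set[str] = set()
        for name in self.names:
            out.update(self.members[name])
        return out

    def restrict_to(self, genes: Iterable[str]) -> "PathwayCollection":
        """Drop genes absent from ``genes``; drop pathways left empty."""
        universe = set(genes)
        names, members = [], {}
        for name in self.names:
            kept = tuple(g for g in self.members[name] if g in universe)
            if kept:
                names.append(name)
                members[name] = kept
        return PathwayCollection(names, members,
                                 {n: self.descriptions.get(n, "") for n in names})

    def write(self, path: str | Path) -> None:
        write_gmt(self, path)


@dataclass
class CohortBundle:
    """A cohort's omics matrices, survival table and optional clinical stage,
    aligned to one shared ordered sample list."""

    name: str
    omics: dict[str, OmicsMatrix]
    survival: SurvivalTable
    stage: pd.Series | None = None

    @property
    def samples(self) -> list[str]:
        return self.survival.samples

    @property
    def n_samples(self) -> int:
        return len(self.survival.data)

    def __post_init__(self) -> None:
        ref = self.survival.samples
        for tag, om in self.omics.items():
            if om.samples != ref:
                raise ValueError(f"{tag} matrix samples are not aligned to survival")
        if self.stage is not None and list(self.stage.index) != ref:
            raise ValueError("stage labels are not aligned to survival")


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------


def read_gmt(path: str | Path) -> PathwayCollection:
    """Parse a GMT gene-set file (MSigDB dialect).

    Each non-empty line: ``name<TAB>description<TAB>gene[<TAB>gene...]``.
    Duplicate genes within a line are dropped, keeping first occurrence.
    """
    names: list[str] = []
    members: dict[str, tuple[str, ...]] = {}
    descriptions: dict[str, str] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n").rstrip("\r")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise FormatError(
                    f"{path}: line {lineno}: expected >=3 tab-separated fields, "
                    f"got {len(parts)}"
                )
            name, desc, *genes = parts
            if name in members:
                raise FormatError(f"{path}: line {lineno}: duplicate pathway name {name!r}")
            seen: dict[str, None] = {}
            for g in genes:
                if g and g not in seen:
                    seen[g] = None
            if not seen:
                raise FormatError(f"{path}: line {lineno}: pathway {name!r} has no genes")
            names.append(name)
            members[name] = tuple(seen)
            descriptions[name] = desc
    return PathwayCollection(names, members, descriptions)


def read_omics_matrix(
    path: str | Path, modality: str = "GE", value_kind: str = "continuous"
) -> OmicsMatrix:
    """Read a tab-separated gene-by-sample matrix.

    First row: sample identifiers (top-left cell empty or ``gene``);
    first column: gene symbols. Any non-numeric or missing cell is an error,
    as is any entry outside {0, 1} for ``value_kind='binary'``.
    """
    try:
        df = pd.read_csv(path, sep="\t", index_col=0, header=0)
    except pd.errors.ParserError as exc:  # ragged rows etc.
        raise FormatError(f"{path}: {exc}") from exc
    df.index = df.index.astype(str)
    df.index.name = "gene"
    df.columns = df.columns.astype(str)
    for col in df.columns:
        if not np.issubdtype(df[col].dtype, np.number):
            bad = df[col][pd.to_numeric(df[col], errors="coerce").isna()]
            raise FormatError(
                f"{path}: non-numeric cell {bad.iloc[0]!r} at gene "
                f"{bad.index[0]!r}, sample {col!r}"
            )
    return OmicsMatrix(df.astype(float), modality, value_kind)


def read_survival_table(path: str | Path, endpoint: str = "OS") -> SurvivalTable:
    """Read a ``sample<TAB>time<TAB>event`` survival table."""
    df = pd.read_csv(path, sep="\t", header=0)
    missing = {"sample", "time", "event"} - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing column(s) {sorted(missing)}")
    df["sample"] = df["sample"].astype(str)
    df = df.set_index("sample")
    return SurvivalTable(df[["time", "event"]].astype(float), endpoint)


def read_gene_list(path: str | Path) -> set[str]:
    """Read a gene list, one symbol per line; '#' comments are ignored."""
    out: set[str] = set()
    with open(path) as fh:
        for raw in fh:
            line = raw.split("#", 1)[0].strip()
            if line:
                out.add(line)
    return out


# ---------------------------------------------------------------------------
# writers
# ---------------------------------------------------------------------------


def write_omics_matrix(matrix: OmicsMatrix, path: str | Path) -> None:
    df = matrix.values.copy()
    df.index.name = "gene"
    if matrix.value_kind == "binary":
        df = df.astype(int)
    df.to_csv(path, sep="\t")


def write_survival_table(table: SurvivalTable, path: str | Path) -> None:
    df = table.data.copy()
    df.index.name = "sample"
    df["event"] = df["event"].astype(int)
    df.to_csv(path, sep="\t")


def write_gmt(collection: PathwayCollection, path: str | Path) -> None:
    with open(path, "w") as fh:
        for name in collection.names:
            desc = collection.descriptions.get(name, "")
            fh.write("\t".join([name, desc, *collection.members[name]]) + "\n")


# ---------------------------------------------------------------------------
# cohort assembly
# ---------------------------------------------------------------------------


def align_cohort(
    omics: Mapping[str, OmicsMatrix] | Sequence[OmicsMatrix],
    survival: SurvivalTable,
    stage: pd.Series | None = None,
    name: str = "cohort",
) -> CohortBundle:
    """Restrict all inputs to the shared samples, in lexicographic order.

    Dropped-sample counts per input are logged. Raises if the intersection
    is empty.
    """
    if not isinstance(omics, Mapping):
        omics = {om.modality: om for om in omics}
    if not omics:
        raise ValueError("at least one omics matrix is required")
    common = set(survival.samples)
    for om in omics.values():
        common &= set(om.samples)
    if stage is not None:
        common &= set(stage.index)
    if not common:
        raise ValueError("sample intersection across inputs is empty")
    order = sorted(common)
    for tag, om in omics.items():
        dropped = len(om.samples) - len(order)
        if dropped:
            logger.info("align_cohort[%s]: dropped %d samples from %s", name, dropped, tag)
    dropped = len(survival.samples) - len(order)
    if dropped:
        logger.info("align_cohort[%s]: dropped %d samples from survival", name, dropped)
    aligned = {tag: om.subset_samples(order) for tag, om in omics.items()}
    surv = survival.subset(order)
    stg = stage.loc[order] if stage is not None else None
    return CohortBundle(name, aligned, surv, stg)
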