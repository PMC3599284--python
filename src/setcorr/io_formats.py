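"""Readers and writers for the formats the tool touches.

Gene sets travel as GMT (the MSigDB distribution format: one set per line,
tab-separated ``name<TAB>description<TAB>member...``). Expression matrices and
sample-group maps are plain TSV with a header row. The full gene x gene-set
correlation matrix can be persisted to HDF5 (datasets ``/rho``, ``/genes``,
``/sets``).
"""

from __future__ import annotations

import logging
import math
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping

import h5py
import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

#: Default pattern marking a directional "down" gene set, e.g. GENESET_EXAMPLE_DN.
DEFAULT_DOWN_PATTERN = r"_DN$"


class GmtParseError(ValueError):
    """Malformed GMT input."""


class TableParseError(ValueError):
    """Malformed TSV table input."""


@dataclass(frozen=True)
class GeneSet:
    """A named gene set with an optional "down" directionality flag.

    ``members`` preserves first-occurrence order (GMT files occasionally repeat
    symbols; duplicates are removed upstream). ``is_down`` marks sets defined by
    down-regulation in their source experiment; their correlations are reported
    with flipped sign for interpretability.
    """

    name: str
    description: str
    members: tuple[str, ...]
    is_down: bool = False

    def __post_init__(self) -> None:
        if not self.name:
            raise ValueError("gene set name must be non-empty")
        if not self.members:
            raise ValueError(f"gene set {self.name!r} has no members")
        if len(set(self.members)) != len(self.members):
            raise ValueError(f"gene set {self.name!r} has duplicate members")

    @property
    def member_set(self) -> frozenset[str]:
        return frozenset(self.members)

    def __len__(self) -> int:
        return len(self.members)


class GeneSetCollection:
    """Ordered collection of uniquely named gene sets (file order preserved)."""

    def __init__(self, sets: Iterable[GeneSet]):
        self.sets: list[GeneSet] = list(sets)
        self._by_name: dict[str, GeneSet] = {}
        for s in self.sets:
            if s.name in self._by_name:
                raise ValueError(f"duplicate gene set name: {s.name!r}")
            self._by_name[s.name] = s

    def __iter__(self) -> Iterator[GeneSet]:
        return iter(self.sets)

    def __len__(self) -> int:
        return len(self.sets)

    def __contains__(self, name: str) -> bool:
        return name in self._by_name

    def __getitem__(self, key: int | str) -> GeneSet:
        if isinstance(key, str):
            return self._by_name[key]
        return self.sets[key]

    @property
    def names(self) -> list[str]:
        return [s.name for s in self.sets]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GeneSetCollection):
            return NotImplemented
        return self.sets == other.sets

    def __repr__(self) -> str:
        return f"GeneSetCollection({len(self.sets)} sets)"


@dataclass(eq=False)
class ExpressionMatrix:
    """Genes x samples matrix of log2 expression (fold-change after standardization).

    Gene and sample identifiers are unique and ordered; values are float64 with
    NaN marking explicitly missing entries (enrichment rejects missing values,
    see :mod:`setcorr.preprocess`).
    """

    gene_ids: tuple[str, ...]
    sample_ids: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.gene_ids = tuple(self.gene_ids)
        self.sample_ids = tuple(self.sample_ids)
        # C-contiguity keeps per-column reductions bit-stable regardless of
        # how the array was sliced or permuted upstream
        self.values = np.ascontiguousarray(self.values, dtype=np.float64)
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValueError("duplicate gene ids")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("duplicate sample ids")
        if self.values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValueError(
                f"values shape {self.values.shape} inconsistent with "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        if np.isinf(self.values).any():
            raise ValueError("expression values must be finite or NaN (missing)")
        self._gene_pos = {g: i for i, g in enumerate(self.gene_ids)}

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "ExpressionMatrix":
        return cls(tuple(map(str, frame.index)), tuple(map(str, frame.columns)),
                   frame.to_numpy(dtype=np.float64))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=list(self.gene_ids),
                            columns=list(self.sample_ids))

    def gene_position(self, gene: str) -> int:
        try:
            return self._gene_pos[gene]
        except KeyError:
            raise KeyError(f"unknown gene: {gene!r}") from None

    def row(self, gene: str) -> np.ndarray:
        return self.values[self.gene_position(gene)]

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def has_missing(self) -> bool:
        return bool(np.isnan(self.values).any())

    def equals(self, other: "ExpressionMatrix") -> bool:
        return (self.gene_ids == other.gene_ids
                and self.sample_ids == other.sample_ids
                and np.array_equal(self.values, other.values, equal_nan=True))


@dataclass
class SampleGroupMap:
    """Maps each sample id to its tissue group and role (case or control)."""

    assignments: dict[str, tuple[str, str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for sid, (group, role) in self.assignments.items():
            if role not in ("case", "control"):
                raise ValueError(f"sample {sid!r}: role must be 'case' or "
                                 f"'control', got {role!r}")

    def tissue_group(self, sample_id: str) -> str:
        return self.assignments[sample_id][0]

    def role(self, sample_id: str) -> str:
        return self.assignments[sample_id][1]

    def samples_with_role(self, role: str) -> list[str]:
        return [s for s, (_, r) in self.assignments.items() if r == role]

    def controls_for_group(self, group: str) -> list[str]:
        return [s for s, (g, r) in self.assignments.items()
                if g == group and r == "control"]


def read_gmt(path: str | Path, down_pattern: str = DEFAULT_DOWN_PATTERN) -> GeneSetCollection:
    """Parse a GMT file into a :class:`GeneSetCollection`.

    Blank lines and lines starting with ``#`` are ignored. Members are
    deduplicated preserving first occurrence (with a logged warning, as MSigDB
    files occasionally repeat symbols). ``down_pattern`` is a case-insensitive
    regex matched against the set name to flag directional "down" sets.
    """
    pattern = re.compile(down_pattern, re.IGNORECASE)
    sets: list[GeneSet] = []
    seen: set[str] = set()
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n").rstrip("\r")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise GmtParseError(
                    f"{path}: line {lineno}: expected >=3 tab-separated fields "
                    f"(name, description, members...), got {len(fields)}")
            name, description = fields[0], fields[1]
            raw_members = [m for m in fields[2:] if m]
            members = list(dict.fromkeys(raw_members))
            if not members:
                raise GmtParseError(f"{path}: line {lineno}: set {name!r} has no members")
            if len(members) < len(raw_members):
                log.warning("gene set %r: removed %d duplicate member(s)",
                            name, len(raw_members) - len(members))
            if name in seen:
                raise GmtParseError(f"{path}: line {lineno}: duplicate set name {name!r}")
            seen.add(name)
            sets.append(GeneSet(name=name, description=description,
                                members=tuple(members),
                                is_down=bool(pattern.search(name))))
    return GeneSetCollection(sets)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    """Write a collection back to GMT, one set per line in collection order."""
    with open(path, "w", encoding="utf-8") as fh:
        for s in collection:
            fh.write("\t".join([s.name, s.description, *s.members]) + "\n")


def _parse_cell(cell: str, gene: str, sample: str, path: str | Path) -> float:
    if cell == "":
        return math.nan
    try:
        return float(cell)
    except ValueError:
        raise TableParseError(
            f"{path}: non-numeric value {cell!r} at gene {gene!r}, "
            f"sample {sample!r}") from None


def read_expression_rows(path: str | Path) -> pd.DataFrame:
    """Read a TSV expression table allowing repeated gene rows.

    Returns a DataFrame whose index may contain duplicates; feed it to
    :func:`setcorr.preprocess.collapse_duplicate_genes`.
    """
    with open(path, encoding="utf-8") as fh:
        lines = [ln.rstrip("\n").rstrip("\r") for ln in fh]
    lines = [ln for ln in lines if ln.strip()]
    if not lines:
        raise TableParseError(f"{path}: empty file")
    header = lines[0].split("\t")
    sample_ids = header[1:]
    if len(set(sample_ids)) != len(sample_ids):
        raise TableParseError(f"{path}: duplicate sample ids in header")
    genes: list[str] = []
    rows: list[list[float]] = []
    for lineno, line in enumerate(lines[1:], start=2):
        fields = line.split("\t")
        if len(fields) != len(header):
            raise TableParseError(
                f"{path}: line {lineno}: expected {len(header)} fields, "
                f"got {len(fields)} (ragged row)")
        gene = fields[0]
        genes.append(gene)
        rows.append([_parse_cell(c, gene, s, path)
                     for c, s in zip(fields[1:], sample_ids)])
    if not genes:
        raise TableParseError(f"{path}: no genes (file contains only a header)")
    return pd.DataFrame(np.asarray(rows, dtype=np.float64),
                        index=genes, columns=sample_ids)


def read_expression_table(path: str | Path) -> ExpressionMatrix:
    """Read a TSV expression table (header of sample ids, first column genes)."""
    frame = read_expression_rows(path)
    dup = frame.index[frame.index.duplicated()].unique()
    if len(dup):
        raise TableParseError(
            f"{path}: duplicate gene row(s) {list(dup[:5])!r}; use "
            f"read_expression_rows + collapse_duplicate_genes to resolve them")
    return ExpressionMatrix.from_frame(frame)


def write_expression_table(matrix: ExpressionMatrix, path: str | Path,
                           gene_column: str = "gene") -> None:
    """Write an expression matrix to TSV at full float precision.

    NaN (missing) values are written as empty cells so the round trip is exact.
    """
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\t".join([gene_column, *matrix.sample_ids]) + "\n")
        for gene, row in zip(matrix.gene_ids, matrix.values):
            cells = ["" if math.isnan(v) else format(v, ".17g") for v in row]
            fh.write("\t".join([gene, *cells]) + "\n")


def read_sample_groups(path: str | Path) -> SampleGroupMap:
    """Read a TSV with columns sample_id, tissue_group, role."""
    frame = pd.read_csv(path, sep="\t", dtype=str)
    required = {"sample_id", "tissue_group", "role"}
    missing = required - set(frame.columns)
    if missing:
        raise TableParseError(f"{path}: missing column(s) {sorted(missing)}")
    if frame["sample_id"].duplicated().any():
        raise TableParseError(f"{path}: duplicate sample ids")
    return SampleGroupMap({row.sample_id: (row.tissue_group, row.role)
                           for row in frame.itertuples()})


def write_sample_groups(groups: SampleGroupMap, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("sample_id\ttissue_group\trole\n")
        for sid, (group, role) in groups.assignments.items():
            fh.write(f"{sid}\t{group}\t{role}\n")


ASSOCIATION_COLUMNS = ["gene", "gene_set", "rho", "reported_rho",
                       "relative_rank", "relative_rank_display", "flipped"]


def write_association_table(index, path: str | Path, top_k: int) -> None:
    """Write the top ``top_k`` gene-set associations of every gene to TSV.

    Columns: gene, gene_set, rho, reported_rho (sign-flipped for "down" sets),
    relative_rank at full precision, a 3-decimal display column, and the
    flipped flag. Rows for each gene are sorted by relative rank ascending
    (strongest association first).
    """
    from .association import rank_gene_sets_for_gene  # cycle-avoiding import

    if top_k < 1:
        raise ValueError(f"top_k must be >= 1, got {top_k}")
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\t".join(ASSOCIATION_COLUMNS) + "\n")
        for gene in index.gene_ids:
            for rec in rank_gene_sets_for_gene(index, gene, k=top_k):
                fh.write("\t".join([
                    rec.gene, rec.set_name,
                    format(rec.rho, ".17g"), format(rec.reported_rho, ".17g"),
                    format(rec.relative_rank, ".17g"),
                    format(rec.relative_rank, ".3f"),
                    str(rec.flipped).lower(),
                ]) + "\n")


def read_association_table(path: str | Path) -> pd.DataFrame:
    frame = pd.read_csv(path, sep="\t")
    missing = set(ASSOCIATION_COLUMNS) - set(frame.columns)
    if missing:
        raise TableParseError(f"{path}: missing column(s) {sorted(missing)}")
    return frame


def save_association_h5(index, path: str | Path) -> None:
    """Persist an AssociationIndex to HDF5 (/rho, /genes, /sets and ranks)."""
    with h5py.File(path, "w") as h5:
        h5.create_dataset("rho", data=index.rho)
        h5.create_dataset("relative_rank", data=index.relative_rank)
        h5.create_dataset("genes", data=np.array(index.gene_ids, dtype="S"))
        h5.create_dataset("sets", data=np.array(index.set_names, dtype="S"))
        h5.create_dataset("is_down", data=np.asarray(index.is_down, dtype=bool))
        h5.attrs["center"] = index.center
        h5.attrs["n_finite"] = index.n_finite


def load_association_h5(path: str | Path):
    from .association import AssociationIndex

    with h5py.File(path, "r") as h5:
        genes = tuple(g.decode() for g in h5["genes"][()])
        sets = tuple(s.decode() for s in h5["sets"][()])
        rho = h5["rho"][()]
        is_down = h5["is_down"][()]
    return AssociationIndex.from_rho(genes, sets, rho, is_down=is_down)
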