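"""Readers and writers for the pipeline's standard formats.

Expression matrices come in as TSV (first column gene id, remaining columns
samples) or GCT 1.2; gene sets as GMT; sample annotations as two/three-column
TSV.  Values are assumed to be on a log2 scale already; ``log2_transform=True``
applies log2(x+1) for raw-scale inputs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from acetylprio.errors import FormatError, ParseError, ValidationError

logger = logging.getLogger(__name__)

STAGES = ("normal", "CIN1", "CIN2", "CIN3", "cancer")

#: two-group state derived from the histological stage; premalignant (CIN)
#: samples are kept in the cohort but excluded from cancer-vs-normal contrasts
STAGE_TO_STATE = {
    "normal": "normal",
    "CIN1": "premalignant",
    "CIN2": "premalignant",
    "CIN3": "premalignant",
    "cancer": "cancer",
}


@dataclass
class ExpressionMatrix:
    """Genes x samples matrix of log2 expression values.

    ``data`` is a float DataFrame indexed by unique gene ids with unique
    sample-id columns and no missing values.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        if self.data.index.has_duplicates:
            raise ValidationError("duplicate gene ids after construction")
        if self.data.columns.has_duplicates:
            raise ValidationError("duplicate sample ids")
        if self.data.isna().any().any():
            raise ValidationError("missing values in expression matrix")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy()

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, log2_transform: bool = False) -> "ExpressionMatrix":
        """Build a matrix from a raw frame, applying the loading conventions.

        Rows with any missing value are dropped (count logged); duplicate gene
        ids are collapsed by keeping the row with the highest mean expression
        (logged) — the usual probe-collapse convention for microarray data.
        """
        frame = frame.astype(float)
        n_missing = int(frame.isna().any(axis=1).sum())
        if n_missing:
            logger.info("dropping %d rows containing missing values", n_missing)
            frame = frame.dropna(axis=0)
        if frame.index.has_duplicates:
            n_dup = int(frame.index.duplicated().sum())
            logger.info("collapsing %d duplicate gene rows by highest mean", n_dup)
            means = frame.mean(axis=1)
            order = np.argsort(-means.to_numpy(), kind="stable")
            frame = frame.iloc[order]
            frame = frame[~frame.index.duplicated(keep="first")]
            frame = frame.sort_index()
        if log2_transform:
            frame = np.log2(frame + 1.0)
        return cls(frame)


@dataclass
class SampleAnnotation:
    """Maps sample ids to histological stage and the derived two-group state."""

    frame: pd.DataFrame  # columns: stage, state; index: sample_id

    def __post_init__(self) -> None:
        unknown = set(self.frame["stage"]) - set(STAGES)
        if unknown:
            raise ValidationError(f"unknown stage labels: {sorted(unknown)}")
        if "state" not in self.frame.columns:
            self.frame = self.frame.assign(state=self.frame["stage"].map(STAGE_TO_STATE))

    @property
    def sample_ids(self) -> list[str]:
        return list(self.frame.index)

    def samples_in_state(self, state: str) -> list[str]:
        return list(self.frame.index[self.frame["state"] == state])

    def samples_in_stage(self, stage: str) -> list[str]:
        return list(self.frame.index[self.frame["stage"] == stage])

    def validate_against(self, matrix: ExpressionMatrix) -> None:
        missing = [s for s in self.frame.index if s not in set(matrix.sample_ids)]
        if missing:
            raise ValidationError(
                f"annotated samples absent from expression matrix: {missing[:10]}"
            )


@dataclass(frozen=True)
class GeneSet:
    """A named set of gene identifiers (insertion order preserved)."""

    name: str
    description: str
    members: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.members:
            raise ValidationError(f"gene set {self.name!r} has no members")
        seen: dict[str, None] = dict.fromkeys(self.members)
        if len(seen) != len(self.members):
            object.__setattr__(self, "members", tuple(seen))

    def __len__(self) -> int:
        return len(self.members)

    def __contains__(self, gene: str) -> bool:
        return gene in set(self.members)

    def intersect(self, genes: Iterable[str]) -> "GeneSet":
        keep = set(genes)
        kept = tuple(g for g in self.members if g in keep)
        n_dropped = len(self.members) - len(kept)
        if n_dropped:
            logger.info("gene set %s: %d members absent from matrix", self.name, n_dropped)
        if not kept:
            from acetylprio.errors import EmptySetError

            raise EmptySetError(f"gene set {self.name!r} empty after intersection")
        return GeneSet(self.name, self.description, kept)


@dataclass
class GeneSetCollection:
    """Ordered collection of named gene sets, as parsed from a GMT file."""

    sets: list[GeneSet] = field(default_factory=list)

    def __getitem__(self, name: str) -> GeneSet:
        for s in self.sets:
            if s.name == name:
                return s
        raise KeyError(f"no gene set named {name!r}")

    def __iter__(self):
        return iter(self.sets)

    def __len__(self) -> int:
        return len(self.sets)

    @property
    def names(self) -> list[str]:
        return [s.name for s in self.sets]


# ---------------------------------------------------------------------------
# expression matrices


def _check_numeric(frame: pd.DataFrame, path: Path) -> pd.DataFrame:
    coerced = frame.apply(pd.to_numeric, errors="coerce")
    bad = coerced.isna() & frame.notna()
    if bad.any().any():
        rows, cols = np.nonzero(bad.to_numpy())
        r, c = rows[0], cols[0]
        raise ParseError(
            f"{path}: non-numeric value {frame.iat[r, c]!r} at gene "
            f"{frame.index[r]!r}, sample {frame.columns[c]!r}"
        )
    return coerced


def read_expression(
    path: str | Path, format: str | None = None, log2_transform: bool = False
) -> ExpressionMatrix:
    """Read a genes x samples expression table (TSV or GCT 1.2)."""
    path = Path(path)
    if format is None:
        format = "gct" if path.suffix.lower() == ".gct" else "tsv"
    if format not in {"tsv", "gct"}:
        raise FormatError(f"unknown expression format {format!r}")
    if format == "gct":
        with open(path) as fh:
            version = fh.readline().strip()
            if version != "#1.2":
                raise FormatError(f"{path}: expected GCT version line '#1.2', got {version!r}")
            dims = fh.readline().split()
            if len(dims) < 2:
                raise FormatError(f"{path}: malformed GCT dimensions line")
            frame = pd.read_csv(fh, sep="\t", index_col=0)
        frame = frame.drop(columns=frame.columns[0])  # Description column
        n_rows, n_cols = int(dims[0]), int(dims[1])
        if frame.shape != (n_rows, n_cols):
            raise FormatError(
                f"{path}: GCT dimensions {n_rows}x{n_cols} do not match table {frame.shape}"
            )
    else:
        frame = pd.read_csv(path, sep="\t", index_col=0)
        if frame.shape[1] == 0:
            raise FormatError(f"{path}: no sample columns found")
    frame.index = frame.index.astype(str)
    frame = _check_numeric(frame, path)
    return ExpressionMatrix.from_frame(frame, log2_transform=log2_transform)


def write_expression(matrix: ExpressionMatrix, path: str | Path, format: str | None = None) -> None:
    """Write a matrix as TSV or GCT 1.2 (round-trips with :func:`read_expression`)."""
    path = Path(path)
    if format is None:
        format = "gct" if path.suffix.lower() == ".gct" else "tsv"
    if format == "gct":
        n_genes, n_samples = matrix.shape
        with open(path, "w") as fh:
            fh.write("#1.2\n")
            fh.write(f"{n_genes}\t{n_samples}\n")
            out = matrix.data.copy()
            out.insert(0, "Description", "na")
            out.index.name = "Name"
            out.to_csv(fh, sep="\t", float_format="%.12g")
    elif format == "tsv":
        out = matrix.data.copy()
        out.index.name = "gene_id"
        out.to_csv(path, sep="\t", float_format="%.12g")
    else:
        raise FormatError(f"unknown expression format {format!r}")


# ---------------------------------------------------------------------------
# annotations


def read_annotation(path: str | Path) -> SampleAnnotation:
    """Read a sample annotation TSV (sample_id, stage[, state])."""
    frame = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    if "stage" not in frame.columns:
        raise FormatError(f"{path}: annotation needs a 'stage' column")
    return SampleAnnotation(frame)


def write_annotation(annotation: SampleAnnotation, path: str | Path) -> None:
    out = annotation.frame.copy()
    out.index.name = "sample_id"
    out.to_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# gene sets (GMT)


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Parse a GMT file: one tab-separated line per set (name, description, members...)."""
    sets = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(
                    f"{path}: line {lineno} has {len(fields)} fields; "
                    "GMT needs name, description and at least one member"
                )
            sets.append(GeneSet(fields[0], fields[1], tuple(fields[2:])))
    return GeneSetCollection(sets)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w") as fh:
        for s in collection:
            fh.write("\t".join([s.name, s.description, *s.members]) + "\n")


# ---------------------------------------------------------------------------
# tabular results


def write_results_table(records: pd.DataFrame | Sequence[Mapping], path: str | Path) -> None:
    """Write pipeline results as a TSV with header; lossless for the package's own tables."""
    frame = records if isinstance(records, pd.DataFrame) else pd.DataFrame(list(records))
    frame.to_csv(path, sep="\t", index=False, float_format="%.12g")


def read_results_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
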