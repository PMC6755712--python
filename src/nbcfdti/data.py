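"""Bipartite drug-target interaction data: containers, I/O and summary statistics.

The central object is :class:`InteractionMatrix`, the binary adjacency matrix
``Y`` of the drug-target interaction (DTI) bipartite network, with targets on
rows and drugs on columns.  A 1 records an experimentally validated
interaction; a 0 means the pair is *untested* (one-class data), never a
confirmed non-interaction.

The canonical interchange format is a tab-separated edge list with header
``target_id<TAB>drug_id`` -- natural for networks at sparsity ~0.006-0.010.
A dense TSV matrix with identifier headers is supported as a convenience.
Auxiliary similarity matrices (target sequence similarity ``S_T``, drug
structural similarity ``S_D``) are consumed as given; this package never
computes them from sequences or structures.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("nbcfdti")

EdgeFormat = Literal["edge-list", "dense"]

#: symmetry tolerance for auxiliary similarity matrices
SYMMETRY_TOL = 1e-9


class DataError(ValueError):
    """Malformed or inconsistent input data."""


@dataclass(frozen=True)
class InteractionMatrix:
    """Binary M x N drug-target adjacency matrix (rows = targets, cols = drugs)."""

    values: np.ndarray
    target_ids: tuple[str, ...]
    drug_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        values = np.asarray(self.values)
        if values.ndim != 2:
            raise DataError(f"interaction matrix must be 2-D, got shape {values.shape}")
        m, n = values.shape
        if m < 1 or n < 1:
            raise DataError(f"interaction matrix must be at least 1x1, got {m}x{n}")
        if not np.isin(values, (0, 1)).all():
            bad = values[~np.isin(values, (0, 1))].ravel()[0]
            raise DataError(f"interaction matrix entries must be 0 or 1, found {bad!r}")
        object.__setattr__(self, "values", values.astype(np.int8, copy=False))
        object.__setattr__(self, "target_ids", tuple(str(t) for t in self.target_ids))
        object.__setattr__(self, "drug_ids", tuple(str(d) for d in self.drug_ids))
        if len(self.target_ids) != m:
            raise DataError(f"{len(self.target_ids)} target ids for {m} rows")
        if len(self.drug_ids) != n:
            raise DataError(f"{len(self.drug_ids)} drug ids for {n} columns")
        for axis, ids in (("target", self.target_ids), ("drug", self.drug_ids)):
            if len(set(ids)) != len(ids):
                seen: set[str] = set()
                dup = next(i for i in ids if i in seen or seen.add(i))
                raise DataError(f"duplicate {axis} id {dup!r}")

    @property
    def n_targets(self) -> int:
        return self.values.shape[0]

    @property
    def n_drugs(self) -> int:
        return self.values.shape[1]

    @property
    def n_interactions(self) -> int:
        return int(self.values.sum())

    def drug_degrees(self) -> np.ndarray:
        """Number of known targets per drug (column sums)."""
        return self.values.sum(axis=0).astype(np.int64)

    def target_degrees(self) -> np.ndarray:
        """Number of known drugs per target (row sums)."""
        return self.values.sum(axis=1).astype(np.int64)

    def replace_values(self, values: np.ndarray) -> "InteractionMatrix":
        """New matrix with the same identifiers and different entries."""
        return InteractionMatrix(values, self.target_ids, self.drug_ids)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, InteractionMatrix):
            return NotImplemented
        return (
            self.target_ids == other.target_ids
            and self.drug_ids == other.drug_ids
            and np.array_equal(self.values, other.values)
        )


@dataclass(frozen=True)
class AuxSimilarityPair:
    """Auxiliary similarities: target-target S_T (M x M) and drug-drug S_D (N x N).

    Typically target sequence similarity and drug structural similarity supplied
    by the user; validated for shape, symmetry and finiteness only.
    """

    target_sim: np.ndarray
    drug_sim: np.ndarray

    def __post_init__(self) -> None:
        for name, mat in (("target_sim", self.target_sim), ("drug_sim", self.drug_sim)):
            arr = np.asarray(mat, dtype=float)
            if arr.ndim != 2 or arr.shape[0] != arr.shape[1]:
                raise DataError(f"{name} must be square, got shape {arr.shape}")
            if not np.isfinite(arr).all():
                raise DataError(f"{name} contains non-finite entries")
            if np.abs(arr - arr.T).max(initial=0.0) > SYMMETRY_TOL:
                raise DataError(f"{name} is not symmetric within {SYMMETRY_TOL}")
            object.__setattr__(self, name, arr)

    def check_shapes(self, m: InteractionMatrix) -> None:
        if self.target_sim.shape[0] != m.n_targets:
            raise DataError(
                f"target_sim is {self.target_sim.shape} but matrix has {m.n_targets} targets"
            )
        if self.drug_sim.shape[0] != m.n_drugs:
            raise DataError(
                f"drug_sim is {self.drug_sim.shape} but matrix has {m.n_drugs} drugs"
            )


@dataclass(frozen=True)
class DatasetStats:
    """Summary of a DTI network: counts, degree extremes/means and sparsity."""

    n_targets: int
    n_drugs: int
    n_interactions: int
    mean_targets_per_drug: float
    mean_drugs_per_target: float
    min_deg_drug: int
    max_deg_drug: int
    min_deg_target: int
    max_deg_target: int
    sparsity: float

    def as_dict(self) -> dict:
        return {k: getattr(self, k) for k in self.__dataclass_fields__}


def dataset_stats(m: InteractionMatrix) -> DatasetStats:
    """Summarize the network as counts, mean/min/max degrees and sparsity.

    Sparsity is the number of known links divided by all M*N possible
    target-drug pairs, reported at full precision.
    """
    dd = m.drug_degrees()
    td = m.target_degrees()
    return DatasetStats(
        n_targets=m.n_targets,
        n_drugs=m.n_drugs,
        n_interactions=m.n_interactions,
        mean_targets_per_drug=float(dd.mean()),
        mean_drugs_per_target=float(td.mean()),
        min_deg_drug=int(dd.min()),
        max_deg_drug=int(dd.max()),
        min_deg_target=int(td.min()),
        max_deg_target=int(td.max()),
        sparsity=m.n_interactions / (m.n_targets * m.n_drugs),
    )


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_interactions(source: str | Path, format: EdgeFormat = "edge-list") -> InteractionMatrix:
    """Read an interaction matrix from a TSV edge list or dense TSV matrix.

    Edge-list rows are ``target_id<TAB>drug_id`` with an optional third value
    column restricted to {0, 1}; duplicate edges collapse to a single 1 and
    unlisted pairs are 0.  Row/column order follows first appearance in the
    file.  Dense files carry drug ids in the header and target ids in the
    first column.
    """
    source = Path(source)
    if format == "edge-list":
        return _read_edge_list(source)
    if format == "dense":
        return _read_dense(source)
    raise DataError(f"unknown format {format!r}")


def _read_edge_list(source: Path) -> InteractionMatrix:
    try:
        lines = source.read_text().splitlines()
    except OSError as exc:
        raise DataError(f"cannot read {source}: {exc}") from exc
    if not lines:
        raise DataError(f"{source}: empty file")
    header = lines[0].rstrip("\n").split("\t")
    if len(header) < 2 or header[0] != "target_id" or header[1] != "drug_id":
        raise DataError(f"{source}: line 1: expected header 'target_id\\tdrug_id', got {lines[0]!r}")
    # optional '#targets='/'#drugs=' comment lines pin the full axis orders,
    # keeping zero-degree nodes and original column order across round trips
    target_ids: list[str] = []
    drug_ids: list[str] = []
    t_index: dict[str, int] = {}
    d_index: dict[str, int] = {}
    edges: set[tuple[int, int]] = set()
    for raw in lines[1:]:
        if raw.startswith("#targets="):
            for tid in raw[len("#targets="):].split(","):
                if tid and tid not in t_index:
                    t_index[tid] = len(target_ids)
                    target_ids.append(tid)
        elif raw.startswith("#drugs="):
            for did in raw[len("#drugs="):].split(","):
                if did and did not in d_index:
                    d_index[did] = len(drug_ids)
                    drug_ids.append(did)
    for lineno, raw in enumerate(lines[1:], start=2):
        if not raw.strip() or raw.startswith("#"):
            continue
        parts = raw.split("\t")
        if len(parts) not in (2, 3):
            raise DataError(f"{source}: line {lineno}: expected 2-3 tab-separated fields, got {raw!r}")
        tid, did = parts[0].strip(), parts[1].strip()
        if not tid or not did:
            raise DataError(f"{source}: line {lineno}: empty identifier in {raw!r}")
        value = 1
        if len(parts) == 3:
            try:
                value = int(parts[2])
            except ValueError:
                raise DataError(f"{source}: line {lineno}: non-integer value {parts[2]!r}") from None
            if value not in (0, 1):
                raise DataError(f"{source}: line {lineno}: value must be 0 or 1, got {value}")
        if tid not in t_index:
            t_index[tid] = len(target_ids)
            target_ids.append(tid)
        if did not in d_index:
            d_index[did] = len(drug_ids)
            drug_ids.append(did)
        if value == 1:
            edges.add((t_index[tid], d_index[did]))
    if not target_ids or not drug_ids:
        raise DataError(f"{source}: no edges found")
    values = np.zeros((len(target_ids), len(drug_ids)), dtype=np.int8)
    for i, j in edges:
        values[i, j] = 1
    return InteractionMatrix(values, tuple(target_ids), tuple(drug_ids))


def _read_dense(source: Path) -> InteractionMatrix:
    try:
        df = pd.read_csv(source, sep="\t", index_col=0)
    except OSError as exc:
        raise DataError(f"cannot read {source}: {exc}") from exc
    except pd.errors.EmptyDataError:
        raise DataError(f"{source}: empty file") from None
    arr = df.to_numpy()
    if not np.isin(arr, (0, 1)).all():
        raise DataError(f"{source}: dense matrix entries must be 0 or 1")
    return InteractionMatrix(arr, tuple(str(t) for t in df.index), tuple(str(d) for d in df.columns))


def write_interactions(m: InteractionMatrix, dest: str | Path, format: EdgeFormat = "edge-list") -> None:
    """Write an interaction matrix so that :func:`read_interactions` round-trips.

    The edge list writes one row per known interaction; identifiers of
    all-zero rows/columns are retained in ``#targets=``/``#drugs=`` comment
    lines so the round trip is exact even for empty networks.
    """
    dest = Path(dest)
    try:
        if format == "edge-list":
            with dest.open("w") as fh:
                fh.write("target_id\tdrug_id\n")
                fh.write("#targets=" + ",".join(m.target_ids) + "\n")
                fh.write("#drugs=" + ",".join(m.drug_ids) + "\n")
                rows, cols = np.nonzero(m.values)
                for i, j in zip(rows.tolist(), cols.tolist()):
                    fh.write(f"{m.target_ids[i]}\t{m.drug_ids[j]}\n")
        elif format == "dense":
            df = pd.DataFrame(m.values, index=list(m.target_ids), columns=list(m.drug_ids))
            df.to_csv(dest, sep="\t", index_label="target_id")
        else:
            raise DataError(f"unknown format {format!r}")
    except OSError as exc:
        raise DataError(f"cannot write {dest}: {exc}") from exc


def read_similarity(source: str | Path) -> tuple[np.ndarray, tuple[str, ...]]:
    """Read a dense TSV similarity matrix; returns (values, ids)."""
    source = Path(source)
    try:
        df = pd.read_csv(source, sep="\t", index_col=0)
    except OSError as exc:
        raise DataError(f"cannot read {source}: {exc}") from exc
    except pd.errors.EmptyDataError:
        raise DataError(f"{source}: empty file") from None
    ids = tuple(str(i) for i in df.index)
    if ids != tuple(str(c) for c in df.columns):
        raise DataError(f"{source}: row and column identifiers differ")
    return df.to_numpy(dtype=float), ids


def write_similarity(values: np.ndarray, ids: Sequence[str], dest: str | Path) -> None:
    """Write a square matrix as dense TSV with matching row/column ids."""
    df = pd.DataFrame(values, index=list(ids), columns=list(ids))
    try:
        df.to_csv(Path(dest), sep="\t", index_label="id")
    except OSError as exc:
        raise DataError(f"cannot write {dest}: {exc}") from exc
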