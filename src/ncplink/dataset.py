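"""Bipartite microbe-disease association networks.

The central object is :class:`AssociationDataset`: a binary adjacency matrix
``MD`` with one row per microbe and one column per disease, ``MD[i, j] = 1``
iff microbe *i* has a recorded association with disease *j*.  Datasets are
loaded from two-column tab-separated edge lists (microbe<TAB>disease); the
benchmark regime this package targets has a few hundred associations among a
few hundred microbes and a few dozen diseases, so dense integer matrices are
used throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .exceptions import IncompatibilityError, InputFormatError, MaskingError

__all__ = [
    "AssociationDataset",
    "DegreeSummary",
    "load_associations",
    "write_associations",
    "degree_statistics",
    "write_degree_table",
    "mask_entries",
]


@dataclass(frozen=True)
class AssociationDataset:
    """A named bipartite binary association network.

    Parameters
    ----------
    microbe_names, disease_names
        Unique, non-empty entity names in first-appearance order.  All
        downstream matrices (similarities, scores) inherit this order.
    MD
        ``(n_microbes, n_diseases)`` array of {0, 1}.
    """

    microbe_names: tuple[str, ...]
    disease_names: tuple[str, ...]
    MD: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "microbe_names", tuple(self.microbe_names))
        object.__setattr__(self, "disease_names", tuple(self.disease_names))
        md = np.asarray(self.MD)
        if md.ndim != 2:
            raise IncompatibilityError("MD must be a 2-D matrix")
        if md.shape != (len(self.microbe_names), len(self.disease_names)):
            raise IncompatibilityError(
                f"MD shape {md.shape} does not match "
                f"{len(self.microbe_names)} microbes x {len(self.disease_names)} diseases"
            )
        if not np.isin(md, (0, 1)).all():
            raise IncompatibilityError("MD entries must be exactly 0 or 1")
        for names, kind in ((self.microbe_names, "microbe"), (self.disease_names, "disease")):
            if any(not n for n in names):
                raise IncompatibilityError(f"empty {kind} name")
            if len(set(names)) != len(names):
                raise IncompatibilityError(f"duplicate {kind} names")
        md = md.astype(np.int8, copy=True)
        md.setflags(write=False)
        object.__setattr__(self, "MD", md)

    # -- basic queries -----------------------------------------------------

    @property
    def n_microbes(self) -> int:
        return len(self.microbe_names)

    @property
    def n_diseases(self) -> int:
        return len(self.disease_names)

    @property
    def n_associations(self) -> int:
        return int(self.MD.sum())

    def microbe_index(self, name: str) -> int:
        try:
            return self.microbe_names.index(name)
        except ValueError:
            raise KeyError(f"unknown microbe: {name!r}") from None

    def disease_index(self, name: str) -> int:
        try:
            return self.disease_names.index(name)
        except ValueError:
            raise KeyError(f"unknown disease: {name!r}") from None

    def known_pairs(self) -> list[tuple[int, int]]:
        """Index pairs (microbe, disease) of all known associations, row-major."""
        rows, cols = np.nonzero(self.MD)
        return list(zip(rows.tolist(), cols.tolist()))

    def unknown_pairs(self) -> list[tuple[int, int]]:
        """Index pairs of all cells with no recorded association."""
        rows, cols = np.nonzero(self.MD == 0)
        return list(zip(rows.tolist(), cols.tolist()))

    # -- construction ------------------------------------------------------

    @classmethod
    def from_edges(cls, edges: Iterable[tuple[str, str]]) -> "AssociationDataset":
        """Build a dataset from (microbe, disease) name pairs.

        Duplicate pairs collapse to a single association; entity order is
        first appearance.
        """
        microbes: dict[str, int] = {}
        diseases: dict[str, int] = {}
        pairs: set[tuple[int, int]] = set()
        for m, d in edges:
            mi = microbes.setdefault(m, len(microbes))
            di = diseases.setdefault(d, len(diseases))
            pairs.add((mi, di))
        if not microbes:
            raise InputFormatError("no associations supplied")
        md = np.zeros((len(microbes), len(diseases)), dtype=np.int8)
        for mi, di in pairs:
            md[mi, di] = 1
        return cls(tuple(microbes), tuple(diseases), md)

    def mask(self, pairs: Sequence[tuple[int, int]]) -> "AssociationDataset":
        """Return a copy with the listed known associations set to 0.

        Masking a cell that is already 0 signals a broken cross-validation
        driver and raises :class:`MaskingError`.
        """
        md = np.array(self.MD, dtype=np.int8)
        for i, j in pairs:
            if md[i, j] != 1:
                raise MaskingError(f"pair ({i}, {j}) is not a known association")
            md[i, j] = 0
        return AssociationDataset(self.microbe_names, self.disease_names, md)


@dataclass(frozen=True)
class DegreeSummary:
    """Degree bookkeeping for an association network.

    ``avg_disease_degree`` is associations per disease, ``avg_microbe_degree``
    associations per microbe; both are kept unrounded (display rounding is
    2 decimal places, see :meth:`display`).
    """

    n_microbes: int
    n_diseases: int
    n_associations: int
    avg_disease_degree: float
    avg_microbe_degree: float
    disease_degree_histogram: dict[int, int]
    microbe_degree_histogram: dict[int, int]

    def display(self) -> dict[str, float]:
        """The two averages rounded to 2 decimals, as reported in tables."""
        return {
            "avg_disease_degree": round(self.avg_disease_degree, 2),
            "avg_microbe_degree": round(self.avg_microbe_degree, 2),
        }


def _parse_edge_line(line: str, lineno: int) -> tuple[str, str]:
    fields = line.split("\t")
    if len(fields) != 2:
        raise InputFormatError(
            f"line {lineno}: expected 2 tab-separated fields, got {len(fields)}: {line!r}"
        )
    microbe, disease = (f.strip() for f in fields)
    if not microbe or not disease:
        raise InputFormatError(f"line {lineno}: empty field in {line!r}")
    return microbe, disease


def load_associations(path: str | Path, header: bool = False) -> AssociationDataset:
    """Load a two-column TSV edge list (microbe<TAB>disease).

    Lines starting with ``#`` are comments.  Duplicate rows collapse to one
    association.  Name matching is exact and case-sensitive after trimming
    surrounding whitespace.

    Parameters
    ----------
    header
        If True, the first non-comment line is discarded as a header.
    """
    edges: list[tuple[str, str]] = []
    skipped_header = not header
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n").rstrip("\r")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            if not skipped_header:
                skipped_header = True
                continue
            edges.append(_parse_edge_line(line, lineno))
    if not edges:
        raise InputFormatError(f"{path}: no association rows found")
    return AssociationDataset.from_edges(edges)


def write_associations(ds: AssociationDataset, path: str | Path) -> None:
    """Write the dataset back as the same TSV edge-list dialect.

    Rows are emitted in an order that re-introduces entities in the
    dataset's own first-appearance order, so loading the written file
    round-trips to an identical dataset whenever such an order exists
    (it always does for datasets that were loaded from an edge list).
    """
    remaining = set(ds.known_pairs())
    order: list[tuple[int, int]] = []
    count_m = count_d = 0
    while remaining:
        emittable = sorted(
            p for p in remaining if p[0] <= count_m and p[1] <= count_d
        )
        if not emittable:  # not realizable as an edge sequence; dump the rest
            order.extend(sorted(remaining))
            break
        for i, j in emittable:
            order.append((i, j))
            count_m = max(count_m, i + 1)
            count_d = max(count_d, j + 1)
        remaining.difference_update(emittable)
    with open(path, "w", encoding="utf-8") as fh:
        for i, j in order:
            fh.write(f"{ds.microbe_names[i]}\t{ds.disease_names[j]}\n")


def degree_statistics(ds: AssociationDataset) -> DegreeSummary:
    """Per-side degree averages and histograms.

    The averages satisfy ``avg * n_entities == n_associations`` exactly
    before rounding.  A zero-association dataset yields averages of 0.
    """
    disease_deg = ds.MD.sum(axis=0).astype(int)
    microbe_deg = ds.MD.sum(axis=1).astype(int)
    n_assoc = int(disease_deg.sum())

    def _hist(deg: np.ndarray) -> dict[int, int]:
        vals, counts = np.unique(deg, return_counts=True)
        return dict(zip(vals.tolist(), counts.tolist()))

    return DegreeSummary(
        n_microbes=ds.n_microbes,
        n_diseases=ds.n_diseases,
        n_associations=n_assoc,
        avg_disease_degree=n_assoc / ds.n_diseases if ds.n_diseases else 0.0,
        avg_microbe_degree=n_assoc / ds.n_microbes if ds.n_microbes else 0.0,
        disease_degree_histogram=_hist(disease_deg),
        microbe_degree_histogram=_hist(microbe_deg),
    )


def write_degree_table(ds: AssociationDataset, path: str | Path) -> None:
    """Per-entity degrees as TSV with columns (entity_type, entity_name, degree)."""
    disease_deg = ds.MD.sum(axis=0)
    microbe_deg = ds.MD.sum(axis=1)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("entity_type\tentity_name\tdegree\n")
        for name, deg in zip(ds.microbe_names, microbe_deg):
            fh.write(f"microbe\t{name}\t{int(deg)}\n")
        for name, deg in zip(ds.disease_names, disease_deg):
            fh.write(f"disease\t{name}\t{int(deg)}\n")


def mask_entries(
    ds: AssociationDataset, pairs: Sequence[tuple[int, int]]
) -> AssociationDataset:
    """Functional alias for :meth:`AssociationDataset.mask`."""
    return ds.mask(pairs)
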