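"""Reading, encoding and writing genotype data.

Genotypes are held as unordered diploid allele pairs per individual per
marker.  For analysis they are turned into an allele-presence matrix with one
0/1 column per (marker, allele) pair -- a biallelic SNP contributes two
columns, a k-allele microsatellite k columns -- and the presence matrix is
then zero-mean centered per column and scaled by ``sqrt(q(1-q))`` where ``q``
is the column's presence frequency.  A heterozygote carries a 1 in both of its
marker's columns; a missing call encodes as all zeros across that marker's
columns and therefore contributes to the column frequency.

Supported file dialects:

* PLINK PED (whitespace separated; columns 2 = individual id, 7+ = allele
  pairs; missing allele ``0``; marker ids from a sibling ``.map`` file when
  present),
* STRUCTURE main data files (two rows per individual, one integer allele per
  locus per row, missing ``-9``, optional leading header row of marker names),
* a simple TSV dialect (header row ``id[<tab>label]<tab>marker...``, one
  individual per line, genotypes written ``A/G``, missing ``./.``).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from ippca.exceptions import ParseError, StructuralError, UsageError

MISSING = -1  # allele-code sentinel inside GenotypeTable.calls

__all__ = [
    "MISSING",
    "GenotypeTable",
    "EncodedMatrix",
    "read_genotypes",
    "encode_presence",
    "center_normalize",
    "encode_table",
    "write_genotypes_tsv",
    "write_assignments",
    "export_structure_inputs",
]


@dataclass
class GenotypeTable:
    """Raw diploid calls for ``m`` individuals at ``n_markers`` markers.

    ``calls`` has shape ``(m, n_markers, 2)`` and stores per-marker allele
    *codes*: indices into ``marker_alleles[j]``.  A missing call is
    ``(-1, -1)``.  ``labels`` are optional ethno/geographic tags used only for
    evaluation, never by the algorithm.
    """

    individual_ids: list[str]
    marker_ids: list[str]
    calls: np.ndarray
    marker_alleles: list[list[str]]
    labels: Optional[list[str]] = None

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int16)
        m, nm = len(self.individual_ids), len(self.marker_ids)
        if self.calls.shape != (m, nm, 2):
            raise StructuralError(
                f"calls shape {self.calls.shape} does not match {m} individuals x {nm} markers"
            )
        if len(set(self.individual_ids)) != m:
            raise StructuralError("individual ids are not unique")
        if len(self.marker_alleles) != nm:
            raise StructuralError("marker_alleles length does not match marker_ids")
        if self.labels is not None and len(self.labels) != m:
            raise StructuralError("labels length does not match individual count")

    @property
    def n_individuals(self) -> int:
        return len(self.individual_ids)

    @property
    def n_markers(self) -> int:
        return len(self.marker_ids)

    def is_missing(self) -> np.ndarray:
        """Boolean (m, n_markers) mask of missing calls."""
        return (self.calls < 0).all(axis=2)

    def subset(self, indices: Sequence[int]) -> "GenotypeTable":
        """Row subset preserving order of ``indices``; labels carried along."""
        idx = np.asarray(indices, dtype=int)
        return GenotypeTable(
            individual_ids=[self.individual_ids[i] for i in idx],
            marker_ids=list(self.marker_ids),
            calls=self.calls[idx],
            marker_alleles=[list(a) for a in self.marker_alleles],
            labels=None if self.labels is None else [self.labels[i] for i in idx],
        )

    def call_symbols(self, i: int, j: int) -> tuple[Optional[str], Optional[str]]:
        """The two allele symbols of individual ``i`` at marker ``j`` (None if missing)."""
        a, b = self.calls[i, j]
        if a < 0 or b < 0:
            return (None, None)
        alleles = self.marker_alleles[j]
        return (alleles[a], alleles[b])


@dataclass
class EncodedMatrix:
    """Zero-mean, variance-normalized allele-presence matrix ``X`` (m x n)."""

    values: np.ndarray
    column_index: list[tuple[str, str]]  # column -> (marker_id, allele symbol)
    column_freq: np.ndarray  # pre-centering column means
    m: int
    n: int


# ---------------------------------------------------------------------------
# Parsing
# ---------------------------------------------------------------------------


def _table_from_symbol_calls(
    individual_ids: list[str],
    marker_ids: list[str],
    sym_calls: list[list[tuple[Optional[str], Optional[str]]]],
    labels: Optional[list[str]] = None,
) -> GenotypeTable:
    """Build a GenotypeTable from per-individual lists of allele-symbol pairs.

    Allele sets per marker are discovered from the data, in first-seen order.
    """
    m, nm = len(individual_ids), len(marker_ids)
    marker_alleles: list[list[str]] = [[] for _ in range(nm)]
    lookup: list[dict[str, int]] = [{} for _ in range(nm)]
    calls = np.full((m, nm, 2), MISSING, dtype=np.int16)
    for i in range(m):
        row = sym_calls[i]
        if len(row) != nm:
            raise StructuralError(
                f"individual '{individual_ids[i]}' has {len(row)} calls, expected {nm}"
            )
        for j, (a, b) in enumerate(row):
            if a is None or b is None:
                continue
            codes = []
            for sym in (a, b):
                if sym not in lookup[j]:
                    lookup[j][sym] = len(marker_alleles[j])
                    marker_alleles[j].append(sym)
                codes.append(lookup[j][sym])
            calls[i, j] = codes
    return GenotypeTable(individual_ids, marker_ids, calls, marker_alleles, labels)


def _read_ped(path: Path) -> GenotypeTable:
    ids: list[str] = []
    sym_calls: list[list[tuple[Optional[str], Optional[str]]]] = []
    n_markers: Optional[int] = None
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            tokens = line.split()
            if not tokens:
                continue
            if len(tokens) < 8 or (len(tokens) - 6) % 2 != 0:
                raise ParseError(f"{path}:{lineno}: malformed PED line ({len(tokens)} fields)")
            nm = (len(tokens) - 6) // 2
            if n_markers is None:
                n_markers = nm
            elif nm != n_markers:
                raise StructuralError(
                    f"{path}:{lineno}: {nm} markers, expected {n_markers}"
                )
            ids.append(tokens[1])
            row = []
            for j in range(n_markers):
                a, b = tokens[6 + 2 * j], tokens[7 + 2 * j]
                if a == "0" or b == "0":
                    row.append((None, None))
                else:
                    row.append((a, b))
            sym_calls.append(row)
    if n_markers is None:
        raise ParseError(f"{path}: empty PED file")
    map_path = path.with_suffix(".map")
    if map_path.exists():
        marker_ids = []
        with open(map_path) as fh:
            for lineno, line in enumerate(fh, start=1):
                tokens = line.split()
                if not tokens:
                    continue
                if len(tokens) < 2:
                    raise ParseError(f"{map_path}:{lineno}: malformed MAP line")
                marker_ids.append(tokens[1])
        if len(marker_ids) != n_markers:
            raise StructuralError(
                f"{map_path}: {len(marker_ids)} markers but PED has {n_markers}"
            )
    else:
        marker_ids = [f"M{j + 1}" for j in range(n_markers)]
    return _table_from_symbol_calls(ids, marker_ids, sym_calls)


def _read_structure(path: Path) -> GenotypeTable:
    rows: list[tuple[str, list[str]]] = []
    header: Optional[list[str]] = None
    with open(path) as fh:
        lines = [(no, ln.split()) for no, ln in enumerate(fh, start=1) if ln.split()]
    if not lines:
        raise ParseError(f"{path}: empty STRUCTURE file")
    # optional header row of marker names: one token fewer than data rows
    body = lines
    if len(lines) >= 2 and len(lines[0][1]) == len(lines[1][1]) - 1:
        header = lines[0][1]
        body = lines[1:]
    n_tok: Optional[int] = None
    for lineno, tokens in body:
        if n_tok is None:
            n_tok = len(tokens)
            if n_tok < 2:
                raise ParseError(f"{path}:{lineno}: malformed STRUCTURE line")
        elif len(tokens) != n_tok:
            raise StructuralError(
                f"{path}:{lineno}: {len(tokens)} fields, expected {n_tok}"
            )
        rows.append((tokens[0], tokens[1:]))
    if len(rows) % 2 != 0:
        raise StructuralError(f"{path}: odd number of data rows (two expected per individual)")
    nm = n_tok - 1
    marker_ids = header if header is not None else [f"M{j + 1}" for j in range(nm)]
    if len(marker_ids) != nm:
        raise StructuralError(f"{path}: header names {len(marker_ids)} markers, data has {nm}")
    ids: list[str] = []
    sym_calls: list[list[tuple[Optional[str], Optional[str]]]] = []
    for k in range(0, len(rows), 2):
        (id1, first), (id2, second) = rows[k], rows[k + 1]
        if id1 != id2:
            raise StructuralError(
                f"{path}: rows {k + 1}/{k + 2} pair individuals '{id1}' and '{id2}'"
            )
        ids.append(id1)
        row = []
        for a, b in zip(first, second):
            if a == "-9" or b == "-9":
                row.append((None, None))
            else:
                row.append((a, b))
        sym_calls.append(row)
    return _table_from_symbol_calls(ids, marker_ids, sym_calls)


def _read_tsv(path: Path) -> GenotypeTable:
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh]
    lines = [ln for ln in lines if ln.strip()]
    if not lines:
        raise ParseError(f"{path}: empty TSV file")
    header = lines[0].split("\t")
    if not header or header[0] != "id":
        raise ParseError(f"{path}:1: TSV header must start with 'id'")
    has_label = len(header) > 1 and header[1] == "label"
    first_marker = 2 if has_label else 1
    marker_ids = header[first_marker:]
    if not marker_ids:
        raise ParseError(f"{path}:1: TSV header names no markers")
    ids: list[str] = []
    labels: list[str] = []
    sym_calls: list[list[tuple[Optional[str], Optional[str]]]] = []
    for lineno, ln in enumerate(lines[1:], start=2):
        fields = ln.split("\t")
        if len(fields) != len(header):
            raise StructuralError(
                f"{path}:{lineno}: {len(fields)} fields, expected {len(header)}"
            )
        ids.append(fields[0])
        if has_label:
            labels.append(fields[1])
        row = []
        for g in fields[first_marker:]:
            if g == "./.":
                row.append((None, None))
            else:
                parts = g.split("/")
                if len(parts) != 2 or not parts[0] or not parts[1]:
                    raise ParseError(f"{path}:{lineno}: malformed genotype '{g}'")
                row.append((parts[0], parts[1]))
        sym_calls.append(row)
    return _table_from_symbol_calls(ids, marker_ids, sym_calls, labels if has_label else None)


_READERS = {"ped": _read_ped, "structure": _read_structure, "tsv": _read_tsv}


def read_genotypes(path, format: str) -> GenotypeTable:
    """Read a genotype file in the named dialect (``ped``, ``structure`` or ``tsv``)."""
    if format not in _READERS:
        raise UsageError(f"unknown format '{format}' (expected ped, structure or tsv)")
    p = Path(path)
    if not p.exists():
        raise UsageError(f"no such file: {p}")
    return _READERS[format](p)


# ---------------------------------------------------------------------------
# Encoding
# ---------------------------------------------------------------------------


def encode_presence(table: GenotypeTable) -> tuple[np.ndarray, list[tuple[str, str]]]:
    """Allele-presence 0/1 matrix: one column per (marker, allele).

    Entry 1 iff the individual carries at least one copy of the allele;
    a missing call gives zeros across all of that marker's columns.  Markers
    with no observed alleles (all calls missing) contribute no columns and are
    reported with a warning.
    """
    m = table.n_individuals
    counts = [len(a) for a in table.marker_alleles]
    dead = [table.marker_ids[j] for j, c in enumerate(counts) if c == 0]
    if dead:
        warnings.warn(
            f"dropped {len(dead)} marker(s) with no observed alleles: {', '.join(dead[:5])}"
            + ("..." if len(dead) > 5 else "")
        )
    offsets = np.concatenate([[0], np.cumsum(counts)])
    ncol = int(offsets[-1])
    column_index = [
        (table.marker_ids[j], sym)
        for j in range(table.n_markers)
        for sym in table.marker_alleles[j]
    ]
    P = np.zeros((m, ncol), dtype=np.float64)
    calls = table.calls  # (m, nm, 2)
    valid = calls >= 0
    cols = offsets[:-1][None, :, None] + calls  # may be junk where invalid
    rows = np.broadcast_to(np.arange(m)[:, None, None], calls.shape)
    P[rows[valid], cols[valid]] = 1.0
    return P, column_index


def center_normalize(
    presence: np.ndarray, column_index: Optional[list[tuple[str, str]]] = None
) -> EncodedMatrix:
    """Center each presence column to zero mean and scale by ``sqrt(q(1-q))``.

    ``q`` is the column mean of the 0/1 indicator over all individuals
    (missing calls having been encoded as zeros beforehand).  Degenerate
    columns (``q`` of 0 or 1) are set identically to zero so that monomorphic
    markers contribute nothing to the covariance while keeping the column
    index stable.
    """
    P = np.asarray(presence, dtype=np.float64)
    m, n = P.shape
    q = P.mean(axis=0)
    X = np.zeros_like(P)
    live = (q > 0.0) & (q < 1.0)
    X[:, live] = (P[:, live] - q[live]) / np.sqrt(q[live] * (1.0 - q[live]))
    if column_index is None:
        column_index = [("", "")] * n
    return EncodedMatrix(values=X, column_index=list(column_index), column_freq=q, m=m, n=n)


def encode_table(table: GenotypeTable) -> EncodedMatrix:
    """Convenience pipeline: presence encoding followed by centering/normalization."""
    P, column_index = encode_presence(table)
    return center_normalize(P, column_index)


# ---------------------------------------------------------------------------
# Writing
# ---------------------------------------------------------------------------


def write_genotypes_tsv(table: GenotypeTable, path) -> None:
    """Write the TSV dialect read back by ``read_genotypes(..., 'tsv')``."""
    with open(path, "w") as fh:
        cols = ["id"] + (["label"] if table.labels is not None else []) + list(table.marker_ids)
        fh.write("\t".join(cols) + "\n")
        for i, ind in enumerate(table.individual_ids):
            fields = [ind]
            if table.labels is not None:
                fields.append(table.labels[i])
            for j in range(table.n_markers):
                a, b = table.call_symbols(i, j)
                fields.append("./." if a is None else f"{a}/{b}")
            fh.write("\t".join(fields) + "\n")


def write_assignments(tree, table: GenotypeTable, tsv_path, tree_json_path=None) -> None:
    """Write per-individual assignments as TSV, optionally plus the split tree as JSON.

    Columns: ``individual_id``, ``subpopulation`` (SP1..SPK in depth-first
    discovery order) and, when the table carries labels, ``label``.
    """
    assignment = tree.assignment
    missing = [i for i in table.individual_ids if i not in assignment]
    if missing:
        raise StructuralError(f"{len(missing)} individual(s) missing from assignment")
    with open(tsv_path, "w") as fh:
        cols = ["individual_id", "subpopulation"] + (["label"] if table.labels is not None else [])
        fh.write("\t".join(cols) + "\n")
        for i, ind in enumerate(table.individual_ids):
            fields = [ind, assignment[ind]]
            if table.labels is not None:
                fields.append(table.labels[i])
            fh.write("\t".join(fields) + "\n")
    if tree_json_path is not None:
        with open(tree_json_path, "w") as fh:
            json.dump(tree.to_dict(), fh, indent=1)
            fh.write("\n")


def export_structure_inputs(tree, table: GenotypeTable, leaves: Sequence[str], path) -> None:
    """Write one STRUCTURE main-data file holding the union of the selected leaves.

    Alleles are recoded to integers 1..k per marker (discovery order), missing
    is -9, two rows per diploid individual, with a leading header row of
    marker names.
    """
    if not leaves:
        raise UsageError("empty leaf selection")
    known = {leaf.leaf_label for leaf in tree.leaves()}
    unknown = [s for s in leaves if s not in known]
    if unknown:
        raise UsageError(f"unknown leaf label(s): {', '.join(unknown)}")
    selected = set(leaves)
    assignment = tree.assignment
    keep = [
        i for i, ind in enumerate(table.individual_ids) if assignment.get(ind) in selected
    ]
    with open(path, "w") as fh:
        fh.write(" ".join(table.marker_ids) + "\n")
        for i in keep:
            for slot in (0, 1):
                fields = [table.individual_ids[i]]
                for j in range(table.n_markers):
                    code = table.calls[i, j, slot]
                    fields.append("-9" if code < 0 else str(int(code) + 1))
                fh.write(" ".join(fields) + "\n")
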