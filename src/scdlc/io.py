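"""Readers/writers for count matrices, labels, rankings and run manifests.

Dense TSV layout: genes in rows, header row of cell ids, first column gene
ids (GEO convention). Sparse layout: MatrixMarket ``.mtx`` triplet with
``genes.tsv``/``barcodes.tsv`` sidecars in the same directory. Labels are a
two-column TSV (cell_id, class_name). All write->read round trips are
bit-exact.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import scipy.io
import scipy.sparse

from .simulate import ClassLabels, CountMatrix

__all__ = [
    "DatasetBundle",
    "read_counts",
    "write_counts_tsv",
    "write_counts_mtx",
    "read_labels",
    "write_labels",
    "bundle_dataset",
    "write_ranking",
    "write_simulation_metadata",
]


class ParseError(ValueError):
    """Malformed input file; message carries file and line context."""


@dataclass
class DatasetBundle:
    """Counts and labels joined one-to-one by cell id."""

    counts: CountMatrix
    labels: ClassLabels
    provenance: dict


def _checksum(counts: np.ndarray) -> str:
    return hashlib.sha256(np.ascontiguousarray(counts).tobytes()).hexdigest()[:16]


def write_counts_tsv(path, matrix: CountMatrix) -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write("gene_id\t" + "\t".join(matrix.cell_ids) + "\n")
        for gid, row in zip(matrix.gene_ids, matrix.counts):
            fh.write(gid + "\t" + "\t".join(str(int(v)) for v in row) + "\n")


def write_counts_mtx(path, matrix: CountMatrix) -> None:
    """MatrixMarket triplet plus genes.tsv / barcodes.tsv sidecars."""
    path = Path(path)
    sparse = scipy.sparse.coo_matrix(matrix.counts)
    scipy.io.mmwrite(str(path), sparse, field="integer")
    (path.parent / "genes.tsv").write_text("\n".join(matrix.gene_ids) + "\n")
    (path.parent / "barcodes.tsv").write_text("\n".join(matrix.cell_ids) + "\n")


def _parse_int(token: str, path, line_no: int, col: int) -> int:
    try:
        value = int(token)
    except ValueError:
        try:
            f = float(token)
        except ValueError:
            raise ParseError(
                f"{path}:{line_no}: column {col}: non-numeric count {token!r}"
            ) from None
        raise ParseError(
            f"{path}:{line_no}: column {col}: non-integer count {token!r}"
        ) from None
    if value < 0:
        raise ParseError(f"{path}:{line_no}: column {col}: negative count {value}")
    return value


def _read_counts_tsv(path: Path, transpose: bool) -> CountMatrix:
    with path.open() as fh:
        header = fh.readline().rstrip("\n")
        if not header:
            raise ParseError(f"{path}:1: empty file")
        cells = header.split("\t")[1:]
        width = len(cells) + 1
        gene_ids: list[str] = []
        rows: list[list[int]] = []
        seen: set[str] = set()
        for line_no, line in enumerate(fh, start=2):
            tokens = line.rstrip("\n").split("\t")
            if line.strip() == "":
                continue
            if len(tokens) != width:
                raise ParseError(
                    f"{path}:{line_no}: ragged row ({len(tokens)} fields, expected {width})"
                )
            gid = tokens[0]
            if gid in seen:
                raise ParseError(f"{path}:{line_no}: duplicate gene id {gid!r}")
            seen.add(gid)
            gene_ids.append(gid)
            rows.append(
                [_parse_int(tok, path, line_no, c + 2) for c, tok in enumerate(tokens[1:])]
            )
    counts = np.array(rows, dtype=np.int64)
    if transpose:
        counts, gene_ids, cells = counts.T, cells, gene_ids
    return CountMatrix(counts=counts, gene_ids=list(gene_ids), cell_ids=list(cells))


def _read_counts_mtx(path: Path, transpose: bool) -> CountMatrix:
    raw = scipy.io.mmread(str(path))
    dense = np.asarray(raw.todense() if scipy.sparse.issparse(raw) else raw)
    if not np.all(dense == np.floor(dense)):
        bad = np.argwhere(dense != np.floor(dense))[0]
        raise ParseError(f"{path}: non-integer count at entry ({bad[0] + 1}, {bad[1] + 1})")
    if np.any(dense < 0):
        bad = np.argwhere(dense < 0)[0]
        raise ParseError(f"{path}: negative count at entry ({bad[0] + 1}, {bad[1] + 1})")
    dense = dense.astype(np.int64)
    genes_path = path.parent / "genes.tsv"
    cells_path = path.parent / "barcodes.tsv"
    for p in (genes_path, cells_path):
        if not p.exists():
            raise ParseError(f"missing MTX sidecar {p}")
    gene_ids = [ln.split("\t")[0] for ln in genes_path.read_text().splitlines() if ln.strip()]
    cell_ids = [ln.split("\t")[0] for ln in cells_path.read_text().splitlines() if ln.strip()]
    if len(set(gene_ids)) != len(gene_ids):
        raise ParseError(f"{genes_path}: duplicate gene ids")
    if transpose:
        dense, gene_ids, cell_ids = dense.T, cell_ids, gene_ids
    if dense.shape != (len(gene_ids), len(cell_ids)):
        raise ParseError(
            f"{path}: matrix shape {dense.shape} does not match sidecars "
            f"({len(gene_ids)} genes, {len(cell_ids)} cells)"
        )
    return CountMatrix(counts=dense, gene_ids=gene_ids, cell_ids=cell_ids)


def read_counts(path, format: str = "auto", transpose: bool = False) -> CountMatrix:
    """Read a count matrix from dense TSV or MatrixMarket MTX.

    ``format='auto'`` picks by extension (.mtx -> MatrixMarket, otherwise
    TSV). ``transpose`` handles cells-in-rows files.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "auto":
        format = "mtx" if path.suffix == ".mtx" else "tsv"
    if format == "tsv":
        return _read_counts_tsv(path, transpose)
    if format == "mtx":
        return _read_counts_mtx(path, transpose)
    raise ValueError(f"unknown format {format!r}; expected auto|tsv|mtx")


def write_labels(path, matrix: CountMatrix, labels: ClassLabels) -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write("cell_id\tclass_name\n")
        for cid, code in zip(matrix.cell_ids, labels.labels):
            fh.write(f"{cid}\t{labels.class_names[code]}\n")


def read_labels(path) -> dict[str, str]:
    """cell_id -> class_name mapping; header row optional."""
    path = Path(path)
    mapping: dict[str, str] = {}
    with path.open() as fh:
        for line_no, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            tokens = line.rstrip("\n").split("\t")
            if len(tokens) != 2:
                raise ParseError(
                    f"{path}:{line_no}: expected 2 tab-separated fields, got {len(tokens)}"
                )
            cid, cname = tokens
            if line_no == 1 and cid.lower() in ("cell_id", "cell", "barcode"):
                continue
            if cid in mapping:
                raise ParseError(f"{path}:{line_no}: duplicate cell id {cid!r}")
            mapping[cid] = cname
    if not mapping:
        raise ParseError(f"{path}: no label rows")
    return mapping


def bundle_dataset(matrix: CountMatrix, label_map: dict[str, str], provenance: dict | None = None) -> DatasetBundle:
    """Join counts and labels by cell id (order-independent).

    Class names map to codes in first-appearance order along the count
    matrix's cell ordering; user-facing indices are 1-based.
    """
    missing = [c for c in matrix.cell_ids if c not in label_map]
    if missing:
        raise ValueError(f"cells missing from labels: {missing[:10]}")
    extra = sorted(set(label_map) - set(matrix.cell_ids))
    if extra:
        raise ValueError(f"labelled cells missing from counts: {extra[:10]}")
    class_names: list[str] = []
    codes = []
    for cid in matrix.cell_ids:
        cname = label_map[cid]
        if cname not in class_names:
            class_names.append(cname)
        codes.append(class_names.index(cname))
    labels = ClassLabels(labels=np.array(codes), class_names=class_names)
    prov = dict(provenance or {})
    prov["counts_checksum"] = _checksum(matrix.counts)
    return DatasetBundle(counts=matrix, labels=labels, provenance=prov)


def write_ranking(path_prefix, ranking) -> None:
    """Ranking as TSV (gene_id, bw_score, rank) and a JSON mirror."""
    prefix = Path(path_prefix)
    gene_ids = ranking.gene_ids or [f"gene{j + 1}" for j in range(ranking.bw_scores.size)]
    with open(f"{prefix}.tsv", "w") as fh:
        fh.write("gene_id\tbw_score\trank\n")
        for rank, j in enumerate(ranking.order, start=1):
            fh.write(f"{gene_ids[j]}\t{ranking.bw_scores[j]:.10g}\t{rank}\n")
    payload = {
        "p": int(ranking.p),
        "selected": [int(j) for j in ranking.selected],
        "selected_gene_ids": [gene_ids[j] for j in ranking.selected],
        "bw_scores": [float(s) for s in ranking.bw_scores],
        "order": [int(j) for j in ranking.order],
    }
    with open(f"{prefix}.json", "w") as fh:
        json.dump(payload, fh, indent=1)


def write_simulation_metadata(path, matrix: CountMatrix) -> None:
    with open(path, "w") as fh:
        json.dump(matrix.metadata, fh, indent=1)
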