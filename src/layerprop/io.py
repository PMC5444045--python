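"""Delimited-text readers and writers, plus run manifests.

All formats are tab-separated with a header row:

* nodes.tsv           — layer, node_id (row order defines node order)
* intra_edges.tsv     — layer, node_a, node_b, weight (undirected, once per pair)
* inter_edges.tsv     — layer_a, node_a, layer_b, node_b, weight
* cooccurrence.tsv    — disease_a, disease_b
* labels / scores     — layer, node_id, value

Weights are written with 17 significant digits so a write/read round trip
reproduces every float bitwise. Sparse triplet blocks (row, col, value) with
a sidecar node-order file are accepted as an alternative intra/inter block
source.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from datetime import datetime, timezone
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np

from .comorbidity import CooccurrenceTable
from .kernels import BitProfileMatrix
from .network import Layer, MultiLayerNetwork, assemble
from .propagation import LabelVector, ScoreVector

_FLOAT_FMT = "{:.17g}"


class MalformedFileError(ValueError):
    """A delimited input file failed to parse; message names file and line."""

    def __init__(self, path: str | Path, line_no: int, message: str):
        super().__init__(f"{path}:{line_no}: {message}")
        self.path = str(path)
        self.line_no = line_no


def _read_rows(path: str | Path, n_cols: int, header: str) -> Iterable[tuple[int, list[str]]]:
    path = Path(path)
    with path.open() as fh:
        first = fh.readline()
        if not first:
            raise MalformedFileError(path, 1, "empty file")
        if first.rstrip("\n").split("\t") != header.split("\t"):
            raise MalformedFileError(path, 1, f"expected header {header!r}")
        for line_no, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != n_cols:
                raise MalformedFileError(
                    path, line_no, f"expected {n_cols} columns, found {len(parts)}"
                )
            yield line_no, parts


def _parse_weight(path: Path, line_no: int, text: str) -> float:
    try:
        return float(text)
    except ValueError:
        raise MalformedFileError(path, line_no, f"bad weight {text!r}") from None


# ---------------------------------------------------------------- networks


def write_network(network: MultiLayerNetwork, directory: str | Path) -> dict[str, Path]:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    nodes = directory / "nodes.tsv"
    with nodes.open("w") as fh:
        fh.write("layer\tnode_id\n")
        for lay in network.layers:
            for nid in lay.node_ids:
                fh.write(f"{lay.name}\t{nid}\n")
    intra = directory / "intra_edges.tsv"
    with intra.open("w") as fh:
        fh.write("layer\tnode_a\tnode_b\tweight\n")
        for lay, blk in zip(network.layers, network.intra_blocks):
            for i in range(lay.size):
                for j in range(i + 1, lay.size):
                    if blk[i, j] != 0:
                        fh.write(
                            f"{lay.name}\t{lay.node_ids[i]}\t{lay.node_ids[j]}\t"
                            + _FLOAT_FMT.format(blk[i, j])
                            + "\n"
                        )
    inter = directory / "inter_edges.tsv"
    with inter.open("w") as fh:
        fh.write("layer_a\tnode_a\tlayer_b\tnode_b\tweight\n")
        for k, blk in enumerate(network.inter_blocks):
            la, lb = network.layers[k], network.layers[k + 1]
            for i in range(la.size):
                for j in range(lb.size):
                    if blk[i, j] != 0:
                        fh.write(
                            f"{la.name}\t{la.node_ids[i]}\t{lb.name}\t{lb.node_ids[j]}\t"
                            + _FLOAT_FMT.format(blk[i, j])
                            + "\n"
                        )
    return {"nodes": nodes, "intra_edges": intra, "inter_edges": inter}


def load_network(directory: str | Path) -> MultiLayerNetwork:
    directory = Path(directory)
    layer_nodes: dict[str, list[str]] = {}
    for _ln, (layer, nid) in _read_rows(directory / "nodes.tsv", 2, "layer\tnode_id"):
        layer_nodes.setdefault(layer, []).append(nid)
    layers = [Layer(name, tuple(ids)) for name, ids in layer_nodes.items()]

    intra: dict[str, list[tuple[str, str, float]]] = {}
    path = directory / "intra_edges.tsv"
    if path.exists():
        for ln, (layer, a, b, w) in _read_rows(path, 4, "layer\tnode_a\tnode_b\tweight"):
            intra.setdefault(layer, []).append((a, b, _parse_weight(path, ln, w)))
    inter: dict[tuple[str, str], list[tuple[str, str, float]]] = {}
    path = directory / "inter_edges.tsv"
    if path.exists():
        for ln, (la, a, lb, b, w) in _read_rows(
            path, 5, "layer_a\tnode_a\tlayer_b\tnode_b\tweight"
        ):
            inter.setdefault((la, lb), []).append((a, b, _parse_weight(path, ln, w)))
    return assemble(layers, intra, inter)


def load_block_triplets(
    path: str | Path, row_order: Iterable[str], col_order: Iterable[str]
) -> np.ndarray:
    """Read a sparse (row, col, value) triplet file into a dense block.

    ``row_order``/``col_order`` come from sidecar node-order files (one id per
    line, :func:`load_node_order`)."""
    rows = {r: i for i, r in enumerate(row_order)}
    cols = {c: j for j, c in enumerate(col_order)}
    blk = np.zeros((len(rows), len(cols)))
    path = Path(path)
    for ln, (r, c, v) in _read_rows(path, 3, "row\tcol\tvalue"):
        if r not in rows:
            raise MalformedFileError(path, ln, f"unknown row id {r!r}")
        if c not in cols:
            raise MalformedFileError(path, ln, f"unknown col id {c!r}")
        blk[rows[r], cols[c]] = _parse_weight(path, ln, v)
    return blk


def load_node_order(path: str | Path) -> list[str]:
    return [line.strip() for line in Path(path).read_text().splitlines() if line.strip()]


# ------------------------------------------------- labels, scores, tables


def write_labels(
    network: MultiLayerNetwork, labels: LabelVector, path: str | Path
) -> Path:
    path = Path(path)
    with path.open("w") as fh:
        fh.write("layer\tnode_id\tlabel\n")
        for (lname, nid), val in zip(network.global_node_ids(), labels.values):
            fh.write(f"{lname}\t{nid}\t" + _FLOAT_FMT.format(val) + "\n")
    return path


def load_labels(network: MultiLayerNetwork, path: str | Path) -> LabelVector:
    values = np.zeros(network.total_size)
    path = Path(path)
    for ln, (lname, nid, val) in _read_rows(path, 3, "layer\tnode_id\tlabel"):
        try:
            idx = network.node_index(lname, nid)
        except KeyError:
            raise MalformedFileError(path, ln, f"unknown node {lname}/{nid}") from None
        values[idx] = _parse_weight(path, ln, val)
    return LabelVector(values)


def write_scores(
    network: MultiLayerNetwork, scores: ScoreVector, path: str | Path
) -> Path:
    path = Path(path)
    with path.open("w") as fh:
        fh.write("layer\tnode_id\tscore\n")
        for (lname, nid), val in zip(network.global_node_ids(), scores.values):
            fh.write(f"{lname}\t{nid}\t" + _FLOAT_FMT.format(val) + "\n")
    return path


def load_scores(network: MultiLayerNetwork, path: str | Path) -> ScoreVector:
    values = np.zeros(network.total_size)
    path = Path(path)
    for ln, (lname, nid, val) in _read_rows(path, 3, "layer\tnode_id\tscore"):
        values[network.node_index(lname, nid)] = _parse_weight(path, ln, val)
    return ScoreVector(values)


def write_cooccurrence(table: CooccurrenceTable, path: str | Path) -> Path:
    path = Path(path)
    with path.open("w") as fh:
        fh.write("disease_a\tdisease_b\n")
        for a, b in sorted(table.pairs):
            fh.write(f"{a}\t{b}\n")
    return path


def load_cooccurrence(path: str | Path) -> CooccurrenceTable:
    pairs = [(a, b) for _ln, (a, b) in _read_rows(path, 2, "disease_a\tdisease_b")]
    return CooccurrenceTable(pairs)


def load_bit_profiles(path: str | Path) -> BitProfileMatrix:
    """Read a dense binary incidence table: header 'entity_id<TAB>f1<TAB>f2...'."""
    path = Path(path)
    with path.open() as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if len(header) < 2 or header[0] != "entity_id":
            raise MalformedFileError(path, 1, "expected header entity_id<TAB>feature...")
        features = tuple(header[1:])
        entities, rows = [], []
        for line_no, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != len(header):
                raise MalformedFileError(
                    path, line_no, f"expected {len(header)} columns, found {len(parts)}"
                )
            entities.append(parts[0])
            try:
                rows.append([int(x) for x in parts[1:]])
            except ValueError:
                raise MalformedFileError(path, line_no, "non-integer profile entry") from None
    return BitProfileMatrix(tuple(entities), features, np.array(rows))


# -------------------------------------------------------------- manifests


def sha256_file(path: str | Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


@dataclass
class RunManifest:
    """Record of one run: command, parameters, seeds and input checksums."""

    command: str
    parameters: dict
    seed: int | None
    input_checksums: dict[str, str]
    version: str
    timestamp: str

    @classmethod
    def create(
        cls,
        command: str,
        parameters: Mapping,
        seed: int | None,
        inputs: Mapping[str, str | Path] = (),
    ) -> "RunManifest":
        from . import __version__

        return cls(
            command=command,
            parameters=dict(parameters),
            seed=seed,
            input_checksums={k: sha256_file(v) for k, v in dict(inputs).items()},
            version=__version__,
            timestamp=datetime.now(timezone.utc).isoformat(),
        )

    def write(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(json.dumps(self.__dict__, indent=2, default=str) + "\n")
        return path


def load_manifest(path: str | Path) -> RunManifest:
    data = json.loads(Path(path).read_text())
    return RunManifest(**data)
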