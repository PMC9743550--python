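"""Readers and writers for matrices, label tables, ROI tables and trees.

Matrices travel as delimited text (CSV/TSV autodetected by extension, header
row of feature ids, first column of observation ids) or as a simple binary
container (a ``.npy`` array next to a small JSON sidecar carrying the ids
and optional coordinates). Trees are serialised to a versioned JSON schema
in which feature masks appear as explicit feature-id lists and observation
membership is stored only at the leaves.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .config import DivikConfig
from .core import DivikNode, DivikTree
from .data import AbundanceMatrix, LabelVector
from .evaluation import RoiAnnotation

TREE_SCHEMA_VERSION = "1"


class SchemaError(ValueError):
    """Raised for unknown or malformed serialised documents."""


def read_matrix(path: str | Path, format: str | None = None) -> AbundanceMatrix:
    """Read an abundance matrix from delimited text or the binary container.

    ``format`` is ``"csv"``, ``"tsv"`` or ``"npy"``; by default it is
    inferred from the file extension.
    """
    path = Path(path)
    fmt = format or ("npy" if path.suffix == ".npy" else path.suffix.lstrip(".").lower() or "csv")
    if fmt == "npy":
        values = np.load(path)
        sidecar = path.with_suffix(".json")
        if not sidecar.exists():
            raise SchemaError(f"binary container requires sidecar {sidecar}")
        meta = json.loads(sidecar.read_text())
        coords = np.asarray(meta["coords"], dtype=int) if meta.get("coords") is not None else None
        if list(values.shape) != meta.get("shape"):
            raise SchemaError("sidecar shape does not match the array")
        return AbundanceMatrix(values, meta["feature_ids"], meta["obs_ids"], coords=coords)
    if fmt in {"csv", "tsv", "tab", "txt"}:
        sep = "\t" if fmt in {"tsv", "tab", "txt"} else ","
        try:
            frame = pd.read_csv(path, sep=sep, index_col=0)
        except (pd.errors.ParserError, pd.errors.EmptyDataError) as exc:
            raise SchemaError(f"malformed matrix file {path}: {exc}") from exc
        if frame.shape[1] == 0:
            raise SchemaError(f"no feature columns found in {path}")
        values = frame.to_numpy(dtype=float)
        return AbundanceMatrix(
            values, [str(c) for c in frame.columns], [str(i) for i in frame.index]
        )
    raise ValueError(f"unknown matrix format {fmt!r}")


def write_matrix(m: AbundanceMatrix, path: str | Path, format: str | None = None) -> None:
    """Write a matrix as delimited text or the binary container (+ sidecar)."""
    path = Path(path)
    fmt = format or ("npy" if path.suffix == ".npy" else path.suffix.lstrip(".").lower() or "csv")
    if fmt == "npy":
        np.save(path, m.values)
        sidecar = path.with_suffix(".json")
        meta = {
            "shape": list(m.values.shape),
            "feature_ids": m.feature_ids,
            "obs_ids": m.obs_ids,
            "coords": m.coords.tolist() if m.coords is not None else None,
        }
        sidecar.write_text(json.dumps(meta, sort_keys=True))
        return
    sep = "\t" if fmt in {"tsv", "tab", "txt"} else ","
    frame = pd.DataFrame(m.values, index=m.obs_ids, columns=m.feature_ids)
    frame.to_csv(path, sep=sep)


def read_labels(path: str | Path) -> tuple[list[str], LabelVector]:
    """Read a two-column (obs_id, label) TSV; returns ids and labels."""
    frame = pd.read_csv(path, sep="\t", dtype=str)
    if frame.shape[1] < 2:
        raise SchemaError("labels table needs obs_id and label columns")
    ids = frame.iloc[:, 0].tolist()
    raw = frame.iloc[:, 1]
    try:
        labels = raw.astype(int).to_numpy()
        names = None
    except ValueError:
        uniq = sorted(raw.unique())
        lut = {u: i for i, u in enumerate(uniq)}
        labels = raw.map(lut).to_numpy()
        names = {i: u for u, i in lut.items()}
    return ids, LabelVector(labels, names=names)


def write_labels(obs_ids: list[str], labels: LabelVector, path: str | Path) -> None:
    frame = pd.DataFrame({"obs_id": obs_ids, "label": labels.labels})
    frame.to_csv(path, sep="\t", index=False)


def read_roi_table(path: str | Path, roi_names: list[str] | None = None) -> tuple[list[str], RoiAnnotation]:
    """Read a two-column (obs_id, roi_name) TSV.

    ``roi_names`` fixes the ROI priority order; by default ROIs are taken in
    order of first appearance.
    """
    frame = pd.read_csv(path, sep="\t", dtype=str)
    if frame.shape[1] < 2:
        raise SchemaError("ROI table needs obs_id and roi_name columns")
    ids = frame.iloc[:, 0].tolist()
    roi_of = frame.iloc[:, 1].to_numpy(dtype=object)
    if roi_names is None:
        seen: list[str] = []
        for r in roi_of:
            if r not in seen and r != "other":
                seen.append(r)
        roi_names = seen
    return ids, RoiAnnotation(roi_of=roi_of, roi_names=roi_names)


def _node_to_dict(node: DivikNode, pool_ids: list[str]) -> dict:
    doc = {
        "node_id": node.node_id,
        "feature_ids": [f for f, keep in zip(pool_ids, node.feature_mask) if keep],
        "k": node.k,
        "stop_reason": node.stop_reason,
        "dunn": node.dunn,
        "children": [_node_to_dict(c, pool_ids) for c in node.children],
    }
    if not node.children:
        doc["obs_index"] = [int(i) for i in node.obs_index]
    return doc


def write_tree(tree: DivikTree, path: str | Path) -> None:
    """Serialise a segmentation tree to versioned JSON."""
    pool_ids = [
        f for f, keep in zip(tree.feature_ids, tree.global_abundance_mask) if keep
    ]
    doc = {
        "schema_version": TREE_SCHEMA_VERSION,
        "config": tree.config.model_dump(),
        "feature_ids": tree.feature_ids,
        "obs_ids": tree.obs_ids,
        "global_kept_feature_ids": pool_ids,
        "root": _node_to_dict(tree.root, pool_ids),
    }
    Path(path).write_text(json.dumps(doc, sort_keys=True, separators=(",", ":")))


def _node_from_dict(doc: dict, pool_index: dict[str, int]) -> DivikNode:
    for key in ("node_id", "feature_ids", "stop_reason", "children"):
        if key not in doc:
            raise SchemaError(f"tree node missing field {key!r}")
    mask = np.zeros(len(pool_index), dtype=bool)
    for f in doc["feature_ids"]:
        mask[pool_index[f]] = True
    children = [_node_from_dict(c, pool_index) for c in doc["children"]]
    if children:
        # children hold ascending indices, so sorting restores the original
        obs_index = np.sort(np.concatenate([c.obs_index for c in children]))
    else:
        obs_index = np.asarray(doc.get("obs_index", []), dtype=int)
    return DivikNode(
        node_id=doc["node_id"],
        obs_index=obs_index,
        feature_mask=mask,
        k=doc.get("k"),
        children=children,
        stop_reason=doc.get("stop_reason"),
        dunn=doc.get("dunn"),
    )


def read_tree(path: str | Path) -> DivikTree:
    """Read a segmentation tree written by :func:`write_tree`."""
    doc = json.loads(Path(path).read_text())
    if doc.get("schema_version") != TREE_SCHEMA_VERSION:
        raise SchemaError(
            f"unknown tree schema version {doc.get('schema_version')!r}"
        )
    pool_ids = doc["global_kept_feature_ids"]
    pool_index = {f: i for i, f in enumerate(pool_ids)}
    kept = set(pool_ids)
    global_mask = np.array([f in kept for f in doc["feature_ids"]], dtype=bool)
    root = _node_from_dict(doc["root"], pool_index)
    return DivikTree(
        root=root,
        config=DivikConfig(**doc["config"]),
        global_abundance_mask=global_mask,
        feature_ids=doc["feature_ids"],
        obs_ids=doc["obs_ids"],
    )


def write_feature_list(feature_ids: list[str], path: str | Path) -> None:
    Path(path).write_text("\n".join(feature_ids) + ("\n" if feature_ids else ""))
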