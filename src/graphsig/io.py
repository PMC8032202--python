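"""Text serialization of signatures, embeddings and bundles.

Signature matrices and embeddings go to TSV with a JSON sidecar recording
the parameters; observation bundles go to a directory of per-bundle TSV
matrices plus a JSON manifest.  Floats are written with 12 significant
digits.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .embedding import EmbeddingResult, SignatureMatrix
from .signatures import ObservationBundle

__all__ = [
    "write_signatures",
    "read_signatures",
    "write_embedding",
    "read_embedding",
    "write_bundles",
    "read_bundles",
]

_FLOAT_FMT = "%.12g"


def _sidecar(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def write_signatures(sigs: SignatureMatrix, path: str | Path,
                     feature_names: Sequence[str] | None = None,
                     **params) -> None:
    path = Path(path)
    m = sigs.rows.shape[1]
    columns = list(feature_names) if feature_names else [f"f{j}" for j in range(m)]
    frame = pd.DataFrame(sigs.rows, columns=columns)
    frame.insert(0, "point_id",
                 sigs.point_ids or [str(i) for i in range(sigs.n_points)])
    if sigs.group_ids is not None:
        frame.insert(1, "group_id", list(sigs.group_ids))
    frame.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)
    meta = {"kind": sigs.kind, **params}
    _sidecar(path).write_text(json.dumps(meta, indent=2))


def read_signatures(path: str | Path) -> SignatureMatrix:
    path = Path(path)
    frame = pd.read_csv(path, sep="\t")
    kind = None
    sidecar = _sidecar(path)
    if sidecar.exists():
        kind = json.loads(sidecar.read_text()).get("kind")
    group_ids = frame.pop("group_id").tolist() if "group_id" in frame else None
    point_ids = frame.pop("point_id").astype(str).tolist()
    return SignatureMatrix(rows=frame.to_numpy(float), point_ids=point_ids,
                           group_ids=group_ids, kind=kind)


def write_embedding(result: EmbeddingResult, path: str | Path, **params) -> None:
    path = Path(path)
    l = result.dimension
    frame = pd.DataFrame(result.coordinates,
                         columns=[f"coord_{k}" for k in range(1, l + 1)])
    n = len(frame)
    frame.insert(0, "point_id",
                 result.point_ids or [str(i) for i in range(n)])
    if result.group_ids is not None:
        frame.insert(1, "group_id", list(result.group_ids))
    frame.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)
    meta = {
        "eigenvalues": result.eigenvalues.tolist(),
        "dimension": result.dimension,
        "diffusion_time": result.diffusion_time,
        "epsilon_prime": result.epsilon_prime,
        **params,
    }
    if result.jackstraw is not None:
        meta["jackstraw"] = {"shuffles": result.jackstraw.shuffles,
                             "seed": result.jackstraw.seed}
    _sidecar(path).write_text(json.dumps(meta, indent=2))


def read_embedding(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_bundles(bundles: Sequence[ObservationBundle], directory: str | Path,
                  labels: Sequence | None = None) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    manifest = []
    for i, bundle in enumerate(bundles):
        name = f"bundle_{i:05d}.tsv"
        np.savetxt(directory / name, bundle.features, delimiter="\t",
                   fmt=_FLOAT_FMT)
        manifest.append({
            "file": name,
            "point_id": bundle.point_id or str(i),
            "feature_names": list(bundle.feature_names)
            if bundle.feature_names is not None else None,
            "label": None if labels is None else _jsonable(labels[i]),
        })
    (directory / "manifest.json").write_text(json.dumps(manifest, indent=2))


def _jsonable(value):
    return value.item() if isinstance(value, np.generic) else value


def read_bundles(directory: str | Path
                 ) -> tuple[list[ObservationBundle], list | None]:
    directory = Path(directory)
    manifest = json.loads((directory / "manifest.json").read_text())
    bundles, labels = [], []
    for entry in manifest:
        features = np.loadtxt(directory / entry["file"], delimiter="\t", ndmin=2)
        bundles.append(ObservationBundle(features=features,
                                         feature_names=entry["feature_names"],
                                         point_id=entry["point_id"]))
        labels.append(entry["label"])
    if all(label is None for label in labels):
        return bundles, None
    return bundles, labels
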