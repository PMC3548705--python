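"""Delimited-text input, artefact export and run manifests.

All numeric exports use 17 significant digits so a write/read round trip
preserves float64 values exactly; rendered figures are the only place where
display rounding happens.
"""

from __future__ import annotations

import dataclasses
import datetime
import hashlib
import json
import logging
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "read_matrix",
    "write_matrix_csv",
    "RunManifest",
    "write_manifest",
    "export_seco_map",
    "export_pairwise_matrix",
    "export_benchmark",
    "export_tree",
    "load_config",
]

_FMT = "%.17g"


def _detect_sep(path: Path) -> str:
    with open(path, "r") as fh:
        first = fh.readline()
    return "\t" if "\t" in first else ","


def _is_number(cell: str) -> bool:
    try:
        float(cell)
        return True
    except (TypeError, ValueError):
        return False


def read_matrix(path, label_column=None):
    """Read a delimited numeric matrix (comma or tab separated, header row
    auto-detected).  Returns ``(X, labels)`` where ``labels`` is the
    extracted label column (by name or 0-based index) or ``None``.
    """
    path = Path(path)
    sep = _detect_sep(path)
    raw = pd.read_csv(path, sep=sep, header=None, dtype=str, skip_blank_lines=True)
    has_header = not all(_is_number(c) for c in raw.iloc[0])
    if has_header:
        columns = [str(c).strip() for c in raw.iloc[0]]
        body = raw.iloc[1:].reset_index(drop=True)
    else:
        columns = [str(i) for i in range(raw.shape[1])]
        body = raw

    label_idx: Optional[int] = None
    if label_column is not None:
        if isinstance(label_column, int):
            if not 0 <= label_column < len(columns):
                raise ValueError(
                    f"label column index {label_column} out of range; file has "
                    f"{len(columns)} columns"
                )
            label_idx = label_column
        else:
            if label_column not in columns:
                raise ValueError(
                    f"label column {label_column!r} not found; available "
                    f"columns: {columns}"
                )
            label_idx = columns.index(label_column)

    labels = None
    if label_idx is not None:
        labels = body.iloc[:, label_idx].to_numpy()
        body = body.drop(columns=body.columns[label_idx])

    values = np.empty(body.shape, dtype=np.float64)
    cols = [c for i, c in enumerate(columns) if i != label_idx]
    for j in range(body.shape[1]):
        col = body.iloc[:, j]
        for i, cell in enumerate(col):
            if not _is_number(cell):
                raise ValueError(
                    f"non-numeric value {cell!r} at data row {i + 1}, "
                    f"column {cols[j]!r}"
                )
        values[:, j] = col.astype(np.float64)
    if labels is not None:
        # integer-looking label columns come back as ints
        if all(_is_number(v) for v in labels):
            as_float = labels.astype(np.float64)
            if np.allclose(as_float, np.round(as_float)):
                labels = as_float.astype(np.int64)
            else:
                labels = as_float
    return values, labels


def write_matrix_csv(path, X, labels=None, header=None, label_name="cohort"):
    """Write a matrix (optionally with a trailing label column) as CSV."""
    path = Path(path)
    X = np.asarray(X, dtype=np.float64)
    if header is None:
        header = [f"v{j + 1}" for j in range(X.shape[1])]
    frame = pd.DataFrame(X, columns=header)
    if labels is not None:
        frame[label_name] = np.asarray(labels)
    frame.to_csv(path, index=False, float_format=_FMT)
    return path


def fingerprint_matrix(X) -> dict:
    X = np.ascontiguousarray(np.asarray(X, dtype=np.float64))
    return {
        "n_rows": int(X.shape[0]),
        "n_cols": int(X.shape[1]),
        "sha256": hashlib.sha256(X.tobytes()).hexdigest(),
    }


@dataclasses.dataclass
class RunManifest:
    command: str
    config: dict
    input_fingerprint: Optional[dict]
    master_seed: Optional[int]
    version: str
    created: str

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)


def write_manifest(out_dir, command, config, X=None, master_seed=None) -> Path:
    from . import __version__

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(
        command=command,
        config=config,
        input_fingerprint=None if X is None else fingerprint_matrix(X),
        master_seed=master_seed,
        version=__version__,
        created=datetime.datetime.now(datetime.timezone.utc).isoformat(),
    )
    path = out_dir / "manifest.json"
    path.write_text(manifest.to_json() + "\n")
    logger.info("manifest written to %s", path)
    return path


def _write_tsv(frame: pd.DataFrame, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    frame.to_csv(path, sep="\t", index=False, float_format=_FMT)
    return path


def export_seco_map(seco_map, path) -> Path:
    """SeCo map as TSV with columns k, run_id, delta_ssq, med_cv."""
    return _write_tsv(seco_map.to_frame(), path)


def export_pairwise_matrix(V, ids, path) -> Path:
    """Square pairwise-concordance matrix with solution ids as header
    row/column."""
    frame = pd.DataFrame(np.asarray(V), index=ids, columns=ids)
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    frame.to_csv(path, sep="\t", index=True, index_label="id", float_format=_FMT)
    return path


def export_benchmark(results, out_dir) -> tuple[Path, Path]:
    """Write the ordered per-repetition CV curves and a summary table.

    ``results`` maps arbitrary column keys (e.g. ``(k, method)``) to
    BenchmarkResult objects.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    curves = {}
    summary_rows = []
    for key, res in results.items():
        name = key if isinstance(key, str) else "_".join(str(x) for x in key)
        curves[name] = res.sorted_cv()
        summary_rows.append(
            {
                "label": name,
                "method": res.method,
                "k": res.k,
                "accuracy_mean": res.accuracy_mean,
                "accuracy_sd": res.accuracy_sd,
                "affinity": res.affinity,
                "cv_mean": float(np.mean(res.cv_values)),
                "n_reps": res.n_reps,
            }
        )
    curves_path = _write_tsv(pd.DataFrame(curves), out_dir / "curves.tsv")
    summary_path = _write_tsv(pd.DataFrame(summary_rows), out_dir / "summary.tsv")
    return curves_path, summary_path


def export_tree(tree, path) -> Path:
    """Partition-tree edge list as TSV."""
    return _write_tsv(tree.to_frame(), path)


def load_config(path) -> dict:
    """Load a YAML or JSON configuration mapping."""
    import yaml

    path = Path(path)
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError(f"config file {path} must contain a mapping")
    return cfg
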