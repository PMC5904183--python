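"""Readers and writers for the package's plain-text interchange formats.

Probe matrices travel as TSV (probe_set_id, gene_id, one column per
sample) with a sidecar design TSV (sample, condition); force curves as
2-column TSV with ``#``-prefixed metadata; images as TIFF pairs
(intensity + label masks); GEO series-matrix files are read directly
(header lines prefixed ``!``, expression table between
``!series_matrix_table_begin`` / ``!series_matrix_table_end``).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .afm import ForceCurve
from .imaging import LabeledImage
from .transcriptome import ProbeMatrix

__all__ = [
    "write_probe_matrix", "read_probe_matrix",
    "write_force_curve", "read_force_curve",
    "write_image", "read_image",
    "read_series_matrix",
    "write_json",
]


def write_probe_matrix(matrix: ProbeMatrix, matrix_path, design_path) -> None:
    matrix.values.reset_index().to_csv(matrix_path, sep="\t", index=False)
    pd.DataFrame({"sample": list(matrix.design),
                  "condition": list(matrix.design.values())}
                 ).to_csv(design_path, sep="\t", index=False)


def read_probe_matrix(matrix_path, design_path) -> ProbeMatrix:
    table = pd.read_csv(matrix_path, sep="\t")
    design = pd.read_csv(design_path, sep="\t")
    return ProbeMatrix.from_frames(table, design)


def write_force_curve(curve: ForceCurve, path) -> None:
    lines = [f"# mode\t{curve.mode}", f"# segment\t{curve.segment}"]
    def fmt(v):
        return repr(float(v)) if isinstance(v, (int, float, np.floating,
                                                np.integer)) else str(v)

    if curve.spring_constant is not None:
        lines.append(f"# spring_constant\t{fmt(curve.spring_constant)}")
    if curve.sensitivity_nm_per_V is not None:
        lines.append(f"# sensitivity_nm_per_V\t{fmt(curve.sensitivity_nm_per_V)}")
    for k, v in curve.metadata.items():
        lines.append(f"# meta:{k}\t{fmt(v)}")
    lines.append("z_um\tsignal")
    for z, s in zip(curve.z, curve.signal):
        lines.append(f"{float(z)!r}\t{float(s)!r}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_force_curve(path) -> ForceCurve:
    meta: dict = {}
    z, sig = [], []
    header_seen = False
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        if line.startswith("#"):
            key, _, val = line[1:].strip().partition("\t")
            meta[key.strip()] = val.strip()
            continue
        if not header_seen:
            header_seen = True  # column header row
            continue
        a, b = line.split("\t")
        z.append(float(a))
        sig.append(float(b))
    extra = {k[5:]: _parse_scalar(v) for k, v in meta.items()
             if k.startswith("meta:")}
    return ForceCurve(
        z=np.array(z), signal=np.array(sig),
        mode=meta.get("mode", "force"),
        segment=meta.get("segment", "approach"),
        spring_constant=(float(meta["spring_constant"])
                         if "spring_constant" in meta else None),
        sensitivity_nm_per_V=(float(meta["sensitivity_nm_per_V"])
                              if "sensitivity_nm_per_V" in meta else None),
        metadata=extra,
    )


def _parse_scalar(text: str):
    for cast in (int, float):
        try:
            return cast(text)
        except ValueError:
            pass
    return text


def write_image(img: LabeledImage, directory, stem: str = "image") -> dict:
    """Write intensity channels and label masks as TIFFs; returns the
    path map. Ground truth (if any) goes to ``<stem>_truth.json``."""
    import tifffile

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {}
    for name, arr in img.channels.items():
        p = directory / f"{stem}_{name}.tif"
        tifffile.imwrite(p, np.asarray(arr, dtype=np.float32))
        paths[f"channel:{name}"] = str(p)
    for name, arr in img.masks.items():
        p = directory / f"{stem}_mask_{name}.tif"
        tifffile.imwrite(p, np.asarray(arr, dtype=np.int32))
        paths[f"mask:{name}"] = str(p)
    if img.truth:
        p = directory / f"{stem}_truth.json"
        write_json(img.truth, p)
        paths["truth"] = str(p)
    return paths


def read_image(channel_paths: dict, mask_paths: dict,
               pixel_size_um: float = 1.0) -> LabeledImage:
    import tifffile

    channels = {name: tifffile.imread(p).astype(float)
                for name, p in channel_paths.items()}
    masks = {name: tifffile.imread(p).astype(np.int64)
             for name, p in mask_paths.items()}
    return LabeledImage(channels=channels, masks=masks,
                        pixel_size_um=pixel_size_um)


def read_series_matrix(path, condition_header: str | None = None):
    """Read a GEO series-matrix file.

    Returns ``(table, metadata)``: the expression table as a DataFrame
    indexed by ID_REF with one column per GSM sample, and the ``!``
    header lines as a dict of lists. When ``condition_header`` names a
    header key (e.g. ``Sample_title``), a ``design`` mapping
    sample → that header's value is returned as a third element.
    """
    header: dict[str, list] = {}
    table_lines: list[str] = []
    in_table = False
    for line in Path(path).read_text().splitlines():
        if line.startswith("!series_matrix_table_begin"):
            in_table = True
            continue
        if line.startswith("!series_matrix_table_end"):
            in_table = False
            continue
        if in_table:
            table_lines.append(line)
        elif line.startswith("!"):
            key, _, rest = line[1:].partition("\t")
            vals = [v.strip().strip('"') for v in rest.split("\t")] if rest else []
            header.setdefault(key, []).extend(vals)
    if not table_lines:
        raise ValueError(f"{path}: no series-matrix table found")
    from io import StringIO

    table = pd.read_csv(StringIO("\n".join(table_lines)), sep="\t")
    table.columns = [str(c).strip().strip('"') for c in table.columns]
    table = table.set_index(table.columns[0])
    table.index = table.index.map(lambda v: str(v).strip().strip('"'))
    table = table.apply(pd.to_numeric, errors="coerce")
    if condition_header is not None:
        labels = header.get(condition_header)
        if not labels or len(labels) != table.shape[1]:
            raise ValueError(f"header {condition_header!r} missing or misaligned")
        design = dict(zip(table.columns, labels))
        return table, header, design
    return table, header


def series_matrix_to_probe_matrix(table: pd.DataFrame, design: dict,
                                  gene_ids=None) -> ProbeMatrix:
    """Treat a gene-level series-matrix table as single-probe genes
    (identifier doubles as probe id unless ``gene_ids`` maps it)."""
    ids = table.index.astype(str)
    genes = ids.map(dict(gene_ids)) if gene_ids is not None else ids
    values = table.copy()
    values.index = pd.MultiIndex.from_arrays([ids, genes],
                                             names=["probe_set_id", "gene_id"])
    return ProbeMatrix(values.astype(float), dict(design))


def write_json(obj, path) -> None:
    def default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, set):
            return sorted(o)
        raise TypeError(f"not JSON serializable: {type(o)}")

    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True,
                                     default=default) + "\n")
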