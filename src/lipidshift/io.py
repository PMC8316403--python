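"""Reading and writing the pipeline's plain-text dialects.

* counts CSV — first column ``analyte``, one column per injection_id,
  UTF-8, ``.`` decimal separator.
* metadata CSV — columns injection_id, mouse_id, tissue, group, replicate, day.
* panel YAML — keys ``classes``, ``species`` (list of labels), ``standards``
  (class code -> list of standard labels), ``tissues``.
"""

from __future__ import annotations

import os
from pathlib import Path

import pandas as pd
import yaml

from .panel import MeasurementSet, PanelDefinition, SampleMeta, panel_from_labels

__all__ = [
    "read_measurements",
    "write_measurements",
    "read_panel",
    "write_panel",
    "write_fold_changes",
]

_META_COLUMNS = ["injection_id", "mouse_id", "tissue", "group", "replicate", "day"]


def read_panel(panel_path: str | os.PathLike) -> PanelDefinition:
    with open(panel_path, "r", encoding="utf-8") as fh:
        doc = yaml.safe_load(fh)
    return panel_from_labels(
        species_labels=list(doc["species"]),
        standards={k: list(v) for k, v in doc["standards"].items()},
        tissues=list(doc.get("tissues", [])) or ["tissue"],
    )


def write_panel(panel: PanelDefinition, panel_path: str | os.PathLike) -> None:
    doc = {
        "classes": [cls.value for cls in panel.class_standard_map],
        "species": [s.label for s in panel.measured_species],
        "standards": {
            cls.value: list(labels) for cls, labels in panel.class_standard_map.items()
        },
        "tissues": list(panel.tissue_list),
    }
    with open(panel_path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def read_measurements(
    counts_path: str | os.PathLike,
    meta_path: str | os.PathLike,
    panel_path: str | os.PathLike,
) -> MeasurementSet:
    """Load and fully validate a MeasurementSet from the three input files."""
    panel = read_panel(panel_path)
    counts = pd.read_csv(counts_path, index_col="analyte", encoding="utf-8")
    meta = pd.read_csv(meta_path, encoding="utf-8")
    missing = [c for c in _META_COLUMNS if c not in meta.columns]
    if missing:
        raise ValueError(f"metadata CSV lacks columns: {missing}")
    samples = [
        SampleMeta(
            injection_id=str(row.injection_id),
            mouse_id=str(row.mouse_id),
            tissue=str(row.tissue),
            group=str(row.group),
            replicate=int(row.replicate),
            day=int(row.day),
        )
        for row in meta.itertuples()
    ]
    return MeasurementSet(panel, samples, counts)


def write_measurements(
    data: MeasurementSet, out_dir: str | os.PathLike
) -> dict[str, Path]:
    """Write counts.csv, metadata.csv and panel.yaml; returns the paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "counts": out / "counts.csv",
        "metadata": out / "metadata.csv",
        "panel": out / "panel.yaml",
    }
    data.counts.rename_axis("analyte").to_csv(paths["counts"], encoding="utf-8")
    pd.DataFrame(
        [
            {
                "injection_id": s.injection_id,
                "mouse_id": s.mouse_id,
                "tissue": s.tissue,
                "group": s.group,
                "replicate": s.replicate,
                "day": s.day,
            }
            for s in data.samples
        ]
    ).to_csv(paths["metadata"], index=False, encoding="utf-8")
    write_panel(data.panel, paths["panel"])
    return paths


def write_fold_changes(records, path: str | os.PathLike) -> None:
    """One row per (species x tissue x mode): the reporting input table."""
    rows = []
    for r in records:
        cat = r.category
        rows.append(
            {
                "species": r.species.label,
                "tissue": r.tissue,
                "mode": r.mode,
                "fold_change": r.fold_change,
                "sem": r.sem,
                "p_value": r.p_value,
                "category": cat.color if cat is not None else "",
                "direction": cat.direction if cat is not None else "",
                "beyond_sem": cat.beyond_sem if cat is not None else "",
            }
        )
    pd.DataFrame(rows).to_csv(path, index=False, encoding="utf-8")
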