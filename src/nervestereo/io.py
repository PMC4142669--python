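"""Plain-text file formats: CSV tables with YAML sidecars.

Every writer has a matching reader and write -> read -> write is
idempotent.  Fiber tables carry the schema
``fiber_id,x_um,y_um,axon_diameter_um,fiber_diameter_um`` with a YAML
sidecar holding the section metadata (id, nerve radius, area, seed).
"""

from __future__ import annotations

import math
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .errors import ParseError
from .estimation import StereologyEstimate
from .sampling import CountingFrame, SamplingDesign
from .synthetic import NerveSection, section_to_table, table_to_section

__all__ = [
    "sidecar_path",
    "write_section",
    "read_section",
    "write_frames",
    "read_frames",
    "write_counts",
    "read_counts",
    "write_estimates",
    "read_estimates",
    "write_design",
    "read_design",
]

FIBER_COLUMNS = ["fiber_id", "x_um", "y_um", "axon_diameter_um", "fiber_diameter_um"]


def sidecar_path(path: Path | str) -> Path:
    path = Path(path)
    return path.with_name(path.stem + ".meta.yaml")


def write_section(section: NerveSection, path: Path | str) -> Path:
    """Write the fiber table (CSV) and its metadata sidecar (YAML)."""
    path = Path(path)
    section_to_table(section).to_csv(path, index=False)
    meta = {
        "section_id": section.section_id,
        "nerve_radius_um": float(section.nerve_radius),
        "nerve_center_x_um": float(section.nerve_center_x),
        "nerve_center_y_um": float(section.nerve_center_y),
        "cross_sectional_area_um2": float(section.cross_sectional_area),
        "seed": section.rng_seed,
    }
    with open(sidecar_path(path), "w") as fh:
        yaml.safe_dump(meta, fh, sort_keys=False)
    return path


def read_section(path: Path | str, *, check_overlap: bool = False) -> NerveSection:
    """Read a fiber table back into a validated :class:`NerveSection`.

    Raises :class:`ParseError` naming the first offending row for missing
    columns, non-numeric values, or geometric violations (d >= D; with
    ``check_overlap`` also pairwise disk overlap).
    """
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    try:
        # round_trip parsing keeps write -> read -> write byte-identical
        table = pd.read_csv(path, sep=sep, float_precision="round_trip")
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise ParseError(f"{path}: cannot parse table: {exc}") from exc
    missing = [c for c in FIBER_COLUMNS if c not in table.columns]
    if missing:
        raise ParseError(f"{path}: missing column(s) {missing}")
    for col in FIBER_COLUMNS:
        coerced = pd.to_numeric(table[col], errors="coerce")
        bad = np.flatnonzero(coerced.isna() & table[col].notna())
        if bad.size or coerced.isna().any():
            row = int(bad[0]) if bad.size else int(np.flatnonzero(coerced.isna())[0])
            raise ParseError(
                f"{path}: non-numeric or empty value in column {col!r} at data row {row + 1}"
            )
        table[col] = coerced
    bad = np.flatnonzero(
        ~(
            (table["axon_diameter_um"] > 0)
            & (table["axon_diameter_um"] < table["fiber_diameter_um"])
        )
    )
    if bad.size:
        raise ParseError(
            f"{path}: need 0 < axon diameter < fiber diameter; "
            f"violated at data row {int(bad[0]) + 1}"
        )
    if table["fiber_id"].duplicated().any():
        row = int(np.flatnonzero(table["fiber_id"].duplicated())[0])
        raise ParseError(f"{path}: duplicate fiber_id at data row {row + 1}")

    meta_file = sidecar_path(path)
    meta = {}
    if meta_file.exists():
        with open(meta_file) as fh:
            meta = yaml.safe_load(fh) or {}
    section = table_to_section(
        table,
        section_id=str(meta.get("section_id", path.stem)),
        nerve_radius=meta.get("nerve_radius_um"),
        cross_sectional_area=meta.get("cross_sectional_area_um2"),
        nerve_center=(
            float(meta.get("nerve_center_x_um", 0.0)),
            float(meta.get("nerve_center_y_um", 0.0)),
        ),
        rng_seed=meta.get("seed"),
    )
    if check_overlap:
        r = section.D / 2.0
        dx = section.x[:, None] - section.x[None, :]
        dy = section.y[:, None] - section.y[None, :]
        sep2 = dx**2 + dy**2 - (r[:, None] + r[None, :]) ** 2
        np.fill_diagonal(sep2, np.inf)
        i, j = np.unravel_index(int(np.argmin(sep2)), sep2.shape)
        if sep2[i, j] < -1e-9:
            raise ParseError(
                f"{path}: fibers at data rows {min(i, j) + 1} and "
                f"{max(i, j) + 1} overlap"
            )
    return section


def write_frames(frames: list[CountingFrame], path: Path | str) -> Path:
    path = Path(path)
    pd.DataFrame(
        {
            "frame_id": [f.frame_id for f in frames],
            "field_id": [f.parent_field_id for f in frames],
            "shape": [f.shape for f in frames],
            "cx_um": [f.center_x for f in frames],
            "cy_um": [f.center_y for f in frames],
            "radius_um": [f.radius if f.radius is not None else "" for f in frames],
            "width_um": [f.width if f.width is not None else "" for f in frames],
            "height_um": [f.height if f.height is not None else "" for f in frames],
            "area_um2": [f.area for f in frames],
            "reference_area_um2": [
                f.reference_area if f.reference_area is not None else ""
                for f in frames
            ],
        }
    ).to_csv(path, index=False)
    return path


def read_frames(path: Path | str) -> list[CountingFrame]:
    df = pd.read_csv(Path(path))
    frames = []
    for _, row in df.iterrows():
        def opt(name):
            v = row.get(name)
            return None if v is None or (isinstance(v, float) and math.isnan(v)) else float(v)

        frames.append(
            CountingFrame(
                frame_id=int(row["frame_id"]),
                parent_field_id=int(row["field_id"]),
                shape=str(row["shape"]),
                center_x=float(row["cx_um"]),
                center_y=float(row["cy_um"]),
                radius=opt("radius_um"),
                width=opt("width_um"),
                height=opt("height_um"),
                reference_area=opt("reference_area_um2"),
            )
        )
    return frames


def write_counts(counts, path: Path | str, summary_path: Path | str | None = None):
    """Long-form counted fibers (frame_id, fiber_id) plus optional per-frame
    summary (frame_id, n_counted, frame_area_um2)."""
    from .counting import SectionCounts

    results = counts.results if isinstance(counts, SectionCounts) else list(counts)
    rows = [
        {"frame_id": r.frame_id, "fiber_id": fid}
        for r in results
        for fid in r.counted_fiber_ids
    ]
    pd.DataFrame(rows, columns=["frame_id", "fiber_id"]).to_csv(Path(path), index=False)
    if summary_path is not None:
        pd.DataFrame(
            {
                "frame_id": [r.frame_id for r in results],
                "n_counted": [r.n_counted for r in results],
                "frame_area_um2": [r.frame_area for r in results],
            }
        ).to_csv(Path(summary_path), index=False)
    return Path(path)


def read_counts(long_path: Path | str, summary_path: Path | str):
    """Rebuild per-frame :class:`CountResult` records from the two CSVs."""
    from .counting import CountResult

    long_df = pd.read_csv(Path(long_path))
    summary = pd.read_csv(Path(summary_path))
    by_frame = {
        int(fid): sorted(int(v) for v in grp["fiber_id"])
        for fid, grp in long_df.groupby("frame_id")
    }
    results = []
    for _, row in summary.iterrows():
        fid = int(row["frame_id"])
        ids = by_frame.get(fid, [])
        if len(ids) != int(row["n_counted"]):
            raise ParseError(
                f"{long_path}: frame {fid} lists {len(ids)} fibers but the "
                f"summary says {int(row['n_counted'])}"
            )
        results.append(
            CountResult(
                frame_id=fid,
                counted_fiber_ids=ids,
                frame_area=float(row["frame_area_um2"]),
            )
        )
    return results


ESTIMATE_COLUMNS = [
    "section_id",
    "modality",
    "total_counted",
    "total_frame_area_um2",
    "density_per_mm2",
    "nerve_area_um2",
    "total_fibers",
]


def write_estimates(estimates: list[StereologyEstimate], path: Path | str) -> Path:
    pd.DataFrame(
        {
            "section_id": [e.section_id for e in estimates],
            "modality": [e.modality for e in estimates],
            "total_counted": [e.total_counted for e in estimates],
            "total_frame_area_um2": [e.total_frame_area for e in estimates],
            "density_per_mm2": [e.density_per_mm2 for e in estimates],
            "nerve_area_um2": [e.nerve_area_um2 for e in estimates],
            "total_fibers": [e.total_fibers for e in estimates],
        }
    ).to_csv(Path(path), index=False)
    return Path(path)


def read_estimates(path: Path | str) -> list[StereologyEstimate]:
    df = pd.read_csv(Path(path))
    missing = [c for c in ESTIMATE_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing column(s) {missing}")
    return [
        StereologyEstimate(
            section_id=str(r["section_id"]),
            modality=str(r["modality"]),
            total_counted=int(r["total_counted"]),
            total_frame_area=float(r["total_frame_area_um2"]),
            density_per_mm2=float(r["density_per_mm2"]),
            nerve_area_um2=float(r["nerve_area_um2"]),
            total_fibers=float(r["total_fibers"]),
        )
        for _, r in df.iterrows()
    ]


def write_design(design: SamplingDesign, path: Path | str) -> Path:
    data = {
        "modality": design.modality,
        "n_fields": design.n_fields,
        "field_width_um": design.field_width,
        "field_height_um": design.field_height,
        "frames_per_field": design.frames_per_field,
        "frame_radius_um": design.frame_radius,
        "seed": design.placement_seed,
    }
    with open(Path(path), "w") as fh:
        yaml.safe_dump(data, fh, sort_keys=False)
    return Path(path)


def read_design(path: Path | str) -> SamplingDesign:
    with open(Path(path)) as fh:
        data = yaml.safe_load(fh)
    try:
        return SamplingDesign(
            modality=data["modality"],
            n_fields=int(data["n_fields"]),
            field_width=float(data["field_width_um"]),
            field_height=float(data["field_height_um"]),
            frames_per_field=int(data["frames_per_field"]),
            frame_radius=(
                None if data.get("frame_radius_um") is None
                else float(data["frame_radius_um"])
            ),
            placement_seed=int(data.get("seed", 0)),
        )
    except KeyError as exc:
        raise ParseError(f"{path}: missing design key {exc}") from exc
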