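"""File formats and run configuration.

Images travel as 8/16-bit grayscale TIFF named
``<sample>_<well>_<row>_<col>.tif`` (a well is a 10 x 10 image array);
tabular outputs are plain UTF-8 comma-separated CSV with headers; cutoffs
and fit parameters are JSON; run configuration is YAML and is copied
verbatim into every results directory for provenance.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import tifffile
import yaml

from .biomarker import CutoffPair, SampleRecord
from .calibration import CalibrationCurve
from .quant import QuantConfig, Spot, SpotHistogram, TIRFImage, WellResult

_TIFF_NAME = re.compile(r"^(?P<sample>.+)_(?P<well>[^_]+)_(?P<row>\d+)_(?P<col>\d+)\.tiff?$")

SAMPLE_SHEET_REQUIRED = ["sample_id", "cohort", "tfi_mrna", "tfi_mprotein"]
SAMPLE_SHEET_OPTIONAL = ["ca199", "os_months", "event"]


# ---------------------------------------------------------------------------
# images
# ---------------------------------------------------------------------------

def write_well_images(
    out_dir: str | Path,
    images: Sequence[TIRFImage],
    sample: str,
    well: str,
    grid: int = 10,
) -> list[Path]:
    """Write frames as 16-bit grayscale TIFFs in acquisition-grid order."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for i, img in enumerate(images):
        row, col = i // grid, i % grid
        path = out_dir / f"{sample}_{well}_{row}_{col}.tif"
        data = np.clip(np.round(img.pixels), 0, np.iinfo(np.uint16).max)
        tifffile.imwrite(path, data.astype(np.uint16))
        paths.append(path)
    return paths


def read_well_images(
    directory: str | Path, pattern: str = "*.tif*", channel: str = "mrna"
) -> list[TIRFImage]:
    """Read a directory of single-channel TIFFs, sorted by (well, row, col).

    Non-matching files are skipped; zero matches or an unreadable file is
    an error naming the offender.  RGB images are rejected (the assay is
    single-channel).
    """
    directory = Path(directory)
    if not directory.is_dir():
        raise FileNotFoundError(f"not a directory: {directory}")
    entries = []
    for path in sorted(directory.glob(pattern)):
        m = _TIFF_NAME.match(path.name)
        if not m:
            continue
        entries.append((m["well"], int(m["row"]), int(m["col"]), path))
    if not entries:
        raise FileNotFoundError(f"no TIFF files matching {pattern!r} in {directory}")
    entries.sort()
    images = []
    for idx, (well, _row, _col, path) in enumerate(entries):
        try:
            data = tifffile.imread(path)
        except Exception as exc:  # noqa: BLE001 - report the corrupt file
            raise OSError(f"unreadable TIFF {path.name}: {exc}") from exc
        if data.ndim != 2:
            raise ValueError(f"{path.name}: expected grayscale, got shape {data.shape}")
        images.append(
            TIRFImage(
                pixels=data.astype(float),
                well_id=well,
                frame_index=idx,
                channel=channel,
            )
        )
    return images


# ---------------------------------------------------------------------------
# sample sheets
# ---------------------------------------------------------------------------

def write_sample_sheet(path: str | Path, samples: Sequence[SampleRecord]) -> None:
    rows = []
    for s in samples:
        rows.append(
            {
                "sample_id": s.sample_id,
                "cohort": s.cohort,
                "tfi_mrna": s.tfi_mrna,
                "tfi_mprotein": s.tfi_mprotein,
                "ca199": s.ca199,
                "os_months": s.os_months,
                "event": s.event,
            }
        )
    pd.DataFrame(rows, columns=SAMPLE_SHEET_REQUIRED + SAMPLE_SHEET_OPTIONAL).to_csv(
        path, index=False
    )


def read_sample_sheet(path: str | Path) -> list[SampleRecord]:
    """Typed sample records from CSV; missing optional fields stay absent."""
    df = pd.read_csv(path)
    missing = [c for c in SAMPLE_SHEET_REQUIRED if c not in df.columns]
    if missing:
        raise ValueError(f"sample sheet missing required columns: {missing}")
    records = []
    for _, row in df.iterrows():
        for col in ("tfi_mrna", "tfi_mprotein"):
            try:
                float(row[col])
            except (TypeError, ValueError):
                raise ValueError(f"non-numeric {col} for sample {row['sample_id']}")
        def _opt(col: str):
            if col not in df.columns or pd.isna(row[col]):
                return None
            return float(row[col])

        event = _opt("event")
        records.append(
            SampleRecord(
                sample_id=str(row["sample_id"]),
                cohort=str(row["cohort"]),
                tfi_mrna=float(row["tfi_mrna"]),
                tfi_mprotein=float(row["tfi_mprotein"]),
                ca199=_opt("ca199"),
                os_months=_opt("os_months"),
                event=int(event) if event is not None else None,
            )
        )
    return records


# ---------------------------------------------------------------------------
# results writers
# ---------------------------------------------------------------------------

def write_truth_csv(path: str | Path, truths: Sequence[Sequence]) -> None:
    """Ground-truth CSV, one row per rendered object across frames."""
    rows = []
    spot_id = 0
    for frame, truth in enumerate(truths):
        for ts in truth:
            rows.append(
                {
                    "spot_id": spot_id,
                    "frame": frame,
                    "row": ts.row,
                    "col": ts.col,
                    "intensity": ts.intensity,
                    "diameter_px": ts.diameter_px,
                    "category": ts.category,
                }
            )
            spot_id += 1
    pd.DataFrame(
        rows,
        columns=["spot_id", "frame", "row", "col", "intensity", "diameter_px", "category"],
    ).to_csv(path, index=False)


def write_well_results_csv(path: str | Path, results: Sequence[WellResult]) -> None:
    pd.DataFrame(
        [
            {
                "well_id": r.well_id,
                "channel": r.channel,
                "l": r.l,
                "n_spots": len(r.retained_spots),
                "tfi": r.tfi,
            }
            for r in results
        ]
    ).to_csv(path, index=False)


def write_spots_csv(path: str | Path, per_frame_spots: Sequence[Sequence[Spot]]) -> None:
    rows = []
    for frame, spots in enumerate(per_frame_spots):
        for s in spots:
            rows.append(
                {
                    "frame": frame,
                    "row": s.centroid[0],
                    "col": s.centroid[1],
                    "diameter_px": s.equivalent_diameter_px,
                    "net_intensity": s.net_intensity,
                    "retained": s.tag == "",
                }
            )
    pd.DataFrame(
        rows, columns=["frame", "row", "col", "diameter_px", "net_intensity", "retained"]
    ).to_csv(path, index=False)


def write_histogram_csv(path: str | Path, hist: SpotHistogram) -> None:
    pd.DataFrame(
        {
            "bin_left": hist.bin_edges[:-1],
            "bin_right": hist.bin_edges[1:],
            "count": hist.counts,
        }
    ).to_csv(path, index=False)


def write_calibration_csv(path: str | Path, points: Sequence[tuple[float, float]]) -> None:
    pd.DataFrame(points, columns=["concentration_ev_per_ml", "tfi"]).to_csv(
        path, index=False
    )


def read_calibration_csv(path: str | Path) -> list[tuple[float, float]]:
    df = pd.read_csv(path)
    for col in ("concentration_ev_per_ml", "tfi"):
        if col not in df.columns:
            raise ValueError(f"calibration CSV missing column {col!r}")
    return list(zip(df["concentration_ev_per_ml"].astype(float), df["tfi"].astype(float)))


def write_curve_json(path: str | Path, curve: CalibrationCurve) -> None:
    payload = dataclasses.asdict(curve)
    Path(path).write_text(json.dumps(payload, indent=2))


def write_cutoffs_json(path: str | Path, cutoffs: CutoffPair) -> None:
    Path(path).write_text(json.dumps(dataclasses.asdict(cutoffs), indent=2))


def read_cutoffs_json(path: str | Path) -> CutoffPair:
    data = json.loads(Path(path).read_text())
    return CutoffPair(**data)


# ---------------------------------------------------------------------------
# run configuration
# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    """Validated run configuration, serialized next to every results set."""

    quant: QuantConfig = field(default_factory=QuantConfig)
    cutoff_mrna: float | None = None
    cutoff_mprotein: float | None = None
    cutoff_provenance: str = "fixed"
    seed: int = 0
    out_dir: str = "results"

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        data = dict(data)
        quant = data.pop("quant", {}) or {}
        return cls(quant=QuantConfig(**quant), **data)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(data)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


def save_provenance(out_dir: str | Path, config: RunConfig) -> Path:
    """Write the exact config (and its hash) into a results directory."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    config.to_yaml(out_dir / "run_config.yaml")
    (out_dir / "manifest.json").write_text(
        json.dumps({"config_hash": config.config_hash(), "seed": config.seed}, indent=2)
    )
    return out_dir / "run_config.yaml"
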