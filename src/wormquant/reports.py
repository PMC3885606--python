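"""Batch orchestration: tile assembly, batch processing, and file-based
manual correction of results.

The workflow mirrors a three-step assay pipeline: batch image
processing over a directory, inspection via overlay images and an
editable corrections file, and tab-separated report printing.  All
reports are UTF-8 TSV with a header line and a leading comment block
recording the configuration hash, so identical inputs + config + seed
reproduce identical files.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .core import GrayImage

__all__ = [
    "PlateLayout",
    "RunConfig",
    "BatchReport",
    "assemble_tiles",
    "batch_process",
    "apply_corrections",
    "write_report",
    "read_report",
]

log = logging.getLogger("wormquant")


@dataclass
class PlateLayout:
    """Tile grid geometry of a scanned well (e.g. 3x4 tiles of 640x480)."""

    rows: int
    cols: int
    tile_size: tuple[int, int]           # (h, w) px
    overlap: int = 0
    well_id: str = ""

    def __post_init__(self) -> None:
        if self.rows < 1 or self.cols < 1:
            raise ValueError("rows and cols must be >= 1")
        if not 0 <= self.overlap < min(self.tile_size):
            raise ValueError("overlap must be >= 0 and smaller than a tile")

    @property
    def mosaic_shape(self) -> tuple[int, int]:
        h, w = self.tile_size
        return (self.rows * h - (self.rows - 1) * self.overlap,
                self.cols * w - (self.cols - 1) * self.overlap)


@dataclass
class RunConfig:
    """Shared run configuration with per-engine parameter blocks."""

    scale: float = 20.0
    fps: float = 7.0
    seed: int = 0
    lifespan: dict = field(default_factory=dict)
    locomotion: dict = field(default_factory=dict)
    length: dict = field(default_factory=dict)
    egg: dict = field(default_factory=dict)
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**data)

    def config_hash(self) -> str:
        blob = json.dumps(self.__dict__, sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


def assemble_tiles(tiles: list[list[GrayImage | None]],
                   layout: PlateLayout) -> GrayImage:
    """Assemble a row-major tile grid into one mosaic image.

    Non-first rows/columns have ``layout.overlap`` px cropped from
    their top/left before placement.  A missing tile raises an error
    naming its grid position.
    """
    if len(tiles) != layout.rows or any(len(row) != layout.cols for row in tiles):
        raise ValueError("tile grid dimensions do not match the layout")
    h, w = layout.tile_size
    out = np.zeros(layout.mosaic_shape, dtype=np.uint8)
    scale = 20.0
    for i in range(layout.rows):
        for j in range(layout.cols):
            tile = tiles[i][j]
            if tile is None:
                raise ValueError(f"missing tile at grid position ({i}, {j})")
            if tile.shape != (h, w):
                raise ValueError(
                    f"tile ({i}, {j}) has shape {tile.shape}, expected {(h, w)}")
            scale = tile.scale
            px = tile.pixels
            r0 = i * (h - layout.overlap)
            c0 = j * (w - layout.overlap)
            ro = layout.overlap if i > 0 else 0
            co = layout.overlap if j > 0 else 0
            out[r0 + ro:r0 + h, c0 + co:c0 + w] = px[ro:, co:]
    return GrayImage(out, scale=scale)


@dataclass
class BatchReport:
    rows: pd.DataFrame
    failures: list[tuple[str, str]]      # (input, message)

    @property
    def exit_code(self) -> int:
        return 1 if self.failures else 0


def _run_engine_on(path: Path, engine: str, cfg: RunConfig) -> dict:
    from . import eggs as eggmod
    from . import length as lenmod
    from . import lifespan as lifemod
    from . import locomotion as locomod
    from . import simulate

    if engine == "length":
        img = GrayImage.from_file(path, scale=cfg.scale)
        p = lenmod.LengthParams(scale=cfg.scale, **cfg.length)
        ms = lenmod.measure_worms(img, p)
        valid = [m for m in ms if m.valid]
        return {
            "input": str(path),
            "n_candidates": len(ms),
            "n_valid": len(valid),
            "mean_length_um": float(np.mean([m.length_um for m in valid]))
            if valid else float("nan"),
        }
    if engine == "egg":
        img = GrayImage.from_file(path, scale=cfg.scale)
        res = eggmod.count_eggs(img, eggmod.EggConfig(**cfg.egg))
        return {"input": str(path), "n_eggs": res.n_eggs,
                "n_raw_detections": res.n_candidates_prefilter}
    if engine == "lifespan":
        files = sorted(p for p in Path(path).iterdir()
                       if p.suffix.lower() in (".png", ".tif", ".tiff"))
        if len(files) < 2:
            raise ValueError(f"{path}: a lifespan input directory needs 2 scans")
        img1 = GrayImage.from_file(files[0], scale=cfg.scale)
        img2 = GrayImage.from_file(files[1], scale=cfg.scale)
        res = lifemod.count_moving_worms(img1, img2,
                                         lifemod.LifespanParams(**cfg.lifespan))
        return {"input": str(path), "n_moving": res.n_moving,
                "n_candidates": len(res.rois),
                "n_extra_movers": len(res.extra_movers)}
    if engine == "locomotion":
        frames = simulate.load_frames(path)
        p = locomod.TrackerParams(fps=cfg.fps, scale=cfg.scale, **cfg.locomotion)
        tracks, summary = locomod.analyze_video(frames, p)
        return {"input": str(path), "n_tracks": summary.n_tracks,
                "mean_velocity_um_s": summary.mean if summary.mean is not None
                else float("nan"),
                "n_stationary": summary.n_excluded_stationary}
    raise ValueError(f"unknown engine {engine!r}")


def batch_process(inputs: list[str | Path], engine: str,
                  cfg: RunConfig | None = None) -> BatchReport:
    """Run one engine over every input; failures are logged and
    reflected in the exit code, never silently dropped."""
    if not inputs:
        raise ValueError("no inputs to process")
    if cfg is None:
        cfg = RunConfig()
    rows, failures = [], []
    for item in sorted(str(p) for p in inputs):
        try:
            rows.append(_run_engine_on(Path(item), engine, cfg))
        except Exception as exc:  # noqa: BLE001 - batch must continue
            log.error("failed on %s: %s", item, exc)
            failures.append((item, str(exc)))
    frame = pd.DataFrame(rows)
    return BatchReport(rows=frame, failures=failures)


def write_report(frame: pd.DataFrame, path: str | Path,
                 cfg: RunConfig | None = None) -> None:
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        if cfg is not None:
            fh.write(f"# wormquant report; config_hash={cfg.config_hash()}\n")
        frame.to_csv(fh, sep="\t", index=False)


def read_report(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")


def apply_corrections(results: pd.DataFrame,
                      corrections: pd.DataFrame) -> pd.DataFrame:
    """Apply a manual-correction table to a results table, atomically.

    ``corrections`` columns: ``action`` (delete|edit|add), ``id``
    (value of the results' first column), ``field``, ``value``.  Any
    correction referencing an unknown id rejects the whole file and
    leaves the results untouched.  The amended table carries an
    ``audit`` column describing what was changed.
    """
    if results.empty and not corrections.empty:
        raise ValueError("cannot correct an empty results table")
    key = results.columns[0]
    out = results.copy()
    if "audit" not in out.columns:
        out["audit"] = ""
    known = set(out[key].astype(str))
    for _, corr in corrections.iterrows():
        action = str(corr["action"]).lower()
        cid = str(corr["id"])
        if action in ("delete", "edit") and cid not in known:
            raise ValueError(f"correction references unknown id {cid!r}; "
                             "correction file rejected")
    for _, corr in corrections.iterrows():
        action = str(corr["action"]).lower()
        cid = str(corr["id"])
        sel = out[key].astype(str) == cid
        if action == "delete":
            out = out[~sel]
        elif action == "edit":
            fld = str(corr["field"])
            out.loc[sel, fld] = corr["value"]
            out.loc[sel, "audit"] = (out.loc[sel, "audit"].astype(str)
                                     + f"edit:{fld};")
        elif action == "add":
            rec = json.loads(str(corr["value"]))
            rec.setdefault("audit", "added;")
            out = pd.concat([out, pd.DataFrame([rec])], ignore_index=True)
        else:
            raise ValueError(f"unknown correction action {action!r}")
        out = out.copy()
    out.loc[:, "audit"] = out["audit"].fillna("")
    deleted = known - set(out[key].astype(str))
    if deleted:
        note = f"deleted:{','.join(sorted(deleted))}"
        out.attrs["audit_note"] = note
    return out.reset_index(drop=True)
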