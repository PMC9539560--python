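"""Six-sheet workbook writer and run driver.

One scan in, one bundle out: an xlsx workbook (or CSV mirror, one file
per sheet) with sheets TotalTraits, OrderTraits, TaprootTaper, Spread,
CylinderDist, LateralDist; the QSM as CSV; and a provenance JSON that
makes the run replayable (seed, SF, every parameter).
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .geometry_io import read_stl, mesh_to_pointcloud, TriMesh
from .cylinder_model import reconstruct, QSM
from .robust_stats import median_model
from .traits import (
    cylinder_distributions,
    order_traits,
    spread,
    taproot_taper,
    total_traits,
)

log = logging.getLogger(__name__)

SHEETS = ["TotalTraits", "OrderTraits", "TaprootTaper", "Spread",
          "CylinderDist", "LateralDist"]
SF_DEPTH_RANGE = (10.0, 30.0)  # recommended scaled-depth window


@dataclass
class RunConfig:
    input: str
    sf: float = 0.1
    seed: int = 42
    runs: int = 5
    output_dir: str = "rootqsm_out"
    format: str = "xlsx"             # or "csv"
    curvature_threshold: float = 0.0
    patch_diameter: float | None = None

    def __post_init__(self):
        if self.sf <= 0:
            raise ValueError("sf must be positive")
        if self.runs < 1:
            raise ValueError("runs must be >= 1")
        if self.format not in ("xlsx", "csv"):
            raise ValueError("format must be xlsx or csv")

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        text = Path(path).read_text()
        try:
            obj = json.loads(text)
        except json.JSONDecodeError:
            obj = {}
            for line in text.splitlines():
                line = line.strip()
                if not line or line.startswith("#") or "=" not in line:
                    continue
                k, v = line.split("=", 1)
                obj[k.strip()] = v.strip()
            for k in ("sf", "curvature_threshold", "patch_diameter"):
                if k in obj:
                    obj[k] = float(obj[k])
            for k in ("seed", "runs"):
                if k in obj:
                    obj[k] = int(obj[k])
        return cls(**obj)


def _sheet_frames(qsm: QSM) -> dict[str, pd.DataFrame]:
    tt = total_traits(qsm)
    frames = {}
    frames["TotalTraits"] = pd.DataFrame([tt.as_dict()]).T.reset_index()
    frames["TotalTraits"].columns = ["trait", "value"]
    frames["OrderTraits"] = order_traits(qsm)
    frames["TaprootTaper"] = taproot_taper(qsm).to_frame()
    sp = spread(qsm)
    frames["Spread"] = pd.DataFrame(
        sp.values,
        index=[f"layer_{i}" for i in range(sp.values.shape[0])],
        columns=[f"az_{int(a)}" for a in sp.direction_edges[:-1]],
    ).reset_index(names="depth_layer")
    for sheet, which in (("CylinderDist", "main"), ("LateralDist", "lateral")):
        try:
            dists = cylinder_distributions(qsm, which)
        except ValueError:
            frames[sheet] = pd.DataFrame()
            continue
        parts = []
        for name, tab in dists.items():
            df = tab.to_frame()
            df.insert(0, "classifier", name)
            parts.append(df)
        frames[sheet] = pd.concat(parts, ignore_index=True)
    return frames


def write_workbook(qsm: QSM, out_dir, fmt: str = "xlsx") -> Path:
    """Write the six trait sheets; returns the workbook (or directory) path."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    frames = _sheet_frames(qsm)
    if fmt == "xlsx":
        path = out_dir / "traits.xlsx"
        with pd.ExcelWriter(path, engine="openpyxl") as xw:
            for sheet in SHEETS:
                frames[sheet].to_excel(xw, sheet_name=sheet, index=False)
        return path
    for sheet in SHEETS:
        frames[sheet].to_csv(out_dir / f"{sheet}.csv", index=False)
    return out_dir


def plot_depth_view(cloud, path) -> None:
    """Diagnostic scatter of the scaled cloud, colored by depth."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    from .geometry_io import depth_colored_view

    scalars = depth_colored_view(cloud)
    fig, ax = plt.subplots(figsize=(5, 7))
    sc = ax.scatter(cloud.points[:, 0], cloud.points[:, 2], c=scalars,
                    s=1, cmap="viridis_r")
    ax.set_xlabel("x (scaled units)")
    ax.set_ylabel("z (scaled units)")
    ax.set_aspect("equal")
    fig.colorbar(sc, ax=ax, label="normalized depth")
    fig.savefig(path, dpi=120, bbox_inches="tight")
    plt.close(fig)


def run(config: RunConfig) -> dict:
    """End-to-end single-scan run; returns a summary dict."""
    in_path = Path(config.input)
    if not in_path.exists():
        raise FileNotFoundError(f"input file not found: {in_path}")
    mesh = read_stl(in_path)
    cloud = mesh_to_pointcloud(mesh, config.sf, config.curvature_threshold)
    depth_units = float(cloud.points[:, 2].max() - cloud.points[:, 2].min())
    if not SF_DEPTH_RANGE[0] <= depth_units <= SF_DEPTH_RANGE[1]:
        warnings.warn(
            f"scaled root depth is {depth_units:.1f} units; the recommended "
            f"working range is {SF_DEPTH_RANGE[0]:.0f}-{SF_DEPTH_RANGE[1]:.0f} "
            "— consider adjusting the scale factor", stacklevel=2)
    rng = np.random.default_rng(config.seed)
    models = [reconstruct(cloud, patch_diameter=config.patch_diameter,
                          seed=int(rng.integers(2**31 - 1)))
              for _ in range(config.runs)]
    qsm = median_model(models)
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    book = write_workbook(qsm, out_dir, config.format)
    qsm.to_csv(out_dir / "qsm.csv")
    provenance = {
        "version": __version__,
        "input": str(in_path),
        "sf": config.sf,
        "seed": config.seed,
        "runs": config.runs,
        "scaled_depth_units": depth_units,
        "n_cylinders": len(qsm.cylinders),
        "qsm_provenance": {k: v for k, v in qsm.provenance.items()},
    }
    with open(out_dir / "provenance.json", "w") as fh:
        json.dump(provenance, fh, indent=2, default=float)
    tt = total_traits(qsm)
    log.info("run complete: %d cylinders, volume %.3f cm^3",
             len(qsm.cylinders), tt.volume)
    return {"qsm": qsm, "traits": tt, "workbook": book, "out_dir": out_dir}


def run_temporal(configs: list[RunConfig], overlaps: list[float],
                 rotation_only: bool = False) -> dict:
    """Register and compare an ordered series of scans.

    ``overlaps`` holds the trimmed-ICP overlap fraction for each
    consecutive pair (length = scans − 1).  Output: per-scan bundles,
    pairwise transforms, growth-spread deltas, and a trait time-series
    table (one column per scan).
    """
    from .temporal import growth_spread, icp
    from .geometry_io import PointCloud

    if len(configs) < 2:
        raise ValueError("temporal mode needs at least 2 scans")
    if len(overlaps) != len(configs) - 1:
        raise ValueError("need exactly one overlap per consecutive scan pair")
    bundles = [run(c) for c in configs]
    transforms = []
    clouds = []
    for c in configs:
        mesh = read_stl(c.input)
        clouds.append(PointCloud(mesh.vertices, scale_factor=1.0))
    for i, ov in enumerate(overlaps):
        tf, rms, converged = icp(clouds[i], clouds[i + 1], overlap_fraction=ov,
                                 rotation_only=rotation_only)
        transforms.append({"transform": tf, "rms": rms, "converged": converged})
        if not converged:
            log.warning("registration %d->%d did not converge (rms %.4g)",
                        i, i + 1, rms)
    deltas = [growth_spread(bundles[i]["qsm"], bundles[i + 1]["qsm"],
                            transforms[i]["transform"])
              for i in range(len(transforms))]
    series = pd.DataFrame(
        {f"scan_{i + 1}": b["traits"].as_dict() for i, b in enumerate(bundles)})
    return {"bundles": bundles, "transforms": transforms,
            "growth_deltas": deltas, "trait_series": series}
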