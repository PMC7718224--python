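"""Stack IO, configuration loading, and run manifests.

Interchange format is multi-page TIFF / OME-TIFF with voxel sizes in um;
configuration is a single YAML schema shared by all commands. Proprietary
microscope formats (CZI) are out of scope — convert externally.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import xml.etree.ElementTree as ET
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import tifffile
import yaml

from .errors import ConfigurationError
from .physics import GelSpec, ProteinSpecies, SeparationConditions
from .stack import ImageStack

_CANONICAL_AXES = "ZYXC"


def write_stack(stack: ImageStack, path: str | Path) -> Path:
    """Write an ImageStack as OME-TIFF with voxel-size metadata."""
    path = Path(path)
    data = stack.voxels
    dz, dy, dx = stack.voxel_size_um
    if data.ndim == 4:
        data = np.moveaxis(data, -1, 1)  # (z, c, y, x)
        axes = "ZCYX"
    else:
        axes = "ZYX"
    metadata = {
        "axes": axes,
        "PhysicalSizeZ": dz,
        "PhysicalSizeY": dy,
        "PhysicalSizeX": dx,
        "PhysicalSizeZUnit": "µm",
        "PhysicalSizeYUnit": "µm",
        "PhysicalSizeXUnit": "µm",
    }
    if stack.channels:
        metadata["Channel"] = {"Name": list(stack.channels)}
    tifffile.imwrite(path, data, ome=True, metadata=metadata)
    return path


def _ome_voxel_size(ome_xml: str):
    try:
        root = ET.fromstring(ome_xml)
    except ET.ParseError:
        return None
    ns = {"ome": root.tag.split("}")[0].strip("{")}
    px = root.find(".//ome:Pixels", ns)
    if px is None:
        return None
    try:
        return (
            float(px.attrib["PhysicalSizeZ"]),
            float(px.attrib["PhysicalSizeY"]),
            float(px.attrib["PhysicalSizeX"]),
        )
    except KeyError:
        return None


def _ome_channels(ome_xml: str):
    try:
        root = ET.fromstring(ome_xml)
    except ET.ParseError:
        return None
    ns = {"ome": root.tag.split("}")[0].strip("{")}
    names = [c.attrib.get("Name", "") for c in root.findall(".//ome:Channel", ns)]
    return names if names and all(names) else None


def read_stack(
    path: str | Path,
    axes: str | None = None,
    voxel_size_um: tuple[float, float, float] | None = None,
    channels: list[str] | None = None,
) -> ImageStack:
    """Read a TIFF/OME-TIFF stack into canonical (z, y, x[, c]) order.

    Axis order and voxel sizes are taken from the file metadata; explicit
    hints override. Files whose axis order or voxel size cannot be
    resolved raise :class:`ConfigurationError` rather than being silently
    misread (RGB-interleaved TIFFs in particular need an ``axes`` hint).
    """
    path = Path(path)
    with tifffile.TiffFile(path) as tif:
        series = tif.series[0]
        data = series.asarray()
        file_axes = series.axes
        if tif.ome_metadata:
            meta_vs = _ome_voxel_size(tif.ome_metadata)
            meta_ch = _ome_channels(tif.ome_metadata)
        else:
            meta_vs = meta_ch = None

    use_axes = (axes or file_axes or "").upper()
    if not use_axes or len(use_axes) != data.ndim:
        raise ConfigurationError(
            f"cannot resolve axis order for {path.name} (file reports "
            f"{file_axes!r}); pass an axes hint"
        )
    if "S" in use_axes and axes is None:
        raise ConfigurationError(
            f"{path.name} has interleaved samples ({file_axes!r}); pass an "
            "explicit axes hint to interpret them"
        )
    unknown = set(use_axes) - set("ZYXCS")
    if unknown:
        raise ConfigurationError(f"unsupported axes {unknown} in {path.name}")
    use_axes = use_axes.replace("S", "C")
    if "Z" not in use_axes or "Y" not in use_axes or "X" not in use_axes:
        raise ConfigurationError(f"need Z, Y and X axes, got {use_axes!r}")

    order = [use_axes.index(a) for a in _CANONICAL_AXES if a in use_axes]
    data = np.transpose(data, order)

    vs = voxel_size_um or meta_vs
    if vs is None:
        raise ConfigurationError(
            f"no voxel size metadata in {path.name}; pass voxel_size_um"
        )
    ch = channels or meta_ch or []
    return ImageStack(
        voxels=data, voxel_size_um=tuple(float(v) for v in vs), channels=ch
    )


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------


def _species_from_dict(d: dict) -> ProteinSpecies:
    try:
        return ProteinSpecies(
            name=d["name"],
            mass_kda=float(d["mass_kda"]),
            r_h_nm=float(d["r_h_nm"]) if "r_h_nm" in d else None,
            d_free=float(d["D_free"]) if "D_free" in d else None,
            d_gel={float(k): float(v) for k, v in d.get("D_gel", {}).items()},
            partition_k={float(k): float(v) for k, v in d.get("k", {}).items()},
            mobility=float(d["mobility"]) if "mobility" in d else None,
            channel=d.get("channel"),
        )
    except (KeyError, ValueError, TypeError) as exc:
        raise ConfigurationError(f"invalid species entry {d.get('name', d)}: {exc}")


def load_config(path: str | Path) -> dict:
    """Load the shared YAML config: species panel, gel, conditions.

    Returns a dict with keys ``species`` (list of ProteinSpecies), ``gel``
    (GelSpec or None), ``conditions`` (SeparationConditions or None), and
    ``raw`` (the unparsed mapping, for module-specific sections).
    """
    path = Path(path)
    raw = yaml.safe_load(path.read_text())
    if not isinstance(raw, dict):
        raise ConfigurationError(f"{path.name}: top level must be a mapping")
    species = [_species_from_dict(s) for s in raw.get("species", [])]
    gel = None
    if "gel" in raw:
        g = raw["gel"]
        try:
            gel = GelSpec(
                percent_t=float(g["percent_T"]),
                thickness_um=float(g.get("thickness_um", 1000.0)),
                well_diameter_um=float(g.get("well_diameter_um", 32.0)),
                well_depth_um=float(g.get("well_depth_um", 40.0)),
                pitch_um=float(g.get("pitch_um", 200.0)),
                temperature_k=float(g.get("temperature_K", 277.15)),
                fiber_radius_nm=(
                    float(g["fiber_radius_nm"]) if "fiber_radius_nm" in g else None
                ),
                volume_fraction=(
                    float(g["volume_fraction"]) if "volume_fraction" in g else None
                ),
            )
        except (KeyError, ValueError, TypeError) as exc:
            raise ConfigurationError(f"invalid gel section: {exc}")
    cond = None
    if "conditions" in raw:
        c = raw["conditions"]
        try:
            cond = SeparationConditions(
                field_v_per_cm=float(c["E_V_per_cm"]),
                ep_time_s=float(c["ep_time_s"]),
                lysis_time_s=float(c.get("lysis_time_s", 0.0)),
                t_diff_s=float(c["t_diff_s"]) if "t_diff_s" in c else None,
                sigma0_um=float(c.get("sigma0_um", 16.0)),
            )
        except (KeyError, ValueError, TypeError) as exc:
            raise ConfigurationError(f"invalid conditions section: {exc}")
    return {"species": species, "gel": gel, "conditions": cond, "raw": raw}


# ---------------------------------------------------------------------------
# run manifests
# ---------------------------------------------------------------------------


def _digest(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


@dataclass
class RunManifest:
    """Record of one CLI run, sufficient to reproduce it."""

    command: str
    seed: int | None = None
    config: dict = field(default_factory=dict)
    inputs: dict = field(default_factory=dict)
    outputs: dict = field(default_factory=dict)
    package_version: str = ""
    timestamp: str = ""

    def add_input(self, path: str | Path) -> None:
        p = Path(path)
        self.inputs[p.name] = _digest(p)

    def add_output(self, path: str | Path) -> None:
        p = Path(path)
        self.outputs[p.name] = _digest(p)

    def write(self, path: str | Path) -> Path:
        from . import __version__

        self.package_version = __version__
        self.timestamp = datetime.now(timezone.utc).isoformat()
        path = Path(path)
        path.write_text(json.dumps(dataclasses.asdict(self), indent=2))
        return path

    @staticmethod
    def read(path: str | Path) -> "RunManifest":
        data = json.loads(Path(path).read_text())
        return RunManifest(**data)
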