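"""Multiresolution XML/HDF5 volume container (BigDataViewer-style layout).

Volumes are stored as a block-mean image pyramid in an HDF5 file using the
conventional cell paths (``t00000/s00/<level>/cells``) plus per-setup
``resolutions`` and ``subdivisions`` tables, with a sibling SpimData-v2 XML
registering the single setup.  Because deskewing happens upstream, the
registration affine encodes only the voxel pitches (pure scaling, no shear).
Single channel, single timepoint.
"""

from __future__ import annotations

import xml.etree.ElementTree as ET
from dataclasses import dataclass
from pathlib import Path

import h5py
import numpy as np

from .reconstruct import Volume

__all__ = ["PyramidSpec", "build_pyramid", "write_bdv", "read_bdv"]


@dataclass(frozen=True)
class PyramidSpec:
    """Per-level downsample factors and storage chunking, in (z, y, x) order."""

    levels: tuple[tuple[int, int, int], ...] = ((1, 1, 1), (2, 2, 2), (4, 4, 4))
    chunk_shape: tuple[int, int, int] = (64, 64, 64)

    def __post_init__(self) -> None:
        if not self.levels:
            raise ValueError("pyramid needs at least one level")
        if tuple(self.levels[0]) != (1, 1, 1):
            raise ValueError("level 0 must have factors (1, 1, 1)")
        for lvl in self.levels:
            if len(lvl) != 3 or any(f < 1 or int(f) != f for f in lvl):
                raise ValueError(f"invalid downsample factors {lvl}")
        for prev, cur in zip(self.levels, self.levels[1:]):
            if any(c < p for p, c in zip(prev, cur)):
                raise ValueError("factors must be non-decreasing per axis")
        if any(c < 1 for c in self.chunk_shape):
            raise ValueError("chunk dimensions must be positive")


def _block_mean(arr: np.ndarray, factors: tuple[int, int, int]) -> np.ndarray:
    """Block-mean downsample; edge blocks average over available voxels."""
    sums = arr.astype(np.float64)
    counts_per_axis = []
    for ax, f in enumerate(factors):
        if f == 1:
            counts_per_axis.append(np.ones(sums.shape[ax]))
            continue
        n = sums.shape[ax]
        idx = np.arange(0, n, f)
        sums = np.add.reduceat(sums, idx, axis=ax)
        counts_per_axis.append(np.diff(np.append(idx, n)).astype(np.float64))
    denom = (counts_per_axis[0][:, None, None]
             * counts_per_axis[1][None, :, None]
             * counts_per_axis[2][None, None, :])
    return sums / denom


def build_pyramid(volume: Volume, spec: PyramidSpec = PyramidSpec()
                  ) -> list[Volume]:
    """Compute the image pyramid: level L is the block mean of level 0.

    Level 0 is returned unchanged (same grid object dtype); higher levels
    are float64 block means of the full-resolution grid, with edge blocks
    averaged over the voxels actually present.
    """
    out: list[Volume] = []
    for lvl, factors in enumerate(spec.levels):
        if lvl == 0:
            grid = volume.grid
        else:
            grid = _block_mean(volume.grid, factors)
        out.append(Volume(
            grid=grid,
            pitches=tuple(p * f for p, f in zip(volume.pitches, factors)),
            provenance=volume.provenance,
            geometry=volume.geometry,
        ))
    return out


def _paths_for(path: str | Path) -> tuple[Path, Path]:
    """Resolve the (h5, xml) sibling pair from either name or a stem."""
    path = Path(path)
    if path.suffix in (".h5", ".xml"):
        path = path.with_suffix("")
    return path.with_suffix(".h5"), path.with_suffix(".xml")


def write_bdv(volume: Volume, spec: PyramidSpec = PyramidSpec(),
              path: str | Path = "dataset", *, compression: str | None = None
              ) -> tuple[Path, Path]:
    """Write a volume as a multiresolution XML/HDF5 dataset.

    Returns the ``(h5_path, xml_path)`` pair.  Level 0 is stored in the
    grid's own dtype (bit-exact round trip for integer data); coarser
    levels of integer volumes are rounded back to that dtype.
    """
    h5_path, xml_path = _paths_for(path)
    pyramid = build_pyramid(volume, spec)
    is_int = np.issubdtype(volume.grid.dtype, np.integer)

    with h5py.File(h5_path, "w") as fh:
        fh.attrs["provenance"] = volume.provenance
        # resolutions/subdivisions tables are in (x, y, z) order
        res = np.array([lvl[::-1] for lvl in spec.levels], dtype=np.float64)
        fh.create_dataset("s00/resolutions", data=res)
        subs = []
        for lvl_vol in pyramid:
            chunk = tuple(min(c, s) for c, s in
                          zip(spec.chunk_shape, lvl_vol.grid.shape))
            subs.append(chunk[::-1])
        fh.create_dataset("s00/subdivisions",
                          data=np.array(subs, dtype=np.int32))
        for lvl, lvl_vol in enumerate(pyramid):
            grid = lvl_vol.grid
            if lvl > 0 and is_int:
                grid = np.rint(grid).astype(volume.grid.dtype)
            chunk = tuple(min(c, s) for c, s in
                          zip(spec.chunk_shape, grid.shape))
            fh.create_dataset(
                f"t00000/s00/{lvl}/cells", data=grid, chunks=chunk,
                compression=compression,
            )

    _write_xml(xml_path, h5_path.name, volume)
    return h5_path, xml_path


def _write_xml(xml_path: Path, h5_name: str, volume: Volume) -> None:
    pz, py, px = volume.pitches
    nz, ny, nx = volume.grid.shape
    root = ET.Element("SpimData", version="0.2")
    ET.SubElement(root, "BasePath", type="relative").text = "."
    seq = ET.SubElement(root, "SequenceDescription")
    loader = ET.SubElement(seq, "ImageLoader", format="bdv.hdf5")
    ET.SubElement(loader, "hdf5", type="relative").text = h5_name
    setups = ET.SubElement(seq, "ViewSetups")
    setup = ET.SubElement(setups, "ViewSetup")
    ET.SubElement(setup, "id").text = "0"
    ET.SubElement(setup, "name").text = "setup 0"
    ET.SubElement(setup, "size").text = f"{nx} {ny} {nz}"
    vox = ET.SubElement(setup, "voxelSize")
    ET.SubElement(vox, "unit").text = "micrometer"
    ET.SubElement(vox, "size").text = f"{px!r} {py!r} {pz!r}"
    tps = ET.SubElement(seq, "Timepoints", type="pattern")
    ET.SubElement(tps, "integerpattern").text = "0"
    regs = ET.SubElement(root, "ViewRegistrations")
    reg = ET.SubElement(regs, "ViewRegistration", timepoint="0", setup="0")
    tr = ET.SubElement(reg, "ViewTransform", type="affine")
    ET.SubElement(tr, "Name").text = "calibration"
    # pure scaling: shear is applied upstream, before saving
    ET.SubElement(tr, "affine").text = (
        f"{px!r} 0.0 0.0 0.0 0.0 {py!r} 0.0 0.0 0.0 0.0 {pz!r} 0.0"
    )
    ET.ElementTree(root).write(xml_path, encoding="unicode",
                               xml_declaration=True)


def read_bdv(path: str | Path, level: int = 0) -> Volume:
    """Read one pyramid level back as a :class:`Volume`.

    Pitches are the level-0 pitches from the XML scaled by that level's
    downsample factors.  A missing level raises ``ValueError`` listing the
    levels present.
    """
    h5_path, xml_path = _paths_for(path)
    if not h5_path.exists():
        raise FileNotFoundError(h5_path)
    with h5py.File(h5_path, "r") as fh:
        available = sorted(int(k) for k in fh["t00000/s00"].keys())
        if level not in available:
            raise ValueError(
                f"level {level} not present; available levels: {available}"
            )
        grid = fh[f"t00000/s00/{level}/cells"][()]
        factors_xyz = fh["s00/resolutions"][level]
        provenance = fh.attrs.get("provenance", "deskewed")

    root = ET.parse(xml_path).getroot()
    size_text = root.find(".//ViewSetup/voxelSize/size").text
    px, py, pz = (float(t) for t in size_text.split())
    fz, fy, fx = (float(f) for f in factors_xyz[::-1])
    return Volume(
        grid=grid,
        pitches=(pz * fz, py * fy, px * fx),
        provenance=str(provenance),
    )
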