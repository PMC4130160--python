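"""Domain containers and standard-format I/O (MRC/MRCS images & volumes, STAR tables).

Conventions used throughout the package
---------------------------------------
* Image arrays are indexed ``pixels[y, x]``; particle coordinates ``(x, y)``
  are 0-based pixels with the origin at the first stored pixel.
* All shift bookkeeping is in pixels; spatial frequencies are in 1/A derived
  from ``pixel_size``.
* Readers never reorder particles or frames: order on disk is the contract.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._mrc import read_mrc, read_mrc_header, write_mrc
from ._star import read_star, write_star
from .errors import FormatError, ParameterError, ShapeError

__all__ = [
    "ImageGrid2D",
    "VolumeGrid3D",
    "MovieParticle",
    "ParticleRecord",
    "read_particle_table",
    "write_particle_table",
    "read_volume",
    "write_volume",
    "read_image",
    "read_image_stack",
    "write_particle_stack",
    "load_movie_particles",
]

#: Columns a particle STAR table must provide.
REQUIRED_STAR_COLUMNS = (
    "rlnMicrographName",
    "rlnCoordinateX",
    "rlnCoordinateY",
    "rlnImageName",
)


@dataclass
class ImageGrid2D:
    """A square real-valued image with a physical pixel size (A/px)."""

    pixels: np.ndarray
    pixel_size: float

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        if self.pixels.ndim != 2 or self.pixels.shape[0] != self.pixels.shape[1]:
            raise ShapeError(f"image must be square 2-D, got shape {self.pixels.shape}")
        side = self.pixels.shape[0]
        if side < 16 or side % 2 != 0:
            raise ShapeError(f"image side must be even and >= 16, got {side}")
        if not np.all(np.isfinite(self.pixels)):
            raise ParameterError("image contains non-finite values")
        if self.pixel_size <= 0:
            raise ParameterError("pixel_size must be positive")

    @property
    def side(self) -> int:
        return self.pixels.shape[0]


@dataclass
class VolumeGrid3D:
    """A cubic real-valued volume with a physical voxel size (A/voxel)."""

    voxels: np.ndarray
    pixel_size: float

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels, dtype=np.float64)
        shape = self.voxels.shape
        if self.voxels.ndim != 3 or len(set(shape)) != 1:
            raise ShapeError(f"volume must be cubic 3-D, got shape {shape}")
        if shape[0] % 2 != 0:
            raise ShapeError(f"volume side must be even, got {shape[0]}")
        if not np.all(np.isfinite(self.voxels)):
            raise ParameterError("volume contains non-finite values")
        if self.pixel_size <= 0:
            raise ParameterError("pixel_size must be positive")

    @property
    def side(self) -> int:
        return self.voxels.shape[0]


@dataclass
class MovieParticle:
    """Per-particle movie: an ordered stack of F frame images plus coordinates.

    Frames are indexed f = 1, ..., F in all formulas; internally they are the
    0-based ``frames`` list.
    """

    particle_id: str
    micrograph_id: str
    coord_x: float
    coord_y: float
    frames: list = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.frames) < 2:
            raise ParameterError(
                f"particle {self.particle_id}: needs >= 2 movie frames, "
                f"got {len(self.frames)}"
            )
        first = self.frames[0]
        for fr in self.frames[1:]:
            if fr.pixels.shape != first.pixels.shape:
                raise ShapeError(
                    f"particle {self.particle_id}: frames differ in shape"
                )
            if fr.pixel_size != first.pixel_size:
                raise ParameterError(
                    f"particle {self.particle_id}: frames differ in pixel size"
                )

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    @property
    def pixel_size(self) -> float:
        return self.frames[0].pixel_size


@dataclass
class ParticleRecord:
    """One row of a particle STAR table with the frame count resolved."""

    particle_id: str
    micrograph_id: str
    coord_x: float
    coord_y: float
    image_path: str
    n_frames: int


def read_particle_table(path: str) -> list[ParticleRecord]:
    """Read a particle STAR table and resolve each referenced frame stack.

    The frame count F of each particle is taken from the depth of the MRCS
    stack its ``rlnImageName`` points to (resolved relative to the STAR file's
    directory).  Raises :class:`FormatError` naming any missing column, and
    :class:`FileNotFoundError` naming a dangling image reference.
    """
    df = read_star(path)
    for col in REQUIRED_STAR_COLUMNS:
        if col not in df.columns:
            raise FormatError(f"{path}: missing required STAR column _{col}")
    base = os.path.dirname(os.path.abspath(path))
    records = []
    depth_cache: dict[str, int] = {}
    for _, row in df.iterrows():
        image_name = str(row["rlnImageName"])
        image_path = os.path.join(base, image_name)
        if image_path not in depth_cache:
            if not os.path.exists(image_path):
                raise FileNotFoundError(
                    f"particle image stack not found: {image_path}"
                )
            depth_cache[image_path] = read_mrc_header(image_path)["nz"]
        records.append(
            ParticleRecord(
                particle_id=image_name,
                micrograph_id=str(row["rlnMicrographName"]),
                coord_x=float(row["rlnCoordinateX"]),
                coord_y=float(row["rlnCoordinateY"]),
                image_path=image_path,
                n_frames=depth_cache[image_path],
            )
        )
    return records


def write_particle_table(records: list[ParticleRecord] | pd.DataFrame, path: str) -> None:
    """Write particle metadata as a STAR table (inverse of read_particle_table)."""
    if isinstance(records, pd.DataFrame):
        df = records
    else:
        df = pd.DataFrame(
            {
                "rlnMicrographName": [r.micrograph_id for r in records],
                "rlnCoordinateX": [r.coord_x for r in records],
                "rlnCoordinateY": [r.coord_y for r in records],
                "rlnImageName": [
                    os.path.relpath(r.image_path, os.path.dirname(os.path.abspath(path)))
                    for r in records
                ],
            }
        )
    write_star(df, path)


def read_volume(path: str) -> VolumeGrid3D:
    """Read a cubic MRC volume."""
    data, pixel_size = read_mrc(path)
    if len(set(data.shape)) != 1:
        raise ShapeError(f"{path}: volume is not cubic, shape {data.shape}")
    return VolumeGrid3D(voxels=data, pixel_size=pixel_size)


def write_volume(volume: VolumeGrid3D, path: str) -> None:
    """Write a volume as 32-bit real MRC."""
    write_mrc(path, volume.voxels, volume.pixel_size, is_stack=False)


def read_image(path: str, index: int = 0) -> ImageGrid2D:
    """Read one 2-D slice from an MRC/MRCS file."""
    data, pixel_size = read_mrc(path)
    if index < 0 or index >= data.shape[0]:
        raise ParameterError(f"{path}: slice {index} out of range (depth {data.shape[0]})")
    return ImageGrid2D(pixels=data[index], pixel_size=pixel_size)


def read_image_stack(path: str) -> list[ImageGrid2D]:
    """Read every slice of an MRCS stack, order preserved."""
    data, pixel_size = read_mrc(path)
    return [ImageGrid2D(pixels=plane, pixel_size=pixel_size) for plane in data]


def write_particle_stack(images: list[ImageGrid2D], path: str) -> None:
    """Write a sequence of equally-shaped images as an MRCS stack."""
    if len(images) == 0:
        raise ParameterError("cannot write an empty image stack")
    shape = images[0].pixels.shape
    pixel_size = images[0].pixel_size
    for im in images[1:]:
        if im.pixels.shape != shape:
            raise ShapeError("all images in a stack must share one shape")
        if im.pixel_size != pixel_size:
            raise ParameterError("all images in a stack must share one pixel size")
    data = np.stack([im.pixels for im in images]).astype(np.float32)
    write_mrc(path, data, pixel_size, is_stack=True)


def load_movie_particles(star_path: str) -> list[MovieParticle]:
    """Load a particle table together with every referenced frame stack."""
    particles = []
    for rec in read_particle_table(star_path):
        particles.append(
            MovieParticle(
                particle_id=rec.particle_id,
                micrograph_id=rec.micrograph_id,
                coord_x=rec.coord_x,
                coord_y=rec.coord_y,
                frames=read_image_stack(rec.image_path),
            )
        )
    return particles
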