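"""Plain-text and TIFF readers/writers for movies, streams and reports.

Formats
-------
csv-stack
    One block per frame.  Each block starts with the header line
    ``#frame <index> tick <t> ny <n_py> nx <n_px>`` followed by ``n_py``
    comma-separated rows of ``n_px`` heights; within a row x varies fastest
    (the same ordering used to stack frames into state vectors).
tiff-stack
    One 32-bit float page per frame; frame ticks stored in the image
    description as JSON.
stream csv
    Header ``# stream nx <n_px> ny <n_py>`` then ``tick,pixel,value`` rows.

All writers are atomic: output goes to a temporary file in the target
directory which is renamed into place on success, so a failed run never
leaves a partial file.
"""

from __future__ import annotations

import json
import os
import tempfile
from contextlib import contextmanager
from pathlib import Path
from typing import Iterator, Literal

import numpy as np

from .afm import GridGeometry, HeightMovie, MeasurementStream
from .metrics import EvaluationReport

__all__ = [
    "FormatError",
    "read_movie",
    "write_movie",
    "read_stream",
    "write_stream",
    "write_report",
]


class FormatError(ValueError):
    """A movie or stream file does not parse under the documented dialect."""


@contextmanager
def _atomic_open(path: Path, mode: str = "w") -> Iterator:
    path = Path(path)
    fd, tmp = tempfile.mkstemp(dir=path.parent or Path("."), suffix=".tmp")
    try:
        with os.fdopen(fd, mode) as handle:
            yield handle
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


def _detect_format(path: Path, fmt: str | None) -> str:
    if fmt is not None:
        return fmt
    suffix = Path(path).suffix.lower()
    if suffix in (".tif", ".tiff"):
        return "tiff-stack"
    return "csv-stack"


def write_movie(
    movie: HeightMovie,
    path: str | os.PathLike,
    fmt: Literal["csv-stack", "tiff-stack"] | None = None,
) -> None:
    """Write a movie losslessly; format inferred from the extension."""
    path = Path(path)
    fmt = _detect_format(path, fmt)
    if fmt == "csv-stack":
        with _atomic_open(path) as fh:
            fh.write(f"# csv-stack units {movie.units} (rows are y, x fastest)\n")
            for f in range(movie.n_frames):
                fh.write(
                    f"#frame {f} tick {int(movie.frame_ticks[f])} "
                    f"ny {movie.geometry.n_py} nx {movie.geometry.n_px}\n"
                )
                for row in movie.frames[f]:
                    fh.write(",".join(repr(float(v)) for v in row) + "\n")
    elif fmt == "tiff-stack":
        import tifffile

        meta = {"frame_ticks": [int(t) for t in movie.frame_ticks], "units": movie.units}
        # tifffile writes atomically enough for our purposes via a temp name
        tmp = path.with_suffix(path.suffix + ".tmp")
        tifffile.imwrite(
            tmp,
            movie.frames.astype(np.float32),
            photometric="minisblack",
            description=json.dumps(meta),
        )
        os.replace(tmp, path)
    else:
        raise FormatError(f"unknown movie format {fmt!r}")


def read_movie(
    path: str | os.PathLike,
    fmt: Literal["csv-stack", "tiff-stack"] | None = None,
) -> HeightMovie:
    """Read a movie written by :func:`write_movie`."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = _detect_format(path, fmt)
    if fmt == "csv-stack":
        return _read_csv_stack(path)
    if fmt == "tiff-stack":
        return _read_tiff_stack(path)
    raise FormatError(f"unknown movie format {fmt!r}")


def _read_csv_stack(path: Path) -> HeightMovie:
    frames: list[np.ndarray] = []
    ticks: list[int] = []
    units = "arbitrary"
    geometry: GridGeometry | None = None
    current: list[list[float]] | None = None
    expected_rows = 0

    def close_frame() -> None:
        nonlocal current
        if current is None:
            return
        if len(current) != expected_rows:
            raise FormatError(
                f"{path}: frame {len(frames)} has {len(current)} rows, expected {expected_rows}"
            )
        frames.append(np.asarray(current, dtype=float))
        current = None

    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#frame"):
                close_frame()
                parts = line.split()
                try:
                    fields = dict(zip(parts[2::2], parts[3::2]))
                    tick = int(fields["tick"])
                    ny, nx = int(fields["ny"]), int(fields["nx"])
                except (IndexError, KeyError, ValueError) as exc:
                    raise FormatError(f"{path}:{lineno}: bad frame header {line!r}") from exc
                geom = GridGeometry(n_px=nx, n_py=ny)
                if geometry is None:
                    geometry = geom
                elif geom != geometry:
                    raise FormatError(f"{path}:{lineno}: frame geometry changed mid-file")
                ticks.append(tick)
                expected_rows = ny
                current = []
            elif line.startswith("#"):
                if "units" in line:
                    units = line.split("units", 1)[1].split("(")[0].strip() or units
            else:
                if current is None:
                    raise FormatError(f"{path}:{lineno}: data before any frame header")
                try:
                    row = [float(v) for v in line.split(",")]
                except ValueError as exc:
                    raise FormatError(f"{path}:{lineno}: non-numeric cell") from exc
                if len(row) != geometry.n_px:  # type: ignore[union-attr]
                    raise FormatError(
                        f"{path}:{lineno}: ragged row of {len(row)} values"
                    )
                current.append(row)
    close_frame()
    if geometry is None:
        raise FormatError(f"{path}: empty movie file")
    return HeightMovie(
        frames=np.stack(frames),
        geometry=geometry,
        frame_ticks=np.asarray(ticks, dtype=int),
        units=units,
    )


def _read_tiff_stack(path: Path) -> HeightMovie:
    import tifffile

    with tifffile.TiffFile(path) as tf:
        data = tf.asarray()
        desc = tf.pages[0].description or "{}"
    if data.ndim == 2:
        data = data[None, ...]
    if data.ndim != 3:
        raise FormatError(f"{path}: expected a stack of 2-D pages, got shape {data.shape}")
    try:
        meta = json.loads(desc)
    except json.JSONDecodeError:
        meta = {}
    n_frames, n_py, n_px = data.shape
    geometry = GridGeometry(n_px=n_px, n_py=n_py)
    ticks = meta.get("frame_ticks")
    if ticks is None or len(ticks) != n_frames:
        ticks = geometry.k * np.arange(1, n_frames + 1)
    return HeightMovie(
        frames=np.asarray(data, dtype=float),
        geometry=geometry,
        frame_ticks=np.asarray(ticks, dtype=int),
        units=meta.get("units", "arbitrary"),
    )


def write_stream(stream: MeasurementStream, path: str | os.PathLike) -> None:
    """Write a measurement stream as tick,pixel,value CSV."""
    path = Path(path)
    with _atomic_open(path) as fh:
        fh.write(f"# stream nx {stream.geometry.n_px} ny {stream.geometry.n_py}\n")
        fh.write("tick,pixel,value\n")
        for t, p, v in zip(stream.ticks, stream.pixels, stream.values):
            fh.write(f"{int(t)},{int(p)},{float(v)!r}\n")


def read_stream(path: str | os.PathLike) -> MeasurementStream:
    """Read a measurement stream written by :func:`write_stream`."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    geometry: GridGeometry | None = None
    ticks: list[int] = []
    pixels: list[int] = []
    values: list[float] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#"):
                parts = line.split()
                if "nx" in parts and "ny" in parts:
                    fields = dict(zip(parts[2::2], parts[3::2]))
                    geometry = GridGeometry(
                        n_px=int(fields["nx"]), n_py=int(fields["ny"])
                    )
                continue
            if line.lower().startswith("tick"):
                continue
            try:
                t, p, v = line.split(",")
                ticks.append(int(t))
                pixels.append(int(p))
                values.append(float(v))
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: bad stream record {line!r}") from exc
    if geometry is None:
        raise FormatError(f"{path}: missing '# stream nx .. ny ..' header")
    if not ticks:
        raise FormatError(f"{path}: empty stream")
    return MeasurementStream(
        ticks=np.asarray(ticks), pixels=np.asarray(pixels),
        values=np.asarray(values), geometry=geometry,
    )


def write_report(report: EvaluationReport, path: str | os.PathLike) -> None:
    """Write an evaluation report as a (frame tick, c.c.) table + summary."""
    path = Path(path)
    with _atomic_open(path) as fh:
        fh.write("frame_tick,cc\n")
        for tick, cc in report.to_rows():
            fh.write(f"{tick},{cc:.6f}\n")
        fh.write(
            f"# mean_cc {report.mean_cc:.6f} sd_cc {report.sd_cc:.6f} "
            f"sem_cc {report.sem_cc:.6f} frames {report.frames_used}\n"
        )
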