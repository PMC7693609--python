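"""Reading/writing thermal sequences and building the zero-mean heat matrix.

Supported on-disk dialects:

``tiff``
    one multi-page 32-bit float TIFF per subject (lossless binary dialect);
``txt_matrix``
    one whitespace-delimited text matrix per frame, numbered
    ``frame_000.txt`` .. — the convention of public infrared screening
    archives that ship per-frame temperature matrices;
``png_stack``
    numbered 16-bit PNGs, temperatures quantized to 0.01 degC with a fixed
    affine mapping (lossy to the quantization step; documented, not used
    where lossless round-trips are required).

The heat matrix X is pixels x frames (p x n, p > n enforced): column j is
the row-major vectorized ROI of frame j, and each row (one pixel's time
course) is mean-centered so the decompositions maximize variance across
acquisition time.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import tifffile
from PIL import Image

from .errors import ValidationError
from .phantom_sim import ThermalSequence

__all__ = [
    "HeatMatrix",
    "read_sequence",
    "write_sequence",
    "build_heat_matrix",
    "default_roi",
    "read_roi_table",
]

# PNG dialect: stored = (T - PNG_OFFSET) / PNG_SCALE as uint16
PNG_OFFSET = -40.0   # degC, camera range floor
PNG_SCALE = 0.01     # degC per count


@dataclass
class HeatMatrix:
    """Zero-mean heat matrix for one subject.

    ``X`` is p x n with p = ROI pixels and n = frames; ``row_mean`` holds
    the per-pixel temporal means removed during centering. ``roi`` is
    (row0, col0, height, width), 0-based and half-open.
    """

    X: np.ndarray
    row_mean: np.ndarray
    roi: tuple[int, int, int, int]
    source_shape: tuple[int, int]

    @property
    def p(self) -> int:
        return self.X.shape[0]

    @property
    def n(self) -> int:
        return self.X.shape[1]

    @property
    def roi_shape(self) -> tuple[int, int]:
        return self.roi[2], self.roi[3]

    def uncenter(self) -> np.ndarray:
        """Original ROI pixel time courses (p x n), centering undone."""
        return self.X + self.row_mean[:, None]

    def frame(self, j: int) -> np.ndarray:
        """Reconstruct the original ROI of frame j (height x width)."""
        return self.uncenter()[:, j].reshape(self.roi_shape)


def _frame_index(path: Path) -> int:
    nums = re.findall(r"(\d+)", path.stem)
    return int(nums[-1]) if nums else 0


def write_sequence(seq: ThermalSequence, path, dialect: str = "tiff") -> Path:
    """Write a sequence to ``path`` (a file for tiff, a directory otherwise)."""
    path = Path(path)
    if dialect == "tiff":
        if path.is_dir() or path.suffix == "":
            path = path / "sequence.tiff" if path.suffix == "" else path
        path.parent.mkdir(parents=True, exist_ok=True)
        tifffile.imwrite(path, seq.frames.astype(np.float32))
        return path
    path.mkdir(parents=True, exist_ok=True)
    for j, frame in enumerate(seq.frames):
        if dialect == "txt_matrix":
            np.savetxt(path / f"frame_{j:03d}.txt", frame, fmt="%.6f")
        elif dialect == "png_stack":
            counts = np.clip((frame - PNG_OFFSET) / PNG_SCALE, 0, 65535)
            Image.fromarray(np.round(counts).astype(np.uint16)).save(
                path / f"frame_{j:03d}.png"
            )
        else:
            raise ValidationError(f"unknown dialect {dialect!r}")
    return path


def read_sequence(path, dialect: str = "tiff", frame_interval: float = 15.0,
                  subject_id: str = "", label: str = "healthy") -> ThermalSequence:
    """Read a thermal sequence; frames are ordered by filename index."""
    path = Path(path)
    if dialect == "tiff":
        tiff_path = path
        if path.is_dir():
            candidates = sorted(path.glob("*.tif*"))
            if not candidates:
                raise OSError(f"no TIFF file found in {path}")
            tiff_path = candidates[0]
        if not tiff_path.exists():
            raise OSError(f"cannot read {tiff_path}: no such file")
        frames = np.asarray(tifffile.imread(tiff_path), dtype=np.float32)
        if frames.ndim == 2:
            frames = frames[None]
    elif dialect in ("txt_matrix", "png_stack"):
        pattern = "*.txt" if dialect == "txt_matrix" else "*.png"
        files = sorted(path.glob(pattern), key=_frame_index)
        if not files:
            raise OSError(f"no {pattern} frames found in {path}")
        loaded = []
        for f in files:
            if dialect == "txt_matrix":
                arr = np.loadtxt(f, dtype=np.float64, ndmin=2)
            else:
                arr = np.asarray(Image.open(f), dtype=np.float64)
                arr = arr * PNG_SCALE + PNG_OFFSET
            loaded.append(arr.astype(np.float32))
        shapes = [a.shape for a in loaded]
        if len(set(shapes)) > 1:
            bad = next(i for i, s in enumerate(shapes) if s != shapes[0])
            raise ValidationError(
                f"inconsistent frame shapes: {files[0].name} is {shapes[0]} "
                f"but {files[bad].name} is {shapes[bad]}"
            )
        frames = np.stack(loaded)
    else:
        raise ValidationError(f"unknown dialect {dialect!r}")
    return ThermalSequence(frames=frames, frame_interval=frame_interval,
                           subject_id=subject_id or path.stem, label=label)


def default_roi(frame_shape, fraction: float = 0.9) -> tuple[int, int, int, int]:
    """Centered square ROI covering ``fraction`` of the shorter frame side."""
    rows, cols = frame_shape
    side = int(round(min(rows, cols) * fraction))
    r0 = (rows - side) // 2
    c0 = (cols - side) // 2
    return (r0, c0, side, side)


def build_heat_matrix(seq: ThermalSequence, roi=None) -> HeatMatrix:
    """Vectorize ROI frames into the p x n heat matrix and mean-center rows.

    Column j is the row-major raveled ROI of frame j; the per-pixel
    temporal mean is removed and stored for exact un-centering.
    Requires p > n (more ROI pixels than frames).
    """
    if roi is None:
        roi = default_roi(seq.frame_shape)
    r0, c0, height, width = (int(v) for v in roi)
    rows, cols = seq.frame_shape
    if r0 < 0 or c0 < 0 or height <= 0 or width <= 0 or r0 + height > rows or c0 + width > cols:
        raise ValidationError(
            f"roi {roi} outside frame bounds {seq.frame_shape}"
        )
    p = height * width
    n = seq.tau
    if p <= n:
        raise ValidationError(
            f"ROI has p={p} pixels for n={n} frames; the heat matrix requires p > n "
            f"(more pixels than frames) — enlarge the ROI or shorten the sequence"
        )
    crop = seq.frames[:, r0:r0 + height, c0:c0 + width].astype(np.float64)
    X = crop.reshape(n, p).T.copy()           # row-major vectorization per frame
    row_mean = X.mean(axis=1)
    X -= row_mean[:, None]
    return HeatMatrix(X=X, row_mean=row_mean, roi=(r0, c0, height, width),
                      source_shape=(rows, cols))


def read_roi_table(path) -> dict[str, tuple[int, int, int, int]]:
    """ROI table CSV: subject_id,row0,col0,height,width -> dict by subject."""
    import pandas as pd

    df = pd.read_csv(path)
    required = {"subject_id", "row0", "col0", "height", "width"}
    if not required.issubset(df.columns):
        raise ValidationError(f"ROI table must have columns {sorted(required)}")
    return {
        str(r.subject_id): (int(r.row0), int(r.col0), int(r.height), int(r.width))
        for r in df.itertuples()
    }
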