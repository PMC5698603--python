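"""Classifier input construction: grid-shaped 3D tensors and flat 2D matrices.

The spatially faithful input places each of the 64 channels at its scalp
position on a 10 x 11 grid, giving a (10, 11, 28) tensor per trial whose
third axis is time; the 46 grid cells without an electrode are zero in every
time slice. The baseline input is the usual (64, 28) channel x time matrix.

Axis convention, used everywhere: axis 0 = grid rows (anterior -> posterior),
axis 1 = grid columns (left -> right), axis 2 = time.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np

GRID_ROWS = 10
GRID_COLS = 11
N_CHANNELS = 64
N_TIME = 28


@dataclass(frozen=True)
class ElectrodeLayout:
    """64 named channels assigned to distinct cells of the 10 x 11 grid."""

    channel_names: tuple[str, ...]
    cells: dict[str, tuple[int, int]]  # name -> (row, col)

    @property
    def rows(self) -> np.ndarray:
        return np.array([self.cells[c][0] for c in self.channel_names])

    @property
    def cols(self) -> np.ndarray:
        return np.array([self.cells[c][1] for c in self.channel_names])

    @property
    def n_empty_cells(self) -> int:
        return GRID_ROWS * GRID_COLS - len(self.channel_names)

    def empty_mask(self) -> np.ndarray:
        """Boolean (10, 11) mask, True where no electrode sits."""
        mask = np.ones((GRID_ROWS, GRID_COLS), dtype=bool)
        mask[self.rows, self.cols] = False
        return mask


def load_layout(path: str | Path | None = None) -> ElectrodeLayout:
    """Read a layout file: one ``channel row col`` triple per line.

    ``#`` starts a comment. The file must assign all 64 channels to distinct
    in-range cells; violations are reported with the offending line number.
    Without a path the bundled BioSemi-64 default layout is used.
    """
    if path is None:
        text = (
            resources.files("p300grid").joinpath("data/biosemi64_grid.txt").read_text()
        )
    else:
        text = Path(path).read_text()

    names: list[str] = []
    cells: dict[str, tuple[int, int]] = {}
    seen_cells: dict[tuple[int, int], int] = {}
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        parts = line.split()
        if len(parts) != 3:
            raise ValueError(f"line {lineno}: expected 'channel row col', got {raw!r}")
        name, row_s, col_s = parts
        try:
            row, col = int(row_s), int(col_s)
        except ValueError as exc:
            raise ValueError(f"line {lineno}: non-integer cell in {raw!r}") from exc
        if not (0 <= row < GRID_ROWS and 0 <= col < GRID_COLS):
            raise ValueError(
                f"line {lineno}: cell ({row}, {col}) outside the "
                f"{GRID_ROWS} x {GRID_COLS} grid"
            )
        if name in cells:
            raise ValueError(f"line {lineno}: channel {name} listed twice")
        if (row, col) in seen_cells:
            raise ValueError(
                f"line {lineno}: cell ({row}, {col}) already taken by the "
                f"channel on line {seen_cells[(row, col)]}"
            )
        names.append(name)
        cells[name] = (row, col)
        seen_cells[(row, col)] = lineno

    if len(names) != N_CHANNELS:
        raise ValueError(f"layout lists {len(names)} channels, expected {N_CHANNELS}")
    return ElectrodeLayout(channel_names=tuple(names), cells=cells)


def build_3d(epoch_data: np.ndarray, layout: ElectrodeLayout) -> np.ndarray:
    """Scatter a (64, 28) epoch onto the grid -> (10, 11, 28) tensor.

    Channel i of the epoch lands at the layout's (row, col) for channel i;
    cells without an electrode are exactly zero in every time slice. The map
    is invertible: ``extract_channels(build_3d(e, lay), lay) == e`` bit-exactly.
    """
    data = np.asarray(epoch_data)
    if data.shape != (N_CHANNELS, N_TIME):
        raise ValueError(f"epoch shape {data.shape} != ({N_CHANNELS}, {N_TIME})")
    tensor = np.zeros((GRID_ROWS, GRID_COLS, N_TIME), dtype=data.dtype)
    tensor[layout.rows, layout.cols, :] = data
    return tensor


def extract_channels(tensor: np.ndarray, layout: ElectrodeLayout) -> np.ndarray:
    """Inverse of :func:`build_3d`: read electrode cells back to (64, 28)."""
    if tensor.shape != (GRID_ROWS, GRID_COLS, N_TIME):
        raise ValueError(f"tensor shape {tensor.shape} != (10, 11, {N_TIME})")
    return tensor[layout.rows, layout.cols, :]


def build_2d(epoch_data: np.ndarray) -> np.ndarray:
    """The baseline flat input: the (64, 28) epoch matrix itself (copied).

    Channel order is the epoch's own (fixed per run); no grid, no padding.
    """
    data = np.asarray(epoch_data)
    if data.shape != (N_CHANNELS, N_TIME):
        raise ValueError(f"epoch shape {data.shape} != ({N_CHANNELS}, {N_TIME})")
    return data.copy()


def build_tensor_stack(
    epochs: list, layout: ElectrodeLayout, kind: str = "3d"
) -> tuple[np.ndarray, np.ndarray]:
    """Stack epochs into classifier inputs ``(X, y)``.

    kind='3d' -> X (n, 10, 11, 28); kind='2d' -> X (n, 64, 28).
    y is the 0/1 target-label vector.
    """
    if kind not in ("3d", "2d"):
        raise ValueError(f"kind must be '3d' or '2d', got {kind!r}")
    if kind == "3d":
        X = np.stack([build_3d(ep.data, layout) for ep in epochs])
    else:
        X = np.stack([build_2d(ep.data) for ep in epochs])
    y = np.array([int(ep.is_target) for ep in epochs], dtype=np.int64)
    return X, y
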