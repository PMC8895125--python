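"""Tumor-bed pH mapping: droplet sampling, map assembly, resection mask.

A stereotactically stepped pipette samples each pixel of the inspected
field with a microliter water droplet; the droplet equilibrates with the
tissue surface, is read on a SERS chip, and the calibration model turns
the spectrum into a pH value. Pixels are visited row-major from the top
left; the map stores raw point measurements (no interpolation) and the
resection rule marks every pixel below the pH threshold (default 7.0).
"""

from __future__ import annotations

import os
from dataclasses import dataclass

import numpy as np

from .buffer import droplet_equilibration
from .exceptions import AssemblyError
from .preprocess import featurize
from .simulate import ChipModel, PHField, ReporterModel, synth_spectrum

PH_LIMITS = (5.0, 8.0)
COLOR_SCALE = (6.0, 7.6)
RESECTION_THRESHOLD = 7.0


@dataclass(frozen=True)
class PixelMeasurement:
    row: int
    col: int
    true_ph: float
    droplet_ph: float
    measured_ph: float


@dataclass
class PHMap:
    """Measured pH values on a rectangular grid of droplet-sampled pixels."""

    values: np.ndarray
    pixel_mm: tuple[float, float] = (1.2, 1.2)
    origin_mm: tuple[float, float] = (0.0, 0.0)
    chip_id: str | None = None
    model_name: str | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise AssemblyError("pH map must be a 2-D grid")
        if not np.all(np.isfinite(self.values)):
            raise AssemblyError("pH map contains non-finite values")
        if np.any(self.values < PH_LIMITS[0]) or np.any(self.values > PH_LIMITS[1]):
            raise AssemblyError("pH map values outside the calibrated range 5-8")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


@dataclass(frozen=True)
class ResectionMask:
    """Pixels designated for excision: measured pH strictly below threshold."""

    mask: np.ndarray
    threshold: float = RESECTION_THRESHOLD


def sample_phantom(
    field: PHField,
    chip: ChipModel,
    model,
    seed: int | np.random.Generator | None = 0,
    reporter: ReporterModel | None = None,
    droplet_k: float | None = None,
    n_acquisitions: int = 3,
) -> list[PixelMeasurement]:
    """Simulate droplet sampling of every pixel of a phantom, row-major.

    For each pixel, the droplet pH follows from the tissue pH and local
    buffer capacity; ``n_acquisitions`` 500 ms scans of the droplet are
    simulated on ``chip`` (the several-second pixel dwell allows a few),
    each is preprocessed and read by ``model`` (anything with a
    ``predict_ph`` method), and the pixel value is the mean of the
    readings. Every scan keeps the acquisition statistics the model was
    calibrated on. Fully deterministic under a fixed seed.
    """
    reporter = reporter or ReporterModel()
    rng = np.random.default_rng(seed)
    rows, cols = field.ph.shape
    kwargs = {} if droplet_k is None else {"k": droplet_k}
    droplet = droplet_equilibration(field.ph, field.beta_t, **kwargs)
    features = []
    coords = [(r, c) for r in range(rows) for c in range(cols)]
    for r, c in coords:
        for _ in range(n_acquisitions):
            spec = synth_spectrum(chip, reporter, float(droplet[r, c]), rng=rng)
            features.append(featurize(spec).values)
    readings = np.clip(model.predict_ph(np.asarray(features)), *PH_LIMITS)
    measured = readings.reshape(len(coords), n_acquisitions).mean(axis=1)
    return [
        PixelMeasurement(r, c, float(field.ph[r, c]), float(droplet[r, c]), float(m))
        for (r, c), m in zip(coords, measured)
    ]


def assemble_map(
    measurements: list[PixelMeasurement],
    rows: int,
    cols: int,
    pixel_mm: tuple[float, float] = (1.2, 1.2),
    **meta,
) -> PHMap:
    """Fill the grid from measurements; explicit (row, col) indices are honored.

    Measurements given in scan order with correct indices and any
    permutation of them produce the same map.
    """
    if len(measurements) != rows * cols:
        raise AssemblyError(f"expected {rows * cols} measurements, got {len(measurements)}")
    values = np.full((rows, cols), np.nan)
    for m in measurements:
        if not (0 <= m.row < rows and 0 <= m.col < cols):
            raise AssemblyError(f"pixel ({m.row}, {m.col}) outside the {rows}x{cols} grid")
        if not np.isnan(values[m.row, m.col]):
            raise AssemblyError(f"pixel ({m.row}, {m.col}) measured twice")
        values[m.row, m.col] = m.measured_ph
    return PHMap(values=values, pixel_mm=pixel_mm, **meta)


def resection_mask(ph_map: PHMap, threshold: float = RESECTION_THRESHOLD) -> ResectionMask:
    """Mark pixels with measured pH below ``threshold`` for excision."""
    return ResectionMask(mask=ph_map.values < threshold, threshold=threshold)


def dice_coefficient(a: np.ndarray, b: np.ndarray) -> float:
    """Dice overlap of two boolean masks (1.0 when both are empty)."""
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    denom = a.sum() + b.sum()
    if denom == 0:
        return 1.0
    return 2.0 * float(np.logical_and(a, b).sum()) / float(denom)


def render_map(
    ph_map: PHMap,
    mask: ResectionMask,
    out_dir: str | os.PathLike,
    color_scale: tuple[float, float] = COLOR_SCALE,
) -> tuple[str, str]:
    """Write the map as a CSV table and a raster heatmap.

    The CSV has one row per pixel (row, col, x_mm, y_mm, pH, resect flag)
    and is byte-identical across re-renders; the heatmap uses a fixed pH
    color scale so maps from different sessions are comparable.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    out_dir = os.fspath(out_dir)
    os.makedirs(out_dir, exist_ok=True)
    rows, cols = ph_map.shape
    csv_path = os.path.join(out_dir, "ph_map.csv")
    with open(csv_path, "w") as fh:
        fh.write("row,col,x_mm,y_mm,ph,resect\n")
        for r in range(rows):
            for c in range(cols):
                x = ph_map.origin_mm[0] + (c + 0.5) * ph_map.pixel_mm[0]
                y = ph_map.origin_mm[1] + (r + 0.5) * ph_map.pixel_mm[1]
                fh.write(
                    f"{r},{c},{x:.2f},{y:.2f},{ph_map.values[r, c]:.3f},"
                    f"{int(mask.mask[r, c])}\n"
                )

    fig, ax = plt.subplots(figsize=(4.2, 3.6))
    im = ax.imshow(
        ph_map.values, cmap="RdYlBu", vmin=color_scale[0], vmax=color_scale[1]
    )
    for r in range(rows):
        for c in range(cols):
            if mask.mask[r, c]:
                ax.plot(c, r, marker="x", color="black", markersize=6)
    fig.colorbar(im, ax=ax, label="pH")
    ax.set_xlabel("column")
    ax.set_ylabel("row")
    ax.set_title(f"pH map ({rows}x{cols}, pixel {ph_map.pixel_mm[0]:.1f} mm)")
    png_path = os.path.join(out_dir, "ph_map.png")
    fig.savefig(png_path, dpi=120, bbox_inches="tight")
    plt.close(fig)
    return csv_path, png_path
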