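"""Phenomenological simulator for pH-responsive SERS chips.

The reporter is a heptamethine cyanine whose Raman bands grow on
acidification: protonation of its piperazine group red-shifts the absorption
onto the 785 nm excitation line, so every conjugated-system band gains
resonance enhancement while the 311 1/cm alkyl C-C bend is untouched and
serves as the internal standard. The simulator does not model the resonance
physics; it reproduces the observable: per-peak amplitudes scale between a
deprotonated (pH 8) and a fully protonated (pH 2) level following a
Henderson-Hasselbalch protonation isotherm.

Chip-to-chip fabrication variability enters through four per-chip knobs:
a global gain, a per-peak amplitude fingerprint, a smooth polynomial
baseline, and a calibration offset that shifts the apparent protonation
response along the pH axis. The offset is what the chip-grouping rule
(groups a-e, from the signed readout error at pH 6.50) measures.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .exceptions import GenerationError
from .io import RamanSpectrum, SpectraDataset, from_records

# ---------------------------------------------------------------------------
# canonical shift axis

#: 1-based crop window used by the preprocessing stage
CROP_WINDOW = (80, 335)
#: Raman-shift span (1/cm) the crop window must cover
CROP_SPAN = (390.0, 1700.0)


def canonical_grid(
    n: int = 400,
    window: tuple[int, int] = CROP_WINDOW,
    span: tuple[float, float] = CROP_SPAN,
) -> np.ndarray:
    """Uniform shift axis placing 1-based points ``window`` at ``span``.

    With the defaults the 80th..335th points sit at 390..1700 1/cm, which
    puts the internal-standard peak (311 1/cm) and its right trough left of
    the crop window. The implied axis starts slightly below 0 1/cm, as CCD
    pixels below the notch-filter edge do.
    """
    step = (span[1] - span[0]) / (window[1] - window[0])
    start = span[0] - (window[0] - 1) * step
    return start + step * np.arange(n)


# ---------------------------------------------------------------------------
# reporter

PEAK_CENTERS = (311.0, 527.0, 558.0, 927.0, 1199.0, 1377.0, 1467.0)
#: fold-change of each band from pH 8 to pH 2; 311 is the invariant standard,
#: 1199 (olefin C-C stretch) gains the most, 558 the least.
PEAK_ENHANCEMENTS = (1.0, 3.0, 2.6, 2.8, 3.4, 3.1, 2.9)
PEAK_BASE_AMPLITUDES = (1000.0, 900.0, 850.0, 420.0, 700.0, 520.0, 380.0)


@dataclass(frozen=True)
class ReporterModel:
    """Spectral model of the reporter dye on the chip surface."""

    peak_centers: tuple[float, ...] = PEAK_CENTERS
    peak_fwhm: tuple[float, ...] = tuple([18.0] * len(PEAK_CENTERS))
    base_amplitudes: tuple[float, ...] = PEAK_BASE_AMPLITUDES
    enhancement_max: tuple[float, ...] = PEAK_ENHANCEMENTS
    pka_app: float = 6.7
    #: apparent Hill coefficient of the surface-bound titration; adsorbed
    #: indicators show strongly broadened curves (site heterogeneity), which
    #: is what makes the intensity ratio near-linear in pH over 5-8
    hill: float = 0.35
    voigt_eta: float = 0.5
    #: pH anchors of the deprotonated / protonated reference states
    anchor_ph: tuple[float, float] = (8.0, 2.0)

    def _f(self, ph):
        return 1.0 / (1.0 + np.power(10.0, self.hill * (np.asarray(ph, float) - self.pka_app)))

    def response_fraction(self, ph: np.ndarray | float) -> np.ndarray | float:
        """Broadened protonation response rescaled to 0 at pH 8 and 1 at pH 2."""
        f_hi = self._f(self.anchor_ph[0])
        f_lo = self._f(self.anchor_ph[1])
        return (self._f(ph) - f_hi) / (f_lo - f_hi)

    def amplitudes(self, ph: float) -> np.ndarray:
        """Per-peak amplitudes (counts) of an ideal unit-gain chip at ``ph``."""
        fr = self.response_fraction(ph)
        # fr is 0 at pH 8 and 1 at pH 2 by construction
        base = np.asarray(self.base_amplitudes)
        enh = np.asarray(self.enhancement_max)
        return base * (1.0 + (enh - 1.0) * fr)


def protonation_fraction(ph, pka_app):
    """Fraction of reporter molecules protonated at ``ph``.

    Henderson-Hasselbalch: ``f = 1 / (1 + 10**(ph - pKa))``; strictly
    decreasing in pH, 0.5 at the apparent pKa.
    """
    return 1.0 / (1.0 + np.power(10.0, np.asarray(ph, dtype=float) - pka_app))


def pseudo_voigt(x: np.ndarray, center: float, fwhm: float, eta: float) -> np.ndarray:
    """Unit-height pseudo-Voigt profile (eta Lorentzian + (1-eta) Gaussian)."""
    half = fwhm / 2.0
    lor = half**2 / ((x - center) ** 2 + half**2)
    gau = np.exp(-4.0 * np.log(2.0) * (x - center) ** 2 / fwhm**2)
    return eta * lor + (1.0 - eta) * gau


# ---------------------------------------------------------------------------
# chips

@dataclass
class ChipModel:
    """Parameters of one simulated SERS chip.

    ``ratio_offset`` shifts the chip's apparent protonation response along
    the pH axis (pH units at readout); together with the peak fingerprint it
    determines the chip's signed error at pH 6.50 and hence its group.
    """

    chip_id: str
    gain: float = 1.0
    ratio_offset: float = 0.0
    peak_factors: np.ndarray = field(
        default_factory=lambda: np.ones(len(PEAK_CENTERS))
    )
    baseline_params: tuple[float, float, float] = (40.0, 20.0, 10.0)
    noise_sigma: float = 8.0
    fitted_calib: tuple[float, float] | None = None
    group: str | None = None
    err: float | None = None

    def __post_init__(self) -> None:
        if self.gain <= 0:
            raise ValueError("chip gain must be positive")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be nonnegative")


def synth_peak_amplitudes(chip: ChipModel, reporter: ReporterModel, ph: float) -> np.ndarray:
    """Per-peak amplitudes of ``chip`` at true solution pH ``ph`` (noise-free)."""
    ideal = reporter.amplitudes(ph + chip.ratio_offset)
    return ideal * chip.peak_factors * chip.gain


def notch_edge(grid: np.ndarray, center: float = 90.0, width: float = 30.0) -> np.ndarray:
    """Transmission of the Rayleigh-rejection edge filter (0 near the laser line).

    Suppresses everything below ~100 1/cm, which pins the spectrum's left
    edge near zero counts — the region the peak-1 left endpoint search
    relies on being below the right-trough level.
    """
    return 0.5 * (1.0 + np.tanh((grid - center) / width))


def chip_baseline(chip: ChipModel, grid: np.ndarray) -> np.ndarray:
    """Smooth per-chip background (counts), scaled by the chip gain."""
    t = (grid - grid[0]) / (grid[-1] - grid[0])
    b0, b1, b2 = chip.baseline_params
    return chip.gain * np.clip(b0 + b1 * t + b2 * t**2, 0.0, None)


def synth_spectrum(
    chip: ChipModel,
    reporter: ReporterModel,
    ph: float,
    rng: np.random.Generator | int | None = None,
    grid: np.ndarray | None = None,
    noise: bool = True,
) -> RamanSpectrum:
    """Simulate one acquisition of ``chip`` at solution pH ``ph``.

    Sum of pseudo-Voigt bands with pH-dependent amplitudes, plus the chip's
    smooth baseline, plus additive Gaussian shot/readout noise. Intensities
    are clipped at zero (a spectrometer reports nonnegative counts).
    """
    if grid is None:
        grid = canonical_grid()
    amps = synth_peak_amplitudes(chip, reporter, ph)
    signal = chip_baseline(chip, grid)
    for amp, center, fwhm in zip(amps, reporter.peak_centers, reporter.peak_fwhm):
        signal = signal + amp * pseudo_voigt(grid, center, fwhm, reporter.voigt_eta)
    signal = signal * notch_edge(grid)
    if noise and chip.noise_sigma > 0:
        rng = np.random.default_rng(rng)
        signal = signal + rng.normal(0.0, chip.noise_sigma, size=grid.size)
    return RamanSpectrum(grid, np.clip(signal, 0.0, None), chip_id=chip.chip_id)


# ---------------------------------------------------------------------------
# chip groups

#: half-open covering closure of the five err intervals
GROUP_BOUNDS = {
    "a": (0.5, np.inf),     # err > 0.5
    "b": (0.1, 0.5),        # 0.1 < err <= 0.5
    "c": (-0.1, 0.1),       # -0.1 <= err <= 0.1
    "d": (-0.2, -0.1),      # -0.2 < err < -0.1
    "e": (-np.inf, -0.2),   # err <= -0.2
}

#: sampling ranges for the target err of each group; finite ends for the
#: open-ended groups, shrunk by a safety margin so that acquisition noise
#: cannot flip a chip across a group boundary
_GROUP_TARGET_RANGES = {
    "a": (0.53, 0.85),
    "b": (0.13, 0.47),
    "c": (-0.07, 0.07),
    "d": (-0.17, -0.13),
    "e": (-0.57, -0.23),
}

#: default composition of a 40-chip batch (group c most frequent)
DEFAULT_GROUP_MIX = {"a": 0.15, "b": 0.20, "c": 0.30, "d": 0.175, "e": 0.175}


def group_from_err(err: float) -> str:
    """Map a signed pH-6.50 readout error to its chip group (a-e)."""
    if err > 0.5:
        return "a"
    if err > 0.1:
        return "b"
    if err >= -0.1:
        return "c"
    if err > -0.2:
        return "d"
    return "e"


def _master_readout_err(chip: ChipModel, reporter: ReporterModel, calib, grid) -> float:
    """Noise-free signed error of the master-calibration readout at pH 6.50."""
    from .baseline import intensity_ratio  # local import to avoid a cycle

    spec = synth_spectrum(chip, reporter, 6.50, grid=grid, noise=False)
    a, b = calib
    return a * intensity_ratio(spec) + b - 6.50


def synth_chip(
    group_target: str,
    seed: np.random.Generator | int | None,
    reporter: ReporterModel | None = None,
    chip_id: str | None = None,
    max_retries: int = 60,
) -> ChipModel:
    """Sample a chip whose pH-6.50 readout error lands in ``group_target``.

    Gain, fingerprint, baseline and noise are sampled freely; the calibration
    offset is then steered (closed loop against the master-calibration
    readout of a simulated pH-6.50 acquisition) until the signed error falls
    in the target interval, with a margin against acquisition noise.
    """
    if group_target not in GROUP_BOUNDS:
        raise GenerationError(f"unknown chip group {group_target!r}")
    from .baseline import master_calibration

    reporter = reporter or ReporterModel()
    rng = np.random.default_rng(seed)
    grid = canonical_grid()
    calib = master_calibration(reporter, grid)
    lo, hi = _GROUP_TARGET_RANGES[group_target]
    for attempt in range(max_retries):
        chip = ChipModel(
            chip_id=chip_id or "chip",
            gain=float(np.exp(rng.normal(0.0, 0.25))),
            ratio_offset=0.0,
            peak_factors=np.exp(rng.normal(0.0, 0.06, size=len(reporter.peak_centers))),
            # background rises with shift (fluorescence wing), which keeps the
            # peak-1 left flank below the trough level and the bounds search
            # well-posed on noisy acquisitions
            baseline_params=(
                float(rng.uniform(20.0, 80.0)),
                float(rng.uniform(5.0, 40.0)),
                float(rng.uniform(-2.0, 20.0)),
            ),
            noise_sigma=float(rng.uniform(4.0, 10.0)),
        )
        target = float(rng.uniform(lo, hi))
        # err responds ~1:1 to ratio_offset; a few Newton steps suffice
        for _ in range(12):
            err = _master_readout_err(chip, reporter, calib, grid)
            if lo - 1e-3 <= err <= hi + 1e-3:
                chip.err = err
                chip.group = group_from_err(err)
                assert chip.group == group_target
                return chip
            chip.ratio_offset += 0.8 * (target - err)
    raise GenerationError(
        f"could not generate a group-{group_target} chip in {max_retries} attempts"
    )


# ---------------------------------------------------------------------------
# database

PH_GRID = tuple(np.round(np.arange(5.00, 8.001, 0.25), 2))


def _group_sequence(n_chips: int, group_mix: dict[str, float]) -> list[str]:
    """Largest-remainder allocation of ``n_chips`` over the group mix."""
    groups = sorted(group_mix)
    quotas = np.array([group_mix[g] for g in groups], dtype=float)
    quotas = quotas / quotas.sum() * n_chips
    counts = np.floor(quotas).astype(int)
    for i in np.argsort(-(quotas - counts))[: n_chips - counts.sum()]:
        counts[i] += 1
    seq: list[str] = []
    for g, c in zip(groups, counts):
        seq.extend([g] * c)
    return seq


def build_database(
    n_chips: int = 40,
    ph_grid: tuple[float, ...] = PH_GRID,
    reps: int = 20,
    group_mix: dict[str, float] | None = None,
    seed: int = 0,
    reporter: ReporterModel | None = None,
    label_noise: float = 0.02,
) -> tuple[SpectraDataset, list[ChipModel]]:
    """Simulate the full calibration database.

    Defaults emulate the study conditions: 40 chips x 13 pH levels
    (5.00..8.00 in 0.25 steps) x 20 replicate acquisitions = 10400 spectra,
    chips drawn from five robustness groups. Each acquisition carries a pH
    tag with pH-meter label noise (sigma ``label_noise``). All randomness
    derives from ``seed`` through named substreams, so the database is
    bit-reproducible.
    """
    reporter = reporter or ReporterModel()
    group_mix = group_mix or DEFAULT_GROUP_MIX
    root = np.random.SeedSequence(seed, spawn_key=(0x5E5,))
    ss_chips, ss_spectra, ss_tags = root.spawn(3)
    chip_seeds = ss_chips.spawn(n_chips)
    rng_spectra = np.random.default_rng(ss_spectra)
    rng_tags = np.random.default_rng(ss_tags)
    grid = canonical_grid()

    groups = _group_sequence(n_chips, group_mix)
    chips: list[ChipModel] = []
    pairs = []
    for i, (g, cs) in enumerate(zip(groups, chip_seeds)):
        chip = synth_chip(g, cs, reporter=reporter, chip_id=f"chip{i:02d}")
        chips.append(chip)
        for ph in ph_grid:
            template = synth_spectrum(chip, reporter, float(ph), grid=grid, noise=False)
            noise = rng_spectra.normal(0.0, chip.noise_sigma, size=(reps, grid.size))
            tags = float(ph) + rng_tags.normal(0.0, label_noise, size=reps)
            for r in range(reps):
                intens = np.clip(template.intensities + noise[r], 0.0, None)
                spec = RamanSpectrum(
                    grid, intens, chip_id=chip.chip_id,
                    nominal_ph=float(ph), ph_tag=float(tags[r]), replicate=r,
                )
                pairs.append(
                    (
                        spec,
                        {
                            "chip_id": chip.chip_id,
                            "chip_group": chip.group,
                            "nominal_ph": float(ph),
                            "ph_tag": float(tags[r]),
                            "replicate": r,
                            "split": None,
                        },
                    )
                )
    return from_records(pairs), chips


# ---------------------------------------------------------------------------
# tissue phantom

@dataclass
class PHField:
    """Ground-truth tissue pH field on a rectangular pixel grid.

    ``beta_t`` is the per-pixel buffer capacity of the interstitial fluid
    (mEq/L/pH); tumor pixels are acidic (pH 6.2-6.8), non-malignant pixels
    neutral (pH 7.0-7.5).
    """

    ph: np.ndarray
    beta_t: np.ndarray
    tumor_mask: np.ndarray
    pixel_mm: tuple[float, float] = (1.2, 1.2)


def synth_phantom(
    rows: int = 8,
    cols: int = 8,
    tumor_geometry: str = "blob",
    seed: int | np.random.Generator | None = 0,
    beta_range: tuple[float, float] = (5.0, 60.0),
    pixel_mm: tuple[float, float] = (1.2, 1.2),
) -> PHField:
    """Simulate a tumor-bed pH field.

    ``tumor_geometry``: "blob" (contiguous elliptical tumor with a mildly
    acid-shifted margin ring), "none" (no tumor) or "full" (all tumor).
    Buffer capacities are uniform in ``beta_range`` (interstitial fluid is
    well above the 2.8 mEq/L/pH feasibility threshold).
    """
    rng = np.random.default_rng(seed)
    shape = (rows, cols)
    mask = np.zeros(shape, dtype=bool)
    if tumor_geometry == "full":
        mask[:] = True
    elif tumor_geometry == "blob":
        cy = rng.uniform(0.3, 0.7) * (rows - 1)
        cx = rng.uniform(0.3, 0.7) * (cols - 1)
        ry = rng.uniform(0.22, 0.32) * rows
        rx = rng.uniform(0.22, 0.32) * cols
        yy, xx = np.mgrid[0:rows, 0:cols]
        mask = ((yy - cy) / ry) ** 2 + ((xx - cx) / rx) ** 2 <= 1.0
        if not mask.any():
            mask[int(round(cy)), int(round(cx))] = True
    elif tumor_geometry != "none":
        raise ValueError(f"unknown tumor_geometry {tumor_geometry!r}")

    ph = rng.uniform(7.2, 7.5, size=shape)
    ring = ndimage.binary_dilation(mask) & ~mask
    ph[ring] = rng.uniform(7.05, 7.3, size=int(ring.sum()))
    ph[mask] = rng.uniform(6.2, 6.8, size=int(mask.sum()))
    if tumor_geometry == "none":
        ph = rng.uniform(7.05, 7.5, size=shape)
    beta = rng.uniform(*beta_range, size=shape)
    return PHField(ph=ph, beta_t=beta, tumor_mask=mask, pixel_mm=pixel_mm)
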