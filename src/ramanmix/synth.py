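"""Ground-truthed synthetic Raman scenes of plant tissue.

Each scene is a non-negative bilinear mixture ``D = C_true S_true * scale``
of component spectra built from Gaussian/Lorentzian bands at the wavenumbers
characteristic of lignin, cellulose, pectin, protein/lipid and water, plus a
smooth component-dependent fluorescence-like background, signal-dependent
Gaussian noise (shot-noise surrogate) and optional cosmic-ray spikes.

Layouts emulate the anatomy of 20 um spruce cross-sections (cell corners and
compound middle lamella, the S1 and S2 secondary-wall layers, water-filled
lumina) and of an Arabidopsis stem section (lignified xylem, pectin-rich
cambium/phloem primary walls, protein/lipid deposits).  Abundance rows sum to
one exactly; ground truth (C_true, S_true, background, spike positions,
region masks) is stored with the scene.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .datamodel import HyperspectralImage, SpectralAxis, regular_axis

__all__ = [
    "BandSpec",
    "ComponentSpectrum",
    "SyntheticScene",
    "render_component",
    "builtin_library",
    "make_scene",
    "diffraction_resolution",
    "LAYOUTS",
]

LAYOUTS = ("spruce", "arabidopsis", "simplex", "lowvar_water")


@dataclass(frozen=True)
class BandSpec:
    """One vibrational band: position (cm^-1), FWHM (cm^-1), relative height."""

    center: float
    width: float
    height: float
    shape: str = "gaussian"

    def __post_init__(self) -> None:
        if self.width <= 0:
            raise ValueError("band width must be positive")
        if self.height < 0:
            raise ValueError("band height must be non-negative")
        if self.shape not in ("gaussian", "lorentzian"):
            raise ValueError("band shape must be gaussian or lorentzian")

    def profile(self, wavenumbers: np.ndarray) -> np.ndarray:
        x = wavenumbers - self.center
        if self.shape == "gaussian":
            return self.height * np.exp(-4.0 * np.log(2.0) * x**2 / self.width**2)
        hw = self.width / 2.0
        return self.height * hw**2 / (x**2 + hw**2)


@dataclass
class ComponentSpectrum:
    """Named pure component: a list of bands plus a fluorescence propensity.

    ``baseline_gain`` scales the smooth background this component drags along
    (different chemical components generate different backgrounds); ``partial``
    flags a component whose bands are not all covered by the rendering axis.
    """

    name: str
    bands: list
    baseline_gain: float = 0.0
    partial: bool = False

    def __post_init__(self) -> None:
        if not self.bands:
            raise ValueError("a component needs at least one band")
        if self.baseline_gain < 0:
            raise ValueError("baseline_gain must be >= 0")


def render_component(spec: ComponentSpectrum, axis: SpectralAxis) -> np.ndarray:
    """Render a component onto an axis; bands outside the axis are skipped."""
    out = np.zeros(axis.n_channels)
    for band in spec.bands:
        if band.center < axis.lo or band.center > axis.hi:
            warnings.warn(
                f"band at {band.center} cm^-1 of component {spec.name!r} "
                "lies outside the axis and was skipped"
            )
            continue
        out += band.profile(axis.wavenumbers)
    return out


def builtin_library(axis: SpectralAxis) -> dict[str, ComponentSpectrum]:
    """Component library for plant cell walls, unit-maximum normalized.

    Band positions follow the standard Raman assignments for plant tissue:
    lignin aromatic ring stretch at 1600, ring-conjugated C=C at 1660 and
    1140/1270 cm^-1; coniferyl alcohol/aldehyde shoulder at 1634 cm^-1;
    cellulose C-O-C / ring modes at 1121 and 1095 cm^-1 (the 1095 band is
    sensitive to microfibril orientation) and the 380 cm^-1 skeletal band;
    the pectin alpha-1,4-glycosidic band at 855 cm^-1; protein/lipid amide
    III 1666, CH2/CH3 bending 1450 and phenylalanine 1005 cm^-1; water as a
    low, very broad OH-bending contribution around 1640 cm^-1.
    """
    g = "gaussian"
    specs = {
        "lignin": ComponentSpectrum("lignin", [
            BandSpec(1600, 24, 1.00, g),
            BandSpec(1660, 28, 0.45, g),
            BandSpec(1140, 26, 0.35, g),
            BandSpec(1270, 30, 0.28, g),
            BandSpec(1334, 30, 0.22, g),
        ], baseline_gain=1.0),
        "lignin_coniferyl": ComponentSpectrum("lignin_coniferyl", [
            BandSpec(1600, 24, 1.00, g),
            BandSpec(1634, 18, 0.62, g),
            BandSpec(1660, 28, 0.40, g),
            BandSpec(1140, 26, 0.32, g),
            BandSpec(1270, 30, 0.26, g),
        ], baseline_gain=1.1),
        "cellulose": ComponentSpectrum("cellulose", [
            BandSpec(1121, 16, 0.95, g),
            BandSpec(1095, 16, 0.75, g),
            BandSpec(380, 18, 0.55, g),
            BandSpec(436, 20, 0.35, g),
            BandSpec(1380, 32, 0.40, g),
            BandSpec(900, 24, 0.20, g),
        ], baseline_gain=0.25),
        "cellulose_oriented": ComponentSpectrum("cellulose_oriented", [
            # polarization parallel to the microfibrils redistributes
            # intensity into 1095 and the 370-550 cm^-1 region
            BandSpec(1121, 14, 0.35, g),
            BandSpec(1095, 14, 1.80, g),
            BandSpec(380, 18, 1.00, g),
            BandSpec(436, 20, 0.65, g),
            BandSpec(520, 26, 0.40, g),
            BandSpec(1380, 32, 0.25, g),
            BandSpec(900, 24, 0.15, g),
        ], baseline_gain=0.25),
        "pectin": ComponentSpectrum("pectin", [
            BandSpec(855, 22, 1.00, g),
            BandSpec(1745, 30, 0.40, g),
            BandSpec(1330, 34, 0.30, g),
            BandSpec(1080, 28, 0.35, g),
        ], baseline_gain=0.4),
        "protein_lipid": ComponentSpectrum("protein_lipid", [
            BandSpec(1450, 26, 1.00, g),
            BandSpec(1666, 30, 0.85, g),
            BandSpec(1005, 12, 0.65, g),
            BandSpec(1305, 30, 0.40, g),
        ], baseline_gain=0.6),
        "water": ComponentSpectrum("water", [
            # OH bending plus the very broad librational background
            BandSpec(1640, 110, 0.85, g),
            BandSpec(520, 420, 0.90, g),
            BandSpec(780, 300, 0.50, g),
        ], baseline_gain=0.1),
    }
    for spec in specs.values():
        covered = [b for b in spec.bands
                   if axis.lo <= b.center <= axis.hi]
        if len(covered) < len(spec.bands):
            spec.partial = True
        if not covered:
            warnings.warn(f"component {spec.name!r} has no band on this axis")
            continue
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            peak = render_component(spec, axis).max()
        if peak > 0:
            for i, b in enumerate(spec.bands):
                spec.bands[i] = BandSpec(b.center, b.width, b.height / peak, b.shape)
    return specs


def _render_library(names, library, axis) -> np.ndarray:
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return np.vstack([render_component(library[n], axis) for n in names])


@dataclass
class SyntheticScene:
    """A generated scene plus its full ground truth."""

    image: HyperspectralImage
    names: list
    S_true: np.ndarray
    C_true: np.ndarray
    background_true: np.ndarray
    spike_locations: list
    region_masks: dict
    seed: int
    scale: float
    manifest: dict = field(default_factory=dict)

    @property
    def signal(self) -> np.ndarray:
        """Noiseless, background-free bilinear part C_true S_true * scale."""
        return self.C_true @ self.S_true * self.scale

    def component_index(self, name: str) -> int:
        return self.names.index(name)


def diffraction_resolution(lambda_nm: float, na: float) -> float:
    """Abbe/Rayleigh lateral resolution limit r = 0.61 lambda / NA, in nm."""
    if lambda_nm <= 0 or na <= 0:
        raise ValueError("wavelength and numerical aperture must be positive")
    return 0.61 * lambda_nm / na


# --------------------------------------------------------------------------
# layouts: each returns (names, C_base [n x k], region_masks {name: grid bool})
# --------------------------------------------------------------------------

def _cell_pattern(grid_shape, cell=12):
    """Ring index of each pixel inside a tiling of square cells.

    0 = cell boundary (middle lamella / corners), 1 = S1 ring, 2+ = S2,
    large = lumen interior.  Also returns a corner mask (boundary crossings).
    """
    rows, cols = grid_shape
    r = np.arange(rows) % cell
    c = np.arange(cols) % cell
    dr = np.minimum(r, cell - 1 - r)[:, None]
    dc = np.minimum(c, cell - 1 - c)[None, :]
    ring = np.minimum(dr, dc) * np.ones((rows, cols), dtype=int)
    corner = (dr <= 0) & (dc <= 0) * np.ones((rows, cols), dtype=bool)
    return ring, corner


def _spruce_layout(grid_shape, rng, cell=12):
    rows, cols = grid_shape
    if min(rows, cols) < cell:
        raise ValueError(
            f"grid {rows}x{cols} too small for the spruce cell pattern "
            f"(needs >= {cell} in each direction)"
        )
    names = ["lignin", "cellulose_oriented", "cellulose", "water"]
    ring, corner = _cell_pattern(grid_shape, cell)
    lumen = ring >= 4
    cml = (ring == 0) & ~corner
    s1 = ring == 1
    s2 = (ring >= 2) & ~lumen
    base = np.empty((rows, cols, 4))
    base[corner] = (0.97, 0.01, 0.02, 0.0)
    base[cml] = (0.90, 0.04, 0.06, 0.0)
    base[s1] = (0.08, 0.80, 0.12, 0.0)
    base[s2] = (0.40, 0.04, 0.56, 0.0)
    base[lumen] = (0.01, 0.0, 0.01, 0.98)
    masks = {"corner": corner, "cml": cml, "s1": s1, "s2": s2, "lumen": lumen}
    return names, base.reshape(rows * cols, 4), masks


def _arabidopsis_layout(grid_shape, rng, cell=12):
    rows, cols = grid_shape
    if min(rows, cols) < cell or cols < 2 * cell:
        raise ValueError(
            f"grid {rows}x{cols} too small for the arabidopsis layout "
            f"(needs >= {cell} rows and >= {2 * cell} columns)"
        )
    names = ["lignin", "lignin_coniferyl", "cellulose_oriented",
             "pectin", "protein_lipid", "water"]
    k = len(names)
    ring, corner = _cell_pattern(grid_shape, cell)
    xylem_cols = int(cols * 0.55)  # left: lignified xylem; right: cambium/phloem
    xylem = np.zeros((rows, cols), bool)
    xylem[:, :xylem_cols] = True
    lumen = (ring >= 4) & xylem
    wall = xylem & ~lumen
    cml = (ring == 0) & xylem
    near_cambium = np.zeros((rows, cols), bool)
    near_cambium[:, max(0, xylem_cols - cell):xylem_cols] = True
    corner_coniferyl = corner & xylem & near_cambium
    primary = ~xylem
    # protein/lipid deposits: seeded blobs in the phloem half
    deposits = np.zeros((rows, cols), bool)
    n_blobs = max(2, (rows * cols) // 300)
    rr = rng.integers(1, rows - 1, n_blobs)
    cc = rng.integers(xylem_cols + 1, cols - 1, n_blobs)
    for a, b in zip(rr, cc):
        deposits[a - 1:a + 2, b - 1:b + 2] = True
    deposits &= primary
    base = np.empty((rows, cols, k))
    base[wall] = (0.28, 0.04, 0.48, 0.16, 0.04, 0.0)
    base[cml] = (0.72, 0.10, 0.08, 0.08, 0.02, 0.0)
    base[corner_coniferyl] = (0.18, 0.70, 0.04, 0.06, 0.02, 0.0)
    base[lumen] = (0.01, 0.0, 0.02, 0.02, 0.0, 0.95)
    base[primary] = (0.04, 0.02, 0.30, 0.54, 0.10, 0.0)
    base[deposits] = (0.02, 0.01, 0.07, 0.10, 0.80, 0.0)
    masks = {
        "xylem_wall": wall, "xylem_cml": cml,
        "corner_coniferyl": corner_coniferyl, "lumen": lumen,
        "primary_wall": primary & ~deposits, "deposits": deposits,
    }
    return names, base.reshape(rows * cols, k), masks


def _simplex_layout(grid_shape, rng, k=3):
    rows, cols = grid_shape
    n = rows * cols
    if n < k:
        raise ValueError("grid too small for the requested number of components")
    names = ["lignin", "cellulose", "water", "pectin",
             "protein_lipid", "lignin_coniferyl"][:k]
    C = rng.dirichlet(np.ones(k), size=n)
    masks = {"pure_pixels": np.zeros((rows, cols), bool)}
    masks["pure_pixels"].flat[:k] = True
    return names, C, masks


def _lowvar_water_layout(grid_shape, rng):
    rows, cols = grid_shape
    if min(rows, cols) < 8:
        raise ValueError("grid too small for the lowvar_water layout")
    names = ["lignin", "cellulose", "water"]
    n = rows * cols
    # nearly one-dimensional plant material; water confined to a small lumen
    a = rng.uniform(0.555, 0.565, size=n)
    C = np.column_stack([a, 1.0 - a, np.zeros(n)])
    lumen = np.zeros((rows, cols), bool)
    h, w = max(2, rows // 6), max(2, cols // 6)
    r0, c0 = rows // 2 - h // 2, cols // 2 - w // 2
    lumen[r0:r0 + h, c0:c0 + w] = True
    flat = lumen.reshape(-1)
    C[flat] = (0.01, 0.01, 0.98)
    return names, C, {"lumen": lumen}


def make_scene(
    layout: str,
    grid_shape: tuple[int, int],
    axis: SpectralAxis | None = None,
    snr: float = np.inf,
    background: str = "none",
    spike_rate: float = 0.0,
    seed: int = 0,
    scale: float = 1000.0,
    k: int = 3,
    plant_pure: bool = True,
    jitter: float = 0.05,
    water_amplitude: float = 0.06,
    cell: int = 12,
) -> SyntheticScene:
    """Generate a ground-truthed synthetic Raman image.

    Parameters
    ----------
    layout
        ``spruce`` (4 components, tiled tracheid cells), ``arabidopsis``
        (6 components, xylem + cambium/phloem), ``simplex`` (``k`` components,
        abundances uniform on the simplex with planted pure pixels) or
        ``lowvar_water`` (water spectrally distinct but < 1% of image
        variance, confined to a small lumen).
    snr
        Requested signal-to-noise as an RMS amplitude ratio; ``inf`` disables
        noise.  Noise is Gaussian with variance proportional to the local
        deterministic signal.
    background
        ``none`` or ``poly3_mix``: a per-pixel cubic polynomial whose
        amplitude is the abundance-weighted sum of component baseline gains.
    spike_rate
        Per-entry cosmic-ray probability in [0, 0.01]; the spike count is a
        Binomial(n_pixels*m, spike_rate) draw.
    """
    if layout not in LAYOUTS:
        raise ValueError(f"unknown layout {layout!r}; choose from {LAYOUTS}")
    if not (snr > 0):
        raise ValueError("snr must be positive (use inf for noiseless)")
    if not (0.0 <= spike_rate <= 0.01):
        raise ValueError("spike_rate must be in [0, 0.01]")
    if background not in ("none", "poly3_mix"):
        raise ValueError("background must be 'none' or 'poly3_mix'")
    axis = axis if axis is not None else regular_axis()
    rng = np.random.default_rng(seed)
    rows, cols = grid_shape
    n = rows * cols

    if layout == "spruce":
        names, C, masks = _spruce_layout(grid_shape, rng, cell)
    elif layout == "arabidopsis":
        names, C, masks = _arabidopsis_layout(grid_shape, rng, cell)
    elif layout == "simplex":
        names, C, masks = _simplex_layout(grid_shape, rng, k)
    else:
        names, C, masks = _lowvar_water_layout(grid_shape, rng)

    # simplex abundances are already random; the lowvar layout's tiny plant
    # contrast is itself the layout parameter and is not jittered further
    if layout not in ("simplex", "lowvar_water") and jitter > 0:
        # multiplicative jitter keeps zeros at zero and rows on the simplex
        C = C * np.exp(jitter * rng.standard_normal(C.shape))
    C = np.clip(C, 0.0, None)
    C /= C.sum(axis=1, keepdims=True)

    kc = len(names)
    if plant_pure and layout != "simplex":
        # plant one pure pixel per component inside its dominant region
        for j in range(kc):
            idx = int(np.argmax(C[:, j]))
            C[idx] = 0.0
            C[idx, j] = 1.0
    if layout == "simplex" and plant_pure:
        C[:kc] = np.eye(kc)

    library = builtin_library(axis)
    S = _render_library(names, library, axis)
    if layout == "lowvar_water":
        S[names.index("water")] *= water_amplitude

    signal = C @ S * scale

    if background == "poly3_mix":
        u = (axis.wavenumbers - axis.lo) / (axis.hi - axis.lo)
        shape = 1.0 - 1.1 * u + 0.9 * u**2 - 0.55 * u**3  # smooth, positive, sloping
        gains = np.array([library[nm].baseline_gain for nm in names])
        amp = (C @ gains) * 0.25 * scale
        bg = amp[:, None] * shape[None, :]
    else:
        bg = np.zeros_like(signal)

    total = signal + bg
    if np.isfinite(snr):
        mean_sig = float(total.mean())
        rms_sig = float(np.sqrt(np.mean(total**2)))
        c_noise = rms_sig / (snr * np.sqrt(max(mean_sig, 1e-30)))
        sigma = c_noise * np.sqrt(np.clip(total, 0.0, None) + 1e-12)
        noise = sigma * rng.standard_normal(total.shape)
    else:
        noise = np.zeros_like(total)

    # counts floor: raw detector counts cannot go negative
    D = np.clip(total + noise, 0.0, None)
    noise = D - total  # realized (floored) noise
    spikes: list[tuple[int, int]] = []
    m = axis.n_channels
    count = int(rng.binomial(n * m, spike_rate)) if spike_rate > 0 else 0
    if count:
        flat = rng.choice(n * m, size=count, replace=False)
        amp = rng.uniform(8.0, 20.0, size=count) * max(total.max(), 1.0)
        for pos, a in zip(flat, amp):
            i, j = divmod(int(pos), m)
            D[i, j] += a
            spikes.append((i, j))

    img = HyperspectralImage(
        grid_shape, axis, D,
        meta={"layout": layout, "seed": str(seed), "snr": str(snr),
              "background": background, "spike_rate": str(spike_rate)},
    )

    manifest = {"layout": layout, "components": list(names), "snr": snr,
                "n_spikes": count}
    if layout == "lowvar_water":
        W = np.outer(C[:, names.index("water")], S[names.index("water")]) * scale
        share = float(np.var(W) / np.var(signal))
        manifest["water_variance_share"] = share
    return SyntheticScene(
        image=img, names=list(names), S_true=S, C_true=C,
        background_true=bg, spike_locations=spikes, region_masks=masks,
        seed=seed, scale=scale, manifest=manifest,
    )
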