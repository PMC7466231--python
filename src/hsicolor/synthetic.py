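"""Synthetic hyperspectral scenes and colour/spectra sample sets.

Real visible/NIR cubes of sausage cores are not publicly deposited, so
every downstream stage is exercised on simulated data with known ground
truth.  Two generators are provided:

``simulate_scene``
    A push-broom-style cube of a roughly circular sample on a dark
    background.  Pixel spectra are convex mixtures of smooth endmember
    spectra (one always carries an absorption dip at 680 nm, the
    oxymyoglobin feature of cooked meat) plus i.i.d. sensor noise, and
    the true CIELAB colour of each pixel is a known linear map of its
    abundances.  Raw counts are encoded through synthetic white/dark
    reference frames as ``raw = dark + R·(white − dark)``, which makes
    the reflectance calibration exactly invertible.

``simulate_sample_set``
    Per-sample mean spectra plus reference colour triplets for three
    casing-treatment groups (control and two surfactant/lactic-acid
    treatments).  Default group colour means and SDs follow the values
    measured by colourimetry on the real sausages (e.g. control
    L* = 56.83 ± 5.48); within-group colour covariance is diagonal, as
    only marginal SDs are reported.  Spectra are an affine function of
    the colour triplet (a smooth baseline plus one smooth loading
    spectrum per colour channel) plus noise.

All randomness flows from a single integer seed through one
``numpy.random.Generator``; draw order is fixed, so outputs are a pure
function of (parameters, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .cube import HypercubeRaw, ReferenceFrame
from .grid import WavelengthGrid, default_grid, make_wavelength_grid
from .preprocess import SpectraMatrix

__all__ = [
    "EndmemberSet",
    "SyntheticScene",
    "SampleSet",
    "GROUP_COLOUR_DEFAULTS",
    "make_wavelength_grid",
    "make_endmembers",
    "simulate_scene",
    "simulate_sample_set",
]

#: Reflectance assigned to background (black plastic stage) pixels at all
#: bands; comfortably below the 0.05 segmentation threshold.
BACKGROUND_REFLECTANCE = 0.02

#: Per-group CIELAB (mean, SD) of sausage core colour: natural casing
#: control and the two casing modifications.
GROUP_COLOUR_DEFAULTS = {
    "control": {"L": (56.83, 5.48), "a": (6.23, 2.42), "b": (20.26, 4.81)},
    "treatment1": {"L": (50.86, 8.90), "a": (7.09, 2.41), "b": (19.75, 4.17)},
    "treatment2": {"L": (51.09, 8.56), "a": (5.72, 1.74), "b": (17.66, 2.89)},
}


@dataclass
class EndmemberSet:
    """Pure constituent spectra (n_endmembers × n_bands), reflectance in [0, 1]."""

    spectra: np.ndarray
    names: list
    grid: WavelengthGrid

    def __post_init__(self) -> None:
        self.spectra = np.asarray(self.spectra, dtype=float)
        if self.spectra.ndim != 2 or self.spectra.shape[1] != len(self.grid):
            raise ValueError("endmember matrix must be (n_endmembers, n_bands)")
        if np.any(self.spectra < 0) or np.any(self.spectra > 1):
            raise ValueError("endmember reflectance must lie in [0, 1]")

    @property
    def n(self) -> int:
        return self.spectra.shape[0]


@dataclass
class SyntheticScene:
    """A raw cube, its reference frames, and full per-pixel ground truth."""

    raw: HypercubeRaw
    white: ReferenceFrame
    dark: ReferenceFrame
    truth_colour: dict            # {"L","a","b"} → (h, w) maps, NaN off-sample
    truth_abundances: np.ndarray  # (h, w, n_endmembers), NaN off-sample
    truth_reflectance: np.ndarray = field(repr=False, default=None)
    region: np.ndarray = field(repr=False, default=None)  # (h, w) bool
    endmembers: EndmemberSet | None = None
    colour_model: np.ndarray | None = None
    seed: int | None = None


@dataclass
class SampleSet:
    """Per-sample mean spectra, reference colours and treatment labels."""

    spectra: SpectraMatrix
    colours: np.ndarray  # (n, 3): L*, a*, b*
    groups: list
    seed: int | None = None
    spectral_link: np.ndarray | None = field(default=None, repr=False)
    baseline: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.colours = np.asarray(self.colours, dtype=float)
        if len(self.groups) != self.spectra.n_samples or len(self.colours) != self.spectra.n_samples:
            raise ValueError("spectra, colours and groups must have one row per sample")


def _smooth_bumps(rng: np.random.Generator, lam: np.ndarray, n_bumps: int,
                  centre_range=(380.0, 1000.0), sigma_range=(25.0, 90.0),
                  depth_range=(0.03, 0.15)) -> np.ndarray:
    """Sum of random Gaussian bands; the smooth building block of spectra."""
    out = np.zeros_like(lam)
    for _ in range(n_bumps):
        c = rng.uniform(*centre_range)
        s = rng.uniform(*sigma_range)
        d = rng.uniform(*depth_range)
        out += d * np.exp(-0.5 * ((lam - c) / s) ** 2)
    return out


def make_endmembers(grid: WavelengthGrid, n: int, seed: int) -> EndmemberSet:
    """Generate ``n`` smooth reflectance endmembers.

    Construction is baseline-minus-Gaussian-absorptions: a gently
    sloping baseline with broad Gaussian absorption bands subtracted.
    Endmember 0 always carries a band centred at exactly 680 nm (depth
    0.10–0.25, width 12–20 nm) and no other band within 600–760 nm, so
    its spectrum has a guaranteed local dip at 680 nm.  Values are
    clipped to [0, 1]; the same (grid, n, seed) always returns the same
    matrix.
    """
    if n < 2:
        raise ValueError("need at least 2 endmembers (mixtures are undefined for fewer)")
    rng = np.random.default_rng(seed)
    lam = grid.values
    x = (lam - lam[0]) / max(lam[-1] - lam[0], 1.0)
    spectra = np.empty((n, len(grid)))
    for i in range(n):
        u0 = rng.uniform(0.55, 0.85)
        u1 = rng.uniform(-0.12, 0.12)
        u2 = rng.uniform(-0.10, 0.10)
        baseline = u0 + u1 * x + u2 * x ** 2
        if i == 0:
            depth = rng.uniform(0.10, 0.25)
            sigma = rng.uniform(12.0, 20.0)
            dip = depth * np.exp(-0.5 * ((lam - 680.0) / sigma) ** 2)
            # further bands kept away from the 600-760 nm window so the
            # 680 nm dip stays a clean local minimum
            side = np.zeros_like(lam)
            for lo, hi in ((395.0, 560.0), (800.0, 985.0)):
                c = rng.uniform(lo, hi)
                s = rng.uniform(20.0, 60.0)
                d = rng.uniform(0.02, 0.10)
                side += d * np.exp(-0.5 * ((lam - c) / s) ** 2)
            absorption = dip + side
        else:
            absorption = _smooth_bumps(rng, lam, n_bumps=int(rng.integers(2, 5)))
        spectra[i] = np.clip(baseline - absorption, 0.0, 1.0)
    names = [f"endmember{i}" for i in range(n)]
    names[0] = "endmember0_680nm_dip"
    return EndmemberSet(spectra=spectra, names=names, grid=grid)


def _default_colour_model(n_endmembers: int, rng: np.random.Generator) -> np.ndarray:
    """Full-rank (3, k) map from abundances to (L*, a*, b*)."""
    anchors = np.array([
        [62.0, 4.0, 23.0],
        [49.0, 8.0, 17.0],
        [55.0, 6.0, 14.0],
    ])
    cols = []
    for j in range(n_endmembers):
        if j < 3:
            cols.append(anchors[j])
        else:
            cols.append(anchors[j % 3] + rng.uniform(-3.0, 3.0, size=3))
    M = np.column_stack(cols)
    return M


def _smooth_field(rng: np.random.Generator, h: int, w: int, n_waves: int = 4) -> np.ndarray:
    """Smooth pseudo-random spatial field in roughly [-1, 1]."""
    r = np.arange(h)[:, None] / max(h - 1, 1)
    c = np.arange(w)[None, :] / max(w - 1, 1)
    out = np.zeros((h, w))
    for _ in range(n_waves):
        fr, fc = rng.uniform(0.5, 2.5, size=2)
        pr, pc = rng.uniform(0, 2 * np.pi, size=2)
        out += rng.uniform(0.3, 1.0) * np.cos(2 * np.pi * fr * r + pr) * np.cos(2 * np.pi * fc * c + pc)
    m = np.max(np.abs(out))
    return out / m if m > 0 else out


def simulate_scene(
    grid: WavelengthGrid | None = None,
    endmembers: EndmemberSet | None = None,
    height: int = 60,
    width: int = 60,
    colour_model: np.ndarray | None = None,
    noise_sd: float = 0.005,
    seed: int = 0,
) -> SyntheticScene:
    """Simulate one raw hypercube with reference frames and ground truth.

    A circular sample region (radius 0.42·min(height, width)) sits on a
    dark background of reflectance 0.02.  Within the region, abundance
    maps are smooth random fields passed through a softmax so they are
    non-negative and sum to 1 per pixel; pixel reflectance is the
    abundance-weighted endmember mixture plus i.i.d. Gaussian noise of
    SD ``noise_sd``.  True colour maps are ``colour_model @ abundances``.

    Draw order from the single seed: endmembers (if not supplied) →
    colour model (if not supplied) → abundance fields → white/dark frame
    structure → noise.
    """
    if height < 1 or width < 1:
        raise ValueError(f"height and width must be >= 1, got {(height, width)}")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    grid = grid or default_grid()
    rng = np.random.default_rng(seed)
    if endmembers is None:
        endmembers = make_endmembers(grid, 3, seed=int(rng.integers(2 ** 31)))
    elif len(endmembers.grid) != len(grid):
        raise ValueError("endmember grid does not match scene grid")
    k = endmembers.n
    if colour_model is None:
        colour_model = _default_colour_model(k, rng)
    colour_model = np.asarray(colour_model, dtype=float)
    if colour_model.shape != (3, k):
        raise ValueError(f"colour_model must be (3, {k}), got {colour_model.shape}")
    if np.linalg.matrix_rank(colour_model) < min(3, k):
        raise ValueError("colour_model must have full rank")

    rows = np.arange(height)[:, None] - (height - 1) / 2.0
    cols = np.arange(width)[None, :] - (width - 1) / 2.0
    region = np.sqrt(rows ** 2 + cols ** 2) <= 0.42 * min(height, width)
    if not region.any():  # degenerate tiny scenes: keep at least the centre pixel
        region[height // 2, width // 2] = True

    # abundances: softmax over k smooth fields (single endmember → all 1)
    if k == 1:
        abund = np.ones((height, width, 1))
    else:
        logits = np.stack([1.5 * _smooth_field(rng, height, width) for _ in range(k)], axis=-1)
        logits -= logits.max(axis=-1, keepdims=True)
        e = np.exp(logits)
        abund = e / e.sum(axis=-1, keepdims=True)

    reflectance = abund @ endmembers.spectra  # (h, w, bands)
    reflectance = np.where(region[:, :, None], reflectance, BACKGROUND_REFLECTANCE)

    # reference frames: smooth spatial gain structure, per-band white level
    white_level = 3000.0 * (0.9 + 0.1 * np.cos((grid.values - 380.0) / 620.0 * np.pi / 2))
    white = white_level[None, None, :] * (1.0 + 0.03 * _smooth_field(rng, height, width)[:, :, None])
    dark = 100.0 * (1.0 + 0.02 * _smooth_field(rng, height, width)[:, :, None]) * np.ones_like(white)

    if noise_sd > 0:
        noisy = reflectance.copy()
        noisy[region] = reflectance[region] + rng.normal(0.0, noise_sd, size=reflectance[region].shape)
        reflectance_obs = noisy
    else:
        reflectance_obs = reflectance

    raw_counts = dark + reflectance_obs * (white - dark)

    truth_abund = np.where(region[:, :, None], abund, np.nan)
    colour_maps = np.einsum("ck,hwk->hwc", colour_model, abund)
    truth_colour = {}
    for i, name in enumerate(("L", "a", "b")):
        m = colour_maps[:, :, i].copy()
        m[~region] = np.nan
        truth_colour[name] = m

    raw = HypercubeRaw(
        data=raw_counts,
        grid=grid,
        meta={"stage_speed_mm_s": 2.08, "spatial_resolution_mm": 0.75,
              "synthetic": True, "seed": int(seed)},
    )
    return SyntheticScene(
        raw=raw,
        white=ReferenceFrame(data=white, kind="white"),
        dark=ReferenceFrame(data=dark, kind="dark"),
        truth_colour=truth_colour,
        truth_abundances=truth_abund,
        truth_reflectance=np.where(region[:, :, None], reflectance, BACKGROUND_REFLECTANCE),
        region=region,
        endmembers=endmembers,
        colour_model=colour_model,
        seed=int(seed),
    )


def _default_spectral_link(grid: WavelengthGrid) -> tuple[np.ndarray, np.ndarray]:
    """(baseline, link) for colour→spectrum generation.

    The baseline is a meat-like reflectance curve with the 680 nm dip;
    the link rows are smooth loading spectra for L*, a*, b*, scaled so
    that one SD of colour moves reflectance by a few hundredths.
    """
    lam = grid.values
    x = (lam - lam[0]) / max(lam[-1] - lam[0], 1.0)
    baseline = 0.35 + 0.15 * x - 0.12 * np.exp(-0.5 * ((lam - 680.0) / 16.0) ** 2)
    vL = 0.006 * (0.6 + 0.4 * x)                                   # broadband lightness
    va = 0.008 * np.exp(-0.5 * ((lam - 560.0) / 60.0) ** 2) \
        - 0.004 * np.exp(-0.5 * ((lam - 680.0) / 25.0) ** 2)       # red-green band
    vb = 0.007 * np.exp(-0.5 * ((lam - 450.0) / 50.0) ** 2) \
        + 0.003 * np.exp(-0.5 * ((lam - 900.0) / 80.0) ** 2)       # yellow-blue band
    return baseline, np.vstack([vL, va, vb])


def simulate_sample_set(
    n_per_group: int,
    group_params: dict | None = None,
    spectral_link: np.ndarray | None = None,
    noise_sd: float = 0.002,
    seed: int = 0,
    grid: WavelengthGrid | None = None,
    baseline: np.ndarray | None = None,
) -> SampleSet:
    """Simulate per-sample mean spectra and reference colours by group.

    Colours are drawn per channel from the group's normal distribution
    (diagonal covariance); each sample's spectrum is
    ``baseline + linkᵀ·(L, a, b) + noise``.  Draw order: colours group by
    group (L, a, b blocks), then the noise matrix.
    """
    if n_per_group < 2:
        raise ValueError("need at least 2 samples per group")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    group_params = group_params or GROUP_COLOUR_DEFAULTS
    for g, chans in group_params.items():
        for ch, (_, sd) in chans.items():
            if sd < 0:
                raise ValueError(f"negative SD for group {g!r} channel {ch!r}")
    grid = grid or default_grid()
    if spectral_link is None:
        default_base, spectral_link = _default_spectral_link(grid)
        if baseline is None:
            baseline = default_base
    spectral_link = np.asarray(spectral_link, dtype=float)
    if spectral_link.shape != (3, len(grid)):
        raise ValueError(f"spectral_link must be (3, {len(grid)})")
    baseline = np.zeros(len(grid)) if baseline is None else np.asarray(baseline, dtype=float)

    rng = np.random.default_rng(seed)
    colours, groups = [], []
    for g in group_params:
        block = np.column_stack([
            rng.normal(group_params[g][ch][0], group_params[g][ch][1], size=n_per_group)
            for ch in ("L", "a", "b")
        ])
        colours.append(block)
        groups.extend([g] * n_per_group)
    colours = np.vstack(colours)

    X = baseline[None, :] + colours @ spectral_link
    if noise_sd > 0:
        X = X + rng.normal(0.0, noise_sd, size=X.shape)
    return SampleSet(
        spectra=SpectraMatrix(X=X, grid=grid, treatment="raw"),
        colours=colours,
        groups=groups,
        seed=int(seed),
        spectral_link=spectral_link,
        baseline=baseline,
    )
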