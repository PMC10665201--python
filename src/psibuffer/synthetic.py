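"""Ground-truth generators for every analysis in the package.

Each generator emulates one class of measurement the analyses operate on:

* osmometry dilution series following the non-ideal model with multiplicative
  instrument noise (default 1%, n = 3 replicates, as for the real
  vapour-pressure measurements);
* co-solutions whose osmolality falls below ideal additivity once a
  condensation threshold (default onset near 700 mOsm kg⁻¹) is crossed,
  via a minimal two-state water-release model: a logistic condensed fraction
  removes part of the macromolecule's non-ideal excess term;
* buffered extract dilution curves derived from the same water-release model;
* punctate microscopy frames in which a controlled fraction ``f`` of a
  conserved total intensity is moved from a diffuse field into Gaussian
  puncta, plus offset and noise;
* cell images with a painted cortical rim, nuclei fields for segmentation,
  and protein sets with tunable overlap enrichment.

All generators are deterministic given their spec and seed.  The water-release
mechanism is a fixture for exercising the statistics, not a physical model.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage import morphology

from .enrichment_stats import ProteinSetTable
from .osmo_model import DilutionSeries, predict_osmolality

__all__ = [
    "SyntheticOsmoSpec",
    "CondensingMixtureSpec",
    "PunctaImageSpec",
    "gen_osmometry_series",
    "gen_condensing_mixture",
    "gen_buffered_dilution",
    "gen_puncta_image",
    "gen_cell_image",
    "gen_nuclei_image",
    "gen_protein_sets",
]


@dataclass
class SyntheticOsmoSpec:
    """Ground truth for synthetic osmometry: model parameters, grid, noise."""

    A_true: float = 1.0
    I_eff_true: float = 0.002
    conc_grid: np.ndarray = field(default_factory=lambda: np.arange(50.0, 401.0, 50.0))
    noise_sd_frac: float = 0.01
    n_replicates: int = 3
    seed: int = 0
    ieff_slope: float = 0.0  # optional linear T-dependence: I_eff(T) = I_eff_true - slope*(T - 300)

    def __post_init__(self) -> None:
        self.conc_grid = np.asarray(self.conc_grid, dtype=float)
        if self.noise_sd_frac < 0:
            raise ValueError("noise_sd_frac must be >= 0")
        if self.I_eff_true * self.conc_grid.max() >= 1.0:
            raise ValueError("I_eff_true * max(conc) >= 1: grid crosses the model pole")

    def ieff_at(self, temperature_k: float) -> float:
        return self.I_eff_true - self.ieff_slope * (temperature_k - 300.0)


@dataclass
class CondensingMixtureSpec:
    """Two-state water-release co-solution: ideal solute + macromolecule.

    Above the condensation threshold ``osm_c`` a logistic fraction of the
    macromolecule condenses, releasing ``hydration_release_frac`` of its
    non-ideal excess osmolality back as free water.
    """

    solute_slope: float = 1.0  # mOsm kg^-1 per conc unit, ideal component
    A: float = 1.0
    I_eff: float = 0.002
    osm_c: float = 700.0  # mOsm kg^-1, condensation onset
    steepness: float = 0.01  # per mOsm kg^-1
    hydration_release_frac: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.hydration_release_frac <= 1.0:
            raise ValueError("hydration_release_frac must lie in [0, 1]")
        if self.osm_c <= 0:
            raise ValueError("osm_c must be positive")


@dataclass
class PunctaImageSpec:
    """Puncta image: fraction ``f`` of a conserved total intensity in spots.

    The diffuse (uncondensed) signal is a smooth wide-Gaussian envelope —
    like the cell-scale intensity profile of a real frame — so its spectral
    power sits in the lowest-frequency rings; condensation moves signal into
    sharp puncta and hence power outward.  ``total_intensity`` is the
    pre-noise, pre-offset integrated signal, conserved across ``f``.
    """

    size: int = 600
    n_puncta: int = 40
    condensed_fraction: float = 0.5
    puncta_sigma: float = 3.0
    total_intensity: float = 5e7
    background_offset: float = 10.0
    envelope_sigma_frac: float = 0.25  # diffuse-field width as fraction of size
    noise_model: str = "poisson"  # or "gaussian" or "none"
    noise_sd: float = 1.0  # gaussian only
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.condensed_fraction <= 1.0:
            raise ValueError("condensed_fraction must lie in [0, 1]")
        margin = int(np.ceil(4 * self.puncta_sigma))
        if 2 * margin >= self.size:
            raise ValueError("puncta do not fit inside the frame")


# ---------------------------------------------------------------------------
# osmometry


def gen_osmometry_series(
    spec: SyntheticOsmoSpec,
    temperature: float = 300.0,
) -> list[DilutionSeries]:
    """Replicate dilution series on the non-ideal curve with 1%-style noise.

    Readings are A·C/(1−I_eff·C)·(1+ε), ε ~ N(0, noise_sd_frac), with a
    per-replicate substream of the seeded generator; per-point sem fields are
    populated from the replicate spread.
    """
    t_k = temperature + 273.15 if temperature < 150 else temperature
    ieff = spec.ieff_at(t_k)
    if ieff < 0:
        raise ValueError("temperature profile drove I_eff negative")
    if ieff * spec.conc_grid.max() >= 1.0:
        raise ValueError("I_eff(T) * max(conc) >= 1: grid crosses the model pole")
    clean = predict_osmolality((spec.A_true, ieff), spec.conc_grid)
    rng = np.random.default_rng(spec.seed)
    readings = np.empty((spec.n_replicates, len(spec.conc_grid)))
    for i in range(spec.n_replicates):
        sub = np.random.default_rng(rng.integers(0, 2**31))
        eps = sub.normal(0.0, spec.noise_sd_frac, size=len(spec.conc_grid)) if spec.noise_sd_frac else 0.0
        readings[i] = clean * (1.0 + eps)
    sem = readings.std(axis=0, ddof=1) / np.sqrt(spec.n_replicates) if spec.n_replicates > 1 else None
    return [
        DilutionSeries(
            solute_name="synthetic",
            temperature=t_k,
            concentrations=spec.conc_grid,
            osmolality=readings[i],
            sem=sem,
            replicate_id=f"rep{i}",
        )
        for i in range(spec.n_replicates)
    ]


def _logistic(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(x, -500, 500)))


def _condensing_observed(spec: CondensingMixtureSpec, conc_solute, conc_macro):
    """Observed osmolality of the two-state water-release model.

    The condensed fraction is a logistic in the *additive* (applied)
    osmolality relative to the threshold — the un-buffered osmotic challenge
    the composition would impose sets how much macromolecule condenses — and
    the observed reading is the additive value minus the released share of
    the macromolecule's non-ideal excess.  Driving the logistic with the
    applied rather than the observed osmolality keeps the model single-valued
    (a self-consistent closure is bistable once the released term is large).
    """
    macro_full = np.asarray(predict_osmolality((spec.A, spec.I_eff), conc_macro))
    additive = spec.solute_slope * np.asarray(conc_solute, dtype=float) + macro_full
    excess = macro_full - spec.A * np.asarray(conc_macro, dtype=float)
    phi = _logistic((additive - spec.osm_c) * spec.steepness)
    observed = additive - phi * spec.hydration_release_frac * excess
    return observed, additive


def gen_condensing_mixture(
    spec: CondensingMixtureSpec,
    conc_grid: np.ndarray,
    mix_ratio: tuple[float, float] = (2.0, 1.0),
) -> tuple[DilutionSeries, DilutionSeries, DilutionSeries]:
    """Observed co-solution series plus the two noise-free component series.

    ``conc_grid`` is total co-solution concentration; the macromolecule takes
    the first mix-ratio share, the ideal solute the second.  The observed
    osmolality never exceeds the additive prediction.
    """
    conc_grid = np.asarray(conc_grid, dtype=float)
    wm, ws = mix_ratio
    fm, fs = wm / (wm + ws), ws / (wm + ws)
    observed, _ = _condensing_observed(spec, fs * conc_grid, fm * conc_grid)
    # component curves are measured over their own in-mixture concentration range
    comp_macro = DilutionSeries(
        "macromolecule",
        300.0,
        fm * conc_grid,
        np.asarray(predict_osmolality((spec.A, spec.I_eff), fm * conc_grid)),
    )
    comp_solute = DilutionSeries(
        "ideal-solute", 300.0, fs * conc_grid, spec.solute_slope * fs * conc_grid
    )
    obs_series = DilutionSeries("co-solution", 300.0, conc_grid, observed)
    return obs_series, comp_macro, comp_solute


def gen_buffered_dilution(
    spec: CondensingMixtureSpec,
    fractions: np.ndarray,
    neat_conc_solute: float = 150.0,
    neat_conc_macro: float = 350.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Extract dilution curve from the water-release model.

    Concentrations scale with the dilution fraction; condensation is active
    near neat, so the curve is linear at low fractions and sub-linear near
    1.0 when the release fraction is > 0.  Returns (fractions, osmolality).
    """
    fractions = np.asarray(fractions, dtype=float)
    if not np.isclose(fractions.max(), 1.0):
        raise ValueError("fractions must include the neat sample (1.0)")
    obs, _ = _condensing_observed(
        spec, fractions * neat_conc_solute, fractions * neat_conc_macro
    )
    return fractions, obs


# ---------------------------------------------------------------------------
# images


def gen_puncta_image(spec: PunctaImageSpec) -> tuple[np.ndarray, dict]:
    """Diffuse field + Gaussian puncta with conserved integrated signal.

    Pre-noise, pre-offset the image integrates exactly to ``total_intensity``
    for every condensed fraction ``f``: (1−f) of it spread uniformly, f of it
    in ``n_puncta`` Gaussian spots (normalized after in-frame truncation).
    Returns the image and a ground-truth dict (f, centers, puncta mask).
    """
    n = spec.size
    f = spec.condensed_fraction
    rng = np.random.default_rng(spec.seed)
    yy, xx = np.mgrid[:n, :n]
    c = (n - 1) / 2.0
    env_sigma = spec.envelope_sigma_frac * n
    envelope = np.exp(-((yy - c) ** 2 + (xx - c) ** 2) / (2 * env_sigma**2))
    signal = (1.0 - f) * spec.total_intensity * envelope / envelope.sum()

    margin = int(np.ceil(4 * spec.puncta_sigma))
    centers = rng.uniform(margin, n - margin, size=(spec.n_puncta, 2))
    puncta = np.zeros((n, n))
    for cy, cx in centers:
        puncta += np.exp(-((yy - cy) ** 2 + (xx - cx) ** 2) / (2 * spec.puncta_sigma**2))
    if f > 0:
        puncta *= f * spec.total_intensity / puncta.sum()
        signal = signal + puncta

    image = signal + spec.background_offset
    if spec.noise_model == "poisson":
        image = rng.poisson(np.clip(image, 0, None)).astype(float)
    elif spec.noise_model == "gaussian":
        image = image + rng.normal(0.0, spec.noise_sd, size=image.shape)
    elif spec.noise_model != "none":
        raise ValueError(f"unknown noise model {spec.noise_model!r}")

    truth = {
        "condensed_fraction": f,
        "centers": centers,
        "signal": signal,
        "puncta_mask": puncta > (puncta.max() * 0.05 if f > 0 else np.inf),
    }
    return image, truth


def gen_cell_image(
    rim_factor: float = 3.0,
    band_width: int = 3,
    size: int = 128,
    radius: int = 40,
    interior_level: float = 100.0,
    offset: float = 20.0,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Disk-shaped cell with a painted cortical rim; returns (image, mask).

    The peripheral ``band_width`` px of the disk are painted at
    ``rim_factor`` x the interior level, over a constant offset plus optional
    Gaussian noise — ground truth for the cortical/cytosolic ratio.
    """
    if rim_factor <= 0:
        raise ValueError("rim_factor must be positive")
    if 2 * (radius + band_width) >= size:
        raise ValueError("cell does not fit in the frame")
    c = size // 2
    yy, xx = np.ogrid[:size, :size]
    mask = np.hypot(yy - c, xx - c) <= radius
    interior = ndimage.binary_erosion(mask, morphology.disk(band_width))
    band = mask & ~interior
    img = np.full((size, size), offset)
    img[interior] += interior_level
    img[band] += rim_factor * interior_level
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        img = img + rng.normal(0.0, noise_sd, size=img.shape)
    return img, mask


def gen_nuclei_image(
    n_nuclei: int = 3,
    size: int = 256,
    axes_range: tuple[int, int] = (12, 22),
    level: float = 200.0,
    background: float = 10.0,
    noise_sd: float = 2.0,
    seed: int = 0,
) -> tuple[np.ndarray, list[np.ndarray]]:
    """Non-touching bright ellipses on a dark background, with truth masks."""
    rng = np.random.default_rng(seed)
    img = np.full((size, size), background)
    masks: list[np.ndarray] = []
    occupied = np.zeros((size, size), dtype=bool)
    yy, xx = np.mgrid[:size, :size]
    attempts = 0
    while len(masks) < n_nuclei and attempts < 500:
        attempts += 1
        a, b = rng.uniform(*axes_range, size=2)
        theta = rng.uniform(0, np.pi)
        m = int(np.ceil(max(a, b))) + 6
        cy, cx = rng.uniform(m, size - m, size=2)
        ct, st = np.cos(theta), np.sin(theta)
        u = (xx - cx) * ct + (yy - cy) * st
        v = -(xx - cx) * st + (yy - cy) * ct
        ellipse = (u / a) ** 2 + (v / b) ** 2 <= 1.0
        if (ndimage.binary_dilation(ellipse, iterations=4) & occupied).any():
            continue
        occupied |= ellipse
        masks.append(ellipse)
        img[ellipse] = level
    if len(masks) < n_nuclei:
        raise RuntimeError("could not place non-touching nuclei; reduce n or sizes")
    if noise_sd > 0:
        img = img + rng.normal(0.0, noise_sd, size=img.shape)
    return img, masks


# ---------------------------------------------------------------------------
# protein sets


def gen_protein_sets(
    universe: int,
    size_a: int,
    size_b: int,
    enrichment_factor: float = 1.0,
    seed: int = 0,
) -> ProteinSetTable:
    """Random protein sets with tunable overlap enrichment.

    Set a is a uniform draw; set b is drawn without replacement with sampling
    weights ``enrichment_factor`` for members of a and 1 otherwise, so factor
    1 gives independent sets and large factors concentrate b inside a.
    """
    if size_a > universe or size_b > universe:
        raise ValueError("set sizes cannot exceed the universe")
    if enrichment_factor <= 0:
        raise ValueError("enrichment factor must be positive")
    rng = np.random.default_rng(seed)
    ids = np.arange(universe)
    set_a = rng.choice(ids, size=size_a, replace=False)
    w = np.ones(universe)
    w[set_a] = enrichment_factor
    set_b = rng.choice(ids, size=size_b, replace=False, p=w / w.sum())
    return ProteinSetTable(
        universe_size=universe,
        set_a=frozenset(int(i) for i in set_a),
        set_b=frozenset(int(i) for i in set_b),
    )
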