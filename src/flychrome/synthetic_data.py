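"""Synthetic reflectances, illuminants and photoreceptor sensitivities.

The analysis needs three classes of natural-scene reflectance spectra and a
pair of irradiance spectra with a known structure:

* **leaf green** — foliage spectra with the chlorophyll signature: strong
  absorption in the blue (~445 nm) and red (~675 nm), leaving a reflectance
  peak near 555 nm and a steep rise at the far-red edge;
* **grey–brown** — melanin-pigmented animal integuments, whose reflectance
  rises monotonically with wavelength, spanning near-black to strongly
  rising orange/pheomelanin-type spectra;
* **control-device fabrics** — blue fabrics with a single reflectance peak
  in the 440–480 nm band and little UV or green–red reflectance, plus black
  (flat, very dark) and violet (blue peak plus long-wavelength tail) fabrics;
* an **open/cloudy** daylight illuminant and a **woodland-shade** illuminant
  whose total photon flux is 4.4% of the open one and whose normalized shape
  is relatively enriched in short wavelengths.

All generators are parametric and deterministic under a fixed seed.  Curve
shapes are the package's own smooth idealizations of those spectral classes;
real measured spectra can be substituted through the CSV loaders in
:mod:`flychrome.spectral_core` without touching any downstream stage.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .spectral_core import MASTER_GRID, Spectrum, SpectrumError, SpectrumTable, WavelengthGrid

#: canonical ordering of the five receptor classes of the higher-fly retina
RECEPTOR_IDS = ("R1-6", "R7p", "R7y", "R8p", "R8y")

SPECIES = ("musca_calliphora", "glossina")


def _gauss(x: np.ndarray, mu: float, sigma: float) -> np.ndarray:
    return np.exp(-0.5 * ((x - mu) / sigma) ** 2)


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def _smooth_noise(rng: np.random.Generator, n: int, corr_pts: int = 15) -> np.ndarray:
    """Zero-mean unit-scale smooth noise (Gaussian-kernel-smoothed white noise)."""
    white = rng.standard_normal(n + 6 * corr_pts)
    k = _gauss(np.arange(-3 * corr_pts, 3 * corr_pts + 1, dtype=float), 0.0, corr_pts)
    smooth = np.convolve(white, k / k.sum(), mode="same")[3 * corr_pts : 3 * corr_pts + n]
    scale = smooth.std()
    return smooth / scale if scale > 0 else smooth


@dataclass(frozen=True)
class GeneratorConfig:
    """Sample sizes, seed and variability envelopes for the generators.

    The default sample sizes (72 leaves, 72 animal integuments) and the
    default variability ranges reproduce the study conditions the pipeline
    is designed around; identical seeds give bit-identical tables.
    """

    n_leaf: int = 72
    n_animal: int = 72
    seed: int = 0
    # leaf envelope: plateau level, chlorophyll band depth, red:blue band
    # ratio, and a broad senescence-like red/green tilt
    leaf_plateau_range: tuple[float, float] = (0.12, 0.45)
    leaf_blue_absorbance_range: tuple[float, float] = (1.0, 2.8)
    leaf_red_to_blue_range: tuple[float, float] = (1.05, 1.50)
    leaf_tilt_sd: float = 0.25
    leaf_noise_amp_range: tuple[float, float] = (0.08, 0.22)
    # flat cuticular-wax specular component; in particular it sets the
    # (small) near-UV reflectance of leaves, comparable to animal integument
    leaf_specular_range: tuple[float, float] = (0.005, 0.035)
    # animal envelope: baseline (300 nm) reflectance, total rise to 700 nm,
    # and exponential curvature of the rise.  Melanin integuments are very
    # dark in the UV, like foliage: neither natural class reflects much UV.
    animal_baseline_range: tuple[float, float] = (0.008, 0.035)
    animal_rise_range: tuple[float, float] = (0.0, 0.65)
    animal_curvature_range: tuple[float, float] = (3.0, 7.0)
    animal_pale_fraction: float = 0.0
    # multiplicative smooth within-class variability (log-scale s.d.):
    # emulates the species-to-species spectral diversity of real samples
    noise_amp_range: tuple[float, float] = (0.10, 0.35)

    def __post_init__(self) -> None:
        if self.n_leaf < 1 or self.n_animal < 1:
            raise SpectrumError("sample sizes must be >= 1")


def _leaf_spectrum(grid: WavelengthGrid, rng: np.random.Generator,
                   config: GeneratorConfig, id: str) -> Spectrum:
    wl = grid.wavelengths
    p0 = rng.uniform(*config.leaf_plateau_range)
    d_blue = rng.uniform(*config.leaf_blue_absorbance_range)
    # red absorbance covaries with blue (both are chlorophyll bands), which
    # keeps the green transmission window — hence the peak — near 555 nm;
    # the floor keeps the 670 nm trough deep even for weakly pigmented leaves
    d_red = max(d_blue * rng.uniform(*config.leaf_red_to_blue_range), 1.0)
    d_uv = rng.uniform(3.2, 4.6)
    w_uv = rng.uniform(55.0, 90.0)
    # chlorophyll blue + red bands plus a deep UV wall; the carotenoid
    # shoulder extends blue absorption through ~500 nm, so reflectance stays
    # low until the steep rise onto the green transmission peak
    absorbance = (
        d_blue * _gauss(wl, 450.0, 52.0)
        + d_blue * _gauss(wl, 494.0, 32.0)
        + d_red * _gauss(wl, 662.0, 50.0)
        + d_uv * _gauss(wl, 340.0, w_uv)
    )
    plateau = p0 * (1.0 + 0.9 * _sigmoid((wl - 705.0) / 7.0))
    values = plateau * np.exp(-absorbance)
    # broad red/green tilt (leaf maturity) plus gentle local variability;
    # both are smooth enough to leave the green-peak position in place
    tilt = np.clip(rng.normal(0.0, config.leaf_tilt_sd), -2 * config.leaf_tilt_sd,
                   2 * config.leaf_tilt_sd)
    values = values * np.exp(tilt * (wl - 500.0) / 200.0)
    specular = rng.uniform(*config.leaf_specular_range)
    spec_tilt = rng.uniform(-0.4, 0.4)
    values = values + specular * (1.0 + spec_tilt * (wl - 500.0) / 400.0)
    amp = rng.uniform(*config.leaf_noise_amp_range)
    values = values * np.exp(amp * _smooth_noise(rng, len(grid), corr_pts=25))
    return Spectrum(grid, np.clip(values, 1e-4, 1.0), "reflectance", id)


def gen_leaf_reflectances(config: GeneratorConfig = GeneratorConfig(),
                          grid: WavelengthGrid = MASTER_GRID) -> SpectrumTable:
    """Generate ``config.n_leaf`` leaf-green reflectance spectra.

    Each spectrum has its 400–680 nm maximum in the 540–570 nm band, with
    chlorophyll absorption troughs near 450 and 670 nm and a far-red edge.
    """
    rng = np.random.default_rng(config.seed)
    wl = grid.wavelengths
    window = (wl >= 400.0) & (wl <= 680.0)
    spectra: list[Spectrum] = []
    for i in range(config.n_leaf):
        # rejection-sample the green-peak position: the variability envelope
        # occasionally drifts a weakly pigmented leaf's maximum outside the
        # 540-570 nm band, and membership of the leaf-green class requires it
        for _ in range(200):
            s = _leaf_spectrum(grid, rng, config, f"leaf_{i:03d}")
            peak = wl[window][int(np.argmax(s.values[window]))]
            if 540.0 <= peak <= 570.0:
                break
        spectra.append(s)
    return SpectrumTable(spectra, {s.id: "leaf" for s in spectra})


def _animal_spectrum(grid: WavelengthGrid, rng: np.random.Generator,
                     config: GeneratorConfig, id: str) -> Spectrum:
    wl = grid.wavelengths
    lo = rng.uniform(*config.animal_baseline_range)
    # a minority of integuments are pale (light grey / buff / white-ish),
    # flat-bright from the UV through the visible
    if rng.random() < config.animal_pale_fraction:
        lo = rng.uniform(0.05, 0.14)
    rise = rng.uniform(*config.animal_rise_range)
    k = rng.uniform(*config.animal_curvature_range)
    # melanin reflectance is nearly flat through the UV and rises from
    # ~400 nm; the residual UV slope varies between samples
    x = np.clip((wl - 400.0) / (grid.stop - 400.0), 0.0, None)
    uv_slope = rng.uniform(0.05, 0.4)
    # monotone rise built in derivative space so smooth variability can
    # modulate the slope without ever producing a decreasing segment
    slope = np.where(wl >= 400.0, np.exp(k * x), uv_slope)
    amp = rng.uniform(*config.noise_amp_range)
    slope = slope * np.exp(amp * _smooth_noise(rng, len(grid)))
    shape = np.concatenate([[0.0], np.cumsum(0.5 * (slope[1:] + slope[:-1]))])
    if shape[-1] > 0:
        shape = shape / shape[-1]
    values = lo + rise * shape
    return Spectrum(grid, np.clip(values, 0.0, 1.0), "reflectance", id)


def gen_animal_reflectances(config: GeneratorConfig = GeneratorConfig(),
                            grid: WavelengthGrid = MASTER_GRID) -> SpectrumTable:
    """Generate ``config.n_animal`` grey–brown (melanin-type) reflectances.

    Every spectrum is monotone non-decreasing in wavelength; the family
    spans flat near-black spectra to steeply rising pheomelanin-type ones.
    """
    rng = np.random.default_rng(config.seed)
    spectra = [_animal_spectrum(grid, rng, config, f"animal_{i:03d}")
               for i in range(config.n_animal)]
    return SpectrumTable(spectra, {s.id: "animal" for s in spectra})


# fixed per-fabric parameters: (blue-peak centre nm, peak height, peak width nm,
# baseline, long-wavelength tail height).  The default eleven ids mirror the
# composition of fabrics used on biting-fly control devices: seven blues,
# three blacks, one violet.
_FABRIC_PARAMS: dict[str, tuple[float, float, float, float, float]] = {
    "phthalogen_blue": (456.0, 0.52, 24.0, 0.016, 0.0),
    "royal_blue": (450.0, 0.44, 23.0, 0.018, 0.0),
    "typical_blue": (462.0, 0.38, 26.0, 0.020, 0.0),
    "zerofly_blue": (446.0, 0.42, 22.0, 0.015, 0.0),
    "blue_generic": (458.0, 0.33, 24.0, 0.022, 0.0),
    "black": (0.0, 0.0, 1.0, 0.030, 0.0),
    "violet": (445.0, 0.36, 24.0, 0.018, 0.38),
}

FABRIC_KINDS = tuple(_FABRIC_PARAMS)

#: the default eleven-fabric evaluation set (7 blue, 3 black, 1 violet)
DEFAULT_FABRIC_SET = (
    "phthalogen_blue", "phthalogen_blue", "blue_generic", "phthalogen_blue",
    "royal_blue", "typical_blue", "zerofly_blue",
    "black", "black", "black",
    "violet",
)


def gen_fabric_reflectances(kinds: tuple[str, ...] | list[str] = DEFAULT_FABRIC_SET,
                            grid: WavelengthGrid = MASTER_GRID) -> SpectrumTable:
    """Generate idealized control-device fabric reflectances.

    Blue kinds have a single reflectance peak in the 440–480 nm band with
    low UV (<0.1 below 400 nm) and low green–red (<0.1 above 540 nm)
    reflectance; ``black`` is flat and very dark; ``violet`` combines the
    blue peak with a rising long-wavelength tail.  Repeated kinds get
    slightly varied copies (deterministic in the repeat index) so the
    default set mimics the spread of nominally similar commercial fabrics.
    """
    if not kinds:
        raise SpectrumError("need at least one fabric kind")
    unknown = [k for k in kinds if k not in _FABRIC_PARAMS]
    if unknown:
        raise SpectrumError(f"unknown fabric kind(s) {unknown}; expected one of {FABRIC_KINDS}")
    wl = grid.wavelengths
    spectra: list[Spectrum] = []
    labels: dict[str, str] = {}
    counts: dict[str, int] = {}
    for kind in kinds:
        rep = counts.get(kind, 0)
        counts[kind] = rep + 1
        centre, height, width, base, tail = _FABRIC_PARAMS[kind]
        # deterministic variation between repeated copies of one kind
        centre += 2.0 * rep
        height *= 1.0 - 0.10 * rep
        base *= 1.0 + 0.15 * rep
        values = np.full_like(wl, base)
        if height > 0:
            values = values + height * _gauss(wl, centre, width)
        if tail > 0:
            values = values + tail * _sigmoid((wl - 648.0) / 22.0)
        id = kind if rep == 0 else f"{kind}_{rep + 1}"
        spectra.append(Spectrum(grid, np.clip(values, 0.0, 1.0), "reflectance", id))
        labels[id] = f"fabric:{kind}"
    return SpectrumTable(spectra, labels)


@dataclass
class IlluminantPair:
    """Open/cloudy and woodland-shade irradiance spectra (photon flux).

    The shade spectrum's total photon flux is ``flux_ratio`` times the open
    spectrum's (default 0.044), and its normalized shape carries a strictly
    greater share of its flux below 450 nm — woodland shade is both much
    dimmer and relatively blue-enriched.
    """

    open: Spectrum
    shade: Spectrum
    flux_ratio: float

    def __post_init__(self) -> None:
        total_open = float(self.open.values.sum() * self.open.grid.step)
        total_shade = float(self.shade.values.sum() * self.shade.grid.step)
        if total_open <= 0:
            raise SpectrumError("open illuminant has zero total flux")
        if abs(total_shade / total_open - self.flux_ratio) > 1e-9:
            raise SpectrumError(
                f"shade/open flux ratio {total_shade / total_open:g} != {self.flux_ratio:g}"
            )


def _photon_blackbody(wl_nm: np.ndarray, temperature: float) -> np.ndarray:
    """Relative blackbody photon-flux spectrum (Planck, photon units)."""
    c2_nm_k = 1.4387769e7  # second radiation constant, nm·K
    return wl_nm**-4 / np.expm1(c2_nm_k / (wl_nm * temperature))


def make_illuminants(grid: WavelengthGrid = MASTER_GRID, flux_ratio: float = 0.044,
                     seed: int | None = None, shade_shape: str = "sky") -> IlluminantPair:
    """Build the open/cloudy and woodland-shade illuminant pair.

    The open spectrum is a broad daylight-like photon-flux curve (~5800 K
    correlated colour temperature); the shade spectrum takes the shape of
    blue skylight filtered through canopy (~8000 K) filtered through canopy shadow
    (``shade_shape="sky"``) or, for degenerate checks, the open shape itself
    (``shade_shape="open"``).  A seed adds gentle low-frequency ripples to
    both shapes.  The open spectrum integrates to 1; the shade spectrum's
    total flux is exactly ``flux_ratio``.
    """
    if not 0.0 < flux_ratio <= 1.0:
        raise SpectrumError(f"flux_ratio must be in (0, 1], got {flux_ratio}")
    if shade_shape not in ("sky", "open"):
        raise SpectrumError(f"unknown shade_shape {shade_shape!r}")
    wl = grid.wavelengths
    open_vals = _photon_blackbody(wl, 5800.0)
    shade_vals = _photon_blackbody(wl, 8000.0) if shade_shape == "sky" else open_vals.copy()
    if seed is not None:
        # gentle low-frequency ripples emulate day-to-day atmospheric
        # variation; the structure is shared by both illuminants (one sky)
        rng = np.random.default_rng(seed)
        x = (wl - grid.start) / (grid.stop - grid.start)
        phases = rng.uniform(0, 2 * np.pi, 3)
        amps = rng.uniform(0.0, 0.02, 3)
        ripple = sum(a * np.cos(2 * np.pi * (j + 1) * x + p)
                     for j, (a, p) in enumerate(zip(amps, phases)))
        open_vals *= 1.0 + ripple
        shade_vals *= 1.0 + ripple
    step = grid.step
    open_vals = open_vals / (open_vals.sum() * step)
    shade_vals = shade_vals / (shade_vals.sum() * step) * flux_ratio
    return IlluminantPair(
        Spectrum(grid, open_vals, "irradiance", "open_cloudy"),
        Spectrum(grid, shade_vals, "irradiance", "woodland_shade"),
        flux_ratio,
    )


@dataclass
class ReceptorTemplates:
    """The five spectral sensitivity curves of the higher-fly retina.

    R1-6 is the broadband outer-receptor class (main peak ~490 nm plus UV
    sensitizing-pigment peaks near 332/350/369 nm); R7p (~335 nm) and R8p
    (~460 nm) form the pale ommatidial pair, R7y (UV triple peak near
    337/355/373 nm) and R8y (~520 nm with UV sensitization) the yellow
    pair.  All curves are peak-normalized to 1.
    """

    templates: dict[str, Spectrum]
    species: str

    def __post_init__(self) -> None:
        if tuple(self.templates) != RECEPTOR_IDS:
            raise SpectrumError(f"expected receptors {RECEPTOR_IDS}, got {tuple(self.templates)}")
        for rid, s in self.templates.items():
            if abs(s.values.max() - 1.0) > 1e-9:
                raise SpectrumError(f"sensitivity {rid} is not peak-normalized")

    def __iter__(self):
        return iter(self.templates.items())

    def __getitem__(self, rid: str) -> Spectrum:
        return self.templates[rid]

    @property
    def grid(self) -> WavelengthGrid:
        return next(iter(self.templates.values())).grid


def govardovskii_alpha(wl_nm: np.ndarray, lambda_max: float) -> np.ndarray:
    """A1 visual-pigment alpha-band absorbance template (Govardovskii et al. 2000)."""
    x = lambda_max / wl_nm
    a = 0.8795 + 0.0459 * np.exp(-((lambda_max - 300.0) ** 2) / 11940.0)
    return 1.0 / (
        np.exp(69.7 * (a - x)) + np.exp(28.0 * (0.922 - x))
        + np.exp(-14.9 * (1.104 - x)) + 0.674
    )


def make_receptor_sensitivities(species: str = "musca_calliphora",
                                grid: WavelengthGrid = MASTER_GRID) -> ReceptorTemplates:
    """Build the five peak-normalized receptor sensitivity templates.

    Curves are sums of a Govardovskii alpha-band at the main peak and
    Gaussian UV lobes at the sensitizing-pigment positions.  The
    ``glossina`` variant shifts the R1-6 main peak +10 nm (to ~500 nm),
    matching the tsetse photopigment.
    """
    if species not in SPECIES:
        raise SpectrumError(f"unknown species {species!r}; expected one of {SPECIES}")
    wl = grid.wavelengths
    r16_peak = 490.0 if species == "musca_calliphora" else 500.0

    def uv_lobes(centres: tuple[float, ...], heights: tuple[float, ...]) -> np.ndarray:
        return sum(h * _gauss(wl, c, 11.0) for c, h in zip(centres, heights))

    curves = {
        "R1-6": govardovskii_alpha(wl, r16_peak)
        + uv_lobes((332.0, 350.0, 369.0), (0.55, 0.64, 0.58)),
        "R7p": govardovskii_alpha(wl, 335.0),
        "R7y": uv_lobes((337.0, 355.0, 373.0), (0.90, 1.00, 0.93))
        + 0.05 * govardovskii_alpha(wl, 460.0),
        "R8p": govardovskii_alpha(wl, 460.0),
        # R8y sits beneath the R7y rhabdomere, whose blue-absorbing screening
        # pigment truncates R8y's short-wavelength flank; its UV sensitization
        # survives (energy transfer) but is modest
        "R8y": govardovskii_alpha(wl, 512.0) * _sigmoid((wl - 480.0) / 18.0)
        + uv_lobes((350.0, 370.0), (0.22, 0.25)),
    }
    templates = {
        rid: Spectrum(grid, vals / vals.max(), "sensitivity", rid)
        for rid, vals in curves.items()
    }
    return ReceptorTemplates(templates, species)


__all__ = [
    "DEFAULT_FABRIC_SET",
    "FABRIC_KINDS",
    "GeneratorConfig",
    "IlluminantPair",
    "RECEPTOR_IDS",
    "ReceptorTemplates",
    "SPECIES",
    "gen_animal_reflectances",
    "gen_fabric_reflectances",
    "gen_leaf_reflectances",
    "govardovskii_alpha",
    "make_illuminants",
    "make_receptor_sensitivities",
]
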