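"""Synthetic 785-nm Raman spectra of adulterated whey protein concentrate.

Generates labelled spectrum sets with the statistical structure a solid-state
Raman screen of protein powders exhibits: narrow crystalline marker bands for
the adulterants (creatine, taurine, L-glutamine), broad protein bands for the
whey matrix, linear intensity-to-mass-fraction mixing, a slowly varying
fluorescence-like baseline, shot-like additive noise and occasional cosmic-ray
spikes.

Marker bands placed for each adulterant:

* taurine    — 528 (SO3 scissoring), 736 (C-S stretch), 1033 (C-N stretch),
  with a secondary band at 1047 cm^-1 prominent in mixtures;
* creatine   — 828 (N-C=N scissoring) and 1394 cm^-1 (CH2/CH3 deformation);
* glutamine  — a strong band at 856 cm^-1.

The standard mixture design mimics a 7-class adulteration study: classes
W (pure whey), WC, WG, WT (one adulterant) and WCG, WCT, WTG (two
adulterants); 32 formulations, two independently prepared copies of each,
three measurement positions per copy, hence 192 spectra.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .spectra import SpectrumSet

__all__ = [
    "PeakSpec",
    "ComponentLibrary",
    "NoiseSpec",
    "CLASSES",
    "ADULTERANTS",
    "default_library",
    "default_axis",
    "component_spectrum",
    "mixture_spectrum",
    "standard_design",
    "generate_dataset",
]

CLASSES = ("W", "WC", "WG", "WT", "WCG", "WCT", "WTG")
ADULTERANTS = ("creatine", "taurine", "glutamine")

#: which adulterants are present in each class
CLASS_COMPOSITION = {
    "W": (),
    "WC": ("creatine",),
    "WG": ("glutamine",),
    "WT": ("taurine",),
    "WCG": ("creatine", "glutamine"),
    "WCT": ("creatine", "taurine"),
    "WTG": ("taurine", "glutamine"),
}


@dataclass(frozen=True)
class PeakSpec:
    """One vibrational band: position, width, strength and line shape.

    Parameters
    ----------
    center
        Band position (cm^-1).
    width
        Full width at half maximum (cm^-1), > 0.
    amplitude
        Peak height per unit mass fraction (arbitrary units, >= 0).
    shape
        ``"gaussian"``, ``"lorentzian"`` or ``"pseudo_voigt"``.
    eta
        Lorentzian mixing fraction for the pseudo-Voigt profile, in [0, 1].
    """

    center: float
    width: float
    amplitude: float
    shape: str = "pseudo_voigt"
    eta: float = 0.5

    def __post_init__(self):
        if self.width <= 0:
            raise ValueError("peak width must be > 0")
        if self.amplitude < 0:
            raise ValueError("peak amplitude must be >= 0")
        if self.shape not in ("gaussian", "lorentzian", "pseudo_voigt"):
            raise ValueError(f"unknown peak shape {self.shape!r}")
        if not 0.0 <= self.eta <= 1.0:
            raise ValueError("pseudo-Voigt mixing fraction must be in [0, 1]")

    def profile(self, axis: np.ndarray) -> np.ndarray:
        """Evaluate the band on ``axis``; the apex value equals ``amplitude``."""
        x = (np.asarray(axis, dtype=float) - self.center) / self.width
        gauss = np.exp(-4.0 * np.log(2.0) * x * x)
        if self.shape == "gaussian":
            line = gauss
        else:
            lorentz = 1.0 / (1.0 + 4.0 * x * x)
            if self.shape == "lorentzian":
                line = lorentz
            else:
                line = self.eta * lorentz + (1.0 - self.eta) * gauss
        return self.amplitude * line


#: broad protein-matrix bands (phenylalanine ring, amide III, CH2 deformation,
#: amide I); centers kept clear of the adulterant marker positions.
_WPC_PEAKS = (
    PeakSpec(620, 28, 0.25),
    PeakSpec(940, 30, 0.35),
    PeakSpec(1003, 18, 1.00),
    PeakSpec(1250, 42, 0.80),
    PeakSpec(1450, 32, 0.90),
    PeakSpec(1660, 36, 1.00),
)

_CREATINE_PEAKS = (
    PeakSpec(578, 10, 1.2),
    PeakSpec(828, 10, 8.0),
    PeakSpec(908, 11, 1.5),
    PeakSpec(1394, 12, 5.0),
)

_TAURINE_PEAKS = (
    PeakSpec(528, 10, 7.0),
    PeakSpec(600, 10, 0.8),
    PeakSpec(736, 10, 5.5),
    PeakSpec(1033, 9, 3.0),
    PeakSpec(1047, 9, 2.5),
)

_GLUTAMINE_PEAKS = (
    PeakSpec(646, 10, 1.0),
    PeakSpec(856, 10, 8.0),
    PeakSpec(1090, 12, 1.5),
    PeakSpec(1326, 12, 1.2),
)


@dataclass(frozen=True)
class ComponentLibrary:
    """Peak lists for the whey matrix and each adulterant."""

    components: dict = field(default_factory=lambda: {
        "wpc": _WPC_PEAKS,
        "creatine": _CREATINE_PEAKS,
        "taurine": _TAURINE_PEAKS,
        "glutamine": _GLUTAMINE_PEAKS,
    })

    def peaks(self, name: str) -> tuple[PeakSpec, ...]:
        try:
            return tuple(self.components[name])
        except KeyError:
            raise KeyError(f"no component named {name!r} in library") from None


def default_library() -> ComponentLibrary:
    return ComponentLibrary()


def default_axis(lo: float = 400.0, hi: float = 1800.0,
                 step: float = 1.0) -> np.ndarray:
    """Uniform wavenumber grid, 400-1800 cm^-1 at 1 cm^-1 (1401 points)."""
    n = int(round((hi - lo) / step)) + 1
    return lo + step * np.arange(n)


@dataclass(frozen=True)
class NoiseSpec:
    """Instrumental artefact model for one acquisition.

    ``noise_sd`` is the additive Gaussian noise standard deviation in
    intensity units (default 1 % of the pure-matrix maximum).  The baseline is
    a random polynomial of degree <= ``baseline_degree`` on the axis rescaled
    to [-1, 1], with coefficients drawn uniformly from ``baseline_ranges``.
    Cosmic-ray spikes hit a spectrum with probability ``spike_prob`` and add a
    one-channel excursion drawn from ``spike_amplitude``.
    """

    noise_sd: float = 0.012
    baseline_degree: int = 2
    baseline_ranges: tuple = ((0.5, 2.0), (-0.5, 0.5), (-0.05, 0.05))
    spike_prob: float = 0.1
    spike_amplitude: tuple = (3.0, 10.0)
    seed: int = 0

    def __post_init__(self):
        if self.noise_sd < 0 or self.spike_prob < 0:
            raise ValueError("noise scale parameters must be >= 0")
        if not 0 <= self.baseline_degree <= 3:
            raise ValueError("baseline degree must be in 0..3")
        if len(self.baseline_ranges) < self.baseline_degree + 1:
            raise ValueError("need one coefficient range per polynomial term")

    def silent(self) -> "NoiseSpec":
        """Copy with noise, baseline and spikes all switched off."""
        return replace(self, noise_sd=0.0, spike_prob=0.0,
                       baseline_ranges=tuple((0.0, 0.0) for _ in self.baseline_ranges))


def component_spectrum(peaks, axis: np.ndarray) -> np.ndarray:
    """Sum of band profiles of one component on ``axis``.

    ``peaks`` is a component name's peak tuple from a :class:`ComponentLibrary`.
    """
    peaks = tuple(peaks)
    if not peaks:
        raise ValueError("component has an empty peak list")
    axis = np.asarray(axis, dtype=float)
    if not np.all(np.diff(axis) > 0):
        raise ValueError("axis must be strictly increasing")
    out = np.zeros_like(axis)
    for p in peaks:
        out += p.profile(axis)
    return out


def _fractions(row) -> dict:
    return {a: float(row[a]) for a in ADULTERANTS}


def clean_mixture(row, library: ComponentLibrary, axis: np.ndarray) -> np.ndarray:
    """Noise-free linear mass mixture for one design row.

    intensity = (1 - sum f) * matrix + sum_k f_k * component_k, with mass
    fractions f taken from the row's percentage columns.
    """
    fr = _fractions(row)
    for name, pct in fr.items():
        if pct < 0:
            raise ValueError(f"negative mass fraction for {name}")
    total = sum(fr.values()) / 100.0
    if total >= 1.0:
        raise ValueError("adulterant mass fractions must sum to < 100 %")
    y = (1.0 - total) * component_spectrum(library.peaks("wpc"), axis)
    for name, pct in fr.items():
        if pct > 0:
            y += (pct / 100.0) * component_spectrum(library.peaks(name), axis)
    return y


def mixture_spectrum(row, library: ComponentLibrary, noise: NoiseSpec,
                     axis: np.ndarray,
                     rng: np.random.Generator | None = None) -> np.ndarray:
    """One simulated acquisition: clean mixture + baseline + noise + spikes.

    Deterministic given the ``NoiseSpec`` seed (or an explicit ``rng``).
    """
    if rng is None:
        rng = np.random.default_rng(noise.seed)
    y = clean_mixture(row, library, axis)
    # fluorescence-like slow baseline on the axis rescaled to [-1, 1]
    u = (2.0 * (axis - axis[0]) / (axis[-1] - axis[0])) - 1.0
    for degree in range(noise.baseline_degree + 1):
        lo, hi = noise.baseline_ranges[degree]
        y = y + rng.uniform(lo, hi) * u ** degree
    if noise.noise_sd > 0:
        y = y + rng.normal(0.0, noise.noise_sd, size=axis.size)
    if rng.uniform() < noise.spike_prob:
        pos = rng.integers(0, axis.size)
        y[pos] += rng.uniform(*noise.spike_amplitude)
    return y


# ---------------------------------------------------------------------------
# standard mixture design: 32 formulations x 2 copies x 3 positions
# ---------------------------------------------------------------------------

#: adulteration levels, mass %.  Single-adulterant classes span 1-10 %; the
#: two-adulterant classes combine levels from the upper half of that range,
#: so that every adulterant present in a blend sits at a clearly
#: quantifiable level and the seven classes remain mutually resolvable (a
#: blend with one adulterant at trace level is indistinguishable from the
#: single-adulterant class by construction, which is not what the class
#: labels assert).
DEFAULT_LEVELS = {
    "single": (1.0, 2.5, 5.0, 7.5, 10.0),
    "pair": ((5.0, 5.0), (5.0, 10.0), (7.5, 7.5), (10.0, 5.0), (10.0, 10.0)),
    "n_pure": 2,
}


def standard_design(levels: dict | None = None) -> pd.DataFrame:
    """Build the 192-row design table (32 formulations, 2 copies, 3 positions).

    ``levels`` may override the adulteration levels: keys ``single`` (five
    mass-% levels used by WC, WG, WT), ``pair`` (five (first, second) mass-%
    pairs used by WCG, WCT, WTG) and ``n_pure`` (pure-matrix formulations).
    """
    cfg = dict(DEFAULT_LEVELS)
    if levels:
        cfg.update(levels)
    single, pair, n_pure = cfg["single"], cfg["pair"], int(cfg["n_pure"])
    if len(single) < 1 or len(pair) < 1 or n_pure < 1:
        raise ValueError("need at least one level per adulterant combination")
    n_form = n_pure + 3 * len(single) + 3 * len(pair)
    if n_form != 32:
        raise ValueError(
            f"level configuration yields {n_form} formulations "
            f"({n_pure} pure + 3x{len(single)} single + 3x{len(pair)} pair); "
            "the standard design requires exactly 32")

    rows = []
    form_id = 0

    def add(label, creatine=0.0, taurine=0.0, glutamine=0.0):
        nonlocal form_id
        form_id += 1
        for copy in (1, 2):
            for position in (1, 2, 3):
                rows.append({
                    "formulation_id": form_id,
                    "sample_id": f"F{form_id:02d}c{copy}",
                    "spectrum_id": f"F{form_id:02d}c{copy}p{position}",
                    "class_label": label,
                    "creatine": creatine,
                    "taurine": taurine,
                    "glutamine": glutamine,
                    "copy": copy,
                    "position": position,
                })

    for _ in range(n_pure):
        add("W")
    for lv in single:
        add("WC", creatine=lv)
    for lv in single:
        add("WG", glutamine=lv)
    for lv in single:
        add("WT", taurine=lv)
    for a, b in pair:
        add("WCG", creatine=a, glutamine=b)
    for a, b in pair:
        add("WCT", creatine=a, taurine=b)
    for a, b in pair:
        add("WTG", taurine=a, glutamine=b)

    design = pd.DataFrame(rows)
    for _, row in design.iterrows():
        present = tuple(a for a in ADULTERANTS if row[a] > 0)
        if set(present) != set(CLASS_COMPOSITION[row["class_label"]]):
            raise ValueError("class label inconsistent with nonzero fractions")
    return design


def generate_dataset(design: pd.DataFrame | None = None,
                     library: ComponentLibrary | None = None,
                     noise: NoiseSpec | None = None,
                     axis: np.ndarray | None = None,
                     seed: int | None = None) -> tuple[pd.DataFrame, SpectrumSet]:
    """Simulate every spectrum of a mixture design.

    Returns the design table and the :class:`SpectrumSet`; bit-identical for
    identical seeds.  ``seed`` overrides ``noise.seed`` when given.
    """
    if design is None:
        design = standard_design()
    library = library or default_library()
    noise = noise or NoiseSpec()
    if axis is None:
        axis = default_axis()
    rng = np.random.default_rng(noise.seed if seed is None else seed)
    X = np.empty((len(design), axis.size))
    for i, (_, row) in enumerate(design.iterrows()):
        X[i] = mixture_spectrum(row, library, noise, axis, rng=rng)
    return design, SpectrumSet(axis, X, design)
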