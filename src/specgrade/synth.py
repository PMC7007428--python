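"""Synthetic ATR-FTIR tissue-spectrum generator.

Emulates a three-class meningioma cohort: grade I (``G1``), grade II (``G2``)
and grade I that later recurred (``G1R``).  Each patient contributes a fixed
number of replicate spectra.  A spectrum is a sum of vibrational absorbance
bands (Gaussian or Lorentzian line shapes) at the canonical biofingerprint
positions — Amide I 1650, Amide II 1550, Amide III 1260, lipid C=O 1750,
CH2 bending 1470, phosphate stretches 1225/1080, carbohydrate 1155, glycogen
1030, protein phosphorylation 970 cm^-1 — modulated by

* class effects: localized multiplicative intensity changes (up or down) at
  marker wavenumbers, shared by every patient of the target class;
* a patient effect: per-band amplitude jitter shared by all of a patient's
  replicates (creates within-patient correlation that survives preprocessing);
* a per-replicate multiplicative gain (ATR contact-pressure scatter), an
  additive polynomial baseline, and white noise.

Gain, baseline and white noise emulate exactly the nuisance variation the
Savitzky-Golay derivative + vector normalisation chain is meant to remove.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .core import CLASS_CODES, CohortDesign, SpectralDataset

__all__ = [
    "Band",
    "BandModel",
    "ClassEffect",
    "default_band_model",
    "default_class_effects",
    "default_study_design",
    "effect_factor",
    "inject_effect",
    "generate_cohort",
]


@dataclass(frozen=True)
class Band:
    """One absorbance band: center/width in cm^-1, unitless base amplitude."""

    center: float
    width: float
    amplitude: float
    shape: str = "gaussian"

    def __post_init__(self) -> None:
        if self.width <= 0:
            raise ValueError("band width must be > 0")
        if self.amplitude < 0:
            raise ValueError("band amplitude must be >= 0")
        if self.shape not in ("gaussian", "lorentzian"):
            raise ValueError(f"unknown band shape {self.shape!r}")

    def profile(self, axis: np.ndarray) -> np.ndarray:
        """Unit-peak line shape evaluated on ``axis``."""
        x = (np.asarray(axis, dtype=float) - self.center) / self.width
        if self.shape == "gaussian":
            return np.exp(-0.5 * x * x)
        return 1.0 / (1.0 + x * x)


@dataclass
class BandModel:
    """Band composition plus nuisance-variation scales.

    ``scatter_sd`` is the log-sd of the per-replicate multiplicative gain,
    ``noise_sd`` the additive white-noise sd (absorbance units), and
    ``patient_sd`` the log-sd of the per-patient per-band amplitude jitter.
    ``baseline_coeffs`` are polynomial coefficients (highest power first)
    over the axis position normalised to [0, 1].
    """

    bands: list[Band]
    baseline_coeffs: tuple[float, ...] = (0.0,)
    scatter_sd: float = 0.0
    noise_sd: float = 0.0
    patient_sd: float = 0.0

    def __post_init__(self) -> None:
        if not self.bands:
            raise ValueError("band model needs at least one band")
        for name in ("scatter_sd", "noise_sd", "patient_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    def amplitudes(self) -> np.ndarray:
        return np.array([b.amplitude for b in self.bands])

    def profiles(self, axis: np.ndarray) -> np.ndarray:
        """(n_bands, n_points) matrix of unit-peak profiles."""
        return np.vstack([b.profile(axis) for b in self.bands])

    def baseline(self, axis: np.ndarray) -> np.ndarray:
        lo, hi = float(np.min(axis)), float(np.max(axis))
        x = (np.asarray(axis, dtype=float) - lo) / (hi - lo) if hi > lo else axis * 0.0
        return np.polyval(self.baseline_coeffs, x)


@dataclass(frozen=True)
class ClassEffect:
    """A class-specific intensity change at one marker wavenumber.

    ``direction="up"`` multiplies the local intensity by ``1 + magnitude`` at
    the marker (decaying with distance); ``"down"`` divides by the same
    factor, so an up and a down of equal magnitude cancel exactly.
    """

    wavenumber: float
    direction: str
    magnitude: float
    target_class: str

    def __post_init__(self) -> None:
        if self.direction not in ("up", "down"):
            raise ValueError(f"direction must be 'up' or 'down', got {self.direction!r}")
        if self.magnitude < 0:
            raise ValueError("magnitude must be >= 0")
        if self.target_class not in CLASS_CODES:
            raise ValueError(f"unknown target class {self.target_class!r}")


# -- defaults: the emulated study design ----------------------------------

# Biofingerprint band assignments (center, width, base amplitude).
_MAIN_BANDS = [
    (1750.0, 14.0, 0.25),  # lipid C=O symmetric stretch
    (1650.0, 28.0, 1.00),  # Amide I
    (1550.0, 22.0, 0.65),  # Amide II
    (1470.0, 14.0, 0.30),  # CH2 bending
    (1260.0, 20.0, 0.35),  # Amide III
    (1225.0, 18.0, 0.35),  # asymmetric phosphate stretch
    (1155.0, 14.0, 0.25),  # carbohydrate CO-O-C stretch
    (1080.0, 22.0, 0.45),  # symmetric phosphate stretch
    (1030.0, 16.0, 0.30),  # glycogen C-O stretch
    (970.0, 14.0, 0.20),  # protein phosphorylation
]

# Broad background absorptions outside / underneath the fingerprint window.
_BACKGROUND_BANDS = [
    (3300.0, 180.0, 0.80),  # Amide A / O-H, N-H stretch envelope
    (2925.0, 60.0, 0.35),  # C-H stretch region
    (1400.0, 260.0, 0.20),  # broad fingerprint envelope
]

# Marker wavenumbers carrying the grade II class effects, with the direction
# of the intensity change relative to grade I (up = higher in grade II).
_G2_EFFECTS = [
    (1651.0, "down"),
    (1593.0, "down"),
    (1546.0, "up"),
    (1500.0, "up"),
    (1454.0, "down"),
    (1377.0, "down"),
    (1227.0, "down"),
    (1122.0, "up"),
]

# Marker wavenumbers carrying the grade I-recurrence effects (up = higher in
# recurring grade I relative to grade I).
_G1R_EFFECTS = [
    (1755.0, "down"),
    (1693.0, "up"),
    (1477.0, "down"),
    (1423.0, "up"),
    (1400.0, "down"),
    (1369.0, "down"),
    (1346.0, "down"),
    (1246.0, "up"),
]

#: Default fractional effect magnitudes per target class.  Grade II differs
#: from grade I only moderately (the hardest comparison); the recurring
#: grade I profile is markedly more distinct.
DEFAULT_EFFECT_MAGNITUDE = {"G2": 0.05, "G1R": 0.15}


def default_band_model() -> BandModel:
    """Band composition and noise scales used as the study conditions.

    Narrow secondary bands are placed at every marker wavenumber so that each
    class effect acts on a real local absorption feature, as it would in
    tissue where the markers sit on distinct molecular vibrations.
    """
    bands = [Band(c, w, a) for c, w, a in _MAIN_BANDS + _BACKGROUND_BANDS]
    marker_positions = {w for w, _ in _G2_EFFECTS} | {w for w, _ in _G1R_EFFECTS}
    bands += [Band(w, 9.0, 0.12) for w in sorted(marker_positions)]
    return BandModel(
        bands=bands,
        baseline_coeffs=(0.04, 0.05),  # gentle linear drift over the range
        scatter_sd=0.10,
        noise_sd=0.004,
        patient_sd=0.40,
    )


def default_class_effects() -> list[ClassEffect]:
    effects = [
        ClassEffect(w, d, DEFAULT_EFFECT_MAGNITUDE["G2"], "G2") for w, d in _G2_EFFECTS
    ]
    effects += [
        ClassEffect(w, d, DEFAULT_EFFECT_MAGNITUDE["G1R"], "G1R")
        for w, d in _G1R_EFFECTS
    ]
    return effects


def default_study_design() -> tuple[CohortDesign, BandModel, list[ClassEffect]]:
    """The emulated cohort: 70/24/5 patients, 10 replicate spectra each,
    4000-400 cm^-1 acquisition at 8 cm^-1 resolution (4 cm^-1 point spacing).
    """
    design = CohortDesign(
        class_sizes={"G1": 70, "G2": 24, "G1R": 5},
        replicates_per_patient=10,
        axis_lo=400.0,
        axis_hi=4000.0,
        resolution=8.0,
        point_spacing=4.0,
    )
    return design, default_band_model(), default_class_effects()


# -- effect mechanics ------------------------------------------------------

def _match_band(effect: ClassEffect, bands: BandModel) -> Band:
    """Band whose support (|x - center| <= 3 width) contains the effect;
    otherwise the nearest band, with a warning."""
    dists = [abs(effect.wavenumber - b.center) / b.width for b in bands.bands]
    j = int(np.argmin(dists))
    if dists[j] > 3.0:
        warnings.warn(
            f"effect at {effect.wavenumber} cm^-1 lies outside all band supports; "
            f"attaching to nearest band at {bands.bands[j].center} cm^-1",
            stacklevel=2,
        )
    return bands.bands[j]


def effect_factor(
    axis: np.ndarray, effect: ClassEffect, bands: BandModel
) -> np.ndarray:
    """Multiplicative intensity factor of one class effect on the axis.

    The factor is ``f ** w(x)`` with ``f = 1 + magnitude`` (up) or its
    reciprocal (down) and ``w`` a unit-peak Gaussian centred at the marker
    wavenumber with the matched band's width, so the change peaks at the
    marker and vanishes away from the band.  Up followed by down of equal
    magnitude is the exact identity.
    """
    band = _match_band(effect, bands)
    x = (np.asarray(axis, dtype=float) - effect.wavenumber) / band.width
    w = np.exp(-0.5 * x * x)
    f = 1.0 + effect.magnitude
    if effect.direction == "down":
        f = 1.0 / f
    return np.power(f, w)


def inject_effect(
    spectrum: np.ndarray,
    axis: np.ndarray,
    effect: ClassEffect,
    bands: BandModel,
) -> np.ndarray:
    """Apply one class effect to a single spectrum (returns a new array)."""
    return np.asarray(spectrum, dtype=float) * effect_factor(axis, effect, bands)


def class_effect_profiles(
    axis: np.ndarray, effects: list[ClassEffect], bands: BandModel
) -> dict[str, np.ndarray]:
    """Combined multiplicative factor per class code (classes without effects
    get the unit profile)."""
    out = {code: np.ones_like(np.asarray(axis, dtype=float)) for code in CLASS_CODES}
    for eff in effects:
        out[eff.target_class] = out[eff.target_class] * effect_factor(axis, eff, bands)
    return out


# -- cohort generation -----------------------------------------------------

def generate_cohort(
    design: CohortDesign,
    bands: BandModel,
    effects: list[ClassEffect],
    seed: int,
    carrier_effects: dict[str, list[ClassEffect]] | None = None,
) -> SpectralDataset:
    """Simulate the full cohort; bit-identical for a fixed seed.

    Patients are labelled ``<class>-<index>`` (``G1-001`` ...), spectra
    ``<patient>-r<replicate>``.  ``carrier_effects`` optionally assigns extra
    effects to named patients (e.g. grade I patients silently carrying the
    recurrence-trend profile), applied on top of their class profile.

    Each replicate spectrum is::

        gain * sum_b amp_b * jitter_pb * profile_b(x) * E_class(x) [* E_carrier(x)]
        + baseline(x) + noise

    with ``gain`` lognormal(0, scatter_sd) per replicate, ``jitter_pb``
    lognormal(0, patient_sd) per patient and band, and white noise of sd
    ``noise_sd`` per point.
    """
    rng = np.random.default_rng(seed)
    axis = design.axis()
    profiles = bands.profiles(axis)  # (n_bands, p)
    amplitudes = bands.amplitudes()
    baseline = bands.baseline(axis)
    class_profiles = class_effect_profiles(axis, effects, bands)
    carrier_effects = carrier_effects or {}

    rows, spec_ids, patient_ids, labels = [], [], [], []
    codes = [c for c in CLASS_CODES if c in design.class_sizes]
    for code in codes:
        for i in range(design.class_sizes[code]):
            pid = f"{code}-{i + 1:03d}"
            jitter = np.exp(rng.normal(0.0, bands.patient_sd, size=amplitudes.size))
            signal = (amplitudes * jitter) @ profiles
            signal = signal * class_profiles[code]
            for eff in carrier_effects.get(pid, []):
                signal = inject_effect(signal, axis, eff, bands)
            for r in range(design.replicates_per_patient):
                gain = np.exp(rng.normal(0.0, bands.scatter_sd))
                noise = rng.normal(0.0, bands.noise_sd, size=axis.size)
                rows.append(gain * signal + baseline + noise)
                spec_ids.append(f"{pid}-r{r + 1:02d}")
                patient_ids.append(pid)
                labels.append(code)

    return SpectralDataset(
        wavenumbers=axis,
        intensities=np.vstack(rows),
        spectrum_ids=np.array(spec_ids, dtype=object),
        patient_ids=np.array(patient_ids, dtype=object),
        labels=np.array(labels, dtype=object),
        stage_tag="raw",
    )
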