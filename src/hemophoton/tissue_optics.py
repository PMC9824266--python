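"""Wavelength-dependent optical properties of the tissue materials.

All engine-facing quantities use millimetre units: absorption and scattering
coefficients in mm^-1, lengths in mm, time in ns (speed of light
c = 299.792458 mm/ns).  The skin-baseline power law and the stratum-corneum
mixing rule are literature fits expressed in cm^-1; they are evaluated in that
convention and divided by 10, which is the only reading that reproduces the
tabulated skin-baseline row (0.163 / 0.110 / 0.066 mm^-1 at 465 / 525 / 615 nm).

Blood absorption is a three-species mixture of deoxyhemoglobin (HHb),
oxyhemoglobin (HbO) and glycated hemoglobin (HbA1c):

    mu_a = mu_HHb + P_HbO (mu_HbO - mu_HHb) + P_HbA1c (mu_HbA1c - mu_HHb)
    P_HbO = SpO2 (1 - HbA1c),   P_HbA1c = HbA1c

where SpO2 and HbA1c are fractions.  Venous blood uses an SpO2 reduced by a
fixed offset (default 0.10).  Pulsatility enters only through the dermal
blood-volume fractions, which double in the systolic phase.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

SPEED_OF_LIGHT_MM_NS = 299.792458

#: The three sensor wavelengths (median wavelengths of an RGB color sensor).
WAVELENGTHS_NM = (465.0, 525.0, 615.0)

# Skin-baseline power law, cm^-1 with wavelength in nm.  The exponent is the
# standard literature value; it reproduces the tabulated baseline row to three
# decimals in mm^-1.
BASELINE_COEFF = 7.8375e8
BASELINE_EXPONENT = -3.255


class UnknownWavelengthError(KeyError):
    """Raised when a chromophore lookup is attempted off the tabulated grid."""


class UnknownMaterialError(KeyError):
    """Raised for a material id with no registered optical properties."""


def _as_spectrum(values) -> dict[float, float]:
    d = {float(k): float(v) for k, v in dict(values).items()}
    if any(v < 0 for v in d.values()):
        raise ValueError("absorption coefficients must be non-negative")
    return d


@dataclass(frozen=True)
class ChromophoreLibrary:
    """Per-wavelength absorption coefficients of the skin chromophores, mm^-1.

    Coefficients are tabulated only at the supported wavelengths; lookups at
    any other wavelength raise :class:`UnknownWavelengthError` rather than
    extrapolate.  Hemoglobin-species coefficients are whole-blood-referenced
    and are mixed directly by :func:`blood_absorption` without concentration
    scaling.
    """

    mu_hbo: dict[float, float] = field(
        default_factory=lambda: {465.0: 8.94, 525.0: 7.18, 615.0: 0.27}
    )
    mu_hhb: dict[float, float] = field(
        default_factory=lambda: {465.0: 4.35, 525.0: 8.18, 615.0: 1.76}
    )
    mu_hba1c: dict[float, float] = field(
        default_factory=lambda: {465.0: 127.68, 525.0: 105.85, 615.0: 39.66}
    )
    mu_melanin: dict[float, float] = field(
        default_factory=lambda: {465.0: 88.66, 525.0: 58.12, 615.0: 33.51}
    )
    # Water is numerically negligible at these wavelengths (Pope & Fry order
    # of magnitude); overridable.
    mu_water: dict[float, float] = field(
        default_factory=lambda: {465.0: 1.06e-5, 525.0: 4.2e-5, 615.0: 2.7e-4}
    )
    baseline_coeff: float = BASELINE_COEFF
    baseline_exponent: float = BASELINE_EXPONENT

    def __post_init__(self):
        for name in ("mu_hbo", "mu_hhb", "mu_hba1c", "mu_melanin", "mu_water"):
            spectrum = _as_spectrum(getattr(self, name))
            missing = set(WAVELENGTHS_NM) - set(spectrum)
            if missing:
                raise ValueError(f"{name} missing required wavelengths {sorted(missing)}")
            object.__setattr__(self, name, spectrum)

    def _get(self, table: dict[float, float], wavelength_nm: float) -> float:
        try:
            return table[float(wavelength_nm)]
        except KeyError:
            raise UnknownWavelengthError(
                f"no chromophore data at {wavelength_nm} nm; "
                f"tabulated wavelengths are {sorted(table)}"
            ) from None

    def hbo(self, wavelength_nm: float) -> float:
        return self._get(self.mu_hbo, wavelength_nm)

    def hhb(self, wavelength_nm: float) -> float:
        return self._get(self.mu_hhb, wavelength_nm)

    def hba1c(self, wavelength_nm: float) -> float:
        return self._get(self.mu_hba1c, wavelength_nm)

    def melanin(self, wavelength_nm: float) -> float:
        return self._get(self.mu_melanin, wavelength_nm)

    def water(self, wavelength_nm: float) -> float:
        return self._get(self.mu_water, wavelength_nm)


DEFAULT_CHROMOPHORES = ChromophoreLibrary()


@dataclass(frozen=True)
class OpticalProperties:
    """Bulk optical properties of one material at one wavelength."""

    mu_a: float  # absorption coefficient, mm^-1
    mu_s: float  # scattering coefficient, mm^-1
    g: float  # scattering anisotropy (mean cosine)
    n: float  # refractive index

    def __post_init__(self):
        if self.mu_a < 0 or self.mu_s < 0:
            raise ValueError("mu_a and mu_s must be non-negative")
        if not -1.0 < self.g < 1.0:
            raise ValueError("anisotropy g must lie in (-1, 1)")
        if self.n < 1.0:
            raise ValueError("refractive index must be >= 1")

    @property
    def mu_t(self) -> float:
        """Total attenuation coefficient mu_a + mu_s, mm^-1."""
        return self.mu_a + self.mu_s


@dataclass(frozen=True)
class SkinSublayerSpec:
    """Volume fractions and thickness of one skin sublayer."""

    name: str
    v_blood_art: float
    v_blood_vein: float
    v_water: float
    v_melanin: float
    thickness_mm: float

    def __post_init__(self):
        for f in (self.v_blood_art, self.v_blood_vein, self.v_water, self.v_melanin):
            if not 0.0 <= f <= 1.0:
                raise ValueError(f"volume fraction out of [0,1] in sublayer {self.name!r}")
        if self.v_blood_art + self.v_blood_vein + self.v_water > 1.0 + 1e-12:
            raise ValueError(f"blood+water fractions exceed 1 in sublayer {self.name!r}")
        if self.thickness_mm <= 0:
            raise ValueError("sublayer thickness must be positive")


#: The six-sublayer skin stack, outermost first.  Cumulative depth 0.95 mm.
SKIN_SUBLAYERS: tuple[SkinSublayerSpec, ...] = (
    SkinSublayerSpec("stratum_corneum", 0.0, 0.0, 0.05, 0.0, 0.02),
    SkinSublayerSpec("epidermis", 0.0, 0.0, 0.2, 0.1, 0.25),
    SkinSublayerSpec("papillary_dermis", 0.02, 0.02, 0.5, 0.0, 0.1),
    SkinSublayerSpec("upper_blood_net_dermis", 0.15, 0.15, 0.6, 0.0, 0.08),
    SkinSublayerSpec("reticular_dermis", 0.02, 0.02, 0.7, 0.0, 0.2),
    SkinSublayerSpec("deep_blood_net_dermis", 0.05, 0.05, 0.05, 0.0, 0.3),
)

SKIN_SUBLAYER_NAMES = tuple(s.name for s in SKIN_SUBLAYERS)

#: Cumulative depth bin edges of the default stack, mm.
SKIN_SUBLAYER_EDGES_MM = tuple(np.cumsum([s.thickness_mm for s in SKIN_SUBLAYERS]))


@dataclass(frozen=True)
class BloodState:
    """Physiological state of the blood compartments.

    HbA1c and SpO2 are fractions (0.06 = 6 %).  ``phase`` selects the cardiac
    phase: in systole the dermal blood-volume fractions double.  Venous SpO2
    is the arterial value minus ``venous_spo2_offset``, clamped to [0, 1].
    """

    hba1c: float = 0.06
    spo2_arterial: float = 0.97
    phase: str = "diastolic"
    venous_spo2_offset: float = 0.10

    def __post_init__(self):
        if not 0.0 <= self.hba1c <= 0.2:
            raise ValueError("HbA1c fraction must lie in [0, 0.2]")
        if not 0.0 <= self.spo2_arterial <= 1.0:
            raise ValueError("arterial SpO2 must lie in [0, 1]")
        if self.phase not in ("systolic", "diastolic"):
            raise ValueError("phase must be 'systolic' or 'diastolic'")

    @property
    def spo2_venous(self) -> float:
        return min(1.0, max(0.0, self.spo2_arterial - self.venous_spo2_offset))

    @property
    def systolic(self) -> bool:
        return self.phase == "systolic"

    def with_phase(self, phase: str) -> "BloodState":
        return replace(self, phase=phase)


def baseline_absorption(
    wavelength_nm: float, chrom: ChromophoreLibrary = DEFAULT_CHROMOPHORES
) -> float:
    """Skin-baseline absorption coefficient, mm^-1.

    Power-law fit evaluated in cm^-1 (coefficient 7.8375e8, wavelength in nm)
    and converted to mm^-1.  Valid over 400-1000 nm.
    """
    if not 400.0 <= wavelength_nm <= 1000.0:
        raise ValueError(f"wavelength {wavelength_nm} nm outside supported range 400-1000 nm")
    return chrom.baseline_coeff * wavelength_nm**chrom.baseline_exponent / 10.0


def blood_absorption(
    state: BloodState,
    compartment: str,
    wavelength_nm: float,
    chrom: ChromophoreLibrary = DEFAULT_CHROMOPHORES,
) -> float:
    """Absorption coefficient of whole blood, mm^-1.

    Three-species mixture of HHb, HbO and HbA1c; the venous compartment uses
    the offset-reduced SpO2.
    """
    if compartment not in ("arterial", "venous"):
        raise ValueError("compartment must be 'arterial' or 'venous'")
    spo2 = state.spo2_arterial if compartment == "arterial" else state.spo2_venous
    mu_hhb = chrom.hhb(wavelength_nm)
    p_hbo = spo2 * (1.0 - state.hba1c)
    p_hba1c = state.hba1c
    return (
        mu_hhb
        + p_hbo * (chrom.hbo(wavelength_nm) - mu_hhb)
        + p_hba1c * (chrom.hba1c(wavelength_nm) - mu_hhb)
    )


def stratum_corneum_absorption(
    wavelength_nm: float,
    spec: SkinSublayerSpec = SKIN_SUBLAYERS[0],
    chrom: ChromophoreLibrary = DEFAULT_CHROMOPHORES,
) -> float:
    """Stratum-corneum absorption, mm^-1.

    Literature mixing rule evaluated in cm^-1 (both the affine term and the
    baseline/water coefficients) and converted to mm^-1.
    """
    if not 400.0 <= wavelength_nm <= 1000.0:
        raise ValueError(f"wavelength {wavelength_nm} nm outside supported range 400-1000 nm")
    base_cm = baseline_absorption(wavelength_nm, chrom) * 10.0
    water_cm = chrom.water(wavelength_nm) * 10.0
    vw = spec.v_water
    mu_cm = ((0.1 - 0.3e-4 * wavelength_nm) + 0.125 * base_cm) * (1.0 - vw) + vw * water_cm
    return mu_cm / 10.0


def epidermis_absorption(
    wavelength_nm: float,
    spec: SkinSublayerSpec = SKIN_SUBLAYERS[1],
    chrom: ChromophoreLibrary = DEFAULT_CHROMOPHORES,
) -> float:
    """Epidermis absorption, mm^-1: melanin/baseline mixture diluted by water."""
    vm, vw = spec.v_melanin, spec.v_water
    return (
        vm * chrom.melanin(wavelength_nm)
        + (1.0 - vm) * baseline_absorption(wavelength_nm, chrom)
    ) * (1.0 - vw) + vw * chrom.water(wavelength_nm)


def skin_sublayer_absorption(
    spec: SkinSublayerSpec,
    state: BloodState,
    wavelength_nm: float,
    chrom: ChromophoreLibrary = DEFAULT_CHROMOPHORES,
) -> float:
    """Absorption of a blood-bearing dermal sublayer, mm^-1.

    Volume-fraction mixture of arterial blood, venous blood, water and
    baseline.  In the systolic phase both blood fractions double.  For the
    upper blood net dermis the doubled fractions exceed unity; the mixture is
    kept linear (the residual baseline weight goes slightly negative), which
    preserves the exact doubling of the blood-term contribution.  A negative
    total would be a configuration error.
    """
    factor = 2.0 if state.systolic else 1.0
    v_art = factor * spec.v_blood_art
    v_vein = factor * spec.v_blood_vein
    mu_art = blood_absorption(state, "arterial", wavelength_nm, chrom)
    mu_vein = blood_absorption(state, "venous", wavelength_nm, chrom)
    v_rest = 1.0 - v_art - v_vein - spec.v_water
    mu = (
        v_art * mu_art
        + v_vein * mu_vein
        + spec.v_water * chrom.water(wavelength_nm)
        + v_rest * baseline_absorption(wavelength_nm, chrom)
    )
    if mu < 0:
        raise ValueError(
            f"negative absorption in sublayer {spec.name!r}: fractions inconsistent"
        )
    return mu


def skin_absorption(
    sublayer: int | str,
    state: BloodState,
    wavelength_nm: float,
    chrom: ChromophoreLibrary = DEFAULT_CHROMOPHORES,
) -> float:
    """Absorption of skin sublayer ``sublayer`` (index 0..5 or name), mm^-1."""
    if isinstance(sublayer, str):
        sublayer = SKIN_SUBLAYER_NAMES.index(sublayer)
    spec = SKIN_SUBLAYERS[sublayer]
    if spec.name == "stratum_corneum":
        return stratum_corneum_absorption(wavelength_nm, spec, chrom)
    if spec.name == "epidermis":
        return epidermis_absorption(wavelength_nm, spec, chrom)
    return skin_sublayer_absorption(spec, state, wavelength_nm, chrom)


# --- static material table -------------------------------------------------

# Scattering/anisotropy/index constants.  mu_s per wavelength; g and n are
# wavelength-independent.  Skin sublayers share a single mu_s per wavelength
# (the source table omits skin scattering rows); g=0.9, n=1.4 are standard
# dermis values.
_STATIC = {
    # material: ({wavelength: mu_a or None (computed)}, {wavelength: mu_s}, g, n)
    "blood": (None, {465.0: 84.61, 525.0: 59.17, 615.0: 53.00}, 0.995, 1.354),
    "muscle": (
        {465.0: 0.88, 525.0: 1.17, 615.0: 0.22},
        {465.0: 2.41, 525.0: 1.71, 615.0: 1.09},
        0.5,
        1.37,
    ),
    "fat": (
        {465.0: 0.005, 525.0: 0.001, 615.0: 0.0004},
        {465.0: 6.47, 525.0: 5.96, 615.0: 5.35},
        0.75,
        1.44,
    ),
    "bone": (
        {465.0: 0.118, 525.0: 0.118, 615.0: 0.068},
        {465.0: 53.40, 525.0: 44.68, 615.0: 35.41},
        0.92,
        1.37,
    ),
    # Nail coefficients are constant across wavelength in the source table.
    "nail": (
        {465.0: 0.012, 525.0: 0.012, 615.0: 0.012},
        {465.0: 21.0, 525.0: 21.0, 615.0: 21.0},
        0.90,
        1.51,
    ),
}

SKIN_MU_S_MM = {465.0: 30.0, 525.0: 25.0, 615.0: 20.0}
SKIN_G = 0.9
SKIN_N = 1.4

MATERIAL_NAMES = ("ambient", "skin", "nail", "fat", "muscle", "bone", "artery", "vein")


def material_properties(
    material: str,
    state: BloodState,
    wavelength_nm: float,
    sublayer: int | None = None,
    chrom: ChromophoreLibrary = DEFAULT_CHROMOPHORES,
    skin_mu_s: dict[float, float] | None = None,
    skin_g: float = SKIN_G,
    skin_n: float = SKIN_N,
) -> OpticalProperties:
    """Optical properties of one material at one wavelength and blood state.

    ``material`` is one of :data:`MATERIAL_NAMES`; for ``skin`` a sublayer
    index 0..5 is required (the skin label is composite and resolved at run
    time).  ``ambient`` is vacuum-like.
    """
    lam = float(wavelength_nm)
    if material == "ambient":
        # refractive index 1, no interactions; g is irrelevant
        return OpticalProperties(0.0, 0.0, 0.0, 1.0)
    if material == "skin":
        if sublayer is None:
            raise ValueError("skin is composite: a sublayer index is required")
        mu_s_tab = skin_mu_s or SKIN_MU_S_MM
        if lam not in mu_s_tab:
            raise UnknownWavelengthError(f"no skin scattering value at {lam} nm")
        mu_a = skin_absorption(sublayer, state, lam, chrom)
        return OpticalProperties(mu_a, mu_s_tab[lam], skin_g, skin_n)
    if material in ("artery", "vein"):
        mu_a_tab, mu_s_tab, g, n = _STATIC["blood"]
        if lam not in mu_s_tab:
            raise UnknownWavelengthError(f"no blood scattering value at {lam} nm")
        compartment = "arterial" if material == "artery" else "venous"
        mu_a = blood_absorption(state, compartment, lam, chrom)
        return OpticalProperties(mu_a, mu_s_tab[lam], g, n)
    if material in _STATIC:
        mu_a_tab, mu_s_tab, g, n = _STATIC[material]
        if lam not in mu_s_tab:
            raise UnknownWavelengthError(f"no data for {material!r} at {lam} nm")
        return OpticalProperties(mu_a_tab[lam], mu_s_tab[lam], g, n)
    raise UnknownMaterialError(f"unknown material {material!r}")


def material_table(
    state: BloodState,
    wavelength_nm: float,
    chrom: ChromophoreLibrary = DEFAULT_CHROMOPHORES,
) -> pd.DataFrame:
    """All materials (skin expanded to sublayers) at one state and wavelength.

    Columns: material, wavelength_nm, mu_a_mm, mu_s_mm, g, n.
    """
    rows = []
    for mat in MATERIAL_NAMES:
        if mat == "skin":
            for i, sub in enumerate(SKIN_SUBLAYERS):
                p = material_properties("skin", state, wavelength_nm, sublayer=i, chrom=chrom)
                rows.append((f"skin/{sub.name}", wavelength_nm, p.mu_a, p.mu_s, p.g, p.n))
        else:
            p = material_properties(mat, state, wavelength_nm, chrom=chrom)
            rows.append((mat, wavelength_nm, p.mu_a, p.mu_s, p.g, p.n))
    return pd.DataFrame(
        rows, columns=["material", "wavelength_nm", "mu_a_mm", "mu_s_mm", "g", "n"]
    )


def save_material_table(path_or_buf, state: BloodState, wavelength_nm: float) -> None:
    material_table(state, wavelength_nm).to_csv(path_or_buf, index=False)


def load_material_table(path_or_buf) -> pd.DataFrame:
    df = pd.read_csv(path_or_buf)
    required = {"material", "wavelength_nm", "mu_a_mm", "mu_s_mm", "g", "n"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"material table missing columns {sorted(missing)}")
    return df
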