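"""Colour-hexagon model of trichromatic hymenopteran vision.

Reflectance spectra are transduced through three photoreceptor classes (UV,
blue, green), von Kries-adapted to a background (typically green foliage), and
placed in the 2-D hexagon chromaticity space in which Euclidean distance
predicts a bee's ability to discriminate two colours. Field experiments put
the reliable-discrimination threshold at 0.1 hexagon units.

The pipeline is::

    P_i = R_i * sum_l  S(l) * S_i(l) * D(l) * dl        (quantum catch)
    R_i = 1 / sum_l I_B(l) * S_i(l) * D(l) * dl          (von Kries factor)
    E_i = P_i / (P_i + 1)                                (transduction)
    x = (sqrt(3)/2) (E_G - E_UV),  y = E_B - (E_UV + E_G)/2

where S is the stimulus reflectance, S_i the receptor sensitivities, D the
illuminant photon flux and I_B the adaptation-background reflectance. The
background itself maps to the hexagon centre (0, 0).
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from floralsignals.spectra_io import (
    DEFAULT_GRID,
    ReflectanceSpectrum,
    SpectrumSet,
    make_grid,
)

SQRT3_2 = np.sqrt(3.0) / 2.0

#: Hexagon colour-category names, one per 60-degree sector; hue angle measured
#: clockwise from the blue vertex (positive y axis), boundaries at odd
#: multiples of 30 degrees.
SECTOR_NAMES = ("blue", "blue-green", "green", "UV-green", "UV", "UV-blue")
ACHROMATIC = "achromatic-center"

#: lambda_max (nm) of a honeybee-like trichromat, the default receptor set.
DEFAULT_LAMBDA_MAX = (344.0, 436.0, 544.0)

DISCRIMINATION_THRESHOLD = 0.1  # hexagon units
DEFAULT_ACHROMATIC_RADIUS = 0.05  # hexagon units; hue undefined at the centre


class DegenerateAdaptationError(ValueError):
    """Adaptation background yields zero catch in some receptor."""


def _pigment_template(wl: np.ndarray, lambda_max: float, width: float = 0.08) -> np.ndarray:
    """Log-normal visual-pigment absorbance template, peak normalised to 1.

    A generic unimodal curve on log-wavelength; ``width`` is the log-domain
    standard deviation (0.08 gives a realistic ~100 nm FWHM for a 544 nm
    pigment).
    """
    return np.exp(-0.5 * (np.log(wl / lambda_max) / width) ** 2)


@dataclass(frozen=True)
class ReceptorSet:
    """Spectral sensitivities of the UV, blue and green receptor classes."""

    wavelengths: np.ndarray
    sensitivities: np.ndarray  # shape (3, n_wavelengths), rows UV, blue, green
    lambda_max: tuple[float, float, float]

    def __post_init__(self) -> None:
        s = np.asarray(self.sensitivities, dtype=float)
        if s.shape != (3, np.asarray(self.wavelengths).size):
            raise ValueError("sensitivities must be (3, n_wavelengths)")
        if np.any(s < 0):
            raise ValueError("sensitivities must be non-negative")
        if not (self.lambda_max[0] < self.lambda_max[1] < self.lambda_max[2]):
            raise ValueError("lambda_max must be ordered UV < blue < green")
        object.__setattr__(self, "sensitivities", s / s.max(axis=1, keepdims=True))

    @classmethod
    def honeybee_like(
        cls,
        grid: tuple[float, float, float] = DEFAULT_GRID,
        lambda_max: tuple[float, float, float] = DEFAULT_LAMBDA_MAX,
    ) -> "ReceptorSet":
        wl = make_grid(grid)
        sens = np.vstack([_pigment_template(wl, lm) for lm in lambda_max])
        return cls(wavelengths=wl, sensitivities=sens, lambda_max=tuple(lambda_max))

    @classmethod
    def from_csvs(cls, paths: tuple, grid=DEFAULT_GRID) -> "ReceptorSet":
        """Load tabulated sensitivities from three two-column CSVs (UV, blue, green)."""
        wl = make_grid(grid)
        rows, peaks = [], []
        for p in paths:
            df = pd.read_csv(p)
            v = np.interp(wl, df.iloc[:, 0].to_numpy(float), df.iloc[:, 1].to_numpy(float))
            rows.append(v)
            peaks.append(wl[int(np.argmax(v))])
        return cls(wavelengths=wl, sensitivities=np.vstack(rows), lambda_max=tuple(peaks))


@dataclass(frozen=True)
class ColorLocus:
    """A stimulus position in hexagon colour space."""

    x: float
    y: float
    E: tuple[float, float, float]  # receptor excitations (UV, blue, green)
    species: str = ""
    patch: str = ""

    @property
    def norm(self) -> float:
        return float(np.hypot(self.x, self.y))


def _load_two_column(name_or_path, grid) -> np.ndarray:
    wl = make_grid(grid)
    if isinstance(name_or_path, np.ndarray):
        if name_or_path.size != wl.size:
            raise ValueError("array fixture does not match the working grid")
        return np.asarray(name_or_path, dtype=float)
    df = pd.read_csv(name_or_path)
    return np.interp(wl, df.iloc[:, 0].to_numpy(float), df.iloc[:, 1].to_numpy(float))


def _bundled(name: str):
    return importlib.resources.files("floralsignals").joinpath("data", name)


def default_illuminant(grid=DEFAULT_GRID) -> np.ndarray:
    """Standard-daylight (D65-like) relative photon flux on the working grid.

    The bundled table is spectral power; photon flux is proportional to
    power times wavelength.
    """
    wl = make_grid(grid)
    power = _load_two_column(_bundled("illuminant_d65.csv"), grid)
    flux = power * wl
    return flux / flux.max()


def default_background(grid=DEFAULT_GRID) -> np.ndarray:
    """Synthetic green-leaf reflectance used as the von Kries adaptation background."""
    return _load_two_column(_bundled("leaf_background_synthetic.csv"), grid)


class HexagonVisionModel(TransformerMixin, BaseEstimator):
    """Transformer from reflectance spectra to hexagon colour loci.

    Parameters
    ----------
    receptors : ReceptorSet or None
        Receptor spectral sensitivities; default is a honeybee-like log-normal
        template trichromat (lambda_max 344/436/544 nm).
    illuminant : array, path or None
        Relative photon flux on the working grid; default D65-like daylight.
    background : array, path or None
        Adaptation-background reflectance; default a green-leaf curve.
    grid : (lo, hi, step)
        Working wavelength grid in nm.

    After :meth:`fit`, ``von_kries_``` holds the three adaptation factors R_i.
    :meth:`transform` maps an (n_samples, n_wavelengths) reflectance matrix to
    an (n_samples, 2) array of hexagon coordinates; :meth:`excitations` returns
    the (n_samples, 3) receptor excitations.
    """

    def __init__(self, receptors=None, illuminant=None, background=None, grid=DEFAULT_GRID):
        self.receptors = receptors
        self.illuminant = illuminant
        self.background = background
        self.grid = grid

    def fit(self, X=None, y=None):
        wl = make_grid(self.grid)
        rec = self.receptors if self.receptors is not None else ReceptorSet.honeybee_like(self.grid)
        if rec.wavelengths.size != wl.size or not np.allclose(rec.wavelengths, wl):
            raise ValueError("receptor set is not on the working grid")
        illum = (
            default_illuminant(self.grid)
            if self.illuminant is None
            else _load_two_column(self.illuminant, self.grid)
        )
        bg = (
            default_background(self.grid)
            if self.background is None
            else _load_two_column(self.background, self.grid)
        )
        if np.any(illum < 0) or np.any(bg < 0) or np.any(bg > 1):
            raise ValueError("illuminant must be >=0 and background in [0, 1]")
        step = self.grid[2]
        bg_catch = (rec.sensitivities * illum * bg).sum(axis=1) * step
        if np.any(bg_catch <= 0):
            raise DegenerateAdaptationError(
                "background yields zero quantum catch in at least one receptor"
            )
        self.wavelengths_ = wl
        self.receptors_ = rec
        self.illuminant_ = illum
        self.background_ = bg
        self.von_kries_ = 1.0 / bg_catch
        # effective per-wavelength weights so that catches = refl @ weights
        self.weights_ = (rec.sensitivities * illum * step * self.von_kries_[:, None]).T
        return self

    def quantum_catches(self, R: np.ndarray) -> np.ndarray:
        check_is_fitted(self, "weights_")
        R = np.atleast_2d(np.asarray(R, dtype=float))
        if R.shape[1] != self.wavelengths_.size:
            raise ValueError("reflectance matrix not on the working grid")
        if np.any(R < 0):
            raise ValueError("negative reflectance")
        return R @ self.weights_

    def excitations(self, R: np.ndarray) -> np.ndarray:
        P = self.quantum_catches(R)
        return P / (P + 1.0)

    def transform(self, R: np.ndarray) -> np.ndarray:
        E = self.excitations(R)
        return _hexagon_xy(E)

    def loci(self, sset: SpectrumSet) -> pd.DataFrame:
        """Full loci table for a SpectrumSet: excitations, coordinates, sector."""
        specs = list(sset)
        R = np.vstack([s.reflectance for s in specs])
        E = self.excitations(R)
        xy = _hexagon_xy(E)
        sectors = [classify_sector_xy(x, y) for x, y in xy]
        return pd.DataFrame(
            {
                "species": [s.species for s in specs],
                "patch": [s.patch for s in specs],
                "E_UV": E[:, 0],
                "E_B": E[:, 1],
                "E_G": E[:, 2],
                "x": xy[:, 0],
                "y": xy[:, 1],
                "sector": sectors,
            }
        )


def _hexagon_xy(E: np.ndarray) -> np.ndarray:
    E = np.atleast_2d(E)
    x = SQRT3_2 * (E[:, 2] - E[:, 0])
    y = E[:, 1] - (E[:, 0] + E[:, 2]) / 2.0
    return np.column_stack([x, y])


# ---------------------------------------------------------------------------
# thin functional surface

def quantum_catch(
    spec: ReflectanceSpectrum,
    receptors: ReceptorSet | None = None,
    illuminant=None,
    background=None,
    grid=DEFAULT_GRID,
) -> np.ndarray:
    """von Kries-normalised quantum catches P = (P_UV, P_B, P_G) of one spectrum."""
    model = HexagonVisionModel(receptors, illuminant, background, grid).fit()
    return model.quantum_catches(spec.reflectance)[0]


def excitation(P) -> np.ndarray:
    """Receptor excitation E = P / (P + 1); monotone saturation onto [0, 1)."""
    P = np.asarray(P, dtype=float)
    if np.any(P < 0):
        raise ValueError("quantum catch must be non-negative")
    return P / (P + 1.0)


def hexagon_locus(E, species: str = "", patch: str = "") -> ColorLocus:
    """Hexagon coordinates of an excitation triple (UV, blue, green)."""
    E = np.asarray(E, dtype=float)
    if E.shape != (3,):
        raise ValueError("E must be a triple (UV, blue, green)")
    if np.any(E < 0) or np.any(E >= 1):
        raise ValueError("excitations must lie in [0, 1)")
    xy = _hexagon_xy(E[None, :])[0]
    return ColorLocus(x=float(xy[0]), y=float(xy[1]), E=tuple(E), species=species, patch=patch)


def hexagon_distance(a, b) -> float:
    """Euclidean distance in hexagon units; predicts discriminability."""
    ax, ay = (a.x, a.y) if isinstance(a, ColorLocus) else a
    bx, by = (b.x, b.y) if isinstance(b, ColorLocus) else b
    return float(np.hypot(ax - bx, ay - by))


def is_distinguishable(a, b, threshold: float = DISCRIMINATION_THRESHOLD) -> bool:
    """Whether two loci differ by strictly more than the behavioural threshold."""
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    return hexagon_distance(a, b) > threshold


def classify_sector_xy(
    x: float, y: float, achromatic_radius: float = DEFAULT_ACHROMATIC_RADIUS
) -> str:
    """Colour-category name of a hexagon position.

    Loci within ``achromatic_radius`` of the centre are 'achromatic-center';
    otherwise the hue angle (clockwise from the blue vertex on +y) falls in one
    of six 60-degree sectors with centres blue 0, blue-green 60, green 120,
    UV-green 180, UV 240, UV-blue 300 degrees.
    """
    if np.hypot(x, y) < achromatic_radius:
        return ACHROMATIC
    theta = np.degrees(np.arctan2(x, y)) % 360.0
    # half-open 60-degree bins with boundaries at odd multiples of 30 degrees
    return SECTOR_NAMES[int(np.floor((theta + 30.0) / 60.0)) % 6]


def classify_sector(
    locus: ColorLocus, achromatic_radius: float = DEFAULT_ACHROMATIC_RADIUS
) -> str:
    return classify_sector_xy(locus.x, locus.y, achromatic_radius)
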