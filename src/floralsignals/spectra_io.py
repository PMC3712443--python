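"""Reading, validation, resampling and aggregation of floral reflectance spectra.

Spectra are wavelength/reflectance tables measured between the UV (300 nm) and
red (700 nm) ends of the hymenopteran-relevant range. All downstream colour
modelling runs on a uniform working grid, by default 300-700 nm at 1 nm steps.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

DEFAULT_GRID = (300.0, 700.0, 1.0)

# Instrument noise around the white standard commonly pushes reflectance a few
# percent above 1; values in (1, 1.05] are clipped, larger ones rejected.
CLIP_CEILING = 1.05


class SpectrumFormatError(ValueError):
    """Input file lacks resolvable wavelength/reflectance columns."""


class SpectrumDataError(ValueError):
    """Spectrum values violate an invariant (monotonicity, range)."""


class CoverageError(ValueError):
    """Spectrum does not span the requested resampling grid."""


@dataclass(frozen=True)
class ReflectanceSpectrum:
    """A single reflectance measurement of one floral patch.

    ``wavelengths`` are strictly increasing nanometres; ``reflectance`` is a
    unitless fraction in [0, 1] at each wavelength.
    """

    wavelengths: np.ndarray
    reflectance: np.ndarray
    species: str = ""
    patch: str = "labellum"
    replicate_id: str = "1"
    n_replicates: int = 1

    def __post_init__(self) -> None:
        wl = np.asarray(self.wavelengths, dtype=float)
        refl = np.asarray(self.reflectance, dtype=float)
        if wl.ndim != 1 or refl.shape != wl.shape:
            raise SpectrumDataError("wavelengths and reflectance must be 1-D and equal length")
        if wl.size < 2:
            raise SpectrumDataError("a spectrum needs at least two samples")
        if np.any(np.diff(wl) <= 0):
            raise SpectrumDataError("wavelengths must be strictly increasing")
        if np.any(refl < 0):
            raise SpectrumDataError("negative reflectance")
        if np.any(refl > CLIP_CEILING):
            raise SpectrumDataError(
                f"reflectance above {CLIP_CEILING} (not a white-standard artefact)"
            )
        refl = np.minimum(refl, 1.0)
        object.__setattr__(self, "wavelengths", wl)
        object.__setattr__(self, "reflectance", refl)

    @property
    def key(self) -> tuple[str, str, str]:
        return (self.species, self.patch, self.replicate_id)


@dataclass
class SpectrumSet:
    """A collection of spectra from one site/habitat.

    (species, patch, replicate_id) triples must be unique.
    """

    spectra: list[ReflectanceSpectrum] = field(default_factory=list)
    site: str = ""
    habitat: str = ""

    def __post_init__(self) -> None:
        keys = [s.key for s in self.spectra]
        if len(set(keys)) != len(keys):
            dupes = {k for k in keys if keys.count(k) > 1}
            raise SpectrumDataError(f"duplicate (species, patch, replicate) triples: {dupes}")

    def __len__(self) -> int:
        return len(self.spectra)

    def __iter__(self):
        return iter(self.spectra)


_DEFAULT_DIALECT = {
    "wavelength": "wavelength_nm",
    "reflectance": "reflectance",
    "species": "species",
    "patch": "patch",
    "replicate": "replicate",
    "site": "site",
    "habitat": "habitat",
    "percent": False,
}


def read_spectra(path, dialect: dict | None = None) -> SpectrumSet:
    """Read a CSV of reflectance spectra into a validated :class:`SpectrumSet`.

    ``dialect`` maps logical column names (wavelength, reflectance, species,
    patch, replicate, site, habitat) to the file's actual column names and may
    set ``percent=True`` when reflectance is recorded in percent (0-100).
    Metadata columns are optional; a bare two-column file reads as one spectrum.
    """
    d = dict(_DEFAULT_DIALECT)
    if dialect:
        d.update(dialect)
    df = pd.read_csv(path)
    for logical in ("wavelength", "reflectance"):
        if d[logical] not in df.columns:
            raise SpectrumFormatError(
                f"column {d[logical]!r} (for {logical}) not found in {path}"
            )
    scale = 0.01 if d["percent"] else 1.0

    meta_cols = [d[k] for k in ("species", "patch", "replicate") if d[k] in df.columns]
    site = str(df[d["site"]].iloc[0]) if d["site"] in df.columns else ""
    habitat = str(df[d["habitat"]].iloc[0]) if d["habitat"] in df.columns else ""

    spectra = []
    groups = df.groupby(meta_cols, sort=True) if meta_cols else [((), df)]
    for key, sub in groups:
        if not isinstance(key, tuple):
            key = (key,)
        meta = dict(zip(meta_cols, map(str, key)))
        wl = sub[d["wavelength"]].to_numpy(dtype=float)
        refl = sub[d["reflectance"]].to_numpy(dtype=float) * scale
        if np.any(np.diff(wl) <= 0):
            raise SpectrumDataError(
                f"wavelengths not strictly increasing for {meta or 'spectrum'}"
            )
        spectra.append(
            ReflectanceSpectrum(
                wavelengths=wl,
                reflectance=refl,
                species=meta.get(d["species"], ""),
                patch=meta.get(d["patch"], "labellum"),
                replicate_id=meta.get(d["replicate"], "1"),
            )
        )
    return SpectrumSet(spectra=spectra, site=site, habitat=habitat)


def make_grid(grid: tuple[float, float, float] = DEFAULT_GRID) -> np.ndarray:
    lo, hi, step = grid
    n = int(round((hi - lo) / step))
    return lo + step * np.arange(n + 1)


def resample(
    spec: ReflectanceSpectrum, grid: tuple[float, float, float] = DEFAULT_GRID
) -> ReflectanceSpectrum:
    """Linearly interpolate a spectrum onto a uniform grid (no extrapolation).

    Idempotent on data already on the target grid.
    """
    wl = make_grid(grid)
    if spec.wavelengths[0] > wl[0] + 1e-9 or spec.wavelengths[-1] < wl[-1] - 1e-9:
        raise CoverageError(
            f"spectrum spans [{spec.wavelengths[0]:g}, {spec.wavelengths[-1]:g}] nm, "
            f"grid requires [{wl[0]:g}, {wl[-1]:g}] nm"
        )
    refl = np.interp(wl, spec.wavelengths, spec.reflectance)
    return replace(spec, wavelengths=wl, reflectance=refl)


def aggregate_replicates(sset: SpectrumSet) -> SpectrumSet:
    """Average replicate spectra per (species, patch).

    All spectra must share a common wavelength grid (resample first). Averaging
    happens on the spectra themselves, before the nonlinear transduction of the
    colour model, so each colour locus remains a function of one mean spectrum.
    The replicate count is recorded on the output spectrum.
    """
    by_pair: dict[tuple[str, str], list[ReflectanceSpectrum]] = {}
    for s in sset:
        by_pair.setdefault((s.species, s.patch), []).append(s)
    out = []
    for (species, patch), reps in sorted(by_pair.items()):
        wl0 = reps[0].wavelengths
        for r in reps[1:]:
            if r.wavelengths.shape != wl0.shape or not np.allclose(r.wavelengths, wl0):
                raise SpectrumDataError(
                    f"mixed wavelength grids for ({species}, {patch}); resample first"
                )
        mean = np.mean([r.reflectance for r in reps], axis=0)
        out.append(
            ReflectanceSpectrum(
                wavelengths=wl0,
                reflectance=mean,
                species=species,
                patch=patch,
                replicate_id="mean",
                n_replicates=len(reps),
            )
        )
    return SpectrumSet(spectra=out, site=sset.site, habitat=sset.habitat)


def to_frame(sset: SpectrumSet) -> pd.DataFrame:
    """Tidy long-format table of a SpectrumSet (one row per wavelength sample)."""
    frames = []
    for s in sset:
        frames.append(
            pd.DataFrame(
                {
                    "species": s.species,
                    "patch": s.patch,
                    "replicate": s.replicate_id,
                    "n_replicates": s.n_replicates,
                    "wavelength_nm": s.wavelengths,
                    "reflectance": s.reflectance,
                }
            )
        )
    df = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame()
    if len(df):
        df.insert(0, "site", sset.site)
        df.insert(1, "habitat", sset.habitat)
    return df


def write_spectra(sset: SpectrumSet, path) -> None:
    to_frame(sset).to_csv(path, index=False)
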