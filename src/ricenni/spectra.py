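"""Canopy spectra: preprocessing, standard-spectrum selection and transforms.

A *standard spectrum* is the per-period (sampling day) canopy reflectance of
samples at near-optimal nitrogen status (0.99 < NNI < 1.01). The remaining
samples of the same period are expressed relative to it through one of four
representations:

    original        Rc
    log             ln Rc
    difference      Rc − Rnc
    logdifference   ln Rc − ln Rnc

where Rc is a sample's reflectance and Rnc the period's standard spectrum.
Reflectance is stored as a fraction in (0, 1]; logs are natural.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter1d

logger = logging.getLogger(__name__)

__all__ = [
    "TRANSFORM_KINDS",
    "SpectrumSet",
    "StandardSpectrum",
    "TransformedSpectra",
    "period_labels",
    "resample_to_1nm",
    "gaussian_denoise",
    "select_standard_spectrum",
    "select_standard_spectra",
    "apply_transform",
    "read_spectra_csv",
    "write_spectra_csv",
]

TRANSFORM_KINDS = ("original", "log", "difference", "logdifference")


def period_labels(agronomy: pd.DataFrame) -> np.ndarray:
    """Period label (experiment + sampling day) per agronomy row."""
    return (agronomy["experiment"].astype(str) + ":d"
            + agronomy["day"].astype(str)).to_numpy()


@dataclass
class SpectrumSet:
    """Wavelength grid plus a (samples × bands) reflectance matrix.

    ``periods`` holds one label per sample identifying its sampling period
    (standard spectra are selected, and differences taken, within a period).
    """

    wavelengths: np.ndarray
    reflectance: np.ndarray
    sample_ids: list
    periods: np.ndarray

    def __post_init__(self) -> None:
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        self.reflectance = np.asarray(self.reflectance, dtype=float)
        self.periods = np.asarray(self.periods)
        if np.any(np.diff(self.wavelengths) <= 0):
            raise ValueError("wavelengths must be strictly increasing")
        n, m = self.reflectance.shape
        if m != self.wavelengths.size:
            raise ValueError("reflectance columns must match wavelength count")
        if n != len(self.sample_ids) or n != self.periods.size:
            raise ValueError("sample_ids/periods must match reflectance rows")

    def row(self, sample_id) -> np.ndarray:
        return self.reflectance[self.sample_ids.index(sample_id)]

    def concat(self, other: "SpectrumSet") -> "SpectrumSet":
        if not np.array_equal(self.wavelengths, other.wavelengths):
            raise ValueError("wavelength grids differ")
        return SpectrumSet(self.wavelengths,
                           np.vstack([self.reflectance, other.reflectance]),
                           self.sample_ids + other.sample_ids,
                           np.concatenate([self.periods, other.periods]))


@dataclass
class StandardSpectrum:
    """Per-period standard spectrum (mean over qualifying NNI≈1 samples)."""

    period: object
    reflectance: np.ndarray
    n_contributing: int
    contributing_ids: tuple = ()
    fallback_used: bool = False

    def __post_init__(self) -> None:
        if self.n_contributing < 1:
            raise ValueError("a standard spectrum needs >= 1 contributing sample")


@dataclass
class TransformedSpectra:
    """One of the four spectral representations, same shape as its source set."""

    kind: str
    wavelengths: np.ndarray
    values: np.ndarray
    sample_ids: list
    periods: np.ndarray
    provenance: dict = field(default_factory=dict)  # period -> standard ids

    def __post_init__(self) -> None:
        if self.kind not in TRANSFORM_KINDS:
            raise ValueError(f"unknown transform kind {self.kind!r}")


def resample_to_1nm(spectra: SpectrumSet, target_min: float = 400.0,
                    target_max: float = 1000.0) -> SpectrumSet:
    """Piecewise-linear resampling onto the integer-nanometre grid.

    The target range must lie inside the native range; no extrapolation.
    """
    wl = spectra.wavelengths
    if target_min < wl[0] or target_max > wl[-1]:
        raise ValueError(
            f"target range [{target_min}, {target_max}] outside native "
            f"range [{wl[0]}, {wl[-1]}]")
    grid = np.arange(np.ceil(target_min), np.floor(target_max) + 0.5)
    out = np.empty((spectra.reflectance.shape[0], grid.size))
    for i, row in enumerate(spectra.reflectance):
        out[i] = np.interp(grid, wl, row)
    return replace(spectra, wavelengths=grid, reflectance=out)


def gaussian_denoise(spectra: SpectrumSet, sigma: float = 2.0) -> SpectrumSet:
    """Gaussian smoothing along wavelength (sigma in grid steps ≈ nm on a 1-nm grid).

    Normalized kernel truncated at 4σ, reflect boundary. ``sigma=0`` is the
    identity.
    """
    if sigma < 0:
        raise ValueError("sigma must be non-negative")
    if sigma == 0:
        return replace(spectra, reflectance=spectra.reflectance.copy())
    smoothed = gaussian_filter1d(spectra.reflectance, sigma=sigma, axis=1,
                                 mode="reflect", truncate=4.0)
    return replace(spectra, reflectance=smoothed)


def select_standard_spectrum(spectra: SpectrumSet, nni: pd.DataFrame,
                             period, window: float = 0.01) -> StandardSpectrum:
    """Standard spectrum of one period: mean reflectance of NNI≈1 samples.

    Samples of the period with ``|NNI − 1| < window`` (open interval) qualify;
    one qualifier → its spectrum, several → their band-wise mean. If none
    qualifies the spectrum of the sample nearest NNI=1 is used and flagged via
    ``fallback_used`` with a warning in the log.

    ``nni`` is a table with columns ``sample_id`` and ``nni``.
    """
    mask = spectra.periods == period
    if not mask.any():
        raise ValueError(f"no samples for period {period!r}")
    ids = [sid for sid, m in zip(spectra.sample_ids, mask) if m]
    nni_map = dict(zip(nni["sample_id"], nni["nni"]))
    missing = [sid for sid in ids if sid not in nni_map]
    if missing:
        raise ValueError(f"samples without NNI record: {missing[:5]}")
    vals = np.array([nni_map[sid] for sid in ids])
    qualify = np.abs(vals - 1.0) < window
    rows = spectra.reflectance[mask]
    if qualify.any():
        chosen = [sid for sid, q in zip(ids, qualify) if q]
        spec = rows[qualify].mean(axis=0)
        return StandardSpectrum(period, spec, int(qualify.sum()),
                                tuple(chosen), fallback_used=False)
    k = int(np.argmin(np.abs(vals - 1.0)))
    logger.warning("period %r has no sample with |NNI-1| < %g; falling back to "
                   "nearest sample %r (NNI=%.3f)", period, window, ids[k], vals[k])
    return StandardSpectrum(period, rows[k].copy(), 1, (ids[k],),
                            fallback_used=True)


def select_standard_spectra(spectra: SpectrumSet, nni: pd.DataFrame,
                            window: float = 0.01) -> dict:
    """Standard spectrum for every period present in the set."""
    return {p: select_standard_spectrum(spectra, nni, p, window)
            for p in pd.unique(spectra.periods)}


def apply_transform(spectra: SpectrumSet, standards: dict | None,
                    kind: str) -> TransformedSpectra:
    """Apply one of the four spectral representations.

    ``standards`` maps period → :class:`StandardSpectrum` and is required for
    the difference kinds. Log kinds demand strictly positive reflectance in
    both the samples and the standards; non-positive values raise rather than
    being clipped.
    """
    if kind not in TRANSFORM_KINDS:
        raise ValueError(f"unknown transform kind {kind!r}")
    r = spectra.reflectance
    provenance: dict = {}
    if kind in ("log", "logdifference") and np.any(r <= 0):
        raise ValueError("log transforms require strictly positive reflectance")
    if kind == "original":
        values = r.copy()
    elif kind == "log":
        values = np.log(r)
    else:
        if standards is None:
            raise ValueError(f"{kind} transform requires per-period standards")
        std = np.empty_like(r)
        for i, period in enumerate(spectra.periods):
            if period not in standards:
                raise ValueError(f"missing standard spectrum for period {period!r}")
            std[i] = standards[period].reflectance
        provenance = {p: standards[p].contributing_ids
                      for p in pd.unique(spectra.periods)}
        if kind == "difference":
            values = r - std
        else:  # logdifference
            if np.any(std <= 0):
                raise ValueError("log transforms require positive standard spectra")
            values = np.log(r) - np.log(std)
    return TransformedSpectra(kind=kind, wavelengths=spectra.wavelengths.copy(),
                              values=values, sample_ids=list(spectra.sample_ids),
                              periods=spectra.periods.copy(),
                              provenance=provenance)


def write_spectra_csv(path, spectra: SpectrumSet | TransformedSpectra) -> None:
    """CSV dialect: ``sample_id, period, wl_400, …, wl_1000`` (one row per sample)."""
    mat = spectra.reflectance if isinstance(spectra, SpectrumSet) else spectra.values
    cols = [_wl_name(w) for w in spectra.wavelengths]
    df = pd.DataFrame(mat, columns=cols)
    df.insert(0, "period", spectra.periods)
    df.insert(0, "sample_id", spectra.sample_ids)
    df.to_csv(path, index=False)


def _wl_name(w: float) -> str:
    return f"wl_{int(round(w))}" if float(w).is_integer() else f"wl_{w:g}"


def read_spectra_csv(path) -> SpectrumSet:
    """Read the spectra CSV dialect written by :func:`write_spectra_csv`.

    A missing ``period`` column is tolerated (all samples get one period).
    """
    df = pd.read_csv(path)
    wl_cols = [c for c in df.columns if c.startswith("wl_")]
    if "sample_id" not in df.columns or not wl_cols:
        raise ValueError("spectra CSV needs a sample_id column and wl_* columns")
    wl = np.array([float(c[3:]) for c in wl_cols])
    order = np.argsort(wl)
    refl = df[wl_cols].to_numpy(float)[:, order]
    periods = (df["period"].to_numpy() if "period" in df.columns
               else np.array(["all"] * len(df)))
    return SpectrumSet(wavelengths=wl[order], reflectance=refl,
                       sample_ids=list(df["sample_id"]), periods=periods)
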