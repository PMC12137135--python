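"""Two-wavelength spectral unmixing of photoacoustic frames into StO2/HbT maps.

Photoacoustic amplitude at wavelength lambda is proportional to the local
optical absorption, which for blood is a linear combination of the
oxy-/deoxyhemoglobin extinction spectra:

    m(lambda) = eps_HbO(lambda) * c_HbO + eps_HbD(lambda) * c_HbD

Per pixel the chromophore concentrations are recovered by non-negative least
squares on this system; oxygen saturation is StO2 = 100 * c_HbO / (c_HbO +
c_HbD) and total hemoglobin HbT = c_HbO + c_HbD (arbitrary units, since the
photoacoustic amplitudes are uncalibrated).  Pixels whose HbT falls below a
noise floor estimated from signal-free corner patches are zeroed and masked.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import nnls

from .exceptions import ConfigurationError, GeometryError, ValidationError

__all__ = [
    "ExtinctionTable",
    "FramePair",
    "FrameStack",
    "OximetryMaps",
    "load_extinction_table",
    "default_extinction_table",
    "unmix_pixel",
    "compute_oximetry",
    "compute_oximetry_stack",
    "estimate_noise_floor",
    "apply_threshold",
]


@dataclass(frozen=True)
class ExtinctionTable:
    """Molar extinction coefficients of HbO/HbD at the acquisition wavelengths.

    Units are cm^-1 M^-1 as tabulated in the standard hemoglobin compilations;
    because photoacoustic amplitudes are in arbitrary units only the ratios
    matter and the unmixed concentrations (hence HbT) are arbitrary-unit.
    """

    wavelengths_nm: tuple[float, ...]
    eps_hbo: tuple[float, ...]
    eps_hbd: tuple[float, ...]

    def __post_init__(self) -> None:
        wl = np.asarray(self.wavelengths_nm, dtype=float)
        eo = np.asarray(self.eps_hbo, dtype=float)
        ed = np.asarray(self.eps_hbd, dtype=float)
        if wl.size < 2 or eo.size != wl.size or ed.size != wl.size:
            raise ValidationError(
                "need >= 2 wavelengths with matching coefficient lists"
            )
        if not np.all(np.diff(wl) > 0):
            raise ValidationError("wavelengths must be strictly increasing")
        if not (np.all(eo > 0) and np.all(ed > 0)):
            raise ValidationError("extinction coefficients must be positive")
        # NIR sign structure that keeps the 2x2 system well conditioned:
        # deoxyhemoglobin dominates at 750 nm, oxyhemoglobin at 850 nm.
        for nm, hbd_dominant in ((750.0, True), (850.0, False)):
            idx = np.nonzero(wl == nm)[0]
            if idx.size:
                i = int(idx[0])
                if hbd_dominant and not ed[i] > eo[i]:
                    raise ValidationError("expected eps_hbd > eps_hbo at 750 nm")
                if not hbd_dominant and not eo[i] > ed[i]:
                    raise ValidationError("expected eps_hbo > eps_hbd at 850 nm")

    @property
    def matrix(self) -> np.ndarray:
        """System matrix E with one row per wavelength, columns (HbO, HbD)."""
        return np.column_stack(
            [np.asarray(self.eps_hbo, float), np.asarray(self.eps_hbd, float)]
        )


@dataclass(frozen=True)
class FramePair:
    """Co-registered 750/850 nm photoacoustic images at one time point."""

    img_750: np.ndarray
    img_850: np.ndarray
    t: float

    def __post_init__(self) -> None:
        a = np.asarray(self.img_750)
        b = np.asarray(self.img_850)
        if a.shape != b.shape:
            raise ValidationError("wavelength channels must share a shape")
        if not np.isfinite(self.t) or self.t < 0:
            raise ValidationError("acquisition time must be finite and >= 0")


@dataclass(frozen=True)
class FrameStack:
    """Time-ordered sequence of frame pairs from one recording."""

    frames: tuple[FramePair, ...]
    pixel_spacing_mm: tuple[float, float] = (0.1, 0.1)

    def __post_init__(self) -> None:
        t = np.array([f.t for f in self.frames])
        if t.size and not np.all(np.diff(t) > 0):
            raise ValidationError("frame times must be strictly increasing")

    @property
    def times(self) -> np.ndarray:
        return np.array([f.t for f in self.frames], dtype=float)

    def __len__(self) -> int:
        return len(self.frames)


@dataclass
class OximetryMaps:
    """Unmixed StO2 (%) and HbT (a.u.) maps with a validity mask.

    Invalid pixels (below the noise floor, or zero signal) store 0 in both
    channels with ``mask`` false; the mask, not the 0, is the authoritative
    no-signal marker so that downstream code never confuses true 0 %
    saturation with absent signal.
    """

    sto2: np.ndarray
    hbt: np.ndarray
    mask: np.ndarray
    t: float = 0.0


_HEMOGLOBIN_CSV = "hemoglobin_extinction.csv"


def load_extinction_table(
    source, wavelengths_nm: Sequence[float] = (750.0, 850.0)
) -> ExtinctionTable:
    """Load extinction coefficients from a CSV with columns
    ``wavelength_nm,eps_hbo,eps_hbd`` and select the acquisition wavelengths.

    Raises
    ------
    ConfigurationError
        If a requested wavelength has no row.
    ValidationError
        If a selected coefficient is non-positive.
    """
    df = pd.read_csv(source)
    required = {"wavelength_nm", "eps_hbo", "eps_hbd"}
    if not required.issubset(df.columns):
        raise ConfigurationError(
            f"extinction table needs columns {sorted(required)}"
        )
    rows = []
    for nm in sorted(float(w) for w in wavelengths_nm):
        hit = df[df["wavelength_nm"] == nm]
        if hit.empty:
            raise ConfigurationError(f"no extinction row at {nm:g} nm")
        rows.append(hit.iloc[0])
    return ExtinctionTable(
        wavelengths_nm=tuple(float(r["wavelength_nm"]) for r in rows),
        eps_hbo=tuple(float(r["eps_hbo"]) for r in rows),
        eps_hbd=tuple(float(r["eps_hbd"]) for r in rows),
    )


def default_extinction_table(
    wavelengths_nm: Sequence[float] = (750.0, 850.0),
) -> ExtinctionTable:
    """Packaged literature extinction values at the standard NIR wavelengths."""
    ref = resources.files("paoximetry.data").joinpath(_HEMOGLOBIN_CSV)
    with ref.open("r") as fh:
        return load_extinction_table(fh, wavelengths_nm)


def _unmix_arrays(
    m: np.ndarray, ext: ExtinctionTable
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized exact non-negative least squares for the 2x2 system.

    ``m`` has shape (..., 2) ordered like ``ext.wavelengths_nm``.  The
    unconstrained 2x2 solution is returned when it is already non-negative;
    otherwise the minimizer lies on an axis of the feasible quadrant, so the
    two single-chromophore projections (and the origin) are compared by
    residual and the best is taken.
    """
    E = ext.matrix
    if E.shape[0] != 2:
        raise ValidationError("closed form requires exactly 2 wavelengths")
    det = E[0, 0] * E[1, 1] - E[0, 1] * E[1, 0]
    m0, m1 = m[..., 0], m[..., 1]
    # unconstrained solve via explicit 2x2 inverse
    c0 = (E[1, 1] * m0 - E[0, 1] * m1) / det
    c1 = (-E[1, 0] * m0 + E[0, 0] * m1) / det
    interior = (c0 >= 0) & (c1 >= 0)

    def _axis_fit(col: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        a = np.maximum(0.0, (col[0] * m0 + col[1] * m1) / (col @ col))
        r = (col[0] * a - m0) ** 2 + (col[1] * a - m1) ** 2
        return a, r

    a_hbo, r_hbo = _axis_fit(E[:, 0])
    a_hbd, r_hbd = _axis_fit(E[:, 1])
    use_hbo = r_hbo <= r_hbd
    edge0 = np.where(use_hbo, a_hbo, 0.0)
    edge1 = np.where(use_hbo, 0.0, a_hbd)
    out0 = np.where(interior, c0, edge0)
    out1 = np.where(interior, c1, edge1)
    return out0, out1


def unmix_pixel(
    m: Sequence[float], ext: ExtinctionTable
) -> tuple[float, float]:
    """Non-negative least-squares unmixing of one measurement pair.

    Solves ``min ||E c - m||_2 s.t. c >= 0`` for c = (c_HbO, c_HbD).  For the
    two-wavelength system the solution is computed in closed form
    (unconstrained solve, then active-set clamp); with more wavelengths an
    iterative NNLS solver is used.
    """
    mv = np.asarray(m, dtype=float)
    if not np.all(np.isfinite(mv)):
        raise ValidationError("measurement must be finite")
    if mv.shape != (len(ext.wavelengths_nm),):
        raise ValidationError("measurement length must match wavelength count")
    if mv.size == 2:
        c0, c1 = _unmix_arrays(mv[None, :], ext)
        return float(c0[0]), float(c1[0])
    sol, _ = nnls(ext.matrix, mv)
    return float(sol[0]), float(sol[1])


def _oximetry_from_concentrations(
    c_hbo: np.ndarray, c_hbd: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    hbt = c_hbo + c_hbd
    mask = hbt > 0
    sto2 = np.zeros_like(hbt)
    np.divide(100.0 * c_hbo, hbt, out=sto2, where=mask)
    return sto2, hbt, mask


def compute_oximetry(pair: FramePair, ext: ExtinctionTable) -> OximetryMaps:
    """Unmix one frame pair into per-pixel StO2 (%) and HbT (a.u.) maps.

    Zero-signal pixels (HbT = 0) are stored as 0 and masked false.
    """
    m = np.stack(
        [np.asarray(pair.img_750, float), np.asarray(pair.img_850, float)],
        axis=-1,
    )
    c_hbo, c_hbd = _unmix_arrays(m, ext)
    sto2, hbt, mask = _oximetry_from_concentrations(c_hbo, c_hbd)
    return OximetryMaps(sto2=sto2, hbt=hbt, mask=mask, t=pair.t)


def compute_oximetry_stack(
    stack: FrameStack, ext: ExtinctionTable
) -> list[OximetryMaps]:
    """Unmix a whole recording at once (vectorized over frames)."""
    if not len(stack):
        return []
    m = np.stack(
        [
            np.stack([np.asarray(f.img_750, float) for f in stack.frames]),
            np.stack([np.asarray(f.img_850, float) for f in stack.frames]),
        ],
        axis=-1,
    )
    c_hbo, c_hbd = _unmix_arrays(m, ext)
    sto2, hbt, mask = _oximetry_from_concentrations(c_hbo, c_hbd)
    return [
        OximetryMaps(sto2=sto2[i], hbt=hbt[i], mask=mask[i], t=f.t)
        for i, f in enumerate(stack.frames)
    ]


def estimate_noise_floor(
    hbt_maps: Sequence[np.ndarray] | np.ndarray, patch_size: int = 20
) -> float:
    """Noise floor for HbT: mean over the two top-corner patches of every frame.

    The top corners of a B-scan lie above the tissue surface and contain no
    hemoglobin signal; their pooled mean HbT estimates the noise level of the
    recording.  One threshold is returned per recording (patches pooled over
    both corners and all frames).
    """
    maps = np.asarray(hbt_maps, dtype=float)
    if maps.ndim == 2:
        maps = maps[None]
    h, w = maps.shape[-2:]
    if h < patch_size or w < 2 * patch_size:
        raise GeometryError(
            f"frames of {h}x{w} px cannot hold two {patch_size}x{patch_size} "
            "top-corner patches"
        )
    left = maps[..., :patch_size, :patch_size]
    right = maps[..., :patch_size, w - patch_size :]
    return float(np.concatenate([left.ravel(), right.ravel()]).mean())


def apply_threshold(maps: OximetryMaps, threshold: float) -> OximetryMaps:
    """Zero and mask every pixel whose HbT is below the noise threshold."""
    if threshold < 0:
        raise ValidationError("threshold must be >= 0")
    keep = (maps.hbt >= threshold) & (maps.hbt > 0)
    return OximetryMaps(
        sto2=np.where(keep, maps.sto2, 0.0),
        hbt=np.where(keep, maps.hbt, 0.0),
        mask=keep,
        t=maps.t,
    )
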