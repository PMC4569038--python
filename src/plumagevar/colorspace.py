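"""Tetrahedral color space for tetrachromat (avian) vision.

A reflectance spectrum is reduced to the relative quantum catches
``(u, s, m, l)`` of the four single-cone classes (UV/VS, short, medium,
long). Because the catches are normalized to sum to one, a color is a
point in the 3-simplex, drawn as a regular tetrahedron with the
achromatic point (equal stimulation) at the origin and the four cone
classes at the vertices. Hue is the direction of the color vector
(azimuth ``theta``, elevation ``phi``), chroma is its length ``r``, and
``r_A = r / r_max`` expresses chroma relative to the maximum attainable
in that hue direction (the tetrahedron boundary). Average brightness is
the mean percent reflectance over the 300-700 nm window and is
independent of the chromatic coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

__all__ = [
    "ConeSensitivitySet",
    "TetraColorMapper",
    "average_replicates",
    "brightness",
    "cone_stimulation",
    "repeatability_icc",
    "tetra_metrics",
    "TETRA_VERTICES",
]

# Wavelength window (nm) over which brightness and catches are evaluated.
WINDOW = (300.0, 700.0)

# Vertices of the color tetrahedron in the (x, y, z) frame used below,
# in cone order u, s, m, l. Each vertex is at distance 0.75 from the
# achromatic origin.
TETRA_VERTICES = np.array(
    [
        [0.0, 0.0, 0.75],
        [-np.sqrt(3.0 / 2.0) / 2.0, -1.0 / (2.0 * np.sqrt(2.0)), -0.25],
        [0.0, 2.0 / (2.0 * np.sqrt(2.0)), -0.25],
        [np.sqrt(3.0 / 2.0) / 2.0, -1.0 / (2.0 * np.sqrt(2.0)), -0.25],
    ]
)

# The 4 faces, each opposite one vertex: (normal, offset) with normal
# pointing away from the origin, precomputed lazily.
_FACES: list[tuple[np.ndarray, float]] | None = None


def _faces() -> list[tuple[np.ndarray, float]]:
    global _FACES
    if _FACES is None:
        faces = []
        for opposite in range(4):
            pts = TETRA_VERTICES[[i for i in range(4) if i != opposite]]
            n = np.cross(pts[1] - pts[0], pts[2] - pts[0])
            d = float(n @ pts[0])
            if d < 0:  # orient outward
                n, d = -n, -d
            faces.append((n, d))
        _FACES = faces
    return _FACES


@dataclass
class ConeSensitivitySet:
    """Gaussian cone sensitivity templates on a wavelength grid.

    The exact templates used for a given analysis must be reported with
    the results; the defaults are generic violet-sensitive songbird-like
    peaks. Curves are un-normalized Gaussians; normalization cancels in
    the relative catches.
    """

    peaks: tuple[float, float, float, float] = (372.0, 456.0, 544.0, 609.0)
    bandwidths: tuple[float, float, float, float] = (50.0, 50.0, 50.0, 50.0)
    labels: tuple[str, str, str, str] = ("u", "s", "m", "l")

    def curves(self, wavelengths: np.ndarray) -> np.ndarray:
        """Return a (4, n_wavelengths) array of sensitivities."""
        wl = np.asarray(wavelengths, dtype=float)
        out = np.empty((4, wl.size))
        for i, (p, b) in enumerate(zip(self.peaks, self.bandwidths)):
            if b <= 0:
                raise ValueError("cone bandwidths must be positive")
            out[i] = np.exp(-0.5 * ((wl - p) / b) ** 2)
        return out


def _check_grid(wavelengths: np.ndarray) -> np.ndarray:
    wl = np.asarray(wavelengths, dtype=float)
    if wl.ndim != 1 or wl.size < 2:
        raise ValueError("wavelength grid must be a 1-D array of length >= 2")
    if np.any(np.diff(wl) <= 0):
        raise ValueError("wavelength grid must be strictly increasing")
    return wl


def average_replicates(reflectance: np.ndarray | pd.DataFrame) -> np.ndarray:
    """Pointwise mean spectrum over replicate scans.

    Parameters
    ----------
    reflectance : array (n_wavelengths, n_replicates) or DataFrame
        Replicate scans on a common wavelength grid, one column each.
    """
    arr = np.asarray(reflectance, dtype=float)
    if arr.ndim == 1:
        arr = arr[:, None]
    if arr.ndim != 2 or arr.shape[1] < 1:
        raise ValueError("expected a (n_wavelengths, n_replicates) array")
    if np.any(arr < 0):
        raise ValueError("reflectance must be nonnegative")
    return arr.mean(axis=1)


def cone_stimulation(
    wavelengths: np.ndarray,
    reflectance: np.ndarray,
    cones: ConeSensitivitySet | None = None,
) -> np.ndarray:
    """Relative quantum catches (u, s, m, l) under an ideal (uniform) illuminant.

    The quantum catch of cone i is the trapezoidal integral of
    ``R(lambda) * C_i(lambda)`` on the native grid; catches are returned
    normalized to sum to one.
    """
    wl = _check_grid(wavelengths)
    refl = np.asarray(reflectance, dtype=float)
    if refl.shape != wl.shape:
        raise ValueError("reflectance and wavelength grids differ in length")
    if np.any(refl < 0):
        raise ValueError("reflectance must be nonnegative")
    cones = cones or ConeSensitivitySet()
    curves = cones.curves(wl)
    catches = np.trapezoid(curves * refl[None, :], wl, axis=1)
    total = catches.sum()
    if total <= 0:
        raise ValueError("all-zero spectrum: cone stimulation undefined")
    return catches / total


def _usml_to_xyz(usml: np.ndarray) -> np.ndarray:
    u, s, m = usml[..., 0], usml[..., 1], usml[..., 2]
    x = ((1.0 - 2.0 * s - m - u) / 2.0) * np.sqrt(3.0 / 2.0)
    y = (-1.0 + 3.0 * m + u) / (2.0 * np.sqrt(2.0))
    z = u - 0.25
    return np.stack([x, y, z], axis=-1)


def max_chroma(direction: np.ndarray) -> float | np.ndarray:
    """Distance from the achromatic origin to the tetrahedron boundary.

    ``direction`` is one or more (3,) vectors; the result is the smallest
    positive ray-face intersection distance over the four faces.
    """
    d = np.atleast_2d(np.asarray(direction, dtype=float))
    norms = np.linalg.norm(d, axis=1, keepdims=True)
    if np.any(norms == 0):
        raise ValueError("direction must be nonzero")
    d = d / norms
    best = np.full(d.shape[0], np.inf)
    for n, off in _faces():
        denom = d @ n
        with np.errstate(divide="ignore"):
            t = np.where(denom > 1e-300, off / denom, np.inf)
        best = np.minimum(best, np.where(t > 0, t, np.inf))
    return best[0] if np.ndim(direction) == 1 else best


def tetra_metrics(usml: np.ndarray) -> dict[str, float]:
    """Tetrahedral color-space geometry for one normalized catch vector.

    Returns a dict with keys ``u s m l x y z theta phi r r_max r_A
    hue_defined``. At the achromatic point (r = 0) the hue angles are
    undefined: they are returned as NaN with ``hue_defined = False`` so
    that downstream averaging cannot silently absorb them, and
    ``r_A = 0``.
    """
    q = np.asarray(usml, dtype=float)
    if q.shape != (4,):
        raise ValueError("usml must be a length-4 vector")
    if np.any(q < 0):
        raise ValueError("cone stimulations must be nonnegative")
    if abs(q.sum() - 1.0) > 1e-9:
        raise ValueError("cone stimulations must sum to 1 (within 1e-9)")
    xyz = _usml_to_xyz(q)
    r = float(np.linalg.norm(xyz))
    out = {
        "u": float(q[0]),
        "s": float(q[1]),
        "m": float(q[2]),
        "l": float(q[3]),
        "x": float(xyz[0]),
        "y": float(xyz[1]),
        "z": float(xyz[2]),
        "r": r,
    }
    if r == 0.0:
        out.update(theta=np.nan, phi=np.nan, r_max=np.nan, r_A=0.0, hue_defined=False)
        return out
    out["theta"] = float(np.arctan2(xyz[1], xyz[0]))
    out["phi"] = float(np.arcsin(xyz[2] / r))
    r_max = float(max_chroma(xyz))
    out["r_max"] = r_max
    out["r_A"] = r / r_max
    out["hue_defined"] = True
    return out


def brightness(wavelengths: np.ndarray, reflectance: np.ndarray) -> float:
    """Mean percent reflectance over the 300-700 nm window (trapezoidal)."""
    wl = _check_grid(wavelengths)
    refl = np.asarray(reflectance, dtype=float)
    if refl.shape != wl.shape:
        raise ValueError("reflectance and wavelength grids differ in length")
    lo, hi = WINDOW
    if wl[0] > lo or wl[-1] < hi:
        raise ValueError(f"grid must cover {lo}-{hi} nm")
    mask = (wl >= lo) & (wl <= hi)
    w, r = wl[mask], refl[mask]
    return float(np.trapezoid(r, w) / (w[-1] - w[0]))


def repeatability_icc(values, groups) -> float:
    """One-way ANOVA intraclass correlation (measurement repeatability).

    ICC = (MS_among - MS_within) / (MS_among + (k0 - 1) MS_within) with
    k0 = (N - sum(n_i^2)/N) / (G - 1), the standard unequal-group-size
    correction. The result is clamped to [-1, 1].
    """
    v = np.asarray(values, dtype=float)
    g = pd.Series(groups)
    if v.shape[0] != g.shape[0]:
        raise ValueError("values and groups differ in length")
    counts = g.groupby(g).size()
    G = len(counts)
    if G < 2:
        raise ValueError("repeatability needs at least two groups")
    if (counts < 2).all():
        raise ValueError("at least one group needs >= 2 replicates")
    N = v.size
    grand = v.mean()
    means = pd.Series(v).groupby(g.values).mean()
    ss_among = float((counts * (means - grand) ** 2).sum())
    ss_within = float(
        sum(((v[g.values == k] - means[k]) ** 2).sum() for k in counts.index)
    )
    ms_among = ss_among / (G - 1)
    ms_within = ss_within / (N - G)
    k0 = (N - float((counts**2).sum()) / N) / (G - 1)
    icc = (ms_among - ms_within) / (ms_among + (k0 - 1) * ms_within)
    return float(np.clip(icc, -1.0, 1.0))


class TetraColorMapper(BaseEstimator, TransformerMixin):
    """Transformer: replicate reflectance spectra -> tetrahedral color metrics.

    Parameters
    ----------
    cones : ConeSensitivitySet, optional
        Cone sensitivity templates; defaults to the package's Gaussian set.
    average_replicates_first : bool
        If True (default), replicates are averaged into one spectrum per
        sample before metrics are computed, matching the field protocol of
        measuring each sample three times and averaging. If False, metrics
        are returned per replicate (used for repeatability).

    ``transform`` accepts a wide spectra table: a DataFrame whose first
    column is ``wavelength_nm`` and whose remaining columns are named
    ``"<sample_id>|rep<k>"`` (or just ``"<sample_id>"`` for single scans).
    It returns one row per sample (or per replicate) with columns
    sample_id, theta, phi, r, r_max, r_A, brightness.
    """

    def __init__(self, cones: ConeSensitivitySet | None = None,
                 average_replicates_first: bool = True):
        self.cones = cones
        self.average_replicates_first = average_replicates_first

    def fit(self, X: pd.DataFrame, y=None):  # stateless; validates only
        self._check(X)
        self.n_features_in_ = X.shape[1]
        return self

    @staticmethod
    def _check(X: pd.DataFrame) -> None:
        if "wavelength_nm" not in X.columns:
            raise ValueError("spectra table must have a wavelength_nm column")
        _check_grid(X["wavelength_nm"].to_numpy())

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        self._check(X)
        cones = self.cones or ConeSensitivitySet()
        wl = X["wavelength_nm"].to_numpy(dtype=float)
        groups: dict[str, list[str]] = {}
        for col in X.columns:
            if col == "wavelength_nm":
                continue
            sample = col.split("|")[0]
            groups.setdefault(sample, []).append(col)
        rows = []
        for sample, cols in groups.items():
            spectra = X[cols].to_numpy(dtype=float)
            if self.average_replicates_first:
                items = [("", average_replicates(spectra))]
            else:
                items = [
                    (c.split("|", 1)[1] if "|" in c else "rep1", spectra[:, i])
                    for i, c in enumerate(cols)
                ]
            for rep, refl in items:
                usml = cone_stimulation(wl, refl, cones)
                met = tetra_metrics(usml)
                row = {"sample_id": sample}
                if not self.average_replicates_first:
                    row["replicate"] = rep
                row.update(
                    theta=met["theta"], phi=met["phi"], r=met["r"],
                    r_max=met.get("r_max", np.nan), r_A=met["r_A"],
                    hue_defined=met["hue_defined"],
                    brightness=brightness(wl, refl),
                )
                rows.append(row)
        return pd.DataFrame(rows)
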