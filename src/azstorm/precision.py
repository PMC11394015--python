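"""Localization precision from nearest-neighbour analysis (NeNA).

A molecule that stays on across two consecutive camera frames is
localized twice; the displacement between the two fits is the vector
difference of two independent localization errors.  With isotropic
Gaussian errors of per-axis sd sigma, that displacement length follows a
Rayleigh distribution with scale sqrt(2)*sigma:

    p(d) = d / (2 sigma^2) * exp(-d^2 / (4 sigma^2))

NeNA therefore pools, over all frames t, the distance from every
localization in frame t to its nearest neighbour in frame t+1 and fits
the normalized distance histogram with that same-molecule term plus two
empirical correction terms for mismatched neighbours (a Gaussian bump at
larger distance and a linearly rising floor):

    f(d) = A * d/(2 sigma^2) exp(-d^2/(4 sigma^2))
         + B * exp(-(d - d_c)^2 / (2 w^2)) / (w sqrt(2 pi))
         + C * d

The fitted sigma is the experimental localization precision.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit
from scipy.spatial import cKDTree

from .loc_io import LocalizationTable

__all__ = [
    "NenaResult",
    "NenaFitError",
    "consecutive_frame_nn_distances",
    "fit_nena",
    "nena_precision",
]


class NenaFitError(RuntimeError):
    """NeNA fit failed; carries initial values and residual diagnostics."""

    def __init__(self, message: str, p0=None, residuals=None):
        super().__init__(message)
        self.p0 = p0
        self.residuals = residuals


@dataclass
class NenaResult:
    """Fitted localization precision and NeNA fit diagnostics."""

    sigma: float                    # nm
    params: dict                    # all fitted model parameters
    nn_distances: np.ndarray        # the raw pooled distance sample (nm)
    bin_width: float
    r_max: float
    bin_centers: np.ndarray = field(repr=False, default=None)
    histogram: np.ndarray = field(repr=False, default=None)   # unit-area density
    fitted: np.ndarray = field(repr=False, default=None)
    residual_rms: float = float("nan")

    def summary(self) -> str:
        lines = [
            "NeNA localization precision fit",
            "-" * 33,
            f"n distances      : {len(self.nn_distances)}",
            f"bin width        : {self.bin_width} nm on [0, {self.r_max}] nm",
            f"sigma            : {self.sigma:.2f} nm",
        ]
        for k, v in self.params.items():
            lines.append(f"{k:<17}: {v:.4g}")
        lines.append(f"residual rms     : {self.residual_rms:.4g}")
        return "\n".join(lines)


def consecutive_frame_nn_distances(table: LocalizationTable) -> np.ndarray:
    """Pooled distances from each localization in frame t to its nearest
    neighbour in frame t+1, over every adjacent frame pair present."""
    df = table.data
    frames = df["frame"].to_numpy()
    order = np.argsort(frames, kind="stable")
    xy = table.xy[order]
    frames = frames[order]
    uniq, starts = np.unique(frames, return_index=True)
    starts = np.append(starts, len(frames))
    by_frame = {f: xy[starts[i]:starts[i + 1]] for i, f in enumerate(uniq)}

    out = []
    for f in uniq:
        nxt = by_frame.get(f + 1)
        if nxt is None or len(nxt) == 0:
            continue
        tree = cKDTree(nxt)
        d, _ = tree.query(by_frame[f], k=1)
        out.append(np.atleast_1d(d))
    if not out:
        raise ValueError("no adjacent-frame localization pairs in table")
    return np.concatenate(out)


def _nena_model(d, sigma, a, b, d_c, w, c):
    same = a * d / (2.0 * sigma**2) * np.exp(-(d**2) / (4.0 * sigma**2))
    mismatch = b * np.exp(-((d - d_c) ** 2) / (2.0 * w**2)) / (w * np.sqrt(2 * np.pi))
    return same + mismatch + c * d


def fit_nena(distances: np.ndarray, bin_width: float = 1.0, r_max: float = 200.0,
             min_sample: int = 100) -> NenaResult:
    """Least-squares NeNA fit of the nearest-neighbour distance histogram.

    The histogram (bins of ``bin_width`` nm on [0, r_max]) is normalized
    to unit area before fitting.  Initial sigma is the histogram mode
    divided by sqrt(2); correction-term amplitudes start at zero.
    """
    d = np.asarray(distances, float)
    d = d[np.isfinite(d)]
    if len(d) < min_sample:
        raise NenaFitError(f"need >= {min_sample} distances, got {len(d)}")
    if np.all(d <= 0):
        raise NenaFitError("degenerate distance sample (all zero)")

    edges = np.arange(0.0, r_max + bin_width, bin_width)
    counts, _ = np.histogram(d, bins=edges)
    density = counts / (counts.sum() * bin_width)
    centers = 0.5 * (edges[:-1] + edges[1:])

    mode = centers[np.argmax(counts)]
    sigma0 = max(mode / np.sqrt(2.0), bin_width / 2.0)
    p0 = [sigma0, 1.0, 0.0, min(4.0 * sigma0, r_max / 2), r_max / 8.0, 0.0]
    lower = [bin_width / 4.0, 0.0, 0.0, 0.0, bin_width, 0.0]
    upper = [r_max, 10.0, 10.0, r_max, r_max, 1.0]
    try:
        popt, _ = curve_fit(_nena_model, centers, density, p0=p0,
                            bounds=(lower, upper), maxfev=20000)
    except RuntimeError as exc:
        resid = density - _nena_model(centers, *p0)
        raise NenaFitError(f"NeNA optimizer did not converge: {exc}",
                           p0=p0, residuals=resid) from exc

    fitted = _nena_model(centers, *popt)
    names = ["sigma", "amp_same", "amp_mismatch", "mismatch_center",
             "mismatch_width", "linear_slope"]
    return NenaResult(
        sigma=float(popt[0]),
        params=dict(zip(names, map(float, popt))),
        nn_distances=d,
        bin_width=bin_width,
        r_max=r_max,
        bin_centers=centers,
        histogram=density,
        fitted=fitted,
        residual_rms=float(np.sqrt(np.mean((density - fitted) ** 2))),
    )


def nena_precision(table: LocalizationTable, bin_width: float = 1.0,
                   r_max: float = 200.0) -> NenaResult:
    """One-call NeNA: pool consecutive-frame NN distances and fit sigma."""
    return fit_nena(consecutive_frame_nn_distances(table),
                    bin_width=bin_width, r_max=r_max)
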