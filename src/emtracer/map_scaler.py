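"""Amplitude scaling of the reference map onto the working map's scale.

The likelihood targets are trained on a reference map/model pair, so the
reference density must first be put on the same amplitude scale (and overall
B-factor falloff) as the working map.  Both maps are mean-subtracted and
Fourier-transformed; amplitudes are radially averaged into equal-width d⁻²
shells to give a Guinier curve (lnF vs d⁻²).  The reference amplitudes are
then multiplied per Fourier voxel by ``exp(lnF_work(s) − lnF_ref(s))``, with
the correction linearly interpolated between shell centres, and clamped to
its value at the d = 10 Å shell for all lower-resolution components (the
low-frequency terms of the two maps describe different molecular envelopes
and would otherwise be grossly over-weighted).  Phases are untouched.
Finally the scaled reference is low-pass filtered to the working map's
resolution, yielding the "simulated" reference used for target training.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .volio import GridMap, _freq_magnitude, lowpass_filter

__all__ = ["GuinierCurve", "guinier", "scale_reference", "CLAMP_D"]

CLAMP_D = 10.0  # Å: resolutions coarser than this use the clamped correction


@dataclass
class GuinierCurve:
    """Radially averaged Fourier amplitudes: lnF per d⁻² shell."""

    inv_d2: np.ndarray  # shell centres, Å⁻²
    lnF: np.ndarray
    counts: np.ndarray

    def __post_init__(self) -> None:
        if np.any(np.diff(self.inv_d2) <= 0):
            raise ValueError("shells must be ordered by increasing d^-2")
        if np.any(self.counts < 1):
            raise ValueError("every shell must contain at least one voxel")

    def lnF_at(self, inv_d2: np.ndarray) -> np.ndarray:
        """Linear interpolation of lnF in d⁻², flat beyond the sampled range."""
        return np.interp(inv_d2, self.inv_d2, self.lnF)


def _shell_edges(gmap: GridMap, n_shells: int | None) -> np.ndarray:
    # one shell per Fourier radius step of the largest box dimension
    extent = max(n * v for n, v in zip(gmap.shape, gmap.voxel_size))
    ds = 1.0 / extent
    s_max = float(np.sqrt(np.sum((0.5 / gmap.voxel_size) ** 2)))
    if n_shells is None:
        n_shells = max(4, int(np.ceil(s_max / ds)))
    edges = np.linspace(0.0, s_max**2, n_shells + 1)  # equal width in d^-2
    return edges


def guinier(gmap: GridMap, n_shells: int | None = None) -> GuinierCurve:
    """Guinier curve of a map: mean Fourier amplitude per d⁻² shell.

    The map is mean-subtracted first, and the DC term is excluded, so the
    curve characterises only the structured signal.  Empty shells are merged
    into their lower neighbour.
    """
    data = gmap.data - gmap.data.mean()
    F = np.fft.rfftn(data)
    s2 = _freq_magnitude(gmap.shape, gmap.voxel_size, rfft=True) ** 2
    amps = np.abs(F).ravel()
    s2 = s2.ravel()
    keep = s2 > 0  # exclude DC
    amps, s2 = amps[keep], s2[keep]
    edges = _shell_edges(gmap, n_shells)
    idx = np.clip(np.digitize(s2, edges) - 1, 0, len(edges) - 2)
    sums = np.bincount(idx, weights=amps, minlength=len(edges) - 1)
    counts = np.bincount(idx, minlength=len(edges) - 1)
    centres = 0.5 * (edges[:-1] + edges[1:])
    empty = counts == 0
    if np.any(empty):
        warnings.warn(f"{empty.sum()} empty Guinier shells merged", stacklevel=2)
    sel = ~empty
    mean_amp = sums[sel] / counts[sel]
    return GuinierCurve(
        inv_d2=centres[sel], lnF=np.log(np.maximum(mean_amp, 1e-300)), counts=counts[sel]
    )


def scale_reference(
    reference: GridMap,
    working: GridMap,
    working_resolution: float,
    n_shells: int | None = None,
) -> GridMap:
    """Scale the reference map's Fourier amplitudes to the working map's
    Guinier curve, clamp below d = 10 Å, and low-pass to the working
    resolution.  Phases of the reference are unchanged."""
    curve_ref = guinier(reference, n_shells)
    curve_work = guinier(working, n_shells)
    data = reference.data - reference.data.mean()
    F = np.fft.rfftn(data)
    s = _freq_magnitude(reference.shape, reference.voxel_size, rfft=True)
    s2 = s**2
    clamp_s2 = 1.0 / CLAMP_D**2
    # correction in log space, evaluated per Fourier voxel; low-resolution
    # region (d >= 10 Å) uses the correction at the nearest-to-10 Å shell
    q = np.where(s2 >= clamp_s2, s2, clamp_s2)
    ln_corr = curve_work.lnF_at(q) - curve_ref.lnF_at(q)
    scaled = F * np.exp(ln_corr)
    # DC of the mean-subtracted map is ~0; leave it alone
    scaled.flat[0] = F.flat[0]
    # restore the (unscaled) map mean removed before the transform
    out = reference.copy(
        data=np.fft.irfftn(scaled, s=reference.shape, axes=(0, 1, 2))
        + reference.data.mean()
    )
    out = lowpass_filter(out, working_resolution)
    out.resolution_hint = working_resolution
    return out
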