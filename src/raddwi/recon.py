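"""Image reconstruction: radial filtered back-projection and EPI Fourier
reconstruction.

The radial chain mirrors offline processing of a radially sampled spin
echo: zero- and first-order phase correction of each view, 1-D inverse
transform to projections, ramp (Ram-Lak) filtering with the analytic
band-limited kernel, and back-projection onto the target matrix.  Magnitude
(not real-part) images are passed downstream, consistent with Rician noise
statistics and the constant offset of the signal model.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from pathlib import Path

import nibabel as nib
import numpy as np

from .acquisition import KSpaceSet

__all__ = [
    "DwiImageStack",
    "phase_correct_radial",
    "correct_radial_stack",
    "fbp_reconstruct",
    "epi_reconstruct",
    "snr",
    "RAYLEIGH_SD_FACTOR",
]

#: SD of the Rayleigh distribution in units of the underlying complex-channel
#: sigma: sqrt(2 - pi/2) ~= 0.655.  Divides a background-magnitude SD to
#: recover the per-channel noise level.
RAYLEIGH_SD_FACTOR = float(np.sqrt(2.0 - np.pi / 2.0))


@dataclass
class DwiImageStack:
    """Magnitude images indexed (b-index, polarity, y, x) for one slice."""

    images: np.ndarray
    pixel_mm: float
    b_values: tuple[float, ...]
    polarities: tuple[int, ...]
    protocol: str

    def __post_init__(self) -> None:
        if np.any(self.images < 0):
            raise ValueError("magnitude images must be non-negative")
        if self.images.shape[:2] != (len(self.b_values), len(self.polarities)):
            raise ValueError("images shape inconsistent with b/polarity lists")

    @property
    def n_images(self) -> int:
        """Diffusion-weighted images per slice (b-values x polarities)."""
        return self.images.shape[0] * self.images.shape[1]

    def to_nifti(self, path: str | Path) -> None:
        """4-D NIfTI (y, x, 1, b*pol) with a JSON sidecar giving the
        b-value/polarity of each volume."""
        path = Path(path)
        n_b, n_pol, ny, nx = self.images.shape
        vol = self.images.reshape(n_b * n_pol, ny, nx).transpose(1, 2, 0)
        aff = np.diag([self.pixel_mm, self.pixel_mm, 1.0, 1.0])
        nib.save(nib.Nifti1Image(vol[:, :, None, :], aff), str(path))
        sidecar = {
            "protocol": self.protocol,
            "volumes": [
                {"b_value": b, "polarity": p}
                for b in self.b_values for p in self.polarities
            ],
        }
        name = path.name
        for suf in (".nii.gz", ".nii"):
            if name.endswith(suf):
                name = name[: -len(suf)]
                break
        path.with_name(name + ".json").write_text(json.dumps(sidecar, indent=2))


# ---------------------------------------------------------------------------
# Radial phase correction
# ---------------------------------------------------------------------------

def phase_correct_radial(view: np.ndarray, return_info: bool = False):
    """Zero- and first-order phase correction of one radial view.

    Centers the echo-peak magnitude at the middle readout index, removes the
    linear phase ramp (estimated from the lag-one autocorrelation of the
    samples) and zeroes the phase at the peak.  Apart from the integer
    recentering shift, the correction is a pure phase operation.
    """
    view = np.asarray(view)
    n = view.size
    if n < 8:
        raise ValueError("view must have >= 8 samples")
    info = {"all_zero": False, "recentered": False,
            "slope": 0.0, "phase0": 0.0}
    if not np.any(view):
        out = view.copy()
        info["all_zero"] = True
        return (out, info) if return_info else out
    center = n // 2
    peak = int(np.argmax(np.abs(view)))
    out = view.copy()
    if peak != center:
        out = np.roll(out, center - peak)
        info["recentered"] = True
    slope = float(np.angle(np.sum(out[1:] * np.conj(out[:-1]))))
    idx = np.arange(n) - center
    out = out * np.exp(-1j * slope * idx)
    phase0 = float(np.angle(out[center]))
    out = out * np.exp(-1j * phase0)
    info["slope"] = slope
    info["phase0"] = phase0
    return (out, info) if return_info else out


def correct_radial_stack(kspace: KSpaceSet) -> KSpaceSet:
    """Echo-referenced zero- and first-order phase correction of a radial
    k-space set.

    First order: each view's echo-peak magnitude is recentered to the
    middle readout index (an integer shift; a no-op when the trajectory has
    no timing error, since the DC sample of a non-negative object dominates
    every view).  Zero order: the phase at the echo peak is set to zero,
    which removes view-to-view bulk phase errors such as those induced by
    motion during diffusion encoding.  The object's own linear phase
    (its in-plane position) is untouched, so the reconstructed geometry is
    preserved.
    """
    if kspace.params.protocol != "RAD":
        raise ValueError("correct_radial_stack expects a RAD k-space set")
    s = kspace.samples
    n_b, n_pol, V, N = s.shape
    center = N // 2
    out = np.empty_like(s)
    for ib in range(n_b):
        for ip in range(n_pol):
            for v in range(V):
                view = s[ib, ip, v]
                if not np.any(view):
                    out[ib, ip, v] = view
                    continue
                peak = int(np.argmax(np.abs(view)))
                if peak != center:
                    view = np.roll(view, center - peak)
                out[ib, ip, v] = view * np.exp(-1j * np.angle(view[center]))
    return replace(kspace, samples=out)


# ---------------------------------------------------------------------------
# Filtered back-projection
# ---------------------------------------------------------------------------

def ramp_kernel(t: np.ndarray) -> np.ndarray:
    """Impulse response of the ramp filter band-limited to |k| <= 1/2
    cycles/sample: h(t) = sinc(t)/2 - sinc^2(t/2)/4."""
    return 0.5 * np.sinc(t) - 0.25 * np.sinc(t / 2.0) ** 2


def fbp_reconstruct(kspace: KSpaceSet, matrix: int | None = None,
                    hann: bool = False) -> DwiImageStack:
    """Reconstruct a radial k-space set by filtered back-projection.

    Per view: inverse 1-D Fourier transform of the k-line gives a parallel
    projection; the projection is convolved with the analytic band-limited
    ramp kernel (optionally Hann-apodized) on an oversampled grid; filtered
    projections are back-projected with linear interpolation.  Output is the
    pixel-wise magnitude of the complex reconstruction.
    """
    p = kspace.params
    if p.protocol != "RAD":
        raise ValueError("fbp_reconstruct expects a RAD k-space set")
    n_b, n_pol, V, N = kspace.samples.shape
    if V < 8:
        raise ValueError("need at least 8 views")
    if matrix is None:
        matrix = N

    pix = p.fov / matrix
    # projection sample positions in units of the k-space-implied pixel
    # (1 / (N * dk) = fov / N); reconstruct on the target grid in the same
    # units so the ramp kernel (unit sample spacing) applies directly.
    t_n = np.arange(N) - N / 2 + 0.5
    kap = (np.arange(N) - N / 2) / N  # cycles per readout sample
    E = np.exp(2j * np.pi * np.outer(t_n, kap)) / N  # inverse DFT, (r, k)

    pad = 8
    rmax = int(np.ceil(N / np.sqrt(2.0))) + 3
    r_fine = np.arange(-rmax * pad, rmax * pad + 1) / pad
    if hann:
        # apodize in the frequency domain: kernel = IFT{ |k| * hann(k) }
        kk = np.linspace(-0.5, 0.5, 4 * N, endpoint=False)
        win = np.abs(kk) * 0.5 * (1 + np.cos(2 * np.pi * kk))
        Hmat = np.zeros((r_fine.size, N))
        for j, tn in enumerate(t_n):
            Hmat[:, j] = np.real(
                (win[None, :] * np.exp(2j * np.pi * np.outer(r_fine - tn, kk))
                 ).sum(axis=1) * (kk[1] - kk[0]))
    else:
        Hmat = ramp_kernel(r_fine[:, None] - t_n[None, :])

    scale = N / matrix  # readout-sample units per target pixel
    xc = (np.arange(matrix) - matrix / 2 + 0.5) * scale
    XP, YP = np.meshgrid(xc, xc)
    thetas = np.arange(V) * np.pi / V

    images = np.zeros((n_b, n_pol, matrix, matrix))
    for ib in range(n_b):
        for ip in range(n_pol):
            recon = np.zeros((matrix, matrix), complex)
            proj = (E @ kspace.samples[ib, ip].T).T  # (V, N)
            pf = proj @ Hmat.T  # (V, fine)
            for v in range(V):
                r = XP * np.cos(thetas[v]) + YP * np.sin(thetas[v])
                recon += (np.interp(r, r_fine, pf[v].real)
                          + 1j * np.interp(r, r_fine, pf[v].imag))
            images[ib, ip] = np.abs(recon) * np.pi / V
    return DwiImageStack(images=images, pixel_mm=pix,
                         b_values=p.b_values, polarities=p.polarities,
                         protocol="RAD")


# ---------------------------------------------------------------------------
# EPI reconstruction
# ---------------------------------------------------------------------------

def epi_reconstruct(kspace: KSpaceSet) -> DwiImageStack:
    """Reassemble EPI interleaves into a full Cartesian raster and inverse
    Fourier transform; output magnitude.

    Even/odd-echo (readout reversal) correction is assumed ideal; only
    shot-to-shot errors present in the data propagate to the image.
    """
    p = kspace.params
    if p.protocol != "EPI":
        raise ValueError("epi_reconstruct expects an EPI k-space set")
    n_b, n_pol, S, L, N = kspace.samples.shape
    M = p.matrix_phase
    if S * L != M or S != p.n_shots:
        raise ValueError(
            f"missing interleave: {S} shots x {L} lines != matrix_phase {M}")
    m = np.arange(N) - N / 2
    ramp_x = np.exp(-1j * np.pi * m / N)
    my = np.arange(M) - M / 2
    ramp_y = np.exp(-1j * np.pi * my / M)

    images = np.zeros((n_b, n_pol, M, N))
    for ib in range(n_b):
        for ip in range(n_pol):
            K = np.zeros((M, N), complex)
            for s in range(S):
                K[s + S * np.arange(L), :] = kspace.samples[ib, ip, s]
            K = K / (ramp_y[:, None] * ramp_x[None, :])
            img = np.fft.fftshift(np.fft.ifft2(np.fft.ifftshift(K)))
            images[ib, ip] = np.abs(img)
    return DwiImageStack(images=images, pixel_mm=p.fov / M,
                         b_values=p.b_values, polarities=p.polarities,
                         protocol="EPI")


# ---------------------------------------------------------------------------
# SNR
# ---------------------------------------------------------------------------

def snr(image: np.ndarray, signal_mask: np.ndarray,
        background_mask: np.ndarray) -> float:
    """Magnitude-image SNR: mean(signal) / (SD(background) / 0.655).

    The background SD of a magnitude image underestimates the per-channel
    noise sigma by the Rayleigh factor sqrt(2 - pi/2) ~= 0.655; dividing by
    it recovers sigma, so the ratio is mean signal over channel noise.
    Returns inf when the background is exactly constant.
    """
    signal_mask = np.asarray(signal_mask, bool)
    background_mask = np.asarray(background_mask, bool)
    if not signal_mask.any() or not background_mask.any():
        raise ValueError("masks must be non-empty")
    if np.any(signal_mask & background_mask):
        raise ValueError("signal and background masks must be disjoint")
    sd = float(np.std(image[background_mask]))
    if sd == 0.0:
        return float("inf")
    return float(np.mean(image[signal_mask]) / (sd / RAYLEIGH_SD_FACTOR))
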