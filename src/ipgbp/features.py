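"""Time–frequency features: CWT scalograms of normalized beats.

The model input is the magnitude of a continuous wavelet transform of each
beat, computed with the Daubechies-8 wavelet.  db8 is an orthogonal
*discrete*-family wavelet with no closed-form mother function, so the CWT is
implemented by cross-correlating the beat with rescaled db8 wavelet
functions obtained from the cascade algorithm, L2-normalized per scale —
the same construction some wavelet toolboxes use when a discrete wavelet is
requested for a CWT.  A Morlet alternative is available through the
``wavelet`` argument for comparison.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import pywt
from scipy import signal as sps
from scipy.ndimage import map_coordinates

__all__ = [
    "Scalogram",
    "default_scales",
    "cwt_scalogram",
    "scalogram_to_image",
    "beats_to_images",
    "write_scalograms",
    "read_scalograms",
]


@dataclass
class Scalogram:
    """CWT coefficient magnitudes for one beat: shape (n_scales, beat_len)."""

    coeffs: np.ndarray
    scales: np.ndarray
    wavelet_name: str


def default_scales(
    n_scales: int = 64,
    fs_eff: float = 154.0,
    fmin: float = 1.0,
    fmax: float = 20.0,
    wavelet: str = "db8",
) -> np.ndarray:
    """Log-spaced scales whose pseudo-frequencies span ``fmin``–``fmax`` Hz.

    ``fs_eff`` is the beat's effective sampling rate (target_len samples per
    beat period; 128 samples at ~1.2 Hz gives ≈154 Hz).  Scale s maps to
    pseudo-frequency fc*fs_eff/s with fc the wavelet's center frequency.
    """
    fc = pywt.central_frequency(wavelet)
    freqs = np.logspace(np.log10(fmax), np.log10(fmin), n_scales)
    return fc * fs_eff / freqs


def _db8_kernels(scales: np.ndarray, precision: int = 10) -> list[np.ndarray]:
    """Rescaled, L2-normalized db8 wavelet kernels from the cascade algorithm."""
    _, psi, x = pywt.Wavelet("db8").wavefun(level=precision)
    support = x[-1]  # 15 for db8
    kernels = []
    for s in scales:
        n = max(int(np.ceil(s * support)), 2)
        grid = np.arange(n) / s  # sample psi(t/s) on the beat's sample grid
        k = np.interp(grid, x, psi)
        norm = np.linalg.norm(k)
        kernels.append(k / norm if norm > 0 else k)
    return kernels


def cwt_scalogram(
    beat: np.ndarray,
    scales: np.ndarray | None = None,
    wavelet: str = "db8",
    precision: int = 10,
) -> Scalogram:
    """CWT coefficient magnitudes of a beat at the given scales.

    Each row is ``|cross-correlation(beat, psi((t)/s))|`` with the kernel
    L2-normalized, evaluated at every sample (mode 'same').  The transform
    is linear in the beat before the magnitude is taken.
    """
    beat = np.asarray(beat, dtype=float)
    if scales is None:
        scales = default_scales(wavelet=wavelet)
    scales = np.asarray(scales, dtype=float)
    if np.any(scales <= 0):
        raise ValueError("scales must be strictly positive")

    if wavelet == "db8":
        kernels = _db8_kernels(scales, precision=precision)
        rows = [np.abs(sps.correlate(beat, k, mode="same")) for k in kernels]
        coeffs = np.vstack(rows)
    else:
        coeffs, _ = pywt.cwt(beat, scales, wavelet)
        coeffs = np.abs(coeffs)
    return Scalogram(coeffs=coeffs, scales=scales, wavelet_name=wavelet)


def scalogram_to_image(sc: Scalogram | np.ndarray, out_shape: tuple[int, int] = (32, 32)) -> np.ndarray:
    """Bilinear-resize a scalogram to ``out_shape`` and min-max scale to [0, 1].

    Align-corners bilinear interpolation, so a separable bilinear ramp stays
    a bilinear ramp under resizing.  A constant scalogram maps to zeros.
    """
    arr = sc.coeffs if isinstance(sc, Scalogram) else np.asarray(sc, dtype=float)
    H, W = out_shape
    hi, wi = arr.shape
    rows = np.linspace(0, hi - 1, H)
    cols = np.linspace(0, wi - 1, W)
    rr, cc = np.meshgrid(rows, cols, indexing="ij")
    img = map_coordinates(arr.astype(float), [rr, cc], order=1, mode="nearest")
    rng = img.max() - img.min()
    if rng <= 1e-12 * max(abs(float(img.max())), 1.0):  # constant up to rounding
        return np.zeros(out_shape)
    return (img - img.min()) / rng


def beats_to_images(
    beats: list,
    scales: np.ndarray | None = None,
    wavelet: str = "db8",
    out_shape: tuple[int, int] = (32, 32),
) -> np.ndarray:
    """Convert BeatSegments (or raw sample arrays) to a stack of model inputs."""
    imgs = []
    for b in beats:
        samples = getattr(b, "samples", b)
        sc = cwt_scalogram(samples, scales=scales, wavelet=wavelet)
        imgs.append(scalogram_to_image(sc, out_shape))
    return np.stack(imgs) if imgs else np.empty((0, *out_shape))


# ---------------------------------------------------------------------------
# on-disk interface


def write_scalograms(h5_path: str | Path, images: np.ndarray, index: pd.DataFrame, csv_path: str | Path | None = None) -> None:
    """Store the image stack (HDF5) and its beat→trial→reference index (CSV)."""
    import h5py

    h5_path = Path(h5_path)
    h5_path.parent.mkdir(parents=True, exist_ok=True)
    with h5py.File(h5_path, "w") as f:
        f.create_dataset("images", data=np.asarray(images, dtype=np.float32))
    if csv_path is None:
        csv_path = h5_path.with_suffix(".index.csv")
    index.to_csv(csv_path, index=False, float_format="%.8g")


def read_scalograms(h5_path: str | Path, csv_path: str | Path | None = None) -> tuple[np.ndarray, pd.DataFrame]:
    import h5py

    h5_path = Path(h5_path)
    with h5py.File(h5_path, "r") as f:
        images = f["images"][...].astype(float)
    if csv_path is None:
        csv_path = h5_path.with_suffix(".index.csv")
    return images, pd.read_csv(csv_path)
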