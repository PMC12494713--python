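"""Session containers, NIfTI I/O, nuisance regression, and band-pass filtering.

A session is held as a dense voxel x time matrix together with a voxel table
(world-mm coordinates in a right/anterior/superior-positive convention and an
anatomical/network label per voxel).  The two preprocessing computations the
drift analysis depends on are ordinary-least-squares nuisance regression
(six motion parameters plus CSF/WM mean signals, with a constant and linear
trend always included) and an ideal FFT band-pass filter (0.01-0.1 Hz by
default), applied in that order.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, replace
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
from scipy.linalg import qr as _qr

from .exceptions import ConfigurationError, FormatError, NumericalError

__all__ = [
    "SessionImage",
    "AcquisitionParams",
    "load_session",
    "write_session",
    "write_labels",
    "write_score_map",
    "regress_nuisance",
    "bandpass",
]

#: Minimum number of timepoints required before band-pass filtering; with
#: fewer samples the 0.01 Hz cutoff is meaningless at typical TRs.
MIN_BANDPASS_TIMEPOINTS = 100

VOXEL_COLUMNS = ["voxel_id", "i", "j", "k", "x_mm", "y_mm", "z_mm", "label"]


@dataclass(frozen=True)
class AcquisitionParams:
    """Repetition time and band-pass corner frequencies (Hz)."""

    tr_s: float
    f_lo: float = 0.01
    f_hi: float = 0.1

    def __post_init__(self) -> None:
        if self.tr_s <= 0:
            raise ConfigurationError(f"tr_s must be positive, got {self.tr_s}")
        nyquist = 1.0 / (2.0 * self.tr_s)
        if not (0.0 < self.f_lo < self.f_hi):
            raise ConfigurationError(
                f"need 0 < f_lo < f_hi, got f_lo={self.f_lo}, f_hi={self.f_hi}"
            )
        if self.f_hi >= nyquist:
            raise ConfigurationError(
                f"f_hi={self.f_hi} Hz is at or above the Nyquist frequency "
                f"{nyquist:.4g} Hz for tr_s={self.tr_s}"
            )

    @property
    def nyquist_hz(self) -> float:
        return 1.0 / (2.0 * self.tr_s)


@dataclass
class SessionImage:
    """One session's voxel x time signal matrix plus voxel coordinate table.

    Parameters
    ----------
    session_id
        Identifier, e.g. ``"ses-07"``.
    signal
        Array of shape ``(n_voxels, n_timepoints)``.
    voxels
        DataFrame with columns ``voxel_id, i, j, k, x_mm, y_mm, z_mm, label``;
        one row per row of ``signal``.
    tr_s
        Repetition time in seconds.
    affine, grid_shape
        Optional NIfTI geometry, kept so a session can be rendered back to a
        3-D grid losslessly.
    """

    session_id: str
    signal: np.ndarray
    voxels: pd.DataFrame
    tr_s: float
    affine: np.ndarray | None = None
    grid_shape: tuple[int, int, int] | None = None

    def __post_init__(self) -> None:
        self.signal = np.asarray(self.signal, dtype=float)
        if self.signal.ndim != 2:
            raise FormatError("signal must be a 2-D (voxels x timepoints) array")
        if len(self.voxels) != self.signal.shape[0]:
            raise FormatError(
                f"voxel table has {len(self.voxels)} rows but signal has "
                f"{self.signal.shape[0]} voxels"
            )
        if self.tr_s <= 0:
            raise ConfigurationError(f"tr_s must be positive, got {self.tr_s}")

    @property
    def n_voxels(self) -> int:
        return self.signal.shape[0]

    @property
    def n_timepoints(self) -> int:
        return self.signal.shape[1]

    def with_signal(self, signal: np.ndarray) -> "SessionImage":
        """Return a copy of this session carrying a new signal matrix."""
        return replace(self, signal=np.asarray(signal, dtype=float))

    def voxel_ids(self, label: str | None = None) -> np.ndarray:
        """Voxel ids, optionally restricted to one label."""
        table = self.voxels
        if label is not None:
            table = table[table["label"] == label]
        return table["voxel_id"].to_numpy()


# ---------------------------------------------------------------------------
# NIfTI I/O
# ---------------------------------------------------------------------------

def load_session(
    image_path: str | Path,
    labels_path: str | Path,
    *,
    session_id: str | None = None,
    tr_s: float | None = None,
    label_names: dict[int, str] | str | Path | None = None,
) -> SessionImage:
    """Load a 4-D NIfTI image and an integer-coded label mask into a session.

    Voxels with label 0 (background) are excluded.  World coordinates are
    derived from the image affine, so ``x_mm/y_mm/z_mm`` follow whatever
    convention the affine encodes (RAS-positive for the phantoms written by
    this package).

    Raises
    ------
    FormatError
        If the image and label grids disagree in shape or affine, or the
        image contains NaNs (the error names the affected voxel count).
    """
    img = nib.load(str(image_path))
    lab = nib.load(str(labels_path))
    data = np.asarray(img.get_fdata(), dtype=float)
    codes = np.asarray(lab.get_fdata()).round().astype(int)
    if data.ndim != 4:
        raise FormatError(f"expected a 4-D image, got shape {data.shape}")
    if codes.shape != data.shape[:3]:
        raise FormatError(
            f"labels grid shape {codes.shape} does not match image grid "
            f"{data.shape[:3]}"
        )
    if not np.allclose(img.affine, lab.affine, atol=1e-4):
        raise FormatError("image and labels affines disagree")

    if isinstance(label_names, (str, Path)):
        with open(label_names) as fh:
            label_names = {int(k): v for k, v in json.load(fh).items()}

    ii, jj, kk = np.nonzero(codes)
    order = np.lexsort((kk, jj, ii))
    ii, jj, kk = ii[order], jj[order], kk[order]
    signal = data[ii, jj, kk, :]
    n_bad = int(np.isnan(signal).any(axis=1).sum())
    if n_bad:
        raise FormatError(f"image contains NaNs in {n_bad} labeled voxels")

    xyz = nib.affines.apply_affine(img.affine, np.column_stack([ii, jj, kk]))
    code_here = codes[ii, jj, kk]
    if label_names is None:
        labels = [f"label_{c}" for c in code_here]
    else:
        labels = [label_names.get(int(c), f"label_{c}") for c in code_here]
    voxels = pd.DataFrame(
        {
            "voxel_id": np.arange(len(ii)),
            "i": ii,
            "j": jj,
            "k": kk,
            "x_mm": xyz[:, 0],
            "y_mm": xyz[:, 1],
            "z_mm": xyz[:, 2],
            "label": labels,
        }
    )
    if tr_s is None:
        zooms = img.header.get_zooms()
        tr_s = float(zooms[3]) if len(zooms) > 3 and zooms[3] > 0 else 1.0
    if session_id is None:
        session_id = Path(image_path).name.split(".")[0]
    return SessionImage(
        session_id=session_id,
        signal=signal,
        voxels=voxels,
        tr_s=float(tr_s),
        affine=np.asarray(img.affine),
        grid_shape=tuple(data.shape[:3]),
    )


def write_session(image: SessionImage, path: str | Path) -> Path:
    """Render a session back onto its 3-D grid and write a 4-D NIfTI.

    Data are stored as float32 (the NIfTI convention for BOLD), so a
    round trip preserves the signal to float32 quantization.
    """
    if image.affine is None or image.grid_shape is None:
        raise ConfigurationError("session carries no grid geometry to render to")
    vol = np.zeros(image.grid_shape + (image.n_timepoints,), dtype=np.float32)
    tab = image.voxels
    vol[tab["i"], tab["j"], tab["k"], :] = image.signal
    out = nib.Nifti1Image(vol, image.affine)
    out.header.set_zooms(out.header.get_zooms()[:3] + (image.tr_s,))
    nib.save(out, str(path))
    return Path(path)


def write_score_map(
    voxels: pd.DataFrame,
    values: np.ndarray,
    affine: np.ndarray,
    grid_shape: tuple[int, int, int],
    path: str | Path,
) -> Path:
    """Render per-voxel scores (z values, drift scores, ...) to a 3-D NIfTI."""
    vol = np.zeros(grid_shape, dtype=np.float32)
    vol[voxels["i"], voxels["j"], voxels["k"]] = np.asarray(values, dtype=np.float32)
    nib.save(nib.Nifti1Image(vol, np.asarray(affine)), str(path))
    return Path(path)


def write_labels(
    voxels: pd.DataFrame,
    affine: np.ndarray,
    grid_shape: tuple[int, int, int],
    path: str | Path,
    names_path: str | Path | None = None,
) -> dict[int, str]:
    """Write an integer-coded label mask (and optional JSON name map)."""
    labels = sorted(voxels["label"].unique())
    codes = {name: idx + 1 for idx, name in enumerate(labels)}
    vol = np.zeros(grid_shape, dtype=np.int16)
    vol[voxels["i"], voxels["j"], voxels["k"]] = voxels["label"].map(codes)
    nib.save(nib.Nifti1Image(vol, np.asarray(affine)), str(path))
    name_map = {code: name for name, code in codes.items()}
    if names_path is not None:
        with open(names_path, "w") as fh:
            json.dump({str(k): v for k, v in name_map.items()}, fh, indent=1)
    return name_map


# ---------------------------------------------------------------------------
# Nuisance regression
# ---------------------------------------------------------------------------

def _design_matrix(
    image: SessionImage,
    nuisance: pd.DataFrame | np.ndarray,
    add_trend: bool,
) -> tuple[np.ndarray, list[str]]:
    if isinstance(nuisance, pd.DataFrame):
        cols = [str(c) for c in nuisance.columns]
        mat = nuisance.to_numpy(dtype=float)
    else:
        mat = np.asarray(nuisance, dtype=float)
        if mat.ndim == 1:
            mat = mat[:, None]
        cols = [f"nuisance_{i}" for i in range(mat.shape[1])]
    if mat.shape[0] != image.n_timepoints:
        raise FormatError(
            f"nuisance has {mat.shape[0]} timepoints but session has "
            f"{image.n_timepoints}"
        )
    n_t = image.n_timepoints
    parts = [np.ones(n_t)]
    names = ["const"]
    if add_trend:
        parts.append(np.linspace(-1.0, 1.0, n_t))
        names.append("trend")
    design = np.column_stack(parts + [mat])
    return design, names + cols


def regress_nuisance(
    image: SessionImage,
    nuisance: pd.DataFrame | np.ndarray,
    *,
    add_trend: bool = True,
) -> SessionImage:
    """Replace each voxel's series by OLS residuals against the nuisance set.

    A constant (and, by default, a linear trend) is always included in the
    design, so residuals are mean-zero and detrended.  Residuals are
    orthogonal to every regressor up to numerical precision.

    Raises
    ------
    NumericalError
        If the design is rank deficient; the message names the collinear
        columns identified by QR column pivoting.
    """
    design, names = _design_matrix(image, nuisance, add_trend)
    rank = np.linalg.matrix_rank(design)
    if rank < design.shape[1]:
        _, rdiag, piv = _qr(design, mode="economic", pivoting=True)
        diag = np.abs(np.diag(rdiag))
        tol = diag.max() * max(design.shape) * np.finfo(float).eps
        bad = [names[piv[i]] for i in range(len(diag)) if diag[i] <= tol]
        raise NumericalError(
            "nuisance design is rank deficient; collinear columns: "
            + ", ".join(bad)
        )
    beta, *_ = np.linalg.lstsq(design, image.signal.T, rcond=None)
    residuals = image.signal.T - design @ beta
    return image.with_signal(residuals.T)


# ---------------------------------------------------------------------------
# Band-pass filter
# ---------------------------------------------------------------------------

def bandpass_matrix(
    signal: np.ndarray, tr_s: float, f_lo: float = 0.01, f_hi: float = 0.1
) -> np.ndarray:
    """Ideal FFT band-pass applied along the last axis of ``signal``.

    The series mean is removed, then Fourier bins with ``f_lo < f < f_hi``
    (strict inequalities) are retained and all others zeroed.
    """
    AcquisitionParams(tr_s=tr_s, f_lo=f_lo, f_hi=f_hi)  # validates band
    signal = np.asarray(signal, dtype=float)
    n_t = signal.shape[-1]
    freqs = np.fft.rfftfreq(n_t, d=tr_s)
    mask = (freqs > f_lo) & (freqs < f_hi)
    spectrum = np.fft.rfft(signal - signal.mean(axis=-1, keepdims=True), axis=-1)
    spectrum[..., ~mask] = 0.0
    return np.fft.irfft(spectrum, n=n_t, axis=-1)


def bandpass(
    image: SessionImage, acquisition: AcquisitionParams | None = None
) -> SessionImage:
    """Band-pass filter every voxel series of a session (0.01-0.1 Hz default)."""
    if acquisition is None:
        acquisition = AcquisitionParams(tr_s=image.tr_s)
    if abs(acquisition.tr_s - image.tr_s) > 1e-9:
        warnings.warn(
            "acquisition tr_s differs from session tr_s; using acquisition",
            stacklevel=2,
        )
    if image.n_timepoints < MIN_BANDPASS_TIMEPOINTS:
        raise ConfigurationError(
            f"band-pass requires >= {MIN_BANDPASS_TIMEPOINTS} timepoints, "
            f"got {image.n_timepoints}"
        )
    filtered = bandpass_matrix(
        image.signal, acquisition.tr_s, acquisition.f_lo, acquisition.f_hi
    )
    return image.with_signal(filtered)
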