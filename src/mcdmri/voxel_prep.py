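"""Voxel screening and averaging.

Mirrors the preprocessing used for the in vivo corpus-callosum analysis:
fit a diffusion tensor on a reference shell, keep voxels with FA above a
threshold whose principal eigenvector lies within a cone of half-angle eta
about the presumed fiber axis, normalize each shell by the mean of its
b=0 rows, and average the surviving voxels into a single signal vector.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .protocol import AcquisitionScheme


def fit_dt(signals: np.ndarray, scheme: AcquisitionScheme) -> np.ndarray:
    """Weighted linear least-squares diffusion-tensor fit on log-signals.

    Rows with non-positive signal are excluded; at least 7 usable rows
    (including b=0 support for the intercept) are required.  Negative
    eigenvalues of the solution are clamped to zero.
    """
    s = np.asarray(signals, dtype=float)
    ok = s > 0
    if ok.sum() < 7:
        raise ValueError("need >= 7 positive-signal rows for a DT fit")
    g = scheme.directions[ok]
    b = scheme.b[ok]
    y = np.log(s[ok])
    X = np.column_stack(
        [
            np.ones(len(b)),
            -b * g[:, 0] ** 2,
            -b * g[:, 1] ** 2,
            -b * g[:, 2] ** 2,
            -2 * b * g[:, 0] * g[:, 1],
            -2 * b * g[:, 0] * g[:, 2],
            -2 * b * g[:, 1] * g[:, 2],
        ]
    )
    w = s[ok] ** 2  # first-order error propagation of log-transformed noise
    coef, *_ = np.linalg.lstsq(X * w[:, None], y * w, rcond=None)
    D = np.array(
        [
            [coef[1], coef[4], coef[5]],
            [coef[4], coef[2], coef[6]],
            [coef[5], coef[6], coef[3]],
        ]
    )
    vals, vecs = np.linalg.eigh(D)
    if np.any(vals < 0):
        vals = np.clip(vals, 0.0, None)
        D = vecs @ np.diag(vals) @ vecs.T
    return D


def fa(tensor: np.ndarray) -> float:
    """Fractional anisotropy from the tensor eigenvalues (0 for the zero
    tensor)."""
    lam = np.linalg.eigvalsh(np.asarray(tensor, dtype=float))
    ssq = np.sum(lam**2)
    if ssq == 0:
        return 0.0
    return float(np.sqrt(1.5 * np.sum((lam - lam.mean()) ** 2) / ssq))


def principal_direction(tensor: np.ndarray) -> np.ndarray:
    """Unit eigenvector of the largest eigenvalue."""
    vals, vecs = np.linalg.eigh(np.asarray(tensor, dtype=float))
    return vecs[:, np.argmax(vals)]


def normalize_by_b0(raw: np.ndarray, scheme: AcquisitionScheme) -> np.ndarray:
    """Divide each shell's rows by the mean of that shell's b=0 rows.

    Shells share an echo time, so this removes TE-dependent scaling.  Works
    on a single signal vector or a (voxels, rows) array.
    """
    raw = np.asarray(raw, dtype=float)
    out = raw.copy()
    single = raw.ndim == 1
    if single:
        out = out[None, :]
    for s in np.unique(scheme.shell_id):
        rows = scheme.shell_id == s
        b0 = rows & scheme.is_b0
        if not b0.any():
            raise ValueError(f"shell {s} has no b=0 row to normalize by")
        ref = out[:, b0].mean(axis=1)
        if np.any(ref <= 0):
            raise ValueError(f"shell {s}: non-positive b=0 mean")
        out[:, rows] = out[:, rows] / ref[:, None]
    return out[0] if single else out


def load_nifti_volume(path: str, mask_path: str | None = None):
    """Load a 4-D NIfTI volume (and optional 3-D mask) as numpy arrays.

    Convenience entry point for scanner data; the selection pipeline itself
    is array-based.
    """
    import nibabel as nib

    vol = np.asarray(nib.load(path).get_fdata(), dtype=float)
    if vol.ndim != 4:
        raise ValueError(f"expected a 4-D volume, got shape {vol.shape}")
    mask = None
    if mask_path is not None:
        mask = np.asarray(nib.load(mask_path).get_fdata()) > 0
        if mask.shape != vol.shape[:-1]:
            raise ValueError("mask shape must match the volume grid")
    return vol, mask


@dataclass
class VoxelSet:
    """Selected voxels with their normalized signals and average."""

    voxel_indices: list[tuple]
    signals: np.ndarray  # (n_selected, n_rows), normalized
    averaged: np.ndarray  # (n_rows,)
    fa_threshold: float
    eta_deg: float
    axis: np.ndarray

    @property
    def n_voxels(self) -> int:
        return len(self.voxel_indices)


def select_voxels(
    volume: np.ndarray,
    scheme: AcquisitionScheme,
    fa_threshold: float = 0.6,
    eta_deg: float = 2.0,
    axis: np.ndarray = (1.0, 0.0, 0.0),
    ref_shell: int | None = None,
    mask: np.ndarray | None = None,
) -> VoxelSet:
    """Screen a 4-D volume (x, y, z, rows) and average the passing voxels.

    Pipeline order: per-shell b=0
    normalization, DT screening on the reference shell (the shell whose
    b-value is closest to 1202 s/mm^2 unless given), cone selection about
    ``axis`` (axial, sign-ambiguous), then arithmetic averaging.  An empty
    selection returns an empty VoxelSet rather than failing.
    """
    axis = np.asarray(axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    vol = np.asarray(volume, dtype=float)
    n_rows = vol.shape[-1]
    if n_rows != len(scheme):
        raise ValueError("volume last axis must match the scheme length")
    if ref_shell is None:
        w = scheme.weighted
        shell_b = {
            int(s): scheme.b_smm2[(scheme.shell_id == s) & w].mean()
            for s in np.unique(scheme.shell_id)
        }
        ref_shell = min(shell_b, key=lambda s: abs(shell_b[s] - 1202.0))
    rows = scheme.shell_rows(ref_shell)
    sub = scheme.take(rows)

    flat = vol.reshape(-1, n_rows)
    if mask is not None:
        keep_voxels = np.flatnonzero(np.asarray(mask).reshape(-1))
    else:
        keep_voxels = np.arange(flat.shape[0])
    cos_eta = np.cos(np.radians(eta_deg))
    selected, sel_signals = [], []
    for v in keep_voxels:
        sig = flat[v]
        if np.any(sig <= 0):
            continue
        norm = normalize_by_b0(sig, scheme)
        try:
            D = fit_dt(norm[rows], sub)
        except ValueError:
            continue
        if fa(D) <= fa_threshold:
            continue
        e1 = principal_direction(D)
        if abs(e1 @ axis) <= cos_eta:  # axial cone: orientation is sign-free
            continue
        selected.append(np.unravel_index(v, vol.shape[:-1]))
        sel_signals.append(norm)
    sig_arr = (
        np.array(sel_signals) if sel_signals else np.empty((0, n_rows))
    )
    avg = sig_arr.mean(axis=0) if len(sel_signals) else np.full(n_rows, np.nan)
    return VoxelSet(
        voxel_indices=selected,
        signals=sig_arr,
        averaged=avg,
        fa_threshold=fa_threshold,
        eta_deg=eta_deg,
        axis=axis,
    )
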