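"""SVD spatiotemporal clutter filtering, dual-aperture ASAP combination,
and intensity thresholding.

A volume sequence is reshaped into a Casorati matrix (voxels x frames); its
lowest-order singular components capture static and slowly varying echoes
(tube walls), which are removed to isolate moving microbubbles.  The two
independently beamformed aperture sequences are then combined by acoustic
sub-aperture processing (ASAP): the magnitude of their zero-lag slow-time
cross-correlation over a short window, square-rooted back to amplitude
units.  Electronic noise is independent between the apertures and averages
out of the cross-correlation, while the common bubble signal survives.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "to_casorati",
    "from_casorati",
    "singular_values",
    "svd_filter",
    "asap_combine",
    "intensity_threshold",
]


def to_casorati(seq: np.ndarray) -> tuple[np.ndarray, tuple[int, ...]]:
    """Reshape (frames, *volume) into a (voxels, frames) Casorati matrix."""
    seq = np.asarray(seq)
    shape = seq.shape
    return seq.reshape(shape[0], -1).T, shape


def from_casorati(mat: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    return mat.T.reshape(shape)


def _temporal_basis(mat: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Right singular vectors and singular values via the frame Gram matrix.

    Economical for the typical voxels >> frames case; returns (V, s) with V
    unitary (frames x frames) and s descending.
    """
    gram = mat.conj().T @ mat
    w, V = np.linalg.eigh(gram)
    order = np.argsort(w)[::-1]
    s = np.sqrt(np.clip(w[order], 0.0, None))
    return V[:, order], s


def _top_temporal_vectors(mat: np.ndarray, k: int) -> np.ndarray:
    """Leading k right singular vectors, by partial or full decomposition."""
    n_frames = mat.shape[1]
    if k >= min(mat.shape) // 4 or n_frames < 64:
        return _temporal_basis(mat)[0][:, :k]
    from scipy.sparse.linalg import LinearOperator, eigsh

    out_dtype = np.complex128 if np.iscomplexobj(mat) else np.float64

    def gram_op(x):
        x = np.asarray(x, dtype=mat.dtype).ravel()
        return (mat.conj().T @ (mat @ x)).astype(out_dtype)

    op = LinearOperator((n_frames, n_frames), matvec=gram_op, dtype=out_dtype)
    v0 = np.ones(n_frames) / np.sqrt(n_frames)  # deterministic start
    _, V = eigsh(op, k=k, which="LA", v0=v0)
    return np.ascontiguousarray(V[:, ::-1]).astype(mat.dtype, copy=False)


def singular_values(seq: np.ndarray, n_values: int | None = None) -> np.ndarray:
    """Singular-value spectrum of the Casorati matrix of ``seq``.

    With ``n_values`` only the leading part of the spectrum is computed,
    which is much cheaper for long sequences.
    """
    mat, _ = to_casorati(seq)
    if n_values is not None and n_values < min(mat.shape) // 4 and mat.shape[1] >= 64:
        from scipy.sparse.linalg import LinearOperator, eigsh

        n_frames = mat.shape[1]
        out_dtype = np.complex128 if np.iscomplexobj(mat) else np.float64

        def gram_op(x):
            x = np.asarray(x, dtype=mat.dtype).ravel()
            return (mat.conj().T @ (mat @ x)).astype(out_dtype)

        op = LinearOperator((n_frames, n_frames), matvec=gram_op, dtype=out_dtype)
        v0 = np.ones(n_frames) / np.sqrt(n_frames)
        w = eigsh(op, k=n_values, which="LA", v0=v0, return_eigenvectors=False)
        return np.sqrt(np.clip(w[::-1], 0.0, None))
    s = _temporal_basis(mat)[1]
    return s if n_values is None else s[:n_values]


def svd_filter(seq: np.ndarray, k_low: int, k_high: int | None = None) -> np.ndarray:
    """Keep singular components [k_low, k_high) of the Casorati matrix.

    ``k_low = 0, k_high = None`` is the identity; the retained and removed
    parts sum to the input exactly (the temporal basis is unitary).
    """
    mat, shape = to_casorati(seq)
    n_vox, n_frames = mat.shape
    if not 0 <= k_low < min(n_vox, n_frames) + 1:
        raise ValueError("k_low out of range")
    if k_high is not None and k_high <= k_low:
        raise ValueError("k_high must exceed k_low")
    if k_low == 0 and (k_high is None or k_high >= n_frames):
        return np.asarray(seq).copy()
    if k_high is None or k_high >= n_frames:
        # subtracting the removed (low-order) band is much cheaper than
        # projecting onto the kept band when the kept band is the long tail
        Vr = _top_temporal_vectors(mat, k_low)
        out = (mat @ Vr) @ Vr.conj().T
        np.subtract(mat, out, out=out)
    else:
        V, _ = _temporal_basis(mat)
        Vk = V[:, k_low:k_high]
        out = (mat @ Vk) @ Vk.conj().T
    if not np.iscomplexobj(seq):
        out = out.real
    return from_casorati(out, shape).astype(seq.dtype, copy=False)


def asap_combine(seq_a: np.ndarray, seq_b: np.ndarray, window: int = 2) -> np.ndarray:
    """Dual-aperture combination by windowed zero-lag cross-correlation.

    Output amplitude = sqrt(|<A conj(B)>_window|) voxelwise, where the mean
    runs over ``window`` consecutive frames (same-length output, edge frames
    use the available neighbors).  Symmetric in its two inputs.
    """
    seq_a = np.asarray(seq_a)
    seq_b = np.asarray(seq_b)
    if seq_a.shape != seq_b.shape:
        raise ValueError("aperture sequences must share shape and grid")
    if window < 1:
        raise ValueError("window must be >= 1")
    prod = seq_a * np.conj(seq_b)
    if window > 1:
        prod = _moving_mean_frames(prod, window)
    out = np.abs(prod)
    np.sqrt(out, out=out)
    return out


def _moving_mean_frames(a: np.ndarray, window: int) -> np.ndarray:
    """Centered moving mean along axis 0 with edge replication.

    Shift-and-add formulation: one output allocation, no padded copy, so
    long sequences stay within memory.
    """
    n = a.shape[0]
    left = window // 2
    out = np.zeros_like(a)
    for off in range(-left, window - left):
        src = np.clip(np.arange(n) + off, 0, n - 1)
        out += a[src]
    out /= window
    return out


def intensity_threshold(
    volume: np.ndarray, threshold: float, db_relative: bool = True,
    ref: float | None = None,
) -> np.ndarray:
    """Boolean mask of voxels at or above the threshold.

    With ``db_relative`` the threshold is in dB below the reference amplitude
    (``ref``, default the volume maximum), e.g. -30; otherwise it is an
    absolute amplitude.
    """
    amp = np.abs(np.asarray(volume))
    if db_relative:
        if ref is None:
            ref = amp.max()
        level = ref * 10.0 ** (threshold / 20.0)
    else:
        level = threshold
    return amp >= level
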