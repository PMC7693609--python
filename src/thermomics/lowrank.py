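"""PCT and sparse PCT decompositions of the heat matrix, and avatars.

PCT (principal component thermography) is the economy SVD X = U Gamma V^T
of the centered p x n heat matrix; the first k left singular vectors,
reshaped to the ROI, are spatial basis images exposing spatiotemporal
variance patterns.

Sparse PCT replaces each principal direction with the penalized variance
maximizer

    max_u  u^T (X X^T) u   s.t.  ||u||_2 = 1,  plus an l1 penalty
                                  (and optional l2 / ridge shrinkage)
                                  or a hard cardinality cap ||u||_0 <= c,

solved by a soft-thresholding / truncated power iteration with projection
deflation between components. With both penalties at zero the iteration
reduces exactly to ordinary power iteration, i.e. to PCT.

The avatar stacks the first three basis images, each min-max normalized to
[0, 1], center-cropped square and resized, as the three channels of the
backbone input image.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from skimage.transform import resize

from .errors import ConvergenceWarning, ValidationError
from .thermal_io import HeatMatrix

__all__ = [
    "BasisSet",
    "Avatar",
    "pct",
    "sparse_pct",
    "variance_fraction",
    "make_avatar",
]


@dataclass
class BasisSet:
    """Spatial basis images and spectrum from a heat-matrix decomposition."""

    bases: list[np.ndarray]           # k images of ROI shape
    singular_values: np.ndarray       # length k, non-increasing, >= 0
    coefficients: np.ndarray          # n x k (columns of V)
    k: int
    method: str                       # {pct, sparse_pct}
    roi_shape: tuple[int, int]
    converged: bool = True
    n_iterations: list[int] = field(default_factory=list)

    @property
    def sparsity(self) -> np.ndarray:
        """Fraction of (near-)zero entries per basis."""
        return np.array([np.mean(np.abs(b) < 1e-12) for b in self.bases])

    def basis_vector(self, i: int) -> np.ndarray:
        return self.bases[i].ravel()


@dataclass
class Avatar:
    """Square 3-channel image feeding the backbone (channels = beta1..3)."""

    image: np.ndarray                 # side x side x 3, values in [0, 1]
    side: int = 224
    channel_order: tuple[str, str, str] = ("beta1", "beta2", "beta3")

    def __post_init__(self) -> None:
        self.image = np.asarray(self.image, dtype=np.float64)
        if self.image.shape != (self.side, self.side, 3):
            raise ValidationError(
                f"avatar image shape {self.image.shape} != ({self.side}, {self.side}, 3)"
            )
        if not np.all(np.isfinite(self.image)):
            raise ValidationError("avatar contains non-finite values")
        if self.image.min() < -1e-9 or self.image.max() > 1 + 1e-9:
            raise ValidationError("avatar values must lie in [0, 1]")


def _fix_signs(u: np.ndarray) -> np.ndarray:
    """Deterministic sign convention: largest-magnitude entry positive."""
    idx = np.argmax(np.abs(u))
    return -u if u[idx] < 0 else u


def pct(hm: HeatMatrix, k: int) -> BasisSet:
    """Principal component thermography: first k left singular vectors of X."""
    n = hm.n
    if not 1 <= k <= n:
        raise ValidationError(f"k={k} out of range [1, {n}]")
    U, s, Vt = np.linalg.svd(hm.X, full_matrices=False)
    bases = []
    V = Vt.T[:, :k].copy()
    for i in range(k):
        u = _fix_signs(U[:, i])
        if not np.allclose(u, U[:, i]):
            V[:, i] = -V[:, i]
        bases.append(u.reshape(hm.roi_shape))
    return BasisSet(bases=bases, singular_values=s[:k].copy(), coefficients=V,
                    k=k, method="pct", roi_shape=hm.roi_shape)


def _soft(z: np.ndarray, t: float) -> np.ndarray:
    return np.sign(z) * np.maximum(np.abs(z) - t, 0.0)


def _sparse_direction(X: np.ndarray, lambda1: float, lambda2: float,
                      card: int | None, max_iter: int, tol: float,
                      u0: np.ndarray) -> tuple[np.ndarray, int, bool]:
    """Penalized power iteration for one direction on S = X X^T (implicit)."""
    u = u0 / np.linalg.norm(u0)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        z = X @ (X.T @ u)
        if lambda2 > 0:
            z = z / (1.0 + lambda2)
        nz = np.linalg.norm(z)
        if nz == 0:          # direction annihilated (rank exhausted)
            return u, it, True
        z = z / nz
        if lambda1 > 0:
            z = _soft(z, lambda1)
            if not np.any(z):
                # threshold wiped everything: keep the single largest entry
                z = np.zeros_like(u)
                w = X @ (X.T @ u)
                z[np.argmax(np.abs(w))] = 1.0
        if card is not None and card < z.size:
            keep = np.argpartition(np.abs(z), -card)[-card:]
            mask = np.zeros_like(z)
            mask[keep] = z[keep]
            z = mask
        z = z / np.linalg.norm(z)
        if np.linalg.norm(z - np.sign(z @ u + 1e-300) * u) < tol:
            u = z
            converged = True
            break
        u = z
    return _fix_signs(u), it, converged


def sparse_pct(hm: HeatMatrix, k: int, lambda1: float = 0.0, lambda2: float = 0.0,
               max_iter: int = 1000, tol: float = 1e-10,
               card: int | None = None, seed: int = 0) -> BasisSet:
    """Sparse PCT via penalized power iteration with projection deflation.

    Parameters
    ----------
    lambda1, lambda2
        l1 soft-threshold level (applied to the unit-normalized update,
        so values in [0, 1) are meaningful) and l2 ridge shrinkage.
    card
        optional hard cardinality cap on non-zero entries per basis
        (truncated power iteration).

    With ``lambda1 = lambda2 = 0`` and no cap, components equal PCT
    components up to sign. Warns (and still returns) on non-convergence.
    """
    n = hm.n
    if not 1 <= k <= n:
        raise ValidationError(f"k={k} out of range [1, {n}]")
    if lambda1 < 0 or lambda2 < 0:
        raise ValidationError("penalties must be non-negative")
    X = hm.X.copy()
    rng = np.random.default_rng(seed)
    bases, svals, coeffs, iters = [], [], [], []
    all_converged = True
    for _ in range(k):
        # deterministic warm start: dominant row direction, fallback random
        u0 = X @ X.sum(axis=0)
        if np.linalg.norm(u0) < 1e-300:
            u0 = rng.standard_normal(X.shape[0])
        u, it, conv = _sparse_direction(X, lambda1, lambda2, card, max_iter, tol, u0)
        all_converged &= conv
        iters.append(it)
        proj = X.T @ u                     # length n
        sigma = np.linalg.norm(proj)
        svals.append(sigma)
        coeffs.append(proj / sigma if sigma > 0 else np.zeros(n))
        bases.append(u.reshape(hm.roi_shape))
        X = X - np.outer(u, proj)          # projection deflation
    if not all_converged:
        warnings.warn(
            f"sparse_pct: power iteration hit max_iter={max_iter} before tol={tol}",
            ConvergenceWarning, stacklevel=2,
        )
    order = np.argsort(svals)[::-1]        # deflation can disorder the spectrum
    return BasisSet(
        bases=[bases[i] for i in order],
        singular_values=np.array([svals[i] for i in order]),
        coefficients=np.stack([coeffs[i] for i in order], axis=1),
        k=k, method="sparse_pct", roi_shape=hm.roi_shape,
        converged=all_converged, n_iterations=[iters[i] for i in order],
    )


def variance_fraction(bs: BasisSet, threshold: float) -> int:
    """Smallest m whose cumulative squared singular values reach ``threshold``."""
    if not 0 < threshold <= 1:
        raise ValidationError("threshold must be in (0, 1]")
    s2 = np.asarray(bs.singular_values, dtype=float) ** 2
    if s2.size == 0 or s2.sum() == 0:
        raise ValidationError("empty or all-zero singular spectrum")
    frac = np.cumsum(s2) / s2.sum()
    return int(np.searchsorted(frac, threshold - 1e-12) + 1)


def _normalize01(img: np.ndarray) -> np.ndarray:
    lo, hi = float(img.min()), float(img.max())
    if hi - lo < 1e-300:
        return np.zeros_like(img)
    return (img - lo) / (hi - lo)


def make_avatar(bs: BasisSet, side: int = 224) -> Avatar:
    """Stack the first three bases as channels of a side x side image.

    Each basis is min-max normalized to [0, 1] independently (a constant
    basis maps to all zeros), center-cropped to a square, and resized with
    bilinear interpolation.
    """
    if bs.k < 3 or len(bs.bases) < 3:
        raise ValidationError(
            f"avatar needs at least 3 bases, got {len(bs.bases)}"
        )
    channels = []
    for b in bs.bases[:3]:
        img = _normalize01(np.asarray(b, dtype=np.float64))
        h, w = img.shape
        s = min(h, w)
        r0, c0 = (h - s) // 2, (w - s) // 2
        img = img[r0:r0 + s, c0:c0 + s]
        if s != side:
            img = resize(img, (side, side), order=1, mode="edge",
                         anti_aliasing=False, preserve_range=True)
        channels.append(np.clip(img, 0.0, 1.0))
    return Avatar(image=np.stack(channels, axis=-1), side=side)
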