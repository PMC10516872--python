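"""Scalar features of episode segments: mean value and K-SVD dictionary codes.

Each (channel, episode) ΔCOE segment is reduced to one scalar either by its
arithmetic mean (μmol/L) or by sparse coding against a dictionary learned
with K-SVD: alternating Orthogonal Matching Pursuit (at most ``T0`` nonzero
coefficients per segment) with per-atom rank-1 SVD updates of the atom and
its coefficients over the segments that use it.

Because the sign of a singular vector is arbitrary, K-SVD codes of the same
data can come out with opposite signs on different runs.  Atoms are
therefore canonicalised by default (first non-negligible coordinate made
positive), which makes runs reproducible; the ambiguity itself can be
observed by learning with ``canonicalize=False`` and different seeds.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.linear_model import orthogonal_mp

__all__ = [
    "EpisodeMatrix",
    "Dictionary",
    "resample_segment",
    "mean_feature",
    "ksvd_learn",
    "ksvd_feature",
]


@dataclass
class EpisodeMatrix:
    """Episode segments as rows of a fixed-length matrix, with row metadata."""

    X: np.ndarray  # (n_episodes, segment_length)
    meta: pd.DataFrame  # one row per episode: sample id, scenario, channel, risk class

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, float)
        if self.X.ndim != 2:
            raise ValueError("episode matrix must be 2-D")
        if not np.isfinite(self.X).all():
            raise ValueError("episode matrix contains non-finite values")
        if len(self.meta) != self.X.shape[0]:
            raise ValueError("metadata rows must match matrix rows")


@dataclass
class Dictionary:
    """Unit-norm atoms (columns of ``D``) with learning metadata."""

    D: np.ndarray  # (segment_length, K)
    K: int
    T0: int
    n_iter: int
    seed: int | None
    final_residual: float
    error_history: list[float] = field(default_factory=list)
    canonical: bool = True

    def save(self, path: str | Path) -> None:
        """Serialise atoms + metadata to a CSV bundle (atoms as columns)."""
        path = Path(path)
        header = (
            f"# K={self.K} T0={self.T0} n_iter={self.n_iter} seed={self.seed} "
            f"final_residual={self.final_residual!r} canonical={self.canonical}\n"
        )
        with open(path, "w") as fh:
            fh.write(header)
            pd.DataFrame(self.D, columns=[f"atom_{k}" for k in range(self.K)]).to_csv(
                fh, index=False
            )

    @classmethod
    def load(cls, path: str | Path) -> "Dictionary":
        path = Path(path)
        with open(path) as fh:
            meta_line = fh.readline().lstrip("# ").split()
            kv = dict(item.split("=", 1) for item in meta_line)
            df = pd.read_csv(fh)
        return cls(
            D=df.to_numpy(),
            K=int(kv["K"]),
            T0=int(kv["T0"]),
            n_iter=int(kv["n_iter"]),
            seed=None if kv["seed"] == "None" else int(kv["seed"]),
            final_residual=float(kv["final_residual"]),
            canonical=kv["canonical"] == "True",
        )


def resample_segment(x: np.ndarray, n_points: int = 64) -> np.ndarray:
    """Linearly resample a segment to a fixed number of points."""
    x = np.asarray(x, float)
    if x.size < 2:
        raise ValueError("segment too short to resample")
    src = np.linspace(0.0, 1.0, x.size)
    dst = np.linspace(0.0, 1.0, n_points)
    return np.interp(dst, src, x)


def mean_feature(segment) -> float:
    """Arithmetic mean of a segment (μmol/L for ΔCOE input)."""
    segment = np.asarray(segment, float)
    if segment.size == 0:
        raise ValueError("empty segment")
    return float(segment.mean())


def _canonicalize(D: np.ndarray, codes: np.ndarray | None = None, tol: float = 1e-10):
    """Flip atom signs so the first non-negligible coordinate is positive."""
    D = D.copy()
    for k in range(D.shape[1]):
        nz = np.flatnonzero(np.abs(D[:, k]) > tol)
        if nz.size and D[nz[0], k] < 0:
            D[:, k] = -D[:, k]
            if codes is not None:
                codes[:, k] = -codes[:, k]
    return D, codes


def _sparse_code(X: np.ndarray, D: np.ndarray, T0: int) -> np.ndarray:
    """OMP codes (rows of X against atom columns of D), ≤ T0 nonzeros each."""
    if T0 == 1:
        # closed form: best single atom by absolute correlation
        corr = X @ D  # atoms are unit norm
        k = np.argmax(np.abs(corr), axis=1)
        codes = np.zeros((X.shape[0], D.shape[1]))
        codes[np.arange(X.shape[0]), k] = corr[np.arange(X.shape[0]), k]
        return codes
    codes = orthogonal_mp(D, X.T, n_nonzero_coefs=T0)
    return np.atleast_2d(codes).T if codes.ndim == 1 else codes.T


def ksvd_learn(
    X: EpisodeMatrix | np.ndarray,
    K: int = 4,
    T0: int = 1,
    n_iter: int = 15,
    seed: int | None = None,
    canonicalize: bool = True,
) -> tuple[Dictionary, np.ndarray]:
    """Learn a K-atom dictionary by K-SVD and return (Dictionary, codes).

    Atoms are initialised from K distinct data rows chosen by the seeded
    RNG.  After each sweep every atom has unit norm, and the Frobenius
    reconstruction error is non-increasing across sweeps (up to 1e-9).
    Unused atoms are re-initialised to the currently worst-represented row.
    """
    A = X.X if isinstance(X, EpisodeMatrix) else np.asarray(X, float)
    if A.ndim != 2:
        raise ValueError("data must be 2-D (episodes × time points)")
    n, L = A.shape
    norms = np.linalg.norm(A, axis=1)
    if not np.any(norms > 0):
        raise ValueError("all-zero data: nothing to learn")
    if not 1 <= T0 <= K:
        raise ValueError("need 1 <= T0 <= K")

    rng = np.random.default_rng(seed)
    candidates = np.flatnonzero(norms > 0)
    picks = rng.choice(candidates, size=min(K, candidates.size), replace=False)
    D = np.empty((L, K))
    for k in range(K):
        row = A[picks[k % picks.size]] + (1e-12 * rng.standard_normal(L) if k >= picks.size else 0.0)
        D[:, k] = row / np.linalg.norm(row)

    errors: list[float] = []
    codes = _sparse_code(A, D, T0)
    for _ in range(n_iter):
        for k in range(K):
            support = np.flatnonzero(codes[:, k] != 0)
            if support.size == 0:
                # repair: re-seed the atom with the worst-represented row
                resid_norm = np.linalg.norm(A - codes @ D.T, axis=1)
                worst = int(np.argmax(resid_norm))
                if resid_norm[worst] > 0:
                    D[:, k] = A[worst] / np.linalg.norm(A[worst])
                continue
            # residual of the supported rows without atom k's contribution
            E = (
                A[support]
                - codes[support] @ D.T
                + np.outer(codes[support, k], D[:, k])
            )
            U, s, Vt = np.linalg.svd(E, full_matrices=False)
            D[:, k] = Vt[0]
            codes[support, k] = s[0] * U[:, 0]
        codes = _sparse_code(A, D, T0)
        errors.append(float(np.linalg.norm(A - codes @ D.T)))

    if canonicalize:
        D, codes = _canonicalize(D, codes)
    d = Dictionary(
        D=D,
        K=K,
        T0=T0,
        n_iter=n_iter,
        seed=seed,
        final_residual=errors[-1] if errors else float(np.linalg.norm(A - codes @ D.T)),
        error_history=errors,
        canonical=canonicalize,
    )
    return d, codes


def ksvd_feature(segment, D: Dictionary | np.ndarray) -> tuple[float, int | None]:
    """Single-atom OMP code of a segment: (coefficient, atom index).

    The selected atom maximises |⟨segment, atom⟩|; the feature is its signed
    coefficient.  A segment orthogonal to every atom yields (0.0, None).
    """
    atoms = D.D if isinstance(D, Dictionary) else np.asarray(D, float)
    segment = np.asarray(segment, float)
    if segment.size != atoms.shape[0]:
        raise ValueError(
            f"segment length {segment.size} does not match atom length {atoms.shape[0]}"
        )
    corr = atoms.T @ segment
    k = int(np.argmax(np.abs(corr)))
    if abs(corr[k]) < 1e-12:
        return 0.0, None
    return float(corr[k]), k
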