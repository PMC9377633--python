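"""Generators for upper-triangular connectivity with controlled spectrum.

A real matrix in real-Schur form reads ``W = Lambda + T``: ``Lambda`` is
block diagonal (real eigenvalues on the diagonal, each complex-conjugate
pair ``alpha +/- i beta`` as a 2x2 rotation-like block
``[[alpha, -beta], [beta, alpha]]``) and ``T`` is strictly upper triangular,
encoding the feedforward coupling between the orthogonal Schur modes.
Sampling ``Lambda`` and ``T`` independently gives direct, independent
control over the eigenspectrum and the degree of non-normality, which a
direct parameterisation of a dense connectivity matrix does not allow.

Conventions:
- the *spectrum norm* is the Frobenius norm of ``Lambda``
  (``sqrt(sum |lambda_k|^2)``), the *feedforward norm* that of ``T``;
- entries of ``T`` at the super-diagonal cells occupied by the 2x2
  eigenvalue blocks are identically zero (those cells belong to
  ``Lambda``);
- the two norms are orthogonal components:
  ``||W||_F^2 = ||Lambda||_F^2 + ||T||_F^2``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import schur
from scipy.stats import ortho_group

__all__ = [
    "SpectrumSpec",
    "FeedforwardSpec",
    "UpperTriangularNetwork",
    "sample_spectrum",
    "default_n_real",
    "assemble",
    "sample_feedforward",
    "scale_feedforward",
    "scale_spectrum_to_norm",
    "split_norm",
    "rotate_to_recurrent",
    "build_network",
    "soc_feedforward_template",
]

#: Stability supremum for real parts used throughout (max Re(lambda) < 1 is
#: required; 0.5 leaves a uniform decay margin).
ALPHA_SUP = 0.5


def default_n_real(N: int) -> int:
    """Number of purely real eigenvalues: 3% of N, complement forced even."""
    n_real = int(round(0.03 * N))
    if (N - n_real) % 2:
        n_real += 1
    return n_real


@dataclass(frozen=True)
class SpectrumSpec:
    """Recipe for sampling an eigenspectrum of size N.

    real_kind:
        - ``uniform_interval``: Re(lambda) ~ U(sup - d_re, sup).
        - ``single_value``: all real parts equal ``value``.
        - ``outlier_zero_trace``: M = |outlier|/sup eigenvalues at ``sup``,
          one purely real outlier at ``outlier``, the rest at 0, so that
          the real parts sum to zero (the no-autapse condition).
        - ``uniform_with_small_outlier``: Re ~ U(-sup, sup) plus one purely
          real balancing eigenvalue enforcing a zero sum.
    imag_kind:
        - ``uniform``: Im ~ U(-d_im/2, d_im/2) in conjugate pairs.
        - ``clustered``: |Im| ~ U(center - radius, center + radius).
    """

    N: int
    real_kind: str = "uniform_with_small_outlier"
    d_re: float = 1.0
    sup: float = ALPHA_SUP
    value: float = 0.0
    outlier: float = 0.0
    imag_kind: str = "uniform"
    d_im: float = 20.0
    cluster_center: float = 0.0
    cluster_radius: float = 0.0
    n_real: int | None = None

    def resolved_n_real(self) -> int:
        n_real = default_n_real(self.N) if self.n_real is None else self.n_real
        if (self.N - n_real) % 2:
            raise ValueError("N - n_real must be even (conjugate pairs)")
        return n_real


@dataclass(frozen=True)
class FeedforwardSpec:
    """Recipe for the strictly-upper feedforward structure T.

    kind:
        - ``uniform``: entries U(-0.5, 0.5) at every allowed position.
        - ``sparse``: uniform entries kept with probability ``sparsity``.
        - ``chain2``: only the first super-diagonal (each Schur mode feeds
          the next one).
        - ``soc_derived``: strictly-upper part of the real Schur form of a
          stability-optimised Dalean matrix (pass it as ``template``).
    The result is rescaled to Frobenius norm ``target_norm``.
    """

    kind: str = "uniform"
    target_norm: float = 75.0
    sparsity: float = 0.1
    template: np.ndarray | None = None


@dataclass
class UpperTriangularNetwork:
    """W = Lambda + T with bookkeeping of both parts."""

    W: np.ndarray
    Lambda: np.ndarray
    T: np.ndarray
    eigenvalues: np.ndarray        # requested spectrum, block order
    block_starts: np.ndarray       # index of the first row of each 2x2 block

    @property
    def N(self) -> int:
        return self.W.shape[0]

    @property
    def spectrum_norm(self) -> float:
        return float(np.linalg.norm(self.Lambda, "fro"))

    @property
    def feedforward_norm(self) -> float:
        return float(np.linalg.norm(self.T, "fro"))


def _real_parts(spec: SpectrumSpec, n_pairs: int, n_real: int, rng: np.random.Generator):
    """Sample real parts for the pair slots and the purely-real slots."""
    kind = spec.real_kind
    if kind == "uniform_interval":
        pair_re = rng.uniform(spec.sup - spec.d_re, spec.sup, n_pairs)
        real_re = rng.uniform(spec.sup - spec.d_re, spec.sup, n_real)
    elif kind == "single_value":
        pair_re = np.full(n_pairs, spec.value)
        real_re = np.full(n_real, spec.value)
    elif kind == "uniform_with_small_outlier":
        if n_real < 1:
            raise ValueError("zero-trace balancing needs at least one real slot")
        # the balancing eigenvalue must itself respect the stability
        # supremum; reject draws whose running sum would violate it
        for _ in range(1000):
            pair_re = rng.uniform(-spec.sup, spec.sup, n_pairs)
            real_re = np.empty(n_real)
            real_re[: n_real - 1] = rng.uniform(-spec.sup, spec.sup, n_real - 1)
            real_re[n_real - 1] = -(2.0 * pair_re.sum() + real_re[: n_real - 1].sum())
            if real_re[n_real - 1] < spec.sup:
                break
        else:  # pragma: no cover - p(reject) ~ 0.5 per draw
            raise RuntimeError("could not draw an admissible balancing eigenvalue")
    elif kind == "outlier_zero_trace":
        if n_real < 1:
            raise ValueError("the outlier must occupy a purely real slot")
        outlier = float(spec.outlier)
        M_exact = abs(outlier) / spec.sup
        M = int(round(M_exact))
        if abs(M - M_exact) > 1e-12:
            outlier = -np.sign(outlier or -1.0) * 0.0 + (-spec.sup * M)
            warnings.warn(
                f"|outlier|/sup = {M_exact:g} is not an integer; rounded to "
                f"M = {M} eigenvalues at {spec.sup} and re-balanced the "
                f"outlier to {outlier:g}",
                UserWarning,
            )
        else:
            outlier = -spec.sup * M
        n_half_pairs = min(M // 2, n_pairs)
        leftover = M - 2 * n_half_pairs
        if leftover > n_real - 1:
            raise ValueError("not enough eigenvalue slots for the requested outlier")
        pair_re = np.zeros(n_pairs)
        idx = rng.permutation(n_pairs)[:n_half_pairs]
        pair_re[idx] = spec.sup
        real_re = np.zeros(n_real)
        real_re[:leftover] = spec.sup
        real_re[n_real - 1] = outlier
    else:
        raise ValueError(f"unknown real_kind {kind!r}")
    return pair_re, real_re


def sample_spectrum(spec: SpectrumSpec, rng: np.random.Generator) -> np.ndarray:
    """Sample N eigenvalues honouring conjugacy and the requested recipe.

    Returns a complex array in *block order*: each conjugate pair occupies
    two adjacent entries (alpha + i beta followed by alpha - i beta), and
    the position of the purely real eigenvalues among the pairs is
    randomised.  Real/imaginary pairings are random except that conjugate
    imaginary parts share a real part.
    """
    n_real = spec.resolved_n_real()
    n_pairs = (spec.N - n_real) // 2

    pair_re, real_re = _real_parts(spec, n_pairs, n_real, rng)

    if spec.imag_kind == "uniform":
        beta = rng.uniform(0.0, spec.d_im / 2.0, n_pairs)
    elif spec.imag_kind == "clustered":
        beta = rng.uniform(
            spec.cluster_center - spec.cluster_radius,
            spec.cluster_center + spec.cluster_radius,
            n_pairs,
        )
    else:
        raise ValueError(f"unknown imag_kind {spec.imag_kind!r}")

    # interleave pairs and reals in a random block order
    blocks: list[np.ndarray] = [
        np.array([a + 1j * b, a - 1j * b]) for a, b in zip(pair_re, beta)
    ] + [np.array([g + 0j]) for g in real_re]
    order = rng.permutation(len(blocks))
    return np.concatenate([blocks[i] for i in order])


def _block_layout(spectrum: np.ndarray):
    """Walk the block-ordered spectrum; return block start indices."""
    starts = []
    i = 0
    N = spectrum.size
    while i < N:
        if abs(spectrum[i].imag) > 0:
            if i + 1 >= N or not np.isclose(spectrum[i + 1], spectrum[i].conjugate()):
                raise ValueError("complex eigenvalues must come in adjacent conjugate pairs")
            starts.append(i)
            i += 2
        else:
            i += 1
    return np.asarray(starts, dtype=int)


def block_mask(spectrum: np.ndarray) -> np.ndarray:
    """Boolean mask of strictly-upper positions *excluded* from T (the
    super-diagonal cells inside the 2x2 eigenvalue blocks)."""
    N = spectrum.size
    mask = np.zeros((N, N), dtype=bool)
    for s in _block_layout(spectrum):
        mask[s, s + 1] = True
    return mask


def assemble(spectrum: np.ndarray, T: np.ndarray) -> UpperTriangularNetwork:
    """Place the spectrum on the (block-)diagonal and add T.

    Real eigenvalues go on the diagonal; each conjugate pair
    ``alpha +/- i beta`` becomes the block ``[[alpha, -beta], [beta, alpha]]``.
    T must be strictly upper triangular and zero at the in-block cells.
    """
    spectrum = np.asarray(spectrum, dtype=complex)
    N = spectrum.size
    T = np.asarray(T, dtype=float)
    if T.shape != (N, N):
        raise ValueError("T has wrong dimensions for this spectrum")
    if np.any(np.tril(T) != 0):
        raise ValueError("T must be strictly upper triangular")
    starts = _block_layout(spectrum)
    Lam = np.zeros((N, N))
    i = 0
    while i < N:
        lam = spectrum[i]
        if abs(lam.imag) > 0:
            a, b = lam.real, lam.imag
            Lam[i, i] = Lam[i + 1, i + 1] = a
            Lam[i, i + 1] = -b
            Lam[i + 1, i] = b
            i += 2
        else:
            Lam[i, i] = lam.real
            i += 1
    if np.any(T[block_mask(spectrum)] != 0):
        raise ValueError("T must vanish at the 2x2 eigenvalue-block cells")
    return UpperTriangularNetwork(
        W=Lam + T, Lambda=Lam, T=T, eigenvalues=spectrum, block_starts=starts
    )


def sample_feedforward(
    spec: FeedforwardSpec, spectrum: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Draw a strictly-upper T compatible with the spectrum's block layout
    and scale it to the requested Frobenius norm."""
    N = spectrum.size
    allowed = np.triu(np.ones((N, N), dtype=bool), k=1) & ~block_mask(spectrum)
    if spec.kind == "uniform":
        T = np.where(allowed, rng.uniform(-0.5, 0.5, (N, N)), 0.0)
    elif spec.kind == "sparse":
        keep = rng.random((N, N)) < spec.sparsity
        T = np.where(allowed & keep, rng.uniform(-0.5, 0.5, (N, N)), 0.0)
    elif spec.kind == "chain2":
        T = np.zeros((N, N))
        sup = np.eye(N, k=1, dtype=bool) & allowed
        T[sup] = rng.uniform(-0.5, 0.5, int(sup.sum()))
    elif spec.kind == "soc_derived":
        if spec.template is None:
            raise ValueError("soc_derived feedforward needs a template matrix")
        T = np.triu(np.asarray(spec.template, dtype=float), k=1)
        T = np.where(allowed, T, 0.0)
    else:
        raise ValueError(f"unknown feedforward kind {spec.kind!r}")
    if spec.target_norm == 0:
        return np.zeros((N, N))
    return scale_feedforward(T, spec.target_norm)


def scale_feedforward(T: np.ndarray, target_norm: float) -> np.ndarray:
    """Linearly rescale T to Frobenius norm ``target_norm``."""
    nrm = np.linalg.norm(T, "fro")
    if target_norm == 0:
        return np.zeros_like(T)
    if nrm == 0:
        raise ValueError("cannot rescale an all-zero T to a nonzero norm")
    return T * (target_norm / nrm)


def scale_spectrum_to_norm(spectrum: np.ndarray, target_norm: float) -> np.ndarray:
    """Rescale the *imaginary* parts so that ``sqrt(sum |lambda|^2)`` hits
    the target.

    Real parts are left untouched: they are capped near 0.5 by the
    stability requirement and cannot carry a large spectrum norm, whereas
    the imaginary diameter is unconstrained.  ``target_norm = 0`` zeroes
    the whole spectrum (nilpotent case).
    """
    spectrum = np.asarray(spectrum, dtype=complex)
    if target_norm == 0:
        return np.zeros_like(spectrum)
    re2 = float(np.sum(spectrum.real**2))
    im2 = float(np.sum(spectrum.imag**2))
    if target_norm**2 < re2:
        raise ValueError(
            f"target norm {target_norm:g} below the norm {np.sqrt(re2):g} "
            "carried by the real parts alone"
        )
    if im2 == 0:
        raise ValueError("spectrum has no imaginary part to rescale")
    c = np.sqrt((target_norm**2 - re2) / im2)
    return spectrum.real + 1j * c * spectrum.imag


def split_norm(
    total_norm: float,
    percent_to_spectrum: float,
    spectrum: np.ndarray,
    T: np.ndarray,
) -> UpperTriangularNetwork:
    """Partition ``total_norm**2`` between spectrum and feedforward parts.

    100% gives a normal matrix (T = 0); 0% a nilpotent one (Lambda = 0).
    """
    if not 0 <= percent_to_spectrum <= 100:
        raise ValueError("percent_to_spectrum must be in [0, 100]")
    frac = percent_to_spectrum / 100.0
    lam_norm = total_norm * np.sqrt(frac)
    ff_norm = total_norm * np.sqrt(1.0 - frac)
    spec_scaled = scale_spectrum_to_norm(spectrum, lam_norm)
    T_scaled = scale_feedforward(T, ff_norm) if ff_norm > 0 else np.zeros_like(T)
    return assemble(spec_scaled, T_scaled)


def rotate_to_recurrent(
    net: UpperTriangularNetwork, rng: np.random.Generator
) -> np.ndarray:
    """Similarity transform by a Haar-random orthogonal matrix.

    ``W_rec = U W U^T`` is a dense recurrent matrix with identical
    eigenvalues, eigenvector-geometry statistics and amplification
    properties (all are orthogonally invariant).
    """
    U = ortho_group.rvs(net.N, random_state=rng)
    return U @ net.W @ U.T


def build_network(
    spectrum_spec: SpectrumSpec,
    feedforward_spec: FeedforwardSpec,
    rng: np.random.Generator,
    spectrum_norm: float | None = None,
) -> UpperTriangularNetwork:
    """Sample spectrum and feedforward structure and assemble the network.

    ``spectrum_norm``, if given, rescales the sampled imaginary parts so
    the spectrum (Frobenius) norm matches it.
    """
    spectrum = sample_spectrum(spectrum_spec, rng)
    if spectrum_norm is not None:
        spectrum = scale_spectrum_to_norm(spectrum, spectrum_norm)
    T = sample_feedforward(feedforward_spec, spectrum, rng)
    return assemble(spectrum, T)


def soc_feedforward_template(W_dale: np.ndarray) -> np.ndarray:
    """Strictly-upper part of the real Schur form of a Dalean matrix.

    Entries belonging to the source's own 2x2 eigenvalue blocks (which
    encode imaginary parts, not feedforward coupling) are removed.  The
    block ordering is the (deterministic) LAPACK one.
    """
    Tform, _ = schur(np.asarray(W_dale, dtype=float), output="real")
    T = np.triu(Tform, k=1)
    # zero the in-block super-diagonal cells of the source's own blocks
    d = np.diag(Tform, -1)
    for i in np.nonzero(np.abs(d) > 1e-12)[0]:
        T[i, i + 1] = 0.0
    return T
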