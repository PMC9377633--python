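"""Eigenvector geometry and dimensionality of the evoked dynamics.

Transient amplification requires non-orthogonal eigenvectors; the metrics
here quantify that geometry and its dynamical footprint:

- pairwise angles between (complex) unit eigenvectors, folded into
  [0, 90] degrees, and the fraction of aligned pairs;
- the effective rank of a matrix — exp of the Shannon entropy of its
  1-norm-normalised singular values — applied to the eigenvector matrix V
  and to the principal-direction matrix P;
- closed forms for a 3x3 upper-triangular toy (one real eigenvalue gamma,
  one conjugate pair alpha +/- i beta, feedforward entries phi_1, phi_2)
  and for the 2x2 excitatory/inhibitory mean-field reduction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.linalg import eig

from .amplification import AMPLIFIED_THRESHOLD, AmplificationReport
from .dynamics import NetworkModel, simulate

__all__ = [
    "GeometryReport",
    "Toy3x3",
    "MeanField2x2",
    "eigvec_angles",
    "eigvec_overlaps",
    "overlap_fraction",
    "effective_rank",
    "build_P",
    "eta_3x3",
    "toy_matrix",
    "meanfield_matrix",
    "meanfield_eigs",
    "geometry_report",
]


@dataclass
class GeometryReport:
    angles: np.ndarray              # condensed pairwise angles, degrees
    percent_small: float            # % of pairs with angle < 45 deg
    percent_big_overlap: float      # % of pairs with |<v_k, v_j>| > 0.7
    erank_V: float
    erank_P: float | None = None    # None when no condition is amplified
    n_amplified: int | None = None


@dataclass(frozen=True)
class Toy3x3:
    """Parameters of the 3x3 upper-triangular toy model."""

    alpha: float
    beta: float
    gamma: float
    phi1: float
    phi2: float

    @property
    def phi_norm(self) -> float:
        return float(np.hypot(self.phi1, self.phi2))


@dataclass(frozen=True)
class MeanField2x2:
    """Mean connection strengths of the two-population reduction (all >= 0)."""

    W_EE: float
    W_EI: float
    W_IE: float
    W_II: float

    def __post_init__(self) -> None:
        if min(self.W_EE, self.W_EI, self.W_IE, self.W_II) < 0:
            raise ValueError("mean-field weights must be non-negative")


def _unit_eigvecs(W: np.ndarray) -> np.ndarray:
    lam, V = eig(np.asarray(W, dtype=float))
    cond = np.linalg.cond(V)
    if cond > 1e14:
        # near-defective matrices (e.g. nilpotent-dominated ones) still
        # yield usable unit eigenvectors for angle/rank statistics; only
        # flag that repeated eigendirections may coincide
        warnings.warn(
            f"eigenvector matrix nearly defective (cond = {cond:.2g}); "
            "angle and rank statistics may degenerate",
            RuntimeWarning,
        )
    return V / np.linalg.norm(V, axis=0)


def eigvec_angles(W: np.ndarray) -> np.ndarray:
    """Pairwise angles (degrees) between unit eigenvectors.

    Uses the complex inner product ``<a, b> = sum_i a_i conj(b_i)``;
    ``cos(theta) = Re<a, b>`` for unit vectors, folded to
    ``min(theta, 180 - theta)`` so angles lie in [0, 90].
    Returns the condensed upper-triangle (N(N-1)/2 values).
    """
    V = _unit_eigvecs(W)
    G = V.conj().T @ V
    iu = np.triu_indices(G.shape[0], k=1)
    cos = np.clip(np.abs(G[iu].real), 0.0, 1.0)
    return np.degrees(np.arccos(cos))


def eigvec_overlaps(W: np.ndarray) -> np.ndarray:
    """Pairwise |<v_k, v_j>| (phase-free overlap moduli), condensed."""
    V = _unit_eigvecs(W)
    G = V.conj().T @ V
    iu = np.triu_indices(G.shape[0], k=1)
    return np.abs(G[iu])


def overlap_fraction(values: np.ndarray, criterion: str = "angle_lt_45") -> float:
    """Percentage of eigenvector pairs meeting an alignment criterion.

    ``angle_lt_45`` expects angles in degrees; ``modulus_gt_0.7`` expects
    overlap moduli.  Both statistics track each other qualitatively.
    """
    values = np.asarray(values, dtype=float)
    if criterion == "angle_lt_45":
        hits = values < 45.0
    elif criterion == "modulus_gt_0.7":
        hits = values > 0.7
    else:
        raise ValueError(f"unknown criterion {criterion!r}")
    return 100.0 * float(np.count_nonzero(hits)) / values.size


def effective_rank(M: np.ndarray) -> float:
    """exp of the Shannon entropy of the 1-norm-normalised singular values.

    A continuous measure of the number of significant dimensions in the
    range of M: N for the identity, 1 for a rank-one matrix, and
    scale-invariant in between.
    """
    M = np.asarray(M)
    sigma = np.linalg.svd(M, compute_uv=False)
    total = sigma.sum()
    if total == 0:
        raise ValueError("effective rank undefined for a zero matrix")
    p = sigma / total
    p = p[p > 0]
    return float(np.exp(-np.sum(p * np.log(p))))


def build_P(
    model: NetworkModel,
    report: AmplificationReport,
    mode: str = "nonlinear",
    variance_mode: str = "first_pc",
    duration: float | None = None,
    dt: float | None = None,
    var_target: float = 0.85,
) -> np.ndarray:
    """Principal directions of the dynamics evoked by amplified conditions.

    For each basis condition whose maximal response norm exceeds the
    amplification threshold, the network is simulated and PCA is run on
    the rate trajectory (time samples as observations, mean over time
    subtracted).  ``first_pc`` stores the leading principal vector per
    condition (N x M); ``var85`` stores, per condition, as many components
    as needed to explain at least ``var_target`` of the variance (N x K).

    Returns an empty (N, 0) matrix when nothing is amplified; its
    effective rank is then undefined.
    """
    if duration is None:
        duration = 100.0 * model.tau
    cols: list[np.ndarray] = []
    for m in np.nonzero(report.amplified_mask)[0]:
        traj = simulate(model, report.basis[:, m], duration=duration, dt=dt, mode=mode)
        R = traj.rates - traj.rates.mean(axis=0)
        _, svals, Vt = np.linalg.svd(R, full_matrices=False)
        if variance_mode == "first_pc":
            cols.append(Vt[0])
        elif variance_mode == "var85":
            var = svals**2
            k = int(np.searchsorted(np.cumsum(var) / var.sum(), var_target) + 1)
            cols.extend(Vt[:k])
        else:
            raise ValueError(f"unknown variance_mode {variance_mode!r}")
    if not cols:
        return np.empty((model.N, 0))
    return np.column_stack(cols)


def toy_matrix(toy: Toy3x3) -> np.ndarray:
    """The 3x3 upper-triangular toy: eigenvalues gamma and alpha -+ i beta,
    feedforward entries phi_1, phi_2 feeding the real eigendirection."""
    return np.array(
        [
            [toy.alpha, toy.beta, toy.phi2],
            [-toy.beta, toy.alpha, toy.phi1],
            [0.0, 0.0, toy.gamma],
        ]
    )


def eta_3x3(toy: Toy3x3) -> float:
    """|eta|: modulus of the normalised inner product of the toy's
    non-orthogonal eigenvector pairs,

        |eta| = phi_norm / sqrt(2 [phi_norm^2 + (alpha - gamma)^2 + beta^2]).

    Grows with the feedforward norm, shrinks with |beta| (the imaginary
    diameter) and with |alpha - gamma| (the real spread).
    """
    denom2 = toy.phi_norm**2 + (toy.alpha - toy.gamma) ** 2 + toy.beta**2
    if denom2 == 0:
        raise ValueError("eta undefined for all-zero toy parameters")
    return float(toy.phi_norm / np.sqrt(2.0 * denom2))


def meanfield_matrix(mf: MeanField2x2) -> np.ndarray:
    """[[W_EE, -W_EI], [W_IE, -W_II]]."""
    return np.array([[mf.W_EE, -mf.W_EI], [mf.W_IE, -mf.W_II]])


def meanfield_eigs(mf: MeanField2x2) -> tuple[complex, complex]:
    """Eigenvalues of the two-population mean-field matrix.

    ``lambda_{1,2} = [(W_EE - W_II) +/- sqrt((W_EE + W_II)^2 - 4 W_EI W_IE)]/2``;
    complex (an oscillatory pair) exactly when
    ``4 W_EI W_IE > (W_EE + W_II)^2``.
    """
    tr_half = 0.5 * (mf.W_EE - mf.W_II)
    disc = (mf.W_EE + mf.W_II) ** 2 - 4.0 * mf.W_EI * mf.W_IE
    root = np.sqrt(complex(disc)) / 2.0
    l1, l2 = tr_half + root, tr_half - root
    if disc >= 0:
        return float(l1.real), float(l2.real)
    return complex(l1), complex(l2)


def geometry_report(
    W: np.ndarray,
    model: NetworkModel | None = None,
    report: AmplificationReport | None = None,
    mode: str = "nonlinear",
    **build_p_kwargs,
) -> GeometryReport:
    """Angles, overlaps, and effective ranks for a connectivity matrix.

    When an amplification report (and its model) is supplied, the
    principal-direction matrix P is built from the amplified conditions
    and its effective rank included.
    """
    angles = eigvec_angles(W)
    overlaps = eigvec_overlaps(W)
    out = GeometryReport(
        angles=angles,
        percent_small=overlap_fraction(angles, "angle_lt_45"),
        percent_big_overlap=overlap_fraction(overlaps, "modulus_gt_0.7"),
        erank_V=effective_rank(_unit_eigvecs(W)),
    )
    if report is not None:
        if model is None:
            model = NetworkModel(W=np.asarray(W, dtype=float))
        P = build_P(model, report, mode=mode, **build_p_kwargs)
        out.n_amplified = report.n_amplified
        out.erank_P = effective_rank(P) if P.shape[1] else None
    return out
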