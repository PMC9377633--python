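"""Sparse excitatory/inhibitory (Dalean) networks and their stabilisation.

Networks of N neurons, half excitatory (non-negative outgoing weights,
first N/2 columns) and half inhibitory (non-positive, last N/2 columns),
sparsely connected with probability ``p`` and no self connections.  All
nonzero excitatory weights equal ``w0/sqrt(N)`` and inhibitory ones
``-(I/E) w0/sqrt(N)``, where the base weight

    w0 = R_outer / sqrt( p (1-p) [1 + (I/E)^2] / 2 )

sets the radius ``R_outer`` of the bulk eigenvalue distribution.  With
inhibition dominating (I/E > 1) the spectrum develops a single strongly
negative real outlier and a denser inner disc of eigenvalues; closed-form
predictions for the outlier and both radii are provided.

Such a raw network with R_outer = 10 is unstable (spectral abscissa well
above 1).  ``soc_stabilise`` turns it into a stability-optimised circuit
(SOC) by gradient descent on the smoothed spectral abscissa, touching only
inhibitory weights while preserving Dale's law, the empty diagonal, a cap
on inhibitory density, and the I/E ratio.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.linalg import solve_continuous_lyapunov
from scipy.optimize import brentq
from scipy.stats import gaussian_kde

__all__ = [
    "DaleSpec",
    "DaleNetwork",
    "SOCConfig",
    "SOCDidNotConverge",
    "base_weight",
    "init_random",
    "spectral_abscissa",
    "smoothed_abscissa",
    "abscissa_gradient",
    "soc_stabilise",
    "scale_inhibition",
    "scale_etoi",
    "frobenius_normalise",
    "predicted_outlier",
    "predicted_radii",
    "empirical_radii",
]


@dataclass(frozen=True)
class DaleSpec:
    """Construction parameters of a Dalean network."""

    N: int = 200
    p: float = 0.1
    R_outer: float = 10.0
    ie_ratio: float = 3.0
    autapses: bool = False

    def __post_init__(self) -> None:
        if self.N % 2:
            raise ValueError("N must be even (half excitatory, half inhibitory)")
        if not 0 < self.p < 1:
            raise ValueError("connection probability p must be in (0, 1)")
        if self.ie_ratio < 0:
            raise ValueError("I/E ratio must be non-negative")


@dataclass
class DaleNetwork:
    """A signed sparse matrix with E/I labels and its provenance."""

    W: np.ndarray
    spec: DaleSpec
    stabilised: bool = False
    optimisation: dict = field(default_factory=dict)

    @property
    def N(self) -> int:
        return self.W.shape[0]

    @property
    def e_indices(self) -> np.ndarray:
        return np.arange(self.N // 2)

    @property
    def i_indices(self) -> np.ndarray:
        return np.arange(self.N // 2, self.N)

    @property
    def ie_ratio_actual(self) -> float:
        """Global ratio of summed |inhibitory| to summed excitatory weights."""
        e_sum = self.W[:, self.e_indices].sum()
        i_sum = -self.W[:, self.i_indices].sum()
        return float(i_sum / e_sum) if e_sum else np.inf

    def eigenvalues(self) -> np.ndarray:
        return np.linalg.eigvals(self.W)

    def check_dale(self, atol: float = 0.0) -> bool:
        ok_e = np.all(self.W[:, self.e_indices] >= -atol)
        ok_i = np.all(self.W[:, self.i_indices] <= atol)
        ok_diag = self.spec.autapses or np.all(np.diag(self.W) == 0)
        return bool(ok_e and ok_i and ok_diag)


@dataclass(frozen=True)
class SOCConfig:
    """Knobs of the inhibitory-weight stabilisation.

    alpha_max : target spectral abscissa (0.5 leaves a decay margin well
        inside the stability limit of 1).
    shift_floor, shift_factor : the Lyapunov factors are evaluated at the
        shift ``s = alpha + max(shift_floor, shift_factor (alpha - alpha_max))``,
        slightly above the current abscissa; the gap closes as the target
        is approached so the gradient stays informative.
    learning_rate : initial gradient step on the inhibitory columns,
        adapted multiplicatively by the line search.
    inhib_density_cap : maximum fraction of nonzero inhibitory entries.
    """

    alpha_max: float = 0.5
    inhib_density_cap: float = 0.4
    learning_rate: float = 10.0
    shift_floor: float = 0.02
    shift_factor: float = 0.3
    max_iter: int = 2_000
    tol: float = 1.0e-3


class SOCDidNotConverge(RuntimeError):
    def __init__(self, best_abscissa: float, iterations: int):
        self.best_abscissa = best_abscissa
        self.iterations = iterations
        super().__init__(
            f"stabilisation stopped after {iterations} iterations with "
            f"spectral abscissa {best_abscissa:.4f}"
        )


def base_weight(spec: DaleSpec) -> float:
    """w0 = R_outer / sqrt(p (1-p) [1 + (I/E)^2] / 2)."""
    k = spec.ie_ratio
    return spec.R_outer / np.sqrt(spec.p * (1 - spec.p) * (1 + k**2) / 2.0)


def init_random(spec: DaleSpec, rng: np.random.Generator) -> DaleNetwork:
    """Raw sparse Dalean matrix before any stabilisation."""
    N = spec.N
    w_e = base_weight(spec) / np.sqrt(N)
    w_i = -spec.ie_ratio * w_e
    mask = rng.random((N, N)) < spec.p
    if not spec.autapses:
        np.fill_diagonal(mask, False)
    W = np.zeros((N, N))
    W[:, : N // 2][mask[:, : N // 2]] = w_e
    W[:, N // 2 :][mask[:, N // 2 :]] = w_i
    return DaleNetwork(W=W, spec=spec)


def spectral_abscissa(W: np.ndarray) -> float:
    return float(np.max(np.linalg.eigvals(W).real))


def _lyap_P(A: np.ndarray, s: float) -> np.ndarray:
    """Controllability-like factor: (A - sI) P + P (A - sI)^T = -I."""
    As = A - s * np.eye(A.shape[0])
    return solve_continuous_lyapunov(As, -np.eye(A.shape[0]))


def _lyap_Q(A: np.ndarray, s: float) -> np.ndarray:
    """Observability-like factor: (A - sI)^T Q + Q (A - sI) = -I."""
    As = A - s * np.eye(A.shape[0])
    return solve_continuous_lyapunov(As.T, -np.eye(A.shape[0]))


def smoothed_abscissa(
    W: np.ndarray, eps: float, alpha: float | None = None
) -> float:
    """Smoothed spectral abscissa: the unique s > alpha(W) with
    ``trace(P(s)) = 1/eps``, P the shifted controllability factor.

    A smooth, differentiable upper bound of the true abscissa that
    accounts for non-normal transient growth, which makes it a robust
    objective for stabilisation.
    """
    if alpha is None:
        alpha = spectral_abscissa(W)

    def f(s: float) -> float:
        return np.trace(_lyap_P(W, s)) - 1.0 / eps

    lo = alpha + 1e-6
    hi = alpha + 1.0
    while f(hi) > 0:
        hi = alpha + 2 * (hi - alpha)
        if hi - alpha > 1e6:
            raise RuntimeError("failed to bracket the smoothed abscissa")
    return float(brentq(f, lo, hi, xtol=1e-8))


def abscissa_gradient(W: np.ndarray, s: float) -> np.ndarray:
    """Gradient of the smoothed abscissa w.r.t. the entries of W,
    ``Q P / trace(Q P)`` evaluated at the smoothed abscissa s."""
    P = _lyap_P(W, s)
    Q = _lyap_Q(W, s)
    QP = Q @ P
    return QP / np.trace(QP)


def _project_inhibitory(
    W: np.ndarray, spec: DaleSpec, support: np.ndarray | None
) -> None:
    """In place: clip inhibitory columns to <= 0, keep the diagonal empty,
    restrict to the allowed support, and restore the I/E ratio."""
    half = spec.N // 2
    inh = W[:, half:]
    np.minimum(inh, 0.0, out=inh)
    if support is not None:
        inh[~support] = 0.0
    if not spec.autapses:
        np.fill_diagonal(W, 0.0)
    e_sum = W[:, :half].sum()
    i_sum = -W[:, half:].sum()
    if i_sum > 0 and e_sum > 0:
        W[:, half:] *= spec.ie_ratio * e_sum / i_sum


def _inhib_density(W: np.ndarray, spec: DaleSpec) -> float:
    half = spec.N // 2
    return float(np.count_nonzero(W[:, half:])) / (spec.N * half)


def soc_stabilise(
    net: DaleNetwork,
    cfg: SOCConfig = SOCConfig(),
    rng: np.random.Generator | None = None,
) -> DaleNetwork:
    """Optimise inhibitory weights until max Re(lambda) <= alpha_max.

    Gradient descent on the spectral abscissa, smoothed by evaluating the
    Lyapunov-factor gradient ``QP/tr(QP)`` at a shift slightly above the
    current abscissa (the shift closes in on the abscissa as it nears the
    target).  Every step modifies only the inhibitory (last N/2) columns —
    zero entries included — then projects back onto the constraint set:
    inhibitory signs, empty diagonal, inhibitory density <= cap (pruning
    weakest-by-magnitude entries and freezing the support thereafter), and
    the requested I/E ratio (linear rescale of all nonzero inhibitory
    weights).  A backtracking line search keeps the abscissa monotonically
    decreasing.

    Raises :class:`SOCDidNotConverge` (carrying the best abscissa
    reached) when the iteration budget runs out or the search stalls.
    """
    spec = net.spec
    W = net.W.copy()
    half = spec.N // 2
    alpha = spectral_abscissa(W)
    if alpha <= cfg.alpha_max + cfg.tol:
        return DaleNetwork(
            W=W, spec=spec, stabilised=True,
            optimisation={"iterations": 0, "abscissa": alpha},
        )
    # start the optimisation from a feasible point: the input may not
    # satisfy the I/E ratio exactly (e.g. after an E-to-I block rescale),
    # and the line search compares against the projected baseline
    _project_inhibitory(W, spec, None)
    alpha = spectral_abscissa(W)
    lr = cfg.learning_rate
    support: np.ndarray | None = None
    floor = cfg.shift_floor

    def project(W_new: np.ndarray) -> None:
        nonlocal support
        _project_inhibitory(W_new, spec, support)
        if support is None and _inhib_density(W_new, spec) > cfg.inhib_density_cap:
            inh = W_new[:, half:]
            mags = np.abs(inh[inh != 0])
            n_keep = int(cfg.inhib_density_cap * spec.N * half)
            cut = np.sort(mags)[max(mags.size - n_keep, 0)]
            support = np.abs(inh) >= cut
            _project_inhibitory(W_new, spec, support)

    it = 0
    while it < cfg.max_iter:
        it += 1
        gap = max(floor, cfg.shift_factor * (alpha - cfg.alpha_max))
        s_ref = alpha + gap
        P = _lyap_P(W, s_ref)
        Q = _lyap_Q(W, s_ref)
        QP = Q @ P
        J = float(np.trace(P))
        G = QP / np.trace(QP)
        Gi = G[:, half:].copy()
        # differentiate through the I/E-restoring rescale: the projection
        # multiplies all inhibitory weights by a common factor, so the
        # component of the gradient that a rescale would undo is removed
        Wi = W[:, half:]
        denom = np.abs(Wi).sum()
        if denom > 0:
            Gi += (Gi * Wi).sum() / denom
        accepted = False
        for _ in range(25):
            W_new = W.copy()
            W_new[:, half:] -= lr * Gi
            project(W_new)
            alpha_new = spectral_abscissa(W_new)
            if alpha_new < alpha - 1e-12:
                W, alpha = W_new, alpha_new
                lr = min(lr * 2.0, 1e3 * cfg.learning_rate)
                accepted = True
                break
            # the true abscissa is nonsmooth where eigenvalue branches
            # cross; fall back to descent on the smooth fixed-shift trace
            # surrogate (whose gradient QP is the step direction)
            if alpha_new < s_ref and float(np.trace(_lyap_P(W_new, s_ref))) < J:
                W, alpha = W_new, alpha_new
                accepted = True
                break
            lr *= 0.5
        if alpha <= cfg.alpha_max + cfg.tol:
            return DaleNetwork(
                W=W, spec=spec, stabilised=True,
                optimisation={"iterations": it, "abscissa": alpha},
            )
        if not accepted:
            # evaluate the gradient closer to the true abscissa and
            # restart the step size
            floor *= 0.2
            lr = cfg.learning_rate
            if floor < 1e-7:
                raise SOCDidNotConverge(alpha, it)
    raise SOCDidNotConverge(alpha, it)


def scale_inhibition(net: DaleNetwork, new_ie_ratio: float) -> DaleNetwork:
    """Multiply every inhibitory entry by ``new_ie / old_ie``.

    The global-inhibition dial: scaling I/E from 40 down to 1 switches a
    short-transient amplifier into a non-amplifying network.
    """
    if new_ie_ratio < 0:
        raise ValueError("new I/E ratio must be non-negative")
    old = net.spec.ie_ratio
    if old == 0:
        raise ValueError("cannot rescale from a zero I/E ratio")
    W = net.W.copy()
    W[:, net.N // 2 :] *= new_ie_ratio / old
    return DaleNetwork(
        W=W,
        spec=replace(net.spec, ie_ratio=new_ie_ratio),
        stabilised=net.stabilised,
        optimisation=dict(net.optimisation),
    )


def scale_etoi(
    spec: DaleSpec,
    wie_over_wee: float,
    cfg: SOCConfig = SOCConfig(),
    rng: np.random.Generator | None = None,
    reference_norm: float | None = None,
) -> DaleNetwork:
    """Build, scale the E-to-I block, stabilise, and norm-match.

    A fresh raw network is drawn, its E-to-I (bottom-left) block is
    multiplied by ``wie_over_wee``, inhibitory weights are optimised at
    the spec's I/E ratio, and the result is uniformly rescaled to the
    Frobenius norm of the ratio-1 reference (computed on the spot from
    the same generator state when not supplied).
    """
    if wie_over_wee <= 0:
        raise ValueError("W_IE/W_EE ratio must be positive")
    if rng is None:
        rng = np.random.default_rng()
    if reference_norm is None and wie_over_wee != 1.0:
        ref = scale_etoi(spec, 1.0, cfg, np.random.default_rng(rng.integers(2**31)))
        reference_norm = float(np.linalg.norm(ref.W, "fro"))
    net = init_random(spec, rng)
    half = spec.N // 2
    net.W[half:, :half] *= wie_over_wee
    soc = soc_stabilise(net, cfg, rng)
    if reference_norm is not None:
        soc = frobenius_normalise(soc, reference_norm)
    return soc


def frobenius_normalise(net: DaleNetwork, target_norm: float) -> DaleNetwork:
    """Uniform rescale of all weights to a target Frobenius norm.

    Signs and the empty diagonal are preserved; note the whole spectrum
    scales by the same factor (eigenvalues of cW are c times those of W).
    """
    nrm = float(np.linalg.norm(net.W, "fro"))
    if nrm == 0:
        raise ValueError("cannot normalise a zero matrix")
    return DaleNetwork(
        W=net.W * (target_norm / nrm),
        spec=net.spec,
        stabilised=net.stabilised,
        optimisation=dict(net.optimisation),
    )


def predicted_outlier(spec: DaleSpec) -> float:
    """Closed-form outlier: gamma ~ (p w0 sqrt(N) / 2) (1 - I/E)."""
    return float(
        spec.p * base_weight(spec) * np.sqrt(spec.N) / 2.0 * (1.0 - spec.ie_ratio)
    )


def predicted_radii(spec: DaleSpec) -> tuple[float, float]:
    """(R_outer, R_inner) of the eigenvalue distribution.

    The outer radius is the construction target by design; the inner
    radius bounding the denser region is
    ``R_outer * sqrt(1 / (2 [1 + (I/E)^2]))``.
    """
    k = spec.ie_ratio
    w0 = base_weight(spec)
    outer = w0 * np.sqrt(spec.p * (1 - spec.p) * (1 + k**2) / 2.0)
    inner = outer * np.sqrt(1.0 / (2.0 * (1 + k**2)))
    return float(outer), float(inner)


def empirical_radii(
    eigenvalues: np.ndarray,
    density_floor: float = 0.005,
    exclude_outlier: bool = True,
) -> tuple[float, float]:
    """Density-based estimate of the outer and inner imaginary radii.

    A Gaussian kernel-density estimate (Silverman bandwidth) of the
    imaginary parts, normalised to unit integral, is scanned on a fine
    grid: the outer radius is the largest |Im| at which the density still
    reaches ``density_floor``; the inner radius is where it first drops
    below half its maximum.  The single most negative real eigenvalue (the
    inhibitory outlier) is excluded by default.
    """
    lam = np.asarray(eigenvalues, dtype=complex).ravel()
    if lam.size < 50:
        raise ValueError("need at least 50 eigenvalues for a density estimate")
    if exclude_outlier:
        lam = np.delete(lam, int(np.argmin(lam.real)))
    im = lam.imag
    if np.allclose(im, 0.0):
        return 0.0, 0.0
    kde = gaussian_kde(im)
    hi = 1.5 * np.max(np.abs(im))
    grid = np.linspace(0.0, hi, 2000)
    dens = 0.5 * (kde(grid) + kde(-grid))   # symmetrised
    above_floor = np.nonzero(dens >= density_floor)[0]
    outer = float(grid[above_floor[-1]]) if above_floor.size else 0.0
    half_max = dens.max() / 2.0
    below_half = np.nonzero(dens < half_max)[0]
    inner = float(grid[below_half[0]]) if below_half.size else float(grid[-1])
    return outer, inner
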