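"""Closed-form spliced/unspliced kinetics with piecewise-constant transcription.

The model is the standard two-equation first-order system used throughout the
RNA-velocity literature,

    du/dt = alpha - beta * u
    ds/dt = beta * u - gamma * s,

with transcription rate ``alpha`` allowed to change as a step function of
latent time t in [0, 1] (a "regime" per constant-alpha interval).  A MURK
(multiple rate kinetics) gene is one whose later regime has a strictly larger
alpha than an earlier one: transcription steps up partway through the
trajectory while the molecule counts u, s stay continuous.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import InvalidParameterError

#: below this |beta - gamma| the degenerate analytic limit is used
_BETA_GAMMA_TOL = 1e-9


@dataclass(frozen=True)
class GeneKinetics:
    """Ground-truth rate parameters for one gene.

    ``alpha_regimes`` holds one transcription rate per regime;
    ``switch_times`` the regime boundaries in latent time (len = regimes - 1,
    strictly increasing, each in (0, 1)).  ``beta`` and ``gamma`` are the
    splicing and degradation rates, constant across regimes.  All rates are
    per unit latent time.
    """

    gene_id: str
    alpha_regimes: tuple
    switch_times: tuple
    beta: float
    gamma: float
    is_murk: bool = False

    def __post_init__(self):
        object.__setattr__(self, "alpha_regimes", tuple(float(a) for a in self.alpha_regimes))
        object.__setattr__(self, "switch_times", tuple(float(t) for t in self.switch_times))
        if len(self.alpha_regimes) != len(self.switch_times) + 1:
            raise InvalidParameterError("need len(alpha_regimes) == len(switch_times) + 1")
        if any(a <= 0 for a in self.alpha_regimes):
            raise InvalidParameterError("all transcription rates must be > 0")
        if self.beta <= 0 or self.gamma <= 0:
            raise InvalidParameterError("beta and gamma must be > 0")
        st = self.switch_times
        if any(not (0 < t < 1) for t in st) or any(b <= a for a, b in zip(st, st[1:])):
            raise InvalidParameterError("switch_times must be strictly increasing in (0,1)")

    def alpha_at(self, t: float) -> float:
        """Transcription rate in force at latent time t (left-continuous in state:
        the boundary itself still belongs to the earlier regime)."""
        idx = int(np.searchsorted(np.asarray(self.switch_times), t, side="left"))
        return self.alpha_regimes[idx]

    def without_boost(self) -> "GeneKinetics":
        """The knockout version: every regime collapsed to the first alpha."""
        return GeneKinetics(
            gene_id=self.gene_id,
            alpha_regimes=(self.alpha_regimes[0],) * len(self.alpha_regimes),
            switch_times=self.switch_times,
            beta=self.beta,
            gamma=self.gamma,
            is_murk=False,
        )


def solve_kinetics(u0, s0, alpha, beta, gamma, tau):
    """Exact solution of the constant-rate system after elapsed time ``tau``.

    Returns ``(u, s)``.  All arguments may be scalars or broadcastable arrays.
    The beta == gamma case is handled by its analytic limit
    (the ``t * exp(-beta t)`` secular term), switched at |beta-gamma| < 1e-9.

    Raises
    ------
    InvalidParameterError
        for non-positive rates, negative elapsed time, or negative initial
        abundances.
    """
    u0 = np.asarray(u0, dtype=float)
    s0 = np.asarray(s0, dtype=float)
    alpha = np.asarray(alpha, dtype=float)
    beta = np.asarray(beta, dtype=float)
    gamma = np.asarray(gamma, dtype=float)
    tau = np.asarray(tau, dtype=float)
    if np.any(alpha <= 0) or np.any(beta <= 0) or np.any(gamma <= 0):
        raise InvalidParameterError("rates alpha, beta, gamma must be > 0")
    if np.any(tau < 0):
        raise InvalidParameterError("elapsed time tau must be >= 0")
    if np.any(u0 < 0) or np.any(s0 < 0):
        raise InvalidParameterError("initial abundances must be >= 0")

    eb = np.exp(-beta * tau)
    eg = np.exp(-gamma * tau)
    du = u0 - alpha / beta  # deviation from unspliced steady state
    u = alpha / beta + du * eb

    # s(t) = alpha/gamma + (s0 - alpha/gamma) e^{-gamma t}
    #        + beta*du * (e^{-beta t} - e^{-gamma t}) / (gamma - beta)
    ds = s0 - alpha / gamma
    diff = gamma - beta
    degenerate = np.abs(diff) < _BETA_GAMMA_TOL
    with np.errstate(divide="ignore", invalid="ignore"):
        cross = np.where(degenerate, beta * du * tau * eb,
                         beta * du * (eb - eg) / np.where(degenerate, 1.0, diff))
    s = alpha / gamma + ds * eg + cross
    if u.ndim == 0 and s.ndim == 0:
        return float(u), float(s)
    return u, s


def steady_state(alpha, beta, gamma):
    """Fixed point (u*, s*) = (alpha/beta, alpha/gamma)."""
    return alpha / beta, alpha / gamma


def propagate_regimes(gene: GeneKinetics, t, initial_condition: str = "steady_state_of_first_regime"):
    """Expected (u, s) at latent time(s) ``t`` by chaining the closed form across regimes.

    The state is continuous at every regime boundary; the boundary instant
    itself is evaluated under the earlier regime (left-continuity).

    Parameters
    ----------
    gene
        Rate parameters and switch schedule.
    t
        Scalar or array of latent times in [0, 1].
    initial_condition
        ``"steady_state_of_first_regime"`` (default): cells enter the
        trajectory already at the first regime's fixed point, so single-regime
        genes are flat and any dynamics come from rate switches.
        ``"zero"``: induction from (0, 0), the classic phase-plot picture.
    """
    t_arr = np.atleast_1d(np.asarray(t, dtype=float))
    if np.any((t_arr < 0) | (t_arr > 1)):
        raise InvalidParameterError("latent time must lie in [0, 1]")
    if initial_condition == "steady_state_of_first_regime":
        u0, s0 = steady_state(gene.alpha_regimes[0], gene.beta, gene.gamma)
    elif initial_condition == "zero":
        u0, s0 = 0.0, 0.0
    else:
        raise InvalidParameterError(f"unknown initial_condition {initial_condition!r}")

    # state at the start of each regime, chained through the boundaries
    bounds = (0.0,) + gene.switch_times
    starts_u = [u0]
    starts_s = [s0]
    for i, sw in enumerate(gene.switch_times):
        uu, ss = solve_kinetics(
            starts_u[i], starts_s[i], gene.alpha_regimes[i],
            gene.beta, gene.gamma, sw - bounds[i],
        )
        starts_u.append(uu)
        starts_s.append(ss)

    # boundary instants belong to the earlier regime (side="left")
    reg = np.searchsorted(np.asarray(gene.switch_times), t_arr, side="left")
    u = np.empty_like(t_arr)
    s = np.empty_like(t_arr)
    for r in np.unique(reg):
        m = reg == r
        u[m], s[m] = solve_kinetics(
            starts_u[r], starts_s[r], gene.alpha_regimes[r],
            gene.beta, gene.gamma, t_arr[m] - bounds[r],
        )
    if np.isscalar(t) or np.asarray(t).ndim == 0:
        return float(u[0]), float(s[0])
    return u, s
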