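"""Toy solute-in-solvent model systems and a seeded Metropolis sampler.

The model is deliberately minimal: single-site particles in a cubic
periodic box interacting through Lennard-Jones (Lorentz-Berthelot
combining) plus Coulomb with Barker-Watts reaction-field damping, sharing
one cutoff.  The alchemical machinery only needs equilibrium ensemble
averages, so sampling is single-particle-displacement Metropolis Monte
Carlo rather than molecular dynamics.

The solute (role ``"solute"``) is the alchemically coupled species: the
reference state ``U_0`` has all solute-solvent interactions switched off,
the target state ``U_1`` is fully interacting, and a coupling parameter
``alpha`` in [0, 1] interpolates between them.  With linear coupling

    U(r; alpha) = (1 - alpha) U_0(r) + alpha U_1(r),

the TI integrand d(U)/d(alpha) equals the instantaneous gap
``dU = U_1 - U_0`` for every configuration.  A soft-core van der Waals
path is provided as well because the linear path is singular at alpha -> 0
when the solute cavity vanishes.

A weak harmonic tether (default 10 kJ/mol/nm^2) pins the solute to the box
centre so the decoupled solute cannot drift; it is present identically in
``U_0`` and ``U_1`` and therefore cancels in ``dU``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Callable

import numpy as np

#: Boltzmann constant, kJ/mol/K.
KB = 0.0083144621
#: Coulomb prefactor e^2/(4 pi eps0), kJ/mol * nm / e^2.
COULOMB = 138.935458

try:  # optional acceleration of the Monte Carlo inner loop
    import numba as _numba
except ImportError:  # pragma: no cover - numba is normally available
    _numba = None


@dataclass(frozen=True)
class ThermoState:
    """Thermodynamic state: temperature (K) and optional pressure (bar)."""

    T: float = 298.15
    P: float | None = None

    def __post_init__(self):
        if self.T <= 0:
            raise ValueError("temperature must be positive")

    @property
    def beta(self) -> float:
        """Inverse thermal energy 1/(k_B T), mol/kJ."""
        return 1.0 / (KB * self.T)


@dataclass(frozen=True)
class Species:
    """A single-site particle type: LJ sigma (nm), epsilon (kJ/mol), charge (e)."""

    name: str
    sigma: float
    epsilon: float
    charge: float
    role: str = "solvent"  # "solvent" | "solute"


@dataclass(frozen=True)
class ToySystem:
    """Cubic periodic box of single-site particles.

    ``species`` maps a name to :class:`Species`; ``labels`` assigns one
    species per site.  Per-site parameter arrays are derived once at
    construction.  ``eps_rf`` is the reaction-field dielectric and
    ``tether_k`` the solute centring spring constant (kJ/mol/nm^2).
    """

    L: float
    r_c: float
    positions: np.ndarray            # (N, 3) nm
    species: dict[str, Species]
    labels: tuple[str, ...]
    eps_rf: float = 78.4
    tether_k: float = 0.0

    sigma: np.ndarray = field(default=None, repr=False)    # type: ignore
    epsilon: np.ndarray = field(default=None, repr=False)  # type: ignore
    charge: np.ndarray = field(default=None, repr=False)   # type: ignore
    solute_mask: np.ndarray = field(default=None, repr=False)  # type: ignore

    def __post_init__(self):
        if self.L <= 2 * self.r_c:
            raise ValueError("box edge must exceed twice the cutoff")
        pos = np.asarray(self.positions, dtype=float)
        object.__setattr__(self, "positions", pos)
        object.__setattr__(self, "labels", tuple(self.labels))
        if pos.shape != (len(self.labels), 3):
            raise ValueError("positions must be (N, 3) matching labels")
        sig = np.array([self.species[l].sigma for l in self.labels])
        eps = np.array([self.species[l].epsilon for l in self.labels])
        q = np.array([self.species[l].charge for l in self.labels])
        sol = np.array([self.species[l].role == "solute" for l in self.labels])
        object.__setattr__(self, "sigma", sig)
        object.__setattr__(self, "epsilon", eps)
        object.__setattr__(self, "charge", q)
        object.__setattr__(self, "solute_mask", sol)

    @property
    def n_sites(self) -> int:
        return len(self.labels)

    def with_positions(self, positions: np.ndarray) -> "ToySystem":
        return replace(self, positions=np.asarray(positions, float))

    def with_site_params(self, sigma=None, epsilon=None, charge=None) -> "ToySystem":
        """Copy with per-site parameter arrays overridden (positions kept)."""
        new = replace(self)
        if sigma is not None:
            object.__setattr__(new, "sigma", np.asarray(sigma, float))
        if epsilon is not None:
            object.__setattr__(new, "epsilon", np.asarray(epsilon, float))
        if charge is not None:
            object.__setattr__(new, "charge", np.asarray(charge, float))
        return new

    def apply_parameters(self, space, K: np.ndarray) -> "ToySystem":
        """Bind a :class:`~fegrad.forcefield.ParameterSpace` physical vector.

        Parameter names follow the ``"<species>.<attribute>"`` convention;
        names not matching a species in this system are ignored (they may
        belong to another molecule's space).
        """
        sig, eps, q = self.sigma.copy(), self.epsilon.copy(), self.charge.copy()
        labels = np.array(self.labels)
        for name, value in zip(space.names, np.asarray(K, float)):
            if "." not in name:
                continue
            sp, attr = name.rsplit(".", 1)
            if sp not in self.species:
                continue
            mask = labels == sp
            if attr == "sigma":
                sig[mask] = value
            elif attr == "epsilon":
                eps[mask] = value
            elif attr == "charge":
                q[mask] = value
            else:
                raise ValueError(f"unknown site attribute {attr!r} in {name!r}")
        return self.with_site_params(sig, eps, q)


# -- pair-energy kernels ---------------------------------------------------


def _rf_constants(r_c: float, eps_rf: float) -> tuple[float, float]:
    """Barker-Watts reaction-field constants (k_rf, c_rf)."""
    k_rf = (eps_rf - 1.0) / ((2.0 * eps_rf + 1.0) * r_c ** 3)
    c_rf = 1.0 / r_c + k_rf * r_c ** 2
    return k_rf, c_rf


def _min_image(d: np.ndarray, L: float) -> np.ndarray:
    return d - L * np.round(d / L)


def _pair_energies(pos: np.ndarray, i_idx, j_idx, L, r_c, sigma, epsilon,
                   charge, eps_rf, *, vdw=True, coulomb=True) -> np.ndarray:
    """Summed pair energy over index pairs for a batch of configurations.

    ``pos`` is (S, N, 3); returns (S,).  Pairs beyond the cutoff contribute
    zero (truncated, unshifted LJ; reaction-field Coulomb is zero at r_c by
    construction).
    """
    d = _min_image(pos[:, i_idx, :] - pos[:, j_idx, :], L)
    r2 = np.einsum("spk,spk->sp", d, d)
    if np.any(r2 < 1e-12):
        raise ValueError("overlapping sites (distance < 1e-6 nm)")
    within = r2 < r_c * r_c
    u = np.zeros(r2.shape)
    if vdw:
        sij = 0.5 * (sigma[i_idx] + sigma[j_idx])
        eij = np.sqrt(epsilon[i_idx] * epsilon[j_idx])
        sr6 = (sij * sij / r2) ** 3
        u += 4.0 * eij * (sr6 * sr6 - sr6)
    if coulomb:
        qq = charge[i_idx] * charge[j_idx]
        if np.any(qq != 0.0):
            k_rf, c_rf = _rf_constants(r_c, eps_rf)
            r = np.sqrt(r2)
            u += COULOMB * qq * (1.0 / r + k_rf * r2 - c_rf)
    return np.sum(np.where(within, u, 0.0), axis=1)


def _softcore_lj(pos, i_idx, j_idx, L, r_c, sigma, epsilon, alpha,
                 alpha_sc=0.5) -> np.ndarray:
    """Beutler-style soft-core LJ pair sum at coupling ``alpha`` (batched)."""
    d = _min_image(pos[:, i_idx, :] - pos[:, j_idx, :], L)
    r2 = np.einsum("spk,spk->sp", d, d)
    within = r2 < r_c * r_c
    sij = 0.5 * (sigma[i_idx] + sigma[j_idx])
    eij = np.sqrt(epsilon[i_idx] * epsilon[j_idx])
    s6 = sij ** 6
    denom = alpha_sc * (1.0 - alpha) ** 2 * s6 + r2 ** 3
    frac = s6 / denom
    u = 4.0 * eij * alpha * (frac * frac - frac)
    return np.sum(np.where(within, u, 0.0), axis=1)


def _softcore_lj_dalpha(pos, i_idx, j_idx, L, r_c, sigma, epsilon, alpha,
                        alpha_sc=0.5) -> np.ndarray:
    """Analytic d/dalpha of the soft-core LJ pair sum (batched).

    With f = s^6/den, den = c (1-a)^2 s^6 + r^6 and U = 4 e a (f^2 - f):
    dU/da = 4 e (f^2 - f) + 4 e a (2 f - 1) * 2 c (1-a) f^2.
    """
    d = _min_image(pos[:, i_idx, :] - pos[:, j_idx, :], L)
    r2 = np.einsum("spk,spk->sp", d, d)
    within = r2 < r_c * r_c
    sij = 0.5 * (sigma[i_idx] + sigma[j_idx])
    eij = np.sqrt(epsilon[i_idx] * epsilon[j_idx])
    s6 = sij ** 6
    den = alpha_sc * (1.0 - alpha) ** 2 * s6 + r2 ** 3
    f = s6 / den
    du = 4.0 * eij * ((f * f - f)
                      + alpha * (2.0 * f - 1.0)
                      * 2.0 * alpha_sc * (1.0 - alpha) * f * f)
    return np.sum(np.where(within, du, 0.0), axis=1)


def _pair_index_lists(n: int, solute_mask: np.ndarray):
    """Index pairs split into solvent-solvent and solute-solvent groups."""
    iu, ju = np.triu_indices(n, k=1)
    cross = solute_mask[iu] ^ solute_mask[ju]
    both = solute_mask[iu] & solute_mask[ju]
    ss = ~cross & ~both
    return (iu[ss], ju[ss]), (iu[cross], ju[cross]), (iu[both], ju[both])


class ToyEngine:
    """Energy engine for a :class:`ToySystem` under an alchemical coupling.

    Splits the potential into the solvent-internal part (plus the solute
    tether), present in both end states, and the solute-solvent part that
    is switched on by ``alpha``.  All evaluators accept a configuration
    batch ``(S, N, 3)`` and an optional physical parameter vector bound
    through a :class:`~fegrad.forcefield.ParameterSpace`.
    """

    def __init__(self, system: ToySystem, coupled: "CoupledPotential",
                 space=None):
        self.system = system
        self.coupled = coupled
        self.space = space
        (self._ss, self._cross, self._uu) = _pair_index_lists(
            system.n_sites, system.solute_mask)
        if len(self._uu[0]):
            raise ValueError("multi-site solutes are not supported")

    def _bound(self, K):
        if K is None or self.space is None:
            return self.system
        return self.system.apply_parameters(self.space, K)

    def _batch(self, pos):
        pos = np.asarray(pos, float)
        return pos[None] if pos.ndim == 2 else pos

    def u0_batch(self, pos, K=None) -> np.ndarray:
        """Reference-state energy: solvent-solvent pairs, the solute tether,
        and any solute-solvent interactions this stage leaves unscaled."""
        sys_ = self._bound(K)
        pos = self._batch(pos)
        u = _pair_energies(pos, *self._ss, sys_.L, sys_.r_c, sys_.sigma,
                           sys_.epsilon, sys_.charge, sys_.eps_rf)
        bg_vdw, bg_coul = self.coupled.background_components()
        if (bg_vdw or bg_coul) and len(self._cross[0]):
            u = u + _pair_energies(pos, *self._cross, sys_.L, sys_.r_c,
                                   sys_.sigma, sys_.epsilon, sys_.charge,
                                   sys_.eps_rf, vdw=bg_vdw, coulomb=bg_coul)
        return u + self._tether(pos, sys_)

    def delta_u_batch(self, pos, K=None) -> np.ndarray:
        """Instantaneous gap dU = U_1 - U_0 = solute-solvent interaction."""
        sys_ = self._bound(K)
        pos = self._batch(pos)
        if len(self._cross[0]) == 0:
            return np.zeros(pos.shape[0])
        vdw, coul = self.coupled.stage_components()
        return _pair_energies(pos, *self._cross, sys_.L, sys_.r_c, sys_.sigma,
                              sys_.epsilon, sys_.charge, sys_.eps_rf,
                              vdw=vdw, coulomb=coul)

    def e_alpha_batch(self, pos, alpha, K=None) -> np.ndarray:
        """Sampled potential at coupling ``alpha`` (linear or soft-core)."""
        sys_ = self._bound(K)
        pos = self._batch(pos)
        u0 = self.u0_batch(pos, K)
        if self.coupled.mode == "linear" or len(self._cross[0]) == 0:
            return u0 + alpha * self.delta_u_batch(pos, K)
        vdw, coul = self.coupled.stage_components()
        u = u0
        if vdw:
            u = u + _softcore_lj(pos, *self._cross, sys_.L, sys_.r_c,
                                 sys_.sigma, sys_.epsilon, alpha,
                                 self.coupled.alpha_sc)
        if coul:
            u = u + alpha * _pair_energies(
                pos, *self._cross, sys_.L, sys_.r_c, sys_.sigma, sys_.epsilon,
                sys_.charge, sys_.eps_rf, vdw=False, coulomb=True)
        return u

    def dudalpha_batch(self, pos, alpha, K=None) -> np.ndarray:
        """TI integrand dE/dalpha per snapshot.

        Equals the instantaneous gap dU for linear coupling; for the
        soft-core path it is the analytic alpha-derivative of the soft-core
        pair energy plus the linearly scaled Coulomb part.
        """
        if self.coupled.mode == "linear":
            return self.delta_u_batch(pos, K)
        sys_ = self._bound(K)
        pos = self._batch(pos)
        if len(self._cross[0]) == 0:
            return np.zeros(pos.shape[0])
        vdw, coul = self.coupled.stage_components()
        out = np.zeros(pos.shape[0])
        if vdw:
            out += _softcore_lj_dalpha(pos, *self._cross, sys_.L, sys_.r_c,
                                       sys_.sigma, sys_.epsilon, alpha,
                                       self.coupled.alpha_sc)
        if coul:
            out += _pair_energies(pos, *self._cross, sys_.L, sys_.r_c,
                                  sys_.sigma, sys_.epsilon, sys_.charge,
                                  sys_.eps_rf, vdw=False, coulomb=True)
        return out

    def cross_energy_batch(self, pos, alpha, K=None) -> np.ndarray:
        """All solute-solvent contributions to E_alpha (background + coupled)."""
        sys_ = self._bound(K)
        pos = self._batch(pos)
        if len(self._cross[0]) == 0:
            return np.zeros(pos.shape[0])
        u = np.zeros(pos.shape[0])
        bg_vdw, bg_coul = self.coupled.background_components()
        if bg_vdw or bg_coul:
            u += _pair_energies(pos, *self._cross, sys_.L, sys_.r_c,
                                sys_.sigma, sys_.epsilon, sys_.charge,
                                sys_.eps_rf, vdw=bg_vdw, coulomb=bg_coul)
        vdw, coul = self.coupled.stage_components()
        if self.coupled.mode == "linear":
            u += alpha * _pair_energies(
                pos, *self._cross, sys_.L, sys_.r_c, sys_.sigma, sys_.epsilon,
                sys_.charge, sys_.eps_rf, vdw=vdw, coulomb=coul)
        else:
            if vdw:
                u += _softcore_lj(pos, *self._cross, sys_.L, sys_.r_c,
                                  sys_.sigma, sys_.epsilon, alpha,
                                  self.coupled.alpha_sc)
            if coul:
                u += alpha * _pair_energies(
                    pos, *self._cross, sys_.L, sys_.r_c, sys_.sigma,
                    sys_.epsilon, sys_.charge, sys_.eps_rf, vdw=False,
                    coulomb=True)
        return u

    def e_alpha_fd_diff(self, pos, alpha, Kp, Km) -> np.ndarray:
        """E_alpha(Kp) - E_alpha(Km) per snapshot.

        When the perturbed parameters touch only solute species, the
        solvent-solvent part cancels exactly and only the (much cheaper)
        solute-solvent terms are recomputed.
        """
        if self.space is not None:
            Kp_ = np.asarray(Kp, float)
            Km_ = np.asarray(Km, float)
            solvent_touched = False
            for i in np.flatnonzero(Kp_ != Km_):
                name = self.space.names[i]
                sp = name.rsplit(".", 1)[0] if "." in name else None
                if sp in self.system.species and \
                        self.system.species[sp].role != "solute":
                    solvent_touched = True
                    break
            if not solvent_touched:
                return (self.cross_energy_batch(pos, alpha, Kp)
                        - self.cross_energy_batch(pos, alpha, Km))
        return (self.e_alpha_batch(pos, alpha, Kp)
                - self.e_alpha_batch(pos, alpha, Km))

    def _tether(self, pos, sys_) -> np.ndarray:
        if sys_.tether_k == 0.0 or not np.any(sys_.solute_mask):
            return np.zeros(pos.shape[0])
        centre = np.full(3, sys_.L / 2.0)
        d = _min_image(pos[:, sys_.solute_mask, :] - centre, sys_.L)
        return 0.5 * sys_.tether_k * np.einsum("spk,spk->s", d, d)


@dataclass(frozen=True)
class CoupledPotential:
    """Alchemical coupling definition between U_0 and U_1.

    ``mode`` is ``"linear"`` (U = (1-a)U_0 + aU_1, exact dU bookkeeping) or
    ``"softcore"`` (Beutler-style vdW path with linearly scaled solute
    charges).  ``stage`` selects which solute-solvent interactions the
    stage couples: ``"combined"`` (both), ``"vdw"`` or ``"electrostatic"``.
    """

    mode: str = "linear"
    stage: str = "combined"
    alpha_sc: float = 0.5

    def __post_init__(self):
        if self.mode not in ("linear", "softcore"):
            raise ValueError(f"unknown coupling mode {self.mode!r}")
        if self.stage not in ("combined", "vdw", "electrostatic"):
            raise ValueError(f"unknown stage {self.stage!r}")

    def stage_components(self) -> tuple[bool, bool]:
        """(vdw, coulomb) of the solute-solvent part this stage *scales*."""
        return {"combined": (True, True),
                "vdw": (True, False),
                "electrostatic": (False, True)}[self.stage]

    def background_components(self) -> tuple[bool, bool]:
        """(vdw, coulomb) of the solute-solvent part present unscaled in U_0.

        An electrostatic stage charges the solute inside an already-grown
        LJ cavity, so the full solute-solvent vdW interaction belongs to
        both end states; the vdW and combined stages grow the cavity from
        a non-interacting solute (charges off during cavity growth).
        """
        return {"combined": (False, False),
                "vdw": (False, False),
                "electrostatic": (True, False)}[self.stage]


def total_energy(system: ToySystem, coupled: CoupledPotential | None = None
                 ) -> float:
    """Fully coupled total energy U_1 of the current configuration."""
    coupled = coupled or CoupledPotential()
    eng = ToyEngine(system, coupled)
    pos = system.positions[None]
    return float(eng.u0_batch(pos)[0] + eng.delta_u_batch(pos)[0])


def coupled_energy(system: ToySystem, coupled: CoupledPotential, alpha: float
                   ) -> float:
    """Energy of the current configuration at coupling ``alpha``."""
    if not 0.0 <= alpha <= 1.0:
        raise ValueError("alpha must lie in [0, 1]")
    eng = ToyEngine(system, coupled)
    return float(eng.e_alpha_batch(system.positions[None], alpha)[0])


# -- snapshots and sampling ------------------------------------------------


@dataclass
class SnapshotSet:
    """Equilibrium configuration samples at a fixed alpha with cached dU."""

    positions: np.ndarray      # (S, N, 3) or (S,) for 1-D test hooks
    delta_u: np.ndarray        # (S,) instantaneous gap U_1 - U_0, kJ/mol
    alpha: float
    engine: object             # ToyEngine or a test-hook engine
    seed: int
    n_equil: int
    save_every: int
    acceptance_ratio: float
    dudalpha: np.ndarray | None = None  # TI integrand; equals delta_u for
                                        # linear coupling (default)

    def __post_init__(self):
        if self.dudalpha is None:
            self.dudalpha = self.delta_u

    @property
    def n_snapshots(self) -> int:
        return len(self.delta_u)

    def recompute_delta_u(self) -> np.ndarray:
        return self.engine.delta_u_batch(self.positions)


if _numba is not None:

    @_numba.njit(cache=True, inline="always")
    def _site_e_nb(pos, p, x, y, z, L, rc2, sigma, epsilon, charge,
                   is_solute, k_rf, c_rf, alpha, vdw_on, coul_on, bg_vdw,
                   bg_coul, softcore, alpha_sc, tether_k, cx, cy, cz):
        n = pos.shape[0]
        e = 0.0
        sp = is_solute[p]
        for j in range(n):
            if j == p:
                continue
            dx = pos[j, 0] - x
            dy = pos[j, 1] - y
            dz = pos[j, 2] - z
            dx -= L * round(dx / L)
            dy -= L * round(dy / L)
            dz -= L * round(dz / L)
            r2 = dx * dx + dy * dy + dz * dz
            if r2 < 1e-12:
                return 1e30
            if r2 > rc2:
                continue
            sij = 0.5 * (sigma[j] + sigma[p])
            eij = math.sqrt(epsilon[j] * epsilon[p])
            qq = charge[j] * charge[p]
            cross = sp != is_solute[j]
            if not cross:
                sr6 = (sij * sij / r2) ** 3
                e += 4.0 * eij * (sr6 * sr6 - sr6)
                if qq != 0.0:
                    r = math.sqrt(r2)
                    e += COULOMB * qq * (1.0 / r + k_rf * r2 - c_rf)
            else:
                if bg_vdw:
                    sr6 = (sij * sij / r2) ** 3
                    e += 4.0 * eij * (sr6 * sr6 - sr6)
                if bg_coul and qq != 0.0:
                    r = math.sqrt(r2)
                    e += COULOMB * qq * (1.0 / r + k_rf * r2 - c_rf)
                if vdw_on:
                    if softcore:
                        s6 = sij ** 6
                        den = alpha_sc * (1.0 - alpha) ** 2 * s6 + r2 ** 3
                        frac = s6 / den
                        e += 4.0 * eij * alpha * (frac * frac - frac)
                    else:
                        sr6 = (sij * sij / r2) ** 3
                        e += alpha * 4.0 * eij * (sr6 * sr6 - sr6)
                if coul_on and qq != 0.0:
                    r = math.sqrt(r2)
                    e += alpha * COULOMB * qq * (1.0 / r + k_rf * r2 - c_rf)
        if sp and tether_k != 0.0:
            dx = x - cx
            dy = y - cy
            dz = z - cz
            dx -= L * round(dx / L)
            dy -= L * round(dy / L)
            dz -= L * round(dz / L)
            e += 0.5 * tether_k * (dx * dx + dy * dy + dz * dz)
        return e

    @_numba.njit(cache=True)
    def _mc_kernel_nb(pos, L, rc2, sigma, epsilon, charge, is_solute, k_rf,
                      c_rf, alpha, beta, vdw_on, coul_on, bg_vdw, bg_coul,
                      softcore, alpha_sc, tether_k, cx, cy, cz, particles,
                      disps, urand, n_equil, save_every, snaps):
        total = particles.shape[0]
        accepted = 0
        s_idx = 0
        for m in range(total):
            p = particles[m]
            ox, oy, oz = pos[p, 0], pos[p, 1], pos[p, 2]
            nx = (ox + disps[m, 0]) % L
            ny = (oy + disps[m, 1]) % L
            nz = (oz + disps[m, 2]) % L
            e_old = _site_e_nb(pos, p, ox, oy, oz, L, rc2, sigma, epsilon,
                               charge, is_solute, k_rf, c_rf, alpha, vdw_on,
                               coul_on, bg_vdw, bg_coul, softcore, alpha_sc,
                               tether_k, cx, cy, cz)
            e_new = _site_e_nb(pos, p, nx, ny, nz, L, rc2, sigma, epsilon,
                               charge, is_solute, k_rf, c_rf, alpha, vdw_on,
                               coul_on, bg_vdw, bg_coul, softcore, alpha_sc,
                               tether_k, cx, cy, cz)
            de = e_new - e_old
            if de <= 0.0 or urand[m] < math.exp(-beta * de):
                pos[p, 0], pos[p, 1], pos[p, 2] = nx, ny, nz
                if m >= n_equil:
                    accepted += 1
            if m >= n_equil and (m - n_equil + 1) % save_every == 0:
                for i in range(pos.shape[0]):
                    snaps[s_idx, i, 0] = pos[i, 0]
                    snaps[s_idx, i, 1] = pos[i, 1]
                    snaps[s_idx, i, 2] = pos[i, 2]
                s_idx += 1
        return accepted


@dataclass(frozen=True)
class SamplerConfig:
    """Metropolis run-length and move-size settings."""

    seed: int
    n_equil: int = 2000
    n_steps: int = 20000
    save_every: int = 100
    max_displacement: float = 0.15   # nm

    def __post_init__(self):
        if not (self.n_steps >= self.save_every >= 1):
            raise ValueError("require n_steps >= save_every >= 1")
        if self.n_equil < 0:
            raise ValueError("n_equil must be non-negative")


def metropolis_sample(system: ToySystem, coupled: CoupledPotential,
                      alpha: float, state: ThermoState,
                      config: SamplerConfig, space=None, K=None
                      ) -> SnapshotSet:
    """Sample the alpha-coupled ensemble by single-particle Metropolis moves.

    Acceptance probability is ``min(1, exp(-beta dE))`` with the energy
    change evaluated from the moved particle's pair interactions only.
    Identical seed and config reproduce the snapshot set bit-for-bit.
    """
    if not 0.0 <= alpha <= 1.0:
        raise ValueError("alpha must lie in [0, 1]")
    sys_ = system.apply_parameters(space, K) if (space is not None and K is not None) else system
    engine = ToyEngine(sys_, coupled, space)
    rng = np.random.default_rng(config.seed)
    beta = state.beta
    n = sys_.n_sites
    pos = sys_.positions.copy()
    vdw_on, coul_on = coupled.stage_components()
    bg_vdw, bg_coul = coupled.background_components()
    softcore = coupled.mode == "softcore"

    sigma, epsilon, charge = sys_.sigma, sys_.epsilon, sys_.charge
    sol_mask = sys_.solute_mask
    L, r_c, eps_rf = sys_.L, sys_.r_c, sys_.eps_rf
    k_rf, c_rf = _rf_constants(r_c, eps_rf)
    centre = np.full(3, L / 2.0)
    any_charge = np.any(charge != 0.0)

    def site_energy(p: int, xyz: np.ndarray) -> float:
        """Energy of site p at position xyz with all other sites, at alpha."""
        others = np.arange(n) != p
        d = _min_image(pos[others] - xyz, L)
        r2 = np.einsum("ik,ik->i", d, d)
        if np.any(r2 < 1e-12):
            return math.inf
        within = r2 < r_c * r_c
        cross = sol_mask[others] ^ sol_mask[p]   # solute-solvent pairs
        sij = 0.5 * (sigma[others] + sigma[p])
        eij = np.sqrt(epsilon[others] * epsilon[p])
        qq = charge[others] * charge[p]
        u_pairs = np.zeros(n - 1)
        # non-alchemical part (solvent-solvent when p is solvent; none when
        # p is the solute apart from the tether)
        ss = ~cross
        if np.any(ss):
            sr6 = (sij[ss] ** 2 / r2[ss]) ** 3
            u = 4.0 * eij[ss] * (sr6 * sr6 - sr6)
            if any_charge:
                r = np.sqrt(r2[ss])
                u = u + COULOMB * qq[ss] * (1.0 / r + k_rf * r2[ss] - c_rf)
            u_pairs[ss] = u
        # solute-solvent part: unscaled background plus the coupled term
        if np.any(cross):
            u = np.zeros(np.count_nonzero(cross))
            r2c = r2[cross]
            if bg_vdw:
                sr6 = (sij[cross] ** 2 / r2c) ** 3
                u += 4.0 * eij[cross] * (sr6 * sr6 - sr6)
            if bg_coul and any_charge:
                r = np.sqrt(r2c)
                u += COULOMB * qq[cross] * (1.0 / r + k_rf * r2c - c_rf)
            if vdw_on:
                if softcore:
                    s6 = sij[cross] ** 6
                    den = coupled.alpha_sc * (1 - alpha) ** 2 * s6 + r2c ** 3
                    frac = s6 / den
                    u += 4.0 * eij[cross] * alpha * (frac * frac - frac)
                else:
                    sr6 = (sij[cross] ** 2 / r2c) ** 3
                    u += alpha * 4.0 * eij[cross] * (sr6 * sr6 - sr6)
            if coul_on and any_charge:
                r = np.sqrt(r2c)
                u += alpha * COULOMB * qq[cross] * (1.0 / r + k_rf * r2c - c_rf)
            u_pairs[cross] = u
        e = float(np.sum(np.where(within, u_pairs, 0.0)))
        if sol_mask[p] and sys_.tether_k:
            dt = _min_image(xyz - centre, L)
            e += 0.5 * sys_.tether_k * float(dt @ dt)
        return e

    total_moves = config.n_equil + config.n_steps
    move_particles = rng.integers(0, n, size=total_moves)
    move_disp = rng.uniform(-config.max_displacement, config.max_displacement,
                            size=(total_moves, 3))
    move_u = rng.random(total_moves)

    if _numba is not None:
        n_snap = config.n_steps // config.save_every
        snaps = np.empty((n_snap, n, 3))
        accepted = _mc_kernel_nb(
            pos, L, r_c * r_c, sigma, epsilon, charge, sol_mask, k_rf, c_rf,
            float(alpha), beta, vdw_on, coul_on, bg_vdw, bg_coul,
            coupled.mode == "softcore", coupled.alpha_sc, sys_.tether_k,
            centre[0], centre[1], centre[2], move_particles, move_disp,
            move_u, config.n_equil, config.save_every, snaps)
        du = engine.delta_u_batch(snaps)
        if not np.all(np.isfinite(du)):
            bad = int(np.flatnonzero(~np.isfinite(du))[0])
            raise FloatingPointError(
                f"non-finite energy during sampling (configuration index {bad})")
        duda = (du if coupled.mode == "linear"
                else engine.dudalpha_batch(snaps, alpha))
        return SnapshotSet(positions=snaps, delta_u=du, alpha=alpha,
                           engine=engine, seed=config.seed,
                           n_equil=config.n_equil,
                           save_every=config.save_every,
                           acceptance_ratio=accepted / max(config.n_steps, 1),
                           dudalpha=duda)

    saved = []
    accepted = 0
    for m in range(total_moves):
        p = int(move_particles[m])
        old = pos[p].copy()
        new = (old + move_disp[m]) % L
        e_old = site_energy(p, old)
        e_new = site_energy(p, new)
        if not math.isfinite(e_new) and not math.isfinite(e_old):
            raise FloatingPointError(
                f"non-finite energy at move {m} (configuration index "
                f"{len(saved)})")
        de = e_new - e_old
        if de <= 0.0 or move_u[m] < math.exp(-beta * de):
            pos[p] = new
            if m >= config.n_equil:
                accepted += 1
        if m >= config.n_equil and (m - config.n_equil + 1) % config.save_every == 0:
            saved.append(pos.copy())

    snaps = np.array(saved)
    du = engine.delta_u_batch(snaps)
    duda = (du if coupled.mode == "linear"
            else engine.dudalpha_batch(snaps, alpha))
    return SnapshotSet(positions=snaps, delta_u=du, alpha=alpha, engine=engine,
                       seed=config.seed, n_equil=config.n_equil,
                       save_every=config.save_every,
                       acceptance_ratio=accepted / max(config.n_steps, 1),
                       dudalpha=duda)


def save_snapshots(path, snapshots: SnapshotSet) -> None:
    """Write a snapshot archive as columnar text with a version header.

    Format: a header line, metadata lines, then one row per site per
    snapshot (snapshot index, site index, x, y, z, and the snapshot's
    cached dU on its first row).
    """
    pos = np.asarray(snapshots.positions)
    if pos.ndim != 3:
        raise ValueError("only 3-D configuration archives are supported")
    s, n, _ = pos.shape
    with open(path, "w") as fh:
        fh.write("# fegrad-snapshots v1\n")
        fh.write(f"# alpha={snapshots.alpha!r} seed={snapshots.seed} "
                 f"n_equil={snapshots.n_equil} "
                 f"save_every={snapshots.save_every} "
                 f"acceptance={snapshots.acceptance_ratio!r} "
                 f"n_snapshots={s} n_sites={n}\n")
        fh.write("snapshot,site,x,y,z,delta_u\n")
        for i in range(s):
            for j in range(n):
                du = repr(float(snapshots.delta_u[i])) if j == 0 else ""
                x, y, z = (float(v) for v in pos[i, j])
                fh.write(f"{i},{j},{x!r},{y!r},{z!r},{du}\n")


def load_snapshots(path, engine=None) -> SnapshotSet:
    """Read an archive written by :func:`save_snapshots`."""
    with open(path) as fh:
        header = fh.readline().strip()
        if header != "# fegrad-snapshots v1":
            raise ValueError(f"unexpected snapshot archive header {header!r}")
        meta = dict(tok.split("=", 1)
                    for tok in fh.readline().lstrip("# ").split())
        fh.readline()  # column names
        s, n = int(meta["n_snapshots"]), int(meta["n_sites"])
        pos = np.empty((s, n, 3))
        du = np.empty(s)
        for line in fh:
            fields = line.rstrip("\n").split(",")
            i, j = int(fields[0]), int(fields[1])
            pos[i, j] = [float(fields[2]), float(fields[3]), float(fields[4])]
            if fields[5]:
                du[i] = float(fields[5])
    return SnapshotSet(positions=pos, delta_u=du,
                       alpha=float(meta["alpha"]), engine=engine,
                       seed=int(meta["seed"]), n_equil=int(meta["n_equil"]),
                       save_every=int(meta["save_every"]),
                       acceptance_ratio=float(meta["acceptance"]))


#: 1 bar * nm^3 in kJ/mol.
BAR_NM3 = 0.0602214076


@dataclass
class NPTSnapshotSet:
    """Constant-pressure samples: configurations with per-snapshot box
    edges and volumes (the box fluctuates, so these do not feed the
    fixed-box gradient pipeline)."""

    positions: np.ndarray   # (S, N, 3)
    box_edges: np.ndarray   # (S,)
    alpha: float
    seed: int
    acceptance_ratio: float
    volume_acceptance: float

    @property
    def volumes(self) -> np.ndarray:
        return self.box_edges ** 3


def metropolis_sample_npt(system: ToySystem, coupled: CoupledPotential,
                          alpha: float, state: ThermoState,
                          config: SamplerConfig, volume_every: int = 100,
                          max_dlnv: float = 0.02) -> NPTSnapshotSet:
    """Optional constant-pressure sampling: particle-move cycles
    interleaved with isotropic volume moves in ln V.

    A volume move scales the box and all coordinates, with acceptance
    min(1, exp(-beta [dU + P dV] + (N+1) ln(V'/V))) targeting the NPT
    density V^N exp(-beta(U + PV)).  One snapshot is saved per cycle
    after equilibration.  The alchemical machinery itself runs in NVT;
    this sampler exists for density-style diagnostics.
    """
    if state.P is None:
        raise ValueError("constant-pressure sampling needs ThermoState.P")
    if not 0.0 <= alpha <= 1.0:
        raise ValueError("alpha must lie in [0, 1]")
    import dataclasses as _dc

    beta = state.beta
    p_kj = state.P * BAR_NM3
    rng = np.random.default_rng(config.seed)
    sys_ = system
    pos = system.positions.copy()
    n = system.n_sites
    n_cycles = (config.n_equil + config.n_steps) // volume_every
    equil_cycles = config.n_equil // volume_every
    saved_pos, saved_L = [], []
    acc_part = acc_vol = tries_vol = 0

    def energy(p, L):
        s = _dc.replace(sys_, L=L, positions=p)
        eng = ToyEngine(s, coupled)
        return float(eng.e_alpha_batch(p[None], alpha)[0])

    for cycle in range(n_cycles):
        sub = _dc.replace(sys_, positions=pos)
        cfg = SamplerConfig(seed=int(rng.integers(2 ** 31)), n_equil=0,
                            n_steps=volume_every, save_every=volume_every,
                            max_displacement=config.max_displacement)
        snaps = metropolis_sample(sub, coupled, alpha, state, cfg)
        pos = snaps.positions[-1].copy()
        acc_part += snaps.acceptance_ratio * volume_every

        v_old = sys_.L ** 3
        v_new = v_old * math.exp(rng.uniform(-max_dlnv, max_dlnv))
        L_new = v_new ** (1 / 3)
        tries_vol += 1
        if L_new > 2 * sys_.r_c:
            scale = L_new / sys_.L
            pos_new = pos * scale
            try:
                du = energy(pos_new, L_new) - energy(pos, sys_.L)
            except ValueError:
                du = math.inf
            arg = -beta * (du + p_kj * (v_new - v_old)) \
                + (n + 1) * math.log(v_new / v_old)
            if arg >= 0 or rng.random() < math.exp(arg):
                sys_ = _dc.replace(sys_, L=L_new)
                pos = pos_new
                acc_vol += 1
        if cycle >= equil_cycles:
            saved_pos.append(pos.copy())
            saved_L.append(sys_.L)

    return NPTSnapshotSet(
        positions=np.array(saved_pos), box_edges=np.array(saved_L),
        alpha=alpha, seed=config.seed,
        acceptance_ratio=acc_part / max(n_cycles * volume_every, 1),
        volume_acceptance=acc_vol / max(tries_vol, 1))


# -- system builders -------------------------------------------------------


def build_solvation_box(solute: Species, solvent_counts: dict[Species, int],
                        L: float, r_c: float = 0.9, seed: int = 0,
                        eps_rf: float = 78.4, tether_k: float = 10.0
                        ) -> ToySystem:
    """Place the solute at the box centre and solvent on a jittered lattice."""
    rng = np.random.default_rng(seed)
    n_solv = sum(solvent_counts.values())
    n_side = math.ceil((n_solv + 1) ** (1 / 3))
    grid = (np.arange(n_side) + 0.5) * (L / n_side)
    lattice = np.array(np.meshgrid(grid, grid, grid)).reshape(3, -1).T
    centre = np.full(3, L / 2.0)
    # drop the lattice point closest to the centre for the solute
    order = np.argsort(np.einsum("ik,ik->i", lattice - centre, lattice - centre))
    lattice = lattice[order]
    solv_sites = lattice[1:n_solv + 1]
    solv_sites = (solv_sites + rng.normal(0.0, 0.02 * L / n_side,
                                          solv_sites.shape)) % L
    species = {solute.name: solute}
    solvent_labels = []
    for sp, count in solvent_counts.items():
        species[sp.name] = sp
        solvent_labels.extend([sp.name] * count)
    rng.shuffle(solvent_labels)
    labels = [solute.name] + solvent_labels
    positions = np.vstack([centre, solv_sites])
    return ToySystem(L=L, r_c=r_c, positions=positions, species=species,
                     labels=tuple(labels), eps_rf=eps_rf, tether_k=tether_k)


# -- 1-D harmonic test hook ------------------------------------------------


class HarmonicEngine:
    """1-D harmonic oscillator test hook: U_a(x) = k_a x^2 / 2.

    The coupled potential interpolates the spring constant linearly between
    ``k0`` and ``k1``; closed-form ensemble averages make this the oracle
    for the TI and parameter-gradient estimators.  Parameters bind through
    a two-parameter space named ``("k0", "k1")``.
    """

    def __init__(self, k0: float, k1: float):
        self.k0, self.k1 = float(k0), float(k1)

    def _consts(self, K):
        if K is None:
            return self.k0, self.k1
        return float(K[0]), float(K[1])

    def delta_u_batch(self, x, K=None) -> np.ndarray:
        k0, k1 = self._consts(K)
        x = np.asarray(x, float)
        return 0.5 * (k1 - k0) * x ** 2

    def e_alpha_batch(self, x, alpha, K=None) -> np.ndarray:
        k0, k1 = self._consts(K)
        x = np.asarray(x, float)
        return 0.5 * ((1 - alpha) * k0 + alpha * k1) * x ** 2


def sample_harmonic(k0: float, k1: float, alpha: float, beta: float,
                    config: SamplerConfig) -> SnapshotSet:
    """Metropolis sampling of the 1-D harmonic hook at coupling ``alpha``."""
    engine = HarmonicEngine(k0, k1)
    k_alpha = (1 - alpha) * k0 + alpha * k1
    rng = np.random.default_rng(config.seed)
    x = 0.0
    saved = []
    accepted = 0
    total = config.n_equil + config.n_steps
    steps = rng.uniform(-config.max_displacement, config.max_displacement, total)
    us = rng.random(total)
    for m in range(total):
        xn = x + steps[m]
        de = 0.5 * k_alpha * (xn * xn - x * x)
        if de <= 0 or us[m] < math.exp(-beta * de):
            x = xn
            if m >= config.n_equil:
                accepted += 1
        if m >= config.n_equil and (m - config.n_equil + 1) % config.save_every == 0:
            saved.append(x)
    xs = np.array(saved)
    return SnapshotSet(positions=xs, delta_u=engine.delta_u_batch(xs),
                       alpha=alpha, engine=engine, seed=config.seed,
                       n_equil=config.n_equil, save_every=config.save_every,
                       acceptance_ratio=accepted / config.n_steps)


def harmonic_dudl_exact(k0: float, k1: float, alpha: float, kT: float) -> float:
    """Closed form <dU>_a = kT (k1 - k0) / (2 k_a)."""
    return kT * (k1 - k0) / (2.0 * ((1 - alpha) * k0 + alpha * k1))


def harmonic_delta_f_exact(k0: float, k1: float, kT: float) -> float:
    """Closed form dF = (kT / 2) ln(k1 / k0)."""
    return 0.5 * kT * math.log(k1 / k0)


def harmonic_dudl_dk1_exact(k0: float, k1: float, alpha: float, kT: float
                            ) -> float:
    """d<dU>_a / d k1 from differentiating the closed form."""
    ka = (1 - alpha) * k0 + alpha * k1
    return kT / (2 * ka) - alpha * (k1 - k0) * kT / (2 * ka * ka)
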