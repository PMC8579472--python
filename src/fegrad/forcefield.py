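"""Force-field parameters and the physical/mathematical coordinate mapping.

Optimisation is carried out in dimensionless "mathematical" coordinates
``k`` related to the physical parameters ``K`` by a shift-and-scale,

    K_i = K_i(0) + t_i * k_i,

where ``K_i(0)`` is the initial value and ``t_i`` the *prior width*: the
expected scale of the parameter's variation over the optimisation.  The
same widths set the strength of the Gaussian prior (quadratic penalty on
``k``) used for regularisation, so a parameter one prior width away from
its starting value contributes ``w_reg * 1`` to the objective.

Units are fixed package-wide: nm for lengths (sigma), kJ/mol for energies
(epsilon), elementary charge e for charges, K for temperatures.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np

KINDS = ("sigma", "epsilon", "charge", "bond_k", "bond_r0")

#: Default prior widths per parameter kind, used when a configuration does
#: not specify one.  Chosen as ~10-30% of typical magnitudes for CG beads.
DEFAULT_PRIOR_WIDTHS = {
    "sigma": 0.05,     # nm
    "epsilon": 0.2,    # kJ/mol
    "charge": 0.1,     # e
    "bond_k": 50.0,    # kJ/mol/nm^2
    "bond_r0": 0.02,   # nm
}

#: Default physical bounds per kind (lower, upper); None means unbounded.
DEFAULT_BOUNDS = {
    "sigma": (1e-6, None),
    "epsilon": (0.0, None),
    "charge": (None, None),
    "bond_k": (0.0, None),
    "bond_r0": (1e-6, None),
}


class ClipWarning(UserWarning):
    """A mapped physical parameter was clipped to its bound."""


@dataclass(frozen=True)
class ParameterSpace:
    """Named physical parameters with prior widths and frozen mask.

    Parameters
    ----------
    names
        Unique identifiers, conventionally ``"<species>.<attribute>"``
        (e.g. ``"solute.epsilon"``) so engines can bind them to a system.
    kinds
        One of :data:`KINDS` per parameter.
    K0
        Initial physical values (the centre of the Gaussian prior).
    t
        Prior widths, same units as ``K0``; all strictly positive.
    frozen
        Mask excluding parameters from optimisation; frozen parameters are
        passed through every mapping unchanged.
    lower, upper
        Optional physical bounds (NaN = unbounded).
    """

    names: tuple[str, ...]
    kinds: tuple[str, ...]
    K0: np.ndarray
    t: np.ndarray
    frozen: np.ndarray
    lower: np.ndarray = field(default=None)  # type: ignore[assignment]
    upper: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        object.__setattr__(self, "names", tuple(self.names))
        object.__setattr__(self, "kinds", tuple(self.kinds))
        object.__setattr__(self, "K0", np.asarray(self.K0, dtype=float))
        object.__setattr__(self, "t", np.asarray(self.t, dtype=float))
        object.__setattr__(self, "frozen", np.asarray(self.frozen, dtype=bool))
        n = len(self.names)
        if len(set(self.names)) != n:
            raise ValueError("parameter names must be unique")
        for kind in self.kinds:
            if kind not in KINDS:
                raise ValueError(f"unknown parameter kind {kind!r}")
        if not (len(self.kinds) == self.K0.size == self.t.size == self.frozen.size == n):
            raise ValueError("inconsistent field lengths in ParameterSpace")
        if np.any(self.t <= 0):
            bad = [self.names[i] for i in np.flatnonzero(self.t <= 0)]
            raise ValueError(f"prior widths must be positive: {bad}")
        if self.lower is None:
            lo = np.array([_bound(k, 0) for k in self.kinds], dtype=float)
            object.__setattr__(self, "lower", lo)
        else:
            object.__setattr__(self, "lower", np.asarray(self.lower, dtype=float))
        if self.upper is None:
            hi = np.array([_bound(k, 1) for k in self.kinds], dtype=float)
            object.__setattr__(self, "upper", hi)
        else:
            object.__setattr__(self, "upper", np.asarray(self.upper, dtype=float))

    # -- construction helpers -------------------------------------------------

    @classmethod
    def create(
        cls,
        names: Sequence[str],
        kinds: Sequence[str],
        K0: Sequence[float],
        t: Sequence[float] | None = None,
        frozen: Sequence[bool] | None = None,
    ) -> "ParameterSpace":
        """Build a space, filling prior widths from kind defaults if omitted."""
        kinds = tuple(kinds)
        if t is None:
            t = [DEFAULT_PRIOR_WIDTHS[k] for k in kinds]
        if frozen is None:
            frozen = [False] * len(kinds)
        return cls(tuple(names), kinds, np.asarray(K0, float),
                   np.asarray(t, float), np.asarray(frozen, bool))

    # -- basic queries --------------------------------------------------------

    @property
    def n_params(self) -> int:
        return len(self.names)

    @property
    def free_indices(self) -> np.ndarray:
        return np.flatnonzero(~self.frozen)

    @property
    def n_free(self) -> int:
        return int(np.count_nonzero(~self.frozen))

    def index(self, name: str) -> int:
        return self.names.index(name)

    # -- coordinate mapping ---------------------------------------------------

    def map_to_physical(self, k: np.ndarray) -> np.ndarray:
        """Map mathematical coordinates to the full physical vector.

        ``k`` has one entry per *unfrozen* parameter.  Values violating a
        bound are clipped to the bound and a :class:`ClipWarning` is issued
        naming the parameter, so a trust-region step can never produce an
        unevaluable force field.
        """
        k = np.atleast_1d(np.asarray(k, dtype=float))
        if k.size != self.n_free:
            raise ValueError(
                f"expected {self.n_free} mathematical coordinates, got {k.size}")
        K = self.K0.copy()
        free = self.free_indices
        K[free] = self.K0[free] + self.t[free] * k
        lo = np.where(np.isnan(self.lower), -np.inf, self.lower)
        hi = np.where(np.isnan(self.upper), np.inf, self.upper)
        clipped = (K < lo) | (K > hi)
        if np.any(clipped):
            for i in np.flatnonzero(clipped):
                warnings.warn(
                    f"parameter {self.names[i]} clipped to bound "
                    f"({K[i]:g} -> [{lo[i]:g}, {hi[i]:g}])",
                    ClipWarning, stacklevel=2)
            K = np.clip(K, lo, hi)
        return K

    def map_to_mathematical(self, K: np.ndarray) -> np.ndarray:
        """Inverse mapping, k_i = (K_i - K_i(0)) / t_i over unfrozen entries."""
        K = np.asarray(K, dtype=float)
        if K.size != self.n_params:
            raise ValueError(
                f"expected {self.n_params} physical values, got {K.size}")
        free = self.free_indices
        return (K[free] - self.K0[free]) / self.t[free]

    # -- perturbations (finite-difference support) ---------------------------

    def perturb(self, index: int | str, step: float, *, allow_zero: bool = False
                ) -> tuple["ParameterSpace", "ParameterSpace"]:
        """Return (plus, minus) copies with parameter ``index`` at K0 +/- step.

        ``step`` is in physical units.  A step that drives sigma or epsilon
        negative raises, naming the parameter; ``allow_zero`` permits a zero
        step for testing only.
        """
        if isinstance(index, str):
            index = self.index(index)
        if step < 0 or (step == 0 and not allow_zero):
            raise ValueError("perturbation step must be positive")
        out = []
        for sgn in (+1.0, -1.0):
            K = self.K0.copy()
            K[index] += sgn * step
            kind = self.kinds[index]
            if kind in ("sigma", "epsilon", "bond_k", "bond_r0") and K[index] < 0:
                raise ValueError(
                    f"perturbation drives {self.names[index]} ({kind}) "
                    f"negative: {K[index]:g}")
            out.append(replace(self, K0=K))
        return out[0], out[1]

    def with_K0(self, K0: np.ndarray) -> "ParameterSpace":
        """Copy with new initial values (re-centres the prior)."""
        return replace(self, K0=np.asarray(K0, dtype=float))


def _bound(kind: str, which: int) -> float:
    b = DEFAULT_BOUNDS[kind][which]
    return np.nan if b is None else float(b)


# -- flat parameter-file I/O ----------------------------------------------

_HEADER = "# fegrad-params v1"


def write_parameter_file(space: ParameterSpace, path: str | Path) -> None:
    """Write a flat key-value parameter file (one record per parameter)."""
    lines = [_HEADER]
    for i, name in enumerate(space.names):
        lo, hi = float(space.lower[i]), float(space.upper[i])
        lines.append(
            f"param name={name} kind={space.kinds[i]} "
            f"value={float(space.K0[i])!r} prior={float(space.t[i])!r} "
            f"frozen={int(space.frozen[i])} lower={lo!r} upper={hi!r}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_parameter_file(path: str | Path) -> ParameterSpace:
    """Read a file written by :func:`write_parameter_file`."""
    text = Path(path).read_text()
    names, kinds, K0, t, frozen, lo, hi = [], [], [], [], [], [], []
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        if not line.startswith("param "):
            raise ValueError(f"unrecognised record: {line!r}")
        fields = dict(tok.split("=", 1) for tok in line[6:].split())
        names.append(fields["name"])
        kinds.append(fields["kind"])
        K0.append(float(fields["value"]))
        t.append(float(fields["prior"]))
        frozen.append(bool(int(fields["frozen"])))
        lo.append(float(fields["lower"]))
        hi.append(float(fields["upper"]))
    return ParameterSpace(tuple(names), tuple(kinds), np.array(K0), np.array(t),
                          np.array(frozen), np.array(lo), np.array(hi))
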