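"""Named, bounded, unit-annotated model parameters.

A :class:`ParameterSpace` is the box :math:`\\Theta \\subset \\mathbb{R}^{N_P}`
over which simulations are sampled, surrogates are conditioned, sensitivity
indices are computed and posteriors are defined.  A :class:`ParameterVector`
is a single point :math:`\\theta \\in \\Theta` in physical units.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.stats import qmc

__all__ = ["ParameterSpace", "ParameterVector"]


@dataclass(frozen=True)
class ParameterSpace:
    """A bounded box of named physical parameters.

    Parameters
    ----------
    names
        Unique parameter identifiers.
    lower, upper
        Per-parameter bounds, physical units; ``lower[i] < upper[i]``.
    units
        Unit strings, one per parameter (for bookkeeping only).
    reference
        Baseline value per parameter, inside the bounds.
    """

    names: tuple[str, ...]
    lower: np.ndarray
    upper: np.ndarray
    units: tuple[str, ...]
    reference: np.ndarray

    def __init__(
        self,
        names: Sequence[str],
        lower: Iterable[float],
        upper: Iterable[float],
        units: Sequence[str],
        reference: Iterable[float],
    ):
        names = tuple(str(n) for n in names)
        lower = np.asarray(list(lower), dtype=float)
        upper = np.asarray(list(upper), dtype=float)
        units = tuple(str(u) for u in units)
        reference = np.asarray(list(reference), dtype=float)
        if len(set(names)) != len(names):
            raise ValueError("parameter names must be unique")
        if not (len(names) == lower.size == upper.size == len(units) == reference.size):
            raise ValueError("names, bounds, units and reference must have equal length")
        if not np.all(lower < upper):
            bad = [names[i] for i in np.nonzero(~(lower < upper))[0]]
            raise ValueError(f"lower must be strictly below upper for {bad}")
        if not np.all((reference >= lower) & (reference <= upper)):
            bad = [names[i] for i in np.nonzero(~((reference >= lower) & (reference <= upper)))[0]]
            raise ValueError(f"reference outside bounds for {bad}")
        for k, v in dict(
            names=names, lower=lower, upper=upper, units=units, reference=reference
        ).items():
            object.__setattr__(self, k, v)

    # -- basic queries -----------------------------------------------------
    def __len__(self) -> int:
        return len(self.names)

    def __contains__(self, name: object) -> bool:
        return name in self.names

    def index(self, name: str) -> int:
        try:
            return self.names.index(name)
        except ValueError:
            raise KeyError(f"unknown parameter {name!r}") from None

    @property
    def widths(self) -> np.ndarray:
        return self.upper - self.lower

    def reference_vector(self) -> "ParameterVector":
        return ParameterVector(self, self.reference.copy())

    # -- scaling -----------------------------------------------------------
    def to_unit(self, values: np.ndarray) -> np.ndarray:
        """Affine map from physical units onto ``[-1, 1]`` per coordinate."""
        return 2.0 * (np.asarray(values, float) - self.lower) / self.widths - 1.0

    def from_unit(self, scaled: np.ndarray) -> np.ndarray:
        return self.lower + (np.asarray(scaled, float) + 1.0) / 2.0 * self.widths

    def contains_values(self, values: np.ndarray) -> bool:
        v = np.asarray(values, float)
        return bool(np.all(v >= self.lower) and np.all(v <= self.upper))

    # -- sampling ----------------------------------------------------------
    def sample_lhs(self, n: int, seed: int) -> np.ndarray:
        """Latin-hypercube sample of ``n`` points, shape ``(n, len(self))``.

        Each parameter gets exactly one sample in every ``1/n`` quantile
        stratum of its range.
        """
        if n < 1:
            raise ValueError("n must be >= 1")
        sampler = qmc.LatinHypercube(d=len(self), seed=int(seed))
        u = sampler.random(n)
        return qmc.scale(u, self.lower, self.upper)

    def subspace(self, names: Sequence[str]) -> "ParameterSpace":
        idx = [self.index(n) for n in names]
        return ParameterSpace(
            [self.names[i] for i in idx],
            self.lower[idx],
            self.upper[idx],
            [self.units[i] for i in idx],
            self.reference[idx],
        )

    def to_dict(self) -> dict:
        return {
            "names": list(self.names),
            "lower": self.lower.tolist(),
            "upper": self.upper.tolist(),
            "units": list(self.units),
            "reference": self.reference.tolist(),
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "ParameterSpace":
        return cls(d["names"], d["lower"], d["upper"], d["units"], d["reference"])


@dataclass(frozen=True)
class ParameterVector:
    """A point in a :class:`ParameterSpace`, physical units, bounds-checked."""

    space: ParameterSpace
    values: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __init__(self, space: ParameterSpace, values):
        if isinstance(values, Mapping):
            missing = [n for n in space.names if n not in values]
            if missing:
                raise KeyError(f"missing parameter values for {missing}")
            values = np.asarray([values[n] for n in space.names], dtype=float)
        else:
            values = np.asarray(values, dtype=float)
        if values.shape != (len(space),):
            raise ValueError(f"expected {len(space)} values, got shape {values.shape}")
        if not space.contains_values(values):
            out = [
                f"{space.names[i]}={values[i]:g} not in [{space.lower[i]:g}, {space.upper[i]:g}]"
                for i in range(len(space))
                if not (space.lower[i] <= values[i] <= space.upper[i])
            ]
            raise ValueError("parameter(s) out of bounds: " + "; ".join(out))
        object.__setattr__(self, "space", space)
        object.__setattr__(self, "values", values)

    def __getitem__(self, name: str) -> float:
        return float(self.values[self.space.index(name)])

    def get(self, name: str, default: float | None = None) -> float | None:
        return self[name] if name in self.space else default

    def replace(self, **updates: float) -> "ParameterVector":
        v = self.values.copy()
        for name, val in updates.items():
            v[self.space.index(name)] = val
        return ParameterVector(self.space, v)

    def as_dict(self) -> dict[str, float]:
        return {n: float(v) for n, v in zip(self.space.names, self.values)}

    def scaled(self) -> np.ndarray:
        """This point mapped to the unit box ``[-1, 1]^{N_P}``."""
        return self.space.to_unit(self.values)
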