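"""Discrete hyperparameter search space for the 1D CNN architecture.

Three architecture hyperparameters are optimized, each over an integer
range:

* ``KS`` — kernel size of each convolutional layer (one value per layer,
  odd-only by default so kernels have a centre tap),
* ``KC`` — kernel count of each convolutional layer,
* ``DLNC`` — neuron counts of the two dense layers that always follow the
  convolutional stack, regardless of its depth.

The number of convolutional layers (``cld``) fixes how many KS/KC entries a
candidate carries; the dense head always has exactly two widths.  The default
bounds reproduce the published configuration: odd kernel sizes 3–81, kernel
counts 16–1024, dense widths 256–4096, three convolutional layers — a space
of 40^3 x 1009^3 x 3841^2 ~ 9.7e20 candidates.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Iterator, Sequence

import numpy as np

__all__ = [
    "AXES",
    "HyperparameterSpace",
    "HPVector",
    "ValidationResult",
    "axis_value_count",
    "cardinality",
    "random_hp",
    "validate_hp",
    "enumerate_space",
]

#: Names of the optimized hyperparameter axes.
AXES = ("KS", "KC", "DLNC")


@dataclass(frozen=True)
class HyperparameterSpace:
    """Bounds and parity rules for the discrete search space.

    Defaults are the full published space; tests and desk-scale runs shrink
    the bounds through the same interface.
    """

    cld: int = 3
    ks_min: int = 3
    ks_max: int = 81
    kc_min: int = 16
    kc_max: int = 1024
    dlnc_min: int = 256
    dlnc_max: int = 4096
    ks_odd_only: bool = True

    def __post_init__(self) -> None:
        if self.cld < 1:
            raise ValueError(f"cld must be >= 1, got {self.cld}")
        for lo, hi, name in (
            (self.ks_min, self.ks_max, "ks"),
            (self.kc_min, self.kc_max, "kc"),
            (self.dlnc_min, self.dlnc_max, "dlnc"),
        ):
            if lo < 1:
                raise ValueError(f"{name}_min must be >= 1, got {lo}")
            if lo > hi:
                raise ValueError(f"{name}_min={lo} exceeds {name}_max={hi}")
        if self.ks_odd_only and (self.ks_min % 2 == 0 or self.ks_max % 2 == 0):
            raise ValueError(
                "ks bounds must be odd when ks_odd_only is set, got "
                f"[{self.ks_min}, {self.ks_max}]"
            )

    def axis_bounds(self, axis: str) -> tuple[int, int]:
        """Return ``(min, max)`` for an axis name in :data:`AXES`."""
        if axis == "KS":
            return self.ks_min, self.ks_max
        if axis == "KC":
            return self.kc_min, self.kc_max
        if axis == "DLNC":
            return self.dlnc_min, self.dlnc_max
        raise ValueError(f"unknown axis {axis!r}; expected one of {AXES}")

    def axis_values(self, axis: str) -> range:
        """Admissible integer values on an axis, as a :class:`range`."""
        lo, hi = self.axis_bounds(axis)
        step = 2 if (axis == "KS" and self.ks_odd_only) else 1
        return range(lo, hi + 1, step)

    def axis_parity(self, axis: str) -> bool:
        return axis == "KS" and self.ks_odd_only


@dataclass(frozen=True)
class HPVector:
    """One candidate architecture: per-layer kernel sizes and counts plus
    the two dense-layer widths."""

    ks: tuple[int, ...]
    kc: tuple[int, ...]
    dlnc: tuple[int, int]

    def __post_init__(self) -> None:
        object.__setattr__(self, "ks", tuple(int(v) for v in self.ks))
        object.__setattr__(self, "kc", tuple(int(v) for v in self.kc))
        object.__setattr__(self, "dlnc", tuple(int(v) for v in self.dlnc))

    def as_tuple(self) -> tuple[int, ...]:
        """Flat ``(ks..., kc..., dlnc1, dlnc2)`` tuple; hashable cache key."""
        return self.ks + self.kc + self.dlnc


@dataclass(frozen=True)
class ValidationResult:
    """Verdict of :func:`validate_hp` with per-field diagnostics."""

    ok: bool
    problems: tuple[str, ...] = ()

    def __bool__(self) -> bool:
        return self.ok


def axis_value_count(space: HyperparameterSpace, axis: str) -> int:
    """Number of admissible values on one axis.

    Odd-only kernel sizes are counted on the odd grid; the other axes count
    every integer in the closed interval.  For the default space this gives
    40 (KS), 1009 (KC) and 3841 (DLNC).
    """
    return len(space.axis_values(axis))


def cardinality(space: HyperparameterSpace) -> int:
    """Exact number of candidate architectures in the space.

    Computed as ``|KS|^cld * |KC|^cld * |DLNC|^2`` with Python integers, so
    the default space's ~9.7e20 is returned exactly.
    """
    n_ks = axis_value_count(space, "KS")
    n_kc = axis_value_count(space, "KC")
    n_dlnc = axis_value_count(space, "DLNC")
    return n_ks**space.cld * n_kc**space.cld * n_dlnc**2


def random_hp(space: HyperparameterSpace, rng: np.random.Generator) -> HPVector:
    """Draw a candidate uniformly: each coordinate independent and uniform
    over its admissible value set."""
    ks_vals = space.axis_values("KS")
    kc_vals = space.axis_values("KC")
    dlnc_vals = space.axis_values("DLNC")
    ks = tuple(ks_vals[i] for i in rng.integers(0, len(ks_vals), space.cld))
    kc = tuple(kc_vals[i] for i in rng.integers(0, len(kc_vals), space.cld))
    dlnc = tuple(dlnc_vals[i] for i in rng.integers(0, len(dlnc_vals), 2))
    return HPVector(ks=ks, kc=kc, dlnc=dlnc)  # type: ignore[arg-type]


def _check_axis(
    values: Sequence[int], axis: str, space: HyperparameterSpace, problems: list[str]
) -> None:
    lo, hi = space.axis_bounds(axis)
    for d, v in enumerate(values, start=1):
        if not lo <= v <= hi:
            problems.append(f"{axis.lower()}[{d}]={v} outside [{lo}, {hi}]")
        elif space.axis_parity(axis) and v % 2 == 0:
            problems.append(f"{axis.lower()}[{d}]={v} violates odd-only parity")


def validate_hp(space: HyperparameterSpace, hp: HPVector) -> ValidationResult:
    """Check a candidate against the space; returns diagnostics, never raises."""
    problems: list[str] = []
    if len(hp.ks) != space.cld:
        problems.append(f"ks has {len(hp.ks)} entries, expected cld={space.cld}")
    if len(hp.kc) != space.cld:
        problems.append(f"kc has {len(hp.kc)} entries, expected cld={space.cld}")
    if len(hp.dlnc) != 2:
        problems.append(f"dlnc has {len(hp.dlnc)} entries, expected exactly 2")
    _check_axis(hp.ks, "KS", space, problems)
    _check_axis(hp.kc, "KC", space, problems)
    _check_axis(hp.dlnc, "DLNC", space, problems)
    return ValidationResult(ok=not problems, problems=tuple(problems))


def enumerate_space(space: HyperparameterSpace) -> Iterator[HPVector]:
    """Yield every candidate in the space (use only on small spaces)."""
    ks_vals = list(space.axis_values("KS"))
    kc_vals = list(space.axis_values("KC"))
    dlnc_vals = list(space.axis_values("DLNC"))
    for ks in itertools.product(ks_vals, repeat=space.cld):
        for kc in itertools.product(kc_vals, repeat=space.cld):
            for dlnc in itertools.product(dlnc_vals, repeat=2):
                yield HPVector(ks=ks, kc=kc, dlnc=dlnc)  # type: ignore[arg-type]
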