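"""The seven species-abundance-distribution models on the octave scale.

Each model gives the expected number of species ``S(R)`` in octave ``R``
(``R = log2 r`` of the abundance ``r``).  The set mixes niche-based models —
geometric series (GS), broken stick (BS), overlapping niche (ON) — with
statistical ones — logseries (LSer), lognormal (LN), logCauchy (LC) and
log-sech (LS):

========  =======================================  ==========================
name      S(R)                                     S* (extrapolated richness)
========  =======================================  ==========================
GS        Sm                                       undefined (area diverges)
BS        Sm * exp(-alpha*2**R + R*ln 2)           Sm / (alpha * ln 2)
ON        Sm * (1 - 2**R / N_oct) * 2**R           Sm / (2 * ln 2)
LSer      Sm * alpha**(2**R),  R >= 0              undefined
LN        Sm * exp(-alpha**2 * (R - Rm)**2)        sqrt(pi) * Sm / alpha
LC        Sm / (1 + alpha**2 * (R - Rm)**2)        pi * Sm / alpha
LS        Sm * sech(alpha * (R - Rm))              pi * Sm / alpha
========  =======================================  ==========================

``Sm`` is the height of the curve (species in the modal octave), ``alpha``
a shape/scale constant, and ``Rm`` the modal octave of the three symmetric
models.  ``S*`` is the area under the complete, untruncated curve — the
theoretical total richness once the species hidden behind the sampling veil
are extrapolated.  For BS, LN, LC and LS the closed forms above equal the
integral of ``S(R)`` over the whole line; the ON value is the conventional
closed form reported with this model family and is *not* the integral of
its octave curve (which depends on the data constant ``N_oct``) — see the
package methods note.

The ON model carries two frozen data constants taken from the observed
histogram (``N_oct``, the octave-transformed total abundance, and ``R_max``);
they are not free parameters, so its parameter count stays ``k = 1``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Mapping

import numpy as np

__all__ = [
    "MODEL_NAMES",
    "ModelSpec",
    "get_model",
    "model_registry",
    "evaluate_model",
    "estimate_total_richness",
]

#: paper-order model names as accepted in CLI/config
MODEL_NAMES = ("gs", "bs", "on", "lser", "ln", "lc", "ls")

LN2 = math.log(2.0)


class UnsupportedModelError(ValueError):
    """The requested quantity is undefined for this model."""


class DomainError(ValueError):
    """Evaluation requested outside the model's domain."""


def _sech(x: np.ndarray) -> np.ndarray:
    # 1/cosh with overflow guard: cosh overflows for |x| > ~710, where
    # sech is indistinguishable from 0
    x = np.asarray(x, dtype=float)
    out = np.zeros_like(x)
    small = np.abs(x) < 700
    out[small] = 1.0 / np.cosh(x[small])
    return out


@dataclass(frozen=True)
class ModelSpec:
    """One SAD model: its octave-scale curve, parameters and S* formula."""

    name: str
    k: int
    param_names: tuple[str, ...]
    func: Callable[..., np.ndarray] = field(repr=False)
    sstar: Callable[..., float] | None = field(default=None, repr=False)
    needs_data_constants: bool = False
    #: admissible (low, high) per parameter; None entries are data dependent
    bounds: tuple[tuple[float, float], ...] = ()

    @property
    def has_sstar(self) -> bool:
        return self.sstar is not None

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.name.upper()


def _gs(R, Sm):
    return np.full_like(np.asarray(R, dtype=float), Sm)


def _bs(R, Sm, alpha):
    R = np.asarray(R, dtype=float)
    with np.errstate(over="ignore"):  # far right tail: exp(-inf) -> 0
        return Sm * np.exp(-alpha * np.exp2(R) + R * LN2)


def _on(R, Sm, *, N_oct, R_max):
    R = np.asarray(R, dtype=float)
    two_R = np.exp2(R)
    if np.any(two_R > N_oct):
        raise DomainError(
            f"ON model undefined where 2**R > N_oct ({N_oct}); got R up to {R.max()}"
        )
    return Sm * (1.0 - two_R / N_oct) * two_R


def _lser(R, Sm, alpha):
    R = np.asarray(R, dtype=float)
    if np.any(R < 0):
        raise DomainError("LSer octave curve is defined for R >= 0 only")
    return Sm * np.power(alpha, np.exp2(R))


def _ln(R, Sm, alpha, Rm):
    R = np.asarray(R, dtype=float)
    return Sm * np.exp(-(alpha**2) * (R - Rm) ** 2)


def _lc(R, Sm, alpha, Rm):
    R = np.asarray(R, dtype=float)
    return Sm / (1.0 + alpha**2 * (R - Rm) ** 2)


def _ls(R, Sm, alpha, Rm):
    R = np.asarray(R, dtype=float)
    return Sm * _sech(alpha * (R - Rm))


_POS = (1e-12, np.inf)

_REGISTRY: dict[str, ModelSpec] = {
    spec.name: spec
    for spec in (
        ModelSpec("gs", 1, ("Sm",), _gs, bounds=(_POS,)),
        ModelSpec(
            "bs", 2, ("Sm", "alpha"), _bs,
            sstar=lambda Sm, alpha: Sm / (alpha * LN2),
            bounds=(_POS, _POS),
        ),
        ModelSpec(
            "on", 1, ("Sm",), _on,
            sstar=lambda Sm: Sm / (2.0 * LN2),
            needs_data_constants=True,
            bounds=(_POS,),
        ),
        ModelSpec(
            "lser", 2, ("Sm", "alpha"), _lser,
            bounds=(_POS, (1e-12, 1.0 - 1e-12)),
        ),
        ModelSpec(
            "ln", 3, ("Sm", "alpha", "Rm"), _ln,
            sstar=lambda Sm, alpha, Rm: math.sqrt(math.pi) * Sm / alpha,
            bounds=(_POS, _POS, (-np.inf, np.inf)),
        ),
        ModelSpec(
            "lc", 3, ("Sm", "alpha", "Rm"), _lc,
            sstar=lambda Sm, alpha, Rm: math.pi * Sm / alpha,
            bounds=(_POS, _POS, (-np.inf, np.inf)),
        ),
        ModelSpec(
            "ls", 3, ("Sm", "alpha", "Rm"), _ls,
            sstar=lambda Sm, alpha, Rm: math.pi * Sm / alpha,
            bounds=(_POS, _POS, (-np.inf, np.inf)),
        ),
    )
}


def get_model(name: str) -> ModelSpec:
    try:
        return _REGISTRY[name.lower()]
    except KeyError:
        raise KeyError(f"unknown model {name!r}; expected one of {MODEL_NAMES}")


def model_registry() -> list[ModelSpec]:
    """The seven model specs in the conventional order GS, BS, ON, LSer, LN, LC, LS."""
    return [_REGISTRY[name] for name in MODEL_NAMES]


def evaluate_model(
    spec: ModelSpec | str,
    theta: Mapping[str, float] | tuple[float, ...],
    R,
    constants: Mapping[str, float] | None = None,
) -> np.ndarray:
    """Expected species count ``S(R)`` for one model at octave(s) ``R``.

    ``theta`` is a mapping (or tuple in ``param_names`` order) of parameter
    values; the ON model additionally requires ``constants`` with ``N_oct``
    and ``R_max`` from the observed histogram.
    """
    if isinstance(spec, str):
        spec = get_model(spec)
    if not isinstance(theta, Mapping):
        theta = dict(zip(spec.param_names, theta))
    args = [float(theta[p]) for p in spec.param_names]
    if spec.needs_data_constants:
        if not constants:
            raise ValueError(f"{spec.name} needs data constants N_oct and R_max")
        return spec.func(R, *args, N_oct=float(constants["N_oct"]),
                         R_max=float(constants["R_max"]))
    return spec.func(R, *args)


def estimate_total_richness(
    spec: ModelSpec | str, theta: Mapping[str, float] | tuple[float, ...]
) -> float:
    """Extrapolated total richness ``S*`` (area under the untruncated curve).

    Undefined for GS (the constant curve has infinite area) and LSer.
    """
    if isinstance(spec, str):
        spec = get_model(spec)
    if not spec.has_sstar:
        raise UnsupportedModelError(f"S* is undefined for the {spec.name.upper()} model")
    if not isinstance(theta, Mapping):
        theta = dict(zip(spec.param_names, theta))
    args = [float(theta[p]) for p in spec.param_names]
    return float(spec.sstar(*args))
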