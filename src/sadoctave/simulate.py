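"""Synthetic hollow-curve communities from the generative form of each model.

The analysis pipeline (bin, fit, select) is validated on communities whose
true generating model is known.  Each of the seven models has a generative
reading:

* **GS** (niche preemption): species ``j`` takes a fixed fraction ``k`` of
  the remaining resource, so its relative abundance is
  ``p_j = k*(1-k)**(j-1)``; abundances are ``round(N*p_j)``.
* **BS** (broken stick): simultaneous random partition; the j-th most
  abundant species has ``p_j = (1/S) * sum_{i=j..S} 1/i``.
* **ON** (overlapping niche): each species' relative abundance is an
  independent draw from the triangular density ``f(r) = 2 - 2r`` on
  ``[0, 1]``, sampled by inverse CDF ``r = 1 - sqrt(1 - u)``.
* **LSer**: per-species abundance from the continuous logseries density
  ``f(r) = alpha**r / (r * E1(-ln alpha))`` on ``[1, inf)`` by tabulated
  inverse CDF (``E1`` the exponential integral).
* **LN / LC / LS**: the species' octave ``R = log2 r`` is drawn from a
  normal / Cauchy / hyperbolic-secant location-scale law centred at ``Rm``
  whose density is proportional to the model's octave curve; then
  ``r = round(2**R)``.

With ``truncate_at_one`` (the veil line) species landing below one
individual are resampled, mimicking the left truncation of every observed
SAD.  GS/BS/ON can alternatively draw ``N`` individuals multinomially over
the relative abundances instead of deterministic rounding.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy import special

from .binning import AbundanceRecord, LayerDataset, OctaveHistogram, bin_octaves
from .fitting import FitOptions
from .models import ModelSpec, evaluate_model, get_model

__all__ = [
    "SyntheticConfig",
    "generate_community",
    "expected_histogram",
    "parameter_recovery_trial",
    "sech_ppf",
]


class GenerationError(RuntimeError):
    """The configuration yielded too few surviving species."""


@dataclass(frozen=True)
class SyntheticConfig:
    """Generator settings for one synthetic community.

    ``S`` is the number of species drawn (before veil-line losses for the
    deterministic models), ``N`` the target total number of individuals
    (GS/BS/ON only).  A seed is mandatory: every community must be exactly
    reproducible.
    """

    model: str
    S: int
    seed: int
    N: int | None = None
    k: float | None = None       # gs preemption fraction, in (0, 1)
    alpha: float | None = None   # lser in (0,1); ln/lc/ls shape > 0
    Rm: float | None = None      # ln/lc/ls modal octave
    truncate_at_one: bool = True
    multinomial: bool = False    # gs/bs/on: sample N individuals instead of rounding

    def __post_init__(self) -> None:
        name = self.model.lower()
        if name not in ("gs", "bs", "on", "lser", "ln", "lc", "ls"):
            raise ValueError(f"unknown model {self.model!r}")
        object.__setattr__(self, "model", name)
        if self.S < 3:
            raise ValueError("S must be at least 3")
        if name in ("gs", "bs", "on") and (self.N is None or self.N < 1):
            raise ValueError(f"{name} needs a target total abundance N")
        if name == "gs" and not (self.k is not None and 0 < self.k < 1):
            raise ValueError("gs needs preemption fraction k in (0, 1)")
        if name == "lser" and not (self.alpha is not None and 0 < self.alpha < 1):
            raise ValueError("lser needs alpha in (0, 1)")
        if name in ("ln", "lc", "ls"):
            if not (self.alpha is not None and self.alpha > 0):
                raise ValueError(f"{name} needs alpha > 0")
            if self.Rm is None:
                raise ValueError(f"{name} needs a modal octave Rm")


def _round_half_up(x: np.ndarray) -> np.ndarray:
    return np.floor(np.asarray(x, dtype=float) + 0.5).astype(int)


def sech_ppf(u, Rm: float = 0.0, alpha: float = 1.0) -> np.ndarray:
    """Quantile function of the hyperbolic-secant law with density
    ``(alpha/pi) * sech(alpha*(x - Rm))``: ``x = Rm + ln(tan(pi*u/2))/alpha``."""
    u = np.asarray(u, dtype=float)
    return Rm + np.log(np.tan(0.5 * math.pi * u)) / alpha


def _lser_inverse_cdf_table(alpha: float, r_max: float = 1e6, knots: int = 4096):
    """Tabulated CDF of f(r) = alpha**r / (r*E1(-ln alpha)) on [1, r_max]."""
    a = -math.log(alpha)
    r = np.logspace(0.0, math.log10(r_max), knots)
    dens = np.exp(-a * r) / (r * special.exp1(a))
    cdf = np.concatenate([[0.0], np.cumsum(np.diff(r) * 0.5 * (dens[1:] + dens[:-1]))])
    return r, cdf


def _sample_lser(rng: np.random.Generator, alpha: float, size: int) -> np.ndarray:
    r_knots, cdf = _lser_inverse_cdf_table(alpha)
    F_max = cdf[-1]
    out = np.empty(size)
    filled = 0
    while filled < size:
        u = rng.random(size - filled)
        ok = u < F_max  # beyond the table: resample the draw
        vals = np.interp(u[ok], cdf, r_knots)
        out[filled:filled + vals.size] = vals
        filled += vals.size
    return out


def _class_consistent_abundance(R: np.ndarray) -> np.ndarray:
    """Integer abundance from a continuous octave draw, class-consistent.

    The draw's octave class is its nearest integer ``C = round(R)``, so the
    class counts follow the model's octave density integrated over
    ``(C - 1/2, C + 1/2]`` — the quantisation that leaves the fitted curve's
    location and shape asymptotically unbiased.  The abundance itself is
    ``round(2**R)`` clipped into the half-open class ``(2**(C-1), 2**C]``
    (class 1 additionally holds abundance 1), so binning the community
    recovers exactly the drawn classes.  Draws below class 1 round to zero
    individuals and are dropped (or resampled at the veil line upstream).
    """
    R = np.asarray(R, dtype=float)
    C = _round_half_up(R)
    r = _round_half_up(np.exp2(R))
    above = C >= 1
    lo = np.where(C > 1, np.exp2(np.clip(C - 1, 0, 62)) + 1, 1.0)
    hi = np.exp2(np.clip(C, 1, 62))
    # draws whose class lies below class 1 are hidden behind the veil: zero
    # individuals (dropped or resampled upstream)
    r = np.where(above, np.clip(r, lo, hi), 0.0).astype(np.int64)
    return r


def _octave_draw(rng: np.random.Generator, cfg: SyntheticConfig, size: int) -> np.ndarray:
    if cfg.model == "ln":
        # density exp(-alpha^2 (R-Rm)^2) is normal with sigma = 1/(alpha*sqrt 2)
        R = rng.normal(cfg.Rm, 1.0 / (cfg.alpha * math.sqrt(2.0)), size)
    elif cfg.model == "lc":
        R = cfg.Rm + rng.standard_cauchy(size) / cfg.alpha
    else:
        R = sech_ppf(rng.random(size), Rm=cfg.Rm, alpha=cfg.alpha)
    # 2**R must stay inside int64; the Cauchy tail can otherwise overflow
    return np.clip(R, -200.0, 62.0)


def _relative_abundances(rng: np.random.Generator, cfg: SyntheticConfig) -> np.ndarray:
    j = np.arange(1, cfg.S + 1)
    if cfg.model == "gs":
        return cfg.k * (1.0 - cfg.k) ** (j - 1)
    if cfg.model == "bs":
        recip = 1.0 / j
        return np.cumsum(recip[::-1])[::-1] / cfg.S  # (1/S) * sum_{i=j..S} 1/i
    # on: independent draws from f(r) = 2 - 2r by inverse CDF
    u = rng.random(cfg.S)
    r = 1.0 - np.sqrt(1.0 - u)
    return r / r.sum()


def generate_community(cfg: SyntheticConfig) -> LayerDataset:
    """Draw one synthetic community; deterministic for a given config.

    Returns a :class:`LayerDataset` labelled ``synthetic/<model>``.  Species
    that round to zero abundance are dropped and counted in
    ``meta['dropped_zero']``; ``meta['resampled']`` counts veil-line
    resampling events for the octave-scale models.
    """
    rng = np.random.default_rng(cfg.seed)
    meta = {"config": cfg, "dropped_zero": 0, "resampled": 0}

    if cfg.model in ("gs", "bs", "on"):
        p = _relative_abundances(rng, cfg)
        if cfg.multinomial:
            abundances = rng.multinomial(cfg.N, p)
        else:
            abundances = _round_half_up(cfg.N * p)
    else:
        if cfg.model == "lser":
            abundances = _round_half_up(_sample_lser(rng, cfg.alpha, cfg.S))
        else:
            R = _octave_draw(rng, cfg, cfg.S)
            if cfg.truncate_at_one:
                # veil line: draws whose octave class falls below the first
                # integer class (abundance < 1 individual) are redrawn
                bad = _round_half_up(R) < 1
                while bad.any():
                    meta["resampled"] += int(bad.sum())
                    R[bad] = _octave_draw(rng, cfg, int(bad.sum()))
                    bad = _round_half_up(R) < 1
            abundances = _class_consistent_abundance(R)

    keep = abundances >= 1
    meta["dropped_zero"] = int((~keep).sum())
    abundances = abundances[keep]
    if abundances.size < 3:
        raise GenerationError(
            f"only {abundances.size} species survived (model={cfg.model}); "
            "increase S or N"
        )
    records = [
        AbundanceRecord(f"sp{i + 1:04d}", int(a)) for i, a in enumerate(abundances)
    ]
    return LayerDataset("synthetic", cfg.model, records, meta=meta)


def expected_histogram(
    spec: ModelSpec | str,
    theta,
    octaves: Sequence[int],
    constants=None,
    dialect: str = "halfopen",
) -> OctaveHistogram:
    """Noiseless histogram with counts ``S(R; theta)`` at the given octaves.

    An exact fixed point for the fitting routines: fitting the generating
    model to this histogram reproduces ``theta`` with zero residual.
    """
    octaves = np.asarray(octaves, dtype=int)
    counts = np.asarray(evaluate_model(spec, theta, octaves, constants), dtype=float)
    name = spec if isinstance(spec, str) else spec.name
    return OctaveHistogram(octaves, counts, dialect, source_label=f"expected/{name}")


def parameter_recovery_trial(
    cfg: SyntheticConfig,
    reps: int,
    fit_opts: FitOptions | None = None,
    dialect: str = "halfopen",
) -> dict:
    """Generate -> bin -> fit-all, ``reps`` times; summarise recovery.

    Reports bias and RMSE of the generating model's fitted shape parameters
    (``alpha``, ``Rm`` where applicable, and richness via ``S*`` against the
    number of species drawn) plus the fraction of replicates in which the
    generating model is selected best by AIC.
    """
    from .selection import fit_all, select_best

    if reps < 1:
        raise ValueError("reps must be >= 1")
    fit_opts = fit_opts or FitOptions()
    child_seeds = np.random.SeedSequence(cfg.seed).generate_state(reps) % (2**31)
    rows = {"alpha": [], "Rm": [], "S_star": []}
    selected = 0
    for i in range(reps):
        ds = generate_community(replace(cfg, seed=int(child_seeds[i])))
        h = bin_octaves(ds, dialect)
        table = fit_all(h, fit_opts)
        if select_best(table, "aic") == cfg.model:
            selected += 1
        fit = table.fits.get(cfg.model)
        if fit is None:
            continue
        if "alpha" in fit.theta:
            rows["alpha"].append(fit.theta["alpha"])
        if "Rm" in fit.theta:
            rows["Rm"].append(fit.theta["Rm"])
        if fit.s_star is not None:
            rows["S_star"].append(fit.s_star)

    def _summary(values: list[float], truth: float | None):
        if not values or truth is None:
            return None
        v = np.asarray(values)
        return {
            "truth": truth,
            "mean": float(v.mean()),
            "bias": float(v.mean() - truth),
            "rmse": float(np.sqrt(np.mean((v - truth) ** 2))),
            "n": int(v.size),
        }

    return {
        "model": cfg.model,
        "reps": reps,
        "selection_rate_aic": selected / reps,
        "alpha": _summary(rows["alpha"], cfg.alpha),
        "Rm": _summary(rows["Rm"], cfg.Rm),
        "S_star": _summary(rows["S_star"], float(cfg.S)),
    }
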