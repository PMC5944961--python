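"""Fit the whole model set to a dataset, flag adequacy and rank models.

A :class:`ComparisonTable` holds one :class:`~sadoctave.fitting.FitResult`
per model for one community layer, in the conventional column order
GS, BS, ON, LSer, LN, LC, LS.  Two adequacy criteria are tracked per model:

* ``chi2_pass`` — the chi-square tail probability is at least the
  significance level (default 0.05), i.e. the model is not rejected;
* ``r2_pass`` — the adjusted coefficient of determination reaches the
  conventional threshold (default 0.50).

"Best overall" is the lowest-AIC model among those passing the chi-square
test, falling back to the unconditional AIC minimum when no model passes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
import pandas as pd

from .binning import OctaveHistogram
from .fitting import FitOptions, FitResult, fit_model
from .models import MODEL_NAMES, get_model, model_registry

__all__ = ["ComparisonTable", "fit_all", "adequacy_flags", "select_best",
           "richness_table"]

#: models whose untruncated curve has finite area, hence an S* column
SSTAR_MODELS = ("bs", "on", "ln", "lc", "ls")

_CRITERIA = ("aic", "bic", "r2")


@dataclass
class ComparisonTable:
    """All model fits for one dataset plus per-model failure records."""

    label: str
    fits: dict[str, FitResult]
    errors: dict[str, str] = field(default_factory=dict)
    options: FitOptions = field(default_factory=FitOptions)

    @property
    def models(self) -> list[str]:
        return [m for m in MODEL_NAMES if m in self.fits or m in self.errors]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for name in MODEL_NAMES:
            if name in self.fits:
                rows.append(self.fits[name].to_row())
            elif name in self.errors:
                rows.append({"model": name, "error": self.errors[name]})
        df = pd.DataFrame(rows)
        df.insert(0, "dataset", self.label)
        return df

    def to_markdown(self) -> str:
        return self.to_frame().to_markdown(index=False)


def fit_all(
    h: OctaveHistogram, opts: FitOptions | None = None, label: str | None = None
) -> ComparisonTable:
    """Fit all seven models to one octave histogram.

    Per-model failures (e.g. LSer on negative octaves, too few octaves for a
    three-parameter model) are recorded as flagged rows; the table is always
    produced.
    """
    opts = opts or FitOptions()
    fits: dict[str, FitResult] = {}
    errors: dict[str, str] = {}
    for spec in model_registry():
        try:
            fits[spec.name] = fit_model(spec, h, opts)
        except Exception as exc:
            errors[spec.name] = f"{type(exc).__name__}: {exc}"
    return ComparisonTable(
        label=label or h.source_label or "dataset", fits=fits, errors=errors,
        options=opts,
    )


def adequacy_flags(table: ComparisonTable, opts: FitOptions | None = None) -> pd.DataFrame:
    """Chi-square and R^2 adequacy per model.

    ``chi2_pass`` is pandas NA when the test probability is undefined
    (degrees of freedom below one).
    """
    opts = opts or table.options
    rows = []
    for name, fit in table.fits.items():
        chi2_pass = pd.NA if np.isnan(fit.p_chi2) else bool(fit.p_chi2 >= opts.alpha_level)
        rows.append(
            {
                "model": name,
                "chi2_pass": chi2_pass,
                "r2_pass": bool(fit.r_d2 >= opts.r2_threshold),
            }
        )
    return pd.DataFrame(rows).set_index("model")


def select_best(table: ComparisonTable, criterion: str = "aic") -> str:
    """Best model by AIC, BIC (argmin) or R_d^2 (argmax).

    Ties go to the model with fewer parameters, then to the conventional
    model order.
    """
    if criterion not in _CRITERIA:
        raise ValueError(f"criterion must be one of {_CRITERIA}")
    candidates = []
    for order, name in enumerate(MODEL_NAMES):
        fit = table.fits.get(name)
        if fit is None:
            continue
        score = {"aic": fit.aic, "bic": fit.bic, "r2": -fit.r_d2}[criterion]
        if np.isnan(score):
            continue
        candidates.append((score, fit.k, order, name))
    if not candidates:
        raise ValueError("no successful fits to rank")
    return min(candidates)[-1]


def select_best_overall(table: ComparisonTable, opts: FitOptions | None = None) -> str:
    """Lowest AIC among chi-square-adequate models, else lowest AIC outright."""
    opts = opts or table.options
    passing = [
        m for m, fit in table.fits.items()
        if not np.isnan(fit.p_chi2) and fit.p_chi2 >= opts.alpha_level
    ]
    candidates = passing or list(table.fits)
    ranked = sorted(
        (table.fits[m].aic, table.fits[m].k, MODEL_NAMES.index(m), m)
        for m in candidates
        if not np.isnan(table.fits[m].aic)
    )
    return ranked[0][-1]


def richness_table(tables: Iterable[ComparisonTable]) -> pd.DataFrame:
    """Observed S versus model-extrapolated S* for each dataset.

    One row per dataset: observed richness, the S* of each finite-area model
    (BS, ON, LN, LC, LS) and a boolean ``<model>_exceeds_S`` flag — an
    extrapolation below the observed richness is internally inconsistent.
    """
    rows = []
    for table in tables:
        row: dict = {"dataset": table.label}
        some_fit = next(iter(table.fits.values()))
        S = float(np.sum(some_fit.observed)) + 0.0
        row["S"] = S
        for name in SSTAR_MODELS:
            fit = table.fits.get(name)
            s_star = None if fit is None else fit.s_star
            row[f"S_star_{name}"] = s_star
            row[f"{name}_exceeds_S"] = None if s_star is None else bool(s_star > S)
        rows.append(row)
    return pd.DataFrame(rows)
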