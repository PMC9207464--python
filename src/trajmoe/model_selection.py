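"""BIC grid search over the number of clusters K and the polynomial degree P."""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .data_model import FitResult, GenotypeMatrix, LongitudinalClinicalData
from .em import EMConfig, FitError, fit, n_free_parameters

__all__ = ["SelectionGrid", "SelectionError", "select_model"]

DEFAULT_K_VALUES = (1, 2, 3, 4)
DEFAULT_P_VALUES = (1, 2)


class SelectionError(RuntimeError):
    """Every grid cell failed to fit."""


@dataclass
class SelectionGrid:
    """Per-(K, P) fit results and BIC scores."""

    cells: dict[tuple[int, int], FitResult | None] = field(default_factory=dict)
    errors: dict[tuple[int, int], str] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for (K, P), res in sorted(self.cells.items()):
            if res is None:
                rows.append({"K": K, "P": P, "bic": np.nan, "loglik": np.nan,
                             "nu": np.nan, "converged": False,
                             "error": self.errors.get((K, P), "")})
            else:
                rows.append({
                    "K": K, "P": P, "bic": res.bic, "loglik": res.loglik,
                    "nu": n_free_parameters(res.params), "converged": res.converged,
                    "error": "",
                })
        return pd.DataFrame(rows)

    def best_cell(self) -> tuple[int, int]:
        ok = {kp: r for kp, r in self.cells.items() if r is not None}
        if not ok:
            raise SelectionError("no grid cell produced a fit")
        # minimal BIC; ties -> smaller K, then smaller P
        return min(ok, key=lambda kp: (ok[kp].bic, kp[0], kp[1]))


def select_model(
    clinical: LongitudinalClinicalData,
    geno: GenotypeMatrix | None,
    K_values=DEFAULT_K_VALUES,
    P_values=DEFAULT_P_VALUES,
    config: EMConfig | None = None,
) -> tuple[FitResult, SelectionGrid]:
    """Fit every (K, P) cell with multi-start EM and return the minimal-BIC fit.

    BIC is computed with the same effective-parameter rule in every cell, so
    scores are comparable across the grid.
    """
    K_values = list(K_values)
    P_values = list(P_values)
    if not K_values or not P_values:
        raise ValueError("K_values and P_values must be nonempty")
    if config is None:
        config = EMConfig()
    grid = SelectionGrid()
    for K in K_values:
        for P in P_values:
            cfg = replace(config, K=K, P=P, gate="none" if K == 1 else config.gate)
            try:
                grid.cells[(K, P)] = fit(clinical, geno, cfg)
            except (FitError, ValueError) as err:
                warnings.warn(f"grid cell (K={K}, P={P}) failed: {err}", RuntimeWarning)
                grid.cells[(K, P)] = None
                grid.errors[(K, P)] = str(err)
    best = grid.best_cell()
    return grid.cells[best], grid
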