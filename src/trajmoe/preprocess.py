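"""Data preparation: covariate adjustment, genotype encoding, marker screening.

Clinical scores are adjusted for nuisance covariates (e.g. gender, treatment
dose) before clustering by taking the residuals of an ordinary least-squares
regression pooled across all patients and visits.  Genotypes arrive as
alternative-allele copy counts in {0, 1, 2} and are mapped to the symmetric
additive coding {-1, 0, 1}.  Markers are screened by deleteriousness (scaled
CADD) and allele frequency, with a known-association list that bypasses the
thresholds.
"""

from __future__ import annotations

import warnings
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .data_model import MarkerAnnotation

__all__ = ["adjust_clinical", "encode_genotypes", "decode_genotypes", "screen_markers"]


def adjust_clinical(values, covariates) -> np.ndarray:
    """OLS residuals of a score on an intercept plus covariates.

    ``covariates`` is a DataFrame (factor columns are dummy-coded) or a 2-d
    array aligned row-for-row with ``values``.  Aliased (rank-deficient)
    columns are handled by the minimum-norm least-squares solution, with a
    warning.  Residuals are mean zero and orthogonal to every column.
    """
    y = np.asarray(values, dtype=float).ravel()
    if isinstance(covariates, pd.DataFrame):
        X = pd.get_dummies(covariates, drop_first=True, dtype=float).to_numpy()
    else:
        X = np.asarray(covariates, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
    if X.shape[0] != y.size:
        raise ValueError("covariate rows must align with score rows")
    if not np.all(np.isfinite(X)):
        raise ValueError("missing covariate values are not allowed")
    D = np.column_stack([np.ones_like(y), X])
    coef, _, rank, _ = np.linalg.lstsq(D, y, rcond=None)
    if rank < D.shape[1]:
        warnings.warn(
            f"covariate design is rank deficient (rank {rank} < {D.shape[1]}); "
            "aliased columns contribute nothing",
            RuntimeWarning,
        )
    return y - D @ coef


def encode_genotypes(calls) -> np.ndarray:
    """Map alternative-allele copy counts {0, 1, 2} to additive {-1, 0, 1}."""
    arr = np.asarray(calls, dtype=float)
    ok = np.isin(arr, (0.0, 1.0, 2.0))
    if not ok.all():
        loc = tuple(int(x) for x in np.argwhere(~ok)[0])
        raise ValueError(f"genotype call out of {{0,1,2}} at position {loc}: {arr[loc]!r}")
    return arr - 1.0


def decode_genotypes(values) -> np.ndarray:
    """Inverse of :func:`encode_genotypes`: {-1, 0, 1} back to {0, 1, 2}."""
    arr = np.asarray(values, dtype=float)
    ok = np.isin(arr, (-1.0, 0.0, 1.0))
    if not ok.all():
        loc = tuple(int(x) for x in np.argwhere(~ok)[0])
        raise ValueError(f"encoded value out of {{-1,0,1}} at position {loc}: {arr[loc]!r}")
    return arr + 1.0


def screen_markers(
    annotation: Iterable[MarkerAnnotation],
    known_assoc: set[str] | Sequence[str] = (),
    cadd_min: float = 25.0,
    maf_min: float = 0.01,
) -> list[str]:
    """Retain known-association markers plus those passing both strict thresholds.

    A marker survives if it is in ``known_assoc``, or if its scaled CADD score
    is strictly greater than ``cadd_min`` and its allele frequency strictly
    greater than ``maf_min`` (the frequency column is used as provided —
    alternative-allele or minor-allele, per the caller's annotation).
    Input order is preserved.
    """
    known = {str(m) for m in known_assoc}
    kept = []
    for ann in annotation:
        if ann.marker_id in known or (
            ann.scaled_cadd > cadd_min and ann.allele_frequency > maf_min
        ):
            kept.append(ann.marker_id)
    return kept
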