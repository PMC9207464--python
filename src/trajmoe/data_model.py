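"""Core containers for longitudinal clinical data, genotypes and model parameters.

The model clusters N patients into K latent subtypes.  Each subtype k is an
"expert": for every clinical variable v it posits a polynomial trajectory in
visit time with Gaussian noise,

    y_iv(j) | z_i = k  ~  N( sum_p alpha_vkp * t_ij^p ,  sigma_vk^2 ),

while cluster membership is driven by a multinomial logistic "gate" over the
genotype vector g_i,

    P(z_i = k | g_i)  =  exp(omega_k0 + omega_k' g_i) / sum_k' exp(...),

with the reference class pinned to zero for identifiability.  These containers
hold the data (ragged visits, an N x L marker matrix) and the parameter blocks,
and enforce the invariants every downstream module relies on.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "LongitudinalClinicalData",
    "GenotypeMatrix",
    "ModelParameters",
    "Responsibilities",
    "MarkerAnnotation",
    "FitResult",
    "AlignmentError",
    "validate_aligned",
]


class AlignmentError(ValueError):
    """Clinical and genotype containers do not describe the same patients."""


@dataclass
class LongitudinalClinicalData:
    """Ragged per-patient visit times and V clinical scores.

    Parameters
    ----------
    patient_ids
        N string identifiers, in cohort order.
    times
        Per patient, a 1-d float array of visit times (user units, e.g. days).
        Visits are sorted by time on construction.
    values
        Per patient, an (n_visits, V) float array; ``NaN`` marks a missing
        visit-variable cell (missing cells simply drop out of likelihood sums).
    variable_names
        The V clinical score labels.
    """

    patient_ids: list[str]
    times: list[np.ndarray]
    values: list[np.ndarray]
    variable_names: list[str]

    def __post_init__(self) -> None:
        self.patient_ids = [str(p) for p in self.patient_ids]
        n = len(self.patient_ids)
        if n == 0:
            raise ValueError("empty cohort: no patients")
        if len(self.times) != n or len(self.values) != n:
            raise ValueError("times/values length must match patient_ids")
        if len(set(self.patient_ids)) != n:
            raise ValueError("duplicate patient ids")
        V = len(self.variable_names)
        times, values = [], []
        for pid, t, y in zip(self.patient_ids, self.times, self.values):
            t = np.asarray(t, dtype=float).ravel()
            y = np.asarray(y, dtype=float).reshape(len(t), -1)
            if t.size == 0:
                raise ValueError(f"patient {pid!r} has no visits")
            if not np.all(np.isfinite(t)):
                raise ValueError(f"patient {pid!r} has non-finite visit times")
            if y.shape[1] != V:
                raise ValueError(
                    f"patient {pid!r} has {y.shape[1]} variables, expected {V}"
                )
            order = np.argsort(t, kind="stable")
            times.append(t[order])
            values.append(y[order])
        self.times = times
        self.values = values

    @property
    def n_patients(self) -> int:
        return len(self.patient_ids)

    @property
    def n_variables(self) -> int:
        return len(self.variable_names)

    def stacked(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Flatten to (all_times, all_values, patient_index) for vector math."""
        t = np.concatenate(self.times)
        y = np.vstack(self.values)
        idx = np.repeat(np.arange(self.n_patients), [len(x) for x in self.times])
        return t, y, idx

    # -- CSV round trip ----------------------------------------------------
    def to_dataframe(self) -> pd.DataFrame:
        t, y, idx = self.stacked()
        df = pd.DataFrame({"patient_id": np.asarray(self.patient_ids)[idx], "time": t})
        for v, name in enumerate(self.variable_names):
            df[name] = y[:, v]
        return df

    def write_csv(self, path: str | Path) -> None:
        self.to_dataframe().to_csv(path, index=False)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "LongitudinalClinicalData":
        required = {"patient_id", "time"}
        if not required.issubset(df.columns):
            raise ValueError(f"clinical table must have columns {sorted(required)}")
        variable_names = [c for c in df.columns if c not in required]
        ids, times, values = [], [], []
        for pid, g in df.groupby("patient_id", sort=False):
            ids.append(str(pid))
            times.append(g["time"].to_numpy(dtype=float))
            values.append(g[variable_names].to_numpy(dtype=float))
        return cls(ids, times, values, variable_names)

    @classmethod
    def read_csv(cls, path: str | Path) -> "LongitudinalClinicalData":
        return cls.from_dataframe(pd.read_csv(path))


@dataclass
class GenotypeMatrix:
    """N x L additive-coded genotype matrix aligned with a clinical cohort.

    Entries use the field's symmetric additive coding: homozygous reference
    -1, heterozygous 0, homozygous alternative 1 (a ``{0,1,2}`` dosage loader
    is provided).  No missing entries are allowed at fit time.
    """

    values: np.ndarray
    marker_ids: list[str]
    patient_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.patient_ids = [str(p) for p in self.patient_ids]
        if self.values.ndim != 2:
            raise ValueError("genotype values must be 2-d")
        n, L = self.values.shape
        if n != len(self.patient_ids):
            raise ValueError("row count must match patient_ids")
        if L != len(self.marker_ids):
            raise ValueError("column count must match marker_ids")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("genotype matrix contains missing/non-finite entries")

    @property
    def n_patients(self) -> int:
        return self.values.shape[0]

    @property
    def n_markers(self) -> int:
        return self.values.shape[1]

    def reordered(self, patient_ids: Sequence[str]) -> "GenotypeMatrix":
        pos = {p: i for i, p in enumerate(self.patient_ids)}
        rows = [pos[p] for p in patient_ids]
        return GenotypeMatrix(self.values[rows], list(self.marker_ids), list(patient_ids))

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values.copy(), columns=self.marker_ids)
        df.insert(0, "patient_id", self.patient_ids)
        return df

    def write_csv(self, path: str | Path) -> None:
        self.to_dataframe().to_csv(path, index=False)

    @classmethod
    def read_csv(cls, path: str | Path, dosage: bool = False) -> "GenotypeMatrix":
        """Read a genotype CSV; with ``dosage=True`` map {0,1,2} -> {-1,0,1}."""
        df = pd.read_csv(path)
        if "patient_id" not in df.columns:
            raise ValueError("genotype table must have a patient_id column")
        ids = df["patient_id"].astype(str).tolist()
        markers = [c for c in df.columns if c != "patient_id"]
        vals = df[markers].to_numpy(dtype=float)
        if dosage:
            from .preprocess import encode_genotypes

            vals = encode_genotypes(vals)
        return cls(vals, markers, ids)


@dataclass
class ModelParameters:
    """All parameter blocks of the mixture of experts.

    ``alpha`` has shape (K, V, P+1) — polynomial coefficients on the rescaled
    time axis; ``sigma`` (K, V) positive noise scales; ``omega0`` (K,) gating
    intercepts and ``omega`` (K, L) gating weights with the reference class row
    identically zero.  ``time_scale`` records the factor user times are divided
    by before powers are taken (guards conditioning with day-scale times).
    """

    alpha: np.ndarray
    sigma: np.ndarray
    omega0: np.ndarray
    omega: np.ndarray
    reference_class: int = 0
    time_scale: float = 1.0

    def __post_init__(self) -> None:
        self.alpha = np.asarray(self.alpha, dtype=float)
        self.sigma = np.asarray(self.sigma, dtype=float)
        self.omega0 = np.asarray(self.omega0, dtype=float)
        self.omega = np.asarray(self.omega, dtype=float)
        K, V, _ = self.alpha.shape
        if self.sigma.shape != (K, V):
            raise ValueError("sigma must be (K, V)")
        if self.omega0.shape != (K,):
            raise ValueError("omega0 must be (K,)")
        if self.omega.ndim != 2 or self.omega.shape[0] != K:
            raise ValueError("omega must be (K, L)")
        if np.any(self.sigma <= 0):
            raise ValueError("sigma must be strictly positive")
        if not (0 <= self.reference_class < K):
            raise ValueError("reference_class out of range")
        r = self.reference_class
        if self.omega0[r] != 0 or np.any(self.omega[r] != 0):
            raise ValueError("reference class gating parameters must be zero")
        if not (np.isfinite(self.time_scale) and self.time_scale > 0):
            raise ValueError("time_scale must be positive and finite")

    @property
    def n_clusters(self) -> int:
        return self.alpha.shape[0]

    @property
    def degree(self) -> int:
        return self.alpha.shape[2] - 1

    @property
    def n_markers(self) -> int:
        return self.omega.shape[1]

    def alpha_user_scale(self) -> np.ndarray:
        """Polynomial coefficients converted back to the user's time unit."""
        p = np.arange(self.degree + 1, dtype=float)
        return self.alpha / self.time_scale ** p

    def to_dict(self) -> dict:
        return {
            "alpha": self.alpha.tolist(),
            "sigma": self.sigma.tolist(),
            "omega0": self.omega0.tolist(),
            "omega": self.omega.tolist(),
            "reference_class": int(self.reference_class),
            "time_scale": float(self.time_scale),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ModelParameters":
        return cls(
            np.asarray(d["alpha"]),
            np.asarray(d["sigma"]),
            np.asarray(d["omega0"]),
            np.asarray(d["omega"]),
            int(d["reference_class"]),
            float(d["time_scale"]),
        )


@dataclass
class Responsibilities:
    """N x K posterior membership probabilities; rows sum to one."""

    tau: np.ndarray

    def __post_init__(self) -> None:
        self.tau = np.asarray(self.tau, dtype=float)
        if self.tau.ndim != 2:
            raise ValueError("tau must be 2-d")
        if np.any(self.tau < 0) or np.any(self.tau > 1):
            raise ValueError("tau entries must lie in [0, 1]")
        if not np.allclose(self.tau.sum(axis=1), 1.0, rtol=0, atol=1e-10):
            raise ValueError("tau rows must sum to 1 within 1e-10")

    @property
    def n_clusters(self) -> int:
        return self.tau.shape[1]

    def hard_labels(self) -> np.ndarray:
        """Argmax assignment per patient; ties go to the lowest class index."""
        return np.argmax(self.tau, axis=1)

    @classmethod
    def from_labels(cls, labels: np.ndarray, K: int) -> "Responsibilities":
        labels = np.asarray(labels, dtype=int)
        tau = np.zeros((labels.size, K))
        tau[np.arange(labels.size), labels] = 1.0
        return cls(tau)


@dataclass
class MarkerAnnotation:
    """Per-marker deleteriousness (scaled CADD) and allele frequency."""

    marker_id: str
    scaled_cadd: float
    allele_frequency: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.allele_frequency <= 1.0):
            raise ValueError("allele_frequency must lie in [0, 1]")

    @staticmethod
    def read_csv(path: str | Path) -> list["MarkerAnnotation"]:
        df = pd.read_csv(path)
        return [
            MarkerAnnotation(str(r.marker_id), float(r.scaled_cadd), float(r.allele_frequency))
            for r in df.itertuples()
        ]


@dataclass
class FitResult:
    """A converged fit: parameters, memberships, selection and provenance."""

    params: ModelParameters
    tau: Responsibilities
    labels: np.ndarray
    objective_trace: list[float]
    loglik: float
    bic: float
    lambda_: float
    support: set[tuple[int, int]]
    n_iter: int
    converged: bool
    seed: int | None = None
    init_id: int | None = None
    omega_se: np.ndarray | None = None
    omega_ci: np.ndarray | None = None
    wald_valid: bool = True

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        expected = self.tau.hard_labels()
        if not np.array_equal(self.labels, expected):
            raise ValueError("labels must be the row-wise argmax of tau")
        nz = {(int(k), int(l)) for k, l in zip(*np.nonzero(self.params.omega))}
        if self.support != nz:
            raise ValueError("support must equal the nonzero pattern of omega")

    def assignments_frame(self, patient_ids: Sequence[str]) -> pd.DataFrame:
        df = pd.DataFrame({"patient_id": list(patient_ids), "label": self.labels})
        for k in range(self.tau.n_clusters):
            df[f"tau_{k}"] = self.tau.tau[:, k]
        return df

    def to_json(self, **extra) -> str:
        payload = {
            "params": self.params.to_dict(),
            "loglik": float(self.loglik),
            "bic": float(self.bic),
            "lambda": float(self.lambda_),
            "support": sorted([list(s) for s in self.support]),
            "n_iter": int(self.n_iter),
            "converged": bool(self.converged),
            "seed": self.seed,
            "init_id": self.init_id,
            "objective_trace": [float(x) for x in self.objective_trace],
            "omega_se": None if self.omega_se is None else self.omega_se.tolist(),
            "omega_ci": None if self.omega_ci is None else self.omega_ci.tolist(),
            "wald_valid": bool(self.wald_valid),
        }
        payload.update(extra)
        return json.dumps(payload, indent=2, sort_keys=True)


def validate_aligned(
    clinical: LongitudinalClinicalData, geno: GenotypeMatrix
) -> tuple[LongitudinalClinicalData, GenotypeMatrix]:
    """Co-sort the genotype rows to clinical-file patient order.

    Raises :class:`AlignmentError` naming the offending ids when the two
    containers do not describe exactly the same patients.
    """
    cids, gids = set(clinical.patient_ids), set(geno.patient_ids)
    if cids != gids:
        missing = sorted(cids - gids)
        extra = sorted(gids - cids)
        parts = []
        if missing:
            parts.append(f"missing from genotypes: {missing}")
        if extra:
            parts.append(f"not in clinical data: {extra}")
        raise AlignmentError("patient id mismatch; " + "; ".join(parts))
    if geno.patient_ids != clinical.patient_ids:
        geno = geno.reordered(clinical.patient_ids)
    return clinical, geno
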