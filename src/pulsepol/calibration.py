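"""Instrument-matrix calibration for the polarization state analyzer.

The analyzer splits backscattered light into four channels whose intensities
``[I1, I2, I3, I4]`` are related to the Stokes vector ``S = (I, Q, U, V)`` of
the light by a linear instrument matrix ``A``::

    S = A @ [I1, I2, I3, I4]^T

``A`` is estimated from calibration measurements pairing reference Stokes
vectors (from a commercial polarimeter) with the channel intensities the
analyzer records for the same incident states.  With exactly four states the
estimate is a plain matrix inversion; with more states it is the ordinary
least-squares solution, which averages down measurement noise.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import TYPE_CHECKING

import numpy as np

if TYPE_CHECKING:  # pragma: no cover - import cycle guard, typing only
    from .simulator import CalibrationSet

__all__ = [
    "InstrumentMatrix",
    "StokesVector",
    "estimate_instrument_matrix",
    "apply_instrument_matrix",
    "normalized_stokes",
]

# Estimates with condition numbers above this are rejected as degenerate.
DEFAULT_CONDITION_CAP = 1e8


@dataclass(frozen=True)
class StokesVector:
    """One Stokes vector (I, Q, U, V) with physicality helpers."""

    I: float
    Q: float
    U: float
    V: float
    nonphysical: bool = False  # flagged when I <= 0 on a particle sample

    def as_array(self) -> np.ndarray:
        return np.array([self.I, self.Q, self.U, self.V], dtype=float)

    @property
    def quv(self) -> tuple[float, float, float]:
        """Intensity-normalized components (q, u, v) = (Q, U, V) / I."""
        if self.I <= 0:
            raise ValueError("cannot normalize a Stokes vector with I <= 0")
        return (self.Q / self.I, self.U / self.I, self.V / self.I)


@dataclass
class InstrumentMatrix:
    """The 4x4 matrix mapping measured channel intensities to Stokes vectors."""

    A: np.ndarray
    n_states: int | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.A = np.asarray(self.A, dtype=float)
        if self.A.shape != (4, 4):
            raise ValueError(f"instrument matrix must be 4x4, got {self.A.shape}")
        if not np.all(np.isfinite(self.A)):
            raise ValueError("instrument matrix has non-finite entries")
        cap = float(self.metadata.get("condition_cap", DEFAULT_CONDITION_CAP))
        if self.condition_number > cap:
            raise ValueError(
                f"instrument matrix condition number {self.condition_number:.3g} "
                f"exceeds cap {cap:.3g}; matrix is effectively singular"
            )

    @property
    def condition_number(self) -> float:
        return float(np.linalg.cond(self.A))

    @property
    def inverse(self) -> np.ndarray:
        return np.linalg.inv(self.A)

    # -- persistence -------------------------------------------------------
    def to_json(self, path: str | Path) -> None:
        payload = {
            "A": self.A.tolist(),
            "condition_number": self.condition_number,
            "n_states": self.n_states,
            "metadata": self.metadata,
        }
        Path(path).write_text(json.dumps(payload, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "InstrumentMatrix":
        payload = json.loads(Path(path).read_text())
        return cls(
            A=np.array(payload["A"], dtype=float),
            n_states=payload.get("n_states"),
            metadata=payload.get("metadata", {}),
        )

    def to_csv(self, path: str | Path) -> None:
        np.savetxt(path, self.A, delimiter=",")

    @classmethod
    def from_csv(cls, path: str | Path) -> "InstrumentMatrix":
        return cls(A=np.loadtxt(path, delimiter=","))


def estimate_instrument_matrix(cal: "CalibrationSet") -> InstrumentMatrix:
    """Least-squares estimate of the instrument matrix from calibration pairs.

    Solves ``min_A sum_k || S_ref[k] - A @ m[k] ||^2`` over all calibration
    states.  With exactly four states and a full-rank measurement matrix this
    reduces to ``A = S_ref @ M^{-1}``; with more states it is the
    pseudo-inverse (ordinary least squares) generalization.

    Parameters
    ----------
    cal
        Calibration set with ``reference_stokes`` and ``measured_components``,
        each of shape ``(n_states, 4)``.

    Raises
    ------
    ValueError
        If fewer than four states are supplied or the stacked measured
        components do not span rank 4 ("degenerate calibration states").
    """
    S_ref = np.asarray(cal.reference_stokes, dtype=float)
    M = np.asarray(cal.measured_components, dtype=float)
    if S_ref.shape != M.shape or S_ref.ndim != 2 or S_ref.shape[1] != 4:
        raise ValueError("calibration set must hold matched (n, 4) arrays")
    n = S_ref.shape[0]
    if n < 4:
        raise ValueError(f"need at least 4 calibration states, got {n}")
    if np.linalg.matrix_rank(M) < 4:
        raise ValueError("degenerate calibration states: measured components have rank < 4")
    # Rows of S_ref/M are states; solve M^T x = S_ref^T column-wise, A = x^T.
    coef, *_ = np.linalg.lstsq(M, S_ref, rcond=None)
    A = coef.T
    return InstrumentMatrix(A=A, n_states=n)


def apply_instrument_matrix(
    A: InstrumentMatrix | np.ndarray,
    components: np.ndarray,
    project: bool = False,
) -> np.ndarray:
    """Map measured polarization components to Stokes vectors, ``S = A @ m``.

    Parameters
    ----------
    A
        Instrument matrix (or bare 4x4 array).
    components
        Array of shape ``(4,)`` or ``(n, 4)`` holding ``[I1, I2, I3, I4]``.
    project
        If true, clip (Q, U, V) of each output to the physical ball of radius
        I (degree of polarization at most 1).  Rows with I <= 0 are left
        untouched; callers flag/drop them.

    Returns
    -------
    Stokes array with the same leading shape as ``components``.
    """
    mat = A.A if isinstance(A, InstrumentMatrix) else np.asarray(A, dtype=float)
    comp = np.asarray(components, dtype=float)
    if not np.all(np.isfinite(comp)):
        raise ValueError("non-finite polarization components")
    squeeze = comp.ndim == 1
    comp = np.atleast_2d(comp)
    S = comp @ mat.T
    if project:
        I = S[:, 0]
        pol = np.linalg.norm(S[:, 1:], axis=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            factor = np.where((I > 0) & (pol > I), I / np.where(pol > 0, pol, 1.0), 1.0)
        S[:, 1:] *= factor[:, None]
    return S[0] if squeeze else S


def normalized_stokes(S: np.ndarray) -> np.ndarray:
    """Intensity-normalized (q, u, v) for Stokes rows; rows with I<=0 give NaN."""
    S = np.atleast_2d(np.asarray(S, dtype=float))
    I = S[:, 0]
    with np.errstate(divide="ignore", invalid="ignore"):
        quv = np.where(I[:, None] > 0, S[:, 1:] / I[:, None], np.nan)
    return quv
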