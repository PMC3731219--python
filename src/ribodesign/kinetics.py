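"""Mass-action model of riboregulation and the Boltzmann rate link.

Association of an sRNA A with its target B passes through a seed-nucleated
intermediate [A:B]* (formed with rate constant k_on, dissolved with k_off)
before hybridizing irreversibly into the final complex A:B with k_hyb.
Free species degrade with delta1 and the final complex with delta2.  When
k_off + k_hyb >> delta1 the intermediate is in quasi-steady state,
[A:B]* = A*B/K_M with K_M = (k_off + k_hyb)/k_on, and the flux into A:B is
proportional to k_hyb/K_M.

k_on is set by the seed length alpha and k_hyb by the formation energy dG,
both through Boltzmann factors with free prefactors; only ratios of
predicted expression folds are therefore meaningful, and the predicted
fold scales as exp(-dG_kin/RT).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .errors import ParameterError

#: (k_off + k_hyb) / delta1 ratio above which the QSSA is flagged valid
QSSA_VALIDITY_RATIO = 10.0


@dataclass(frozen=True)
class KineticParameters:
    k_on: float = 1.0
    k_off: float = 9.0
    k_hyb: float = 1.0
    delta1: float = 0.0
    delta2: float = 0.0
    #: apply delta2 to the final complex (default) and/or the intermediate
    degrade_intermediate: bool = False

    def __post_init__(self) -> None:
        for name in ("k_on", "k_off", "k_hyb", "delta1", "delta2"):
            if getattr(self, name) < 0:
                raise ParameterError(f"{name} must be non-negative")

    @property
    def k_m(self) -> float:
        if self.k_on == 0:
            raise ParameterError("K_M undefined for k_on = 0")
        return (self.k_off + self.k_hyb) / self.k_on

    @classmethod
    def from_energies(
        cls,
        alpha: int,
        delta_g: float,
        g_p: float = -1.28,
        rt: float = 0.61,
        c_on: float = 1.0,
        c_hyb: float = 1.0,
        **kwargs,
    ) -> "KineticParameters":
        """Boltzmann parameterization: k_on from the seed, k_hyb from dG."""
        return cls(
            k_on=c_on * math.exp(-alpha * g_p / rt),
            k_hyb=c_hyb * math.exp(-delta_g / rt),
            **kwargs,
        )


def simulate(
    params: KineticParameters,
    a0: float,
    b0: float,
    horizon: float,
    n_points: int = 200,
    clamp_free: bool = False,
    rtol: float = 1e-8,
) -> pd.DataFrame:
    """Integrate the three-step scheme; columns t, A, B, intermediate, complex.

    ``clamp_free`` holds A and B at their initial values (e.g. constitutive
    expression balancing consumption), which isolates the intermediate's
    approach to its quasi-steady state.
    """
    if a0 < 0 or b0 < 0:
        raise ParameterError("initial concentrations must be non-negative")
    if horizon <= 0:
        raise ParameterError("horizon must be > 0")
    p = params

    def rhs(_t, y):
        a, b, inter, cx = y
        assoc = p.k_on * a * b
        d_inter = assoc - (p.k_off + p.k_hyb) * inter
        if p.degrade_intermediate:
            d_inter -= p.delta2 * inter
        d_cx = p.k_hyb * inter - p.delta2 * cx
        if clamp_free:
            da = db = 0.0
        else:
            da = -assoc + p.k_off * inter - p.delta1 * a
            db = -assoc + p.k_off * inter - p.delta1 * b
        return [da, db, d_inter, d_cx]

    t_eval = np.linspace(0.0, horizon, n_points)
    sol = solve_ivp(
        rhs, (0.0, horizon), [a0, b0, 0.0, 0.0],
        method="LSODA", t_eval=t_eval, rtol=rtol, atol=1e-12,
    )
    frame = pd.DataFrame(
        {"t": sol.t, "A": sol.y[0], "B": sol.y[1],
         "intermediate": sol.y[2], "complex": sol.y[3]}
    )
    # integration noise can dip microscopically below zero
    for col in ("A", "B", "intermediate", "complex"):
        frame[col] = frame[col].clip(lower=0.0)
    return frame


def qssa_intermediate(
    params: KineticParameters, a: float, b: float
) -> tuple[float, bool]:
    """Quasi-steady-state intermediate A*B/K_M and a validity flag.

    The reduction assumes k_off + k_hyb >> delta1 (sRNA degradation is
    slow); the flag is False when the ratio falls below
    :data:`QSSA_VALIDITY_RATIO`.
    """
    value = a * b / params.k_m
    if params.delta1 == 0:
        valid = True
    else:
        valid = (params.k_off + params.k_hyb) / params.delta1 >= QSSA_VALIDITY_RATIO
    return value, valid


@dataclass(frozen=True)
class FoldPrediction:
    delta_g_kin: float
    rt: float
    scale: float
    predicted_fold: float


def predicted_fold(
    delta_g_kin: float, rt: float = 0.61, scale: float = 1.0
) -> FoldPrediction:
    """Expression fold change scaling exponentially with dG_kin.

    The multiplicative prefactor is free; the ratio between two predictions
    depends only on their dG_kin difference.
    """
    if rt <= 0:
        raise ParameterError("RT must be > 0")
    if scale <= 0:
        raise ParameterError("scale must be > 0")
    return FoldPrediction(
        delta_g_kin=delta_g_kin,
        rt=rt,
        scale=scale,
        predicted_fold=scale * math.exp(-delta_g_kin / rt),
    )
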