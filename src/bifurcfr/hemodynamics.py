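"""Scaling-law boundary conditions, blood rheology and the 27-case study grid.

Inlet flow and branch flow splits for the bifurcation follow empirical
diameter scaling laws for the coronary tree:

* resting flow of a vessel of diameter ``d``:  q = 1.43 * d**2.55  (mL/min)
* flow split of two daughter branches:  Q_SB/Q_DMB = (d_SB/d_DMB)**2.27

Hyperemia is modelled by multiplying the resting flow by the coronary flow
reserve (CFR, = 3 at maximal vasodilation).  Blood is shear-thinning and is
described by the Carreau model; interface units are mm and mL/min, with SI
used internally for viscosity and the Reynolds number.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .errors import InvalidParameterError

#: exponent of the resting-flow diameter scaling law
RESTING_FLOW_COEFF = 1.43
RESTING_FLOW_EXPONENT = 2.55
#: exponent of the daughter-branch flow-split law
FLOW_SPLIT_EXPONENT = 2.27

MMHG_PER_PA = 1.0 / 133.322
ML_MIN_TO_M3_S = 1e-6 / 60.0


@dataclass(frozen=True)
class RheologyParams:
    """Carreau-model constants and density for blood.

    mu = mu_inf + (mu_0 - mu_inf) * (1 + (lambda_ * S)^2)^((n - 1)/2)

    Defaults are the values commonly used for human blood: zero-shear
    viscosity 0.25 Pa s, infinite-shear viscosity 0.0035 Pa s, time constant
    25 s, power-law index 0.25, density 1060 kg/m^3.
    """

    mu_inf: float = 0.0035  # Pa s
    mu_0: float = 0.25      # Pa s
    lambda_: float = 25.0   # s
    n: float = 0.25         # dimensionless
    rho: float = 1060.0     # kg/m^3

    def __post_init__(self) -> None:
        if not (self.mu_0 >= self.mu_inf > 0):
            raise InvalidParameterError("require mu_0 >= mu_inf > 0")
        if self.lambda_ <= 0:
            raise InvalidParameterError("lambda_ must be positive")
        if not (0 < self.n <= 1):
            raise InvalidParameterError("power-law index n must be in (0, 1]")
        if self.rho <= 0:
            raise InvalidParameterError("density must be positive")


@dataclass(frozen=True)
class FlowConditions:
    """Inlet flow and outlet split for one simulated case.

    ``inlet_flow`` is the imposed hyperemic inlet flow in mL/min;
    ``cfr_multiplier`` the coronary flow reserve it embodies; ``split_dmb`` /
    ``split_sb`` the fractions of inlet flow leaving through the distal main
    branch and the side branch.
    """

    inlet_flow: float = 120.0
    cfr_multiplier: float = 3.0
    split_dmb: float = 0.65
    split_sb: float = 0.35
    rheology: RheologyParams = field(default_factory=RheologyParams)

    def __post_init__(self) -> None:
        if self.inlet_flow <= 0:
            raise InvalidParameterError("inlet_flow must be positive")
        if abs(self.split_dmb + self.split_sb - 1.0) > 1e-9:
            raise InvalidParameterError("flow split fractions must sum to 1")
        if not (0 < self.split_dmb < 1 and 0 < self.split_sb < 1):
            raise InvalidParameterError("flow split fractions must lie in (0, 1)")

    @property
    def q_dmb(self) -> float:
        """Distal-main-branch flow in mL/min."""
        return self.inlet_flow * self.split_dmb

    @property
    def q_sb(self) -> float:
        """Side-branch flow in mL/min."""
        return self.inlet_flow * self.split_sb


def resting_flow(d: float) -> float:
    """Resting flow (mL/min) of a coronary vessel of diameter ``d`` (mm).

    Evaluates the empirical scaling law q = 1.43 * d**2.55.
    """
    if d <= 0:
        raise InvalidParameterError(f"diameter must be positive, got {d}")
    return RESTING_FLOW_COEFF * d ** RESTING_FLOW_EXPONENT


def hyperemic_flow(resting: float, cfr: float) -> float:
    """Hyperemic flow (mL/min) given resting flow and coronary flow reserve."""
    if resting <= 0 or cfr <= 0:
        raise InvalidParameterError("resting flow and CFR must be positive")
    return resting * cfr


def diameter_flow_split(d_sb: float, d_dmb: float) -> tuple[float, float]:
    """Fractions of parent flow through (side branch, distal main branch).

    The flow ratio follows Q_SB/Q_DMB = (d_SB/d_DMB)**2.27; the returned
    fractions sum to one exactly.
    """
    if d_sb <= 0 or d_dmb <= 0:
        raise InvalidParameterError("daughter diameters must be positive")
    r = (d_sb / d_dmb) ** FLOW_SPLIT_EXPONENT
    sb = r / (1.0 + r)
    return sb, 1.0 - sb


def carreau_viscosity(shear_rate, p: RheologyParams = RheologyParams()):
    """Carreau dynamic viscosity (Pa s) at the given shear rate (1/s).

    Accepts a scalar or ndarray shear rate; strictly decreasing in the shear
    rate for n < 1, bounded between mu_inf and mu_0.
    """
    import numpy as np

    s = np.asarray(shear_rate, dtype=float)
    if np.any(s < 0):
        raise InvalidParameterError("shear rate must be non-negative")
    mu = p.mu_inf + (p.mu_0 - p.mu_inf) * (1.0 + (p.lambda_ * s) ** 2) ** ((p.n - 1.0) / 2.0)
    return float(mu) if np.isscalar(shear_rate) else mu


def reynolds_number(d: float, q: float, p: RheologyParams, mu_eff: float | None = None) -> float:
    """Reynolds number of flow ``q`` (mL/min) in a vessel of diameter ``d`` (mm).

    Uses the section-mean velocity v = Q/(pi d^2/4); ``mu_eff`` defaults to the
    infinite-shear Carreau viscosity.
    """
    import math

    if d <= 0 or q <= 0:
        raise InvalidParameterError("diameter and flow must be positive")
    mu = p.mu_inf if mu_eff is None else mu_eff
    if mu <= 0:
        raise InvalidParameterError("viscosity must be positive")
    d_m = d * 1e-3
    q_si = q * ML_MIN_TO_M3_S
    v = q_si / (math.pi * d_m ** 2 / 4.0)
    return p.rho * v * d_m / mu


# ---------------------------------------------------------------------------
# study grid

#: distal bifurcation angles investigated (degrees)
STUDY_ANGLES_DEG = (40.0, 55.0, 70.0)
#: side-branch diameter stenoses investigated (%)
STUDY_SB_STENOSES_PCT = (40.0, 60.0, 80.0)
#: DMB:SB flow splits investigated (fraction of inlet flow to the SB)
STUDY_SB_SPLITS = (0.25, 0.35, 0.45)


def case_id(sb_pct: float, alpha_deg: float, split_sb: float) -> str:
    """Case nomenclature ``"<SB %DS>%-<angle>deg-<SB flow %>%"``."""
    return f"{sb_pct:.0f}%-{alpha_deg:.0f}deg-{split_sb * 100:.0f}%"


def case_grid(inlet_flow: float = 120.0,
              rheology: RheologyParams = RheologyParams()) -> list[tuple[str, "BifurcationSpec", FlowConditions]]:
    """The full 27-case study design.

    Combines 3 distal angles (40/55/70 deg), 3 SB stenoses (40/60/80 %) and 3
    flow splits (55:45, 65:35, 75:25 DMB:SB) with PMB and DMB stenosis fixed
    at 60 % and the imposed hyperemic inlet flow (default 120 mL/min).
    Returns ``(case_id, BifurcationSpec, FlowConditions)`` triples in a
    deterministic, order-stable sequence (stenosis, then split, then angle).
    """
    from .geometry import BifurcationSpec

    cases = []
    for sb_pct in STUDY_SB_STENOSES_PCT:
        for split_sb in STUDY_SB_SPLITS:
            for alpha in STUDY_ANGLES_DEG:
                spec = BifurcationSpec(alpha_deg=alpha, stenosis_sb_pct=sb_pct)
                flow = FlowConditions(inlet_flow=inlet_flow, split_dmb=1.0 - split_sb,
                                      split_sb=split_sb, rheology=rheology)
                cases.append((case_id(sb_pct, alpha, split_sb), spec, flow))
    return cases
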