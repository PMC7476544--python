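"""Binary-mixture response surfaces: CA and IA references plus deviations.

Two reference models predict the joint effect of a binary mixture from the
single-chemical curves:

* Concentration addition (CA, Loewe additivity): the components behave as
  dilutions of one another, so a mixture sits at the effect level Y where the
  toxic units computed against the effect-level-Y effective concentrations
  sum to one: sum_i c_i / EC_{Y,i} = 1.
* Independent action (IA, Bliss independence): per-chemical non-response
  probabilities multiply, y = u_max * q1 * q2 with
  q_i = 1 / (1 + (c_i/EC50_i)**beta_i).

Departures from either reference are captured by a deviation function G built
from the TU fractions z_i (toxic units normalized to sum to one):

* S/A (synergism/antagonism):  G = a * z1 * z2
* DR (dose-ratio dependent):   G = (a + b_DR * z_lead) * z1 * z2
* DL (dose-level dependent):   G = a * (1 - b_DL * sum_TU) * z1 * z2   (CA)
                               G = a * (1 - b_DL * E_ref)  * z1 * z2   (IA)

where sum_TU is the EC50-based total toxic unit and E_ref the reference IA
effect fraction 1 - q1*q2.  G enters CA as sum_i c_i / EC_{Y,i} = exp(G) and
IA as y = u_max * (q1*q2)**exp(-G).  In both entries G = 0 recovers the
reference and G < 0 means lower mobility than the reference (synergism),
G > 0 higher (antagonism).  These algebraic forms are this package's
reconstruction of the MIXTOX deviation family from its published sign,
reduction and switch behaviour; see docs/methods.md.
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq
from skimage import measure

from .dose_response import LogLogisticParams, predict_mobility

__all__ = [
    "Base",
    "DeviationKind",
    "DeviationSpec",
    "MixtureParams",
    "TUState",
    "SwitchLocus",
    "toxic_units",
    "deviation_g",
    "predict_ca",
    "predict_ia",
    "predict_mixture",
    "switch_locus",
    "isobole_grid",
]


class Base(str, enum.Enum):
    CA = "CA"
    IA = "IA"


class DeviationKind(str, enum.Enum):
    NONE = "NONE"
    SA = "SA"
    DR = "DR"
    DL = "DL"


@dataclass(frozen=True)
class DeviationSpec:
    """Reference model plus deviation kind and its parameters.

    ``lead_index`` names the chemical whose TU fraction carries the b_DR
    coefficient (0-based; default chemical 0, AgNO3 in the motivating assay).
    """

    base: Base = Base.CA
    kind: DeviationKind = DeviationKind.NONE
    a: float = 0.0
    b_dr: float = 0.0
    b_dl: float = 0.0
    lead_index: int = 0

    def __post_init__(self) -> None:
        if self.lead_index not in (0, 1):
            raise ValueError("lead_index must be 0 or 1")


@dataclass(frozen=True)
class MixtureParams:
    """Full parameter vector of one fitted mixture model.

    The two chemicals share the control response ``u_max``; each carries its
    own slope and EC50.  ``chem`` entries are built with that shared u_max.
    """

    u_max: float
    chem: tuple[LogLogisticParams, LogLogisticParams]
    deviation: DeviationSpec = field(default_factory=DeviationSpec)

    def __post_init__(self) -> None:
        for p in self.chem:
            if p.u_max != self.u_max:
                raise ValueError("chemicals must share the mixture u_max")


@dataclass(frozen=True)
class TUState:
    """Toxic units of a concentration pair and their normalized fractions."""

    tu: tuple[float, float]
    sum_tu: float
    z: tuple[float, float]
    degenerate: bool = False


@dataclass(frozen=True)
class SwitchLocus:
    """Where a DR or DL deviation changes sign (synergism <-> antagonism)."""

    exists: bool
    z_lead: float | None = None
    sum_tu_star: float | None = None
    effect_fraction_star: float | None = None
    tu_ratio: float | None = None
    conc_ratio: float | None = None


def toxic_units(concs: tuple[float, float], ec50s: tuple[float, float]) -> TUState:
    """TU_i = C_i / EC50_i and the TU fractions z_i = TU_i / sum_TU.

    A zero-dose pair is degenerate: sum_TU = 0, z set to (0.5, 0.5) and
    flagged (any deviation G is forced to zero there).
    """
    if any(c < 0 for c in concs):
        raise ValueError("concentrations must be non-negative")
    if any(e <= 0 for e in ec50s):
        raise ValueError("EC50s must be positive")
    tu = (concs[0] / ec50s[0], concs[1] / ec50s[1])
    s = tu[0] + tu[1]
    if s == 0.0:
        return TUState(tu=tu, sum_tu=0.0, z=(0.5, 0.5), degenerate=True)
    return TUState(tu=tu, sum_tu=s, z=(tu[0] / s, tu[1] / s))


def deviation_g(
    spec: DeviationSpec,
    tu: TUState,
    ref_effect_fraction: float | None = None,
) -> float:
    """Evaluate the deviation function G for one mixture point.

    ``ref_effect_fraction`` (the IA reference effect, in [0, 1]) is required
    only for an IA dose-level deviation and ignored otherwise.
    """
    if spec.kind is DeviationKind.NONE or tu.degenerate:
        return 0.0
    z1, z2 = tu.z
    prod = z1 * z2
    if spec.kind is DeviationKind.SA:
        return spec.a * prod
    if spec.kind is DeviationKind.DR:
        z_lead = tu.z[spec.lead_index]
        return (spec.a + spec.b_dr * z_lead) * prod
    # DL
    if spec.base is Base.CA:
        return spec.a * (1.0 - spec.b_dl * tu.sum_tu) * prod
    if ref_effect_fraction is None:
        raise ValueError("IA-DL deviation needs the reference effect fraction")
    return spec.a * (1.0 - spec.b_dl * ref_effect_fraction) * prod


def _check_concs(concs: tuple[float, float]) -> None:
    if any(c < 0 for c in concs):
        raise ValueError("concentrations must be non-negative")


def predict_ca(params: MixtureParams, concs: tuple[float, float]) -> float:
    """Percent mobile under concentration addition (with optional deviation).

    Solves  sum_i c_i / [EC50_i * ((1-Y)/Y)**(1/beta_i)] = exp(G)  for the
    mobility fraction Y in (0, 1).  The left side is strictly increasing in
    Y, so the root is bracketed and unique; G uses EC50-based toxic units and
    is therefore constant during the solve.
    """
    _check_concs(concs)
    if concs[0] == 0.0 and concs[1] == 0.0:
        return params.u_max
    p1, p2 = params.chem
    if concs[1] == 0.0:
        return predict_mobility(p1, concs[0])
    if concs[0] == 0.0:
        return predict_mobility(p2, concs[1])

    tu = toxic_units(concs, (p1.ec50, p2.ec50))
    with np.errstate(over="ignore"):
        target = float(np.exp(np.float64(deviation_g(params.deviation, tu))))

    def lhs_minus_target(y: float) -> float:
        r = np.float64((1.0 - y) / y)
        with np.errstate(over="ignore", divide="ignore"):
            lhs = (concs[0] / (p1.ec50 * r ** (1.0 / p1.beta))
                   + concs[1] / (p2.ec50 * r ** (1.0 / p2.beta)))
        return float(lhs) - target

    # The left side rises monotonically from 0 (y -> 0) to +inf (y -> 1); at
    # float-representable brackets an extreme target can still sit outside,
    # in which case the solution is indistinguishable from 0 or u_max.
    lo, hi = 1e-300, 1.0 - 1e-16
    if lhs_minus_target(lo) >= 0.0:
        return 0.0
    if lhs_minus_target(hi) <= 0.0:
        return params.u_max
    y = brentq(lhs_minus_target, lo, hi, xtol=1e-15, rtol=8.9e-16,
               maxiter=200)
    return params.u_max * y


def predict_ia(params: MixtureParams, concs: tuple[float, float]) -> float:
    """Percent mobile under independent action (with optional deviation).

    Reference: y = u_max * q1 * q2.  With a deviation the survival product is
    raised to exp(-G): G < 0 depresses mobility below the reference
    (synergism), G > 0 raises it (antagonism), and G = 0 is exact recovery.
    """
    _check_concs(concs)
    p1, p2 = params.chem
    q1 = 1.0 / (1.0 + (concs[0] / p1.ec50) ** p1.beta)
    q2 = 1.0 / (1.0 + (concs[1] / p2.ec50) ** p2.beta)
    prod = q1 * q2
    if params.deviation.kind is DeviationKind.NONE:
        return params.u_max * prod
    tu = toxic_units(concs, (p1.ec50, p2.ec50))
    g = deviation_g(params.deviation, tu, ref_effect_fraction=1.0 - prod)
    return params.u_max * prod ** np.exp(-g)


def predict_mixture(params: MixtureParams, concs: tuple[float, float],
                    base: Base | str | None = None) -> float:
    """Dispatch to the CA or IA surface (default: the spec's own base)."""
    base = Base(base) if base is not None else params.deviation.base
    return predict_ca(params, concs) if base is Base.CA else predict_ia(params, concs)


def switch_locus(spec: DeviationSpec, ec50s: tuple[float, float]) -> SwitchLocus:
    """Locate the synergism/antagonism sign change of a DR or DL deviation.

    DR: G changes sign where a + b_DR * z_lead = 0; a switch exists only if
    that zero lies strictly inside (0, 1), i.e. when a and b_DR have opposite
    signs and |a| < |b_DR|.  The locus is reported as the TU fraction of the
    lead chemical, the other:lead TU ratio, and its native-unit concentration
    ratio equivalent.

    CA-DL: the sign change sits at sum_TU = 1/b_DL (needs b_DL > 0; b_DL = 1
    puts it exactly at the mixture EC50 level).  IA-DL: at reference effect
    fraction 1/b_DL (needs b_DL > 1 so the crossing is reachable).
    """
    if spec.kind not in (DeviationKind.DR, DeviationKind.DL):
        raise ValueError("switch locus is defined for DR and DL deviations only")

    if spec.kind is DeviationKind.DR:
        if spec.b_dr == 0.0:
            return SwitchLocus(exists=False)
        z_star = -spec.a / spec.b_dr
        if not 0.0 < z_star < 1.0:
            return SwitchLocus(exists=False)
        tu_ratio = (1.0 - z_star) / z_star
        lead, other = spec.lead_index, 1 - spec.lead_index
        conc_ratio = tu_ratio * ec50s[other] / ec50s[lead]
        return SwitchLocus(exists=True, z_lead=z_star, tu_ratio=tu_ratio,
                           conc_ratio=conc_ratio)

    if spec.base is Base.CA:
        if spec.b_dl <= 0.0:
            return SwitchLocus(exists=False)
        return SwitchLocus(exists=True, sum_tu_star=1.0 / spec.b_dl)
    if spec.b_dl <= 1.0:
        return SwitchLocus(exists=False)
    return SwitchLocus(exists=True, effect_fraction_star=1.0 / spec.b_dl)


def isobole_grid(
    params: MixtureParams,
    effect_levels: list[float],
    c1_max: float | None = None,
    c2_max: float | None = None,
    n_grid: int = 101,
    base: Base | str | None = None,
) -> list[dict]:
    """Extract iso-effect contours of the mixture surface on a rectangle.

    The surface is evaluated on an ``n_grid`` x ``n_grid`` rectilinear grid
    over [0, c1_max] x [0, c2_max] (defaults: twice each EC50) and contour
    polylines at each mobility level (percent) are traced by marching squares.
    Returns one record per contour point with keys ``base``, ``deviation``,
    ``effect_percent``, ``c1``, ``c2``.  Levels unreachable on the grid yield
    no rows and a warning.
    """
    base = Base(base) if base is not None else params.deviation.base
    for lvl in effect_levels:
        if not 0.0 < lvl < 100.0:
            raise ValueError(f"effect level {lvl} outside (0, 100)")
    if n_grid == 0:
        return []
    p1, p2 = params.chem
    c1_max = c1_max if c1_max is not None else 2.0 * p1.ec50
    c2_max = c2_max if c2_max is not None else 2.0 * p2.ec50
    c1s = np.linspace(0.0, c1_max, n_grid)
    c2s = np.linspace(0.0, c2_max, n_grid)
    surface = np.empty((n_grid, n_grid))
    for i, c1 in enumerate(c1s):
        for j, c2 in enumerate(c2s):
            surface[i, j] = predict_mixture(params, (c1, c2), base)

    rows: list[dict] = []
    for lvl in effect_levels:
        contours = measure.find_contours(surface, level=lvl)
        if not contours:
            warnings.warn(f"effect level {lvl}% not reachable on the grid",
                          stacklevel=2)
            continue
        for k, poly in enumerate(contours):
            # fractional grid indices -> concentrations
            c1_pts = np.interp(poly[:, 0], np.arange(n_grid), c1s)
            c2_pts = np.interp(poly[:, 1], np.arange(n_grid), c2s)
            for c1, c2 in zip(c1_pts, c2_pts):
                rows.append({
                    "base": base.value,
                    "deviation": params.deviation.kind.value,
                    "effect_percent": lvl,
                    "segment": k,
                    "c1": float(c1),
                    "c2": float(c2),
                })
    return rows
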