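"""Seeded synthetic bioassay generator emulating the study design.

No raw immobilization counts were deposited for the motivating experiment, so
this module generates datasets with the same structure: two single-chemical
dilution series (AgNO3 in μg/L over 0.5–2.5, ZnO nanoparticles in mg/L over
0.04–20), three binary mixture rays at fixed TU ratios (5:5, 3:7, 7:3 — MIX
I/II/III) crossed with seven total-toxic-unit levels spanning 0.0625–2.0, a
shared control, and eight replicate wells of five neonates per treatment.
Immobilization counts are binomial draws around the model-predicted mobility,
the natural noise model for a quantal endpoint; no overdispersion term is
added.

The seven ΣTU levels are log-spaced (constant factor 2^(5/6)): a factor-2
serial dilution covering exactly 0.0625–2.0 would give only six levels, so
the stated seven-level span is honoured by a slightly denser geometric
series.  Single-chemical defaults (6 AgNO3 + 7 ZnO levels) make the default
design 35 treatments in total.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .dose_response import QuantalObservation
from .inference import Dataset, MixtureFitConfig, fit_model
from .mixture_surface import Base, MixtureParams, predict_mixture

__all__ = [
    "DesignSpec",
    "RecoverySummary",
    "build_design",
    "simulate_dataset",
    "simulate_single_chemical",
    "recovery_study",
    "DEFAULT_DESIGN",
]


def _log_levels(lo: float, hi: float, n: int) -> tuple[float, ...]:
    return tuple(float(v) for v in np.geomspace(lo, hi, n))


@dataclass(frozen=True)
class DesignSpec:
    """Layout of one simulated study.

    ``ray_ratios`` are TU-fraction pairs (chemical 1, chemical 2) summing to
    one; ``sum_tu_levels`` the total toxic units along each ray.
    """

    single_levels: tuple[tuple[float, ...], tuple[float, ...]] = (
        _log_levels(0.5, 2.5, 6),
        _log_levels(0.04, 20.0, 7),
    )
    ray_ratios: tuple[tuple[float, float], ...] = (
        (0.5, 0.5), (0.3, 0.7), (0.7, 0.3))
    sum_tu_levels: tuple[float, ...] = _log_levels(0.0625, 2.0, 7)
    n_replicates: int = 8
    n_per_replicate: int = 5
    include_control: bool = True

    def __post_init__(self) -> None:
        for r in self.ray_ratios:
            if abs(r[0] + r[1] - 1.0) > 1e-12:
                raise ValueError(f"ray ratio {r} does not sum to 1")
        if any(l <= 0 for levels in self.single_levels for l in levels):
            raise ValueError("single-chemical levels must be positive")
        if any(s <= 0 for s in self.sum_tu_levels):
            raise ValueError("sum-TU levels must be positive")


DEFAULT_DESIGN = DesignSpec()


@dataclass
class RecoverySummary:
    """Percentile summary of repeated simulate-and-refit parameter estimates."""

    median: dict[str, float]
    lo: dict[str, float]
    hi: dict[str, float]
    n_sims: int
    n_failed: int
    seed: int


def build_design(spec: DesignSpec,
                 ec50s: tuple[float, float]) -> list[tuple[float, float]]:
    """Expand a design into the deterministic list of concentration pairs.

    Mixture treatments convert TU coordinates to native units via
    C_i = z_i * ΣTU * EC50_i; single-chemical treatments keep their native
    levels; the control is (0, 0).  The default design yields 21 mixture +
    6 + 7 single + 1 control = 35 treatments.
    """
    treatments: list[tuple[float, float]] = []
    if spec.include_control:
        treatments.append((0.0, 0.0))
    for level in spec.single_levels[0]:
        treatments.append((level, 0.0))
    for level in spec.single_levels[1]:
        treatments.append((0.0, level))
    for z1, z2 in spec.ray_ratios:
        for s in spec.sum_tu_levels:
            treatments.append((z1 * s * ec50s[0], z2 * s * ec50s[1]))
    return treatments


def _draw_counts(y_pred: float, spec: DesignSpec, treatment_id: str,
                 concs: tuple[float, float], rng: np.random.Generator,
                 records: list[QuantalObservation]) -> None:
    if not 0.0 <= y_pred <= 100.0:
        raise AssertionError(f"predicted mobility {y_pred} outside [0, 100]")
    p_immobile = 1.0 - y_pred / 100.0
    counts = rng.binomial(spec.n_per_replicate, p_immobile,
                          size=spec.n_replicates)
    for r, k in enumerate(counts):
        records.append(QuantalObservation(
            concentrations=concs, replicate_id=f"r{r + 1}",
            n_exposed=spec.n_per_replicate, n_immobile=int(k),
            treatment_id=treatment_id))


def simulate_dataset(true_params: MixtureParams, base: Base | str,
                     design: DesignSpec = DEFAULT_DESIGN,
                     seed: int | np.random.SeedSequence = 0) -> Dataset:
    """Simulate one full study dataset from a known mixture model.

    Per treatment and replicate well, the immobilized count is
    Binomial(n_per_replicate, 1 - y_pred/100).  The same seed reproduces the
    dataset exactly.
    """
    base = Base(base)
    rng = np.random.default_rng(seed)
    ec50s = (true_params.chem[0].ec50, true_params.chem[1].ec50)
    records: list[QuantalObservation] = []
    for t, concs in enumerate(build_design(design, ec50s)):
        y = predict_mixture(true_params, concs, base)
        _draw_counts(y, design, f"t{t:02d}", concs, rng, records)
    units = (true_params.chem[0].unit_label, true_params.chem[1].unit_label)
    return Dataset(observations=records, units=units)


def simulate_single_chemical(params, levels: Sequence[float],
                             n_replicates: int = 8, n_per_replicate: int = 5,
                             include_control: bool = True,
                             seed: int | np.random.SeedSequence = 0,
                             ) -> list[QuantalObservation]:
    """Simulate a one-chemical dilution series with binomial noise."""
    from .dose_response import predict_mobility

    rng = np.random.default_rng(seed)
    concs = ([0.0] if include_control else []) + list(levels)
    records: list[QuantalObservation] = []
    for t, c in enumerate(concs):
        y = predict_mobility(params, c)
        p_immobile = 1.0 - y / 100.0
        counts = rng.binomial(n_per_replicate, p_immobile, size=n_replicates)
        for r, k in enumerate(counts):
            records.append(QuantalObservation(
                concentrations=(float(c),), replicate_id=f"r{r + 1}",
                n_exposed=n_per_replicate, n_immobile=int(k),
                treatment_id=f"t{t:02d}"))
    return records


def recovery_study(true_params: MixtureParams, base: Base | str,
                   design: DesignSpec = DEFAULT_DESIGN, n_sims: int = 200,
                   seed: int = 0,
                   fit_config: MixtureFitConfig | None = None,
                   ) -> RecoverySummary:
    """Repeated simulate-and-refit under the generating model.

    Each simulation uses an independent child stream of ``seed``; the fitted
    model has the same base and deviation kind as the truth.  Individual fit
    failures are excluded and counted.
    """
    base = Base(base)
    kind = true_params.deviation.kind
    root = np.random.SeedSequence(seed)
    children = root.spawn(n_sims)
    rows: list[dict[str, float]] = []
    n_failed = 0
    for child in children:
        data = simulate_dataset(true_params, base, design, seed=child)
        try:
            fit = fit_model(data, base, kind, fit_config)
        except (RuntimeError, ValueError):
            n_failed += 1
            continue
        p = fit.params
        rows.append({
            "u_max": p.u_max,
            "beta1": p.chem[0].beta, "beta2": p.chem[1].beta,
            "ec50_1": p.chem[0].ec50, "ec50_2": p.chem[1].ec50,
            "a": p.deviation.a, "b_dr": p.deviation.b_dr,
            "b_dl": p.deviation.b_dl,
        })
    if not rows:
        raise RuntimeError("every simulated fit failed")
    names = rows[0].keys()
    arr = {k: np.array([r[k] for r in rows]) for k in names}
    return RecoverySummary(
        median={k: float(np.median(v)) for k, v in arr.items()},
        lo={k: float(np.percentile(v, 2.5)) for k, v in arr.items()},
        hi={k: float(np.percentile(v, 97.5)) for k, v in arr.items()},
        n_sims=n_sims, n_failed=n_failed, seed=seed)
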