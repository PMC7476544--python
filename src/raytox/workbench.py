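"""File formats, run configuration, reporting, and the command-line pipeline.

The CLI chains the analysis stages through flat files only:

    raytox simulate --truth params.json --seed 7 -o data.csv
    raytox select -i data.csv -o ledger.json --alpha 0.05
    raytox isobole --params fit.json --levels 25,50,75 -o contours.csv

Dataset CSV schema (one row per replicate well): ``treatment``,
``replicate``, ``conc1``, ``unit1``, ``conc2``, ``unit2``, ``n_exposed``,
``n_immobile``.  Concentrations always travel with their unit labels; toxic
units are the only place units cancel.  Parameter sets are JSON documents
mirroring the MixtureParams field names.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass
from pathlib import Path

import click
import pandas as pd

from .dose_response import FitConfig, LogLogisticParams, QuantalObservation, fit_single
from .inference import (Dataset, MixtureFitConfig, ModelSelection, fit_model,
                        select_model)
from .mixture_surface import (Base, DeviationKind, DeviationSpec,
                              MixtureParams, isobole_grid, switch_locus,
                              toxic_units)
from .synthetic_data import DEFAULT_DESIGN, DesignSpec, simulate_dataset

log = logging.getLogger("raytox")

__all__ = [
    "RunConfig",
    "read_dataset",
    "write_dataset",
    "params_to_json",
    "params_from_json",
    "report_selection",
    "cli",
]

_COLUMNS = ["treatment", "replicate", "conc1", "unit1", "conc2", "unit2",
            "n_exposed", "n_immobile"]


@dataclass
class RunConfig:
    """Pipeline-level settings shared by the CLI subcommands."""

    alpha: float = 0.05
    bootstrap_draws: int = 999
    multistart: int = 16
    seed: int = 0
    aggregation: str = "treatment_mean"

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must lie in (0, 1)")
        if self.bootstrap_draws < 0:
            raise ValueError("bootstrap_draws must be >= 0")
        if self.aggregation not in ("treatment_mean", "replicate"):
            raise ValueError(f"unknown aggregation {self.aggregation!r}")


# ---------------------------------------------------------------------------
# Dataset I/O


def write_dataset(dataset: Dataset, path: str | Path) -> None:
    rows = [{
        "treatment": obs.treatment_id,
        "replicate": obs.replicate_id,
        "conc1": obs.concentrations[0],
        "unit1": dataset.units[0],
        "conc2": obs.concentrations[1],
        "unit2": dataset.units[1],
        "n_exposed": obs.n_exposed,
        "n_immobile": obs.n_immobile,
    } for obs in dataset.observations]
    pd.DataFrame(rows, columns=_COLUMNS).to_csv(path, index=False)


def read_dataset(path: str | Path) -> Dataset:
    """Read and validate a replicate-level dataset CSV.

    Malformed rows are reported with their file line number (header = line
    1).  A header-only file yields an empty Dataset with a warning.
    """
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in _COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    if df.empty:
        warnings.warn(f"{path}: no data rows", stacklevel=2)
        return Dataset(observations=[], units=("", ""))
    units = (str(df["unit1"].iloc[0]), str(df["unit2"].iloc[0]))
    for col, label in (("unit1", units[0]), ("unit2", units[1])):
        bad = df.index[df[col].astype(str) != label]
        if len(bad):
            raise ValueError(
                f"{path}: line {bad[0] + 2}: inconsistent unit label "
                f"{df[col].iloc[bad[0]]!r} (expected {label!r})")
    observations = []
    for idx, row in df.iterrows():
        try:
            observations.append(QuantalObservation(
                concentrations=(float(row["conc1"]), float(row["conc2"])),
                replicate_id=str(row["replicate"]),
                n_exposed=int(row["n_exposed"]),
                n_immobile=int(row["n_immobile"]),
                treatment_id=str(row["treatment"]),
            ))
        except (ValueError, TypeError) as exc:
            raise ValueError(f"{path}: line {idx + 2}: {exc}") from exc
    return Dataset(observations=observations, units=units)


_SINGLE_COLUMNS = ["chemical", "conc", "unit", "replicate", "n_exposed",
                   "n_immobile"]


def read_single_chemical_csv(path: str | Path) -> dict[str, list[QuantalObservation]]:
    """Read a one-chemical-per-row bioassay CSV, grouped by chemical.

    Schema: ``chemical``, ``conc``, ``unit``, ``replicate``, ``n_exposed``,
    ``n_immobile`` (one header row, UTF-8, decimal point).  Each chemical
    must carry a single consistent unit label.  Treatments are keyed by
    concentration.
    """
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in _SINGLE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    out: dict[str, list[QuantalObservation]] = {}
    units: dict[str, str] = {}
    for idx, row in df.iterrows():
        chem = str(row["chemical"])
        unit = str(row["unit"])
        if units.setdefault(chem, unit) != unit:
            raise ValueError(
                f"{path}: line {idx + 2}: unit {unit!r} conflicts with "
                f"{units[chem]!r} for chemical {chem!r}")
        try:
            obs = QuantalObservation(
                concentrations=(float(row["conc"]),),
                replicate_id=str(row["replicate"]),
                n_exposed=int(row["n_exposed"]),
                n_immobile=int(row["n_immobile"]),
                treatment_id=f"{chem}@{row['conc']}")
        except (ValueError, TypeError) as exc:
            raise ValueError(f"{path}: line {idx + 2}: {exc}") from exc
        out.setdefault(chem, []).append(obs)
    return out


# ---------------------------------------------------------------------------
# Parameter JSON


def params_to_json(params: MixtureParams) -> dict:
    return {
        "u_max": params.u_max,
        "chem": [{"beta": p.beta, "ec50": p.ec50, "unit_label": p.unit_label}
                 for p in params.chem],
        "deviation": {
            "base": params.deviation.base.value,
            "kind": params.deviation.kind.value,
            "a": params.deviation.a,
            "b_dr": params.deviation.b_dr,
            "b_dl": params.deviation.b_dl,
            "lead_index": params.deviation.lead_index,
        },
    }


def params_from_json(doc: dict) -> MixtureParams:
    dev = doc.get("deviation", {})
    spec = DeviationSpec(
        base=Base(dev.get("base", "CA")),
        kind=DeviationKind(dev.get("kind", "NONE")),
        a=float(dev.get("a", 0.0)), b_dr=float(dev.get("b_dr", 0.0)),
        b_dl=float(dev.get("b_dl", 0.0)),
        lead_index=int(dev.get("lead_index", 0)))
    u_max = float(doc["u_max"])
    chem = tuple(
        LogLogisticParams(u_max=u_max, beta=float(c["beta"]),
                          ec50=float(c["ec50"]),
                          unit_label=str(c.get("unit_label", "")))
        for c in doc["chem"])
    return MixtureParams(u_max=u_max, chem=chem, deviation=spec)


# ---------------------------------------------------------------------------
# Reporting


def _ledger_rows(selection: ModelSelection) -> list[dict]:
    rows = []
    for (base, kind), fit in selection.fits.items():
        p = fit.params
        test = selection.tests.get((base, kind))
        rows.append({
            "model": f"{base}-{kind}" if kind != "NONE" else base,
            "C_max": p.u_max,
            "beta1": p.chem[0].beta, "beta2": p.chem[1].beta,
            "EC50_1": p.chem[0].ec50, "EC50_2": p.chem[1].ec50,
            "a": p.deviation.a if kind != "NONE" else None,
            "b_DR": p.deviation.b_dr if kind == "DR" else None,
            "b_DL": p.deviation.b_dl if kind == "DL" else None,
            "SS": fit.ss,
            "chi2": test.chi2 if test else None,
            "df": test.df if test else None,
            "p": test.p if test else None,
        })
    return rows


def report_selection(selection: ModelSelection, dataset: Dataset,
                     out_prefix: str | Path) -> dict:
    """Write the model-fit ledger, predicted-vs-observed, and switch summary.

    Emits ``<prefix>_ledger.csv`` / ``.json`` (one row per fitted model, the
    machine-readable fit-summary table), ``<prefix>_pred_obs.csv`` (treatment
    means against the best model's predictions, mixture rows tagged by their
    TU-fraction ray), and, when the winning model carries a DR or DL
    deviation, a switch-locus section in the JSON (TU ratio and native-unit
    concentration-ratio equivalent of the synergism/antagonism crossover).
    """
    out_prefix = Path(out_prefix)
    rows = _ledger_rows(selection)
    pd.DataFrame(rows).to_csv(f"{out_prefix}_ledger.csv", index=False)

    best_fit = selection.fits[selection.best]
    doc: dict = {
        "models": rows,
        "best": f"{selection.best[0]}-{selection.best[1]}".removesuffix("-NONE"),
        "alpha": selection.alpha,
        "best_params": params_to_json(best_fit.params),
    }

    from .mixture_surface import predict_mixture
    concs, means = dataset.treatment_means()
    ec50s = (best_fit.params.chem[0].ec50, best_fit.params.chem[1].ec50)
    po_rows = []
    for c, m in zip(concs, means):
        pred = predict_mixture(best_fit.params, tuple(c), best_fit.base)
        if c[0] > 0 and c[1] > 0:
            ray = f"z1={toxic_units(tuple(c), ec50s).z[0]:.2f}"
        elif c[0] == c[1] == 0.0:
            ray = "control"
        else:
            ray = "single-1" if c[0] > 0 else "single-2"
        po_rows.append({"conc1": c[0], "conc2": c[1], "ray": ray,
                        "observed": m, "predicted": pred})
    pd.DataFrame(po_rows).to_csv(f"{out_prefix}_pred_obs.csv", index=False)

    if best_fit.kind in (DeviationKind.DR, DeviationKind.DL):
        locus = switch_locus(best_fit.params.deviation, ec50s)
        doc["switch"] = {
            "exists": locus.exists,
            "z_lead": locus.z_lead,
            "tu_ratio_other_to_lead": locus.tu_ratio,
            "conc_ratio_other_to_lead": locus.conc_ratio,
            "sum_tu_star": locus.sum_tu_star,
            "effect_fraction_star": locus.effect_fraction_star,
        }
    with open(f"{out_prefix}_ledger.json", "w") as fh:
        json.dump(doc, fh, indent=2)
    return doc


# ---------------------------------------------------------------------------
# CLI


@click.group()
@click.option("-v", "--verbose", is_flag=True, help="log fits at INFO level")
def cli(verbose: bool) -> None:
    """Mixture-toxicity response-surface analysis for quantal bioassays."""
    logging.basicConfig(
        level=logging.INFO if verbose else logging.WARNING,
        format="%(levelname)s %(name)s: %(message)s")


@cli.command()
@click.option("--truth", required=True, type=click.Path(exists=True),
              help="MixtureParams JSON used as the generating model")
@click.option("--design", type=click.Path(exists=True),
              help="DesignSpec JSON (default: the built-in 35-treatment design)")
@click.option("--base", default=None, help="CA or IA (default: truth's base)")
@click.option("--seed", default=0, show_default=True, type=int)
@click.option("-o", "--out", required=True, type=click.Path())
def simulate(truth: str, design: str | None, base: str | None, seed: int,
             out: str) -> None:
    """Simulate a bioassay dataset CSV from a known mixture model."""
    with open(truth) as fh:
        params = params_from_json(json.load(fh))
    spec = DEFAULT_DESIGN
    if design:
        with open(design) as fh:
            doc = json.load(fh)
        doc = {k: (tuple(tuple(x) if isinstance(x, list) else x for x in v)
                   if isinstance(v, list) else v) for k, v in doc.items()}
        spec = DesignSpec(**doc)
    b = Base(base) if base else params.deviation.base
    dataset = simulate_dataset(params, b, spec, seed=seed)
    write_dataset(dataset, out)
    sidecar = Path(out).with_suffix(".truth.json")
    design_doc = {
        "single_levels": [list(l) for l in spec.single_levels],
        "ray_ratios": [list(r) for r in spec.ray_ratios],
        "sum_tu_levels": list(spec.sum_tu_levels),
        "n_replicates": spec.n_replicates,
        "n_per_replicate": spec.n_per_replicate,
        "include_control": spec.include_control,
    }
    with open(sidecar, "w") as fh:
        json.dump({"truth": params_to_json(params), "base": b.value,
                   "design": design_doc, "seed": seed}, fh, indent=2)
    click.echo(f"wrote {len(dataset.observations)} rows to {out}")


@cli.command("fit-single")
@click.option("-i", "--data", "path", required=True, type=click.Path(exists=True))
@click.option("--chemical", type=click.IntRange(1, 2), default=1,
              show_default=True, help="which concentration column to fit")
@click.option("--bootstrap", default=999, show_default=True, type=int)
@click.option("--seed", default=0, show_default=True, type=int)
@click.option("-o", "--out", required=True, type=click.Path())
def fit_single_cmd(path: str, chemical: int, bootstrap: int, seed: int,
                   out: str) -> None:
    """Fit the single-chemical log-logistic curve with bootstrap EC50 CI."""
    dataset = read_dataset(path)
    obs = dataset.single_chemical(chemical - 1)
    fit = fit_single(obs, FitConfig(bootstrap_draws=bootstrap,
                                    bootstrap_seed=seed))
    doc = {"u_max": fit.params.u_max, "beta": fit.params.beta,
           "ec50": fit.params.ec50,
           "unit": dataset.units[chemical - 1],
           "ss": fit.ss, "n_obs": fit.n_obs, "ci_ec50": fit.ci_ec50}
    with open(out, "w") as fh:
        json.dump(doc, fh, indent=2)
    click.echo(json.dumps(doc))


@cli.command("fit-mixture")
@click.option("-i", "--data", "path", required=True, type=click.Path(exists=True))
@click.option("--base", required=True, type=click.Choice(["CA", "IA"]))
@click.option("--deviation", default="NONE", show_default=True,
              type=click.Choice(["NONE", "SA", "DR", "DL"]))
@click.option("--seed", default=0, show_default=True, type=int)
@click.option("-o", "--out", required=True, type=click.Path())
def fit_mixture_cmd(path: str, base: str, deviation: str, seed: int,
                    out: str) -> None:
    """Fit one mixture model (base + deviation) to a dataset."""
    dataset = read_dataset(path)
    fit = fit_model(dataset, base, deviation, MixtureFitConfig(seed=seed))
    doc = params_to_json(fit.params)
    doc.update(ss=fit.ss, n_obs=fit.n_obs, k_params=fit.k_params,
               converged=fit.converged)
    with open(out, "w") as fh:
        json.dump(doc, fh, indent=2)
    click.echo(f"{base}-{deviation}: SS={fit.ss:.2f}")


@cli.command()
@click.option("-i", "--data", "path", required=True, type=click.Path(exists=True))
@click.option("--alpha", default=0.05, show_default=True, type=float)
@click.option("--seed", default=0, show_default=True, type=int)
@click.option("-o", "--out", required=True, type=click.Path(),
              help="output prefix for the ledger/report files")
def select(path: str, alpha: float, seed: int, out: str) -> None:
    """Fit all eight models, run the nested chi-square tests, pick the best."""
    dataset = read_dataset(path)
    cfg = MixtureFitConfig(seed=seed, alpha=alpha)
    selection = select_model(dataset, cfg)
    prefix = str(out).removesuffix(".json")
    doc = report_selection(selection, dataset, prefix)
    click.echo(f"best model: {doc['best']}")


@cli.command()
@click.option("--params", "params_path", required=True,
              type=click.Path(exists=True), help="MixtureParams JSON")
@click.option("--levels", default="25,50,75", show_default=True,
              help="comma-separated mobility percentages")
@click.option("--base", default=None, help="CA or IA (default: params' base)")
@click.option("--c1-max", type=float, default=None)
@click.option("--c2-max", type=float, default=None)
@click.option("--n-grid", default=101, show_default=True, type=int)
@click.option("-o", "--out", required=True, type=click.Path())
def isobole(params_path: str, levels: str, base: str | None,
            c1_max: float | None, c2_max: float | None, n_grid: int,
            out: str) -> None:
    """Extract iso-effect contour polylines of a mixture surface to CSV."""
    with open(params_path) as fh:
        params = params_from_json(json.load(fh))
    lvls = [float(x) for x in levels.split(",")]
    rows = isobole_grid(params, lvls, c1_max=c1_max, c2_max=c2_max,
                        n_grid=n_grid, base=base)
    df = pd.DataFrame(rows, columns=["base", "deviation", "effect_percent",
                                     "segment", "c1", "c2"])
    df["unit1"] = params.chem[0].unit_label
    df["unit2"] = params.chem[1].unit_label
    df.to_csv(out, index=False)
    click.echo(f"wrote {len(df)} contour points to {out}")


@cli.command()
@click.option("-i", "--data", "path", required=True, type=click.Path(exists=True))
@click.option("--ledger", required=True, type=click.Path(exists=True),
              help="selection ledger JSON produced by `select`")
@click.option("-o", "--out", required=True, type=click.Path())
def report(path: str, ledger: str, out: str) -> None:
    """Recompute predicted-vs-observed for the best model in a ledger."""
    dataset = read_dataset(path)
    with open(ledger) as fh:
        doc = json.load(fh)
    params = params_from_json(doc["best_params"])
    from .mixture_surface import predict_mixture
    concs, means = dataset.treatment_means()
    rows = [{"conc1": c[0], "conc2": c[1], "observed": m,
             "predicted": predict_mixture(params, tuple(c))}
            for c, m in zip(concs, means)]
    pd.DataFrame(rows).to_csv(out, index=False)
    click.echo(f"wrote {len(rows)} treatment rows to {out}")
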