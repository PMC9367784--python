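"""One-at-a-time sensitivity and Monte-Carlo uncertainty propagation.

The inventory is a sum of products of its parameters, so every output is
piecewise linear in each single parameter; the one-at-a-time (OAT)
elasticity (ΔE/E)/(Δp/p) of a linear output equals the perturbed term's
share of that output, which makes the elasticities directly auditable
against the inventory's own shares.

Monte Carlo draws parameter vectors from independent per-parameter
distributions (plain sampling, no Latin hypercube, for auditability),
rebuilds the inventory per draw and summarizes each output.  Identical
(scenario, distributions, n, seed) inputs give bit-identical summaries.

Parameters are addressed by dot paths into the scenario model, e.g.
``herd.enteric_ef``, ``factors.ef_farm_corn``, ``gwp.gwp_ch4``.
Outputs are addressed by id: ``total``, ``gas:<CO2|CH4|N2O>``,
``industry:<planting|breeding>``, ``<process>`` or ``<process>:<gas>``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from .config import EmissionFactorSet, ScenarioSpec
from .report import GASES, InventoryReport, build_inventory

__all__ = [
    "UsageError",
    "ParameterDistribution",
    "UncertaintySummary",
    "get_parameter",
    "set_parameter",
    "extract_output",
    "default_outputs",
    "oat_elasticity",
    "monte_carlo",
    "default_distributions",
    "load_distributions",
]

#: Scenario fields that are fractions; their sampled values are kept in [0, 1].
_FRACTION_FIELDS = {
    "planting.n_fertilizer_share",
    "planting.compound_fertilizer_share",
    "planting.compound_n_content",
    "planting.straw_feed_fraction",
    "planting.straw_burn_fraction",
    "manure.return_rate",
    "manure.ms_fraction",
    "manure.f_gas",
    "manure.f_leach",
    "factors.f_gas_fert",
    "factors.f_gas_manure",
    "factors.f_leach_soil",
}


class UsageError(ValueError):
    """A parameter path, output id or distribution was specified wrongly."""


def get_parameter(spec: ScenarioSpec, path: str) -> float:
    """Resolve a dot path to a numeric scenario parameter."""
    obj = spec
    for part in path.split("."):
        if not hasattr(obj, part):
            raise UsageError(f"unknown parameter path {path!r} (no field {part!r})")
        obj = getattr(obj, part)
    if isinstance(obj, bool) or not isinstance(obj, (int, float)):
        raise UsageError(f"parameter {path!r} is not numeric")
    return float(obj)


def set_parameter(spec: ScenarioSpec, path: str, value: float) -> ScenarioSpec:
    """Return a copy of ``spec`` with the dot-addressed parameter replaced.

    The copy is re-validated, so a value that breaks a scenario invariant
    raises the usual validation error.
    """
    get_parameter(spec, path)  # raises UsageError on a bad path
    data = spec.model_dump()
    node = data
    *parents, leaf = path.split(".")
    for part in parents:
        node = node[part]
    node[leaf] = value
    return ScenarioSpec.model_validate(data)


def extract_output(report: InventoryReport, output: str) -> float:
    """Read one output quantity (CO₂-eq kg·a⁻¹) out of an inventory."""
    if output == "total":
        return report.total
    if output.startswith("gas:"):
        gas = output.split(":", 1)[1]
        if gas not in GASES:
            raise UsageError(f"unknown gas in output id {output!r}")
        return report.gas_totals()[gas]
    if output.startswith("industry:"):
        industry = output.split(":", 1)[1]
        totals = report.industry_totals()
        if industry not in totals:
            raise UsageError(f"unknown industry in output id {output!r}")
        return totals[industry]
    if ":" in output:
        process, gas = output.split(":", 1)
    else:
        process, gas = output, None
    known = {e.process for e in report.entries}
    if process not in known:
        raise UsageError(
            f"unknown output id {output!r}; processes in this report: {sorted(known)}"
        )
    return report.get(process, gas)


def default_outputs(report: InventoryReport) -> list[str]:
    """``total``, each gas, and each process present in the report."""
    outs = ["total"] + [f"gas:{g}" for g in GASES]
    seen: list[str] = []
    for e in report.entries:
        if e.process not in seen:
            seen.append(e.process)
    return outs + seen


def oat_elasticity(
    spec: ScenarioSpec,
    parameter: str,
    relative_delta: float,
    output: str,
    mode: str = "replication",
) -> float:
    """Central-difference elasticity of ``output`` w.r.t. ``parameter``.

    (ΔE/E)/(Δp/p) evaluated at the scenario's value with a symmetric
    ±relative_delta perturbation.  For outputs linear in the parameter
    this equals the parameter's term share of the output exactly.
    """
    if not 0 < relative_delta <= 0.5:
        raise UsageError("relative_delta must be in (0, 0.5]")
    p0 = get_parameter(spec, parameter)
    if p0 == 0:
        raise UsageError(
            f"parameter {parameter!r} is zero; a relative perturbation is undefined"
        )
    e0 = extract_output(build_inventory(spec, mode), output)
    if e0 == 0:
        raise UsageError(f"output {output!r} is zero at the scenario value")
    lo = extract_output(
        build_inventory(set_parameter(spec, parameter, p0 * (1 - relative_delta)), mode),
        output,
    )
    hi = extract_output(
        build_inventory(set_parameter(spec, parameter, p0 * (1 + relative_delta)), mode),
        output,
    )
    return (hi - lo) / (2.0 * relative_delta * e0)


@dataclass(frozen=True)
class ParameterDistribution:
    """Sampling distribution for one dot-addressed scenario parameter.

    kinds and their ``params``:

    - ``uniform``: ``low``, ``high``
    - ``triangular``: ``low``, ``mode``, ``high``
    - ``normal``: ``mean``, ``sd``, truncated at 0 (and at 1 for
      fraction-valued parameters)
    """

    path: str
    kind: str
    params: dict
    units: str = ""

    def __post_init__(self) -> None:
        needed = {
            "uniform": ("low", "high"),
            "triangular": ("low", "mode", "high"),
            "normal": ("mean", "sd"),
        }
        if self.kind not in needed:
            raise UsageError(f"unknown distribution kind {self.kind!r}")
        missing = [k for k in needed[self.kind] if k not in self.params]
        if missing:
            raise UsageError(
                f"distribution for {self.path!r} ({self.kind}) missing {missing}"
            )
        if self.kind in ("uniform", "triangular") and (
            self.params["low"] > self.params["high"]
        ):
            raise UsageError(f"empty interval for {self.path!r}")

    def _bounds(self) -> tuple[float, float]:
        upper = 1.0 if self.path in _FRACTION_FIELDS else np.inf
        return 0.0, upper

    def sample(self, rng: np.random.Generator) -> float:
        lo, hi = self._bounds()
        if self.kind == "uniform":
            a, b = self.params["low"], self.params["high"]
            x = a if a == b else rng.uniform(a, b)
        elif self.kind == "triangular":
            a, m, b = self.params["low"], self.params["mode"], self.params["high"]
            x = a if a == b else rng.triangular(a, m, b)
        else:  # truncated normal, by rejection
            for _ in range(1000):
                x = rng.normal(self.params["mean"], self.params["sd"])
                if lo <= x <= hi:
                    break
        return float(min(max(x, lo), hi))


@dataclass
class UncertaintySummary:
    """Monte-Carlo summary: one row per output, plus provenance."""

    frame: pd.DataFrame  # index: output id; columns: mean, sd, p2.5, p50, p97.5
    n: int
    seed: int
    mode: str

    def to_dict(self) -> dict:
        return {
            "n": self.n,
            "seed": self.seed,
            "mode": self.mode,
            "outputs": {
                out: {k: float(v) for k, v in row.items()}
                for out, row in self.frame.iterrows()
            },
        }


def monte_carlo(
    spec: ScenarioSpec,
    dists: Sequence[ParameterDistribution],
    n: int,
    seed: int,
    mode: str = "replication",
    outputs: Optional[Sequence[str]] = None,
) -> UncertaintySummary:
    """Propagate parameter uncertainty through the inventory.

    Draws ``n`` parameter vectors with a generator seeded by ``seed``
    (parameters sampled in the given order within each draw), rebuilds
    the inventory per draw and summarizes every requested output with
    mean, standard deviation and the 2.5/50/97.5 percentiles.
    """
    if n < 1:
        raise UsageError("n must be >= 1")
    for d in dists:
        get_parameter(spec, d.path)  # fail on unresolvable paths before sampling
    base = build_inventory(spec, mode)
    outs = list(outputs) if outputs is not None else default_outputs(base)
    for out in outs:
        extract_output(base, out)

    rng = np.random.default_rng(seed)
    samples = np.empty((n, len(outs)))
    for i in range(n):
        data = spec.model_dump()
        for d in dists:
            node = data
            *parents, leaf = d.path.split(".")
            for part in parents:
                node = node[part]
            node[leaf] = d.sample(rng)
        drawn = ScenarioSpec.model_validate(data)
        rep = build_inventory(drawn, mode)
        for j, out in enumerate(outs):
            samples[i, j] = extract_output(rep, out)

    pcts = np.percentile(samples, [2.5, 50.0, 97.5], axis=0)
    frame = pd.DataFrame(
        {
            "mean": samples.mean(axis=0),
            "sd": samples.std(axis=0, ddof=1) if n > 1 else np.zeros(len(outs)),
            "p2.5": pcts[0],
            "p50": pcts[1],
            "p97.5": pcts[2],
        },
        index=pd.Index(outs, name="output"),
    )
    return UncertaintySummary(frame=frame, n=n, seed=seed, mode=mode)


def default_distributions(spec: ScenarioSpec) -> list[ParameterDistribution]:
    """±20% uniform bands on every emission factor, plus the published
    feed-intake range where one exists.

    Factor bands cover all :class:`EmissionFactorSet` fields and the
    animal-level factors (enteric CH₄, manure-management CH₄/N₂O);
    fraction-valued factors are clipped to [0, 1].  Conventional
    scenarios additionally perturb the common-corn (roughage) intake over
    its published 8–10 kg·head⁻¹·d⁻¹ range; the ecological-cycle silage
    intake has no published range and is left fixed.
    """
    paths = [f"factors.{name}" for name in EmissionFactorSet.model_fields]
    paths += ["herd.enteric_ef", "manure.mm_ch4_ef", "manure.mm_n2o_direct_ef"]
    dists = []
    for path in paths:
        value = get_parameter(spec, path)
        low, high = 0.8 * value, 1.2 * value
        if path in _FRACTION_FIELDS:
            high = min(high, 1.0)
        dists.append(
            ParameterDistribution(path=path, kind="uniform", params={"low": low, "high": high})
        )
    if spec.model_kind == "non-EC":
        dists.append(
            ParameterDistribution(
                path="planting.feed_intake_per_head_day",
                kind="uniform",
                params={"low": 8.0, "high": 10.0},
                units="kg·head⁻¹·d⁻¹",
            )
        )
    return dists


def load_distributions(path: str | Path) -> list[ParameterDistribution]:
    """Read a YAML/JSON list of {path, kind, params[, units]} records."""
    data = yaml.safe_load(Path(path).read_text())
    if not isinstance(data, list):
        raise UsageError(f"{path}: distribution file must contain a list")
    return [ParameterDistribution(**item) for item in data]
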