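"""Randomized but structurally valid scenario generation.

Every pipeline stage can be exercised without external data: the
generator samples scenario parameters inside closed intervals anchored to
the published values and ranges, starting from the corresponding
published fixture and replacing only the sampled fields.  Pinning every
interval to a point therefore reproduces the published scenario — and
its inventory — exactly; the generator is a strict superset of the
fixtures.

Structural rules are preserved by construction: ecological-cycle
scenarios never burn straw, and conventional scenarios keep the two
retained straw fates (feed + burn) summing to the published 0.9563
unless the burn fraction is sampled explicitly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .config import ScenarioSpec, paper_scenarios, save_scenario
from .sensitivity import UsageError, get_parameter

__all__ = [
    "GenerationRanges",
    "default_ranges",
    "paper_pinned_ranges",
    "generate_scenario",
    "generate_suite",
    "STRAW_FATE_TOTAL",
]

#: Published sum of the two retained straw fates (feed 9.88% + burn 85.75%).
STRAW_FATE_TOTAL = 0.9563


@dataclass
class GenerationRanges:
    """Closed sampling intervals per dot-addressed parameter.

    ``herd.herd_size`` is sampled log-uniformly when ``herd_log_uniform``
    is set (the default), so herd-linearity properties are exercised
    across scales; all other parameters are sampled uniformly.
    ``include_paper_overrides`` keeps the published fixture's as-printed
    process overrides in the generated scenario (used by pinned ranges).
    """

    model_kind: str = "EC"
    seed: int = 0
    ranges: dict[str, tuple[float, float]] = field(default_factory=dict)
    herd_log_uniform: bool = True
    include_paper_overrides: bool = False


def _paper_fixture(model_kind: str) -> ScenarioSpec:
    ec, nonec = paper_scenarios()
    if model_kind == "EC":
        return ec
    if model_kind == "non-EC":
        return nonec
    raise UsageError(f"unknown model kind {model_kind!r}")


def _band(value: float, fraction_cap: bool = False) -> tuple[float, float]:
    lo, hi = 0.8 * value, 1.2 * value
    return (lo, min(hi, 1.0) if fraction_cap else hi)


def default_ranges(model_kind: str, seed: int = 0) -> GenerationRanges:
    """±20% bands around the published values, the published intake range
    for conventional scenarios, and a log-uniform herd size 10⁴–10⁷."""
    base = _paper_fixture(model_kind)
    ranges: dict[str, tuple[float, float]] = {"herd.herd_size": (1e4, 1e7)}
    for path in (
        "herd.live_weight",
        "herd.enteric_ef",
        "herd.n_excretion_rate",
        "herd.manure_per_head_day",
        "planting.planting_area",
        "planting.fertilizer_application_rate",
        "manure.vs_rate",
        "manure.mm_ch4_ef",
        "manure.mm_n2o_direct_ef",
    ):
        ranges[path] = _band(get_parameter(base, path))
    for path in (
        "planting.n_fertilizer_share",
        "planting.compound_fertilizer_share",
        "planting.compound_n_content",
        "manure.ms_fraction",
        "manure.f_gas",
        "manure.f_leach",
    ):
        ranges[path] = _band(get_parameter(base, path), fraction_cap=True)
    if model_kind == "non-EC":
        # published roughage range; feed fraction band keeps burn = 0.9563 - feed valid
        ranges["planting.feed_intake_per_head_day"] = (8.0, 10.0)
        ranges["planting.straw_feed_fraction"] = _band(0.0988, fraction_cap=True)
        ranges["manure.return_rate"] = _band(0.45, fraction_cap=True)
    else:
        ranges["planting.feed_intake_per_head_day"] = (18.0, 22.0)
    return GenerationRanges(model_kind=model_kind, seed=seed, ranges=ranges)


def paper_pinned_ranges(model_kind: str, seed: int = 0) -> GenerationRanges:
    """Every interval pinned to the published value: sampling reproduces
    the published fixture (including its overrides) exactly."""
    base = _paper_fixture(model_kind)
    paths = [
        f"{section}.{name}"
        for section, model in (
            ("herd", base.herd),
            ("planting", base.planting),
            ("manure", base.manure),
            ("factors", base.factors),
            ("gwp", base.gwp),
        )
        for name, value in model.model_dump().items()
        if not isinstance(value, bool)
    ]
    ranges = {p: (get_parameter(base, p), get_parameter(base, p)) for p in paths}
    return GenerationRanges(
        model_kind=model_kind,
        seed=seed,
        ranges=ranges,
        herd_log_uniform=False,
        include_paper_overrides=True,
    )


def generate_scenario(ranges: GenerationRanges) -> ScenarioSpec:
    """Sample one validated scenario inside the given intervals.

    Deterministic under a fixed seed: parameters are visited in sorted
    path order with a generator seeded by ``ranges.seed``.
    """
    for path, (lo, hi) in ranges.ranges.items():
        if lo > hi:
            raise UsageError(f"empty interval for {path!r}: ({lo}, {hi})")
        if lo < 0:
            raise UsageError(f"interval for {path!r} extends below 0")
    base = _paper_fixture(ranges.model_kind)
    data = base.model_dump()
    if not ranges.include_paper_overrides:
        data["overrides"] = {}
    data["name"] = f"synthetic-{ranges.model_kind}-seed{ranges.seed}"

    rng = np.random.default_rng(ranges.seed)
    for path in sorted(ranges.ranges):
        lo, hi = ranges.ranges[path]
        if lo == hi:
            value = lo
        elif path == "herd.herd_size" and ranges.herd_log_uniform:
            value = float(np.exp(rng.uniform(np.log(lo), np.log(hi))))
        else:
            value = float(rng.uniform(lo, hi))
        node = data
        *parents, leaf = path.split(".")
        for part in parents:
            node = node[part]
        node[leaf] = value

    if ranges.model_kind == "EC":
        data["planting"]["straw_burn_fraction"] = 0.0
    elif "planting.straw_burn_fraction" not in ranges.ranges:
        feed = data["planting"]["straw_feed_fraction"]
        data["planting"]["straw_burn_fraction"] = max(STRAW_FATE_TOTAL - feed, 0.0)
    return ScenarioSpec.model_validate(data)


def generate_suite(
    n: int, ranges: GenerationRanges, seed: int, outdir: str | Path
) -> tuple[list[ScenarioSpec], Path]:
    """Write ``n`` scenario files plus a manifest; byte-reproducible.

    Per-scenario seeds are spawned deterministically from ``seed``; the
    manifest records the suite seed, the intervals and each file's seed.
    """
    if n < 1:
        raise UsageError("n must be >= 1")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    child_seeds = [int(s) for s in np.random.SeedSequence(seed).generate_state(n) % (2**31)]
    specs: list[ScenarioSpec] = []
    entries = []
    for i, child in enumerate(child_seeds):
        r = GenerationRanges(
            model_kind=ranges.model_kind,
            seed=child,
            ranges=ranges.ranges,
            herd_log_uniform=ranges.herd_log_uniform,
            include_paper_overrides=ranges.include_paper_overrides,
        )
        spec = generate_scenario(r)
        name = f"scenario_{i:03d}.yaml"
        save_scenario(spec, outdir / name)
        specs.append(spec)
        entries.append({"file": name, "seed": child})
    manifest = outdir / "manifest.json"
    manifest.write_text(
        json.dumps(
            {
                "suite_seed": seed,
                "n": n,
                "model_kind": ranges.model_kind,
                "herd_log_uniform": ranges.herd_log_uniform,
                "include_paper_overrides": ranges.include_paper_overrides,
                "ranges": {k: list(v) for k, v in sorted(ranges.ranges.items())},
                "scenarios": entries,
            },
            indent=2,
        )
    )
    return specs, manifest
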