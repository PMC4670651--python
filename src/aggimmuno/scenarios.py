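"""Named parameter presets and randomized grids for both simulators.

The preset catalogue is data, not code: each preset is a YAML file under
``aggimmuno/presets/`` holding only published parameter values or the
package's frozen defaults, so every scenario the models are exercised with
can be audited in one place.  Presets either describe a cross-linking
sweep grid (``kind: crosslink``) or a list of ADA scenarios sharing a
common base configuration (``kind: ada``).

:func:`random_grid` draws randomized cross-linking parameter sets inside
the physiological ranges (total drug 500--1e5 pM, aggregation fraction
2--15%, valency 10--100, Ka 1e-7--1e-3 pM^-1) for property-based testing.
"""

from __future__ import annotations

import importlib.resources as resources
from dataclasses import asdict
from typing import Any, Mapping

import numpy as np
import yaml

from .ada import (
    AdaScenario,
    CellularParams,
    Epitope,
    PkParams,
    Regimen,
    SubcellularParams,
)
from .crosslink import CrosslinkParams, initial_aggregate_conc

__all__ = [
    "PresetError",
    "list_presets",
    "load_preset_dict",
    "build_preset",
    "scenario_from_dict",
    "scenario_to_dict",
    "random_grid",
    "DEFAULT_RANGES",
]

# Physiological sampling windows for randomized cross-linking scenarios.
DEFAULT_RANGES: dict[str, tuple[float, float]] = {
    "ag_total_pM": (500.0, 1e5),  # 30 ug interferon-beta .. 40 mg mAb dose
    "p": (0.02, 0.15),  # aggregation fraction
    "n": (10, 100),  # valency
    "Ka": (1e-7, 1e-3),  # pM^-1
    "specific_fraction": (1e-6, 1e-2),
}


class PresetError(KeyError):
    """Unknown preset name or malformed preset file."""


def _preset_dir():
    return resources.files("aggimmuno") / "presets"


def list_presets() -> list[str]:
    """Names of all packaged presets."""
    return sorted(
        p.name.removesuffix(".yaml")
        for p in _preset_dir().iterdir()
        if p.name.endswith(".yaml")
    )


def load_preset_dict(name: str) -> dict:
    """Raw YAML contents of a preset."""
    path = _preset_dir() / f"{name}.yaml"
    try:
        text = path.read_text()
    except FileNotFoundError as exc:
        raise PresetError(
            f"unknown preset '{name}'; available: {', '.join(list_presets())}"
        ) from exc
    data = yaml.safe_load(text)
    if not isinstance(data, dict) or "kind" not in data:
        raise PresetError(f"preset '{name}' is malformed (missing 'kind')")
    return data


def _merge(base: Mapping[str, Any] | None, override: Mapping[str, Any] | None) -> dict:
    out: dict[str, Any] = dict(base or {})
    for key, val in (override or {}).items():
        if isinstance(val, Mapping) and isinstance(out.get(key), Mapping):
            out[key] = _merge(out[key], val)
        else:
            out[key] = val
    return out


def scenario_from_dict(cfg: Mapping[str, Any]) -> AdaScenario:
    """Build an :class:`AdaScenario` from a nested plain-dict config."""
    sub_cfg = dict(cfg.get("subcellular", {}))
    epitopes = tuple(
        Epitope(**e) for e in sub_cfg.pop("epitopes", [])
    ) or None
    sub_kwargs = sub_cfg if epitopes is None else {**sub_cfg, "epitopes": epitopes}
    return AdaScenario(
        name=cfg["name"],
        regimen=Regimen(**cfg.get("regimen", {"dose_mg": 40.0})),
        subcellular=SubcellularParams(**sub_kwargs),
        cellular=CellularParams(**cfg.get("cellular", {})),
        pk=PkParams(**cfg.get("pk", {})),
        t_end=cfg.get("t_end"),
        reference=cfg.get("reference"),
    )


def scenario_to_dict(scn: AdaScenario) -> dict:
    """Serialize a scenario to the same plain-dict form (round-trippable)."""
    out = {
        "name": scn.name,
        "regimen": asdict(scn.regimen),
        "subcellular": {
            **{k: v for k, v in asdict(scn.subcellular).items() if k != "epitopes"},
            "epitopes": [asdict(e) for e in scn.subcellular.epitopes],
        },
        "cellular": {
            **{k: v for k, v in asdict(scn.cellular).items() if k != "kd_ladder_pM"},
            "kd_ladder_pM": list(scn.cellular.kd_ladder_pM),
        },
        "pk": asdict(scn.pk),
    }
    if scn.t_end is not None:
        out["t_end"] = scn.t_end
    if scn.reference is not None:
        out["reference"] = scn.reference
    return out


def build_preset(name: str):
    """Expand a preset into runnable configurations.

    Returns a list of :class:`AdaScenario` for ``kind: ada`` presets (each
    non-reference scenario carries the preset's reference name) and a dict
    of :func:`aggimmuno.crosslink.sweep` keyword arguments for
    ``kind: crosslink`` presets.
    """
    data = load_preset_dict(name)
    kind = data["kind"]
    if kind == "crosslink":
        return dict(data["sweep"])
    if kind != "ada":
        raise PresetError(f"preset '{name}' has unsupported kind '{kind}'")

    shared = data.get("shared", {})
    scenarios: list[AdaScenario] = []
    if "dose_ladder_mg" in data:
        ref_condition = data.get("reference_condition")
        for dose in data["dose_ladder_mg"]:
            for cond in data["conditions"]:
                cfg = _merge(shared, cond)
                cfg = _merge(cfg, {"regimen": {"dose_mg": dose}})
                cfg["name"] = f"{cond['name']}@{dose:g}mg"
                if ref_condition and cond["name"] != ref_condition:
                    cfg["reference"] = f"{ref_condition}@{dose:g}mg"
                scenarios.append(scenario_from_dict(cfg))
        return scenarios

    ref_name = data.get("reference")
    for entry in data["scenarios"]:
        cfg = _merge(shared, entry)
        if ref_name and entry["name"] != ref_name:
            cfg.setdefault("reference", ref_name)
        scenarios.append(scenario_from_dict(cfg))
    return scenarios


def run_preset(name: str, dt_out: float = 0.1) -> dict:
    """Run every scenario of an ADA preset, resolving references in-preset.

    Returns a name -> :class:`aggimmuno.ada.AdaResult` mapping; scenarios
    that declare a reference get their cumulative-ADA fold change against
    it (each reference scenario is simulated once).
    """
    from .ada import AdaResult, run_scenario  # local: keep import cheap

    built = build_preset(name)
    if isinstance(built, dict):
        raise PresetError(f"preset '{name}' is a cross-linking preset")
    by_name = {s.name: s for s in built}
    results: dict[str, AdaResult] = {}

    def _run(scn_name: str) -> AdaResult:
        if scn_name in results:
            return results[scn_name]
        scn = by_name[scn_name]
        ref = None
        if scn.reference is not None:
            if scn.reference not in by_name:
                raise PresetError(
                    f"scenario '{scn_name}' references unknown scenario "
                    f"'{scn.reference}'"
                )
            ref = _run(scn.reference)
        results[scn_name] = run_scenario(scn, reference=ref, dt_out=dt_out)
        return results[scn_name]

    for s in built:
        _run(s.name)
    return results


def random_grid(
    seed: int,
    n_scenarios: int = 20,
    ranges: Mapping[str, tuple[float, float]] | None = None,
) -> list[dict]:
    """Randomized cross-linking parameter sets inside physiological bounds.

    Concentrations, Ka and the antigen-specific fraction are sampled
    log-uniformly; the aggregation fraction uniformly; valency as a uniform
    integer.  Reproducible given ``seed``.  Each entry carries the raw
    draws plus the derived initial aggregate concentration and a ready
    :class:`CrosslinkParams`.
    """
    rng = np.random.default_rng(seed)
    eff = dict(DEFAULT_RANGES)
    for key, bounds in (ranges or {}).items():
        if key not in eff:
            raise PresetError(f"unknown range key '{key}'")
        lo, hi = bounds
        if not lo < hi:
            raise PresetError(f"empty range for '{key}': {bounds}")
        eff[key] = (lo, hi)

    out: list[dict] = []
    for _ in range(n_scenarios):
        ag = float(np.exp(rng.uniform(*np.log(eff["ag_total_pM"]))))
        p = float(rng.uniform(*eff["p"]))
        n = int(rng.integers(eff["n"][0], eff["n"][1] + 1))
        ka = float(np.exp(rng.uniform(*np.log(eff["Ka"]))))
        frac = float(np.exp(rng.uniform(*np.log(eff["specific_fraction"]))))
        aga0 = initial_aggregate_conc(ag, p, n)
        out.append({
            "ag_total_pM": ag,
            "p": p,
            "n": n,
            "Ka": ka,
            "specific_fraction": frac,
            "Aga0": aga0,
            "params": CrosslinkParams.from_fraction(
                n=n, Ka=ka, Aga0=aga0, specific_fraction=frac
            ),
        })
    return out
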