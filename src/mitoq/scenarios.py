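"""Named, reproducible scenario presets.

Every simulation experiment the model was designed for is registered here
as a preset built from the reference parameter set (the estimated
starting probabilities and lifetimes of the five processes) with
documented overrides: single-process runs, the networking/recycling
interplay, aging vs non-aging cells, stable repair, stressed cells,
high-energy-demand (hec) cells and their networking/recycling rescue
strategies, and doubled-parameter robustness variants.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Dict, Mapping, Optional, Tuple

from .core import LONG_LIFETIME, Direction, ModelParameters, ProcessTimeLaw
from .integrator import PROCESS_NAMES, SimulationConfig
from . import io as _io

__all__ = [
    "ScenarioSpec",
    "reference_parameters",
    "build_scenario",
    "scenario_names",
    "apply_overrides",
]

#: Reference values of the free parameters.  Networking (fission/fusion)
#: is about five times more frequent than the other processes; all other
#: starting probabilities are equal (principle of indifference), and every
#: lifetime is 50000 tu.
_REFERENCE = dict(
    gamma=1.0,
    ff1=2.0,
    ff2=3.0,
    f_rd=0.03,
    rho0_ffm=0.05,
    tau_ffm=50_000.0,
    rho0_ffp=0.05,
    tau_ffp=50_000.0,
    rho0_mb=0.01,
    tau_mb=50_000.0,
    rho0_rep=0.01,
    tau_rep=50_000.0,
    rho0_ec=0.01,
    tau_ec=50_000.0,
    rho0_ed=0.01,
    tau_ed=50_000.0,
)


def reference_parameters(cap_ffp_fission: bool = False, **overrides: float) -> ModelParameters:
    """The reference :class:`ModelParameters`, with optional flat overrides.

    Accepted override keys are the flat names in ``_REFERENCE`` (e.g.
    ``rho0_ec=0.05`` or ``tau_rep=5e8``).  The proteinaceous fusion and
    fission laws share ``rho0_ffp``/``tau_ffp`` and run in opposite
    directions (fusion decays, fission grows with age).
    ``cap_ffp_fission`` lets the growing fission law saturate at 1 --
    needed only for strongly boosted networking variants whose law would
    otherwise leave [0, 1] inside the 100000 tu horizon.
    """
    vals = dict(_REFERENCE)
    unknown = set(overrides) - set(vals)
    if unknown:
        raise ValueError(f"unknown parameter override(s): {sorted(unknown)}")
    vals.update(overrides)
    return ModelParameters(
        gamma=vals["gamma"],
        ff1=vals["ff1"],
        ff2=vals["ff2"],
        f_rd=vals["f_rd"],
        law_ffm=ProcessTimeLaw(vals["rho0_ffm"], vals["tau_ffm"], Direction.DECAY),
        law_ffp_fusion=ProcessTimeLaw(vals["rho0_ffp"], vals["tau_ffp"], Direction.DECAY),
        law_ffp_fission=ProcessTimeLaw(
            vals["rho0_ffp"], vals["tau_ffp"], Direction.GROWTH, cap=cap_ffp_fission
        ),
        law_mb=ProcessTimeLaw(vals["rho0_mb"], vals["tau_mb"], Direction.GROWTH),
        law_rep=ProcessTimeLaw(vals["rho0_rep"], vals["tau_rep"], Direction.DECAY),
        law_ec=ProcessTimeLaw(vals["rho0_ec"], vals["tau_ec"], Direction.GROWTH),
        law_ed=ProcessTimeLaw(vals["rho0_ed"], vals["tau_ed"], Direction.GROWTH),
    )


@dataclass(frozen=True)
class ScenarioSpec:
    """A named, fully resolved simulation setup."""

    name: str
    description: str
    config: SimulationConfig


def _cfg(enabled: Tuple[str, ...], n_steps: int, params: ModelParameters) -> SimulationConfig:
    return SimulationConfig(params=params, enabled=enabled, n_steps=n_steps)


_NETWORKING = ("ff_metabolic", "ff_protein")
_STABLE_ALL = {k: LONG_LIFETIME for k in _REFERENCE if k.startswith("tau_")}

# name -> (description, config factory)
_REGISTRY: Dict[str, Tuple[str, Callable[[], SimulationConfig]]] = {
    "single_ff": (
        "Fission/fusion only (metabolic + proteinaceous), 30000 tu",
        lambda: _cfg(_NETWORKING, 30_000, reference_parameters()),
    ),
    "ff_metabolic_only": (
        "Metabolic (kiss-and-run) fission/fusion only, 30000 tu",
        lambda: _cfg(("ff_metabolic",), 30_000, reference_parameters()),
    ),
    "ff_protein_only": (
        "Proteinaceous (inner-membrane) fission/fusion only, 30000 tu",
        lambda: _cfg(("ff_protein",), 30_000, reference_parameters()),
    ),
    "single_mb": (
        "Mitophagy/biogenesis recycling only, 30000 tu",
        lambda: _cfg(("mb",), 30_000, reference_parameters()),
    ),
    "single_repair": (
        "Binomial repair only, 30000 tu",
        lambda: _cfg(("repair",), 30_000, reference_parameters()),
    ),
    "single_ec": (
        "Energy consumption (internal ROS damage) only, 30000 tu",
        lambda: _cfg(("ec",), 30_000, reference_parameters()),
    ),
    "single_ed": (
        "Stochastic external damage only, 30000 tu",
        lambda: _cfg(("ed",), 30_000, reference_parameters()),
    ),
    "interplay": (
        "Networking plus recycling, other processes absent, 30000 tu",
        lambda: _cfg(_NETWORKING + ("mb",), 30_000, reference_parameters()),
    ),
    "aging": (
        "All five processes at reference values over 100000 tu",
        lambda: _cfg(PROCESS_NAMES, 100_000, reference_parameters()),
    ),
    "non_aging": (
        "All processes frozen in time (every lifetime 5e8 tu)",
        lambda: _cfg(PROCESS_NAMES, 100_000, reference_parameters(**_STABLE_ALL)),
    ),
    "stable_repair": (
        "Aging cell with a time-stable repair mechanism (tau_rep = 5e8 tu)",
        lambda: _cfg(PROCESS_NAMES, 100_000, reference_parameters(tau_rep=LONG_LIFETIME)),
    ),
    "stressed": (
        "Stressed cell: rho0_ec = 0.05, rho0_ed = 0.1, f_rd = 0.3",
        lambda: _cfg(
            PROCESS_NAMES,
            100_000,
            reference_parameters(rho0_ec=0.05, rho0_ed=0.1, f_rd=0.3),
        ),
    ),
    "stressed_stable_ec": (
        "Stressed cell with time-stabilised energy consumption",
        lambda: _cfg(
            PROCESS_NAMES,
            100_000,
            reference_parameters(rho0_ec=0.05, rho0_ed=0.1, f_rd=0.3, tau_ec=LONG_LIFETIME),
        ),
    ),
    "stressed_stable_ed": (
        "Stressed cell with time-stabilised external damage",
        lambda: _cfg(
            PROCESS_NAMES,
            100_000,
            reference_parameters(rho0_ec=0.05, rho0_ed=0.1, f_rd=0.3, tau_ed=LONG_LIFETIME),
        ),
    ),
    "stressed_stable_both": (
        "Stressed cell with both damage processes time-stabilised",
        lambda: _cfg(
            PROCESS_NAMES,
            100_000,
            reference_parameters(
                rho0_ec=0.05, rho0_ed=0.1, f_rd=0.3,
                tau_ec=LONG_LIFETIME, tau_ed=LONG_LIFETIME,
            ),
        ),
    ),
    "hec": (
        "High-energy-demand cell: rho0_ec raised to 0.05",
        lambda: _cfg(PROCESS_NAMES, 100_000, reference_parameters(rho0_ec=0.05)),
    ),
    "hec_net_boost": (
        "hec with networking starting probabilities raised to 0.5",
        lambda: _cfg(
            PROCESS_NAMES, 100_000,
            reference_parameters(rho0_ec=0.05, rho0_ffm=0.5, rho0_ffp=0.5,
                                 cap_ffp_fission=True),
        ),
    ),
    "hec_net_stable": (
        "hec with time-stabilised networking (tau_FF = 5e8 tu)",
        lambda: _cfg(
            PROCESS_NAMES, 100_000,
            reference_parameters(rho0_ec=0.05, tau_ffm=LONG_LIFETIME, tau_ffp=LONG_LIFETIME),
        ),
    ),
    "hec_net_boost_stable": (
        "hec with boosted and time-stabilised networking",
        lambda: _cfg(
            PROCESS_NAMES, 100_000,
            reference_parameters(
                rho0_ec=0.05, rho0_ffm=0.5, rho0_ffp=0.5,
                tau_ffm=LONG_LIFETIME, tau_ffp=LONG_LIFETIME,
            ),
        ),
    ),
    "hec_rec_boost": (
        "hec with recycling starting probability raised to 0.05",
        lambda: _cfg(PROCESS_NAMES, 100_000, reference_parameters(rho0_ec=0.05, rho0_mb=0.05)),
    ),
    "hec_rec_stable": (
        "hec with time-stabilised recycling (tau_mb = 5e8 tu)",
        lambda: _cfg(
            PROCESS_NAMES, 100_000,
            reference_parameters(rho0_ec=0.05, tau_mb=LONG_LIFETIME),
        ),
    ),
    "hec_rec_boost_stable": (
        "hec with boosted and time-stabilised recycling",
        lambda: _cfg(
            PROCESS_NAMES, 100_000,
            reference_parameters(rho0_ec=0.05, rho0_mb=0.05, tau_mb=LONG_LIFETIME),
        ),
    ),
    "hec_all_boost": (
        "hec with boosted networking and recycling probabilities",
        lambda: _cfg(
            PROCESS_NAMES, 100_000,
            reference_parameters(rho0_ec=0.05, rho0_ffm=0.5, rho0_ffp=0.5, rho0_mb=0.05,
                                 cap_ffp_fission=True),
        ),
    ),
    "hec_all_boost_stable": (
        "hec with boosted + stabilised networking and recycling",
        lambda: _cfg(
            PROCESS_NAMES, 100_000,
            reference_parameters(
                rho0_ec=0.05, rho0_ffm=0.5, rho0_ffp=0.5, rho0_mb=0.05,
                tau_ffm=LONG_LIFETIME, tau_ffp=LONG_LIFETIME, tau_mb=LONG_LIFETIME,
            ),
        ),
    ),
    "hec_best_strategy": (
        "hec rescue: boosted networking + recycling, networking stabilised",
        lambda: _cfg(
            PROCESS_NAMES, 100_000,
            reference_parameters(
                rho0_ec=0.05, rho0_ffm=0.5, rho0_ffp=0.5, rho0_mb=0.05,
                tau_ffm=LONG_LIFETIME, tau_ffp=LONG_LIFETIME,
            ),
        ),
    ),
    "s1_interplay_net": (
        "Interplay with doubled networking parameters (rho0_FF 0.1, tau_FF 100000)",
        lambda: _cfg(
            _NETWORKING + ("mb",), 30_000,
            reference_parameters(rho0_ffm=0.1, rho0_ffp=0.1, tau_ffm=100_000.0, tau_ffp=100_000.0),
        ),
    ),
    "s1_interplay_rec": (
        "Interplay with doubled recycling parameters (rho0_mb 0.02, tau_mb 100000)",
        lambda: _cfg(
            _NETWORKING + ("mb",), 30_000,
            reference_parameters(rho0_mb=0.02, tau_mb=100_000.0),
        ),
    ),
    "s1_stable_repair": (
        "Stable repair with doubled repair probability (rho0_rep 0.02)",
        lambda: _cfg(
            PROCESS_NAMES, 100_000,
            reference_parameters(rho0_rep=0.02, tau_rep=LONG_LIFETIME),
        ),
    ),
    "aging_doubled": (
        "Aging with every starting probability and lifetime doubled",
        lambda: _cfg(
            PROCESS_NAMES, 100_000,
            reference_parameters(
                rho0_ffm=0.1, rho0_ffp=0.1, rho0_mb=0.02, rho0_rep=0.02,
                rho0_ec=0.02, rho0_ed=0.02, f_rd=0.03,
                tau_ffm=100_000.0, tau_ffp=100_000.0, tau_mb=100_000.0,
                tau_rep=100_000.0, tau_ec=100_000.0, tau_ed=100_000.0,
            ),
        ),
    ),
}


def scenario_names() -> Tuple[str, ...]:
    """All registered preset names."""
    return tuple(_REGISTRY)


def scenario_description(name: str) -> str:
    return _REGISTRY[name][0]


def apply_overrides(config: SimulationConfig, overrides: Mapping[str, object]) -> SimulationConfig:
    """Apply dotted-key overrides (e.g. ``{"Q": 4, "params.laws.ec.rho0": 0.05}``)."""
    tree = _io.config_to_dict(config)
    for key, value in overrides.items():
        node = tree
        parts = str(key).split(".")
        for part in parts[:-1]:
            if part not in node or not isinstance(node[part], dict):
                raise KeyError(f"unknown config path {key!r}")
            node = node[part]
        if parts[-1] not in node:
            raise KeyError(f"unknown config field {key!r}")
        node[parts[-1]] = value
    return _io.config_from_dict(tree)


def build_scenario(name: str, overrides: Optional[Mapping[str, object]] = None) -> ScenarioSpec:
    """Construct a registered scenario preset, optionally with overrides.

    Raises
    ------
    KeyError
        If ``name`` is not a registered preset.
    """
    if name not in _REGISTRY:
        raise KeyError(
            f"unknown scenario {name!r}; available: {', '.join(_REGISTRY)}"
        )
    description, factory = _REGISTRY[name]
    config = factory()
    if overrides:
        config = apply_overrides(config, overrides)
    return ScenarioSpec(name=name, description=description, config=config)
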