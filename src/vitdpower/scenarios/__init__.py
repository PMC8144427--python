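"""Bundled scenario configurations.

``table1``: the 1-year fixed-dose experiment grid (baselines 15..75
nmol/L, dose equivalents 10/20/40 nmol/L, risk ceilings u = 2 and 4,
n = 100..1500 per arm).  ``summer_trial`` / ``winter_trial``: the 6-month
start-date experiments (May-October vs November-April, u = 2).
``rcct_demo``: a concentration-controlled design.
"""

from importlib import resources
from pathlib import Path

__all__ = ["available_scenarios", "scenario_path", "load_scenario"]


def available_scenarios() -> list[str]:
    return sorted(
        p.stem for p in resources.files(__name__).iterdir() if p.name.endswith(".yaml")
    )


def scenario_path(name: str) -> Path:
    path = resources.files(__name__) / f"{name}.yaml"
    if not path.is_file():
        raise KeyError(f"unknown scenario {name!r}; available: {available_scenarios()}")
    return Path(str(path))


def load_scenario(name: str):
    from ..config import load_config

    return load_config(scenario_path(name))
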