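"""Shared helpers for the numbered analysis drivers."""

from pathlib import Path

from fvgap.synthetic_world import WorldConfig, WorldPanel, generate_world

RESULTS = Path(__file__).resolve().parent.parent / "results"
WORLD_DIR = RESULTS / "world"

#: The study world: 20 countries in 7 regions, 4 F&V commodities, 1961-2050.
STUDY_CONFIG = WorldConfig(seed=7)


def get_world() -> WorldPanel:
    """Load the study world from results/world, generating it if absent."""
    if (WORLD_DIR / "world_manifest.json").exists():
        return WorldPanel.from_csv(WORLD_DIR)
    world = generate_world(STUDY_CONFIG)
    world.to_csv(WORLD_DIR)
    return world
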