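import pytest

from gcweld.assembly import assemble_circle, plan_vector, release_fragments
from gcweld.fixtures import KIT_CORE_DEVICES, generate_kit

KIT_SEED = 1


@pytest.fixture(scope="session")
def kit():
    """The seeded synthetic catalog: 8 devices, donors, parts DB."""
    return generate_kit(KIT_SEED)


@pytest.fixture(scope="session")
def core_devices(kit):
    """The 4-device self-replicating set (1 ZraI replicon + 3 EcoRV devices)."""
    return [kit.devices[i] for i in KIT_CORE_DEVICES]


@pytest.fixture(scope="session")
def core_plan(core_devices):
    return plan_vector("self_replicating_strain_specific", core_devices, plan_id="core")


@pytest.fixture(scope="session")
def core_fragments(core_plan, kit):
    return release_fragments(core_plan, kit)


@pytest.fixture(scope="session")
def core_assembly(core_fragments, core_plan):
    return assemble_circle(core_fragments, plan=core_plan)
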