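"""Shared builders for synthetic D-value systems used as solver oracles."""

from qwasi.core import Volumes, ZValueSet
from qwasi.transfer import DValueSet

_D_FIELDS = (
    "d12d", "d12p", "d12w", "d12r", "d21d", "d24d", "d24s", "d42d", "d42r",
    "d10m", "d20m", "d40m", "d10t", "d20t", "d23h",
)


def unit_z() -> ZValueSet:
    return ZValueSet(1.0, 1.0, 1.0, 1.0, 1.0, 1.0, 1.0, 1.0)


def unit_volumes() -> Volumes:
    return Volumes(1.0, 1.0, 1.0, 0.0, 0.0, 0.0, 1.0)


def random_d_values(rng) -> DValueSet:
    """A random positive system with rates stable under a 1-hour RK4 step."""
    values = {name: float(rng.uniform(0.02, 0.2)) for name in _D_FIELDS}
    values["t01t"] = float(rng.uniform(0.1, 1.0))
    values["t02t"] = float(rng.uniform(0.1, 1.0))
    return DValueSet(**values)
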